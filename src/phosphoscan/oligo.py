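"""Mutagenic oligo tiling and overlap-extension assembly products.

The library is built by annealing and extending a pool of overlapping
mutagenic oligonucleotides that together span the mutated region.  Each tile
(oligo) exists in several variants — one per state combination of the
phosphosites it covers — and consecutive tiles share a constant overlap
window so that any variant of one tile anneals to any variant of the next.
The combinatorial product of per-tile variants is therefore the full
genotype library.

Tiles are modeled at the sense-strand level: the alternating-strand
anneal/extend chemistry reduces, combinatorially, to merging sequences on
exact overlap matches, which is what :func:`enumerate_assembly_products`
does.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .scheme import LibrarySpec, PhosphositeScheme, genotype_from_dna, genotype_to_dna

__all__ = ["TilePlan", "AssemblyResult", "TilingError", "tile_region",
           "enumerate_assembly_products"]


class TilingError(ValueError):
    """Raised when no tiling satisfies the overlap/site constraints."""


@dataclass(frozen=True)
class TilePlan:
    """A tiling of the region into overlapping oligos with variant sets.

    ``tiles`` are 1-based inclusive ``(start, end)`` coordinates on the
    region DNA.  ``tile_sites`` lists, per tile, the indices (into the
    scheme's site tuple) of the phosphosites whose codons lie inside that
    tile and outside every overlap window.  ``variants`` maps, per tile,
    a per-covered-site state string to the tile's DNA sequence.
    """

    region_dna: str
    scheme: PhosphositeScheme
    tiles: tuple[tuple[int, int], ...]
    tile_sites: tuple[tuple[int, ...], ...]
    variants: tuple[dict[str, str], ...] = field(repr=False)

    @property
    def n_tiles(self) -> int:
        return len(self.tiles)

    @property
    def overlaps(self) -> tuple[int, ...]:
        """Overlap length between each pair of consecutive tiles."""
        return tuple(
            self.tiles[i][1] - self.tiles[i + 1][0] + 1
            for i in range(self.n_tiles - 1)
        )

    @property
    def variant_counts(self) -> tuple[int, ...]:
        return tuple(len(v) for v in self.variants)


def _site_spans(scheme: PhosphositeScheme) -> list[tuple[int, int]]:
    """1-based inclusive bp span of each site's two codons on the region."""
    spans = []
    for site in scheme.sites:
        start = 3 * scheme.site_offset(site) + 1
        spans.append((start, start + 5))
    return spans


def tile_region(
    region_dna: str,
    spec: LibrarySpec,
    n_tiles: int,
    overlap_range: tuple[int, int] = (21, 27),
) -> TilePlan:
    """Tile the region into ``n_tiles`` overlapping oligos.

    Constraints: consecutive overlaps lie in ``overlap_range``; the tiles
    cover the region exactly; no phosphosite codon pair intersects an
    overlap window (so every site is interior to exactly one tile, and the
    overlap sequence is identical across all variants of adjacent tiles).

    The solver is a deterministic depth-first search placing each cut point
    leftmost-feasible at maximal overlap, so a given input always yields the
    same plan.  Raises :class:`TilingError` when the constraints cannot be
    met, naming the obstructing site when one can be identified.
    """
    scheme = spec.scheme
    omin, omax = overlap_range
    if not (0 < omin <= omax):
        raise TilingError("overlap range must satisfy 0 < min <= max")
    length = len(region_dna)
    if length != 3 * scheme.region_length:
        raise TilingError(
            f"region DNA length {length} does not match scheme span "
            f"({3 * scheme.region_length} bp)"
        )
    if n_tiles < 1:
        raise TilingError("need at least one tile")
    if n_tiles == 1:
        return _build_plan(region_dna, spec, [(1, length)])

    spans = _site_spans(scheme)

    def window_clear(lo: int, hi: int) -> bool:
        return all(e < lo or s > hi for s, e in spans)

    # DFS over tile end positions. State: (tile index, start of current tile).
    # A tile must be long enough to hold its flanking overlaps disjointly.
    dead: set[tuple[int, int]] = set()

    def solve(i: int, start: int, prev_ov: int) -> list[tuple[int, int]] | None:
        if (i, start) in dead:
            return None
        remaining = n_tiles - i  # tiles still to place, including this one
        if remaining == 1:
            if length - start + 1 >= prev_ov + 1:
                return [(start, length)]
            return None
        min_end = start + prev_ov + omin - 1  # keep flanking windows disjoint
        for end in range(min_end, length):
            # prune: remaining tiles must be able to reach the region end
            if end - (remaining - 1) * (omax - 1) > length:
                break
            for ov in range(omax, omin - 1, -1):
                win_lo = end - ov + 1
                if win_lo <= start + prev_ov:
                    continue
                if not window_clear(win_lo, end):
                    continue
                rest = solve(i + 1, win_lo, ov)
                if rest is not None:
                    return [(start, end)] + rest
        dead.add((i, start))
        return None

    tiles = solve(0, 1, 0)
    if tiles is None:
        blocked = _diagnose_blocked_site(scheme, spans, length, n_tiles, omin)
        raise TilingError(
            f"no {n_tiles}-tile plan with overlaps in {overlap_range} exists"
            + (f" (site {blocked} obstructs every cut point)" if blocked else "")
        )
    return _build_plan(region_dna, spec, tiles)


def _diagnose_blocked_site(scheme, spans, length, n_tiles, omin) -> str | None:
    # Heuristic: a site whose span leaves less than one overlap of clearance
    # to a region end is a likely obstruction.
    for site, (s, e) in zip(scheme.sites, spans):
        if s <= omin or e > length - omin:
            return site.label
    return None


def _build_plan(
    region_dna: str, spec: LibrarySpec, tiles: list[tuple[int, int]]
) -> TilePlan:
    scheme = spec.scheme
    spans = _site_spans(scheme)
    tile_sites: list[tuple[int, ...]] = []
    variants: list[dict[str, str]] = []
    assigned: set[int] = set()
    for start, end in tiles:
        covered = tuple(
            k
            for k, (s, e) in enumerate(spans)
            if s >= start and e <= end and k not in assigned
        )
        assigned.update(covered)
        tile_sites.append(covered)
        tile_variants: dict[str, str] = {}
        alphabets = [sorted(spec.allowed_states[k]) for k in covered]
        for combo in itertools.product(*alphabets):
            full = ["W"] * scheme.n_sites
            for k, state in zip(covered, combo):
                full[k] = state
            mutated = genotype_to_dna(region_dna, scheme, "".join(full))
            tile_variants["".join(combo)] = mutated[start - 1 : end]
        variants.append(tile_variants)
    if assigned != set(range(scheme.n_sites)):
        missing = [scheme.sites[k].label
                   for k in range(scheme.n_sites) if k not in assigned]
        raise TilingError(f"sites not covered by any tile: {missing}")
    return TilePlan(
        region_dna=region_dna,
        scheme=scheme,
        tiles=tuple(tiles),
        tile_sites=tuple(tile_sites),
        variants=tuple(variants),
    )


@dataclass
class AssemblyResult:
    """Products of overlap-extension assembly over a tile plan.

    ``products`` maps genotype -> assembled region DNA; combinations whose
    chosen variants disagree inside an overlap window cannot anneal and are
    excluded, tallied in ``n_impossible``.
    """

    products: dict[str, str]
    n_impossible: int


def enumerate_assembly_products(plan: TilePlan) -> AssemblyResult:
    """Enumerate every assembly: one variant per tile, merged on overlaps.

    For an intact plan the product count is the product of per-tile variant
    counts (e.g. 2·2·4·4·2·4 = 256 for a 6-tile A/E plan) and the genotypes
    recovered from the assembled DNA reproduce the enumerated library.
    """
    overlaps = plan.overlaps
    products: dict[str, str] = {}
    n_impossible = 0
    for choice in itertools.product(*(v.items() for v in plan.variants)):
        seqs = [seq for _, seq in choice]
        assembled = seqs[0]
        ok = True
        for i in range(1, len(seqs)):
            ov = overlaps[i - 1]
            if assembled[-ov:] != seqs[i][:ov]:
                ok = False
                break
            assembled += seqs[i][ov:]
        if not ok:
            n_impossible += 1
            continue
        genotype = genotype_from_dna(assembled, plan.region_dna, plan.scheme)
        products[genotype] = assembled
    return AssemblyResult(products=products, n_impossible=n_impossible)
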