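"""Phosphosite schemes, genotype encoding, and library enumeration.

A *phosphosite scheme* lists the mutable CDK consensus sites (S/T-P motifs)
inside a contiguous protein region, together with the DNA codon replacements
used to realize each mutant state.  A *genotype* is a fixed-length string over
the per-site state alphabet:

``W``
    wild type — the S/T-P motif is retained.
``A``
    unphosphorylatable — the phosphoacceptor is replaced by alanine (A-P),
    blocking phosphorylation while keeping the proline.
``E``
    phosphomimetic — the motif is replaced by two glutamates (E-E), mimicking
    the negative charge of the phosphorylated residue.

Genotype strings run N- to C-terminal, so ``"AAAEEAAA"`` in an 8-site scheme
means phosphomimetic substitutions at sites 4 and 5 and alanine elsewhere.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio.Seq import Seq

__all__ = [
    "Site",
    "PhosphositeScheme",
    "LibrarySpec",
    "SchemeError",
    "ReferenceMismatchError",
    "STATES",
    "enumerate_library",
    "apply_genotype",
    "genotype_to_dna",
    "genotype_from_dna",
    "translate",
    "count_state",
]

#: Full per-site state alphabet; individual libraries restrict it per site.
STATES = ("A", "E", "W")

#: Default two-codon replacements for the (phosphoacceptor, proline) codon
#: pair.  ``W`` is absent on purpose: wild type keeps the original codons.
#: Codons are chosen so that any two states' six-base blocks differ at >= 2
#: positions (also versus the common S/T-P wild-type codons): a single
#: sequencing error can then never convert one allele's sequence window
#: into another's, which is what makes exact-match counting robust.
DEFAULT_CODON_MAP: dict[str, tuple[str, str]] = {
    "A": ("GCA", "CCT"),
    "E": ("GAA", "GAA"),
}


class SchemeError(ValueError):
    """Raised for an internally inconsistent scheme or library spec."""


class ReferenceMismatchError(ValueError):
    """Raised when a reference sequence disagrees with the scheme at a site."""


@dataclass(frozen=True)
class Site:
    """One mutable phosphosite: an S/T phosphoacceptor followed by a proline."""

    label: str
    position: int  # 1-based protein residue index of the phosphoacceptor
    wt_residue: str  # "S" or "T"

    def __post_init__(self) -> None:
        if self.wt_residue not in ("S", "T"):
            raise SchemeError(
                f"site {self.label}: wild-type residue must be S or T, "
                f"got {self.wt_residue!r}"
            )
        if self.position < 1:
            raise SchemeError(f"site {self.label}: position must be >= 1")


@dataclass(frozen=True)
class PhosphositeScheme:
    """The mutable sites of one scanned region.

    Parameters
    ----------
    sites
        Sites in N->C order; positions must be strictly increasing.
    region_span
        ``(first, last)`` 1-based residue numbers of the mutated region.
        Every site's phosphoacceptor *and* its following proline must fall
        inside the span (each site occupies exactly two codons).
    codon_map
        Per-state two-codon DNA replacement for the (S/T, P) codon pair.
    """

    sites: tuple[Site, ...]
    region_span: tuple[int, int]
    codon_map: Mapping[str, tuple[str, str]] = field(
        default_factory=lambda: dict(DEFAULT_CODON_MAP)
    )

    def __post_init__(self) -> None:
        object.__setattr__(self, "sites", tuple(self.sites))
        first, last = self.region_span
        if first > last:
            raise SchemeError("region_span first residue exceeds last")
        positions = [s.position for s in self.sites]
        if any(b <= a for a, b in zip(positions, positions[1:])):
            raise SchemeError("site positions must be strictly increasing")
        labels = [s.label for s in self.sites]
        if len(set(labels)) != len(labels):
            raise SchemeError("site labels must be unique")
        for s in self.sites:
            if not (first <= s.position and s.position + 1 <= last):
                raise SchemeError(
                    f"site {s.label} (residues {s.position}-{s.position + 1}) "
                    f"falls outside region span {self.region_span}"
                )
        for state, codons in self.codon_map.items():
            if len(codons) != 2 or any(len(c) != 3 for c in codons):
                raise SchemeError(f"codon_map[{state!r}] must be two codons")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def region_length(self) -> int:
        """Region length in residues."""
        return self.region_span[1] - self.region_span[0] + 1

    def site_offset(self, site: Site) -> int:
        """0-based residue offset of a site's phosphoacceptor in the region."""
        return site.position - self.region_span[0]

    def check_genotype(self, genotype: str, allowed: Sequence[str] | None = None) -> None:
        """Validate a genotype string against this scheme.

        ``allowed`` optionally restricts the per-site alphabet (one string of
        allowed states per site, as in :class:`LibrarySpec`).
        """
        if len(genotype) != self.n_sites:
            raise SchemeError(
                f"genotype {genotype!r} has {len(genotype)} states; "
                f"scheme has {self.n_sites} sites"
            )
        for k, state in enumerate(genotype):
            site_allowed = STATES if allowed is None else allowed[k]
            if state not in site_allowed:
                raise SchemeError(
                    f"genotype {genotype!r}: state {state!r} at site "
                    f"{self.sites[k].label} not in allowed set {site_allowed}"
                )


@dataclass(frozen=True)
class LibrarySpec:
    """A combinatorial library: per-site allowed states plus a reference allele.

    ``allowed_states`` is one string per site, e.g. ``("AE",) * 8`` for the
    A/E library or ``("WA",) * 8`` for WT/A.  ``fixed_background`` records
    invariant mutations outside the scanned region (e.g. ``"3N"`` for the
    stabilized-phosphodegron background); it does not change enumeration, only
    bookkeeping and the meaning of the reference allele.

    The reference genotype need not be an enumerated member: in the A/E
    screen the wild-type (all-W) allele is carried as a spike-in alongside
    the 256 A/E combinations.  The competed pool is
    :func:`pool_genotypes` = enumerated members plus the reference.
    """

    scheme: PhosphositeScheme
    allowed_states: tuple[str, ...]
    reference_genotype: str
    fixed_background: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "allowed_states", tuple(self.allowed_states))
        if len(self.allowed_states) != self.scheme.n_sites:
            raise SchemeError(
                "allowed_states must give one state set per scheme site"
            )
        for k, states in enumerate(self.allowed_states):
            if not states:
                raise SchemeError(
                    f"site {self.scheme.sites[k].label}: empty allowed state set"
                )
            bad = set(states) - set(STATES)
            if bad:
                raise SchemeError(f"unknown states {bad} at site index {k}")
            if len(set(states)) != len(states):
                raise SchemeError(f"duplicate states at site index {k}")
        self.scheme.check_genotype(self.reference_genotype)

    @property
    def size(self) -> int:
        """Number of enumerated members (the reference spike-in excluded)."""
        size = 1
        for states in self.allowed_states:
            size *= len(states)
        return size

    @property
    def reference_is_member(self) -> bool:
        return all(
            s in allowed
            for s, allowed in zip(self.reference_genotype, self.allowed_states)
        )

    def pool_genotypes(self) -> list[str]:
        """Genotypes in the competed pool: the library plus the reference."""
        members = enumerate_library(self)
        if not self.reference_is_member:
            members.append(self.reference_genotype)
        return members


def uniform_library(
    scheme: PhosphositeScheme,
    states: str,
    reference_genotype: str,
    fixed_background: str | None = None,
) -> LibrarySpec:
    """Library with the same allowed state set at every site (A/E, WT/A, WT/E)."""
    return LibrarySpec(
        scheme=scheme,
        allowed_states=(states,) * scheme.n_sites,
        reference_genotype=reference_genotype,
        fixed_background=fixed_background,
    )


def enumerate_library(spec: LibrarySpec) -> list[str]:
    """All genotypes of the library, lexicographically ordered.

    The result is the Cartesian product of the per-site allowed states: for
    the 8-site A/E library this is the full set of 256 combinations.
    """
    alphabets = [sorted(states) for states in spec.allowed_states]
    return ["".join(combo) for combo in itertools.product(*alphabets)]


def count_state(genotype: str, state: str) -> int:
    """Number of sites carrying ``state`` (e.g. phosphomimetic count)."""
    return genotype.count(state)


def _check_region_protein(
    region_protein: str, scheme: PhosphositeScheme
) -> None:
    if len(region_protein) != scheme.region_length:
        raise SchemeError(
            f"region protein length {len(region_protein)} does not match "
            f"region span {scheme.region_span} ({scheme.region_length} residues)"
        )
    for site in scheme.sites:
        off = scheme.site_offset(site)
        if region_protein[off] != site.wt_residue:
            raise ReferenceMismatchError(
                f"site {site.label}: expected {site.wt_residue} at residue "
                f"{site.position}, found {region_protein[off]!r}"
            )
        if region_protein[off + 1] != "P":
            raise ReferenceMismatchError(
                f"site {site.label}: expected P at residue {site.position + 1}, "
                f"found {region_protein[off + 1]!r}"
            )


#: Amino acids the mutant states write at the (phosphoacceptor, +1) pair.
_STATE_RESIDUES = {"A": ("A", "P"), "E": ("E", "E")}


def apply_genotype(
    region_protein: str, scheme: PhosphositeScheme, genotype: str
) -> str:
    """Realize a genotype at the protein level.

    ``W`` leaves the S/T-P motif intact, ``A`` writes A-P, ``E`` writes E-E;
    every other residue is returned unchanged.
    """
    scheme.check_genotype(genotype)
    _check_region_protein(region_protein, scheme)
    out = list(region_protein)
    for site, state in zip(scheme.sites, genotype):
        if state == "W":
            continue
        off = scheme.site_offset(site)
        out[off], out[off + 1] = _STATE_RESIDUES[state]
    return "".join(out)


def translate(dna: str) -> str:
    """Translate an in-frame DNA string (standard code, no stop handling)."""
    if len(dna) % 3 != 0:
        raise SchemeError(f"DNA length {len(dna)} is not a multiple of 3")
    return str(Seq(dna).translate())


def genotype_to_dna(
    region_dna: str, scheme: PhosphositeScheme, genotype: str
) -> str:
    """Realize a genotype at the DNA level (the allele amplicon payload).

    Non-W sites have their two codons (phosphoacceptor + proline) replaced by
    the scheme's ``codon_map`` entry; W sites keep the original codons
    byte-for-byte, so the all-W genotype returns ``region_dna`` unchanged.
    Translation commutes: ``translate(genotype_to_dna(d, g)) ==
    apply_genotype(translate(d), g)``.
    """
    scheme.check_genotype(genotype)
    region_protein = translate(region_dna)
    _check_region_protein(region_protein, scheme)
    out = list(region_dna)
    for site, state in zip(scheme.sites, genotype):
        if state == "W":
            continue
        try:
            codon1, codon2 = scheme.codon_map[state]
        except KeyError:
            raise SchemeError(
                f"codon_map has no replacement for state {state!r}"
            ) from None
        bp = 3 * scheme.site_offset(site)
        out[bp : bp + 3] = codon1
        out[bp + 3 : bp + 6] = codon2
    return "".join(out)


def genotype_from_dna(
    mutant_dna: str, region_dna: str, scheme: PhosphositeScheme
) -> str:
    """Read the genotype back from a realized DNA sequence.

    The inverse of :func:`genotype_to_dna` for codon maps whose replacements
    differ from the wild-type codons (true of the default map).
    """
    if len(mutant_dna) != len(region_dna):
        raise SchemeError("mutant and reference DNA lengths differ")
    states = []
    for site in scheme.sites:
        bp = 3 * scheme.site_offset(site)
        pair = (mutant_dna[bp : bp + 3], mutant_dna[bp + 3 : bp + 6])
        if pair == (region_dna[bp : bp + 3], region_dna[bp + 3 : bp + 6]):
            states.append("W")
            continue
        for state, codons in scheme.codon_map.items():
            if pair == tuple(codons):
                states.append(state)
                break
        else:
            raise SchemeError(
                f"site {site.label}: codon pair {pair} matches neither the "
                "wild-type codons nor any codon_map entry"
            )
    return "".join(states)


def allele_table(
    region_dna: str, scheme: PhosphositeScheme, genotypes: Iterable[str]
) -> dict[str, str]:
    """Map each genotype to its realized DNA amplicon."""
    return {g: genotype_to_dna(region_dna, scheme, g) for g in genotypes}
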