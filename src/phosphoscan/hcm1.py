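"""Default Hcm1 transactivation-domain (TAD) scheme and a synthetic region.

The budding-yeast forkhead transcription factor Hcm1 carries eight CDK
consensus sites (S/T-P) in its TAD.  Five phosphoacceptor positions are
printed in the literature (T428, T440, T447, T460, S471); the remaining three
C-terminal serines are unnumbered, so this module assigns them placeholder
positions 482, 489 and 496 (labels S482/S489/S496).  The placeholders are
used only to lay out the synthetic fixture region and are NOT authoritative
residue numbers.

The region DNA returned by :func:`synthetic_tad_region` is a synthetic
90-codon (270 bp) sequence built from a fixed codon table: it encodes the
correct S/T-P motifs at every scheme position with a neutral filler protein
elsewhere.  It is a stand-in fixture for the real HCM1 amplicon, which is not
reproduced here.
"""

from __future__ import annotations

from .scheme import LibrarySpec, PhosphositeScheme, Site, uniform_library

__all__ = [
    "tad_scheme",
    "synthetic_tad_region",
    "ae_library",
    "ae_library_3n",
    "wt_a_library",
    "wt_e_library",
]

#: Printed positions for the five numbered sites; placeholders for the rest.
_TAD_SITES = (
    ("T428", 428, "T"),
    ("T440", 440, "T"),
    ("T447", 447, "T"),
    ("T460", 460, "T"),
    ("S471", 471, "S"),
    ("S482", 482, "S"),  # placeholder position
    ("S489", 489, "S"),  # placeholder position
    ("S496", 496, "S"),  # placeholder position
)

_REGION_SPAN = (421, 510)  # 90 residues = 270 bp

# One codon per amino acid, frozen so the fixture is deterministic.
_CODON = {
    "G": "GGT", "N": "AAC", "L": "TTG", "Q": "CAA", "K": "AAG",
    "D": "GAT", "V": "GTT", "I": "ATT", "R": "AGA", "F": "TTT",
    "S": "TCT", "T": "ACT", "P": "CCA", "A": "GCT", "E": "GAA",
}

# Filler residues avoid S/T/P so no accidental CDK motifs appear.
_FILLER = "GNLQKDVIRF"


def tad_scheme() -> PhosphositeScheme:
    """The 8-site Hcm1 TAD scheme with the default codon map."""
    return PhosphositeScheme(
        sites=tuple(Site(label, pos, wt) for label, pos, wt in _TAD_SITES),
        region_span=_REGION_SPAN,
    )


def synthetic_tad_protein() -> str:
    """Synthetic 90-residue region protein with S/T-P at each scheme site."""
    scheme = tad_scheme()
    protein = [
        _FILLER[i % len(_FILLER)] for i in range(scheme.region_length)
    ]
    for site in scheme.sites:
        off = scheme.site_offset(site)
        protein[off] = site.wt_residue
        protein[off + 1] = "P"
    return "".join(protein)


def synthetic_tad_region() -> str:
    """Synthetic 270-bp region DNA encoding :func:`synthetic_tad_protein`."""
    return "".join(_CODON[aa] for aa in synthetic_tad_protein())


def ae_library() -> LibrarySpec:
    """The 256-member A/E library (every site A or E).

    The screen's reference allele is the wild-type gene (all-W genotype),
    carried in the pool as a spike-in alongside the 256 enumerated members.
    """
    return uniform_library(tad_scheme(), "AE", "WWWWWWWW")


def ae_library_3n() -> LibrarySpec:
    """The 3N A/E library: A/E scan on the stabilized (3N) background.

    Identical enumeration to the A/E library; the 3N phosphodegron mutations
    sit outside the scanned region and the reference allele is hcm1-3N
    (all-W TAD on the 3N background) rather than wild type.
    """
    return uniform_library(
        tad_scheme(), "AE", "WWWWWWWW", fixed_background="3N"
    )


def wt_a_library() -> LibrarySpec:
    """The 256-member WT/A library (every site wild type or alanine)."""
    return uniform_library(tad_scheme(), "WA", "WWWWWWWW")


def wt_e_library() -> LibrarySpec:
    """The 256-member WT/E library (every site wild type or phosphomimetic)."""
    return uniform_library(tad_scheme(), "WE", "WWWWWWWW")
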