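"""Run configuration: YAML parsing and count-table I/O.

A run config bundles the scheme, the library definition, the screen
metadata (timepoints, replicates, reference) and either a FASTQ manifest or
a precomputed count table.  A minimal example::

    scheme:
      region_span: [421, 510]
      sites:
        - {label: T428, position: 428, wt: T}
        - {label: T440, position: 440, wt: T}
      codon_map: {A: [GCT, CCA], E: [GAA, GAA]}
    library:
      allowed_states: AE          # one string, or a list with one per site
      reference_genotype: WW
      background: null
    region_fasta: region.fa       # omit to use the built-in synthetic region
    counts_tsv: counts.tsv        # or: fastq_manifest: manifest.tsv
    screen:
      timepoints_h: [0, 12, 24, 36, 48, 60, 72]
    options: {pseudocount: 0.5, read_length: 150, seed: 1}
    out_dir: out

The FASTQ manifest is a TSV with columns ``replicate, timepoint_h, r1, r2``,
one row per sequencing sample, uniquely keyed by (replicate, timepoint).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import pandas as pd
import yaml
from Bio import SeqIO

from . import hcm1
from .scheme import DEFAULT_CODON_MAP, LibrarySpec, PhosphositeScheme, Site

__all__ = ["RunConfig", "ConfigError", "load_config", "read_count_table",
           "read_manifest"]


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Everything one screen analysis needs, resolved and validated."""

    library: LibrarySpec
    region_dna: str
    timepoints_h: list[float]
    out_dir: str = "out"
    counts_tsv: str | None = None
    fastq_manifest: str | None = None
    pseudocount: float = 0.5
    read_length: int = 150
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.timepoints_h != sorted(self.timepoints_h):
            raise ConfigError("timepoints must be increasing")
        if self.timepoints_h and self.timepoints_h[0] != 0:
            raise ConfigError("timepoints must start at 0 (the t0 sample)")
        if self.counts_tsv is None and self.fastq_manifest is None:
            raise ConfigError("need either counts_tsv or fastq_manifest")


def _parse_scheme(node: dict) -> PhosphositeScheme:
    sites = tuple(
        Site(label=s["label"], position=int(s["position"]),
             wt_residue=s.get("wt", s.get("wt_residue")))
        for s in node["sites"]
    )
    codon_map = {
        state: tuple(codons)
        for state, codons in node.get("codon_map", DEFAULT_CODON_MAP).items()
    }
    return PhosphositeScheme(
        sites=sites,
        region_span=tuple(node["region_span"]),
        codon_map=codon_map,
    )


def load_config(path: str) -> RunConfig:
    """Parse a YAML run config, falling back to the built-in Hcm1 defaults
    for any of scheme / library / region that is omitted."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    base = os.path.dirname(os.path.abspath(path))

    def resolve(p):
        return p if p is None or os.path.isabs(p) else os.path.join(base, p)

    if "scheme" in raw:
        scheme = _parse_scheme(raw["scheme"])
    else:
        scheme = hcm1.tad_scheme()

    lib_node = raw.get("library", {})
    allowed = lib_node.get("allowed_states", "AE")
    if isinstance(allowed, str):
        allowed = (allowed,) * scheme.n_sites
    library = LibrarySpec(
        scheme=scheme,
        allowed_states=tuple(allowed),
        reference_genotype=lib_node.get("reference_genotype",
                                        "W" * scheme.n_sites),
        fixed_background=lib_node.get("background"),
    )

    if raw.get("region_fasta"):
        record = next(SeqIO.parse(resolve(raw["region_fasta"]), "fasta"))
        region_dna = str(record.seq).upper()
    else:
        region_dna = hcm1.synthetic_tad_region()

    screen = raw.get("screen", {})
    options = raw.get("options", {})
    return RunConfig(
        library=library,
        region_dna=region_dna,
        timepoints_h=[float(t) for t in screen.get(
            "timepoints_h", [0, 12, 24, 36, 48, 60, 72])],
        out_dir=resolve(raw.get("out_dir", "out")),
        counts_tsv=resolve(raw.get("counts_tsv")),
        fastq_manifest=resolve(raw.get("fastq_manifest")),
        pseudocount=float(options.get("pseudocount", 0.5)),
        read_length=int(options.get("read_length", 150)),
        seed=options.get("seed"),
    )


#: Canonical count-table schema (the interchange hub between stages).
COUNT_COLUMNS = ["genotype", "replicate", "timepoint_h", "count"]


def read_count_table(path: str, column_map: dict | None = None) -> pd.DataFrame:
    """Read a count TSV, optionally renaming foreign column headers.

    ``column_map`` maps source column names onto the canonical schema
    (genotype, replicate, timepoint_h, count), so externally produced
    tables can be adapted without editing the file.
    """
    df = pd.read_csv(path, sep="\t")
    if column_map:
        df = df.rename(columns=column_map)
    missing = set(COUNT_COLUMNS) - set(df.columns)
    if missing:
        raise ConfigError(
            f"count table {path} missing columns {sorted(missing)}; "
            "use column_map to adapt foreign headers"
        )
    return df[COUNT_COLUMNS]


def read_manifest(path: str) -> pd.DataFrame:
    """Read a FASTQ manifest TSV (replicate, timepoint_h, r1, r2)."""
    df = pd.read_csv(path, sep="\t")
    required = {"replicate", "timepoint_h", "r1", "r2"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigError(f"manifest missing columns {sorted(missing)}")
    keys = df[["replicate", "timepoint_h"]].apply(tuple, axis=1)
    if keys.duplicated().any():
        raise ConfigError("manifest rows must be unique per (replicate, timepoint)")
    base = os.path.dirname(os.path.abspath(path))
    for col in ("r1", "r2"):
        df[col] = df[col].map(
            lambda p: p if os.path.isabs(p) else os.path.join(base, p)
        )
    return df
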