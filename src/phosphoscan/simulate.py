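"""Pooled serial-dilution competition simulator with sequencing readout.

Models the screen: a pool of genotypes grows exponentially in batch culture,
is sampled and diluted every ``dt`` hours (default 12 h for 72 h), and the
composition at each timepoint is read out by paired-end amplicon sequencing.

Per-genotype fitness is parameterized directly as a selection coefficient
``s`` in log2-fraction change per hour — the same scale the downstream
estimator reports — with the reference genotype at ``s = 0``.  Between
dilutions each genotype grows as

    N_g(t + dt) = N_g(t) * 2 ** ((r0 + s_g) * dt)

where ``r0`` is the reference growth rate in doublings per hour; its value
cancels in every fraction-based quantity.  Optional stochastic layers, each
independently seeded per replicate: a multinomial bottleneck at every
dilution, multinomial read sampling at every timepoint, and uniform
per-base substitution errors in the emitted reads.

With all stochastic layers disabled the simulator returns expected
(real-valued) read counts, so the fitness pipeline applied to its output
recovers ``s`` to numerical precision — the pipeline's core oracle.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["CompetitionModel", "SimulationError", "simulate_pool",
           "emit_fastq", "simulate_pairwise"]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class SimulationError(ValueError):
    pass


@dataclass
class CompetitionModel:
    """Configuration of one pooled competition screen.

    Parameters
    ----------
    genotypes
        Pool members, reference included.
    s
        True selection coefficient per genotype (log2 fraction change per
        hour).  The reference genotype must have ``s = 0``.
    reference
        Reference genotype label (normalization anchor).
    r0
        Reference growth rate, doublings/hour.  Default 0.25 (~2.8 h
        doubling time, a typical budding-yeast rate in rich medium); any
        positive value cancels in selection coefficients.
    dt, n_cycles
        Dilution interval (hours) and number of growth/dilution cycles.
        Defaults 12 h x 6 cycles give timepoints 0, 12, ..., 72 h.
    init_cells
        Total cells at t0, split equally across genotypes unless
        ``init_fractions`` is given.
    bottleneck
        Cells carried through each dilution (stochastic mode: multinomial
        draw of this size).
    depth
        Read pairs sampled per timepoint.
    replicates
        Number of biological replicates (independent random streams).
    """

    genotypes: Sequence[str]
    s: Mapping[str, float]
    reference: str
    r0: float = 0.25
    dt: float = 12.0
    n_cycles: int = 6
    init_cells: float = 1e7
    init_fractions: Mapping[str, float] | None = None
    bottleneck: float = 1e7
    depth: int = 1_000_000
    replicates: int = 3
    read_length: int = 150
    error_rate: float = 0.0
    seed: int | None = None
    stochastic_bottleneck: bool = True
    stochastic_reads: bool = True

    def __post_init__(self) -> None:
        self.genotypes = list(self.genotypes)
        if len(set(self.genotypes)) != len(self.genotypes):
            raise SimulationError("duplicate genotypes in pool")
        if self.reference not in self.genotypes:
            raise SimulationError("reference genotype not in pool")
        missing = [g for g in self.genotypes if g not in self.s]
        if missing:
            raise SimulationError(f"no selection coefficient for {missing[:3]}...")
        if abs(float(self.s[self.reference])) > 1e-12:
            raise SimulationError("reference selection coefficient must be 0")
        if self.n_cycles < 1 or self.dt <= 0:
            raise SimulationError("need at least one cycle of positive length")
        if (self.stochastic_bottleneck and self.bottleneck < 1) or (
            self.stochastic_reads and self.depth < 1
        ):
            raise SimulationError(
                "stochastic layers need a positive bottleneck/depth"
            )

    @property
    def timepoints(self) -> np.ndarray:
        return np.arange(self.n_cycles + 1) * self.dt

    def s_vector(self) -> np.ndarray:
        return np.array([float(self.s[g]) for g in self.genotypes])


def _replicate_rngs(seed: int | None, n: int) -> list[np.random.Generator]:
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(child) for child in ss.spawn(n)]


def simulate_pool(model: CompetitionModel) -> pd.DataFrame:
    """Run the competition and return a tidy count table.

    Returns a DataFrame with columns ``genotype, replicate, timepoint_h,
    count``.  Each cycle grows the pool for ``dt`` hours, samples reads,
    then dilutes to the bottleneck; t0 is sampled before any growth.
    Stochastic layers (multinomial bottleneck and read sampling) are applied
    when enabled; otherwise counts are exact expectations (real-valued).
    """
    n = len(model.genotypes)
    growth = 2.0 ** ((model.r0 + model.s_vector()) * model.dt)
    rngs = _replicate_rngs(model.seed, model.replicates)
    any_stochastic = model.stochastic_bottleneck or model.stochastic_reads
    if any_stochastic and model.seed is None:
        raise SimulationError("stochastic simulation requires a seed")

    if model.init_fractions is None:
        init = np.full(n, model.init_cells / n)
    else:
        frac = np.array([model.init_fractions[g] for g in model.genotypes])
        if not np.isclose(frac.sum(), 1.0):
            raise SimulationError("init_fractions must sum to 1")
        init = model.init_cells * frac

    records = []
    for rep_idx, rng in enumerate(rngs, start=1):
        cells = init.astype(float).copy()
        for cycle, t in enumerate(model.timepoints):
            if cycle > 0:
                cells = cells * growth
            frac = cells / cells.sum()
            if model.stochastic_reads:
                reads = rng.multinomial(model.depth, frac).astype(float)
            else:
                reads = model.depth * frac
            records.append((rep_idx, t, reads))
            if cycle < model.n_cycles:  # dilute after sampling
                if model.stochastic_bottleneck:
                    cells = rng.multinomial(
                        int(model.bottleneck), frac
                    ).astype(float)
                else:
                    cells = frac * model.bottleneck
    rows = []
    for rep_idx, t, reads in records:
        for g, c in zip(model.genotypes, reads):
            rows.append((g, rep_idx, t, c))
    df = pd.DataFrame(rows, columns=["genotype", "replicate", "timepoint_h",
                                     "count"])
    if model.stochastic_reads:
        df["count"] = df["count"].astype(np.int64)
    return df


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _mutate_reads(reads: np.ndarray, error_rate: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Apply uniform substitution errors to a (n_reads, read_len) byte array."""
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    mask = rng.random(reads.shape) < error_rate
    n_err = int(mask.sum())
    if n_err == 0:
        return reads
    # substitute with one of the three *other* bases, uniformly
    idx = np.searchsorted(bases, reads[mask])
    shift = rng.integers(1, 4, size=n_err)
    reads[mask] = bases[(idx + shift) % 4]
    return reads


def emit_fastq(
    counts: pd.DataFrame,
    alleles: Mapping[str, str],
    out_dir: str,
    read_length: int = 150,
    error_rate: float = 0.0,
    seed: int | None = None,
    prefix: str = "sim",
) -> list[dict]:
    """Write paired FASTQ files realizing a count table.

    Read 1 is the first ``read_length`` bases of the genotype's amplicon;
    read 2 is the reverse complement of the last ``read_length`` bases, so a
    pair covers the whole amplicon (required: amplicon length must not
    exceed ``2 * read_length``, else interior sites would go unobserved).
    Substitution errors are applied per base at ``error_rate``; qualities
    are constant placeholders.  Returns a manifest: one dict per
    (replicate, timepoint) with the mate file paths.
    """
    lengths = {len(a) for a in alleles.values()}
    if len(lengths) != 1:
        raise SimulationError("allele amplicons must have equal length")
    (amp_len,) = lengths
    if amp_len > 2 * read_length:
        raise SimulationError(
            f"amplicon ({amp_len} bp) exceeds paired coverage "
            f"(2 x {read_length} bp); sites would be unobserved"
        )
    if error_rate > 0 and seed is None:
        raise SimulationError("error simulation requires a seed")
    rng = np.random.default_rng(seed)
    os.makedirs(out_dir, exist_ok=True)
    qual = "I" * read_length
    manifest = []
    for (rep, t), grp in counts.groupby(["replicate", "timepoint_h"],
                                        sort=True):
        r1_path = os.path.join(out_dir, f"{prefix}_rep{rep}_t{t:g}_R1.fastq")
        r2_path = os.path.join(out_dir, f"{prefix}_rep{rep}_t{t:g}_R2.fastq")
        with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
            serial = 0
            for _, row in grp.iterrows():
                count = int(row["count"])
                if count == 0:
                    continue
                amp = alleles[row["genotype"]]
                r1 = amp[:read_length]
                r2 = _revcomp(amp[-read_length:])
                block1 = np.frombuffer(
                    r1.encode() * count, dtype=np.uint8
                ).reshape(count, read_length).copy()
                block2 = np.frombuffer(
                    r2.encode() * count, dtype=np.uint8
                ).reshape(count, read_length).copy()
                if error_rate > 0:
                    block1 = _mutate_reads(block1, error_rate, rng)
                    block2 = _mutate_reads(block2, error_rate, rng)
                for i in range(count):
                    serial += 1
                    name = f"{prefix}:{rep}:{t:g}:{serial}"
                    f1.write(f"@{name}/1\n{block1[i].tobytes().decode()}\n"
                             f"+\n{qual}\n")
                    f2.write(f"@{name}/2\n{block2[i].tobytes().decode()}\n"
                             f"+\n{qual}\n")
        manifest.append({"replicate": int(rep), "timepoint_h": float(t),
                         "r1": r1_path, "r2": r2_path})
    return manifest


def simulate_pairwise(
    s_mut: float,
    dt: float = 12.0,
    n_cycles: int = 6,
    n_cells: int = 5000,
    replicates: int = 3,
    seed: int | None = None,
    init_percent: float = 50.0,
) -> pd.DataFrame:
    """Two-strain co-culture assay read out by flow cytometry.

    The special case of the pool with one mutant against the reference;
    composition at each timepoint is measured by drawing ``n_cells`` cells
    (binomial, emulating the cytometer sample) and reporting percentages.
    With ``seed=None`` the exact expected percentages are returned.

    Returns columns ``replicate, timepoint_h, percent_mut, percent_ref``.
    """
    if not (0 < init_percent < 100):
        raise SimulationError("initial percentage must be in (0, 100)")
    times = np.arange(n_cycles + 1) * dt
    f0 = init_percent / 100.0
    odds = (f0 / (1 - f0)) * 2.0 ** (s_mut * times)
    frac = odds / (1 + odds)
    rows = []
    rngs = _replicate_rngs(seed, replicates)
    for rep_idx, rng in enumerate(rngs, start=1):
        if seed is None:
            p = frac
        else:
            p = rng.binomial(n_cells, frac) / n_cells
        for t, pm in zip(times, p):
            rows.append((rep_idx, t, 100 * pm, 100 * (1 - pm)))
    return pd.DataFrame(
        rows, columns=["replicate", "timepoint_h", "percent_mut",
                       "percent_ref"]
    )
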