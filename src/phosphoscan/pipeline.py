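"""End-to-end screen analysis: counting -> fitness -> group summaries.

:func:`run_screen` composes the pipeline stages over a :class:`RunConfig`
and writes every output table as TSV, plus a JSON run log recording the
parameters and a hash of the genotype library (to guard against scheme
drift between the counting and fitness stages).  Given identical inputs
and seeds the outputs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass

import pandas as pd

from . import __version__
from .config import RunConfig, read_count_table, read_manifest
from .counting import build_matcher, combine_counts, count_reads
from .fitness import FitnessTable, enrichment_matrix, estimate_sc, log2_fractions
from .groupstats import (cumulative_sc, group_by_count, group_by_site,
                         replicate_correlation)
from .scheme import allele_table

__all__ = ["ScreenResult", "PipelineError", "run_screen", "library_hash"]


class PipelineError(RuntimeError):
    """A stage failure, wrapped with the stage name."""


@dataclass
class ScreenResult:
    counts: pd.DataFrame
    discards: pd.DataFrame | None
    fitness: FitnessTable
    enrichment_mean: pd.DataFrame
    by_count: pd.DataFrame
    by_site: pd.DataFrame
    cdf: pd.DataFrame
    correlations: pd.DataFrame | None
    out_dir: str


def library_hash(genotypes) -> str:
    """SHA-256 over the sorted genotype list: a fingerprint of the library."""
    payload = "\n".join(sorted(genotypes)).encode()
    return hashlib.sha256(payload).hexdigest()


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # annotate with the failing stage
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


@_stage("count")
def _obtain_counts(config: RunConfig):
    if config.counts_tsv is not None:
        return read_count_table(config.counts_tsv), None
    manifest = read_manifest(config.fastq_manifest)
    pool = config.library.pool_genotypes()
    alleles = allele_table(config.region_dna, config.library.scheme, pool)
    matcher = build_matcher(alleles, config.read_length)
    slices = [
        (int(row.replicate), float(row.timepoint_h),
         count_reads(row.r1, row.r2, matcher))
        for row in manifest.itertuples()
    ]
    return combine_counts(slices)


def run_screen(config: RunConfig) -> ScreenResult:
    """Run the full analysis and write the output bundle to ``out_dir``.

    Outputs: ``counts.tsv`` (and ``discards.tsv`` when counting from
    FASTQ), ``fitness.tsv``, ``enrichment.tsv``, ``groups_by_count.tsv``,
    ``groups_by_site.tsv``, ``cdf.tsv``, ``replicate_correlation.tsv`` and
    ``run_log.json``.  On a stage failure, outputs produced so far stay on
    disk alongside a ``FAILED`` marker naming the stage.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    out = lambda name: os.path.join(config.out_dir, name)  # noqa: E731
    reference = config.library.reference_genotype
    try:
        counts, discards = _obtain_counts(config)
        counts.to_csv(out("counts.tsv"), sep="\t", index=False)
        if discards is not None:
            discards.to_csv(out("discards.tsv"), sep="\t", index=False)

        fit = _stage("fitness")(_fit)(counts, config)
        fit.summary.to_csv(out("fitness.tsv"), sep="\t")
        _, enrichment_mean = _stage("fitness")(enrichment_matrix)(
            counts, reference, config.pseudocount
        )
        enrichment_mean.to_csv(out("enrichment.tsv"), sep="\t")

        labels = [s.label for s in config.library.scheme.sites]
        by_count = _stage("groups")(group_by_count)(fit, state="E")
        by_site = _stage("groups")(group_by_site)(fit, site_labels=labels)
        cdf = _stage("groups")(cumulative_sc)(fit)
        by_count.to_csv(out("groups_by_count.tsv"), sep="\t")
        by_site.to_csv(out("groups_by_site.tsv"), sep="\t")
        cdf.to_csv(out("cdf.tsv"), sep="\t", index=False)
        correlations = None
        if len(fit.replicates) >= 2:
            correlations = _stage("groups")(replicate_correlation)(fit)
            correlations.to_csv(out("replicate_correlation.tsv"), sep="\t")
    except PipelineError as exc:
        with open(out("FAILED"), "w") as fh:
            fh.write(str(exc) + "\n")
        raise

    log = {
        "phosphoscan_version": __version__,
        "reference_genotype": reference,
        "background": config.library.fixed_background,
        "timepoints_h": config.timepoints_h,
        "pseudocount": config.pseudocount,
        "read_length": config.read_length,
        "seed": config.seed,
        "library_size": config.library.size,
        "library_sha256": library_hash(config.library.pool_genotypes()),
        "input": config.counts_tsv or config.fastq_manifest,
    }
    with open(out("run_log.json"), "w") as fh:
        json.dump(log, fh, indent=2)

    return ScreenResult(
        counts=counts, discards=discards, fitness=fit,
        enrichment_mean=enrichment_mean, by_count=by_count, by_site=by_site,
        cdf=cdf, correlations=correlations, out_dir=config.out_dir,
    )


def _fit(counts: pd.DataFrame, config: RunConfig) -> FitnessTable:
    log2f = log2_fractions(counts, config.pseudocount)
    return estimate_sc(log2f, config.library.reference_genotype,
                       timepoints=config.timepoints_h)
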