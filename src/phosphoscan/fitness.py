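"""Selection coefficients and enrichment matrices from count tables.

The selection coefficient (SC) of a genotype is the slope of an ordinary
least-squares fit of its log2 read fraction against time (hours), minus the
same slope for the reference allele.  The reference therefore has SC = 0 in
every replicate by construction; mutants less fit than the reference have
negative SC, fitter mutants positive SC.  Replicates are fit independently
and then averaged.

A symmetric pseudocount (default 0.5) is added to every genotype at every
timepoint before fractions are formed, so zero-count genotypes stay finite;
set it to 0 to reproduce raw fractions.  All SC-scale quantities are
invariant to sequencing depth: multiplying every count at a timepoint by a
constant shifts all log2 fractions equally and cancels in the
reference-normalized slope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["FitnessTable", "FitnessError", "log2_fractions", "estimate_sc",
           "enrichment_matrix", "pairwise_sc"]


class FitnessError(ValueError):
    pass


REQUIRED_COLUMNS = ("genotype", "replicate", "timepoint_h", "count")


def _check_counts(counts: pd.DataFrame) -> None:
    missing = set(REQUIRED_COLUMNS) - set(counts.columns)
    if missing:
        raise FitnessError(f"count table missing columns {sorted(missing)}")
    if (counts["count"] < 0).any():
        raise FitnessError("negative counts")


def log2_fractions(counts: pd.DataFrame, pseudocount: float = 0.5) -> pd.DataFrame:
    """Per-sample log2 read fractions.

    Returns a genotype-indexed DataFrame whose columns are a MultiIndex of
    ``(replicate, timepoint_h)``; entries are
    ``log2((count + pseudocount) / sum(count + pseudocount))``.  Fractions
    sum to 1 within each sample before the log.  A sample with zero total
    raw count (and zero pseudocount) is an error: the sample is missing.
    """
    _check_counts(counts)
    wide = counts.pivot_table(
        index="genotype", columns=["replicate", "timepoint_h"],
        values="count", aggfunc="sum", fill_value=0,
    )
    adj = wide + pseudocount
    totals = adj.sum(axis=0)
    if (totals <= 0).any():
        bad = totals[totals <= 0].index.tolist()
        raise FitnessError(f"all-zero timepoint(s) {bad}: sample missing")
    return np.log2(adj / totals)


@dataclass
class FitnessTable:
    """Per-genotype selection coefficients with replicate-level detail.

    ``per_replicate``: tidy frame (genotype, replicate, slope, intercept,
    resid_ss, sc).  ``summary``: genotype-indexed frame with the replicate
    SC columns, ``mean_sc``, ``sd_sc`` (ddof=1) and ``n_reps``.
    """

    per_replicate: pd.DataFrame
    summary: pd.DataFrame
    reference: str
    timepoints: np.ndarray

    @property
    def genotypes(self) -> list[str]:
        return list(self.summary.index)

    @property
    def replicates(self) -> list:
        return sorted(self.per_replicate["replicate"].unique())

    def sc_values(self) -> pd.DataFrame:
        """Genotype x replicate matrix of selection coefficients."""
        return self.per_replicate.pivot(
            index="genotype", columns="replicate", values="sc"
        )


def _ols_slope(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Slope, intercept and residual sum of squares of an OLS line."""
    slope, intercept = np.polyfit(t, y, 1)
    resid = y - (slope * t + intercept)
    return float(slope), float(intercept), float(resid @ resid)


def estimate_sc(
    log2f: pd.DataFrame,
    reference: str,
    timepoints: np.ndarray | None = None,
) -> FitnessTable:
    """Selection coefficients from a log2-fraction table.

    For each replicate, fits one unweighted OLS line per genotype over all
    timepoints and subtracts the reference genotype's slope.  Requires at
    least two timepoints and the reference present in the table.  A
    genotype absent from a replicate (all-NaN column) yields NaN for that
    replicate; the mean is taken over the available replicates.
    """
    if reference not in log2f.index:
        raise FitnessError(f"reference genotype {reference!r} not in table")
    replicates = sorted({rep for rep, _ in log2f.columns})
    rows = []
    for rep in replicates:
        sub = log2f[rep]
        t = (np.asarray(sorted(sub.columns), dtype=float)
             if timepoints is None else np.asarray(timepoints, dtype=float))
        if len(t) < 2:
            raise FitnessError("need at least two timepoints")
        sub = sub[sorted(sub.columns)]
        ref_slope, _, _ = _ols_slope(t, sub.loc[reference].to_numpy(float))
        for genotype, y in sub.iterrows():
            yv = y.to_numpy(float)
            if np.isnan(yv).any():
                rows.append((genotype, rep, np.nan, np.nan, np.nan, np.nan))
                continue
            slope, intercept, rss = _ols_slope(t, yv)
            rows.append((genotype, rep, slope, intercept, rss,
                         slope - ref_slope))
    per_rep = pd.DataFrame(
        rows, columns=["genotype", "replicate", "slope", "intercept",
                       "resid_ss", "sc"],
    )
    sc = per_rep.pivot(index="genotype", columns="replicate", values="sc")
    summary = sc.copy()
    summary.columns = [f"sc_rep{r}" for r in sc.columns]
    summary["mean_sc"] = sc.mean(axis=1)
    summary["sd_sc"] = sc.std(axis=1, ddof=1)
    summary["n_reps"] = sc.notna().sum(axis=1)
    first_rep = log2f[replicates[0]]
    t = (np.asarray(sorted(first_rep.columns), dtype=float)
         if timepoints is None else np.asarray(timepoints, dtype=float))
    return FitnessTable(per_replicate=per_rep, summary=summary,
                        reference=reference, timepoints=t)


def enrichment_matrix(
    counts: pd.DataFrame,
    reference: str,
    pseudocount: float = 0.5,
) -> tuple[dict, pd.DataFrame]:
    """Reference-normalized log2 fold change versus the t0 sample.

    ``E_g(t) = [log2 f_g(t) - log2 f_g(0)] - [log2 f_ref(t) - log2 f_ref(0)]``
    — the heatmap quantity: 0 everywhere at t0 and 0 at all times for the
    reference row.  Returns ``(per_replicate, mean)`` where
    ``per_replicate`` maps replicate -> genotype x timepoint DataFrame and
    ``mean`` is the replicate average.
    """
    log2f = log2_fractions(counts, pseudocount)
    per_rep: dict = {}
    for rep in sorted({r for r, _ in log2f.columns}):
        sub = log2f[rep]
        sub = sub[sorted(sub.columns)]
        if 0.0 not in sub.columns:
            raise FitnessError(f"replicate {rep}: no t0 sample")
        if reference not in sub.index:
            raise FitnessError(f"reference {reference!r} missing")
        rel = sub.sub(sub[0.0], axis=0)  # vs time zero
        per_rep[rep] = rel - rel.loc[reference]  # vs reference
    mean = sum(per_rep.values()) / len(per_rep)
    return per_rep, mean


def pairwise_sc(
    timepoints_h: np.ndarray, percent_mut: np.ndarray
) -> float:
    """Selection coefficient from a two-strain composition time course.

    The flow-cytometry analogue of the screen: SC is the OLS slope of
    ``log2(p_mut / p_ref)`` against time in hours, where the two strains'
    percentages sum to 100.  Percentages of exactly 0 or 100 make the log
    ratio undefined; truncate the course before the fixed point and refit.
    """
    t = np.asarray(timepoints_h, dtype=float)
    p = np.asarray(percent_mut, dtype=float)
    if t.shape != p.shape or t.size < 2:
        raise FitnessError("need matching time/percentage arrays, >= 2 points")
    if ((p <= 0) | (p >= 100)).any():
        raise FitnessError(
            "composition of 0% or 100% has an undefined log ratio; "
            "truncate the time course to the informative window"
        )
    slope, _, _ = _ols_slope(t, np.log2(p / (100.0 - p)))
    return slope
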