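"""Summaries of the phosphorylation code across the library.

Groups selection coefficients by the number of sites in a given state
(how many phosphomimetic substitutions does a mutant carry?) or by the
state at each individual site (what does an E at site k do, marginalized
over the other sites?), and reports medians with Tukey box-and-whisker
statistics.  Groups pool replicate-level SC values, not per-genotype means,
so a k-of-8 group in a 3-replicate A/E screen holds C(8, k) * 3 values.

Quartiles use linear interpolation (R's default type-7, the convention of
``boxplot()``); whiskers extend to the most extreme point within 1.5 x IQR
of the quartiles and points beyond are listed as outliers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .fitness import FitnessError, FitnessTable

__all__ = ["tukey_box", "group_by_count", "group_by_site", "cumulative_sc",
           "replicate_correlation"]


def tukey_box(values: np.ndarray) -> dict:
    """Median, quartiles, 1.5*IQR whiskers and outliers of a sample."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        return {"n": 0, "median": np.nan, "q25": np.nan, "q75": np.nan,
                "whisker_lo": np.nan, "whisker_hi": np.nan, "outliers": []}
    q25, med, q75 = np.percentile(v, [25, 50, 75])  # type-7 interpolation
    iqr = q75 - q25
    lo_fence, hi_fence = q25 - 1.5 * iqr, q75 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    return {
        "n": int(v.size),
        "median": float(med),
        "q25": float(q25),
        "q75": float(q75),
        "whisker_lo": float(inside.min()),
        "whisker_hi": float(inside.max()),
        "outliers": sorted(v[(v < lo_fence) | (v > hi_fence)].tolist()),
    }


def _replicate_values(fitness: FitnessTable, genotypes) -> np.ndarray:
    sc = fitness.sc_values()
    return sc.loc[list(genotypes)].to_numpy(float).ravel()


def group_by_count(fitness: FitnessTable, state: str = "E",
                   members_only: bool = True) -> pd.DataFrame:
    """Boxplot statistics by number of sites carrying ``state``.

    One row per k = 0..n_sites; pools all replicate SC values of genotypes
    with exactly k sites in the given state.  ``members_only`` drops the
    reference spike-in when it is not an enumerated library member (e.g.
    the all-W wild type in the A/E screen), so the k-groups partition the
    library proper.
    """
    sc = fitness.sc_values()
    genotypes = list(sc.index)
    if members_only and fitness.reference in genotypes:
        enumerated = [g for g in genotypes if g != fitness.reference]
        # keep the reference when it is a genuine member state combination
        if not _uses_same_alphabet(fitness.reference, enumerated):
            genotypes = enumerated
    n_sites = len(genotypes[0])
    rows = []
    for k in range(n_sites + 1):
        members = [g for g in genotypes if g.count(state) == k]
        stats = tukey_box(_replicate_values(fitness, members)
                          if members else np.array([]))
        rows.append({"k": k, "n_genotypes": len(members), **stats})
    return pd.DataFrame(rows).set_index("k")


def _uses_same_alphabet(reference: str, genotypes: list[str]) -> bool:
    alphabet = {c for g in genotypes for c in g}
    return set(reference) <= alphabet


def group_by_site(fitness: FitnessTable, site_labels=None,
                  members_only: bool = True) -> pd.DataFrame:
    """Boxplot statistics per (site, state): the marginal effect of a site.

    For each site position and each state observed there, pools the
    replicate SC values of every genotype carrying that state at that site
    (the half-library of 128 genotypes in a two-state 256-member screen).
    """
    sc = fitness.sc_values()
    genotypes = list(sc.index)
    if members_only and fitness.reference in genotypes:
        enumerated = [g for g in genotypes if g != fitness.reference]
        if not _uses_same_alphabet(fitness.reference, enumerated):
            genotypes = enumerated
    n_sites = len(genotypes[0])
    labels = (list(site_labels) if site_labels is not None
              else [f"site{i + 1}" for i in range(n_sites)])
    rows = []
    for i in range(n_sites):
        states = sorted({g[i] for g in genotypes})
        for state in states:
            members = [g for g in genotypes if g[i] == state]
            stats = tukey_box(_replicate_values(fitness, members))
            rows.append({"site": labels[i], "state": state,
                         "n_genotypes": len(members), **stats})
    return pd.DataFrame(rows).set_index(["site", "state"])


def cumulative_sc(fitness: FitnessTable) -> pd.DataFrame:
    """Right-continuous empirical CDF over all replicate SC values.

    Returns columns ``sc`` (sorted unique values) and ``cum_fraction``
    (fraction of values <= sc), rising monotonically to 1 — the cumulative
    frequency curve used to compare screens on a common axis.
    """
    values = fitness.sc_values().to_numpy(float).ravel()
    values = values[~np.isnan(values)]
    if values.size == 0:
        raise FitnessError("no selection coefficients to summarize")
    xs = np.unique(values)
    cum = np.searchsorted(np.sort(values), xs, side="right") / values.size
    return pd.DataFrame({"sc": xs, "cum_fraction": cum})


def replicate_correlation(fitness: FitnessTable) -> pd.DataFrame:
    """Pearson correlation of SC vectors between every pair of replicates."""
    sc = fitness.sc_values()
    if sc.shape[1] < 2:
        raise FitnessError("need at least two replicates")
    if (sc.std(ddof=0) == 0).any():
        raise FitnessError("zero-variance replicate: correlation undefined")
    return sc.corr(method="pearson")
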