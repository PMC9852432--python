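"""Group summaries: per-count/per-site medians, boxplot stats, CDF."""

import math

import numpy as np
import pandas as pd
import pytest

from phosphoscan.fitness import FitnessError, estimate_sc, log2_fractions
from phosphoscan.groupstats import (
    cumulative_sc,
    group_by_count,
    group_by_site,
    replicate_correlation,
    tukey_box,
)
from phosphoscan.simulate import CompetitionModel, simulate_pool


def _fitness_from_s(s: dict, reference: str, replicates: int = 3,
                    jitter: float = 0.0, seed: int = 0):
    """Noise-free screen realizing the given s, optionally replicate jitter."""
    rng = np.random.default_rng(seed)
    frames = []
    for rep in range(1, replicates + 1):
        s_rep = {
            g: (v + (rng.normal(0, jitter) if g != reference else 0.0))
            for g, v in s.items()
        }
        model = CompetitionModel(
            genotypes=list(s), s=s_rep, reference=reference,
            stochastic_bottleneck=False, stochastic_reads=False,
            replicates=1,
        )
        counts = simulate_pool(model)
        counts["replicate"] = rep
        frames.append(counts)
    counts = pd.concat(frames, ignore_index=True)
    return estimate_sc(log2_fractions(counts, 0), reference)


@pytest.fixture(scope="module")
def additive_fitness(ae_truth):
    """A/E screen where s depends only on the phosphomimetic count."""
    pool = list(ae_truth)
    s = {g: 0.002 * g.count("E") for g in pool}
    s["WWWWWWWW"] = 0.0
    return _fitness_from_s(s, "WWWWWWWW")


class TestGroupByCount:
    def test_group_sizes_are_binomial_times_replicates(self, additive_fitness):
        table = group_by_count(additive_fitness, state="E")
        for k in range(9):
            assert table.loc[k, "n_genotypes"] == math.comb(8, k)
            assert table.loc[k, "n"] == math.comb(8, k) * 3
        assert table["n_genotypes"].sum() == 256  # partition of the library

    def test_constant_sc_gives_constant_medians(self, ae_truth):
        s = {g: 0.0 for g in ae_truth}
        fit = _fitness_from_s(s, "WWWWWWWW", replicates=2)
        table = group_by_count(fit, state="E")
        assert np.allclose(table["median"], 0.0, atol=1e-12)

    def test_additive_effect_gives_linear_medians(self, additive_fitness):
        table = group_by_count(additive_fitness, state="E")
        assert np.allclose(table["median"], 0.002 * np.arange(9), atol=1e-9)

    def test_medians_match_sort_oracle(self, additive_fitness):
        sc = additive_fitness.sc_values()
        genos = [g for g in sc.index if g != "WWWWWWWW"]
        table = group_by_count(additive_fitness, state="E")
        for k in range(9):
            vals = sorted(
                v for g in genos if g.count("E") == k
                for v in sc.loc[g].tolist()
            )
            n = len(vals)
            oracle = (vals[n // 2] if n % 2 else
                      0.5 * (vals[n // 2 - 1] + vals[n // 2]))
            assert np.isclose(table.loc[k, "median"], oracle)


class TestGroupBySite:
    def test_each_site_state_group_has_half_library(self, additive_fitness):
        table = group_by_site(additive_fitness)
        assert (table["n_genotypes"] == 128).all()  # 2^7
        assert len(table) == 16  # 8 sites x 2 states

    def test_symmetric_fitness_gives_equal_medians(self, additive_fitness):
        # s depends only on the E count, so every site is exchangeable
        table = group_by_site(additive_fitness)
        for state in ("A", "E"):
            medians = table.xs(state, level="state")["median"]
            assert np.allclose(medians, medians.iloc[0], atol=1e-9)

    def test_single_site_effect_localizes(self, ae_truth):
        # only site 4 (index 3) carries an effect
        s = {g: (0.01 if g[3] == "E" else 0.0) for g in ae_truth}
        s["WWWWWWWW"] = 0.0
        fit = _fitness_from_s(s, "WWWWWWWW", replicates=2)
        table = group_by_site(
            fit, site_labels=[f"s{i}" for i in range(1, 9)]
        )
        gaps = {
            site: abs(table.loc[(site, "E"), "median"]
                      - table.loc[(site, "A"), "median"])
            for site in (f"s{i}" for i in range(1, 9))
        }
        assert gaps["s4"] == pytest.approx(0.01, abs=1e-9)
        for site, gap in gaps.items():
            if site != "s4":
                assert gap < 1e-9


class TestCumulativeSc:
    def test_single_value_steps_to_one(self):
        fit = _make_trivial_fitness([("g", 1, 0.25)])
        cdf = cumulative_sc(fit)
        assert cdf["cum_fraction"].tolist() == [1.0]

    def test_direct_count(self):
        fit = _make_trivial_fitness(
            [("a", 1, -1.0), ("b", 1, 0.0), ("c", 1, 1.0)]
        )
        cdf = cumulative_sc(fit).set_index("sc")
        assert cdf.loc[0.0, "cum_fraction"] == pytest.approx(2 / 3)

    def test_monotone_bounded_reaching_one(self, additive_fitness):
        cdf = cumulative_sc(additive_fitness)
        frac = cdf["cum_fraction"].to_numpy()
        assert (np.diff(frac) >= 0).all()
        assert 0 < frac[0] <= 1
        assert frac[-1] == 1.0


class TestReplicateCorrelation:
    def test_identical_replicates_correlate_perfectly(self, ae_truth):
        fit = _fitness_from_s(
            {g: v for g, v in ae_truth.items()}, "WWWWWWWW", replicates=2
        )
        corr = replicate_correlation(fit)
        assert np.allclose(corr.to_numpy(), 1.0)

    def test_anticorrelated_vectors(self):
        fit = _make_trivial_fitness(
            [("a", 1, 1.0), ("b", 1, -1.0), ("c", 1, 0.5),
             ("a", 2, -1.0), ("b", 2, 1.0), ("c", 2, -0.5)]
        )
        corr = replicate_correlation(fit)
        assert corr.loc[1, 2] == pytest.approx(-1.0)

    def test_independent_noise_decorrelates(self, ae_truth):
        s = {g: 0.0 for g in ae_truth}
        fit = _fitness_from_s(s, "WWWWWWWW", replicates=2, jitter=0.01,
                              seed=3)
        corr = replicate_correlation(fit)
        assert abs(corr.loc[1, 2]) < 0.2

    def test_single_replicate_rejected(self):
        fit = _make_trivial_fitness([("a", 1, 0.1), ("b", 1, 0.2)])
        with pytest.raises(FitnessError, match="two replicates"):
            replicate_correlation(fit)


class TestTukeyBox:
    def test_matches_numpy_percentiles_and_fences(self):
        rng = np.random.default_rng(4)
        v = rng.normal(size=200)
        box = tukey_box(v)
        q25, med, q75 = np.percentile(v, [25, 50, 75])
        assert box["median"] == pytest.approx(med)
        assert box["q25"] == pytest.approx(q25)
        assert box["q75"] == pytest.approx(q75)
        iqr = q75 - q25
        inside = v[(v >= q25 - 1.5 * iqr) & (v <= q75 + 1.5 * iqr)]
        assert box["whisker_lo"] == pytest.approx(inside.min())
        assert box["whisker_hi"] == pytest.approx(inside.max())
        assert len(box["outliers"]) == (len(v) - len(inside))


def _make_trivial_fitness(rows):
    """FitnessTable straight from (genotype, replicate, sc) triples."""
    from phosphoscan.fitness import FitnessTable

    per_rep = pd.DataFrame(
        [(g, rep, np.nan, np.nan, np.nan, sc) for g, rep, sc in rows],
        columns=["genotype", "replicate", "slope", "intercept", "resid_ss",
                 "sc"],
    )
    sc = per_rep.pivot(index="genotype", columns="replicate", values="sc")
    summary = sc.copy()
    summary.columns = [f"sc_rep{r}" for r in sc.columns]
    summary["mean_sc"] = sc.mean(axis=1)
    summary["sd_sc"] = sc.std(axis=1, ddof=1)
    summary["n_reps"] = sc.notna().sum(axis=1)
    return FitnessTable(per_replicate=per_rep, summary=summary,
                        reference=rows[0][0], timepoints=np.array([0.0]))
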