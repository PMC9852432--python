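"""Selection-coefficient estimation from count tables."""

import numpy as np
import pandas as pd
import pytest

from phosphoscan.fitness import (
    FitnessError,
    enrichment_matrix,
    estimate_sc,
    log2_fractions,
    pairwise_sc,
)
from phosphoscan.simulate import CompetitionModel, simulate_pool


def _table(rows):
    return pd.DataFrame(
        rows, columns=["genotype", "replicate", "timepoint_h", "count"]
    )


class TestLog2Fractions:
    def test_uniform_counts(self):
        counts = _table([(f"g{i}", 1, 0.0, 100) for i in range(4)])
        log2f = log2_fractions(counts, pseudocount=0)
        assert np.allclose(log2f.to_numpy(), -2.0)

    def test_pseudocount_arithmetic(self):
        counts = _table([("a", 1, 0.0, 0), ("b", 1, 0.0, 10)])
        log2f = log2_fractions(counts, pseudocount=0.5)
        assert np.isclose(2 ** log2f.loc["a", (1, 0.0)], 0.5 / 11)
        assert np.isclose(2 ** log2f.loc["b", (1, 0.0)], 10.5 / 11)

    def test_depth_scale_invariance(self):
        counts = _table([("a", 1, 0.0, 30), ("b", 1, 0.0, 70)])
        doubled = counts.assign(count=counts["count"] * 2)
        assert np.allclose(
            log2_fractions(counts, 0).to_numpy(),
            log2_fractions(doubled, 0).to_numpy(),
        )

    def test_all_zero_timepoint_rejected(self):
        counts = _table([("a", 1, 0.0, 0), ("b", 1, 0.0, 0)])
        with pytest.raises(FitnessError, match="missing"):
            log2_fractions(counts, pseudocount=0)


class TestEstimateSc:
    def test_hand_ols_on_collinear_points(self):
        # mutant/reference log2 ratio gains exactly +1 per 12 h
        times = [0.0, 12.0, 24.0, 36.0]
        rows = []
        for t in times:
            ratio = 2 ** (t / 12)
            rows.append(("mut", 1, t, 100 * ratio))
            rows.append(("ref", 1, t, 100))
        fit = estimate_sc(log2_fractions(_table(rows), 0), "ref")
        assert np.isclose(fit.summary.loc["mut", "mean_sc"], 1 / 12)

    def test_proportional_counts_give_zero_sc(self):
        rows = []
        for t in (0.0, 12.0, 24.0):
            rows.append(("mut", 1, t, 300 * (t + 1)))
            rows.append(("ref", 1, t, 100 * (t + 1)))
        fit = estimate_sc(log2_fractions(_table(rows), 0), "ref")
        assert np.isclose(fit.summary.loc["mut", "mean_sc"], 0.0)

    def test_reference_sc_identically_zero_per_replicate(self):
        rng = np.random.default_rng(0)
        rows = [
            (g, rep, t, rng.integers(50, 500))
            for g in ("a", "b", "ref")
            for rep in (1, 2, 3)
            for t in (0.0, 12.0, 24.0, 36.0)
        ]
        fit = estimate_sc(log2_fractions(_table(rows), 0.5), "ref")
        per_rep = fit.per_replicate.set_index(["genotype", "replicate"])
        for rep in (1, 2, 3):
            assert per_rep.loc[("ref", rep), "sc"] == 0.0

    def test_depth_invariance_of_sc(self):
        rng = np.random.default_rng(1)
        rows = [
            (g, 1, t, int(rng.integers(100, 1000)))
            for g in ("a", "b", "ref")
            for t in (0.0, 12.0, 24.0)
        ]
        counts = _table(rows)
        scaled = counts.copy()
        at_12 = scaled["timepoint_h"] == 12.0
        scaled.loc[at_12, "count"] *= 17  # rescale one timepoint's depth
        f1 = estimate_sc(log2_fractions(counts, 0), "ref")
        f2 = estimate_sc(log2_fractions(scaled, 0), "ref")
        assert np.allclose(f1.summary["mean_sc"], f2.summary["mean_sc"])

    def test_missing_reference_rejected(self):
        counts = _table([("a", 1, 0.0, 1), ("a", 1, 12.0, 1)])
        with pytest.raises(FitnessError, match="reference"):
            estimate_sc(log2_fractions(counts, 0.5), "ref")

    def test_replicate_mean_and_sd(self):
        rows = []
        for rep, slope in ((1, 0.01), (2, 0.02), (3, 0.03)):
            for t in (0.0, 12.0, 24.0):
                rows.append(("mut", rep, t, 1000 * 2 ** (slope * t)))
                rows.append(("ref", rep, t, 1000))
        fit = estimate_sc(log2_fractions(_table(rows), 0), "ref")
        assert np.isclose(fit.summary.loc["mut", "mean_sc"], 0.02)
        assert np.isclose(fit.summary.loc["mut", "sd_sc"], 0.01)
        assert fit.summary.loc["mut", "n_reps"] == 3


class TestNoiseFreeOracle:
    def test_pipeline_recovers_true_s_exactly(self, ae_library, ae_truth):
        pool = ae_library.pool_genotypes()
        model = CompetitionModel(
            genotypes=pool, s=ae_truth, reference="WWWWWWWW",
            stochastic_bottleneck=False, stochastic_reads=False,
            replicates=1,
        )
        counts = simulate_pool(model)
        fit = estimate_sc(log2_fractions(counts, 0), "WWWWWWWW")
        err = np.abs(
            fit.summary["mean_sc"]
            - pd.Series({g: ae_truth[g] for g in fit.summary.index})
        )
        assert err.max() < 1e-10

    def test_sc_equals_enrichment_row_slope(self, ae_library, ae_truth):
        """Algebraic identity: SC also equals the OLS slope of the
        reference-normalized enrichment row against time."""
        pool = ae_library.pool_genotypes()
        model = CompetitionModel(
            genotypes=pool, s=ae_truth, reference="WWWWWWWW",
            depth=100_000, replicates=1, seed=13,
        )
        counts = simulate_pool(model)
        fit = estimate_sc(log2_fractions(counts, 0.5), "WWWWWWWW")
        per_rep, _ = enrichment_matrix(counts, "WWWWWWWW", 0.5)
        E = per_rep[1]
        t = np.asarray(sorted(E.columns), dtype=float)
        sc = fit.per_replicate.set_index(["genotype", "replicate"])["sc"]
        for g in ["AAAAAAAA", "EEEEEEEE", "AAAEEAAA"]:
            slope = np.polyfit(t, E.loc[g].to_numpy(float), 1)[0]
            assert np.isclose(slope, sc.loc[(g, 1)], atol=1e-12)


class TestEnrichmentMatrix:
    def test_t0_column_and_reference_row_are_zero(self):
        rng = np.random.default_rng(2)
        rows = [
            (g, 1, t, int(rng.integers(100, 1000)))
            for g in ("a", "b", "ref")
            for t in (0.0, 12.0, 24.0)
        ]
        per_rep, mean = enrichment_matrix(_table(rows), "ref", 0.5)
        E = per_rep[1]
        assert np.allclose(E[0.0], 0.0)
        assert np.allclose(E.loc["ref"], 0.0)
        assert np.allclose(mean.to_numpy(), E.to_numpy())

    def test_noise_free_closed_form(self):
        model = CompetitionModel(
            genotypes=["ref", "mut"], s={"ref": 0.0, "mut": 0.01},
            reference="ref", stochastic_bottleneck=False,
            stochastic_reads=False, replicates=1,
        )
        counts = simulate_pool(model)
        _, mean = enrichment_matrix(counts, "ref", 0)
        assert np.isclose(mean.loc["mut", 72.0], 0.72)  # s * t

    def test_missing_t0_rejected(self):
        counts = _table([("a", 1, 12.0, 5), ("ref", 1, 12.0, 5),
                         ("a", 1, 24.0, 5), ("ref", 1, 24.0, 5)])
        with pytest.raises(FitnessError, match="t0"):
            enrichment_matrix(counts, "ref", 0.5)


class TestPairwiseSc:
    def test_constant_5050_gives_zero(self):
        t = np.arange(0, 73, 12.0)
        assert pairwise_sc(t, np.full(t.size, 50.0)) == pytest.approx(0.0)

    def test_exact_logistic_course_inverts_model(self):
        t = np.arange(0, 73, 12.0)
        odds = 2 ** (0.02 * t)
        p = 100 * odds / (1 + odds)
        assert pairwise_sc(t, p) == pytest.approx(0.02)

    def test_saturated_composition_rejected(self):
        t = np.array([0.0, 12.0, 24.0])
        with pytest.raises(FitnessError, match="truncate"):
            pairwise_sc(t, np.array([50.0, 90.0, 100.0]))

    def test_recovers_truth_from_cytometry_simulation(self):
        from phosphoscan.simulate import simulate_pairwise

        s_true = 0.05
        df = simulate_pairwise(s_mut=s_true, seed=21, replicates=3)
        estimates = [
            pairwise_sc(grp["timepoint_h"].to_numpy(),
                        grp["percent_mut"].to_numpy())
            for _, grp in df.groupby("replicate")
        ]
        # binomial counting error at 5000 cells is small; 3 replicates
        assert abs(np.mean(estimates) - s_true) < 0.01
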