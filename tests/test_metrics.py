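import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from imputebench import (
    GenotypePanel,
    ImputationResult,
    MafBins,
    build_accuracy_table,
    concordance_rate,
    maf,
    metric_correlations,
    r2_dose,
    r2_gt,
    rsq_model,
    rsq_model_haploid,
    summarize_by_bin,
)


class TestR2Metrics:
    def test_perfect_imputation_gives_one(self):
        g = np.array([0, 1, 2, 1, 0])
        assert r2_dose(g, g.astype(float)) == pytest.approx(1.0)
        assert r2_gt(g, g) == pytest.approx(1.0)

    def test_constant_prediction_is_na(self):
        g = np.array([0, 1, 2, 1])
        assert np.isnan(r2_dose(g, np.full(4, 1.3)))
        assert np.isnan(r2_gt(g, np.zeros(4, dtype=int)))

    def test_monomorphic_truth_is_na(self):
        assert np.isnan(r2_dose(np.zeros(4, dtype=int), np.array([0.1, 0.4, 0.2, 0.9])))

    @pytest.mark.parametrize(
        "g,d",
        [
            ((0, 1, 2, 1, 0), (0.1, 0.9, 1.8, 1.2, 0.0)),
            ((0, 1, 2, 2), (0.0, 1.0, 1.0, 2.0)),
            ((2, 0, 1, 1, 2, 0), (1.7, 0.3, 0.8, 1.1, 2.0, 0.2)),
        ],
    )
    def test_matches_independent_pearson(self, g, d):
        want = stats.pearsonr(np.asarray(g, float), np.asarray(d, float))[0] ** 2
        assert r2_dose(g, d) == pytest.approx(want, abs=1e-12)

    def test_r2_gt_example_matches_oracle(self):
        g, b = np.array([0, 1, 2, 2]), np.array([0, 1, 1, 2])
        want = stats.pearsonr(g.astype(float), b.astype(float))[0] ** 2
        assert r2_gt(g, b) == pytest.approx(want, abs=1e-12)

    def test_length_mismatch_and_bad_values(self):
        with pytest.raises(ValueError):
            r2_dose([0, 1], [0.5])
        with pytest.raises(ValueError):
            r2_dose([0, 3, 1], [0.5, 0.5, 0.5])
        with pytest.raises(ValueError):
            r2_dose([0, 1, 1], [0.5, 2.5, 0.5])


class TestConcordance:
    def test_exact_fraction(self):
        assert concordance_rate([0, 1, 2, 1], [0, 1, 1, 1]) == pytest.approx(0.75)
        assert concordance_rate([1], [1]) == 1.0

    def test_monomorphic_all_major_is_perfect_but_r2_undefined(self):
        """CR = 1 for a lost monomorphic marker while the correlation metrics
        are NA - the reason CR overstates rare-variant accuracy."""
        g = np.zeros(6, dtype=int)
        b = np.zeros(6, dtype=int)
        assert concordance_rate(g, b) == 1.0
        assert np.isnan(r2_gt(g, b))


class TestRsqModel:
    def test_constant_dosage_is_zero(self):
        assert rsq_model(np.full(8, 0.7)) == 0.0

    def test_constant_at_bounds_is_na(self):
        assert np.isnan(rsq_model(np.zeros(5)))
        assert np.isnan(rsq_model(np.full(5, 2.0)))

    def test_hard_calls_without_hets_saturate_at_one(self):
        d = np.array([0.0, 2.0, 2.0, 0.0, 2.0])
        assert rsq_model(d) == 1.0

    def test_direct_formula_on_mixed_dosages(self):
        d = np.array([0.2, 1.0, 1.1, 1.8])
        p = d.mean() / 2
        want = np.mean((d - d.mean()) ** 2) / (2 * p * (1 - p))
        assert rsq_model(d) == pytest.approx(want, abs=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0, 2, allow_nan=False), min_size=1, max_size=40))
    def test_allele_relabel_invariance(self, d):
        # dosages on a 1e-6 grid so that 2 - d is exactly representable and the
        # boundary checks (p in {0, 1}) see the same configuration either way
        d = np.round(np.asarray(d), 6)
        a, b = rsq_model(d), rsq_model(2.0 - d)
        assert (np.isnan(a) and np.isnan(b)) or a == pytest.approx(b, abs=1e-9)

    def test_haploid_form(self):
        hd = np.array([0.0, 1.0, 1.0, 0.0])
        assert rsq_model_haploid(hd) == 1.0
        assert rsq_model_haploid(np.full(4, 0.5)) == 0.0


class TestMaf:
    @pytest.mark.parametrize(
        "g,want", [((0, 0, 0), 0.0), ((1, 1, 1, 1), 0.5), ((0, 1, 2, 0), 0.375)]
    )
    def test_examples(self, g, want):
        assert maf(g) == pytest.approx(want)

    def test_missing_ignored(self):
        assert maf([0, 1, 2, 0, -1]) == pytest.approx(0.375)


def _toy_result(truth, dosages=None, best=None, rsq=None):
    d = truth.genotypes.astype(float) if dosages is None else dosages
    b = truth.genotypes if best is None else best
    r = np.full(truth.n_markers, np.nan) if rsq is None else rsq
    return ImputationResult(truth.markers, truth.samples, d, b, r)


class TestAccuracyTable:
    def test_identity_imputation_is_perfect(self, tiny_panel):
        panel, _ = tiny_panel
        table = build_accuracy_table(panel, _toy_result(panel))
        # perfect best guess: CR is 1 everywhere and r2_gt is 1 wherever defined
        assert np.allclose(table["cr"], 1.0)
        r2 = table["r2_gt"].to_numpy()
        assert np.allclose(r2[np.isfinite(r2)], 1.0)
        variable = panel.genotypes.max(axis=1) > panel.genotypes.min(axis=1)
        assert np.isfinite(r2[variable]).all()

    def test_metrics_depend_only_on_evaluated_subset(self, tiny_panel):
        panel, _ = tiny_panel
        rng = np.random.default_rng(3)
        dosages = np.clip(panel.genotypes + rng.normal(0, 0.3, panel.genotypes.shape), 0, 2)
        result = _toy_result(panel, dosages=dosages)
        sub_ids = ["s1", "s3"]
        table = build_accuracy_table(panel, result, sub_ids)
        direct = build_accuracy_table(
            panel.subset_samples(sub_ids), result.subset_samples(sub_ids)
        )
        pd.testing.assert_frame_equal(table, direct)
        assert (table["n_samples"] == 2).all()

    def test_monomorphic_truth_with_variable_dosage(self):
        truth = GenotypePanel(["m"], ["a", "b", "c"], np.zeros((1, 3), dtype=np.int8))
        result = ImputationResult(
            ["m"], ["a", "b", "c"],
            np.array([[0.1, 0.9, 0.2]]), np.array([[0, 1, 0]], dtype=np.int8),
            np.array([np.nan]),
        )
        table = build_accuracy_table(truth, result)
        assert np.isnan(table.loc[0, "r2_dose"])
        assert table.loc[0, "cr"] == pytest.approx(2 / 3)

    def test_reported_rsq_preferred_recompute_on_request(self, tiny_panel):
        panel, _ = tiny_panel
        rsq = np.linspace(0.1, 0.6, panel.n_markers)
        result = _toy_result(panel, rsq=rsq)
        reported = build_accuracy_table(panel, result)
        np.testing.assert_allclose(reported["rsq_model"], rsq)
        recomputed = build_accuracy_table(panel, result, rsq_source="recompute")
        want = [rsq_model(row.astype(float)) for row in panel.genotypes]
        np.testing.assert_allclose(recomputed["rsq_model"], want)

    def test_no_shared_markers_raises(self, tiny_panel):
        panel, _ = tiny_panel
        other = ImputationResult(
            ["zzz"], panel.samples, np.zeros((1, 4)), np.zeros((1, 4), dtype=np.int8),
            np.array([np.nan]),
        )
        with pytest.raises(ValueError, match="share no markers"):
            build_accuracy_table(panel, other)


class TestBinsAndCorrelations:
    def _table(self):
        return pd.DataFrame(
            {
                "marker_id": [f"m{i}" for i in range(6)],
                "maf_true": [0.01, 0.03, 0.10, 0.25, 0.0, 0.40],
                "r2_dose": [0.5, np.nan, 0.8, 1.0, np.nan, 0.9],
                "r2_gt": [0.4, 0.6, 0.7, 1.0, np.nan, 0.8],
                "cr": [1.0, 0.9, 0.8, 1.0, 1.0, 0.95],
                "rsq_model": [0.6, 0.7, 0.75, 0.95, np.nan, 0.85],
                "n_samples": [10] * 6,
            }
        )

    def test_bin_assignment_edges(self):
        bins = MafBins()
        labels = bins.assign([0.0, 0.01, 0.02, 0.049, 0.05, 0.5])
        assert labels[0] is None
        assert list(labels[1:]) == [
            "rare", "low_frequency", "low_frequency", "common", "common",
        ]

    def test_single_bin_equals_global_mean(self):
        table = self._table()
        bins = MafBins(edges=(0.0, 0.5), labels=("all",))
        out = summarize_by_bin(table, bins).set_index("bin")
        # maf=0 marker is in the global row but no bin
        assert out.loc["global", "mean_cr"] == pytest.approx(table["cr"].mean())
        assert out.loc["all", "n_markers"] == 5

    def test_bin_mean_and_na_handling(self):
        table = self._table()
        out = summarize_by_bin(table).set_index("bin")
        assert out.loc["common", "mean_r2_dose"] == pytest.approx(np.mean([0.8, 1.0, 0.9]))
        # rare+low_frequency bins carry one NA r2_dose between them
        assert out.loc["low_frequency", "n_r2_dose"] == 0
        assert out.loc["rare", "mean_r2_dose"] == pytest.approx(0.5)
        assert out.loc["global", "n_r2_dose"] == 4

    def test_correlation_with_itself_is_one(self):
        table = self._table()
        table["rsq_model"] = table["r2_dose"]
        out = metric_correlations(table, maf_min=0.0).set_index("metric")
        assert out.loc["r2_dose", "correlation"] == pytest.approx(1.0)

    def test_constant_rsq_gives_na(self):
        table = self._table()
        table["rsq_model"] = 0.5
        out = metric_correlations(table, maf_min=0.0).set_index("metric")
        assert np.isnan(out.loc["r2_dose", "correlation"])

    def test_matches_numpy_oracle_with_maf_filter(self):
        table = self._table()
        out = metric_correlations(table, maf_min=0.05).set_index("metric")
        sub = table[table["maf_true"] >= 0.05]
        want = np.corrcoef(sub["rsq_model"], sub["cr"])[0, 1]
        assert out.loc["cr", "correlation"] == pytest.approx(want, abs=1e-12)

    def test_too_few_markers_raises(self):
        with pytest.raises(ValueError):
            metric_correlations(self._table(), maf_min=0.45)
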