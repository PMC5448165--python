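"""Empirical null, z-scores, FDR calibration and filter tests."""

import numpy as np
import pandas as pd
import pytest

from erk_decode.de_caller import (
    build_empirical_null,
    call_regulated,
    classify_primary,
    secondary_filters,
    threshold_for_fdr,
    z_scores,
)
from erk_decode.errors import DegenerateNullError, InsufficientReplicationError
from erk_decode.io_formats import ExpressionMatrix
from erk_decode.synthetic_data import default_variance


def _matrix(values, columns, genes=None):
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    vdf = pd.DataFrame(values, index=genes, columns=columns)
    meta = pd.DataFrame([c.rsplit("_", 2) for c in columns], index=columns,
                        columns=["condition", "time", "replicate"])
    meta["time"] = meta["time"].astype(float)
    meta["replicate"] = meta["replicate"].astype(int)
    return ExpressionMatrix(values=vdf, samples=meta)


def _replicated_null_matrix(rng, n_genes=10_000, n_reps=3):
    """Pure-null matrix: anchor triplicate + UT triplicate, level-dependent noise."""
    level = rng.uniform(4.0, 12.0, n_genes)
    sd = np.sqrt(default_variance(level))
    cols = [f"UT_0_{r}" for r in (1, 2, 3)]
    cols += [f"ON_120_{r}" for r in range(1, n_reps + 1)]
    vals = level[:, None] + rng.normal(0, 1, (n_genes, len(cols))) * sd[:, None]
    return _matrix(vals, cols), level, sd


class TestBuildEmpiricalNull:
    def test_recovers_level_dependent_variance(self, rng):
        matrix, level, sd = _replicated_null_matrix(rng)
        null = build_empirical_null(matrix, "ON", time=120.0, window=2000)
        # compare at interior ranks only (moving average is truncated at edges)
        interior = slice(2000, 8000)
        truth = default_variance(null.ranked_means[interior])
        rel = np.abs(null.variance_curve[interior] - truth) / truth
        assert np.median(rel) < 0.15
        assert np.quantile(rel, 0.9) < 0.15

    def test_window_one_gives_raw_variances(self, rng):
        matrix, _, _ = _replicated_null_matrix(rng, n_genes=50)
        null = build_empirical_null(matrix, "ON", time=120.0, window=1)
        sub = matrix.values[[c for c in matrix.values.columns
                             if c.startswith("ON")]]
        raw = np.sort(sub.var(axis=1, ddof=1).to_numpy())
        order = np.argsort(sub.mean(axis=1).to_numpy(), kind="stable")
        assert np.allclose(null.variance_curve,
                           sub.var(axis=1, ddof=1).to_numpy()[order])

    def test_identical_replicates_flagged_degenerate(self):
        vals = np.tile(np.array([[8.0], [5.0]]), (1, 6))
        matrix = _matrix(vals, ["UT_0_1", "UT_0_2", "UT_0_3",
                                "ON_120_1", "ON_120_2", "ON_120_3"])
        null = build_empirical_null(matrix, "ON", time=120.0, window=1)
        assert null.degenerate
        with pytest.raises(DegenerateNullError):
            null.variance_at(6.0)

    def test_insufficient_replicates(self):
        matrix = _matrix(np.ones((3, 2)), ["UT_0_1", "ON_120_1"])
        with pytest.raises(InsufficientReplicationError):
            build_empirical_null(matrix, "ON", time=120.0)


class TestZScores:
    def test_null_z_has_unit_sd(self, rng):
        matrix, _, _ = _replicated_null_matrix(rng)
        null = build_empirical_null(matrix, "ON", time=120.0)
        z = z_scores(matrix, null)
        assert abs(z.to_numpy().std() - 1.0) < 0.05

    def test_zero_when_equal_to_baseline_mean(self, rng):
        matrix, _, _ = _replicated_null_matrix(rng, n_genes=100)
        base = matrix.values[["UT_0_1", "UT_0_2", "UT_0_3"]].mean(axis=1)
        matrix.values["ON_120_1"] = base
        null = build_empirical_null(matrix, "ON", time=120.0, window=10)
        z = z_scores(matrix, null)
        assert np.allclose(z["ON_120_1"], 0.0, atol=1e-12)

    def test_scaled_deviation_gives_that_z(self, rng):
        """A deviation of exactly 5.6 difference-SDs scores z = 5.6."""
        from erk_decode.de_caller import NullModel

        matrix, _, _ = _replicated_null_matrix(rng, n_genes=50)
        variance = 0.04
        null = NullModel(ranked_means=np.array([0.0, 20.0]),
                         variance_curve=np.array([variance, variance]),
                         window=1, n_replicates=3)
        base = matrix.values[["UT_0_1", "UT_0_2", "UT_0_3"]].mean(axis=1)
        sd_diff = np.sqrt(variance * (1 + 1 / 3))
        matrix.values["ON_120_1"] = base + 5.6 * sd_diff
        z = z_scores(matrix, null)
        assert np.allclose(z["ON_120_1"], 5.6, atol=1e-12)


class TestThresholdForFdr:
    def test_fdr_curve_monotone_and_threshold_finite(self, rng):
        matrix, level, sd = _replicated_null_matrix(rng, n_genes=4000)
        # spike 100 induced genes
        idx = matrix.values.index[:100]
        on_cols = [c for c in matrix.values.columns if c.startswith("ON")]
        matrix.values.loc[idx, on_cols] += 4.0
        null = build_empirical_null(matrix, "ON", time=120.0)
        z = z_scores(matrix, null)
        thr, table = threshold_for_fdr(matrix, null, z, "ON",
                                       anchor_time=120.0, target_fdr=0.01)
        assert np.isfinite(thr)
        assert (np.diff(table["fdr"]) <= 1e-12).all()

    def test_unachievable_target_returns_inf(self, rng):
        matrix, _, _ = _replicated_null_matrix(rng, n_genes=500)
        null = build_empirical_null(matrix, "ON", time=120.0)
        z = z_scores(matrix, null)
        with pytest.warns(UserWarning, match="no threshold"):
            thr, _ = threshold_for_fdr(matrix, null, z, "ON",
                                       anchor_time=120.0, target_fdr=1e-9,
                                       thresholds=[0.5, 1.0])
        assert np.isinf(thr)

    def test_requires_exactly_three_replicates(self, rng):
        matrix, _, _ = _replicated_null_matrix(rng, n_genes=50, n_reps=4)
        null = build_empirical_null(matrix, "ON", time=120.0, window=10)
        z = z_scores(matrix, null)
        with pytest.raises(InsufficientReplicationError):
            threshold_for_fdr(matrix, null, z, "ON", anchor_time=120.0)


class TestCallRegulated:
    def test_directions(self):
        z = pd.DataFrame({"s1": [7.1, -6.0, 1.0], "s2": [2.0, 2.0, -2.0]},
                         index=["up_g", "down_g", "flat_g"])
        calls = call_regulated(z, 5.6)
        assert calls.loc["up_g", "direction"] == "up"
        assert calls.loc["down_g", "direction"] == "down"
        assert calls.loc["flat_g", "direction"] == "none"
        assert not calls.loc["flat_g", "is_regulated"]

    def test_gene_permutation_invariance(self, rng):
        matrix, _, _ = _replicated_null_matrix(rng, n_genes=300)
        null = build_empirical_null(matrix, "ON", time=120.0, window=100)
        z = z_scores(matrix, null)
        calls = call_regulated(z, 2.0)
        perm = rng.permutation(matrix.values.index.to_numpy())
        matrix2 = ExpressionMatrix(values=matrix.values.loc[perm],
                                   samples=matrix.samples)
        null2 = build_empirical_null(matrix2, "ON", time=120.0, window=100)
        z2 = z_scores(matrix2, null2)
        calls2 = call_regulated(z2, 2.0)
        assert calls2.loc[calls.index, "is_regulated"].equals(
            calls["is_regulated"])

    def test_pure_null_calls_rare_at_paper_threshold(self, rng):
        matrix, _, _ = _replicated_null_matrix(rng)
        null = build_empirical_null(matrix, "ON", time=120.0)
        z = z_scores(matrix, null)
        frac = call_regulated(z, 5.6)["is_regulated"].mean()
        assert frac <= 1e-3


class TestSecondaryFilters:
    def test_transient_and_constant_genes_dropped(self, small_dataset,
                                                  small_null):
        matrix, truth = small_dataset
        values = matrix.values.copy()
        on_cols = matrix.samples.index[matrix.samples["condition"] == "ON"]
        on_times = matrix.samples.loc[on_cols, "time"].to_numpy()
        # inject a rise-then-fall gene (peaks at 60 min, back to baseline)
        pulse_shape = 8.0 + 4.0 * np.exp(-((on_times - 60) / 60.0) ** 2)
        values.loc["transient_g"] = 8.0
        values.loc["transient_g", on_cols] = pulse_shape
        # inject a constant gene with an inflated z column (SD ~ 0)
        values.loc["const_g"] = 8.0
        matrix2 = ExpressionMatrix(values=values, samples=matrix.samples)
        calls = pd.DataFrame(
            {"max_abs_z": 10.0, "z_extreme": 10.0, "direction": "up",
             "is_regulated": True},
            index=values.index)
        calls.loc[values.index[:50], ["is_regulated"]] = False
        calls.loc[values.index[:50], "direction"] = "none"
        out = secondary_filters(calls, matrix2, small_null, seed=7)
        assert not out.loc["transient_g", "passed_monotone"]
        assert not out.loc["const_g", "passed_sd"]
        assert out.loc["const_g", "sd_log2fc"] == pytest.approx(0.0)

    def test_small_unregulated_pool_warns(self, small_dataset, small_null):
        matrix, _ = small_dataset
        calls = pd.DataFrame(
            {"max_abs_z": 10.0, "z_extreme": 10.0, "direction": "up",
             "is_regulated": True},
            index=matrix.values.index)
        calls.iloc[:3, calls.columns.get_loc("is_regulated")] = False
        with pytest.warns(UserWarning, match="replacement"):
            secondary_filters(calls, matrix, small_null, seed=7)


class TestClassifyPrimary:
    def _calls(self):
        return pd.DataFrame(
            {"direction": ["up", "up", "down"],
             "is_regulated": [True, True, True]},
            index=["prim", "sec", "down_g"])

    def test_cyhx_induction_defines_primary(self):
        z_cyhx = pd.DataFrame({"ONCYHX_120_1": [8.0, 1.0, -7.0]},
                              index=["prim", "sec", "down_g"])
        out = classify_primary(self._calls(), z_cyhx, threshold=5.6)
        assert out.loc["prim", "is_primary"] == True  # noqa: E712
        assert out.loc["sec", "is_primary"] == False  # noqa: E712
        assert out.loc["down_g", "is_primary"] == True  # noqa: E712

    def test_missing_cyhx_leaves_flag_undefined(self):
        out = classify_primary(self._calls(), None)
        assert out["is_primary"].isna().all()
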