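"""Empirical-null differential-expression calling.

Replicates of a single anchor condition provide an expression-level-dependent
variance model: genes are ranked by their mean expression across the anchor
replicates and a moving average of the per-gene replicate variances serves as
the expected variance at a given expression level.  Fold changes against the
untreated baseline are standardized into z-scores with this model; the false
discovery rate of a |z| threshold is estimated from leave-one-out contrasts
within the anchor replicates (one replicate against the mean of the others).

Regulated genes then pass two secondary filters: a fold-change
standard-deviation filter calibrated on a size-matched random sample of
unregulated genes, and a monotonicity filter on the sustained-induction
trajectory.  Genes still induced under cycloheximide co-treatment are flagged
as primary response genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateNullError, InsufficientReplicationError

__all__ = [
    "Z_CUTOFF",
    "NullModel",
    "build_empirical_null",
    "z_scores",
    "threshold_for_fdr",
    "call_regulated",
    "secondary_filters",
    "classify_primary",
]

#: |z| threshold used for regulation calls (paper operating point, FDR ~1%).
Z_CUTOFF = 5.6

#: Default moving-average window (genes) of the variance model.
DEFAULT_WINDOW = 2000


@dataclass
class NullModel:
    """Expression-level-dependent variance model.

    ``variance_curve[i]`` is the smoothed expected per-observation variance
    for a gene whose mean expression equals ``ranked_means[i]``; lookups
    interpolate linearly between ranked neighbours (clamped at the ends).
    """

    ranked_means: np.ndarray
    variance_curve: np.ndarray
    window: int
    n_replicates: int

    @property
    def degenerate(self) -> bool:
        return bool(np.any(self.variance_curve <= 0))

    def variance_at(self, level):
        """Expected variance at the given expression level(s)."""
        if self.degenerate:
            raise DegenerateNullError(
                "variance model contains non-positive values")
        return np.interp(level, self.ranked_means, self.variance_curve)


def _moving_average_truncated(x: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average, truncated (not padded) at the edges."""
    n = x.size
    half_lo = (window - 1) // 2
    half_hi = window // 2
    csum = np.concatenate(([0.0], np.cumsum(x)))
    idx = np.arange(n)
    lo = np.maximum(idx - half_lo, 0)
    hi = np.minimum(idx + half_hi, n - 1)
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)


def build_empirical_null(matrix, replicate_condition: str, time=None,
                         window: int = DEFAULT_WINDOW) -> NullModel:
    """Build the variance model from the replicates of one condition.

    Genes are ranked by their mean across the chosen replicates; the
    expected variance at each rank is the centred moving average of the
    per-gene unbiased replicate variances.
    """
    samples = matrix.samples
    mask = samples["condition"] == replicate_condition
    if time is not None:
        mask &= samples["time"] == time
    cols = samples.index[mask]
    if len(cols) < 2:
        raise InsufficientReplicationError(
            f"condition {replicate_condition!r} has {len(cols)} replicate(s); "
            "need >= 2 to estimate variance")
    sub = matrix.values[cols].to_numpy()
    n_genes = sub.shape[0]
    if window > n_genes:
        warnings.warn(f"window {window} > {n_genes} genes; shrunk to gene count")
        window = n_genes
    means = sub.mean(axis=1)
    variances = sub.var(axis=1, ddof=1)
    order = np.argsort(means, kind="stable")
    curve = _moving_average_truncated(variances[order], window)
    return NullModel(ranked_means=means[order], variance_curve=curve,
                     window=window, n_replicates=len(cols))


def _baseline_columns(matrix, baseline_condition: str):
    cols = matrix.samples.index[matrix.samples["condition"] == baseline_condition]
    if len(cols) == 0:
        raise ValueError(f"no baseline samples with condition {baseline_condition!r}")
    return list(cols)


def z_scores(matrix, null: NullModel, baseline_condition: str = "UT") -> pd.DataFrame:
    """Standardize each sample's deviation from the untreated baseline.

    z_ij = (p_ij - mean_baseline_i) / sqrt(v(level_i) * (1 + 1/n_baseline)),
    where v is the expected per-observation variance at the gene's mean
    expression level across all samples.  The (1 + 1/n) factor accounts for
    the sampling noise of the baseline mean, so z has unit variance under
    the null.
    """
    base_cols = _baseline_columns(matrix, baseline_condition)
    other_cols = [c for c in matrix.values.columns if c not in base_cols]
    values = matrix.values
    baseline_mean = values[base_cols].mean(axis=1)
    level = values.mean(axis=1)
    denom = np.sqrt(null.variance_at(level.to_numpy())
                    * (1.0 + 1.0 / len(base_cols)))
    z = values[other_cols].sub(baseline_mean, axis=0).div(denom, axis=0)
    return z


def threshold_for_fdr(matrix, null: NullModel, z: pd.DataFrame,
                      anchor_condition: str, anchor_time=None,
                      target_fdr: float = 0.01,
                      thresholds=None):
    """Pick the smallest |z| threshold with estimated FDR <= target.

    False positives at each candidate threshold are counted from
    leave-one-out contrasts within the three anchor replicates (each
    replicate against the mean of the other two, standardized with the same
    variance model and a (1 + 1/2) factor), averaged over the three
    rotations.  FDR(threshold) = expected FP / genes called at that
    threshold in the real contrasts; the curve is monotonized with a
    running minimum so larger thresholds never report a larger FDR.

    Returns ``(threshold, table)`` where the table holds per-threshold
    expected FP counts, call counts and the monotonized FDR.  If no
    threshold achieves the target, the threshold is +inf (0 calls).
    """
    if not (0 < target_fdr < 1):
        raise ValueError("target_fdr must be in (0, 1)")
    samples = matrix.samples
    mask = samples["condition"] == anchor_condition
    if anchor_time is not None:
        mask &= samples["time"] == anchor_time
    cols = list(samples.index[mask])
    if len(cols) != 3:
        raise InsufficientReplicationError(
            "leave-one-out FDR estimation requires exactly 3 anchor "
            f"replicates, found {len(cols)}")
    sub = matrix.values[cols].to_numpy()
    level = matrix.values.mean(axis=1).to_numpy()
    denom = np.sqrt(null.variance_at(level) * (1.0 + 0.5))
    loo = np.empty_like(sub)
    for i in range(3):
        others = [j for j in range(3) if j != i]
        loo[:, i] = (sub[:, i] - sub[:, others].mean(axis=1)) / denom

    max_abs_z = z.abs().max(axis=1).to_numpy()
    if thresholds is None:
        thresholds = np.arange(0.0, 20.0001, 0.05)
    thresholds = np.asarray(thresholds, dtype=float)

    abs_loo = np.abs(loo)
    # per-rotation gene-level FP counts, averaged over the three rotations
    fp = np.array([np.mean([(abs_loo[:, i] > t).sum() for i in range(3)])
                   for t in thresholds])
    called = np.array([(max_abs_z > t).sum() for t in thresholds])
    raw = np.where(called > 0, fp / np.maximum(called, 1), 0.0)
    # conservative monotonization: FDR at a threshold is the worst raw
    # estimate at or above it, so the curve is non-increasing in threshold
    fdr = np.maximum.accumulate(raw[::-1])[::-1]

    table = pd.DataFrame({"threshold": thresholds, "expected_fp": fp,
                          "n_called": called, "fdr": fdr})
    ok = fdr <= target_fdr
    if not ok.any():
        warnings.warn("no threshold achieves the target FDR; returning +inf")
        return np.inf, table
    return float(thresholds[np.argmax(ok)]), table


def call_regulated(z: pd.DataFrame, threshold: float = Z_CUTOFF,
                   conditions=None, sample_conditions=None) -> pd.DataFrame:
    """Call a gene regulated if any sample exceeds |z| > threshold.

    Direction is the sign of the most extreme z.  ``conditions`` restricts
    the scored samples; ``sample_conditions`` maps sample name -> condition
    (needed only when restricting).
    """
    if not (threshold > 0):
        raise ValueError("threshold must be > 0")
    cols = list(z.columns)
    if conditions is not None:
        cols = [c for c in cols if sample_conditions[c] in set(conditions)]
    sub = z[cols]
    idx_extreme = sub.abs().to_numpy().argmax(axis=1)
    z_extreme = sub.to_numpy()[np.arange(len(sub)), idx_extreme]
    max_abs = np.abs(z_extreme)
    regulated = max_abs > threshold
    direction = np.where(~regulated, "none",
                         np.where(z_extreme > 0, "up", "down"))
    return pd.DataFrame({
        "gene": sub.index,
        "max_abs_z": max_abs,
        "z_extreme": z_extreme,
        "direction": direction,
        "is_regulated": regulated,
    }).set_index("gene")


def secondary_filters(calls: pd.DataFrame, matrix, null: NullModel,
                      sd_fdr: float = 0.05, baseline_condition: str = "UT",
                      on_condition: str = "ON", monotone_tolerance_sd: float = 3.0,
                      seed: int = 20170503) -> pd.DataFrame:
    """Apply the fold-change-SD and monotonicity filters to regulated genes.

    The SD filter drops regulated genes whose log2 fold-change standard
    deviation across all non-baseline samples falls below a cut-off chosen
    so that a fraction ``sd_fdr`` of a size-matched random sample of
    unregulated genes would pass.  The monotonicity filter keeps a gene iff
    its replicate-mean trajectory under sustained induction is monotone in
    the called direction within tolerance: each step may move against the
    trend by at most ``monotone_tolerance_sd`` expected step-SDs, where the
    step SD comes from the smoothed variance model at the gene's level
    (sqrt(2 * v)).  Real rise-then-fall shapes drop by several step-SDs and
    are rejected; replicate noise on a plateau is not.
    """
    if calls.empty:
        raise ValueError("calls table is empty")
    rng = np.random.default_rng(seed)
    base_cols = _baseline_columns(matrix, baseline_condition)
    other_cols = [c for c in matrix.values.columns if c not in base_cols]
    log2fc = matrix.values[other_cols].sub(
        matrix.values[base_cols].mean(axis=1), axis=0)
    sd_log2fc = log2fc.std(axis=1, ddof=1)

    regulated = calls.index[calls["is_regulated"]]
    unregulated = calls.index[~calls["is_regulated"]]
    n = len(regulated)
    if n == 0:
        out = calls.copy()
        out["sd_log2fc"] = sd_log2fc
        out["passed_sd"] = False
        out["passed_monotone"] = False
        return out
    if len(unregulated) >= n:
        pool = rng.choice(unregulated.to_numpy(), size=n, replace=False)
    else:
        warnings.warn("unregulated pool smaller than regulated set; "
                      "sampling with replacement")
        pool = rng.choice(unregulated.to_numpy(), size=n, replace=True)
    cutoff = np.quantile(sd_log2fc.loc[pool].to_numpy(), 1.0 - sd_fdr)
    passed_sd = sd_log2fc >= cutoff

    # monotonicity in the sustained condition, anchored at the baseline mean
    samples_on = matrix.samples[matrix.samples["condition"] == on_condition]
    on_times = np.sort(samples_on["time"].unique())
    traj = pd.concat(
        [matrix.values[base_cols].mean(axis=1).rename(0.0)] +
        [matrix.values[samples_on.index[samples_on["time"] == t]]
         .mean(axis=1).rename(float(t)) for t in on_times],
        axis=1)
    level = matrix.values.mean(axis=1).to_numpy()
    step_sd = pd.Series(np.sqrt(2.0 * null.variance_at(level)),
                        index=matrix.values.index)
    tol = monotone_tolerance_sd * step_sd
    diffs = traj.diff(axis=1).iloc[:, 1:]
    up_ok = diffs.gt(-tol, axis=0).all(axis=1)
    down_ok = diffs.lt(tol, axis=0).all(axis=1)
    passed_mono = pd.Series(False, index=calls.index)
    passed_mono[calls["direction"] == "up"] = up_ok
    passed_mono[calls["direction"] == "down"] = down_ok

    out = calls.copy()
    out["sd_log2fc"] = sd_log2fc
    out["sd_cutoff"] = cutoff
    out["passed_sd"] = calls["is_regulated"] & passed_sd
    out["passed_monotone"] = calls["is_regulated"] & passed_mono
    out["is_regulated"] = (calls["is_regulated"] & passed_sd & passed_mono)
    return out


def classify_primary(calls: pd.DataFrame, z_cyhx: pd.DataFrame | None,
                     threshold: float = Z_CUTOFF) -> pd.DataFrame:
    """Flag regulated genes still induced under cycloheximide as primary.

    A gene is primary iff any cycloheximide-co-treatment sample shows a
    sign-matched z beyond the threshold.  With no cycloheximide data the
    flag is left missing, not False.
    """
    out = calls.copy()
    if z_cyhx is None or z_cyhx.shape[1] == 0:
        out["is_primary"] = pd.Series(pd.NA, index=out.index, dtype="boolean")
        return out
    zc = z_cyhx.reindex(out.index)
    up_hit = (zc > threshold).any(axis=1)
    down_hit = (zc < -threshold).any(axis=1)
    is_primary = pd.Series(False, index=out.index, dtype="boolean")
    is_primary[(out["direction"] == "up") & up_hit] = True
    is_primary[(out["direction"] == "down") & down_hit] = True
    is_primary[~out["is_regulated"]] = False
    out["is_primary"] = is_primary
    return out
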