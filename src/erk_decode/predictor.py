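"""Prediction under new signalling inputs and signal-duration decode capacity.

Fitted per-gene parameters are transferable across signalling scenarios:
given a measured pERK time course, an input function is deduced by
normalizing the replicate-mean pERK2 log2 fold change to the mean induction
of the training (sustained) condition and linearly interpolating; feeding
that input to the model from the basal steady state predicts each gene's
log2 fold change trajectory.

Decode capacity quantifies how strongly a gene's maximal relative amplitude
depends on signal duration: long-lived transcripts (ILGs) integrate the
signal and reach high amplitude only under long inputs, so their
long/short-scenario amplitude ratio is large.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import NormalizationError
from .kinetic_model import (
    GeneParams,
    PiecewiseInput,
    relative_amplitude,
    solve_expression,
)

__all__ = [
    "deduce_input",
    "predict_log2fc",
    "prediction_error",
    "decode_capacity",
]

#: Mean pERK2 log2 fold change of the sustained training condition.
DEFAULT_TRAINING_MEAN = 3.89


def deduce_input(perk=None, training_mean: float = DEFAULT_TRAINING_MEAN,
                 scenario: str | None = None,
                 pulse_duration: float = 120.0) -> PiecewiseInput:
    """Turn measured or named pERK activity into a model input function.

    ``scenario="sustained"`` gives the unit step (pERK = 1 for t > 0);
    ``scenario="pulse"`` a unit pulse of ``pulse_duration`` minutes.  With a
    measured table instead, the replicate-mean log2 fold change at each time
    is divided by ``training_mean`` (100% signalling amplitude), clamped
    below at 0, linearly interpolated, and held constant after the last
    time point.
    """
    if scenario == "sustained":
        return PiecewiseInput.sustained()
    if scenario == "pulse":
        return PiecewiseInput.pulse(pulse_duration)
    if scenario is not None:
        raise ValueError(f"unknown scenario {scenario!r}")
    if not (training_mean > 0):
        raise NormalizationError("training-condition mean must be > 0")
    df = perk.data if hasattr(perk, "data") else perk
    if df is None or len(df) == 0:
        raise ValueError("no pERK measurements supplied")
    means = df.groupby("time")["log2fc"].mean().sort_index()
    if len(means) < 2:
        raise ValueError("measured input needs >= 2 time points")
    values = np.clip(means.to_numpy() / training_mean, 0.0, None)
    return PiecewiseInput(times=tuple(means.index.to_numpy(dtype=float)),
                          values=tuple(values), mode="linear",
                          before_first=0.0)


def predict_log2fc(params: GeneParams, input: PiecewiseInput,
                   times) -> np.ndarray:
    """Predicted log2 fold change: model from basal steady state minus k0/gamma."""
    traj = solve_expression(params, input, times, initial="steady")
    return traj - params.basal_ss


def prediction_error(predicted, observed, observed_times=None,
                     predicted_times=None):
    """Mean of absolute residuals and its scale-free counterpart.

    Predictions must be evaluated at the observed times (no interpolation of
    the observations).  ``relative_error`` = mean_error / max |observed|,
    defined only when that maximum is positive.
    """
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted_times is not None and observed_times is not None:
        observed_times = np.asarray(observed_times, dtype=float)
        predicted_times = np.asarray(predicted_times, dtype=float)
        idx = {t: i for i, t in enumerate(predicted_times)}
        if not all(t in idx for t in observed_times):
            raise ValueError("predictions missing at some observed times; "
                             "evaluate the model at the observed grid")
        predicted = predicted[[idx[t] for t in observed_times]]
    if predicted.shape[0] != observed.shape[0]:
        raise ValueError("predicted/observed length mismatch")
    mean_error = float(np.mean(np.abs(observed - predicted)))
    max_obs = float(np.max(np.abs(observed))) if observed.size else 0.0
    relative_error = mean_error / max_obs if max_obs > 0 else np.nan
    return mean_error, relative_error


def decode_capacity(fits: pd.DataFrame, scenarios: dict,
                    scenario_pair=("sustained", "pulse120"),
                    times=None) -> pd.DataFrame:
    """Maximum relative amplitude per scenario and the long/short ratio.

    ``fits`` must carry columns k0, k, gamma, delta_t and class; scenarios
    map names to PiecewiseInput.  Genes with undefined amplitude (k = 0) are
    skipped with a warning.
    """
    if times is None:
        times = np.linspace(0.0, 600.0, 241)
    times = np.asarray(times, dtype=float)
    long_name, short_name = scenario_pair
    rows = []
    for gene, row in fits.iterrows():
        if not (row["k"] > 0):
            warnings.warn(f"gene {gene}: k = 0, amplitude undefined; skipped")
            continue
        params = GeneParams(k0=row["k0"], k=row["k"], gamma=row["gamma"],
                            delta_t=row["delta_t"])
        rec = {"gene": gene, "class": row.get("class", "")}
        for name, inp in scenarios.items():
            traj = solve_expression(params, inp, times)
            rec[f"max_amplitude_{name}"] = float(
                relative_amplitude(traj, params).max())
        short_amp = rec[f"max_amplitude_{short_name}"]
        rec["amplitude_ratio"] = (
            rec[f"max_amplitude_{long_name}"] / short_amp
            if short_amp > 0 else np.inf)
        rows.append(rec)
    return pd.DataFrame(rows).set_index("gene") if rows else pd.DataFrame()
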