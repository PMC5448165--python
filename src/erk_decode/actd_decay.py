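"""Half-life estimation from transcription-shutdown (actinomycin D) series.

Quantile normalisation assumes constant total RNA, which transcriptional
shutdown violates; shutdown samples are instead normalised so that the
median log2 expression of a set of long-lived reference mRNAs (half-life
above 16 h) is constant across time points.  Each gene's normalised series
is then converted to linear scale and fitted by least squares to

    M(t) = B + A * exp(-gamma * t)

with amplitude A > 0, offset B >= 0 and decay rate gamma > 0, giving
half-life ln(2)/gamma.  A literal offset-only form M(t) = M0 + exp(-gamma*t)
is selectable for comparison.  Non-decaying series are flagged with an
infinite-half-life sentinel rather than a spurious rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .kinetic_model import LN2

__all__ = ["DecayFit", "normalize_to_longlived", "fit_decay",
           "fit_decay_matrix", "summarize_halflives"]

#: Reference transcripts must exceed this half-life (min) = 16 h.
LONG_LIVED_MIN = 960.0


@dataclass
class DecayFit:
    """Exponential decay fit for one gene."""

    gene: str
    amplitude: float
    offset: float
    gamma: float
    half_life: float
    rss: float
    reliable: bool


def normalize_to_longlived(matrix, reference_genes):
    """Remove per-sample scale shifts using long-lived reference transcripts.

    Subtracts each sample's median log2 expression over the reference set
    and adds back the across-sample mean of those medians, so the reference
    median is identical in every sample while typical expression levels are
    preserved.  Returns a new matrix of the same type.
    """
    present = [g for g in reference_genes if g in matrix.values.index]
    if len(present) < 5:
        raise ValueError(f"only {len(present)} reference genes present; "
                         "need >= 5 for a stable median")
    ref_median = matrix.values.loc[present].median(axis=0)
    shift = ref_median - ref_median.mean()
    new_values = matrix.values.sub(shift, axis=1)
    return type(matrix)(values=new_values, samples=matrix.samples.copy())


def fit_decay(times, log2_values, gene: str = "", form: str = "amplitude") -> DecayFit:
    """Fit an exponential decay to one normalised log2 series.

    The fit runs on the linear scale (2**log2 value).  ``form="amplitude"``
    fits B + A*exp(-gamma*t); ``form="literal"`` fits M0 + exp(-gamma*t).
    Requires >= 4 time points including t = 0.  A series that does not
    decrease overall yields half_life = +inf with ``reliable=False``.
    """
    times = np.asarray(times, dtype=float)
    x = np.asarray(log2_values, dtype=float)
    if times.size < 4:
        raise ValueError("decay fit needs >= 4 time points")
    if times.min() != 0.0:
        raise ValueError("decay series must include the shutdown time t = 0")
    order = np.argsort(times)
    times, x = times[order], x[order]
    y = np.power(2.0, x)

    if y[-1] >= y[0]:  # no net decay: rate not identifiable
        return DecayFit(gene=gene, amplitude=np.nan, offset=np.nan,
                        gamma=0.0, half_life=np.inf, rss=np.nan,
                        reliable=False)

    span = y[0] - y.min()
    # initial decay rate from the time at which half the span is lost
    below = times[y <= y[0] - 0.5 * span]
    t_half0 = below[0] if below.size else times[-1] / 2.0
    gamma0 = LN2 / max(t_half0, 1e-6)
    try:
        if form == "amplitude":
            def model(t, a, b, g):
                return b + a * np.exp(-g * t)
            p0 = (max(span, 1e-9), max(y.min(), 0.0), gamma0)
            bounds = ([0.0, 0.0, 1e-8], [np.inf, np.inf, 10.0])
            popt, _ = curve_fit(model, times, y, p0=p0, bounds=bounds,
                                maxfev=20000)
            a, b, g = popt
        elif form == "literal":
            def model(t, b, g):
                return b + np.exp(-g * t)
            popt, _ = curve_fit(model, times, y,
                                p0=(max(y.min(), 0.0), gamma0),
                                bounds=([0.0, 1e-8], [np.inf, 10.0]),
                                maxfev=20000)
            b, g = popt
            a = 1.0
        else:
            raise ValueError(f"unknown decay form {form!r}")
    except RuntimeError:
        return DecayFit(gene=gene, amplitude=np.nan, offset=np.nan,
                        gamma=0.0, half_life=np.inf, rss=np.nan,
                        reliable=False)
    resid = y - model(times, *popt)
    return DecayFit(gene=gene, amplitude=float(a), offset=float(b),
                    gamma=float(g), half_life=float(LN2 / g),
                    rss=float(np.dot(resid, resid)), reliable=True)


def fit_decay_matrix(matrix, condition: str = "ActD",
                     form: str = "amplitude") -> pd.DataFrame:
    """Fit every gene of a shutdown-condition matrix; one row per gene."""
    samples = matrix.samples
    cols = samples.index[samples["condition"] == condition]
    if len(cols) == 0:
        cols = samples.index
    times = samples.loc[cols, "time"].to_numpy(dtype=float)
    rows = []
    for gene in matrix.values.index:
        fit = fit_decay(times, matrix.values.loc[gene, cols].to_numpy(),
                        gene=gene, form=form)
        rows.append({"gene": gene, "gamma": fit.gamma,
                     "half_life": fit.half_life, "offset": fit.offset,
                     "amplitude": fit.amplitude, "rss": fit.rss,
                     "reliable": fit.reliable})
    return pd.DataFrame(rows).set_index("gene")


def summarize_halflives(estimates: pd.DataFrame) -> pd.DataFrame:
    """Median/mean/SD of half-life estimates across datasets, per gene.

    ``estimates`` is genes x datasets (e.g. model-derived, shutdown ON,
    shutdown OFF, metabolic labelling).  Infinite sentinels and missing
    values are excluded; their count is reported.
    """
    vals = estimates.to_numpy(dtype=float)
    finite = np.isfinite(vals)
    rows = []
    for i, gene in enumerate(estimates.index):
        v = vals[i, finite[i]]
        if v.size == 0:
            rows.append({"gene": gene, "median": np.nan, "mean": np.nan,
                         "sd": np.nan, "n_used": 0,
                         "excluded_count": int((~finite[i]).sum())})
            continue
        rows.append({
            "gene": gene,
            "median": float(np.median(v)),
            "mean": float(np.mean(v)),
            "sd": float(np.std(v, ddof=1)) if v.size > 1 else np.nan,
            "n_used": int(v.size),
            "excluded_count": int((~finite[i]).sum()),
        })
    return pd.DataFrame(rows).set_index("gene")
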