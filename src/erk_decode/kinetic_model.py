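"""Delayed linear ODE model of signal-driven mRNA dynamics.

The model describes a transcript's abundance ``m(t)`` under a time-varying
ERK activity input ``pERK(t)``::

    dm/dt = k0 + k * pERK(t - delta_t) - gamma * m(t)

with basal transcription rate ``k0``, ERK-dependent transcription rate ``k``,
first-order degradation rate ``gamma`` and a transcriptional delay
``delta_t`` that lumps all steps between kinase activation and productive
transcription.  Because the ODE is linear with piecewise-linear forcing, the
solution is computed exactly by piecewise-exponential propagation between
input breakpoints — no numerical integration is needed.

Derived quantities:

* half-life ``t_half = ln(2)/gamma``
* response time ``r = delta_t + t_half`` — the time at which a gene under a
  sustained step input reaches half of its maximal relative amplitude
* relative amplitude — expression rescaled between the basal steady state
  ``k0/gamma`` (0%) and the induced steady state ``(k0+k)/gamma`` (100%).

Temporal classes are defined on the (half-life, delay) plane: genes with a
delay above 30 min are delayed-early genes (DEG); among immediately
transcribed genes, half-lives up to 120 min mark immediate-early genes (IEG)
and longer-lived transcripts immediate-late genes (ILG).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "GeneParams",
    "PiecewiseInput",
    "KineticSummary",
    "ParameterScan",
    "DELAY_THRESHOLD_MIN",
    "HALFLIFE_THRESHOLD_MIN",
    "solve_expression",
    "relative_amplitude",
    "derive_kinetics",
    "classify_param_point",
    "scan_parameter_space",
    "default_scenarios",
]

#: Delay (min) separating delayed-early genes from immediately transcribed ones.
DELAY_THRESHOLD_MIN = 30.0
#: Half-life (min) separating immediate-early from immediate-late genes.
HALFLIFE_THRESHOLD_MIN = 120.0

LN2 = float(np.log(2.0))


@dataclass(frozen=True)
class GeneParams:
    """Kinetic parameters of one gene.

    Parameters
    ----------
    k0 : float
        Basal transcription rate (expression units / min), >= 0.
    k : float
        ERK-dependent transcription rate (expression units / min), >= 0.
    gamma : float
        Degradation rate (1/min), > 0.
    delta_t : float
        Transcriptional delay (min), >= 0.
    """

    k0: float
    k: float
    gamma: float
    delta_t: float = 0.0

    def __post_init__(self) -> None:
        if not (self.gamma > 0):
            raise ValueError(f"gamma must be > 0, got {self.gamma}")
        if self.k0 < 0 or self.k < 0:
            raise ValueError("transcription rates k0, k must be >= 0")
        if self.delta_t < 0:
            raise ValueError("delta_t must be >= 0")

    @property
    def basal_ss(self) -> float:
        """Pre-stimulus steady state k0/gamma."""
        return self.k0 / self.gamma

    @property
    def induced_ss(self) -> float:
        """Steady state under saturating sustained input, (k0+k)/gamma."""
        return (self.k0 + self.k) / self.gamma

    @property
    def half_life(self) -> float:
        return LN2 / self.gamma


@dataclass(frozen=True)
class PiecewiseInput:
    """pERK activity as a piecewise trajectory (fraction of training mean).

    ``mode="step"``: value ``values[i]`` holds on ``[times[i], times[i+1])``.
    ``mode="linear"``: linear interpolation between breakpoints.
    Before the first breakpoint the input equals ``before_first``; after the
    last it holds the last value.
    """

    times: tuple = field(default=(0.0,))
    values: tuple = field(default=(1.0,))
    mode: Literal["step", "linear"] = "step"
    before_first: float = 0.0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or t.size == 0 or t.size != v.size:
            raise ValueError("times and values must be equal-length 1-D")
        if np.any(np.diff(t) <= 0):
            raise ValueError("breakpoint times must be strictly increasing")
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise ValueError("input values must be finite and >= 0")
        if self.mode not in ("step", "linear"):
            raise ValueError(f"unknown input mode {self.mode!r}")
        object.__setattr__(self, "times", tuple(t))
        object.__setattr__(self, "values", tuple(v))

    @classmethod
    def sustained(cls) -> "PiecewiseInput":
        """Unit step: pERK(t) = 1 for t > 0, 0 before."""
        return cls(times=(0.0,), values=(1.0,), mode="step")

    @classmethod
    def pulse(cls, duration: float) -> "PiecewiseInput":
        """Unit pulse of the given duration (min) starting at t = 0."""
        if duration <= 0:
            raise ValueError("pulse duration must be > 0")
        return cls(times=(0.0, float(duration)), values=(1.0, 0.0), mode="step")

    def __call__(self, t):
        """Evaluate the input at time(s) ``t`` (right-continuous for steps)."""
        t = np.asarray(t, dtype=float)
        times = np.asarray(self.times)
        values = np.asarray(self.values)
        if self.mode == "step":
            idx = np.searchsorted(times, t, side="right") - 1
            out = np.where(idx < 0, self.before_first, values[np.clip(idx, 0, None)])
        else:
            out = np.interp(t, times, values)
            out = np.where(t < times[0], self.before_first, out)
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class KineticSummary:
    """Derived per-gene kinetics: half-life, response time and steady states."""

    half_life: float
    response_time: float
    basal_ss: float
    induced_ss: float


def _forcing_segments(inp: PiecewiseInput, delta_t: float, t_end: float):
    """Break [0, t_end] at the delay-shifted input breakpoints.

    Yields (a, b, qa, qb): segment bounds and the (one-sided) input values at
    the segment endpoints; within each open segment the shifted input
    q(t) = pERK(t - delta_t) is linear (constant for step mode).
    """
    shifted = np.asarray(inp.times) + delta_t
    values = np.asarray(inp.values)
    cuts = np.concatenate(([0.0], shifted[(shifted > 0) & (shifted < t_end)], [t_end]))
    cuts = np.unique(cuts)
    segs = []
    for a, b in zip(cuts[:-1], cuts[1:]):
        if inp.mode == "step":
            if a < shifted[0]:
                q = inp.before_first
            else:
                q = values[np.searchsorted(shifted, a, side="right") - 1]
            segs.append((a, b, float(q), float(q)))
        else:
            def one_sided(t, left):
                if (t <= shifted[0]) if left else (t < shifted[0]):
                    return float(inp.before_first)
                if t >= shifted[-1]:
                    return float(values[-1])
                return float(np.interp(t, shifted, values))

            segs.append((a, b, one_sided(a, left=False), one_sided(b, left=True)))
    return segs


def _solve_raw(k0, k, gamma, delta_t, inp: PiecewiseInput, times: np.ndarray, m0: float):
    """Exact solution at sorted query times; no validation (hot path)."""
    n = times.size
    out = np.empty(n)
    if n == 0:
        return out
    t_end = times[-1]
    if t_end == 0.0:
        out[:] = m0
        return out
    m = m0
    for a, b, qa, qb in _forcing_segments(inp, delta_t, t_end):
        # forcing F(t) = C + D*t on [a, b]
        if b > a:
            d_in = (qb - qa) / (b - a)
        else:  # pragma: no cover - degenerate zero-length segment
            d_in = 0.0
        C = k0 + k * (qa - d_in * a)
        D = k * d_in
        # particular solution P(t) = C/g + D*t/g - D/g^2
        p_a = C / gamma + D * a / gamma - D / gamma**2
        sel = (times >= a) & (times <= b)
        if np.any(sel):
            ts = times[sel]
            p_t = C / gamma + D * ts / gamma - D / gamma**2
            out[sel] = p_t + (m - p_a) * np.exp(-gamma * (ts - a))
        p_b = C / gamma + D * b / gamma - D / gamma**2
        m = p_b + (m - p_a) * np.exp(-gamma * (b - a))
    out[times == 0.0] = m0
    return out


def solve_expression(params: GeneParams, input: PiecewiseInput, times,
                     initial="steady") -> np.ndarray:
    """Solve the delayed linear ODE exactly at the query times.

    Parameters
    ----------
    params : GeneParams
    input : PiecewiseInput
        pERK trajectory; the delay is applied by evaluating it at
        ``t - delta_t`` (equal to ``before_first`` for arguments before the
        first breakpoint).
    times : array-like
        Sorted query grid, all >= 0 (min).
    initial : "steady" or float
        Expression at t = 0; "steady" means the pre-stimulus equilibrium
        ``k0/gamma``.

    Returns
    -------
    ndarray of expression values on the same scale as ``k0`` and ``k``.
    """
    times = np.atleast_1d(np.asarray(times, dtype=float))
    if times.size and np.any(times < 0):
        raise ValueError("query times must be >= 0 (t = 0 is stimulation)")
    if times.size > 1 and np.any(np.diff(times) < 0):
        raise ValueError("query times must be sorted ascending")
    m0 = params.basal_ss if initial == "steady" else float(initial)
    return _solve_raw(params.k0, params.k, params.gamma, params.delta_t,
                      input, times, m0)


def relative_amplitude(expression, params: GeneParams) -> np.ndarray:
    """Rescale expression to percent of the basal-to-induced span.

    0% at the basal steady state k0/gamma, 100% at the induced steady state
    (k0+k)/gamma.  Values outside [0, 100] are possible for noisy data and
    are not clamped.
    """
    if params.k <= 0:
        raise ValueError("relative amplitude undefined for k = 0 "
                         "(basal and induced steady states coincide)")
    expression = np.asarray(expression, dtype=float)
    return 100.0 * (expression - params.basal_ss) / (params.k / params.gamma)


def derive_kinetics(params: GeneParams) -> KineticSummary:
    """Half-life ln(2)/gamma, response time delta_t + half-life, steady states."""
    hl = LN2 / params.gamma
    return KineticSummary(
        half_life=hl,
        response_time=params.delta_t + hl,
        basal_ss=params.basal_ss,
        induced_ss=params.induced_ss,
    )


def classify_param_point(half_life: float, delta_t: float) -> str:
    """Temporal class from the (half-life, delay) plane.

    DEG iff delta_t > 30 min; otherwise ILG iff half-life > 120 min;
    otherwise IEG.  Both boundaries are inclusive on the IEG side.
    """
    if not (half_life > 0):
        raise ValueError("half_life must be > 0")
    if delta_t < 0:
        raise ValueError("delta_t must be >= 0")
    if delta_t > DELAY_THRESHOLD_MIN:
        return "DEG"
    if half_life > HALFLIFE_THRESHOLD_MIN:
        return "ILG"
    return "IEG"


def default_scenarios() -> dict:
    """Named signalling scenarios: sustained step, 2-h pulse, transient peak.

    The transient scenario is an EGF-like interpolated shape: rapid rise to
    a peak above the training mean (~1.4x) followed by decay towards a low
    plateau.
    """
    transient = PiecewiseInput(
        times=(0.0, 10.0, 60.0, 240.0, 600.0),
        values=(0.0, 1.4, 0.8, 0.35, 0.2),
        mode="linear",
    )
    return {
        "sustained": PiecewiseInput.sustained(),
        "pulse120": PiecewiseInput.pulse(120.0),
        "transient": transient,
    }


@dataclass
class ParameterScan:
    """Amplitude grids of the parameter-space simulation.

    ``amplitude[s, t, h, d]`` is the relative amplitude (percent) for
    scenario ``s`` at time ``t`` with half-life ``h`` and delay ``d``;
    ``exceeds_half[s, h, d]`` marks parameter combinations whose amplitude
    ever exceeds 50% within the simulated window.
    """

    scenarios: list
    times: np.ndarray
    half_lives: np.ndarray
    delays: np.ndarray
    amplitude: np.ndarray
    exceeds_half: np.ndarray

    def to_frame(self):
        """Long-format table (scenario, time, half_life, delta_t, amplitude_pct)."""
        import pandas as pd

        s, t, h, d = np.meshgrid(
            np.arange(len(self.scenarios)), self.times, self.half_lives,
            self.delays, indexing="ij")
        return pd.DataFrame({
            "scenario": np.asarray(self.scenarios)[s.ravel()],
            "time": t.ravel(),
            "half_life": h.ravel(),
            "delta_t": d.ravel(),
            "amplitude_pct": self.amplitude.ravel(),
        })


def scan_parameter_space(halflife_grid=None, delay_grid=None, scenarios=None,
                         times=None) -> ParameterScan:
    """Simulate relative response amplitude over a (half-life, delay) grid.

    Each grid cell solves the model with k0 = 0, k = 1 (the amplitude is
    invariant to k0 and k) under every scenario and rescales to percent of
    the sustained plateau.
    """
    if halflife_grid is None:
        halflife_grid = np.geomspace(10.0, 600.0, 25)
    if delay_grid is None:
        delay_grid = np.linspace(0.0, 300.0, 13)
    if scenarios is None:
        scenarios = default_scenarios()
    if times is None:
        times = np.linspace(0.0, 600.0, 61)
    halflife_grid = np.asarray(halflife_grid, dtype=float)
    delay_grid = np.asarray(delay_grid, dtype=float)
    times = np.asarray(times, dtype=float)
    if halflife_grid.size == 0 or delay_grid.size == 0:
        raise ValueError("parameter grids must be non-empty")

    names = list(scenarios)
    amp = np.empty((len(names), times.size, halflife_grid.size, delay_grid.size))
    for si, name in enumerate(names):
        inp = scenarios[name]
        for hi, hl in enumerate(halflife_grid):
            for di, dt in enumerate(delay_grid):
                params = GeneParams(k0=0.0, k=1.0, gamma=LN2 / hl, delta_t=dt)
                traj = solve_expression(params, inp, times)
                amp[si, :, hi, di] = relative_amplitude(traj, params)
    exceeds = (amp > 50.0).any(axis=1)
    return ParameterScan(scenarios=names, times=times, half_lives=halflife_grid,
                         delays=delay_grid, amplitude=amp, exceeds_half=exceeds)
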