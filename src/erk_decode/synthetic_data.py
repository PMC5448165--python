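"""Ground-truthed synthetic data for every pipeline stage.

The generator emulates the design of a replicated log2 microarray
time-course experiment on an inducible ERK system: per-gene kinetic
parameters drawn within class-consistent ranges, pERK trajectories for
sustained / pulsed / transient scenarios, replicate expression matrices with
expression-level-dependent Gaussian noise, and exponential decay series
after transcriptional shutdown with long-lived reference transcripts and
optional library-size drift.

All draws flow through one :class:`numpy.random.Generator` seeded
explicitly, so output is byte-identical for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .errors import ConfigError
from .kinetic_model import (
    LN2,
    GeneParams,
    PiecewiseInput,
    classify_param_point,
    solve_expression,
)

__all__ = [
    "SyntheticTruth",
    "default_variance",
    "default_design",
    "sample_gene_params",
    "simulate_perk",
    "simulate_experiment",
    "simulate_decay_experiment",
    "DEFAULT_CLASS_RANGES",
]

#: Training-condition mean pERK2 log2 fold change emulated by the generator.
TRAINING_MEAN_LOG2FC = 3.89
#: Peak pERK2 log2 fold change of the transient (EGF-like) scenario.
TRANSIENT_PEAK_LOG2FC = 5.43

#: Per-class (half-life range, delay range) in minutes, spanning the fitted
#: ranges of the three temporal classes.
DEFAULT_CLASS_RANGES = {
    "IEG": {"half_life": (10.0, 117.0), "delta_t": (0.0, 30.0)},
    "ILG": {"half_life": (124.0, 561.0), "delta_t": (0.0, 30.0)},
    "DEG": {"half_life": (30.0, 120.0), "delta_t": (45.0, 180.0)},
}


def default_variance(level):
    """Default microarray-like noise: variance decreasing with expression.

    variance(level) = 0.02 + 0.6 * 2**(-(level - 4)) in squared log2 units.
    """
    level = np.asarray(level, dtype=float)
    return 0.02 + 0.6 * np.power(2.0, -(level - 4.0))


@dataclass
class SyntheticTruth:
    """Per-gene ground truth plus the noise model and seed used."""

    params: pd.DataFrame  # gene-indexed: k0, k, gamma, delta_t, class, ...
    variance_fn: Callable = field(default=default_variance)
    seed: int | None = None

    def gene_params(self, gene: str) -> GeneParams:
        row = self.params.loc[gene]
        return GeneParams(k0=row["k0"], k=row["k"], gamma=row["gamma"],
                          delta_t=row["delta_t"])


def _check_ranges(ranges):
    for label, r in ranges.items():
        hl_lo, hl_hi = r["half_life"]
        dt_lo, dt_hi = r["delta_t"]
        if hl_lo <= 0 or hl_lo > hl_hi or dt_lo < 0 or dt_lo > dt_hi:
            raise ConfigError(f"invalid range for class {label}")
        corners = [(hl, dt) for hl in (hl_lo, hl_hi) for dt in (dt_lo, dt_hi)]
        for hl, dt in corners:
            if classify_param_point(hl, dt) != label:
                raise ConfigError(
                    f"range for {label} includes ({hl}, {dt}) which "
                    f"classifies as {classify_param_point(hl, dt)}")


def sample_gene_params(n_per_class: dict, ranges: dict | None = None,
                       seed: int | None = None,
                       basal_level_induced=(6.0, 11.0),
                       basal_level_uninduced=(4.0, 12.0),
                       log2fc_ss=(3.0, 6.0),
                       secondary_fraction: float = 0.3,
                       variance_fn: Callable = default_variance) -> SyntheticTruth:
    """Draw class-consistent kinetic parameters for a synthetic cohort.

    ``n_per_class`` maps "IEG"/"ILG"/"DEG"/"uninduced" to gene counts.
    Rates are drawn log-uniformly, delays uniformly, within the class
    ranges; induced genes get a basal log2 level in ``basal_level_induced``
    and a steady-state induction of ``log2fc_ss`` log2 units (k = fc *
    gamma), while uninduced genes have k = 0.  A ``secondary_fraction`` of
    induced genes is marked secondary (their induction requires new protein
    synthesis and disappears under cycloheximide).
    """
    ranges = dict(DEFAULT_CLASS_RANGES if ranges is None else ranges)
    _check_ranges(ranges)
    rng = np.random.default_rng(seed)
    rows = []
    for label in ("IEG", "ILG", "DEG"):
        n = int(n_per_class.get(label, 0))
        if n == 0:
            continue
        hl_lo, hl_hi = ranges[label]["half_life"]
        dt_lo, dt_hi = ranges[label]["delta_t"]
        hl = np.exp(rng.uniform(np.log(hl_lo), np.log(hl_hi), n))
        dt = rng.uniform(dt_lo, dt_hi, n)
        gamma = LN2 / hl
        basal = rng.uniform(*basal_level_induced, n)
        fc = rng.uniform(*log2fc_ss, n)
        secondary = rng.random(n) < secondary_fraction
        for i in range(n):
            rows.append({
                "k0": basal[i] * gamma[i], "k": fc[i] * gamma[i],
                "gamma": gamma[i], "delta_t": dt[i], "class": label,
                "induced": True, "is_primary": not secondary[i],
                "basal_level": basal[i], "log2fc_ss": fc[i],
            })
    n_un = int(n_per_class.get("uninduced", 0))
    if n_un:
        hl = np.exp(rng.uniform(np.log(30.0), np.log(600.0), n_un))
        basal = rng.uniform(*basal_level_uninduced, n_un)
        for i in range(n_un):
            rows.append({
                "k0": basal[i] * LN2 / hl[i], "k": 0.0,
                "gamma": LN2 / hl[i], "delta_t": 0.0, "class": "none",
                "induced": False, "is_primary": False,
                "basal_level": basal[i], "log2fc_ss": 0.0,
            })
    df = pd.DataFrame(rows)
    df.index = [f"G{i + 1:05d}" for i in range(len(df))]
    df.index.name = "gene"
    # shuffle so class blocks are not contiguous
    df = df.loc[rng.permutation(df.index)]
    return SyntheticTruth(params=df, variance_fn=variance_fn, seed=seed)


def simulate_perk(scenario: str, times=None, noise_sd: float = 0.0,
                  replicates: int = 3, seed: int | None = None,
                  pulse_duration: float = 120.0,
                  training_mean: float = TRAINING_MEAN_LOG2FC,
                  peak: float = TRANSIENT_PEAK_LOG2FC) -> pd.DataFrame:
    """Simulate pERK2 log2 fold-change measurements for one scenario.

    sustained: constant at the training mean for t > 0; pulse: same until
    ``pulse_duration`` then rapid exponential shutdown (10-min timescale);
    transient: fast rise to ``peak`` at 10 min then slower decay (EGF-like).
    Returns a tidy table (condition, time, replicate, log2fc).
    """
    if times is None:
        times = np.array([0.0, 10.0, 30.0, 60.0, 120.0, 180.0, 240.0,
                          360.0, 480.0, 600.0])
    times = np.asarray(times, dtype=float)
    rng = np.random.default_rng(seed)
    if scenario == "sustained":
        clean = np.where(times > 0, training_mean, 0.0)
    elif scenario == "pulse":
        if pulse_duration <= 0:
            raise ValueError("pulse duration must be > 0")
        clean = np.where(times > 0, training_mean, 0.0)
        after = times > pulse_duration
        clean = np.where(after,
                         training_mean * np.exp(-(times - pulse_duration) / 10.0),
                         clean)
    elif scenario == "transient":
        rise = np.clip(times / 10.0, 0.0, 1.0) * peak
        decay = peak * np.exp(-(times - 10.0) / 45.0)
        clean = np.where(times <= 10.0, rise, np.maximum(decay, 0.0))
        clean = np.where(times > 0, np.maximum(clean, 0.0), 0.0)
    else:
        raise ValueError(f"unknown pERK scenario {scenario!r}")
    rows = []
    for rep in range(1, replicates + 1):
        noisy = clean + rng.normal(0.0, noise_sd, times.size)
        for t, v in zip(times, noisy):
            rows.append({"condition": scenario, "time": t,
                         "replicate": rep, "log2fc": v})
    return pd.DataFrame(rows)


def default_design() -> pd.DataFrame:
    """Replicated time-course design: untreated baseline, sustained
    induction with a triplicated 2-h anchor, a 2-h pulse arm and a
    cycloheximide co-treatment arm."""
    rows = [("UT", 0.0, r) for r in (1, 2, 3)]
    for t in (30.0, 60.0, 120.0, 180.0, 240.0, 360.0, 480.0, 600.0):
        reps = (1, 2, 3) if t == 120.0 else (1,)
        rows += [("ON", t, r) for r in reps]
    rows += [("ONOFF", t, 1) for t in (180.0, 240.0, 360.0, 600.0)]
    rows += [("ONCYHX", t, 1) for t in (120.0, 240.0)]
    return pd.DataFrame(rows, columns=["condition", "time", "replicate"])


#: Input function per condition of the default design.
CONDITION_INPUTS = {
    "UT": None,
    "ON": PiecewiseInput.sustained(),
    "ONOFF": PiecewiseInput.pulse(120.0),
    "ONCYHX": PiecewiseInput.sustained(),
}


def simulate_experiment(truth: SyntheticTruth, design: pd.DataFrame | None = None,
                        seed: int | None = None,
                        condition_inputs: dict | None = None):
    """Simulate a replicate expression matrix from the ground truth.

    Each gene's noiseless trajectory solves the kinetic model under the
    condition's input; observations add Gaussian noise with SD =
    sqrt(variance_fn(level)).  In the cycloheximide condition, genes marked
    secondary lose their induction (k set to 0), emulating the block of
    mediator protein synthesis.  Returns ``(ExpressionMatrix, truth_table)``.
    """
    from .io_formats import ExpressionMatrix

    if design is None:
        design = default_design()
    if "UT" not in set(design["condition"]):
        raise ValueError("design must include an untreated (UT) baseline")
    if condition_inputs is None:
        condition_inputs = CONDITION_INPUTS
    rng = np.random.default_rng(seed)
    genes = truth.params.index
    p = truth.params
    k0s = p["k0"].to_numpy()
    ks = p["k"].to_numpy()
    gammas = p["gamma"].to_numpy()
    dts = p["delta_t"].to_numpy()
    secondary = (p["induced"] & ~p["is_primary"]).to_numpy()
    columns, clean_cols = [], []
    for cond, grp in design.groupby("condition", sort=False):
        inp = condition_inputs.get(cond)
        times = np.sort(grp["time"].unique())
        clean = np.empty((len(genes), times.size))
        for gi in range(len(genes)):
            k = 0.0 if (cond == "ONCYHX" and secondary[gi]) else ks[gi]
            if inp is None or k == 0.0:
                clean[gi] = k0s[gi] / gammas[gi]
            else:
                params = GeneParams(k0=k0s[gi], k=k, gamma=gammas[gi],
                                    delta_t=dts[gi])
                clean[gi] = solve_expression(params, inp, times)
        t_index = {t: j for j, t in enumerate(times)}
        for _, r in grp.sort_values(["time", "replicate"]).iterrows():
            columns.append(f"{r['condition']}_{r['time']:g}_{int(r['replicate'])}")
            clean_cols.append(clean[:, t_index[r["time"]]])
    clean_mat = np.column_stack(clean_cols)
    noise_sd = np.sqrt(truth.variance_fn(clean_mat))
    values = clean_mat + rng.normal(0.0, 1.0, clean_mat.shape) * noise_sd
    vdf = pd.DataFrame(values, index=genes, columns=columns)
    meta = pd.DataFrame(
        [c.rsplit("_", 2) for c in columns],
        columns=["condition", "time", "replicate"], index=columns)
    meta["time"] = meta["time"].astype(float)
    meta["replicate"] = meta["replicate"].astype(int)
    return ExpressionMatrix(values=vdf, samples=meta), p.copy()


def simulate_decay_experiment(truth: SyntheticTruth, times=None,
                              reference_count: int = 61,
                              drift: float = 0.0, noise_sd: float = 0.0,
                              seed: int | None = None,
                              offset_fraction: float = 0.0):
    """Simulate a transcription-shutdown series with reference transcripts.

    Every gene decays exponentially (linear scale) from its basal level at
    its own rate; ``reference_count`` extra long-lived transcripts
    (half-life > 16 h) are appended as the normalisation reference.
    ``drift`` adds a linear per-sample log2 offset (library-size artefact)
    to be removed by reference normalisation.  Returns
    ``(ExpressionMatrix, decay_truth, reference_ids)``.
    """
    from .io_formats import ExpressionMatrix

    if times is None:
        times = np.array([0.0, 30.0, 60.0, 120.0, 240.0, 480.0])
    times = np.asarray(times, dtype=float)
    if 0.0 not in times:
        raise ValueError("decay series must include t = 0 (shutdown time)")
    rng = np.random.default_rng(seed)

    p = truth.params
    gammas = p["gamma"].to_numpy()
    levels = (p["k0"] / p["gamma"]).to_numpy()
    genes = list(p.index)

    ref_ids = [f"REF{i + 1:04d}" for i in range(reference_count)]
    # reference transcripts (half-life > 16 h) are modelled as stable over
    # the shutdown window, so reference normalisation is exact
    gammas = np.concatenate([gammas, np.zeros(reference_count)])
    levels = np.concatenate([levels, rng.uniform(6.0, 12.0, reference_count)])
    genes = genes + ref_ids

    linear0 = np.power(2.0, levels)
    frac = offset_fraction
    decay = ((1.0 - frac) * np.exp(-np.outer(gammas, times)) + frac)
    log2_vals = np.log2(linear0[:, None] * decay)
    log2_vals = log2_vals + drift * times[None, :]
    log2_vals = log2_vals + rng.normal(0.0, noise_sd, log2_vals.shape)

    columns = [f"ActD_{t:g}_1" for t in times]
    vdf = pd.DataFrame(log2_vals, index=genes, columns=columns)
    meta = pd.DataFrame({"condition": "ActD", "time": times, "replicate": 1},
                        index=columns)
    with np.errstate(divide="ignore"):
        decay_truth = pd.DataFrame(
            {"gamma": gammas, "half_life": LN2 / gammas}, index=genes)
    return ExpressionMatrix(values=vdf, samples=meta), decay_truth, ref_ids
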