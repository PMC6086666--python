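"""Synthetic sessions for the direction-discrimination / wagering task.

The generator emulates the statistical structure the analysis pipeline
assumes: uniform coherences from the task set, truncated-exponential stimulus
durations (range 95-925 ms, mean 350 ms), laser on a random half of trials,
sure-bet target on a random half, logistic choices and Gaussian sure-bet
probabilities, Poisson-like multi-unit counts with linear coherence tuning,
a variable multiplicative suppression on laser trials, and an injected
behavioral shift that may be attenuated by pluggable "compensation" kernels
in trial number f(T) and stimulus duration g(D).

Everything is a pure function of (config, seed); ground truth per trial is
returned for recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Callable

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import truncnorm

from .spikes import SpikeTrainSet
from .trials import COHERENCE_SET, DURATION_RANGE, TrialTable


# --------------------------------------------------------------------------
# compensation kernels


@dataclass(frozen=True)
class CompensationKernel:
    """Multiplicative attenuation in [0, 1] of the injected shift.

    Forms:
      * ``constant`` — 1 everywhere (no compensation).
      * ``step`` — 1 below ``boundary``, ``after`` at/above it.
      * ``logistic_decay`` — smooth decay from 1 toward ``floor`` with the
        given ``midpoint`` and ``scale`` (same units as the input variable).
    """

    form: str = "constant"
    boundary: float = 300.0
    after: float = 0.0
    midpoint: float = 400.0
    scale: float = 100.0
    floor: float = 0.0

    def __post_init__(self) -> None:
        if self.form not in ("constant", "step", "logistic_decay"):
            raise ValueError(f"unknown kernel form {self.form!r}")
        for v, name in [(self.after, "after"), (self.floor, "floor")]:
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0,1]")

    def __call__(self, x: np.ndarray | float) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.form == "constant":
            return np.ones_like(x)
        if self.form == "step":
            return np.where(x < self.boundary, 1.0, self.after)
        out = self.floor + (1.0 - self.floor) / (
            1.0 + np.exp((x - self.midpoint) / self.scale)
        )
        return out


# --------------------------------------------------------------------------
# configuration


@dataclass
class SimConfig:
    """Full generative specification for a synthetic cohort.

    Defaults are the task's study conditions; the injected shift ``s0``
    defaults to 0 (no perturbation effect) so any behavioral effect in a
    simulation is explicit.  :meth:`study_conditions` returns the
    perturbation-plus-compensation scenario used by the analysis drivers.
    """

    n_sessions: int = 23
    trials_per_session: int = 900
    coherence_set: tuple[float, ...] = COHERENCE_SET
    duration_low_ms: float = DURATION_RANGE[0]
    duration_high_ms: float = DURATION_RANGE[1]
    duration_mean_ms: float = 350.0
    laser_fraction: float = 0.5
    ts_fraction: float = 0.5

    # behavioral kernel
    b0: float = 0.0                # choice intercept
    b1: float = 0.12               # choice slope, logits per % coherence
    conf_A: float = 0.62           # sure-bet amplitude
    conf_mu: float = 0.0           # sure-bet peak location, % coh
    conf_sigma: float = 16.0       # sure-bet width, % coh
    s0: float = 0.0                # injected shift on laser trials, % coh
    laser_slope_gain: float = 1.0  # multiplies b1 on laser trials
    kernel_trial: CompensationKernel = field(default_factory=CompensationKernel)
    kernel_duration: CompensationKernel = field(default_factory=CompensationKernel)
    independent_conf_shift: float | None = None  # if set, confidence uses this s0
    zero_coh_reward: str = "random"  # {"random", "always"}

    # neural kernel
    baseline_rate: float = 40.0    # sp/s at 0% coherence
    tuning_gain: float = 0.4       # sp/s per signed % coherence
    suppression_mean: float = -0.33
    suppression_sd: float = 0.25
    count_dispersion: float = 0.0  # gamma mixing; 0 = pure Poisson
    latency_ms: float = 40.0       # visual response latency
    opsin_delay_ms: float = 5.0    # suppression onset after laser onset
    laser_onset_ms: float = 20.0   # laser onset after stimulus onset
    rebound: bool = True
    rebound_gain: float = 2.5      # rebound burst rate / baseline
    rebound_dur_ms: float = 80.0
    ramp_down_ms: float = 140.0
    reward_ratio: float = 0.55     # sure-bet / direction reward size

    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.laser_fraction <= 1.0 and 0.0 <= self.ts_fraction <= 1.0):
            raise ValueError("laser_fraction and ts_fraction must be in [0,1]")
        if not (self.duration_low_ms < self.duration_mean_ms < self.duration_high_ms):
            raise ValueError("duration target mean must lie strictly inside the range")
        if not (-1.0 <= self.suppression_mean <= 0.0):
            raise ValueError("suppression_mean must be in [-1, 0]")
        if self.zero_coh_reward not in ("random", "always"):
            raise ValueError("zero_coh_reward must be 'random' or 'always'")

    @classmethod
    def study_conditions(cls, seed: int = 0, **overrides) -> "SimConfig":
        """Study-conditions scenario: a -5% coh shift on laser trials that
        decays across the session (logistic in trial number, midpoint 400)
        and vanishes for stimuli longer than 300 ms (step in duration)."""
        kw = dict(
            s0=-5.0,
            kernel_trial=CompensationKernel("logistic_decay", midpoint=400.0, scale=100.0),
            kernel_duration=CompensationKernel("step", boundary=300.0, after=0.0),
            seed=seed,
        )
        kw.update(overrides)
        return cls(**kw)


def config_to_dict(config: SimConfig) -> dict:
    d = asdict(config)
    d["kernel_trial"] = asdict(config.kernel_trial)
    d["kernel_duration"] = asdict(config.kernel_duration)
    return d


def config_from_dict(d: dict) -> SimConfig:
    d = dict(d)
    for k in ("kernel_trial", "kernel_duration"):
        if k in d and isinstance(d[k], dict):
            d[k] = CompensationKernel(**d[k])
    if "coherence_set" in d:
        d["coherence_set"] = tuple(d["coherence_set"])
    return SimConfig(**d)


# --------------------------------------------------------------------------
# duration law


def truncated_exp_rate(low: float, high: float, mean: float) -> float:
    """Rate of an exponential truncated to [low, high] with the given mean.

    Solved by 1-D root finding; the truncated mean is
    ``low + 1/lam - span*exp(-lam*span)/(1 - exp(-lam*span))`` with
    ``span = high - low``.
    """
    span = high - low

    def trunc_mean(lam: float) -> float:
        z = lam * span
        return low + 1.0 / lam - span * math.exp(-z) / (1.0 - math.exp(-z))

    target = mean
    mid = low + span / 2.0
    if not (low < target < mid):
        # exponential truncation can only realize means in (low, midpoint)
        raise ValueError(
            f"target mean {target} not achievable on [{low}, {high}] "
            "by a truncated exponential"
        )
    return brentq(lambda lam: trunc_mean(lam) - target, 1e-8, 1.0, xtol=1e-12)


def sample_truncated_exp(
    rng: np.random.Generator, n: int, low: float, high: float, mean: float
) -> np.ndarray:
    lam = truncated_exp_rate(low, high, mean)
    span = high - low
    u = rng.random(n)
    # inverse CDF of the truncated exponential
    return low - np.log1p(-u * (1.0 - math.exp(-lam * span))) / lam


# --------------------------------------------------------------------------
# stage 1: task variables


def sample_task_variables(config: SimConfig, n: int, seed: int) -> pd.DataFrame:
    """Draw per-trial task variables (single session's worth of rows)."""
    rng = np.random.default_rng(seed)
    coh = rng.choice(np.asarray(config.coherence_set, float), size=n)
    sign = rng.choice([-1.0, 1.0], size=n)
    signed = coh * sign
    signed[coh == 0.0] = 0.0
    dur = sample_truncated_exp(
        rng, n, config.duration_low_ms, config.duration_high_ms, config.duration_mean_ms
    )
    return pd.DataFrame(
        {
            "trial_index": np.arange(1, n + 1),
            "signed_coherence": signed,
            "duration_ms": dur,
            "laser_on": (rng.random(n) < config.laser_fraction).astype(int),
            "ts_available": (rng.random(n) < config.ts_fraction).astype(int),
        }
    )


# --------------------------------------------------------------------------
# stage 2: behavior


def effective_shift(config: SimConfig, task: pd.DataFrame) -> np.ndarray:
    """Injected shift per trial: s0 * f(T) * g(D) on laser trials, else 0."""
    f = config.kernel_trial(task["trial_index"].to_numpy(float))
    g = config.kernel_duration(task["duration_ms"].to_numpy(float))
    return config.s0 * f * g * task["laser_on"].to_numpy(float)


def simulate_behavior(task: pd.DataFrame, config: SimConfig, seed: int) -> pd.DataFrame:
    """Draw outcomes (sure-bet, then direction choice) for a task table.

    Sure-bet probability: ``A * exp(-(C + mu + delta_eff)^2 / (2 sigma^2))``
    on sure-bet-available trials.  Remaining trials choose the preferred
    direction with probability ``logistic(b0 + b1_eff * (C + s_eff))``.
    Choice and confidence share one injected shift unless
    ``independent_conf_shift`` is set.
    """
    rng = np.random.default_rng(seed)
    df = task.copy()
    n = len(df)
    C = df["signed_coherence"].to_numpy(float)
    laser = df["laser_on"].to_numpy(float)
    s_eff = effective_shift(config, df)
    if config.independent_conf_shift is None:
        d_eff = s_eff
    else:
        conf_cfg = config.independent_conf_shift
        f = config.kernel_trial(df["trial_index"].to_numpy(float))
        g = config.kernel_duration(df["duration_ms"].to_numpy(float))
        d_eff = conf_cfg * f * g * laser

    p_sb = config.conf_A * np.exp(
        -((C + config.conf_mu + d_eff) ** 2) / (2.0 * config.conf_sigma**2)
    )
    sure = (df["ts_available"].to_numpy(int) == 1) & (rng.random(n) < p_sb)

    b1_eff = config.b1 * np.where(laser == 1.0, config.laser_slope_gain, 1.0)
    q = config.b0 + b1_eff * (C + s_eff)
    p_pref = 1.0 / (1.0 + np.exp(-q))
    pref = rng.random(n) < p_pref

    outcome = np.where(sure, "sure_bet", np.where(pref, "pref_choice", "null_choice"))
    correct = np.full(n, np.nan)
    dir_trial = ~sure
    nonzero = C != 0.0
    correct[dir_trial & nonzero] = (
        pref[dir_trial & nonzero] == (C[dir_trial & nonzero] > 0)
    ).astype(float)

    rewarded = np.zeros(n, dtype=int)
    rewarded[sure] = 1
    rewarded[dir_trial & nonzero & (correct == 1.0)] = 1
    zero_dir = dir_trial & ~nonzero
    if config.zero_coh_reward == "random":
        rewarded[zero_dir] = (rng.random(int(zero_dir.sum())) < 0.5).astype(int)
    else:
        rewarded[zero_dir] = 1

    df["outcome"] = outcome
    df["correct"] = correct
    df["rewarded"] = rewarded
    df["_s_eff"] = s_eff
    df["_d_eff"] = d_eff
    return df


# --------------------------------------------------------------------------
# stage 3: multi-unit counts


def expected_visual_rate(config: SimConfig, C: np.ndarray) -> np.ndarray:
    """No-laser expected MU rate: baseline + gain*C, floored at 0 sp/s."""
    return np.maximum(config.baseline_rate + config.tuning_gain * np.asarray(C, float), 0.0)


def _truncnorm_loc_for_mean(target: float, sd: float) -> float:
    """Location of a normal truncated to [-1, 0] whose truncated mean equals
    ``target`` (truncation pulls the mean toward the interval center, so the
    location must be solved, not set to the target)."""

    def trunc_mean(loc: float) -> float:
        a = (-1.0 - loc) / sd
        b = (0.0 - loc) / sd
        return float(truncnorm.mean(a, b, loc=loc, scale=sd))

    return brentq(lambda m: trunc_mean(m) - target, -3.0, 2.0, xtol=1e-10)


def sample_suppression(config: SimConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    """Per-trial fractional suppression u in [-1, 0] (rate multiplier 1+u).

    The truncated distribution's mean equals ``suppression_mean`` exactly.
    """
    if config.suppression_sd == 0.0:
        return np.full(n, config.suppression_mean)
    loc = _truncnorm_loc_for_mean(config.suppression_mean, config.suppression_sd)
    a = (-1.0 - loc) / config.suppression_sd
    b = (0.0 - loc) / config.suppression_sd
    return truncnorm.rvs(
        a, b, loc=loc, scale=config.suppression_sd,
        size=n, random_state=rng,
    )


def simulate_mu_counts(df: pd.DataFrame, config: SimConfig, seed: int) -> pd.DataFrame:
    """Attach mu_count / mu_rate drawn over the analysis window.

    The window runs from 60 ms after stimulus onset to 60 ms after offset, so
    its length equals the stimulus duration.  Laser trials multiply the
    expected rate by (1 + u) with u from the truncated suppression law.
    """
    rng = np.random.default_rng(seed)
    out = df.copy()
    n = len(out)
    rate = expected_visual_rate(config, out["signed_coherence"].to_numpy(float))
    u = np.zeros(n)
    laser = out["laser_on"].to_numpy(int) == 1
    u[laser] = sample_suppression(config, rng, int(laser.sum()))
    rate_eff = rate * (1.0 + u)
    window_s = out["duration_ms"].to_numpy(float) / 1000.0
    lam = rate_eff * window_s
    if config.count_dispersion > 0.0:
        shape = 1.0 / config.count_dispersion
        lam = lam * rng.gamma(shape, 1.0 / shape, size=n)
    count = rng.poisson(lam)
    out["mu_count"] = count
    out["mu_rate"] = count / window_s
    out["_suppression_u"] = u
    out["_expected_rate"] = rate_eff
    return out


# --------------------------------------------------------------------------
# stage 4: spike trains


def simulate_spike_trains(
    df: pd.DataFrame, config: SimConfig, seed: int, pre_ms: float = 100.0,
    post_ms: float = 300.0,
) -> SpikeTrainSet:
    """Inhomogeneous-Poisson trains per trial, aligned to stimulus onset.

    Rate profile: baseline before the visual latency; the trial's visually
    driven rate from latency to offset+latency; on laser trials the
    suppression factor steps in at laser onset + opsin delay and (with a
    ramp-down) fades linearly back to 1 over ``ramp_down_ms``; with no
    ramp-down and ``rebound`` set, a burst at ``rebound_gain`` x baseline
    follows laser offset.
    """
    rng = np.random.default_rng(seed)
    trains: list[np.ndarray] = []
    dur = df["duration_ms"].to_numpy(float)
    laser = df["laser_on"].to_numpy(int) == 1
    vis_rate = expected_visual_rate(config, df["signed_coherence"].to_numpy(float))
    if "_suppression_u" in df.columns:
        u = df["_suppression_u"].to_numpy(float)
    else:
        u = np.where(laser, config.suppression_mean, 0.0)

    for i in range(len(df)):
        t0, t1 = -pre_ms, dur[i] + post_ms
        edges = np.arange(t0, t1 + 1.0, 1.0)
        t = edges[:-1]
        rate = np.full(t.size, config.baseline_rate)
        vis = (t >= config.latency_ms) & (t < dur[i] + config.latency_ms)
        rate[vis] = vis_rate[i]
        if laser[i]:
            sup_on = config.laser_onset_ms + config.opsin_delay_ms
            laser_off = dur[i] + config.laser_onset_ms
            factor = np.ones(t.size)
            factor[(t >= sup_on) & (t < laser_off)] = 1.0 + u[i]
            if config.ramp_down_ms > 0:
                ramp = (t >= laser_off) & (t < laser_off + config.ramp_down_ms)
                frac = (t[ramp] - laser_off) / config.ramp_down_ms
                factor[ramp] = (1.0 + u[i]) + (-u[i]) * frac
            elif config.rebound:
                rb = (t >= laser_off) & (t < laser_off + config.rebound_dur_ms)
                factor[rb] = np.maximum(factor[rb], 1.0)
                rate[rb] = np.maximum(rate[rb], config.rebound_gain * config.baseline_rate)
            rate = rate * factor
        counts = rng.poisson(rate * 1e-3)
        idx = np.repeat(np.arange(t.size), counts)
        times = t[idx] + rng.random(idx.size)
        trains.append(np.sort(times))
    return SpikeTrainSet(
        trains,
        dur,
        trial_index=df["trial_index"].to_numpy()
        if "trial_index" in df.columns
        else None,
        session_id=list(df["session_id"]) if "session_id" in df.columns else None,
    )


# --------------------------------------------------------------------------
# driver


def generate_sessions(
    config: SimConfig, include_spikes: bool = False
) -> tuple[TrialTable, SpikeTrainSet | None, pd.DataFrame]:
    """Generate a full cohort: trial table, optional spike trains, ground truth.

    All randomness flows from ``config.seed`` through per-session,
    per-stage child seeds, so outputs are bit-reproducible.
    """
    root = np.random.SeedSequence(config.seed)
    session_seeds = root.spawn(config.n_sessions)
    frames = []
    for s, ss in enumerate(session_seeds):
        seeds = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(3)]
        task = sample_task_variables(config, config.trials_per_session, seeds[0])
        task.insert(0, "session_id", f"S{s + 1:02d}")
        beh = simulate_behavior(task, config, seeds[1])
        full = simulate_mu_counts(beh, config, seeds[2])
        frames.append(full)
    df = pd.concat(frames, ignore_index=True)

    spikes = None
    if include_spikes:
        spike_seed = int(root.spawn(1)[0].generate_state(1)[0] % (2**31))
        spikes = simulate_spike_trains(df, config, spike_seed)

    truth = df[
        ["session_id", "trial_index", "_s_eff", "_d_eff", "_suppression_u", "_expected_rate"]
    ].rename(
        columns={
            "_s_eff": "shift_injected",
            "_d_eff": "conf_shift_injected",
            "_suppression_u": "suppression_u",
            "_expected_rate": "expected_rate",
        }
    )
    df = df.drop(columns=["_s_eff", "_d_eff", "_suppression_u", "_expected_rate"])

    table = TrialTable(df)
    for meta in table.sessions.values():
        meta.reward_ratio = config.reward_ratio
        meta.ramp_down_used = config.ramp_down_ms > 0
    return table, spikes, truth
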