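"""Neural effect metrics: fractional suppression (dR), PSTHs, single-unit
suppression summaries, and ROC/Weibull neurometric thresholds.

The per-trial suppression index for a laser trial is

    dR = (R_laser - Rbar_no_laser) / Rbar_no_laser

where the baseline Rbar is the mean multi-unit rate of no-laser trials from
the same session, motion direction, coherence, and stimulus-duration
quartile.  dR = -1 is complete silencing; dR is undefined when the matched
group is empty.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.metrics import roc_auc_score

from .spikes import SpikeTrainSet
from .trials import _as_frame

__all__ = [
    "compute_delta_r",
    "delta_r_sham",
    "PsthTrace",
    "compute_psth",
    "SuppressionSummary",
    "su_suppression_summary",
    "NeurometricFit",
    "neurometric_threshold",
    "bootstrap_delta_r_diff",
]


def _duration_quartiles(df: pd.DataFrame) -> pd.Series:
    """Quartile (0-3) of stimulus duration, computed per session over all
    trials (laser and no-laser).  Degenerate sessions (constant duration)
    collapse to a single bin."""

    def _q(d: pd.Series) -> pd.Series:
        if d.nunique() < 4:
            return pd.Series(np.zeros(len(d)), index=d.index)
        return pd.qcut(d, 4, labels=False, duplicates="drop")

    return df.groupby("session_id")["duration_ms"].transform(_q)


_MATCH_KEY = ["session_id", "signed_coherence", "duration_quartile"]


def compute_delta_r(table) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Attach the per-laser-trial suppression index dR as a derived column.

    Returns ``(table_with_columns, index_table)`` where the index table has
    one row per laser trial with the matched-group bookkeeping (baseline
    mean, group size).  Laser trials whose matched no-laser group is empty
    or has zero mean rate get dR = NaN and are counted in the index table's
    ``undefined`` flag.
    """
    df = _as_frame(table).copy()
    df["duration_quartile"] = _duration_quartiles(df)
    no_laser = df[df["laser_on"].astype(int) == 0]
    base = (
        no_laser.groupby(_MATCH_KEY)["mu_rate"]
        .agg(baseline_mean="mean", group_n="size")
        .reset_index()
    )
    laser = df[df["laser_on"].astype(int) == 1]
    merged = laser.merge(base, on=_MATCH_KEY, how="left")
    ok = merged["baseline_mean"].notna() & (merged["baseline_mean"] > 0)
    dr = np.where(
        ok,
        (merged["mu_rate"] - merged["baseline_mean"]) / merged["baseline_mean"],
        np.nan,
    )
    idx = merged[_MATCH_KEY + ["trial_index", "mu_rate", "baseline_mean", "group_n"]].copy()
    idx["delta_r"] = dr
    idx["undefined"] = ~ok

    df["delta_r"] = np.nan
    df.loc[laser.index, "delta_r"] = dr
    return df, idx


def add_no_laser_delta_r(table) -> pd.DataFrame:
    """Attach a leave-self-out dR to no-laser trials.

    Each no-laser trial is compared to the matched-group mean of the *other*
    no-laser trials (excluding itself, to avoid self-contamination), putting
    laser and no-laser trials on the same dR scale for split analyses.
    Existing laser-trial dR values are preserved.
    """
    df = _as_frame(table).copy()
    if "duration_quartile" not in df.columns:
        df["duration_quartile"] = _duration_quartiles(df)
    no_laser = df[df["laser_on"].astype(int) == 0]
    g = no_laser.groupby(_MATCH_KEY)["mu_rate"]
    total = g.transform("sum")
    n = g.transform("size")
    loo_mean = (total - no_laser["mu_rate"]) / (n - 1)
    ok = (n >= 2) & (loo_mean > 0)
    dr = np.where(ok, (no_laser["mu_rate"] - loo_mean) / loo_mean, np.nan)
    if "delta_r" not in df.columns:
        df["delta_r"] = np.nan
    df.loc[no_laser.index, "delta_r"] = dr
    return df


def delta_r_sham(no_laser_table, seed: int) -> pd.DataFrame:
    """Relabel an exact random half of no-laser trials as "sham laser".

    Each sham trial's dR is computed against the matched-group mean of the
    *remaining* (non-sham) no-laser trials, mirroring the real dR
    computation with a fictitious laser category.  Returns a copy with
    ``sham_laser`` and ``delta_r`` columns.
    """
    df = _as_frame(no_laser_table)
    if (df["laser_on"].astype(int) == 1).any():
        raise ValueError("sham construction requires no-laser trials only")
    if len(df) < 4:
        raise ValueError("too few trials to split into sham halves")
    rng = np.random.default_rng(seed)
    out = df.copy()
    perm = rng.permutation(len(out))
    sham = np.zeros(len(out), dtype=int)
    sham[perm[: len(out) // 2]] = 1
    out["sham_laser"] = sham
    out["duration_quartile"] = _duration_quartiles(out)

    rest = out[out["sham_laser"] == 0]
    base = (
        rest.groupby(_MATCH_KEY)["mu_rate"]
        .agg(baseline_mean="mean", group_n="size")
        .reset_index()
    )
    shamrows = out[out["sham_laser"] == 1]
    merged = shamrows.merge(base, on=_MATCH_KEY, how="left")
    ok = merged["baseline_mean"].notna() & (merged["baseline_mean"] > 0)
    dr = np.where(
        ok,
        (merged["mu_rate"] - merged["baseline_mean"]) / merged["baseline_mean"],
        np.nan,
    )
    out["delta_r"] = np.nan
    out.loc[shamrows.index, "delta_r"] = dr
    return out


# --------------------------------------------------------------------------
# PSTH


@dataclass
class PsthTrace:
    """Trial-averaged firing-rate time course at 1 ms resolution."""

    time_ms: np.ndarray
    rate: np.ndarray            # sp/s
    n_trials: int
    align: str = "onset"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ms": self.time_ms, "rate_sp_s": self.rate})


def compute_psth(
    spikes: SpikeTrainSet,
    align: str = "onset",
    window: tuple[float, float] = (-100.0, 500.0),
    boxcar_ms: int = 40,
) -> PsthTrace:
    """Trial-averaged PSTH: 1 ms bins, causal boxcar smoothing, sp/s.

    The causal boxcar at time t averages the preceding ``boxcar_ms`` bins
    (t - boxcar + 1 .. t); at the window start it is truncated and
    renormalized over the available bins.
    """
    if len(spikes) == 0:
        raise ValueError("PSTH requires at least one trial")
    lo, hi = window
    if hi <= lo:
        raise ValueError("empty PSTH window")
    edges = np.arange(lo, hi + 1.0, 1.0)
    trains = spikes.aligned(align)
    counts = np.zeros(edges.size - 1)
    for t in trains:
        counts += np.histogram(t, bins=edges)[0]
    mean_counts = counts / len(trains)

    k = int(boxcar_ms)
    csum = np.cumsum(mean_counts)
    smooth = np.empty_like(mean_counts)
    for i in range(mean_counts.size):
        j = max(0, i - k + 1)
        total = csum[i] - (csum[j - 1] if j > 0 else 0.0)
        smooth[i] = total / (i - j + 1)
    return PsthTrace(edges[:-1], smooth * 1000.0, len(trains), align)


# --------------------------------------------------------------------------
# single-unit suppression


@dataclass
class SuppressionSummary:
    """Population summary of single-unit laser suppression (percent)."""

    baseline_subtracted_mean: float
    baseline_subtracted_sem: float
    raw_mean: float
    raw_sem: float
    n_units: int
    n_excluded: int
    per_unit: pd.DataFrame = field(repr=False, default=None)


def su_suppression_summary(units: pd.DataFrame) -> SuppressionSummary:
    """Summarize laser suppression across isolated single units.

    ``units`` needs columns ``baseline_rate`` (pre-stimulus), ``stim_rate``
    (stimulus alone) and ``stim_laser_rate`` (stimulus + laser), one row per
    unit.  Two population statistics, as percentages (mean +/- SEM):

    * suppression of the baseline-subtracted visual response,
      100 * (stim - laser) / (stim - baseline) — can exceed 100% when the
      laser drives the rate below baseline;
    * raw reduction of the stimulus-epoch rate, 100 * (stim - laser) / stim.

    Units with a non-positive baseline-subtracted response are excluded
    (denominator undefined) and counted.
    """
    df = units.copy()
    vis = df["stim_rate"] - df["baseline_rate"]
    keep = vis > 0
    n_excluded = int((~keep).sum())
    df = df[keep]
    if len(df) == 0:
        raise ValueError("no unit has a positive baseline-subtracted response")
    bs = 100.0 * (df["stim_rate"] - df["stim_laser_rate"]) / (df["stim_rate"] - df["baseline_rate"])
    raw = 100.0 * (df["stim_rate"] - df["stim_laser_rate"]) / df["stim_rate"]
    per_unit = pd.DataFrame(
        {"baseline_subtracted_pct": bs, "raw_reduction_pct": raw}, index=df.index
    )
    sem = lambda x: float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else float("nan")
    return SuppressionSummary(
        float(bs.mean()), sem(bs), float(raw.mean()), sem(raw),
        len(df), n_excluded, per_unit,
    )


# --------------------------------------------------------------------------
# neurometric threshold


@dataclass
class NeurometricFit:
    """Ideal-observer performance vs coherence with a cumulative Weibull fit.

    ``alpha`` is the neuronal threshold: the coherence supporting 82%
    correct, from  P(x) = 1 - 0.5 * exp(-(x/alpha)^k).
    """

    coherences: np.ndarray
    roc_areas: np.ndarray
    n_per_level: np.ndarray
    alpha: float
    slope_k: float
    norm_constants: dict[str, float]
    dropped_levels: list[float] = field(default_factory=list)

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return 1.0 - 0.5 * np.exp(-((x / self.alpha) ** self.slope_k))


def _weibull_nll(theta: np.ndarray, x: np.ndarray, k_corr: np.ndarray, n: np.ndarray) -> float:
    alpha, k = theta
    p = 1.0 - 0.5 * np.exp(-((x / alpha) ** k))
    p = np.clip(p, 1e-9, 1.0 - 1e-9)
    return -float(np.sum(k_corr * np.log(p) + (n - k_corr) * np.log(1.0 - p)))


def neurometric_threshold(table, min_levels: int = 2) -> NeurometricFit:
    """Neuronal threshold from normalized rates via ROC + Weibull.

    Per session, MU rates are normalized to that session's mean rate at
    51.2% coherence in the preferred direction; normalized rates are pooled
    across sessions; per unsigned coherence the preferred- vs
    null-direction rate distributions give an ROC area (ideal-observer
    proportion correct); proportion correct vs coherence is fit by binomial
    ML with a cumulative Weibull.  0% coherence carries no direction label
    and is excluded.
    """
    df = _as_frame(table).copy()
    norms = {}
    frames = []
    for sid, g in df.groupby("session_id"):
        ref = g.loc[np.isclose(g["signed_coherence"], 51.2), "mu_rate"]
        if len(ref) == 0 or ref.mean() <= 0:
            continue
        norms[str(sid)] = float(ref.mean())
        g = g.copy()
        g["norm_rate"] = g["mu_rate"] / ref.mean()
        frames.append(g)
    if not frames:
        raise ValueError("no session has preferred 51.2% coherence trials")
    pooled = pd.concat(frames, ignore_index=True)

    levels, rocs, ns, dropped = [], [], [], []
    for c in sorted(pooled["signed_coherence"].abs().unique()):
        if c == 0:
            continue
        pref = pooled.loc[np.isclose(pooled["signed_coherence"], c), "norm_rate"]
        null = pooled.loc[np.isclose(pooled["signed_coherence"], -c), "norm_rate"]
        if len(pref) == 0 or len(null) == 0:
            dropped.append(float(c))
            continue
        y = np.r_[np.ones(len(pref)), np.zeros(len(null))]
        scores = np.r_[pref.to_numpy(), null.to_numpy()]
        rocs.append(float(roc_auc_score(y, scores)))
        levels.append(float(c))
        ns.append(len(pref) + len(null))
    if len(levels) < min_levels:
        raise ValueError(f"fewer than {min_levels} usable coherence levels")
    x = np.asarray(levels)
    pc = np.asarray(rocs)
    n = np.asarray(ns, dtype=float)
    if pc.max() < 0.55:
        raise ValueError("ideal observer at chance at every coherence: fit unidentifiable")

    k_corr = pc * n
    best = None
    for a0 in (10.0, 25.0, 50.0):
        for k0 in (1.0, 1.5, 3.0):
            res = minimize(
                _weibull_nll, np.array([a0, k0]), args=(x, k_corr, n),
                method="L-BFGS-B", bounds=[(0.5, 500.0), (0.1, 20.0)],
                options={"ftol": 1e-12},
            )
            if best is None or res.fun < best.fun - 1e-12:
                best = res
    alpha, k = best.x
    return NeurometricFit(x, pc, n.astype(int), float(alpha), float(k), norms, dropped)


# --------------------------------------------------------------------------
# bootstrap


def bootstrap_delta_r_diff(
    group_a: np.ndarray,
    group_b: np.ndarray,
    n_boot: int = 2000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> dict:
    """Bootstrap the difference in mean dR between two trial groups.

    Resamples each group with replacement; returns the observed difference
    (mean_a - mean_b), a percentile CI, and a two-sided p-value from the
    bootstrap distribution's coverage of zero.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if n_boot < 100:
        raise ValueError("n_boot < 100 gives unstable intervals")
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    rng = np.random.default_rng(seed)
    idx_a = rng.integers(0, len(a), size=(n_boot, len(a)))
    idx_b = rng.integers(0, len(b), size=(n_boot, len(b)))
    diffs = a[idx_a].mean(axis=1) - b[idx_b].mean(axis=1)
    lo = (1.0 - ci_level) / 2.0
    ci = (float(np.quantile(diffs, lo)), float(np.quantile(diffs, 1.0 - lo)))
    p_lo = (np.sum(diffs <= 0.0) + 1.0) / (n_boot + 1.0)
    p_hi = (np.sum(diffs >= 0.0) + 1.0) / (n_boot + 1.0)
    return {
        "difference": float(a.mean() - b.mean()),
        "ci": ci,
        "p": float(min(1.0, 2.0 * min(p_lo, p_hi))),
        "mean_a": float(a.mean()),
        "mean_b": float(b.mean()),
        "sem_a": float(np.std(a, ddof=1) / np.sqrt(len(a))) if len(a) > 1 else float("nan"),
        "sem_b": float(np.std(b, ddof=1) / np.sqrt(len(b))) if len(b) > 1 else float("nan"),
        "n_a": int(len(a)),
        "n_b": int(len(b)),
    }
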