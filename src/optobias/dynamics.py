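"""Effect dynamics: sliding-window shift curves, the sham-laser null,
median-split interaction GLMs, and early/late and short/long-duration
comparisons.

Window semantics: windows slide over *laser* trials sorted by the chosen
variable (suppression dR, trial number, or stimulus duration); every window
is fit jointly with the full filtered no-laser comparison set, so the curve
traces how the laser-induced shift varies with the sorting variable while
the baseline stays fixed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import psychometrics as psy
from .neural import delta_r_sham
from .trials import _as_frame

__all__ = [
    "EffectCurve",
    "sliding_effect_curve",
    "sham_laser_curve",
    "GlmInteractionResult",
    "glm_interaction_test",
    "SplitComparison",
    "early_late_analysis",
    "duration_split_analysis",
]

#: conditioning defaults (printed analysis values); all overridable.
DELTA_R_CUT = -0.25
DURATION_CUT_MS = 300.0
TRIAL_CUT = 500
DELTA_R_MEDIAN_CUT = -0.35
TRIAL_MEDIAN_CUT = 578
TRIAL_CONF_CUT = 300


@dataclass
class EffectCurve:
    """Sliding-window shift estimates vs a sorting variable."""

    sort_by: str
    window_width: int
    step: int
    table: pd.DataFrame       # x, choice_shift(_se), conf_shift(_se), n_laser
    filters: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.table)


def _split_filters(filters: dict | None) -> tuple[dict, dict]:
    """Separate laser-only filters (on dR) from filters on all trials."""
    laser_only, common = {}, {}
    for col, spec in (filters or {}).items():
        (laser_only if col == "delta_r" else common)[col] = spec
    return laser_only, common


def _apply(df: pd.DataFrame, filters: dict) -> pd.DataFrame:
    from .trials import select_trials

    return select_trials(df, filters) if filters else df


def _window_starts(n: int, width: int, step: int) -> list[int]:
    if width >= n:
        return [0]
    starts = list(range(0, n - width + 1, step))
    if starts[-1] != n - width:
        starts.append(n - width)  # cover the tail so every trial is windowed
    return starts


def _fit_window(
    window_laser: pd.DataFrame,
    comparison: pd.DataFrame,
    indicator: str,
    include_confidence: bool,
) -> dict:
    data = pd.concat([window_laser, comparison], ignore_index=True)
    row: dict = {"n_laser": len(window_laser)}
    try:
        cf = psy.fit_choice_full(data, indicator=indicator)
        row["choice_shift"], row["choice_shift_se"] = psy.choice_shift(cf)
        row["choice_ok"] = True
    except (psy.SeparationError, ValueError, ZeroDivisionError) as exc:
        row.update(choice_shift=np.nan, choice_shift_se=np.nan, choice_ok=False)
        row["choice_error"] = str(exc)
    if include_confidence:
        try:
            wager = data.loc[data["ts_available"].astype(int) == 1]
            if indicator != "laser_on":
                lf = wager.drop(columns=["laser_on"]).rename(columns={indicator: "laser_on"})
            else:
                lf = wager
            conf = psy.fit_confidence(lf)
            row["conf_shift"] = conf.delta
            row["conf_shift_se"] = conf.delta_se
            row["conf_ok"] = conf.converged
        except (ValueError, np.linalg.LinAlgError) as exc:
            row.update(conf_shift=np.nan, conf_shift_se=np.nan, conf_ok=False)
            row["conf_error"] = str(exc)
    return row


def sliding_effect_curve(
    table,
    sort_by: str = "delta_r",
    window_width: int = 2100,
    step: int = 10,
    filters: dict | None = None,
    include_confidence: bool = True,
    indicator: str = "laser_on",
) -> EffectCurve:
    """Choice and confidence shifts over a sliding window of laser trials.

    Laser trials (``indicator`` == 1) passing the filters are sorted by
    ``sort_by`` (stable sort, original order breaks ties); each window of
    ``window_width`` trials, advanced by ``step``, is fit jointly with ALL
    filtered comparison (indicator == 0) trials.  dR filters apply to laser
    trials only (dR is undefined elsewhere); other filters apply to all
    trials.  The abscissa is the window mean of the sorting variable.
    Non-convergent windows are flagged, never dropped.
    """
    df = _as_frame(table)
    laser_only, common = _split_filters(filters)
    df = _apply(df, common)
    laser = df.loc[df[indicator].astype(int) == 1]
    laser = _apply(laser, laser_only)
    comparison = df.loc[df[indicator].astype(int) == 0]
    if sort_by not in laser.columns:
        raise KeyError(f"sort variable {sort_by!r} absent from table")
    laser = laser.loc[laser[sort_by].notna()]
    if len(laser) == 0:
        raise ValueError("no laser trials pass the filters")
    if window_width > len(laser):
        warnings.warn(
            f"window width {window_width} exceeds {len(laser)} laser trials; "
            "falling back to a single window",
            stacklevel=2,
        )
    order = laser[sort_by].to_numpy().argsort(kind="stable")
    laser = laser.iloc[order]

    rows = []
    for s in _window_starts(len(laser), window_width, step):
        win = laser.iloc[s : s + window_width]
        row = _fit_window(win, comparison, indicator, include_confidence)
        row["x"] = float(win[sort_by].mean())
        rows.append(row)
    out = pd.DataFrame(rows).sort_values("x", kind="stable").reset_index(drop=True)
    return EffectCurve(sort_by, window_width, step, out, dict(filters or {}))


def sham_laser_curve(
    no_laser_table,
    n_rep: int = 100,
    sort_by: str = "delta_r",
    window_width: int = 2100,
    step: int = 10,
    seed: int = 0,
    filters: dict | None = None,
    include_confidence: bool = True,
) -> EffectCurve:
    """Null effect curve from fictitious ("sham") laser labels.

    Per repetition, an exact random half of the no-laser trials is labeled
    sham; sham dR is computed against the remaining trials; the sliding
    curve of sham-vs-rest shifts is built exactly as for real laser trials.
    Curves are averaged pointwise across repetitions (exact-half splits keep
    the window grid identical), and the pointwise SE is the between-
    repetition spread of the mean.  Any systematic deviation from zero
    reflects intrinsic rate-choice covariation (choice probability), not
    photosuppression.
    """
    df = _as_frame(no_laser_table)
    _, common = _split_filters(filters)
    df = _apply(df, common)
    root = np.random.SeedSequence(seed)
    curves = []
    for child in root.spawn(n_rep):
        rep_seed = int(child.generate_state(1)[0] % (2**31))
        shammed = delta_r_sham(df, rep_seed)
        curve = sliding_effect_curve(
            shammed,
            sort_by=sort_by,
            window_width=window_width,
            step=step,
            filters=None,
            include_confidence=include_confidence,
            indicator="sham_laser",
        )
        curves.append(curve.table)
    n_windows = min(len(c) for c in curves)
    shift_cols = ["choice_shift"] + (["conf_shift"] if include_confidence else [])
    cols = ["x"] + shift_cols + [f"{c}_se" for c in shift_cols]
    stacked = {c: np.vstack([cv[c].to_numpy()[:n_windows] for cv in curves]) for c in cols}
    out = pd.DataFrame({"x": np.nanmean(stacked["x"], axis=0)})
    for c in shift_cols:
        vals = stacked[c]
        out[c] = np.nanmean(vals, axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            # spread of the mean across relabelings (shrinks as 1/sqrt(n_rep))
            out[f"{c}_se"] = np.nanstd(vals, axis=0, ddof=1) / np.sqrt(
                np.sum(np.isfinite(vals), axis=0).clip(min=1)
            )
            # average single-curve fit SE: the sampling scale of one cohort,
            # appropriate for testing the curve against zero (relabelings
            # share the cohort's realized choices, so the between-rep spread
            # understates cohort-level noise)
            out[f"{c}_fit_se"] = np.nanmean(stacked[f"{c}_se"], axis=0)
    out["n_rep"] = n_rep
    out["n_laser"] = curves[0]["n_laser"].to_numpy()[:n_windows]
    return EffectCurve(sort_by, window_width, step, out, dict(filters or {}))


# --------------------------------------------------------------------------
# interaction GLMs


@dataclass
class GlmInteractionResult:
    """Median-split interaction test for a laser-by-covariate modulation.

    The model adds to the laser choice model an indicator I_S for the split
    (e.g. short duration) and all two-way interactions; the coefficient of
    I_L x I_S (b6) measures whether the laser effect differs across the
    split.  Confidence outcomes use piecewise logistic fits on each flank of
    the bell curve (C < 0 and C > 0, zero included in both) with a
    Bonferroni x2 correction.
    """

    split: str
    outcome: str
    cutoff: float
    filters: dict
    fits: dict                   # side label -> ChoiceFit ("all" for choice)
    beta6: dict
    p: dict
    p_adjusted: float
    n_trials: int

    @property
    def significant(self) -> bool:
        return self.p_adjusted < 0.05


_GLM_NAMES = ["b0", "b1_coh", "b2_laser", "b3_split", "b4_coh_x_laser",
              "b5_coh_x_split", "b6_laser_x_split"]


def _glm_fit(df: pd.DataFrame, y: np.ndarray, split_ind: np.ndarray) -> psy.ChoiceFit:
    C = df["signed_coherence"].to_numpy(float)
    L = df["laser_on"].to_numpy(float)
    S = split_ind.astype(float)
    X = np.column_stack([np.ones_like(C), C, L, S, C * L, C * S, L * S])
    if S.min() == S.max():
        raise ValueError("split indicator is constant: one indicator cell is empty")
    if (L * S).max() == 0 or ((1 - L) * S).max() == 0:
        raise ValueError("empty laser-by-split cell")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("collinear interaction design (split confounded with laser)")
    params, cov, se, t, p, llf = psy._fit_logit(y, X, _GLM_NAMES)
    return psy.ChoiceFit("interaction", _GLM_NAMES, params, cov, se, t, p, llf, len(df))


def _default_split_spec(split: str, outcome: str) -> tuple[float, dict]:
    if split == "duration":
        return DURATION_CUT_MS, {"delta_r": ("<", DELTA_R_CUT), "trial_index": ("<", TRIAL_CUT)}
    if split == "trial_number":
        cut = TRIAL_CONF_CUT if outcome == "confidence" else TRIAL_MEDIAN_CUT
        return cut, {"delta_r": ("<", DELTA_R_CUT), "duration_ms": ("<", DURATION_CUT_MS)}
    if split == "delta_r":
        return DELTA_R_MEDIAN_CUT, {}
    raise ValueError(f"unknown split {split!r}")


def glm_interaction_test(
    table,
    split: str,
    outcome: str = "choice",
    cutoff: float | None = None,
    filters: dict | None = None,
) -> GlmInteractionResult:
    """Test whether the laser effect depends on duration, dR, or trial number.

    Default cutoffs and conditioning follow the analysis conventions:
    duration split at 300 ms conditioned on dR < -0.25 and T < 500;
    trial-number split at 578 (choice) or 300 (confidence) conditioned on
    dR < -0.25 and D < 300 ms; dR split at its median -0.35 (no-laser
    trials receive a leave-self-out dR so the split indicator is not
    confounded with the laser indicator).
    """
    df = _as_frame(table)
    default_cut, default_filters = _default_split_spec(split, outcome)
    if cutoff is None:
        cutoff = default_cut
    if filters is None:
        filters = default_filters
    laser_only, common = _split_filters(filters)
    df = _apply(df, common)
    if laser_only:
        laser = _apply(df.loc[df["laser_on"].astype(int) == 1], laser_only)
        df = pd.concat([laser, df.loc[df["laser_on"].astype(int) == 0]], ignore_index=True)

    if split == "duration":
        S = (df["duration_ms"].to_numpy(float) < cutoff).astype(float)
    elif split == "trial_number":
        S = (df["trial_index"].to_numpy(float) < cutoff).astype(float)
    else:
        # dR is defined only for laser trials by default; give no-laser
        # trials a leave-self-out dR so the split is not confounded with
        # the laser indicator
        no_laser_dr = df.loc[df["laser_on"].astype(int) == 0, "delta_r"]
        if no_laser_dr.isna().all():
            from .neural import add_no_laser_delta_r

            df = add_no_laser_delta_r(df)
        dr = df["delta_r"].to_numpy(float)
        S = (np.nan_to_num(dr, nan=np.inf) < cutoff).astype(float)

    if outcome == "choice":
        sub = df["outcome"] != "sure_bet"
        d = df.loc[sub]
        fit = _glm_fit(d, (d["outcome"] == "pref_choice").to_numpy(float), S[sub.to_numpy()])
        beta6 = {"all": float(fit.params[6])}
        p = {"all": float(fit.pvalues[6])}
        return GlmInteractionResult(
            split, outcome, float(cutoff), dict(filters), {"all": fit},
            beta6, p, p["all"], len(d),
        )
    if outcome != "confidence":
        raise ValueError(f"unknown outcome {outcome!r}")

    sub = df["ts_available"].astype(int) == 1
    d = df.loc[sub]
    Sd = S[sub.to_numpy()]
    y = (d["outcome"] == "sure_bet").to_numpy(float)
    fits, beta6, pvals = {}, {}, {}
    C = d["signed_coherence"].to_numpy(float)
    for label, side in [("neg", C <= 0), ("pos", C >= 0)]:
        fit = _glm_fit(d.loc[side], y[side], Sd[side])
        fits[label] = fit
        beta6[label] = float(fit.params[6])
        pvals[label] = float(fit.pvalues[6])
    p_adj = min(1.0, 2.0 * min(pvals.values()))
    return GlmInteractionResult(
        split, outcome, float(cutoff), dict(filters), fits, beta6, pvals, p_adj, len(d)
    )


# --------------------------------------------------------------------------
# split comparisons


@dataclass
class SplitComparison:
    """Two disjoint trial groups fit and summarized side by side."""

    split: str
    boundary: float
    groups: dict
    filters: dict = field(default_factory=dict)

    def shift_table(self) -> pd.DataFrame:
        rows = []
        for label, g in self.groups.items():
            rows.append(
                {
                    "group": label,
                    "choice_shift": g["choice_shift"],
                    "choice_shift_se": g["choice_shift_se"],
                    "choice_p": g["choice_p"],
                    "conf_shift": g["conf_shift"],
                    "conf_shift_se": g["conf_shift_se"],
                    "conf_p": g["conf_p"],
                    "mean_delta_r": g["mean_delta_r"],
                    "sem_delta_r": g["sem_delta_r"],
                    "n_laser": g["n_laser"],
                    "n_no_laser": g["n_no_laser"],
                }
            )
        return pd.DataFrame(rows)


def _group_summary(group: pd.DataFrame, delta_r_cut: float) -> dict:
    laser = group.loc[
        (group["laser_on"].astype(int) == 1) & (group["delta_r"] < delta_r_cut)
    ]
    no_laser = group.loc[group["laser_on"].astype(int) == 0]
    data = pd.concat([laser, no_laser], ignore_index=True)
    out = {"n_laser": len(laser), "n_no_laser": len(no_laser)}
    try:
        cf = psy.fit_choice_full(data)
        out["choice_fit"] = cf
        out["choice_shift"], out["choice_shift_se"] = psy.choice_shift(cf)
        out["choice_p"] = float(cf.pvalues[2])
    except (psy.SeparationError, ValueError, ZeroDivisionError):
        out.update(choice_fit=None, choice_shift=np.nan, choice_shift_se=np.nan,
                   choice_p=np.nan)
    try:
        conf = psy.fit_confidence(data)
        out["conf_fit"] = conf
        out["conf_shift"] = conf.delta
        out["conf_shift_se"] = conf.delta_se
        out["conf_p"] = conf.delta_p
    except (ValueError, np.linalg.LinAlgError):
        out.update(conf_fit=None, conf_shift=np.nan, conf_shift_se=np.nan,
                   conf_p=np.nan)
    dr = laser["delta_r"].to_numpy(float)
    dr = dr[np.isfinite(dr)]
    out["mean_delta_r"] = float(dr.mean()) if dr.size else float("nan")
    out["sem_delta_r"] = (
        float(np.std(dr, ddof=1) / np.sqrt(dr.size)) if dr.size > 1 else float("nan")
    )
    # coherence-resolved no-laser responses (direction-selectivity summary)
    out["rate_by_coherence"] = (
        no_laser.groupby("signed_coherence")["mu_rate"].agg(["mean", "sem", "size"]).reset_index()
    )
    return out


def early_late_analysis(
    table,
    boundary: int = TRIAL_CUT,
    min_session_trials: int = 800,
    delta_r_cut: float = DELTA_R_CUT,
) -> SplitComparison:
    """Compare laser effects on early (T <= boundary) vs late session trials.

    Only sessions long enough to populate both epochs are used
    (``min_session_trials``); within each epoch the laser group is limited
    to clearly suppressed trials (dR < cutoff) and compared against all
    no-laser trials of that epoch.
    """
    df = _as_frame(table)
    if "delta_r" not in df.columns:
        raise KeyError("delta_r column required; run compute_delta_r first")
    counts = df.groupby("session_id")["trial_index"].max()
    keep = counts[counts >= min_session_trials].index
    if len(keep) == 0:
        raise ValueError(f"no session reaches {min_session_trials} trials")
    df = df.loc[df["session_id"].isin(keep)]
    early = df.loc[df["trial_index"] <= boundary]
    late = df.loc[df["trial_index"] > boundary]
    groups = {
        "early": _group_summary(early, delta_r_cut),
        "late": _group_summary(late, delta_r_cut),
    }
    groups["early"]["n_sessions"] = groups["late"]["n_sessions"] = len(keep)
    return SplitComparison("trial_number", float(boundary), groups,
                           {"delta_r": ("<", delta_r_cut)})


def duration_split_analysis(
    table,
    boundary: float = DURATION_CUT_MS,
    trial_cut: int = TRIAL_CUT,
    delta_r_cut: float = DELTA_R_CUT,
) -> SplitComparison:
    """Compare laser effects on short (D < boundary) vs long stimulus trials.

    Restricted to the first ``trial_cut`` trials of each session (where the
    session-level compensation has not yet taken hold), laser trials with
    dR < cutoff vs all no-laser trials.
    """
    df = _as_frame(table)
    if "delta_r" not in df.columns:
        raise KeyError("delta_r column required; run compute_delta_r first")
    df = df.loc[df["trial_index"] < trial_cut]
    short = df.loc[df["duration_ms"] < boundary]
    long_ = df.loc[df["duration_ms"] >= boundary]
    groups = {
        "short": _group_summary(short, delta_r_cut),
        "long": _group_summary(long_, delta_r_cut),
    }
    return SplitComparison("duration", float(boundary), groups,
                           {"delta_r": ("<", delta_r_cut), "trial_index": ("<", trial_cut)})
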