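"""Trial tables for the motion-discrimination / post-decision-wagering task.

A trial table is a :class:`pandas.DataFrame` with one row per behavioral trial
and a fixed schema (:data:`REQUIRED_COLUMNS`).  The sign convention is global:
``signed_coherence > 0`` means motion toward the preferred direction of the
suppressed neural cluster.  :func:`apply_preference_flip` is the only operation
that changes this mapping (used for outlier sessions whose behavioral effects
ran opposite to the local neural preference).

Derived columns (``delta_r``, ``duration_quartile``) are added by the neural
metrics module; extra columns always pass through I/O untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Unsigned coherence levels (% coherent dots) used in the task.
COHERENCE_SET: tuple[float, ...] = (0.0, 3.2, 6.4, 12.8, 25.6, 51.2)

#: Stimulus/laser duration range in ms (truncated-exponential support).
DURATION_RANGE: tuple[float, float] = (95.0, 925.0)

#: Valid trial outcomes.
OUTCOMES: tuple[str, ...] = ("pref_choice", "null_choice", "sure_bet")

REQUIRED_COLUMNS: tuple[str, ...] = (
    "session_id",
    "trial_index",
    "signed_coherence",
    "duration_ms",
    "laser_on",
    "ts_available",
    "outcome",
    "correct",
    "rewarded",
    "mu_count",
    "mu_rate",
)

#: Schema version written as a comment line at the top of delimited files.
SCHEMA_VERSION = "optobias-trials-1"

#: Analysis window for multi-unit counts: 60 ms after stimulus onset to 60 ms
#: after offset, so the window length equals the stimulus duration.
COUNT_WINDOW_OFFSET_MS = 60.0


class SchemaError(ValueError):
    """A required column is missing or unparseable."""


class TrialValidationError(ValueError):
    """A trial table violates a schema invariant."""


@dataclass(frozen=True)
class Violation:
    """One invariant violation located by row (positional index) and column."""

    row: int | None
    column: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - repr convenience
        where = "table" if self.row is None else f"row {self.row}"
        return f"{where} [{self.column}]: {self.message}"


@dataclass
class SessionMeta:
    """Per-session metadata.

    reward_ratio is the sure-bet reward size relative to the direction-choice
    reward (must lie in (0, 1) — the sure bet is smaller but guaranteed).
    """

    session_id: str
    monkey: str = "sim"
    preference_flipped: bool = False
    ramp_down_used: bool = True
    laser_power_mW: float = 1.0
    reward_ratio: float = 0.55

    def __post_init__(self) -> None:
        if not (0.0 < self.reward_ratio < 1.0):
            raise ValueError(f"reward_ratio must be in (0,1), got {self.reward_ratio}")


@dataclass
class TrialTable:
    """Ordered trial records plus a per-session metadata index."""

    trials: pd.DataFrame
    sessions: dict[str, SessionMeta] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.trials.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        for sid in self.trials["session_id"].unique():
            self.sessions.setdefault(str(sid), SessionMeta(session_id=str(sid)))

    def __len__(self) -> int:
        return len(self.trials)

    def copy(self) -> "TrialTable":
        return TrialTable(
            self.trials.copy(),
            {k: SessionMeta(**vars(v)) for k, v in self.sessions.items()},
        )


def _as_frame(table: "TrialTable | pd.DataFrame") -> pd.DataFrame:
    return table.trials if isinstance(table, TrialTable) else table


def validate_trials(
    table: "TrialTable | pd.DataFrame",
    coherence_set: Sequence[float] = COHERENCE_SET,
    duration_range: tuple[float, float] = DURATION_RANGE,
) -> list[Violation]:
    """Check every schema invariant; return a report (empty iff valid).

    Violations are report entries, never exceptions: callers decide whether a
    dirty table is fatal.
    """
    df = _as_frame(table)
    report: list[Violation] = []
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            report.append(Violation(None, col, "required column missing"))
    if report:
        return report

    coh_ok = np.isclose(
        np.abs(df["signed_coherence"].to_numpy(float))[:, None],
        np.asarray(coherence_set, float)[None, :],
        atol=1e-9,
    ).any(axis=1)
    for i in np.flatnonzero(~coh_ok):
        report.append(
            Violation(
                int(i),
                "signed_coherence",
                f"|C|={abs(df['signed_coherence'].iat[i]):g} not in coherence set "
                f"{tuple(coherence_set)}",
            )
        )

    lo, hi = duration_range
    dur = df["duration_ms"].to_numpy(float)
    for i in np.flatnonzero((dur < lo) | (dur > hi)):
        report.append(
            Violation(int(i), "duration_ms", f"D={dur[i]:g} outside [{lo:g}, {hi:g}] ms")
        )

    bad_outcome = ~df["outcome"].isin(OUTCOMES)
    for i in np.flatnonzero(bad_outcome.to_numpy()):
        report.append(Violation(int(i), "outcome", f"unknown outcome {df['outcome'].iat[i]!r}"))

    sb_no_ts = (df["outcome"] == "sure_bet") & (df["ts_available"].astype(int) == 0)
    for i in np.flatnonzero(sb_no_ts.to_numpy()):
        report.append(
            Violation(int(i), "ts_available", "sure_bet outcome on a trial without the sure-bet target")
        )

    if (df["mu_count"].to_numpy(float) < 0).any():
        for i in np.flatnonzero(df["mu_count"].to_numpy(float) < 0):
            report.append(Violation(int(i), "mu_count", "negative spike count"))

    # mu_rate must equal mu_count over the analysis-window duration (= D) in s.
    expect = df["mu_count"].to_numpy(float) / (dur / 1000.0)
    rate = df["mu_rate"].to_numpy(float)
    off = ~np.isclose(rate, expect, rtol=1e-6, atol=0.5)
    for i in np.flatnonzero(off):
        report.append(
            Violation(
                int(i),
                "mu_rate",
                f"mu_rate={rate[i]:g} inconsistent with mu_count/duration={expect[i]:g}",
            )
        )

    dup = df.duplicated(subset=["session_id", "trial_index"])
    for i in np.flatnonzero(dup.to_numpy()):
        report.append(Violation(int(i), "trial_index", "duplicate trial_index within session"))
    return report


def _parse_numeric(df: pd.DataFrame, col: str, kind: type) -> pd.Series:
    try:
        return df[col].astype(kind)
    except (ValueError, TypeError):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = int(np.flatnonzero(coerced.isna().to_numpy())[0])
        raise SchemaError(
            f"column {col!r}: unparseable numeric value {df[col].iat[bad]!r} at row {bad}"
        ) from None


def read_trials(
    path: str | Path,
    dialect: str = "delimited",
    validate: bool = True,
) -> TrialTable:
    """Read a trial table from disk.

    ``dialect='delimited'`` (the contract) reads tab-separated UTF-8 text with
    a header row and optional leading ``#`` comment lines.  ``dialect='mat_v5'``
    is a best-effort adapter for MATLAB v5 files holding the same named arrays.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "mat_v5":
        df = _read_mat_v5(path)
    elif dialect == "delimited":
        df = pd.read_csv(path, sep="\t", comment="#", dtype={"session_id": str})
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    for col, kind in [
        ("trial_index", int),
        ("signed_coherence", float),
        ("duration_ms", float),
        ("laser_on", int),
        ("ts_available", int),
        ("correct", float),  # NaN allowed (undefined for sure-bet / 0% coh)
        ("rewarded", int),
        ("mu_count", int),
        ("mu_rate", float),
    ]:
        df[col] = _parse_numeric(df, col, kind)
    if "delta_r" in df.columns:
        df["delta_r"] = pd.to_numeric(df["delta_r"], errors="coerce")

    table = TrialTable(df)
    if validate:
        report = validate_trials(table)
        if report:
            raise TrialValidationError(
                f"{len(report)} invariant violation(s); first: {report[0]}"
            )
    return table


def _read_mat_v5(path: Path) -> pd.DataFrame:
    from scipy.io import loadmat

    raw = loadmat(path, squeeze_me=True, simplify_cells=True)
    cols = {}
    for col in REQUIRED_COLUMNS:
        if col in raw:
            cols[col] = np.atleast_1d(raw[col])
    if "session_id" in cols:
        cols["session_id"] = [str(s) for s in cols["session_id"]]
    return pd.DataFrame(cols)


def write_trials(table: "TrialTable | pd.DataFrame", path: str | Path) -> Path:
    """Write a delimited trial table (lossless to >= 10 significant digits)."""
    df = _as_frame(table)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# schema: {SCHEMA_VERSION}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.12g")
    return path


def apply_preference_flip(table: TrialTable, session_id: str) -> TrialTable:
    """Reverse the preferred-direction convention for one session.

    Negates signed coherence and swaps pref/null outcomes for that session
    only; ``correct``/``rewarded`` and neural counts are unchanged (the trial
    happened; only its frame of reference changes).  Involution: flipping
    twice restores the original table.
    """
    if session_id not in set(table.trials["session_id"].astype(str)):
        raise KeyError(f"unknown session_id {session_id!r}")
    out = table.copy()
    df = out.trials
    m = df["session_id"].astype(str) == str(session_id)
    df.loc[m, "signed_coherence"] = -df.loc[m, "signed_coherence"]
    # avoid -0.0 artifacts so flip∘flip is bit-identical
    df.loc[m & (df["signed_coherence"] == 0.0), "signed_coherence"] = 0.0
    swap = {"pref_choice": "null_choice", "null_choice": "pref_choice"}
    df.loc[m, "outcome"] = df.loc[m, "outcome"].map(lambda o: swap.get(o, o))
    meta = out.sessions[str(session_id)]
    meta.preference_flipped = not meta.preference_flipped
    return out


# Filter specs: column -> value (equality), (op, value) with op in
# {"<", "<=", ">", ">=", "=="}, or a callable Series -> bool mask.
FilterSpec = Mapping[str, object]


def select_trials(
    table: "TrialTable | pd.DataFrame",
    filters: FilterSpec | None = None,
    where: Callable[[pd.DataFrame], "pd.Series | np.ndarray"] | None = None,
) -> pd.DataFrame:
    """Select rows satisfying every filter; order preserved.

    ``filters`` maps column names to an equality value, an ``(op, value)``
    pair, or a per-column callable.  Filters referencing a derived column
    (e.g. ``delta_r``) require it to be present.
    """
    df = _as_frame(table)
    mask = np.ones(len(df), dtype=bool)
    for col, spec in (filters or {}).items():
        if col not in df.columns:
            raise KeyError(
                f"filter references column {col!r} absent from table "
                "(derived columns must be computed first)"
            )
        series = df[col]
        if callable(spec):
            m = np.asarray(spec(series), dtype=bool)
        elif isinstance(spec, tuple) and len(spec) == 2 and isinstance(spec[0], str):
            op, val = spec
            ops = {
                "<": series < val,
                "<=": series <= val,
                ">": series > val,
                ">=": series >= val,
                "==": series == val,
            }
            if op not in ops:
                raise ValueError(f"unknown filter op {op!r}")
            m = ops[op].to_numpy()
        else:
            m = (series == spec).to_numpy()
        mask &= np.asarray(m, dtype=bool) & ~pd.isna(series).to_numpy()
    if where is not None:
        mask &= np.asarray(where(df), dtype=bool)
    return df.loc[mask]


def choice_trials(table: "TrialTable | pd.DataFrame") -> pd.DataFrame:
    """Direction-choice trials: sure-bet outcomes excluded.

    Includes both sure-bet-unavailable and sure-bet-waived trials, which is
    how all choice analyses are run unless noted.
    """
    df = _as_frame(table)
    return df.loc[df["outcome"] != "sure_bet"]


def wager_trials(table: "TrialTable | pd.DataFrame") -> pd.DataFrame:
    """Trials where the sure-bet target was available (confidence analyses)."""
    df = _as_frame(table)
    return df.loc[df["ts_available"].astype(int) == 1]
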