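"""End-to-end pipeline: simulate (or load) a cohort, compute suppression
indices, fit the psychometric models, run the dynamics analyses, and write a
machine-readable summary.

Re-running with the same configuration is bit-identical: every stochastic
stage draws its seed deterministically from the single root seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from statsmodels.stats.proportion import proportion_confint

from . import dynamics, neural, psychometrics as psy
from .simulate import SimConfig, config_from_dict, config_to_dict, generate_sessions
from .trials import TrialTable, read_trials, write_trials

__all__ = [
    "RunConfig",
    "run_pipeline",
    "summarize_reward_rate",
    "proportion_summary",
]

_ANALYSIS_KEYS = {
    "delta_r_strong_cut": -0.45,
    "delta_r_cut": -0.25,
    "duration_cut_ms": 300.0,
    "trial_cut": 500,
    "min_session_trials": 800,
    "window_width": 2100,
    "window_step": 10,
    "n_boot": 2000,
    "n_rep_sham": 100,
    "run_sliding": False,
    "run_sham": False,
    "include_confidence_curves": True,
}


@dataclass
class RunConfig:
    """Configuration for one reproducible pipeline run."""

    out_dir: str = "results/run"
    seed: int = 0
    simulate: SimConfig | None = None
    input_path: str | None = None
    analysis: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.input_path is None):
            raise ValueError("exactly one of 'simulate' or 'input_path' must be set")
        unknown = set(self.analysis) - set(_ANALYSIS_KEYS)
        if unknown:
            raise ValueError(f"unknown analysis key(s): {sorted(unknown)}")
        merged = dict(_ANALYSIS_KEYS)
        merged.update(self.analysis)
        self.analysis = merged

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {"out_dir", "seed", "simulate", "input_path", "analysis"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "simulate" in raw and raw["simulate"] is not None:
            raw["simulate"] = config_from_dict(raw["simulate"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = {"out_dir": self.out_dir, "seed": self.seed, "analysis": dict(self.analysis)}
        d["simulate"] = config_to_dict(self.simulate) if self.simulate else None
        d["input_path"] = self.input_path
        return d


def summarize_reward_rate(table, reward_ratio: float = 0.55) -> dict:
    """Mean reward per trial (in direction-reward units) by laser condition.

    Correct direction choices earn 1 unit, sure-bet choices earn
    ``reward_ratio`` units, errors earn 0.  Returns the two rates and their
    laser/no-laser ratio.
    """
    df = table.trials if isinstance(table, TrialTable) else table
    amount = np.where(
        df["outcome"] == "sure_bet",
        reward_ratio,
        df["rewarded"].to_numpy(float),
    )
    laser = df["laser_on"].astype(int).to_numpy() == 1
    rate_laser = float(amount[laser].mean()) if laser.any() else float("nan")
    rate_no = float(amount[~laser].mean()) if (~laser).any() else float("nan")
    return {
        "reward_rate_laser": rate_laser,
        "reward_rate_no_laser": rate_no,
        "reward_rate_ratio": rate_laser / rate_no if rate_no else float("nan"),
    }


def proportion_summary(k: int, n: int) -> dict:
    """Percentage with a 95% Wilson score interval."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not (0 <= k <= n):
        raise ValueError("k must satisfy 0 <= k <= n")
    lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
    return {
        "percent": 100.0 * k / n,
        "ci_low": 100.0 * float(lo),
        "ci_high": 100.0 * float(hi),
        "k": int(k),
        "n": int(n),
    }


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (bool, int, float, str)) or obj is None:
        return obj
    return str(obj)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write its report bundle.

    Stages: simulate/load -> validate -> dR -> pooled choice/confidence
    fits (strong-suppression subset vs all no-laser trials) -> sure-bet
    sensitivity check -> interaction GLMs -> early/late and short/long
    splits -> optional sliding and sham curves.  Writes delimited tables,
    ``summary.json``, and a plain-text log under ``out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    a = config.analysis
    log: list[str] = []
    cfg_dict = config.to_dict()
    cfg_dict.pop("out_dir")  # hash the scientific config, not where it lands
    cfg_hash = hashlib.sha256(
        json.dumps(_jsonable(cfg_dict), sort_keys=True).encode()
    ).hexdigest()[:16]
    log.append(f"config_hash: {cfg_hash}")
    log.append(f"seed: {config.seed}")

    def stage(name):
        log.append(f"stage: {name}")

    try:
        if config.simulate is not None:
            stage("simulate")
            sim = config.simulate
            sim.seed = config.seed
            table, _, truth = generate_sessions(sim)
            truth.to_csv(out / "ground_truth.tsv", sep="\t", index=False)
        else:
            stage("load")
            table = read_trials(config.input_path)
            truth = None
        df = table.trials
        log.append(f"n_trials: {len(df)}")

        stage("delta_r")
        df, dr_index = neural.compute_delta_r(df)
        n_undef = int(dr_index["undefined"].sum())
        log.append(f"delta_r_undefined: {n_undef}")
        write_trials(df, out / "trials_with_delta_r.tsv")

        summary: dict = {"config_hash": cfg_hash, "seed": config.seed, "n_trials": len(df)}
        laser_dr = df.loc[df["laser_on"].astype(int) == 1, "delta_r"].dropna()
        summary["mean_delta_r"] = float(laser_dr.mean())
        summary["sem_delta_r"] = float(laser_dr.std(ddof=1) / np.sqrt(len(laser_dr)))

        stage("pooled_fits")
        strong = df.loc[
            (df["laser_on"].astype(int) == 1) & (df["delta_r"] < a["delta_r_strong_cut"])
        ]
        no_laser = df.loc[df["laser_on"].astype(int) == 0]
        pooled = pd.concat([strong, no_laser], ignore_index=True)
        summary["n_strong_suppression_laser"] = len(strong)
        try:
            cf = psy.fit_choice_full(pooled)
            shift, shift_se = psy.choice_shift(cf)
            summary["choice_shift_strong"] = shift
            summary["choice_shift_strong_se"] = shift_se
            summary["choice_shift_strong_p"] = float(cf.pvalues[2])
        except (psy.SeparationError, ValueError) as exc:
            log.append(f"pooled choice fit failed: {exc}")
        try:
            conf = psy.fit_confidence(pooled)
            summary["conf_shift_strong"] = conf.delta
            summary["conf_shift_strong_se"] = conf.delta_se
            summary["conf_shift_strong_p"] = conf.delta_p
        except (ValueError, np.linalg.LinAlgError) as exc:
            log.append(f"pooled confidence fit failed: {exc}")

        stage("ts_sensitivity")
        try:
            ts = psy.fit_ts_sensitivity(df)
            summary["ts_interaction_b3"] = float(ts.params[3])
            summary["ts_interaction_p"] = float(ts.pvalues[3])
        except (psy.SeparationError, ValueError) as exc:
            log.append(f"ts sensitivity fit failed: {exc}")

        stage("reward_rate")
        ratio = (
            config.simulate.reward_ratio
            if config.simulate is not None
            else next(iter(table.sessions.values())).reward_ratio
        )
        summary.update(summarize_reward_rate(df, reward_ratio=ratio))

        stage("glm_interactions")
        for split in ("duration", "trial_number"):
            for outcome in ("choice", "confidence"):
                try:
                    res = dynamics.glm_interaction_test(df, split, outcome)
                    summary[f"glm_{split}_{outcome}_p"] = res.p_adjusted
                except (ValueError, psy.SeparationError) as exc:
                    log.append(f"glm {split}/{outcome} failed: {exc}")

        stage("early_late")
        try:
            el = dynamics.early_late_analysis(
                df,
                boundary=a["trial_cut"],
                min_session_trials=a["min_session_trials"],
                delta_r_cut=a["delta_r_cut"],
            )
            el.shift_table().to_csv(out / "early_late.tsv", sep="\t", index=False)
            for label, g in el.groups.items():
                summary[f"{label}_choice_shift"] = g["choice_shift"]
                summary[f"{label}_choice_shift_se"] = g["choice_shift_se"]
                summary[f"{label}_conf_shift"] = g["conf_shift"]
                summary[f"{label}_conf_shift_se"] = g["conf_shift_se"]
                summary[f"{label}_mean_delta_r"] = g["mean_delta_r"]
        except (ValueError, KeyError) as exc:
            log.append(f"early/late failed: {exc}")

        stage("duration_split")
        try:
            ds = dynamics.duration_split_analysis(
                df,
                boundary=a["duration_cut_ms"],
                trial_cut=a["trial_cut"],
                delta_r_cut=a["delta_r_cut"],
            )
            ds.shift_table().to_csv(out / "duration_split.tsv", sep="\t", index=False)
            for label, g in ds.groups.items():
                summary[f"{label}_choice_shift"] = g["choice_shift"]
                summary[f"{label}_choice_shift_se"] = g["choice_shift_se"]
                summary[f"{label}_conf_shift"] = g["conf_shift"]
                summary[f"{label}_conf_shift_se"] = g["conf_shift_se"]
                summary[f"{label}_mean_delta_r"] = g["mean_delta_r"]
        except (ValueError, KeyError) as exc:
            log.append(f"duration split failed: {exc}")

        if a["run_sliding"]:
            stage("sliding")
            curve = dynamics.sliding_effect_curve(
                df,
                sort_by="delta_r",
                window_width=a["window_width"],
                step=a["window_step"],
                include_confidence=a["include_confidence_curves"],
            )
            curve.table.to_csv(out / "sliding_delta_r.tsv", sep="\t", index=False)
            summary["sliding_n_windows"] = len(curve)

        if a["run_sham"]:
            stage("sham")
            sham = dynamics.sham_laser_curve(
                no_laser,
                n_rep=a["n_rep_sham"],
                window_width=a["window_width"],
                step=a["window_step"],
                seed=config.seed + 1,
                include_confidence=a["include_confidence_curves"],
            )
            sham.table.to_csv(out / "sham_curve.tsv", sep="\t", index=False)
            summary["sham_max_abs_choice_shift"] = float(
                np.nanmax(np.abs(sham.table["choice_shift"]))
            )
    except Exception as exc:
        log.append(f"ABORTED: {type(exc).__name__}: {exc}")
        (out / "run.log").write_text("\n".join(log) + "\n", encoding="utf-8")
        raise RuntimeError(f"pipeline aborted at {log[-2] if len(log) > 1 else '?'}: {exc}") from exc

    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(_jsonable(summary), fh, indent=2, sort_keys=True)
    (out / "run.log").write_text("\n".join(log) + "\n", encoding="utf-8")
    return summary
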