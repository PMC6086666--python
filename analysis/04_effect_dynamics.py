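#!/usr/bin/env python
"""Compensation dynamics: do the behavioral effects fade across the session
and within the trial while the neural suppression stays constant?

Runs the early/late and short/long-duration split comparisons, the
median-split interaction GLMs, and sliding-window curves over trial number
and duration.  Writes results/early_late.tsv, results/duration_split.tsv,
results/sliding_trials.tsv, results/sliding_duration.tsv.
"""

from pathlib import Path

from optobias import (
    duration_split_analysis,
    early_late_analysis,
    glm_interaction_test,
    read_trials,
)
from optobias.dynamics import sliding_effect_curve

OUT = Path("results")


def main() -> None:
    df = read_trials(OUT / "cohort_delta_r.tsv").trials

    el = early_late_analysis(df, boundary=500, min_session_trials=800)
    el.shift_table().to_csv(OUT / "early_late.tsv", sep="\t", index=False)
    for label, g in el.groups.items():
        print(f"{label:5s}: choice shift {g['choice_shift']:+.2f} "
              f"+/- {g['choice_shift_se']:.2f}% coh; "
              f"confidence {g['conf_shift']:+.2f}; mean dR {g['mean_delta_r']:.3f}")

    ds = duration_split_analysis(df, boundary=300.0, trial_cut=500)
    ds.shift_table().to_csv(OUT / "duration_split.tsv", sep="\t", index=False)
    for label, g in ds.groups.items():
        print(f"{label:5s}: choice shift {g['choice_shift']:+.2f} "
              f"+/- {g['choice_shift_se']:.2f}% coh; "
              f"confidence {g['conf_shift']:+.2f}; mean dR {g['mean_delta_r']:.3f}")

    for split in ("duration", "trial_number"):
        for outcome in ("choice", "confidence"):
            res = glm_interaction_test(df, split, outcome)
            print(f"interaction {split} x laser ({outcome}): "
                  f"p = {res.p_adjusted:.4g}")

    for sort_by, width, fname, filters in [
        ("trial_index", 1750, "sliding_trials.tsv",
         {"delta_r": ("<", -0.25), "duration_ms": ("<", 300.0)}),
        ("duration_ms", 1600, "sliding_duration.tsv",
         {"delta_r": ("<", -0.25), "trial_index": ("<", 500)}),
    ]:
        curve = sliding_effect_curve(
            df, sort_by=sort_by, window_width=width, step=200,
            filters=filters, include_confidence=True,
        )
        curve.table.to_csv(OUT / fname, sep="\t", index=False)
        t = curve.table
        print(f"sliding {sort_by}: shift {t['choice_shift'].iloc[0]:+.2f}% coh at "
              f"{t['x'].iloc[0]:.0f} -> {t['choice_shift'].iloc[-1]:+.2f}% coh at "
              f"{t['x'].iloc[-1]:.0f}")


if __name__ == "__main__":
    main()
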