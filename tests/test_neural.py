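import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from optobias import (
    SimConfig,
    SpikeTrainSet,
    bootstrap_delta_r_diff,
    compute_delta_r,
    compute_psth,
    delta_r_sham,
    generate_sessions,
    neurometric_threshold,
    read_spike_sidecar,
    su_suppression_summary,
    write_spike_sidecar,
)


def _mini_table(rates_laser, rates_no_laser, coh=12.8):
    """One session, one coherence/direction, durations in one quartile band."""
    rows = []
    t = 1
    for r in rates_no_laser:
        rows.append(("S", t, coh, 1000.0 * 10 / max(r, 1e-9) if r else 400.0, 0, r))
        t += 1
    for r in rates_laser:
        rows.append(("S", t, coh, 400.0, 1, r))
        t += 1
    df = pd.DataFrame(
        rows, columns=["session_id", "trial_index", "signed_coherence",
                       "duration_ms", "laser_on", "mu_rate"]
    )
    df["duration_ms"] = 400.0
    df["ts_available"] = 0
    df["outcome"] = "pref_choice"
    df["correct"] = 1.0
    df["rewarded"] = 1
    df["mu_count"] = (df["mu_rate"] * 0.4).round().astype(int)
    return df


class TestDeltaR:
    def test_hand_computed_case(self):
        df = _mini_table([30.0], [40.0, 60.0])
        out, idx = compute_delta_r(df)
        dr = out.loc[out["laser_on"] == 1, "delta_r"].iloc[0]
        assert dr == pytest.approx(-0.4)
        assert idx["group_n"].iloc[0] == 2

    def test_matched_mean_gives_zero(self):
        df = _mini_table([50.0], [40.0, 60.0])
        out, _ = compute_delta_r(df)
        assert out.loc[out["laser_on"] == 1, "delta_r"].iloc[0] == pytest.approx(0.0)

    def test_empty_matched_group_flagged_undefined(self):
        df = _mini_table([30.0], [40.0])
        df.loc[df["laser_on"] == 0, "signed_coherence"] = -12.8  # different direction
        out, idx = compute_delta_r(df)
        assert out.loc[out["laser_on"] == 1, "delta_r"].isna().all()
        assert idx["undefined"].all()

    def test_scale_invariance(self):
        df = _mini_table([30.0, 20.0], [40.0, 60.0, 50.0])
        out1, _ = compute_delta_r(df)
        df2 = df.copy()
        df2["mu_rate"] *= 7.3
        out2, _ = compute_delta_r(df2)
        np.testing.assert_allclose(
            out1["delta_r"].dropna(), out2["delta_r"].dropna(), rtol=1e-12
        )

    def test_no_laser_rows_have_no_delta_r(self):
        df = _mini_table([30.0], [40.0, 60.0])
        out, _ = compute_delta_r(df)
        assert out.loc[out["laser_on"] == 0, "delta_r"].isna().all()


class TestShamDeltaR:
    def test_deterministic_given_seed(self, null_cohort):
        df, _ = null_cohort
        no_laser = df[df["laser_on"] == 0].drop(columns=["delta_r", "duration_quartile"])
        a = delta_r_sham(no_laser, seed=5)
        b = delta_r_sham(no_laser, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_rejects_laser_trials(self, null_cohort):
        df, _ = null_cohort
        with pytest.raises(ValueError):
            delta_r_sham(df, seed=1)

    def test_sham_mean_near_zero_on_homogeneous_rates(self):
        """With rate-homogeneous trials and large matched groups the sham
        construction is an unbiased null: mean sham dR ~ 0."""
        cfg = SimConfig(n_sessions=1, trials_per_session=8000, tuning_gain=0.0,
                        laser_fraction=0.0, s0=0.0, seed=71)
        table, _, _ = generate_sessions(cfg)
        sham = delta_r_sham(table.trials, seed=9)
        dr = sham["delta_r"].dropna()
        sem = dr.std(ddof=1) / np.sqrt(len(dr))
        assert abs(dr.mean()) < 2 * sem + 0.005

    def test_relabeling_spread_matches_binomial_split(self, null_cohort):
        """The between-relabeling SD of the mean sham dR should be of the
        order SD(dR)/sqrt(n_sham) (random half-splits)."""
        df, _ = null_cohort
        no_laser = df[df["laser_on"] == 0].drop(columns=["delta_r", "duration_quartile"])
        means = []
        for s in range(60):
            dr = delta_r_sham(no_laser, seed=100 + s)["delta_r"].dropna()
            means.append(dr.mean())
        between = np.std(means, ddof=1)
        one = delta_r_sham(no_laser, seed=100)["delta_r"].dropna()
        predicted = one.std(ddof=1) / np.sqrt(len(one))
        assert 0.3 * predicted < between < 3.0 * predicted


class TestPsth:
    def test_no_spikes_zero_trace(self):
        s = SpikeTrainSet([np.array([]), np.array([])], [300.0, 300.0])
        trace = compute_psth(s, window=(0.0, 200.0))
        assert np.all(trace.rate == 0.0)
        assert trace.rate.size == 200

    def test_single_spike_boxcar_response(self):
        """One spike at 100 ms in one trial: the causal 40 ms boxcar puts
        1/40 spikes/ms = 25 sp/s on bins 100-139 and nothing elsewhere."""
        s = SpikeTrainSet([np.array([100.2])], [300.0])
        trace = compute_psth(s, window=(0.0, 300.0))
        t = trace.time_ms
        on = (t >= 100) & (t < 140)
        np.testing.assert_allclose(trace.rate[on], 25.0)
        np.testing.assert_allclose(trace.rate[~on], 0.0)

    def test_homogeneous_rate_recovered(self):
        rng = np.random.default_rng(0)
        trains = []
        for _ in range(500):
            n = rng.poisson(80 * 0.5)
            trains.append(np.sort(rng.random(n) * 500.0))
        s = SpikeTrainSet(trains, np.full(500, 500.0))
        trace = compute_psth(s, window=(0.0, 500.0))
        interior = trace.rate[trace.time_ms >= 40]
        assert np.all(np.abs(interior - 80.0) < 8.0)
        assert abs(interior.mean() - 80.0) < 1.0

    def test_spike_mass_conserved_in_interior(self):
        """Away from window edges the boxcar redistributes but conserves
        total spike mass."""
        rng = np.random.default_rng(1)
        trains = [np.sort(100.0 + rng.random(20) * 200.0) for _ in range(30)]
        s = SpikeTrainSet(trains, np.full(30, 400.0))
        trace = compute_psth(s, window=(0.0, 400.0))
        total_rate_mass = trace.rate.sum() / 1000.0 * s.__len__()  # sp/ms * ms * trials
        total_spikes = sum(len(t) for t in trains)
        assert total_rate_mass == pytest.approx(total_spikes, rel=1e-9)

    def test_empty_window_rejected(self):
        s = SpikeTrainSet([np.array([1.0])], [300.0])
        with pytest.raises(ValueError):
            compute_psth(s, window=(100.0, 100.0))

    def test_sidecar_roundtrip(self, tmp_path):
        s = SpikeTrainSet(
            [np.array([1.25, 7.5]), np.array([]), np.array([3.0])],
            [300.0, 250.0, 400.0],
            trial_index=np.array([1, 2, 3]),
        )
        p = write_spike_sidecar(s, tmp_path / "spk.txt")
        back = read_spike_sidecar(p)
        assert len(back) == 3
        np.testing.assert_allclose(back.offsets_ms, s.offsets_ms)
        np.testing.assert_allclose(back.trains[0], s.trains[0])
        assert back.trains[1].size == 0


class TestSuSuppression:
    def test_laser_at_baseline_is_full_suppression(self):
        units = pd.DataFrame(
            {"baseline_rate": [10.0], "stim_rate": [50.0], "stim_laser_rate": [10.0]}
        )
        s = su_suppression_summary(units)
        assert s.baseline_subtracted_mean == pytest.approx(100.0)
        assert s.raw_mean == pytest.approx(80.0)

    def test_no_change_gives_zero(self):
        units = pd.DataFrame(
            {"baseline_rate": [10.0, 5.0], "stim_rate": [50.0, 30.0],
             "stim_laser_rate": [50.0, 30.0]}
        )
        s = su_suppression_summary(units)
        assert s.baseline_subtracted_mean == pytest.approx(0.0)
        assert s.raw_mean == pytest.approx(0.0)

    def test_nonresponsive_unit_excluded(self):
        units = pd.DataFrame(
            {"baseline_rate": [10.0, 20.0], "stim_rate": [50.0, 20.0],
             "stim_laser_rate": [10.0, 5.0]}
        )
        s = su_suppression_summary(units)
        assert s.n_units == 1 and s.n_excluded == 1

    def test_below_baseline_suppression_exceeds_100_percent(self):
        units = pd.DataFrame(
            {"baseline_rate": [10.0], "stim_rate": [50.0], "stim_laser_rate": [6.0]}
        )
        s = su_suppression_summary(units)
        assert s.baseline_subtracted_mean == pytest.approx(110.0)


def _roc_consistent_table(alpha=25.0, k=1.5, n_per_level=500, seed=0):
    """Rates whose pref/null distributions realize the ROC areas implied by
    a Weibull ideal-observer curve: normal rate distributions separated by
    d' = sqrt(2) * Phi^-1(PC)."""
    rng = np.random.default_rng(seed)
    rows = []
    t = 1
    for c in (3.2, 6.4, 12.8, 25.6, 51.2):
        pc = 1.0 - 0.5 * np.exp(-((c / alpha) ** k))
        d = np.sqrt(2.0) * norm.ppf(pc)
        for sign, loc in ((1, d), (-1, 0.0)):
            for r in rng.normal(loc * 2.0 + 20.0, 2.0, size=n_per_level):
                rows.append(("S", t, sign * c, 400.0, 0, max(r, 0.0)))
                t += 1
    df = pd.DataFrame(
        rows, columns=["session_id", "trial_index", "signed_coherence",
                       "duration_ms", "laser_on", "mu_rate"]
    )
    df["ts_available"] = 0
    df["outcome"] = "pref_choice"
    df["correct"] = 1.0
    df["rewarded"] = 1
    df["mu_count"] = (df["mu_rate"] * 0.4).round().astype(int)
    return df


class TestNeurometric:
    def test_weibull_alpha_recovery(self):
        df = _roc_consistent_table(alpha=25.0, k=1.5, n_per_level=500, seed=3)
        fit = neurometric_threshold(df)
        assert abs(fit.alpha - 25.0) / 25.0 < 0.15

    def test_chance_performance_unidentifiable(self):
        df = _roc_consistent_table(alpha=25.0, k=1.5, n_per_level=200, seed=4)
        rng = np.random.default_rng(5)
        df["mu_rate"] = rng.normal(20.0, 2.0, size=len(df))  # no direction signal
        with pytest.raises(ValueError, match="chance|nidentifiable"):
            neurometric_threshold(df)

    def test_roc_invariant_under_monotone_transform(self):
        df = _roc_consistent_table(seed=6, n_per_level=300)
        fit1 = neurometric_threshold(df)
        df2 = df.copy()
        df2["mu_rate"] = np.exp(df2["mu_rate"] / 10.0)
        fit2 = neurometric_threshold(df2)
        # per-session normalization differs, but ROC (rank-based) does not
        np.testing.assert_allclose(fit1.roc_areas, fit2.roc_areas, atol=1e-12)

    def test_step_performance_localizes_alpha(self):
        """Near-step ideal-observer performance (chance below a boundary,
        perfect above) must place alpha within one coherence step."""
        rng = np.random.default_rng(7)
        rows = []
        t = 1
        for c in (3.2, 6.4, 12.8, 25.6, 51.2):
            sep = 0.0 if c < 20.0 else 30.0
            for sign, loc in ((1, sep), (-1, 0.0)):
                for r in rng.normal(loc + 20.0, 1.0, size=300):
                    rows.append(("S", t, sign * c, 400.0, 0, max(r, 0.0)))
                    t += 1
        df = pd.DataFrame(
            rows, columns=["session_id", "trial_index", "signed_coherence",
                           "duration_ms", "laser_on", "mu_rate"]
        )
        df["ts_available"] = 0
        df["outcome"] = "pref_choice"
        df["correct"] = 1.0
        df["rewarded"] = 1
        df["mu_count"] = (df["mu_rate"] * 0.4).round().astype(int)
        fit = neurometric_threshold(df)
        assert 12.8 <= fit.alpha <= 25.6 + 1e-9


class TestBootstrap:
    def test_identical_groups_ci_contains_zero(self):
        rng = np.random.default_rng(8)
        g = rng.normal(-0.3, 0.1, size=1000)
        res = bootstrap_delta_r_diff(g, g.copy(), n_boot=1000, seed=1)
        assert res["ci"][0] <= 0.0 <= res["ci"][1]
        assert res["difference"] == pytest.approx(0.0)

    def test_small_n_boot_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_delta_r_diff([0.1], [0.2], n_boot=10)

    def test_offset_detected_with_coverage(self):
        """Groups offset by 0.1: the 95% CI should exclude 0 and cover the
        true offset in the vast majority of replicates."""
        rng = np.random.default_rng(9)
        exclude, cover = 0, 0
        n_meta = 100
        for i in range(n_meta):
            a = rng.normal(-0.40, 0.15, size=2000)
            b = rng.normal(-0.30, 0.15, size=2000)
            res = bootstrap_delta_r_diff(a, b, n_boot=500, seed=10 + i)
            lo, hi = res["ci"]
            if not (lo <= 0.0 <= hi):
                exclude += 1
            if lo <= -0.1 <= hi:
                cover += 1
        assert exclude == n_meta  # SE of the diff ~ 0.005, offset is 20 SE
        assert cover >= 0.9 * n_meta

    def test_deterministic_given_seed(self):
        a = np.linspace(-0.5, -0.1, 50)
        b = np.linspace(-0.4, 0.0, 50)
        r1 = bootstrap_delta_r_diff(a, b, n_boot=200, seed=3)
        r2 = bootstrap_delta_r_diff(a, b, n_boot=200, seed=3)
        assert r1 == r2
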