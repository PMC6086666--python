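import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from optobias import (
    SeparationError,
    SimConfig,
    choice_shift,
    fit_choice_full,
    fit_choice_simple,
    fit_confidence,
    fit_ts_sensitivity,
    sample_task_variables,
    simulate_behavior,
)
from optobias.psychometrics import ChoiceFit

from oracles import grid_ml_logit


def _toy_trials(seed=0, n=16):
    """A small mixed toy set with both laser states and noisy choices."""
    rng = np.random.default_rng(seed)
    C = rng.choice([-25.6, -6.4, 0.0, 6.4, 25.6], size=n)
    L = rng.integers(0, 2, size=n)
    p = 1.0 / (1.0 + np.exp(-(0.1 + 0.08 * C - 0.5 * L)))
    pref = rng.random(n) < p
    return pd.DataFrame(
        {
            "session_id": "T",
            "trial_index": np.arange(1, n + 1),
            "signed_coherence": C,
            "duration_ms": 300.0,
            "laser_on": L,
            "ts_available": 0,
            "outcome": np.where(pref, "pref_choice", "null_choice"),
            "correct": np.nan,
            "rewarded": 0,
            "mu_count": 10,
            "mu_rate": 10 / 0.3,
        }
    )


class TestChoiceOracle:
    @pytest.mark.parametrize("seed", [1, 2, 5])
    def test_full_model_matches_grid_search_on_toys(self, seed):
        df = _toy_trials(seed=seed)
        fit = fit_choice_full(df)
        C = df["signed_coherence"].to_numpy(float)
        L = df["laser_on"].to_numpy(float)
        X = np.column_stack([np.ones_like(C), C, L, C * L])
        y = (df["outcome"] == "pref_choice").to_numpy(float)
        beta = grid_ml_logit(y, X)
        np.testing.assert_allclose(fit.params, beta, atol=1e-2)

    @pytest.mark.parametrize("seed", [4, 13])
    def test_simple_model_matches_grid_search_on_toys(self, seed):
        df = _toy_trials(seed=seed, n=14)
        fit = fit_choice_simple(df)
        C = df["signed_coherence"].to_numpy(float)
        X = np.column_stack([np.ones_like(C), C])
        y = (df["outcome"] == "pref_choice").to_numpy(float)
        beta = grid_ml_logit(y, X)
        np.testing.assert_allclose(fit.params, beta, atol=1e-2)


class TestChoiceFits:
    def test_parameter_recovery_null_laser_terms(self):
        cfg = SimConfig(b0=0.0, b1=0.12, s0=0.0, ts_fraction=0.0)
        t = sample_task_variables(cfg, 50_000, seed=41)
        beh = simulate_behavior(t, cfg, seed=42)
        fit = fit_choice_full(beh)
        truth = [0.0, 0.12, 0.0, 0.0]
        for est, se, tr in zip(fit.params, fit.se, truth):
            assert abs(est - tr) < 3 * se

    def test_deterministic_choices_raise_separation(self):
        df = _toy_trials(seed=6, n=20)
        df = df[df["signed_coherence"] != 0].copy()
        df["outcome"] = np.where(df["signed_coherence"] > 0, "pref_choice", "null_choice")
        with pytest.raises(SeparationError):
            fit_choice_simple(df)

    def test_symmetric_choices_give_flat_slope(self):
        rows = []
        for c in (-25.6, -6.4, 6.4, 25.6):
            for outcome in ("pref_choice", "null_choice"):
                for _ in range(10):
                    rows.append((c, outcome))
        df = _toy_trials(seed=0, n=len(rows))
        df["signed_coherence"] = [r[0] for r in rows]
        df["outcome"] = [r[1] for r in rows]
        fit = fit_choice_simple(df)
        assert abs(fit.params[1]) < 1e-6

    def test_single_laser_state_rejected_for_full_model(self):
        df = _toy_trials(seed=7)
        df["laser_on"] = 0
        with pytest.raises(ValueError, match="both"):
            fit_choice_full(df)

    def test_simple_model_nests_in_full_model(self):
        """Nesting: the simple model on no-laser trials must equal the full
        model's no-laser branch when fit to the same single-state data."""
        df = _toy_trials(seed=8, n=400)
        no_laser = df[df["laser_on"] == 0]
        simple = fit_choice_simple(no_laser)
        # independent check on pooled data: full log-lik >= simple log-lik (nesting)
        full = fit_choice_full(df)
        pooled_simple = fit_choice_simple(df)
        assert full.llf >= pooled_simple.llf - 1e-9
        assert simple.model == "simple" and len(simple.params) == 2

    def test_trial_order_invariance(self):
        df = _toy_trials(seed=9, n=300)
        fit1 = fit_choice_full(df)
        fit2 = fit_choice_full(df.sample(frac=1.0, random_state=3))
        np.testing.assert_allclose(fit1.params, fit2.params, atol=1e-8)

    def test_duplication_scales_se_by_sqrt2(self):
        df = _toy_trials(seed=10, n=500)
        fit1 = fit_choice_full(df)
        fit2 = fit_choice_full(pd.concat([df, df], ignore_index=True))
        np.testing.assert_allclose(fit2.params, fit1.params, atol=1e-6)
        np.testing.assert_allclose(fit2.se, fit1.se / np.sqrt(2), rtol=1e-3)


class TestChoiceShift:
    def _fit_with(self, b1, b2, cov=None):
        params = np.array([0.0, b1, b2, 0.0])
        cov = np.eye(4) * 1e-4 if cov is None else cov
        se = np.sqrt(np.diag(cov))
        return ChoiceFit("full", ["b0", "b1_coh", "b2_ind", "b3"], params, cov, se,
                         params / se, np.ones(4), 0.0, 100)

    def test_ratio_definition(self):
        shift, _ = choice_shift(self._fit_with(0.1, 0.5))
        assert shift == pytest.approx(5.0)

    def test_zero_numerator(self):
        cov = np.diag([1e-4, 1e-4, 4e-4, 1e-4])
        shift, se = choice_shift(self._fit_with(0.1, 0.0, cov))
        assert shift == 0.0
        assert se == pytest.approx(np.sqrt(4e-4) / 0.1)

    def test_tiny_slope_rejected(self):
        with pytest.raises(ZeroDivisionError):
            choice_shift(self._fit_with(1e-8, 0.5))

    def test_propagated_se_matches_replicate_spread(self):
        """Delta-method SE of b2/b1 vs the empirical SD of the shift over
        independent replicates of the same generative process."""
        cfg = SimConfig(s0=-3.0, ts_fraction=0.0)
        shifts, ses = [], []
        for rep in range(200):
            t = sample_task_variables(cfg, 3_000, seed=1000 + rep)
            beh = simulate_behavior(t, cfg, seed=5000 + rep)
            sh, se = choice_shift(fit_choice_full(beh))
            shifts.append(sh)
            ses.append(se)
        empirical_sd = np.std(shifts, ddof=1)
        assert abs(np.mean(ses) - empirical_sd) < 0.2 * empirical_sd


class TestConfidenceFit:
    def test_null_delta_recovery(self):
        cfg = SimConfig(conf_A=0.6, conf_mu=0.0, conf_sigma=15.0, s0=0.0)
        t = sample_task_variables(cfg, 50_000, seed=51)
        beh = simulate_behavior(t, cfg, seed=52)
        fit = fit_confidence(beh)
        assert abs(fit.delta) < 3 * fit.delta_se + 0.05
        assert abs(fit.A - 0.6) < 0.03
        assert abs(fit.sigma - 15.0) < 1.5

    def test_injected_delta_recovery(self):
        cfg = SimConfig(s0=-3.0)
        t = sample_task_variables(cfg, 50_000, seed=53)
        beh = simulate_behavior(t, cfg, seed=54)
        fit = fit_confidence(beh)
        assert abs(fit.delta - (-3.0)) < 3 * fit.delta_se

    def test_predicted_probability_bounded_by_amplitude(self):
        cfg = SimConfig(s0=-2.0)
        t = sample_task_variables(cfg, 20_000, seed=55)
        beh = simulate_behavior(t, cfg, seed=56)
        fit = fit_confidence(beh)
        grid = np.linspace(-60, 60, 301)
        for laser in (0, 1):
            p = fit.predict(grid, laser)
            assert np.all(p >= 0) and np.all(p <= fit.A + 1e-12)

    def test_single_coherence_level_unidentifiable(self):
        df = _toy_trials(seed=12, n=40)
        df["ts_available"] = 1
        df["signed_coherence"] = 0.0
        df["outcome"] = ["sure_bet", "pref_choice"] * 20
        with pytest.raises(ValueError, match="nidentifiable|distinct"):
            fit_confidence(df)

    def test_wls_cross_check_agrees_with_mle(self):
        cfg = SimConfig(s0=-3.0)
        t = sample_task_variables(cfg, 40_000, seed=57)
        beh = simulate_behavior(t, cfg, seed=58)
        mle = fit_confidence(beh, method="mle")
        wls = fit_confidence(beh, method="wls")
        assert abs(mle.delta - wls.delta) < 1.0


class TestTsSensitivity:
    def test_null_interaction_p_uniform(self):
        """With identical sensitivity in both sure-bet states the Wald p of
        the interaction must be uniform across replicates."""
        cfg = SimConfig(s0=0.0)
        pvals = []
        for rep in range(200):
            t = sample_task_variables(cfg, 4_000, seed=2000 + rep)
            beh = simulate_behavior(t, cfg, seed=6000 + rep)
            fit = fit_ts_sensitivity(beh)
            pvals.append(fit.pvalues[3])
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_waived_sensitivity_gain_detected(self):
        """A 30% higher slope when the sure bet is waived must be a highly
        significant interaction at large n."""
        cfg = SimConfig(s0=0.0, ts_fraction=0.5)
        t = sample_task_variables(cfg, 50_000, seed=61)
        beh = simulate_behavior(t, cfg, seed=62)
        # regenerate the direction choices with a ts-dependent slope
        rng = np.random.default_rng(63)
        C = beh["signed_coherence"].to_numpy(float)
        slope = 0.12 * np.where(beh["ts_available"] == 1, 1.3, 1.0)
        keep_sb = beh["outcome"] == "sure_bet"
        p = 1.0 / (1.0 + np.exp(-slope * C))
        pref = rng.random(len(beh)) < p
        beh.loc[~keep_sb, "outcome"] = np.where(
            pref[~keep_sb], "pref_choice", "null_choice"
        )
        fit = fit_ts_sensitivity(beh)
        assert fit.params[3] > 0
        assert fit.pvalues[3] < 1e-3
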