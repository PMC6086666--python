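"""Psychometric models: choice logistic regressions and the Gaussian
confidence (sure-bet) function.

The choice model with laser terms is

    P_pref = 1 / (1 + exp(-Q)),   Q = b0 + b1*C + b2*I_L + b3*C*I_L

where C is signed coherence (% coh, positive toward the suppressed cluster's
preferred direction) and I_L the laser indicator.  The laser-induced bias in
coherence units is the ratio b2/b1 ("shift"); b3 captures a sensitivity
change.  The plotted-curve model drops the laser terms.  The confidence
function is a Gaussian in coherence,

    P_sb = A * exp(-(C + mu + delta*I_L)^2 / (2 sigma^2)),

whose laser term delta is the confidence shift in % coh.

All fits are binomial maximum likelihood with Hessian-based standard errors
(square roots of the diagonal of the inverse Hessian at the optimum).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import norm
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import (
    PerfectSeparationError,
    PerfectSeparationWarning,
)

from .trials import choice_trials, wager_trials

__all__ = [
    "SeparationError",
    "ChoiceFit",
    "ConfidenceFit",
    "fit_choice_full",
    "fit_choice_simple",
    "fit_ts_sensitivity",
    "choice_shift",
    "fit_confidence",
]

#: coefficients larger than this (in logits) are treated as evidence of
#: (quasi-)complete separation; on the coherence scales used here genuine
#: ML estimates are orders of magnitude smaller.
_SEPARATION_COEF = 25.0


class SeparationError(RuntimeError):
    """Complete or quasi-complete separation: the ML estimate diverges and
    the shift ratio b2/b1 is meaningless.  Names the degenerate direction."""


@dataclass
class ChoiceFit:
    """A fitted choice logistic model."""

    model: str                      # "full" (with indicator terms) or "simple"
    names: list[str]
    params: np.ndarray
    cov: np.ndarray
    se: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray
    llf: float
    n_trials: int
    indicator: str = "laser_on"     # which column supplied the indicator

    def predict(self, C: np.ndarray, laser: int = 0) -> np.ndarray:
        C = np.asarray(C, dtype=float)
        q = self.params[0] + self.params[1] * C
        if self.model == "full":
            q = q + self.params[2] * laser + self.params[3] * C * laser
        return 1.0 / (1.0 + np.exp(-q))

    @property
    def shift(self) -> float:
        return choice_shift(self)[0]

    @property
    def shift_se(self) -> float:
        return choice_shift(self)[1]

    def summary_dict(self) -> dict:
        out = {"model": self.model, "n_trials": self.n_trials, "llf": self.llf}
        for nm, p, s, pv in zip(self.names, self.params, self.se, self.pvalues):
            out[nm] = p
            out[f"{nm}_se"] = s
            out[f"{nm}_p"] = pv
        if self.model == "full":
            sh, sh_se = choice_shift(self)
            out["shift"] = sh
            out["shift_se"] = sh_se
            out["shift_p"] = self.pvalues[2]
        return out


def _fit_logit(y: np.ndarray, X: np.ndarray, names: list[str]) -> tuple:
    """Binomial ML via statsmodels Logit with explicit separation policy."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if len(np.unique(y)) < 2:
        raise SeparationError("outcome is constant; model unidentifiable")
    model = sm.Logit(y, X)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            res = model.fit(disp=0, maxiter=500, method="newton")
    except (PerfectSeparationError, PerfectSeparationWarning) as exc:
        raise SeparationError(f"perfect separation detected: {exc}") from None
    except np.linalg.LinAlgError as exc:
        raise SeparationError(f"singular information matrix: {exc}") from None
    params = np.asarray(res.params)
    if np.any(np.abs(params) > _SEPARATION_COEF) or not np.all(np.isfinite(params)):
        j = int(np.nanargmax(np.abs(params)))
        raise SeparationError(
            f"quasi-complete separation along {names[j]!r} "
            f"(coefficient {params[j]:.3g})"
        )
    cov = np.asarray(res.cov_params())
    se = np.sqrt(np.diag(cov))
    t = params / se
    p = 2.0 * norm.sf(np.abs(t))
    return params, cov, se, t, p, float(res.llf)


def _indicator_design(df: pd.DataFrame, indicator: str) -> tuple[np.ndarray, np.ndarray, list[str]]:
    C = df["signed_coherence"].to_numpy(float)
    I = df[indicator].to_numpy(float)
    X = np.column_stack([np.ones_like(C), C, I, C * I])
    y = (df["outcome"] == "pref_choice").to_numpy(float)
    return y, X, ["b0", "b1_coh", "b2_ind", "b3_coh_x_ind"]


def fit_choice_full(trials: pd.DataFrame, indicator: str = "laser_on") -> ChoiceFit:
    """Fit the four-term choice model on direction-choice trials.

    ``trials`` may include sure-bet outcomes; they are excluded here.  Both
    indicator states must be present.
    """
    df = choice_trials(trials)
    if df[indicator].nunique() < 2:
        raise ValueError(
            f"full model requires both {indicator} states; got a single state"
        )
    y, X, names = _indicator_design(df, indicator)
    params, cov, se, t, p, llf = _fit_logit(y, X, names)
    return ChoiceFit("full", names, params, cov, se, t, p, llf, len(df), indicator)


def fit_choice_simple(trials: pd.DataFrame) -> ChoiceFit:
    """Two-term choice model for a single trial group (plotted curves)."""
    df = choice_trials(trials)
    C = df["signed_coherence"].to_numpy(float)
    X = np.column_stack([np.ones_like(C), C])
    y = (df["outcome"] == "pref_choice").to_numpy(float)
    names = ["b0", "b1_coh"]
    params, cov, se, t, p, llf = _fit_logit(y, X, names)
    return ChoiceFit("simple", names, params, cov, se, t, p, llf, len(df))


def fit_ts_sensitivity(trials: pd.DataFrame) -> ChoiceFit:
    """Choice model with the sure-bet availability indicator, no-laser trials.

    Tests whether discrimination sensitivity is higher when the sure bet was
    available but waived (the slope-interaction coefficient b3).
    """
    df = trials.loc[trials["laser_on"].astype(int) == 0]
    return fit_choice_full(df, indicator="ts_available")


def choice_shift(fit: ChoiceFit) -> tuple[float, float]:
    """Horizontal bias b2/b1 in % coherence with its delta-method SE."""
    if fit.model != "full":
        raise ValueError("shift is defined for the full (indicator) model only")
    b1, b2 = fit.params[1], fit.params[2]
    if abs(b1) < 1e-6:
        raise ZeroDivisionError("slope |b1| < 1e-6: shift undefined")
    shift = b2 / b1
    # first-order propagation of the ratio
    g = np.zeros(len(fit.params))
    g[1] = -b2 / b1**2
    g[2] = 1.0 / b1
    var = float(g @ fit.cov @ g)
    return float(shift), float(np.sqrt(max(var, 0.0)))


# --------------------------------------------------------------------------
# confidence (sure-bet) fit


@dataclass
class ConfidenceFit:
    """Fitted Gaussian confidence function (A, mu, sigma, delta)."""

    params: np.ndarray              # A, mu, sigma, delta
    cov: np.ndarray
    se: np.ndarray
    llf: float
    n_trials: int
    converged: bool
    at_boundary: bool
    method: str = "mle"
    names: list[str] = field(default_factory=lambda: ["A", "mu", "sigma", "delta"])

    @property
    def A(self) -> float:
        return float(self.params[0])

    @property
    def mu(self) -> float:
        return float(self.params[1])

    @property
    def sigma(self) -> float:
        return float(self.params[2])

    @property
    def delta(self) -> float:
        return float(self.params[3])

    @property
    def delta_se(self) -> float:
        return float(self.se[3])

    @property
    def delta_p(self) -> float:
        if not np.isfinite(self.se[3]) or self.se[3] == 0:
            return float("nan")
        return float(2.0 * norm.sf(abs(self.params[3] / self.se[3])))

    def predict(self, C: np.ndarray, laser: int = 0) -> np.ndarray:
        A, mu, sigma, delta = self.params
        C = np.asarray(C, dtype=float)
        return A * np.exp(-((C + mu + delta * laser) ** 2) / (2.0 * sigma**2))

    def summary_dict(self) -> dict:
        out = {
            "n_trials": self.n_trials,
            "llf": self.llf,
            "converged": self.converged,
            "at_boundary": self.at_boundary,
        }
        for nm, p, s in zip(self.names, self.params, self.se):
            out[nm] = float(p)
            out[f"{nm}_se"] = float(s)
        out["delta_p"] = self.delta_p
        return out


def _conf_nll(theta: np.ndarray, C: np.ndarray, I: np.ndarray, y: np.ndarray) -> float:
    A, mu, sigma, delta = theta
    p = A * np.exp(-((C + mu + delta * I) ** 2) / (2.0 * sigma**2))
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    return -float(np.sum(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def _conf_nll_grad(theta: np.ndarray, C: np.ndarray, I: np.ndarray, y: np.ndarray):
    """Negative log-likelihood and its analytic gradient."""
    A, mu, sigma, delta = theta
    z = C + mu + delta * I
    E = np.exp(-(z**2) / (2.0 * sigma**2))
    p = np.clip(A * E, 1e-12, 1.0 - 1e-12)
    nll = -float(np.sum(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))
    w = y / p - (1.0 - y) / (1.0 - p)       # d logLik / dp
    dA = E
    core = A * E * (-z / sigma**2)
    dmu = core
    ddelta = core * I
    dsigma = A * E * (z**2) / sigma**3
    grad = -np.array(
        [np.sum(w * dA), np.sum(w * dmu), np.sum(w * dsigma), np.sum(w * ddelta)]
    )
    return nll, grad


def _numeric_hessian(f, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    n = len(x)
    h = rel_step * (1.0 + np.abs(x))
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n)
            ej = np.zeros(n)
            ei[i] = h[i]
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


def fit_confidence(
    trials: pd.DataFrame,
    include_laser_term: bool = True,
    method: str = "mle",
) -> ConfidenceFit:
    """Fit the Gaussian confidence function on sure-bet-available trials.

    Binomial ML by default (``method='mle'``); ``method='wls'`` minimizes
    count-weighted squared error on per-(C, laser) proportions as a
    cross-check.  Multi-start from a deterministic list of initial points;
    SEs from the numeric Hessian at the optimum.  With
    ``include_laser_term=False`` delta is pinned at 0 (single-group curve).
    """
    df = wager_trials(trials)
    C = df["signed_coherence"].to_numpy(float)
    I = df["laser_on"].to_numpy(float) if include_laser_term else np.zeros(len(df))
    y = (df["outcome"] == "sure_bet").to_numpy(float)
    if len(np.unique(C)) < 2:
        raise ValueError("fewer than 2 distinct coherence levels: unidentifiable")
    if len(df) == 0:
        raise ValueError("no sure-bet-available trials")

    # deterministic initial values from binned proportions
    grp = pd.DataFrame({"C": C, "y": y}).groupby("C")["y"].mean()
    A0 = float(np.clip(grp.max(), 0.05, 1.0))
    mu0 = float(-grp.idxmax())
    bounds = [(1e-3, 1.0), (-60.0, 60.0), (1.0, 150.0), (-30.0, 30.0)]
    starts = []
    for sig in (8.0, 16.0, 30.0):
        for m in (mu0, 0.0):
            starts.append(np.array([A0, m, sig, 0.0]))

    use_jac = False
    if method == "mle":
        objective = lambda th: _conf_nll_grad(th, C, I, y)
        use_jac = True
    elif method == "wls":
        pg = (
            pd.DataFrame({"C": C, "I": I, "y": y})
            .groupby(["C", "I"])["y"]
            .agg(["mean", "count"])
            .reset_index()
        )
        Cg, Ig = pg["C"].to_numpy(), pg["I"].to_numpy()
        pobs, ng = pg["mean"].to_numpy(), pg["count"].to_numpy(float)

        def objective(th):
            A, mu, sigma, delta = th
            pm = A * np.exp(-((Cg + mu + delta * Ig) ** 2) / (2.0 * sigma**2))
            return float(np.sum(ng * (pobs - pm) ** 2))
    else:
        raise ValueError(f"unknown method {method!r}")

    if not include_laser_term:
        bounds[3] = (0.0, 0.0)

    best = None
    for x0 in starts:
        res = minimize(
            objective, x0, method="L-BFGS-B", bounds=bounds, jac=use_jac,
            options={"ftol": 1e-10, "gtol": 1e-9, "maxiter": 500},
        )
        if best is None or res.fun < best.fun - 1e-12:
            best = res

    theta = np.asarray(best.x)
    at_boundary = bool(
        np.isclose(theta[0], 1.0, atol=1e-6) or np.isclose(theta[0], 1e-3, atol=1e-9)
    )
    nll = lambda th: _conf_nll(th, C, I, y)
    free = [i for i in range(4) if bounds[i][0] != bounds[i][1]]
    H = _numeric_hessian(nll, theta)
    se = np.full(4, np.nan)
    cov = np.full((4, 4), np.nan)
    try:
        Hf = H[np.ix_(free, free)]
        covf = np.linalg.inv(Hf)
        diag = np.diag(covf)
        if np.all(diag > 0):
            for a, i in enumerate(free):
                se[i] = np.sqrt(diag[a])
                for b, j in enumerate(free):
                    cov[i, j] = covf[a, b]
    except np.linalg.LinAlgError:
        pass
    return ConfidenceFit(
        params=theta,
        cov=cov,
        se=se,
        llf=-nll(theta),
        n_trials=len(df),
        converged=bool(best.success),
        at_boundary=at_boundary,
        method=method,
    )
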