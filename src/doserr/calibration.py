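"""Non-averaging dose-error correction estimators.

* **unadjusted** — fit on a single realization of the surrogate
  (observed) dose vector; the only estimator that feels classical error.
* **regression calibration (RC)** — fit on the across-realization mean
  of the true-dose group means (the conditional expectation of true
  dose given the observed grouping).
* **extended regression calibration (ERC)** — RC point estimate with the
  interval widened for shared dose uncertainty: the per-realization
  refit spread is combined with the profile-likelihood variance by a law
  of total variance and the profile interval inflated symmetrically
  about the estimate.  At zero Berkson error every realization is
  identical and ERC reduces exactly to RC.
* **Monte Carlo maximum likelihood (MCML)** — maximize the Monte Carlo
  likelihood ``(1/m) sum_k L_k(theta)``, the average over dose-vector
  realizations of the grouped Poisson likelihood; intervals are profile
  intervals of the same averaged likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, minimize
from scipy.special import logsumexp
from scipy.stats import chi2

from . import _batch
from .cohort_sim import GroupedCohort, MetaEnsemble
from .rr_poisson import FitResult, ProfileInterval, fit_with_ci

__all__ = [
    "DoseVectorSet",
    "fit_unadjusted",
    "fit_regression_calibration",
    "fit_erc",
    "fit_mcml",
    "mcml_log_likelihood",
]


@dataclass(frozen=True)
class DoseVectorSet:
    """The ``m`` per-group dose vectors of one ensemble plus their mean."""

    vectors: np.ndarray  # (m, n_groups)

    def __post_init__(self) -> None:
        v = np.atleast_2d(np.asarray(self.vectors, dtype=float))
        if np.any(v <= 0) or not np.all(np.isfinite(v)):
            raise ValueError("dose vectors must be finite and > 0")
        object.__setattr__(self, "vectors", v)

    @classmethod
    def from_matrix(cls, matrix) -> "DoseVectorSet":
        return cls(np.atleast_2d(np.asarray(matrix, dtype=float)))

    @property
    def m(self) -> int:
        return self.vectors.shape[0]

    @property
    def mean_vector(self) -> np.ndarray:
        return self.vectors.mean(axis=0)


def fit_unadjusted(cohort: GroupedCohort, ensemble: MetaEnsemble,
                   form: str = "linear-quadratic") -> FitResult:
    """Fit on the designated surrogate dose vector (no error correction)."""
    return fit_with_ci(cohort, ensemble.unadjusted_dose_vector, form, method="unadjusted")


def fit_regression_calibration(cohort: GroupedCohort, doses: DoseVectorSet,
                               form: str = "linear-quadratic") -> FitResult:
    """Fit on the mean dose vector (conditional expectation of true dose)."""
    return fit_with_ci(cohort, doses.mean_vector, form, method="regression_calibration")


def _inflate(ci: ProfileInterval, center: float, sd_between: float) -> ProfileInterval:
    """Widen a profile interval for between-realization coefficient spread."""
    if not (np.isfinite(ci.lo) and np.isfinite(ci.hi)) or ci.hi <= ci.lo:
        return ci
    sd_within = (ci.hi - ci.lo) / (2.0 * 1.959963984540054)
    if sd_within <= 0:
        return ci
    factor = float(np.sqrt(1.0 + (sd_between / sd_within) ** 2))
    return ProfileInterval(
        lo=center - factor * (center - ci.lo),
        hi=center + factor * (ci.hi - center),
        lo_flag=ci.lo_flag,
        hi_flag=ci.hi_flag,
    )


def fit_erc(cohort: GroupedCohort, doses: DoseVectorSet,
            form: str = "linear-quadratic") -> FitResult:
    """Extended regression calibration: RC point estimate, interval
    inflated by the spread of per-dose-realization refits."""
    rc = fit_regression_calibration(cohort, doses, form)
    rc.method = "erc"
    if doses.m == 1:
        rc.diagnostics["erc_inflation"] = "skipped (single dose realization)"
        return rc
    per = _batch.fit_batch(cohort.cases_array(), cohort.offsets_array(),
                           doses.vectors, form)
    ok = per["converged"]
    rc.diagnostics["erc_refits_used"] = int(ok.sum())
    rc.diagnostics["erc_refits_failed"] = int((~ok).sum())
    if ok.sum() < 2:
        rc.diagnostics["erc_inflation"] = "skipped (too few converged refits)"
        return rc
    sd_between_alpha = float(np.std(per["alpha"][ok], ddof=1))
    if rc.ci_alpha is not None:
        rc.ci_alpha = _inflate(rc.ci_alpha, rc.alpha_hat, sd_between_alpha)
    if form == "linear-quadratic" and rc.ci_beta is not None:
        sd_between_beta = float(np.std(per["beta"][ok], ddof=1))
        rc.ci_beta = _inflate(rc.ci_beta, rc.beta_hat, sd_between_beta)
    return rc


# ---------------------------------------------------------------------------
# MCML


def mcml_log_likelihood(alpha: float, beta: float, kappa: float,
                        cohort: GroupedCohort, doses: DoseVectorSet) -> float:
    """Monte Carlo averaged log-likelihood
    ``log[(1/m) sum_k L_k(alpha, beta, kappa)]`` (log-sum-exp stabilized)."""
    ll = _batch.loglik_at(alpha, beta, kappa, cohort.cases_array(),
                          cohort.offsets_array(), doses.vectors)
    if np.all(np.isneginf(ll)):
        return float("-inf")
    return float(logsumexp(ll) - np.log(doses.m))


def _mcml_neg(theta, y, T, D, form):
    if form == "linear":
        kappa, alpha = theta
        beta = 0.0
    else:
        kappa, alpha, beta = theta
    ll = _batch.loglik_at(alpha, beta, kappa, y, T, D)
    if np.all(np.isneginf(ll)):
        return 1e12
    return -(logsumexp(ll) - np.log(D.shape[0]))


def _mcml_maximize(y, T, D, form, x0):
    res = minimize(_mcml_neg, x0, args=(y, T, D, form), method="Nelder-Mead",
                   options={"maxiter": 4000, "xatol": 1e-10, "fatol": 1e-12})
    return res.x, -res.fun, res


def _mcml_profile(y, T, D, form, which, theta_val, x0):
    """Maximize the MC-averaged log-likelihood with one coefficient fixed."""
    if form == "linear":
        def neg(x):
            return _mcml_neg([x[0], theta_val], y, T, D, form)
        start = [x0[0]]
    elif which == "alpha":
        def neg(x):
            return _mcml_neg([x[0], theta_val, x[1]], y, T, D, form)
        start = [x0[0], x0[2]]
    else:
        def neg(x):
            return _mcml_neg([x[0], x[1], theta_val], y, T, D, form)
        start = [x0[0], x0[1]]
    res = minimize(neg, start, method="Nelder-Mead",
                   options={"maxiter": 2000, "xatol": 1e-9, "fatol": 1e-11})
    return -res.fun, res.x


def fit_mcml(cohort: GroupedCohort, doses: DoseVectorSet,
             form: str = "linear-quadratic", level: float = 0.95) -> FitResult:
    y = cohort.cases_array()
    T = cohort.offsets_array()
    D = doses.vectors
    # start from the regression-calibration fit (always feasible)
    rc = _batch.fit_batch(y, T, D.mean(axis=0, keepdims=True), form)
    if form == "linear":
        x0 = np.array([rc["kappa"][0], rc["alpha"][0]])
    else:
        x0 = np.array([rc["kappa"][0], rc["alpha"][0], rc["beta"][0]])
    xhat, llhat, res = _mcml_maximize(y, T, D, form, x0)
    converged = bool(res.success)
    thresh = float(chi2.ppf(level, 1))

    def ci_for(which: str, theta_hat: float) -> ProfileInterval:
        warm = {"x": xhat}

        def dev(t):
            f, nuis = _mcml_profile(y, T, D, form, which, t, xhat)
            return 2.0 * (llhat - f) - thresh

        endpoints = {}
        flags = {}
        for side, name in ((1.0, "hi"), (-1.0, "lo")):
            h = 0.25 * max(abs(theta_hat), 0.5)
            t_in, t_out = theta_hat, None
            for _ in range(60):
                t_try = t_in + side * h
                if dev(t_try) >= 0:
                    t_out = t_try
                    break
                t_in = t_try
                h *= 1.8
            if t_out is None:
                endpoints[name] = side * np.inf
                flags[name] = "open"
                continue
            lo_, hi_ = sorted((t_in, t_out))
            endpoints[name] = float(brentq(dev, lo_, hi_, xtol=1e-8, rtol=1e-10))
            flags[name] = None
        return ProfileInterval(lo=endpoints["lo"], hi=endpoints["hi"],
                               lo_flag=flags["lo"], hi_flag=flags["hi"])

    if form == "linear":
        kappa_hat, alpha_hat = xhat
        beta_hat = None
        n_par = 2
    else:
        kappa_hat, alpha_hat, beta_hat = xhat
        n_par = 3
    out = FitResult(
        method="mcml",
        form=form,
        alpha_hat=float(alpha_hat),
        beta_hat=None if beta_hat is None else float(beta_hat),
        kappa_hat=float(kappa_hat),
        loglik=float(llhat),
        aic=-2.0 * float(llhat) + 2.0 * n_par,
        converged=converged,
        diagnostics={} if converged else {"reason": "optimizer did not converge"},
    )
    out.ci_alpha = ci_for("alpha", out.alpha_hat)
    if form == "linear-quadratic":
        out.ci_beta = ci_for("beta", out.beta_hat)
    return out
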