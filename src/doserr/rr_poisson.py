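"""Grouped Poisson regression with a linear relative-risk link.

Rates for dose group ``g`` are ``T_g exp(kappa) (1 + alpha d_g + beta d_g^2)``
with person-year offset ``T_g``.  Point estimation is by maximum
likelihood, intervals by the profile likelihood (deviance rise of the
chi-square(1) quantile), and model comparison by AIC with the intercept
counted as a free parameter (3 parameters for the linear-quadratic
form, 2 for the linear form).

The log-likelihood convention is ``sum_g [y_g log mu_g - mu_g]`` with no
``log y_g!`` term; the choice cancels from every downstream quantity
(MLEs, profile intervals, AIC differences, AIC softmax weights).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from . import _batch
from .cohort_sim import GroupedCohort

__all__ = [
    "FitResult",
    "ProfileInterval",
    "log_likelihood",
    "fit_mle",
    "profile_ci",
    "aic",
]

_STATUS_NAMES = {
    _batch.OK: None,
    _batch.BOUNDARY: "boundary",
    _batch.OPEN: "open",
    _batch.FAILED: "failed",
}


@dataclass(frozen=True)
class ProfileInterval:
    """A profile-likelihood interval; iterates as ``(lo, hi)``.

    ``lo_flag``/``hi_flag`` are ``None`` for a regular endpoint,
    ``"boundary"`` when the positivity constraint was reached before the
    deviance threshold, ``"open"`` for an unbounded side.
    """

    lo: float
    hi: float
    lo_flag: str | None = None
    hi_flag: str | None = None

    def __iter__(self):
        return iter((self.lo, self.hi))

    def contains(self, value: float) -> bool:
        return self.lo <= value <= self.hi


@dataclass
class FitResult:
    """Point estimates, intervals and diagnostics from one model fit."""

    method: str
    form: str
    alpha_hat: float
    kappa_hat: float
    loglik: float
    aic: float
    converged: bool
    beta_hat: float | None = None
    ci_alpha: ProfileInterval | None = None
    ci_beta: ProfileInterval | None = None
    diagnostics: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.converged:
            for name, est, ci in (("alpha", self.alpha_hat, self.ci_alpha),
                                  ("beta", self.beta_hat, self.ci_beta)):
                if ci is not None and est is not None and math.isfinite(ci.lo) and math.isfinite(ci.hi):
                    if not (ci.lo <= est <= ci.hi):
                        self.diagnostics[f"ci_{name}_contains_estimate"] = False
        elif "reason" not in self.diagnostics:
            self.diagnostics["reason"] = "not converged"

    def to_dict(self) -> dict[str, Any]:
        def _ci(ci):
            if ci is None:
                return None
            return {"lo": ci.lo, "hi": ci.hi, "lo_flag": ci.lo_flag, "hi_flag": ci.hi_flag}

        return {
            "method": self.method,
            "form": self.form,
            "alpha_hat": self.alpha_hat,
            "beta_hat": self.beta_hat,
            "kappa_hat": self.kappa_hat,
            "ci_alpha": _ci(self.ci_alpha),
            "ci_beta": _ci(self.ci_beta),
            "loglik": self.loglik,
            "aic": self.aic,
            "converged": self.converged,
            "diagnostics": {k: v for k, v in self.diagnostics.items()
                            if isinstance(v, (str, int, float, bool, type(None)))},
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def log_likelihood(
    alpha: float, beta: float, kappa: float,
    cohort: GroupedCohort, dose_vector,
) -> float:
    """Grouped Poisson log-likelihood at one parameter point.

    Returns ``-inf`` (not an exception) when ``1 + alpha d + beta d^2``
    is non-positive in any group, so optimizers and samplers can reject.
    """
    ll = _batch.loglik_at(
        alpha, beta, kappa, cohort.cases_array(), cohort.offsets_array(),
        np.atleast_2d(np.asarray(dose_vector, dtype=float)),
    )
    return float(ll[0])


def fit_mle(cohort: GroupedCohort, dose_vector, form: str = "linear-quadratic",
            method: str = "mle") -> FitResult:
    """Maximum-likelihood fit of the grouped ERR model on one dose vector."""
    y = cohort.cases_array()
    T = cohort.offsets_array()
    D = np.atleast_2d(np.asarray(dose_vector, dtype=float))
    fit = _batch.fit_batch(y, T, D, form)
    conv = bool(fit["converged"][0])
    return FitResult(
        method=method,
        form=form,
        alpha_hat=float(fit["alpha"][0]),
        beta_hat=float(fit["beta"][0]) if form == "linear-quadratic" else None,
        kappa_hat=float(fit["kappa"][0]),
        loglik=float(fit["loglik"][0]),
        aic=float(fit["aic"][0]),
        converged=conv,
        diagnostics={} if conv else {"reason": "gradient norm above tolerance"},
    )


def profile_ci(
    cohort: GroupedCohort, dose_vector, form: str = "linear-quadratic",
    which: str = "alpha", level: float = 0.95,
) -> ProfileInterval:
    """Profile-likelihood interval for one coefficient on one dose vector."""
    y = cohort.cases_array()
    T = cohort.offsets_array()
    D = np.atleast_2d(np.asarray(dose_vector, dtype=float))
    ci = _batch.profile_ci_batch(y, T, D, form, which, level)
    return ProfileInterval(
        lo=float(ci["lo"][0]), hi=float(ci["hi"][0]),
        lo_flag=_STATUS_NAMES[int(ci["lo_status"][0])],
        hi_flag=_STATUS_NAMES[int(ci["hi_status"][0])],
    )


def fit_with_ci(
    cohort: GroupedCohort, dose_vector, form: str = "linear-quadratic",
    method: str = "mle", level: float = 0.95,
) -> FitResult:
    """Convenience: MLE plus profile intervals for every coefficient."""
    res = fit_mle(cohort, dose_vector, form, method=method)
    res.ci_alpha = profile_ci(cohort, dose_vector, form, "alpha", level)
    if form == "linear-quadratic":
        res.ci_beta = profile_ci(cohort, dose_vector, form, "beta", level)
    return res


def aic(fit: FitResult) -> float:
    """Akaike information criterion, ``-2 loglik + 2 (free parameters)``."""
    if not fit.converged:
        raise ValueError("AIC requested for a non-converged fit")
    n_par = 3 if fit.form == "linear-quadratic" else 2
    return -2.0 * fit.loglik + 2.0 * n_par
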