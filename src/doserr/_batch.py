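"""Vectorized grouped Poisson excess-relative-risk fitting.

Everything here works on batches: one shared grouped cohort
(``y`` cases, ``T`` person-year offsets over ``G`` dose groups) fitted
against ``m`` per-group dose vectors ``D`` of shape ``(m, G)`` at once.
The model for group ``g`` is

    mu_g = T_g * exp(kappa) * R_g,   R_g = 1 + alpha*d_g + beta*d_g^2,

with the hard constraint ``R_g > 0`` (log-likelihood is -inf outside).
The intercept ``kappa`` is concentrated out analytically:
``exp(kappa_hat) = N / sum_g T_g R_g`` with ``N = sum y``, leaving the
concentrated objective

    f(a, b) = sum_g y_g log R_g - N log(sum_g T_g R_g),

which differs from the full log-likelihood ``sum y log mu - mu`` (the
fixed constant convention used throughout; no ``log y!`` term) by
``N log N - N + sum_g y_g log T_g``.

Maximization is damped Newton with analytic gradients/Hessians,
vectorized over the batch; profile-likelihood confidence intervals are
found by geometric bracketing plus bisection on the profile deviance,
with the nuisance coefficient re-maximized by a warm-started 1-D Newton
at every trial point.
"""

from __future__ import annotations

import numpy as np

__all__ = ["BatchData", "fit_batch", "profile_ci_batch", "loglik_at", "CHI2_95_1DF"]

#: 95% quantile of chi-square with 1 df (profile-deviance threshold).
CHI2_95_1DF = 3.8414588206941285

# endpoint status codes
OK = 0
BOUNDARY = 1  # positivity constraint reached before the deviance threshold
OPEN = 2      # deviance never reached the threshold (open interval side)
FAILED = 3

_GRAD_TOL = 1e-8
_DEV_TOL = 1e-5


class BatchData:
    """Precomputed arrays for one cohort fitted against ``m`` dose vectors."""

    def __init__(self, y, T, D):
        y = np.asarray(y, dtype=float)
        T = np.asarray(T, dtype=float)
        D = np.atleast_2d(np.asarray(D, dtype=float))
        if D.shape[1] != y.shape[0] or T.shape[0] != y.shape[0]:
            raise ValueError(f"shape mismatch: y {y.shape}, T {T.shape}, D {D.shape}")
        if np.any(D <= 0):
            raise ValueError("dose vectors must be > 0")
        self.y = y
        self.T = T
        self.D = D
        self.D2 = D * D
        self.N = float(y.sum())
        self.m, self.G = D.shape
        # constant linking f to the full log-likelihood
        self.loglik_const = float(
            self.N * np.log(self.N) - self.N + np.sum(y * np.log(T))
        ) if self.N > 0 else float(-np.sum(0.0 * T))

    def subset(self, idx) -> "BatchData":
        sub = object.__new__(BatchData)
        sub.y, sub.T, sub.N, sub.G = self.y, self.T, self.N, self.G
        sub.loglik_const = self.loglik_const
        sub.D = self.D[idx]
        sub.D2 = self.D2[idx]
        sub.m = sub.D.shape[0]
        return sub


def _f_only(bd: BatchData, a, b):
    """Concentrated objective f(a, b); -inf where positivity fails."""
    a = np.atleast_1d(np.asarray(a, dtype=float))
    b = np.atleast_1d(np.asarray(b, dtype=float))
    R = 1.0 + a[:, None] * bd.D + b[:, None] * bd.D2
    feas = R.min(axis=1) > 0.0
    Rs = np.where(R > 0.0, R, 1.0)
    S = (bd.T * Rs).sum(axis=1)
    f = (bd.y * np.log(Rs)).sum(axis=1) - bd.N * np.log(S)
    f = np.where(feas, f, -np.inf)
    return f, feas


def _derivs(bd: BatchData, a, b):
    """Gradient and Hessian of f at feasible (a, b)."""
    R = 1.0 + a[:, None] * bd.D + b[:, None] * bd.D2
    S = (bd.T * R).sum(axis=1)
    Su = (bd.T * bd.D).sum(axis=1)
    Sv = (bd.T * bd.D2).sum(axis=1)
    yR = bd.y / R
    fa = (yR * bd.D).sum(axis=1) - bd.N * Su / S
    fb = (yR * bd.D2).sum(axis=1) - bd.N * Sv / S
    yR2 = bd.y / (R * R)
    faa = -(yR2 * bd.D2).sum(axis=1) + bd.N * (Su / S) ** 2
    fab = -(yR2 * bd.D * bd.D2).sum(axis=1) + bd.N * Su * Sv / (S * S)
    fbb = -(yR2 * bd.D2 * bd.D2).sum(axis=1) + bd.N * (Sv / S) ** 2
    return fa, fb, faa, fab, fbb


def _line_search(bd, a, b, da, db, f_cur, active):
    """Backtracking step; returns updated (a, b, f). No move where stuck."""
    gamma = np.where(active, 1.0, 0.0)
    a_new, b_new, f_new = a.copy(), b.copy(), f_cur.copy()
    todo = active.copy()
    for _ in range(60):
        if not todo.any():
            break
        at = a + gamma * da
        bt = b + gamma * db
        ft, _ = _f_only(bd, at, bt)
        good = todo & np.isfinite(ft) & (ft >= f_cur - 1e-12 * (1.0 + np.abs(f_cur)))
        improved = good & (ft >= f_new)
        a_new[improved] = at[improved]
        b_new[improved] = bt[improved]
        f_new[improved] = ft[improved]
        todo = todo & ~good
        gamma[todo] *= 0.5
    return a_new, b_new, f_new


def _newton_2d(bd: BatchData, a0=None, b0=None, max_iter=200):
    """Maximize f over (a, b) for every problem in the batch."""
    m = bd.m
    a = np.zeros(m) if a0 is None else np.array(a0, dtype=float)
    b = np.zeros(m) if b0 is None else np.array(b0, dtype=float)
    f, feas = _f_only(bd, a, b)
    if not feas.all():  # fall back to the always-feasible origin
        a[~feas] = 0.0
        b[~feas] = 0.0
        f, _ = _f_only(bd, a, b)
    converged = np.zeros(m, dtype=bool)
    for _ in range(max_iter):
        fa, fb, faa, fab, fbb = _derivs(bd, a, b)
        gscale = _GRAD_TOL * (1.0 + bd.N)
        converged = (np.abs(fa) < gscale) & (np.abs(fb) < gscale)
        active = ~converged
        if not active.any():
            break
        det = faa * fbb - fab * fab
        nd = (faa < 0) & (det > 0)  # negative-definite Hessian
        da = np.where(nd, -(fbb * fa - fab * fb) / np.where(det != 0, det, 1.0), 0.0)
        db = np.where(nd, -(-fab * fa + faa * fb) / np.where(det != 0, det, 1.0), 0.0)
        # gradient-ascent fallback where Newton is unusable
        scale = np.abs(faa) + np.abs(fbb) + 1e-8
        da = np.where(nd, da, fa / scale)
        db = np.where(nd, db, fb / scale)
        a_new, b_new, f_new = _line_search(bd, a, b, da, db, f, active)
        moved = active & (f_new > f)
        stalled = active & ~moved
        a, b, f = a_new, b_new, f_new
        if stalled.any() and not moved.any():
            break
    fa, fb, faa, fab, fbb = _derivs(bd, a, b)
    gscale = _GRAD_TOL * (1.0 + bd.N)
    converged = (np.abs(fa) < gscale) & (np.abs(fb) < gscale)
    det = faa * fbb - fab * fab
    with np.errstate(divide="ignore", invalid="ignore"):
        var_a = np.where(det != 0, -fbb / det, np.nan)
        var_b = np.where(det != 0, -faa / det, np.nan)
    return a, b, f, converged, var_a, var_b


def _newton_1d(bd: BatchData, a0=None, max_iter=200):
    """Maximize f over a with b = 0 (linear form)."""
    m = bd.m
    a = np.zeros(m) if a0 is None else np.array(a0, dtype=float)
    zeros = np.zeros(m)
    f, feas = _f_only(bd, a, zeros)
    a[~feas] = 0.0
    if not feas.all():
        f, _ = _f_only(bd, a, zeros)
    for _ in range(max_iter):
        fa, _, faa, _, _ = _derivs(bd, a, zeros)
        gscale = _GRAD_TOL * (1.0 + bd.N)
        active = np.abs(fa) >= gscale
        if not active.any():
            break
        da = np.where(faa < 0, -fa / faa, np.sign(fa) * (np.abs(fa) / (np.abs(faa) + 1e-8)))
        a, _, f = _line_search(bd, a, zeros, da, zeros, f, active)
    fa, _, faa, _, _ = _derivs(bd, a, zeros)
    converged = np.abs(fa) < _GRAD_TOL * (1.0 + bd.N)
    with np.errstate(divide="ignore", invalid="ignore"):
        var_a = np.where(faa != 0, -1.0 / faa, np.nan)
    return a, f, converged, var_a


def _max_over_nuisance(bd: BatchData, theta, nuis0, which: str, max_iter=80):
    """Profile step: maximize f over the other coefficient at fixed theta.

    ``which`` names the *fixed* coefficient ("alpha" fixes a, maximizes
    over b; "beta" the reverse).  Returns (nuisance_hat, f_profile).
    """
    theta = np.asarray(theta, dtype=float)
    nu = np.array(nuis0, dtype=float)

    def fab(nu_arr):
        if which == "alpha":
            return theta, nu_arr
        return nu_arr, theta

    # ensure a feasible start: R = 1 + a d + b d^2 > 0 is monotone
    # increasing in the nuisance times positive powers of d, so pushing
    # the nuisance up always restores feasibility
    a_, b_ = fab(nu)
    f, feas = _f_only(bd, a_, b_)
    if not feas.all():
        bad = ~feas
        if which == "alpha":  # nuisance is b: need b > max_g -(1 + a d)/d^2
            lb = np.max(-(1.0 + theta[bad, None] * bd.D[bad]) / bd.D2[bad], axis=1)
        else:  # nuisance is a: need a > max_g -(1 + b d^2)/d
            lb = np.max(-(1.0 + theta[bad, None] * bd.D2[bad]) / bd.D[bad], axis=1)
        nu[bad] = lb + 0.5 * (1.0 + np.abs(lb))
        a_, b_ = fab(nu)
        f, _ = _f_only(bd, a_, b_)
    for _ in range(max_iter):
        a_, b_ = fab(nu)
        fa, fb, faa, fab_, fbb = _derivs(bd, a_, b_)
        g = fb if which == "alpha" else fa
        h = fbb if which == "alpha" else faa
        active = np.abs(g) >= _GRAD_TOL * (1.0 + bd.N)
        if not active.any():
            break
        dn = np.where(h < 0, -g / h, np.sign(g) * (np.abs(g) / (np.abs(h) + 1e-8)))
        if which == "alpha":
            _, nu, f = _line_search(bd, a_, nu, np.zeros_like(dn), dn, f, active)
        else:
            nu, _, f = _line_search(bd, nu, b_, dn, np.zeros_like(dn), f, active)
    return nu, f


def fit_batch(y, T, D, form: str = "linear-quadratic") -> dict:
    """Maximum-likelihood fit of the grouped ERR Poisson model for every
    dose vector in ``D``; returns arrays keyed by parameter name."""
    bd = BatchData(y, T, D)
    if form == "linear":
        a, f, converged, var_a = _newton_1d(bd)
        b = np.zeros_like(a)
        var_b = np.full_like(a, np.nan)
        n_par = 2  # alpha, kappa
    elif form == "linear-quadratic":
        a, b, f, converged, var_a, var_b = _newton_2d(bd)
        n_par = 3
    else:
        raise ValueError(f"unknown form {form!r}")
    R = 1.0 + a[:, None] * bd.D + b[:, None] * bd.D2
    S = (bd.T * R).sum(axis=1)
    kappa = np.log(bd.N) - np.log(S)
    loglik = f + bd.loglik_const
    return {
        "alpha": a,
        "beta": b,
        "kappa": kappa,
        "f": f,
        "loglik": loglik,
        "aic": -2.0 * loglik + 2.0 * n_par,
        "converged": converged,
        "var_alpha": var_a,
        "var_beta": var_b,
        "n_par": n_par,
    }


def _profile_f(bd: BatchData, theta, nuis, which: str, form: str):
    """Profile objective at fixed coefficient values (batch)."""
    if form == "linear":
        if which != "alpha":
            raise ValueError("linear form has no beta")
        f, _ = _f_only(bd, theta, np.zeros_like(theta))
        return np.zeros_like(theta), f
    return _max_over_nuisance(bd, theta, nuis, which)


def _lower_bound_linear(bd: BatchData):
    # positivity 1 + a d > 0 for all groups
    return -1.0 / bd.D.max(axis=1)


def profile_ci_batch(
    y, T, D, form: str = "linear-quadratic", which: str = "alpha",
    level: float = 0.95, fit: dict | None = None,
) -> dict:
    """Profile-likelihood confidence intervals, vectorized over dose vectors.

    Each endpoint is where the profile deviance ``2*(f_hat - f_prof)``
    crosses the chi-square(1) quantile for ``level``, located by
    geometric bracketing from the MLE followed by bisection.  Sides on
    which the deviance never reaches the threshold are reported open
    (``+/-inf``, status OPEN); for the linear form a side may stop at
    the positivity boundary (status BOUNDARY).
    """
    from scipy.stats import chi2

    bd = BatchData(y, T, D)
    if fit is None:
        fit = fit_batch(y, T, D, form)
    thresh = float(chi2.ppf(level, 1))
    theta_hat = fit["alpha"] if which == "alpha" else fit["beta"]
    nuis_hat = fit["beta"] if which == "alpha" else fit["alpha"]
    var = fit["var_alpha"] if which == "alpha" else fit["var_beta"]
    f_hat = fit["f"]
    m = bd.m
    sd = np.sqrt(np.where(np.isfinite(var) & (var > 0), var, np.nan))
    sd = np.where(np.isfinite(sd), sd, np.maximum(np.abs(theta_hat), 1.0) * 0.5)

    lower_cap = None
    if form == "linear":
        lower_cap = _lower_bound_linear(bd)

    out = {}
    for side, name in ((1.0, "hi"), (-1.0, "lo")):
        status = np.full(m, OK, dtype=int)
        # bracketing: inner point (dev < thresh) and outer point (dev >= thresh)
        t_in = theta_hat.copy()
        t_out = np.full(m, np.nan)
        h = sd.copy()
        nuis = nuis_hat.copy()
        unresolved = np.ones(m, dtype=bool)
        at_cap = np.zeros(m, dtype=bool)
        for _ in range(120):
            if not unresolved.any():
                break
            idx = np.where(unresolved)[0]
            t_try = t_in[idx] + side * h[idx]
            capped = np.zeros(idx.shape, dtype=bool)
            if lower_cap is not None and side < 0:
                cap = lower_cap[idx] * (1.0 - 1e-12) + 1e-300
                capped = t_try <= cap
                t_try = np.maximum(t_try, cap)
            sub = bd.subset(idx)
            nu_new, f_prof = _profile_f(sub, t_try, nuis[idx], which, form)
            nuis[idx] = nu_new
            dev = 2.0 * (f_hat[idx] - f_prof)
            crossed = dev >= thresh
            # outer point found
            gi = idx[crossed]
            t_out[gi] = t_try[crossed]
            unresolved[gi] = False
            # still inside: advance
            still = ~crossed
            si = idx[still]
            t_in[si] = t_try[still]
            h[si] *= 1.8
            # capped without crossing -> boundary endpoint
            cb = still & capped
            if cb.any():
                ci_ = idx[cb]
                status[ci_] = BOUNDARY
                t_out[ci_] = t_in[ci_]
                unresolved[ci_] = False
        open_side = unresolved
        if open_side.any():
            status[open_side] = OPEN
            t_out[open_side] = side * np.inf
        # bisection on problems with a true bracket
        refine = status == OK
        for _ in range(100):
            idx = np.where(refine)[0]
            if idx.size == 0:
                break
            mid = 0.5 * (t_in[idx] + t_out[idx])
            sub = bd.subset(idx)
            nu_new, f_prof = _profile_f(sub, mid, nuis[idx], which, form)
            nuis[idx] = nu_new
            dev = 2.0 * (f_hat[idx] - f_prof)
            inside = dev < thresh
            t_in[idx[inside]] = mid[inside]
            t_out[idx[~inside]] = mid[~inside]
            done = (np.abs(dev - thresh) < _DEV_TOL) | (
                np.abs(t_out[idx] - t_in[idx]) < 1e-12 * (1.0 + np.abs(mid))
            )
            refine[idx[done]] = False
        endpoint = np.where(status == OK, 0.5 * (t_in + t_out), t_out)
        out[name] = endpoint
        out[name + "_status"] = status
    return {
        "lo": out["lo"], "hi": out["hi"],
        "lo_status": out["lo_status"], "hi_status": out["hi_status"],
        "level": level, "threshold": thresh,
    }


def loglik_at(alpha, beta, kappa, y, T, D) -> np.ndarray:
    """Full log-likelihood ``sum y log mu - mu`` (no log y! term) of one
    parameter point against each dose vector in ``D``; -inf where the
    relative risk is non-positive in any group."""
    y = np.asarray(y, dtype=float)
    T = np.asarray(T, dtype=float)
    D = np.atleast_2d(np.asarray(D, dtype=float))
    R = 1.0 + alpha * D + beta * D * D
    feas = R.min(axis=1) > 0.0
    Rs = np.where(R > 0.0, R, 1.0)
    ek = np.exp(kappa)
    ll = (y * (kappa + np.log(T) + np.log(Rs))).sum(axis=1) - ek * (T * Rs).sum(axis=1)
    return np.where(feas, ll, -np.inf)
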