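"""Model-averaging estimators over an ensemble of dose-vector realizations.

**Quasi-2DMC with Bayesian model averaging.**  The ``m`` group-mean
dose-vector realizations are treated as competing models with mixture
weights ``p_j`` parameterized through a softmax of latent variables
``lambda_j`` (``j = 1..m-1``, the last weight being the remainder).  The
posterior of the dose-response parameters is the ``p``-weighted mixture
of the per-vector grouped Poisson posteriors.  Sampling alternates
Metropolis-Hastings updates of (a) the dose-response parameters
``kappa, alpha, beta`` one at a time against the mixture likelihood and
(b) the ``lambda`` vector in consecutive blocks with a single joint
accept per block.  All parameters have vague normal priors.  Two (or
more) chains are run so the Brooks-Gelman-Rubin statistic can be
computed; burn-in draws are discarded.

**Frequentist model averaging (FMA).**  Each dose vector is fitted by
maximum likelihood; per-vector coefficient SDs are recovered from the
profile-likelihood intervals as the minimum half-width divided by 1.96;
AIC softmax weights ``exp(-AIC_j/2)/sum_k exp(-AIC_k/2)`` weight ``k``
normal draws per fit, and the weighted mean and weighted 2.5/97.5
centiles give the combined estimate and interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from . import _batch
from .calibration import DoseVectorSet
from .cohort_sim import GroupedCohort
from .error_model import _as_seedseq
from .rr_poisson import FitResult, ProfileInterval

__all__ = [
    "BmaSettings",
    "PosteriorSummary",
    "softmax_probs",
    "mixture_log_likelihood",
    "run_quasi_2dmc_bma",
    "bgr_statistic",
    "FmaPerVectorFits",
    "fma_fit_all",
    "fma_weights",
    "fma_combine",
    "fit_fma",
]


@dataclass(frozen=True)
class BmaSettings:
    """MCMC settings for the quasi-2DMC BMA sampler."""

    prior_sd: float = 1000.0
    proposal_sd_kappa: float = 0.2
    proposal_sd_alpha_beta: float = 1.0
    proposal_sd_lambda: float = 2.0
    lambda_block: int = 10
    n_chains: int = 2
    burn_in: int = 1000
    n_keep: int = 1000
    bgr_threshold: float = 1.03
    accept_range: tuple[float, float] = (0.05, 0.80)

    def __post_init__(self) -> None:
        for name in ("prior_sd", "proposal_sd_kappa", "proposal_sd_alpha_beta",
                     "proposal_sd_lambda"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.lambda_block < 1:
            raise ValueError("lambda_block must be >= 1")
        if self.n_chains < 2:
            raise ValueError("need >= 2 chains for the BGR statistic")
        if self.burn_in < 0 or self.n_keep < 1:
            raise ValueError("invalid burn_in / n_keep")


@dataclass
class PosteriorSummary:
    """Posterior means, equal-tail 95% intervals and MCMC diagnostics."""

    mean_alpha: float
    mean_kappa: float
    ci_alpha: tuple[float, float]
    mean_beta: float | None = None
    ci_beta: tuple[float, float] | None = None
    bgr: dict[str, float] = field(default_factory=dict)
    acceptance: dict[str, float] = field(default_factory=dict)
    p_weights_mean: np.ndarray | None = None
    n_draws: int = 0
    converged: bool = True
    notes: list[str] = field(default_factory=list)


def softmax_probs(lambdas) -> np.ndarray:
    """Mixture weights from latent softmax variables.

    For ``m-1`` latent values the weights are
    ``p_j = exp(lambda_j) / (1 + sum_k exp(lambda_k))`` for ``j < m`` and
    ``p_m`` the remainder, i.e. a softmax over ``(lambda, 0)``;
    log-sum-exp stabilized, sums to one exactly."""
    lam = np.atleast_1d(np.asarray(lambdas, dtype=float))
    full = np.concatenate([lam, [0.0]])
    p = np.exp(full - logsumexp(full))
    return p / p.sum()


def mixture_log_likelihood(alpha: float, beta: float, kappa: float, p,
                           cohort: GroupedCohort, doses: DoseVectorSet) -> float:
    """``log sum_k p_k L_k(alpha, beta, kappa)`` over the dose vectors."""
    p = np.asarray(p, dtype=float)
    if p.shape[0] != doses.m:
        raise ValueError("weight vector length does not match dose vectors")
    if abs(p.sum() - 1.0) > 1e-8:
        raise ValueError("weights must sum to 1")
    ll = _batch.loglik_at(alpha, beta, kappa, cohort.cases_array(),
                          cohort.offsets_array(), doses.vectors)
    with np.errstate(divide="ignore"):
        logp = np.log(p)
    terms = logp + ll
    if np.all(np.isneginf(terms)):
        return float("-inf")
    return float(logsumexp(terms))


def bgr_statistic(chains) -> float:
    """Brooks-Gelman-Rubin potential scale reduction factor.

    ``sqrt([(n-1)/n * W + B/n] / W)`` with ``W`` the mean within-chain
    variance and ``B/n`` the variance of the chain means, for chains of
    length ``n``.  Identical chains give ``sqrt((n-1)/n)`` (just below
    1).  Returns nan (with a warning) when the within-chain variance is
    zero."""
    x = np.atleast_2d(np.asarray(chains, dtype=float))
    c, n = x.shape
    if c < 2:
        raise ValueError("need >= 2 chains")
    if n < 2:
        raise ValueError("need >= 2 draws per chain")
    w = x.var(axis=1, ddof=1).mean()
    if w == 0:
        warnings.warn("zero within-chain variance; BGR undefined", RuntimeWarning,
                      stacklevel=2)
        return float("nan")
    b_over_n = x.mean(axis=1).var(ddof=1)
    v_hat = (n - 1) / n * w + b_over_n
    return float(np.sqrt(v_hat / w))


def _chain_start(kappa0: float, settings: BmaSettings, chain_idx: int, form: str):
    """Overdispersed starts: chain c sits 2c proposal-SDs from chain 0."""
    off = 2.0 * chain_idx
    return (
        kappa0 + off * settings.proposal_sd_kappa,
        0.0 + off * settings.proposal_sd_alpha_beta,
        (0.0 + off * settings.proposal_sd_alpha_beta) if form == "linear-quadratic" else 0.0,
    )


def _run_chain(y, T, D, form, settings: BmaSettings, rng, start):
    """One MH chain of the quasi-2DMC sampler.

    Step (a) updates the dose-response parameters one at a time against
    the pooled (symmetrically weighted) average of the per-dose-vector
    log-likelihoods, ``(1/m) sum_k log L_k(theta)``, times the normal
    priors.  Pooling log-likelihoods forces one parameter vector to
    compromise across every dose realization simultaneously; when the
    realizations differ by a large shared scale factor this attenuates
    the fitted curvature, inflates the linear coefficient and leaves a
    deceptively tight posterior -- the failure mode this estimator is
    known for.  Step (b) updates the latent weight variables ``lambda``
    in consecutive blocks (joint accept per block) against their
    conditional ``exp(sum_k p_k(lambda) log L_k) x prior``; the weight
    draws feed the posterior weight summaries but, by construction of
    the pooled step (a), not the dose-response update.
    """
    m = D.shape[0]
    n_lam = m - 1
    prior_var = settings.prior_sd**2
    D2 = D * D
    N = float(y.sum())
    ylogT = float(np.sum(y * np.log(T)))

    def ll_vec(alpha, beta, kappa):
        """Per-dose-vector log-likelihood; None if any vector infeasible."""
        R = 1.0 + alpha * D + beta * D2
        if R.min() <= 0.0:
            return None
        return (np.log(R) @ y) + (N * kappa + ylogT) - np.exp(kappa) * (R @ T)

    kappa, alpha, beta = start
    ll = ll_vec(alpha, beta, kappa)
    if ll is None:
        raise RuntimeError("infeasible chain start")
    lam = np.zeros(n_lam)
    lam_full = np.concatenate([lam, [0.0]])

    blocks = [(s, min(s + settings.lambda_block, n_lam))
              for s in range(0, n_lam, settings.lambda_block)]
    n_blocks = len(blocks)
    block_starts = np.array([s for s, _ in blocks], dtype=int)
    block_sizes = np.array([e - s for s, e in blocks], dtype=int)

    params = ["kappa", "alpha"] + (["beta"] if form == "linear-quadratic" else [])
    prop_sd = {"kappa": settings.proposal_sd_kappa,
               "alpha": settings.proposal_sd_alpha_beta,
               "beta": settings.proposal_sd_alpha_beta}
    acc = {p: 0 for p in params}
    acc_lambda = 0
    lam_trials = 0

    n_iter = settings.burn_in + settings.n_keep
    kept = {p: np.empty(settings.n_keep) for p in params}
    p_sum = np.zeros(m)

    theta = {"kappa": kappa, "alpha": alpha, "beta": beta}
    pooled = float(ll.mean())  # symmetric pooling drives the theta update

    def weights():
        w = np.exp(lam_full - lam_full.max())
        return w, w.sum()

    w, W0 = weights()

    for it in range(n_iter):
        # (a) dose-response parameters, single-site random walk against
        # the pooled average log-likelihood plus prior
        for pname in params:
            prop = theta.copy()
            prop[pname] = theta[pname] + prop_sd[pname] * rng.standard_normal()
            ll_prop = ll_vec(prop["alpha"], prop["beta"], prop["kappa"])
            if ll_prop is not None:
                pooled_prop = float(ll_prop.mean())
            else:  # some dose vector infeasible: every p_k > 0, so reject
                pooled_prop = -np.inf
            logr = (pooled_prop - pooled
                    + (theta[pname]**2 - prop[pname]**2) / (2.0 * prior_var))
            if np.log(rng.uniform()) < logr:
                theta = prop
                ll = ll_prop
                pooled = pooled_prop
                acc[pname] += 1

        # (b) lambda in consecutive blocks, joint accept per block, against
        # its conditional W1/W0 with W1 = sum_k w_k loglik_k, W0 = sum_k w_k.
        # Blocks are disjoint, so per-block candidate deltas are computed
        # vectorized up front; only the running sums are sequential.
        if n_lam > 0:
            w, W0 = weights()
            W1 = float(np.dot(w, ll))
            cond = W1 / W0
            shift = lam_full.max()
            new_lam = lam + settings.proposal_sd_lambda * rng.standard_normal(n_lam)
            with np.errstate(over="ignore"):
                nw = np.exp(np.minimum(new_lam - shift, 700.0))
            dw = nw - w[:n_lam]
            d1b = np.add.reduceat(dw * ll[:n_lam], block_starts).tolist()
            d0b = np.add.reduceat(dw, block_starts).tolist()
            pdb = (np.add.reduceat(lam * lam - new_lam * new_lam, block_starts)
                   / (2.0 * prior_var)).tolist()
            logu = np.log(rng.uniform(size=n_blocks)).tolist()
            accepted = np.zeros(n_blocks, dtype=bool)
            for bi in range(n_blocks):
                d0 = d0b[bi]
                if W0 + d0 <= 0.0:
                    continue
                cond_new = (W1 + d1b[bi]) / (W0 + d0)
                if logu[bi] < cond_new - cond + pdb[bi]:
                    W1 += d1b[bi]
                    W0 += d0
                    cond = cond_new
                    accepted[bi] = True
            if accepted.any():
                elem = np.repeat(accepted, block_sizes)
                lam[elem] = new_lam[elem]
                lam_full[:n_lam][elem] = new_lam[elem]
                w[:n_lam][elem] = nw[elem]
                acc_lambda += int(accepted.sum())
            lam_trials += n_blocks

        if it >= settings.burn_in:
            j = it - settings.burn_in
            for pname in params:
                kept[pname][j] = theta[pname]
            if n_lam > 0:
                p_sum += w / W0
            else:
                p_sum += 1.0

    out_acc = {p: acc[p] / n_iter for p in params}
    out_acc["lambda_blocks"] = acc_lambda / lam_trials if lam_trials else float("nan")
    return kept, p_sum / settings.n_keep, out_acc


def run_quasi_2dmc_bma(
    cohort: GroupedCohort, doses: DoseVectorSet, form: str = "linear-quadratic",
    settings: BmaSettings | None = None, seed=0,
) -> tuple[PosteriorSummary, FitResult]:
    """Run the quasi-2DMC BMA sampler and summarize the posterior.

    Returns the posterior summary (means, equal-tail 95% intervals, BGR
    per parameter, acceptance rates, posterior mean mixture weights) and
    a FitResult whose point estimates and intervals are taken from it.
    Convergence failures (BGR above threshold, acceptance outside the
    configured range) are reported through ``converged`` and the
    diagnostics, never silently."""
    settings = settings or BmaSettings()
    y = cohort.cases_array()
    T = cohort.offsets_array()
    D = doses.vectors
    kappa0 = float(np.log(max(cohort.n_total_cases, 1)) - np.log(T.sum()))
    rngs = [np.random.default_rng(s) for s in _as_seedseq(seed).spawn(settings.n_chains)]

    chains = []
    for c in range(settings.n_chains):
        start = _chain_start(kappa0, settings, c, form)
        chains.append(_run_chain(y, T, D, form, settings, rngs[c], start))

    params = ["kappa", "alpha"] + (["beta"] if form == "linear-quadratic" else [])
    draws = {p: np.stack([ch[0][p] for ch in chains]) for p in params}
    p_weights = np.mean([ch[1] for ch in chains], axis=0)
    acc = {k: float(np.mean([ch[2][k] for ch in chains])) for k in chains[0][2]}

    bgr = {}
    notes: list[str] = []
    for p in params:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            bgr[p] = bgr_statistic(draws[p])
        if not np.isfinite(bgr[p]):
            notes.append(f"BGR undefined for {p} (zero within-chain variance)")

    converged = True
    for p in params:
        if not np.isfinite(bgr[p]) or bgr[p] > settings.bgr_threshold:
            converged = False
            notes.append(f"BGR for {p} = {bgr[p]:.4f} above {settings.bgr_threshold}")
        lo, hi = settings.accept_range
        if not (lo <= acc[p] <= hi):
            converged = False
            notes.append(f"acceptance for {p} = {acc[p]:.3f} outside [{lo}, {hi}]")

    pooled = {p: draws[p].ravel() for p in params}
    q = lambda x: (float(np.quantile(x, 0.025)), float(np.quantile(x, 0.975)))
    summary = PosteriorSummary(
        mean_alpha=float(pooled["alpha"].mean()),
        mean_kappa=float(pooled["kappa"].mean()),
        ci_alpha=q(pooled["alpha"]),
        mean_beta=float(pooled["beta"].mean()) if "beta" in pooled else None,
        ci_beta=q(pooled["beta"]) if "beta" in pooled else None,
        bgr=bgr,
        acceptance=acc,
        p_weights_mean=p_weights,
        n_draws=settings.n_chains * settings.n_keep,
        converged=converged,
        notes=notes,
    )
    ll_at_mean = mixture_log_likelihood(
        summary.mean_alpha, summary.mean_beta or 0.0, summary.mean_kappa,
        p_weights, cohort, doses)
    fit = FitResult(
        method="quasi_2dmc_bma",
        form=form,
        alpha_hat=summary.mean_alpha,
        beta_hat=summary.mean_beta,
        kappa_hat=summary.mean_kappa,
        ci_alpha=ProfileInterval(*summary.ci_alpha),
        ci_beta=ProfileInterval(*summary.ci_beta) if summary.ci_beta else None,
        loglik=ll_at_mean,
        aic=float("nan"),
        converged=converged,
        diagnostics={"bgr_" + k: v for k, v in bgr.items()}
        | {"accept_" + k: v for k, v in acc.items()}
        | ({"reason": "; ".join(notes)} if not converged else {}),
    )
    return summary, fit


# ---------------------------------------------------------------------------
# Frequentist model averaging


@dataclass
class FmaPerVectorFits:
    """Per-dose-vector MLEs, AICs and CI-derived SDs for FMA."""

    form: str
    alpha: np.ndarray
    sd_alpha: np.ndarray
    aic: np.ndarray
    included: np.ndarray  # converged fits with a usable SD
    beta: np.ndarray | None = None
    sd_beta: np.ndarray | None = None
    n_unbounded: int = 0
    n_excluded: int = 0


def _ci_sd(theta, lo, hi, lo_status, hi_status):
    """Minimum CI half-width / 1.96; fall back to the finite side when one
    side is open.  Returns (sd, n_open_sides, usable)."""
    lo_w = theta - lo
    hi_w = hi - theta
    lo_open = ~np.isfinite(lo_w)
    hi_open = ~np.isfinite(hi_w)
    half = np.where(lo_open, hi_w, np.where(hi_open, lo_w, np.minimum(lo_w, hi_w)))
    usable = np.isfinite(half) & (half > 0)
    n_open = int((lo_open | hi_open).sum())
    return half / 1.959963984540054, n_open, usable


def fma_fit_all(cohort: GroupedCohort, doses: DoseVectorSet,
                form: str = "linear-quadratic") -> FmaPerVectorFits:
    """Fit every dose vector; recover per-coefficient SDs from the
    profile-likelihood intervals (minimum half-width / 1.96)."""
    y = cohort.cases_array()
    T = cohort.offsets_array()
    D = doses.vectors
    fit = _batch.fit_batch(y, T, D, form)
    ci_a = _batch.profile_ci_batch(y, T, D, form, "alpha", fit=fit)
    sd_a, open_a, usable_a = _ci_sd(fit["alpha"], ci_a["lo"], ci_a["hi"],
                                    ci_a["lo_status"], ci_a["hi_status"])
    included = fit["converged"] & usable_a
    n_open = open_a
    beta = sd_b = None
    if form == "linear-quadratic":
        ci_b = _batch.profile_ci_batch(y, T, D, form, "beta", fit=fit)
        sd_b, open_b, usable_b = _ci_sd(fit["beta"], ci_b["lo"], ci_b["hi"],
                                        ci_b["lo_status"], ci_b["hi_status"])
        included &= usable_b
        n_open += open_b
        beta = fit["beta"]
    n_excluded = int((~included).sum())
    if n_excluded:
        warnings.warn(f"FMA: excluded {n_excluded} per-vector fits "
                      "(non-converged or degenerate interval)", RuntimeWarning,
                      stacklevel=2)
    return FmaPerVectorFits(
        form=form, alpha=fit["alpha"], sd_alpha=sd_a, aic=fit["aic"],
        included=included, beta=beta, sd_beta=sd_b,
        n_unbounded=n_open, n_excluded=n_excluded,
    )


def fma_weights(aics) -> np.ndarray:
    """AIC softmax weights ``exp(-AIC_j/2) / sum_k exp(-AIC_k/2)``
    (lower AIC -> higher weight); log-sum-exp stabilized."""
    a = np.atleast_1d(np.asarray(aics, dtype=float))
    finite = np.isfinite(a)
    if not finite.any():
        raise ValueError("no finite AIC values")
    half = np.where(finite, -a / 2.0, -np.inf)
    w = np.exp(half - logsumexp(half[finite]))
    return w / w.sum()


def _weighted_quantile(x: np.ndarray, w: np.ndarray, q: float) -> float:
    """Smallest sample whose cumulative normalized weight reaches ``q``."""
    order = np.argsort(x, kind="stable")
    xs = x[order]
    cw = np.cumsum(w[order])
    cw /= cw[-1]
    idx = int(np.searchsorted(cw, q, side="left"))
    return float(xs[min(idx, xs.size - 1)])


def fma_combine(fits: FmaPerVectorFits, weights, k: int = 100, seed=0) -> FitResult:
    """Combine per-vector fits: ``k`` normal draws per fit per coefficient,
    each carrying its vector's AIC weight / k; weighted mean gives the
    central estimate, weighted 2.5/97.5 centiles the 95% interval."""
    if k < 1:
        raise ValueError("k must be >= 1")
    w = np.asarray(weights, dtype=float)
    inc = fits.included
    if not inc.any():
        raise ValueError("no usable per-vector fits")
    w = np.where(inc, w, 0.0)
    w = w / w.sum()
    rng = np.random.default_rng(_as_seedseq(seed))
    idx = np.where(inc)[0]
    w_samples = np.repeat(w[idx] / k, k)

    def combine(theta, sd):
        samples = (theta[idx, None] + sd[idx, None] * rng.standard_normal((idx.size, k))).ravel()
        center = float(np.sum(w_samples * samples))
        lo = _weighted_quantile(samples, w_samples, 0.025)
        hi = _weighted_quantile(samples, w_samples, 0.975)
        return center, ProfileInterval(lo, hi)

    alpha_hat, ci_alpha = combine(fits.alpha, fits.sd_alpha)
    beta_hat = ci_beta = None
    if fits.form == "linear-quadratic":
        beta_hat, ci_beta = combine(fits.beta, fits.sd_beta)
    return FitResult(
        method="fma",
        form=fits.form,
        alpha_hat=alpha_hat,
        beta_hat=beta_hat,
        kappa_hat=float("nan"),
        ci_alpha=ci_alpha,
        ci_beta=ci_beta,
        loglik=float("nan"),
        aic=float("nan"),
        converged=True,
        diagnostics={"fma_excluded": fits.n_excluded,
                     "fma_unbounded_ci_sides": fits.n_unbounded,
                     "fma_k": k},
    )


def fit_fma(cohort: GroupedCohort, doses: DoseVectorSet,
            form: str = "linear-quadratic", k: int = 100, seed=0) -> FitResult:
    """The full FMA pipeline: per-vector fits, AIC weights, combination."""
    fits = fma_fit_all(cohort, doses, form)
    aics = np.where(fits.included, fits.aic, np.inf)
    return fma_combine(fits, fma_weights(aics), k=k, seed=seed)
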