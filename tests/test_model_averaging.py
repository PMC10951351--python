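"""Quasi-2DMC BMA sampler components and frequentist model averaging."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from doserr import (
    LINEAR_QUADRATIC_TRUTH,
    BmaSettings,
    DoseVectorSet,
    ErrorConfig,
    bgr_statistic,
    build_ensemble,
    fit_mcml,
    fma_combine,
    fma_fit_all,
    fma_weights,
    mixture_log_likelihood,
    run_quasi_2dmc_bma,
    softmax_probs,
)
from doserr.calibration import mcml_log_likelihood
from doserr.model_averaging import _weighted_quantile
from doserr.rr_poisson import fit_with_ci, log_likelihood


# ---------------------------------------------------------------- softmax


def test_softmax_probs_symmetry_and_arithmetic():
    np.testing.assert_allclose(softmax_probs(np.zeros(999)),
                               np.full(1000, 1e-3), rtol=1e-12)
    np.testing.assert_array_equal(softmax_probs(np.array([])), [1.0])
    np.testing.assert_allclose(softmax_probs([np.log(2.0)]),
                               [2 / 3, 1 / 3], rtol=1e-12)


@settings(max_examples=50, deadline=None)
@given(st.lists(st.floats(-200, 200), min_size=1, max_size=40),
       st.floats(-100, 100))
def test_softmax_and_fma_weights_normalize_and_shift(lams, shift):
    p = softmax_probs(np.array(lams))
    assert abs(p.sum() - 1.0) < 1e-12
    w = fma_weights(np.array(lams))
    assert abs(w.sum() - 1.0) < 1e-12
    np.testing.assert_allclose(fma_weights(np.array(lams) + shift), w,
                               rtol=1e-9, atol=1e-12)


def test_fma_weights_arithmetic():
    np.testing.assert_allclose(fma_weights([0.0, 2.0]),
                               [np.e / (1 + np.e), 1 / (1 + np.e)], rtol=1e-12)
    with pytest.raises(ValueError):
        fma_weights([np.inf, np.nan])


# ------------------------------------------------------- mixture likelihood


@pytest.fixture(scope="module")
def mixture_inputs(groups, berkson_heavy):
    ens = build_ensemble(groups, berkson_heavy, LINEAR_QUADRATIC_TRUTH,
                         m=25, n_cases=250, seed=17, keep_individual=False)
    return ens.cohort, DoseVectorSet(ens.group_dose_vectors)


def test_mixture_log_likelihood_against_brute_force(mixture_inputs):
    cohort, doses = mixture_inputs
    rng = np.random.default_rng(3)
    p = rng.dirichlet(np.ones(doses.m))
    theta = (0.4, 1.2, -8.0)
    got = mixture_log_likelihood(*theta, p, cohort, doses)
    per = np.array([log_likelihood(*theta, cohort, v) for v in doses.vectors])
    shift = per.max()
    expected = shift + np.log(np.sum(p * np.exp(per - shift)))
    assert got == pytest.approx(expected, rel=1e-12)


def test_mixture_degenerate_and_uniform_identities(mixture_inputs):
    cohort, doses = mixture_inputs
    theta = (0.3, 1.8, -8.5)
    p = np.zeros(doses.m)
    p[7] = 1.0
    assert mixture_log_likelihood(*theta, p, cohort, doses) == pytest.approx(
        log_likelihood(*theta, cohort, doses.vectors[7]), rel=1e-12)
    uniform = np.full(doses.m, 1.0 / doses.m)
    assert mixture_log_likelihood(*theta, uniform, cohort, doses) == pytest.approx(
        mcml_log_likelihood(*theta, cohort, doses), rel=1e-12)


# ----------------------------------------------------------------- BGR


def test_bgr_hand_computation():
    """Two 5-draw toy chains, checked against the closed form computed
    from definition: W mean within-variance, B/n variance of means."""
    c1 = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    c2 = np.array([2.0, 4.0, 6.0, 8.0, 10.0])
    w = (c1.var(ddof=1) + c2.var(ddof=1)) / 2  # (2.5 + 10)/2 = 6.25
    b_over_n = np.var([c1.mean(), c2.mean()], ddof=1)  # (3-6)^2... = 4.5
    expected = np.sqrt((4 / 5 * w + b_over_n) / w)
    assert bgr_statistic(np.stack([c1, c2])) == pytest.approx(expected, rel=1e-12)


def test_bgr_directionality():
    rng = np.random.default_rng(0)
    x = rng.standard_normal(500)
    same = bgr_statistic(np.stack([x, x]))
    assert same == pytest.approx(np.sqrt(499 / 500), rel=1e-9)
    shifted = bgr_statistic(np.stack([x, x + 50.0]))
    assert shifted > 10
    with pytest.warns(RuntimeWarning):
        assert np.isnan(bgr_statistic(np.ones((2, 20))))


# ----------------------------------------------------------------- FMA


def test_fma_sd_from_ci_half_widths(mixture_inputs):
    cohort, doses = mixture_inputs
    fits = fma_fit_all(cohort, doses, "linear-quadratic")
    assert fits.alpha.shape == (doses.m,)
    assert np.all(fits.sd_alpha[fits.included] > 0)
    # spot-check the min-half-width/1.96 rule on one vector
    ref = fit_with_ci(cohort, doses.vectors[0], "linear-quadratic")
    half = min(ref.alpha_hat - ref.ci_alpha.lo, ref.ci_alpha.hi - ref.alpha_hat)
    assert fits.sd_alpha[0] == pytest.approx(half / 1.96, rel=1e-3)


def test_fma_combine_single_vector_normal_limit(mixture_inputs):
    """With one vector and many draws, the FMA central estimate converges
    to the MLE and the interval to MLE +/- 1.96 SD."""
    cohort, doses = mixture_inputs
    single = DoseVectorSet(doses.vectors[:1])
    fits = fma_fit_all(cohort, single, "linear-quadratic")
    out = fma_combine(fits, np.array([1.0]), k=100_000, seed=9)
    sd = fits.sd_alpha[0]
    assert out.alpha_hat == pytest.approx(fits.alpha[0], abs=4 * sd / np.sqrt(1e5))
    assert out.ci_alpha.lo == pytest.approx(fits.alpha[0] - 1.96 * sd, abs=0.03 * sd * 1.96)
    assert out.ci_alpha.hi == pytest.approx(fits.alpha[0] + 1.96 * sd, abs=0.03 * sd * 1.96)


def test_fma_identical_vectors_degeneracy(mixture_inputs):
    cohort, doses = mixture_inputs
    v = doses.vectors[0]
    twin = DoseVectorSet(np.stack([v, v]))
    single = DoseVectorSet(v[None, :])
    f_twin = fma_fit_all(cohort, twin, "linear-quadratic")
    f_single = fma_fit_all(cohort, single, "linear-quadratic")
    out_twin = fma_combine(f_twin, fma_weights(f_twin.aic), k=200, seed=5)
    out_single = fma_combine(f_single, fma_weights(f_single.aic), k=400, seed=5)
    assert out_twin.alpha_hat == pytest.approx(out_single.alpha_hat, abs=0.05)


def test_weighted_quantile_matches_brute_force():
    rng = np.random.default_rng(12)
    x = rng.standard_normal(400)
    w = rng.uniform(0.1, 2.0, size=400)
    for q in (0.025, 0.5, 0.975):
        got = _weighted_quantile(x, w, q)
        # brute force: sort, accumulate, first sample reaching q
        order = np.argsort(x)
        cum = 0.0
        total = w.sum()
        for idx in order:
            cum += w[idx]
            if cum / total >= q:
                expected = x[idx]
                break
        assert got == expected


# ----------------------------------------------------------------- sampler


def test_bma_single_vector_posterior_matches_mle(groups):
    """At m=1 the sampler reduces to a single-model Bayesian fit: with
    vague priors the posterior centres near the MLE."""
    ec = ErrorConfig(sigma_share_class=0.2, sigma_unshare_class=0.2)
    ens = build_ensemble(groups, ec, LINEAR_QUADRATIC_TRUTH, m=1,
                         n_cases=250, seed=23, keep_individual=False)
    doses = DoseVectorSet(ens.group_dose_vectors)
    mle = fit_with_ci(ens.cohort, doses.vectors[0], "linear-quadratic")
    settings_ = BmaSettings(burn_in=1500, n_keep=3000)
    summary, fit = run_quasi_2dmc_bma(ens.cohort, doses, "linear-quadratic",
                                      settings_, seed=2)
    # posterior mean within the (fairly wide) profile interval, posterior
    # interval overlapping the profile interval substantially
    assert mle.ci_alpha.lo < summary.mean_alpha < mle.ci_alpha.hi
    assert mle.ci_beta.lo < summary.mean_beta < mle.ci_beta.hi
    assert fit.ci_beta.contains(mle.beta_hat)


def test_bma_p_weights_exchangeable_at_zero_berkson(groups):
    """With identical dose vectors the latent-weight posterior is
    exchangeable: which components carry weight in a finite run is pure
    Monte-Carlo accident, so it must be seed-dependent, not data-driven."""
    ec = ErrorConfig(sigma_share_class=0.2, sigma_unshare_class=0.2)
    ens = build_ensemble(groups, ec, LINEAR_QUADRATIC_TRUTH, m=20,
                         n_cases=250, seed=29, keep_individual=False)
    doses = DoseVectorSet(ens.group_dose_vectors)
    cfg = BmaSettings(burn_in=300, n_keep=700)
    s1, _ = run_quasi_2dmc_bma(ens.cohort, doses, "linear-quadratic", cfg, seed=3)
    s2, _ = run_quasi_2dmc_bma(ens.cohort, doses, "linear-quadratic", cfg, seed=4)
    for s in (s1, s2):
        assert s.p_weights_mean.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(s.p_weights_mean > 0)
    # rank patterns across seeds are unrelated (no component is preferred
    # by the data; any concentration is sampling noise)
    from scipy.stats import spearmanr

    rho = spearmanr(s1.p_weights_mean, s2.p_weights_mean).statistic
    assert abs(rho) < 0.6
    assert int(np.argmax(s1.p_weights_mean)) != int(np.argmax(s2.p_weights_mean))


def test_bma_settings_validation():
    with pytest.raises(ValueError):
        BmaSettings(n_chains=1)
    with pytest.raises(ValueError):
        BmaSettings(proposal_sd_lambda=0.0)
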