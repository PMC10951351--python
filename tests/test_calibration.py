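"""Unadjusted, regression-calibration, ERC and MCML estimators."""

import numpy as np
import pytest

from doserr import (
    LINEAR_QUADRATIC_TRUTH,
    DoseVectorSet,
    ErrorConfig,
    build_ensemble,
    fit_erc,
    fit_mcml,
    fit_regression_calibration,
    fit_unadjusted,
    fit_with_ci,
)
from doserr.calibration import mcml_log_likelihood


@pytest.fixture(scope="module")
def berkson_ensemble(groups, berkson_heavy):
    return build_ensemble(groups, berkson_heavy, LINEAR_QUADRATIC_TRUTH,
                          m=40, n_cases=250, seed=31, keep_individual=False)


def test_dose_vector_set_validation():
    with pytest.raises(ValueError):
        DoseVectorSet(np.array([[1.0, -0.5]]))
    dvs = DoseVectorSet(np.array([[1.0, 2.0], [3.0, 4.0]]))
    np.testing.assert_array_equal(dvs.mean_vector, [2.0, 3.0])


def test_degenerate_equality_at_zero_berkson(groups):
    """With zero Berkson error the dose vectors all equal the central
    estimates, so unadjusted-on-true-dose, RC, ERC and MCML coincide."""
    ec = ErrorConfig(sigma_share_class=0.2, sigma_unshare_class=0.2)
    ens = build_ensemble(groups, ec, LINEAR_QUADRATIC_TRUTH, m=5,
                         n_cases=250, seed=101, keep_individual=False)
    doses = DoseVectorSet(ens.group_dose_vectors)
    rc = fit_regression_calibration(ens.cohort, doses, "linear-quadratic")
    erc = fit_erc(ens.cohort, doses, "linear-quadratic")
    mcml = fit_mcml(ens.cohort, doses, "linear-quadratic")
    plain = fit_with_ci(ens.cohort, np.array(groups.central_doses),
                        "linear-quadratic")
    for other in (erc, mcml, plain):
        assert other.alpha_hat == pytest.approx(rc.alpha_hat, abs=1e-6)
        assert other.beta_hat == pytest.approx(rc.beta_hat, abs=1e-6)
    # ERC interval reduces exactly to the RC interval
    assert tuple(erc.ci_alpha) == pytest.approx(tuple(rc.ci_alpha), abs=1e-9)
    assert tuple(erc.ci_beta) == pytest.approx(tuple(rc.ci_beta), abs=1e-9)


def test_single_realization_identities(groups, berkson_heavy):
    ens = build_ensemble(groups, berkson_heavy, LINEAR_QUADRATIC_TRUTH, m=1,
                         n_cases=250, seed=55, keep_individual=False)
    doses = DoseVectorSet(ens.group_dose_vectors)
    rc = fit_regression_calibration(ens.cohort, doses, "linear-quadratic")
    erc = fit_erc(ens.cohort, doses, "linear-quadratic")
    mcml = fit_mcml(ens.cohort, doses, "linear-quadratic")
    direct = fit_with_ci(ens.cohort, doses.vectors[0], "linear-quadratic")
    assert rc.alpha_hat == pytest.approx(direct.alpha_hat, abs=1e-9)
    assert erc.alpha_hat == pytest.approx(direct.alpha_hat, abs=1e-9)
    assert "skipped" in erc.diagnostics["erc_inflation"]
    assert tuple(erc.ci_alpha) == pytest.approx(tuple(rc.ci_alpha), abs=1e-9)
    assert mcml.alpha_hat == pytest.approx(direct.alpha_hat, abs=1e-4)
    assert mcml.beta_hat == pytest.approx(direct.beta_hat, abs=1e-4)


def test_erc_interval_wider_under_shared_berkson(berkson_ensemble):
    doses = DoseVectorSet(berkson_ensemble.group_dose_vectors)
    rc = fit_regression_calibration(berkson_ensemble.cohort, doses,
                                    "linear-quadratic")
    erc = fit_erc(berkson_ensemble.cohort, doses, "linear-quadratic")
    assert erc.alpha_hat == rc.alpha_hat  # same point estimate
    assert erc.ci_alpha.lo < rc.ci_alpha.lo
    assert erc.ci_alpha.hi > rc.ci_alpha.hi
    assert erc.ci_beta.lo < rc.ci_beta.lo
    assert erc.ci_beta.hi > rc.ci_beta.hi


def test_mcml_objective_matches_brute_force(berkson_ensemble):
    """The MC-averaged log-likelihood equals the log of the plain average
    of per-vector likelihoods, summed directly at moderate m."""
    doses = DoseVectorSet(berkson_ensemble.group_dose_vectors)
    cohort = berkson_ensemble.cohort
    from doserr.rr_poisson import log_likelihood

    theta = (0.3, 1.5, float(np.log(250 / sum(cohort.offsets)) - 1.0))
    per = np.array([
        log_likelihood(theta[0], theta[1], theta[2], cohort, v)
        for v in doses.vectors
    ])
    shift = per.max()
    expected = shift + np.log(np.mean(np.exp(per - shift)))
    got = mcml_log_likelihood(theta[0], theta[1], theta[2], cohort, doses)
    assert got == pytest.approx(expected, rel=1e-12)
    # bounded by the extreme per-vector log-likelihoods
    assert per.min() <= got <= per.max()


def test_mcml_interval_satisfies_deviance_threshold(berkson_ensemble):
    doses = DoseVectorSet(berkson_ensemble.group_dose_vectors)
    fit = fit_mcml(berkson_ensemble.cohort, doses, "linear-quadratic")
    assert fit.converged
    assert fit.ci_alpha.lo <= fit.alpha_hat <= fit.ci_alpha.hi
    assert fit.ci_beta.lo <= fit.beta_hat <= fit.ci_beta.hi


def test_unadjusted_uses_surrogate_and_ignores_berkson(groups):
    """Under fixed seeds the unadjusted fit is untouched by Berkson-error
    changes, while RC/ERC/MCML and the model-averaging inputs are
    untouched by classical-error changes."""
    base = ErrorConfig(sigma_share_berkson=0.2, sigma_unshare_berkson=0.2,
                       sigma_share_class=0.2, sigma_unshare_class=0.2)
    berkson_bumped = ErrorConfig(sigma_share_berkson=0.5, sigma_unshare_berkson=0.5,
                                 sigma_share_class=0.2, sigma_unshare_class=0.2)
    e1 = build_ensemble(groups, base, LINEAR_QUADRATIC_TRUTH, m=3,
                        n_cases=250, seed=4, keep_individual=False)
    e2 = build_ensemble(groups, berkson_bumped, LINEAR_QUADRATIC_TRUTH, m=3,
                        n_cases=250, seed=4, keep_individual=False)
    np.testing.assert_array_equal(e1.unadjusted_dose_vector,
                                  e2.unadjusted_dose_vector)

    classical_bumped = ErrorConfig(sigma_share_berkson=0.2, sigma_unshare_berkson=0.2,
                                   sigma_share_class=0.5, sigma_unshare_class=0.5)
    e3 = build_ensemble(groups, classical_bumped, LINEAR_QUADRATIC_TRUTH, m=3,
                        n_cases=250, seed=4, keep_individual=False)
    np.testing.assert_array_equal(e1.group_dose_vectors, e3.group_dose_vectors)
    assert e1.cohort == e3.cohort
    d1 = DoseVectorSet(e1.group_dose_vectors)
    d3 = DoseVectorSet(e3.group_dose_vectors)
    f1 = fit_regression_calibration(e1.cohort, d1, "linear-quadratic")
    f3 = fit_regression_calibration(e3.cohort, d3, "linear-quadratic")
    assert f1.to_dict() == f3.to_dict()


def test_unadjusted_degenerates_to_central_doses(groups, zero_error):
    ens = build_ensemble(groups, zero_error, LINEAR_QUADRATIC_TRUTH, m=2,
                         n_cases=250, seed=8, keep_individual=False)
    fit = fit_unadjusted(ens.cohort, ens, "linear-quadratic")
    ref = fit_with_ci(ens.cohort, np.array(groups.central_doses),
                      "linear-quadratic", method="unadjusted")
    # group averaging of identical doses is exact only to summation order,
    # so compare at solver precision rather than bitwise
    assert fit.alpha_hat == pytest.approx(ref.alpha_hat, abs=1e-8)
    assert fit.beta_hat == pytest.approx(ref.beta_hat, abs=1e-8)
    assert tuple(fit.ci_alpha) == pytest.approx(tuple(ref.ci_alpha), abs=1e-6)
    assert tuple(fit.ci_beta) == pytest.approx(tuple(ref.ci_beta), abs=1e-6)
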