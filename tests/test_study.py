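"""Study orchestration: coverage, mean coefficients, ERR bias, tables."""

import numpy as np
import pytest

from doserr import (
    LINEAR_QUADRATIC_TRUTH,
    LINEAR_TRUTH,
    BmaSettings,
    ErrorConfig,
    StudyConfig,
    coverage,
    err_bias,
    mean_coefficients,
    run_study,
    write_tables,
)
from doserr.rr_poisson import FitResult, ProfileInterval
from doserr.study import StudyResult, default_scenarios, scenario_label


def _fit(alpha, ci, beta=None, ci_beta=None, converged=True):
    return FitResult(
        method="mle", form="linear-quadratic" if beta is not None else "linear",
        alpha_hat=alpha, beta_hat=beta, kappa_hat=0.0, loglik=-1.0, aic=8.0,
        converged=converged,
        ci_alpha=ProfileInterval(*ci) if ci else None,
        ci_beta=ProfileInterval(*ci_beta) if ci_beta else None,
    )


def test_coverage_trivial_cases():
    always = [_fit(1.0, (-np.inf, np.inf)) for _ in range(10)]
    assert coverage(always, 3.0).percent == 100.0
    never = [_fit(1.0, (0.5, 1.5)) for _ in range(10)]
    assert coverage(never, 3.0).percent == 0.0
    mixed = [_fit(1.0, (0.0, 2.0)), _fit(1.0, (2.5, 3.5))]
    assert coverage(mixed, 3.0).percent == 50.0
    # unconverged fits are excluded and counted
    res = coverage(mixed + [_fit(1.0, (0.0, 9.0), converged=False)], 3.0)
    assert res.percent == 50.0 and res.n_excluded == 1
    with pytest.raises(ValueError):
        coverage([_fit(1.0, None)], 3.0, "beta")


def test_coverage_monotone_in_interval_width():
    rng = np.random.default_rng(1)
    fits = [_fit(a, (a - w, a + w))
            for a, w in zip(rng.normal(3, 1, 50), rng.uniform(0.1, 2, 50))]
    base = coverage(fits, 3.0).percent
    widened = [_fit(f.alpha_hat, (f.ci_alpha.lo - 0.5, f.ci_alpha.hi + 0.5))
               for f in fits]
    assert coverage(widened, 3.0).percent >= base


def test_mean_coefficients():
    fits = [_fit(1.0, (0, 2), beta=1.0, ci_beta=(0, 2)),
            _fit(3.0, (2, 4), beta=5.0, ci_beta=(4, 6))]
    assert mean_coefficients(fits) == (2.0, 3.0)
    assert mean_coefficients([fits[0]]) == (1.0, 1.0)
    with pytest.raises(ValueError):
        mean_coefficients([_fit(1.0, (0, 2), converged=False)])


def test_err_bias_identities():
    assert err_bias(0.25, 2.0, LINEAR_QUADRATIC_TRUTH, 0.7) == pytest.approx(0.0)
    # linear model: bias is dose-free and equals 100*(alpha_mean/alpha - 1)
    assert err_bias(3.345, float("nan"), LINEAR_TRUTH, 0.1) == pytest.approx(11.5)
    assert err_bias(3.345, float("nan"), LINEAR_TRUTH, 1.0) == pytest.approx(11.5)
    with pytest.raises(ValueError):
        err_bias(1.0, 1.0, RiskModelSpec_zero(), 0.5)


def RiskModelSpec_zero():
    from doserr import RiskModelSpec

    return RiskModelSpec(alpha=0.0, beta=0.0)


@pytest.fixture(scope="module")
def tiny_study_config():
    return StudyConfig(
        n_meta=2, m_sub=10, n_cases=120,
        scenarios=(
            ErrorConfig(sigma_share_berkson=0.2, sigma_unshare_berkson=0.2,
                        sigma_share_class=0.2, sigma_unshare_class=0.2),
        ),
        risk_models=(LINEAR_QUADRATIC_TRUTH, LINEAR_TRUTH),
        methods=("unadjusted", "regression_calibration", "erc", "mcml",
                 "quasi_2dmc_bma", "fma"),
        bma_settings=BmaSettings(burn_in=60, n_keep=60),
        fma_k=20,
        master_seed=11,
    )


def test_run_study_smoke_and_determinism(tiny_study_config):
    """A one-scenario, all-methods miniature study populates every cell
    and reproduces bit-identically under the same master seed."""
    r1 = run_study(tiny_study_config)
    r2 = run_study(tiny_study_config)
    assert r1.to_json() == r2.to_json()
    for form in ("linear-quadratic", "linear"):
        scen = r1.results[form][scenario_label(tiny_study_config.scenarios[0])]
        for method in tiny_study_config.methods:
            cell = scen[method]
            if cell is None:  # a method with zero converged fits is reported missing
                continue
            assert 0.0 <= cell["coverage_alpha"] <= 100.0
            assert np.isfinite(cell["mean_alpha"])
            assert set(cell["err_bias"]) == {"0.1", "1.0"}


def test_classical_error_does_not_move_true_dose_methods():
    """Scenario cells for RC are identical across scenarios differing only
    in classical error, under the shared seeding scheme."""
    scen_a = ErrorConfig(sigma_share_berkson=0.2, sigma_unshare_berkson=0.2,
                         sigma_share_class=0.2, sigma_unshare_class=0.2)
    scen_b = ErrorConfig(sigma_share_berkson=0.2, sigma_unshare_berkson=0.2,
                         sigma_share_class=0.5, sigma_unshare_class=0.5)
    config = StudyConfig(
        n_meta=2, m_sub=6, n_cases=100, scenarios=(scen_a, scen_b),
        risk_models=(LINEAR_QUADRATIC_TRUTH,),
        methods=("regression_calibration", "unadjusted"),
        master_seed=5,
    )
    res = run_study(config)
    cells = res.results["linear-quadratic"]
    rc_a = cells[scenario_label(scen_a)]["regression_calibration"]
    rc_b = cells[scenario_label(scen_b)]["regression_calibration"]
    assert rc_a == rc_b
    un_a = cells[scenario_label(scen_a)]["unadjusted"]
    un_b = cells[scenario_label(scen_b)]["unadjusted"]
    assert un_a["mean_alpha"] != un_b["mean_alpha"]


def test_write_tables_round_trip(tmp_path, tiny_study_config):
    import pandas as pd

    result = run_study(tiny_study_config)
    paths = write_tables(result, tmp_path)
    names = {p.name for p in paths}
    assert names == {
        "table_coverage_lq.csv", "table_coverage_linear.csv",
        "table_mean_coefs_lq.csv", "table_mean_coefs_linear.csv",
        "table_err_bias.csv",
    }
    label = scenario_label(tiny_study_config.scenarios[0])
    cov = pd.read_csv(tmp_path / "table_coverage_lq.csv")
    cell = result.results["linear-quadratic"][label]["regression_calibration"]
    assert cov.loc[0, "regression_calibration_coverage_alpha"] == cell["coverage_alpha"]
    bias = pd.read_csv(tmp_path / "table_err_bias.csv")
    assert bias.loc[0, "regression_calibration_bias_at_0.1Gy"] == pytest.approx(
        cell["err_bias"]["0.1"], rel=1e-12)
    # JSON round trip preserves everything
    restored = StudyResult.from_json(result.to_json())
    assert restored.results == result.results


def test_default_scenario_grid():
    scens = default_scenarios()
    assert len(scens) == 6
    assert all(s.sigma_share_class == 0.2 and s.sigma_unshare_class == 0.2
               for s in scens)
    assert scenario_label(scens[2]) == "uB20_sB50_uC20_sC20"


def test_config_validation(groups):
    with pytest.raises(ValueError):
        StudyConfig(methods=())
    with pytest.raises(ValueError):
        StudyConfig(methods=("nope",))
    with pytest.raises(ValueError):
        StudyConfig(pred_doses=(0.0,))
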