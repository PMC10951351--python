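"""Simulation-study orchestration: scenarios x meta-ensembles x methods.

For each error scenario and risk model, ``run_study`` builds ``n_meta``
independent meta-ensembles, runs the requested correction methods on
each, and aggregates 95%-interval coverage of the true coefficients,
ensemble-mean coefficients, and the percent bias in predicted excess
relative risk

    100 * [(alpha_mean * D + beta_mean * D^2) / (alpha * D + beta * D^2) - 1]

at the configured prediction doses.  Results are serializable to JSON
and to a set of CSV tables (coverage, mean coefficients, ERR bias).

Seeding is hierarchical: the master seed, the risk-model index, the
Berkson error magnitudes and the ensemble index determine every stream.
Because classical error magnitudes are deliberately excluded from the
seed, scenarios differing only in classical error share their dose and
case draws, so every estimator that uses true doses produces identical
results across such scenarios -- classical error affects only the
unadjusted fit, exactly as the error model implies.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .calibration import (
    DoseVectorSet,
    fit_erc,
    fit_mcml,
    fit_regression_calibration,
    fit_unadjusted,
)
from .cohort_sim import (
    LINEAR_QUADRATIC_TRUTH,
    LINEAR_TRUTH,
    RiskModelSpec,
    build_ensemble,
)
from .error_model import DoseGroupSpec, ErrorConfig, default_groups, dose_correlation
from .model_averaging import BmaSettings, fit_fma, run_quasi_2dmc_bma
from .rr_poisson import FitResult

__all__ = [
    "ALL_METHODS",
    "StudyConfig",
    "StudyResult",
    "CoverageResult",
    "coverage",
    "mean_coefficients",
    "err_bias",
    "run_study",
    "write_tables",
    "default_scenarios",
    "scenario_label",
]

ALL_METHODS = (
    "unadjusted",
    "regression_calibration",
    "erc",
    "mcml",
    "quasi_2dmc_bma",
    "fma",
)


def default_scenarios() -> tuple[ErrorConfig, ...]:
    """The default grid: six (unshared, shared) Berkson rows, classical
    error fixed at 20%/20%."""
    berkson = ((0.0, 0.0), (0.2, 0.2), (0.2, 0.5), (0.0, 0.5), (0.5, 0.2), (0.5, 0.5))
    return tuple(
        ErrorConfig(
            sigma_unshare_berkson=u, sigma_share_berkson=s,
            sigma_unshare_class=0.2, sigma_share_class=0.2,
        )
        for u, s in berkson
    )


def scenario_label(ec: ErrorConfig) -> str:
    def pct(x: float) -> str:
        return f"{100 * x:g}"

    return (f"uB{pct(ec.sigma_unshare_berkson)}_sB{pct(ec.sigma_share_berkson)}"
            f"_uC{pct(ec.sigma_unshare_class)}_sC{pct(ec.sigma_share_class)}")


@dataclass(frozen=True)
class StudyConfig:
    """Complete configuration for one simulation study."""

    n_meta: int = 500
    m_sub: int = 1000
    n_cases: int = 250
    scenarios: tuple[ErrorConfig, ...] = field(default_factory=default_scenarios)
    risk_models: tuple[RiskModelSpec, ...] = (LINEAR_QUADRATIC_TRUTH, LINEAR_TRUTH)
    methods: tuple[str, ...] = ALL_METHODS
    groups: DoseGroupSpec = field(default_factory=default_groups)
    bma_settings: BmaSettings = field(default_factory=BmaSettings)
    fma_k: int = 100
    pred_doses: tuple[float, ...] = (0.1, 1.0)
    master_seed: int = 1

    def __post_init__(self) -> None:
        if self.n_meta < 1 or self.m_sub < 1 or self.n_cases < 1:
            raise ValueError("n_meta, m_sub and n_cases must be >= 1")
        if not self.methods:
            raise ValueError("methods must be non-empty")
        unknown = set(self.methods) - set(ALL_METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")
        if any(d <= 0 for d in self.pred_doses):
            raise ValueError("pred_doses must be > 0")


class CoverageResult(NamedTuple):
    percent: float
    n_used: int
    n_excluded: int


def _get_ci(fit: FitResult, coefficient: str):
    return fit.ci_alpha if coefficient == "alpha" else fit.ci_beta


def coverage(fits: Sequence[FitResult], true_value: float,
             coefficient: str = "alpha") -> CoverageResult:
    """Percent of converged fits whose 95% interval covers the truth."""
    used = 0
    hit = 0
    excluded = 0
    for f in fits:
        ci = _get_ci(f, coefficient)
        if not f.converged or ci is None:
            excluded += 1
            continue
        used += 1
        if ci.lo <= true_value <= ci.hi:
            hit += 1
    if used == 0:
        raise ValueError("no converged fits with an interval for "
                         f"coefficient {coefficient!r}")
    return CoverageResult(100.0 * hit / used, used, excluded)


def mean_coefficients(fits: Sequence[FitResult]) -> tuple[float, float]:
    """Arithmetic means of (alpha, beta) over converged fits; beta is nan
    for linear-form fits."""
    alphas = [f.alpha_hat for f in fits if f.converged]
    if not alphas:
        raise ValueError("no converged fits")
    betas = [f.beta_hat for f in fits if f.converged and f.beta_hat is not None]
    beta_mean = float(np.mean(betas)) if betas else float("nan")
    return float(np.mean(alphas)), beta_mean


def err_bias(alpha_mean: float, beta_mean: float, risk: RiskModelSpec,
             d_pred: float) -> float:
    """Percent bias in predicted excess relative risk at dose ``d_pred``."""
    true_err = risk.alpha * d_pred + risk.beta * d_pred**2
    if true_err <= 0:
        raise ValueError(f"true ERR non-positive at d_pred={d_pred}")
    if np.isnan(beta_mean):
        beta_mean = 0.0
    est_err = alpha_mean * d_pred + beta_mean * d_pred**2
    return 100.0 * (est_err / true_err - 1.0)


@dataclass
class StudyResult:
    """Aggregated study output (machine-readable coverage/bias tables)."""

    config_summary: dict[str, Any]
    results: dict[str, dict[str, dict[str, Any]]]  # form -> scenario -> method
    dose_correlations: dict[str, float]
    convergence_report: dict[str, dict[str, Any]]

    def to_json(self, **kwargs) -> str:
        return json.dumps({
            "config": self.config_summary,
            "results": self.results,
            "dose_correlations": self.dose_correlations,
            "convergence_report": self.convergence_report,
        }, **kwargs)

    @classmethod
    def from_json(cls, text: str) -> "StudyResult":
        d = json.loads(text)
        return cls(
            config_summary=d["config"],
            results=d["results"],
            dose_correlations=d["dose_correlations"],
            convergence_report=d["convergence_report"],
        )


def _run_method(method: str, ensemble, doses: DoseVectorSet, form: str,
                config: StudyConfig, seed_bma, seed_fma) -> FitResult:
    cohort = ensemble.cohort
    if method == "unadjusted":
        return fit_unadjusted(cohort, ensemble, form)
    if method == "regression_calibration":
        return fit_regression_calibration(cohort, doses, form)
    if method == "erc":
        return fit_erc(cohort, doses, form)
    if method == "mcml":
        return fit_mcml(cohort, doses, form)
    if method == "quasi_2dmc_bma":
        return run_quasi_2dmc_bma(cohort, doses, form, config.bma_settings,
                                  seed=seed_bma)[1]
    if method == "fma":
        return fit_fma(cohort, doses, form, k=config.fma_k, seed=seed_fma)
    raise ValueError(f"unknown method {method!r}")


def _ensemble_seed(config: StudyConfig, risk_idx: int, ec: ErrorConfig,
                   ensemble_idx: int) -> np.random.SeedSequence:
    # classical magnitudes deliberately excluded: scenarios differing only
    # in classical error share dose/case draws (see module docstring)
    berkson_key = (int(round(ec.sigma_unshare_berkson * 1_000_000)),
                   int(round(ec.sigma_share_berkson * 1_000_000)))
    return np.random.SeedSequence(
        [config.master_seed, risk_idx, *berkson_key, ensemble_idx])


def run_study(config: StudyConfig, progress: bool = False) -> StudyResult:
    """Run the full study; see module docstring for the aggregation."""
    results: dict[str, dict[str, dict[str, Any]]] = {}
    correlations: dict[str, float] = {}
    convergence: dict[str, dict[str, Any]] = {}

    for risk_idx, risk in enumerate(config.risk_models):
        form = risk.form
        form_res = results.setdefault(form, {})
        for ec in config.scenarios:
            label = scenario_label(ec)
            fits: dict[str, list[FitResult]] = {m: [] for m in config.methods}
            for e_idx in range(config.n_meta):
                ss = _ensemble_seed(config, risk_idx, ec, e_idx)
                ss_build, ss_bma, ss_fma = ss.spawn(3)
                keep = e_idx == 0  # first ensemble keeps doses for correlation
                ensemble = build_ensemble(
                    config.groups, ec, risk, m=config.m_sub,
                    n_cases=config.n_cases, seed=ss_build, keep_individual=keep,
                )
                if keep and label not in correlations:
                    if config.m_sub >= 3:
                        with warnings.catch_warnings():
                            warnings.simplefilter("ignore", RuntimeWarning)
                            correlations[label] = dose_correlation(
                                ensemble.dose_ensemble.true_doses,
                                seed=np.random.SeedSequence(
                                    [config.master_seed, 9090, e_idx]))
                    else:
                        correlations[label] = float("nan")
                    ensemble.dose_ensemble.true_doses = None
                    ensemble.dose_ensemble.surrogate_doses = None
                doses = DoseVectorSet(ensemble.group_dose_vectors)
                for method in config.methods:
                    fits[method].append(_run_method(
                        method, ensemble, doses, form, config, ss_bma, ss_fma))
                if progress:
                    print(f"[{form}] {label} ensemble {e_idx + 1}/{config.n_meta}",
                          flush=True)

            scen_res: dict[str, Any] = {}
            for method, flist in fits.items():
                cell: dict[str, Any] = {}
                n_conv = sum(f.converged for f in flist)
                convergence.setdefault(form, {}).setdefault(label, {})[method] = {
                    "n_converged": n_conv, "n_total": len(flist)}
                if n_conv == 0:
                    scen_res[method] = None  # missing cell, run continues
                    continue
                a_mean, b_mean = mean_coefficients(flist)
                cell["mean_alpha"] = a_mean
                cell["mean_beta"] = b_mean if not np.isnan(b_mean) else None
                cov_a = coverage(flist, risk.alpha, "alpha")
                cell["coverage_alpha"] = cov_a.percent
                cell["n_used"] = cov_a.n_used
                cell["n_excluded"] = cov_a.n_excluded
                if form == "linear-quadratic":
                    cell["coverage_beta"] = coverage(flist, risk.beta, "beta").percent
                cell["err_bias"] = {
                    str(d): err_bias(a_mean, b_mean, risk, d)
                    for d in config.pred_doses
                }
                scen_res[method] = cell
            form_res[label] = scen_res

    config_summary = {
        "n_meta": config.n_meta,
        "m_sub": config.m_sub,
        "n_cases": config.n_cases,
        "master_seed": config.master_seed,
        "methods": list(config.methods),
        "pred_doses": list(config.pred_doses),
        "scenarios": [scenario_label(ec) for ec in config.scenarios],
        "risk_models": [
            {"form": r.form, "alpha": r.alpha, "beta": r.beta}
            for r in config.risk_models
        ],
    }
    return StudyResult(
        config_summary=config_summary,
        results=results,
        dose_correlations=correlations,
        convergence_report=convergence,
    )


# ---------------------------------------------------------------------------
# CSV tables


def _rows_for_form(result: StudyResult, form: str):
    return result.results.get(form, {})


def write_tables(result: StudyResult, out_dir) -> list[Path]:
    """Emit the study result as CSV tables (one row per scenario, one
    column group per method): interval coverage, mean coefficients and
    percent ERR bias."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    methods = result.config_summary.get("methods", list(ALL_METHODS))
    pred_doses = [str(d) for d in result.config_summary.get("pred_doses", [0.1, 1.0])]
    written: list[Path] = []

    def emit(name: str, columns: list[str], rows: list[dict]):
        path = out / name
        pd.DataFrame(rows, columns=columns).to_csv(path, index=False)
        written.append(path)

    # coverage, linear-quadratic
    cols = ["scenario", "dose_correlation"] + [
        f"{m}_{c}" for m in methods for c in ("coverage_alpha", "coverage_beta")]
    rows = []
    for label, scen in _rows_for_form(result, "linear-quadratic").items():
        row = {"scenario": label,
               "dose_correlation": result.dose_correlations.get(label)}
        for m in methods:
            cell = scen.get(m)
            row[f"{m}_coverage_alpha"] = None if cell is None else cell.get("coverage_alpha")
            row[f"{m}_coverage_beta"] = None if cell is None else cell.get("coverage_beta")
        rows.append(row)
    emit("table_coverage_lq.csv", cols, rows)

    # coverage, linear
    cols = ["scenario"] + [f"{m}_coverage_alpha" for m in methods]
    rows = []
    for label, scen in _rows_for_form(result, "linear").items():
        row = {"scenario": label}
        for m in methods:
            cell = scen.get(m)
            row[f"{m}_coverage_alpha"] = None if cell is None else cell.get("coverage_alpha")
        rows.append(row)
    emit("table_coverage_linear.csv", cols, rows)

    # mean coefficients, linear-quadratic
    cols = ["scenario"] + [f"{m}_{c}" for m in methods for c in ("mean_alpha", "mean_beta")]
    rows = []
    for label, scen in _rows_for_form(result, "linear-quadratic").items():
        row = {"scenario": label}
        for m in methods:
            cell = scen.get(m)
            row[f"{m}_mean_alpha"] = None if cell is None else cell.get("mean_alpha")
            row[f"{m}_mean_beta"] = None if cell is None else cell.get("mean_beta")
        rows.append(row)
    emit("table_mean_coefs_lq.csv", cols, rows)

    # mean coefficient + percent bias, linear
    cols = ["scenario"] + [f"{m}_{c}" for m in methods for c in ("mean_alpha", "pct_bias")]
    rows = []
    for label, scen in _rows_for_form(result, "linear").items():
        row = {"scenario": label}
        for m in methods:
            cell = scen.get(m)
            row[f"{m}_mean_alpha"] = None if cell is None else cell.get("mean_alpha")
            bias = None
            if cell is not None:
                bias = cell.get("err_bias", {}).get(pred_doses[0])
            row[f"{m}_pct_bias"] = bias
        rows.append(row)
    emit("table_mean_coefs_linear.csv", cols, rows)

    # ERR bias, linear-quadratic
    cols = ["scenario"] + [f"{m}_bias_at_{d}Gy" for m in methods for d in pred_doses]
    rows = []
    for label, scen in _rows_for_form(result, "linear-quadratic").items():
        row = {"scenario": label}
        for m in methods:
            cell = scen.get(m)
            for d in pred_doses:
                row[f"{m}_bias_at_{d}Gy"] = (
                    None if cell is None else cell.get("err_bias", {}).get(d))
        rows.append(row)
    emit("table_err_bias.csv", cols, rows)
    return written
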