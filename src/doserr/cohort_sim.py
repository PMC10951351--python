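"""Meta-simulation ensembles: dose realizations plus a simulated cancer
cohort collapsed to dose groups.

One *meta-simulation* consists of ``m`` *sub-simulations* of true and
surrogate doses for the whole cohort, plus a single multinomial draw of
``N`` cancer cases across dose groups.  The case distribution is driven
by each individual's relative risk ``RR = 1 + alpha*d + beta*d^2``
averaged over the ``m`` true-dose realizations, scaled by ``exp(kappa)``
so the individual case probabilities sum to one; it is held constant
across the sub-simulations of its meta-simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np

from .error_model import (
    DoseEnsemble,
    DoseGroupSpec,
    ErrorConfig,
    _as_seedseq,
    draw_error_fields,
    generate_surrogate_doses,
    generate_true_doses,
    group_mean_doses,
)

__all__ = [
    "RiskModelSpec",
    "GroupedCohort",
    "MetaEnsemble",
    "mean_relative_risks",
    "normalizing_constant",
    "simulate_cases",
    "build_ensemble",
    "collapse_to_groups",
]

Form = Literal["linear", "linear-quadratic"]


@dataclass(frozen=True)
class RiskModelSpec:
    """Excess-relative-risk dose response ``RR(d) = 1 + alpha*d + beta*d^2``.

    ``alpha`` is the linear ERR coefficient (1/Gy), ``beta`` the
    quadratic one (1/Gy^2); ``form="linear"`` forces ``beta = 0``.
    """

    alpha: float
    beta: float = 0.0
    form: Form = "linear-quadratic"

    def __post_init__(self) -> None:
        if self.form not in ("linear", "linear-quadratic"):
            raise ValueError(f"unknown form {self.form!r}")
        if self.form == "linear" and self.beta != 0.0:
            raise ValueError("form='linear' requires beta = 0")

    def rr(self, dose) -> np.ndarray:
        d = np.asarray(dose, dtype=float)
        return 1.0 + self.alpha * d + self.beta * d * d


#: Default linear-quadratic truth (per Gy / per Gy^2).
LINEAR_QUADRATIC_TRUTH = RiskModelSpec(alpha=0.25, beta=2.0, form="linear-quadratic")
#: Default linear truth.
LINEAR_TRUTH = RiskModelSpec(alpha=3.0, beta=0.0, form="linear")


@dataclass(frozen=True)
class GroupedCohort:
    """Per-group case counts and person-year offsets."""

    cases: tuple[int, ...]
    offsets: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.cases) != len(self.offsets):
            raise ValueError("cases and offsets length mismatch")
        if any(c < 0 for c in self.cases):
            raise ValueError("negative case count")
        if any(o <= 0 for o in self.offsets):
            raise ValueError("offsets must be > 0")

    @property
    def n_total_cases(self) -> int:
        return int(sum(self.cases))

    @property
    def n_groups(self) -> int:
        return len(self.cases)

    def cases_array(self) -> np.ndarray:
        return np.asarray(self.cases, dtype=float)

    def offsets_array(self) -> np.ndarray:
        return np.asarray(self.offsets, dtype=float)


@dataclass
class MetaEnsemble:
    """One meta-simulation: dose ensemble, cohort, and designated dose
    vectors for the estimators.

    ``group_dose_vectors`` is the ``(m, n_groups)`` matrix of true-dose
    group means consumed by MCML and the model-averaging fits;
    ``unadjusted_dose_vector`` is the surrogate group-mean vector of the
    first sub-simulation, used only by unadjusted regression (averaging
    surrogate means over sub-simulations would cancel the shared
    classical error the unadjusted fit is supposed to feel).
    """

    groups: DoseGroupSpec
    error_config: ErrorConfig
    risk: "RiskModelSpec"
    dose_ensemble: DoseEnsemble
    cohort: GroupedCohort
    kappa_sim: float
    unadjusted_dose_vector: np.ndarray

    @property
    def group_dose_vectors(self) -> np.ndarray:
        return self.dose_ensemble.group_mean_true

    @property
    def rc_dose_vector(self) -> np.ndarray:
        """Across-sub-simulation average of the group-mean true doses."""
        return self.group_dose_vectors.mean(axis=0)


def mean_relative_risks(dose_ensemble: DoseEnsemble, risk: RiskModelSpec) -> np.ndarray:
    """Per-individual relative risk averaged over sub-simulations.

    Individual ``i`` receives ``(1/m) * sum_j (1 + alpha*D_ij + beta*D_ij^2)``,
    i.e. the expectation of RR over the dose realizations (not the RR of
    the average dose; the two differ in the quadratic term).
    """
    d = dose_ensemble.true_doses
    if d is None:
        raise ValueError("dose ensemble does not retain individual true doses")
    mean_d = d.mean(axis=0)
    mean_d2 = np.mean(d * d, axis=0)
    rr = 1.0 + risk.alpha * mean_d + risk.beta * mean_d2
    if np.any(rr <= 0):
        raise ValueError(
            "mean relative risk <= 0 for some individual: risk model "
            f"(alpha={risk.alpha}, beta={risk.beta}) invalid over the dose support"
        )
    return rr


def normalizing_constant(mean_rr: np.ndarray, weights: np.ndarray | None = None) -> float:
    """Log scaling constant kappa with ``exp(kappa) * sum_i w_i RR_i = 1``."""
    rr = np.asarray(mean_rr, dtype=float)
    if rr.size == 0:
        raise ValueError("empty mean_rr")
    if np.any(rr <= 0):
        raise ValueError("mean_rr must be > 0")
    w = np.ones_like(rr) if weights is None else np.asarray(weights, dtype=float)
    return float(-np.log(np.sum(w * rr)))


def simulate_cases(
    mean_rr: np.ndarray,
    groups: DoseGroupSpec,
    n_cases: int = 250,
    seed=0,
    weights: np.ndarray | None = None,
) -> GroupedCohort:
    """Multinomial draw of ``n_cases`` cases across dose groups.

    Group probabilities are proportional to the within-group sums of
    ``w_i * RR_i`` (individual-level Bernoulli-sum collapsed to the
    group level).  Weights default to uniform.
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    rr = np.asarray(mean_rr, dtype=float)
    w = np.ones_like(rr) if weights is None else np.asarray(weights, dtype=float)
    score = np.add.reduceat(w * rr, groups.group_starts)
    total = score.sum()
    if total <= 0:
        raise ValueError("all group case probabilities are zero")
    p = score / total
    rng = np.random.default_rng(_as_seedseq(seed))
    counts = rng.multinomial(int(n_cases), p)
    return GroupedCohort(
        cases=tuple(int(c) for c in counts),
        offsets=tuple(float(x) for x in groups.person_years),
    )


def collapse_to_groups(
    dose_matrix: np.ndarray, groups: DoseGroupSpec, cohort: GroupedCohort,
) -> tuple[GroupedCohort, np.ndarray]:
    """Collapse individual doses to per-sub-simulation group means.

    Returns the (unchanged, already grouped) cohort and the
    ``(m, n_groups)`` group-mean dose matrix whose across-row average is
    the regression-calibration dose vector.
    """
    return cohort, group_mean_doses(dose_matrix, groups)


def build_ensemble(
    groups: DoseGroupSpec,
    error_config: ErrorConfig,
    risk: RiskModelSpec,
    m: int = 1000,
    n_cases: int = 250,
    seed=0,
    keep_individual: bool = True,
) -> MetaEnsemble:
    """Generate one meta-simulation ensemble, reproducibly from ``seed``.

    Pipeline: error fields -> true/surrogate dose matrices -> group
    means -> per-individual mean RR -> normalizing constant -> one
    multinomial case draw.  ``seed`` spawns one child stream for the
    error fields and an independent one for case sampling.  With
    ``keep_individual=False`` the (m x n_total) dose matrices are
    dropped after the group means are computed, which bounds memory in
    long study runs.
    """
    ss_fields, ss_cases = _as_seedseq(seed).spawn(2)
    draws = draw_error_fields(m, groups, error_config, seed=ss_fields)
    true = generate_true_doses(groups, draws, error_config)
    surr = generate_surrogate_doses(groups, draws, error_config)
    del draws

    ensemble = DoseEnsemble(
        true_doses=true,
        surrogate_doses=surr,
        group_mean_true=group_mean_doses(true, groups),
        group_mean_surrogate=group_mean_doses(surr, groups),
    )
    rr = mean_relative_risks(ensemble, risk)
    kappa = normalizing_constant(rr)
    cohort = simulate_cases(rr, groups, n_cases=n_cases, seed=ss_cases)
    unadjusted = ensemble.group_mean_surrogate[0].copy()
    if not keep_individual:
        ensemble = replace(ensemble, true_doses=None, surrogate_doses=None)
    return MetaEnsemble(
        groups=groups,
        error_config=error_config,
        risk=risk,
        dose_ensemble=ensemble,
        cohort=cohort,
        kappa_sim=kappa,
        unadjusted_dose_vector=unadjusted,
    )
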