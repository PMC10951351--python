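"""Lognormal shared/unshared Berkson and classical dose-error model.

True and surrogate doses for individual ``i`` of dose group ``k_i`` in
sub-simulation ``j`` are

    D_true,i,j = D_cent,k_i * exp[-(s_B^2 + u_B^2)/2] * exp[s_B*eps_j + u_B*delta_ij]
    D_surr,i,j = D_cent,k_i * exp[-(s_C^2 + u_C^2)/2] * exp[s_C*mu_j  + u_C*kappa_ij]

where ``s``/``u`` are the shared/unshared log-scale standard deviations
(geometric SDs) of the Berkson (B) and classical (C) components, and
``eps_j, delta_ij, mu_j, kappa_ij`` are i.i.d. standard normal.  The
``exp[-sigma^2/2]`` factors make the theoretical mean of each dose equal
to the group's central estimate.  Shared draws (``eps``, ``mu``) are
common to every individual within a sub-simulation and generate
between-individual dose correlation; unshared draws are independent.

Setting both Berkson SDs to zero leaves a pure classical-error model
(true dose equals the central estimate); setting both classical SDs to
zero leaves a pure Berkson model (surrogate equals the central estimate).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ErrorConfig",
    "DoseGroupSpec",
    "ErrorDraws",
    "DoseEnsemble",
    "default_groups",
    "draw_error_fields",
    "generate_true_doses",
    "generate_surrogate_doses",
    "group_mean_doses",
    "dose_correlation",
    "analytic_dose_correlation",
]


@dataclass(frozen=True)
class ErrorConfig:
    """Log-scale SDs (geometric SDs) of the four error components."""

    sigma_share_berkson: float = 0.0
    sigma_unshare_berkson: float = 0.0
    sigma_share_class: float = 0.0
    sigma_unshare_class: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "sigma_share_berkson",
            "sigma_unshare_berkson",
            "sigma_share_class",
            "sigma_unshare_class",
        ):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")


@dataclass(frozen=True)
class DoseGroupSpec:
    """Dose groups: interval labels, central dose estimates (Gy),
    person-year offsets and individual counts per group.

    Individuals are laid out group-contiguously: columns
    ``group_start[g] : group_start[g] + n_individuals[g]`` of any dose
    matrix belong to group ``g``.
    """

    group_bounds: tuple[str, ...]
    central_doses: tuple[float, ...]
    person_years: tuple[float, ...]
    n_individuals: tuple[int, ...]

    def __post_init__(self) -> None:
        k = len(self.central_doses)
        if not (len(self.group_bounds) == len(self.person_years) == len(self.n_individuals) == k):
            raise ValueError("group field lengths differ")
        if k < 1:
            raise ValueError("need at least one dose group")
        cd = np.asarray(self.central_doses, dtype=float)
        if np.any(cd <= 0) or np.any(np.diff(cd) <= 0):
            raise ValueError("central_doses must be strictly increasing and > 0")
        if np.any(np.asarray(self.person_years, dtype=float) <= 0):
            raise ValueError("person_years must be > 0")
        if any(int(n) < 2 for n in self.n_individuals):
            raise ValueError("each group needs n_individuals >= 2")

    @property
    def n_groups(self) -> int:
        return len(self.central_doses)

    @property
    def n_total(self) -> int:
        return int(sum(self.n_individuals))

    @property
    def group_index(self) -> np.ndarray:
        """Group label per individual, shape ``(n_total,)``."""
        return np.repeat(np.arange(self.n_groups), self.n_individuals)

    @property
    def group_starts(self) -> np.ndarray:
        return np.concatenate([[0], np.cumsum(self.n_individuals)[:-1]]).astype(int)

    @property
    def central_per_individual(self) -> np.ndarray:
        return np.asarray(self.central_doses, dtype=float)[self.group_index]


#: Dose-group boundaries (Gy) of the synthetic bone-marrow-dose cohort.
DEFAULT_BOUNDS = ("0-0.07", "0.08-0.19", "0.20-0.99", "1.00-2.49", "2.50+")
#: Central dose estimates (Gy); the uppermost group is pinned at 2 Gy,
#: the rest sit near plausible person-year-weighted group means.
DEFAULT_CENTRAL_DOSES = (0.03, 0.12, 0.5, 1.5, 2.0)
#: Low-dose-heavy population fractions across the five groups.
DEFAULT_GROUP_FRACTIONS = (0.70, 0.15, 0.10, 0.04, 0.01)


def default_groups(n_total: int = 10_000) -> DoseGroupSpec:
    """The default five-group cohort (``n_total`` individuals, person-years
    proportional to group size)."""
    n = tuple(int(round(f * n_total)) for f in DEFAULT_GROUP_FRACTIONS)
    return DoseGroupSpec(
        group_bounds=DEFAULT_BOUNDS,
        central_doses=DEFAULT_CENTRAL_DOSES,
        person_years=tuple(float(x) for x in n),
        n_individuals=n,
    )


@dataclass
class ErrorDraws:
    """Standard-normal error fields for one dose ensemble.

    ``eps``/``mu`` (shared Berkson / classical) have shape ``(m,)``;
    ``delta``/``kappa_err`` (unshared) have shape ``(m, n_total)``.
    """

    eps: np.ndarray
    mu: np.ndarray
    delta: np.ndarray
    kappa_err: np.ndarray

    @property
    def m(self) -> int:
        return self.eps.shape[0]

    @property
    def n_total(self) -> int:
        return self.delta.shape[1]


@dataclass
class DoseEnsemble:
    """True and surrogate dose realizations plus their group means."""

    true_doses: np.ndarray | None
    surrogate_doses: np.ndarray | None
    group_mean_true: np.ndarray
    group_mean_surrogate: np.ndarray


def _as_seedseq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def draw_error_fields(m: int, groups: DoseGroupSpec, config: ErrorConfig, seed=0) -> ErrorDraws:
    """Draw the four N(0,1) error fields for ``m`` sub-simulations.

    The four fields come from four independent child streams of ``seed``
    (fixed order: eps, delta, mu, kappa_err), so the Berkson and classical
    components never share random numbers: changing one sigma can never
    perturb another component's draws.  ``config`` is accepted for
    interface symmetry; the draws themselves are sigma-free.
    """
    del config  # draws are unit-scale; sigmas enter in the dose formulas
    m = int(m)
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    n = groups.n_total
    ss_eps, ss_delta, ss_mu, ss_kappa = _as_seedseq(seed).spawn(4)
    return ErrorDraws(
        eps=np.random.default_rng(ss_eps).standard_normal(m),
        delta=np.random.default_rng(ss_delta).standard_normal((m, n)),
        mu=np.random.default_rng(ss_mu).standard_normal(m),
        kappa_err=np.random.default_rng(ss_kappa).standard_normal((m, n)),
    )


def _lognormal_field(
    central: np.ndarray, shared_sd: float, unshared_sd: float,
    shared_draw: np.ndarray, unshared_draw: np.ndarray,
) -> np.ndarray:
    if unshared_draw.shape[0] != shared_draw.shape[0] or unshared_draw.shape[1] != central.shape[0]:
        raise ValueError(
            f"draw shapes {shared_draw.shape}/{unshared_draw.shape} do not match "
            f"{central.shape[0]} individuals"
        )
    if shared_sd == 0.0 and unshared_sd == 0.0:
        # exact degeneracy: dose == central estimate, bit for bit
        return np.broadcast_to(central, unshared_draw.shape).copy()
    log_dose = np.multiply(unshared_sd, unshared_draw)
    log_dose += shared_sd * shared_draw[:, None]
    log_dose += -0.5 * (shared_sd**2 + unshared_sd**2)
    np.exp(log_dose, out=log_dose)
    log_dose *= central
    return log_dose


def generate_true_doses(groups: DoseGroupSpec, draws: ErrorDraws, config: ErrorConfig) -> np.ndarray:
    """True doses (Gy), shape ``(m, n_total)``; Berkson components only."""
    return _lognormal_field(
        groups.central_per_individual,
        config.sigma_share_berkson, config.sigma_unshare_berkson,
        draws.eps, draws.delta,
    )


def generate_surrogate_doses(groups: DoseGroupSpec, draws: ErrorDraws, config: ErrorConfig) -> np.ndarray:
    """Surrogate doses (Gy), shape ``(m, n_total)``; classical components only."""
    return _lognormal_field(
        groups.central_per_individual,
        config.sigma_share_class, config.sigma_unshare_class,
        draws.mu, draws.kappa_err,
    )


def group_mean_doses(dose_matrix: np.ndarray, groups: DoseGroupSpec) -> np.ndarray:
    """Arithmetic group-mean doses, shape ``(m, n_groups)``."""
    dose_matrix = np.asarray(dose_matrix, dtype=float)
    if dose_matrix.ndim != 2 or dose_matrix.shape[1] != groups.n_total:
        raise ValueError(
            f"dose matrix has shape {dose_matrix.shape}, expected (m, {groups.n_total})"
        )
    sums = np.add.reduceat(dose_matrix, groups.group_starts, axis=1)
    return sums / np.asarray(groups.n_individuals, dtype=float)


def analytic_dose_correlation(shared_sd: float, unshared_sd: float) -> float:
    """Pearson correlation between two individuals' lognormal dose series,

    ``(exp(s^2) - 1) / (exp(s^2 + u^2) - 1)``,

    implied by the shared/unshared error decomposition.  Undefined (nan)
    when both SDs are zero."""
    s2, u2 = shared_sd**2, unshared_sd**2
    if s2 + u2 == 0:
        return float("nan")
    if s2 == 0:
        return 0.0
    return float(np.expm1(s2) / np.expm1(s2 + u2))


def dose_correlation(
    dose_matrix: np.ndarray, max_pairs: int = 500, seed=0,
) -> float:
    """Average sample Pearson correlation between pairs of individuals'
    dose series across sub-simulations.

    Up to ``max_pairs`` distinct (unordered) pairs of individuals are
    sampled (seeded); for each, the correlation of the two dose series
    over the ``m`` sub-simulations is computed, and the pair correlations
    are averaged.  A pair in which both series are the same constant
    (pure shared scaling with zero shared SD collapses to equal
    constants) contributes 1.0; other degenerate pairs are excluded with
    a warning.  Returns nan if every pair is excluded.
    """
    x = np.asarray(dose_matrix, dtype=float)
    m, n = x.shape
    if n < 2:
        raise ValueError("need at least 2 individuals")
    if m < 3:
        raise ValueError("need at least 3 sub-simulations")
    rng = np.random.default_rng(_as_seedseq(seed))
    n_pairs_total = n * (n - 1) // 2
    if n_pairs_total <= max_pairs:
        ii, jj = np.triu_indices(n, k=1)
    else:
        ii = np.empty(max_pairs, dtype=int)
        jj = np.empty(max_pairs, dtype=int)
        seen: set[tuple[int, int]] = set()
        k = 0
        while k < max_pairs:
            a, b = rng.integers(0, n, size=2)
            if a == b:
                continue
            pair = (min(a, b), max(a, b))
            if pair in seen:
                continue
            seen.add(pair)
            ii[k], jj[k] = pair
            k += 1

    xi = x[:, ii]
    xj = x[:, jj]
    xi_c = xi - xi.mean(axis=0)
    xj_c = xj - xj.mean(axis=0)
    si = np.sqrt((xi_c**2).sum(axis=0))
    sj = np.sqrt((xj_c**2).sum(axis=0))
    ok = (si > 0) & (sj > 0)
    corr = np.full(ii.shape, np.nan)
    corr[ok] = (xi_c[:, ok] * xj_c[:, ok]).sum(axis=0) / (si[ok] * sj[ok])

    both_const = (si == 0) & (sj == 0)
    identical = both_const & np.all(xi == xj, axis=0)
    corr[identical] = 1.0
    excluded = ~ok & ~identical
    if excluded.any():
        warnings.warn(
            f"excluded {int(excluded.sum())} degenerate (constant, non-identical) "
            "pairs from the dose correlation",
            RuntimeWarning,
            stacklevel=2,
        )
    valid = ~np.isnan(corr)
    if not valid.any():
        return float("nan")
    return float(corr[valid].mean())
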