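"""Non-linear mixed-effects (NLME) population fitting with MAP estimates.

Every model parameter p of subject j combines a fixed effect θ_p shared
across the population with a subject-level random effect η_p^j ~ N(0, ω_p²):

    p_j = θ_p + η_p^j          (normal family; the signal scale ξ)
    p_j = θ_p · exp(η_p^j)     (lognormal family; the four rates)

Estimation is an alternating MAP/EM scheme with a Laplace (mode)
approximation of each subject's random-effect posterior:

* E-like step — for each subject, minimize ½·V(p_j) + Σ_p η_p²/(2ω_p²)
  over η (the per-subject MAP problem; V is the χ² data cost), and take
  the inverse Hessian of that objective at the MAP as the approximate
  posterior covariance of η;
* M-like step — re-center θ on the implied individual parameter values
  (arithmetic mean for the normal family, geometric mean for lognormal)
  and update each ω_p² to the mean of (centered η_p² + posterior variance
  of η_p) across subjects.

The posterior-variance term is essential: updating ω from the MAP effects
alone ratchets ω toward zero, because MAP estimates are themselves shrunk
by the current ω (the joint penalized objective is unbounded below in
ln ω).  With the correction the update is the M-step of EM under the
Laplace approximation, and ω converges to the between-subject SD instead
of collapsing.  The population is initialized at typical values estimated
previously in healthy subjects (ξ = 1.6 and rates k_diff = 1.7, k_ph = 4.7,
k_hp = 28, k_hb = 38, each ×10⁻³ s⁻¹).

Because MAP estimates are shrunk toward the population, subjects with
sparse data inherit plausible kinetics from the cohort — the property that
makes short (≤10 min) acquisition protocols workable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import minimize

from .cohort_io import Cohort, PatientRecord
from .core_model import DoseProtocol, PhysiologicalConstants, RateParameters
from .errors import ConvergenceError, InsufficientDataError, ValidationError
from .sts_fit import (
    FIT_TIME_MIN,
    FitResult,
    GofResult,
    ObservationSet,
    gof_test,
)
from .uncertainty import UncertaintyConfig

log = logging.getLogger(__name__)

__all__ = [
    "ParameterDistribution",
    "PopulationModel",
    "IndividualEstimate",
    "default_population",
    "individual_parameter",
    "neg_log_joint",
    "fit_individual_map",
    "fit_population",
    "leave_one_out_truncated_fit",
]

#: ω values below this are treated as effectively degenerate (no variation)
OMEGA_FLOOR = 1e-8


@dataclass(frozen=True)
class ParameterDistribution:
    """Population distribution of one model parameter.

    ``omega`` is the random-effect SD: in parameter units for the normal
    family, dimensionless log-SD for the lognormal family.
    """

    name: str
    family: str  # "normal" | "lognormal"
    theta: float
    omega: float

    def __post_init__(self) -> None:
        if self.family not in ("normal", "lognormal"):
            raise ValidationError(f"unknown family {self.family!r}")
        if self.family == "lognormal" and self.theta <= 0:
            raise ValidationError(f"{self.name}: lognormal theta must be > 0")
        if self.omega < 0:
            raise ValidationError(f"{self.name}: omega must be >= 0")


@dataclass(frozen=True)
class PopulationModel:
    """One distribution per model parameter, in canonical order."""

    distributions: tuple[ParameterDistribution, ...]

    def __post_init__(self) -> None:
        names = [d.name for d in self.distributions]
        if names != ["k_diff", "k_ph", "k_hp", "k_hb", "xi"]:
            raise ValidationError(
                "population model needs exactly (k_diff, k_ph, k_hp, k_hb, xi), "
                f"got {names}"
            )
        families = {d.name: d.family for d in self.distributions}
        if families["xi"] != "normal" or any(
            families[k] != "lognormal" for k in ("k_diff", "k_ph", "k_hp", "k_hb")
        ):
            raise ValidationError(
                "ξ must be normal and the four rates lognormal"
            )

    def __iter__(self):
        return iter(self.distributions)

    def __getitem__(self, name: str) -> ParameterDistribution:
        for d in self.distributions:
            if d.name == name:
                return d
        raise KeyError(name)

    def typical_params(self) -> RateParameters:
        """Individual parameters at η = 0."""
        return self.params_from_eta(np.zeros(5))

    def params_from_eta(self, eta: np.ndarray) -> RateParameters:
        vals = [individual_parameter(d, e) for d, e in zip(self.distributions, eta)]
        return RateParameters(*vals)

    def thetas(self) -> np.ndarray:
        return np.array([d.theta for d in self.distributions])

    def omegas(self) -> np.ndarray:
        return np.array([d.omega for d in self.distributions])

    def with_values(self, thetas, omegas) -> "PopulationModel":
        return PopulationModel(
            tuple(
                replace(d, theta=float(t), omega=float(w))
                for d, t, w in zip(self.distributions, thetas, omegas)
            )
        )


def default_population() -> PopulationModel:
    """Healthy-cohort population priors.

    Typical values are ξ = 1.6 and rates (1.7, 4.7, 28, 38)×10⁻³ s⁻¹.
    Initial random-effect SDs are deliberately generous — chosen so the
    estimation is not unnecessarily limited — because the EM ω update
    adapts downward quickly but upward only slowly: 1.0 for ξ (natural
    scale) and 0.5 for each rate (log scale, ≈50% CV).  The alternating
    scheme re-estimates them; pass a custom :class:`PopulationModel` to
    override.
    """
    return PopulationModel(
        (
            ParameterDistribution("k_diff", "lognormal", 1.7e-3, 0.5),
            ParameterDistribution("k_ph", "lognormal", 4.7e-3, 0.5),
            ParameterDistribution("k_hp", "lognormal", 28e-3, 0.5),
            ParameterDistribution("k_hb", "lognormal", 38e-3, 0.5),
            ParameterDistribution("xi", "normal", 1.6, 1.0),
        )
    )


def individual_parameter(dist: ParameterDistribution, eta: float) -> float:
    """Map a random effect to the subject-level parameter value."""
    if dist.family == "normal":
        return dist.theta + eta
    return dist.theta * float(np.exp(eta))


@dataclass(frozen=True)
class IndividualEstimate:
    """MAP estimate of one subject within a population model."""

    patient_id: str
    eta: np.ndarray
    params: RateParameters
    map_objective: float
    gof: GofResult

    def to_fit_result(self, n_obs_each: int) -> FitResult:
        return FitResult(
            params=self.params,
            gof=self.gof,
            n_obs_liver=n_obs_each,
            n_obs_spleen=n_obs_each,
            converged=True,
            method="NLME",
        )


def _eta_penalty(eta: np.ndarray, omegas: np.ndarray) -> float:
    """Σ_p η_p²/(2ω_p²) with the ω = 0 convention (0 if η = 0, else +inf)."""
    pen = 0.0
    for e, w in zip(eta, omegas):
        if w <= OMEGA_FLOOR:
            if abs(e) > 0:
                return np.inf
        else:
            pen += e * e / (2.0 * w * w)
    return pen


def neg_log_joint(
    eta_all: dict[str, np.ndarray],
    pop: PopulationModel,
    cohort: Cohort,
    constants: PhysiologicalConstants = PhysiologicalConstants(),
    doses: dict[str, DoseProtocol] | None = None,
    config: UncertaintyConfig = UncertaintyConfig(),
) -> float:
    """Joint penalized objective over the whole cohort (up to constants).

    Σ_j [ ½·V(p_j) + Σ_p η_{p,j}²/(2ω_p²) ] + Σ_j Σ_p ln ω_p
    """
    omegas = pop.omegas()
    total = 0.0
    log_w = float(np.sum(np.log(np.maximum(omegas, OMEGA_FLOOR))))
    for patient in cohort:
        eta = np.asarray(eta_all[patient.patient_id], dtype=float)
        pen = _eta_penalty(eta, omegas)
        if not np.isfinite(pen):
            return np.inf
        dose = _dose_for(patient, doses)
        obs = ObservationSet(patient, config)
        total += 0.5 * obs.chi2(pop.params_from_eta(eta), constants, dose)
        total += pen + log_w
    return float(total)


def _dose_for(patient: PatientRecord, doses: dict[str, DoseProtocol] | None) -> DoseProtocol:
    if doses and patient.patient_id in doses:
        return doses[patient.patient_id]
    return DoseProtocol(body_weight=patient.body_weight)


def _map_objective_factory(obs, pop, constants, dose):
    omegas = pop.omegas()
    fixed = omegas <= OMEGA_FLOOR  # degenerate dimensions stay at eta = 0
    free = ~fixed

    def objective(ef: np.ndarray) -> float:
        eta = np.zeros(5)
        eta[free] = ef
        try:
            params = pop.params_from_eta(eta)
        except ValidationError:
            return np.inf
        try:
            data_term = 0.5 * obs.chi2(params, constants, dose)
        except Exception:
            return np.inf
        return data_term + float(np.sum(ef * ef / (2.0 * omegas[free] ** 2)))

    return objective, free


def _hessian(objective, x: np.ndarray, h: float = 1e-3) -> np.ndarray:
    """Central finite-difference Hessian of a scalar objective at ``x``."""
    n = x.size
    if n == 0:
        return np.zeros((0, 0))
    f0 = objective(x)
    H = np.empty((n, n))
    for i in range(n):
        e = np.zeros(n)
        e[i] = h
        H[i, i] = (objective(x + e) - 2.0 * f0 + objective(x - e)) / h**2
    for i in range(n):
        for j in range(i + 1, n):
            ei = np.zeros(n); ei[i] = h
            ej = np.zeros(n); ej[j] = h
            H[i, j] = H[j, i] = (
                objective(x + ei + ej) - objective(x + ei - ej)
                - objective(x - ei + ej) + objective(x - ei - ej)
            ) / (4.0 * h**2)
    if not np.all(np.isfinite(H)):
        return np.zeros((n, n))
    return H


def _posterior_variance(objective, x: np.ndarray, omegas_free: np.ndarray) -> np.ndarray:
    """Laplace posterior variances of the free η at the MAP point.

    Diagonal of the inverse Hessian of the per-subject objective (data term
    plus prior), clipped to [0, ω²]: conditioning on data can only sharpen
    the prior.
    """
    H = _hessian(objective, x)
    if x.size == 0:
        return np.zeros(0)
    if not np.all(np.isfinite(H)) or not np.any(H):
        return omegas_free**2
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
    return np.clip(np.diag(cov).copy(), 0.0, omegas_free**2)


def _minimize_map(obs, pop, constants, dose, eta0=None) -> tuple[np.ndarray, float]:
    """MAP η for one subject; never returns a point worse than the start."""
    objective, free = _map_objective_factory(obs, pop, constants, dose)
    nfree = int(free.sum())
    start = np.zeros(5) if eta0 is None else np.asarray(eta0, dtype=float).copy()
    start[~free] = 0.0
    s = start[free]
    f_start = objective(s)
    best_x, best_f = s, f_start
    if nfree:
        res = minimize(objective, s, method="L-BFGS-B",
                       options={"maxiter": 300, "ftol": 1e-12, "gtol": 1e-9})
        improved = np.isfinite(res.fun) and res.fun < best_f
        if improved:
            best_x, best_f = res.x, float(res.fun)
        # simplex polish helps on cold starts; skip when a warm start was
        # already (numerically) optimal
        if eta0 is None or not np.isfinite(f_start) or f_start - best_f > 1e-9:
            res = minimize(objective, best_x, method="Nelder-Mead",
                           options={"maxiter": 400, "xatol": 1e-9, "fatol": 1e-11})
            if np.isfinite(res.fun) and res.fun < best_f:
                best_x, best_f = res.x, float(res.fun)
    if not np.isfinite(best_f):
        raise ConvergenceError(
            f"patient {obs.patient_id}: MAP objective non-finite at start"
        )
    eta = np.zeros(5)
    eta[free] = best_x
    return eta, float(best_f)


def fit_individual_map(
    patient: PatientRecord,
    pop: PopulationModel,
    constants: PhysiologicalConstants = PhysiologicalConstants(),
    dose: DoseProtocol | None = None,
    config: UncertaintyConfig = UncertaintyConfig(),
    eta0: np.ndarray | None = None,
    alpha: float = 0.05,
) -> IndividualEstimate:
    """MAP estimate of one subject's random effects given a population.

    Minimizes ½·V(p(η)) + Σ_p η_p²/(2ω_p²); the goodness of fit is then
    evaluated from the implied parameters on the fitted observations.
    """
    if dose is None:
        dose = DoseProtocol(body_weight=patient.body_weight)
    obs = ObservationSet(patient, config)
    eta, fval = _minimize_map(obs, pop, constants, dose, eta0)
    params = pop.params_from_eta(eta)
    gof = gof_test(obs.chi2(params, constants, dose), obs.n_obs, alpha)
    return IndividualEstimate(
        patient_id=patient.patient_id,
        eta=eta,
        params=params,
        map_objective=fval,
        gof=gof,
    )


@dataclass
class PopulationFit:
    """Outcome of the alternating population estimation."""

    population: PopulationModel
    estimates: list[IndividualEstimate]
    objective_trace: list[float]
    n_iter: int
    converged: bool


def fit_population(
    cohort: Cohort,
    init: PopulationModel | None = None,
    constants: PhysiologicalConstants = PhysiologicalConstants(),
    doses: dict[str, DoseProtocol] | None = None,
    config: UncertaintyConfig = UncertaintyConfig(),
    tol: float = 1e-4,
    max_iter: int = 200,
    freeze_population: bool = False,
    warm_etas: dict[str, np.ndarray] | None = None,
    alpha: float = 0.05,
) -> PopulationFit:
    """Alternating MAP/moment estimation of (θ, ω) and all random effects.

    Iterates an E-like step (per-subject MAP η) and an M-like step
    (re-center θ, set ω to the SD of the η) until the maximum relative
    change in (θ, ω) drops below ``tol`` or ``max_iter`` is reached; in the
    latter case the best iterate is returned flagged unconverged.  With
    ``freeze_population`` the (θ, ω) stay at their initial values and only
    the MAP step runs.
    """
    if len(cohort) < 2 and not freeze_population:
        raise ValidationError("population estimation needs at least 2 patients")
    pop = init if init is not None else default_population()
    obs_sets = {p.patient_id: ObservationSet(p, config) for p in cohort}
    dose_map = {p.patient_id: _dose_for(p, doses) for p in cohort}
    etas = {
        p.patient_id: (
            np.array(warm_etas[p.patient_id], dtype=float)
            if warm_etas and p.patient_id in warm_etas
            else np.zeros(5)
        )
        for p in cohort
    }
    trace: list[float] = []
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        # E-like step: subject-level MAP random effects + Laplace variances
        omegas = pop.omegas()
        free = omegas > OMEGA_FLOOR
        total = 0.0
        post_var = np.zeros((len(cohort), 5))
        for j, p in enumerate(cohort):
            obs = obs_sets[p.patient_id]
            dose = dose_map[p.patient_id]
            eta, fval = _minimize_map(obs, pop, constants, dose,
                                      eta0=etas[p.patient_id])
            etas[p.patient_id] = eta
            total += fval
            if not freeze_population:
                objective, free_j = _map_objective_factory(obs, pop, constants, dose)
                post_var[j, free_j] = _posterior_variance(
                    objective, eta[free_j], omegas[free_j]
                )
        total += len(cohort) * float(np.sum(np.log(np.maximum(omegas, OMEGA_FLOOR))))
        trace.append(total)
        if freeze_population:
            converged = True
            break

        # M-like step: re-center theta on the MAP effects; EM omega update
        # with the Laplace posterior-variance term (the plain SD of the MAP
        # etas ratchets omega toward zero because MAP estimates are shrunk)
        E = np.array([etas[p.patient_id] for p in cohort])  # (n, 5)
        mean_eta = E.mean(axis=0)
        spread = np.mean((E - mean_eta) ** 2, axis=0)
        if np.any(free) and np.all(spread[free] < 1e-16):
            # all subjects share one optimum: the population MLE is that
            # common unpenalized optimum with zero between-subject variance
            first = cohort.patients[0]
            wide = pop.with_values(pop.thetas(), np.where(free, 1e3, 0.0))
            eta_opt, _ = _minimize_map(
                obs_sets[first.patient_id], wide, constants,
                dose_map[first.patient_id], eta0=etas[first.patient_id],
            )
            thetas = pop.thetas().copy()
            for k, d in enumerate(pop.distributions):
                if d.family == "normal":
                    thetas[k] = d.theta + eta_opt[k]
                else:
                    thetas[k] = d.theta * np.exp(eta_opt[k])
            pop = pop.with_values(thetas, np.zeros(5))
            for pid in etas:
                etas[pid] = np.zeros(5)
            converged = True
            break
        thetas = pop.thetas().copy()
        for k, d in enumerate(pop.distributions):
            if d.family == "normal":
                thetas[k] = d.theta + mean_eta[k]
            else:
                thetas[k] = d.theta * np.exp(mean_eta[k])
        E = E - mean_eta  # individual parameters unchanged by re-centering
        second_moment = np.mean(E * E, axis=0)
        new_omegas = np.sqrt(second_moment + np.mean(post_var, axis=0))
        # zero observed between-subject variation: once theta has absorbed
        # the common shift, the population is degenerate along that axis
        degenerate = second_moment < 1e-16
        collapse = degenerate & (np.abs(mean_eta) < 1e-8)
        new_omegas[degenerate] = omegas[degenerate]  # let re-centering finish
        new_omegas[collapse] = 0.0
        new_omegas[~free] = 0.0
        for pid in etas:
            etas[pid] = etas[pid] - mean_eta

        old = np.concatenate([pop.thetas(), pop.omegas()])
        new = np.concatenate([thetas, new_omegas])
        rel = np.abs(new - old) / np.maximum(np.abs(old), 1e-12)
        pop = pop.with_values(thetas, new_omegas)
        if float(rel.max()) < tol:
            converged = True
            break
    if not converged:
        log.warning("fit_population: max_iter=%d reached without tol=%g", max_iter, tol)

    estimates = []
    for p in cohort:
        obs = obs_sets[p.patient_id]
        eta = etas[p.patient_id]
        params = pop.params_from_eta(eta)
        objective, free = _map_objective_factory(obs, pop, constants, dose_map[p.patient_id])
        fval = float(objective(eta[free]))
        gof = gof_test(obs.chi2(params, constants, dose_map[p.patient_id]), obs.n_obs, alpha)
        estimates.append(
            IndividualEstimate(p.patient_id, eta, params, fval, gof)
        )
    return PopulationFit(pop, estimates, trace, n_iter, converged)


def leave_one_out_truncated_fit(
    cohort: Cohort,
    target_patient_id: str,
    cutoff_s: float = 600.0,
    constants: PhysiologicalConstants = PhysiologicalConstants(),
    doses: dict[str, DoseProtocol] | None = None,
    config: UncertaintyConfig = UncertaintyConfig(),
    init: PopulationModel | None = None,
    warm: PopulationFit | None = None,
    tol: float = 1e-4,
    max_iter: int = 3,
) -> IndividualEstimate:
    """Truncated-data NLME estimate in a leave-one-out design.

    One subject's series is truncated at ``cutoff_s`` (inclusive) while all
    other subjects keep their complete series; the population is fitted on
    that modified cohort and the target's MAP estimate — obtained from its
    ≤cutoff observations only — is returned.  This mimics deploying a
    short protocol on a new patient when population distributions are
    already established.

    ``warm`` (a previous full-data fit) seeds the population and the
    random effects, which shortens the re-fit considerably.
    """
    target = cohort.get(target_patient_id)
    usable = target.times >= FIT_TIME_MIN
    if not np.any(usable & (target.times <= cutoff_s)):
        raise InsufficientDataError(
            f"patient {target_patient_id}: no usable observation in "
            f"[{FIT_TIME_MIN:g}, {cutoff_s:g}] s"
        )
    if np.isfinite(cutoff_s) and not np.any(target.times > cutoff_s):
        raise InsufficientDataError(
            f"patient {target_patient_id}: no observation after {cutoff_s:g} s"
        )
    if not np.any(target.times > cutoff_s):  # nothing truncated: identity case
        if warm is not None:
            for est in warm.estimates:
                if est.patient_id == target_patient_id:
                    return est
    patients = [
        p.restrict(p.times <= cutoff_s) if p.patient_id == target_patient_id else p
        for p in cohort
    ]
    modified = Cohort(patients, provenance=cohort.provenance)
    fit = fit_population(
        modified,
        init=warm.population if warm is not None else init,
        constants=constants,
        doses=doses,
        config=config,
        tol=tol,
        max_iter=max_iter,
        warm_etas={e.patient_id: e.eta for e in warm.estimates} if warm is not None else None,
    )
    for est in fit.estimates:
        if est.patient_id == target_patient_id:
            return est
    raise KeyError(target_patient_id)  # pragma: no cover
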