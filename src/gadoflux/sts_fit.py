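"""Standard-two-stage (STS) per-patient fitting and χ² goodness of fit.

Each subject is fitted independently by minimizing the weighted
least-squares cost

    V(p) = Σ_i Σ_t (ŷ_i(t) − y_i(t))² / σ_i(t)²,   i ∈ {liver, spleen},

where σ is the effective per-timepoint standard deviation (ROI SEM floored
at the cohort uncertainty limit).  Under a correct model with Gaussian
noise the cost follows a χ² distribution, which yields a per-patient
goodness-of-fit test with degrees of freedom equal to the number of
observations entering the cost.

Only observations at 3 min (180 s) or later after injection are fitted:
earlier acquisitions fall in the arterial/portal-venous wash-in phases
where the well-mixed compartment assumption does not hold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.stats import chi2 as chi2_dist

from .cohort_io import PatientRecord
from .core_model import (
    DoseProtocol,
    PhysiologicalConstants,
    RateParameters,
    predict_delta_r1,
    simulate,
)
from .errors import ConvergenceError, InsufficientDataError, ValidationError
from .uncertainty import UncertaintyConfig, effective_sigma

#: observations before this time (s) are excluded from all fitting
FIT_TIME_MIN = 180.0

#: minimum allowed value of the signal scale ξ during optimization
XI_LOWER_BOUND = 1e-6

_LOG_RATE_BOUNDS = (-25.0, 3.0)


@dataclass(frozen=True)
class GofResult:
    """χ² goodness-of-fit outcome for one subject."""

    chi2: float
    df: int
    critical_value: float
    passed: bool


@dataclass(frozen=True)
class FitResult:
    """Converged parameter estimate for one subject."""

    params: RateParameters
    gof: GofResult
    n_obs_liver: int
    n_obs_spleen: int
    converged: bool
    method: str  # "STS" or "NLME"


@dataclass(frozen=True)
class OptimizerSettings:
    """Multi-start simplex + gradient-polish settings for the STS stage."""

    n_starts: int = 10
    seed: int = 0
    jitter_sd: float = 0.7      # log-scale SD of the multi-start jitter
    nm_maxiter: int = 800
    polish: bool = True
    freeze: tuple[str, ...] = ()  # parameter names held at their start value


class ObservationSet:
    """Fitted observations of one patient, with effective σ precomputed.

    Caches the simulation grid so repeated cost evaluations during
    optimization avoid re-validating inputs.
    """

    def __init__(
        self,
        patient: PatientRecord,
        config: UncertaintyConfig = UncertaintyConfig(),
        t_min: float = FIT_TIME_MIN,
    ):
        mask = patient.times >= t_min
        if not np.any(mask):
            raise InsufficientDataError(
                f"patient {patient.patient_id}: no usable observations at "
                f"t >= {t_min:g} s"
            )
        self.patient_id = patient.patient_id
        self.times = patient.times[mask]
        self.y_liver = patient.liver_dr1[mask]
        self.y_spleen = patient.spleen_dr1[mask]
        self.sigma_liver = effective_sigma(patient.liver_sem[mask], config)
        self.sigma_spleen = effective_sigma(patient.spleen_sem[mask], config)

    @property
    def n_obs(self) -> int:
        return 2 * self.times.size

    def predict(
        self,
        params: RateParameters,
        constants: PhysiologicalConstants,
        dose: DoseProtocol,
    ) -> tuple[np.ndarray, np.ndarray]:
        traj = simulate(params, constants, dose, self.times)
        return predict_delta_r1(traj, params, constants)

    def chi2(
        self,
        params: RateParameters,
        constants: PhysiologicalConstants,
        dose: DoseProtocol,
    ) -> float:
        liver, spleen = self.predict(params, constants, dose)
        return float(
            np.sum(((liver - self.y_liver) / self.sigma_liver) ** 2)
            + np.sum(((spleen - self.y_spleen) / self.sigma_spleen) ** 2)
        )


def chi2_cost(
    params: RateParameters,
    patient: PatientRecord,
    constants: PhysiologicalConstants,
    dose: DoseProtocol,
    config: UncertaintyConfig = UncertaintyConfig(),
) -> float:
    """Weighted least-squares cost V(p) over the usable (t >= 3 min) data."""
    return ObservationSet(patient, config).chi2(params, constants, dose)


def gof_test(chi2: float, df: int, alpha: float = 0.05) -> GofResult:
    """χ² goodness-of-fit test at significance level ``alpha``.

    ``df`` is the number of observations in the fitted time series.  The
    fit passes when the cost does not exceed the (1 − alpha) quantile.
    """
    if df < 1:
        raise ValidationError(f"df must be >= 1, got {df}")
    critical = float(chi2_dist.ppf(1.0 - alpha, df))
    return GofResult(chi2=float(chi2), df=int(df), critical_value=critical,
                     passed=bool(chi2 <= critical))


# ---------------------------------------------------------------------------
# optimization internals

def _pack(params: RateParameters) -> np.ndarray:
    """(log k_diff, log k_ph, log k_hp, log k_hb, ξ) optimizer vector."""
    tiny = 1e-12
    return np.array(
        [
            np.log(max(params.k_diff, tiny)),
            np.log(max(params.k_ph, tiny)),
            np.log(max(params.k_hp, tiny)),
            np.log(max(params.k_hb, tiny)),
            params.xi,
        ]
    )


def _unpack(z: np.ndarray) -> RateParameters:
    return RateParameters(
        k_diff=float(np.exp(z[0])),
        k_ph=float(np.exp(z[1])),
        k_hp=float(np.exp(z[2])),
        k_hb=float(np.exp(z[3])),
        xi=float(max(z[4], XI_LOWER_BOUND)),
    )


_FREEZE_INDEX = {"k_diff": 0, "k_ph": 1, "k_hp": 2, "k_hb": 3, "xi": 4}


def minimize_chi2(
    obs: ObservationSet,
    constants: PhysiologicalConstants,
    dose: DoseProtocol,
    start: RateParameters,
    settings: OptimizerSettings = OptimizerSettings(),
) -> tuple[RateParameters, float, bool]:
    """Multi-start Nelder–Mead with an L-BFGS-B polish on the best optimum.

    The four rates are optimized as log-values (positivity by construction);
    ξ is optimized on its natural scale with a small positive lower bound.
    Returns (best parameters, best cost, converged flag).
    """
    rng = np.random.default_rng(settings.seed)
    z0 = _pack(start)
    free = np.array([i for i in range(5) if _FREEZE_INDEX_INV[i] not in settings.freeze])
    if free.size == 0:
        raise ValidationError("cannot freeze all parameters")

    def objective(zf: np.ndarray) -> float:
        z = z0.copy()
        z[free] = zf
        try:
            return obs.chi2(_unpack(z), constants, dose)
        except (ValidationError, FloatingPointError):
            return np.inf

    lo = np.array([_LOG_RATE_BOUNDS[0]] * 4 + [XI_LOWER_BOUND])
    hi = np.array([_LOG_RATE_BOUNDS[1]] * 4 + [50.0])
    bounds = list(zip(lo[free], hi[free]))

    starts = [z0[free]]
    for _ in range(settings.n_starts - 1):
        jitter = rng.normal(0.0, settings.jitter_sd, size=5)
        zj = z0 + jitter
        zj[4] = max(start.xi * np.exp(0.5 * jitter[4]), XI_LOWER_BOUND)
        starts.append(np.clip(zj, lo, hi)[free])

    best_z, best_f, any_success = None, np.inf, False
    for s in starts:
        res = minimize(
            objective,
            s,
            method="Nelder-Mead",
            bounds=bounds,
            options={"maxiter": settings.nm_maxiter, "xatol": 1e-8, "fatol": 1e-10},
        )
        if np.isfinite(res.fun) and res.fun < best_f:
            best_z, best_f = res.x, res.fun
            any_success = any_success or res.success
    if best_z is None:
        raise ConvergenceError(
            f"patient {obs.patient_id}: all {settings.n_starts} starts produced "
            "non-finite costs"
        )
    if settings.polish:
        res = minimize(objective, best_z, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": 500, "ftol": 1e-14, "gtol": 1e-10})
        if np.isfinite(res.fun) and res.fun <= best_f:
            best_z, best_f = res.x, res.fun
            any_success = True
        # simplex re-start from the polished point tightens flat directions
        res = minimize(objective, best_z, method="Nelder-Mead", bounds=bounds,
                       options={"maxiter": settings.nm_maxiter,
                                "xatol": 1e-10, "fatol": 1e-12})
        if np.isfinite(res.fun) and res.fun <= best_f:
            best_z, best_f = res.x, res.fun
    z = z0.copy()
    z[free] = best_z
    return _unpack(z), float(best_f), bool(any_success)


_FREEZE_INDEX_INV = {v: k for k, v in _FREEZE_INDEX.items()}


def fit_sts(
    patient: PatientRecord,
    constants: PhysiologicalConstants = PhysiologicalConstants(),
    dose: DoseProtocol | None = None,
    config: UncertaintyConfig = UncertaintyConfig(),
    settings: OptimizerSettings = OptimizerSettings(),
    start: RateParameters | None = None,
    alpha: float = 0.05,
) -> FitResult:
    """Fit one subject by χ² minimization and attach its goodness of fit.

    Multi-start initial points are centered on the healthy-population
    typical values unless ``start`` overrides them.  Degrees of freedom of
    the test equal the number of fitted observations.
    """
    if dose is None:
        dose = DoseProtocol(body_weight=patient.body_weight)
    obs = ObservationSet(patient, config)
    if np.all(obs.y_liver == 0) and np.all(obs.y_spleen == 0):
        raise ConvergenceError(
            f"patient {patient.patient_id}: all observations are zero; "
            "the signal scale ξ is unidentifiable"
        )
    if start is None:
        from .nlme_fit import default_population

        start = default_population().typical_params()
    params, cost, converged = minimize_chi2(obs, constants, dose, start, settings)
    gof = gof_test(cost, obs.n_obs, alpha)
    n = obs.times.size
    return FitResult(params=params, gof=gof, n_obs_liver=n, n_obs_spleen=n,
                     converged=converged, method="STS")
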