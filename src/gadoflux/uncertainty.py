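"""Measurement-uncertainty model for the ΔR1 time series.

MRI signal intensities carry no absolute scale, so per-timepoint noise is
estimated from the normalized signal S = SI(t)/SI(0) by standard error
propagation, averaged within each subject and then across the cohort to
give a lower limit on the data uncertainty.  During model fitting the
per-timepoint standard deviation is the ROI SEM, floored at that cohort
lower limit (default 0.18 on the ΔR1 scale).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

#: cohort-level lower limit of the data uncertainty
DEFAULT_SIGMA_FLOOR = 0.18


@dataclass(frozen=True)
class UncertaintyConfig:
    """Effective-σ rule: σ = max(SEM, sigma_floor) when the flag is set,
    otherwise σ = sigma_floor everywhere."""

    sigma_floor: float = DEFAULT_SIGMA_FLOOR
    use_sem_when_larger: bool = True

    def __post_init__(self) -> None:
        if self.sigma_floor <= 0:
            raise ValidationError("sigma_floor must be > 0")


def normalized_si_uncertainty(si_t, si_0, sigma_si_t, sigma_si_0):
    """Propagated standard deviation of the normalized signal S = SI(t)/SI(0).

    σ_S = |SI(t)/SI(0)| · sqrt((σ_SI(t)/SI(t))² + (σ_SI(0)/SI(0))²)

    Accepts scalars or broadcastable arrays.
    """
    si_t = np.asarray(si_t, dtype=float)
    si_0 = np.asarray(si_0, dtype=float)
    if np.any(si_0 == 0):
        raise ZeroDivisionError("baseline signal intensity SI(0) must be non-zero")
    if np.any(si_t == 0):
        raise ZeroDivisionError("signal intensity SI(t) must be non-zero")
    s = si_t / si_0
    out = np.abs(s) * np.sqrt(
        (np.asarray(sigma_si_t, dtype=float) / si_t) ** 2
        + (np.asarray(sigma_si_0, dtype=float) / si_0) ** 2
    )
    return float(out) if out.ndim == 0 else out


def cohort_lower_limit(per_patient_mean_sigmas) -> float:
    """Cohort lower limit of uncertainty: the mean of per-patient mean σ.

    Each entry is one subject's average σ over its liver and spleen ROIs;
    the cohort estimate is their arithmetic mean (the location of a normal
    distribution fitted to the histogram).
    """
    arr = np.asarray(per_patient_mean_sigmas, dtype=float)
    if arr.size == 0:
        raise ValidationError("need at least one per-patient σ")
    return float(np.mean(arr))


def effective_sigma(sem, config: UncertaintyConfig = UncertaintyConfig()):
    """Per-timepoint σ used in every χ² computation.

    The ROI SEM is used when it exceeds the cohort floor; otherwise the
    floor itself is the standard deviation.
    """
    arr = np.asarray(sem, dtype=float)
    if np.any(arr < 0):
        raise ValidationError("SEM values must be >= 0")
    if config.use_sem_when_larger:
        out = np.maximum(arr, config.sigma_floor)
    else:
        out = np.full_like(arr, config.sigma_floor)
    return float(out) if out.ndim == 0 else out
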