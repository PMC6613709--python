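"""Evaluation stages: protocol truncation, concordance, fibrosis analysis.

Four study questions are wired here:

1. Can the model describe each subject's full time series (per-patient χ²
   goodness of fit)?
2. Can a 10-minute protocol replace the 30-minute one?  Each subject's
   series is split into estimation data (3–10 min) and validation data
   (>10 min); the model is fitted on the estimation part by STS or by NLME
   (leave-one-out truncation) and judged by a separate χ² test on each part.
3. Do model predictions agree with gadolinium concentrations measured in
   blood and biopsy samples (Lin's concordance correlation)?
4. Does hepatocyte uptake (k_ph) track histological fibrosis stage, and
   can a k_ph cut-off flag advanced fibrosis (≥F3)?
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .cohort_io import Cohort, PatientRecord
from .core_model import (
    DoseProtocol,
    PhysiologicalConstants,
    RateParameters,
    blood_concentration,
    liver_tissue_concentration,
    simulate,
)
from .errors import InsufficientDataError, ValidationError
from .nlme_fit import (
    IndividualEstimate,
    PopulationFit,
    PopulationModel,
    fit_population,
    leave_one_out_truncated_fit,
)
from .sts_fit import (
    FIT_TIME_MIN,
    FitResult,
    GofResult,
    ObservationSet,
    OptimizerSettings,
    fit_sts,
    gof_test,
)
from .uncertainty import UncertaintyConfig

log = logging.getLogger(__name__)

#: default estimation/validation cutoff: 10 min after injection
DEFAULT_CUTOFF_S = 600.0

#: k_ph cut-off (s⁻¹) for the advanced-fibrosis classifier
DEFAULT_KPH_CUTOFF = 0.00198

ADVANCED_STAGES = ("F3", "F4")


@dataclass(frozen=True)
class SplitDataset:
    """Estimation (3–10 min) / validation (>10 min) partition of a record."""

    estimation: PatientRecord
    validation: PatientRecord | None
    insufficient: bool  # True when there is no validation data


def split_at_cutoff(patient: PatientRecord, cutoff_s: float = DEFAULT_CUTOFF_S) -> SplitDataset:
    """Partition the usable observations at the protocol cutoff (inclusive)."""
    usable = patient.times >= FIT_TIME_MIN
    est_mask = usable & (patient.times <= cutoff_s)
    val_mask = usable & (patient.times > cutoff_s)
    if not np.any(est_mask):
        raise InsufficientDataError(
            f"patient {patient.patient_id}: no estimation data in "
            f"[{FIT_TIME_MIN:g}, {cutoff_s:g}] s"
        )
    validation = patient.restrict(val_mask) if np.any(val_mask) else None
    return SplitDataset(
        estimation=patient.restrict(est_mask),
        validation=validation,
        insufficient=validation is None,
    )


@dataclass
class TruncationRow:
    """Per-patient outcome of the truncation experiment."""

    patient_id: str
    fibrosis_stage: str
    method: str
    params: RateParameters | None
    estimation_gof: GofResult | None
    validation_gof: GofResult | None
    error: str | None = None


@dataclass
class TruncationReport:
    rows: list[TruncationRow]
    n_eligible: int
    n_insufficient: int

    @property
    def estimation_pass(self) -> int:
        return sum(1 for r in self.rows if r.estimation_gof and r.estimation_gof.passed)

    @property
    def validation_pass(self) -> int:
        return sum(1 for r in self.rows if r.validation_gof and r.validation_gof.passed)

    def validation_pass_fraction(self) -> float:
        n = sum(1 for r in self.rows if r.validation_gof is not None)
        if n == 0:
            raise ValidationError("no patient produced a validation GOF")
        return self.validation_pass / n


def _subset_gof(
    record: PatientRecord,
    params: RateParameters,
    constants: PhysiologicalConstants,
    dose: DoseProtocol,
    config: UncertaintyConfig,
    alpha: float,
) -> GofResult:
    obs = ObservationSet(record, config)
    return gof_test(obs.chi2(params, constants, dose), obs.n_obs, alpha)


def truncation_experiment(
    cohort: Cohort,
    method: str,
    constants: PhysiologicalConstants = PhysiologicalConstants(),
    doses: dict[str, DoseProtocol] | None = None,
    config: UncertaintyConfig = UncertaintyConfig(),
    cutoff_s: float = DEFAULT_CUTOFF_S,
    settings: OptimizerSettings = OptimizerSettings(),
    population_init: PopulationModel | None = None,
    warm_fit: PopulationFit | None = None,
    population_max_iter: int = 25,
    alpha: float = 0.05,
) -> TruncationReport:
    """Fit each subject on ≤cutoff data, judge GOF on both data subsets.

    ``method`` is "STS" (independent per-patient fit on the truncated
    series) or "NLME" (leave-one-out truncated population fit).  Patients
    without post-cutoff data are flagged and skipped; per-patient fit
    failures are recorded as flagged rows, never abort the cohort.  For the
    NLME arm a full-data population fit (``warm_fit``, computed on demand
    when absent) warm-starts every leave-one-out re-fit.
    """
    method = method.upper()
    if method not in ("STS", "NLME"):
        raise ValidationError(f"method must be STS or NLME, got {method!r}")
    if method == "NLME" and warm_fit is None:
        warm_fit = fit_population(
            cohort, init=population_init, constants=constants, doses=doses,
            config=config, max_iter=population_max_iter,
        )
    rows: list[TruncationRow] = []
    n_insufficient = 0
    for patient in cohort:
        dose = doses.get(patient.patient_id) if doses else None
        if dose is None:
            dose = DoseProtocol(body_weight=patient.body_weight)
        try:
            split = split_at_cutoff(patient, cutoff_s)
        except InsufficientDataError as exc:
            rows.append(TruncationRow(patient.patient_id, patient.fibrosis_stage,
                                      method, None, None, None, error=str(exc)))
            n_insufficient += 1
            continue
        if split.insufficient and np.isfinite(cutoff_s):
            n_insufficient += 1
            rows.append(TruncationRow(patient.patient_id, patient.fibrosis_stage,
                                      method, None, None, None,
                                      error="no validation data after cutoff"))
            continue
        try:
            if method == "STS":
                fit = fit_sts(split.estimation, constants, dose, config, settings)
                params = fit.params
            else:
                est = leave_one_out_truncated_fit(
                    cohort, patient.patient_id, cutoff_s, constants, doses, config,
                    init=population_init, warm=warm_fit,
                )
                params = est.params
        except Exception as exc:
            log.warning("truncation fit failed for %s: %s", patient.patient_id, exc)
            rows.append(TruncationRow(patient.patient_id, patient.fibrosis_stage,
                                      method, None, None, None, error=str(exc)))
            continue
        est_gof = _subset_gof(split.estimation, params, constants, dose, config, alpha)
        val_gof = (
            _subset_gof(split.validation, params, constants, dose, config, alpha)
            if split.validation is not None
            else None
        )
        rows.append(TruncationRow(patient.patient_id, patient.fibrosis_stage,
                                  method, params, est_gof, val_gof))
    n_eligible = sum(1 for r in rows if r.error is None)
    return TruncationReport(rows, n_eligible, n_insufficient)


# ---------------------------------------------------------------------------
# agreement statistics

def lins_ccc(x, y) -> float:
    """Lin's concordance correlation coefficient r_c.

    r_c = 2·s_xy / (s_x² + s_y² + (x̄ − ȳ)²) with population
    (n-denominator) moments.  Penalizes both dispersion and location shift,
    so r_c = 1 iff y = x elementwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValidationError("lins_ccc needs two equal-length vectors of size >= 2")
    mx, my = x.mean(), y.mean()
    sx2 = np.mean((x - mx) ** 2)
    sy2 = np.mean((y - my) ** 2)
    sxy = np.mean((x - mx) * (y - my))
    denom = sx2 + sy2 + (mx - my) ** 2
    if denom == 0:
        raise ValidationError("lins_ccc undefined: zero variance and equal means")
    return float(2.0 * sxy / denom)


def pearson_r(x, y) -> float:
    return float(stats.pearsonr(np.asarray(x, float), np.asarray(y, float))[0])


def predict_sample_concentrations(
    fit,
    t_sample: float = 1800.0,
    constants: PhysiologicalConstants = PhysiologicalConstants(),
    dose: DoseProtocol | None = None,
    hematocrit: float = 0.45,
) -> tuple[float, float]:
    """Model-predicted (whole-blood mM, liver wet-tissue mM) at sample time.

    ``fit`` may be a :class:`RateParameters`, a :class:`FitResult` or an
    :class:`IndividualEstimate`.  The default sample time is 30 min —
    immediately after the imaging protocol, when blood draw and biopsy are
    taken.
    """
    params = getattr(fit, "params", fit)
    if not isinstance(params, RateParameters):
        raise ValidationError("fit must carry RateParameters")
    if dose is None:
        raise ValidationError("a dose protocol is required")
    if t_sample <= dose.t_injection_start:
        raise ValidationError(
            f"t_sample={t_sample} s is not after the injection start"
        )
    traj = simulate(params, constants, dose, np.array([t_sample]))
    blood = blood_concentration(traj, t_sample, hematocrit)
    tissue = liver_tissue_concentration(traj, constants, t_sample)
    return blood, tissue


# ---------------------------------------------------------------------------
# fibrosis-stage group analysis and classifier

STAGE_ORDER = ("F0", "F1", "F2", "F3", "F4")


def fibrosis_group_analysis(
    estimates: pd.DataFrame,
    parameters: tuple[str, ...] = ("k_diff", "k_ph", "k_hp", "k_hb", "xi"),
    min_group_size: int = 2,
) -> dict[str, dict]:
    """Per-parameter fibrosis-stage statistics.

    ``estimates`` needs one row per patient with a ``fibrosis_stage``
    column plus one column per parameter.  For each parameter the result
    carries stage means and SEMs, a one-way ANOVA (F, p) and Tukey HSD
    pairwise adjusted p-values across stages with at least
    ``min_group_size`` patients; undersized or unknown-stage groups are
    skipped with a warning.
    """
    if "fibrosis_stage" not in estimates.columns:
        raise ValidationError("estimates must have a fibrosis_stage column")
    staged = estimates[estimates["fibrosis_stage"].isin(STAGE_ORDER)]
    sizes = staged["fibrosis_stage"].value_counts()
    kept = [s for s in STAGE_ORDER if sizes.get(s, 0) >= min_group_size]
    dropped = [s for s in STAGE_ORDER if 0 < sizes.get(s, 0) < min_group_size]
    if dropped:
        log.warning("fibrosis groups skipped (fewer than %d patients): %s",
                    min_group_size, dropped)
    if len(kept) < 2:
        raise ValidationError("need >= 2 fibrosis groups with enough patients")
    data = staged[staged["fibrosis_stage"].isin(kept)]
    out: dict[str, dict] = {}
    for param in parameters:
        groups = [data.loc[data["fibrosis_stage"] == s, param].to_numpy(float)
                  for s in kept]
        means = {s: float(np.mean(g)) for s, g in zip(kept, groups)}
        sems = {s: float(stats.sem(g)) if g.size > 1 else float("nan")
                for s, g in zip(kept, groups)}
        values = np.concatenate(groups)
        if np.ptp(values) == 0:  # identical values: no variation to test
            anova_f, anova_p = 0.0, 1.0
            tukey = None
        else:
            anova_f, anova_p = stats.f_oneway(*groups)
            labels = np.concatenate([[s] * g.size for s, g in zip(kept, groups)])
            res = pairwise_tukeyhsd(values, labels, alpha=0.05)
            tukey = pd.DataFrame(
                res.summary().data[1:], columns=res.summary().data[0]
            )
        out[param] = {
            "stages": kept,
            "group_means": means,
            "group_sems": sems,
            "anova_F": float(anova_f),
            "anova_p": float(anova_p),
            "tukey": tukey,
        }
    return out


def mann_whitney_groups(x, y) -> tuple[float, float]:
    """Unpaired two-tailed Mann–Whitney U test between two groups."""
    u, p = stats.mannwhitneyu(np.asarray(x, float), np.asarray(y, float),
                              alternative="two-sided")
    return float(u), float(p)


def paired_method_comparison(a, b) -> tuple[float, float]:
    """Paired two-tailed comparison of two estimation methods.

    Implemented as the Wilcoxon signed-rank test, the standard paired
    counterpart of the Mann–Whitney test.
    """
    w, p = stats.wilcoxon(np.asarray(a, float), np.asarray(b, float))
    return float(w), float(p)


@dataclass(frozen=True)
class ConfusionMatrix:
    """2×2 patient counts for the advanced-fibrosis classifier."""

    tn: int
    fp: int
    fn: int
    tp: int

    def __post_init__(self) -> None:
        if min(self.tn, self.fp, self.fn, self.tp) < 0:
            raise ValidationError("confusion-matrix cells must be >= 0")

    @property
    def total(self) -> int:
        return self.tn + self.fp + self.fn + self.tp

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if (self.tn + self.fp) else float("nan")


def advanced_fibrosis_confusion(
    estimates: pd.DataFrame,
    cutoff: float = DEFAULT_KPH_CUTOFF,
) -> ConfusionMatrix:
    """Classify advanced fibrosis (≥F3) from the hepatocyte uptake rate.

    Predicted advanced ⇔ k_ph < cutoff: uptake falls with worsening
    fibrosis, so low uptake flags advanced disease.  Patients without a
    known stage are excluded with a warning.
    """
    if not {"k_ph", "fibrosis_stage"}.issubset(estimates.columns):
        raise ValidationError("estimates must have k_ph and fibrosis_stage columns")
    staged = estimates[estimates["fibrosis_stage"].isin(STAGE_ORDER)]
    n_dropped = len(estimates) - len(staged)
    if n_dropped:
        log.warning("advanced_fibrosis_confusion: %d unstaged patients excluded",
                    n_dropped)
    kph = staged["k_ph"].to_numpy(float)
    truth = staged["fibrosis_stage"].isin(ADVANCED_STAGES).to_numpy()
    pred = kph < cutoff
    return ConfusionMatrix(
        tn=int(np.sum(~truth & ~pred)),
        fp=int(np.sum(~truth & pred)),
        fn=int(np.sum(truth & ~pred)),
        tp=int(np.sum(truth & pred)),
    )
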