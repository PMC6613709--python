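"""Patient time-series I/O: CSV/JSON cohorts, MAT reader, results writer.

A cohort is a list of per-patient ΔR1 time series (liver and spleen ROI
means with their SEMs), body weight and an optional histological fibrosis
stage (Batts–Ludwig F0–F4).  Times are stored in seconds relative to the
start of the contrast injection; an optional pre-injection baseline row is
encoded with a negative time and ΔR1 = 0.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import loadmat

from .errors import FormatError, ValidationError

log = logging.getLogger(__name__)

FIBROSIS_STAGES = ("F0", "F1", "F2", "F3", "F4", "unknown")

#: numeric stage codes used in MAT files -> stage labels
STAGE_CODE_MAP = {0: "F0", 1: "F1", 2: "F2", 3: "F3", 4: "F4"}


@dataclass
class PatientRecord:
    """One subject's liver/spleen ΔR1 time series.

    ``times`` are seconds since injection start (strictly increasing; at
    most one pre-injection point, which must have ΔR1 = 0 in both
    tissues).  ``liver_sem``/``spleen_sem`` are the per-timepoint standard
    errors of the mean across the ROIs.
    """

    patient_id: str
    times: np.ndarray
    liver_dr1: np.ndarray
    liver_sem: np.ndarray
    spleen_dr1: np.ndarray
    spleen_sem: np.ndarray
    body_weight: float = 70.0
    fibrosis_stage: str = "unknown"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        for name in ("liver_dr1", "liver_sem", "spleen_dr1", "spleen_sem"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape != self.times.shape:
                raise ValidationError(
                    f"patient {self.patient_id}: {name} length {arr.size} "
                    f"!= times length {self.times.size}"
                )
        if self.times.ndim != 1 or self.times.size == 0:
            raise ValidationError(f"patient {self.patient_id}: empty time series")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError(
                f"patient {self.patient_id}: times must be strictly increasing"
            )
        for name in ("liver_sem", "spleen_sem"):
            if np.any(getattr(self, name) < 0):
                raise ValidationError(
                    f"patient {self.patient_id}: {name} contains negative values"
                )
        pre = self.times < 0
        if pre.sum() > 1:
            raise ValidationError(
                f"patient {self.patient_id}: at most one pre-injection time allowed"
            )
        if pre.any() and (
            np.any(self.liver_dr1[pre] != 0) or np.any(self.spleen_dr1[pre] != 0)
        ):
            raise ValidationError(
                f"patient {self.patient_id}: pre-injection ΔR1 must be 0"
            )
        if self.body_weight <= 0:
            raise ValidationError(f"patient {self.patient_id}: body_weight must be > 0")
        if self.fibrosis_stage not in FIBROSIS_STAGES:
            raise ValidationError(
                f"patient {self.patient_id}: fibrosis_stage must be one of "
                f"{FIBROSIS_STAGES}, got {self.fibrosis_stage!r}"
            )

    def restrict(self, mask: np.ndarray, suffix: str = "") -> "PatientRecord":
        """A copy keeping only the time points selected by ``mask``."""
        return PatientRecord(
            patient_id=self.patient_id + suffix,
            times=self.times[mask],
            liver_dr1=self.liver_dr1[mask],
            liver_sem=self.liver_sem[mask],
            spleen_dr1=self.spleen_dr1[mask],
            spleen_sem=self.spleen_sem[mask],
            body_weight=self.body_weight,
            fibrosis_stage=self.fibrosis_stage,
        )


@dataclass
class Cohort:
    """A validated, non-empty collection of patient records."""

    patients: list[PatientRecord]
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.patients:
            raise ValidationError("cohort must contain at least one patient")
        ids = [p.patient_id for p in self.patients]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate patient ids: {dupes}")

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self):
        return iter(self.patients)

    def get(self, patient_id: str) -> PatientRecord:
        for p in self.patients:
            if p.patient_id == patient_id:
                return p
        raise KeyError(patient_id)


# ---------------------------------------------------------------------------
# CSV (long format) and JSON readers/writers

CSV_COLUMNS = [
    "patient_id",
    "time_s",
    "tissue",
    "dr1",
    "sem",
    "body_weight",
    "fibrosis_stage",
]


def write_cohort(cohort: Cohort, path: str | Path, format: str = "csv") -> None:
    """Write a cohort as long-format CSV or nested JSON."""
    path = Path(path)
    if format == "csv":
        rows = []
        for p in cohort:
            for tissue, dr1, sem in (
                ("liver", p.liver_dr1, p.liver_sem),
                ("spleen", p.spleen_dr1, p.spleen_sem),
            ):
                for t, y, s in zip(p.times, dr1, sem):
                    rows.append(
                        (p.patient_id, repr(float(t)), tissue, repr(float(y)),
                         repr(float(s)), repr(float(p.body_weight)), p.fibrosis_stage)
                    )
        df = pd.DataFrame(rows, columns=CSV_COLUMNS)
        df.to_csv(path, index=False)
    elif format == "json":
        payload = {
            "provenance": cohort.provenance,
            "patients": [
                {
                    "patient_id": p.patient_id,
                    "fibrosis_stage": p.fibrosis_stage,
                    "body_weight": p.body_weight,
                    "times": p.times.tolist(),
                    "liver_dr1": p.liver_dr1.tolist(),
                    "liver_sem": p.liver_sem.tolist(),
                    "spleen_dr1": p.spleen_dr1.tolist(),
                    "spleen_sem": p.spleen_sem.tolist(),
                }
                for p in cohort
            ],
        }
        path.write_text(json.dumps(payload, indent=1))
    else:
        raise ValidationError(f"unsupported cohort format: {format!r}")


def read_cohort(path: str | Path, format: str | None = None) -> Cohort:
    """Read a cohort from long-format CSV or nested JSON.

    Any invariant violation is reported with the offending patient id and
    field; no patient is silently dropped.
    """
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower() or "csv"
    if format == "csv":
        try:
            df = pd.read_csv(path, float_precision="round_trip")
        except Exception as exc:
            raise FormatError(f"could not parse {path}: {exc}") from exc
        missing = [c for c in CSV_COLUMNS[:5] if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: missing required columns {missing}")
        patients = []
        for pid, grp in df.groupby("patient_id", sort=False):
            liver = grp[grp["tissue"] == "liver"].sort_values("time_s")
            spleen = grp[grp["tissue"] == "spleen"].sort_values("time_s")
            if len(liver) != len(spleen) or not np.array_equal(
                liver["time_s"].to_numpy(), spleen["time_s"].to_numpy()
            ):
                raise FormatError(
                    f"patient {pid}: liver and spleen rows must share the same times"
                )
            weight = float(grp["body_weight"].iloc[0]) if "body_weight" in grp else 70.0
            stage = str(grp["fibrosis_stage"].iloc[0]) if "fibrosis_stage" in grp else "unknown"
            try:
                patients.append(
                    PatientRecord(
                        patient_id=str(pid),
                        times=liver["time_s"].to_numpy(float),
                        liver_dr1=liver["dr1"].to_numpy(float),
                        liver_sem=liver["sem"].to_numpy(float),
                        spleen_dr1=spleen["dr1"].to_numpy(float),
                        spleen_sem=spleen["sem"].to_numpy(float),
                        body_weight=weight,
                        fibrosis_stage=stage,
                    )
                )
            except ValidationError as exc:
                raise FormatError(f"{path}: {exc}") from exc
        return Cohort(patients, provenance=str(path))
    if format == "json":
        try:
            payload = json.loads(path.read_text())
        except Exception as exc:
            raise FormatError(f"could not parse {path}: {exc}") from exc
        try:
            patients = [
                PatientRecord(
                    patient_id=str(rec["patient_id"]),
                    times=rec["times"],
                    liver_dr1=rec["liver_dr1"],
                    liver_sem=rec["liver_sem"],
                    spleen_dr1=rec["spleen_dr1"],
                    spleen_sem=rec["spleen_sem"],
                    body_weight=float(rec.get("body_weight", 70.0)),
                    fibrosis_stage=str(rec.get("fibrosis_stage", "unknown")),
                )
                for rec in payload["patients"]
            ]
        except KeyError as exc:
            raise FormatError(f"{path}: missing required field {exc}") from exc
        except ValidationError as exc:
            raise FormatError(f"{path}: {exc}") from exc
        return Cohort(patients, provenance=payload.get("provenance", str(path)))
    raise ValidationError(f"unsupported cohort format: {format!r}")


# ---------------------------------------------------------------------------
# MAT reader

#: canonical variable names expected inside a MAT cohort file; a mapping
#: config can rename any of them when a deposited file uses other names.
DEFAULT_MAT_FIELDS = {
    "patient_id": "patient_id",
    "times": "times",
    "liver_dr1": "liver_dr1",
    "liver_sem": "liver_sem",
    "spleen_dr1": "spleen_dr1",
    "spleen_sem": "spleen_sem",
    "body_weight": "body_weight",
    "fibrosis_stage": "fibrosis_stage",
}


def read_s1_mat(path: str | Path, field_map: dict[str, str] | None = None) -> Cohort:
    """Read a cohort stored as a MAT struct array named ``patients``.

    The canonical layout is a 1×N struct array with per-patient fields
    named as in :data:`DEFAULT_MAT_FIELDS`; ``field_map`` overrides
    canonical-name -> file-name when the deposited file differs.  Numeric
    fibrosis codes 0–4 map to stages F0–F4; a missing stage field degrades
    to ``unknown`` with a logged warning, as do unknown extra fields.
    """
    fmap = dict(DEFAULT_MAT_FIELDS)
    if field_map:
        fmap.update(field_map)
    try:
        mat = loadmat(str(path), squeeze_me=True, struct_as_record=False)
    except Exception as exc:
        raise FormatError(f"could not read MAT file {path}: {exc}") from exc
    if "patients" not in mat:
        raise FormatError(f"{path}: no 'patients' struct array found")
    structs = np.atleast_1d(mat["patients"])
    patients = []
    for k, s in enumerate(structs):
        avail = set(getattr(s, "_fieldnames", []))
        extra = avail - set(fmap.values())
        if extra:
            log.warning("MAT patient %d: ignoring unknown fields %s", k, sorted(extra))
        required = ("times", "liver_dr1", "spleen_dr1")
        for key in required:
            if fmap[key] not in avail:
                raise FormatError(
                    f"{path}: patient {k} lacks time-series variable {fmap[key]!r}"
                )

        def get(key, default=None):
            return getattr(s, fmap[key]) if fmap[key] in avail else default

        times = np.atleast_1d(np.asarray(get("times"), dtype=float))
        zeros = np.zeros_like(times)
        stage_raw = get("fibrosis_stage")
        if stage_raw is None:
            log.warning("MAT patient %d: no fibrosis stage; using 'unknown'", k)
            stage = "unknown"
        elif isinstance(stage_raw, str):
            stage = stage_raw
        else:
            code = int(stage_raw)
            if code not in STAGE_CODE_MAP:
                log.warning("MAT patient %d: stage code %s unknown", k, code)
                stage = "unknown"
            else:
                stage = STAGE_CODE_MAP[code]
        pid = get("patient_id", f"P{k + 1:03d}")
        patients.append(
            PatientRecord(
                patient_id=str(pid),
                times=times,
                liver_dr1=np.atleast_1d(np.asarray(get("liver_dr1"), dtype=float)),
                liver_sem=np.atleast_1d(np.asarray(get("liver_sem", zeros), dtype=float)),
                spleen_dr1=np.atleast_1d(np.asarray(get("spleen_dr1"), dtype=float)),
                spleen_sem=np.atleast_1d(np.asarray(get("spleen_sem", zeros), dtype=float)),
                body_weight=float(get("body_weight", 70.0)),
                fibrosis_stage=stage,
            )
        )
    return Cohort(patients, provenance=str(path))


# ---------------------------------------------------------------------------
# Results writer

RESULT_COLUMNS = [
    "patient_id",
    "fibrosis_stage",
    "k_diff",
    "k_ph",
    "k_hp",
    "k_hb",
    "xi",
    "chi2",
    "df",
    "gof",
    "method",
]


def write_results(path: str | Path, fits: list[dict]) -> None:
    """Write per-patient fit results as CSV (one row per patient).

    Each entry of ``fits`` must provide the keys in :data:`RESULT_COLUMNS`
    (``gof`` is "pass" or "reject").  Floats are serialized with ``repr``
    so a round trip preserves at least 12 significant digits.
    """
    if not fits:
        raise ValidationError("fits must be non-empty")
    path = Path(path)
    rows = []
    for fit in fits:
        missing = [c for c in RESULT_COLUMNS if c not in fit]
        if missing:
            raise ValidationError(f"fit entry missing keys: {missing}")
        rows.append(
            [
                fit["patient_id"],
                fit["fibrosis_stage"],
                *(repr(float(fit[c])) for c in ("k_diff", "k_ph", "k_hp", "k_hb", "xi", "chi2")),
                int(fit["df"]),
                fit["gof"],
                fit["method"],
            ]
        )
    pd.DataFrame(rows, columns=RESULT_COLUMNS).to_csv(path, index=False)


def read_results(path: str | Path) -> pd.DataFrame:
    """Read back a results table written by :func:`write_results`."""
    try:
        return pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:
        raise FormatError(f"could not parse results file {path}: {exc}") from exc
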