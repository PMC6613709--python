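"""Whole-body gadoxetate compartment model and MRI signal model.

The dynamic model tracks gadoxetate concentration in three well-mixed
compartments — hepatocytes (``C_hep``), blood plasma (``C_p``) and the
extracellular extravascular space (``C_ees``) — connected by five fluxes:

* plasma <-> EES diffusion (rate ``k_diff``),
* hepatocyte uptake of the albumin-unbound plasma fraction via the OATP1
  transporter family (``k_ph``),
* back-flux from hepatocytes to plasma via MRP3 (``k_hp``),
* biliary excretion from hepatocytes via MRP2 (``k_hb``),
* renal clearance of unbound plasma gadoxetate (``CLr``).

The system is linear and time-invariant with a piecewise-constant infusion
input, so the default solver propagates the exact solution with matrix
exponentials over constant-input intervals.  A general-purpose stiff
integrator (:func:`simulate_ivp`) is retained as an independent cross-check.

The signal model converts compartment concentrations into the change in
longitudinal relaxation rate (ΔR1, s⁻¹) observed in liver and spleen ROIs,
using tissue volume fractions, tissue-specific relaxivities and a global
scale factor ξ.

Units are SI-based throughout: seconds, litres, mmol, mM (mmol/L), s⁻¹.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from .errors import SimulationError, ValidationError

__all__ = [
    "PhysiologicalConstants",
    "RateParameters",
    "DoseProtocol",
    "CompartmentTrajectory",
    "ode_rhs",
    "infusion_rate",
    "simulate",
    "simulate_ivp",
    "predict_delta_r1",
    "liver_tissue_concentration",
    "blood_concentration",
]


@dataclass(frozen=True)
class PhysiologicalConstants:
    """Fixed physiological constants of the whole-body model.

    Volumes are whole-body compartment volumes in litres; fractions are
    dimensionless tissue composition fractions; relaxivities are in
    mM⁻¹ s⁻¹.  ``CLr`` is the renal plasma clearance in L/s (the default
    corresponds to 118 mL/min).
    """

    V_l: float = 1.43        # liver volume (L)
    V_p: float = 2.57        # plasma volume (L)
    V_ees: float = 14.77     # extracellular extravascular space volume (L)
    Alb: float = 0.9         # fraction of gadoxetate not bound to albumin
    v_h: float = 0.68        # hepatocyte volume fraction of the liver
    CLr: float = 118.0 / 60.0 / 1000.0  # renal clearance (L/s)
    v_p_l: float = 0.12      # plasma fraction in liver
    v_ees_l: float = 0.20    # EES fraction in liver
    v_p_s: float = 0.35      # plasma fraction in spleen
    v_ees_s: float = 0.20    # EES fraction in spleen
    r1_hep: float = 10.7     # hepatocyte relaxivity (mM⁻¹ s⁻¹)
    r1_p: float = 7.3        # plasma relaxivity (mM⁻¹ s⁻¹)
    r1_ees: float = 6.9      # EES relaxivity (mM⁻¹ s⁻¹)

    def __post_init__(self) -> None:
        for name in ("V_l", "V_p", "V_ees"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        for name in ("Alb", "v_h", "v_p_l", "v_ees_l", "v_p_s", "v_ees_s"):
            val = getattr(self, name)
            if not 0 < val <= 1:
                raise ValidationError(f"{name} must be in (0, 1], got {val}")
        for name in ("r1_hep", "r1_p", "r1_ees"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if self.CLr < 0:
            raise ValidationError("CLr must be >= 0")

    @classmethod
    def from_config(cls, path: str | Path) -> "PhysiologicalConstants":
        """Load constants from a flat key-value JSON config file.

        Keys match field names; missing keys keep their defaults and
        unknown keys raise a validation error.
        """
        known = {f.name for f in fields(cls)}
        data = json.loads(Path(path).read_text())
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown constant names in {path}: {sorted(unknown)}")
        return cls(**data)


@dataclass(frozen=True)
class RateParameters:
    """Subject-level model parameters.

    The four rates are first-order rate constants in s⁻¹; ``xi`` is the
    dimensionless global signal scale ξ of the relaxation model.
    """

    k_diff: float  # plasma <-> EES exchange (s⁻¹)
    k_ph: float    # hepatocyte uptake, OATP1 (s⁻¹)
    k_hp: float    # hepatocyte -> plasma back-flux, MRP3 (s⁻¹)
    k_hb: float    # hepatocyte -> bile excretion, MRP2 (s⁻¹)
    xi: float      # signal scale ξ (dimensionless)

    def __post_init__(self) -> None:
        for name in ("k_diff", "k_ph", "k_hp", "k_hb"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValidationError(f"{name} must be finite and >= 0, got {v}")
        if not np.isfinite(self.xi) or self.xi <= 0:
            raise ValidationError(f"xi must be finite and > 0, got {self.xi}")

    def as_array(self) -> np.ndarray:
        return np.array([self.k_diff, self.k_ph, self.k_hp, self.k_hb, self.xi])

    @classmethod
    def from_array(cls, arr) -> "RateParameters":
        return cls(*(float(v) for v in arr))


PARAMETER_NAMES = ("k_diff", "k_ph", "k_hp", "k_hb", "xi")


@dataclass(frozen=True)
class DoseProtocol:
    """Weight-based bolus injection of gadoxetate.

    The clinical protocol administers ``dose_volume_per_kg`` mL/kg of a
    ``formulation_concentration`` mmol/mL formulation through a power
    injector at ``injection_rate`` mL/s, modelled as a rectangular pulse.
    """

    body_weight: float                      # kg
    dose_volume_per_kg: float = 0.1         # mL/kg
    formulation_concentration: float = 0.25  # mmol/mL
    injection_rate: float = 1.0             # mL/s
    t_injection_start: float = 0.0          # s

    def __post_init__(self) -> None:
        if self.body_weight <= 0:
            raise ValidationError("body_weight must be > 0")
        if self.dose_volume_per_kg < 0 or self.formulation_concentration < 0:
            raise ValidationError("dose volume and concentration must be >= 0")
        if self.injection_rate <= 0:
            raise ValidationError("injection_rate must be > 0")

    @property
    def total_dose(self) -> float:
        """Injected amount (mmol)."""
        return self.body_weight * self.dose_volume_per_kg * self.formulation_concentration

    @property
    def duration(self) -> float:
        """Injection duration (s) = injected volume / injector rate."""
        return self.body_weight * self.dose_volume_per_kg / self.injection_rate

    @property
    def t_injection_end(self) -> float:
        return self.t_injection_start + self.duration

    @classmethod
    def from_config(cls, path: str | Path, body_weight: float) -> "DoseProtocol":
        known = {f.name for f in fields(cls)} - {"body_weight"}
        data = json.loads(Path(path).read_text())
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown dose settings in {path}: {sorted(unknown)}")
        return cls(body_weight=body_weight, **data)


@dataclass(frozen=True)
class CompartmentTrajectory:
    """Simulated compartment concentrations (mM) on a time grid (s)."""

    times: np.ndarray
    C_hep: np.ndarray
    C_p: np.ndarray
    C_ees: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1 or np.any(np.diff(t) <= 0):
            raise ValidationError("times must be a strictly increasing 1-d array")
        for name in ("C_hep", "C_p", "C_ees"):
            c = np.asarray(getattr(self, name), dtype=float)
            if c.shape != t.shape:
                raise ValidationError(f"{name} must have the same length as times")

    def at(self, t: float) -> tuple[float, float, float]:
        """Concentrations at a simulated time point ``t`` (must be on the grid)."""
        idx = np.flatnonzero(np.isclose(self.times, t))
        if idx.size == 0:
            raise ValidationError(f"time {t} s is not on the simulated grid")
        i = int(idx[0])
        return float(self.C_hep[i]), float(self.C_p[i]), float(self.C_ees[i])


def system_matrices(
    params: RateParameters, constants: PhysiologicalConstants
) -> np.ndarray:
    """State matrix A of dx/dt = A x + b(t) with x = (C_hep, C_p, C_ees)."""
    c = constants
    p = params
    lv = c.V_l * c.v_h
    A = np.array(
        [
            [-(p.k_hp + p.k_hb), p.k_ph * c.Alb, 0.0],
            [
                p.k_hp * lv / c.V_p,
                -(p.k_ph * c.Alb * lv + c.CLr * c.Alb + p.k_diff * c.Alb * c.V_ees)
                / c.V_p,
                p.k_diff * c.V_ees / c.V_p,
            ],
            [0.0, p.k_diff * c.Alb, -p.k_diff],
        ]
    )
    return A


def infusion_rate(t: float, dose: DoseProtocol) -> float:
    """Gadoxetate infusion rate u(t) in mmol/s (rectangular bolus pulse)."""
    if dose.duration == 0.0 or dose.total_dose == 0.0:
        return 0.0
    if dose.t_injection_start <= t < dose.t_injection_end:
        return dose.total_dose / dose.duration
    return 0.0


def ode_rhs(
    state,
    t: float,
    params: RateParameters,
    constants: PhysiologicalConstants,
    dose: DoseProtocol,
) -> tuple[float, float, float]:
    """Right-hand side of the compartment ODE system (mM/s).

    ``state`` is the concentration triple (C_hep, C_p, C_ees).  The three
    balance equations are

    dC_hep/dt = k_ph·C_p·Alb − k_hp·C_hep − k_hb·C_hep
    dC_p/dt   = [(k_hp·C_hep − k_ph·C_p·Alb)·V_l·v_h − CLr·C_p·Alb
                 + k_diff·(C_ees − C_p·Alb)·V_ees + u(t)] / V_p
    dC_ees/dt = k_diff·(C_p·Alb − C_ees)
    """
    x = np.asarray(state, dtype=float)
    if x.shape != (3,) or not np.all(np.isfinite(x)):
        raise ValidationError(f"state must be 3 finite concentrations, got {state!r}")
    A = system_matrices(params, constants)
    dx = A @ x
    dx[1] += infusion_rate(t, dose) / constants.V_p
    return float(dx[0]), float(dx[1]), float(dx[2])


def _breakpoints(dose: DoseProtocol, t_end: float) -> list[tuple[float, float, float]]:
    """Intervals (t0, t1, u) with constant infusion rate covering [start, t_end]."""
    t0 = dose.t_injection_start
    te = dose.t_injection_end
    rate = dose.total_dose / dose.duration if dose.duration > 0 and dose.total_dose > 0 else 0.0
    if rate == 0.0 or te <= t0:
        return [(t0, t_end, 0.0)]
    if t_end <= te:
        return [(t0, t_end, rate)]
    return [(t0, te, rate), (te, t_end, 0.0)]


def simulate(
    params: RateParameters,
    constants: PhysiologicalConstants,
    dose: DoseProtocol,
    times,
) -> CompartmentTrajectory:
    """Exact forward simulation at the requested times.

    The state is zero before the injection starts; afterwards the linear
    time-invariant system is propagated segment-by-segment with the matrix
    exponential of the augmented 4×4 system, which is exact for the
    piecewise-constant bolus input.
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size == 0 or np.any(np.diff(t) <= 0):
        raise ValidationError("times must be a non-empty strictly increasing array")

    out = np.zeros((t.size, 3))
    t_start = dose.t_injection_start
    post = t > t_start
    if not np.any(post):
        return CompartmentTrajectory(t, out[:, 0], out[:, 1], out[:, 2])

    A = system_matrices(params, constants)
    grid = np.unique(np.concatenate([[t_start], t[post]]))
    segments: list[tuple[float, float, float]] = []
    for t0, t1, u in _breakpoints(dose, grid[-1]):
        inner = grid[(grid > t0) & (grid < t1)]
        edges = np.concatenate([[t0], inner, [t1]])
        for a, b in zip(edges[:-1], edges[1:]):
            segments.append((a, b, u))

    # augmented system d/dt (x, 1) = [[A, b], [0, 0]] (x, 1); batched expm
    M = np.zeros((len(segments), 4, 4))
    for k, (a, b, u) in enumerate(segments):
        M[k, :3, :3] = A * (b - a)
        M[k, 1, 3] = u / constants.V_p * (b - a)
    try:
        P = expm(M)
    except Exception as exc:  # pragma: no cover - expm very rarely fails
        raise SimulationError(f"matrix exponential failed: {exc}") from exc
    if not np.all(np.isfinite(P)):
        raise SimulationError(
            f"non-finite propagator for params {params} (check rate magnitudes)"
        )

    x = np.zeros(4)
    x[3] = 1.0
    values = {t_start: x[:3].copy()}
    for k, (a, b, u) in enumerate(segments):
        x = P[k] @ x
        values[b] = x[:3].copy()

    for i in np.flatnonzero(post):
        out[i] = values[t[i]]
    # exact solution of a positive system; clip solver-level round-off only
    np.clip(out, 0.0, None, out=out)
    return CompartmentTrajectory(t, out[:, 0], out[:, 1], out[:, 2])


def simulate_ivp(
    params: RateParameters,
    constants: PhysiologicalConstants,
    dose: DoseProtocol,
    times,
    rtol: float = 1e-9,
    atol: float = 1e-12,
) -> CompartmentTrajectory:
    """Cross-check path: integrate the same system with a stiff ODE solver.

    Integration restarts at the injection-pulse edges so the discontinuous
    input does not degrade the error control.
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size == 0 or np.any(np.diff(t) <= 0):
        raise ValidationError("times must be a non-empty strictly increasing array")
    out = np.zeros((t.size, 3))
    post = t > dose.t_injection_start
    if not np.any(post):
        return CompartmentTrajectory(t, out[:, 0], out[:, 1], out[:, 2])

    A = system_matrices(params, constants)
    t_end = float(t[post][-1])
    x = np.zeros(3)
    collected: dict[float, np.ndarray] = {}
    for t0, t1, u in _breakpoints(dose, t_end):
        b = np.array([0.0, u / constants.V_p, 0.0])
        t_eval = t[(t > t0) & (t <= t1)]
        sol = solve_ivp(
            lambda _t, _x: A @ _x + b,
            (t0, t1),
            x,
            method="LSODA",
            t_eval=t_eval if t_eval.size else None,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise SimulationError(f"ODE solver failed on [{t0}, {t1}]: {sol.message}")
        for ti, xi in zip(sol.t, sol.y.T):
            collected[float(ti)] = xi
        x = sol.y[:, -1]
    for i in np.flatnonzero(post):
        out[i] = collected[float(t[i])]
    return CompartmentTrajectory(t, out[:, 0], out[:, 1], out[:, 2])


def predict_delta_r1(
    traj: CompartmentTrajectory,
    params: RateParameters,
    constants: PhysiologicalConstants,
) -> tuple[np.ndarray, np.ndarray]:
    """ΔR1 (s⁻¹) in liver and spleen for a simulated trajectory.

    ΔR1_liver  = ξ·(C_hep·v_h·r1_hep + C_p·v_p_l·r1_p + C_ees·v_ees_l·r1_ees)
    ΔR1_spleen = ξ·(C_p·v_p_s·r1_p + C_ees·v_ees_s·r1_ees)
    """
    c = constants
    liver = params.xi * (
        traj.C_hep * c.v_h * c.r1_hep
        + traj.C_p * c.v_p_l * c.r1_p
        + traj.C_ees * c.v_ees_l * c.r1_ees
    )
    spleen = params.xi * (
        traj.C_p * c.v_p_s * c.r1_p + traj.C_ees * c.v_ees_s * c.r1_ees
    )
    return liver, spleen


def liver_tissue_concentration(
    traj: CompartmentTrajectory, constants: PhysiologicalConstants, t: float
) -> float:
    """Total gadoxetate concentration in liver tissue (mM per L wet tissue).

    Volume-fraction decomposition of the liver signal without relaxivities:
    v_h·C_hep + v_p_l·C_p + v_ees_l·C_ees.
    """
    if t < traj.times[0] or t > traj.times[-1]:
        raise ValidationError(
            f"t={t} s outside simulated range [{traj.times[0]}, {traj.times[-1]}]"
        )
    c_hep, c_p, c_ees = traj.at(t)
    c = constants
    return c.v_h * c_hep + c.v_p_l * c_p + c.v_ees_l * c_ees


def blood_concentration(
    traj: CompartmentTrajectory, t: float, hematocrit: float
) -> float:
    """Whole-blood gadoxetate concentration (mM) at a simulated time.

    Gadoxetate is extracellular, so the whole-blood value is the plasma
    concentration diluted by the red-cell volume fraction.
    """
    if not 0 <= hematocrit < 1:
        raise ValidationError(f"hematocrit must be in [0, 1), got {hematocrit}")
    _, c_p, _ = traj.at(t)
    return c_p * (1.0 - hematocrit)


def replace_params(params: RateParameters, **kwargs) -> RateParameters:
    """Return a copy of ``params`` with the given fields replaced."""
    return replace(params, **kwargs)
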