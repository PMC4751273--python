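"""Physical parameters, unit conversions and dimensionless-number utilities.

Everything internal to the package is SI: metres, seconds, mol m^-3 (which is
numerically identical to millimolar, a deliberate choice that removes the most
common unit hazard of this model). Conversions to and from the units used in
experimental reports (ug/ul, mm, minutes) happen only at the API boundary.

The default :class:`Parameters` describe the drainage of 3 kDa dextran through
mouse cerebral gray matter: tortuosity-scaled effective diffusion in the
extracellular space (ECS), slow bulk flow along white-matter fibre tracts, and
fast convective drainage along vascular basement membranes, coupled by a
first-order take-up rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

from .errors import InvalidParameterError

__all__ = [
    "Parameters",
    "CaseSpec",
    "CASE_TABLE",
    "ADVECTIVELY_UNCONSTRAINED",
    "mass_to_molar",
    "temperature_correct_diffusion",
    "courant_timestep",
    "peclet",
    "build_case",
    "drainage_velocity_from_observation",
]

#: Sentinel returned by :func:`courant_timestep` when there is no advection and
#: the time step is therefore not limited by the CFL condition.
ADVECTIVELY_UNCONSTRAINED = math.inf


@dataclass(frozen=True)
class Parameters:
    """Physical constants and protocol settings of the clearance model.

    Attributes
    ----------
    D_star:
        Effective diffusion coefficient of the solute in gray matter, m^2/s.
        This is the tortuosity-scaled *tissue* value (already divided by
        lambda_gray^2), measured directly in cortex.
    lambda_gray:
        Isotropic tortuosity of gray matter (dimensionless).
    lambda_white_par, lambda_white_perp:
        White-matter tortuosity along and across the fibre axis.
    u_white:
        Bulk-flow speed along white-matter fibres, m/s.
    u_b:
        Apparent perivascular drainage speed along basement membranes, m/s
        (2.5 mm in 5 min).
    k_b:
        First-order take-up rate from ECS into the basement-membrane
        compartment, 1/s.
    k_d:
        First-order degradation rate, 1/s. Zero for dextran, which is not
        enzymatically degraded; kept as a knob for other solutes.
    c0:
        Injected concentration, mol/m^3 (= mM).
    t_inject:
        Injection duration, s.
    t_total:
        Total simulated time, s (injection + observation).
    u_inject:
        Optional radial convective speed (m/s) emulating the fluid pushed
        out by the injection itself, active only during the injection
        window. Zero by default: speeds up to ~4e-6 m/s have a negligible
        effect on the tracer distribution, so the flow is normally omitted.
    detection_fraction:
        Detection threshold as a fraction of ``c0`` (0.1 % criterion).
    C_max:
        Courant-number bound used for the advective time-step limit.
    """

    D_star: float = 8.7e-11
    lambda_gray: float = 1.60
    lambda_white_par: float = 1.47
    lambda_white_perp: float = 1.68
    u_white: float = 1.75e-7
    u_b: float = 8.33e-6
    k_b: float = 2.5e-4
    k_d: float = 0.0
    u_inject: float = 0.0
    c0: float = 0.33
    t_inject: float = 120.0
    t_total: float = 1920.0
    detection_fraction: float = 1e-3
    C_max: float = 0.5

    def __post_init__(self) -> None:
        nonneg = (
            "D_star", "lambda_gray", "lambda_white_par", "lambda_white_perp",
            "u_white", "u_b", "k_b", "k_d", "u_inject", "c0", "t_inject",
            "t_total",
        )
        for name in nonneg:
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0, got {getattr(self, name)!r}")
        if not 0.0 < self.detection_fraction < 1.0:
            raise InvalidParameterError(
                f"detection_fraction must lie in (0, 1), got {self.detection_fraction!r}")
        if not 0.0 < self.C_max <= 1.0:
            raise InvalidParameterError(f"C_max must lie in (0, 1], got {self.C_max!r}")

    @property
    def D_free(self) -> float:
        """Free-medium diffusion coefficient implied by the gray-matter value.

        Recovered as ``D_star * lambda_gray**2`` so that the gray-matter
        effective coefficient stays exactly at its measured value while the
        white-matter tensor can be formed as ``D_free / lambda**2`` per axis.
        """
        return self.D_star * self.lambda_gray**2

    @property
    def detection_threshold(self) -> float:
        """Absolute detection concentration, mol m^-3."""
        return self.detection_fraction * self.c0

    def replace(self, **changes) -> "Parameters":
        """Return a copy with the given fields replaced (validated again)."""
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


#: Multiplier rows (diffusion, bulk flow, drainage, uptake) of the simulation
#: case matrix. A-cases probe diffusion alone, B-cases add white-matter bulk
#: flow, C-cases add perivascular drainage and uptake.
CASE_TABLE: dict[str, tuple[float, float, float, float]] = {
    "A1": (1.0, 0.0, 0.0, 0.0),
    "A2": (5.0, 0.0, 0.0, 0.0),
    "A3": (10.0, 0.0, 0.0, 0.0),
    "B1": (1.0, 1.0, 0.0, 0.0),
    "B2": (1.0, 5.0, 0.0, 0.0),
    "B3": (1.0, 10.0, 0.0, 0.0),
    "C1": (1.0, 1.0, 1.0, 1.0),
    "C2": (1.0, 1.0, 0.5, 1.0),
    "C3": (1.0, 1.0, 0.5, 0.1),
    "C4": (5.0, 1.0, 0.5, 0.1),
}


@dataclass(frozen=True)
class CaseSpec:
    """One simulation case: multipliers applied to the default parameters.

    ``case_id`` is normally one of the ten canonical ids in
    :data:`CASE_TABLE`, in which case the multipliers must match the table
    row exactly. The id ``"custom"`` is accepted with arbitrary non-negative
    multipliers, which is convenient for isolating single mechanisms.
    """

    case_id: str
    diffusion_multiplier: float
    bulkflow_multiplier: float
    drainage_multiplier: float
    uptake_multiplier: float

    def __post_init__(self) -> None:
        mult = (self.diffusion_multiplier, self.bulkflow_multiplier,
                self.drainage_multiplier, self.uptake_multiplier)
        if any(m < 0 for m in mult):
            raise InvalidParameterError(f"case multipliers must be >= 0, got {mult!r}")
        if self.case_id in CASE_TABLE and mult != CASE_TABLE[self.case_id]:
            raise InvalidParameterError(
                f"case {self.case_id!r} must carry multipliers {CASE_TABLE[self.case_id]!r}, "
                f"got {mult!r}")
        if self.case_id not in CASE_TABLE and self.case_id != "custom":
            raise InvalidParameterError(
                f"unknown case id {self.case_id!r}; valid ids: "
                f"{sorted(CASE_TABLE)} or 'custom'")

    @property
    def multipliers(self) -> tuple[float, float, float, float]:
        return (self.diffusion_multiplier, self.bulkflow_multiplier,
                self.drainage_multiplier, self.uptake_multiplier)


def build_case(case_id: str) -> CaseSpec:
    """Return the canonical :class:`CaseSpec` for one of the ten case ids."""
    try:
        mult = CASE_TABLE[case_id]
    except KeyError:
        raise KeyError(
            f"unknown case id {case_id!r}; valid ids are {sorted(CASE_TABLE)}") from None
    return CaseSpec(case_id, *mult)


def custom_case(diffusion: float = 1.0, bulkflow: float = 0.0,
                drainage: float = 0.0, uptake: float = 0.0) -> CaseSpec:
    """Build an ad-hoc case with explicit multipliers (id ``"custom"``)."""
    return CaseSpec("custom", diffusion, bulkflow, drainage, uptake)


def mass_to_molar(mass_concentration: float, molecular_weight: float) -> float:
    """Convert a mass concentration in ug/ul to molarity in mol m^-3.

    ``ug/ul`` equals ``g/L``; dividing by the molecular weight in g/mol gives
    mol/L, and multiplying by 1000 yields mol/m^3 (numerically equal to mM).

    Parameters
    ----------
    mass_concentration:
        Concentration in ug/ul (>= 0).
    molecular_weight:
        Molecular weight in Da = g/mol (> 0).
    """
    if molecular_weight <= 0:
        raise InvalidParameterError(
            f"molecular_weight must be > 0, got {molecular_weight!r}")
    if mass_concentration < 0:
        raise InvalidParameterError(
            f"mass_concentration must be >= 0, got {mass_concentration!r}")
    return mass_concentration / molecular_weight * 1e3


def temperature_correct_diffusion(D_ref: float, T_ref: float, T_target: float,
                                  mu_ref: float, mu_target: float) -> float:
    """Stokes-Einstein temperature correction of a diffusion coefficient.

    ``D_target = D_ref * (T_target / T_ref) * (mu_ref / mu_target)`` with
    temperatures in kelvin and dynamic viscosities in Pa s. Used to move a
    coefficient measured at room/experimental temperature to body temperature
    with the viscosity of water at each temperature.
    """
    vals = dict(D_ref=D_ref, T_ref=T_ref, T_target=T_target,
                mu_ref=mu_ref, mu_target=mu_target)
    for name, v in vals.items():
        if v <= 0:
            raise InvalidParameterError(f"{name} must be > 0, got {v!r}")
    return D_ref * (T_target / T_ref) * (mu_ref / mu_target)


def courant_timestep(dx: float, speed: float, C: float) -> float:
    """Largest time step satisfying the CFL condition ``u*dt/dx <= C``.

    Returns :data:`ADVECTIVELY_UNCONSTRAINED` (``math.inf``) when ``speed``
    is zero, so the caller can fall back to the diffusive stability cap.
    """
    if dx <= 0:
        raise InvalidParameterError(f"dx must be > 0, got {dx!r}")
    if C <= 0:
        raise InvalidParameterError(f"C must be > 0, got {C!r}")
    if speed < 0:
        raise InvalidParameterError(f"speed must be >= 0, got {speed!r}")
    if speed == 0.0:
        return ADVECTIVELY_UNCONSTRAINED
    return C * dx / speed


def peclet(L: float, U: float, D: float) -> float:
    """Peclet number ``Pe = L*U/D``: convective over diffusive transport.

    For this model the natural length scale is the height of the mouse brain
    (5.5 mm); ``Pe >> 1`` marks drainage-dominated clearance.
    """
    if D <= 0:
        raise InvalidParameterError(f"D must be > 0, got {D!r}")
    if L <= 0:
        raise InvalidParameterError(f"L must be > 0, got {L!r}")
    if U < 0:
        raise InvalidParameterError(f"U must be >= 0, got {U!r}")
    return L * U / D


def drainage_velocity_from_observation(distance: float, time: float) -> float:
    """Apparent drainage speed from an observed maximum travel distance.

    A tracer front observed ``distance`` metres from the injection site
    ``time`` seconds after injection implies a straight-path speed of
    ``distance / time`` (e.g. 2.5 mm in 5 min -> 8.33e-6 m/s).
    """
    if distance < 0:
        raise InvalidParameterError(f"distance must be >= 0, got {distance!r}")
    if time <= 0:
        raise InvalidParameterError(f"time must be > 0, got {time!r}")
    return distance / time
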