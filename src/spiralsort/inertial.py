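"""Dimensionless numbers and inertial force models.

Three lift-coefficient formulations are provided:

* ``EXP_FIT_A`` - exponential fit to straight-channel lift data,
  C_L = 3.4368 * Re^-0.714 (geometry-blind).
* ``EXP_FIT_B`` - alternative exponential fit, C_L = 1.3665 * Re^-0.59.
* ``DIMENSIONLESS_GEOMETRIC`` - the dimensionless geometric form that folds in
  the duct shape and particle size, C_L = AR^2 * H / (a * Re), algebraically
  identical to AR * H^2 / (W * a * Re).

Force balance: the net inertial lift F_L = C_L * rho * U_m^2 * a^4 / H^2
competes with the Stokes drag of the Dean secondary flow,
F_D = 3 pi mu U_D a with U_D = 1.8e-4 * De^1.63 m/s.  The sortability
indicator is R_F = k * F_L / F_D with a single calibration constant k fixed
once at a reference condition (the design cut-off size).  Under the geometric
lift coefficient F_L ~ a^3 and F_D ~ a, so R_F scales exactly as a^2.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

from .errors import (
    CalibrationMissingError,
    InvalidGeometryError,
    InvalidParticleError,
)
from .geometry import ChannelCrossSection, SpiralGeometry
from .hydraulics import FluidSpec, FlowCondition, WATER, mean_velocity

# empirical Dean secondary-flow correlation U_D = DEAN_VELOCITY_PREFACTOR * De^DEAN_VELOCITY_EXPONENT
DEAN_VELOCITY_PREFACTOR = 1.8e-4  # m/s
DEAN_VELOCITY_EXPONENT = 1.63

# coefficients of the two exponential lift-coefficient fits
EXP_FIT_A_COEFFS = (3.4368, -0.714)
EXP_FIT_B_COEFFS = (1.3665, -0.59)


class LiftModelVariant(enum.Enum):
    EXP_FIT_A = "exp_fit_a"
    EXP_FIT_B = "exp_fit_b"
    DIMENSIONLESS_GEOMETRIC = "dimensionless_geometric"


@dataclass(frozen=True)
class LiftModel:
    """A lift-coefficient formulation; coefficients are fixed per variant."""

    variant: LiftModelVariant = LiftModelVariant.DIMENSIONLESS_GEOMETRIC

    @property
    def coefficients(self) -> tuple[float, float] | None:
        if self.variant is LiftModelVariant.EXP_FIT_A:
            return EXP_FIT_A_COEFFS
        if self.variant is LiftModelVariant.EXP_FIT_B:
            return EXP_FIT_B_COEFFS
        return None  # geometric form has no free coefficients

    @classmethod
    def from_name(cls, name: str) -> "LiftModel":
        return cls(LiftModelVariant(name.lower()))


@dataclass(frozen=True)
class ParticleSpec:
    """A spherical particle of diameter ``diameter`` (m)."""

    diameter: float
    label: str = ""

    def __post_init__(self) -> None:
        if not self.diameter > 0:
            raise InvalidParticleError("particle diameter must be positive")

    @classmethod
    def from_um(cls, diameter_um: float, label: str = "") -> "ParticleSpec":
        return cls(diameter_um * 1e-6, label or f"{diameter_um:g}um")


def reynolds_number(fluid: FluidSpec, cs: ChannelCrossSection, flow_rate: float) -> float:
    """Channel Reynolds number Re = rho * U_m * D_h / mu."""
    if flow_rate <= 0:
        raise ValueError("flow rate must be positive")
    u_m = mean_velocity(flow_rate, cs)
    return fluid.density * u_m * cs.hydraulic_diameter / fluid.viscosity


def dean_number(re: float, cs: ChannelCrossSection, radius: float) -> float:
    """Dean number De = Re * sqrt(D_h / (2R)) at curvature radius R."""
    if radius <= 0:
        raise InvalidGeometryError("curvature radius must be positive")
    return re * math.sqrt(cs.hydraulic_diameter / (2.0 * radius))


def radius_for_dean(de: float, re: float, cs: ChannelCrossSection) -> float:
    """Curvature radius at which the channel reaches Dean number ``de``."""
    if de <= 0 or re <= 0:
        raise ValueError("De and Re must be positive")
    return cs.hydraulic_diameter / (2.0 * (de / re) ** 2)


def confinement_ratio(p: ParticleSpec, cs: ChannelCrossSection) -> float:
    """CR = a/H; inertial focusing requires CR >= 0.07."""
    return p.diameter / cs.height


CRITICAL_CONFINEMENT_RATIO = 0.07


def lift_coefficient(
    model: LiftModel,
    re: float,
    cs: ChannelCrossSection | None = None,
    p: ParticleSpec | None = None,
) -> float:
    """Evaluate C_L for the chosen formulation at channel Reynolds number Re."""
    if re <= 0:
        raise ValueError("Re must be positive")
    if model.variant is LiftModelVariant.EXP_FIT_A:
        c, e = EXP_FIT_A_COEFFS
        return c * re**e
    if model.variant is LiftModelVariant.EXP_FIT_B:
        c, e = EXP_FIT_B_COEFFS
        return c * re**e
    # dimensionless geometric form needs the duct and the particle
    if cs is None or p is None:
        raise InvalidParticleError(
            "geometric lift coefficient requires a cross-section and a particle"
        )
    ar = cs.aspect_ratio
    return ar**2 * cs.height / (p.diameter * re)


def lift_coefficient_geometric_alt(
    re: float, cs: ChannelCrossSection, p: ParticleSpec
) -> float:
    """Second printed algebraic form AR * H^2 / (W * a * Re); identical to the first."""
    return cs.aspect_ratio * cs.height**2 / (cs.width * p.diameter * re)


def dean_velocity(
    de: float,
    prefactor: float = DEAN_VELOCITY_PREFACTOR,
    exponent: float = DEAN_VELOCITY_EXPONENT,
) -> float:
    """Secondary-flow velocity magnitude U_D = prefactor * De^exponent (m/s)."""
    if de < 0:
        raise ValueError("De must be non-negative")
    if de == 0:
        return 0.0
    return prefactor * de**exponent


@dataclass(frozen=True)
class ForceBalance:
    """Lift and Dean-drag magnitudes plus their calibrated ratio R_F = k*F_L/F_D."""

    lift: float   # N
    drag: float   # N
    ratio: float
    k: float
    reynolds: float
    dean: float


def lift_force(
    p: ParticleSpec,
    cond: FlowCondition,
    cs: ChannelCrossSection,
    model: LiftModel,
    fluid: FluidSpec = WATER,
) -> float:
    """Net inertial lift magnitude F_L = C_L * rho * U_m^2 * a^4 / H^2 (N)."""
    u_m = cond.mean_velocity(cs)
    re = reynolds_number(fluid, cs, cond.flow_rate)
    c_l = lift_coefficient(model, re, cs, p)
    return c_l * fluid.density * u_m**2 * p.diameter**4 / cs.height**2


def dean_drag_force(
    p: ParticleSpec,
    de: float,
    fluid: FluidSpec = WATER,
    prefactor: float = DEAN_VELOCITY_PREFACTOR,
    exponent: float = DEAN_VELOCITY_EXPONENT,
) -> float:
    """Stokes drag from the Dean secondary flow, F_D = 3 pi mu U_D a (N)."""
    u_d = dean_velocity(de, prefactor, exponent)
    return 3.0 * math.pi * fluid.viscosity * u_d * p.diameter


def force_ratio(
    p: ParticleSpec,
    cond: FlowCondition,
    geom: SpiralGeometry,
    cs: ChannelCrossSection,
    model: LiftModel,
    k: float | None = None,
    fluid: FluidSpec = WATER,
    reference_radius: float | None = None,
) -> ForceBalance:
    """Calibrated lift-to-Dean-drag ratio R_F = k * F_L / F_D.

    The Dean drag is evaluated at ``reference_radius`` (default: the radial
    midpoint of the spiral, since De varies loop to loop while the design rule
    quotes one number per size).  ``k`` must come from
    :func:`calibrate_force_ratio`; requesting a calibrated ratio without it is
    an error rather than a silent k=1.
    """
    if k is None:
        raise CalibrationMissingError(
            "force_ratio requires a calibration constant k; "
            "run calibrate_force_ratio first (k is stored on the device preset)"
        )
    radius = geom.mid_radius if reference_radius is None else reference_radius
    re = reynolds_number(fluid, cs, cond.flow_rate)
    de = dean_number(re, cs, radius)
    f_l = lift_force(p, cond, cs, model, fluid)
    f_d = dean_drag_force(p, de, fluid)
    return ForceBalance(lift=f_l, drag=f_d, ratio=k * f_l / f_d, k=k,
                        reynolds=re, dean=de)


def calibrate_force_ratio(
    cond: FlowCondition,
    geom: SpiralGeometry,
    cs: ChannelCrossSection,
    model: LiftModel,
    target_ratio: float = 1.12,
    reference_diameter: float = 9e-6,
    fluid: FluidSpec = WATER,
    reference_radius: float | None = None,
) -> float:
    """Solve k so that R_F(reference_diameter) equals ``target_ratio``.

    The default anchors the cut-off size (9 um) to the design-point ratio 1.12;
    all size scaling is then parameter-free (a^2 under the geometric model).
    """
    p_ref = ParticleSpec(reference_diameter)
    raw = force_ratio(
        p_ref, cond, geom, cs, model, k=1.0, fluid=fluid,
        reference_radius=reference_radius,
    )
    return target_ratio / raw.ratio
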