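"""Equilibrium streamline prediction and validation against measurements.

The full 3-D flow field is replaced by a reduced-order 1-D balance of lateral
forces across the channel width, x in (0, W), measured from the inner wall:

* inertial lift acts as a restoring field toward the duct's lateral
  equilibrium offset x_eq (a fraction of W near the inner wall), with profile
  (x_eq - x)/W and magnitude F_L;
* Dean drag entrains particles outward, with the two-vortex profile
  sin(pi x / W) (zero at both walls, peaking mid-width) and magnitude F_D.

The focused position is the root of k*F_L*(x_eq - x)/W + F_D*sin(pi x/W)
nearest the inner wall.  Because the calibrated ratio R_F = k F_L/F_D grows
as a^2 under the geometric lift model, larger particles sit closer to x_eq,
i.e. nearer the inner wall — the ordering the device exploits.  In the
straight-channel limit (De -> 0) the Dean term vanishes and the root is the
lift-only equilibrium offset.  Both profiles are pluggable.

Prediction quality is scored by the normalized error
|d_sim - d_exp| / d_exp per size, and lift models are ranked by mean error.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import NoEquilibriumError
from .geometry import ChannelCrossSection, SpiralGeometry, UM
from .hydraulics import FluidSpec, FlowCondition, MBAR, WATER
from .inertial import (
    CRITICAL_CONFINEMENT_RATIO,
    LiftModel,
    ParticleSpec,
    confinement_ratio,
    dean_drag_force,
    dean_number,
    force_ratio,
    lift_force,
    reynolds_number,
)

# default lateral equilibrium offset of the lift-only duct, as a fraction of W
DEFAULT_EQUILIBRIUM_OFFSET_FRACTION = 0.2
# uniform scan resolution used to bracket the root
DEFAULT_N_SCAN = 512


def lift_profile(x: np.ndarray, width: float, x_eq: float) -> np.ndarray:
    """Restoring lift shape: positive (outward) below x_eq, vanishing at x_eq."""
    return (x_eq - x) / width


def dean_profile(x: np.ndarray, width: float) -> np.ndarray:
    """Two-vortex outward entrainment shape, zero at both walls, peak mid-width."""
    return np.sin(np.pi * x / width)


@dataclass(frozen=True)
class StreamlinePrediction:
    particle: ParticleSpec
    condition: FlowCondition
    distance: float        # m from the inner wall (nan when unfocused)
    dispersion: float      # m, synthetic streamline spread (0 for pure prediction)
    focused: bool
    wall_contact: bool = False  # True when the math root is within a/2 of a wall

    @property
    def distance_um(self) -> float:
        return self.distance / UM


def net_lateral_force(
    x: np.ndarray,
    f_lift: float,
    f_drag: float,
    k: float,
    width: float,
    x_eq: float,
    lift_shape: Callable = lift_profile,
    dean_shape: Callable = dean_profile,
) -> np.ndarray:
    """Signed lateral force (positive = away from the inner wall), N."""
    return k * f_lift * lift_shape(x, width, x_eq) + f_drag * dean_shape(x, width)


def equilibrium_distance(
    p: ParticleSpec,
    cond: FlowCondition,
    cs: ChannelCrossSection,
    geom: SpiralGeometry,
    model: LiftModel,
    k: float,
    fluid: FluidSpec = WATER,
    x_eq_fraction: float = DEFAULT_EQUILIBRIUM_OFFSET_FRACTION,
    n_scan: int = DEFAULT_N_SCAN,
    reference_radius: float | None = None,
    lift_shape: Callable = lift_profile,
    dean_shape: Callable = dean_profile,
) -> StreamlinePrediction:
    """Distance of the focused streamline to the inner wall (particle center).

    Scans ``n_scan`` uniform points over (a/2, W - a/2), takes the sign change
    nearest the inner wall and refines it with Brent's method.  Particles
    below the critical confinement ratio do not focus and are returned
    flagged, with distance NaN.  Absence of any sign change raises
    :class:`NoEquilibriumError` rather than clamping.
    """
    if confinement_ratio(p, cs) < CRITICAL_CONFINEMENT_RATIO:
        return StreamlinePrediction(p, cond, float("nan"), 0.0, focused=False)
    fb = force_ratio(p, cond, geom, cs, model, k=k, fluid=fluid,
                     reference_radius=reference_radius)
    width = cs.width
    x_eq = x_eq_fraction * width
    lo, hi = p.diameter / 2.0, width - p.diameter / 2.0
    if lo >= hi:
        raise NoEquilibriumError("particle does not fit in the channel width")
    xs = np.linspace(lo, hi, n_scan)
    f = net_lateral_force(xs, fb.lift, fb.drag, fb.k, width, x_eq,
                          lift_shape, dean_shape)
    sign = np.sign(f)
    # indices where the sign changes between consecutive scan points
    flips = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
    exact = np.nonzero(f == 0.0)[0]
    if exact.size:
        root = float(xs[exact[0]])
    elif flips.size:
        i = flips[0]  # nearest the inner wall; ties broken toward the inner wall
        root = float(
            brentq(
                lambda x: net_lateral_force(
                    np.asarray(x), fb.lift, fb.drag, fb.k, width, x_eq,
                    lift_shape, dean_shape
                ),
                xs[i], xs[i + 1], xtol=1e-12,
            )
        )
    else:
        raise NoEquilibriumError(
            f"no lateral force sign change in ({lo:.3g}, {hi:.3g}) m "
            f"for a={p.diameter/UM:.3g} um"
        )
    wall_contact = root < p.diameter / 2.0 or root > width - p.diameter / 2.0
    return StreamlinePrediction(p, cond, root, 0.0, focused=True,
                                wall_contact=wall_contact)


def focusing_length(
    p: ParticleSpec,
    cond: FlowCondition,
    cs: ChannelCrossSection,
    model: LiftModel,
    fluid: FluidSpec = WATER,
    pinned_lift_coefficient: float | None = None,
) -> float:
    """Minimum channel length to reach the focused streamline, in meters.

    L_f = pi * mu * H^2 / (rho * U_m * a^2 * C_L); the focusing requirement
    passes when L_f does not exceed the spiral's total length.
    ``pinned_lift_coefficient`` bypasses the model's Re-dependence (useful
    for sensitivity studies where C_L is held fixed).
    """
    from .inertial import lift_coefficient  # local to keep import surface tidy

    u_m = cond.mean_velocity(cs)
    if pinned_lift_coefficient is not None:
        c_l = pinned_lift_coefficient
    else:
        re = reynolds_number(fluid, cs, cond.flow_rate)
        c_l = lift_coefficient(model, re, cs, p)
    if c_l <= 0:
        raise ValueError("lift coefficient must be positive")
    return math.pi * fluid.viscosity * cs.height**2 / (
        fluid.density * u_m * p.diameter**2 * c_l
    )


def normalized_error(d_sim, d_exp):
    """Relative prediction error |d_sim - d_exp| / d_exp (element-wise)."""
    d_sim = np.asarray(d_sim, dtype=float)
    d_exp = np.asarray(d_exp, dtype=float)
    if np.any(d_exp == 0):
        raise ValueError("normalized error undefined for zero measured distance")
    err = np.abs(d_sim - d_exp) / np.abs(d_exp)
    return float(err) if err.ndim == 0 else err


@dataclass(frozen=True)
class StreamlineMeasurement:
    """One measured streamline: bead size, driving pressure, distance stats."""

    size: float       # m
    pressure: float   # Pa
    mean_distance: float  # m from inner wall
    sd: float         # m

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("streamline sd must be non-negative")


def read_streamline_measurements(path) -> list[StreamlineMeasurement]:
    """Read a delimited table with header size_um, pressure_mbar, dist_mean_um, dist_sd_um."""
    df = pd.read_csv(path)
    return [
        StreamlineMeasurement(
            size=row.size_um * UM,
            pressure=row.pressure_mbar * MBAR,
            mean_distance=row.dist_mean_um * UM,
            sd=row.dist_sd_um * UM,
        )
        for row in df.itertuples()
    ]


def model_comparison(
    measurements: Sequence[StreamlineMeasurement],
    device,
    models: Sequence[LiftModel],
    target_ratio: float = 1.12,
    reference_diameter: float = 9e-6,
    **equilibrium_kwargs,
) -> pd.DataFrame:
    """Score lift models against measured streamlines via the normalized error.

    Each model is calibrated ONCE at the device's design condition (the
    cut-off size is pinned to the design-point force ratio), then predicts
    the streamline distance for every measurement row, resolving each row's
    pressure to a flow through the rigid-device resistance.  The single
    calibration is what lets the models' different Reynolds-number exponents
    show up across the pressure sweep.  Unfocused sizes are excluded with a
    warning.  The result has one row per (model, measurement) plus a ``rank``
    column ordering models by mean error (rank 1 = best).

    ``device`` is a :class:`spiralsort.config.Device` (or anything exposing
    ``cross_section``, ``spiral``, ``fluid``, ``design_flow``, ``resistance``).
    """
    from .inertial import calibrate_force_ratio

    if len(measurements) == 0:
        raise ValueError("need at least one measurement")
    cs, geom, fluid = device.cross_section, device.spiral, device.fluid
    resistance = device.resistance
    rows = []
    for model in models:
        k = calibrate_force_ratio(
            device.design_flow, geom, cs, model,
            target_ratio=target_ratio,
            reference_diameter=reference_diameter,
            fluid=fluid,
        )
        for m in measurements:
            cond = FlowCondition.from_pressure_mbar(
                m.pressure / MBAR, resistance, fluid
            )
            pred = equilibrium_distance(
                ParticleSpec(m.size), cond, cs, geom, model,
                k=k, fluid=fluid, **equilibrium_kwargs,
            )
            if not pred.focused:
                warnings.warn(
                    f"size {m.size/UM:.3g} um below critical confinement; "
                    "excluded from model comparison",
                    stacklevel=2,
                )
                continue
            rows.append(
                {
                    "model": model.variant.value,
                    "size_um": m.size / UM,
                    "pressure_mbar": m.pressure / MBAR,
                    "dist_sim_um": pred.distance_um,
                    "dist_exp_um": m.mean_distance / UM,
                    "error": normalized_error(pred.distance, m.mean_distance),
                }
            )
    table = pd.DataFrame(rows)
    mean_err = table.groupby("model")["error"].mean().sort_values()
    ranks = {name: i + 1 for i, name in enumerate(mean_err.index)}
    table["rank"] = table["model"].map(ranks)
    return table
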