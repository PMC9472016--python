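"""Design-rule checks and cut-off tuning.

Three requirements gate a sorter design for a set of particle sizes:

#1  focusing: confinement ratio CR = a/H >= 0.07 AND focusing length
    L_f <= total spiral length;
#2  sortability: the calibrated lift/Dean force ratio R_F lies inside a band
    (default [0.5, 5.5], the printed sortable extremes for 6-20 um);
#3  throughput: reported (ml/min), no hard threshold.

The outlet junction is abstracted as a streamtube partition: the upstream
width splits into bands whose width fractions equal each outlet's balanced
flow fraction (plug-flow approximation; a parabolic-profile alternative is
provided).  The cut-off size is the particle whose predicted streamline
coincides with the innermost dividing boundary; tuning moves either the flow
or the bifurcation position until that holds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .config import CUTOFF_DIAMETER, CUTOFF_FORCE_RATIO, Device
from .errors import CalibrationMissingError, SpiralSortError, TuningInfeasibleError
from .focusing import equilibrium_distance, focusing_length
from .geometry import UM, ChannelCrossSection, OutletChannel, OutletNetwork
from .hydraulics import (
    FlowCondition,
    balance_outlet_flows,
    si_to_ul_min,
)
from .inertial import (
    CRITICAL_CONFINEMENT_RATIO,
    ParticleSpec,
    confinement_ratio,
    dean_number,
    force_ratio,
    lift_coefficient,
    reynolds_number,
)

DEFAULT_FORCE_RATIO_BAND = (0.5, 5.5)
# the band edges are one-decimal quantities; admit ratios within half a
# printed ULP of the band (0.498 and 5.53 are inside a [0.5, 5.5] band)
FORCE_RATIO_BAND_TOLERANCE = 0.05
TUNING_TOLERANCE = 0.1e-6  # m; |streamline - boundary| at convergence
SEPARATION_RANGE = 2e-6    # m; verification probes cut-off +/- 1 um


@dataclass(frozen=True)
class DesignReport:
    """Pass/fail verdicts per requirement, with every quantity echoed."""

    device_name: str
    flow_ul_min: float
    reynolds: float
    dean_min: float
    dean_max: float
    throughput_ml_min: float
    table: pd.DataFrame  # one row per size: CR, Lf, R_F, per-requirement flags

    @property
    def all_pass(self) -> bool:
        return bool(self.table[["req1_pass", "req2_pass"]].all().all())


def check_requirements(
    device: Device,
    cond: FlowCondition | None = None,
    sizes_um: Sequence[float] = (6, 8, 10, 12, 16, 20),
    rf_band: tuple[float, float] = DEFAULT_FORCE_RATIO_BAND,
) -> DesignReport:
    """Evaluate requirements #1-#3 for each particle size."""
    if len(sizes_um) == 0:
        raise ValueError("need at least one particle size")
    if device.calibration_k is None:
        raise CalibrationMissingError(
            "device has no calibration constant; use Device.calibrated()"
        )
    cond = cond or device.design_flow
    cs, geom, fluid = device.cross_section, device.spiral, device.fluid
    re = reynolds_number(fluid, cs, cond.flow_rate)
    rows = []
    for a_um in sizes_um:
        p = ParticleSpec.from_um(a_um)
        cr = confinement_ratio(p, cs)
        lf = focusing_length(p, cond, cs, device.lift_model, fluid)
        cl = lift_coefficient(device.lift_model, re, cs, p)
        rf = force_ratio(
            p, cond, geom, cs, device.lift_model, k=device.calibration_k, fluid=fluid
        ).ratio
        rows.append(
            {
                "size_um": a_um,
                "CR": cr,
                "Lf_mm": lf * 1e3,
                "C_L": cl,
                "R_F": rf,
                "req1_pass": cr >= CRITICAL_CONFINEMENT_RATIO
                and lf <= geom.total_length,
                "req2_pass": (rf_band[0] - FORCE_RATIO_BAND_TOLERANCE
                              <= rf
                              <= rf_band[1] + FORCE_RATIO_BAND_TOLERANCE),
            }
        )
    return DesignReport(
        device_name=device.name,
        flow_ul_min=cond.flow_ul_min,
        reynolds=re,
        dean_min=dean_number(re, cs, geom.outer_radius),
        dean_max=dean_number(re, cs, geom.inner_radius),
        throughput_ml_min=cond.flow_ul_min / 1000.0,
        table=pd.DataFrame(rows),
    )


def _parabolic_fraction_to_width(f: np.ndarray) -> np.ndarray:
    """Invert the parabolic-profile cumulative flow F(t)=3t^2-2t^3 per fraction."""
    out = np.empty_like(f)
    for i, fi in enumerate(f):
        out[i] = brentq(lambda t: 3 * t**2 - 2 * t**3 - fi, 0.0, 1.0, xtol=1e-14)
    return out


def dividing_streamline(
    network: OutletNetwork,
    flows: Mapping[str, float] | None = None,
    partition: Literal["plug", "parabolic"] = "plug",
) -> np.ndarray:
    """Band boundaries (m from the inner wall) partitioning the upstream width.

    Under the plug-flow streamtube approximation the band widths are the flow
    fractions times the upstream width; the parabolic alternative accounts for
    a 1-D Poiseuille profile across the width.  Boundaries are returned inner
    to outer (N-1 values for N outlets).
    """
    if flows is None:
        flows = balance_outlet_flows(network, 1.0)
    q = np.array([flows[label] for label in network.labels], dtype=float)
    fractions = q / q.sum()
    if not math.isclose(float(fractions.sum()), 1.0, rel_tol=1e-9):
        raise SpiralSortError("outlet flow fractions do not sum to 1")
    cum = np.cumsum(fractions)[:-1]
    if partition == "plug":
        widths = cum
    elif partition == "parabolic":
        widths = _parabolic_fraction_to_width(cum)
    else:
        raise ValueError(f"unknown partition {partition!r}")
    return widths * network.upstream_width


def streamline_in_upstream_coords(distance_main: float, cs_main: ChannelCrossSection,
                                  network: OutletNetwork) -> float:
    """Map a main-channel streamline position to the widened outlet section.

    Streamtubes preserve their flow fraction through the widening, so under
    plug flow the width fraction is conserved: d_up = (d/W) * W_up.
    """
    return distance_main / cs_main.width * network.upstream_width


@dataclass(frozen=True)
class TuneResult:
    device: Device
    condition: FlowCondition
    free_variable: str
    tuned_value: float             # flow in ul/min, or boundary position in m
    residual: float                # |streamline - boundary| in m
    verification: pd.DataFrame     # sizes cutoff-1, cutoff, cutoff+1


def _cutoff_streamline_up(device: Device, cond: FlowCondition, a: float) -> float:
    pred = equilibrium_distance(
        ParticleSpec(a), cond, device.cross_section, device.spiral,
        device.lift_model, k=device.calibration_k, fluid=device.fluid,
    )
    if not pred.focused:
        raise TuningInfeasibleError(
            f"target size {a/UM:.3g} um is below the critical confinement ratio"
        )
    return streamline_in_upstream_coords(pred.distance, device.cross_section,
                                         device.outlets)


def _verification_table(device: Device, cond: FlowCondition, cutoff: float,
                        boundary: float) -> pd.DataFrame:
    rows = []
    for a in (cutoff - SEPARATION_RANGE / 2, cutoff, cutoff + SEPARATION_RANGE / 2):
        d_up = _cutoff_streamline_up(device, cond, a)
        rows.append(
            {
                "size_um": round(a / UM, 6),
                "dist_up_um": d_up / UM,
                "boundary_um": boundary / UM,
                "side": "inner" if d_up <= boundary else "outer",
            }
        )
    return pd.DataFrame(rows)


def _retarget_outlet_widths(network: OutletNetwork,
                            fractions: np.ndarray) -> OutletNetwork:
    """Resize outlet widths (fixed total width and heights) to realize given
    balanced-flow fractions: f_i ~ 1/S_i implies w_i ~ 1/f_i."""
    total_w = sum(o.cross_section.width for o in network.outlets)
    inv = 1.0 / fractions
    new_w = total_w * inv / inv.sum()
    outlets = tuple(
        OutletChannel(
            o.label,
            ChannelCrossSection(w, o.cross_section.height),
            o.length,
        )
        for o, w in zip(network.outlets, new_w)
    )
    return OutletNetwork(outlets=outlets, upstream_width=network.upstream_width)


def tune_cutoff(
    device: Device,
    target_cutoff: float = CUTOFF_DIAMETER,
    free_variable: Literal["flow", "bifurcation_position"] = "flow",
    cond: FlowCondition | None = None,
    tolerance: float = TUNING_TOLERANCE,
    flow_bracket: tuple[float, float] = (0.25, 4.0),
    max_iter: int = 200,
) -> TuneResult:
    """Place the target-size streamline on the innermost dividing boundary.

    ``free_variable="flow"`` bisects the flow rate (bracket given as multiples
    of the current design flow) until the predicted streamline of the
    ``target_cutoff`` particle coincides with the boundary to ``tolerance``
    (0.1 um).  ``"bifurcation_position"`` instead moves the boundary onto the
    streamline at the fixed flow, re-deriving outlet widths that realize the
    required flow split at fixed total outlet width.  The result carries a
    verification table for the cut-off and its +/- 1 um neighbors (the 2 um
    separation range).
    """
    if device.calibration_k is None:
        raise CalibrationMissingError("tune_cutoff needs a calibrated device")
    cond = cond or device.design_flow
    boundaries = dividing_streamline(device.outlets)
    boundary = float(boundaries[0])

    if free_variable == "flow":
        def residual(q_si: float) -> float:
            c = FlowCondition(flow_rate=q_si, fluid=device.fluid)
            return _cutoff_streamline_up(device, c, target_cutoff) - boundary

        q0 = cond.flow_rate
        lo, hi = flow_bracket[0] * q0, flow_bracket[1] * q0
        r_lo, r_hi = residual(lo), residual(hi)
        if r_lo == 0.0:
            q_star = lo
        elif r_hi == 0.0:
            q_star = hi
        elif r_lo * r_hi > 0:
            raise TuningInfeasibleError(
                f"no flow in [{si_to_ul_min(lo):.0f}, {si_to_ul_min(hi):.0f}] ul/min "
                f"puts the {target_cutoff/UM:g} um streamline on the boundary"
            )
        else:
            # bracketed bisection (Brent-refined) far past the 0.1 um position
            # tolerance, so re-tuning a tuned device is a fixed point
            q_star = float(brentq(residual, lo, hi, xtol=q0 * 1e-12,
                                  maxiter=max_iter))
        if abs(residual(q_star)) > tolerance:
            raise TuningInfeasibleError("flow bisection did not converge")
        tuned_cond = FlowCondition(flow_rate=q_star, fluid=device.fluid)
        # calibration k stays pinned to the original reference condition;
        # recalibrating here would move the streamline it just placed
        tuned_device = replace(device, design_flow=tuned_cond)
        res = abs(_cutoff_streamline_up(tuned_device, tuned_cond, target_cutoff)
                  - boundary)
        return TuneResult(
            device=tuned_device,
            condition=tuned_cond,
            free_variable="flow",
            tuned_value=si_to_ul_min(q_star),
            residual=res,
            verification=_verification_table(tuned_device, tuned_cond,
                                             target_cutoff, boundary),
        )

    if free_variable == "bifurcation_position":
        d_up = _cutoff_streamline_up(device, cond, target_cutoff)
        w_up = device.outlets.upstream_width
        if not (0 < d_up < w_up):
            raise TuningInfeasibleError(
                "target streamline lies outside the upstream width"
            )
        f_inner = d_up / w_up
        old_fracs = np.array(
            list(balance_outlet_flows(device.outlets, 1.0).values())
        )
        rest = old_fracs[1:] / old_fracs[1:].sum() * (1.0 - f_inner)
        new_fracs = np.concatenate([[f_inner], rest])
        new_network = _retarget_outlet_widths(device.outlets, new_fracs)
        tuned_device = replace(device, outlets=new_network)
        new_boundary = float(dividing_streamline(new_network)[0])
        res = abs(d_up - new_boundary)
        return TuneResult(
            device=tuned_device,
            condition=cond,
            free_variable="bifurcation_position",
            tuned_value=new_boundary,
            residual=res,
            verification=_verification_table(tuned_device, cond,
                                             target_cutoff, new_boundary),
        )

    raise ValueError(f"unknown free variable {free_variable!r}")
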