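"""Pressure-flow relations for the spiral channel and its outlet network.

The channel obeys Hagen-Poiseuille behavior: pressure drop is linear in flow
through the rectangular-duct resistance.  The spiral's own resistance uses the
straight-duct formula (curvature corrections are second order at De <= 31).
PDMS compliance is handled empirically through a measured Q_exp/Q_th ratio
curve rather than a constitutive model.

Outlet flows at a shared junction follow the balance law Q_i * S_i = const
(equal pressure drops under Hagen-Poiseuille), i.e. Q_i proportional to 1/S_i.

Units: SI internally (Pa, m^3/s); external interfaces quote mbar and ul/min.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DesignInfeasibleError, InvalidGeometryError
from .geometry import ChannelCrossSection, OutletNetwork

# external unit conversions
UL_PER_MIN = 1e-9 / 60.0  # m^3/s per (ul/min)
MBAR = 100.0              # Pa per mbar
ML_PER_MIN = 1e-6 / 60.0  # m^3/s per (ml/min)


def ul_min_to_si(q_ul_min: float) -> float:
    return q_ul_min * UL_PER_MIN


def si_to_ul_min(q_si: float) -> float:
    return q_si / UL_PER_MIN


@dataclass(frozen=True)
class FluidSpec:
    """Newtonian carrier fluid; blood dilutions >= 1:94 are water-like."""

    density: float = 1000.0    # kg/m^3
    viscosity: float = 1.0e-3  # Pa*s

    def __post_init__(self) -> None:
        if self.density <= 0 or self.viscosity <= 0:
            raise ValueError("fluid density and viscosity must be positive")


WATER = FluidSpec()


def mean_velocity(flow_rate: float, cs: ChannelCrossSection) -> float:
    """Bulk velocity V = Q/S in m/s for Q in m^3/s."""
    area = cs.area
    if area <= 0:
        raise InvalidGeometryError("zero cross-section area")
    return flow_rate / area


def rect_channel_resistance(
    cs: ChannelCrossSection,
    length: float,
    fluid: FluidSpec = WATER,
    n_terms: int = 50,
) -> float:
    """Hydraulic resistance of a rectangular duct, Pa*s/m^3.

    Exact Fourier-series solution of laminar flow in a rectangle, truncated at
    ``n_terms`` odd modes::

        R = 12 mu L / (w h^3 * [1 - sum_{n odd} (192/pi^5)(h/w)(1/n^5) tanh(n pi w / 2h)])

    with h <= w (the duct is transposed internally if given the other way).
    """
    if length <= 0:
        raise InvalidGeometryError("channel length must be positive")
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    w, h = cs.width, cs.height
    if h > w:
        w, h = h, w
    n = np.arange(1, 2 * n_terms, 2, dtype=float)  # odd modes
    series = np.sum(np.tanh(n * math.pi * w / (2.0 * h)) / n**5)
    factor = 1.0 - (192.0 / math.pi**5) * (h / w) * series
    return 12.0 * fluid.viscosity * length / (w * h**3 * factor)


def rect_channel_resistance_approx(
    cs: ChannelCrossSection, length: float, fluid: FluidSpec = WATER
) -> float:
    """Closed-form shallow-duct approximation R = 12 mu L / (w h^3 (1 - 0.63 h/w)).

    Agrees with the series solution within 1% for h/w <= 0.3.
    """
    if length <= 0:
        raise InvalidGeometryError("channel length must be positive")
    w, h = cs.width, cs.height
    if h > w:
        w, h = h, w
    return 12.0 * fluid.viscosity * length / (w * h**3 * (1.0 - 0.63 * h / w))


def pressure_drop(
    flow_rate: float,
    cs: ChannelCrossSection,
    length: float,
    fluid: FluidSpec = WATER,
) -> float:
    """Hagen-Poiseuille pressure loss dP = R*Q in Pa."""
    return rect_channel_resistance(cs, length, fluid) * flow_rate


@dataclass(frozen=True)
class DeformationCurve:
    """Measured PDMS compliance as tabulated (pressure, Q_exp/Q_th) points.

    Ratios must be >= 1 (positive pressure can only dilate the channel).
    Evaluation interpolates linearly between points and holds the end values
    constant outside the tabulated range.
    """

    pressures: tuple[float, ...]  # Pa, increasing
    ratios: tuple[float, ...]

    def __post_init__(self) -> None:
        p = tuple(float(x) for x in self.pressures)
        r = tuple(float(x) for x in self.ratios)
        if len(p) != len(r) or len(p) == 0:
            raise ValueError("pressures and ratios must be equal-length, non-empty")
        if any(b <= a for a, b in zip(p, p[1:])):
            raise ValueError("pressures must be strictly increasing")
        if any(x < 1.0 for x in r):
            raise ValueError("Q_exp/Q_th ratios must be >= 1")
        object.__setattr__(self, "pressures", p)
        object.__setattr__(self, "ratios", r)

    def __call__(self, pressure: float) -> float:
        return float(np.interp(pressure, self.pressures, self.ratios))

    @classmethod
    def from_csv(cls, path) -> "DeformationCurve":
        """Read a two-column delimited file with header pressure_mbar, ratio."""
        df = pd.read_csv(path)
        return cls(
            pressures=tuple(df["pressure_mbar"].to_numpy(float) * MBAR),
            ratios=tuple(df["ratio"].to_numpy(float)),
        )


@dataclass(frozen=True)
class FlowCondition:
    """Operating point given either as a flow or as a driving pressure.

    Exactly one of flow/pressure is primary.  When driven by pressure, the
    flow is resolved through the device resistance, optionally corrected by a
    measured compliance curve: Q = ratio(P) * P / R.
    """

    flow_rate: float          # m^3/s (always resolved)
    pressure: float | None = None  # Pa, when pressure-driven
    fluid: FluidSpec = WATER

    def __post_init__(self) -> None:
        if not self.flow_rate > 0:
            raise ValueError("flow rate must be positive")

    @classmethod
    def from_flow_ul_min(cls, q_ul_min: float, fluid: FluidSpec = WATER) -> "FlowCondition":
        return cls(flow_rate=ul_min_to_si(q_ul_min), fluid=fluid)

    @classmethod
    def from_pressure_mbar(
        cls,
        p_mbar: float,
        resistance: float,
        fluid: FluidSpec = WATER,
        compliance: DeformationCurve | None = None,
    ) -> "FlowCondition":
        p = p_mbar * MBAR
        q = p / resistance
        if compliance is not None:
            q *= compliance(p)
        return cls(flow_rate=q, pressure=p, fluid=fluid)

    @property
    def flow_ul_min(self) -> float:
        return si_to_ul_min(self.flow_rate)

    def mean_velocity(self, cs: ChannelCrossSection) -> float:
        return mean_velocity(self.flow_rate, cs)


def balance_outlet_flows(network: OutletNetwork, q_total: float) -> dict[str, float]:
    """Split a total flow over outlets so that Q_i * S_i is equal across them.

    Equal outlet pressure drops under Hagen-Poiseuille give Q_i proportional
    to 1/S_i; the split is solved analytically and conserves mass exactly.
    Returns {label: flow} in the units of ``q_total``.
    """
    if q_total <= 0:
        raise ValueError("total flow must be positive")
    areas = np.asarray(network.areas())
    if np.any(areas <= 0):
        raise InvalidGeometryError("all outlet areas must be positive")
    weights = 1.0 / areas
    flows = q_total * weights / weights.sum()
    # enforce exact conservation against float round-off
    flows[-1] = q_total - flows[:-1].sum()
    return dict(zip(network.labels, flows))


def outlet_flow_fractions(network: OutletNetwork) -> dict[str, float]:
    """Balanced flow fractions (sum to 1), inner outlet first."""
    flows = balance_outlet_flows(network, 1.0)
    return flows


def required_outlet_resistances(
    network: OutletNetwork,
    q_total: float,
    fluid: FluidSpec = WATER,
    target_dp: float | None = None,
) -> pd.DataFrame:
    """Per-outlet resistances/lengths that equalize outlet pressure drops.

    At the balanced flows Q_i ~ 1/S_i, each outlet's current pressure drop is
    dP_i = R(cs_i, L_i) * Q_i.  The common target drop defaults to the largest
    dP_i so every correction lengthens a channel (feasible by construction);
    an explicit ``target_dp`` below some balanced dP_i raises
    DesignInfeasibleError, since a channel cannot have negative length.

    Returns a table with columns: outlet, area_um2, Q_ul_min, dP_baseline_mbar,
    dP_target_mbar, R_required, length_required_mm.
    """
    flows = balance_outlet_flows(network, q_total)
    rows = []
    baseline_dp = {}
    for o in network.outlets:
        r = rect_channel_resistance(o.cross_section, o.length, fluid)
        baseline_dp[o.label] = r * flows[o.label]
    dp_target = max(baseline_dp.values()) if target_dp is None else float(target_dp)
    for o in network.outlets:
        q = flows[o.label]
        r_req = dp_target / q
        # resistance is linear in length, so scale the baseline
        r_base = rect_channel_resistance(o.cross_section, o.length, fluid)
        length_req = o.length * r_req / r_base
        if length_req <= 0 or r_req <= 0:
            raise DesignInfeasibleError(
                f"outlet {o.label!r}: required length {length_req:.3g} m is not realizable"
            )
        if target_dp is not None and dp_target < baseline_dp[o.label] * (1 - 1e-12):
            raise DesignInfeasibleError(
                f"outlet {o.label!r}: target pressure drop below baseline; "
                "shortening below zero length is impossible"
            )
        rows.append(
            {
                "outlet": o.label,
                "area_um2": o.cross_section.area / 1e-12,
                "Q_ul_min": si_to_ul_min(q),
                "dP_baseline_mbar": baseline_dp[o.label] / MBAR,
                "dP_target_mbar": dp_target / MBAR,
                "R_required": r_req,
                "length_required_mm": length_req * 1e3,
            }
        )
    return pd.DataFrame(rows)


def deformation_ratio(
    measured_q: float,
    cs: ChannelCrossSection,
    length: float,
    pressure: float,
    fluid: FluidSpec = WATER,
    rigidity_threshold: float = 1.05,
) -> tuple[float, bool]:
    """Q_exp/Q_th with Q_th = P/R for a rigid device.

    Returns (ratio, within_rigidity) where the flag marks the 5%-deformation
    acceptance band (ratio <= 1.05) used to qualify PDMS curing protocols.
    """
    if pressure <= 0:
        raise ValueError("pressure must be positive")
    q_th = pressure / rect_channel_resistance(cs, length, fluid)
    ratio = measured_q / q_th
    return ratio, ratio <= rigidity_threshold
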