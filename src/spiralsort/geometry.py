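"""Double-spiral channel geometry.

All lengths are stored internally in SI meters.  Constructors with unit
suffixes (``from_um``) are provided because device drawings quote channel
dimensions in micrometers and loop radii in millimeters.

The double spiral is modeled as an ordered list of loop curvature radii
(innermost first).  Arc length per loop is approximated by a full circle,
:math:`2\\pi R_i`; the S-shaped reversal between the two sub-spirals
contributes no extra length unless an explicit total-length override is given
(Archimedean arcs differ from circles by well under 1% at millimeter radii).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

from .errors import InvalidGeometryError

# unit helpers (SI base is the meter)
UM = 1e-6
MM = 1e-3


@dataclass(frozen=True)
class ChannelCrossSection:
    """Rectangular duct cross-section, width x height, in meters."""

    width: float
    height: float

    def __post_init__(self) -> None:
        if not (self.width > 0 and self.height > 0):
            raise InvalidGeometryError(
                f"cross-section dimensions must be positive, "
                f"got {self.width} x {self.height} m"
            )

    @classmethod
    def from_um(cls, width_um: float, height_um: float) -> "ChannelCrossSection":
        return cls(width_um * UM, height_um * UM)

    @property
    def area(self) -> float:
        """Cross-sectional area W*H in m^2."""
        return self.width * self.height

    @property
    def aspect_ratio(self) -> float:
        """AR = H/W (shallow ducts have AR < 1)."""
        return self.height / self.width

    @property
    def hydraulic_diameter(self) -> float:
        """D_h = 2WH/(W+H) in m."""
        return 2.0 * self.width * self.height / (self.width + self.height)


def cross_section_area(cs: ChannelCrossSection) -> float:
    """Duct area S = W*H in m^2."""
    return cs.area


def aspect_ratio(cs: ChannelCrossSection) -> float:
    """Duct aspect ratio AR = H/W."""
    return cs.aspect_ratio


def hydraulic_diameter(cs: ChannelCrossSection) -> float:
    """Rectangular-duct hydraulic diameter D_h = 2WH/(W+H) in m."""
    return cs.hydraulic_diameter


@dataclass(frozen=True)
class SpiralGeometry:
    """Loop layout of a (double) spiral channel.

    Parameters
    ----------
    loop_radii
        Curvature radii in meters, strictly increasing, innermost first.
    loop_spacing
        Nominal radial distance between successive loops (m); informational
        when radii were supplied explicitly.
    total_length
        Channel length in meters.  Defaults to the sum of full-circle arcs.
    direction_switch_loop
        Index after which the winding sense flips (double spiral); affects
        only the orientation flag of the Dean vortices, not any magnitude.
    reconstructed
        True when the radii were back-solved from published Dean-number
        anchors rather than taken from a drawing.
    """

    loop_radii: tuple[float, ...]
    loop_spacing: float = 0.0
    total_length: float = field(default=0.0)
    direction_switch_loop: int | None = None
    reconstructed: bool = False

    def __post_init__(self) -> None:
        if len(self.loop_radii) == 0:
            raise InvalidGeometryError("spiral must have at least one loop")
        radii = tuple(float(r) for r in self.loop_radii)
        if any(r <= 0 for r in radii):
            raise InvalidGeometryError("loop radii must be positive")
        if any(b <= a for a, b in zip(radii, radii[1:])):
            raise InvalidGeometryError("loop radii must be strictly increasing")
        object.__setattr__(self, "loop_radii", radii)
        if self.total_length <= 0:
            object.__setattr__(self, "total_length", sum(2 * math.pi * r for r in radii))

    @property
    def n_loops(self) -> int:
        return len(self.loop_radii)

    @property
    def inner_radius(self) -> float:
        return self.loop_radii[0]

    @property
    def outer_radius(self) -> float:
        return self.loop_radii[-1]

    @property
    def mid_radius(self) -> float:
        """Radial midpoint, the reference radius for single-number force ratios."""
        return 0.5 * (self.inner_radius + self.outer_radius)

    def with_total_length(self, total_length: float) -> "SpiralGeometry":
        return replace(self, total_length=total_length)


def generate_loop_radii(
    inner_radius: float,
    spacing: float,
    n_loops: int,
    total_length: float | None = None,
) -> SpiralGeometry:
    """Build an arithmetic-progression spiral: radii[i] = inner + i*spacing.

    ``total_length``, when given (e.g. from a drawing), overrides the
    computed sum of circular arcs.
    """
    if n_loops < 1:
        raise InvalidGeometryError("n_loops must be >= 1")
    if inner_radius <= 0:
        raise InvalidGeometryError("inner_radius must be positive")
    if spacing < 0:
        raise InvalidGeometryError("spacing must be non-negative")
    radii = tuple(inner_radius + i * spacing for i in range(n_loops))
    geom = SpiralGeometry(loop_radii=radii, loop_spacing=spacing)
    if total_length is not None:
        geom = geom.with_total_length(total_length)
    return geom


@dataclass(frozen=True)
class OutletChannel:
    """One outlet branch: its cross-section and resistance-setting length."""

    label: str
    cross_section: ChannelCrossSection
    length: float  # m

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise InvalidGeometryError(f"outlet {self.label!r}: length must be positive")


@dataclass(frozen=True)
class OutletNetwork:
    """Outlet branches sharing one upstream junction, listed inner to outer."""

    outlets: tuple[OutletChannel, ...]
    upstream_width: float  # m, width of the channel just before the junction

    def __post_init__(self) -> None:
        object.__setattr__(self, "outlets", tuple(self.outlets))
        if len(self.outlets) < 2:
            raise InvalidGeometryError("outlet network needs at least two outlets")
        labels = [o.label for o in self.outlets]
        if len(set(labels)) != len(labels):
            raise InvalidGeometryError(f"outlet labels must be unique, got {labels}")
        if self.upstream_width <= 0:
            raise InvalidGeometryError("upstream width must be positive")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(o.label for o in self.outlets)

    def areas(self) -> tuple[float, ...]:
        return tuple(o.cross_section.area for o in self.outlets)


def make_outlet_network(
    specs: Sequence[tuple[str, float, float, float]],
    upstream_width_um: float,
) -> OutletNetwork:
    """Convenience builder from (label, width_um, height_um, length_mm) tuples."""
    outlets = tuple(
        OutletChannel(label, ChannelCrossSection.from_um(w, h), l * MM)
        for label, w, h, l in specs
    )
    return OutletNetwork(outlets=outlets, upstream_width=upstream_width_um * UM)
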