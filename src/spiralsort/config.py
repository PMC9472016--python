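"""Device configuration: schema, presets, parsing and serialization.

A device config is a nested key-value document (YAML) with explicit unit
suffixes on every length key::

    name: WB1
    cross_section: {width_um: 300, height_um: 85}
    spiral:
      n_loops: 12
      spacing_um: 450
      inner_radius_mm: 0.4          # or: radii_mm: [..] explicit list
      total_length_mm: 334          # optional override of the arc-length sum
    outlets:
      - {label: inner, width_um: 70, height_um: 85, length_mm: 10}
      - ...
    upstream_width_um: 300
    fluid: {density_kg_m3: 1000, viscosity_pa_s: 1.0e-3}
    design_flow_ul_min: 860
    lift_model: dimensionless_geometric
    calibration_k: null             # filled in by calibrate()

Unknown keys are rejected with the offending path in the message; configs
round-trip losslessly through serialize/parse.

Two named presets ship with the package:

* ``WB1``  - original design: 300x85 um duct, trifurcated outlet
  (inner 70, middle 145, outer 85 um wide, all 85 um high), 860 ul/min.
* ``WB1r`` - redesign: 300x89 um effective duct, channel widened to 500 um
  before a bifurcation (inner 103, outer 412 um wide), 940 ul/min.

The per-loop radii of the spiral are not published; preset radii are
reconstructed by back-solving the two printed Dean-number anchors
(De = 30.39 at the innermost loop, 6.94 at the outermost, at the WB1 design
flow) and interpolating linearly, flagged ``reconstructed``.  The printed
total length (334 mm) overrides the circular-arc sum.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from .errors import ConfigError
from .geometry import (
    MM,
    UM,
    ChannelCrossSection,
    OutletNetwork,
    SpiralGeometry,
    generate_loop_radii,
    make_outlet_network,
)
from .hydraulics import (
    FlowCondition,
    FluidSpec,
    rect_channel_resistance,
)
from .inertial import (
    LiftModel,
    calibrate_force_ratio,
    radius_for_dean,
    reynolds_number,
)

# published design anchors used to reconstruct the unpublished loop radii
DEAN_INNER_LOOP = 30.39
DEAN_OUTER_LOOP = 6.94
ANCHOR_FLOW_UL_MIN = 860.0
CUTOFF_DIAMETER = 9e-6        # design cut-off size
CUTOFF_FORCE_RATIO = 1.12     # design-point lift/Dean ratio at the cut-off


@dataclass(frozen=True)
class Device:
    """A fully resolved sorter: geometry, hydraulics and force-model choices."""

    name: str
    cross_section: ChannelCrossSection
    spiral: SpiralGeometry
    outlets: OutletNetwork
    fluid: FluidSpec
    design_flow: FlowCondition
    lift_model: LiftModel
    calibration_k: float | None = None

    @property
    def resistance(self) -> float:
        """Straight-duct hydraulic resistance of the spiral channel, Pa*s/m^3."""
        return rect_channel_resistance(
            self.cross_section, self.spiral.total_length, self.fluid
        )

    def calibrated(
        self,
        target_ratio: float = CUTOFF_FORCE_RATIO,
        reference_diameter: float = CUTOFF_DIAMETER,
    ) -> "Device":
        """Return a copy with k solved so R_F(reference) = target at the design flow."""
        k = calibrate_force_ratio(
            self.design_flow, self.spiral, self.cross_section, self.lift_model,
            target_ratio=target_ratio,
            reference_diameter=reference_diameter,
            fluid=self.fluid,
        )
        return replace(self, calibration_k=k)


def _reconstructed_spiral(
    cs: ChannelCrossSection,
    n_loops: int = 12,
    total_length_mm: float = 334.0,
    fluid: FluidSpec = FluidSpec(),
) -> SpiralGeometry:
    """Radii interpolated between the Dean anchors at the published design flow."""
    cond = FlowCondition.from_flow_ul_min(ANCHOR_FLOW_UL_MIN, fluid)
    re = reynolds_number(fluid, cs, cond.flow_rate)
    r_in = radius_for_dean(DEAN_INNER_LOOP, re, cs)
    r_out = radius_for_dean(DEAN_OUTER_LOOP, re, cs)
    radii = tuple(np.linspace(r_in, r_out, n_loops))
    geom = SpiralGeometry(
        loop_radii=radii,
        loop_spacing=(r_out - r_in) / (n_loops - 1),
        direction_switch_loop=n_loops // 2,
        reconstructed=True,
    )
    return geom.with_total_length(total_length_mm * MM)


def _preset_wb1() -> Device:
    cs = ChannelCrossSection.from_um(300, 85)
    return Device(
        name="WB1",
        cross_section=cs,
        spiral=_reconstructed_spiral(cs),
        outlets=make_outlet_network(
            [("inner", 70, 85, 10.0), ("middle", 145, 85, 10.0), ("outer", 85, 85, 10.0)],
            upstream_width_um=300,
        ),
        fluid=FluidSpec(),
        design_flow=FlowCondition.from_flow_ul_min(860),
        lift_model=LiftModel.from_name("dimensionless_geometric"),
    )


def _preset_wb1r() -> Device:
    # effective measured height 89 um (profilometry), outlet branches drawn at 85
    cs = ChannelCrossSection.from_um(300, 89)
    return Device(
        name="WB1r",
        cross_section=cs,
        spiral=_reconstructed_spiral(ChannelCrossSection.from_um(300, 85)),
        outlets=make_outlet_network(
            [("inner", 103, 85, 10.0), ("outer", 412, 85, 10.0)],
            upstream_width_um=500,
        ),
        fluid=FluidSpec(),
        design_flow=FlowCondition.from_flow_ul_min(940),
        lift_model=LiftModel.from_name("dimensionless_geometric"),
    )


_PRESETS = {"WB1": _preset_wb1, "WB1r": _preset_wb1r}


def get_preset(name: str, calibrate: bool = True) -> Device:
    """Resolve a bundled device preset by name (case-sensitive: WB1, WB1r)."""
    try:
        device = _PRESETS[name]()
    except KeyError:
        raise ConfigError(f"unknown preset {name!r}; available: {sorted(_PRESETS)}")
    return device.calibrated() if calibrate else device


# ---------------------------------------------------------------------------
# schema-checked parsing

_TOP_KEYS = {
    "name", "cross_section", "spiral", "outlets", "upstream_width_um",
    "fluid", "design_flow_ul_min", "lift_model", "calibration_k",
}
_CS_KEYS = {"width_um", "height_um"}
_SPIRAL_KEYS = {
    "n_loops", "spacing_um", "inner_radius_mm", "radii_mm", "total_length_mm",
}
_OUTLET_KEYS = {"label", "width_um", "height_um", "length_mm"}
_FLUID_KEYS = {"density_kg_m3", "viscosity_pa_s"}


def _check_keys(section: Mapping[str, Any], allowed: set[str], where: str) -> None:
    if not isinstance(section, Mapping):
        raise ConfigError(f"{where}: expected a mapping, got {type(section).__name__}")
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(
            f"{where}: unknown key(s) {sorted(unknown)} (allowed: {sorted(allowed)}); "
            "note that every length key carries an explicit unit suffix"
        )


def _require(section: Mapping[str, Any], key: str, where: str) -> Any:
    if key not in section:
        raise ConfigError(f"{where}: missing required key {key!r}")
    return section[key]


def device_from_dict(doc: Mapping[str, Any]) -> Device:
    """Build a Device from a parsed config mapping, validating the schema."""
    _check_keys(doc, _TOP_KEYS, "config")
    name = str(doc.get("name", "custom"))

    cs_doc = _require(doc, "cross_section", "config")
    _check_keys(cs_doc, _CS_KEYS, "config.cross_section")
    cs = ChannelCrossSection.from_um(
        float(_require(cs_doc, "width_um", "config.cross_section")),
        float(_require(cs_doc, "height_um", "config.cross_section")),
    )

    sp_doc = _require(doc, "spiral", "config")
    _check_keys(sp_doc, _SPIRAL_KEYS, "config.spiral")
    total_length = (
        float(sp_doc["total_length_mm"]) * MM if "total_length_mm" in sp_doc else None
    )
    if "radii_mm" in sp_doc:
        radii = tuple(float(r) * MM for r in sp_doc["radii_mm"])
        spiral = SpiralGeometry(loop_radii=radii)
        if total_length is not None:
            spiral = spiral.with_total_length(total_length)
    else:
        spiral = generate_loop_radii(
            float(_require(sp_doc, "inner_radius_mm", "config.spiral")) * MM,
            float(sp_doc.get("spacing_um", 0.0)) * UM,
            int(_require(sp_doc, "n_loops", "config.spiral")),
            total_length=total_length,
        )

    outlet_docs = _require(doc, "outlets", "config")
    if not isinstance(outlet_docs, list) or len(outlet_docs) < 2:
        raise ConfigError("config.outlets: expected a list of >= 2 outlets")
    specs = []
    for i, od in enumerate(outlet_docs):
        where = f"config.outlets[{i}]"
        _check_keys(od, _OUTLET_KEYS, where)
        specs.append(
            (
                str(_require(od, "label", where)),
                float(_require(od, "width_um", where)),
                float(_require(od, "height_um", where)),
                float(_require(od, "length_mm", where)),
            )
        )
    outlets = make_outlet_network(
        specs, upstream_width_um=float(_require(doc, "upstream_width_um", "config"))
    )

    fl_doc = doc.get("fluid", {})
    _check_keys(fl_doc, _FLUID_KEYS, "config.fluid")
    fluid = FluidSpec(
        density=float(fl_doc.get("density_kg_m3", 1000.0)),
        viscosity=float(fl_doc.get("viscosity_pa_s", 1.0e-3)),
    )

    flow = FlowCondition.from_flow_ul_min(
        float(_require(doc, "design_flow_ul_min", "config")), fluid
    )
    try:
        lift = LiftModel.from_name(str(doc.get("lift_model", "dimensionless_geometric")))
    except ValueError as exc:
        raise ConfigError(f"config.lift_model: {exc}") from exc
    k = doc.get("calibration_k")
    return Device(
        name=name, cross_section=cs, spiral=spiral, outlets=outlets,
        fluid=fluid, design_flow=flow, lift_model=lift,
        calibration_k=None if k is None else float(k),
    )


def device_to_dict(device: Device) -> dict[str, Any]:
    """Serialize a Device to the config mapping (explicit radii, lossless)."""
    return {
        "name": device.name,
        "cross_section": {
            "width_um": device.cross_section.width / UM,
            "height_um": device.cross_section.height / UM,
        },
        "spiral": {
            "radii_mm": [r / MM for r in device.spiral.loop_radii],
            "total_length_mm": device.spiral.total_length / MM,
        },
        "outlets": [
            {
                "label": o.label,
                "width_um": o.cross_section.width / UM,
                "height_um": o.cross_section.height / UM,
                "length_mm": o.length / MM,
            }
            for o in device.outlets.outlets
        ],
        "upstream_width_um": device.outlets.upstream_width / UM,
        "fluid": {
            "density_kg_m3": device.fluid.density,
            "viscosity_pa_s": device.fluid.viscosity,
        },
        "design_flow_ul_min": device.design_flow.flow_ul_min,
        "lift_model": device.lift_model.variant.value,
        "calibration_k": device.calibration_k,
    }


def load_device_config(source: str | Path) -> Device:
    """Load a device from a YAML config file, or resolve a preset by name."""
    if isinstance(source, str) and source in _PRESETS:
        return get_preset(source)
    path = Path(source)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping):
        raise ConfigError(f"{path}: config root must be a mapping")
    return device_from_dict(doc)


def save_device_config(device: Device, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(device_to_dict(device), fh, sort_keys=False)


def config_hash(device: Device) -> str:
    """Stable sha256 of the canonical config, for report provenance."""
    canonical = json.dumps(device_to_dict(device), sort_keys=True)
    return hashlib.sha256(canonical.encode("utf-8")).hexdigest()[:16]
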