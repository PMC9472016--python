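"""Result serialization and the synthetic fixture generator.

Delimited outputs are comma-separated with a header row, UTF-8, period
decimal separator, floats at 6 significant digits.  Structured summaries are
JSON and always embed the seed, the calibration constant and a config hash.

The fixture generator emulates the bead calibration experiments: streamline
tables over a bead-size x pressure grid (6-20 um beads, 1500-4000 mbar in
100 mbar steps) produced by a chosen lift model plus seeded Gaussian noise,
and a mixed bead population table (2e5 beads/ml split across six sizes).
Fixture dispersion is synthetic bookkeeping, never physics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .config import Device, config_hash
from .focusing import equilibrium_distance
from .geometry import UM
from .hydraulics import FlowCondition, MBAR
from .inertial import LiftModel, ParticleSpec, calibrate_force_ratio
from .sorting import SortingOutcome, default_dispersion

FLOAT_FORMAT = "%.6g"

DEFAULT_FIXTURE_SIZES_UM = (6.0, 8.0, 10.0, 12.0, 20.0)
DEFAULT_PRESSURE_GRID_MBAR = tuple(range(1500, 4001, 100))
MIXTURE_SIZES_UM = (6.0, 8.0, 10.0, 12.0, 16.0, 20.0)
MIXTURE_TOTAL_PER_ML = 200_000


@dataclass(frozen=True)
class FixtureSpec:
    """Deterministic recipe for synthetic measurement/population tables.

    ``model`` names the generating lift model (``None`` = the device's own).
    """

    seed: int
    sizes_um: tuple[float, ...] = DEFAULT_FIXTURE_SIZES_UM
    pressures_mbar: tuple[float, ...] = DEFAULT_PRESSURE_GRID_MBAR
    noise_um: float = 0.0
    model: str | None = None


def generate_fixture(
    spec: FixtureSpec, device: Device
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic streamline measurements and a mixed bead population table.

    Streamline distances come from the device's own lift model at each
    pressure point (pressure resolved to flow through the rigid-device
    resistance), perturbed by seeded Gaussian noise of sd ``noise_um``; the
    reported dispersion column uses the synthetic sigma(a) fixture model.
    """
    rng = np.random.default_rng(spec.seed)
    resistance = device.resistance
    sigma = default_dispersion(device.outlets.upstream_width)
    if spec.model is None:
        model, k = device.lift_model, device.calibration_k
    else:
        model = LiftModel.from_name(spec.model)
        k = calibrate_force_ratio(
            device.design_flow, device.spiral, device.cross_section, model,
            fluid=device.fluid,
        )
    rows = []
    for p_mbar in spec.pressures_mbar:
        cond = FlowCondition.from_pressure_mbar(p_mbar, resistance, device.fluid)
        for size_um in spec.sizes_um:
            pred = equilibrium_distance(
                ParticleSpec.from_um(size_um), cond, device.cross_section,
                device.spiral, model, k=k, fluid=device.fluid,
            )
            d_um = pred.distance / UM + rng.normal(0.0, spec.noise_um)
            rows.append(
                {
                    "size_um": size_um,
                    "pressure_mbar": float(p_mbar),
                    "dist_mean_um": d_um,
                    "dist_sd_um": sigma(size_um * UM) / UM,
                }
            )
    measurements = pd.DataFrame(rows)

    per_size = MIXTURE_TOTAL_PER_ML // len(MIXTURE_SIZES_UM)
    populations = pd.DataFrame(
        {
            "label": [f"{s:g}um" for s in MIXTURE_SIZES_UM],
            "mean_size_um": MIXTURE_SIZES_UM,
            "sd_um": [0.0] * len(MIXTURE_SIZES_UM),
            "count": [per_size] * len(MIXTURE_SIZES_UM),
        }
    )
    return measurements, populations


def write_table(df: pd.DataFrame, path: str | Path,
                index: bool = False) -> Path:
    """Write a delimited table with stable column order and fixed precision."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=index, float_format=FLOAT_FORMAT)
    return path


def write_outcome_report(
    outcome: SortingOutcome,
    device: Device,
    path: str | Path,
) -> tuple[Path, Path]:
    """Persist a sorting outcome: counts matrix (CSV) + JSON summary.

    The summary carries seed, calibration constant and config hash so a run
    is reproducible from its own report.
    """
    path = Path(path)
    counts_path = path.with_suffix(".counts.csv")
    write_table(outcome.counts, counts_path, index=True)
    summary = {
        "device": device.name,
        "config_hash": config_hash(device),
        "calibration_k": device.calibration_k,
        "seed": outcome.seed,
        "cutoff_um": outcome.cutoff / UM,
        "boundaries_um": list(outcome.boundaries_um),
        "yields": {k: round(v, 6) for k, v in outcome.yields.items()},
        "global_yield": round(outcome.global_yield, 6),
    }
    summary_path = path.with_suffix(".summary.json")
    summary_path.parent.mkdir(parents=True, exist_ok=True)
    with open(summary_path, "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return counts_path, summary_path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
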