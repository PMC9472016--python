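"""Monte-Carlo virtual sorting experiments and enrichment statistics.

Each simulated particle draws a diameter from its population, is placed at
the predicted equilibrium streamline for that size (mapped to the widened
outlet section), jittered by a Gaussian streamline dispersion, and assigned
to the outlet whose streamtube band contains it.  Particles below the
critical confinement ratio never focus; they are spread uniformly across the
width (Dean-mixing fallback) with a warning.

Yields follow the bead-experiment definitions: for populations above the
cut-off, inner-outlet count over total; below the cut-off, the summed
non-inner counts over total.  Removal, fold-difference, dilution and
parallel-device throughput arithmetic round out the enrichment statistics.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import CUTOFF_DIAMETER, Device
from .design import dividing_streamline, streamline_in_upstream_coords
from .errors import CalibrationMissingError
from .focusing import equilibrium_distance
from .geometry import UM
from .hydraulics import FlowCondition, si_to_ul_min, ul_min_to_si
from .inertial import (
    CRITICAL_CONFINEMENT_RATIO,
    ParticleSpec,
    confinement_ratio,
)


@dataclass(frozen=True)
class ParticlePopulation:
    """A particle population: point mass (sd=0) or truncated normal sizes."""

    label: str
    mean_size: float  # m
    sd: float         # m; 0 means a monodisperse population
    count: int        # particles per simulated sample (or per ml)

    def __post_init__(self) -> None:
        if self.mean_size <= 0:
            raise ValueError("mean size must be positive")
        if self.sd < 0 or self.count < 0:
            raise ValueError("sd and count must be non-negative")

    @classmethod
    def from_um(cls, label: str, mean_um: float, sd_um: float, count: int
                ) -> "ParticlePopulation":
        return cls(label, mean_um * UM, sd_um * UM, count)

    def draw_sizes(self, rng: np.random.Generator) -> np.ndarray:
        if self.sd == 0:
            return np.full(self.count, self.mean_size)
        sizes = rng.normal(self.mean_size, self.sd, self.count)
        # truncate at zero by redrawing (negligible mass at these CVs)
        bad = sizes <= 0
        while bad.any():
            sizes[bad] = rng.normal(self.mean_size, self.sd, int(bad.sum()))
            bad = sizes <= 0
        return sizes


def read_population_table(path) -> list[ParticlePopulation]:
    """Read a delimited table with header label, mean_size_um, sd_um, count."""
    df = pd.read_csv(path)
    return [
        ParticlePopulation.from_um(str(r.label), float(r.mean_size_um),
                                   float(r.sd_um), int(r.count))
        for r in df.itertuples()
    ]


def default_dispersion(width: float, reference_size: float = 9e-6,
                       floor: float = 0.5e-6, scale: float = 0.03
                       ) -> Callable[[float], float]:
    """Synthetic streamline-dispersion model for fixtures (not physics):
    sigma(a) = max(floor, scale * W * reference_size / a)."""
    def sigma(a: float) -> float:
        return max(floor, scale * width * reference_size / a)
    return sigma


def constant_dispersion(sigma_um: float) -> Callable[[float], float]:
    return lambda a: sigma_um * UM


@dataclass(frozen=True)
class SortingOutcome:
    """Counts matrix plus the derived yields and provenance."""

    counts: pd.DataFrame          # index: population label, columns: outlet labels
    yields: Mapping[str, float]   # per-population yield in [0, 1]
    global_yield: float
    seed: int
    cutoff: float                 # m
    boundaries_um: tuple[float, ...]

    def population_total(self, label: str) -> int:
        return int(self.counts.loc[label].sum())


def _distance_interpolator(
    sizes: np.ndarray,
    device: Device,
    cond: FlowCondition,
    n_grid: int = 64,
) -> Callable[[np.ndarray], np.ndarray]:
    """Vectorized size -> focused distance (m) via a solved grid.

    Unique sizes up to ``n_grid`` are solved exactly; continuous distributions
    are interpolated on a monotone grid spanning the drawn range.
    """
    def solve(a: float) -> float:
        return equilibrium_distance(
            ParticleSpec(a), cond, device.cross_section, device.spiral,
            device.lift_model, k=device.calibration_k, fluid=device.fluid,
        ).distance

    unique = np.unique(sizes)
    if unique.size <= n_grid:
        table = {a: solve(a) for a in unique}
        return lambda arr: np.array([table[a] for a in arr])
    grid = np.linspace(unique.min(), unique.max(), n_grid)
    d_grid = np.array([solve(a) for a in grid])
    return lambda arr: np.interp(arr, grid, d_grid)


def simulate_sort(
    populations: Sequence[ParticlePopulation],
    device: Device,
    cond: FlowCondition | None = None,
    dispersion: Callable[[float], float] | None = None,
    seed: int | None = None,
    cutoff: float = CUTOFF_DIAMETER,
    tie: str = "inner",
) -> SortingOutcome:
    """Virtual sorting run; ``seed`` is mandatory (reproducibility contract)."""
    if seed is None:
        raise ValueError("simulate_sort requires an explicit seed")
    if device.calibration_k is None:
        raise CalibrationMissingError("simulate_sort needs a calibrated device")
    if tie not in ("inner", "outer"):
        raise ValueError("tie must be 'inner' or 'outer'")
    cond = cond or device.design_flow
    rng = np.random.default_rng(seed)
    network = device.outlets
    w_main = device.cross_section.width
    w_up = network.upstream_width
    boundaries = dividing_streamline(network)
    labels = network.labels
    if dispersion is None:
        dispersion = default_dispersion(w_up)

    count_rows = {}
    yields = {}
    correct = 0
    total = 0
    h = device.cross_section.height
    for pop in populations:
        sizes = pop.draw_sizes(rng)
        n = sizes.size
        positions = np.empty(n)
        focused_mask = sizes / h >= CRITICAL_CONFINEMENT_RATIO
        if (~focused_mask).any():
            warnings.warn(
                f"population {pop.label!r}: {int((~focused_mask).sum())} particles "
                "below critical confinement; assigned by Dean-mixing fallback "
                "(uniform over width)",
                stacklevel=2,
            )
            positions[~focused_mask] = rng.uniform(0.0, w_up,
                                                   int((~focused_mask).sum()))
        if focused_mask.any():
            d_of = _distance_interpolator(sizes[focused_mask], device, cond)
            d_main = d_of(sizes[focused_mask])
            d_up = d_main / w_main * w_up
            sigma = np.array([dispersion(a) for a in sizes[focused_mask]])
            d_up = d_up + rng.normal(0.0, 1.0, int(focused_mask.sum())) * sigma
            positions[focused_mask] = d_up

        # band assignment; a particle exactly on a boundary goes to the
        # inner-side outlet by default (favors capture sensitivity)
        side = "left" if tie == "inner" else "right"
        idx = np.searchsorted(boundaries, positions, side=side)
        counts = np.bincount(idx, minlength=len(labels))
        count_rows[pop.label] = counts

        if n:
            if pop.mean_size > cutoff:
                good = int(counts[0])  # inner outlet collects the large fraction
            else:
                good = int(counts[1:].sum())
            yields[pop.label] = good / n
            correct += good
            total += n

    counts_df = pd.DataFrame.from_dict(count_rows, orient="index",
                                       columns=list(labels))
    counts_df.index.name = "population"
    return SortingOutcome(
        counts=counts_df,
        yields=yields,
        global_yield=correct / total if total else float("nan"),
        seed=seed,
        cutoff=cutoff,
        boundaries_um=tuple(boundaries / UM),
    )


def removal_percentage(retained_count: float, baseline_count: float) -> float:
    """Percent of a background population excluded: 100*(1 - retained/baseline).

    A retained count above baseline yields a negative removal, reported with a
    warning rather than clamped.
    """
    if baseline_count <= 0:
        raise ValueError("baseline count must be positive")
    removal = 100.0 * (1.0 - retained_count / baseline_count)
    if removal < 0:
        warnings.warn("retained count exceeds baseline; negative removal reported",
                      stacklevel=2)
    return removal


def fold_difference(count_a: float, count_b: float) -> tuple[float, int]:
    """Detection-efficiency fold change a/b, raw and floor-rounded."""
    if count_b <= 0:
        raise ValueError("fold difference undefined for non-positive denominator")
    raw = count_a / count_b
    return raw, math.floor(raw)


@dataclass(frozen=True)
class ThroughputPlan:
    """Parallel-device processing plan for a diluted blood sample."""

    n_devices: int
    per_device_flow: float   # m^3/s
    dilution_factor: float   # 1:x dilution => x
    blood_volume: float      # m^3
    combined_flow: float = field(init=False)
    diluted_volume: float = field(init=False)
    processing_time_min: int = field(init=False)

    def __post_init__(self) -> None:
        if min(self.n_devices, self.per_device_flow, self.dilution_factor,
               self.blood_volume) <= 0:
            raise ValueError("all throughput-plan inputs must be positive")
        combined = self.n_devices * self.per_device_flow
        diluted = self.blood_volume * self.dilution_factor
        object.__setattr__(self, "combined_flow", combined)
        object.__setattr__(self, "diluted_volume", diluted)
        # whole minutes, rounded up
        minutes = diluted / (combined * 60.0)
        # relative guard so an exact whole-minute result never rounds up twice
        object.__setattr__(self, "processing_time_min",
                           math.ceil(minutes * (1.0 - 1e-9)))

    @property
    def combined_flow_ml_min(self) -> float:
        return si_to_ul_min(self.combined_flow) / 1000.0


def throughput_plan(
    n_devices: int,
    per_device_flow_ul_min: float,
    blood_volume_ml: float,
    dilution_factor: float = 1.0,
) -> ThroughputPlan:
    """Combined flow, diluted volume and ceil-minutes processing time."""
    return ThroughputPlan(
        n_devices=n_devices,
        per_device_flow=ul_min_to_si(per_device_flow_ul_min),
        dilution_factor=dilution_factor,
        blood_volume=blood_volume_ml * 1e-6,
    )


DILUTION_THRESHOLD = 94.0


def dilution_guard(dilution_x: float) -> bool:
    """Advisory check that a 1:x blood dilution is at or above the 1:94 floor
    below which sorting efficiency degrades."""
    return dilution_x >= DILUTION_THRESHOLD
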