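"""End-to-end synthetic benchmark workflows.

These compose the generators with the measurement pipelines the way a
validation experiment would: render ground-truthed inputs, run the full
measurement chain, and return measured values alongside the truth.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Sequence

import numpy as np

from .cells import DetectionLimits, auto_tune, measure_cells
from .halo import HaloMeasurement, HaloParams, measure_plate
from .synth import CellFieldParams, PlateTruth, generate_cell_field, generate_plate_image

__all__ = [
    "DEFAULT_POPULATION_LIMITS",
    "measure_length_population",
    "dose_series_round_trip",
]

DEFAULT_POPULATION_LIMITS = DetectionLimits(
    min_area=100,
    max_area=6000,
    min_elongation=1.2,
    max_elongation=10.0,
    max_complexity=1.15,
)


def measure_length_population(
    n_cells: int,
    length_mean: float,
    length_cv: float = 0.20,
    snr: float = 5.0,
    cells_per_field: int = 50,
    seed: int = 0,
    limits: DetectionLimits = DEFAULT_POPULATION_LIMITS,
    pixel_size: float = 0.1,
) -> tuple[np.ndarray, np.ndarray]:
    """Render a population over several fields and measure it end to end.

    Detection is auto-tuned on the first field and the tuned parameters are
    reused for the rest, as in a batch acquired under constant imaging
    conditions.  Returns (measured lengths in px, true lengths in px); the
    measured sample can be slightly smaller than ``n_cells`` if the detector
    drops a cell.
    """
    cell_intensity = 500.0
    base = CellFieldParams(
        n_cells=cells_per_field,
        length_mean=length_mean,
        length_cv=length_cv,
        cell_intensity=cell_intensity,
        noise_sd=cell_intensity / snr,
        pixel_size=pixel_size,
        seed=0,
    )
    rng = np.random.default_rng(seed)
    counts = [cells_per_field] * (n_cells // cells_per_field)
    if n_cells % cells_per_field:
        counts.append(n_cells % cells_per_field)

    measured: list[float] = []
    truth: list[float] = []
    tuning = None
    for count in counts:
        params = replace(base, n_cells=count, seed=int(rng.integers(0, 2**31 - 1)))
        image, truths = generate_cell_field(params)
        if tuning is None:
            tuning = auto_tune(image, limits)
        ms = measure_cells(image, limits, pixel_size=pixel_size, tuning=tuning)
        measured.extend(m.length_px for m in ms)
        truth.extend(t.length for t in truths)
    return np.asarray(measured), np.asarray(truth)


def dose_series_round_trip(
    amounts: Sequence[float],
    slope: float = 90.0,
    pixel_size_mm: float = 0.05,
    disk_diameter_mm: float = 6.0,
    radius_noise_cv: float = 0.02,
    n_artifacts: int = 8,
    image_noise_sd: float = 5.0,
    shape: tuple[int, int] = (1200, 1200),
    seed: int = 0,
) -> tuple[list[PlateTruth], list[float], list[HaloMeasurement]]:
    """Generate a plate dose series with r² = slope x amount and remeasure it.

    Each plate's true halo radius (net of the disk) is r = sqrt(slope x A) mm
    with multiplicative noise of CV ``radius_noise_cv``, rendered at
    ``pixel_size_mm`` per pixel with ``n_artifacts`` lawn specks.  Returns
    (plate truths, true net halo diameters in mm, pipeline measurements).
    """
    rng = np.random.default_rng(seed)
    params = HaloParams(
        disk_diameter=disk_diameter_mm, pixel_size=pixel_size_mm, unit="mm"
    )
    truths: list[PlateTruth] = []
    true_d_mm: list[float] = []
    measurements: list[HaloMeasurement] = []
    center = (shape[1] / 2.0, shape[0] / 2.0)
    for amount in amounts:
        r_mm = float(np.sqrt(slope * amount))
        r_mm *= 1.0 + radius_noise_cv * float(rng.standard_normal())
        clearing_px = 2.0 * r_mm / pixel_size_mm + disk_diameter_mm / pixel_size_mm
        truth = PlateTruth(
            shape=shape,
            disk_center=center,
            disk_diameter=disk_diameter_mm / pixel_size_mm,
            halo_diameter=clearing_px,
            n_artifacts=n_artifacts,
        )
        image = generate_plate_image(
            truth, noise_sd=image_noise_sd, seed=int(rng.integers(0, 2**31 - 1))
        )
        truths.append(truth)
        true_d_mm.append(2.0 * r_mm)
        measurements.append(measure_plate(image, params))
    return truths, true_d_mm, measurements
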