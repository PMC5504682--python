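"""Ground-truthed synthetic inputs: micrographs, plate photographs, annotations.

Every downstream stage of the pipeline (cell morphometry, halo quantification,
synteny arithmetic) can be exercised against inputs whose true answer is known,
without downloading any real data.  Cells are rendered as spherocylinders (a rod
of length ``length - width`` capped by two half-disks of diameter ``width``),
the standard idealization of a rod-shaped bacterium; plates are rendered as a
biomass lawn over a red background with a circular clearing (inhibition halo)
around a central white disk filter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_dilation, gaussian_filter
from scipy.special import expit

__all__ = [
    "CellTruth",
    "CellFieldParams",
    "PlateTruth",
    "PlacementError",
    "generate_cell_field",
    "generate_plate_image",
    "generate_toy_annotation",
]

_SQUARE3 = np.ones((3, 3), dtype=bool)


class PlacementError(RuntimeError):
    """Raised when cells cannot be placed without exceeding the overlap budget."""


@dataclass(frozen=True)
class CellTruth:
    """Ground truth for one rendered cell.

    ``length`` is end-to-end including the hemispherical caps, matching the
    bounding-rectangle definition used by the measurement pipeline.  ``angle``
    is the orientation of the long axis in degrees from the image x axis
    (y pointing down), in [0, 180).
    """

    center: tuple[float, float]  # (x, y) in pixels
    length: float  # pixels, cap to cap
    width: float  # pixels
    angle: float  # degrees in [0, 180)
    intensity: float  # fluorescence units above background

    def __post_init__(self) -> None:
        if not (self.length >= self.width > 0):
            raise ValueError("require length >= width > 0")
        if not (0.0 <= self.angle < 180.0):
            raise ValueError("angle must lie in [0, 180)")


@dataclass(frozen=True)
class CellFieldParams:
    """Parameters of a synthetic field of autofluorescent rod cells.

    Length and width are drawn from a lognormal (default) or normal
    distribution parameterized by mean and coefficient of variation; the
    lognormal default guarantees positive support.  Noise is additive
    Gaussian, so SNR = (cell_intensity - background) / noise_sd.
    ``max_overlap`` is the tolerated fraction of a new cell's footprint
    already occupied; the default 0 means non-touching cells separated by at
    least ``min_gap`` pixels (the measurement algorithm has no declumping
    step, so touching cells are a modelled failure mode, not the default).
    """

    shape: tuple[int, int] = (512, 512)  # (rows, cols)
    n_cells: int = 50
    length_mean: float = 40.0  # px
    length_cv: float = 0.15
    width_mean: float = 12.0  # px
    width_cv: float = 0.05
    distribution: str = "lognormal"  # or "normal"
    cell_intensity: float = 500.0  # above background
    background: float = 100.0
    noise_sd: float = 50.0  # SNR 10 by default
    blur_sigma: float = 1.0  # px
    max_overlap: float = 0.0
    min_gap: int = 4  # px clearance enforced when max_overlap == 0
    angle_range: tuple[float, float] = (0.0, 180.0)  # degrees
    pixel_size: float = 0.1  # µm per pixel
    seed: int | None = None
    max_attempts_per_cell: int = 300

    def __post_init__(self) -> None:
        if self.length_mean <= self.width_mean:
            raise ValueError("mean length must exceed mean width")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if not (0.0 <= self.max_overlap <= 1.0):
            raise ValueError("max_overlap must lie in [0, 1]")
        if self.distribution not in ("lognormal", "normal"):
            raise ValueError("distribution must be 'lognormal' or 'normal'")
        lo, hi = self.angle_range
        if not (0.0 <= lo <= hi <= 180.0) or lo >= 180.0:
            raise ValueError("angle_range must satisfy 0 <= lo <= hi <= 180, lo < 180")


def _sample_size(rng: np.random.Generator, family: str, mean: float, cv: float) -> float:
    if cv <= 0:
        return mean
    if family == "lognormal":
        sigma2 = math.log1p(cv * cv)
        mu = math.log(mean) - sigma2 / 2.0
        return float(rng.lognormal(mu, math.sqrt(sigma2)))
    return float(rng.normal(mean, cv * mean))


def _spherocylinder_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    length: float,
    width: float,
    angle_deg: float,
    pad: float,
) -> tuple[slice, slice, np.ndarray]:
    """Rasterize a spherocylinder: pixel centers within width/2 of the axis segment."""
    cx, cy = center
    radius = width / 2.0
    half = max(length - width, 0.0) / 2.0
    theta = math.radians(angle_deg)
    ux, uy = math.cos(theta), math.sin(theta)
    reach = half + radius + pad
    r0 = max(int(math.floor(cy - reach)), 0)
    r1 = min(int(math.ceil(cy + reach)) + 1, shape[0])
    c0 = max(int(math.floor(cx - reach)), 0)
    c1 = min(int(math.ceil(cx + reach)) + 1, shape[1])
    yy = np.arange(r0, r1, dtype=float)[:, None] - cy
    xx = np.arange(c0, c1, dtype=float)[None, :] - cx
    along = xx * ux + yy * uy
    across = -xx * uy + yy * ux
    dx = np.maximum(np.abs(along) - half, 0.0)
    mask = dx * dx + across * across <= radius * radius
    return slice(r0, r1), slice(c0, c1), mask


def generate_cell_field(
    params: CellFieldParams,
) -> tuple[np.ndarray, list[CellTruth]]:
    """Render a field of spherocylindrical cells with known ground truth.

    Returns the float64 grayscale image and one :class:`CellTruth` per placed
    cell.  The same parameters (including seed) give a bit-identical image.

    Raises
    ------
    PlacementError
        If a cell cannot be placed within ``max_attempts_per_cell`` tries
        without exceeding ``max_overlap``.
    """
    rng = np.random.default_rng(params.seed)
    nrows, ncols = params.shape
    canvas = np.zeros((nrows, ncols), dtype=float)
    occupied = np.zeros((nrows, ncols), dtype=bool)
    truths: list[CellTruth] = []

    for i in range(params.n_cells):
        for _ in range(params.max_attempts_per_cell):
            length = _sample_size(rng, params.distribution, params.length_mean, params.length_cv)
            width = _sample_size(rng, params.distribution, params.width_mean, params.width_cv)
            if length < width or width <= 0:
                continue
            lo, hi = params.angle_range
            angle = float(rng.uniform(lo, hi)) if hi > lo else float(lo)
            margin = length / 2.0 + params.min_gap + 2.0
            if 2.0 * margin >= min(nrows, ncols):
                raise PlacementError(
                    f"cell of length {length:.1f} px cannot fit in a {params.shape} image"
                )
            cx = float(rng.uniform(margin, ncols - 1 - margin))
            cy = float(rng.uniform(margin, nrows - 1 - margin))
            pad = params.min_gap + 2.0
            sr, sc, mask = _spherocylinder_mask(
                (nrows, ncols), (cx, cy), length, width, angle, pad
            )
            if params.max_overlap <= 0.0:
                probe = (
                    binary_dilation(mask, structure=_SQUARE3, iterations=params.min_gap)
                    if params.min_gap > 0
                    else mask
                )
                ok = not np.any(occupied[sr, sc] & probe)
            else:
                inter = np.count_nonzero(occupied[sr, sc] & mask)
                ok = inter <= params.max_overlap * np.count_nonzero(mask)
            if ok:
                canvas[sr, sc] += params.cell_intensity * mask
                occupied[sr, sc] |= mask
                truths.append(
                    CellTruth(
                        center=(cx, cy),
                        length=length,
                        width=width,
                        angle=angle,
                        intensity=params.cell_intensity,
                    )
                )
                break
        else:
            raise PlacementError(
                f"failed to place cell {i + 1}/{params.n_cells} after "
                f"{params.max_attempts_per_cell} attempts (overlap budget "
                f"{params.max_overlap})"
            )

    image = canvas + params.background
    if params.blur_sigma > 0:
        image = gaussian_filter(image, params.blur_sigma)
    if params.noise_sd > 0:
        image = image + rng.normal(0.0, params.noise_sd, image.shape)
    return image, truths


@dataclass(frozen=True)
class PlateTruth:
    """Ground truth for one synthetic disk-diffusion plate photograph.

    The clearing (inhibition halo) exposes the red background through the
    lawn; its outer boundary has the stated diameter.  The white disk filter
    sits at the center.  ``edge_softness`` is the width (px) of the logistic
    ramp between lawn and clearing — real halos are diffuse, a hard edge is
    the softness-0 limit.

    Defaults emulate a plate photographed at ~20 px/mm (0.05 mm/px): a 6 mm
    disk filter is 120 px and halos span several hundred px.  The smoothing
    morphology of the halo pipeline erodes 70 px deep, so halos must be
    comfortably larger than that to survive it, as they are at this scale.
    """

    shape: tuple[int, int] = (900, 900)  # (rows, cols)
    disk_center: tuple[float, float] = (450.0, 450.0)  # (x, y) px
    disk_diameter: float = 120.0  # px (6 mm at 20 px/mm)
    halo_diameter: float = 560.0  # px, outer clearing boundary (28 mm)
    lawn_rgb: tuple[float, float, float] = (30.0, 120.0, 60.0)
    background_rgb: tuple[float, float, float] = (230.0, 40.0, 40.0)
    edge_softness: float = 2.0  # px
    n_artifacts: int = 0
    artifact_radius: tuple[float, float] = (5.0, 15.0)  # min, max px

    def __post_init__(self) -> None:
        if self.halo_diameter < self.disk_diameter:
            raise ValueError("halo diameter must be >= disk diameter")
        if self.edge_softness < 0:
            raise ValueError("edge_softness must be >= 0")
        if self.n_artifacts < 0:
            raise ValueError("n_artifacts must be >= 0")


def generate_plate_image(
    truth: PlateTruth,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> np.ndarray:
    """Render an RGB plate photograph (uint8) from its ground truth.

    Artifacts are small bright-red specks painted on the lawn, away from the
    halo edge, emulating reflections and debris that the smoothing morphology
    of the halo pipeline is designed to erase.

    Raises
    ------
    ValueError
        If the halo (plus its soft edge) does not fit inside the image.
    """
    nrows, ncols = truth.shape
    cx, cy = truth.disk_center
    halo_r = truth.halo_diameter / 2.0
    reach = halo_r + 3.0 * truth.edge_softness
    if cx - reach < 0 or cy - reach < 0 or cx + reach > ncols - 1 or cy + reach > nrows - 1:
        raise ValueError("halo exceeds image bounds")

    rng = np.random.default_rng(seed)
    yy = np.arange(nrows, dtype=float)[:, None] - cy
    xx = np.arange(ncols, dtype=float)[None, :] - cx
    dist = np.hypot(xx, yy)

    lawn = np.asarray(truth.lawn_rgb, dtype=float)
    bg = np.asarray(truth.background_rgb, dtype=float)
    if truth.edge_softness > 0:
        ramp = expit((halo_r - dist) / truth.edge_softness)
    else:
        ramp = (dist <= halo_r).astype(float)
    img = lawn[None, None, :] + (bg - lawn)[None, None, :] * ramp[..., None]

    # bright specks on the lawn, clear of the halo's soft edge
    for _ in range(truth.n_artifacts):
        r_lo, r_hi = truth.artifact_radius
        for _ in range(1000):
            radius = float(rng.uniform(r_lo, r_hi))
            sx = float(rng.uniform(radius + 2, ncols - 3 - radius))
            sy = float(rng.uniform(radius + 2, nrows - 3 - radius))
            keepout = halo_r + 4.0 * truth.edge_softness + 2.0 * radius + 10.0
            if math.hypot(sx - cx, sy - cy) > keepout:
                break
        else:
            raise PlacementError("could not place plate artifact outside the halo")
        speck = np.hypot(xx - (sx - cx), yy - (sy - cy)) <= radius
        img[speck] = bg

    disk = dist <= truth.disk_diameter / 2.0
    img[disk] = 255.0

    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, img.shape)
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def generate_toy_annotation(
    genes,
    path,
    genome_id: str = "toygenome",
    source: str = "rodquant",
) -> None:
    """Write a toy GFF3 annotation from ``(gene_id, start, end, strand)`` specs.

    Coordinates are 1-based inclusive.  An empty spec list yields a valid
    header-only file.  The output round-trips through the synteny reader.
    """
    specs = list(genes)
    lines = ["##gff-version 3"]
    if specs:
        max_end = 0
        for gene_id, start, end, strand in specs:
            start, end = int(start), int(end)
            if start > end:
                raise ValueError(f"gene {gene_id!r}: start {start} > end {end}")
            if start < 1:
                raise ValueError(f"gene {gene_id!r}: coordinates must be >= 1")
            if strand not in ("+", "-"):
                raise ValueError(f"gene {gene_id!r}: strand must be '+' or '-'")
            max_end = max(max_end, end)
        lines.append(f"##sequence-region {genome_id} 1 {max_end}")
        for gene_id, start, end, strand in specs:
            attrs = f"ID={gene_id};Name={gene_id};gene={gene_id};locus_tag={gene_id}"
            lines.append(
                "\t".join(
                    [
                        genome_id,
                        source,
                        "gene",
                        str(int(start)),
                        str(int(end)),
                        ".",
                        strand,
                        ".",
                        attrs,
                    ]
                )
            )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
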