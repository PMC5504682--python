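import numpy as np
import pytest

import rodquant as rq

# acceptance window wide enough for the default synthetic cell population
# (lognormal lengths around 40 px, widths around 12 px)
LIMITS = rq.DetectionLimits(
    min_area=100,
    max_area=6000,
    min_elongation=1.2,
    max_elongation=10.0,
    max_complexity=1.15,
)


@pytest.fixture(scope="session")
def default_limits() -> rq.DetectionLimits:
    return LIMITS


@pytest.fixture(scope="session")
def cell_field():
    """A 50-cell field at SNR 10 with its ground truth."""
    params = rq.CellFieldParams(n_cells=50, seed=11)
    image, truths = rq.generate_cell_field(params)
    return params, image, truths


@pytest.fixture(scope="session")
def clean_plate():
    """A hard-edged, noiseless plate with its ground truth."""
    truth = rq.PlateTruth(edge_softness=0.0)
    return truth, rq.generate_plate_image(truth)


@pytest.fixture
def make_gff(tmp_path):
    """Factory writing a toy GFF3 from (id, start, end, strand) specs."""

    def _make(genes, name="toy.gff3", **kwargs):
        path = tmp_path / name
        rq.generate_toy_annotation(genes, path, **kwargs)
        return path

    return _make


def single_cell_image(
    length=50.0, width=10.0, angle=0.0, noise_sd=0.0, blur_sigma=0.0, seed=5
):
    """One deterministic cell on a quiet background."""
    params = rq.CellFieldParams(
        shape=(128, 128),
        n_cells=1,
        length_mean=length,
        length_cv=0.0,
        width_mean=width,
        width_cv=0.0,
        noise_sd=noise_sd,
        blur_sigma=blur_sigma,
        angle_range=(angle, angle),
        seed=seed,
    )
    return rq.generate_cell_field(params)


def sweep_min_rect_area(points, step_deg=0.05):
    """Brute-force oracle: minimum bounding-box area over a rotation sweep."""
    pts = np.asarray(points, dtype=float)
    thetas = np.deg2rad(np.arange(0.0, 90.0, step_deg))
    cos, sin = np.cos(thetas), np.sin(thetas)
    xs = cos[:, None] * pts[None, :, 0] + sin[:, None] * pts[None, :, 1]
    ys = -sin[:, None] * pts[None, :, 0] + cos[:, None] * pts[None, :, 1]
    w = xs.max(axis=1) - xs.min(axis=1)
    h = ys.max(axis=1) - ys.min(axis=1)
    return float((w * h).min())
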