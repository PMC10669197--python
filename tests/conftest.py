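import numpy as np
import pytest

from vesselage.image import BinaryMask, Volume3D
from vesselage.phantom import CurveSpec, GridSpec, make_parametric_curve, rasterize_tube


def random_smooth_polyline(rng: np.random.Generator, n_points: int = 80) -> np.ndarray:
    """Random low-frequency Fourier curve: smooth, non-degenerate, mm scale."""
    t = np.linspace(0.0, 1.0, n_points)
    pts = np.empty((n_points, 3))
    for axis in range(3):
        coef = rng.normal(0.0, 4.0, size=3)
        phase = rng.uniform(0.0, 2 * np.pi, size=3)
        pts[:, axis] = sum(
            c * np.sin((k + 1) * np.pi * t + p) for k, (c, p) in enumerate(zip(coef, phase))
        )
    # add a drift so endpoints never coincide
    pts[:, 0] += 30.0 * t
    return pts


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Haar-ish random rotation matrix via QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


@pytest.fixture(scope="session")
def straight_tube():
    """Noise-free straight tube (radius 3 mm) along z on a 0.5 mm grid."""
    grid = GridSpec(shape=(48, 48, 100), spacing=(0.5, 0.5, 0.5))
    curve = make_parametric_curve(CurveSpec(kind="straight", length=36.0, sample_count=201))
    pts = curve[:, [1, 2, 0]] + np.array([12.0, 12.0, 7.0])  # vertical, centered
    volume, mask = rasterize_tube(pts, [3.0], grid, vessel_intensity=200.0,
                                  background_intensity=50.0, noise_sd=0.0)
    return {"volume": volume, "mask": mask, "polyline": pts, "radius": 3.0, "grid": grid}


@pytest.fixture(scope="session")
def helix_spec():
    return CurveSpec(kind="helix", radius=10.0, pitch=20.0, turns=1.0, sample_count=4001)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
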