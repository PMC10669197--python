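"""Independent tortuosity oracle for parametric phantom curves.

Ground-truth tortuosity values are computed here from closed forms,
adaptive quadrature, and a very dense uniformly-resampled polyline using
law-of-cosines angle arithmetic.  This module deliberately shares no
computation code with :mod:`vesselage.morphometry`: agreement between the
two is asserted in tests, not by construction.
"""

from __future__ import annotations

import numpy as np
from scipy import integrate

from ..morphometry import SegmentTortuosity
from .curves import CurveSpec, make_parametric_curve

__all__ = ["analytic_tortuosity", "dense_polyline_tortuosity"]

_DENSE_POINTS = 200_001


def _closed_form_lengths(spec: CurveSpec) -> tuple[float, float]:
    """(curve length, Euclidean endpoint length) from closed form/quadrature."""
    if spec.kind == "straight":
        return spec.length, spec.length
    if spec.kind == "helix":
        r, c = spec.radius, spec.pitch / (2.0 * np.pi)
        theta_end = 2.0 * np.pi * spec.turns
        lc = theta_end * np.hypot(r, c)
        end = np.array([r * np.cos(theta_end) - r, r * np.sin(theta_end), c * theta_end])
        return float(lc), float(np.linalg.norm(end))
    if spec.kind == "sinusoid":
        a, w = spec.amplitude, spec.wavelength
        speed = lambda x: np.sqrt(1.0 + (a * 2.0 * np.pi / w * np.cos(2.0 * np.pi * x / w)) ** 2)
        lc, _ = integrate.quad(speed, 0.0, spec.span, limit=400)
        end_y = a * np.sin(2.0 * np.pi * spec.span / w)
        return float(lc), float(np.hypot(spec.span, end_y))
    raise ValueError(
        "analytic lengths unsupported for kind 'siphon'; use dense_polyline_tortuosity"
    )


def _uniform_arclength_resample(points: np.ndarray, n_out: int) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    si = np.linspace(0.0, s[-1], n_out)
    return np.column_stack([np.interp(si, s, points[:, k]) for k in range(3)])


def dense_polyline_tortuosity(points: np.ndarray, n_dense: int = _DENSE_POINTS) -> SegmentTortuosity:
    """Tortuosity of an arbitrary polyline via dense uniform resampling and
    law-of-cosines angles (independent of the morphometry code path)."""
    pts = _uniform_arclength_resample(np.asarray(points, dtype=float), n_dense)
    a = np.linalg.norm(pts[1:-1] - pts[:-2], axis=1)
    b = np.linalg.norm(pts[2:] - pts[1:-1], axis=1)
    c = np.linalg.norm(pts[2:] - pts[:-2], axis=1)
    lc = float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))
    l = float(np.linalg.norm(pts[-1] - pts[0]))
    cos_phi = np.clip((a**2 + b**2 - c**2) / (2.0 * a * b), -1.0, 1.0)
    # collinear triples land at cos = -1 only up to rounding in the squared
    # form; snap them so straight curves give an exact zero turning angle
    cos_phi = np.where(cos_phi <= -1.0 + 1e-12, -1.0, cos_phi)
    phi_deg = np.degrees(np.arccos(cos_phi))
    soam = float(np.sum(180.0 - phi_deg) / lc)
    rl = l / lc
    ti = float(np.mean((a + b) / c))
    return SegmentTortuosity(lc=lc, l=l, rl=rl, soam=soam, pad=soam / rl, ti=ti)


def analytic_tortuosity(spec: CurveSpec, n_dense: int = _DENSE_POINTS) -> SegmentTortuosity:
    """Ground-truth tortuosity for straight/helix/sinusoid specs.

    lc, l and RL come from closed forms or quadrature; SOAM, PAD and TI from
    the dense-polyline oracle.  Siphon curves have no closed form and are
    rejected — call :func:`dense_polyline_tortuosity` on their sampled
    points explicitly.
    """
    if spec.kind == "siphon":
        raise ValueError("kind 'siphon' unsupported by analytic_tortuosity (no closed form)")
    lc, l = _closed_form_lengths(spec)
    dense_spec = CurveSpec(**{**spec.__dict__, "sample_count": max(spec.sample_count, 20001)})
    dense = dense_polyline_tortuosity(make_parametric_curve(dense_spec), n_dense)
    rl = l / lc
    return SegmentTortuosity(lc=lc, l=l, rl=rl, soam=dense.soam, pad=dense.soam / rl, ti=dense.ti)
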