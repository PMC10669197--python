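"""Parametric 3D curve generators with known geometry.

Four curve kinds cover the phantom needs: ``straight``, ``helix``,
``sinusoid`` and ``siphon`` (a C1-continuous chain of circular arcs with
optional torsion between arcs, mimicking a carotid-siphon C-shape).
All coordinates are in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["CurveSpec", "make_parametric_curve", "CURVE_KINDS"]

CURVE_KINDS = ("straight", "helix", "sinusoid", "siphon")


@dataclass(frozen=True)
class CurveSpec:
    """Declarative description of a parametric curve.

    Parameters by kind:

    * straight: ``length`` (mm)
    * helix: ``radius`` (mm), ``pitch`` (mm per turn), ``turns``
    * sinusoid: ``amplitude`` (mm, may be 0), ``wavelength`` (mm), ``span`` (mm)
    * siphon: ``arcs`` — sequence of (radius mm, sweep-angle degrees) pairs;
      ``torsion_deg`` — rotation about the tangent applied between arcs
    """

    kind: str
    length: float | None = None
    radius: float | None = None
    pitch: float | None = None
    turns: float | None = None
    amplitude: float | None = None
    wavelength: float | None = None
    span: float | None = None
    arcs: Sequence[tuple[float, float]] = field(default=())
    torsion_deg: float = 0.0
    sample_count: int = 1001

    def __post_init__(self) -> None:
        if self.kind not in CURVE_KINDS:
            raise ValueError(f"unknown curve kind {self.kind!r}; expected one of {CURVE_KINDS}")
        if self.sample_count < 3:
            raise ValueError(f"sample_count must be >= 3, got {self.sample_count}")
        checks: list[tuple[str, float | None]] = []
        if self.kind == "straight":
            checks = [("length", self.length)]
        elif self.kind == "helix":
            checks = [("radius", self.radius), ("pitch", self.pitch), ("turns", self.turns)]
        elif self.kind == "sinusoid":
            checks = [("wavelength", self.wavelength), ("span", self.span)]
            if self.amplitude is None or self.amplitude < 0:
                raise ValueError(f"parameter 'amplitude' must be >= 0, got {self.amplitude}")
        elif self.kind == "siphon":
            if not self.arcs:
                raise ValueError("parameter 'arcs' must be a nonempty sequence of (radius, angle_deg)")
            for i, (r, a) in enumerate(self.arcs):
                if r <= 0:
                    raise ValueError(f"parameter 'arcs[{i}].radius' must be > 0, got {r}")
                if a <= 0:
                    raise ValueError(f"parameter 'arcs[{i}].angle_deg' must be > 0, got {a}")
        for name, value in checks:
            if value is None or value <= 0:
                raise ValueError(f"parameter {name!r} must be > 0, got {value}")


def make_parametric_curve(spec: CurveSpec) -> np.ndarray:
    """Sample the curve as an ordered (sample_count, 3) array of mm points."""
    n = spec.sample_count
    if spec.kind == "straight":
        t = np.linspace(0.0, spec.length, n)
        return np.column_stack([t, np.zeros(n), np.zeros(n)])
    if spec.kind == "helix":
        theta = np.linspace(0.0, 2.0 * np.pi * spec.turns, n)
        r, c = spec.radius, spec.pitch / (2.0 * np.pi)
        return np.column_stack([r * np.cos(theta) - r, r * np.sin(theta), c * theta])
    if spec.kind == "sinusoid":
        x = np.linspace(0.0, spec.span, n)
        y = spec.amplitude * np.sin(2.0 * np.pi * x / spec.wavelength)
        return np.column_stack([x, y, np.zeros(n)])
    return _siphon_points(spec)


def _rodrigues(v: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    return (v * np.cos(angle)
            + np.cross(axis, v) * np.sin(angle)
            + axis * np.dot(axis, v) * (1.0 - np.cos(angle)))


def _siphon_points(spec: CurveSpec) -> np.ndarray:
    """Chain of circular arcs sharing tangents at joints (C1), with an
    optional fixed torsion rotation of the bending plane between arcs."""
    arc_lengths = [r * np.radians(a) for r, a in spec.arcs]
    total = sum(arc_lengths)
    # distribute samples across arcs proportionally to arc length
    counts = [max(2, int(round((n_l / total) * (spec.sample_count - 1)))) for n_l in arc_lengths]
    while sum(counts) + 1 > spec.sample_count:
        counts[int(np.argmax(counts))] -= 1
    while sum(counts) + 1 < spec.sample_count:
        counts[int(np.argmin(counts))] += 1

    p = np.zeros(3)
    tangent = np.array([0.0, 0.0, 1.0])
    normal = np.array([1.0, 0.0, 0.0])
    pts = [p.copy()]
    for (r, a_deg), cnt in zip(spec.arcs, counts):
        alpha = np.radians(a_deg)
        center = p + r * normal
        for theta in np.linspace(0.0, alpha, cnt + 1)[1:]:
            q = center - r * normal * np.cos(theta) + r * tangent * np.sin(theta)
            pts.append(q)
        new_tangent = tangent * np.cos(alpha) + normal * np.sin(alpha)
        new_normal = normal * np.cos(alpha) - tangent * np.sin(alpha)
        p = pts[-1].copy()
        tangent, normal = new_tangent, new_normal
        if spec.torsion_deg:
            normal = _rodrigues(normal, tangent, np.radians(spec.torsion_deg))
    return np.asarray(pts)
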