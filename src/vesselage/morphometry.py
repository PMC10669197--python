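"""Per-segment vessel morphometry: six tortuosity descriptors and seven
diameter statistics.

Conventions (documented because several are ambiguous in the literature):

* Angles are in degrees, so SOAM and PAD carry units of degrees/mm.
* SOAM sums the turning angle ``180 - phi_i`` over interior points and
  divides by the total curve length ``lc``.
* PAD defaults to ``SOAM / RL`` (quotient reading); a ``pad_definition``
  switch selects the product reading ``SOAM * RL`` instead.
* The triangular index averages ``(a_i + b_i) / c_i`` over interior points
  using immediate neighbours on the (uniformly resampled) polyline.
* Diameters are ``2 x`` the anisotropy-aware Euclidean distance transform of
  the binary mask sampled at the voxel containing each centerline point.
* Percentiles use linear interpolation; the standard deviation is the
  population form (divide by N).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image import BinaryMask

__all__ = [
    "SegmentTortuosity",
    "DiameterStats",
    "SegmentFeatures",
    "FEATURE_SUFFIXES",
    "curve_length",
    "euclidean_length",
    "relative_length",
    "soam",
    "product_of_angle_distance",
    "triangular_index",
    "diameters_along",
    "diameter_stats",
    "segment_features",
]

#: Canonical per-segment feature key order (13 values).
FEATURE_SUFFIXES = (
    "lc",
    "l",
    "RL",
    "SOAM",
    "PAD",
    "TI",
    "diam_mean",
    "diam_min",
    "diam_max",
    "diam_std",
    "diam_p25",
    "diam_p50",
    "diam_p75",
)

PAD_DEFINITIONS = ("soam_over_rl", "soam_times_rl")


@dataclass(frozen=True)
class SegmentTortuosity:
    """The six tortuosity descriptors of one vessel segment."""

    lc: float  # curve length, mm
    l: float  # Euclidean endpoint distance, mm
    rl: float  # relative length, dimensionless, (0, 1]
    soam: float  # degrees/mm
    pad: float  # degrees/mm
    ti: float  # dimensionless, >= 1


@dataclass(frozen=True)
class DiameterStats:
    """Seven summary statistics of the per-point diameter sequence (mm)."""

    mean: float
    min: float
    max: float
    std: float
    p25: float
    p50: float
    p75: float


@dataclass(frozen=True)
class SegmentFeatures:
    """All 13 features of a labeled vessel segment."""

    label: str
    tortuosity: SegmentTortuosity
    diameters: DiameterStats

    def values(self) -> tuple[float, ...]:
        t, d = self.tortuosity, self.diameters
        return (t.lc, t.l, t.rl, t.soam, t.pad, t.ti,
                d.mean, d.min, d.max, d.std, d.p25, d.p50, d.p75)

    def to_dict(self) -> dict[str, float]:
        """Features keyed ``{label}_{suffix}`` in the canonical order."""
        return {f"{self.label}_{s}": v for s, v in zip(FEATURE_SUFFIXES, self.values())}

    def is_complete(self) -> bool:
        return all(np.isfinite(v) for v in self.values())


def _as_points(polyline) -> np.ndarray:
    pts = np.asarray(getattr(polyline, "points", polyline), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError(f"expected an (N, 3) polyline, got shape {pts.shape}")
    return pts


def curve_length(polyline) -> float:
    """Sum of consecutive-point Euclidean distances (mm)."""
    pts = _as_points(polyline)
    if len(pts) < 2:
        raise ValueError("curve_length requires at least 2 points")
    return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))


def euclidean_length(polyline) -> float:
    """Straight-line distance between the first and last point (mm)."""
    pts = _as_points(polyline)
    if len(pts) < 2:
        raise ValueError("euclidean_length requires at least 2 points")
    return float(np.linalg.norm(pts[-1] - pts[0]))


def relative_length(polyline) -> float:
    lc = curve_length(polyline)
    l = euclidean_length(polyline)
    if lc == 0.0:
        raise ValueError("relative_length undefined: curve length lc is zero")
    if l == 0.0:
        raise ValueError("relative_length undefined: Euclidean length l is zero (closed loop)")
    return l / lc


def _interior_angles_deg(pts: np.ndarray) -> np.ndarray:
    """Angle phi_i (degrees) at each interior point between the two chords
    to its neighbours; computed via atan2 for stability near 180 degrees."""
    v1 = pts[:-2] - pts[1:-1]
    v2 = pts[2:] - pts[1:-1]
    n1 = np.linalg.norm(v1, axis=1)
    n2 = np.linalg.norm(v2, axis=1)
    if np.any(n1 == 0) or np.any(n2 == 0):
        bad = int(np.argmax((n1 == 0) | (n2 == 0)))
        raise ValueError(f"repeated consecutive points near interior index {bad + 1}; angle undefined")
    cross = np.linalg.norm(np.cross(v1, v2), axis=1)
    dot = np.einsum("ij,ij->i", v1, v2)
    return np.degrees(np.arctan2(cross, dot))


def soam(polyline) -> float:
    """Sum of angle metrics: total turning over curve length (degrees/mm)."""
    pts = _as_points(polyline)
    if len(pts) < 3:
        raise ValueError("soam requires at least 3 points")
    phi = _interior_angles_deg(pts)
    return float(np.sum(180.0 - phi) / curve_length(pts))


def product_of_angle_distance(polyline, pad_definition: str = "soam_over_rl") -> float:
    """PAD combines SOAM with the relative length; default is SOAM / RL."""
    if pad_definition not in PAD_DEFINITIONS:
        raise ValueError(f"pad_definition must be one of {PAD_DEFINITIONS}, got {pad_definition!r}")
    s = soam(polyline)
    rl = relative_length(polyline)
    return s / rl if pad_definition == "soam_over_rl" else s * rl


def triangular_index(polyline) -> float:
    """Mean over interior points of (a + b) / c; >= 1, equal to 1 when straight."""
    pts = _as_points(polyline)
    if len(pts) < 3:
        raise ValueError("triangular_index requires at least 3 points")
    a = np.linalg.norm(pts[1:-1] - pts[:-2], axis=1)
    b = np.linalg.norm(pts[2:] - pts[1:-1], axis=1)
    c = np.linalg.norm(pts[2:] - pts[:-2], axis=1)
    if np.any(c == 0):
        bad = int(np.argmax(c == 0))
        raise ValueError(f"degenerate triangle (c = 0, fold-back) at interior index {bad + 1}")
    return float(np.mean((a + b) / c))


def distance_field(mask: BinaryMask) -> np.ndarray:
    """Anisotropy-aware Euclidean distance transform of the mask (mm)."""
    return ndimage.distance_transform_edt(mask.values, sampling=np.asarray(mask.spacing))


def diameters_along(
    polyline,
    mask: BinaryMask,
    interpolate: bool = False,
    tolerance_voxels: int = 1,
    edt: np.ndarray | None = None,
) -> np.ndarray:
    """Local vessel diameter (mm) at each centerline point.

    Diameter is twice the Euclidean distance transform of the mask
    (``scipy.ndimage.distance_transform_edt`` with per-axis sampling) at the
    voxel containing the point.  Points whose nearest voxel falls outside
    the mask are snapped to the closest in-mask voxel within
    ``tolerance_voxels`` (Chebyshev); beyond that the point is rejected.
    With ``interpolate=True`` the distance field is sampled trilinearly at
    the exact point instead.  ``edt`` accepts a precomputed
    :func:`distance_field` to avoid recomputation across segments.
    """
    pts = _as_points(polyline)
    if len(pts) == 0:
        raise ValueError("diameters_along requires at least one point")
    values = mask.values
    spacing = np.asarray(mask.spacing)
    if edt is None:
        edt = distance_field(mask)
    elif edt.shape != values.shape:
        raise ValueError("precomputed edt shape does not match the mask")
    shape = np.asarray(values.shape)

    out = np.empty(len(pts))
    for i, p in enumerate(pts):
        cont = (p - np.asarray(mask.origin)) / spacing
        vox = np.rint(cont).astype(int)
        if np.any(vox < 0) or np.any(vox >= shape):
            raise ValueError(f"centerline point {i} at {p.tolist()} maps outside the mask grid")
        if not values[tuple(vox)]:
            vox = _snap_into_mask(vox, cont, values, spacing, tolerance_voxels)
            if vox is None:
                raise ValueError(f"centerline point {i} at {p.tolist()} lies outside the mask")
        if interpolate:
            d = float(ndimage.map_coordinates(edt, cont.reshape(3, 1), order=1)[0])
            if d <= 0:  # interpolation straddling the boundary; fall back to voxel value
                d = float(edt[tuple(vox)])
        else:
            d = float(edt[tuple(vox)])
        out[i] = 2.0 * d
    return out


def _snap_into_mask(vox, cont, values, spacing, tol):
    if tol <= 0:
        return None
    shape = np.asarray(values.shape)
    best, best_d = None, np.inf
    rng = range(-tol, tol + 1)
    for di in rng:
        for dj in rng:
            for dk in rng:
                cand = vox + np.array([di, dj, dk])
                if np.any(cand < 0) or np.any(cand >= shape) or not values[tuple(cand)]:
                    continue
                d = float(np.linalg.norm((cand - cont) * spacing))
                if d < best_d - 1e-12 or (abs(d - best_d) <= 1e-12 and best is not None
                                          and tuple(cand) < tuple(best)):
                    best, best_d = cand, d
    return best


def diameter_stats(diameters) -> DiameterStats:
    d = np.asarray(diameters, dtype=float)
    if d.size == 0:
        raise ValueError("diameter_stats requires a nonempty sequence")
    p25, p50, p75 = np.percentile(d, [25, 50, 75])
    return DiameterStats(
        mean=float(np.mean(d)),
        min=float(np.min(d)),
        max=float(np.max(d)),
        std=float(np.std(d)),  # population form
        p25=float(p25),
        p50=float(p50),
        p75=float(p75),
    )


def segment_tortuosity(polyline, pad_definition: str = "soam_over_rl") -> SegmentTortuosity:
    pts = _as_points(polyline)
    return SegmentTortuosity(
        lc=curve_length(pts),
        l=euclidean_length(pts),
        rl=relative_length(pts),
        soam=soam(pts),
        pad=product_of_angle_distance(pts, pad_definition),
        ti=triangular_index(pts),
    )


def segment_features(
    polyline,
    mask: BinaryMask,
    label: str,
    pad_definition: str = "soam_over_rl",
    interpolate_diameters: bool = False,
    edt: np.ndarray | None = None,
) -> SegmentFeatures:
    """Extract the full 13-value feature set of one labeled segment."""
    tort = segment_tortuosity(polyline, pad_definition)
    diam = diameter_stats(
        diameters_along(polyline, mask, interpolate=interpolate_diameters, edt=edt)
    )
    return SegmentFeatures(label=label, tortuosity=tort, diameters=diam)
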