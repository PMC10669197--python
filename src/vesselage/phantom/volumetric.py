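"""End-to-end volumetric phantom subjects.

Each subject is one noisy volume containing three non-overlapping tubes
standing in for the right/left internal carotid arteries and the basilar
artery, together with true endpoints and generative ground truth so the
whole extraction pipeline can be validated without external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ..cohort import SEGMENT_LABELS
from ..image import BinaryMask, Volume3D, save_volume
from ..morphometry import DiameterStats, SegmentFeatures
from .curves import CurveSpec, make_parametric_curve
from .oracle import dense_polyline_tortuosity
from .raster import GridSpec, GroundTruth, _interp_radii, rasterize_tube

__all__ = ["AgeDrivenParams", "VolumetricSubject", "simulate_volumetric_subject", "write_subject"]

DEFAULT_GRID = GridSpec(shape=(128, 128, 96), spacing=(0.5, 0.5, 0.5))

# Per-label placement: mm offset of the curve's local origin, and whether
# the local x axis is mirrored (to mimic left/right symmetry).
_ANCHORS = {
    "R-ICA": (np.array([40.0, 16.0, 9.0]), False),
    "L-ICA": (np.array([16.0, 16.0, 9.0]), True),
    "BA": (np.array([28.0, 40.0, 9.0]), False),
}


@dataclass(frozen=True)
class AgeDrivenParams:
    """Knobs linking subject age to phantom geometry.

    Tube radius grows linearly with age:
    ``radius = base_radius_mm + radius_slope_mm_per_year * (age - 50)``,
    floored at 0.8 mm.  ``tortuosity_scale`` scales the helix radius /
    sinusoid amplitude; ``kinds`` picks the curve kind per segment in
    (R-ICA, L-ICA, BA) order.
    """

    age: float
    base_radius_mm: float = 2.0
    radius_slope_mm_per_year: float = 0.012
    tortuosity_scale: float = 1.0
    kinds: tuple[str, str, str] = ("helix", "helix", "sinusoid")
    noise_sd: float = 10.0
    vessel_intensity: float = 200.0
    background_intensity: float = 50.0

    def radius_mm(self) -> float:
        return max(0.8, self.base_radius_mm + self.radius_slope_mm_per_year * (self.age - 50.0))


@dataclass
class VolumetricSubject:
    volume: Volume3D
    mask: BinaryMask  # combined true mask of the three tubes
    endpoints: dict[str, dict[str, list[int]]]  # per label: endpoint_a / endpoint_b voxels
    truths: dict[str, GroundTruth]
    age: float


def _curve_spec(kind: str, scale: float) -> CurveSpec:
    if kind == "straight":
        return CurveSpec(kind="straight", length=28.0, sample_count=801)
    if kind == "helix":
        return CurveSpec(kind="helix", radius=max(0.5, 4.0 * scale), pitch=28.0, turns=1.0,
                         sample_count=801)
    if kind == "sinusoid":
        return CurveSpec(kind="sinusoid", amplitude=2.0 * scale, wavelength=30.0, span=30.0,
                         sample_count=801)
    raise ValueError(f"unsupported segment curve kind {kind!r}")


def _place(points: np.ndarray, kind: str, anchor: np.ndarray, mirror: bool) -> np.ndarray:
    """Orient the curve so its long axis runs along z, then translate."""
    local = points.copy()
    if kind in ("straight", "sinusoid"):
        # local x is the long axis -> map (x, y, z) to (y, z, x)
        local = local[:, [1, 2, 0]]
    if mirror:
        local[:, 0] = -local[:, 0]
    return local + anchor


def simulate_volumetric_subject(
    params: AgeDrivenParams,
    grid: GridSpec = DEFAULT_GRID,
    seed: int = 0,
) -> VolumetricSubject:
    """One noisy three-tube volume plus endpoints and ground truth.

    Deterministic under ``seed``; rejects configurations whose tubes
    overlap on the grid.
    """
    radius = params.radius_mm()
    masks: dict[str, np.ndarray] = {}
    truths: dict[str, GroundTruth] = {}
    endpoints: dict[str, dict[str, list[int]]] = {}
    origin = np.asarray(grid.origin)
    spacing = np.asarray(grid.spacing)

    for label, kind in zip(SEGMENT_LABELS, params.kinds):
        spec = _curve_spec(kind, params.tortuosity_scale)
        anchor, mirror = _ANCHORS[label]
        pts = _place(make_parametric_curve(spec), kind, anchor, mirror)
        profile = np.full(len(pts), radius)
        _, tube_mask = rasterize_tube(
            pts, profile, grid,
            vessel_intensity=params.vessel_intensity,
            background_intensity=params.background_intensity,
            noise_sd=0.0,
        )
        masks[label] = tube_mask.values
        tort = dense_polyline_tortuosity(pts)
        diam = 2.0 * _interp_radii(pts, profile, np.linspace(0.0, tort.lc, 512))
        stats = DiameterStats(
            mean=float(np.mean(diam)), min=float(np.min(diam)), max=float(np.max(diam)),
            std=float(np.std(diam)), p25=float(np.percentile(diam, 25)),
            p50=float(np.percentile(diam, 50)), p75=float(np.percentile(diam, 75)),
        )
        truths[label] = GroundTruth(
            polyline=pts,
            radius_profile=profile,
            true_features=SegmentFeatures(label=label, tortuosity=tort, diameters=stats),
        )
        vox_a = np.rint((pts[0] - origin) / spacing).astype(int)
        vox_b = np.rint((pts[-1] - origin) / spacing).astype(int)
        endpoints[label] = {"endpoint_a": vox_a.tolist(), "endpoint_b": vox_b.tolist()}

    labels = list(SEGMENT_LABELS)
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            if (masks[labels[i]] & masks[labels[j]]).any():
                raise ValueError(f"tube overlap between segments {labels[i]} and {labels[j]}")

    combined = masks[labels[0]] | masks[labels[1]] | masks[labels[2]]
    values = np.where(combined, params.vessel_intensity, params.background_intensity).astype(float)
    if params.noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = np.clip(values + rng.normal(0.0, params.noise_sd, size=values.shape), 0.0, None)
    spacing_t = tuple(float(s) for s in spacing)
    origin_t = tuple(float(o) for o in origin)
    return VolumetricSubject(
        volume=Volume3D(values=values, spacing=spacing_t, origin=origin_t),
        mask=BinaryMask(values=combined, spacing=spacing_t, origin=origin_t),
        endpoints=endpoints,
        truths=truths,
        age=params.age,
    )


def write_subject(subject: VolumetricSubject, out_dir) -> dict[str, str]:
    """Persist a subject: NIfTI volume, endpoint annotations and a JSON
    ground-truth sidecar (polyline mm, radii mm, true features)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    vol_path = out / "volume.nii.gz"
    save_volume(subject.volume, vol_path)
    ep_path = out / "endpoints.json"
    ep_path.write_text(json.dumps(subject.endpoints, indent=2))
    gt = {
        label: {
            "polyline_mm": t.polyline.tolist(),
            "radii_mm": t.radius_profile.tolist(),
            "true_features": t.true_features.to_dict(),
        }
        for label, t in subject.truths.items()
    }
    gt_path = out / "ground_truth.json"
    gt_path.write_text(json.dumps(gt, indent=2))
    return {"volume": str(vol_path), "endpoints": str(ep_path), "ground_truth": str(gt_path)}
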