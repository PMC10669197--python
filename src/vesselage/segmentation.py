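"""Seeded region growing of bright vessels on a 3D angiography volume.

The inclusion rule is a global intensity threshold, given either absolutely
or as a percentile of the volume's intensities; the grown mask is the set
of above-threshold voxels connected (6- or 26-connectivity) to a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .image import BinaryMask, Volume3D

__all__ = ["SeedSpec", "region_growing", "mask_summary"]

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass(frozen=True)
class SeedSpec:
    """Seeds plus the inclusion rule for region growing.

    Exactly one of ``threshold`` (absolute intensity) or
    ``threshold_percentile`` (percentile of the volume's intensities) must
    be given.
    """

    seeds: Sequence[tuple[int, int, int]]
    threshold: float | None = None
    threshold_percentile: float | None = None
    connectivity: int = 26

    def __post_init__(self) -> None:
        if len(self.seeds) == 0:
            raise ValueError("at least one seed voxel is required")
        if (self.threshold is None) == (self.threshold_percentile is None):
            raise ValueError("give exactly one of threshold or threshold_percentile")
        if self.connectivity not in (6, 26):
            raise ValueError(f"connectivity must be 6 or 26, got {self.connectivity}")
        if self.threshold_percentile is not None and not 0 <= self.threshold_percentile <= 100:
            raise ValueError(f"threshold_percentile must be in [0, 100], got {self.threshold_percentile}")

    def resolve_threshold(self, volume: Volume3D) -> float:
        if self.threshold is not None:
            return float(self.threshold)
        return float(np.percentile(volume.values, self.threshold_percentile))


def region_growing(volume: Volume3D, spec: SeedSpec) -> BinaryMask:
    """Grow the above-threshold region connected to the seeds.

    Deterministic; rejects seeds outside the grid or failing the inclusion
    rule (naming the offending seed).
    """
    thresh = spec.resolve_threshold(volume)
    above = volume.values >= thresh
    shape = np.asarray(volume.shape)
    for seed in spec.seeds:
        s = np.asarray(seed, dtype=int)
        if s.shape != (3,) or np.any(s < 0) or np.any(s >= shape):
            raise ValueError(f"seed {tuple(seed)} is outside the volume grid {tuple(shape)}")
        if not above[tuple(s)]:
            raise ValueError(
                f"seed {tuple(seed)} fails the inclusion rule: intensity "
                f"{volume.values[tuple(s)]:.4g} < threshold {thresh:.4g}"
            )
    labels, _ = ndimage.label(above, structure=_STRUCTURES[spec.connectivity])
    keep = {int(labels[tuple(np.asarray(s, dtype=int))]) for s in spec.seeds}
    keep.discard(0)
    mask = np.isin(labels, sorted(keep))
    return BinaryMask.like(volume, mask)


def largest_component(mask: BinaryMask) -> BinaryMask:
    """Optional post-filter: keep only the largest 26-connected component."""
    labels, n = ndimage.label(mask.values, structure=_STRUCTURES[26])
    if n <= 1:
        return mask
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return BinaryMask.like(mask, labels == int(np.argmax(counts)))


def mask_summary(mask: BinaryMask) -> dict:
    """QC summary: voxel count, physical volume, 26-connected component count."""
    count = int(mask.values.sum())
    _, n_comp = ndimage.label(mask.values, structure=_STRUCTURES[26])
    return {
        "voxel_count": count,
        "volume_mm3": count * float(np.prod(mask.spacing)),
        "component_count": int(n_comp),
    }
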