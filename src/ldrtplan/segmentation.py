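"""Liver-referenced SUV thresholding and target separation.

Gross tumor volumes are delineated on PET by thresholding the SUV volume at
the normal-liver mean plus two standard deviations (the sample, n−1, standard
deviation), then separating the supra-threshold region into discrete
connected components under 6-connectivity (face adjacency).  Components
smaller than a minimum volume are discarded as noise islands — the automated
counterpart of the manual review-and-edit step of a clinical workflow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import ImageVolume, StructureMask, _require_same_grid

__all__ = ["SUVThreshold", "GTVSet", "compute_suv_threshold", "segment_gtvs"]


@dataclass(frozen=True)
class SUVThreshold:
    """Liver-referenced segmentation threshold: value = mu + 2*sigma."""

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    @property
    def value(self) -> float:
        return self.mu + 2.0 * self.sigma


@dataclass
class GTVSet:
    """Separated targets: pairwise-disjoint single-component masks, sorted
    inferior→superior by centroid."""

    gtvs: list[StructureMask]
    threshold: SUVThreshold
    discarded_components: int

    def __len__(self) -> int:
        return len(self.gtvs)

    def __iter__(self):
        return iter(self.gtvs)

    def summary(self) -> list[dict]:
        return [
            {
                "id": g.name,
                "centroid_mm": [round(float(c), 3) for c in g.centroid_mm()],
                "volume_cc": round(g.volume_cc, 4),
            }
            for g in self.gtvs
        ]


def compute_suv_threshold(pet: ImageVolume, liver_mask: StructureMask) -> SUVThreshold:
    """Sample mean and sample (n−1) standard deviation of PET under the liver
    mask; threshold value is mu + 2·sigma."""
    _require_same_grid(pet.grid, liver_mask.grid, "PET and liver mask")
    if liver_mask.is_empty():
        raise ValueError("liver mask is empty: SUV threshold undefined")
    vals = pet.values[liver_mask.mask]
    mu = float(vals.mean())
    sigma = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    return SUVThreshold(mu=mu, sigma=sigma)


# face adjacency in 3D
_CONN6 = ndimage.generate_binary_structure(3, 1)


def segment_gtvs(
    pet: ImageVolume,
    threshold: SUVThreshold,
    body: StructureMask,
    min_volume_cc: float = 0.1,
) -> GTVSet:
    """Threshold PET inside the body and separate targets.

    A voxel is supra-threshold iff SUV >= threshold.value (inclusive — the
    threshold is a *lower* bound).  Connected components are labeled under
    6-connectivity; components smaller than ``min_volume_cc`` are discarded
    and counted.  No liver exclusion is applied: normal liver sits below
    mu + 2·sigma on average, and avid disease inside the liver should be found.
    An empty result is valid.
    """
    _require_same_grid(pet.grid, body.grid, "PET and body mask")
    if threshold.value < 0:
        raise ValueError("threshold must be >= 0")
    binary = body.mask & (pet.values >= threshold.value)
    labels, n = ndimage.label(binary, structure=_CONN6)
    if n == 0:
        return GTVSet([], threshold, 0)

    vox_cc = pet.grid.voxel_volume_cc
    counts = np.bincount(labels.ravel())[1:]  # skip background
    keep = np.flatnonzero(counts * vox_cc >= min_volume_cc) + 1
    discarded = int(n - keep.size)

    gtvs = []
    for lab in keep:
        m = StructureMask(f"GTV_{lab}", labels == lab, pet.grid, role="GTV",
                          derivation=f"PET >= {threshold.value:.4g} (liver mu+2sigma)")
        gtvs.append(m)
    gtvs.sort(key=lambda g: g.centroid_mm()[2])  # inferior -> superior
    for i, g in enumerate(gtvs, start=1):
        g.name = f"GTV_{i}"
    return GTVSet(gtvs, threshold, discarded)
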