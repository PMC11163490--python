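"""Margin expansions, boolean algebra and distance geometry on masks.

Expansion is metric: a voxel joins the expanded structure iff its center lies
within the requested margin of some source voxel center, measured in patient
mm, so a 1 cm margin means 1 cm regardless of voxel size.  Anisotropic
margins use a per-direction half-ellipsoid acceptance test (the extent toward
each of the six anatomical directions can differ).  Membership is always by
voxel center, consistent with the phantom voxelization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .core import Grid, ImageVolume, StructureMask, _require_same_grid

__all__ = [
    "MarginSpec",
    "StructureSet",
    "expand",
    "combine",
    "distance_map",
    "derive_planning_structures",
]


@dataclass(frozen=True)
class MarginSpec:
    """Per-direction margins in mm (all >= 0).

    ``left``/``right`` act along x, ``anterior``/``posterior`` along y,
    ``inferior``/``superior`` along z (superior = +z).
    """

    left: float = 0.0
    right: float = 0.0
    anterior: float = 0.0
    posterior: float = 0.0
    inferior: float = 0.0
    superior: float = 0.0

    def __post_init__(self) -> None:
        if any(m < 0 for m in self.as_tuple()):
            raise ValueError(f"margins must be >= 0, got {self}")

    @classmethod
    def isotropic(cls, mm: float) -> "MarginSpec":
        return cls(mm, mm, mm, mm, mm, mm)

    @classmethod
    def lateral_ap_si(cls, lateral_ap: float, superior: float, inferior: float) -> "MarginSpec":
        """The junction-helper pattern: one lateral/AP value, separate SI values."""
        return cls(lateral_ap, lateral_ap, lateral_ap, lateral_ap, inferior, superior)

    def as_tuple(self) -> tuple[float, ...]:
        return (self.left, self.right, self.anterior, self.posterior,
                self.inferior, self.superior)

    def is_isotropic(self) -> bool:
        return len(set(self.as_tuple())) == 1

    def is_zero(self) -> bool:
        return all(m == 0 for m in self.as_tuple())


def _halfellipsoid_element(margin: MarginSpec, spacing) -> np.ndarray:
    """Structuring element of voxel offsets accepted by the directional test.

    An offset d (mm, from source voxel to candidate voxel) is accepted iff
    sum_i (d_i / m_i(sign d_i))^2 <= 1, where m_i picks the margin for the
    direction of d_i; a zero margin admits only zero displacement on that
    axis.  +x = left, +y = anterior, +z = superior (so a source voxel grows
    toward 'left' by the left margin, etc.).
    """
    pos = (margin.left, margin.anterior, margin.superior)
    neg = (margin.right, margin.posterior, margin.inferior)
    spacing = np.asarray(spacing, dtype=float)
    half = [int(np.floor(max(pos[a], neg[a]) / spacing[a])) for a in range(3)]
    offs = [np.arange(-h, h + 1) * spacing[a] for a, h in enumerate(half)]
    dx, dy, dz = np.meshgrid(*offs, indexing="ij", sparse=True)

    total = np.zeros((len(offs[0]), len(offs[1]), len(offs[2])))
    for a, d in enumerate((dx, dy, dz)):
        m = np.where(d >= 0, pos[a], neg[a])
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(d == 0, 0.0, (d / m) ** 2)
        term = np.where((m == 0) & (d != 0), np.inf, term)
        total = total + term
    return total <= 1.0


def expand(mask: StructureMask, margin: MarginSpec | float,
           name: str | None = None) -> StructureMask:
    """Metric margin expansion of a structure.

    For an isotropic margin m the result is exactly
    {voxel v : Euclidean distance from v's center to the nearest source voxel
    center <= m}; anisotropic margins use the half-ellipsoid test of
    :func:`_halfellipsoid_element`.  Always a superset of the input.
    """
    if not isinstance(margin, MarginSpec):
        margin = MarginSpec.isotropic(float(margin))
    out_name = name or f"{mask.name}+{margin}"
    deriv = f"expand({mask.name}, {margin})"
    if margin.is_zero() or mask.is_empty():
        return StructureMask(out_name, mask.mask.copy(), mask.grid, "helper", deriv)

    if margin.is_isotropic():
        m = margin.left
        dist = ndimage.distance_transform_edt(~mask.mask, sampling=mask.grid.spacing)
        grown = dist <= m + 1e-9
    else:
        # out[v] = 1 iff mask[v - o] for some accepted offset o; convolution
        # with the element indexed by offset gives exactly that sum
        se = _halfellipsoid_element(margin, mask.grid.spacing)
        conv = signal.fftconvolve(mask.mask.astype(np.float32), se.astype(np.float32),
                                  mode="same")
        grown = conv > 0.5
        grown |= mask.mask
    return StructureMask(out_name, grown, mask.grid, "helper", deriv)


def combine(a: StructureMask, b: StructureMask, op: str,
            name: str | None = None) -> StructureMask:
    """Voxelwise boolean combination: ``union``, ``intersect`` or ``subtract``."""
    _require_same_grid(a.grid, b.grid, f"structures {a.name!r}/{b.name!r}")
    if op == "union":
        out = a.mask | b.mask
    elif op == "intersect":
        out = a.mask & b.mask
    elif op == "subtract":
        out = a.mask & ~b.mask
    else:
        raise ValueError(f"op must be union|intersect|subtract, got {op!r}")
    return StructureMask(name or f"{a.name}_{op}_{b.name}", out, a.grid, "helper",
                         f"{op}({a.name}, {b.name})")


def union_all(masks: list[StructureMask], name: str = "All_PTVs",
              role: str = "helper") -> StructureMask:
    if not masks:
        raise ValueError("need at least one structure")
    out = np.zeros(masks[0].grid.shape, dtype=bool)
    for m in masks:
        _require_same_grid(masks[0].grid, m.grid)
        out |= m.mask
    return StructureMask(name, out, masks[0].grid, role,
                         f"union({', '.join(m.name for m in masks)})")


def distance_map(mask: StructureMask) -> ImageVolume:
    """Per-voxel Euclidean distance (mm) to the nearest mask voxel, 0 inside.

    Anisotropic spacing is respected; distances are center-to-center.
    """
    if mask.is_empty():
        raise ValueError(f"distance map of empty structure {mask.name!r} is undefined")
    dist = ndimage.distance_transform_edt(~mask.mask, sampling=mask.grid.spacing)
    return ImageVolume(dist, mask.grid, unit="mm")


@dataclass
class StructureSet:
    """Named collection of structures sharing one grid."""

    structures: dict[str, StructureMask]

    def __getitem__(self, name: str) -> StructureMask:
        return self.structures[name]

    def __contains__(self, name: str) -> bool:
        return name in self.structures

    def names(self) -> list[str]:
        return list(self.structures)


def derive_planning_structures(ptvs: list[StructureMask],
                               external: StructureMask) -> StructureSet:
    """Standard normal-tissue helper structures used by both planning styles.

    * ``All_PTVs`` — union of all PTVs;
    * ``NormalTissue`` — external minus All_PTVs;
    * ``NormalTissue_2cm`` — external minus All_PTVs expanded by 2 cm.
    """
    if not ptvs:
        raise ValueError("need at least one PTV")
    all_ptvs = union_all(ptvs, "All_PTVs")
    _require_same_grid(all_ptvs.grid, external.grid)
    normal = combine(external, all_ptvs, "subtract", "NormalTissue")
    normal.role = "normal"
    normal_2cm = combine(external, expand(all_ptvs, 20.0), "subtract", "NormalTissue_2cm")
    normal_2cm.role = "normal"
    out = {"All_PTVs": all_ptvs, "NormalTissue": normal, "NormalTissue_2cm": normal_2cm}
    return StructureSet(out)


def expand_gtv_to_ptv(gtv: StructureMask, margin_mm: float = 10.0) -> StructureMask:
    """The standard GTV→PTV derivation: isotropic 1 cm setup/contouring margin."""
    ptv = expand(gtv, margin_mm, name=gtv.name.replace("GTV", "PTV"))
    ptv.role = "PTV"
    return ptv
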