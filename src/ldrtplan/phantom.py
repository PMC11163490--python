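"""Synthetic polymetastatic phantoms.

Generates paired PET-like (SUV) and CT-like (density) volumes for a body with
a liver reference region and an arbitrary number of hyperintense ellipsoidal
lesions, plus day-of-treatment variants exhibiting target movement, regression
(including complete disappearance), progression and body-habitus change.
Every phantom carries its ground-truth lesion records so downstream stages
(segmentation, planning geometry, dose, adaptation) are testable end to end.

The body is an elliptical cylinder (axial cross-section ellipse, finite
superior-inferior extent); the liver is an ellipsoid inside it.  A voxel
belongs to a lesion iff its center lies inside the lesion ellipsoid — no
partial-volume modelling.  PET noise is independent per-voxel Gaussian,
clipped at zero; none of the physics of real PET (scatter, PSF, decay
correction) is emulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .core import Grid, ImageVolume, StructureMask

__all__ = [
    "LesionSpec",
    "BodySpec",
    "LiverSpec",
    "PhantomSpec",
    "Phantom",
    "AnatomyChangeSpec",
    "LesionChange",
    "PhantomValidationError",
    "generate_phantom",
    "apply_anatomy_change",
]

MAX_LESIONS = 200


class PhantomValidationError(ValueError):
    """A phantom or change specification violates its invariants."""


@dataclass(frozen=True)
class LesionSpec:
    """One ellipsoidal lesion: center/radii in patient mm, uniform SUV inside."""

    id: str
    center: tuple[float, float, float]
    radii: tuple[float, float, float]
    suv_level: float
    density_level: float = 1.05

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.radii):
            raise PhantomValidationError(f"lesion {self.id!r}: radii must be > 0")
        if self.suv_level <= 0:
            raise PhantomValidationError(f"lesion {self.id!r}: suv_level must be > 0")

    def volume_cc(self) -> float:
        """Analytic ellipsoid volume (4/3)·π·abc in cc."""
        a, b, c = self.radii
        return 4.0 / 3.0 * np.pi * a * b * c / 1000.0

    def contains(self, x, y, z) -> np.ndarray:
        cx, cy, cz = self.center
        rx, ry, rz = self.radii
        return ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 + ((z - cz) / rz) ** 2 <= 1.0


@dataclass(frozen=True)
class BodySpec:
    """Elliptical-cylinder body: axial center/radii (mm) and SI extent (mm)."""

    center_xy: tuple[float, float]
    radii_xy: tuple[float, float]
    z_range: tuple[float, float]
    density: float = 1.0

    def contains(self, x, y, z) -> np.ndarray:
        cx, cy = self.center_xy
        rx, ry = self.radii_xy
        inside_xy = ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 <= 1.0
        return inside_xy & (z >= self.z_range[0]) & (z <= self.z_range[1])

    def scaled(self, factor: float) -> "BodySpec":
        return replace(self, radii_xy=(self.radii_xy[0] * factor, self.radii_xy[1] * factor))


@dataclass(frozen=True)
class LiverSpec:
    """Ellipsoidal liver reference region with SUV mean μ and spread σ."""

    center: tuple[float, float, float]
    radii: tuple[float, float, float]
    suv_mean: float = 1.0
    suv_sd: float = 0.2

    def __post_init__(self) -> None:
        if self.suv_sd < 0:
            raise PhantomValidationError("liver suv_sd must be >= 0")

    def contains(self, x, y, z) -> np.ndarray:
        cx, cy, cz = self.center
        rx, ry, rz = self.radii
        return ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 + ((z - cz) / rz) ** 2 <= 1.0


@dataclass(frozen=True)
class PhantomSpec:
    grid_shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    body: BodySpec
    liver: LiverSpec
    lesions: tuple[LesionSpec, ...] = ()
    background_suv_mean: float = 0.8
    background_suv_sd: float = 0.1
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "lesions", tuple(self.lesions))
        if not 0 <= len(self.lesions) <= MAX_LESIONS:
            raise PhantomValidationError(
                f"lesion count must be in [0, {MAX_LESIONS}], got {len(self.lesions)}"
            )
        if any(s <= 0 for s in self.spacing):
            raise PhantomValidationError(f"spacing must be > 0, got {self.spacing}")
        ids = [l.id for l in self.lesions]
        if len(set(ids)) != len(ids):
            raise PhantomValidationError("lesion ids must be unique")

    @property
    def grid(self) -> Grid:
        return Grid(self.grid_shape, self.spacing, self.origin)


@dataclass
class Phantom:
    """Generated volumes plus the ground truth they were built from."""

    pet: ImageVolume
    ct: ImageVolume
    external_mask: StructureMask
    liver_mask: StructureMask
    truth_lesions: tuple[LesionSpec, ...]
    spec: PhantomSpec

    @property
    def grid(self) -> Grid:
        return self.pet.grid


def voxelize_lesion(lesion: LesionSpec, grid: Grid) -> np.ndarray:
    """Boolean volume of voxels whose centers lie inside the lesion ellipsoid."""
    x, y, z = grid.meshgrid()
    return lesion.contains(x, y, z)


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Build PET/CT volumes and masks from a :class:`PhantomSpec`.

    PET values: Gaussian background noise inside the body, liver voxels drawn
    with mean μ and sd σ, lesion voxels set to their ``suv_level`` (lesions
    override background and liver).  Deterministic for a fixed seed.

    Raises
    ------
    PhantomValidationError
        If any lesion's voxelization is not contained in the body.
    """
    grid = spec.grid
    x, y, z = grid.meshgrid()
    body = spec.body.contains(x, y, z)
    liver = spec.liver.contains(x, y, z) & body

    rng = np.random.default_rng(spec.seed)
    pet = np.zeros(grid.shape)
    pet[body] = spec.background_suv_mean + spec.background_suv_sd * rng.standard_normal(
        int(body.sum())
    )
    pet[liver] = spec.liver.suv_mean + spec.liver.suv_sd * rng.standard_normal(
        int(liver.sum())
    )
    ct = np.zeros(grid.shape)
    ct[body] = spec.body.density

    for lesion in spec.lesions:
        vox = voxelize_lesion(lesion, grid)
        if not vox.any():
            raise PhantomValidationError(
                f"lesion {lesion.id!r} covers no voxel on this grid"
            )
        if (vox & ~body).any():
            raise PhantomValidationError(
                f"lesion {lesion.id!r} extends outside the body contour"
            )
        pet[vox] = lesion.suv_level
        ct[vox] = lesion.density_level
        liver &= ~vox  # liver_mask is *normal* liver: avid disease excluded

    np.clip(pet, 0.0, None, out=pet)
    return Phantom(
        pet=ImageVolume(pet, grid, unit="SUV"),
        ct=ImageVolume(ct, grid, unit="density"),
        external_mask=StructureMask("External", body, grid, role="external"),
        liver_mask=StructureMask("Liver", liver, grid, role="liver"),
        truth_lesions=spec.lesions,
        spec=spec,
    )


@dataclass(frozen=True)
class LesionChange:
    """Per-lesion day-of change: rigid shift, size scale (0 removes), SUV scale."""

    shift: tuple[float, float, float] = (0.0, 0.0, 0.0)
    scale: float = 1.0
    suv_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.scale < 0:
            raise PhantomValidationError("lesion scale must be >= 0")
        if self.suv_scale < 0:
            raise PhantomValidationError("suv_scale must be >= 0")


@dataclass(frozen=True)
class AnatomyChangeSpec:
    """Day-of-treatment perturbation: setup shift, per-lesion response or
    progression, new lesions, and body-habitus change."""

    global_shift: tuple[float, float, float] = (0.0, 0.0, 0.0)
    per_lesion_changes: dict[str, LesionChange] = field(default_factory=dict)
    new_lesions: tuple[LesionSpec, ...] = ()
    body_scale: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "new_lesions", tuple(self.new_lesions))
        if self.body_scale <= 0:
            raise PhantomValidationError("body_scale must be > 0")


def apply_anatomy_change(phantom: Phantom, change: AnatomyChangeSpec) -> Phantom:
    """Return a new phantom on the same grid with the change applied.

    Lesions are moved/scaled/removed per ``change``; new lesions appended;
    the body cross-section scaled by ``body_scale``; the whole anatomy (body,
    liver, lesions) rigidly shifted by ``global_shift``.  The output's
    ``truth_lesions`` reflect the post-change geometry; a lesion with scale 0
    is absent and its voxels revert to background.  Identity changes are
    voxel-identical to the input (the noise seed is reused unless the change
    supplies its own).
    """
    known = {l.id for l in phantom.truth_lesions}
    unknown = set(change.per_lesion_changes) - known
    if unknown:
        raise PhantomValidationError(f"unknown lesion id(s) in change: {sorted(unknown)}")

    gs = np.asarray(change.global_shift, dtype=float)
    new_lesions: list[LesionSpec] = []
    for lesion in phantom.truth_lesions:
        lc = change.per_lesion_changes.get(lesion.id, LesionChange())
        if lc.scale == 0:
            continue
        new_lesions.append(
            replace(
                lesion,
                center=tuple(np.asarray(lesion.center) + np.asarray(lc.shift) + gs),
                radii=tuple(np.asarray(lesion.radii) * lc.scale),
                suv_level=lesion.suv_level * lc.suv_scale,
            )
        )
    for lesion in change.new_lesions:
        new_lesions.append(replace(lesion, center=tuple(np.asarray(lesion.center) + gs)))

    spec = phantom.spec
    body = spec.body.scaled(change.body_scale)
    body = replace(
        body,
        center_xy=(body.center_xy[0] + gs[0], body.center_xy[1] + gs[1]),
        z_range=(body.z_range[0] + gs[2], body.z_range[1] + gs[2]),
    )
    liver = replace(spec.liver, center=tuple(np.asarray(spec.liver.center) + gs))
    day_spec = replace(
        spec,
        body=body,
        liver=liver,
        lesions=tuple(new_lesions),
        seed=spec.seed if change.seed is None else change.seed,
    )
    return generate_phantom(day_spec)


# ---------------------------------------------------------------------------
# YAML (de)serialization of specs — the structured-config interface.

def _floats(xs) -> list[float]:
    return [float(x) for x in xs]


def _lesion_to_dict(l: LesionSpec) -> dict:
    return {
        "id": l.id, "center": _floats(l.center), "radii": _floats(l.radii),
        "suv_level": float(l.suv_level), "density_level": float(l.density_level),
    }


def _lesion_from_dict(d: dict) -> LesionSpec:
    return LesionSpec(
        id=str(d["id"]), center=tuple(d["center"]), radii=tuple(d["radii"]),
        suv_level=float(d["suv_level"]),
        density_level=float(d.get("density_level", 1.05)),
    )


def spec_to_dict(spec: PhantomSpec) -> dict:
    return {
        "grid_shape": [int(s) for s in spec.grid_shape],
        "spacing": _floats(spec.spacing),
        "origin": _floats(spec.origin),
        "body": {
            "center_xy": _floats(spec.body.center_xy),
            "radii_xy": _floats(spec.body.radii_xy),
            "z_range": _floats(spec.body.z_range),
            "density": float(spec.body.density),
        },
        "liver": {
            "center": _floats(spec.liver.center),
            "radii": _floats(spec.liver.radii),
            "suv_mean": float(spec.liver.suv_mean),
            "suv_sd": float(spec.liver.suv_sd),
        },
        "lesions": [_lesion_to_dict(l) for l in spec.lesions],
        "background_suv_mean": float(spec.background_suv_mean),
        "background_suv_sd": float(spec.background_suv_sd),
        "seed": int(spec.seed),
    }


def spec_from_dict(d: dict) -> PhantomSpec:
    return PhantomSpec(
        grid_shape=tuple(d["grid_shape"]),
        spacing=tuple(d["spacing"]),
        origin=tuple(d.get("origin", (0.0, 0.0, 0.0))),
        body=BodySpec(
            center_xy=tuple(d["body"]["center_xy"]),
            radii_xy=tuple(d["body"]["radii_xy"]),
            z_range=tuple(d["body"]["z_range"]),
            density=float(d["body"].get("density", 1.0)),
        ),
        liver=LiverSpec(
            center=tuple(d["liver"]["center"]),
            radii=tuple(d["liver"]["radii"]),
            suv_mean=float(d["liver"].get("suv_mean", 1.0)),
            suv_sd=float(d["liver"].get("suv_sd", 0.2)),
        ),
        lesions=tuple(_lesion_from_dict(x) for x in d.get("lesions", [])),
        background_suv_mean=float(d.get("background_suv_mean", 0.8)),
        background_suv_sd=float(d.get("background_suv_sd", 0.1)),
        seed=int(d.get("seed", 0)),
    )


def change_to_dict(change: AnatomyChangeSpec) -> dict:
    return {
        "global_shift": _floats(change.global_shift),
        "per_lesion_changes": {
            k: {"shift": _floats(v.shift), "scale": float(v.scale),
                "suv_scale": float(v.suv_scale)}
            for k, v in change.per_lesion_changes.items()
        },
        "new_lesions": [_lesion_to_dict(l) for l in change.new_lesions],
        "body_scale": change.body_scale,
        "seed": change.seed,
    }


def change_from_dict(d: dict) -> AnatomyChangeSpec:
    return AnatomyChangeSpec(
        global_shift=tuple(d.get("global_shift", (0.0, 0.0, 0.0))),
        per_lesion_changes={
            str(k): LesionChange(
                shift=tuple(v.get("shift", (0.0, 0.0, 0.0))),
                scale=float(v.get("scale", 1.0)),
                suv_scale=float(v.get("suv_scale", 1.0)),
            )
            for k, v in d.get("per_lesion_changes", {}).items()
        },
        new_lesions=tuple(_lesion_from_dict(x) for x in d.get("new_lesions", [])),
        body_scale=float(d.get("body_scale", 1.0)),
        seed=d.get("seed"),
    )


def load_spec(path: str) -> PhantomSpec:
    with open(path) as fh:
        return spec_from_dict(yaml.safe_load(fh))


def save_spec(spec: PhantomSpec, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(spec_to_dict(spec), fh, sort_keys=False)


def load_change(path: str) -> AnatomyChangeSpec:
    with open(path) as fh:
        return change_from_dict(yaml.safe_load(fh))


def save_change(change: AnatomyChangeSpec, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(change_to_dict(change), fh, sort_keys=False)
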