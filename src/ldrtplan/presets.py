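"""Reference study configurations.

Ready-made inputs used by the examples, the test suite and the acceptance
script: a generic polymetastatic phantom with a configurable lesion burden,
a three-region (thorax/abdomen/pelvis) 31-target layout for plan-geometry
bookkeeping, and a randomized "super-margin" day-of change that moves or
grows every lesion by clearly more than the 1 cm PTV margin.
"""

from __future__ import annotations

import numpy as np

from .core import Grid, StructureMask
from .phantom import (
    AnatomyChangeSpec,
    BodySpec,
    LesionChange,
    LesionSpec,
    LiverSpec,
    Phantom,
    PhantomSpec,
)

__all__ = [
    "polymetastatic_spec",
    "three_region_targets",
    "super_margin_change",
]


def polymetastatic_spec(
    n_lesions: int = 15,
    seed: int = 0,
    grid_shape: tuple[int, int, int] = (64, 64, 96),
    spacing: tuple[float, float, float] = (4.0, 4.0, 4.0),
    noise: bool = True,
    min_separation_mm: float = 30.0,
    lesion_radius_mm: tuple[float, float] = (5.0, 10.0),
    lesion_suv: tuple[float, float] = (3.0, 8.0),
) -> PhantomSpec:
    """A polymetastatic patient: elliptical-cylinder body, ellipsoidal liver
    (SUV mean 1.0, sd 0.2 when noisy), and ``n_lesions`` well-separated
    ellipsoidal lesions placed by seeded rejection sampling.

    Lesion burden defaults cover the clinically reported range (a handful to
    several dozen targets, median in the teens).  ``noise=False`` produces
    the noise-free phantom used for exact-recovery checks.
    """
    extent = np.array(grid_shape) * np.array(spacing)
    cx, cy = extent[0] / 2, extent[1] / 2
    body = BodySpec(
        center_xy=(cx, cy),
        radii_xy=(0.44 * extent[0], 0.36 * extent[1]),
        z_range=(0.0, float(extent[2] - spacing[2])),
    )
    liver = LiverSpec(
        center=(cx + 0.17 * extent[0], cy, 0.65 * extent[2]),
        radii=(0.18 * extent[0], 0.14 * extent[1], 0.11 * extent[2]),
        suv_mean=1.0,
        suv_sd=0.2 if noise else 0.0,
    )

    rng = np.random.default_rng(seed)
    centers: list[np.ndarray] = []
    lesions: list[LesionSpec] = []
    z_lo, z_hi = 50.0, extent[2] - 55.0
    attempts = 0
    while len(lesions) < n_lesions:
        attempts += 1
        if attempts > 20000:
            raise RuntimeError(
                f"could not place {n_lesions} lesions with "
                f"{min_separation_mm} mm separation; enlarge the grid"
            )
        r = rng.uniform(*lesion_radius_mm)
        # keep the whole lesion (plus shift headroom) inside the body
        frac = rng.uniform(0.0, 0.60)
        theta = rng.uniform(0.0, 2 * np.pi)
        c = np.array([
            cx + frac * (body.radii_xy[0] - r - 20.0) * np.cos(theta),
            cy + frac * (body.radii_xy[1] - r - 20.0) * np.sin(theta),
            rng.uniform(z_lo, z_hi),
        ])
        if any(np.linalg.norm(c - p) < min_separation_mm for p in centers):
            continue
        centers.append(c)
        lesions.append(
            LesionSpec(
                id=f"L{len(lesions) + 1:02d}",
                center=tuple(c),
                radii=(r, r * rng.uniform(0.8, 1.0), r * rng.uniform(0.8, 1.0)),
                suv_level=float(rng.uniform(*lesion_suv)),
            )
        )
    return PhantomSpec(
        grid_shape=grid_shape,
        spacing=spacing,
        body=body,
        liver=liver,
        lesions=tuple(lesions),
        background_suv_mean=0.8,
        background_suv_sd=0.1 if noise else 0.0,
        seed=seed,
    )


def three_region_targets() -> tuple[list[StructureMask], list[tuple[float, float, str]]]:
    """The 31-target thorax/abdomen/pelvis layout for plan-geometry
    bookkeeping: 11 thorax targets spanning > 26 cm (forcing two isocenters),
    10 abdomen and 10 pelvis targets each within a single-isocenter span,
    with target-free gaps between regions.

    Returns the PTV masks (20 mm boxes on a 4×4×5 mm grid about 1.1 m long)
    and the matching (z_min, z_max, region) map.
    """
    grid = Grid((40, 40, 220), (4.0, 4.0, 5.0))
    rng = np.random.default_rng(1234)

    def box(center_mm, half_mm=10.0):
        x, y, zc = center_mm
        gx, gy, gz = grid.meshgrid()
        return (np.abs(gx - x) <= half_mm) & (np.abs(gy - y) <= half_mm) & (
            np.abs(gz - zc) <= half_mm
        )

    layout = [
        ("pelvis", 10, (40.0, 240.0)),
        ("abdomen", 10, (410.0, 590.0)),
        ("thorax", 11, (710.0, 1000.0)),
    ]
    ptvs: list[StructureMask] = []
    k = 0
    for region, count, (z_lo, z_hi) in layout:
        zs = np.linspace(z_lo, z_hi, count)
        for z in zs:
            k += 1
            x = 80.0 + 60.0 * rng.random()
            y = 80.0 + 60.0 * rng.random()
            ptvs.append(StructureMask(f"PTV_{k:02d}", box((x, y, z)), grid, role="PTV"))
    region_map = [
        (-100.0, 330.0, "pelvis"),
        (330.0, 660.0, "abdomen"),
        (660.0, 1200.0, "thorax"),
    ]
    return ptvs, region_map


def super_margin_change(phantom: Phantom, seed: int = 0) -> AnatomyChangeSpec:
    """A day-of change in which *every* lesion moves or grows beyond the
    1 cm PTV margin: an SI shift of 12–18 mm (either direction) or a size
    scale of 1.5–1.7.  Used to probe the scheduled plan's failure mode."""
    rng = np.random.default_rng(seed)
    changes: dict[str, LesionChange] = {}
    for lesion in phantom.truth_lesions:
        if rng.random() < 0.5:
            dz = rng.uniform(12.0, 18.0) * (1 if rng.random() < 0.5 else -1)
            changes[lesion.id] = LesionChange(shift=(0.0, 0.0, dz))
        else:
            changes[lesion.id] = LesionChange(scale=float(rng.uniform(1.5, 1.7)))
    return AnatomyChangeSpec(per_lesion_changes=changes)
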