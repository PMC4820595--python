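"""NEMA NU 4-2008 phantom geometry: analytic specs and voxelized maps.

Defines the image-quality (IQ) phantom, the NECR mouse phantom and the
cylindrical regions all VOI analysis is built on.  Regions live in physical
millimetres, independent of any grid; voxelization uses the
voxel-center-in-region rule, so masks are deterministic and grids are
interchangeable.

Coordinate convention: right-handed, scanner axis = z, units mm,
0-based voxel indices.  ``VoxelGrid.origin`` is the physical position of the
center of voxel (0, 0, 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import yaml

__all__ = [
    "MATERIAL_AIR",
    "MATERIAL_WATER",
    "MATERIAL_PMMA",
    "MATERIAL_ALUMINUM",
    "MU_511_PER_MM",
    "VoxelGrid",
    "CylinderRegion",
    "IQPhantomSpec",
    "MousePhantomSpec",
    "voxelize_region",
    "build_iq_phantom",
    "build_mouse_phantom",
    "save_map_nifti",
    "load_map_nifti",
]

# Material labels for MaterialMap volumes.
MATERIAL_AIR = 0
MATERIAL_WATER = 1
MATERIAL_PMMA = 2
MATERIAL_ALUMINUM = 3

#: 511 keV linear attenuation coefficients, mm^-1 (water 0.096/cm,
#: PMMA 0.112/cm, aluminum 0.226/cm, air ~0).
MU_511_PER_MM = {
    MATERIAL_AIR: 0.0,
    MATERIAL_WATER: 0.0096,
    MATERIAL_PMMA: 0.0112,
    MATERIAL_ALUMINUM: 0.0226,
}


@dataclass(frozen=True)
class VoxelGrid:
    """Regular voxel grid in scanner coordinates.

    Parameters
    ----------
    shape : tuple of int
        Number of voxels along (x, y, z).
    voxel_size : tuple of float
        Voxel edge length in mm along (x, y, z).  The in-plane default of
        0.776 mm matches the reconstructed pixel size used throughout.
    origin : tuple of float
        Physical mm position of the center of voxel (0, 0, 0).
    """

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float] = (0.776, 0.776, 2.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) <= 0 for s in self.shape):
            raise ValueError(f"shape must be a positive integer triple, got {self.shape}")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be positive, got {self.voxel_size}")

    @classmethod
    def centered(
        cls,
        shape: tuple[int, int, int],
        voxel_size: tuple[float, float, float] = (0.776, 0.776, 2.0),
    ) -> "VoxelGrid":
        """Grid whose physical center coincides with the scanner axis origin."""
        origin = tuple(-(n - 1) / 2.0 * v for n, v in zip(shape, voxel_size))
        return cls(shape=tuple(int(s) for s in shape), voxel_size=tuple(voxel_size), origin=origin)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        vx, vy, vz = self.voxel_size
        return vx * vy * vz

    def axis_coords(self, axis: int) -> np.ndarray:
        """Physical mm coordinates of voxel centers along one axis."""
        return self.origin[axis] + self.voxel_size[axis] * np.arange(self.shape[axis])

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return np.meshgrid(
            self.axis_coords(0), self.axis_coords(1), self.axis_coords(2), indexing="ij"
        )

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-to-mm affine (diagonal scaling + origin translation)."""
        aff = np.diag([*self.voxel_size, 1.0])
        aff[:3, 3] = self.origin
        return aff


@dataclass(frozen=True)
class CylinderRegion:
    """Axis-aligned cylinder (axis along scanner z), in physical mm.

    ``center`` is the cylinder's geometric center; ``length`` its full axial
    extent.
    """

    center: tuple[float, float, float]
    radius: float
    length: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError(f"radius must be > 0, got {self.radius}")
        if self.length <= 0:
            raise ValueError(f"length must be > 0, got {self.length}")

    @property
    def volume(self) -> float:
        """Analytic volume in mm^3."""
        return np.pi * self.radius**2 * self.length

    def contains(self, x: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
        cx, cy, cz = self.center
        radial = (x - cx) ** 2 + (y - cy) ** 2 <= self.radius**2
        axial = np.abs(z - cz) <= self.length / 2.0
        return radial & axial


def _default_rods() -> list[CylinderRegion]:
    # Five fillable rods, diameters 1..5 mm, centers 7 mm from the phantom
    # axis, spread at 72 deg, occupying the bottom 20 mm section.
    rods = []
    for i, diameter in enumerate((1.0, 2.0, 3.0, 4.0, 5.0)):
        angle = 2.0 * np.pi * i / 5.0
        cx = 7.0 * np.cos(angle)
        cy = 7.0 * np.sin(angle)
        rods.append(CylinderRegion(center=(cx, cy, -15.0), radius=diameter / 2.0, length=20.0))
    return rods


@dataclass(frozen=True)
class IQPhantomSpec:
    """NEMA NU 4-2008 image-quality phantom.

    A 30 mm diameter x 50 mm long cylinder in three axial sections
    (z measured from the phantom center):

    * bottom 20 mm (z in [-25, -5]): solid PMMA with five fillable rods
      (diameters 1-5 mm, centers 7 mm off-axis),
    * middle 15 mm (z in [-5, 10]): open uniform activity chamber,
    * top 15 mm (z in [10, 25]): uniform activity surrounding two cold
      chambers (8 mm inner / 10 mm outer diameter), one air, one
      nonradioactive water.

    ``activity_concentration`` is the aqueous activity in Bq/mL filling every
    active compartment.
    """

    body: CylinderRegion = field(
        default_factory=lambda: CylinderRegion((0.0, 0.0, 0.0), 15.0, 50.0)
    )
    uniform_region: CylinderRegion = field(
        default_factory=lambda: CylinderRegion((0.0, 0.0, 2.5), 15.0, 15.0)
    )
    cold_air: CylinderRegion = field(
        default_factory=lambda: CylinderRegion((-6.0, 0.0, 17.5), 4.0, 15.0)
    )
    cold_water: CylinderRegion = field(
        default_factory=lambda: CylinderRegion((6.0, 0.0, 17.5), 4.0, 15.0)
    )
    cold_wall_outer_radius: float = 5.0
    rods: tuple[CylinderRegion, ...] = field(default_factory=lambda: tuple(_default_rods()))
    wall_thickness: float = 2.0
    activity_concentration: float = 1.0e5  # Bq/mL

    def __post_init__(self) -> None:
        if self.activity_concentration < 0:
            raise ValueError("activity_concentration must be >= 0")
        centers = [r.center for r in self.rods]
        radii = [r.radius for r in self.rods]
        for i in range(len(self.rods)):
            for j in range(i + 1, len(self.rods)):
                d = np.hypot(
                    centers[i][0] - centers[j][0], centers[i][1] - centers[j][1]
                )
                if d < radii[i] + radii[j]:
                    raise ValueError(f"rods {i} and {j} overlap")
        for cold in (self.cold_air, self.cold_water):
            d = np.hypot(cold.center[0], cold.center[1])
            if d + self.cold_wall_outer_radius > self.body.radius:
                raise ValueError("cold chamber extends outside the phantom body")

    def to_yaml(self) -> str:
        def cyl(c: CylinderRegion) -> dict:
            return {"center": list(c.center), "radius": c.radius, "length": c.length}

        doc = {
            "body": cyl(self.body),
            "uniform_region": cyl(self.uniform_region),
            "cold_air": cyl(self.cold_air),
            "cold_water": cyl(self.cold_water),
            "cold_wall_outer_radius": self.cold_wall_outer_radius,
            "rods": [cyl(r) for r in self.rods],
            "wall_thickness": self.wall_thickness,
            "activity_concentration": self.activity_concentration,
        }
        return yaml.safe_dump(doc, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "IQPhantomSpec":
        doc = yaml.safe_load(text)

        def cyl(d: dict) -> CylinderRegion:
            return CylinderRegion(tuple(d["center"]), d["radius"], d["length"])

        return cls(
            body=cyl(doc["body"]),
            uniform_region=cyl(doc["uniform_region"]),
            cold_air=cyl(doc["cold_air"]),
            cold_water=cyl(doc["cold_water"]),
            cold_wall_outer_radius=doc["cold_wall_outer_radius"],
            rods=tuple(cyl(r) for r in doc["rods"]),
            wall_thickness=doc["wall_thickness"],
            activity_concentration=doc["activity_concentration"],
        )


@dataclass(frozen=True)
class MousePhantomSpec:
    """NEMA NU 4 mouse-sized count-rate phantom: 25 mm diameter x 70 mm."""

    body: CylinderRegion = field(
        default_factory=lambda: CylinderRegion((0.0, 0.0, 0.0), 12.5, 70.0)
    )
    total_activity: float = 1.0e6  # Bq


def voxelize_region(region: CylinderRegion, grid: VoxelGrid) -> np.ndarray:
    """Boolean mask of grid voxels whose *centers* lie inside ``region``.

    Degenerate regions (smaller than a voxel, off-grid) may produce an empty
    mask; that is not an error.
    """
    x, y, z = grid.meshgrid()
    return region.contains(x, y, z)


def _require_grid_covers(region: CylinderRegion, grid: VoxelGrid, what: str) -> None:
    lo = [grid.origin[a] - grid.voxel_size[a] / 2 for a in range(3)]
    hi = [
        grid.origin[a] + grid.voxel_size[a] * (grid.shape[a] - 1) + grid.voxel_size[a] / 2
        for a in range(3)
    ]
    cx, cy, cz = region.center
    needs = [
        (cx - region.radius, cx + region.radius),
        (cy - region.radius, cy + region.radius),
        (cz - region.length / 2, cz + region.length / 2),
    ]
    for axis, (nlo, nhi) in enumerate(needs):
        if nlo < lo[axis] - 1e-9 or nhi > hi[axis] + 1e-9:
            raise ValueError(
                f"grid does not cover the {what} along axis {axis}: "
                f"needs [{nlo:.1f}, {nhi:.1f}] mm, grid spans [{lo[axis]:.1f}, {hi[axis]:.1f}] mm"
            )


def build_iq_phantom(
    spec: IQPhantomSpec, grid: VoxelGrid
) -> tuple[np.ndarray, np.ndarray]:
    """Voxelize the IQ phantom into an activity map (Bq/mL) and material map.

    Returns
    -------
    activity : float array, shape ``grid.shape``
        Activity concentration in Bq/mL.  Nonzero only in the uniform
        chamber, the active part of the cold-chamber section, and the rods.
    material : int array, shape ``grid.shape``
        Material labels (``MATERIAL_*``): air outside, water in active and
        cold-water compartments, PMMA in walls and the solid rod section.
    """
    _require_grid_covers(spec.body, grid, "IQ phantom body")

    x, y, z = grid.meshgrid()
    material = np.full(grid.shape, MATERIAL_AIR, dtype=np.int8)
    activity = np.zeros(grid.shape, dtype=np.float64)

    outer = CylinderRegion(
        spec.body.center, spec.body.radius + spec.wall_thickness, spec.body.length
    )
    body_mask = spec.body.contains(x, y, z)
    material[outer.contains(x, y, z)] = MATERIAL_PMMA

    z0 = spec.body.center[2] - spec.body.length / 2.0
    rod_section = (z >= z0) & (z < z0 + 20.0)
    active_section = body_mask & (z >= z0 + 20.0)  # uniform + cold-chamber sections

    material[active_section] = MATERIAL_WATER
    activity[active_section] = spec.activity_concentration

    # Bottom section: solid PMMA, activity only inside the rods.
    material[body_mask & rod_section] = MATERIAL_PMMA
    for rod in spec.rods:
        m = rod.contains(x, y, z)
        material[m] = MATERIAL_WATER
        activity[m] = spec.activity_concentration

    # Cold chambers: wall annulus is PMMA; interiors are air / cold water.
    for cold, label in ((spec.cold_air, MATERIAL_AIR), (spec.cold_water, MATERIAL_WATER)):
        wall = CylinderRegion(cold.center, spec.cold_wall_outer_radius, cold.length)
        wm = wall.contains(x, y, z)
        material[wm] = MATERIAL_PMMA
        activity[wm] = 0.0
        im = cold.contains(x, y, z)
        material[im] = label
        activity[im] = 0.0

    return activity, material


def build_mouse_phantom(
    grid: VoxelGrid, spec: MousePhantomSpec | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Voxelize the uniform mouse phantom; activity normalized to the spec total.

    The activity map is scaled so ``sum(activity) * voxel_volume(mL)`` equals
    ``spec.total_activity`` exactly on the voxelized support.
    """
    spec = spec or MousePhantomSpec()
    _require_grid_covers(spec.body, grid, "mouse phantom")
    mask = voxelize_region(spec.body, grid)
    if not mask.any():
        raise ValueError("mouse phantom voxelizes to an empty volume on this grid")
    material = np.where(mask, MATERIAL_WATER, MATERIAL_AIR).astype(np.int8)
    voxel_ml = grid.voxel_volume / 1000.0  # mm^3 -> mL
    conc = spec.total_activity / (mask.sum() * voxel_ml)  # Bq/mL
    activity = np.where(mask, conc, 0.0)
    return activity, material


def save_map_nifti(volume: np.ndarray, grid: VoxelGrid, path: str) -> None:
    """Write a map as NIfTI with the grid's mm affine."""
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float32), grid.affine), path)


def load_map_nifti(path: str) -> tuple[np.ndarray, VoxelGrid]:
    img = nib.load(path)
    aff = img.affine
    grid = VoxelGrid(
        shape=tuple(int(s) for s in img.shape[:3]),
        voxel_size=tuple(float(aff[i, i]) for i in range(3)),
        origin=tuple(float(aff[i, 3]) for i in range(3)),
    )
    return np.asarray(img.dataobj), grid
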