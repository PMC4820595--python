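"""NEMA NU 4-2008 image-quality metrics and energy-window selection.

Metrics on a reconstructed IQ-phantom volume:

* nonuniformity (NU): %SD of a 22.5 mm x 10 mm VOI centered in the uniform
  region (sample SD, n-1),
* recovery coefficients (RC): per rod, the mean of the axial line profile
  through the hottest pixel of the rod ROI, divided by the uniform mean,
  with the %SD_RC combining profile and uniform-region variability in
  quadrature,
* spillover ratio (SOR): mean of a 4 mm x 7.5 mm VOI in each cold chamber
  (air, nonradioactive water) over the uniform mean, in percent — may be
  negative after scatter/prompt-gamma over-subtraction,
* weighted SOR (wSOR): sqrt(f_air SOR_air^2 + f_water SOR_water^2) with
  mouse-carcass volume fractions f_air = 0.027, f_water = 0.973.

The optimal energy window is the one minimizing wSOR.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phantom_geometry import CylinderRegion, IQPhantomSpec, VoxelGrid, voxelize_region
from .reconstruction import ReconImage
from .reference import F_AIR, F_WATER
from .synthetic_acquisition import EnergyWindow

__all__ = [
    "VOIDefinition",
    "RodResult",
    "IQReport",
    "standard_vois",
    "nonuniformity",
    "recovery_coefficients",
    "spillover_ratio",
    "weighted_sor",
    "select_optimal_window",
    "compute_iq_report",
    "reports_to_dataframe",
]


@dataclass(frozen=True)
class VOIDefinition:
    """A named cylindrical VOI with its NEMA role."""

    region: CylinderRegion
    role: str  # uniform | cold_air | cold_water | rod

    def mask(self, grid: VoxelGrid) -> np.ndarray:
        m = voxelize_region(self.region, grid)
        if not m.any():
            raise ValueError(f"{self.role} VOI voxelizes to an empty mask")
        return m


def standard_vois(spec: IQPhantomSpec) -> dict[str, VOIDefinition]:
    """NEMA NU 4 VOIs derived from the phantom spec.

    Uniform: 22.5 mm diameter x 10 mm, centered in the uniform region.
    Cold: 4 mm diameter x 7.5 mm (half the chamber size), axially centered.
    """
    u = spec.uniform_region
    vois = {
        "uniform": VOIDefinition(
            CylinderRegion(u.center, radius=11.25, length=10.0), "uniform"
        )
    }
    for name, chamber in (("cold_air", spec.cold_air), ("cold_water", spec.cold_water)):
        vois[name] = VOIDefinition(
            CylinderRegion(chamber.center, radius=2.0, length=7.5), name
        )
    return vois


def nonuniformity(image: ReconImage, uniform_voi: VOIDefinition) -> float:
    """%SD of the uniform VOI: 100 x SD / mean (sample SD)."""
    vals = image.volume[uniform_voi.mask(image.grid)]
    mean = float(vals.mean())
    if mean <= 0:
        raise ValueError(f"uniform VOI mean must be > 0, got {mean}")
    return 100.0 * float(vals.std(ddof=1)) / mean


@dataclass(frozen=True)
class RodResult:
    diameter_mm: float
    rc: float | None  # None when the rod is not discernible
    pct_sd: float | None


def recovery_coefficients(
    image: ReconImage,
    spec: IQPhantomSpec,
    uniform_mean: float,
    uniform_sd: float,
    discernibility_k: float = 3.0,
    estimator: str = "profile",
) -> list[RodResult]:
    """Per-rod recovery coefficient and %SD_RC.

    Slices spanning the central 10 mm of the rod section are averaged into
    one transverse image; the hottest pixel inside each rod's ROI (a circle
    of twice the rod diameter) fixes the profile location; the axial line
    profile at that location across the same slices gives
    ``RC = mean(profile) / uniform_mean`` (``estimator='profile'``, the NEMA
    procedure) or ``RC = max / uniform_mean`` (``estimator='max'``).

    ``%SD_RC = 100 x sqrt(CV_profile^2 + CV_uniform^2)``.

    A rod whose ROI maximum does not rise ``k`` uniform-region SDs above the
    rod section's zero-activity background is reported not discernible
    (rc = None); the default k = 3 is a 3-sigma noise floor.
    """
    if uniform_mean <= 0:
        raise ValueError("uniform_mean must be > 0")
    if estimator not in ("profile", "max"):
        raise ValueError("estimator must be 'profile' or 'max'")
    grid = image.grid
    rods = sorted(spec.rods, key=lambda r: r.radius)
    threshold = discernibility_k * uniform_sd
    zc = rods[0].center[2]
    z = grid.axis_coords(2)
    central = np.abs(z - zc) <= 5.0  # central 10 mm of the 20 mm rod section
    rod_slices = np.abs(z - zc) <= rods[0].length / 2.0
    if not central.any():
        raise ValueError("grid has no slices in the central rod section")
    mean_img = image.volume[:, :, central].mean(axis=2)
    xs = grid.axis_coords(0)[:, None]
    ys = grid.axis_coords(1)[None, :]
    results = []
    for rod in rods:
        cx, cy, _ = rod.center
        # ROI circle of twice the rod diameter => ROI radius = rod diameter
        roi = (xs - cx) ** 2 + (ys - cy) ** 2 <= (2.0 * rod.radius) ** 2
        if not roi.any():
            raise ValueError(f"empty ROI for {2 * rod.radius:.0f} mm rod")
        masked = np.where(roi, mean_img, -np.inf)
        i, j = np.unravel_index(np.argmax(masked), masked.shape)
        peak = mean_img[i, j]
        if peak < threshold:
            results.append(RodResult(2.0 * rod.radius, None, None))
            continue
        profile = image.volume[i, j, rod_slices]
        if estimator == "profile":
            rc = float(profile.mean()) / uniform_mean
        else:
            rc = float(peak) / uniform_mean
        cv_p = float(profile.std(ddof=1)) / float(profile.mean()) if profile.mean() != 0 else np.inf
        cv_u = uniform_sd / uniform_mean
        pct_sd = 100.0 * float(np.sqrt(cv_p**2 + cv_u**2))
        results.append(RodResult(2.0 * rod.radius, rc, pct_sd))
    return results


def spillover_ratio(image: ReconImage, cold_voi: VOIDefinition, uniform_mean: float) -> float:
    """SOR% = 100 x mean(cold VOI) / uniform mean; negatives allowed."""
    if uniform_mean <= 0:
        raise ValueError("uniform_mean must be > 0")
    vals = image.volume[cold_voi.mask(image.grid)]
    return 100.0 * float(vals.mean()) / uniform_mean


def weighted_sor(sor_air_pct: float, sor_water_pct: float,
                 f_air: float = F_AIR, f_water: float = F_WATER) -> float:
    """wSOR = sqrt(f_air SOR_air^2 + f_water SOR_water^2), in percent units."""
    if f_air < 0 or f_water < 0:
        raise ValueError("weights must be >= 0")
    if abs(f_air + f_water - 1.0) > 1e-6:
        raise ValueError("weights must sum to 1")
    return float(np.sqrt(f_air * sor_air_pct**2 + f_water * sor_water_pct**2))


@dataclass
class IQReport:
    """All NEMA NU 4 metrics for one window / correction set."""

    window: EnergyWindow
    nonuniformity_pct: float
    rods: list[RodResult]
    sor_air_pct: float
    sor_water_pct: float
    wsor: float
    corrections: list[str] = field(default_factory=list)

    def as_jsonable(self) -> dict:
        return {
            "window_keV": list(self.window.key()),
            "nonuniformity_pct": self.nonuniformity_pct,
            "rods": [
                {"diameter_mm": r.diameter_mm, "rc": r.rc, "pct_sd": r.pct_sd}
                for r in self.rods
            ],
            "sor_air_pct": self.sor_air_pct,
            "sor_water_pct": self.sor_water_pct,
            "wsor": self.wsor,
            "corrections": list(self.corrections),
        }


def compute_iq_report(
    image: ReconImage,
    spec: IQPhantomSpec,
    window: EnergyWindow,
    corrections: list[str] | None = None,
    rc_estimator: str = "profile",
) -> IQReport:
    """Run the full NEMA NU 4 metric set on one reconstructed volume."""
    vois = standard_vois(spec)
    uvals = image.volume[vois["uniform"].mask(image.grid)]
    u_mean = float(uvals.mean())
    u_sd = float(uvals.std(ddof=1))
    nu = nonuniformity(image, vois["uniform"])
    rods = recovery_coefficients(image, spec, u_mean, u_sd, estimator=rc_estimator)
    sor_a = spillover_ratio(image, vois["cold_air"], u_mean)
    sor_w = spillover_ratio(image, vois["cold_water"], u_mean)
    return IQReport(
        window=window,
        nonuniformity_pct=nu,
        rods=rods,
        sor_air_pct=sor_a,
        sor_water_pct=sor_w,
        wsor=weighted_sor(sor_a, sor_w),
        corrections=list(corrections or []),
    )


def select_optimal_window(reports: list[IQReport]) -> EnergyWindow:
    """Window minimizing wSOR; ties broken toward the larger ULD."""
    if not reports:
        raise ValueError("no reports to select from")
    best = min(reports, key=lambda r: (r.wsor, -r.window.uld))
    ties = [r for r in reports if r.wsor == best.wsor and r is not best]
    if ties:
        warnings.warn(
            f"wSOR tie at {best.wsor:.4f}; choosing wider window {best.window}"
        )
    return best.window


def reports_to_dataframe(reports: list[IQReport]) -> pd.DataFrame:
    """Tabulate reports: one row per window (SOR air/water, wSOR, NU, RCs)."""
    rows = []
    for r in reports:
        row = {
            "window": str(r.window),
            "lld_keV": r.window.key()[0],
            "uld_keV": r.window.key()[1],
            "corrections": "+".join(r.corrections),
            "nonuniformity_pct": r.nonuniformity_pct,
            "sor_air_pct": r.sor_air_pct,
            "sor_water_pct": r.sor_water_pct,
            "wsor": r.wsor,
        }
        for rod in r.rods:
            row[f"rc_{rod.diameter_mm:.0f}mm"] = rod.rc
            row[f"rc_{rod.diameter_mm:.0f}mm_pct_sd"] = rod.pct_sd
        rows.append(row)
    return pd.DataFrame(rows)
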