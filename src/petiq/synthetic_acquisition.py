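"""Synthetic PET acquisition model for the energy-window study.

Generates per-energy-window sinogram components (trues, scatter, randoms,
prompt-gamma) and count-rate series with the statistical structure the
analysis assumes: Poisson counts, scatter as a broad blur of the emission,
randoms scaling with activity squared, and a prompt-gamma contamination whose
share of all prompts equals the window's prompt-gamma coincidence fraction
(PGF).  ^124^I emits 602-1691 keV cascade gammas with only 23% of decays
producing a positron, so a cascade gamma paired with an annihilation photon
produces a spurious "prompt-gamma" coincidence; the generator injects that
component either flat across the field of view (its default, matching its
appearance as diffuse background) or as a blurred copy of the emission.

Geometry is reduced to independent 2D transaxial slices (direct planes
only); projections are discrete Radon transforms.  Every stochastic
operation takes an explicit seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.transform import radon

from .phantom_geometry import MU_511_PER_MM, VoxelGrid
from .reference import SENSITIVITY_UNCORRECTED_PCT

__all__ = [
    "IsotopeSpec",
    "I124",
    "F18",
    "EnergyWindow",
    "AcquisitionConfig",
    "SinogramSet",
    "CountRates",
    "SensitivityAcquisition",
    "geometric_sensitivity_for_window",
    "scatter_fraction_for_window",
    "forward_project",
    "expected_trues_sinogram",
    "attenuation_factors",
    "scatter_component",
    "prompt_gamma_component",
    "randoms_component",
    "apply_poisson",
    "simulate_sensitivity_acquisition",
    "simulate_countrates",
]

DEFAULT_SEED = 20160322


@dataclass(frozen=True)
class IsotopeSpec:
    """Decay physics of a PET isotope.

    ``branching_ratio`` is the positron fraction per decay; ``gamma_lines``
    are (energy keV, intensity per decay) pairs for the cascade photons that
    cause prompt-gamma coincidences.
    """

    name: str
    half_life_s: float
    branching_ratio: float
    gamma_lines: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 < self.branching_ratio <= 1.0:
            raise ValueError("branching_ratio must be in (0, 1]")
        if self.half_life_s <= 0:
            raise ValueError("half_life_s must be > 0")
        for e, i in self.gamma_lines:
            if not 0.0 <= i <= 1.0:
                raise ValueError(f"gamma line intensity out of [0,1]: {i}")

    @property
    def decay_constant(self) -> float:
        return np.log(2.0) / self.half_life_s


#: ^124^I: half-life 4.18 d, 23% positron branching, cascade gammas at
#: 602 (60%), 722 (10%) and 1691 (11%) keV.
I124 = IsotopeSpec(
    "I-124",
    half_life_s=4.18 * 86400.0,
    branching_ratio=0.23,
    gamma_lines=((602.0, 0.60), (722.0, 0.10), (1691.0, 0.11)),
)

#: ^18^F: half-life 109.74 min, 97% positron branching, no cascade gammas.
F18 = IsotopeSpec("F-18", half_life_s=109.74 * 60.0, branching_ratio=0.97)


@dataclass(frozen=True, order=True)
class EnergyWindow:
    """Photon acceptance window [lld, uld] in keV."""

    lld: float
    uld: float

    def __post_init__(self) -> None:
        if not self.lld < self.uld:
            raise ValueError(f"need lld < uld, got {self.lld}~{self.uld}")
        if self.lld <= 0:
            raise ValueError("lld must be positive")

    @property
    def width(self) -> float:
        return self.uld - self.lld

    def key(self) -> tuple[int, int]:
        return (int(round(self.lld)), int(round(self.uld)))

    def __str__(self) -> str:
        return f"{self.key()[0]}~{self.key()[1]}"


@dataclass(frozen=True)
class AcquisitionConfig:
    """Knobs of the synthetic scanner.

    The defaults emulate an Inveon-like geometry (161 mm ring, ~100 mm
    transaxial FOV) at the study's reconstruction sampling: 0.776 mm radial
    bins matched to the reconstructed pixel size, 180 views over 180 deg.

    ``scatter_fraction`` / ``geometric_sensitivity``: if None they are
    derived per energy window (see :func:`scatter_fraction_for_window` and
    :func:`geometric_sensitivity_for_window`).  ``randoms_coefficient`` is
    the randoms rate per squared MBq at the 350~750 reference window width;
    randoms scale with window width.  ``sensitivity_scale`` down-samples the
    detected counts of image simulations to a tractable level without
    changing component ratios.
    """

    n_angles: int = 180
    n_radial_bins: int = 64
    radial_bin_size: float = 0.776  # mm
    scatter_fraction: float | None = None
    scatter_sigma_bins: float = 12.0
    prompt_gamma_shape: str = "flat"  # "flat" | "object"
    randoms_coefficient: float = 1000.0  # cps / MBq^2 at 400 keV window width
    deadtime_tau: float = 0.2e-6  # s, non-paralyzable
    resolution_fwhm_mm: float = 2.38  # system + positron-range blur for 124I
    geometric_sensitivity: float | None = None  # fraction, per window if None
    sensitivity_scale: float = 1.0
    intrinsic_background_rate: float = 50.0  # cps, Lu-176 crystal background
    transaxial_fov_mm: float = 100.0
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.scatter_fraction is not None and not 0.0 <= self.scatter_fraction < 1.0:
            raise ValueError("scatter_fraction must be in [0, 1)")
        if self.deadtime_tau < 0:
            raise ValueError("deadtime_tau must be >= 0")
        if self.prompt_gamma_shape not in ("flat", "object"):
            raise ValueError("prompt_gamma_shape must be 'flat' or 'object'")


def geometric_sensitivity_for_window(
    window: EnergyWindow, config: AcquisitionConfig | None = None
) -> float:
    """Positron-event detection efficiency (fraction) for an energy window.

    Anchored to the measured ^18^F absolute sensitivities (branching-ratio
    corrected, i.e. per positron decay): at LLD 350 keV the efficiency rises
    mildly with ULD; at LLD 400 keV it is distinctly lower.  Values between
    measured ULDs are linearly interpolated; beyond the measured range the
    endpoint slope is extended.
    """
    if config is not None and config.geometric_sensitivity is not None:
        return config.geometric_sensitivity
    br_f18 = F18.branching_ratio
    table = SENSITIVITY_UNCORRECTED_PCT["F-18"]
    lld, uld = window.lld, window.uld
    if abs(lld - 400.0) < 25.0:
        return table[(400, 590)] / br_f18 / 100.0
    ulds = np.array([550.0, 600.0, 650.0, 750.0])
    sens = np.array([table[(350, int(u))] for u in (550, 600, 650, 750)]) / br_f18 / 100.0
    # linear extension beyond the last anchor (slope of the final segment)
    if uld > ulds[-1]:
        slope = (sens[-1] - sens[-2]) / (ulds[-1] - ulds[-2])
        return float(sens[-1] + slope * (uld - ulds[-1]))
    return float(np.interp(uld, ulds, sens))


def scatter_fraction_for_window(
    window: EnergyWindow, config: AcquisitionConfig | None = None
) -> float:
    """Default scatter fraction per window.

    Scattered photons lose energy, so acceptance of scatter is governed by
    the LLD: 0.30 at 350 keV falling linearly to 0.10 at 400 keV (model
    defaults, not measured values).  The ULD has negligible effect because
    scatter lies below the photopeak.
    """
    if config is not None and config.scatter_fraction is not None:
        return config.scatter_fraction
    sf = 0.30 - 0.004 * (window.lld - 350.0)
    return float(np.clip(sf, 0.10, 0.95))


# ---------------------------------------------------------------------------
# Sinogram components
# ---------------------------------------------------------------------------


def _theta(config: AcquisitionConfig) -> np.ndarray:
    return np.linspace(0.0, 180.0, config.n_angles, endpoint=False)


def forward_project(
    activity: np.ndarray, grid: VoxelGrid, config: AcquisitionConfig
) -> np.ndarray:
    """Discrete Radon transform of the activity volume, slice by slice.

    Returns line integrals (activity concentration x path length, units
    Bq/mL x mm) indexed ``(angle, radial_bin, slice)``.  The radial sampling
    equals the in-plane voxel size; the number of radial bins equals the
    in-plane grid size.
    """
    activity = np.asarray(activity, dtype=np.float64)
    if activity.ndim != 3:
        raise ValueError("activity must be a 3D (x, y, z) volume")
    if np.any(activity < 0):
        raise ValueError("activity must be non-negative")
    if not activity.any():
        warnings.warn("forward_project: empty activity volume, returning zero sinogram")
    nx, ny, nz = activity.shape
    if nx != ny:
        raise ValueError("in-plane grid must be square for the Radon projector")
    theta = _theta(config)
    sino = np.empty((config.n_angles, nx, nz), dtype=np.float64)
    for k in range(nz):
        # radon returns (radial, angle); scale pixel sums to mm integrals
        sino[:, :, k] = radon(activity[:, :, k], theta=theta, circle=True).T
    return sino * grid.voxel_size[0]


def expected_trues_sinogram(
    activity: np.ndarray,
    grid: VoxelGrid,
    config: AcquisitionConfig,
    isotope: IsotopeSpec,
    window: EnergyWindow,
    duration_s: float,
) -> np.ndarray:
    """Expected true-coincidence counts per sinogram bin.

    The Radon projection fixes the spatial distribution; the total mass is
    total decays x positron branching ratio x per-window geometric
    sensitivity x ``sensitivity_scale``.
    """
    proj = forward_project(activity, grid, config)
    total = proj.sum()
    if total <= 0:
        return proj
    total_activity_bq = float(np.sum(activity)) * grid.voxel_volume / 1000.0
    lam = isotope.decay_constant
    decays = total_activity_bq * (1.0 - np.exp(-lam * duration_s)) / lam
    g = geometric_sensitivity_for_window(window, config)
    trues = decays * isotope.branching_ratio * g * config.sensitivity_scale
    return proj * (trues / total)


def attenuation_factors(
    material: np.ndarray, grid: VoxelGrid, config: AcquisitionConfig
) -> np.ndarray:
    """511 keV attenuation factor exp(-integral of mu) per sinogram bin.

    Factors are in (0, 1]; lines through air only give exactly 1.
    """
    mu = np.zeros(material.shape, dtype=np.float64)
    for label, mu_val in MU_511_PER_MM.items():
        mu[material == label] = mu_val
    theta = _theta(config)
    nx, ny, nz = mu.shape
    att = np.empty((config.n_angles, nx, nz), dtype=np.float64)
    for k in range(nz):
        path = radon(mu[:, :, k], theta=theta, circle=True).T * grid.voxel_size[0]
        att[:, :, k] = np.exp(-path)
    return np.clip(att, None, 1.0)


def scatter_component(true_sino: np.ndarray, scatter_fraction: float,
                      sigma_bins: float = 12.0) -> np.ndarray:
    """Broad scatter estimate: radially blurred trues, mass-locked to SF.

    The returned mass equals ``SF/(1-SF) x mass(true)`` so the scatter share
    of (trues + scatter) is exactly ``scatter_fraction``.
    """
    if not 0.0 <= scatter_fraction < 1.0:
        raise ValueError("scatter_fraction must be in [0, 1)")
    if scatter_fraction == 0.0 or not np.any(true_sino):
        return np.zeros_like(true_sino)
    blurred = ndimage.gaussian_filter1d(true_sino, sigma=sigma_bins, axis=1,
                                        mode="constant")
    target = scatter_fraction / (1.0 - scatter_fraction) * true_sino.sum()
    return blurred * (target / blurred.sum())


def prompt_gamma_component(
    true_sino: np.ndarray,
    scatter_sino: np.ndarray,
    pgf: float,
    shape: str = "flat",
    random_sino: np.ndarray | None = None,
) -> np.ndarray:
    """Prompt-gamma contamination sized so PG / (all prompts) = ``pgf``.

    ``shape='flat'`` spreads the component uniformly over every sinogram bin
    (diffuse spurious background); ``shape='object'`` follows a blurred copy
    of the emission (trues + scatter).
    """
    if not 0.0 <= pgf < 1.0:
        raise ValueError("pgf must be in [0, 1)")
    other = true_sino + scatter_sino
    if random_sino is not None:
        other = other + random_sino
    mass = pgf / (1.0 - pgf) * other.sum()
    if mass == 0.0:
        return np.zeros_like(true_sino)
    if shape == "flat":
        pg = np.full_like(true_sino, 1.0 / true_sino.size)
    elif shape == "object":
        pg = ndimage.gaussian_filter1d(true_sino + scatter_sino, sigma=6.0, axis=1,
                                       mode="constant")
        pg = pg / pg.sum()
    else:
        raise ValueError("shape must be 'flat' or 'object'")
    return pg * mass


def randoms_component(
    activity_mbq: float,
    config: AcquisitionConfig,
    sinogram_shape: tuple[int, int, int],
    duration_s: float = 1.0,
    window: EnergyWindow | None = None,
) -> np.ndarray:
    """Flat randoms sinogram; total rate = coefficient x activity^2.

    The coefficient is referenced to a 400 keV wide window and scales
    linearly with window width (wider windows accept more singles).
    """
    if activity_mbq < 0:
        raise ValueError("activity must be >= 0")
    width_factor = 1.0 if window is None else window.width / 400.0
    rate = config.randoms_coefficient * activity_mbq**2 * width_factor
    total = rate * duration_s
    n = int(np.prod(sinogram_shape))
    return np.full(sinogram_shape, total / n, dtype=np.float64)


@dataclass
class SinogramSet:
    """Per-component sinograms of one acquisition.

    Before Poisson sampling, ``prompts`` is exactly the elementwise sum of
    the stored components; ``noisy_prompts`` is filled by
    :func:`apply_poisson`.
    """

    true_: np.ndarray
    scatter: np.ndarray
    random: np.ndarray
    prompt_gamma: np.ndarray
    window: EnergyWindow
    duration_s: float
    seed: int | None = None
    noisy_prompts: np.ndarray | None = None

    def __post_init__(self) -> None:
        shapes = {a.shape for a in (self.true_, self.scatter, self.random, self.prompt_gamma)}
        if len(shapes) != 1:
            raise ValueError(f"component shapes differ: {shapes}")
        for name in ("true_", "scatter", "random", "prompt_gamma"):
            if np.any(getattr(self, name) < 0):
                raise ValueError(f"{name} component has negative bins")

    @property
    def prompts(self) -> np.ndarray:
        return self.true_ + self.scatter + self.random + self.prompt_gamma

    def save(self, stem: str | Path) -> None:
        """Write components as raw float64 arrays + one JSON sidecar."""
        stem = Path(stem)
        meta = {
            "shape": list(self.true_.shape),
            "dtype": "float64",
            "order": "C",
            "axes": ["angle", "radial", "slice"],
            "window_keV": list(self.window.key()),
            "duration_s": self.duration_s,
            "seed": self.seed,
            "components": {},
        }
        for name in ("true_", "scatter", "random", "prompt_gamma", "noisy_prompts"):
            arr = getattr(self, name)
            if arr is None:
                continue
            fname = f"{stem.name}_{name.rstrip('_')}.raw"
            np.asarray(arr, dtype=np.float64).tofile(stem.parent / fname)
            meta["components"][name] = fname
        (stem.parent / f"{stem.name}.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, stem: str | Path) -> "SinogramSet":
        stem = Path(stem)
        meta = json.loads((stem.parent / f"{stem.name}.json").read_text())
        shape = tuple(meta["shape"])

        def rd(name: str) -> np.ndarray | None:
            fname = meta["components"].get(name)
            if fname is None:
                return None
            return np.fromfile(stem.parent / fname, dtype=np.float64).reshape(shape)

        return cls(
            true_=rd("true_"),
            scatter=rd("scatter"),
            random=rd("random"),
            prompt_gamma=rd("prompt_gamma"),
            window=EnergyWindow(*meta["window_keV"]),
            duration_s=meta["duration_s"],
            seed=meta["seed"],
            noisy_prompts=rd("noisy_prompts"),
        )


def apply_poisson(sinogram_set: SinogramSet, seed: int | None = None) -> SinogramSet:
    """Poisson-sample the prompts; noiseless components are kept alongside.

    Reproducible: the same seed yields identical counts.
    """
    seed = sinogram_set.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    noisy = rng.poisson(sinogram_set.prompts).astype(np.float64)
    return replace(sinogram_set, noisy_prompts=noisy, seed=seed)


# ---------------------------------------------------------------------------
# Sensitivity and count-rate simulations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SensitivityAcquisition:
    """One simulated sensitivity measurement (point/line source, low activity)."""

    isotope: IsotopeSpec
    window: EnergyWindow
    prompt_counts: float
    background_counts: float
    background_duration_s: float
    duration_s: float
    activity_bq: float


def simulate_sensitivity_acquisition(
    isotope: IsotopeSpec,
    window: EnergyWindow,
    true_pgf: float,
    activity_bq: float,
    duration_s: float = 300.0,
    config: AcquisitionConfig | None = None,
    seed: int = DEFAULT_SEED,
    background_duration_s: float = 3600.0,
) -> SensitivityAcquisition:
    """Simulate a low-activity sensitivity scan with known injected PGF.

    Expected trues = decays x branching ratio x geometric sensitivity;
    prompt-gamma coincidences are added so their share of all coincidences is
    ``true_pgf`` (zero for pure positron emitters), plus a constant
    ^176^Lu-like intrinsic background.  Warns if the dead-time loss at this
    activity exceeds 1%, which would bias a sensitivity measurement.
    """
    if not 0.0 <= true_pgf < 1.0:
        raise ValueError("true_pgf must be in [0, 1)")
    if activity_bq <= 0:
        raise ValueError("activity must be > 0")
    config = config or AcquisitionConfig()
    g = geometric_sensitivity_for_window(window, config)
    lam = isotope.decay_constant
    decays = activity_bq * (1.0 - np.exp(-lam * duration_s)) / lam
    trues = decays * isotope.branching_ratio * g
    coincidence_rate = trues / duration_s / (1.0 - true_pgf)
    loss = 1.0 - 1.0 / (1.0 + coincidence_rate * config.deadtime_tau)
    if loss >= 0.01:
        warnings.warn(
            f"dead-time loss {loss:.1%} >= 1% at {activity_bq/1e3:.0f} kBq; "
            "sensitivity will be biased low"
        )
    pg = true_pgf / (1.0 - true_pgf) * trues
    bg_rate = config.intrinsic_background_rate
    rng = np.random.default_rng(seed)
    prompt_counts = float(rng.poisson(trues + pg + bg_rate * duration_s))
    background_counts = float(rng.poisson(bg_rate * background_duration_s))
    return SensitivityAcquisition(
        isotope=isotope,
        window=window,
        prompt_counts=prompt_counts,
        background_counts=background_counts,
        background_duration_s=background_duration_s,
        duration_s=duration_s,
        activity_bq=activity_bq,
    )


@dataclass(frozen=True)
class CountRates:
    """Observed coincidence rates (cps) at one activity and window.

    ``trues`` is the prompt-gamma-corrected true rate; ``prompt_gamma`` is
    the spurious cascade-coincidence rate implied by the window's PGF.
    """

    activity_mbq: float
    trues: float
    scatter: float
    randoms: float
    prompt_gamma: float
    window: EnergyWindow

    def __post_init__(self) -> None:
        for name in ("trues", "scatter", "randoms", "prompt_gamma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} rate must be >= 0")


def simulate_countrates(
    activity_grid_mbq: list[float] | np.ndarray,
    window: EnergyWindow,
    config: AcquisitionConfig | None = None,
    pgf: float | None = None,
    isotope: IsotopeSpec = I124,
    noisy: bool = False,
    seed: int = DEFAULT_SEED,
) -> list[CountRates]:
    """Analytic count-rate model over an activity series (mouse phantom).

    Ideal trues are linear in activity (branching ratio x per-window
    sensitivity), scatter follows the window's scatter fraction, randoms grow
    with activity squared, the prompt-gamma rate follows the window's PGF,
    and all coincidences saturate under a shared non-paralyzable dead time.
    ``pgf=None`` looks the window up in the measured ^124^I PGF table.
    """
    config = config or AcquisitionConfig()
    if pgf is None:
        from .pgf_sensitivity import PGFTable  # local import: avoid cycle at import time

        pgf = PGFTable.reference().lookup(window)
    rng = np.random.default_rng(seed)
    out = []
    for a in activity_grid_mbq:
        if a <= 0:
            raise ValueError("activities must be > 0")
        g = geometric_sensitivity_for_window(window, config)
        sf = scatter_fraction_for_window(window, config)
        trues = a * 1.0e6 * isotope.branching_ratio * g
        scatter = sf / (1.0 - sf) * trues
        pg = pgf / (1.0 - pgf) * (trues + scatter)
        randoms = config.randoms_coefficient * a**2 * window.width / 400.0
        total = trues + scatter + pg + randoms
        live = 1.0 / (1.0 + total * config.deadtime_tau)  # non-paralyzable loss
        rates = np.array([trues, scatter, randoms, pg]) * live
        if noisy:
            rates = rng.poisson(rates).astype(float)
        out.append(
            CountRates(
                activity_mbq=float(a),
                trues=float(rates[0]),
                scatter=float(rates[1]),
                randoms=float(rates[2]),
                prompt_gamma=float(rates[3]),
                window=window,
            )
        )
    return out
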