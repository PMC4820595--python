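"""2D filtered backprojection, slice by slice.

Plain ramp filter (no apodization) at full Nyquist cutoff by default,
linear-interpolation backprojection, 0.776 mm pixels matched to the radial
bin size.  FBP is linear, so negative sinogram bins left by the
scatter/prompt-gamma subtraction propagate into the image — required for
negative cold-region spillover ratios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from skimage.transform import iradon

from .phantom_geometry import VoxelGrid
from .synthetic_acquisition import AcquisitionConfig, EnergyWindow

__all__ = ["ReconImage", "fbp_reconstruct", "ssrb_collapse"]


@dataclass
class ReconImage:
    """Reconstructed volume plus acquisition/correction metadata."""

    volume: np.ndarray  # (x, y, z), relative activity concentration
    grid: VoxelGrid
    window: EnergyWindow | None = None
    corrections: list[dict] = field(default_factory=list)

    def save(self, path: str) -> None:
        nib.save(nib.Nifti1Image(self.volume.astype(np.float32), self.grid.affine), path)


def fbp_reconstruct(
    sinogram: np.ndarray,
    grid: VoxelGrid,
    config: AcquisitionConfig | None = None,
    filter_name: str = "ramp",
    cutoff: float = 1.0,
    window: EnergyWindow | None = None,
    corrections: list[dict] | None = None,
) -> ReconImage:
    """Filtered backprojection of an ``(angle, radial, slice)`` sinogram.

    Angles are assumed uniformly spaced over 180 degrees.  ``cutoff`` < 1
    truncates the ramp at that fraction of Nyquist (frequency-domain
    hard cut).  Output pixels are ``grid.voxel_size`` in-plane; image
    values are divided by the in-plane pixel size so the projector and the
    reconstructor are mutually inverse in physical (mm) units.
    """
    sino = np.asarray(sinogram, dtype=np.float64)
    if sino.ndim == 2:
        sino = sino[:, :, None]
    n_angles, n_radial, n_slices = sino.shape
    if n_angles < 16:
        warnings.warn(f"only {n_angles} projection angles; expect streak artifacts")
    if grid.shape[0] != n_radial or grid.shape[1] != n_radial:
        raise ValueError(
            f"grid in-plane shape {grid.shape[:2]} must match radial bins {n_radial}"
        )
    theta = np.linspace(0.0, 180.0, n_angles, endpoint=False)
    volume = np.empty((n_radial, n_radial, n_slices), dtype=np.float64)
    for k in range(n_slices):
        s = sino[:, :, k]
        if cutoff < 1.0:
            s = _apply_cutoff(s, cutoff)
        volume[:, :, k] = iradon(
            s.T,
            theta=theta,
            filter_name=filter_name,
            interpolation="linear",
            circle=True,
            output_size=n_radial,
        )
    volume /= grid.voxel_size[0]
    return ReconImage(
        volume=volume,
        grid=grid,
        window=window,
        corrections=list(corrections or []),
    )


def _apply_cutoff(sino_2d: np.ndarray, cutoff: float) -> np.ndarray:
    """Hard low-pass along the radial axis at ``cutoff`` x Nyquist."""
    n = sino_2d.shape[1]
    freq = np.fft.rfftfreq(n)  # cycles/bin, Nyquist = 0.5
    mask = (freq <= cutoff * 0.5).astype(float)
    return np.fft.irfft(np.fft.rfft(sino_2d, axis=1) * mask[None, :], n=n, axis=1)


def ssrb_collapse(oblique_sinograms: np.ndarray) -> np.ndarray:
    """Single-slice rebinning stub: average oblique segments into direct planes.

    The simulator only produces direct planes; this exists so externally
    supplied 4D ``(segment, angle, radial, slice)`` data can be collapsed.
    Not a Fourier rebinning.
    """
    arr = np.asarray(oblique_sinograms, dtype=np.float64)
    if arr.ndim != 4:
        raise ValueError("expected (segment, angle, radial, slice) data")
    return arr.mean(axis=0)
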