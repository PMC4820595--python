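"""Sinogram-domain correction chain.

Order convention (recorded in the :class:`CorrectionLedger`):
normalization -> dead time -> attenuation -> scatter / prompt-gamma -> decay.

The prompt-gamma correction subtracts ``scatter x PGF`` from the emission
sinogram.  Negative bins produced by the subtraction are preserved, never
clipped — cold-region spillover ratios can legitimately go negative after
over-subtraction, and clipping would bias them upward.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .synthetic_acquisition import IsotopeSpec, SinogramSet

__all__ = [
    "CorrectionLedger",
    "normalize",
    "deadtime_correct",
    "attenuation_correct",
    "estimate_scatter",
    "prompt_gamma_correct",
    "scatter_correct",
    "decay_correct",
    "correct_emission",
]

#: Canonical application order for the full chain.
CORRECTION_ORDER = ("normalization", "deadtime", "attenuation", "scatter", "prompt_gamma", "decay")


@dataclass
class CorrectionLedger:
    """Ordered provenance record of applied corrections."""

    steps: list[dict] = field(default_factory=list)

    def record(self, name: str, **params) -> None:
        if any(s["name"] == name for s in self.steps):
            raise ValueError(f"correction '{name}' already applied in this chain")
        self.steps.append({"name": name, **params})

    def names(self) -> list[str]:
        return [s["name"] for s in self.steps]

    def as_jsonable(self) -> list[dict]:
        return [dict(s) for s in self.steps]


def normalize(emission_sino: np.ndarray, norm_sino: np.ndarray | None = None,
              ledger: CorrectionLedger | None = None) -> np.ndarray:
    """Divide by per-bin detector efficiency factors (default: all ones)."""
    if norm_sino is None:
        out = np.array(emission_sino, dtype=np.float64, copy=True)
    else:
        norm = np.asarray(norm_sino, dtype=np.float64)
        if np.any(norm <= 0):
            raise ValueError("normalization factors must be > 0")
        out = emission_sino / norm
    if ledger is not None:
        ledger.record("normalization", uniform=norm_sino is None)
    return out


def deadtime_correct(observed_rate: float | np.ndarray, tau: float,
                     ledger: CorrectionLedger | None = None) -> float | np.ndarray:
    """Invert non-paralyzable dead time: R = R_obs / (1 - R_obs * tau)."""
    if tau < 0:
        raise ValueError("tau must be >= 0")
    obs = np.asarray(observed_rate, dtype=np.float64)
    if np.any(obs * tau >= 1.0):
        raise ValueError("observed_rate * tau >= 1: unphysical for non-paralyzable model")
    out = obs / (1.0 - obs * tau)
    if ledger is not None:
        ledger.record("deadtime", tau_s=tau)
    return float(out) if np.isscalar(observed_rate) else out


def attenuation_correct(emission_sino: np.ndarray, attenuation_sino: np.ndarray,
                        ledger: CorrectionLedger | None = None) -> np.ndarray:
    """Divide by attenuation factors (each in (0, 1])."""
    att = np.asarray(attenuation_sino, dtype=np.float64)
    if att.shape != np.shape(emission_sino):
        raise ValueError("attenuation sinogram shape mismatch")
    if np.any(att <= 0):
        raise ValueError("attenuation factors must be > 0")
    out = emission_sino / att
    if ledger is not None:
        ledger.record("attenuation")
    return out


def estimate_scatter(
    emission_sino: np.ndarray,
    method: str = "tail_fit",
    truth: np.ndarray | None = None,
    object_support_bins: int | None = None,
    smooth_sigma: float = 8.0,
) -> np.ndarray:
    """Scatter sinogram estimate.

    ``method='truth'`` returns the simulator's stored scatter component
    unchanged (unit-test / oracle mode).  ``method='tail_fit'`` fits, per
    angle and slice, a Gaussian through the emission tails outside the
    object support (central ``object_support_bins`` radial bins) and
    interpolates it under the object; the fit is a least-squares parabola in
    log-counts, which is exact for Gaussian tails.
    """
    emission = np.asarray(emission_sino, dtype=np.float64)
    if method == "truth":
        if truth is None:
            raise ValueError("truth mode needs the stored scatter component")
        return np.array(truth, copy=True)
    if method != "tail_fit":
        raise ValueError("method must be 'truth' or 'tail_fit'")
    if not emission.any():
        return np.zeros_like(emission)
    n_r = emission.shape[1]
    if object_support_bins is None:
        object_support_bins = n_r // 2
    half = object_support_bins // 2
    center = n_r // 2
    tail = np.ones(n_r, dtype=bool)
    tail[max(center - half, 0): center + half] = False
    if not tail.any():
        raise ValueError("no radial bins outside the object support for tail fitting")
    r = np.arange(n_r) - center
    # mean tail profile per (angle, slice), smoothed; fit A*exp(-r^2/2s^2)
    est = np.empty_like(emission)
    prof = emission.mean(axis=0)  # (radial, slice) averaged over angles
    for k in range(emission.shape[2]):
        y = np.maximum(prof[:, k], 0.0)
        yt = y[tail]
        if yt.sum() <= 0:
            est[:, :, k] = 0.0
            continue
        w = yt
        logy = np.log(np.maximum(yt, 1e-12))
        # weighted quadratic fit in r; concavity clamped so the shape stays Gaussian
        coef = np.polyfit(r[tail], logy, 2, w=np.sqrt(w))
        if coef[0] > 0:
            coef[0] = 0.0
        fit = np.exp(np.polyval(coef, r))
        fit = ndimage.gaussian_filter1d(fit, smooth_sigma, mode="nearest")
        est[:, :, k] = fit[None, :]
    return np.clip(est, 0.0, None)


def prompt_gamma_correct(emission_sino: np.ndarray, scatter_sino: np.ndarray,
                         pgf: float, ledger: CorrectionLedger | None = None) -> np.ndarray:
    """Prompt-gamma-corrected emission = emission - scatter x PGF.

    Elementwise; negatives preserved.
    """
    if not 0.0 <= pgf < 1.0:
        raise ValueError("pgf must be in [0, 1)")
    scatter = np.asarray(scatter_sino, dtype=np.float64)
    if scatter.shape != np.shape(emission_sino):
        raise ValueError("scatter sinogram shape mismatch")
    out = emission_sino - scatter * pgf
    if ledger is not None:
        ledger.record("prompt_gamma", pgf=pgf)
    return out


def scatter_correct(emission_sino: np.ndarray, scatter_sino: np.ndarray,
                    ledger: CorrectionLedger | None = None) -> np.ndarray:
    """Subtract the scatter estimate; negatives preserved."""
    scatter = np.asarray(scatter_sino, dtype=np.float64)
    if scatter.shape != np.shape(emission_sino):
        raise ValueError("scatter sinogram shape mismatch")
    out = emission_sino - scatter
    if ledger is not None:
        ledger.record("scatter")
    return out


def decay_correct(counts: float | np.ndarray, elapsed_s: float,
                  isotope: IsotopeSpec,
                  ledger: CorrectionLedger | None = None) -> float | np.ndarray:
    """Decay-correct counts back to the reference time: x 2^(elapsed/T_half)."""
    if elapsed_s < 0:
        raise ValueError("elapsed time must be >= 0")
    factor = 2.0 ** (elapsed_s / isotope.half_life_s)
    if ledger is not None:
        ledger.record("decay", elapsed_s=elapsed_s, isotope=isotope.name, factor=factor)
    return counts * factor


def correct_emission(
    sinogram_set: SinogramSet,
    attenuation_sino: np.ndarray,
    pgf: float,
    apply_scatter: bool = True,
    apply_prompt_gamma: bool = True,
    scatter_method: str = "truth",
    norm_sino: np.ndarray | None = None,
    subtract_randoms: bool = True,
    pg_from_scatter_corrected: bool = False,
) -> tuple[np.ndarray, CorrectionLedger]:
    """Full correction chain on a (noisy) acquisition.

    Starts from the noisy prompts if present, subtracts the randoms estimate,
    then applies normalization -> attenuation -> scatter subtraction and/or
    prompt-gamma subtraction (``scatter x PGF``).  The nested variants AC,
    AC+SC and AC+SC+PGF are selected with the two ``apply_*`` flags.

    ``pg_from_scatter_corrected`` controls whether the scatter estimate used
    for the prompt-gamma term is taken before (default, the literal
    emission-sinogram formulation) or after its own subtraction; both give
    the same result here because the same scatter estimate is used for both
    subtractions.
    """
    ledger = CorrectionLedger()
    prompts = sinogram_set.noisy_prompts
    if prompts is None:
        prompts = sinogram_set.prompts
    emission = np.array(prompts, dtype=np.float64, copy=True)
    if subtract_randoms:
        emission = emission - sinogram_set.random
        ledger.record("randoms_subtraction")
    emission = normalize(emission, norm_sino, ledger)
    emission = attenuation_correct(emission, attenuation_sino, ledger)
    if apply_scatter or apply_prompt_gamma:
        scatter = estimate_scatter(emission, method=scatter_method,
                                   truth=sinogram_set.scatter)
        if scatter_method == "truth":
            # stored component is detected counts; move it into the AC'd frame
            scatter = scatter / attenuation_sino
    if apply_scatter:
        emission = scatter_correct(emission, scatter, ledger)
    if apply_prompt_gamma:
        emission = prompt_gamma_correct(emission, scatter, pgf, ledger)
    return emission, ledger
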