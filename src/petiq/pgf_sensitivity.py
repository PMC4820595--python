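"""Sensitivity analysis and prompt-gamma coincidence fraction (PGF) estimation.

For a non-pure positron emitter such as ^124^I (23% positron branching,
cascade gammas at 602-1691 keV), part of the recorded coincidences pair a
cascade gamma with an annihilation photon instead of two annihilation
photons.  The PGF for an energy window is estimated from paired sensitivity
measurements of ^124^I and a pure emitter (^18^F):

1. absolute sensitivity S = net coincidences / decays (percent),
2. branching-ratio-corrected sensitivity S* = S / branching ratio
   (percent of positron decays),
3. PGF = (S*_124I - S*_18F) / S*_124I.

A pure emitter's corrected sensitivity equals the geometric detection
efficiency; any excess in the ^124^I corrected sensitivity is prompt-gamma
contamination, so the relative excess is the fraction of ^124^I coincidences
that are prompt-gamma events.
"""

from __future__ import annotations

import csv
import io
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .reference import REFERENCE_PGF
from .synthetic_acquisition import (
    EnergyWindow,
    IsotopeSpec,
    SensitivityAcquisition,
)

__all__ = [
    "SensitivityMeasurement",
    "PGFTable",
    "absolute_sensitivity",
    "branching_ratio_correct",
    "compute_pgf",
    "pgf_for_window",
    "sensitivity_from_acquisition",
    "extrapolate_sleeve_sensitivity",
]


def absolute_sensitivity(
    prompt_counts: float,
    background_counts: float,
    duration_s: float,
    activity_bq: float,
    background_duration_s: float | None = None,
    isotope: IsotopeSpec | None = None,
) -> float:
    """Absolute sensitivity in percent of decays.

    The intrinsic/background measurement (typically a long separate scan) is
    converted to a rate and subtracted from the prompts:
    ``S = 100 x (prompts - bg_rate x duration) / decays``.
    With an ``isotope`` given, the number of decays accounts for decay of
    the source during the scan (a 1.6% effect for a 5-min ^18^F scan, which
    would otherwise leak into the PGF); without one, decays = activity x
    duration.  A net count below zero (background fluctuation) is floored at
    0 with a warning.
    """
    if duration_s <= 0:
        raise ValueError("duration must be > 0")
    if activity_bq <= 0:
        raise ValueError("activity must be > 0")
    bg_dur = duration_s if background_duration_s is None else background_duration_s
    if bg_dur <= 0:
        raise ValueError("background duration must be > 0")
    net = prompt_counts - background_counts / bg_dur * duration_s
    if net < 0:
        warnings.warn("net counts negative after background subtraction; flooring at 0")
        net = 0.0
    if isotope is None:
        decays = duration_s * activity_bq
    else:
        lam = isotope.decay_constant
        decays = activity_bq * (1.0 - np.exp(-lam * duration_s)) / lam
    return 100.0 * net / decays


def branching_ratio_correct(sensitivity_pct: float, isotope: IsotopeSpec) -> float:
    """Convert percent-of-decays sensitivity to percent-of-positron-decays."""
    if isotope.branching_ratio <= 0:
        raise ValueError("branching ratio must be > 0")
    return sensitivity_pct / isotope.branching_ratio


def compute_pgf(s_i124_corrected_pct: float, s_f18_corrected_pct: float) -> float:
    """PGF = (S*_124I - S*_18F) / S*_124I, clipped to [0, 1).

    Both inputs are branching-ratio-corrected sensitivities in percent.  A
    negative difference (measurement noise) clips to 0 with a warning.
    """
    if s_i124_corrected_pct <= 0:
        raise ValueError("124I corrected sensitivity must be > 0")
    pgf = (s_i124_corrected_pct - s_f18_corrected_pct) / s_i124_corrected_pct
    if pgf < 0:
        warnings.warn(f"negative PGF {pgf:.4f} clipped to 0")
        return 0.0
    return float(min(pgf, np.nextafter(1.0, 0.0)))


@dataclass(frozen=True)
class SensitivityMeasurement:
    """One isotope/window sensitivity result (raw and corrected, percent)."""

    isotope: IsotopeSpec
    window: EnergyWindow
    prompt_counts: float
    background_counts: float
    duration_s: float
    activity_bq: float
    sensitivity_uncorrected_pct: float
    sensitivity_br_corrected_pct: float


def sensitivity_from_acquisition(acq: SensitivityAcquisition) -> SensitivityMeasurement:
    """Reduce a (simulated or real) sensitivity acquisition to sensitivities."""
    s = absolute_sensitivity(
        acq.prompt_counts,
        acq.background_counts,
        acq.duration_s,
        acq.activity_bq,
        background_duration_s=acq.background_duration_s,
        isotope=acq.isotope,
    )
    return SensitivityMeasurement(
        isotope=acq.isotope,
        window=acq.window,
        prompt_counts=acq.prompt_counts,
        background_counts=acq.background_counts,
        duration_s=acq.duration_s,
        activity_bq=acq.activity_bq,
        sensitivity_uncorrected_pct=s,
        sensitivity_br_corrected_pct=branching_ratio_correct(s, acq.isotope),
    )


def extrapolate_sleeve_sensitivity(
    sleeve_counts: dict[int, float]
) -> float:
    """Zero-sleeve sensitivity by log-linear extrapolation over sleeve number.

    The NEMA NU 2 sensitivity protocol surrounds the line source with 1-5
    aluminum sleeves of 1 mm wall; attenuation is exponential in sleeve
    thickness, so log(counts) is linear in sleeve count and the intercept at
    zero sleeves is the unattenuated sensitivity.
    """
    if len(sleeve_counts) < 2:
        raise ValueError("need at least two sleeve measurements to extrapolate")
    n = np.array(sorted(sleeve_counts))
    y = np.array([sleeve_counts[k] for k in n], dtype=float)
    if np.any(y <= 0):
        raise ValueError("sleeve counts must be positive for log-linear fit")
    slope, intercept = np.polyfit(n, np.log(y), 1)
    return float(np.exp(intercept))


@dataclass(frozen=True)
class PGFTable:
    """Ordered map EnergyWindow -> PGF fraction in [0, 1)."""

    entries: tuple[tuple[EnergyWindow, float], ...]

    def __post_init__(self) -> None:
        for w, p in self.entries:
            if not 0.0 <= p < 1.0:
                raise ValueError(f"PGF out of [0,1) for {w}: {p}")

    @classmethod
    def from_dict(cls, mapping: dict[tuple[int, int], float]) -> "PGFTable":
        entries = tuple(
            (EnergyWindow(*key), float(pgf)) for key, pgf in sorted(mapping.items())
        )
        return cls(entries)

    @classmethod
    def reference(cls) -> "PGFTable":
        """The measured ^124^I PGF table for the Inveon study windows."""
        return cls.from_dict(REFERENCE_PGF)

    @classmethod
    def from_csv(cls, source: str | Path) -> "PGFTable":
        text = Path(source).read_text()
        rows = list(csv.DictReader(io.StringIO(text)))
        return cls.from_dict(
            {(int(r["lld_keV"]), int(r["uld_keV"])): float(r["pgf"]) for r in rows}
        )

    @classmethod
    def packaged(cls) -> "PGFTable":
        """Load the CSV fixture shipped with the package (same as reference)."""
        text = resources.files("petiq.data").joinpath("pgf_inveon_124i.csv").read_text()
        rows = list(csv.DictReader(io.StringIO(text)))
        return cls.from_dict(
            {(int(r["lld_keV"]), int(r["uld_keV"])): float(r["pgf"]) for r in rows}
        )

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["lld_keV", "uld_keV", "pgf"])
            for win, pgf in self.entries:
                w.writerow([win.key()[0], win.key()[1], pgf])

    def as_dict(self) -> dict[tuple[int, int], float]:
        return {w.key(): p for w, p in self.entries}

    def lookup(self, window: EnergyWindow) -> float:
        return pgf_for_window(self, window)


def pgf_for_window(table: PGFTable, window: EnergyWindow) -> float:
    """PGF for a window: exact lookup, else linear interpolation in ULD.

    Interpolation runs along windows sharing the query's LLD.  Queries
    outside the tabulated ULD range clamp to the nearest endpoint with a
    warning; an LLD absent from the table with no exact match is an error.
    """
    if not table.entries:
        raise ValueError("PGF table is empty")
    exact = table.as_dict().get(window.key())
    if exact is not None:
        return exact
    same_lld = [(w.uld, p) for w, p in table.entries if w.key()[0] == window.key()[0]]
    if len(same_lld) < 2:
        raise KeyError(
            f"window {window} not in PGF table and no bracketing entries at its LLD"
        )
    ulds, pgfs = zip(*sorted(same_lld))
    if window.uld < ulds[0] or window.uld > ulds[-1]:
        warnings.warn(f"ULD {window.uld} outside table range; clamping to endpoint")
    return float(np.interp(window.uld, ulds, pgfs))
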