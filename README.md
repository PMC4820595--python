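# petiq

Energy-window optimization and NEMA NU 4-2008 image-quality analysis for
non-pure positron emitters in preclinical PET, built around ^124^I on
Inveon-class small-animal scanners.

## The problem

^124^I is attractive for longitudinal small-animal imaging (half-life
4.18 d) but only 23% of its decays emit a positron, and its decay cascade
emits high-energy gammas (602, 722, 1691 keV). A cascade gamma recorded in
coincidence with an annihilation photon produces a *prompt-gamma
coincidence* — a spurious event that appears as diffuse background, inflates
cold-region spillover, and biases quantification. Choosing the acquisition
energy window is therefore a trade-off: a wide window collects more trues
but also more prompt-gamma background.

`petiq` implements the analysis chain a physicist needs to pick the window
on *image-quality* grounds rather than count-rate grounds:

1. **PGF estimation.** The prompt-gamma coincidence fraction for a window is
   measured from paired sensitivity scans of ^124^I and a pure positron
   emitter (^18^F). With branching-ratio-corrected sensitivities
   S\* = S / BR,

       PGF = (S*_124I − S*_18F) / S*_124I

   since a pure emitter's corrected sensitivity is the geometric detection
   efficiency, any relative excess for ^124^I is prompt-gamma contamination.
2. **Prompt-gamma correction** in the sinogram domain:
   `corrected = emission − scatter × PGF`, applied after normalization and
   attenuation correction; negative bins are preserved.
3. **2D FBP reconstruction** (ramp filter, 0.776 mm pixels) and
   **NEMA NU 4-2008 metrics**: nonuniformity (%SD of the uniform VOI),
   per-rod recovery coefficients with
   %SD_RC = 100·sqrt(CV²_profile + CV²_uniform), and spillover ratios for
   the air and nonradioactive-water cold chambers.
4. **Window selection** by the weighted spillover ratio

       wSOR = sqrt(f_air·SOR²_air + f_water·SOR²_water),

   with mouse-carcass volume fractions f_air = 0.027, f_water = 0.973; the
   window minimizing wSOR is optimal.
5. **PGF-augmented NECR**, `NECR = T² / (T + S + 2fR + f·P_g)`, for
   comparison with count-rate-based window selection.

A synthetic NEMA NU 4 phantom acquisition simulator (analytic projector,
per-window scatter/randoms/prompt-gamma components, Poisson noise) makes the
whole pipeline runnable and testable without scanner data.

## Worked example

```python
from petiq import (
    I124, F18, EnergyWindow, AcquisitionConfig,
    simulate_sensitivity_acquisition, sensitivity_from_acquisition,
    compute_pgf, weighted_sor,
)

window = EnergyWindow(350, 750)
config = AcquisitionConfig()

# paired sensitivity scans: 506 kBq 124I and 673 kBq 18F, 5 min each
acq_i = simulate_sensitivity_acquisition(I124, window, true_pgf=0.31,
                                         activity_bq=506e3, duration_s=300.0,
                                         config=config, seed=42)
acq_f = simulate_sensitivity_acquisition(F18, window, true_pgf=0.0,
                                         activity_bq=673e3, duration_s=300.0,
                                         config=config, seed=43)
m_i = sensitivity_from_acquisition(acq_i)
m_f = sensitivity_from_acquisition(acq_f)
print(f"124I sensitivity: {m_i.sensitivity_uncorrected_pct:.2f}% "
      f"({m_i.sensitivity_br_corrected_pct:.2f}% per positron)")
print(f"18F  sensitivity: {m_f.sensitivity_uncorrected_pct:.2f}% "
      f"({m_f.sensitivity_br_corrected_pct:.2f}% per positron)")
pgf = compute_pgf(m_i.sensitivity_br_corrected_pct, m_f.sensitivity_br_corrected_pct)
print(f"estimated PGF at {window}: {pgf:.2f}")
print(f"wSOR at {window}: {weighted_sor(-5.54, 0.26):.2f}")
```

prints

```
124I sensitivity: 2.27% (9.88% per positron)
18F  sensitivity: 6.61% (6.82% per positron)
estimated PGF at 350~750: 0.31
wSOR at 350~750: 0.95
```

The ^124^I source yields only ~2.3% of decays as coincidences, but per
*positron* decay it appears 45% more sensitive than ^18^F — that excess is
the 31% prompt-gamma contamination at the wide 350~750 keV window. The wSOR
of 0.95 combines the measured cold-chamber spillovers (−5.54% air, 0.26%
water) into the scalar the window selection minimizes.

The full study (11 windows, three nested correction sets, PGF + IQ + NECR
tracks) runs from the command line:

```bash
petiq -v run-study --seed 7 --out study_out   # ~20 s at desk scale
```

and writes per-window CSV tables (PGF, SOR/wSOR, recovery coefficients,
NECR curves) plus a manifest with the config hash and seed.

## Layout

- `src/petiq/phantom_geometry.py` — NEMA NU 4 IQ and mouse phantoms, voxelization
- `src/petiq/synthetic_acquisition.py` — projector, component model, noise, count rates
- `src/petiq/pgf_sensitivity.py` — sensitivities, PGF estimation, PGF tables
- `src/petiq/corrections.py` — normalization/attenuation/dead-time/decay/scatter/prompt-gamma chain
- `src/petiq/reconstruction.py` — 2D filtered backprojection
- `src/petiq/iq_metrics.py` — NU, RC, SOR, wSOR, window selection
- `src/petiq/necr.py` — prompt-gamma-augmented NECR curves
- `src/petiq/cli_report.py` — study orchestration, reporting, CLI
- `docs/methods.md` — model assumptions, parameter choices, limitations
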