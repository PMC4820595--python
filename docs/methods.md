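# Methods

## Scope and model overview

`petiq` analyzes the choice of PET energy window for ^124^I, a non-pure
positron emitter whose 602–1691 keV cascade gammas create prompt-gamma
coincidences. The package contains (a) the analysis proper — prompt-gamma
coincidence fraction (PGF) estimation, sinogram-domain corrections, NEMA
NU 4-2008 metrics, weighted-SOR window selection, and a PGF-augmented NECR
model — and (b) a synthetic acquisition model that generates data with the
statistical structure the analysis assumes. The synthetic model is an
analytic component model, not photon transport: it exists to exercise and
validate the analysis, not to predict scanner-specific absolute numbers.

## PGF estimation

For a window w, absolute sensitivity is S(w) = net coincidences / decays,
with the intrinsic ^176^Lu crystal background measured separately (default
1 h) and subtracted as a rate. Net counts are divided by the
decay-integrated number of decays, A₀(1−e^{−λT})/λ — for a 5-min ^18^F scan
ignoring decay would bias S by 1.6% and every derived PGF by ~+0.015, so
this is not optional. Branching-ratio correction divides by the positron
fraction (0.23 for ^124^I, 0.97 for ^18^F), putting both isotopes on a
per-positron-decay scale, and

PGF(w) = (S*₁₂₄ᵢ(w) − S*₁₈F(w)) / S*₁₂₄ᵢ(w).

The ^124^I-normalized form is used because PGF is defined as the fraction of
*recorded ^124^I coincidences* that are prompt-gamma events; with the
generator's bookkeeping (prompt-gamma share of coincidences = PGF exactly)
this estimator is unbiased, which the parameter-recovery tests confirm to
±0.02 across injected PGF ∈ {0, 0.13, 0.31}.

PGF tables are keyed by (LLD, ULD); lookups between tabulated ULDs at a
shared LLD interpolate linearly, and out-of-range queries clamp to the
nearest endpoint with a warning. The NEMA NU 2 aluminum-sleeve protocol is
supported by log-linear extrapolation of counts to zero sleeve thickness.

## Correction chain

Order: randoms subtraction → normalization → dead time → attenuation →
scatter / prompt-gamma → decay. The order is a package convention; each
step records itself in a `CorrectionLedger` embedded in output sidecars.
The prompt-gamma correction is `emission − scatter × PGF`, elementwise.
Negative bins are **never clipped**: cold-region means can legitimately go
negative after over-subtraction (measured SOR(air) reaches −6.47%), and
clipping would bias SOR upward. Dead time uses the non-paralyzable model
R = R_obs/(1 − R_obs·τ). Scatter can be taken from the simulator (oracle
mode for tests) or estimated by a Gaussian tail fit outside the object
support; the tail fit recovers the simulated scatter mass to ~15% on the
uniform phantom, which is adequate for its role here but is far cruder than
a single-scatter simulation.

## Reconstruction

2D filtered backprojection per axial slice, plain ramp filter at full
Nyquist, linear-interpolation backprojection, 0.776 mm pixels matched to
the radial bin size (the projector and reconstructor are mutually inverse
in mm units). FBP is linear, so the sign-preservation requirement above
propagates into images. Accuracy floor, verified by test: a uniform disk
round-trips with <3% in-disk mean error and <2% residual outside. Fourier
rebinning of oblique data is out of scope (the simulator emits direct
planes only); an SSRB averaging stub exists for externally supplied 4D data
and is clearly labelled as not a Fourier rebinning.

## NEMA NU 4-2008 metrics

* **Nonuniformity**: %SD (sample SD, n−1) of a 22.5 mm × 10 mm cylindrical
  VOI centered in the uniform region.
* **Recovery coefficients**: slices over the central 10 mm of the rod
  section are averaged; the hottest pixel in each rod ROI (circle of twice
  the rod diameter) fixes the location; RC = mean of the axial profile
  there / uniform mean (a max-pixel variant is available behind
  `estimator="max"`). %SD_RC combines profile and uniform CVs in
  quadrature. A rod whose peak does not rise 3 uniform-SDs above the rod
  section's zero-activity background is reported "not discernible" — at
  study count levels this removes the 1 mm rod, matching practice; the
  factor is configurable.
* **Spillover ratios**: mean of a 4 mm × 7.5 mm VOI centered in each cold
  chamber (half the chamber size, to reduce sensitivity to the long ^124^I
  positron range) divided by the uniform mean; negative values pass
  through.
* **wSOR** = sqrt(f_air·SOR²_air + f_water·SOR²_water) with f_air = 0.027
  and f_water = 0.973, the lung/water volume fractions of a mouse carcass.
  The optimal window is the argmin of wSOR; ties break toward the wider
  window (more trues at equal spillover) and are logged.

## NECR with a prompt-gamma term

NECR = T² / (T + S + 2fR + f·P_g), where T is the prompt-gamma-corrected
trues rate, f the average fraction of the projection subtended by the
object (diameter/FOV for a centered cylinder; 0.25 for the 25 mm mouse
phantom in the 100 mm FOV), and P_g the prompt-gamma coincidence rate,
taken as PGF/(1−PGF)·(T+S). The prompt-gamma penalty enters the denominator
weighted by f for the same reason randoms do: a flat background outside the
object can be discarded. An alternative "literal" reading that adds the
dimensionless f·PGF is provided for sensitivity analysis; it is negligible
at realistic rates and is not the default. With PGF = 0 the expression
reduces exactly to the classical NECR.

## Synthetic acquisition model

What it emulates, per energy window:

* **Trues** — discrete Radon transform (per-slice) of the activity map,
  attenuated by analytic 511 keV line integrals (μ = 0.096/cm water,
  0.112/cm PMMA, 0.226/cm aluminum), blurred radially by a Gaussian PSF of
  FWHM 2.38 mm (the reported ^124^I reconstructed resolution — without a
  PSF the phantom rods would show no partial-volume loss), and scaled so
  total counts = decays × BR × g(w) × duration. The per-window geometric
  sensitivity g(w) interpolates the measured ^18^F sensitivities in ULD.
* **Scatter** — a wide radial Gaussian blur (σ = 12 bins) of the trues with
  mass SF/(1−SF)·mass(trues). The default scatter fraction depends on the
  LLD only (0.30 at 350 keV → 0.10 at 400 keV, linear): scatter lies below
  the photopeak, so the LLD governs its acceptance. These are model
  defaults, not measured values.
* **Prompt gamma** — flat across the sinogram by default (the component
  appears as diffuse background), with mass set so its share of all prompts
  equals the window's PGF; an "object" shape (blurred emission) is
  available since the true spatial distribution is not established.
* **Randoms** — flat, rate = 1000 cps/MBq² × (window width / 400 keV). The
  coefficient is a model default chosen so the NECR curve peaks inside the
  1–50 MBq study range (~39 MBq).
* **Dead time** — shared non-paralyzable τ = 0.2 µs applied to all
  coincidence components; at the sensitivity-scan activities (506/673 kBq)
  losses stay below the 1% threshold the protocol requires, and the
  simulator warns when an activity violates it.
* **Noise** — Poisson sampling of the summed prompts, with the noiseless
  components stored alongside; every stochastic operation takes an explicit
  seed (default 20160322) and is reproducible bit-for-bit.

**Count scale.** The physical IQ protocol (14.4 MBq × 4700 s, chosen to
match positron counts with a standard ^18^F acquisition) corresponds to
~10¹¹ detected events. The simulator's `sensitivity_scale` down-samples
detected counts without changing component ratios; the study default of 0.1
puts reconstructed nonuniformity in the 5–10% range observed on real
hardware (≈7% at these settings), so noise-driven metrics operate in a
realistic regime. This is a choice of operating point for the synthetic
study, set once.

What the model does **not** capture: energy-resolved photon transport (the
14.5% energy resolution enters only through the per-window scatter-fraction
defaults), detector-block geometry and gaps, oblique planes/FORE,
positron-range asymmetry between air and water, scanner normalization
structure, and the absolute magnitudes of scatter/randoms on any particular
scanner. Consequently the synthetic study validates *relationships* (PGF
recovery, correction efficacy, metric stability across windows, NECR
shape), not the acquired-image values of any real system; in particular the
synthetic wSOR ranking across windows reflects the flat prompt-gamma model
and need not reproduce a measured ranking.

## Numerical and design notes

* Voxelization is voxel-center-in-region; VOIs and phantom compartments are
  defined in physical mm, grid-independent. Voxelized volumes converge to
  analytic volumes as the grid refines (tested at two resolutions).
* The projector/reconstructor rotation center is the n//2 pixel
  (scikit-image convention); phantoms are defined in physical coordinates,
  and forward/backprojection share the convention, so analyses are
  internally consistent.
* The study grid default is 64×64 in-plane (0.776 mm) × 27 slices (2 mm);
  the test suite uses 14 slices (4 mm) to stay fast. Both cover the full
  50 mm phantom.
* Sinograms are stored as raw float64 arrays with a JSON sidecar (shape,
  axes, window, seed, components); volumes as NIfTI with a mm affine;
  configs as YAML; tables as CSV. A study run records a manifest with the
  config hash and seed, and identical config + seed reproduce byte-identical
  outputs (tested).
* The dataclass defaults of `IQPhantomSpec` place the rod section at
  z ∈ [−25, −5] mm, the uniform chamber at [−5, 10] and the cold chambers
  at [10, 25], with a 2 mm PMMA wall; the wall material/thickness of real
  phantoms varies and both are configurable.

## Known limitations

* The tail-fit scatter estimator assumes a single broad Gaussian per slice;
  it will misbehave for strongly off-center or multi-object scenes.
* The prompt-gamma correction removes `scatter × PGF`; under the flat
  contamination model this removes only part of the injected prompt-gamma
  mass, so corrected spillover shrinks but does not vanish (the tests
  assert strict reduction, not elimination).
* Count-rate simulation treats the window's effect on randoms as a linear
  width factor and ignores pile-up mispositioning, which is one reason
  count-based and image-based window rankings disagree.
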