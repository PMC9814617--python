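# Methods

`sorsq` implements a complete through-container quantification workflow for
alcohol-based hand sanitizers measured by spatially offset Raman spectroscopy
(SORS): a physics-structured simulator of traditional/offset acquisition
pairs, scaled-subtraction and baseline preprocessing, multivariate engines
(MCR-ALS, PLS, ε-SVR), and a three-class quality decision tree.  This note
records the model, its assumptions, and the numerical choices that were
genuinely open.

## Measurement model

A traditional (zero-offset) and an offset acquisition of one sample are
modelled as linear mixtures of a container surface spectrum C(ν), a content
spectrum A(ν), a smooth fluorescence baseline b(ν), and noise:

    traditional = w_s·C + w_c·A + b + ε
    offset      = v_s·C + v_c·A + b/2 + ε′

with the defining SORS property v_c/v_s > w_c/w_s (the offset geometry is
relatively enriched in subsurface photons).  Content weights decrease with
container opacity; surface weights increase.  Glass containers contribute no
sharp bands, only broad silica structure (~560, ~1090 cm⁻¹) and a stronger
fluorescence baseline (amber glass strongest).

The content spectrum is the volume-fraction-weighted sum of pure-component
spectra.  Each component is a sum of Lorentzian bands (default fwhm
15–24 cm⁻¹, typical of liquids) at literature positions — e.g. ethanol 882,
1049, 1092, 1454 cm⁻¹; methanol 1030 cm⁻¹; 2-propanol 818, 950 cm⁻¹;
1-propanol 859, 888, 968 cm⁻¹ — scaled by the spontaneous Raman factor
(ν₀−ν)⁴ / (1−e^(−hcν/kT)) for 830 nm excitation at 298.15 K.  Relative band
intensities are synthetic-truth values chosen so the strongest-band ordering
is qualitatively correct; no instrument data underlie them.  Water
contributes only weak broad in-range structure (libration ~430 cm⁻¹ and the
1640 cm⁻¹ bend).

C–O and C–C stretching band centers shift with total alcohol fraction x as
Δν(x) = ±A·e^(−x/t), the exponential-decay law that describes
hydrogen-bonding–driven shifts in alcohol–water mixtures; defaults A = 10
cm⁻¹, t = 30 % v/v, with C–O modes moving up on dilution and C–C modes
down.  These are declared synthetic-truth parameters (the fitted values for
real mixtures are not publicly available).  Band tables are calibrated so the
literature position is reproduced exactly at the reference formulation
strength (80 % v/v for ethanol/methanol, 75 % for the propanols).

Noise is additive Gaussian with sd = 0.005·√(I·I_max) plus a 10 % dark
floor — a shot-noise-like approximation of Poisson-limited CCD detection at
0.5 % of the spectrum maximum.  All randomness flows from
`numpy.random.SeedSequence`; a cohort is bit-reproducible from its seed.

### What the simulator does not emulate

Photon-migration depth profiles, container thickness, colorants and liners,
gel-vs-liquid matrix effects, cosmic rays, detector nonlinearity, and
wavenumber-axis miscalibration.  Passing tests therefore demonstrate the
correctness and internal consistency of the analysis chain under the stated
physics, not instrument-grade performance on real products.

## Cohort designs

* Training: 4 alcohols × 9 containers = 36 single-alcohol content–container
  combinations at reference strength, plus augmentation in the fixed
  semitransparent HDPE container: 2 reference blanks, binary
  contaminant-in-approved mixtures at {2.5, 5, 10, 15, 20, 30} % v/v at fixed
  total alcohol (2 bases × 2 contaminants), and single-alcohol dilution
  series at {20, 35, 50, 65} % v/v — 78 combination-level spectra, each the
  average of 5 replicates.  Venetian-blinds cross-validation uses 39 splits
  of thickness one (sample i → fold i mod 39; two samples per fold).
* Test: 173 samples — 65 fair (approved alcohol U(62, 88) %), 24 subpotent
  (U(35, 58) %), 84 contaminated (methanol and/or 1-propanol replacing the
  approved alcohol at 2.5–30 % v/v; 20 % of cases carry both contaminants) —
  in randomly assigned containers; 120 house / 53 commercial origin labels.
  Ground-truth class labels are the construction classes.

## Preprocessing

Fixed order: iterative polynomial baseline (order 5, min-clip refitting) on
each acquisition → scaled subtraction → Whittaker/AsLS baseline → area
normalization.

Scale factor.  `content = offset − s·traditional`.  When container band
windows are known, s is the minimum over windows of the
|traditional|-weighted median of point-wise offset/traditional ratios — the
exact minimiser of the windowed L1 criterion, taken per window because
content overlap can only bias a window's ratio upward (a consequence of the
SORS enrichment inequality), so the cleanest window is the smallest.  Glass
containers use windows at their broad silica centers.  With no window
information, s is the largest value whose negative-lobe energy stays within
a noise floor estimated from second differences — the point at which surface
features begin to over-subtract.  Negative excursions are kept (clipping
would bias the band ratios used downstream).

Whittaker baseline.  Asymmetric least squares with second-difference penalty
λ = 1e5 and asymmetry p = 0.01 on the 1 cm⁻¹ grid, with peak-adaptive
weights w = p·e^(−r/k) for positive residuals r (k = 10 % of the signal
span).  The plain (p, 1−p) weighting contracts band intensity by several
percent on every application because it keeps chasing band tails; the
decaying weights remove this while still following low-contrast broad humps
(residual glass structure, fluorescence remnants).  Known limitation: heavy
Lorentzian tails and ~100 cm⁻¹ band clusters are themselves broad structure,
where repeated application still contracts the spectrum by ~2 %.  An
optional automatic λ search (fidelity–roughness product criterion on a log
grid) is provided but not used by default.

Area normalization.  The spectrum is divided by the trapezoidal integral of
the absolute value of a lightly smoothed copy (Whittaker smoother, λ = 1e4).
Integrating |raw intensity| would add the rectified noise ~0.8·σ per
channel to the area; with noise levels varying ~3× across container
opacities this inflates areas of opaque-container spectra by up to ~25 % and
systematically depresses their normalized band amplitudes.  Smoothing
preserves band integrals while suppressing the rectification bias.

Peak location uses 3-point parabolic refinement of the window maximum
(sub-grid resolution; concentration-dependent shifts are a few cm⁻¹ at most
and would otherwise be quantized away).

## Multivariate engines

MCR-ALS.  Non-negative alternating least squares, X ≈ C·S, solved exactly
per half-step with an active-set NNLS on the normal equations, so the
objective is non-increasing by construction.  Initialization picks the k
most mutually dissimilar rows (orthogonal-projection purity); components are
sorted by explained variance, and per-component fits partition the
cumulative fit in proportion to each rank-1 term's energy.  Constraints are
non-negativity only (no closure/unimodality).  Component identities are
assigned by maximal cosine similarity to reference spectra with one-to-one
(Hungarian) matching.

PLS.  Mean-centered (no variance scaling — spectra are already
area-normalized) NIPALS-equivalent factorization with 4 or 8 latent
variables, venetian-blinds CV, and Q-residual / Hotelling T² diagnostics
with 95 % limits (Box χ² approximation for Q, F-based for T²); diagnostics
flag samples but exclude nothing.

SVR.  ε-insensitive support vector regression with Gaussian RBF kernel, one
independent model per alcohol.  Features are the fingerprint windows within
±45 cm⁻¹ of any known component band: quiet channels carry no analyte
signal, and their noise otherwise dominates the kernel distances for
low-transmittance containers, pulling predictions toward the training mean.
Spectra are mean-centered and scaled by one global standard deviation
(preserving relative spectral structure).  Grid search over C ∈ 10⁰…10⁴ and
γ ∈ 10⁻⁴…10¹ (6 log-spaced values each, ε = 0.5 % v/v) minimises the
venetian-blinds CV RMSE; ties break toward smaller C, then smaller γ.  The
quadratic-programming solver is libsvm (scikit-learn); grid search, CV
layout, preprocessing state and persistence are owned here.

## Screening

Decision tree with contamination precedence: contaminated if any contaminant
≥ 5 % v/v (the upper edge of the method's 1–5 % detection-limit band),
else subpotent if ethanol + 2-propanol < 60 % v/v (CDC minimum; a WHO
preset with a 75 % floor is provided), else fair.  Negative predictions are
clamped to zero.  Contaminated samples constructed below the 5 % decision
threshold are irreducible tree errors by design — the same failure mode the
original screening method reports for low-level contamination.

Limit of detection.  From a blank-anchored dilution series: the mean blank
window shape is fitted to each replicate by a single scale factor and
subtracted (cancelling the approved-alcohol band tail and its multiplicative
jitter), the residual is correlated with a unit-norm Lorentzian band profile
(matched filter), and a concentration is detected when this signal exceeds
the blank mean by 3 blank standard deviations in ≥ 95 % of replicates.  The
LOD is the lowest detected tested concentration.

## Problem sizes and determinism

The default study replication uses the full 1601-point grid, 5 replicates
per training combination (390 + 173 simulated pairs), the 78-spectrum
averaged training matrix, and the 180-spectrum replicate-level matrix for
MCR; it completes in about a minute on one CPU.  The dedicated acceptance
checks reuse one such run.  Every stage seed derives from the global seed
via a documented SeedSequence word scheme (`stage_seed`), so deterministic
stages are bit-reproducible and stochastic results are exactly repeatable
for a given seed.
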