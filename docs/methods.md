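# Methods

This note records the models, parameter choices and numerical decisions
behind `rnawaxs`, and what the synthetic-data tests do and do not show
about real measurements.

## Idealized RNA models

All models are *reduced*: every heavy atom of phosphate, ribose and
base is present, hydrogens are folded into their parent heavy atom's
form factor (f(0) = Z + n_H).  At q ≤ 2.4 Å⁻¹ explicit hydrogens change
intensities by well under a percent while quadrupling the Debye pair
count.  Geometry is template-based — one nucleotide template per
residue placed on a mathematically regular helix — with no energy
minimization.  This is deliberate: the wide-angle features under study
are set by exactly the regularities the templates encode (backbone
helix radius and phasing, axial rise, coplanar stacked base planes),
so an idealized placement reproduces the features without molecular
dynamics.

Helical parameters (`HelicalParams`, all overridable):

| parameter | duplex default | triplex default | why |
|---|---|---|---|
| rise (Å/step) | 2.81 | 3.26 | canonical A-RNA; triple-stacking repeat |
| twist (°/step) | 32.7 (11 bp/turn) | 30.51 (11.8/turn) | canonical A-RNA; calibration knob |
| P radius (Å) | 8.8 (both strands) | 8.6 (all three) | calibrated, see below |
| strand phases (°) | 0, 110 | 0, 124, 200 | calibrated, see below |
| base anchor radius (Å) | 5.9 | 5.9 | glycosidic attachment |

The triplex rise of 3.26 Å is fixed by the stacking repeat of base
triples; the remaining values are free geometric knobs.  They were
calibrated once, by grid search, so that the Debye profiles of the
default models place their detected maxima at the diagnostic positions
(triplex backbone triplet near 1.0/1.4/1.7 Å⁻¹, stacking near
1.93 Å⁻¹, duplex groove near 0.8 Å⁻¹); with the defaults above the
models emit 1.03/1.38/1.69/1.93 and 0.77 Å⁻¹.  The calibration is to
those peak positions only — the models make no claim to base-pairing
chemistry, sugar pucker or groove-depth realism.

Hairpin loops bridge the two terminal stem phosphates on a circular
arc whose chord length matches the backbone step (so consecutive P–P
distances stay within 5.0–6.8 Å through the loop); 1–2-nt loops are
rejected as sterically impossible.  The folded 46-nt construct
(12U-5C-12U-5C-12A) is built as a 12-triple U·A-U core with the two
5-C linkers as capping arcs: 46 residues on one chain.

Disordered strands are self-avoiding coarse walks on phosphate
positions (mean step 5.9 Å, sd 0.6 Å clipped to [5.0, 6.8], 4.0 Å
exclusion, immediate fold-back forbidden), decorated with nucleotide
templates in random orientations.  A rigidly fixed step length would
imprint a sharp artificial correlation peak at 2π/5.9 ≈ 1.06 Å⁻¹ on an
otherwise featureless profile, so only helically stacked runs keep the
exact step.  `stacking_propensity` is the per-residue probability of
joining a stacked run (straight continuation, regular 30° azimuth
advance): 0 emulates rU30, ~0.6 emulates the partial ordering of rA30,
and the generator's own run labels are the bookkeeping that tests
count.  Known limitation: the walk's broad backbone-correlation
maximum centers near q ≈ 1.0 Å⁻¹, somewhat above the ≈ 0.8 Å⁻¹
observed for disordered strands; it is broad (width ≥ 0.3 Å⁻¹) and is
correctly ignored by the state classifier's sharpness rule.

## Debye scattering

I(q) = ΣᵢΣⱼ fᵢ(q)fⱼ(q)·sinc(q·rᵢⱼ), with the q→0 limit taken
analytically (never by division), so I(0) = (Σfᵢ(0))² exactly.  Form
factors use the standard 4-Gaussian International-Tables
parameterization.  Two evaluation modes share one code path for the
species grouping: `exact` performs the literal pair sum; `histogram`
bins pair distances per species pair at 0.01 Å (error well under any
structural peak width at q ≤ 2.4) and reduces the sum to one matrix
product — models of ~1,500 atoms evaluate in well under a second.

Profiles are computed with a uniform excluded-volume correction by
default (Gaussian-sphere displaced solvent, water density
0.334 e/Å³, scale configurable): solution experiments measure excess
intensity over solvent, and in vacuum the coherent form-factor decay
reduces every wide-angle feature to a shoulder with no local maximum.
With solvent contrast the features appear as the local maxima seen in
measured, background-subtracted data.  `excluded_volume=False` restores
vacuum scattering (used by the closed-form algebra tests).

## Fingerprinting

Peak detection operates on an affinely normalized profile
((I−min)/(max−min)), making every downstream decision exactly invariant
to positive rescaling and constant offsets.  The normalized profile is
smoothed by an 11-point quadratic Savitzky–Golay fit (preserves
positions to < 0.005 Å⁻¹ on the default 0.005 Å⁻¹ grid; 21 points
recommended for photon-noise-limited reduced profiles), a morphological
opening over a 0.45 Å⁻¹ window provides the local baseline (exact on
monotone stretches, so featureless decays yield no spurious bumps), and
positions are refined by parabolic interpolation.  Reported prominence
is relative to the local baseline level (floored at 2% of the dynamic
range so near-zero backgrounds cannot amplify noise).

Band windows default to helical-radius 0.30–0.50, major-groove
0.70–0.90, backbone 0.90–1.10 / 1.30–1.50 / 1.60–1.80, base-stacking
1.85–2.00 Å⁻¹ — symmetric about the feature centers, which are the
only quantities the data fix.  Each window takes at most one peak (the
most prominent; others are reported as shadowed).

The state call follows a rule table — triplex: ≥ 2 backbone bands and
no groove; duplex: groove and < 2 backbone bands; mixed: groove and
≥ 2 backbone bands; unstructured: nothing diagnostic — with three
floors deciding whether a hit "counts":

- sharpness: width ≤ 0.28 Å⁻¹.  Only sharp features mark well-defined
  molecular dimensions; the broad correlation maximum of a disordered
  chain must not fire a groove or backbone rule.
- noise-free profiles: relative prominence ≥ 2% (detection itself
  reports everything above 1%).
- profiles carrying uncertainties: statistical significance ≥ 6, where
  significance is peak prominence in intensity units over the noise
  surviving the smoothing filter (σ times the filter's coefficient
  norm).  On subtracted single-shot averages this is the meaningful
  scale; a fixed prominence floor would either drown real features or
  pass noise excursions.

All floors are recorded in every report and configurable.

## Shot reduction

The detector model is a flat panel normal to the beam: q(pixel) =
(4π/λ)·sin(½·atan(r/D)), λ = 12.3984/E keV·Å.  The default geometry
(6 keV, 106 mm) covers 0.12–2.4 Å⁻¹.  Radial averaging takes the mean
of unmasked pixels per q bin (500 linear bins by default); empty bins
are flagged NaN, never zero-filled.  Each shot is divided by its
pulse-energy reading, then a two-stage robust filter rejects outliers:
(1) spike — any bin exceeding 6 scaled MADs above the per-bin median
across shots (ice diffraction hits isolated bins hard); (2) drift —
integrated intensity beyond 5 MADs from the median.  Kept + rejected =
total always, per role.  The reduced profile is mean(sample) −
scale·mean(buffer) (scale 1.0 by default) with per-bin standard errors
propagated in quadrature.

## Kinetics and decomposition

The folding pathway is modelled as two sequential first-order steps
with closed-form fractions (and the k₁ = k₂ limiting form); the
defaults k₁ = 300 s⁻¹, k₂ = 60 s⁻¹ put the duplex transient's maximum
at ln(k₁/k₂)/(k₁−k₂) ≈ 6.7 ms — visible at 6 ms, diminished at 10 ms,
gone before 60 ms.  These are generator choices that realize the
observed qualitative sequence, not measured rates.

Mixture fits are nonnegative least squares on a 0.3–2.0 Å⁻¹ window
(excluding the noisy low-q edge and detector edge), inverse-sigma
weighted when uncertainties are present.  The default mode reports raw
nonnegative coefficients plus their sum (beam-illuminated concentration
may vary); `nonneg-sum1` normalizes the composition, which is
scale-invariant.  A basis with collinear columns on the window is
rejected naming the offending pair.

## Synthetic experiments

The generator emulates the serial measurement: per shot, expected
counts = pulse × (solute mixture + water background), realized as
Poisson draws per q bin (fast 1-D path) or per pixel through the
detector geometry (2-D path, used at small n to exercise radial
averaging).  Pulse energies are log-normal with 15% relative sd; the
water background has a broad maximum near q = 2 Å⁻¹; contaminated
frames (2% default; 5% in the stress tests) receive localized
high-intensity spikes.  Defaults: 15,000 background and 4,000 solute
counts per bin per pulse — chosen once so that the scaled-down study
(2,000 shots per point versus the ~16,000 of a full experiment; five
time points 0/6/10/60/1000 ms) leaves the diagnostic features
statistically detectable in a single reduced time point, as they are in
full-scale averages.  Every stack carries its truth (per-frame pulse
energies and contamination labels, true fractions, the generating
mixture profile), sub-seeds derive deterministically from the master
seed, and bundles round-trip bit-identically through HDF5.

The basis states are computed from the models: disordered 46-nt
ensemble (24 conformers, stacking propensity 0.15), the 29-nt
12U-5C-12A hairpin with its remaining 17 nt as a disordered tail
(8 conformers), and the folded 46-nt triplex construct.

What passing tests show: the pipeline's statistics are calibrated
(recovery within stated error bars), selection is sensitive and
specific against known contamination, and the state logic reads the
correct sequence off data with realistic Poisson/jitter/contamination
structure.  What they do not show: robustness to real-detector
systematics (gain maps, geometry miscalibration, parasitic scattering),
jet instabilities beyond a scalar drift, solvent-density changes on
mixing, or radiation damage; and the synthetic profiles inherit the
idealized models' geometry, so real profiles' positions may differ in
detail.

## Problem sizes

Default test and acceptance scales: models up to ~1,500 atoms
(histogram Debye, sub-second), ensembles of 24–30 conformers, 2,000
shots per role per time point, 5 time points.  The full suite runs in
well under a minute on one CPU.
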