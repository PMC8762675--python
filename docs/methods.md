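# Methods

`octsf` implements a point-to-point structure–function analysis for outer
retinal degenerations, with hydroxychloroquine (HCQ) retinopathy as the
motivating disease. Function is measured by Humphrey 10-2 perimetry (68
loci, dB sensitivity); structure by SD-OCT-derived metrics sampled at the
retinal locations of those same loci. Because no patient data ship with
the package, a first-class synthetic cohort generator produces complete
study cohorts with a known ground-truth structure–function rule, so every
stage — image preprocessing, scaffold sampling, grading, regression and
prediction — can be validated against an oracle.

## The scaffold

The 10-2 program tests a 2° lattice at odd-degree offsets within the
central 10°; keeping every point with squared eccentricity ≤ 82 deg²
reproduces the instrument's 68-point layout (maximum eccentricity 9.06°).
Loci are grouped into five concentric rings by eccentricity band — ring 1
is the 4 central points (±1°, ±1°), ring 2 the parafoveal points, ring 5
the extremities; points whose eccentricity ties two bands are assigned to
the outermost qualifying ring. The digital scaffold places a circular
spot of 288 µm diameter (1 retinal degree at the conversion 288 µm/°) at
each locus, registered to the fovea on the OCT en-face lattice.
Visual-field coordinates are mirrored into a canonical right-eye retinal
frame (left-eye x negated, VF y inverted); a spot's mask is the set of
lattice points whose physical centres fall inside the spot. Thickness
and EZ-loss features average over the native 288 µm spot; the four
intensity features use a spot enlarged to 576 µm for robustness (the
enlargement is applied to all intensity features since they are reported
together; both diameters are configurable). A locus whose spot is not
fully inside the scanned area is kept in the table but flagged invalid.

## OCT metrics

Inputs per eye are an intensity volume, three segmented surfaces (ILM,
OPL, RPE; sub-pixel depths per A-scan) and a binary en-face EZ-loss map.
Layer segmentation and EZ segmentation are out of scope: surfaces and
maps are consumed, not computed. Processing order is smooth → normalize
→ measure:

1. **Bilateral smoothing.** Each B-scan is filtered in 2-D (the lattice
   is strongly anisotropic, so 3-D filtering would mix B-scans 120 µm
   apart). Defaults: spatial σ 3 px, range σ 10% of the volume's 99th
   percentile intensity, 9×9 window. The filter is implemented
   in-package (shift-and-accumulate with a numba fast path whose range
   weights use an 8192-bin lookup table over 6σ; an exact numpy fallback
   is equivalent to ~1e-3 relative) because exact left–right mirror
   equivariance is part of the module contract and is verified by test.
2. **Intensity normalization.** One scalar rescales the whole volume so
   the mean intensity of the inner retina (the ILM→OPL slab, the only
   segmented slab above the outer retina) equals a fixed target (default
   100). This removes per-acquisition gain differences and is idempotent
   and invariant to any prior global gain.
3. **Per-A-scan metrics.** TRT = (RPE − ILM)·axial pitch and
   ORT = (RPE − OPL)·axial pitch use the sub-pixel surfaces directly.
   Mean and minimum intensity are computed over the closed voxel window
   between surfaces rounded half-up to the nearest voxel, for the total
   retina (TR: ILM→RPE) and outer retina (OR: OPL→RPE). Windows are
   accumulated in sequential order so the vectorised implementation is
   bit-identical to a naive per-voxel loop.

EZ fraction at a locus is the fraction of the 288 µm mask's lattice
points marked as EZ loss, ranging 0 (no loss) to 1 (complete loss).

## Grading

Severity groups follow the foveal-B-scan EZ-loss extent: group 1 ≤ 100
µm; group 2 (100, 1000] µm; group 3 > 1000 µm with a preserved central
island > 500 µm; group 4 foveal involvement. Extent 0 maps to
"unaffected" so generated labels round-trip through the classifier; an
extent > 1000 µm with island ≤ 500 µm and no foveal involvement
contradicts the scheme and raises instead of guessing. Visual-field
abnormality requires ≥ 3 contiguous pattern-deviation-flagged loci
(4-connectivity on the 2° lattice by default; 8 available) or a full
ring scotoma (every locus of some ring flagged). mfERG evidence is an
R1/R2 ring ratio above, or an absolute R1 amplitude below, configurable
normative limits. An eye is toxic when the VF rule holds and an
objective modality (mfERG or OCT) corroborates it; the mfERG-positive
but VF-negative fellow eye of a toxic patient is labelled mild toxicity.
Group-4 eyes are excluded from all point-to-point analyses (unreliable
fixation invalidates the locus registration).

## Statistics

Locus-wise *modified z-scores* standardise each metric against the
unaffected reference: z = (x − μ_unaffected)/σ_unaffected per (locus,
metric), with sample SD (n−1). EZ fraction is not z-scored — unaffected
eyes carry no EZ loss, so its reference SD is zero. Severity-group mean
z-maps average z per locus over the eyes of each group (rendered in VF
view as right-eye data). Ring-grouped univariate fits are ordinary
least squares of sensitivity on one metric over all valid (eye, locus)
points of a ring, reporting slope, intercept, R², mean absolute residual
and the SD of absolute residuals; R² of a zero-variance response is 0 by
convention (with a warning), and a zero-variance predictor is an error.
All-point fits pool every locus after z-scoring both variables.

The multivariate model is a random forest (500 trees, squared-error
criterion, bootstrap capped at 10,474 samples or the training-fold size,
whichever is smaller; all other hyperparameters are library defaults,
recorded in the run manifest) over nine features: EZ fraction, TRT, ORT,
TR/OR mean intensity, TR/OR minimum intensity, and the locus (x, y) in
degrees relative to the fovea. Evaluation is leave-one-patient-out:
both eyes of the held-out patient are removed from that fold's training
set. Reported errors pool all held-out predictions: MAE and the SD of
absolute errors, RMSE, R², mean signed error, the 95% interval of a
single-locus error (mean ± 1.96·RMSE), and the MAE of per-eye mean
sensitivity. Feature importance is mean decrease in impurity, averaged
unweighted over folds and renormalised to sum 1; a separate model
restricted to unaffected + group-1 eyes probes which features matter
before appreciable EZ loss. A single seed drives deterministic fold-wise
sub-seeds.

## The synthetic cohort

The generator emulates a Spectralis-style macular cube: 30° × 25° field,
121 horizontal B-scans at 60 µm spacing in the clinical geometry. The
default desk-scale geometry keeps the field but halves both in-plane
densities (61 B-scans × 256 depth × 384 width, 120 µm spacing, 22.5 µm
lateral pitch, 3.87 µm axial pitch) for an 8× smaller volume; a further
"reduced" preset (31 × 192 × 288) is used for fast end-to-end runs.
The default cohort is 10 unaffected patients plus 3/2/3/2 patients in
severity groups 1–4 (20 patients, 40 eyes), a scaled-down mirror of a
screening cohort dominated by unaffected eyes. Problem sizes for tests
and the acceptance script were chosen at these scales as the package's
standard study conditions.

Per eye, severity drives an annular EZ lesion centred on the fovea:

* group 1 — a thin ring (≈45 µm wide) whose foveal-B-scan extent is
  lattice-exact and ≤ 100 µm. Its radius (615–680 µm) lies in the
  geometric gap between the ring-1 and ring-2 spot edges, so mild EZ
  loss is *below the scaffold's detection limit* (EZ fraction 0 at every
  locus) — mirroring clinical group 1, "little or no appreciable EZ
  loss", where early functional change is carried by outer-retinal
  thinning;
* group 2 — a parafoveal annulus with foveal extent in (100, 1000] µm;
* group 3 — severe pericentral atrophy (outer radius ≈ 2.5–3 mm,
  reaching rings 3–5) preserving a foveal island > 500 µm;
* group 4 — a foveal-involving disc.

Annulus boundaries get a smooth angular dither (≤ 20 µm; none for the
thin group-1 ring). Surfaces are smooth low-order fields: an RPE at 70%
depth, a baseline ORT of 160 µm with ± ≤ 8 µm anatomical variation, an
inner retina of 170 µm with a Gaussian foveal pit (ILM dips toward the
RPE at the fovea). The lesion thins the outer retina *in and around*
the EZ defect: the binary lesion is blurred with a 250 µm Gaussian halo
and scaled to a severity-dependent peak (20/28/36/45 µm for groups 1–4),
so thinning precedes frank EZ loss spatially, as in early toxicity.

The forward image model renders layered reflectivity bands
(hyperreflective ILM line, EZ band and RPE; hyporeflective nuclear
layers, with the INL the darkest band of the inner retina), suppresses
the EZ band where the loss map is set, then applies multiplicative gamma
speckle (unit mean, shape 16 → CV 25%) and an independent per-B-scan
gain factor (SD 10%) that makes the normalization step non-trivial.

Ground-truth sensitivity at each locus follows

    S = s0 − ecc_slope·ecc − beta_ez·EZfrac − beta_ort·ΔORT + ε

with defaults s0 = 34 dB, ecc_slope = 0.3 dB/°, beta_ez = 20 dB at full
EZ loss, beta_ort = 0.25 dB/µm of thinning, ε ~ N(0, 2 dB) test–retest
noise. EZfrac and ΔORT are averaged over the same 288 µm masks the
extraction pipeline uses, so with noise off the generative rule is
recoverable from extracted features to numerical precision. Sensitivity
is not floored at 0 dB (a floor would break the linear-recovery oracle;
with the default parameters values stay non-negative up to noise).
Pattern-deviation flags are set where the *noise-free* pathological
deficit reaches 5 dB — a stand-in for the instrument's normative P < 2%
flag, which no public normative database reproduces. MD is the mean
deviation from the healthy template s0 − ecc_slope·ecc and PSD the
sample SD of deviations. mfERG ring amplitudes (normative means
120/60/40/30/25 nV/deg², 5% log-normal noise) are attenuated by three
times the EZ-loss area fraction in each ring territory (capped at 90%);
the deliberately steep coefficient makes even modest parafoveal lesions
shift R1/R2 past its synthetic normative limit, as ring-ratio screening
is meant to be sensitive.

What the generator does *not* emulate: realistic speckle statistics,
vasculature and shadowing, motion artifacts, fixation error, age effects
on the normative field, or asymmetric disease by default (an optional
`asymmetric_fraction` makes the left eye one group milder). Passing
tests therefore demonstrate the correctness of the pipeline's geometry,
algebra and protocol — not clinical performance on real scans.

## Numerical choices

* Degree↔µm conversion fixed at 288 µm/° (configurable).
* Surface rounding: half-up to the nearest voxel; depth windows closed
  at both ends.
* The fovea is the lattice's geometric centre in generated data; the
  real-data path takes an explicit fovea coordinate from the sidecar.
* OLS by the closed-form normal equations (cross-checked against
  `scipy.stats.linregress` to 1e-10).
* `max_samples` for the forest is capped per training fold; fold order
  follows sorted patient ids; fold seeds are spawned from the global
  seed with `numpy.random.SeedSequence`.
* Empty locus masks (coarse lattice or zero spot diameter) invalidate
  the locus with a warning rather than dropping the row.
* The run manifest records configuration, package version, per-stage
  counts and timings; because it contains wall-clock timings it is the
  one output excluded from byte-identity comparisons between runs.

## Known limitations

* The group-1 lesion is sub-resolution for the scaffold by design; a
  study of *detectable* mild EZ loss would need a denser test pattern.
* Severity intervals are rasterisation-aware but assume the lateral
  pitch is ≤ 50 µm for group-1 lesions (coarser pitches cannot represent
  a ≤ 100 µm extent; the generator raises).
* The toxicity eligibility pipeline is a faithful but simplified
  composition of the screening rules; it is not a validated clinical
  decision aid.
* Z-scores require ≥ 2 reference eyes per locus and non-degenerate
  reference variance; metrics failing this are flagged, not imputed.
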