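# Methods

## Quantification protocol

Inputs are a 4D dynamic PET volume (NIfTI-1), a co-registered 3D integer
label volume with a FreeSurfer-color-LUT-style name table, and a frame
timing CSV (`start_sec,duration_sec`). The package validates grid-shape and
frame-count consistency and refuses mismatches; it performs no
registration, resampling or motion correction — inputs are assumed already
on a common grid. Activities are assumed decay-corrected, as produced by
standard reconstruction.

Regional TACs are unweighted voxel means per frame over each ROI's label
mask, treated as samples at the frame mid-times. Left/right labels pool
into bilateral ROIs (`Left-X`/`Right-X` and `ctx-lh-X`/`ctx-rh-X` both
normalise, unpaired hemispheric labels pass through with a warning), and
the five standard cortical composites (PREF_FS, GR_FS, TEMP_FS, OCC_FS,
PREC_FS) pool member voxels into a single TAC before fitting. Pooling (not
averaging member BP values) is the default because hemispheric merging in
the protocol operates on ROIs, not on fitted parameters; `composite_mode=
"average"` switches to a volume-weighted mean of member BP_ND values, and
on the phantom the two agree to ~0.001.

### Reference Logan fit

With target TAC C_T and reference TAC C_R, the transformed variables

    Y(t) = ∫₀ᵗ C_T dτ / C_T(t),
    X(t) = ( ∫₀ᵗ C_R dτ + C_R(t)/k2′ ) / C_T(t)

are fit by ordinary least squares over frames with mid-time ≥ t*; the slope
is DVR and BP_ND = DVR − 1. Running integrals use the trapezoid rule over
frame mid-times with an initial triangle anchored at (0, 0) — the
pre-injection state — which makes results bit-reproducible. Rate constants
are per minute internally; schedules are seconds, converted in one place.

Parameters and defaults:

- `k2_ref = 0.16 /min` — the protocol's fixed reference washout. A target
  that is a constant multiple of the reference yields the exact DVR for
  *any* k2′ (the abscissa offset is absorbed by the intercept −1/k2′), and
  on SRTM-generated curves the BP_ND spread over the ten-fold range
  0.05–0.5/min measures < 0.002 — the basis for fixing it.
- `t_star = 1800 s` — fits the last six frames (30–60 min). The protocol
  does not specify the fit window; 1800 s gives ≤ 0.011 absolute recovery
  error for BP_ND up to 1.5 on noiseless SRTM curves and is configurable.
- Unweighted OLS; no frame-duration weighting. A frame's stored value is
  the frame-average activity.

### SRTM forward model

The simplified reference tissue model used by the phantom (and as the
independent oracle in tests) is

    C_T(t) = R1·C_R(t) + (k2 − R1·k2a) ∫₀ᵗ C_R(τ) e^{−k2a(t−τ)} dτ,
    k2a = k2 / (1 + BP_ND).

The convolution is evaluated exactly for piecewise-linear C_R on a uniform
fine grid (one-pole recursion), so its accuracy is limited only by the grid
resolution of C_R itself (default 0.6 s); it matches stiff ODE integration
to < 0.1 %.

### Two-component partial-volume correction

A binary brain-tissue mask (every named gray/white structure; CSF,
ventricles, vessels, choroid plexus and background excluded, list
configurable) is smoothed with an isotropic Gaussian PSF. The CSF dilution
factor of a region is the regional mean of the smoothed mask, clamped to
[0.05, 1] with a warning at the floor; the regional TAC is divided by it
before fitting. Defaults: FWHM 6.0 mm (typical reconstructed resolution of
a 1990s-era 3D brain scanner; the protocol never states the kernel),
reference TAC corrected as well (`correct_reference=True`; whether the
original workflow corrected the cerebellum is unstated, so both behaviours
are exposed). The factor is computed on the smoothed mask averaged over the
ROI, the reading most consistent with a per-region scalar dilution.

Two properties pin the implementation down: if target and reference factors
are equal the correction cancels exactly in the DVR (Logan scale algebra,
verified to 1e−15), and the factor for a slab below a planar brain/CSF
boundary matches the erf closed form of a Gaussian-blurred half-space
within 1 %.

### Summary metrics and statistics

- MCBP: unweighted mean BP_ND of PREF_FS, PREC_FS, GR_FS, TEMP_FS; PiB
  status positive iff MCBP > 0.18 (strict, per the printed criterion).
- ΔBP% / ΔVOL%: (100/N)·Σ|x₁−x₂|/|(x₁+x₂)/2| across subjects. The printed
  source of the formula is an image and unreadable; the standard
  test-retest convention (absolute difference over pair mean) is adopted.
  The absolute pair mean keeps the metric a non-negative percent for
  near-zero or negative BP values (CSF-like regions sit near DVR 0.15,
  i.e. BP ≈ −0.85). Subjects with a zero pair mean are excluded with a
  warning.
- ICC: ANOVA variance components. One-way (subject, residual) for plain
  replicates, with the standard adjusted replicate count when unbalanced;
  two-way (subject, rater, residual) for a balanced subject × rater
  layout. Negative component estimates truncate to zero; ICC =
  σ²_subject/(σ²_subject+σ²_rater+σ²_residual). The between-subject
  component sits in the numerator: the prose description of the estimand
  says "within-subject variance", but an agreement ICC near 1 for reliable
  measures requires the between-subject component, so that is what is
  implemented (it matches an independent implementation, pingouin's
  ICC(1,1), to 1e−9). Fixed covariates (age, ApoE4, CDR) are removed by
  least-squares residualisation before component estimation; a full REML
  mixed model was considered and left out because the balanced and
  moderately unbalanced designs this package targets are served exactly by
  the ANOVA closed forms. Confidence intervals use the exact F interval
  for the balanced one-way layout (approximate when a rater component is
  present).
- Threshold search: candidates are midpoints of adjacent sorted values
  plus the two extremes (everyone-negative: the maximum value under strict
  >; everyone-positive: just below the minimum). NOD is the count of
  subjects whose `value > threshold` classification disagrees with the
  reference; ties break toward the smaller threshold. Exhaustive
  enumeration over all achievable classifications confirms optimality on
  1000 random instances.

## The digital phantom

The phantom emulates a 60-minute dynamic PiB acquisition (default frame
schedule 25×5 s, 9×20 s, 10×1 min, 9×5 min; 64×64×48 grid at 2×2×2.5 mm —
small enough for seconds-scale tests while keeping the reconstruction's
aspect ratio). Anatomy: an ellipsoidal cerebrum with a thin (~2 voxel)
cortical ribbon — real cortex is thinner than the PET PSF, which matters
for boundary-sensitivity behaviour — split into nine named FreeSurfer
parcels per hemisphere by z-band and azimuth; white matter; lateral
ventricles, caudate and putamen; a sulcal CSF rim; a cerebellar ellipsoid
(the reference region, BP_ND exactly 0); and a brainstem column bounded by
CSF/background.

Kinetics: the cerebellar curve is a one-tissue model (k2 = 0.16/min,
matching the fixed Logan washout) driven by a gamma-variate arterial
input; CSF spaces carry 0.15× the reference curve; every other region
follows SRTM. The default parcel BP_ND values form an amyloid-positive
pattern (precuneus 0.80 down to cuneus 0.20, white matter 0.35 of
non-displaceable retention), with R1 near 1 for gray matter and 0.8 for
white matter; `binding_scale` scales the whole pattern (0 gives a null
phantom, ~0.3 an amyloid-negative subject).

Because amyloid deposition varies smoothly in space, the per-parcel BP
values are Gaussian-smoothed (12 mm FWHM) over the cerebral tissue mask
before TAC synthesis, then quantized in steps of 0.01; kinetics are
therefore continuous across parcel borders even where parcel means differ,
while R1/k2 stay at parcel values. Ground-truth regional BP_ND is the mean
of the quantized field over the region — the value the generator actually
put there. Optional isotropic Gaussian blur emulates scanner resolution;
optional Gaussian noise has variance proportional to activity over frame
duration (count statistics). All randomness flows from one integer seed.

### Segmentation perturbation

`perturb_segmentation` emulates run-to-run variability of an automated
MRI segmentation with two mechanisms: symmetric boundary jitter (a
fraction `magnitude` of each region's boundary voxels flips to a uniformly
chosen differing tissue neighbour) and a per-region whole-outline dilation
or erosion (signed Gaussian draw, sd `outline_shift_sd`) that produces the
few-percent coherent volume changes seen between repeated segmentations.
CSF spaces and the cerebellar reference are frozen — the pial surface is
comparatively stable in practice and sulcal CSF in real data consists of
warm partial-volume slivers rather than the phantom's cold rim — so
exchange happens between tissue labels. Interior voxels are never touched,
every region keeps at least one voxel, and total labeled mass is conserved
within 2 %.

The bundled test-retest cohort (`build_testretest_cohort`, N = 10 default,
per-subject binding scale uniform on [0.2, 1.3] so both PiB classes occur)
uses magnitude 0.05 and outline-shift sd 0.1, calibrated so regional
volumes differ by a nominal ~5 % between the two segmentations. On the
unblurred phantom this yields ΔBP% below 1 % for every region of ≥ 500
voxels with BP_ND test-retest ICC ≈ 1 — binding is an order of magnitude
more stable than the volumes that define it, because the exchanged
boundary voxels carry locally identical kinetics.

### What the phantom does and does not emulate

It emulates: the frame schedule, realistic TAC shapes and binding levels,
bilateral FreeSurfer-style labelling with real label IDs, spatially smooth
binding, scanner blur, duration-scaled noise, and segmentation
variability. It does not emulate: cortical folding, attenuation/scatter
physics, motion, reconstruction artefacts, decay, or anatomically
realistic region shapes. Passing the closure tests therefore demonstrates
the correctness of the estimation chain under the stated kinetic model,
not performance on scanner data; in particular the test-retest contrast
quantifies region-definition uncertainty only, not full scan-rescan
variability.

## Numerical choices and degenerate inputs

- Integrals: trapezoid over mid-times with origin anchor; Logan needs ≥ 3
  frames past t* and positive target activity in the window, else a
  ValueError.
- Dice is undefined (error) when both masks are empty; empty ROIs error in
  TAC extraction and are collected per run.
- Dilution factors clamp to [0.05, 1] with a warning; `correct_tac`
  rejects factors outside (0, 1].
- `threshold_search` tie-break: smallest threshold. `delta_pct` excludes
  zero-mean pairs with a warning, errors if none remain.
- ICC errors on subjects with a single observation and on collinear
  covariates; a rater component requires a balanced subject × rater
  layout (drop the rater column for the one-way decomposition otherwise).
- Repeated runs on identical inputs produce byte-identical CSV outputs.

## Known limitations

- The Logan fit window and integration rule are package defaults, not
  protocol-specified values; changing t* shifts BP_ND slightly (Logan's
  noiseless bias decreases with later t*).
- Two-component PVC only; gray/white three-component correction is out of
  scope (more sensitive to registration error and not part of the core
  protocol).
- The ANOVA ICC's F-based interval is exact only for the balanced one-way
  layout.
- The phantom's geometry is convex and coarse; Dice overlap against manual
  ROIs and cohort-level regional tables require real scans and are out of
  scope.
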