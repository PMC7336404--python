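# Methods

This note documents the models, conventions and numerical choices behind
`glioradiomics`: a pipeline that stratifies gliomas by IDH mutation status
and WHO grade from rCBV (relative cerebral blood volume) perfusion maps via
masked radiomic features and a random-forest classifier, exercised end to
end on synthetic cohorts.

## Pipeline overview

1. **Simulate** (`synthdata`) — generate a multi-centre cohort of rCBV-like
   volumes, tumour masks, basal-ganglia reference masks, labels and
   acquisition covariates.
2. **Normalise** (`normalize`) — resample to an isotropic grid, restrict
   the reference region to the tumour-free hemisphere minus any tumour
   voxels, and z-score the map against that clean reference.
3. **Extract** (`features`) — 29 features per tumour: 4 shape, 13
   histogram, 12 rotation-invariant Haralick texture.
4. **Compare** (`stats`) — residualize features on acquisition bins, age
   and sex; two-sample Wilcoxon (Mann–Whitney) tests and Cliff's delta per
   feature for IDH status and each grade pair.
5. **Classify** (`classify`) — random forests under stratified 2-fold
   cross-validation with many repeats; consensus confusion matrices,
   accuracy/sensitivity/specificity, within-one-grade fraction, and
   error-versus-acquisition-parameter t-tests.
6. **Introspect** (`introspect`) — contrast corrected features between each
   misclassification category and its correctly classified counterpart.

## Intensity normalisation

rCBV maps are dimensionless and scanner-dependent, so tumour voxels are
converted to z-scores against the intensity distribution of the
contralateral basal ganglia (deep grey matter is less affected by
white-matter degeneration than centrum semiovale white matter):

    z(v) = (rcbv(v) − mean_ref) / sd_ref

with the **sample** standard deviation (n−1 denominator) of the clean
reference voxels.  The clean reference is the reference mask intersected
with the tumour-free hemisphere (mid-plane split of axis 0) minus any
tumour voxels; an empty clean reference or one with zero spread is a hard
error.  The z-map is invariant under any positive affine rescaling of the
raw map, which is the point of the construction.

Resampling to the isotropic grid (default 1 mm) happens **before**
z-scoring.  The output grid is anchored at the input origin with extent
`ceil(input_extent / target)` per axis and cell-centred trilinear
interpolation (nearest-neighbour plus a >0.5 re-binarization guard for
masks).  Registration is out of scope: synthetic subjects are generated
pre-aligned, and the pipeline asserts grid identity instead.

## Feature definitions

**Shape (4).** On the isotropic mask with spacing `s`:
`volume = N_voxels s³`; `surface = N_exposed_faces s²` with 6-connectivity
(grid boundary counts as outside); `sav = surface/volume`;
`non_compactness = surface³ / (36π volume²)`, the sphere-normalized
isoperimetric ratio.  Face counting is exact on boxes and deterministic.
One known bias: the staircase boundary of a digitized sphere carries about
1.5× the analytic surface area, so a digitized ball scores ≈ 3.6 rather
than the continuum sphere's 1.0 — non-compactness remains scale-free and
monotone in boundary irregularity, which is what the analysis uses.

**Histogram (13).** Mean, skewness, kurtosis, standard deviation, min, max
and the 1/5/25/50/75/95/99th percentiles of the masked z-values.
Conventions: population moments; kurtosis is **excess** (Fisher) kurtosis —
group medians of corrected kurtosis can legitimately be negative;
skewness/kurtosis of a zero-variance input are defined as 0; percentiles
interpolate linearly between order statistics.

**Texture (12).** Masked z-values are quantized to `Ng = 32` equal-width
bins spanning the per-tumour `[min, max]` (a constant region degenerates to
a single bin).  Symmetric grey-level co-occurrence matrices are accumulated
at distance 1 voxel for the 13 unique 3D directions, counting only pairs
with both endpoints inside the mask; directions with no valid pair are
excluded.  The 12 statistics — ASM, contrast, correlation, sum square
(sum-of-squares variance), sum average, IDM, sum entropy, entropy,
difference variance, sum variance, difference entropy, IMC1 — are computed
per direction and arithmetically averaged over the non-empty directions,
which is what makes them rotation-invariant on the grid (exact under 90°
rotations).

Numerical conventions: logarithms base 2 with `0·log 0 := 0`; correlation
with zero marginal variance is 0; `imc1 = (HXY − HXY1)/max(HX, HY)` with
`0/0 := 0`; *sum variance* is computed about the sum average (the
corrected reading of the classical definition, whose original print
references sum entropy); *sum square* is the co-occurrence variance about
the row-marginal mean.  `Ng`, the GLCM distance, and the non-compactness
definition are configurable but these defaults are used throughout.

## Covariate correction and group comparison

Acquisition parameters are dichotomized to the analysis bins — field
strength 1.5/3 T, TR ≤1499/≥1500 ms, TE 25–44/45–55 ms, FA 90/<90°, slice
thickness <5/≥5 mm, matrix <128/≥128, in-plane resolution ≤1/(1,2)/≥2 mm —
and enter a least-squares model together with manufacturer indicators, age
(continuous) and sex.  Features are replaced by their residuals (mean 0
over the fitting cohort); linearly dependent design columns are dropped
with a warning (with fixed per-centre protocols several bins are exact
functions of the manufacturer, which is expected).  A flag restricts
correction to intensity-based features, leaving shape features centred
only, for the alternative reading of "intensity-based features were
corrected"; the default corrects all 29.

Group differences use the two-sided Mann–Whitney test (exact null for
pooled n ≤ 12 without ties, tie-corrected normal approximation otherwise;
two completely identical samples give p = 1) and Cliff's delta
`(#{a>b} − #{a<b})/(n_a n_b)` with the first group fixed as wildtype (IDH
comparison) or the lower grade (grade pairs), so a positive delta means
that group is stochastically larger.  P-values are reported unadjusted with
significance at p ≤ 0.05, matching the descriptive, per-feature reporting
style of the analysis; no multiplicity correction is applied.

## Classification

Inputs are the 29 features plus one-hot indicators of the dichotomized
acquisition bins.  Task-specific forests: IDH (binary) 200 trees, max depth
10, min samples per leaf 4; grade (3-class) 800 trees, max depth 50, min
samples per leaf 4.  Training uses stratified 2-fold cross-validation
repeated 250 times by default, so each subject is predicted once per
repeat.  Per-repeat seeds are spawned from the master seed
(`SeedSequence(master, spawn_key=(repeat,))`), one for the fold split and
one per fold's forest, making runs bit-reproducible.

The **consensus** label of a subject is the argmax of its mean class-vote
proportions across repeats, with exact ties resolved to the lower ordinal
class.  From the consensus confusion matrix (rows = truth) the pipeline
derives accuracy, sensitivity/specificity for the binary task (positive
class = IDH-mutant; an explicitly documented choice since either convention
is defensible), and for the grade task the fraction of subjects predicted
within one grade (|predicted − true| ≤ 1 with grades encoded 2/3/4; the
strict `< 1` variant is a one-line change).

The numeric error per repeat is `predicted − true` on the encoded labels.
Per-subject mean signed and mean absolute errors are compared between the
bins of every acquisition parameter with Welch's two-sample t-test
(identical zero-variance groups return p = 1); bins with fewer than two
subjects are skipped.

## Misclassification introspection

Corrected features are standardized to cohort z-scores (sample sd), and
each error category (truth a, consensus b ≠ a) is contrasted against the
correctly classified subjects of the **same true class** (mean z
difference plus Mann–Whitney p per feature).  Contrasting against the
correctly classified subjects of the *predicted* class is available via
`reference="predicted_class"`; the same-truth reference is the default
because the question asked is "what made these class-a tumours look like
class b".  Categories with fewer than two subjects on either side are
skipped.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, not
brain anatomy.  Per subject:

* **Tumour mask** — a digitized ellipsoid (radii drawn per class from
  `radius_range_mm`, default 9–14 mm) whose implicit function is perturbed
  by `0.35 × irregularity ×` a smooth unit-variance Gaussian random field
  (2.5 mm correlation length), then hemisphere-clipped, hole-filled and
  reduced to its largest connected component.  At irregularity 0 the mask
  is exactly the digitized ellipsoid; SAV and non-compactness increase
  monotonically with the irregularity amplitude.
* **Intensities** — background `N(0.8, 0.15)`; reference regions (two
  mirrored basal-ganglia-like ellipsoids) `N(1.0, 0.2)`; tumour voxels
  `location + centre_offset + spread × H + heterogeneity × C`, where `H` is
  a spatially correlated unit field (per-class correlation length) passed
  through the monotone exponential skewing transform `(exp(s·g) − 1)/s`
  (identity as s → 0; an odd transform such as sinh would leave the
  symmetric field symmetric, which is why the exponential form is used) and
  `C` is a coarse 8 mm field driving realized GLCM entropy/variance.
* **Covariates** — fixed per centre (each centre is one scanner protocol),
  with centres assigned cyclically after a seeded class interleave so
  centre and class are not confounded; age `N(49, 13)` clipped to 20–81;
  sex 60/40 M/F.

Default class effects encode the qualitative group structure the analysis
targets: wildtype and higher grades have higher rCBV location, spread and
coarse heterogeneity; IDH-mutant tumours have positive skew (wildtype
negative), longer texture correlation, and smoother, more compact shapes;
irregularity rises with grade.  The default class mix reproduces realistic
marginals (≈30/22/48% for grades II/III/IV, ≈45% IDH-mutant, grade IV
dominated by wildtype).  Only effect *directions* are calibrated;
magnitudes are round numbers chosen once at the scale of the reference sd.

Per-subject RNG streams are spawned from the master seed
(`SeedSequence(master, spawn_key=(subject_index,))`), so any prefix of a
cohort is independent of cohort size, and identical configurations give
bit-identical volumes and manifests.  Class counts follow the configured
mix by largest-remainder apportionment with deterministic ties.

What the generator does **not** model: raw DSC time series, contrast
kinetics or leakage, anatomy, registration error, partial-volume effects,
infiltrative margins, necrotic cores.  Passing tests therefore demonstrate
the correctness and calibration of the computational pipeline — not
clinical performance; the headline accuracies on real multi-centre data
cannot be reproduced without the patient data.

## Problem sizes and determinism

Unit tests run on 64³ 1 mm grids with cohorts of 12–18 subjects and reduced
repeat counts; the calibration suite uses a 40-subject null cohort with
1000 relabelling replicates and a 20-seed, 80-subject planted-effect suite;
classification sanity uses a 120-subject strongly separated cohort with 25
of the 250 repeats (consensus metrics stabilise long before 250).
`scripts/acceptance.py` runs 120 subjects with 100 repeats.  All CSV/JSON
artifacts of `run_all` are byte-identical across reruns of the same
configuration; the run log records the package version, configuration hash
and master seed.

## Known limitations

* Surface area by face counting over-estimates curved boundaries (see
  above); comparisons between masks of similar digitization are unaffected,
  but absolute non-compactness values are not comparable to mesh-based
  implementations.
* Equal-width quantization on the per-tumour range ties texture features to
  the tumour's own intensity extremes; a fixed global range is not
  implemented.
* The IMC1 sign convention differs between published implementations; the
  one documented above is used consistently.
* With per-centre fixed protocols, acquisition-bin effects are confounded
  with centre effects by construction — as in any observational multi-centre
  cohort without protocol randomisation.
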