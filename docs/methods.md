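# Methods

This note documents the models, estimators and numerical choices behind
`psmarad`, and what the synthetic phantoms do and do not establish.

## The prediction problem

Each lesion carries a binary endpoint: ISUP grade group 1 (clinically
non-significant prostate cancer) versus grade 2 and above, with
post-surgical histopathology as the label standard of truth. Lesions whose
imaging contour has no histological correspondence are false positives and
are removed before modeling. Predictors are radiomics features computed
from the lesion's PET SUVbw map (g/mL) and/or its MRI-ADC map
(10^-6 mm²/s).

## Synthetic phantom cohorts

Real patient imaging is not redistributable, so the package ships a
generator whose output has the statistical structure the analysis relies
on. Per patient, a PET-like and an ADC-like volume are simulated on one
physical frame (default 100×100×96 mm; PET voxels 2.5×2.5×4 mm, MRI
2.5×2.5×3 mm — the frame divides both slice thicknesses so the resampled
grids coincide). Backgrounds and lesion interiors are Gaussian random
fields: white noise smoothed at a configured correlation length, affinely
rescaled to the target mean and SD. Lesions are ellipsoids (semi-axes
4–9 mm) placed away from the frame edge.

Grade dependence enters in three ways. ISUP 2+ lesions have higher mean
SUV, lower mean ADC, and rougher texture (shorter correlation length,
double amplitude). Each lesion also receives a random mean offset
(SD 1.5 g/mL for SUV, 150 units for ADC); the configured `effect_size` is
the standardized mean difference (Cohen's d) of per-lesion mean intensity
between classes, realized by separating the class means by
`effect_size × between-lesion SD`. The default 1.5 gives a clearly
learnable but not degenerate signal; `effect_size=0` is the null cohort.
Empirically the configured d is recovered within the ±20% band the tests
check.

Dual-modality realism: the PET and MRI contours of one lesion are drawn
with independently jittered centers (SD 0.4 mm per axis per modality) and
radii (SD 8%). At these magnitudes roughly three quarters of dual-visible
lesions satisfy the pairing rules, and all three pairing outcomes
(containment, >80% intersection, no association) occur — mirroring a
cohort in which 31 of 37/49 lesions paired. Visibility is Bernoulli per
modality (defaults 0.85 PET, 0.65 MRI); 10% of contours are
histology-negative and are painted with benign-class appearance. Patient
class composition is fixed at round(p·n) ISUP-1 patients (default 11/28)
rather than sampled, so small cohorts cannot degenerate to one class.

What the phantoms do **not** emulate: scanner physics (PSF, noise
correlations, reconstruction artifacts), anatomical context, non-ellipsoid
lesion shapes, inter-observer contouring behaviour, and any correlation
between lesion size and grade. Passing tests therefore demonstrate that
the pipeline machinery is correct and that the modeling recovers signal of
a known size — not clinical performance on real images.

## Preprocessing

All geometry uses voxel-center coordinates in mm. Volumes and masks are
resampled once, before perturbation and extraction, to 1 mm isotropic:
trilinear interpolation for intensities, nearest neighbour (then
re-binarization) for masks, output shape = physical extent rounded to
whole voxels. PET lesions whose SUVmax inside the mask is below 3 g/mL are
dropped (inclusive threshold: a stated *minimum* positivity value is
attained).

## Contour perturbation

Variants at −1, +1 and +2 mm are computed by thresholding Euclidean
distance transforms: expansion by d includes every voxel center within
distance d of the mask; contraction keeps voxels whose depth (distance to
the nearest background voxel center) exceeds d. This generalizes to
non-integer deltas and guarantees voxel-wise nesting
minus1 ⊆ orig ⊆ plus1 ⊆ plus2. A −2 mm variant is not offered — with
lesions a few mm across it empties too many masks to be useful. A
contraction that empties a mask is flagged degenerate and the lesion is
dropped listwise for that variant downstream.

## Feature battery

75 features, registry-driven and namespaced by family (`stat.`, `ivh.`,
`morph.`, `glcm.`, `glrlm.`, `glszm.`, `gldzm.`). Grey levels are
quantized to a fixed bin number (default 32) between the ROI minimum and
maximum: level = min(⌊N_g(x−min)/(max−min)⌋+1, N_g); a constant ROI maps
to level 1. Fixed bin size is deliberately not offered.

Notable definitions and conventions:

- **First order**: population moments; skewness/kurtosis are reported
  missing (not NaN) on zero-variance ROIs; entropy/uniformity use the
  discretized histogram (log base 2); the 90th discretized-intensity
  percentile is included alongside the raw percentiles.
- **IVH**: intensity fraction γ = (x−min)/(max−min); V_f is the volume
  fraction with γ ≥ f, I_f the (1−f) intensity quantile. Constant ROIs
  report V10 = V90 = 0 and zero differences by convention.
- **Morphology**: volume is voxel-counting; surface area is a
  marching-cubes mesh of the 0.5 level set of the mask after Gaussian
  smoothing with sigma 0.8 voxel. Meshing the raw binary mask leaves a
  staircase surface whose ~8% area overestimate for a sphere does not
  vanish with size; the smoothed mesh converges (sphericity 0.997 for a
  20 mm digital ball) at the cost of ≲1% error for small lesions, where
  sphericity can marginally exceed 1. Masks the smoothing would erase fall
  back to the binary mesh. Flatness and elongation are
  √(λ_least/λ_major) and √(λ_minor/λ_major) of the voxel-coordinate
  covariance; *inverse elongation* is the reciprocal of elongation, and
  *area/volume density* use the axis-aligned bounding box — both are
  vendor-ambiguous names, resolved this way and documented here.
- **GLCM/GLRLM**: symmetric matrices at Chebyshev distance 1 over the 13
  unique 3D directions, features computed per direction and averaged
  ("averaged" aggregation; "merged" — matrices summed first — is available
  behind a flag). Directions with no valid pairs are skipped; features
  undefined in a direction (zero grey-level variance) are averaged over
  the directions where defined, and missing if defined nowhere. Both IBSI
  variants of information correlation are separate keys.
- **GLSZM/GLDZM**: zones are 26-connected equal-level components; zone
  distance is the minimum city-block distance to the ROI border, with
  border voxels (including those on the image edge) at distance 1.

Every texture matrix is tested for exact equality against naive
brute-force enumeration (pair scanning, run walking, flood fill, BFS
border distances) on small fixtures.

## Stability screening

Features are screened with the two-way, absolute-agreement,
single-measurement ICC (contour variants as a fixed crossed factor):

    ICC = (MS_R − MS_E) / (MS_R + (k−1)MS_E + (k/n)(MS_C − MS_E))

Absolute agreement is the right flavour here because contour inflation
produces systematic offsets in contour-dependent features, which this form
penalizes. Zero total variance is defined as ICC 1 (perfect agreement);
fewer than 3 usable lesions yields a missing ICC. Lesions with any missing
variant are dropped listwise per feature; a feature losing more than 20%
of lesions is dropped outright. Retention requires ICC strictly greater
than the threshold (default 0.6). The screening uses all contoured
lesions; the histology join is applied afterwards, at modeling time, since
feature reliability under re-contouring is a property of the imaging, not
of the labels.

## Pairing

Overlap fraction is |A∩B| / min(|A|,|B|): with this denominator,
containment is the continuous limit (fraction → 1) of partial overlap.
Containment tolerates up to 5% of the inner mask outside the outer one
(discretization slack between independently drawn contours) and assigns
the inner contour as the analysis mask on both modalities; otherwise an
overlap fraction strictly above 0.8 yields the voxel intersection;
otherwise no association. Matching is one-to-one and greedy by descending
overlap with a lexicographic lesion-id tie-break, so one large MRI lesion
matched by several PET foci yields exactly one pair, deterministically.

## Modeling

Each configuration runs `n_repeats` = 30 independent iterations. Per
iteration: a stratified lesion-level 2/3–1/3 split (|train| = round(2n/3),
per-class counts rounded and repaired to the total, ≥1 lesion per class
per side); training-set median imputation and standardization, with the
test set transformed by the training statistics only; an L1-penalized
logistic path of 100 log-spaced penalties from λ_max = max|Xᵀ(y−ȳ)|/n
down four decades, the penalty chosen to minimize mean held-out binomial
deviance over stratified internal 3-fold CV (ties to the sparser penalty),
then refit on the full training set. An all-zero model is legitimate: its
constant scores give AUC 0.5 under the tie convention. A patient-grouped
split mode exists behind a flag for leakage-sensitive analyses; the
default is lesion-level, matching how the feature datasets are defined.

AUC is the Mann–Whitney statistic with ties counted 1/2, identical (to
1e-12, tested) to the trapezoidal area under the empirical ROC. The
reported aggregates are the arithmetic mean AUC over iterations, the best
iteration (maximal test AUC; ties broken by train AUC then index — note
this "best" is selected on the test set and is reported for comparability,
not as an unbiased estimate), and per-feature selection frequencies. The
individual L1 fits use liblinear with intercept_scaling = 100, which
leaves the intercept effectively unpenalized.

Model (e) concatenates the stability-filtered PET and MRI feature sets of
the paired lesions with modality prefixes, so its candidate count is the
sum of the two stable sets.

## Determinism and problem sizes

Every stochastic step derives from `numpy.random.SeedSequence`: the
pipeline master seed spawns the simulation seed (stage 0) and the modeling
seed (stage 1); the modeling seed spawns one child per iteration and per
model. Same config and seed reproduce byte-identical output files
(verified by SHA-256 in the run manifest). Default problem sizes — 28
patients, 1–3 lesions each, 100×100×96 mm frames, 30 CV repeats — were
chosen so a complete run finishes in a few minutes on one CPU while
keeping ~40–50 lesions per modality and ~20–25 pairs, the scale the
analysis design targets.

## Known limitations

- The feature battery covers all families the analysis uses but is not a
  census of any vendor's catalogue; absolute feature values are comparable
  only within this implementation.
- The smoothed-mesh surface area trades a small positive bias on tiny
  lesions for asymptotic correctness.
- Synthetic cohorts make the classes cleanly separable at the default
  effect size; AUCs near 1 on phantoms say nothing about clinical data.
- Lesion-level splitting can share a patient between train and test; the
  grouped mode avoids this at the cost of coarser splits.
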