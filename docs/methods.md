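# Methods

This note documents the models, conventions, parameters and design
choices behind `pbshift`, and what the synthetic validation does and
does not establish about real data.

## The quantity being measured

Positional brain shift (PBS) is the quasi-static deformation of brain
tissue under gravity when the head changes orientation, here between
prone and supine. It is measured as a dense displacement field u(x)
between two volumes of the same head, extracted by non-rigid
registration after the two scans have been brought into a common rigid
frame using the skull alone. All coordinates are world RAS millimetres
(+x right, +y anterior, +z superior); displacement components are
stored in world mm regardless of voxel size or anisotropy.

Field convention: u lives on the fixed (supine) grid and satisfies
`moving(x + u(x)) ≈ fixed(x)` — it carries each supine-grid voxel to
the corresponding material point's prone-aligned position. A net
posterior shift therefore appears as a negative mean P–A component.

## Displacement extraction

**Skull-restricted affine.** The skull is rigid between poses, so the
affine stage maximises normalized cross-correlation only inside the
skull mask (dilated by 2 voxels to include its intensity edges). This
prevents the brain's own motion from biasing the rigid frame. An
affine (not rigid) model absorbs residual scanner-geometry differences
between the two acquisitions. Multi-resolution (4×/2×/1×),
regular-step gradient descent with physical-shift parameter scaling.
Divergence is judged on the finest level's metric trace only — metric
values are not comparable across resolution levels.

**Elastic stage.** A multi-level cubic B-spline free-form deformation:
a coarse control mesh (4 cells per axis) refined twice (scale factors
1, 2, 4), giving a finest control spacing of ≈4 voxels; similarity is
normalized cross-correlation over the dilated brain mask; optimizer is
LBFGS (solution accuracy 1e-5, 60 iterations per level; tighter
accuracies only grind the line search without improving the recovered
field). Local (windowed) NCC is available
(`RegistrationParams(similarity="lncc")`) but is not the default: on
phantoms without intensity inhomogeneity it converges markedly worse
with this optimizer, and global NCC within the mask recovers the
ground-truth field to ≈0.05 voxel. There is no explicit bending-energy
term; regularity comes from the B-spline mesh's parsimony and the
coarse-to-fine schedule. Folding (non-positive Jacobian determinant of
x ↦ x + u inside the brain) is detected and reported, not forbidden.

**Accuracy.** On the default 64³ phantom pair the recovered field has a
mean endpoint error of ≈0.15 mm (0.05 voxel), SD ≈0.11 mm, against a
ground-truth field of mean magnitude 0.57 mm — the measurement error is
several times smaller than the signal. This is the same validation
protocol used for the statistics the pipeline reports (mean, SD, 5th
and 95th percentile of the per-voxel endpoint error over the brain).

## Spatial normalization and derived covariates

Subjects are mapped to a template (the mean-geometry phantom) by an
affine estimated from the supine volume. Displacement vectors are
reoriented by the **rotation part only** of the subject→template
linear map, obtained by polar decomposition — a pure rotation preserves
every vector's magnitude exactly, keeping deformation and head
orientation in correspondence; scaling a field's vectors with the
anatomy would destroy that.

Gravity: in the scanner frame gravity is fixed by bore geometry —
toward the subject's posterior in neutral supine, toward the anterior
in neutral prone. Head-pose deviations enter as a rotation (positive
about the L–R axis = downward tilt); gravity is pulled back through the
pose rotation and pushed through the normalization rotation. In the
spherical convention below, neutral supine gravity is azimuth −90°,
elevation 180°; a 10° downward tilt gives elevation 170°.

Geometry: APD (antero-posterior diameter) and MCB (maximum cranial
breadth) are world-space extents of the intracranial (skull-interior)
mask after rotating it into template orientation — rotation only, so
sizes stay subject-native. Extents are edge-to-edge: voxel-centre
range plus one voxel spacing. At desk-scale spacing this measurement
carries quantization error of order one voxel; synthetic cohorts
therefore also store the exactly drawn diameters, and the statistics
module is validated against those (an errors-in-variables attenuation
of regression slopes is a property of the measurement, not of the
estimator).

## Strain analysis

F = ∂u/∂x + I by spacing-aware finite differences (central where both
along-axis neighbours are in the mask, one-sided where one is; voxels
with no in-mask neighbour along some axis are excluded from all
statistics rather than zero-filled). Derivatives along voxel axes are
mapped through the inverse of the affine's linear part, so anisotropic
and oblique grids need no special cases. E = ½(FᵀF − I) is invariant
to rigid motion; it is split into E_hyd = tr(E)/3 (volume change at
small strains) and E_dev = E − E_hyd·I (shape change, trace-free). The
deviatoric definition subtracts E_hyd·I — the only reading under which
the deviatoric part remains a trace-free tensor. No pre-smoothing of
the field is applied by default. Central differences are exact for
fields up to quadratic in position; the whole chain matches a
brute-force per-voxel implementation to 1e-12.

## Spherical convention and cohort statistics

Azimuth is measured in the axial plane from the positive L–R axis
(subject's right): `atan2(anterior, right)`, so +90° = anterior, −90° =
posterior, and values descending from −90° toward −180° are
progressively leftward. Elevation is measured in the sagittal
projection from the positive P–A axis: `atan2(superior, anterior)`, so
90° = superior and 180° = posterior; the L–R component does not affect
elevation. Angles are computed in (−180°, 180°] with a display wrap to
[0°, 360°). Because the typical shift direction (posterior, slightly
superior) sits near 180° elevation, all rank/OLS statistics on angles
first re-branch them about their circular mean.

Cohort direction summaries use the direction of the mean vector, not
the mean of angles (robust near antipodal samples); angular spread is
the circular standard deviation. "Inter-subject variability" is fixed
throughout as the across-subject standard deviation of the per-subject
summary — voxel-wise (then brain-averaged) for the whole-brain tables,
of ROI means for ROI summaries. Whole-brain tables report, per
component and magnitude, the mean and SD over brain voxels of the
across-subject mean field, plus that variability.

Spearman correlations use exact two-sided p-values for n ≤ 12 without
ties, computed from the exact null distribution of S = Σd² by a
subset dynamic program (arithmetically identical to enumerating all n!
permutations, verified against brute-force enumeration at small n).
With ties, or n > 12, the t-approximation is used. OLS slopes are
rescaled to reporting units (per 10 mm of diameter, per 10° of gravity
elevation). No multiple-testing correction is applied.

## The synthetic cohort generator

The generator defines the study conditions under which everything
above is validated.

**Phantom.** An ellipsoidal intracranial cavity (default semi-axes
68.5 × 88 × 60 mm → MCB 137 mm, APD 176 mm, the population means used
as calibration anchors) inside a 6 mm skull shell whose intensity
(2.4) strictly dominates all tissue. Tissue is smoothed seeded
Gaussian noise (correlation length 4 mm, contrast 0.5) over
per-structure mean intensities, giving local registration features
everywhere. Embedded structures — ventricles, thalamus, caudate,
putamen, pallidum, STN/RN/SN, brainstem, plus a cortical GM shell and
WM — define a disjoint label atlas with hemisphere-resolved ids.
Default grid: 64³ at 3.2 mm, the coarsest isotropic grid that contains
the calibrated head with margin; all resolutions are config changes.

**Ground-truth shift field.** An analytic field:
rigid rotation (0.7°) about the L–R axis through an inferior-central
pivot, posterior translation, a leftward component, and a convex-in-y
term whose derivative is positive anterior / negative posterior
(expansion in front, compression behind). The sum is multiplied by a
boundary-damping envelope — the Euclidean distance to the zero set
(outside-brain, plus one-voxel falx and tentorium bands), normalized,
raised to an exponent (default 1, keeping the field C¹), then
tanh-saturated (knee 8) so displacement plateaus over the deep
interior. Finally the field is rescaled so the brain-mean magnitude is
exactly the target (default 0.57 mm). Consequences, all verified by
tests: zero displacement outside the brain and on the membrane bands;
deep structures shift more than cortex (deep surgical ROI means
0.74–0.85 mm vs ≈0.45 mm cortical); mean components ≈ (−0.10, −0.31,
+0.09) mm — small leftward, dominant posterior, slight superior;
anterior-positive / posterior-negative hydrostatic strain. The exact
construction of the field is this package's own parametric family,
chosen to be analytic so strain ground truth exists in closed form.

**Cohorts.** Per subject, MCB and APD rescale the cavity axes
(137 ± 6 mm, 176 ± 6 mm), supine and prone head tilts are drawn
(8.3 ± 6.2° and 9.9 ± 8.9° downward), and the field's summary
statistics are shifted linearly: −0.018 mm magnitude and −1.086°
elevation per degree of downward supine tilt; −2.066° azimuth, −2.917°
elevation and −0.012 mm magnitude per mm of MCB. Couplings are applied
before per-subject residual noise (0.03 mm magnitude, 1.5° angles) —
and they are applied *exactly*: the subject's field is rotated so its
mean-vector direction equals the cohort-reference direction (the field
realised on the mean-geometry phantom) plus the coupling offsets, and
the magnitude enters through the exact mean-magnitude rescale. Without
referencing to the mean-geometry field, the geometric side-effect of
rescaling the cavity would leak into the built-in slopes. The residual
noise SDs are part of the study conditions, sized so that
coupling-slope recovery at n = 25 is estimator-limited (slope standard
errors 2–6%), not noise-limited. Prone volumes are backward warps of
the supine phantom through the subject's truth field, making the truth
field the exact registration ground truth. All randomness descends
from one integer seed via `numpy.random.SeedSequence` spawning.

**What the generator does not emulate**, and hence what passing tests
do not show about real data: MR physics (noise spectra, bias fields,
gradient-nonlinearity distortion), cortical folding and CSF spaces,
tissue heterogeneity in mechanical response, and non-ellipsoidal skull
shape. Registration accuracy on these phantoms is an upper bound on
real-data accuracy; the statistics and strain machinery, in contrast,
are exact computations whose validation transfers directly.

## Problem sizes and numerical choices

Default runs use 64³ grids at 3.2 mm; the test suite and the
reproduction script use 48³/4.5 mm and 40³/5.4 mm (structure-free) for
cohort statistics, where only the brain mask matters. Parameter
recovery is assessed on single-coupling cohorts (one slope active at a
time): with all couplings active simultaneously, chance correlation
between tilt and MCB draws at n = 25 biases pairwise OLS slopes far
beyond the estimator's own error, which is a property of small-sample
observational regression, not of the pipeline. Tie-breaks and
degenerate inputs: zero vectors have undefined angles and are flagged;
constant covariates yield flagged NaN correlations; empty masks and
ROIs raise; resampling uses linear interpolation for intensities and
nearest-neighbour for labels (no new label values, ever).

## Known limitations

* The normalization stage is affine (one shared phantom topology makes
  elastic normalization unnecessary for synthetic cohorts); real-data
  normalization quality is out of scope.
* The elastic registration does not enforce diffeomorphism; folding is
  reported, not prevented.
* Deep-ROI magnitudes sit at the top of the intended 0.52–0.77 mm
  calibration band (0.74–0.85 mm): a single-ellipsoid cavity without
  sulci or CSF pockets cannot fully flatten the depth profile.
* The phantom and its field are mirror-symmetric about the mid-sagittal
  plane (up to the uniform lateral component), so left/right ROI
  summaries coincide; real cohorts show hemispheric asymmetry that this
  generator does not model.
* Exact Spearman p-values require tie-free data; tied ranks fall back
  to the t-approximation.
* APD/MCB from masks carry ~1-voxel quantization error at desk-scale
  resolution; regressions against them attenuate accordingly.
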