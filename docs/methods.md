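# Methods

`striatseg` implements an MR-free pipeline for segmenting the striatum and
its subregions on vesicular-monoamine-transporter (VMAT2) PET — tracers such
as [18F]-FP-DTBZ whose striatal binding falls with nigrostriatal
dopaminergic degeneration — and for quantifying uptake as SUVR against a
cerebellar reference. This note records the models, parameter choices and
numerical decisions, and what the synthetic evaluation does and does not
establish.

## The segmentation model

**Atlas database.** A cohort of PET scans with co-registered whole-brain
label images (in practice derived from each subject's MR parcellation; here
from the phantom ground truth) is fused into (i) a groupwise PET template,
built by iteratively registering every scan to the running voxelwise
average — one affine pass, then deformable passes — and (ii) one atlas per
subject: its PET warped to template space, skull-stripped, partial-volume
corrected, smoothed, and histogram-specified both globally (over the brain)
and locally (over the striatum). The template's label image is the
voxelwise majority vote of all warped subject labels; ties take the
smallest code. The template's own brain and striatum intensity quantiles
are stored as the histogram-specification reference for atlases and
targets alike.

**Two-step atlas selection.** A target PET is warped to template space,
stripped, smoothed and specified the same way (targets skip partial-volume
correction). Similarity to each atlas is the mean-squared error (MSE)
between histogram-specified images: step 1 ranks all atlases by global MSE
over the brain mask and keeps the best `k1 = 10`; step 2 re-ranks these by
local MSE over the striatum (template striatal labels dilated by 1 voxel to
tolerate registration slack) and keeps the best `k2 = 5`. Histogram
specification matters here: it removes overall intensity-distribution
differences so MSE measures *pattern* similarity — which atlases have the
same spatial distribution of binding, i.e. comparable disease severity —
rather than global brightness.

**Joint label fusion (JLF).** Each selected atlas is deformably registered
to the target and its labels are warped (nearest-neighbour) into native
target space. Per voxel, each atlas contributes the absolute-difference
patch `y_i(p) = |A_i(x + d_i + p) − T(x + p)|^β` at its best-matching
offset `d_i` (patch radius 2 voxels, search radius 2 voxels, smallest
patch SSD; off-grid reads are zero); the dependency matrix
`M_ij = Σ_p y_i(p) y_j(p)` captures *correlated* atlas errors, and voting
weights solve `(M + λ·mean(diag M)·I) w = 1` (λ = 0.1, plus a 1e-9-scale
jitter so exactly singular systems — which arise when λ = 0 — remain
solvable). Negative weights are clipped and the vector renormalized, so the
fused label is a convex weighted plurality vote; label-code ties take the
smallest code. Voxels where all atlases agree take that label directly,
which is exact under any convex weighting. When every atlas patch matches
the target exactly (M = 0) the weights fall back to equal.

**Template-based baseline.** One deformable registration of the target to
the template; the dense field is inverted (fixed-point iteration) and the
template's label image is warped back to native space. This is the
classic single-reference approach the multi-atlas design improves on.

**Subregions.** The striatum is split into hemispheres by a sagittal plane
through the putamen's left-right midpoint. The stated rule "median x of
all putamen voxels" is numerically unstable for a bimodal coordinate
distribution (any count imbalance snaps the median to the inner edge of
the larger lateral cluster), so the plane is placed midway between the
median x of each side (sides split at the centroid); the two definitions
coincide for balanced sets. Within each hemisphere the putamen and caudate
are divided into anterior/median/posterior thirds of equal length along
the 3D line joining the structure's anterior-most and posterior-most voxel
centers (ties at the endpoints resolved by smallest x then z); voxels
project onto this line as t ∈ [0, 1] and the bands are the half-open
intervals t < 1/3, 1/3 ≤ t < 2/3, t ≥ 2/3, so boundary voxels join the
more anterior band. The nucleus accumbens passes through undivided. Note
that equal-length thirds of an ellipsoid-like structure are not
equal-volume: the middle band carries roughly 40–60 % more voxels than the
tapered ends. A degenerate single-slice structure goes entirely to the
median band.

**SUVR.** `SUVR = mean uptake in target region / mean uptake in the
cerebellum`, with the cerebellum taken from the same label volume that
produced the subregions. Bilateral values (the default) pool left and
right voxels before averaging, i.e. a voxel-weighted mean; per-hemisphere
values are available behind a flag.

**Evaluation statistics.** Dice = 2|A∩B|/(|A|+|B|). Method agreement uses
ICC(3,1) — the two-way mixed-effects, single-measure, *consistency*
intraclass correlation, which ignores a constant additive offset between
methods; values are reported as computed, without clipping. Group
comparisons use a pooled-variance two-sample t-test and Cohen's d on the
pooled SD; no multiple-comparison adjustment is applied across the seven
subregions. Published group summaries for the reference cohort are
reproduced with group sizes 20 (healthy) and 28 (parkinsonian) — the full
cohort minus the 20 atlas subjects.

## Preprocessing parameters

| step | default | notes |
| --- | --- | --- |
| smoothing FWHM | (3.7, 3.7, 6.6) mm | per-axis Gaussian; σ = FWHM/√(8 ln 2); mask-normalized so the brain rim is not diluted by background |
| PVC | reblurred Van Cittert, 6.0 mm PSF, α = 1.5, ≤ 10 iterations, stop at relative L2 change < 0.01 | f₀ = g; f_{k+1} = clip(f_k + α·h⊗(g − h⊗f_k)); update restricted to the brain VOI; atlases only, never targets |
| histogram specification | 256 matched quantiles | monotone piecewise-linear quantile map, clamped at the ends; resolution-independent |
| registration | affine: correlation metric, full sampling, regular-step gradient descent, 2 levels; deformable: + multi-resolution fast symmetric-forces demons on histogram-matched images, levels (4×, 2×, 1×) with (40, 20, 6) iterations, field smoothing 1.2 voxels | all settings deterministic (no random sampling; ITK forced single-threaded), so the pipeline is bitwise reproducible |

The smoothing kernel is deliberately anisotropic: scanner resolution along
the axial direction is poorer, and the printed protocol this mirrors uses
3.7 × 3.7 × 6.6 mm. The single 10-iteration deconvolution reading of the
PVC settings is used (the alternative nested-loop reading has no effect
before the stopping criterion triggers).

## The synthetic cohort

Real scans of this kind are not redistributable, so the package ships a
generator whose defaults define the study conditions used by every test:

* **Grid** 64 × 80 × 64 voxels at 2.0 mm — the striatum is well resolved
  (putamen ≈ 1,900 voxels) while a full experiment (template build, 20
  atlases, 20 test subjects, ≈ 150 registrations) runs on one CPU in well
  under half an hour.
* **Anatomy**: mirror-symmetric ellipsoids for brain envelope, cerebellum,
  caudate, putamen and accumbens, rasterized with precedence
  accumbens > putamen > caudate > cerebellum > brain.
* **Uptake** (ratios vs cerebellum ≡ 1; brain background 0.4): healthy
  putamen 3.6, caudate 3.0, accumbens 2.5, uniform; parkinsonian putamen
  2.0 → 1.5 and caudate 2.1 → 1.45 linearly anterior → posterior,
  accumbens 2.1 — the posterior putamen is the most affected region, as in
  dopaminergic degeneration. Two between-subject variability sources make
  the cohort realistic rather than 20 copies of one brain: a per-structure
  log-normal uptake jitter (SD 0.10; published cohort SDs are 10–20 % of
  group means) and, for parkinsonian subjects, a *severity* continuum:
  the subject's profile is the healthy profile moved toward the
  parkinsonian one by s/E[s], s ~ U(0.5, 0.95), so the group mean stays at
  the stated profile while severity spans the clinical range — mild cases
  approach healthy contrast, severe cases approach background. Cerebellar
  uptake is pinned at 1 (it is the reference).
* **Inter-subject deformation**: a band-limited random displacement field —
  20 Gaussian bumps with σ ∈ [5, 12] mm and random directions, globally
  scaled so max |u| equals `deform_amplitude` = 10 mm. The spectrum
  deliberately includes shape detail at and below the PSF scale: real
  anatomical variation is not fully recoverable from 6-mm-blurred images,
  and this is what keeps single-registration label transfer in the
  realistic accuracy regime instead of saturating. Truth labels are warped
  with nearest-neighbour interpolation, then uptake is assigned on the
  deformed labels, so ground truth is exact by construction.
* **Imaging**: Gaussian PSF of 6.0 mm FWHM, then additive Gaussian noise
  with SD 0.08 × cerebellar activity (post-reconstruction PET noise is
  approximately Gaussian and this is simpler to seed than Poisson).

What the phantom does *not* emulate: non-ellipsoidal anatomy, spatially
correlated reconstruction noise, attenuation/scatter residuals,
off-target binding, and — most importantly — anatomy–intensity
decoupling (real MR-derived label boundaries partly sit where PET carries
no gradient information). Passing tests therefore show the pipeline's
mechanics are correct and well-behaved under realistic contrast, blur,
noise and shape variation; they do not certify real-scan accuracy.

## Experiment design and problem sizes

`run_experiment` mirrors the evaluation design: an atlas cohort of 10
healthy + 10 parkinsonian phantoms builds the database (template from all
20, 2 groupwise iterations in the pipeline default); 10 + 10 *held-out*
test subjects (fresh seeds spawned from a separate stream — atlas seeds are
never reused) are segmented by both methods; reports are per-structure
Dice vs truth, per-subregion SUVR ICC vs truth-mask SUVRs, and the
healthy-vs-parkinsonian group table. The target-to-template registration
is computed once per subject and shared by the two methods (they would
otherwise recompute the identical transform). `scripts/acceptance.py` runs
a 12-atlas / 10-test version of the same experiment — smaller but
structurally identical — plus the reference-cohort t statistics.

## Numerical decisions

* Geometry: NIfTI sform if valid, else qform, else error; everything is
  reoriented to RAS on load; voxel indices 0-based, world coordinates mm.
* Label resampling is always nearest-neighbour; codes can never be
  invented by interpolation.
* The hemisphere rule assigns x < x₀ to the right-hand code table and
  x > x₀ to the left, with ties going left. The naming convention is
  applied identically to pipeline and truth labels, so every comparison is
  unaffected by it.
* ICC as printed in the source formula is degenerate (its numerator and
  denominator quote the same variance); ICC(3,1) from the two-way ANOVA
  decomposition implements the stated "two-way mixed, consistency" intent
  and is cross-checked against an independent implementation in the tests.
* Seeds: every stochastic object derives from one master seed through
  `numpy` `SeedSequence` spawning; ITK runs single-threaded, demons and
  affine registration use full deterministic sampling. Two runs of the
  same experiment produce byte-identical TSV outputs.

## Known limitations

* Ellipsoid anatomy makes hemisphere symmetry and structure convexity
  cleaner than reality; thirds boundaries on real caudate curvature would
  be noisier.
* The demons backend assumes histogram-matched intensities; with strongly
  non-monotone intensity relationships (not the case for a single tracer)
  a mutual-information affine stage would have to carry more weight.
* JLF uses the label at the voxel itself while searching intensity patches
  (the documented rule); variants that also shift the label lookup exist
  and can further correct residual registration error.
* The dense-field inverse is rasterized on the template grid; for targets
  whose native geometry differs strongly from the template grid the
  inversion error grows near the field-of-view edge.
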