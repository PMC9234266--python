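# striatseg

MR-free multi-atlas segmentation and SUVR quantification of striatal VMAT2
PET.

## The problem

PET tracers that bind the vesicular monoamine transporter (VMAT2), such as
[18F]-FP-DTBZ, image the integrity of nigrostriatal dopaminergic terminals:
striatal binding falls with Parkinson-type degeneration, most strongly in
the posterior putamen. Quantifying this requires delineating the striatum —
caudate, putamen, nucleus accumbens — and a cerebellar reference region on
each scan. The usual route runs through each subject's MR image, which is
expensive and often unavailable in clinical PET workflows. `striatseg`
segments the striatum and its functional subregions *from the PET image
alone*, using a database of PET atlases, and quantifies uptake as

    SUVR = mean uptake(target region) / mean uptake(cerebellum)

## The method

1. **Atlas database** — a cohort of PET scans with co-registered label
   images is fused into a groupwise PET template (iterative register-and-
   average) plus one atlas per subject: its PET warped to template space,
   skull-stripped, partial-volume corrected (reblurred Van Cittert, 6 mm
   PSF, α = 1.5, ≤ 10 iterations, tol 0.01), smoothed (3.7 × 3.7 × 6.6 mm
   FWHM) and histogram-specified to the template globally (brain) and
   locally (striatum).
2. **Two-step atlas selection** — the target is warped to template space
   and preprocessed the same way; atlases are ranked by mean-squared error
   of the globally specified images over the brain (keep best 10), then
   re-ranked by MSE of the locally specified images over the striatum
   (keep best 5). Histogram specification makes MSE measure binding
   *pattern* similarity — effectively matching disease severity.
3. **Joint label fusion** — each selected atlas is deformably registered
   to the target; its labels are warped to native space; per voxel, patch
   similarities at the best-matching search offset build a dependency
   matrix `M_ij = Σ_p |A_i−T|^β |A_j−T|^β` whose regularized inverse gives
   voting weights `w ∝ (M + λ·mean(diag M)·I)⁻¹ 1` that down-weight atlases
   making correlated errors; the fused label is the convex weighted
   plurality vote.
4. **Subregions** — a sagittal plane through the putamen's left-right
   midpoint splits hemispheres; putamen and caudate are each cut into
   anterior / median / posterior thirds of equal length along their
   front-to-back axis; the accumbens stays whole: 7 subregions × 2
   hemispheres.
5. **Quantification and statistics** — subregion SUVRs against the whole
   cerebellum; Dice overlap, two-way mixed consistency ICC(3,1), pooled
   two-sample t and Cohen's d for healthy-vs-parkinsonian comparisons.

A single-registration template-based baseline (`--method template`) is
included for comparison, and a phantom generator (`striatseg simulate`)
produces full synthetic cohorts — ellipsoid anatomy, group-specific uptake
with a parkinsonian severity continuum, PSF blur, noise, and smooth
inter-subject deformation — so the entire pipeline runs with no external
data. See `docs/methods.md` for models, parameters and limitations.

## Worked example

Run the full synthetic evaluation — build a 20-atlas database from 10
healthy + 10 parkinsonian phantoms, segment 20 held-out phantoms with both
methods, and score everything against the ground truth:

```sh
striatseg run-experiment --seed 0 --out run/
```

which prints (abridged):

```
"mean_dice": {
  "multiatlas:accumbens": 0.765, "multiatlas:caudate": 0.838,
  "multiatlas:putamen": 0.878,  "multiatlas:striatum": 0.873,
  "template:accumbens": 0.784,  "template:caudate": 0.860,
  "template:putamen": 0.887,    "template:striatum": 0.885 },
"icc": {
  "multiatlas:APu": 0.988, "multiatlas:MPu": 0.988, "multiatlas:PPu": 0.967,
  "multiatlas:ACa": 0.955, "multiatlas:MCa": 0.979, "multiatlas:PCa": 0.957,
  "multiatlas:NAc": 0.967, ... },
"elapsed_s": 495.0
```

Reading the numbers: the multi-atlas method recovers the whole striatum at
a mean Dice of 0.87 against ground truth, with the small nucleus accumbens
— as expected — the hardest structure (0.77). Its subregion SUVRs agree
with truth-mask SUVRs at ICC ≥ 0.95 across all seven subregions. The
accompanying `group_stats.tsv` separates the synthetic healthy and
parkinsonian groups in every subregion (all p < 0.002), with the largest t
in the median/posterior putamen — the hallmark pattern of dopaminergic
degeneration. On this phantom cohort the single-template baseline is not
weaker than the multi-atlas method (0.885 vs 0.873): synthetic
inter-subject variability is a smooth deformation that one registration to
a clean average template can track; `docs/methods.md` discusses why real
cohorts behave differently.

Individual stages are available as subcommands (`simulate`,
`build-atlases`, `segment`, `subregions`, `suvr`, `evaluate`) and as
library functions (`striatseg.segment.segment_multiatlas`, ...).

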