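# Methods

This note documents the models, defaults and design choices behind
`smritrack`, in the order data flows through the pipeline.

## The biomarker and its reference

The metabolic lesion is defined as the set of voxels whose Cho/NAA ratio
is at least `factor` (default 2.0) times a scalar reference: the
arithmetic mean of Cho/NAA over contralateral normal-appearing white
matter (NAWM). The comparison is inclusive (≥), matching the biomarker's
name. The reference region can be a manual mask or, as a fallback, the
lesion (FLAIR) mask reflected across the mid-sagittal grid plane,
restricted to brain and to the lesion's complement; the reference
requires at least 50 voxels inside ratio coverage (configurable) and
records its provenance (`MANUAL_MASK` / `MIRRORED`). The mean is the
default statistic; a median option exists but is never the default.

Ratio maps are computed on the intersection of the Cho and NAA coverage
lattices. Voxels whose NAA falls below a floor (default 10⁻⁶ × median
NAA over coverage) are **excluded from coverage**, not clipped: clipping
a near-zero denominator would fabricate arbitrarily extreme ratios.
Thresholded masks drop 26-connected components smaller than
`min_component_cc` (default 0.1 cc) — a deterministic stand-in for the
expert contour editing used in clinical practice; both knobs are
config-exposed.

## Grids, units, coverage

All volumes in a series share one axis-aligned grid
(`world = origin + index · spacing`, mm). Volumes are reported in cc,
distances in mm. Spectroscopic coverage is an explicit boolean lattice
carried beside every metabolite map — not a sentinel value — because
coverage matching needs an unambiguous "no data" notion. Registration
between timepoints is assumed already done upstream; the package only
harmonizes grids (nearest-neighbour for masks, trilinear for values,
with any target voxel whose stencil touches uncovered source data
excluded from output coverage). Overlap metrics are computed on whatever
common grid the series lives on; the working grid is a configuration
choice recorded in outputs.

## Overlap metrics

Dice is `2|A∩B|/(|A|+|B|)`. Two empty masks give 1.0 with a warning (a
responder whose biomarker volume vanished at both timepoints is perfect
agreement, and must not crash a cohort battery); exactly one empty mask
gives 0. Hausdorff is the full (100th percentile) symmetric
boundary-to-boundary maximum, in mm, between centres of surface voxels —
mask voxels with at least one face-adjacent (6-connectivity) outside or
off-grid neighbour. Undefined pairs (an empty mask) are flagged in the
battery, never given an invented value. The implementation uses a k-d
tree for the directed distances and is tested for *exact* agreement with
an all-pairs brute-force oracle. An HD95 variant and an all-voxel
(rather than boundary) variant exist for sensitivity checks only.

The battery fixes the reference at the single pre-RT timepoint and emits
one record per post-RT timepoint per mask family.

## Longitudinal change and the progression rule

Two serial maps are comparable only after coverage matching: voxels
lacking data at either timepoint are excluded from both. Difference maps
are later − earlier (positive = increase; rendered red over blue in the
inspection plots). Consecutive means adjacent in scan order; the overlap
battery uses the baseline-anchored convention instead.

An interval's call is a pure function of two summaries — the medians of
voxelwise ΔCho and Δ(Cho/NAA) over an ROI — and two dead bands:

- both medians above their band → `TRUE_PROGRESSION`;
- ratio median above its band, Cho median below −band →
  `PSEUDOPROGRESSION`;
- anything else → `STABLE_OR_RESPONSE`.

The ROI is the union of the pair's biomarker masks. When that union is
empty (a responder), the pipeline falls back to the FLAIR union and
records the ROI source, so responders get a call instead of an error.
The median (not the mean) makes the rule robust to the mixed-sign rim
that registration error and lesion growth produce. Dead-band defaults —
0.1 in ratio units, 5% of the patient's NAWM Cho for Cho — are
engineering choices that sit well above the noise floor of a median over
hundreds of voxels and well below the planted effect sizes; they are not
inferred study values, and both are config-exposed. Cho is assumed
comparable across scans after upstream institutional normalization; an
optional NAWM-Cho rescaling hook covers acquisitions where it is not.

## Cohort statistics

The FLAIR-vs-biomarker volume relation is an ordinary least-squares
regression (slope, intercept, Pearson r, two-tailed p for non-zero
slope, standard error of the estimate) with a pointwise 95% confidence
band for the mean response, `ŷ ± t₀.₉₇₅,ₙ₋₂ · s · √(1/n + (x−x̄)²/Sₓₓ)`.

The two primary hypotheses (DSC and HD, biomarker vs FLAIR, paired by
patient × pre/post pair) are gated: paired t requires Shapiro–Wilk
p > 0.05 in **both** groups and Levene p > 0.05; otherwise the Wilcoxon
signed-rank test. Effect size is the paired-sample Cohen's d
(mean of differences / SD of differences; qualitative cuts 0.2/0.5/0.8).
The two test p-values form one Holm–Bonferroni family at α = 0.05: the
i-th smallest p is held to α/(m−i+1), rejections stop at the first
failure, and once stopped the effective threshold no longer grows, so
`significant` is exactly `p ≤ threshold` entry-wise.

Wilcoxon details (reports in this field are usually silent on them, so
they are pinned here and by an enumeration oracle in the tests): zero differences are dropped; at least 5 non-zero differences
are required; with no ties among |d| and n ≤ 25 the two-sided p comes
from the exact null distribution of the positive-rank sum (subset-sum
recursion, doubling the smaller tail, capped at 1); otherwise a
tie-corrected normal approximation without continuity correction.
Identical paired groups (every difference zero for both hypotheses) are
reported as p = 1, d = 0 rather than an error — "no evidence of any
difference" is the only defensible cohort-level reading of that
degenerate input.

Under a paired null the measured family-wise rejection rate is ~0.053
over 2000 repetitions (nominal 0.05, Monte-Carlo SE 0.005) — see
`analysis/04_stats_calibration.py`, which recomputes it.

## The phantom

The phantom emulates exactly the features the pipeline consumes and
nothing deeper in the physics: no spectral lineshapes, no k-space, no
suppression artifacts.

- **Geometry.** Brain = analytic ellipsoid, lesion = sphere, rasterized
  by voxel-centre inclusion, so ground truth is exact. Defaults: 64³
  grid at 3 mm; brain semi-axes (84, 90, 78) mm; lesion radius 15 mm at
  (−38, 8, 4) mm, safely inside the left hemisphere. A lesion whose
  bounding sphere leaves the brain is rejected at construction.
- **Contrast.** NAWM background Cho 1.0, NAA 1.5 (arbitrary units).
  Inside the lesion Cho is multiplied and NAA divided by √m so that
  Cho/NAA is exactly m × the NAWM ratio (default m = 3): both directions
  of real tumor contrast (Cho up, NAA down) are present.
- **Coverage.** Brain minus a rind where the depth-from-surface is ≤ 6
  mm (default), emulating the partial head coverage of spectroscopic
  acquisitions.
- **Masks.** NAWM = lesion mirrored across the mid-sagittal plane
  (disjoint from the lesion by construction); FLAIR = lesion dilated by
  an isotropic 4 mm margin — broader than, and correlated with, the
  metabolic lesion, as in real data.
- **Noise.** Additive Gaussian per metabolite per voxel (default SD 0.1
  = 10% of NAWM Cho), floored at 0.01 so concentrations stay positive
  and ratios defined everywhere in coverage.
- **Evolution modes.** Per-timepoint multiplicative schedules
  `step^k` (k = 0 at the pre-RT scan) for lesion radius, Cho and NAA:
  stable (1, 1, 1); response (0.88, 0.85, 1.10 — ratio decays toward
  NAWM, lesion shrinks); true progression (1.12, 1.12, 0.96 — Cho and
  ratio strictly rise, lesion grows); pseudoprogression (1.0, 0.93,
  0.80 — Cho falls, NAA falls faster, ratio rises). Step values are
  chosen so each mode's defining signs clear the dead bands by a wide
  margin at 10% noise; the geometric form extends any mode to any number
  of follow-ups.
- **Timepoints.** Default {−1, 1, 4, 7, 10} months from RT: one
  baseline, then one month post-RT and every three months after.
- **Registration jitter.** Cohorts written by `simulate_cohort` displace
  the lesion rigidly at each follow-up (Gaussian, 2 mm SD per axis), with
  an *independent* displacement for the FLAIR mask — the anatomic and
  spectroscopic volumes are registered separately in practice, so their
  residuals decorrelate. Without this the phantom's pre/post masks are
  identical up to growth and the paired overlap statistics are
  degenerate (all differences exactly zero). `PhantomConfig` itself
  defaults to zero jitter, which the exact-recovery tests rely on.
- **Seeding.** One integer seed; every (patient, timepoint) draws from
  `default_rng([seed, patient_index, timepoint_index])`, jitter from a
  parallel substream, so cohorts are bit-reproducible and insertion of a
  patient never perturbs another.

What passing on the phantom does *not* show: robustness to lineshape and
baseline artifacts, partial-volume mixing at real tissue interfaces,
deformable (not rigid) misregistration, heterogeneous lesion texture, or
inter-scanner intensity drift. The phantom validates the pipeline's
logic, not scanner physics.

## Problem sizes

The validation batteries run on a reduced phantom (36³ grid at 3 mm,
10 mm lesion, 4 mm coverage rind) and two-timepoint series, chosen so a
600-series classification battery completes in seconds on one CPU; the
full-size phantom behaves identically in spot checks, only slower. The
statistical calibration uses 2000 repetitions at 20 pairs; regression
recovery uses 100 seeds at n = 200.

## Known limitations

- The mirrored-NAWM fallback assumes approximate left–right symmetry of
  the head and a strictly lateralized lesion; midline lesions need a
  manual NAWM mask.
- No automatic FLAIR segmentation, registration estimation, DICOM
  ingestion or surgical-cavity detection; those are upstream of this
  package by design.
- Cohort-level overlap statistics treat pre/post pairs within a patient
  as independent observations, as is common in small pilot cohorts;
  with more patients a mixed-effects model would be preferable and is
  deliberately out of scope.
- The progression rule is a two-threshold dead-band rule on medians; it
  is explicit and auditable but has no claim to optimality against
  histopathological ground truth.
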