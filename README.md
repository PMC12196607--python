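# smritrack

Longitudinal analysis of whole-brain spectroscopic MRI (sMRI) in brain
tumors — built around the **Cho/NAA ≥ 2X** metabolic biomarker used to
guide radiotherapy in high-grade glioma, where contrast enhancement is
often absent and T2-FLAIR conflates tumor with edema and treatment
effect.

It is written for imaging scientists who have serial, co-registered
metabolite maps (choline, N-acetyl aspartate) with partial spectroscopic
coverage, structural T2-FLAIR masks, and want to:

- segment the biomarker region — voxels where Cho/NAA is at least twice
  the mean Cho/NAA of contralateral normal-appearing white matter (NAWM):
  `CHO_NAA_2X = { v : (Cho/NAA)(v) ≥ 2 · mean(Cho/NAA | NAWM) }`;
- track raw volume (cc) and percent change per scan for the biomarker
  and FLAIR mask families;
- compute coverage-matched, signed voxel-level difference maps of Cho
  and Cho/NAA between consecutive scans (voxels lacking data at either
  timepoint are excluded from both);
- quantify pre- vs post-radiotherapy spatial agreement with the Dice
  similarity coefficient, `DSC = 2|A∩B| / (|A|+|B|)`, and the full
  symmetric boundary Hausdorff distance in mm,
  `HD = max( max_{p∈∂A} min_{q∈∂B} ‖p−q‖, max_{q∈∂B} min_{p∈∂A} ‖p−q‖ )`;
- compare the two mask families statistically: Shapiro–Wilk and Levene
  gates choose between a paired t-test and a Wilcoxon signed-rank test
  (exact null distribution at small n), with paired Cohen's d and
  Holm–Bonferroni family-wise control at α = 0.05;
- classify each interval as **true progression** (Cho/NAA and Cho both
  rise), **pseudoprogression** (Cho/NAA rises while Cho falls — NAA
  collapsing from treatment effect, not proliferation), or
  stable/response, via dead-banded medians of the voxelwise changes.

Because real patient series are rarely shareable, the package ships a
seeded digital-phantom generator (`smritrack.phantom`) producing
longitudinal cohorts with exact ground truth under four evolution modes
(stable, response, true progression, pseudoprogression), so every stage
is testable end to end without any download.

## Worked example

```sh
python analysis/01_simulate_cohort.py   # 6-patient phantom cohort -> scratch/cohort/
python analysis/02_run_study.py         # full study -> results/study/
```

which prints (seed 11, default configuration):

```
patients analysed: 6, failed: 0
FLAIR vs Cho/NAA>=2X volumes: R^2 = 0.994, slope = 1.232 (n = 30 scans)
median volumes: Cho/NAA>=2X 14.04 cc, FLAIR 22.10 cc
DSC: WILCOXON p = 0.345, Cohen's d = -0.30 (small), Holm threshold 0.025 -> not significant
HD: WILCOXON p = 0.983, Cohen's d = 0.04 (negligible), Holm threshold 0.025 -> not significant
per-patient consensus calls:
PHANTOM000    STABLE_OR_RESPONSE
PHANTOM001    STABLE_OR_RESPONSE
PHANTOM002      TRUE_PROGRESSION
PHANTOM003     PSEUDOPROGRESSION
PHANTOM004      TRUE_PROGRESSION
PHANTOM005    STABLE_OR_RESPONSE
```

Reading: the phantom FLAIR volume is a dilation of the metabolic lesion,
so the two volumes are tightly linearly related (R² = 0.99); DSC is
non-normal so the gate routes it to Wilcoxon; neither family-wise
hypothesis reaches its Holm-adjusted threshold on this small cohort; and
every patient's planted evolution mode is recovered from the Cho /
Cho-NAA-ratio change maps alone. `analysis/03_mode_recovery.py` and
`analysis/04_stats_calibration.py` run the larger recovery and
calibration batteries.

The same stages are available as a CLI
(`smritrack simulate | segment | track | diff | overlap | stats | run-all`);
see `smritrack --help`.

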