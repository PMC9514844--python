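# tractvelocity

Tools for linking white-matter microstructure to individual differences in
behaviour through the MR g-ratio and its conduction-velocity
interpretation.

## The scientific problem

The conduction velocity of a myelinated axon depends on its inner diameter
*d* and on the relative thickness of its myelin sheath, summarised by the
g-ratio *g* = *d*/*D* (*D* = outer fibre diameter). Rushton's classical
model gives

    v  ∝  d · √(−ln g)

so velocity rises with larger axons and (up to an optimum at
*g* = e^(−1/2) ≈ 0.61) with relatively thicker myelin. An aggregate
g-ratio can be estimated per voxel from quantitative MRI: a
magnetisation-transfer-saturation (MTsat) map calibrated to a myelin
volume fraction (MVF = α·MTsat, α = 0.1683 by default) and NODDI maps
combined into an axonal volume fraction
(AWF = (1 − ν_iso)·ν_icvf, AVF = (1 − MVF)·AWF), giving

    g_MR = √( AVF / (AVF + MVF) ).

`tractvelocity` implements, for researchers running tract-level
individual-differences studies:

- **Voxelwise g-ratio mapping** from MTsat/NODDI NIfTI inputs, plus the
  Rushton velocity index and an iso-velocity (d, g) simulation used to
  interpret g-ratio associations microstructurally.
- **Probabilistic tract ROI extraction**: atlas thresholding (≥ 25% by
  default), per-participant refinement to white matter (≥ 90% WM
  probability), and WM-probability-weighted tract means with ROI voxel
  counts.
- **A covariate-adjusted correlation battery**: partial correlations
  (covariates: age, gender, scanner, ROI voxel count; df = n − 2 − k) with
  10,000-rep percentile bootstrap CIs, Bonferroni correction over the
  primary tracts (0.05/3 → p < 0.017), a Meng–Rosenthal–Rubin z test
  comparing the dependent correlations with the primary and control
  outcomes, two-way random-effects absolute-agreement ICCs for scoring
  reliability, and a pre-check that ROI sizes are unrelated to the
  outcome.
- **A synthetic cohort generator** reproducing the study conditions
  (n = 217; age 20–41, 29.0 ± 5.60; 109 F / 108 M; 3 scanners; tract
  metric and outcome marginals; ROI sizes 129.11 ± 25.68) with
  user-specified covariate-adjusted correlations and exact ground truth,
  both as tables and as voxel-level NIfTI map sets.

## Worked example

```python
import numpy as np
import tractvelocity as tv

# voxelwise chain at the observed parahippocampal-cingulum means
cube = lambda v: tv.VoxelMap(np.full((1, 1, 1), v))
mvf = tv.calibrate_mvf(cube(0.959), alpha=0.1683)        # MVF = 0.1614
awf = tv.compute_awf(cube(0.480), cube(0.04))            # AWF = 0.4608
g = tv.compute_gratio(mvf, tv.compute_avf(mvf, awf))
print(round(float(g.values[0, 0, 0]), 3))                # 0.840

# synthetic cohort with a covariate-adjusted g-ratio/recall correlation of 0.18
cfg = tv.SyntheticConfig(seed=1)
cohort, truth = tv.generate_cohort(cfg)
covs = cohort[["age", "gender", "scanner",
               "parahippocampal_cingulum__n_voxels"]].to_numpy(float)
res = tv.partial_correlation_with_ci(
    cohort["parahippocampal_cingulum__g_ratio"],
    cohort["internal_details"], covs, n_boot=2000, seed=1,
)
print(res)   # r(211) = 0.25, p = 0.000287, 95% CI = 0.12, 0.37

comp = tv.compare_dependent_correlations(0.5, 0.3, 0.4, n=103)
print(round(comp.z, 2))                                  # 2.06
```

The first number is the aggregate g-ratio implied by the formula chain at
the printed tract means. The partial correlation is one simulated
cohort's estimate of the built-in effect (ρ = 0.18; single draws scatter
with SD ≈ 1/√212 ≈ 0.07, here 0.25), with df = 217 − 2 − 4 = 211 and a
percentile bootstrap CI. The final line is the dependent-correlation
z test for two overlapping correlations measured on the same sample.

A config-driven end-to-end run (`tractvelocity run --config pipeline.yaml`)
computes g-ratio maps, extracts weighted tract means, joins the
behavioural table and writes the battery report; `simulate`, `map`,
`extract`, `stats` and `isovel` expose the stages individually.

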