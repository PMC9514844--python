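# Methods

This note documents the models, numerical conventions and design choices
behind `tractvelocity`, and what the synthetic-data experiments do and do
not demonstrate.

## Biophysical model

**Aggregate g-ratio.** Per voxel, the myelin volume fraction is calibrated
linearly from magnetisation transfer saturation, MVF = α·MTsat with
α = 0.1683 by default. The axonal water fraction combines the NODDI
intracellular and isotropic fractions, AWF = (1 − ν_iso)·ν_icvf; the
axonal volume fraction is AVF = (1 − MVF)·AWF; and the aggregate g-ratio
follows the standard fibre-volume convention

    g = √(AVF / (AVF + MVF)).

The square-root form is adopted deliberately: it is the convention of the
g-ratio-weighted imaging framework the calibration factor comes from, and
it reduces to d/D for a single idealised fibre. Volume fractions are kept
physical: negative MTsat clips to 0 (count logged), MVF clips into
[0, 1 − 1e−9], negative inputs to the g-ratio produce NaN with a logged
warning count, and any non-finite operand propagates NaN at that voxel.

A caveat on plugging printed tract means into this chain: the scalar
composition at MTsat = 0.959, ν_icvf = 0.480, ν_iso = 0.04 yields
g ≈ 0.840, whereas voxelwise averaging of g over a tract (a nonlinear
functional) can differ — and deposited MTsat values may be expressed in
units other than those the calibration α assumes. The scalar chain is
therefore exposed and tested as a *formula check*, not as a reproduction
of any cohort's tract-mean g-ratio.

**Conduction velocity.** Rushton's relation v = d·√(−ln g) is used with
the proportionality constant fixed at 1, so v is an ordinal index, not
m/s — the analyses only ever interpret signs and orderings. The
iso-velocity simulation evaluates v and the myelin thickness
t = d(1 − g)/(2g) on a (d, g) lattice (default d ∈ [0.1, 3.0] µm,
g ∈ [0.4, 0.95], 200×200 nodes, a plausible range for central white
matter) and extracts iso-velocity contours by marching-squares
(`skimage.measure.find_contours`); an exhaustive cell-crossing oracle in
the tests bounds the contour error by one grid cell, and the stored
tolerance is derived from the largest within-cell value swing.

**Scenario logic.** Under the working assumption that a significant
brain–behaviour association reflects *faster* conduction, the signs of
the g-ratio and myelin-marker (MTsat) associations map to microstructural
scenarios: negative g-ratio association → thicker myelin (with a larger
axon too if MTsat is positively associated); positive g-ratio
association → predominantly larger inner axon diameter; null g-ratio with
positive MTsat → proportional growth; null/null → no change. A negative
myelin association with a null g-ratio association has no interpretation
in this scheme and returns `indeterminate`.

## ROI extraction

Tract ROIs are the atlas voxels with probability ≥ `min_prob` (default
0.25, inclusive, honouring "minimum probability"); atlases on a 0–100
scale are auto-detected (any value > 1) and rescaled. `min_prob = 0` is
interpreted as "strictly positive voxels" so that binary 0/1 tract masks
from non-probabilistic atlases select exactly their labelled voxels — a
literal ≥ 0 would select the whole grid. Each participant's ROI is then
restricted to voxels whose white-matter probability is ≥ `min_wm`
(default 0.90), and those raw probabilities become the extraction
weights: mean = Σwᵢxᵢ/Σwᵢ over finite voxels (non-finite voxels drop out
of numerator and denominator, count logged). Weights are deliberately not
renormalised or transformed. No resampling is performed; all of a
participant's maps must share shape and affine (affine entries compared
at 1e−4 mm), since spatial normalisation happens upstream of this
package.

## Statistics

**Partial correlation.** x and y are each residualized on
[intercept | covariates] by least squares; r is the Pearson correlation
of the residuals, with df = n − 2 − k and a two-sided p from
t = r√(df/(1 − r²)). Scanner enters as a single numeric covariate by
default so that the standard four-covariate design (age, gender, scanner,
ROI voxel count) gives df = 211 at n = 217; dummy coding is available
(`dummy_code_scanner`) with df adjusted. Constant covariates are dropped
with a warning rather than failing the whole battery.

**Bootstrap CIs.** Case resampling of whole participant rows, percentile
intervals by default (BCa available), 10,000 replicates in production and
reproducible from a seed. Degenerate resamples (singular design, zero
residual variance) are redrawn with a logged count. The bootstrap loop is
computed by batched normal-equation residualization for speed; a test
pins it to the scalar estimator. Percentile intervals for correlations
are known to run slightly below nominal coverage at moderate effect
sizes; the Monte-Carlo calibration below quantifies this (~0.92–0.95 at
ρ = 0.18, n = 217).

**Comparing dependent overlapping correlations.** Two correlations
sharing one variable are compared with the Meng–Rosenthal–Rubin extension
of the Fisher z transformation (the method behind the familiar R
implementation): z = (z₁ − z₂)√((n − 3)/(2(1 − r₁₂)h)) with
h = (1 − f·r̄²)/(1 − r̄²), f = min(1, (1 − r₁₂)/(2(1 − r̄²))). The battery
feeds it the two covariate-adjusted correlations and, by default, the
covariate-adjusted correlation between the two outcomes as r₁₂ (the raw
correlation is available), with n = number of participants (an
`n_adjusted_comparison` flag substitutes n − k; the literature does not
prescribe an adjustment).

**Multiplicity and gating.** Bonferroni over the primary tracts only
(0.05/3 → 0.017 threshold); metrics and outcomes within a tract are not
further corrected, and exploratory tracts are reported at uncorrected
0.05 with a tier label. The dependent-correlation comparison runs only
where the primary-outcome association is significant, and is judged at
0.05 — matching the sequential logic of the analysis it implements.

**ICC.** Inter-rater reliability uses the two-way random-effects
absolute-agreement decomposition: ICC(A,1) =
(MS_R − MS_E)/(MS_R + (k−1)MS_E + (k/n)(MS_C − MS_E)) and its
average-measures analogue. Cross-checked against pingouin in the tests.

## Synthetic data

`generate_cohort` draws covariates (age truncated-normal 29.0 ± 5.60 on
[20, 41]; exact 109/108 gender split and near-equal scanner counts,
shuffled — emulating a recruited cohort rather than a random sample),
then builds all tract metrics and outcomes from a joint standard normal
whose correlation matrix carries the configured (metric, outcome)
correlations and the outcome–outcome correlation (default 0.2 between the
primary and control outcome — a mild positive value, configurable, since
no empirical estimate is available), adds optional covariate effects
(default zero) and rescales each column to its target mean/SD. Because
the covariates are independent of the residual block, the population
covariate-adjusted correlation of each configured pair equals its ρ
exactly; unconfigured pairs are null.

Bounded outcomes (internal details [4.60, 44.60]; external details
[0.8, 17.40]) are enforced by jointly redrawing offending rows, i.e. the
realized law is a truncated multivariate normal with targets specified
pre-truncation. At the defaults the internal-details bounds are mild
(±2.7 SD) but the external-details floor sits at −1.4 SD, which raises
its realized mean by ≈ 0.5 and, through the outcome correlation, the
internal-details mean by ≈ 0.2; the attenuation of the configured
metric–outcome correlations from this truncation is < 0.005 and the
fidelity tests account for the documented bias. Laboratory scores are
modelled unbounded-normal (several of their printed ranges sit within
1 SD of the mean, where truncation would distort the marginals far more
than the scores' role — null association columns — warrants). ROI voxel
counts are drawn directly (129.11 ± 25.68, rounded, floor 1).

`generate_voxel_cohort` embeds each participant's latent tract means in
32³ map sets: a tube along one axis with a radially graded atlas
probability profile, white-matter probability built from a
participant-level plateau (0.95 ± 0.009), a radial falloff and per-voxel
segmentation noise (SD 0.02) so the 90% refinement bites stochastically
and ROI sizes vary realistically (≈ 130 ± 22 voxels — here an *emergent*
geometric quantity rather than a drawn column). The NODDI maps are
constructed by inverting the g-ratio chain from the latent (g, MTsat,
ν_iso) triple, so with zero within-tract noise the voxelwise g inside the
tract equals the latent g exactly and the end-to-end pipeline reproduces
the tabular battery; the neurite-density map is therefore whatever the
chain implies rather than an independent marginal (the printed MTsat
mean, calibration α and mean g are not jointly consistent under the
scalar chain, so a voxel model cannot satisfy all four marginals at
once — consistency of the measurement chain was chosen over marginal
fidelity of ν_icvf). Ground truth stores the exact weighted mean of every
map under the default thresholds, computed with independent plain-numpy
bookkeeping at generation time.

**What the generator does not emulate:** diffusion acquisition and
fitting noise, spatially structured artefacts, scanner-specific biases
(scanner is assigned independently of all metrics by default),
non-Gaussian behavioural distributions, or inter-tract spatial
correlation. Passing recovery and null-control simulations therefore
demonstrates the correctness and calibration of the statistical machinery
under the assumed data-generating model, not robustness to real
acquisition artefacts.

## Simulation sizes and numerical choices

Recovery experiments run 200 replicates with 2,000 bootstrap replicates
(Monte-Carlo SE on the mean recovered r ≈ 0.005; on coverage ≈ 0.018),
and null controls 1,000 replicates — sizes chosen to make the Monte-Carlo
error a small fraction of the effects being checked while keeping a full
run under a minute. Production analyses default to 10,000 bootstrap
replicates. Seeds propagate through `numpy.random.default_rng`
throughout; identical seeds give bit-identical cohorts, intervals and
battery tables. Ties at thresholds are resolved inclusively (≥) for both
ROI probabilities, matching "minimum probability" wording; significance
comparisons are strict (<) against thresholds.

## Known limitations

- The velocity index is ordinal; no attempt is made to express it in m/s
  or to model internodal distance and membrane properties.
- The calibration α is a single global scalar; tissue- or
  participant-specific calibration is out of scope.
- The battery is residualization-based throughout; no mixed-effects
  modelling, FDR procedures, or imputation (complete cases only, with an
  abort-by-default policy when participants are missing inputs).
- Atlas and maps must already be on a common grid; no registration or
  resampling is performed.
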