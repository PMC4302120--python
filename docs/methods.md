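# Methods

## The design and the model

The package analyses monozygotic twin pairs discordant for birth weight.
Each pair contributes one observation per probe: the difference in
cell-composition-adjusted M-values between the smaller and the bigger twin
(smaller − bigger, so a positive intercept means higher methylation in the
smaller twin). For probe `j` and pair `i`,

    d_ij = α_j + β1_j·Δbw%_i + β2_j·age_i + β3_j·sex_i
           + u_plate(i) + u_well(i) + u_sentrix(i) + ε_ij

with Δbw% = 100·(bw₊ − bw₋)/bw₊ (heavier twin in the denominator, so the
quantity is invariant to relabeling), sex coded female = 1, and plate,
well and sentrix position as crossed random intercepts. The intercept α
is the qualitative-discordance effect: the expected intra-pair difference
when all covariates are zero. Covariates are entered uncentered, matching
that interpretation; a centering option is available in the design frame
for users who prefer a within-sample reference point.

Because the response is a difference of natural-log odds of methylation,
`exp(coef × Δ)` is the odds ratio for intra-pair differential methylation
over a covariate change Δ (e.g. per decade of age, Δ = 10). A
"fold-change" response — the difference of log beta values — is available
behind `PipelineConfig.response = "beta-log-ratio"`; the M-value
difference is the default because it keeps the odds-ratio reading exact.

### Fitting

Per probe, the three variance components are estimated by restricted
maximum likelihood. Writing V(γ) = I + Σ_k γ_k Z_k Z_kᵀ with γ_k the
variance ratios, the fixed effects and residual variance are profiled out
and only γ is optimized (L-BFGS-B, non-negative bounds). This closed-form
profiling makes the per-probe fit fast enough for genome-wide scans on a
single CPU and converges reliably at n = 150 pairs; statsmodels' general
`MixedLM` is used in the test suite as an independent oracle for the
fixed-effect estimates.

If the optimizer fails or any variance component is estimated at the
boundary (γ ≤ 1e−6), the probe is refit by ordinary least squares with
the same fixed effects and flagged (`fallback`). Note a structural fact
about this design: batch assignments are pair-constant (twins of a pair
are processed on the same array), so purely additive batch effects cancel
exactly in the pair difference, and on synthetic data the fallback is the
typical path. The random effects matter for real data where batch can
interact with the difference (e.g. position-dependent measurement error).

P-values per fixed effect use a t statistic on `n_pairs − 4` residual
degrees of freedom for both the REML and the OLS path. This is a
deliberate simplification relative to Satterthwaite-type approximations;
with ≈ 150 pairs and at most ~40 random-effect levels the difference is
negligible, and the simplification keeps the null calibration exact on
the OLS path (verified by simulation). Probes with fewer than 10
non-missing pairs are skipped with a recorded status, never aborting the
scan. Benjamini–Hochberg q-values are computed per effect across probes,
separately for the full scan and the extreme-subset scan
(Δbw% ≥ 25 by default; the strict > variant is a switch — the inclusive
boundary matches the stratification convention used in the enrichment
analysis).

## Quality control

**Probe level.** One pair carries technical replicates (4 per twin, 8
arrays). With twin means treated as fixed, the replicate mixed model
reduces to the pooled within-twin residual SD with `n − 2` degrees of
freedom (df = 6 in the 8-replicate design); this closed form gives
identical point estimates to an explicit two-group fit and needs no
iterative mixed-model machinery (oracle-tested to 1e−10). Probes with SD
strictly above 0.05 on the beta scale are removed. Independently, cells
with detection p strictly above 0.01 are masked, and probes with strictly
more than 5% masked cells are dropped. Both comparisons are strict
because the rules are stated as exceedances.

**Sample level.** Genome-wide intra-pair Pearson correlation (beta scale,
probes unmasked in both twins) is compared to a pseudo-twin null: each of
10,000 replicates draws two distinct true pairs within the same age group
(sampling with replacement across replicates rather than enumerating all
pairings) and one random member of each. The null is stratified by age
group (young < 45 ≤ old, the midpoint of the cohort's two recruitment
waves) because twin correlation declines with age. Pairs strictly below
their group's empirical 2.5th percentile are flagged and excluded. The
null pass computes correlations over probes unmasked in all samples so it
can be fully vectorized; with the default sporadic missingness (< 0.1% of
cells) the difference from pairwise-complete correlations is immaterial.

**Ordering.** Probe QC runs before sample QC by default
(`PipelineConfig.probe_qc_first`); the study description does not fix
this order, and with both filters being marginal rules the outcome is
insensitive to it.

## Cell-composition adjustment

Composition `w` per sample solves `min ‖b − Rw‖²` s.t. `w ≥ 0` over the
reference's discriminating probes, by Lawson–Hanson NNLS (the common
reference-based projection; weights are not forced to sum to one unless
`sum_to_one` is set, in which case SLSQP with the simplex constraint is
used and one composition column is dropped from the subsequent
regression for identifiability). Estimation is on the beta scale, where
mixtures of cell types are linear in the reference profiles;
residualization is per-probe OLS of M-values on intercept + compositions,
excluding masked cells. Selection of discriminating probes from sorted
cell data is out of scope: the reference supplies its own probe subset.

## The synthetic generator

The generator emulates the study conditions: 150 pairs (desk scale 20,000
probes; vector-level operations are exercised at the full 485,577-probe
width), ages in two waves (30–37 and 57–74, 77/150 pairs old), ≈52% male
pairs, heavier-twin birth weights from a truncated normal (mean 2,760 g,
range 1,100–4,625 g, chosen so the cohort mean is ≈2,500 g), and
Δbw% = 5 + 43·Beta(2, 4), giving support in (5, 48) and a median ≈18%.
Gestational ages are integers in 33–42 with median 39, missing for half
of the pre-1973 births (birth year = reference year 2009 − age; the
recruitment year is a free parameter since it is not fixed by the design).
Pairs sit six to an array; the plate, well and slide-position cycles are
deliberately out of phase so the three batch factors are crossed rather
than aliased (aliased factors make the variance split unidentifiable).

Methylation is generated on the natural-log logit scale so planted
coefficients carry the model's odds-ratio units: per probe, a bimodal
baseline (peaks near beta 0.1 and 0.9, logit SD 0.5), plus a shared pair
effect N(0, τ²) (τ = 0.5), batch offsets N(0, 0.1²) per factor level, and
individual noise N(0, 0.25²). On a designated discriminating subset the
beta value is instead the linear mixture R·w of uniform reference
profiles with Dirichlet compositions (concentration ≈ whole-blood
proportions, granulocyte-dominant), so noiseless deconvolution is exact.
Planted effects are added to the smaller twin's logit value at disjoint
causal probe sets: a constant α (default 0.2), a Δbw% slope (−0.02 per
percent), an age slope, and a sex effect. Causal sets are kept disjoint
from the discriminating subset so model tests do not depend on the
composition-adjustment step. M and U intensities are constructed so that
M/(M + U + 100) reproduces beta exactly.

**Bad pairs** model poor sample quality: their two twins receive
*independent* pair effects with an inflated SD (default 3τ) instead of a
shared draw. The inflation is needed for the construct to be detectable:
with independent draws at the original τ a bad pair's correlation would
sit exactly at the centre of the pseudo-twin null and would be flagged
only at the nominal 2.5% rate, whereas the flagged pairs in this design
are "exceptionally lower" than the null. Covariates are untouched.
**Failing probes** scatter their replicate measurements uniformly on
(0.2, 0.8) so the replicate SD exceeds 0.05; **high-missingness probes**
receive detection p > 0.01 in just over 5% of samples.

Randomness uses named `SeedSequence` spawn keys per component (baseline,
compositions, pair effects, batch, noise, …), so one seed fully
determines the output and no draw depends on twin-role labels — swapping
the bigger/smaller labels relocates the planted contribution without
changing any noise (the label-antisymmetry property, asserted in tests).

### What the generator does not emulate

Probe-type (Infinium I/II) chemistry and within-array normalization,
genomic autocorrelation between neighbouring probes, SNP-affected probes,
mosaicism between co-twins, chorionicity, and realistic detection-p
physics. Passing tests therefore demonstrate the statistical properties
of the pipeline (calibration, power, recovery, QC behaviour) under the
assumed variance structure, not robustness to those artefacts in real
array data.

## Numerical choices

- Logit clipping epsilon 1e−4 (generator betas are interior; user data
  may contain 0/1).
- Deconvolution solved to stationarity ≈1e−9 (NNLS is exact;
  SLSQP uses ftol 1e−12).
- Residualization uses the pseudoinverse, so collinear compositions
  degrade to the identifiable projection (constant compositions reduce to
  per-probe centering).
- REML boundary tolerance 1e−6 on the variance ratios; p-values clipped
  away from 0 at float-tiny.
- BH ties are resolved by the step-up construction itself; q-values are
  monotone and capped at 1; skipped probes carry NaN p and q.
- The pseudo-twin null requires ≥ 4 individuals and ≥ 2 pairs per age
  group; pairs with fewer than 3 shared unmasked probes get a missing
  correlation and fail QC conservatively.

## Problem sizes in the shipped checks

The test suite and acceptance script run the simulations at sizes chosen
to finish in minutes on one CPU while keeping Monte-Carlo error well
inside the asserted margins: null calibration at 150 pairs × 2,000 probes
(2–3 replicates), effect recovery over 100 replicate fits of single
causal probes at 150 pairs, bad-pair detection at 150 pairs × 5,000
probes across 20 seeds (5 in the acceptance script) with the full 10,000
permutation replicates, and deconvolution at 500 reference probes. The
485,577-probe retention check runs on a probe-statistic vector rather
than a full matrix, as matrices at that width are out of desk scope.
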