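# Methods

`microphen` implements the statistical chain used to relate 16S amplicon
OTU abundances to plant performance in drought trials — a controlled
high-throughput phenotyping ("phenotyper") setting and a split-plot field
setting — together with a synthetic-data generator that plants known
effects so every stage can be validated by recovery rather than by
inspection. This note records the models, the defaults and why they were
chosen, the numerical decisions, and what the synthetic validation does
and does not establish.

## OTU-table quality control (`microphen.qc`)

The filter chain is applied in a fixed order:

1. **Sample depth.** Samples with total counts strictly below
   `min_depth = 10,000` are removed.
2. **Proportional rescaling.** Each sample is multiplied by
   `ref_depth / total`, where `ref_depth` defaults to the deepest sample's
   total. Rescaled values stay fractional; rounding would introduce
   arbitrary boundary behavior at the count cutoffs.
3. **OTU bounds on rescaled counts** (`min_count = 100`,
   `max_count = 200,000`). An OTU is removed when it falls below the low
   bound in *every* sample — keeping rare-but-real OTUs that are well
   observed somewhere — or above the high bound in *any* sample, guarding
   against single-sample blowups (chimeras, contamination). The
   alternative per-sample low-bound semantics is available via
   `low_bound_scope="any_sample"`.
4. **Taxon removal.** OTUs flagged `plastid`, `mitochondrial` or `unknown`
   (explicit flag column, or derived from the lineage) are dropped;
   OTUs with no taxonomy row count as unknown.
5. **Total-sum scaling** to relative abundances (rows sum to 1).

`aggregate_rank` sums counts over a taxonomy rank and preserves per-sample
totals exactly; empty labels aggregate as `unclassified_<parent>`.

## Calibration (`microphen.calibration`)

Field responses carry structured nuisance variation. Calibration proceeds
in two steps, soil/spatial first, then genotype:

- **Soil PCA.** The soil chemistry panel (pH, cations, nutrients, …) is
  standardized (it mixes units) and reduced to its first `k = 3` principal
  components. Scores are sign-fixed (largest loading positive) so results
  are reproducible across linear-algebra backends.
- **Spatial + soil regression.** Each response (a phenotype, or one OTU's
  relative abundance) is regressed on an intercept, the soil PCs, and a
  spatial term; the *raw residuals* are the calibrated values. The default
  spatial term is a degree-2 polynomial in scaled (row, col) — five fixed
  effects, enough to absorb smooth gradients at trial scale. An
  `exp_kernel` option fits generalized least squares under an exponential
  spatial correlation (range profiled over a coarse grid by Gaussian
  likelihood, fixed nugget) and subtracts the spatial field's BLUP, i.e.
  returns universal-kriging residuals. The polynomial is the default
  because it is fast, exactly testable (a noiseless planted trend
  calibrates to machine zero), and sufficient for the trends the generator
  plants; the kernel option exists for fields whose structure is patchy
  rather than smooth.
- **Genotype adjustment** removes per-genotype means (equivalent to
  one-hot regression). Singleton genotypes get a zero residual and a
  warning.
- **Outliers.** Cook's distance on the cell-means (full interaction)
  linear model of the design factors, cutoff `4/n` by default. The cutoff
  is configurable because no universal threshold exists; `4/n` is the
  common rule of thumb.
- **Variance partition.** Sequential (type-I) sums of squares per design
  term via cumulative QR projections, normalized by the total SS; the
  residual completes the decomposition to 1. Term order is the caller's,
  as is conventional for sequential ANOVA.

OTU abundances are calibrated on the proportional scale without a log
transform — residuals may be negative — because the downstream
change-point stage consumes calibrated abundance directly.

## Community statistics (`microphen.diversity`)

Shannon diversity uses the natural log. Bray–Curtis dissimilarity is
`sum|u-v| / sum(u+v)` per pair.

PERMANOVA partitions the Gower-centered squared-distance matrix over a
sequence of design terms (interactions expand `A*B → A, B, A:B`).
Orthonormal bases of the cumulative design spaces are precomputed by SVD
(the dummy blocks of nested terms overlap, so plain QR would
over-project); per-term SS is the increment in `tr(H G)`. The pseudo-F for
each term uses the full-model residual mean square. p-values come from
free permutation of sample labels — a strata option permutes within
blocks — with the `(1 + b) / (1 + m)` estimator so no p-value is exactly
zero; `n_perm="exact"` enumerates all label orderings for small n.
"Partial R²" is `SS_term / SS_total`; some field reports label this
quantity "partial correlation", and it is what the per-term effect-size
column of this package's output means. Sums of partial R² plus the
residual fraction equal 1 by construction.

## Indicator OTUs (`microphen.indicator`)

For OTU abundance x and sample groups, specificity
`A = mean(x | target) / Σ_g mean(x | g)`, fidelity
`B = fraction of target samples with x > 0`, and the indicator statistic
is `sqrt(A·B)` (plain IndVal with the square-root transform; the
group-size-corrected variant is deliberately not the default). With
`combinations=True`, group pairs are also scored: a combination's
specificity sums its member groups' means over the same denominator, and
its fidelity pools the member samples. Each OTU's statistic is the max
over candidate groups; the permutation p-value re-maximizes within every
label permutation, which accounts for the selection. Exhaustive
enumeration is available at small n.

The fold-change heat-map matrix is
`log2((x + c) / (median_control + c))` with pseudocount `c` defaulting to
half the smallest nonzero relative abundance in the matrix — the smallest
perturbation that keeps the log finite. Row order comes from complete-
linkage hierarchical clustering on Euclidean distances, rows pre-sorted by
label so equal-distance merges resolve deterministically.

## Differential abundance (`microphen.diffabund`)

Per-OTU counts are modeled as zero-inflated negative binomial: with
probability π a structural zero, otherwise NB2 (variance `μ + μ²/θ`) with
log link, a log library-size offset, and fixed effects for the treatment
term plus block. Replicate/block structure is handled with fixed
covariates rather than random effects: at trial scale this loses little
and keeps estimation to plain maximum likelihood. The zero-inflation
component is intercept-only (one π per OTU) — the quantity of interest is
the treatment coefficient on the mean, not covariate-dependent zeros.
Optimization is multi-start (default start, then a plain-NB warm start
with the inflation logit at −3); the convergence flag is honest, and
non-converged fits contribute p = 1 downstream. Inference is a Wald test
on the treatment coefficient; the reference level defaults to the
well-watered arm so positive coefficients read as drought enrichment.

Phylum-level contrasts use plain NB (aggregated counts are rarely
zero-inflated) with pairwise level-vs-reference contrasts. All p-values
are Benjamini–Hochberg adjusted — across OTUs within a compartment, or
across (phylum, contrast) pairs — with FDR controlled at 0.05. The BH
step-up is implemented in-package (five lines) and cross-checked against
statsmodels' implementation in the tests.

Note that with a library-size offset, coefficients are changes in log
*share* of the community, not absolute load — the standard compositional
caveat of count-based microbiome models.

## Change-point association (`microphen.changepoint`)

The core model: a phenotype is unaffected by an OTU until its calibrated
abundance crosses a threshold, then responds linearly —
`y = α + β·max(0, x − τ) + ε`, continuous at τ, with samples at exactly
x = τ on the flat segment.

- **Fitting.** Candidate thresholds are the unique observed abundances
  between the 10th and 90th percentiles with at least `min_above = 5`
  samples strictly above. For each candidate, the two-parameter least
  squares fit has a closed form, so the scan is a vectorized exact grid
  search; τ̂ minimizes RSS with ties to the smaller threshold. An
  observed-value grid makes noiseless recovery exact and is the
  convention in threshold regression. At the reference noise level
  (τ = 0.3, β = 1, σ = 0.2, n = 100) the estimator is median-unbiased
  with per-seed scatter of roughly the largest grid gap — threshold
  location is intrinsically a low-information parameter.
- **Slope inference.** Case-resampling bootstrap: pairs are resampled,
  the hinge is refit on each resample (grid restricted to the resample's
  own 10–90 band; fully vectorized over resamples), and the two-sided
  percentile p-value of β* is reported with `(1 + b)/(1 + B)` tail
  smoothing. Degenerate resamples (no valid threshold) contribute a zero
  slope, which is conservative; a warning fires if they exceed 10%.
  Empirical size at α = 0.05 is ≤ 0.07 across the simulation designs in
  the tests. An asymptotic t-test at fixed τ̂ is available but flagged
  anti-conservative (it ignores threshold estimation).
- **Hit rule.** An OTU is a hit when the slope is significant (p < α,
  default 0.05) for *both* phenotypes of the assay *and* both slopes share
  a sign; the shared sign is the hit direction. No multiplicity adjustment
  is applied across the OTU scan by default — hits are raw dual-phenotype
  calls, with the dual requirement itself the false-positive control; a BH
  option over per-OTU p-values can be layered on by the caller. The dual
  rule's error control assumes the two phenotypes' noise is not strongly
  correlated: with near-duplicate phenotypes the two tests collapse into
  one and the effective error rate is the single-test α.

## Synthetic experiments (`microphen.synthetic`)

The generator emulates the statistical structure the pipeline assumes,
with every planted parameter recorded in `SyntheticTruth`.

- **Layout.** Split-plot: blocks are horizontal grid bands, watering is
  randomized to contiguous main plots within each block, and genotype (or
  SynCom-arm × replicate) subplots are randomized within main plots.
  Defaults: phenotyper mode 8 blocks × 2 watering × 4 SynCom arms
  (control, A, B, B+V) × 6 replicates = 384 pots (48 per arm × watering,
  the scale of a real phenotyping run); field mode 8 blocks × 2 watering ×
  24 genotypes = 384 plots.
- **Soil.** Each property loads on shared smooth latent fields (degree-2
  polynomial trends by default; an exponential-kernel Gaussian random
  field option) plus independent noise — spatially autocorrelated and
  mutually correlated, which is exactly what soil PCA plus spatial
  regression is meant to remove.
- **Counts.** Baseline abundances are log-normal (meanlog 0, sdlog 1.5),
  the standard heavy-tailed community model. Designated OTUs receive
  multiplicative treatment effects. Sampling is Dirichlet-multinomial at a
  uniform random depth in 20,000–80,000: per-cell gamma weights with shape
  θ = 2 give NB-like overdispersion, and θ = ∞ degenerates to exact
  multinomial sampling. Zero inflation is independent Bernoulli(π = 0.1)
  per cell, matching the ZINB model the differential stage fits.
- **Phenotypes.** Two correlated phenotypes per mode (area & fresh weight;
  height & dry weight) are assembled as intercept + genotype + drought +
  soil-PC + spatial trend + Σ hinge(causal OTU abundance) + shared latent
  vigor + Gaussian noise (σ = 0.5, shared σ = 0.3).
- **Planted causal effects.** 10 causal OTUs (half negative, half
  positive) affect both phenotypes. Their baselines are floored at the
  community's 75th percentile — a threshold association is only defined
  for taxa the survey actually detects. Thresholds resolve to the 50th
  percentile of realized abundance, guaranteeing τ inside the observed
  support. Slopes are specified relative to noise: the phenotype change
  accumulated from τ to the 99th-percentile abundance is
  `effect_sd = 4` noise SDs, comfortably above the ~3σ detectability
  floor. A note on interference: because all causal OTUs load on the same
  two phenotypes, each OTU's regression sees the others as extra residual
  variance, and the attainable test statistic saturates near
  `sqrt(n_drought / (m − 1))` regardless of effect size; at the default
  scale (192 drought samples, m = 10) this is ≈ 4.6 and recall of planted
  effects is 9–10/10, while at half the sample size it drops to ~60–70%
  no matter how large the effects are made.

**What the synthetic validation does not show.** The generator draws OTUs
independently given the design (no ecological interaction networks), has
no sequencing-error or chimera structure, no compartment-specific
phylogenetic signal, and its spatial trends are smooth by construction.
Passing recovery tests therefore demonstrates that the *statistical
machinery* is correct under the model the analysis assumes — not that the
model captures every feature of real amplicon data.

## Pipeline and reproducibility

`run_pipeline` sequences QC → calibration → diversity → indicator →
differential abundance → change-point, writes every stage table as TSV
plus a JSON summary, and is deterministic given the seed (all randomness
flows from `numpy.random.default_rng` seeded per stage). Failures halt
with the stage name and cause. Cross-experiment intersection keys hits on
(genus, direction) by default, since different experiments' OTU universes
do not share identifiers; `otu_id` keying serves within-experiment
comparisons. The differential stage restricts to the most prevalent OTUs
(`diffabund_max_otus = 100`) — per-OTU maximum-likelihood ZINB on
near-absent OTUs is noise.

`scripts/acceptance.py` re-runs the main recovery simulations from
scratch at the defaults above (hinge recovery over 100 seeds; a pooled
3 × 100-OTU global-null scan; a full 500-OTU end-to-end phenotyper run;
the PERMANOVA exact-enumeration oracle at n = 6; 50-replicate ZINB
recovery at n = 500; the closed-form checks) and writes the measured
quantities as JSON. Problem sizes were chosen so the whole script
completes in a few minutes on one core.
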