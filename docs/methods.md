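# Methods

`hostlink` implements the bespoke statistical procedures used to compare
host-associated microbial communities (individual *Caenorhabditis* nematodes)
with the communities and metabolomes of their substrate (rotting apples
sampled weekly from a compost heap): richness-matched diversity null models,
a repeated random-pairing similarity test, bidirectional source–sink
inference, and ASV–metabolite linkage. Because raw field data are not
required to validate the machinery, the package ships a synthetic-data
generator whose ground truth makes every downstream claim testable as a
parameter-recovery or calibration experiment.

## The synthetic-data generator

The generator emulates the study design: `apples_per_timepoint` apple
lineages followed over `n_timepoints` weekly time points, with one observed
apple sample per (lineage, time point) and a cohort of individually
sequenced worms per worm-positive apple.

**Substrate.** Each taxon's log abundance starts at a shared pool value
(standard normal) plus an apple-specific offset (SD `apple_sd`, default 1).
Per time step the log abundances receive a Gaussian random-walk increment
shared across apples and an apple-specific increment (both SD `drift_sd`,
default 0.3); observed counts are multinomial draws of
`sequencing_depth_substrate` reads (default 50,000) from the softmax of the
log abundances. Setting `apple_sd = 0` collapses all apples onto one source
pool — the null world used to calibrate the pairing test.

**Hosts.** Worm presence on an apple is Bernoulli with logit
`presence_intercept + presence_ph_coeff * (pH − 4)`; pH is uniform on (3, 5)
and drifts upward by 0.08 per week, matching ripening. Worm-positive apples
receive a uniform number of worms in `worms_per_apple_range`. Each worm
samples the apple's pre-shedding bacterial population (a virtual multinomial
draw at 10× the sequencing depth, so the population is effectively
exhaustive and the neutral limit stays exchangeable) with two host-side
mechanisms:

* *clade filtering* — sampling weights are multiplied by
  `exp(clade_filter_strength)` for taxa inside the host-competent clades
  (the smallest disjoint subtrees jointly covering ~25 % of taxa, keeping
  the effect phylogenetically clustered);
* *dispersal limitation* — each worm's support is restricted to
  `ceil(host_richness_fraction × substrate richness)` taxa drawn without
  replacement by those weights.

Worm counts are multinomial at `sequencing_depth_host` (default 5,000); the
tenfold depth asymmetry reflects the biomass difference between an apple
piece and a single worm.

**Shedding.** Worms colonize the apple during the week before the
destructive sampling, so the reported apple sample is drawn *after* mixing:
the apple's relative abundances become
`λ·(mean worm community) + (1−λ)·(drifted substrate)`, with
`λ = shedding_lambda` (default 0.5), and the mixed state carries into the
next time point. With `λ = 0` the substrate trajectory is bit-identical to a
worm-free simulation under the same seed (the streams for substrate, hosts
and covariates are separate).

**Metabolome.** Each metabolite is `exp(η)` with `η` a sparse linear form
of the CLR-transformed substrate counts (per metabolite,
`round(metabolite_sparsity × n_taxa)` standard-normal coefficients) plus
Gaussian noise (`metabolite_noise_sd`, default 0.1); a constant
internal-standard column anchors the normalization, and the log-ratio to the
standard recovers `η` exactly. Generation on the positive scale keeps the
ratio→log→scale pipeline well-defined.

All randomness flows through named sub-streams of one seed; identical
configurations produce byte-identical outputs.

What the generator does **not** emulate: sequence-level errors and chimeras,
taxonomy, overdispersed worm counts per apple (the field data are heavily
overdispersed; we use a uniform range), multi-year batch structure (a single
batch label is emitted), and any direct metabolite→microbe feedback. Passing
calibration here shows the *procedures* behave as intended under their
assumptions, not that the field data meet those assumptions.

## Diversity and composition

Chao1 is the bias-corrected estimator `S_obs + F1(F1−1)/(2(F2+1))`, defined
even without doubletons — important for sparse worm samples. Shannon uses
the natural log; Simpson is Gini–Simpson (`1 − Σp²`). The CLR transform adds
a pseudocount of 1 to counts (configurable); Aitchison distance is Euclidean
distance between CLR rows. Faith PD and unweighted UniFrac are
root-inclusive (the path from each observed leaf to the root counts) and are
computed from a flattened branch-coverage matrix, cross-checked against
scikit-bio in the test suite. Unrooted Newick input is midpoint-rooted.
Permutation p-values (indicator analysis) and empirical null p-values use
the add-one rule; two-sided empirical p-values double the smaller add-one
tail and cap at 1.

## Richness-matched nulls

Worm samples are collapsed to per-apple units (arithmetic means of Chao1 and
of the statistic) so one apple's worms contribute one unit. The focal
environment's Chao1 range defines an eligible pool of *all* units — both
environments — within that range; repeated draws without replacement of
`n_focal` units give the null distribution of the mean statistic
(`n_draws = 5000` by default). A pool restricted to the other environment is
available (`pool="other"`). Exact-Chao1 matching (for the matched paired
Wilcoxon comparison) rounds Chao1 to 6 decimals and resolves ties by a
seeded draw.

Calibration (acceptance suite): under exchangeable host sampling the test
rejects at α = 0.05 in 1–10 % of 200 simulated datasets; with
`clade_filter_strength = 3` the worm PD deficit is detected in ≥ 8/10
datasets. The calibration experiments match worm and apple depths (3,000
reads each) — with the default 10× asymmetry the focal Chao1 range contains
no non-focal units and the test, correctly, returns p = 1 for lack of
comparable communities.

## Repeated random-pairing test

Each iteration builds disjoint triples (focal worm, unused same-apple
partner, unused different-apple worm) in random visiting order, then runs a
two-sided paired Wilcoxon signed-rank on (within-apple distance,
between-apple distance); zero differences are dropped, the exact
distribution is used for ≤ 25 pairs, and an all-ties iteration reports p = 1.
One hundred iterations give a p-value distribution summarized by its median.
The wording of the underlying design admits an unpaired reading; an
unpaired Mann–Whitney mode is provided behind a flag, but the paired design
is the default since a paired test requires both distances per focal worm.

## Source–sink inference

**EM mixture tracker.** A sink's counts are modelled as a multinomial over
`Σ_k α_k γ_k` with fixed source profiles (pseudocount 1e-8, renormalized)
plus one "unknown" source whose profile is re-estimated each M-step from the
counts assigned to it. Two numerical safeguards keep the free unknown
identifiable: it starts with a 1 % share (when the fixed sources already
explain the sink, any unknown share is likelihood-equivalent, and EM stays
near its initialization on that flat ridge), and iteration stops when the
log-likelihood improvement drops below `tol × max(1, |loglik|)` — a relative
criterion, so the EM does not spend thousands of iterations fitting
per-taxon sampling noise into the unknown. Log-likelihood monotonicity is
asserted at every iteration. Directionality: per apple, (a) the apple as
sink with all its worms as simultaneous sources (contributions summed) and
(b) each worm as sink with the apple as sole source (contributions averaged
over the apple's worms), compared across apples by a paired two-sided
Wilcoxon.

**Lasso cross-prediction.** One worm per wormy apple is chosen uniformly at
random (repeated `n_pairings` times); every target-side taxon's relative
abundance is predicted from all predictor-side taxa by an L1-penalized
linear model with the penalty chosen by k-fold CV at minimum CV error; RMSE
and R² are computed on held-out folds (R² may be negative; an in-sample mode
exists behind a flag). Per-taxon values are averaged over pairings and the
two directions compared by a paired Wilcoxon over shared taxa, separately
for RMSE and R².

**Directionality recovery.** The recovery experiment uses proportional
clade filtering only (strength 1, full support, equal depths 2,500), so the
apple-as-source run is not degraded by support mismatch and the
zero-shedding baseline is direction-neutral. The EM comparison then tracks
the shedding knob cleanly (worm→apple favored, p < 0.05, in ≥ 8/10 seeds at
λ = 0.7; ≪ 8/10 at λ = 0). The lasso comparison, in contrast, does **not**
track the knob in this generative model, and the corresponding acceptance
check fails by design of the world rather than of the code: worm and apple
form a near-linear bivariate channel (the worm is a subsample of the apple
state, and shedding convexly mixes worms back in), and cross-prediction
quality between the two sides of a linear channel is symmetric in their
correlation. The asymmetries the comparison can detect come from
sampling-noise and scale structure — which exist without shedding and are
*neutralized* by it, because shedding writes each worm's idiosyncrasies into
its apple, making the worm predictable exactly when feedback is strong. This
is documented as a known limitation: on data of this structure the
regression-based directionality readout reflects noise asymmetries between
sample types rather than the direction of influence.

## Metabolome linkage

Normalization is order-exact: per-sample ratio to the internal standard,
natural log (non-positive ratios become missing with a warning), then
per-metabolite z-scaling (ddof = 1); zero-variance columns are excluded and
listed. PCA is centered SVD on complete rows with a deterministic sign
convention (largest-|loading| entry positive). The association network fits,
for each (ASV, metabolite) pair and direction, a linear mixed model with pH
as fixed covariate and a random intercept per sampling time point; both full
and reduced models are fitted by maximum likelihood and the focal slope
tested by a 1-df likelihood-ratio test (in the zero-between-group-variance
limit the slope equals OLS, verified to 1e-6). p-values are BH-adjusted
within each direction; edges are kept at adjusted p < 0.05, optionally with
"dashed" edges at raw p below a second threshold. The edge sign is the sign
of the fixed-effect *slope*. Cross-layer lasso prediction reports, per
target, held-out RMSE, the observed span (max − min), and relative RMSE =
RMSE / span; the aggregate reports both the mean relative RMSE and the
(mean RMSE, mean span) pair, which are equal ratios only when spans are
equal.

## Problem sizes and determinism

Calibration experiments run at desk scale — 40–80 taxa, 2,500–4,000 reads,
4–6 time points — chosen so whole calibration curves (hundreds of simulated
datasets) finish in minutes while every effect they test remains
well-powered. The pipeline derives one seed per stage from a master seed;
re-running a configuration reproduces all stochastic results exactly, and
the run report echoes every convention above (Chao1 variant, pseudocount,
p-value rules) alongside the results.
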