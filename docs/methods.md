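# Methods

## Synthetic cohort model

Expression of gene *g* in sample *s* is generated on a Gaussian z-like
scale as

    x_gs = Σ_f e_g[level_f(s)]  +  a_g · sign_g · P_g(age_s)
           + Σ_r β_r · h(z_r(s)) · 1[g ∈ targets(r)]  +  ε_gs

* **Factor effects** `e_g` (organ, strain, sex, and the age term of
  archetype-free genes): one draw per gene × level, with the level
  vector of each gene normalized to zero mean and an exact
  between-level variance equal to the target fraction. The direction of
  each gene's response is random, the magnitude calibrated, so realized
  cohort variance fractions equal the plan at any gene count rather
  than only in expectation. (With free chi-square magnitudes and only a
  handful of levels, the per-gene variance ratio is Jensen-biased
  several points below its target — incompatible with ±0.05 recovery
  contracts at 500 genes.)
* **Age archetypes** `P_g`: deterministic trajectories over the design
  ages, zero-mean and unit max-abs — monotone `up`/`down`, `inflect6`
  (rise to the second sampled age, sustained decline), and
  `peak_adolescent` (pronounced spike at the second age, primary
  decline by mid-life). The amplitude `a_g` is set so the age term
  contributes exactly the planted age variance fraction;
  `sign_g = −1` for members of the second set of an antiparallel pair.
* **Regulators**: targets receive `β·h(z_r)` where `z_r` is the
  regulator's standardized expression and `h(z) = z + max(z − 0.5, 0)`
  — a linear drive plus an activation term above +0.5 SD. The
  nonlinearity keeps the dependence visible to forest importance while
  weak for purely linear screens, and the asymmetry is structural: the
  regulator is driven only by its own factors/noise, the targets share
  one upstream cause.
* **Noise** `ε`: iid Gaussian. By default its SD is √(residual
  fraction) so fractions are self-consistent; an explicit `noise_sd`
  overrides this for noise-sweep experiments.
* Default variance hierarchy (fractions): organ 0.873, residual 0.0575,
  strain 0.0274, sex 0.0031, age 0.0026 — organ ≫ residual > strain >
  sex > age, the regime the harmonization stage exists for.
* **Age concentration**: in the default planted structure the
  cohort-wide age fraction is carried entirely by the trajectory genes
  (`concentrate_age_in_archetypes`). A cohort-wide age share of a
  fraction of a percent is an average dominated by null genes; the
  informative subset of a real cohort holds a many-fold higher per-gene
  share (and correspondingly detectable hit–hit correlations, ~0.15–0.2
  after correction). With the budget spread uniformly instead, hit-gene
  correlations drop to ~0.04 and the module stage has nothing to find.
  Structures built directly (without archetypes) keep uniform per-gene
  fractions, which is what the variance-recovery tests need.

Replicates within a design cell are exchangeable; no within-cell
correlation, count-dispersion model or read-level simulation is
attempted. An optional `exp` transform produces FPKM-like positive
values; all downstream stages operate on the corrected z-scale.

What passing tests on this generator do **not** show: robustness to
unbalanced designs, missing cells, count noise at low expression, or
correlated replicate structure in real cohorts.

## Harmonization and PVCA

`zscore_within` standardizes each gene per group (population SD;
zero-variance genes map to 0). `combat_eb` is the parametric
empirical-Bayes location/scale batch model: gene-wise pooled
standardization, per-batch location/scale estimates shrunk toward
normal / inverse-gamma priors fit across genes by moments, iterated to
a 1e-6 relative tolerance, then back-transformed. No covariate
preservation term is modeled and age is never corrected. The
implementation agrees with Bioconductor `sva::ComBat` to ~1e-6 on
shared fixtures (asserted in the test suite, where sva serves as the
independent oracle).

`apply_plan` applies steps in order; with nesting on (default), step k
is fit separately inside each stratum of the previously corrected
covariates — consecutively fitted subgroups. A flat mode exists for
comparison; note that with nesting, sequences of z-score steps compose
to a single z-score within the finest stratification, so correction
*order* only matters through ComBat's nonlinear shrinkage or in flat
mode.

PVCA: genes are standardized, principal components retained up to a
cumulative-variance threshold (default 0.6, minimum 2 PCs). Per PC the
centered score covariance `y yᵀ` is regressed by nonnegative least
squares on one Gram matrix `Z_f Z_fᵀ` per factor plus the identity — a
MINQUE(0)-style method-of-moments variance-component estimate with the
nonnegativity clamp built into the solver. Single-level factors get
fraction 0 with a warning. Fractions are eigenvalue-weighted averages,
normalized to sum to one. Main effects only; interactions are not
modeled. For *recovery* experiments (comparing estimated fractions to
planted ones) the retention threshold is raised to 0.99: at 0.6 the
retained PCs span only the dominant factor's subspace, which is the
correct behavior of PVCA but measures "variance among top PCs", not the
full decomposition.

`search_order` enumerates all permutations × method assignments for up
to 4 covariates (≤ 48 plans for 3 covariates × 2 methods), ranks by the
corrected age fraction, ties broken by fewer ComBat steps then
lexicographic plan text.

## Boruta engine

Each run: append an independently permuted shadow copy of every active
feature, fit a random forest (regression for numeric age, classification
for categorical), compute a Z-like importance per column, and award a
hit to every real feature whose importance exceeds the best shadow.
Decisions per feature by two-sided exact binomial test at p = ½ on the
hit count, with alpha divided by the number of still-undecided
attributes (Bonferroni, switchable). Rejected features leave the model;
confirmed features stay (they still shape multivariate importance);
whatever is undecided at `max_runs` is tentative. "Non-rejected" =
confirmed ∪ tentative; the ensemble counts non-rejections over
independent iterations and averages meanImp/normHits.

Importance is the per-tree impurity importance summarized as
mean / SD over trees ("Z-like"). Out-of-bag permutation importance is
available (`importance="permutation"`) but costs
O(trees × features × samples) per run; the impurity Z-score preserves
the property the shadow comparison needs — a stable score for a
genuinely informative feature, an unstable one for a competing or null
feature — at a fraction of the cost, which is what makes the all-vs-all
CrossBoruta stage tractable on a single CPU. `max_features="sqrt"` for
both forest types for the same reason.

A practical floor: with Bonferroni over m attributes, a feature can
only be rejected once `2^-runs < alpha/m`; e.g. alpha 0.01 and m = 100
requires ≥ 14 runs. Configurations below that floor leave everything
tentative by construction — `max_runs` defaults to 100 and desk-scale
experiments here use 15–25.

Prediction evaluation: stratified k-fold forests; in numeric mode the
regression output is snapped to the nearest design age level so
accuracy and Cohen's κ are comparable between modes. κ is computed from
the pooled confusion matrix as (p_o − p_e)/(1 − p_e).

## Co-expression modules

Unsigned adjacency `|cor|^β`; the soft power is the smallest integer
whose connectivity distribution passes the scale-free fit threshold
(0.94), else the best-fitting power, flagged. The fit index is the
signed R² of log₁₀(bin frequency) on log₁₀(bin mean connectivity) over
10 equal-width bins; a flat histogram returns 0. On small networks
(tens of nodes) the fit index is unreliable and tends to its maximum at
extreme powers that erase all connectivity, so the orchestrated
pipeline uses the scanned power only when the threshold was genuinely
met and falls back to β = 5 otherwise (the power regime typical of
unsigned networks at this correlation level); the flag is carried in
the run report. Dissimilarity is 1 − TOM (unsigned topological
overlap); average-linkage hierarchical clustering with a static cut —
when no height is given, the cut is scanned downward across the
merge-height *range* (TOM distances concentrate just below 1, so
absolute-height cuts miss the structure) and the largest height
yielding the most adequately sized modules is kept. Clusters below
`min_module_size` are grey. Module eigengenes are the first PC of the standardized module
expression, unit variance, sign-aligned with the module's mean profile
(making the pipeline deterministic up to this convention). The reported
"mean intra-module correlation" is the signed mean pairwise Pearson r
among members.

Antiparallel split: per-gene profiles are the median expression per age
level (pooling organs/strains/sexes; input is expected on the
harmonized z-scale, so these are medians of z-scores), clustered by
average linkage on correlation distance and cut at 0.22 — i.e. the
threshold acts on trajectory shape, not on raw sample vectors. The two
largest subgroups are summarized; the split is flagged antiparallel
when their mean profiles correlate below −0.5. Flat-profile genes are
parked in a "flat" bin rather than distorting the correlation distance.

## CrossBoruta network

One ensemble per target gene, predictors = all other genes (design
covariates excluded by default; a flag restores them). Per-target seeds
are SHA-256 hashes of (master seed, target id), so results are
identical regardless of execution order or parallelization. Every
feature non-rejected in ≥ 1 iteration becomes a directed edge
target → feature with iteration-averaged meanImp/normHits; the edge
decision is "confirmed" when confirmed in a majority of its non-rejected
iterations, else "tentative" (a declared convention — only the averaged
statistics are canonical). Constant targets are skipped and logged.

Node statistics on the hit-restricted network: AAS as the in/out
meanImp-sum ratio with an explicit "no value" sentinel when the node
was never a target (and −∞ log₂ when a target but never a feature);
hub score as the count of distinct selecting targets (optionally
confirmed-only); closeness per connected component,
`(n_comp − 1)/Σ d`, unweighted undirected by default with a weighted
variant using edge length 1/meanImp. Quantile thresholds use the
linear-interpolation convention. GraphML and TSV exports round-trip
through the companion reader, including the AAS sentinel.

## Problem sizes and numerical choices

Desk-scale defaults used by the tests and the acceptance script: the
full 7 × 2 × 2 × 5 factorial at 3 replicates per cell (420 samples) with
300 transcripts for the end-to-end stages; 500 genes for variance
recovery; 200 × 100 null matrices over 50 repetitions for the
family-wise error control check; 20-seed repetitions for recovery and
hierarchy experiments on 12–25-gene cohorts. Forests use 40–150 trees
in experiments (500 by default in the library). Degenerate inputs are
handled explicitly: constant genes are dropped (modules) or mapped to
zero (z-scoring), singleton groups and single batches are rejected or
pass through with a warning, empty hit sets abort network restriction.

## Known limitations

* The impurity Z-score slightly favors high-cardinality-style features
  compared to permutation importance; both are exposed but only the
  fast path is exercised at scale.
* PVCA here models main effects only; factor interactions (e.g.
  organ × age trajectories) are absorbed by the residual.
* The antiparallel distance threshold (0.22) is applied to
  age-summarized profiles as a convention; other profile definitions
  would shift the effective threshold.
* The static module cut is simpler than adaptive branch-cutting;
  fine-grained nested modules may be merged.
* The generator's exchangeable replicates and Gaussian noise do not
  emulate count overdispersion, so absolute hit counts are not
  comparable to real-cohort runs — only the recovery and ordering
  properties are.
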