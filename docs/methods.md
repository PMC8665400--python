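# Methods

This note documents the statistical procedures implemented in `megclust`,
the assumptions behind them, the synthetic-data generator used to validate
them, and the design choices made where the methodology was genuinely open.

## 1. The spatio-spectral cluster-permutation test

### Inputs and the cell statistic

The test takes a participants × nodes × frequency-steps tensor of post/pre
power ratios, a per-participant behavioural post/pre ratio (CPT-III
commission score by default; values below 1 mean improvement), a
per-participant age covariate, and a spatial adjacency graph over source
nodes. At each (node, step) cell it computes a partial Spearman correlation:
ranks of the power ratio and of the behavioural ratio (average ranks for
ties) are each residualised on `[1, ranks(age)]` by least squares, and the
correlation of the residuals is referred to a two-sided t distribution with
n − 3 degrees of freedom. A constant covariate degrades gracefully to the
plain Spearman correlation (the projector drops the rank column); constant
cells are flagged invalid and excluded (rho = 0, p = 1).

Rank-based partialing assumes the covariate acts monotonically on both
variables; it removes rank-linear age trends, not arbitrary nonlinear
confounding. With n around 29 the per-cell test has meaningful power only
for |rho| above roughly 0.37 — cluster aggregation, not per-cell testing, is
what carries the inference.

### Cluster forming

1. Threshold cells at `alpha_node` (default 0.05) and split by correlation
   sign: every member of a cluster must share the sign.
2. Spectral persistence: per node and sign, keep only cells lying in runs of
   at least `min_consecutive_steps` consecutive significant steps (default
   4, i.e. a 1-Hz interval on the default 1/3-Hz axis). The filter is
   applied to nodes before component finding because the persistence
   requirement attaches to a node's spectral profile; a variant that instead
   requires the assembled cluster's span to reach 4 steps is available
   (`persistence_mode="cluster_span"`).
3. Connected components on the node × frequency lattice: cells (v1, s) and
   (v2, s) connect when (v1, v2) is a spatial edge; (v, s) and (v, s±1)
   always connect. Components are found with sparse graph machinery; a
   brute-force transitive-closure oracle checks it in the tests.
4. Spatial extent: every step of a cluster's frequency span must involve at
   least `ceil(min_extent_fraction × n_nodes)` nodes (default 1%, i.e. 12
   nodes on the default 1200-node grid). By default sub-threshold steps are
   *trimmed* — removed from the component, with components re-formed until
   stable — rather than invalidating the whole cluster. The alternative
   (`extent_mode="discard"`) drops any component with a weak step; it is
   fragile in practice, because a single node whose significant run pokes
   one step past the cluster's band stretches the span and would void an
   otherwise solid cluster.
5. The cluster mass is the sum of member rho values (all one sign, so
   |mass| is the summed |rho|).

### Permutation inference

The behavioural ratio is permuted across participants `n_permutations`
times (default 5000); power and age stay paired, since the hypothesis being
broken is the behaviour–power correspondence (a `shuffle="joint"` switch
also shuffles age with behaviour). The entire map → cluster pipeline is
re-run per permutation and the maximum absolute surrogate mass recorded;
permutations yielding no surviving cluster contribute 0, the conservative
standard for max-statistic nulls. Each observed cluster's p-value is
`(#{null ≥ |mass|} + 1) / (B + 1)`, which cannot be zero; the plain
proportion `#/B` can be recovered from the stored null vector.

Observed clusters are computed once from the unshuffled data, so increasing
B refines p-values without changing which clusters are reported.
Determinism is guaranteed by a single seeded generator. Two implementation
notes: per-permutation correlation maps reduce to one matrix product because
the tensor-side rank residuals are permutation-invariant, and significance
thresholding inside the loop compares |rho| against the critical value
equivalent to `p < alpha_node` at fixed df instead of evaluating millions of
t-distribution tails.

Because of the persistence and extent filters plus the mass of ties at
zero, the procedure is conservative under the null: the realized familywise
error rate sits well below alpha. The acceptance suite checks the one-sided
property (FWER ≤ α within Monte-Carlo error), which is what max-statistic
control guarantees.

### Post hoc summaries

For a significant cluster, the per-participant mean power ratio over its
members serves as the cluster's marker; its age-partialed Spearman
correlation with the behavioural ratio is reported for the whole sample and
separately per arm, together with the extent-per-step profile and the
peak-extent step. ROI occupancy tabulates, per labeled region, how many of
its nodes the cluster touches at any step (n/N and percent), sorted by n
descending then name.

## 2. Trial-level analytics

- **Baseline comparisons.** Pooled-variance (Student) two-sample t for
  continuous characteristics (Welch available) and Pearson chi-square
  without continuity correction for 2×2 tables, via the shortcut form
  `N(ad−bc)² / ((a+b)(c+d)(a+c)(b+d))`.
- **Mixed model.** Scores are z-scored against the whole-sample baseline
  mean/SD so the condition × period interaction coefficient reads as a
  standardized mean difference. The model has fixed effects period,
  condition, their interaction (age optionally added stepwise when it lowers
  the ML AIC) and a participant random intercept. Estimates come from REML
  (statsmodels MixedLM); the likelihood-ratio chi-square for the interaction
  uses ML refits, since REML likelihoods are not comparable across
  fixed-effects structures. The Wald p uses a t reference with
  participants − 2 degrees of freedom, appropriate for a between-participant
  contrast at this size; a z reference would be mildly anti-conservative at
  n = 29. If no participant's score changes at all the interaction is 0 by
  construction and the result is flagged degenerate rather than fitted.
- **Effect size.** Hedges g for the pre/post contrast uses the averaged
  pre/post SD denominator `sqrt((sd_pre² + sd_post²)/2)` and the
  small-sample correction `J = 1 − 3/(4(n−1) − 1)`.
- **Respondents.** A participant responds when
  `(pre − post)/sd_ref ≥ threshold` (default 0.64 SD, inclusive), with
  `sd_ref` defaulting to the whole-sample baseline SD; a drop in commission
  errors is improvement. A cutoff-based counter covers questionnaire scales
  with clinical cutoffs.
- **Power and PPV.** Post hoc power is simulated: cohorts with a participant
  random intercept of variance `icc` (default 0.5, i.e. a pre–post
  correlation of 0.5 on unit total variance — the variance split is
  otherwise unidentified in a summary-statistics design) and a standardized
  interaction of `effect_sd` are fitted with the same mixed model, and power
  is the rejection fraction (default 200 simulations). PPV follows the
  prestudy-odds formula `power·R / (power·R + alpha)` exactly.
- **Questionnaires.** Paired t tests per scale and arm, with Bonferroni
  adjustment applied within each questionnaire family (each instrument is
  its own family; the correction factor is the family size, not the grand
  total).

## 3. The synthetic-data generator

The generator is first-class, tested code: it defines the study conditions
under which every downstream guarantee is demonstrated.

- **Source space.** A regular 3D grid (default 10 mm spacing) clipped to a
  mildly anisotropic ellipsoid (axis ratios 1 : 1.1 : 0.95, the y axis
  anterior–posterior), taking the requested number of nodes (default 1200)
  closest to the centre in ellipsoidal radius with lexicographic
  tie-breaking — fully deterministic. Spatial adjacency uses a Euclidean
  threshold of 1.05 × spacing (6-connectivity on the grid); k-nearest is
  available for irregular layouts.
- **Cohort.** Two arms (default 15/14), ages uniform on 8–11 years, CPT
  commission baselines Normal(53.87, 8.37) and Normal(48.79, 7.53), arm mean
  pre-to-post shifts −6.07 and +0.85, and a within-participant change SD of
  5 T-score points — a plausible test–retest spread that also yields
  respondent proportions in the observed range. Sex and treatment flags are
  Bernoulli with the study's arm-level frequencies.
- **Spectra.** Per cell, `1/f^1.5` background plus a Gaussian alpha bump
  (centre 10.5 Hz, width 1.5 Hz) whose amplitude is weighted toward
  posterior nodes, plus a small floor, under multiplicative log-normal cell
  noise (sd 0.2). All values are strictly positive.
- **Planted effect.** A spatially connected ball of nodes (default radius
  25 mm around the most posterior node) in a frequency band (default
  11.67–13.33 Hz). Inside it the log power ratio is
  `a − b·z(cpt_ratio) + η_i + ε`, with a participant-level component η
  shared across the cluster (sd `noise_sd_log_ratio`, default 0.1) and a
  per-cell jitter ε (sd 0.3 × that); outside, the log ratio is pure per-cell
  noise with the marginal variance matched to the inside. The slope b is
  calibrated through the Gaussian-copula relation r = 2 sin(πρ/6) between
  Pearson and Spearman correlation so the cluster-mean marker correlates
  with the behavioural ratio at `target_rho` (default −0.56, negative:
  behavioural improvement accompanies a power increase). The two-component
  noise is deliberate: a single per-cell term cannot both cap the
  cluster-level correlation and keep per-cell correlations detectable.
  Setting `noise_sd_log_ratio = 0` makes the outside ratio exactly 1 and the
  inside an exact function of the behavioural ratio (with a warning that a
  fractional target correlation is then unreachable). Linearity in the
  z-scored behavioural ratio is an implementation convenience — Spearman
  only needs monotonicity.
- **What it does not emulate.** Raw MEG time series, sensor noise, head
  movement, source leakage, spatially correlated noise fields, or
  non-monotone behaviour–power coupling. Passing tests therefore show the
  statistics behave correctly under the assumed data-generating structure,
  not that any particular real dataset satisfies that structure.

An optional per-node normalisation (`PowerTensor.to_relative`) converts
absolute to relative power before the ratio; the default pipeline uses
absolute power.

## 4. Numerical choices and degenerate inputs

- Ties in ranks: average ranks throughout; significance is strict
  (`p < alpha`).
- Frequency axes must be uniform to ~1e-9 (relative) and strictly
  increasing; the default axis is 2–45 Hz at 1/3 Hz (130 steps).
- Text round trips are bit-exact: matrices at 17 significant digits,
  cohort tables re-read with round-trip float parsing.
- Zero/negative pre power or pre behavioural scores are rejected before any
  ratio; constant cells and constant markers are flagged, not silently
  propagated.
- Mixed-model optimizer: statsmodels' default, with Powell and Nelder–Mead
  fallbacks; boundary (singular) fits surface as a flagged failure rather
  than a wrong number.

## 5. Problem sizes used in the validation studies

The simulation-based checks run at desk scale, chosen to make their
Monte-Carlo error small relative to the asserted bounds: familywise error
uses 200 replicate null cohorts (29 participants, 300 nodes, 40 frequency
steps, 500 permutations each); planted-cluster recovery uses 20 seeds at
target correlation −0.6 on a band-centred 25-step axis; generator
calibration uses 50 replicates on a 120-node grid; mixed-model type-I error
and interaction recovery use 200 simulations each. The exhaustive
permutation oracle runs at n = 6 participants (720 orderings) on a 3-node
lattice.

## 6. Known limitations

- The per-step extent filter interacts with the persistence filter: after
  trimming, edge nodes may retain fewer than `min_consecutive_steps` member
  cells in the final cluster; the persistence criterion applies to the
  significance map, not to final membership.
- The permutation scheme assumes exchangeability of the behavioural ratio
  across participants under the null; arm-dependent variance of the
  behavioural ratio would violate it mildly.
- Spearman-to-Pearson calibration of the planted effect is exact only under
  a Gaussian copula; the achieved correlation is recorded per dataset in
  `ClusterTruth.achieved_rho` rather than assumed.
- P-values below `1/(B+1)` are unattainable by construction; report the
  null vector alongside any headline p.
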