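# Methods

`symnet` implements a symptom-level network analysis of depression and
anxiety screening data: a regularized Gaussian graphical model over the ten
CESD-10 and seven GAD-7 items, expected-influence and bridge
expected-influence centrality, and bootstrap assessment of accuracy and
stability.  A synthetic ordinal-survey generator with a known true network
stands in for survey data, so every stage of the pipeline can be validated
against ground truth.

## Model

The analysis treats the 17 item scores of a participant as a random vector
whose conditional-independence structure is an undirected network.  Under a
Gaussian graphical model with precision (concentration) matrix K, the edge
weight between items i and j is the partial correlation

    w_ij = -K_ij / sqrt(K_ii * K_jj),

the correlation between the two items after controlling for the remaining
fifteen.  Estimation proceeds in four steps:

1. **Correlation.** Pairwise Spearman correlations with average ranks for
   ties (`spearman_matrix`).  Spearman rather than polychoric correlation
   is used because item scores are ordinal and strongly right-skewed;
   sparse cross-tables make polychoric estimates unstable.  A pairwise
   Spearman matrix need not be positive semidefinite, so eigenvalues below
   a floor (1e-4) are clipped and the matrix rescaled to unit diagonal
   (`repair_psd`); already-PSD inputs pass through untouched.
2. **Graphical lasso.** For a penalty λ, K maximizes
   `log det K − tr(S K) − λ Σ_{i≠j} |K_ij|` with the diagonal unpenalized.
   The solver is coordinate descent (scikit-learn's `graphical_lasso`);
   tests verify the returned objective against an independent
   smoothed-continuation L-BFGS maximizer to 1e-6 on 3- and 4-variable
   problems.
3. **Penalty path.** 100 log-spaced penalties from λ_max (the largest
   absolute off-diagonal correlation, at which the model is exactly empty)
   down to λ_max/100.  Path length and minimum ratio follow the convention
   of the psychometric-network toolchain and are config-exposed.
4. **EBIC selection.** Each fit is scored with the extended BIC,
   `−2·loglik + E·log n + 4·E·γ·log p`, where E is the number of nonzero
   off-diagonal pairs (|K_ij| > 1e-8) and γ = 0.5, the conventional value
   favouring sparse, interpretable networks.  Exact EBIC ties break toward
   the larger penalty.  Sub-tolerance weights are set exactly to zero so
   the edge count is well defined in floating point.

## Centrality

Expected influence of node i is the signed sum `EI_i = Σ_j w_ij` (one-step);
node strength is the absolute sum.  Bridge expected influence restricts the
signed sum to edges whose endpoint lies in the other community, with the
two communities fixed a priori by instrument membership (CESD vs GAD).
Raw values are the primary outputs; z-scores (n−1 divisor) are provided for
plotting.  These statistics satisfy, and the tests assert, the exact
identities `EI = BEI + within-community EI` and
`Σ_i EI_i = 2 Σ_{i<j} w_ij`.

## Bootstrap accuracy and stability

* **Edge accuracy** — non-parametric bootstrap: rows resampled with
  replacement, the *entire* estimation (penalty path and EBIC selection
  included) re-run per replicate, and percentile 95% CIs taken per edge.
  Percentile rather than BCa intervals are the simplest defensible choice
  and the toolchain default.  Replicates whose estimation fails are
  skipped and counted; more than 10% failures aborts.
* **Difference tests** — two edges (or two node centralities) differ at
  level α if the (α/2, 1−α/2) percentile interval of their per-replicate
  differences excludes zero.  Tests are unadjusted for multiplicity,
  matching the standard procedure; edge-level tests are computed for edges
  nonzero in the full-sample network.
* **Case-dropping stability** — for each drop proportion q in
  {0.05, …, 0.75}, B subsamples of ⌈(1−q)n⌉ rows are re-estimated and the
  Pearson correlation between subsample and full-sample centrality vectors
  recorded.  The CS-coefficient is the largest q at which ≥ 95% of
  correlations stay ≥ 0.7; values below 0.25 indicate inadequate
  stability, above 0.5 ideal.  The 0.75 grid cap bounds the coefficient
  at 0.75.
* **Seeding** — per-replicate generators derive from
  `SeedSequence((master_seed, stream, replicate))`, so results are
  reproducible and independent of execution order.

## Synthetic data generator

The generator is a latent-Gaussian (Gaussian copula) threshold model — the
standard generative model under which Spearman-based GGM estimation of
ordinal items is meaningful.  A `TrueNetwork` specifies partial
correlations; its implied precision matrix (unit diagonal, off-diagonal
−w_ij) is inverted and rescaled to a latent correlation matrix; n latent
normal vectors are discretized per item at three thresholds into 0–3
responses.

* **Marginals.** Default thresholds are calibrated by root-finding so each
  item's expected score matches a target mean (depression items 0.50–1.45,
  anxiety items 0.12–0.32 — strongly right-skewed, anxiety symptoms much
  rarer than depression symptoms in this population).  Cut points use
  fixed gaps of 0.9 latent SD, giving monotone-decreasing category
  probabilities.
* **Structure.** The default study network anchors six strong
  within-community edges (weights 0.26–0.39, four depression, two anxiety)
  and six weak bridge edges (0.05–0.10, five of them incident to the
  nervousness/anxiety item), plus seeded random within-community filler
  edges (U(0.05, 0.18), 35% of remaining pairs).  If a requested network's
  precision matrix is not positive definite, all weights are uniformly
  shrunk (preserving relative structure, unlike per-edge clipping) until
  the minimum eigenvalue exceeds 0.05, and the factor is reported.
* **Missingness.** Survey codes ("unable", "don't know", "not applicable")
  are injected completely at random at a configurable cell rate.  The
  analysis is complete-case, so the missingness mechanism cannot affect
  pipeline correctness; MCAR is an explicit simplification.  The default
  rate is 0, so a fully defaulted run analyzes all 1685 generated
  participants — matching the post-exclusion sample size of the survey
  wave the pipeline is designed around; missingness is switched on
  explicitly where the filter itself is under test.

### What the generator does and does not emulate

It reproduces: 17 ordinal items with right-skewed marginals, a
two-community dependence structure with strong within- and weak
cross-community partial correlations, eligibility covariates (age,
diagnosis flag), survey missing codes, and the study's sample size.  It
does not emulate multi-stage survey sampling, household clustering, survey
weights, demographic covariates beyond age/diagnosis, or
missing-not-at-random response behaviour.  Passing tests therefore
demonstrate correctness of the estimation machinery under the model's own
assumptions — not that conclusions drawn from any particular real survey
are right.

### Discretization attenuation

Cutting a latent Gaussian at thresholds attenuates correlations, strongly
so for items whose mass concentrates in one category.  Estimated edge
weights on ordinal data are therefore systematically smaller than the
latent generating weights (e.g. an anchor weight of 0.39 is recovered
around 0.27 at n = 1685), and latent bridge edges of 0.05 are usually
regularized away.  Two consequences are reflected in the validation
design:

* Parameter recovery is asserted on the *correlation* between true and
  estimated weights (≥ 0.9 on true-nonzero pairs at n = 2000), not on
  their absolute agreement, and the recovery experiment uses a sparse
  within-community graph (density 0.15, weights U(0.25, 0.40)) so the
  precision matrix is positive definite without shrinkage and the premise
  "all within weights ≥ 0.25" holds exactly.
* Bootstrap CI *coverage* is evaluated on latent-scale (continuous) data
  from a known 6-node network, where the estimand coincides with the
  generating weight; with ordinal data the CIs correctly cover the
  attenuated estimand rather than the latent weight, so latent-scale
  coverage would be misleadingly low at any sample size.  Measured
  coverage at n = 400, B = 50, 20 replications is ≈ 0.83–0.86.  Lasso
  shrinkage additionally biases strong-edge estimates toward zero, which
  is why coverage sits below the nominal 95% even on continuous data —
  a known property of bootstrapping regularized estimators.

## Numerical choices

* Glasso convergence: duality-gap tolerance 1e-4 (the coordinate-descent
  ecosystem default; tighter gaps are unreachable on some problems because
  the gap estimate itself has a numerical floor ≈ 1e-5), max 500
  iterations, deterministic sweep order.  Non-convergence at a path point
  raises; `select_network` skips such points and errors only if the whole
  path fails.
* λ = 0 is solved by direct inversion (errors on singular input).
* Variances and SDs use the n−1 divisor throughout, including inside
  Cronbach's α.
* Degenerate inputs: constant items are rejected by name; an all-zero
  correlation matrix yields a single-point penalty path at 0 with a
  warning; zero-spread vectors cannot be z-standardized (the centrality
  table reports NaN z-scores for degenerate statistics rather than
  failing the run).
* Reduced problem sizes in tests and in the acceptance script (6-node
  networks for bootstrap simulations, B ≤ 50, 10–15-point penalty paths
  with min-ratio 0.1–0.15 inside bootstrap loops) were chosen so the full
  validation executes in minutes; at these settings the selected model on
  the study-size problem is essentially identical to the 100-point-path
  model (same edge set, λ within one grid step).  Library defaults remain
  B = 1000, 100 path points, drop grid 0.05–0.75.

## Scale scoring conventions

CESD-10 totals range 0–30 with depression screened at ≥ 10; GAD-7 totals
range 0–21 with severity bands at 5/10/15 and "anxiety present" defined as
≥ 5 for prevalence and comorbidity.  All cutoffs are closed lower bounds.
No reverse-coding is applied: the generator emits (and the scorer expects)
items already coded so that higher = more severe, as in the survey
instrument's pre-coded release; a column-mapping config accommodates other
datasets.  Cronbach's α values on synthetic data reflect the generator's
dependence structure and the skewed marginals (the α of the anxiety items
is low because their variances are tiny), and are reported descriptively,
not calibrated to any external value.

## Known limitations

* Cross-sectional, group-level model: edges are conditional associations,
  not causal or within-person dynamics.
* Bootstrap CIs around regularized edges are accuracy envelopes, not
  exact confidence intervals (shrinkage bias; see above).
* The MCAR missingness and the absence of survey design features mean the
  generator validates the pipeline, not survey-inference properties.
* Polychoric correlations, Ising/mixed graphical models, directed
  networks and two-step centrality indices are out of scope.
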