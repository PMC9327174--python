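# Methods

## Model

A cohort is a patient-by-feature table with an explicit observation mask.
Cluster-input features are typed: continuous and ordinal features receive
Gaussian univariate factors (ordinal scores such as GCS are treated
numerically), binary and nominal features receive categorical factors.
Each mixture component multiplies its univariate factors by one
compensating ratio `N₂(x_i,x_j)/(N(x_i)N(x_j))` per edge of a dependency
forest; the bivariate Gaussian's marginals are tied to the univariate
parameters, so each tree component of the forest is a tree-Markov
Gaussian and the component density integrates to one.  Binary features
may sit on an edge, in which case their univariate factor is replaced by
the Gaussian marginal on the 0/1 coding (normalisation requires matching
marginals; consistency is preferred over per-feature fidelity).  Nominal
features may not sit on edges.

Missing entries are marginalised, not imputed: a missing feature's
univariate factor integrates to one, and an edge factor is dropped unless
both endpoints are observed.  With tied marginals this is *exact*
whenever the missing feature has degree ≤ 1 in the forest.  For an
interior node with two or more edges, dropping all its factors treats its
observed neighbours as conditionally independent — a deliberate
approximation (the exact marginal would couple the neighbours with
correlation ρ₁ρ₂).  The packaged default forest (pH–BE, pH–PaCO₂,
GCSm–GCSt, GCSm–pupils) has interior nodes of degree 2, so the
approximation is mild and only active when pH or GCS motor is missing.

## Estimation

EM from a seeded random start: per-patient responsibilities drawn from a
flat Dirichlet, followed by an M-step.  The M-step uses
responsibility-weighted moments: means/sds over all patients observing
the feature (1/n maximum-likelihood normalisation), category frequencies
floored at 1e-6 and renormalised, and per-edge correlations as weighted
Pearson coefficients over patients observing *both* endpoints,
standardised by the new univariate parameters.  With complete data this
two-stage update is the exact joint maximiser for a decomposable
tree-Gaussian model (moment matching on nodes and edges), so the
log-likelihood is monotone.  Under missingness the edge update is
approximate and EM becomes a *generalized* EM: the iteration continues
through small likelihood dips, tracks the best state seen, and stops at
relative change < 1e-6 (default) or after ten iterations without
improvement; decreases above 1% of |L| raise an internal-consistency
error.  The recorded trace keeps accepted (ascending) values only.

Two numerical guards matter in practice:

* **Variance floors.**  Each cluster/feature variance is floored at
  1e-4 × pooled variance, and additionally — for Gaussian factors on
  grid-valued (ordinal or binary-coded) features — at `h²/12`, the
  within-cell variance of rounding to a grid with spacing `h`.  Without
  the discretization floor, EM places near-zero-variance spikes on single
  discrete levels (e.g. GCS motor = 6) and the likelihood rewards carving
  clusters by exact score values.
* **Component re-seeding.**  If at convergence some component has no
  patient hard-assigned to it, the component is re-centred on the
  worst-fit patient with pooled spreads and weight 1/n, and iteration
  continues (a bounded number of times).  A fit at candidate K must
  actually use K components; otherwise the stability protocol's 1/K
  penalty is biased toward inflated K, because a (K+1)-component fit that
  silently collapses to the K-cluster solution reproduces it perfectly.

Correlations are capped at |ρ| ≤ 0.999; clusters with essentially no
responsibility mass on a feature keep their previous parameters with a
warning.  `best_of_restarts` runs ten (configurable) seeds and keeps the
highest final log-likelihood, ties to the lowest seed index.

## Selecting the number of clusters

For each K in a candidate range, `n_repetitions` independent
best-of-restarts fits are compared pairwise with the cluster similarity
index: the contingency table of two hard assignments is matched
one-to-one (Hungarian assignment, maximizing agreement; a greedy matcher
is available for cross-checks) and the matched agreement is divided by n.
CSI is symmetric, relabeling-invariant, and equals 1 exactly when the two
partitions coincide.  The selected K maximises `median CSI − 1/K` (ties
to the smallest K); the penalty compensates CSI's drift toward 1 as K
shrinks.  Repetition j of candidate k draws its seed from a stream
derived from (master seed, k, j), making the whole protocol reproducible
from one integer.  The default protocol is K ∈ 3..15 with 20 repetitions
of 10 restarts; the test suite and the acceptance script run a reduced
protocol (K ∈ 3..9, 5 repetitions × 3 restarts, n = 600, EM capped at
300 iterations) sized for a single-CPU desk run.

## Feature importance and outcome evaluation

Mutual information between the cluster label and feature i is the
plug-in quantity `I(C;X) = Σ_c π̂_c KL(p_c ‖ p̄)` with `p̄ = Σ_j π̂_j p_j`,
cluster shares π̂ from the hard assignment and per-cluster distributions
from the fitted model.  Categorical features are summed exactly; Gaussian
features use stratified fixed-seed Monte Carlo (default 50,000 draws)
with a reported standard error.  Values are in nats by default (bits via
`units="bits"`); the importance threshold is MI > 0.1.  Reported MI is
clipped at zero where Monte-Carlo noise produces small negatives.

Outcome association uses GOS-E (1–8): mortality = GOS-E 1, unfavourable
= GOS-E < 5.  Logistic models are maximum-likelihood fits (statsmodels
Newton/IRLS); Nagelkerke R² is Cox–Snell rescaled,
`R²_N = [1 − exp(2(ll₀−ll)/n)] / [1 − exp(2·ll₀/n)]`.  Adding K−1 cluster
indicators (reference = lowest label) to a base covariate model is tested
with the likelihood-ratio statistic against χ²(K−1).  Covariates for the
regression stage only are completed by observed-median/mode imputation
with flags — a documented simplification; the clustering path never
imputes.  Per-cluster observed vs predicted outcome tables compute
differences as predicted − observed; with integer report formatting the
percentages are rounded half-up first and differences recomputed on the
rounded scale, matching how such tables are printed clinically.  Two
endpoints are tested without multiplicity adjustment, mirroring common
reporting practice; interpret pairs of p-values accordingly.

## Synthetic cohort generator

`default_scheme` plants six clusters (A–F) over twelve admission
features: age, GCS motor/total, lactate, SpO₂, creatinine, glucose, base
excess, pH, PaCO₂, temperature, pupil reactivity, with edges pH–BE
(ρ=0.7), pH–PaCO₂ (−0.45), GCSm–GCSt (0.8), GCSm–pupils (0.5).  The
profiles follow the qualitative endotype pattern of ICU TBI cohorts:
mild-GCS/normal metabolism (A), moderate GCS (B), a small
metabolic-stress cluster with high creatinine/glucose/lactate (C), severe
GCS with clean metabolism (D), very low GCS with poor pupil reactivity
(E), and a hypoxic shock-like cluster (F, lowest SpO₂).  Numeric features
joined by edges are sampled root-to-leaf from the implied tree-Markov
Gaussian; ordinals are rounded, clipped Gaussians; GOS-E is drawn from
per-cluster outcome distributions shaped after published per-cluster
frequencies.  Missingness is 20% MCAR on every cluster input (an MAR
variant, with rates depending on GCS, can be configured through
`apply_missingness` for robustness experiments).  One master seed drives
labels, features, outcomes and masks through separate derived streams.

Two generator choices were made for testability and are deliberate
deviations from the published cohort's composition: mixing weights are
smoothed (0.24/0.15/0.07/0.19/0.21/0.14) so the rarest cluster keeps ~7%
of patients and remains recoverable at n = 600 (a 2.8% cluster is not),
and cluster separations were set — once, by checking that a classifier
using the *true* generative parameters reaches ARI ≈ 0.92–0.94 under 20%
missingness — so the planted structure is genuinely well separated.
What passing tests show, therefore, is that the estimator recovers
well-separated planted structure through realistic missingness, not that
six clusters would be found in any real cohort; real admission data are
skewed, have MNAR components, and their cluster structure is far less
crisp (real analyses show exactly the intermediate-severity instability
this generator only hints at).  On some realisations the maximum-
likelihood six-cluster solution is a genuinely different partition from
the planted one (observed ARI ≈ 0.72–0.78 on two of ten master seeds);
this is a property of ML clustering on finite samples, and the
stability protocol's occasional selection of 5 or 7 on such realisations
is the same phenomenon.

## Degenerate inputs and edge cases

Patients with no observed cluster-input features are excluded at load
time (logged); patients with everything missing at fit time would get
responsibilities equal to the mixing weights.  Features entirely missing
keep their initialisation parameters with a warning.  Empty clusters in
`cluster_profile` yield undefined rows with a warning.  Quantiles are
type-7 (linear interpolation) on observed values only.  Labelings passed
to CSI may use any label values; constant labelings are handled (CSI at
least the largest cluster share).  Hard assignment breaks ties toward
the lowest cluster index; labels are 1-based throughout.

## Limitations

* No covariance structure beyond forest edges; no robust/t components;
  no Bayesian treatment.
* The regression stage's single median/mode imputation understates
  covariate uncertainty relative to multiple imputation; it exists to
  exercise the comparison machinery, not to make clinical claims.
* MI is model-based (plug-in); it inherits any model misfit. An
  empirical estimate can be obtained by discretising raw data, which is
  out of scope here.
* The marginalisation approximation at interior forest nodes (above) and
  the both-observed edge-correlation update mean EM under missingness is
  generalized EM, not exact EM.
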