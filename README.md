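# endomix

Endotype discovery in mixed-type clinical cohorts: model-based clustering
of ICU admission data with missingness, stability-based selection of the
number of clusters, mutual-information feature importance, and outcome
association.

## The problem

Traumatic brain injury (and critical illness generally) is conventionally
graded by a single severity score (the Glasgow coma scale), which hides
enormous pathophysiological heterogeneity.  Unsupervised clustering of
admission data — demographics, GCS scores, pupil reactivity, blood gases,
lactate, glucose, creatinine, temperature — can reveal *endotypes*:
subgroups with distinct underlying physiology (e.g. "moderate GCS with
metabolic stress" vs "severe GCS with normal metabolism") that plain
severity grading conflates.  Such data are mixed-type (continuous labs,
ordinal scores, binary flags, nominal categories) and substantially
incomplete, which rules out off-the-shelf Gaussian mixtures on complete
cases.

## The model

Each of K clusters is a product of univariate factors times one
*compensating factor* per strongly-correlated feature pair:

```
p_c(x) = Π_i p_c(x_i) · Π_{(i,j)∈F}  N₂(x_i, x_j; μ, σ, ρ_c) / ( N(x_i) N(x_j) )
```

where `F` is a *dependency forest* of feature pairs (pH–base excess,
pH–PaCO₂, GCS motor–total, GCS motor–pupils, ...), each pair is a
bivariate Gaussian whose marginals are tied to the univariate factors,
and categorical features contribute category probabilities.  On a forest
this is a properly normalised tree-Markov density.  The mixture

```
p(x) = Σ_c π_c p_c(x)
```

is fitted by EM **without imputation**: a missing feature's univariate
factor marginalises to one and an edge factor is dropped unless both
endpoints are observed, so the E-step uses exactly the observed entries.

The number of clusters is chosen by a stability protocol: for each
candidate K, repeated best-of-restarts fits are compared pairwise with
the **cluster similarity index** (CSI — the fraction of patients assigned
to the same cluster after optimally matching cluster labels between two
fits), and the K maximising `median CSI − 1/K` is selected.  Fitted
clusters are interpreted through the mutual information I(C; X_i) between
the cluster label and each feature (features with MI > 0.1 nats are
flagged), and evaluated against outcome (GOS-E: mortality = GOS-E 1,
unfavourable = GOS-E < 5) with logistic models, Nagelkerke pseudo-R² and
a likelihood-ratio test for adding K−1 cluster indicators to a base
covariate model.

Because real cohorts of this kind sit behind data-sharing agreements, the
package ships a synthetic-cohort generator (`default_scheme`) that plants
six clusters with qualitatively realistic GCS/metabolic profiles,
forest-correlated pairs, 20% MCAR missingness and cluster-dependent
GOS-E distributions, so the whole pipeline is testable end to end.

## Worked example

```python
import numpy as np
import endomix as em
from sklearn.metrics import adjusted_rand_score

cfg = em.default_scheme(n_patients=600, seed=3)     # planted 6-cluster cohort
cohort, truth = em.generate_cohort(cfg)

est = em.GraphMixture(n_components=6, forest=cfg.forest,
                      n_restarts=10, random_state=3).fit(cohort)
print("converged:", est.converged_, " final log-likelihood:",
      round(est.loglik_trace_[-1], 1))
print("cluster sizes:", np.bincount(est.labels_)[1:])
print("ARI vs planted labels:", round(adjusted_rand_score(truth, est.labels_), 3))
print(em.mi_report(est.model_, est.labels_, cohort).head(5)
        [["feature", "mi", "important"]].to_string(index=False))
```

prints

```
converged: True  final log-likelihood: -8416.3
cluster sizes: [ 50 112 144  90  86 118]
ARI vs planted labels: 0.922
         feature       mi  important
       gcs_total 1.108807       True
       gcs_motor 0.784487       True
         lactate 0.692091       True
            spo2 0.591164       True
pupil_reactivity 0.403070       True
```

The fit recovers the six planted clusters (adjusted Rand index 0.92
despite 20% missing cells), and the mutual-information ranking identifies
the GCS scores and the metabolic features (lactate, SpO₂) as the main
cluster discriminators — the signature pattern of endotype analyses of
ICU trauma cohorts.  `StabilitySelector` runs the full protocol over a
range of K, and `endomix select-k --help` (plus `simulate`, `validate`,
`screen`, `fit`, `evaluate`) exposes the same pipeline on CSVs from the
shell.

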