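"""Mixture of probabilistic graph models over mixed-type data, fitted by EM.

Each mixture component is a product of univariate factors (Gaussian for
continuous/ordinal features, categorical for binary/nominal) times one
compensating ratio factor per dependency-forest edge::

    p_c(x) = prod_i p_c(x_i) * prod_{(i,j) in forest} N2(x_i, x_j) / (N(x_i) N(x_j))

where the bivariate Gaussian N2 shares its marginal (mu, sigma) with the
univariate factors, so the density is properly normalised on a forest.
Missing entries contribute nothing to a component's log-density: the
univariate factor of a missing feature marginalises to one, and an edge
factor is dropped unless both endpoints are observed.  The EM fit
therefore needs no imputation.

Cluster labels produced by :func:`hard_assign` (and by the
:class:`GraphMixture` estimator) are 1-based, matching clinical reporting
of clusters as 1..k (or A..F).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.base import BaseEstimator, ClusterMixin

from .schema import CohortTable, ValidationError
from .screen import DependencyForest

_LOG_2PI = math.log(2.0 * math.pi)


class EMConsistencyError(RuntimeError):
    """The observed-data log-likelihood decreased beyond numerical slack."""


class NumericalError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# numeric encoding of a cohort for the model
# ---------------------------------------------------------------------------

@dataclass
class ModelMeta:
    """Model-facing view of the schema: which factor each feature gets."""

    names: list[str]
    kinds: list[str]  # 'gaussian' | 'categorical'
    levels: list[tuple | None]
    edge_names: tuple[tuple[str, str], ...]
    edge_idx: np.ndarray  # (E, 2) int indices into names
    disc_floor: np.ndarray | None = None  # (p,) absolute variance floors

    def __post_init__(self):
        if self.disc_floor is None:
            # Gaussian factors on grid-valued (ordinal/binary-coded) features
            # get a discretization variance floor of spacing^2/12 — the
            # within-cell variance of rounding — so no component can collapse
            # onto a single discrete level.
            floors = np.zeros(len(self.names))
            for j, (kind, lv) in enumerate(zip(self.kinds, self.levels)):
                if kind == "gaussian" and lv is not None and len(lv) > 1:
                    try:
                        grid = np.sort(np.asarray(lv, dtype=float))
                        spacing = float(np.min(np.diff(grid)))
                    except (TypeError, ValueError):
                        spacing = 1.0  # binary coded by level index
                    floors[j] = spacing**2 / 12.0
            self.disc_floor = floors

    @property
    def p(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)


@dataclass
class ModelData:
    """Numeric-coded records: values (or level indices) with a mask."""

    meta: ModelMeta
    X: np.ndarray  # (n, p) float; NaN where missing; categorical = level index
    M: np.ndarray  # (n, p) bool

    @property
    def n(self) -> int:
        return self.X.shape[0]


def encode(cohort: CohortTable, forest: DependencyForest | None = None) -> ModelData:
    """Code the cluster-input features of a cohort for the mixture model.

    Continuous and ordinal features always get Gaussian univariate
    factors; binary/nominal features get categorical factors unless they
    sit on a forest edge, in which case the (binary) feature is treated
    numerically via its level index so the bivariate Gaussian is defined
    (nominal features may never sit on an edge).
    """
    forest = forest or DependencyForest()
    forest.validate_against(cohort)
    names = cohort.cluster_input_names
    on_edge = forest.nodes
    kinds, levels = [], []
    cols, masks = [], []
    for name in names:
        spec = cohort.feature(name)
        m = cohort.mask[name].to_numpy()
        vals = cohort.records[name]
        x = np.full(cohort.n_patients, np.nan)
        if spec.kind in ("continuous", "ordinal") or (
            spec.kind == "binary" and name in on_edge
        ):
            kinds.append("gaussian")
            levels.append(spec.levels)
            if spec.kind == "binary":
                lut = {lv: i for i, lv in enumerate(spec.levels)}
                x[m] = [float(lut[v]) for v in vals[m]]
            else:
                x[m] = pd.to_numeric(vals[m]).to_numpy(dtype=float)
        else:
            kinds.append("categorical")
            levels.append(spec.levels)
            lut = {lv: i for i, lv in enumerate(spec.levels)}
            x[m] = [float(lut[v]) for v in vals[m]]
        cols.append(x)
        masks.append(m)
    name_idx = {n_: i for i, n_ in enumerate(names)}
    for a, b in forest:
        if a not in name_idx or b not in name_idx:
            raise ValidationError(f"forest edge {a!r}-{b!r} references a non-cluster_input feature")
    edge_idx = np.array([[name_idx[a], name_idx[b]] for a, b in forest], dtype=int).reshape(-1, 2)
    meta = ModelMeta(list(names), kinds, levels, tuple(forest.edges), edge_idx)
    return ModelData(meta, np.column_stack(cols), np.column_stack(masks))


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclass
class ComponentParams:
    """One cluster's parameters in record-oriented form.

    ``univariate`` maps a feature name to ``("gaussian", mu, sd)`` or
    ``("categorical", probs)``; ``bivariate`` maps an edge (name pair) to
    its correlation.  The bivariate Gaussians share the univariate
    marginals by construction, so no extra parameters appear here.
    """

    names: list[str]
    kinds: list[str]
    levels: list[tuple | None]
    univariate: dict
    bivariate: dict


@dataclass
class MixtureModel:
    weights: np.ndarray  # (k,)
    means: np.ndarray  # (k, p), NaN on categorical columns
    sds: np.ndarray  # (k, p)
    cat_probs: dict  # col index -> (k, L)
    rhos: np.ndarray  # (k, E)
    forest: DependencyForest
    meta: ModelMeta

    @property
    def k(self) -> int:
        return len(self.weights)

    def component(self, c: int) -> ComponentParams:
        uni, bi = {}, {}
        for j, name in enumerate(self.meta.names):
            if self.meta.kinds[j] == "gaussian":
                uni[name] = ("gaussian", float(self.means[c, j]), float(self.sds[c, j]))
            else:
                uni[name] = ("categorical", self.cat_probs[j][c].copy())
        for e, (a, b) in enumerate(self.meta.edge_names):
            bi[(a, b)] = float(self.rhos[c, e])
        return ComponentParams(
            list(self.meta.names), list(self.meta.kinds), list(self.meta.levels), uni, bi
        )

    def to_dict(self) -> dict:
        return {
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "cat_probs": {str(j): p.tolist() for j, p in self.cat_probs.items()},
            "rhos": self.rhos.tolist(),
            "edges": [list(e) for e in self.forest.edges],
            "feature_names": self.meta.names,
            "feature_kinds": self.meta.kinds,
            "feature_levels": [list(lv) if lv is not None else None for lv in self.meta.levels],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MixtureModel":
        forest = DependencyForest(tuple((a, b) for a, b in d["edges"]))
        names = list(d["feature_names"])
        idx = {n_: i for i, n_ in enumerate(names)}
        edge_idx = np.array([[idx[a], idx[b]] for a, b in forest], dtype=int).reshape(-1, 2)
        meta = ModelMeta(
            names,
            list(d["feature_kinds"]),
            [tuple(lv) if lv is not None else None for lv in d["feature_levels"]],
            tuple(forest.edges),
            edge_idx,
        )
        return cls(
            np.asarray(d["weights"], float),
            np.asarray(d["means"], float),
            np.asarray(d["sds"], float),
            {int(j): np.asarray(p, float) for j, p in d["cat_probs"].items()},
            np.asarray(d["rhos"], float).reshape(len(d["weights"]), -1),
            forest,
            meta,
        )


@dataclass
class FitResult:
    model: MixtureModel
    responsibilities: np.ndarray  # (n, k)
    loglik_trace: list[float]
    converged: bool
    n_iter: int
    seed: int

    @property
    def loglik(self) -> float:
        return self.loglik_trace[-1]

    @property
    def labels(self) -> np.ndarray:
        return hard_assign(self.responsibilities)


# ---------------------------------------------------------------------------
# densities
# ---------------------------------------------------------------------------

def _edge_term(zi, zj, rho):
    om = 1.0 - rho**2
    return -0.5 * np.log(om) - (rho**2 * (zi**2 + zj**2) - 2.0 * rho * zi * zj) / (2.0 * om)


def log_density_matrix(data: ModelData, model: MixtureModel) -> np.ndarray:
    """Per-patient, per-component log-density of the observed entries (n, k)."""
    X, M = data.X, data.M
    n = X.shape[0]
    k = model.k
    L = np.zeros((n, k))
    for j, kind in enumerate(data.meta.kinds):
        obs = M[:, j]
        if not obs.any():
            continue
        if kind == "gaussian":
            mu = model.means[:, j]
            sd = model.sds[:, j]
            z = (X[obs, j][:, None] - mu[None, :]) / sd[None, :]
            L[obs] += -0.5 * z**2 - np.log(sd)[None, :] - 0.5 * _LOG_2PI
        else:
            codes = X[obs, j].astype(int)
            probs = model.cat_probs[j]  # (k, L)
            L[obs] += np.log(probs.T[codes])
    for e in range(len(data.meta.edge_names)):
        i, j = data.meta.edge_idx[e]
        both = M[:, i] & M[:, j]
        if not both.any():
            continue
        zi = (X[both, i][:, None] - model.means[None, :, i]) / model.sds[None, :, i]
        zj = (X[both, j][:, None] - model.means[None, :, j]) / model.sds[None, :, j]
        L[both] += _edge_term(zi, zj, model.rhos[None, :, e])
    return L


def component_log_density(record: Mapping, params: ComponentParams) -> float:
    """Log-density of one patient's observed entries under one component.

    ``record`` maps feature names to values; a missing feature is absent,
    None, or NaN.  All features missing gives 0 (density 1 over the empty
    observation).
    """
    def _missing(v):
        return v is None or (isinstance(v, float) and math.isnan(v))

    total = 0.0
    obs = {}
    for j, name in enumerate(params.names):
        v = record.get(name)
        if _missing(v):
            continue
        kind = params.kinds[j]
        if kind == "gaussian":
            if params.levels[j] is not None and not isinstance(v, (int, float)):
                v = float(list(params.levels[j]).index(v))
            _, mu, sd = params.univariate[name]
            z = (float(v) - mu) / sd
            total += -0.5 * z**2 - math.log(sd) - 0.5 * _LOG_2PI
            obs[name] = z
        else:
            _, probs = params.univariate[name]
            lv = list(params.levels[j])
            if v not in lv:
                raise ValidationError(f"value {v!r} outside declared levels for {name!r}")
            total += math.log(probs[lv.index(v)])
    for (a, b), rho in params.bivariate.items():
        if a in obs and b in obs:
            total += float(_edge_term(np.float64(obs[a]), np.float64(obs[b]), rho))
    return total


def record_log_likelihood(model: MixtureModel, record: Mapping) -> float:
    """Observed-data mixture log-likelihood of a single record."""
    lls = np.array(
        [component_log_density(record, model.component(c)) for c in range(model.k)]
    )
    return float(logsumexp(np.log(model.weights) + lls))


# ---------------------------------------------------------------------------
# EM steps
# ---------------------------------------------------------------------------

def e_step(data: ModelData, model: MixtureModel) -> tuple[np.ndarray, float]:
    """Responsibilities and total observed-data log-likelihood.

    r[n, c] = pi_c exp(l_nc) / sum_j pi_j exp(l_nj), computed via
    log-sum-exp.  A patient with nothing observed gets r = pi.
    """
    L = log_density_matrix(data, model)
    if not np.isfinite(L).all():
        bad = np.argwhere(~np.isfinite(L))[0]
        raise NumericalError(
            f"non-finite component log-density for patient {bad[0]}, component {bad[1]}"
        )
    A = np.log(model.weights)[None, :] + L
    lse = logsumexp(A, axis=1)
    R = np.exp(A - lse[:, None])
    return R, float(lse.sum())


def _pooled_model(data: ModelData, k: int, forest: DependencyForest,
                  var_floor_frac: float = 1e-4, cat_floor: float = 1e-6) -> MixtureModel:
    """All components at the pooled (global) parameters; used as the
    fallback baseline for degenerate clusters and as m_step's 'previous'
    model on the first iteration."""
    p = data.meta.p
    means = np.full((k, p), np.nan)
    sds = np.full((k, p), np.nan)
    cat_probs = {}
    for j, kind in enumerate(data.meta.kinds):
        obs = data.M[:, j]
        if kind == "gaussian":
            if obs.any():
                x = data.X[obs, j]
                mu, var = float(x.mean()), float(x.var())
            else:
                mu, var = 0.0, 1.0
            floor = max(var_floor_frac * max(var, 1e-12), data.meta.disc_floor[j], 1e-12)
            sd = math.sqrt(max(var, floor))
            means[:, j] = mu
            sds[:, j] = sd
        else:
            nl = len(data.meta.levels[j])
            if obs.any():
                codes = data.X[obs, j].astype(int)
                freq = np.bincount(codes, minlength=nl).astype(float)
                freq = np.clip(freq / freq.sum(), cat_floor, None)
                freq /= freq.sum()
            else:
                freq = np.full(nl, 1.0 / nl)
            cat_probs[j] = np.tile(freq, (k, 1))
    rhos = np.zeros((k, len(data.meta.edge_names)))
    return MixtureModel(np.full(k, 1.0 / k), means, sds, cat_probs, rhos, forest, data.meta)


def m_step(
    data: ModelData,
    R: np.ndarray,
    forest: DependencyForest,
    prev: MixtureModel | None = None,
    var_floor_frac: float = 1e-4,
    cat_floor: float = 1e-6,
    rho_cap: float = 0.999,
    degenerate_eps: float = 1e-8,
) -> MixtureModel:
    """Responsibility-weighted parameter re-estimation.

    Means/sds use every patient observing the feature (1/n-style MLE
    normalisation); category probabilities are floored and renormalised;
    each edge correlation uses only patients observing both endpoints,
    standardised by the new univariate parameters (tied marginals).  A
    cluster with essentially no responsibility mass on a feature keeps its
    previous value for that parameter, with a warning.
    """
    n, k = R.shape
    if not np.allclose(R.sum(axis=1), 1.0, atol=1e-8):
        raise ValidationError("responsibility rows must sum to 1")
    if prev is None:
        prev = _pooled_model(data, k, forest, var_floor_frac, cat_floor)
    meta = data.meta
    Xf = np.where(data.M, np.nan_to_num(data.X), 0.0)
    weights = R.sum(axis=0) / n
    means = prev.means.copy()
    sds = prev.sds.copy()
    cat_probs = {j: p.copy() for j, p in prev.cat_probs.items()}
    rhos = prev.rhos.copy()

    for j, kind in enumerate(meta.kinds):
        obs = data.M[:, j]
        if not obs.any():
            warnings.warn(
                f"feature {meta.names[j]!r} has no observed values; parameters held",
                UserWarning,
                stacklevel=2,
            )
            continue
        w = R * obs[:, None]  # (n, k)
        sw = w.sum(axis=0)
        ok = sw > degenerate_eps
        if not ok.all():
            warnings.warn(
                f"degenerate cluster(s) {np.flatnonzero(~ok).tolist()} for feature "
                f"{meta.names[j]!r}; parameters held at previous values",
                UserWarning,
                stacklevel=2,
            )
        if kind == "gaussian":
            swm = np.where(ok, sw, 1.0)
            mu = (w * Xf[:, j : j + 1]).sum(axis=0) / swm
            var = (w * (Xf[:, j : j + 1] - mu[None, :]) ** 2).sum(axis=0) / swm
            pooled_var = float(data.X[obs, j].var())
            floor = max(var_floor_frac * max(pooled_var, 1e-12), data.meta.disc_floor[j])
            sd = np.sqrt(np.maximum(var, floor))
            means[:, j] = np.where(ok, mu, prev.means[:, j])
            sds[:, j] = np.where(ok, sd, prev.sds[:, j])
        else:
            nl = len(meta.levels[j])
            codes = data.X[:, j]
            counts = np.zeros((k, nl))
            for l in range(nl):
                sel = obs & (codes == l)
                if sel.any():
                    counts[:, l] = R[sel].sum(axis=0)
            tot = counts.sum(axis=1)
            probs = cat_probs[j]
            new = np.clip(counts / np.where(ok, tot, 1.0)[:, None], cat_floor, None)
            new /= new.sum(axis=1, keepdims=True)
            cat_probs[j] = np.where(ok[:, None], new, probs)

    for e in range(len(meta.edge_names)):
        i, j = meta.edge_idx[e]
        both = data.M[:, i] & data.M[:, j]
        if not both.any():
            warnings.warn(
                f"no patient observes both endpoints of edge {meta.edge_names[e]}; "
                "correlation held",
                UserWarning,
                stacklevel=2,
            )
            continue
        w = R[both]  # (n_b, k)
        zi = (data.X[both, i][:, None] - means[None, :, i]) / sds[None, :, i]
        zj = (data.X[both, j][:, None] - means[None, :, j]) / sds[None, :, j]
        sxy = (w * zi * zj).sum(axis=0)
        sxx = (w * zi**2).sum(axis=0)
        syy = (w * zj**2).sum(axis=0)
        den = np.sqrt(sxx * syy)
        ok = (w.sum(axis=0) > degenerate_eps) & (den > 1e-12)
        rho = np.clip(np.where(ok, sxy / np.where(den > 0, den, 1.0), 0.0), -rho_cap, rho_cap)
        rhos[:, e] = np.where(ok, rho, prev.rhos[:, e])

    return MixtureModel(weights, means, sds, cat_probs, rhos, forest, meta)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _as_data(cohort, forest: DependencyForest | None) -> ModelData:
    if isinstance(cohort, ModelData):
        return cohort
    return encode(cohort, forest)


def fit_em(
    cohort,
    k: int,
    forest: DependencyForest | None = None,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> FitResult:
    """One EM run from a seeded random initialisation.

    Initial responsibilities are drawn from a flat Dirichlet per patient,
    followed by an M-step.  Iterates until the relative change of the
    observed-data log-likelihood drops below ``tol`` or ``max_iter`` is
    hit.

    With complete data the M-step is the exact maximiser, so the
    likelihood trace is non-decreasing.  Under missingness the edge
    correlations are re-estimated from both-observed patients only, an
    approximation without a strict ascent guarantee, so the iteration is
    a generalized EM: it continues through small likelihood dips, keeps
    the best state seen, and stops after ten iterations without
    improvement.  ``loglik_trace`` records the accepted (ascending)
    values and is therefore monotone.  A large decrease (> 1% of |L|)
    raises :class:`EMConsistencyError` as an EM bug trap.
    """
    forest = forest or DependencyForest()
    data = _as_data(cohort, forest)
    if k < 1:
        raise ValidationError("k must be >= 1")
    if data.n < k:
        raise ValidationError(f"need at least k={k} patients, got {data.n}")
    rng = np.random.default_rng(seed)
    R0 = rng.dirichlet(np.ones(k), size=data.n)
    model = m_step(data, R0, forest)
    trace: list[float] = []
    converged = False
    best: tuple[MixtureModel, np.ndarray, float] | None = None
    prev_ll = None
    stall = 0
    reseed_budget = 3 * k
    it = 0
    for it in range(1, max_iter + 1):
        R, ll = e_step(data, model)
        if prev_ll is not None and prev_ll - ll > 1e-2 * max(1.0, abs(prev_ll)):
            raise EMConsistencyError(
                f"log-likelihood dropped from {prev_ll:.10g} to {ll:.10g} at iter {it}"
            )
        if best is None or ll > best[2]:
            best = (model, R, ll)
            trace.append(ll)
            stall = 0
        else:
            stall += 1
        if prev_ll is not None and abs(ll - prev_ll) / max(1.0, abs(prev_ll)) < tol:
            # a candidate-k fit must use all k components: re-seed any that
            # collapsed (see _reseed_empty) instead of accepting a
            # degenerate smaller mixture
            hard_counts = np.bincount(R.argmax(axis=1), minlength=R.shape[1])
            if reseed_budget > 0 and (hard_counts == 0).any() and it < max_iter - 20:
                model = _reseed_empty(data, model, R)
                reseed_budget -= 1
                prev_ll = None
                stall = 0
                continue
            converged = True
            break
        if stall >= 10:
            break
        prev_ll = ll
        model = m_step(data, R, forest, prev=model)
    model, R, _ = best
    return FitResult(model, R, trace, converged, it, seed)


def _reseed_empty(data: ModelData, model: MixtureModel, R: np.ndarray) -> MixtureModel:
    """Re-seed components with essentially no responsibility mass.

    A component to which no patient hard-assigns is recentred on the
    worst-fit patient (lowest mixture log-likelihood), with pooled
    spreads, zero edge correlations and a 1/n mixing weight, so that a
    K-component fit cannot silently collapse into a smaller mixture.
    Deterministic.
    """
    n, k = R.shape
    L = log_density_matrix(data, model)
    per_patient = logsumexp(np.log(model.weights)[None, :] + L, axis=1)
    order = np.argsort(per_patient)  # worst-fit first
    pooled = _pooled_model(data, k, model.forest)
    weights = model.weights.copy()
    means = model.means.copy()
    sds = model.sds.copy()
    cat_probs = {j: p.copy() for j, p in model.cat_probs.items()}
    rhos = model.rhos.copy()
    dying = np.flatnonzero(np.bincount(R.argmax(axis=1), minlength=k) == 0)
    for rank, c in enumerate(dying):
        i = int(order[rank % n])
        for j, kind in enumerate(data.meta.kinds):
            if kind == "gaussian":
                means[c, j] = data.X[i, j] if data.M[i, j] else pooled.means[0, j]
                sds[c, j] = pooled.sds[0, j]
            else:
                cat_probs[j][c] = pooled.cat_probs[j][0]
        rhos[c, :] = 0.0
        weights[c] = 1.0 / n
    weights /= weights.sum()
    return MixtureModel(weights, means, sds, cat_probs, rhos, model.forest, model.meta)


def restart_seeds(seed: int, n_restarts: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n_restarts)]


def best_of_restarts(
    cohort,
    k: int,
    forest: DependencyForest | None = None,
    n_restarts: int = 10,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> FitResult:
    """Fit ``n_restarts`` EM runs from derived seeds; keep the highest
    final log-likelihood (ties broken by lowest seed index)."""
    if n_restarts < 1:
        raise ValidationError("n_restarts must be >= 1")
    forest = forest or DependencyForest()
    data = _as_data(cohort, forest)
    best: FitResult | None = None
    failures = []
    for s in restart_seeds(seed, n_restarts):
        try:
            fit = fit_em(data, k, forest, seed=s, tol=tol, max_iter=max_iter)
        except (EMConsistencyError, NumericalError) as exc:  # pragma: no cover
            failures.append(exc)
            continue
        if best is None or fit.loglik > best.loglik:
            best = fit
    if best is None:
        raise RuntimeError(f"all {n_restarts} restarts failed: {failures}")
    return best


def hard_assign(R: np.ndarray) -> np.ndarray:
    """Most probable cluster per patient, 1-based; ties go to the lowest
    cluster index (argmax convention)."""
    R = np.asarray(R, dtype=float)
    if R.ndim != 2 or ((R < -1e-12) | (R > 1 + 1e-12)).any():
        raise ValidationError("responsibilities must be an (n, k) matrix in [0, 1]")
    return R.argmax(axis=1) + 1


def cluster_profile(cohort: CohortTable, labels: np.ndarray) -> pd.DataFrame:
    """Per-cluster summary table: median (IQR) for numeric features on
    observed values, counts (%) per level for categorical features."""
    labels = np.asarray(labels)
    if len(labels) != cohort.n_patients:
        raise ValidationError("labels length must match cohort size")
    rows = []
    clusters = sorted(set(int(l) for l in labels))
    for f in cohort.schema:
        if f.role != "cluster_input":
            continue
        for c in clusters:
            in_c = labels == c
            m = cohort.mask[f.name].to_numpy() & in_c
            if f.kind in ("continuous", "ordinal"):
                if not m.any():
                    warnings.warn(
                        f"no observed {f.name!r} values in cluster {c}", UserWarning, stacklevel=2
                    )
                    med = q1 = q3 = float("nan")
                else:
                    x = pd.to_numeric(cohort.records[f.name][m]).to_numpy(dtype=float)
                    q1, med, q3 = np.percentile(x, [25, 50, 75])  # type-7 linear quantiles
                rows.append(
                    dict(feature=f.name, cluster=c, kind=f.kind, level=None,
                         n=int(m.sum()), median=med, q1=q1, q3=q3, count=None, pct=None)
                )
            else:
                vals = cohort.records[f.name][m]
                n_obs = int(m.sum())
                for lv in f.levels:
                    cnt = int((vals == lv).sum())
                    rows.append(
                        dict(feature=f.name, cluster=c, kind=f.kind, level=lv,
                             n=n_obs, median=None, q1=None, q3=None, count=cnt,
                             pct=100.0 * cnt / n_obs if n_obs else float("nan"))
                    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------

class GraphMixture(ClusterMixin, BaseEstimator):
    """Scikit-learn style estimator wrapping the graph-mixture EM fit.

    Parameters
    ----------
    n_components : number of clusters K.
    forest : DependencyForest, pair list, or None for a plain product model.
    n_restarts : EM runs from different seeds; the highest-likelihood fit
        is kept.
    tol, max_iter : EM convergence controls (relative log-likelihood
        change).
    random_state : master seed for the restarts.

    Attributes (after ``fit``)
    --------------------------
    model_ : the fitted :class:`MixtureModel`.
    weights_, means_, sds_, correlations_ : parameter arrays.
    responsibilities_ : (n, k) membership probabilities.
    labels_ : hard 1-based assignments of the training cohort.
    loglik_trace_, n_iter_, converged_ : fit diagnostics of the best run.
    """

    def __init__(
        self,
        n_components: int = 6,
        forest=None,
        n_restarts: int = 10,
        tol: float = 1e-6,
        max_iter: int = 500,
        random_state: int = 0,
    ):
        self.n_components = n_components
        self.forest = forest
        self.n_restarts = n_restarts
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    def _forest(self) -> DependencyForest:
        if self.forest is None:
            return DependencyForest()
        if isinstance(self.forest, DependencyForest):
            return self.forest
        return DependencyForest(tuple((a, b) for a, b in self.forest))

    def fit(self, X: CohortTable, y=None):
        if not isinstance(X, CohortTable):
            raise TypeError("GraphMixture expects a CohortTable")
        fit = best_of_restarts(
            X,
            self.n_components,
            self._forest(),
            n_restarts=self.n_restarts,
            seed=self.random_state,
            tol=self.tol,
            max_iter=self.max_iter,
        )
        self.fit_result_ = fit
        self.model_ = fit.model
        self.weights_ = fit.model.weights
        self.means_ = fit.model.means
        self.sds_ = fit.model.sds
        self.correlations_ = fit.model.rhos
        self.responsibilities_ = fit.responsibilities
        self.labels_ = hard_assign(fit.responsibilities)
        self.loglik_trace_ = fit.loglik_trace
        self.n_iter_ = fit.n_iter
        self.converged_ = fit.converged
        return self

    def predict_proba(self, X: CohortTable) -> np.ndarray:
        data = encode(X, self.model_.forest)
        R, _ = e_step(data, self.model_)
        return R

    def predict(self, X: CohortTable) -> np.ndarray:
        return hard_assign(self.predict_proba(X))

    def score(self, X: CohortTable, y=None) -> float:
        data = encode(X, self.model_.forest)
        _, ll = e_step(data, self.model_)
        return ll / data.n
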