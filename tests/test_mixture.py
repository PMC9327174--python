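"""Graph-mixture model: densities, EM steps, fitting, estimator API."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal, norm
from sklearn.base import clone
from sklearn.metrics import adjusted_rand_score
from sklearn.mixture import GaussianMixture

from endomix import (
    CohortTable,
    DependencyForest,
    FeatureSpec,
    GraphMixture,
    best_of_restarts,
    cluster_profile,
    component_log_density,
    e_step,
    encode,
    fit_em,
    hard_assign,
    m_step,
    record_log_likelihood,
)
from endomix.mixture import (
    MixtureModel,
    ModelData,
    ModelMeta,
    log_density_matrix,
    restart_seeds,
)
from endomix.schema import ValidationError


def gaussian_model(weights, means, sds, edges=(), rhos=None, names=None):
    """Hand-build an all-Gaussian mixture model."""
    means = np.asarray(means, dtype=float)
    k, p = means.shape
    names = names or [f"f{j}" for j in range(p)]
    forest = DependencyForest(tuple(edges))
    idx = {n: i for i, n in enumerate(names)}
    edge_idx = np.array([[idx[a], idx[b]] for a, b in forest], dtype=int).reshape(-1, 2)
    meta = ModelMeta(names, ["gaussian"] * p, [None] * p, tuple(forest.edges), edge_idx)
    rhos = np.zeros((k, len(forest))) if rhos is None else np.asarray(rhos, float)
    return MixtureModel(
        np.asarray(weights, float), means, np.asarray(sds, float), {}, rhos, forest, meta
    )


def random_model_and_data(rng, k=2, p=3, n=40, n_edges=1, missing=0.0):
    means = rng.normal(0, 3, size=(k, p))
    sds = rng.uniform(0.5, 2.0, size=(k, p))
    names = [f"f{j}" for j in range(p)]
    edges = [(names[2 * e], names[2 * e + 1]) for e in range(min(n_edges, p // 2))]
    rhos = rng.uniform(-0.7, 0.7, size=(k, len(edges)))
    w = rng.dirichlet(np.ones(k))
    model = gaussian_model(w, means, sds, edges, rhos, names)
    lab = rng.integers(0, k, size=n)
    X = means[lab] + sds[lab] * rng.normal(size=(n, p))
    M = rng.random((n, p)) >= missing
    X = np.where(M, X, np.nan)
    return model, ModelData(model.meta, X, M)


# ---------------------------------------------------------------------------
# component log-density
# ---------------------------------------------------------------------------

def test_all_missing_record_has_zero_log_density():
    model = gaussian_model([1.0], [[0.0, 1.0]], [[1.0, 2.0]], edges=[("f0", "f1")])
    assert component_log_density({"f0": None, "f1": float("nan")}, model.component(0)) == 0.0


def test_zero_rho_reduces_to_product_of_univariates():
    model = gaussian_model([1.0], [[0.0, 1.0]], [[1.0, 2.0]], edges=[("f0", "f1")])
    got = component_log_density({"f0": 0.3, "f1": -1.2}, model.component(0))
    want = norm.logpdf(0.3, 0, 1) + norm.logpdf(-1.2, 1, 2)
    assert got == pytest.approx(want, abs=1e-12)


def test_edge_factor_matches_explicit_bivariate_normal():
    rho = 0.6
    model = gaussian_model(
        [1.0], [[0.5, -1.0]], [[1.5, 0.7]], edges=[("f0", "f1")], rhos=[[rho]]
    )
    x = {"f0": 1.1, "f1": -0.4}
    cov = np.array([[1.5**2, rho * 1.5 * 0.7], [rho * 1.5 * 0.7, 0.7**2]])
    want = multivariate_normal.logpdf([1.1, -0.4], mean=[0.5, -1.0], cov=cov)
    got = component_log_density(x, model.component(0))
    assert got == pytest.approx(want, abs=1e-10)


def test_one_endpoint_missing_drops_edge_factor():
    model = gaussian_model(
        [1.0], [[0.0, 0.0]], [[1.0, 1.0]], edges=[("f0", "f1")], rhos=[[0.9]]
    )
    got = component_log_density({"f0": 0.7, "f1": None}, model.component(0))
    assert got == pytest.approx(norm.logpdf(0.7), abs=1e-12)


def test_scalar_and_vectorized_densities_agree():
    rng = np.random.default_rng(5)
    model, data = random_model_and_data(rng, k=3, p=4, n=30, n_edges=2, missing=0.3)
    L = log_density_matrix(data, model)
    for i in range(data.n):
        record = {
            name: (data.X[i, j] if data.M[i, j] else None)
            for j, name in enumerate(model.meta.names)
        }
        for c in range(model.k):
            assert L[i, c] == pytest.approx(
                component_log_density(record, model.component(c)), abs=1e-10
            )


# ---------------------------------------------------------------------------
# E-step / M-step
# ---------------------------------------------------------------------------

def test_e_step_single_component_and_all_missing_row():
    rng = np.random.default_rng(0)
    model, data = random_model_and_data(rng, k=1, p=2, n=10)
    R, _ = e_step(data, model)
    assert np.allclose(R, 1.0)
    model2, data2 = random_model_and_data(rng, k=3, p=2, n=5)
    data2.M[0, :] = False
    R2, _ = e_step(data2, model2)
    assert np.allclose(R2[0], model2.weights, atol=1e-12)


def test_e_step_midpoint_symmetry():
    model = gaussian_model([0.5, 0.5], [[0.0], [2.0]], [[1.0], [1.0]])
    data = ModelData(model.meta, np.array([[1.0]]), np.array([[True]]))
    R, _ = e_step(data, model)
    assert R[0] == pytest.approx([0.5, 0.5], abs=1e-12)


def test_m_step_k1_complete_data_is_mle():
    rng = np.random.default_rng(1)
    x = rng.normal(3.0, 2.0, size=(50, 1))
    meta = ModelMeta(["f0"], ["gaussian"], [None], (), np.zeros((0, 2), int))
    data = ModelData(meta, x, np.ones_like(x, dtype=bool))
    model = m_step(data, np.ones((50, 1)), DependencyForest())
    assert model.means[0, 0] == pytest.approx(x.mean())
    assert model.sds[0, 0] == pytest.approx(x.std())  # 1/n normalisation


def test_m_step_hard_responsibilities_equal_subset_statistics():
    rng = np.random.default_rng(2)
    model, data = random_model_and_data(rng, k=2, p=4, n=80, n_edges=2)
    lab = rng.integers(0, 2, size=80)
    R = np.zeros((80, 2))
    R[np.arange(80), lab] = 1.0
    fitted = m_step(data, R, model.forest)
    for c in range(2):
        sub = data.X[lab == c]
        assert np.allclose(fitted.means[c], sub.mean(axis=0))
        assert np.allclose(fitted.sds[c], sub.std(axis=0), atol=1e-10)
        for e, (i, j) in enumerate(model.meta.edge_idx):
            zi = (sub[:, i] - fitted.means[c, i]) / fitted.sds[c, i]
            zj = (sub[:, j] - fitted.means[c, j]) / fitted.sds[c, j]
            want = (zi * zj).sum() / np.sqrt((zi**2).sum() * (zj**2).sum())
            assert fitted.rhos[c, e] == pytest.approx(want, abs=1e-10)
    assert np.allclose(fitted.weights, np.bincount(lab) / 80)


def test_m_step_fully_missing_feature_held_with_warning():
    rng = np.random.default_rng(3)
    model, data = random_model_and_data(rng, k=2, p=3, n=20)
    data.M[:, 2] = False
    with pytest.warns(UserWarning, match="no observed values"):
        fitted = m_step(data, np.full((20, 2), 0.5), model.forest)
    pooled = fitted.means[:, 2]
    again = m_step(data, np.full((20, 2), 0.5), model.forest, prev=fitted)
    assert np.array_equal(again.means[:, 2], pooled)


def test_m_step_rejects_bad_responsibilities():
    rng = np.random.default_rng(4)
    model, data = random_model_and_data(rng, k=2, p=2, n=10)
    with pytest.raises(ValidationError, match="sum to 1"):
        m_step(data, np.full((10, 2), 0.7), model.forest)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def two_cluster_cohort(n=1000, seed=0, sep=4.0):
    rng = np.random.default_rng(seed)
    lab = rng.integers(0, 2, size=n)
    x = np.where(lab == 0, 0.0, sep) + rng.normal(size=n)
    y = np.where(lab == 0, 0.0, sep) + rng.normal(size=n)
    schema = [
        FeatureSpec("pid", "nominal", role="id"),
        FeatureSpec("a", "continuous"),
        FeatureSpec("b", "continuous"),
    ]
    rec = pd.DataFrame({"pid": [str(i) for i in range(n)], "a": x, "b": y})
    return CohortTable(schema, rec), lab


def test_fit_em_recovers_separated_clusters():
    cohort, lab = two_cluster_cohort()
    fit = fit_em(cohort, 2, seed=0)
    assert adjusted_rand_score(lab, fit.labels) >= 0.95
    assert fit.converged


def test_loglik_trace_nondecreasing_complete_data():
    rng = np.random.default_rng(7)
    for _ in range(10):
        model, data = random_model_and_data(
            rng, k=int(rng.integers(1, 4)), p=3, n=40, n_edges=1
        )
        fit = fit_em(data, model.k, model.forest, seed=int(rng.integers(1 << 16)), max_iter=60)
        t = np.array(fit.loglik_trace)
        assert (np.diff(t) >= -1e-8 * np.maximum(1.0, np.abs(t[:-1]))).all()


def test_matches_diagonal_gmm_from_same_initialization():
    cohort, _ = two_cluster_cohort(n=200, seed=5)
    fit = fit_em(cohort, 2, seed=3, tol=1e-12, max_iter=2000)
    data = encode(cohort, None)
    R0 = np.random.default_rng(3).dirichlet(np.ones(2), size=200)
    m0 = m_step(data, R0, DependencyForest())
    gm = GaussianMixture(
        2,
        covariance_type="diag",
        weights_init=m0.weights,
        means_init=m0.means,
        precisions_init=1 / m0.sds**2,
        reg_covar=0,
        tol=1e-12,
        max_iter=2000,
    ).fit(data.X)
    assert fit.loglik == pytest.approx(gm.score(data.X) * 200, abs=1e-6)


def test_marginalized_likelihood_equals_numerical_integration():
    rng = np.random.default_rng(11)
    model, data = random_model_and_data(rng, k=2, p=3, n=1, n_edges=1)
    # f1 sits on the single edge (degree 1); integrate it out numerically
    X = np.array([[0.5, np.nan, -0.3]])
    M = np.array([[True, False, True]])
    direct = e_step(ModelData(model.meta, X, M), model)[1]
    grid = np.linspace(-40, 40, 8001)
    Xg = np.tile(X, (len(grid), 1))
    Xg[:, 1] = grid
    Mg = np.ones_like(Xg, dtype=bool)
    L = log_density_matrix(ModelData(model.meta, Xg, Mg), model)
    from scipy.special import logsumexp

    mix = logsumexp(np.log(model.weights)[None, :] + L, axis=1)
    integral = np.trapezoid(np.exp(mix), grid)
    assert integral == pytest.approx(math.exp(direct), rel=1e-6)


def test_best_of_restarts_properties():
    cohort, _ = two_cluster_cohort(n=150, seed=9)
    single = best_of_restarts(cohort, 2, n_restarts=1, seed=4)
    direct = fit_em(cohort, 2, seed=restart_seeds(4, 1)[0])
    assert single.loglik == pytest.approx(direct.loglik)
    best = best_of_restarts(cohort, 2, n_restarts=5, seed=4)
    for s in restart_seeds(4, 5):
        assert best.loglik >= fit_em(cohort, 2, seed=s).loglik - 1e-9


def test_hard_assign_examples_and_partition():
    assert hard_assign(np.array([[0.1, 0.7, 0.2]]))[0] == 2
    assert hard_assign(np.array([[0.5, 0.5]]))[0] == 1  # tie to lowest index
    rng = np.random.default_rng(0)
    R = rng.dirichlet(np.ones(4), size=50)
    lab = hard_assign(R)
    assert lab.shape == (50,)
    assert set(lab) <= {1, 2, 3, 4}
    assert sum(np.bincount(lab)[1:]) == 50


def test_record_log_likelihood_matches_e_step():
    rng = np.random.default_rng(13)
    model, data = random_model_and_data(rng, k=3, p=3, n=6, missing=0.4)
    _, total = e_step(data, model)
    by_record = sum(
        record_log_likelihood(
            model,
            {
                name: (data.X[i, j] if data.M[i, j] else None)
                for j, name in enumerate(model.meta.names)
            },
        )
        for i in range(6)
    )
    assert total == pytest.approx(by_record, abs=1e-8)


# ---------------------------------------------------------------------------
# cluster profile
# ---------------------------------------------------------------------------

def test_cluster_profile_median_iqr(make, schema):
    cohort = make(
        schema,
        {
            "pid": list("abcdef"),
            "glucose": [1.0, 2, 3, 4, 5, 9],
            "lactate": [2.0] * 6,
            "gcs_total": [12] * 6,
            "sedated": ["no"] * 5 + ["yes"],
            "cause": ["road"] * 6,
            "gose": [5] * 6,
        },
    )
    labels = np.array([1, 1, 1, 1, 1, 2])
    prof = cluster_profile(cohort, labels)
    g1 = prof[(prof.feature == "glucose") & (prof.cluster == 1)].iloc[0]
    assert (g1["median"], g1.q1, g1.q3) == (3.0, 2.0, 4.0)
    g2 = prof[(prof.feature == "glucose") & (prof.cluster == 2)].iloc[0]
    assert g2["median"] == 9.0 and g2.q1 == g2.q3 == 9.0  # single member
    sed = prof[(prof.feature == "sedated") & (prof.cluster == 1) & (prof.level == "no")]
    assert sed.iloc[0]["pct"] == pytest.approx(100.0)


def test_cluster_profile_matches_sort_based_quantile_oracle(make, schema):
    rng = np.random.default_rng(17)
    n = 40
    vals = rng.normal(size=n)
    cohort = make(
        schema,
        {
            "pid": [str(i) for i in range(n)],
            "glucose": vals,
            "lactate": [2.0] * n,
            "gcs_total": [12] * n,
            "sedated": ["no"] * n,
            "cause": ["road"] * n,
            "gose": [5] * n,
        },
    )
    labels = np.ones(n, dtype=int)
    prof = cluster_profile(cohort, labels).set_index("feature")

    def type7(x, q):
        x = np.sort(x)
        h = (len(x) - 1) * q
        lo = int(np.floor(h))
        return x[lo] + (h - lo) * (x[min(lo + 1, len(x) - 1)] - x[lo])

    row = prof.loc["glucose"]
    assert row["median"] == pytest.approx(type7(vals, 0.5))
    assert row["q1"] == pytest.approx(type7(vals, 0.25))
    assert row["q3"] == pytest.approx(type7(vals, 0.75))


# ---------------------------------------------------------------------------
# estimator API
# ---------------------------------------------------------------------------

def test_graph_mixture_estimator_api():
    cohort, lab = two_cluster_cohort(n=300, seed=2)
    est = GraphMixture(n_components=2, n_restarts=2, random_state=0)
    assert clone(est).get_params()["n_components"] == 2
    est.set_params(max_iter=200)
    fitted = est.fit(cohort)
    assert fitted is est
    assert est.converged_ and est.weights_.shape == (2,)
    assert np.array_equal(est.predict(cohort), est.labels_)
    proba = est.predict_proba(cohort)
    assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-10)
    assert adjusted_rand_score(lab, est.labels_) >= 0.95
    assert est.score(cohort) == pytest.approx(est.loglik_trace_[-1] / 300)


def test_model_json_round_trip():
    cohort, _ = two_cluster_cohort(n=100, seed=8)
    fit = fit_em(cohort, 2, seed=1)
    back = MixtureModel.from_dict(fit.model.to_dict())
    data = encode(cohort, back.forest)
    _, ll_orig = e_step(data, fit.model)
    _, ll_back = e_step(data, back)
    assert ll_back == pytest.approx(ll_orig, abs=1e-10)
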