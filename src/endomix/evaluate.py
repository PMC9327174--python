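"""Cluster interpretation and outcome association.

Feature importance is the mutual information between the cluster label
and each feature under the fitted model,

    I(C; X) = sum_c pi_c * KL( p_c(x) || pbar(x) ),   pbar = sum_j pi_j p_j,

reported in nats (MI > 0.1 flags a feature as informative).  Outcome
association uses logistic regression on GOS-E-derived endpoints
(mortality = GOS-E 1, unfavourable = GOS-E < 5): Nagelkerke pseudo-R2,
and a likelihood-ratio test for adding k-1 cluster indicators to a base
(IMPACT-style) covariate model.  Missing covariates are completed by a
simple median/mode imputation, used by the regression stage only — the
clustering itself never imputes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2

from .mixture import MixtureModel
from .schema import CohortTable, ValidationError


class RankDeficiencyError(ValueError):
    pass


# ---------------------------------------------------------------------------
# mutual information
# ---------------------------------------------------------------------------

@dataclass
class FeatureMI:
    feature: str
    value: float  # in the requested units
    se: float  # Monte-Carlo standard error (0 for exact categorical sums)
    units: str = "nats"


def _cluster_shares(labels: np.ndarray, k: int) -> np.ndarray:
    labels = np.asarray(labels)
    counts = np.bincount(labels - 1, minlength=k).astype(float)
    return counts / counts.sum()


def feature_mi(
    model: MixtureModel,
    feature: str,
    labels: np.ndarray,
    cohort: CohortTable | None = None,
    n_draws: int = 50_000,
    seed: int = 0,
    units: str = "nats",
) -> FeatureMI:
    """Plug-in mutual information of one feature with the cluster label.

    Cluster shares come from the hard assignment; per-cluster feature
    distributions from the fitted model.  Categorical features are summed
    exactly over levels; Gaussian features use fixed-seed Monte Carlo
    (``n_draws`` split across components) with a reported standard error.
    """
    if feature not in model.meta.names:
        raise KeyError(feature)
    if cohort is not None and not cohort.mask[feature].any():
        warnings.warn(f"feature {feature!r} fully missing; MI undefined", UserWarning,
                      stacklevel=2)
        return FeatureMI(feature, float("nan"), float("nan"), units)
    j = model.meta.index(feature)
    pi = _cluster_shares(labels, model.k)
    scale = 1.0 if units == "nats" else 1.0 / math.log(2.0)
    if units not in ("nats", "bits"):
        raise ValidationError(f"unknown units {units!r}")

    if model.meta.kinds[j] == "categorical":
        P = model.cat_probs[j]  # (k, L)
        pbar = pi @ P
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = P * (np.log(P) - np.log(pbar)[None, :])
        mi = float((pi[:, None] * np.where(P > 0, terms, 0.0)).sum())
        return FeatureMI(feature, mi * scale, 0.0, units)

    mu = model.means[:, j]
    sd = model.sds[:, j]
    rng = np.random.default_rng(seed)
    m = max(1, n_draws // model.k)
    total, var = 0.0, 0.0
    for c in range(model.k):
        if pi[c] == 0:
            continue
        x = rng.normal(mu[c], sd[c], size=m)
        z = (x[:, None] - mu[None, :]) / sd[None, :]
        logp = -0.5 * z**2 - np.log(sd)[None, :] - 0.5 * math.log(2 * math.pi)
        log_pbar = _logsumexp_weighted(logp, pi)
        f = logp[:, c] - log_pbar
        total += pi[c] * f.mean()
        var += pi[c] ** 2 * f.var(ddof=1) / m
    return FeatureMI(feature, total * scale, math.sqrt(var) * scale, units)


def _logsumexp_weighted(logp: np.ndarray, pi: np.ndarray) -> np.ndarray:
    lw = np.full_like(pi, -np.inf)
    nz = pi > 0
    lw[nz] = np.log(pi[nz])
    a = logp + lw[None, :]
    amax = a.max(axis=1, keepdims=True)
    return (amax[:, 0]) + np.log(np.exp(a - amax).sum(axis=1))


def mi_report(
    model: MixtureModel,
    labels: np.ndarray,
    cohort: CohortTable | None = None,
    threshold: float = 0.1,
    n_draws: int = 50_000,
    seed: int = 0,
    units: str = "nats",
) -> pd.DataFrame:
    """MI of every model feature, sorted descending, with rank and the
    MI > threshold importance flag.  Small negative Monte-Carlo estimates
    are clipped to zero."""
    rows = []
    for name in model.meta.names:
        fm = feature_mi(model, name, labels, cohort, n_draws=n_draws, seed=seed, units=units)
        val = fm.value if math.isnan(fm.value) else max(0.0, fm.value)
        rows.append(dict(feature=name, mi=val, se=fm.se, units=units))
    df = pd.DataFrame(rows).sort_values("mi", ascending=False, kind="mergesort")
    df["rank"] = np.arange(1, len(df) + 1)
    df["important"] = df["mi"] > threshold
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# simple imputation (regression stage only)
# ---------------------------------------------------------------------------

def impute_simple(cohort: CohortTable) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Observed-median (numeric) / observed-mode (categorical) completion.

    Returns the completed table and a boolean flag table marking imputed
    cells.  The outcome and id columns are never imputed.  The clustering
    path never calls this; it exists for the regression stage only.
    """
    records = cohort.records.copy()
    flags = pd.DataFrame(False, index=records.index, columns=records.columns)
    for f in cohort.schema:
        if f.role in ("id", "outcome"):
            continue
        m = cohort.mask[f.name].to_numpy()
        if not m.any():
            raise ValidationError(f"feature {f.name!r} has zero observed values; cannot impute")
        if m.all():
            continue
        vals = records[f.name]
        if f.kind in ("continuous", "ordinal"):
            med = float(np.median(pd.to_numeric(vals[m]).to_numpy(dtype=float)))
            if f.kind == "ordinal":
                lv = np.asarray(f.levels, dtype=float)
                fill = f.levels[int(np.abs(lv - med).argmin())]
            else:
                fill = med
        else:
            counts = vals[m].value_counts()
            top = counts.max()
            # deterministic tie-break: first declared level among the modes
            fill = next(lv for lv in f.levels if counts.get(lv, 0) == top)
        col = vals.copy()
        col[~m] = fill
        records[f.name] = col
        flags.loc[~m, f.name] = True
    return records, flags


# ---------------------------------------------------------------------------
# logistic regression, pseudo-R2, likelihood-ratio test
# ---------------------------------------------------------------------------

@dataclass
class LogisticFit:
    params: pd.Series
    loglik: float
    n: int
    converged: bool


def _design(X, n: int) -> pd.DataFrame:
    if X is None:
        X = pd.DataFrame(index=range(n))
    elif not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X, dtype=float))
        X.columns = [f"x{i}" for i in range(X.shape[1])]
    d = X.astype(float).copy()
    d.insert(0, "intercept", 1.0)
    return d


def fit_logistic(y, X=None) -> LogisticFit:
    """Maximum-likelihood logistic regression (IRLS/Newton).

    ``X`` is a covariate table without an intercept column (one is added);
    ``X=None`` fits the intercept-only model.  Perfect separation produces
    a warning and capped coefficients; duplicated or collinear columns
    raise :class:`RankDeficiencyError`; constant ``y`` is an error.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValidationError("y must be a binary 0/1 vector")
    if len(np.unique(y)) < 2:
        raise ValidationError("y is constant; logistic fit undefined")
    d = _design(X, len(y))
    if np.isnan(d.to_numpy()).any():
        raise ValidationError("covariates contain missing values; impute first")
    if np.linalg.matrix_rank(d.to_numpy()) < d.shape[1]:
        raise RankDeficiencyError("covariate matrix is rank deficient (duplicated/collinear columns)")
    mod = sm.Logit(y, d)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = mod.fit(disp=0, maxiter=200)
            params = res.params
            converged = bool(res.mle_retvals.get("converged", True))
        except Exception:
            res = mod.fit(disp=0, method="bfgs", maxiter=500)
            params = res.params
            converged = False
    cap = 30.0
    if np.abs(params.to_numpy()).max() > cap:
        warnings.warn("possible perfect separation; coefficients capped", UserWarning,
                      stacklevel=2)
        params = params.clip(-cap, cap)
    ll = float(mod.loglike(params.to_numpy()))
    return LogisticFit(params=params, loglik=ll, n=len(y), converged=converged)


def nagelkerke_r2(ll_model: float, ll_null: float, n: int) -> float:
    """Nagelkerke pseudo-R2: Cox-Snell rescaled to [0, 1)."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    ll_model = max(ll_model, ll_null)  # nested models; guard tiny numerics
    r2_cs = 1.0 - math.exp(2.0 * (ll_null - ll_model) / n)
    denom = 1.0 - math.exp(2.0 * ll_null / n)
    return r2_cs / denom if denom > 0 else 0.0


@dataclass
class RegressionComparison:
    ll_base: float
    ll_extended: float
    r2_base: float
    r2_extended: float
    lr_stat: float
    df: int
    p_value: float


def lr_test_added_clusters(y, base_covariates, labels, k: int) -> RegressionComparison:
    """Does the cluster label add predictive value over base covariates?

    Fits the base logistic model and the base + (k-1) cluster-indicator
    model (reference = lowest cluster label); the likelihood-ratio
    statistic 2*(ll_ext - ll_base) is referred to chi-squared with one
    degree of freedom per indicator.  Nagelkerke R2 for both models is
    computed against the intercept-only null.
    """
    labels = np.asarray(labels)
    y = np.asarray(y, dtype=float)
    present = sorted(set(int(l) for l in labels))
    if len(present) < k:
        warnings.warn(
            f"only {len(present)} of {k} clusters present; df reduced to {len(present) - 1}",
            UserWarning,
            stacklevel=2,
        )
    dummies = pd.DataFrame(
        {f"cluster_{c}": (labels == c).astype(float) for c in present[1:]}
    )
    base = (
        base_covariates.reset_index(drop=True)
        if isinstance(base_covariates, pd.DataFrame)
        else _design(base_covariates, len(y)).drop(columns="intercept")
    )
    ext = pd.concat([base, dummies], axis=1)
    fit_base = fit_logistic(y, base if base.shape[1] else None)
    fit_ext = fit_logistic(y, ext)
    fit_null = fit_logistic(y, None)
    df = len(present) - 1
    lr = max(0.0, 2.0 * (fit_ext.loglik - fit_base.loglik))
    return RegressionComparison(
        ll_base=fit_base.loglik,
        ll_extended=fit_ext.loglik,
        r2_base=nagelkerke_r2(fit_base.loglik, fit_null.loglik, len(y)),
        r2_extended=nagelkerke_r2(fit_ext.loglik, fit_null.loglik, len(y)),
        lr_stat=lr,
        df=df,
        p_value=float(chi2.sf(lr, df)) if df > 0 else float("nan"),
    )


# ---------------------------------------------------------------------------
# observed vs predicted outcome per cluster
# ---------------------------------------------------------------------------

def outcome_comparison(
    labels,
    gose,
    predicted_mortality=None,
    predicted_unfavourable=None,
    digits: int | None = None,
) -> pd.DataFrame:
    """Per-cluster observed vs model-predicted outcome percentages.

    Observed mortality is the share with GOS-E = 1, observed unfavourable
    the share with GOS-E < 5; predicted percentages are cluster means of
    per-patient predicted probabilities x 100.  Differences are
    predicted - observed.  With ``digits`` set, the observed/predicted
    percentages are rounded half-up to that precision and the differences
    recomputed on the rounded scale, matching clinical-report formatting
    (difference = predicted - observed holds exactly on whichever scale is
    reported).
    """
    labels = np.asarray(labels)
    gose = np.asarray(gose, dtype=float)
    if labels.shape != gose.shape:
        raise ValidationError("labels and gose must have equal length")
    if ((gose < 1) | (gose > 8)).any():
        raise ValidationError("GOS-E values must be in 1..8")
    for p in (predicted_mortality, predicted_unfavourable):
        if p is not None:
            p = np.asarray(p, dtype=float)
            if ((p < 0) | (p > 1)).any():
                raise ValidationError("predicted probabilities must be in [0, 1]")
    rows = []
    for c in sorted(set(int(l) for l in labels)):
        in_c = labels == c
        n = int(in_c.sum())
        obs_mort = 100.0 * (gose[in_c] == 1).mean()
        obs_unfav = 100.0 * (gose[in_c] < 5).mean()
        row = dict(cluster=c, n=n, observed_mortality=obs_mort, observed_unfavourable=obs_unfav)
        if predicted_mortality is not None:
            pm = 100.0 * float(np.asarray(predicted_mortality, float)[in_c].mean())
            row["predicted_mortality"] = pm
            row["diff_mortality"] = pm - obs_mort
        if predicted_unfavourable is not None:
            pu = 100.0 * float(np.asarray(predicted_unfavourable, float)[in_c].mean())
            row["predicted_unfavourable"] = pu
            row["diff_unfavourable"] = pu - obs_unfav
        rows.append(row)
    df = pd.DataFrame(rows)
    if digits is not None:
        def _half_up(x):
            scale = 10.0**digits
            return np.floor(np.asarray(x, dtype=float) * scale + 0.5) / scale

        for col in df.columns:
            if col.startswith(("observed", "predicted")):
                df[col] = _half_up(df[col])
        if "diff_mortality" in df:
            df["diff_mortality"] = df["predicted_mortality"] - df["observed_mortality"]
        if "diff_unfavourable" in df:
            df["diff_unfavourable"] = df["predicted_unfavourable"] - df["observed_unfavourable"]
    return df
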