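"""Cluster-count selection by repeated-fit stability.

For every candidate K the best-of-restarts fit is repeated several times
with fresh seeds; agreement between repetitions is measured by the
cluster similarity index (CSI): the fraction of patients assigned to the
same cluster by two fits, after a one-to-one matching of cluster labels
between the fits.  Because CSI drifts upward for small K, the median CSI
is penalised by 1/K, and the K with the highest penalised median is
selected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.base import BaseEstimator

from .mixture import FitResult, best_of_restarts, encode, hard_assign
from .schema import CohortTable, ValidationError
from .screen import DependencyForest


def _contingency(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    ua, ia = np.unique(a, return_inverse=True)
    ub, ib = np.unique(b, return_inverse=True)
    table = np.zeros((len(ua), len(ub)), dtype=np.int64)
    np.add.at(table, (ia, ib), 1)
    return table, ua, ub


def csi(labels_a: Sequence, labels_b: Sequence, matching: str = "optimal") -> float:
    """Cluster similarity index between two labelings, in [0, 1].

    The k x k contingency table is matched one-to-one between the two
    labelings — optimally (Hungarian assignment, default) or greedily —
    and the matched agreement divided by n is returned.  Symmetric in its
    arguments; 1 iff the labelings are identical up to relabeling.
    Clusters left unmatched (unequal effective cluster counts) contribute
    zero agreement.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("labelings must be equal-length 1-d arrays")
    n = len(a)
    if n == 0:
        raise ValidationError("empty labelings")
    table, _, _ = _contingency(a, b)
    if matching == "optimal":
        rows, cols = linear_sum_assignment(table, maximize=True)
        agree = int(table[rows, cols].sum())
    elif matching == "greedy":
        t = table.astype(float).copy()
        agree = 0
        for _ in range(min(t.shape)):
            r, c = np.unravel_index(np.argmax(t), t.shape)
            if t[r, c] <= 0:
                break
            agree += int(t[r, c])
            t[r, :] = -1
            t[:, c] = -1
    else:
        raise ValidationError(f"unknown matching {matching!r}")
    return agree / n


def match_permutation(ref: np.ndarray, lab: np.ndarray) -> dict:
    """Mapping from ``lab``'s label values to ``ref``'s, maximizing
    agreement (same matching as :func:`csi`); unmatched labels keep fresh
    ids beyond ref's range."""
    table, ur, ul = _contingency(ref, lab)
    rows, cols = linear_sum_assignment(table, maximize=True)
    mapping = {ul[c]: ur[r] for r, c in zip(rows, cols)}
    nxt = int(max(ur)) + 1
    for v in ul:
        if v not in mapping:
            mapping[v] = nxt
            nxt += 1
    return mapping


@dataclass
class KStability:
    k: int
    labels: list[np.ndarray]
    logliks: list[float]
    csis: np.ndarray
    median: float
    q1: float
    q3: float
    min: float
    max: float
    penalized_median: float
    representative: FitResult | None = None


@dataclass
class StabilityCurve:
    per_k: dict[int, KStability]

    @property
    def selected_k(self) -> int:
        return select_k(self)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            dict(
                k=s.k,
                median_csi=s.median,
                q1_csi=s.q1,
                q3_csi=s.q3,
                min_csi=s.min,
                max_csi=s.max,
                penalized_median=s.penalized_median,
            )
            for s in self.per_k.values()
        ]
        return pd.DataFrame(rows).sort_values("k").reset_index(drop=True)


def repetition_seed(master_seed: int, k: int, repetition: int) -> int:
    """Deterministic seed stream for repetition j of candidate k."""
    ss = np.random.SeedSequence([int(master_seed), int(k), int(repetition)])
    return int(ss.generate_state(1)[0] % (2**31))


def stability_protocol(
    cohort,
    forest: DependencyForest | None = None,
    k_range: Iterable[int] = range(3, 16),
    n_repetitions: int = 20,
    n_restarts: int = 10,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> StabilityCurve:
    """Run the full stability protocol over candidate cluster counts.

    For each k: ``n_repetitions`` independent best-of-restarts fits, all
    pairwise CSIs between their hard assignments, and the summary
    statistics (median/IQR/min/max, penalised median = median - 1/k).  The
    repetition with the highest log-likelihood is kept as the
    representative fit for each k.
    """
    if n_repetitions < 2:
        raise ValidationError("n_repetitions must be >= 2")
    forest = forest or DependencyForest()
    data = encode(cohort, forest) if isinstance(cohort, CohortTable) else cohort
    per_k: dict[int, KStability] = {}
    for k in k_range:
        labels, logliks, fits = [], [], []
        for j in range(n_repetitions):
            try:
                fit = best_of_restarts(
                    data, k, forest,
                    n_restarts=n_restarts,
                    seed=repetition_seed(seed, k, j),
                    tol=tol, max_iter=max_iter,
                )
            except RuntimeError as exc:
                warnings.warn(f"repetition {j} for k={k} failed: {exc}", UserWarning, stacklevel=2)
                continue
            labels.append(hard_assign(fit.responsibilities))
            logliks.append(fit.loglik)
            fits.append(fit)
        if len(labels) < 2:
            warnings.warn(f"k={k} dropped: fewer than 2 successful repetitions", UserWarning,
                          stacklevel=2)
            continue
        csis = np.array([csi(a, b) for a, b in combinations(labels, 2)])
        med = float(np.median(csis))
        q1, q3 = (float(q) for q in np.percentile(csis, [25, 75]))
        rep = fits[int(np.argmax(logliks))]
        per_k[k] = KStability(
            k=k, labels=labels, logliks=logliks, csis=csis,
            median=med, q1=q1, q3=q3,
            min=float(csis.min()), max=float(csis.max()),
            penalized_median=med - 1.0 / k,
            representative=rep,
        )
    if not per_k:
        raise RuntimeError("stability protocol failed for every candidate k")
    return StabilityCurve(per_k)


def select_k(curve: StabilityCurve) -> int:
    """The k with the highest penalised median CSI; ties to the smallest k."""
    if not curve.per_k:
        raise ValidationError("empty stability curve")
    best_k, best_v = None, -np.inf
    for k in sorted(curve.per_k):
        v = curve.per_k[k].penalized_median
        if v > best_v:
            best_k, best_v = k, v
    return best_k


def assignment_map(curve: StabilityCurve, k: int) -> pd.DataFrame:
    """Patient x model table of aligned labels for stability visualisation.

    Models are ordered by descending log-likelihood; each model's labels
    are permuted to best match the first (highest-likelihood) model using
    the same one-to-one matching as CSI.
    """
    if k not in curve.per_k:
        raise ValidationError(f"k={k} not in stability curve")
    s = curve.per_k[k]
    order = np.argsort(s.logliks)[::-1]
    ref = s.labels[order[0]]
    cols = {}
    for rank, idx in enumerate(order, start=1):
        lab = s.labels[idx]
        mapping = match_permutation(ref, lab)
        cols[f"model_{rank}"] = np.array([mapping[v] for v in lab])
    return pd.DataFrame(cols)


class StabilitySelector(BaseEstimator):
    """Estimator running the stability protocol and fitting the selected K.

    After ``fit``: ``curve_`` (the full StabilityCurve), ``selected_k_``,
    ``model_`` (representative fit at the selected K, i.e. the repetition
    with the highest log-likelihood), and ``labels_``.
    """

    def __init__(
        self,
        k_min: int = 3,
        k_max: int = 15,
        forest=None,
        n_repetitions: int = 20,
        n_restarts: int = 10,
        tol: float = 1e-6,
        max_iter: int = 500,
        random_state: int = 0,
    ):
        self.k_min = k_min
        self.k_max = k_max
        self.forest = forest
        self.n_repetitions = n_repetitions
        self.n_restarts = n_restarts
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X: CohortTable, y=None):
        forest = self.forest
        if forest is not None and not isinstance(forest, DependencyForest):
            forest = DependencyForest(tuple((a, b) for a, b in forest))
        self.curve_ = stability_protocol(
            X,
            forest,
            k_range=range(self.k_min, self.k_max + 1),
            n_repetitions=self.n_repetitions,
            n_restarts=self.n_restarts,
            seed=self.random_state,
            tol=self.tol,
            max_iter=self.max_iter,
        )
        self.selected_k_ = select_k(self.curve_)
        self.model_ = self.curve_.per_k[self.selected_k_].representative
        self.labels_ = hard_assign(self.model_.responsibilities)
        return self
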