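"""Correlation screening and the dependency forest.

Pairs of strongly linearly correlated admission features (classically
pH with base excess, pH with PaCO2, GCS motor with total score, ...)
are modelled jointly in the mixture via bivariate-Gaussian compensating
factors.  This module computes the pairwise-complete Pearson matrix and
builds the set of jointly-modelled pairs, constrained to a forest so the
product-with-ratio density stays properly normalised.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .schema import CohortTable, ValidationError

#: the eight hand-picked strongly correlated admission-feature pairs used in
#: the CENTER-TBI endotype analysis, as a ready-made override for cohorts
#: following the full 35-feature schema
CENTER_TBI_PAIRS = (
    ("ph", "base_excess"),
    ("ph", "paco2"),
    ("gcs_motor", "gcs_total"),
    ("rotterdam", "midline_shift"),
    ("rotterdam", "fisher"),
    ("gcs_motor", "pupil_reactivity"),
    ("age", "asa_ps"),
    ("age", "anticoagulants"),
)


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b) -> bool:
        """Merge the sets of a and b; return False if already joined (cycle)."""
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[ra] = rb
        return True


def edges_form_forest(edges: Sequence[tuple[str, str]]) -> bool:
    nodes = {n for e in edges for n in e}
    uf = _UnionFind(nodes)
    return all(a != b and uf.union(a, b) for a, b in edges)


@dataclass(frozen=True)
class DependencyForest:
    """An acyclic set of unordered feature pairs modelled jointly.

    A feature may appear in several edges (pH sits on two), but no cycle is
    allowed: on a forest, tying each bivariate Gaussian's marginals to the
    univariate factors makes the product-with-ratio density integrate to 1.
    """

    edges: tuple[tuple[str, str], ...] = ()

    def __post_init__(self):
        canon = []
        seen = set()
        for a, b in self.edges:
            if a == b:
                raise ValidationError(f"self-edge {a!r}-{b!r} not allowed")
            key = frozenset((a, b))
            if key in seen:
                raise ValidationError(f"repeated edge {a!r}-{b!r}")
            seen.add(key)
            canon.append((a, b))
        if not edges_form_forest(canon):
            raise ValidationError("edge set contains a cycle; must be a forest")
        object.__setattr__(self, "edges", tuple(canon))

    def __len__(self):
        return len(self.edges)

    def __iter__(self):
        return iter(self.edges)

    @property
    def nodes(self) -> set[str]:
        return {n for e in self.edges for n in e}

    def degree(self, name: str) -> int:
        return sum(name in e for e in self.edges)

    def validate_against(self, cohort: CohortTable) -> None:
        for a, b in self.edges:
            for name in (a, b):
                try:
                    spec = cohort.feature(name)
                except KeyError:
                    raise ValidationError(f"forest references unknown feature {name!r}") from None
                if not spec.is_numeric:
                    raise ValidationError(
                        f"forest endpoint {name!r} has kind {spec.kind!r}; "
                        "only numeric-codable features may sit on an edge"
                    )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.edges, columns=["feature_a", "feature_b"])


def numeric_coded(cohort: CohortTable, name: str) -> np.ndarray:
    """One feature as a float vector (NaN where missing).

    Continuous/ordinal features keep their values; binary features are
    coded as the index of their level (0/1).
    """
    spec = cohort.feature(name)
    m = cohort.mask[name].to_numpy()
    out = np.full(cohort.n_patients, np.nan)
    vals = cohort.records[name]
    if spec.kind == "continuous":
        out[m] = pd.to_numeric(vals[m]).to_numpy(dtype=float)
    elif spec.kind in ("ordinal", "binary"):
        if spec.kind == "binary":
            lut = {lv: i for i, lv in enumerate(spec.levels)}
            out[m] = [lut[v] for v in vals[m]]
        else:
            out[m] = [float(v) for v in vals[m]]
    else:
        raise ValidationError(f"feature {name!r} of kind {spec.kind!r} is not numeric-codable")
    return out


def pearson_matrix(
    cohort: CohortTable,
    min_pairs: int = 10,
    include: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations between numeric-codable features.

    Each entry uses only patients observing both features; entries with
    fewer than ``min_pairs`` complete pairs, or with zero variance on the
    complete pairs, are left NaN (undefined) with a warning.
    """
    if include is None:
        include = [
            f.name for f in cohort.schema if f.role == "cluster_input" and f.is_numeric
        ]
    if len(include) < 2:
        raise ValidationError("need at least 2 numeric-codable features")
    cols = {n: numeric_coded(cohort, n) for n in include}
    p = len(include)
    corr = np.eye(p)
    for i in range(p):
        for j in range(i + 1, p):
            x, y = cols[include[i]], cols[include[j]]
            both = ~np.isnan(x) & ~np.isnan(y)
            r = np.nan
            if both.sum() < min_pairs:
                warnings.warn(
                    f"fewer than {min_pairs} complete pairs for "
                    f"{include[i]!r}-{include[j]!r}; correlation undefined",
                    UserWarning,
                    stacklevel=2,
                )
            else:
                xv, yv = x[both], y[both]
                if np.std(xv) == 0 or np.std(yv) == 0:
                    warnings.warn(
                        f"zero variance on complete pairs for "
                        f"{include[i]!r}-{include[j]!r}; correlation undefined",
                        UserWarning,
                        stacklevel=2,
                    )
                else:
                    r = float(np.corrcoef(xv, yv)[0, 1])
            corr[i, j] = corr[j, i] = r
    return pd.DataFrame(corr, index=include, columns=include)


def build_dependency_forest(
    corr: pd.DataFrame,
    threshold: float = 0.4,
    override: Sequence[tuple[str, str]] | None = None,
) -> DependencyForest:
    """Choose the jointly-modelled pairs from a correlation matrix.

    With an explicit ``override`` pair list (e.g. the hand-picked
    CENTER-TBI pairs) the list is validated as a forest and returned.
    Otherwise a maximum-|r| spanning forest over the suprathreshold edges
    is built greedily (Kruskal): edges in descending |r|, skipping any that
    would close a cycle.
    """
    if override is not None:
        return DependencyForest(tuple((a, b) for a, b in override))
    if not (0 < threshold < 1):
        raise ValidationError(f"threshold must be in (0,1), got {threshold}")
    names = list(corr.columns)
    cand = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            r = corr.iloc[i, j]
            if np.isfinite(r) and abs(r) >= threshold:
                cand.append((abs(r), names[i], names[j]))
    cand.sort(key=lambda t: (-t[0], t[1], t[2]))
    uf = _UnionFind(names)
    edges = [(a, b) for _, a, b in cand if uf.union(a, b)]
    return DependencyForest(tuple(edges))
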