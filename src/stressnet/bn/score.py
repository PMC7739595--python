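"""Decomposable BIC scoring for discrete and hybrid (CLG) networks.

The network score is the sum over nodes of *family scores*; the family
score of node ``X`` with parents ``Pa`` is the maximised log-likelihood
of ``X | Pa`` minus ``d/2 * ln(N)``, where ``d`` counts the free
parameters of the local distribution.  Higher is better.  Family scores
are cached per (child, parent set) so local search moves only pay for
the families they touch.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd

from stressnet.bn.dag import Dag

_VAR_FLOOR = 1e-12


def parameter_space_size(n_variables: int, n_levels: int) -> int:
    """Size of the parameter combination space, ``v ** l``.

    Counts parameter combinations for a discretised network of
    ``n_variables`` variables with ``n_levels`` levels each under the
    variables-to-the-power-of-levels convention (10 binary variables
    give 100 combinations, 10 three-level variables give 1,000).
    """
    if n_variables < 0 or n_levels < 0:
        raise ValueError("counts must be non-negative")
    return int(n_variables) ** int(n_levels)


class DiscreteScorer:
    """BIC family scores on a fully discrete table."""

    def __init__(self, data: pd.DataFrame):
        if len(data) == 0:
            raise ValueError("empty data")
        if data.isna().any().any():
            raise ValueError("data contains missing values")
        self.n = len(data)
        self.columns: tuple[str, ...] = tuple(data.columns)
        self.codes: dict[str, np.ndarray] = {}
        self.card: dict[str, int] = {}
        self.levels: dict[str, list] = {}
        for col in data.columns:
            cat = pd.Categorical(data[col])
            self.codes[col] = np.asarray(cat.codes, dtype=np.int64)
            self.card[col] = len(cat.categories)
            self.levels[col] = list(cat.categories)
            if self.card[col] < 1:
                raise ValueError(f"column {col!r} has no observed states")
        self._log_n = math.log(self.n)
        self._cache: dict[tuple, float] = {}

    def family_score(self, child: str, parents: tuple[str, ...]) -> float:
        parents = tuple(sorted(parents))
        key = (child, parents)
        cached = self._cache.get(key)
        if cached is not None:
            return cached
        k = self.card[child]
        ncfg = 1
        idx = np.zeros(self.n, dtype=np.int64)
        for p in parents:
            idx = idx * self.card[p] + self.codes[p]
            ncfg *= self.card[p]
        joint = idx * k + self.codes[child]
        counts = np.bincount(joint, minlength=ncfg * k).reshape(ncfg, k)
        totals = counts.sum(axis=1)
        logt = np.zeros(ncfg, dtype=np.float64)
        np.log(totals, out=logt, where=totals > 0)
        rows, cols = np.nonzero(counts)
        c = counts[rows, cols].astype(np.float64)
        ll = float((c * (np.log(c) - logt[rows])).sum())
        d = (k - 1) * ncfg
        score = ll - 0.5 * d * self._log_n
        self._cache[key] = score
        return score

    def score(self, dag: Dag) -> float:
        return sum(self.family_score(v, tuple(dag.parents(v))) for v in self.columns)


class HybridScorer:
    """BIC family scores on a mixed table (CLG model class).

    Float columns are continuous nodes with, per configuration of their
    discrete parents, a linear-Gaussian model in their continuous
    parents; all other columns are discrete.  Discrete children with
    continuous parents score ``-inf`` (outside the model class).
    """

    def __init__(self, data: pd.DataFrame):
        if len(data) == 0:
            raise ValueError("empty data")
        if data.isna().any().any():
            raise ValueError("data contains missing values")
        self.n = len(data)
        self.columns: tuple[str, ...] = tuple(data.columns)
        self.continuous: tuple[str, ...] = tuple(c for c in data.columns if pd.api.types.is_float_dtype(data[c]))
        self.discrete: tuple[str, ...] = tuple(c for c in data.columns if c not in self.continuous)
        self.values: dict[str, np.ndarray] = {
            c: np.asarray(data[c], dtype=np.float64) for c in self.continuous
        }
        self.codes: dict[str, np.ndarray] = {}
        self.card: dict[str, int] = {}
        self.levels: dict[str, list] = {}
        for col in self.discrete:
            cat = pd.Categorical(data[col])
            self.codes[col] = np.asarray(cat.codes, dtype=np.int64)
            self.card[col] = len(cat.categories)
            self.levels[col] = list(cat.categories)
        self._log_n = math.log(self.n)
        self._cache: dict[tuple, float] = {}

    def _config_index(self, disc_parents: Sequence[str]) -> tuple[np.ndarray, int]:
        idx = np.zeros(self.n, dtype=np.int64)
        ncfg = 1
        for p in disc_parents:
            idx = idx * self.card[p] + self.codes[p]
            ncfg *= self.card[p]
        return idx, ncfg

    def family_score(self, child: str, parents: tuple[str, ...]) -> float:
        parents = tuple(sorted(parents))
        key = (child, parents)
        cached = self._cache.get(key)
        if cached is not None:
            return cached
        if child in self.codes:
            score = self._discrete_family(child, parents)
        else:
            score = self._gaussian_family(child, parents)
        self._cache[key] = score
        return score

    def _discrete_family(self, child: str, parents: tuple[str, ...]) -> float:
        if any(p in self.values for p in parents):
            return -math.inf  # continuous parent of a discrete node: outside CLG
        k = self.card[child]
        idx, ncfg = self._config_index(parents)
        joint = idx * k + self.codes[child]
        counts = np.bincount(joint, minlength=ncfg * k).reshape(ncfg, k)
        totals = counts.sum(axis=1)
        logt = np.zeros(ncfg, dtype=np.float64)
        np.log(totals, out=logt, where=totals > 0)
        rows, cols = np.nonzero(counts)
        c = counts[rows, cols].astype(np.float64)
        ll = float((c * (np.log(c) - logt[rows])).sum())
        d = (k - 1) * ncfg
        return ll - 0.5 * d * self._log_n

    def _gaussian_family(self, child: str, parents: tuple[str, ...]) -> float:
        disc = [p for p in parents if p in self.codes]
        cont = [p for p in parents if p in self.values]
        y = self.values[child]
        idx, ncfg = self._config_index(disc)
        p = len(cont)
        ll = 0.0
        if ncfg == 1:
            ll = self._group_loglik(y, cont, slice(None))
        else:
            order = np.argsort(idx, kind="stable")
            sorted_idx = idx[order]
            boundaries = np.flatnonzero(np.diff(sorted_idx)) + 1
            for grp in np.split(order, boundaries):
                ll += self._group_loglik(y, cont, grp)
        d = (p + 2) * ncfg
        return ll - 0.5 * d * self._log_n

    def _group_loglik(self, y: np.ndarray, cont: Sequence[str], rows) -> float:
        yg = y[rows]
        ng = yg.size
        if ng == 0:
            return 0.0
        if cont and ng > len(cont) + 1:
            X = np.column_stack([np.ones(ng)] + [self.values[c][rows] for c in cont])
            beta, *_ = np.linalg.lstsq(X, yg, rcond=None)
            resid = yg - X @ beta
            sigma2 = float(resid @ resid) / ng
        else:
            mu = yg.mean()
            sigma2 = float(((yg - mu) ** 2).mean())
        sigma2 = max(sigma2, _VAR_FLOOR)
        return -0.5 * ng * (math.log(2.0 * math.pi * sigma2) + 1.0)

    def score(self, dag: Dag) -> float:
        return sum(self.family_score(v, tuple(dag.parents(v))) for v in self.columns)


def make_scorer(data: pd.DataFrame):
    """Pick the scorer matching the table's dtypes."""
    if any(pd.api.types.is_float_dtype(data[c]) for c in data.columns):
        return HybridScorer(data)
    return DiscreteScorer(data)


def bic_score(dag: Dag, data: pd.DataFrame) -> float:
    """Network BIC: log-likelihood minus ``d/2 * ln(N)``; higher is better."""
    scorer = make_scorer(data)
    missing = set(scorer.columns) ^ set(dag.nodes)
    if missing:
        raise ValueError(f"dag nodes and data columns differ: {sorted(missing)}")
    return scorer.score(dag)
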