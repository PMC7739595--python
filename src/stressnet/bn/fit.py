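"""Parameter estimation for learned structures.

Discrete nodes get conditional probability tables with optional Laplace
smoothing; continuous nodes (float columns) get, per configuration of
their discrete parents, an intercept, linear coefficients on their
continuous parents and a residual standard deviation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from stressnet.bn.dag import Dag

_SD_FLOOR = 1e-9


@dataclass
class CPT:
    """Conditional probability table of one discrete node.

    ``table`` has one row per configuration of ``parents`` (row-major
    in the listed parent order) and one column per child state.
    """

    parents: tuple[str, ...]
    parent_cards: tuple[int, ...]
    states: tuple[str, ...]
    table: np.ndarray

    def row_index(self, parent_codes: np.ndarray) -> np.ndarray:
        """Mixed-radix row index; ``parent_codes`` is (n_parents, n_samples)."""
        idx = np.zeros(parent_codes.shape[1], dtype=np.int64)
        for k, card in enumerate(self.parent_cards):
            idx = idx * card + parent_codes[k]
        return idx


@dataclass
class LinearGaussian:
    """CLG local model of one continuous node.

    Per discrete-parent configuration: ``coef[cfg] = (intercept,
    slopes...)`` over ``cont_parents`` and residual sd ``sd[cfg]``.
    """

    disc_parents: tuple[str, ...]
    disc_cards: tuple[int, ...]
    cont_parents: tuple[str, ...]
    coef: np.ndarray   # (ncfg, 1 + n_cont)
    sd: np.ndarray     # (ncfg,)


@dataclass
class DiscreteBayesNet:
    dag: Dag
    states: dict[str, tuple[str, ...]]
    cpts: dict[str, CPT]
    n_fitted: int = 0

    @property
    def nodes(self) -> tuple[str, ...]:
        return self.dag.nodes

    def validate(self) -> None:
        for node, cpt in self.cpts.items():
            sums = cpt.table.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValueError(f"CPT rows of {node!r} do not sum to 1")

    def to_json(self) -> str:
        payload = {
            "type": "discrete",
            "nodes": {
                node: {
                    "states": list(self.states[node]),
                    "parents": list(cpt.parents),
                    "table": cpt.table.tolist(),
                }
                for node, cpt in self.cpts.items()
            },
            "arcs": sorted([u, v] for u, v in self.dag.arcs),
            "n_fitted": self.n_fitted,
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "DiscreteBayesNet":
        payload = json.loads(text)
        dag = Dag(payload["nodes"].keys(), [tuple(a) for a in payload["arcs"]])
        states = {n: tuple(spec["states"]) for n, spec in payload["nodes"].items()}
        cpts = {}
        for n, spec in payload["nodes"].items():
            parents = tuple(spec["parents"])
            cpts[n] = CPT(
                parents=parents,
                parent_cards=tuple(len(states[p]) for p in parents),
                states=states[n],
                table=np.asarray(spec["table"], dtype=float),
            )
        return cls(dag=dag, states=states, cpts=cpts, n_fitted=payload.get("n_fitted", 0))


@dataclass
class HybridBayesNet:
    """CLG network: discrete nodes with CPTs, continuous with linear-Gaussians."""

    dag: Dag
    states: dict[str, tuple[str, ...]]          # discrete nodes only
    cpts: dict[str, CPT]
    gaussians: dict[str, LinearGaussian] = field(default_factory=dict)
    n_fitted: int = 0

    @property
    def nodes(self) -> tuple[str, ...]:
        return self.dag.nodes

    @property
    def discrete_nodes(self) -> tuple[str, ...]:
        return tuple(self.cpts)

    @property
    def continuous_nodes(self) -> tuple[str, ...]:
        return tuple(self.gaussians)

    def validate(self) -> None:
        for node, cpt in self.cpts.items():
            if not np.allclose(cpt.table.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(f"CPT rows of {node!r} do not sum to 1")
            if any(p in self.gaussians for p in cpt.parents):
                raise ValueError(f"discrete node {node!r} has a continuous parent")
        for node, lg in self.gaussians.items():
            if np.any(lg.sd <= 0):
                raise ValueError(f"non-positive residual sd at {node!r}")


def _fit_cpt(
    child: str,
    parents: tuple[str, ...],
    codes: dict[str, np.ndarray],
    cards: dict[str, int],
    levels: dict[str, tuple[str, ...]],
    smoothing: float,
) -> CPT:
    k = cards[child]
    ncfg = 1
    idx = np.zeros(next(iter(codes.values())).shape[0], dtype=np.int64)
    for p in parents:
        idx = idx * cards[p] + codes[p]
        ncfg *= cards[p]
    joint = idx * k + codes[child]
    counts = np.bincount(joint, minlength=ncfg * k).reshape(ncfg, k).astype(float)
    counts += smoothing
    totals = counts.sum(axis=1, keepdims=True)
    if np.any(totals == 0):
        bad = int(np.flatnonzero(totals.ravel() == 0)[0])
        raise ValueError(
            f"unobserved parent configuration {bad} for node {child!r} with smoothing=0"
        )
    table = counts / totals
    return CPT(
        parents=parents,
        parent_cards=tuple(cards[p] for p in parents),
        states=levels[child],
        table=table,
    )


def _fit_gaussian(
    child: str,
    parents: tuple[str, ...],
    data: pd.DataFrame,
    codes: dict[str, np.ndarray],
    cards: dict[str, int],
    continuous: set[str],
) -> LinearGaussian:
    disc = tuple(p for p in parents if p not in continuous)
    cont = tuple(p for p in parents if p in continuous)
    y = np.asarray(data[child], dtype=float)
    n = y.size
    idx = np.zeros(n, dtype=np.int64)
    ncfg = 1
    for p in disc:
        idx = idx * cards[p] + codes[p]
        ncfg *= cards[p]
    coef = np.zeros((ncfg, 1 + len(cont)))
    sd = np.full(ncfg, np.nan)
    Xall = (
        np.column_stack([np.ones(n)] + [np.asarray(data[c], dtype=float) for c in cont])
        if cont
        else np.ones((n, 1))
    )
    for cfg in range(ncfg):
        rows = np.flatnonzero(idx == cfg) if ncfg > 1 else np.arange(n)
        if rows.size == 0:
            # Fall back to the pooled fit for unobserved configurations.
            rows = np.arange(n)
        X, yg = Xall[rows], y[rows]
        beta, *_ = np.linalg.lstsq(X, yg, rcond=None)
        resid = yg - X @ beta
        dof = max(rows.size - X.shape[1], 1)
        coef[cfg] = beta
        sd[cfg] = max(float(np.sqrt(resid @ resid / dof)), _SD_FLOOR)
    return LinearGaussian(
        disc_parents=disc,
        disc_cards=tuple(cards[p] for p in disc),
        cont_parents=cont,
        coef=coef,
        sd=sd,
    )


def fit_parameters(
    dag: Dag,
    data: pd.DataFrame,
    smoothing: float = 1.0,
) -> DiscreteBayesNet | HybridBayesNet:
    """Fit local distributions of ``dag`` from ``data``.

    Float columns become linear-Gaussian nodes; all other columns
    become discrete nodes with Laplace-smoothed CPTs (``smoothing=0``
    gives the raw MLE and raises on unobserved parent configurations).
    """
    if set(dag.nodes) - set(data.columns):
        raise ValueError("data does not cover all dag nodes")
    if smoothing < 0:
        raise ValueError("smoothing must be >= 0")
    continuous = {c for c in dag.nodes if pd.api.types.is_float_dtype(data[c])}
    codes: dict[str, np.ndarray] = {}
    cards: dict[str, int] = {}
    levels: dict[str, tuple[str, ...]] = {}
    for col in dag.nodes:
        if col in continuous:
            continue
        cat = pd.Categorical(data[col])
        codes[col] = np.asarray(cat.codes, dtype=np.int64)
        cards[col] = len(cat.categories)
        levels[col] = tuple(str(s) for s in cat.categories)

    cpts: dict[str, CPT] = {}
    gaussians: dict[str, LinearGaussian] = {}
    for node in dag.nodes:
        parents = tuple(sorted(dag.parents(node)))
        if node in continuous:
            gaussians[node] = _fit_gaussian(node, parents, data, codes, cards, continuous)
        else:
            if any(p in continuous for p in parents):
                raise ValueError(f"discrete node {node!r} has a continuous parent")
            cpts[node] = _fit_cpt(node, parents, codes, cards, levels, smoothing)

    states = {n: levels[n] for n in cpts}
    if gaussians:
        net = HybridBayesNet(dag=dag.copy(), states=states, cpts=cpts, gaussians=gaussians, n_fitted=len(data))
    else:
        net = DiscreteBayesNet(dag=dag.copy(), states=states, cpts=cpts, n_fitted=len(data))
    net.validate()
    return net
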