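"""Constrained local search over DAG structures.

Moves are single-arc additions, deletions and reversals; Tabu search
keeps a short-term memory of recently applied moves whose inverses are
forbidden, which lets the search walk out of local optima.  The best
structure encountered is returned.  All candidate moves are enumerated
in a fixed order, so results are deterministic for a given data set and
parameter set.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import pandas as pd

from stressnet.bn.constraints import ConstraintSet, clg_blacklist
from stressnet.bn.dag import Dag, CycleError
from stressnet.bn.score import HybridScorer, make_scorer

_EPS = 1e-9


@dataclass(frozen=True)
class SearchParams:
    """Knobs for structure search and bootstrap model averaging."""

    tabu_len: int = 10
    max_iter: int = 100
    patience: int = 15            # stop after this many non-improving moves
    smoothing: float = 1.0        # CPT pseudo-count used downstream when fitting
    n_bootstrap: int = 1000
    inclusion: float = 0.3        # minimum arc strength to keep in the average
    significance: float = 0.5     # strength above which an arc is "significant"
    seed: int | None = None

    def __post_init__(self):
        if not (0.0 < self.inclusion < 1.0 and 0.0 < self.significance < 1.0):
            raise ValueError("thresholds must lie in (0, 1)")
        if self.inclusion > self.significance:
            raise ValueError("inclusion threshold must not exceed significance threshold")
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")


def _effective_constraints(scorer, constraints: ConstraintSet | None) -> ConstraintSet:
    constraints = constraints or ConstraintSet()
    if isinstance(scorer, HybridScorer) and scorer.continuous:
        constraints = constraints.merged_with(
            extra_blacklist=clg_blacklist(scorer.discrete, scorer.continuous)
        )
    return constraints


def _start_dag(nodes, constraints: ConstraintSet) -> Dag:
    dag = Dag(nodes)
    for u, v in sorted(constraints.whitelist):
        if u not in dag.nodes or v not in dag.nodes:
            raise ValueError(f"whitelisted arc over unknown node: {(u, v)}")
        dag.add_arc(u, v)
    return dag


def _search(
    data: pd.DataFrame,
    constraints: ConstraintSet | None,
    params: SearchParams,
    *,
    use_tabu: bool,
    scorer=None,
) -> Dag:
    scorer = scorer if scorer is not None else make_scorer(data)
    constraints = _effective_constraints(scorer, constraints)
    nodes = list(scorer.columns)
    dag = _start_dag(nodes, constraints)

    fam = {v: scorer.family_score(v, tuple(dag.parents(v))) for v in nodes}
    current = sum(fam.values())
    best_score = current
    best_dag = dag.copy()
    tabu_until: dict[tuple, int] = {}
    stall = 0

    pairs = [(u, v) for u, v in itertools.permutations(nodes, 2)]

    def admissible(move: tuple, delta: float, it: int) -> bool:
        # Tabu moves are only admissible by aspiration: they must beat
        # the best score seen so far.
        if not use_tabu:
            return True
        if tabu_until.get(move, -1) < it:
            return True
        return current + delta > best_score + _EPS

    for it in range(params.max_iter):
        best_move = None
        best_delta = -math.inf
        for u, v in pairs:
            if dag.has_arc(u, v):
                pv = dag.parents(v)
                if not constraints.requires(u, v):
                    delta = scorer.family_score(v, tuple(pv - {u})) - fam[v]
                    if delta > best_delta + _EPS and admissible(("del", u, v), delta, it):
                        best_move, best_delta = ("del", u, v), delta
                    if not constraints.forbids(v, u) and dag.can_reverse(u, v):
                        delta = (
                            scorer.family_score(v, tuple(pv - {u}))
                            - fam[v]
                            + scorer.family_score(u, tuple(dag.parents(u) | {v}))
                            - fam[u]
                        )
                        if delta > best_delta + _EPS and admissible(("rev", u, v), delta, it):
                            best_move, best_delta = ("rev", u, v), delta
            elif not constraints.forbids(u, v) and dag.can_add(u, v):
                delta = scorer.family_score(v, tuple(dag.parents(v) | {u})) - fam[v]
                if delta > best_delta + _EPS and admissible(("add", u, v), delta, it):
                    best_move, best_delta = ("add", u, v), delta

        if best_move is None:
            break
        if not use_tabu and best_delta <= _EPS:
            break  # greedy hill climbing stops at the first local optimum

        kind, u, v = best_move
        if kind == "add":
            dag.add_arc(u, v)
            fam[v] = scorer.family_score(v, tuple(dag.parents(v)))
            inverse = ("del", u, v)
        elif kind == "del":
            dag.remove_arc(u, v)
            fam[v] = scorer.family_score(v, tuple(dag.parents(v)))
            inverse = ("add", u, v)
        else:
            dag.reverse_arc(u, v)
            fam[v] = scorer.family_score(v, tuple(dag.parents(v)))
            fam[u] = scorer.family_score(u, tuple(dag.parents(u)))
            inverse = ("rev", v, u)
        current += best_delta
        tabu_until[inverse] = it + params.tabu_len
        tabu_until[best_move] = it + params.tabu_len

        if current > best_score + _EPS:
            best_score = current
            best_dag = dag.copy()
            stall = 0
        else:
            stall += 1
            if stall >= params.patience:
                break

    return best_dag


def tabu_search(
    data: pd.DataFrame,
    constraints: ConstraintSet | None = None,
    params: SearchParams | None = None,
    *,
    scorer=None,
) -> Dag:
    """Learn a DAG by Tabu search under the given constraints.

    The returned graph contains every whitelisted arc, no blacklisted
    arc, and is the best-scoring structure encountered.  Float columns
    in ``data`` switch scoring to the conditional-linear-Gaussian model
    class (with continuous -> discrete arcs forbidden automatically).
    """
    return _search(data, constraints, params or SearchParams(), use_tabu=True, scorer=scorer)


def hill_climb(
    data: pd.DataFrame,
    constraints: ConstraintSet | None = None,
    params: SearchParams | None = None,
    *,
    scorer=None,
) -> Dag:
    """Greedy hill climbing (first local optimum); baseline for Tabu."""
    return _search(data, constraints, params or SearchParams(), use_tabu=False, scorer=scorer)


def exhaustive_search(
    data: pd.DataFrame,
    constraints: ConstraintSet | None = None,
) -> tuple[Dag, float]:
    """Best DAG by enumerating every acyclic structure (small node sets).

    Each unordered node pair contributes three options (no arc, forward
    arc, backward arc); cyclic combinations are discarded.  Intended as
    a test oracle for <= 5 nodes.
    """
    scorer = make_scorer(data)
    constraints = _effective_constraints(scorer, constraints)
    nodes = list(scorer.columns)
    if len(nodes) > 5:
        raise ValueError("exhaustive enumeration limited to 5 nodes")
    node_pairs = list(itertools.combinations(nodes, 2))
    best: tuple[Dag, float] | None = None
    for choice in itertools.product((0, 1, 2), repeat=len(node_pairs)):
        dag = Dag(nodes)
        try:
            for (a, b), c in zip(node_pairs, choice):
                if c == 1:
                    dag.add_arc(a, b)
                elif c == 2:
                    dag.add_arc(b, a)
        except CycleError:
            continue
        arcs = dag.arcs
        if any((u, v) in constraints.blacklist for u, v in arcs):
            continue
        if any(a not in arcs for a in constraints.whitelist):
            continue
        s = scorer.score(dag)
        if best is None or s > best[1] + _EPS:
            best = (dag, s)
    assert best is not None
    return best
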