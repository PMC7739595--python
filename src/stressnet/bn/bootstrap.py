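"""Bootstrap arc strengths and model averaging.

Structures are learned on nonparametric bootstrap resamples of the
prepared table; the strength of an arc is the fraction of learned
structures containing it in either direction, and its direction score
is the fraction of those oriented in the canonical (lexicographic)
direction.  The averaged network keeps arcs above an inclusion
threshold, oriented by majority.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from stressnet.bn.constraints import ConstraintSet
from stressnet.bn.dag import Dag, CycleError
from stressnet.bn.search import SearchParams, tabu_search

_EPS = 1e-12


@dataclass
class ArcStrengthTable:
    """Per unordered node pair: inclusion frequency and orientation.

    ``strength`` is direction-agnostic; ``direction`` is the fraction
    of containing models oriented ``node_a -> node_b`` where
    ``node_a < node_b`` lexicographically.
    """

    frame: pd.DataFrame  # columns: node_a, node_b, strength, direction
    n_models: int

    def __post_init__(self):
        s = self.frame["strength"]
        d = self.frame["direction"]
        if ((s < -_EPS) | (s > 1 + _EPS)).any() or ((d < -_EPS) | (d > 1 + _EPS)).any():
            raise ValueError("strengths and directions must lie in [0, 1]")

    def strength_of(self, u: str, v: str) -> float:
        a, b = sorted((u, v))
        row = self.frame[(self.frame.node_a == a) & (self.frame.node_b == b)]
        return float(row.strength.iloc[0]) if len(row) else 0.0

    def to_csv(self, path) -> None:
        out = []
        for row in self.frame.itertuples(index=False):
            if row.direction >= 0.5:
                u, v, direction = row.node_a, row.node_b, row.direction
            else:
                u, v, direction = row.node_b, row.node_a, 1.0 - row.direction
            out.append({"from": u, "to": v, "strength": row.strength, "direction": direction})
        pd.DataFrame(out, columns=["from", "to", "strength", "direction"]).to_csv(path, index=False)


def bootstrap_strength(
    data: pd.DataFrame,
    constraints: ConstraintSet | None = None,
    params: SearchParams | None = None,
    *,
    group: pd.Series | None = None,
) -> ArcStrengthTable:
    """Arc strengths from ``params.n_bootstrap`` resampled structure fits.

    Rows are resampled with replacement; passing ``group`` (e.g., a
    participant id per row) switches to resampling whole groups.
    Deterministic given ``params.seed``.
    """
    params = params or SearchParams()
    rng = np.random.default_rng(params.seed)
    n = len(data)
    counts: dict[tuple[str, str], int] = {}
    forward: dict[tuple[str, str], int] = {}
    if group is not None:
        group = np.asarray(group)
        group_rows = {g: np.flatnonzero(group == g) for g in pd.unique(group)}
        group_keys = list(group_rows)
    for _ in range(params.n_bootstrap):
        if group is None:
            rows = rng.integers(0, n, size=n)
        else:
            picked = rng.integers(0, len(group_keys), size=len(group_keys))
            rows = np.concatenate([group_rows[group_keys[i]] for i in picked])
        sample = data.iloc[rows].reset_index(drop=True)
        dag = tabu_search(sample, constraints, params)
        for u, v in dag.arcs:
            a, b = sorted((u, v))
            counts[(a, b)] = counts.get((a, b), 0) + 1
            if (u, v) == (a, b):
                forward[(a, b)] = forward.get((a, b), 0) + 1
    records = []
    for (a, b), c in sorted(counts.items()):
        records.append(
            {
                "node_a": a,
                "node_b": b,
                "strength": c / params.n_bootstrap,
                "direction": forward.get((a, b), 0) / c,
            }
        )
    frame = pd.DataFrame(records, columns=["node_a", "node_b", "strength", "direction"])
    return ArcStrengthTable(frame=frame, n_models=params.n_bootstrap)


def _find_cycle(arcs: set[tuple[str, str]]) -> list[tuple[str, str]] | None:
    children: dict[str, list[str]] = {}
    for u, v in arcs:
        children.setdefault(u, []).append(v)
        children.setdefault(v, [])
    color: dict[str, int] = {n: 0 for n in children}
    stack_path: list[str] = []

    def dfs(n: str) -> list[str] | None:
        color[n] = 1
        stack_path.append(n)
        for c in children[n]:
            if color[c] == 1:
                i = stack_path.index(c)
                return stack_path[i:] + [c]
            if color[c] == 0:
                found = dfs(c)
                if found:
                    return found
        color[n] = 2
        stack_path.pop()
        return None

    for n in children:
        if color[n] == 0:
            cyc = dfs(n)
            if cyc:
                return list(zip(cyc[:-1], cyc[1:]))
            stack_path.clear()
    return None


def average_network(
    strengths: ArcStrengthTable,
    inclusion: float = 0.3,
    significance: float = 0.5,
    *,
    strict_inclusion: bool = False,
    nodes: tuple[str, ...] | None = None,
) -> tuple[Dag, dict[tuple[str, str], str]]:
    """Model-averaged DAG plus per-arc significance labels.

    Arcs with strength at least ``inclusion`` (strictly above when
    ``strict_inclusion``) are retained, oriented by majority direction;
    arcs with strength above ``significance`` are labelled
    ``"significant"``, the rest ``"non-significant"``.  Should the
    retained arcs form a cycle, the weakest arc of each cycle is
    removed.  Direction ties prefer the orientation keeping the graph
    acyclic, falling back to the lexicographic direction.
    """
    if not (0 < inclusion < 1 and 0 < significance < 1) or inclusion > significance:
        raise ValueError("thresholds must lie in (0, 1) with inclusion <= significance")
    kept: dict[tuple[str, str], float] = {}
    tied: set[tuple[str, str]] = set()
    for row in strengths.frame.itertuples(index=False):
        passed = row.strength > inclusion if strict_inclusion else row.strength >= inclusion
        if not passed:
            continue
        if row.direction > 0.5:
            arc = (row.node_a, row.node_b)
        elif row.direction < 0.5:
            arc = (row.node_b, row.node_a)
        else:
            arc = (row.node_a, row.node_b)
            tied.add(arc)
        kept[arc] = row.strength

    arcs = set(kept)
    while True:
        cycle = _find_cycle(arcs)
        if cycle is None:
            break
        # Prefer flipping a direction-tied arc on the cycle; otherwise
        # drop the weakest arc of the cycle.
        flipped = False
        for arc in cycle:
            if arc in tied and (arc[1], arc[0]) not in arcs:
                arcs.remove(arc)
                candidate = (arc[1], arc[0])
                arcs.add(candidate)
                if _find_cycle(arcs) is None:
                    kept[candidate] = kept.pop(arc)
                    tied.discard(arc)
                    flipped = True
                    break
                arcs.remove(candidate)
                arcs.add(arc)
        if flipped:
            continue
        weakest = min(cycle, key=lambda a: (kept[a], a))
        arcs.remove(weakest)
        kept.pop(weakest)

    all_nodes = set(nodes or ())
    all_nodes.update(strengths.frame.node_a)
    all_nodes.update(strengths.frame.node_b)
    dag = Dag(sorted(all_nodes))
    for u, v in sorted(arcs, key=lambda a: (-kept[a], a)):
        try:
            dag.add_arc(u, v)
        except CycleError:  # pragma: no cover - repaired above
            continue
    labels = {
        arc: ("significant" if kept[arc] > significance else "non-significant")
        for arc in dag.arcs
    }
    return dag, labels
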