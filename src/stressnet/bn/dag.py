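"""Directed acyclic graphs with cheap mutation, for local structure search."""

from __future__ import annotations

import json
from typing import Iterable, Iterator


class CycleError(ValueError):
    """Raised when an operation would introduce a directed cycle."""


class Dag:
    """A directed acyclic graph over named nodes.

    Arc insertion, deletion and reversal are O(V+E) worst case (cycle
    check by reachability); parent/child lookups are O(1).
    """

    __slots__ = ("_parents", "_children")

    def __init__(self, nodes: Iterable[str] = (), arcs: Iterable[tuple[str, str]] = ()):
        self._parents: dict[str, set[str]] = {n: set() for n in nodes}
        self._children: dict[str, set[str]] = {n: set() for n in self._parents}
        for u, v in arcs:
            self.add_arc(u, v)

    # -- introspection -------------------------------------------------

    @property
    def nodes(self) -> tuple[str, ...]:
        return tuple(self._parents)

    @property
    def arcs(self) -> frozenset[tuple[str, str]]:
        return frozenset((u, v) for v, ps in self._parents.items() for u in ps)

    def parents(self, node: str) -> frozenset[str]:
        return frozenset(self._parents[node])

    def children(self, node: str) -> frozenset[str]:
        return frozenset(self._children[node])

    def has_arc(self, u: str, v: str) -> bool:
        return u in self._parents.get(v, ())

    def has_path(self, u: str, v: str) -> bool:
        """True iff a directed path u -> ... -> v exists (including u == v)."""
        if u == v:
            return True
        stack, seen = [u], {u}
        while stack:
            for w in self._children[stack.pop()]:
                if w == v:
                    return True
                if w not in seen:
                    seen.add(w)
                    stack.append(w)
        return False

    def ancestors(self, node: str) -> frozenset[str]:
        stack, seen = list(self._parents[node]), set()
        while stack:
            n = stack.pop()
            if n not in seen:
                seen.add(n)
                stack.extend(self._parents[n])
        return frozenset(seen)

    def topological_order(self) -> list[str]:
        indeg = {n: len(ps) for n, ps in self._parents.items()}
        ready = sorted(n for n, d in indeg.items() if d == 0)
        order: list[str] = []
        while ready:
            n = ready.pop(0)
            order.append(n)
            for c in sorted(self._children[n]):
                indeg[c] -= 1
                if indeg[c] == 0:
                    ready.append(c)
        if len(order) != len(self._parents):
            raise CycleError("graph contains a directed cycle")
        return order

    # -- mutation ------------------------------------------------------

    def add_node(self, node: str) -> None:
        self._parents.setdefault(node, set())
        self._children.setdefault(node, set())

    def add_arc(self, u: str, v: str) -> None:
        if u == v:
            raise ValueError(f"self-arc {u!r} -> {v!r} not allowed")
        if u not in self._parents or v not in self._parents:
            missing = u if u not in self._parents else v
            raise KeyError(f"unknown node {missing!r}")
        if u in self._parents[v]:
            raise ValueError(f"duplicate arc {u!r} -> {v!r}")
        if self.has_path(v, u):
            raise CycleError(f"arc {u!r} -> {v!r} would create a cycle")
        self._parents[v].add(u)
        self._children[u].add(v)

    def remove_arc(self, u: str, v: str) -> None:
        self._parents[v].remove(u)
        self._children[u].remove(v)

    def reverse_arc(self, u: str, v: str) -> None:
        self.remove_arc(u, v)
        try:
            self.add_arc(v, u)
        except CycleError:
            self._parents[v].add(u)
            self._children[u].add(v)
            raise

    def can_add(self, u: str, v: str) -> bool:
        return u != v and u not in self._parents[v] and not self.has_path(v, u)

    def can_reverse(self, u: str, v: str) -> bool:
        if u not in self._parents[v]:
            return False
        self.remove_arc(u, v)
        ok = not self.has_path(u, v)
        self._parents[v].add(u)
        self._children[u].add(v)
        return ok

    # -- conversion ----------------------------------------------------

    def copy(self) -> "Dag":
        new = Dag.__new__(Dag)
        new._parents = {n: set(ps) for n, ps in self._parents.items()}
        new._children = {n: set(cs) for n, cs in self._children.items()}
        return new

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Dag):
            return NotImplemented
        return set(self.nodes) == set(other.nodes) and self.arcs == other.arcs

    def __hash__(self) -> int:
        return hash((frozenset(self.nodes), self.arcs))

    def __repr__(self) -> str:
        return f"Dag(nodes={len(self._parents)}, arcs={sum(map(len, self._parents.values()))})"

    def __iter__(self) -> Iterator[str]:
        return iter(self._parents)

    def to_json(self) -> str:
        payload = {
            "nodes": sorted(self.nodes),
            "arcs": sorted([u, v] for u, v in self.arcs),
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "Dag":
        payload = json.loads(text)
        return cls(payload["nodes"], [tuple(a) for a in payload["arcs"]])

    def to_dot(self, arc_labels: dict[tuple[str, str], str] | None = None) -> str:
        lines = ["digraph G {"]
        for n in sorted(self.nodes):
            lines.append(f'  "{n}";')
        for u, v in sorted(self.arcs):
            label = ""
            if arc_labels and (u, v) in arc_labels:
                label = f' [label="{arc_labels[(u, v)]}"]'
            lines.append(f'  "{u}" -> "{v}"{label};')
        lines.append("}")
        return "\n".join(lines) + "\n"
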