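"""Structural constraints (blacklists/whitelists) for structure search.

Includes generators for the rule families used by the two analyses:
temporal ordering between time slices, independent-to-explanatory
restrictions, same-variable slice arcs, named explanatory-pair
restrictions, and the automatic continuous-to-discrete blacklist
required by conditional-linear-Gaussian networks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from stressnet.bn.dag import Dag, CycleError

Arc = tuple[str, str]


@dataclass(frozen=True)
class ConstraintSet:
    """Forbidden (blacklist) and mandatory (whitelist) directed arcs."""

    blacklist: frozenset[Arc] = field(default_factory=frozenset)
    whitelist: frozenset[Arc] = field(default_factory=frozenset)

    def __post_init__(self):
        object.__setattr__(self, "blacklist", frozenset(self.blacklist))
        object.__setattr__(self, "whitelist", frozenset(self.whitelist))
        overlap = self.blacklist & self.whitelist
        if overlap:
            raise ValueError(f"arcs both blacklisted and whitelisted: {sorted(overlap)}")
        reversed_conflict = {(v, u) for u, v in self.whitelist} & self.blacklist
        # A whitelisted u->v with blacklisted v->u is fine; what is not
        # allowed is a whitelisted arc itself appearing in the blacklist
        # (checked above).  The reversed case is recorded for information
        # only and is legal.
        del reversed_conflict
        nodes = {n for a in self.whitelist for n in a}
        probe = Dag(nodes)
        try:
            for u, v in sorted(self.whitelist):
                probe.add_arc(u, v)
        except CycleError as exc:
            raise ValueError("whitelist arcs form a directed cycle") from exc

    def forbids(self, u: str, v: str) -> bool:
        return (u, v) in self.blacklist

    def requires(self, u: str, v: str) -> bool:
        return (u, v) in self.whitelist

    def merged_with(self, extra_blacklist: Iterable[Arc] = (), extra_whitelist: Iterable[Arc] = ()) -> "ConstraintSet":
        return ConstraintSet(
            blacklist=self.blacklist | frozenset(extra_blacklist),
            whitelist=self.whitelist | frozenset(extra_whitelist),
        )


def _cross(sources: Sequence[str], targets: Sequence[str]) -> set[Arc]:
    return {(u, v) for u in sources for v in targets if u != v}


def two_slice_blacklist(
    explanatory: Sequence[str],
    slice_vars: Sequence[str],
    *,
    outcome_base: str = "injured",
    explanatory_pairs: Iterable[Arc] = (),
) -> set[Arc]:
    """Blacklist rule families for the two-time-slice analysis.

    Parameters
    ----------
    explanatory
        Time-stable variables (no slice suffix).
    slice_vars
        Base names of the time-varying variables; their columns carry
        ``_1``/``_2`` suffixes in the prepared table.
    outcome_base
        Base name of the per-interval outcome node (also suffixed).
    explanatory_pairs
        Extra directed arcs among explanatory variables to forbid.

    Rules produced: every slice-2 node -> slice-1 node arc (temporal
    order), every slice node -> explanatory arc, same-variable
    ``X_1 -> X_2`` arcs, plus the named explanatory pairs.
    """
    bases = list(slice_vars) + [outcome_base]
    slice1 = [f"{b}_1" for b in bases]
    slice2 = [f"{b}_2" for b in bases]
    bl: set[Arc] = set()
    bl |= _cross(slice2, slice1)                       # temporal order
    bl |= _cross(slice1 + slice2, list(explanatory))   # independent -> explanatory
    bl |= {(f"{b}_1", f"{b}_2") for b in bases}        # same-variable slice arcs
    bl |= set(explanatory_pairs)
    return bl


def first_network_constraints(
    explanatory: Sequence[str],
    slice_vars: Sequence[str],
    *,
    outcome_base: str = "injured",
    nle_var: str = "nle",
) -> ConstraintSet:
    """Default constraints for the discretised two-slice network.

    Blacklists the temporal/explanatory/same-variable rule families and
    the named explanatory pairs (competitive level -> gender and
    baseline life events -> gender/sport type); whitelists the
    life-event -> outcome arc in each slice.
    """
    pairs: set[Arc] = set()
    if "comp_level" in explanatory and "gender" in explanatory:
        pairs.add(("comp_level", "gender"))
    if "baseline_nle" in explanatory:
        if "gender" in explanatory:
            pairs.add(("baseline_nle", "gender"))
        if "sport_type" in explanatory:
            pairs.add(("baseline_nle", "sport_type"))
    bl = two_slice_blacklist(explanatory, slice_vars, outcome_base=outcome_base, explanatory_pairs=pairs)
    wl = {
        (f"{nle_var}_1", f"{outcome_base}_1"),
        (f"{nle_var}_2", f"{outcome_base}_2"),
    }
    return ConstraintSet(blacklist=frozenset(bl - wl), whitelist=frozenset(wl))


def second_network_constraints(
    explanatory: Sequence[str],
    change_vars: Sequence[str],
    *,
    outcome: str = "injured",
) -> ConstraintSet:
    """Constraints for the change-score network.

    Change scores and the outcome may not point at explanatory
    variables, and the competitive level -> gender restriction is kept.
    The continuous -> discrete restriction needed for the hybrid model
    class is added automatically at search time from column dtypes.
    """
    bl = _cross(list(change_vars) + [outcome], list(explanatory))
    if "comp_level" in explanatory and "gender" in explanatory:
        bl.add(("comp_level", "gender"))
    return ConstraintSet(blacklist=frozenset(bl))


def clg_blacklist(discrete: Sequence[str], continuous: Sequence[str]) -> set[Arc]:
    """All continuous -> discrete arcs, forbidden in CLG networks."""
    return _cross(list(continuous), list(discrete))
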