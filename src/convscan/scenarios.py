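"""Binary convergent scenarios from a continuous trait reconstruction.

A scenario binarises the node-wise trait values at one cutoff: nodes on the
"greater" side are convergent, unless the root would be convergent, in which
case the orientation is inverted so the root is always ancestral.  A branch
is identified by its child node; transition branches are the ancestral->
convergent cut edges.  Candidate cutoffs sit at the boundaries between
adjacent trait bins; scenarios are deduplicated on their convergent branch
set and filtered to a minimum number of independent transitions, which
guards against phylogenetic pseudoreplication.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io import AnalysisConfig
from .tree import Tree

__all__ = [
    "Scenario",
    "bin_node_values",
    "scenario_from_cutoff",
    "enumerate_scenarios",
    "restrict_scenario",
    "save_scenarios",
    "load_scenarios",
]


@dataclass(frozen=True)
class Scenario:
    """One binarisation of the trait: convergent branches + transitions."""

    id: str
    cutoff: float
    inverted: bool
    convergent_branches: frozenset[str]
    transition_branches: frozenset[str]

    def __post_init__(self):
        if not self.transition_branches <= self.convergent_branches:
            raise ValueError("transition branches must be convergent branches")

    @property
    def n_transitions(self) -> int:
        return len(self.transition_branches)

    def is_convergent(self, node_id: str) -> bool:
        return node_id in self.convergent_branches


def bin_node_values(values: dict[str, float], bin_width: float) -> dict[str, int]:
    """Bin trait values: bin(v) = floor((v - min) / width); min maps to bin 0."""
    if not values:
        raise ValueError("empty node value map")
    if not bin_width > 0:
        raise ValueError("bin_width must be > 0")
    vmin = min(values.values())
    return {k: int(np.floor((v - vmin) / bin_width)) for k, v in values.items()}


def scenario_from_cutoff(
    tree: Tree, values: dict[str, float], cutoff: float
) -> Scenario:
    """Place convergent and transition branches for one trait cutoff.

    Default orientation calls ``value >= cutoff`` convergent; if the root
    lands on that side the orientation is inverted (``value < cutoff``
    convergent) so the root is always ancestral.
    """
    vals = [values[n.id] for n in tree.postorder()]
    if not min(vals) < cutoff < max(vals):
        raise ValueError(
            f"cutoff {cutoff} outside the open range of node values "
            f"({min(vals)}, {max(vals)})"
        )
    inverted = values[tree.root.id] >= cutoff
    if inverted:
        state = {n.id: values[n.id] < cutoff for n in tree.postorder()}
    else:
        state = {n.id: values[n.id] >= cutoff for n in tree.postorder()}
    convergent = frozenset(
        n.id for n in tree.postorder() if state[n.id] and n.parent is not None
    )
    transitions = frozenset(
        n.id
        for n in tree.postorder()
        if n.parent is not None and state[n.id] and not state[n.parent.id]
    )
    return Scenario(
        id=f"c{cutoff:.4f}",
        cutoff=float(cutoff),
        inverted=bool(inverted),
        convergent_branches=convergent,
        transition_branches=transitions,
    )


def enumerate_scenarios(
    tree: Tree, values: dict[str, float], config: AnalysisConfig
) -> list[Scenario]:
    """All retained scenarios: one candidate cutoff per interior bin boundary.

    Boundaries are ``min + k * bin_width`` for k = 1 .. ceil(range/width)-1;
    candidates are deduplicated on their convergent branch set (first cutoff
    kept) and dropped when they carry fewer than ``config.min_transitions``
    independent transitions.  Returned in increasing cutoff order.
    """
    vmin = min(values.values())
    vmax = max(values.values())
    span = vmax - vmin
    if span <= 0:
        return []
    n_bins = int(np.ceil(span / config.bin_width))
    retained: list[Scenario] = []
    seen: set[frozenset[str]] = set()
    for k in range(1, n_bins):
        cutoff = vmin + k * config.bin_width
        if not (vmin < cutoff < vmax):
            continue
        scen = scenario_from_cutoff(tree, values, cutoff)
        if scen.n_transitions < config.min_transitions:
            continue
        if scen.convergent_branches in seen:
            continue
        seen.add(scen.convergent_branches)
        retained.append(scen)
    return retained


def restrict_scenario(scenario: Scenario, pruned: Tree) -> Scenario:
    """Project a scenario onto a (gap-)pruned tree.

    Retained nodes keep their convergent/ancestral state; transition branches
    are recomputed as the ancestral->convergent edges of the pruned topology.
    """
    convergent = frozenset(
        n.id
        for n in pruned.postorder()
        if n.parent is not None and scenario.is_convergent(n.id)
    )
    transitions = frozenset(
        n.id
        for n in pruned.postorder()
        if n.parent is not None
        and scenario.is_convergent(n.id)
        and not scenario.is_convergent(n.parent.id)
    )
    return Scenario(
        id=scenario.id,
        cutoff=scenario.cutoff,
        inverted=scenario.inverted,
        convergent_branches=convergent,
        transition_branches=transitions,
    )


# ---------------------------------------------------------------------------
# JSON serialisation


def save_scenarios(scenarios: list[Scenario], path: str | Path) -> None:
    payload = [
        {
            "id": s.id,
            "cutoff": s.cutoff,
            "inverted": s.inverted,
            "n_transitions": s.n_transitions,
            "convergent_branches": sorted(s.convergent_branches),
            "transition_branches": sorted(s.transition_branches),
        }
        for s in scenarios
    ]
    with open(path, "w") as fh:
        json.dump({"scenarios": payload}, fh, indent=1)
        fh.write("\n")


def load_scenarios(path: str | Path) -> list[Scenario]:
    with open(path) as fh:
        payload = json.load(fh)
    return [
        Scenario(
            id=s["id"],
            cutoff=float(s["cutoff"]),
            inverted=bool(s["inverted"]),
            convergent_branches=frozenset(s["convergent_branches"]),
            transition_branches=frozenset(s["transition_branches"]),
        )
        for s in payload["scenarios"]
    ]
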