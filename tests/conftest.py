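"""Shared fixtures and independent oracle helpers."""

from __future__ import annotations

import numpy as np
import pytest

import convscan as cs
from convscan.engine import FlatTree
from convscan.tree import Tree, random_bifurcating_tree


@pytest.fixture(scope="session")
def profiles_c10() -> cs.ProfileSet:
    return cs.load_profiles("c10")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1)


# ---------------------------------------------------------------------------
# Independent oracles (kept free of the code paths they check)


def tip_distances(tree: Tree) -> tuple[list[str], np.ndarray, dict[str, np.ndarray]]:
    """Pairwise tip path lengths and per-node root-to-x distances by id."""
    nodes = list(tree.postorder())
    depth: dict[int, float] = {id(tree.root): 0.0}
    for node in tree.preorder():
        if node.parent is not None:
            depth[id(node)] = depth[id(node.parent)] + (node.length or 0.0)
    tips = tree.tips()
    labels = [t.label for t in tips]
    # distance between tips via MRCA depth
    ancestors: dict[int, list[int]] = {}
    for tip in tips:
        chain = []
        node = tip
        while node is not None:
            chain.append(id(node))
            node = node.parent
        ancestors[id(tip)] = chain
    D = np.zeros((len(tips), len(tips)))
    for i, a in enumerate(tips):
        for j, b in enumerate(tips):
            if i >= j:
                continue
            seen = set(ancestors[id(a)])
            mrca = next(x for x in ancestors[id(b)] if x in seen)
            D[i, j] = D[j, i] = depth[id(a)] + depth[id(b)] - 2 * depth[mrca]
    node_depth = {n.id: depth[id(n)] for n in nodes}
    return labels, D, node_depth


def gls_node_estimate(tree: Tree, traits: dict[str, float], node_id: str) -> float:
    """GLS/ML ancestral estimate at one node via the full BM covariance matrix.

    The tree is conceptually rerooted at the node; the covariance of tip i
    and j is then the length of their shared path from the node, and the
    estimate is the GLS mean (1' V^-1 x) / (1' V^-1 1).
    """
    labels, D, _ = tip_distances(tree)
    # distance from node_id to every tip, via depths and MRCAs
    depth: dict[int, float] = {id(tree.root): 0.0}
    for node in tree.preorder():
        if node.parent is not None:
            depth[id(node)] = depth[id(node.parent)] + (node.length or 0.0)

    def chain(node):
        out = []
        while node is not None:
            out.append(id(node))
            node = node.parent
        return out

    target = tree[node_id]
    target_chain = set(chain(target))
    d = np.empty(len(labels))
    for i, lab in enumerate(labels):
        tip = next(t for t in tree.tips() if t.label == lab)
        mrca = next(x for x in chain(tip) if x in target_chain)
        d[i] = depth[id(tip)] + depth[id(target)] - 2 * depth[mrca]
    n = len(labels)
    V = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            V[i, j] = (d[i] + d[j] - D[i, j]) / 2.0
    x = np.array([traits[lab] for lab in labels])
    Vinv1 = np.linalg.solve(V, np.ones(n))
    Vinvx = np.linalg.solve(V, x)
    return float(np.ones(n) @ Vinvx / (np.ones(n) @ Vinv1))


def enumeration_loglik(
    tree: Tree,
    column: dict[str, int],
    scenario,
    pi_anc: np.ndarray,
    pi_conv: np.ndarray | None,
    model: str,
) -> float:
    """Exhaustive sum over all 20^(n internal) ancestral-state assignments.

    Materialises the joint probability tensor over internal states with one
    explicit factor per edge; no pruning recursion is involved.
    """
    flat = FlatTree(tree)
    parent_of = {}
    for i, node in enumerate(flat.nodes):
        for j, other in enumerate(flat.nodes):
            if node.parent is other:
                parent_of[i] = j
    internal = [i for i in range(flat.n) if not flat.is_tip[i]]
    pos = {i: d for d, i in enumerate(internal)}
    n_int = len(internal)
    bpi, bebt, bcond = flat.branch_assignment(scenario, pi_anc, pi_conv, model)
    tensor = np.ones((20,) * n_int)
    for i in range(flat.n - 1):
        if bcond[i]:
            M = np.tile(bpi[i], (20, 1))
        else:
            M = bebt[i] * np.eye(20) + (1 - bebt[i]) * np.tile(bpi[i], (20, 1))
        p = pos[parent_of[i]]
        if flat.is_tip[i]:
            vec = M[:, column[flat.nodes[i].label]]
            shape = [1] * n_int
            shape[p] = 20
            tensor = tensor * vec.reshape(shape)
        else:
            Mr = np.moveaxis(
                M.reshape(20, 20, *([1] * (n_int - 2))), [0, 1], [p, pos[i]]
            )
            tensor = tensor * Mr
    root_pos = pos[flat.n - 1]
    shape = [1] * n_int
    shape[root_pos] = 20
    total = float((tensor * pi_anc.reshape(shape)).sum())
    return np.log(total) if total > 0 else -np.inf


def random_clade_scenario(tree: Tree, rng: np.random.Generator):
    """A scenario whose convergent set is one random non-root clade."""
    from convscan.scenarios import Scenario

    candidates = [n for n in tree.postorder() if n.parent is not None]
    node = candidates[int(rng.integers(len(candidates)))]
    conv = set()

    def collect(nd):
        conv.add(nd.id)
        for child in nd.children:
            collect(child)

    collect(node)
    return Scenario("clade", 0.0, False, frozenset(conv), frozenset({node.id}))


@pytest.fixture(scope="session")
def planted_experiment(profiles_c10):
    """64-tip balanced tree with a 7-transition scenario and planted sites.

    Shared by the discovery-performance and calibration checks; simulating
    once per session keeps the suite fast.
    """
    from convscan.tree import balanced_tree

    tree = balanced_tree(6, 0.3)
    tips = tree.tip_labels()
    conv_tips = (
        set(tips[0:4]) | set(tips[8:12]) | set(tips[16:18]) | set(tips[24:26])
        | set(tips[32:34]) | {tips[48], tips[56]}
    )
    traits = cs.TraitTable(
        {lab: (10.0 if lab in conv_tips else 0.0) for lab in tips}
    )
    values = cs.reconstruct_bm(tree, traits)
    config = cs.AnalysisConfig(bin_width=2.0, min_transitions=5, n_sims=200, seed=1)
    scens = cs.enumerate_scenarios(tree, values, config)
    true = next(s for s in scens if s.n_transitions == 7)
    rng = np.random.default_rng(1)
    aln, truth = cs.simulate_dataset(
        tree, true, 100, 400, profiles_c10, [("hydrophobic", "charged")], rng
    )
    return {
        "tree": tree,
        "values": values,
        "config": config,
        "scenarios": scens,
        "true_scenario": true,
        "alignment": aln,
        "truth": truth,
    }
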