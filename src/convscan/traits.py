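"""Ancestral reconstruction of a continuous trait under Brownian motion.

The estimator is the Felsenstein-style two-pass message scheme: an upward
pass computes, for every node, the precision-weighted mean of the tip values
below it; a downward pass folds in the information from the rest of the tree.
For a fixed tree this is exactly the generalized-least-squares / maximum
likelihood point estimate at every node.  Point estimates only — no
uncertainty is propagated.
"""

from __future__ import annotations

import numpy as np

from .io import TraitTable
from .tree import Node, Tree, TreeError, prune_to_tips

__all__ = ["reconstruct_bm", "prune_to_traits", "simulate_bm"]

#: Zero-length branches are replaced by this fraction of the tree height to
#: keep the precision weights finite.
_EPS_FRACTION = 1e-8


def prune_to_traits(tree: Tree, traits: TraitTable) -> Tree:
    """Restrict the tree to tips that have a trait value (>= 4 required)."""
    shared = [t for t in tree.tip_labels() if t in traits]
    if len(shared) < 4:
        raise TreeError(
            f"only {len(shared)} tree tips have trait values; need at least 4"
        )
    if len(shared) == tree.n_tips:
        return tree
    return prune_to_tips(tree, shared)


def _effective_lengths(tree: Tree) -> dict[int, float]:
    height = tree.height()
    eps = _EPS_FRACTION * (height if height > 0 else 1.0)
    out: dict[int, float] = {}
    for node in tree.postorder():
        if node.parent is not None:
            out[id(node)] = max(node.length or 0.0, eps)
    return out


def reconstruct_bm(tree: Tree, traits: TraitTable) -> dict[str, float]:
    """ML/GLS trait value at every node; tips keep their observed values.

    Every tip must have a trait value (prune the tree first with
    :func:`prune_to_traits` if it does not).
    """
    tips = tree.tips()
    if len(tips) < 2:
        raise TreeError("need at least 2 tips for reconstruction")
    missing = [t.label for t in tips if t.label not in traits]
    if missing:
        raise TreeError(f"tips missing from trait table: {missing}")

    lengths = _effective_lengths(tree)

    # Upward pass: (mean, variance) of the conditional tip-data message at
    # each node, *before* traversing the branch above it.
    up: dict[int, tuple[float, float]] = {}
    for node in tree.postorder():
        if node.is_tip:
            up[id(node)] = (traits[node.label], 0.0)
        else:
            wsum = 0.0
            msum = 0.0
            for child in node.children:
                m, v = up[id(child)]
                s = v + lengths[id(child)]
                w = 1.0 / s
                wsum += w
                msum += w * m
            up[id(node)] = (msum / wsum, 1.0 / wsum)

    # Downward pass: message arriving at each node from the rest of the tree
    # (None at the root).
    down: dict[int, tuple[float, float] | None] = {id(tree.root): None}
    for node in tree.preorder():
        parent_msg = down[id(node)]
        for child in node.children:
            wsum = 0.0
            msum = 0.0
            if parent_msg is not None:
                m, v = parent_msg
                w = 1.0 / v if v > 0 else np.inf
                wsum += w
                msum += w * m
            for sib in node.children:
                if sib is child:
                    continue
                m, v = up[id(sib)]
                s = v + lengths[id(sib)]
                w = 1.0 / s
                wsum += w
                msum += w * m
            down[id(child)] = (msum / wsum, 1.0 / wsum + lengths[id(child)])

    values: dict[str, float] = {}
    for node in tree.postorder():
        if node.is_tip:
            values[node.id] = traits[node.label]
            continue
        m_up, v_up = up[id(node)]
        msg = down[id(node)]
        if msg is None:
            values[node.id] = m_up
        else:
            m_dn, v_dn = msg
            w_up = 1.0 / v_up if v_up > 0 else np.inf
            w_dn = 1.0 / v_dn
            values[node.id] = (w_up * m_up + w_dn * m_dn) / (w_up + w_dn)
    return values


def simulate_bm(
    tree: Tree,
    rng: np.random.Generator,
    root_value: float = 0.0,
    sigma2: float = 1.0,
) -> dict[str, float]:
    """Simulate a Brownian trait down the tree; returns value at every node."""
    values: dict[str, float] = {}
    state: dict[int, float] = {id(tree.root): root_value}
    for node in tree.preorder():
        if node.parent is not None:
            t = node.length or 0.0
            state[id(node)] = state[id(node.parent)] + rng.normal(
                0.0, np.sqrt(sigma2 * t)
            )
        values[node.id] = state[id(node)]
    return values
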