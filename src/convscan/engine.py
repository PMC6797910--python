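"""Site-wise model comparison: null vs profile-change-with-one-change.

For every alignment column the engine computes Felsenstein pruning
likelihoods under branch-specific versions of the profile process:

* null  - a single profile on every branch;
* PC    - the convergent branches use a second profile, nothing forced;
* OC    - one profile everywhere, but transition branches are conditioned on
          at least one substitution event;
* PCOC  - convergent branches use the second profile and the child state of
          each transition branch is drawn from it (the conditioned matrix of
          the closed-form process is exactly P*_ij = pi_j).

The posterior probability of the convergent model comes from the likelihood
ratio of the profile-maximised PCOC and null fits under equal model priors.
Likelihoods are maximised over single profiles (null) and ordered profile
pairs (PCOC); gapped taxa are handled by per-column tree pruning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .io import GAP, Alignment, AnalysisConfig, SiteReport, SiteRow
from .model import ProfileSet, profile_beta
from .scenarios import Scenario, restrict_scenario
from .tree import Tree, prune_to_tips

__all__ = [
    "SiteModelFit",
    "prune_gaps",
    "site_likelihood",
    "site_pp",
    "scan_alignment",
]

_MODELS = ("null", "PC", "OC", "PCOC")


@dataclass
class SiteModelFit:
    site_index: int
    scenario_id: str | None
    best_profile_anc_id: str
    best_profile_conv_id: str | None
    loglik_null: float
    loglik_pcoc: float
    pp: float


# ---------------------------------------------------------------------------
# Flattened tree representation


class FlatTree:
    """Postorder-indexed arrays for fast repeated pruning passes."""

    def __init__(self, tree: Tree):
        self.tree = tree
        self.nodes = list(tree.postorder())
        index = {id(n): i for i, n in enumerate(self.nodes)}
        self.n = len(self.nodes)
        self.children = [
            [index[id(c)] for c in node.children] for node in self.nodes
        ]
        self.lengths = np.array(
            [n.length if n.parent is not None else 0.0 for n in self.nodes]
        )
        self.is_tip = np.array([n.is_tip for n in self.nodes])
        self.ids = [n.id for n in self.nodes]
        self.tip_indices = [i for i in range(self.n) if self.is_tip[i]]
        self.tip_labels = [self.nodes[i].label for i in self.tip_indices]
        self._tip_pos = {node_i: col for col, node_i in enumerate(self.tip_indices)}

    def encode_columns(self, columns: list[dict[str, int]]) -> np.ndarray:
        """Stack taxon->code dicts into an (m, n_tips) array in flat tip order."""
        out = np.empty((len(columns), len(self.tip_labels)), dtype=np.int16)
        for r, col in enumerate(columns):
            for c, label in enumerate(self.tip_labels):
                out[r, c] = col[label]
        return out

    def branch_assignment(
        self,
        scenario: Scenario | None,
        pi_anc: np.ndarray,
        pi_conv: np.ndarray | None,
        model: str,
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-node (profile, e^{-beta t}, conditioned?) arrays for one model."""
        if model not in _MODELS:
            raise ValueError(f"unknown model {model!r}")
        if model != "null" and scenario is None:
            raise ValueError(f"model {model} requires a scenario")
        if model in ("PC", "PCOC"):
            if pi_conv is None:
                raise ValueError(f"model {model} requires a convergent profile")
            if np.allclose(pi_anc, pi_conv):
                raise ValueError("convergent profile must differ from ancestral")
        if scenario is not None:
            unknown = (
                scenario.convergent_branches | scenario.transition_branches
            ) - set(self.ids)
            if unknown:
                raise ValueError(
                    f"scenario references unknown branch ids: {sorted(unknown)}"
                )
        bpi = np.tile(pi_anc, (self.n, 1))
        bcond = np.zeros(self.n, dtype=bool)
        if scenario is not None:
            conv = np.array(
                [nid in scenario.convergent_branches for nid in self.ids]
            )
            trans = np.array(
                [nid in scenario.transition_branches for nid in self.ids]
            )
            if model in ("PC", "PCOC"):
                bpi[conv] = pi_conv
            if model in ("OC", "PCOC"):
                bcond = trans
        betas = 1.0 / (1.0 - np.einsum("ij,ij->i", bpi, bpi))
        bebt = np.exp(-betas * self.lengths)
        return bpi, bebt, bcond


def _loglik_batch(
    flat: FlatTree,
    tipcols: np.ndarray,
    bpi: np.ndarray,
    bebt: np.ndarray,
    bcond: np.ndarray,
    root_prior: np.ndarray,
) -> np.ndarray:
    """Pruning log-likelihood for a batch of columns; returns (m,)."""
    m = tipcols.shape[0]
    eye = np.eye(20)
    messages: list[np.ndarray | None] = [None] * flat.n
    logscale = np.zeros(m)
    root_idx = flat.n - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        for i in range(flat.n):
            if flat.is_tip[i]:
                partial = eye[tipcols[:, flat._tip_pos[i]]]
            else:
                partial = messages[flat.children[i][0]]
                for c in flat.children[i][1:]:
                    partial = partial * messages[c]
                scale = partial.max(axis=1)
                ok = scale > 0
                logscale += np.where(ok, np.log(np.where(ok, scale, 1.0)), -np.inf)
                partial = partial / np.where(ok, scale, 1.0)[:, None]
            if i == root_idx:
                like = partial @ root_prior
                return logscale + np.where(like > 0, np.log(np.maximum(like, 1e-300)), -np.inf)
            stat = partial @ bpi[i]
            if bcond[i]:
                messages[i] = np.broadcast_to(stat[:, None], (m, 20)).copy()
            else:
                messages[i] = bebt[i] * partial + (1.0 - bebt[i]) * stat[:, None]
    raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# Public single-column API


def prune_gaps(
    tree: Tree, column: dict[str, int | str]
) -> tuple[Tree | None, dict[str, int]]:
    """Drop gapped taxa from the column and restrict the tree accordingly.

    Accepts residue codes (gap = -1) or characters.  Returns ``(None, {})``
    when fewer than two ungapped taxa remain.
    """
    from .io import AA_INDEX

    clean: dict[str, int] = {}
    for taxon, value in column.items():
        if isinstance(value, str):
            value = GAP if value in "-X?." else AA_INDEX[value]
        if value != GAP:
            clean[taxon] = int(value)
    keep = [t for t in tree.tip_labels() if t in clean]
    if len(keep) < 2:
        return None, {}
    if len(keep) == tree.n_tips:
        return tree, clean
    return prune_to_tips(tree, keep), clean


def site_likelihood(
    tree: Tree,
    column: dict[str, int],
    scenario: Scenario | None,
    profile_anc: np.ndarray,
    profile_conv: np.ndarray | None = None,
    model: str = "null",
) -> float:
    """Pruning log-likelihood of one gap-free column under one model."""
    flat = FlatTree(tree)
    missing = set(flat.tip_labels) - set(column)
    if missing:
        raise ValueError(f"column missing taxa: {sorted(missing)}")
    tipcols = flat.encode_columns([column])
    if np.any(tipcols < 0):
        raise ValueError("column contains gaps; prune first")
    pi_anc = np.asarray(profile_anc, dtype=float)
    pi_conv = None if profile_conv is None else np.asarray(profile_conv, dtype=float)
    bpi, bebt, bcond = flat.branch_assignment(scenario, pi_anc, pi_conv, model)
    return float(_loglik_batch(flat, tipcols, bpi, bebt, bcond, pi_anc)[0])


# ---------------------------------------------------------------------------
# Profile-maximised scoring (shared by the scan and the bootstrap)


def score_columns(
    flat: FlatTree,
    tipcols: np.ndarray,
    scenario: Scenario,
    profiles: ProfileSet,
) -> dict[str, np.ndarray]:
    """Best null and PCOC fits for a batch of columns under one scenario.

    Returns arrays: ``pp``, ``loglik_null``, ``loglik_pcoc``, ``null_idx``,
    ``anc_idx``, ``conv_idx`` (profile indices of the ML fits).
    """
    m = tipcols.shape[0]
    K = profiles.K
    null_ll = np.full((K, m), -np.inf)
    for k in range(K):
        pi = profiles.matrix[k]
        bpi, bebt, bcond = flat.branch_assignment(None, pi, None, "null")
        null_ll[k] = _loglik_batch(flat, tipcols, bpi, bebt, bcond, pi)
    null_idx = null_ll.argmax(axis=0)
    loglik_null = null_ll.max(axis=0)

    best_pcoc = np.full(m, -np.inf)
    anc_idx = np.zeros(m, dtype=int)
    conv_idx = np.ones(m, dtype=int)
    for a in range(K):
        pi_a = profiles.matrix[a]
        for c in range(K):
            if c == a:
                continue
            pi_c = profiles.matrix[c]
            bpi, bebt, bcond = flat.branch_assignment(scenario, pi_a, pi_c, "PCOC")
            ll = _loglik_batch(flat, tipcols, bpi, bebt, bcond, pi_a)
            better = ll > best_pcoc
            best_pcoc[better] = ll[better]
            anc_idx[better] = a
            conv_idx[better] = c

    delta = best_pcoc - loglik_null
    pp = expit(delta)
    pp[np.isnan(delta)] = 0.5  # both models impossible (zero-length degeneracies)
    return {
        "pp": pp,
        "loglik_null": loglik_null,
        "loglik_pcoc": best_pcoc,
        "null_idx": null_idx,
        "anc_idx": anc_idx,
        "conv_idx": conv_idx,
    }


def site_pp(
    tree: Tree,
    column: dict[str, int],
    scenario: Scenario,
    profiles: ProfileSet,
    site_index: int = 0,
) -> SiteModelFit:
    """Profile-maximised fit of one gap-free column under one scenario."""
    flat = FlatTree(tree)
    tipcols = flat.encode_columns([column])
    res = score_columns(flat, tipcols, scenario, profiles)
    return SiteModelFit(
        site_index=site_index,
        scenario_id=scenario.id,
        best_profile_anc_id=profiles.ids[int(res["anc_idx"][0])],
        best_profile_conv_id=profiles.ids[int(res["conv_idx"][0])],
        loglik_null=float(res["loglik_null"][0]),
        loglik_pcoc=float(res["loglik_pcoc"][0]),
        pp=float(res["pp"][0]),
    )


# ---------------------------------------------------------------------------
# Alignment-wide scan


def scan_alignment(
    alignment: Alignment,
    tree: Tree,
    scenarios: list[Scenario],
    profiles: ProfileSet,
    config: AnalysisConfig | None = None,
) -> SiteReport:
    """Score every alignment column, maximising PP over all viable scenarios.

    Sites with fewer than 4 ungapped taxa, or with no scenario retaining
    ``min_transitions`` transitions after gap-pruning, are marked
    ``skipped_gaps``.  Sites with max PP below ``pp_threshold`` are marked
    ``below_threshold``; the rest are left ``unresolved`` pending bootstrap
    calibration.
    """
    if config is None:
        config = AnalysisConfig()
    if not scenarios:
        raise ValueError("no scenarios supplied")
    extra = set(alignment.taxa) - set(tree.tip_labels())
    if extra:
        raise ValueError(f"alignment taxa not in tree: {sorted(extra)}")
    if set(alignment.taxa) != set(tree.tip_labels()):
        tree = prune_to_tips(tree, alignment.taxa)

    rows: dict[int, SiteRow] = {}
    # group columns by gap pattern so each pruned tree is built once
    patterns: dict[frozenset[str], list[int]] = {}
    for site in range(1, alignment.length + 1):
        col = alignment.data[:, site - 1]
        gapped = frozenset(
            t for t, code in zip(alignment.taxa, col) if code == GAP
        )
        patterns.setdefault(gapped, []).append(site)

    for gapped, sites in patterns.items():
        ungapped = [t for t in alignment.taxa if t not in gapped]
        if len(ungapped) < 4:
            for site in sites:
                rows[site] = SiteRow(site_index=site, call="skipped_gaps")
            continue
        sub = tree if not gapped else prune_to_tips(tree, ungapped)
        viable: list[Scenario] = []
        for scen in scenarios:
            restricted = scen if not gapped else restrict_scenario(scen, sub)
            if restricted.n_transitions >= config.min_transitions:
                viable.append(restricted)
        if not viable:
            for site in sites:
                rows[site] = SiteRow(site_index=site, call="skipped_gaps")
            continue

        flat = FlatTree(sub)
        order = [alignment.taxa.index(t) for t in flat.tip_labels]
        tipcols = alignment.data[np.ix_(order, [s - 1 for s in sites])].T.astype(
            np.int16
        )

        best_pp = np.full(len(sites), -1.0)
        best_scen = [None] * len(sites)
        for scen in viable:
            res = score_columns(flat, tipcols, scen, profiles)
            better = res["pp"] > best_pp
            best_pp[better] = res["pp"][better]
            for i in np.nonzero(better)[0]:
                best_scen[i] = scen
        for i, site in enumerate(sites):
            scen = best_scen[i]
            pp = float(best_pp[i])
            call = "below_threshold" if pp < config.pp_threshold else "unresolved"
            rows[site] = SiteRow(
                site_index=site,
                max_pp=pp,
                best_cutoff=scen.cutoff,
                best_scenario_id=scen.id,
                n_transitions=scen.n_transitions,
                call=call,
            )

    return SiteReport([rows[s] for s in sorted(rows)])
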