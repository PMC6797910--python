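"""Profile-mixture (CAT-style) substitution model and sequence simulation.

Each site evolves under one of K amino-acid frequency profiles.  The
per-profile process is the profile-driven one-parameter (F81-type) chain,
q_ij = beta * pi_j for i != j, with beta = 1 / (1 - sum(pi^2)) so that one
unit of branch length equals one expected substitution per site at
stationarity.  Its transition probabilities have the closed form

    P_ij(t) = exp(-beta t) * delta_ij + (1 - exp(-beta t)) * pi_j.

Convergent scenarios are simulated by switching the profile on convergent
branches and drawing the child state of each transition branch directly from
the convergent profile (the process conditioned on at least one event, which
for this chain is exactly a draw from pi).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .io import AA_ORDER, Alignment
from .scenarios import Scenario
from .tree import Tree

__all__ = [
    "ProfileSet",
    "RateModel",
    "load_profiles",
    "transition_matrix",
    "simulate_column",
    "simulate_columns",
    "simulate_dataset",
]

#: Profile entries are floored here and renormalised; keeps likelihoods
#: finite and the one-change draw well-defined.
PROFILE_FLOOR = 1e-6

_BUNDLED = {
    "c10": "profiles_c10_synthetic.tsv",
    "c60": "profiles_c60_synthetic.tsv",
}


def _floor_and_normalise(matrix: np.ndarray) -> np.ndarray:
    matrix = np.asarray(matrix, dtype=float)
    if np.any(matrix < 0) or np.any(~np.isfinite(matrix)):
        raise ValueError("profile frequencies must be finite and nonnegative")
    sums = matrix.sum(axis=-1, keepdims=True)
    if np.any(sums <= 0):
        raise ValueError("all-zero profile row")
    matrix = matrix / sums
    matrix = np.maximum(matrix, PROFILE_FLOOR)
    return matrix / matrix.sum(axis=-1, keepdims=True)


@dataclass
class ProfileSet:
    """K amino-acid frequency profiles in fixed residue order ACDEFGHIKLMNPQRSTVWY."""

    ids: list[str]
    matrix: np.ndarray  # (K, 20)

    def __post_init__(self):
        self.matrix = _floor_and_normalise(self.matrix)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(AA_ORDER):
            raise ValueError("profile matrix must be K x 20")
        if len(self.ids) != self.matrix.shape[0]:
            raise ValueError("profile ids do not match matrix rows")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate profile ids")
        if self.K < 2:
            raise ValueError("need at least 2 profiles")

    @property
    def K(self) -> int:
        return self.matrix.shape[0]

    def profile(self, profile_id: str) -> np.ndarray:
        return self.matrix[self.ids.index(profile_id)]

    def subset(self, ids: list[str]) -> "ProfileSet":
        return ProfileSet(list(ids), np.vstack([self.profile(i) for i in ids]))


def load_profiles(source: str | Path) -> ProfileSet:
    """Load a profile TSV (id + 20 frequency columns) or a bundled set id.

    Bundled ids: ``"c10"`` (10 chemically-motivated synthetic profiles) and
    ``"c60"`` (60 synthetic CAT-style categories).
    """
    if isinstance(source, str) and source in _BUNDLED:
        ref = resources.files("convscan.data") / _BUNDLED[source]
        with resources.as_file(ref) as path:
            return _read_profile_tsv(path)
    return _read_profile_tsv(Path(source))


def _read_profile_tsv(path: Path) -> ProfileSet:
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    if df.shape[1] != 21:
        raise ValueError(
            f"profile rows must have an id plus 20 frequencies; got {df.shape[1]} columns"
        )
    ids = [str(i) for i in df.iloc[:, 0]]
    matrix = df.iloc[:, 1:].to_numpy(dtype=float)
    return ProfileSet(ids, matrix)


# ---------------------------------------------------------------------------
# The per-profile process


def profile_beta(profile: np.ndarray) -> float:
    """Rate normalisation 1 / (1 - sum pi^2): one substitution per unit length."""
    return 1.0 / (1.0 - float(np.dot(profile, profile)))


@dataclass
class RateModel:
    """F81-type process with stationary distribution ``profile``."""

    profile: np.ndarray

    def __post_init__(self):
        self.profile = _floor_and_normalise(np.atleast_2d(self.profile))[0]
        self.beta = profile_beta(self.profile)

    def rate_matrix(self) -> np.ndarray:
        q = self.beta * np.tile(self.profile, (len(self.profile), 1))
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        return q


def transition_matrix(model: RateModel, t: float) -> np.ndarray:
    """Closed-form P(t) = e^(-beta t) I + (1 - e^(-beta t)) 1 pi^T."""
    if t < 0:
        raise ValueError("branch length must be nonnegative")
    e = np.exp(-model.beta * t)
    n = len(model.profile)
    return e * np.eye(n) + (1.0 - e) * np.tile(model.profile, (n, 1))


# ---------------------------------------------------------------------------
# Simulation


def _draw_categorical(prob: np.ndarray, rng: np.random.Generator, n: int) -> np.ndarray:
    """Draw n states; prob is (20,) shared or (n, 20) per-draw."""
    cdf = np.cumsum(np.atleast_2d(prob), axis=1)
    u = rng.random(n)
    if cdf.shape[0] == 1:
        out = np.searchsorted(cdf[0], u, side="right")
    else:
        out = (u[:, None] > cdf).sum(axis=1)
    return np.minimum(out, cdf.shape[1] - 1).astype(np.int16)


def simulate_columns(
    tree: Tree,
    scenario: Scenario | None,
    profile_anc: np.ndarray,
    profile_conv: np.ndarray | None,
    n: int,
    rng: np.random.Generator,
    branch_lengths: dict[str, float] | None = None,
) -> tuple[list[str], np.ndarray]:
    """Simulate ``n`` independent alignment columns along the tree.

    Returns (tip labels in postorder, states array of shape (n_tips, n)).
    ``profile_anc``/``profile_conv`` may be a single (20,) profile or an
    (n, 20) per-column stack (used by the noisy null bootstrap arm).
    ``branch_lengths`` optionally overrides node branch lengths by id.
    """
    profile_anc = _floor_and_normalise(np.asarray(profile_anc, dtype=float))
    if scenario is not None:
        if profile_conv is None:
            raise ValueError("convergent profile required when a scenario is given")
        known = set(tree.nodes)
        unknown = (scenario.convergent_branches | scenario.transition_branches) - known
        if unknown:
            raise ValueError(f"scenario references unknown branch ids: {sorted(unknown)}")
        profile_conv = _floor_and_normalise(np.asarray(profile_conv, dtype=float))

    def beta_of(prof: np.ndarray) -> np.ndarray | float:
        p = np.atleast_2d(prof)
        return 1.0 / (1.0 - np.einsum("ij,ij->i", p, p))

    beta_anc = beta_of(profile_anc)
    beta_conv = beta_of(profile_conv) if profile_conv is not None else None

    states: dict[str, np.ndarray] = {}
    states[tree.root.id] = _draw_categorical(profile_anc, rng, n)
    for node in tree.preorder():
        if node.parent is None:
            continue
        t = node.length or 0.0
        if branch_lengths is not None and node.id in branch_lengths:
            t = branch_lengths[node.id]
        parent_state = states[node.parent.id]
        if scenario is not None and node.id in scenario.transition_branches:
            # one-change contract: child state drawn directly from pi_C
            states[node.id] = _draw_categorical(profile_conv, rng, n)
            continue
        if scenario is not None and node.id in scenario.convergent_branches:
            prof, beta = profile_conv, beta_conv
        else:
            prof, beta = profile_anc, beta_anc
        keep = rng.random(n) < np.exp(-np.asarray(beta) * t)
        fresh = _draw_categorical(prof, rng, n)
        states[node.id] = np.where(keep, parent_state, fresh)

    tips = tree.tips()
    labels = [tip.label for tip in tips]
    return labels, np.vstack([states[tip.id] for tip in tips]).astype(np.int8)


def simulate_column(
    tree: Tree,
    scenario: Scenario | None,
    profile_anc: np.ndarray,
    profile_conv: np.ndarray | None,
    rng: np.random.Generator,
) -> dict[str, int]:
    """Simulate a single column; returns tip label -> residue code."""
    labels, states = simulate_columns(tree, scenario, profile_anc, profile_conv, 1, rng)
    return {lab: int(states[i, 0]) for i, lab in enumerate(labels)}


def simulate_dataset(
    tree: Tree,
    scenario: Scenario | None,
    n_convergent_sites: int,
    n_null_sites: int,
    profiles: ProfileSet,
    profile_pairs: list[tuple[str, str]],
    rng: np.random.Generator,
) -> tuple[Alignment, pd.DataFrame]:
    """Simulate an alignment with planted convergent and null sites.

    Convergent sites cycle through ``profile_pairs`` (ancestral id,
    convergent id) and evolve under ``scenario``; null sites cycle through
    the same pairs but use only the ancestral profile.  Returns the alignment
    (convergent sites first) and a truth table with one row per site.
    """
    if n_convergent_sites < 0 or n_null_sites < 0:
        raise ValueError("site counts must be nonnegative")
    if n_convergent_sites > 0 and scenario is None:
        raise ValueError("a scenario is required to plant convergent sites")
    if not profile_pairs:
        raise ValueError("need at least one profile pair")

    columns: list[np.ndarray] = []
    truth_rows: list[dict] = []
    labels: list[str] | None = None
    for i in range(n_convergent_sites):
        anc_id, conv_id = profile_pairs[i % len(profile_pairs)]
        labels, col = simulate_columns(
            tree, scenario, profiles.profile(anc_id), profiles.profile(conv_id), 1, rng
        )
        columns.append(col[:, 0])
        truth_rows.append(
            {"site_index": i + 1, "kind": "convergent",
             "profile_anc": anc_id, "profile_conv": conv_id}
        )
    for j in range(n_null_sites):
        anc_id, _ = profile_pairs[j % len(profile_pairs)]
        labels, col = simulate_columns(
            tree, None, profiles.profile(anc_id), None, 1, rng
        )
        columns.append(col[:, 0])
        truth_rows.append(
            {"site_index": n_convergent_sites + j + 1, "kind": "null",
             "profile_anc": anc_id, "profile_conv": ""}
        )
    if labels is None:
        labels = [t.label for t in tree.tips()]
        data = np.empty((len(labels), 0), dtype=np.int8)
    else:
        data = np.column_stack(columns).astype(np.int8)
    truth = pd.DataFrame(
        truth_rows, columns=["site_index", "kind", "profile_anc", "profile_conv"]
    )
    return Alignment(labels, data), truth
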