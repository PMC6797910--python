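"""Simulation bootstrap for per-site confidence thresholds and final calls.

For each site whose maximum PP clears the reporting threshold, two
distributions of PP are built on the site's own gap-pruned tree using the
site's maximum-likelihood profile pair and best scenario:

* the null arm simulates non-convergent evolution under the ancestral
  profile with Dirichlet noise added, giving the false-positive threshold
  (the 1-alpha quantile of null PPs);
* the convergent arm simulates profile-shift evolution with transitions
  placed by the best scenario, giving the false-negative threshold
  (the beta quantile of convergent PPs).

A site is called adaptive when its PP sits above the null threshold and
clear of the convergent one, non-adaptive in the mirror case, and
unresolved in the middle ground or when the two shaded regions overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .engine import FlatTree, SiteModelFit, score_columns, site_pp
from .io import GAP, Alignment, AnalysisConfig, SiteReport
from .model import ProfileSet, _floor_and_normalise, simulate_columns
from .scenarios import Scenario, restrict_scenario
from .tree import Tree, prune_to_tips

__all__ = [
    "BootstrapThresholds",
    "perturb_profile",
    "perturb_profiles",
    "calibrate_site",
    "classify_site",
    "calibrate_report",
]


@dataclass
class BootstrapThresholds:
    site_index: int
    threshold_upper: float  # (1 - alpha) quantile of PP under null sims
    threshold_lower: float  # beta quantile of PP under convergent sims
    n_sims: int
    null_pps: np.ndarray | None = field(default=None, repr=False)
    conv_pps: np.ndarray | None = field(default=None, repr=False)


def perturb_profiles(
    profile: np.ndarray, concentration: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """n Dirichlet(concentration * profile) draws, floored and renormalised."""
    if concentration <= 0:
        raise ValueError("concentration must be > 0")
    draws = rng.dirichlet(concentration * np.asarray(profile, dtype=float), size=n)
    return _floor_and_normalise(draws)


def perturb_profile(
    profile: np.ndarray, concentration: float, rng: np.random.Generator
) -> np.ndarray:
    return perturb_profiles(profile, concentration, 1, rng)[0]


def _quantile_type1(sorted_values: np.ndarray, p: float) -> float:
    """Inverse-ECDF quantile: smallest value with ECDF >= p."""
    n = len(sorted_values)
    idx = max(int(np.ceil(p * n)) - 1, 0)
    return float(sorted_values[idx])


def calibrate_site(
    tree: Tree,
    scenario: Scenario,
    fit: SiteModelFit,
    profiles: ProfileSet,
    config: AnalysisConfig,
    rng: np.random.Generator,
    diagnostic_equal_profiles: bool = False,
) -> BootstrapThresholds:
    """Bootstrap PP thresholds for one site on its gap-pruned tree.

    ``scenario`` must be the site's best scenario restricted to ``tree``.
    Null columns evolve under the ML ancestral profile with per-simulation
    Dirichlet noise; convergent columns evolve under the un-perturbed ML
    pair with the scenario's transitions.  Both arms are rescored with the
    same scenario and profile set as the observed column.

    ``diagnostic_equal_profiles`` replaces the convergent arm with a second
    independent run of the null generator, so both arms share one generator;
    the resulting threshold overlap verifies the calibration is honest.
    """
    pi_anc = profiles.profile(fit.best_profile_anc_id)
    if fit.best_profile_conv_id is None:
        raise ValueError("fit lacks a convergent profile id")
    pi_conv = profiles.profile(fit.best_profile_conv_id)
    n = config.n_sims

    noisy_anc = perturb_profiles(pi_anc, config.noise_concentration, n, rng)
    if diagnostic_equal_profiles:
        _, null_cols = simulate_columns(tree, None, noisy_anc, None, n, rng)
        noisy2 = perturb_profiles(pi_anc, config.noise_concentration, n, rng)
        _, conv_cols = simulate_columns(tree, None, noisy2, None, n, rng)
    elif config.branch_noise_sigma > 0:
        _, null_cols = _simulate_with_branch_noise(
            tree, None, noisy_anc, None, n, rng, config.branch_noise_sigma
        )
        _, conv_cols = _simulate_with_branch_noise(
            tree, scenario, pi_anc, pi_conv, n, rng, config.branch_noise_sigma
        )
    else:
        _, null_cols = simulate_columns(tree, None, noisy_anc, None, n, rng)
        _, conv_cols = simulate_columns(tree, scenario, pi_anc, pi_conv, n, rng)

    flat = FlatTree(tree)
    # simulate_columns emits tips in flat (postorder) order already
    both = np.hstack([null_cols, conv_cols]).T.astype(np.int16)
    pps = score_columns(flat, both, scenario, profiles)["pp"]
    null_pps = np.sort(pps[:n])
    conv_pps = np.sort(pps[n:])

    alpha = 1.0 - config.confidence
    return BootstrapThresholds(
        site_index=fit.site_index,
        threshold_upper=_quantile_type1(null_pps, config.confidence),
        threshold_lower=_quantile_type1(conv_pps, alpha),
        n_sims=n,
        null_pps=null_pps,
        conv_pps=conv_pps,
    )


def _simulate_with_branch_noise(tree, scenario, prof_anc, prof_conv, n, rng, sigma):
    """Per-simulation lognormal branch-length multipliers (conservative mode)."""
    cols = []
    ids = [node.id for node in tree.postorder() if node.parent is not None]
    base = {node.id: node.length or 0.0 for node in tree.postorder() if node.parent}
    for i in range(n):
        mult = np.exp(rng.normal(0.0, sigma, size=len(ids)))
        lengths = {nid: base[nid] * m for nid, m in zip(ids, mult)}
        pa = prof_anc[i] if prof_anc.ndim == 2 else prof_anc
        _, col = simulate_columns(
            tree, scenario, pa, prof_conv, 1, rng, branch_lengths=lengths
        )
        cols.append(col[:, 0])
    return None, np.column_stack(cols)


def classify_site(pp: float, th: BootstrapThresholds) -> str:
    """Adaptive / non-adaptive / unresolved region membership of a PP value."""
    if pp >= th.threshold_upper and pp > th.threshold_lower:
        return "adaptive"
    if pp <= th.threshold_lower and pp < th.threshold_upper:
        return "non_adaptive"
    return "unresolved"


def calibrate_report(
    report: SiteReport,
    alignment: Alignment,
    tree: Tree,
    scenarios: list[Scenario],
    profiles: ProfileSet,
    config: AnalysisConfig,
) -> SiteReport:
    """Finalize a scanned report: bootstrap every site at or above threshold.

    Each site gets its own RNG stream derived from ``config.seed`` and the
    site index, so calls are reproducible and independent of scan order.
    """
    by_id = {s.id: s for s in scenarios}
    if set(alignment.taxa) != set(tree.tip_labels()):
        tree = prune_to_tips(tree, alignment.taxa)
    for row in report:
        if row.max_pp is None or row.max_pp < config.pp_threshold:
            continue
        scen = by_id[row.best_scenario_id]
        col = alignment.column(row.site_index)
        ungapped = {t: c for t, c in col.items() if c != GAP}
        sub = (
            tree
            if len(ungapped) == len(col)
            else prune_to_tips(tree, list(ungapped))
        )
        restricted = scen if sub is tree else restrict_scenario(scen, sub)
        fit = site_pp(sub, ungapped, restricted, profiles, row.site_index)
        rng = np.random.default_rng(np.random.SeedSequence((config.seed, row.site_index)))
        th = calibrate_site(sub, restricted, fit, profiles, config, rng)
        row.threshold_upper = th.threshold_upper
        row.threshold_lower = th.threshold_lower
        row.call = classify_site(row.max_pp, th)
    return report
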