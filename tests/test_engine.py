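"""Pruning likelihoods, posterior probabilities, and the alignment scan."""

import itertools

import numpy as np
import pytest
from scipy.special import expit

import convscan as cs
from convscan.engine import FlatTree, _loglik_batch, prune_gaps, scan_alignment, site_pp
from convscan.io import GAP, AnalysisConfig
from convscan.scenarios import Scenario
from convscan.tree import balanced_tree, random_bifurcating_tree

from conftest import enumeration_loglik, random_clade_scenario, tip_distances


class TestPruneGaps:
    def test_no_gaps_identity(self):
        tree = cs.parse_newick("((A:1,B:1):1,C:1);")
        col = {"A": 0, "B": 1, "C": 2}
        sub, clean = prune_gaps(tree, col)
        assert sub is tree
        assert clean == col

    def test_gapped_taxon_removed_path_lengths_kept(self):
        tree = cs.parse_newick("(((A:1,B:2):0.5,C:1):1,(D:1,E:2):1);")
        labels, D, _ = tip_distances(tree)
        sub, clean = prune_gaps(tree, {"A": 0, "B": 1, "C": GAP, "D": 3, "E": 4})
        assert "C" not in clean
        labels2, D2, _ = tip_distances(sub)
        for i, a in enumerate(labels2):
            for j, b in enumerate(labels2):
                assert D2[i, j] == pytest.approx(
                    D[labels.index(a), labels.index(b)], abs=1e-12
                )

    def test_all_gapped_empty_result(self):
        tree = cs.parse_newick("(A:1,B:1);")
        sub, clean = prune_gaps(tree, {"A": GAP, "B": "-"})
        assert sub is None
        assert clean == {}


class TestSiteLikelihood:
    def test_no_time_no_change(self):
        tree = cs.parse_newick("(A:0,B:0);")
        pi = np.full(20, 0.05)
        ll = cs.site_likelihood(tree, {"A": 0, "B": 1}, None, pi)
        assert ll == -np.inf

    def test_independence_at_stationarity(self):
        tree = cs.parse_newick("(A:1e6,B:1e6);")
        pi = np.full(20, 0.05)
        ll = cs.site_likelihood(tree, {"A": 3, "B": 17}, None, pi)
        assert ll == pytest.approx(np.log(1 / 400), rel=1e-6)

    def test_matches_enumeration_all_models(self, profiles_c10, rng):
        for _ in range(8):
            n = int(rng.integers(3, 6))
            tree = random_bifurcating_tree(n, rng)
            col = {lab: int(rng.integers(0, 20)) for lab in tree.tip_labels()}
            scen = random_clade_scenario(tree, rng)
            pa, pc = profiles_c10.matrix[0], profiles_c10.matrix[1]
            for model in ("null", "PC", "OC", "PCOC"):
                s = None if model == "null" else scen
                c = pc if model in ("PC", "PCOC") else None
                got = cs.site_likelihood(tree, col, s, pa, c, model)
                want = enumeration_loglik(tree, col, s, pa, c, model)
                assert got == pytest.approx(want, abs=1e-9)

    @pytest.mark.parametrize("model", ["null", "PC", "OC", "PCOC"])
    def test_likelihood_is_a_distribution(self, profiles_c10, model):
        # summing over every possible 2-tip column must give exactly 1
        tree = cs.parse_newick("(A:0.7,B:1.1);")
        scen = Scenario("s", 0.0, False, frozenset({"A"}), frozenset({"A"}))
        pa, pc = profiles_c10.matrix[2], profiles_c10.matrix[5]
        s = None if model == "null" else scen
        c = pc if model in ("PC", "PCOC") else None
        flat = FlatTree(tree)
        cols = np.array(list(itertools.product(range(20), repeat=2)), dtype=np.int16)
        order = [flat.tip_labels.index(t) for t in ("A", "B")]
        bpi, bebt, bcond = flat.branch_assignment(s, pa, c, model)
        lls = _loglik_batch(flat, cols[:, order], bpi, bebt, bcond, pa)
        assert np.exp(lls).sum() == pytest.approx(1.0, abs=1e-9)

    def test_identical_profiles_rejected_for_pcoc(self, profiles_c10):
        tree = cs.parse_newick("(A:1,B:1);")
        scen = Scenario("s", 0.0, False, frozenset({"A"}), frozenset({"A"}))
        pi = profiles_c10.matrix[0]
        with pytest.raises(ValueError, match="differ"):
            cs.site_likelihood(tree, {"A": 0, "B": 0}, scen, pi, pi, "PCOC")


class TestSitePP:
    def test_pp_is_the_equal_prior_posterior(self, profiles_c10, rng):
        tree = random_bifurcating_tree(6, rng)
        scen = random_clade_scenario(tree, rng)
        col = {lab: int(rng.integers(0, 20)) for lab in tree.tip_labels()}
        fit = site_pp(tree, col, scen, profiles_c10)
        assert fit.pp == pytest.approx(
            expit(fit.loglik_pcoc - fit.loglik_null), abs=1e-12
        )
        assert 0 <= fit.pp <= 1

    def test_sharp_convergent_column_has_high_pp(self):
        # 4 convergent tips all K against 4 ancestral tips all D, with
        # sharply contrasting single-residue-dominated profiles in the set
        tree = balanced_tree(3, 0.3)
        tips = tree.tip_labels()
        conv = set(tips[:4])
        # convergent clade = first four tips plus their internal nodes n2, n5, n6
        scen = Scenario(
            "s", 0.0, False,
            frozenset(set(tips[:4]) | {"n2", "n5", "n6"}), frozenset({"n6"}),
        )
        d_rich = np.full(20, 0.1 / 19)
        d_rich[2] = 0.9
        k_rich = np.full(20, 0.1 / 19)
        k_rich[8] = 0.9
        sharp = cs.ProfileSet(
            ["d_rich", "k_rich", "uniform"],
            np.vstack([d_rich, k_rich, np.full(20, 0.05)]),
        )
        col = {t: (8 if t in conv else 2) for t in tips}  # K vs D
        fit = site_pp(tree, col, scen, sharp)
        assert fit.pp > 0.99
        assert fit.best_profile_anc_id == "d_rich"
        assert fit.best_profile_conv_id == "k_rich"

    def test_constant_column_no_signal(self, profiles_c10):
        tree = balanced_tree(3, 0.3)
        tips = tree.tip_labels()
        scen = Scenario(
            "s", 0.0, False,
            frozenset(set(tips[:4]) | {"n2", "n5", "n6"}), frozenset({"n6"}),
        )
        col = {t: 9 for t in tips}
        fit = site_pp(tree, col, scen, profiles_c10)
        assert fit.pp <= 0.5 + 1e-6


class TestScanAlignment:
    def test_permuting_taxon_order_leaves_pp_unchanged(self, profiles_c10, rng):
        tree = balanced_tree(4, 0.3)
        tips = tree.tip_labels()
        scen = random_clade_scenario(tree, rng)
        while scen.n_transitions < 1 or len(scen.convergent_branches) < 3:
            scen = random_clade_scenario(tree, rng)
        data = rng.integers(0, 20, size=(16, 12)).astype(np.int8)
        aln = cs.Alignment(list(tips), data)
        config = AnalysisConfig(min_transitions=1)
        rep1 = scan_alignment(aln, tree, [scen], profiles_c10, config)
        perm = rng.permutation(16)
        aln2 = cs.Alignment([tips[i] for i in perm], data[perm])
        rep2 = scan_alignment(aln2, tree, [scen], profiles_c10, config)
        for r1, r2 in zip(rep1, rep2):
            assert r1.max_pp == pytest.approx(r2.max_pp, abs=1e-10)

    def test_gap_handling_and_calls(self, profiles_c10):
        tree = balanced_tree(3, 0.3)
        tips = tree.tip_labels()
        scen = Scenario(
            "s", 0.0, False,
            frozenset(set(tips[:4]) | {"n2", "n5", "n6"}),
            frozenset({"n6", tips[0]}),
        )
        data = np.full((8, 3), 5, dtype=np.int8)
        data[:, 1] = GAP              # fully gapped column
        data[2:, 2] = GAP             # only 2 ungapped taxa
        aln = cs.Alignment(list(tips), data)
        config = AnalysisConfig(min_transitions=1)
        report = scan_alignment(aln, tree, [scen], profiles_c10, config)
        assert report.row(1).call in ("below_threshold", "unresolved")
        assert report.row(2).call == "skipped_gaps"
        assert report.row(3).call == "skipped_gaps"

    def test_scenario_dropped_when_transitions_lost_to_gaps(self, profiles_c10):
        tree = balanced_tree(3, 0.3)
        tips = tree.tip_labels()
        # transitions on two tip branches; gapping those tips kills the scenario
        scen = Scenario(
            "s", 0.0, False, frozenset({tips[0], tips[4]}),
            frozenset({tips[0], tips[4]}),
        )
        data = np.full((8, 1), 5, dtype=np.int8)
        data[0, 0] = GAP
        data[4, 0] = GAP
        aln = cs.Alignment(list(tips), data)
        config = AnalysisConfig(min_transitions=2)
        report = scan_alignment(aln, tree, [scen], profiles_c10, config)
        assert report.row(1).call == "skipped_gaps"

    def test_no_scenarios_error(self, profiles_c10):
        tree = balanced_tree(2, 0.3)
        aln = cs.Alignment(tree.tip_labels(), np.zeros((4, 2), dtype=np.int8))
        with pytest.raises(ValueError, match="scenario"):
            scan_alignment(aln, tree, [], profiles_c10)
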