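import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oracles import stepup_fdr

from pitscreen.io_formats import Alignment, CladeConfig, parse_newick
from pitscreen.models import CodonModelSpec
from pitscreen.selection_tests import (
    SelectionTestResult,
    branch_model_test,
    branch_site_scan,
    call_candidates,
    fdr_adjust,
    filter_ogg,
    prune_user_tree,
)
from pitscreen.synthetic_data import (
    default_species_tree,
    simulate_codon_alignment,
)


def make_result(gene, p, w0=0.2, w1=2.0, t=0.05):
    return SelectionTestResult(
        gene=gene, lnl0=-100.0, lnl1=-99.0, omega0=w0, omega1=w1,
        kappa=2.0, lrt=2.0, p_value=p, foreground_t=t,
    )


class TestFilterOgg:
    def _aln(self, rows):
        return Alignment("g", "codon", rows)

    def _config(self):
        return CladeConfig(
            foreground={"P1", "P2", "P3", "P4", "P5"},
            outgroup={"O1", "O2", "O3", "O4", "O5"},
        )

    def test_high_missing_species_removed(self):
        # P5: 4 of 12 columns missing (>20%) -> removed
        seqs = {t: "ATGAAAGGGCCC" for t in ["P1", "P2", "P3", "P4", "O1", "O2", "O3", "O4"]}
        seqs["P5"] = "ATGAAAGG----"[:12]
        aln = self._aln(seqs)
        out = filter_ogg(aln, self._config())
        assert out is not None
        assert "P5" not in out.taxa
        assert out.n_taxa == 8

    def test_boundary_four_and_four_accepted(self):
        seqs = {t: "ATGAAA" for t in ["P1", "P2", "P3", "P4", "O1", "O2", "O3", "O4"]}
        assert filter_ogg(self._aln(seqs), self._config()) is not None

    def test_three_foreground_rejected(self):
        seqs = {t: "ATGAAA" for t in ["P1", "P2", "P3", "O1", "O2", "O3", "O4"]}
        assert filter_ogg(self._aln(seqs), self._config()) is None

    def test_exactly_twenty_percent_missing_kept(self):
        seqs = {t: "ATGAAAGGGCCCTTT" for t in
                ["P1", "P2", "P3", "P4", "O1", "O2", "O3", "O4"]}
        seqs["P1"] = "ATGAAAGGGCCC---"  # 3/15 = 20%, not "more than 20%"
        out = filter_ogg(self._aln(seqs), self._config())
        assert out is not None and "P1" in out.taxa


class TestPruneUserTree:
    def test_path_lengths_preserved(self):
        tree = default_species_tree()
        keep = {
            "Crotalus_mitchellii", "Crotalus_horridus", "Gloydius_brevicaudus",
            "Deinagkistrodon_acutus", "Azemiops_feae", "Vipera_berus",
            "Thamnophis_sirtalis", "Ophiophagus_hannah",
        }
        pruned = prune_user_tree(tree, keep, keep - {"Azemiops_feae", "Vipera_berus",
                                                    "Thamnophis_sirtalis", "Ophiophagus_hannah"})
        assert set(pruned.tip_names()) == keep
        for a, b in [("Crotalus_mitchellii", "Vipera_berus"),
                     ("Gloydius_brevicaudus", "Ophiophagus_hannah")]:
            m_old = tree.mrca({a, b})
            m_new = pruned.mrca({a, b})
            old = tree.path_length(m_old, a) + tree.path_length(m_old, b)
            new = pruned.path_length(m_new, a) + pruned.path_length(m_new, b)
            assert new == pytest.approx(old, abs=1e-12)

    def test_keep_all_preserves_topology(self):
        tree = default_species_tree()
        from pitscreen.synthetic_data import CROTALINAE_TAXA

        pruned = prune_user_tree(tree, tree.tip_names(), CROTALINAE_TAXA)
        assert sorted(pruned.tip_names()) == sorted(tree.tip_names())
        stem = [n for n in pruned.preorder() if n.label == "FG"]
        assert len(stem) == 1
        assert pruned.tip_set(stem[0]) == CROTALINAE_TAXA

    def test_single_foreground_survivor_errors(self):
        tree = default_species_tree()
        keep = {"Crotalus_mitchellii", "Vipera_berus", "Azemiops_feae",
                "Thamnophis_sirtalis"}
        with pytest.raises(ValueError):
            prune_user_tree(tree, keep, {"Crotalus_mitchellii"})


class TestBranchModelTest:
    def test_chi2_reference_value(self):
        from scipy.stats import chi2

        assert chi2.sf(3.841, df=1) == pytest.approx(0.05, abs=1e-3)

    def test_null_data_small_lrt(self, six_taxon_labeled_tree):
        spec = CodonModelSpec(
            kappa=2.0, omega_by_class={"BG": 0.3}, frequencies=np.full(61, 1 / 61)
        )
        aln = simulate_codon_alignment(six_taxon_labeled_tree, spec, 300, seed=21)
        res = branch_model_test(aln, six_taxon_labeled_tree, seed=1)
        assert res.lrt >= 0
        assert res.lnl1 >= res.lnl0 - 1e-6
        assert res.lrt < 8  # no selection signal simulated

    def test_strong_foreground_signal_detected(self, six_taxon_labeled_tree):
        spec = CodonModelSpec(
            kappa=2.0, omega_by_class={"BG": 0.2, "FG": 3.0},
            frequencies=np.full(61, 1 / 61),
        )
        aln = simulate_codon_alignment(six_taxon_labeled_tree, spec, 500, seed=33)
        res = branch_model_test(aln, six_taxon_labeled_tree, seed=1)
        assert res.omega1 > res.omega0
        assert res.p_value < 0.01


class TestFdrAdjust:
    def test_hand_example(self):
        q = fdr_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_value(self):
        assert fdr_adjust([0.5]) == pytest.approx([0.5])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.2])

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=50))
    @settings(max_examples=50, deadline=None)
    def test_matches_stepup_definition(self, ps):
        q = fdr_adjust(ps)
        assert np.allclose(q, stepup_fdr(ps))
        order = np.argsort(ps)
        assert np.all(np.diff(q[order]) >= -1e-12)  # monotone in p
        assert np.all(q <= 1 + 1e-12)


class TestCallCandidates:
    def test_all_conditions_met(self):
        rs = [make_result("a", 0.001), make_result("b", 0.9)]
        out = call_candidates(rs)
        assert out == {"a"}
        assert rs[0].q_value is not None

    def test_omega_direction_required(self):
        rs = [make_result("a", 0.001, w0=2.0, w1=0.2), make_result("b", 0.9)]
        assert call_candidates(rs) == set()

    def test_low_rate_excluded_before_adjustment(self):
        rs = [
            make_result("a", 0.001, t=0.0),
            make_result("b", 0.03),
            make_result("c", 0.9),
        ]
        out = call_candidates(rs)
        assert "a" not in out
        assert rs[0].low_rate_excluded
        assert rs[0].q_value is None
        # BH denominator excludes the low-rate gene: q_b = 0.03 * 2 / 1
        assert rs[1].q_value == pytest.approx(0.06)

    def test_order_invariance(self):
        rs1 = [make_result(g, p) for g, p in [("a", 0.01), ("b", 0.2), ("c", 0.04)]]
        rs2 = list(reversed([make_result(g, p) for g, p in [("a", 0.01), ("b", 0.2), ("c", 0.04)]]))
        assert call_candidates(rs1) == call_candidates(rs2)


class TestBranchSiteScan:
    def test_alternative_dominates_null_and_posteriors_rank_sites(self, six_taxon_labeled_tree):
        """Sites simulated under foreground omega=4 receive higher
        positive-class posteriors than strongly purifying sites."""
        pi = np.full(61, 1 / 61)
        hot = CodonModelSpec(kappa=2.0, omega_by_class={"BG": 0.2, "FG": 4.0}, frequencies=pi)
        cold = CodonModelSpec(kappa=2.0, omega_by_class={"BG": 0.1, "FG": 0.1}, frequencies=pi)
        aln_hot = simulate_codon_alignment(six_taxon_labeled_tree, hot, 60, seed=2)
        aln_cold = simulate_codon_alignment(six_taxon_labeled_tree, cold, 140, seed=3)
        merged = Alignment(
            "g", "codon",
            {t: aln_hot.sequences[t] + aln_cold.sequences[t] for t in aln_hot.taxa},
        )
        res = branch_site_scan(merged, six_taxon_labeled_tree)
        assert res.lnl_alt >= res.lnl_null
        assert res.omega2 >= 1.0
        hot_med = np.median(res.site_posteriors[:60])
        cold_med = np.median(res.site_posteriors[60:])
        assert hot_med > cold_med
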