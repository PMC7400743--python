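import numpy as np
import pytest

from conftest import SIX_TAXON_NEWICK, random_codon_alignment
from oracles import brute_force_log_likelihood

from pitscreen.io_formats import Alignment, parse_newick
from pitscreen.likelihood import (
    estimate_branch_lengths,
    fit_model,
    log_likelihood,
    make_tree_likelihood,
)
from pitscreen.models import (
    AMINO_ACIDS,
    CodonModelSpec,
    ProteinModelSpec,
)
from pitscreen.synthetic_data import (
    simulate_codon_alignment,
    simulate_protein_alignment,
)


def random_protein_alignment(taxa, n_sites, seed, missing_rate=0.0):
    rng = np.random.default_rng(seed)
    seqs = {}
    for t in taxa:
        chars = list(rng.choice(list(AMINO_ACIDS), size=n_sites))
        for i in range(n_sites):
            if rng.random() < missing_rate:
                chars[i] = "-"
        seqs[t] = "".join(chars)
    return Alignment("rand", "protein", sequences=seqs)


TREE_SHAPES = [
    "(A:0.3,B:0.5);",
    "((A:0.2,B:0.4):0.1,C:0.3);",
    "((A:0.1,B:0.2):0.15,(C:0.05,D:0.3):0.1);",
    "(((A:0.1,B:0.1):0.1,C:0.2):0.05,D:0.4);",
    "((((A:0.1,B:0.2):0.05,C:0.1):0.1,D:0.2):0.05,E:0.3);",
    "(((A:0.2,B:0.1):0.1,(C:0.1,D:0.1):0.2):0.05,E:0.15);",
]


class TestPruningOracle:
    @pytest.mark.parametrize("newick", TREE_SHAPES)
    @pytest.mark.parametrize("missing_rate", [0.0, 0.25])
    def test_codon_pruning_equals_enumeration(self, newick, missing_rate):
        """Pruning lnL equals direct summation over all internal-state
        assignments, on every tree shape up to 5 tips and 4 codon sites."""
        tree = parse_newick(newick, name="t")
        taxa = tree.tip_names()
        aln = random_codon_alignment(taxa, 4, seed=len(newick) * 7 + 1,
                                     missing_rate=missing_rate)
        # non-uniform frequencies so transition matrices are asymmetric
        pi = np.random.default_rng(0).dirichlet(np.ones(61) * 3)
        spec = CodonModelSpec(kappa=2.5, omega_by_class={"BG": 0.3}, frequencies=pi)
        lnl = log_likelihood(aln, tree, spec)
        oracle = brute_force_log_likelihood(aln, tree, spec)
        assert abs(lnl - oracle) / max(1.0, abs(oracle)) < 1e-10

    def test_two_class_codon_model_matches_enumeration(self):
        tree = parse_newick("((A:0.1,B:0.2):0.3,(C:0.1,D:0.1):0.05);", name="t")
        tree.mrca({"A", "B"}).label = "FG"
        aln = random_codon_alignment(["A", "B", "C", "D"], 3, seed=5)
        spec = CodonModelSpec(
            kappa=2.0, omega_by_class={"BG": 0.2, "FG": 3.0},
            frequencies=np.full(61, 1 / 61),
        )
        lnl = log_likelihood(aln, tree, spec)
        oracle = brute_force_log_likelihood(aln, tree, spec)
        assert abs(lnl - oracle) / max(1.0, abs(oracle)) < 1e-10

    @pytest.mark.parametrize("newick", TREE_SHAPES[:4])
    def test_protein_pruning_equals_enumeration(self, newick):
        tree = parse_newick(newick, name="t")
        aln = random_protein_alignment(tree.tip_names(), 4, seed=3, missing_rate=0.2)
        spec = ProteinModelSpec()
        lnl = log_likelihood(aln, tree, spec)
        oracle = brute_force_log_likelihood(aln, tree, spec)
        assert abs(lnl - oracle) / max(1.0, abs(oracle)) < 1e-10


class TestLikelihoodProperties:
    def test_identical_sequences_short_branches_approach_prior(self):
        tree = parse_newick("(A:1e-9,B:1e-9);", name="t")
        pi = np.full(61, 1 / 61)
        spec = CodonModelSpec(kappa=2.0, omega_by_class={"BG": 0.5}, frequencies=pi)
        aln = Alignment("g", "codon", {"A": "ATGAAA", "B": "ATGAAA"})
        lnl = log_likelihood(aln, tree, spec)
        assert lnl == pytest.approx(2 * np.log(1 / 61), abs=1e-4)

    def test_all_missing_column_contributes_zero(self):
        tree = parse_newick("((A:0.1,B:0.2):0.1,C:0.3);", name="t")
        spec = CodonModelSpec(
            kappa=2.0, omega_by_class={"BG": 0.5}, frequencies=np.full(61, 1 / 61)
        )
        base = Alignment("g", "codon", {"A": "ATGAAA", "B": "ATGAAG", "C": "ATGCCC"})
        extended = Alignment(
            "g", "codon",
            {t: s + "---" for t, s in base.sequences.items()},
        )
        assert log_likelihood(extended, tree, spec) == pytest.approx(
            log_likelihood(base, tree, spec), abs=1e-12
        )

    def test_invariant_to_tip_order(self):
        tree = parse_newick("((A:0.1,B:0.2):0.1,(C:0.3,D:0.1):0.2);", name="t")
        spec = CodonModelSpec(
            kappa=2.0, omega_by_class={"BG": 0.5}, frequencies=np.full(61, 1 / 61)
        )
        aln = random_codon_alignment(["A", "B", "C", "D"], 20, seed=9)
        shuffled = Alignment(
            "g", "codon", {t: aln.sequences[t] for t in ["D", "B", "A", "C"]}
        )
        assert log_likelihood(aln, tree, spec) == pytest.approx(
            log_likelihood(shuffled, tree, spec), abs=1e-9
        )

    def test_pattern_compression_does_not_change_value(self):
        tree = parse_newick("((A:0.1,B:0.2):0.1,C:0.3);", name="t")
        spec = CodonModelSpec(
            kappa=2.0, omega_by_class={"BG": 0.5}, frequencies=np.full(61, 1 / 61)
        )
        aln = random_codon_alignment(["A", "B", "C"], 50, seed=2)
        # duplicate every column so compression actually collapses patterns
        doubled = Alignment(
            "g", "codon", {t: s + s for t, s in aln.sequences.items()}
        )
        assert log_likelihood(doubled, tree, spec) == pytest.approx(
            2 * log_likelihood(aln, tree, spec), rel=1e-12
        )

    def test_invariant_to_rerooting_one_ratio(self):
        """The same unrooted tree rooted on two different branches gives the
        same lnL under a reversible one-ratio model."""
        spec = CodonModelSpec(
            kappa=2.0, omega_by_class={"BG": 0.5}, frequencies=np.full(61, 1 / 61)
        )
        aln = random_codon_alignment(["A", "B", "C", "D"], 30, seed=4)
        rooted_ab = parse_newick("((A:0.1,B:0.2):0.05,(C:0.3,D:0.15):0.1);")
        # same unrooted tree, rooted along the terminal branch to C
        rooted_c = parse_newick("(C:0.15,((A:0.1,B:0.2):0.15,D:0.15):0.15);")
        assert log_likelihood(aln, rooted_ab, spec) == pytest.approx(
            log_likelihood(aln, rooted_c, spec), abs=1e-8
        )

    def test_tip_without_sequence_errors(self):
        tree = parse_newick("(A:0.1,B:0.1);")
        spec = CodonModelSpec(
            kappa=2.0, omega_by_class={"BG": 0.5}, frequencies=np.full(61, 1 / 61)
        )
        aln = Alignment("g", "codon", {"A": "ATG"})
        with pytest.raises(ValueError):
            log_likelihood(aln, tree, spec)


class TestFitModel:
    def test_forcing_classes_equal_recovers_one_ratio(self, six_taxon_labeled_tree):
        spec1 = CodonModelSpec(
            kappa=2.0, omega_by_class={"BG": 0.5}, frequencies=np.full(61, 1 / 61)
        )
        aln = simulate_codon_alignment(six_taxon_labeled_tree, spec1, 200, seed=8)
        one = fit_model(aln, six_taxon_labeled_tree, spec1,
                        free={"kappa", "omega", "branch_lengths"}, n_starts=1)
        # two-class spec but only the background omega free, FG tied by
        # resolving to the same value at every evaluation
        spec_tied = CodonModelSpec(
            kappa=one.estimates["kappa"],
            omega_by_class={"BG": one.estimates["omega_by_class"]["BG"]},
            frequencies=spec1.frequencies,
        )
        tied_lnl = log_likelihood(aln, one.tree, spec_tied)
        assert tied_lnl == pytest.approx(one.log_likelihood, abs=1e-6)

    def test_two_ratio_dominates_one_ratio(self, six_taxon_labeled_tree):
        spec = CodonModelSpec(
            kappa=2.0, omega_by_class={"BG": 0.4, "FG": 1.5},
            frequencies=np.full(61, 1 / 61),
        )
        aln = simulate_codon_alignment(six_taxon_labeled_tree, spec, 150, seed=12)
        one = fit_model(
            aln, six_taxon_labeled_tree,
            CodonModelSpec(kappa=2.0, omega_by_class={"BG": 0.4},
                           frequencies=spec.frequencies),
            n_starts=1,
        )
        two = fit_model(
            aln, one.tree,
            CodonModelSpec(
                kappa=one.estimates["kappa"],
                omega_by_class={"BG": one.estimates["omega_by_class"]["BG"],
                                "FG": one.estimates["omega_by_class"]["BG"]},
                frequencies=spec.frequencies,
            ),
            n_starts=1,
        )
        assert two.log_likelihood >= one.log_likelihood - 1e-6

    def test_refit_from_optimum_is_stationary(self, six_taxon_labeled_tree):
        spec = CodonModelSpec(
            kappa=2.0, omega_by_class={"BG": 0.5}, frequencies=np.full(61, 1 / 61)
        )
        aln = simulate_codon_alignment(six_taxon_labeled_tree, spec, 150, seed=3)
        first = fit_model(aln, six_taxon_labeled_tree, spec, n_starts=1)
        refit_spec = CodonModelSpec(
            kappa=first.estimates["kappa"],
            omega_by_class=dict(first.estimates["omega_by_class"]),
            frequencies=spec.frequencies,
        )
        second = fit_model(aln, first.tree, refit_spec, n_starts=1)
        assert abs(second.log_likelihood - first.log_likelihood) < 1e-6 * abs(
            first.log_likelihood
        )

    def test_omega_recovery_moderate_data(self, six_taxon_labeled_tree):
        """A single 500-codon replicate recovers omega=0.5 within +-30%."""
        spec = CodonModelSpec(
            kappa=2.0, omega_by_class={"BG": 0.5}, frequencies=np.full(61, 1 / 61),
            frequency_mode="uniform",
        )
        aln = simulate_codon_alignment(six_taxon_labeled_tree, spec, 500, seed=42)
        fit = fit_model(
            aln, six_taxon_labeled_tree,
            CodonModelSpec(kappa=2.0, omega_by_class={"BG": 0.4},
                           frequencies=np.full(61, 1 / 61)),
            n_starts=1,
        )
        w = fit.estimates["omega_by_class"]["BG"]
        assert 0.35 < w < 0.65


class TestEstimateBranchLengths:
    def test_round_trip_recovers_lengths(self):
        tree = parse_newick(SIX_TAXON_NEWICK, name="t")
        spec = ProteinModelSpec()  # WAG, single rate
        aln = simulate_protein_alignment(tree, spec, 1000, seed=17)
        est = estimate_branch_lengths(aln, tree, spec, plus_f=False)
        true_t, est_t = [], []
        for node in tree.preorder():
            if node.parent is None:
                continue
            tips = frozenset(
                n.name for n in [node] if node.is_tip
            ) or frozenset(t for t in tree.tip_set(node))
            true_t.append((tips, node.length))
        est_map = {
            est.tip_set(n): n.length for n in est.preorder() if n.parent is not None
        }
        rel_errors = []
        for tips, t in true_t:
            rel_errors.append(abs(est_map[tips] - t) / t)
        assert np.mean(rel_errors) < 0.15

    def test_identical_sequences_collapse_branch(self):
        tree = parse_newick("((A:0.1,B:0.1):0.1,(C:0.2,D:0.2):0.1);", name="t")
        spec = ProteinModelSpec()
        aln = simulate_protein_alignment(tree, spec, 400, seed=5)
        # make B a copy of A: their connecting branches should go to ~0
        aln.sequences["B"] = aln.sequences["A"]
        est = estimate_branch_lengths(aln, tree, spec, plus_f=False)
        a = est.find_tip("A")
        b = est.find_tip("B")
        assert a.length + b.length < 1e-4

    def test_likelihood_ascends(self):
        tree = parse_newick(SIX_TAXON_NEWICK, name="t")
        spec = ProteinModelSpec()
        aln = simulate_protein_alignment(tree, spec, 300, seed=6)
        start = tree.copy()
        for n in start.preorder():
            if n.parent is not None:
                n.length = 0.05
        before = log_likelihood(aln, start, spec)
        est = estimate_branch_lengths(aln, start, spec, plus_f=False)
        after = log_likelihood(aln, est, spec)
        assert after >= before
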