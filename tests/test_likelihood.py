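"""Alignment I/O, Newick handling, pruning likelihood, and fixed-tree fitting."""

import itertools

import numpy as np
import pytest

from phylomodeltest.likelihood import (
    AlignmentData,
    AlignmentError,
    LikelihoodEngine,
    TreeError,
    log_likelihood,
    optimize_on_fixed_tree,
    read_alignment,
    read_newick,
    write_newick,
)
from phylomodeltest.simulate import SimulationSpec, random_tree, simulate_alignment
from phylomodeltest.substitution import SubstitutionModel

from conftest import brute_force_lnl


# ---------------------------------------------------------------------------
# alignment I/O
# ---------------------------------------------------------------------------

def test_fasta_round_trip(tmp_path):
    p = tmp_path / "toy.fasta"
    p.write_text(">A\nACGT\n>B\nAC-T\n")
    aln = read_alignment(p, "fasta")
    assert aln.taxa == ["A", "B"]
    assert aln.n_sites == 4
    assert aln.sequence("B") == "AC-T".replace("-", "N")


def test_format_sniffing(tmp_path):
    p = tmp_path / "toy.txt"
    p.write_text(">A\nACGT\n>B\nACGA\n")
    assert read_alignment(p).n_taxa == 2


def test_phylip_sequential(tmp_path):
    p = tmp_path / "toy.phy"
    p.write_text(" 4 10\nalpha  ACGTACGTAC\nbeta   ACGTACGTAA\n"
                 "gamma  ACGAACGTAC\ndelta  CCGTACGTAC\n")
    aln = read_alignment(p, "phylip")
    assert aln.n_taxa == 4 and aln.n_sites == 10
    assert aln.taxa[0] == "alpha"


def test_phylip_interleaved(tmp_path):
    p = tmp_path / "toy.phy"
    p.write_text(
        " 3 12\nA          ACGTAC\nB          ACGTAA\nC          ACGAAC\n\n"
        "GTACGT\nGTACGA\nGTACAA\n"
    )
    aln = read_alignment(p, "phylip")
    assert (aln.n_taxa, aln.n_sites) == (3, 12)
    assert aln.sequence("A") == "ACGTACGTACGT"


def test_ragged_rows_rejected():
    with pytest.raises(AlignmentError):
        AlignmentData.from_sequences(["A", "B"], ["ACGT", "ACG"])


def test_duplicate_taxa_rejected():
    with pytest.raises(AlignmentError):
        AlignmentData.from_sequences(["A", "A"], ["ACGT", "ACGT"])


def test_empty_file_rejected(tmp_path):
    p = tmp_path / "empty.fasta"
    p.write_text("")
    with pytest.raises(AlignmentError):
        read_alignment(p, "fasta")


def test_invalid_character_rejected():
    with pytest.raises(AlignmentError, match="invalid character"):
        AlignmentData.from_sequences(["A"], ["AC!T"])


def test_pattern_compression_bookkeeping():
    aln = AlignmentData.from_sequences(
        ["A", "B"], ["AACCA", "AAGGA"]
    )
    assert aln.pattern_weights.sum() == aln.n_sites
    assert aln.n_patterns == 2  # (A,A) and (C,G)


def test_empirical_freqs_positive_and_normalized():
    aln = AlignmentData.from_sequences(["A", "B"], ["AAAA", "AAAA"])
    f = aln.empirical_freqs()
    assert abs(f.sum() - 1.0) < 1e-12
    assert np.all(f > 0)  # C/G/T floored away from zero


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

def test_newick_round_trip():
    text = "((A:0.1,B:0.1):0.05,C:0.2,D:0.2);"
    tree = read_newick(text)
    assert sorted(tree.taxa()) == ["A", "B", "C", "D"]
    assert write_newick(read_newick(write_newick(tree))) == write_newick(tree)


def test_rooted_input_collapsed():
    tree = read_newick("((A:0.1,B:0.1):0.025,(C:0.2,D:0.2):0.025);")
    assert len(tree.root.children) == 3
    total = sum(n.length for n in tree.postorder() if n.parent is not None)
    assert abs(total - 0.65) < 1e-12


def test_branch_count_unrooted():
    tree = random_tree(8, seed=0)
    assert len(tree.edges()) == 2 * 8 - 3


def test_bad_newick_rejected():
    with pytest.raises(TreeError):
        read_newick("((A,B,C;")


def test_duplicate_leaf_labels_rejected():
    with pytest.raises(TreeError):
        read_newick("((A:1,A:1):1,B:1,C:1);")


# ---------------------------------------------------------------------------
# likelihood engine
# ---------------------------------------------------------------------------

def test_two_taxa_zero_length_identical_sites():
    tree = read_newick("(A:0.0,B:0.0);")
    aln = AlignmentData.from_sequences(["A", "B"], ["A", "A"])
    model = SubstitutionModel("111111", alpha=1e5)
    # branch lengths are floored at 1e-8, hence the slightly loose tolerance
    assert log_likelihood(tree, aln, model) == pytest.approx(np.log(0.25), abs=1e-7)


def test_two_taxa_jc_closed_form():
    t = 0.3
    tree = read_newick(f"(A:{t / 2},B:{t / 2});")
    model = SubstitutionModel("111111", alpha=1e7)  # effectively no rate het.
    same = 0.25 * (0.25 + 0.75 * np.exp(-4 * t / 3))
    diff = 0.25 * (0.25 - 0.25 * np.exp(-4 * t / 3))
    aln_same = AlignmentData.from_sequences(["A", "B"], ["G", "G"])
    aln_diff = AlignmentData.from_sequences(["A", "B"], ["G", "C"])
    assert log_likelihood(tree, aln_same, model) == pytest.approx(
        np.log(same), abs=1e-5
    )
    assert log_likelihood(tree, aln_diff, model) == pytest.approx(
        np.log(diff), abs=1e-5
    )


def test_matches_exhaustive_state_sum(quartet_tree, quartet_alignment, hky_model):
    expected = brute_force_lnl(quartet_tree, quartet_alignment, hky_model)
    got = log_likelihood(quartet_tree, quartet_alignment, hky_model)
    assert got == pytest.approx(expected, abs=1e-9)


def test_root_placement_invariance(small_sim):
    tree, model, aln = small_sim
    ref = log_likelihood(tree, aln, model)
    internal = [n for n in tree.postorder()
                if not n.is_leaf and n.parent is not None]
    assert internal
    for node in internal:
        t2 = tree.copy()
        nodes2 = list(t2.postorder())
        target = nodes2[list(tree.postorder()).index(node)]
        t2.reroot(target)
        assert log_likelihood(t2, aln, model) == pytest.approx(ref, abs=1e-8)


@pytest.mark.parametrize("n_taxa", [4, 5])
def test_pattern_probabilities_sum_to_one(n_taxa):
    tree = random_tree(n_taxa, seed=3, min_bl=0.05, max_bl=0.4)
    model = SubstitutionModel(
        "123456",
        free_rates=[0.8, 1.5, 2.5, 0.6, 3.0],
        freqs=[0.3, 0.2, 0.26, 0.24],
        alpha=0.7,
    )
    taxa = tree.taxa()
    total = 0.0
    for states in itertools.product("ACGT", repeat=n_taxa):
        aln = AlignmentData.from_sequences(taxa, [s for s in states])
        total += np.exp(log_likelihood(tree, aln, model))
    assert total == pytest.approx(1.0, abs=1e-10)


def test_pattern_compression_neutrality(small_sim):
    tree, model, aln = small_sim
    # recompute the likelihood site by site, bypassing compression entirely
    seqs = {t: aln.sequence(t) for t in aln.taxa}
    per_site = 0.0
    for s in range(0, aln.n_sites, 40):  # spot-check a spread of sites
        cols = AlignmentData.from_sequences(
            aln.taxa, [seqs[t][s] for t in aln.taxa]
        )
        per_site += log_likelihood(tree, cols, model)
    chunk = AlignmentData.from_sequences(
        aln.taxa, ["".join(seqs[t][s] for s in range(0, aln.n_sites, 40))
                   for t in aln.taxa]
    )
    assert log_likelihood(tree, chunk, model) == pytest.approx(per_site, abs=1e-8)


def test_ambiguity_codes_as_indicator_sums():
    tree = read_newick("(A:0.1,B:0.1);")
    model = SubstitutionModel("111111", alpha=1.0)
    l_n = log_likelihood(
        tree, AlignmentData.from_sequences(["A", "B"], ["N", "G"]), model
    )
    parts = [
        np.exp(log_likelihood(
            tree, AlignmentData.from_sequences(["A", "B"], [b, "G"]), model
        ))
        for b in "ACGT"
    ]
    assert np.exp(l_n) == pytest.approx(sum(parts), rel=1e-10)
    # R = A or G
    l_r = log_likelihood(
        tree, AlignmentData.from_sequences(["A", "B"], ["R", "G"]), model
    )
    assert np.exp(l_r) == pytest.approx(parts[0] + parts[2], rel=1e-10)


def test_taxon_mismatch_rejected(quartet_tree):
    aln = AlignmentData.from_sequences(["A", "B", "C", "X"], ["A", "C", "G", "T"])
    with pytest.raises(ValueError, match="match"):
        LikelihoodEngine(quartet_tree, aln)


# ---------------------------------------------------------------------------
# fixed-tree optimization
# ---------------------------------------------------------------------------

@pytest.mark.filterwarnings("ignore::UserWarning")
def test_branch_sweeps_monotone(small_sim):
    tree, model, aln = small_sim
    engine = LikelihoodEngine(tree.copy(), aln)
    engine.set_model(model)
    prev = engine.lnl()
    for _ in range(4):
        cur = engine.optimize_branch_lengths(sweeps=1)
        assert cur >= prev - 1e-9
        prev = cur


@pytest.mark.filterwarnings("ignore::UserWarning")
def test_fit_improves_and_params_counted(small_sim):
    tree, model, aln = small_sim
    fit = optimize_on_fixed_tree(tree, aln, "121121", "empirical",
                                 tol=1e-3, max_sweeps=10)
    assert np.isfinite(fit.lnL) and fit.lnL < 0
    # (k-1)=1 rate + alpha + 2T-3 = 9 branches
    assert fit.n_free_params == 1 + 1 + 9
    fit_ml = optimize_on_fixed_tree(tree, aln, "121121", "ml_estimated",
                                    tol=1e-3, max_sweeps=10)
    assert fit_ml.n_free_params == fit.n_free_params + 3
    assert fit_ml.lnL >= fit.lnL - 0.5  # ML freqs should not hurt much
    fit_nobl = optimize_on_fixed_tree(tree, aln, "121121", "empirical",
                                      tol=1e-3, max_sweeps=3,
                                      include_branch_lengths=False)
    assert fit_nobl.n_free_params == 2


@pytest.mark.filterwarnings("ignore::UserWarning")
def test_nested_model_lnl_ordering(small_sim):
    tree, _, aln = small_sim
    fits = {
        s: optimize_on_fixed_tree(tree, aln, s, "empirical",
                                  tol=1e-3, max_sweeps=8)
        for s in ["111111", "121121", "123456"]
    }
    assert fits["123456"].lnL >= fits["121121"].lnL - 1e-6
    assert fits["121121"].lnL >= fits["111111"].lnL - 1e-6


@pytest.mark.slow
@pytest.mark.filterwarnings("ignore::UserWarning")
def test_simulate_and_refit_recovers_lnl_and_alpha():
    true_tree = random_tree(10, seed=21, min_bl=0.05, max_bl=0.3)
    model = SubstitutionModel("111111", alpha=0.5)
    aln = simulate_alignment(SimulationSpec(true_tree, model, 5000, seed=4))
    truth_lnl = log_likelihood(true_tree, aln, model)
    fit = optimize_on_fixed_tree(true_tree, aln, "111111", "fixed_equal",
                                 tol=1e-3, max_sweeps=15)
    assert fit.lnL >= truth_lnl - 1e-6  # ML fit at least as good as truth
    assert fit.lnL - truth_lnl < 40  # same ballpark on 5000 sites
    assert 0.35 <= fit.model.alpha <= 0.7
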