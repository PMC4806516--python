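import numpy as np
import pytest

from phylomodeltest.likelihood import AlignmentData, read_newick
from phylomodeltest.simulate import (
    SimulationSpec,
    random_tree,
    simulate_alignment,
)
from phylomodeltest.substitution import SubstitutionModel


@pytest.fixture(scope="session")
def quartet_tree():
    return read_newick("((A:0.1,B:0.15):0.05,C:0.2,D:0.12);")


@pytest.fixture(scope="session")
def quartet_alignment():
    return AlignmentData.from_sequences(
        ["A", "B", "C", "D"],
        ["ACGTACGTAC", "ACGTACGAAC", "ACGAACGTTC", "CCGAACGTTC"],
    )


@pytest.fixture(scope="session")
def hky_model():
    return SubstitutionModel(
        "121121",
        free_rates=[4.0],
        freqs=[0.35, 0.15, 0.22, 0.28],
        alpha=0.6,
    )


@pytest.fixture(scope="session")
def small_sim():
    """6-taxon alignment simulated under HKY-like parameters, with its truth."""
    tree = random_tree(6, seed=11, min_bl=0.05, max_bl=0.3)
    model = SubstitutionModel(
        "121121", free_rates=[3.0], freqs=[0.3, 0.2, 0.2, 0.3], alpha=0.8
    )
    aln = simulate_alignment(SimulationSpec(tree, model, 800, seed=7))
    return tree, model, aln


def brute_force_lnl(tree, aln, model):
    """Exhaustive oracle: sum the Gamma-mixture likelihood over all internal
    state assignments, one site at a time, via naive recursion."""
    from phylomodeltest.substitution import (
        build_q,
        gamma_category_rates,
        transition_probs,
    )

    qm = build_q(model)
    cats = gamma_category_rates(model.alpha, model.ncat)
    code = {"A": 0, "C": 1, "G": 2, "T": 3}

    def site_like(leaf_states):
        total = 0.0
        for r in cats:
            def partial(node):
                if node.is_leaf:
                    v = np.zeros(4)
                    v[leaf_states[node.label]] = 1.0
                    return v
                out = np.ones(4)
                for c in node.children:
                    p = transition_probs(qm, c.length, r)
                    out *= p @ partial(c)
                return out

            total += model.freqs @ partial(tree.root) / len(cats)
        return total

    lnl = 0.0
    seqs = {t: aln.sequence(t) for t in aln.taxa}
    for s in range(aln.n_sites):
        states = {t: code[seqs[t][s]] for t in aln.taxa}
        lnl += np.log(site_like(states))
    return lnl
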