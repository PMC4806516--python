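"""Robinson-Foulds tree comparison and the cross-set significance procedure."""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .likelihood.trees import PhyloTree

__all__ = [
    "bipartitions",
    "rf_distance",
    "relative_rf",
    "branch_score",
    "significance_analysis",
    "SignificanceResult",
]


class TopologyError(ValueError):
    pass


def bipartitions(tree: PhyloTree, with_lengths: bool = False):
    """Nontrivial bipartitions induced by internal edges.

    Each bipartition is canonicalized as the frozenset of taxa on the side
    *not* containing the reference taxon (the lexicographically smallest
    label), so representations agree across differently rooted copies.
    """
    taxa = frozenset(tree.taxa())
    ref = min(taxa)
    out = {} if with_lengths else set()
    below: dict[int, frozenset] = {}
    for node in tree.postorder():
        if node.is_leaf:
            below[id(node)] = frozenset([node.label])
            continue
        clade = frozenset().union(*(below[id(c)] for c in node.children))
        below[id(node)] = clade
        if node.parent is None:
            continue
        side = clade if ref not in clade else taxa - clade
        if len(side) < 2 or len(side) > len(taxa) - 2:
            continue  # trivial split
        if with_lengths:
            out[side] = node.length or 0.0
        else:
            out.add(side)
    return out


def rf_distance(t1: PhyloTree, t2: PhyloTree) -> int:
    """Symmetric-difference size of the nontrivial bipartition sets."""
    if set(t1.taxa()) != set(t2.taxa()):
        raise TopologyError("trees have different leaf sets")
    return len(bipartitions(t1) ^ bipartitions(t2))


def relative_rf(t1: PhyloTree, t2: PhyloTree) -> float:
    """RF divided by its maximum 2*(T-3) for fully resolved trees."""
    n = t1.n_taxa()
    if n < 4:
        return 0.0
    return rf_distance(t1, t2) / (2.0 * (n - 3))


def branch_score(t1: PhyloTree, t2: PhyloTree) -> float:
    """Kuhner-Felsenstein branch score between two trees.

    Square root of summed squared branch-length differences over matched
    bipartitions (leaf edges matched by label); a bipartition present in only
    one tree contributes its full length.
    """
    if set(t1.taxa()) != set(t2.taxa()):
        raise TopologyError("trees have different leaf sets")

    def edge_lengths(tree):
        d = dict(bipartitions(tree, with_lengths=True))
        for leaf in tree.leaves():
            d[frozenset([leaf.label])] = leaf.length or 0.0
        return d

    e1, e2 = edge_lengths(t1), edge_lengths(t2)
    total = 0.0
    for key in e1.keys() | e2.keys():
        total += (e1.get(key, 0.0) - e2.get(key, 0.0)) ** 2
    return float(np.sqrt(total))


@dataclass
class SignificanceResult:
    mean_cross_rrf: float
    random_expectation: float
    p_value: float
    classification: str  # higher | lower | indistinguishable
    n_permutations: int


def significance_analysis(
    best_fit_trees: list[PhyloTree],
    gtr_trees: list[PhyloTree],
    n_permutations: int = 1000,
    seed: int = 0,
    alpha: float = 0.01,
) -> SignificanceResult:
    """Compare cross-set mean rRF against the within-baseline expectation.

    The random expectation is the mean rRF over all pairs of the baseline
    (GTR) tree set.  Significance comes from a two-sided permutation test
    that shuffles set labels over the pooled trees and recomputes the mean
    cross-set rRF.
    """
    if len(best_fit_trees) < 2 or len(gtr_trees) < 2:
        raise TopologyError("need at least 2 trees per set")
    pool = list(best_fit_trees) + list(gtr_trees)
    n1 = len(best_fit_trees)
    n = len(pool)
    # cache pairwise distances over the pool
    dist = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        dist[i, j] = dist[j, i] = relative_rf(pool[i], pool[j])

    def mean_cross(idx1, idx2):
        return float(dist[np.ix_(idx1, idx2)].mean())

    def mean_within(idx):
        if len(idx) < 2:
            return 0.0
        sub = dist[np.ix_(idx, idx)]
        m = len(idx)
        return float(sub.sum() / (m * (m - 1)))

    obs = mean_cross(range(n1), range(n1, n))
    expectation = mean_within(list(range(n1, n)))

    rng = np.random.default_rng(seed)
    ge = le = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        stat = mean_cross(perm[:n1], perm[n1:])
        if stat >= obs - 1e-15:
            ge += 1
        if stat <= obs + 1e-15:
            le += 1
    p_high = (ge + 1) / (n_permutations + 1)
    p_low = (le + 1) / (n_permutations + 1)
    p = min(1.0, 2.0 * min(p_high, p_low))

    if p < alpha and obs > expectation:
        cls = "higher"
    elif p < alpha and obs < expectation:
        cls = "lower"
    else:
        cls = "indistinguishable"
    return SignificanceResult(
        mean_cross_rrf=obs,
        random_expectation=expectation,
        p_value=p,
        classification=cls,
        n_permutations=n_permutations,
    )
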