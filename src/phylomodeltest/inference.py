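"""Starting-tree construction and ML tree search.

The starting tree is built by randomized stepwise addition under Fitch
parsimony; the ML search hill-climbs over nearest-neighbor-interchange (NNI)
neighborhoods with branch-length re-optimization at evaluated moves and full
parameter re-optimization at accepted moves.  All tie-breaking is
first-encountered in a fixed traversal order, so results are fully
deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .likelihood.alignment import AlignmentData
from .likelihood.engine import LikelihoodEngine
from .likelihood.optimize import FitResult, optimize_on_fixed_tree
from .likelihood.trees import DEFAULT_BRANCH_LENGTH, Node, PhyloTree

__all__ = [
    "SearchConfig",
    "fitch_score",
    "parsimony_start_tree",
    "nni_neighbors",
    "ml_search",
]


@dataclass
class SearchConfig:
    seed: int = 0
    max_rounds: int = 50
    move_set: str = "nni"
    nni_branch_sweeps: int = 1
    tol: float = 1e-3
    fit_kwargs: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Fitch parsimony
# ---------------------------------------------------------------------------

def _fitch(tree: PhyloTree, leaf_masks: dict[str, np.ndarray],
           weights: np.ndarray) -> int:
    """Vectorized Fitch count over compressed patterns.

    Multifurcations are resolved by sequential pairwise combination, which
    leaves the parsimony score unchanged (equivalent to inserting zero-length
    edges).
    """
    changes = np.zeros(len(weights), dtype=np.int64)
    states: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf:
            states[id(node)] = leaf_masks[node.label]
            continue
        acc = None
        for child in node.children:
            s = states[id(child)]
            if acc is None:
                acc = s
                continue
            inter = acc & s
            union = acc | s
            miss = inter == 0
            changes += miss
            acc = np.where(miss, union, inter)
        states[id(node)] = acc
    return int(changes @ weights)


def fitch_score(tree: PhyloTree, aln: AlignmentData) -> int:
    """Minimum number of state changes under Fitch parsimony."""
    if sorted(tree.taxa()) != sorted(aln.taxa):
        raise ValueError("tree taxa do not match alignment taxa")
    masks = {t: aln.patterns[i] for i, t in enumerate(aln.taxa)}
    return _fitch(tree, masks, aln.pattern_weights)


def parsimony_start_tree(aln: AlignmentData, seed: int = 0) -> PhyloTree:
    """Randomized stepwise-addition parsimony tree.

    Taxa are inserted in a seed-shuffled order, each at the first placement
    (in postorder over current edges) attaining the minimum Fitch score.
    """
    if aln.n_taxa < 3:
        raise ValueError("stepwise addition needs at least 3 taxa")
    rng = np.random.default_rng(seed)
    order = [aln.taxa[i] for i in rng.permutation(aln.n_taxa)]
    masks = {t: aln.patterns[i] for i, t in enumerate(aln.taxa)}
    weights = aln.pattern_weights

    root = Node()
    for taxon in order[:3]:
        root.add_child(Node(taxon))
    tree = PhyloTree(root)

    def insert_leaf(edge: Node, taxon: str) -> Node:
        """Split ``edge`` with a new internal node carrying a new leaf."""
        parent = edge.parent
        wedge = Node()
        parent.children[parent.children.index(edge)] = wedge
        wedge.parent = parent
        wedge.children = [edge]
        edge.parent = wedge
        leaf = Node(taxon)
        wedge.children.append(leaf)
        leaf.parent = wedge
        return wedge

    def remove_wedge(wedge: Node) -> None:
        parent = wedge.parent
        edge = wedge.children[0]
        parent.children[parent.children.index(wedge)] = edge
        edge.parent = parent

    for taxon in order[3:]:
        best_score = None
        best_edge = None
        edges = [n for n in tree.postorder() if n.parent is not None]
        for edge in edges:
            wedge = insert_leaf(edge, taxon)
            score = _fitch(tree, masks, weights)
            remove_wedge(wedge)
            if best_score is None or score < best_score:
                best_score, best_edge = score, edge
        insert_leaf(best_edge, taxon)

    for node in tree.postorder():
        if node.parent is not None:
            node.length = DEFAULT_BRANCH_LENGTH
    return tree


# ---------------------------------------------------------------------------
# NNI search
# ---------------------------------------------------------------------------

def nni_neighbors(tree: PhyloTree) -> list[PhyloTree]:
    """Both NNI rearrangements around every internal edge, as tree copies."""
    neighbors = []
    base = list(tree.postorder())
    internal_edges = [
        i for i, n in enumerate(base)
        if n.parent is not None and not n.is_leaf
    ]
    for idx in internal_edges:
        for which in (0, 1):
            t = tree.copy()
            nodes = list(t.postorder())
            v = nodes[idx]
            u = v.parent
            w = next(c for c in u.children if c is not v)
            c = v.children[which]
            v.remove_child(c)
            u.remove_child(w)
            v.add_child(w)
            u.add_child(c)
            neighbors.append(t)
    return neighbors


def ml_search(
    start: PhyloTree,
    aln: AlignmentData,
    model_string: str,
    freq_mode: str = "empirical",
    config: SearchConfig | None = None,
) -> FitResult:
    """NNI hill climbing from ``start`` under one substitution model.

    Each candidate neighbor is scored with branch lengths re-optimized under
    the current model parameters; an accepted move triggers a full parameter
    re-optimization.  Terminates when no neighbor improves the lnL by more
    than ``config.tol``.
    """
    if config is None:
        config = SearchConfig()
    if config.move_set != "nni":
        raise ValueError(f"unsupported move set {config.move_set!r}")

    current = optimize_on_fixed_tree(
        start, aln, model_string, freq_mode, **config.fit_kwargs
    )

    for _ in range(config.max_rounds):
        best_lnl = current.lnL
        best_tree = None
        for neighbor in nni_neighbors(current.tree):
            engine = LikelihoodEngine(neighbor, aln)
            engine.set_model(current.model)
            lnl = engine.optimize_branch_lengths(sweeps=config.nni_branch_sweeps)
            if lnl > best_lnl + config.tol:
                best_lnl = lnl
                best_tree = neighbor
        if best_tree is None:
            break
        refit = optimize_on_fixed_tree(
            best_tree, aln, model_string, freq_mode,
            initial_model=current.model, **config.fit_kwargs,
        )
        if refit.lnL < best_lnl:  # keep the branch-optimized evaluation
            refit = FitResult(
                model=current.model, tree=best_tree, lnL=best_lnl,
                n_free_params=current.n_free_params,
            )
        current = refit
    return current
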