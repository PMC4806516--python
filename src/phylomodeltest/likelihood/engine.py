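"""Felsenstein pruning likelihood with a discrete-Gamma mixture.

The engine caches site-pattern indicator vectors and the node traversal order
for one (tree, alignment) pair.  Partial likelihoods are stored flattened as
(n_patterns, ncat*4) with the Gamma categories side by side, so crossing an
edge is a single GEMM against a block-diagonal transition matrix built from
one symmetric eigendecomposition of the scaled reversible generator.
Per-pattern log scalers (shared across categories) guard against underflow.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize_scalar

from ..substitution import SubstitutionModel, build_q, gamma_category_rates
from .alignment import AlignmentData
from .trees import PhyloTree

__all__ = ["LikelihoodEngine", "log_likelihood"]

MIN_BRANCH_LENGTH = 1e-8
MAX_BRANCH_LENGTH = 20.0

_LEAF_PARTIALS = np.array(
    [[(m >> b) & 1 for b in range(4)] for m in range(16)], dtype=float
)


class LikelihoodEngine:
    """Likelihood of one alignment on one (fixed-topology) tree."""

    def __init__(self, tree: PhyloTree, aln: AlignmentData):
        if sorted(tree.taxa()) != sorted(aln.taxa):
            raise ValueError(
                f"tree taxa {sorted(tree.taxa())} do not match "
                f"alignment taxa {sorted(aln.taxa)}"
            )
        self.tree = tree
        self.aln = aln
        self.weights = aln.pattern_weights.astype(float)
        self._leaf_raw = {
            taxon: _LEAF_PARTIALS[aln.patterns[i]]  # (npat, 4)
            for i, taxon in enumerate(aln.taxa)
        }
        self._leaf_codes = {
            taxon: aln.patterns[i] for i, taxon in enumerate(aln.taxa)
        }
        self._leaf_flat: dict[str, np.ndarray] = {}
        self._mask_flat = None  # (16, ncat*4) indicator rows per IUPAC mask
        self._refresh_traversal()
        self.model: SubstitutionModel | None = None
        self._qm = None
        self._cat_rates = None
        self._pi_flat = None
        #: multiplies every branch length; used transiently during fitting
        self.rate_scale = 1.0

    # -- bookkeeping --------------------------------------------------------

    def _refresh_traversal(self) -> None:
        self._postorder = list(self.tree.postorder())
        self._buf_pool: dict[str, np.ndarray] = {}

    def _buf(self, key: str) -> np.ndarray:
        """Reusable (npat, ncat*4) scratch buffer; avoids allocator churn."""
        buf = self._buf_pool.get(key)
        shape = (self.aln.n_patterns, 4 * self.model.ncat)
        if buf is None or buf.shape != shape:
            buf = np.empty(shape)
            self._buf_pool[key] = buf
        return buf

    def _cross_edge_out(self, node, down: dict, pm: np.ndarray,
                        out: np.ndarray) -> np.ndarray:
        """``down[node] @ pm`` into ``out``; leaf case gathers pm rows."""
        if node.is_leaf:
            np.take(self._mask_flat @ pm, self._leaf_codes[node.label],
                    axis=0, out=out)
            return out
        return np.matmul(down[id(node)], pm, out=out)

    def set_model(self, model: SubstitutionModel) -> None:
        ncat = model.ncat
        if self.model is None or self.model.ncat != ncat:
            self._leaf_flat = {
                t: np.tile(p, (1, ncat)) for t, p in self._leaf_raw.items()
            }
            self._mask_flat = np.tile(_LEAF_PARTIALS, (1, ncat))
        self.model = model
        self._qm = build_q(model)
        self._cat_rates = gamma_category_rates(model.alpha, ncat)
        self._pi_flat = np.tile(model.freqs, ncat)

    def _pmat_flat(self, t: float) -> np.ndarray:
        """Block-diagonal (ncat*4, ncat*4) matrix holding P(t r_c)^T blocks."""
        t_eff = max(t, MIN_BRANCH_LENGTH) * self.rate_scale
        p = self._qm.expm_multi(self._cat_rates * t_eff)
        np.maximum(p, 0.0, out=p)
        ncat = self.model.ncat
        blk = np.zeros((4 * ncat, 4 * ncat))
        for c in range(ncat):
            blk[4 * c : 4 * c + 4, 4 * c : 4 * c + 4] = p[c].T
        return blk

    def _pmat_flat_batch(self, edges) -> dict[int, np.ndarray]:
        """Transposed block transition matrices for many edges in one shot."""
        ncat = self.model.ncat
        ts = np.array(
            [max(e.length, MIN_BRANCH_LENGTH) for e in edges]
        ) * self.rate_scale
        t_eff = np.multiply.outer(ts, self._cat_rates)  # (E, ncat)
        qm = self._qm
        lam = np.exp(t_eff[:, :, None] * qm.eigvals[None, None, :])
        p = np.einsum("ij,ecj,jk->ecik", qm._left, lam, qm._right)
        np.maximum(p, 0.0, out=p)
        blk = np.zeros((len(edges), 4 * ncat, 4 * ncat))
        for c in range(ncat):
            blk[:, 4 * c : 4 * c + 4, 4 * c : 4 * c + 4] = (
                p[:, c].transpose(0, 2, 1)
            )
        return {id(e): blk[i] for i, e in enumerate(edges)}

    def apply_rate_scale(self) -> None:
        """Fold the current rate_scale into the stored branch lengths."""
        if self.rate_scale != 1.0:
            for n in self._postorder:
                if n.parent is not None:
                    n.length = max(n.length * self.rate_scale, MIN_BRANCH_LENGTH)
            self.rate_scale = 1.0

    # -- core recursions ----------------------------------------------------

    def _down_pass(self):
        """Postorder conditional likelihoods below every node.

        Returns (down, scaler, pmats) keyed by node id; ``down`` holds
        (npat, ncat*4) arrays, ``scaler`` per-pattern log factors, ``pmats``
        the transposed block transition matrix of each edge.
        """
        down: dict[int, np.ndarray] = {}
        scaler: dict[int, object] = {}  # float 0.0 or (npat,) array
        pmats = self._pmat_flat_batch(
            [n for n in self._postorder if n.parent is not None]
        )
        scratch = self._buf("down_scratch")
        for i, node in enumerate(self._postorder):
            if node.is_leaf:
                down[id(node)] = self._leaf_flat[node.label]
                scaler[id(node)] = 0.0
                continue
            acc = self._buf(f"down_{i}")
            sc = 0.0
            for j, child in enumerate(node.children):
                target = acc if j == 0 else scratch
                contrib = self._cross_edge_out(child, down,
                                               pmats[id(child)], target)
                if j > 0:
                    np.multiply(acc, contrib, out=acc)
                sc = sc + scaler[id(child)]
            if acc.max() < 1e-120:  # rescale only when drifting toward underflow
                m = acc.max(axis=1)
                np.maximum(m, 1e-300, out=m)
                acc /= m[:, None]
                sc = sc + np.log(m)
            down[id(node)] = acc
            scaler[id(node)] = sc
        return down, scaler, pmats

    def _root_lnl(self, down, scaler) -> float:
        root = self.tree.root
        site = (down[id(root)] @ self._pi_flat) / self.model.ncat
        return float(
            self.weights @ (np.log(np.maximum(site, 1e-300)) + scaler[id(root)])
        )

    def lnl(self) -> float:
        """Log-likelihood under the current model and branch lengths."""
        down, scaler, _ = self._down_pass()
        return self._root_lnl(down, scaler)

    def _up_pass(self, down, scaler, pmats):
        """Preorder partials of everything *outside* each node's subtree."""
        up: dict[int, np.ndarray] = {}
        upsc: dict[int, object] = {}
        counter = 0
        for idx, node in enumerate(self.tree.preorder()):
            if node.is_leaf:
                continue
            if node.parent is None:
                above = None  # identity: nothing above the root
                above_sc = 0.0
            else:
                above = np.matmul(up[id(node)], pmats[id(node)],
                                  out=self._buf(f"up_above_{idx}"))
                above_sc = upsc[id(node)]
            contribs = [
                self._cross_edge_out(c, down, pmats[id(c)],
                                     self._buf(f"up_ctr_{j}"))
                for j, c in enumerate(node.children)
            ]
            for child in node.children:
                g = self._buf(f"up_{counter}")
                counter += 1
                gsc = above_sc
                parts = [] if above is None else [above]
                for l, other in enumerate(node.children):
                    if other is child:
                        continue
                    parts.append(contribs[l])
                    gsc = gsc + scaler[id(other)]
                if len(parts) == 1:
                    np.copyto(g, parts[0])
                else:
                    np.multiply(parts[0], parts[1], out=g)
                    for extra in parts[2:]:
                        np.multiply(g, extra, out=g)
                if g.max() < 1e-120:
                    m = g.max(axis=1)
                    np.maximum(m, 1e-300, out=m)
                    g /= m[:, None]
                    gsc = gsc + np.log(m)
                up[id(child)] = g
                upsc[id(child)] = gsc
        return up, upsc

    # -- branch-length optimization -----------------------------------------

    def _edge_lnl_fn(self, edge, down, scaler, up, upsc):
        """Log-likelihood as a function of one branch length."""
        g = np.multiply(up[id(edge)], self._pi_flat[None, :],
                        out=self._buf("edge_g"))
        const_sc = scaler[id(edge)] + upsc[id(edge)]
        ncat = self.model.ncat
        tmp = self._buf("edge_tmp")

        def fn(t: float) -> float:
            across = self._cross_edge_out(edge, down, self._pmat_flat(t), tmp)
            np.multiply(across, g, out=across)
            site = across.sum(axis=1) / ncat
            return float(
                self.weights @ (np.log(np.maximum(site, 1e-300)) + const_sc)
            )

        return fn

    def optimize_branch_lengths(self, sweeps: int = 1, xtol: float = 1e-4,
                                exact: bool = False) -> float:
        """Brent-optimize each branch in turn; returns the final lnL.

        In the default (fast) mode the partials are computed once per sweep,
        so later branches in a sweep see slightly stale neighbors — a Jacobi-
        style update.  If a fast sweep ever lowers the likelihood it is rolled
        back and redone exactly (partials refreshed before every branch), which
        keeps the result monotone.  ``exact=True`` forces the slow path.
        """
        edges = [n for n in self._postorder if n.parent is not None]
        lnl = None
        for _ in range(sweeps):
            old_lengths = [e.length for e in edges]
            start_lnl = None
            for edge in edges:
                if exact or start_lnl is None:
                    down, scaler, pmats = self._down_pass()
                    up, upsc = self._up_pass(down, scaler, pmats)
                fn = self._edge_lnl_fn(edge, down, scaler, up, upsc)
                current = fn(edge.length)
                if start_lnl is None:
                    start_lnl = current
                res = minimize_scalar(
                    lambda t: -fn(t),
                    bounds=(MIN_BRANCH_LENGTH, MAX_BRANCH_LENGTH),
                    method="bounded",
                    options={"xatol": xtol, "maxiter": 20},
                )
                if -res.fun > current:
                    edge.length = float(res.x)
                    if exact:
                        lnl = float(-res.fun)
            if not exact:
                lnl = self.lnl()
                if lnl < start_lnl:
                    for e, t in zip(edges, old_lengths):
                        e.length = t
                    lnl = self.optimize_branch_lengths(
                        sweeps=1, xtol=xtol, exact=True
                    )
        return self.lnl() if lnl is None else lnl


def log_likelihood(tree: PhyloTree, aln: AlignmentData, model: SubstitutionModel) -> float:
    """One-shot pruning log-likelihood (builds a throwaway engine)."""
    engine = LikelihoodEngine(tree, aln)
    engine.set_model(model)
    return engine.lnl()
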