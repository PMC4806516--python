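"""Coordinate-ascent model fitting on a fixed tree topology."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from ..substitution import SubstitutionModel
from .alignment import AlignmentData
from .engine import LikelihoodEngine
from .trees import PhyloTree, DEFAULT_BRANCH_LENGTH

__all__ = ["FitResult", "optimize_on_fixed_tree", "ConvergenceWarning"]

_LOG_RATE_BOUNDS = (np.log(1e-4), np.log(1e4))
_LOG_ALPHA_BOUNDS = (np.log(0.02), np.log(100.0))
_FREQ_BOUNDS = (-15.0, 15.0)


class ConvergenceWarning(UserWarning):
    pass


@dataclass
class FitResult:
    model: SubstitutionModel
    tree: PhyloTree
    lnL: float
    n_free_params: int
    n_sweeps: int = 0
    converged: bool = True


def _pack(model: SubstitutionModel, opt_freqs: bool) -> np.ndarray:
    x = list(np.log(model.free_rates)) + [np.log(model.alpha)]
    if opt_freqs:
        x += list(np.log(model.freqs[:3] / model.freqs[3]))
    return np.array(x)


def _unpack(x: np.ndarray, model: SubstitutionModel, opt_freqs: bool) -> SubstitutionModel:
    n_rates = len(model.free_rates)
    free_rates = np.exp(x[:n_rates])
    alpha = float(np.exp(x[n_rates]))
    if opt_freqs:
        z = np.concatenate([x[n_rates + 1 :], [0.0]])
        z -= z.max()
        freqs = np.exp(z)
        freqs /= freqs.sum()
    else:
        freqs = model.freqs
    return SubstitutionModel(
        model_string=model.model_string,
        free_rates=free_rates,
        freqs=freqs,
        alpha=alpha,
        freq_mode=model.freq_mode,
        ncat=model.ncat,
    )


def _optimize_parameters(engine: LikelihoodEngine, opt_freqs: bool,
                         maxiter: int = 60) -> float:
    """Jointly optimize rates, alpha, (freqs,) and a global branch scale.

    The scale multiplies every branch length; folding it into the joint
    optimization absorbs the strong tree-length/alpha/rates coupling that
    otherwise forces many coordinate-ascent sweeps.
    """
    model = engine.model
    x0 = np.concatenate([_pack(model, opt_freqs), [0.0]])  # trailing log-scale
    n_rates = len(model.free_rates)
    bounds = (
        [_LOG_RATE_BOUNDS] * n_rates
        + [_LOG_ALPHA_BOUNDS]
        + ([_FREQ_BOUNDS] * 3 if opt_freqs else [])
        + [(-3.0, 3.0)]
    )

    def objective(x):
        engine.set_model(_unpack(x[:-1], model, opt_freqs))
        engine.rate_scale = float(np.exp(x[-1]))
        return -engine.lnl()

    baseline = -objective(x0)
    res = minimize(
        objective, x0, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": maxiter, "ftol": 1e-10},
    )
    if -res.fun >= baseline:
        objective(res.x)
        engine.apply_rate_scale()
        return float(-res.fun)
    engine.set_model(model)
    engine.rate_scale = 1.0
    return float(baseline)


def _project_rates(model_string: str, initial: "SubstitutionModel") -> "np.ndarray":
    """Warm-start rates for one model from another's fitted exchangeabilities.

    Each tie class takes the mean of the donor's rates over its positions,
    rescaled so the class containing GT is 1.
    """
    from ..model_space import normalize
    from ..substitution import rate_classes

    target = normalize(model_string)
    donor = initial.rates  # expanded 6-vector
    free_classes, fixed = rate_classes(target)
    means = {
        d: float(np.mean([donor[i] for i in range(6) if target[i] == d]))
        for d in set(target)
    }
    return np.array([means[d] / means[fixed] for d in free_classes])


def optimize_on_fixed_tree(
    tree: PhyloTree,
    aln: AlignmentData,
    model_string: str,
    freq_mode: str = "empirical",
    *,
    alpha0: float = 1.0,
    tol: float = 1e-4,
    max_sweeps: int = 25,
    include_branch_lengths: bool = True,
    optimize_branches: bool = True,
    initial_model: SubstitutionModel | None = None,
    param_maxiter: int = 60,
) -> FitResult:
    """Fit all free parameters of one substitution model on a fixed topology.

    Alternates bounded quasi-Newton optimization of the substitution
    parameters (log-rates, log-alpha, frequency logits when ``freq_mode`` is
    ``ml_estimated``) with per-branch Brent sweeps until the lnL gain of a
    full sweep drops below ``tol``.  The topology is never modified.
    """
    tree = tree.copy()
    tree.set_default_branch_lengths(DEFAULT_BRANCH_LENGTH)
    engine = LikelihoodEngine(tree, aln)

    if initial_model is not None:
        model = SubstitutionModel(
            model_string=model_string,
            free_rates=_project_rates(model_string, initial_model),
            freqs=initial_model.freqs,
            alpha=initial_model.alpha,
            freq_mode=freq_mode,
            ncat=initial_model.ncat,
        )
    else:
        if freq_mode == "fixed_equal":
            freqs = np.full(4, 0.25)
        else:
            freqs = aln.empirical_freqs()
        model = SubstitutionModel(
            model_string=model_string, freqs=freqs, alpha=alpha0,
            freq_mode=freq_mode,
        )
    engine.set_model(model)

    opt_freqs = freq_mode == "ml_estimated"
    lnl = engine.lnl()
    converged = False
    sweep = 0
    for sweep in range(1, max_sweeps + 1):
        # later sweeps only polish parameters near the optimum
        it = param_maxiter if sweep == 1 else min(param_maxiter, 10)
        lnl_new = _optimize_parameters(engine, opt_freqs, maxiter=it)
        if optimize_branches:
            lnl_new = engine.optimize_branch_lengths(sweeps=1)
        if lnl_new - lnl < tol:
            lnl = max(lnl, lnl_new)
            converged = True
            break
        lnl = lnl_new
    if not converged:
        warnings.warn(
            f"model {model_string}: no convergence after {max_sweeps} sweeps",
            ConvergenceWarning,
            stacklevel=2,
        )
    fitted = engine.model
    return FitResult(
        model=fitted,
        tree=tree,
        lnL=lnl,
        n_free_params=fitted.n_free_params(aln.n_taxa, include_branch_lengths),
        n_sweeps=sweep,
        converged=converged,
    )
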