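"""Information-criterion scoring and best-model selection over all 203 models.

Five criterion variants are supported: AIC, AICc-S, AICc-M, BIC-S, BIC-M,
where S uses the number of alignment sites as sample size and M uses
sites x taxa.  Per-criterion minima live in mergeable :class:`ResultList`
objects whose merge is associative, commutative, and tie-broken by the
lexicographically smaller model string — so results are invariant to
evaluation order and worker count.
"""

from __future__ import annotations

import math
import warnings
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field

import pandas as pd

from .likelihood.alignment import AlignmentData
from .likelihood.optimize import FitResult, optimize_on_fixed_tree
from .likelihood.trees import PhyloTree
from .model_space import k_of, sorted_models

__all__ = [
    "CRITERIA",
    "CriterionSpec",
    "ResultList",
    "sample_size",
    "criterion_score",
    "merge_results",
    "evaluate_all_models",
]

CRITERIA = ("AIC", "AICc-S", "AICc-M", "BIC-S", "BIC-M")


class SelectionError(ValueError):
    pass


@dataclass(frozen=True)
class CriterionSpec:
    family: str             # AIC | AICc | BIC
    sample_size_mode: str | None  # 'S' | 'M' | None

    @classmethod
    def from_name(cls, name: str) -> "CriterionSpec":
        if name == "AIC":
            return cls("AIC", None)
        try:
            family, mode = name.split("-")
        except ValueError:
            raise SelectionError(f"unknown criterion {name!r}") from None
        if family not in ("AICc", "BIC") or mode not in ("S", "M"):
            raise SelectionError(f"unknown criterion {name!r}")
        return cls(family, mode)


def sample_size(mode: str | None, sites: int, taxa: int) -> int:
    if sites < 1 or taxa < 1:
        raise SelectionError("sites and taxa must be >= 1")
    if mode == "S":
        return sites
    if mode == "M":
        return sites * taxa
    raise SelectionError(f"unknown sample size mode {mode!r}")


def criterion_score(spec: CriterionSpec, lnL: float, n_free: int,
                    n_sample: int | None = None) -> float:
    """Score under one criterion; NaN when AICc is undefined (n <= k+1)."""
    aic = 2.0 * n_free - 2.0 * lnL
    if spec.family == "AIC":
        return aic
    if n_sample is None:
        raise SelectionError(f"{spec.family} requires a sample size")
    if spec.family == "AICc":
        denom = n_sample - n_free - 1
        if denom <= 0:
            return math.nan
        return aic + 2.0 * n_free * (n_free + 1) / denom
    if spec.family == "BIC":
        return n_free * math.log(n_sample) - 2.0 * lnL
    raise SelectionError(f"unknown family {spec.family!r}")


@dataclass
class Entry:
    score: float
    model: str
    fit: FitResult | None = None


@dataclass
class ResultList:
    """Per-criterion running minima of (score, model) pairs."""

    criteria: tuple[str, ...] = CRITERIA
    best: dict[str, Entry | None] = field(default_factory=dict)

    def __post_init__(self):
        for c in self.criteria:
            self.best.setdefault(c, None)

    def update(self, criterion: str, score: float, model: str,
               fit: FitResult | None = None) -> None:
        if criterion not in self.best:
            raise SelectionError(f"criterion {criterion!r} not tracked")
        if math.isnan(score):
            return
        cur = self.best[criterion]
        if (
            cur is None
            or score < cur.score
            or (score == cur.score and model < cur.model)
        ):
            self.best[criterion] = Entry(score, model, fit)

    def winners(self) -> dict[str, str | None]:
        return {c: (e.model if e else None) for c, e in self.best.items()}


def merge_results(a: ResultList, b: ResultList) -> ResultList:
    if a.criteria != b.criteria:
        raise SelectionError("criterion sets differ")
    out = ResultList(criteria=a.criteria)
    for rl in (a, b):
        for c, e in rl.best.items():
            if e is not None:
                out.update(c, e.score, e.model, e.fit)
    return out


def _score_row(criteria, fit: FitResult, sites: int, taxa: int) -> dict:
    row = {
        "model_string": fit.model.model_string,
        "k": k_of(fit.model.model_string),
        "n_free": fit.n_free_params,
        "lnL": fit.lnL,
    }
    for name in criteria:
        spec = CriterionSpec.from_name(name)
        n = None
        if spec.sample_size_mode is not None:
            n = sample_size(spec.sample_size_mode, sites, taxa)
        score = criterion_score(spec, fit.lnL, fit.n_free_params, n)
        if math.isnan(score):
            warnings.warn(
                f"{name} undefined for model {fit.model.model_string} "
                f"(n={n} <= n_free+1={fit.n_free_params + 1}); excluded",
                stacklevel=2,
            )
        row[name] = score
    return row


# module-level state for worker processes (set once per pool via initializer)
_WORKER_CTX: dict = {}


def _init_worker(tree_newick, aln_taxa, aln_seqs, freq_mode, fit_kwargs,
                 initial_params):
    from .likelihood.trees import read_newick
    from .substitution import SubstitutionModel

    _WORKER_CTX["tree"] = read_newick(tree_newick)
    _WORKER_CTX["aln"] = AlignmentData.from_sequences(aln_taxa, aln_seqs)
    _WORKER_CTX["freq_mode"] = freq_mode
    _WORKER_CTX["fit_kwargs"] = fit_kwargs
    _WORKER_CTX["initial"] = (
        SubstitutionModel(**initial_params) if initial_params else None
    )


def _fit_one(model_string: str) -> FitResult:
    return optimize_on_fixed_tree(
        _WORKER_CTX["tree"],
        _WORKER_CTX["aln"],
        model_string,
        _WORKER_CTX["freq_mode"],
        initial_model=_WORKER_CTX["initial"],
        **_WORKER_CTX["fit_kwargs"],
    )


def evaluate_all_models(
    aln: AlignmentData,
    tree: PhyloTree,
    freq_mode: str = "empirical",
    workers: int = 1,
    models: list[str] | None = None,
    criteria: tuple[str, ...] = CRITERIA,
    warm_start: bool = True,
    **fit_kwargs,
) -> tuple[ResultList, pd.DataFrame]:
    """Fit every model on the fixed tree and rank under all criteria.

    With ``warm_start`` (default) a GTR pilot fit is computed first and its
    branch lengths, frequencies, alpha, and tie-class-averaged rates seed
    every other model's optimization — a deterministic preprocessing step, so
    results stay identical for any ``workers`` value: fits are independent
    tasks and the reduction is a merge of minima.

    Returns the mergeable per-criterion minima plus the full score table
    (one row per model).
    """
    if workers < 1:
        raise SelectionError("workers must be >= 1")
    if models is None:
        models = sorted_models()

    gtr_fit = None
    initial = None
    base_tree = tree
    if warm_start:
        # the pilot starts cold, so give it fuller optimization settings
        pilot_kwargs = dict(fit_kwargs)
        pilot_kwargs["max_sweeps"] = max(6, fit_kwargs.get("max_sweeps", 25))
        pilot_kwargs["param_maxiter"] = max(30, fit_kwargs.get("param_maxiter", 60))
        gtr_fit = optimize_on_fixed_tree(tree, aln, "123456", freq_mode,
                                         **pilot_kwargs)
        base_tree = gtr_fit.tree
        initial = gtr_fit.model

    fits: list[FitResult] = []
    if workers == 1:
        for m in models:
            if gtr_fit is not None and m == "123456":
                fits.append(gtr_fit)
                continue
            fits.append(
                optimize_on_fixed_tree(base_tree, aln, m, freq_mode,
                                       initial_model=initial, **fit_kwargs)
            )
    else:
        seqs = [aln.sequence(t) for t in aln.taxa]
        initial_params = None
        if initial is not None:
            initial_params = dict(
                model_string=initial.model_string,
                free_rates=list(initial.free_rates),
                freqs=list(initial.freqs),
                alpha=initial.alpha,
                freq_mode=initial.freq_mode,
                ncat=initial.ncat,
            )
        init_args = (base_tree.to_newick(), aln.taxa, seqs, freq_mode,
                     fit_kwargs, initial_params)
        with ProcessPoolExecutor(
            max_workers=workers, initializer=_init_worker, initargs=init_args
        ) as pool:
            futures = {m: pool.submit(_fit_one, m) for m in models}
            for m in models:
                if gtr_fit is not None and m == "123456":
                    futures[m].cancel()
                    fits.append(gtr_fit)
                    continue
                try:
                    fits.append(futures[m].result())
                except Exception:
                    # one retry in-process, then give up
                    fits.append(
                        optimize_on_fixed_tree(base_tree, aln, m, freq_mode,
                                               initial_model=initial,
                                               **fit_kwargs)
                    )

    results = ResultList(criteria=tuple(criteria))
    rows = []
    for fit in fits:
        row = _score_row(criteria, fit, aln.n_sites, aln.n_taxa)
        rows.append(row)
        for name in criteria:
            results.update(name, row[name], row["model_string"], fit)
    table = pd.DataFrame(rows).sort_values(["k", "model_string"]).reset_index(drop=True)
    return results, table
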