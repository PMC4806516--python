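"""Enumeration of the 203 non-redundant time-reversible nucleotide model strings.

A model string is six digits over {1..6}, one per rate position in the fixed
order (AC, AG, AT, CG, CT, GT); positions sharing a digit have their
exchangeability rates constrained equal.  Two strings are semantically
identical when they induce the same partition of the six positions, so each
equivalence class is represented by a unique *normalized* string (a
restricted-growth string).  Two independent generators of the full set are
provided: a brute-force enumerator (optionally prefix-restricted) and an
inductive character-replacement algorithm.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

__all__ = [
    "RATE_POSITIONS",
    "ModelSet",
    "is_valid",
    "is_normalized",
    "normalize",
    "k_of",
    "k_prefix",
    "tie_partition",
    "phase1_models",
    "phase2_expansions",
    "derive_models",
    "enumerate_brute_force",
    "generate_inductive",
    "to_engine_string",
    "sorted_models",
    "write_model_strings",
]

#: Rate position order used throughout: indices into the model string.
RATE_POSITIONS = ("AC", "AG", "AT", "CG", "CT", "GT")

_ALPHABET = frozenset("123456")


class ModelStringError(ValueError):
    """Raised for malformed or non-normalized model strings."""


def _check(s: str) -> str:
    if not isinstance(s, str) or len(s) != 6 or not set(s) <= _ALPHABET:
        raise ModelStringError(
            f"model string must be 6 characters over {{1..6}}, got {s!r}"
        )
    return s


@dataclass
class ModelSet:
    """Result of a full model-space enumeration.

    Attributes
    ----------
    models : set of str
        All normalized, pairwise-distinct model strings.
    per_k_counts : dict
        Number of models per count of distinct rates ``k``.
    enumerated_candidates : int
        Raw strings inspected by the producing algorithm.
    """

    models: set[str] = field(default_factory=set)
    per_k_counts: dict[int, int] = field(default_factory=dict)
    enumerated_candidates: int = 0

    @property
    def n_redundant(self) -> int:
        return self.enumerated_candidates - len(self.models)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return len(self.models)


def is_valid(s: str) -> bool:
    try:
        _check(s)
    except ModelStringError:
        return False
    return True


def is_normalized(s: str) -> bool:
    """True iff every first occurrence of a digit v is preceded by exactly {1..v-1}."""
    _check(s)
    seen: set[int] = set()
    for ch in s:
        v = int(ch)
        if v not in seen:
            if seen != set(range(1, v)):
                return False
            seen.add(v)
    return True


def normalize(s: str) -> str:
    """Canonical representative of the tie partition induced by ``s``.

    Digits are re-assigned incrementally from 1 in order of each tie class's
    leftmost position, which is exactly the restricted-growth normal form.
    """
    _check(s)
    mapping: dict[str, str] = {}
    out = []
    for ch in s:
        if ch not in mapping:
            mapping[ch] = str(len(mapping) + 1)
        out.append(mapping[ch])
    return "".join(out)


def k_of(s: str) -> int:
    """Number of distinct substitution rates of the model."""
    _check(s)
    return len(set(s))


def k_prefix(s: str) -> str:
    """Shortest prefix of a k-model containing all k digit values.

    Defined whenever the digit set is exactly {1..k} (true for every
    normalized string, but also for near-normal strings like 124311).
    """
    _check(s)
    k = k_of(s)
    need = set(str(d) for d in range(1, k + 1))
    if set(s) != need:
        raise ModelStringError(
            f"k_prefix requires digit set {{1..{k}}}, got {s!r}"
        )
    seen: set[str] = set()
    for i, ch in enumerate(s):
        seen.add(ch)
        if seen == need:
            return s[: i + 1]
    raise AssertionError("unreachable")  # pragma: no cover


def tie_partition(s: str) -> frozenset[frozenset[int]]:
    """Partition of position indices {0..5} into classes of tied rates."""
    _check(s)
    classes: dict[str, list[int]] = {}
    for i, ch in enumerate(s):
        classes.setdefault(ch, []).append(i)
    return frozenset(frozenset(v) for v in classes.values())


def phase1_models(s: str) -> list[str]:
    """Phase 1 of the induction step k -> k+1 on a normalized k-model.

    Each occurrence of the digit ``k`` outside the k-prefix is replaced by
    ``k+1``, one new (k+1)-model per occurrence; the replaced position becomes
    the end of the new model's (k+1)-prefix.
    """
    if not is_normalized(s):
        raise ModelStringError(f"induction requires a normalized string, got {s!r}")
    k = k_of(s)
    if k == 6:
        raise ModelStringError("a 6-model has no derivable successors")
    old, new = str(k), str(k + 1)
    plen = len(k_prefix(s))
    return [
        s[: i] + new + s[i + 1 :] for i in range(plen, 6) if s[i] == old
    ]


def phase2_expansions(m: str) -> set[str]:
    """Phase-2 recursion on a freshly derived (k+1)-model.

    Further unprotected occurrences of the old digit ``k`` are replaced by
    ``k+1``, only ever strictly right of the last replaced position, and each
    product is expanded recursively in turn.
    """
    if not is_normalized(m):
        raise ModelStringError(f"induction requires a normalized string, got {m!r}")
    k1 = k_of(m)
    old, new = str(k1 - 1), str(k1)
    out: set[str] = set()

    def recurse(cur: str, start: int) -> None:
        for i in range(start, 6):
            if cur[i] == old:
                child = cur[:i] + new + cur[i + 1 :]
                out.add(child)
                recurse(child, i + 1)

    recurse(m, m.rindex(new) + 1)
    return out


def derive_models(s: str) -> set[str]:
    """All (k+1)-models derivable from a normalized k-model by rate splitting."""
    out: set[str] = set()
    for m in phase1_models(s):
        out.add(m)
        out |= phase2_expansions(m)
    return out


def generate_inductive() -> ModelSet:
    """Build S_1 ... S_6 by iterated rate splitting, starting from 111111."""
    levels: dict[int, set[str]] = {1: {"111111"}}
    candidates = 1
    for k in range(1, 6):
        nxt: set[str] = set()
        for m in levels[k]:
            derived = derive_models(m)
            candidates += len(derived)
            nxt |= derived
        levels[k + 1] = nxt
    models = set().union(*levels.values())
    return ModelSet(
        models=models,
        per_k_counts={k: len(v) for k, v in levels.items()},
        enumerated_candidates=candidates,
    )


def enumerate_brute_force(optimized: bool = False) -> ModelSet:
    """Enumerate raw strings, normalize, and keep first-seen distinct forms.

    With ``optimized=False`` all 6**6 = 46656 strings are inspected (counting
    from 111111 to 666666 base 6).  With ``optimized=True`` position n only
    draws from {1..n}, cutting the candidate count to 6! = 720.
    """
    if optimized:
        ranges = [range(1, n + 2) for n in range(6)]
    else:
        ranges = [range(1, 7)] * 6
    models: set[str] = set()
    candidates = 0
    for digits in itertools.product(*ranges):
        candidates += 1
        models.add(normalize("".join(map(str, digits))))
    per_k: dict[int, int] = {}
    for m in models:
        per_k[k_of(m)] = per_k.get(k_of(m), 0) + 1
    return ModelSet(models=models, per_k_counts=per_k, enumerated_candidates=candidates)


def to_engine_string(s: str) -> str:
    """Same encoding over the alphabet {0..5} (each digit decremented)."""
    _check(s)
    return "".join(str(int(ch) - 1) for ch in s)


def sorted_models(models: set[str] | None = None) -> list[str]:
    """Stable order used for reporting and export: by k, then lexicographic."""
    if models is None:
        models = generate_inductive().models
    return sorted(models, key=lambda m: (k_of(m), m))


def write_model_strings(path, zero_based: bool = False) -> None:
    """Write the full model list, one string per line."""
    with open(path, "w") as fh:
        for m in sorted_models():
            fh.write((to_engine_string(m) if zero_based else m) + "\n")
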