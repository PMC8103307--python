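"""Independent brute-force oracles used to cross-check the implementation.

These deliberately re-derive results with different algorithms than the
library (linear scans, exhaustive tallies, memoized pairwise-conflict
recursion, finite differences) so a bug in the implementation cannot hide
in its own test.
"""

from typing import Dict, List, Sequence, Set, Tuple

import numpy as np


def runs_from_tags(tags: Sequence[str]) -> List[Tuple[int, int, str]]:
    """Entity runs (first_token, last_token, category) via a linear scanner
    that treats any I-X not continuing an X run as a new run."""
    runs = []
    i = 0
    while i < len(tags):
        if tags[i] == "O":
            i += 1
            continue
        cat = tags[i].split("-", 1)[1]
        j = i + 1
        while j < len(tags) and tags[j] == f"I-{cat}":
            j += 1
        runs.append((i, j - 1, cat))
        i = j
    return runs


def tally_votes(predictions: Sequence[Sequence[Tuple]]) -> Dict[Tuple, int]:
    """Vote counts by exhaustive counting of models containing each key."""
    keys = {k for pred in predictions for k in pred}
    return {k: sum(1 for pred in predictions if k in set(pred)) for k in keys}


def pairwise_f1(a: Set[Tuple], b: Set[Tuple]) -> float:
    tp = len(a & b)
    if tp == 0 or not a or not b:
        return 0.0
    p, r = tp / len(a), tp / len(b)
    return 2 * p * r / (p + r)


def resolve_by_conflict_recursion(
    candidates: Sequence[Tuple],
    priority: Dict[Tuple, Tuple],
    overlaps,
) -> Set[Tuple]:
    """Fixpoint semantics of overlap resolution, computed independently:
    a candidate survives iff no surviving higher-priority candidate
    overlaps it (memoized recursion over the priority order)."""
    ordered = sorted(candidates, key=lambda c: priority[c])
    kept: Dict[Tuple, bool] = {}
    for c in ordered:
        kept[c] = not any(kept[d] for d in ordered
                          if priority[d] < priority[c] and overlaps(c, d))
    return {c for c, ok in kept.items() if ok}


def numeric_gradient(loss_fn, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    grad = np.zeros_like(x)
    flat = x.reshape(-1)
    gflat = grad.reshape(-1)
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        lp = loss_fn()
        flat[i] = orig - eps
        lm = loss_fn()
        flat[i] = orig
        gflat[i] = (lp - lm) / (2 * eps)
    return grad


def negation_scope_oracle(words: List[str], trigger_words: List[List[str]],
                          terminators: Set[str], obs_idx: int,
                          window: int = 6) -> bool:
    """Walk every position; the observation is negated iff it sits in the
    forward window of some trigger occurrence, not past a terminator."""
    for i in range(len(words)):
        for trig in trigger_words:
            if words[i:i + len(trig)] != trig:
                continue
            pos = i + len(trig)
            steps = 0
            while pos < len(words) and steps < window:
                if words[pos] in terminators:
                    break
                if pos == obs_idx:
                    return True
                pos += 1
                steps += 1
    return False
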