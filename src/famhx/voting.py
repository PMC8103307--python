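"""Voting ensemble over N entity taggers' predictions.

Each model contributes its predicted entities; a candidate is an exact
(document, category, span) triple, and its vote count is the number of
models that produced it.  Candidates at or above the voting threshold
survive, and overlap conflicts between surviving same-category spans are
resolved by vote count, then by which candidate was produced by the
higher-ranking model (models are ranked by their average pairwise F1
agreement with the other ensemble members), then by span position.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Sequence, Set, Tuple

from .model import Category, Entity

CandidateKey = Tuple[str, str, int, int]  # (doc_id, category, start, end)


@dataclass(frozen=True)
class VoteTable:
    candidates: Dict[CandidateKey, FrozenSet[int]]
    n_models: int
    texts: Dict[CandidateKey, str]

    def votes(self, key: CandidateKey) -> int:
        return len(self.candidates[key])


@dataclass(frozen=True)
class EnsembleConfig:
    threshold: int = 5

    def validate(self, n_models: int) -> None:
        if not (1 <= self.threshold <= n_models):
            raise ValueError(
                f"threshold {self.threshold} outside [1, {n_models}]")


@dataclass(frozen=True)
class ModelRanking:
    pairwise_f1: Tuple[Tuple[float, ...], ...]
    mean_agreement: Tuple[float, ...]
    rank: Tuple[int, ...]  # model indices, best first

    def position(self, model_index: int) -> int:
        """0-based rank position (0 = best)."""
        return self.rank.index(model_index)


def collect_votes(predictions: Sequence[Sequence[Entity]]) -> VoteTable:
    """Tally exact span+category candidates over all models' outputs."""
    candidates: Dict[CandidateKey, Set[int]] = {}
    texts: Dict[CandidateKey, str] = {}
    for idx, entities in enumerate(predictions):
        for e in entities:
            key = e.key()
            candidates.setdefault(key, set()).add(idx)
            texts.setdefault(key, e.text)
    return VoteTable(
        candidates={k: frozenset(v) for k, v in candidates.items()},
        n_models=len(predictions),
        texts=texts,
    )


def _prf1(system: Set[CandidateKey], reference: Set[CandidateKey]) -> float:
    tp = len(system & reference)
    if not system or not reference or tp == 0:
        return 0.0
    p = tp / len(system)
    r = tp / len(reference)
    return 2 * p * r / (p + r)


def rank_models(predictions: Sequence[Sequence[Entity]]) -> ModelRanking:
    """Rank models by average pairwise entity F1 against the other models.

    F1 uses exact span+category matching; higher mean agreement ranks
    higher, ties broken by model index (lower index first).
    """
    n = len(predictions)
    if n < 2:
        raise ValueError("ranking needs at least 2 models")
    keysets = [set(e.key() for e in pred) for pred in predictions]
    matrix = [[0.0] * n for _ in range(n)]
    means = []
    for i in range(n):
        total = 0.0
        for j in range(n):
            if i == j:
                continue
            matrix[i][j] = _prf1(keysets[i], keysets[j])
            total += matrix[i][j]
        means.append(total / (n - 1))
    order = sorted(range(n), key=lambda i: (-means[i], i))
    return ModelRanking(
        pairwise_f1=tuple(tuple(row) for row in matrix),
        mean_agreement=tuple(means),
        rank=tuple(order),
    )


def _overlap(a: CandidateKey, b: CandidateKey) -> bool:
    return (a[0] == b[0] and a[1] == b[1]
            and a[2] < b[3] and b[2] < a[3])


def _priority(votes: VoteTable, ranking: ModelRanking, key: CandidateKey):
    """Sort key: more votes first, then best-ranked voter, then position."""
    best_rank = min(ranking.position(m) for m in votes.candidates[key])
    return (-len(votes.candidates[key]), best_rank, key[2], key[3], key[1])


def resolve_entities(votes: VoteTable, ranking: ModelRanking,
                     config: EnsembleConfig) -> List[Entity]:
    """Threshold, then resolve overlapping same-category candidates.

    Keeps candidates with votes >= threshold; among character-overlapping
    survivors of the same category the higher vote count wins, ties go to
    the candidate whose best-ranked voter outranks the other's, remaining
    ties to the earlier span.  The result contains no two overlapping
    same-category entities.
    """
    config.validate(votes.n_models)
    survivors = [k for k in votes.candidates
                 if len(votes.candidates[k]) >= config.threshold]
    survivors.sort(key=lambda k: _priority(votes, ranking, k))
    accepted: List[CandidateKey] = []
    for key in survivors:
        if not any(_overlap(key, other) for other in accepted):
            accepted.append(key)
    accepted.sort()
    return [Entity(doc_id, Category(cat), votes.texts[(doc_id, cat, s, e)], s, e)
            for doc_id, cat, s, e in accepted]


def thresholded_candidates(votes: VoteTable, threshold: int) -> Set[CandidateKey]:
    """Pre-resolution candidate pool at a threshold (monotone in it)."""
    return {k for k, v in votes.candidates.items() if len(v) >= threshold}
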