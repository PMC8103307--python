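"""Relation extraction: candidate pairs, lexical features, OGD classifiers.

Every family member is paired with every living-status and every
observation mention of the same document.  Pairs with a newline between
the two mentions are pruned (related entities essentially never span
lines in family-history sections).  Each pair is described by sparse
lexical indicators — the words inside each mention, up to 7 words on each
side of each mention, the words between the pair, and a bucketed count of
family members lying between them — hashed into a 2^18-dimensional space.

Two binary logistic models (one per relation type) are trained by online
gradient descent: per-example updates, learning rate 0.5 with
inverse-square-root decay, 100 passes with seeded shuffling.  Positive
pairs then become relations, with the living-status score or the negation
attribute attached by the rule components.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np

from .model import (Category, Document, Entity, Relation, RelationType,
                    Token)
from .rules import CueLexicon, detect_negation, score_living_status

HASH_BITS = 18
HASH_DIM = 1 << HASH_BITS
WINDOW = 7


@dataclass(frozen=True)
class CandidatePair:
    doc_id: str
    family_member: Entity
    other: Entity
    label: Optional[bool] = None  # True = related (train mode only)

    def __post_init__(self) -> None:
        if self.family_member.category is not Category.FAMILY_MEMBER:
            raise ValueError("pair head must be a FamilyMember")
        if self.other.doc_id != self.doc_id or self.family_member.doc_id != self.doc_id:
            raise ValueError("pair entities must come from the same document")

    @property
    def type(self) -> RelationType:
        return (RelationType.FM_LIVING_STATUS
                if self.other.category is Category.LIVING_STATUS
                else RelationType.FM_OBSERVATION)


def _gold_pair_keys(gold_relations: Iterable[Relation]) -> Set[Tuple]:
    keys = set()
    for r in gold_relations:
        if r.family_member.start is None or r.other.start is None:
            raise ValueError("training gold relations must carry entity offsets")
        keys.add((r.doc_id, r.family_member.start, r.family_member.end,
                  r.other.start, r.other.end))
    return keys


def _newline_between(doc: Document, a: Entity, b: Entity) -> bool:
    lo = min(a.end, b.end)
    hi = max(a.start, b.start)
    return lo < hi and "\n" in doc.text[lo:hi]


def generate_candidate_pairs(
    entities: Sequence[Entity],
    doc: Document,
    mode: str = "test",
    gold_relations: Optional[Sequence[Relation]] = None,
) -> List[CandidatePair]:
    """All FM x LS and FM x OBS pairs of a document.

    ``mode="train"`` labels each pair against the gold relations and
    requires them; negatives split by a newline are dropped.  The newline
    filter is also applied at inference so train and test pair
    distributions match.
    """
    if mode not in ("train", "test"):
        raise ValueError("mode must be 'train' or 'test'")
    if mode == "train":
        if gold_relations is None:
            raise ValueError("train mode requires gold relations")
        gold_keys = _gold_pair_keys(gold_relations)
    fms = [e for e in entities
           if e.category is Category.FAMILY_MEMBER and e.doc_id == doc.doc_id]
    others = [e for e in entities
              if e.category is not Category.FAMILY_MEMBER and e.doc_id == doc.doc_id]
    pairs: List[CandidatePair] = []
    for fm in fms:
        for other in others:
            label = None
            if mode == "train":
                label = (doc.doc_id, fm.start, fm.end,
                         other.start, other.end) in gold_keys
            if _newline_between(doc, fm, other) and not label:
                continue  # prune negatives (and test pairs) spanning lines
            pairs.append(CandidatePair(doc.doc_id, fm, other, label))
    pairs.sort(key=lambda p: (p.family_member.start, p.family_member.end,
                              p.other.start, p.other.end))
    return pairs


def _doc_tokens(doc: Document) -> List[Token]:
    return [t for s in doc.sentences for t in s.tokens]


def _token_range(tokens: Sequence[Token], start: int, end: int) -> Tuple[int, int]:
    """Indices [i, j) of tokens overlapping the character span."""
    i = next((k for k, t in enumerate(tokens) if t.end > start), len(tokens))
    j = next((k for k in range(len(tokens) - 1, -1, -1)
              if tokens[k].start < end), -1) + 1
    return i, max(i, j)


def extract_features(pair: CandidatePair, doc: Document,
                     entities: Sequence[Entity]) -> List[str]:
    """Namespaced lexical indicator features for a candidate pair.

    Windows are exactly 7 tokens each side, truncated at document edges;
    ``fm_count_between`` counts FamilyMember entities strictly between the
    pair's spans, bucketed at {0, 1, 2, 3+}.
    """
    tokens = _doc_tokens(doc)
    words = [t.text.lower() for t in tokens]
    fm, other = pair.family_member, pair.other
    fi, fj = _token_range(tokens, fm.start, fm.end)
    oi, oj = _token_range(tokens, other.start, other.end)
    feats: List[str] = []
    feats += [f"fm_w={w}" for w in words[fi:fj]]
    feats += [f"ot_w={w}" for w in words[oi:oj]]
    feats += [f"fm_l7={w}" for w in words[max(0, fi - WINDOW):fi]]
    feats += [f"fm_r7={w}" for w in words[fj:fj + WINDOW]]
    feats += [f"ot_l7={w}" for w in words[max(0, oi - WINDOW):oi]]
    feats += [f"ot_r7={w}" for w in words[oj:oj + WINDOW]]
    lo, hi = (fj, oi) if fm.start <= other.start else (oj, fi)
    feats += [f"btw={w}" for w in words[lo:hi]]
    span_lo = min(fm.end, other.end)
    span_hi = max(fm.start, other.start)
    n_between = sum(
        1 for e in entities
        if e.category is Category.FAMILY_MEMBER and e.doc_id == doc.doc_id
        and e.start is not None and e.start >= span_lo and e.end <= span_hi
        and e.key() != fm.key())
    feats.append(f"fm_between={min(n_between, 3)}")
    return feats


def hash_features(feats: Iterable[str]) -> np.ndarray:
    """Distinct hashed indices in [0, 2^18) for string indicator features."""
    return np.unique([zlib.crc32(f.encode("utf-8")) % HASH_DIM for f in feats])


@dataclass
class LinearRelationModel:
    """Hashed-feature logistic model trained by online gradient descent."""

    weights: np.ndarray = field(
        default_factory=lambda: np.zeros(HASH_DIM))
    bias: float = 0.0
    passes: int = 100
    seed: int = 0
    learning_rate: float = 0.5

    def decision(self, idx: np.ndarray) -> float:
        return float(self.weights[idx].sum() + self.bias)

    def probability(self, idx: np.ndarray) -> float:
        z = np.clip(self.decision(idx), -60, 60)
        return float(1.0 / (1.0 + np.exp(-z)))


def logistic_gradient(model: LinearRelationModel, idx: np.ndarray,
                      label: int) -> Tuple[np.ndarray, float]:
    """Gradient of the logistic loss wrt (active weights, bias).

    For binary indicators the per-weight gradient is simply p - y.
    """
    g = model.probability(idx) - label
    return np.full(len(idx), g), g


def train_relation_model(
    examples: Sequence[Tuple[List[str], bool]],
    passes: int = 100,
    seed: int = 0,
    learning_rate: float = 0.5,
) -> LinearRelationModel:
    """OGD training: per-example updates, lr ``0.5/sqrt(t)``, seeded
    shuffling each pass.  Raises on single-class data."""
    labels = {bool(lab) for _, lab in examples}
    if labels != {True, False}:
        raise ValueError("training data must contain both classes")
    model = LinearRelationModel(passes=passes, seed=seed,
                                learning_rate=learning_rate)
    hashed = [(hash_features(f), int(lab)) for f, lab in examples]
    rng = np.random.default_rng(seed)
    order = np.arange(len(hashed))
    t = 0
    for _ in range(passes):
        rng.shuffle(order)
        for j in order:
            idx, y = hashed[j]
            t += 1
            lr = learning_rate / np.sqrt(t)
            gw, gb = logistic_gradient(model, idx, y)
            model.weights[idx] -= lr * gw
            model.bias -= lr * gb
    return model


def classify_pairs(
    model: LinearRelationModel,
    pairs: Sequence[CandidatePair],
    features: Sequence[List[str]],
) -> List[Tuple[CandidatePair, bool, float]]:
    """Deterministic classification; probability >= 0.5 means related."""
    out = []
    for pair, feats in zip(pairs, features):
        p = model.probability(hash_features(feats))
        out.append((pair, p >= 0.5, p))
    return out


def assemble_relations(
    positive_pairs: Sequence[CandidatePair],
    docs: Dict[str, Document],
    cues: CueLexicon,
) -> List[Relation]:
    """Attach rule-based attributes to classified-positive pairs.

    Living-status relations get the 0/2/4 score of the status phrase;
    observation relations get ConText negation over the observation's
    sentence.  Duplicate (document, family member, other) tuples collapse
    to a single relation.
    """
    seen: Set[Tuple] = set()
    relations: List[Relation] = []
    for pair in positive_pairs:
        doc = docs[pair.doc_id]
        if pair.type is RelationType.FM_LIVING_STATUS:
            score, negation = score_living_status(pair.other.text, cues), None
        else:
            sent = doc.sentence_at(pair.other.start)
            if sent is None:
                raise ValueError("observation offsets outside any sentence")
            score, negation = None, detect_negation(sent, pair.other, cues)
        fm_attrs = pair.family_member.attrs
        fm_id = ((fm_attrs.normalized_name, fm_attrs.side)
                 if fm_attrs is not None else pair.family_member.key())
        key = (pair.doc_id, pair.type, fm_id, pair.other.text.lower(),
               score, negation)
        if key in seen:
            continue
        seen.add(key)
        relations.append(Relation(pair.doc_id, pair.type, pair.family_member,
                                  pair.other, score=score, negation=negation))
    return relations
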