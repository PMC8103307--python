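"""Shared-task scoring: micro-averaged P/R/F1 with attribute-aware matching.

Matching is document-level over unique tuples.  A family member matches on
(document, normalized name, family side); an observation matches when the
system and reference texts share at least one lowercase alphanumeric word
(greedy one-to-one assignment in document order, each reference consumed at
most once).  Relations additionally compare the living-status score or the
observation negation.  A :class:`MatchSpec` can ignore any one attribute,
which is how attribute-ablation numbers are produced; ignoring an attribute
can only turn mismatches into matches, so every metric is monotone in it.

Counts are pooled over categories (micro-averaging): overall TP/FP/FN are
sums, precision = 100*TP/(TP+FP), recall = 100*TP/(TP+FN), F1 their
harmonic mean, all reported as percentages rounded to 2 decimals.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .model import (Category, Entity, FamilyMemberAttrs, LivingStatusAttrs,
                    ObservationAttrs, Relation, RelationType, Document)
from .rules import (CueLexicon, FamilyLexicon, assign_family_side,
                    detect_negation, normalize_family_member,
                    score_living_status)


@dataclass(frozen=True)
class MatchSpec:
    ignore_side: bool = False
    ignore_living_status: bool = False
    ignore_negation: bool = False


def micro_prf(tp: int, fp: int, fn: int) -> Tuple[float, float, float]:
    """(precision, recall, F1) as percentages; zero denominators give 0."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    p = 100.0 * tp / (tp + fp) if tp + fp else 0.0
    r = 100.0 * tp / (tp + fn) if tp + fn else 0.0
    f = 2 * p * r / (p + r) if p + r else 0.0
    return round(p, 2), round(r, 2), round(f, 2)


def f1_from_pr(precision: float, recall: float) -> float:
    """Harmonic mean of already-computed precision/recall percentages."""
    if precision + recall == 0:
        return 0.0
    return round(2 * precision * recall / (precision + recall), 2)


@dataclass
class CategoryCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def prf(self) -> Tuple[float, float, float]:
        return micro_prf(self.tp, self.fp, self.fn)


@dataclass
class EvalReport:
    categories: Dict[str, CategoryCounts] = field(default_factory=dict)

    @property
    def overall(self) -> CategoryCounts:
        return CategoryCounts(
            tp=sum(c.tp for c in self.categories.values()),
            fp=sum(c.fp for c in self.categories.values()),
            fn=sum(c.fn for c in self.categories.values()),
        )

    def to_dict(self) -> Dict[str, Dict[str, float]]:
        out = {}
        rows = dict(self.categories)
        rows["Overall"] = self.overall
        for name, c in rows.items():
            p, r, f = c.prf
            out[name] = {"tp": c.tp, "fp": c.fp, "fn": c.fn,
                         "precision": p, "recall": r, "f1": f}
        return out


def _words(text: str) -> frozenset:
    return frozenset(re.findall(r"[a-z0-9]+", text.lower()))


def _greedy_overlap_counts(system: List[Tuple], reference: List[Tuple]) -> CategoryCounts:
    """Greedy 1:1 matching; items are (hard_key, word_set) tuples.

    A system item matches the first unconsumed reference item with the
    same hard key and >= 1 word in common.
    """
    consumed = [False] * len(reference)
    tp = 0
    for skey, swords in system:
        for i, (rkey, rwords) in enumerate(reference):
            if consumed[i] or rkey != skey:
                continue
            if swords & rwords:
                consumed[i] = True
                tp += 1
                break
    return CategoryCounts(tp=tp, fp=len(system) - tp,
                          fn=len(reference) - tp)


def _exact_counts(system: set, reference: set) -> CategoryCounts:
    tp = len(system & reference)
    return CategoryCounts(tp=tp, fp=len(system) - tp, fn=len(reference) - tp)


def _fm_tuple(e: Entity, spec: MatchSpec) -> Tuple:
    attrs = e.attrs
    if not isinstance(attrs, FamilyMemberAttrs):
        raise ValueError("family-member entities need attributes for evaluation")
    return (e.doc_id, attrs.normalized_name,
            "NA" if spec.ignore_side else attrs.side)


def _unique(items: Iterable[Tuple]) -> List[Tuple]:
    seen, out = set(), []
    for it in items:
        if it not in seen:
            seen.add(it)
            out.append(it)
    return out


def evaluate_entities(system: Sequence[Entity], reference: Sequence[Entity],
                      spec: MatchSpec = MatchSpec()) -> EvalReport:
    """Entity scoring (subtask-1 style).

    Family members match on (doc, normalized name, side); observations and
    living-status mentions match on word overlap of their surface text.
    Living-status scores and observation negation are not part of entity
    matching (the entity task does not evaluate them).
    """
    report = EvalReport()
    sys_fm = set(_fm_tuple(e, spec) for e in system
                 if e.category is Category.FAMILY_MEMBER)
    ref_fm = set(_fm_tuple(e, spec) for e in reference
                 if e.category is Category.FAMILY_MEMBER)
    report.categories["FamilyMember"] = _exact_counts(sys_fm, ref_fm)
    for cat in (Category.OBSERVATION, Category.LIVING_STATUS):
        sys_items = _unique(((e.doc_id,), _words(e.text))
                            for e in system if e.category is cat)
        ref_items = _unique(((e.doc_id,), _words(e.text))
                            for e in reference if e.category is cat)
        report.categories[cat.value] = _greedy_overlap_counts(
            list(sys_items), list(ref_items))
    return report


def evaluate_relations(system: Sequence[Relation], reference: Sequence[Relation],
                       spec: MatchSpec = MatchSpec()) -> EvalReport:
    """Relation scoring (subtask-2 style) with attribute-aware tuples."""
    report = EvalReport()

    def ls_tuple(r: Relation) -> Tuple:
        return (_fm_tuple(r.family_member, spec),
                None if spec.ignore_living_status else r.score)

    sys_ls = set(ls_tuple(r) for r in system
                 if r.type is RelationType.FM_LIVING_STATUS)
    ref_ls = set(ls_tuple(r) for r in reference
                 if r.type is RelationType.FM_LIVING_STATUS)
    report.categories["LivingStatus"] = _exact_counts(sys_ls, ref_ls)

    def obs_item(r: Relation) -> Tuple:
        hard = (_fm_tuple(r.family_member, spec),
                None if spec.ignore_negation else r.negation)
        return (hard, _words(r.other.text))

    sys_obs = _unique(obs_item(r) for r in system
                      if r.type is RelationType.FM_OBSERVATION)
    ref_obs = _unique(obs_item(r) for r in reference
                      if r.type is RelationType.FM_OBSERVATION)
    report.categories["Observation"] = _greedy_overlap_counts(
        list(sys_obs), list(ref_obs))
    return report


def attribute_accuracy(
    docs: Dict[str, Document],
    gold_entities: Sequence[Entity],
    gold_relations: Sequence[Relation],
    lexicon: FamilyLexicon,
    cues: CueLexicon,
) -> Dict[str, float]:
    """Accuracy of each attribute heuristic on reference-standard concepts.

    The rules run on the gold spans (oracle entity boundaries) and their
    outputs are compared with the gold attributes; accuracy is the
    percentage of correct predictions among instances, per task.
    """
    counts = {k: [0, 0] for k in
              ("normalization", "side", "living_status", "negation")}

    def score(task: str, correct: bool) -> None:
        counts[task][1] += 1
        counts[task][0] += int(correct)

    for e in gold_entities:
        if e.category is not Category.FAMILY_MEMBER or e.start is None:
            continue
        attrs = e.attrs
        if not isinstance(attrs, FamilyMemberAttrs):
            continue
        sent = docs[e.doc_id].sentence_at(e.start)
        pred_norm = normalize_family_member(e.text, lexicon, sent, e.start)
        score("normalization", pred_norm == attrs.normalized_name)
        if pred_norm is not None:
            pred_side = assign_family_side(e.text, pred_norm, cues, sent, e.start)
            score("side", pred_side == attrs.side)
    for r in gold_relations:
        if r.type is RelationType.FM_LIVING_STATUS:
            score("living_status",
                  score_living_status(r.other.text, cues) == r.score)
        else:
            if r.other.start is None:
                continue
            sent = docs[r.doc_id].sentence_at(r.other.start)
            score("negation",
                  detect_negation(sent, r.other, cues) == r.negation)
    return {task: round(100.0 * ok / n, 2) if n else 0.0
            for task, (ok, n) in counts.items()}


def sweep_thresholds(
    predictions: Sequence[Sequence[Entity]],
    reference: Sequence[Entity],
    attach=None,
    spec: MatchSpec = MatchSpec(),
    thresholds: Sequence[int] = range(1, 11),
) -> Dict[int, Tuple[EvalReport, int]]:
    """One entity report per voting threshold, plus the candidate-pool size.

    ``attach`` maps resolved entities to attribute-bearing entities before
    scoring (identity by default).  The candidate pool is non-increasing
    in the threshold.
    """
    from .voting import (EnsembleConfig, collect_votes, rank_models,
                         resolve_entities, thresholded_candidates)

    votes = collect_votes(predictions)
    ranking = rank_models(predictions)
    attach = attach or (lambda ents: ents)
    out: Dict[int, Tuple[EvalReport, int]] = {}
    for t in thresholds:
        resolved = resolve_entities(votes, ranking, EnsembleConfig(threshold=t))
        report = evaluate_entities(attach(resolved), reference, spec)
        out[t] = (report, len(thresholded_candidates(votes, t)))
    return out
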