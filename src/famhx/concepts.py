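"""External-concept channels: semantic-type mapping and auxiliary BIO inputs.

A concept tagger (UMLS-style, or a medical-problem model) marks spans in a
document with a semantic type.  To decide which semantic types are useful
evidence for observation entities, each type's mentions are aligned with
gold observations on the training set; types whose mapping probability
(aligned / total) exceeds a threshold (default 0.70, strict) are kept.
Mentions of kept types are re-encoded as BIO tags aligned with each
sentence's tokens and fed to the neural tagger as an extra input channel.

Real UMLS-backed and clinical-challenge concept taggers are
license-restricted, so the concrete
tagger here is a pluggable interface plus a dictionary-based implementation
used for testing and the synthetic corpus; any object with a ``name`` and a
``tag(doc)`` method can stand behind a channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .model import Category, Document, Entity, Sentence


@dataclass(frozen=True)
class ConceptMention:
    doc_id: str
    semantic_type: str
    start: int
    end: int


@dataclass(frozen=True)
class TypeRow:
    aligned: int
    total: int

    @property
    def probability(self) -> float:
        return self.aligned / self.total

    def __post_init__(self) -> None:
        if not (0 <= self.aligned <= self.total) or self.total == 0:
            raise ValueError("need 0 <= aligned <= total with total > 0")


@dataclass(frozen=True)
class SemanticTypeMap:
    rows: Mapping[str, TypeRow]
    threshold: float = 0.70

    @property
    def kept(self) -> frozenset:
        """Semantic types whose mapping probability strictly exceeds the
        threshold ("over 70%" means 0.70 itself is dropped)."""
        return frozenset(t for t, r in self.rows.items()
                         if r.probability > self.threshold)

    def to_dict(self) -> Dict[str, object]:
        return {"threshold": self.threshold,
                "rows": {t: [r.aligned, r.total] for t, r in self.rows.items()}}

    @classmethod
    def from_dict(cls, data: Mapping[str, object]) -> "SemanticTypeMap":
        rows = {t: TypeRow(a, n) for t, (a, n) in data["rows"].items()}
        return cls(rows=rows, threshold=data["threshold"])


def _overlaps(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    return a_start < b_end and b_start < a_end


def build_semantic_type_map(
    concept_mentions: Sequence[ConceptMention],
    gold_observations: Sequence[Entity],
    threshold: float = 0.70,
) -> SemanticTypeMap:
    """Alignment statistics of concept mentions against gold observations.

    A mention is *aligned* when it shares at least one character with a
    gold observation span of the same document.  Types with no mentions
    never appear in the map (their probability is undefined).
    """
    gold_by_doc: Dict[str, List[Tuple[int, int]]] = {}
    for e in gold_observations:
        if e.category is not Category.OBSERVATION or e.start is None:
            continue
        gold_by_doc.setdefault(e.doc_id, []).append((e.start, e.end))
    totals: Dict[str, int] = {}
    aligned: Dict[str, int] = {}
    for m in concept_mentions:
        totals[m.semantic_type] = totals.get(m.semantic_type, 0) + 1
        if any(_overlaps(m.start, m.end, s, e)
               for s, e in gold_by_doc.get(m.doc_id, ())):
            aligned[m.semantic_type] = aligned.get(m.semantic_type, 0) + 1
    rows = {t: TypeRow(aligned.get(t, 0), n) for t, n in totals.items()}
    return SemanticTypeMap(rows=rows, threshold=threshold)


@dataclass(frozen=True)
class AuxChannel:
    name: str
    tags: Tuple[str, ...]


def derive_aux_channel(
    concept_mentions: Iterable[ConceptMention],
    semantic_map: Optional[SemanticTypeMap],
    sentence: Sentence,
    name: str = "concepts",
    category: str = Category.OBSERVATION.value,
) -> AuxChannel:
    """Re-encode kept-type mentions as BIO tags over the sentence tokens.

    With ``semantic_map=None`` every mention is kept (used for channels,
    like a medical-problem tagger, whose output is already task-relevant).
    Mentions of dropped types, and tokens outside any mention, are ``O``.
    """
    kept = semantic_map.kept if semantic_map is not None else None
    tags = ["O"] * len(sentence.tokens)
    relevant = [m for m in concept_mentions
                if (kept is None or m.semantic_type in kept)
                and _overlaps(m.start, m.end, sentence.start, sentence.end)]
    relevant.sort(key=lambda m: (m.start, m.end))
    for m in relevant:
        first = True
        for i, tok in enumerate(sentence.tokens):
            if _overlaps(tok.start, tok.end, m.start, m.end):
                tags[i] = ("B-" if first else "I-") + category
                first = False
    return AuxChannel(name=name, tags=tuple(tags))


class DictionaryConceptTagger:
    """Phrase-dictionary concept tagger (mock for license-restricted tools).

    Matches lowercase vocabulary phrases at word boundaries anywhere in the
    document text and emits one mention per occurrence, typed by the
    dictionary.
    """

    def __init__(self, name: str, vocabulary: Mapping[str, str]) -> None:
        self.name = name
        self.vocabulary = {k.lower(): v for k, v in vocabulary.items()}

    def tag(self, doc: Document) -> List[ConceptMention]:
        low = doc.text.lower()
        out: List[ConceptMention] = []
        for phrase, stype in sorted(self.vocabulary.items()):
            start = low.find(phrase)
            while start != -1:
                end = start + len(phrase)
                boundary = ((start == 0 or not low[start - 1].isalnum())
                            and (end == len(low) or not low[end].isalnum()))
                if boundary:
                    out.append(ConceptMention(doc.doc_id, stype, start, end))
                start = low.find(phrase, start + 1)
        out.sort(key=lambda m: (m.start, m.end, m.semantic_type))
        return out


@dataclass
class ChannelProvider:
    """Binds a concept tagger (plus optional semantic-type filter) to the
    tagger-input interface; caches mentions per document."""

    tagger: DictionaryConceptTagger
    semantic_map: Optional[SemanticTypeMap] = None
    category: str = Category.OBSERVATION.value
    _cache: Dict[str, List[ConceptMention]] = field(default_factory=dict, repr=False)

    @property
    def name(self) -> str:
        return self.tagger.name

    def channel_for(self, doc: Document, sentence: Sentence) -> AuxChannel:
        key = (doc.doc_id, hash(doc.text))  # doc_ids may recur across corpora
        if key not in self._cache:
            self._cache[key] = self.tagger.tag(doc)
        return derive_aux_channel(self._cache[key], self.semantic_map,
                                  sentence, name=self.name, category=self.category)
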