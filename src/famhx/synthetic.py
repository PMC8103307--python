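"""Deterministic generator of family-history-style notes with gold annotations.

Real family-history corpora are access-restricted, so every pipeline stage
is exercised on generated notes that emulate their annotated structure:
multi-sentence documents mixing family-member mentions (with numeric
modifiers, side-of-family modifiers, and nested kinship like "mother's
sister"), disease observations, living-status phrases (not-alive, healthy,
and neutral cues), negation triggers, observations unrelated to any family
member, and entity pairs split across line breaks.

Generation is template-based so gold character offsets are exact by
construction, and driven by a single seeded generator so a given
configuration reproduces byte-identical corpora.  Default rates mirror the
annotation statistics the generator emulates: in particular about 23% of
observation entities participate in no relation (978 observation entities
vs 753 observation relations in the reference training data).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .model import (Category, Document, Entity, FamilyMemberAttrs,
                    LivingStatusAttrs, ObservationAttrs, Relation,
                    RelationType)
from .preprocess import preprocess

#: Disease vocabulary with coarse semantic types (used by the mock concept
#: tagger): neoplasms, diseases/syndromes, signs/symptoms, mental/behavioral.
DISEASES: Dict[str, str] = {
    "breast cancer": "neop", "colon cancer": "neop", "lung cancer": "neop",
    "prostate cancer": "neop", "ovarian cancer": "neop", "leukemia": "neop",
    "lymphoma": "neop", "melanoma": "neop", "pancreatic cancer": "neop",
    "diabetes": "dsyn", "hypertension": "dsyn", "heart disease": "dsyn",
    "coronary artery disease": "dsyn", "stroke": "dsyn", "asthma": "dsyn",
    "arthritis": "dsyn", "osteoporosis": "dsyn", "kidney disease": "dsyn",
    "thyroid disease": "dsyn", "high cholesterol": "dsyn", "emphysema": "dsyn",
    "glaucoma": "dsyn", "anemia": "dsyn", "cirrhosis": "dsyn",
    "alzheimer disease": "dsyn", "seizures": "sosy", "migraines": "sosy",
    "depression": "mobd", "anxiety": "mobd", "alcoholism": "mobd",
    "dementia": "mobd",
}

_FIRST_KIN = [("mother", "Mother"), ("father", "Father"), ("brother", "Brother"),
              ("sister", "Sister"), ("son", "Son"), ("daughter", "Daughter")]
_SECOND_KIN = [("grandmother", "Grandmother"), ("grandfather", "Grandfather"),
               ("uncle", "Uncle"), ("aunt", "Aunt"), ("cousin", "Cousin")]
_PLURAL_KIN = [("uncles", "Uncle"), ("aunts", "Aunt"), ("brothers", "Brother"),
               ("sisters", "Sister"), ("cousins", "Cousin")]
_NUM_WORDS = ["two", "three", "four", "five"]
_TOWNS = ["Ohio", "Denver", "Florida", "Texas", "Oregon"]
_POSS = ["his", "her", "the patient's"]

_DEFAULT_RATES: Dict[str, float] = {
    "negation": 0.12,       # related observation mentioned as negated
    "side_cue": 0.5,        # second-degree kin carries a side modifier
    "numeric": 0.12,        # numeric kin modifier ("three uncles")
    "nested": 0.15,         # kin possessed by another kin ("mother's sister")
    "unrelated_obs": 0.23,  # observation participating in no relation
    "cross_line": 0.3,      # sentence separator is a newline
}


@dataclass(frozen=True)
class GenConfig:
    n_documents: int = 100
    sentences_per_doc: Tuple[int, int] = (4, 8)
    seed: int = 0
    rates: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_documents < 1:
            raise ValueError("n_documents must be >= 1")
        lo, hi = self.sentences_per_doc
        if not (1 <= lo <= hi):
            raise ValueError("invalid sentences_per_doc range")
        merged = dict(_DEFAULT_RATES)
        for key, val in self.rates.items():
            if key not in _DEFAULT_RATES:
                raise ValueError(f"unknown rate {key!r}")
            if not (0.0 <= val <= 1.0):
                raise ValueError(f"rate {key!r} outside [0, 1]")
            merged[key] = val
        object.__setattr__(self, "rates", merged)


class _SentenceBuilder:
    """Accumulates literal text and marked entity spans for one sentence."""

    def __init__(self) -> None:
        self._parts: List[str] = []
        self._len = 0
        self.entities: List[Tuple[int, int, Category, object]] = []
        self.relations: List[Tuple[int, int, RelationType,
                                   Optional[int], Optional[str]]] = []

    def lit(self, text: str) -> None:
        self._parts.append(text)
        self._len += len(text)

    def ent(self, text: str, category: Category, attrs: object) -> int:
        start = self._len
        self.lit(text)
        self.entities.append((start, self._len, category, attrs))
        return len(self.entities) - 1

    def rel(self, fm_idx: int, other_idx: int, rtype: RelationType,
            score: Optional[int] = None, negation: Optional[str] = None) -> None:
        self.relations.append((fm_idx, other_idx, rtype, score, negation))

    @property
    def text(self) -> str:
        raw = "".join(self._parts)
        return raw[:1].upper() + raw[1:] if raw else raw


def _pick(rng: np.random.Generator, items: Sequence):
    return items[int(rng.integers(len(items)))]


def _kin_phrase(rng: np.random.Generator, rates: Dict[str, float]
                ) -> Tuple[str, FamilyMemberAttrs]:
    """A kin surface phrase plus its gold attributes."""
    if rng.random() < 0.4:
        surface, name = _pick(rng, _SECOND_KIN)
        if rng.random() < rates["side_cue"]:
            side = _pick(rng, ["maternal", "paternal"])
            return f"{side} {surface}", FamilyMemberAttrs(name, side.capitalize())
        return surface, FamilyMemberAttrs(name, "NA")
    surface, name = _pick(rng, _FIRST_KIN)
    return surface, FamilyMemberAttrs(name, "NA")


def _sentence(rng: np.random.Generator, rates: Dict[str, float]) -> _SentenceBuilder:
    sb = _SentenceBuilder()
    draw = rng.random()
    if draw < 0.08:
        sb.lit(_pick(rng, ["the patient was seen in clinic today.",
                           "review of systems was unremarkable.",
                           "family history was discussed at the visit."]))
        return sb
    obs_text = _pick(rng, sorted(DISEASES))
    if draw < 0.34:
        _living_status_sentence(rng, rates, sb)
    elif rng.random() < rates["unrelated_obs"]:
        _unrelated_obs_sentence(rng, sb, obs_text)
    elif rng.random() < rates["negation"]:
        _negated_sentence(rng, rates, sb, obs_text)
    elif rng.random() < rates["nested"]:
        _nested_sentence(rng, sb, obs_text)
    elif rng.random() < rates["numeric"]:
        _numeric_sentence(rng, sb, obs_text)
    else:
        _simple_related_sentence(rng, rates, sb, obs_text)
    return sb


def _living_status_sentence(rng, rates, sb: _SentenceBuilder) -> None:
    phrase, attrs = _kin_phrase(rng, rates)
    fm = sb.ent(phrase, Category.FAMILY_MEMBER, attrs)
    variant = int(rng.integers(5))
    if variant == 0:
        sb.lit(" is ")
        ls = sb.ent("alive and well", Category.LIVING_STATUS, LivingStatusAttrs(4))
        sb.lit(".")
        score = 4
    elif variant == 1:
        sb.lit(" is ")
        ls = sb.ent("deceased", Category.LIVING_STATUS, LivingStatusAttrs(0))
        sb.lit(".")
        score = 0
    elif variant == 2:
        sb.lit(" ")
        ls = sb.ent("passed away", Category.LIVING_STATUS, LivingStatusAttrs(0))
        sb.lit(f" at age {int(rng.integers(55, 95))}.")
        score = 0
    elif variant == 3:
        sb.lit(" ")
        ls = sb.ent(f"lives in {_pick(rng, _TOWNS)}", Category.LIVING_STATUS,
                    LivingStatusAttrs(2))
        sb.lit(".")
        score = 2
    else:
        sb.lit(" is ")
        ls = sb.ent("in good health", Category.LIVING_STATUS, LivingStatusAttrs(4))
        sb.lit(".")
        score = 4
    sb.rel(fm, ls, RelationType.FM_LIVING_STATUS, score=score)


def _unrelated_obs_sentence(rng, sb: _SentenceBuilder, obs_text: str) -> None:
    variant = int(rng.integers(3))
    if variant == 0:
        sb.lit("no family history of ")
        sb.ent(obs_text, Category.OBSERVATION, ObservationAttrs("Negated"))
        sb.lit(".")
    elif variant == 1:
        sb.lit("family history includes ")
        sb.ent(obs_text, Category.OBSERVATION, ObservationAttrs("Non_Negated"))
        sb.lit(".")
    else:
        sb.lit("there is a family history of ")
        sb.ent(obs_text, Category.OBSERVATION, ObservationAttrs("Non_Negated"))
        sb.lit(".")


def _negated_sentence(rng, rates, sb: _SentenceBuilder, obs_text: str) -> None:
    phrase, attrs = _kin_phrase(rng, rates)
    variant = int(rng.integers(3))
    if variant == 0:
        sb.lit(f"{_pick(rng, _POSS)} ")
        fm = sb.ent(phrase, Category.FAMILY_MEMBER, attrs)
        sb.lit(" has no history of ")
        obs = sb.ent(obs_text, Category.OBSERVATION, ObservationAttrs("Negated"))
        sb.lit(".")
    elif variant == 1:
        fm = sb.ent(phrase, Category.FAMILY_MEMBER, attrs)
        sb.lit(" denies ")
        obs = sb.ent(obs_text, Category.OBSERVATION, ObservationAttrs("Negated"))
        sb.lit(".")
    else:
        fm = sb.ent(phrase, Category.FAMILY_MEMBER, attrs)
        sb.lit(" was negative for ")
        obs = sb.ent(obs_text, Category.OBSERVATION, ObservationAttrs("Negated"))
        sb.lit(".")
    sb.rel(fm, obs, RelationType.FM_OBSERVATION, negation="Negated")


def _nested_sentence(rng, sb: _SentenceBuilder, obs_text: str) -> None:
    parent_surface, parent_name = _pick(rng, [("mother", "Mother"),
                                              ("father", "Father")])
    target_surface, composed = _pick(
        rng, [("sister", "Aunt"), ("brother", "Uncle")])
    side = "Maternal" if parent_name == "Mother" else "Paternal"
    sb.lit(f"{_pick(rng, _POSS)} ")
    parent = sb.ent(parent_surface, Category.FAMILY_MEMBER,
                    FamilyMemberAttrs(parent_name, "NA"))
    if rng.random() < 0.5:
        sb.lit("'s ")
        target = sb.ent(target_surface, Category.FAMILY_MEMBER,
                        FamilyMemberAttrs(composed, side))
        sb.lit(" had ")
    else:
        sb.lit(" has a ")
        target = sb.ent(target_surface, Category.FAMILY_MEMBER,
                        FamilyMemberAttrs(composed, side))
        sb.lit(" with ")
    obs = sb.ent(obs_text, Category.OBSERVATION, ObservationAttrs("Non_Negated"))
    sb.lit(".")
    sb.rel(target, obs, RelationType.FM_OBSERVATION, negation="Non_Negated")


def _numeric_sentence(rng, sb: _SentenceBuilder, obs_text: str) -> None:
    num = _pick(rng, _NUM_WORDS)
    surface, name = _pick(rng, _PLURAL_KIN)
    sb.lit(f"{_pick(rng, _POSS)} ")
    fm = sb.ent(f"{num} {surface}", Category.FAMILY_MEMBER,
                FamilyMemberAttrs(name, "NA"))
    sb.lit(" have ")
    obs = sb.ent(obs_text, Category.OBSERVATION, ObservationAttrs("Non_Negated"))
    sb.lit(".")
    sb.rel(fm, obs, RelationType.FM_OBSERVATION, negation="Non_Negated")


def _simple_related_sentence(rng, rates, sb: _SentenceBuilder, obs_text: str) -> None:
    phrase, attrs = _kin_phrase(rng, rates)
    variant = int(rng.integers(3))
    if variant == 0:
        sb.lit(f"{_pick(rng, _POSS)} ")
        fm = sb.ent(phrase, Category.FAMILY_MEMBER, attrs)
        sb.lit(" has ")
        obs = sb.ent(obs_text, Category.OBSERVATION, ObservationAttrs("Non_Negated"))
        sb.lit(".")
    elif variant == 1:
        fm = sb.ent(phrase, Category.FAMILY_MEMBER, attrs)
        sb.lit(" was diagnosed with ")
        obs = sb.ent(obs_text, Category.OBSERVATION, ObservationAttrs("Non_Negated"))
        sb.lit(f" in {int(rng.integers(1985, 2019))}.")
    else:
        sb.lit(f"{_pick(rng, _POSS)} ")
        fm = sb.ent(phrase, Category.FAMILY_MEMBER, attrs)
        sb.lit(" ")
        ls = sb.ent("died", Category.LIVING_STATUS, LivingStatusAttrs(0))
        sb.lit(" of ")
        obs = sb.ent(obs_text, Category.OBSERVATION, ObservationAttrs("Non_Negated"))
        sb.lit(".")
        sb.rel(fm, ls, RelationType.FM_LIVING_STATUS, score=0)
    sb.rel(fm, obs, RelationType.FM_OBSERVATION, negation="Non_Negated")


def generate_document(
    rng: np.random.Generator,
    doc_id: str,
    config: GenConfig,
) -> Tuple[Document, List[Entity], List[Relation]]:
    """One note plus its gold entities and relations (offsets exact)."""
    lo, hi = config.sentences_per_doc
    n_sent = int(rng.integers(lo, hi + 1))
    builders = [_sentence(rng, config.rates) for _ in range(n_sent)]
    parts: List[str] = []
    offsets: List[int] = []
    pos = 0
    for i, sb in enumerate(builders):
        offsets.append(pos)
        parts.append(sb.text)
        pos += len(sb.text)
        if i < n_sent - 1:
            sep = "\n" if rng.random() < config.rates["cross_line"] else " "
            parts.append(sep)
            pos += 1
    text = "".join(parts) + "\n"
    doc = preprocess(text, doc_id)
    entities: List[Entity] = []
    relations: List[Relation] = []
    for sb, base in zip(builders, offsets):
        idx_map = {}
        for i, (s, e, category, attrs) in enumerate(sb.entities):
            ent = Entity(doc_id, category, text[base + s:base + e],
                         base + s, base + e, attrs=attrs)
            idx_map[i] = ent
            entities.append(ent)
        for fm_i, other_i, rtype, score, negation in sb.relations:
            relations.append(Relation(doc_id, rtype, idx_map[fm_i],
                                      idx_map[other_i], score=score,
                                      negation=negation))
    return doc, entities, relations


def generate_corpus(config: GenConfig
                    ) -> Tuple[List[Document], List[Entity], List[Relation]]:
    """Seed-deterministic corpus: (documents, gold entities, gold relations)."""
    rng = np.random.default_rng(config.seed)
    docs: List[Document] = []
    entities: List[Entity] = []
    relations: List[Relation] = []
    for i in range(config.n_documents):
        doc, ents, rels = generate_document(rng, f"synth{i:04d}", config)
        docs.append(doc)
        entities.extend(ents)
        relations.extend(rels)
    return docs, entities, relations
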