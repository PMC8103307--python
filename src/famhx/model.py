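"""Core data model for family-history information extraction.

A clinical note is represented as a :class:`Document` — the raw text plus an
ordered list of sentences, each holding offset-faithful, POS-tagged tokens.
All character coordinates are 0-based, half-open, into the document text.

Extracted information is carried by :class:`Entity` (family member,
observation, or living-status mention, with category-specific attributes)
and :class:`Relation` (a typed pair linking a family member to a living
status — which carries an ordinal health score — or to an observation —
which carries a negation flag).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Tuple


class Category(str, enum.Enum):
    FAMILY_MEMBER = "FamilyMember"
    OBSERVATION = "Observation"
    LIVING_STATUS = "LivingStatus"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Canonical normalized family-member names, split by degree of kinship.
FIRST_DEGREE = (
    "Father", "Mother", "Parent", "Brother", "Sister", "Sibling",
    "Son", "Daughter", "Child",
)
SECOND_DEGREE = (
    "Grandfather", "Grandmother", "Grandparent", "Uncle", "Aunt", "Cousin",
)
NORMALIZED_NAMES = FIRST_DEGREE + SECOND_DEGREE

SIDES = ("Paternal", "Maternal", "NA")
NEGATIONS = ("Negated", "Non_Negated")
#: Living-status scores: 0 = not alive, 2 = alive (health unknown),
#: 4 = alive and healthy.
LIVING_STATUS_SCORES = (0, 2, 4)


def degree_of(normalized_name: str) -> str:
    """Degree ('first' or 'second') implied by a normalized kin name."""
    if normalized_name in FIRST_DEGREE:
        return "first"
    if normalized_name in SECOND_DEGREE:
        return "second"
    raise ValueError(f"unknown normalized family member name: {normalized_name!r}")


@dataclass(frozen=True)
class Token:
    text: str
    start: int
    end: int
    pos: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad token span ({self.start}, {self.end})")
        if not self.pos:
            raise ValueError("token POS tag must be non-empty")


@dataclass(frozen=True)
class Sentence:
    start: int
    end: int
    text: str
    tokens: Tuple[Token, ...]

    def __post_init__(self) -> None:
        if len(self.text) != self.end - self.start:
            raise ValueError("sentence text length inconsistent with span")
        prev = self.start
        for tok in self.tokens:
            if tok.start < prev or tok.end > self.end:
                raise ValueError("token spans must be ordered and nested in sentence")
            if tok.text != self.text[tok.start - self.start : tok.end - self.start]:
                raise ValueError(f"token text {tok.text!r} does not match sentence slice")
            prev = tok.end


@dataclass(frozen=True)
class Document:
    doc_id: str
    text: str
    sentences: Tuple[Sentence, ...]

    def __post_init__(self) -> None:
        prev = 0
        for sent in self.sentences:
            if sent.start < prev or sent.end > len(self.text):
                raise ValueError("sentence spans must be ordered and within the text")
            if sent.text != self.text[sent.start : sent.end]:
                raise ValueError("sentence text does not match document slice")
            prev = sent.end

    def sentence_at(self, offset: int) -> Optional[Sentence]:
        """Sentence whose span contains the character ``offset``."""
        for sent in self.sentences:
            if sent.start <= offset < sent.end:
                return sent
        return None


@dataclass(frozen=True)
class FamilyMemberAttrs:
    normalized_name: str
    side: str = "NA"
    degree: str = field(default="")

    def __post_init__(self) -> None:
        if self.normalized_name not in NORMALIZED_NAMES:
            raise ValueError(f"unknown normalized name {self.normalized_name!r}")
        if self.side not in SIDES:
            raise ValueError(f"unknown family side {self.side!r}")
        implied = degree_of(self.normalized_name)
        if self.degree and self.degree != implied:
            raise ValueError("degree inconsistent with normalized name")
        object.__setattr__(self, "degree", implied)
        if self.degree == "first" and self.side != "NA":
            raise ValueError("first-degree relatives carry no family side")


@dataclass(frozen=True)
class ObservationAttrs:
    negation: str = "Non_Negated"

    def __post_init__(self) -> None:
        if self.negation not in NEGATIONS:
            raise ValueError(f"negation must be one of {NEGATIONS}")


@dataclass(frozen=True)
class LivingStatusAttrs:
    score: int = 2

    def __post_init__(self) -> None:
        if self.score not in LIVING_STATUS_SCORES:
            raise ValueError(f"living-status score must be in {LIVING_STATUS_SCORES}")


_ATTR_TYPES = {
    Category.FAMILY_MEMBER: FamilyMemberAttrs,
    Category.OBSERVATION: ObservationAttrs,
    Category.LIVING_STATUS: LivingStatusAttrs,
}


@dataclass(frozen=True)
class Entity:
    """A typed mention.  ``start``/``end`` are document character offsets.

    Entities read back from the document-level annotation files carry no
    offsets (the interchange format is tuple-based); those have
    ``start is None``.
    """

    doc_id: str
    category: Category
    text: str
    start: Optional[int] = None
    end: Optional[int] = None
    attrs: object = None

    def __post_init__(self) -> None:
        if (self.start is None) != (self.end is None):
            raise ValueError("start and end must be set together")
        if self.start is not None and not (0 <= self.start < self.end):
            raise ValueError("entity span must be non-empty")
        if self.attrs is not None and not isinstance(self.attrs, _ATTR_TYPES[self.category]):
            raise ValueError(
                f"attrs {type(self.attrs).__name__} invalid for category {self.category}"
            )

    @property
    def span(self) -> Optional[Tuple[int, int]]:
        if self.start is None:
            return None
        return (self.start, self.end)

    def key(self) -> Tuple[str, str, int, int]:
        """Identity used by the voting ensemble: exact span plus category."""
        if self.start is None:
            raise ValueError("entity without offsets has no span key")
        return (self.doc_id, self.category.value, self.start, self.end)


class RelationType(str, enum.Enum):
    FM_LIVING_STATUS = "FamilyMember_LivingStatus"
    FM_OBSERVATION = "FamilyMember_Observation"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class Relation:
    doc_id: str
    type: RelationType
    family_member: Entity
    other: Entity
    score: Optional[int] = None
    negation: Optional[str] = None

    def __post_init__(self) -> None:
        if self.family_member.category is not Category.FAMILY_MEMBER:
            raise ValueError("relation head must be a FamilyMember entity")
        if self.type is RelationType.FM_LIVING_STATUS:
            if self.other.category is not Category.LIVING_STATUS:
                raise ValueError("FM-LS relation tail must be a LivingStatus entity")
            if self.score not in LIVING_STATUS_SCORES or self.negation is not None:
                raise ValueError("FM-LS relation carries a score and no negation")
        else:
            if self.other.category is not Category.OBSERVATION:
                raise ValueError("FM-OBS relation tail must be an Observation entity")
            if self.negation not in NEGATIONS or self.score is not None:
                raise ValueError("FM-OBS relation carries a negation and no score")
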