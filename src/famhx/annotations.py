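"""Reading and writing the document-level annotation interchange files.

Two tab-separated files describe a corpus's extracted content, one record
per line, no quoting:

entity file
    ``doc_id<TAB>FamilyMember<TAB>normalized_name<TAB>side``
    ``doc_id<TAB>Observation<TAB>surface_text<TAB>negation``
    ``doc_id<TAB>LivingStatus<TAB>surface_text<TAB>score``

relation file
    ``doc_id<TAB>fm_normalized<TAB>fm_side<TAB>LivingStatus<TAB>score``
    ``doc_id<TAB>fm_normalized<TAB>fm_side<TAB>Observation<TAB>obs_text<TAB>negation``

Records are document-level tuples (no character offsets), matching how the
shared task scores outputs.  Writing sorts lines, so output is
byte-deterministic, and reading back what was written preserves the
logical content.
"""

from __future__ import annotations

import os
from typing import Iterable, List, Tuple

from .model import (
    Category,
    Entity,
    FamilyMemberAttrs,
    LivingStatusAttrs,
    NEGATIONS,
    NORMALIZED_NAMES,
    ObservationAttrs,
    Relation,
    RelationType,
    SIDES,
)

ENTITY_FILE = "entities.tsv"
RELATION_FILE = "relations.tsv"


class AnnotationFormatError(ValueError):
    def __init__(self, path: str, lineno: int, message: str) -> None:
        super().__init__(f"{path}:{lineno}: {message}")
        self.path, self.lineno = path, lineno


def _parse_entity_line(path: str, lineno: int, fields: List[str]) -> Entity:
    if len(fields) != 4:
        raise AnnotationFormatError(path, lineno, f"expected 4 fields, got {len(fields)}")
    doc_id, category, f3, f4 = fields
    if category == Category.FAMILY_MEMBER.value:
        if f3 not in NORMALIZED_NAMES:
            raise AnnotationFormatError(path, lineno, f"unknown normalized name {f3!r}")
        if f4 not in SIDES:
            raise AnnotationFormatError(path, lineno, f"unknown family side {f4!r}")
        return Entity(doc_id, Category.FAMILY_MEMBER, f3,
                      attrs=FamilyMemberAttrs(f3, f4))
    if category == Category.OBSERVATION.value:
        if f4 not in NEGATIONS:
            raise AnnotationFormatError(path, lineno, f"unknown negation value {f4!r}")
        return Entity(doc_id, Category.OBSERVATION, f3, attrs=ObservationAttrs(f4))
    if category == Category.LIVING_STATUS.value:
        try:
            score = int(f4)
            attrs = LivingStatusAttrs(score)
        except ValueError:
            raise AnnotationFormatError(path, lineno, f"bad living-status score {f4!r}")
        return Entity(doc_id, Category.LIVING_STATUS, f3, attrs=attrs)
    raise AnnotationFormatError(path, lineno, f"unknown entity category {category!r}")


def _parse_relation_line(path: str, lineno: int, fields: List[str]) -> Relation:
    if len(fields) < 5:
        raise AnnotationFormatError(path, lineno, f"expected >=5 fields, got {len(fields)}")
    doc_id, fm_norm, fm_side, kind = fields[:4]
    if fm_norm not in NORMALIZED_NAMES:
        raise AnnotationFormatError(path, lineno, f"unknown normalized name {fm_norm!r}")
    if fm_side not in SIDES:
        raise AnnotationFormatError(path, lineno, f"unknown family side {fm_side!r}")
    fm = Entity(doc_id, Category.FAMILY_MEMBER, fm_norm,
                attrs=FamilyMemberAttrs(fm_norm, fm_side))
    if kind == Category.LIVING_STATUS.value:
        if len(fields) != 5:
            raise AnnotationFormatError(path, lineno, "living-status relation takes 5 fields")
        try:
            score = int(fields[4])
            other = Entity(doc_id, Category.LIVING_STATUS, fields[4],
                           attrs=LivingStatusAttrs(score))
        except ValueError:
            raise AnnotationFormatError(path, lineno, f"bad score {fields[4]!r}")
        return Relation(doc_id, RelationType.FM_LIVING_STATUS, fm, other, score=score)
    if kind == Category.OBSERVATION.value:
        if len(fields) != 6:
            raise AnnotationFormatError(path, lineno, "observation relation takes 6 fields")
        obs_text, negation = fields[4], fields[5]
        if negation not in NEGATIONS:
            raise AnnotationFormatError(path, lineno, f"unknown negation value {negation!r}")
        other = Entity(doc_id, Category.OBSERVATION, obs_text,
                       attrs=ObservationAttrs(negation))
        return Relation(doc_id, RelationType.FM_OBSERVATION, fm, other, negation=negation)
    raise AnnotationFormatError(path, lineno, f"unknown relation tail type {kind!r}")


def _read_lines(path: str) -> Iterable[Tuple[int, List[str]]]:
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            yield lineno, line.split("\t")


def read_annotations(entity_path: str, relation_path: str) -> Tuple[List[Entity], List[Relation]]:
    entities = [_parse_entity_line(entity_path, n, f) for n, f in _read_lines(entity_path)]
    relations = [_parse_relation_line(relation_path, n, f) for n, f in _read_lines(relation_path)]
    return entities, relations


def entity_line(e: Entity) -> str:
    if e.category is Category.FAMILY_MEMBER:
        if not isinstance(e.attrs, FamilyMemberAttrs):
            raise ValueError("FamilyMember entity needs attributes to be written")
        return "\t".join((e.doc_id, e.category.value, e.attrs.normalized_name, e.attrs.side))
    if e.category is Category.OBSERVATION:
        neg = e.attrs.negation if isinstance(e.attrs, ObservationAttrs) else "Non_Negated"
        return "\t".join((e.doc_id, e.category.value, e.text, neg))
    score = e.attrs.score if isinstance(e.attrs, LivingStatusAttrs) else 2
    return "\t".join((e.doc_id, e.category.value, e.text, str(score)))


def relation_line(r: Relation) -> str:
    fm = r.family_member.attrs
    if not isinstance(fm, FamilyMemberAttrs):
        raise ValueError("relation head needs family-member attributes to be written")
    head = (r.doc_id, fm.normalized_name, fm.side)
    if r.type is RelationType.FM_LIVING_STATUS:
        return "\t".join(head + (Category.LIVING_STATUS.value, str(r.score)))
    return "\t".join(head + (Category.OBSERVATION.value, r.other.text, r.negation))


STANDOFF_FILE = "gold_standoff.tsv"


def write_standoff(entities: Iterable[Entity], relations: Iterable[Relation],
                   path: str) -> None:
    """Offset-bearing gold in one TSV (E/R records).

    The document-level files above are the interchange format; this
    standoff file additionally keeps character spans so learned components
    can be retrained from files.  Entities must carry offsets.
    """
    lines = []
    for e in entities:
        if e.start is None:
            raise ValueError("standoff entities must carry offsets")
        if e.category is Category.FAMILY_MEMBER:
            f5, f6 = e.attrs.normalized_name, e.attrs.side
        elif e.category is Category.OBSERVATION:
            f5, f6 = e.attrs.negation if e.attrs else "Non_Negated", ""
        else:
            f5, f6 = str(e.attrs.score if e.attrs else 2), ""
        lines.append("\t".join(("E", e.doc_id, e.category.value,
                                str(e.start), str(e.end), f5, f6)))
    for r in relations:
        attr = str(r.score) if r.type is RelationType.FM_LIVING_STATUS else r.negation
        lines.append("\t".join(
            ("R", r.doc_id, r.type.value,
             str(r.family_member.start), str(r.family_member.end),
             str(r.other.start), str(r.other.end), attr)))
    with open(path, "w", encoding="utf-8") as fh:
        for line in sorted(lines):  # 'E' sorts before 'R': entities first
            fh.write(line + "\n")


def read_standoff(path: str, texts) -> Tuple[List[Entity], List[Relation]]:
    """Read a standoff file; ``texts`` maps doc_id -> raw document text."""
    entities: List[Entity] = []
    index = {}
    relations: List[Relation] = []
    for lineno, fields in _read_lines(path):
        kind = fields[0]
        if kind == "E":
            if len(fields) != 7:
                raise AnnotationFormatError(path, lineno, "E record takes 7 fields")
            _, doc_id, cat, start, end, f5, f6 = fields
            start, end = int(start), int(end)
            if doc_id not in texts:
                raise AnnotationFormatError(path, lineno, f"unknown document {doc_id!r}")
            text = texts[doc_id][start:end]
            category = Category(cat)
            if category is Category.FAMILY_MEMBER:
                attrs = FamilyMemberAttrs(f5, f6)
            elif category is Category.OBSERVATION:
                attrs = ObservationAttrs(f5)
            else:
                attrs = LivingStatusAttrs(int(f5))
            ent = Entity(doc_id, category, text, start, end, attrs=attrs)
            entities.append(ent)
            index[(doc_id, start, end)] = ent
        elif kind == "R":
            if len(fields) != 8:
                raise AnnotationFormatError(path, lineno, "R record takes 8 fields")
            _, doc_id, rtype, fs, fe, os_, oe, attr = fields
            try:
                fm = index[(doc_id, int(fs), int(fe))]
                other = index[(doc_id, int(os_), int(oe))]
            except KeyError:
                raise AnnotationFormatError(path, lineno, "relation references unknown entity")
            rel_type = RelationType(rtype)
            if rel_type is RelationType.FM_LIVING_STATUS:
                relations.append(Relation(doc_id, rel_type, fm, other, score=int(attr)))
            else:
                relations.append(Relation(doc_id, rel_type, fm, other, negation=attr))
        else:
            raise AnnotationFormatError(path, lineno, f"unknown record kind {kind!r}")
    return entities, relations


def write_annotations(entities: Iterable[Entity], relations: Iterable[Relation],
                      out_dir: str) -> Tuple[str, str]:
    """Write the two TSV files into ``out_dir``; returns their paths."""
    os.makedirs(out_dir, exist_ok=True)
    epath = os.path.join(out_dir, ENTITY_FILE)
    rpath = os.path.join(out_dir, RELATION_FILE)
    with open(epath, "w", encoding="utf-8") as fh:
        for line in sorted(entity_line(e) for e in entities):
            fh.write(line + "\n")
    with open(rpath, "w", encoding="utf-8") as fh:
        for line in sorted(relation_line(r) for r in relations):
            fh.write(line + "\n")
    return epath, rpath
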