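"""BIO tag codec: entity spans <-> per-token label sequences.

Labels are ``O`` or ``B-``/``I-`` prefixed category names.  Decoding
repairs malformed sequences (an ``I-X`` not preceded by ``B-X``/``I-X``
opens a new entity, i.e. is treated as ``B-X``) rather than dropping
tokens — this favors recall, which is how voting candidates are harvested.
"""

from __future__ import annotations

from typing import Iterable, List, Sequence

from .model import Category, Document, Entity, Sentence

LABELS = ("O",) + tuple(
    f"{p}-{c.value}" for c in Category for p in ("B", "I")
)


def encode_bio(sentence: Sentence, entities: Iterable[Entity]) -> List[str]:
    """Label each token of ``sentence`` from the entities covering it.

    Entities must lie within the sentence span and must not overlap each
    other (overlapping gold spans — same or cross category — are a corpus
    defect and raise ``ValueError``).  A token belongs to an entity when
    their character spans intersect; the first such token gets ``B-``,
    later ones ``I-``.
    """
    inside = [e for e in entities
              if e.start is not None
              and e.start < sentence.end and e.end > sentence.start]
    inside.sort(key=lambda e: (e.start, e.end))
    for prev, cur in zip(inside, inside[1:]):
        if cur.start < prev.end:
            raise ValueError(
                f"overlapping gold spans ({prev.start},{prev.end}) and "
                f"({cur.start},{cur.end}) in doc {prev.doc_id!r}"
            )
    for e in inside:
        if e.start < sentence.start or e.end > sentence.end:
            raise ValueError("entity extends beyond sentence boundary")
    tags = ["O"] * len(sentence.tokens)
    for e in inside:
        first = True
        for i, tok in enumerate(sentence.tokens):
            if tok.start < e.end and tok.end > e.start:
                tags[i] = ("B-" if first else "I-") + e.category.value
                first = False
    return tags


def decode_bio(tags: Sequence[str], sentence: Sentence, doc_id: str) -> List[Entity]:
    """Inverse of :func:`encode_bio`, with repair of leading ``I-`` tags."""
    if len(tags) != len(sentence.tokens):
        raise ValueError(
            f"tag sequence length {len(tags)} != token count {len(sentence.tokens)}"
        )
    entities: List[Entity] = []
    run_cat = None  # category name of the open run
    run_start = run_end = 0

    def close() -> None:
        nonlocal run_cat
        if run_cat is not None:
            text = sentence.text[run_start - sentence.start : run_end - sentence.start]
            entities.append(
                Entity(doc_id, Category(run_cat), text, run_start, run_end)
            )
            run_cat = None

    for tok, tag in zip(sentence.tokens, tags):
        if tag == "O":
            close()
            continue
        prefix, cat = tag.split("-", 1)
        if prefix == "B" or cat != run_cat:
            close()
            run_cat, run_start = cat, tok.start
        run_end = tok.end
    close()
    return entities
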