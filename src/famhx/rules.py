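"""Rule-based components: family-member matching and attribute heuristics.

Four deterministic heuristics live here, mirroring the post-processing
stages of the extraction pipeline:

* dictionary + POS matching of family-member mentions,
* normalization of kin surface forms (``"his dad"`` -> ``Father``,
  ``"three uncles"`` -> ``Uncle``), including re-normalization through a
  possessing relative (the patient's mother's "sister" is the patient's
  ``Aunt``),
* family-side assignment (Paternal / Maternal / NA) from cue phrases,
  searched in the mention first and then out to the sentence boundary,
* living-status scoring (0 = not alive, 4 = alive and healthy, 2 =
  otherwise; the not-alive check runs first) and ConText-style negation
  detection with a forward trigger scope.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from typing import Dict, List, Optional, Sequence, Set, Tuple

import yaml

from .model import Category, Document, Entity, Sentence, degree_of

_NOUN_TAGS = {"NN", "NNP", "NNS"}
_NUMBER_WORDS = {
    "one", "two", "three", "four", "five", "six", "seven", "eight",
    "nine", "ten", "eleven", "twelve", "several", "many", "few",
}
_SKIP_WORDS = {"the", "a", "an", "his", "her", "their", "my", "our", "s"}
#: words allowed between a possessing kin term and the kin term it modifies
_HAVE_VERBS = {"has", "had", "have"}
_HAVE_FILLERS = {"a", "an", "one", "the"} | _NUMBER_WORDS


@dataclass(frozen=True)
class FamilyLexicon:
    """Surface kin terms and the kin-composition table."""

    terms: Dict[str, str]
    composition: Dict[str, Dict[str, str]]

    def __post_init__(self) -> None:
        for name in self.terms.values():
            degree_of(name)  # raises on a name outside the annotated set
        for ctx, row in self.composition.items():
            degree_of(ctx)
            for tgt, res in row.items():
                degree_of(tgt)
                degree_of(res)


@dataclass(frozen=True)
class CueLexicon:
    paternal: Tuple[str, ...]
    maternal: Tuple[str, ...]
    not_alive: Tuple[str, ...]
    healthy: Tuple[str, ...]
    negation_triggers: Tuple[str, ...]
    negation_terminators: Tuple[str, ...]

    def __post_init__(self) -> None:
        for field in ("paternal", "maternal", "not_alive", "healthy",
                      "negation_triggers", "negation_terminators"):
            cues = getattr(self, field)
            if not cues:
                raise ValueError(f"cue list {field!r} must be non-empty")
            if any(c != c.lower() for c in cues):
                raise ValueError(f"cue list {field!r} must be lowercase")


def _resource_text(name: str) -> str:
    return resources.files("famhx.resources").joinpath(name).read_text(encoding="utf-8")


def load_family_lexicon(path: Optional[str] = None) -> FamilyLexicon:
    raw = yaml.safe_load(open(path, encoding="utf-8").read() if path
                         else _resource_text("family_lexicon.yaml"))
    return FamilyLexicon(terms=dict(raw["terms"]),
                         composition={k: dict(v) for k, v in raw["composition"].items()})


def load_cue_lexicon(path: Optional[str] = None) -> CueLexicon:
    raw = yaml.safe_load(open(path, encoding="utf-8").read() if path
                         else _resource_text("cues.yaml"))
    return CueLexicon(
        paternal=tuple(raw["paternal"]),
        maternal=tuple(raw["maternal"]),
        not_alive=tuple(raw["not_alive"]),
        healthy=tuple(raw["healthy"]),
        negation_triggers=tuple(raw["negation_triggers"]),
        negation_terminators=tuple(raw["negation_terminators"]),
    )


def match_family_members(doc: Document, lexicon: FamilyLexicon) -> List[Entity]:
    """One FamilyMember entity per kin-term token tagged as a noun.

    Excluded relatives (spouse, nephew, ...) are simply absent from the
    lexicon, so they never match; nor do kin words used as verbs
    ("they will father a child").
    """
    out = []
    for sent in doc.sentences:
        for tok in sent.tokens:
            if tok.pos in _NOUN_TAGS and tok.text.lower() in lexicon.terms:
                out.append(Entity(doc.doc_id, Category.FAMILY_MEMBER,
                                  tok.text, tok.start, tok.end))
    return out


def _kin_words(text: str) -> List[str]:
    return [w for w in re.findall(r"[a-z]+", text.lower())
            if w not in _NUMBER_WORDS and w not in _SKIP_WORDS and not w.isdigit()]


def normalize_family_member(
    entity_text: str,
    lexicon: FamilyLexicon,
    sentence: Optional[Sentence] = None,
    entity_start: Optional[int] = None,
) -> Optional[str]:
    """Normalized kin name for a mention, or ``None`` when unnormalizable.

    The text is lowercased, numeric modifiers and determiners are stripped,
    and the last remaining kin word is looked up.  When the sentence is
    supplied, the nearest preceding kin token in possessive position
    (``mother's sister``) or have-construction (``mother has a sister``)
    re-normalizes the result through the composition table.  Unknown kin
    words yield ``None`` — the caller surfaces the failure rather than
    guessing.
    """
    base = None
    for word in _kin_words(entity_text):
        if word in lexicon.terms:
            base = lexicon.terms[word]
    if base is None:
        return None
    if sentence is None or entity_start is None:
        return base
    context = _preceding_kin(sentence, entity_start, lexicon)
    if context is not None:
        return lexicon.composition.get(context, {}).get(base, base)
    return base


def _preceding_kin(sentence: Sentence, entity_start: int,
                   lexicon: FamilyLexicon) -> Optional[str]:
    """Normalized name of a kin token modifying the mention at ``entity_start``.

    The modifier must be the nearest kin token before the mention, linked to
    it by a possessive clitic or a short have-construction; coordination
    ("mother and father") does not count as modification.
    """
    toks = [t for t in sentence.tokens if t.end <= entity_start]
    for i in range(len(toks) - 1, -1, -1):
        low = toks[i].text.lower()
        if low in lexicon.terms:
            between = [t.text.lower() for t in toks[i + 1:]]
            if between == ["'s"]:
                return lexicon.terms[low]
            if between and between[0] in _HAVE_VERBS and \
                    all(w in _HAVE_FILLERS for w in between[1:]):
                return lexicon.terms[low]
            return None
    return None


def assign_family_side(
    entity_text: str,
    normalized_name: str,
    cues: CueLexicon,
    sentence: Optional[Sentence] = None,
    entity_start: Optional[int] = None,
) -> str:
    """Family side for a mention: first-degree relatives are always NA;
    otherwise cues are searched in the mention text, then the sentence."""
    if degree_of(normalized_name) == "first":
        return "NA"
    hit = _nearest_cue(entity_text.lower(), 0, cues)
    if hit is None and sentence is not None:
        anchor = (entity_start - sentence.start) if entity_start is not None else 0
        hit = _nearest_cue(sentence.text.lower(), anchor, cues)
    return hit if hit is not None else "NA"


def _nearest_cue(text: str, anchor: int, cues: CueLexicon) -> Optional[str]:
    best: Optional[Tuple[int, int, str]] = None
    for side, cue_list in (("Paternal", cues.paternal), ("Maternal", cues.maternal)):
        for cue in cue_list:
            pos = text.find(cue)
            while pos != -1:
                cand = (abs(pos - anchor), pos, side)
                if best is None or cand < best:
                    best = cand
                pos = text.find(cue, pos + 1)
    return best[2] if best else None


def score_living_status(phrase: str, cues: CueLexicon) -> int:
    """Ordinal living-status score from a living-status phrase.

    Not-alive cues take precedence (checked first); a healthy cue without a
    not-alive cue scores 4; otherwise the relative is assumed alive with
    unknown health (2).
    """
    if not phrase:
        raise ValueError("living-status phrase must be non-empty")
    low = phrase.lower()
    if any(cue in low for cue in cues.not_alive):
        return 0
    if any(cue in low for cue in cues.healthy):
        return 4
    return 2


def _token_texts(sentence: Sentence) -> List[str]:
    return [t.text.lower() for t in sentence.tokens]


def detect_negation(sentence: Sentence, observation: Entity,
                    cues: CueLexicon, window: int = 6) -> str:
    """ConText-style negation for an observation inside ``sentence``.

    A pre-scope trigger opens a forward scope running to the sentence end,
    to a termination conjunction, or over at most ``window`` tokens,
    whichever comes first; the observation is Negated when its first token
    falls inside any trigger's scope.
    """
    if observation.start is None or not (
            sentence.start <= observation.start < sentence.end):
        raise ValueError("observation must lie inside the sentence")
    words = _token_texts(sentence)
    obs_idx = next(i for i, t in enumerate(sentence.tokens)
                   if t.end > observation.start)
    triggers = [tuple(t.split()) for t in cues.negation_triggers]
    terminators = set(cues.negation_terminators)
    for i in range(len(words)):
        for trig in triggers:
            j = i + len(trig)
            if tuple(words[i:j]) != trig:
                continue
            end = min(j + window, len(words))
            for k in range(j, end):
                if words[k] in terminators:
                    end = k
                    break
            if j <= obs_idx < end:
                return "Negated"
    return "Non_Negated"
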