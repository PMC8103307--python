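"""Sentence splitting, tokenization, and part-of-speech tagging.

Clinical family-history sections are short, line-oriented, and lexically
narrow, so a compact rule tagger over a regex tokenizer is sufficient here:
sentences break at terminal punctuation and at newlines, tokens are words /
numbers / possessive clitics / punctuation, and POS tags come from a small
closed-class lexicon plus suffix and context rules (Penn Treebank tagset).
Everything is offset-faithful: each token's text equals the document
substring at its span, which downstream entity spans rely on.
"""

from __future__ import annotations

import re
from typing import List, Tuple

from .model import Document, Sentence, Token

_TOKEN_RE = re.compile(r"[A-Za-z]+|[0-9]+(?:\.[0-9]+)?|'s|[^\sA-Za-z0-9]")

# Closed-class and high-frequency lexicon.  Keys lowercase.
_LEXICON = {
    "the": "DT", "a": "DT", "an": "DT", "this": "DT", "that": "DT",
    "these": "DT", "those": "DT", "no": "DT", "all": "DT", "both": "DT",
    "any": "DT", "some": "DT", "each": "DT",
    "his": "PRP$", "her": "PRP$", "their": "PRP$", "my": "PRP$",
    "our": "PRP$", "its": "PRP$", "your": "PRP$",
    "he": "PRP", "she": "PRP", "they": "PRP", "it": "PRP", "i": "PRP",
    "we": "PRP", "you": "PRP", "him": "PRP", "them": "PRP", "us": "PRP",
    "who": "WP", "which": "WDT",
    "is": "VBZ", "are": "VBP", "was": "VBD", "were": "VBD", "be": "VB",
    "been": "VBN", "being": "VBG", "am": "VBP",
    "has": "VBZ", "have": "VBP", "had": "VBD",
    "does": "VBZ", "do": "VBP", "did": "VBD",
    "died": "VBD", "dies": "VBZ", "denies": "VBZ", "denied": "VBD",
    "reports": "VBZ", "reported": "VBD", "confirms": "VBZ",
    "lives": "VBZ", "lived": "VBD", "suffers": "VBZ", "remains": "VBZ",
    "includes": "VBZ", "passed": "VBD", "diagnosed": "VBN", "says": "VBZ",
    "will": "MD", "would": "MD", "can": "MD", "could": "MD", "may": "MD",
    "might": "MD", "must": "MD", "should": "MD",
    "to": "TO", "of": "IN", "in": "IN", "on": "IN", "at": "IN",
    "with": "IN", "without": "IN", "from": "IN", "for": "IN", "by": "IN",
    "as": "IN", "about": "IN",
    "and": "CC", "or": "CC", "but": "CC", "nor": "CC",
    "not": "RB", "also": "RB", "however": "RB", "currently": "RB",
    "still": "RB", "well": "RB", "otherwise": "RB", "never": "RB",
    "healthy": "JJ", "alive": "JJ", "deceased": "JJ", "dead": "JJ",
    "good": "JJ", "general": "JJ", "significant": "JJ", "aware": "JJ",
    "unknown": "JJ", "medical": "JJ", "maternal": "JJ", "paternal": "JJ",
    "twin": "JJ", "several": "JJ", "many": "JJ", "unremarkable": "JJ",
    "there": "EX",
    "one": "CD", "two": "CD", "three": "CD", "four": "CD", "five": "CD",
    "six": "CD", "seven": "CD", "eight": "CD", "nine": "CD", "ten": "CD",
    "'s": "POS",
    "age": "NN", "ago": "RB", "years": "NNS", "year": "NN",
}


def _tag_word(word: str, prev_tag: str, sentence_initial: bool) -> str:
    lower = word.lower()
    if lower in _LEXICON:
        tag = _LEXICON[lower]
        # base verbs after a modal or infinitival "to" ("will father a child")
        if prev_tag in ("MD", "TO") and tag.startswith(("NN", "VB")):
            return "VB"
        return tag
    if re.fullmatch(r"[0-9]+(?:\.[0-9]+)?", word):
        return "CD"
    if not word[0].isalpha():
        return word  # punctuation tags itself (PTB style for . , : etc.)
    if prev_tag in ("MD", "TO"):
        return "VB"
    if word[0].isupper() and not sentence_initial:
        return "NNP"
    if lower.endswith("ing") and len(lower) > 4:
        return "VBG"
    if lower.endswith("ed") and len(lower) > 3:
        return "VBD"
    if lower.endswith("ly") and len(lower) > 3:
        return "RB"
    if lower.endswith("s") and not lower.endswith(("ss", "us", "is")) and len(lower) > 2:
        return "NNS"
    return "NN"


def _split_sentence_spans(text: str) -> List[Tuple[int, int]]:
    """Half-open character spans of sentences; whitespace-trimmed.

    A boundary falls after '.', '!', '?' and at every newline.  Text with
    no terminator forms a single sentence.
    """
    spans: List[Tuple[int, int]] = []
    start = None
    i = 0
    n = len(text)
    while i < n:
        ch = text[i]
        if ch == "\n":
            if start is not None:
                spans.append((start, i))
                start = None
            i += 1
            continue
        if start is None and not ch.isspace():
            start = i
        if ch in ".!?" and start is not None:
            spans.append((start, i + 1))
            start = None
        i += 1
    if start is not None:
        spans.append((start, n))
    # trim trailing whitespace inside each span
    trimmed = []
    for s, e in spans:
        while e > s and text[e - 1].isspace():
            e -= 1
        if e > s:
            trimmed.append((s, e))
    return trimmed


def preprocess(raw_text: str, doc_id: str) -> Document:
    """Turn a raw note into an offset-faithful, POS-tagged :class:`Document`.

    Deterministic for a fixed input.  Raises ``ValueError`` on an empty or
    whitespace-only note (an unusable document).
    """
    if not raw_text or not raw_text.strip():
        raise ValueError(f"document {doc_id!r} is empty: nothing to process")
    sentences = []
    for s, e in _split_sentence_spans(raw_text):
        sent_text = raw_text[s:e]
        tokens = []
        prev_tag = ""
        for m in _TOKEN_RE.finditer(sent_text):
            word = m.group(0)
            tag = _tag_word(word, prev_tag, sentence_initial=not tokens)
            tokens.append(Token(word, s + m.start(), s + m.end(), tag))
            prev_tag = tag
        sentences.append(Sentence(s, e, sent_text, tuple(tokens)))
    return Document(doc_id, raw_text, tuple(sentences))
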