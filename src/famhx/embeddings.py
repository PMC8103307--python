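"""Word-representation providers feeding the sequence tagger.

Two kinds of provider exist.  A *trainable* provider only declares a
dimension; the tagger owns the corresponding lookup matrix and updates it
during training.  A *static* provider maps a sentence's token texts to a
fixed vector sequence: either a hashed character-n-gram embedding (robust
to unseen words, deterministic, no training) or vectors read from a
word2vec-text file, so externally pretrained embeddings can be plugged in
without being required.
"""

from __future__ import annotations

import zlib
from typing import Dict, List, Optional, Sequence

import numpy as np


class EmbeddingProvider:
    """Contract: ``vectors(tokens)`` returns one ``dim``-vector per token."""

    name: str = "base"
    kind: str = "static"  # or "contextual"
    trainable: bool = False
    dim: int = 0

    def vectors(self, tokens: Sequence[str]) -> np.ndarray:
        raise NotImplementedError

    def spec(self) -> Dict[str, object]:
        return {"name": self.name, "kind": self.kind, "dim": self.dim,
                "trainable": self.trainable}


class LookupEmbedding(EmbeddingProvider):
    """Randomly initialized lookup table trained with the tagger."""

    name = "lookup"
    trainable = True

    def __init__(self, dim: int = 50) -> None:
        self.dim = dim

    def vectors(self, tokens: Sequence[str]) -> np.ndarray:
        raise TypeError("trainable lookup vectors live inside the tagger")


class CharHashEmbedding(EmbeddingProvider):
    """Hashed character-trigram embedding (signed counts, L2-scaled).

    Gives every token — seen or unseen — a deterministic dense vector from
    its spelling, which is what lets the tagger generalize over lexical
    variants without any pretrained file.
    """

    name = "charhash"

    def __init__(self, dim: int = 20, n: int = 3) -> None:
        self.dim = dim
        self.n = n

    def _token_vector(self, token: str) -> np.ndarray:
        vec = np.zeros(self.dim)
        padded = f"^{token.lower()}$"
        grams = [padded[i:i + self.n] for i in range(max(1, len(padded) - self.n + 1))]
        for g in grams:
            h = zlib.crc32(g.encode("utf-8"))
            sign = 1.0 if (h >> 16) & 1 else -1.0
            vec[h % self.dim] += sign
        norm = np.linalg.norm(vec)
        return vec / norm if norm > 0 else vec

    def vectors(self, tokens: Sequence[str]) -> np.ndarray:
        if not tokens:
            return np.zeros((0, self.dim))
        return np.stack([self._token_vector(t) for t in tokens])


class WordVectorFile(EmbeddingProvider):
    """Static vectors from a text file, one ``token v1 v2 ...`` per line.

    A leading ``<count> <dim>`` header line (word2vec text dialect) is
    accepted and skipped.  Unknown tokens map to the zero vector.
    """

    name = "wordfile"

    def __init__(self, path: str, lowercase: bool = True) -> None:
        self.path = path
        self.lowercase = lowercase
        self._table: Dict[str, np.ndarray] = {}
        dim: Optional[int] = None
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh):
                parts = line.rstrip().split()
                if not parts:
                    continue
                if lineno == 0 and len(parts) == 2 and all(p.isdigit() for p in parts):
                    continue  # header
                word, values = parts[0], parts[1:]
                vec = np.array([float(v) for v in values])
                if dim is None:
                    dim = len(vec)
                elif len(vec) != dim:
                    raise ValueError(f"{path}: inconsistent vector length at line {lineno + 1}")
                self._table[word.lower() if lowercase else word] = vec
        if dim is None:
            raise ValueError(f"{path}: no vectors found")
        self.dim = dim

    def vectors(self, tokens: Sequence[str]) -> np.ndarray:
        out = np.zeros((len(tokens), self.dim))
        for i, tok in enumerate(tokens):
            key = tok.lower() if self.lowercase else tok
            if key in self._table:
                out[i] = self._table[key]
        return out


def default_providers(lookup_dim: int = 50, char_dim: int = 20) -> List[EmbeddingProvider]:
    return [LookupEmbedding(lookup_dim), CharHashEmbedding(char_dim)]
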