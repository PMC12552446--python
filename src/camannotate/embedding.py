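"""Deterministic reference text embedder.

Real deployments plug a sentence-embedding backend (any object with an
``embed(text) -> 1-D array`` method) into the classification and label-cleanup
code.  For tests and fully offline runs the package ships
:class:`HashedNgramEmbedder`, a hashed character n-gram frequency embedder:
dependency-free, order-insensitive across runs and platforms, and
whitespace/case normalising by construction.  It is *not* a semantic model —
similarity reflects shared character n-grams only — but it satisfies the
embedder contract (deterministic text -> fixed-length vector) that all
retrieval logic is written against.
"""

from __future__ import annotations

import re
import zlib

import numpy as np

_WS_RE = re.compile(r"\s+")
# keep word characters, spaces and "/" (labels such as "image dark/blurred/obscured")
_PUNCT_RE = re.compile(r"[^\w\s/]")


def normalize_text(text: str, strip_punctuation: bool = True) -> str:
    """Lowercase, optionally strip punctuation, and collapse whitespace."""
    t = text.lower()
    if strip_punctuation:
        t = _PUNCT_RE.sub(" ", t)
    return _WS_RE.sub(" ", t).strip()


class HashedNgramEmbedder:
    """Hashed character n-gram frequency vectors, L2-normalised.

    Parameters
    ----------
    dim : int
        Embedding dimensionality (default 256).
    ngram : int
        Character n-gram width (default 3).
    seed : int
        Salt mixed into the hash so alternative vocabular layouts can be
        produced; fixed by default so embeddings are stable across sessions.
    strip_punctuation : bool
        Whether punctuation is removed before n-gram extraction.
    """

    def __init__(self, dim: int = 256, ngram: int = 3, seed: int = 17,
                 strip_punctuation: bool = True):
        if dim < 2:
            raise ValueError("dim must be >= 2")
        if ngram < 1:
            raise ValueError("ngram must be >= 1")
        self.dim = int(dim)
        self.ngram = int(ngram)
        self.seed = int(seed)
        self.strip_punctuation = bool(strip_punctuation)
        self._salt = f"{self.seed}:".encode()

    def embed(self, text: str) -> np.ndarray:
        """Embed one string; all-whitespace input yields the zero vector."""
        t = normalize_text(text, self.strip_punctuation)
        v = np.zeros(self.dim, dtype=float)
        if not t:
            return v
        padded = f" {t} "
        n = self.ngram
        if len(padded) < n:
            padded = padded.ljust(n)
        for i in range(len(padded) - n + 1):
            gram = padded[i:i + n]
            idx = zlib.crc32(self._salt + gram.encode("utf-8")) % self.dim
            v[idx] += 1.0
        norm = np.linalg.norm(v)
        if norm > 0:
            v /= norm
        return v

    def embed_many(self, texts) -> np.ndarray:
        """Embed a sequence of strings into an (n, dim) matrix."""
        texts = list(texts)
        out = np.empty((len(texts), self.dim), dtype=float)
        for i, t in enumerate(texts):
            out[i] = self.embed(t)
        return out

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"HashedNgramEmbedder(dim={self.dim}, ngram={self.ngram}, "
                f"seed={self.seed})")
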