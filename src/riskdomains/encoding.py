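"""Sentence embeddings behind a pluggable encoder contract.

Sentences become fixed-width vectors (default 512 dimensions, matching the
Universal Sentence Encoder's output width) through one of two encoders:

``pretrained_adapter``
    A thin adapter around an external pretrained sentence encoder.  It is
    resolved lazily and raises a clear error when no encoder is available,
    never silently substituting anything.  The adapter receives *raw text*
    (pretrained encoders expect natural language).

``hashed_fallback``
    A deterministic, offline signed-hash bag-of-tokens encoder: each token
    is hashed (with the spec seed) to a dense +/-1 pattern, the patterns are
    summed and L2-normalized.  It consumes the merged+stemmed token view so
    merged MWEs act as single distinctive tokens.  Tokens that share no
    vocabulary map to nearly orthogonal directions at d=512, which is the
    property the downstream geometry relies on.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .corpus import SentenceRecord

DEFAULT_DIM = 512


@dataclass(frozen=True)
class EncoderSpec:
    """How to turn sentences into vectors; same spec + same text = same vector."""

    kind: str = "hashed_fallback"  # or "pretrained_adapter"
    dimension: int = DEFAULT_DIM
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("hashed_fallback", "pretrained_adapter"):
            raise ValueError(f"unknown encoder kind: {self.kind!r}")
        if self.dimension <= 0:
            raise ValueError("dimension must be positive")
        if self.kind == "hashed_fallback" and self.dimension < 8:
            raise ValueError("fallback encoder needs dimension >= 8")


#: Optional registry slot for a pretrained text->vector callable.
_ADAPTER: Callable[[list[str]], np.ndarray] | None = None


def register_adapter(fn: Callable[[list[str]], np.ndarray] | None) -> None:
    """Install (or clear) the pretrained-encoder adapter callable.

    The callable maps a list of raw-text strings to an ``(n, d)`` array.
    """
    global _ADAPTER
    _ADAPTER = fn


def _token_pattern(token: str, dimension: int, seed: int) -> np.ndarray:
    """Deterministic dense +/-1 pattern for one token (stable across runs)."""
    digest = hashlib.blake2b(
        f"{seed}\x00{token}".encode("utf-8"), digest_size=8
    ).digest()
    rng = np.random.Generator(np.random.PCG64(int.from_bytes(digest, "little")))
    return rng.integers(0, 2, size=dimension).astype(np.float64) * 2.0 - 1.0


def fallback_embed(tokens: Sequence[str], dimension: int = DEFAULT_DIM, seed: int = 0) -> np.ndarray:
    """Signed-hash bag-of-tokens embedding, L2-normalized.

    An empty token list yields the zero vector (norm 0), which downstream
    scoring treats as a degenerate input.
    """
    if dimension < 8:
        raise ValueError("dimension must be >= 8")
    vec = np.zeros(dimension, dtype=np.float64)
    for tok in tokens:
        vec += _token_pattern(tok, dimension, seed)
    norm = float(np.linalg.norm(vec))
    if norm > 0:
        vec /= norm
    return vec


def encode_sentences(sentences: Sequence[SentenceRecord], spec: EncoderSpec) -> np.ndarray:
    """Encode a corpus to an ``(n, spec.dimension)`` float64 matrix."""
    if spec.kind == "pretrained_adapter":
        if _ADAPTER is None:
            raise RuntimeError(
                "no pretrained encoder adapter is registered; install one with "
                "riskdomains.encoding.register_adapter(fn) or use the "
                "hashed_fallback encoder (EncoderSpec(kind='hashed_fallback'))"
            )
        mat = np.asarray(_ADAPTER([s.raw_text for s in sentences]), dtype=np.float64)
        if mat.shape != (len(sentences), spec.dimension):
            raise ValueError(
                f"adapter returned shape {mat.shape}, expected {(len(sentences), spec.dimension)}"
            )
        return mat
    # hashed fallback: token patterns are cached per vocabulary for speed
    cache: dict[str, np.ndarray] = {}
    out = np.zeros((len(sentences), spec.dimension), dtype=np.float64)
    for i, sent in enumerate(sentences):
        vec = out[i]
        for tok in sent.stemmed_tokens:
            pat = cache.get(tok)
            if pat is None:
                pat = _token_pattern(tok, spec.dimension, spec.seed)
                cache[tok] = pat
            vec += pat
        norm = float(np.linalg.norm(vec))
        if norm > 0:
            vec /= norm
    return out


# ------------------------------------------------------------- cache I/O
def save_embeddings(path: str | Path, matrix: np.ndarray, spec: EncoderSpec) -> None:
    """Persist an embedding matrix (.npy) with a JSON sidecar of the spec."""
    path = Path(path)
    np.save(path, matrix)
    sidecar = path.with_suffix(path.suffix + ".json") if path.suffix != ".npy" else path.with_suffix(".json")
    with open(sidecar, "w", encoding="utf-8") as fh:
        json.dump({"kind": spec.kind, "dimension": spec.dimension, "seed": spec.seed}, fh)


def load_embeddings(path: str | Path) -> tuple[np.ndarray, EncoderSpec]:
    path = Path(path)
    matrix = np.load(path)
    sidecar = path.with_suffix(".json")
    with open(sidecar, encoding="utf-8") as fh:
        meta = json.load(fh)
    return matrix, EncoderSpec(**meta)
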