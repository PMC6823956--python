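"""Cosine-similarity baseline classifier.

Each test sentence is scored against every domain megadocument by cosine
similarity in the shared embedding space; thresholding those scores yields
the baseline's open-world predictions.  Two aggregation modes are offered:

``centroid`` (default)
    Score against the L2-normalized mean of the megadocument's sentence
    vectors — one dot product per domain.

``max``
    The exact pairwise formulation: the score is the maximum cosine
    similarity over all member sentences of the megadocument.  Quadratic in
    corpus size, provided for sensitivity checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .corpus import Megadocument
from .domains import DomainLabel, RISK_DOMAINS


@dataclass
class DomainScores:
    """Per-domain real-valued scores for one sentence."""

    sentence_id: str
    scores: Mapping[DomainLabel, float]
    degenerate: bool = False

    def as_vector(self, order: Sequence[DomainLabel] = RISK_DOMAINS) -> np.ndarray:
        return np.array([self.scores[d] for d in order], dtype=np.float64)

    def argmax(self) -> DomainLabel:
        return max(self.scores, key=lambda d: self.scores[d])


def megadocument_vector(
    md: Megadocument, vectors: Mapping[str, np.ndarray]
) -> np.ndarray:
    """L2-normalized centroid of the megadocument's member-sentence vectors.

    ``vectors`` maps sentence id to its embedding.
    """
    if not md.sentences:
        raise ValueError(f"megadocument for {md.domain} is empty")
    mat = np.stack([vectors[s.id] for s in md.sentences])
    centroid = mat.mean(axis=0)
    norm = float(np.linalg.norm(centroid))
    if norm > 0:
        centroid = centroid / norm
    return centroid


def cosine_scores(
    v: np.ndarray,
    domain_vectors: Sequence[tuple[DomainLabel, np.ndarray]],
    sentence_id: str = "",
) -> DomainScores:
    """Cosine similarity of ``v`` against each domain vector.

    A zero-norm sentence vector yields all-zero scores with the degenerate
    flag set (an empty sentence carries no directional information).
    """
    vnorm = float(np.linalg.norm(v))
    if vnorm == 0.0:
        return DomainScores(sentence_id, {d: 0.0 for d, _ in domain_vectors}, degenerate=True)
    scores: dict[DomainLabel, float] = {}
    for dom, dvec in domain_vectors:
        dnorm = float(np.linalg.norm(dvec))
        scores[dom] = float(v @ dvec / (vnorm * dnorm)) if dnorm > 0 else 0.0
    return DomainScores(sentence_id, scores)


@dataclass
class CosineBaseline:
    """Megadocument-similarity classifier over a fixed embedding space."""

    aggregate: str = "centroid"  # or "max"
    _centroids: list[tuple[DomainLabel, np.ndarray]] = field(default_factory=list)
    _members: dict[DomainLabel, np.ndarray] = field(default_factory=dict)

    def fit(
        self, megadocs: Sequence[Megadocument], vectors: Mapping[str, np.ndarray]
    ) -> "CosineBaseline":
        if self.aggregate not in ("centroid", "max"):
            raise ValueError(f"unknown aggregate mode: {self.aggregate!r}")
        self._centroids = [
            (md.domain, megadocument_vector(md, vectors)) for md in megadocs
        ]
        if self.aggregate == "max":
            for md in megadocs:
                mat = np.stack([vectors[s.id] for s in md.sentences]).astype(np.float64)
                norms = np.linalg.norm(mat, axis=1, keepdims=True)
                norms[norms == 0] = 1.0
                self._members[md.domain] = mat / norms
        return self

    def score(self, v: np.ndarray, sentence_id: str = "") -> DomainScores:
        if self.aggregate == "centroid":
            return cosine_scores(v, self._centroids, sentence_id)
        vnorm = float(np.linalg.norm(v))
        if vnorm == 0.0:
            return DomainScores(
                sentence_id, {d: 0.0 for d, _ in self._centroids}, degenerate=True
            )
        unit = v / vnorm
        scores = {
            dom: float(np.max(members @ unit)) for dom, members in self._members.items()
        }
        return DomainScores(sentence_id, scores)

    def score_matrix(self, X: np.ndarray, ids: Sequence[str]) -> list[DomainScores]:
        return [self.score(X[i], ids[i]) for i in range(len(ids))]
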