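"""Open-world thresholding: scores -> multilabel predictions with Other fallback.

Domains differ in how homogeneous their language is, so raw scores are not
comparable across domains.  Each domain gets its own threshold

    threshold_D = mean(scores_D) + alpha * sd(scores_D)

computed over a score population — by default the model's scores on the
*training* sentences of that domain, so thresholds are fixed before any
test sentence is seen.  ``alpha`` trades precision against recall; the
reference settings are 0.5 for the MLP and 1.25 for the RBF network.  A
sentence is assigned every domain whose score meets its threshold
(``>=``); a sentence meeting no threshold is classified ``Other``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .baseline import DomainScores
from .corpus import LabeledSentence
from .domains import DomainLabel, RISK_DOMAINS

ALPHA_MLP = 0.5
ALPHA_RBF = 1.25


@dataclass(frozen=True)
class ThresholdSet:
    """Per-domain thresholds with the statistics they derive from."""

    thresholds: Mapping[DomainLabel, float]
    alpha: float
    score_stats: Mapping[DomainLabel, tuple[float, float, int]]  # mean, sd, n

    def __post_init__(self) -> None:
        for dom, (mean, sd, n) in self.score_stats.items():
            if n < 2:
                raise ValueError(f"domain {dom.value} has n={n} < 2 scores")

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "domains": {
                d.value: {
                    "mean": self.score_stats[d][0],
                    "sd": self.score_stats[d][1],
                    "n": self.score_stats[d][2],
                    "threshold": self.thresholds[d],
                }
                for d in self.thresholds
            },
        }

    @classmethod
    def from_dict(cls, obj: Mapping) -> "ThresholdSet":
        from .domains import parse_label

        thresholds = {}
        stats = {}
        for name, row in obj["domains"].items():
            dom = parse_label(name)
            thresholds[dom] = float(row["threshold"])
            stats[dom] = (float(row["mean"]), float(row["sd"]), int(row["n"]))
        return cls(thresholds=thresholds, alpha=float(obj["alpha"]), score_stats=stats)


@dataclass(frozen=True)
class Prediction:
    """Open-world multilabel outcome for one sentence."""

    sentence_id: str
    labels: frozenset[DomainLabel]

    @property
    def is_other(self) -> bool:
        return self.labels == frozenset({DomainLabel.OTHER})


def compute_thresholds(
    score_table: Sequence[DomainScores],
    alpha: float,
    population: Sequence[LabeledSentence] | None = None,
) -> ThresholdSet:
    """Derive per-domain thresholds from a score table.

    With ``population`` given (the labeled training corpus), the statistics
    for domain D are computed over the scores that D's *own* sentences
    received on D — the in-domain population, matched by sentence id.
    Without it, all sentences' scores on D form the population.
    """
    if not score_table:
        raise ValueError("empty score table")
    pops: dict[DomainLabel, list[float]] = {d: [] for d in RISK_DOMAINS}
    if population is not None:
        by_id = {ls.sentence.id: ls for ls in population}
        for ds in score_table:
            ls = by_id.get(ds.sentence_id)
            if ls is None:
                continue
            for dom in ls.labels:
                if dom in pops:
                    pops[dom].append(ds.scores[dom])
    else:
        for ds in score_table:
            for dom in RISK_DOMAINS:
                pops[dom].append(ds.scores[dom])
    thresholds: dict[DomainLabel, float] = {}
    stats: dict[DomainLabel, tuple[float, float, int]] = {}
    for dom, vals in pops.items():
        if len(vals) < 2:
            raise ValueError(f"domain {dom.value} has fewer than 2 scores")
        arr = np.asarray(vals, dtype=np.float64)
        mean = float(arr.mean())
        sd = float(arr.std())  # population standard deviation
        thresholds[dom] = mean + alpha * sd
        stats[dom] = (mean, sd, len(vals))
    return ThresholdSet(thresholds=thresholds, alpha=alpha, score_stats=stats)


def predict_labels(scores: DomainScores, thresholds: ThresholdSet) -> Prediction:
    """Assign every domain whose score meets its threshold; none -> Other."""
    labels = frozenset(
        dom for dom, thr in thresholds.thresholds.items() if scores.scores[dom] >= thr
    )
    if not labels:
        labels = frozenset({DomainLabel.OTHER})
    return Prediction(sentence_id=scores.sentence_id, labels=labels)


def predict_all(
    score_table: Sequence[DomainScores], thresholds: ThresholdSet
) -> list[Prediction]:
    return [predict_labels(ds, thresholds) for ds in score_table]
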