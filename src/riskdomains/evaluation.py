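"""Multilabel evaluation against the adjudicated gold standard.

Per-domain precision, recall and F1 are computed by set membership: a
domain counts as a true positive on a sentence when it appears in both the
gold label set and the predicted set.  Macro metrics are unweighted means
over domains — primarily over the seven risk domains, with a variant that
also averages in ``Other``.  Gold label *order* (prevalence) is ignored for
scoring; a secondary first-domain accuracy mirrors annotating with only the
most prevalent domain.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .corpus import LabeledSentence
from .domains import ALL_LABELS, DomainLabel, RISK_DOMAINS
from .thresholds import Prediction


@dataclass(frozen=True)
class DomainMetrics:
    precision: float
    recall: float
    f1: float
    support: int
    tp: int = 0
    fp: int = 0
    fn: int = 0


@dataclass(frozen=True)
class EvalReport:
    per_domain: Mapping[DomainLabel, DomainMetrics]
    macro_precision: float
    macro_recall: float
    macro_f1: float
    macro_incl_other: tuple[float, float, float]
    first_domain_accuracy: float

    def to_rows(self) -> list[dict]:
        """Rows for a CSV report: one per domain plus the macro line."""
        rows = [
            {
                "domain": d.value,
                "precision": m.precision,
                "recall": m.recall,
                "f1": m.f1,
                "support": m.support,
            }
            for d, m in self.per_domain.items()
        ]
        rows.append(
            {
                "domain": "MACRO",
                "precision": self.macro_precision,
                "recall": self.macro_recall,
                "f1": self.macro_f1,
                "support": sum(m.support for m in self.per_domain.values()),
            }
        )
        return rows


def _prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f1


def confusion_detail(
    gold: Sequence[LabeledSentence], pred: Sequence[Prediction]
) -> dict[DomainLabel, tuple[int, int, int]]:
    """Per-domain (tp, fp, fn) over all eight labels, by set membership."""
    gold_by_id = {ls.sentence.id: ls.label_set for ls in gold}
    if len(gold_by_id) != len(gold):
        raise ValueError("duplicate ids in gold")
    pred_by_id = {p.sentence_id: p.labels for p in pred}
    if len(pred_by_id) != len(pred):
        raise ValueError("duplicate ids in predictions")
    if set(gold_by_id) != set(pred_by_id):
        raise ValueError("gold and prediction id sets differ")
    counts = {d: [0, 0, 0] for d in ALL_LABELS}
    for sid, gset in gold_by_id.items():
        pset = pred_by_id[sid]
        for dom in ALL_LABELS:
            in_g, in_p = dom in gset, dom in pset
            if in_g and in_p:
                counts[dom][0] += 1
            elif in_p:
                counts[dom][1] += 1
            elif in_g:
                counts[dom][2] += 1
    return {d: tuple(c) for d, c in counts.items()}


def evaluate(gold: Sequence[LabeledSentence], pred: Sequence[Prediction]) -> EvalReport:
    """Score predictions against gold; macro means are unweighted over
    domains, excluding zero-support domains (with the incl-Other variant
    reported alongside)."""
    counts = confusion_detail(gold, pred)
    per_domain: dict[DomainLabel, DomainMetrics] = {}
    for dom in ALL_LABELS:
        tp, fp, fn = counts[dom]
        p, r, f1 = _prf(tp, fp, fn)
        per_domain[dom] = DomainMetrics(
            precision=p, recall=r, f1=f1, support=tp + fn, tp=tp, fp=fp, fn=fn
        )

    def _macro(domains: Sequence[DomainLabel]) -> tuple[float, float, float]:
        rows = [per_domain[d] for d in domains if per_domain[d].support > 0]
        if not rows:
            return 0.0, 0.0, 0.0
        k = len(rows)
        return (
            sum(m.precision for m in rows) / k,
            sum(m.recall for m in rows) / k,
            sum(m.f1 for m in rows) / k,
        )

    macro = _macro(RISK_DOMAINS)
    macro_other = _macro(ALL_LABELS)

    pred_by_id = {p.sentence_id: p.labels for p in pred}
    hits = sum(1 for ls in gold if ls.first_label in pred_by_id[ls.sentence.id])
    first_acc = hits / len(gold) if gold else 0.0

    return EvalReport(
        per_domain=per_domain,
        macro_precision=macro[0],
        macro_recall=macro[1],
        macro_f1=macro[2],
        macro_incl_other=macro_other,
        first_domain_accuracy=first_acc,
    )
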