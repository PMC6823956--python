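"""Inter-annotator agreement and gold-standard construction.

Each of k annotators assigns every sentence an ordered list of domain
labels (most prevalent first).  Agreement is summarized by:

* **Fleiss's kappa** — chance-corrected pairwise agreement for more than
  two annotators, with chance agreement from the pooled category marginals:
  ``kappa = (P_bar - P_e) / (1 - P_e)``.
* **Cohen's multi-kappa** (Davies & Fleiss, 1982) — the same observed
  agreement, but chance agreement uses *annotator-specific* marginals
  averaged over annotator pairs: ``P_e = mean over pairs (j,l) of
  sum_k p_jk * p_lk``.
* **Total agreement / disagreement** — set-theoretic: total agreement means
  every annotator produced the identical label set; total disagreement
  means every pair of annotators' sets intersect emptily.

Since annotations are multilabel, both kappas need a categorical unit.  Two
views are provided: ``label_set`` treats each distinct label *set* as one
category (the "Overall" reduction), ``first_label`` uses only the first,
most prevalent label (the "First Domain Only" reduction).

The gold standard arises by majority adjudication: when at least two
annotators agree exactly on the label set, that set is gold; remaining
items are routed to manual expert review, never silently labeled.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Hashable, Sequence

from .corpus import LabeledSentence, SentenceRecord
from .domains import DomainLabel, parse_label


@dataclass(frozen=True)
class AnnotationItem:
    sentence_id: str
    text: str
    labels_by_annotator: tuple[tuple[DomainLabel, ...], ...]  # ordered lists

    def __post_init__(self) -> None:
        for labels in self.labels_by_annotator:
            if not labels:
                raise ValueError(f"{self.sentence_id}: empty label list")
            if len(set(labels)) != len(labels):
                raise ValueError(f"{self.sentence_id}: duplicate labels")


@dataclass
class AnnotationTable:
    """Every annotator labels every item with an ordered domain list."""

    annotators: tuple[str, ...]
    items: list[AnnotationItem] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.annotators) < 2:
            raise ValueError("need at least 2 annotators")
        for item in self.items:
            if len(item.labels_by_annotator) != len(self.annotators):
                raise ValueError(
                    f"{item.sentence_id}: expected {len(self.annotators)} annotations"
                )

    def __len__(self) -> int:
        return len(self.items)


@dataclass(frozen=True)
class AgreementReport:
    fleiss_kappa: float
    multi_kappa: float
    mean_accuracy: float | None
    n_total_agreement: int
    n_total_disagreement: int
    n_items: int


def _categories(item: AnnotationItem, view: str) -> list[Hashable]:
    if view == "first_label":
        return [labels[0] for labels in item.labels_by_annotator]
    if view == "label_set":
        return [frozenset(labels) for labels in item.labels_by_annotator]
    raise ValueError(f"unknown view: {view!r}")


def fleiss_kappa(table: AnnotationTable, view: str = "label_set") -> float:
    """Fleiss's kappa over the chosen categorical reduction."""
    if not table.items:
        raise ValueError("empty table")
    n = len(table.annotators)
    rows = [Counter(_categories(item, view)) for item in table.items]
    cats = sorted({c for row in rows for c in row}, key=repr)
    N = len(rows)
    # observed pairwise agreement per item
    p_bar = sum(
        (sum(c * c for c in row.values()) - n) / (n * (n - 1)) for row in rows
    ) / N
    # pooled marginals
    p_e = sum((sum(row[c] for row in rows) / (N * n)) ** 2 for c in cats)
    if p_e >= 1.0:
        raise ValueError("chance agreement is 1 (all mass on one category); kappa undefined")
    return (p_bar - p_e) / (1.0 - p_e)


def multi_kappa(table: AnnotationTable, view: str = "label_set") -> float:
    """Davies-Fleiss multi-kappa: annotator-specific marginals in the chance term."""
    if not table.items:
        raise ValueError("empty table")
    n = len(table.annotators)
    N = len(table.items)
    per_item = [_categories(item, view) for item in table.items]
    cats = sorted({c for row in per_item for c in row}, key=repr)
    # observed agreement: as in Fleiss
    p_bar = 0.0
    for row in per_item:
        counts = Counter(row)
        p_bar += (sum(c * c for c in counts.values()) - n) / (n * (n - 1))
    p_bar /= N
    # annotator marginals
    marg = [Counter(row[j] for row in per_item) for j in range(n)]
    pairs = 0
    p_e = 0.0
    for j in range(n):
        for l in range(j + 1, n):
            pairs += 1
            p_e += sum((marg[j][c] / N) * (marg[l][c] / N) for c in cats)
    p_e /= pairs
    if p_e >= 1.0:
        raise ValueError("chance agreement is 1; kappa undefined")
    return (p_bar - p_e) / (1.0 - p_e)


def agreement_counts(table: AnnotationTable) -> tuple[int, int]:
    """(n_total_agreement, n_total_disagreement) by the set definitions."""
    n_agree = 0
    n_disagree = 0
    for item in table.items:
        sets = [frozenset(labels) for labels in item.labels_by_annotator]
        if all(s == sets[0] for s in sets):
            n_agree += 1
        elif all(
            not (sets[j] & sets[l])
            for j in range(len(sets))
            for l in range(j + 1, len(sets))
        ):
            n_disagree += 1
    return n_agree, n_disagree


def adjudicate(
    table: AnnotationTable,
) -> tuple[list[LabeledSentence], list[AnnotationItem]]:
    """Majority adjudication into (gold, manual_review).

    Items where at least two annotators agree exactly on the label set take
    that set as gold (ordered per the first agreeing annotator); the rest
    go to the manual-review list for expert adjudication.
    """
    gold: list[LabeledSentence] = []
    review: list[AnnotationItem] = []
    for item in table.items:
        sets = [frozenset(labels) for labels in item.labels_by_annotator]
        winner: frozenset[DomainLabel] | None = None
        counts = Counter(sets)
        best, n_best = counts.most_common(1)[0]
        if n_best >= 2:
            winner = best
        if winner is None:
            review.append(item)
        else:
            ordered = next(
                labels
                for labels in item.labels_by_annotator
                if frozenset(labels) == winner
            )
            gold.append(
                LabeledSentence(
                    sentence=SentenceRecord.build(item.sentence_id, item.text),
                    labels=ordered,
                )
            )
    return gold, review


def annotator_accuracy(
    table: AnnotationTable,
    gold: Sequence[LabeledSentence],
    view: str = "label_set",
) -> tuple[dict[str, float], float]:
    """Per-annotator accuracy against gold, plus the mean.

    ``label_set`` (strict, default): correct iff the annotator's label set
    equals the gold set exactly.  ``first_label``: correct iff the first
    labels match.  Items without a gold entry raise.
    """
    gold_by_id = {ls.sentence.id: ls for ls in gold}
    missing = [it.sentence_id for it in table.items if it.sentence_id not in gold_by_id]
    if missing:
        raise ValueError(f"gold missing for items: {missing[:5]}")
    accs: dict[str, float] = {}
    for j, name in enumerate(table.annotators):
        hits = 0
        for item in table.items:
            g = gold_by_id[item.sentence_id]
            labels = item.labels_by_annotator[j]
            if view == "first_label":
                hits += labels[0] == g.first_label
            else:
                hits += frozenset(labels) == g.label_set
        accs[name] = hits / len(table.items)
    return accs, sum(accs.values()) / len(accs)


def agreement_report(
    table: AnnotationTable,
    gold: Sequence[LabeledSentence] | None = None,
    view: str = "label_set",
) -> AgreementReport:
    n_agree, n_disagree = agreement_counts(table)
    mean_acc = None
    if gold is not None:
        _, mean_acc = annotator_accuracy(table, gold, view=view)
    return AgreementReport(
        fleiss_kappa=fleiss_kappa(table, view),
        multi_kappa=multi_kappa(table, view),
        mean_accuracy=mean_acc,
        n_total_agreement=n_agree,
        n_total_disagreement=n_disagree,
        n_items=len(table),
    )


# ----------------------------------------------------------------------- I/O
def read_annotation_csv(path: str | Path) -> tuple[AnnotationTable, list[LabeledSentence] | None]:
    """Read an annotation CSV: ``id,text,annotator_*...[,gold]`` with labels
    as semicolon-separated ordered lists.  Returns the table and, when a
    gold column is present, the gold sentences."""
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        fields = reader.fieldnames or []
        ann_cols = [c for c in fields if c not in ("id", "text", "gold")]
        has_gold = "gold" in fields
        items: list[AnnotationItem] = []
        gold: list[LabeledSentence] = []
        for row in reader:
            labels = tuple(
                tuple(parse_label(x) for x in row[c].split(";") if x.strip())
                for c in ann_cols
            )
            items.append(AnnotationItem(row["id"], row.get("text", ""), labels))
            if has_gold and row["gold"].strip():
                gold.append(
                    LabeledSentence(
                        sentence=SentenceRecord.build(row["id"], row.get("text", "")),
                        labels=tuple(parse_label(x) for x in row["gold"].split(";") if x.strip()),
                    )
                )
    table = AnnotationTable(annotators=tuple(ann_cols), items=items)
    return table, (gold if has_gold else None)


def write_annotation_csv(
    table: AnnotationTable,
    path: str | Path,
    gold: Sequence[LabeledSentence] | None = None,
) -> None:
    gold_by_id = {ls.sentence.id: ls for ls in gold} if gold else {}
    with open(path, "w", newline="", encoding="utf-8") as fh:
        cols = ["id", "text", *table.annotators] + (["gold"] if gold else [])
        writer = csv.writer(fh)
        writer.writerow(cols)
        for item in table.items:
            row = [item.sentence_id, item.text]
            row += [";".join(l.value for l in labels) for labels in item.labels_by_annotator]
            if gold:
                g = gold_by_id.get(item.sentence_id)
                row.append(";".join(l.value for l in g.labels) if g else "")
            writer.writerow(row)
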