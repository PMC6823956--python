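"""Inter-annotator agreement statistics and gold adjudication."""

import itertools

import numpy as np
import pytest

from riskdomains import (
    AnnotationItem,
    AnnotationTable,
    DomainLabel,
    adjudicate,
    agreement_counts,
    agreement_report,
    annotator_accuracy,
    fleiss_kappa,
    multi_kappa,
)
from riskdomains.agreement import read_annotation_csv, write_annotation_csv

M, S, A, T, O = (
    DomainLabel.MOOD,
    DomainLabel.SUBSTANCE,
    DomainLabel.APPEARANCE,
    DomainLabel.THOUGHT_CONTENT,
    DomainLabel.OTHER,
)


def _table(rows):
    items = [
        AnnotationItem(f"s{i}", "x", tuple(tuple(labs) for labs in row))
        for i, row in enumerate(rows)
    ]
    k = len(rows[0])
    return AnnotationTable(annotators=tuple(f"ann{j}" for j in range(k)), items=items)


# ------------------------------------------------- independent oracles
def _pairwise_fleiss(categories_per_item):
    """Fleiss's kappa by direct pair counting (independent formulation)."""
    items = categories_per_item
    n = len(items[0])
    agree = []
    for row in items:
        pairs = list(itertools.combinations(range(n), 2))
        agree.append(sum(row[a] == row[b] for a, b in pairs) / len(pairs))
    p_bar = np.mean(agree)
    pooled = [c for row in items for c in row]
    cats = set(pooled)
    p_e = sum((pooled.count(c) / len(pooled)) ** 2 for c in cats)
    return (p_bar - p_e) / (1 - p_e)


def _pairwise_multikappa(categories_per_item):
    """Davies-Fleiss multi-kappa by direct pair counting."""
    items = categories_per_item
    n = len(items[0])
    N = len(items)
    pairs = list(itertools.combinations(range(n), 2))
    agree = [sum(row[a] == row[b] for a, b in pairs) / len(pairs) for row in items]
    p_bar = np.mean(agree)
    cats = {c for row in items for c in row}
    p_e = np.mean([
        sum(
            (sum(row[a] == c for row in items) / N)
            * (sum(row[b] == c for row in items) / N)
            for c in cats
        )
        for a, b in pairs
    ])
    return (p_bar - p_e) / (1 - p_e)


ORACLE_TABLE = _table([
    [[M], [M], [M]],
    [[S], [S], [M]],
    [[A], [M], [M]],
    [[S], [S], [S]],
    [[M], [A], [S]],
    [[A], [A], [M]],
])


def test_perfect_agreement_gives_kappa_one():
    t = _table([[[M], [M], [M]], [[S], [S], [S]]])
    assert fleiss_kappa(t) == pytest.approx(1.0)
    assert multi_kappa(t) == pytest.approx(1.0)


def test_balanced_split_perfect_agreement():
    t = _table([[[M], [M], [M]], [[S], [S], [S]], [[M], [M], [M]], [[S], [S], [S]]])
    assert fleiss_kappa(t) == pytest.approx(1.0)


def test_fleiss_matches_brute_force_oracle():
    cats = [[labs[0] for labs in item.labels_by_annotator] for item in ORACLE_TABLE.items]
    assert fleiss_kappa(ORACLE_TABLE, view="first_label") == pytest.approx(
        _pairwise_fleiss(cats), abs=1e-10
    )


def test_fleiss_matches_statsmodels():
    from statsmodels.stats.inter_rater import aggregate_raters
    from statsmodels.stats.inter_rater import fleiss_kappa as sm_fleiss

    data = np.array(
        [[labs[0].value for labs in item.labels_by_annotator] for item in ORACLE_TABLE.items]
    )
    counts, _ = aggregate_raters(data)
    assert fleiss_kappa(ORACLE_TABLE, view="first_label") == pytest.approx(
        sm_fleiss(counts), abs=1e-10
    )


def test_multi_kappa_matches_brute_force_oracle():
    cats = [[labs[0] for labs in item.labels_by_annotator] for item in ORACLE_TABLE.items]
    assert multi_kappa(ORACLE_TABLE, view="first_label") == pytest.approx(
        _pairwise_multikappa(cats), abs=1e-10
    )


def test_label_set_view_uses_full_sets():
    t = _table([
        [[M, T], [M, T], [M]],
        [[M, T], [M, T], [M, T]],
    ])
    cats = [[frozenset(labs) for labs in item.labels_by_annotator] for item in t.items]
    assert fleiss_kappa(t, view="label_set") == pytest.approx(
        _pairwise_fleiss(cats), abs=1e-10
    )


def test_multi_kappa_close_to_fleiss_with_identical_marginals():
    t = _table([[[M], [M], [M]], [[S], [S], [S]], [[M], [S], [M]], [[S], [M], [S]]])
    assert abs(multi_kappa(t) - fleiss_kappa(t)) < 0.01


def test_degenerate_single_category_errors():
    t = _table([[[M], [M], [M]]])
    with pytest.raises(ValueError):
        fleiss_kappa(t)
    with pytest.raises(ValueError):
        multi_kappa(t)


def test_chance_level_agreement_near_zero():
    rng = np.random.default_rng(99)
    labels = list(DomainLabel)
    rows = [
        [[labels[rng.integers(8)]] for _ in range(3)] for _ in range(1000)
    ]
    t = _table(rows)
    assert abs(fleiss_kappa(t, view="first_label")) < 0.05
    assert abs(multi_kappa(t, view="first_label")) < 0.05


# ----------------------------------------------------- counts/adjudication
def test_agreement_counts_definitions():
    t = _table([
        [[M], [M], [M]],          # total agreement
        [[M], [S], [A]],          # total disagreement (pairwise-empty)
        [[M, T], [M], [M]],       # partial: neither
        [[M], [M], [S]],          # partial (two agree)
    ])
    assert agreement_counts(t) == (1, 1)


def test_adjudication_majority_and_review():
    t = _table([
        [[S], [S], [M]],          # majority Substance
        [[M], [S], [A]],          # three-way split -> manual review
        [[T, M], [M, T], [T, M]], # same set, ordered per first agreeing annotator
    ])
    gold, review = adjudicate(t)
    assert [ls.labels for ls in gold] == [(S,), (T, M)]
    assert [item.sentence_id for item in review] == ["s1"]


def test_annotator_accuracy_strict_and_first_label():
    t = _table([
        [[M], [M], [S]],
        [[S], [S], [S]],
    ])
    gold, _ = adjudicate(t)
    accs, mean = annotator_accuracy(t, gold)
    assert accs == {"ann0": 1.0, "ann1": 1.0, "ann2": 0.5}
    assert mean == pytest.approx((1.0 + 1.0 + 0.5) / 3)


def test_report_perfect_fixed_point():
    t = _table([[[M], [M], [M]], [[S], [S], [S]]])
    gold, _ = adjudicate(t)
    rep = agreement_report(t, gold)
    assert rep.fleiss_kappa == pytest.approx(1.0)
    assert rep.multi_kappa == pytest.approx(1.0)
    assert rep.mean_accuracy == 1.0
    assert rep.n_total_agreement == 2 and rep.n_total_disagreement == 0


def test_annotation_csv_roundtrip(tmp_path):
    t = _table([[[M, T], [M], [S]], [[S], [S], [S]]])
    gold, _ = adjudicate(t)
    path = tmp_path / "ann.csv"
    write_annotation_csv(t, path, gold=gold)
    t2, gold2 = read_annotation_csv(path)
    assert t2.annotators == t.annotators
    assert [i.labels_by_annotator for i in t2.items] == [
        i.labels_by_annotator for i in t.items
    ]
    assert [ls.labels for ls in gold2] == [ls.labels for ls in gold]
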