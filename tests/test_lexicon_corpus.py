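"""Lexicon I/O, weak labeling, megadocuments, and TF-IDF MWE mining."""

import math
from collections import Counter

import pytest

from riskdomains import (
    DomainLabel,
    DomainLexicon,
    LabeledSentence,
    SentenceRecord,
    build_megadocuments,
    match_domains,
    match_sentences,
    mine_mwe_candidates,
)


def _rec(text, id="s0"):
    return SentenceRecord.build(id, text)


# ----------------------------------------------------------------- lexicon
def test_lexicon_json_roundtrip(tmp_path, clinical_lexicon):
    path = tmp_path / "lex.json"
    clinical_lexicon.write_json(path)
    again = DomainLexicon.read_json(path)
    assert again.to_dict() == clinical_lexicon.to_dict()


def test_lexicon_tsv_roundtrip(tmp_path, clinical_lexicon):
    path = tmp_path / "lex.tsv"
    clinical_lexicon.write_tsv(path)
    again = DomainLexicon.read_tsv(path)
    assert again.to_dict() == clinical_lexicon.to_dict()


def test_lexicon_rejects_long_keyphrases():
    with pytest.raises(ValueError):
        DomainLexicon.from_dict(
            {"Mood": {"keyphrases": ["one two three four"]}}
        )


def test_lexicon_rejects_other_entries():
    with pytest.raises(ValueError):
        DomainLexicon.from_dict({"Other": {"keywords": ["misc"]}})


def test_lexicon_counts(clinical_lexicon):
    assert clinical_lexicon.n_keywords() == 19
    assert clinical_lexicon.n_keyphrases() == 3


# ------------------------------------------------------------ weak labeling
def test_keyword_match_labels_substance(clinical_lexicon):
    labeled = match_sentences([_rec("patient used cocaine daily")], clinical_lexicon)
    assert len(labeled) == 1
    assert labeled[0].labels == (DomainLabel.SUBSTANCE,)


def test_keyphrase_matches_contiguous_span(clinical_lexicon):
    hits = match_domains(_rec("notable linear thinking today"), clinical_lexicon)
    assert DomainLabel.THOUGHT_PROCESS in hits
    # the words apart do not match
    assert not match_domains(_rec("linear progress in thinking"), clinical_lexicon)


def test_no_hit_is_excluded(clinical_lexicon):
    labeled, excluded = match_sentences(
        [_rec("patient slept well")], clinical_lexicon, return_excluded=True
    )
    assert labeled == [] and len(excluded) == 1


def test_tied_multi_domain_hit_is_excluded(clinical_lexicon):
    labeled, excluded = match_sentences(
        [_rec("cocaine use while depressed")], clinical_lexicon, return_excluded=True
    )
    assert labeled == [] and len(excluded) == 1


def test_majority_hit_wins(clinical_lexicon):
    # two Substance tokens against one Mood token
    labeled = match_sentences(
        [_rec("cocaine and marijuana while depressed")], clinical_lexicon
    )
    assert labeled[0].labels == (DomainLabel.SUBSTANCE,)


def test_exclude_policy_drops_all_multi_hits(clinical_lexicon):
    labeled = match_sentences(
        [_rec("cocaine and marijuana while depressed")],
        clinical_lexicon,
        policy="exclude",
    )
    assert labeled == []


def test_match_partition(clinical_lexicon):
    corpus = [
        _rec("cocaine use", "a"),
        _rec("feeling depressed", "b"),
        _rec("slept well", "c"),
        _rec("cocaine while depressed", "d"),
    ]
    labeled, excluded = match_sentences(corpus, clinical_lexicon, return_excluded=True)
    ids = [ls.sentence.id for ls in labeled] + [r.id for r in excluded]
    assert sorted(ids) == ["a", "b", "c", "d"]


# ------------------------------------------------------------ megadocuments
def test_megadocument_partition():
    labeled = [
        LabeledSentence(_rec(f"tok{i}", f"s{i}"), (dom,))
        for i, dom in enumerate(
            [DomainLabel.MOOD] * 3 + [DomainLabel.SUBSTANCE] * 2
        )
    ]
    mds = build_megadocuments(labeled)
    assert sorted((md.domain, len(md)) for md in mds) == [
        (DomainLabel.MOOD, 3),
        (DomainLabel.SUBSTANCE, 2),
    ]
    assert sum(len(md) for md in mds) == 5


def test_megadocument_rejects_other():
    with pytest.raises(ValueError):
        build_megadocuments([LabeledSentence(_rec("x"), (DomainLabel.OTHER,))])


def test_megadocument_rejects_multilabel():
    with pytest.raises(ValueError):
        build_megadocuments(
            [LabeledSentence(_rec("x"), (DomainLabel.MOOD, DomainLabel.SUBSTANCE))]
        )


# --------------------------------------------------------------- MWE mining
def _brute_force_tfidf(labeled, n_range=(2, 3)):
    """Independent enumeration of every n-gram with the same TF-IDF formula."""
    by_domain = {}
    for ls in labeled:
        by_domain.setdefault(ls.first_label, []).append(ls.sentence)
    tf = {}
    for dom, sents in by_domain.items():
        counts = Counter()
        for s in sents:
            for n in n_range:
                toks = list(s.tokens)
                for i in range(len(toks) - n + 1):
                    counts[tuple(toks[i : i + n])] += 1
        tf[dom] = counts
    df = Counter()
    for counts in tf.values():
        for g in counts:
            df[g] += 1
    n_docs = len(by_domain)
    out = {}
    for dom, counts in tf.items():
        scored = {
            g: c * (math.log((1 + n_docs) / (1 + df[g])) + 1.0) for g, c in counts.items()
        }
        out[dom] = scored
    return out


def test_tfidf_matches_brute_force_oracle():
    texts = {
        DomainLabel.MOOD: [
            "panic attack last night",
            "severe panic attack today",
            "panic attack with racing heart",
        ],
        DomainLabel.SUBSTANCE: [
            "drinking last night",
            "heavy drinking today again",
        ],
        DomainLabel.APPEARANCE: ["well groomed young man today"],
    }
    labeled = [
        LabeledSentence(_rec(t, f"{dom.value}{i}"), (dom,))
        for dom, ts in texts.items()
        for i, t in enumerate(ts)
    ]
    mined = mine_mwe_candidates(labeled, top_k=50)
    oracle = _brute_force_tfidf(labeled)
    for dom, cands in mined.items():
        for c in cands:
            assert c.tfidf_score == pytest.approx(oracle[dom][c.ngram], abs=1e-12)
        # descending order
        scores = [c.tfidf_score for c in cands]
        assert scores == sorted(scores, reverse=True)


def test_domain_specific_bigram_outranks_ubiquitous_one():
    # "panic attack" occurs only in Mood; "last night" occurs in both domains
    labeled = [
        LabeledSentence(_rec("panic attack last night", "m0"), (DomainLabel.MOOD,)),
        LabeledSentence(_rec("panic attack again", "m1"), (DomainLabel.MOOD,)),
        LabeledSentence(_rec("drinking last night", "s0"), (DomainLabel.SUBSTANCE,)),
    ]
    mined = mine_mwe_candidates(labeled, top_k=50)
    mood = {c.ngram: c.tfidf_score for c in mined[DomainLabel.MOOD]}
    assert mood[("panic", "attack")] > mood[("last", "night")]


def test_single_domain_ranking_reduces_to_frequency():
    labeled = [
        LabeledSentence(_rec("panic attack panic attack", "m0"), (DomainLabel.MOOD,)),
        LabeledSentence(_rec("racing heart once", "m1"), (DomainLabel.MOOD,)),
    ]
    mined = mine_mwe_candidates(labeled, n_range=(2,), top_k=50)[DomainLabel.MOOD]
    tf = Counter()
    for ls in labeled:
        toks = ls.sentence.tokens
        for i in range(len(toks) - 1):
            tf[tuple(toks[i : i + 2])] += 1
    ranked_by_tf = sorted(tf.items(), key=lambda kv: (-kv[1], kv[0]))
    assert [c.ngram for c in mined] == [g for g, _ in ranked_by_tf]


def test_top_k_zero_rejected():
    with pytest.raises(ValueError):
        mine_mwe_candidates([], top_k=0)
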