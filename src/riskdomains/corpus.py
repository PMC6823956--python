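"""Weak-supervision corpus construction.

The training corpus is built without manual labels: each sentence is matched
against the clinician lexicon and receives a domain label when it contains a
domain keyword as a whole token or a keyphrase as a contiguous token span.
Sentences hitting no domain are excluded; sentences hitting two or more
domains are also excluded, keeping each domain megadocument clean
(training labels are strictly single even though inference is multilabel).

TF-IDF mining over the per-domain megadocuments surfaces candidate bigrams
and trigrams for human review; accepted candidates become lexicon
keyphrases and are merged into single tokens downstream.
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .domains import DomainLabel, parse_label
from .lexicon import DomainLexicon
from .preprocess import merge_mwes, normalize_and_tokenize, stem_tokens


# --------------------------------------------------------------------- types
@dataclass(frozen=True)
class SentenceRecord:
    """A sentence with its token views.

    ``tokens`` is the normalized token list; ``merged_tokens`` has accepted
    MWEs joined into single underscore tokens (non-stemmed); in
    ``stemmed_tokens`` every non-MWE token is Porter-stemmed.
    """

    id: str
    raw_text: str
    tokens: tuple[str, ...]
    merged_tokens: tuple[str, ...]
    stemmed_tokens: tuple[str, ...]

    @classmethod
    def build(
        cls,
        id: str,
        raw_text: str,
        keyphrases: Iterable[Sequence[str]] = (),
    ) -> "SentenceRecord":
        tokens = tuple(normalize_and_tokenize(raw_text))
        merged = tuple(merge_mwes(tokens, keyphrases))
        stemmed = tuple(stem_tokens(merged))
        return cls(id=id, raw_text=raw_text, tokens=tokens,
                   merged_tokens=merged, stemmed_tokens=stemmed)


@dataclass(frozen=True)
class LabeledSentence:
    """A sentence with one (training) or more (gold) ordered domain labels."""

    sentence: SentenceRecord
    labels: tuple[DomainLabel, ...]

    def __post_init__(self) -> None:
        if not self.labels:
            raise ValueError("label list must be non-empty")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate labels")

    @property
    def label_set(self) -> frozenset[DomainLabel]:
        return frozenset(self.labels)

    @property
    def first_label(self) -> DomainLabel:
        return self.labels[0]


@dataclass
class Megadocument:
    """All training sentences of one domain, the unit for TF-IDF mining,
    baseline similarity and RBF prototype clustering."""

    domain: DomainLabel
    sentences: list[SentenceRecord]
    token_multiset: Counter = field(default_factory=Counter)

    def __len__(self) -> int:
        return len(self.sentences)


@dataclass(frozen=True)
class MweCandidate:
    """A mined bigram/trigram with its per-domain TF-IDF score."""

    ngram: tuple[str, ...]
    domain: DomainLabel
    tfidf_score: float


# ------------------------------------------------------------------ matching
def match_domains(record: SentenceRecord, lexicon: DomainLexicon) -> dict[DomainLabel, int]:
    """Domains whose keyword or keyphrase occurs in the sentence, with the
    number of matching token/keyphrase occurrences per domain."""
    toks = record.tokens
    hits: dict[DomainLabel, int] = {}
    for dom in lexicon.domains():
        count = 0
        kws = lexicon.keywords.get(dom)
        if kws:
            count += sum(1 for t in toks if t in kws)
        for phrase in lexicon.keyphrases.get(dom, ()):
            span = len(phrase)
            count += sum(
                1 for i in range(len(toks) - span + 1) if tuple(toks[i : i + span]) == phrase
            )
        if count:
            hits[dom] = count
    return hits


def match_sentences(
    corpus: Sequence[SentenceRecord],
    lexicon: DomainLexicon,
    *,
    policy: str = "majority",
    return_excluded: bool = False,
):
    """Weakly label a corpus against the lexicon.

    Every training sentence receives exactly one label.  Under the default
    ``majority`` policy a sentence matching several domains is assigned the
    domain with the most keyword/keyphrase occurrences (even though it may
    genuinely involve several domains — a known source of label noise in
    weakly supervised corpora); ties stay ambiguous and are excluded.  The
    stricter ``exclude`` policy drops every multi-domain hit.  Sentences
    matching no domain are always excluded.

    With ``return_excluded=True`` returns ``(labeled, excluded)`` so that
    the partition ``labeled + excluded == corpus`` can be audited.
    """
    if policy not in ("majority", "exclude"):
        raise ValueError(f"unknown disambiguation policy: {policy!r}")
    labeled: list[LabeledSentence] = []
    excluded: list[SentenceRecord] = []
    for rec in corpus:
        hits = match_domains(rec, lexicon)
        winner: DomainLabel | None = None
        if len(hits) == 1:
            winner = next(iter(hits))
        elif len(hits) > 1 and policy == "majority":
            ranked = sorted(hits.items(), key=lambda kv: -kv[1])
            if ranked[0][1] > ranked[1][1]:
                winner = ranked[0][0]
        if winner is not None:
            labeled.append(LabeledSentence(sentence=rec, labels=(winner,)))
        else:
            excluded.append(rec)
    if return_excluded:
        return labeled, excluded
    return labeled


# ------------------------------------------------------------- megadocuments
def build_megadocuments(labeled: Sequence[LabeledSentence]) -> list[Megadocument]:
    """Partition a single-label training corpus into per-domain megadocuments."""
    groups: dict[DomainLabel, list[SentenceRecord]] = {}
    for ls in labeled:
        if len(ls.labels) != 1:
            raise ValueError(f"training sentence {ls.sentence.id} has multiple labels")
        if ls.first_label is DomainLabel.OTHER:
            raise ValueError("Other is never a training label")
        groups.setdefault(ls.first_label, []).append(ls.sentence)
    megadocs = []
    for dom, sents in groups.items():
        counts: Counter = Counter()
        for s in sents:
            counts.update(s.stemmed_tokens)
        megadocs.append(Megadocument(domain=dom, sentences=sents, token_multiset=counts))
    megadocs.sort(key=lambda m: m.domain.value)
    return megadocs


# ------------------------------------------------------------- MWE mining
def _ngrams(tokens: Sequence[str], n: int) -> Iterable[tuple[str, ...]]:
    return (tuple(tokens[i : i + n]) for i in range(len(tokens) - n + 1))


def mine_mwe_candidates(
    labeled: Sequence[LabeledSentence],
    n_range: Sequence[int] = (2, 3),
    top_k: int = 50,
) -> dict[DomainLabel, list[MweCandidate]]:
    """Rank candidate bigrams/trigrams per domain by TF-IDF.

    Term frequency is the raw n-gram count within the domain megadocument;
    inverse document frequency treats each megadocument as one document:
    ``idf = ln((1 + D) / (1 + df)) + 1`` with ``D`` megadocuments and ``df``
    the number containing the n-gram (smoothed, strictly positive, so a
    single-document corpus ranks by raw frequency).  Output is a
    human-review artifact; accepted candidates become lexicon keyphrases.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    if any(n not in (2, 3) for n in n_range):
        raise ValueError("only bigrams and trigrams are mined")
    megadocs = build_megadocuments(labeled)
    n_docs = len(megadocs)
    tf: dict[DomainLabel, Counter] = {}
    for md in megadocs:
        counts: Counter = Counter()
        for sent in md.sentences:
            for n in n_range:
                counts.update(_ngrams(sent.tokens, n))
        tf[md.domain] = counts
    df: Counter = Counter()
    for counts in tf.values():
        df.update(counts.keys())
    out: dict[DomainLabel, list[MweCandidate]] = {}
    for md in megadocs:
        scored = [
            MweCandidate(
                ngram=gram,
                domain=md.domain,
                tfidf_score=count * (math.log((1 + n_docs) / (1 + df[gram])) + 1.0),
            )
            for gram, count in tf[md.domain].items()
        ]
        scored.sort(key=lambda c: (-c.tfidf_score, c.ngram))
        out[md.domain] = scored[:top_k]
    return out


# ----------------------------------------------------------------------- I/O
def read_corpus(path: str | Path, keyphrases: Iterable[Sequence[str]] = ()) -> list[SentenceRecord]:
    """Read sentences from JSONL (``{"id","text"}``) or plain text (one per
    line, ids auto-assigned ``s0, s1, ...``), chosen by file extension."""
    path = Path(path)
    records: list[SentenceRecord] = []
    keyphrases = list(keyphrases)
    with open(path, encoding="utf-8") as fh:
        if path.suffix in {".jsonl", ".json"}:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                obj = json.loads(line)
                records.append(SentenceRecord.build(str(obj["id"]), obj["text"], keyphrases))
        else:
            for i, line in enumerate(fh):
                line = line.strip()
                if line:
                    records.append(SentenceRecord.build(f"s{i}", line, keyphrases))
    return records


def read_labeled(path: str | Path, keyphrases: Iterable[Sequence[str]] = ()) -> list[LabeledSentence]:
    """Read a labeled corpus from JSONL ``{"id","text","labels":[...]}``."""
    keyphrases = list(keyphrases)
    out: list[LabeledSentence] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            obj = json.loads(line)
            rec = SentenceRecord.build(str(obj["id"]), obj["text"], keyphrases)
            labels = tuple(parse_label(l) for l in obj["labels"])
            out.append(LabeledSentence(sentence=rec, labels=labels))
    return out


def write_labeled(labeled: Sequence[LabeledSentence], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for ls in labeled:
            fh.write(json.dumps({
                "id": ls.sentence.id,
                "text": ls.sentence.raw_text,
                "labels": [l.value for l in ls.labels],
            }) + "\n")
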