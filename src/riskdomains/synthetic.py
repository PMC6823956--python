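"""Seeded generator of EHR-like sentence corpora with known domain structure.

No real clinical text is shipped or downloaded: the generator emits
word-like nonsense tokens with the *statistical* shape the pipeline cares
about — seven domain vocabularies with controllable pairwise overlap
(mirroring the observation that Interpersonal, Mood and Thought Content
share a noisy region of vector space), a quotidian background vocabulary,
clinically-styled multiword expressions whose component tokens are
background words (uninformative in isolation, distinctive as a sequence),
sentences drawn from one or two domains with length variation, and
out-of-domain background-only sentences for the open-world ``Other``
outcome.

A subset of each domain's unique keywords and MWEs is exported as the
planted clinician lexicon, so weak labeling has partial coverage and is
imperfect by design, like a real hand-built lexicon.

Everything is driven by one integer seed; regeneration with the same
config is byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .agreement import AnnotationItem, AnnotationTable
from .corpus import LabeledSentence, SentenceRecord
from .domains import ALL_LABELS, DomainLabel, RISK_DOMAINS
from .lexicon import DomainLexicon
from .preprocess import porter_stem

_CONSONANTS = "bdfgklmnprstvz"
_VOWELS = "aeiou"

#: Moderate shared-vocabulary fraction among the three confusable domains.
CONFUSABLE_TRIO = (
    DomainLabel.INTERPERSONAL,
    DomainLabel.MOOD,
    DomainLabel.THOUGHT_CONTENT,
)


def overlap_matrix(trio_overlap: float = 0.2) -> np.ndarray:
    """Symmetric 7x7 overlap fractions: ``trio_overlap`` within the
    Interpersonal/Mood/ThoughtContent trio, zero elsewhere."""
    mat = np.zeros((7, 7))
    idx = [RISK_DOMAINS.index(d) for d in CONFUSABLE_TRIO]
    for i in idx:
        for j in idx:
            if i != j:
                mat[i, j] = trio_overlap
    return mat


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for one synthetic bundle.

    Defaults describe the reference condition: 2000 training / 500 test
    sentences, moderate (0.2) vocabulary overlap among the confusable
    trio, ~5% two-domain test sentences and ~6% background-only (Other)
    test sentences (the proportions observed in annotated psychiatric EHR
    gold standards), 8-24 token sentences, and an exported lexicon
    covering 85% of each domain's unique keywords and MWEs.
    """

    n_train: int = 2000
    n_test: int = 500
    vocab_size_per_domain: int = 50
    background_vocab_size: int = 250
    overlap: np.ndarray = field(default_factory=overlap_matrix)
    mwe_per_domain: int = 6
    multilabel_rate: float = 0.05  # share of two-domain sentences in the gold corpus
    other_rate: float = 0.06  # share of background-only (Other) sentences
    mwe_rate: float = 0.2  # domain sentences additionally anchored by an MWE
    domain_token_rate: float = 0.6  # per-slot probability of a domain token
    cross_domain_rate: float = 0.05  # background slots drawing a stray other-domain token
    lexicon_coverage: float = 0.85  # fraction of keywords/MWEs exported
    sentence_length: tuple[int, int] = (8, 24)
    seed: int = 13

    def __post_init__(self) -> None:
        for rate in (self.multilabel_rate, self.other_rate, self.mwe_rate,
                     self.domain_token_rate, self.cross_domain_rate,
                     self.lexicon_coverage):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        mat = np.asarray(self.overlap)
        if mat.shape != (7, 7) or not np.allclose(mat, mat.T) or np.any(np.diag(mat) != 0):
            raise ValueError("overlap must be a symmetric 7x7 matrix with zero diagonal")
        if self.sentence_length[0] < 3 or self.sentence_length[1] < self.sentence_length[0]:
            raise ValueError("sentence_length must be (min>=3, max>=min)")
        if min(self.n_train, self.n_test, self.vocab_size_per_domain,
               self.background_vocab_size, self.mwe_per_domain) < 1:
            raise ValueError("sizes must be positive")


@dataclass
class SynthBundle:
    """A generated study bundle: planted lexicon, corpora, gold, annotations."""

    config: SynthConfig
    lexicon: DomainLexicon
    train: list[LabeledSentence]
    test_gold: list[LabeledSentence]
    vocab: dict[DomainLabel, list[str]]  # full per-domain vocabularies
    mwes: dict[DomainLabel, list[tuple[str, ...]]]
    background: list[str]


def _make_word(rng: np.random.Generator, taken: set[str]) -> str:
    """A pronounceable nonsense token whose Porter stem is globally unique."""
    while True:
        n_syll = int(rng.integers(2, 5))
        word = "".join(
            _CONSONANTS[rng.integers(len(_CONSONANTS))] + _VOWELS[rng.integers(len(_VOWELS))]
            for _ in range(n_syll)
        )
        stem = porter_stem(word)
        if stem not in taken:
            taken.add(stem)
            return word


def _streams(seed: int) -> dict[str, np.random.Generator]:
    """Independent, deterministically derived substreams per generator
    component (common-random-numbers design: changing one knob, e.g. the
    overlap of one domain pair, leaves the draws of unrelated components
    untouched, so paired experiments compare like with like)."""
    ss = np.random.SeedSequence(seed)
    names = ["shared", "background", "mwes", "train", "test"]
    names += [f"vocab_{d.value}" for d in RISK_DOMAINS]
    names += [f"lex_{d.value}" for d in RISK_DOMAINS]
    return {
        name: np.random.Generator(np.random.PCG64(child))
        for name, child in zip(names, ss.spawn(len(names)))
    }


#: Zipf exponent of the background word distribution ("quotidian" words are
#: heavily reused), and the slice of mid-frequency background words all
#: MWE components are drawn from.  Sharing one small component pool across
#: every domain's MWEs makes the unmerged component tokens genuinely
#: ambiguous — they occur in ordinary background use and inside several
#: domains' expressions — so only the merged expression is informative.
_ZIPF_EXPONENT = 1.0
_MWE_COMPONENT_SLICE = (20, 30)


def _build_vocabularies(
    config: SynthConfig, streams: dict[str, np.random.Generator]
) -> tuple[dict[DomainLabel, list[str]], dict[DomainLabel, list[str]], list[str]]:
    """Per-domain vocabularies with the configured pairwise sharing, the
    domain-unique subsets, and the background vocabulary."""
    taken: set[str] = set()
    mat = np.asarray(config.overlap)
    size = config.vocab_size_per_domain
    shared: dict[tuple[int, int], list[str]] = {}
    for i in range(7):
        for j in range(i + 1, 7):
            n_shared = int(round(mat[i, j] * size))
            if n_shared:
                shared[(i, j)] = [
                    _make_word(streams["shared"], taken) for _ in range(n_shared)
                ]
    vocab: dict[DomainLabel, list[str]] = {}
    unique: dict[DomainLabel, list[str]] = {}
    for i, dom in enumerate(RISK_DOMAINS):
        pool: list[str] = []
        for (a, b), words in shared.items():
            if i in (a, b):
                pool.extend(words)
        if len(pool) > size:
            raise ValueError(
                f"overlap demands {len(pool)} shared tokens for {dom.value}, "
                f"more than vocab_size_per_domain={size}"
            )
        rng = streams[f"vocab_{dom.value}"]
        uniq = [_make_word(rng, taken) for _ in range(size - len(pool))]
        unique[dom] = uniq
        vocab[dom] = pool + uniq
    background = [
        _make_word(streams["background"], taken)
        for _ in range(config.background_vocab_size)
    ]
    return vocab, unique, background


def _zipf_cumweights(n: int) -> np.ndarray:
    w = 1.0 / np.arange(1, n + 1, dtype=np.float64) ** _ZIPF_EXPONENT
    return np.cumsum(w / w.sum())


def _build_mwes(
    config: SynthConfig, rng: np.random.Generator, background: list[str]
) -> dict[DomainLabel, list[tuple[str, ...]]]:
    """Domain-unique 2-3 token sequences whose components are *common*
    background words: individually quotidian and uninformative, distinctive
    only as a contiguous expression."""
    lo = min(_MWE_COMPONENT_SLICE[0], max(len(background) - 10, 0))
    hi = min(_MWE_COMPONENT_SLICE[1], len(background))
    pool_idx = np.arange(lo, hi)
    seen: set[tuple[str, ...]] = set()
    mwes: dict[DomainLabel, list[tuple[str, ...]]] = {}
    for dom in RISK_DOMAINS:
        out: list[tuple[str, ...]] = []
        while len(out) < config.mwe_per_domain:
            n = int(rng.integers(2, 4))
            idx = rng.choice(pool_idx, size=n, replace=False)
            phrase = tuple(background[k] for k in idx)
            if phrase not in seen:
                seen.add(phrase)
                out.append(phrase)
        mwes[dom] = out
    return mwes


def _domain_sentence(
    rng: np.random.Generator,
    config: SynthConfig,
    domains: Sequence[DomainLabel],
    vocab: dict[DomainLabel, list[str]],
    mwes: dict[DomainLabel, list[tuple[str, ...]]],
    background: list[str],
    bg_cum: np.ndarray,
) -> tuple[list[str], list[DomainLabel]]:
    """A sentence drawing from one or two domains; labels ordered by prevalence."""
    lo, hi = config.sentence_length
    length = int(rng.integers(lo, hi + 1))
    counts = {d: 0 for d in domains}
    tokens: list[str] = []
    use_mwe = {d: bool(rng.random() < config.mwe_rate) for d in domains}
    rate = config.domain_token_rate / len(domains)
    for _ in range(length):
        drawn = False
        for d in domains:
            # MWE-anchored sentences carry somewhat thinner plain-keyword
            # signal: the expression itself does part of the semantic work
            p = rate * (0.7 if use_mwe[d] else 1.0)
            if rng.random() < p:
                tokens.append(vocab[d][rng.integers(len(vocab[d]))])
                counts[d] += 1
                drawn = True
                break
        if not drawn:
            tokens.append(_background_token(rng, config, vocab, background, bg_cum))
    for d in domains:
        if use_mwe[d]:
            phrase = mwes[d][rng.integers(len(mwes[d]))]
            pos = int(rng.integers(0, len(tokens) + 1))
            tokens[pos:pos] = list(phrase)
            counts[d] += len(phrase)
        elif counts[d] == 0:  # every domain sentence carries some domain signal
            pos = int(rng.integers(0, len(tokens)))
            tokens[pos] = vocab[d][rng.integers(len(vocab[d]))]
            counts[d] += 1
    ordered = sorted(domains, key=lambda d: -counts[d])
    return tokens, ordered


def _background_token(
    rng: np.random.Generator,
    config: SynthConfig,
    vocab: dict[DomainLabel, list[str]],
    background: list[str],
    bg_cum: np.ndarray,
) -> str:
    """A non-signal token: usually a Zipf-distributed background word,
    occasionally a stray token from an unrelated domain (clinical
    vocabulary is context-sensitive; domain words appear incidentally
    everywhere)."""
    if rng.random() < config.cross_domain_rate:
        d = RISK_DOMAINS[int(rng.integers(7))]
        return vocab[d][int(rng.integers(len(vocab[d])))]
    return background[int(np.searchsorted(bg_cum, rng.random()))]


def _background_sentence(
    rng: np.random.Generator,
    config: SynthConfig,
    vocab: dict[DomainLabel, list[str]],
    background: list[str],
    bg_cum: np.ndarray,
) -> list[str]:
    lo, hi = config.sentence_length
    length = int(rng.integers(lo, hi + 1))
    return [
        _background_token(rng, config, vocab, background, bg_cum) for _ in range(length)
    ]


def _export_lexicon(
    config: SynthConfig,
    streams: dict[str, np.random.Generator],
    vocab: dict[DomainLabel, list[str]],
    unique: dict[DomainLabel, list[str]],
    mwes: dict[DomainLabel, list[tuple[str, ...]]],
) -> DomainLexicon:
    keywords: dict[DomainLabel, frozenset[str]] = {}
    keyphrases: dict[DomainLabel, frozenset[tuple[str, ...]]] = {}
    for dom in RISK_DOMAINS:
        rng = streams[f"lex_{dom.value}"]
        # prefer domain-unique tokens as keywords; a domain whose whole
        # vocabulary is shared (extreme overlap) exports shared tokens
        pool = unique[dom] if unique[dom] else vocab[dom]
        n_kw = max(1, int(round(config.lexicon_coverage * len(pool))))
        idx = rng.choice(len(pool), size=n_kw, replace=False)
        keywords[dom] = frozenset(pool[k] for k in idx)
        n_kp = max(1, int(round(config.lexicon_coverage * len(mwes[dom]))))
        idx = rng.choice(len(mwes[dom]), size=n_kp, replace=False)
        keyphrases[dom] = frozenset(mwes[dom][k] for k in idx)
    return DomainLexicon(keywords=keywords, keyphrases=keyphrases)


def generate(config: SynthConfig = SynthConfig()) -> SynthBundle:
    """Generate a full study bundle from one seed."""
    streams = _streams(config.seed)
    vocab, unique, background = _build_vocabularies(config, streams)
    bg_cum = _zipf_cumweights(len(background))
    mwes = _build_mwes(config, streams["mwes"], background)
    lexicon = _export_lexicon(config, streams, vocab, unique, mwes)
    keyphrases = [p for ps in mwes.values() for p in ps]

    train: list[LabeledSentence] = []
    rng = streams["train"]
    for i in range(config.n_train):
        dom = RISK_DOMAINS[int(rng.integers(7))]
        tokens, ordered = _domain_sentence(
            rng, config, [dom], vocab, mwes, background, bg_cum
        )
        rec = SentenceRecord.build(f"train{i}", " ".join(tokens), keyphrases)
        train.append(LabeledSentence(sentence=rec, labels=tuple(ordered)))

    test: list[LabeledSentence] = []
    rng = streams["test"]
    for i in range(config.n_test):
        u = rng.random()
        if u < config.other_rate:
            tokens = _background_sentence(rng, config, vocab, background, bg_cum)
            labels: tuple[DomainLabel, ...] = (DomainLabel.OTHER,)
        else:
            if u < config.other_rate + config.multilabel_rate:
                pair = rng.choice(7, size=2, replace=False)
                doms = [RISK_DOMAINS[int(k)] for k in pair]
            else:
                doms = [RISK_DOMAINS[int(rng.integers(7))]]
            tokens, ordered = _domain_sentence(
                rng, config, doms, vocab, mwes, background, bg_cum
            )
            labels = tuple(ordered)
        rec = SentenceRecord.build(f"test{i}", " ".join(tokens), keyphrases)
        test.append(LabeledSentence(sentence=rec, labels=labels))

    return SynthBundle(
        config=config,
        lexicon=lexicon,
        train=train,
        test_gold=test,
        vocab=vocab,
        mwes=mwes,
        background=background,
    )


def simulate_annotators(
    gold: Sequence[LabeledSentence],
    k: int = 3,
    noise: float = 0.2,
    seed: int = 0,
    kernel: str = "overlap",
    overlap: np.ndarray | None = None,
) -> AnnotationTable:
    """Simulated annotators who reproduce gold with probability 1 - noise.

    On a corrupted item an annotator with the ``uniform`` kernel draws one
    label uniformly from all eight (pure chance agreement at noise=1); with
    the ``overlap`` kernel each gold label is replaced by a confusable
    neighbour, concentrating disagreement on high-overlap domain pairs.
    """
    if k < 2:
        raise ValueError("need k >= 2 annotators")
    if not 0.0 <= noise <= 1.0:
        raise ValueError("noise must lie in [0, 1]")
    if kernel not in ("overlap", "uniform"):
        raise ValueError(f"unknown kernel: {kernel!r}")
    if overlap is None:
        overlap = overlap_matrix()
    rng = np.random.Generator(np.random.PCG64(seed))
    items: list[AnnotationItem] = []
    for ls in gold:
        rows: list[tuple[DomainLabel, ...]] = []
        for _ in range(k):
            if rng.random() >= noise:
                rows.append(tuple(ls.labels))
                continue
            if kernel == "uniform":
                rows.append((ALL_LABELS[int(rng.integers(8))],))
                continue
            corrupted: list[DomainLabel] = []
            for lab in ls.labels:
                if lab is DomainLabel.OTHER:
                    corrupted.append(ALL_LABELS[int(rng.integers(8))])
                    continue
                i = RISK_DOMAINS.index(lab)
                weights = np.asarray(overlap)[i].astype(float) + 0.02
                weights = np.append(weights, 0.05)  # small mass on Other
                weights /= weights.sum()
                j = int(rng.choice(8, p=weights))
                corrupted.append(ALL_LABELS[j] if j < 7 else DomainLabel.OTHER)
            dedup = tuple(dict.fromkeys(corrupted))
            rows.append(dedup if dedup else (DomainLabel.OTHER,))
        items.append(AnnotationItem(ls.sentence.id, ls.sentence.raw_text, tuple(rows)))
    names = tuple(f"annotator_{j + 1}" for j in range(k))
    return AnnotationTable(annotators=names, items=items)


def small_n_mwe_config(n_train: int = 200, seed: int = 13) -> SynthConfig:
    """The MWE-effect study condition: a corpus whose domain signal is
    mostly carried by a couple of very frequent MWEs per domain, with thin
    plain-keyword signal.  Comparing merged against unmerged preprocessing
    on this condition isolates what the expression itself contributes over
    its individually ambiguous component words."""
    return SynthConfig(
        n_train=n_train,
        n_test=300,
        mwe_per_domain=2,
        mwe_rate=0.9,
        domain_token_rate=0.15,
        seed=seed,
    )
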