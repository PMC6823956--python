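"""Sentence normalization: tokenization, Porter stemming, MWE merging.

The preprocessing contract mirrors how clinical MWEs are handled throughout
the pipeline: a sentence is lowercased and tokenized, accepted multiword
keyphrases are merged into single underscore-joined tokens, and only the
remaining (non-MWE) tokens are Porter-stemmed.  Merged MWE tokens stay
unstemmed so that e.g. ``linear_thinking`` survives intact rather than
degrading to ``linear_think``.

The tokenizer is a lowercase regex word tokenizer that strips punctuation
but keeps clinically meaningful internal characters (``/``, ``-``, ``+``),
so tokens like ``si/hi`` or ``follow-up`` survive.
"""

from __future__ import annotations

import re
from typing import Iterable, Sequence

_TOKEN_RE = re.compile(r"[a-z0-9]+(?:[/+\-'][a-z0-9]+)*")

MWE_JOIN = "_"


def normalize_and_tokenize(raw_text: str) -> list[str]:
    """Lowercase and tokenize ``raw_text``.

    Punctuation is stripped except ``/``, ``-``, ``+`` and ``'`` when they
    appear *inside* a token.  Empty or whitespace-only input yields an empty
    list.  Deterministic for fixed input.

    >>> normalize_and_tokenize("No SI, No HI, No hallucinations")
    ['no', 'si', 'no', 'hi', 'no', 'hallucinations']
    """
    return _TOKEN_RE.findall(raw_text.lower())


def merge_mwes(tokens: Sequence[str], keyphrases: Iterable[Sequence[str]]) -> list[str]:
    """Replace keyphrase occurrences with single underscore-joined tokens.

    Matching is leftmost-first and longest-first (trigrams beat bigrams at
    the same start position); matches never overlap.  Already-merged tokens
    (containing ``_``) are opaque, which makes the operation idempotent.
    """
    phrases = sorted({tuple(p) for p in keyphrases}, key=len, reverse=True)
    if not phrases:
        return list(tokens)
    by_first: dict[str, list[tuple[str, ...]]] = {}
    for p in phrases:
        by_first.setdefault(p[0], []).append(p)
    out: list[str] = []
    i = 0
    n = len(tokens)
    while i < n:
        tok = tokens[i]
        merged = False
        if MWE_JOIN not in tok:
            for p in by_first.get(tok, ()):
                span = len(p)
                if i + span <= n and tuple(tokens[i : i + span]) == p and not any(
                    MWE_JOIN in t for t in tokens[i + 1 : i + span]
                ):
                    out.append(MWE_JOIN.join(p))
                    i += span
                    merged = True
                    break
        if not merged:
            out.append(tok)
            i += 1
    return out


def stem_tokens(tokens: Sequence[str]) -> list[str]:
    """Porter-stem every token except merged MWE tokens (those with ``_``)."""
    return [t if MWE_JOIN in t else porter_stem(t) for t in tokens]


# --------------------------------------------------------------------------
# Porter stemmer (classic 1980 algorithm).
# --------------------------------------------------------------------------

_VOWELS = set("aeiou")


def _is_cons(word: str, i: int) -> bool:
    ch = word[i]
    if ch in _VOWELS:
        return False
    if ch == "y":
        return i == 0 or not _is_cons(word, i - 1)
    return True


def _measure(stem: str) -> int:
    """Number of VC sequences: [C](VC)^m[V]."""
    m = 0
    prev_vowel = False
    for i in range(len(stem)):
        if _is_cons(stem, i):
            if prev_vowel:
                m += 1
            prev_vowel = False
        else:
            prev_vowel = True
    return m


def _has_vowel(stem: str) -> bool:
    return any(not _is_cons(stem, i) for i in range(len(stem)))


def _ends_double_cons(word: str) -> bool:
    return (
        len(word) >= 2
        and word[-1] == word[-2]
        and _is_cons(word, len(word) - 1)
    )


def _ends_cvc(word: str) -> bool:
    # *o: stem ends cvc where the final c is not w, x or y
    if len(word) < 3:
        return False
    return (
        _is_cons(word, len(word) - 3)
        and not _is_cons(word, len(word) - 2)
        and _is_cons(word, len(word) - 1)
        and word[-1] not in "wxy"
    )


_STEP2 = [
    ("ational", "ate"), ("tional", "tion"), ("enci", "ence"), ("anci", "ance"),
    ("izer", "ize"), ("abli", "able"), ("alli", "al"), ("entli", "ent"),
    ("eli", "e"), ("ousli", "ous"), ("ization", "ize"), ("ation", "ate"),
    ("ator", "ate"), ("alism", "al"), ("iveness", "ive"), ("fulness", "ful"),
    ("ousness", "ous"), ("aliti", "al"), ("iviti", "ive"), ("biliti", "ble"),
]

_STEP3 = [
    ("icate", "ic"), ("ative", ""), ("alize", "al"), ("iciti", "ic"),
    ("ical", "ic"), ("ful", ""), ("ness", ""),
]

_STEP4 = [
    "al", "ance", "ence", "er", "ic", "able", "ible", "ant", "ement",
    "ment", "ent", "ion", "ou", "ism", "ate", "iti", "ous", "ive", "ize",
]


def porter_stem(word: str) -> str:
    """Stem a single lowercase token with the classic Porter algorithm."""
    if len(word) <= 2:
        return word
    w = word

    # Step 1a
    if w.endswith("sses"):
        w = w[:-2]
    elif w.endswith("ies"):
        w = w[:-2]
    elif w.endswith("ss"):
        pass
    elif w.endswith("s"):
        w = w[:-1]

    # Step 1b
    if w.endswith("eed"):
        if _measure(w[:-3]) > 0:
            w = w[:-1]
    else:
        flag = False
        if w.endswith("ed") and _has_vowel(w[:-2]):
            w = w[:-2]
            flag = True
        elif w.endswith("ing") and _has_vowel(w[:-3]):
            w = w[:-3]
            flag = True
        if flag:
            if w.endswith(("at", "bl", "iz")):
                w += "e"
            elif _ends_double_cons(w) and w[-1] not in "lsz":
                w = w[:-1]
            elif _measure(w) == 1 and _ends_cvc(w):
                w += "e"

    # Step 1c
    if w.endswith("y") and _has_vowel(w[:-1]):
        w = w[:-1] + "i"

    # Step 2
    for suffix, repl in _STEP2:
        if w.endswith(suffix):
            stem = w[: -len(suffix)]
            if _measure(stem) > 0:
                w = stem + repl
            break

    # Step 3
    for suffix, repl in _STEP3:
        if w.endswith(suffix):
            stem = w[: -len(suffix)]
            if _measure(stem) > 0:
                w = stem + repl
            break

    # Step 4
    for suffix in _STEP4:
        if w.endswith(suffix):
            stem = w[: -len(suffix)]
            if suffix == "ion" and (not stem or stem[-1] not in "st"):
                continue
            if _measure(stem) > 1:
                w = stem
            break

    # Step 5a
    if w.endswith("e"):
        stem = w[:-1]
        m = _measure(stem)
        if m > 1 or (m == 1 and not _ends_cvc(stem)):
            w = stem

    # Step 5b
    if _measure(w) > 1 and _ends_double_cons(w) and w.endswith("l"):
        w = w[:-1]

    return w
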