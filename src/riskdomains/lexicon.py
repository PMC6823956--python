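"""Clinician lexicon of per-domain keywords and multiword keyphrases.

A :class:`DomainLexicon` maps each of the seven risk domains to single-token
keywords and 2-3 token keyphrases (multiword expressions, MWEs).  The lexicon
drives weak supervision: a sentence is assigned a training label when it
contains a keyword as a whole token or a keyphrase as a contiguous token
span.  Keyphrases accepted from TF-IDF mining are folded back into the
lexicon via :meth:`DomainLexicon.with_keyphrases`.

Two on-disk formats are supported: a JSON mapping
``{domain: {"keywords": [...], "keyphrases": [...]}}`` and a two-column TSV
dialect ``domain<TAB>phrase`` where multi-token phrases are keyphrases.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .domains import DomainLabel, RISK_DOMAINS, parse_label


def _normalize_phrase(phrase: str) -> tuple[str, ...]:
    return tuple(phrase.lower().split())


@dataclass(frozen=True)
class DomainLexicon:
    """Per-domain keywords (single tokens) and keyphrases (2-3 token MWEs)."""

    keywords: Mapping[DomainLabel, frozenset[str]] = field(default_factory=dict)
    keyphrases: Mapping[DomainLabel, frozenset[tuple[str, ...]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for dom in self.keywords:
            if dom is DomainLabel.OTHER:
                raise ValueError("Other carries no lexicon entries")
        for dom, phrases in self.keyphrases.items():
            if dom is DomainLabel.OTHER:
                raise ValueError("Other carries no lexicon entries")
            for p in phrases:
                if not 2 <= len(p) <= 3:
                    raise ValueError(f"keyphrase must have 2 or 3 tokens: {p!r}")
        if not any(self.keywords.get(d) or self.keyphrases.get(d) for d in RISK_DOMAINS):
            raise ValueError("lexicon is empty")

    @classmethod
    def from_dict(cls, entries: Mapping[str, Mapping[str, Sequence[str]]]) -> "DomainLexicon":
        """Build from ``{domain: {"keywords": [...], "keyphrases": [...]}}``."""
        keywords: dict[DomainLabel, frozenset[str]] = {}
        keyphrases: dict[DomainLabel, frozenset[tuple[str, ...]]] = {}
        for name, entry in entries.items():
            dom = parse_label(name)
            kws = frozenset(w.strip().lower() for w in entry.get("keywords", ()) if w.strip())
            kps = frozenset(
                _normalize_phrase(p) for p in entry.get("keyphrases", ()) if p.strip()
            )
            if kws:
                keywords[dom] = kws
            if kps:
                keyphrases[dom] = kps
        return cls(keywords=keywords, keyphrases=keyphrases)

    def to_dict(self) -> dict[str, dict[str, list[str]]]:
        out: dict[str, dict[str, list[str]]] = {}
        for dom in RISK_DOMAINS:
            kws = sorted(self.keywords.get(dom, ()))
            kps = sorted(" ".join(p) for p in self.keyphrases.get(dom, ()))
            if kws or kps:
                out[dom.value] = {"keywords": kws, "keyphrases": kps}
        return out

    # ------------------------------------------------------------------ I/O
    @classmethod
    def read_json(cls, path: str | Path) -> "DomainLexicon":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))

    def write_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "DomainLexicon":
        """Read the two-column ``domain<TAB>phrase`` dialect."""
        entries: dict[str, dict[str, list[str]]] = {}
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                try:
                    name, phrase = line.split("\t", 1)
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: expected 'domain<TAB>phrase'") from exc
                slot = entries.setdefault(name, {"keywords": [], "keyphrases": []})
                if len(phrase.split()) > 1:
                    slot["keyphrases"].append(phrase)
                else:
                    slot["keywords"].append(phrase)
        return cls.from_dict(entries)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for dom in RISK_DOMAINS:
                for kw in sorted(self.keywords.get(dom, ())):
                    fh.write(f"{dom.value}\t{kw}\n")
                for kp in sorted(self.keyphrases.get(dom, ())):
                    fh.write(f"{dom.value}\t{' '.join(kp)}\n")

    # ------------------------------------------------------------ utilities
    def domains(self) -> list[DomainLabel]:
        """Domains with at least one entry."""
        return [d for d in RISK_DOMAINS if self.keywords.get(d) or self.keyphrases.get(d)]

    def all_keyphrases(self) -> list[tuple[str, ...]]:
        """Every keyphrase across domains, trigrams before bigrams."""
        phrases = {p for ps in self.keyphrases.values() for p in ps}
        return sorted(phrases, key=lambda p: (-len(p), p))

    def with_keyphrases(
        self, accepted: Mapping[DomainLabel, Iterable[Sequence[str]]]
    ) -> "DomainLexicon":
        """A new lexicon with mined keyphrases merged in (human accept-list)."""
        keyphrases = {d: set(ps) for d, ps in self.keyphrases.items()}
        for dom, phrases in accepted.items():
            slot = keyphrases.setdefault(dom, set())
            slot.update(tuple(p) for p in phrases)
        return DomainLexicon(
            keywords=dict(self.keywords),
            keyphrases={d: frozenset(ps) for d, ps in keyphrases.items()},
        )

    def n_keywords(self) -> int:
        return sum(len(v) for v in self.keywords.values())

    def n_keyphrases(self) -> int:
        return sum(len(v) for v in self.keyphrases.values())
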