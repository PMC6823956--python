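"""The seven readmission risk-factor domains plus the open-world ``Other`` label.

The seven domains (Appearance, Mood, Interpersonal, Occupation, Thought
Content, Thought Process, Substance) jointly cover the clinical aspects of a
psychiatric patient's symptoms and functioning that recur in admission notes
and discharge summaries.  ``Other`` is the none-of-the-above outcome of
open-world prediction and annotation; it is never a training label.
"""

from __future__ import annotations

from enum import Enum


class DomainLabel(str, Enum):
    """One of the seven risk-factor domains, or the open-world ``Other``."""

    APPEARANCE = "Appearance"
    MOOD = "Mood"
    INTERPERSONAL = "Interpersonal"
    OCCUPATION = "Occupation"
    THOUGHT_CONTENT = "ThoughtContent"
    THOUGHT_PROCESS = "ThoughtProcess"
    SUBSTANCE = "Substance"
    OTHER = "Other"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Canonical ordering of the seven trainable domains.  This order is the
#: label order of every score vector, one-hot matrix and threshold set.
RISK_DOMAINS: tuple[DomainLabel, ...] = (
    DomainLabel.APPEARANCE,
    DomainLabel.MOOD,
    DomainLabel.INTERPERSONAL,
    DomainLabel.OCCUPATION,
    DomainLabel.THOUGHT_CONTENT,
    DomainLabel.THOUGHT_PROCESS,
    DomainLabel.SUBSTANCE,
)

#: All eight labels (the seven domains plus Other).
ALL_LABELS: tuple[DomainLabel, ...] = RISK_DOMAINS + (DomainLabel.OTHER,)

#: Index of each risk domain in :data:`RISK_DOMAINS`.
DOMAIN_INDEX: dict[DomainLabel, int] = {d: i for i, d in enumerate(RISK_DOMAINS)}


def parse_label(name: str) -> DomainLabel:
    """Parse a domain name, tolerating spacing/case variants like ``thought content``."""
    key = "".join(ch for ch in name.strip().lower() if ch.isalnum())
    for label in ALL_LABELS:
        if key == label.value.lower():
            return label
    raise ValueError(f"unknown domain label: {name!r}")
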