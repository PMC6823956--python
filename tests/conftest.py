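import pytest

from riskdomains import DomainLexicon


@pytest.fixture
def clinical_lexicon():
    """A small hand-written lexicon in the style of a clinician keyword
    list (synthetic example entries, not the study lexicon)."""
    return DomainLexicon.from_dict(
        {
            "Substance": {"keywords": ["cocaine", "marijuana", "etoh", "narcotic"]},
            "Mood": {"keywords": ["depressed", "anxious", "labile"]},
            "ThoughtProcess": {
                "keywords": ["tangential", "perseverant"],
                "keyphrases": ["linear thinking", "flight of ideas"],
            },
            "ThoughtContent": {
                "keywords": ["delusion", "hallucinations", "paranoid"],
                "keyphrases": ["ideas of reference"],
            },
            "Appearance": {"keywords": ["disheveled", "groomed"]},
            "Interpersonal": {"keywords": ["boyfriend", "family"]},
            "Occupation": {"keywords": ["job", "school", "homework"]},
        }
    )
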