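"""Weak supervision: from a clinician lexicon to a labeled training corpus.

Builds a tiny lexicon, matches a handful of sentences against it, and mines
TF-IDF-ranked bigram/trigram candidates for human review.  The printed
labels show which sentences the lexicon can claim for training and why
ambiguous ones are dropped.
"""

from riskdomains import DomainLexicon, SentenceRecord, match_sentences, mine_mwe_candidates

lexicon = DomainLexicon.from_dict({
    "Substance": {"keywords": ["cocaine", "marijuana", "etoh"]},
    "Mood": {"keywords": ["depressed", "anxious"]},
    "ThoughtProcess": {"keywords": ["tangential"], "keyphrases": ["linear thinking"]},
})

sentences = [
    "Patient used marijuana once",
    "Pt indicates that his mood is becoming more depressed",
    "Notable linear thinking and flight of ideas",
    "Cocaine use while depressed",          # ambiguous: one hit per domain
    "Patient slept well through the night",  # no lexicon hit
]
records = [SentenceRecord.build(f"s{i}", t) for i, t in enumerate(sentences)]

labeled, excluded = match_sentences(records, lexicon, return_excluded=True)
print("weakly labeled training sentences:")
for ls in labeled:
    print(f"  [{ls.first_label.value:14s}] {ls.sentence.raw_text}")
print("excluded (no hit, or tied multi-domain hit):")
for rec in excluded:
    print(f"  {rec.raw_text}")

candidates = mine_mwe_candidates(labeled, top_k=3)
print("\ntop TF-IDF bigram/trigram candidates per domain (for human review):")
for dom, cands in candidates.items():
    for c in cands[:2]:
        print(f"  {dom.value:14s} {' '.join(c.ngram):28s} tf-idf={c.tfidf_score:.3f}")

# Phrases a reviewer accepts would be merged back into the lexicon as
# keyphrases and treated as single non-stemmed tokens downstream.
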