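"""Inter-annotator agreement and gold adjudication on simulated annotators.

Simulates three annotators who reproduce the gold labels with 80%
probability and otherwise confuse a domain with an overlapping neighbour,
then reports Fleiss's kappa, the Davies-Fleiss multi-kappa, set-theoretic
total agreement/disagreement counts, majority adjudication, and
per-annotator accuracy against gold.
"""

from riskdomains import (
    SynthConfig,
    adjudicate,
    agreement_report,
    generate,
    simulate_annotators,
)

bundle = generate(SynthConfig(n_train=10, n_test=400, seed=13))
table = simulate_annotators(bundle.test_gold, k=3, noise=0.2, seed=13)

report = agreement_report(table, gold=bundle.test_gold)
print(f"items annotated:        {report.n_items}")
print(f"Fleiss's kappa:         {report.fleiss_kappa:.3f}")
print(f"multi-kappa:            {report.multi_kappa:.3f}")
print(f"mean annotator accuracy:{report.mean_accuracy:.3f}")
print(f"total agreement:        {report.n_total_agreement} "
      f"({100 * report.n_total_agreement / report.n_items:.0f}%)")
print(f"total disagreement:     {report.n_total_disagreement}")

gold, review = adjudicate(table)
print(f"\nmajority adjudication:  {len(gold)} gold items, "
      f"{len(review)} routed to manual expert review")

# Kappa around 0.6 with 20% annotator noise sits in the "moderate to
# substantial" band typical of sentence-level clinical annotation tasks;
# items without a two-annotator exact match are never silently labeled.
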