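"""Open-world thresholding: mean + alpha*sd per domain, Other as fallback.

Trains the MLP once on a small bundle, then re-thresholds its test scores
at several alphas to show the precision/recall trade: low alpha assigns
more (and more speculative) domain labels, high alpha pushes borderline
sentences into Other.  The reference operating points are alpha=0.5 (MLP)
and alpha=1.25 (RBF).
"""

from riskdomains import (
    LabeledSentence,
    MlpConfig,
    SynthConfig,
    compute_thresholds,
    generate,
    predict_all,
    run_on_bundle,
)
from riskdomains.baseline import DomainScores
from riskdomains.domains import RISK_DOMAINS
from riskdomains.encoding import EncoderSpec, encode_sentences
from riskdomains.evaluation import evaluate
from riskdomains.pipeline import _rebuild

bundle = generate(SynthConfig(n_train=800, n_test=300, seed=13))
result = run_on_bundle(bundle, models=("mlp",), mlp_config=MlpConfig(epochs=60, seed=5))
model = result.results["mlp"].model

records = _rebuild([ls.sentence for ls in bundle.test_gold], bundle.lexicon)
gold = [
    LabeledSentence(sentence=r, labels=ls.labels)
    for r, ls in zip(records, bundle.test_gold)
]
scores = model.score_matrix(encode_sentences(records, EncoderSpec(seed=13)))
table = [
    DomainScores(records[i].id, dict(zip(RISK_DOMAINS, scores[i].tolist())))
    for i in range(len(records))
]

print(f"{'alpha':>6s} {'macro-P':>8s} {'macro-R':>8s} {'macro-F1':>8s} {'%Other':>7s}")
for alpha in (0.0, 0.25, 0.5, 1.0, 1.5, 2.5):
    thresholds = compute_thresholds(table, alpha=alpha)
    preds = predict_all(table, thresholds)
    rep = evaluate(gold, preds)
    pct_other = 100 * sum(p.is_other for p in preds) / len(preds)
    print(
        f"{alpha:6.2f} {rep.macro_precision:8.3f} {rep.macro_recall:8.3f} "
        f"{rep.macro_f1:8.3f} {pct_other:6.1f}%"
    )

# Raising alpha never adds a domain label to any sentence (monotone), and
# in the limit every sentence becomes Other.
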