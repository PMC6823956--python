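"""End-to-end pipeline: weak labeling -> encoding -> models -> thresholds -> evaluation.

One call runs the whole study design on a corpus with a planted or real
lexicon: sentences are weakly labeled by lexicon matching, MWEs are merged
and remaining tokens stemmed, sentences are embedded, the cosine baseline
and/or neural classifiers are fitted on the weakly labeled megadocuments,
per-domain thresholds are derived from each model's scores on its own
training sentences, and open-world multilabel predictions are scored
against gold.

``mwe_mode`` reproduces the with/without-MWE comparisons: ``"no_merge"``
keeps keyphrase matching but disables token merging (a pure
feature-representation toggle, the "no MWEs" model variants), while
``"off"`` removes keyphrases from weak labeling as well, shrinking the
training corpus the lexicon can claim.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .baseline import CosineBaseline, DomainScores
from .corpus import (
    LabeledSentence,
    SentenceRecord,
    build_megadocuments,
    match_sentences,
)
from .domains import RISK_DOMAINS
from .encoding import EncoderSpec, encode_sentences
from .evaluation import EvalReport, evaluate
from .lexicon import DomainLexicon
from .neural import (
    MlpConfig,
    RbfConfig,
    TrainedModel,
    compute_width,
    one_hot,
    select_prototypes,
    train_mlp,
    train_rbf,
)
from .synthetic import SynthBundle
from .thresholds import (
    ALPHA_MLP,
    ALPHA_RBF,
    Prediction,
    ThresholdSet,
    compute_thresholds,
    predict_all,
)


@dataclass
class ModelResult:
    name: str
    report: EvalReport
    thresholds: ThresholdSet
    predictions: list[Prediction]
    model: TrainedModel | CosineBaseline | None = None


@dataclass
class PipelineResult:
    results: dict[str, ModelResult]
    n_train_labeled: int
    n_train_input: int

    def macro_f1(self, name: str) -> float:
        return self.results[name].report.macro_f1


def _rebuild(records: Sequence[SentenceRecord], lexicon: DomainLexicon) -> list[SentenceRecord]:
    keyphrases = lexicon.all_keyphrases()
    return [SentenceRecord.build(r.id, r.raw_text, keyphrases) for r in records]


def run_pipeline(
    train_sentences: Sequence[SentenceRecord],
    test_gold: Sequence[LabeledSentence],
    lexicon: DomainLexicon,
    *,
    models: Sequence[str] = ("baseline", "mlp", "rbf"),
    mwe_mode: str = "on",
    encoder: EncoderSpec | None = None,
    seed: int = 13,
    mlp_config: MlpConfig | None = None,
    rbf_config: RbfConfig | None = None,
    alpha_baseline: float = ALPHA_MLP,
    threshold_population: str = "target",
) -> PipelineResult:
    """Run the full study on raw training sentences and a gold test set.

    ``seed`` drives the encoder hash, network initialization and k-means;
    sub-seeds are derived with fixed offsets so runs are reproducible.

    ``threshold_population`` selects the score population behind the
    per-domain threshold formula mean + alpha*sd: ``"target"`` (default)
    uses the model's scores on the unlabeled target corpus, so thresholds
    adapt to how similar the target data is to the training data;
    ``"train_in_domain"`` uses each domain's own training sentences;
    ``"train_all"`` uses all training scores.  No gold labels are ever
    consulted.
    """
    if threshold_population not in ("target", "train_in_domain", "train_all"):
        raise ValueError(f"unknown threshold population: {threshold_population!r}")
    if mwe_mode not in ("on", "no_merge", "off"):
        raise ValueError(f"unknown mwe_mode: {mwe_mode!r}")
    if mwe_mode == "off":
        lexicon = DomainLexicon(keywords=dict(lexicon.keywords), keyphrases={})
    encoder = encoder or EncoderSpec(kind="hashed_fallback", seed=seed % (2**31 - 7))

    # weak labeling always sees the lexicon's keyphrases (unless mwe_mode
    # is "off"); "no_merge" disables only the feature representation step,
    # leaving MWE component tokens unmerged
    merge_lexicon = lexicon if mwe_mode == "on" else DomainLexicon(
        keywords=dict(lexicon.keywords), keyphrases={}
    )
    # keyphrase matching inspects raw token spans, so records merged (or
    # not) per mwe_mode can be matched against the full lexicon directly
    train_records = _rebuild(train_sentences, merge_lexicon)
    labeled = match_sentences(train_records, lexicon)
    if not labeled:
        raise ValueError("weak labeling matched no training sentences")
    megadocs = build_megadocuments(labeled)

    train_recs = [ls.sentence for ls in labeled]
    X_train = encode_sentences(train_recs, encoder)
    train_vectors: Mapping[str, np.ndarray] = {
        r.id: X_train[i] for i, r in enumerate(train_recs)
    }
    train_ids = [r.id for r in train_recs]
    Y_train = one_hot([ls.first_label for ls in labeled])

    test_records = _rebuild([ls.sentence for ls in test_gold], merge_lexicon)
    gold = [
        LabeledSentence(sentence=rec, labels=ls.labels)
        for rec, ls in zip(test_records, test_gold)
    ]
    X_test = encode_sentences(test_records, encoder)
    test_ids = [r.id for r in test_records]

    results: dict[str, ModelResult] = {}

    def _finish(name, scorer, train_scores, alpha, model_obj):
        test_scores = scorer(X_test, test_ids)
        if threshold_population == "target":
            thresholds = compute_thresholds(test_scores, alpha)
        elif threshold_population == "train_in_domain":
            thresholds = compute_thresholds(train_scores, alpha, population=labeled)
        else:
            thresholds = compute_thresholds(train_scores, alpha)
        preds = predict_all(test_scores, thresholds)
        results[name] = ModelResult(
            name=name,
            report=evaluate(gold, preds),
            thresholds=thresholds,
            predictions=preds,
            model=model_obj,
        )

    if "baseline" in models:
        base = CosineBaseline().fit(megadocs, train_vectors)
        _finish(
            "baseline",
            base.score_matrix,
            base.score_matrix(X_train, train_ids),
            alpha_baseline,
            base,
        )

    def _net_scores(model: TrainedModel, X: np.ndarray, ids: Sequence[str]) -> list[DomainScores]:
        S = model.score_matrix(X)
        return [
            DomainScores(ids[i], dict(zip(RISK_DOMAINS, S[i].tolist())))
            for i in range(len(ids))
        ]

    if "mlp" in models:
        cfg = mlp_config or MlpConfig(seed=(seed * 7 + 1) % (2**31 - 1))
        mlp = train_mlp(X_train, Y_train, cfg)
        _finish(
            "mlp",
            lambda X, ids: _net_scores(mlp, X, ids),
            _net_scores(mlp, X_train, train_ids),
            ALPHA_MLP,
            mlp,
        )

    if "rbf" in models:
        smallest = min(len(md) for md in megadocs)
        cfg = rbf_config or RbfConfig(
            prototypes_per_domain=min(100, smallest),
            seed=(seed * 7 + 2) % (2**31 - 1),
        )
        prototypes = select_prototypes(
            megadocs,
            train_vectors,
            k_per_domain=cfg.prototypes_per_domain,
            seed=(seed * 7 + 3) % (2**31 - 1),
        )
        width = compute_width(prototypes, cfg.width_rule, cfg.custom_width, cfg.output_nodes)
        rbf = train_rbf(X_train, Y_train, cfg, prototypes, width)
        _finish(
            "rbf",
            lambda X, ids: _net_scores(rbf, X, ids),
            _net_scores(rbf, X_train, train_ids),
            ALPHA_RBF,
            rbf,
        )

    return PipelineResult(
        results=results,
        n_train_labeled=len(labeled),
        n_train_input=len(train_sentences),
    )


def run_on_bundle(bundle: SynthBundle, **kwargs) -> PipelineResult:
    """Run the pipeline on a synthetic bundle's raw sentences and gold."""
    seed = kwargs.pop("seed", bundle.config.seed)
    return run_pipeline(
        [ls.sentence for ls in bundle.train],
        bundle.test_gold,
        bundle.lexicon,
        seed=seed,
        **kwargs,
    )


def mwe_effect(n_train: int = 200, seed: int = 13) -> tuple[float, float]:
    """Macro-F1 of the MLP with and without MWE merging on the MWE-heavy
    study condition, holding the weakly labeled corpus fixed.

    Epochs are scaled inversely with corpus size so both corpus sizes see
    a comparable number of optimization steps (the reference schedule is
    60 epochs at 2000 sentences).
    """
    from .synthetic import generate, small_n_mwe_config

    bundle = generate(small_n_mwe_config(n_train=n_train, seed=seed))
    epochs = max(60, int(round(60 * 2000 / max(n_train, 1))))
    cfg = MlpConfig(epochs=epochs, seed=(seed * 7 + 1) % (2**31 - 1))
    f1_on = run_on_bundle(bundle, models=("mlp",), mlp_config=cfg).macro_f1("mlp")
    f1_off = run_on_bundle(
        bundle, models=("mlp",), mlp_config=cfg, mwe_mode="no_merge"
    ).macro_f1("mlp")
    return f1_on, f1_off
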