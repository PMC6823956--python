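"""MLP and RBF networks, k-means prototypes, and the shared width rule."""

import itertools

import numpy as np
import pytest

from riskdomains import (
    DomainLabel,
    Megadocument,
    MlpConfig,
    RbfConfig,
    SentenceRecord,
    compute_width,
    one_hot,
    rbf_hidden,
    select_prototypes,
    train_mlp,
    train_rbf,
)
from riskdomains.domains import RISK_DOMAINS
from riskdomains.neural import load_model, save_model


def _separable_data(rng, n_per_class=20, dim=32, n_classes=7):
    """Linearly separable blobs, one per domain."""
    X, labels = [], []
    for k in range(n_classes):
        center = np.zeros(dim)
        center[k] = 4.0
        X.append(center + 0.3 * rng.normal(size=(n_per_class, dim)))
        labels += [RISK_DOMAINS[k]] * n_per_class
    return np.vstack(X), one_hot(labels)


# ------------------------------------------------------------------- MLP
def test_mlp_trainable_parameter_count():
    model = train_mlp(
        np.zeros((2, 512)), one_hot([DomainLabel.MOOD, DomainLabel.MOOD]),
        MlpConfig(epochs=1),
    )
    # dense layers: 512*250 + 250 + 250*7 + 7
    assert model.n_parameters() == 512 * 250 + 250 + 250 * 7 + 7 == 130_007


def test_mlp_loss_decreases_on_constant_data():
    X = np.tile(np.linspace(-1, 1, 16), (10, 1))
    Y = one_hot([DomainLabel.SUBSTANCE] * 10)
    model = train_mlp(X, Y, MlpConfig(input_nodes=16, hidden_nodes=8, epochs=20, seed=0))
    assert model.history[-1] < model.history[0]


def test_mlp_fits_separable_blobs():
    rng = np.random.default_rng(0)
    X, Y = _separable_data(rng)
    model = train_mlp(X, Y, MlpConfig(input_nodes=32, hidden_nodes=32, epochs=60, seed=1))
    acc = np.mean(np.argmax(model.score_matrix(X), axis=1) == np.argmax(Y, axis=1))
    assert acc >= 0.95
    assert model.history[-1] < model.history[0]


def test_mlp_scores_are_sigmoids_not_normalized():
    rng = np.random.default_rng(1)
    X, Y = _separable_data(rng, n_per_class=10)
    model = train_mlp(X, Y, MlpConfig(input_nodes=32, hidden_nodes=16, epochs=20, seed=2))
    S = model.score_matrix(X)
    assert np.all((S > 0) & (S < 1))
    # independent per-node likelihoods: rows need not sum to one
    assert not np.allclose(S.sum(axis=1), 1.0)


def test_mlp_reproducible_with_seed():
    rng = np.random.default_rng(2)
    X, Y = _separable_data(rng, n_per_class=8)
    cfg = MlpConfig(input_nodes=32, hidden_nodes=16, epochs=10, seed=42)
    a = train_mlp(X, Y, cfg)
    b = train_mlp(X, Y, cfg)
    assert abs(a.history[-1] - b.history[-1]) < 1e-6
    assert np.array_equal(a.params["W1"], b.params["W1"])


def test_mlp_shape_mismatch_errors():
    with pytest.raises(ValueError):
        train_mlp(np.zeros((3, 512)), np.zeros((2, 7)), MlpConfig(epochs=1))
    with pytest.raises(ValueError):
        train_mlp(np.zeros((0, 512)), np.zeros((0, 7)), MlpConfig(epochs=1))


# ------------------------------------------------------------- prototypes
def _exhaustive_kmeans(points, k):
    """Globally optimal k-means by enumerating all assignments (tiny n)."""
    n = len(points)
    best_inertia, best_centroids = np.inf, None
    for assign in itertools.product(range(k), repeat=n):
        if len(set(assign)) != k:
            continue
        cents = np.stack([
            points[np.array(assign) == j].mean(axis=0) for j in range(k)
        ])
        inertia = sum(
            np.sum((points[i] - cents[assign[i]]) ** 2) for i in range(n)
        )
        if inertia < best_inertia - 1e-12:
            best_inertia, best_centroids = inertia, cents
    return best_centroids, best_inertia


def _md_with_vectors(domain, vectors):
    sents = [SentenceRecord.build(f"{domain.value}{i}", "x") for i in range(len(vectors))]
    md = Megadocument(domain=domain, sentences=sents)
    mapping = {s.id: v for s, v in zip(sents, vectors)}
    return md, mapping


def test_prototypes_k_equals_n_returns_points():
    rng = np.random.default_rng(3)
    pts = rng.normal(size=(4, 5))
    md, vecs = _md_with_vectors(DomainLabel.MOOD, pts)
    protos = select_prototypes([md], vecs, k_per_domain=4, seed=0)
    assert sorted(map(tuple, np.round(protos, 9))) == sorted(map(tuple, np.round(pts, 9)))


def test_prototypes_k1_is_domain_mean():
    rng = np.random.default_rng(4)
    pts = rng.normal(size=(6, 3))
    md, vecs = _md_with_vectors(DomainLabel.MOOD, pts)
    protos = select_prototypes([md], vecs, k_per_domain=1, seed=0)
    assert np.allclose(protos[0], pts.mean(axis=0))


def test_prototypes_match_exhaustive_search_on_separated_blobs():
    rng = np.random.default_rng(5)
    pts = np.vstack([
        np.array([0.0, 0.0]) + 0.1 * rng.normal(size=(5, 2)),
        np.array([10.0, 10.0]) + 0.1 * rng.normal(size=(5, 2)),
    ])
    md, vecs = _md_with_vectors(DomainLabel.MOOD, pts)
    protos = select_prototypes([md], vecs, k_per_domain=2, seed=0)
    oracle, _ = _exhaustive_kmeans(pts, 2)
    assert np.allclose(
        sorted(map(tuple, protos)), sorted(map(tuple, oracle)), atol=1e-8
    )


def test_prototypes_error_names_small_domain():
    md, vecs = _md_with_vectors(DomainLabel.SUBSTANCE, np.zeros((2, 3)))
    with pytest.raises(ValueError, match="Substance"):
        select_prototypes([md], vecs, k_per_domain=5, seed=0)


# ------------------------------------------------------------------ width
def test_width_two_prototypes_distance_two():
    protos = np.array([[0.0, 0.0], [2.0, 0.0]])
    assert compute_width(protos, rule="dmax_sqrt2m") == pytest.approx(1.0)


def test_width_scales_linearly_with_inputs():
    rng = np.random.default_rng(6)
    protos = rng.normal(size=(5, 4))
    for rule in ("dmax_sqrt2m", "dmax_sqrt2c", "dmax"):
        w = compute_width(protos, rule=rule)
        assert compute_width(3.0 * protos, rule=rule) == pytest.approx(3.0 * w)


def test_width_unit_simplex():
    protos = np.eye(3)  # pairwise distance sqrt(2), m=3
    assert compute_width(protos, rule="dmax_sqrt2m") == pytest.approx(
        np.sqrt(2) / np.sqrt(6)
    )


def test_width_degenerate_errors():
    with pytest.raises(ValueError):
        compute_width(np.zeros((1, 3)))
    with pytest.raises(ValueError):
        compute_width(np.zeros((4, 3)))  # all identical


# ------------------------------------------------------------- RBF kernel
def test_rbf_activation_is_one_at_prototype():
    protos = np.array([[1.0, 2.0], [3.0, 4.0]])
    act = rbf_hidden(np.array([1.0, 2.0]), protos, width=0.5)[0]
    assert act[0] == pytest.approx(1.0)
    assert 0.0 < act[1] < 1.0


def test_rbf_activation_at_sigma_sqrt2_distance():
    sigma = 0.7
    protos = np.array([[0.0, 0.0]])
    v = np.array([sigma * np.sqrt(2), 0.0])
    act = rbf_hidden(v, protos, width=sigma)[0, 0]
    assert act == pytest.approx(np.exp(-1.0))


def test_rbf_activation_monotone_in_distance():
    protos = np.array([[0.0]])
    dists = np.linspace(0, 5, 30)[:, None]
    acts = rbf_hidden(dists, protos, width=1.0)[:, 0]
    assert np.all(np.diff(acts) < 0)
    assert np.all((acts > 0) & (acts <= 1))


# ------------------------------------------------------------ RBF network
def test_rbf_output_layer_parameter_count():
    rng = np.random.default_rng(7)
    X = rng.normal(size=(10, 512))
    Y = one_hot([DomainLabel.MOOD] * 10)
    protos = rng.normal(size=(700, 512))
    model = train_rbf(X, Y, RbfConfig(epochs=1), protos, width=1.0)
    assert model.n_parameters() == 700 * 7 + 7 == 4_907


def test_rbf_fits_separable_blobs():
    rng = np.random.default_rng(8)
    X, Y = _separable_data(rng, n_per_class=12, dim=16)
    # tiny corpus = one batch per epoch, so extra epochs keep the number of
    # optimization steps comparable to a full-size run
    cfg = RbfConfig(input_nodes=16, prototypes_per_domain=2, epochs=600, seed=3)
    labels = [RISK_DOMAINS[k] for k in np.argmax(Y, axis=1)]
    megadocs, vectors = [], {}
    for k, dom in enumerate(RISK_DOMAINS):
        pts = X[np.array(labels) == dom]
        md, vecs = _md_with_vectors(dom, pts)
        megadocs.append(md)
        vectors.update(vecs)
    protos = select_prototypes(megadocs, vectors, k_per_domain=2, seed=0)
    model = train_rbf(X, Y, cfg, protos)
    acc = np.mean(np.argmax(model.score_matrix(X), axis=1) == np.argmax(Y, axis=1))
    assert acc >= 0.9


def test_rbf_reproducible_with_seed():
    rng = np.random.default_rng(9)
    X, Y = _separable_data(rng, n_per_class=6, dim=8)
    protos = rng.normal(size=(14, 8))
    cfg = RbfConfig(input_nodes=8, prototypes_per_domain=2, epochs=10, seed=5)
    a = train_rbf(X, Y, cfg, protos, width=1.0)
    b = train_rbf(X, Y, cfg, protos, width=1.0)
    assert abs(a.history[-1] - b.history[-1]) < 1e-6


def test_model_save_load_roundtrip(tmp_path):
    rng = np.random.default_rng(10)
    X, Y = _separable_data(rng, n_per_class=5, dim=8)
    model = train_mlp(X, Y, MlpConfig(input_nodes=8, hidden_nodes=4, epochs=5, seed=0))
    save_model(model, tmp_path / "m")
    again = load_model(tmp_path / "m")
    assert np.array_equal(model.score_matrix(X), again.score_matrix(X))
    assert again.label_order == RISK_DOMAINS
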