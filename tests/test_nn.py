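import numpy as np
import pytest

import graphstab._batching as batching_mod
import graphstab.nn as nn_mod
from graphstab._batching import GraphBatch, digest_graph
from graphstab.graphs import build_residue_graph
from graphstab.nn import (
    GraphStabilityClassifier,
    ModelConfig,
    TrainedModel,
    _backward,
    _forward,
    bce_with_logits,
    init_model,
    init_params,
    predict_proba,
    train,
)
from graphstab.synthetic import make_helix_coords


def _random_graphs(rng, sizes, radius=8.0):
    out = []
    for n in sizes:
        coords = rng.normal(scale=4.0, size=(n, 3))
        feats = rng.normal(size=(n, 6))
        out.append(build_residue_graph("A" * n, feats, coords, radius=radius))
    return out


def _toy_separable(n_graphs=30, seed=0):
    """Graphs whose label is determined by feature column 6 alone."""
    rng = np.random.default_rng(seed)
    graphs, labels = [], []
    for i in range(n_graphs):
        n = int(rng.integers(8, 13))
        label = i % 2
        feats = np.column_stack(
            [rng.normal(scale=0.1, size=(n, 5)), np.full(n, 0.9 if label else 0.1)]
        )
        graphs.append(build_residue_graph("A" * n, feats, make_helix_coords(n)))
        labels.append(label)
    return graphs, np.array(labels)


def test_backward_matches_finite_differences(monkeypatch):
    """Analytic gradients of every parameter array agree with central
    finite differences on a mixed batch (multi-graph, isolated node,
    partial pooling)."""
    monkeypatch.setattr(batching_mod, "_DTYPE", np.float64)
    monkeypatch.setattr(nn_mod, "_DTYPE", np.float64)
    rng = np.random.default_rng(0)
    graphs = _random_graphs(rng, (5, 7, 1, 4))
    cfg = ModelConfig(
        hidden_units=8, dropout=0.0, pooling_ratio=0.6, max_epochs=10, patience=5
    )
    params = {k: v.astype(np.float64) for k, v in init_params(cfg, seed=3).items()}
    params["gat.a_dist"][:] = 0.3  # exercise the distance-attention path
    batch = GraphBatch([digest_graph(g) for g in graphs])
    y = np.array([1.0, 0.0, 1.0, 0.0])

    def loss_of(params):
        logits, cache = _forward(params, batch, cfg, training=False)
        loss, grad = bce_with_logits(logits, y)
        return loss, cache, grad

    _, cache, gl = loss_of(params)
    grads = _backward(params, batch, cache, gl)
    eps = 1e-6
    for name, p in params.items():
        num = np.zeros_like(p)
        it = np.nditer(p, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            old = p[idx]
            p[idx] = old + eps
            lp, _, _ = loss_of(params)
            p[idx] = old - eps
            lm, _, _ = loss_of(params)
            p[idx] = old
            num[idx] = (lp - lm) / (2 * eps)
        scale = max(np.abs(num).max(), np.abs(grads[name]).max(), 1e-10)
        assert np.abs(num - grads[name]).max() / scale < 1e-6, name


def test_init_is_seeded_and_sized():
    cfg = ModelConfig()
    a = init_model(cfg, seed=5)
    b = init_model(cfg, seed=5)
    c = init_model(cfg, seed=6)
    assert a.params["gat.W"].shape == (6, 128)  # input dim 6 -> hidden 128
    assert a.params["sage.W_self"].shape == (128, 128)
    for k in a.params:
        np.testing.assert_array_equal(a.params[k], b.params[k])
    assert not np.array_equal(a.params["gat.W"], c.params["gat.W"])


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        ModelConfig(dropout=1.0)
    with pytest.raises(ValueError):
        ModelConfig(pooling_ratio=0.0)
    with pytest.raises(ValueError):
        ModelConfig(patience=100, max_epochs=50)


def test_pooling_ratio_one_keeps_all_nodes():
    rng = np.random.default_rng(1)
    graphs = _random_graphs(rng, (6, 9))
    cfg = ModelConfig(hidden_units=8, pooling_ratio=1.0, max_epochs=5, patience=5)
    params = init_params(cfg, seed=0)
    batch = GraphBatch([digest_graph(g) for g in graphs])
    _, cache = _forward(params, batch, cfg, training=False)
    assert len(cache["keep"]) == batch.n_nodes


def test_zeroed_head_gives_probability_half(quick_model):
    model = TrainedModel(
        config=quick_model.config,
        params={**quick_model.params,
                "fc2.W": np.zeros_like(quick_model.params["fc2.W"]),
                "fc2.b": np.zeros_like(quick_model.params["fc2.b"])},
        train_losses=[], val_losses=[], best_epoch=0, stopped_epoch=0,
    )
    rng = np.random.default_rng(2)
    p = predict_proba(model, _random_graphs(rng, (5, 8)))
    np.testing.assert_allclose(p, 0.5, atol=1e-12)


def test_probabilities_strictly_inside_unit_interval(quick_model, synthetic_graphs):
    p = predict_proba(quick_model, synthetic_graphs[0][:20])
    assert ((p > 0) & (p < 1)).all()


def test_batched_prediction_matches_one_by_one(quick_model, synthetic_graphs):
    graphs = synthetic_graphs[0][:10]
    together = predict_proba(quick_model, graphs)
    singles = np.array([predict_proba(quick_model, [g])[0] for g in graphs])
    np.testing.assert_allclose(together, singles, atol=1e-6)


def test_feature_dimension_mismatch_rejected(quick_model):
    rng = np.random.default_rng(3)
    batch = GraphBatch([digest_graph(g) for g in _random_graphs(rng, (4,))])
    batch.x = batch.x[:, :5]  # corrupt the feature width
    with pytest.raises(ValueError, match="feature dimension"):
        _forward(quick_model.params, batch, quick_model.config, training=False)


def test_training_reduces_loss_and_is_deterministic():
    graphs, labels = _toy_separable()
    cfg = ModelConfig(hidden_units=16, max_epochs=25, patience=25, batch_size=8, seed=4)
    m1 = train(init_model(cfg), graphs, labels)
    m2 = train(init_model(cfg), graphs, labels)
    assert m1.train_losses[-1] < m1.train_losses[0]
    np.testing.assert_allclose(m1.train_losses, m2.train_losses, atol=1e-6)
    np.testing.assert_allclose(m1.val_losses, m2.val_losses, atol=1e-6)
    assert m1.stopped_epoch == m2.stopped_epoch


def test_single_class_training_rejected():
    graphs, labels = _toy_separable(10)
    cfg = ModelConfig(hidden_units=8, max_epochs=5, patience=5)
    with pytest.raises(ValueError, match="both classes"):
        train(init_model(cfg), graphs, np.ones(10))


def test_flat_validation_loss_stops_after_patience():
    """With an (effectively) zero learning rate the validation loss is flat
    from epoch 1, so training must stop exactly ``patience`` epochs later."""
    graphs, labels = _toy_separable(12)
    cfg = ModelConfig(
        hidden_units=8, learning_rate=1e-30, patience=50, max_epochs=120,
        batch_size=8, seed=0,
    )
    m = train(init_model(cfg), graphs, labels)
    assert m.best_epoch == 1
    assert m.stopped_epoch == 51  # 1 best + 50 non-improving
    assert len(m.train_losses) == len(m.val_losses) == 51


def test_capacity_on_separable_toy_graphs():
    """The network must fit 30 graphs whose label is carried by the
    conservation column alone to >= 95% training accuracy."""
    graphs, labels = _toy_separable()
    cfg = ModelConfig(max_epochs=300, patience=300, batch_size=8, seed=0)
    m = train(init_model(cfg), graphs, labels)
    acc = ((predict_proba(m, graphs) >= 0.5).astype(int) == labels).mean()
    assert acc >= 0.95


def test_checkpoint_round_trip(tmp_path, quick_model, synthetic_graphs):
    path = tmp_path / "model.npz"
    quick_model.save(path)
    back = TrainedModel.load(path)
    assert back.config == quick_model.config
    graphs = synthetic_graphs[0][:5]
    np.testing.assert_allclose(
        predict_proba(back, graphs), predict_proba(quick_model, graphs), atol=0
    )
    log = tmp_path / "log.csv"
    quick_model.write_training_log(log)
    assert log.read_text().startswith("epoch,train_loss,val_loss")


def test_estimator_sklearn_contract():
    from sklearn.base import clone

    est = GraphStabilityClassifier(hidden_units=16, max_epochs=5)
    params = est.get_params()
    assert params["hidden_units"] == 16
    cloned = clone(est)
    assert cloned.get_params() == params
    est.set_params(batch_size=4)
    assert est.batch_size == 4
    with pytest.raises(ValueError):
        est.set_params(bogus=1)
    with pytest.raises(RuntimeError, match="not fitted"):
        est.predict([])


def test_estimator_fit_predict(synthetic_graphs):
    graphs, labels, _, _ = synthetic_graphs
    est = GraphStabilityClassifier(
        hidden_units=16, max_epochs=6, patience=6, batch_size=32, seed=0
    )
    est.fit(graphs[:80], labels[:80])
    proba = est.predict_proba(graphs[80:90])
    assert proba.shape == (10, 2)
    np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-12)
    assert set(est.predict(graphs[80:90])) <= {0, 1}
    assert est.n_epochs_ == len(est.train_losses_)
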