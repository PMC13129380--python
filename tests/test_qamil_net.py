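"""Attention-MIL network: oracle equivalence, algebraic contracts,
invariances, and training determinism."""

import math
from dataclasses import replace

import numpy as np
import pytest

import qcmil
from qcmil import (
    AttentionParams,
    EmptyBagError,
    RunConfig,
    aggregate,
    attention_weights,
    bag_loss,
    classify,
    quality_weight,
    total_loss,
    train,
)
from qcmil.qamil_net import _batch_loss_and_grads, _init_model

from conftest import make_bag


def naive_attention(X, params):
    """Instance-by-instance re-implementation: explicit matrix products,
    normalization, rectifier, then a plain softmax."""
    scores = []
    for x in X:
        h = [sum(params.V[l, m] * x[m] for m in range(len(x)))
             for l in range(params.L)]
        mu = sum(h) / len(h)
        var = sum((hi - mu) ** 2 for hi in h) / len(h)
        ln = [params.gamma[l] * (h[l] - mu) / math.sqrt(var + 1e-5)
              + params.beta[l] for l in range(params.L)]
        r = [max(v, 0.0) for v in ln]
        scores.append(sum(params.w[l] * r[l] for l in range(params.L)))
    exps = [math.exp(s) for s in scores]
    return np.array([e / sum(exps) for e in exps])


def random_params(rng, L, M):
    return AttentionParams(V=rng.normal(size=(L, M)),
                           w=rng.normal(size=L),
                           gamma=rng.uniform(0.5, 1.5, L),
                           beta=rng.normal(size=L) * 0.1)


# ---------------------------------------------------------------------------
# operation-level contracts
# ---------------------------------------------------------------------------

def test_quality_weight_identity_annihilation_and_arithmetic():
    X = np.array([[2.0, -4.0], [1.0, 1.0]])
    np.testing.assert_array_equal(quality_weight(X, np.ones(2)), X)
    np.testing.assert_array_equal(quality_weight(X, np.zeros(2)),
                                  np.zeros_like(X))
    np.testing.assert_allclose(quality_weight(X[:1], np.array([0.5])),
                               [[1.0, -2.0]])


def test_attention_singleton_and_symmetry():
    rng = np.random.default_rng(0)
    params = random_params(rng, 8, 3)
    np.testing.assert_allclose(attention_weights(rng.normal(size=(1, 3)),
                                                 params), [1.0])
    x = rng.normal(size=3)
    a = attention_weights(np.stack([x, x]), params)
    np.testing.assert_allclose(a, [0.5, 0.5])


def test_attention_matches_naive_oracle():
    rng = np.random.default_rng(1)
    for _ in range(10):
        K, L, M = rng.integers(1, 7), int(rng.integers(2, 12)), 4
        params = random_params(rng, L, M)
        X = rng.normal(size=(K, M))
        np.testing.assert_allclose(attention_weights(X, params),
                                   naive_attention(X, params), atol=1e-6)


def test_attention_empty_bag_raises():
    with pytest.raises(EmptyBagError):
        attention_weights(np.empty((0, 3)), random_params(
            np.random.default_rng(0), 4, 3))


def test_aggregate_cases():
    rng = np.random.default_rng(2)
    X = rng.normal(size=(3, 4))
    np.testing.assert_array_equal(aggregate(X[:1], np.array([1.0])), X[0])
    np.testing.assert_allclose(aggregate(X, np.full(3, 1 / 3)), X.mean(0))
    a = np.array([0.2, 0.5, 0.3])
    np.testing.assert_allclose(aggregate(X, a),
                               sum(a[k] * X[k] for k in range(3)), atol=1e-9)


def test_classify_closed_forms():
    z = np.zeros(3)
    np.testing.assert_allclose(classify(z, np.zeros((2, 3)), np.zeros(2)),
                               [0.5, 0.5])
    # shift invariance: equal logits regardless of magnitude
    np.testing.assert_allclose(
        classify(np.array([7.0]), np.array([[1.0], [1.0]]), np.zeros(2)),
        [0.5, 0.5])
    p = classify(np.array([1.0]), np.array([[math.log(3.0)], [0.0]]),
                 np.zeros(2))
    np.testing.assert_allclose(p, [0.75, 0.25], atol=1e-12)


def test_bag_loss_closed_forms():
    assert bag_loss(np.array([0.0, 1.0]), 1) == pytest.approx(0.0)
    assert bag_loss(np.array([0.5, 0.5]), 0) == pytest.approx(math.log(2))
    assert bag_loss(np.array([0.75, 0.25]), 1) == pytest.approx(
        -math.log(0.25))


def test_total_loss_endpoints():
    assert total_loss(0.2, 0.4, 1.0) == pytest.approx(0.2)
    assert total_loss(0.2, 0.4, 0.0) == pytest.approx(0.4)
    assert total_loss(0.2, 0.4, 0.5) == pytest.approx(0.3)


# ---------------------------------------------------------------------------
# batched training gradients match the manual forward pass
# ---------------------------------------------------------------------------

def test_batch_gradients_match_finite_differences():
    rng = np.random.default_rng(3)
    cfg = RunConfig()
    cfg = replace(cfg, mil=replace(cfg.mil, L=6, seed=0))
    model = _init_model(5, 2, cfg, np.array([0.5, 0.5]))
    Xs = [rng.normal(size=(4, 5)), rng.normal(size=(2, 5)),
          rng.normal(size=(3, 5))]
    ys = np.array([0, 1, 1])
    starts = np.array([0, 4, 6])
    Xc = np.concatenate(Xs)
    loss, grads = _batch_loss_and_grads(Xc, starts, ys, model)

    params = {"V": model.attn.V, "w": model.attn.w, "gamma": model.attn.gamma,
              "beta": model.attn.beta, "U": model.U, "b": model.b}
    eps = 1e-6
    rng2 = np.random.default_rng(4)
    for name, arr in params.items():
        idx = tuple(rng2.integers(0, s) for s in arr.shape)
        orig = arr[idx]
        arr[idx] = orig + eps
        lp = _batch_loss_and_grads(Xc, starts, ys, model)[0]
        arr[idx] = orig - eps
        lm = _batch_loss_and_grads(Xc, starts, ys, model)[0]
        arr[idx] = orig
        assert grads[name][idx] == pytest.approx((lp - lm) / (2 * eps),
                                                 abs=1e-4), name


# ---------------------------------------------------------------------------
# model-level invariances and degenerate inputs
# ---------------------------------------------------------------------------

def _toy_model(seed=0, M=4, **mil_kw):
    cfg = RunConfig()
    cfg = replace(cfg, mil=replace(cfg.mil, L=8, seed=seed, **mil_kw))
    return _init_model(M, 2, cfg, np.array([0.5, 0.5])), cfg


def test_prediction_invariant_to_permutation_and_duplication():
    rng = np.random.default_rng(5)
    model, _ = _toy_model(use_cfcm=False, use_qism=False)
    bag = make_bag("b", rng.normal(size=(6, 4)),
                   qualities=rng.uniform(0.4, 1.0, 6), label=1)
    p0 = model.predict(bag)
    assert p0.attention.min() >= 0
    assert p0.attention.sum() == pytest.approx(1.0, abs=1e-6)
    assert p0.probs.sum() == pytest.approx(1.0, abs=1e-6)

    perm = rng.permutation(6)
    shuffled = make_bag("b", bag.features[perm], bag.qualities[perm], label=1)
    p1 = model.predict(shuffled)
    np.testing.assert_allclose(p1.probs, p0.probs, atol=1e-12)
    np.testing.assert_allclose(p1.z, p0.z, atol=1e-12)

    doubled = make_bag("b", np.vstack([bag.features, bag.features]),
                       np.concatenate([bag.qualities, bag.qualities]),
                       label=1)
    p2 = model.predict(doubled)
    np.testing.assert_allclose(p2.probs, p0.probs, atol=1e-9)


def test_zero_quality_instance_contributes_nothing():
    rng = np.random.default_rng(6)
    model, _ = _toy_model(use_cfcm=False, use_qism=False, use_qam=True)
    base = rng.normal(size=(3, 4))
    bag = make_bag("b", base, qualities=[0.9, 0.8, 0.0])
    # replacing the s=0 instance's features changes nothing
    other = base.copy()
    other[2] = 100.0
    bag2 = make_bag("b", other, qualities=[0.9, 0.8, 0.0])
    np.testing.assert_allclose(model.predict(bag).probs,
                               model.predict(bag2).probs, atol=1e-12)


def test_empty_after_screening_gets_flagged_prior():
    model, _ = _toy_model()
    model.class_prior = np.array([0.7, 0.3])
    bag = make_bag("b", np.ones((2, 4)), qualities=[0.1, 0.2])  # all below 0.3
    pred = model.predict(bag)
    assert pred.empty_after_screening
    assert pred.attention.size == 0
    np.testing.assert_array_equal(pred.probs, [0.7, 0.3])


def test_prediction_feature_width_mismatch():
    model, _ = _toy_model(M=4)
    with pytest.raises(ValueError):
        model.predict(make_bag("b", np.ones((2, 5))))


# ---------------------------------------------------------------------------
# training behavior
# ---------------------------------------------------------------------------

def _small_splits(seed=42):
    sim = qcmil.SimulationConfig(n_bags=24, instances_per_bag=(15, 30),
                                 seed=seed)
    splits = qcmil.generate_splits(sim)
    return splits["train"][0], splits["test"][0]

def _small_cfg(seed=42, **mil_kw):
    cfg = RunConfig()
    return replace(cfg, mil=replace(cfg.mil, epochs=4, seed=seed, **mil_kw))


def test_training_is_bitwise_deterministic():
    tr, te = _small_splits()
    cfg = _small_cfg()
    m1, h1 = train(tr, cfg, val_cohort=te)
    m2, h2 = train(tr, cfg, val_cohort=te)
    assert h1.equals(h2)
    np.testing.assert_array_equal(m1.attn.V, m2.attn.V)
    np.testing.assert_array_equal(m1.U, m2.U)
    b = te.bags[0]
    np.testing.assert_array_equal(m1.predict(b).probs, m2.predict(b).probs)


def test_history_schema_and_loss_composition():
    tr, te = _small_splits()
    cfg = _small_cfg()
    _, h = train(tr, cfg, val_cohort=te)
    assert list(h.columns) == ["epoch", "loss", "loss_bag", "loss_supcon",
                               "val_auc"]
    assert len(h) == cfg.mil.epochs
    lam = cfg.mil.lam
    np.testing.assert_allclose(
        h["loss"], lam * h["loss_bag"] + (1 - lam) * h["loss_supcon"])
    # with the comparison stage ablated, lambda is forced to 1
    _, h0 = train(tr, replace(cfg, mil=replace(cfg.mil, use_cfcm=False)))
    assert h0["loss_supcon"].isna().all()
    np.testing.assert_allclose(h0["loss"], h0["loss_bag"])


def test_training_errors_on_single_class_and_empty():
    tr, _ = _small_splits()
    neg_only = qcmil.Cohort(bags=[b for b in tr.bags if b.label == 0],
                            C=2, M=tr.M)
    with pytest.raises(ValueError):
        train(neg_only, _small_cfg())
    with pytest.raises(ValueError):
        train(qcmil.Cohort(bags=[], C=2, M=tr.M), _small_cfg())


def test_model_round_trips_through_checkpoint(tmp_path):
    tr, te = _small_splits()
    model, _ = train(tr, _small_cfg())
    path = str(tmp_path / "model.json")
    model.save(path)
    back = qcmil.QAMILModel.load(path)
    b = te.bags[0]
    np.testing.assert_allclose(back.predict(b).probs, model.predict(b).probs,
                               atol=1e-12)


def test_learns_separable_cohort_and_attends_to_abnormal():
    """On an easy synthetic cohort the model reaches high test AUC and its
    attention concentrates on abnormal-labeled instances."""
    sim = qcmil.SimulationConfig(seed=11)
    splits = qcmil.generate_splits(sim)
    tr, te = splits["train"][0], splits["test"][0]
    cfg = replace(RunConfig(), mil=replace(RunConfig().mil, seed=11))
    model, _ = train(tr, cfg)
    auc = qcmil.roc_auc(te.labels, model.decision_scores(te))
    assert auc >= 0.9

    report = qcmil.export_attention_report(model, te)
    by_label = report.groupby("cell_label")["attention_weight"].mean()
    assert by_label["abnormal"] > by_label["normal"]
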