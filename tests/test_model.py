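"""Fusion, classification, evaluation, training behaviour."""

import numpy as np
import pytest

from ddirel import nn
from ddirel import synthetic_data as sd
from ddirel.corpus_io import LABELS
from ddirel.model import (
    DDIConfig,
    DDIModel,
    classify,
    evaluate,
    fuse,
    kfold_indices,
)

SMALL_CFG = dict(
    d=16, n_layers=1, n_heads=2, d_ff=32, d_m=8, mgnn_steps=1, epochs=2
)


# ---------------------------------------------------------------- fuse

def test_fuse_concatenation_order():
    out = fuse([1.0, 2.0], [3.0, 4.0], [5.0, 6.0], [7.0], [8.0])
    assert out.tolist() == [1, 2, 3, 4, 5, 6, 7, 8]


def test_fuse_zero_blocks():
    out = fuse(np.zeros(2), np.zeros(2), np.zeros(2), np.zeros(1), np.zeros(1))
    assert out.shape == (8,) and not out.any()


def test_fuse_round_trip_slicing(rng):
    blocks = [rng.normal(size=3), rng.normal(size=3), rng.normal(size=3),
              rng.normal(size=2), rng.normal(size=2)]
    out = fuse(*blocks)
    cuts = np.cumsum([3, 3, 3, 2])
    for got, want in zip(np.split(out, cuts), blocks):
        np.testing.assert_array_equal(got, want)


def test_fuse_shape_mismatch_names_block():
    with pytest.raises(ValueError, match="mol2"):
        fuse(np.zeros(2), np.zeros(2), np.zeros(2), np.zeros(1), np.zeros(3))


# ---------------------------------------------------------------- classify

def test_classify_uniform_for_zero_parameters():
    probs = classify(np.ones(4), np.zeros((5, 4)), np.zeros(5))
    np.testing.assert_allclose(probs, 0.2)


def test_classify_extreme_logit_is_stable():
    w = np.zeros((5, 1))
    b = np.array([1000.0, 0, 0, 0, 0])
    probs = classify(np.ones(1), w, b)
    assert probs[0] == pytest.approx(1.0)
    assert np.isfinite(probs).all()


def test_classify_matches_logsumexp_oracle(rng):
    from scipy.special import logsumexp

    h = rng.normal(size=6)
    w, b = rng.normal(size=(5, 6)) * 3, rng.normal(size=5)
    logits = w @ h + b
    expected = np.exp(logits - logsumexp(logits))
    np.testing.assert_allclose(classify(h, w, b), expected, atol=1e-10)


def test_classify_shift_invariant(rng):
    h = rng.normal(size=4)
    w, b = rng.normal(size=(5, 4)), rng.normal(size=5)
    np.testing.assert_allclose(
        classify(h, w, b), classify(h, w, b + 7.5), atol=1e-12
    )


def test_classify_rejects_nonfinite():
    with pytest.raises(ValueError, match="finite"):
        classify(np.array([np.inf]), np.ones((5, 1)), np.zeros(5))


# ---------------------------------------------------------------- evaluate

def test_evaluate_all_correct():
    gold = ["Mechanism", "Effect", "Advice", "Int", "False"]
    rep = evaluate(gold, gold)
    assert rep.micro.precision == rep.micro.recall == rep.micro.f1 == 1.0


def test_evaluate_f1_harmonic_mean():
    # 1 TP, 1 FP, 1 FN for Effect: P = R = 0.5 -> F1 = 0.5
    gold = ["Effect", "Effect", "False"]
    pred = ["Effect", "False", "Effect"]
    rep = evaluate(pred, gold)
    s = rep.per_class["Effect"]
    assert (s.precision, s.recall, s.f1) == (0.5, 0.5, 0.5)


def test_evaluate_hand_confusion_contingency_oracle(rng):
    gold = [LABELS[i] for i in rng.integers(0, 5, size=200)]
    pred = [LABELS[i] for i in rng.integers(0, 5, size=200)]
    rep = evaluate(pred, gold)
    for lab in LABELS[:4]:
        tp = sum(1 for p, g in zip(pred, gold) if p == g == lab)
        fp = sum(1 for p, g in zip(pred, gold) if p == lab != g)
        fn = sum(1 for p, g in zip(pred, gold) if g == lab != p)
        s = rep.per_class[lab]
        assert s.precision == pytest.approx(tp / (tp + fp) if tp + fp else 0.0)
        assert s.recall == pytest.approx(tp / (tp + fn) if tp + fn else 0.0)


def test_evaluate_cross_checked_against_sklearn(rng):
    from sklearn.metrics import precision_recall_fscore_support

    gold = [LABELS[i] for i in rng.integers(0, 5, size=300)]
    pred = [LABELS[i] for i in rng.integers(0, 5, size=300)]
    rep = evaluate(pred, gold)
    p, r, f1, _ = precision_recall_fscore_support(
        gold, pred, labels=list(LABELS[:4]), average="micro", zero_division=0
    )
    assert rep.micro.precision == pytest.approx(p)
    assert rep.micro.recall == pytest.approx(r)
    assert rep.micro.f1 == pytest.approx(f1)


def test_evaluate_permutation_invariant(rng):
    gold = [LABELS[i] for i in rng.integers(0, 5, size=50)]
    pred = [LABELS[i] for i in rng.integers(0, 5, size=50)]
    perm = rng.permutation(50)
    a = evaluate(pred, gold)
    b = evaluate([pred[i] for i in perm], [gold[i] for i in perm])
    assert a == b


def test_evaluate_input_validation():
    with pytest.raises(ValueError, match="length"):
        evaluate(["False"], ["False", "False"])
    with pytest.raises(ValueError, match="unknown label"):
        evaluate(["Bogus"], ["False"])


# ---------------------------------------------------------------- folds

def test_kfold_partition_properties():
    folds = kfold_indices(23, 4, seed=9)
    assert len(folds) == 4
    all_test = np.concatenate([test for _, test in folds])
    assert sorted(all_test.tolist()) == list(range(23))
    for train, test in folds:
        assert set(train) & set(test) == set()
        assert len(train) + len(test) == 23
    assert all(
        np.array_equal(a[1], b[1])
        for a, b in zip(folds, kfold_indices(23, 4, seed=9))
    )


# ---------------------------------------------------------------- training

def test_config_rejects_all_blocks_disabled():
    with pytest.raises(ValueError, match="at least one"):
        DDIConfig(use_pooled=False, use_interaction=False,
                  use_entities=False, use_molecular=False)


def test_memorise_single_instance(small_corpus):
    instances, table = small_corpus
    inst = instances[0]
    cfg = DDIConfig(**{**SMALL_CFG, "epochs": 200, "batch_size": 1,
                       "oversample_ratio": 0.0})
    model = DDIModel([inst], drug_smiles=table, config=cfg)
    result = model.fit(seed=1)
    assert result.loss_curve[-1] < 0.05
    assert result.predict([inst]) == [inst.label]


def test_fit_deterministic_given_seed(small_corpus):
    instances, table = small_corpus
    cfg = DDIConfig(**SMALL_CFG)
    r1 = DDIModel(instances[:30], drug_smiles=table, config=cfg).fit(seed=5)
    r2 = DDIModel(instances[:30], drug_smiles=table, config=cfg).fit(seed=5)
    assert r1.loss_curve == r2.loss_curve


def test_gradient_check_classifier_parameters(small_corpus):
    """Finite-difference gradients of the batch loss agree with autodiff."""
    instances, table = small_corpus
    cfg = DDIConfig(**SMALL_CFG)
    model = DDIModel(instances[:4], drug_smiles=table, config=cfg)
    model._initialise(seed=0)
    batch = instances[:2]
    labels = [LABELS.index(i.label) for i in batch]

    def loss_value():
        losses = [
            nn.cross_entropy_logits(model._forward(inst), lab)
            for inst, lab in zip(batch, labels)
        ]
        return nn.concat([l.reshape(1) for l in losses]).mean()

    w = model.heads["w_cls"]
    loss = loss_value()
    w.grad = None
    loss.backward()
    analytic = w.grad.copy()
    eps = 1e-6
    rng = np.random.default_rng(0)
    for _ in range(10):
        idx = (int(rng.integers(w.shape[0])), int(rng.integers(w.shape[1])))
        orig = w.data[idx]
        w.data[idx] = orig + eps
        hi = float(loss_value().data)
        w.data[idx] = orig - eps
        lo = float(loss_value().data)
        w.data[idx] = orig
        numeric = (hi - lo) / (2 * eps)
        assert analytic[idx] == pytest.approx(numeric, abs=1e-4)


def test_empty_training_set_rejected():
    with pytest.raises(ValueError, match="empty"):
        DDIModel([])


def test_predict_proba_normalised(small_corpus):
    instances, table = small_corpus
    cfg = DDIConfig(**SMALL_CFG)
    res = DDIModel(instances[:20], drug_smiles=table, config=cfg).fit(seed=0)
    probs = res.predict_proba(instances[20:30])
    assert probs.shape == (10, 5)
    np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
    assert np.all(probs >= 0)


def test_summary_mentions_blocks_and_metrics(small_corpus):
    instances, table = small_corpus
    cfg = DDIConfig(**SMALL_CFG)
    res = DDIModel(instances[:20], drug_smiles=table, config=cfg).fit(seed=0)
    text = res.summary(instances[20:30])
    assert "feature blocks" in text and "micro" in text


def test_ablation_variant_equals_default_model(small_corpus):
    """The 'full' ablation variant is the default model bit-for-bit."""
    from ddirel.model import ablate

    instances, table = small_corpus
    cfg = DDIConfig(**SMALL_CFG)
    reports = ablate(
        instances[:30], instances[30:45], drug_smiles=table, config=cfg,
        variants={"full": {}}, seeds=(3,),
    )
    direct = DDIModel(instances[:30], drug_smiles=table, config=cfg).fit(seed=3)
    assert reports["full"][0] == direct.evaluate(instances[30:45])
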