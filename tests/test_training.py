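"""Training loop, folds, regularizers, personalization noise."""

from __future__ import annotations

import numpy as np
import pytest

from stagernet import (
    SleepStage,
    StagerConfig,
    TrainConfig,
    generate_cohort,
    make_cv_folds,
    perturb_demographics,
    train_single,
    train_stager,
)
from stagernet._nn import Adam, masked_cross_entropy
from stagernet.architecture import StagerModel
from stagernet.training import FoldSplit, audit_fold_isolation, regularization_terms


# ---------------------------------------------------------------------------
# folds
# ---------------------------------------------------------------------------


def test_three_subjects_three_singletons():
    folds = make_cv_folds(["a", "b", "c"], np.random.default_rng(0))
    assert sorted(len(g) for g in folds.groups) == [1, 1, 1]


def test_29_subjects_group_sizes():
    ids = [f"s{i}" for i in range(29)]
    folds = make_cv_folds(ids, np.random.default_rng(0))
    assert sorted(len(g) for g in folds.groups) == [9, 10, 10]


def test_every_subject_validates_exactly_once():
    ids = [f"s{i}" for i in range(10)]
    folds = make_cv_folds(ids, np.random.default_rng(1))
    seen = []
    for k in range(folds.n_folds):
        train, val = folds.fold(k)
        assert set(train).isdisjoint(val)
        assert sorted(train + val) == sorted(ids)
        seen.extend(val)
    assert sorted(seen) == sorted(ids)


def test_too_few_subjects():
    with pytest.raises(ValueError):
        make_cv_folds(["a", "b"], np.random.default_rng(0))


def test_foldsplit_validation():
    with pytest.raises(ValueError):
        FoldSplit(groups=[["a", "b", "c"], ["d"], ["e"]])  # sizes differ > 1
    with pytest.raises(ValueError):
        FoldSplit(groups=[["a"], ["a"], ["b"]])  # overlap


def test_audit_fold_isolation():
    cohort = generate_cohort(2, 1, 0.25, rng_seed=0)
    with pytest.raises(ValueError):
        audit_fold_isolation(cohort, cohort)


# ---------------------------------------------------------------------------
# demographics noise
# ---------------------------------------------------------------------------


def test_perturb_noop():
    rng = np.random.default_rng(0)
    assert perturb_demographics(40.0, 1, 0.0, 0.0, rng) == (40.0, 1)


def test_perturb_gender_always_masked_at_p1():
    rng = np.random.default_rng(0)
    for _ in range(20):
        assert perturb_demographics(40.0, -1, 0.0, 1.0, rng)[1] == 0


def test_perturb_age_noise_sd():
    rng = np.random.default_rng(0)
    deltas = [perturb_demographics(40.0, 1, 5.0, 0.0, rng)[0] - 40.0
              for _ in range(10_000)]
    assert 4.8 <= np.std(deltas) <= 5.2


def test_perturb_validation():
    rng = np.random.default_rng(0)
    with pytest.raises(ValueError):
        perturb_demographics(40.0, 2, 0.0, 0.0, rng)
    with pytest.raises(ValueError):
        perturb_demographics(40.0, 1, -1.0, 0.0, rng)
    with pytest.raises(ValueError):
        perturb_demographics(40.0, 1, 0.0, 1.5, rng)


# ---------------------------------------------------------------------------
# regularizers
# ---------------------------------------------------------------------------


def _tiny_model(**kw):
    cfg = StagerConfig(n_conv_layers=1, conv_filters=(2,), units_per_layer=4,
                       window_samples=64, **kw)
    return StagerModel(cfg, seed=0)


def test_no_penalties_no_terms():
    loss, grads = regularization_terms(_tiny_model())
    assert loss == 0.0 and grads == {}


def test_l2_closed_form():
    lam = 0.01
    model = _tiny_model(l2_conv=lam)
    w = model.params["conv0_W"]
    loss, grads = regularization_terms(model)
    assert loss == pytest.approx(lam * np.sum(w * w))
    np.testing.assert_allclose(grads["conv0_W"], 2 * lam * w)
    assert "conv0_b" not in grads  # biases are never penalized


def test_l1_closed_form_on_recurrent_kernels():
    lam = 0.02
    model = _tiny_model(l1_rec=lam)
    loss, grads = regularization_terms(model)
    expected = lam * sum(
        np.sum(np.abs(model.params[f"{n}_{s}"]))
        for n in model.recurrent_layer_names() for s in ("Wx", "Wh")
    )
    assert loss == pytest.approx(expected)
    np.testing.assert_allclose(grads["rec0_Wx"],
                               lam * np.sign(model.params["rec0_Wx"]))


def test_dropout_off_at_inference():
    model = _tiny_model(dropout_forward=0.3, dropout_recurrent=0.2)
    X = np.random.default_rng(0).normal(0, 20, (2, 3, 64))
    a = model.forward_sequence(X)  # no dropout_rng -> deterministic
    b = model.forward_sequence(X)
    np.testing.assert_array_equal(a, b)


def test_dropout_active_with_rng():
    model = _tiny_model(dropout_forward=0.5)
    X = np.random.default_rng(0).normal(0, 20, (2, 3, 64))
    a = model.forward_sequence(X, dropout_rng=np.random.default_rng(1))
    b = model.forward_sequence(X, dropout_rng=np.random.default_rng(2))
    assert np.max(np.abs(a - b)) > 0


# ---------------------------------------------------------------------------
# loss and optimizer
# ---------------------------------------------------------------------------


def test_masked_loss_all_unknown_is_zero():
    rng = np.random.default_rng(0)
    probs = rng.dirichlet(np.ones(5), size=(2, 4))
    labels = np.full((2, 4), int(SleepStage.UNKNOWN))
    mask = np.zeros((2, 4))
    loss, dlogits = masked_cross_entropy(probs, labels, mask)
    assert loss == 0.0
    np.testing.assert_array_equal(dlogits, np.zeros_like(probs))


def test_masked_loss_matches_hand_computation():
    probs = np.array([[[0.2, 0.5, 0.1, 0.1, 0.1]]])
    labels = np.array([[1]])
    mask = np.ones((1, 1))
    loss, dlogits = masked_cross_entropy(probs, labels, mask)
    assert loss == pytest.approx(-np.log(0.5))
    np.testing.assert_allclose(dlogits[0, 0],
                               probs[0, 0] - np.array([0, 1, 0, 0, 0]))


def test_adam_first_step_magnitude():
    params = {"w": np.array([10.0])}
    opt = Adam(params, lr=0.001)
    opt.step(params, {"w": np.array([4.0])})  # gradient of (w-8)^2 at 10
    # bias-corrected first step has magnitude ~= lr regardless of gradient size
    assert params["w"][0] == pytest.approx(10.0 - 0.001, abs=1e-6)


def test_adam_decay_shrinks_rate():
    a = {"w": np.array([1.0])}
    b = {"w": np.array([1.0])}
    Adam(a, lr=0.1, decay=0.0).step(a, {"w": np.array([1.0])})
    opt = Adam(b, lr=0.1, decay=1.0)
    opt.step(b, {"w": np.array([1.0])})
    assert abs(1.0 - b["w"][0]) <= abs(1.0 - a["w"][0])


# ---------------------------------------------------------------------------
# train_single / train_stager
# ---------------------------------------------------------------------------

_DESK = dict(n_conv_layers=2, conv_filters=(4, 8), units_per_layer=8)


def _mini_data(n_subjects=3, hours=0.25, seed=0):
    return generate_cohort(n_subjects, 1, hours, rng_seed=seed)


def test_zero_epochs_returns_initialization():
    cfg = StagerConfig(**_DESK)
    tcfg = TrainConfig(n_epochs=0, batch_size=2, seq_len_windows=4,
                       batches_per_epoch=1, seed=3)
    data = _mini_data()
    model, curves = train_single(cfg, tcfg, data, seed=3)
    # re-derive the init the trainer used (same seed fan-out)
    ss = np.random.SeedSequence(3)
    init_ss = ss.spawn(4)[0]
    fresh = StagerModel(cfg, seed=int(init_ss.generate_state(1)[0] % (2**31)))
    for k in model.params:
        np.testing.assert_array_equal(model.params[k], fresh.params[k])
    assert curves.train_loss == []


def test_training_reproducible():
    cfg = StagerConfig(**_DESK)
    tcfg = TrainConfig(n_epochs=2, batch_size=2, seq_len_windows=4,
                       batches_per_epoch=2, seed=5)
    data = _mini_data(seed=1)
    _, c1 = train_single(cfg, tcfg, data, data, seed=5)
    _, c2 = train_single(cfg, tcfg, data, data, seed=5)
    np.testing.assert_allclose(c1.train_loss, c2.train_loss, atol=1e-12)
    np.testing.assert_allclose(c1.val_kappa, c2.val_kappa, atol=1e-4)


def test_loss_decreases_during_training():
    cfg = StagerConfig(**_DESK)
    tcfg = TrainConfig(n_epochs=8, batch_size=4, seq_len_windows=8,
                       batches_per_epoch=2, seed=0, eval_every=8)
    data = _mini_data(seed=2)
    _, curves = train_single(cfg, tcfg, data, seed=0)
    assert np.mean(curves.train_loss[-2:]) < np.mean(curves.train_loss[:2])


def test_overfit_single_recording():
    """Memorization sanity: a reduced model driven onto one short recording
    reaches high training Kappa (deterministic run scores 0.92)."""
    data = [_mini_data(n_subjects=1, hours=0.5, seed=4)[0]]
    cfg = StagerConfig(**_DESK)
    tcfg = TrainConfig(n_epochs=400, batch_size=4, seq_len_windows=8,
                       batches_per_epoch=2, seed=1, eval_every=400,
                       learning_rate=0.005)
    _, curves = train_single(cfg, tcfg, data, seed=1)
    assert curves.train_kappa[-1] >= 0.9


def test_train_stager_runs_requested_fold_with_isolation():
    data = _mini_data(n_subjects=3, seed=3)
    cfg = StagerConfig(**_DESK)
    tcfg = TrainConfig(n_epochs=1, batch_size=2, seq_len_windows=2,
                       batches_per_epoch=1, seed=0)
    results = train_stager(cfg, tcfg, data, fold_indices=[0])
    assert len(results) == 1
    model, curves = results[0]
    assert len(curves.train_loss) == 1
    assert np.isfinite(curves.val_kappa[-1])


def test_eval_every_skips_with_nan():
    data = _mini_data(seed=5)
    cfg = StagerConfig(**_DESK)
    tcfg = TrainConfig(n_epochs=3, batch_size=2, seq_len_windows=2,
                       batches_per_epoch=1, seed=0, eval_every=3)
    _, curves = train_single(cfg, tcfg, data, data, seed=0)
    assert np.isnan(curves.train_kappa[0]) and np.isnan(curves.train_kappa[1])
    assert np.isfinite(curves.train_kappa[2])
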