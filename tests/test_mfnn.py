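"""Fuzzy neural network: memberships, forward pass, gradients, training, risk."""

import numpy as np
import pandas as pd
import pytest

from pdpipe import (
    FuzzySet,
    SyntheticSpec,
    TrainState,
    assign_risk,
    forward,
    generate_pd_dataset,
    init_model,
    membership,
    predict,
    preprocess,
    split_dataset,
    train,
    update_weights,
)
from pdpipe.errors import ConfigError, ContractError, TrainingError
from pdpipe.io import SplitSpec
from pdpipe.mfnn import (
    PARAM_KEYS,
    cross_entropy,
    loss_and_gradients,
)


def test_membership_closed_forms():
    """mu = 1 at the center, exp(-1/2) one width away, symmetric around it."""
    fs = FuzzySet(center=0.4, width=0.2)
    assert membership(0.4, fs) == 1.0
    assert membership(0.6, fs) == pytest.approx(np.exp(-0.5), abs=1e-12)
    assert membership(0.6, fs) == pytest.approx(0.606531, abs=1e-6)
    for delta in (0.05, 0.13, 0.4):
        assert membership(0.4 + delta, fs) == pytest.approx(
            membership(0.4 - delta, fs), abs=1e-15
        )
    with pytest.raises(ContractError):
        FuzzySet(center=0.0, width=0.0)


def brute_force_forward(model, x):
    """Straight-line scalar oracle for the four layers (product t-norm)."""
    mus = np.array(
        [
            [
                np.exp(-((x[j] - model.centers[r, j]) ** 2)
                       / (2 * model.widths[r, j] ** 2))
                for j in range(model.n_features)
            ]
            for r in range(model.n_rules)
        ]
    )
    w = mus.prod(axis=1)
    g = w / w.sum()
    rule_out = np.array(
        [model.coefs[r] @ x + model.biases[r] for r in range(model.n_rules)]
    )
    s = g * rule_out
    logits = model.head_w @ s + model.head_b
    e = np.exp(logits - logits.max())
    return e / e.sum()


def _random_model(seed=0, n_rules=3, d=2, n=30):
    rng = np.random.default_rng(seed)
    X = rng.uniform(0, 1, (n, d))
    y = rng.integers(0, 2, n)
    m = init_model(X, y, n_rules=n_rules, seed=seed)
    m.coefs = rng.normal(0, 0.5, m.coefs.shape)
    m.biases = rng.normal(0, 0.5, m.biases.shape)
    return m, X, y


def test_forward_matches_brute_force_oracle():
    """Vectorized forward equals the scalar four-layer oracle to 1e-10."""
    model, X, _ = _random_model(seed=4)
    probs, _ = forward(model, X)
    for i in range(len(X)):
        assert np.allclose(probs[i], brute_force_forward(model, X[i]), atol=1e-10)


def test_forward_probabilities_sum_to_one():
    model, X, _ = _random_model(seed=9, n_rules=4, d=3)
    probs, w = forward(model, X)
    assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-12)
    assert (w > 0).all() and (w <= 1.0).all()


def test_forward_symmetric_model_gives_half():
    """Zero consequents and a zero class head make every output [0.5, 0.5]."""
    model, X, y = _random_model(seed=1)
    model.coefs[:] = 0.0
    model.biases[:] = 0.0
    model.head_b[:] = 0.0
    probs, _ = forward(model, X)
    assert np.allclose(probs, 0.5, atol=1e-12)


def test_forward_arity_mismatch():
    model, _, _ = _random_model()
    with pytest.raises(ContractError):
        forward(model, np.zeros((4, 5)))


def test_init_centers_near_class_centroids(toy_norm):
    """With one rule per class, centers sit at the class medians."""
    X = toy_norm.values[["PPE", "spread1"]]
    model = init_model(X, toy_norm.labels, n_rules=2, seed=0)
    for cls, r in ((0, 0), (1, 1)):
        med = X[toy_norm.labels == cls].median().to_numpy()
        assert np.allclose(model.centers[r], med, atol=1e-12)
    assert (model.widths >= 0.05).all()


def test_init_determinism_and_errors(toy_norm):
    X = toy_norm.values[["PPE", "spread1"]]
    a = init_model(X, toy_norm.labels, n_rules=4, seed=3)
    b = init_model(X, toy_norm.labels, n_rules=4, seed=3)
    assert a.to_json() == b.to_json()
    with pytest.raises(ConfigError):
        init_model(X, toy_norm.labels, n_rules=100, seed=0)


def test_gradients_match_finite_differences():
    """Analytic gradients vs central differences, every parameter group."""
    model, X, y = _random_model(seed=3, n_rules=2, d=2, n=12)
    _, grads = loss_and_gradients(model, X, y)
    eps = 1e-6
    for key in PARAM_KEYS:
        arr = getattr(model, key)
        it = np.nditer(arr, flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            orig = arr[i]
            arr[i] = orig + eps
            lp = cross_entropy(model, X, y)
            arr[i] = orig - eps
            lm = cross_entropy(model, X, y)
            arr[i] = orig
            fd = (lp - lm) / (2 * eps)
            denom = max(abs(fd), abs(grads[key][i]), 1e-8)
            assert abs(grads[key][i] - fd) / denom < 1e-4, key


def test_momentum_update_hand_arithmetic():
    """Two steps on L = (w-2)^2/2 match pencil-and-paper momentum math."""
    state = TrainState(learning_rate=0.5, momentum=0.9)
    w = np.array([0.0])
    w = update_weights(state, "w", w, gradient=w - 2.0)  # grad = -2
    assert w[0] == pytest.approx(1.0, abs=1e-15)  # -0.5*(-2) + 0.9*0
    w = update_weights(state, "w", w, gradient=w - 2.0)  # grad = -1
    assert w[0] == pytest.approx(2.4, abs=1e-15)  # 1 + (0.5 + 0.9*1)


def test_zero_gradient_zero_momentum_is_fixed_point():
    state = TrainState(learning_rate=0.6, momentum=0.9)
    w = np.array([1.5])
    out = update_weights(state, "w", w, gradient=np.zeros(1))
    assert out[0] == 1.5


def test_update_rejects_nonfinite_gradient():
    state = TrainState()
    with pytest.raises(TrainingError):
        update_weights(state, "w", np.ones(1), np.array([np.nan]))


def test_learning_rate_range_accepted_quietly():
    import warnings

    from pdpipe import RunConfig

    for tau in (0.4, 0.6, 0.8):
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            RunConfig(learning_rate=tau)


def test_single_epoch_descends_on_fixture(toy_norm):
    """One full-batch step does not increase the training loss."""
    X = toy_norm.values[["PPE", "spread1"]]
    model = init_model(X, toy_norm.labels, n_rules=2, seed=0)
    before = cross_entropy(model, X.to_numpy(), toy_norm.labels)
    trained, history = train(
        model, X, toy_norm.labels, state=TrainState(), epochs=1
    )
    assert history["train_loss"][0] == pytest.approx(before, abs=1e-12)
    assert history["final_train_loss"] <= before + 1e-12


def test_training_learns_separable_1d():
    """One-feature training: separable classes (d=6, negligible overlap)
    reach >= 0.95 train accuracy in >= 9/10 seeds; overlapping classes
    (d=3, Bayes accuracy ~93%) still land within 4 points of Bayes."""
    for effect, floor, need in ((6.0, 0.95, 9), (3.0, 0.893, 9)):
        wins = 0
        for seed in range(10):
            table, _ = generate_pd_dataset(
                SyntheticSpec(n_rows=200, n_informative=1, n_noise=0,
                              effect_size=effect, seed=seed,
                              feature_name_style="generic")
            )
            norm, _ = preprocess(table)
            model = init_model(norm.values, norm.labels, n_rules=2, seed=seed)
            model, _ = train(model, norm.values, norm.labels,
                             state=TrainState(), epochs=200)
            _, pred, _ = predict(model, norm.values)
            wins += (pred == norm.labels).mean() >= floor
        assert wins >= need, f"effect={effect}: {wins}/10"


def test_training_permutation_consistency():
    """Full-batch training is invariant to the order of the training rows."""
    table, _ = generate_pd_dataset(SyntheticSpec(n_rows=80, seed=2))
    norm, _ = preprocess(table)
    X = norm.values[["PPE", "spread1"]]
    perm = np.random.default_rng(0).permutation(len(X))
    m1 = init_model(X, norm.labels, n_rules=2, seed=1)
    m2 = init_model(X.iloc[perm], norm.labels[perm], n_rules=2, seed=1)
    t1, _ = train(m1, X, norm.labels, state=TrainState(), epochs=20)
    t2, _ = train(m2, X.iloc[perm], norm.labels[perm], state=TrainState(), epochs=20)
    assert np.allclose(t1.coefs, t2.coefs, atol=1e-9)
    assert np.allclose(t1.centers, t2.centers, atol=1e-9)


def test_model_json_roundtrip():
    from pdpipe.mfnn import MFNNModel

    model, _, _ = _random_model(seed=8)
    back = MFNNModel.from_json(model.to_json())
    for key in PARAM_KEYS:
        assert np.array_equal(getattr(model, key), getattr(back, key))
    assert back.feature_names == model.feature_names


@pytest.mark.parametrize(
    "p,expected",
    [(0.0, "low"), (0.32, "low"), (0.33, "medium"), (0.5, "medium"),
     (0.66, "high"), (1.0, "high")],
)
def test_assign_risk_piecewise(p, expected):
    r = assign_risk(p)
    assert r.risk_class == expected
    assert r.predicted_label == int(p >= 0.5)


def test_assign_risk_bad_thresholds():
    with pytest.raises(ConfigError):
        assign_risk(0.5, thresholds=(0.7, 0.3))
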