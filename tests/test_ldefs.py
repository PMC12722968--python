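"""Entropy, information gain, logistic scoring, selection, MI ordering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pdpipe import (
    entropy,
    finest_subset,
    information_gain,
    ldefs_select,
    logistic_decision_scores,
    mutual_information,
    select_features,
)
from pdpipe.errors import ContractError
from pdpipe.ldefs import compute_gains, equal_frequency_bins


def brute_force_ig(values, labels, n_bins):
    """Oracle: IG from the explicit joint count table."""
    codes = equal_frequency_bins(values, n_bins)
    n = len(labels)

    def h(v):
        _, c = np.unique(v, return_counts=True)
        p = c / len(v)
        return -(p * np.log2(p)).sum()

    cond = sum(
        (codes == b).sum() / n * h(np.asarray(labels)[codes == b])
        for b in np.unique(codes)
    )
    return h(labels) - cond


def test_entropy_closed_forms():
    """1 bit at 50/50, 0 at purity, 0.811278 bits at 75/25."""
    assert entropy([0, 1, 0, 1]) == pytest.approx(1.0, abs=1e-15)
    assert entropy([1, 1, 1]) == 0.0
    assert entropy([0, 0, 0, 1]) == pytest.approx(0.8112781244591328, abs=1e-12)
    with pytest.raises(ContractError):
        entropy([])


@given(st.lists(st.integers(0, 1), min_size=1, max_size=200))
@settings(max_examples=50, deadline=None)
def test_entropy_bounds(labels):
    h = entropy(labels)
    assert 0.0 <= h <= 1.0 + 1e-12


def test_ig_perfect_predictor():
    """A feature that copies the label gains exactly H(Y)."""
    labels = np.array([0, 1] * 20)
    ig = information_gain(labels.astype(float), labels, n_bins=2)
    assert ig == pytest.approx(entropy(labels), abs=1e-12)


def test_ig_independent_feature_near_zero():
    """An independent feature at n=2000 gains < 0.02 bits (finite-sample bias)."""
    rng = np.random.default_rng(5)
    labels = rng.integers(0, 2, 2000)
    feature = rng.standard_normal(2000)
    assert information_gain(feature, labels, n_bins=10) < 0.02


def test_ig_constant_feature_zero():
    assert information_gain(np.ones(20), np.tile([0, 1], 10)) == 0.0


def test_ig_matches_brute_force_on_fixture(toy_norm):
    """IG equals the joint-count oracle on the 12-row fixture to 1e-12."""
    for name in toy_norm.feature_names:
        mine = information_gain(toy_norm.values[name], toy_norm.labels, n_bins=4)
        oracle = brute_force_ig(toy_norm.values[name], toy_norm.labels, n_bins=4)
        assert mine == pytest.approx(oracle, abs=1e-12)


def test_ig_bounded_by_label_entropy(toy_norm):
    h_y = entropy(toy_norm.labels)
    for name in toy_norm.feature_names:
        ig = information_gain(toy_norm.values[name], toy_norm.labels)
        assert 0.0 <= ig <= h_y + 1e-12


def test_ig_monotone_transform_invariance():
    """Equal-frequency binning makes IG blind to monotone feature transforms."""
    rng = np.random.default_rng(11)
    labels = rng.integers(0, 2, 300)
    x = rng.uniform(0.1, 5.0, 300) + labels
    for f in (np.log, np.sqrt, lambda v: v**3):
        assert information_gain(f(x), labels) == pytest.approx(
            information_gain(x, labels), abs=1e-12
        )


def test_mi_agrees_with_sklearn_and_ig(toy_norm):
    """Joint-count MI = binning IG = sklearn's MI (nats -> bits) per feature."""
    from sklearn.metrics import mutual_info_score

    for name in toy_norm.feature_names:
        codes = equal_frequency_bins(toy_norm.values[name], 4)
        mi = mutual_information(toy_norm.values[name], toy_norm.labels, n_bins=4)
        ig = information_gain(toy_norm.values[name], toy_norm.labels, n_bins=4)
        skl = mutual_info_score(codes, toy_norm.labels) / np.log(2)
        assert mi == pytest.approx(ig, abs=1e-12)
        assert mi == pytest.approx(skl, abs=1e-10)


def _gain_frame(gains: dict) -> pd.DataFrame:
    return pd.DataFrame({"H_y": 1.0, "G_Infor": pd.Series(gains)})


def test_logistic_scores_all_equal_gains():
    scores = logistic_decision_scores(_gain_frame({"a": 0.4, "b": 0.4, "c": 0.4}))
    assert (scores.table["P"] == 0.5).all()


def test_logistic_scores_standardization():
    """Gains {0.9,0.1,0.1,0.1}: top z = sqrt(3) under population SD."""
    scores = logistic_decision_scores(
        _gain_frame({"a": 0.9, "b": 0.1, "c": 0.1, "d": 0.1})
    )
    # oracle: z = 0.6 / sqrt(0.12) = sqrt(3); sigma(sqrt(3)) = 0.8496745530898385
    assert scores.table.loc["a", "P"] == pytest.approx(0.8496745530898385, abs=1e-12)
    assert scores.table["P"].idxmax() == "a"


def test_logistic_scores_monotone_in_gain():
    rng = np.random.default_rng(2)
    gains = {f"f{i}": g for i, g in enumerate(rng.uniform(0, 1, 10))}
    scores = logistic_decision_scores(_gain_frame(gains)).table
    order_g = scores["G_Infor"].sort_values().index
    assert list(scores["P"].sort_values().index) == list(order_g)


def test_select_threshold_and_fallback():
    """All P < threshold triggers the deterministic top-k_min fallback."""
    scores = logistic_decision_scores(
        _gain_frame({"a": 0.50, "b": 0.45, "c": 0.40, "d": 0.35, "e": 0.10, "f": 0.05})
    )
    out = select_features(scores, threshold=0.85, k_min=4)
    assert out.fallback_used
    assert out.selected == ["a", "b", "c", "d"]


def test_select_brute_force_equivalence(toy_norm):
    """Selection equals a brute-force filter over the score list."""
    gains = compute_gains(toy_norm, n_bins=4)
    scores = logistic_decision_scores(gains)
    for threshold in (0.3, 0.6, 0.85):
        out = select_features(scores, threshold=threshold, k_min=1)
        if not out.fallback_used:
            expect = sorted(
                n for n in scores.table.index
                if scores.table.at[n, "P"] >= threshold
            )
            assert sorted(out.selected) == expect


def test_select_tie_break_by_name():
    scores = logistic_decision_scores(
        _gain_frame({"zed": 0.4, "abc": 0.4, "mid": 0.1})
    )
    out = select_features(scores, threshold=0.99, k_min=1)
    assert out.selected == ["abc"]  # equal P, ascending-name tiebreak


def test_finest_subset_ordering(toy_norm):
    """f_b sorts by MI descending and matches the IG ordering."""
    sub = finest_subset(
        toy_norm.feature_names, toy_norm.values, toy_norm.labels, n_bins=4
    )
    assert list(sub.mi_values.index) == sub.f_b
    assert (sub.mi_values.diff().dropna() <= 1e-12).all()
    single = finest_subset(["PPE"], toy_norm.values, toy_norm.labels, n_bins=4)
    assert single.f_b == ["PPE"]


def test_ldefs_recovers_planted_features():
    """4 planted d=2 features land in f_b's top 4 (>=3 of 4) in >=90% of seeds."""
    hits = 0
    n_seeds = 25
    for seed in range(n_seeds):
        from pdpipe import SyntheticSpec, generate_pd_dataset, preprocess

        table, truth = generate_pd_dataset(
            SyntheticSpec(n_rows=500, n_informative=4, n_noise=18,
                          effect_size=2.0, seed=seed)
        )
        norm, _ = preprocess(table)
        _, sub = ldefs_select(norm, threshold=0.85, k_min=4)
        overlap = len(set(sub.f_b[:4]) & set(truth["informative_features"]))
        hits += overlap >= 3
    assert hits >= int(np.ceil(0.9 * n_seeds))
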