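"""Logistic-decision feature selection on information gain.

Each feature is discretized into equal-frequency bins and scored by the
information gain it provides about the PD label,

    IG(X; Y) = H(Y) - sum_b (n_b / N) H(Y | bin b)     (bits),

the gains are standardized across features and squashed through a sigmoid
into a score P in (0,1), and features with P at or above a threshold
(default 0.85, i.e. a gain well above the across-feature mean) are selected.
A top-k fallback guarantees a non-empty selection.  The selected features
are finally ordered by mutual information with the label — estimated from
the joint bin/label count table, a deliberately separate route that must
agree with the gain — giving the "finest subset" f_b fed to the classifier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ContractError
from .preprocessing import NormalizedDataset

logger = logging.getLogger("pdpipe")


def entropy(labels) -> float:
    """Shannon entropy of a label vector in bits, with 0*log0 = 0."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ContractError("entropy of an empty label vector")
    _, counts = np.unique(labels, return_counts=True)
    p = counts / labels.size
    return float(-(p * np.log2(p)).sum())


def equal_frequency_bins(values, n_bins: int) -> np.ndarray:
    """Bin indices from equal-frequency (quantile) discretization.

    A feature with at most ``n_bins`` distinct values is binned by value
    (quantile edges on heavily tied data can collapse informative levels
    into one bin — e.g. a binary feature with a 2:1 imbalance has its
    median at the majority value).  Otherwise duplicate quantile edges
    collapse, so a constant feature lands in a single bin.  Invariant to
    strictly monotone transforms up to ties.
    """
    if n_bins < 2:
        raise ContractError("n_bins must be >= 2")
    values = np.asarray(values, dtype=float)
    if np.isnan(values).any():
        raise ContractError("binning requires complete (preprocessed) values")
    distinct = np.unique(values)
    if len(distinct) <= n_bins:
        return np.searchsorted(distinct, values).astype(int)
    codes = pd.qcut(values, q=n_bins, labels=False, duplicates="drop")
    codes = np.asarray(codes)
    if np.isnan(codes).any():  # all values identical: qcut yields no bins
        return np.zeros(len(values), dtype=int)
    return codes.astype(int)


def _conditional_entropy(bin_codes: np.ndarray, labels: np.ndarray) -> float:
    n = len(labels)
    h = 0.0
    for b in np.unique(bin_codes):
        in_bin = labels[bin_codes == b]
        h += (len(in_bin) / n) * entropy(in_bin)
    return h


def information_gain(values, labels, n_bins: int = 10) -> float:
    """IG of a discretized feature about the label, in bits.

    Always within [0, H(Y)]; a constant feature gains nothing.
    """
    labels = np.asarray(labels)
    codes = equal_frequency_bins(values, n_bins)
    ig = entropy(labels) - _conditional_entropy(codes, labels)
    return max(ig, 0.0)  # clamp -0.0 / rounding dust


def mutual_information(values, labels, n_bins: int = 10) -> float:
    """MI(feature; label) in bits from the joint bin/label count table.

    Same discretization as :func:`information_gain`; estimated from joint
    counts, sum_{x,y} p(x,y) log2 p(x,y)/(p(x)p(y)), so the two estimators
    must agree — a cheap internal consistency check.
    """
    labels = np.asarray(labels)
    codes = equal_frequency_bins(values, n_bins)
    joint = pd.crosstab(codes, labels).to_numpy().astype(float)
    joint /= joint.sum()
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = joint * np.log2(joint / (px * py))
    return float(max(np.nansum(terms), 0.0))


@dataclass
class GainTable:
    """Per-feature entropy/gain/logistic-score table with selection flags."""

    table: pd.DataFrame  # columns: H_y, G_Infor, P, selected
    h_y: float
    threshold: float | None = None
    fallback_used: bool = False

    @property
    def selected(self) -> list[str]:
        sel = self.table[self.table["selected"]]
        return list(sel.index)


def compute_gains(norm: NormalizedDataset, n_bins: int = 10) -> pd.DataFrame:
    """Label entropy and per-feature information gain for every feature."""
    labels = np.asarray(norm.labels)
    h_y = entropy(labels)
    gains = {
        name: information_gain(norm.values[name], labels, n_bins)
        for name in norm.values.columns
    }
    return pd.DataFrame({"H_y": h_y, "G_Infor": pd.Series(gains)})


def logistic_decision_scores(gains: pd.DataFrame) -> GainTable:
    """Sigmoid of the across-feature standardized gain.

    P_j = sigma((G_j - mean G) / popSD(G)); monotone in the gain, and when
    every gain is equal (SD = 0) all scores are exactly 0.5.
    """
    if len(gains) < 2:
        raise ContractError("logistic scoring needs >= 2 features")
    g = gains["G_Infor"]
    sd = float(g.std(ddof=0))
    # tolerance: identical gains leave float dust in the SD (~1e-17)
    degenerate = sd <= 1e-12 * max(1.0, float(g.abs().max()))
    z = pd.Series(0.0, index=g.index) if degenerate else (g - g.mean()) / sd
    p = 1.0 / (1.0 + np.exp(-z))
    table = gains.copy()
    table["P"] = p
    table["selected"] = False
    return GainTable(table=table, h_y=float(gains["H_y"].iloc[0]))


def select_features(
    scores: GainTable, threshold: float = 0.85, k_min: int = 4
) -> GainTable:
    """Keep features with P >= threshold; fall back to the top k_min.

    Ties break deterministically by (P descending, name ascending).  If
    fewer than ``k_min`` features pass the threshold, the top ``k_min`` by
    score are selected instead and the fallback is recorded.
    """
    if not 0.0 < threshold < 1.0:
        raise ContractError("threshold must be in (0,1)")
    if k_min < 1:
        raise ContractError("k_min must be >= 1")
    table = scores.table.copy()
    # stable sort after a name pre-sort gives the (P desc, name asc) tiebreak
    order = table.sort_index(kind="mergesort").sort_values(
        by="P", ascending=False, kind="mergesort"
    )
    passed = [name for name in order.index if order.at[name, "P"] >= threshold]
    fallback = len(passed) < k_min
    chosen = list(order.index[: min(k_min, len(order))]) if fallback else passed
    table["selected"] = table.index.isin(chosen)
    if fallback:
        logger.info(
            "LDEFS: %d feature(s) passed threshold %.2f; top-%d fallback used",
            len(passed), threshold, k_min,
        )
    return GainTable(
        table=table, h_y=scores.h_y, threshold=threshold, fallback_used=fallback
    )


@dataclass
class FinestSubset:
    """Selected features ordered by mutual information with the label."""

    f_b: list[str]
    mi_values: pd.Series


def finest_subset(
    selected: list[str],
    values: pd.DataFrame,
    labels,
    n_bins: int = 10,
) -> FinestSubset:
    """Order the selected features by descending MI with the label."""
    if not selected:
        raise ContractError("finest_subset needs >= 1 selected feature")
    labels = np.asarray(labels)
    mi = pd.Series(
        {name: mutual_information(values[name], labels, n_bins) for name in selected}
    )
    ordered = mi.sort_index(kind="mergesort").sort_values(
        ascending=False, kind="mergesort"
    )
    return FinestSubset(f_b=list(ordered.index), mi_values=ordered)


def ldefs_select(
    norm: NormalizedDataset,
    n_bins: int = 10,
    threshold: float = 0.85,
    k_min: int = 4,
    weights: pd.Series | None = None,
) -> tuple[GainTable, FinestSubset]:
    """Full selection stage: gains -> logistic scores -> subset -> ordering.

    ``weights`` (the DASR W_g) optionally multiplies the gains before
    scoring; by default selection is driven by gain alone and the weights
    are only reported alongside.
    """
    gains = compute_gains(norm, n_bins)
    if weights is not None:
        gains = gains.copy()
        gains["G_Infor"] = gains["G_Infor"] * weights.reindex(gains.index)
    scores = logistic_decision_scores(gains)
    scores = select_features(scores, threshold=threshold, k_min=k_min)
    subset = finest_subset(scores.selected, norm.values, norm.labels, n_bins)
    return scores, subset
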