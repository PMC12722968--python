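"""Disease-affect scaling: per-feature two-class separation weights.

For each feature the two class-conditional means and variances are compared
through a pooled-standard-error standardized mean difference

    B_A(j) = |m1(j) - m0(j)| / sqrt( v0(j)/c0 + v1(j)/c1 )

(c = class count, v = sample variance), normalized across the T_A features
into weights W_g that sum to 1, and blended with an assumed error rate
E_rate into the finest-feature score

    F2(j) = W_g(j) * (1 - E_rate) + (1 - W_g(j)) * E_rate / T_A.

Larger B_A means the feature separates healthy from PD recordings more
strongly relative to its within-class noise; the weights feed the feature
report and, optionally, gate the downstream selection stage.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, DegenerateClassError
from .preprocessing import NormalizedDataset

logger = logging.getLogger("pdpipe")

#: Divisor when both class variances vanish but the means differ.
ZERO_VARIANCE_EPS = 1e-12


@dataclass
class ClassSplitStats:
    """Per-feature class counts, means, and sample variances."""

    count0: int
    count1: int
    mean0: pd.Series
    mean1: pd.Series
    var0: pd.Series
    var1: pd.Series

    @property
    def n_rows(self) -> int:
        return self.count0 + self.count1

    @property
    def feature_names(self) -> list[str]:
        return list(self.mean0.index)


@dataclass
class FeatureWeights:
    """The separation statistic and its normalized/blended forms."""

    b_a: pd.Series
    w_g: pd.Series
    f2: pd.Series
    e_rate: float

    @property
    def n_features(self) -> int:
        return len(self.b_a)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"B_A": self.b_a, "W_g": self.w_g, "F2": self.f2})

    def ranked(self) -> list[str]:
        """Feature names by descending weight (ties broken by name)."""
        df = self.to_frame().sort_values(
            ["W_g", "B_A"], ascending=False, kind="mergesort"
        )
        return list(df.index)


def class_split_stats(norm: NormalizedDataset) -> ClassSplitStats:
    """Class-conditional mean and sample variance of every feature."""
    labels = np.asarray(norm.labels)
    mask1 = labels == 1
    c0, c1 = int((~mask1).sum()), int(mask1.sum())
    if c0 < 2 or c1 < 2:
        raise DegenerateClassError(
            f"need >= 2 rows per class, got {c0} (healthy) and {c1} (PD)"
        )
    v0 = norm.values.loc[~mask1]
    v1 = norm.values.loc[mask1]
    return ClassSplitStats(
        count0=c0,
        count1=c1,
        mean0=v0.mean(),
        mean1=v1.mean(),
        var0=v0.var(ddof=1),
        var1=v1.var(ddof=1),
    )


def separation_statistic(stats: ClassSplitStats) -> pd.Series:
    """B_A: absolute mean difference over its pooled standard error."""
    diff = (stats.mean1 - stats.mean0).abs()
    se = np.sqrt(stats.var0 / stats.count0 + stats.var1 / stats.count1)
    b_a = diff / se.replace(0.0, np.nan)
    # both variances zero: 0 when the means agree, |diff|/eps when they differ
    degenerate = se == 0.0
    b_a[degenerate & (diff == 0.0)] = 0.0
    b_a[degenerate & (diff > 0.0)] = diff[degenerate & (diff > 0.0)] / ZERO_VARIANCE_EPS
    return b_a


def normalize_weights(b_a: pd.Series) -> pd.Series:
    """W_g: B_A rescaled to sum to 1 across the T_A features."""
    total = b_a.sum()
    if total == 0.0:
        warnings.warn(
            "no feature separates the classes; falling back to uniform weights",
            stacklevel=2,
        )
        return pd.Series(1.0 / len(b_a), index=b_a.index)
    return b_a / total


def finest_feature_score(w_g: pd.Series, e_rate: float) -> pd.Series:
    """F2: weight discounted by the assumed error rate."""
    t_a = len(w_g)
    return w_g * (1.0 - e_rate) + (1.0 - w_g) * e_rate / t_a


def dasr_weights(stats: ClassSplitStats, e_rate: float = 0.05) -> FeatureWeights:
    """Full weighting stage: B_A, normalized W_g, and F2 per feature.

    Deterministic and equivariant under feature reordering; increasing a
    feature's class-mean separation (variances fixed) never lowers its W_g.
    """
    if not 0.0 <= e_rate < 1.0:
        raise ConfigError(f"e_rate {e_rate} not in [0,1)")
    b_a = separation_statistic(stats)
    w_g = normalize_weights(b_a)
    f2 = finest_feature_score(w_g, e_rate)
    logger.info("DASR: top feature %s (W_g=%.4f)", w_g.idxmax(), w_g.max())
    return FeatureWeights(b_a=b_a, w_g=w_g, f2=f2, e_rate=e_rate)
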