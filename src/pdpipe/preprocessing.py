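"""Z-score normalization and record cleaning (the ZSN stage).

Per feature, the mean M_n and *population* standard deviation s_d are
computed over present records only.  Each value is z-scored as

    z = (x - M_n) / s_d        if s_d != 0
    z =  x - M_n               if s_d == 0

and the z-scores are then min-max scaled to [0,1] using the per-feature
min/max of the z-scored values (F_v), yielding the normalized matrix Pre_D.
Record cleaning drops rows that are mostly missing, imputes the rest, and
removes rows carrying "irrelevant" values (|z| beyond a cutoff).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ContractError, EmptyDatasetError, StatsError
from .io import FeatureTable


@dataclass
class ColumnStats:
    """Per-feature moments, and the z-score range once min-max is fitted."""

    means: pd.Series
    sds: pd.Series
    n_present: pd.Series
    z_min: pd.Series | None = None
    z_max: pd.Series | None = None

    @property
    def feature_names(self) -> list[str]:
        return list(self.means.index)

    def to_dict(self) -> dict:
        d = {
            "means": self.means.to_dict(),
            "sds": self.sds.to_dict(),
            "n_present": {k: int(v) for k, v in self.n_present.items()},
        }
        if self.z_min is not None:
            d["z_min"] = self.z_min.to_dict()
            d["z_max"] = self.z_max.to_dict()
        return d


@dataclass
class NormalizedDataset:
    """Min-max scaled z-scores (Pre_D) with their provenance."""

    values: pd.DataFrame
    labels: np.ndarray
    stats: ColumnStats
    dropped_rows: list[tuple[int, str]] = field(default_factory=list)

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_rows(self) -> int:
        return len(self.values)

    def restrict(self, features: list[str]) -> "NormalizedDataset":
        missing = set(features) - set(self.values.columns)
        if missing:
            raise ContractError(f"unknown features {sorted(missing)}")
        return NormalizedDataset(
            values=self.values[features].copy(),
            labels=self.labels,
            stats=self.stats,
            dropped_rows=self.dropped_rows,
        )


def column_stats(table: FeatureTable) -> ColumnStats:
    """Mean and population SD per feature over present records only."""
    values = table.values
    n_present = values.notna().sum()
    empty = n_present[n_present == 0]
    if len(empty):
        raise StatsError(f"all-missing column(s): {list(empty.index)}")
    means = values.mean(skipna=True)
    # population SD: sqrt( sum (x - mean)^2 / n_present )
    sds = values.std(skipna=True, ddof=0)
    return ColumnStats(means=means, sds=sds, n_present=n_present)


def zscore(table: FeatureTable | pd.DataFrame, stats: ColumnStats) -> pd.DataFrame:
    """Two-branch z-score: divide by s_d unless s_d = 0, then just center."""
    values = table.values if isinstance(table, FeatureTable) else table
    if list(values.columns) != stats.feature_names:
        raise ContractError(
            "feature names of table and stats differ: "
            f"{list(values.columns)} vs {stats.feature_names}"
        )
    centered = values - stats.means
    divisor = stats.sds.replace(0.0, 1.0)  # s_d = 0 branch: keep (x - M_n)
    return centered / divisor


@dataclass
class CleanResult:
    table: FeatureTable
    dropped_rows: list[tuple[int, str]]


def clean_records(
    table: FeatureTable,
    policy: str = "impute_mean",
    z_cutoff: float = 4.0,
    max_missing_frac: float = 0.2,
) -> CleanResult:
    """Fill or remove unreliable records; output has no missing cells.

    1. Rows with too many missing cells are dropped (all of them under
       ``drop_row``; those above ``max_missing_frac`` under ``impute_mean``).
    2. Remaining missing cells are imputed with the column mean over present
       records.
    3. Rows containing any \\|z\\| > ``z_cutoff`` are dropped as carrying
       irrelevant values.  Because removing an outlier changes the column
       statistics, step 3 recomputes and repeats until no row is flagged;
       the operation is therefore idempotent.

    Dropped row indices (relative to the input table) are recorded with a
    reason, ``"missing"`` or ``"irrelevant"``.
    """
    if policy not in ("impute_mean", "drop_row"):
        raise ContractError(f"unknown missingness policy {policy!r}")

    dropped: list[tuple[int, str]] = []
    keep = np.arange(table.n_rows)
    values = table.values.copy()

    miss_frac = values.isna().mean(axis=1).to_numpy()
    bound = 0.0 if policy == "drop_row" else max_missing_frac
    too_missing = miss_frac > bound
    for i in np.flatnonzero(too_missing):
        dropped.append((int(keep[i]), "missing"))
    values = values.loc[~too_missing]
    keep = keep[~too_missing]
    if len(values) == 0:
        raise EmptyDatasetError("all rows dropped by the missingness policy")

    if values.isna().any().any():
        values = values.fillna(values.mean(skipna=True))
    if values.isna().any().any():  # a column that was all-missing among survivors
        raise StatsError("cannot impute an all-missing column")

    while True:
        sub = FeatureTable(values=values.reset_index(drop=True),
                           labels=table.labels[keep])
        z = zscore(sub, column_stats(sub))
        bad = (z.abs() > z_cutoff).any(axis=1).to_numpy()
        if not bad.any():
            break
        for i in np.flatnonzero(bad):
            dropped.append((int(keep[i]), "irrelevant"))
        values = values.loc[~bad]
        keep = keep[~bad]
        if len(values) == 0:
            raise EmptyDatasetError("all rows dropped as irrelevant")

    ids = [table.row_ids[i] for i in keep] if table.row_ids is not None else None
    cleaned = FeatureTable(
        values=values.reset_index(drop=True), labels=table.labels[keep], row_ids=ids
    )
    return CleanResult(table=cleaned, dropped_rows=dropped)


def minmax_normalize(z: pd.DataFrame, stats: ColumnStats) -> pd.DataFrame:
    """Scale z-scores to [0,1] per feature: (z - min F_v)/(max F_v - min F_v).

    On first use the z-score range F_v is measured from ``z`` and stored in
    ``stats``; subsequent calls reuse the stored range (so validation/test
    data is scaled exactly as the data the stats were fitted on) and clip to
    [0,1].  A constant feature maps to 0 everywhere.
    """
    if list(z.columns) != stats.feature_names:
        raise ContractError("feature names of z-matrix and stats differ")
    if stats.z_min is None:
        stats.z_min = z.min()
        stats.z_max = z.max()
    span = stats.z_max - stats.z_min
    safe_span = span.replace(0.0, 1.0)
    out = (z - stats.z_min) / safe_span
    out.loc[:, span == 0.0] = 0.0
    return out.clip(0.0, 1.0)


@dataclass
class Preprocessor:
    """Fitted cleaning + normalization, reusable on held-out tables."""

    stats: ColumnStats
    policy: str = "impute_mean"
    z_cutoff: float = 4.0
    max_missing_frac: float = 0.2

    def transform(self, table: FeatureTable) -> NormalizedDataset:
        cleaned = clean_records(
            table, self.policy, self.z_cutoff, self.max_missing_frac
        )
        z = zscore(cleaned.table, self.stats)
        pre = minmax_normalize(z, self.stats)
        return NormalizedDataset(
            values=pre,
            labels=cleaned.table.labels,
            stats=self.stats,
            dropped_rows=cleaned.dropped_rows,
        )


def preprocess(
    table: FeatureTable,
    policy: str = "impute_mean",
    z_cutoff: float = 4.0,
    max_missing_frac: float = 0.2,
) -> tuple[NormalizedDataset, Preprocessor]:
    """Clean, z-score and min-max normalize; returns the data and the fit.

    The returned :class:`Preprocessor` carries the fitted statistics so
    held-out partitions can be transformed without re-fitting (leakage-free
    evaluation); pass those partitions to ``Preprocessor.transform``.
    """
    cleaned = clean_records(table, policy, z_cutoff, max_missing_frac)
    stats = column_stats(cleaned.table)
    z = zscore(cleaned.table, stats)
    pre = minmax_normalize(z, stats)
    norm = NormalizedDataset(
        values=pre,
        labels=cleaned.table.labels,
        stats=stats,
        dropped_rows=cleaned.dropped_rows,
    )
    prep = Preprocessor(
        stats=stats, policy=policy, z_cutoff=z_cutoff,
        max_missing_frac=max_missing_frac,
    )
    return norm, prep
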