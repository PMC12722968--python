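"""Feature-table I/O, run configuration, and the train/validation/test split.

The pipeline's currency is the :class:`FeatureTable`: an ordered set of
recordings, each with ~22 numeric dysphonia features (jitter, shimmer,
noise-to-harmonics ratios, nonlinear dynamical measures ...) and a binary
``status`` label (0 = healthy, 1 = Parkinson's disease).  Missing cells are
carried explicitly as NaN and counted, never silently dropped.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

from .errors import ConfigError, ParseError, SchemaError, StratificationError

logger = logging.getLogger("pdpipe")

#: Case-insensitive tokens that denote a missing cell in input CSVs.
MISSING_TOKENS = frozenset({"", "na", "nan"})

#: Column names treated as row identifiers when auto-detecting.
ID_COLUMN_NAMES = ("name", "id")


@dataclass
class FeatureTable:
    """Rows x named numeric features plus a binary label.

    Parameters
    ----------
    values
        Numeric matrix as a DataFrame; NaN marks a missing cell.
    labels
        Per-row label in {0, 1} (0 = healthy, 1 = PD).
    row_ids
        Optional per-row string identifiers (recording names).
    """

    values: pd.DataFrame
    labels: np.ndarray
    row_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.labels) != len(self.values):
            raise SchemaError(
                f"{len(self.labels)} labels for {len(self.values)} rows"
            )
        bad = set(np.unique(self.labels)) - {0, 1}
        if bad:
            raise SchemaError(f"labels must be in {{0,1}}, found {sorted(bad)}")
        if self.values.shape[1] < 1 or self.values.shape[0] < 1:
            raise SchemaError("feature table needs >= 1 row and >= 1 feature")
        if self.row_ids is not None and len(self.row_ids) != len(self.values):
            raise SchemaError("row_ids length mismatch")
        self.values = self.values.astype(float)
        self.values.index = pd.RangeIndex(len(self.values))

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_rows(self) -> int:
        return len(self.values)

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def n_missing(self) -> pd.Series:
        """Missing-cell count per feature column."""
        return self.values.isna().sum()

    def take(self, indices: np.ndarray | list[int]) -> "FeatureTable":
        """Row subset preserving parent order of ``indices`` as given."""
        idx = np.asarray(indices, dtype=int)
        ids = [self.row_ids[i] for i in idx] if self.row_ids is not None else None
        return FeatureTable(
            values=self.values.iloc[idx].reset_index(drop=True),
            labels=self.labels[idx],
            row_ids=ids,
        )

    def to_dataframe(self, label_column: str = "status") -> pd.DataFrame:
        df = self.values.copy()
        df[label_column] = self.labels
        if self.row_ids is not None:
            df.insert(0, "name", self.row_ids)
        return df

    def write_csv(self, path, label_column: str = "status") -> None:
        # 17 significant digits round-trips IEEE doubles exactly
        self.to_dataframe(label_column).to_csv(path, index=False, float_format="%.17g")


def _parse_cell(token: str, row: int, column: str) -> float:
    token = token.strip()
    if token.lower() in MISSING_TOKENS:
        return np.nan
    try:
        return float(token)
    except ValueError:
        raise ParseError(
            f"non-numeric value {token!r} at row {row}, column {column!r}"
        ) from None


def read_feature_table(
    path,
    label_column: str = "status",
    id_column: str | None = "auto",
) -> FeatureTable:
    """Read a CSV in the UCI/Kaggle Parkinson's-voice dialect.

    All non-ID columns must parse as numeric or one of the recognized
    missing tokens (empty, "NA", "NaN", case-insensitive); anything else
    raises :class:`ParseError` naming the offending cell.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if label_column not in raw.columns:
        raise SchemaError(
            f"label column {label_column!r} not in {list(raw.columns)}"
        )
    if id_column == "auto":
        id_column = next((c for c in ID_COLUMN_NAMES if c in raw.columns), None)
    row_ids = list(raw[id_column]) if id_column else None

    labels = []
    for r, token in enumerate(raw[label_column]):
        v = _parse_cell(token, r, label_column)
        if np.isnan(v) or v not in (0.0, 1.0):
            raise SchemaError(f"label at row {r} is {token!r}, expected 0 or 1")
        labels.append(int(v))

    feature_cols = [c for c in raw.columns if c not in (label_column, id_column)]
    if not feature_cols:
        raise SchemaError("no feature columns found")
    data = {
        c: [_parse_cell(tok, r, c) for r, tok in enumerate(raw[c])]
        for c in feature_cols
    }
    values = pd.DataFrame(data, columns=feature_cols)
    logger.info(
        "read %d rows x %d features from %s (%d missing cells)",
        len(values), len(feature_cols), path, int(values.isna().sum().sum()),
    )
    return FeatureTable(values=values, labels=np.array(labels), row_ids=row_ids)


@dataclass(frozen=True)
class SplitSpec:
    """Proportions and seed for the train/validation/test partition."""

    train_frac: float = 0.6
    val_frac: float = 0.2
    test_frac: float = 0.2
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        for f in (self.train_frac, self.val_frac, self.test_frac):
            if not 0.0 < f < 1.0:
                raise ConfigError(f"split fraction {f} not in (0,1)")
        total = self.train_frac + self.val_frac + self.test_frac
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"split fractions sum to {total}, expected 1")


def _allocate(n: int, spec: SplitSpec) -> tuple[int, int, int]:
    # train and validation take the floor; test takes the remainder
    n_train = int(np.floor(spec.train_frac * n))
    n_val = int(np.floor(spec.val_frac * n))
    return n_train, n_val, n - n_train - n_val


def split_dataset(
    table: FeatureTable, spec: SplitSpec
) -> tuple[FeatureTable, FeatureTable, FeatureTable]:
    """Partition rows into train/validation/test, stratified by label.

    The partitions are disjoint, their union is the input, and row order
    within each partition follows the parent table.  Deterministic for a
    fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    buckets: list[list[int]] = [[], [], []]
    if spec.stratified:
        for cls in (0, 1):
            cls_idx = np.flatnonzero(table.labels == cls)
            if len(cls_idx) == 0:
                raise StratificationError(f"class {cls} absent from the table")
            n_tr, n_va, n_te = _allocate(len(cls_idx), spec)
            if min(n_tr, n_va, n_te) < 1:
                raise StratificationError(
                    f"class {cls} has {len(cls_idx)} rows: too few for a "
                    f"{spec.train_frac}/{spec.val_frac}/{spec.test_frac} split"
                )
            perm = rng.permutation(len(cls_idx))
            shuffled = cls_idx[perm]
            buckets[0].extend(shuffled[:n_tr])
            buckets[1].extend(shuffled[n_tr : n_tr + n_va])
            buckets[2].extend(shuffled[n_tr + n_va :])
    else:
        n_tr, n_va, _ = _allocate(table.n_rows, spec)
        perm = rng.permutation(table.n_rows)
        buckets = [list(perm[:n_tr]), list(perm[n_tr : n_tr + n_va]), list(perm[n_tr + n_va :])]

    parts = tuple(table.take(sorted(b)) for b in buckets)
    logger.info(
        "split %d rows -> %d/%d/%d (seed=%d, stratified=%s)",
        table.n_rows, parts[0].n_rows, parts[1].n_rows, parts[2].n_rows,
        spec.seed, spec.stratified,
    )
    return parts


@dataclass
class RunConfig:
    """Every tunable the pipeline exposes, with its default.

    ``learning_rate`` defaults to 0.6, the midpoint of the 0.4-0.8 range the
    training rule is specified for; values outside that range are accepted
    with a warning.
    """

    ldefs_threshold: float = 0.85
    learning_rate: float = 0.6
    momentum: float = 0.9
    epochs: int = 300
    patience: int = 30
    n_rules: int = 4
    n_bins: int = 10
    k_min: int = 4
    e_rate: float = 0.05
    z_cutoff: float = 4.0
    risk_thresholds: tuple[float, float] = (0.33, 0.66)
    missingness_policy: str = "impute_mean"
    max_missing_frac: float = 0.2
    fit_on: str = "train"  # "train" avoids leakage; "all" normalizes collectively
    train_frac: float = 0.6
    val_frac: float = 0.2
    test_frac: float = 0.2
    seed: int = 0
    t_norm: str = "product"
    update_rule: str = "momentum"
    combine: str = "gain"  # or "gain_times_weight": gate selection by DASR weight

    def __post_init__(self) -> None:
        if not 0.0 < self.ldefs_threshold < 1.0:
            raise ConfigError("ldefs_threshold must be in (0,1)")
        if not 0.0 < self.learning_rate <= 1.0:
            raise ConfigError("learning_rate must be in (0,1]")
        if not 0.4 <= self.learning_rate <= 0.8:
            warnings.warn(
                f"learning_rate {self.learning_rate} outside the recommended "
                "0.4-0.8 range",
                stacklevel=2,
            )
        if self.momentum < 0:
            raise ConfigError("momentum must be >= 0")
        if not 0.0 <= self.e_rate < 1.0:
            raise ConfigError("e_rate must be in [0,1)")
        t1, t2 = self.risk_thresholds
        if not 0.0 < t1 < t2 < 1.0:
            raise ConfigError("risk thresholds must be strictly increasing in (0,1)")
        if self.missingness_policy not in ("impute_mean", "drop_row"):
            raise ConfigError(f"unknown missingness policy {self.missingness_policy!r}")
        if self.fit_on not in ("train", "all"):
            raise ConfigError("fit_on must be 'train' or 'all'")
        if self.combine not in ("gain", "gain_times_weight"):
            raise ConfigError("combine must be 'gain' or 'gain_times_weight'")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "risk_thresholds" in data:
            data["risk_thresholds"] = tuple(data["risk_thresholds"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d["risk_thresholds"] = list(self.risk_thresholds)
        return d

    def split_spec(self) -> SplitSpec:
        return SplitSpec(
            train_frac=self.train_frac,
            val_frac=self.val_frac,
            test_frac=self.test_frac,
            seed=self.seed,
        )
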