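"""Synthetic two-class voice-feature tables with planted structure.

The generator emulates the statistical shape of dysphonia datasets: a block
of informative features whose class-conditional means differ by a chosen
standardized effect size, an equicorrelated block of noise features with no
class signal, optional missing-completely-at-random cells, and either UCI-style
dysphonia names (PPE, spread1, D2, MDVP:RAP, ...) or generic names.  Ground
truth (which features carry signal) is returned alongside, so feature-weighting
and feature-selection stages can be scored against a known answer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import FeatureTable

# Real dysphonia feature names; the first four are the ones reported as most
# informative for PD voice data, so "uci" style plants the signal there.
UCI_FEATURE_NAMES = [
    "PPE", "spread1", "D2", "MDVP:RAP",
    "MDVP:Fo(Hz)", "MDVP:Fhi(Hz)", "MDVP:Flo(Hz)",
    "MDVP:Jitter(%)", "MDVP:Jitter(Abs)", "MDVP:PPQ", "Jitter:DDP",
    "MDVP:Shimmer", "MDVP:Shimmer(dB)", "Shimmer:APQ3", "Shimmer:APQ5",
    "MDVP:APQ", "Shimmer:DDA", "NHR", "HNR",
    "RPDE", "DFA", "spread2",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic feature table."""

    n_rows: int = 400
    n_informative: int = 4
    n_noise: int = 18
    effect_size: float = 2.0
    class_balance: float = 0.5
    noise_correlation: float = 0.2
    missing_rate: float = 0.0
    seed: int = 0
    feature_name_style: str = "uci"

    def __post_init__(self) -> None:
        if self.n_informative + self.n_noise < 1:
            raise ConfigError("need at least one feature")
        if self.effect_size < 0:
            raise ConfigError("effect_size must be >= 0")
        if not 0.0 <= self.missing_rate <= 0.5:
            raise ConfigError("missing_rate must be in [0, 0.5]")
        if not 0.0 < self.class_balance < 1.0:
            raise ConfigError("class_balance must be in (0,1)")
        n1 = round(self.class_balance * self.n_rows)
        if n1 < 2 or self.n_rows - n1 < 2:
            raise ConfigError("each class needs >= 2 rows")
        if self.feature_name_style not in ("uci", "generic"):
            raise ConfigError("feature_name_style must be 'uci' or 'generic'")
        if not 0.0 <= self.noise_correlation < 1.0:
            raise ConfigError("noise_correlation must be in [0,1)")


def _feature_names(spec: SyntheticSpec) -> tuple[list[str], list[str]]:
    p = spec.n_informative + spec.n_noise
    if spec.feature_name_style == "uci":
        names = list(UCI_FEATURE_NAMES)
        while len(names) < p:
            names.append(f"extra_{len(names) - len(UCI_FEATURE_NAMES) + 1}")
        names = names[:p]
    else:
        names = [f"inf_{j + 1}" for j in range(spec.n_informative)] + [
            f"noise_{j + 1}" for j in range(spec.n_noise)
        ]
    return names, names[: spec.n_informative]


def generate_pd_dataset(spec: SyntheticSpec) -> tuple[FeatureTable, dict]:
    """Generate a feature table plus a ground-truth record.

    Informative feature j is N(0,1) within class 0 and N(effect_size, 1)
    within class 1, i.e. the class means differ by ``effect_size`` pooled
    SDs.  Noise features share a latent factor giving pairwise correlation
    ``noise_correlation`` and have zero mean difference in expectation.
    Each column is then given its own location and scale so downstream
    normalization has real work to do.  Purely a function of the spec.
    """
    rng = np.random.default_rng(spec.seed)
    n, p_inf, p_noise = spec.n_rows, spec.n_informative, spec.n_noise
    p = p_inf + p_noise

    n1 = round(spec.class_balance * n)
    labels = np.zeros(n, dtype=int)
    labels[:n1] = 1
    rng.shuffle(labels)

    X = np.empty((n, p))
    if p_inf:
        X[:, :p_inf] = rng.standard_normal((n, p_inf))
        X[:, :p_inf] += spec.effect_size * labels[:, None]
    if p_noise:
        rho = spec.noise_correlation
        common = rng.standard_normal((n, 1))
        own = rng.standard_normal((n, p_noise))
        X[:, p_inf:] = np.sqrt(rho) * common + np.sqrt(1.0 - rho) * own

    # per-feature location/scale jitter: abstract analogue of the wildly
    # different units of real dysphonia measures (Hz vs dB vs ratios)
    loc = rng.uniform(-5.0, 5.0, size=p)
    scale = rng.uniform(0.5, 3.0, size=p)
    X = loc + scale * X

    names, informative = _feature_names(spec)
    table = FeatureTable(values=pd.DataFrame(X, columns=names), labels=labels)
    if spec.missing_rate > 0:
        table = inject_missingness(table, spec.missing_rate, seed=spec.seed + 1)
    truth = {
        "informative_features": informative,
        "effect_size": spec.effect_size,
        "spec": spec.__dict__ | {},
    }
    return table, truth


def inject_missingness(table: FeatureTable, rate: float, seed: int) -> FeatureTable:
    """Mask a fraction ``rate`` of feature cells completely at random.

    Exactly ``round(rate * n_cells)`` cells become NaN; labels are never
    touched (they live outside the feature matrix).
    """
    if not 0.0 <= rate < 1.0:
        raise ConfigError(f"missing rate {rate} not in [0,1)")
    if rate == 0.0:
        return table
    rng = np.random.default_rng(seed)
    n_cells = table.n_rows * table.n_features
    n_mask = int(round(rate * n_cells))
    flat = rng.choice(n_cells, size=n_mask, replace=False)
    values = table.values.to_numpy().copy()
    values[np.unravel_index(flat, values.shape)] = np.nan
    return FeatureTable(
        values=pd.DataFrame(values, columns=table.feature_names),
        labels=table.labels.copy(),
        row_ids=list(table.row_ids) if table.row_ids is not None else None,
    )


def make_worked_toy() -> FeatureTable:
    """Fixed 12-row, 4-feature fixture used across the test suite.

    Two informative columns (PPE, spread1) with clearly separated class
    means and two noise columns with none; 6 rows per class; hard-coded so
    every platform sees identical values.
    """
    data = {
        "PPE": [0.10, 0.15, 0.12, 0.20, 0.18, 0.14,
                0.35, 0.40, 0.32, 0.45, 0.38, 0.42],
        "spread1": [-6.8, -7.2, -6.5, -7.0, -6.9, -7.4,
                    -5.0, -5.5, -4.8, -5.2, -5.6, -4.9],
        "noise_a": [1.2, 3.4, 2.2, 2.8, 1.9, 3.1,
                    2.0, 2.9, 1.5, 3.3, 2.4, 2.6],
        "noise_b": [0.50, 0.90, 0.70, 0.60, 0.80, 0.55,
                    0.65, 0.85, 0.52, 0.75, 0.95, 0.60],
    }
    labels = np.array([0] * 6 + [1] * 6)
    return FeatureTable(values=pd.DataFrame(data), labels=labels)
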