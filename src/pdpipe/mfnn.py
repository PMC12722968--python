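"""Four-layer fuzzy neural network classifier with risk-class output.

Layer 1 passes the selected feature values through.  Layer 2 fuzzifies each
input against per-rule Gaussian fuzzy sets,

    mu_{r,j}(x_j) = exp( -(x_j - c_{r,j})^2 / (2 z_{r,j}^2) ),

layer 3 combines the memberships of rule r with a t-norm (product by
default) into a firing strength w_r and evaluates the rule's linear
consequent R_r = p_r . x + q_r, and the normalized weighted rule outputs
g_r R_r (g_r = w_r / sum w) are mapped by a linear class head to two logits
whose softmax gives P(healthy) and P(PD).  Although the architecture is
conventionally described with Mamdani-style If-Then rules, the consequents
are linear functions of the inputs, i.e. Takagi-Sugeno form; the printed
rule equations take precedence over the naming.

Training is full-batch gradient descent on the softmax cross-entropy with a
momentum update

    delta_new = -tau * grad + alpha * delta_prev,   theta += delta_new,

applied to all parameter groups (centers, widths, consequent coefficients
and biases, class head), with early stopping on validation stagnation.  The
learning rate tau is meant to live in 0.4-0.8.  Predicted PD probabilities
are finally stratified into low/medium/high risk classes by two thresholds.
"""

from __future__ import annotations

import copy
import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, ContractError, TrainingError

logger = logging.getLogger("pdpipe")

WIDTH_FLOOR = 0.05
FIRING_GUARD = 1e-300  # below this total firing, fall back to uniform weights

PARAM_KEYS = ("centers", "widths", "coefs", "biases", "head_w", "head_b")


@dataclass
class FuzzySet:
    """One Gaussian fuzzy set: a center and a positive width."""

    center: float
    width: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ContractError(f"fuzzy-set width must be > 0, got {self.width}")


def membership(x: float, fset: FuzzySet) -> float:
    """Gaussian membership of a crisp value in a fuzzy set, in (0,1]."""
    return float(np.exp(-((x - fset.center) ** 2) / (2.0 * fset.width**2)))


@dataclass
class RuleNode:
    """One If-Then rule: fuzzy antecedents plus a linear consequent."""

    antecedent: list[FuzzySet]
    coef: np.ndarray  # per-feature consequent weights (p_r, q_r, ...)
    bias: float


@dataclass
class MFNNModel:
    """The trainable network: rule parameters and the class head.

    Parameter arrays (R rules, d features):
      centers (R,d), widths (R,d) — antecedent fuzzy sets;
      coefs (R,d), biases (R,)    — linear rule consequents;
      head_w (2,R), head_b (2,)   — class head over weighted rule outputs.
    """

    feature_names: list[str]
    centers: np.ndarray
    widths: np.ndarray
    coefs: np.ndarray
    biases: np.ndarray
    head_w: np.ndarray
    head_b: np.ndarray
    t_norm: str = "product"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rules < 1:
            raise ConfigError("need >= 1 rule")
        if self.t_norm not in ("product", "min"):
            raise ConfigError("t_norm must be 'product' or 'min'")
        if (self.widths <= 0).any():
            raise ContractError("all widths must be > 0")

    @property
    def n_rules(self) -> int:
        return self.centers.shape[0]

    @property
    def n_features(self) -> int:
        return self.centers.shape[1]

    def rules(self) -> list[RuleNode]:
        """View the parameter arrays as rule objects."""
        return [
            RuleNode(
                antecedent=[
                    FuzzySet(float(self.centers[r, j]), float(self.widths[r, j]))
                    for j in range(self.n_features)
                ],
                coef=self.coefs[r].copy(),
                bias=float(self.biases[r]),
            )
            for r in range(self.n_rules)
        ]

    def params(self) -> dict[str, np.ndarray]:
        return {k: getattr(self, k) for k in PARAM_KEYS}

    def copy(self) -> "MFNNModel":
        return copy.deepcopy(self)

    def to_json(self) -> str:
        payload = {k: getattr(self, k).tolist() for k in PARAM_KEYS}
        payload["feature_names"] = self.feature_names
        payload["t_norm"] = self.t_norm
        payload["seed"] = self.seed
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "MFNNModel":
        data = json.loads(text)
        return cls(
            feature_names=data["feature_names"],
            t_norm=data["t_norm"],
            seed=data["seed"],
            **{k: np.asarray(data[k], dtype=float) for k in PARAM_KEYS},
        )


def init_model(
    values: np.ndarray | "pd.DataFrame",
    labels,
    feature_names: list[str] | None = None,
    n_rules: int = 4,
    seed: int = 0,
    t_norm: str = "product",
) -> MFNNModel:
    """Data-driven initialization.

    Rules are assigned to classes round-robin; each rule's centers are the
    per-class, per-feature quantiles at (k + 1/2)/K for the k-th rule of a
    class, so with one rule per class the centers sit at the class medians.
    Widths are half the center spread per feature, floored at 0.05.
    Consequents start at zero; the class head is small seeded noise (the
    only stochastic element), which breaks symmetry so gradients reach the
    consequents.
    """
    X, names = _as_array(values, feature_names)
    labels = np.asarray(labels, dtype=int)
    if n_rules < 2:
        raise ConfigError("n_rules must be >= 2 (one per class at least)")
    if len(X) == 0:
        raise ConfigError("empty training set")
    if n_rules > len(np.unique(X, axis=0)):
        raise ConfigError("n_rules exceeds the number of distinct training rows")

    rng = np.random.default_rng(seed)
    d = X.shape[1]
    per_class = [n_rules // 2 + (1 if (n_rules % 2 and c == 1) else 0) for c in (0, 1)]
    centers = np.empty((n_rules, d))
    r = 0
    for cls, k_cls in zip((0, 1), per_class):
        Xc = X[labels == cls]
        if len(Xc) == 0:
            raise ConfigError(f"class {cls} absent from the training set")
        for k in range(k_cls):
            q = (k + 0.5) / k_cls
            centers[r] = np.quantile(Xc, q, axis=0)
            r += 1

    spread = centers.max(axis=0) - centers.min(axis=0)
    denom = max(n_rules - 1, 1)
    widths = np.maximum(spread / (2.0 * denom), WIDTH_FLOOR)
    widths = np.broadcast_to(widths, (n_rules, d)).copy()

    return MFNNModel(
        feature_names=names,
        centers=centers,
        widths=widths,
        coefs=np.zeros((n_rules, d)),
        biases=np.zeros(n_rules),
        head_w=rng.normal(0.0, 0.5, size=(2, n_rules)),
        head_b=np.zeros(2),
        t_norm=t_norm,
        seed=seed,
    )


def _as_array(values, feature_names=None) -> tuple[np.ndarray, list[str]]:
    if hasattr(values, "columns"):  # DataFrame
        return values.to_numpy(dtype=float), list(values.columns)
    X = np.asarray(values, dtype=float)
    names = feature_names or [f"x{j}" for j in range(X.shape[1])]
    return X, names


def _softmax(logits: np.ndarray) -> np.ndarray:
    shifted = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=1, keepdims=True)


def forward(model: MFNNModel, x) -> tuple[np.ndarray, np.ndarray]:
    """Class probabilities and rule firing strengths for input row(s).

    Accepts a single feature vector or an (n, d) batch; returns
    (probabilities (n,2), firing strengths (n,R)).
    """
    X = np.atleast_2d(np.asarray(x, dtype=float))
    if X.shape[1] != model.n_features:
        raise ContractError(
            f"input has {X.shape[1]} features, model expects {model.n_features}"
        )
    cache = _forward_cache(model, X)
    return cache["probs"], cache["w"]


def _forward_cache(model: MFNNModel, X: np.ndarray) -> dict:
    diff = X[:, None, :] - model.centers[None, :, :]  # (n,R,d)
    quad = (diff**2) / (2.0 * model.widths[None, :, :] ** 2)
    if model.t_norm == "product":
        logw = -quad.sum(axis=2)  # (n,R)
        w = np.exp(logw)
    else:  # min t-norm: weakest membership wins
        w = np.exp(-quad).min(axis=2)
    total = w.sum(axis=1)
    guarded = total < FIRING_GUARD
    g = np.empty_like(w)
    safe = ~guarded
    g[safe] = w[safe] / total[safe, None]
    g[guarded] = 1.0 / model.n_rules
    rule_out = X @ model.coefs.T + model.biases  # (n,R)
    s = g * rule_out
    logits = s @ model.head_w.T + model.head_b  # (n,2)
    probs = _softmax(logits)
    return {
        "X": X, "diff": diff, "w": w, "total": total, "guarded": guarded,
        "g": g, "rule_out": rule_out, "s": s, "logits": logits, "probs": probs,
    }


def cross_entropy(model: MFNNModel, X, y) -> float:
    """Mean softmax cross-entropy of the model on (X, y)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=int)
    probs = _forward_cache(model, X)["probs"]
    p_true = np.clip(probs[np.arange(len(y)), y], 1e-12, None)
    return float(-np.log(p_true).mean())


def loss_and_gradients(model: MFNNModel, X, y) -> tuple[float, dict[str, np.ndarray]]:
    """Analytic full-batch gradients of the cross-entropy loss.

    Only defined for the product t-norm (the min t-norm is not smooth); the
    guarded uniform-firing branch contributes no antecedent gradient.
    """
    if model.t_norm != "product":
        raise TrainingError("gradient training requires the product t-norm")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=int)
    n = len(y)
    c = _forward_cache(model, X)

    p_true = np.clip(c["probs"][np.arange(n), y], 1e-12, None)
    loss = float(-np.log(p_true).mean())

    dlogits = c["probs"].copy()
    dlogits[np.arange(n), y] -= 1.0
    dlogits /= n  # (n,2)

    grads: dict[str, np.ndarray] = {}
    grads["head_w"] = dlogits.T @ c["s"]  # (2,R)
    grads["head_b"] = dlogits.sum(axis=0)  # (2,)

    ds = dlogits @ model.head_w  # (n,R)
    drule = ds * c["g"]
    grads["coefs"] = drule.T @ c["X"]  # (R,d)
    grads["biases"] = drule.sum(axis=0)

    dg = ds * c["rule_out"]  # (n,R)
    # g = w / total; guarded rows have constant g
    dot = (dg * c["g"]).sum(axis=1, keepdims=True)
    dw = (dg - dot) / c["total"][:, None]
    dw[c["guarded"]] = 0.0
    dlogw = dw * c["w"]  # (n,R)

    inv_var = 1.0 / model.widths[None, :, :] ** 2
    grads["centers"] = (dlogw[:, :, None] * c["diff"] * inv_var).sum(axis=0)
    grads["widths"] = (
        dlogw[:, :, None] * c["diff"] ** 2 / model.widths[None, :, :] ** 3
    ).sum(axis=0)
    return loss, grads


@dataclass
class TrainState:
    """Learning rate, momentum coefficient, and the running update buffers."""

    learning_rate: float = 0.6
    momentum: float = 0.9
    update_rule: str = "momentum"
    velocity: dict[str, np.ndarray] = field(default_factory=dict)
    epoch: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.learning_rate <= 1.0:
            raise ConfigError("learning rate must be in (0,1]")
        if self.momentum < 0:
            raise ConfigError("momentum must be >= 0")
        if self.update_rule not in ("momentum", "literal"):
            raise ConfigError("update_rule must be 'momentum' or 'literal'")


def update_weights(
    state: TrainState, key: str, weight: np.ndarray, gradient: np.ndarray
) -> np.ndarray:
    """One momentum step on a parameter array; returns the new weights.

    delta_new = -tau * gradient + alpha * delta_prev;  w_new = w + delta_new.
    The previous update is buffered per parameter group in ``state``.  The
    alternative "literal" rule, w_new = tau * (-gradient) + alpha * w, treats
    the second term as shrinking the weight itself rather than carrying
    momentum; it is available for comparison but not the default.
    """
    if not np.all(np.isfinite(gradient)):
        raise TrainingError(
            f"non-finite gradient for {key!r} at epoch {state.epoch}"
        )
    if state.update_rule == "literal":
        return state.learning_rate * (-gradient) + state.momentum * weight
    prev = state.velocity.get(key, np.zeros_like(weight))
    delta = -state.learning_rate * gradient + state.momentum * prev
    state.velocity[key] = delta
    return weight + delta


def train(
    model: MFNNModel,
    train_values,
    train_labels,
    val_values=None,
    val_labels=None,
    state: TrainState | None = None,
    epochs: int = 300,
    patience: int = 30,
) -> tuple[MFNNModel, dict]:
    """Full-batch gradient training with early stopping.

    Returns the best model (by validation loss when a validation set is
    given, else final) and a history dict with per-epoch train/val losses.
    Raises :class:`TrainingError` if the loss becomes non-finite, which
    usually means the learning rate is too large.
    """
    X, _ = _as_array(train_values, model.feature_names)
    y = np.asarray(train_labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise TrainingError("training set must contain both classes")
    has_val = val_values is not None and val_labels is not None
    if has_val:
        Xv, _ = _as_array(val_values, model.feature_names)
        yv = np.asarray(val_labels, dtype=int)
    state = state or TrainState()

    model = model.copy()
    history: dict = {"train_loss": [], "val_loss": []}
    best_val = np.inf
    best_model = model.copy()
    stale = 0

    for epoch in range(epochs):
        state.epoch = epoch
        loss, grads = loss_and_gradients(model, X, y)
        if not np.isfinite(loss):
            raise TrainingError(
                f"loss diverged at epoch {epoch}; try a smaller learning rate"
            )
        history["train_loss"].append(loss)
        for key in PARAM_KEYS:
            new = update_weights(state, key, getattr(model, key), grads[key])
            if key == "widths":
                new = np.maximum(new, WIDTH_FLOOR)
            setattr(model, key, new)

        if has_val:
            vloss = cross_entropy(model, Xv, yv)
            history["val_loss"].append(vloss)
            if vloss < best_val - 1e-9:
                best_val = vloss
                best_model = model.copy()
                stale = 0
            else:
                stale += 1
                if stale >= patience:
                    logger.info("early stop at epoch %d (val %.4f)", epoch, best_val)
                    break

    final = best_model if has_val else model
    history["final_train_loss"] = cross_entropy(final, X, y)
    return final, history


@dataclass
class RiskAssignment:
    """PD probability stratified into a risk class."""

    probability: float
    risk_class: str
    predicted_label: int
    thresholds: tuple[float, float]


def assign_risk(
    probability: float, thresholds: tuple[float, float] = (0.33, 0.66)
) -> RiskAssignment:
    """Map P(PD) to low/medium/high risk; the label cut stays at 0.5."""
    t1, t2 = thresholds
    if not 0.0 < t1 < t2 < 1.0:
        raise ConfigError(f"thresholds must be strictly increasing in (0,1): {thresholds}")
    if not 0.0 <= probability <= 1.0:
        raise ContractError(f"probability {probability} outside [0,1]")
    if probability < t1:
        risk = "low"
    elif probability < t2:
        risk = "medium"
    else:
        risk = "high"
    return RiskAssignment(
        probability=float(probability),
        risk_class=risk,
        predicted_label=int(probability >= 0.5),
        thresholds=(t1, t2),
    )


def predict(
    model: MFNNModel, values, thresholds: tuple[float, float] = (0.33, 0.66)
) -> tuple[np.ndarray, np.ndarray, list[RiskAssignment]]:
    """PD probabilities, hard labels, and risk assignments for a batch."""
    probs, _ = forward(model, values)
    p1 = probs[:, 1]
    risks = [assign_risk(float(p), thresholds) for p in p1]
    labels = np.array([r.predicted_label for r in risks])
    return p1, labels, risks
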