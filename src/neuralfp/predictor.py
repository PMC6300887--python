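"""End-to-end per-ADR classifiers on top of neural fingerprints.

Each ADR gets its own fingerprint network and logistic head (optionally with
one batch-normalized hidden layer), trained jointly by ADAM on minibatches.
The loss is mean cross-entropy plus an L2 penalty on the head weights
(lambda1) and on the fingerprint vectors themselves (lambda2), the latter
encouraging the attention writes to spread and keeping the learned
fingerprints small and interpretable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .chem_io import LabelMatrix, MoleculeGraph
from . import neural_fingerprint as nf

logger = logging.getLogger(__name__)

_BN_EPS = 1e-5


class PredictorError(ValueError):
    pass


@dataclass
class TrainConfig:
    """Hyper-parameters for end-to-end training.

    Defaults follow the reference configuration: radius R=4, K=50 fingerprint
    bits, one hidden layer of 100 units with batch normalization, lambda1=1e-4,
    lambda2=1e-2, ADAM on minibatches of 100.  Learning rate and epoch count
    are package defaults.
    """

    R: int = 4
    K: int = 50
    hidden_units: int = 100  # 0 disables the hidden layer
    lambda1: float = 1e-4
    lambda2: float = 1e-2
    batch_size: int = 100
    epochs: int = 50
    learning_rate: float = 1e-3
    seed: int = 0
    batch_norm: bool = True
    activation: str = "tanh"
    write_levels: tuple[int, ...] | None = None
    hidden_dims: list[int] | None = None
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if min(self.R, self.K, self.batch_size, self.epochs) < 1 or self.learning_rate <= 0:
            raise PredictorError("R, K, batch_size, epochs, learning_rate must be positive")
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise PredictorError("lambda1 and lambda2 must be non-negative")


@dataclass
class PredictorParams:
    """Head weights: linear (w, b) or hidden layer (W1, gamma, beta, W2, b2)."""

    lambda1: float
    lambda2: float
    hidden_units: int
    w: np.ndarray | None = None  # (K,) linear head
    b: float = 0.0
    W1: np.ndarray | None = None  # (K, h)
    gamma: np.ndarray | None = None
    beta: np.ndarray | None = None
    W2: np.ndarray | None = None  # (h,)
    b2: float = 0.0
    batch_norm: bool = True
    bn_mean: np.ndarray | None = None
    bn_var: np.ndarray | None = None
    bn_momentum: float = 0.9

    def keys(self) -> list[str]:
        if self.hidden_units:
            ks = ["W1", "W2", "b2"]
            if self.batch_norm:
                ks += ["gamma", "beta"]
            else:
                ks += ["beta"]  # plain bias when batch norm is off
            return ks
        return ["w", "b"]


def init_head(K: int, config: TrainConfig, rng: np.random.Generator) -> PredictorParams:
    h = config.hidden_units
    head = PredictorParams(
        lambda1=config.lambda1, lambda2=config.lambda2, hidden_units=h,
        batch_norm=config.batch_norm,
    )
    if h:
        head.W1 = rng.normal(0.0, 1.0 / np.sqrt(K), size=(K, h))
        head.gamma = np.ones(h)
        head.beta = np.zeros(h)
        head.W2 = rng.normal(0.0, 1.0 / np.sqrt(h), size=h)
        head.b2 = 0.0
        head.bn_mean = np.zeros(h)
        head.bn_var = np.ones(h)
    else:
        head.w = np.zeros(K)
        head.b = 0.0
    return head


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def head_forward(Z: np.ndarray, head: PredictorParams, training: bool) -> tuple[np.ndarray, dict]:
    """Logits of the head; caches intermediates for backward."""
    cache: dict = {"Z": Z}
    if not head.hidden_units:
        return Z @ head.w + head.b, cache
    P = Z @ head.W1
    if head.batch_norm:
        if training:
            mu = P.mean(axis=0)
            var = P.var(axis=0)
            head.bn_mean = head.bn_momentum * head.bn_mean + (1 - head.bn_momentum) * mu
            head.bn_var = head.bn_momentum * head.bn_var + (1 - head.bn_momentum) * var
        else:
            mu, var = head.bn_mean, head.bn_var
        invstd = 1.0 / np.sqrt(var + _BN_EPS)
        Phat = (P - mu) * invstd
        Q = head.gamma * Phat + head.beta
        cache.update(P=P, Phat=Phat, invstd=invstd, training=training)
    else:
        Q = P + head.beta
        cache.update(P=P)
    Hdn = np.maximum(Q, 0.0)
    cache.update(Q=Q, Hdn=Hdn)
    return Hdn @ head.W2 + head.b2, cache


def head_backward(dlogit: np.ndarray, head: PredictorParams, cache: dict) -> tuple[dict, np.ndarray]:
    """Backward through the head; returns (parameter grads, dZ)."""
    Z = cache["Z"]
    grads: dict = {}
    if not head.hidden_units:
        grads["w"] = Z.T @ dlogit + 2.0 * head.lambda1 * head.w
        grads["b"] = dlogit.sum()
        return grads, np.outer(dlogit, head.w)
    Hdn = cache["Hdn"]
    grads["W2"] = Hdn.T @ dlogit + 2.0 * head.lambda1 * head.W2
    grads["b2"] = dlogit.sum()
    dH = np.outer(dlogit, head.W2)
    dQ = dH * (cache["Q"] > 0)
    if head.batch_norm:
        Phat, invstd = cache["Phat"], cache["invstd"]
        grads["gamma"] = (dQ * Phat).sum(axis=0)
        grads["beta"] = dQ.sum(axis=0)
        dPhat = dQ * head.gamma
        if cache.get("training"):
            B = Phat.shape[0]
            dP = (invstd / B) * (B * dPhat - dPhat.sum(axis=0) - Phat * (dPhat * Phat).sum(axis=0))
        else:
            dP = dPhat * invstd
    else:
        grads["beta"] = dQ.sum(axis=0)
        dP = dQ
    grads["W1"] = Z.T @ dP + 2.0 * head.lambda1 * head.W1
    return grads, dP @ head.W1.T


def loss(Z: np.ndarray, y: np.ndarray, head: PredictorParams) -> float:
    """Mean cross-entropy + lambda1*||w||^2 + lambda2*sum_i ||z_i||^2."""
    Z = np.asarray(Z, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(Z) != len(y):
        raise PredictorError(f"{len(Z)} fingerprints vs {len(y)} labels")
    if len(np.unique(y)) < 2:
        logger.info("degenerate labels: all samples are class %s", y[0] if len(y) else "?")
    logits, _ = head_forward(Z, head, training=False)
    # numerically stable log-loss: log(1+e^-|x|) + max(x,0) - x*y
    ce = np.log1p(np.exp(-np.abs(logits))) + np.maximum(logits, 0.0) - logits * y
    if head.hidden_units:
        wnorm = float((head.W1 ** 2).sum() + (head.W2 ** 2).sum())
    else:
        wnorm = float((head.w ** 2).sum())
    total = float(ce.mean() + head.lambda1 * wnorm + head.lambda2 * (Z ** 2).sum())
    if not np.isfinite(total):
        raise PredictorError("non-finite loss")
    return total


@dataclass
class ADRModel:
    """A trained per-ADR model: fingerprint network + head + config."""

    fp_params: nf.FingerprintParams
    head: PredictorParams
    config: TrainConfig
    history: list[float] = field(default_factory=list)

    def fingerprints(self, molecules: list[MoleculeGraph]) -> np.ndarray:
        feats = [nf.featurize_molecule(m, self.fp_params.encoding) for m in molecules]
        Z, _ = nf.forward(nf.PackedGraphs.pack(feats), self.fp_params)
        return Z

    def predict_proba(self, molecules: list[MoleculeGraph], on_error: str = "raise"):
        return predict_proba(self, molecules, on_error=on_error)


class _Adam:
    def __init__(self, lr: float):
        self.lr = lr
        self.m: dict = {}
        self.v: dict = {}
        self.t = 0
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8

    def step(self, params_get, params_set, grads: dict) -> None:
        self.t += 1
        for k, g in grads.items():
            if k not in self.m:
                self.m[k] = np.zeros_like(g)
                self.v[k] = np.zeros_like(g)
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * np.square(g)
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            params_set(k, params_get(k) - self.lr * mhat / (np.sqrt(vhat) + self.eps))


def _batch_grads(packed, y, fp_params, head):
    """Joint loss value and gradients for one minibatch."""
    B = len(y)
    Z, cache = nf.forward(packed, fp_params)
    logits, hcache = head_forward(Z, head, training=True)
    p = _sigmoid(logits)
    ce = float(np.mean(np.log1p(np.exp(-np.abs(logits))) + np.maximum(logits, 0.0) - logits * y))
    dlogit = (p - y) / B
    head_grads, dZ = head_backward(dlogit, head, hcache)
    dZ = dZ + 2.0 * head.lambda2 * Z
    fp_grads = nf.backward(packed, fp_params, cache, dZ)
    if head.hidden_units:
        wnorm = float((head.W1 ** 2).sum() + (head.W2 ** 2).sum())
    else:
        wnorm = float((head.w ** 2).sum())
    batch_loss = ce + head.lambda1 * wnorm + head.lambda2 * float((Z ** 2).sum())
    return batch_loss, fp_grads, head_grads


def train_adr_model(
    molecules: list[MoleculeGraph],
    y: np.ndarray,
    config: TrainConfig | None = None,
) -> ADRModel:
    """Jointly train fingerprint network and head for one ADR.

    Deterministic given ``config.seed``; returns the model with its per-epoch
    mean training loss history.
    """
    config = config or TrainConfig()
    y = np.asarray(y, dtype=float).ravel()
    if len(molecules) != len(y):
        raise PredictorError(f"{len(molecules)} molecules vs {len(y)} labels")
    n_pos, n_neg = int(y.sum()), int(len(y) - y.sum())
    if n_pos < 2 or n_neg < 2:
        raise PredictorError(f"need >= 2 positives and >= 2 negatives, got {n_pos}/{n_neg}")

    rng = np.random.default_rng(config.seed)
    fp_params = nf.init_params(
        R=config.R, K=config.K, hidden_dims=config.hidden_dims,
        seed=int(rng.integers(0, 2**31 - 1)), activation=config.activation,
        write_levels=config.write_levels,
    )
    head = init_head(config.K, config, rng)
    feats = [nf.featurize_molecule(m, fp_params.encoding) for m in molecules]

    adam = _Adam(config.learning_rate)

    def get(key):
        return fp_params.get(key) if isinstance(key, tuple) else getattr(head, key)

    def setp(key, value):
        if isinstance(key, tuple):
            if key[0] == "H":
                fp_params.H[key[1]][key[2]] = value
            elif key[0] == "b":
                fp_params.b[key[1]] = value
            else:
                fp_params.F[key[1]] = value
        else:
            setattr(head, key, value)

    n = len(feats)
    history = []
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            packed = nf.PackedGraphs.pack([feats[i] for i in idx])
            batch_loss, fp_grads, head_grads = _batch_grads(packed, y[idx], fp_params, head)
            if not np.isfinite(batch_loss):
                raise PredictorError(f"non-finite loss at epoch {_epoch}")
            adam.step(get, setp, {**fp_grads, **head_grads})
            epoch_loss += batch_loss
            n_batches += 1
        history.append(epoch_loss / n_batches)
    return ADRModel(fp_params=fp_params, head=head, config=config, history=history)


def predict_proba(model: ADRModel, molecules: list[MoleculeGraph], on_error: str = "raise"):
    """Predicted ADR probabilities, deterministic (batch norm in inference mode).

    With ``on_error='record'`` unfeaturizable molecules yield NaN plus an
    explicit per-molecule error entry instead of aborting.
    """
    feats, errors, ok = [], {}, []
    for i, m in enumerate(molecules):
        try:
            feats.append(nf.featurize_molecule(m, model.fp_params.encoding))
            ok.append(i)
        except Exception as exc:  # noqa: BLE001 - reported per molecule
            if on_error == "raise":
                raise
            errors[m.mol_id] = str(exc)
    probs = np.full(len(molecules), np.nan)
    if feats:
        Z, _ = nf.forward(nf.PackedGraphs.pack(feats), model.fp_params)
        logits, _ = head_forward(Z, model.head, training=False)
        probs[ok] = _sigmoid(logits)
    if on_error == "record":
        return probs, errors
    return probs


def cross_validate(
    molecules: list[MoleculeGraph],
    labels: LabelMatrix | np.ndarray,
    config: TrainConfig | None = None,
    folds: int = 10,
):
    """Stratified K-fold out-of-fold predictions for every ADR column.

    Returns (scores, fold_assignments): scores is N x M with each drug scored
    exactly once per ADR by a model that never saw it; fold_assignments is
    M x N.  ADRs with fewer positives (or negatives) than ``folds`` fall back
    to fewer folds with a warning.
    """
    config = config or TrainConfig()
    if folds < 2:
        raise PredictorError("folds must be >= 2")
    Y = labels.y if isinstance(labels, LabelMatrix) else np.asarray(labels)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, m = Y.shape
    scores = np.full((n, m), np.nan)
    assignments = np.full((m, n), -1, dtype=int)
    for col in range(m):
        y = Y[:, col].astype(int)
        n_pos, n_neg = int(y.sum()), int(len(y) - y.sum())
        eff = min(folds, n_pos, n_neg)
        if eff < folds:
            logger.warning("ADR column %d: only %d/%d pos/neg, using %d folds", col, n_pos, n_neg, eff)
        if eff < 2:
            raise PredictorError(f"ADR column {col} has too few samples of one class for CV")
        skf = StratifiedKFold(n_splits=eff, shuffle=True, random_state=config.seed)
        for fold, (train_idx, test_idx) in enumerate(skf.split(np.zeros(n), y)):
            model = train_adr_model([molecules[i] for i in train_idx], y[train_idx], config)
            scores[test_idx, col] = predict_proba(model, [molecules[i] for i in test_idx])
            assignments[col, test_idx] = fold
    return scores, assignments


def config_to_dict(config: TrainConfig) -> dict:
    return asdict(config)


def grid_search(
    molecules: list[MoleculeGraph],
    y: np.ndarray,
    base_config: TrainConfig,
    grid: dict[str, list],
    folds: int = 3,
):
    """Exhaustive hyper-parameter grid selected by cross-validated F1.

    ``grid`` maps TrainConfig field names to candidate values.  Ties in F1
    break toward stronger regularization (larger lambda1, then lambda2).
    Returns (best_config, results) where results is a list of
    (config, f1) pairs in evaluation order.
    """
    import itertools

    from .evaluation import _confusion_metrics

    names = sorted(grid)
    results = []
    for combo in itertools.product(*(grid[n] for n in names)):
        cfg = TrainConfig(**{**config_to_dict(base_config), **dict(zip(names, combo))})
        scores, _ = cross_validate(molecules, np.asarray(y).reshape(-1, 1), cfg, folds=folds)
        f1 = _confusion_metrics(
            np.asarray(y).ravel(), (scores[:, 0] >= cfg.threshold).astype(int)
        )["f1"]
        results.append((cfg, float(f1)))
    best, _ = max(results, key=lambda r: (r[1], r[0].lambda1, r[0].lambda2))
    return best, results
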