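"""Neural proportional-hazards risk model.

A fully connected network (ReLU activations, inverted dropout) maps the
signature genes of one sample to a single linear risk output eta — the log
relative hazard. The training loss is the negative Breslow partial
log-likelihood of eta over the samples of a batch (risk sets are formed
within the batch, the standard device for mini-batch Cox training; full
batch is used below a size threshold and for exactness checks). The final
layer has no bias: the partial likelihood is shift-invariant, so a bias is
unidentifiable.

The gradient of the loss with respect to eta has the closed form
``-(d_i - exp(eta_i) * A_i)/m`` (see :func:`tepcox.survival.cox_loglik_grad_eta`)
and is backpropagated through the layers analytically; optimization is Adam
with decoupled L2 weight decay, early stopping on a held-out event-stratified
fraction. All randomness — initialization, the validation split, batch
shuffling, dropout masks — flows from a single seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._containers import ExpressionMatrix
from .survival import _check_outcomes, cox_loglik_grad_eta, cox_partial_loglik

__all__ = [
    "TrainConfig",
    "DeepCoxModel",
    "RiskScores",
    "train_deepcox",
    "predict_risk",
    "save_model",
    "load_model",
]

_FORMAT_VERSION = 1


@dataclass
class TrainConfig:
    """Architecture and optimizer settings for :func:`train_deepcox`."""

    hidden: tuple[int, ...] = (64, 32)
    dropout: float = 0.1
    learning_rate: float = 1e-3
    weight_decay: float = 1e-4
    max_epochs: int = 300
    batch_size: int | None = None  # None: full batch if n < 256, else 128
    val_frac: float = 0.2  # 0 disables early stopping
    patience: int = 10

    def validate(self):
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must lie in [0, 1)")
        if any(h <= 0 for h in self.hidden):
            raise ValueError("hidden widths must be positive")
        if self.batch_size is not None and self.batch_size < 64:
            raise ValueError("batch size below 64 gives unstable risk sets")
        if not 0 <= self.val_frac < 1:
            raise ValueError("val_frac must lie in [0, 1)")


@dataclass
class RiskScores:
    """Per-sample risk scores on the log-relative-hazard scale."""

    sample_ids: list[str]
    score: np.ndarray

    def __post_init__(self):
        self.score = np.asarray(self.score, dtype=float)
        if len(self.sample_ids) != len(self.score):
            raise ValueError("ids and scores must align")
        if not np.all(np.isfinite(self.score)):
            raise ValueError("risk scores must be finite")

    def aligned_to(self, sample_ids: list[str]) -> np.ndarray:
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        return self.score[[idx[s] for s in sample_ids]]


@dataclass
class DeepCoxModel:
    """Trained network: weights, architecture, signature gene list, log."""

    gene_ids: list[str]
    hidden: tuple[int, ...]
    dropout: float
    weights: list[np.ndarray]  # per layer; last layer shape (width, 1)
    biases: list[np.ndarray]  # per hidden layer (final layer has no bias)
    seed: int
    train_log: dict = field(default_factory=dict)

    def __post_init__(self):
        dims = [len(self.gene_ids), *self.hidden, 1]
        for i, w in enumerate(self.weights):
            if w.shape != (dims[i], dims[i + 1]):
                raise ValueError(
                    f"layer {i} weight shape {w.shape} != {(dims[i], dims[i+1])}"
                )
        if len(self.biases) != len(self.hidden):
            raise ValueError("one bias vector per hidden layer expected")

    def forward(self, X: np.ndarray) -> np.ndarray:
        """Evaluation-mode forward pass (dropout disabled)."""
        h = X
        for w, b in zip(self.weights[:-1], self.biases):
            h = np.maximum(h @ w + b, 0.0)
        return (h @ self.weights[-1]).ravel()


def _init_params(dims, rng):
    weights, biases = [], []
    for i in range(len(dims) - 1):
        w = rng.standard_normal((dims[i], dims[i + 1])) * np.sqrt(2.0 / dims[i])
        weights.append(w)
        if i < len(dims) - 2:
            biases.append(np.zeros(dims[i + 1]))
    return weights, biases


def _forward_train(X, weights, biases, dropout, rng):
    """Training forward pass; returns eta and the per-layer caches."""
    h = X
    caches = []
    for w, b in zip(weights[:-1], biases):
        z = h @ w + b
        a = np.maximum(z, 0.0)
        if dropout > 0:
            mask = (rng.uniform(size=a.shape) >= dropout) / (1.0 - dropout)
            a = a * mask
        else:
            mask = None
        caches.append((h, z, mask))
        h = a
    eta = (h @ weights[-1]).ravel()
    caches.append((h, None, None))
    return eta, caches


def _backward(grad_eta, weights, caches, dropout):
    """Backpropagate d(loss)/d(eta) through the layers."""
    grads_w = [None] * len(weights)
    grads_b = [None] * (len(weights) - 1)
    h_last = caches[-1][0]
    grads_w[-1] = h_last.T @ grad_eta[:, None]
    delta = grad_eta[:, None] @ weights[-1].T
    for i in range(len(weights) - 2, -1, -1):
        h, z, mask = caches[i]
        if mask is not None:
            delta = delta * mask
        delta = delta * (z > 0)
        grads_w[i] = h.T @ delta
        grads_b[i] = delta.sum(axis=0)
        if i > 0:
            delta = delta @ weights[i].T
    return grads_w, grads_b


def _stratified_split(event, val_frac, rng):
    n = len(event)
    val = np.zeros(n, dtype=bool)
    for status in (0, 1):
        idx = rng.permutation(np.flatnonzero(event == status))
        k = int(round(val_frac * len(idx)))
        val[idx[:k]] = True
    return ~val, val


def train_deepcox(
    expr_selected: ExpressionMatrix,
    time,
    event,
    config: TrainConfig | None = None,
    seed: int = 0,
) -> DeepCoxModel:
    """Train the network on preprocessed signature-gene expression.

    ``expr_selected`` must already be restricted to the signature genes and
    transformed with frozen preprocessing parameters. Requires at least 20
    events. Deterministic given ``seed``.
    """
    config = config or TrainConfig()
    config.validate()
    time, event = _check_outcomes(time, event)
    X = expr_selected.values.T.astype(float)  # samples x genes
    n, p = X.shape
    if n != len(time):
        raise ValueError("expression samples must align with outcomes")
    if event.sum() < 20:
        raise ValueError(f"need at least 20 events, got {int(event.sum())}")

    rng = np.random.default_rng(seed)
    dims = [p, *config.hidden, 1]
    weights, biases = _init_params(dims, rng)

    if config.val_frac > 0:
        tr_mask, va_mask = _stratified_split(event, config.val_frac, rng)
        if event[va_mask].sum() == 0 or event[tr_mask].sum() == 0:
            raise ValueError("validation split has no events; lower val_frac")
    else:
        tr_mask = np.ones(n, dtype=bool)
        va_mask = np.zeros(n, dtype=bool)
    Xtr, ttr, etr = X[tr_mask], time[tr_mask], event[tr_mask]
    Xva, tva, eva = X[va_mask], time[va_mask], event[va_mask]
    n_tr = len(ttr)

    if config.batch_size is None:
        batch_size = n_tr if n_tr < 256 else 128
    else:
        batch_size = min(config.batch_size, n_tr)
    full_batch = batch_size >= n_tr

    # Adam state
    m_w = [np.zeros_like(w) for w in weights]
    v_w = [np.zeros_like(w) for w in weights]
    m_b = [np.zeros_like(b) for b in biases]
    v_b = [np.zeros_like(b) for b in biases]
    b1, b2, eps = 0.9, 0.999, 1e-8
    step = 0

    def monitor_loglik():
        if va_mask.any():
            eta = _eval_eta(Xva, weights, biases)
            return cox_partial_loglik(eta, tva, eva) / max(len(tva), 1)
        eta = _eval_eta(Xtr, weights, biases)
        return cox_partial_loglik(eta, ttr, etr) / n_tr

    def _eval_eta(Xm, ws, bs):
        h = Xm
        for w, b in zip(ws[:-1], bs):
            h = np.maximum(h @ w + b, 0.0)
        return (h @ ws[-1]).ravel()

    best_ll = -np.inf
    best_weights = [w.copy() for w in weights]
    best_biases = [b.copy() for b in biases]
    best_epoch = 0
    history = []
    since_best = 0
    lr = config.learning_rate
    for epoch in range(1, config.max_epochs + 1):
        if config.val_frac == 0 and config.max_epochs > 1:
            # smooth exponential annealing: without early stopping the run
            # should converge tightly (the linear-equivalence contract)
            frac = (epoch - 1) / (config.max_epochs - 1)
            lr = config.learning_rate * 10.0 ** (-4 * frac)
        order = rng.permutation(n_tr) if not full_batch else np.arange(n_tr)
        for start in range(0, n_tr, batch_size):
            idx = order[start : start + batch_size]
            if etr[idx].sum() < 2:
                warnings.warn(
                    "mini-batch with fewer than 2 events skipped",
                    RuntimeWarning,
                    stacklevel=2,
                )
                continue
            eta, caches = _forward_train(
                Xtr[idx], weights, biases, config.dropout, rng
            )
            _, g_eta, _ = cox_loglik_grad_eta(eta, ttr[idx], etr[idx])
            grad_eta = -g_eta / len(idx)  # d(loss)/d(eta)
            gw, gb = _backward(grad_eta, weights, caches, config.dropout)
            step += 1
            lr_t = lr * np.sqrt(1 - b2**step) / (1 - b1**step)
            for i in range(len(weights)):
                g = gw[i] + config.weight_decay * weights[i]
                m_w[i] = b1 * m_w[i] + (1 - b1) * g
                v_w[i] = b2 * v_w[i] + (1 - b2) * g**2
                weights[i] -= lr_t * m_w[i] / (np.sqrt(v_w[i]) + eps)
            for i in range(len(biases)):
                m_b[i] = b1 * m_b[i] + (1 - b1) * gb[i]
                v_b[i] = b2 * v_b[i] + (1 - b2) * gb[i] ** 2
                biases[i] -= lr_t * m_b[i] / (np.sqrt(v_b[i]) + eps)
        ll = monitor_loglik()
        history.append(ll)
        if ll > best_ll + 1e-12:
            best_ll = ll
            best_weights = [w.copy() for w in weights]
            best_biases = [b.copy() for b in biases]
            best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            # anneal on plateau so full-batch runs can converge tightly
            if since_best % 20 == 0 and lr > 1e-6:
                lr *= 0.5
        if config.val_frac > 0 and since_best >= config.patience:
            break
    if best_epoch == 0:
        warnings.warn(
            "training never improved on the initial model; returning it",
            RuntimeWarning,
            stacklevel=2,
        )
    if full_batch and config.dropout == 0 and config.val_frac == 0:
        # deterministic polish: backtracking-line-search gradient descent on
        # the full objective, so exactness contracts (e.g. the linear
        # reduction to the Newton Cox solution) hold tightly
        best_weights, best_biases = _polish_full_batch(
            Xtr, ttr, etr, best_weights, best_biases, config.weight_decay
        )
    return DeepCoxModel(
        gene_ids=list(expr_selected.gene_ids),
        hidden=tuple(config.hidden),
        dropout=config.dropout,
        weights=best_weights,
        biases=best_biases,
        seed=seed,
        train_log={
            "monitor_loglik_per_epoch": history,
            "best_epoch": best_epoch,
            "best_monitor_loglik": best_ll,
            "n_train": int(n_tr),
            "n_val": int(va_mask.sum()),
            "batch_size": int(batch_size),
        },
    )


def _polish_full_batch(X, time, event, weights, biases, weight_decay,
                       max_iter=300, tol=1e-10):
    """Gradient descent with backtracking on the full-batch objective."""
    n = len(time)
    rng = np.random.default_rng(0)  # unused by dropout-free forward pass

    def objective(ws, bs):
        eta, _ = _forward_train(X, ws, bs, 0.0, rng)
        ll = cox_partial_loglik(eta, time, event)
        pen = 0.5 * weight_decay * sum(float((w**2).sum()) for w in ws)
        return -ll / n + pen

    obj = objective(weights, biases)
    step = 1.0
    for _ in range(max_iter):
        eta, caches = _forward_train(X, weights, biases, 0.0, rng)
        _, g_eta, _ = cox_loglik_grad_eta(eta, time, event)
        gw, gb = _backward(-g_eta / n, weights, caches, 0.0)
        gw = [g + weight_decay * w for g, w in zip(gw, weights)]
        gnorm2 = sum(float((g**2).sum()) for g in gw)
        gnorm2 += sum(float((g**2).sum()) for g in gb)
        if gnorm2 < tol**2:
            break
        step = min(step * 2.0, 1e3)
        for _ in range(60):
            cand_w = [w - step * g for w, g in zip(weights, gw)]
            cand_b = [b - step * g for b, g in zip(biases, gb)]
            cand_obj = objective(cand_w, cand_b)
            if cand_obj <= obj - 1e-4 * step * gnorm2:
                break
            step /= 2
        else:
            break
        if obj - cand_obj < 1e-14 * (abs(obj) + 1):
            weights, biases, obj = cand_w, cand_b, cand_obj
            break
        weights, biases, obj = cand_w, cand_b, cand_obj
    return weights, biases


def predict_risk(model: DeepCoxModel, expr: ExpressionMatrix) -> RiskScores:
    """Evaluation-mode risk scores, aligned to the model's gene list.

    Deterministic (dropout disabled) and invariant to sample and gene order
    of ``expr``; genes missing from ``expr`` raise.
    """
    try:
        sub = expr.subset_genes(model.gene_ids)
    except KeyError as exc:
        raise ValueError(f"expression lacks signature genes: {exc}") from exc
    scores = model.forward(sub.values.T)
    return RiskScores(sample_ids=list(sub.sample_ids), score=scores)


def save_model(model: DeepCoxModel, path) -> None:
    """Persist to a documented JSON container (text; bitwise round trip)."""
    path = Path(path)
    payload = {
        "format": "tepcox-deepcox-model",
        "version": _FORMAT_VERSION,
        "gene_ids": model.gene_ids,
        "hidden": list(model.hidden),
        "dropout": model.dropout,
        "seed": model.seed,
        "train_log": model.train_log,
        "weights": [[w.shape, [h.hex() for h in w.ravel()]] for w in model.weights],
        "biases": [[b.shape, [h.hex() for h in b.ravel()]] for b in model.biases],
    }
    def _enc(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        raise TypeError(type(o))
    path.write_text(json.dumps(payload, default=_enc))


def load_model(path) -> DeepCoxModel:
    """Load a model saved by :func:`save_model`; errors on version mismatch."""
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise ValueError(f"corrupted model file {path}: {exc}") from exc
    if not isinstance(payload, dict) or payload.get("format") != "tepcox-deepcox-model":
        raise ValueError(f"{path} is not a model file")
    if payload.get("version") != _FORMAT_VERSION:
        raise ValueError(
            f"model format version {payload.get('version')} unsupported "
            f"(expected {_FORMAT_VERSION})"
        )
    def _arr(entry):
        shape, hexes = entry
        return np.array([float.fromhex(h) for h in hexes]).reshape(shape)
    return DeepCoxModel(
        gene_ids=list(payload["gene_ids"]),
        hidden=tuple(payload["hidden"]),
        dropout=float(payload["dropout"]),
        weights=[_arr(e) for e in payload["weights"]],
        biases=[_arr(e) for e in payload["biases"]],
        seed=int(payload["seed"]),
        train_log=payload.get("train_log", {}),
    )
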