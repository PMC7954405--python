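"""Single- and two-branch GRU discharge-disposition classifiers.

The single-branch model runs one GRU over the hourly vitals matrix and feeds
its final hidden state (128 units) to a sigmoid linear head. The parallel
model adds an independent GRU branch over the daily actigraphy feature rows;
the two final hidden states are concatenated (256) before the head — the two
branches consume their modalities on separate time scales and share no
parameters.

Training minimizes binary cross-entropy on each stay's final prediction with
Adam (lr 1e-3, L2 weight decay 1e-3), batches of 32, 25% dropout on branch
inputs and on the pre-head hidden representation, and early stopping on the
loss of a random 20% carve-out of the development set. Risk-score
trajectories at each 24-h boundary are exposed for monitoring; supervising
them is available behind a config flag but off by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from icu_acuity.nn import (
    F4,
    Adam,
    bce_loss,
    gru_backward,
    gru_backward_final,
    gru_forward,
    init_gru_params,
    sigmoid,
)

EHR_INPUT_DIM = 6
ACT_INPUT_DIM = 9
WINDOW_HOURS = 24


class ModelContractError(ValueError):
    pass


class TrainingError(ValueError):
    pass


@dataclass(frozen=True)
class ModelConfig:
    """Training hyperparameters (defaults follow the study protocol)."""

    hidden_dim: int = 128
    dropout: float = 0.25
    learning_rate: float = 1e-3
    weight_decay: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 100
    patience: int = 10
    early_stop_fraction: float = 0.20
    seed: int = 0
    grad_clip: float = 5.0
    supervise_windows: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout < 1.0:
            raise ModelContractError("dropout must lie in [0, 1)")
        if min(self.learning_rate, self.weight_decay) < 0 or self.batch_size < 1:
            raise ModelContractError("invalid optimizer parameters")
        if self.max_epochs < 1 or self.patience < 1:
            raise ModelContractError("max_epochs and patience must be positive")


@dataclass
class StayTensors:
    """Preprocessed inputs for one stay (branch name -> (T, I) float32)."""

    inputs: dict[str, np.ndarray]
    label: int
    stay_id: str = ""


class GRUClassifier:
    """GRU branch(es) + sigmoid linear head over concatenated final states.

    Parameters live in a flat name->array dict (``ehr.W``, ``ehr.U``,
    ``ehr.b``, optionally ``act.*``, plus ``head.w`` and ``head.b``) so they
    can be checkpointed and selectively transferred.
    """

    def __init__(
        self,
        branch_dims: dict[str, int],
        hidden_dim: int,
        rng: np.random.Generator,
    ):
        self.branch_dims = dict(branch_dims)
        self.hidden_dim = hidden_dim
        self.params: dict[str, np.ndarray] = {}
        for name, input_dim in self.branch_dims.items():
            for k, v in init_gru_params(input_dim, hidden_dim, rng).items():
                self.params[f"{name}.{k}"] = v
        concat = hidden_dim * len(self.branch_dims)
        bound = 1.0 / math.sqrt(concat)
        self.params["head.w"] = rng.uniform(-bound, bound, size=(concat,)).astype(F4)
        self.params["head.b"] = rng.uniform(-bound, bound, size=(1,)).astype(F4)
        self.frozen: set[str] = set()

    @property
    def branch_names(self) -> list[str]:
        return list(self.branch_dims)

    def clone_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_params(self, params: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = params[k].copy()

    # -- batched forward/backward ------------------------------------------

    def _check_batch(self, batch: dict[str, tuple[np.ndarray, np.ndarray]]) -> None:
        if set(batch) != set(self.branch_dims):
            raise ModelContractError(
                f"model expects modalities {sorted(self.branch_dims)}, got {sorted(batch)}"
            )

    def forward(
        self,
        batch: dict[str, tuple[np.ndarray, np.ndarray]],
        train: bool = False,
        rng: np.random.Generator | None = None,
        dropout: float = 0.0,
    ):
        """Batch forward pass; returns (logits (B,), cache for backward)."""
        self._check_batch(batch)
        caches = {}
        finals = []
        for name in self.branch_names:
            X, lengths = batch[name]
            X = X.astype(F4, copy=False)
            if train and dropout > 0.0:
                keep = (rng.random(X.shape) >= dropout).astype(F4) / F4(1.0 - dropout)
                X = X * keep
            _, h_final, cache = gru_forward(
                X, lengths, self.params[f"{name}.W"], self.params[f"{name}.U"], self.params[f"{name}.b"]
            )
            caches[name] = cache
            finals.append(h_final)
        h_cat = np.concatenate(finals, axis=1)
        hid_mask = None
        if train and dropout > 0.0:
            hid_mask = (rng.random(h_cat.shape) >= dropout).astype(F4) / F4(1.0 - dropout)
            h_cat = h_cat * hid_mask
        logits = h_cat @ self.params["head.w"] + self.params["head.b"][0]
        return logits, (caches, h_cat, hid_mask)

    def backward(self, dlogits: np.ndarray, fwd_cache) -> dict[str, np.ndarray]:
        caches, h_cat, hid_mask = fwd_cache
        grads: dict[str, np.ndarray] = {}
        grads["head.w"] = (h_cat.T @ dlogits).astype(F4)
        grads["head.b"] = np.array([dlogits.sum()], dtype=F4)
        dh_cat = dlogits[:, None] * self.params["head.w"][None, :]
        if hid_mask is not None:
            dh_cat = dh_cat * hid_mask
        H = self.hidden_dim
        for i, name in enumerate(self.branch_names):
            cache = caches[name]
            dh_final = np.ascontiguousarray(dh_cat[:, i * H : (i + 1) * H], dtype=F4)
            dW, dU, db = gru_backward_final(dh_final, cache, self.params[f"{name}.U"])
            grads[f"{name}.W"] = dW
            grads[f"{name}.U"] = dU
            grads[f"{name}.b"] = db
        return grads

    # -- per-stay prediction -----------------------------------------------

    def predict(self, stay: StayTensors) -> tuple[float, np.ndarray]:
        """Final risk score and the per-24-h-window score trajectory.

        Evaluation mode (no dropout), deterministic. The trajectory applies
        the head to the hidden state at each 24-h boundary; its last entry is
        the final score.
        """
        self._check_batch(stay.inputs)
        h_by_branch = {}
        for name in self.branch_names:
            x = stay.inputs[name]
            if x.ndim != 2 or x.shape[1] != self.branch_dims[name]:
                raise ModelContractError(
                    f"branch '{name}' expects (T, {self.branch_dims[name]}) input, got {x.shape}"
                )
            if x.shape[0] < 1:
                raise ModelContractError(f"branch '{name}' received an empty sequence")
            X = x[None].astype(F4, copy=False)
            h_seq, _, _ = gru_forward(
                X,
                np.array([x.shape[0]]),
                self.params[f"{name}.W"],
                self.params[f"{name}.U"],
                self.params[f"{name}.b"],
                return_sequence=True,
            )
            h_by_branch[name] = h_seq[0]
        T = h_by_branch["ehr"].shape[0]
        n_windows = max(1, math.ceil(T / WINDOW_HOURS))
        scores = np.empty(n_windows)
        w = self.params["head.w"]
        b = self.params["head.b"][0]
        for d in range(n_windows):
            parts = []
            for name in self.branch_names:
                if name == "ehr":
                    t_idx = min((d + 1) * WINDOW_HOURS, T) - 1
                else:  # daily-resolution branch: one step per 24-h window
                    t_idx = min(d, h_by_branch[name].shape[0] - 1)
                parts.append(h_by_branch[name][t_idx])
            logit = float(np.concatenate(parts) @ w + b)
            scores[d] = 1.0 / (1.0 + math.exp(-logit))
        return float(scores[-1]), scores


def build_single_rnn(
    input_dim: int = EHR_INPUT_DIM,
    config: ModelConfig = ModelConfig(),
    rng: np.random.Generator | None = None,
) -> GRUClassifier:
    """Vitals-only model: one GRU branch ('ehr') + linear head (128 -> 1)."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    return GRUClassifier({"ehr": input_dim}, config.hidden_dim, rng)


def build_parallel_rnn(
    ehr_input_dim: int = EHR_INPUT_DIM,
    act_input_dim: int = ACT_INPUT_DIM,
    config: ModelConfig = ModelConfig(),
    rng: np.random.Generator | None = None,
) -> GRUClassifier:
    """Two-branch multi-resolution model ('ehr' hourly + 'act' daily, 256 -> 1)."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    return GRUClassifier(
        {"ehr": ehr_input_dim, "act": act_input_dim}, config.hidden_dim, rng
    )


def _pad_batch(stays: list[StayTensors], branch_names: list[str]):
    batch = {}
    for name in branch_names:
        xs = [s.inputs[name] for s in stays]
        lengths = np.array([x.shape[0] for x in xs])
        T = int(lengths.max())
        X = np.zeros((len(xs), T, xs[0].shape[1]), dtype=F4)
        for i, x in enumerate(xs):
            X[i, : x.shape[0]] = x
        batch[name] = (X, lengths)
    return batch


def _dataset_loss(model: GRUClassifier, stays: list[StayTensors], y: np.ndarray) -> float:
    logits, _ = model.forward(_pad_batch(stays, model.branch_names))
    return bce_loss(logits, y)


def _elementwise_bce(logits: np.ndarray, y: np.ndarray) -> np.ndarray:
    z = logits.astype(np.float64)
    return np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))


def _window_supervised_step(
    model: GRUClassifier,
    stays: list[StayTensors],
    y: np.ndarray,
    dropout: float,
    rng: np.random.Generator | None,
):
    """Loss and gradients when every 24-h window prediction is supervised.

    Each stay contributes the mean BCE over its window-boundary predictions
    (the final prediction is the last window's). Returns (loss, grads);
    grads is None in evaluation mode (dropout <= 0 and rng None).
    """
    train_mode = rng is not None
    batch = _pad_batch(stays, model.branch_names)
    h_seqs, caches, lengths = {}, {}, {}
    for name in model.branch_names:
        X, lens = batch[name]
        if train_mode and dropout > 0.0:
            keep = (rng.random(X.shape) >= dropout).astype(F4) / F4(1.0 - dropout)
            X = X * keep
        h_seq, _, cache = gru_forward(
            X,
            lens,
            model.params[f"{name}.W"],
            model.params[f"{name}.U"],
            model.params[f"{name}.b"],
            return_sequence=True,
        )
        h_seqs[name], caches[name], lengths[name] = h_seq, cache, lens
    H = model.hidden_dim
    ehr_len = lengths["ehr"]
    n_windows = np.maximum(1, np.ceil(ehr_len / WINDOW_HOURS)).astype(int)
    weight = 1.0 / (n_windows * len(stays))
    w = model.params["head.w"]
    b0 = model.params["head.b"][0]
    dh_seq = {name: np.zeros_like(h_seqs[name]) for name in model.branch_names}
    gw = np.zeros_like(w, dtype=np.float64)
    gb = 0.0
    total = 0.0
    for d in range(int(n_windows.max())):
        sel = np.flatnonzero(n_windows > d)
        idx = {}
        parts = []
        for name in model.branch_names:
            if name == "ehr":
                t = np.minimum((d + 1) * WINDOW_HOURS, ehr_len[sel]) - 1
            else:
                t = np.minimum(d, lengths[name][sel] - 1)
            idx[name] = t
            parts.append(h_seqs[name][sel, t])
        h_cat = np.concatenate(parts, axis=1)
        mask = None
        if train_mode and dropout > 0.0:
            mask = (rng.random(h_cat.shape) >= dropout).astype(F4) / F4(1.0 - dropout)
            h_cat = h_cat * mask
        logits = h_cat @ w + b0
        wb = weight[sel]
        total += float(np.sum(wb * _elementwise_bce(logits, y[sel])))
        if not train_mode:
            continue
        dlogit = ((sigmoid(logits) - y[sel]) * wb).astype(F4)
        gw += h_cat.T.astype(np.float64) @ dlogit
        gb += float(dlogit.sum())
        dh_cat = dlogit[:, None] * w[None, :]
        if mask is not None:
            dh_cat = dh_cat * mask
        for i, name in enumerate(model.branch_names):
            dh_seq[name][sel, idx[name]] += dh_cat[:, i * H : (i + 1) * H]
    if not train_mode:
        return total, None
    grads = {"head.w": gw.astype(F4), "head.b": np.array([gb], dtype=F4)}
    for name in model.branch_names:
        dW, dU, db = gru_backward(dh_seq[name], caches[name], model.params[f"{name}.U"])
        grads[f"{name}.W"] = dW
        grads[f"{name}.U"] = dU
        grads[f"{name}.b"] = db
    return total, grads


def train(
    model: GRUClassifier,
    stays: list[StayTensors],
    config: ModelConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Train in place with Adam, dropout, and loss-based early stopping.

    A random ``early_stop_fraction`` of the provided development stays is held
    out; training stops after ``patience`` epochs without improvement of the
    held-out loss and the best parameters are restored. Returns the training
    history (epoch, train_loss, heldout_loss).
    """
    if not stays:
        raise TrainingError("empty training dataset")
    labels = np.array([s.label for s in stays])
    if labels.min() == labels.max():
        raise TrainingError("training requires both outcome classes")
    for s in stays:
        if set(s.inputs) != set(model.branch_dims):
            raise ModelContractError(
                f"stay {s.stay_id!r} modalities {sorted(s.inputs)} do not match model"
            )
    rng = rng if rng is not None else np.random.default_rng(config.seed)

    n = len(stays)
    n_es = min(max(1, int(round(config.early_stop_fraction * n))), n - 1)
    perm = rng.permutation(n)
    es_idx, tr_idx = perm[:n_es], perm[n_es:]
    es_set = [stays[i] for i in es_idx]
    tr_set = [stays[i] for i in tr_idx]
    y_es = labels[es_idx]
    y_tr = labels[tr_idx]

    opt = Adam(
        model.params,
        lr=config.learning_rate,
        weight_decay=config.weight_decay,
        clip_norm=config.grad_clip,
    )
    best_loss = math.inf
    best_params = model.clone_params()
    best_epoch = 0
    bad_epochs = 0
    history = []
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(len(tr_set))
        train_losses = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            batch_stays = [tr_set[i] for i in idx]
            yb = y_tr[idx].astype(F4)
            if config.supervise_windows:
                loss, grads = _window_supervised_step(
                    model, batch_stays, yb, config.dropout, rng
                )
                train_losses.append(loss)
            else:
                batch = _pad_batch(batch_stays, model.branch_names)
                logits, cache = model.forward(
                    batch, train=True, rng=rng, dropout=config.dropout
                )
                train_losses.append(bce_loss(logits, yb))
                dlogits = ((sigmoid(logits) - yb) / F4(len(idx))).astype(F4)
                grads = model.backward(dlogits, cache)
            opt.step(grads, skip=model.frozen)
        if config.supervise_windows:
            heldout, _ = _window_supervised_step(
                model, es_set, y_es.astype(F4), 0.0, None
            )
        else:
            heldout = _dataset_loss(model, es_set, y_es.astype(F4))
        history.append(
            {"epoch": epoch, "train_loss": float(np.mean(train_losses)), "heldout_loss": heldout}
        )
        if heldout < best_loss - 1e-7:
            best_loss = heldout
            best_params = model.clone_params()
            best_epoch = epoch
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= config.patience:
                break
    model.set_params(best_params)
    hist = pd.DataFrame(history)
    hist.attrs["best_epoch"] = best_epoch
    return hist


# ---------------------------------------------------------------------------
# Checkpoints: flat named-tensor archive
# ---------------------------------------------------------------------------


def checkpoint_from_model(model: GRUClassifier) -> dict[str, np.ndarray]:
    return model.clone_params()


def save_checkpoint(params: dict[str, np.ndarray], path: str | Path) -> None:
    np.savez(path, **params)


def load_checkpoint(path: str | Path) -> dict[str, np.ndarray]:
    with np.load(path) as f:
        return {k: f[k].copy() for k in f.files}
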