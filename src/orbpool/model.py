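"""Atomistic regression model and training loop.

The model maps each atom's environment descriptor (plus a one-hot encoding
of the atom's own element, which carries the on-site identity the radial
descriptor cannot see) through a small MLP to a per-atom scalar
``eps_i``; a pooling head aggregates these to the molecular prediction.
For wa/owa heads a second MLP produces raw per-atom scores that are
normalized by a softmax over the molecule's atoms, so the weights are
nonnegative and sum to one -- this rigorously enforces size-intensivity.

Training minimizes the joint loss, averaged over the systems of a batch,

    loss_A = alpha * (P_A - E_A)^2 + beta * sum_i (w_iA - l_iA)^2

with beta = 0 for every head except OWA, by Adam with mini-batches,
early stopping on validation energy RMSE, and full determinism for a
fixed seed.  Per-atom outputs are produced in normalized target units and
un-normalized *per atom* before pooling, so extensive (sum) and intensive
heads both scale correctly by construction.

Everything here is NumPy with explicit backpropagation; networks are
small (two hidden layers of a few dozen units) and run on one CPU core.
"""

from __future__ import annotations

import copy
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .core import (
    AtomicSystem,
    ConfigurationError,
    LabeledDataError,
    LabeledDataset,
    ValidationError,
)
from .descriptors import DescriptorConfig, featurize
from .localization import sanitize_fractions
from .pooling import PoolingHead, softmax_weights

__all__ = [
    "ModelConfig",
    "LossConfig",
    "TrainedModel",
    "owa_loss",
    "train",
    "predict",
    "select_alpha_beta",
    "save_model",
    "load_model",
]

logger = logging.getLogger(__name__)

_ACTIVATIONS = {
    "tanh": (np.tanh, lambda a: 1.0 - a * a),
    # softplus with derivative expressed via the stored activation
    "softplus": (
        lambda x: np.logaddexp(0.0, x),
        lambda a: 1.0 - np.exp(-a),
    ),
}


@dataclass
class ModelConfig:
    """Architecture, descriptor, pooling and optimizer settings."""

    descriptor: DescriptorConfig
    pooling: PoolingHead
    energy_net_layers: tuple[int, ...] = (64, 64)
    weight_net_layers: tuple[int, ...] = (64, 64)
    activation: str = "tanh"
    share_trunk: bool = False
    seed: int = 0
    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 500
    patience: int = 50

    def __post_init__(self) -> None:
        if self.activation not in _ACTIVATIONS:
            raise ConfigurationError(f"unknown activation {self.activation!r}")
        if not self.energy_net_layers:
            raise ConfigurationError("energy net needs at least one hidden layer")


@dataclass
class LossConfig:
    """Relative weights of the energy and localization loss terms."""

    alpha: float = 1.0
    beta: float = 0.0

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0 or self.alpha + self.beta <= 0:
            raise ValidationError("need alpha, beta >= 0 and alpha + beta > 0")


class _MLP:
    """Minimal dense network with explicit backprop and Adam state."""

    def __init__(self, sizes: list[int], activation: str, rng: np.random.Generator,
                 act_last: bool = False):
        self.sizes = list(sizes)
        self.activation = activation
        self.act_last = act_last
        self.W = []
        self.b = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            scale = np.sqrt(1.0 / fan_in)
            self.W.append(rng.normal(0.0, scale, (fan_in, fan_out)))
            self.b.append(np.zeros(fan_out))
        self._adam_t = 0
        self._m = [np.zeros_like(w) for w in self.W + self.b]
        self._v = [np.zeros_like(w) for w in self.W + self.b]

    def forward(self, X: np.ndarray):
        act, _ = _ACTIVATIONS[self.activation]
        cache = [X]
        h = X
        n_layers = len(self.W)
        for k, (W, b) in enumerate(zip(self.W, self.b)):
            h = h @ W + b
            if k < n_layers - 1 or self.act_last:
                h = act(h)
            cache.append(h)
        return h, cache

    def backward(self, cache, grad_out: np.ndarray):
        """Accumulate parameter grads; return grad wrt the input."""
        _, dact = _ACTIVATIONS[self.activation]
        self.gW = [None] * len(self.W)
        self.gb = [None] * len(self.b)
        g = grad_out
        n_layers = len(self.W)
        for k in range(n_layers - 1, -1, -1):
            if k < n_layers - 1 or self.act_last:
                g = g * dact(cache[k + 1])
            self.gW[k] = cache[k].T @ g
            self.gb[k] = g.sum(axis=0)
            g = g @ self.W[k].T
        return g

    def adam_step(self, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self._adam_t += 1
        params = self.W + self.b
        grads = self.gW + self.gb
        t = self._adam_t
        for p, g, m, v in zip(params, grads, self._m, self._v):
            m *= beta1
            m += (1 - beta1) * g
            v *= beta2
            v += (1 - beta2) * g * g
            mhat = m / (1 - beta1**t)
            vhat = v / (1 - beta2**t)
            p -= lr * mhat / (np.sqrt(vhat) + eps)

    def state(self):
        return [a.copy() for a in self.W + self.b]

    def load_state(self, state):
        n = len(self.W)
        for k in range(n):
            self.W[k] = state[k].copy()
            self.b[k] = state[n + k].copy()


@dataclass
class TrainedModel:
    """A trained (or freshly initialized) model with its normalizers."""

    config: ModelConfig
    loss_config: LossConfig
    energy_trunk: _MLP = field(repr=False, default=None)
    energy_head: _MLP = field(repr=False, default=None)
    weight_net: _MLP | None = field(repr=False, default=None)
    feat_mean: np.ndarray = None
    feat_std: np.ndarray = None
    y_mean: float = 0.0
    y_std: float = 1.0
    history: list[dict] = field(default_factory=list)
    model_id: str = ""

    # -- feature pipeline ---------------------------------------------------
    def features(self, system: AtomicSystem) -> np.ndarray:
        desc = featurize(system, self.config.descriptor).values
        X = (desc - self.feat_mean) / self.feat_std
        channels = self.config.descriptor.element_channels
        onehot = np.zeros((system.n_atoms, len(channels)))
        col = {z: i for i, z in enumerate(channels)}
        for i, el in enumerate(system.elements):
            onehot[i, col[el]] = 1.0
        return np.hstack([X, onehot])

    def _forward_atoms(self, X: np.ndarray):
        h, trunk_cache = self.energy_trunk.forward(X)
        eps_raw, head_cache = self.energy_head.forward(h)
        z = None
        w_cache = None
        if self.weight_net is not None:
            w_in = h if self.config.share_trunk else X
            z, w_cache = self.weight_net.forward(w_in)
        return eps_raw[:, 0], z[:, 0] if z is not None else None, (
            trunk_cache, head_cache, w_cache
        )

    def predict(
        self, system: AtomicSystem, fractions: np.ndarray | None = None
    ) -> tuple[float, np.ndarray | None]:
        """Predicted energy (eV) and, for weight-bearing heads, the weights."""
        head = self.config.pooling
        X = self.features(system)
        eps_raw, z, _ = self._forward_atoms(X)
        eps = eps_raw * self.y_std + self.y_mean
        weights = None
        if head.uses_weight_net:
            weights = softmax_weights(z, head.mode, 1.0)
        elif head.name == "softmax":
            weights = softmax_weights(eps, head.mode, head.temperature)
        energy = head(eps, weights=weights, fractions=fractions)
        return float(energy), weights


def predict(
    model: TrainedModel, system: AtomicSystem, fractions: np.ndarray | None = None
) -> tuple[float, np.ndarray | None]:
    return model.predict(system, fractions=fractions)


def owa_loss(
    pred_energy: float,
    ref_energy: float,
    pred_weights: np.ndarray | None,
    ref_fractions: np.ndarray | None,
    cfg: LossConfig,
) -> float:
    """Per-system joint loss alpha*(dE)^2 + beta*sum_i (w_i - l_i)^2."""
    loss = cfg.alpha * (float(pred_energy) - float(ref_energy)) ** 2
    if cfg.beta > 0:
        if pred_weights is None or ref_fractions is None:
            raise LabeledDataError("beta > 0 requires weights and reference fractions")
        l = np.asarray(ref_fractions, dtype=float)
        if np.any(l < -1e-10) or abs(float(l.sum()) - 1.0) > 1e-6:
            raise ValidationError("reference fractions must be a simplex vector")
        loss += cfg.beta * float(np.sum((np.asarray(pred_weights) - l) ** 2))
    return float(loss)


# ---------------------------------------------------------------------------
# segment helpers for batched molecules (atoms stacked contiguously)


def _starts(sizes: np.ndarray) -> np.ndarray:
    return np.concatenate([[0], np.cumsum(sizes)[:-1]])


def _seg_sum(x: np.ndarray, starts: np.ndarray) -> np.ndarray:
    return np.add.reduceat(x, starts)


def _seg_softmax(z: np.ndarray, sizes: np.ndarray, starts: np.ndarray,
                 sign: float) -> np.ndarray:
    zz = sign * z
    zmax = np.maximum.reduceat(zz, starts)
    e = np.exp(zz - np.repeat(zmax, sizes))
    return e / np.repeat(_seg_sum(e, starts), sizes)


def _init_model(model_cfg: ModelConfig, loss_cfg: LossConfig,
                din: int) -> TrainedModel:
    rng = np.random.default_rng(model_cfg.seed)
    elayers = list(model_cfg.energy_net_layers)
    trunk = _MLP([din] + elayers, model_cfg.activation, rng, act_last=True)
    head = _MLP([elayers[-1], 1], model_cfg.activation, rng)
    wnet = None
    if model_cfg.pooling.uses_weight_net:
        w_in = elayers[-1] if model_cfg.share_trunk else din
        wnet = _MLP(
            [w_in] + list(model_cfg.weight_net_layers) + [1],
            model_cfg.activation, rng,
        )
    return TrainedModel(
        config=model_cfg,
        loss_config=loss_cfg,
        energy_trunk=trunk,
        energy_head=head,
        weight_net=wnet,
    )


def _pool_batch(head: PoolingHead, eps: np.ndarray, w: np.ndarray | None,
                sizes: np.ndarray, starts: np.ndarray):
    """Batched pooling: returns (P per molecule, dP/deps per atom)."""
    name = head.name
    if name == "sum":
        return _seg_sum(eps, starts), np.ones_like(eps)
    if name == "avg":
        P = _seg_sum(eps, starts) / sizes
        return P, np.repeat(1.0 / sizes, sizes)
    if name == "max":
        grad = np.zeros_like(eps)
        P = np.empty(len(sizes))
        for m, (s, n) in enumerate(zip(starts, sizes)):
            seg = eps[s:s + n]
            j = int(np.argmax(seg) if head.softmax_sign > 0 else np.argmin(seg))
            P[m] = seg[j]
            grad[s + j] = 1.0
        return P, grad
    if name == "softmax":
        sw = _seg_softmax(eps, sizes, starts, head.softmax_sign / head.temperature)
        P = _seg_sum(sw * eps, starts)
        grad = sw * (1.0 + head.softmax_sign / head.temperature
                     * (eps - np.repeat(P, sizes)))
        return P, grad
    # wa / owa / coeff: w supplied by caller
    P = _seg_sum(w * eps, starts)
    return P, w


def train(
    dataset: LabeledDataset,
    model_cfg: ModelConfig,
    loss_cfg: LossConfig | None = None,
    max_epochs: int | None = None,
    patience: int | None = None,
    val_fraction: float = 0.1,
) -> TrainedModel:
    """Train a model; deterministic for a fixed ``model_cfg.seed``.

    Records tagged ``val`` are the validation set; if none exist, a
    ``val_fraction`` of the training records is held out (for fewer than
    five records the training set doubles as the monitor set, which turns
    early stopping into plain convergence monitoring).  The best-on-
    validation parameters are restored at the end.
    """
    loss_cfg = loss_cfg or LossConfig()
    head = model_cfg.pooling
    if loss_cfg.beta > 0 and head.name != "owa":
        raise ValidationError("beta > 0 is only meaningful for the owa head")
    max_epochs = max_epochs if max_epochs is not None else model_cfg.max_epochs
    patience = patience if patience is not None else model_cfg.patience

    train_ds = dataset.split("train")
    val_ds = dataset.split("val")
    rng = np.random.default_rng(model_cfg.seed)
    if len(train_ds) == 0:
        raise LabeledDataError("training split is empty")
    if len(val_ds) == 0:
        n = len(train_ds)
        n_val = int(round(val_fraction * n))
        if n >= 5 and n_val >= 1:
            perm = rng.permutation(n)
            val_ds = train_ds.subset(perm[:n_val])
            train_ds = train_ds.subset(perm[n_val:])
        else:
            val_ds = train_ds

    needs_l = head.name in ("owa", "coeff")
    for name, ds in (("train", train_ds), ("val", val_ds)):
        if needs_l:
            for i, (_, ref) in enumerate(ds):
                if ref.localization_fractions is None:
                    raise LabeledDataError(
                        f"{head.name} head requires localization fractions; "
                        f"{name} record {i} has none"
                    )

    # --- features and labels ------------------------------------------------
    def _prep(ds: LabeledDataset):
        feats = [featurize(s, model_cfg.descriptor).values for s, _ in ds]
        y = np.array([ref.target_energy for _, ref in ds])
        l = None
        if needs_l:
            l = [sanitize_fractions(ref.localization_fractions)[0] for _, ref in ds]
        return feats, y, l

    tr_feats, tr_y, tr_l = _prep(train_ds)
    va_feats, va_y, va_l = _prep(val_ds)

    stacked = np.vstack(tr_feats)
    feat_mean = stacked.mean(axis=0)
    feat_std = stacked.std(axis=0)
    feat_std[feat_std < 1e-8] = 1.0
    y_mean = float(tr_y.mean())
    y_std = float(tr_y.std())
    if y_std < 1e-8:
        y_std = 1.0

    din = stacked.shape[1] + len(model_cfg.descriptor.element_channels)
    model = _init_model(model_cfg, loss_cfg, din)
    model.feat_mean = feat_mean
    model.feat_std = feat_std
    model.y_mean = y_mean
    model.y_std = y_std

    def _inputs(ds, feats):
        Xs = []
        channels = model_cfg.descriptor.element_channels
        col = {z: i for i, z in enumerate(channels)}
        for (system, _), f in zip(ds, feats):
            X = (f - feat_mean) / feat_std
            onehot = np.zeros((system.n_atoms, len(channels)))
            for i, el in enumerate(system.elements):
                onehot[i, col[el]] = 1.0
            Xs.append(np.hstack([X, onehot]))
        return Xs

    tr_X = _inputs(train_ds, tr_feats)
    va_X = _inputs(val_ds, va_feats)
    tr_sizes = np.array([x.shape[0] for x in tr_X])
    va_sizes = np.array([x.shape[0] for x in va_X])

    sign = head.softmax_sign

    def _forward_eval(Xs, sizes, l_list):
        X = np.vstack(Xs)
        starts = _starts(sizes)
        eps_raw, z, _ = model._forward_atoms(X)
        eps = eps_raw * y_std + y_mean
        w = None
        if head.uses_weight_net:
            w = _seg_softmax(z, sizes, starts, sign)
        elif head.name == "coeff":
            w = np.concatenate(l_list)
        P, _ = _pool_batch(head, eps, w, sizes, starts)
        return P, w

    def _val_rmse():
        P, _ = _forward_eval(va_X, va_sizes, va_l)
        return float(np.sqrt(np.mean((P - va_y) ** 2)))

    n_train = len(tr_X)
    batch = max(1, min(model_cfg.batch_size, n_train))
    best_rmse = np.inf
    best_state = None
    best_epoch = -1
    bad_epochs = 0
    alpha, beta = loss_cfg.alpha, loss_cfg.beta

    for epoch in range(max_epochs):
        order = rng.permutation(n_train)
        epoch_loss = 0.0
        for b0 in range(0, n_train, batch):
            idx = order[b0:b0 + batch]
            B = len(idx)
            X = np.vstack([tr_X[i] for i in idx])
            sizes = tr_sizes[idx]
            starts = _starts(sizes)
            y = tr_y[idx]
            eps_raw, z, caches = model._forward_atoms(X)
            trunk_cache, head_cache, w_cache = caches
            eps = eps_raw * y_std + y_mean
            w = None
            l_flat = None
            if head.uses_weight_net:
                w = _seg_softmax(z, sizes, starts, sign)
            elif head.name == "coeff":
                l_flat = np.concatenate([tr_l[i] for i in idx])
                w = l_flat
            if head.name == "owa" and beta > 0:
                l_flat = np.concatenate([tr_l[i] for i in idx])
            P, dPdeps = _pool_batch(head, eps, w, sizes, starts)
            dE = P - y
            loss = alpha * np.mean(dE**2)
            if beta > 0:
                loss += beta * np.mean(_seg_sum((w - l_flat) ** 2, starts))
            epoch_loss += loss * B
            # gradients
            dLdP = 2.0 * alpha * dE / B
            g_eps = np.repeat(dLdP, sizes) * dPdeps * y_std
            grad_h = model.energy_head.backward(head_cache, g_eps[:, None])
            if head.uses_weight_net:
                g_w = np.repeat(dLdP, sizes) * eps
                if beta > 0:
                    g_w = g_w + (2.0 * beta / B) * (w - l_flat)
                inner = np.repeat(_seg_sum(g_w * w, starts), sizes)
                g_z = sign * w * (g_w - inner)
                grad_w_in = model.weight_net.backward(w_cache, g_z[:, None])
                if model.config.share_trunk:
                    grad_h = grad_h + grad_w_in
            model.energy_trunk.backward(trunk_cache, grad_h)
            lr = model_cfg.learning_rate
            model.energy_trunk.adam_step(lr)
            model.energy_head.adam_step(lr)
            if model.weight_net is not None:
                model.weight_net.adam_step(lr)
        epoch_loss /= n_train
        val_rmse = _val_rmse()
        model.history.append(
            {"epoch": epoch, "train_loss": float(epoch_loss), "val_rmse": val_rmse}
        )
        if val_rmse < best_rmse - 1e-12:
            best_rmse = val_rmse
            best_epoch = epoch
            best_state = (
                model.energy_trunk.state(),
                model.energy_head.state(),
                model.weight_net.state() if model.weight_net else None,
            )
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs > patience:
                break

    if best_state is not None:
        model.energy_trunk.load_state(best_state[0])
        model.energy_head.load_state(best_state[1])
        if model.weight_net is not None:
            model.weight_net.load_state(best_state[2])
    logger.info(
        "training done: head=%s best val RMSE %.4f eV at epoch %d",
        head.name, best_rmse, best_epoch,
    )
    model.model_id = f"{head.name}-{head.mode}-seed{model_cfg.seed}"
    return model


def select_alpha_beta(
    dataset: LabeledDataset,
    model_cfg: ModelConfig,
    grid: list[tuple[float, float]],
    **train_kwargs,
) -> tuple[float, float]:
    """Grid-select (alpha, beta) by validation energy RMSE.

    Ties (equal RMSE) are broken toward the larger beta, i.e. more
    localization supervision.
    """
    if not grid:
        raise ValidationError("grid must be non-empty")
    results = []
    for alpha, beta in grid:
        m = train(dataset, model_cfg, LossConfig(alpha=alpha, beta=beta),
                  **train_kwargs)
        rmse = min(h["val_rmse"] for h in m.history)
        logger.info("grid point alpha=%g beta=%g: val RMSE %.4f eV",
                    alpha, beta, rmse)
        results.append((rmse, -beta, (alpha, beta)))
    results.sort(key=lambda r: (r[0], r[1]))
    return results[0][2]


# ---------------------------------------------------------------------------
# checkpointing: one .npz archive holding config (JSON) + parameter arrays


def save_model(model: TrainedModel, path: str | Path) -> None:
    cfg = {
        "descriptor": {
            "element_channels": list(model.config.descriptor.element_channels),
            "cutoff_radius": model.config.descriptor.cutoff_radius,
            "n_centers": model.config.descriptor.n_centers,
        },
        "pooling": {
            "name": model.config.pooling.name,
            "mode": model.config.pooling.mode,
            "temperature": model.config.pooling.temperature,
        },
        "model": {
            k: v for k, v in asdict(model.config).items()
            if k not in ("descriptor", "pooling")
        },
        "loss": asdict(model.loss_config),
        "y_mean": model.y_mean,
        "y_std": model.y_std,
        "model_id": model.model_id,
    }
    arrays = {"feat_mean": model.feat_mean, "feat_std": model.feat_std}
    for prefix, net in (
        ("trunk", model.energy_trunk),
        ("ehead", model.energy_head),
        ("wnet", model.weight_net),
    ):
        if net is None:
            continue
        for k, a in enumerate(net.state()):
            arrays[f"{prefix}_{k}"] = a
    np.savez(path, config_json=json.dumps(cfg), **arrays)


def load_model(path: str | Path) -> TrainedModel:
    data = np.load(path, allow_pickle=False)
    cfg = json.loads(str(data["config_json"]))
    desc = DescriptorConfig(
        element_channels=tuple(cfg["descriptor"]["element_channels"]),
        cutoff_radius=cfg["descriptor"]["cutoff_radius"],
        n_centers=cfg["descriptor"]["n_centers"],
    )
    head = PoolingHead(**cfg["pooling"])
    mc = cfg["model"]
    model_cfg = ModelConfig(
        descriptor=desc,
        pooling=head,
        energy_net_layers=tuple(mc["energy_net_layers"]),
        weight_net_layers=tuple(mc["weight_net_layers"]),
        activation=mc["activation"],
        share_trunk=mc["share_trunk"],
        seed=mc["seed"],
        learning_rate=mc["learning_rate"],
        batch_size=mc["batch_size"],
        max_epochs=mc["max_epochs"],
        patience=mc["patience"],
    )
    din = data["feat_mean"].shape[0] + len(desc.element_channels)
    model = _init_model(model_cfg, LossConfig(**cfg["loss"]), din)
    model.feat_mean = data["feat_mean"]
    model.feat_std = data["feat_std"]
    model.y_mean = float(cfg["y_mean"])
    model.y_std = float(cfg["y_std"])
    model.model_id = cfg["model_id"]
    for prefix, net in (
        ("trunk", model.energy_trunk),
        ("ehead", model.energy_head),
        ("wnet", model.weight_net),
    ):
        if net is None:
            continue
        n = len(net.W) * 2
        net.load_state([data[f"{prefix}_{k}"] for k in range(n)])
    return model
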