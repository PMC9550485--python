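"""Unsupervised training of the registration network.

One optimization step per image pair (batch size 1): forward pass, total
loss on the fused field phi_final, backward pass, ADAM update.  The
learning rate starts at 1e-4 and is halved at the start of a scheduled
epoch (default 40 of 70), matching the training protocol of the source
study.  Runs are fully reproducible given the seed.

The public surface is the scikit-learn style estimator
:class:`MHNetRegistration` (``fit`` trains on pairs, ``predict`` returns
displacement fields, ``transform`` returns warped volumes); the
module-level :func:`train` / :func:`register_pair` are thin wrappers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .autodiff import Tensor
from .losses import LossConfig, total_loss_graph
from .network import MHNet, NetworkConfig, build_network
from .volumes import DisplacementField, Volume
from .warp import WarpConfig, warp

__all__ = [
    "TrainConfig",
    "Adam",
    "MHNetRegistration",
    "train",
    "register_pair",
    "planned_steps",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class TrainConfig:
    epochs: int = 70
    lr: float = 1e-4
    lr_halve_epoch: int = 40
    batch_size: int = 1
    seed: int = 0
    shuffle: bool = True
    grad_clip: float | None = None
    checkpoint_every: int = 0  # 0 = only at the end
    loss: LossConfig = field(default_factory=LossConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.lr_halve_epoch > self.epochs:
            raise ValueError("lr_halve_epoch must not exceed epochs")


def planned_steps(epochs: int, n_pairs: int) -> int:
    """Total optimization steps for a run: epochs x pairs (batch size 1)."""
    return int(epochs) * int(n_pairs)


class Adam:
    """Standard ADAM with bias correction (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, params, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def _pair_arrays(pair):
    f, m = pair
    f = f.data if isinstance(f, Volume) else np.asarray(f)
    m = m.data if isinstance(m, Volume) else np.asarray(m)
    return f, m


class MHNetRegistration(BaseEstimator):
    """Unsupervised deformable registration estimator.

    Parameters mirror :class:`TrainConfig`; ``network`` and ``loss`` accept
    the corresponding config dataclasses (or None for defaults).

    After ``fit``:

    ``net_``
        the trained :class:`~mhnet.network.MHNet`;
    ``loss_history_``
        per-epoch mean total loss;
    ``n_steps_``
        number of optimization steps performed (epochs x pairs).
    """

    def __init__(self, network=None, loss=None, epochs=70, lr=1e-4,
                 lr_halve_epoch=40, batch_size=1, seed=0, shuffle=True,
                 grad_clip=None, boundary_mode="clamp"):
        self.network = network
        self.loss = loss
        self.epochs = epochs
        self.lr = lr
        self.lr_halve_epoch = lr_halve_epoch
        self.batch_size = batch_size
        self.seed = seed
        self.shuffle = shuffle
        self.grad_clip = grad_clip
        self.boundary_mode = boundary_mode

    # -- training -----------------------------------------------------------
    def fit(self, X, y=None):
        """Train on ``X``, a sequence of (reference, moving) pairs.

        Each element of a pair may be a :class:`~mhnet.volumes.Volume` or a
        plain 3D array; all pairs must share one spatial shape divisible
        by 16.
        """
        pairs = [_pair_arrays(p) for p in X]
        if not pairs:
            raise ValueError("training requires at least one image pair")
        shape = pairs[0][0].shape
        for f, m in pairs:
            if f.shape != shape or m.shape != shape:
                raise ValueError(
                    f"all training volumes must share shape {shape}; "
                    f"got {f.shape} / {m.shape}"
                )
        net_cfg = self.network or NetworkConfig()
        loss_cfg = self.loss or LossConfig()
        self.net_ = build_network(net_cfg, seed=self.seed)
        dtype = self.net_.dtype
        pairs = [(f.astype(dtype), m.astype(dtype)) for f, m in pairs]

        opt = Adam(self.net_.parameters(), lr=self.lr)
        rng = np.random.default_rng(self.seed)
        history = []
        step = 0
        for epoch in range(self.epochs):
            if epoch == self.lr_halve_epoch:
                opt.lr = opt.lr / 2.0
            order = np.arange(len(pairs))
            if self.shuffle:
                rng.shuffle(order)
            epoch_losses = []
            for idx in order:
                f, m = pairs[idx]
                x = Tensor(np.stack([f, m]))
                fields = self.net_.forward_graph(x)
                loss = total_loss_graph(
                    Tensor(f), Tensor(m), fields.phi_final, loss_cfg,
                    boundary_mode=self.boundary_mode,
                )
                value = loss.item()
                if not np.isfinite(value):
                    raise FloatingPointError(
                        f"non-finite loss at step {step}: {value}"
                    )
                opt.zero_grad()
                loss.backward()
                if self.grad_clip is not None:
                    self._clip_grads(self.grad_clip)
                opt.step()
                epoch_losses.append(value)
                step += 1
            history.append(float(np.mean(epoch_losses)))
        self.loss_history_ = history
        self.n_steps_ = step
        self.final_lr_ = opt.lr
        return self

    def _clip_grads(self, max_norm):
        total = np.sqrt(
            sum(float(np.sum(p.grad**2)) for p in self.net_.parameters()
                if p.grad is not None)
        )
        if total > max_norm:
            scale = max_norm / (total + 1e-12)
            for p in self.net_.parameters():
                if p.grad is not None:
                    p.grad = p.grad * scale

    # -- inference ----------------------------------------------------------
    def _require_fitted(self):
        if not hasattr(self, "net_"):
            raise AttributeError(
                "this MHNetRegistration instance is not fitted yet"
            )

    def predict(self, X):
        """Displacement fields for a sequence of (reference, moving) pairs."""
        self._require_fitted()
        out = []
        for pair in X:
            f, m = _pair_arrays(pair)
            u = self.net_.predict_field(f, m)
            out.append(DisplacementField(u.astype(np.float32)))
        return out

    def transform(self, X):
        """Warped moving volumes for a sequence of pairs."""
        self._require_fitted()
        warped = []
        for pair, phi in zip(X, self.predict(X)):
            f, m = pair
            mv = m if isinstance(m, Volume) else Volume(np.asarray(m))
            warped.append(warp(mv, phi, WarpConfig(self.boundary_mode)))
        return warped


# ---------------------------------------------------------------------------
# functional wrappers and checkpointing
# ---------------------------------------------------------------------------

def train(pairs, cfg: TrainConfig | None = None):
    """Train a network on (reference, moving) pairs; returns (estimator,
    per-epoch loss history)."""
    cfg = cfg or TrainConfig()
    est = MHNetRegistration(
        network=cfg.network, loss=cfg.loss, epochs=cfg.epochs, lr=cfg.lr,
        lr_halve_epoch=cfg.lr_halve_epoch, batch_size=cfg.batch_size,
        seed=cfg.seed, shuffle=cfg.shuffle, grad_clip=cfg.grad_clip,
    )
    est.fit(pairs)
    return est, est.loss_history_


def register_pair(net, f: Volume, m: Volume, boundary_mode="clamp"):
    """One forward pass + warp; returns (DisplacementField, warped Volume)."""
    model = net.net_ if isinstance(net, MHNetRegistration) else net
    u = model.predict_field(f.data, m.data)
    phi = DisplacementField(u.astype(np.float32))
    return phi, warp(m, phi, WarpConfig(boundary_mode))


def save_checkpoint(est: MHNetRegistration, path) -> None:
    est._require_fitted()
    net = est.net_
    arrays = {f"p{i}": a for i, a in enumerate(net.state_arrays())}
    meta = {
        "network": net.cfg.to_dict(),
        "loss_history": list(getattr(est, "loss_history_", [])),
        "seed": est.seed,
    }
    np.savez(path, _meta=json.dumps(meta), **arrays)


def load_checkpoint(path) -> MHNetRegistration:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["_meta"]))
        arrays = [data[f"p{i}"] for i in range(len(data.files) - 1)]
    cfg = NetworkConfig.from_dict(meta["network"])
    est = MHNetRegistration(network=cfg, seed=meta.get("seed", 0))
    est.net_ = build_network(cfg, seed=0)
    est.net_.load_state_arrays(arrays)
    est.loss_history_ = meta.get("loss_history", [])
    est.n_steps_ = len(est.loss_history_)
    return est
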