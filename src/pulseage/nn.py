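"""A compact 1D convolutional network for pulse-to-age regression, in numpy.

The architecture is deliberately small — two stride-1 convolutional
layers with no pooling, two fully connected layers with dropout, and a
single linear output neuron — to limit capacity at cohort sizes of a
few hundred participants. Convolutions are evaluated as batched matrix
products over sliding windows (im2col), and gradients are derived by
hand, which keeps the whole model dependency-free and bit-reproducible
given a seed. Adam and momentum SGD optimizers are provided with shared
decay-rate / weight-decay conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


@dataclass(frozen=True)
class CNNConfig:
    """Architecture and regularization of the pulse-age CNN.

    Defaults follow the compact reference design: conv 16×11 then 32×9
    (stride 1, no pooling), two 1024-unit fully connected layers with
    dropout 0.2 after each, one linear output.
    """

    input_length: int = 200
    conv: tuple[tuple[int, int], ...] = ((16, 11), (32, 9))  # (filters, kernel)
    fc: tuple[int, ...] = (1024, 1024)
    dropout: float = 0.2

    def __post_init__(self) -> None:
        length = self.input_length
        for _, k in self.conv:
            if k > length:
                raise ValueError(f"kernel {k} exceeds input length {length}")
            length = length - k + 1

    @classmethod
    def small(cls) -> "CNNConfig":
        """Desk-scale preset: same depth and kernels, narrower head."""
        return cls(conv=((16, 11), (16, 9)), fc=(128, 128))


def receptive_field(cfg: CNNConfig) -> int:
    """Receptive field of the conv stack: sum(kernel - 1) + 1 for
    stride-1, no-pooling stacks."""
    return sum(k - 1 for _, k in cfg.conv) + 1


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 1e-3
    batch_size: int = 128
    optimizer: Literal["adam", "sgd"] = "adam"
    beta1: float = 0.9
    beta2: float = 0.999
    weight_decay: float = 1e-7
    max_epochs: int = 100
    patience: int = 10


class CNN1D:
    """Forward/backward pulse-age regressor on 200-sample pulses."""

    def __init__(self, cfg: CNNConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng([seed, 977])
        self.W: list[np.ndarray] = []
        self.b: list[np.ndarray] = []
        length = cfg.input_length
        c_in = 1
        for c_out, k in cfg.conv:
            fan_in = k * c_in
            w = rng.normal(0, np.sqrt(2.0 / fan_in), size=(fan_in, c_out))
            self.W.append(w.astype(np.float32))
            self.b.append(np.zeros(c_out, dtype=np.float32))
            length = length - k + 1
            c_in = c_out
        self.conv_out_len = length
        dim = length * c_in
        for units in cfg.fc:
            w = rng.normal(0, np.sqrt(2.0 / dim), size=(dim, units))
            self.W.append(w.astype(np.float32))
            self.b.append(np.zeros(units, dtype=np.float32))
            dim = units
        self.W.append(
            rng.normal(0, np.sqrt(1.0 / dim), size=(dim, 1)).astype(np.float32)
        )
        self.b.append(np.zeros(1, dtype=np.float32))
        self.n_conv = len(cfg.conv)
        self.n_fc = len(cfg.fc)

    # -- forward -----------------------------------------------------------

    def forward(
        self,
        x: np.ndarray,
        train: bool = False,
        rng: np.random.Generator | None = None,
    ) -> np.ndarray:
        """Predict ages for a (B, 200) batch; caches for backward."""
        x = np.asarray(x, dtype=np.float32)
        B = x.shape[0]
        h = x[:, :, None]  # (B, L, C=1)
        cache: list[dict] = []
        for li in range(self.n_conv):
            k = self.cfg.conv[li][1]
            win = sliding_window_view(h, k, axis=1)  # (B, L', C, k)
            win = np.ascontiguousarray(win.transpose(0, 1, 3, 2))  # (B,L',k,C)
            Lp = win.shape[1]
            flat = win.reshape(B, Lp, -1)
            z = flat @ self.W[li] + self.b[li]
            a = np.maximum(z, 0.0)
            cache.append({"flat": flat, "z": z, "in_shape": h.shape})
            h = a
        conv_act = h  # (B, L'', C'') post-ReLU activations of last conv
        v = h.reshape(B, -1)
        drop_masks: list[np.ndarray | None] = []
        for fi in range(self.n_fc):
            li = self.n_conv + fi
            z = v @ self.W[li] + self.b[li]
            a = np.maximum(z, 0.0)
            if train and self.cfg.dropout > 0:
                if rng is None:
                    raise ValueError("training forward pass needs an rng")
                keep = 1.0 - self.cfg.dropout
                mask = (rng.random(a.shape) < keep).astype(np.float32) / keep
                a = a * mask
            else:
                mask = None
            cache.append({"v": v, "z": z, "mask": mask})
            drop_masks.append(mask)
            v = a
        li = self.n_conv + self.n_fc
        y = v @ self.W[li] + self.b[li]
        cache.append({"v": v})
        self._cache = cache
        self._conv_act = conv_act
        return y[:, 0]

    def predict(self, x: np.ndarray, batch_size: int = 1024) -> np.ndarray:
        out = []
        for i in range(0, len(x), batch_size):
            out.append(self.forward(x[i : i + batch_size], train=False))
        return np.concatenate(out) if out else np.empty(0)

    # -- backward ----------------------------------------------------------

    def backward(self, dy: np.ndarray, stop_at_conv: bool = False):
        """Gradients of sum(dy * y) w.r.t. parameters.

        With ``stop_at_conv`` the backward pass returns the gradient at
        the last conv layer's post-ReLU activations (for Grad-CAM)
        without accumulating parameter gradients.
        """
        cache = self._cache
        gW = [np.zeros_like(w) for w in self.W]
        gb = [np.zeros_like(b) for b in self.b]
        li = self.n_conv + self.n_fc
        v = cache[li]["v"]
        d = dy[:, None].astype(np.float32)  # (B, 1)
        if not stop_at_conv:
            gW[li] = v.T @ d
            gb[li] = d.sum(axis=0)
        d = d @ self.W[li].T
        for fi in reversed(range(self.n_fc)):
            li = self.n_conv + fi
            c = cache[li]
            if c["mask"] is not None:
                d = d * c["mask"]
            d = d * (c["z"] > 0)
            if not stop_at_conv:
                gW[li] = c["v"].T @ d
                gb[li] = d.sum(axis=0)
            d = d @ self.W[li].T
        B = d.shape[0]
        d = d.reshape(self._conv_act.shape)  # (B, L'', C'')
        if stop_at_conv:
            return d
        for li in reversed(range(self.n_conv)):
            c = cache[li]
            d = d * (c["z"] > 0)
            Lp = d.shape[1]
            flat = c["flat"]  # (B, Lp, k*C_in)
            gW[li] = np.einsum("blf,blc->fc", flat, d, optimize=True)
            gb[li] = d.sum(axis=(0, 1))
            if li > 0:
                dflat = d @ self.W[li].T  # (B, Lp, k*C_in)
                k = self.cfg.conv[li][1]
                Bs, _, C_in = cache[li]["in_shape"]
                L_in = cache[li]["in_shape"][1]
                dwin = dflat.reshape(B, Lp, k, C_in)
                dh = np.zeros((B, L_in, C_in), dtype=np.float32)
                for j in range(k):
                    dh[:, j : j + Lp, :] += dwin[:, :, j, :]
                d = dh
        return gW, gb

    def grad_cam_raw(self, x: np.ndarray) -> np.ndarray:
        """Per-pulse Grad-CAM map at conv-stack resolution.

        Channel weights are the time-averaged gradients of the output
        w.r.t. the last conv layer's activations; the map is the
        rectified channel-weighted activation sum.
        """
        self.forward(np.asarray(x, dtype=np.float32), train=False)
        acts = self._conv_act  # (B, L, C)
        grads = self.backward(np.ones(len(x), dtype=np.float32),
                              stop_at_conv=True)
        alpha = grads.mean(axis=1, keepdims=True)  # (B, 1, C)
        return np.maximum((alpha * acts).sum(axis=2), 0.0)  # (B, L)


# ---------------------------------------------------------------------------
# optimizers
# ---------------------------------------------------------------------------


class _Optimizer:
    def __init__(self, model: CNN1D, tc: TrainConfig):
        self.model = model
        self.tc = tc

    def _apply_weight_decay(self, gW):
        if self.tc.weight_decay > 0:
            for g, w in zip(gW, self.model.W):
                g += self.tc.weight_decay * w
        return gW


class Adam(_Optimizer):
    def __init__(self, model: CNN1D, tc: TrainConfig):
        super().__init__(model, tc)
        self.mW = [np.zeros_like(w) for w in model.W]
        self.vW = [np.zeros_like(w) for w in model.W]
        self.mb = [np.zeros_like(b) for b in model.b]
        self.vb = [np.zeros_like(b) for b in model.b]
        self.t = 0

    def step(self, gW, gb):
        gW = self._apply_weight_decay(gW)
        tc = self.tc
        self.t += 1
        bc1 = 1 - tc.beta1**self.t
        bc2 = 1 - tc.beta2**self.t
        eps = 1e-8
        for i in range(len(gW)):
            for g, w, m, v in (
                (gW[i], self.model.W[i], self.mW[i], self.vW[i]),
                (gb[i], self.model.b[i], self.mb[i], self.vb[i]),
            ):
                m *= tc.beta1
                m += (1 - tc.beta1) * g
                v *= tc.beta2
                v += (1 - tc.beta2) * g * g
                w -= tc.lr * (m / bc1) / (np.sqrt(v / bc2) + eps)


class MomentumSGD(_Optimizer):
    """SGD with momentum; the first decay rate serves as the momentum
    coefficient."""

    def __init__(self, model: CNN1D, tc: TrainConfig):
        super().__init__(model, tc)
        self.uW = [np.zeros_like(w) for w in model.W]
        self.ub = [np.zeros_like(b) for b in model.b]

    def step(self, gW, gb):
        gW = self._apply_weight_decay(gW)
        tc = self.tc
        for i in range(len(gW)):
            self.uW[i] = tc.beta1 * self.uW[i] + gW[i]
            self.ub[i] = tc.beta1 * self.ub[i] + gb[i]
            self.model.W[i] -= tc.lr * self.uW[i]
            self.model.b[i] -= tc.lr * self.ub[i]


def make_optimizer(model: CNN1D, tc: TrainConfig) -> _Optimizer:
    if tc.optimizer == "adam":
        return Adam(model, tc)
    if tc.optimizer == "sgd":
        return MomentumSGD(model, tc)
    raise ValueError(f"unknown optimizer {tc.optimizer!r}")


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    model: CNN1D
    best_val_mae: float
    best_epoch: int
    history: list[float] = field(default_factory=list)


def fit(
    model: CNN1D,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    tc: TrainConfig,
    seed: int = 0,
) -> FitResult:
    """Mini-batch MSE training with early stopping on validation MAE.

    Best-epoch weights are restored at the end; everything is
    deterministic given the seed.
    """
    rng = np.random.default_rng([seed, 523])
    opt = make_optimizer(model, tc)
    x_train = np.asarray(x_train, dtype=np.float32)
    y_train = np.asarray(y_train, dtype=np.float32)
    n = len(x_train)
    best = np.inf
    best_epoch = -1
    best_W = [w.copy() for w in model.W]
    best_b = [b.copy() for b in model.b]
    history: list[float] = []
    since_best = 0
    for epoch in range(tc.max_epochs):
        order = rng.permutation(n)
        for i0 in range(0, n, tc.batch_size):
            idx = order[i0 : i0 + tc.batch_size]
            xb, yb = x_train[idx], y_train[idx]
            pred = model.forward(xb, train=True, rng=rng)
            dy = (2.0 / len(idx)) * (pred - yb)
            gW, gb = model.backward(dy)
            opt.step(gW, gb)
        val_mae = float(np.mean(np.abs(model.predict(x_val) - y_val)))
        history.append(val_mae)
        if val_mae < best - 1e-6:
            best = val_mae
            best_epoch = epoch
            best_W = [w.copy() for w in model.W]
            best_b = [b.copy() for b in model.b]
            since_best = 0
        else:
            since_best += 1
            if since_best >= tc.patience:
                break
    model.W = best_W
    model.b = best_b
    return FitResult(model=model, best_val_mae=best, best_epoch=best_epoch,
                     history=history)
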