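"""Backbone adapter contract and a tiny trainable numpy CNN.

Any convolutional classifier can drive the saliency and fusion stages as
long as it exposes, per the adapter contract:

* ``embed`` — the penultimate (post-pooling, pre-head) feature vector;
* ``predict_proba`` — probability of the lesion class (index 1);
* ``trace_conv`` — activations of the last convolutional layer together
  with the gradient of a class score with respect to those activations.

:class:`TinyConvNet` is a small seeded CNN (three conv blocks, global
average pooling, dropout head, two-class output) that satisfies the
contract and trains at desk scale. It exists so the full pipeline can be
exercised end to end on synthetic data; it is not a stand-in for any
particular large architecture.
"""

from __future__ import annotations

from abc import ABC, abstractmethod
from dataclasses import dataclass

import numpy as np

from . import _nn
from .errors import AdapterError, NumericError
from .imaging import RadiographSample, resize

__all__ = [
    "ConvTrace",
    "BackboneAdapter",
    "TinyConvNet",
    "TrainingConfig",
    "build_test_backbone",
    "train_backbone",
]


@dataclass(frozen=True)
class ConvTrace:
    """Last-conv activations ``A`` (h, w, k) and class-score gradients ``G``."""

    activations: np.ndarray
    gradients: np.ndarray

    def __post_init__(self) -> None:
        a, g = np.asarray(self.activations, float), np.asarray(self.gradients, float)
        if a.shape != g.shape or a.ndim != 3:
            raise NumericError(f"activations {a.shape} and gradients {g.shape} must share a (h, w, k) shape")
        if not (np.all(np.isfinite(a)) and np.all(np.isfinite(g))):
            raise NumericError("non-finite values in conv trace")
        object.__setattr__(self, "activations", a)
        object.__setattr__(self, "gradients", g)


class BackboneAdapter(ABC):
    """Contract a convolutional classifier must satisfy."""

    name: str
    input_side: int
    embedding_dim: int
    last_conv_shape: tuple[int, int, int]
    capabilities: frozenset[str] = frozenset({"embed", "grad_conv", "predict_proba"})

    @abstractmethod
    def embed(self, images: np.ndarray) -> np.ndarray:
        """(n, side, side) batch -> (n, embedding_dim) penultimate features."""

    @abstractmethod
    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        """(n, side, side) batch -> (n,) probability of the lesion class."""

    @abstractmethod
    def trace_conv(self, image: np.ndarray, target_class: int) -> ConvTrace:
        """Last-conv activations and d(score of target_class)/d(activations)."""

    def prepare(self, sample: RadiographSample) -> np.ndarray:
        """Resize a sample to the adapter's expected input side."""
        return resize(sample, self.input_side).pixels

    def _check_batch(self, images: np.ndarray) -> np.ndarray:
        images = np.asarray(images, dtype=float)
        if images.ndim == 2:
            images = images[None]
        if images.ndim != 3 or images.shape[1:] != (self.input_side, self.input_side):
            raise AdapterError(
                f"{self.name}: expected (n, {self.input_side}, {self.input_side}) batch, got {images.shape}"
            )
        return images


class TinyConvNet(BackboneAdapter):
    """Seeded numpy CNN: [conv-relu-pool] x2, conv-relu, GAP, dropout, dense."""

    def __init__(self, seed: int = 0, side: int = 64, conv_channels: tuple[int, int, int] = (8, 16, 32), name: str | None = None):
        if side % 4 != 0:
            raise AdapterError("input side must be divisible by 4")
        rng = np.random.default_rng(seed)
        c1, c2, c3 = conv_channels
        self.name = name or f"tinyconv-s{seed}"
        self.input_side = side
        self.conv1 = _nn.Conv3x3(1, c1, rng)
        self.conv2 = _nn.Conv3x3(c1, c2, rng)
        self.conv3 = _nn.Conv3x3(c2, c3, rng)
        self.head = _nn.Dense(c3, 2, rng)
        self.embedding_dim = c3
        self.last_conv_shape = (side // 4, side // 4, c3)
        self.dropout = 0.30
        self.seed = seed

    # -- forward ------------------------------------------------------------

    def _forward_conv(self, x: np.ndarray, caches: list[dict] | None = None) -> np.ndarray:
        """(n, 1, s, s) -> (n, c3, s/4, s/4) post-ReLU last-conv activations."""
        x = x - 0.5  # center [0, 1] inputs so early layers start symmetric
        cs = [{}, {}, {}, {}, {}] if caches is not None else [None] * 5
        a1 = _nn.relu(self.conv1.forward(x, cs[0]))
        p1 = _nn.maxpool2(a1, cs[1])
        a2 = _nn.relu(self.conv2.forward(p1, cs[2]))
        p2 = _nn.maxpool2(a2, cs[3])
        a3 = _nn.relu(self.conv3.forward(p2, cs[4]))
        if caches is not None:
            caches.extend(cs)
            caches.append({"a1": a1, "a2": a2, "a3": a3})
        return a3

    def embed(self, images: np.ndarray) -> np.ndarray:
        x = self._check_batch(images)[:, None, :, :]
        return self._forward_conv(x).mean(axis=(2, 3))

    def logits(self, images: np.ndarray) -> np.ndarray:
        return self.head.forward(self.embed(images))

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        return _nn.softmax(self.logits(images))[:, 1]

    def trace_conv(self, image: np.ndarray, target_class: int) -> ConvTrace:
        if "grad_conv" not in self.capabilities:  # pragma: no cover - contract guard
            raise AdapterError(f"{self.name} does not support grad_conv")
        x = self._check_batch(image)[:1, None, :, :]
        a = self._forward_conv(x)[0]  # (c3, h, w)
        h, w = a.shape[1:]
        # score = head(GAP(A)); dscore/dA is the head weight spread over the GAP
        g = np.broadcast_to(
            self.head.w[:, int(target_class)][:, None, None] / (h * w), a.shape
        )
        return ConvTrace(
            activations=np.transpose(a, (1, 2, 0)),
            gradients=np.transpose(np.ascontiguousarray(g), (1, 2, 0)),
        )

    # -- persistence ----------------------------------------------------------

    def _params(self) -> list[np.ndarray]:
        return [
            self.conv1.w, self.conv1.b, self.conv2.w, self.conv2.b,
            self.conv3.w, self.conv3.b, self.head.w, self.head.b,
        ]

    def save(self, path: str) -> None:
        np.savez(path, **{f"p{i}": p for i, p in enumerate(self._params())},
                 side=self.input_side, seed=self.seed,
                 channels=np.array([self.conv1.c_out, self.conv2.c_out, self.conv3.c_out]))

    @classmethod
    def load(cls, path: str) -> "TinyConvNet":
        data = np.load(path)
        net = cls(seed=int(data["seed"]), side=int(data["side"]),
                  conv_channels=tuple(int(c) for c in data["channels"]))
        for i, p in enumerate(net._params()):
            p[...] = data[f"p{i}"]
        return net


def build_test_backbone(seed: int = 0, side: int = 64, conv_channels: tuple[int, int, int] = (8, 16, 32)) -> TinyConvNet:
    """Build the seeded desk-scale test backbone."""
    return TinyConvNet(seed=seed, side=side, conv_channels=conv_channels)


@dataclass(frozen=True)
class TrainingConfig:
    """Backbone training settings (Adam, early stopping, L2 on conv weights).

    Defaults follow the reference protocol (lr 1e-4, patience 10,
    L2 1e-4, dropout 0.30); desk-scale runs typically raise the learning
    rate and cap epochs.
    """

    epochs: int = 50
    batch_size: int = 32
    learning_rate: float = 1e-4
    l2: float = 1e-4
    patience: int = 10
    seed: int = 0


def train_backbone(
    net: TinyConvNet,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
    config: TrainingConfig = TrainingConfig(),
) -> dict:
    """Train in place with Adam + early stopping; returns a history dict."""
    rng = np.random.default_rng(config.seed)
    x_train = np.asarray(x_train, float)[:, None, :, :]
    y_train = np.asarray(y_train, int)
    params = net._params()
    opt = _nn.Adam(params, lr=config.learning_rate)
    best_val, best_state, since_best = -np.inf, None, 0
    history: dict = {"loss": [], "val_accuracy": []}

    for _epoch in range(config.epochs):
        order = rng.permutation(len(y_train))
        epoch_loss = 0.0
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, yb = x_train[idx], y_train[idx]
            caches: list[dict] = []
            a3 = net._forward_conv(xb, caches)
            acts = caches[5]
            emb = a3.mean(axis=(2, 3))
            if net.dropout > 0:
                keep = (rng.random(emb.shape) >= net.dropout) / (1 - net.dropout)
                emb_d = emb * keep
            else:
                keep = None
                emb_d = emb
            logits = net.head.forward(emb_d)
            loss, dlogits = _nn.cross_entropy_grad(logits, yb)
            epoch_loss += loss * len(idx)

            demb, dwh, dbh = net.head.backward(dlogits, emb_d)
            if keep is not None:
                demb = demb * keep
            h, w = a3.shape[2:]
            da3 = np.broadcast_to(demb[:, :, None, None] / (h * w), a3.shape)
            da3 = _nn.relu_backward(da3, acts["a3"])
            dp2, dw3, db3 = net.conv3.backward(da3, caches[4])
            da2 = _nn.relu_backward(_nn.maxpool2_backward(dp2, caches[3]), acts["a2"])
            dp1, dw2, db2 = net.conv2.backward(da2, caches[2])
            da1 = _nn.relu_backward(_nn.maxpool2_backward(dp1, caches[1]), acts["a1"])
            _, dw1, db1 = net.conv1.backward(da1, caches[0])

            # L2 weight decay on convolutional weights only
            dw1 += config.l2 * net.conv1.w
            dw2 += config.l2 * net.conv2.w
            dw3 += config.l2 * net.conv3.w
            opt.step([dw1, db1, dw2, db2, dw3, db3, dwh, dbh])

        history["loss"].append(epoch_loss / len(y_train))
        if x_val is not None and len(x_val):
            val_acc = float(np.mean((net.predict_proba(x_val) >= 0.5).astype(int) == y_val))
            history["val_accuracy"].append(val_acc)
            if val_acc > best_val:
                best_val, since_best = val_acc, 0
                best_state = [p.copy() for p in params]
            else:
                since_best += 1
                if since_best >= config.patience:
                    break
    if best_state is not None:
        for p, b in zip(params, best_state):
            p[...] = b
    return history
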