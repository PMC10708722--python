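"""Convolutional autoencoder for scalogram-image compression.

The canonical architecture compresses a 256x256x1 image through five
stride-2 3x3 "same" convolutions (16, 32, 64, 128, 255 filters) to an
8x8x255 latent code, and reconstructs it through five matching
transposed convolutions (128, 64, 32, 16, 1 filters).  Kernel 3x3 and
stride 2 are the unique layer hyperparameters consistent with the
reference per-layer parameter counts and output shapes, which
:func:`parameter_report` reproduces symbolically.

Hidden activations are ReLU; the final decoder layer is a sigmoid so
reconstructions live in [0, 1] like the normalised scalograms.  The
training loss is the mean squared reconstruction error (the averaged
squared L2 reconstruction norm), minimised with Adam.  The latent
bottleneck deliberately has 255 filters, not 256: the reference
parameter counts confirm that width.

Everything runs in NumPy on the CPU; gradients of the conv /
transposed-conv pair are exact adjoints (finite-difference checked in
the test suite) and training is bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from ._nn import (
    Adam,
    conv2d,
    conv2d_backward,
    conv2d_transpose,
    conv2d_transpose_backward,
    glorot_uniform,
    relu,
    sigmoid,
)

#: Default ceiling for the PSNR of a perfect reconstruction (MSE = 0).
PSNR_CAP_DB = 100.0

CANONICAL_IMAGE_SIZE = 256
CANONICAL_ENCODER_FILTERS = (16, 32, 64, 128, 255)


@dataclass(frozen=True)
class CAEArchitecture:
    """Symmetric encoder/decoder stack of stride-2 same-padded layers."""

    image_size: int = CANONICAL_IMAGE_SIZE
    encoder_filters: tuple[int, ...] = CANONICAL_ENCODER_FILTERS
    kernel_size: int = 3
    stride: int = 2

    def __post_init__(self) -> None:
        if not self.encoder_filters:
            raise ValueError("at least one encoder layer is required")
        if self.image_size % (self.stride ** len(self.encoder_filters)) != 0:
            raise ValueError(
                "image_size must be divisible by stride**n_layers "
                f"({self.stride}**{len(self.encoder_filters)})"
            )

    @property
    def decoder_filters(self) -> tuple[int, ...]:
        return tuple(reversed(self.encoder_filters[:-1])) + (1,)

    @property
    def latent_hw(self) -> int:
        return self.image_size // (self.stride ** len(self.encoder_filters))

    @property
    def latent_shape(self) -> tuple[int, int, int]:
        return (self.latent_hw, self.latent_hw, self.encoder_filters[-1])

    @property
    def latent_dim(self) -> int:
        h, w, c = self.latent_shape
        return h * w * c


@dataclass
class LatentCode:
    """A flattened bottleneck code with its window provenance."""

    values: np.ndarray
    window_index: int = 0
    class_id: str | None = None


def parameter_report(arch: CAEArchitecture = CAEArchitecture()) -> dict:
    """Per-layer output shapes and trainable parameter counts.

    Computed symbolically from the layer specs (kernel k, stride s,
    channel widths): a conv or transposed-conv layer with c_in inputs
    and c_out filters holds ``k*k*c_in*c_out + c_out`` parameters.
    """
    k = arch.kernel_size
    rows_enc = []
    size = arch.image_size
    c_in = 1
    for f in arch.encoder_filters:
        size //= arch.stride
        rows_enc.append(
            {
                "layer": "Conv2D",
                "output_shape": (size, size, f),
                "params": k * k * c_in * f + f,
            }
        )
        c_in = f
    rows_dec = []
    for f in arch.decoder_filters:
        size *= arch.stride
        rows_dec.append(
            {
                "layer": "Conv2DTranspose",
                "output_shape": (size, size, f),
                "params": k * k * c_in * f + f,
            }
        )
        c_in = f
    return {
        "encoder": rows_enc,
        "decoder": rows_dec,
        "encoder_total": sum(r["params"] for r in rows_enc),
        "decoder_total": sum(r["params"] for r in rows_dec),
        "total": sum(r["params"] for r in rows_enc + rows_dec),
    }


def psnr(original: np.ndarray, reconstruction: np.ndarray, cap: float = PSNR_CAP_DB) -> float:
    """Peak signal-to-noise ratio in dB for images on the [0, 1] scale.

    ``10 * log10(1 / MSE)``, capped at ``cap`` dB when the MSE is zero
    (or so small that the formula would exceed the cap).
    """
    a = np.asarray(original, dtype=np.float64)
    b = np.asarray(reconstruction, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    mse = float(np.mean((a - b) ** 2))
    if mse == 0.0:
        return cap
    return min(10.0 * np.log10(1.0 / mse), cap)


class ConvAutoencoder(TransformerMixin, BaseEstimator):
    """Sklearn-style convolutional autoencoder.

    ``fit`` trains on a stack of images (n, S, S) with pixel values in
    [0, 1]; ``transform`` returns flattened latent codes of length
    ``architecture.latent_dim``.  Training is seeded and
    bit-reproducible on a single thread.
    """

    def __init__(
        self,
        image_size: int = CANONICAL_IMAGE_SIZE,
        encoder_filters: Sequence[int] = CANONICAL_ENCODER_FILTERS,
        kernel_size: int = 3,
        stride: int = 2,
        epochs: int = 10,
        batch_size: int = 32,
        learning_rate: float = 1e-3,
        seed: int = 0,
    ):
        self.image_size = image_size
        self.encoder_filters = tuple(encoder_filters)
        self.kernel_size = kernel_size
        self.stride = stride
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.seed = seed

    # -- construction -------------------------------------------------

    @property
    def architecture(self) -> CAEArchitecture:
        return CAEArchitecture(
            image_size=self.image_size,
            encoder_filters=self.encoder_filters,
            kernel_size=self.kernel_size,
            stride=self.stride,
        )

    def initialize(self) -> "ConvAutoencoder":
        """Build seeded Glorot-initialised weights without training."""
        arch = self.architecture
        rng = np.random.default_rng(self.seed)
        k = arch.kernel_size
        layers = []
        c_in = 1
        for f in arch.encoder_filters:
            w = glorot_uniform(rng, (k, k, c_in, f), k * k * c_in, k * k * f)
            layers.append({"type": "conv", "w": w, "b": np.zeros(f), "act": "relu"})
            c_in = f
        dec = arch.decoder_filters
        for i, f in enumerate(dec):
            w = glorot_uniform(rng, (k, k, f, c_in), k * k * c_in, k * k * f)
            act = "sigmoid" if i == len(dec) - 1 else "relu"
            layers.append({"type": "convt", "w": w, "b": np.zeros(f), "act": act})
            c_in = f
        self.layers_ = layers
        self.architecture_ = arch
        self.loss_history_ = []
        return self

    def parameter_report(self) -> dict:
        return parameter_report(self.architecture)

    # -- forward / backward -------------------------------------------

    def _forward(self, x: np.ndarray, with_cache: bool = False):
        caches = []
        h = x
        for layer in self.layers_:
            if layer["type"] == "conv":
                z = conv2d(h, layer["w"], layer["b"], self.stride)
            else:
                z = conv2d_transpose(h, layer["w"], layer["b"], self.stride)
            y = relu(z) if layer["act"] == "relu" else sigmoid(z)
            if with_cache:
                caches.append((h, z, y))
            h = y
        return (h, caches) if with_cache else h

    def _backward(self, dy: np.ndarray, caches) -> list[np.ndarray]:
        grads: list[np.ndarray] = []
        for layer, (h_in, z, y) in zip(reversed(self.layers_), reversed(caches)):
            if layer["act"] == "relu":
                dz = dy * (z > 0)
            else:
                dz = dy * y * (1.0 - y)
            if layer["type"] == "conv":
                dy, dw, db = conv2d_backward(dz, h_in, layer["w"], self.stride)
            else:
                dy, dw, db = conv2d_transpose_backward(dz, h_in, layer["w"], self.stride)
            grads.extend([db, dw])
        grads.reverse()
        return grads

    # -- estimator API -------------------------------------------------

    def _as_nhwc(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 3:
            X = X[..., np.newaxis]
        if X.ndim != 4 or X.shape[1] != self.image_size or X.shape[2] != self.image_size:
            raise ValueError(
                f"expected images of shape (n, {self.image_size}, {self.image_size})"
            )
        return X

    def fit(self, X, y=None) -> "ConvAutoencoder":
        X = self._as_nhwc(X)
        if X.shape[0] == 0:
            raise ValueError("cannot train on an empty image set")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        self.initialize()
        params = [p for layer in self.layers_ for p in (layer["w"], layer["b"])]
        opt = Adam(params, lr=self.learning_rate)
        rng = np.random.default_rng(self.seed + 1)
        n = X.shape[0]
        for _ in range(self.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                xb = X[idx]
                xhat, caches = self._forward(xb, with_cache=True)
                diff = xhat - xb
                epoch_loss += float(np.sum(diff**2))
                dy = 2.0 * diff / diff.size
                grads = self._backward(dy, caches)
                opt.step(grads)  # ordered (w, b) per layer, matching params
            self.loss_history_.append(epoch_loss / X.size)
        return self

    def encode(self, X, batch_size: int = 32) -> np.ndarray:
        """Flattened latent codes, shape (n, latent_dim)."""
        if not hasattr(self, "layers_"):
            raise ValueError("model is neither trained nor initialized")
        X = self._as_nhwc(X)
        n_enc = len(self.encoder_filters)
        codes = []
        for start in range(0, X.shape[0], batch_size):
            h = X[start : start + batch_size]
            for layer in self.layers_[:n_enc]:
                z = conv2d(h, layer["w"], layer["b"], self.stride)
                h = relu(z)
            codes.append(h.reshape(h.shape[0], -1))
        return np.concatenate(codes, axis=0)

    def decode(self, codes: np.ndarray, batch_size: int = 32) -> np.ndarray:
        """Reconstructions in [0, 1], shape (n, S, S, 1)."""
        if not hasattr(self, "layers_"):
            raise ValueError("model is neither trained nor initialized")
        codes = np.asarray(codes, dtype=np.float64)
        if codes.ndim == 1:
            codes = codes[np.newaxis, :]
        arch = self.architecture_
        if codes.shape[1] != arch.latent_dim:
            raise ValueError(f"expected codes of length {arch.latent_dim}")
        n_enc = len(self.encoder_filters)
        outs = []
        for start in range(0, codes.shape[0], batch_size):
            h = codes[start : start + batch_size].reshape(-1, *arch.latent_shape)
            for layer in self.layers_[n_enc:]:
                z = conv2d_transpose(h, layer["w"], layer["b"], self.stride)
                h = relu(z) if layer["act"] == "relu" else sigmoid(z)
            outs.append(h)
        return np.concatenate(outs, axis=0)

    def reconstruct(self, X, batch_size: int = 32) -> np.ndarray:
        return self.decode(self.encode(X, batch_size), batch_size)

    def transform(self, X) -> np.ndarray:
        return self.encode(X)

    def reconstruction_psnr(self, X, cap: float = PSNR_CAP_DB) -> float:
        """PSNR (dB) of the model's reconstruction of an image stack."""
        X = self._as_nhwc(X)
        return psnr(X, self.reconstruct(X), cap=cap)

    # -- persistence ---------------------------------------------------

    def save_weights(self, path) -> None:
        """Serialize all layer weights and the loss history to one
        ``.npz`` checkpoint file."""
        if not hasattr(self, "layers_"):
            raise ValueError("model is neither trained nor initialized")
        arrays = {"loss_history": np.asarray(self.loss_history_)}
        for i, layer in enumerate(self.layers_):
            arrays[f"w{i}"] = layer["w"]
            arrays[f"b{i}"] = layer["b"]
        np.savez(path, **arrays)

    def load_weights(self, path) -> "ConvAutoencoder":
        """Restore weights from a checkpoint written by ``save_weights``.

        The estimator's architecture parameters must match the
        checkpoint's array shapes.
        """
        self.initialize()
        with np.load(path) as data:
            self.loss_history_ = list(data["loss_history"])
            for i, layer in enumerate(self.layers_):
                w, b = data[f"w{i}"], data[f"b{i}"]
                if w.shape != layer["w"].shape:
                    raise ValueError(
                        f"checkpoint layer {i} shape {w.shape} does not match "
                        f"architecture {layer['w'].shape}"
                    )
                layer["w"], layer["b"] = w, b
        return self
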