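"""Hybrid feature fusion: PCA-reduced latent codes + statistical bank.

The autoencoder's flattened bottleneck codes are reduced to 128
principal components, then concatenated with the 16 statistical
features of the same window (latent block first, statistical block
second, fixed order).  The window index of the two blocks must match —
the fusion exists precisely to align time–frequency and statistical
views of the *same* EEG packet, so a mismatch is a hard error.

Two numerical policies:

* PCA is fitted on the training split only and uses the exact full SVD
  with a deterministic sign convention (each component's
  largest-magnitude loading is positive), so results do not depend on
  solver randomisation.  Transforming test data never updates the
  fitted model.
* The statistical features are z-scored with training-split mean and
  standard deviation before concatenation: their raw scales (e.g.
  energy vs skewness) differ by orders of magnitude and would
  otherwise dominate the classifier input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA

from .cae import LatentCode


class IndexAlignmentError(ValueError):
    """The latent and statistical blocks refer to different windows."""


@dataclass
class PCAModel:
    """Fitted PCA: data mean, orthonormal components (rows), and the
    non-increasing explained variance of each component."""

    mean: np.ndarray
    components: np.ndarray
    explained_variance: np.ndarray

    @property
    def n_components(self) -> int:
        return self.components.shape[0]


def _fix_signs(components: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-|loading| entry positive."""
    idx = np.argmax(np.abs(components), axis=1)
    signs = np.sign(components[np.arange(components.shape[0]), idx])
    signs[signs == 0] = 1.0
    return components * signs[:, np.newaxis]


def fit_pca(codes: np.ndarray, n_components: int = 128) -> PCAModel:
    """Fit PCA on (training) latent codes, shape (n_codes, latent_dim).

    ``n_components`` is reduced with a warning if it exceeds what the
    data can support (min(n_codes - 1, latent_dim)).
    """
    codes = np.asarray(codes, dtype=np.float64)
    if codes.ndim == 1:
        codes = codes[np.newaxis, :]
    if codes.shape[0] < 2:
        raise ValueError("fit_pca requires at least 2 codes")
    limit = min(codes.shape[0] - 1, codes.shape[1])
    if n_components > limit:
        warnings.warn(
            f"n_components={n_components} exceeds the data rank limit {limit}; reducing",
            RuntimeWarning,
            stacklevel=2,
        )
        n_components = limit
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(codes)
    return PCAModel(
        mean=pca.mean_.copy(),
        components=_fix_signs(pca.components_.copy()),
        explained_variance=pca.explained_variance_.copy(),
    )


def reduce(code: np.ndarray | LatentCode, model: PCAModel) -> np.ndarray:
    """Project a code (or stack of codes) onto the fitted components."""
    values = code.values if isinstance(code, LatentCode) else np.asarray(code, dtype=np.float64)
    if values.shape[-1] != model.mean.shape[0]:
        raise ValueError(
            f"code length {values.shape[-1]} != fitted dimension {model.mean.shape[0]}"
        )
    return (values - model.mean) @ model.components.T


def fuse(
    latent: np.ndarray,
    stats: np.ndarray,
    latent_index: int | None = None,
    stats_index: int | None = None,
) -> np.ndarray:
    """Concatenate one window's PCA-latent block and statistical block.

    If both indices are given they must agree (the per-window alignment
    constraint of the hybrid pool).
    """
    if latent_index is not None and stats_index is not None and latent_index != stats_index:
        raise IndexAlignmentError(
            f"window index mismatch: latent {latent_index} vs stats {stats_index}"
        )
    latent = np.asarray(latent, dtype=np.float64).ravel()
    stats = np.asarray(stats, dtype=np.float64).ravel()
    return np.concatenate([latent, stats])


class HybridFeatureFusion(BaseEstimator):
    """Fit-on-train / transform-anywhere fusion of the two feature blocks.

    ``fit(latent, stats)`` learns the PCA on the latent codes and the
    z-scoring statistics of the feature bank from the training split;
    ``transform(latent, stats)`` returns the (n, n_components + 16)
    hybrid matrix.  Slicing ``[:, :n_components]`` and
    ``[:, n_components:]`` recovers the constituent blocks exactly.
    """

    def __init__(self, n_components: int = 128, zscore_stats: bool = True):
        self.n_components = n_components
        self.zscore_stats = zscore_stats

    def fit(self, latent: np.ndarray, stats: np.ndarray) -> "HybridFeatureFusion":
        latent = np.asarray(latent, dtype=np.float64)
        stats = np.asarray(stats, dtype=np.float64)
        if latent.shape[0] != stats.shape[0]:
            raise IndexAlignmentError(
                f"block row counts differ: {latent.shape[0]} vs {stats.shape[0]}"
            )
        self.pca_ = fit_pca(latent, self.n_components)
        self.stats_mean_ = stats.mean(axis=0)
        sd = stats.std(axis=0)
        sd[sd == 0] = 1.0  # constant features pass through centred
        self.stats_scale_ = sd
        return self

    def transform(self, latent: np.ndarray, stats: np.ndarray) -> np.ndarray:
        latent = np.asarray(latent, dtype=np.float64)
        stats = np.asarray(stats, dtype=np.float64)
        if latent.shape[0] != stats.shape[0]:
            raise IndexAlignmentError(
                f"block row counts differ: {latent.shape[0]} vs {stats.shape[0]}"
            )
        reduced = reduce(latent, self.pca_)
        if self.zscore_stats:
            stats = (stats - self.stats_mean_) / self.stats_scale_
        return np.hstack([reduced, stats])

    def fit_transform(self, latent: np.ndarray, stats: np.ndarray) -> np.ndarray:
        return self.fit(latent, stats).transform(latent, stats)
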