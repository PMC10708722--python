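"""The 16-feature statistical bank computed per window.

Conventions, fixed once and used everywhere:

* variance and standard deviation use the sample (N-1) normalisation;
* kurtosis and skewness are the *non-excess* standardised moments
  ``(1/N) * sum(((s - mu) / sigma) ** k)`` for k = 4 and 3, so a
  Gaussian signal has kurtosis ~= 3;
* crest factor uses the signed maximum ``max(s) / rms`` while
  peak-to-RMS uses ``max(|s|) / rms`` — they are intentionally distinct
  features;
* clearance factor is ``max(|s|) / mean(sqrt(|s|)) ** 2`` (the standard
  definition);
* energy is ``sum(s**2)`` and power is ``sum(s**2) / N``, so
  ``energy == N * power`` exactly.

A constant window has sigma == 0; its skewness, kurtosis and (for an
all-zero window) the ratio factors are returned as 0 with a warning so
downstream feature matrices stay finite.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .windowing import WindowSegment

#: Fixed feature order; this is also the CSV column order.
STAT_FEATURE_NAMES = (
    "minimum",
    "maximum",
    "mean",
    "standard_deviation",
    "kurtosis",
    "skewness",
    "rms",
    "crest_factor",
    "range",
    "energy",
    "clearance_factor",
    "variance",
    "impulse_factor",
    "power",
    "peak_to_rms",
    "shape_factor",
)

N_STAT_FEATURES = len(STAT_FEATURE_NAMES)


def compute_stats(window: WindowSegment | np.ndarray) -> np.ndarray:
    """Compute the 16 statistical features of one window.

    Returns a vector in the order of :data:`STAT_FEATURE_NAMES`.
    Requires at least 2 finite samples.
    """
    s = window.samples if isinstance(window, WindowSegment) else np.asarray(window, dtype=np.float64)
    n = s.size
    if n < 2:
        raise ValueError("compute_stats requires a window of at least 2 samples")
    if not np.all(np.isfinite(s)):
        raise ValueError("compute_stats requires finite samples")

    mn = float(np.min(s))
    mx = float(np.max(s))
    mu = float(np.sum(s) / n)
    dev = s - mu
    variance = float(np.sum(dev**2) / (n - 1))
    sigma = float(np.sqrt(variance))
    energy = float(np.sum(s**2))
    power = energy / n
    rms = float(np.sqrt(power))
    abs_s = np.abs(s)
    peak = float(np.max(abs_s))
    mean_abs = float(np.mean(abs_s))
    mean_sqrt_abs = float(np.mean(np.sqrt(abs_s)))

    if sigma > 0:
        kurtosis = float(np.mean((dev / sigma) ** 4))
        skewness = float(np.mean((dev / sigma) ** 3))
    else:
        warnings.warn(
            "constant window (sigma == 0): skewness/kurtosis undefined, returning 0",
            RuntimeWarning,
            stacklevel=2,
        )
        kurtosis = 0.0
        skewness = 0.0

    if rms > 0:
        crest = mx / rms
        peak_to_rms = peak / rms
    else:
        warnings.warn(
            "all-zero window: ratio factors undefined, returning 0",
            RuntimeWarning,
            stacklevel=2,
        )
        crest = 0.0
        peak_to_rms = 0.0
    clearance = peak / mean_sqrt_abs**2 if mean_sqrt_abs > 0 else 0.0
    impulse = peak / mean_abs if mean_abs > 0 else 0.0
    shape = rms / mean_abs if mean_abs > 0 else 0.0

    return np.array(
        [
            mn,
            mx,
            mu,
            sigma,
            kurtosis,
            skewness,
            rms,
            crest,
            mx - mn,
            energy,
            clearance,
            variance,
            impulse,
            power,
            peak_to_rms,
            shape,
        ]
    )


def stat_feature_matrix(windows) -> np.ndarray:
    """Stack per-window feature vectors into an (n_windows, 16) matrix."""
    return np.stack([compute_stats(w) for w in windows])


class StatFeatureExtractor(TransformerMixin, BaseEstimator):
    """Stateless sklearn transformer: (n_windows, omega) -> (n_windows, 16)."""

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2:
            raise ValueError("expected a 2-D (n_windows, omega) array")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2:
            raise ValueError("expected a 2-D (n_windows, omega) array")
        return stat_feature_matrix(X)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(STAT_FEATURE_NAMES, dtype=object)
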