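"""Morlet CWT scalogram images of EEG windows.

Each window is transformed with the continuous wavelet transform using
a complex Morlet mother wavelet, and the coefficient magnitude matrix
(scales x time) is resampled to a square single-channel image and
min-max normalised to [0, 1].

The scale grid is logarithmically spaced to cover pseudo-frequencies
0.5–85 Hz (just below the 86.8 Hz Nyquist frequency at the 173.61 Hz
sampling rate), spanning the clinical EEG bands from slow delta to
gamma.  Scales are sorted ascending, so row 0 of the scalogram is the
smallest scale (highest frequency) and time runs left to right.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pywt
from skimage.transform import resize
from sklearn.base import BaseEstimator, TransformerMixin

from .io import DEFAULT_FS
from .windowing import WindowSegment

#: Default complex Morlet: bandwidth 1.5, center frequency 1.0 cycles.
DEFAULT_WAVELET = "cmor1.5-1.0"


def morlet_scales(
    wavelet: str = DEFAULT_WAVELET,
    fs: float = DEFAULT_FS,
    n_scales: int = 128,
    fmin: float = 0.5,
    fmax: float = 85.0,
) -> np.ndarray:
    """Log-spaced scale grid covering pseudo-frequencies [fmin, fmax] Hz.

    The scale for frequency f is ``fc * fs / f`` with fc the wavelet
    center frequency; the grid is returned ascending (high frequency
    first row of the scalogram).
    """
    if not 0 < fmin < fmax:
        raise ValueError("need 0 < fmin < fmax")
    if fmax >= fs / 2:
        raise ValueError(f"fmax={fmax} must stay below the Nyquist frequency {fs / 2}")
    fc = pywt.central_frequency(wavelet)
    freqs = np.logspace(np.log10(fmax), np.log10(fmin), n_scales)
    return fc * fs / freqs


@dataclass(frozen=True)
class CWTParams:
    """CWT configuration: mother wavelet, scale grid, sampling rate,
    and output image size in pixels."""

    wavelet: str = DEFAULT_WAVELET
    fs: float = DEFAULT_FS
    scales: np.ndarray = field(default=None)  # type: ignore[assignment]
    n_scales: int = 128
    fmin: float = 0.5
    fmax: float = 85.0
    image_size: int = 256

    def __post_init__(self) -> None:
        if self.image_size < 8:
            raise ValueError("image_size must be >= 8")
        if self.scales is None:
            object.__setattr__(
                self,
                "scales",
                morlet_scales(self.wavelet, self.fs, self.n_scales, self.fmin, self.fmax),
            )
        scales = np.asarray(self.scales, dtype=np.float64)
        if scales.size < 2 or np.any(scales <= 0):
            raise ValueError("scales must be >= 2 strictly positive values")
        if np.any(np.diff(scales) <= 0):
            raise ValueError("scales must be sorted strictly ascending")
        object.__setattr__(self, "scales", scales)

    @property
    def frequencies(self) -> np.ndarray:
        """Pseudo-frequency (Hz) of each scale."""
        return pywt.scale2frequency(self.wavelet, self.scales) * self.fs


@dataclass
class ScalogramImage:
    """A square single-channel magnitude image with pixels in [0, 1]."""

    pixels: np.ndarray
    window_index: int = 0
    class_id: str | None = None


def cwt(window: WindowSegment | np.ndarray, params: CWTParams) -> np.ndarray:
    """Complex CWT coefficients, shape (n_scales, omega).

    ``coefficients[j, k]`` approximates the wavelet transform at scale
    ``scales[j]`` and translation ``k / fs``; the transform is linear
    in the input.
    """
    x = window.samples if isinstance(window, WindowSegment) else np.asarray(window, dtype=np.float64)
    if x.size < 2:
        raise ValueError("cwt requires a window of at least 2 samples")
    coef, _ = pywt.cwt(x, params.scales, params.wavelet, method="fft")
    return coef


def render_image(coefficients: np.ndarray, image_size: int = 256) -> np.ndarray:
    """Magnitude image: |coefficients| resampled bilinearly to
    (image_size, image_size) and min-max normalised to [0, 1].

    A constant coefficient matrix has no dynamic range; it renders as
    an all-zero image with a warning.
    """
    mag = np.abs(np.asarray(coefficients))
    if not np.all(np.isfinite(mag)):
        raise ValueError("coefficient matrix must be finite")
    img = resize(
        mag, (image_size, image_size), order=1, mode="edge",
        anti_aliasing=False, preserve_range=True,
    )
    lo, hi = float(img.min()), float(img.max())
    if hi <= lo:
        warnings.warn(
            "degenerate (constant) coefficient matrix: rendering an all-zero image",
            RuntimeWarning,
            stacklevel=2,
        )
        return np.zeros((image_size, image_size))
    return (img - lo) / (hi - lo)


def scalogram(window: WindowSegment | np.ndarray, params: CWTParams) -> ScalogramImage:
    """Full window -> image transform (CWT magnitude, resample, normalise)."""
    pixels = render_image(cwt(window, params), params.image_size)
    if isinstance(window, WindowSegment):
        return ScalogramImage(pixels, window_index=window.index, class_id=window.class_id)
    return ScalogramImage(pixels)


def save_png(image: ScalogramImage | np.ndarray, path) -> None:
    """Optional 8-bit grayscale PNG export for visual inspection.

    Not part of the numeric pipeline; the classifier consumes float
    images directly.
    """
    from PIL import Image

    pixels = image.pixels if isinstance(image, ScalogramImage) else np.asarray(image)
    Image.fromarray((np.clip(pixels, 0, 1) * 255).astype(np.uint8), mode="L").save(path)


class ScalogramTransformer(TransformerMixin, BaseEstimator):
    """Sklearn transformer: (n_windows, omega) -> (n_windows, S, S) images."""

    def __init__(
        self,
        wavelet: str = DEFAULT_WAVELET,
        fs: float = DEFAULT_FS,
        n_scales: int = 128,
        fmin: float = 0.5,
        fmax: float = 85.0,
        image_size: int = 256,
    ):
        self.wavelet = wavelet
        self.fs = fs
        self.n_scales = n_scales
        self.fmin = fmin
        self.fmax = fmax
        self.image_size = image_size

    def _params(self) -> CWTParams:
        return CWTParams(
            wavelet=self.wavelet, fs=self.fs, n_scales=self.n_scales,
            fmin=self.fmin, fmax=self.fmax, image_size=self.image_size,
        )

    def fit(self, X, y=None):
        self.params_ = self._params()
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2:
            raise ValueError("expected a 2-D (n_windows, omega) array")
        params = getattr(self, "params_", None) or self._params()
        return np.stack([scalogram(row, params).pixels for row in X])
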