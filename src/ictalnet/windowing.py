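"""Overlapping sliding-window segmentation.

For a signal of length ``L``, window length ``omega`` and overlap
``theta`` (both in samples), the i-th window (1-based) covers the
1-based inclusive sample range::

    start_i = 1 + (i - 1) * (omega - theta)
    end_i   = omega + (i - 1) * (omega - theta)

Windows are emitted for i = 1..n with n = floor((L - omega) /
(omega - theta)) + 1; trailing samples that do not fill a final window
are dropped (the count is logged).  Coordinates are kept 1-based
inclusive inside this module so that assertions can be written directly
against the closed form; slicing converts at the array boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import ChainedSignal

logger = logging.getLogger(__name__)

#: Window length used throughout the study, samples.
DEFAULT_OMEGA = 1458
#: Overlap between consecutive windows, samples.
DEFAULT_THETA = 486


@dataclass(frozen=True)
class WindowParams:
    """Window length ``omega`` and overlap ``theta``, in samples."""

    omega: int = DEFAULT_OMEGA
    theta: int = DEFAULT_THETA

    def __post_init__(self) -> None:
        if self.omega <= 0:
            raise ValueError("window length omega must be positive")
        if not 0 <= self.theta < self.omega:
            raise ValueError(
                f"overlap theta must satisfy 0 <= theta < omega, got "
                f"theta={self.theta}, omega={self.omega}"
            )

    @property
    def step(self) -> int:
        return self.omega - self.theta


@dataclass
class WindowSegment:
    """One window: 1-based index and inclusive [start, end] positions."""

    index: int
    start: int
    end: int
    samples: np.ndarray
    class_id: str | None = None

    def __len__(self) -> int:
        return self.samples.size


def count_windows(length: int, params: WindowParams) -> int:
    """Closed-form number of full windows in a signal of ``length`` samples."""
    if length < params.omega:
        raise ValueError(f"signal length {length} is shorter than the window {params.omega}")
    return (length - params.omega) // params.step + 1


def dropped_samples(length: int, params: WindowParams) -> int:
    """Trailing samples not covered by the final full window."""
    n = count_windows(length, params)
    last_end = params.omega + (n - 1) * params.step
    return length - last_end


def segment(signal: ChainedSignal | np.ndarray, params: WindowParams) -> list[WindowSegment]:
    """Cut a chained signal into overlapping windows.

    Consecutive windows share exactly ``theta`` samples.  Requires
    ``len(signal) >= omega``.
    """
    if isinstance(signal, ChainedSignal):
        samples = signal.samples
        class_id = signal.class_id
    else:
        samples = np.asarray(signal, dtype=np.float64)
        class_id = None
    length = samples.size
    n = count_windows(length, params)
    dropped = dropped_samples(length, params)
    if dropped:
        logger.info(
            "segment: %d windows (omega=%d, theta=%d), %d trailing samples dropped",
            n, params.omega, params.theta, dropped,
        )
    windows = []
    for i in range(1, n + 1):
        start = 1 + (i - 1) * params.step
        end = params.omega + (i - 1) * params.step
        windows.append(
            WindowSegment(
                index=i,
                start=start,
                end=end,
                samples=samples[start - 1 : end],
                class_id=class_id,
            )
        )
    return windows


def window_matrix(windows: list[WindowSegment]) -> np.ndarray:
    """Stack window samples into an (n_windows, omega) array."""
    return np.stack([w.samples for w in windows])
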