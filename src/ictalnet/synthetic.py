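"""Seeded synthetic five-class EEG generator.

Emulates the metadata and coarse morphology of the five Bonn epilepsy
sets so the whole pipeline is testable without downloading the corpus:

* ``Z`` — healthy, eyes open: 1/f-like background plus a modest alpha
  (10 Hz) oscillation.
* ``O`` — healthy, eyes closed: same background with a markedly larger
  alpha amplitude (eye closure enhances the posterior alpha rhythm).
* ``N`` — interictal, opposite hemisphere: background plus sparse
  Poisson-timed biphasic interictal spikes.
* ``F`` — interictal, epileptogenic zone: like ``N`` with twice the
  spike rate.
* ``S`` — ictal: a high-amplitude rhythmic 3–5 Hz discharge with a
  second-harmonic component, superimposed on background noise.

All morphology parameters are stand-ins chosen for plausibility and
class separability; they are not fit to the real corpus.  Amplitudes
are unitless (no calibration to physical microvolts is attempted).
Records default to 4097 samples at 173.61 Hz, 100 records per class,
matching the corpus metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .io import CLASS_ORDER, DEFAULT_FS, RECORD_LENGTH, EEGRecord, write_record

#: Width of the biphasic interictal spike transient, seconds.
SPIKE_WIDTH_S = 0.070


@dataclass(frozen=True)
class ClassModel:
    """Generative parameters for one synthetic class.

    ``background_bands`` lists (center frequency Hz, amplitude a.u.)
    sinusoidal components; ``spike_rate`` is the Poisson rate of
    interictal spikes in events/s (0 for Z, O, S); ``ictal_freq`` and
    ``ictal_amplitude`` describe the rhythmic seizure discharge (S
    only).
    """

    class_id: str
    background_bands: tuple[tuple[float, float], ...] = ()
    noise_sigma: float = 1.0
    spike_rate: float = 0.0
    spike_amplitude: float = 0.0
    ictal_freq: float = 0.0
    ictal_amplitude: float = 0.0
    n_samples: int = RECORD_LENGTH
    fs: float = DEFAULT_FS

    def __post_init__(self) -> None:
        if self.spike_rate < 0:
            raise ValueError("spike_rate must be >= 0")
        for name in ("noise_sigma", "spike_amplitude", "ictal_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if any(a < 0 or f <= 0 for f, a in self.background_bands):
            raise ValueError("background bands need positive frequency and amplitude >= 0")
        if self.n_samples < 2 or self.fs <= 0:
            raise ValueError("n_samples >= 2 and fs > 0 required")


def default_class_models() -> dict[str, ClassModel]:
    """The default five-class configuration.

    Chosen so that per-record energy trivially separates S from the
    healthy classes, O has a visibly larger alpha rhythm than Z, and F
    doubles the spike rate of N (it sits inside the epileptogenic
    zone, so it is similar to N but distinguishable).
    """
    return {
        "Z": ClassModel("Z", background_bands=((10.0, 1.0),)),
        "O": ClassModel("O", background_bands=((10.0, 2.5),)),
        "N": ClassModel(
            "N", background_bands=((6.0, 1.0),), spike_rate=1.0, spike_amplitude=5.0
        ),
        "F": ClassModel(
            "F", background_bands=((6.0, 1.0),), spike_rate=2.0, spike_amplitude=5.0
        ),
        "S": ClassModel(
            "S",
            background_bands=((10.0, 0.5),),
            noise_sigma=1.0,
            ictal_freq=4.0,
            ictal_amplitude=8.0,
        ),
    }


def _pink_noise(rng: np.random.Generator, n: int, sigma: float) -> np.ndarray:
    """1/f-like background: white noise through a first-order IIR lowpass,
    rescaled to standard deviation ``sigma``."""
    w = rng.standard_normal(n + 200)
    x = np.empty_like(w)
    a = 0.95
    acc = 0.0
    # lfilter-free loop avoided: use scipy-equivalent recursion vectorised
    # via cumulative form is numerically awkward; n is small, do it simply.
    for i in range(w.size):
        acc = a * acc + w[i]
        x[i] = acc
    x = x[200:]  # drop filter transient
    sd = x.std()
    if sd > 0 and sigma > 0:
        x = x * (sigma / sd)
    else:
        x = np.zeros(n)
    return x


def _spike_kernel(fs: float) -> np.ndarray:
    """Biphasic raised-cosine transient of ~70 ms (canonical interictal
    spike width): a positive lobe followed by a negative one, tapered by
    a Hann window so it starts and ends at zero."""
    n = max(int(round(SPIKE_WIDTH_S * fs)), 4)
    t = np.arange(n) / n
    hann = 0.5 - 0.5 * np.cos(2 * np.pi * t)
    return np.sin(2 * np.pi * t) * hann


def _synthesize(model: ClassModel, rng: np.random.Generator) -> np.ndarray:
    n = model.n_samples
    fs = model.fs
    t = np.arange(n) / fs
    x = _pink_noise(rng, n, model.noise_sigma)
    for freq, amp in model.background_bands:
        phase = rng.uniform(0, 2 * np.pi)
        # slow random amplitude modulation for a non-stationary rhythm
        mod = 1.0 + 0.3 * np.sin(2 * np.pi * rng.uniform(0.1, 0.4) * t + rng.uniform(0, 2 * np.pi))
        x += amp * mod * np.sin(2 * np.pi * freq * t + phase)
    if model.spike_rate > 0 and model.spike_amplitude > 0:
        kernel = _spike_kernel(fs)
        n_events = rng.poisson(model.spike_rate * n / fs)
        starts = rng.integers(0, max(n - kernel.size, 1), size=n_events)
        for s0 in starts:
            amp = model.spike_amplitude * (1.0 + 0.2 * rng.standard_normal())
            x[s0 : s0 + kernel.size] += amp * kernel
    if model.ictal_amplitude > 0 and model.ictal_freq > 0:
        phase = rng.uniform(0, 2 * np.pi)
        # fundamental plus a weak second harmonic: sharp rhythmic discharge
        x += model.ictal_amplitude * (
            np.sin(2 * np.pi * model.ictal_freq * t + phase)
            + 0.3 * np.sin(4 * np.pi * model.ictal_freq * t + 2 * phase)
        )
    return x


def generate_class(model: ClassModel, n_records: int, seed: int) -> list[EEGRecord]:
    """Generate ``n_records`` seeded records for one class.

    Identical (model, n_records, seed) yields bit-identical output.
    """
    if n_records < 1:
        raise ValueError("n_records must be >= 1")
    rng = np.random.default_rng(seed)
    return [
        EEGRecord(_synthesize(model, rng), fs=model.fs, class_id=model.class_id, record_index=i)
        for i in range(n_records)
    ]


def class_seed(master_seed: int, class_id: str) -> int:
    """Deterministic per-class child seed (< 2**31) from a master seed."""
    idx = CLASS_ORDER.index(class_id)
    ss = np.random.SeedSequence([int(master_seed), idx])
    return int(ss.generate_state(1, np.uint32)[0] % (2**31))


def generate_dataset(
    config: Mapping[str, ClassModel] | None = None,
    n_records: int = 100,
    seed: int = 0,
) -> dict[str, list[EEGRecord]]:
    """Generate a full five-class dataset keyed by class id.

    Per-class seeds are derived deterministically from the master seed,
    so each class is reproducible in isolation.
    """
    if config is None:
        config = default_class_models()
    missing = [c for c in CLASS_ORDER if c not in config]
    if missing:
        raise ValueError(f"missing class models: {missing}")
    return {
        c: generate_class(config[c], n_records, class_seed(seed, c))
        for c in CLASS_ORDER
    }


def write_dataset(dataset: Mapping[str, list[EEGRecord]], root: str | Path) -> Path:
    """Write records in the ASCII dialect into per-class directories."""
    root = Path(root)
    for class_id, records in dataset.items():
        for rec in records:
            write_record(rec, root / class_id / f"{class_id}{rec.record_index:03d}.txt")
    return root


def load_models_yaml(path: str | Path) -> dict[str, ClassModel]:
    """Read class models from a YAML mapping of class id to field values.

    Fields not given fall back to the defaults of :func:`default_class_models`.
    """
    with Path(path).open("r") as fh:
        raw = yaml.safe_load(fh) or {}
    models = default_class_models()
    for class_id, overrides in raw.items():
        if class_id not in models:
            raise ValueError(f"unknown class id in config: {class_id!r}")
        overrides = dict(overrides or {})
        if "background_bands" in overrides:
            overrides["background_bands"] = tuple(
                (float(f), float(a)) for f, a in overrides["background_bands"]
            )
        models[class_id] = replace(models[class_id], **overrides)
    return models
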