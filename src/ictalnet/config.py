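"""End-to-end pipeline configuration and static validation.

Defaults reproduce the study configuration: 1458-sample windows with
486-sample overlap, 256x256 Morlet scalograms, the five-layer
(16, 32, 64, 128, 255) autoencoder, 128 principal components, and a
128-unit LSTM trained for 50 epochs with batch size 32 and Adam.

:func:`reduced_config` is a desk-scale profile (20 records per class,
64x64 scalograms, a three-layer (8, 16, 32) autoencoder trained 10
epochs, a 32-unit LSTM trained 20 epochs) sized so a full five-class
run completes in minutes on one CPU core while exercising every stage.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

from .windowing import WindowParams

VALID_FEATURE_ARMS = ("fused", "latent", "stats")
VALID_SPLITS = ("window", "record")


@dataclass(frozen=True)
class PipelineConfig:
    scenario: str = "F-N-O-Z-S"
    n_records: int = 100
    fs: float = 173.61
    window: WindowParams = field(default_factory=WindowParams)
    # CWT / scalogram
    wavelet: str = "cmor1.5-1.0"
    n_scales: int = 128
    fmin: float = 0.5
    fmax: float = 85.0
    image_size: int = 256
    # autoencoder
    cae_filters: tuple[int, ...] = (16, 32, 64, 128, 255)
    cae_epochs: int = 20
    cae_batch_size: int = 32
    cae_learning_rate: float = 1e-3
    # fusion
    n_components: int = 128
    # classifier
    lstm_units: int = 128
    lstm_epochs: int = 50
    lstm_batch_size: int = 32
    lstm_learning_rate: float = 1e-3
    framing: str = "vector"
    # protocol
    features: str = "fused"
    split: str = "window"
    test_fraction: float = 0.2
    seed: int = 0
    data_dir: str | None = None  # read an on-disk ASCII corpus instead of generating

    def with_(self, **kwargs) -> "PipelineConfig":
        return replace(self, **kwargs)


def reduced_config(**overrides) -> PipelineConfig:
    """The desk-scale profile (see module docstring)."""
    cfg = PipelineConfig(
        n_records=20,
        n_scales=64,
        image_size=64,
        cae_filters=(8, 16, 32),
        cae_epochs=10,
        lstm_units=32,
        lstm_epochs=20,
    )
    return cfg.with_(**overrides) if overrides else cfg


def derive_seed(master_seed: int, label: str) -> int:
    """Stable per-stage child seed (< 2**31) from the master seed."""
    return (int(master_seed) * 1_000_003 + zlib.crc32(label.encode())) % (2**31)


def validate_config(config: PipelineConfig) -> list[str]:
    """Static validation; returns a list of human-readable violations
    (empty iff every module precondition holds)."""
    from .evaluation import build_scenario  # deferred: avoids an import cycle

    violations: list[str] = []
    try:
        build_scenario(config.scenario)
    except ValueError as exc:
        violations.append(f"scenario: {exc}")
    if config.n_records < 1:
        violations.append("n_records must be >= 1")
    if config.seed < 0:
        violations.append("seed must be non-negative")
    if not 0 < config.test_fraction < 1:
        violations.append("test_fraction must be in (0, 1)")
    if config.features not in VALID_FEATURE_ARMS:
        violations.append(f"features must be one of {VALID_FEATURE_ARMS}")
    if config.split not in VALID_SPLITS:
        violations.append(f"split must be one of {VALID_SPLITS}")
    if not 0 < config.fmin < config.fmax:
        violations.append("need 0 < fmin < fmax")
    if config.fmax >= config.fs / 2:
        violations.append("fmax must stay below the Nyquist frequency fs/2")
    if config.n_scales < 2:
        violations.append("n_scales must be >= 2")
    if config.image_size < 8:
        violations.append("image_size must be >= 8")
    n_layers = len(config.cae_filters)
    if config.image_size % (2**n_layers) != 0 or config.image_size // (2**n_layers) < 1:
        violations.append("image_size must be divisible by 2**len(cae_filters)")
    else:
        latent_dim = (config.image_size // (2**n_layers)) ** 2 * config.cae_filters[-1]
        if config.n_components > latent_dim:
            violations.append(
                f"fusion: n_components={config.n_components} exceeds the "
                f"latent dimension {latent_dim}"
            )
    for name in ("cae_epochs", "lstm_epochs", "cae_batch_size", "lstm_batch_size", "lstm_units"):
        if getattr(config, name) < 1:
            violations.append(f"{name} must be >= 1")
    if config.framing not in ("scalar", "vector"):
        violations.append("framing must be 'scalar' or 'vector'")
    return violations
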