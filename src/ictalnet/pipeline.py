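"""End-to-end orchestration: data, featurization, training, evaluation,
artifact writing.

``run`` executes the whole flow for one configured scenario — generate
or load records, chain and window, compute the statistical bank and
scalograms, train the autoencoder, fuse features, train the LSTM,
evaluate on the held-out split — and writes the metric report, the
confusion matrix and a manifest with a SHA-256 content hash per
artifact, so a run is fully reproducible from (config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path
import pandas as pd

from .config import PipelineConfig, validate_config
from .evaluation import ScenarioResult, ablation, ablation_table, featurize, run_scenario
from .io import EEGRecord, load_dataset_dir
from .synthetic import generate_dataset

logger = logging.getLogger(__name__)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def load_or_generate(config: PipelineConfig) -> dict[str, list[EEGRecord]]:
    """Synthetic records by default; an on-disk ASCII corpus if
    ``config.data_dir`` is set (the adapter path for the real data)."""
    if config.data_dir is not None:
        return load_dataset_dir(config.data_dir, fs=config.fs)
    return generate_dataset(n_records=config.n_records, seed=config.seed)


def _write_result(result: ScenarioResult, out_dir: Path, stem: str) -> list[Path]:
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    metrics_path = out_dir / f"{stem}_metrics.csv"
    pd.DataFrame([result.as_row()]).to_csv(metrics_path, index=False)
    paths.append(metrics_path)
    cm_path = out_dir / f"{stem}_confusion.csv"
    labels = result.scenario.labels
    pd.DataFrame(result.confusion, index=labels, columns=labels).to_csv(cm_path)
    paths.append(cm_path)
    return paths


def run(config: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Run one scenario end to end; returns a result bundle.

    The bundle holds the ``ScenarioResult``, the output paths and the
    manifest (artifact -> SHA-256).  Stage failures are re-raised with
    the stage name prepended.
    """
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid configuration: " + "; ".join(violations))
    stages: list[tuple[str, float]] = []

    def _stage(name, fn, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            out = fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        dt = time.perf_counter() - t0
        stages.append((name, dt))
        logger.info("stage %-12s %6.2fs", name, dt)
        return out

    dataset = _stage("data", load_or_generate, config)
    feat = _stage("featurize", featurize, dataset, config.scenario, config)
    result = _stage("classify", run_scenario, dataset, config.scenario, config, featurized=feat)

    bundle = {"result": result, "stages": stages, "paths": [], "manifest": {}}
    if out_dir is not None:
        out_dir = Path(out_dir)
        stem = result.scenario.name.replace("-", "")
        paths = _write_result(result, out_dir, stem)
        manifest = {p.name: _sha256(p) for p in paths}
        manifest_path = out_dir / f"{stem}_manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        bundle["paths"] = paths + [manifest_path]
        bundle["manifest"] = manifest
    return bundle


def run_ablation(config: PipelineConfig, out_dir: str | Path | None = None,
                 scenario: str = "F-N-O-Z-S") -> dict:
    """Latent / stats / fused arms on identical splits; optional CSV."""
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid configuration: " + "; ".join(violations))
    dataset = load_or_generate(config)
    results = ablation(dataset, config, scenario=scenario)
    table = ablation_table(results)
    bundle = {"results": results, "table": table, "paths": []}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        path = out_dir / "ablation.csv"
        table.to_csv(path, index=False)
        bundle["paths"] = [path]
    return bundle


def config_to_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    d["window"] = {"omega": config.window.omega, "theta": config.window.theta}
    return d
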