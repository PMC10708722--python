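"""Scenario construction, metrics, the scenario runner and the ablation.

A *scenario* is a classification problem over the five EEG classes:
groups of classes separated by hyphens, where letters inside one group
are merged into a single label.  ``"FN-S"`` is a binary problem whose
first label pools classes F and N against the seizure class S;
``"F-N-O-Z-S"`` is the full five-class problem.  The study's catalogue
spans 8 binary, 4 three-class, 2 four-class and 1 five-class scenario.

Metrics follow the usual confusion-matrix definitions: accuracy
``(TP + TN) / (TP + TN + FP + FN)``, precision ``TP / (TP + FP)``,
recall/sensitivity ``TP / (TP + FN)`` and the F1 score as the harmonic
mean of precision and recall.  Binary scenarios use the seizure (last)
group as the positive class; multi-class scenarios report macro
averages over one-vs-rest counts, plus per-class sensitivities.

The scenario runner executes the whole pipeline — chain, window,
statistical features + scalograms, autoencoder, PCA fusion, LSTM — on
a train split and evaluates on the held-out split.  The default split
is at the window level after chaining, which mirrors the
chain-then-window order of the segmentation stage but lets overlapping
windows of one record land on both sides of the split; a record-level
split mode avoids that leakage by partitioning records before
chaining.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import train_test_split

from .cae import ConvAutoencoder
from .config import PipelineConfig, derive_seed
from .features import stat_feature_matrix
from .fusion import HybridFeatureFusion
from .io import CLASS_ORDER, EEGRecord, chain_records
from .lstm import LSTMClassifier
from .scalogram import CWTParams, scalogram
from .windowing import segment

logger = logging.getLogger(__name__)

#: The study's 15 classification scenarios.
SCENARIO_CATALOGUE = (
    "N-S", "Z-S", "O-S", "F-S", "FN-S", "FNZ-S", "FNO-S", "NOZ-S",
    "F-O-S", "N-Z-S", "O-Z-S", "FN-OZ-S",
    "F-O-Z-S", "N-O-Z-S",
    "F-N-O-Z-S",
)


@dataclass(frozen=True)
class ScenarioSpec:
    """Ordered, disjoint groups of classes; one label per group."""

    name: str
    groups: tuple[frozenset[str], ...]
    group_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.groups:
            if not g:
                raise ValueError(f"{self.name!r}: empty class group")
            bad = g - set(CLASS_ORDER)
            if bad:
                raise ValueError(f"{self.name!r}: unknown class letters {sorted(bad)}")
            if g & seen:
                raise ValueError(f"{self.name!r}: overlapping groups ({sorted(g & seen)})")
            seen |= g
        if len(self.groups) < 2:
            raise ValueError(f"{self.name!r}: a scenario needs at least 2 groups")

    @property
    def n_labels(self) -> int:
        return len(self.groups)

    @property
    def labels(self) -> tuple[str, ...]:
        """Group label strings, spelled as parsed (e.g. 'FN')."""
        if self.group_names is not None:
            return self.group_names
        return tuple(
            "".join(c for c in CLASS_ORDER if c in g) for g in self.groups
        )

    @property
    def classes(self) -> tuple[str, ...]:
        return tuple(c for c in CLASS_ORDER if any(c in g for g in self.groups))


def build_scenario(name: str) -> ScenarioSpec:
    """Parse a scenario string such as ``"FN-OZ-S"`` (hyphen or en-dash)."""
    canonical = name.replace("–", "-").strip().upper()
    parts = [p for p in canonical.split("-") if p]
    groups = tuple(frozenset(p) for p in parts)
    return ScenarioSpec(name=canonical, groups=groups, group_names=tuple(parts))


def confusion(y_true, y_pred, n_labels: int) -> np.ndarray:
    """Counts matrix with rows = true label, columns = predicted label."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors must have equal length")
    if y_true.size and (y_true.max() >= n_labels or y_pred.max() >= n_labels):
        raise ValueError("labels must be < n_labels")
    return _sk_confusion(y_true, y_pred, labels=np.arange(n_labels))


@dataclass
class MetricReport:
    """Accuracy, F1, precision, recall and per-class sensitivity, all
    as percentages in [0, 100]."""

    accuracy: float
    f1: float
    precision: float
    recall: float
    sensitivity: dict[str, float] = field(default_factory=dict)

    def as_row(self) -> dict:
        row = {
            "accuracy_pct": self.accuracy,
            "f1_pct": self.f1,
            "precision_pct": self.precision,
            "recall_pct": self.recall,
        }
        for label, v in self.sensitivity.items():
            row[f"sensitivity_{label}_pct"] = v
        return row


def metrics(cm: np.ndarray, class_names: Sequence[str] | None = None) -> MetricReport:
    """Metric report from a confusion matrix.

    Binary matrices treat class 1 as positive; larger matrices use
    macro averaging over one-vs-rest counts.  A class with zero
    support gets NaN sensitivity and is excluded from macro averages
    (with a warning).
    """
    cm = np.asarray(cm)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1] or cm.shape[0] < 2:
        raise ValueError("confusion matrix must be square, at least 2x2")
    total = cm.sum()
    if total <= 0:
        raise ValueError("empty confusion matrix")
    k = cm.shape[0]
    names = list(class_names) if class_names is not None else [str(i) for i in range(k)]

    support = cm.sum(axis=1)
    if np.any(support == 0):
        warnings.warn(
            f"classes with zero support excluded from macro averages: "
            f"{[names[i] for i in np.flatnonzero(support == 0)]}",
            RuntimeWarning,
            stacklevel=2,
        )
    diag = np.diag(cm).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        recall_per = np.where(support > 0, diag / support, np.nan)
    accuracy = 100.0 * diag.sum() / total

    if k == 2:
        tn, fp, fn, tp = cm[0, 0], cm[0, 1], cm[1, 0], cm[1, 1]
        precision = 100.0 * tp / (tp + fp) if tp + fp > 0 else 0.0
        recall = 100.0 * tp / (tp + fn) if tp + fn > 0 else 0.0
        f1 = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    else:
        colsum = cm.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            prec_per = np.where(colsum > 0, diag / colsum, 0.0)
            prec_per = np.where(support > 0, prec_per, np.nan)
            f1_per = np.where(
                prec_per + recall_per > 0,
                2 * prec_per * recall_per / (prec_per + recall_per),
                0.0,
            )
        precision = 100.0 * float(np.nanmean(prec_per))
        recall = 100.0 * float(np.nanmean(recall_per))
        f1 = 100.0 * float(np.nanmean(f1_per))

    sens = {
        names[i]: (100.0 * recall_per[i] if np.isfinite(recall_per[i]) else float("nan"))
        for i in range(k)
    }
    return MetricReport(
        accuracy=float(accuracy),
        f1=float(f1),
        precision=float(precision),
        recall=float(recall),
        sensitivity=sens,
    )


# ---------------------------------------------------------------------
# scenario runner
# ---------------------------------------------------------------------


@dataclass
class FeaturizedScenario:
    """All per-window artifacts of a scenario, before classification."""

    scenario: ScenarioSpec
    windows: np.ndarray  # (n, omega)
    labels: np.ndarray  # (n,) integer group labels
    stats: np.ndarray  # (n, 16)
    images: np.ndarray  # (n, S, S)
    train_idx: np.ndarray
    test_idx: np.ndarray

    def split_checksum(self) -> int:
        """Fingerprint of the train/test partition (for controlled
        comparisons across ablation arms)."""
        return hash((self.train_idx.tobytes(), self.test_idx.tobytes()))


@dataclass
class ScenarioResult:
    scenario: ScenarioSpec
    report: MetricReport
    confusion: np.ndarray
    psnr_train_db: float
    psnr_test_db: float
    n_train: int
    n_test: int
    split_checksum: int = 0

    def as_row(self) -> dict:
        return {"scenario": self.scenario.name, **self.report.as_row()}


def _scenario_windows(
    dataset: Mapping[str, Sequence[EEGRecord]],
    scenario: ScenarioSpec,
    config: PipelineConfig,
):
    """Chain and window every class the scenario references.

    Returns (windows, labels, record_ids) where record_ids tags each
    window with the record its *start* falls in (used by the
    record-level split).
    """
    missing = [c for c in scenario.classes if c not in dataset or not dataset[c]]
    if missing:
        raise ValueError(f"dataset lacks records for classes {missing}")
    wparams = config.window
    rows, labels, rec_ids = [], [], []
    for label_idx, group in enumerate(scenario.groups):
        for class_id in sorted(group, key=CLASS_ORDER.index):
            records = list(dataset[class_id])[: config.n_records]
            chained = chain_records(records, class_id=class_id)
            bounds = np.asarray(chained.source_record_boundaries)
            for w in segment(chained, wparams):
                rows.append(w.samples)
                labels.append(label_idx)
                rec = int(np.searchsorted(bounds, w.start - 1, side="right") - 1)
                rec_ids.append(f"{class_id}{rec}")
    return np.stack(rows), np.asarray(labels), np.asarray(rec_ids)


def _split_indices(labels, rec_ids, config: PipelineConfig, seed: int):
    n = labels.shape[0]
    if config.split == "window":
        train_idx, test_idx = train_test_split(
            np.arange(n),
            test_size=config.test_fraction,
            stratify=labels,
            random_state=seed % (2**31),
        )
    elif config.split == "record":
        # partition source records, then send all their windows together
        rng = np.random.default_rng(seed)
        uniq = np.unique(rec_ids)
        test_records = set()
        for class_prefix in {r.rstrip("0123456789") for r in uniq}:
            recs = sorted(r for r in uniq if r.rstrip("0123456789") == class_prefix)
            n_test = max(int(round(len(recs) * config.test_fraction)), 1)
            test_records |= set(rng.choice(recs, size=n_test, replace=False))
        mask = np.isin(rec_ids, sorted(test_records))
        train_idx, test_idx = np.flatnonzero(~mask), np.flatnonzero(mask)
    else:
        raise ValueError(f"unknown split mode {config.split!r}")
    return np.sort(train_idx), np.sort(test_idx)


def featurize(
    dataset: Mapping[str, Sequence[EEGRecord]],
    scenario: ScenarioSpec | str,
    config: PipelineConfig,
) -> FeaturizedScenario:
    """Window the scenario's classes and compute the per-window
    statistical bank and scalogram images (split-independent work)."""
    if isinstance(scenario, str):
        scenario = build_scenario(scenario)
    windows, labels, rec_ids = _scenario_windows(dataset, scenario, config)
    train_idx, test_idx = _split_indices(
        labels, rec_ids, config, derive_seed(config.seed, "split:" + scenario.name)
    )
    stats = stat_feature_matrix(windows)
    cwt_params = CWTParams(
        wavelet=config.wavelet,
        fs=config.fs,
        n_scales=config.n_scales,
        fmin=config.fmin,
        fmax=config.fmax,
        image_size=config.image_size,
    )
    logger.info("featurize %s: %d windows", scenario.name, windows.shape[0])
    images = np.stack([scalogram(w, cwt_params).pixels for w in windows])
    return FeaturizedScenario(scenario, windows, labels, stats, images, train_idx, test_idx)


def _classify(feat: FeaturizedScenario, config: PipelineConfig, arm: str) -> ScenarioResult:
    """Train CAE + fusion + LSTM on the train split, evaluate on test."""
    tr, te = feat.train_idx, feat.test_idx
    cae = ConvAutoencoder(
        image_size=config.image_size,
        encoder_filters=config.cae_filters,
        epochs=config.cae_epochs,
        batch_size=config.cae_batch_size,
        learning_rate=config.cae_learning_rate,
        seed=derive_seed(config.seed, "cae:" + feat.scenario.name),
    )
    cae.fit(feat.images[tr])
    psnr_train = cae.reconstruction_psnr(feat.images[tr])
    psnr_test = cae.reconstruction_psnr(feat.images[te])
    codes = cae.encode(feat.images)

    fusionizer = HybridFeatureFusion(n_components=config.n_components)
    fusionizer.fit(codes[tr], feat.stats[tr])
    hybrid = fusionizer.transform(codes, feat.stats)
    k = fusionizer.pca_.n_components
    if arm == "fused":
        X = hybrid
    elif arm == "latent":
        X = hybrid[:, :k]
    elif arm == "stats":
        X = hybrid[:, k:]
    else:
        raise ValueError(f"unknown feature arm {arm!r}")

    clf = LSTMClassifier(
        units=config.lstm_units,
        epochs=config.lstm_epochs,
        batch_size=config.lstm_batch_size,
        learning_rate=config.lstm_learning_rate,
        seed=derive_seed(config.seed, "lstm:" + feat.scenario.name),
        framing=config.framing,
    )
    clf.fit(X[tr], feat.labels[tr])
    y_pred = clf.predict(X[te])
    cm = confusion(feat.labels[te], y_pred, feat.scenario.n_labels)
    report = metrics(cm, class_names=feat.scenario.labels)
    return ScenarioResult(
        scenario=feat.scenario,
        report=report,
        confusion=cm,
        psnr_train_db=psnr_train,
        psnr_test_db=psnr_test,
        n_train=tr.size,
        n_test=te.size,
        split_checksum=feat.split_checksum(),
    )


def run_scenario(
    dataset: Mapping[str, Sequence[EEGRecord]],
    scenario: ScenarioSpec | str,
    config: PipelineConfig,
    featurized: FeaturizedScenario | None = None,
) -> ScenarioResult:
    """Full pipeline on one scenario: featurize (unless supplied),
    train on the train split, evaluate on the held-out split."""
    feat = featurized if featurized is not None else featurize(dataset, scenario, config)
    return _classify(feat, config, config.features)


ABLATION_ARMS = ("latent", "stats", "fused")


def ablation(
    dataset: Mapping[str, Sequence[EEGRecord]],
    config: PipelineConfig,
    scenario: ScenarioSpec | str = "F-N-O-Z-S",
    featurized: FeaturizedScenario | None = None,
) -> dict[str, ScenarioResult]:
    """Latent-only vs stats-only vs fused, on identical splits and seeds.

    All three arms share the featurization and the train/test
    partition (equal ``split_checksum``), so the comparison isolates
    the feature set.
    """
    feat = featurized if featurized is not None else featurize(dataset, scenario, config)
    return {arm: _classify(feat, config, arm) for arm in ABLATION_ARMS}


def ablation_table(results: Mapping[str, ScenarioResult]) -> pd.DataFrame:
    rows = []
    for arm, res in results.items():
        rows.append({"features": arm, **res.report.as_row()})
    return pd.DataFrame(rows)
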