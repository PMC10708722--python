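"""Reading, writing and chaining of single-channel ASCII EEG records.

The on-disk dialect is the one used by the University of Bonn epilepsy
corpus: one numeric sample per line (LF or CRLF), one file per record,
one directory per class (``Z/``, ``O/``, ``N/``, ``F/``, ``S/``).  The
reader accepts floats as a superset of the corpus' integer samples so
that synthetic real-valued records round-trip through the same code
path.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

#: Default sampling rate of the Bonn corpus, Hz.
DEFAULT_FS = 173.61

#: Default record length of the Bonn corpus, samples.
RECORD_LENGTH = 4097

#: Canonical class ordering used everywhere a deterministic order is needed.
CLASS_ORDER = ("Z", "O", "N", "F", "S")


@dataclass
class EEGRecord:
    """One single-channel EEG record with its sampling rate and label."""

    samples: np.ndarray
    fs: float = DEFAULT_FS
    class_id: str | None = None
    record_index: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("EEGRecord samples must be a 1-D vector")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("EEGRecord samples must be finite")

    def __len__(self) -> int:
        return self.samples.size


@dataclass
class ChainedSignal:
    """All records of one class concatenated into a single continuous signal.

    ``source_record_boundaries`` holds the 0-based offset at which each
    member record starts; the first entry is always 0.
    """

    samples: np.ndarray
    class_id: str | None
    fs: float
    source_record_boundaries: list[int] = field(default_factory=lambda: [0])

    def __len__(self) -> int:
        return self.samples.size


def read_record(
    path: str | Path,
    fs: float = DEFAULT_FS,
    class_id: str | None = None,
    record_index: int = 0,
) -> EEGRecord:
    """Parse one ASCII record (one numeric token per line).

    Raises ``FileNotFoundError`` for a missing file and ``ValueError``
    (naming the 1-based line number) for a non-numeric line or an empty
    file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"EEG record not found: {path}")
    values: list[float] = []
    with path.open("r") as fh:
        for lineno, line in enumerate(fh, start=1):
            token = line.strip()
            if not token:
                continue
            try:
                values.append(float(token))
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric sample {token!r} on line {lineno}"
                ) from None
    if not values:
        raise ValueError(f"{path}: empty record file")
    return EEGRecord(np.asarray(values), fs=fs, class_id=class_id, record_index=record_index)


def write_record(record: EEGRecord, path: str | Path) -> Path:
    """Write one record in the one-sample-per-line ASCII dialect."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        for v in record.samples:
            fh.write(f"{v:.10g}\n")
    return path


def chain_records(records: Sequence[EEGRecord], class_id: str | None = None) -> ChainedSignal:
    """Concatenate records (in list order) into one continuous signal.

    All records must share the same sampling rate and class label; the
    start offset of every member record is kept so windows can be traced
    back to their source record.
    """
    if not records:
        raise ValueError("cannot chain an empty record list")
    fs = records[0].fs
    cid = class_id if class_id is not None else records[0].class_id
    boundaries: list[int] = []
    offset = 0
    for rec in records:
        if rec.fs != fs:
            raise ValueError(f"mixed sampling rates in chain: {rec.fs} != {fs}")
        if cid is not None and rec.class_id is not None and rec.class_id != cid:
            raise ValueError(f"mixed classes in chain: {rec.class_id} != {cid}")
        boundaries.append(offset)
        offset += len(rec)
    samples = np.concatenate([rec.samples for rec in records])
    return ChainedSignal(samples=samples, class_id=cid, fs=fs, source_record_boundaries=boundaries)


def load_class_dir(
    directory: str | Path, class_id: str | None = None, fs: float = DEFAULT_FS
) -> list[EEGRecord]:
    """Load every ``*.txt``/``*.TXT`` record of one class directory.

    Files are read in lexicographic filename order so chaining is
    deterministic regardless of filesystem enumeration order.
    """
    directory = Path(directory)
    if class_id is None:
        class_id = directory.name
    paths = sorted(
        (p for p in directory.iterdir() if p.suffix.lower() == ".txt"),
        key=lambda p: p.name,
    )
    if not paths:
        raise FileNotFoundError(f"no .txt records found in {directory}")
    return [
        read_record(p, fs=fs, class_id=class_id, record_index=i)
        for i, p in enumerate(paths)
    ]


def load_dataset_dir(
    root: str | Path,
    classes: Iterable[str] = CLASS_ORDER,
    fs: float = DEFAULT_FS,
) -> dict[str, list[EEGRecord]]:
    """Load a directory-per-class corpus layout (the Bonn adapter)."""
    root = Path(root)
    return {c: load_class_dir(root / c, class_id=c, fs=fs) for c in classes}


def export_csv(records: Sequence[EEGRecord], path: str | Path) -> Path:
    """Long-format CSV export: record_id, sample_index, value."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["record_id", "sample_index", "value"])
        for rec in records:
            rid = f"{rec.class_id or 'X'}{rec.record_index:03d}"
            for i, v in enumerate(rec.samples):
                writer.writerow([rid, i, repr(float(v))])
    return path
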