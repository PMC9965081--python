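"""Labelled tri-axial accelerometer sequences: data model, on-disk formats, LOSO splits.

A recording is a ``(T, 3)`` acceleration matrix in units of g (gravity ~ 1.0 on the
vertical axis at rest) with a dense per-frame integer label sequence.  Frames are
0-based and a labelled segment ``[s, e)`` is half-open, so segment and window
arithmetic compose without off-by-one corrections.

Two on-disk representations are supported:

* an HDF5 container with one group per sample (lossless round-trip), and
* a plain-text per-sample CSV dialect with header ``t,ax,ay,az,label`` for
  interoperability (one file per recording; a directory of such files is a dataset).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import h5py
import numpy as np

__all__ = [
    "ActivityCatalog",
    "AccelSample",
    "Dataset",
    "canonical_catalog",
    "ACTIVITY_NAMES",
    "write_dataset",
    "read_dataset",
    "write_sample_csv",
    "read_sample_csv",
    "loso_splits",
    "ParseError",
    "ValidationError",
]

#: Canonical class order: index 0 is the no-movement background; 1..6 are the
#: six target activities in fixed order.
ACTIVITY_NAMES = (
    "background",
    "get-up",
    "laying",
    "stand-up",
    "picking",
    "sitting",
    "walking",
)

CANONICAL_FPS = 15.0
CANONICAL_SAMPLE_LENGTH = 250


class ParseError(ValueError):
    """A file did not match the documented layout; names the first bad record."""


class ValidationError(ValueError):
    """Structurally parseable input that violates a type invariant."""


@dataclass(frozen=True)
class ActivityCatalog:
    """Ordered class-label catalog; ``index_of`` is a bijection onto 0..C-1."""

    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValidationError("catalog names must be unique")
        if len(self.names) < 1:
            raise ValidationError("catalog must contain at least one class")

    @property
    def n_classes(self) -> int:
        return len(self.names)

    def index_of(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown activity label {name!r}") from None

    def to_json(self) -> str:
        return json.dumps({"names": list(self.names)})

    @classmethod
    def from_json(cls, text: str) -> "ActivityCatalog":
        obj = json.loads(text)
        return cls(names=tuple(obj["names"]))


def canonical_catalog() -> ActivityCatalog:
    """The fixed 7-class catalog (background + 6 activities)."""
    return ActivityCatalog(names=ACTIVITY_NAMES)


@dataclass
class AccelSample:
    """One recording: frames ``(T, 3)`` in g, per-frame labels, identity, rate."""

    frames: np.ndarray
    labels: np.ndarray
    subject_id: str
    sample_id: str
    fps: float = CANONICAL_FPS

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.frames.ndim != 2 or self.frames.shape[1] != 3:
            raise ValidationError(
                f"frames must have shape (T, 3), got {self.frames.shape}"
            )
        if self.labels.ndim != 1:
            raise ValidationError("labels must be one-dimensional")
        if len(self.frames) != len(self.labels):
            raise ValidationError(
                f"frames ({len(self.frames)}) and labels ({len(self.labels)}) "
                "must have identical length"
            )
        if len(self.frames) < 1:
            raise ValidationError("a sample must contain at least one frame")

    @property
    def n_frames(self) -> int:
        return len(self.labels)

    def validate_labels(self, catalog: ActivityCatalog) -> None:
        bad = (self.labels < 0) | (self.labels >= catalog.n_classes)
        if bad.any():
            t = int(np.argmax(bad))
            raise ValidationError(
                f"sample {self.sample_id!r}: label {int(self.labels[t])} at frame {t} "
                f"outside catalog range [0, {catalog.n_classes})"
            )


@dataclass
class Dataset:
    """An ordered collection of samples sharing one catalog."""

    samples: list[AccelSample] = field(default_factory=list)
    catalog: ActivityCatalog = field(default_factory=canonical_catalog)

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValidationError("sample_ids must be unique within a dataset")
        for s in self.samples:
            s.validate_labels(self.catalog)

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self) -> Iterator[AccelSample]:
        return iter(self.samples)

    @property
    def subject_ids(self) -> list[str]:
        return sorted({s.subject_id for s in self.samples})

    def subset(self, subject_ids: Sequence[str]) -> "Dataset":
        keep = set(subject_ids)
        return Dataset(
            samples=[s for s in self.samples if s.subject_id in keep],
            catalog=self.catalog,
        )


# ---------------------------------------------------------------------------
# HDF5 container: root attrs carry the catalog (JSON); one group per sample.
# ---------------------------------------------------------------------------

def write_dataset(dataset: Dataset, path: str | Path) -> None:
    """Serialize ``dataset`` losslessly to an HDF5 container."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["format"] = "cefhar-dataset-v1"
        f.attrs["catalog"] = dataset.catalog.to_json()
        f.attrs["n_samples"] = len(dataset)
        for i, s in enumerate(dataset):
            g = f.create_group(f"sample_{i:06d}")
            g.create_dataset("frames", data=s.frames, dtype=np.float64)
            g.create_dataset("labels", data=s.labels, dtype=np.int64)
            g.attrs["subject_id"] = s.subject_id
            g.attrs["sample_id"] = s.sample_id
            g.attrs["fps"] = s.fps


def _read_hdf5(path: Path) -> Dataset:
    with h5py.File(path, "r") as f:
        if f.attrs.get("format") != "cefhar-dataset-v1":
            raise ParseError(f"{path}: not a cefhar dataset container")
        catalog = ActivityCatalog.from_json(f.attrs["catalog"])
        samples = []
        for key in sorted(f.keys()):
            g = f[key]
            samples.append(
                AccelSample(
                    frames=g["frames"][()],
                    labels=g["labels"][()],
                    subject_id=str(g.attrs["subject_id"]),
                    sample_id=str(g.attrs["sample_id"]),
                    fps=float(g.attrs["fps"]),
                )
            )
    return Dataset(samples=samples, catalog=catalog)


# ---------------------------------------------------------------------------
# CSV dialect: header "t,ax,ay,az,label"; one file per recording.  The file
# stem encodes identity as "<subject>__<sample>" (a stem without the double
# underscore is treated as sample id with subject "unknown").
# ---------------------------------------------------------------------------

CSV_HEADER = ["t", "ax", "ay", "az", "label"]


def write_sample_csv(sample: AccelSample, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(CSV_HEADER)
        for t in range(sample.n_frames):
            ax, ay, az = sample.frames[t]
            w.writerow([t, repr(float(ax)), repr(float(ay)), repr(float(az)),
                        int(sample.labels[t])])


def read_sample_csv(
    path: str | Path,
    catalog: ActivityCatalog | None = None,
    subject_id: str | None = None,
    sample_id: str | None = None,
    fps: float = CANONICAL_FPS,
) -> AccelSample:
    """Parse one per-sample CSV; raises :class:`ParseError` naming the first bad line."""
    path = Path(path)
    catalog = catalog or canonical_catalog()
    if subject_id is None or sample_id is None:
        stem = path.stem
        if "__" in stem:
            sub, samp = stem.split("__", 1)
        else:
            sub, samp = "unknown", stem
        subject_id = subject_id or sub
        sample_id = sample_id or samp
    frames: list[list[float]] = []
    labels: list[int] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        for lineno, row in enumerate(reader, start=1):
            if lineno == 1:
                if [c.strip() for c in row] != CSV_HEADER:
                    raise ParseError(
                        f"{path}:1: expected header {','.join(CSV_HEADER)!r}, "
                        f"got {','.join(row)!r}"
                    )
                continue
            if not row:
                continue
            if len(row) != 5:
                raise ParseError(
                    f"{path}:{lineno}: expected 5 columns, got {len(row)}"
                )
            try:
                frames.append([float(row[1]), float(row[2]), float(row[3])])
                labels.append(int(row[4]))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
    if not frames:
        raise ParseError(f"{path}: no data rows")
    sample = AccelSample(
        frames=np.array(frames), labels=np.array(labels),
        subject_id=subject_id, sample_id=sample_id, fps=fps,
    )
    sample.validate_labels(catalog)
    return sample


def read_dataset(path: str | Path, catalog: ActivityCatalog | None = None) -> Dataset:
    """Read a dataset: HDF5 container, a single CSV, or a directory of CSVs."""
    path = Path(path)
    if path.is_dir():
        catalog = catalog or canonical_catalog()
        samples = [
            read_sample_csv(p, catalog) for p in sorted(path.glob("*.csv"))
        ]
        if not samples:
            raise ParseError(f"{path}: no .csv files found")
        return Dataset(samples=samples, catalog=catalog)
    if path.suffix.lower() == ".csv":
        catalog = catalog or canonical_catalog()
        return Dataset(samples=[read_sample_csv(path, catalog)], catalog=catalog)
    return _read_hdf5(path)


# ---------------------------------------------------------------------------
# Leave-one-subject-out splits
# ---------------------------------------------------------------------------

def loso_splits(dataset: Dataset) -> list[tuple[Dataset, Dataset]]:
    """One (train, test) fold per subject, ordered by subject id.

    In fold *k* the test set is exactly the samples of subject *k*; the union of
    test sets over all folds is the dataset.
    """
    subjects = dataset.subject_ids
    if len(subjects) < 2:
        raise ValidationError(
            f"leave-one-subject-out requires >= 2 subjects, got {len(subjects)}"
        )
    folds = []
    for held_out in subjects:
        train = Dataset(
            samples=[s for s in dataset if s.subject_id != held_out],
            catalog=dataset.catalog,
        )
        test = Dataset(
            samples=[s for s in dataset if s.subject_id == held_out],
            catalog=dataset.catalog,
        )
        folds.append((train, test))
    return folds
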