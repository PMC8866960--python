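"""Volume/label NIfTI I/O, cohort catalogs, and train/test/fold splits.

The canonical in-memory axis order is ``(row, column, slice)`` where the slice
axis is the delineation plane of the domain (axial for the low-resolution
source protocol, coronal for the high-resolution target protocol). Splits
operate strictly at subject level so that no anatomy leaks between fit,
validation, and test sets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "Volume", "LabelMap", "CatalogEntry", "DatasetCatalog", "FoldSplit",
    "read_volume", "write_volume", "read_labels", "write_labels",
    "make_split",
]


@dataclass
class Volume:
    """A 3D susceptibility map in ppm with voxel-size metadata (mm)."""

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    orientation: str = "row-col-slice"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {self.data.shape}")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size components must be > 0, got {self.voxel_size}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size))


@dataclass
class LabelMap:
    """Integer label volume aligned to a :class:`Volume`; 0 is background."""

    data: np.ndarray
    class_ids: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.uint8)
        present = set(int(v) for v in np.unique(self.data)) - {0}
        if not self.class_ids:
            self.class_ids = frozenset(present)
        elif not present <= set(self.class_ids):
            raise ValueError(f"labels contain unexpected classes {present - set(self.class_ids)}")


def _affine(voxel_size) -> np.ndarray:
    return np.diag(list(voxel_size) + [1.0])


def write_volume(path: str | Path, volume: Volume) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(volume.data.astype(np.float32), _affine(volume.voxel_size))
    img.header.set_zooms(volume.voxel_size)
    try:
        nib.save(img, str(path))
    except OSError as exc:  # pragma: no cover - environment dependent
        raise OSError(f"failed to write volume to {path}: {exc}") from exc
    return path


def read_volume(path: str | Path) -> Volume:
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:
        raise ValueError(f"cannot parse NIfTI file {path}: {exc}") from exc
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume(np.asanyarray(img.dataobj).astype(np.float32), zooms)


def write_labels(path: str | Path, labels: LabelMap, voxel_size) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(labels.data.astype(np.uint8), _affine(voxel_size))
    img.header.set_zooms(voxel_size)
    nib.save(img, str(path))
    return path


def read_labels(path: str | Path, volume: Volume) -> LabelMap:
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:
        raise ValueError(f"cannot parse NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.shape != volume.data.shape:
        raise ValueError(f"label shape {data.shape} does not match volume shape "
                         f"{volume.data.shape} for {path}")
    return LabelMap(np.rint(data).astype(np.uint8))


# --------------------------------------------------------------------- catalog
@dataclass
class CatalogEntry:
    subject_id: str
    volume_path: str
    label_path: str


@dataclass
class DatasetCatalog:
    """Manifest of a cohort: paired volume/label files plus domain metadata."""

    entries: list[CatalogEntry]
    domain_name: str
    label_scheme: str
    voxel_size: tuple[float, float, float]
    seed: int | None = None

    def __post_init__(self):
        ids = [e.subject_id for e in self.entries]
        if len(ids) != len(set(ids)):
            raise ValueError("subject ids in catalog are not unique")

    @property
    def subject_ids(self) -> list[str]:
        return [e.subject_id for e in self.entries]

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "domain_name": self.domain_name,
            "label_scheme": self.label_scheme,
            "voxel_size": list(self.voxel_size),
            "seed": self.seed,
            "entries": [vars(e) for e in self.entries],
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        return path

    @classmethod
    def load(cls, path: str | Path, check_paths: bool = True) -> "DatasetCatalog":
        path = Path(path)
        payload = json.loads(path.read_text())
        cat = cls(entries=[CatalogEntry(**e) for e in payload["entries"]],
                  domain_name=payload["domain_name"],
                  label_scheme=payload["label_scheme"],
                  voxel_size=tuple(payload["voxel_size"]),
                  seed=payload.get("seed"))
        if check_paths:
            missing = [p for e in cat.entries for p in (e.volume_path, e.label_path)
                       if not Path(p).exists()]
            if missing:
                raise FileNotFoundError(f"catalog references missing files: {missing}")
        return cat


# ----------------------------------------------------------------------- split
@dataclass
class FoldSplit:
    """Subject-level train/test split with k validation folds over train."""

    train_ids: list[str]
    test_ids: list[str]
    folds: list[tuple[list[str], list[str]]]  # (fit_ids, val_ids)
    seed: int

    def __post_init__(self):
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test sets overlap")
        val_all = [s for _, val in self.folds for s in val]
        if sorted(val_all) != sorted(self.train_ids):
            raise ValueError("fold validation sets do not partition the training cohort")
        for fit, val in self.folds:
            if set(fit) & set(val):
                raise ValueError("a fold's fit and validation sets overlap")

    @property
    def n_folds(self) -> int:
        return len(self.folds)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {"train_ids": self.train_ids, "test_ids": self.test_ids,
                   "folds": [{"fit": f, "val": v} for f, v in self.folds],
                   "seed": self.seed}
        path.write_text(json.dumps(payload, indent=2) + "\n")
        return path

    @classmethod
    def load(cls, path: str | Path) -> "FoldSplit":
        payload = json.loads(Path(path).read_text())
        return cls(train_ids=payload["train_ids"], test_ids=payload["test_ids"],
                   folds=[(f["fit"], f["val"]) for f in payload["folds"]],
                   seed=payload["seed"])


def make_split(catalog: DatasetCatalog, n_test: int, n_folds: int = 5,
               seed: int = 0) -> FoldSplit:
    """Randomly split a cohort into train/test and k near-equal validation folds.

    Deterministic for a fixed seed. Fold validation sets partition the
    training cohort and differ in size by at most one subject.
    """
    ids = list(catalog.subject_ids)
    if n_test >= len(ids):
        raise ValueError(f"n_test={n_test} must be smaller than cohort size {len(ids)}")
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    rng = np.random.default_rng(seed)
    order = list(np.array(ids)[rng.permutation(len(ids))])
    test_ids = sorted(order[:n_test])
    train_ids = order[n_test:]
    chunks = np.array_split(np.arange(len(train_ids)), n_folds)
    folds = []
    for chunk in chunks:
        val = sorted(train_ids[i] for i in chunk)
        fit = sorted(s for s in train_ids if s not in set(val))
        folds.append((fit, val))
    return FoldSplit(train_ids=sorted(train_ids), test_ids=test_ids,
                     folds=folds, seed=seed)
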