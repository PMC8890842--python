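"""Image containers, folder I/O, preprocessing and dataset partitioning.

The on-disk layout mirrors the Kvasir v1 convention: one subdirectory per
class, holding JPEG/PNG frames.  In memory a :class:`LabeledImageSet`
keeps images (possibly of heterogeneous resolution), integer labels,
class names and stable sample ids.  Model input is always a 32x32x3
float tensor in [0, 1].
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from skimage.transform import resize


# --------------------------------------------------------------------
# containers
# --------------------------------------------------------------------
@dataclass
class LabeledImageSet:
    """Ordered collection of RGB images with integer class labels.

    ``images`` is a list of HxWx3 float arrays in [0, 1] (resolutions may
    differ before preprocessing).  ``labels[i]`` indexes into
    ``class_names``; ``sample_ids`` are unique stable strings.
    """

    images: list[np.ndarray]
    labels: np.ndarray
    class_names: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if not (len(self.images) == len(self.labels) == len(self.sample_ids)):
            raise ValueError(
                f"inconsistent lengths: {len(self.images)} images, "
                f"{len(self.labels)} labels, {len(self.sample_ids)} ids"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids are not unique")
        if len(self.labels) and (self.labels.min() < 0 or self.labels.max() >= len(self.class_names)):
            raise ValueError(f"labels must lie in [0, {len(self.class_names)})")

    def __len__(self) -> int:
        return len(self.images)

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_classes)

    def subset(self, indices) -> "LabeledImageSet":
        indices = np.asarray(indices, dtype=np.int64)
        return LabeledImageSet(
            images=[self.images[i] for i in indices],
            labels=self.labels[indices],
            class_names=list(self.class_names),
            sample_ids=[self.sample_ids[i] for i in indices],
        )

    def to_tensors(self, side: int = 32) -> np.ndarray:
        """Preprocess every image to a (n, side, side, 3) float32 stack."""
        return np.stack([preprocess_image(im, side) for im in self.images]).astype(np.float32)


@dataclass
class SplitSpec:
    """Fractions for the two-level split: test off the full set, then
    validation off the remaining training portion."""

    test_fraction: float = 0.20
    val_fraction_of_train: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("test_fraction", "val_fraction_of_train"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be strictly inside (0, 1), got {v}")


@dataclass
class SSLPartition:
    """The initial labeled/unlabeled split of a training set.

    ``uds`` retains its true labels internally — they are never shown to
    the learner, only used for pseudo-label accuracy diagnostics.
    """

    lds: LabeledImageSet
    uds: LabeledImageSet
    m_percent: float = field(default=100.0)


# --------------------------------------------------------------------
# I/O
# --------------------------------------------------------------------
def load_image_folder(root_path: str | Path, class_names: list[str]) -> LabeledImageSet:
    """Read a class-per-subfolder image directory (Kvasir v1 layout).

    Files are ordered lexicographically by path within each class, so the
    result is deterministic.  Raises if a class folder is missing or
    empty, or a file cannot be decoded.
    """
    root = Path(root_path)
    if not root.is_dir():
        raise FileNotFoundError(f"dataset root does not exist: {root}")
    images: list[np.ndarray] = []
    labels: list[int] = []
    ids: list[str] = []
    for ci, name in enumerate(class_names):
        cdir = root / name
        if not cdir.is_dir():
            raise FileNotFoundError(f"missing class folder: {cdir}")
        files = sorted(p for p in cdir.iterdir() if p.suffix.lower() in {".jpg", ".jpeg", ".png"})
        if not files:
            raise ValueError(f"class folder is empty: {cdir}")
        for path in files:
            try:
                with Image.open(path) as im:
                    arr = np.asarray(im.convert("RGB"), dtype=np.float32) / 255.0
            except Exception as exc:  # noqa: BLE001 - re-raise with file name
                raise ValueError(f"cannot decode image file: {path}") from exc
            images.append(arr)
            labels.append(ci)
            ids.append(f"{name}/{path.name}")
    return LabeledImageSet(images, np.array(labels), list(class_names), ids)


def write_image_folder(dataset: LabeledImageSet, root_path: str | Path) -> None:
    """Export a dataset as PNG files in the class-per-subfolder layout."""
    root = Path(root_path)
    for ci, name in enumerate(dataset.class_names):
        (root / name).mkdir(parents=True, exist_ok=True)
    for img, label, sid in zip(dataset.images, dataset.labels, dataset.sample_ids):
        fname = sid.split("/")[-1]
        if not fname.endswith(".png"):
            fname += ".png"
        out = (np.clip(img, 0, 1) * 255).round().astype(np.uint8)
        Image.fromarray(out).save(root / dataset.class_names[label] / fname)


def write_split_manifest(path: str | Path, parts: dict[str, LabeledImageSet]) -> None:
    """CSV manifest (sample_id, class, partition) for reproducibility."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample_id", "class", "partition"])
        for part, ds in parts.items():
            for sid, label in zip(ds.sample_ids, ds.labels):
                writer.writerow([sid, ds.class_names[label], part])


# --------------------------------------------------------------------
# preprocessing
# --------------------------------------------------------------------
def preprocess_image(image: np.ndarray, target_side: int = 32) -> np.ndarray:
    """Resize an RGB image to target_side x target_side, intensities in [0, 1].

    uint8 input is scaled by 1/255; float input is assumed to already be
    on [0, 1].  Resizing is bilinear, with a Gaussian prefilter when
    downscaling (anti-aliasing) so the output mean tracks the input mean.
    """
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected an RGB image (H, W, 3), got shape {arr.shape}")
    if arr.dtype == np.uint8:
        arr = arr.astype(np.float32) / 255.0
    else:
        arr = arr.astype(np.float32)
    if arr.shape[:2] == (target_side, target_side):
        return np.clip(arr, 0.0, 1.0)
    anti_alias = min(arr.shape[:2]) > target_side
    out = resize(arr, (target_side, target_side), order=1, anti_aliasing=anti_alias, preserve_range=True)
    return np.clip(out.astype(np.float32), 0.0, 1.0)


# --------------------------------------------------------------------
# splits
# --------------------------------------------------------------------
def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def stratified_split(
    dataset: LabeledImageSet, fraction_first: float, seed: int
) -> tuple[LabeledImageSet, LabeledImageSet]:
    """Split per class: round-half-up of fraction_first to the first part.

    Disjoint, exhaustive, deterministic for a given seed.
    """
    if not 0.0 < fraction_first < 1.0:
        raise ValueError(f"fraction_first must be in (0, 1), got {fraction_first}")
    rng = np.random.default_rng(seed)
    first_idx: list[int] = []
    second_idx: list[int] = []
    for c in range(dataset.n_classes):
        cls_idx = np.flatnonzero(dataset.labels == c)
        if len(cls_idx) == 0:
            raise ValueError(f"class {dataset.class_names[c]!r} has no samples")
        cls_idx = rng.permutation(cls_idx)
        n_first = _round_half_up(fraction_first * len(cls_idx))
        n_first = min(max(n_first, 0), len(cls_idx))
        first_idx.extend(cls_idx[:n_first])
        second_idx.extend(cls_idx[n_first:])
    return dataset.subset(sorted(first_idx)), dataset.subset(sorted(second_idx))


def make_ssl_partition(train_set: LabeledImageSet, m_percent: float, seed: int) -> SSLPartition:
    """Partition a training set into an initial labeled set (LDS, m% per
    class, minimum 1) and an unlabeled pool (UDS, the complement)."""
    if len(train_set) == 0:
        raise ValueError("train_set is empty")
    if not 0.0 < m_percent <= 100.0:
        raise ValueError(f"m_percent must be in (0, 100], got {m_percent}")
    rng = np.random.default_rng(seed)
    lds_idx: list[int] = []
    uds_idx: list[int] = []
    for c in range(train_set.n_classes):
        cls_idx = np.flatnonzero(train_set.labels == c)
        if len(cls_idx) == 0:
            raise ValueError(f"class {train_set.class_names[c]!r} has no samples")
        cls_idx = rng.permutation(cls_idx)
        n_lab = max(1, _round_half_up(m_percent / 100.0 * len(cls_idx)))
        lds_idx.extend(cls_idx[:n_lab])
        uds_idx.extend(cls_idx[n_lab:])
    return SSLPartition(
        lds=train_set.subset(sorted(lds_idx)),
        uds=train_set.subset(sorted(uds_idx)),
        m_percent=m_percent,
    )
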