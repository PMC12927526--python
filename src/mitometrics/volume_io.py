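"""NIfTI volume I/O and benchmark dataset-layout validation.

Volumes are carried in memory as ``(z, y, x)``-ordered numpy arrays together
with their physical voxel spacing in nanometres. On disk they are NIfTI-1
``.nii.gz`` files whose natural axis order is ``(x, y, z)``; this module maps
between the two conventions on every read/write so that all morphology and
evaluation code sees a single unambiguous layout.

Instance label volumes are stored as unsigned 16-bit integers (0 denotes
background, each positive value one instance); image volumes as single-channel
float32. Dataset directories follow the nnU-Net-compatible layout
(``imagesTr/``, ``labelsTr/``, ``imagesTs/``, ``labelsTs/``, ``dataset.json``,
``split.json``, ``metadata.csv``, checksum manifest).
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "InstanceVolume",
    "ImageVolume",
    "DatasetDescriptor",
    "ChecksumReport",
    "VolumeFormatError",
    "LabelOverflowError",
    "DatasetLayoutError",
    "read_labels",
    "write_labels",
    "read_image",
    "write_image",
    "read_dataset_descriptor",
    "verify_checksums",
    "write_checksum_manifest",
    "read_checksum_manifest",
]

MAX_LABEL = np.iinfo(np.uint16).max  # labels must fit the on-disk uint16 dtype

#: filename convention: me2-<dataset>_<split><XX>[_<channel>].nii.gz
FILENAME_RE = re.compile(
    r"^me2-(?P<dataset>[A-Za-z0-9.\-]+)_(?P<split>train|val|test)"
    r"(?P<index>\d+)(?:_(?P<channel>\d{4}))?\.nii\.gz$"
)


class VolumeFormatError(ValueError):
    """A NIfTI file violates the label/image volume contract."""


class LabelOverflowError(VolumeFormatError):
    """A label value does not fit in unsigned 16-bit storage."""


class DatasetLayoutError(ValueError):
    """A dataset directory violates the expected layout or split rules."""


@dataclass
class InstanceVolume:
    """A 3D grid of non-negative integer instance labels.

    Parameters
    ----------
    labels
        ``(z, y, x)`` integer array. 0 is background; each positive value is
        one instance.
    spacing
        Physical voxel size ``(z, y, x)`` in nanometres.
    name
        Identifier used in reports and exported tables.
    """

    labels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    name: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3 or min(self.labels.shape) < 1:
            raise VolumeFormatError(
                f"labels must be a non-empty 3D grid, got shape {self.labels.shape}"
            )
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise VolumeFormatError(
                f"labels must have an integer dtype, got {self.labels.dtype}"
            )
        if self.labels.size and self.labels.min() < 0:
            raise VolumeFormatError(
                f"labels must be non-negative, found minimum {self.labels.min()}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise VolumeFormatError(f"spacing must be 3 positive values, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def instance_ids(self) -> np.ndarray:
        """Distinct positive labels present, ascending."""
        ids = np.unique(self.labels)
        return ids[ids > 0]

    def voxel_counts(self) -> dict[int, int]:
        """Voxel count per positive label."""
        counts = np.bincount(self.labels.ravel())
        return {int(i): int(c) for i, c in enumerate(counts) if i > 0 and c > 0}

    def mask(self, instance_id: int) -> np.ndarray:
        """Boolean mask of one instance; raises ``KeyError`` if absent."""
        m = self.labels == instance_id
        if instance_id <= 0 or not m.any():
            raise KeyError(f"instance id {instance_id} not present in volume {self.name!r}")
        return m

    def foreground(self) -> np.ndarray:
        """Binary semantic mask (any positive label)."""
        return self.labels > 0


@dataclass
class ImageVolume:
    """A single-channel grayscale 3D image with voxel spacing in nm."""

    intensities: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    name: str = ""

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float32)
        if self.intensities.ndim != 3:
            raise VolumeFormatError(
                f"intensities must be a single-channel 3D grid, got shape "
                f"{self.intensities.shape}"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise VolumeFormatError("intensities contain non-finite values")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise VolumeFormatError(f"spacing must be 3 positive values, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape


def _affine_from_spacing(spacing_zyx: tuple[float, float, float]) -> np.ndarray:
    # nibabel's natural data order is (x, y, z)
    sz, sy, sx = spacing_zyx
    return np.diag([sx, sy, sz, 1.0])


def _load_nifti(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise VolumeFormatError(f"{path.name}: expected a 3D volume, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]  # (x, y, z)
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    return np.transpose(data, (2, 1, 0)), spacing


def read_labels(path: str | Path) -> InstanceVolume:
    """Read an instance label volume from a NIfTI file.

    The voxel data must be integer-valued and non-negative; spacing is taken
    from the header and preserved exactly.
    """
    data, spacing = _load_nifti(path)
    name = Path(path).name.removesuffix(".nii.gz").removesuffix(".nii")
    if not np.issubdtype(data.dtype, np.integer):
        if not np.allclose(data, np.round(data), atol=0, rtol=0):
            raise VolumeFormatError(
                f"{Path(path).name}: label data is not integer-valued "
                f"(dtype {data.dtype})"
            )
        data = np.round(data).astype(np.int64)
    if data.size and data.min() < 0:
        raise VolumeFormatError(
            f"{Path(path).name}: negative label value {int(data.min())} found; "
            "labels must be non-negative"
        )
    return InstanceVolume(labels=data.astype(np.int64), spacing=spacing, name=name)


def write_labels(vol: InstanceVolume, path: str | Path) -> Path:
    """Write an instance label volume as gzip-compressed uint16 NIfTI.

    Raises
    ------
    LabelOverflowError
        If any label exceeds 65535. Reindex the volume first
        (:func:`mitometrics.standardize.reindex_instances`).
    """
    path = Path(path)
    vmax = int(vol.labels.max()) if vol.labels.size else 0
    if vmax > MAX_LABEL:
        raise LabelOverflowError(
            f"label {vmax} exceeds uint16 maximum {MAX_LABEL}; "
            "reindex instances before writing"
        )
    data = np.transpose(vol.labels.astype(np.uint16), (2, 1, 0))
    img = nib.Nifti1Image(data, _affine_from_spacing(vol.spacing))
    img.header.set_zooms((vol.spacing[2], vol.spacing[1], vol.spacing[0]))
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))
    return path


def read_image(path: str | Path) -> ImageVolume:
    """Read a single-channel grayscale volume from NIfTI."""
    data, spacing = _load_nifti(path)
    name = Path(path).name.removesuffix(".nii.gz").removesuffix(".nii")
    return ImageVolume(intensities=data.astype(np.float32), spacing=spacing, name=name)


def write_image(img_vol: ImageVolume, path: str | Path) -> Path:
    """Write a grayscale volume as float32 NIfTI (.nii.gz)."""
    path = Path(path)
    data = np.transpose(img_vol.intensities.astype(np.float32), (2, 1, 0))
    img = nib.Nifti1Image(data, _affine_from_spacing(img_vol.spacing))
    img.header.set_zooms((img_vol.spacing[2], img_vol.spacing[1], img_vol.spacing[0]))
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))
    return path


# ---------------------------------------------------------------------------
# dataset layout


@dataclass
class DatasetDescriptor:
    """Validated view of an nnU-Net-compatible dataset directory."""

    root: Path
    name: str
    modality: str | None = None
    channel_names: dict[str, str] = field(default_factory=dict)
    spacing: tuple[float, float, float] | None = None
    train_images: list[str] = field(default_factory=list)
    train_labels: list[str] = field(default_factory=list)
    test_images: list[str] = field(default_factory=list)
    test_labels: list[str] = field(default_factory=list)
    splits: dict[str, list[str]] = field(default_factory=dict)
    metadata: dict[str, dict[str, str]] = field(default_factory=dict)
    extra: dict = field(default_factory=dict)  # unknown dataset.json keys, pass-through


def _case_id(filename: str) -> str:
    """Case identifier: filename without channel suffix and extension."""
    m = FILENAME_RE.match(filename)
    if m is None:
        return filename.removesuffix(".nii.gz")
    base = filename.removesuffix(".nii.gz")
    if m.group("channel") is not None:
        base = base.rsplit("_", 1)[0]
    return base


def _validate_names(files: list[str], folder: str, is_image: bool, errors: list[str]) -> None:
    for f in files:
        m = FILENAME_RE.match(f)
        if m is None:
            errors.append(f"{folder}/{f}: does not match me2-<dataset>_<split>XX[_<channel>].nii.gz")
            continue
        if is_image and m.group("channel") is None:
            errors.append(f"{folder}/{f}: image filename missing channel suffix (e.g. _0000)")
        if not is_image and m.group("channel") is not None:
            errors.append(f"{folder}/{f}: label filename must not carry a channel suffix")


def read_dataset_descriptor(root: str | Path) -> DatasetDescriptor:
    """Read and validate ``dataset.json``/``split.json`` and the file layout.

    Checks the filename convention, image/label pairing, and disjointness of
    the train/val/test splits. All violations are collected and raised
    together as a :class:`DatasetLayoutError`.
    """
    root = Path(root)
    ds_path = root / "dataset.json"
    if not ds_path.exists():
        raise DatasetLayoutError(f"{root}: dataset.json not found")
    try:
        meta = json.loads(ds_path.read_text())
    except json.JSONDecodeError as e:
        raise DatasetLayoutError(f"{ds_path}: malformed JSON ({e})") from e

    errors: list[str] = []

    def listdir(sub: str) -> list[str]:
        d = root / sub
        return sorted(p.name for p in d.glob("*.nii.gz")) if d.is_dir() else []

    train_images = listdir("imagesTr")
    train_labels = listdir("labelsTr")
    test_images = listdir("imagesTs")
    test_labels = listdir("labelsTs")

    _validate_names(train_images, "imagesTr", True, errors)
    _validate_names(train_labels, "labelsTr", False, errors)
    _validate_names(test_images, "imagesTs", True, errors)
    _validate_names(test_labels, "labelsTs", False, errors)

    # image/label pairing: every training image needs a label, and vice versa
    ti_cases = {_case_id(f) for f in train_images}
    tl_cases = {_case_id(f) for f in train_labels}
    for c in sorted(ti_cases - tl_cases):
        errors.append(f"imagesTr: image {c} has no matching label in labelsTr")
    for c in sorted(tl_cases - ti_cases):
        errors.append(f"labelsTr: label {c} has no matching image in imagesTr")
    if test_labels:
        si_cases = {_case_id(f) for f in test_images}
        sl_cases = {_case_id(f) for f in test_labels}
        for c in sorted(si_cases - sl_cases):
            errors.append(f"imagesTs: image {c} has no matching label in labelsTs")
        for c in sorted(sl_cases - si_cases):
            errors.append(f"labelsTs: label {c} has no matching image in imagesTs")

    split_path = root / "split.json"
    if split_path.exists():
        try:
            splits = json.loads(split_path.read_text())
        except json.JSONDecodeError as e:
            raise DatasetLayoutError(f"{split_path}: malformed JSON ({e})") from e
        splits = {k: list(v) for k, v in splits.items()}
    else:
        # infer from folder membership: validation unstated -> empty
        splits = {"train": sorted(ti_cases), "val": [], "test": sorted(_case_id(f) for f in test_images)}

    names = list(splits)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            overlap = set(splits[a]) & set(splits[b])
            for c in sorted(overlap):
                errors.append(f"split.json: case {c} listed in both {a!r} and {b!r}")

    metadata: dict[str, dict[str, str]] = {}
    md_path = root / "metadata.csv"
    if md_path.exists():
        import pandas as pd

        df = pd.read_csv(md_path, dtype=str)
        key = df.columns[0]
        metadata = {str(row[key]): {c: row[c] for c in df.columns} for _, row in df.iterrows()}

    if errors:
        raise DatasetLayoutError(
            f"{root}: {len(errors)} layout violation(s):\n  " + "\n  ".join(errors)
        )

    known = {"name", "dataset_name", "modality", "channel_names", "spacing", "voxel_spacing"}
    spacing = meta.get("spacing") or meta.get("voxel_spacing")
    return DatasetDescriptor(
        root=root,
        name=str(meta.get("name") or meta.get("dataset_name") or root.name),
        modality=meta.get("modality"),
        channel_names=meta.get("channel_names", {}),
        spacing=tuple(spacing) if spacing else None,
        train_images=train_images,
        train_labels=train_labels,
        test_images=test_images,
        test_labels=test_labels,
        splits=splits,
        metadata=metadata,
        extra={k: v for k, v in meta.items() if k not in known},
    )


# ---------------------------------------------------------------------------
# checksums


@dataclass
class ChecksumReport:
    """Per-file integrity report from :func:`verify_checksums`."""

    statuses: dict[str, str]  # relpath -> "match" | "mismatch" | "missing"

    @property
    def passed(self) -> bool:
        return all(s == "match" for s in self.statuses.values())

    def failures(self) -> dict[str, str]:
        return {p: s for p, s in self.statuses.items() if s != "match"}


def _digest(path: Path, algorithm: str) -> str:
    h = hashlib.new(algorithm)
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def verify_checksums(
    root: str | Path, manifest: dict[str, str] | str | Path, algorithm: str = "sha256"
) -> ChecksumReport:
    """Verify file digests against a manifest.

    ``manifest`` is either a mapping ``relpath -> hex digest`` or a path to a
    plain-text manifest with one ``<hex>  <relpath>`` entry per line. Missing
    files are report entries, never exceptions.
    """
    root = Path(root)
    if not isinstance(manifest, dict):
        manifest = read_checksum_manifest(manifest)
    statuses: dict[str, str] = {}
    for rel, expected in manifest.items():
        p = root / rel
        if not p.exists():
            statuses[rel] = "missing"
        else:
            statuses[rel] = "match" if _digest(p, algorithm) == expected.lower() else "mismatch"
    return ChecksumReport(statuses=statuses)


def read_checksum_manifest(path: str | Path) -> dict[str, str]:
    """Parse a ``<hex>  <relpath>`` manifest file."""
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        digest, _, rel = line.partition("  ")
        if not rel:
            raise DatasetLayoutError(f"malformed manifest line: {line!r}")
        out[rel.strip()] = digest.strip().lower()
    return out


def write_checksum_manifest(
    root: str | Path, files: list[str | Path], path: str | Path, algorithm: str = "sha256"
) -> dict[str, str]:
    """Compute digests for ``files`` (relative to ``root``) and write a manifest."""
    root = Path(root)
    manifest = {str(f): _digest(root / f, algorithm) for f in files}
    lines = [f"{digest}  {rel}" for rel, digest in sorted(manifest.items())]
    Path(path).write_text("\n".join(lines) + "\n")
    return manifest
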