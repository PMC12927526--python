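"""Seeded 3D phantoms with controllable segmentation difficulty.

The generator rasterizes simple analytic primitives — balls, tubes,
dumbbells (two cubes joined by a thin neck) and branched tube unions — into
an instance-labeled volume, with a configurable minimum Chebyshev gap between
instances. Dense gap-0 placements produce high dilation-collision (DCI)
volumes; radius-1 dumbbell necks produce erosion-fragile (EFI >= 1)
instances, so the difficulty metrics can be exercised with known answers.

:func:`perturb_prediction` derives a degraded "prediction" from a ground
truth by applying logged merge / split / drop / boundary-noise / spurious-blob
events. Events are constructed to be geometrically non-interacting (each
ground-truth instance participates in at most one event; boundary dilations
only claim voxels that are background in both volumes; injected blobs touch
nothing), so the :class:`PerturbationLog` can predict the exact instance-level
TP/FP/FN counts of a subsequent Hungarian-matched evaluation by pure
bookkeeping over recorded voxel counts.

All randomness flows from a single ``numpy.random.default_rng(seed)``; the
same spec and seed reproduce bit-identical volumes.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi

from .volume_io import (
    ImageVolume,
    InstanceVolume,
    write_checksum_manifest,
    write_image,
    write_labels,
)

__all__ = [
    "PhantomSpec",
    "PerturbationSpec",
    "PerturbationLog",
    "PlacementError",
    "generate_phantom",
    "perturb_prediction",
    "make_fixture_dataset",
]


class PlacementError(RuntimeError):
    """Packing was infeasible within the retry budget."""

    def __init__(self, achieved: int, requested: int):
        self.achieved = achieved
        self.requested = requested
        super().__init__(
            f"placed only {achieved} of {requested} instances within the retry budget; "
            "reduce count, sizes, or gap"
        )


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for a synthetic instance-labeled volume.

    Parameters
    ----------
    shape
        Grid shape (z, y, x) in voxels.
    spacing
        Voxel size (z, y, x) in nm; metadata only, the geometry is voxel-based.
    n_instances
        Instances to place in addition to ``abutting_pairs``.
    primitives
        Mix of primitive names drawn uniformly per instance:
        "ball", "tube", "dumbbell", "branched", "cube".
    size_range
        Characteristic half-size/radius range in voxels (inclusive).
    gap
        Minimum Chebyshev gap in voxels between distinct instances
        (0 = abutting allowed, overlap never).
    neck_radius
        Neck half-width of dumbbells; 1 gives a 1-voxel-thick neck that a
        radius-1 erosion removes.
    abutting_pairs
        Number of face-abutting cube pairs placed first (two labels each);
        each member of a pair has DCI >= 1 at dilation radius 1.
    seed
        PRNG seed; identical (spec, seed) gives bit-identical output.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (16.0, 16.0, 16.0)
    n_instances: int = 8
    primitives: tuple[str, ...] = ("ball", "tube", "dumbbell", "branched")
    size_range: tuple[int, int] = (3, 6)
    gap: int = 1
    neck_radius: int = 1
    abutting_pairs: int = 0
    seed: int = 0
    max_attempts: int = 500

    def __post_init__(self) -> None:
        if min(self.shape) < 8:
            raise ValueError(f"shape too small for placement: {self.shape}")
        if self.gap < 0 or self.n_instances < 0 or self.abutting_pairs < 0:
            raise ValueError("gap, n_instances and abutting_pairs must be non-negative")
        if self.size_range[0] < 1 or self.size_range[1] < self.size_range[0]:
            raise ValueError(f"invalid size_range {self.size_range}")
        unknown = set(self.primitives) - {"ball", "tube", "dumbbell", "branched", "cube"}
        if unknown:
            raise ValueError(f"unknown primitives: {sorted(unknown)}")


# ---------------------------------------------------------------------------
# analytic primitive rasterizers (local boolean boxes)


def _ball(radius: int) -> np.ndarray:
    n = 2 * radius + 1
    zz, yy, xx = np.ogrid[:n, :n, :n]
    return (zz - radius) ** 2 + (yy - radius) ** 2 + (xx - radius) ** 2 <= radius**2


def _cube(side: int) -> np.ndarray:
    return np.ones((side, side, side), dtype=bool)


def _tube(length: int, radius: int, rng: np.random.Generator) -> np.ndarray:
    """Capsule of given axis length and radius along a random direction."""
    d = rng.normal(size=3)
    d /= np.linalg.norm(d)
    half = d * (length / 2)
    pad = radius + 1
    extent = np.ceil(np.abs(half) * 2).astype(int) + 2 * pad + 1
    center = (extent - 1) / 2
    p0, p1 = center - half, center + half
    grid = np.stack(
        np.meshgrid(*[np.arange(e) for e in extent], indexing="ij"), axis=-1
    ).astype(float)
    seg = p1 - p0
    t = np.clip(((grid - p0) @ seg) / (seg @ seg), 0.0, 1.0)
    closest = p0 + t[..., None] * seg
    return np.linalg.norm(grid - closest, axis=-1) <= radius


def _dumbbell(cube_side: int, neck_radius: int, neck_len: int) -> np.ndarray:
    """Two cubes joined along x by a neck of half-width ``neck_radius``."""
    s, w = cube_side, 2 * neck_radius - 1
    shape = (s, s, 2 * s + neck_len)
    out = np.zeros(shape, dtype=bool)
    out[:, :, :s] = True
    out[:, :, s + neck_len :] = True
    c = s // 2
    lo, hi = c - (w // 2), c + (w // 2) + 1
    out[lo:hi, lo:hi, s : s + neck_len] = True
    return out


def _branched(arm_len: int, radius: int, rng: np.random.Generator) -> np.ndarray:
    """Union of three capsules sharing one endpoint (a Y-junction)."""
    pad = arm_len + radius + 2
    n = 2 * pad + 1
    center = np.array([pad, pad, pad], dtype=float)
    grid = np.stack(np.meshgrid(*[np.arange(n)] * 3, indexing="ij"), axis=-1).astype(float)
    out = np.zeros((n, n, n), dtype=bool)
    for _ in range(3):
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        p1 = center + d * arm_len
        seg = p1 - center
        t = np.clip(((grid - center) @ seg) / (seg @ seg), 0.0, 1.0)
        closest = center + t[..., None] * seg
        out |= np.linalg.norm(grid - closest, axis=-1) <= radius
    return out


def _trim(mask: np.ndarray) -> np.ndarray:
    box = ndi.find_objects(mask.astype(np.int8))[0]
    return mask[box]


def _rasterize(primitive: str, spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    lo, hi = spec.size_range
    size = int(rng.integers(lo, hi + 1))
    if primitive == "ball":
        return _ball(size)
    if primitive == "cube":
        return _cube(2 * size + 1)
    if primitive == "tube":
        return _trim(_tube(length=3 * size, radius=max(1, size // 2), rng=rng))
    if primitive == "dumbbell":
        side = max(5, 2 * size - 1)  # cube cores must survive a radius-1 erosion
        return _dumbbell(side, spec.neck_radius, neck_len=max(3, size))
    if primitive == "branched":
        return _trim(_branched(arm_len=2 * size, radius=max(1, size // 2), rng=rng))
    raise ValueError(primitive)


def _fits(labels: np.ndarray, mask: np.ndarray, corner: tuple[int, int, int], gap: int) -> bool:
    """True if ``mask`` at ``corner`` keeps a Chebyshev gap >= ``gap`` to existing labels."""
    sl = tuple(slice(c, c + s) for c, s in zip(corner, mask.shape))
    if any(s.stop > dim for s, dim in zip(sl, labels.shape)):
        return False
    if (labels[sl][mask] > 0).any():
        return False
    if gap == 0:
        return True
    # grow the candidate by the gap (pad first: dilation does not extend the
    # array) and require the grown region to stay clear of existing instances
    probe = ndi.binary_dilation(
        np.pad(mask, gap), structure=np.ones((2 * gap + 1,) * 3, dtype=bool)
    )
    ext = tuple(
        slice(max(0, c - gap), min(dim, c + s + gap))
        for c, s, dim in zip(corner, mask.shape, labels.shape)
    )
    local = tuple(
        slice(e.start - (c - gap), e.stop - (c - gap)) for e, c in zip(ext, corner)
    )
    return not (labels[ext][probe[local]] > 0).any()


def _place(
    labels: np.ndarray,
    mask: np.ndarray,
    label: int,
    gap: int,
    rng: np.random.Generator,
    attempts: int,
) -> bool:
    shape = labels.shape
    if any(m > d for m, d in zip(mask.shape, shape)):
        return False
    for _ in range(attempts):
        corner = tuple(
            int(rng.integers(0, d - m + 1)) for d, m in zip(shape, mask.shape)
        )
        if _fits(labels, mask, corner, gap):
            sl = tuple(slice(c, c + s) for c, s in zip(corner, mask.shape))
            labels[sl][mask] = label
            return True
    return False


def generate_phantom(spec: PhantomSpec) -> InstanceVolume:
    """Rasterize a phantom volume from a spec.

    Instances never overlap and keep pairwise Chebyshev gaps >= ``spec.gap``
    (members of an abutting pair touch by construction). Labels are 1..N in
    placement order. Raises :class:`PlacementError` when the packing cannot be
    realized within the retry budget, reporting the achieved count.
    """
    rng = np.random.default_rng(spec.seed)
    labels = np.zeros(spec.shape, dtype=np.int64)
    next_id = 1
    requested = 2 * spec.abutting_pairs + spec.n_instances

    for _ in range(spec.abutting_pairs):
        lo, hi = spec.size_range
        side = int(rng.integers(max(2, lo), hi + 1))
        pair = np.zeros((side, side, 2 * side), dtype=np.int8)
        pair[:, :, :side] = 1
        pair[:, :, side:] = 2
        axis = int(rng.integers(0, 3))
        pair = np.moveaxis(pair, 2, axis)
        placed = _place(labels, pair > 0, -1, spec.gap, rng, spec.max_attempts)
        if not placed:
            raise PlacementError(next_id - 1, requested)
        # split the provisional -1 marker into the two abutting labels (the
        # pair box is fully occupied, so its bounding box aligns with `pair`)
        sl = ndi.find_objects((labels == -1).astype(np.int8))[0]
        sub = labels[sl]
        sub[pair == 1] = next_id
        sub[pair == 2] = next_id + 1
        next_id += 2

    for _ in range(spec.n_instances):
        # a drawn primitive can be too large for the remaining space (or the
        # grid itself); redraw a handful of times before declaring infeasible
        for _draw in range(10):
            primitive = spec.primitives[int(rng.integers(0, len(spec.primitives)))]
            mask = _rasterize(primitive, spec, rng)
            if _place(labels, mask, next_id, spec.gap, rng, spec.max_attempts):
                break
        else:
            raise PlacementError(next_id - 1, requested)
        next_id += 1

    return InstanceVolume(
        labels=labels, spacing=spec.spacing, name=f"phantom-seed{spec.seed}"
    )


# ---------------------------------------------------------------------------
# degraded predictions with a bookkeeping log


@dataclass(frozen=True)
class PerturbationSpec:
    """Recipe for deriving a degraded prediction from a ground truth.

    Each ground-truth instance receives at most one event, drawn in order
    drop -> split -> (merge pairing) -> boundary noise, so events never
    interact and the log's TP/FP/FN prediction is exact.
    """

    merge_probability: float = 0.0
    split_probability: float = 0.0
    drop_probability: float = 0.0
    boundary_probability: float = 0.0
    boundary_radius: int = 1
    spurious_rate: float = 0.0  # expected number of injected background blobs
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("merge_probability", "split_probability", "drop_probability",
                     "boundary_probability"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.drop_probability + self.split_probability > 1.0:
            raise ValueError("drop_probability + split_probability must be <= 1")
        if self.spurious_rate < 0 or self.boundary_radius < 0:
            raise ValueError("spurious_rate and boundary_radius must be non-negative")


@dataclass
class PerturbationLog:
    """Applied perturbation events, sufficient to predict evaluation counts."""

    events: list[dict] = field(default_factory=list)

    def add(self, kind: str, **fields) -> None:
        self.events.append({"kind": kind, **fields})

    def of_kind(self, kind: str) -> list[dict]:
        return [e for e in self.events if e["kind"] == kind]

    def expected_instance_counts(self, tau: float = 0.5) -> dict[str, int]:
        """Exact instance TP/FP/FN a Hungarian evaluation at ``tau`` will report.

        Valid because events are geometrically independent: the IoU matrix is
        block-diagonal over events, so the global optimal assignment decomposes
        into per-event assignments computable from recorded voxel counts.
        """
        tp = fp = fn = 0
        for e in self.events:
            kind = e["kind"]
            if kind == "keep":
                tp += 1
            elif kind == "drop":
                fn += 1
            elif kind == "inject":
                fp += 1
            elif kind == "split":
                # fragments partition the original: IoU_k = s_k / orig
                ious = [s / e["orig_size"] for s in e["sizes"]]
                best = max(ious)
                if best >= tau:
                    tp += 1
                    fp += len(ious) - 1
                else:
                    fn += 1
                    fp += len(ious)
            elif kind == "merge":
                # merged prediction = disjoint union: IoU_k = s_k / sum(s)
                total = sum(e["sizes"])
                best = max(e["sizes"]) / total
                if best >= tau:
                    tp += 1
                    fn += len(e["sizes"]) - 1
                else:
                    fn += len(e["sizes"])
                    fp += 1
            elif kind == "boundary":
                old, new = e["old_size"], e["new_size"]
                if new == 0:
                    fn += 1
                elif min(old, new) / max(old, new) >= tau:
                    tp += 1
                else:
                    fn += 1
                    fp += 1
            else:
                raise ValueError(f"unknown event kind {kind!r}")
        return {"tp": tp, "fp": fp, "fn": fn}

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.events, indent=2) + "\n")


def perturb_prediction(
    gt: InstanceVolume, pspec: PerturbationSpec
) -> tuple[InstanceVolume, PerturbationLog]:
    """Apply logged merge/split/drop/boundary/inject errors to a ground truth.

    Deterministic per seed; the returned log describes exactly the events
    applied, in application order.
    """
    rng = np.random.default_rng(pspec.seed)
    labels = gt.labels.copy()
    log = PerturbationLog()
    ids = sorted(gt.voxel_counts())
    sizes = gt.voxel_counts()
    next_id = (max(ids) if ids else 0) + 1

    untouched: list[int] = []
    split_ids: list[int] = []
    dropped: list[int] = []
    for i in ids:
        r = rng.random()
        if r < pspec.drop_probability:
            dropped.append(i)
        elif r < pspec.drop_probability + pspec.split_probability:
            split_ids.append(i)
        else:
            untouched.append(i)

    for i in dropped:
        labels[labels == i] = 0
        log.add("drop", gt_id=i)

    for i in split_ids:
        coords = np.argwhere(labels == i)
        extents = coords.max(axis=0) - coords.min(axis=0)
        axis = int(np.argmax(extents))
        cut = float(np.median(coords[:, axis]))
        part_b = coords[:, axis] > cut
        if not part_b.any() or part_b.all():
            untouched.append(i)  # degenerate geometry, cannot split in half
            continue
        bcoords = coords[part_b]
        labels[tuple(bcoords.T)] = next_id
        s_total = len(coords)
        s_b = len(bcoords)
        log.add("split", gt_id=i, new_pred_id=next_id,
                orig_size=s_total, sizes=[s_total - s_b, s_b])
        next_id += 1

    # merge pairing among instances not otherwise perturbed
    rng.shuffle(untouched)
    merged: set[int] = set()
    for a, b in zip(untouched[::2], untouched[1::2]):
        if rng.random() < pspec.merge_probability:
            labels[labels == b] = a
            log.add("merge", gt_ids=sorted((a, b)), pred_id=a,
                    sizes=[sizes[a], sizes[b]])
            merged.update((a, b))
    remaining = sorted(i for i in untouched if i not in merged)

    gt_background = gt.labels == 0
    for i in remaining:
        if pspec.boundary_radius > 0 and rng.random() < pspec.boundary_probability:
            se = np.ones((2 * pspec.boundary_radius + 1,) * 3, dtype=bool)
            mask = labels == i
            if rng.random() < 0.5:
                new_mask = ndi.binary_erosion(mask, structure=se, border_value=0)
            else:
                # grow only into voxels background in both volumes: other
                # instances' IoUs are untouched, so events stay independent
                grown = ndi.binary_dilation(mask, structure=se)
                new_mask = mask | (grown & gt_background & (labels == 0))
            labels[mask] = 0
            labels[new_mask] = i
            log.add("boundary", gt_id=i,
                    op="erode" if new_mask.sum() < mask.sum() else "dilate",
                    old_size=int(mask.sum()), new_size=int(new_mask.sum()))
        else:
            log.add("keep", gt_id=i)

    n_blobs = int(rng.poisson(pspec.spurious_rate))
    for _ in range(n_blobs):
        radius = int(rng.integers(2, 4))
        blob = _ball(radius)
        # gap 1 from everything (gt and current prediction) keeps blobs independent
        target = ((labels > 0) | (~gt_background)).astype(np.int64)
        placed = _place(target, blob, -1, gap=1, rng=rng, attempts=100)
        if placed:
            labels[target == -1] = next_id
            log.add("inject", pred_id=next_id, size=int(blob.sum()))
            next_id += 1

    pred = InstanceVolume(labels=labels, spacing=gt.spacing, name=f"{gt.name}-pred")
    return pred, log


# ---------------------------------------------------------------------------
# on-disk fixture layout


def _synthesize_image(vol: InstanceVolume, rng: np.random.Generator) -> ImageVolume:
    """Smoothed label indicator plus Gaussian noise; no EM realism intended."""
    base = ndi.gaussian_filter(vol.foreground().astype(np.float32), sigma=1.0)
    noisy = base + rng.normal(0.0, 0.05, size=vol.shape).astype(np.float32)
    return ImageVolume(intensities=noisy, spacing=vol.spacing, name=vol.name)


def make_fixture_dataset(
    root: str | Path,
    spec: PhantomSpec,
    n_train: int = 2,
    n_val: int = 1,
    n_test: int = 1,
    dataset_name: str = "synth",
) -> Path:
    """Write a complete nnU-Net-style benchmark directory of phantom volumes.

    Generates ``n_train + n_val + n_test`` phantom/image pairs (validation
    cases live under ``imagesTr`` and are designated by ``split.json``, as in
    nnU-Net), plus ``dataset.json``, ``split.json``, ``metadata.csv`` and a
    SHA-256 ``checksums.sha256`` manifest. The layout validates cleanly with
    :func:`mitometrics.volume_io.read_dataset_descriptor`.
    """
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    files: list[str] = []
    train_cases: list[str] = []
    val_cases: list[str] = []
    test_cases: list[str] = []
    for k in range(n_train + n_val + n_test):
        vol = generate_phantom(dataclasses.replace(spec, seed=spec.seed + k))
        img = _synthesize_image(vol, rng)
        if k < n_train + n_val:
            split, idx = "train", k
            img_dir, lab_dir = "imagesTr", "labelsTr"
        else:
            split, idx = "test", k - n_train - n_val
            img_dir, lab_dir = "imagesTs", "labelsTs"
        case = f"me2-{dataset_name}_{split}{idx:02d}"
        write_labels(vol, root / lab_dir / f"{case}.nii.gz")
        write_image(img, root / img_dir / f"{case}_0000.nii.gz")
        files += [f"{lab_dir}/{case}.nii.gz", f"{img_dir}/{case}_0000.nii.gz"]
        (train_cases if k < n_train else val_cases if k < n_train + n_val else test_cases).append(case)

    dataset_json = {
        "name": dataset_name,
        "modality": "synthetic-EM",
        "channel_names": {"0": "EM"},
        "spacing": list(spec.spacing),
        "numTraining": n_train + n_val,
        "numTest": n_test,
        "file_ending": ".nii.gz",
        "generator": {"spec": dataclasses.asdict(spec), "seed": spec.seed},
    }
    (root / "dataset.json").write_text(json.dumps(dataset_json, indent=2) + "\n")
    (root / "split.json").write_text(
        json.dumps({"train": train_cases, "val": val_cases, "test": test_cases}, indent=2) + "\n"
    )
    (root / "metadata.csv").write_text(
        "dataset,system,tissue,cell_type,voxel_size,modality,source\n"
        f"{dataset_name},synthetic,none,none,"
        f"{'x'.join(str(s) for s in spec.spacing)}nm,synthetic-EM,mitometrics\n"
    )
    files += ["dataset.json", "split.json", "metadata.csv"]
    write_checksum_manifest(root, files, root / "checksums.sha256")
    return root
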