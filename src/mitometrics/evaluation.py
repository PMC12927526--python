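"""Two-tier segmentation scoring: voxel-level and Hungarian-matched instance-level.

Semantic accuracy binarizes both volumes to foreground/background and reports
``TP / (TP + FP + FN)`` over voxels. Instance accuracy matches predicted to
ground-truth instances one-to-one with the Hungarian algorithm on an IoU cost
matrix (cost = -IoU over the full rectangular matrix), then discards matched
pairs below the IoU threshold tau; matched pairs with IoU >= tau are TPs,
unmatched predictions FPs, unmatched ground-truth instances FNs, and the
accuracy is again ``TP / (TP + FP + FN)``. The default tau is 0.5
("Accuracy@50"); boundary semantics are inclusive, so a pair at exactly
IoU = 0.5 counts as matched at tau = 0.5.

Degenerate inputs are resolved explicitly: with no ground-truth and no
predicted instances both accuracies are 1.0 (nothing to find, nothing found);
with instances on exactly one side the accuracy is 0.0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .volume_io import InstanceVolume

__all__ = [
    "IoUTable",
    "MatchResult",
    "SemanticResult",
    "EvaluationReport",
    "semantic_accuracy",
    "iou_table",
    "match_instances",
    "instance_accuracy",
    "evaluate",
    "sweep_tau",
]

DEFAULT_TAU = 0.5
DEFAULT_SIZE_BINS = (500, 5_000, 50_000)


def _check_shapes(gt: InstanceVolume, pred: InstanceVolume) -> None:
    if gt.shape != pred.shape:
        raise ValueError(f"shape mismatch: ground truth {gt.shape} vs prediction {pred.shape}")


@dataclass
class SemanticResult:
    """Voxel-level foreground/background agreement."""

    tp_vox: int
    fp_vox: int
    fn_vox: int

    @property
    def accuracy(self) -> float:
        denom = self.tp_vox + self.fp_vox + self.fn_vox
        return 1.0 if denom == 0 else self.tp_vox / denom

    def to_dict(self) -> dict:
        return {
            "tp_vox": self.tp_vox,
            "fp_vox": self.fp_vox,
            "fn_vox": self.fn_vox,
            "accuracy_sem": self.accuracy,
        }


def semantic_accuracy(gt: InstanceVolume, pred: InstanceVolume) -> SemanticResult:
    """Voxel-level TP/FP/FN after binarizing any positive label to foreground."""
    _check_shapes(gt, pred)
    g = gt.foreground()
    p = pred.foreground()
    return SemanticResult(
        tp_vox=int(np.count_nonzero(g & p)),
        fp_vox=int(np.count_nonzero(~g & p)),
        fn_vox=int(np.count_nonzero(g & ~p)),
    )


@dataclass
class IoUTable:
    """Dense ground-truth x prediction IoU matrix with aligned id lists."""

    gt_ids: np.ndarray
    pred_ids: np.ndarray
    iou: np.ndarray  # |G| x |P|, values in [0, 1]
    gt_sizes: dict[int, int] = field(default_factory=dict)
    pred_sizes: dict[int, int] = field(default_factory=dict)


def iou_table(gt: InstanceVolume, pred: InstanceVolume) -> IoUTable:
    """Exact pairwise intersection-over-union between all instance pairs.

    Computed in a single sparse overlap pass over foreground voxels; pairs
    with empty intersection have IoU 0. Ids are listed ascending so the
    matrix layout (and hence any solver tie-breaking) is reproducible.
    """
    _check_shapes(gt, pred)
    g = gt.labels.ravel()
    p = pred.labels.ravel()
    fg = (g > 0) | (p > 0)
    g = g[fg]
    p = p[fg]

    gt_sizes = {int(i): int(c) for i, c in zip(*np.unique(g[g > 0], return_counts=True))}
    pred_sizes = {int(i): int(c) for i, c in zip(*np.unique(p[p > 0], return_counts=True))}
    gt_ids = np.array(sorted(gt_sizes), dtype=np.int64)
    pred_ids = np.array(sorted(pred_sizes), dtype=np.int64)

    iou = np.zeros((len(gt_ids), len(pred_ids)), dtype=float)
    both = (g > 0) & (p > 0)
    if both.any():
        pair_keys, inter = np.unique(
            np.stack([g[both], p[both]]), axis=1, return_counts=True
        )
        gt_row = {int(i): r for r, i in enumerate(gt_ids)}
        pred_col = {int(i): c for c, i in enumerate(pred_ids)}
        for (gi, pi), n in zip(pair_keys.T, inter):
            union = gt_sizes[int(gi)] + pred_sizes[int(pi)] - int(n)
            iou[gt_row[int(gi)], pred_col[int(pi)]] = int(n) / union
    return IoUTable(gt_ids=gt_ids, pred_ids=pred_ids, iou=iou,
                    gt_sizes=gt_sizes, pred_sizes=pred_sizes)


@dataclass
class MatchResult:
    """One-to-one instance assignment at IoU threshold tau."""

    tau: float
    matches: list[tuple[int, int, float]]  # (gt_id, pred_id, iou), iou >= tau
    unmatched_gt: list[int]  # false negatives
    unmatched_pred: list[int]  # false positives

    @property
    def tp(self) -> int:
        return len(self.matches)

    @property
    def fp(self) -> int:
        return len(self.unmatched_pred)

    @property
    def fn(self) -> int:
        return len(self.unmatched_gt)

    def to_frame(self) -> pd.DataFrame:
        """Per-instance match table with status in {TP, FP, FN}."""
        rows = [(g, p, i, "TP") for g, p, i in self.matches]
        rows += [(g, None, 0.0, "FN") for g in self.unmatched_gt]
        rows += [(None, p, 0.0, "FP") for p in self.unmatched_pred]
        return pd.DataFrame(rows, columns=["gt_id", "pred_id", "iou", "status"])


def match_instances(
    table: IoUTable, tau: float = DEFAULT_TAU, premask: bool = False
) -> MatchResult:
    """Hungarian assignment on the IoU table, then tau filtering.

    The optimal one-to-one assignment maximizes total IoU over the full
    rectangular matrix; afterwards pairs with IoU < tau are discarded to the
    unmatched sets. With ``premask=True`` sub-threshold entries are zeroed
    before solving instead (for comparison with tools that pre-mask).
    """
    if not (0 < tau <= 1):
        raise ValueError(f"tau must be in (0, 1], got {tau}")
    iou = table.iou
    if premask:
        iou = np.where(iou >= tau, iou, 0.0)
    matched_gt: set[int] = set()
    matched_pred: set[int] = set()
    matches: list[tuple[int, int, float]] = []
    if iou.size:
        rows, cols = linear_sum_assignment(-iou)
        for r, c in zip(rows, cols):
            if table.iou[r, c] >= tau:
                g, p = int(table.gt_ids[r]), int(table.pred_ids[c])
                matches.append((g, p, float(table.iou[r, c])))
                matched_gt.add(g)
                matched_pred.add(p)
    return MatchResult(
        tau=tau,
        matches=sorted(matches),
        unmatched_gt=sorted(int(g) for g in table.gt_ids if int(g) not in matched_gt),
        unmatched_pred=sorted(int(p) for p in table.pred_ids if int(p) not in matched_pred),
    )


def instance_accuracy(match: MatchResult) -> float:
    """``TP / (TP + FP + FN)`` over instances; 1.0 when there is nothing on either side."""
    denom = match.tp + match.fp + match.fn
    return 1.0 if denom == 0 else match.tp / denom


@dataclass
class StratumReport:
    """Instance-level counts restricted to one size bin (voxel counts)."""

    lo: float
    hi: float
    tp: int
    fp: int
    fn: int

    @property
    def accuracy(self) -> float:
        denom = self.tp + self.fp + self.fn
        return 1.0 if denom == 0 else self.tp / denom

    def to_dict(self) -> dict:
        return {
            "bin": [self.lo, self.hi],
            "tp_inst": self.tp,
            "fp_inst": self.fp,
            "fn_inst": self.fn,
            "accuracy_inst": self.accuracy,
        }


@dataclass
class EvaluationReport:
    """Combined semantic and instance-level scores for one volume pair."""

    semantic: SemanticResult
    match: MatchResult
    strata: list[StratumReport] | None = None

    @property
    def accuracy_sem(self) -> float:
        return self.semantic.accuracy

    @property
    def accuracy_inst(self) -> float:
        return instance_accuracy(self.match)

    def to_dict(self) -> dict:
        out = {
            "semantic": self.semantic.to_dict(),
            "instance": {
                "tau": self.match.tau,
                "tp_inst": self.match.tp,
                "fp_inst": self.match.fp,
                "fn_inst": self.match.fn,
                "accuracy_inst": self.accuracy_inst,
            },
        }
        if self.strata is not None:
            out["strata"] = [s.to_dict() for s in self.strata]
        return out

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def _bin_edges(size_bins: tuple[int, ...]) -> list[tuple[float, float]]:
    edges = [0.0, *sorted(size_bins), np.inf]
    return list(zip(edges[:-1], edges[1:]))


def evaluate(
    gt: InstanceVolume,
    pred: InstanceVolume,
    tau: float = DEFAULT_TAU,
    size_bins: tuple[int, ...] | None = None,
) -> EvaluationReport:
    """Score a prediction against ground truth at both tiers.

    With ``size_bins`` (ascending voxel-count edges), instance TP/FP/FN are
    additionally recomputed per size bin: matched pairs and unmatched ground
    truth go to the bin of the ground-truth instance's voxel count, unmatched
    predictions to the bin of their own voxel count.
    """
    sem = semantic_accuracy(gt, pred)
    table = iou_table(gt, pred)
    match = match_instances(table, tau)
    strata = None
    if size_bins is not None:
        strata = []
        for lo, hi in _bin_edges(tuple(size_bins)):
            in_bin = lambda n: lo <= n < hi  # noqa: E731
            tp = sum(1 for g, _, _ in match.matches if in_bin(table.gt_sizes[g]))
            fn = sum(1 for g in match.unmatched_gt if in_bin(table.gt_sizes[g]))
            fp = sum(1 for p in match.unmatched_pred if in_bin(table.pred_sizes[p]))
            strata.append(StratumReport(lo=lo, hi=hi, tp=tp, fp=fp, fn=fn))
    return EvaluationReport(semantic=sem, match=match, strata=strata)


def sweep_tau(
    gt: InstanceVolume, pred: InstanceVolume, taus: list[float]
) -> list[tuple[float, float]]:
    """Instance accuracy at each threshold, re-using a single IoU table.

    ``taus`` must be strictly increasing in (0, 1]; the returned accuracies
    are non-increasing in tau.
    """
    taus = list(taus)
    if any(b <= a for a, b in zip(taus, taus[1:])):
        raise ValueError(f"taus must be strictly increasing, got {taus}")
    if any(not (0 < t <= 1) for t in taus):
        raise ValueError(f"every tau must be in (0, 1], got {taus}")
    table = iou_table(gt, pred)
    return [(t, instance_accuracy(match_instances(table, t))) for t in taus]
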