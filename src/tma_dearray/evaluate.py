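"""Scoring of de-arraying results against ground truth.

Two tasks are scored: *localization* (was each present core found near its
true center?) and *array coordinates* (was each found core given the correct
row/column?).  Counts follow the usual conventions — TP correctly handled
cores, FN missed present cores, FP spurious or mis-assigned cores, TN empty
design positions left empty — and feed six metrics:

    A = (TP+TN)/(TP+TN+FP+FN)      P = TP/(TP+FP)        R = TP/(TP+FN)
    F = 2PR/(P+R)                  G = sqrt(PR)          JSC = TP/(TP+FP+FN)

When FP = 0 the Jaccard coefficient coincides with the recall.  Because the
origin of the array coordinate system is arbitrary (the grid translation is
only defined modulo the lattice), coordinate scoring allows one global
integer offset, estimated as the most common (gt - predicted) difference
over position-matched cores; transposes and reflections are *not* allowed.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid_register import DearrayResult

__all__ = ["MetricsReport", "match_localizations", "match_coordinates", "score"]

LOCALIZATION_TOL_FACTOR = 0.5  # matching tolerance as a fraction of r_core


@dataclass
class MetricsReport:
    task: str
    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    precision: float
    recall: float
    f_score: float
    g_score: float
    jaccard: float
    degenerate: bool = False

    def as_row(self) -> dict:
        return {
            "task": self.task,
            "TP": self.tp,
            "TN": self.tn,
            "FP": self.fp,
            "FN": self.fn,
            "A": self.accuracy,
            "P": self.precision,
            "R": self.recall,
            "F": self.f_score,
            "G": self.g_score,
            "JSC": self.jaccard,
        }


def _greedy_match(pred: np.ndarray, gt: np.ndarray, tol: float) -> list[tuple[int, int]]:
    """One-to-one matching by increasing distance, bounded by tol."""
    if len(pred) == 0 or len(gt) == 0:
        return []
    d = np.linalg.norm(pred[:, None, :] - gt[None, :, :], axis=-1)
    cand = [(d[i, j], i, j) for i in range(len(pred)) for j in range(len(gt)) if d[i, j] <= tol]
    cand.sort(key=lambda c: c[0])
    used_p: set[int] = set()
    used_g: set[int] = set()
    out = []
    for _, i, j in cand:
        if i in used_p or j in used_g:
            continue
        used_p.add(i)
        used_g.add(j)
        out.append((i, j))
    return out


def match_localizations(
    result: DearrayResult, gt_table: pd.DataFrame, tol: float
) -> tuple[int, int, int, int]:
    """(TP, TN, FP, FN) for the localization task.

    Predictions are the core centers of the result; GT rows flagged present
    must be matched within ``tol`` px, absent rows left unmatched count as TN.
    """
    pred = np.array([[c.x, c.y] for c in result.cores]) if result.cores else np.empty((0, 2))
    present = gt_table[gt_table["present"]]
    absent = gt_table[~gt_table["present"]]
    matches = _greedy_match(pred, present[["x", "y"]].to_numpy(), tol)
    tp = len(matches)
    fn = len(present) - tp
    fp = len(pred) - tp
    tn = 0
    if len(absent) and len(pred):
        d = np.linalg.norm(
            pred[:, None, :] - absent[["x", "y"]].to_numpy()[None, :, :], axis=-1
        )
        tn = int(np.sum(d.min(axis=0) > tol))
    else:
        tn = len(absent)
    return tp, tn, fp, fn


def match_coordinates(
    result: DearrayResult, gt_table: pd.DataFrame, tol: float
) -> tuple[int, int, int, int]:
    """(TP, TN, FP, FN) for the array-coordinate task.

    Cores are first matched to GT nodes by position (within ``tol``); the
    modal (gt - predicted) integer offset aligns the two coordinate systems,
    then TP counts cores whose offset-corrected coordinate equals the GT
    node's, FP those mis-assigned (or spurious), FN present GT nodes with no
    correctly-assigned core.
    """
    assigned = [c for c in result.cores if c.p is not None]
    pred = np.array([[c.x, c.y] for c in assigned]) if assigned else np.empty((0, 2))
    present = gt_table[gt_table["present"]].reset_index(drop=True)
    absent = gt_table[~gt_table["present"]]
    matches = _greedy_match(pred, present[["x", "y"]].to_numpy(), tol)
    diffs = Counter()
    for i, j in matches:
        gk, gl = int(present.loc[j, "k"]), int(present.loc[j, "l"])
        pk, pl = assigned[i].p
        diffs[(gk - pk, gl - pl)] += 1
    offset = diffs.most_common(1)[0][0] if diffs else (0, 0)
    tp = 0
    for i, j in matches:
        gk, gl = int(present.loc[j, "k"]), int(present.loc[j, "l"])
        pk, pl = assigned[i].p
        if (pk + offset[0], pl + offset[1]) == (gk, gl):
            tp += 1
    fp = len(assigned) - tp
    fn = len(present) - tp
    tn = 0
    if len(absent) and len(pred):
        d = np.linalg.norm(
            pred[:, None, :] - absent[["x", "y"]].to_numpy()[None, :, :], axis=-1
        )
        tn = int(np.sum(d.min(axis=0) > tol))
    else:
        tn = len(absent)
    return tp, tn, fp, fn


def score(tp: int, tn: int, fp: int, fn: int, task: str = "localization") -> MetricsReport:
    """Compute the six metrics; degenerate denominators yield 0 with a flag."""
    if min(tp, tn, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    total = tp + tn + fp + fn
    degenerate = total == 0 or (tp + fp) == 0 or (tp + fn) == 0
    acc = (tp + tn) / total if total else 0.0
    prec = tp / (tp + fp) if (tp + fp) else 0.0
    rec = tp / (tp + fn) if (tp + fn) else 0.0
    f = 2 * prec * rec / (prec + rec) if (prec + rec) else 0.0
    g = float(np.sqrt(prec * rec))
    jsc = tp / (tp + fp + fn) if (tp + fp + fn) else 0.0
    return MetricsReport(
        task=task,
        tp=tp,
        tn=tn,
        fp=fp,
        fn=fn,
        accuracy=acc,
        precision=prec,
        recall=rec,
        f_score=f,
        g_score=g,
        jaccard=jsc,
        degenerate=degenerate,
    )
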