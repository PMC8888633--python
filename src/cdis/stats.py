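"""Delineation statistics: pooled ROC analysis and correlated-AUC inference.

Delineation performance is quantified at the voxel level: scalar-map
values are pooled over all patient cases inside the prostate gland, with
positive / negative populations defined by one of four tasks
(csPCa-vs-healthy, csPCa-vs-insPCa, csPCa-vs-rest, PCa-vs-healthy).
The empirical ROC curve and its trapezoidal AUC summarize each modality.

Two modalities computed on the same cases give correlated AUC estimates,
so their difference is tested with the Hanley-McNeil critical ratio

    z = (A1 - A2) / sqrt(SE1^2 + SE2^2 - 2 r SE1 SE2)

where each standard error is

    SE = sqrt( [ A(1-A) + (nP-1)(Q1 - A^2) + (nN-1)(Q2 - A^2) ] / (nP nN) ),
    Q1 = A / (2 - A),   Q2 = 2 A^2 / (1 + A),

and r is the correlation between the two AUC estimates, obtained by
interpolating a lookup table at the average of the two AUCs and the
average of the between-modality Pearson correlations of the positive and
negative populations (per-patient class medians, since voxel-to-voxel
correspondence across modalities of differing native resolution is not
assumed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
from scipy import stats as sps
from scipy.interpolate import RegularGridInterpolator
from sklearn.metrics import roc_curve as _sk_roc_curve

from .volumes import ImageVolume, TissueLabelSet

__all__ = [
    "ROCCurve",
    "AUCComparison",
    "TissueHistograms",
    "TASKS",
    "pool_voxels",
    "empirical_roc",
    "auc",
    "auc_score",
    "hanley_mcneil_se",
    "estimate_r",
    "interpolate_r_table",
    "compare_auc",
    "tissue_histograms",
]

#: Delineation tasks: canonical name -> (positive classes, negative classes).
#: Class tokens: "csPCa", "insPCa", "healthy".
TASKS: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "cspca-vs-healthy": (("csPCa",), ("healthy",)),
    "cspca-vs-inspca": (("csPCa",), ("insPCa",)),
    "cspca-vs-rest": (("csPCa",), ("insPCa", "healthy")),
    "pca-vs-healthy": (("csPCa", "insPCa"), ("healthy",)),
}


def _canonical_task(task: str) -> str:
    key = task.lower().replace("_", "-")
    if key not in TASKS:
        raise ValueError(f"unknown task {task!r}; expected one of {sorted(TASKS)}")
    return key


def _class_mask(labels: TissueLabelSet, cls: str) -> np.ndarray:
    if cls == "healthy":
        return labels.healthy_mask
    return labels.class_mask(cls)


# ----------------------------------------------------------------------
# pooling and ROC
# ----------------------------------------------------------------------

def pool_voxels(
    maps_per_case: Sequence[ImageVolume],
    labels_per_case: Sequence[TissueLabelSet],
    task: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Flatten voxel scores and binary labels over all cases for a task.

    Voxels outside the gland are excluded; within the gland only voxels
    belonging to the task's positive or negative classes contribute.
    Order is stable: cases in the given order, positives before
    negatives within each case.
    """
    task = _canonical_task(task)
    pos_classes, neg_classes = TASKS[task]
    if len(maps_per_case) != len(labels_per_case):
        raise ValueError("one label set per map is required")
    scores, labels = [], []
    for vol, lab in zip(maps_per_case, labels_per_case):
        if vol.shape != lab.gland.shape:
            raise ValueError("map and labels must share a grid")
        pos = np.zeros(vol.shape, dtype=bool)
        for c in pos_classes:
            pos |= _class_mask(lab, c)
        neg = np.zeros(vol.shape, dtype=bool)
        for c in neg_classes:
            neg |= _class_mask(lab, c)
        neg &= ~pos  # a voxel can never be both
        scores.append(vol.data[pos])
        labels.append(np.ones(int(pos.sum()), dtype=np.int8))
        scores.append(vol.data[neg])
        labels.append(np.zeros(int(neg.sum()), dtype=np.int8))
    y_score = np.concatenate(scores)
    y_true = np.concatenate(labels)
    if not (y_true == 1).any():
        raise ValueError(f"no positive voxels for task {task!r}")
    if not (y_true == 0).any():
        raise ValueError(f"no negative voxels for task {task!r}")
    return y_score, y_true


@dataclass
class ROCCurve:
    """Empirical ROC: descending thresholds with tied scores grouped."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    n_pos: int
    n_neg: int


def empirical_roc(scores: Sequence[float], labels: Sequence[int]) -> ROCCurve:
    """Threshold sweep over the unique scores (ties grouped)."""
    y_score = np.asarray(scores, dtype=float)
    y_true = np.asarray(labels)
    n_pos = int((y_true == 1).sum())
    n_neg = int((y_true == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    fpr, tpr, thr = _sk_roc_curve(y_true, y_score, drop_intermediate=False)
    return ROCCurve(thresholds=thr, tpr=tpr, fpr=fpr, n_pos=n_pos, n_neg=n_neg)


def auc(curve: ROCCurve) -> float:
    """Trapezoidal area under the ROC curve.

    Equals the Mann-Whitney concordance probability with ties counted
    as one half.
    """
    return float(np.trapezoid(curve.tpr, curve.fpr))


def auc_score(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Convenience: ``auc(empirical_roc(scores, labels))``."""
    return auc(empirical_roc(scores, labels))


# ----------------------------------------------------------------------
# Hanley-McNeil framework
# ----------------------------------------------------------------------

def hanley_mcneil_se(A: float, n_pos: int, n_neg: int) -> float:
    """Standard error of an empirical AUC (Hanley-McNeil closed form)."""
    if not 0.0 <= A <= 1.0:
        raise ValueError(f"AUC must be in [0, 1], got {A}")
    if n_pos < 1 or n_neg < 1:
        raise ValueError("both class counts must be >= 1")
    q1 = A / (2.0 - A)
    q2 = 2.0 * A * A / (1.0 + A)
    var = (
        A * (1.0 - A)
        + (n_pos - 1) * (q1 - A * A)
        + (n_neg - 1) * (q2 - A * A)
    ) / (n_pos * n_neg)
    return float(np.sqrt(max(var, 0.0)))


_R_TABLE_CACHE: RegularGridInterpolator | None = None


def _load_r_table() -> RegularGridInterpolator:
    global _R_TABLE_CACHE
    if _R_TABLE_CACHE is None:
        ref = resources.files("cdis") / "data" / "hanley_mcneil_r_table_synthetic.tsv"
        rows = []
        r_grid: list[float] = []
        a_grid: list[float] | None = None
        with ref.open() as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if a_grid is None:
                    a_grid = [float(x) for x in parts[1:]]
                    continue
                r_grid.append(float(parts[0]))
                rows.append([float(x) for x in parts[1:]])
        _R_TABLE_CACHE = RegularGridInterpolator(
            (np.array(r_grid), np.array(a_grid)),
            np.array(rows),
            method="linear",
            bounds_error=False,
            fill_value=None,
        )
    return _R_TABLE_CACHE


def interpolate_r_table(mean_r: float, mean_A: float) -> float:
    """AUC-estimate correlation r from (mean Pearson r, mean AUC).

    Bilinear interpolation of the packaged lookup table; inputs at or
    beyond the table boundary clamp to the boundary, with a mean Pearson
    correlation of 1 mapping to r = 1.  A mean AUC below 0.5 (an
    anti-discriminating pair) is folded to 1 - A, which leaves the
    correlation of the area estimates unchanged.
    """
    if not -1.0 <= mean_r <= 1.0:
        raise ValueError("mean_r must be in [-1, 1]")
    if not 0.0 <= mean_A <= 1.0:
        raise ValueError("mean_A must be in [0, 1]")
    if mean_A < 0.5:
        mean_A = 1.0 - mean_A
    interp = _load_r_table()
    r_lo, r_hi = interp.grid[0][0], interp.grid[0][-1]
    a_lo, a_hi = interp.grid[1][0], interp.grid[1][-1]
    if mean_r >= 1.0:
        return 1.0
    mr = float(np.clip(mean_r, r_lo, r_hi))
    ma = float(np.clip(mean_A, a_lo, a_hi))
    return float(np.clip(interp([[mr, ma]])[0], -1.0, 1.0))


def estimate_r(
    map1_per_case: Sequence[ImageVolume],
    map2_per_case: Sequence[ImageVolume],
    labels_per_case: Sequence[TissueLabelSet],
    task: str,
) -> float:
    """Correlation between the AUC estimates of two modalities.

    Because the modalities' native resolutions differ, voxel-to-voxel
    pairing is not assumed: per case, the median map value over the
    task's positive-class voxels and negative-class voxels is taken, and
    Pearson correlations across cases give r_P (positives) and r_N
    (negatives).  The lookup table is then interpolated at the average
    of (r_P, r_N) and of the two pooled AUCs.
    """
    task = _canonical_task(task)
    pos_classes, neg_classes = TASKS[task]
    if not (len(map1_per_case) == len(map2_per_case) == len(labels_per_case)):
        raise ValueError("all per-case sequences must have equal length")
    med1_p, med2_p, med1_n, med2_n = [], [], [], []
    for v1, v2, lab in zip(map1_per_case, map2_per_case, labels_per_case):
        pos = np.zeros(v1.shape, dtype=bool)
        for c in pos_classes:
            pos |= _class_mask(lab, c)
        neg = np.zeros(v1.shape, dtype=bool)
        for c in neg_classes:
            neg |= _class_mask(lab, c)
        neg &= ~pos
        if pos.any():
            med1_p.append(float(np.median(v1.data[pos])))
            med2_p.append(float(np.median(v2.data[pos])))
        if neg.any():
            med1_n.append(float(np.median(v1.data[neg])))
            med2_n.append(float(np.median(v2.data[neg])))
    if len(med1_p) < 3 or len(med1_n) < 3:
        raise ValueError("need >= 3 cases contributing each class")
    for series in (med1_p, med2_p, med1_n, med2_n):
        if np.ptp(series) == 0:
            raise ValueError("zero variance in a per-case median series")
    r_p = float(sps.pearsonr(med1_p, med2_p).statistic)
    r_n = float(sps.pearsonr(med1_n, med2_n).statistic)
    s1, y = pool_voxels(map1_per_case, labels_per_case, task)
    s2, _ = pool_voxels(map2_per_case, labels_per_case, task)
    a1 = auc_score(s1, y)
    a2 = auc_score(s2, y)
    return interpolate_r_table((r_p + r_n) / 2.0, (a1 + a2) / 2.0)


@dataclass
class AUCComparison:
    """Paired-modality correlated-AUC test record."""

    A1: float
    A2: float
    SE1: float
    SE2: float
    r: float
    z: float
    p: float


def compare_auc(A1: float, SE1: float, A2: float, SE2: float, r: float) -> AUCComparison:
    """Critical ratio z for the difference of two correlated AUCs and its
    two-sided normal p-value."""
    for a in (A1, A2):
        if not 0.0 <= a <= 1.0:
            raise ValueError("AUCs must be in [0, 1]")
    if SE1 < 0 or SE2 < 0:
        raise ValueError("standard errors must be >= 0")
    if not -1.0 <= r <= 1.0:
        raise ValueError("r must be in [-1, 1]")
    denom_sq = SE1 * SE1 + SE2 * SE2 - 2.0 * r * SE1 * SE2
    if A1 == A2:
        return AUCComparison(A1, A2, SE1, SE2, r, 0.0, 1.0)
    if denom_sq <= 0:
        raise ValueError(
            "non-positive variance of the AUC difference; the comparison "
            "is degenerate (r ~ 1 with equal standard errors)"
        )
    z = (A1 - A2) / float(np.sqrt(denom_sq))
    p = float(2.0 * sps.norm.sf(abs(z)))
    return AUCComparison(A1, A2, SE1, SE2, r, float(z), p)


# ----------------------------------------------------------------------
# histograms
# ----------------------------------------------------------------------

@dataclass
class TissueHistograms:
    """Per-tissue-class normalized histograms on common bin edges."""

    bin_edges: np.ndarray
    frequencies: dict[str, np.ndarray]  # class -> normalized counts


def tissue_histograms(
    maps_per_case: Sequence[ImageVolume],
    labels_per_case: Sequence[TissueLabelSet],
    bins: int = 64,
) -> TissueHistograms:
    """Pooled voxel-value histograms for healthy / insPCa / csPCa tissue.

    Bin edges are shared across classes (spanning the pooled gland-voxel
    range); each class's frequencies are normalized to sum 1.  Empty
    classes are omitted with a warning.
    """
    pooled: dict[str, list[np.ndarray]] = {"healthy": [], "insPCa": [], "csPCa": []}
    for vol, lab in zip(maps_per_case, labels_per_case):
        for cls in pooled:
            m = _class_mask(lab, cls)
            if m.any():
                pooled[cls].append(vol.data[m])
    values = {c: np.concatenate(v) for c, v in pooled.items() if v}
    if not values:
        raise ValueError("no in-gland voxels in any class")
    allv = np.concatenate(list(values.values()))
    lo, hi = float(allv.min()), float(allv.max())
    if lo == hi:
        hi = lo + 1.0
    edges = np.linspace(lo, hi, bins + 1)
    freqs = {}
    for cls in ("healthy", "insPCa", "csPCa"):
        if cls not in values:
            warnings.warn(f"class {cls!r} has no voxels; omitted", stacklevel=2)
            continue
        counts, _ = np.histogram(values[cls], bins=edges)
        freqs[cls] = counts / counts.sum()
    return TissueHistograms(bin_edges=edges, frequencies=freqs)
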