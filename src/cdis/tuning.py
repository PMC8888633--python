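"""Contribution-coefficient tuning (the tuned map variant).

The per-b exponents rho control how much each b-value contributes to the
mixed map.  Tuning maximizes the pooled voxel-level delineation AUC for
a chosen task over rho with a Nelder-Mead simplex search started at the
baseline rho = 1.

In log space the mixed score is linear in rho, so scaling all
coefficients by a positive constant rescales the log-map without
changing voxel ranks — the AUC objective has an exact scale-invariance
ridge.  Nelder-Mead handles such flat ridges poorly, so by default the
first coefficient is frozen at 1 and only the remaining ones are
searched; the option can be disabled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import convolve
from scipy.optimize import minimize

from .diffusion import DWISeries, default_signal_floor
from .mixing import MixingConfig, make_kernel
from .stats import TASKS, _canonical_task, _class_mask, auc_score
from .volumes import TissueLabelSet

__all__ = ["TuningOptions", "TuningResult", "tune_coefficients"]


@dataclass(frozen=True)
class TuningOptions:
    """Nelder-Mead settings; all deterministic."""

    freeze_first: bool = True      # pin rho[0] = 1 to remove the scale ridge
    simplex_step: float = 0.25     # per-vertex perturbation of the start
    xatol: float = 1e-4
    fatol: float = 1e-4
    max_evals_per_dim: int = 500


@dataclass
class TuningResult:
    rho_opt: tuple[float, ...]
    auc_baseline: float
    auc_opt: float
    n_evaluations: int
    converged: bool
    task: str

    def to_dict(self) -> dict:
        return {
            "rho_opt": list(self.rho_opt),
            "auc_baseline": self.auc_baseline,
            "auc_opt": self.auc_opt,
            "n_evaluations": self.n_evaluations,
            "converged": self.converged,
            "task": self.task,
        }


class _PooledObjective:
    """1 - pooled AUC as a function of rho, with per-case precomputation.

    For each case the clamped log-signal stack, kernel, boundary weight
    normalization, and task voxel masks are computed once; an objective
    evaluation is then one tensordot, one exponential, one convolution
    and a rank statistic per case.  Per-case median-gland calibration is
    applied before pooling, matching how the maps are pooled in the
    statistics module (calibration changes nothing within a case but
    does change cross-case pooling).
    """

    def __init__(
        self,
        series_per_case: Sequence[DWISeries],
        labels_per_case: Sequence[TissueLabelSet],
        config: MixingConfig,
        task: str,
    ):
        pos_classes, neg_classes = TASKS[task]
        self.cases = []
        self.labels = []
        any_pos = any_neg = False
        for series, lab in zip(series_per_case, labels_per_case):
            floor = default_signal_floor(series)
            stack = series.signal_stack(config.b_set)
            log_s = np.log(np.maximum(stack, floor))
            kernel = make_kernel(config, series.grid.spacing)
            wsum = convolve(
                np.ones(stack.shape[1:]), kernel, mode="constant", cval=0.0
            )
            gland = lab.gland_mask
            pos = np.zeros(gland.shape, dtype=bool)
            for c in pos_classes:
                pos |= _class_mask(lab, c)
            neg = np.zeros(gland.shape, dtype=bool)
            for c in neg_classes:
                neg |= _class_mask(lab, c)
            neg &= ~pos
            any_pos |= bool(pos.any())
            any_neg |= bool(neg.any())
            self.cases.append((log_s, kernel, wsum, gland, pos, neg))
            self.labels.append(
                np.concatenate(
                    [np.ones(int(pos.sum()), dtype=np.int8),
                     np.zeros(int(neg.sum()), dtype=np.int8)]
                )
            )
        if not (any_pos and any_neg):
            raise ValueError(f"task {task!r} has an empty class across all cases")
        self.y = np.concatenate(self.labels)
        self.n_evaluations = 0

    def pooled_auc(self, rho: np.ndarray) -> float:
        scores = []
        for log_s, kernel, wsum, gland, pos, neg in self.cases:
            product = np.exp(np.tensordot(rho, log_s, axes=(0, 0)))
            mixed = convolve(product, kernel, mode="constant", cval=0.0) / wsum
            z = float(np.median(mixed[gland]))
            mixed = mixed / z if z > 0 else mixed
            scores.append(mixed[pos])
            scores.append(mixed[neg])
        return auc_score(np.concatenate(scores), self.y)

    def __call__(self, rho: np.ndarray) -> float:
        self.n_evaluations += 1
        return 1.0 - self.pooled_auc(rho)


def tune_coefficients(
    series_per_case: Sequence[DWISeries],
    labels_per_case: Sequence[TissueLabelSet],
    config: MixingConfig,
    task: str = "cspca-vs-healthy",
    options: TuningOptions = TuningOptions(),
) -> TuningResult:
    """Maximize the pooled delineation AUC over rho with Nelder-Mead.

    The search starts at rho = 1 (which is always evaluated, so the
    returned optimum can never fall below the baseline) and returns the
    best coefficient vector *evaluated*, not merely the final simplex
    centroid.  Deterministic given inputs and options.
    """
    task = _canonical_task(task)
    if len(series_per_case) < 1:
        raise ValueError("at least one case is required")
    n_b = len(config.b_set)
    obj = _PooledObjective(series_per_case, labels_per_case, config, task)

    best: dict = {"f": np.inf, "rho": None}

    def expand(free: np.ndarray) -> np.ndarray:
        if options.freeze_first:
            return np.concatenate([[1.0], free])
        return np.asarray(free, dtype=float)

    def f(free: np.ndarray) -> float:
        rho = expand(free)
        val = obj(rho)
        if val < best["f"]:
            best["f"] = val
            best["rho"] = rho.copy()
        return val

    d = n_b - 1 if options.freeze_first else n_b
    x0 = np.ones(d)
    baseline = f(x0)  # rho = 1 is always the first evaluation
    if d == 0:
        return TuningResult(
            rho_opt=tuple(expand(x0)),
            auc_baseline=1.0 - baseline,
            auc_opt=1.0 - baseline,
            n_evaluations=obj.n_evaluations,
            converged=True,
            task=task,
        )
    simplex = np.tile(x0, (d + 1, 1))
    for i in range(d):
        simplex[i + 1, i] += options.simplex_step
    res = minimize(
        f,
        x0,
        method="Nelder-Mead",
        options={
            "initial_simplex": simplex,
            "xatol": options.xatol,
            "fatol": options.fatol,
            "maxfev": options.max_evals_per_dim * d,
        },
    )
    return TuningResult(
        rho_opt=tuple(best["rho"]),
        auc_baseline=1.0 - baseline,
        auc_opt=1.0 - best["f"],
        n_evaluations=obj.n_evaluations,
        converged=bool(res.success),
        task=task,
    )
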