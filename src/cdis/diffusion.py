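"""Diffusion physics and estimation.

The mono-exponential signal model ``S(b) = S(0) * exp(-b * A)`` links the
diffusion-weighted signal at weighting factor ``b`` (s/mm^2) to the
apparent diffusion coefficient ``A`` (mm^2/s).  This module provides:

* the b-value of a pulsed-gradient spin-echo sequence from its gradient
  pulse parameters,
* the per-voxel least-squares ADC estimate from >= 2 native acquisitions
  (ordinary least squares of log-signal on b),
* synthesis of signal volumes at un-acquired b-values by extrapolating a
  reference acquisition along the fitted decay.

Synthetic high-b volumes extend a routine clinical 3-point DWI protocol
(b = 50, 400, 800 s/mm^2) up to b-values (1000..7000 s/mm^2) that would
be slow and noisy to acquire natively; they feed the signal-mixing stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .volumes import ImageVolume

__all__ = [
    "GradientPulseSpec",
    "ADCMap",
    "DWISeries",
    "compute_bvalue",
    "fit_adc",
    "synthesize_signal",
    "extend_series",
    "PROTON_GYROMAGNETIC_RATIO",
]

#: Proton gyromagnetic ratio, rad s^-1 T^-1.
PROTON_GYROMAGNETIC_RATIO = 2.6752218744e8


@dataclass(frozen=True)
class GradientPulseSpec:
    """Pulsed-gradient pair: strength G (T/m), duration delta (s),
    separation Delta (s), gyromagnetic ratio gamma (rad s^-1 T^-1)."""

    G: float
    delta: float
    Delta: float
    gamma: float = PROTON_GYROMAGNETIC_RATIO

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.G < 0 or self.delta < 0:
            raise ValueError("G and delta must be non-negative")
        if self.Delta < self.delta / 3:
            raise ValueError(
                "Delta < delta/3 gives a negative effective diffusion time"
            )


def compute_bvalue(pulse: GradientPulseSpec) -> float:
    """b-value in s/mm^2 for a pulsed-gradient pair.

    b = gamma^2 G^2 delta^2 (Delta - delta/3), evaluated in SI (s/m^2)
    and converted to the conventional s/mm^2 (1 s/m^2 = 1e-6 s/mm^2).
    """
    b_si = (pulse.gamma ** 2) * (pulse.G ** 2) * (pulse.delta ** 2) * (
        pulse.Delta - pulse.delta / 3.0
    )
    return b_si * 1e-6


@dataclass
class ADCMap:
    """Apparent diffusion coefficient map (mm^2/s) plus a record of which
    voxels required signal clamping before the log transform."""

    volume: ImageVolume
    fit_mask: ImageVolume

    def export_clinical_units(self) -> ImageVolume:
        """ADC rescaled to the clinical convention of 1e-6 mm^2/s."""
        return self.volume.with_data(self.volume.data * 1e6)


@dataclass
class DWISeries:
    """Co-registered DWI volumes indexed by b-value.

    Entries are ``(b, volume, provenance)`` with provenance ``"native"``
    or ``"synthetic"``; b-values strictly increasing and all volumes on
    one shared grid.
    """

    acquisitions: list[tuple[float, ImageVolume, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        bs = self.b_values
        if any(b < 0 for b in bs):
            raise ValueError("b-values must be >= 0")
        if any(b2 <= b1 for b1, b2 in zip(bs, bs[1:])):
            raise ValueError(f"b-values must be strictly increasing, got {bs}")
        grid = self.acquisitions[0][1] if self.acquisitions else None
        for _, vol, prov in self.acquisitions:
            if prov not in ("native", "synthetic"):
                raise ValueError(f"unknown provenance {prov!r}")
            if grid is not None and not vol.same_grid(grid):
                raise ValueError("all volumes in a series must share one grid")

    @classmethod
    def from_native(cls, pairs: Sequence[tuple[float, ImageVolume]]) -> "DWISeries":
        ordered = sorted(((float(b), v) for b, v in pairs), key=lambda t: t[0])
        return cls([(b, v, "native") for b, v in ordered])

    # ------------------------------------------------------------------
    @property
    def b_values(self) -> list[float]:
        return [b for b, _, _ in self.acquisitions]

    @property
    def native_b_values(self) -> list[float]:
        return [b for b, _, p in self.acquisitions if p == "native"]

    @property
    def grid(self) -> ImageVolume:
        return self.acquisitions[0][1]

    def volume(self, b: float) -> ImageVolume:
        for bi, vol, _ in self.acquisitions:
            if bi == b:
                return vol
        raise KeyError(f"no acquisition at b={b}")

    def is_native(self, b: float) -> bool:
        for bi, _, prov in self.acquisitions:
            if bi == b:
                return prov == "native"
        raise KeyError(f"no acquisition at b={b}")

    def signal_stack(self, b_values: Sequence[float] | None = None) -> np.ndarray:
        """Array of shape (n_b, nx, ny, nz) in the given b order."""
        bs = list(b_values) if b_values is not None else self.b_values
        return np.stack([self.volume(b).data for b in bs], axis=0)


# ----------------------------------------------------------------------
# estimation / synthesis
# ----------------------------------------------------------------------

def _clamped_log(signals: np.ndarray, floor: float) -> tuple[np.ndarray, np.ndarray]:
    clamped = signals < floor
    return np.log(np.maximum(signals, floor)), clamped


def default_signal_floor(series: DWISeries) -> float:
    """1e-6 of the native-signal maximum: small enough not to bias fits,
    large enough to keep the log transform finite.

    Only native acquisitions define the scale — synthetic extrapolations
    can reach arbitrarily large values at voxels where noise drives the
    fitted ADC negative, and must not inflate the floor.
    """
    native = [vol for _, vol, p in series.acquisitions if p == "native"]
    if not native:
        native = [vol for _, vol, _ in series.acquisitions]
    peak = max(float(vol.data.max()) for vol in native)
    return max(peak, 1.0) * 1e-6


def fit_adc(series: DWISeries, floor: float | None = None) -> ADCMap:
    """Per-voxel ordinary least-squares ADC from the native acquisitions.

    The estimate is the negated slope of log-signal against b::

        A(x) = - sum_i (b_i - b_mean) (log S_i(x) - logS_mean(x))
               / sum_i (b_i - b_mean)^2

    Signals below ``floor`` are clamped to ``floor`` before the log and
    the affected voxels recorded in ``fit_mask``.  Only native
    acquisitions enter the fit, so appending synthetic volumes never
    changes the estimate.
    """
    native = [(b, v) for b, v, p in series.acquisitions if p == "native"]
    if len(native) < 2:
        raise ValueError("ADC fitting requires at least 2 native acquisitions")
    if floor is None:
        floor = default_signal_floor(series)
    if floor <= 0:
        raise ValueError("floor must be positive")
    b = np.array([bv for bv, _ in native])
    stack = np.stack([v.data for _, v in native], axis=0)
    log_s, clamped = _clamped_log(stack, floor)
    db = b - b.mean()
    dlog = log_s - log_s.mean(axis=0)
    slope = np.tensordot(db, dlog, axes=(0, 0)) / (db @ db)
    grid = series.grid
    return ADCMap(
        volume=grid.with_data(-slope),
        fit_mask=grid.with_data(clamped.any(axis=0).astype(np.uint8)),
    )


def synthesize_signal(
    series: DWISeries,
    b_ref: float,
    adc: ADCMap,
    b_target: float,
) -> ImageVolume:
    """Extrapolate the reference acquisition to ``b_target`` along the
    fitted mono-exponential decay:  S_hat(x) = S_ref(x) exp(-(b - b_ref) A(x)).
    """
    if b_target < 0:
        raise ValueError("b_target must be >= 0")
    try:
        native = series.is_native(b_ref)
    except KeyError:
        native = False
    if not native:
        raise ValueError(f"b_ref={b_ref} is not a native acquisition")
    ref = series.volume(b_ref)
    if b_target == b_ref:
        return ref.with_data(ref.data.copy())
    return ref.with_data(ref.data * np.exp(-(b_target - b_ref) * adc.volume.data))


def extend_series(
    series: DWISeries,
    targets: Sequence[float],
    b_ref: float | None = None,
    floor: float | None = None,
    clamp_adc_nonnegative: bool = False,
) -> DWISeries:
    """Append synthetic acquisitions at each target b-value.

    ``b_ref`` defaults to the lowest native b-value — the highest-SNR
    image, which anchors the extrapolation.  Set
    ``clamp_adc_nonnegative`` to floor negative ADC estimates at 0
    (noise can drive the OLS slope negative; by default the raw
    estimator is preserved).
    """
    targets = sorted(float(t) for t in targets)
    native_bs = set(series.b_values)
    for t in targets:
        if t in native_bs:
            raise ValueError(f"target b={t} collides with an existing acquisition")
    if not targets:
        return DWISeries(list(series.acquisitions))
    if b_ref is None:
        b_ref = min(series.native_b_values)
    adc = fit_adc(series, floor=floor)
    if clamp_adc_nonnegative:
        adc = ADCMap(
            volume=adc.volume.with_data(np.maximum(adc.volume.data, 0.0)),
            fit_mask=adc.fit_mask,
        )
    entries = list(series.acquisitions)
    for t in targets:
        entries.append((t, synthesize_signal(series, b_ref, adc, t), "synthetic"))
    entries.sort(key=lambda e: e[0])
    return DWISeries(entries)
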