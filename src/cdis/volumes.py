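"""Image-volume containers and spatial harmonization.

All downstream computation (ADC fitting, signal synthesis, mixing,
voxel-level ROC pooling) happens on a single common voxel grid, so this
module owns the two jobs that make that possible: reading volumes from
DICOM series / NIfTI with correct geometry, and resampling everything
onto a reference grid.  World coordinates follow the DICOM patient
convention (LPS); NIfTI affines are converted on load.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import SimpleITK as sitk

logger = logging.getLogger(__name__)

__all__ = [
    "ImageVolume",
    "TissueLabelSet",
    "GeometryError",
    "load_volume",
    "save_volume",
    "load_dwi_series",
    "resample_to_grid",
    "load_label_set",
]

#: Lesion masks are accepted if at least this fraction of their voxels
#: fall inside the gland after resampling; chosen to tolerate edge
#: effects of nearest-neighbour resampling.
LESION_INSIDE_GLAND_MIN_FRACTION = 0.95

_CANONICAL_ORIENTATION = "LPS"


class GeometryError(ValueError):
    """Raised when volume geometry is invalid or irreconcilable."""


@dataclass
class ImageVolume:
    """A 3-D scalar grid with physical geometry.

    Attributes
    ----------
    data:
        Array indexed ``[x, y, z]`` (fastest-varying axis first, matching
        the order of ``spacing``).  Arbitrary physical units.
    spacing:
        Voxel spacing ``(dx, dy, dz)`` in mm; all components positive.
    origin:
        World coordinates (mm, LPS) of the center of voxel ``(0, 0, 0)``.
    direction:
        3x3 matrix whose *columns* are the direction cosines of the
        image axes; orthonormal within 1e-6.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3-D data, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacing must be positive, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)
        self.direction = np.asarray(self.direction, dtype=float).reshape(3, 3)
        if not np.allclose(self.direction @ self.direction.T, np.eye(3), atol=1e-6):
            raise GeometryError("direction matrix is not orthonormal within 1e-6")
        if np.issubdtype(self.data.dtype, np.floating) and np.isnan(self.data).any():
            n = int(np.isnan(self.data).sum())
            logger.warning("mapping %d NaN voxel(s) to 0", n)
            self.data = np.nan_to_num(self.data, nan=0.0)

    # ------------------------------------------------------------------
    # geometry helpers
    # ------------------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> world (mm, LPS) map, 0-based indices."""
        aff = np.eye(4)
        aff[:3, :3] = self.direction @ np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff

    def same_grid(self, other: "ImageVolume", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
            and np.allclose(self.direction, other.direction, atol=tol)
        )

    def with_data(self, data: np.ndarray) -> "ImageVolume":
        """New volume sharing this geometry with different voxel values."""
        if data.shape != self.data.shape:
            raise ValueError("data shape must match the grid")
        return ImageVolume(data, self.spacing, self.origin, self.direction.copy())

    # ------------------------------------------------------------------
    # SimpleITK bridge (array order [x,y,z] <-> sitk order [z,y,x])
    # ------------------------------------------------------------------
    def to_sitk(self) -> sitk.Image:
        img = sitk.GetImageFromArray(np.ascontiguousarray(self.data.transpose(2, 1, 0)))
        img.SetSpacing(self.spacing)
        img.SetOrigin(self.origin)
        img.SetDirection(tuple(self.direction.flatten()))
        return img

    @classmethod
    def from_sitk(cls, img: sitk.Image) -> "ImageVolume":
        data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
        return cls(
            data,
            tuple(img.GetSpacing()),
            tuple(img.GetOrigin()),
            np.array(img.GetDirection()).reshape(3, 3),
        )


# ----------------------------------------------------------------------
# I/O
# ----------------------------------------------------------------------

def _read_dicom_series(path: Path) -> sitk.Image:
    reader = sitk.ImageSeriesReader()
    files = reader.GetGDCMSeriesFileNames(str(path))
    if not files:
        raise IOError(f"no DICOM series found in {path}")
    reader.SetFileNames(files)
    try:
        return reader.Execute()
    except RuntimeError as exc:  # pragma: no cover - corrupt input path
        raise IOError(f"failed to read DICOM series in {path}: {exc}") from exc


def load_volume(path: str | Path, format_hint: str | None = None) -> ImageVolume:
    """Load a volume from a NIfTI file or a DICOM series directory.

    The volume is reoriented to the canonical LPS axis order; world
    coordinates of every voxel are preserved by the reorientation.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file or directory: {path}")
    fmt = format_hint
    if fmt is None:
        fmt = "dicom" if path.is_dir() else "nifti"
    if fmt == "dicom":
        img = _read_dicom_series(path)
    elif fmt == "nifti":
        try:
            img = sitk.ReadImage(str(path))
        except RuntimeError as exc:
            raise IOError(f"failed to read {path}: {exc}") from exc
    else:
        raise ValueError(f"unknown format hint {fmt!r}")
    if img.GetDimension() == 4:  # single-frame 4-D NIfTI
        img = img[:, :, :, 0]
    img = sitk.DICOMOrient(img, _CANONICAL_ORIENTATION)
    img = sitk.Cast(img, sitk.sitkFloat64)
    return ImageVolume.from_sitk(img)


def save_volume(vol: ImageVolume, path: str | Path) -> None:
    """Write a volume as NIfTI (.nii / .nii.gz)."""
    sitk.WriteImage(vol.to_sitk(), str(Path(path)))


def resample_to_grid(
    vol: ImageVolume,
    ref: ImageVolume,
    interpolation: str = "linear",
) -> ImageVolume:
    """Resample ``vol`` onto the grid of ``ref``.

    ``linear`` for signals, ``nearest`` for masks/labels; regions of the
    reference grid outside the source extent are filled with 0.
    """
    if interpolation == "linear":
        interp = sitk.sitkLinear
    elif interpolation == "nearest":
        interp = sitk.sitkNearestNeighbor
    else:
        raise ValueError(f"unknown interpolation {interpolation!r}")
    if vol.same_grid(ref):
        return ref.with_data(vol.data.copy())
    out = sitk.Resample(
        vol.to_sitk(),
        ref.to_sitk(),
        sitk.Transform(),
        interp,
        0.0,
        sitk.sitkFloat64,
    )
    return ImageVolume.from_sitk(out)


def load_dwi_series(
    paths: Sequence[str | Path],
    b_values: Sequence[float],
):
    """Load multi-b-value DWI volumes onto one grid, sorted by b-value.

    All volumes are resampled (linearly) to the grid of the *first* path,
    which by convention is the lowest-b native acquisition.  Returns a
    :class:`~cdis.diffusion.DWISeries` with every entry flagged native.
    """
    from .diffusion import DWISeries  # deferred: avoids import cycle

    if len(paths) != len(b_values):
        raise ValueError("paths and b_values must have equal length")
    if len(paths) < 2:
        raise ValueError("at least 2 acquisitions are required")
    bs = [float(b) for b in b_values]
    if len(set(bs)) != len(bs):
        raise ValueError(f"duplicate b-values: {bs}")
    if any(b < 0 for b in bs):
        raise ValueError("b-values must be >= 0")
    vols = [load_volume(p) for p in paths]
    ref = vols[0]
    for v in vols[1:]:
        _check_overlap(v, ref)
    vols = [resample_to_grid(v, ref, "linear") for v in vols]
    order = np.argsort(bs, kind="stable")
    return DWISeries.from_native(
        [(bs[i], vols[i]) for i in order],
    )


def _check_overlap(vol: ImageVolume, ref: ImageVolume) -> None:
    """Reject volumes whose fields of view are disjoint from the reference."""
    corners = np.array(
        [[i, j, k] for i in (0, vol.shape[0] - 1)
         for j in (0, vol.shape[1] - 1)
         for k in (0, vol.shape[2] - 1)],
        dtype=float,
    )
    world = (vol.affine @ np.c_[corners, np.ones(len(corners))].T)[:3].T
    ref_corners = np.array(
        [[i, j, k] for i in (0, ref.shape[0] - 1)
         for j in (0, ref.shape[1] - 1)
         for k in (0, ref.shape[2] - 1)],
        dtype=float,
    )
    ref_world = (ref.affine @ np.c_[ref_corners, np.ones(len(ref_corners))].T)[:3].T
    lo1, hi1 = world.min(0), world.max(0)
    lo2, hi2 = ref_world.min(0), ref_world.max(0)
    if np.any(hi1 < lo2) or np.any(hi2 < lo1):
        raise GeometryError("fields of view are disjoint; grids irreconcilable")


# ----------------------------------------------------------------------
# Tissue labels
# ----------------------------------------------------------------------

LESION_CLASSES = ("csPCa", "insPCa")

#: Zone label codes used throughout: 0 background, 1 PZ, 2 TZ, 3 AS.
ZONE_CODES = {"background": 0, "PZ": 1, "TZ": 2, "AS": 3}


@dataclass
class TissueLabelSet:
    """Gland / zone / lesion masks defining the voxel populations.

    ``healthy`` is derived as gland minus the union of all lesions, so it
    is disjoint from every lesion by construction.  Clinical significance
    follows the Gleason-score convention: csPCa is Gleason >= 7, insPCa
    is Gleason < 7.
    """

    gland: ImageVolume
    zones: ImageVolume
    lesions: list[tuple[ImageVolume, str]]
    healthy: ImageVolume = field(init=False)

    def __post_init__(self) -> None:
        gland = self.gland.data > 0
        lesion_union = np.zeros_like(gland)
        for mask, cls in self.lesions:
            if cls not in LESION_CLASSES:
                raise ValueError(
                    f"lesion class must be one of {LESION_CLASSES}, got {cls!r}"
                )
            if not mask.same_grid(self.gland):
                raise GeometryError("lesion mask is not on the gland grid")
            m = mask.data > 0
            n_in = int((m & gland).sum())
            n_tot = int(m.sum())
            if n_tot == 0:
                raise ValueError("empty lesion mask")
            if n_in == 0:
                raise ValueError("lesion mask is entirely outside the gland")
            frac = n_in / n_tot
            if frac < LESION_INSIDE_GLAND_MIN_FRACTION:
                warnings.warn(
                    f"only {frac:.1%} of lesion voxels fall inside the gland",
                    stacklevel=2,
                )
            lesion_union |= m
        self.healthy = self.gland.with_data((gland & ~lesion_union).astype(np.uint8))

    # convenience boolean masks --------------------------------------
    @property
    def gland_mask(self) -> np.ndarray:
        return self.gland.data > 0

    @property
    def healthy_mask(self) -> np.ndarray:
        return self.healthy.data > 0

    def class_mask(self, cls: str) -> np.ndarray:
        """Union of lesion masks of one class, clipped to the gland."""
        out = np.zeros(self.gland.shape, dtype=bool)
        for mask, c in self.lesions:
            if c == cls:
                out |= mask.data > 0
        return out & self.gland_mask

    @property
    def cancer_mask(self) -> np.ndarray:
        return self.class_mask("csPCa") | self.class_mask("insPCa")


def load_label_set(
    gland_path: str | Path,
    zones_path: str | Path | None,
    lesion_manifest: str | Path | dict,
    ref: ImageVolume,
) -> TissueLabelSet:
    """Load masks and resample them (nearest-neighbour) to ``ref``.

    ``lesion_manifest`` maps lesion NIfTI paths to class labels, either as
    a dict or a path to a JSON file ``{"lesion1.nii.gz": "csPCa"}``;
    relative paths resolve against the manifest location.
    """
    gland = resample_to_grid(load_volume(gland_path), ref, "nearest")
    if zones_path is not None:
        zones = resample_to_grid(load_volume(zones_path), ref, "nearest")
    else:
        zones = ref.with_data(np.zeros(ref.shape, dtype=np.uint8))
    if isinstance(lesion_manifest, (str, Path)):
        manifest_path = Path(lesion_manifest)
        with open(manifest_path) as fh:
            mapping: dict = json.load(fh)
        base = manifest_path.parent
    else:
        mapping = dict(lesion_manifest)
        base = Path(".")
    lesions = []
    for rel, cls in mapping.items():
        p = Path(rel)
        if not p.is_absolute():
            p = base / p
        lesions.append((resample_to_grid(load_volume(p), ref, "nearest"), cls))
    return TissueLabelSet(gland=gland, zones=zones, lesions=lesions)
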