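"""Digital multi-b-value prostate DWI phantoms.

Each phantom emulates the on-disk structure of a clinical prostate mpMRI
case: native DWI volumes at b = {50, 400, 800} s/mm^2 on a ~2 mm
in-plane / 3 mm slice grid, a whole-gland mask, a peripheral-zone /
transition-zone / anterior-stroma zone partition, and spherical lesions
labelled clinically significant (csPCa) or insignificant (insPCa).

Tissue classes follow the restricted-diffusion picture of the prostate:
glandular healthy peripheral zone has a high baseline signal that decays
quickly with b (high ADC); stromal tissue (TZ, AS) has a lower baseline
signal, with the anterior stroma additionally showing an ADC in the
cancer range — the tissue that makes ADC maps prone to false positives;
cancer combines an elevated baseline signal with slow decay (low ADC),
the combination that makes it hyperintense across the whole b-value
range.  Default ADCs order csPCa < insPCa < TZ < healthy PZ.

Noise is Rician — the modulus of the noiseless signal plus circularly
symmetric complex Gaussian noise — which is the standard model for MRI
magnitude images.  Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .diffusion import DWISeries
from .volumes import ImageVolume, TissueLabelSet, ZONE_CODES

__all__ = ["TissueParams", "LesionSpec", "PhantomSpec", "generate_phantom",
           "default_study_spec"]

#: Cohort-level fraction of lesions that are clinically significant
#: (76 of 299 tumors = 25.4%), used when sampling lesion classes.
CSPCA_LESION_FRACTION = 76 / 299


@dataclass(frozen=True)
class TissueParams:
    """Mono-exponential parameters: baseline signal S0 (a.u.) and
    apparent diffusion coefficient (mm^2/s)."""

    S0: float
    adc: float

    def __post_init__(self) -> None:
        if self.S0 < 0:
            raise ValueError("S0 must be >= 0")
        if not 0.0 <= self.adc <= 4e-3:
            raise ValueError("adc must lie in [0, 4e-3] mm^2/s")


DEFAULT_TISSUES: dict[str, TissueParams] = {
    "background": TissueParams(S0=120.0, adc=3.0e-3),
    "PZ": TissueParams(S0=1000.0, adc=1.8e-3),
    "TZ": TissueParams(S0=750.0, adc=1.3e-3),
    # fibromuscular stroma: low baseline signal at every b, but an ADC in
    # the cancer range — the classic ADC false-positive tissue that the
    # correlated-diffusion product resolves (low S0 keeps its product low)
    "AS": TissueParams(S0=420.0, adc=0.8e-3),
    "csPCa": TissueParams(S0=1250.0, adc=0.7e-3),
    "insPCa": TissueParams(S0=1000.0, adc=1.0e-3),
}


@dataclass(frozen=True)
class LesionSpec:
    center_mm: tuple[float, float, float]  # offset from gland center
    radius_mm: float
    cls: str  # csPCa | insPCa
    tissue: TissueParams

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("lesion radius must be positive")
        if self.cls not in ("csPCa", "insPCa"):
            raise ValueError(f"unknown lesion class {self.cls!r}")


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, tissue parameters, acquisition and noise settings."""

    shape: tuple[int, int, int] = (96, 96, 12)
    spacing: tuple[float, float, float] = (2.0, 2.0, 3.0)
    gland_semiaxes_mm: tuple[float, float, float] = (24.0, 20.0, 16.0)
    tz_semiaxes_mm: tuple[float, float, float] = (14.0, 11.0, 10.0)
    as_depth_mm: float = 6.0  # anterior slab thickness carved out as AS
    lesions: tuple[LesionSpec, ...] = ()
    tissues: dict[str, TissueParams] = field(
        default_factory=lambda: dict(DEFAULT_TISSUES)
    )
    noise_sigma: float = 25.0
    native_b_values: tuple[float, ...] = (50.0, 400.0, 800.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if len(self.native_b_values) < 2:
            raise ValueError("at least 2 native b-values are required")


def _voxel_coords_mm(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Voxel-center coordinates (mm) relative to the grid center."""
    axes = [
        (np.arange(n) - (n - 1) / 2.0) * d
        for n, d in zip(spec.shape, spec.spacing)
    ]
    return np.meshgrid(*axes, indexing="ij")


def _ellipsoid(coords, semiaxes, center=(0.0, 0.0, 0.0)) -> np.ndarray:
    q = sum(
        ((c - c0) / a) ** 2 for c, c0, a in zip(coords, center, semiaxes)
    )
    return q <= 1.0


def generate_phantom(
    spec: PhantomSpec,
) -> tuple[DWISeries, TissueLabelSet, dict[str, ImageVolume]]:
    """Build one phantom case.

    Returns the native DWI series, the tissue label set, and ground-truth
    maps: ``"S0"`` and ``"adc"`` (the noiseless mono-exponential
    parameters per voxel) plus a noiseless ``"t2w"``-like anatomical
    volume for overlay testing.
    """
    coords = _voxel_coords_mm(spec)
    gland = _ellipsoid(coords, spec.gland_semiaxes_mm)
    tz = _ellipsoid(coords, spec.tz_semiaxes_mm) & gland
    # anterior slab of the gland outside the TZ, mimicking fibromuscular stroma
    y = coords[1]
    anterior_edge = -spec.gland_semiaxes_mm[1]
    as_mask = gland & ~tz & (y <= anterior_edge + spec.as_depth_mm)
    pz = gland & ~tz & ~as_mask

    zone_codes = np.zeros(spec.shape, dtype=np.uint8)
    zone_codes[pz] = ZONE_CODES["PZ"]
    zone_codes[tz] = ZONE_CODES["TZ"]
    zone_codes[as_mask] = ZONE_CODES["AS"]

    s0 = np.full(spec.shape, spec.tissues["background"].S0)
    adc = np.full(spec.shape, spec.tissues["background"].adc)
    for name, mask in (("PZ", pz), ("TZ", tz), ("AS", as_mask)):
        s0[mask] = spec.tissues[name].S0
        adc[mask] = spec.tissues[name].adc

    lesion_masks: list[tuple[np.ndarray, str]] = []
    for les in spec.lesions:
        if not _point_in_ellipsoid(les.center_mm, spec.gland_semiaxes_mm):
            raise ValueError(f"lesion at {les.center_mm} lies outside the gland")
        sphere = _ellipsoid(coords, (les.radius_mm,) * 3, les.center_mm) & gland
        s0[sphere] = les.tissue.S0
        adc[sphere] = les.tissue.adc
        lesion_masks.append((sphere, les.cls))

    spacing = spec.spacing
    origin = tuple(-(n - 1) / 2.0 * d for n, d in zip(spec.shape, spacing))

    def vol(arr: np.ndarray) -> ImageVolume:
        return ImageVolume(np.asarray(arr, dtype=float), spacing, origin)

    rng = np.random.default_rng(spec.seed)
    acquisitions = []
    for b in spec.native_b_values:
        clean = s0 * np.exp(-b * adc)
        if spec.noise_sigma > 0:
            n_re = rng.normal(0.0, spec.noise_sigma, spec.shape)
            n_im = rng.normal(0.0, spec.noise_sigma, spec.shape)
            noisy = np.sqrt((clean + n_re) ** 2 + n_im ** 2)
        else:
            noisy = clean
        acquisitions.append((float(b), vol(noisy)))
    series = DWISeries.from_native(acquisitions)

    labels = TissueLabelSet(
        gland=vol(gland.astype(np.uint8)),
        zones=vol(zone_codes),
        lesions=[(vol(m.astype(np.uint8)), cls) for m, cls in lesion_masks],
    )

    # T2w-like anatomy: bright glandular PZ, darker stroma and cancer.
    # Noiseless voxel-wise, but scaled by a per-case receiver-gain factor
    # so case-level intensity statistics vary across a cohort.
    t2 = np.full(spec.shape, 150.0)
    t2[pz] = 900.0
    t2[tz] = 500.0
    t2[as_mask] = 350.0
    for m, cls in lesion_masks:
        t2[m] = 380.0 if cls == "csPCa" else 450.0
    t2 *= rng.uniform(0.85, 1.15)

    truth = {"S0": vol(s0), "adc": vol(adc), "t2w": vol(t2)}
    return series, labels, truth


def _point_in_ellipsoid(p: Sequence[float], semiaxes: Sequence[float]) -> bool:
    return sum((c / a) ** 2 for c, a in zip(p, semiaxes)) <= 1.0


def default_study_spec(n_cases: int, seed: int = 0) -> list[PhantomSpec]:
    """Phantom cohort with case-to-case jitter of geometry and tissue.

    Every case carries 1-3 lesions placed inside the gland; lesion
    classes are drawn so that roughly one lesion in four is clinically
    significant, mirroring the tumor-level class mix of the emulated
    cohort.  Case ``i`` derives its own reproducible sub-seed from
    ``seed``.
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    rng = np.random.default_rng(seed)
    specs = []
    for i in range(n_cases):
        case_seed = int(rng.integers(0, 2**31 - 1))
        crng = np.random.default_rng(case_seed)
        gland_ax = tuple(
            float(a * crng.uniform(0.9, 1.1)) for a in (24.0, 20.0, 16.0)
        )
        tz_ax = tuple(float(a * 0.55) for a in gland_ax)
        tissues = {
            name: TissueParams(
                S0=p.S0 * float(crng.uniform(0.92, 1.08)),
                adc=p.adc * float(crng.uniform(0.92, 1.08)),
            )
            for name, p in DEFAULT_TISSUES.items()
        }
        n_lesions = int(crng.integers(1, 4))
        lesions = []
        for _ in range(n_lesions):
            cls = "csPCa" if crng.uniform() < CSPCA_LESION_FRACTION else "insPCa"
            radius = float(crng.uniform(4.0, 8.0))
            # rejection-sample a center comfortably inside the gland
            while True:
                u = crng.uniform(-0.65, 0.65, size=3)
                center = tuple(float(ui * ai) for ui, ai in zip(u, gland_ax))
                if _point_in_ellipsoid(center, gland_ax):
                    break
            base = tissues[cls]
            lesions.append(
                LesionSpec(
                    center_mm=center,
                    radius_mm=radius,
                    cls=cls,
                    tissue=TissueParams(
                        S0=base.S0 * float(crng.uniform(0.95, 1.05)),
                        adc=base.adc * float(crng.uniform(0.95, 1.05)),
                    ),
                )
            )
        specs.append(
            PhantomSpec(
                gland_semiaxes_mm=gland_ax,
                tz_semiaxes_mm=tz_ax,
                lesions=tuple(lesions),
                tissues=tissues,
                seed=case_seed,
            )
        )
    return specs
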