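# cdis — synthetic correlated diffusion imaging for prostate MRI

`cdis` computes **synthetic correlated diffusion imaging (CDI^s)** maps
from routine multi-b-value diffusion-weighted MRI (DWI) and evaluates how
well they delineate clinically significant prostate cancer (csPCa,
Gleason ≥ 7) from insignificant cancer (insPCa) and healthy tissue.  It
is aimed at imaging researchers who have per-patient DWI volumes (DICOM
or NIfTI) with gland/zone/lesion segmentations, and at anyone who wants a
fully synthetic, download-free test bed for the method: a digital
prostate phantom generator reproduces the data structure of a clinical
cohort end to end.

## The method

A clinical 3-point protocol acquires signals S_b at b = {50, 400, 800}
s/mm². Per voxel, the mono-exponential model `S(b) = S(0)·exp(−b·A)`
is fitted by ordinary least squares on log-signal,

    Â(x) = − Σᵢ (bᵢ − b̄)(log S_bᵢ(x) − mean log S) / Σᵢ (bᵢ − b̄)²,

and **synthetic acquisitions** are extrapolated from the b = 50 reference
to un-acquired b-values (1000…7000 s/mm², 1000 apart):

    Ŝ_b(x) = S_50(x) · exp(−(b − 50)·Â(x)).

Native and synthetic signals are then **mixed** into a single map: the
contribution-weighted product Π_k S_{b_k}(x′)^{ρ_k} is averaged over a
local 6 × 6 × 3 mm volume with Gaussian weights (Σ = diag(4, 4, 0) mm²)
and divided by a calibration factor Z, the median of the uncalibrated
map inside the prostate gland:

    CDI^s(x) = (1/Z) Σ_{x′∈V(x)} w(x′ − x) Π_k S_{b_k}(x′)^{ρ_k}.

Cancerous tissue keeps high signal across the whole b-range (restricted
diffusion), so its product is hyperintense; calibration makes the
dynamic range comparable across scanners and patients.  The
contribution coefficients ρ (all 1 by default) can be **tuned** with a
Nelder–Mead search maximizing voxel-pooled delineation AUC (the tuned
map is denoted CDI^s_t).

Delineation is quantified by pooling gland voxels across cases,
computing empirical ROC curves and trapezoidal AUC per modality
(CDI^s, CDI^s_t, ADC, T2w, K^trans), and testing AUC differences
between modalities computed on the same cases with the Hanley–McNeil
critical ratio `z = (A₁−A₂)/√(SE₁² + SE₂² − 2r·SE₁SE₂)`, where the
correlation r between the two AUC estimates is interpolated from a
packaged lookup table at the mean AUC and the mean per-patient-median
Pearson correlation.

## Worked example

Generate a 3-case phantom cohort, compute maps for one case, and run the
pooled statistics:

```sh
cdis phantom --cases 3 --seed 4 --out study/
cdis compute study/case000 --out maps/
cdis stats study/ --out stats/
```

`cdis compute` prints the calibration factor and writes
`cdis.nii.gz` (calibrated map), `cdis_log.nii.gz` (log-space display
version), `adc.nii.gz` (ADC in 10⁻⁶ mm²/s), and a PNG heatmap overlay
on the T2w-like volume.  Programmatically, the same 20-case study the
acceptance script runs prints (seed 1):

```
auc_cdis_cspca_vs_healthy        0.9876   (54 225 pooled voxels)
auc_cdis_tuned_cspca_vs_healthy  0.99996
auc_adc_cspca_vs_healthy         0.9770
auc_t2w_cspca_vs_healthy         0.9569
z_cdis_vs_adc_cspca_vs_healthy   3.392    (p = 0.00069)
```

Read: on phantoms built to follow the restricted-diffusion tissue
model, the correlated-diffusion map separates csPCa from healthy gland
voxels with AUC ≈ 0.99, ahead of the ADC map (gap ≈ 0.011, significant
at z = 3.4) and T2w; coefficient tuning adds a further small gain.
Absolute values depend on the phantom's noise and tissue settings — the
qualitative ordering is the reproducible statement.

## Layout

- `src/cdis/volumes.py` — volume I/O (DICOM/NIfTI via SimpleITK), common-grid resampling, tissue label sets
- `src/cdis/diffusion.py` — b-value physics, least-squares ADC, synthetic signal extension
- `src/cdis/mixing.py` — calibrated Gaussian-weighted signal mixing, log display transform
- `src/cdis/tuning.py` — Nelder–Mead coefficient optimization against pooled AUC
- `src/cdis/stats.py` — voxel pooling, empirical ROC/AUC, Hanley–McNeil SE / r / critical ratio
- `src/cdis/phantom.py` — digital prostate DWI phantom cohort generator
- `src/cdis/pipeline.py`, `src/cdis/cli.py` — study orchestration and the `cdis` command

See `docs/methods.md` for the modelling assumptions, parameter choices,
and known limitations.
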