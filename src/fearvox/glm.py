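"""First-level voxel-wise model: Gaussian smoothing, OLS GLM, contrasts,
and percent-signal-change scaling.

Estimation is ordinary least squares per voxel.  Group inference downstream
is permutation-based (sign flipping), which does not require first-level
whiteness, so no prewhitening is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import nibabel as nib
import numpy as np
from scipy import ndimage

from .design import DesignMatrix, HrfKernel, TrialSchedule, _convolve_events

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class BoldDataset:
    """A 4D BOLD run: intensities, repetition time, brain mask and affine."""

    data: np.ndarray  # (x, y, z, t)
    tr_s: float
    mask: np.ndarray  # (x, y, z) boolean
    affine: np.ndarray  # 4x4 voxel-to-world (mm)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.data.shape[:3]:
            raise ValueError("mask shape must equal the spatial shape of the data")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def voxel_size_mm(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def to_nifti(self) -> nib.Nifti1Image:
        img = nib.Nifti1Image(self.data.astype(np.float32), self.affine)
        img.header.set_zooms((*self.voxel_size_mm, self.tr_s))
        return img


def load_bold(bold_path, mask_path) -> BoldDataset:
    img = nib.load(str(bold_path))
    mask_img = nib.load(str(mask_path))
    tr = float(img.header.get_zooms()[3])
    return BoldDataset(
        data=np.asarray(img.dataobj, dtype=float),
        tr_s=tr,
        mask=np.asarray(mask_img.dataobj) > 0,
        affine=img.affine,
    )


@dataclass
class CopeMap:
    """Contrast of parameter estimates with its variance map.

    Values are finite exactly on mask voxels; NaN elsewhere.
    """

    values: np.ndarray
    varcope: np.ndarray
    contrast_name: str
    subject_id: str = ""
    affine: np.ndarray | None = None
    mask: np.ndarray | None = None

    def to_nifti(self) -> nib.Nifti1Image:
        affine = np.eye(4) if self.affine is None else self.affine
        return nib.Nifti1Image(self.values.astype(np.float32), affine)

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))


def cope_filename(subject_id: str, contrast_name: str, task: str = "cond") -> str:
    return f"sub-{subject_id}_task-{task}_contrast-{contrast_name}_cope.nii.gz"


def smooth_gaussian(bold: BoldDataset, fwhm_mm: float) -> BoldDataset:
    """Spatially smooth each volume with an isotropic Gaussian.

    ``fwhm_mm`` is the kernel's full width at half maximum in millimetres
    (2, 5 or 8 mm in the analyses this package reproduces; 0 disables
    smoothing).  Anisotropic voxels are handled by a per-axis sigma.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be non-negative")
    if fwhm_mm == 0:
        return bold
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / bold.voxel_size_mm
    out = np.empty_like(bold.data)
    for t in range(bold.n_volumes):
        out[..., t] = ndimage.gaussian_filter(bold.data[..., t], sigma=sigma_vox)
    return BoldDataset(data=out, tr_s=bold.tr_s, mask=bold.mask, affine=bold.affine)


@dataclass
class GlmFit:
    betas: np.ndarray  # (n_regressors, n_maskvoxels)
    sigma2: np.ndarray  # (n_maskvoxels,)
    dof: int
    design: DesignMatrix
    mask: np.ndarray
    affine: np.ndarray


def fit_glm(bold: BoldDataset, design: DesignMatrix) -> GlmFit:
    """Ordinary-least-squares fit of the design to every mask voxel."""
    X = design.matrix
    if X.shape[0] != bold.n_volumes:
        raise ValueError(
            f"design has {X.shape[0]} rows but data has {bold.n_volumes} volumes"
        )
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify (a superset of) the offending columns for the error message
        _, r = np.linalg.qr(X)
        diag = np.abs(np.diag(r))
        bad = [design.names[i] for i in np.where(diag < 1e-8 * diag.max())[0]]
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
            f"collinear columns include: {bad}"
        )
    Y = bold.data[bold.mask].T  # (n_volumes, n_maskvoxels)
    betas, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ betas
    dof = bold.n_volumes - rank
    sigma2 = (resid**2).sum(axis=0) / dof
    return GlmFit(
        betas=betas,
        sigma2=sigma2,
        dof=dof,
        design=design,
        mask=bold.mask,
        affine=bold.affine,
    )


def compute_contrast(fit: GlmFit, contrast, name: str = "",
                     subject_id: str = "") -> CopeMap:
    """cope = c'beta; varcope = sigma^2 * c'(X'X)^-1 c, as 3D maps."""
    if isinstance(contrast, str):
        name = name or contrast
        contrast = fit.design.contrasts[contrast]
    c = np.asarray(contrast, dtype=float)
    if c.shape[0] != fit.betas.shape[0]:
        raise ValueError("contrast length must equal the number of regressors")
    X = fit.design.matrix
    xtx_inv = np.linalg.pinv(X.T @ X)
    cope_flat = c @ fit.betas
    var_flat = fit.sigma2 * float(c @ xtx_inv @ c)
    values = np.full(fit.mask.shape, np.nan)
    varcope = np.full(fit.mask.shape, np.nan)
    values[fit.mask] = cope_flat
    varcope[fit.mask] = var_flat
    return CopeMap(
        values=values,
        varcope=varcope,
        contrast_name=name,
        subject_id=subject_id,
        affine=fit.affine,
        mask=fit.mask,
    )


def unit_response_peak(schedule: TrialSchedule, hrf: HrfKernel) -> float:
    """Peak of a single-event regressor: one stimulus-length boxcar
    convolved with the HRF.  Used to convert betas to percent signal change."""
    dur = schedule.stim_duration_s
    n_vol = int(np.ceil((dur + 32.0) / schedule.tr_s))
    reg = _convolve_events(
        np.array([0.0]), np.array([dur]), hrf, schedule.tr_s, n_vol
    )
    return float(reg.max())


def percent_signal_change(
    cope: CopeMap,
    bold: BoldDataset,
    design: DesignMatrix,
    schedule: TrialSchedule,
    hrf: HrfKernel,
) -> CopeMap:
    """Scale a cope to percent signal change.

    PSC = 100 * cope * peak(unit event response) / voxel temporal mean.
    The scaling makes the map invariant to global intensity rescaling.
    Voxels with non-positive temporal mean are dropped from the mask with
    a warning.
    """
    peak = unit_response_peak(schedule, hrf)
    mean_img = bold.data.mean(axis=3)
    mask = bold.mask.copy()
    bad = mask & (mean_img <= 0)
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} voxels have non-positive temporal mean; "
            "excluded from the PSC mask",
            stacklevel=2,
        )
        mask &= ~bad
    values = np.full(cope.values.shape, np.nan)
    varcope = np.full(cope.values.shape, np.nan)
    values[mask] = 100.0 * cope.values[mask] * peak / mean_img[mask]
    varcope[mask] = cope.varcope[mask] * (100.0 * peak / mean_img[mask]) ** 2
    return CopeMap(
        values=values,
        varcope=varcope,
        contrast_name=f"{cope.contrast_name}_psc",
        subject_id=cope.subject_id,
        affine=cope.affine,
        mask=mask,
    )
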