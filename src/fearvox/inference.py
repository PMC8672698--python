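"""Group-level permutation inference with TFCE and max-statistic FWER
control.

The one-sample design (is the mean cope nonzero?) is tested by sign
flipping: under the null of a symmetric error distribution, each subject's
cope map may have its sign flipped without changing the joint law, so the
null distribution of the maximum TFCE score over the mask is rebuilt from
random (or, for small n, all 2^n) sign patterns.  Family-wise corrected
p-values compare each voxel's observed TFCE score with that max-null.

A covariate mode tests the slope of a subject-level predictor (for
example trait anxiety or differential pupil response) with Freedman–Lane
residual permutation under the same max-TFCE correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._tfce import neighbor_offsets, tfce_kernel

DEFAULT_TFCE = {"E": 0.5, "H": 2.0, "n_steps": 100, "connectivity": 26}


@dataclass
class GroupSample:
    """Stacked subject-level contrast maps over a common mask."""

    copes: np.ndarray  # (n_subjects, n_maskvoxels)
    mask: np.ndarray  # 3D boolean
    voxel_size_mm: float | np.ndarray = 2.0
    covariate: np.ndarray | None = None
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.copes = np.asarray(self.copes, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.copes.shape[1] != int(self.mask.sum()):
            raise ValueError("copes second dimension must match mask voxel count")
        if not np.isfinite(self.copes).all():
            raise ValueError("copes must be finite on the mask")
        if self.covariate is not None:
            cov = np.asarray(self.covariate, dtype=float)
            if cov.shape != (self.copes.shape[0],):
                raise ValueError("covariate length must equal n_subjects")
            self.covariate = cov - cov.mean()

    @property
    def n_subjects(self) -> int:
        return self.copes.shape[0]

    @classmethod
    def from_maps(cls, maps: list[np.ndarray], mask: np.ndarray, **kw) -> GroupSample:
        mask = np.asarray(mask, dtype=bool)
        copes = np.stack([np.asarray(m, dtype=float)[mask] for m in maps])
        return cls(copes=copes, mask=mask, **kw)


@dataclass
class StatResult:
    """Voxel-wise statistic, its TFCE enhancement, and FWER-corrected p."""

    tmap: np.ndarray
    tfce_map: np.ndarray
    pcorr_map: np.ndarray
    n_permutations: int
    seed: int | None
    alpha: float = 0.05
    mask: np.ndarray | None = None
    max_null: np.ndarray | None = None
    exhaustive: bool = False

    @property
    def significant(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.nan_to_num(self.pcorr_map, nan=1.0) < self.alpha


def one_sample_tmap(sample: GroupSample) -> np.ndarray:
    """Per-voxel one-sample t statistic, t = mean / (sd / sqrt(n)).

    Voxels with zero sample variance are assigned t = 0 by convention.
    """
    if sample.n_subjects < 2:
        raise ValueError("one-sample t requires at least 2 subjects")
    t_flat = _signflip_tmaps(sample.copes, np.ones((1, sample.n_subjects)))[0]
    out = np.zeros(sample.mask.shape)
    out[sample.mask] = t_flat
    return out


def _signflip_tmaps(copes: np.ndarray, flips: np.ndarray,
                    chunk: int = 128) -> np.ndarray:
    """One-sample t maps for a batch of sign-flip patterns, computed in
    chunks with the direct mean/sd formulas (numerically stable even for
    near-degenerate flip patterns)."""
    n, n_vox = copes.shape
    out = np.empty((flips.shape[0], n_vox))
    for lo in range(0, flips.shape[0], chunk):
        block = flips[lo:lo + chunk]
        flipped = block[:, :, None] * copes[None, :, :]
        mean = flipped.mean(axis=1)
        sd = flipped.std(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = mean / (sd / np.sqrt(n))
        t[~np.isfinite(t)] = 0.0
        out[lo:lo + chunk] = t
    return out


def tfce_transform(
    statmap: np.ndarray,
    mask: np.ndarray | None = None,
    E: float = 0.5,
    H: float = 2.0,
    n_steps: int = 100,
    connectivity: int = 26,
) -> np.ndarray:
    """Threshold-free cluster enhancement of a 3D statistic map.

    Only the positive part is enhanced; run the negated map through the
    transform for the opposite direction.  ``n_steps`` sets the threshold
    ladder resolution, dh = max/n_steps.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    stat = np.asarray(statmap, dtype=np.float64).copy()
    if mask is not None:
        stat[~np.asarray(mask, dtype=bool)] = 0.0
    np.maximum(stat, 0.0, out=stat)
    offs = neighbor_offsets(connectivity)
    return tfce_kernel(stat, float(E), float(H), int(n_steps), offs)


def _all_sign_patterns(n: int) -> np.ndarray:
    bits = np.arange(2**n, dtype=np.int64)
    signs = ((bits[:, None] >> np.arange(n)) & 1) * 2 - 1
    return signs.astype(float)


def permutation_test(
    sample: GroupSample,
    n_perm: int = 5000,
    alpha: float = 0.05,
    seed: int | None = 0,
    tfce_params: dict | None = None,
) -> StatResult:
    """One-sample sign-flip permutation test with max-TFCE FWER control.

    When ``2**n_subjects <= n_perm`` all sign patterns are enumerated, the
    p-values are exact and the seed is irrelevant.  Otherwise ``n_perm``
    random patterns are drawn and the identity permutation enters through
    the (b + 1)/(m + 1) convention, which keeps the test valid.
    """
    if sample.covariate is not None:
        return covariate_test(sample, n_perm=n_perm, alpha=alpha, seed=seed,
                              tfce_params=tfce_params)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    params = dict(DEFAULT_TFCE, **(tfce_params or {}))
    n = sample.n_subjects

    tmap = one_sample_tmap(sample)
    tfce_obs = tfce_transform(tmap, sample.mask, **params)

    exhaustive = 2**n <= n_perm
    if exhaustive:
        flips = _all_sign_patterns(n)
    else:
        rng = np.random.default_rng(seed)
        flips = rng.choice([-1.0, 1.0], size=(n_perm, n))
    t_null = _signflip_tmaps(sample.copes, flips)

    max_null = np.empty(flips.shape[0])
    stat3d = np.zeros(sample.mask.shape)
    for p in range(flips.shape[0]):
        stat3d[sample.mask] = t_null[p]
        max_null[p] = tfce_transform(stat3d, sample.mask, **params).max()

    obs_flat = tfce_obs[sample.mask]
    exceed = (max_null[:, None] >= obs_flat[None, :]).sum(axis=0)
    if exhaustive:
        p_flat = exceed / flips.shape[0]
    else:
        p_flat = (1.0 + exceed) / (flips.shape[0] + 1.0)
    pcorr = np.full(sample.mask.shape, np.nan)
    pcorr[sample.mask] = p_flat
    return StatResult(
        tmap=tmap,
        tfce_map=tfce_obs,
        pcorr_map=pcorr,
        n_permutations=flips.shape[0],
        seed=seed,
        alpha=alpha,
        mask=sample.mask,
        max_null=max_null,
        exhaustive=exhaustive,
    )


def _covariate_tmaps(resid: np.ndarray, covs: np.ndarray, scc: float,
                     dof: int) -> np.ndarray:
    """t statistics for the covariate slope, one row per permuted covariate.

    ``resid`` are the intercept-model residuals (columns mean 0), so the
    residual sum of squares of the full model is ssE - slope^2 * scc.
    """
    ss_e = (resid**2).sum(axis=0)
    slope = (covs @ resid) / scc
    rss = np.maximum(ss_e[None, :] - slope**2 * scc, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = slope / np.sqrt(rss / dof / scc)
    t[~np.isfinite(t)] = 0.0
    return t


def covariate_test(
    sample: GroupSample,
    n_perm: int = 5000,
    alpha: float = 0.05,
    seed: int | None = 0,
    tfce_params: dict | None = None,
) -> StatResult:
    """Slope test for a demeaned subject-level covariate.

    Fits cope ~ intercept + covariate per voxel and tests the slope t
    statistic; the null is built by Freedman–Lane permutation (permuting
    the intercept-model residuals, equivalently the covariate entries),
    with the same max-TFCE family-wise correction as the one-sample test.
    """
    if sample.covariate is None:
        raise ValueError("sample has no covariate")
    cov = sample.covariate
    if np.allclose(cov, cov[0]):
        raise ValueError("covariate is constant; slope is not identifiable")
    n = sample.n_subjects
    if n < 3:
        raise ValueError("covariate test requires at least 3 subjects")
    params = dict(DEFAULT_TFCE, **(tfce_params or {}))
    dof = n - 2
    scc = float(cov @ cov)
    resid = sample.copes - sample.copes.mean(axis=0, keepdims=True)

    t_obs_flat = _covariate_tmaps(resid, cov[None, :], scc, dof)[0]
    tmap = np.zeros(sample.mask.shape)
    tmap[sample.mask] = t_obs_flat
    tfce_obs = tfce_transform(tmap, sample.mask, **params)

    rng = np.random.default_rng(seed)
    covs = np.stack([cov[rng.permutation(n)] for _ in range(n_perm)])
    t_null = _covariate_tmaps(resid, covs, scc, dof)

    max_null = np.empty(n_perm)
    stat3d = np.zeros(sample.mask.shape)
    for p in range(n_perm):
        stat3d[sample.mask] = t_null[p]
        max_null[p] = tfce_transform(stat3d, sample.mask, **params).max()

    obs_flat = tfce_obs[sample.mask]
    exceed = (max_null[:, None] >= obs_flat[None, :]).sum(axis=0)
    p_flat = (1.0 + exceed) / (n_perm + 1.0)
    pcorr = np.full(sample.mask.shape, np.nan)
    pcorr[sample.mask] = p_flat
    return StatResult(
        tmap=tmap,
        tfce_map=tfce_obs,
        pcorr_map=pcorr,
        n_permutations=n_perm,
        seed=seed,
        alpha=alpha,
        mask=sample.mask,
        max_null=max_null,
    )
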