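"""Probabilistic-ROI statistics: mask binarization, significant-voxel
accounting with local maxima, susceptibility-dropout quantification, and
mean signal-change analyses (2x2 repeated-measures ANOVA, paired t).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import stats as sps

from .design import CONDITIONS


@dataclass
class ProbMask:
    """Probabilistic atlas mask; probabilities encoded 0-1 or 0-100
    (auto-detected: any value above 1 implies the percent encoding)."""

    prob: np.ndarray
    affine: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.prob = np.asarray(self.prob, dtype=float)
        if self.prob.max() > 1.0:
            self.prob = self.prob / 100.0
        if self.prob.min() < 0 or self.prob.max() > 1:
            raise ValueError("probabilities outside [0, 1] after decoding")

    @classmethod
    def from_nifti(cls, path, name: str = "") -> ProbMask:
        img = nib.load(str(path))
        return cls(prob=np.asarray(img.dataobj, dtype=float), affine=img.affine,
                   name=name or str(path))


def binarize_mask(pm: ProbMask, threshold: float) -> np.ndarray:
    """Binary mask at the strict threshold prob > threshold."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    out = pm.prob > threshold
    if not out.any():
        warnings.warn(f"binarized mask '{pm.name}' at {threshold} is empty",
                      stacklevel=2)
    return out


@dataclass
class RoiReport:
    mask_name: str
    threshold: float
    n_mask_voxels: int
    n_significant: int
    percent: float
    local_maxima: list = field(default_factory=list)  # [(x, y, z, stat), ...]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "mask_name": self.mask_name,
                    "threshold": self.threshold,
                    "n_mask_voxels": self.n_mask_voxels,
                    "n_significant": self.n_significant,
                    "percent": self.percent,
                    "local_maxima": [
                        {"x_mm": x, "y_mm": y, "z_mm": z, "stat": s}
                        for x, y, z, s in self.local_maxima
                    ],
                },
                fh,
                indent=2,
            )


_FACE_NEIGHBORS = [
    (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)
]


def _local_maxima(statmap: np.ndarray, region: np.ndarray) -> list[tuple]:
    """Voxel indices of local maxima of ``statmap`` within ``region``.

    A voxel is a candidate when its statistic is >= every face-connected
    neighbour inside the region; flat plateaus are reduced to the voxel
    with the lowest flat index.
    """
    idx = np.argwhere(region)
    shape = statmap.shape
    candidates = []
    for i, j, k in idx:
        v = statmap[i, j, k]
        is_max = True
        for di, dj, dk in _FACE_NEIGHBORS:
            ni, nj, nk = i + di, j + dj, k + dk
            if (
                0 <= ni < shape[0]
                and 0 <= nj < shape[1]
                and 0 <= nk < shape[2]
                and region[ni, nj, nk]
                and statmap[ni, nj, nk] > v
            ):
                is_max = False
                break
        if is_max:
            candidates.append((i, j, k))
    if not candidates:
        return []
    # collapse connected equal-valued candidates to the lowest flat index
    from scipy import ndimage

    cand_mask = np.zeros(shape, dtype=bool)
    for c in candidates:
        cand_mask[c] = True
    labels, n_lab = ndimage.label(cand_mask, structure=ndimage.generate_binary_structure(3, 1))
    peaks = []
    for lab in range(1, n_lab + 1):
        members = np.argwhere(labels == lab)
        vals = np.array([statmap[tuple(m)] for m in members])
        best = vals.max()
        winners = members[vals == best]
        flat = np.ravel_multi_index(winners.T, shape)
        peaks.append(tuple(winners[np.argmin(flat)]))
    return peaks


def roi_report(
    sig_mask: np.ndarray,
    statmap: np.ndarray,
    roi: np.ndarray,
    affine: np.ndarray,
    mask_name: str = "",
    threshold: float = float("nan"),
) -> RoiReport:
    """Count significant voxels inside an ROI and list local maxima in
    world (mm) coordinates, sorted by descending statistic."""
    sig_mask = np.asarray(sig_mask, dtype=bool)
    roi = np.asarray(roi, dtype=bool)
    if sig_mask.shape != statmap.shape or roi.shape != statmap.shape:
        raise ValueError("sig_mask, statmap and roi must share a grid")
    region = sig_mask & roi
    n_roi = int(roi.sum())
    n_sig = int(region.sum())
    peaks_vox = _local_maxima(np.asarray(statmap, dtype=float), region)
    maxima = []
    for i, j, k in peaks_vox:
        world = affine @ np.array([i, j, k, 1.0])
        maxima.append((float(world[0]), float(world[1]), float(world[2]),
                       float(statmap[i, j, k])))
    maxima.sort(key=lambda m: -m[3])
    return RoiReport(
        mask_name=mask_name,
        threshold=threshold,
        n_mask_voxels=n_roi,
        n_significant=n_sig,
        percent=100.0 * n_sig / n_roi if n_roi else 0.0,
        local_maxima=maxima,
    )


@dataclass
class DropoutReport:
    subject_id: str
    mask_name: str
    fraction_dropout: float
    dropout_mask: np.ndarray


def detect_dropout(
    mean_epi: np.ndarray,
    roi: np.ndarray,
    brain_mask: np.ndarray,
    factor: float = 0.5,
    subject_id: str = "",
    mask_name: str = "",
) -> DropoutReport:
    """Flag susceptibility dropout: ROI voxels whose mean EPI intensity
    falls below ``factor`` (default 50%) of the subject's whole-brain mean
    EPI signal.  Scale-invariant by construction."""
    mean_epi = np.asarray(mean_epi, dtype=float)
    roi = np.asarray(roi, dtype=bool)
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if not brain_mask.any():
        raise ValueError("brain mask is empty")
    reference = mean_epi[brain_mask].mean()
    if reference == 0:
        raise ValueError("mean EPI reference is zero")
    dropout = roi & (mean_epi < factor * reference)
    n_roi = int(roi.sum())
    frac = float(dropout.sum()) / n_roi if n_roi else 0.0
    return DropoutReport(
        subject_id=subject_id,
        mask_name=mask_name,
        fraction_dropout=frac,
        dropout_mask=dropout,
    )


def extract_condition_means(psc_maps: dict, roi: np.ndarray) -> pd.DataFrame:
    """Average percent-signal-change maps over an ROI, per subject and
    condition.

    ``psc_maps`` maps subject id -> {condition -> 3D array or CopeMap}.
    Returns a subjects x conditions DataFrame (columns in the canonical
    condition order).
    """
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValueError("ROI is empty")
    rows = {}
    for subj, cond_maps in psc_maps.items():
        row = {}
        for cond in CONDITIONS:
            m = cond_maps[cond]
            values = getattr(m, "values", m)
            row[cond] = float(np.asarray(values)[roi].mean())
        rows[subj] = row
    df = pd.DataFrame.from_dict(rows, orient="index")[list(CONDITIONS)]
    if not np.isfinite(df.to_numpy()).all():
        raise ValueError("condition means contain non-finite values")
    return df


def paired_t(a, b) -> tuple[float, int, float]:
    """Classic paired t test; returns (t, df, p).

    Conventions for degenerate inputs: identical vectors give t = 0,
    p = 1; nonzero constant differences give t = +/-inf with p -> 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("paired_t needs two equal-length vectors, n >= 2")
    d = a - b
    n = len(d)
    df = n - 1
    sd = d.std(ddof=1)
    if sd == 0:
        if np.allclose(d, 0):
            return 0.0, df, 1.0
        return float(np.sign(d.mean()) * np.inf), df, 0.0
    t = d.mean() / (sd / np.sqrt(n))
    p = 2 * sps.t.sf(abs(t), df)
    return float(t), df, float(p)


def rm_anova_2x2(cm: pd.DataFrame) -> pd.DataFrame:
    """Within-subject 2x2 ANOVA on condition means.

    Factors: picture type (face/house) and learned threat (CS+/CS-).
    With two levels per factor each effect reduces to a paired t on the
    corresponding difference scores, so F = t^2 with df = (1, n - 1) and
    partial eta squared = F / (F + df2).  Effects are returned for
    ``picture``, ``threat`` and ``picture_x_threat``.
    """
    data = cm[list(CONDITIONS)].to_numpy(dtype=float)
    n = data.shape[0]
    if n < 2:
        raise ValueError("ANOVA requires at least 2 subjects")
    csp_face, csm_face, csp_house, csm_house = data.T
    effects = {
        "picture": (csp_face + csm_face) / 2 - (csp_house + csm_house) / 2,
        "threat": (csp_face + csp_house) / 2 - (csm_face + csm_house) / 2,
        "picture_x_threat": (csp_face - csm_face) - (csp_house - csm_house),
    }
    rows = []
    for name, diff in effects.items():
        t, df, _ = paired_t(diff, np.zeros(n))
        f = t**2
        df1, df2 = 1, df
        p = float(sps.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0
        eta = f / (f + df2) if np.isfinite(f) else 1.0
        rows.append({"effect": name, "F": f, "df1": df1, "df2": df2,
                     "p": p, "partial_eta_sq": eta})
    return pd.DataFrame(rows).set_index("effect")
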