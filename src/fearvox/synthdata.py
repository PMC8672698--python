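"""Synthetic multi-subject BOLD and pupil data with known ground truth.

The generator reproduces the statistical structure the analysis assumes —
the 52-trial conditioning schedule, condition-specific haemodynamic
effects expressed in percent signal change, polynomial drift, AR(1) plus
white noise, motion-coupled nuisance signal, a localized low-signal
(susceptibility dropout) region, and event-locked pupil dilations with
blink gaps — so every pipeline stage can be validated against planted
parameters without any external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .design import (
    CONDITIONS,
    DesignMatrix,
    HrfKernel,
    TrialSchedule,
    build_design_matrix,
    build_trial_sequence,
    hrf_double_gamma,
    schedule_to_tsv,
)
from .glm import BoldDataset, unit_response_peak
from .roi_stats import ProbMask

DEFAULT_SHAPE = (24, 24, 12)
BASELINE = 1000.0


def _default_affine(voxel_mm: float = 2.0) -> np.ndarray:
    aff = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    aff[:3, 3] = -voxel_mm * np.array([12, 12, 6])
    return aff


def _cube(shape, center, half) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    sl = tuple(slice(max(0, c - half), min(s, c + half + 1))
               for c, s in zip(center, shape))
    m[sl] = True
    return m


@dataclass
class GroundTruth:
    """Planted parameters a simulation is generated from.

    ``effect_psc`` holds per-condition response amplitudes in percent
    signal change; each condition's effect lives on its entry of
    ``active_regions``.  Noise defaults (white sd 1% of baseline, AR(1)
    coefficient 0.3, quadratic drift, mild motion coupling) keep
    permutation inference non-trivial but powered at n = 16.
    """

    shape: tuple = DEFAULT_SHAPE
    effect_psc: dict = field(default_factory=dict)  # condition -> amplitude (%)
    active_regions: dict = field(default_factory=dict)  # condition -> 3D bool
    dropout_region: np.ndarray | None = None
    pupil_amplitudes: np.ndarray | None = None  # (n_conditions, n_trials)
    white_sd: float = 0.01 * BASELINE
    ar1_coef: float = 0.3
    drift_order: int = 2
    drift_amplitude: float = 0.005 * BASELINE
    motion_gain: float = 0.5
    dropout_scale: float = 0.3
    seed: int = 0
    affine: np.ndarray = field(default_factory=_default_affine)

    @classmethod
    def default(cls, seed: int = 0, effect_psc: dict | None = None,
                shape: tuple = DEFAULT_SHAPE) -> "GroundTruth":
        """A standard truth: one active cube per condition pair and a
        dropout cube near the 'inferior' edge of the volume."""
        effect_psc = effect_psc or {
            "csp_face": 1.0, "csm_face": 0.5, "csp_house": 1.0, "csm_house": 0.5
        }
        cx, cy, cz = (s // 2 for s in shape)
        regions = {
            cond: _cube(shape, (cx + dx, cy + dy, cz), 1)
            for cond, (dx, dy) in zip(
                CONDITIONS, [(-5, -5), (5, -5), (-5, 5), (5, 5)]
            )
        }
        dropout = _cube(shape, (cx, cy, 1), 1)
        return cls(
            shape=shape,
            effect_psc=effect_psc,
            active_regions=regions,
            dropout_region=dropout,
            seed=seed,
        )


def _smooth_random_walk(rng, n, scale) -> np.ndarray:
    steps = rng.normal(0, scale, size=n)
    kernel = np.ones(5) / 5.0
    return np.convolve(np.cumsum(steps), kernel, mode="same")


def simulate_subject_bold(
    schedule: TrialSchedule,
    truth: GroundTruth,
    shape: tuple | None = None,
    tr_s: float | None = None,
    n_volumes: int | None = None,
    hrf: HrfKernel | None = None,
) -> tuple[BoldDataset, np.ndarray]:
    """Simulate one subject's 4D run and its motion-parameter table.

    signal = baseline * (1 + sum_c effect_c/100 * regressor_c / peak)
             + drift + motion-coupled nuisance + AR(1) + white noise,
    with the dropout region scaled down to ``truth.dropout_scale`` of
    baseline.  Planted effects therefore read out exactly in percent
    signal change.
    """
    shape = shape or truth.shape
    tr_s = tr_s or schedule.tr_s
    n_volumes = n_volumes or schedule.n_volumes
    hrf = hrf or hrf_double_gamma(0.1)
    rng = np.random.default_rng(truth.seed)

    motion = np.column_stack(
        [_smooth_random_walk(rng, n_volumes, 0.02) for _ in range(6)]
    )
    design = build_design_matrix(schedule, motion, tr_s, n_volumes, hrf)
    peak = unit_response_peak(schedule, hrf)

    data = np.full((*shape, n_volumes), BASELINE)
    mean_amp = float(np.mean(list(truth.effect_psc.values()) or [0.0]))
    for cond, amp in truth.effect_psc.items():
        region = truth.active_regions.get(cond)
        if region is None or amp == 0:
            continue
        course = BASELINE * (amp / 100.0) * design.column(cond) / peak
        # filler trials of every condition evoke the mean response, carried
        # by the shared filler regressor so recovery stays within the model
        course = course + BASELINE * (mean_amp / 100.0) * design.column("filler") / peak
        data[region] += course

    t_norm = np.linspace(-1, 1, n_volumes)
    drift = np.zeros(n_volumes)
    for k in range(1, truth.drift_order + 1):
        drift += rng.normal(0, truth.drift_amplitude) * t_norm**k
    data += drift

    if truth.motion_gain:
        nuis = truth.motion_gain * BASELINE * 0.001 * motion.sum(axis=1)
        coupling = rng.uniform(0.5, 1.5, size=shape)
        data += coupling[..., None] * nuis

    if truth.white_sd > 0:
        eps = rng.normal(0, truth.white_sd, size=(*shape, n_volumes))
        if truth.ar1_coef:
            noise = np.empty_like(eps)
            noise[..., 0] = eps[..., 0] / np.sqrt(1 - truth.ar1_coef**2)
            for t in range(1, n_volumes):
                noise[..., t] = truth.ar1_coef * noise[..., t - 1] + eps[..., t]
            data += noise
        else:
            data += eps

    if truth.dropout_region is not None:
        data[truth.dropout_region] *= truth.dropout_scale

    mask = np.ones(shape, dtype=bool)
    bold = BoldDataset(data=data, tr_s=tr_s, mask=mask, affine=truth.affine)
    return bold, motion


def simulate_group(
    n_subjects: int,
    between_subject_sd: float = 0.2,
    truth_template: GroundTruth | None = None,
    seed: int = 0,
    schedule: TrialSchedule | None = None,
) -> tuple[list[tuple[BoldDataset, np.ndarray, GroundTruth]], TrialSchedule]:
    """Simulate a group: subject effect amplitudes are drawn around the
    template's (Normal with sd ``between_subject_sd``), with independent
    noise seeds derived from the master seed."""
    if n_subjects < 2:
        raise ValueError("a group needs at least 2 subjects")
    template = truth_template or GroundTruth.default(seed=seed)
    schedule = schedule or build_trial_sequence(counterbalance_seed=seed)
    master = np.random.default_rng(seed)
    subjects = []
    for _ in range(n_subjects):
        amp = {
            cond: a + master.normal(0, between_subject_sd)
            for cond, a in template.effect_psc.items()
        }
        truth_s = GroundTruth(
            shape=template.shape,
            effect_psc=amp,
            active_regions=template.active_regions,
            dropout_region=template.dropout_region,
            white_sd=template.white_sd,
            ar1_coef=template.ar1_coef,
            drift_order=template.drift_order,
            drift_amplitude=template.drift_amplitude,
            motion_gain=template.motion_gain,
            dropout_scale=template.dropout_scale,
            seed=int(master.integers(2**31)),
            affine=template.affine,
        )
        subjects.append((*simulate_subject_bold(schedule, truth_s), truth_s))
    return subjects, schedule


# ---------------------------------------------------------------------------
# pupil traces
# ---------------------------------------------------------------------------


def default_pupil_amplitudes(n_trials: int = 13) -> np.ndarray:
    """Acquisition-phase amplitude pattern: the CS+ dilation grows
    linearly across trials (0.15 to 0.45 a.u.) as the threat association
    is learned, while the CS- stays flat at 0.15."""
    amp = np.zeros((4, n_trials))
    ramp = np.linspace(0.15, 0.45, n_trials)
    amp[0] = amp[2] = ramp  # CS+ face / house
    amp[1] = amp[3] = 0.15  # CS- face / house
    return amp


def pupil_response_kernel(rate_hz: float, peak_s: float = 1.3,
                          duration_s: float = 6.0) -> np.ndarray:
    """Gamma-shaped pupil dilation kernel, peak-normalised, peaking at
    roughly ``peak_s`` after event onset."""
    t = np.arange(0, duration_s, 1.0 / rate_hz)
    shape_k = 4.0
    scale = peak_s / (shape_k - 1)
    kern = t ** (shape_k - 1) * np.exp(-t / scale)
    return kern / kern.max()


def simulate_pupil_trace(
    schedule: TrialSchedule,
    truth: GroundTruth,
    rate_hz: float = 250.0,
    blink_rate_per_min: float = 6.0,
    noise_sd: float = 0.02,
    baseline_mean: float = 3.0,
    wander_sd: float = 0.1,
    seed: int | None = None,
) -> tuple[np.ndarray, "np.ndarray", "np.ndarray"]:
    """Event-locked pupil trace: slow baseline wander + per-trial
    dilations with planted condition/trial amplitudes + white noise +
    blink gaps (100-400 ms runs of invalid samples).

    ``truth.pupil_amplitudes`` is (4, n_trials) in condition order; when
    absent a default with CS+ > CS- is used.  Returns (t_s, diameter,
    valid); wrap in :class:`~fearvox.pupil.PupilTimeSeries`.
    """
    if rate_hz not in (250.0, 500.0, 250, 500):
        raise ValueError("rate must be 250 or 500 Hz")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    total_s = schedule.trials[-1].onset_s + schedule.stim_duration_s + schedule.isi_s
    n = int(round(total_s * rate_hz))
    t_s = np.arange(n) / rate_hz

    amp = truth.pupil_amplitudes
    if amp is None:
        amp = default_pupil_amplitudes(
            max(sum(1 for tr in schedule.trials if tr.condition == c)
                for c in CONDITIONS)
        )

    diameter = np.full(n, baseline_mean)
    if wander_sd > 0:
        slow = rng.normal(0, wander_sd, size=max(int(total_s / 10) + 2, 4))
        diameter += np.interp(t_s, np.linspace(0, total_s, len(slow)), slow)

    kern = pupil_response_kernel(rate_hz)
    counters = {c: 0 for c in CONDITIONS}
    for tr in schedule.trials:
        ci = CONDITIONS.index(tr.condition)
        k = counters[tr.condition]
        counters[tr.condition] += 1
        a = amp[ci, k] if k < amp.shape[1] else amp[ci, -1]
        i0 = int(round(tr.onset_s * rate_hz))
        i1 = min(i0 + len(kern), n)
        diameter[i0:i1] += a * kern[: i1 - i0]

    if noise_sd > 0:
        diameter = diameter + rng.normal(0, noise_sd, size=n)

    valid = np.ones(n, dtype=bool)
    if blink_rate_per_min > 0:
        n_blinks = rng.poisson(blink_rate_per_min * total_s / 60.0)
        for _ in range(n_blinks):
            start = rng.integers(0, n)
            dur = int(rng.uniform(0.1, 0.4) * rate_hz)
            valid[start:start + dur] = False
            diameter[start:start + dur] = 0.0  # tracker reports junk in blinks

    return t_s, diameter, valid


def make_prob_mask(shape: tuple, center: tuple, radius_sigma: float,
                   affine: np.ndarray | None = None,
                   name: str = "synthetic") -> ProbMask:
    """Synthetic probabilistic ROI: isotropic Gaussian with maximum 1 at
    ``center``, standing in for a probabilistic atlas region.  Its
    binarizations at 0.01 / 0.25 / 0.50 are nested by construction."""
    if not all(0 <= c < s for c, s in zip(center, shape)):
        raise ValueError("center must lie inside the volume")
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    prob = np.exp(-d2 / (2.0 * radius_sigma**2))
    return ProbMask(prob=prob, affine=affine if affine is not None
                    else _default_affine(), name=name)


# ---------------------------------------------------------------------------
# BIDS-like export
# ---------------------------------------------------------------------------


def export_bids_tree(
    out_dir,
    n_subjects: int,
    seed: int = 0,
    truth_template: GroundTruth | None = None,
) -> Path:
    """Write a BIDS-like tree: per-subject bold NIfTI, events TSV and
    confounds TSV, plus a truth.json with the planted parameters."""
    out = Path(out_dir)
    subjects, schedule = simulate_group(
        n_subjects, truth_template=truth_template, seed=seed
    )
    truth_log = {}
    for i, (bold, motion, truth_s) in enumerate(subjects, start=1):
        sub = f"{i:02d}"
        func = out / f"sub-{sub}" / "func"
        func.mkdir(parents=True, exist_ok=True)
        nib.save(bold.to_nifti(), str(func / f"sub-{sub}_task-cond_bold.nii.gz"))
        schedule_to_tsv(schedule, func / f"sub-{sub}_task-cond_events.tsv")
        pd.DataFrame(
            motion, columns=[f"motion{j + 1}" for j in range(6)]
        ).to_csv(func / f"sub-{sub}_task-cond_desc-confounds.tsv", sep="\t",
                 index=False)
        truth_log[f"sub-{sub}"] = {
            "effect_psc": truth_s.effect_psc,
            "seed": truth_s.seed,
        }
    with open(out / "truth.json", "w") as fh:
        json.dump({"master_seed": seed, "subjects": truth_log}, fh, indent=2)
    return out
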