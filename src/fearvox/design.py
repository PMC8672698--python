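"""Trial schedules and first-level design matrices for a Pavlovian
fear-conditioning experiment.

The experimental design interleaves *target* trials (used for estimation)
with *filler* trials (structural trials that absorb all shock
reinforcements).  Four conditioned stimuli are shown: a CS+ face, a CS-
face, a CS+ house and a CS- house.  Each condition appears on 13 trials
(7 targets + 6 fillers by default); every CS+ filler co-terminates with an
electric shock (the US), so reinforcement is 6/13 (46%) per CS+ while no
target trial is ever reinforced.  Trial onsets are locked to the start of
a BOLD volume acquisition.

First-level modelling follows the standard mass-univariate approach: each
event stream is convolved with a double-gamma haemodynamic response
function on an oversampled grid, sampled at volume onsets, and augmented
with temporal derivatives and motion confounds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

CONDITIONS = ("csp_face", "csm_face", "csp_house", "csm_house")

#: Default oversampling resolution (s) for building boxcars and convolving.
OVERSAMPLE_DT = 0.1

#: Minimum silence (s) required between a shock and the next target onset.
MIN_US_TO_TARGET_S = 8.0

#: Delay of the first shock pulse before stimulus offset (s); the second
#: pulse co-terminates with the CS.
US_LEAD_S = 0.3


class InvalidConfigError(ValueError):
    """Raised when a design configuration violates the paradigm's rules."""


@dataclass(frozen=True)
class Trial:
    onset_s: float
    condition: str
    role: str  # "target" | "filler"
    reinforced: bool
    us_onset_s: float | None = None

    @property
    def trial_type(self) -> str:
        return self.condition


@dataclass(frozen=True)
class TrialSchedule:
    """Ordered conditioning-phase events plus the timing grid they live on."""

    trials: tuple[Trial, ...]
    stim_duration_s: float
    isi_s: float
    tr_s: float
    n_volumes: int

    def __len__(self) -> int:
        return len(self.trials)

    def onsets(self, condition: str | None = None, role: str | None = None) -> np.ndarray:
        sel = [
            t.onset_s
            for t in self.trials
            if (condition is None or t.condition == condition)
            and (role is None or t.role == role)
        ]
        return np.asarray(sel, dtype=float)

    def us_onsets(self) -> np.ndarray:
        return np.asarray(
            [t.us_onset_s for t in self.trials if t.reinforced], dtype=float
        )

    def to_events_frame(self) -> pd.DataFrame:
        """BIDS-style events table (onset, duration, trial_type, role, reinforced)."""
        return pd.DataFrame(
            {
                "onset": [t.onset_s for t in self.trials],
                "duration": [self.stim_duration_s] * len(self.trials),
                "trial_type": [t.condition for t in self.trials],
                "role": [t.role for t in self.trials],
                "reinforced": [int(t.reinforced) for t in self.trials],
            }
        )


def schedule_to_tsv(schedule: TrialSchedule, path) -> None:
    schedule.to_events_frame().to_csv(path, sep="\t", index=False)


def schedule_from_tsv(path, stim_duration_s: float, isi_s: float, tr_s: float,
                      n_volumes: int) -> TrialSchedule:
    """Read a BIDS-style events TSV back into a :class:`TrialSchedule`."""
    df = pd.read_csv(path, sep="\t")
    trials = []
    for _, row in df.iterrows():
        reinforced = bool(int(row["reinforced"]))
        us = float(row["onset"]) + float(row["duration"]) - US_LEAD_S if reinforced else None
        trials.append(
            Trial(
                onset_s=float(row["onset"]),
                condition=str(row["trial_type"]),
                role=str(row["role"]),
                reinforced=reinforced,
                us_onset_s=us,
            )
        )
    return TrialSchedule(
        trials=tuple(trials),
        stim_duration_s=stim_duration_s,
        isi_s=isi_s,
        tr_s=tr_s,
        n_volumes=n_volumes,
    )


def _round_up_to_volume(t_s: float, tr_s: float) -> float:
    k = int(np.ceil(round(t_s / tr_s, 9)))
    return k * tr_s


def build_trial_sequence(
    n_target_per_cond: int = 7,
    n_filler_per_cond: int = 6,
    n_reinforced: int = 6,
    stim_duration_s: float = 4.0,
    isi_s: float = 20.0,
    tr_s: float = 2.0,
    counterbalance_seed: int = 0,
) -> TrialSchedule:
    """Generate the conditioning-phase trial schedule.

    Targets come in repeating blocks of four (one per condition, in a
    seed-determined order that is fixed across blocks).  The first two
    blocks run uninterrupted and unreinforced, acting as habituation.
    From the third block on, one or two fillers are inserted between
    successive targets until all fillers are placed; every CS+ filler is
    reinforced (up to ``n_reinforced`` per CS+ condition).  All onsets are
    volume-locked and shocks are verified to precede the next target onset
    by at least 8 s so shock-related activity cannot leak into
    target-locked estimates.
    """
    if n_reinforced > n_filler_per_cond:
        raise InvalidConfigError(
            "n_reinforced exceeds n_filler_per_cond: every reinforced trial "
            "must be a filler"
        )
    if min(stim_duration_s, isi_s, tr_s) <= 0:
        raise InvalidConfigError("durations must be positive")
    if n_target_per_cond < 1:
        raise InvalidConfigError("need at least one target per condition")

    rng = np.random.default_rng(counterbalance_seed)
    block_order = [CONDITIONS[i] for i in rng.permutation(4)]

    # target stream: n_target_per_cond blocks of the same 4-condition order
    target_stream = [c for _ in range(n_target_per_cond) for c in block_order]

    # filler conditions, shuffled; CS+ fillers are reinforced first
    filler_conditions: list[str] = []
    reinforced_flags: list[bool] = []
    for cond in CONDITIONS:
        is_csp = cond.startswith("csp")
        for j in range(n_filler_per_cond):
            filler_conditions.append(cond)
            reinforced_flags.append(is_csp and j < n_reinforced)
    if filler_conditions:
        perm = rng.permutation(len(filler_conditions))
        filler_conditions = [filler_conditions[i] for i in perm]
        reinforced_flags = [reinforced_flags[i] for i in perm]

    # gaps: between successive targets starting after the first two blocks
    # (i.e. after target index 7 in the default design)
    n_targets = len(target_stream)
    first_gap = min(2 * 4, n_targets)  # fillers only after the 8 habituation trials
    gap_slots = list(range(first_gap, n_targets + 1))  # +1: gap after last target
    n_fillers = len(filler_conditions)
    if n_fillers and not gap_slots:
        raise InvalidConfigError("no room to place fillers after habituation")
    fillers_per_gap = np.zeros(len(gap_slots), dtype=int)
    if n_fillers:
        base, extra = divmod(n_fillers, len(gap_slots))
        if base > 2:
            raise InvalidConfigError("too many fillers for 1-2 per inter-target gap")
        fillers_per_gap[:] = base
        if extra:
            bump = rng.choice(len(gap_slots), size=extra, replace=False)
            fillers_per_gap[bump] += 1

    # assemble ordered (condition, role, reinforced) stream
    stream: list[tuple[str, str, bool]] = []
    f = 0
    gap_alloc = dict(zip(gap_slots, fillers_per_gap))
    for i, cond in enumerate(target_stream):
        for _ in range(gap_alloc.get(i, 0)):
            stream.append((filler_conditions[f], "filler", reinforced_flags[f]))
            f += 1
        stream.append((cond, "target", False))
    for _ in range(gap_alloc.get(n_targets, 0)):
        stream.append((filler_conditions[f], "filler", reinforced_flags[f]))
        f += 1

    # volume-locked onsets
    soa = _round_up_to_volume(stim_duration_s + isi_s, tr_s)
    trials = []
    for i, (cond, role, reinforced) in enumerate(stream):
        onset = i * soa
        us = onset + stim_duration_s - US_LEAD_S if reinforced else None
        trials.append(Trial(onset, cond, role, reinforced, us))

    # shock-to-target separation check
    last_us = -np.inf
    for t in trials:
        if t.role == "target" and t.onset_s - last_us < MIN_US_TO_TARGET_S:
            raise InvalidConfigError(
                "a target onset falls within 8 s of a shock; increase the ISI"
            )
        if t.reinforced:
            last_us = t.us_onset_s + US_LEAD_S  # second pulse, at CS offset

    scan_end = trials[-1].onset_s + stim_duration_s + isi_s
    n_volumes = int(np.ceil(round(scan_end / tr_s, 9)))
    return TrialSchedule(
        trials=tuple(trials),
        stim_duration_s=stim_duration_s,
        isi_s=isi_s,
        tr_s=tr_s,
        n_volumes=n_volumes,
    )


# ---------------------------------------------------------------------------
# haemodynamic response function
# ---------------------------------------------------------------------------

#: (peak_delay_s, undershoot_delay_s, peak_dispersion, undershoot_dispersion,
#: undershoot_ratio) — canonical double-gamma settings.
DEFAULT_HRF_PARAMS = (6.0, 16.0, 3.0, 3.0, 6.0)


@dataclass(frozen=True)
class HrfKernel:
    samples: np.ndarray
    dt_s: float
    params: tuple = DEFAULT_HRF_PARAMS

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) * self.dt_s


def hrf_double_gamma(
    dt_s: float,
    duration_s: float = 32.0,
    params: tuple = DEFAULT_HRF_PARAMS,
) -> HrfKernel:
    """Canonical double-gamma HRF, peak-normalised to 1.

    The kernel is the difference of two gamma densities — a positive lobe
    with mean ``peak_delay_s`` and a later undershoot with mean
    ``undershoot_delay_s``, the latter scaled by ``1/undershoot_ratio``.
    Each gamma is parameterised by its mean and variance (the dispersion),
    so the positive lobe peaks a little before its mean, near 5.5 s for the
    defaults.  The value at t=0 is exactly 0 and the kernel has decayed to
    essentially nothing by 32 s.
    """
    if dt_s <= 0:
        raise InvalidConfigError("dt_s must be positive")
    peak_delay, under_delay, peak_disp, under_disp, ratio = params
    if peak_disp <= 0 or under_disp <= 0:
        raise InvalidConfigError("dispersions must be positive")
    t = np.arange(0.0, duration_s + dt_s / 2, dt_s)

    def gamma_density(mean: float, var: float) -> np.ndarray:
        shape = mean**2 / var
        scale = var / mean
        return sps.gamma.pdf(t, a=shape, scale=scale)

    kern = gamma_density(peak_delay, peak_disp)
    if np.isfinite(ratio):
        kern = kern - gamma_density(under_delay, under_disp) / ratio
    peak = kern.max()
    if peak > 0:
        kern = kern / peak
    return HrfKernel(samples=kern, dt_s=dt_s, params=tuple(params))


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------


@dataclass
class DesignMatrix:
    matrix: np.ndarray  # n_volumes x n_regressors
    names: list[str]
    contrasts: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_volumes(self) -> int:
        return self.matrix.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=self.names)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _convolve_events(
    onsets: np.ndarray,
    durations: np.ndarray,
    hrf: HrfKernel,
    tr_s: float,
    n_volumes: int,
    dt: float = OVERSAMPLE_DT,
) -> np.ndarray:
    """Boxcar-convolve events on a fine grid and sample at volume onsets."""
    scan_end = n_volumes * tr_s
    n_fine = int(np.ceil(scan_end / dt)) + 1
    box = np.zeros(n_fine)
    for onset, dur in zip(onsets, durations):
        if onset >= scan_end:
            warnings.warn(
                f"event at {onset:.1f}s is beyond scan end ({scan_end:.1f}s); truncated",
                stacklevel=3,
            )
            continue
        i0 = int(round(onset / dt))
        i1 = max(i0 + 1, min(int(round((onset + dur) / dt)), n_fine))
        box[i0:i1] = 1.0
    if hrf.dt_s != dt:
        # resample the kernel onto the oversampling grid
        t_fine = np.arange(0.0, hrf.times[-1] + dt / 2, dt)
        kern = np.interp(t_fine, hrf.times, hrf.samples)
    else:
        kern = hrf.samples
    # scale by dt so the result approximates the continuous convolution
    # integral and is independent of the oversampling grid
    conv = np.convolve(box, kern)[:n_fine] * dt
    vol_idx = np.round(np.arange(n_volumes) * tr_s / dt).astype(int)
    return conv[np.minimum(vol_idx, n_fine - 1)]


def _temporal_derivative(x: np.ndarray) -> np.ndarray:
    """Backward first difference, zero-padded at the first sample."""
    d = np.empty_like(x)
    d[0] = 0.0
    d[1:] = np.diff(x)
    return d


def build_design_matrix(
    schedule: TrialSchedule,
    motion: np.ndarray | pd.DataFrame,
    tr_s: float | None = None,
    n_volumes: int | None = None,
    hrf: HrfKernel | None = None,
) -> DesignMatrix:
    """First-level design matrix for one subject.

    Regressors of interest are the four CS target regressors (7 events
    each by default).  Regressors of no interest: a filler regressor, a
    shock (US) regressor, the temporal derivative of every task regressor,
    the six motion parameters and their first differences, and a constant.

    Contrasts use unit-sum-of-positive-weights (+0.5/-0.5) so a contrast
    value reads as a condition-mean difference:

    - ``csp_vs_csm``: learned threat, (CS+ - CS-) averaged over pictures
    - ``face_vs_house``: picture type, (face - house) averaged over threat
    - one elementary contrast per CS condition (for signal-change maps)
    """
    tr_s = schedule.tr_s if tr_s is None else tr_s
    n_volumes = schedule.n_volumes if n_volumes is None else n_volumes
    if hrf is None:
        hrf = hrf_double_gamma(OVERSAMPLE_DT)
    motion = np.asarray(motion, dtype=float)
    if motion.size == 0:
        motion = np.zeros((n_volumes, 6))
    if motion.shape[0] != n_volumes:
        raise ValueError(
            f"motion table has {motion.shape[0]} rows, expected {n_volumes}"
        )

    dur = schedule.stim_duration_s
    task_cols: list[np.ndarray] = []
    task_names: list[str] = []
    for cond in CONDITIONS:
        onsets = schedule.onsets(condition=cond, role="target")
        task_cols.append(
            _convolve_events(onsets, np.full(len(onsets), dur), hrf, tr_s, n_volumes)
        )
        task_names.append(cond)

    filler_onsets = schedule.onsets(role="filler")
    task_cols.append(
        _convolve_events(
            filler_onsets, np.full(len(filler_onsets), dur), hrf, tr_s, n_volumes
        )
    )
    task_names.append("filler")

    us_onsets = schedule.us_onsets()
    task_cols.append(
        _convolve_events(
            us_onsets, np.full(len(us_onsets), US_LEAD_S), hrf, tr_s, n_volumes
        )
    )
    task_names.append("us")

    cols = list(task_cols)
    names = list(task_names)
    for name, col in zip(task_names, task_cols):
        cols.append(_temporal_derivative(col))
        names.append(f"{name}_td")
    for j in range(6):
        cols.append(motion[:, j])
        names.append(f"motion{j + 1}")
    for j in range(6):
        cols.append(_temporal_derivative(motion[:, j]))
        names.append(f"motion{j + 1}_td")
    cols.append(np.ones(n_volumes))
    names.append("constant")

    matrix = np.column_stack(cols)
    n_reg = matrix.shape[1]

    def make_contrast(weights: dict[str, float]) -> np.ndarray:
        c = np.zeros(n_reg)
        for k, w in weights.items():
            c[names.index(k)] = w
        return c

    contrasts = {
        "csp_vs_csm": make_contrast(
            {"csp_face": 0.5, "csm_face": -0.5, "csp_house": 0.5, "csm_house": -0.5}
        ),
        "face_vs_house": make_contrast(
            {"csp_face": 0.5, "csm_face": 0.5, "csp_house": -0.5, "csm_house": -0.5}
        ),
    }
    for cond in CONDITIONS:
        contrasts[cond] = make_contrast({cond: 1.0})

    return DesignMatrix(matrix=matrix, names=names, contrasts=contrasts)
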