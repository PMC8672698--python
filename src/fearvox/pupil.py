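"""Pupillometry preprocessing and statistics for the conditioning task.

The pipeline order is fixed: blink/missing-sample cleaning, zero-phase
low-pass filtering, per-trial peak-minus-baseline extraction, missing-trial
replacement and subject exclusion, then within-subject z-scoring.  The
trial-level analysis averages face and house stimuli of the same threat
value, leaving 13 CS+ and 13 CS- trials per phase, and tests the stimulus
main effect and the trial x stimulus interaction with a within-subject
two-factor repeated-measures ANOVA.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal as spsig
from scipy import stats as sps

from .design import TrialSchedule


@dataclass(frozen=True)
class PupilTimeSeries:
    """Uniformly sampled pupil-diameter trace with per-sample validity."""

    t_s: np.ndarray
    diameter: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "t_s", np.asarray(self.t_s, dtype=float))
        object.__setattr__(self, "diameter", np.asarray(self.diameter, dtype=float))
        object.__setattr__(self, "valid", np.asarray(self.valid, dtype=bool))
        dt = np.diff(self.t_s)
        if len(dt) and not np.allclose(dt, dt[0]):
            raise ValueError("pupil trace must be uniformly sampled")

    @property
    def rate_hz(self) -> float:
        return 1.0 / (self.t_s[1] - self.t_s[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_s": self.t_s, "diameter": self.diameter,
             "valid": self.valid.astype(int)}
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "PupilTimeSeries":
        df = pd.read_csv(path, sep="\t")
        return cls(df["time_s"].to_numpy(), df["diameter"].to_numpy(),
                   df["valid"].to_numpy().astype(bool))


def _invalid_runs(valid: np.ndarray) -> list[tuple[int, int]]:
    """(start, stop) index pairs of maximal runs of invalid samples."""
    inv = ~valid
    if not inv.any():
        return []
    edges = np.flatnonzero(np.diff(np.concatenate(([0], inv.view(np.int8), [0]))))
    return list(zip(edges[::2], edges[1::2]))


def clean_missing(ts: PupilTimeSeries, gap_len: int = 10,
                  pad_ms: float = 100.0) -> PupilTimeSeries:
    """Remove samples around blink gaps and interpolate.

    Every run of at least ``gap_len`` consecutive invalid samples is
    extended by ``pad_ms`` on each side (the tracker's recovery samples
    around a blink are unreliable) and marked invalid.  All invalid
    samples are then replaced by linear interpolation between the nearest
    valid neighbours; runs touching the trace edges are filled by
    constant extension of the nearest valid sample.
    """
    valid = ts.valid.copy()
    pad = int(round(pad_ms / 1000.0 * ts.rate_hz))
    n = len(valid)
    for start, stop in _invalid_runs(ts.valid):
        if stop - start >= gap_len:
            valid[max(0, start - pad):min(n, stop + pad)] = False
    if not valid.any():
        raise ValueError("trace has no valid samples left after padding")
    diameter = ts.diameter.copy()
    idx = np.arange(n)
    diameter[~valid] = np.interp(idx[~valid], idx[valid], diameter[valid])
    return PupilTimeSeries(ts.t_s, diameter, valid)


def lowpass(ts: PupilTimeSeries, order: int = 3,
            cutoff_hz: float = 4.0) -> PupilTimeSeries:
    """Zero-phase (forward-backward) Butterworth low-pass filter.

    Zero-phase filtering avoids shifting response-peak latencies.
    """
    nyq = ts.rate_hz / 2.0
    if cutoff_hz >= nyq:
        raise ValueError(f"cutoff {cutoff_hz} Hz >= Nyquist {nyq} Hz")
    sos = spsig.butter(order, cutoff_hz, btype="low", fs=ts.rate_hz, output="sos")
    filtered = spsig.sosfiltfilt(sos, ts.diameter)
    return replace(ts, diameter=filtered)


def extract_trial_response(
    ts: PupilTimeSeries,
    onsets_s: np.ndarray,
    baseline_ms: float = 500.0,
    window_s: tuple[float, float] = (0.0, 4.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Peak change from baseline per trial.

    Baseline is the mean diameter over the ``baseline_ms`` before onset;
    the response is the maximum diameter in the (onset, onset + 4 s]
    window minus that baseline.  Trials whose windows fall outside the
    trace are flagged out-of-bounds (second return value) and get NaN.
    """
    onsets_s = np.asarray(onsets_s, dtype=float)
    responses = np.full(len(onsets_s), np.nan)
    oob = np.zeros(len(onsets_s), dtype=bool)
    t = ts.t_s
    for i, onset in enumerate(onsets_s):
        b0, b1 = onset - baseline_ms / 1000.0, onset
        w0, w1 = onset + window_s[0], onset + window_s[1]
        if b0 < t[0] or w1 > t[-1]:
            oob[i] = True
            continue
        base_sel = (t >= b0) & (t < b1)
        win_sel = (t > w0) & (t <= w1)
        responses[i] = ts.diameter[win_sel].max() - ts.diameter[base_sel].mean()
    return responses, oob


def trial_loss_fractions(
    raw_valid: np.ndarray,
    t_s: np.ndarray,
    onsets_s: np.ndarray,
    baseline_ms: float = 500.0,
    window_s: tuple[float, float] = (0.0, 4.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Fraction of invalid samples (pre-cleaning) in each trial's baseline
    and response windows."""
    onsets_s = np.asarray(onsets_s, dtype=float)
    base_loss = np.ones(len(onsets_s))
    win_loss = np.ones(len(onsets_s))
    for i, onset in enumerate(onsets_s):
        base_sel = (t_s >= onset - baseline_ms / 1000.0) & (t_s < onset)
        win_sel = (t_s > onset + window_s[0]) & (t_s <= onset + window_s[1])
        if base_sel.any():
            base_loss[i] = 1.0 - raw_valid[base_sel].mean()
        if win_sel.any():
            win_loss[i] = 1.0 - raw_valid[win_sel].mean()
    return base_loss, win_loss


def flag_and_replace_trials(
    trials: pd.DataFrame,
    loss_threshold: float = 0.5,
    exclude_fraction: float = 1.0 / 3.0,
) -> tuple[pd.DataFrame, bool]:
    """Replace missing trials and decide subject exclusion.

    ``trials`` needs columns ``condition``, ``trial_index`` (1-based,
    within condition), ``response``, ``base_loss``, ``win_loss`` and
    optionally ``oob``.  A trial is *missing* when signal loss exceeded
    ``loss_threshold`` in its baseline or response window (or its window
    fell outside the trace); missing responses are replaced by evaluating
    an OLS line fitted over that condition's non-missing
    (trial_index, response) pairs — the across-trial linear trend.
    The subject is excluded when at least ``exclude_fraction`` of all
    trials in the phase were missing.
    """
    out = trials.copy()
    missing = (out["base_loss"] > loss_threshold) | (out["win_loss"] > loss_threshold)
    if "oob" in out:
        missing |= out["oob"].astype(bool)
    missing |= ~np.isfinite(out["response"])
    out["missing"] = missing.to_numpy()
    out["replaced"] = False
    for cond, grp in out.groupby("condition"):
        miss = grp["missing"].to_numpy()
        if not miss.any():
            continue
        good_x = grp.loc[~grp["missing"], "trial_index"].to_numpy(dtype=float)
        good_y = grp.loc[~grp["missing"], "response"].to_numpy(dtype=float)
        bad_idx = grp.index[grp["missing"]]
        bad_x = grp.loc[bad_idx, "trial_index"].to_numpy(dtype=float)
        if len(good_x) >= 2:
            slope, intercept = np.polyfit(good_x, good_y, 1)
            pred = intercept + slope * bad_x
        else:
            import warnings

            warnings.warn(
                f"condition {cond!r} has {len(good_x)} usable trials; "
                "replacing by condition mean",
                stacklevel=2,
            )
            pred = np.full(len(bad_x), good_y.mean() if len(good_y) else 0.0)
        out.loc[bad_idx, "response"] = pred
        out.loc[bad_idx, "replaced"] = True
    excluded = out["missing"].mean() >= exclude_fraction
    return out, bool(excluded)


def average_face_house(trials: pd.DataFrame) -> pd.DataFrame:
    """Collapse the four CS conditions to CS+ / CS- by averaging the face
    and house variants at each trial index."""
    out = trials.copy()
    out["threat"] = out["condition"].str.startswith("csp").map(
        {True: "csp", False: "csm"}
    )
    agg = (
        out.groupby(["threat", "trial_index"], as_index=False)["response"]
        .mean()
        .rename(columns={"threat": "condition"})
    )
    return agg.sort_values(["condition", "trial_index"], ignore_index=True)


def zscore_within_subject(trials: pd.DataFrame,
                          column: str = "response") -> pd.DataFrame:
    """z-transform responses across all trials of the phase (one subject)."""
    x = trials[column].to_numpy(dtype=float)
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot z-score: zero variance across trials")
    out = trials.copy()
    out[column] = (x - x.mean()) / sd
    return out


def process_subject(
    ts: PupilTimeSeries,
    schedule: TrialSchedule,
    baseline_ms: float = 500.0,
    window_s: tuple[float, float] = (0.0, 4.0),
    gap_len: int = 10,
    pad_ms: float = 100.0,
    lowpass_hz: float = 4.0,
) -> tuple[pd.DataFrame, bool]:
    """Full single-subject pupil pipeline.

    Returns the z-scored 13 x 2 (trial x CS+/CS-) trial table and the
    exclusion flag.  All 13 trials per condition (targets and fillers)
    enter the pupil analysis.
    """
    onsets = np.array([t.onset_s for t in schedule.trials])
    conditions = [t.condition for t in schedule.trials]
    base_loss, win_loss = trial_loss_fractions(
        ts.valid, ts.t_s, onsets, baseline_ms, window_s
    )
    cleaned = clean_missing(ts, gap_len=gap_len, pad_ms=pad_ms)
    filtered = lowpass(cleaned, cutoff_hz=lowpass_hz)
    responses, oob = extract_trial_response(filtered, onsets, baseline_ms, window_s)
    table = pd.DataFrame(
        {
            "condition": conditions,
            "response": responses,
            "base_loss": base_loss,
            "win_loss": win_loss,
            "oob": oob,
        }
    )
    table["trial_index"] = table.groupby("condition").cumcount() + 1
    table, excluded = flag_and_replace_trials(table)
    collapsed = average_face_house(table)
    collapsed = zscore_within_subject(collapsed)
    return collapsed, excluded


# ---------------------------------------------------------------------------
# group statistics
# ---------------------------------------------------------------------------


def _two_way_rm_f(data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Stimulus and trial-x-stimulus F statistics of the within-subject
    two-factor ANOVA, vectorised over leading batch dimensions.

    ``data`` has shape (..., n_subjects, n_trials, 2).  Each effect is
    tested against its interaction with subjects (the standard univariate
    repeated-measures error terms)."""
    data = np.asarray(data, dtype=float)
    *batch, n, a, b = data.shape
    grand = data.mean(axis=(-3, -2, -1), keepdims=True)
    mean_s = data.mean(axis=(-2, -1), keepdims=True)
    mean_a = data.mean(axis=(-3, -1), keepdims=True)
    mean_b = data.mean(axis=(-3, -2), keepdims=True)
    mean_sb = data.mean(axis=-2, keepdims=True)
    mean_sa = data.mean(axis=-1, keepdims=True)
    mean_ab = data.mean(axis=-3, keepdims=True)

    ss_b = (n * a * (mean_b - grand) ** 2).sum(axis=(-3, -2, -1))
    ss_bs = (a * (mean_sb - mean_b - mean_s + grand) ** 2).sum(axis=(-3, -2, -1))
    ss_ab = (n * (mean_ab - mean_a - mean_b + grand) ** 2).sum(axis=(-3, -2, -1))
    resid = (
        data - mean_ab - mean_sa - mean_sb
        + mean_a + mean_b + mean_s - grand
    )
    ss_abs = (resid**2).sum(axis=(-3, -2, -1))

    df_b, df_bs = b - 1, (b - 1) * (n - 1)
    df_ab, df_abs = (a - 1) * (b - 1), (a - 1) * (b - 1) * (n - 1)
    scale = np.maximum(((data - grand) ** 2).sum(axis=(-3, -2, -1)), 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_b = (ss_b / df_b) / (ss_bs / df_bs)
        f_ab = (ss_ab / df_ab) / (ss_abs / df_abs)
    # degenerate error terms: F = 0 when the effect is also null, else inf
    f_b = np.where(ss_bs <= 1e-14 * scale,
                   np.where(ss_b <= 1e-14 * scale, 0.0, np.inf), f_b)
    f_ab = np.where(ss_abs <= 1e-14 * scale,
                    np.where(ss_ab <= 1e-14 * scale, 0.0, np.inf), f_ab)
    return f_b, f_ab


def trial_by_stimulus_anova(group: list[pd.DataFrame] | np.ndarray,
                            n_trials: int = 13) -> pd.DataFrame:
    """Trial (13) x stimulus (CS+ vs CS-) repeated-measures ANOVA.

    ``group`` is either a list of per-subject trial tables (as returned
    by :func:`process_subject`) or an array of shape
    (n_subjects, n_trials, 2) with columns ordered (CS+, CS-).  Reports
    the stimulus main effect with df (1, n - 1) and the interaction with
    df (n_trials - 1, (n_trials - 1)(n - 1)), sphericity-uncorrected,
    with partial eta squared.
    """
    if isinstance(group, np.ndarray):
        data = group
    else:
        mats = []
        for table in group:
            piv = table.pivot(index="trial_index", columns="condition",
                              values="response")
            if piv.shape != (n_trials, 2) or piv.isna().any().any():
                raise ValueError(
                    "each subject needs a complete "
                    f"{n_trials} x 2 trial table"
                )
            mats.append(piv[["csp", "csm"]].to_numpy())
        data = np.stack(mats)
    n, a, b = data.shape
    if a != n_trials or b != 2:
        raise ValueError(f"expected shape (n, {n_trials}, 2), got {data.shape}")
    if not np.isfinite(data).all():
        raise ValueError("trial tables must be complete (no NaN)")
    f_b, f_ab = _two_way_rm_f(data)
    rows = [
        {
            "effect": "stimulus",
            "F": float(f_b),
            "df1": 1,
            "df2": n - 1,
            "p": float(sps.f.sf(f_b, 1, n - 1)),
            "partial_eta_sq": float(f_b / (f_b + (n - 1))) if f_b > 0 else 0.0,
        },
        {
            "effect": "trial_x_stimulus",
            "F": float(f_ab),
            "df1": a - 1,
            "df2": (a - 1) * (n - 1),
            "p": float(sps.f.sf(f_ab, a - 1, (a - 1) * (n - 1))),
            "partial_eta_sq": float(f_ab * (a - 1) / (f_ab * (a - 1) + (a - 1) * (n - 1)))
            if f_ab > 0
            else 0.0,
        },
    ]
    return pd.DataFrame(rows).set_index("effect")
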