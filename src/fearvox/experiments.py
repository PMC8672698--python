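"""Simulation experiments that validate the inference machinery under the
study's conditions: null calibration of the permutation test, recovery of
a planted group effect, and end-to-end recovery of the conditioned pupil
response.  These are the package's standard self-checks; the test suite
and the acceptance script both run them.
"""

from __future__ import annotations

import numpy as np

from . import synthdata
from .design import TrialSchedule, build_trial_sequence
from .inference import GroupSample, permutation_test
from .pupil import PupilTimeSeries, _two_way_rm_f, process_subject
from .synthdata import GroundTruth


def fwer_calibration(
    n_datasets: int = 200,
    n_subjects: int = 12,
    n_perm: int = 500,
    shape: tuple = (8, 8, 6),
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Family-wise error rate of the sign-flip max-TFCE test under a
    global null (independent standard-normal copes).  Should sit at or
    just below ``alpha``."""
    rng = np.random.default_rng(seed)
    mask = np.ones(shape, bool)
    n_false = 0
    for _ in range(n_datasets):
        copes = rng.standard_normal((n_subjects, mask.sum()))
        sample = GroupSample(copes=copes, mask=mask)
        res = permutation_test(sample, n_perm=n_perm, alpha=alpha,
                               seed=int(rng.integers(2**31)))
        n_false += int(res.significant.any())
    return n_false / n_datasets


def planted_cube_recovery(
    n_seeds: int = 20,
    n_subjects: int = 16,
    n_perm: int = 1000,
    shape: tuple = (16, 16, 10),
    effect_d: float = 2.0,
    cube_half: int = 1,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[float, int]:
    """Sensitivity and false positives for a planted 27-voxel cube.

    Subject copes are unit-variance noise plus ``effect_d`` inside a
    3x3x3 cube (between-subject Cohen's d = 2).  Returns the fraction of
    cube voxels detected at FWER alpha (pooled over repetitions) and the
    total number of significant voxels outside a 1-voxel dilation of the
    cube (expected: none)."""
    from scipy import ndimage

    rng = np.random.default_rng(seed)
    mask = np.ones(shape, bool)
    center = tuple(s // 2 for s in shape)
    cube = synthdata._cube(shape, center, cube_half)
    dilated = ndimage.binary_dilation(
        cube, structure=ndimage.generate_binary_structure(3, 3)
    )
    n_hit = 0
    n_cube_total = 0
    n_false = 0
    for _ in range(n_seeds):
        copes = rng.standard_normal((n_subjects, mask.sum()))
        copes[:, cube[mask]] += effect_d
        sample = GroupSample(copes=copes, mask=mask)
        res = permutation_test(sample, n_perm=n_perm, alpha=alpha,
                               seed=int(rng.integers(2**31)))
        sig = res.significant
        n_hit += int(sig[cube].sum())
        n_cube_total += int(cube.sum())
        n_false += int(sig[~dilated].sum())
    return n_hit / n_cube_total, n_false


def pupil_interaction_power(
    n_sims: int = 100,
    n_subjects: int = 8,
    n_null: int = 99,
    schedule: TrialSchedule | None = None,
    seed: int = 0,
) -> float:
    """End-to-end power of the trial x stimulus interaction.

    Each simulation runs ``n_subjects`` synthetic traces (CS+ dilation
    amplitude growing linearly over trials, CS- flat — the acquisition
    pattern) through the full pupil pipeline and compares the observed
    interaction F with the 95th percentile of a stimulus-shuffled null
    (CS+/CS- labels swapped at random within subject and trial).
    Returns the fraction of simulations whose F beats the null."""
    schedule = schedule or build_trial_sequence(counterbalance_seed=seed)
    rng = np.random.default_rng(seed)
    n_trials = 13
    wins = 0
    for _ in range(n_sims):
        tables = []
        for _ in range(n_subjects):
            truth = GroundTruth(seed=int(rng.integers(2**31)))
            t_s, d, v = synthdata.simulate_pupil_trace(schedule, truth)
            table, _ = process_subject(PupilTimeSeries(t_s, d, v), schedule)
            piv = table.pivot(index="trial_index", columns="condition",
                              values="response")
            tables.append(piv[["csp", "csm"]].to_numpy())
        data = np.stack(tables)  # (n_subjects, 13, 2)
        _, f_obs = _two_way_rm_f(data)
        swap = rng.random((n_null, n_subjects, n_trials)) < 0.5
        null_data = np.where(swap[..., None], data[None, ..., ::-1],
                             data[None, ...])
        _, f_null = _two_way_rm_f(null_data)
        wins += int(f_obs > np.percentile(f_null, 95))
    return wins / n_sims
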