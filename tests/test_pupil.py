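import numpy as np
import pandas as pd
import pytest

from fearvox import pupil, synthdata
from fearvox.pupil import (
    PupilTimeSeries,
    average_face_house,
    clean_missing,
    extract_trial_response,
    flag_and_replace_trials,
    lowpass,
    trial_by_stimulus_anova,
    trial_loss_fractions,
    zscore_within_subject,
)


def make_ts(diameter, rate=250.0, valid=None):
    n = len(diameter)
    valid = np.ones(n, bool) if valid is None else valid
    return PupilTimeSeries(np.arange(n) / rate, np.asarray(diameter, float), valid)


class TestCleanMissing:
    def test_clean_trace_unchanged(self):
        ts = make_ts(np.sin(np.arange(1000) / 50))
        out = clean_missing(ts)
        np.testing.assert_array_equal(out.diameter, ts.diameter)
        assert out.valid.all()

    def test_padding_100ms_at_250hz(self):
        """A 10-sample gap at 250 Hz is padded by 25 samples (100 ms) on
        each side: 60 samples are treated as invalid in total."""
        valid = np.ones(1000, bool)
        valid[500:510] = False
        ts = make_ts(np.ones(1000), valid=valid)
        out = clean_missing(ts)
        assert (~out.valid).sum() == 60
        assert not out.valid[475:535].any()
        assert out.valid[474] and out.valid[535]

    def test_padding_scales_with_rate(self):
        valid = np.ones(2000, bool)
        valid[1000:1010] = False
        ts = make_ts(np.ones(2000), rate=500.0, valid=valid)
        out = clean_missing(ts)
        assert (~out.valid).sum() == 10 + 2 * 50

    def test_short_gap_interpolated_without_padding(self):
        valid = np.ones(200, bool)
        valid[100:105] = False  # below the 10-sample rule
        ramp = np.arange(200.0)
        data = ramp.copy()
        data[100:105] = -99.0
        ts = make_ts(data, valid=valid)
        out = clean_missing(ts)
        assert (~out.valid).sum() == 5
        np.testing.assert_allclose(out.diameter, ramp, atol=1e-10)

    def test_linear_ramp_reconstructed(self):
        """Linear interpolation is exact on a linear signal."""
        ramp = np.linspace(0, 10, 500)
        valid = np.ones(500, bool)
        valid[200:230] = False
        corrupted = ramp.copy()
        corrupted[200:230] = 0.0
        out = clean_missing(make_ts(corrupted, valid=valid))
        np.testing.assert_allclose(out.diameter, ramp, atol=1e-10)

    def test_edge_gap_constant_extension(self):
        valid = np.ones(300, bool)
        valid[:40] = False
        data = np.full(300, 5.0)
        data[:40] = 0.0
        out = clean_missing(make_ts(data, valid=valid))
        np.testing.assert_allclose(out.diameter, 5.0)

    def test_fully_invalid_trace_rejected(self):
        with pytest.raises(ValueError):
            clean_missing(make_ts(np.zeros(100), valid=np.zeros(100, bool)))


class TestLowpass:
    def test_constant_unchanged(self):
        ts = make_ts(np.full(1000, 3.3))
        out = lowpass(ts)
        np.testing.assert_allclose(out.diameter, 3.3, atol=1e-9)

    def test_passband_preserved(self):
        """0.5 Hz is well inside the 4 Hz passband: amplitude within 2%."""
        t = np.arange(5000) / 250.0
        ts = make_ts(np.sin(2 * np.pi * 0.5 * t))
        out = lowpass(ts)
        mid = out.diameter[1000:4000]
        assert mid.max() == pytest.approx(1.0, abs=0.02)

    def test_stopband_attenuated(self):
        """20 Hz is far above cutoff: residual amplitude below 10%."""
        t = np.arange(5000) / 250.0
        ts = make_ts(np.sin(2 * np.pi * 20.0 * t))
        out = lowpass(ts)
        assert np.abs(out.diameter[1000:4000]).max() < 0.1

    def test_cutoff_above_nyquist_rejected(self):
        ts = make_ts(np.zeros(100), rate=250.0)
        with pytest.raises(ValueError):
            lowpass(ts, cutoff_hz=130.0)


class TestExtractTrialResponse:
    def test_flat_trace_zero_response(self):
        ts = make_ts(np.full(3000, 2.0))
        resp, oob = extract_trial_response(ts, [5.0])
        assert resp[0] == 0.0 and not oob[0]

    def test_constructed_peak_minus_baseline(self):
        """Baseline mean 3.0, window max 3.7 -> response 0.7."""
        rate = 250.0
        d = np.full(3000, 3.0)
        onset = 4.0
        peak_idx = int((onset + 1.5) * rate)
        d[peak_idx:peak_idx + 50] = 3.7
        resp, _ = extract_trial_response(make_ts(d), [onset])
        assert resp[0] == pytest.approx(0.7)

    def test_window_outside_trace_flagged(self):
        ts = make_ts(np.ones(500))  # 2 s at 250 Hz
        resp, oob = extract_trial_response(ts, [0.2, 1.0])
        assert oob[0]  # baseline precedes trace start
        assert oob[1]  # response window runs past trace end
        assert np.isnan(resp).all()


class TestFlagAndReplace:
    def base_table(self, n_per=13):
        rows = []
        for cond in ("csp_face", "csm_face", "csp_house", "csm_house"):
            for i in range(1, n_per + 1):
                rows.append(
                    {"condition": cond, "trial_index": i,
                     "response": float(i), "base_loss": 0.0, "win_loss": 0.0}
                )
        return pd.DataFrame(rows)

    def test_no_missing_passthrough(self):
        out, excluded = flag_and_replace_trials(self.base_table())
        assert not excluded
        assert not out["missing"].any()
        assert not out["replaced"].any()

    def test_replacement_lies_on_line(self):
        """Responses on an exact line: the replacement for a missing
        trial falls on the same line."""
        table = self.base_table()
        table.loc[
            (table.condition == "csp_face") & (table.trial_index == 7),
            ["base_loss", "response"],
        ] = [0.9, np.nan]
        out, excluded = flag_and_replace_trials(table)
        row = out[(out.condition == "csp_face") & (out.trial_index == 7)]
        assert row["replaced"].item()
        assert row["response"].item() == pytest.approx(7.0)
        assert not excluded

    def test_loss_must_exceed_half(self):
        table = self.base_table()
        sel = (table.condition == "csm_face") & (table.trial_index == 3)
        table.loc[sel, "win_loss"] = 0.5  # exactly half: kept
        out, _ = flag_and_replace_trials(table)
        assert not out.loc[sel, "missing"].item()
        table.loc[sel, "win_loss"] = 0.51
        out, _ = flag_and_replace_trials(table)
        assert out.loc[sel, "missing"].item()

    @pytest.mark.parametrize("n_missing,expect_excluded", [(17, False), (18, True)])
    def test_exclusion_threshold_one_third(self, n_missing, expect_excluded):
        """18 of 52 missing trials (>= 1/3) excludes the subject; 17 does
        not."""
        table = self.base_table()
        table.loc[: n_missing - 1, "base_loss"] = 1.0
        _, excluded = flag_and_replace_trials(table)
        assert excluded is expect_excluded

    def test_sparse_condition_mean_fallback(self):
        table = self.base_table(n_per=3)
        sel = table.condition == "csp_house"
        table.loc[sel & (table.trial_index > 1), "base_loss"] = 1.0
        with pytest.warns(UserWarning, match="condition mean"):
            out, _ = flag_and_replace_trials(table)
        replaced = out[sel & (out.trial_index > 1)]["response"]
        np.testing.assert_allclose(replaced, 1.0)


class TestZscore:
    def trial_frame(self, values):
        return pd.DataFrame(
            {"condition": ["csp"] * len(values), "trial_index":
             range(1, len(values) + 1), "response": values}
        )

    def test_mean_zero_sd_one(self):
        rng = np.random.default_rng(0)
        out = zscore_within_subject(self.trial_frame(rng.normal(2, 5, 26)))
        assert out["response"].mean() == pytest.approx(0.0, abs=1e-10)
        assert out["response"].std(ddof=1) == pytest.approx(1.0, abs=1e-10)

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=26)
        z1 = zscore_within_subject(self.trial_frame(x))["response"]
        z2 = zscore_within_subject(self.trial_frame(3.0 * x + 7.0))["response"]
        np.testing.assert_allclose(z1, z2, atol=1e-10)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=26)
        z = zscore_within_subject(self.trial_frame(x))["response"].to_numpy()
        np.testing.assert_allclose(z, (x - x.mean()) / x.std(ddof=1), atol=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            zscore_within_subject(self.trial_frame(np.ones(26)))


class TestAverageFaceHouse:
    def test_face_house_collapse(self):
        rows = []
        for cond, r in [("csp_face", 1.0), ("csp_house", 3.0),
                        ("csm_face", 0.0), ("csm_house", 2.0)]:
            rows.append({"condition": cond, "trial_index": 1, "response": r})
        out = average_face_house(pd.DataFrame(rows))
        assert out[out.condition == "csp"]["response"].item() == 2.0
        assert out[out.condition == "csm"]["response"].item() == 1.0


class TestTrialByStimulusAnova:
    def test_identical_conditions_zero_f(self):
        rng = np.random.default_rng(3)
        per_trial = rng.normal(size=(1, 13, 1))
        data = np.tile(per_trial, (10, 1, 2))
        res = trial_by_stimulus_anova(data)
        assert res.loc["stimulus", "F"] == pytest.approx(0.0, abs=1e-20)
        assert res.loc["trial_x_stimulus", "F"] == pytest.approx(0.0, abs=1e-20)

    def test_interaction_df_at_n76_and_n77(self):
        rng = np.random.default_rng(4)
        for n, df2 in [(76, 900), (77, 912)]:
            res = trial_by_stimulus_anova(rng.normal(size=(n, 13, 2)))
            assert res.loc["trial_x_stimulus", "df1"] == 12
            assert res.loc["trial_x_stimulus", "df2"] == df2
            assert res.loc["stimulus", "df2"] == n - 1

    def test_matches_statsmodels_oracle(self):
        from statsmodels.stats.anova import AnovaRM

        rng = np.random.default_rng(5)
        data = rng.normal(size=(9, 13, 2))
        res = trial_by_stimulus_anova(data)
        rows = [
            {"subj": s, "trial": i, "stim": j, "y": data[s, i, j]}
            for s in range(9) for i in range(13) for j in range(2)
        ]
        ref = AnovaRM(pd.DataFrame(rows), "y", "subj",
                      within=["trial", "stim"]).fit().anova_table
        assert res.loc["stimulus", "F"] == pytest.approx(
            ref.loc["stim", "F Value"]
        )
        assert res.loc["trial_x_stimulus", "F"] == pytest.approx(
            ref.loc["trial:stim", "F Value"]
        )

    def test_partial_eta_sq_formula(self):
        rng = np.random.default_rng(6)
        res = trial_by_stimulus_anova(rng.normal(size=(12, 13, 2)))
        f = res.loc["trial_x_stimulus", "F"]
        assert res.loc["trial_x_stimulus", "partial_eta_sq"] == pytest.approx(
            f * 12 / (f * 12 + 12 * 11)
        )

    def test_incomplete_table_rejected(self):
        data = np.random.default_rng(7).normal(size=(5, 13, 2))
        data[2, 4, 1] = np.nan
        with pytest.raises(ValueError):
            trial_by_stimulus_anova(data)


class TestPipeline:
    def test_pipeline_order_matters(self, default_schedule):
        """Filtering before cleaning smears blink artifacts into valid
        samples; the fixed order (clean, then filter) avoids that."""
        truth = synthdata.GroundTruth.default(seed=21)
        t_s, d, v = synthdata.simulate_pupil_trace(
            default_schedule, truth, seed=22, blink_rate_per_min=12.0
        )
        ts = PupilTimeSeries(t_s, d, v)
        onsets = np.array([t.onset_s for t in default_schedule.trials])
        proper = extract_trial_response(lowpass(clean_missing(ts)), onsets)[0]
        swapped = extract_trial_response(clean_missing(lowpass(ts)), onsets)[0]
        assert not np.allclose(proper, swapped, atol=1e-3)

    def test_end_to_end_recovery(self, default_schedule):
        """Planted CS+ > CS- amplitudes survive the full pipeline."""
        truth = synthdata.GroundTruth.default(seed=23)
        t_s, d, v = synthdata.simulate_pupil_trace(default_schedule, truth,
                                                   seed=24)
        table, excluded = pupil.process_subject(
            PupilTimeSeries(t_s, d, v), default_schedule
        )
        assert not excluded
        means = table.groupby("condition")["response"].mean()
        assert means["csp"] > means["csm"]
        # z-scoring: mean 0, sd 1 across the 26 trials
        assert table["response"].mean() == pytest.approx(0.0, abs=1e-10)
        assert table["response"].std(ddof=1) == pytest.approx(1.0, abs=1e-10)

    def test_loss_fractions_use_precleaning_validity(self):
        rate = 250.0
        n = 3000
        valid = np.ones(n, bool)
        onset = 6.0
        i0 = int(onset * rate)
        valid[i0 + 10:i0 + 10 + 600] = False  # 2.4 s of the 4 s window
        base_loss, win_loss = trial_loss_fractions(
            valid, np.arange(n) / rate, [onset]
        )
        assert base_loss[0] == 0.0
        assert win_loss[0] == pytest.approx(0.6, abs=0.01)
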