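"""Synthetic EEG and cohort generators: determinism, rendering, planted paths."""

import numpy as np
import pytest
from scipy import stats as sst

import sleepmicro as sm
from sleepmicro.filters import bandpass_spindle


class TestGenerateEEG:
    def test_construction_returns_planned_truth(self):
        plan = [sm.spindle_event("C3", 30.0 * i + 10, 1.0, 30.0, 12.0)
                for i in range(5)]
        rec, hyp, truth = sm.generate_eeg(300.0, 256.0, ["F3", "C3"], plan,
                                          seed=0)
        assert len(truth) == 5
        assert rec.duration_s == 300.0
        assert hyp.n_epochs == 10
        assert all(t.kind == "spindle" for t in truth)

    def test_zero_noise_empty_plan_is_silent(self):
        rec, _, truth = sm.generate_eeg(60.0, 128.0, ["F3", "C3"],
                                        background_noise_sd=0.0, seed=0)
        assert truth == []
        assert np.all(rec.data == 0.0)

    def test_seed_determinism_bit_identical(self):
        plan = [sm.so_event("F3", 40.0)]
        r1, _, _ = sm.generate_eeg(120.0, 128.0, ["F3", "C3"], plan, seed=7)
        r2, _, _ = sm.generate_eeg(120.0, 128.0, ["F3", "C3"], plan, seed=7)
        assert np.array_equal(r1.data, r2.data)
        r3, _, _ = sm.generate_eeg(120.0, 128.0, ["F3", "C3"], plan, seed=8)
        assert not np.array_equal(r1.data, r3.data)

    def test_event_outside_recording_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            sm.generate_eeg(60.0, 128.0, ["F3", "C3"],
                            [sm.spindle_event("C3", 59.5, 1.0)], seed=0)

    def test_event_in_wake_epoch_rejected(self):
        with pytest.raises(ValueError, match="N2/N3"):
            sm.generate_eeg(60.0, 128.0, ["F3", "C3"],
                            [sm.spindle_event("C3", 10.0, 1.0)],
                            stages=["W", "N2"], seed=0)

    def test_requires_central_and_frontal(self):
        with pytest.raises(ValueError, match="frontal"):
            sm.generate_eeg(60.0, 128.0, ["C3", "C4"], seed=0)
        with pytest.raises(ValueError, match="central"):
            sm.generate_eeg(60.0, 128.0, ["F3", "F4"], seed=0)

    def test_ground_truth_invariants(self):
        with pytest.raises(ValueError, match="9-16"):
            sm.GroundTruthEvent("spindle", "C3", 0.0, 1.0, 30.0, 5.0)
        with pytest.raises(ValueError, match=r"\(0, 1.25\]"):
            sm.GroundTruthEvent("SO", "F3", 0.0, 1.0, 150.0, 2.0)

    def test_injected_spindle_raises_sigma_band_power(self):
        """Band-limited 9-16 Hz power over a spindle window exceeds an
        adjacent event-free window when PTP >= 5x the noise SD."""
        plan = [sm.spindle_event("C3", 40.0, 1.0, amplitude_uv=25.0)]
        rec, _, _ = sm.generate_eeg(120.0, 256.0, ["F3", "C3"], plan,
                                    background_noise_sd=5.0, seed=3)
        filt = bandpass_spindle(rec.get("C3"), 256.0)
        ev = np.mean(filt[int(40 * 256):int(41 * 256)] ** 2)
        ref = np.mean(filt[int(50 * 256):int(51 * 256)] ** 2)
        assert ev > ref

    def test_rendered_spindle_ptp_close_to_plan(self):
        plan = [sm.spindle_event("C3", 40.0, 1.0, amplitude_uv=40.0)]
        rec, _, _ = sm.generate_eeg(120.0, 256.0, ["F3", "C3"], plan,
                                    background_noise_sd=0.0, seed=0)
        seg = rec.get("C3")[int(40 * 256):int(41 * 256)]
        assert seg.max() - seg.min() == pytest.approx(40.0, rel=0.05)

    def test_rendered_so_spans_pnzc_with_planned_amplitude(self):
        plan = [sm.so_event("F3", 60.0, freq_hz=0.8, amplitude_uv=150.0)]
        rec, _, _ = sm.generate_eeg(120.0, 256.0, ["F3", "C3"], plan,
                                    background_noise_sd=0.0, seed=0)
        seg = rec.get("F3")[int(60 * 256):int(61.25 * 256)]
        assert seg.max() - seg.min() == pytest.approx(150.0, rel=0.02)
        assert seg[1] < 0 and seg[-1] > 0  # trough phase first, peak second

    def test_flatline_artifact_zeroes_signal(self):
        arts = [sm.ArtifactSpec("flatline", "C3", 30.0, 3.0)]
        rec, _, _ = sm.generate_eeg(90.0, 128.0, ["F3", "C3"],
                                    artifact_plan=arts,
                                    background_noise_sd=5.0, seed=4)
        assert np.all(rec.get("C3")[int(30 * 128):int(33 * 128)] == 0.0)
        assert np.any(rec.get("C3")[: int(30 * 128)] != 0.0)


class TestGenerateCohort:
    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            sm.CohortConfig(n=0)
        with pytest.raises(ValueError):
            sm.CohortConfig(n=10, noise_sd=0.0)

    def test_determinism_bit_identical(self):
        cfg = sm.CohortConfig(n=200, a_path=0.3, seed=42)
        t1, t2 = sm.generate_cohort(cfg), sm.generate_cohort(cfg)
        assert t1.equals(t2)

    def test_null_config_no_exposure_outcome_correlation(self):
        t = sm.generate_cohort(sm.CohortConfig(n=2000, seed=0))
        r = np.corrcoef(t["exposure"], t["outcome"])[0, 1]
        assert abs(r) < 3 / np.sqrt(len(t))
        # metrics independent of cognition under the null
        r2 = np.corrcoef(t["sp_density"], t["mmse_36"])[0, 1]
        assert abs(r2) < 4 / np.sqrt(len(t))

    def test_ols_path_recovery(self):
        """OLS on the generated table recovers the planted paths."""
        t = sm.generate_cohort(sm.CohortConfig(n=5000, a_path=0.5, b_path=0.4,
                                               c_prime=0.2, seed=3))
        a = np.polyfit(t["exposure"], t["mediator"], 1)[0]
        X = np.column_stack([np.ones(len(t)), t["exposure"], t["mediator"]])
        coef, *_ = np.linalg.lstsq(X, t["outcome"], rcond=None)
        assert a == pytest.approx(0.5, abs=0.05)
        assert coef[2] == pytest.approx(0.4, abs=0.05)
        assert coef[1] == pytest.approx(0.2, abs=0.05)

    def test_moment_convergence_large_n(self):
        """Configured structural moments recovered within 3 SEs at n=10000."""
        n = 10_000
        t = sm.generate_cohort(sm.CohortConfig(n=n, a_path=0.5, b_path=0.4,
                                               c_prime=0.2, gamma=0.3, seed=9))
        se = 1 / np.sqrt(n)
        assert np.mean(t["exposure"]) == pytest.approx(0.0, abs=3 * se)
        assert np.std(t["exposure"]) == pytest.approx(1.0, abs=3 * se)
        X = np.column_stack([np.ones(n), t["exposure"], t["mediator"],
                             t["exposure"] * t["moderator"]])
        coef, *_ = np.linalg.lstsq(X, t["outcome"], rcond=None)
        # OLS SEs ~ noise_sd/sqrt(n) for standardized regressors
        assert coef[1] == pytest.approx(0.2, abs=3 * se)
        assert coef[2] == pytest.approx(0.4, abs=3 * se)
        assert coef[3] == pytest.approx(0.3, abs=3 * se)

    def test_skew_rejects_normality(self):
        t = sm.generate_cohort(sm.CohortConfig(n=500, skew=2.0, seed=5))
        assert sst.shapiro(t["abeta42"]).pvalue < 0.05
        assert sst.skew(t["abeta42"]) > 0  # right-skewed

    def test_unskewed_biomarker_roughly_normal(self):
        t = sm.generate_cohort(sm.CohortConfig(n=500, seed=5))
        assert sst.shapiro(t["abeta42"]).pvalue > 0.001

    def test_clinical_anchors(self):
        t = sm.generate_cohort(sm.CohortConfig(n=4000, seed=1))
        assert np.mean(t["age"]) == pytest.approx(74.7, abs=0.5)
        assert np.median(t["abeta42"]) == pytest.approx(516, rel=0.05)
        assert np.mean(t["mmse_0"]) == pytest.approx(23.2, abs=0.3)
        assert set(t["sex"]) == {0, 1}
        assert (t["ratio_ptau_abeta42"]
                == t["ptau181"] / t["abeta42"]).all()

    def test_decline_generator_controls_indicator(self):
        t = sm.generate_cohort(sm.CohortConfig(n=3000, seed=2,
                                               decline_beta=-1.0))
        assert t["mmse_decline"].mean() < 0.3  # strongly suppressed odds
        t0 = sm.generate_cohort(sm.CohortConfig(n=3000, seed=2,
                                                decline_beta=0.0))
        # intercept -0.5 alone: P(decline) = sigmoid(-0.5) ~ 0.38
        assert t0["mmse_decline"].mean() == pytest.approx(0.378, abs=0.03)
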