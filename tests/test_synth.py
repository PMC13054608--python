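"""Generator checks: calibration, waveform synthesis, cohort structure."""

import numpy as np
import pandas as pd
import pytest

from freqtagsl import blocks as blocks_mod
from freqtagsl import synth
from freqtagsl.aggregate import combined_snr
from freqtagsl.channels import OCCIPITAL_APRIORI
from freqtagsl.paradigm import InvalidInputError
from freqtagsl.spectral import amplitude_spectrum, snr_spectrum
from freqtagsl.synth import (
    GenerativeParams,
    calibrate_amplitude,
    rice_mean,
    simulate_block_eeg,
    simulate_cohort,
    simulate_test_behaviour,
)


class TestCalibrateAmplitude:
    SIGMA = 0.7

    @property
    def floor(self):
        return rice_mean(0.0, self.SIGMA)

    def test_unit_target_needs_no_signal(self):
        assert calibrate_amplitude(1.0, self.floor, self.SIGMA) == 0.0

    def test_strictly_increasing_in_target(self):
        amps = [calibrate_amplitude(s, self.floor, self.SIGMA)
                for s in np.linspace(1.05, 6.0, 12)]
        assert np.all(np.diff(amps) > 0)

    def test_matches_monte_carlo_oracle(self):
        # oracle: 1e5 draws of |a e^{i phi} + Z|
        a = calibrate_amplitude(3.0, self.floor, self.SIGMA)
        rng = np.random.default_rng(0)
        z = rng.normal(0, self.SIGMA, (100_000, 2))
        measured = np.abs(a + z[:, 0] + 1j * z[:, 1]).mean() / self.floor
        assert measured == pytest.approx(3.0, rel=0.01)

    def test_sub_unit_target_rejected(self):
        with pytest.raises(InvalidInputError):
            calibrate_amplitude(0.9, self.floor, self.SIGMA)

    def test_noise_free_limit(self):
        assert calibrate_amplitude(2.0, 0.5, 0.0) == pytest.approx(1.0)


class TestSimulateBlockEEG:
    def test_seeded_call_is_bit_identical(self):
        p = GenerativeParams()
        a = simulate_block_eeg(p, {}, 0.3, 0.15, np.random.default_rng(7))
        b = simulate_block_eeg(p, {}, 0.3, 0.15, np.random.default_rng(7))
        assert np.array_equal(a.data, b.data)
        assert a.data.shape == (128, 20000)

    def test_local_maxima_at_harmonic_bins(self):
        p = GenerativeParams()
        blk = simulate_block_eeg(p, {}, 0.9, 0.8, np.random.default_rng(3))
        spec = amplitude_spectrum(blk)
        occ = np.array(OCCIPITAL_APRIORI) - 1
        mean_amp = spec.amp[occ].mean(axis=0)
        for f in synth.CANDIDATE_FREQS:
            k = spec.bin_of(f)
            assert mean_amp[k] > mean_amp[k - 1]
            assert mean_amp[k] > mean_amp[k + 1]

    def test_measured_log_base_snr_hits_target(self):
        # generative value 0.302 recovered through the spectral chain
        p = GenerativeParams()
        vals = []
        for i in range(80):
            blk = simulate_block_eeg(p, {}, 0.302, 0.152, np.random.default_rng(900 + i))
            snr = snr_spectrum(amplitude_spectrum(blk))
            vals.append(np.log(combined_snr(snr, OCCIPITAL_APRIORI, synth.BASE_HARMONICS)))
        assert np.mean(vals) == pytest.approx(0.302, abs=0.03)

    def test_zero_doublet_signal_measures_unit_snr(self):
        p = GenerativeParams()
        vals = []
        for i in range(60):
            blk = simulate_block_eeg(p, {}, 0.302, 0.0, np.random.default_rng(50 + i),
                                     gain=None)
            snr = snr_spectrum(amplitude_spectrum(blk))
            vals.append(combined_snr(snr, OCCIPITAL_APRIORI, synth.DOUBLET_HARMONICS))
        assert 0.95 <= np.mean(vals) <= 1.10

    def test_scaling_all_channel_gains_leaves_snr_unchanged(self):
        p = GenerativeParams()
        gain = synth.channel_gain_map()
        a = simulate_block_eeg(p, {}, 0.5, 0.3, np.random.default_rng(2), gain=gain)
        b = simulate_block_eeg(p, {}, 0.5, 0.3, np.random.default_rng(2), gain=3.0 * gain)
        sa = snr_spectrum(amplitude_spectrum(a))
        sb = snr_spectrum(amplitude_spectrum(b))
        assert np.allclose(sa.snr[:, sa.valid], sb.snr[:, sb.valid], rtol=1e-9)


class TestSimulateCohort:
    def test_default_cohort_has_80_sessions(self, fast_cohort):
        assert len(fast_cohort.sessions) == 80
        counts = fast_cohort.sessions.groupby("timepoint").size()
        assert counts.to_dict() == {"T1": 30, "T2": 27, "T3": 23}

    def test_attrition_is_monotone(self, fast_cohort):
        roster = {
            tp: set(g.subject_id)
            for tp, g in fast_cohort.sessions.groupby("timepoint")
        }
        assert roster["T3"] <= roster["T2"] <= roster["T1"]

    def test_deterministic_under_master_seed(self):
        a = simulate_cohort(master_seed=5, mode="fast")
        b = simulate_cohort(master_seed=5, mode="fast")
        pd.testing.assert_frame_equal(a.blocks, b.blocks)
        pd.testing.assert_frame_equal(a.tests, b.tests)

    def test_long_run_valid_fraction_matches_configured_rate(self):
        # pooled over cohorts: binomial error well inside +/- 2 points
        n_valid = n_rec = 0
        for s in range(6):
            c = simulate_cohort(master_seed=100 + s, mode="fast")
            rep = blocks_mod.finalize_block_table(c.blocks).attrs["filter_report"]
            n_valid += rep["n_valid"]
            n_rec += rep["n_recorded"]
        assert n_valid / n_rec == pytest.approx(0.7642, abs=0.02)

    def test_block_counts_within_protocol_bounds(self, fast_cohort):
        assert fast_cohort.sessions.n_blocks_shown.between(8, 15).all()
        per = fast_cohort.blocks.groupby(["subject_id", "timepoint"]).size()
        assert per.between(8, 15).all()


class TestSimulateTestBehaviour:
    def test_noise_free_link_evaluates_exactly(self):
        p = GenerativeParams()
        quiet = synth.BehaviourLink(
            slopes=p.behaviour.slopes, intercepts=p.behaviour.intercepts,
            trial_sd_s=0.0,
        )
        params = GenerativeParams(behaviour=quiet)
        trials = simulate_test_behaviour(params, 0.2, "T3", np.random.default_rng(0))
        novel = trials[trials.trial_type == "novel"].looking_s.mean()
        familiar = trials[trials.trial_type == "familiar"].looking_s.mean()
        assert novel - familiar == pytest.approx(4.421 * 0.2 + 0.484)

    def test_null_link_gives_zero_preference(self):
        null = synth.BehaviourLink(
            slopes={"T1": 0, "T2": 0, "T3": 0},
            intercepts={"T1": 0, "T2": 0, "T3": 0}, trial_sd_s=0.0,
        )
        params = GenerativeParams(behaviour=null)
        trials = simulate_test_behaviour(params, 0.7, "T2", np.random.default_rng(0))
        assert trials.looking_s.nunique() == 1

    def test_regression_recovers_generating_slope(self):
        # 500 simulated T3 subjects: fitted preference-on-LI slope within
        # 2 SE of the generating 4.421
        p = GenerativeParams()
        rng = np.random.default_rng(8)
        # learning-index distribution as in a default cohort at T3
        li = rng.normal(-0.07, 0.15, 500)
        prefs = []
        for x in li:
            tr = simulate_test_behaviour(p, float(x), "T3", rng)
            prefs.append(
                tr[tr.trial_type == "novel"].looking_s.mean()
                - tr[tr.trial_type == "familiar"].looking_s.mean()
            )
        slope, intercept = np.polyfit(li, prefs, 1)
        resid = np.array(prefs) - (slope * li + intercept)
        se = resid.std(ddof=2) / (li.std(ddof=1) * np.sqrt(len(li)))
        assert abs(slope - 4.421) < 2 * se


class TestNullTopographies:
    def test_shape_and_positive(self, rng):
        topo = synth.null_snr_topographies(7, n_blocks=3, rng=rng)
        assert topo.shape == (7, 128)
        assert (topo > 0).all()

    def test_null_mean_slightly_above_one(self):
        # E[|Z0| / mean|Z_1..10|] = 1.027...: the neighbour-ratio bias
        topo = synth.null_snr_topographies(200, n_blocks=8,
                                           rng=np.random.default_rng(0))
        assert topo.mean() == pytest.approx(1.027, abs=0.01)
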