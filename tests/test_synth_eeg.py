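from dataclasses import replace

import numpy as np
import pytest
from scipy import signal as sg

from chordaffect import band_dynamics as bd
from chordaffect import chord_stimuli as cs
from chordaffect import synth_eeg as se
from chordaffect.preprocess import epoch_and_baseline


class TestLRTCSeries:
    def test_determinism(self):
        a = se.gen_lrtc_series(2**13, 0.7, 42)
        b = se.gen_lrtc_series(2**13, 0.7, 42)
        assert np.array_equal(a, b)

    def test_white_noise_limit(self):
        vals = [
            bd.dfa_exponent(se.gen_lrtc_series(2**17, 0.5, s), 250.0)[0]
            for s in range(3)
        ]
        assert abs(np.mean(vals) - 0.50) < 0.03

    def test_h07_recovery(self):
        vals = [
            bd.dfa_exponent(se.gen_lrtc_series(2**17, 0.7, s), 250.0)[0]
            for s in range(3)
        ]
        assert abs(np.mean(vals) - 0.70) < 0.05

    def test_invalid_h_rejected(self):
        for h in (0.0, 1.0, -0.2, 1.5):
            with pytest.raises(ValueError):
                se.gen_lrtc_series(2**13, h, 0)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            se.gen_lrtc_series(100, 0.5, 0)

    def test_standardised(self):
        x = se.gen_lrtc_series(2**14, 0.6, 3)
        assert abs(x.mean()) < 1e-12
        assert x.std() == pytest.approx(1.0)

    def test_envelope_dfa_preserved_after_positivity_transform(self):
        # raw fGn within +-0.05 and exponential envelopes within +-0.10
        raw, env = [], []
        for s in range(20):
            g = se.gen_lrtc_series(2**16, 0.7, s)
            raw.append(bd.dfa_exponent(g, 250.0)[0])
            e = se.lrtc_envelope(2**16, 0.7, 2.0, 0.4, s)
            env.append(bd.dfa_exponent(e, 250.0)[0])
        assert abs(np.mean(raw) - 0.7) < 0.05
        assert abs(np.mean(env) - 0.7) < 0.10
        assert all(e > 0 for e in (np.min(env),))


class TestBandOscillation:
    def test_power_concentrated_in_band(self):
        env = np.ones(50_000)
        x = se.gen_band_oscillation((8.0, 12.0), env, 250.0, 0)
        freqs, psd = sg.periodogram(x, fs=250.0)
        frac = psd[(freqs >= 7) & (freqs <= 13)].sum() / psd.sum()
        assert frac >= 0.80

    def test_zero_envelope_gives_zero_signal(self):
        x = se.gen_band_oscillation((8.0, 12.0), np.zeros(5000), 250.0, 0)
        assert np.all(x == 0)

    def test_envelope_recovered_by_hilbert(self):
        # modulation must sit inside the band's bandwidth to be recoverable
        n = 60_000
        env = se.lrtc_envelope(
            n, 0.7, 3.0, 1.0, 1, sample_rate=250.0, smooth_hz=0.5
        )
        x = se.gen_band_oscillation((8.0, 12.0), env, 250.0, 2)
        rec = bd.band_envelope(x, bd.ALPHA, 250.0)
        r = np.corrcoef(rec, env)[0, 1]
        assert r > 0.8

    def test_band_beyond_nyquist_rejected(self):
        with pytest.raises(ValueError):
            se.gen_band_oscillation((100.0, 130.0), np.ones(1000), 250.0, 0)


class TestERPTemplate:
    def test_dissonant_exceeds_neutral_in_late_window(self, montage, truth):
        t = se.template_times_ms(truth, 250.0)
        sel = (t >= 290) & (t <= 310)
        diss = se.gen_erp_template("dissonant", montage, truth, 250.0)
        neut = se.gen_erp_template("neutral", montage, truth, 250.0)
        assert np.abs(diss[:, sel]).max() > np.abs(neut[:, sel]).max()

    def test_zero_amplitude_truth_gives_zero_kernel(self, montage, truth):
        zero = truth.scaled(erp_gain=0.0)
        tmpl = se.gen_erp_template("dissonant", montage, zero, 250.0)
        assert np.all(tmpl == 0)

    def test_peak_latency_matches_component(self, montage, truth):
        tmpl = se.gen_erp_template("dissonant", montage, truth, 250.0)
        t = se.template_times_ms(truth, 250.0)
        pz = montage.index("Pz")
        sel = (t >= 250) & (t <= 350)
        peak_t = t[sel][np.argmax(tmpl[pz, sel])]
        assert abs(peak_t - 300.0) <= 1000.0 / 250.0

    def test_unknown_condition_rejected(self, montage, truth):
        with pytest.raises(ValueError):
            se.gen_erp_template("weird", montage, truth, 250.0)


@pytest.fixture(scope="module")
def chord_only_schedule():
    specs = [
        s for s in cs.build_stimulus_set()
        if s.chord.category is not cs.ChordCategory.neutral_click
    ]
    return cs.make_schedule(specs, repetitions=1, seed=3)


class TestSimulateRecording:
    def test_event_count_matches_schedule(self, montage, truth, schedule):
        quiet = replace(
            truth.scaled(noise_gain=0.0), bands=tuple()
        )
        rec = se.simulate_recording(montage, schedule, quiet, 0)
        assert len(rec.events) == 210
        assert rec.sfreq == 500.0
        assert rec.n_channels == 64

    def test_noise_free_epochs_equal_template(self, montage, truth, chord_only_schedule):
        quiet = replace(truth.scaled(noise_gain=0.0), bands=tuple())
        rec = se.simulate_recording(montage, chord_only_schedule, quiet, 0)
        epochs = epoch_and_baseline(rec)
        for cond in ("consonant", "dissonant"):
            tmpl = se.gen_erp_template(cond, montage, quiet, 500.0)
            sel = [i for i, c in enumerate(epochs.conditions) if c == cond]
            avg = epochs.data[sel].mean(axis=0)
            assert np.allclose(avg, tmpl, atol=1e-6)

    def test_linearity_in_erp_gain(self, montage, truth, chord_only_schedule):
        quiet = replace(truth.scaled(noise_gain=0.0), bands=tuple())
        scaled = quiet.scaled(erp_gain=3.0)
        rec1 = se.simulate_recording(montage, chord_only_schedule, quiet, 0)
        rec3 = se.simulate_recording(montage, chord_only_schedule, scaled, 0)
        assert np.allclose(rec3.data, 3.0 * rec1.data, atol=1e-9)

    def test_snr_improves_with_trial_count(self, montage, truth):
        tmpl = se.gen_erp_template("dissonant", montage, truth, 250.0)
        corrs = []
        for n_trials in (2, 10, 60):
            ep, labels, _ = se.simulate_epochs(
                montage, truth, n_trials, seed=5, conditions=("dissonant",)
            )
            avg = ep.mean(axis=0)
            corrs.append(np.corrcoef(avg.ravel(), tmpl.ravel())[0, 1])
        assert corrs[0] < corrs[1] < corrs[2]

    def test_empty_schedule_rejected(self, montage, truth):
        empty = cs.Schedule(trials=(), repetitions=1, seed=0)
        with pytest.raises(ValueError):
            se.simulate_recording(montage, empty, truth, 0)


class TestBehaviour:
    def test_bookkeeping_accuracy_equals_congruency(self, schedule, truth):
        df = se.simulate_behaviour(schedule, truth, 0.0, 0)
        assert (df["accuracy"] == df["congruent"]).all()
        assert (df["rt_ms"] > 0).all()
        assert set(df["response"]) <= set(se.RESPONSES)

    def test_deterministic_accuracy_when_intercept_huge(self, schedule, truth):
        beh = replace(truth.behaviour, intercept=50.0, beta_dissonant=0.0,
                      beta_neutral=0.0, beta_predictor=0.0, beta_dissonant_x=0.0,
                      beta_neutral_x=0.0, sd_subject_intercept=0.0,
                      sd_subject_slope=0.0, sd_item_intercept=0.0)
        t = replace(truth, behaviour=beh)
        df = se.simulate_behaviour(schedule, t, 0.0, 1)
        assert df["congruent"].all()

    def test_rt_mean_matches_published_value(self, schedule, truth):
        frames = se.simulate_trial_tables(
            schedule, truth, np.zeros(30), 2
        )
        sel = (frames["stimulus_type"] == "dissonant") & frames["congruent"]
        mean_rt = frames.loc[sel, "rt_ms"].mean()
        assert abs(mean_rt - 522.0) / 522.0 < 0.05

    def test_accuracy_rates_match_model_probabilities(self, schedule, truth):
        from scipy.special import expit

        beh = replace(truth.behaviour, sd_subject_intercept=0.0,
                      sd_subject_slope=0.0, sd_item_intercept=0.0)
        t = replace(truth, behaviour=beh)
        frames = se.simulate_trial_tables(schedule, t, np.zeros(40), 3)
        for cond in se.CONDITIONS:
            p_true = expit(beh.accuracy_logit(cond, 0.0))
            sub = frames[frames["stimulus_type"] == cond]
            n = len(sub)
            rate = sub["accuracy"].mean()
            # 4-sigma binomial interval
            assert abs(rate - p_true) < 4 * np.sqrt(p_true * (1 - p_true) / n)

    def test_invalid_probability_table_rejected(self):
        with pytest.raises(ValueError):
            se.BehaviourTruth(
                response_probs={
                    "consonant": {"pleasant": 0.5, "neutral": 0.2, "unpleasant": 0.2},
                    "dissonant": {"pleasant": 0.1, "neutral": 0.2, "unpleasant": 0.7},
                    "neutral": {"pleasant": 0.1, "neutral": 0.8, "unpleasant": 0.1},
                }
            )

    def test_determinism(self, schedule, truth):
        a = se.simulate_behaviour(schedule, truth, 0.3, 9)
        b = se.simulate_behaviour(schedule, truth, 0.3, 9)
        assert a.equals(b)
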