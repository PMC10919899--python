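"""Stimulus battery, preprocessing chain, and synthetic recordings."""

import numpy as np
import pytest

from vorloop.circuit import simulate_closed_loop
from vorloop.fitting import fit_sine
from vorloop.synth import (
    NoiseSpec,
    cycle_average,
    dataset2_frequencies,
    desaccade,
    fold_ipsi_contra,
    generate_dataset2,
    generate_recordings,
    generate_stimulus_battery,
    hgvp_select,
    learning_targets,
    preprocess_rate,
    true_circuit_params,
)

DT = 5e-4


class TestStimulusBattery:
    def test_exactly_25_conditions(self):
        assert len(generate_stimulus_battery()) == 25

    def test_class_counts(self):
        batt = generate_stimulus_battery()
        by_class = {}
        for c in batt:
            by_class.setdefault(c.name.split("_")[0], []).append(c)
        assert len(by_class["vord"]) == 8
        assert len(by_class["x2"]) == 8
        assert len(by_class["x0"]) == 8
        assert len(by_class["pursuit"]) == 1

    def test_pursuit_amplitude_and_frequency(self):
        c = next(c for c in generate_stimulus_battery()
                 if c.name.startswith("pursuit"))
        assert c.frequency == 0.5
        assert abs(np.max(np.abs(c.T)) - 31.4) < 1e-6
        assert np.all(c.H == 0)

    def test_cancellation_and_x2_target_identities(self):
        for c in generate_stimulus_battery():
            if c.name.startswith("x0"):
                assert np.max(np.abs(c.T - c.H)) == 0
            elif c.name.startswith("x2"):
                assert np.max(np.abs(c.T + c.H)) == 0
            elif c.name.startswith("vord"):
                assert not c.lights

    def test_dark_conditions_produce_zero_slip_regardless_of_eye(self):
        truth = true_circuit_params()["pre"]
        c = next(c for c in generate_stimulus_battery()
                 if c.name == "vord_sine_2.0")
        tr = simulate_closed_loop(truth, c)
        assert np.all(tr.R == 0)


class TestLearningTargets:
    def test_printed_constants(self):
        t = learning_targets()
        assert (t.sine_decrease, t.sine_increase) == (0.72, -0.55)
        assert (t.step_sustained_decrease, t.step_sustained_increase) \
            == (1.36, -0.75)
        assert (t.step_transient_increase, t.step_transient_decrease) \
            == (1.62, -1.01)

    def test_averaged_targets_are_means_of_low_frequency_studies(self):
        t = learning_targets()
        assert abs(t.averaged_decrease - np.mean([0.72, 1.36])) < 1e-12
        assert abs(t.averaged_increase - np.mean([-0.55, -0.75])) < 1e-12
        assert t.averaged_decrease == 1.04
        assert t.averaged_increase == -0.65

    def test_behavioral_change_fraction(self):
        assert learning_targets().behavior_change_frac == 0.6


class TestDataset2:
    def test_fifteen_frequencies_spanning_half_to_fifty_hz(self):
        f = dataset2_frequencies()
        assert f.size == 15
        assert f[0] == 0.5 and f[-1] == 50.0
        assert np.any(f == 12.5)

    def test_one_frequency_excluded_from_fits(self):
        truths = true_circuit_params()
        df = generate_dataset2(truths["pre"], truths["post_increase"],
                               truths["post_decrease"])
        assert len(df) == 15
        assert df["excluded"].sum() == 1
        assert len(df[~df["excluded"]]) == 14

    def test_gain_phase_at_half_hz_matches_time_domain_simulation(self):
        """Frequency-domain gains cross-checked against sinusoid regression
        on a long closed-loop simulation (< 1% mismatch)."""
        truths = true_circuit_params()
        df = generate_dataset2(truths["pre"], truths["post_increase"],
                               truths["post_decrease"])
        row = df[df["freq_hz"] == 0.5].iloc[0]
        batt = generate_stimulus_battery()
        c = next(c for c in batt if c.name == "vord_sine_0.5")
        tr = simulate_closed_loop(truths["pre"], c)
        fr = fit_sine(tr.E, 0.5, DT, amplitude=10.0)
        gain = abs(-fr.complex_gain)
        phase = np.degrees(np.angle(-fr.complex_gain))
        assert abs(gain - row["gain_pre"]) < 0.01 * row["gain_pre"]
        assert abs(phase - row["phase_pre"]) < 0.5


class TestDesaccade:
    def test_smooth_trace_unchanged(self):
        t = np.arange(4000) * DT
        eye = 10 * np.sin(2 * np.pi * 0.5 * t)
        cleaned, mask = desaccade(eye, 30.0, DT)
        assert not mask.any()
        np.testing.assert_array_equal(cleaned, eye)

    def test_single_spike_removed_and_interpolated(self):
        eye = np.zeros(2000)
        eye[1000:1020] = 100.0
        cleaned, mask = desaccade(eye, 30.0, DT)
        assert mask[1005]
        assert np.max(np.abs(cleaned)) < 1.0

    def test_excised_set_matches_brute_force_oracle(self):
        rng = np.random.default_rng(4)
        t = np.arange(6000) * DT
        eye = 8 * np.sin(2 * np.pi * 0.5 * t)
        slow = eye.copy()
        for _ in range(5):
            i = rng.integers(200, 5800)
            eye[i:i + 40] += rng.choice([-1, 1]) * 120.0
        cleaned, mask = desaccade(eye, 30.0, DT, slow_phase=slow)
        # independent rule-by-rule oracle with the same guard window
        fast = np.abs(eye - slow) > 30.0
        g = int(round(10e-3 / DT))
        oracle = np.zeros(eye.size, dtype=bool)
        for i in np.where(fast)[0]:
            oracle[max(0, i - g): i + g + 1] = True
        np.testing.assert_array_equal(mask, oracle)
        assert np.max(np.abs(cleaned - slow)) < 5.0


class TestPreprocessRate:
    def test_constant_rate_gives_zero_modulation(self):
        out = preprocess_rate(np.full(4000, 80.0), DT, periodic=True)
        assert np.max(np.abs(out)) < 1e-9

    def test_sinusoidal_modulation_preserved(self):
        t = np.arange(8000) * DT
        rate = 80 + 15 * np.sin(2 * np.pi * 2 * t)
        out = preprocess_rate(rate, DT, periodic=True)
        fr = fit_sine(out, 2.0, DT)
        # 10 ms Gaussian smoothing attenuates a 2 Hz sine by < 1%
        assert abs(fr.gain - 15.0) < 0.2

    def test_folding_cancels_common_mode(self):
        t = np.arange(4000) * DT
        sig = np.sin(2 * np.pi * t)
        folded = fold_ipsi_contra(sig + 0.3, -sig + 0.3)
        np.testing.assert_allclose(folded, sig, atol=1e-12)

    def test_poisson_spikes_recover_modulation_within_mc_bands(self):
        rng = np.random.default_rng(5)
        t = np.arange(20000) * DT
        lam = (80 + 20 * np.sin(2 * np.pi * 1 * t)) * DT
        n_trials = 60
        acc = np.zeros(t.size)
        for _ in range(n_trials):
            spikes = rng.poisson(lam) / DT
            acc += preprocess_rate(spikes, DT, periodic=True)
        fr = fit_sine(acc / n_trials, 1.0, DT)
        # Monte-Carlo standard error of the amplitude ~ sqrt(2 rate/(T n))
        assert abs(fr.gain - 20.0) < 1.5

    def test_cycle_average_reduces_to_single_period(self):
        t = np.arange(8000) * DT
        sig = np.sin(2 * np.pi * 1.0 * t)
        avg = cycle_average(sig, 1.0, DT)
        assert avg.size == int(1.0 / DT)
        np.testing.assert_allclose(avg, sig[: avg.size], atol=1e-9)


class TestHgvpSelection:
    def test_low_modulation_rejected(self):
        cells = [dict(pursuit_amp=5, pursuit_phase_deg=0, cancel_amp=30,
                      cancel_phase_deg=0, horizontal_preference=True)]
        assert hgvp_select(cells) == []

    def test_compliant_cell_accepted(self):
        cells = [dict(pursuit_amp=30, pursuit_phase_deg=10, cancel_amp=30,
                      cancel_phase_deg=-10, horizontal_preference=True)]
        assert hgvp_select(cells) == [0]

    def test_randomized_population_matches_rule_oracle(self):
        rng = np.random.default_rng(6)
        cells = [dict(pursuit_amp=rng.uniform(0, 40),
                      pursuit_phase_deg=rng.uniform(-90, 90),
                      cancel_amp=rng.uniform(0, 40),
                      cancel_phase_deg=rng.uniform(-90, 90),
                      horizontal_preference=bool(rng.integers(0, 2)))
                 for _ in range(50)]
        expected = [i for i, c in enumerate(cells)
                    if c["pursuit_amp"] >= 10
                    and abs(c["pursuit_phase_deg"]) < 45
                    and c["cancel_amp"] >= 10
                    and abs(c["cancel_phase_deg"]) < 45
                    and c["horizontal_preference"]]
        assert hgvp_select(cells) == expected


@pytest.fixture(scope="module")
def small_battery():
    return [c for c in generate_stimulus_battery()
            if c.name in ("vord_sine_0.5", "vord_step_500")]


class TestGenerateRecordings:
    def test_zero_noise_single_trial_equals_clean_simulation(self,
                                                             small_battery):
        truth = true_circuit_params()["pre"]
        quiet = NoiseSpec(rate_sd=0.0, eye_sd=0.0, saccade_rate=0.0,
                          cell_scale_sd=0.0)
        rec = generate_recordings(truth, small_battery, n_cells=2,
                                  n_trials=1, noise=quiet, seed=0)
        for c in small_battery:
            tr = simulate_closed_loop(truth, c)
            np.testing.assert_allclose(rec.eye[c.name], tr.E, atol=1e-9)
            # preprocessing smooths the rate: compare the smoothed truth
            from scipy.ndimage import gaussian_filter1d
            smoothed = gaussian_filter1d(tr.P, sigma=10e-3 / DT,
                                         mode="nearest")
            resid = rec.purkinje[c.name] - (smoothed - smoothed.mean()
                                            if c.waveform == "sine"
                                            else smoothed)
            if c.waveform == "step":
                resid -= resid[: int(0.05 / DT)].mean()
            assert np.max(np.abs(resid)) < 0.5

    def test_trial_average_error_shrinks_as_sqrt_n(self, small_battery):
        """Residual noise on trial-averaged traces scales ~ 1/sqrt(n)."""
        truth = true_circuit_params()["pre"]
        cond = small_battery[0]
        clean = simulate_closed_loop(truth, cond).P
        from scipy.ndimage import gaussian_filter1d
        clean_s = gaussian_filter1d(clean, sigma=10e-3 / DT, mode="nearest")
        clean_s -= clean_s.mean()
        errs = []
        for n in (4, 16, 64):
            rec = generate_recordings(
                truth, [cond], n_cells=1, n_trials=n,
                noise=NoiseSpec(saccade_rate=0.0, cell_scale_sd=0.0),
                seed=11)
            errs.append(np.std(rec.purkinje[cond.name] - clean_s))
        ratio1 = errs[0] / errs[1]
        ratio2 = errs[1] / errs[2]
        assert 1.3 < ratio1 < 3.1   # ideal 2 per 4x trial increase
        assert 1.3 < ratio2 < 3.1

    def test_injected_saccades_fully_removed(self, small_battery):
        truth = true_circuit_params()["pre"]
        spec = NoiseSpec(rate_sd=0.0, eye_sd=0.0, saccade_rate=2.0,
                         saccade_speed=100.0, cell_scale_sd=0.0)
        rec = generate_recordings(truth, [small_battery[0]], n_cells=1,
                                  n_trials=3, noise=spec, seed=2)
        clean = simulate_closed_loop(truth, small_battery[0]).E
        # saccades at 100 deg/s vastly exceed the 30 deg/s threshold and are
        # excised; interpolation residue stays tiny relative to saccade size
        assert np.max(np.abs(rec.eye[small_battery[0].name] - clean)) < 10.0

    def test_cell_scale_population_mean_is_exactly_one(self):
        truth = true_circuit_params()["pre"]
        batt = [generate_stimulus_battery()[0]]
        rec = generate_recordings(truth, batt, n_cells=7, n_trials=1,
                                  noise=NoiseSpec(), seed=3)
        np.testing.assert_allclose(rec.cell_scales.mean(axis=0), 1.0,
                                   atol=1e-12)

    def test_unstable_truth_rejected(self):
        truth = true_circuit_params()["pre"].copy()
        truth.g = 1.2
        with pytest.raises(ValueError):
            generate_recordings(truth, [generate_stimulus_battery()[0]])
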