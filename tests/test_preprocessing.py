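import numpy as np
import pytest

from distexp import (
    SimConfig,
    baseline_correct,
    detect_emg_artifacts,
    detect_heog_steps,
    fir_filter,
    generate_design,
    interpolate_channels,
    ocular_regression,
    preprocess,
    rereference,
    simulate_epochs,
)
from distexp.exceptions import ChannelError, InsufficientDataError, ParameterError

from conftest import make_epochs, make_trials


@pytest.fixture
def rng():
    return np.random.default_rng(0)


class TestRereference:
    def test_formula_and_zero_for_identical_refs(self, montage, rng):
        data = rng.normal(0, 1, (2, 68, 16))
        a1, a2 = montage.index("A1"), montage.index("A2")
        ep = make_epochs(data, montage, trials=make_trials(2))
        out = rereference(ep)
        expected = data - data[:, [a1, a2], :].mean(axis=1, keepdims=True)
        assert np.allclose(out.data, expected)
        # all channels equal to the refs -> zero output
        same = np.broadcast_to(data[:, :1, :], data.shape).copy()
        out2 = rereference(make_epochs(same, montage, trials=make_trials(2)))
        assert np.allclose(out2.data, 0.0)

    def test_idempotent_after_first_application(self, montage, rng):
        ep = make_epochs(rng.normal(0, 1, (1, 68, 16)), montage,
                         trials=make_trials(1))
        once = rereference(ep)
        twice = rereference(once)  # refs are zero-mean after first pass
        assert np.allclose(once.data, twice.data)

    def test_missing_ref_channel(self, montage, rng):
        ep = make_epochs(rng.normal(0, 1, (1, 68, 8)), montage,
                         trials=make_trials(1))
        with pytest.raises(ChannelError):
            rereference(ep, ref_channels=("A1", "NOPE"))


class TestFIRFilter:
    def test_highpass_removes_dc(self, montage):
        data = np.full((1, 68, 512), 7.0)
        ep = make_epochs(data, montage, sfreq=256.0, trials=make_trials(1))
        out = fir_filter(ep, "highpass", 0.1)
        # < 1% of the 7 uV DC offset in the fully-overlapped central region
        # (the outer quarters are the padding the epochs carry for this)
        assert np.abs(out.data[:, :, 128:384]).max() < 0.07

    def test_lowpass_preserves_passband_sine(self, montage):
        sfreq, n = 256.0, 1024
        t = np.arange(n) / sfreq
        sine = np.sin(2 * np.pi * 5.0 * t)
        data = np.tile(sine, (1, 68, 1))
        ep = make_epochs(data, montage, sfreq=sfreq, trials=make_trials(1))
        out = fir_filter(ep, "lowpass", 30.0)
        mid = slice(n // 4, 3 * n // 4)  # avoid edges
        amp = np.abs(out.data[0, 0, mid]).max()
        assert abs(amp - 1.0) < 0.01

    def test_zero_in_zero_out(self, montage):
        ep = make_epochs(np.zeros((1, 68, 128)), montage, trials=make_trials(1))
        assert np.all(fir_filter(ep, "lowpass", 30.0).data == 0.0)

    def test_cutoff_above_nyquist_rejected(self, montage):
        ep = make_epochs(np.zeros((1, 68, 64)), montage, sfreq=100.0,
                         trials=make_trials(1))
        with pytest.raises(ParameterError):
            fir_filter(ep, "lowpass", 60.0)


class TestBaselineCorrect:
    def test_offset_removed_and_window_mean_zero(self, montage, rng):
        data = rng.normal(0, 1, (3, 68, 100)) + 5.0
        ep = make_epochs(data, montage, sfreq=100.0, tmin_ms=-500.0,
                         trials=make_trials(3))
        out = baseline_correct(ep, (-500.0, -300.0))
        mask = out.time_mask(-500.0, -300.0)
        assert np.allclose(out.data[:, :, mask].mean(axis=-1), 0.0, atol=1e-12)
        # constant trial: offset removed everywhere
        const = make_epochs(np.full((1, 68, 100), 3.0), montage, sfreq=100.0,
                            tmin_ms=-500.0, trials=make_trials(1))
        assert np.allclose(baseline_correct(const, (-500.0, -300.0)).data, 0.0)

    def test_whole_epoch_window_is_mean_centering(self, montage, rng):
        data = rng.normal(0, 1, (2, 68, 50))
        ep = make_epochs(data, montage, sfreq=100.0, tmin_ms=0.0,
                         trials=make_trials(2))
        out = baseline_correct(ep, (0.0, ep.times[-1]))
        assert np.allclose(out.data, data - data.mean(axis=-1, keepdims=True))

    def test_empty_window_rejected(self, montage):
        ep = make_epochs(np.zeros((1, 68, 50)), montage, tmin_ms=0.0,
                         trials=make_trials(1))
        with pytest.raises(ParameterError):
            baseline_correct(ep, (-900.0, -800.0))


class TestEMGDetection:
    def _epochs(self, montage, rng, n_trials=40, sfreq=512.0, n_samp=512):
        data = rng.normal(0, 1.0, (n_trials, 68, n_samp))
        return make_epochs(data, montage, sfreq=sfreq,
                           trials=make_trials(n_trials))

    def test_injected_burst_flagged(self, montage, rng):
        ep = self._epochs(montage, rng)
        t = np.arange(100) / 512.0
        burst = 10.0 * np.sin(2 * np.pi * 130.0 * t)
        ep.data[7, :64, 200:300] += burst[None, :]
        mask, z, _ = detect_emg_artifacts(ep)
        assert mask[7]
        assert z[7] == z.max()

    def test_clean_data_low_false_flag_rate(self, montage, rng):
        ep = self._epochs(montage, rng, n_trials=100)
        mask, _, _ = detect_emg_artifacts(ep)
        assert mask.mean() < 0.05

    def test_identical_trials_not_flagged(self, montage, rng):
        one = rng.normal(0, 1, (1, 68, 512))
        data = np.repeat(one, 20, axis=0)
        ep = make_epochs(data, montage, sfreq=512.0, trials=make_trials(20))
        mask, _, _ = detect_emg_artifacts(ep)
        assert not mask.any()

    def test_too_few_trials_rejected(self, montage, rng):
        ep = self._epochs(montage, rng, n_trials=5)
        with pytest.raises(InsufficientDataError):
            detect_emg_artifacts(ep)


class TestHEOGSteps:
    def _epochs(self, montage, n_trials=4, sfreq=512.0, n_samp=512):
        return make_epochs(np.zeros((n_trials, 68, n_samp)), montage,
                           sfreq=sfreq, trials=make_trials(n_trials))

    def test_flat_heog_no_flags(self, montage):
        assert not detect_heog_steps(self._epochs(montage)).any()

    @pytest.mark.parametrize("step_uv,expected", [(40.0, True), (10.0, False)])
    def test_step_threshold(self, montage, step_uv, expected):
        ep = self._epochs(montage)
        heog = ep.montage.index("HEOG")
        ep.data[1, heog, 256:] += step_uv
        mask = detect_heog_steps(ep, thresh_uv=20.0)
        assert mask[1] == expected
        assert not mask[[0, 2, 3]].any()


class TestInterpolation:
    def test_identical_good_channels_reproduced(self, montage):
        data = np.full((2, 68, 16), 4.0)
        ep = make_epochs(data, montage, trials=make_trials(2))
        out = interpolate_channels(ep, {"Cz"})
        assert np.allclose(out.data[:, montage.index("Cz"), :], 4.0)

    def test_zero_neighbors_zero_interpolation(self, montage):
        ep = make_epochs(np.zeros((1, 68, 8)), montage, trials=make_trials(1))
        out = interpolate_channels(ep, {"Pz"})
        assert np.all(out.data == 0.0)

    def test_smooth_map_leave_one_out(self, montage):
        """A linear scalp gradient is recovered within a small error."""
        data = np.zeros((1, 68, 4))
        for ch in montage.scalp_channels:
            x, y = montage.positions[ch]
            data[0, montage.index(ch), :] = 1.0 + 0.5 * x + 0.3 * y
        ep = make_epochs(data, montage, trials=make_trials(1))
        for ch in ("Pz", "Cz", "PO3"):
            out = interpolate_channels(ep, {ch})
            truth = data[0, montage.index(ch), 0]
            err = abs(out.data[0, montage.index(ch), 0] - truth)
            assert err < 0.1  # map spans ~1 uV across the scalp

    def test_good_channels_untouched(self, montage, rng=np.random.default_rng(1)):
        data = rng.normal(0, 1, (1, 68, 8))
        ep = make_epochs(data, montage, trials=make_trials(1))
        out = interpolate_channels(ep, {"Oz"})
        keep = [i for i, c in enumerate(montage.channels) if c != "Oz"]
        assert np.array_equal(out.data[:, keep, :], data[:, keep, :])


class TestOcularRegression:
    def test_exact_multiple_removed(self, montage, rng):
        data = np.zeros((3, 68, 64))
        veog = rng.normal(0, 10, (3, 64))
        data[:, montage.index("VEOG"), :] = veog
        data[:, montage.index("Fp1"), :] = 0.5 * veog
        ep = make_epochs(data, montage, trials=make_trials(3))
        out = ocular_regression(ep)
        assert np.abs(out.data[:, montage.index("Fp1"), :]).max() < 1e-9

    def test_orthogonal_channel_unchanged(self, montage):
        n = 64
        t = np.arange(n)
        data = np.zeros((1, 68, n))
        data[0, montage.index("VEOG"), :] = np.sin(2 * np.pi * t / n)
        data[0, montage.index("Oz"), :] = np.cos(2 * np.pi * t / n)
        ep = make_epochs(data, montage, trials=make_trials(1))
        out = ocular_regression(ep)
        assert np.allclose(out.data[0, montage.index("Oz"), :],
                           data[0, montage.index("Oz"), :], atol=1e-9)

    def test_blink_removal_recovers_signal(self, montage, rng):
        n_tr, n_s = 20, 256
        signal = rng.normal(0, 1, (n_tr, 64, n_s))
        blink = rng.normal(0, 1, (n_tr, n_s))
        blink = np.cumsum(blink, axis=-1)  # slow, blink-like
        blink -= blink.mean()
        data = np.zeros((n_tr, 68, n_s))
        scalp_idx = [montage.index(c) for c in montage.scalp_channels]
        mix = 10.0 * blink[:, None, :] / blink.std()
        data[:, scalp_idx, :] = signal + mix
        data[:, montage.index("VEOG"), :] = 5.0 * blink / blink.std()
        ep = make_epochs(data, montage, trials=make_trials(n_tr))
        out = ocular_regression(ep)
        rec = out.data[:, scalp_idx, :].ravel()
        r = np.corrcoef(rec, signal.ravel())[0, 1]
        assert r > 0.99

    def test_zero_variance_veog_warns_noop(self, montage, rng):
        data = rng.normal(0, 1, (2, 68, 16))
        data[:, montage.index("VEOG"), :] = 0.0
        ep = make_epochs(data, montage, trials=make_trials(2))
        with pytest.warns(UserWarning):
            out = ocular_regression(ep)
        assert np.array_equal(out.data, data)


class TestFullChain:
    def test_null_calibration_and_sensitivity(self, montage):
        """Artifact-free trials survive (<5% loss); injected artifacts die."""
        cfg = SimConfig(seed=21, experiment=2, blocks_per_condition=1,
                        n_sessions=1, sfreq=512, emg_rate=0.08, heog_rate=0.08,
                        emg_amp_mult=10.0, heog_step_uv=40.0)
        table = generate_design(cfg, 0)
        epochs, log = simulate_epochs(table, cfg, montage)
        clean, report = preprocess(epochs)
        flagged = set(report["trial"])
        injected = set(log["emg_trials"]) | set(log["heog_trials"])
        assert injected <= flagged, "every injected artifact must be caught"
        false_rate = len(flagged - injected) / (epochs.n_trials - len(injected))
        assert false_rate < 0.05
        steps = [h["op"] for h in clean.history]
        assert steps[-5:] == ["rereference", "fir_filter", "reject_emg",
                              "ocular_regression", "reject_heog_steps"]
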