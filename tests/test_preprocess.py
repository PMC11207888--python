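import numpy as np
import pytest

from plidrift.bands import DEFAULT_BANDS, BandDefinition
from plidrift.montage import MontageSpec
from plidrift.preprocess import (EpochSet, Recording, band_decompose,
                                 bandpass_fir, baseline_correct, epoch, notch,
                                 qc_reject, rereference, resample)


def _recording(data, fs, labels, refs=(), has_refs=False):
    m = MontageSpec(labels=tuple(labels), reference_labels=tuple(refs))
    return Recording(data=np.asarray(data, float), sampling_rate=fs,
                     montage=m, has_references=has_refs)


def _rms(x):
    return np.sqrt(np.mean(np.square(x)))


class TestResample:
    def test_512_to_256_sample_count(self):
        rec = _recording(np.random.default_rng(0).standard_normal((2, 512 * 60)),
                         512.0, ["C3", "C4"])
        out = resample(rec, 256.0)
        assert out.data.shape == (2, 60 * 256)
        assert out.sampling_rate == 256.0

    def test_identity(self):
        rec = _recording(np.ones((1, 100)), 256.0, ["Cz"])
        assert resample(rec, 256.0) is rec

    def test_upsampling_rejected(self):
        rec = _recording(np.ones((1, 100)), 256.0, ["Cz"])
        with pytest.raises(ValueError, match="upsampling"):
            resample(rec, 512.0)

    def test_sinusoid_preserved(self):
        t512 = np.arange(512 * 10) / 512.0
        rec = _recording(np.sin(2 * np.pi * 10 * t512)[None, :], 512.0, ["Cz"])
        out = resample(rec, 256.0)
        t256 = np.arange(256 * 10) / 256.0
        expected = np.sin(2 * np.pi * 10 * t256)
        # compare away from the ends (polyphase edge effects)
        sl = slice(256, -256)
        assert np.allclose(out.data[0, sl], expected[sl], atol=0.01)
        assert abs(_rms(out.data[0, sl]) / _rms(expected[sl]) - 1) < 0.01


class TestRereference:
    def test_zero_mastoids_identity(self, rng):
        data = rng.standard_normal((4, 100))
        data[2:] = 0.0
        rec = _recording(data, 256.0, ["C3", "C4"], refs=["M1", "M2"], has_refs=True)
        out = rereference(rec)
        assert np.array_equal(out.data, data[:2])
        assert out.data.shape[0] == 2

    def test_common_signal_cancels(self):
        common = np.linspace(0, 1, 50)
        data = np.tile(common, (4, 1))
        rec = _recording(data, 256.0, ["C3", "C4"], refs=["M1", "M2"], has_refs=True)
        out = rereference(rec)
        assert np.allclose(out.data, 0.0)

    def test_hand_computed_subtraction(self, rng):
        data = rng.standard_normal((4, 20))
        rec = _recording(data, 256.0, ["C3", "C4"], refs=["M1", "M2"], has_refs=True)
        out = rereference(rec)
        expected = data[:2] - data[2:].mean(axis=0)
        assert np.allclose(out.data, expected)

    def test_idempotent_after_removal(self, rng):
        data = rng.standard_normal((4, 20))
        rec = _recording(data, 256.0, ["C3", "C4"], refs=["M1", "M2"], has_refs=True)
        once = rereference(rec)
        assert rereference(once) is once

    def test_missing_mastoid(self, rng):
        rec = _recording(rng.standard_normal((2, 20)), 256.0, ["C3", "C4"])
        rec.has_references = True
        with pytest.raises(ValueError):
            rereference(rec, ("M1", "M2"))


class TestBandpass:
    fs = 256.0

    def _tone(self, freq, seconds=60):
        t = np.arange(int(self.fs * seconds)) / self.fs
        return np.sin(2 * np.pi * freq * t)[None, :]

    def _gain_db(self, freq, low, high):
        x = self._tone(freq)
        rec = _recording(x, self.fs, ["Cz"])
        y = bandpass_fir(rec, low, high).data
        sl = slice(x.shape[1] // 4, -x.shape[1] // 4)  # avoid edge transients
        return 20 * np.log10(_rms(y[0, sl]) / _rms(x[0, sl]))

    def test_slow_drift_attenuated(self):
        assert self._gain_db(0.1, 1.0, 45.0) < -20

    def test_passband_flat(self):
        assert abs(self._gain_db(10.0, 8.0, 12.0)) < 1.0

    def test_mains_attenuated_by_broadband_filter(self):
        assert self._gain_db(50.0, 1.0, 45.0) < -20

    def test_zero_phase(self):
        x = self._tone(10.0, seconds=20)
        rec = _recording(x, self.fs, ["Cz"])
        y = bandpass_fir(rec, 8.0, 12.0).data[0]
        sl = slice(1000, -1000)
        lags = [np.dot(x[0, sl], np.roll(y, k)[sl]) for k in range(-5, 6)]
        assert int(np.argmax(lags)) - 5 == 0

    def test_band_outside_nyquist(self):
        rec = _recording(np.ones((1, 1000)), self.fs, ["Cz"])
        with pytest.raises(ValueError):
            bandpass_fir(rec, 30.0, 200.0)


class TestNotch:
    def test_target_killed_neighbours_kept(self):
        fs = 256.0
        t = np.arange(int(fs * 30)) / fs
        for freq, lim, cmp in [(50.0, -20, "lt"), (45.0, -1.0, "gt")]:
            x = np.sin(2 * np.pi * freq * t)[None, :]
            rec = _recording(x, fs, ["Cz"])
            y = notch(rec, 50.0).data
            sl = slice(2000, -2000)
            gain = 20 * np.log10(_rms(y[0, sl]) / _rms(x[0, sl]))
            if cmp == "lt":
                assert gain < lim
            else:
                assert gain > lim


class TestEpoch:
    def _rec(self, seconds, fs=64.0, n_ch=2):
        n = int(seconds * fs)
        data = np.arange(n_ch * n, dtype=float).reshape(n_ch, n)
        return _recording(data, fs, ["C3", "C4"][:n_ch])

    def test_no_trim_grid(self):
        es = epoch(self._rec(600), window=300, step=150, trim=0)
        assert es.n_epochs == 3
        assert list(es.start_times) == [0.0, 150.0, 300.0]

    def test_containment_rule(self):
        es = epoch(self._rec(3750), window=300, step=150, trim=300)
        starts = es.start_times
        assert starts.min() >= 300.0
        assert (starts + 300.0).max() <= 3450.0

    def test_partition_reconstructs(self):
        rec = self._rec(600)
        es = epoch(rec, window=200, step=200, trim=0)
        rebuilt = np.concatenate(list(es.epochs), axis=-1)
        assert np.array_equal(rebuilt, rec.data)

    def test_too_short(self):
        with pytest.raises(ValueError, match="at least"):
            epoch(self._rec(100), window=300, step=150, trim=300)


class TestBaseline:
    def _es(self, data, fs=64.0):
        m = MontageSpec(labels=("C3", "C4"))
        return EpochSet(epochs=data, sampling_rate=fs, montage=m,
                        epoch_duration=data.shape[-1] / fs, step=data.shape[-1] / fs)

    def test_constant_channel_zeroed(self):
        es = self._es(np.full((1, 2, 50), 7.0))
        assert np.allclose(baseline_correct(es).epochs, 0.0)

    def test_zero_mean_unchanged(self, rng):
        data = rng.standard_normal((2, 2, 50))
        data -= data.mean(axis=-1, keepdims=True)
        es = self._es(data)
        assert np.allclose(baseline_correct(es).epochs, data, atol=1e-12)

    def test_offset_removed(self):
        t = np.arange(64) / 64.0
        sine = np.sin(2 * np.pi * 8 * t)
        data = np.tile(sine + 3.0, (1, 2, 1))
        out = baseline_correct(self._es(data)).epochs[0, 0]
        assert np.allclose(out, sine - sine.mean(), atol=1e-12)
        assert abs(out.mean()) < 1e-10


class TestQC:
    def _es(self, epochs):
        m = MontageSpec(labels=("C3", "C4"))
        return EpochSet(epochs=epochs, sampling_rate=128.0, montage=m,
                        epoch_duration=epochs.shape[-1] / 128.0,
                        step=epochs.shape[-1] / 128.0)

    def _hf_epochs(self, rng, n=6, boost=None):
        t = np.arange(256) / 128.0
        base = np.sin(2 * np.pi * 30 * t)  # inside the 20-40 Hz QC band
        epochs = np.stack([
            np.tile(base, (2, 1)) + 0.01 * rng.standard_normal((2, 256))
            for _ in range(n)
        ])
        if boost is not None:
            epochs[boost] *= np.sqrt(10.0)  # +10 dB of 20-40 Hz power
        return epochs

    def test_identical_epochs_all_kept(self, rng):
        es = self._es(np.tile(rng.standard_normal((2, 256)), (5, 1, 1)))
        assert qc_reject(es).retained_mask.all()

    def test_10db_outlier_rejected(self, rng):
        es = self._es(self._hf_epochs(rng, boost=2))
        with pytest.warns(UserWarning, match="excluding 1"):
            out = qc_reject(es)
        assert not out.retained_mask[2]
        assert out.retained_mask.sum() == 5

    def test_infinite_threshold_keeps_all(self, rng):
        es = self._es(self._hf_epochs(rng, boost=2))
        assert qc_reject(es, threshold_db=np.inf).retained_mask.all()

    def test_monotone_in_threshold(self, rng):
        es = self._es(self._hf_epochs(rng, boost=1))
        with pytest.warns(UserWarning):
            strict = qc_reject(es, threshold_db=3.0)
        lax = qc_reject(es, threshold_db=12.0)
        # raising the threshold never rejects additional epochs
        assert (lax.retained_mask >= strict.retained_mask).all()

    def test_needs_three_epochs(self, rng):
        es = self._es(self._hf_epochs(rng, n=2))
        with pytest.raises(ValueError, match="3 epochs"):
            qc_reject(es)


class TestBandDecompose:
    def test_returns_all_bands(self, rng):
        m = MontageSpec(labels=("C3", "C4"))
        es = EpochSet(epochs=rng.standard_normal((3, 2, 512)), sampling_rate=256.0,
                      montage=m, epoch_duration=2.0, step=2.0)
        out = band_decompose(es, DEFAULT_BANDS)
        assert set(out) == {"delta", "theta", "alpha", "beta", "gamma"}
        for es_band in out.values():
            assert es_band.epochs.shape == es.epochs.shape

    def test_band_above_nyquist_rejected(self, rng):
        m = MontageSpec(labels=("C3",))
        es = EpochSet(epochs=rng.standard_normal((3, 1, 128)), sampling_rate=64.0,
                      montage=m, epoch_duration=2.0, step=2.0)
        with pytest.raises(ValueError, match="Nyquist"):
            band_decompose(es, (BandDefinition("gamma", 31.0, 45.0),))

    def test_isolates_band_content(self, rng):
        fs = 256.0
        t = np.arange(int(fs * 4)) / fs
        mix = np.sin(2 * np.pi * 10 * t) + np.sin(2 * np.pi * 25 * t)
        m = MontageSpec(labels=("C3",))
        es = EpochSet(epochs=np.tile(mix, (3, 1, 1)), sampling_rate=fs,
                      montage=m, epoch_duration=4.0, step=4.0)
        out = band_decompose(es, DEFAULT_BANDS)
        sl = slice(256, -256)
        alpha = out["alpha"].epochs[0, 0, sl]
        beta = out["beta"].epochs[0, 0, sl]
        # each band keeps its own tone and rejects the other
        assert np.std(alpha) > 0.5 and np.std(beta) > 0.5
        corr = np.corrcoef(alpha, np.sin(2 * np.pi * 10 * t)[sl])[0, 1]
        assert abs(corr) > 0.99
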