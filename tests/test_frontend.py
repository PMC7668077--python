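"""Front-end tests: STFT against a direct DFT oracle, filterbank geometry,
compression identities, and the multithreshold construction."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.signal import get_window

from ear2cortex.frontend import (
    AudioSignal,
    CompressionSpec,
    ConfigurationError,
    FilterbankSpec,
    InputError,
    MultithresholdSpec,
    PluginFrontEnd,
    apply_compression,
    build_front_end,
    center_frequencies,
    load_cochleagram,
    make_cochleagram,
    make_multithreshold_cochleagram,
    read_wav,
    resolve_compression,
    save_cochleagram,
    stft_power_spectrogram,
    triangular_filterbank,
    write_wav,
)


def direct_windowed_dft(x, fs, frame_ms, hop_ms, mode):
    """Brute-force STFT oracle: explicit DFT-matrix product per frame."""
    win = int(round(frame_ms * fs / 1000.0))
    hop = int(round(hop_ms * fs / 1000.0))
    n_frames = int(np.ceil(x.size / hop))
    padded = np.zeros((n_frames - 1) * hop + win)
    padded[: x.size] = x
    w = get_window("hann", win, fftbins=True)
    k = np.arange(win // 2 + 1)
    n = np.arange(win)
    dft = np.exp(-2j * np.pi * np.outer(k, n) / win)
    rows = []
    for f in range(n_frames):
        frame = padded[f * hop : f * hop + win] * w
        rows.append(np.abs(dft @ frame))
    S = np.array(rows)
    return S**2 if mode == "power" else S


class TestSTFT:
    @pytest.mark.parametrize("mode", ["amplitude", "power"])
    def test_matches_direct_dft_oracle(self, rng, mode):
        """100-ms random signal agrees with a sample-by-sample windowed DFT."""
        x = rng.standard_normal(4800)
        audio = AudioSignal(x, 48000.0)
        spec = FilterbankSpec(16, spectrogram_mode=mode)
        S, freqs = stft_power_spectrogram(audio, spec)
        expected = direct_windowed_dft(x, 48000.0, 20.0, 10.0, mode)
        np.testing.assert_allclose(S, expected, rtol=1e-9, atol=1e-12)
        np.testing.assert_allclose(freqs, np.fft.rfftfreq(960, 1 / 48000.0))

    def test_zero_signal_gives_zero_matrix(self, fspec16):
        S, _ = stft_power_spectrogram(AudioSignal(np.zeros(4800), 48000.0), fspec16)
        assert not np.any(S)

    def test_pure_tone_energy_concentrates_at_tone_bins(self, fspec16):
        """A 1-kHz tone produces a single horizontal band near 1 kHz."""
        t = np.arange(48000) / 48000.0
        audio = AudioSignal(np.sin(2 * np.pi * 1000 * t), 48000.0)
        S, freqs = stft_power_spectrogram(audio, fspec16)
        # interior frames (edge frames see the zero-padded boundary)
        for frame in S[2:-2]:
            peak_freq = freqs[np.argmax(frame)]
            assert abs(peak_freq - 1000.0) <= freqs[1]

    def test_one_row_per_hop(self, noise_audio, fspec16):
        S, _ = stft_power_spectrogram(noise_audio, fspec16)
        assert S.shape[0] == int(np.ceil(noise_audio.samples.size / 480))

    def test_low_sample_rate_rejected(self, fspec16):
        with pytest.raises(ConfigurationError, match="sample rate"):
            stft_power_spectrogram(AudioSignal(np.zeros(1000), 8000.0), fspec16)

    def test_empty_audio_rejected(self, fspec16):
        with pytest.raises(InputError):
            stft_power_spectrogram(AudioSignal(np.zeros(0), 48000.0), fspec16)


class TestTriangularFilterbank:
    def test_two_channel_centers_geometric(self):
        """Centers for n=2 span [500, 8000] with ratio (8000/500)^(1/1)."""
        centers = center_frequencies(2, 500.0, 8000.0)
        assert centers[1] / centers[0] == pytest.approx((8000 / 500) ** 1.0)
        np.testing.assert_allclose(centers, [500.0, 8000.0])

    def test_channel_count_nesting(self):
        """n and 2n channels both span [f_min, f_max] geometrically."""
        for n in (4, 8, 16):
            c = center_frequencies(n, 500.0, 22627.0)
            assert c[0] == pytest.approx(500.0) and c[-1] == pytest.approx(22627.0)
            np.testing.assert_allclose(np.diff(np.log(c)), np.diff(np.log(c))[0])

    def test_apex_at_center_frequency(self):
        """Each row peaks at the FFT bin nearest its center (triangle apex)."""
        freqs = np.fft.rfftfreq(960, 1 / 48000.0)
        spec = FilterbankSpec(8, 500.0, 16000.0)
        W = triangular_filterbank(spec, freqs)
        assert np.all(W >= 0) and np.all(W <= 1.0)
        centers = center_frequencies(8, 500.0, 16000.0)
        bin_width = freqs[1] - freqs[0]
        for i, c in enumerate(centers):
            assert abs(freqs[np.argmax(W[i])] - c) <= bin_width

    def test_passband_fully_covered(self):
        """Every FFT bin strictly between first and last center has weight."""
        freqs = np.fft.rfftfreq(960, 1 / 48000.0)
        spec = FilterbankSpec(8, 500.0, 16000.0)
        W = triangular_filterbank(spec, freqs)
        inside = (freqs > 500.0) & (freqs < 16000.0)
        assert np.all(W[:, inside].sum(axis=0) > 0)

    def test_too_many_channels_for_fft_resolution(self):
        freqs = np.fft.rfftfreq(64, 1 / 48000.0)  # 750-Hz bins
        with pytest.raises(ConfigurationError, match="support"):
            triangular_filterbank(FilterbankSpec(64, 500.0, 22627.0), freqs)

    def test_range_outside_fft_bins_rejected(self):
        freqs = np.fft.rfftfreq(960, 1 / 16000.0)
        with pytest.raises(ConfigurationError):
            triangular_filterbank(FilterbankSpec(8, 500.0, 22627.0), freqs)


class TestCompression:
    def test_log1plus_at_zero(self):
        out = apply_compression(np.zeros((2, 2)), CompressionSpec("log1plus"))
        assert np.all(out == 0.0)

    def test_thresholded_log_clamps_below_theta(self):
        comp = CompressionSpec("log_thresholded", theta=0.1)
        x = np.array([0.0, 0.05, 0.1, 1.0])
        out = apply_compression(x, comp)
        np.testing.assert_allclose(out[:3], np.log(0.1))
        assert out[3] == pytest.approx(np.log(1.0))

    def test_hill_is_half_at_halfmax(self):
        """After the log rescaling, input mapping to r = halfmax gives 0.5."""
        comp = CompressionSpec(
            "hill", theta=1e-6, hill_halfmax=0.5, hill_exponent=3.0,
            hill_rescale=(np.log(1e-6), np.log(1.0)),
        )
        # r = (log(x) - lo)/(hi - lo) = 0.5  =>  x = exp(midpoint of log range)
        x_half = np.exp(0.5 * (np.log(1e-6) + np.log(1.0)))
        out = apply_compression(np.array([x_half]), comp)
        assert out[0] == pytest.approx(0.5)

    def test_hill_bounded_unit_interval(self, rng):
        x = rng.random((4, 50)) * 10
        comp = resolve_compression(x, CompressionSpec("hill"), "power")
        out = apply_compression(x, comp)
        assert np.all(out >= 0) and np.all(out <= 1)

    @pytest.mark.parametrize(
        "comp",
        [
            CompressionSpec("lin"),
            CompressionSpec("log_thresholded", theta=0.01),
            CompressionSpec("log1plus", log1plus_scale=0.5),
            CompressionSpec("power_log", theta=0.001),
            CompressionSpec(
                "hill", theta=0.001, hill_rescale=(np.log(0.001), np.log(10.0))
            ),
        ],
        ids=lambda c: c.kind,
    )
    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(data=st.data())
    def test_monotone_nondecreasing(self, comp, data):
        """x <= y elementwise implies f(x) <= f(y) for every kind."""
        vals = data.draw(
            st.lists(st.floats(0, 10, allow_nan=False), min_size=1, max_size=20)
        )
        x = np.array(vals)
        bump = data.draw(st.floats(0, 5))
        lo, hi = apply_compression(x, comp), apply_compression(x + bump, comp)
        assert np.all(hi >= lo - 1e-12)

    def test_log_compression_shrinks_high_level_dynamic_range(self):
        """On a 60-dB span, log compression equalizes increments that the
        linear map leaves two orders of magnitude apart."""
        x = np.geomspace(0.01, 10.0, 64)
        comp = resolve_compression(x, CompressionSpec("log_thresholded"), "amplitude")
        lin = apply_compression(x, CompressionSpec("lin"))
        logc = apply_compression(x, comp)

        def top_vs_bottom(y):
            return (y[-1] - y[32]) / (y[31] - y[0])

        assert top_vs_bottom(logc) < top_vs_bottom(lin) / 10

    def test_negative_input_rejected(self):
        with pytest.raises(InputError):
            apply_compression(np.array([-1.0]), CompressionSpec("lin"))

    def test_nonpositive_theta_rejected(self):
        with pytest.raises(ConfigurationError):
            CompressionSpec("log_thresholded", theta=0.0)

    def test_unresolved_theta_rejected(self):
        with pytest.raises(ConfigurationError, match="unresolved"):
            apply_compression(np.ones(3), CompressionSpec("log_thresholded"))

    def test_auto_theta_sits_60db_below_peak(self):
        x = np.array([[2.0, 0.0002]])
        comp = resolve_compression(x, CompressionSpec("log_thresholded"), "amplitude")
        assert comp.theta == pytest.approx(2.0 * 10 ** (-60 / 20))


class TestCochleagram:
    def test_click_activity_localized_in_time(self):
        x = np.zeros(48000)
        x[24000] = 1.0
        cg = make_cochleagram(
            AudioSignal(x, 48000.0), FilterbankSpec(16), CompressionSpec("lin")
        )
        energy = cg.values.sum(axis=0)
        active = np.flatnonzero(energy > 1e-12 * energy.max())
        # click at 0.5 s: only frames whose 20-ms window overlaps it respond
        assert active.size <= 3 and np.all(np.abs(active - 50) <= 2)

    def test_silence_with_thresholded_log_is_constant_floor(self):
        cg = make_cochleagram(
            AudioSignal(np.zeros(24000), 48000.0),
            FilterbankSpec(8),
            CompressionSpec("log_thresholded", theta=0.01),
        )
        np.testing.assert_allclose(cg.values, np.log(0.01))

    def test_white_noise_smooth_across_frequency(self, rng):
        """Noise responses, normalized by filter bandwidth, are flat in
        frequency: no channel deviates far from the cross-channel mean."""
        x = rng.standard_normal(5 * 48000)
        audio = AudioSignal(x / np.abs(x).max(), 48000.0)
        fspec = FilterbankSpec(32, spectrogram_mode="power")
        cg = make_cochleagram(audio, fspec, CompressionSpec("lin"))
        S, freqs = stft_power_spectrogram(audio, fspec)
        W = triangular_filterbank(fspec, freqs)
        per_bandwidth = cg.values.mean(axis=1) / W.sum(axis=1)
        spread = np.abs(per_bandwidth - per_bandwidth.mean())
        assert np.all(spread < 0.25 * per_bandwidth.mean())

    def test_output_rows_equal_channel_count(self, noise_audio):
        cg = make_cochleagram(noise_audio, FilterbankSpec(16), CompressionSpec("lin"))
        assert cg.n_channels == 16 and cg.center_freqs.size == 16

    def test_scaling_input_never_decreases_output(self, noise_audio):
        """Corpus-relative thresholds keep compression monotone in level."""
        for name in ("spec-lin", "spec-log", "spec-log1plus", "spec-power", "spec-hill"):
            fe = build_front_end(name, 8)
            lo = fe(noise_audio)
            hi = fe(AudioSignal(noise_audio.samples * 4.0, 48000.0))
            assert np.all(hi.values >= lo.values - 1e-9), name


class TestMultithreshold:
    def test_identical_triples_collapse_to_triplication(self, noise_audio):
        fspec = FilterbankSpec(8, spectrogram_mode="power")
        mt = MultithresholdSpec(
            thetas_db_down=(40.0, 40.0, 40.0),
            hill_halfmaxes=(0.5, 0.5, 0.5),
            hill_exponents=(2.0, 2.0, 2.0),
        )
        cg = make_multithreshold_cochleagram(noise_audio, fspec, mt)
        single = make_cochleagram(
            noise_audio, fspec,
            CompressionSpec("hill", theta_db_down=40.0),
        )
        assert cg.values.shape[0] == 24
        for block in range(3):
            np.testing.assert_array_equal(
                cg.values[8 * block : 8 * (block + 1)], single.values
            )

    def test_low_tone_activates_low_threshold_channels_only(self):
        """A tone 50 dB below peak clears only the lowest threshold."""
        fs = 48000.0
        t = np.arange(int(fs)) / fs
        loud = np.sin(2 * np.pi * 2000 * t)
        quiet = 10 ** (-50 / 20) * np.sin(2 * np.pi * 8000 * t)
        audio = AudioSignal(loud[: int(fs / 2)].tolist() + quiet[: int(fs / 2)].tolist(), fs)
        fspec = FilterbankSpec(8, spectrogram_mode="power")
        cg = make_multithreshold_cochleagram(audio, fspec, MultithresholdSpec())
        # 8-kHz channel during the quiet half, per threshold class
        centers = cg.center_freqs[:8]
        ch = int(np.argmin(np.abs(centers - 8000)))
        quiet_bins = slice(60, 95)
        low, mid, high = (cg.values[8 * b + ch, quiet_bins].mean() for b in range(3))
        assert low > 0.2
        assert high < 0.05
        assert low > mid and mid >= high

    def test_block_layout_and_ordering(self, noise_audio):
        cg = make_multithreshold_cochleagram(
            noise_audio, FilterbankSpec(4, spectrogram_mode="power"),
            MultithresholdSpec(),
        )
        assert cg.provenance["threshold_classes"] == ["LTH", "MTH", "HTH"]
        np.testing.assert_allclose(cg.center_freqs[:4], cg.center_freqs[4:8])
        thetas = [c["theta"] for c in cg.provenance["compression"]]
        assert thetas[0] < thetas[1] < thetas[2]

    def test_decreasing_thresholds_rejected(self):
        with pytest.raises(ConfigurationError):
            MultithresholdSpec(thetas=(0.1, 0.01, 0.001))


class TestIO:
    def test_wav_round_trip(self, tmp_path, noise_audio):
        path = tmp_path / "x.wav"
        write_wav(path, noise_audio)
        back = read_wav(path)
        assert back.sample_rate == 48000.0
        np.testing.assert_allclose(back.samples, noise_audio.samples, atol=1e-6)

    def test_stereo_rejected(self, tmp_path):
        import scipy.io.wavfile

        path = tmp_path / "stereo.wav"
        scipy.io.wavfile.write(path, 48000, np.zeros((100, 2), dtype=np.int16))
        with pytest.raises(InputError, match="mono"):
            read_wav(path)

    def test_cochleagram_round_trip_bit_exact(self, tmp_path, noise_audio):
        cg = make_cochleagram(
            noise_audio, FilterbankSpec(8), CompressionSpec("log_thresholded")
        )
        path = tmp_path / "cg.npz"
        save_cochleagram(path, cg)
        back = load_cochleagram(path)
        np.testing.assert_array_equal(back.values, cg.values)
        np.testing.assert_array_equal(back.center_freqs, cg.center_freqs)
        assert back.bin_ms == cg.bin_ms
        assert back.provenance == cg.provenance

    def test_plugin_adapter_averages_stochastic_repeats(self, noise_audio):
        calls = []

        def provider(samples, fs, n_channels):
            calls.append(1)
            values = np.full((n_channels, 10), float(len(calls)))
            return values, np.geomspace(500, 8000, n_channels), 10.0

        fe = PluginFrontEnd(provider, name="toy", n_repeats=4)
        cg = fe(noise_audio, 4)
        assert len(calls) == 4
        np.testing.assert_allclose(cg.values, (1 + 2 + 3 + 4) / 4.0)
        assert cg.provenance["n_repeats"] == 4
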