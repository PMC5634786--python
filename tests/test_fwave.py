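"""Unit and property tests for fundamental-waveform extraction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from speechffr.fwave import (
    TARGET_RATE,
    AudioSignal,
    FundamentalWaveform,
    IMFSet,
    assemble_waveform,
    check_alignment,
    decompose_segment,
    emd,
    extract_fundamental_waveform,
    extract_segments,
    gate_silence,
    instantaneous_frequency,
    preprocess_audio,
    satisfies_imf_criterion,
    select_fundamental_mode,
    track_f0,
)

from conftest import tone


def rms(x):
    return float(np.sqrt(np.mean(np.square(x))))


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

class TestPreprocessAudio:
    def test_passband_tone_survives_resampling(self):
        out = preprocess_audio(tone(100.0, duration=1.0, rate=44100))
        assert out.rate == TARGET_RATE
        # compare RMS away from filter edges; < 1 dB change
        core = out.samples[2000:-2000]
        assert abs(20 * np.log10(rms(core) / (1 / np.sqrt(2)))) < 1.0

    def test_stopband_tone_attenuated_80db(self):
        out = preprocess_audio(tone(2000.0, duration=1.0, rate=8820))
        attenuation = 20 * np.log10(rms(out.samples[2000:-2000]) / (1 / np.sqrt(2)))
        assert attenuation <= -80.0

    def test_impulse_delay_compensated(self):
        x = np.zeros(8820)
        x[4410] = 1.0
        out = preprocess_audio(AudioSignal(x, 8820))
        energy = out.samples**2
        centre = float(np.sum(np.arange(energy.size) * energy) / energy.sum())
        assert abs(centre - 4410) <= 1.0

    def test_low_rate_rejected(self):
        with pytest.raises(ValueError, match="rate"):
            preprocess_audio(tone(100.0, rate=8000))


class TestGateSilence:
    def test_all_zero_unchanged(self):
        out = gate_silence(AudioSignal(np.zeros(1000), TARGET_RATE))
        assert not np.any(out.samples)

    def test_quiet_section_zeroed_loud_kept(self):
        loud = tone(150.0, duration=0.5).samples
        quiet = 0.05 * tone(150.0, duration=0.5).samples
        out = gate_silence(AudioSignal(np.concatenate([loud, quiet]), TARGET_RATE))
        n = loud.size
        # quiet half (envelope 0.05 < 0.1 * 1.0) is zeroed
        assert not np.any(out.samples[n + 200:])
        # loud half is untouched away from the boundary
        assert np.array_equal(out.samples[:n - 200], loud[:n - 200])

    def test_constant_amplitude_tone_untouched_in_interior(self):
        x = tone(150.0, duration=1.0)
        out = gate_silence(x)
        assert np.array_equal(out.samples[500:-500], x.samples[500:-500])


# ---------------------------------------------------------------------------
# f0 tracking
# ---------------------------------------------------------------------------

class TestTrackF0:
    def test_pure_tone_tracked_within_1hz(self):
        track = track_f0(tone(150.0, duration=1.0))
        assert track.voiced.all()
        assert np.all(np.abs(track.f0 - 150.0) < 1.0)

    def test_subsonic_tone_voiceless(self):
        track = track_f0(tone(50.0, duration=1.0))
        assert not track.voiced.any()

    def test_f0_jump_splits_voicing(self):
        a = tone(120.0, duration=0.5).samples
        b = tone(200.0, duration=0.5).samples
        track = track_f0(AudioSignal(np.concatenate([a, b]), TARGET_RATE))
        runs = track.voiced_runs()
        assert len(runs) >= 2
        # the 10 Hz jump rule holds inside every voiced run
        for i0, i1 in runs:
            assert np.all(np.abs(np.diff(track.f0[i0:i1 + 1])) <= 10.0)

    def test_short_signal_gives_empty_track(self):
        track = track_f0(tone(150.0, duration=0.01))
        assert track.f0.size == 0

    def test_idempotent_voicing_on_gated_signal(self, short_speech_prepped):
        first = track_f0(short_speech_prepped)
        second = track_f0(short_speech_prepped)
        assert np.array_equal(first.voiced, second.voiced)


class TestExtractSegments:
    def test_constant_f0_spline_is_constant(self):
        audio = tone(200.0, duration=0.5)
        track = track_f0(audio)
        segs = extract_segments(track, audio)
        assert len(segs) == 1
        f = segs[0].f0_at_samples(audio.rate)
        assert np.allclose(f, 200.0, atol=1.0)

    def test_spline_reproduces_knots_exactly(self):
        from speechffr.fwave import F0Track

        times = np.array([0.0, 0.05, 0.1, 0.15])
        f0 = np.array([100.0, 110.0, 118.0, 125.0])
        track = F0Track(times, f0)
        audio = tone(150.0, duration=0.2)
        (seg,) = extract_segments(track, audio)
        assert np.allclose(seg.f0_fn(times), f0, rtol=0, atol=1e-9)

    def test_two_voiced_runs_give_two_disjoint_segments(self):
        voiced = tone(150.0, duration=0.4).samples
        gap = np.zeros(int(0.3 * TARGET_RATE))
        audio = AudioSignal(np.concatenate([voiced, gap, voiced]), TARGET_RATE)
        track = track_f0(audio)
        segs = extract_segments(track, audio)
        assert len(segs) == 2
        assert segs[0].stop <= segs[1].start


# ---------------------------------------------------------------------------
# empirical mode decomposition
# ---------------------------------------------------------------------------

class TestEMD:
    def test_sinusoid_is_its_own_imf(self):
        x = tone(200.0, duration=0.5).samples
        modes, residual = emd(x)
        r = np.corrcoef(modes[0], x)[0, 1]
        assert r > 0.99
        assert rms(residual) < 0.01 * rms(x)

    def test_well_separated_tones_split_into_modes(self):
        t = np.arange(int(0.5 * TARGET_RATE)) / TARGET_RATE
        hi = np.cos(2 * np.pi * 300 * t)
        lo = np.cos(2 * np.pi * 80 * t + 0.7)
        modes, _ = emd(hi + lo)
        assert len(modes) >= 2
        # interior samples only: mirror boundaries distort the edges
        sl = slice(400, -400)
        r_hi = abs(np.corrcoef(modes[0][sl], hi[sl])[0, 1])
        r_lo = max(
            abs(np.corrcoef(m[sl], lo[sl])[0, 1]) for m in modes[1:]
        )
        assert r_hi > 0.95
        assert r_lo > 0.95

    def test_completeness_and_imf_criterion(self, short_speech_prepped):
        track = track_f0(short_speech_prepped)
        segs = extract_segments(track, short_speech_prepped)
        assert segs
        for seg in segs[:5]:
            x = short_speech_prepped.samples[seg.start:seg.stop]
            modes, residual = emd(x)
            recon = np.sum(modes, axis=0) + residual
            assert np.max(np.abs(recon - x)) <= 1e-8 * max(np.max(np.abs(x)), 1e-30)
            for mode in modes:
                assert satisfies_imf_criterion(mode)

    def test_constant_input_is_pure_residual(self):
        imfs = decompose_segment(np.full(1000, 2.5))
        assert imfs.n_modes == 0
        assert np.array_equal(imfs.residual, np.full(1000, 2.5))

    @settings(deadline=None, max_examples=10, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_completeness_on_random_smooth_signals(self, seed):
        rng = np.random.default_rng(seed)
        x = np.cumsum(rng.standard_normal(2000))
        x -= np.linspace(x[0], x[-1], x.size)
        modes, residual = emd(x)
        recon = np.sum(modes, axis=0) + residual if modes else residual
        scale = max(np.max(np.abs(x)), 1e-30)
        assert np.max(np.abs(recon - x)) <= 1e-8 * scale


class TestSelectFundamentalMode:
    def _imfset(self, modes, freqs, amps):
        modes = np.asarray(modes, float)
        return IMFSet(
            modes=modes,
            residual=np.zeros(modes.shape[1]),
            inst_freq=np.asarray(freqs, float),
            inst_amp=np.asarray(amps, float),
            rate=TARGET_RATE,
        )

    def test_single_matching_mode_passes_through(self):
        n = 100
        mode = np.sin(np.linspace(0, 10, n))
        imfs = self._imfset([mode], [np.full(n, 150.0)], [np.ones(n)])
        values, choice = select_fundamental_mode(imfs, np.full(n, 150.0))
        assert np.array_equal(values, mode)
        assert np.all(choice == 0)

    def test_largest_amplitude_candidate_wins(self):
        n = 10
        imfs = self._imfset(
            [np.full(n, 5.0), np.full(n, 7.0)],
            [np.full(n, 150.0), np.full(n, 160.0)],
            [np.full(n, 1.0), np.full(n, 0.5)],
        )
        values, choice = select_fundamental_mode(imfs, np.full(n, 155.0))
        assert np.all(choice == 0)
        assert np.all(values == 5.0)

    def test_no_candidate_yields_zero(self):
        n = 10
        imfs = self._imfset(
            [np.full(n, 5.0)], [np.full(n, 400.0)], [np.full(n, 1.0)]
        )
        values, choice = select_fundamental_mode(imfs, np.full(n, 150.0))
        assert np.all(values == 0.0)
        assert np.all(choice == -1)


# ---------------------------------------------------------------------------
# crossfaded assembly
# ---------------------------------------------------------------------------

class TestAssembleWaveform:
    def test_single_constant_piece_flat_inside_ramps(self):
        ramp = int(round(0.010 * TARGET_RATE))
        fw = assemble_waveform([(1000, np.ones(3000))], 6000)
        inner = fw.samples[1000 + ramp:4000 - ramp]
        assert np.allclose(inner, 1.0, atol=1e-9)
        assert not np.any(fw.samples[:1000 - ramp])
        assert fw.voicing_mask[1000:4000].all()
        assert not fw.voicing_mask[:1000].any()

    def test_abutting_constant_pieces_crossfade_to_constant(self):
        fw = assemble_waveform(
            [(500, np.ones(2000)), (2500, np.ones(2000))], 6000
        )
        # complementary ramps: no dip at the junction
        assert np.allclose(fw.samples[2400:2600], 1.0, atol=1e-9)

    def test_empty_pieces_give_silent_waveform(self):
        fw = assemble_waveform([], 5000)
        assert not np.any(fw.samples)
        assert not np.any(fw.quadrature)
        assert not fw.voicing_mask.any()

    def test_out_of_range_piece_rejected(self):
        with pytest.raises(ValueError, match="span"):
            assemble_waveform([(4500, np.ones(1000))], 5000)

    @settings(deadline=None, max_examples=15, derandomize=True)
    @given(st.lists(st.integers(200, 1500), min_size=1, max_size=4))
    def test_partition_of_unity_for_abutting_pieces(self, lengths):
        """Abutting unit pieces always blend back to one in the interior."""
        pieces, pos = [], 1000
        for ln in lengths:
            pieces.append((pos, np.ones(ln)))
            pos += ln
        fw = assemble_waveform(pieces, pos + 1000)
        ramp = int(round(0.010 * TARGET_RATE))
        inner = fw.samples[1000 + ramp:pos - ramp]
        if inner.size:
            assert np.allclose(inner, 1.0, atol=1e-9)


# ---------------------------------------------------------------------------
# alignment and end-to-end extraction
# ---------------------------------------------------------------------------

class TestCheckAlignment:
    def test_waveform_against_itself_peaks_at_zero(self, short_fwave):
        speech = AudioSignal(short_fwave.samples, short_fwave.rate)
        res = check_alignment(speech, short_fwave)
        assert res.lag_samples == 0

    def test_delayed_waveform_gives_negative_lag(self, short_fwave):
        shift = int(round(0.005 * TARGET_RATE))
        delayed = FundamentalWaveform(
            np.roll(short_fwave.samples, shift),
            np.roll(short_fwave.quadrature, shift),
            np.roll(short_fwave.voicing_mask, shift),
            short_fwave.rate,
        )
        speech = AudioSignal(short_fwave.samples, short_fwave.rate)
        res = check_alignment(speech, delayed)
        assert res.lag_samples == -shift

    def test_zero_variance_rejected(self, short_fwave):
        with pytest.raises(ValueError, match="variance"):
            check_alignment(
                AudioSignal(np.zeros(len(short_fwave)), TARGET_RATE), short_fwave
            )


class TestEndToEnd:
    def test_extraction_introduces_no_latency(self, short_speech, short_fwave):
        res = check_alignment(preprocess_audio(short_speech), short_fwave)
        assert abs(res.lag_samples) <= 1

    def test_waveform_tracks_known_f0_contour(self):
        from speechffr.simulate import SynthSpeechSpec, synth_speech

        contour = lambda t: 140.0 + 30.0 * np.sin(2 * np.pi * t / 4.0)
        speech = synth_speech(
            SynthSpeechSpec(f0_contour=contour, pause_fraction=0.0, seed=9),
            8.0,
        )
        fwave = extract_fundamental_waveform(speech)
        fi = instantaneous_frequency(fwave)
        t = np.arange(fi.size) / fwave.rate
        ok = np.isfinite(fi)
        assert ok.mean() > 0.8
        err = fi[ok] - contour(t[ok])
        assert np.sqrt(np.mean(err**2)) < 5.0

    def test_waveform_zero_outside_voicing(self, short_fwave):
        ramp = int(round(0.010 * TARGET_RATE))
        # erode the unvoiced complement by the crossfade ramp width
        from scipy.ndimage import binary_dilation

        near_voiced = binary_dilation(short_fwave.voicing_mask, iterations=ramp)
        assert not np.any(short_fwave.samples[~near_voiced])
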