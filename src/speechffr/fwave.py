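"""Extraction of the fundamental waveform of running speech.

The fundamental waveform is the nonstationary oscillation that tracks the
fundamental frequency (pitch) of voiced speech in both instantaneous frequency
and amplitude.  It is the regressor against which a scalp recording is
cross-correlated to read out the brainstem's frequency-following response to
continuous, non-repetitive speech.

The extraction proceeds in five steps:

1. the speech signal is downsampled to 8820 Hz and low-pass filtered at
   1500 Hz with a delay-compensated linear-phase FIR filter;
2. pauses are silenced: samples where the envelope falls below a fraction
   (default 10%) of its maximum are set to zero;
3. the fundamental frequency f0 is tracked by the autocorrelation method in
   50 ms rectangular windows hopping every 1 ms; windows whose best
   periodicity lies outside 60-400 Hz, or whose f0 jumps by more than 10 Hz
   between successive windows, are marked voiceless;
4. every maximal voiced run is decomposed by empirical mode decomposition
   (EMD); at each sample the intrinsic mode function (IMF) whose
   instantaneous frequency lies within 20% of the spline-interpolated f0 and
   whose instantaneous amplitude is largest is selected;
5. the selected pieces are joined by 10 ms cosine crossfades, and the Hilbert
   transform of the assembled waveform provides the 90-degree-shifted
   quadrature component.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Callable, Sequence

import numpy as np
from scipy import signal
from scipy.fft import next_fast_len
from scipy.interpolate import make_interp_spline
from scipy.ndimage import median_filter

#: Common working rate (Hz) for speech and for the lag grid of the
#: cross-correlation: 44100 / 5.
TARGET_RATE = 8820

_LOWPASS_CUTOFF_HZ = 1575.0  # centre of the 1500-1650 Hz transition band
_LOWPASS_WIDTH_HZ = 150.0
_STOP_ATTEN_DB = 80.0


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class AudioSignal:
    """A sampled pressure-like waveform (mono) with its sampling rate."""

    samples: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("AudioSignal is mono: expected a 1-D sample array")
        if not self.rate > 0:
            raise ValueError("sampling rate must be positive")
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Length of the signal in seconds."""
        return self.samples.size / self.rate


@dataclass
class F0Track:
    """Windowed fundamental-frequency estimates.

    ``f0`` holds one estimate (Hz) per analysis window; voiceless windows are
    marked ``NaN``.  ``window_times`` are the window centres in seconds.
    """

    window_times: np.ndarray
    f0: np.ndarray
    win_s: float = 0.050
    hop_s: float = 0.001

    @property
    def voiced(self) -> np.ndarray:
        return np.isfinite(self.f0)

    def voiced_runs(self) -> list[tuple[int, int]]:
        """Maximal runs of voiced windows as inclusive ``(first, last)`` pairs."""
        v = self.voiced
        if v.size == 0:
            return []
        edges = np.flatnonzero(np.diff(v.astype(np.int8)))
        starts = np.concatenate([[0], edges + 1])
        stops = np.concatenate([edges, [v.size - 1]])
        return [(int(a), int(b)) for a, b in zip(starts, stops) if v[a]]


@dataclass
class VoicedSegment:
    """A maximal voiced stretch with a continuous f0 interpolant.

    ``start``/``stop`` delimit the half-open sample span in the 8820 Hz
    signal; ``f0_fn`` maps time (s) to f0 (Hz) and reproduces the window
    estimates exactly at the knots.
    """

    start: int
    stop: int
    f0_fn: Callable[[np.ndarray], np.ndarray]
    knot_times: np.ndarray
    knot_f0: np.ndarray

    def f0_at_samples(self, rate: float) -> np.ndarray:
        t = np.arange(self.start, self.stop) / rate
        return np.asarray(self.f0_fn(t), dtype=float)


@dataclass
class IMFSet:
    """Intrinsic mode functions of one voiced segment with Hilbert spectra."""

    modes: np.ndarray      # (n_modes, n_samples)
    residual: np.ndarray
    inst_freq: np.ndarray  # Hz, same shape as modes
    inst_amp: np.ndarray
    rate: float

    @property
    def n_modes(self) -> int:
        return self.modes.shape[0]

    def reconstruction(self) -> np.ndarray:
        out = self.residual.copy()
        if self.n_modes:
            out += self.modes.sum(axis=0)
        return out


@dataclass
class FundamentalWaveform:
    """The fundamental waveform, its quadrature and the voicing mask."""

    samples: np.ndarray
    quadrature: np.ndarray
    voicing_mask: np.ndarray
    rate: float = TARGET_RATE

    def __len__(self) -> int:
        return self.samples.size


@dataclass
class AlignmentResult:
    """Lag of maximum cross-correlation between speech and its waveform."""

    lag_ms: float
    lag_samples: int
    amplitude: float


# ---------------------------------------------------------------------------
# step 1: resampling and low-pass filtering
# ---------------------------------------------------------------------------

def design_lowpass(rate: float = TARGET_RATE) -> np.ndarray:
    """Kaiser-window linear-phase FIR: transition 1500-1650 Hz, -80 dB stop."""
    nyq = rate / 2.0
    numtaps, beta = signal.kaiserord(_STOP_ATTEN_DB, _LOWPASS_WIDTH_HZ / nyq)
    numtaps += 1 - numtaps % 2  # odd length -> integer group delay
    return signal.firwin(numtaps, _LOWPASS_CUTOFF_HZ, window=("kaiser", beta), fs=rate)


def filter_zero_phase(x: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Apply a linear-phase FIR and remove its group delay.

    The filter's (odd) length gives an integer group delay of
    ``(len(taps) - 1) // 2`` samples, which is trimmed from the full
    convolution so the net latency is zero.
    """
    x = np.asarray(x, float)
    if x.size < taps.size:
        raise ValueError(
            f"signal ({x.size} samples) shorter than filter ({taps.size} taps)"
        )
    d = (taps.size - 1) // 2
    y = signal.oaconvolve(x, taps, mode="full")
    return y[d:d + x.size]


def preprocess_audio(audio: AudioSignal) -> AudioSignal:
    """Downsample to 8820 Hz and low-pass at 1500 Hz with zero net latency."""
    if audio.rate < TARGET_RATE:
        raise ValueError(
            f"input rate {audio.rate} Hz below the working rate {TARGET_RATE} Hz"
        )
    x = audio.samples
    if audio.rate != TARGET_RATE:
        if float(audio.rate).is_integer():
            frac = Fraction(TARGET_RATE, int(audio.rate))
        else:
            frac = Fraction(TARGET_RATE / audio.rate).limit_denominator(10_000)
        x = signal.resample_poly(x, frac.numerator, frac.denominator)
    taps = design_lowpass(TARGET_RATE)
    return AudioSignal(filter_zero_phase(x, taps), TARGET_RATE)


# ---------------------------------------------------------------------------
# step 2: silence gating
# ---------------------------------------------------------------------------

def gate_silence(
    audio: AudioSignal,
    threshold_frac: float = 0.1,
    smooth_s: float = 0.010,
) -> AudioSignal:
    """Zero all samples where the envelope is below a fraction of its maximum.

    The envelope is the magnitude of the analytic signal smoothed by a 10 ms
    moving average.  An all-zero input is returned unchanged.
    """
    x = audio.samples
    if x.size == 0 or not np.any(x):
        return AudioSignal(x.copy(), audio.rate)
    env = np.abs(signal.hilbert(x, next_fast_len(x.size))[:x.size])
    k = max(1, int(round(smooth_s * audio.rate)))
    env = np.convolve(env, np.ones(k) / k, mode="same")
    out = x.copy()
    out[env < threshold_frac * env.max()] = 0.0
    return AudioSignal(out, audio.rate)


# ---------------------------------------------------------------------------
# step 3: f0 tracking by autocorrelation
# ---------------------------------------------------------------------------

def track_f0(
    audio: AudioSignal,
    f0_min: float = 60.0,
    f0_max: float = 400.0,
    max_jump: float = 10.0,
    win_s: float = 0.050,
    hop_s: float = 0.001,
    clarity: float = 0.25,
) -> F0Track:
    """Track f0 in 50 ms rectangular windows with a 1 ms hop.

    In each window the autocorrelation is evaluated over lags covering a band
    slightly wider than ``[f0_min, f0_max]``, so that dominant periodicities
    just outside the accepted range are detected and flagged voiceless rather
    than snapped to the band edge.  The highest peak is refined by parabolic
    interpolation.  A window is voiceless when it is silent (zero energy),
    when the normalised peak falls below ``clarity`` (an indistinct
    periodicity, typical of gating boundaries), when the implied f0 lies
    outside ``[f0_min, f0_max]``, or when it differs by more than ``max_jump``
    Hz from the estimate of the preceding window.
    """
    x = audio.samples
    rate = audio.rate
    win = int(round(win_s * rate))
    n = x.size
    if n < win:
        e = np.empty(0)
        return F0Track(e, e.copy(), win_s=win_s, hop_s=hop_s)
    hop = hop_s * rate
    n_win = int(np.floor((n - win) / hop)) + 1
    starts = np.round(np.arange(n_win) * hop).astype(np.int64)
    times = (starts + 0.5 * win) / rate

    lag_lo = max(2, int(np.floor(rate / (f0_max * 1.25))))
    lag_hi = min(int(np.ceil(rate / (f0_min * 0.8))), win - 2)
    lags = np.arange(lag_lo, lag_hi + 1)

    cs0 = np.concatenate([[0.0], np.cumsum(x * x)])
    energy = cs0[starts + win] - cs0[starts]

    # windowed autocorrelation, one vectorised pass per lag
    r = np.empty((n_win, lags.size), dtype=np.float32)
    for j, k in enumerate(lags):
        c = np.concatenate([[0.0], np.cumsum(x[: n - k] * x[k:])])
        r[:, j] = c[starts + win - k] - c[starts]
    np.divide(r, energy[:, None], out=r, where=energy[:, None] > 0)

    best = np.argmax(r, axis=1)
    rows = np.arange(n_win)
    r0 = r[rows, best].astype(float)
    interior = (best > 0) & (best < lags.size - 1)
    rm = r[rows, np.maximum(best - 1, 0)].astype(float)
    rp = r[rows, np.minimum(best + 1, lags.size - 1)].astype(float)
    # the rectangular-window autocorrelation carries a deterministic
    # (1 - k/win) taper; undo it locally so the parabolic interpolation is
    # not skewed toward smaller lags (the taper stays in place for peak
    # *selection*, where it usefully favours the one-period peak)
    k0 = lags[best].astype(float)
    r0 = r0 * win / (win - k0)
    rm = rm * win / (win - (k0 - 1.0))
    rp = rp * win / (win - (k0 + 1.0))
    denom = rm - 2.0 * r0 + rp
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = np.where(interior & (denom < 0), 0.5 * (rm - rp) / denom, 0.0)
    delta = np.clip(delta, -0.5, 0.5)
    lag_star = lags[best] + delta
    f0 = rate / lag_star

    valid = (energy > 0) & (r0 > clarity) & (f0 >= f0_min) & (f0 <= f0_max)
    jump = np.zeros(n_win, dtype=bool)
    jump[1:] = valid[1:] & valid[:-1] & (np.abs(np.diff(f0)) > max_jump)
    voiced = valid & ~jump
    f0_out = np.where(voiced, f0, np.nan)
    return F0Track(times, f0_out, win_s=win_s, hop_s=hop_s)


# ---------------------------------------------------------------------------
# step 3b: voiced segments with spline-interpolated f0
# ---------------------------------------------------------------------------

def extract_segments(track: F0Track, audio: AudioSignal) -> list[VoicedSegment]:
    """One segment per maximal voiced run, with a cubic-spline f0 interpolant.

    Runs of a single window carry no interpolable span and are dropped.  For
    runs of two or three windows the spline degree is reduced accordingly
    (the interpolant still reproduces the knots exactly).
    """
    rate = audio.rate
    segments: list[VoicedSegment] = []
    for i0, i1 in track.voiced_runs():
        if i1 == i0:
            continue
        t = track.window_times[i0:i1 + 1]
        f = track.f0[i0:i1 + 1]
        k = 3 if t.size >= 4 else t.size - 1
        spl = make_interp_spline(t, f, k=k, bc_type="natural" if k == 3 else None)
        start = int(round(t[0] * rate))
        stop = min(len(audio), int(round(t[-1] * rate)) + 1)
        if stop - start < 2:
            continue
        segments.append(VoicedSegment(start, stop, spl, t.copy(), f.copy()))
    return segments


# ---------------------------------------------------------------------------
# step 4: empirical mode decomposition
# ---------------------------------------------------------------------------

def _extrema_indices(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of local maxima and minima; plateaus count once."""
    s = np.sign(np.diff(x))
    if s.size == 0:
        e = np.empty(0, dtype=np.int64)
        return e, e.copy()
    idx = np.arange(s.size)
    idx[s == 0] = -1
    idx = np.maximum.accumulate(idx)
    sf = np.where(idx >= 0, s[np.maximum(idx, 0)], 0.0)
    ch = np.diff(sf)
    maxima = np.nonzero((ch < 0) & (sf[:-1] > 0))[0] + 1
    minima = np.nonzero((ch > 0) & (sf[:-1] < 0))[0] + 1
    return maxima, minima


def _mirror_envelope(x: np.ndarray, ext_idx: np.ndarray, nbsym: int = 2):
    """Cubic-spline envelope through extrema, mirror-extended at both ends."""
    n = x.size
    if ext_idx.size < 2:
        return None
    p = ext_idx.astype(np.int64)
    v = x[p]
    k = min(nbsym, p.size)
    lp, lv = (-p[:k])[::-1], v[:k][::-1]
    if p[0] == 0:
        lp, lv = lp[:-1], lv[:-1]
    rp, rv = (2 * (n - 1) - p[-k:])[::-1], v[-k:][::-1]
    if p[-1] == n - 1:
        rp, rv = rp[1:], rv[1:]
    pos = np.concatenate([lp, p, rp])
    val = np.concatenate([lv, v, rv])
    keep = np.concatenate([[True], np.diff(pos) > 0])
    pos, val = pos[keep], val[keep]
    if pos.size < 2:
        return None
    deg = 3 if pos.size >= 4 else pos.size - 1
    return make_interp_spline(pos, val, k=deg)(np.arange(n))


def _count_zero_crossings(x: np.ndarray) -> int:
    s = np.sign(x)
    s = s[s != 0]
    return int(np.count_nonzero(np.diff(s)))


def satisfies_imf_criterion(h: np.ndarray) -> bool:
    """Extrema and zero-crossing counts equal or differing by one."""
    mx, mn = _extrema_indices(h)
    return abs(int(mx.size + mn.size) - _count_zero_crossings(h)) <= 1


def emd(
    x: Sequence[float],
    max_imfs: int = 12,
    sd_tol: float = 0.2,
    max_sift: int = 200,
    min_extrema: int = 4,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Empirical mode decomposition by sifting.

    Envelopes are cubic splines through mirror-extended extrema.  Sifting of
    a mode stops once the normalised squared envelope mean (the SD criterion)
    falls below ``sd_tol`` and the extrema/zero-crossing property holds, or
    after ``max_sift`` iterations.  Decomposition stops when fewer than
    ``min_extrema`` (at least four) extrema remain or after ``max_imfs``
    modes; raising ``min_extrema`` skips oscillations slower than any
    frequency of interest, leaving them in the residual.  The residual is
    computed by subtraction, so modes + residual reconstruct the input to
    machine precision.
    """
    x = np.asarray(x, dtype=float)
    min_extrema = max(4, min_extrema)
    modes: list[np.ndarray] = []
    r = x.copy()
    for _ in range(max_imfs):
        mx, mn = _extrema_indices(r)
        if mx.size + mn.size < min_extrema:
            break
        h = r.copy()
        for _ in range(max_sift):
            mx, mn = _extrema_indices(h)
            if mx.size < 2 or mn.size < 2:
                break
            upper = _mirror_envelope(h, mx)
            lower = _mirror_envelope(h, mn)
            if upper is None or lower is None:
                break
            m = 0.5 * (upper + lower)
            denom = float(np.dot(h, h))
            if denom == 0.0:
                break
            sd = float(np.dot(m, m)) / denom
            h = h - m
            if sd < sd_tol and satisfies_imf_criterion(h):
                break
        modes.append(h)
        r = r - h
    residual = x - np.sum(modes, axis=0) if modes else x.copy()
    return modes, residual


def decompose_segment(
    segment_signal: Sequence[float],
    rate: float = TARGET_RATE,
    smooth_s: float = 0.005,
    stop_below_hz: float = 50.0,
    **emd_kwargs,
) -> IMFSet:
    """EMD of one voiced segment plus per-mode Hilbert spectra.

    Instantaneous frequency is the central-difference derivative of the
    analytic-signal phase, median-filtered over 5 ms to suppress derivative
    spikes; instantaneous amplitude is the analytic-signal magnitude.
    Decomposition stops once the residual oscillates more slowly than
    ``stop_below_hz`` (judged by its extrema density): such modes lie below
    the admissible f0 range and can never be selected, so they stay in the
    residual.  Segments with fewer than four extrema are returned
    undecomposed, as a pure residual.
    """
    x = np.asarray(segment_signal, dtype=float)
    mx, mn = _extrema_indices(x)
    if mx.size + mn.size < 4:
        z = np.zeros((0, x.size))
        return IMFSet(z, x.copy(), z.copy(), z.copy(), rate)
    emd_kwargs.setdefault(
        "min_extrema", int(2.0 * stop_below_hz * x.size / rate)
    )
    mode_list, residual = emd(x, **emd_kwargs)
    modes = np.asarray(mode_list)
    if modes.shape[0] == 0:
        z = np.zeros((0, x.size))
        return IMFSet(z, residual, z.copy(), z.copy(), rate)
    nfft = next_fast_len(x.size)
    analytic = signal.hilbert(modes, N=nfft, axis=1)[:, :x.size]
    amp = np.abs(analytic)
    phase = np.unwrap(np.angle(analytic), axis=1)
    freq = np.gradient(phase, axis=1) * rate / (2.0 * np.pi)
    # median-filter on a 5x decimated grid: derivative spikes remain
    # isolated outliers there, and the selection rule only needs the
    # frequency to a few percent
    stride = 5
    k = int(round(smooth_s * rate / stride))
    k += 1 - k % 2
    if k >= 3 and freq.shape[1] > stride * k:
        coarse = median_filter(freq[:, ::stride], size=(1, k), mode="nearest")
        freq = coarse[:, np.minimum(
            np.arange(freq.shape[1]) // stride, coarse.shape[1] - 1
        )]
    return IMFSet(modes, residual, freq, amp, rate)


def select_fundamental_mode(
    imfs: IMFSet,
    f0: Sequence[float],
    rel_tol: float = 0.2,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample choice of the fundamental mode.

    At each sample, candidate modes have instantaneous frequency within
    ``rel_tol`` (default 20%) of the target f0; among candidates, the mode
    with the largest instantaneous amplitude wins.  Returns the selected
    values (zero where no candidate exists) and the chosen mode index per
    sample (-1 where none).
    """
    f0 = np.asarray(f0, dtype=float)
    n = f0.size
    if imfs.n_modes == 0:
        return np.zeros(n), np.full(n, -1, dtype=np.int64)
    rel = np.abs(imfs.inst_freq - f0[None, :]) / f0[None, :]
    cand = rel < rel_tol
    amp = np.where(cand, imfs.inst_amp, -np.inf)
    choice = np.argmax(amp, axis=0).astype(np.int64)
    choice[~cand.any(axis=0)] = -1
    cols = np.arange(n)
    values = np.where(choice >= 0, imfs.modes[np.maximum(choice, 0), cols], 0.0)
    return values, choice


def _pieces_from_choice(
    values: np.ndarray, choice: np.ndarray, offset: int
) -> list[tuple[int, np.ndarray]]:
    """Split a per-sample selection into pieces at mode switches."""
    n = choice.size
    if n == 0:
        return []
    cut = np.nonzero(np.diff(choice))[0] + 1
    bounds = np.concatenate([[0], cut, [n]])
    return [
        (offset + int(a), values[a:b].copy())
        for a, b in zip(bounds[:-1], bounds[1:])
        if choice[a] >= 0
    ]


# ---------------------------------------------------------------------------
# step 5: crossfaded assembly
# ---------------------------------------------------------------------------

def assemble_waveform(
    pieces: Sequence[tuple[int, np.ndarray]],
    total_length: int,
    rate: float = TARGET_RATE,
    crossfade_ms: float = 10.0,
) -> FundamentalWaveform:
    """Join waveform pieces with 10 ms raised-cosine crossfades.

    Each piece's weight is its span indicator smoothed by a normalised Hann
    kernel of the crossfade width.  Because the smoothing is linear, the
    weights of abutting or overlapping pieces sum to the smoothed union
    indicator: coincident constant pieces crossfade to the constant instead
    of summing, and isolated pieces ramp to zero over half a window on each
    side.  The quadrature is the Hilbert transform of the assembled waveform.
    """
    out = np.zeros(total_length)
    mask = np.zeros(total_length, dtype=bool)
    width = int(round(crossfade_ms / 1000.0 * rate))
    width += 1 - width % 2
    half = width // 2
    kernel = np.hanning(width)
    kernel /= kernel.sum()
    for start, vals in pieces:
        vals = np.asarray(vals, dtype=float)
        if vals.size == 0:
            continue
        stop = start + vals.size
        if start < 0 or stop > total_length:
            raise ValueError("piece span outside [0, total_length)")
        mask[start:stop] = True
        a = max(0, start - half)
        b = min(total_length, stop + half)
        indicator = np.zeros(b - a)
        indicator[start - a:stop - a] = 1.0
        weight = signal.convolve(indicator, kernel, mode="same")
        padded = np.concatenate(
            [np.full(start - a, vals[0]), vals, np.full(b - stop, vals[-1])]
        )
        out[a:b] += weight * padded
    if np.any(out):
        quad = signal.hilbert(out, next_fast_len(total_length))[:total_length].imag
    else:
        quad = np.zeros(total_length)
    return FundamentalWaveform(out, quad, mask, rate)


# ---------------------------------------------------------------------------
# full pipeline and diagnostics
# ---------------------------------------------------------------------------

def extract_fundamental_waveform(
    audio: AudioSignal,
    silence_frac: float = 0.1,
    f0_min: float = 60.0,
    f0_max: float = 400.0,
    max_jump: float = 10.0,
    rel_tol: float = 0.2,
    crossfade_ms: float = 10.0,
) -> FundamentalWaveform:
    """Run the full extraction: preprocess, gate, track, decompose, assemble."""
    prepped = preprocess_audio(audio)
    gated = gate_silence(prepped, threshold_frac=silence_frac)
    track = track_f0(gated, f0_min=f0_min, f0_max=f0_max, max_jump=max_jump)
    segments = extract_segments(track, gated)
    pieces: list[tuple[int, np.ndarray]] = []
    for seg in segments:
        xs = gated.samples[seg.start:seg.stop]
        f0 = seg.f0_at_samples(gated.rate)
        imfs = decompose_segment(xs, rate=gated.rate)
        values, choice = select_fundamental_mode(imfs, f0, rel_tol=rel_tol)
        pieces.extend(_pieces_from_choice(values, choice, seg.start))
    return assemble_waveform(
        pieces, len(gated), rate=gated.rate, crossfade_ms=crossfade_ms
    )


def check_alignment(
    speech: AudioSignal,
    fwave: FundamentalWaveform,
    max_lag_ms: float = 20.0,
) -> AlignmentResult:
    """Lag (ms) of the maximum cross-correlation between speech and waveform.

    Positive lag means the waveform's best match occurs when the first
    argument (the speech) is read later than the waveform, i.e. a waveform
    that has been artificially delayed yields a negative lag.  A correctly
    extracted waveform yields zero.  The reported amplitude is the peak of
    the normalised complex correlation (waveform and quadrature jointly).
    """
    if speech.rate != fwave.rate:
        raise ValueError("speech and waveform must share a sampling rate")
    n = min(len(speech), len(fwave))
    x = speech.samples[:n] - speech.samples[:n].mean()
    w = fwave.samples[:n] - fwave.samples[:n].mean()
    q = fwave.quadrature[:n] - fwave.quadrature[:n].mean()
    nx, nw = np.linalg.norm(x), np.linalg.norm(w)
    if nx == 0 or nw == 0:
        raise ValueError("zero-variance input: correlation undefined")
    lag_max = int(round(max_lag_ms / 1000.0 * fwave.rate))
    c_w = signal.correlate(x, w, mode="full", method="fft")
    c_q = signal.correlate(x, q, mode="full", method="fft")
    centre = n - 1
    window = slice(centre - lag_max, centre + lag_max + 1)
    lags = np.arange(-lag_max, lag_max + 1)
    i = int(np.argmax(c_w[window]))
    z = c_w[window] - 1j * c_q[window]
    amplitude = float(np.max(np.abs(z)) / (nx * nw))
    return AlignmentResult(
        lag_ms=float(lags[i] / fwave.rate * 1000.0),
        lag_samples=int(lags[i]),
        amplitude=amplitude,
    )


def instantaneous_frequency(
    fwave: FundamentalWaveform,
    min_run_s: float = 0.025,
    smooth_s: float = 0.010,
) -> np.ndarray:
    """Per-sample instantaneous frequency of the waveform, NaN when unvoiced.

    Computed per voiced run from the analytic-signal phase derivative,
    median-filtered over ``smooth_s`` — one pitch period by default, which
    suppresses the pitch-rate ripple that any slight harmonic distortion of
    the waveform imprints on the raw phase derivative.  Runs shorter than
    ``min_run_s`` are left NaN (too short for a meaningful analytic phase).
    """
    n = len(fwave)
    out = np.full(n, np.nan)
    v = fwave.voicing_mask.astype(np.int8)
    if n == 0 or not v.any():
        return out
    edges = np.flatnonzero(np.diff(v))
    starts = np.concatenate([[0], edges + 1])
    stops = np.concatenate([edges + 1, [n]])
    min_len = int(round(min_run_s * fwave.rate))
    k = int(round(smooth_s * fwave.rate))
    k += 1 - k % 2
    for a, b in zip(starts, stops):
        if not fwave.voicing_mask[a] or b - a < min_len:
            continue
        seg = fwave.samples[a:b]
        if not np.any(seg):
            continue
        analytic = signal.hilbert(seg, next_fast_len(b - a))[:b - a]
        phase = np.unwrap(np.angle(analytic))
        freq = np.gradient(phase) * fwave.rate / (2.0 * np.pi)
        if k >= 3:
            freq = median_filter(freq, size=k, mode="nearest")
        out[a:b] = freq
    return out
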