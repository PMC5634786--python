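"""Preprocessing of scalp recordings and stimulus-aligned epoching.

The brainstem's frequency-following response lives between 100 and 300 Hz,
far below typical EEG amplifier rates, and is buried under cortical activity,
mains interference and movement artifacts.  The chain implemented here —
channel averaging, sinusoidal-regression line-noise removal, artifact
blanking, a delay-compensated 100-300 Hz linear-phase band-pass, and
epoching — is latency-neutral by construction, which matters because the
response is characterised by a millisecond-scale peak latency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal

from .fwave import TARGET_RATE, filter_zero_phase

_STOP_ATTEN_DB = 80.0


@dataclass
class NeuralRecording:
    """One or more simultaneously sampled voltage channels.

    ``stimulus_offset`` is the time (s) of the first recording sample on the
    stimulus clock; a known constant acoustic delay (e.g. 1 ms of earphone
    tubing) is handled separately at correlation time.
    """

    channels: np.ndarray  # (n_channels, n_samples)
    rate: float
    stimulus_offset: float = 0.0

    def __post_init__(self) -> None:
        self.channels = np.atleast_2d(np.asarray(self.channels, dtype=float))
        if not self.rate > 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.channels.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate


@dataclass
class NeuralEpochSet:
    """Equal-length single-channel epochs aligned to stimulus time."""

    epochs: np.ndarray  # (n_epochs, n_samples)
    rate: float
    epoch_duration: float
    epoch_start_times: np.ndarray  # seconds, stimulus clock

    def __post_init__(self) -> None:
        self.epochs = np.atleast_2d(np.asarray(self.epochs, dtype=float))
        self.epoch_start_times = np.asarray(self.epoch_start_times, dtype=float)

    @property
    def n_epochs(self) -> int:
        return 0 if self.epochs.size == 0 else self.epochs.shape[0]


def average_channels(rec: NeuralRecording) -> NeuralRecording:
    """Samplewise mean across measurement channels."""
    if rec.channels.shape[0] < 1:
        raise ValueError("recording has no channels")
    mean = rec.channels.mean(axis=0, keepdims=True)
    return NeuralRecording(mean, rec.rate, rec.stimulus_offset)


def suppress_line_noise(
    x: np.ndarray,
    rate: float,
    mains_freq: float = 50.0,
    max_harmonic_hz: float = 300.0,
    window_s: float = 4.0,
) -> np.ndarray:
    """Attenuate mains interference by windowed sinusoidal regression.

    In sliding windows (default 4 s, 50% overlap) a sine/cosine pair at the
    mains frequency and each of its harmonics up to ``max_harmonic_hz`` is
    fitted by least squares and subtracted; the cleaned windows are
    recombined with Hann weights (constant-overlap-add).  Unlike a notch
    filter this removes only the locally stationary sinusoidal component and
    does not ring inside the 100-300 Hz response band.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n == 0:
        return x.copy()
    if not mains_freq < rate / 2:
        raise ValueError("mains frequency must be below the Nyquist frequency")
    freqs = np.arange(mains_freq, min(max_harmonic_hz, 0.95 * rate / 2) + 1e-9,
                      mains_freq)
    win = int(round(window_s * rate))
    if win >= n:
        win = n
    step = max(1, win // 2)
    taper = np.hanning(win) if win > 1 else np.ones(1)
    acc = np.zeros(n)
    wacc = np.zeros(n)
    t_all = np.arange(n) / rate
    starts = list(range(0, max(n - win, 0) + 1, step))
    if starts[-1] + win < n:
        starts.append(n - win)
    for s in starts:
        sl = slice(s, s + win)
        t = t_all[sl]
        cols = [np.sin(2 * np.pi * f * t) for f in freqs]
        cols += [np.cos(2 * np.pi * f * t) for f in freqs]
        design = np.column_stack(cols)
        coef, *_ = np.linalg.lstsq(design, x[sl], rcond=None)
        cleaned = x[sl] - design @ coef
        acc[sl] += taper * cleaned
        wacc[sl] += taper
    out = np.where(wacc > 0, acc / np.where(wacc > 0, wacc, 1.0), x)
    return out


def blank_artifacts(
    x: np.ndarray,
    rate: float,
    threshold: float = 20e-3,
    pad_s: float = 0.010,
) -> np.ndarray:
    """Zero episodes whose absolute voltage exceeds ``threshold``.

    Scalp potentials above the threshold (default 20 mV) cannot originate in
    the brainstem and are treated as artifacts.  Each exceedance is extended
    by ``pad_s`` on both sides to remove filter-smeared flanks.  The
    operation is idempotent.
    """
    if not threshold > 0:
        raise ValueError("threshold must be positive")
    x = np.asarray(x, dtype=float)
    bad = np.abs(x) > threshold
    if not bad.any():
        return x.copy()
    pad = int(round(pad_s * rate))
    if pad > 0:
        kernel = np.ones(2 * pad + 1)
        bad = np.convolve(bad.astype(float), kernel, mode="same") > 0
    out = x.copy()
    out[bad] = 0.0
    return out


def design_bandpass(rate: float) -> tuple[np.ndarray, np.ndarray]:
    """High-pass (90-100 Hz transition) and low-pass (300-360 Hz) FIR pair."""
    nyq = rate / 2.0
    n_hp, beta_hp = signal.kaiserord(_STOP_ATTEN_DB, 10.0 / nyq)
    n_hp += 1 - n_hp % 2
    hp = signal.firwin(n_hp, 95.0, window=("kaiser", beta_hp),
                       pass_zero=False, fs=rate)
    n_lp, beta_lp = signal.kaiserord(_STOP_ATTEN_DB, 60.0 / nyq)
    n_lp += 1 - n_lp % 2
    lp = signal.firwin(n_lp, 330.0, window=("kaiser", beta_lp), fs=rate)
    return hp, lp


def bandpass_brainstem(x: np.ndarray, rate: float) -> np.ndarray:
    """Band-pass 100-300 Hz with zero net latency.

    A cascade of two delay-compensated linear-phase FIR filters: a high-pass
    with transition band 90-100 Hz (removing cortical activity, which
    dominates below 100 Hz) and a low-pass with transition band 300-360 Hz,
    both with 80 dB stopband attenuation.
    """
    if rate < 720.0:
        raise ValueError("rate too low for a 100-300 Hz band-pass")
    hp, lp = design_bandpass(rate)
    return filter_zero_phase(filter_zero_phase(np.asarray(x, float), hp), lp)


def make_epochs(
    x: np.ndarray,
    rate: float,
    discard_head: float = 10.0,
    epoch_len: float = 3.0,
    max_epochs: int | None = 40,
    stimulus_offset: float = 0.0,
) -> NeuralEpochSet:
    """Cut a recording into consecutive non-overlapping epochs.

    The first ``discard_head`` seconds are dropped (onset transients), then
    up to ``max_epochs`` epochs of ``epoch_len`` seconds are taken back to
    back; any remainder is discarded.  ``max_epochs=None`` keeps every full
    epoch.
    """
    x = np.asarray(x, dtype=float)
    n_len = int(round(epoch_len * rate))
    head = int(round(discard_head * rate))
    avail = (x.size - head) // n_len if x.size > head else 0
    n_ep = int(avail) if max_epochs is None else min(int(avail), max_epochs)
    if n_ep <= 0:
        warnings.warn("recording too short: no epochs after head discard")
        return NeuralEpochSet(
            np.empty((0, n_len)), rate, epoch_len, np.empty(0)
        )
    body = x[head:head + n_ep * n_len]
    epochs = body.reshape(n_ep, n_len)
    starts = stimulus_offset + discard_head + epoch_len * np.arange(n_ep)
    return NeuralEpochSet(epochs, rate, epoch_len, starts)


def decimate_to(x: np.ndarray, rate: float, target_rate: float = TARGET_RATE) -> np.ndarray:
    """Resample a band-limited signal to the common working rate.

    The preprocessed recording carries no content above 360 Hz, so polyphase
    decimation to 8820 Hz preserves it while matching the waveform's lag
    grid.
    """
    if rate == target_rate:
        return np.asarray(x, dtype=float).copy()
    frac = Fraction(target_rate / rate).limit_denominator(10_000)
    return signal.resample_poly(np.asarray(x, float), frac.numerator, frac.denominator)


def preprocess_recording(
    rec: NeuralRecording,
    mains_freq: float = 50.0,
    artifact_threshold: float = 20e-3,
    target_rate: float = TARGET_RATE,
) -> tuple[np.ndarray, float]:
    """Full chain: average, de-line, blank, band-pass, decimate.

    Returns the preprocessed single-channel signal and its rate (the common
    working rate, so the signal is directly comparable with the fundamental
    waveform's lag grid).
    """
    mono = average_channels(rec).channels[0]
    clean = suppress_line_noise(mono, rec.rate, mains_freq=mains_freq)
    clean = blank_artifacts(clean, rec.rate, threshold=artifact_threshold)
    clean = bandpass_brainstem(clean, rec.rate)
    clean = decimate_to(clean, rec.rate, target_rate)
    return clean, target_rate
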