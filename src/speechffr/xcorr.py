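"""Complex cross-correlation of neural epochs with the fundamental waveform.

Each epoch is Pearson-correlated, lag by lag, with the fundamental waveform
(real part) and with its Hilbert-transform quadrature (imaginary part).
Following the conjugate convention of a complex cross-correlation against
the analytic waveform w + i*H[w], the stored complex value is

    z(lag) = r_waveform(lag) - i * r_quadrature(lag),

so that a response locked to the waveform at phase phi appears with argument
-phi ("inverse phase") while its amplitude |z| is phase-invariant.  Positive
lag means the neural signal (first argument) lags the waveform: a brainstem
response appears at a positive latency of several milliseconds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal

from .fwave import FundamentalWaveform
from .neuro import NeuralEpochSet


@dataclass
class ComplexCorrelation:
    """Per-lag complex correlation values on a uniform lag grid (ms)."""

    lags_ms: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.lags_ms = np.asarray(self.lags_ms, dtype=float)
        self.values = np.asarray(self.values, dtype=complex)
        if self.lags_ms.shape != self.values.shape:
            raise ValueError("lag grid and values must have equal length")

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.values)


@dataclass
class PeakResponse:
    """Latency, amplitude and phase of the response peak."""

    latency_ms: float
    amplitude: float
    phase_rad: float
    flat: bool = False  # amplitude was constant over the search window


def complex_correlate(
    epoch: np.ndarray,
    fwave_slice: np.ndarray,
    quad_slice: np.ndarray,
    rate: float,
    lag_min_ms: float = 0.0,
    lag_max_ms: float = 25.0,
) -> ComplexCorrelation:
    """Normalised complex correlation of one epoch over a window of lags.

    ``fwave_slice`` and ``quad_slice`` must start ``lag_max`` samples before
    the epoch (in stimulus time) and end ``lag_min`` samples before the
    epoch does, i.e. have length ``len(epoch) + lag_max - lag_min`` samples,
    so every lagged window lies inside the slice.  Correlations are
    Pearson coefficients (zero-mean, unit-variance over the epoch), making
    amplitudes comparable across epochs and subjects.
    """
    epoch = np.asarray(epoch, dtype=float)
    lag_min = int(round(lag_min_ms / 1000.0 * rate))
    lag_max = int(round(lag_max_ms / 1000.0 * rate))
    if lag_max < lag_min:
        raise ValueError("empty lag window")
    n = epoch.size
    expected = n + lag_max - lag_min
    lags_ms = np.arange(lag_min, lag_max + 1) / rate * 1000.0

    e = epoch - epoch.mean()
    se = float(np.linalg.norm(e))
    if se == 0.0:
        raise ValueError("zero-variance epoch: correlation undefined")

    parts = []
    for w in (fwave_slice, quad_slice):
        w = np.asarray(w, dtype=float)
        if w.size != expected:
            raise ValueError(
                f"waveform slice must have {expected} samples, got {w.size}"
            )
        cs = np.concatenate([[0.0], np.cumsum(w)])
        cs2 = np.concatenate([[0.0], np.cumsum(w * w)])
        offsets = np.arange(lag_max - lag_min + 1)
        s1 = cs[offsets + n] - cs[offsets]
        s2 = cs2[offsets + n] - cs2[offsets]
        var = s2 - s1 * s1 / n
        var = np.maximum(var, 0.0)
        sw = np.sqrt(var)
        if np.any(sw == 0.0):
            raise ValueError("zero-variance waveform window: correlation undefined")
        num = signal.correlate(w, e, mode="valid", method="fft")
        # offset j corresponds to lag (lag_max - j) samples; flip to ascending
        r = (num / (se * sw))[::-1]
        parts.append(r)
    values = parts[0] - 1j * parts[1]
    return ComplexCorrelation(lags_ms, values)


def correlate_epochs(
    epoch_set: NeuralEpochSet,
    fwave: FundamentalWaveform,
    lag_min_ms: float = 0.0,
    lag_max_ms: float = 25.0,
    earphone_delay_ms: float = 0.0,
) -> list[ComplexCorrelation]:
    """Complex correlation of every epoch against the waveform.

    The waveform slice for each epoch is taken at the epoch's stimulus start
    time, shifted by the earphone's acoustic delay (the sound reaches the
    ear that much later, so latencies are measured from ear arrival).
    Epochs whose waveform window is degenerate (entirely unvoiced, hence
    zero variance) are skipped.
    """
    if epoch_set.rate != fwave.rate:
        raise ValueError(
            "epoching rate differs from the waveform rate; decimate first "
            "(see neuro.decimate_to)"
        )
    rate = fwave.rate
    lag_min = int(round(lag_min_ms / 1000.0 * rate))
    lag_max = int(round(lag_max_ms / 1000.0 * rate))
    n = epoch_set.epochs.shape[1] if epoch_set.n_epochs else 0
    total = len(fwave)
    out: list[ComplexCorrelation] = []
    for epoch, t0 in zip(epoch_set.epochs, epoch_set.epoch_start_times):
        i0 = int(round((t0 - earphone_delay_ms / 1000.0) * rate))
        a = i0 - lag_max
        b = i0 + n - lag_min
        if a < 0 or b > total:
            continue  # waveform does not cover this epoch's lag range
        try:
            out.append(
                complex_correlate(
                    epoch,
                    fwave.samples[a:b],
                    fwave.quadrature[a:b],
                    rate,
                    lag_min_ms=lag_min_ms,
                    lag_max_ms=lag_max_ms,
                )
            )
        except ValueError:
            continue
    return out


def average_correlations(
    correlations: Sequence[ComplexCorrelation],
) -> ComplexCorrelation:
    """Complex mean of correlation functions sharing one lag grid."""
    if len(correlations) == 0:
        raise ValueError("cannot average an empty list of correlations")
    grid = correlations[0].lags_ms
    for c in correlations[1:]:
        if c.lags_ms.shape != grid.shape or not np.allclose(c.lags_ms, grid):
            raise ValueError("correlations must share an identical lag grid")
    values = np.mean([c.values for c in correlations], axis=0)
    return ComplexCorrelation(grid.copy(), values)


def locate_peak(
    corr: ComplexCorrelation,
    search_window_ms: tuple[float, float] = (0.0, 25.0),
) -> PeakResponse:
    """Latency, amplitude and phase of the maximum of ``|values|``.

    Ties (a flat amplitude profile) are broken toward the smallest latency
    and flagged.  The phase is the argument of the complex correlation at
    the peak; with the conjugate convention a burst locked at waveform phase
    phi yields peak phase -phi, so the modelled phase is recovered by
    negation.
    """
    lo, hi = search_window_ms
    mask = (corr.lags_ms >= lo) & (corr.lags_ms <= hi)
    if not mask.any():
        raise ValueError("lag grid does not cover the search window")
    lags = corr.lags_ms[mask]
    vals = corr.values[mask]
    amp = np.abs(vals)
    i = int(np.argmax(amp))  # first maximum = smallest latency on ties
    flat = bool(np.allclose(amp, amp[0]))
    return PeakResponse(
        latency_ms=float(lags[i]),
        amplitude=float(amp[i]),
        phase_rad=float(np.angle(vals[i])),
        flat=flat,
    )


def epoch_values_at(
    latency_ms: float,
    correlations: Sequence[ComplexCorrelation],
) -> np.ndarray:
    """Per-epoch complex values at (the nearest lag to) a given latency."""
    values = []
    for c in correlations:
        i = int(np.argmin(np.abs(c.lags_ms - latency_ms)))
        values.append(c.values[i])
    return np.asarray(values, dtype=complex)
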