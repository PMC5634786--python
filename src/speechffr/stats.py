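"""Statistical assessment of the speech-evoked brainstem response.

Per-subject significance is tested with a one-sample Hotelling's T-squared
test on the (Re, Im) epoch values of the complex correlation at the peak
latency: if no phase-locked response is present, those values are bivariate
normal with zero mean (central limit theorem over the many samples each
correlation averages).  Attention effects are quantified by amplitude ratios
between attended and ignored streams and tested with Student's t-tests;
segment-wise analyses relate response amplitude to the fundamental frequency
(low-pass behaviour) and to latency.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .fwave import FundamentalWaveform, instantaneous_frequency
from .xcorr import complex_correlate, locate_peak


@dataclass
class HotellingResult:
    t2: float
    f_stat: float
    df: tuple[int, int]
    p: float
    n: int


@dataclass
class AttentionResult:
    """Attended vs ignored response amplitudes for one subject and speaker."""

    amp_attended: float
    amp_ignored: float
    ratio: float
    two_sample_t: float
    two_sample_p: float


@dataclass
class SegmentCorrelationResult:
    """Pearson correlation across short-segment response measures."""

    r: float
    p: float
    n_segments: int
    n_excluded: int


def hotelling_one_sample(values: Sequence[complex]) -> HotellingResult:
    """One-sample Hotelling's T-squared test of complex values against zero.

    T2 = n * mean' S^-1 mean with the sample covariance S of (Re, Im);
    under the null, T2 * (n-2) / (2(n-1)) follows F(2, n-2).
    """
    z = np.asarray(values, dtype=complex)
    n = z.size
    if n < 3:
        raise ValueError("Hotelling test needs at least 3 values")
    x = np.column_stack([z.real, z.imag])
    m = x.mean(axis=0)
    s = np.cov(x.T, ddof=1)
    det = np.linalg.det(s)
    if not np.isfinite(det) or det <= 0:
        raise np.linalg.LinAlgError(
            "sample covariance of (Re, Im) is singular; the epoch values are "
            "degenerate (collinear or constant)"
        )
    t2 = float(n * m @ np.linalg.solve(s, m))
    f_stat = t2 * (n - 2) / (2.0 * (n - 1))
    p = float(sps.f.sf(f_stat, 2, n - 2))
    return HotellingResult(t2=t2, f_stat=f_stat, df=(2, n - 2), p=p, n=n)


def attention_compare(
    attended_epoch_values: Sequence[complex],
    ignored_epoch_values: Sequence[complex],
) -> AttentionResult:
    """Compare response amplitudes between attended and ignored speech.

    The per-condition amplitude is the magnitude of the epoch-averaged
    complex correlation (phase-coherent averaging suppresses the noise
    floor); the two-sample Student's t-test is run on the per-epoch
    amplitudes ``|z_e|``.  Real-valued inputs are interpreted directly as
    per-epoch amplitudes.
    """
    a = np.asarray(attended_epoch_values)
    b = np.asarray(ignored_epoch_values)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 epochs per condition")
    amp_a = float(np.abs(np.mean(a)))
    amp_b = float(np.abs(np.mean(b)))
    if amp_b == 0.0:
        raise ZeroDivisionError("ignored-condition amplitude is zero: infinite ratio")
    t, p = sps.ttest_ind(np.abs(a), np.abs(b), equal_var=True)
    return AttentionResult(
        amp_attended=amp_a,
        amp_ignored=amp_b,
        ratio=amp_a / amp_b,
        two_sample_t=float(t),
        two_sample_p=float(p),
    )


def ratio_population_test(ratios: Sequence[float]) -> float:
    """One-tailed p for the population mean ratio exceeding unity."""
    r = np.asarray(ratios, dtype=float)
    if r.size < 2:
        raise ValueError("need at least 2 subjects")
    if np.ptp(r) == 0.0 and r[0] == 1.0:
        return 0.5  # t = 0/0 -> no evidence either way
    _, p = sps.ttest_1samp(r, 1.0, alternative="greater")
    return float(p)


def ratio_difference_test(
    male_ratios: Sequence[float], female_ratios: Sequence[float]
) -> float:
    """Two-tailed two-sample p for a speaker difference in attention ratios."""
    a = np.asarray(male_ratios, dtype=float)
    b = np.asarray(female_ratios, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 subjects per group")
    _, p = sps.ttest_ind(a, b, equal_var=True)
    return float(p)


def latency_difference_test(latency_diffs: Sequence[float]) -> float:
    """Two-tailed p for the mean attended-ignored latency difference vs zero."""
    d = np.asarray(latency_diffs, dtype=float)
    if d.size < 2:
        raise ValueError("need at least 2 subjects")
    if np.ptp(d) == 0.0 and d[0] == 0.0:
        return 1.0  # exactly null data: no evidence of a difference
    _, p = sps.ttest_1samp(d, 0.0)
    return float(p)


def _segment_measures(
    fwave: FundamentalWaveform,
    neural: np.ndarray,
    rate: float,
    n_segments: int,
    lag_window_ms: tuple[float, float],
    earphone_delay_ms: float,
    start_offset_s: float,
):
    """Peak amplitude, latency and mean f0 for consecutive equal segments."""
    if rate != fwave.rate:
        raise ValueError("neural signal must be at the waveform rate")
    neural = np.asarray(neural, dtype=float)
    start = int(round(start_offset_s * rate))
    usable = min(neural.size, len(fwave)) - start
    seg_len = usable // n_segments
    if seg_len < 2:
        raise ValueError("not enough data for the requested number of segments")
    lag_min = int(round(lag_window_ms[0] / 1000.0 * rate))
    lag_max = int(round(lag_window_ms[1] / 1000.0 * rate))
    delay = int(round(earphone_delay_ms / 1000.0 * rate))
    f_inst = instantaneous_frequency(fwave)
    amps, lats, freqs = [], [], []
    n_excluded = 0
    # zero-pad the waveform so early segments can look back over the full
    # lag range even near the start of the recording
    pad = lag_max + max(delay, 0)
    w = np.concatenate([np.zeros(pad), fwave.samples])
    q = np.concatenate([np.zeros(pad), fwave.quadrature])
    slice_len = seg_len + lag_max - lag_min
    for k in range(n_segments):
        i0 = start + k * seg_len
        epoch = neural[i0:i0 + seg_len]
        j0 = i0 - delay + pad - lag_max  # padded index of (i0 - delay - lag_max)
        fseg = f_inst[i0:i0 + seg_len]
        voiced = np.isfinite(fseg)
        if not voiced.any():
            n_excluded += 1
            continue
        try:
            corr = complex_correlate(
                epoch,
                w[j0:j0 + slice_len],
                q[j0:j0 + slice_len],
                rate,
                lag_min_ms=lag_window_ms[0],
                lag_max_ms=lag_window_ms[1],
            )
        except ValueError:
            n_excluded += 1
            continue
        peak = locate_peak(corr, search_window_ms=lag_window_ms)
        amps.append(peak.amplitude)
        lats.append(peak.latency_ms)
        freqs.append(float(np.mean(fseg[voiced])))
    return np.array(amps), np.array(lats), np.array(freqs), n_excluded


def amplitude_frequency_analysis(
    fwave: FundamentalWaveform,
    neural: np.ndarray,
    rate: float,
    n_segments: int = 160,
    lag_window_ms: tuple[float, float] = (0.0, 25.0),
    earphone_delay_ms: float = 0.0,
    start_offset_s: float = 0.0,
) -> SegmentCorrelationResult:
    """Correlation of per-segment response amplitude with mean f0.

    The recording is split into ``n_segments`` equal consecutive segments;
    each yields the peak amplitude of its complex correlation and the mean
    fundamental frequency over its voiced samples.  The Pearson correlation
    across segments is tested one-tailed for a NEGATIVE relation (the
    brainstem response has a low-pass character).  Segments without voiced
    content are excluded and counted.
    """
    amps, _, freqs, n_excl = _segment_measures(
        fwave, neural, rate, n_segments, lag_window_ms, earphone_delay_ms,
        start_offset_s,
    )
    if amps.size < 3:
        raise ValueError("fewer than 3 usable segments")
    if np.ptp(freqs) < 1e-3 * max(np.mean(freqs), 1.0):
        raise ValueError("constant fundamental frequency across segments: "
                         "correlation undefined")
    r, p = sps.pearsonr(freqs, amps, alternative="less")
    return SegmentCorrelationResult(float(r), float(p), int(amps.size), n_excl)


def amplitude_latency_analysis(
    fwave: FundamentalWaveform,
    neural: np.ndarray,
    rate: float,
    segment_len_s: float = 120.0,
    lag_window_ms: tuple[float, float] = (0.0, 25.0),
    earphone_delay_ms: float = 0.0,
    start_offset_s: float = 0.0,
) -> SegmentCorrelationResult:
    """Two-tailed correlation of per-segment amplitude with peak latency.

    Long segments (default 120 s) are needed for a reliable latency; fewer
    than three segments is an error.
    """
    usable_s = (min(np.asarray(neural).size, len(fwave)) / rate) - start_offset_s
    n_segments = int(usable_s // segment_len_s)
    if n_segments < 3:
        raise ValueError("need at least 3 segments for a correlation")
    amps, lats, _, n_excl = _segment_measures(
        fwave, neural, rate, n_segments, lag_window_ms, earphone_delay_ms,
        start_offset_s,
    )
    if amps.size < 3:
        raise ValueError("fewer than 3 usable segments")
    r, p = sps.pearsonr(lats, amps)
    return SegmentCorrelationResult(float(r), float(p), int(amps.size), n_excl)
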