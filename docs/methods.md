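# Methods

`speechffr` measures the auditory brainstem's frequency-following response
to running, non-repetitive speech.  The central obstacle is that the
fundamental frequency (f0) of natural speech wanders continuously between
roughly 100 and 300 Hz, so the phase-locked brainstem response cannot be
read out by averaging over repeated presentations or by correlating against
a fixed-frequency reference.  The method instead extracts a *fundamental
waveform* — a nonstationary oscillation that follows the speech f0 in both
instantaneous frequency and amplitude — and uses it, together with its
Hilbert transform, as a complex-valued regressor for the scalp recording.

## Fundamental-waveform extraction

1. **Resampling and low-pass filtering.**  Speech is brought to a common
   working rate of 8820 Hz (44100/5) and low-pass filtered with a
   linear-phase FIR filter (transition band 1500–1650 Hz, stopband −80 dB,
   passband ripple well under 1 dB, Kaiser design, ~295 taps).  The filter's
   group delay is compensated exactly, so this stage is latency-free.

2. **Silence gating.**  The envelope is the magnitude of the analytic
   signal smoothed by a 10 ms moving average.  Samples where it falls below
   10% of its maximum are zeroed.  The estimator is parameter-light and the
   10% threshold is configurable.

3. **f0 tracking.**  Autocorrelation in 50 ms rectangular windows with a
   1 ms hop.  The search covers a band slightly wider than the admissible
   60–400 Hz so that a dominant periodicity just outside the range is
   detected and the window flagged voiceless, rather than being snapped to
   the band edge.  The biased (rectangular-window) autocorrelation estimate
   is used for peak *selection* because its lag taper favours the
   one-period peak over its multiples; for the sub-sample parabolic
   interpolation the deterministic `(1 − k/win)` taper is divided out
   locally, which removes a bias of up to ~1 Hz at typical f0.  Windows are
   voiceless when silent, when the normalised peak is below 0.25 (an
   indistinct periodicity, typical of gating boundaries), when f0 leaves
   60–400 Hz, or when the estimate jumps by more than 10 Hz between
   successive windows.  The jump rule compares raw successive estimates and
   marks the later window, without cascading.

4. **Segmentation and interpolation.**  Each maximal voiced run becomes a
   segment; its windowed f0 estimates are interpolated by a natural cubic
   spline (degree reduced for runs of two or three windows).  Runs of a
   single window are dropped — they carry no interpolable span.

5. **Empirical mode decomposition.**  Sifting with cubic-spline envelopes
   through mirror-extended extrema (two extrema reflected about each end).
   A mode is accepted when the SD criterion Σm²/Σh² falls below 0.2 *and*
   its extrema and zero-crossing counts differ by at most one, with a
   generous cap of 200 sifting iterations (stubborn low-amplitude riding
   waves occasionally need more than the customary few dozen sifts); at
   most 12 modes.  Decomposition stops early once
   the residual's extrema density implies oscillations below 50 Hz:
   such modes lie below the admissible f0 range and can never be selected,
   so they are left inside the residual.  The residual is defined by
   subtraction, making the reconstruction exact to machine precision.

6. **Mode selection.**  Per mode, the instantaneous frequency is the
   central-difference derivative of the analytic-signal phase and the
   instantaneous amplitude is the analytic-signal magnitude.  The frequency
   is median-filtered over 5 ms to suppress derivative spikes; the filter
   runs on a 5× decimated grid (spikes remain isolated outliers there, and
   the selection rule needs the frequency only to a few percent).  At each
   sample, modes whose instantaneous frequency lies within 20% of the
   spline-interpolated f0 are candidates and the one with the largest
   instantaneous amplitude is selected; samples without candidates get
   zero.  Selection may switch modes within a segment.

7. **Crossfaded assembly.**  Selected pieces are joined with 10 ms cosine
   crossfades, implemented by smoothing each piece's span indicator with a
   normalised Hann kernel.  Because the smoothing is linear, the weights of
   abutting pieces form a partition of unity — two abutting constant pieces
   blend to the constant, with no dip or doubling — and isolated pieces
   ramp to zero over half a window.  The quadrature is the Hilbert
   transform of the assembled waveform.

The whole chain is latency-neutral: the cross-correlation between the
preprocessed speech and the extracted waveform peaks at lag 0 ± 1 sample.

## Neural preprocessing

Channels are averaged; mains interference is removed by least-squares
regression of sine/cosine pairs at the mains frequency (default 50 Hz) and
its harmonics up to 300 Hz in 4 s windows with 50% overlap, recombined with
Hann weights.  Unlike a notch filter this removes only the locally
stationary sinusoid and cannot ring inside the response band.  Episodes
exceeding 20 mV in magnitude (configurable — the value is far above any
brainstem potential and flags amplifier/muscle artifacts) are zeroed with
10 ms of padding on each side.  The recording is then band-passed to
100–300 Hz by a cascade of two delay-compensated linear-phase FIR filters
(high-pass transition 90–100 Hz, which also removes the cortical response
concentrated below 100 Hz; low-pass transition 300–360 Hz; both −80 dB
stopband) and decimated to 8820 Hz.  The first 10 s are discarded and the
remainder cut into 3 s epochs (40 by default, matching a two-minute
recording; uncapped for long simulations).

## Complex correlation and the response peak

Each epoch is Pearson-correlated, lag by lag over 0–25 ms, with the
fundamental waveform (real part) and with its quadrature (imaginary part).
Following the conjugate convention of a cross-correlation against the
analytic waveform, the stored value is `z = r_w − i·r_q`, so a response
locked at waveform phase φ appears with argument −φ and the imposed phase
is recovered by negation.  Positive lag means the neural signal lags the
waveform; a 1 ms earphone tube delay can be subtracted so latencies are
measured from ear arrival.  The per-lag Pearson normalisation makes
amplitudes comparable across epochs and subjects; the absolute amplitude
scale of published human data depends on an unstated normalisation, so only
relative quantities (ratios, latencies, phases) are treated as
recoverable.  Epoch correlations are averaged as complex numbers and the
response is characterised by the latency, amplitude and phase of the
amplitude peak; exact ties break toward the smallest latency and are
flagged.

A caveat established during validation: the amplitude profile of the
complex correlation is broad (a lifetime of a few milliseconds, set by the
spread of fundamental frequencies in the stimulus), so under heavy noise
the argmax latency wobbles by a few tenths of a millisecond while the
phase-versus-lag curve barely moves.  The simulation's phase-recovery error
is therefore evaluated at the modelled delay, where the reading is
well-conditioned; the peak's own phase is still reported, as it is the
quantity available for real recordings.

## Statistics

Per-subject significance uses a one-sample Hotelling T² test on the
(Re, Im) epoch values at the peak latency: T² = n·m̄ᵀS⁻¹m̄ with sample
covariance S, and T²(n−2)/(2(n−1)) ~ F(2, n−2) under the bivariate normal
null implied by the central limit theorem.  Attention effects are
summarised per subject and speaker by the ratio of attended to ignored
amplitudes — the amplitudes of the epoch-averaged (phase-coherent) complex
correlations, which suppress the incoherent noise floor that would bias a
mean of per-epoch magnitudes — with a classic two-sample Student t-test
(equal variances assumed) on the per-epoch magnitudes.  Population tests
are one-tailed one-sample t vs 1 for ratios, two-tailed two-sample t for
speaker differences, and two-tailed one-sample t vs 0 for latency
differences.  The amplitude–frequency analysis splits the recording into
160 equal segments, computes each segment's peak correlation amplitude and
mean f0 over voiced samples, and tests the Pearson correlation one-tailed
for a negative (low-pass) relation; the amplitude–latency analysis uses
120 s segments (the minimum for a reliable latency) and a two-tailed test.
Segments without voiced content are excluded and counted.

## Generative model

The synthetic-speech generator emulates voiced speech: harmonics (8 by
default, base amplitudes 1/h) of the integrated phase of a smoothly
wandering f0 contour, each harmonic modulated by an independent slow random
envelope (±40%), interrupted by pauses (voiced stretches of ~1.5 s
alternating with pauses sized to a 20% pause fraction, joined by 20 ms
cosine ramps).  The default contour wanders within 120–250 Hz; the
two-speaker scenario uses 105–135 Hz ("male") and 185–245 Hz ("female") so
the two pitch tracks stay spectrally separate, as typical speaking ranges
do.  What it does *not* emulate: formant structure, fricatives and other
unvoiced speech sounds, amplitude dynamics of natural prosody, or
microvariation (jitter/shimmer) of real glottal cycles.  Passing tests
therefore demonstrate the correctness of the signal-processing chain on
harmonically clean voiced material, not tracking performance on
conversational audio.

The response model triggers one Gaussian burst (width = 1 ms standard
deviation; a FWHM interpretation is available) per fundamental cycle at
each upward crossing of the waveform's instantaneous phase through φ,
shifts all bursts by τ, scales the clean train to 1 µV RMS, and adds
seeded Gaussian noise with a 1/f power spectrum (flat below 1 Hz,
band-limited to the recording band) at an exact signal-to-noise ratio,
computed over voiced spans.  The 1/f spectrum is a synthetic stand-in for a
silent-trial scalp recording; real electrode noise in the 100–300 Hz band
can be appreciably smaller relative to its broadband power, so a given
broadband SNR is, if anything, a harsher condition here than with real
noise.  In the two-speaker scenario each gain condition is simulated as two
presentations (attend-male, attend-female) sharing the same burst trains,
so the attended/ignored amplitude ratio of a speaker across presentations
estimates the imposed gain directly.

## Problem sizes and numerical choices

Validation simulations use 10 min of speech for delay/phase recovery and
the 160-segment analysis, and two presentations of ~16 min (320 epochs
each) for the attention scenario, as in the validation design the package
follows; shorter versions of the same checks appear in the unit tests.
The lag grid spacing is 1/8820 s ≈ 0.113 ms.  All FIR filters use odd-length
Kaiser designs with exact integer group-delay compensation.  Degenerate
inputs (all-zero audio, zero-variance epochs, entirely unvoiced waveform
windows, singular covariance) raise explicit errors or are skipped and
counted, as documented per function.  Random draws all flow from explicit
seeds; identical configuration and seeds give byte-identical outputs.

## Known limitations

- The waveform extraction assumes a single speaker per audio stream;
  two-speaker mixtures are handled by extracting each speaker's waveform
  from its own clean recording.
- EMD mode mixing can leave brief gaps (no candidate mode within 20% of
  f0) inside voiced segments; these samples are zero by construction.
- The absolute correlation amplitude depends on the chosen normalisation
  and on the noise spectrum, and is not comparable across noise models.
- The f0 tracker is tuned for the 60–400 Hz speech range and is not a
  general-purpose pitch tracker.
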