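# speechffr

Measuring the human auditory brainstem's response to running,
non-repetitive speech from scalp (EEG) recordings.

The brainstem phase-locks to the periodicity of voiced speech — the
frequency-following response at the fundamental frequency f0 — but natural
speech has an f0 that wanders continuously between roughly 100 and 300 Hz,
so the classic approach of averaging thousands of repetitions of the same
short stimulus does not apply.  `speechffr` implements a regression-style
alternative for researchers in auditory neuroscience:

1. **Fundamental waveform.**  From the speech audio, empirical mode
   decomposition (EMD) extracts a nonstationary oscillation `w(t)` that
   follows the speech f0 in instantaneous frequency and amplitude.  Voiced
   stretches are found by autocorrelation-based f0 tracking (50 ms windows,
   1 ms hop, 60–400 Hz, voiceless when f0 jumps by more than 10 Hz between
   windows); per segment, the intrinsic mode function within 20% of the
   interpolated f0 with the largest instantaneous amplitude is selected and
   pieces are joined by 10 ms cosine crossfades.

2. **Complex correlation.**  The preprocessed recording `x(t)` (averaged
   channels, mains-regression cleaning, artifact blanking, 100–300 Hz
   linear-phase band-pass, 3 s epochs) is correlated at lags ℓ ∈ [0, 25] ms
   with the waveform and its Hilbert transform ŵ:

       z(ℓ) = corr(x, w_ℓ) − i · corr(x, ŵ_ℓ),

   the complex cross-correlation against the analytic waveform.  Averaged
   over epochs, |z| peaks at the response latency (≈ 9 ms in humans,
   placing the source in the brainstem), and arg z at the peak gives the
   response phase (negated, by the conjugate convention).

3. **Statistics.**  Per-subject significance by one-sample Hotelling T² on
   the (Re, Im) epoch values at the peak; attentional modulation by
   attended/ignored amplitude ratios and Student t-tests; segment-wise
   amplitude–frequency (low-pass behaviour) and amplitude–latency
   correlations.

Because no public recordings accompany the method, the package ships a
generative model for end-to-end validation: synthetic voiced speech
(harmonics of a wandering f0 with pauses), a burst-train brainstem response
(one Gaussian burst of 1 ms width per fundamental cycle at phase φ,
delayed by τ), and seeded 1/f noise at a prescribed SNR.  Processing this
simulated recording through the full pipeline recovers τ as the peak
latency and φ as the negated correlation phase.

## Worked example

Simulate two minutes of speech-like audio, build the burst-train response
with φ = π/4 and τ = 8 ms, add 1/f noise at −20 dB SNR, and analyse it:

```sh
$ speechffr simulate --duration 120 --seed 7 --out demo
recovered latency 8.28 ms (error +0.277 ms), -phase 0.416 rad (error -0.102 rad)
```

`demo_recovery.json` then contains

```json
{
  "amplitude": 0.09784149663797295,
  "hotelling_p": 1.0433046504560102e-18,
  "latency_error_ms": 0.2766439909297045,
  "latency_ms": 8.276643990929704,
  "n_epochs": 36,
  "phase_error_rad": -0.10236700575697544,
  "phase_rad": -0.41564609300964145
}
```

Reading: from 36 three-second epochs at −20 dB SNR the amplitude of the
averaged complex correlation peaks at 8.28 ms — the imposed 8 ms delay
recovered to within a third of a millisecond — with a normalised amplitude
of 0.098, overwhelmingly significant under Hotelling's T²
(p ≈ 10⁻¹⁸).  The phase error compares the negated correlation phase at
the modelled delay with the imposed φ = π/4; it is within ~0.1 rad.
`demo_correlation.txt` holds the full complex correlation (lag, real,
imaginary) for plotting.

The same stages are available for real data: `extract-fwave` (WAV in,
waveform/quadrature/voicing out), `preprocess-neuro`, `correlate`,
`hotelling`, `attention-stats`, and the end-to-end `run-single` /
`run-two` commands; every run writes a provenance record with the
configuration and seeds.  All functionality is equally usable as a library
(`import speechffr`).

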