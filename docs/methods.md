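# Methods

## The alternating-polarity PSTH family

Spike trains collected to the two polarities of a stimulus are binned
into half-open bins `[kΔ, (k+1)Δ)` (0-based from stimulus onset) to give
the positive- and negative-polarity PSTHs `p(t)` and `n(t)`. The
canonical unit is count-per-bin; the rate view divides by
`n_reps × bin_width` and is derived on demand, never stored. A duration
that is not an exact multiple of the bin width is an error rather than a
silent truncation, so spike-count conservation (`Σ p =` number of
positive-polarity spikes) holds exactly.

From the pair, the package derives

| signal | definition | interpretation |
|---|---|---|
| `s(t)` | `(p+n)/2` | polarity-tolerant envelope (ENV) |
| `d(t)` | `(p−n)/2` | polarity-sensitive fine structure (TFS) |
| `a(t)` | `d + jH{d}` | analytic signal |
| `e(t)` | `|a|/√2` | Hilbert envelope |
| `ϕ(t)` | `√2·rms(d)·cos∠a` | constant-envelope Hilbert phase |

The √2 factors make `e` and `ϕ` power-matched to `d`:
`cos∠a` is a constant-rms (≈ 1/√2) signal, so scaling by `√2·rms(d)`
gives `rms(ϕ) = rms(d)`, and the exact reconstruction
`d = e·ϕ/rms(d)` holds elementwise. Both identities are exact on
narrowband signals sampled over whole numbers of cycles and hold to
≈ 1e−9 on the band-limited PSTHs used here; broadband signals with
appreciable edge energy degrade them gracefully. The Hilbert transform
is computed over the full record in the frequency domain (no
segmentation); envelope/phase values within roughly `3/bandwidth` of the
record edges should be treated as guard samples.

Before Hilbert analysis, `d(t)` is band-limited near the fiber's CF
(default: 2nd-order Butterworth band-pass, 200-Hz bandwidth, applied
forward-backward so the pass is zero-phase). This spectral specificity
is what keeps `e(t)` free of rectifier distortion.

Subtracting the polarity pair cancels even-order distortion products:
for a rectified response to a tone at `f`, power at `2f` in `D(f)` sits
tens of dB below its level in `P(f)` (verified ≥ 20 dB on simulated
fibers). Evoked-potential (FFR) waveform pairs go through the identical
functions; the difference FFR is halved by default for consistency with
`d = (p−n)/2`, with `halve=False` available for the plain-subtraction
convention common in the FFR literature.

## Correlograms via PSTHs

The shuffled autocorrelogram (SAC) tallies all ordered between-train
spike-pair intervals; the shuffled cross-correlogram (SCC) tallies pairs
across two sets. Binning a pair at the *bin-index difference*
`floor(t_b/Δ) − floor(t_a/Δ)` makes the tally factorize exactly through
the count PSTH:

    SAC(X) = R(PSTH_X) − Σᵢ R(x̄ᵢ),     SCC(X,Y) = R_xy(PSTH_X, PSTH_Y)

with `R` the raw auto/cross-correlation. `sac_fast`/`scc_fast` implement
the right-hand sides (FFT correlation, rounded back to integers);
`sac_tally`/`scc_tally` implement the left-hand sides and serve as
oracles — the two agree bitwise. Instrumented counters expose the cost:
for `M` trains of `n` spikes the tally performs `M(M−1)n²` comparisons
(24.5 × 10⁶ for 50 × 100) versus `Mn` binning increments (5 000) for the
PSTH route.

Rate normalization follows the Louage convention: SAC counts are divided
by `M(M−1)·r²·Δ·D` (mean rate `r`, duration `D`), SCC counts by
`L·M·r_X·r_Y·Δ·D`, putting chance coincidence at 1. The finite-duration
triangle `1 − |τ|/D` is subtracted where a chance level of 0 is wanted.
Then

    sumcor = (mean same-polarity SAC + cross-polarity SCC) / 2
    difcor =  mean same-polarity SAC − cross-polarity SCC

isolate ENV and TFS coincidence structure. The difcor is proportional to
the autocorrelation of `d(t)` up to the within-train pairs that shuffling
excludes; the agreement is asymptotic in the train count (Pearson
r > 0.999 at 100 repetitions per polarity, ≈ 0.997 at 50). The sumcor
peak height is reported raw (broadband maximum) or *adjusted* — spectral
content outside the modulation-related bands zeroed by a brick-wall DFT
mask — because the raw peak conflates modulation coding with rectifier
distortion and stochasticity noise, particularly at low CF.

Vector strength is also available two ways: directly
(`|Σ exp(−j2πf tₖ)|/N`) and as the per-spike synchronized rate
`VS(f) = |D(f)|/N` from the plain-sum DFT magnitude of the count-unit
difference PSTH. With the halved difference convention used here the
compound-PSTH scale is restored by a factor 2 (`halved=True`), at which
the curve agrees with direct vector strength computed on pooled,
polarity-flipped spikes to within binning error (< 2 % at 0.1-ms bins).

## Spectra

`dft_spectrum` returns one-sided plain-sum DFT magnitude (the convention
the VS relation needs) or Parseval-consistent power (`Σ bins = Σ x²`).
`multitaper_psd` computes DPSS eigenspectra (`scipy.signal.windows.dpss`)
combined with Thomson adaptive weights; defaults NW = 3, K = 2. Because a
PSTH is a plain signal, both even and odd tapers are usable, whereas a
correlogram — an even sequence — admits only even tapers; this is the
source of the up-to-2× variance advantage of PSTH spectra over
correlogram spectra at matched resolution. The like-for-like K = 1 vs
K = 2 comparison on white noise shows the ceiling (ratio ≤ ~2.5 with
sampling slack); the end-to-end difcor-DFT vs multitaper-d(t)
fractional-power comparison typically exceeds it because the difcor
estimator also differs in grid and compensation.

Band metrics use bin-center inclusion over half-open `[lo, hi)` bands:
modulation-band power (10-Hz bands at Fm, 2Fm, 3Fm), rectifier-distortion
power (10-Hz bands at `2Fc` and `2Fc ± Fm`), fractional power
(band / total; the DC bin is excluded from the denominator by default
because the mean rate of a count PSTH would dominate it — set
`exclude_dc=False` for the literal full-range denominator), and
carrier-to-sideband power ratios at the exact `Fc` and `Fc ± Fm` bins.

## Modulation filterbank

Rectified PSTHs can be projected into the modulation domain through
octave-wide Butterworth band-passes (edges `Fm/√2 … Fm·√2`) at 2, 4, 8,
16, 32, 64, 128 Hz, run forward-backward. "Fourth-order" counts the two
passes by default (2nd-order sections squared in magnitude);
`order_counts_passes=False` makes each pass full order instead. The
outputs are the "internal representations" that envelope-based speech
intelligibility models consume; scoring back-ends are out of scope.

## Trajectory demodulation and the harmonicgram

Power along a known frequency trajectory `f(t)` is estimated by
integrating the trajectory into phase (`Φ[n] = Σ f[m]/fs`, in cycles),
heterodyning `x·exp(−j2πΦ)`, and keeping `|f| ≤ W/2` with a zero-phase
FFT brick-wall low-pass. Demodulation is pointwise unitary, and the
power estimate is doubled because only the positive-frequency image of
the real signal lands near DC. The spectral resolution is `1/duration`
regardless of nonstationarity — for the 2-s, 400→800-Hz chirp test
signal, 0.5 Hz versus the 30 Hz of a 50-ms spectrogram window
(20 Hz window-inverse + 10 Hz within-window sweep): a 60-fold gain.
`W` must be at least `1/duration`; demodulating by the *instantaneous*
frequency instead of its integral would be dimensionally wrong and is
not offered.

The harmonicgram applies this along `k·F0(t)` for every harmonic `k`,
using the integrated phase `k·Φ(t)`. Rows whose trajectory crosses
Nyquist are flagged invalid rather than silently zeroed. Formant-band
power sums the `n` rows closest to the F0-normalized formant contour
`F(t)/F0(t)` at each sample, with exact half-integer ties broken toward
the even harmonic (round-half-to-even); a noise floor is available from
harmonics far above the response band (e.g. k = 29–31). Stimulus-to-
response latency, when it matters, is estimated by peak normalized
cross-correlation over `[0, max_lag]` and applied as a trajectory shift.

## The synthetic-data generator

The spike simulator is a deliberately minimal phenomenological chain —
not a biophysical cochlea:

1. polarity flip of the stimulus;
2. cochlear band-pass: zero-phase Butterworth at CF. Default bandwidth
   is ERB-like (`0.108·CF + 24.7` Hz) floored at 150 Hz; the floor
   reflects the broadened effective tuning at the moderate (≈ 65 dB SPL)
   levels these analyses emulate and keeps ±20-Hz modulation sidebands
   inside the filter at low CF.
3. saturating transduction: `max_rate·(σ(sat_slope·v) − ½)` floored at
   0 (defaults `max_rate` 1000 spikes/s, `sat_slope` 8) — the source of
   realistic rectifier distortion;
4. phase-locking roll-off: zero-phase low-pass with corner 3 kHz and a
   *shallow* effective-2nd-order magnitude slope, so carrier locking
   declines gradually (VS ≈ 0.55 at 500 Hz, ≈ 0.05 at 8 kHz) rather
   than vanishing abruptly — with a steeper roll-off the highest-CF
   fibers carry no carrier information above the Poisson noise floor
   and TFS metrics there would measure nothing but sampling noise;
5. spontaneous offset (default 50 spikes/s) and Bernoulli sampling of
   the inhomogeneous Poisson intensity with an absolute refractory
   period (0.75 ms), fully seeded.

Because every filter is zero-phase, simulated responses carry no
latency; `estimate_latency` exists for externally recorded data.

What the generator emulates: phase locking with roll-off, envelope
following, rectifier distortion, polarity symmetry, Poisson-like
stochasticity. What it does not: two-tone suppression, compressive gain,
adaptation, efferent feedback, long-range rate correlations
(fractional-Gaussian-noise spiking), middle-ear filtering. Passing tests
therefore certify the *analyses* under realistic first-order spike
statistics, not the biology of the periphery.

Stimuli: SAM tones `(1 + depth·cos2πFm t)·cos2πFc t` (peak-normalized);
the chirp-plus-tones signal (1.4 and 2 kHz tones plus a 400→800 Hz
linear chirp over 2 s); and a dynamic vowel — a harmonic complex whose
fundamental rises linearly 100→120 Hz over 188 ms with formant contours
F1 630→570 Hz, F2 1200→1500 Hz, F3 2500 Hz, realized by evaluating
second-order resonance envelopes (bandwidths 90/110/170 Hz) at each
harmonic's instantaneous frequency. Its F1/F0 contour runs 6.3 → 4.75,
crossing 5.5 at 88.5 ms, and F2/F0 reaches 12.5, which is what the
harmonicgram of a simulated low-CF pool tracks (dominant row switching
from harmonic 6 to 5 near 90 ms).

## Study-condition experiment sizes

The canned experiments (`appsth.experiments`) use these problem sizes,
chosen as realistic desk-scale analogues of single-laboratory datasets:

- complexity counts: 50 repetitions × 100 spikes (uniform spike times).
- SAM grid: 24 log-spaced CFs 250 Hz–8 kHz, SAM at CF (Fm 20 Hz, 100 %
  depth), 1-s stimulus, 75 repetitions per polarity (the inclusion
  threshold typical of per-unit spectral analyses), fs 40 kHz, PSTH bin
  25 µs. The rep count keeps deterministic sidebands above the
  single-bin sampling-noise floor at the highest CFs.
- variance-ratio experiment: CF 900 Hz fiber, stationary 98-Hz harmonic
  complex with vowel-like formants, 100-ms window, 12 independent draws
  of 25 repetitions per polarity, 0.1-ms bins; fractional power at the
  single bin nearest the 6th harmonic (588 Hz). The difcor uses no
  taper; `d(t)` uses NW = 3, K = 2 adaptive multitaper.
- dynamic-vowel harmonicgram: fibers with CF < 1 kHz from the standard
  grid, 25 repetitions per polarity, 50-µs bins, W = 20 Hz.

## Numerical choices and degenerate inputs

- Spikes exactly on a bin edge go to the right-opening bin; a 1e−9-bin
  guard absorbs float jitter in `t/Δ`.
- FFT correlation results are rounded to integers (counts are integers;
  the float error is ≪ 0.5).
- Correlogram lag grids are symmetric (`−L…L` bins); `max_lag` defaults
  to `min(D/2, 25 ms)`, bin width to 50 µs.
- DC-only signals: `analytic` warns (phase undefined); `hilbert_phase`
  of an all-zero signal raises; vector strength of zero spikes raises;
  fractional power of a zero spectrum raises.
- Off-grid frequencies in single-bin metrics fall to the nearest bin
  with a warning.
- Brick-wall band edges are inclusive (`|f| ≤ W/2`); spectral band
  membership is half-open `[lo, hi)` by bin center.

## Known limitations

- The fast-correlogram identity requires the bin-index convention; a
  tally over raw time differences re-binned to the lag grid differs at
  bin boundaries.
- Hilbert envelope/phase near record edges are contaminated within
  ≈ 3/bandwidth of each end.
- The harmonicgram needs the true F0 contour; F0 estimation from audio
  is out of scope, and latency errors between stimulus and response blur
  rows for fast trajectories (mitigate with `estimate_latency` and a
  wider W).
- The simulator's high-CF TFS behaviour is phenomenological; conclusions
  about absolute phase-locking limits should not be drawn from it.
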