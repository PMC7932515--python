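# appsth — alternating-polarity PSTH analysis of auditory temporal coding

`appsth` is a toolkit for quantifying how auditory neurons encode the
temporal structure of complex sounds. It targets a long-standing gap in
auditory neuroscience: single-unit spike trains (point processes) and
evoked far-field potentials such as the frequency-following response
(continuous voltages) are analyzed with different tools, even though they
reflect the same underlying coding. The bridge is the family of
peristimulus time histograms built from responses to the two polarities
of a stimulus — the *alternating-polarity PSTHs*:

- `p(t)`, `n(t)` — PSTHs for the positive- and negative-polarity stimulus;
- `s(t) = (p + n) / 2` — the polarity-tolerant **envelope** (ENV) component;
- `d(t) = (p − n) / 2` — the polarity-sensitive **temporal-fine-structure**
  (TFS) component, in which even-order rectifier distortions cancel;
- `a(t) = d(t) + jH{d(t)}` — the analytic signal of `d` (`H` = Hilbert
  transform);
- `e(t) = |a(t)|/√2` — the Hilbert envelope;
- `ϕ(t) = √2·rms(d)·cos∠a(t)` — the Hilbert phase, a constant-envelope TFS
  signal with `rms(ϕ) = rms(d)` and `d = e·ϕ/rms(d)`.

Because these are ordinary sampled signals, everything built for
continuous data applies directly: multitaper (DPSS) spectra, modulation
filterbanks, and trajectory demodulation. Classic spike-train metrics come
along for free and become fast:

- **Vector strength**: `VS(f) = |D(f)|/N`, the synchronized rate per spike,
  read off the spectrum of the difference PSTH.
- **Shuffled correlograms**: `SAC(X) = R(PSTH_X) − Σᵢ R(x̄ᵢ)` and
  `SCC(X,Y) = R_xy(PSTH_X, PSTH_Y)` — integer-exact identities that replace
  O(N²) interval tallying with O(N) PSTH construction, verified bitwise
  against the brute-force tally.
- **sumcor / difcor**: polarity-tolerant and polarity-sensitive
  correlograms with Louage-style rate normalization.
- **Harmonicgram**: for a sound with time-varying fundamental `F0(t)`,
  demodulating by the integrated phase of `k·F0(t)` and low-pass filtering
  at ±W/2 yields the time-varying power along every harmonic — a
  harmonic-number × time image with `1/duration` spectral resolution,
  far better than any sliding-window spectrogram.

A phenomenological auditory-nerve fiber simulator (band-pass cochlear
filter → saturating rectifier → phase-locking low-pass → inhomogeneous
Poisson spiking with refractoriness) generates realistic test data, so
every analysis is exercised end to end without recorded data.

## Worked example

Simulate a fiber (CF = 1 kHz) responding to a 100 %-depth SAM tone
(Fm = 20 Hz) at both polarities, decompose, and compare envelope/TFS
metrics:

```python
import numpy as np
import appsth as ap

stim = ap.make_sam_tone(fc=1000.0, fm=20.0, depth=1.0, dur=1.0, fs=40000.0)
spikes = ap.simulate_both_polarities(stim, ap.ANFiberParams(cf=1000.0),
                                     n_reps_per_polarity=75, seed=0)
p = ap.build_psth(spikes, polarity=1, bin_width=25e-6)
n = ap.build_psth(spikes, polarity=-1, bin_width=25e-6)
parts = ap.decompose(p, n, band=(900.0, 1100.0))   # 200-Hz band at CF

S = ap.dft_spectrum(parts["s"], "power")
E = ap.dft_spectrum(parts["e"], "power")
bands = [(15, 25), (35, 45), (55, 65)]             # Fm and two harmonics
print("Fm-band power of S(f):", ap.band_power(S, bands))
print("rectifier distortion in S(f):",
      ap.rectifier_distortion_power(S, 1000, 20))
print("rectifier distortion in E(f):",
      ap.rectifier_distortion_power(E, 1000, 20))
```

prints (seed 0):

```
Fm-band power of S(f): 514.75
rectifier distortion in S(f): 116.22
rectifier distortion in E(f): 0.0001
```

Both envelope views carry the 20-Hz modulation (S: 514.8, E: 444.1), but
the sum PSTH also contains strong spurious power near 2 kHz (2×CF) from
synaptic rectification — distortion that is absent from the band-limited
Hilbert envelope. On the TFS side, the carrier-to-lower-sideband power
ratio rises from 11.9 for `d(t)` to 196.0 for `ϕ(t)`: the Hilbert phase
isolates the carrier. The identity check
`sac_fast(...) == sac_tally(...)` on the same spikes is exact while the
tally performs 163,773,442 pair comparisons against 12,884 PSTH
increments. Vector strength at the carrier read from `|D(f)|` is 0.504.

A thin CLI mirrors the library
(`appsth simulate | decompose | correlogram | spectrum | modbank |
harmonicgram`), writing CSV outputs and a manifest per run:

```bash
appsth --seed 7 --outdir out simulate --fc 1000 --cf 1000 --reps 25
appsth --outdir out decompose --spikes out/spikes.csv --bin 0.0001 --bandcenter 1000
```

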