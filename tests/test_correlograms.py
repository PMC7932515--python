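"""SAC/SCC identities, sumcor/difcor, and vector-strength relations."""

import numpy as np
import pytest

import appsth as ap
from appsth.correlograms import (detrend_correlogram, normalize_correlogram,
                                 scc_tally)
from appsth.spectral import correlogram_spectrum


def _random_set(rng, n_trains=10, mean_spikes=50, dur=0.2):
    trains = [np.sort(rng.uniform(0, dur, rng.poisson(mean_spikes)))
              for _ in range(n_trains)]
    return ap.SpikeTrainSet(trains, [1] * n_trains, dur)


class TestSacTally:
    def test_hand_enumeration_two_trains(self):
        sts = ap.SpikeTrainSet([[0.0], [0.001]], [1, 1], 0.01)
        c = ap.sac_tally(sts, 1e-3, 5e-3)
        i_plus = np.argmin(np.abs(c.lags - 1e-3))
        i_minus = np.argmin(np.abs(c.lags + 1e-3))
        assert c.values[i_plus] == 1
        assert c.values[i_minus] == 1
        assert c.values.sum() == 2

    def test_single_train_is_error(self):
        with pytest.raises(ap.ValidationError):
            ap.sac_tally(ap.SpikeTrainSet([[0.001]], [1], 0.01), 1e-3, 5e-3)

    def test_worked_operation_counts(self):
        """50 trains x 100 spikes: 24.5e6 tally ops vs 5000 PSTH increments."""
        from appsth.experiments import complexity_counts
        tally_ops, psth_ops = complexity_counts(50, 100, duration=1.0, seed=5)
        assert tally_ops == 24_500_000
        assert psth_ops == 5_000


class TestFastIdentity:
    def test_sac_fast_bitwise_equals_tally_many_seeds(self):
        """The PSTH-autocorrelation identity is integer-exact."""
        for seed in range(20):
            rng = np.random.default_rng(seed)
            sts = _random_set(rng)
            a = ap.sac_tally(sts, 50e-6, 0.01)
            b = ap.sac_fast(sts, 50e-6, 0.01)
            assert np.array_equal(a.values, b.values), f"seed {seed}"

    def test_scc_fast_bitwise_equals_tally(self):
        rng = np.random.default_rng(77)
        X, Y = _random_set(rng), _random_set(rng)
        a = scc_tally(X, Y, 50e-6, 0.01)
        b = ap.scc_fast(X, Y, 50e-6, 0.01)
        assert np.array_equal(a.values, b.values)

    def test_sac_is_even(self):
        rng = np.random.default_rng(3)
        c = ap.sac_fast(_random_set(rng), 50e-6, 0.01)
        assert np.array_equal(c.values, c.values[::-1])

    def test_complexity_scaling(self):
        """Tally ops grow as (M*n)^2-ish; PSTH ops as M*n."""
        t1, p1 = [], []
        from appsth.experiments import complexity_counts
        for m in (5, 10, 20):
            t, p = complexity_counts(m, 20, duration=0.5, seed=m)
            t1.append(t)
            p1.append(p)
        assert t1 == [5 * 4 * 400, 10 * 9 * 400, 20 * 19 * 400]
        assert p1 == [100, 200, 400]

    def test_scc_hand_example(self):
        X = ap.SpikeTrainSet([[0.0]], [1], 0.01)
        Y = ap.SpikeTrainSet([[0.002]], [1], 0.01)
        c = ap.scc_fast(X, Y, 1e-3, 5e-3)
        i = np.argmin(np.abs(c.lags - 2e-3))
        assert c.values[i] == 1
        assert c.values.sum() == 1

    def test_scc_of_identical_copy_vs_sac(self):
        """SCC(X, X) keeps within-train pairs the SAC excludes."""
        rng = np.random.default_rng(8)
        sts = _random_set(rng, n_trains=6, mean_spikes=20)
        copy = ap.SpikeTrainSet(list(sts.trains), sts.polarities, sts.duration)
        scc = ap.scc_fast(sts, copy, 50e-6, 0.005)
        sac = ap.sac_fast(sts, 50e-6, 0.005)
        diff = scc.values - sac.values
        assert np.all(diff >= 0)
        i0 = np.argmin(np.abs(scc.lags))
        assert diff[i0] >= sts.n_spikes  # every spike pairs with itself

    def test_empty_set_scc_is_zero(self):
        X = ap.SpikeTrainSet([[], []], [1, 1], 0.01)
        Y = ap.SpikeTrainSet([[0.002]], [1], 0.01)
        c = ap.scc_fast(X, Y, 1e-3, 5e-3)
        assert np.all(c.values == 0)


@pytest.fixture(scope="module")
def sam_spikes():
    """High-CF (8 kHz) SAM response: envelope coding, no carrier locking."""
    stim = ap.make_sam_tone(8000.0, 20.0, 1.0, 0.5, 40000.0)
    return ap.simulate_both_polarities(stim, ap.ANFiberParams(cf=8000.0),
                                       25, seed=9)


@pytest.fixture(scope="module")
def tone_spikes():
    """Low-CF (500 Hz) pure-tone response: strong carrier locking."""
    stim = ap.make_sam_tone(500.0, 20.0, 0.0, 0.5, 40000.0)
    return ap.simulate_both_polarities(stim, ap.ANFiberParams(cf=500.0),
                                       25, seed=10)


class TestSumcorDifcor:
    def test_difcor_flat_for_envelope_only_response(self, sam_spikes,
                                                    tone_spikes):
        """Above the phase-locking roll-off the difcor loses its structure."""
        _, difcor_hi = ap.sumcor_difcor(sam_spikes.select(1),
                                        sam_spikes.select(-1), 50e-6)
        _, difcor_lo = ap.sumcor_difcor(tone_spikes.select(1),
                                        tone_spikes.select(-1), 50e-6)
        rms_hi = np.sqrt(np.mean(difcor_hi.values ** 2))
        rms_lo = np.sqrt(np.mean(difcor_lo.values ** 2))
        assert rms_hi < 0.15 * rms_lo

    def test_sumcor_peaks_at_zero_with_fm_periodicity(self, sam_spikes):
        sumcor, _ = ap.sumcor_difcor(sam_spikes.select(1),
                                     sam_spikes.select(-1), 50e-6)
        # smooth over 1 ms to suppress bin-level counting noise before
        # locating the broad 50-ms-period envelope peak
        kernel = np.ones(21) / 21
        smooth = np.convolve(sumcor.values, kernel, mode="same")
        peak_lag = sumcor.lags[np.argmax(smooth)]
        assert abs(peak_lag) <= 1e-3
        sp = correlogram_spectrum(sumcor)
        sp.values[0] = 0
        peak_f = sp.freqs[np.argmax(sp.values)]
        assert peak_f == pytest.approx(20.0, abs=sp.df)

    def test_difcor_oscillates_at_tone_frequency(self, tone_spikes):
        _, difcor = ap.sumcor_difcor(tone_spikes.select(1),
                                     tone_spikes.select(-1), 50e-6)
        sp = correlogram_spectrum(difcor)
        sp.values[0] = 0
        assert sp.freqs[np.argmax(sp.values)] == pytest.approx(500.0, abs=sp.df)

    def test_difcor_proportional_to_d_autocorrelation(self):
        """The difcor tracks the autocorrelation of d(t) (r > 0.999).

        The shuffled correlograms exclude within-train pairs while R(d)
        keeps them, so the identity is asymptotic in the train count;
        100 repetitions per polarity puts the residual below 1e-3.
        """
        bw = 50e-6
        stim = ap.make_sam_tone(500.0, 20.0, 0.0, 0.5, 40000.0)
        spikes = ap.simulate_both_polarities(stim, ap.ANFiberParams(cf=500.0),
                                             100, seed=10)
        _, difcor = ap.sumcor_difcor(spikes.select(1), spikes.select(-1), bw)
        p = ap.build_psth(spikes, 1, bw)
        n = ap.build_psth(spikes, -1, bw)
        d = ap.diff_component(p, n)
        from scipy.signal import fftconvolve
        r_full = fftconvolve(d.values, d.values[::-1])
        center = d.n - 1
        L = (difcor.values.size - 1) // 2
        r = r_full[center - L:center + L + 1]
        corr = np.corrcoef(difcor.values, r)[0, 1]
        assert corr > 0.999

    def test_missing_polarity_raises(self, tone_spikes):
        with pytest.raises(ap.ValidationError):
            ap.sumcor_difcor(tone_spikes.select(1),
                             ap.SpikeTrainSet([[0.01]], [-1], 0.5), 50e-6)


class TestSumcorPeakHeight:
    def test_flat_zero_sumcor(self):
        c = ap.Correlogram(np.linspace(-0.02, 0.02, 801), np.zeros(801), 50e-6,
                           "rate-detrended")
        assert ap.sumcor_peak_height(c, "raw") == 0.0
        assert ap.sumcor_peak_height(c, "adjusted", [(15, 25)]) == pytest.approx(0.0)

    def test_band_covering_all_power_matches_raw(self):
        lags = np.linspace(-0.025, 0.025, 1001)
        vals = np.cos(2 * np.pi * 20.0 * lags)
        c = ap.Correlogram(lags, vals, lags[1] - lags[0], "rate-detrended")
        raw = ap.sumcor_peak_height(c, "raw")
        adj = ap.sumcor_peak_height(c, "adjusted", [(15, 25)])
        assert adj == pytest.approx(raw, rel=0.02)

    def test_adjusted_not_larger_than_raw(self):
        stim = ap.make_sam_tone(500.0, 20.0, 1.0, 0.5, 40000.0)
        sts = ap.simulate_both_polarities(stim, ap.ANFiberParams(cf=500.0), 25,
                                          seed=11)
        sumcor, _ = ap.sumcor_difcor(sts.select(1), sts.select(-1), 50e-6)
        raw = ap.sumcor_peak_height(sumcor, "raw")
        adj = ap.sumcor_peak_height(sumcor, "adjusted",
                                    [(15, 25), (35, 45), (55, 65)])
        assert adj <= raw + 1e-9

    def test_empty_band_list_raises(self):
        c = ap.Correlogram(np.zeros(3), np.zeros(3), 1e-3, "rate-detrended")
        with pytest.raises(ap.ValidationError):
            ap.sumcor_peak_height(c, "adjusted", [])


class TestRateNormalization:
    def test_chance_level_unity_then_zero(self):
        """Uncorrelated Poisson trains: normalized SAC ~1, detrended ~0."""
        rng = np.random.default_rng(40)
        sts = _random_set(rng, n_trains=40, mean_spikes=200, dur=0.5)
        sac = ap.sac_fast(sts, 1e-3, 0.02)
        norm = normalize_correlogram(sac, sts.n_trains, sts.n_spikes, sts.duration)
        assert np.mean(norm.values) == pytest.approx(1.0, abs=0.05)
        flat = detrend_correlogram(norm, sts.duration)
        assert abs(np.mean(flat.values)) < 0.05


class TestVectorStrength:
    def test_perfect_locking(self):
        times = np.arange(100) * 0.01  # all at phase 0 of 100 Hz
        assert ap.vector_strength(times, 100.0) == pytest.approx(1.0)

    def test_uniform_spikes_near_zero(self, rng):
        times = rng.uniform(0, 10.0, 4000)
        assert ap.vector_strength(times, 100.0) < 3 / np.sqrt(4000)

    def test_symmetric_four_phase_cancellation(self):
        f = 100.0
        times = np.array([0.0, 0.25, 0.5, 0.75]) / f
        assert ap.vector_strength(times, f) == pytest.approx(0.0, abs=1e-12)

    def test_no_spikes_raises(self):
        with pytest.raises(ap.ValidationError):
            ap.vector_strength([], 100.0)


class TestVsFromSpectrum:
    def test_zero_difference_psth(self):
        sp = ap.Spectrum(np.arange(10.0), np.zeros(10))
        vs = ap.vs_from_spectrum(sp, 100)
        assert np.all(vs.values == 0)

    def test_bounded_by_one_and_matches_direct_vs(self):
        """VS(f) from |D(f)| agrees with direct VS on phase-locked spikes."""
        f = 500.0
        stim = ap.make_sam_tone(f, 20.0, 0.0, 0.5, 40000.0)
        sts = ap.simulate_both_polarities(stim, ap.ANFiberParams(cf=f), 25,
                                          seed=3)
        p = ap.build_psth(sts, 1, 1e-4)
        n = ap.build_psth(sts, -1, 1e-4)
        d = ap.diff_component(p, n)
        vs_curve = ap.vs_from_spectrum(ap.dft_spectrum(d, "magnitude"),
                                       sts.n_spikes)
        assert np.all(vs_curve.values <= 1.0 + 1e-9)
        i = np.argmin(np.abs(vs_curve.freqs - f))
        half = 0.5 / f
        pooled = np.concatenate(
            [tr if pol == 1 else tr + half
             for tr, pol in zip(sts.trains, sts.polarities)])
        direct = ap.vector_strength(pooled, f)
        assert vs_curve.values[i] == pytest.approx(direct, rel=0.02)

    def test_zero_spikes_raises(self):
        sp = ap.Spectrum(np.arange(10.0), np.zeros(10))
        with pytest.raises(ap.ValidationError):
            ap.vs_from_spectrum(sp, 0)
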