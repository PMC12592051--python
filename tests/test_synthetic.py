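import numpy as np
import pytest
from scipy import stats, special

from somnoscale import avalanches as av
from somnoscale import synthetic as syn
from somnoscale.recordings import zscore
from somnoscale.spectral import welch_psd


class TestSeedDeterminism:
    @pytest.mark.parametrize("make", [
        lambda s: syn.gen_white(500, s),
        lambda s: syn.gen_fgn(0.8, 512, s),
        lambda s: syn.gen_random_walk(500, s),
        lambda s: syn.gen_powerlaw_sample(2.0, 3, 500, s),
        lambda s: syn.gen_spectral_mixture([(1.0, 10.0, 2.0)], 1.0, 2000,
                                           200.0, s),
        lambda s: syn.gen_branching_raster(cascades=200, seed=s).binned.counts,
    ])
    def test_same_seed_same_output(self, make):
        np.testing.assert_array_equal(make(11), make(11))
        assert not np.array_equal(make(11), make(12))


class TestWhite:
    def test_moments(self):
        x = syn.gen_white(100_000, 0)
        assert abs(x.var() - 1) < 0.02
        assert abs(np.corrcoef(x[:-1], x[1:])[0, 1]) < 0.02


class TestFGN:
    def test_h_half_is_white(self):
        x = syn.gen_fgn(0.5, 2**17, 1)
        assert abs(np.corrcoef(x[:-1], x[1:])[0, 1]) < 0.02

    def test_lag1_autocorrelation_closed_form(self):
        x = syn.gen_fgn(0.8, 2**17, 2)
        rho1 = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert abs(rho1 - (2**1.6 - 2) / 2) < 0.03

    def test_unit_variance(self):
        assert abs(syn.gen_fgn(0.7, 2**16, 3).var() - 1) < 0.1

    def test_invalid_h(self):
        with pytest.raises(ValueError):
            syn.gen_fgn(1.2, 100, 0)


class TestRandomWalk:
    def test_differencing_recovers_white_exactly(self):
        w = syn.gen_white(5000, 4)
        rw = syn.gen_random_walk(5000, 4)
        np.testing.assert_allclose(np.diff(rw), w[1:], atol=1e-12)
        assert rw[0] == w[0]

    def test_variance_grows_linearly(self):
        walks = np.array([syn.gen_random_walk(2000, 100 + i)
                          for i in range(300)])
        v = walks.var(axis=0)
        slope = stats.linregress(np.arange(2000), v).slope
        assert abs(slope - 1.0) < 0.15


class TestSpectralMixture:
    def test_single_bump_peak_location(self):
        x = syn.gen_spectral_mixture([(2.0, 12.0, 1.0)], 0.0, 12000, 200.0, 5)
        psd = welch_psd(x, 200.0)
        m = psd.band_mask(1.0, 75.0)
        peak = psd.freqs_hz[m][np.argmax(psd.power[m])]
        assert abs(peak - 12.0) <= 200.0 / 600

    def test_background_slope_recovered(self):
        """Zero-amplitude components give pure 1/f^beta; log-log periodogram
        slope ~ -beta."""
        beta = 1.5
        x = syn.gen_spectral_mixture([], beta, 60000, 200.0, 6)
        from somnoscale.spectral import periodogram
        psd = periodogram(x, 200.0)
        m = psd.band_mask(0.7, 75.0)
        reg = stats.linregress(np.log10(psd.freqs_hz[m]),
                               np.log10(psd.power[m]))
        assert abs(reg.slope + beta) < 0.15

    def test_center_out_of_band_rejected(self):
        with pytest.raises(ValueError):
            syn.gen_spectral_mixture([(1.0, 90.0, 2.0)], 1.0, 2000, 200.0, 0)


class TestBranchingRaster:
    def test_subcritical_limit_mostly_singletons(self):
        res = syn.gen_branching_raster(m_b=0.01, cascades=5000, seed=1,
                                       build_raster=False)
        assert (res.sizes == 1).mean() >= 0.99

    def test_counts_match_cascade_bookkeeping(self):
        res = syn.gen_branching_raster(m_b=0.9, cascades=500, seed=2)
        avs = av.extract_avalanches(res.binned)
        # generator inserts empty bins, so extraction recovers cascades 1:1
        assert len(avs) == 500
        np.testing.assert_array_equal(
            np.sort([a.size for a in avs]), np.sort(res.sizes))
        np.testing.assert_array_equal(
            np.sort([a.duration for a in avs]), np.sort(res.durations))
        assert res.binned.counts.sum() == res.sizes.sum()

    def test_raster_consistent_with_counts(self):
        res = syn.gen_branching_raster(m_b=0.8, cascades=300, seed=3)
        binned_again = av.bin_raster(res.raster, bin_ms=10)
        np.testing.assert_array_equal(binned_again.counts, res.binned.counts)

    def test_critical_exponent_near_mean_field(self):
        res = syn.gen_branching_raster(m_b=1.0, cascades=100_000, seed=4,
                                       build_raster=False)
        fit = av.fit_power_law(res.sizes)
        assert abs(fit.exponent - 1.5) < 0.1

    def test_tau_decreases_with_branching_ratio(self):
        """Fitted tau strictly decreasing over m_b in {0.7, 0.85, 1.0}."""
        taus = []
        for m in (0.7, 0.85, 1.0):
            res = syn.gen_branching_raster(m_b=m, cascades=30_000, seed=5,
                                           build_raster=False)
            taus.append(av.fit_power_law(res.sizes).exponent)
        assert taus[0] > taus[1] > taus[2]

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            syn.gen_branching_raster(m_b=0.0)
        with pytest.raises(ValueError):
            syn.gen_branching_raster(n_channels=0)


class TestPowerlawSample:
    def test_support_and_xmin_frequency(self):
        tau, xmin = 2.0, 3
        s = syn.gen_powerlaw_sample(tau, xmin, 100_000, 6)
        assert s.min() == xmin
        p_xmin = xmin**-tau / special.zeta(tau, xmin)
        freq = (s == xmin).mean()
        se = np.sqrt(p_xmin * (1 - p_xmin) / s.size)
        assert abs(freq - p_xmin) < 3 * se

    def test_tail_beyond_table_handled(self):
        s = syn.gen_powerlaw_sample(1.3, 1, 50_000, 7, table_size=100)
        assert s.max() > 101  # exercises the zeta bisection path
        assert s.min() == 1

    def test_invalid(self):
        with pytest.raises(ValueError):
            syn.gen_powerlaw_sample(0.9, 3, 10, 0)


class TestRasterToSignal:
    def test_single_planted_event_detected_at_index(self):
        events = np.zeros((1, 12000), dtype=np.uint8)
        events[0, 6000] = 1
        raster = av.EventRaster(events=events, fs=200.0)
        epoch = syn.raster_to_signal(raster, seed=8)
        det = av.detect_events(zscore(epoch))
        assert det.events[0, 6000] == 1

    def test_no_events_noise_floor(self):
        """With nothing planted, detections occur at the (low) spontaneous
        crossing rate of the smoothed noise, matched against an independent
        simulation of the same noise model."""
        raster = av.EventRaster(events=np.zeros((8, 12000), dtype=np.uint8),
                                fs=200.0)
        epoch = syn.raster_to_signal(raster, seed=9)
        det = av.detect_events(zscore(epoch))
        observed = det.n_events

        # independent oracle: direct simulation of smoothed Gaussian noise
        from scipy import ndimage
        rng = np.random.default_rng(77)
        crossings = []
        for _ in range(30):
            n = ndimage.gaussian_filter1d(rng.standard_normal(12000),
                                          syn.NOISE_SMOOTH_SAMPLES,
                                          mode="wrap")
            n /= n.std()
            below = n < -2.0
            crossings.append(np.count_nonzero(below[1:] & ~below[:-1])
                             + below[0])
        mu, sd = np.mean(crossings) * 8, np.std(crossings) * np.sqrt(8) * 3
        assert abs(observed - mu) <= max(sd * 3, 10)

    def test_shallow_pulse_rejected(self):
        raster = av.EventRaster(events=np.zeros((1, 100), dtype=np.uint8),
                                fs=200.0)
        with pytest.raises(ValueError):
            syn.raster_to_signal(raster, pulse_amp_sd=-1.5)

    def test_seed_determinism(self):
        events = np.zeros((2, 1000), dtype=np.uint8)
        events[0, 500] = 1
        raster = av.EventRaster(events=events, fs=200.0)
        a = syn.raster_to_signal(raster, seed=10)
        b = syn.raster_to_signal(raster, seed=10)
        np.testing.assert_array_equal(a.samples, b.samples)


class TestEndToEndChain:
    def test_exponent_survives_signal_embedding(self):
        """Size exponent fitted after z-score -> detect -> bin -> extract on
        the embedded signal matches the fit on the noiseless raster within
        0.15."""
        res = syn.gen_branching_raster(n_channels=16, m_b=1.0, cascades=3000,
                                       seed=11, size_cap=200,
                                       spacing_bins=10)
        noiseless = av.fit_power_law(
            [a.size for a in av.extract_avalanches(
                av.bin_raster(res.raster, bin_ms=10))], min_tail=30)
        epoch = syn.raster_to_signal(res.raster, seed=12)
        det = av.detect_events(zscore(epoch))
        recovered = av.fit_power_law(
            [a.size for a in av.extract_avalanches(
                av.bin_raster(det, bin_ms=10))], min_tail=30)
        assert abs(recovered.exponent - noiseless.exponent) < 0.15
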