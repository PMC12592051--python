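import numpy as np
import pytest

from somnoscale import avalanches as av
from somnoscale.recordings import ChannelInfo, Epoch, zscore
from somnoscale.synthetic import gen_branching_raster, gen_powerlaw_sample


def brute_force_runs(counts):
    """Independent oracle: enumerate active runs one bin at a time."""
    out, size, dur, start = [], 0, 0, None
    for i, c in enumerate(list(counts) + [0]):
        if c > 0:
            if start is None:
                start = i
            size += c
            dur += 1
        elif start is not None:
            out.append((size, dur, start))
            size, dur, start = 0, 0, None
    return out


def zscored_epoch_with_motif():
    """Long z-scored channel embedding the motif 0,-a,-a,0,-a so the
    crossing rule can be hand-traced."""
    rng = np.random.default_rng(0)
    x = rng.standard_normal(12000) * 0.1
    x[1000:1005] = [0, -3.0, -3.1, 0, -3.0]
    x = (x - x.mean()) / x.std()
    return Epoch(samples=x[None, :], fs=200.0)


class TestDetectEvents:
    def test_one_event_per_negative_excursion(self):
        e = zscored_epoch_with_motif()
        raster = av.detect_events(e)
        idx = np.nonzero(raster.events[0])[0]
        # motif produces crossings at its 2nd and 5th samples only
        assert {1001, 1004} <= set(idx)
        assert 1002 not in idx  # still below threshold, no new event

    def test_all_zero_like_channel_no_events(self, rng):
        x = rng.standard_normal(12000) * 0.01
        x = (x - x.mean()) / x.std()  # z-scored, but never near -2... scaled
        e = Epoch(samples=(x * 0.4 + np.zeros_like(x))[None, :] / (x * 0.4).std())
        e = zscore(e)
        # a sub-threshold start counts once; otherwise counts are crossings
        raster = av.detect_events(e, threshold_sd=-50.0)
        assert raster.n_events == 0

    def test_non_zscored_input_rejected(self, rng):
        e = Epoch(samples=rng.standard_normal((1, 1000)) * 3)
        with pytest.raises(ValueError, match="z-scored"):
            av.detect_events(e)

    def test_default_threshold(self, small_epoch):
        raster = av.detect_events(zscore(small_epoch))
        assert raster.threshold_sd == -2.0


class TestBinRaster:
    def test_bin_count_at_defaults(self, small_epoch):
        raster = av.detect_events(zscore(small_epoch))
        binned = av.bin_raster(raster)
        assert binned.counts.size == 6000  # 12000 samples / 2 per 10 ms bin
        assert binned.counts.sum() == raster.n_events

    def test_empty_raster(self):
        r = av.EventRaster(events=np.zeros((2, 100), dtype=np.uint8), fs=200.0)
        assert av.bin_raster(r).counts.sum() == 0

    def test_non_integer_samples_per_bin(self):
        r = av.EventRaster(events=np.zeros((1, 100), dtype=np.uint8), fs=200.0)
        with pytest.raises(ValueError):
            av.bin_raster(r, bin_ms=7)


class TestExtractAvalanches:
    def test_hand_traced_examples(self):
        got = av.extract_avalanches(av.BinnedActivity(np.array([1, 2, 0, 1, 0])))
        assert [(a.size, a.duration, a.start_bin) for a in got] == \
            [(3, 2, 0), (1, 1, 3)]
        assert got[0].edge and not got[1].edge
        assert av.extract_avalanches(av.BinnedActivity(np.zeros(5, int))) == []
        (single,) = av.extract_avalanches(av.BinnedActivity(np.array([5])))
        assert (single.size, single.duration, single.edge) == (5, 1, True)

    def test_oracle_equivalence_and_conservation(self):
        """Exact agreement with brute-force run enumeration on 1,000 random
        count sequences; sum of sizes conserves total events."""
        rng = np.random.default_rng(99)
        for _ in range(1000):
            n = rng.integers(1, 40)
            counts = rng.poisson(0.8, size=n)
            got = av.extract_avalanches(av.BinnedActivity(counts))
            assert [(a.size, a.duration, a.start_bin) for a in got] == \
                brute_force_runs(counts)
            assert sum(a.size for a in got) == counts.sum()
            assert all(a.size >= a.duration for a in got)


class TestMeanActivity:
    def test_arithmetic(self):
        assert av.mean_activity_per_active_bin(
            av.BinnedActivity(np.array([1, 2, 0, 1]))) == pytest.approx(4 / 3)
        assert av.mean_activity_per_active_bin(
            av.BinnedActivity(np.ones(10, int))) == 1.0

    def test_no_active_bins(self):
        with pytest.raises(ValueError):
            av.mean_activity_per_active_bin(av.BinnedActivity(np.zeros(2, int)))


class TestSubsample:
    def _epoch(self, n_ch, rng):
        return Epoch(samples=rng.standard_normal((n_ch, 100)),
                     channels=[ChannelInfo(f"c{i}") for i in range(n_ch)])

    def test_deterministic_and_metadata_preserved(self, rng):
        e = self._epoch(20, rng)
        s1 = av.subsample_channels(e, k=16, seed=5)
        s2 = av.subsample_channels(e, k=16, seed=5)
        assert [c.channel_id for c in s1.channels] == \
            [c.channel_id for c in s2.channels]
        assert s1.n_channels == 16
        np.testing.assert_array_equal(s1.samples, s2.samples)

    def test_identity_and_too_few(self, rng):
        e16 = self._epoch(16, rng)
        assert av.subsample_channels(e16, k=16) is e16
        with pytest.raises(ValueError, match="at least 16"):
            av.subsample_channels(self._epoch(12, rng), k=16)


class TestPowerLawFit:
    def test_recovery_within_two_stderr(self):
        s = gen_powerlaw_sample(2.0, 3, 100_000, seed=4)
        fit = av.fit_power_law(s)
        assert abs(fit.exponent - 2.0) < 2 * fit.stderr
        assert fit.xmin == 3 and fit.n_tail == 100_000
        assert 0 <= fit.ks_distance <= 1

    def test_truncated_model_recovers_cutoff(self):
        # sample from x^-1.5 e^(-0.01 x) by rejection from the pure law
        # (rejection uniforms come from an independent stream)
        rng = np.random.default_rng(987654)
        s = gen_powerlaw_sample(1.5, 3, 200_000, seed=8)
        keep = rng.uniform(size=s.size) < np.exp(-0.01 * (s - 3))
        fit = av.fit_power_law(s[keep], truncated=True)
        assert abs(fit.exponent - 1.5) < 0.05
        assert abs(fit.lambda_cutoff - 0.01) < 0.005

    def test_degenerate_and_small_samples_rejected(self):
        with pytest.raises(ValueError, match="equal"):
            av.fit_power_law([5] * 100)
        with pytest.raises(ValueError, match="at least"):
            av.fit_power_law([3, 4, 5] * 3)

    def test_stderr_shrinks_with_n(self):
        fits = [av.fit_power_law(gen_powerlaw_sample(2.0, 3, n, seed=1))
                for n in (1000, 10_000)]
        assert fits[1].stderr < fits[0].stderr

    def test_summary_uses_ab_notation(self):
        fit = av.fit_power_law(gen_powerlaw_sample(2.0, 3, 5000, seed=2))
        assert "(" in fit.exponent_ab() and ")" in fit.exponent_ab()


class TestSizeDurationScaling:
    def test_exact_power_relation(self):
        avs = []
        for T in range(1, 21):
            s = T**1.2
            # two avalanches per duration averaging exactly to T^1.2
            avs += [av.Avalanche(size=int(round(s * 10)) , duration=T,
                                 start_bin=0)]
        # exact mean: use sizes 10*T^1.2 so <s>(T) = 10 T^1.2
        fit = av.size_duration_scaling(avs)
        assert fit.gamma == pytest.approx(1.2, abs=1e-2)
        assert fit.r_squared > 0.9999

    def test_single_duration_errors(self):
        avs = [av.Avalanche(5, 2, 0)] * 10
        with pytest.raises(ValueError):
            av.size_duration_scaling(avs)


class TestCracklingCheck:
    def test_arithmetic(self):
        rep = av.crackling_check(1.5, 2.0, gamma=2.0)
        assert rep.gamma_pred == pytest.approx(2.0)
        assert not rep.in_reference_band
        rep2 = av.crackling_check(2.0, 2.0, gamma=1.0)
        assert rep2.gamma_pred == pytest.approx(1.0)
        assert not rep2.in_reference_band

    def test_cohort_mean_exponents_land_in_reference_band(self):
        # N3 and W cohort-mean exponent pairs imply gamma in [1.10, 1.40]
        n3 = av.crackling_check(1.78, 1.90, gamma=1.16)
        assert n3.in_reference_band
        w = av.crackling_check(2.21, 2.58, gamma=1.15)
        assert w.in_reference_band

    def test_tau_must_exceed_one(self):
        with pytest.raises(ValueError):
            av.crackling_check(1.0, 2.0, 1.5)


class TestSensitivitySweep:
    @pytest.fixture(scope="class")
    def critical_epoch(self):
        res = gen_branching_raster(n_channels=16, m_b=1.0, cascades=4000,
                                   seed=3, size_cap=200, spacing_bins=10)
        from somnoscale.synthetic import raster_to_signal
        return zscore(raster_to_signal(res.raster, seed=4))

    def test_factorial_table_shape(self, critical_epoch):
        df = av.sensitivity_sweep(critical_epoch, min_tail=30)
        assert len(df) == 9
        assert set(df.bin_ms) == {10.0, 15.0, 20.0}
        assert set(df.threshold_sd) == {-2.2, -2.0, -1.8}

    def test_tau_robust_across_parameter_grid(self, critical_epoch):
        """On a critical raster the fitted tau is stable over the bin-width
        and threshold grid (relative variation well below 5%), and the
        mean-activity and avalanche-count columns are populated."""
        df = av.sensitivity_sweep(critical_epoch, min_tail=30)
        assert not df.failed.any()
        assert df.attrs["rel_variation_tau"] < 0.05
        assert (df.mean_activity >= 1).all()
        assert (df.n_avalanches > 0).all()

    def test_empty_epoch_flags_all_cells(self, rng):
        quiet = zscore(Epoch(samples=rng.standard_normal((2, 12000)) * 0.01))
        # threshold far below any sample: no events anywhere
        df = av.sensitivity_sweep(quiet, thresholds_sd=(-40.0, -50.0),
                                  bins_ms=(10.0,))
        assert df.failed.all()
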