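"""Complex-spike statistics tests: densities, correlograms, PSTH
bootstrap, gallop, mixture model, synthetic generator."""

import numpy as np
import pytest
from scipy import stats

from olivenet import (build_protocol, correlogram,
                      cross_stimulus_intervals, gallop_test,
                      generate_synthetic_trains, icsi_density,
                      mixture_model_fit, psth, psth_bootstrap,
                      rhythmicity_score, stimulus_rate_response)
from olivenet.spiketrains import RhythmicityResult


class TestIcsiDensity:
    def test_periodic_train_single_peak(self):
        train = np.arange(0, 60000, 100.0)
        d = icsi_density(train)
        peak = d.grid_ms[np.argmax(d.density)]
        assert peak == pytest.approx(100.0, abs=2.0)

    def test_unit_mass_per_interval(self):
        # intervals well inside the support: total mass = 1 per interval
        train = np.cumsum(np.full(51, 200.0))
        d = icsi_density(train, suppress_zero_lag=False)
        mass = np.trapezoid(d.density, d.grid_ms)
        assert mass == pytest.approx(1.0, rel=5e-3)

    def test_poisson_close_to_exponential(self, rng):
        isi = rng.exponential(1000.0, size=20000)
        train = np.cumsum(isi)
        d = icsi_density(train, suppress_zero_lag=False)
        lam = 1.0 / 1000.0
        expected = lam * np.exp(-lam * d.grid_ms)
        inner = (d.grid_ms > 20) & (d.grid_ms < 480)
        assert np.max(np.abs(d.density[inner] - expected[inner])) < 3e-4

    def test_stimulus_exclusion(self):
        train = np.array([0.0, 100.0, 1000.0, 1100.0])
        stim = np.array([50.0])  # removes the spike at 100 ms
        d = icsi_density(train, stim, stimulus_exclusion=True,
                         suppress_zero_lag=False)
        assert d.n_intervals == 2

    def test_too_few_intervals_rejected(self):
        with pytest.raises(ValueError, match="1"):
            icsi_density(np.array([5.0]))


class TestRhythmicity:
    def test_broad_density_not_significant(self, rng):
        """ISIs spread uniformly over a wide band: no narrow preferred
        interval, so the peak stays within 3 SD of the density values."""
        isi = rng.uniform(250.0, 800.0, size=3000)
        train = np.cumsum(isi)
        r = rhythmicity_score(icsi_density(train))
        assert not r.significant

    def test_gated_train_peak_at_cycle(self):
        ts = generate_synthetic_trains(1, 600000.0, base_rate_hz=3.0,
                                       osc_weight=1.0, osc_freq_hz=8.0,
                                       seed=5)
        r = rhythmicity_score(icsi_density(ts.trains[0]))
        assert r.significant
        assert r.peak_latency_ms == pytest.approx(125.0, abs=15.0)

    def test_strict_threshold_convention(self):
        RhythmicityResult(100.0, 3.0, False)  # z == 3 is not significant
        with pytest.raises(ValueError):
            RhythmicityResult(100.0, 3.0, True)
        RhythmicityResult(100.0, 3.0001, True)


class TestCorrelogram:
    def test_periodic_auto_peaks(self):
        train = np.arange(0, 30000, 100.0)
        c = correlogram(train)
        # counts concentrated at multiples of the period
        near = np.zeros_like(c.lags_ms, dtype=bool)
        for k in range(-5, 6):
            if k != 0:
                near |= np.abs(c.lags_ms - 100.0 * k) <= 10.0
        assert c.counts[near].sum() > 0.95 * c.counts.sum()
        assert c.counts[np.abs(c.lags_ms) <= 30.0].sum() == 0

    def test_identical_trains_peak_at_zero(self, rng):
        train = np.sort(rng.uniform(0, 60000, 300))
        c = correlogram(train, train)
        assert np.abs(c.lags_ms[np.argmax(c.counts)]) <= 20.0

    def test_shifted_train_side_peak_positive(self, rng):
        a = np.sort(rng.uniform(0, 120000, 400))
        b = a + 100.0
        c = correlogram(a, b)
        assert c.side_peak_latency_ms == pytest.approx(100.0, abs=10.0)
        assert c.side_peak_z > 3.0

    def test_flip_orientation(self, rng):
        a = np.sort(rng.uniform(0, 120000, 400))
        b = a - 100.0  # echo on the negative side before flipping
        c = correlogram(a, b)
        assert c.flipped
        assert c.side_peak_latency_ms == pytest.approx(100.0, abs=10.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            correlogram(np.empty(0))


class TestPsth:
    def test_no_spikes(self):
        r = psth(np.empty(0), np.array([100.0, 600.0]))
        assert np.all(r.counts == 0)

    def test_deterministic_response_single_bin(self):
        stim = np.arange(0, 50000, 1000.0)
        train = stim + 60.0
        r = psth(train, stim)
        i = np.argmax(r.probability)
        assert r.bin_edges_ms[i] == 60.0
        assert r.probability[i] == pytest.approx(1.0)
        assert r.probability.sum() == pytest.approx(1.0)

    def test_per_order_partition(self, rng):
        stim = np.arange(0, 60000, 1000.0)
        train = np.sort(rng.uniform(0, 60000, 500))
        r = psth(train, stim)
        np.testing.assert_allclose(r.by_order.sum(axis=0), r.counts)


class TestPsthBootstrap:
    def test_deterministic_response_detected(self):
        stim = np.arange(500.0, 120000, 1200.0)
        rngl = np.random.default_rng(3)
        spont = np.sort(rngl.uniform(0, 120000, 100))
        train = np.sort(np.concatenate([stim + 50.0, spont]))
        train = train[np.concatenate([[True], np.diff(train) > 1.0])]
        r = psth_bootstrap(train, stim, n_boot=300, seed=1)
        assert r.first_peak_ms is not None
        assert r.first_peak_ms == pytest.approx(55.0, abs=10.0)

    def test_double_peak_oscillatory_response(self):
        stim = np.arange(1000.0, 400000, 800.0)
        ts = generate_synthetic_trains(
            1, 400000.0, base_rate_hz=3.0, osc_weight=1.0, osc_freq_hz=8.0,
            stimuli=stim, reset_on_stimulus=True,
            response_probability=0.9, response_latency_ms=30.0, seed=2)
        r = psth_bootstrap(ts.trains[0], stim, n_boot=300, seed=4)
        assert r.first_peak_ms is not None and r.second_peak_ms is not None
        gap = r.second_peak_ms - r.first_peak_ms
        assert gap == pytest.approx(125.0, abs=30.0)

    def test_null_train_rarely_significant(self, rng):
        """Stimulus-independent trains trip the 99%/10 ms rule rarely."""
        stim = np.arange(500.0, 60000, 1000.0)
        n_fp = 0
        n_cells = 30
        for i in range(n_cells):
            train = np.cumsum(rng.exponential(800.0, size=90))
            train = train[train < 60000]
            if train.size < 5:
                continue
            r = psth_bootstrap(train, stim, n_boot=250, seed=i)
            if r.first_peak_ms is not None:
                n_fp += 1
        assert n_fp / n_cells <= 0.1

    def test_degenerate_train_rejected(self):
        with pytest.raises(ValueError):
            psth_bootstrap(np.array([1.0, 2.0]), np.array([10.0]))


class TestGallop:
    @staticmethod
    def _sched(n=42, short=250.0, long=400.0):
        return build_protocol("gallop", short=short, long=long, n=n)

    def test_respond_to_every_stimulus(self):
        sched = self._sched()
        train = sched.onsets_ms + 50.0
        r = gallop_test(train, sched)
        assert r.response_ratio == pytest.approx(0.5, abs=0.03)
        assert r.fisher_p > 0.9

    def test_short_only_preference_significant(self):
        """20 short hits vs 0 long hits out of 20 each; exact
        hypergeometric two-sided p = 2 / C(40, 20)."""
        sched = self._sched(n=41)
        iv = np.diff(sched.onsets_ms)
        onsets = sched.onsets_ms
        hits = [onsets[j] + 50.0 for j in range(1, onsets.size)
                if iv[j - 1] == 250.0]
        r = gallop_test(np.array(sorted(hits)), sched)
        assert r.short_hits == 20 and r.long_hits == 0
        from math import comb

        expect = 2.0 / comb(40, 20)
        assert r.fisher_p == pytest.approx(expect, rel=1e-6)
        assert r.fisher_p < 0.001

    def test_conditional_filter_rule(self):
        """Only response windows whose preceding window contained a spike
        stay eligible; totals match a hand count."""
        sched = build_protocol("gallop", short=250.0, long=400.0, n=9)
        onsets = sched.onsets_ms
        iv = np.diff(onsets)
        # spikes after stimuli 0, 1, 2, 5 -> eligible windows 1, 2, 3, 6
        train = np.sort(onsets[[0, 1, 2, 5]] + 30.0)
        r = gallop_test(train, sched, conditional=True,
                        response_window_ms=(20.0, 200.0))
        elig = [1, 2, 3, 6]
        short_total = sum(1 for j in elig if iv[j - 1] == 250.0)
        assert r.short_total == short_total
        assert r.long_total == len(elig) - short_total
        # of the eligible windows only 1 and 2 contain a spike
        assert r.short_hits + r.long_hits == 2

    def test_fisher_matches_hypergeometric_oracle(self):
        """Two-sided Fisher p equals the sum of hypergeometric point
        probabilities <= that of the observed table."""
        from scipy.stats import hypergeom

        for a, b, c, d in [(5, 3, 2, 6), (10, 0, 4, 8), (1, 9, 7, 3),
                           (12, 12, 0, 12), (6, 6, 6, 6), (0, 8, 8, 0)]:
            p_scipy = stats.fisher_exact([[a, b], [c, d]])[1]
            n1, n2, k = a + b, c + d, a + c
            rv = hypergeom(n1 + n2, n1, k)
            p0 = rv.pmf(a)
            support = np.arange(max(0, k - n2), min(k, n1) + 1)
            oracle = rv.pmf(support)[rv.pmf(support)
                                     <= p0 * (1 + 1e-9)].sum()
            assert p_scipy == pytest.approx(oracle, rel=1e-7)

    def test_bootstrap_null_symmetric_train(self, rng):
        sched = self._sched(n=60)
        train = np.cumsum(rng.exponential(400.0, 60))
        train = train[train < sched.onsets_ms[-1] + 300]
        r = gallop_test(train, sched, bootstrap=200, seed=0)
        assert r.bootstrap_p is not None and r.bootstrap_p > 0.05


class TestCrossStimulusIntervals:
    def test_hand_example(self):
        train = np.array([880.0, 1080.0])
        stim = np.array([1000.0])
        iv = cross_stimulus_intervals(train, stim)
        assert np.array_equal(iv, [200.0])

    def test_no_pre_spike_no_contribution(self):
        iv = cross_stimulus_intervals(np.array([1080.0]),
                                      np.array([1000.0]))
        assert iv.size == 0

    def test_matches_bruteforce_scan(self, rng):
        train = np.sort(rng.uniform(0, 20000, 60))
        stim = np.arange(1000.0, 11000.0, 1000.0)
        got = cross_stimulus_intervals(train, stim)
        expected = []
        for s in stim:
            pre = [t for t in train if s - 300.0 <= t < s]
            post = [t for t in train if s + 20.0 <= t <= s + 200.0]
            if pre and post:
                expected.append(min(post) - max(pre))
        np.testing.assert_allclose(np.sort(got), np.sort(expected))


class TestMixtureModel:
    @staticmethod
    def _dataset(weight, seed, n_stim=400):
        # stimulus period is an integer number of 125 ms gate cycles so
        # the pre-stimulus gate stays aligned with the response spike
        stim = np.arange(1000.0, 1000.0 + n_stim * 1000.0, 1000.0)
        ts = generate_synthetic_trains(
            1, stim[-1] + 1000.0, base_rate_hz=1.5, osc_weight=weight,
            osc_freq_hz=8.0, stimuli=stim, reset_on_stimulus=True,
            response_probability=0.6, seed=seed)
        tr = ts.trains[0]
        iv = cross_stimulus_intervals(tr, stim)
        first = []
        for s in stim:
            post = tr[(tr >= s + 20.0) & (tr <= s + 200.0)]
            pre = tr[(tr >= s - 300.0) & (tr < s)]
            if post.size and pre.size:
                first.append(post[0] - s)
        refr = float(np.diff(tr).min())
        return iv, np.asarray(first), refr

    def test_recovers_oscillatory_process(self):
        iv, first, refr = self._dataset(1.0, seed=11)
        fit = mixture_model_fit(iv, 8.0, refr, first, n_runs=300, seed=0)
        assert fit.best_weight >= 0.8

    def test_recovers_uniform_process(self):
        iv, first, refr = self._dataset(0.0, seed=12)
        fit = mixture_model_fit(iv, 8.0, refr, first, n_runs=300, seed=0)
        assert fit.best_weight <= 0.2

    def test_refractory_matches_min_icsi(self):
        ts = generate_synthetic_trains(1, 300000.0, base_rate_hz=2.0,
                                       refractory_ms=50.0, seed=3)
        refr = float(np.diff(ts.trains[0]).min())
        assert refr >= 50.0
        assert refr == pytest.approx(50.0, abs=15.0)

    def test_empty_intervals_rejected(self):
        with pytest.raises(ValueError):
            mixture_model_fit(np.empty(0), 8.0, 50.0, np.array([50.0]))


class TestStimulusRateResponse:
    @staticmethod
    def _ts(rate_hz, cs_per_stim, duration=60000.0):
        from olivenet import SpikeTrainSet

        stim = np.arange(500.0, duration - 300.0, 1000.0 / rate_hz)
        trains = [np.sort(stim[::max(int(1 / cs_per_stim), 1)] + 40.0)]
        return SpikeTrainSet(trains=trains, stimulus_times=stim,
                             duration_ms=duration)

    def test_one_spike_per_stimulus_slope_one(self):
        data = {r: self._ts(r, 1.0) for r in (1.0, 2.0, 4.0)}
        out = stimulus_rate_response(data)
        assert out["slope"] == pytest.approx(1.0, abs=0.1)
        assert out["r_squared"] > 0.95

    def test_fixed_rate_slope_zero(self):
        from olivenet import SpikeTrainSet

        data = {}
        for r in (1.0, 2.0, 4.0):
            stim = np.arange(500.0, 59000.0, 1000.0 / r)
            train = np.arange(250.0, 60000.0, 1000.0)
            data[r] = SpikeTrainSet(trains=[train], stimulus_times=stim,
                                    duration_ms=60000.0)
        out = stimulus_rate_response(data)
        assert out["slope"] == pytest.approx(0.0, abs=0.05)

    def test_matches_closed_form_regression(self):
        from olivenet import SpikeTrainSet

        xs = [1.0, 2.0, 3.0, 4.0]
        ys = [0.9, 1.1, 1.4, 1.5]
        data = {}
        for x, y in zip(xs, ys):
            n = int(y * 60)
            train = np.linspace(100.0, 59000.0, n)
            stim = np.arange(500.0, 59000.0, 1000.0 / x)
            data[x] = SpikeTrainSet(trains=[train], stimulus_times=stim,
                                    duration_ms=60000.0)
        out = stimulus_rate_response(data)
        got_y = [1000.0 * data[x].trains[0].size / 60000.0 for x in xs]
        mx, my = np.mean(xs), np.mean(got_y)
        slope = (np.sum((np.array(xs) - mx)
                        * (np.array(got_y) - my))
                 / np.sum((np.array(xs) - mx) ** 2))
        assert out["slope"] == pytest.approx(slope, rel=1e-9)


class TestSyntheticGenerator:
    def test_uniform_isi_is_shifted_exponential(self):
        ts = generate_synthetic_trains(1, 1000000.0, base_rate_hz=1.0,
                                       refractory_ms=50.0, osc_weight=0.0,
                                       seed=7)
        isi = np.diff(ts.trains[0])
        assert isi.min() >= 50.0
        ks = stats.kstest(isi - 50.0, "expon",
                          args=(0, (isi - 50.0).mean()))
        assert ks.pvalue > 0.01

    def test_gated_icsi_peaks_at_cycle_multiples(self):
        ts = generate_synthetic_trains(1, 600000.0, base_rate_hz=3.0,
                                       osc_weight=1.0,
                                       osc_freq_hz=8.0, seed=8)
        d = icsi_density(ts.trains[0])
        g, dens = d.grid_ms, d.density

        def band(a, b):
            return dens[(g >= a) & (g < b)].sum()

        peak1 = g[(g >= 100) & (g <= 150)][
            np.argmax(dens[(g >= 100) & (g <= 150)])]
        assert peak1 == pytest.approx(125.0, abs=12.0)
        # the one-cycle band dominates its neighbors (gate humps are
        # ~60 ms wide at 8 Hz, so higher multiples overlap)
        assert band(100, 150) > 1.8 * band(150, 200)
        assert band(100, 150) > 1.5 * band(50, 100)

    def test_rate_calibration(self):
        ts = generate_synthetic_trains(2, 1000000.0, base_rate_hz=1.0,
                                       refractory_ms=50.0,
                                       osc_weight=0.5, seed=9)
        for tr in ts.trains:
            rate = 1000.0 * tr.size / ts.duration_ms
            assert rate == pytest.approx(1.0, rel=0.1)

    def test_deterministic_per_seed(self):
        a = generate_synthetic_trains(2, 50000.0, seed=1)
        b = generate_synthetic_trains(2, 50000.0, seed=1)
        assert all(np.array_equal(x, y)
                   for x, y in zip(a.trains, b.trains))
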