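"""Photon-pair histograms, g_E estimator, correlation ratios, intensity FCS."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fretcorr as fc
from fretcorr.bursts import Burst, BurstFilterPolicy, apply_filters, find_bursts
from fretcorr.correlation import (
    PAIR_AA,
    PAIR_AD,
    PAIR_DA,
    PAIR_DD,
    correlation_ratios,
    fret_correlation,
    intensity_correlations,
    log_edges,
    mean_apparent_E,
    pair_histograms,
    pair_histograms_bruteforce,
    uniform_edges,
)
from fretcorr.fitting import fit_single_exponential
from fretcorr.photons import PhotonStream


def _burst_stream(times, channels, dets=None):
    s = PhotonStream(np.asarray(times, float), np.asarray(channels), detectors=dets)
    ch = s.channels
    b = Burst(0, len(times) - 1, s.times[0], s.times[-1] - s.times[0],
              int((ch == 0).sum()), int((ch == 1).sum()), 0)
    return s, [b]


class TestMeanApparentE:
    def test_pooled_over_bursts(self):
        bursts = [
            Burst(0, 39, 0.0, 100.0, n_raw_D=10, n_raw_A=30, n_AA=0),
            Burst(40, 79, 200.0, 100.0, n_raw_D=30, n_raw_A=10, n_AA=0),
        ]
        assert mean_apparent_E(bursts) == pytest.approx(0.5)

    def test_all_acceptor(self):
        assert mean_apparent_E([Burst(0, 9, 0, 1, 0, 10, 0)]) == 1.0

    def test_no_photons_raises(self):
        with pytest.raises(ValueError):
            mean_apparent_E([Burst(0, 0, 0, 1, 0, 0, 0)])


class TestPairEnumeration:
    def test_two_photon_burst(self):
        s, b = _burst_stream([0.0, 1.0], [1, 0])  # A then D, lag 1
        ph = pair_histograms(b, s, np.arange(0.0, 5.0))
        assert ph.counts[PAIR_AD, 1] == 1
        assert ph.counts.sum() == 1

    def test_three_photon_burst(self):
        s, b = _burst_stream([0.0, 1.0, 2.0], [1, 0, 0])  # A, D, D
        ph = pair_histograms(b, s, np.arange(0.0, 5.0))
        assert ph.counts[PAIR_AD, 1] == 1  # A->D at lag 1
        assert ph.counts[PAIR_AD, 2] == 1  # A->D at lag 2
        assert ph.counts[PAIR_DD, 1] == 1  # D->D at lag 1
        assert ph.total[1] == 2 and ph.total[2] == 1

    def test_total_pair_count_combinatorics(self):
        rng = np.random.default_rng(0)
        n = 60
        s, b = _burst_stream(np.sort(rng.uniform(0, 100, n)), rng.integers(0, 2, n))
        ph = pair_histograms(b, s, np.array([0.0, 200.0]))
        assert ph.total.sum() == n * (n - 1) // 2

    def test_equal_timestamps_fall_in_first_bin(self):
        s, b = _burst_stream([5.0, 5.0, 6.0], [1, 0, 1])
        ph = pair_histograms(b, s, np.arange(0.0, 4.0))
        assert ph.counts[PAIR_AD, 0] == 1  # tie ordered by stream index

    @given(
        n=st.integers(5, 200),
        seed=st.integers(0, 10_000),
        log_bins=st.booleans(),
        exclude=st.booleans(),
    )
    @settings(max_examples=40, deadline=None)
    def test_fast_path_matches_bruteforce(self, n, seed, log_bins, exclude):
        """The sorted-sweep counter and O(n^2) enumeration agree bin by bin."""
        rng = np.random.default_rng(seed)
        t = np.sort(rng.uniform(0, 500.0, n))
        ch = rng.integers(0, 2, n)
        det = rng.integers(0, 4, n).astype(np.int8)
        s, b = _burst_stream(t, ch, dets=det)
        edges = log_edges(0.5, 600.0, 6) if log_bins else uniform_edges(7.0, 300.0)
        fast = pair_histograms(b, s, edges, exclude_same_detector=exclude)
        slow = pair_histograms_bruteforce(b, s, edges, exclude_same_detector=exclude)
        assert np.array_equal(fast.counts, slow.counts)

    def test_pairs_never_span_bursts(self):
        t = np.concatenate([np.arange(10.0), 10_000 + np.arange(10.0)])
        ch = np.zeros(20)
        s = PhotonStream(t, ch)
        policy = BurstFilterPolicy(min_photons=5)
        bursts = find_bursts(s, policy, gap=100.0)
        ph = pair_histograms(bursts, s, np.array([0.0, 50_000.0]))
        assert ph.total.sum() == 2 * (10 * 9 // 2)


class TestFretCorrelation:
    def test_iid_coloring_is_null(self):
        """Random i.i.d. colours: g_E = 0 and all f_XY = 1 within error."""
        rng = np.random.default_rng(3)
        streams, bursts, idx = [], [], 0
        t_all, c_all = [], []
        for k in range(300):
            n = rng.poisson(80) + 2
            t0 = k * 10_000.0
            t = np.sort(rng.uniform(t0, t0 + 1000.0, n))
            c = (rng.random(n) < 0.3).astype(np.int8)
            t_all.append(t)
            c_all.append(c)
            bursts.append(
                Burst(idx, idx + n - 1, t[0], t[-1] - t[0],
                      int((c == 0).sum()), int((c == 1).sum()), 0)
            )
            idx += n
        s = PhotonStream(np.concatenate(t_all), np.concatenate(c_all))
        ph = pair_histograms(bursts, s, uniform_edges(50.0, 800.0))
        corr = fret_correlation(ph)
        assert np.nanmax(np.abs(corr.g)) < 0.003
        ratios = correlation_ratios(ph)
        for key in ("f_AA", "f_DD", "f_AD", "f_DA"):
            assert np.nanmax(np.abs(ratios[key] - 1.0)) < 0.05

    def test_binwise_conservation_identity(self):
        """The four pair fractions sum to one in every populated bin, exactly."""
        rng = np.random.default_rng(9)
        n = 400
        s, b = _burst_stream(np.sort(rng.uniform(0, 2000, n)), rng.integers(0, 2, n))
        ph = pair_histograms(b, s, uniform_edges(20.0, 1000.0))
        N = ph.total
        m = N > 0
        frac_sum = (ph.counts[:, m] / N[m]).sum(axis=0)
        assert np.array_equal(ph.counts.sum(axis=0), N)
        np.testing.assert_allclose(frac_sum, 1.0, rtol=0, atol=1e-15)

    def test_static_mixture_plateau(self, static_run):
        """Static 50/50 mixture at low concentration: g_E flat near
        (E2 - E1)^2 / 4 = 0.16."""
        ph = pair_histograms(
            static_run["bursts"], static_run["stream"], uniform_edges(50.0, 1500.0)
        )
        corr = fret_correlation(ph)
        m = corr.n_pairs > 1000
        level = np.nanmean(corr.g[m])
        assert level == pytest.approx(0.16, abs=0.015)
        # flat: no bin deviates strongly from the plateau
        assert np.nanmax(np.abs(corr.g[m] - level)) < 0.02

    def test_two_state_amplitude_and_rate(self, two_state_run):
        """g_E(0+) ~ p1 p2 (E2-E1)^2 and decay rate k12 + k21."""
        ph = pair_histograms(
            two_state_run["bursts"], two_state_run["stream"], uniform_edges(10.0, 1200.0)
        )
        corr = fret_correlation(ph)
        res = fit_single_exponential(corr)
        assert res.amplitudes[0] == pytest.approx(0.25 * 0.6**2, rel=0.15)
        assert res.taus[0] == pytest.approx(100.0, rel=0.12)


class TestIntensityCorrelations:
    def test_constant_rate_stream_is_flat(self):
        rng = np.random.default_rng(1)
        t = np.sort(rng.uniform(0, 1e6, 40_000))
        s = PhotonStream(t, np.ones(t.size, np.int8))
        corr = intensity_correlations(s, ("A", "A"), uniform_edges(50.0, 2000.0), 1e6)
        assert np.nanmax(np.abs(corr.g - 1.0)) < 0.05

    def test_two_state_brightness_switching_bunches(self):
        """Switching emitter: G(tau) = 1 + A exp(-(k12+k21) tau)."""
        rng = np.random.default_rng(2)
        dt, n_steps, k = 1.0, 2_000_000, 0.002
        from fretcorr import _kernels

        K = np.array([[-k, k], [k, -k]])
        states = _kernels.simulate_state_path_const(
            n_steps, K, np.array([0.5, 0.5]), dt, 77
        )
        rates = np.array([0.02, 0.2])
        counts = rng.poisson(rates[states] * dt)
        t = np.repeat(np.arange(n_steps) * dt, counts) + rng.random(counts.sum()) * dt
        s = PhotonStream(np.sort(t), np.ones(t.size, np.int8))
        corr = intensity_correlations(
            s, ("A", "A"), uniform_edges(10.0, 2000.0), n_steps * dt
        )
        res = fit_single_exponential((corr.lag, corr.g - 1.0))
        assert res.taus[0] == pytest.approx(1.0 / (2 * k), rel=0.15)

    def test_pair_ratio_matches_intensity_ratio(self, two_state_run):
        """Within-burst pair fractions track the ratio of conventional
        intensity correlations on burst-dense data (5% on populated bins)."""
        stream = two_state_run["stream"]
        bursts = two_state_run["bursts"]
        edges = uniform_edges(25.0, 600.0)
        ph = pair_histograms(bursts, stream, edges)
        g_aa = intensity_correlations(stream, ("A", "A"), edges)
        g_nn_counts = np.zeros_like(g_aa.g)
        # all-pair correlation: sum the four ordered-pair channels
        total = None
        for pair in (("A", "A"), ("D", "D"), ("A", "D"), ("D", "A")):
            c = intensity_correlations(stream, pair, edges).n_pairs
            total = c if total is None else total + c
        ratio_intensity = g_aa.n_pairs / total
        ratio_pairs = ph.counts[PAIR_AA] / ph.total
        m = (ph.total > 20_000) & (total > 20_000)
        np.testing.assert_allclose(ratio_pairs[m], ratio_intensity[m], rtol=0.05)
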