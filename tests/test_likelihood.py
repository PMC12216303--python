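"""Photon-by-photon likelihood, ML fitting, BIC and recoloring."""

import numpy as np
import pytest
from scipy.linalg import expm

import fretcorr as fc
from fretcorr.likelihood import (
    bic,
    burst_log_likelihood,
    extract_photon_data,
    maximize_likelihood,
    recolor,
    total_log_likelihood,
)
from fretcorr.theory import detection_matrices
from tests.conftest import synthetic_photon_data


class TestBurstLikelihood:
    def test_single_photon_closed_form(self):
        """One acceptor photon, equal populations, eps (0.2, 0.8), n = 1:
        L = ln(0.5*0.2 + 0.5*0.8) = ln 0.5."""
        m = fc.two_state_model(0.005, eps=(0.2, 0.8))
        V = detection_matrices(m.eps, np.ones(2), np.ones(2))
        L = burst_log_likelihood(np.array([0.0]), np.array([1]), m, V)
        assert L == pytest.approx(np.log(0.5), abs=1e-12)

    def test_single_state_poisson_path(self):
        """One state, eps = 1, rate n: two acceptor photons with gap tau give
        L = 2 ln n - n tau (the Poisson path density)."""
        m = fc.KineticModel(("s",), np.zeros((1, 1)), np.array([1.0]),
                            np.array([0.3]), np.array([0.3]))
        n = 0.3
        V = detection_matrices(m.eps, np.array([n]), np.array([n]))
        tau = 7.0
        L = burst_log_likelihood(np.array([0.0, tau]), np.array([1, 1]), m, V)
        assert L == pytest.approx(2 * np.log(n) - n * tau, rel=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_master_equation_path_sum(self, seed):
        """Independent oracle: scipy expm propagation of the detection-dressed
        master equation on short toy bursts, 1e-6 relative agreement."""
        rng = np.random.default_rng(seed)
        m = fc.two_state_model(*rng.uniform(1e-3, 0.05, 2), eps=(0.15, 0.85))
        V = detection_matrices(m.eps, np.full(2, 0.25), np.full(2, 0.2))
        tau = np.concatenate([[0.0], rng.exponential(8.0, 4)])
        ch = rng.integers(0, 2, 5)
        F = {0: V.V_D, 1: V.V_A}
        N = np.diag(V.total_rates)
        v = F[int(ch[0])] @ m.p_eq
        for j in range(1, 5):
            v = F[int(ch[j])] @ (expm((m.K - N) * tau[j]) @ v)
        oracle = np.log(v.sum())
        L = burst_log_likelihood(tau, ch, m, V)
        assert L == pytest.approx(oracle, rel=1e-6)

    def test_two_state_kernel_equals_general_path(self):
        rng = np.random.default_rng(5)
        tau = np.concatenate([[0.0], rng.exponential(5.0, 60)])
        ch = rng.integers(0, 2, 61).astype(np.int8)
        m = fc.two_state_model(0.004, 0.009, eps=(0.2, 0.8))
        n = 0.35
        V = detection_matrices(m.eps, np.full(2, n), np.full(2, n))
        L_general = burst_log_likelihood(tau, ch, m, V)
        data = type("D", (), {})()
        from fretcorr import _kernels

        L_kernel = _kernels.loglik_two_state(
            tau, ch, np.array([1] + [0] * 60, np.uint8), 0.004, 0.009, 0.2, 0.8, n
        )
        assert L_kernel == pytest.approx(L_general, rel=1e-12)


class TestBIC:
    def test_printed_arithmetic(self):
        assert bic(16.8, 4, 1000) == pytest.approx(4 * np.log(1000) - 33.6)

    def test_zero_case(self):
        assert bic(0.0, 0, 1000) == 0.0

    def test_better_likelihood_lowers_bic(self):
        assert bic(20.0, 4, 1000) < bic(16.8, 4, 1000)


class TestMaximumLikelihood:
    def test_recovers_rate_on_synthetic_bursts(self):
        data = synthetic_photon_data(800, 0.005, (0.2, 0.8), 0.2, 1000.0, seed=1)
        fit = maximize_likelihood(data, seed=2)
        assert fit.params["k12"] == pytest.approx(0.005, rel=0.1)
        assert fit.params["eps1"] == pytest.approx(0.2, abs=0.02)
        assert fit.params["eps2"] == pytest.approx(0.8, abs=0.02)
        assert fit.params["n"] == pytest.approx(0.2, rel=0.05)

    def test_estimator_consistency_with_burst_count(self):
        """Relative error of k shrinks with the number of bursts."""
        errs = {}
        for M in (250, 1000, 4000):
            data = synthetic_photon_data(M, 0.005, (0.2, 0.8), 0.2, 500.0, seed=7)
            fit = maximize_likelihood(data, n_restarts=2, seed=3)
            errs[M] = abs(fit.params["k12"] - 0.005) / 0.005
        assert errs[4000] < 0.10
        assert all(e < 0.25 for e in errs.values())

    def test_label_ordering(self):
        data = synthetic_photon_data(200, 0.005, (0.2, 0.8), 0.2, 800.0, seed=9)
        fit = maximize_likelihood(data, seed=4)
        assert fit.params["eps1"] < fit.params["eps2"]

    def test_refit_of_recolored_data_is_self_consistent(self, two_state_run,
                                                        two_state_fit):
        """Recoloring with the fitted model and refitting returns the
        recoloring parameters within fit error."""
        stream = two_state_run["stream"]
        bursts = two_state_run["bursts"]
        rec = recolor(stream, bursts, two_state_fit.model, n_realizations=1, seed=5)[0]
        data = extract_photon_data(rec, bursts)
        refit = maximize_likelihood(data, n_restarts=2, seed=6)
        assert refit.params["k12"] == pytest.approx(two_state_fit.params["k12"], rel=0.12)
        assert refit.params["eps2"] == pytest.approx(two_state_fit.params["eps2"], abs=0.03)


class TestRecoloring:
    def test_timestamps_preserved_bit_exactly(self, two_state_run, two_state_fit):
        stream = two_state_run["stream"]
        rec = recolor(stream, two_state_run["bursts"], two_state_fit.model,
                      n_realizations=2, seed=1)
        for r in rec:
            assert np.array_equal(r.times, stream.times)
            assert np.array_equal(r.slots, stream.slots)

    def test_degenerate_efficiencies_color_everything_acceptor(self, two_state_run):
        model = fc.two_state_model(0.005, eps=(1.0, 1.0))
        rec = recolor(two_state_run["stream"], two_state_run["bursts"], model,
                      n_realizations=1, seed=2)[0]
        data = extract_photon_data(rec, two_state_run["bursts"])
        assert np.all(data.channels == 1)

    def test_color_fractions_match_equilibrium(self, two_state_run):
        """Expected acceptor fraction = sum_i p_eq,i eps_i."""
        model = fc.two_state_model(0.005, eps=(0.1, 0.7))
        rec = recolor(two_state_run["stream"], two_state_run["bursts"], model,
                      n_realizations=3, seed=3)
        fracs = []
        for r in rec:
            data = extract_photon_data(r, two_state_run["bursts"])
            fracs.append(np.mean(data.channels == 1))
        assert np.mean(fracs) == pytest.approx(0.4, abs=0.01)

    def test_general_path_matches_two_state_statistics(self, two_state_run):
        """The n-state numpy recoloring path agrees with the 2-state kernel in
        distribution (same switching statistics feed the same colours)."""
        from fretcorr.likelihood import _recolor_general, extract_photon_data

        data = extract_photon_data(two_state_run["stream"], two_state_run["bursts"])
        model = fc.two_state_model(0.005, eps=(0.0, 1.0))  # colour = state
        colors = _recolor_general(data, model, np.random.default_rng(11))
        # acceptor fraction ~ 1/2 and strong correlation at short gaps
        assert np.mean(colors) == pytest.approx(0.5, abs=0.02)
        short = data.tau[1:] < 20.0
        same = colors[1:] == colors[:-1]
        inside = data.is_first[1:] == 0
        agree = np.mean(same[short & inside])
        theory = 0.5 * (1 + np.exp(-0.01 * np.mean(data.tau[1:][short & inside])))
        assert agree == pytest.approx(theory, abs=0.03)
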