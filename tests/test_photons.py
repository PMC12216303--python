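"""State dynamics, photon emission, instrumental imperfections and PIE."""

import numpy as np
import pytest
from scipy import stats

import fretcorr as fc
from fretcorr.confocal import DiffusionConfig, ParticleTrack
from fretcorr.kinetics import (
    InstrumentModel,
    PIEConfig,
    build_bleach_matrices,
    two_state_model,
)
from fretcorr.photons import (
    SLOT_AEX,
    SLOT_DEX,
    PhotonStream,
    emit_photons,
    simulate_photon_stream,
    simulate_pie,
    simulate_state_path,
)


def _flat_track(n, r=0.0, dt=1.0):
    return ParticleTrack(0, 0.0, np.full(n, r))


@pytest.fixture
def cfg():
    return DiffusionConfig(duration=0.01, seed=1)


class TestStatePath:
    def test_frozen_chain_for_zero_rates(self, cfg):
        model = fc.static_mixture_model(eps=(0.1, 0.9))
        track = _flat_track(5000, r=1.0)
        states = simulate_state_path(track, model, cfg, seed=3)
        assert np.all(states == states[0])

    def test_dwell_times_are_exponential(self, cfg):
        """Symmetric 2-state at k = 0.005/us: dwells ~ Exp(mean 200 us)."""
        model = two_state_model(0.005)
        track = _flat_track(2_000_000, r=1.0)
        states = simulate_state_path(track, model, cfg, seed=11)
        switch = np.flatnonzero(np.diff(states) != 0)
        dwells = np.diff(switch) * cfg.dt
        assert dwells.size > 3000
        res = stats.kstest(dwells, "expon", args=(0, 200.0))
        assert res.pvalue > 0.01

    def test_asymmetric_rates_occupancy(self, cfg):
        """k12 = k, k21 = 2k gives equilibrium occupancy (2/3, 1/3)."""
        model = two_state_model(0.005, 0.010)
        track = _flat_track(2_000_000, r=1.0)
        states = simulate_state_path(track, model, cfg, seed=4)
        f0 = np.mean(states == 0)
        assert f0 == pytest.approx(2.0 / 3.0, abs=0.02)

    def test_position_dependent_generator_matches_const_outside_beam(self, cfg):
        """With K1 active, a particle far outside the beam sees only K0."""
        model, bleach = build_bleach_matrices(3e-3, (0.1, 0.9), 8e-4, 8e-4)
        track = _flat_track(200_000, r=2.9)  # intensity ~ 0
        states = simulate_state_path(track, model, cfg, bleach=bleach, seed=5)
        # no photobleaching far from the beam: D (0) and A (3) never appear
        assert set(np.unique(states)) <= {1, 2}


class TestEmission:
    def test_pure_acceptor_without_imperfections(self, cfg):
        model = fc.static_mixture_model(eps=(1.0, 1.0))
        inst = InstrumentModel.ideal()
        track = _flat_track(20000, r=0.0)
        states = simulate_state_path(track, model, cfg, seed=1)
        ph = emit_photons(track, states, model, inst, cfg, seed=2)
        assert len(ph) > 100
        assert np.all(ph.channels == 1)

    def test_acceptor_fraction_with_gamma(self, cfg):
        """eps = 0.5, gamma = 1.15: raw fraction 1.15*0.5/(1.15*0.5+0.5)."""
        model = fc.static_mixture_model(eps=(0.5, 0.5), gamma=1.15)
        inst = InstrumentModel.ideal()
        track = _flat_track(300_000, r=0.0)
        states = simulate_state_path(track, model, cfg, seed=1)
        ph = emit_photons(track, states, model, inst, cfg, seed=2)
        frac = np.mean(ph.channels == 1)
        expect = 1.15 * 0.5 / (1.15 * 0.5 + 0.5)
        se = np.sqrt(expect * (1 - expect) / len(ph))
        assert frac == pytest.approx(expect, abs=4 * se)

    def test_total_rate_conservation(self, cfg):
        """Detected rate at radius r is I(r) * state-weighted emission rate."""
        model = two_state_model(0.005, eps=(0.2, 0.8))
        inst = InstrumentModel.ideal()
        r0 = 0.3
        track = _flat_track(400_000, r=r0)
        states = simulate_state_path(track, model, cfg, seed=8)
        ph = emit_photons(track, states, model, inst, cfg, seed=9)
        rate_a, rate_d = model.center_rates(0.0)
        per_state = rate_a + rate_d
        expected = float(
            np.mean(per_state[states]) * fc.intensity(r0, cfg.w0) * len(track) * cfg.dt
        )
        assert len(ph) == pytest.approx(expected, abs=4 * np.sqrt(expected))

    def test_crosstalk_reassigns_channels(self, cfg):
        model = fc.static_mixture_model(eps=(0.0, 0.0))  # donor-only emission
        inst = InstrumentModel(gamma=1.0, beta_DA=0.05, beta_AD=0.0, alpha=0.0,
                               bg_D=0.0, bg_A=0.0)
        track = _flat_track(300_000, r=0.0)
        states = simulate_state_path(track, model, cfg, seed=1)
        ph = emit_photons(track, states, model, inst, cfg, seed=2)
        frac_a = np.mean(ph.channels == 1)
        se = np.sqrt(0.05 * 0.95 / len(ph))
        assert frac_a == pytest.approx(0.05, abs=4 * se)


class TestPIE:
    def test_slots_are_exclusive_and_dex_subset_reproduces(self):
        cfg = DiffusionConfig(duration=2.0, seed=6)
        model = two_state_model(0.005, eps=(0.1, 0.9))
        inst = InstrumentModel(pie=PIEConfig(gamma_pie=2.0))
        stream = simulate_photon_stream(cfg, model, inst)
        assert set(np.unique(stream.slots)) <= {SLOT_DEX, SLOT_AEX}
        dex = stream.dex_only()
        assert np.all(dex.slots == SLOT_DEX)
        assert len(dex) + int(np.sum(stream.slots == SLOT_AEX)) == len(stream)

    def test_stoichiometry_expectation(self, cfg):
        """gamma_PIE = 2, intact acceptor, eps = 0.5 -> S -> 0.5."""
        model = fc.static_mixture_model(eps=(0.5, 0.5))
        inst = InstrumentModel.ideal(pie=PIEConfig(gamma_pie=2.0))
        track = _flat_track(400_000, r=0.0)
        states = simulate_state_path(track, model, cfg, seed=1)
        ph = emit_photons(track, states, model, inst, cfg, seed=2)
        n_dex = int(np.sum(ph.slots == SLOT_DEX))
        n_aa = int(np.sum((ph.slots == SLOT_AEX) & (ph.channels == 1)))
        S = n_dex / (n_dex + 2.0 * n_aa)
        assert S == pytest.approx(0.5, abs=0.01)

    def test_bleached_acceptor_emits_no_aex(self, cfg):
        model, bleach = build_bleach_matrices(0.0, (0.1, 0.9), 0.0, 0.0)
        model.p0 = np.array([1.0, 0.0, 0.0, 0.0])  # donor-only state
        inst = InstrumentModel.ideal(pie=PIEConfig(gamma_pie=2.0))
        track = _flat_track(100_000, r=0.0)
        states = simulate_state_path(track, model, cfg, bleach=bleach, seed=1)
        ph = emit_photons(track, states, model, inst, cfg, seed=2)
        assert np.sum(ph.slots == SLOT_AEX) == 0
        assert len(ph) > 100  # the donor still emits

    def test_nanotimes_within_period(self):
        inst = InstrumentModel(pie=PIEConfig(period_ns=50.0), irf_sigma_ns=2.0)
        stream = PhotonStream(
            np.arange(1000.0), np.zeros(1000), slots=np.tile([0, 1], 500)
        )
        out = simulate_pie(stream, inst, np.random.default_rng(0))
        assert np.all((out.nanotimes >= 0) & (out.nanotimes < 50.0))

    def test_requires_pie_config(self):
        stream = PhotonStream(np.arange(10.0), np.zeros(10))
        with pytest.raises(ValueError):
            simulate_pie(stream, InstrumentModel.ideal(), np.random.default_rng(0))


class TestStreamInvariants:
    def test_sorted_and_deterministic(self):
        cfg = DiffusionConfig(duration=1.0, seed=55)
        model = two_state_model(0.005)
        inst = InstrumentModel()
        s1 = simulate_photon_stream(cfg, model, inst)
        s2 = simulate_photon_stream(cfg, model, inst)
        assert np.all(np.diff(s1.times) >= 0)
        assert np.array_equal(s1.times, s2.times)
        assert np.array_equal(s1.channels, s2.channels)

    def test_unsorted_stream_rejected(self):
        with pytest.raises(ValueError):
            PhotonStream(np.array([2.0, 1.0]), np.array([0, 1]))


class TestCGPhotophysics:
    def test_rates_scale_linearly(self):
        from fretcorr.fixtures import illustrative_cg_model
        from fretcorr.photons import cg_rates

        cg = illustrative_cg_model()
        em_a, em_d, K = cg_rates(cg, 0.0)
        assert np.all(em_a == 0) and np.all(em_d == 0)
        em_a, em_d, K = cg_rates(cg, cg.k_ex_max)
        assert np.array_equal(em_a, cg.emission_a_max)
        assert np.array_equal(em_d, cg.emission_d_max)
        assert np.allclose(K.sum(axis=0), 0.0, atol=1e-12)
        em_a_h, _, _ = cg_rates(cg, cg.k_ex_max / 2)
        assert np.allclose(em_a_h, cg.emission_a_max / 2)

    def test_out_of_range_clamps_with_warning(self):
        from fretcorr.fixtures import illustrative_cg_model

        cg = illustrative_cg_model()
        with pytest.warns(RuntimeWarning):
            em_a, _, _ = cg.rates_at(2 * cg.k_ex_max)
        assert np.array_equal(em_a, cg.emission_a_max)

    def test_tt_state_is_dark(self):
        from fretcorr.fixtures import illustrative_cg_model

        cg = illustrative_cg_model()
        assert cg.emission_a_max[3] == 0.0 and cg.emission_d_max[3] == 0.0
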