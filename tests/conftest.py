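"""Shared simulated datasets (session-scoped: the expensive forward runs)."""

from __future__ import annotations

import numpy as np
import pytest

import fretcorr as fc
from fretcorr import _kernels
from fretcorr.likelihood import PhotonData, extract_photon_data, maximize_likelihood


@pytest.fixture(scope="session")
def two_state_run():
    """Symmetric 2-state exchange at k = 5/ms, eps (0.2, 0.8), ideal optics.

    Matches the conditions under which photon-by-photon ML fits are
    benchmarked: no background, gamma = 1, burst threshold 50.
    """
    cfg = fc.DiffusionConfig(duration=90.0, seed=101)
    model = fc.two_state_model(0.005, eps=(0.2, 0.8), lambda_tot=cfg.lambda_tot)
    inst = fc.InstrumentModel.ideal()
    stream = fc.simulate_photon_stream(cfg, model, inst)
    policy = fc.BurstFilterPolicy(min_photons=50)
    kept = fc.apply_filters(fc.find_bursts(stream, policy, gap=50.0), inst, policy)
    data = extract_photon_data(stream, kept)
    return {"cfg": cfg, "model": model, "inst": inst, "stream": stream,
            "bursts": kept, "data": data}


@pytest.fixture(scope="session")
def two_state_fit(two_state_run):
    return maximize_likelihood(two_state_run["data"], seed=1)


@pytest.fixture(scope="session")
def four_state_run():
    """Hidden 4-state chain (non-Markov on the FRET coordinate) at k = 5/ms."""
    cfg = fc.DiffusionConfig(duration=120.0, seed=202)
    model = fc.four_state_chain_model(0.005, eps=(0.2, 0.8), lambda_tot=cfg.lambda_tot)
    inst = fc.InstrumentModel.ideal()
    stream = fc.simulate_photon_stream(cfg, model, inst)
    policy = fc.BurstFilterPolicy(min_photons=50)
    kept = fc.apply_filters(fc.find_bursts(stream, policy, gap=50.0), inst, policy)
    data = extract_photon_data(stream, kept)
    return {"cfg": cfg, "model": model, "inst": inst, "stream": stream,
            "bursts": kept, "data": data}


@pytest.fixture(scope="session")
def four_state_fit(four_state_run):
    return maximize_likelihood(four_state_run["data"], seed=1)


@pytest.fixture(scope="session")
def static_run():
    """Non-interconverting 50/50 mixture of eps 0.1 / 0.9 at 50 pM."""
    cfg = fc.DiffusionConfig(duration=30.0, seed=303)
    model = fc.static_mixture_model(eps=(0.1, 0.9), lambda_tot=cfg.lambda_tot)
    inst = fc.InstrumentModel.ideal()
    stream = fc.simulate_photon_stream(cfg, model, inst)
    policy = fc.BurstFilterPolicy(min_photons=100)
    kept = fc.apply_filters(fc.find_bursts(stream, policy, gap=50.0), inst, policy)
    return {"cfg": cfg, "model": model, "inst": inst, "stream": stream, "bursts": kept}


@pytest.fixture(scope="session")
def single_state_run():
    """Single conformational state: any g_E structure is a diffusion artifact."""
    cfg = fc.DiffusionConfig(duration=60.0, seed=404)
    model = fc.static_mixture_model(eps=(0.5, 0.5), lambda_tot=cfg.lambda_tot)
    inst = fc.InstrumentModel.ideal()
    stream = fc.simulate_photon_stream(cfg, model, inst)
    policy = fc.BurstFilterPolicy(min_photons=100)
    kept = fc.apply_filters(fc.find_bursts(stream, policy, gap=50.0), inst, policy)
    return {"cfg": cfg, "stream": stream, "bursts": kept}


@pytest.fixture(scope="session")
def bleach_run():
    """4-state photobleaching scheme with PIE and the matching burst filters."""
    fx = fc.make_fixture("bleaching", seed=3, duration_s=120.0)
    return fx


def synthetic_photon_data(M, k, eps, n_rate, T_us, seed):
    """Fixed-intensity synthetic bursts for likelihood benchmarks.

    Photon times uniform over the burst window with Poisson totals; colours
    drawn from an exact 2-state Markov path at the photon times.
    """
    rng = np.random.default_rng(seed)
    taus, chans, firsts = [], [], []
    for i in range(M):
        n = rng.poisson(n_rate * T_us)
        if n < 2:
            continue
        t = np.sort(rng.uniform(0.0, T_us, n))
        tau = np.empty(n)
        tau[0] = 0.0
        tau[1:] = np.diff(t)
        f = np.zeros(n, np.uint8)
        f[0] = 1
        col = _kernels.recolor_two_state(
            tau, f, k, k, eps[0], eps[1], int(rng.integers(1, 2**31 - 1))
        )
        taus.append(tau)
        chans.append(col)
        firsts.append(f)
    return PhotonData(
        tau=np.concatenate(taus),
        channels=np.concatenate(chans).astype(np.int8),
        is_first=np.concatenate(firsts),
        stream_idx=np.zeros(sum(len(t) for t in taus), np.int64),
        n_bursts=len(taus),
    )
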