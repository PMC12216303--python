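"""Deterministic small simulated datasets tying the simulator to the analysis.

Each fixture regenerates identically under a fixed seed and carries its
ground truth, so tests and demos can check recovered timescales against the
parameters that generated the photons.  Durations are kept to a few tens of
simulated seconds: enough bursts for stable correlation functions at the
default 50 pM while staying fast to generate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bursts import BurstFilterPolicy, apply_filters, find_bursts
from .confocal import DiffusionConfig
from .kinetics import (
    CGPhotophysicsModel,
    InstrumentModel,
    KineticModel,
    PIEConfig,
    build_bleach_matrices,
    four_state_chain_model,
    static_mixture_model,
    two_state_model,
)
from .photons import PhotonStream, simulate_photon_stream

__all__ = ["Fixture", "FIXTURE_NAMES", "make_fixture", "illustrative_cg_model"]

FIXTURE_NAMES = (
    "two-state",
    "four-state-chain",
    "static-mixture",
    "bleaching",
    "cg-triplet",
    "idp-nsfcs",
)


@dataclass
class Fixture:
    name: str
    stream: PhotonStream
    cfg: DiffusionConfig
    model: KineticModel
    inst: InstrumentModel
    policy: BurstFilterPolicy
    gap_us: float
    truth: dict = field(default_factory=dict)

    def bursts(self, filtered: bool = True):
        bursts = find_bursts(self.stream, self.policy, gap=self.gap_us)
        if filtered:
            return apply_filters(bursts, self.inst, self.policy)
        return bursts


def illustrative_cg_model() -> CGPhotophysicsModel:
    """Bundled coarse-grained triplet scheme with illustrative rate constants.

    Triplet lifetimes of ~3 us (T->S rates 0.33/us) and excitation-linear
    S->T crossing rates of 0.02/us at the beam centre give a triplet
    occupancy of a few percent -- representative of green/red organic dye
    pairs at moderate excitation, not a fitted characterisation of any
    specific pair.  Emission rates at full excitation put half the 0.4/us
    total in each channel for the all-singlet state; a dye in its triplet is
    dark, so the TS state emits only weak direct-excitation acceptor signal
    and the ST state emits donor-only at the unquenched rate.
    """
    k_ts = 1.0 / 3.0  # 1/us, triplet decay
    k_st = 0.02  # 1/us at k_ex_max
    # states: SS, TS, ST, TT  (donor manifold first letter, acceptor second)
    st = np.zeros((4, 4))
    st[1, 0] = k_st  # SS -> TS (donor crossing)
    st[2, 0] = k_st  # SS -> ST (acceptor crossing, via FRET-excited acceptor)
    st[3, 1] = k_st  # TS -> TT
    st[3, 2] = k_st  # ST -> TT
    np.fill_diagonal(st, -st.sum(axis=0))
    ts = np.zeros((4, 4))
    ts[0, 1] = k_ts  # TS -> SS
    ts[0, 2] = k_ts  # ST -> SS
    ts[1, 3] = k_ts  # TT -> TS
    ts[2, 3] = k_ts  # TT -> ST
    np.fill_diagonal(ts, -ts.sum(axis=0))
    return CGPhotophysicsModel(
        emission_a_max=np.array([0.2, 0.02, 0.0, 0.0]),
        emission_d_max=np.array([0.2, 0.0, 0.4, 0.0]),
        st_rates_max=st,
        ts_rates=ts,
        k_ex_max=0.08,
    )


def make_fixture(name: str, seed: int, duration_s: float | None = None) -> Fixture:
    """Generate one of the named datasets; deterministic under (name, seed)."""
    if name == "two-state":
        dur = 30.0 if duration_s is None else duration_s
        cfg = DiffusionConfig(duration=dur, seed=seed)
        model = two_state_model(0.005, eps=(0.1, 0.9), lambda_tot=cfg.lambda_tot)
        inst = InstrumentModel()
        stream = simulate_photon_stream(cfg, model, inst)
        return Fixture(
            name, stream, cfg, model, inst,
            BurstFilterPolicy(min_photons=100), 50.0,
            truth={"k": 0.005, "eps": (0.1, 0.9), "relax_time_us": 100.0},
        )
    if name == "four-state-chain":
        dur = 30.0 if duration_s is None else duration_s
        cfg = DiffusionConfig(duration=dur, seed=seed)
        model = four_state_chain_model(0.005, eps=(0.2, 0.8), lambda_tot=cfg.lambda_tot)
        inst = InstrumentModel.ideal()
        stream = simulate_photon_stream(cfg, model, inst)
        return Fixture(
            name, stream, cfg, model, inst,
            BurstFilterPolicy(min_photons=50), 50.0,
            truth={"k": 0.005, "eps": (0.2, 0.8)},
        )
    if name == "static-mixture":
        dur = 20.0 if duration_s is None else duration_s
        cfg = DiffusionConfig(duration=dur, seed=seed)
        model = static_mixture_model(eps=(0.1, 0.9), lambda_tot=cfg.lambda_tot)
        inst = InstrumentModel.ideal()
        stream = simulate_photon_stream(cfg, model, inst)
        return Fixture(
            name, stream, cfg, model, inst,
            BurstFilterPolicy(min_photons=100), 50.0,
            truth={"eps": (0.1, 0.9), "plateau": (0.9 - 0.1) ** 2 / 4.0},
        )
    if name == "bleaching":
        dur = 30.0 if duration_s is None else duration_s
        cfg = DiffusionConfig(duration=dur, seed=seed)
        model, bleach = build_bleach_matrices(
            3e-3, (0.1, 0.9), 8e-4, 8e-4, lambda_tot=cfg.lambda_tot
        )
        inst = InstrumentModel(
            gamma=1.0, beta_DA=0.0, beta_AD=0.0, alpha=0.0, bg_D=0.0, bg_A=0.0,
            pie=PIEConfig(gamma_pie=2.0),
        )
        stream = simulate_photon_stream(cfg, model, inst, bleach=bleach)
        return Fixture(
            name, stream, cfg, model, inst,
            BurstFilterPolicy(min_photons=75), 50.0,
            truth={"k": 3e-3, "k_A": 8e-4, "k_D": 8e-4, "eps": (0.1, 0.9)},
        )
    if name == "cg-triplet":
        dur = 10.0 if duration_s is None else duration_s
        cfg = DiffusionConfig(duration=dur, seed=seed, dt=0.5)
        cg = illustrative_cg_model()
        model = cg.as_kinetic_model()
        inst = InstrumentModel.ideal()
        stream = simulate_photon_stream(cfg, model, inst, bleach=cg)
        return Fixture(
            name, stream, cfg, model, inst,
            BurstFilterPolicy(min_photons=75), 50.0,
            truth={"triplet_time_us": 3.0, "cg": cg},
        )
    if name == "idp-nsfcs":
        # fast chain reconfiguration: 50 ns relaxation, resolved at dt = 20 ns
        dur = 2.0 if duration_s is None else duration_s
        cfg = DiffusionConfig(duration=dur, seed=seed, dt=0.02, c0=100.0)
        model = two_state_model(10.0, eps=(0.3, 0.7), lambda_tot=cfg.lambda_tot)
        inst = InstrumentModel(
            gamma=1.0, beta_DA=0.0, beta_AD=0.0, alpha=0.0, bg_D=0.0, bg_A=0.0,
            n_detectors_per_channel=2,
        )
        stream = simulate_photon_stream(cfg, model, inst)
        return Fixture(
            name, stream, cfg, model, inst,
            BurstFilterPolicy(min_photons=150), 50.0,
            truth={"k": 10.0, "relax_time_us": 0.05},
        )
    raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
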