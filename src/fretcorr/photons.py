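"""Photon streams and the stochastic photon-emission engine.

The :class:`PhotonStream` is the exchange object between simulator and
analysis: time-ordered records of (arrival time in us, channel, detector,
excitation slot, optional nanotime in ns).

The engine walks every particle track produced by
:mod:`fretcorr.confocal`, simulates its conformational/photophysical state
path (exact Gillespie within each frozen-rate step) and emits donor and
acceptor photons as Poisson counts per step, with crosstalk, direct acceptor
excitation, background and pulsed interleaved excitation (PIE).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .confocal import DiffusionConfig, ParticleTrack, simulate_tracks
from .kinetics import BleachModel, CGPhotophysicsModel, InstrumentModel, KineticModel

__all__ = [
    "CHANNEL_DONOR",
    "CHANNEL_ACCEPTOR",
    "SLOT_DEX",
    "SLOT_AEX",
    "PhotonStream",
    "simulate_state_path",
    "emit_photons",
    "simulate_pie",
    "cg_rates",
    "simulate_photon_stream",
]

CHANNEL_DONOR = 0
CHANNEL_ACCEPTOR = 1
SLOT_DEX = 0
SLOT_AEX = 1


@dataclass
class PhotonStream:
    """Time-ordered photon records.

    times are in us and must be non-decreasing; channel is 0 (donor) or
    1 (acceptor); detector identifies the physical detector (equal to the
    channel in 2-detector setups); slot is 0 for donor-excitation photons,
    1 for acceptor-excitation photons.  nanotimes (ns within the excitation
    period) are optional and only meaningful for pulsed excitation.
    """

    times: np.ndarray
    channels: np.ndarray
    detectors: np.ndarray | None = None
    slots: np.ndarray | None = None
    nanotimes: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.channels = np.asarray(self.channels, np.int8)
        if self.detectors is None:
            self.detectors = self.channels.astype(np.int8)
        else:
            self.detectors = np.asarray(self.detectors, np.int8)
        if self.slots is None:
            self.slots = np.zeros(self.times.size, np.int8)
        else:
            self.slots = np.asarray(self.slots, np.int8)
        n = self.times.size
        for name in ("channels", "detectors", "slots"):
            if getattr(self, name).size != n:
                raise ValueError(f"{name} length mismatch")
        if self.nanotimes is not None:
            self.nanotimes = np.asarray(self.nanotimes, float)
            if self.nanotimes.size != n:
                raise ValueError("nanotimes length mismatch")
        if n > 1 and np.any(np.diff(self.times) < 0):
            raise ValueError("photon times must be non-decreasing")

    def __len__(self) -> int:
        return self.times.size

    def select(self, mask: np.ndarray) -> "PhotonStream":
        return PhotonStream(
            self.times[mask],
            self.channels[mask],
            self.detectors[mask],
            self.slots[mask],
            None if self.nanotimes is None else self.nanotimes[mask],
            dict(self.meta),
        )

    def dex_only(self) -> "PhotonStream":
        """Donor-excitation photons only (drops the Aex slot)."""
        return self.select(self.slots == SLOT_DEX)

    @staticmethod
    def merge(streams: list["PhotonStream"]) -> "PhotonStream":
        """Concatenate and stably time-sort several streams."""
        times = np.concatenate([s.times for s in streams])
        order = np.argsort(times, kind="stable")
        have_nt = all(s.nanotimes is not None for s in streams)
        return PhotonStream(
            times[order],
            np.concatenate([s.channels for s in streams])[order],
            np.concatenate([s.detectors for s in streams])[order],
            np.concatenate([s.slots for s in streams])[order],
            np.concatenate([s.nanotimes for s in streams])[order] if have_nt else None,
        )


def _seed_from(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1, np.uint64)[0] % (2**31 - 1))


def simulate_state_path(
    track: ParticleTrack,
    model: KineticModel,
    cfg: DiffusionConfig,
    bleach: BleachModel | CGPhotophysicsModel | None = None,
    seed: int = 0,
) -> np.ndarray:
    """State index per track step; generator frozen at K(r(t_k)) within a step.

    With a :class:`BleachModel` (or CG scheme) the generator is
    K0 + I(r) K1; otherwise the model's K applies everywhere.
    """
    if len(track) == 0:
        raise ValueError("track is empty")
    if isinstance(bleach, CGPhotophysicsModel):
        bleach = bleach.as_bleach_model()
    if bleach is None:
        K0 = model.K
        K1 = np.zeros_like(model.K)
    else:
        K0, K1 = bleach.K0, bleach.K1
    # largest total exit rate over I in [0, 1]
    worst = np.max(-np.diag(K0) + np.maximum(0.0, -np.diag(K1)))
    if worst * cfg.dt > 10.0:
        warnings.warn(
            "expected >10 transitions per step; dt is too coarse for these rates",
            RuntimeWarning,
            stacklevel=2,
        )
    if not np.any(K1):
        return _kernels.simulate_state_path_const(
            len(track),
            np.ascontiguousarray(K0),
            np.ascontiguousarray(model.p0),
            cfg.dt,
            seed,
        )
    return _kernels.simulate_state_path(
        np.ascontiguousarray(track.radii),
        cfg.w0,
        np.ascontiguousarray(K0),
        np.ascontiguousarray(K1),
        np.ascontiguousarray(model.p0),
        cfg.dt,
        seed,
    )


def emit_photons(
    track: ParticleTrack,
    states: np.ndarray,
    model: KineticModel,
    inst: InstrumentModel,
    cfg: DiffusionConfig,
    seed: int = 0,
) -> PhotonStream:
    """Photon emission along one track (no background; that is stream-level).

    Per step, acceptor and donor counts are Poisson with means
    a_i eps_i I(r) dt and d_i (1 - eps_i) I(r) dt (direct excitation adds
    alpha a_i to the acceptor mean); crosstalk reassigns channels photon by
    photon; with PIE an acceptor-excitation photon stream with per-state rate
    (total Dex rate)/gamma_PIE is added for acceptor-intact states.
    """
    if states.shape[0] != len(track):
        raise ValueError("states must align with track steps")
    rate_a, rate_d = model.center_rates(inst.alpha)
    if inst.pie is not None:
        tot = rate_a + rate_d
        rate_aa = np.where(model.acceptor_present, tot / inst.pie.gamma_pie, 0.0)
    else:
        rate_aa = np.zeros_like(rate_a)
    t, c, s = _kernels.emit_photons(
        np.ascontiguousarray(track.radii),
        np.ascontiguousarray(states),
        track.birth_time,
        cfg.dt,
        cfg.w0,
        np.ascontiguousarray(rate_a),
        np.ascontiguousarray(rate_d),
        np.ascontiguousarray(rate_aa),
        inst.beta_DA,
        inst.beta_AD,
        seed,
    )
    order = np.argsort(t, kind="stable")
    return PhotonStream(t[order], c[order], None, s[order])


def _background_stream(
    inst: InstrumentModel, duration_us: float, rng: np.random.Generator
) -> PhotonStream:
    """Uniform Poisson background in both channels over the full record."""
    parts_t, parts_c = [], []
    for chan, rate_khz in ((CHANNEL_DONOR, inst.bg_D), (CHANNEL_ACCEPTOR, inst.bg_A)):
        n = rng.poisson(rate_khz * 1e-3 * duration_us)
        parts_t.append(rng.random(n) * duration_us)
        parts_c.append(np.full(n, chan, np.int8))
    t = np.concatenate(parts_t)
    c = np.concatenate(parts_c)
    order = np.argsort(t, kind="stable")
    t, c = t[order], c[order]
    if inst.pie is not None:
        slots = rng.integers(0, 2, t.size).astype(np.int8)
    else:
        slots = np.zeros(t.size, np.int8)
    return PhotonStream(t, c, None, slots)


def simulate_pie(
    stream: PhotonStream, inst: InstrumentModel, rng: np.random.Generator
) -> PhotonStream:
    """Assign nanotimes (ns within the PIE period) from the slot pulse offsets.

    Nanotimes are the pulse offset plus IRF jitter (folded into the period);
    with a zero-width IRF they are delta functions at the offsets.
    """
    if inst.pie is None:
        raise ValueError("InstrumentModel.pie is not configured")
    offsets = np.where(
        stream.slots == SLOT_AEX, inst.pie.acceptor_offset_ns, inst.pie.donor_offset_ns
    )
    if inst.irf_sigma_ns > 0:
        jitter = np.abs(rng.normal(0.0, inst.irf_sigma_ns, stream.times.size))
    else:
        jitter = 0.0
    nanotimes = np.mod(offsets + jitter, inst.pie.period_ns)
    return PhotonStream(
        stream.times, stream.channels, stream.detectors, stream.slots, nanotimes,
        dict(stream.meta),
    )


def cg_rates(model: CGPhotophysicsModel, k_ex: float):
    """Emission and transition rates of the CG triplet scheme at k_ex (1/ns)."""
    return model.rates_at(k_ex)


def simulate_photon_stream(
    cfg: DiffusionConfig,
    model: KineticModel,
    inst: InstrumentModel,
    bleach: BleachModel | CGPhotophysicsModel | None = None,
) -> PhotonStream:
    """Full forward simulation: diffusion -> state dynamics -> photon stream.

    Deterministic under (cfg, model, inst) and cfg.seed; every particle uses
    independent substreams so the track set is invariant under changes that
    only add particles.
    """
    master = np.random.SeedSequence((cfg.seed, 0x9E3779B9))
    bg_rng = np.random.default_rng(master.spawn(1)[0])
    duration_us = cfg.duration * 1e6
    parts: list[PhotonStream] = []
    for track in simulate_tracks(cfg):
        ss_states, ss_phot = master.spawn(2)
        states = simulate_state_path(
            track, model, cfg, bleach, seed=_seed_from(ss_states)
        )
        ph = emit_photons(track, states, model, inst, cfg, seed=_seed_from(ss_phot))
        if len(ph):
            parts.append(ph)
    parts.append(_background_stream(inst, duration_us, bg_rng))
    stream = PhotonStream.merge(parts)
    if inst.n_detectors_per_channel == 2:
        det_rng = np.random.default_rng(master.spawn(1)[0])
        stream.detectors = (
            stream.channels * 2 + det_rng.integers(0, 2, len(stream))
        ).astype(np.int8)
    if inst.pie is not None:
        stream = simulate_pie(stream, inst, np.random.default_rng(master.spawn(1)[0]))
    stream.meta.update(
        {
            "seed": cfg.seed,
            "duration_s": cfg.duration,
            "dt_us": cfg.dt,
            "c0_pM": cfg.c0,
        }
    )
    return stream
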