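"""Photon stream file formats and run configuration.

Two dialects are supported: a Photon-HDF5-style container (groups
``photon_data/timestamps`` as integer clock ticks with a stored tick unit,
``detectors``, ``slots``, optional ``nanotimes``) and a plain CSV fallback
(time_us, channel, detector, slot[, nanotime_ns]).  Timestamps are stored as
integer ticks of the acquisition clock (default 32 ps) so round trips are
exact; microsecond floats are recovered by a single multiplication whose
error is far below half a tick even for hour-long streams.

Run configuration is a flat TOML file with [diffusion], [model],
[instrument] and [analysis] sections mirroring the dataclass field names.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .confocal import DiffusionConfig
from .kinetics import (
    InstrumentModel,
    PIEConfig,
    build_bleach_matrices,
    four_state_chain_model,
    static_mixture_model,
    two_state_model,
)
from .photons import PhotonStream

__all__ = [
    "DEFAULT_TICK_NS",
    "read_photons",
    "write_photons",
    "read_photons_csv",
    "write_photons_csv",
    "read_photons_hdf5",
    "write_photons_hdf5",
    "load_config",
    "config_hash",
    "build_simulation",
]

#: default acquisition clock: 32 ps per tick
DEFAULT_TICK_NS = 0.032
_TICKS_PER_US_DEFAULT = 31250  # 1 us / 32 ps, exact integer


def write_photons_csv(stream: PhotonStream, path) -> None:
    df = pd.DataFrame(
        {
            "time_us": stream.times,
            "channel": stream.channels,
            "detector": stream.detectors,
            "slot": stream.slots,
        }
    )
    if stream.nanotimes is not None:
        df["nanotime_ns"] = stream.nanotimes
    df.to_csv(path, index=False, float_format="%.17g")


def read_photons_csv(path) -> PhotonStream:
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"time_us", "channel"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing mandatory columns: {sorted(missing)}")
    t = df["time_us"].to_numpy(float)
    bad = np.flatnonzero(np.diff(t) < 0)
    if bad.size:
        raise ValueError(f"timestamps not sorted at row {int(bad[0]) + 1}")
    return PhotonStream(
        t,
        df["channel"].to_numpy(np.int8),
        df["detector"].to_numpy(np.int8) if "detector" in df else None,
        df["slot"].to_numpy(np.int8) if "slot" in df else None,
        df["nanotime_ns"].to_numpy(float) if "nanotime_ns" in df else None,
    )


def write_photons_hdf5(stream: PhotonStream, path, tick_ns: float = DEFAULT_TICK_NS) -> None:
    ticks_per_us = 1e3 / tick_ns
    ts = np.round(stream.times * ticks_per_us).astype(np.int64)
    with h5py.File(path, "w") as f:
        g = f.create_group("photon_data")
        d = g.create_dataset("timestamps", data=ts)
        d.attrs["unit_seconds"] = tick_ns * 1e-9
        g.create_dataset("detectors", data=stream.detectors.astype(np.int8))
        g.create_dataset("channels", data=stream.channels.astype(np.int8))
        g.create_dataset("slots", data=stream.slots.astype(np.int8))
        if stream.nanotimes is not None:
            g.create_dataset("nanotimes", data=stream.nanotimes)
        f.attrs["provenance"] = json.dumps(stream.meta, default=str)


def read_photons_hdf5(path) -> PhotonStream:
    with h5py.File(path, "r") as f:
        if "photon_data" not in f or "timestamps" not in f["photon_data"]:
            raise ValueError("missing mandatory photon_data/timestamps")
        g = f["photon_data"]
        ts = g["timestamps"][:]
        unit_s = float(g["timestamps"].attrs.get("unit_seconds", DEFAULT_TICK_NS * 1e-9))
        bad = np.flatnonzero(np.diff(ts) < 0)
        if bad.size:
            raise ValueError(f"timestamps not sorted at record {int(bad[0]) + 1}")
        t_us = ts.astype(np.float64) * (unit_s * 1e6)
        stream = PhotonStream(
            t_us,
            g["channels"][:].astype(np.int8) if "channels" in g else g["detectors"][:] % 2,
            g["detectors"][:].astype(np.int8) if "detectors" in g else None,
            g["slots"][:].astype(np.int8) if "slots" in g else None,
            g["nanotimes"][:] if "nanotimes" in g else None,
        )
        if "provenance" in f.attrs:
            stream.meta.update(json.loads(f.attrs["provenance"]))
    return stream


def write_photons(stream: PhotonStream, path) -> None:
    path = Path(path)
    if path.suffix in {".h5", ".hdf5"}:
        write_photons_hdf5(stream, path)
    else:
        write_photons_csv(stream, path)


def read_photons(path, dialect: str | None = None) -> PhotonStream:
    path = Path(path)
    if dialect is None:
        dialect = "photon-hdf5" if path.suffix in {".h5", ".hdf5"} else "csv"
    if dialect == "photon-hdf5":
        return read_photons_hdf5(path)
    if dialect == "csv":
        return read_photons_csv(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def load_config(path) -> dict:
    with open(path, "rb") as fh:
        return tomllib.load(fh)


def config_hash(cfg: dict) -> str:
    """Stable hash of a configuration mapping, embedded in run artifacts."""
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def build_simulation(cfg: dict, seed: int | None = None):
    """Instantiate (DiffusionConfig, KineticModel, InstrumentModel, bleach)
    from a configuration mapping (see the TOML layout in the docs)."""
    dif = dict(cfg.get("diffusion", {}))
    if seed is not None:
        dif["seed"] = seed
    dcfg = DiffusionConfig(**dif)
    m = dict(cfg.get("model", {}))
    kind = m.pop("kind", "two-state")
    bleach = None
    if kind == "two-state":
        model = two_state_model(
            m.get("k12", m.get("k", 0.005)),
            m.get("k21"),
            eps=tuple(m.get("eps", (0.1, 0.9))),
            lambda_tot=dcfg.lambda_tot,
            gamma=m.get("gamma", 1.0),
        )
    elif kind == "static-mixture":
        model = static_mixture_model(
            eps=tuple(m.get("eps", (0.1, 0.9))),
            populations=tuple(m.get("populations", (0.5, 0.5))),
            lambda_tot=dcfg.lambda_tot,
            gamma=m.get("gamma", 1.0),
        )
    elif kind == "four-state-chain":
        model = four_state_chain_model(
            m.get("k", 0.005), eps=tuple(m.get("eps", (0.2, 0.8))),
            lambda_tot=dcfg.lambda_tot,
        )
    elif kind == "bleaching":
        model, bleach = build_bleach_matrices(
            m.get("k", 3e-3),
            tuple(m.get("eps", (0.1, 0.9))),
            m.get("k_A", 8e-4),
            m.get("k_D", 8e-4),
            lambda_tot=dcfg.lambda_tot,
            gamma=m.get("gamma", 1.0),
        )
    else:
        raise ValueError(f"unknown model kind {kind!r}")
    i = dict(cfg.get("instrument", {}))
    pie = None
    if "pie" in i:
        pie = PIEConfig(**i.pop("pie"))
    elif i.pop("use_pie", False):
        pie = PIEConfig()
    inst = InstrumentModel(pie=pie, **i)
    return dcfg, model, inst, bleach
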