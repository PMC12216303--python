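"""Brownian dynamics of freely diffusing molecules in a confocal detection volume.

Molecules diffuse in a sphere of radius ``R`` centred on a radially symmetric
Gaussian excitation profile.  Only the radial coordinate is propagated: the
angular degrees of freedom of isotropic diffusion integrate out, leaving the
radial Ito equation

    r(t + dt) = r(t) + 2 D dt / r(t) + dr,    dr ~ Normal(0, 2 D dt)

A particle is removed when it first leaves the sphere; the loss is compensated
by periodically inserting new particles according to the solution of the
diffusion equation for a sphere that refills from a constant bulk
concentration at its boundary.  This birth--death scheme keeps the mean
occupancy at the bulk value ``n0 = (4/3) pi R^3 c0``.

Internal units: time in microseconds, length in micrometres, rates in 1/us.
Concentrations are supplied in pM and converted with Avogadro's number.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from ._kernels import simulate_radial_track

__all__ = [
    "AVOGADRO",
    "PM_TO_PER_UM3",
    "DiffusionConfig",
    "ParticleTrack",
    "step_radial",
    "intensity",
    "replenishment_density",
    "mean_replenished_count",
    "sample_replenishment_radii",
    "spawn_particles",
    "simulate_tracks",
]

AVOGADRO = 6.02214076e23
#: particles per um^3 for a 1 pM solution
PM_TO_PER_UM3 = 1e-12 * AVOGADRO / 1e15


@dataclass(frozen=True)
class DiffusionConfig:
    """Parameters of the Brownian-dynamics / confocal-volume simulation.

    Parameters
    ----------
    D
        Diffusion coefficient in um^2/s (50 corresponds to a medium-sized
        protein).
    dt
        Integration time step in us.
    R
        Radius of the simulation sphere in um.
    T_new
        Replenishment period in us; must be a positive integer multiple
        of ``dt``.
    c0
        Bulk concentration in pM.
    duration
        Total simulated time in seconds.
    seed
        Master seed; every particle receives an independent substream.
    w0
        1/e^2 waist of the Gaussian excitation profile in um.
    lambda_tot
        Maximum total detected photon rate at the centre of the spot in MHz
        (numerically equal to photons/us).
    """

    D: float = 50.0
    dt: float = 1.0
    R: float = 3.0
    T_new: float = 1000.0
    c0: float = 50.0
    duration: float = 1.0
    seed: int = 0
    w0: float = 0.4
    lambda_tot: float = 0.4

    def __post_init__(self) -> None:
        if not (self.D > 0 and self.dt > 0):
            raise ValueError("D and dt must be positive")
        if not self.R > self.w0:
            raise ValueError("simulation sphere must enclose the beam waist (R > w0)")
        ratio = self.T_new / self.dt
        if not (self.T_new > 0 and abs(ratio - round(ratio)) < 1e-9):
            raise ValueError("T_new must be a positive integer multiple of dt")
        if self.c0 < 0:
            raise ValueError("c0 must be nonnegative")

    @property
    def D_um2_per_us(self) -> float:
        return self.D * 1e-6

    @property
    def c0_per_um3(self) -> float:
        return self.c0 * PM_TO_PER_UM3

    @property
    def mean_initial_count(self) -> float:
        """n0 = (4/3) pi R^3 c0, the bulk-equilibrium particle number."""
        return 4.0 / 3.0 * math.pi * self.R**3 * self.c0_per_um3

    @property
    def n_steps(self) -> int:
        return int(round(self.duration * 1e6 / self.dt))


@dataclass
class ParticleTrack:
    """Radial trajectory of one particle from birth until it exits the sphere."""

    particle_id: int
    birth_time: float  # us
    radii: np.ndarray = field(repr=False)  # um, one sample per dt step

    def __len__(self) -> int:
        return self.radii.size


def step_radial(r: float, cfg: DiffusionConfig, noise: float) -> float:
    """One radial Euler step; negative excursions are reflected at the origin.

    The drift term 2 D dt / r is the spurious-drift correction that makes the
    1-D radial walk equivalent to isotropic 3-D diffusion.
    """
    if not (np.isfinite(r) and np.isfinite(noise)):
        raise ValueError("r and noise must be finite")
    if r <= 0:
        raise ValueError("r must be positive")
    D = cfg.D_um2_per_us
    r_next = r + 2.0 * D * cfg.dt / r + noise * math.sqrt(2.0 * D * cfg.dt)
    return abs(r_next)


def intensity(r, w0: float):
    """Relative Gaussian excitation intensity exp(-2 r^2 / w0^2)."""
    r = np.asarray(r, dtype=float)
    out = np.exp(-2.0 * r**2 / w0**2)
    return out if out.ndim else float(out)


def replenishment_density(
    r, cfg: DiffusionConfig, tol: float = 1e-12, n_max: int = 10_000
):
    """Relative concentration c(r, T_new)/c0 of the refilling sphere.

    Fourier series solution of the radial diffusion equation with an empty
    initial sphere and fixed boundary concentration.  The series is truncated
    once the envelope of the remaining terms falls below ``tol`` (the
    exponential factor decays like exp(-D n^2 pi^2 t / R^2)).
    """
    r = np.atleast_1d(np.asarray(r, dtype=float))
    if np.any(r < 0) or np.any(r > cfg.R):
        raise ValueError("r must lie in [0, R]")
    D = cfg.D_um2_per_us
    t = cfg.T_new
    R = cfg.R
    decay = D * math.pi**2 * t / R**2
    out = np.ones_like(r)
    inner = r > 0
    ri = r[inner]
    acc = np.zeros_like(ri)
    for n in range(1, n_max + 1):
        damp = math.exp(-decay * n * n)
        if damp / n < tol:
            break
        acc += ((-1) ** n / n) * np.sin(n * math.pi * ri / R) * damp
    out[inner] = 1.0 + (2.0 * R / math.pi) / ri * acc
    out[~inner] = 0.0  # absorbing r->0 limit of the boundary-value problem
    np.clip(out, 0.0, None, out=out)
    if out.size == 1:
        return float(out[0])
    return out


def mean_replenished_count(cfg: DiffusionConfig) -> float:
    """Mean number of particles entering the sphere per replenishment period.

    Closed form of the volume integral of the truncated Fourier series:
    n_new = c0 [ (4/3) pi R^3 - (8 R^3 / pi) sum_n exp(-D n^2 pi^2 T/R^2)/n^2 ].
    """
    D = cfg.D_um2_per_us
    decay = D * math.pi**2 * cfg.T_new / cfg.R**2
    s = 0.0
    for n in range(1, 10_000 + 1):
        term = math.exp(-decay * n * n) / (n * n)
        s += term
        if term < 1e-15:
            break
    vol = 4.0 / 3.0 * math.pi * cfg.R**3
    return cfg.c0_per_um3 * (vol - 8.0 * cfg.R**3 / math.pi * s)


def _replenishment_cdf(cfg: DiffusionConfig, table_size: int = 4096):
    """Tabulated inverse-CDF support for P_new(r) = 4 pi r^2 c_new(r)/n_new."""
    grid = np.linspace(0.0, cfg.R, table_size)
    pdf = 4.0 * math.pi * grid**2 * replenishment_density(grid, cfg)
    cdf = np.concatenate([[0.0], np.cumsum((pdf[1:] + pdf[:-1]) / 2.0 * np.diff(grid))])
    cdf /= cdf[-1]
    return cdf, grid


def sample_replenishment_radii(
    cfg: DiffusionConfig,
    n: int,
    rng: np.random.Generator,
    table_size: int = 4096,
    _table=None,
) -> np.ndarray:
    """Draw ``n`` radii from P_new(r) = 4 pi r^2 c_new(r) / n_new by inverse CDF.

    The cumulative integral is tabulated on ``table_size`` points; P_new has no
    closed-form inverse.
    """
    if n == 0:
        return np.empty(0)
    cdf, grid = _table if _table is not None else _replenishment_cdf(cfg, table_size)
    u = rng.random(n)
    return np.interp(u, cdf, grid)


def spawn_particles(cfg: DiffusionConfig, rng: np.random.Generator) -> np.ndarray:
    """Initial radii at t=0: Poisson(n0) particles uniform by volume (r^2 law)."""
    count = rng.poisson(cfg.mean_initial_count)
    return cfg.R * rng.random(count) ** (1.0 / 3.0)


def simulate_tracks(cfg: DiffusionConfig) -> Iterator[ParticleTrack]:
    """Generate all particle tracks of one run, in birth order.

    Particles present at t=0 are placed uniformly by volume; at every multiple
    of T_new a Poisson(n_new) batch is inserted with radii from P_new.  Each
    particle is integrated with its own counter-based substream spawned from
    the master seed, so the track of a given particle does not depend on how
    many others exist.
    """
    master = np.random.SeedSequence(cfg.seed)
    spawn_ss, *_ = master.spawn(1)
    spawn_rng = np.random.default_rng(spawn_ss)
    n_new = mean_replenished_count(cfg)
    steps_per_period = int(round(cfg.T_new / cfg.dt))
    total_steps = cfg.n_steps

    D = cfg.D_um2_per_us
    pid = 0

    def _launch(r0: float, birth_step: int) -> ParticleTrack:
        nonlocal pid
        seed = int(master.spawn(1)[0].generate_state(1, np.uint64)[0] % (2**63 - 1))
        radii = simulate_radial_track(
            r0, D, cfg.dt, cfg.R, total_steps - birth_step, seed
        )
        track = ParticleTrack(pid, birth_step * cfg.dt, radii)
        pid += 1
        return track

    for r0 in spawn_particles(cfg, spawn_rng):
        yield _launch(float(r0), 0)

    table = _replenishment_cdf(cfg)
    step = steps_per_period
    while step < total_steps:
        count = spawn_rng.poisson(n_new)
        for r0 in sample_replenishment_radii(cfg, count, spawn_rng, _table=table):
            yield _launch(float(r0), step)
        step += steps_per_period
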