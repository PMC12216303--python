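"""Photon-by-photon maximum likelihood for kinetic models, BIC and recoloring.

The likelihood of a burst with photon colours c_1..c_N and inter-photon times
tau_2..tau_N under an n-state kinetic model with generator K and diagonal
detection matrices V_A, V_D (total rate matrix N = V_A + V_D) is

    L_i = ln( 1^T [ prod_{j=N..2} F(c_j) e^{(K - N) tau_j} ] F(c_1) p_eq )

with F(A) = V_A, F(D) = V_D.  The propagated vector is renormalised after
every photon (log-accumulation), so products over hundreds of photons do not
underflow.  Fits maximise the summed log-likelihood over all bursts; the
Bayesian information criterion BIC = R ln T - 2 L scores model complexity,
with T the total number of photons (the information-bearing length of the
data).

Recoloring is the goodness-of-fit surrogate: conformational state paths are
redrawn from the fitted chain on the *original* photon timestamps and new
colours drawn from the per-state efficiencies; model misfit shows up as a
systematic difference between the data's and the recolored ensemble's FRET
correlation functions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from . import _kernels
from .bursts import Burst
from .kinetics import KineticModel, two_state_model
from .photons import SLOT_DEX, PhotonStream
from .theory import DetectionMatrices

__all__ = [
    "PhotonData",
    "extract_photon_data",
    "burst_log_likelihood",
    "total_log_likelihood",
    "LikelihoodFit",
    "maximize_likelihood",
    "bic",
    "recolor",
]


@dataclass
class PhotonData:
    """Concatenated burst photon records for likelihood evaluation.

    tau: gap to the previous photon within the burst (0 for the first photon);
    channels: 0 donor / 1 acceptor; is_first: 1 at burst starts;
    stream_idx: position of each photon in the parent stream (for recoloring).
    """

    tau: np.ndarray
    channels: np.ndarray
    is_first: np.ndarray
    stream_idx: np.ndarray
    n_bursts: int

    @property
    def n_photons(self) -> int:
        return self.tau.size


def extract_photon_data(stream: PhotonStream, bursts: list[Burst]) -> PhotonData:
    """Collect the Dex-slot photons of the selected bursts."""
    taus, chans, firsts, idxs = [], [], [], []
    for b in bursts:
        sl = np.arange(b.first, b.last + 1)
        mask = stream.slots[sl] == SLOT_DEX
        idx = sl[mask]
        if idx.size == 0:
            continue
        t = stream.times[idx]
        tau = np.empty(idx.size)
        tau[0] = 0.0
        tau[1:] = np.diff(t)
        f = np.zeros(idx.size, np.uint8)
        f[0] = 1
        taus.append(tau)
        chans.append(stream.channels[idx])
        firsts.append(f)
        idxs.append(idx)
    if not taus:
        raise ValueError("no burst photons to analyse")
    return PhotonData(
        tau=np.concatenate(taus),
        channels=np.concatenate(chans).astype(np.int8),
        is_first=np.concatenate(firsts),
        stream_idx=np.concatenate(idxs),
        n_bursts=len(taus),
    )


def burst_log_likelihood(
    tau: np.ndarray,
    channels: np.ndarray,
    model: KineticModel,
    V: DetectionMatrices,
) -> float:
    """Log-likelihood of a single burst under an arbitrary kinetic model.

    General n-state path via the eigendecomposition of K - N; the fast
    fitting path for two-state models lives in the numba kernel.
    """
    K = model.K
    N = np.diag(V.total_rates)
    M = K - N
    w, U = np.linalg.eig(M)
    Uinv = np.linalg.inv(U)
    F = {0: V.V_D, 1: V.V_A}
    v = F[int(channels[0])] @ model.p_eq
    s = v.sum()
    if not s > 0:
        return -np.inf
    logl = np.log(s)
    v = v / s
    for j in range(1, tau.size):
        P = np.real(U @ (np.exp(w * tau[j])[:, None] * Uinv))
        v = F[int(channels[j])] @ (P @ v)
        s = v.sum()
        if not (np.isfinite(s) and s > 0):
            raise FloatingPointError(f"non-finite likelihood at photon {j}")
        logl += np.log(s)
        v = v / s
    return float(logl)


def total_log_likelihood(
    data: PhotonData, k12: float, k21: float, e1: float, e2: float, n: float
) -> float:
    """Summed two-state log-likelihood over all bursts (numba fast path)."""
    return float(
        _kernels.loglik_two_state(
            data.tau, data.channels, data.is_first, k12, k21, e1, e2, n
        )
    )


@dataclass
class LikelihoodFit:
    """Result of a photon-by-photon ML fit."""

    params: dict
    log_likelihood: float
    bic: float
    n_photons: int
    n_bursts: int
    converged: bool
    model: KineticModel = field(repr=False, default=None)
    restarts: list = field(default_factory=list, repr=False)


def bic(log_likelihood: float, R: int, T: int) -> float:
    """BIC = R ln T - 2 L; lower is better, larger L lowers it."""
    if T <= 1:
        raise ValueError("T must exceed 1")
    return R * np.log(T) - 2.0 * log_likelihood


def _unpack(theta, symmetric):
    if symmetric:
        lk, le1, le2, ln = theta
        k12 = k21 = np.exp(lk)
    else:
        lk12, lk21, le1, le2, ln = theta
        k12, k21 = np.exp(lk12), np.exp(lk21)
    e1 = 1.0 / (1.0 + np.exp(-le1))
    e2 = 1.0 / (1.0 + np.exp(-le2))
    return k12, k21, e1, e2, np.exp(theta[-1])


def maximize_likelihood(
    data: PhotonData,
    symmetric: bool = True,
    n_restarts: int = 5,
    seed: int = 0,
    k_bounds: tuple[float, float] = (1e-6, 1.0),
) -> LikelihoodFit:
    """Two-state ML fit of (k, eps1, eps2, n) by bounded quasi-Newton.

    Rates and the total photon rate are optimised in log space, efficiencies
    through a logistic transform; ``n_restarts`` seeded random starts guard
    against the multimodality of short-burst likelihoods.  Reported rates are
    ordered so eps1 < eps2.
    """
    rng = np.random.default_rng(seed)
    mean_rate = 1.0 / max(np.mean(data.tau[data.is_first == 0]), 1e-9)

    def negloglik(theta):
        k12, k21, e1, e2, n = _unpack(theta, symmetric)
        val = _kernels.loglik_two_state(
            data.tau, data.channels, data.is_first, k12, k21, e1, e2, n
        )
        return -val if np.isfinite(val) else 1e300

    lo, hi = np.log(k_bounds[0]), np.log(k_bounds[1])
    best = None
    attempts = []
    for trial in range(n_restarts):
        if trial == 0:
            k0 = np.log(1e-3)
            e10, e20 = -1.5, 1.5
            n0 = np.log(mean_rate)
        else:
            k0 = rng.uniform(lo, hi)
            e10, e20 = np.sort(rng.normal(0.0, 2.0, 2))
            n0 = np.log(mean_rate) + rng.normal(0.0, 0.3)
        theta0 = [k0, e10, e20, n0] if symmetric else [k0, k0, e10, e20, n0]
        bounds = ([(lo, hi)] if symmetric else [(lo, hi)] * 2) + [
            (-8.0, 8.0),
            (-8.0, 8.0),
            (n0 - 3.0, n0 + 3.0),
        ]
        res = minimize(negloglik, theta0, method="L-BFGS-B", bounds=bounds)
        attempts.append(res)
        if best is None or res.fun < best.fun:
            best = res
    k12, k21, e1, e2, n = _unpack(best.x, symmetric)
    if e1 > e2:  # label-swap symmetry
        e1, e2 = e2, e1
        k12, k21 = k21, k12
    logl = -best.fun
    R = len(best.x)
    fitted = two_state_model(k12, k21, eps=(e1, e2), lambda_tot=n)
    return LikelihoodFit(
        params={"k12": k12, "k21": k21, "eps1": e1, "eps2": e2, "n": n},
        log_likelihood=logl,
        bic=bic(logl, R, data.n_photons),
        n_photons=data.n_photons,
        n_bursts=data.n_bursts,
        converged=bool(best.success),
        model=fitted,
        restarts=[(-a.fun, a.success) for a in attempts],
    )


def _recolor_general(data: PhotonData, model: KineticModel, rng) -> np.ndarray:
    """Unconditional Markov recoloring for arbitrary state counts (numpy path)."""
    K = model.K
    w, U = np.linalg.eig(K)
    Uinv = np.linalg.inv(U)
    # per-photon transition matrices T[j, i] = P(state j | previous state i)
    P = np.real(np.einsum("sk,tk,kj->tsj", U, np.exp(np.multiply.outer(data.tau, w)), Uinv))
    P = np.clip(P, 0.0, None)
    P /= P.sum(axis=1, keepdims=True)
    colors = np.empty(data.n_photons, np.int8)
    u_state = rng.random(data.n_photons)
    u_color = rng.random(data.n_photons)
    s = 0
    for j in range(data.n_photons):
        probs = model.p_eq if data.is_first[j] else P[j, :, s]
        s = int(np.searchsorted(np.cumsum(probs), u_state[j]))
        s = min(s, model.n_states - 1)
        colors[j] = 1 if u_color[j] < model.eps[s] else 0
    return colors


def recolor(
    stream: PhotonStream,
    bursts: list[Burst],
    model: KineticModel,
    n_realizations: int = 10,
    seed: int = 0,
) -> list[PhotonStream]:
    """Redraw burst photon colours from a kinetic model, timestamps untouched.

    A state trajectory of the chain is simulated at the recorded photon
    detection times of every burst, and each photon's colour is drawn with
    probability eps(state) for the acceptor.  Returns ``n_realizations``
    streams; photons outside the selected bursts keep their original colour.
    """
    data = extract_photon_data(stream, bursts)
    two_state = model.n_states == 2
    out = []
    master = np.random.SeedSequence((seed, 0xC0105))
    for ss in master.spawn(n_realizations):
        if two_state:
            colors = _kernels.recolor_two_state(
                data.tau,
                data.is_first,
                model.K[1, 0],
                model.K[0, 1],
                model.eps[0],
                model.eps[1],
                int(ss.generate_state(1, np.uint64)[0] % (2**31 - 1)),
            )
        else:
            colors = _recolor_general(data, model, np.random.default_rng(ss))
        channels = stream.channels.copy()
        channels[data.stream_idx] = colors
        out.append(
            PhotonStream(
                stream.times.copy(),
                channels,
                stream.detectors.copy(),
                stream.slots.copy(),
                None if stream.nanotimes is None else stream.nanotimes.copy(),
                dict(stream.meta),
            )
        )
    return out
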