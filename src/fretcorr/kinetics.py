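"""Kinetic and instrument models for the photon emission engine.

A :class:`KineticModel` is a continuous-time Markov chain over conformational
(or photophysical) states.  Each state carries a true FRET efficiency eps_i
and acceptor/donor brightnesses (a_i, d_i) in photons/us at the beam centre.
Rate matrices follow the column convention dp/dt = K p (columns sum to zero,
off-diagonals nonnegative, K[j, s] is the rate from s to j).

:class:`BleachModel` adds an intensity-scaled part, K(r) = K0 + I(r) K1, used
for photobleaching and for the coarse-grained triplet scheme whose S->T
transitions are proportional to the excitation rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "KineticModel",
    "InstrumentModel",
    "PIEConfig",
    "BleachModel",
    "CGPhotophysicsModel",
    "two_state_model",
    "four_state_chain_model",
    "static_mixture_model",
    "build_bleach_matrices",
    "stationary_distribution",
]


def _check_generator(K: np.ndarray, atol: float = 1e-10) -> None:
    K = np.asarray(K, float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValueError("rate matrix must be square")
    off = K - np.diag(np.diag(K))
    if np.any(off < -atol):
        raise ValueError("off-diagonal rates must be nonnegative")
    col = K.sum(axis=0)
    if np.any(np.abs(col) > atol * max(1.0, np.abs(K).max())):
        raise ValueError("columns of a generator must sum to zero")


def stationary_distribution(K: np.ndarray) -> np.ndarray:
    """Equilibrium distribution p_eq with K p_eq = 0 (unique for an ergodic chain).

    For reducible chains (absorbing states, k=0 mixtures) the null space can
    be degenerate; the returned vector is the nonnegative normalised null
    vector closest to uniform over the null space.
    """
    K = np.asarray(K, float)
    w, v = np.linalg.eig(K)
    null = np.abs(w) < 1e-10 * max(1.0, np.abs(K).max())
    if not null.any():
        raise ValueError("rate matrix has no stationary distribution")
    basis = np.real(v[:, null])
    # project the uniform distribution onto the null space, then normalise
    coef, *_ = np.linalg.lstsq(basis, np.full(K.shape[0], 1.0 / K.shape[0]), rcond=None)
    p = basis @ coef
    p = np.clip(np.real(p), 0.0, None)
    if p.sum() <= 0:
        p = np.clip(np.real(basis[:, 0]), 0.0, None)
    return p / p.sum()


@dataclass
class KineticModel:
    """States, rate matrix, per-state FRET efficiencies and brightnesses.

    ``acceptor_present`` / ``donor_present`` mark photobleached species:
    a state without an acceptor emits no direct-excitation and no Aex
    photons; a state without a donor emits no donor-excited photons except
    direct acceptor excitation.
    """

    states: Sequence[str]
    K: np.ndarray
    eps: np.ndarray
    a: np.ndarray
    d: np.ndarray
    p0: np.ndarray | None = None
    acceptor_present: np.ndarray | None = None
    donor_present: np.ndarray | None = None
    p_eq: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.K = np.asarray(self.K, float)
        self.eps = np.asarray(self.eps, float)
        self.a = np.asarray(self.a, float)
        self.d = np.asarray(self.d, float)
        _check_generator(self.K)
        n = len(self.states)
        for name in ("eps", "a", "d"):
            arr = getattr(self, name)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have one entry per state")
        if np.any((self.eps < 0) | (self.eps > 1)):
            raise ValueError("eps must lie in [0, 1]")
        if np.any(self.a < 0) or np.any(self.d < 0):
            raise ValueError("brightnesses must be nonnegative")
        self.p_eq = stationary_distribution(self.K)
        if self.p0 is None:
            self.p0 = self.p_eq.copy()
        else:
            self.p0 = np.asarray(self.p0, float)
            if abs(self.p0.sum() - 1.0) > 1e-9 or np.any(self.p0 < 0):
                raise ValueError("p0 must be a probability vector")
        ones = np.ones(n, dtype=bool)
        if self.acceptor_present is None:
            self.acceptor_present = ones.copy()
        if self.donor_present is None:
            self.donor_present = ones.copy()
        self.acceptor_present = np.asarray(self.acceptor_present, bool)
        self.donor_present = np.asarray(self.donor_present, bool)

    @property
    def n_states(self) -> int:
        return len(self.states)

    def center_rates(self, alpha: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
        """Per-state (acceptor, donor) photon rates at the beam centre, Dex slot.

        Acceptor: FRET emission a_i eps_i (needs donor and acceptor intact)
        plus direct excitation alpha a_i (needs acceptor intact).  Donor:
        d_i (1 - eps_i) when the donor is intact.
        """
        both = self.acceptor_present & self.donor_present
        rate_a = np.where(both, self.a * self.eps, 0.0)
        rate_a = rate_a + alpha * np.where(self.acceptor_present, self.a, 0.0)
        rate_d = np.where(self.donor_present, self.d * (1.0 - np.where(both, self.eps, 0.0)), 0.0)
        return rate_a, rate_d


@dataclass(frozen=True)
class PIEConfig:
    """Pulsed interleaved excitation: alternating donor/acceptor pulses."""

    period_ns: float = 50.0
    donor_offset_ns: float = 0.0
    acceptor_offset_ns: float = 25.0
    gamma_pie: float = 2.0


@dataclass(frozen=True)
class InstrumentModel:
    """Detection imperfections of the confocal microscope.

    gamma is the acceptor/donor brightness-detection correction
    Q_A xi_A / (Q_D xi_D); beta_DA / beta_AD are spectral crosstalk
    probabilities; alpha the acceptor direct-excitation probability;
    backgrounds in kHz.
    """

    gamma: float = 1.15
    beta_DA: float = 0.05
    beta_AD: float = 0.003
    alpha: float = 0.048
    bg_D: float = 2.0
    bg_A: float = 1.0
    pie: PIEConfig | None = None
    irf_sigma_ns: float = 0.0
    n_detectors_per_channel: int = 1

    def __post_init__(self) -> None:
        for p in (self.beta_DA, self.beta_AD, self.alpha):
            if not 0.0 <= p < 1.0:
                raise ValueError("probabilities must lie in [0, 1)")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.bg_D < 0 or self.bg_A < 0:
            raise ValueError("backgrounds must be nonnegative")

    @classmethod
    def ideal(cls, pie: PIEConfig | None = None) -> "InstrumentModel":
        """No background, no crosstalk, no direct excitation, gamma = 1."""
        return cls(gamma=1.0, beta_DA=0.0, beta_AD=0.0, alpha=0.0,
                   bg_D=0.0, bg_A=0.0, pie=pie)


@dataclass
class BleachModel:
    """Intensity-dependent generator K(r) = K0 + I(r) K1."""

    K0: np.ndarray
    K1: np.ndarray

    def __post_init__(self) -> None:
        self.K0 = np.asarray(self.K0, float)
        self.K1 = np.asarray(self.K1, float)
        for I in (0.0, 0.5, 1.0):
            _check_generator(self.K0 + I * self.K1)

    def at_intensity(self, I: float) -> np.ndarray:
        return self.K0 + I * self.K1


def _scaled_brightness(eps, p_ref, gamma, lambda_tot):
    """Brightness pair (a, d) with a/d = gamma, population-weighted total rate
    lambda_tot at the beam centre."""
    eps = np.asarray(eps, float)
    mean_eps = float(np.dot(p_ref, eps))
    d = lambda_tot / (gamma * mean_eps + (1.0 - mean_eps))
    return gamma * d, d


def two_state_model(
    k12: float,
    k21: float | None = None,
    eps: tuple[float, float] = (0.1, 0.9),
    lambda_tot: float = 0.4,
    gamma: float = 1.0,
    p0: Sequence[float] | None = None,
) -> KineticModel:
    """Two-state exchange with rates k12 (1->2) and k21 (defaults symmetric).

    Brightnesses satisfy a/d = gamma and are scaled so the equilibrium-averaged
    total detected rate at the beam centre is lambda_tot (photons/us).
    """
    if k21 is None:
        k21 = k12
    K = np.array([[-k12, k21], [k12, -k21]])
    tot = k12 + k21
    p_eq = np.array([k21, k12]) / tot if tot > 0 else np.array([0.5, 0.5])
    a, d = _scaled_brightness(eps, p_eq, gamma, lambda_tot)
    return KineticModel(
        states=("low", "high"),
        K=K,
        eps=np.asarray(eps, float),
        a=np.full(2, a),
        d=np.full(2, d),
        p0=None if p0 is None else np.asarray(p0, float),
    )


def static_mixture_model(
    eps: tuple[float, float] = (0.1, 0.9),
    populations: tuple[float, float] = (0.5, 0.5),
    lambda_tot: float = 0.4,
    gamma: float = 1.0,
) -> KineticModel:
    """Non-interconverting two-species mixture (k = 0): static heterogeneity."""
    p0 = np.asarray(populations, float)
    p0 = p0 / p0.sum()
    a, d = _scaled_brightness(eps, p0, gamma, lambda_tot)
    return KineticModel(
        states=("low", "high"),
        K=np.zeros((2, 2)),
        eps=np.asarray(eps, float),
        a=np.full(2, a),
        d=np.full(2, d),
        p0=p0,
    )


def four_state_chain_model(
    k: float,
    eps: tuple[float, float] = (0.2, 0.8),
    lambda_tot: float = 0.4,
) -> KineticModel:
    """Linear 4-state chain 1' <-> 1 <-> 2 <-> 2' with all rates k.

    States 1', 1 share eps[0] and 2, 2' share eps[1]: on the FRET coordinate
    the chain is a hidden (non-Markov) two-state system.
    """
    K = k * np.array(
        [
            [-1.0, 1.0, 0.0, 0.0],
            [1.0, -2.0, 1.0, 0.0],
            [0.0, 1.0, -2.0, 1.0],
            [0.0, 0.0, 1.0, -1.0],
        ]
    )
    e = np.array([eps[0], eps[0], eps[1], eps[1]])
    p_eq = np.full(4, 0.25)
    a, d = _scaled_brightness(e, p_eq, 1.0, lambda_tot)
    return KineticModel(
        states=("1p", "1", "2", "2p"),
        K=K,
        eps=e,
        a=np.full(4, a),
        d=np.full(4, d),
    )


def build_bleach_matrices(
    k: float,
    eps: tuple[float, float],
    k_A: float,
    k_D: float,
    lambda_tot: float = 0.4,
    gamma: float = 1.0,
    p0: Sequence[float] = (0.1, 0.4, 0.4, 0.1),
) -> tuple[KineticModel, BleachModel]:
    """Four-state photobleaching scheme {D, DA1, DA2, A}.

    K0 holds the conformational exchange DA1 <-> DA2 at rate k; K1 the
    intensity-proportional bleaching: the acceptor bleaches from state i at
    k_A eps_i (DA_i -> D) and the donor at k_D (1 - eps_i) (DA_i -> A),
    reflecting that bleaching happens out of the excited state that the FRET
    efficiency populates.
    """
    if min(k, k_A, k_D) < 0:
        raise ValueError("rates must be nonnegative")
    e1, e2 = eps
    eh1, eh2 = 1.0 - e1, 1.0 - e2
    K0 = np.array(
        [
            [0.0, 0.0, 0.0, 0.0],
            [0.0, -k, k, 0.0],
            [0.0, k, -k, 0.0],
            [0.0, 0.0, 0.0, 0.0],
        ]
    )
    K1 = np.array(
        [
            [0.0, k_A * e1, k_A * e2, 0.0],
            [0.0, -k_A * e1 - k_D * eh1, 0.0, 0.0],
            [0.0, 0.0, -k_A * e2 - k_D * eh2, 0.0],
            [0.0, k_D * eh1, k_D * eh2, 0.0],
        ]
    )
    p_ref = np.array([0.0, 0.5, 0.5, 0.0])
    e = np.array([0.0, e1, e2, 1.0])
    a, d = _scaled_brightness(np.array([e1, e2]), np.array([0.5, 0.5]), gamma, lambda_tot)
    model = KineticModel(
        states=("D", "DA1", "DA2", "A"),
        K=K0,  # conformational part; the bleach part is applied via BleachModel
        eps=e,
        a=np.full(4, a),
        d=np.full(4, d),
        p0=np.asarray(p0, float),
        acceptor_present=np.array([False, True, True, True]),
        donor_present=np.array([True, True, True, False]),
    )
    # stationary distribution of K0 restricted to the DA states
    model.p_eq = p_ref
    return model, BleachModel(K0=K0, K1=K1)


@dataclass
class CGPhotophysicsModel:
    """Coarse-grained triplet photophysics: states {SS, TS, ST, TT}.

    Singlet-manifold radiative dynamics (nanoseconds) are folded into
    per-state emission rates, linear in the excitation rate k_ex; the TT state
    is dark.  S->T transition rates grow linearly with k_ex while T->S rates
    are k_ex-independent.  The rate constants are configuration inputs; the
    bundled defaults (see :func:`fretcorr.fixtures.illustrative_cg_model`) are
    illustrative values for a green/red dye pair, not a fitted photophysical
    characterisation.
    """

    emission_a_max: np.ndarray  # acceptor rate per state at k_ex_max (1/us)
    emission_d_max: np.ndarray
    st_rates_max: np.ndarray  # (4,4) generator part linear in k_ex, at k_ex_max
    ts_rates: np.ndarray  # (4,4) constant generator part
    k_ex_max: float = 0.08  # 1/ns at the beam centre

    states = ("SS", "TS", "ST", "TT")

    def __post_init__(self) -> None:
        self.emission_a_max = np.asarray(self.emission_a_max, float)
        self.emission_d_max = np.asarray(self.emission_d_max, float)
        self.st_rates_max = np.asarray(self.st_rates_max, float)
        self.ts_rates = np.asarray(self.ts_rates, float)
        if self.emission_a_max[3] != 0.0 or self.emission_d_max[3] != 0.0:
            raise ValueError("the TT state must be dark")
        _check_generator(self.ts_rates + self.st_rates_max)
        _check_generator(self.ts_rates)
        if np.any(self.emission_a_max < 0) or np.any(self.emission_d_max < 0):
            raise ValueError("emission rates must be nonnegative")

    def rates_at(self, k_ex: float, clamp_warning: bool = True):
        """Emission and transition rates at excitation rate k_ex (1/ns)."""
        import warnings

        if k_ex < 0.0 or k_ex > self.k_ex_max:
            if clamp_warning:
                warnings.warn(
                    f"k_ex={k_ex} outside [0, {self.k_ex_max}]; clamping",
                    RuntimeWarning,
                    stacklevel=2,
                )
            k_ex = min(max(k_ex, 0.0), self.k_ex_max)
        frac = k_ex / self.k_ex_max
        em_a = frac * self.emission_a_max
        em_d = frac * self.emission_d_max
        K = self.ts_rates + frac * self.st_rates_max
        return em_a, em_d, K

    def as_bleach_model(self) -> BleachModel:
        """Express the CG scheme as K(r) = K0 + I(r) K1 for the simulator.

        I(r) plays the role of k_ex(r)/k_ex_max, which is exact because the
        excitation rate follows the Gaussian beam profile.
        """
        return BleachModel(K0=self.ts_rates, K1=self.st_rates_max)

    def as_kinetic_model(self) -> KineticModel:
        """KineticModel view: emission rates at the centre, eps per CG state.

        The per-state "efficiency" is the acceptor fraction of the emission at
        full excitation; brightness arrays carry the actual rates so the
        emission engine reproduces the CG rates exactly.
        """
        tot = self.emission_a_max + self.emission_d_max
        eps = np.where(tot > 0, self.emission_a_max / np.where(tot > 0, tot, 1.0), 0.0)
        # encode a_i eps_i = emission_a and d_i (1-eps_i) = emission_d
        a = np.where(eps > 0, self.emission_a_max / np.where(eps > 0, eps, 1.0), 0.0)
        d = np.where(eps < 1, self.emission_d_max / np.where(eps < 1, 1.0 - eps, 1.0), 0.0)
        return KineticModel(
            states=self.states,
            K=self.ts_rates + self.st_rates_max,
            eps=eps,
            a=a,
            d=d,
            p0=np.array([1.0, 0.0, 0.0, 0.0]),
        )
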