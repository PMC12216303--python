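"""Analytic FRET correlation functions and small closed-form results.

For an n-state Markov chain with generator K (dp/dt = K p), diagonal
efficiency matrix eps and equilibrium p_eq, the ideal (uniform-brightness)
FRET correlation function is

    g_eps(tau) = 1^T eps e^{K tau} eps p_eq - (1^T eps p_eq)^2

With per-state detection matrices V_A, V_D (brightness, efficiency and
background) the measured pair correlations are
g_XY(tau) = 1^T V_X e^{K tau} V_Y p_eq, and the measured g_E follows by
feeding the ratios g_XY/g into the same combination as the photon-pair
estimator.  For two-state models without background this reduces to closed
forms relating g_E to g_eps through the brightness contrast, which is what
makes relaxation times read off g_E robust to imperfect gamma.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .kinetics import KineticModel

__all__ = [
    "DetectionMatrices",
    "detection_matrices",
    "analytic_gE_ideal",
    "pair_correlation",
    "mean_E_analytic",
    "analytic_gE_nonideal",
    "gE_two_state_uniform_brightness",
    "gE_two_state_state_brightness",
    "zwanzig_error",
    "multi_molecule_fraction",
    "detectable_delta_E",
    "nsfcs_intensity_model",
    "nsfcs_fret_model",
]


@dataclass
class DetectionMatrices:
    """Diagonal per-state photon-rate matrices for acceptor and donor.

    V_A = A eps + A_b and V_D = D (I - eps) + D_b, where A, D hold per-state
    brightnesses, eps the true efficiencies and A_b, D_b uniform background
    rates.  In the ideal case this reduces to V_A = n diag(eps_i),
    V_D = n diag(1 - eps_i).
    """

    V_A: np.ndarray
    V_D: np.ndarray

    def __post_init__(self) -> None:
        self.V_A = np.asarray(self.V_A, float)
        self.V_D = np.asarray(self.V_D, float)
        for V in (self.V_A, self.V_D):
            if not np.allclose(V, np.diag(np.diag(V))):
                raise ValueError("detection matrices must be diagonal")
            if np.any(np.diag(V) < 0):
                raise ValueError("detection rates must be nonnegative")

    @property
    def total_rates(self) -> np.ndarray:
        return np.diag(self.V_A) + np.diag(self.V_D)


def detection_matrices(
    eps: np.ndarray,
    a: np.ndarray,
    d: np.ndarray,
    bg_A: float = 0.0,
    bg_D: float = 0.0,
) -> DetectionMatrices:
    """Build V_A, V_D from brightness/efficiency vectors and backgrounds."""
    eps = np.asarray(eps, float)
    return DetectionMatrices(
        V_A=np.diag(np.asarray(a, float) * eps + bg_A),
        V_D=np.diag(np.asarray(d, float) * (1.0 - eps) + bg_D),
    )


def analytic_gE_ideal(model: KineticModel):
    """Ideal-condition FRET correlation function tau -> g_eps(tau).

    Exact only for uniform brightness (a_i = d_i for all states); vectorised
    over tau via the eigendecomposition of K.
    """
    K = model.K
    eps = model.eps
    p_eq = model.p_eq
    w, V = np.linalg.eig(K)
    Vinv = np.linalg.inv(V)
    mean = float(eps @ p_eq)
    # 1^T eps e^{Kt} eps p_eq = sum_m c_m e^{w_m t}
    left = eps @ V  # row of 1^T diag(eps) V
    right = Vinv @ (eps * p_eq)
    coef = left * right

    def g(tau):
        tau = np.asarray(tau, float)
        val = np.real(np.exp(np.multiply.outer(tau, w)) @ coef) - mean**2
        return float(val) if val.ndim == 0 else val

    return g


def pair_correlation(model: KineticModel, V: DetectionMatrices, which: str):
    """Analytic pair-rate correlation for ordered pair type ``which``.

    ``which`` names (earlier, later) photon types, matching the estimator's
    pair convention: "AD" means acceptor first, donor a lag tau later, i.e.
    1^T V_D e^{K tau} V_A p_eq.  "NN" uses V_A + V_D on both sides.
    """
    sel = {"A": V.V_A, "D": V.V_D, "N": V.V_A + V.V_D}
    VX, VY = sel[which[1]], sel[which[0]]  # later photon acts last (leftmost)
    K = model.K
    p_eq = model.p_eq
    w, U = np.linalg.eig(K)
    Uinv = np.linalg.inv(U)
    left = np.ones(model.n_states) @ VX @ U
    right = Uinv @ (VY @ p_eq)
    coef = left * right

    def g(tau):
        tau = np.asarray(tau, float)
        val = np.real(np.exp(np.multiply.outer(tau, w)) @ coef)
        return float(val) if val.ndim == 0 else val

    return g


def mean_E_analytic(model: KineticModel, V: DetectionMatrices) -> float:
    """Uncorrected mean apparent efficiency 1^T V_A p / (1^T (V_A + V_D) p)."""
    nA = float(np.diag(V.V_A) @ model.p_eq)
    nD = float(np.diag(V.V_D) @ model.p_eq)
    return nA / (nA + nD)


def analytic_gE_nonideal(model: KineticModel, V: DetectionMatrices):
    """Measured FRET correlation function under brightness/background effects.

    Applies the estimator's pair combination to the analytic ratios
    g_XY(tau)/g(tau) with the analytic <E>; agrees with the two-state closed
    forms identically when backgrounds vanish.
    """
    E = mean_E_analytic(model, V)
    g_aa = pair_correlation(model, V, "AA")
    g_dd = pair_correlation(model, V, "DD")
    g_ad = pair_correlation(model, V, "AD")
    g_da = pair_correlation(model, V, "DA")
    g_nn = pair_correlation(model, V, "NN")

    def g(tau):
        N = g_nn(tau)
        return (
            (1.0 - E) ** 2 * g_aa(tau)
            + E**2 * g_dd(tau)
            - E * (1.0 - E) * (g_ad(tau) + g_da(tau))
        ) / N

    return g


def gE_two_state_uniform_brightness(g_eps, a: float, d: float, mean_eps: float):
    """Closed form for state-independent brightness (two-state, no background).

    g_E(tau) = <n>^{-2} a^2 d^2 g_eps(tau) / (<n>^2 + (a-d)^2 g_eps(tau)),
    <n> = a <eps> + d (1 - <eps>).  At a = d this is g_eps itself.
    """
    n_mean = a * mean_eps + d * (1.0 - mean_eps)

    def g(tau):
        ge = np.asarray(g_eps(tau), float)
        return (a * d) ** 2 * ge / (n_mean**2 * (n_mean**2 + (a - d) ** 2 * ge))

    return g


def gE_two_state_state_brightness(
    g_eps,
    eps: tuple[float, float],
    a: tuple[float, float],
    d: tuple[float, float],
    populations: tuple[float, float] = (0.5, 0.5),
):
    """Closed form for state-dependent brightness (two-state, no background).

    With n_{A,i} = a_i eps_i, n_{D,i} = d_i (1 - eps_i), n_i = n_{A,i} + n_{D,i}:

    g_E = <n>^{-2} (n_D1 n_A2 - n_A1 n_D2)^2 g_eps
          / (<n>^2 (eps1 - eps2)^2 + (n_2 - n_1)^2 g_eps)
    """
    e1, e2 = eps
    nA = (a[0] * e1, a[1] * e2)
    nD = (d[0] * (1.0 - e1), d[1] * (1.0 - e2))
    n1, n2 = nA[0] + nD[0], nA[1] + nD[1]
    p1, p2 = populations
    n_mean = p1 * n1 + p2 * n2
    num = (nD[0] * nA[1] - nA[0] * nD[1]) ** 2

    def g(tau):
        ge = np.asarray(g_eps(tau), float)
        return num * ge / (n_mean**2 * (n_mean**2 * (e1 - e2) ** 2 + (n2 - n1) ** 2 * ge))

    return g


def zwanzig_error(tau_D: float, M: float, T: float) -> float:
    """Relative statistical error sqrt(2 tau_D / (M T)) of a correlation
    function estimated from M finite trajectories of length T."""
    if min(tau_D, M, T) <= 0:
        raise ValueError("tau_D, M and T must be positive")
    return math.sqrt(2.0 * tau_D / (M * T))


def multi_molecule_fraction(c0_pM: float, volume_fl: float = 1.0) -> float:
    """Conditional probability that an occupied confocal volume holds > 1 molecule.

    Occupancy is Poisson with mean mu = c0 V N_A; the burst-relevant quantity
    is P(k > 1 | k >= 1) = (1 - e^-mu (1 + mu)) / (1 - e^-mu).
    """
    if c0_pM < 0 or volume_fl <= 0:
        raise ValueError("concentration must be >= 0 and volume > 0")
    mu = c0_pM * 1e-12 * volume_fl * 1e-15 * 6.02214076e23
    if mu == 0.0:
        return 0.0
    return (1.0 - math.exp(-mu) * (1.0 + mu)) / (1.0 - math.exp(-mu))


def detectable_delta_E(amplitude_floor: float = 0.002) -> float:
    """Smallest detectable two-state efficiency gap |E2 - E1|.

    Inverts the equal-population amplitude g_E(0) = (E2 - E1)^2 / 4 at the
    residual diffusion-artifact floor.
    """
    return 2.0 * math.sqrt(amplitude_floor)


@dataclass
class NsfcsParams:
    """Parameters of the sub-microsecond (nsFCS) fit models.

    Amplitude/time pairs: antibunching (c_ab, tau_ab), conformational
    bunching (c_b, tau_b), triplet (c_T, tau_T), unassigned (c_S, tau_S);
    diffusion time t_D and aspect ratio s; a_XY the inverse mean occupancy.
    """

    c_ab: float = 0.0
    tau_ab: float = 1.0
    c_b: float = 0.0
    tau_b: float = 1.0
    c_T: float = 0.0
    tau_T: float = 1.0
    c_S: float = 0.0
    tau_S: float = 1.0
    t_D: float = 1000.0
    s: float = 0.2
    a_XY: float = 1.0


def nsfcs_intensity_model(t, p: NsfcsParams, cross: bool = False):
    """nsFCS intensity correlation with antibunching, bunching, triplet,
    unassigned and diffusion factors.

    The bunching factor carries a plus sign for autocorrelations and a minus
    sign for cross-correlations (chain reconfiguration moves intensity
    between the channels).
    """
    t = np.asarray(t, float)
    sign = -1.0 if cross else 1.0
    num = (
        (1.0 - p.c_ab * np.exp(-t / p.tau_ab))
        * (1.0 + sign * p.c_b * np.exp(-t / p.tau_b))
        * (1.0 + p.c_T * np.exp(-t / p.tau_T))
        * (1.0 + p.c_S * np.exp(-t / p.tau_S))
    )
    den = (1.0 + t / p.t_D) * np.sqrt(1.0 + p.s**2 * t / p.t_D)
    return 1.0 + p.a_XY * num / den


def nsfcs_fret_model(t, p: NsfcsParams):
    """nsFCS FRET correlation: antibunching factor times the sum of bunching,
    triplet and unassigned decays (diffusion is suppressed by construction)."""
    t = np.asarray(t, float)
    return (1.0 - p.c_ab * np.exp(-t / p.tau_ab)) * (
        p.c_b * np.exp(-t / p.tau_b)
        + p.c_T * np.exp(-t / p.tau_T)
        + p.c_S * np.exp(-t / p.tau_S)
    )
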