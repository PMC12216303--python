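"""FRET correlation functions from within-burst photon pairs.

The estimator assigns E = 1 to acceptor and E = 0 to donor photons, collects
all ordered photon pairs within each burst, bins them by lag into the
pair-type histograms N_AA, N_DD, N_AD, N_DA (first index = earlier photon),
and combines them with the burst-averaged apparent efficiency <E> into

    g_E(tau) = (1-<E>)^2 N_AA/N + <E>^2 N_DD/N - <E>(1-<E>) (N_AD + N_DA)/N

Because every pair stems from a single molecule's transit, the strong
intensity modulation of diffusion through the confocal volume cancels in the
ratios N_XY/N, leaving the conformational dynamics.

The normalised correlation ratios f_XY = N_XY / (weight N) are the
photobleaching diagnostic: mid-burst acceptor bleaching breaks the
f_AD / f_DA symmetry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .bursts import Burst
from .photons import SLOT_DEX, PhotonStream

__all__ = [
    "PAIR_AA",
    "PAIR_DD",
    "PAIR_AD",
    "PAIR_DA",
    "PairHistogram",
    "CorrelationFunction",
    "uniform_edges",
    "log_edges",
    "mean_apparent_E",
    "pair_histograms",
    "pair_histograms_bruteforce",
    "per_burst_pair_histograms",
    "bootstrap_fret_correlation",
    "fret_correlation",
    "correlation_ratios",
    "intensity_correlations",
]

PAIR_AA, PAIR_DD, PAIR_AD, PAIR_DA = 0, 1, 2, 3


def uniform_edges(bin_us: float, max_lag_us: float, start_us: float = 0.0) -> np.ndarray:
    """Uniform lag-bin edges [start, start+bin, ..., >= max_lag]."""
    n = int(np.ceil((max_lag_us - start_us) / bin_us))
    return start_us + bin_us * np.arange(n + 1)

def log_edges(min_lag_us: float, max_lag_us: float, bins_per_decade: int = 8) -> np.ndarray:
    """Logarithmic lag-bin edges, ``bins_per_decade`` bins per decade."""
    n = int(np.ceil(np.log10(max_lag_us / min_lag_us) * bins_per_decade))
    return min_lag_us * 10 ** (np.arange(n + 1) / bins_per_decade)


@dataclass
class PairHistogram:
    """Lag-binned ordered photon-pair counts; sufficient statistic for g_E."""

    edges: np.ndarray  # us, length B+1
    counts: np.ndarray  # int64 (4, B): AA, DD, AD, DA
    mean_E: float  # apparent <E> of the contributing bursts
    n_bursts: int = 0
    uniform: bool = True

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def total(self) -> np.ndarray:
        """N(tau): all pairs irrespective of colour, per bin."""
        return self.counts.sum(axis=0)


@dataclass
class CorrelationFunction:
    """g_E(tau) (and optionally the normalised ratios) on lag-bin centers.

    Bins without pairs carry NaN; per-bin total pair counts serve as fit
    weights.
    """

    lag: np.ndarray  # us (bin centers)
    g: np.ndarray
    n_pairs: np.ndarray
    ratios: dict = field(default_factory=dict)

    def defined(self) -> np.ndarray:
        return np.isfinite(self.g)


def mean_apparent_E(bursts: list[Burst]) -> float:
    """<E> = pooled raw Dex acceptor fraction over all selected bursts."""
    nA = sum(b.n_raw_A for b in bursts)
    nD = sum(b.n_raw_D for b in bursts)
    if nA + nD == 0:
        raise ValueError("no Dex photons in the selected bursts")
    return nA / (nA + nD)


def _burst_dex_photons(stream: PhotonStream, burst: Burst):
    sl = slice(burst.first, burst.last + 1)
    mask = stream.slots[sl] == SLOT_DEX
    t = stream.times[sl][mask]
    c = stream.channels[sl][mask]
    d = stream.detectors[sl][mask]
    return t, c, d


def pair_histograms(
    bursts: list[Burst],
    stream: PhotonStream,
    edges: np.ndarray,
    exclude_same_detector: bool = False,
) -> PairHistogram:
    """Ordered within-burst photon pairs, binned by lag.

    Only donor-excitation photons enter; pairs never span bursts.  A photon is
    never paired with itself; two distinct photons with equal timestamps fall
    in the first bin, ordered by their stream index.  Under the nanosecond
    (nsFCS) policy, pairs on the same physical detector are skipped to remove
    dead-time and afterpulsing artifacts.

    The sweep per burst is output-sensitive: sorted two-pointer enumeration
    that stops at the largest lag of interest, rather than all n(n-1)/2 pairs.
    """
    edges = np.asarray(edges, float)
    if edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("edges must be strictly increasing with >= 2 entries")
    widths = np.diff(edges)
    uniform = bool(np.allclose(widths, widths[0], rtol=1e-9))
    counts = np.zeros((4, edges.size - 1), np.int64)
    for b in bursts:
        t, c, d = _burst_dex_photons(stream, b)
        if np.any(np.diff(t) < 0):
            raise ValueError("stream is not time-sorted")
        _kernels.count_pairs(t, c, d, edges, uniform, exclude_same_detector, counts)
    return PairHistogram(
        edges=edges,
        counts=counts,
        mean_E=mean_apparent_E(bursts),
        n_bursts=len(bursts),
        uniform=uniform,
    )


def pair_histograms_bruteforce(
    bursts: list[Burst],
    stream: PhotonStream,
    edges: np.ndarray,
    exclude_same_detector: bool = False,
) -> PairHistogram:
    """All-pairs O(n^2) reference enumeration (test oracle for pair_histograms)."""
    edges = np.asarray(edges, float)
    counts = np.zeros((4, edges.size - 1), np.int64)
    type_code = {(1, 1): PAIR_AA, (0, 0): PAIR_DD, (1, 0): PAIR_AD, (0, 1): PAIR_DA}
    for b in bursts:
        t, c, d = _burst_dex_photons(stream, b)
        n = t.size
        for i in range(n):
            for j in range(i + 1, n):
                lag = t[j] - t[i]
                if lag < edges[0] or lag >= edges[-1]:
                    continue
                if exclude_same_detector and d[i] == d[j]:
                    continue
                k = int(np.searchsorted(edges, lag, side="right")) - 1
                counts[type_code[(int(c[i]), int(c[j]))], k] += 1
    return PairHistogram(
        edges=edges,
        counts=counts,
        mean_E=mean_apparent_E(bursts),
        n_bursts=len(bursts),
    )


def per_burst_pair_histograms(
    bursts: list[Burst],
    stream: PhotonStream,
    edges: np.ndarray,
    exclude_same_detector: bool = False,
):
    """Pair-type counts per burst: array (n_bursts, 4, B) plus raw (nA, nD).

    Summing over the first axis reproduces :func:`pair_histograms`; keeping
    the per-burst resolution enables burst-resampling (bootstrap) error bars,
    which are the honest uncertainty for g_E: pairs within one burst are
    strongly correlated, so per-pair shot noise underestimates the error.
    """
    edges = np.asarray(edges, float)
    widths = np.diff(edges)
    uniform = bool(np.allclose(widths, widths[0], rtol=1e-9))
    out = np.zeros((len(bursts), 4, edges.size - 1), np.int64)
    raw = np.zeros((len(bursts), 2), np.int64)  # (nA, nD) per burst
    for i, b in enumerate(bursts):
        t, c, d = _burst_dex_photons(stream, b)
        _kernels.count_pairs(t, c, d, edges, uniform, exclude_same_detector, out[i])
        raw[i, 0] = int(np.sum(c == 1))
        raw[i, 1] = int(np.sum(c == 0))
    return out, raw


def bootstrap_fret_correlation(
    per_burst_counts: np.ndarray,
    raw_counts: np.ndarray,
    edges: np.ndarray,
    n_boot: int = 25,
    seed: int = 0,
) -> np.ndarray:
    """Burst-resampled realisations of g_E(tau): array (n_boot, B).

    Bursts are drawn with replacement; <E> is recomputed per resample.
    """
    rng = np.random.default_rng(seed)
    nb = per_burst_counts.shape[0]
    out = np.empty((n_boot, per_burst_counts.shape[2]))
    for r in range(n_boot):
        idx = rng.integers(0, nb, nb)
        counts = per_burst_counts[idx].sum(axis=0)
        nA, nD = raw_counts[idx].sum(axis=0)
        ph = PairHistogram(
            edges=np.asarray(edges, float),
            counts=counts,
            mean_E=nA / (nA + nD),
            n_bursts=nb,
        )
        out[r] = fret_correlation(ph).g
    return out


def fret_correlation(ph: PairHistogram) -> CorrelationFunction:
    """g_E(tau) from the pair histogram; NaN where no pairs fell in a bin."""
    E = ph.mean_E
    N = ph.total.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        g = (
            (1.0 - E) ** 2 * ph.counts[PAIR_AA]
            + E**2 * ph.counts[PAIR_DD]
            - E * (1.0 - E) * (ph.counts[PAIR_AD] + ph.counts[PAIR_DA])
        ) / N
    g = np.where(N > 0, g, np.nan)
    return CorrelationFunction(lag=ph.centers, g=g, n_pairs=ph.total.copy())


def correlation_ratios(ph: PairHistogram) -> dict[str, np.ndarray]:
    """Normalised correlation ratios f_XY(tau), plus the two-sided cross view.

    f_AA = N_AA/(<E>^2 N), f_DD = N_DD/((1-<E>)^2 N),
    f_AD/DA = N_AD/DA/(<E>(1-<E>) N).  In the two-sided convention the AD
    branch is plotted at positive and the DA branch mirrored to negative lags.
    """
    E = ph.mean_E
    N = ph.total.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        f_aa = np.where(N > 0, ph.counts[PAIR_AA] / (E**2 * N), np.nan)
        f_dd = np.where(N > 0, ph.counts[PAIR_DD] / ((1 - E) ** 2 * N), np.nan)
        f_ad = np.where(N > 0, ph.counts[PAIR_AD] / (E * (1 - E) * N), np.nan)
        f_da = np.where(N > 0, ph.counts[PAIR_DA] / (E * (1 - E) * N), np.nan)
    lag = ph.centers
    return {
        "lag": lag,
        "f_AA": f_aa,
        "f_DD": f_dd,
        "f_AD": f_ad,
        "f_DA": f_da,
        "two_sided_lag": np.concatenate([-lag[::-1], lag]),
        "two_sided_cross": np.concatenate([f_da[::-1], f_ad]),
    }


def intensity_correlations(
    stream: PhotonStream,
    pair: tuple[str, str],
    edges: np.ndarray,
    duration_us: float | None = None,
    bursts: list[Burst] | None = None,
    exclude_same_detector: bool = False,
) -> CorrelationFunction:
    """Conventional normalised intensity correlation G_XY(tau).

    Estimated from photon pairs over the whole record (or restricted to
    bursts):  G_XY(tau_k) = C_XY(k) T / (n_X n_Y dtau_k), the standard
    start-stop FCS estimator; for a memoryless constant-rate stream G = 1.
    ``pair`` selects the channels, e.g. ("A", "A") or ("D", "A").
    """
    edges = np.asarray(edges, float)
    code = {"D": 0, "A": 1}
    cx, cy = code[pair[0].upper()], code[pair[1].upper()]
    if duration_us is None:
        duration_us = float(stream.times[-1] - stream.times[0]) if len(stream) else 0.0
    counts = np.zeros((4, edges.size - 1), np.int64)
    widths = np.diff(edges)
    uniform = bool(np.allclose(widths, widths[0], rtol=1e-9))
    if bursts is None:
        sel = stream.select(stream.slots == SLOT_DEX)
        _kernels.count_pairs(
            sel.times, sel.channels, sel.detectors, edges, uniform,
            exclude_same_detector, counts,
        )
        n_x = int(np.sum(sel.channels == cx))
        n_y = int(np.sum(sel.channels == cy))
    else:
        n_x = n_y = 0
        for b in bursts:
            t, c, d = _burst_dex_photons(stream, b)
            _kernels.count_pairs(t, c, d, edges, uniform, exclude_same_detector, counts)
            n_x += int(np.sum(c == cx))
            n_y += int(np.sum(c == cy))
    if cx == cy:
        pair_counts = counts[PAIR_AA if cx == 1 else PAIR_DD].astype(float)
    else:
        # ordered enumeration: X-then-Y pairs at positive lag
        idx = PAIR_AD if (cx, cy) == (1, 0) else PAIR_DA
        pair_counts = counts[idx].astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        g = pair_counts * duration_us / (n_x * n_y * widths)
    g = np.where(pair_counts > 0, g, np.nan)
    lag = 0.5 * (edges[:-1] + edges[1:])
    return CorrelationFunction(lag=lag, g=g, n_pairs=pair_counts.astype(np.int64))
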