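"""Burst identification, FRET corrections, and PIE-based filters.

A burst is the photon cluster emitted during one molecule's transit of the
confocal volume.  Bursts are found with an inter-photon-gap criterion followed
by a total-photon threshold.  Raw counts are corrected for background,
spectral crosstalk, acceptor direct excitation and the detection-efficiency
factor gamma, in that order, giving the corrected efficiency

    E~ = n_DA / (gamma n_DD + n_DA)

With pulsed interleaved excitation the acceptor-excitation counts give the
stoichiometry S (the donor-excitation photon fraction) and the asymmetry alpha_PIE
(difference of mean Dex and Aex arrival times), the filters used to reject
donor-only molecules and mid-burst acceptor photobleaching.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kinetics import InstrumentModel
from .photons import CHANNEL_ACCEPTOR, CHANNEL_DONOR, SLOT_AEX, SLOT_DEX, PhotonStream

__all__ = [
    "Burst",
    "BurstFilterPolicy",
    "find_bursts",
    "correct_counts",
    "corrected_efficiency",
    "stoichiometry",
    "burst_asymmetry",
    "apply_filters",
    "fret_histogram",
    "burst_table",
]


@dataclass
class Burst:
    """One contiguous photon segment with per-type counts and filter statistics."""

    first: int
    last: int  # inclusive photon indices into the parent stream
    t_start: float  # us
    duration: float  # us
    n_raw_D: int  # Dex-slot donor photons
    n_raw_A: int  # Dex-slot acceptor photons
    n_AA: int  # Aex-slot acceptor photons
    mean_t_dex: float = np.nan  # us
    mean_t_aex: float = np.nan  # us
    n_DD: float = np.nan  # corrected
    n_DA: float = np.nan  # corrected
    E_corr: float = np.nan
    S: float = np.nan
    alpha_pie_ms: float = np.nan
    floored: bool = False  # a corrected count went negative and was clipped
    passed: bool = True

    @property
    def n_photons(self) -> int:
        return self.last - self.first + 1

    @property
    def n_dex(self) -> int:
        return self.n_raw_D + self.n_raw_A


@dataclass(frozen=True)
class BurstFilterPolicy:
    """Thresholds applied to candidate bursts.

    min_photons counts all photons in the run (both slots), matching burst
    identification on the full stream; s_range and alpha_max_ms only apply
    when PIE data are present; e_min removes the donor-only population that
    direct-excitation correction pushes below zero.
    """

    min_photons: int = 100
    s_range: tuple[float, float] = (0.25, 0.75)
    alpha_max_ms: float = 0.1
    e_min: float | None = None

    def __post_init__(self) -> None:
        if self.min_photons < 1:
            raise ValueError("min_photons must be >= 1")
        if not self.s_range[0] < self.s_range[1]:
            raise ValueError("s_range must be increasing")


def find_bursts(
    stream: PhotonStream,
    policy: BurstFilterPolicy,
    gap: float = 50.0,
) -> list[Burst]:
    """Maximal runs of photons with successive gaps < ``gap`` us and at least
    ``policy.min_photons`` photons.

    Duration is last minus first arrival time.  Raw per-type counts are taken
    from the excitation slots; slot mean arrival times are filled in for the
    PIE filters where both slots are populated.
    """
    n = len(stream)
    if n == 0:
        return []
    t = stream.times
    if np.any(np.diff(t) < 0):
        raise ValueError("stream must be time-sorted")
    gaps = np.diff(t)
    breaks = np.flatnonzero(gaps >= gap)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [n - 1]])
    bursts: list[Burst] = []
    for first, last in zip(starts, ends):
        if last - first + 1 < policy.min_photons:
            continue
        sl = slice(first, last + 1)
        ch = stream.channels[sl]
        slot = stream.slots[sl]
        tt = t[sl]
        dex = slot == SLOT_DEX
        aex = slot == SLOT_AEX
        b = Burst(
            first=int(first),
            last=int(last),
            t_start=float(t[first]),
            duration=float(t[last] - t[first]),
            n_raw_D=int(np.sum(dex & (ch == CHANNEL_DONOR))),
            n_raw_A=int(np.sum(dex & (ch == CHANNEL_ACCEPTOR))),
            n_AA=int(np.sum(aex & (ch == CHANNEL_ACCEPTOR))),
        )
        if dex.any():
            b.mean_t_dex = float(tt[dex].mean())
        if aex.any():
            b.mean_t_aex = float(tt[aex].mean())
        bursts.append(b)
    return bursts


def correct_counts(burst: Burst, inst: InstrumentModel) -> tuple[float, float]:
    """Background, crosstalk and direct-excitation corrected (n_DD, n_DA).

    Order: background first, then crosstalk (both directions), then direct
    excitation -- via the Aex acceptor count when PIE data exist, otherwise
    the alpha (n_DD + n_DA) proxy.  Negative intermediate counts are floored
    at zero and flagged.  gamma is *not* applied here; it enters the
    efficiency denominator in :func:`corrected_efficiency`.
    """
    # backgrounds are in kHz = 1e-3 photons/us
    nD = burst.n_raw_D - inst.bg_D * 1e-3 * burst.duration
    nA = burst.n_raw_A - inst.bg_A * 1e-3 * burst.duration
    floored = False
    if nD < 0:
        nD, floored = 0.0, True
    if nA < 0:
        nA, floored = 0.0, True
    # spectral crosstalk, both directions
    nDD = nD - inst.beta_AD * nA
    nDA = nA - inst.beta_DA * nD
    # acceptor direct excitation: Aex count when PIE data exist, else proxy
    if burst.n_AA > 0:
        nDA -= inst.alpha * burst.n_AA
    else:
        nDA -= inst.alpha * max(nDD + nDA, 0.0)
    if nDD < 0:
        nDD, floored = 0.0, True
    burst.n_DD = float(nDD)
    burst.n_DA = float(nDA)
    burst.floored = floored
    return burst.n_DD, burst.n_DA


def corrected_efficiency(burst: Burst, inst: InstrumentModel) -> float:
    """Corrected FRET efficiency E~ = n_DA / (gamma n_DD + n_DA).

    May legitimately fall outside [0, 1]: donor-only bursts sit below zero
    once direct excitation is corrected for.
    """
    if np.isnan(burst.n_DD):
        correct_counts(burst, inst)
    denom = inst.gamma * burst.n_DD + burst.n_DA
    burst.E_corr = float(burst.n_DA / denom) if denom != 0 else np.nan
    return burst.E_corr


def stoichiometry(burst: Burst, gamma_pie: float) -> float:
    """S = (n_DD + n_DA) / (n_DD + n_DA + gamma_PIE n_AA); undefined -> NaN."""
    if np.isnan(burst.n_DD):
        raise ValueError("correct_counts must run before stoichiometry")
    dex = burst.n_DD + burst.n_DA
    denom = dex + gamma_pie * burst.n_AA
    burst.S = float(dex / denom) if denom > 0 else np.nan
    return burst.S


def burst_asymmetry(burst: Burst) -> float:
    """alpha_PIE = <t_Dex> - <t_Aex> in ms; NaN if either slot is empty.

    Acceptor photobleaching mid-burst depletes late Aex photons, making the
    asymmetry positive.
    """
    if np.isnan(burst.mean_t_dex) or np.isnan(burst.mean_t_aex):
        burst.alpha_pie_ms = np.nan
    else:
        burst.alpha_pie_ms = (burst.mean_t_dex - burst.mean_t_aex) * 1e-3
    return burst.alpha_pie_ms


def apply_filters(
    bursts: list[Burst],
    inst: InstrumentModel,
    policy: BurstFilterPolicy,
    use_pie: bool | None = None,
) -> list[Burst]:
    """Annotate bursts with corrected quantities and return the survivors.

    With PIE (detected from the data unless forced) the stoichiometry window
    and the alpha_PIE bleach filter are applied; without it only the photon
    threshold (already enforced by find_bursts) and the optional e_min bound.
    """
    if use_pie is None:
        use_pie = any(b.n_AA > 0 for b in bursts)
    gamma_pie = inst.pie.gamma_pie if inst.pie is not None else 2.0
    kept: list[Burst] = []
    for b in bursts:
        correct_counts(b, inst)
        corrected_efficiency(b, inst)
        ok = True
        if use_pie:
            stoichiometry(b, gamma_pie)
            burst_asymmetry(b)
            lo, hi = policy.s_range
            ok &= np.isfinite(b.S) and lo <= b.S <= hi
            ok &= np.isfinite(b.alpha_pie_ms) and abs(b.alpha_pie_ms) <= policy.alpha_max_ms
        if policy.e_min is not None:
            ok &= np.isfinite(b.E_corr) and b.E_corr >= policy.e_min
        b.passed = bool(ok)
        if ok:
            kept.append(b)
    return kept


def fret_histogram(
    bursts: list[Burst], bins: int | np.ndarray = 41, range_: tuple[float, float] = (-0.1, 1.1)
):
    """Histogram of corrected burst efficiencies.

    Returns (counts, edges); metadata lives in the burst list itself (len).
    An empty burst list yields an all-zero histogram.
    """
    e = np.array([b.E_corr for b in bursts if np.isfinite(b.E_corr)])
    if isinstance(bins, int):
        edges = np.linspace(range_[0], range_[1], bins + 1)
    else:
        edges = np.asarray(bins, float)
    counts, edges = np.histogram(e, bins=edges)
    return counts, edges


def burst_table(bursts: list[Burst]):
    """Burst summary as a pandas DataFrame (CSV-exportable)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "burst_id": np.arange(len(bursts)),
            "t_start_us": [b.t_start for b in bursts],
            "T_us": [b.duration for b in bursts],
            "nD_raw": [b.n_raw_D for b in bursts],
            "nA_raw": [b.n_raw_A for b in bursts],
            "nAA": [b.n_AA for b in bursts],
            "E_corr": [b.E_corr for b in bursts],
            "S": [b.S for b in bursts],
            "alpha_pie_ms": [b.alpha_pie_ms for b in bursts],
            "pass_filters": [b.passed for b in bursts],
        }
    )
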