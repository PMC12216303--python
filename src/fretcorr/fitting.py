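"""Weighted multi-exponential fitting of correlation functions.

Correlation decays are fitted with sums of exponentials and an offset,
weighted by the per-lag total pair counts (shot-noise weighting).  Global
fits share selected parameters (typically a fast relaxation time and the
offset) across datasets while amplitudes and slow times stay local.  The
offset can alternatively be fixed from the tail of the curve, mirroring the
practice of reading static heterogeneity off the long-lag plateau.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import lmfit
import numpy as np

from .correlation import CorrelationFunction

__all__ = [
    "ExpFitResult",
    "fit_exponentials",
    "fit_exponentials_global",
    "fit_single_exponential",
    "apparent_relaxation_time",
]


@dataclass
class ExpFitResult:
    """Amplitudes c_i, relaxation times tau_i (us) and offset of one dataset."""

    amplitudes: np.ndarray
    taus: np.ndarray
    offset: float
    stderr_taus: np.ndarray
    redchi: float
    result: lmfit.minimizer.MinimizerResult = field(repr=False, default=None)

    @property
    def rates(self) -> np.ndarray:
        """Relaxation rates 1/tau_i in 1/us."""
        return 1.0 / self.taus


def _exp_sum(t, amps, taus, offset):
    out = np.full_like(np.asarray(t, float), offset)
    for c, tau in zip(amps, taus):
        out = out + c * np.exp(-np.asarray(t, float) / tau)
    return out


def _prepare(curve):
    if isinstance(curve, CorrelationFunction):
        m = curve.defined() & (curve.n_pairs > 0)
        return curve.lag[m], curve.g[m], curve.n_pairs[m].astype(float)
    t, g = curve
    t = np.asarray(t, float)
    g = np.asarray(g, float)
    return t, g, np.ones_like(g)


def _tail_offset(t, g, tail_us: float = 100.0) -> float:
    mask = t >= t.max() - tail_us
    if not mask.any():
        mask = t >= np.median(t)
    return float(np.mean(g[mask]))


def fit_exponentials(
    curve,
    n_exp: int = 1,
    offset: str | float = "free",
    tau_guesses: np.ndarray | None = None,
    weighted: bool = True,
) -> ExpFitResult:
    """Weighted least-squares fit of ``n_exp`` exponentials plus an offset.

    curve: a CorrelationFunction (pair counts become weights) or a (lag, g)
    tuple.  offset: "free", "tail" (mean of the final 100 us), or a number to
    fix.  Relaxation times are fitted in log space via positive lmfit bounds.
    """
    t, g, npairs = _prepare(curve)
    if t.size < 2 * n_exp + 2:
        raise ValueError("not enough defined lag bins for the requested model")
    params = lmfit.Parameters()
    if tau_guesses is None:
        span = max(t.max() / 3.0, t.min() * 2.0 + 1e-12)
        tau_guesses = np.geomspace(max(t.min(), span / 100.0), span, n_exp)
    amp0 = (g.max() - g.min()) / n_exp if g.max() > g.min() else 0.01
    for i in range(n_exp):
        params.add(f"c{i}", value=max(amp0, 1e-6))
        params.add(f"tau{i}", value=float(tau_guesses[i]), min=t.min() / 10.0 + 1e-12,
                   max=t.max() * 100.0)
    if offset == "free":
        params.add("offset", value=float(np.min(g)))
    elif offset == "tail":
        params.add("offset", value=_tail_offset(t, g), vary=False)
    else:
        params.add("offset", value=float(offset), vary=False)
    w = np.sqrt(npairs) if weighted else np.ones_like(g)

    def resid(p):
        amps = [p[f"c{i}"].value for i in range(n_exp)]
        taus = [p[f"tau{i}"].value for i in range(n_exp)]
        return (_exp_sum(t, amps, taus, p["offset"].value) - g) * w

    res = lmfit.minimize(resid, params, method="leastsq")
    taus = np.array([res.params[f"tau{i}"].value for i in range(n_exp)])
    amps = np.array([res.params[f"c{i}"].value for i in range(n_exp)])
    order = np.argsort(taus)
    stderr = np.array(
        [
            res.params[f"tau{i}"].stderr if res.params[f"tau{i}"].stderr else np.nan
            for i in range(n_exp)
        ]
    )
    return ExpFitResult(
        amplitudes=amps[order],
        taus=taus[order],
        offset=float(res.params["offset"].value),
        stderr_taus=stderr[order],
        redchi=float(res.redchi),
        result=res,
    )


def apparent_relaxation_time(tau, g, rel_cutoff: float = 0.01) -> float:
    """Apparent relaxation time of a noise-free near-exponential decay.

    Least-squares slope of ln g over the lags where the curve exceeds
    ``rel_cutoff`` of its initial value, i.e. equal weight per decade of
    decay.  For analytic curves this is the natural reading of "the"
    relaxation time of a function that is exponential up to a weak
    amplitude distortion: an unweighted linear-space fit would instead be
    dominated by the earliest lags, where brightness-induced harmonics
    concentrate, and overstates the timescale distortion.
    """
    tau = np.asarray(tau, float)
    g = np.asarray(g, float)
    if g[0] <= 0:
        raise ValueError("decay must start positive")
    mask = g > g[0] * rel_cutoff
    if mask.sum() < 3:
        raise ValueError("decay range too short for the cutoff")
    slope = np.polyfit(tau[mask], np.log(g[mask]), 1)[0]
    if slope >= 0:
        raise ValueError("curve does not decay")
    return -1.0 / slope


def fit_single_exponential(curve, offset: str | float = 0.0) -> ExpFitResult:
    """Convenience wrapper: one exponential, offset fixed to 0 by default
    (the convention for simulated two-state decays)."""
    return fit_exponentials(curve, n_exp=1, offset=offset)


def fit_exponentials_global(
    curves: list,
    n_exp: int = 2,
    global_taus: tuple[int, ...] = (0,),
    offset: str = "global",
) -> list[ExpFitResult]:
    """Global fit of several correlation functions with shared parameters.

    ``global_taus`` lists which relaxation times (by index, fastest first)
    are shared across datasets; amplitudes are always local.  offset:
    "global" (one shared free offset), "free" (per dataset) or "tail".
    """
    data = [_prepare(c) for c in curves]
    params = lmfit.Parameters()
    t_all = np.concatenate([d[0] for d in data])
    span = max(t_all.max() / 3.0, t_all.min() * 2.0 + 1e-12)
    guesses = np.geomspace(max(t_all.min(), span / 100.0), span, n_exp)
    for i in range(n_exp):
        if i in global_taus:
            params.add(f"tau{i}", value=float(guesses[i]), min=1e-12)
    for k, (t, g, npairs) in enumerate(data):
        for i in range(n_exp):
            params.add(f"c{i}_{k}", value=(g.max() - g.min()) / n_exp + 1e-6)
            if i not in global_taus:
                params.add(f"tau{i}_{k}", value=float(guesses[i]), min=1e-12)
        if offset == "free":
            params.add(f"offset_{k}", value=float(np.min(g)))
        elif offset == "tail":
            params.add(f"offset_{k}", value=_tail_offset(t, g), vary=False)
    if offset == "global":
        params.add("offset_g", value=float(np.min(np.concatenate([d[1] for d in data]))))

    def resid(p):
        pieces = []
        for k, (t, g, npairs) in enumerate(data):
            amps = [p[f"c{i}_{k}"].value for i in range(n_exp)]
            taus = [
                p[f"tau{i}"].value if i in global_taus else p[f"tau{i}_{k}"].value
                for i in range(n_exp)
            ]
            off = p["offset_g"].value if offset == "global" else p[f"offset_{k}"].value
            pieces.append((_exp_sum(t, amps, taus, off) - g) * np.sqrt(npairs))
        return np.concatenate(pieces)

    res = lmfit.minimize(resid, params, method="leastsq")
    out = []
    for k in range(len(data)):
        taus = np.array(
            [
                res.params[f"tau{i}"].value
                if i in global_taus
                else res.params[f"tau{i}_{k}"].value
                for i in range(n_exp)
            ]
        )
        amps = np.array([res.params[f"c{i}_{k}"].value for i in range(n_exp)])
        off = (
            res.params["offset_g"].value
            if offset == "global"
            else res.params[f"offset_{k}"].value
        )
        order = np.argsort(taus)
        def _se(i):
            name = f"tau{i}" if i in global_taus else f"tau{i}_{k}"
            return res.params[name].stderr if res.params[name].stderr else np.nan
        stderr = np.array([_se(i) for i in range(n_exp)])
        out.append(
            ExpFitResult(
                amplitudes=amps[order],
                taus=taus[order],
                offset=float(off),
                stderr_taus=stderr[order],
                redchi=float(res.redchi),
                result=res,
            )
        )
    return out
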