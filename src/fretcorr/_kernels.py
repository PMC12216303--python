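"""Numba kernels for the photon-level hot loops.

Everything here is deliberately free of Python objects: plain arrays in, plain
arrays out.  Each kernel seeds numba's thread-local RNG itself, so results are
reproducible and independent of call order across particles.

Conventions shared with the rest of the package:
  * time in us, rates in 1/us, lengths in um
  * channel codes: 0 = donor, 1 = acceptor
  * excitation-slot codes: 0 = donor excitation (Dex), 1 = acceptor (Aex)
  * pair-type codes: 0 = AA, 1 = DD, 2 = AD (acceptor first), 3 = DA
  * rate matrices use the column convention dp/dt = K p; K[j, s] is the
    rate from state s to state j.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def simulate_radial_track(r0, D, dt, R, max_steps, seed):
    """Euler-Maruyama radial walk from r0 until first exit (r > R).

    Returns the retained samples (all <= R), starting with r0.  A step that
    would go negative is reflected at the origin.
    """
    np.random.seed(seed)
    cap = 16384
    out = np.empty(cap)
    out[0] = r0
    n = 1
    r = r0
    drift = 2.0 * D * dt
    sigma = np.sqrt(2.0 * D * dt)
    block = 512  # normals drawn in blocks; scalar draws dominate otherwise
    noise = np.random.standard_normal(block)
    bi = 0
    # growth is hoisted out of the hot loop: tight inner loop per capacity
    done = False
    while not done:
        limit = cap if cap < max_steps else max_steps
        while n < limit:
            if bi == block:
                noise = np.random.standard_normal(block)
                bi = 0
            r = r + drift / r + noise[bi] * sigma
            bi += 1
            if r < 0.0:
                r = -r
            if r > R:
                done = True
                break
            out[n] = r
            n += 1
        if n >= max_steps:
            done = True
        if not done:
            cap *= 2
            grown = np.empty(cap)
            grown[:n] = out[:n]
            out = grown
    return out[:n].copy()


@njit(cache=True)
def simulate_state_path_const(n, K, p0, dt, seed):
    """State path for a position-independent generator: global Gillespie,
    states filled in dwell-time runs (fast path for plain kinetic models)."""
    np.random.seed(seed)
    ns = p0.size
    states = np.empty(n, dtype=np.int64)
    u = np.random.random()
    s = ns - 1
    acc = 0.0
    for i in range(ns):
        acc += p0[i]
        if u < acc:
            s = i
            break
    k = 0
    t_abs = 0.0  # time of the *next* transition, in steps
    while k < n:
        q = -K[s, s]
        if q <= 0.0:
            for j in range(k, n):
                states[j] = s
            return states
        t_abs += -np.log(np.random.random()) / (q * dt)
        stop = int(t_abs) + 1
        if stop > n:
            stop = n
        for j in range(k, stop):
            states[j] = s
        k = stop
        # destination proportional to off-diagonal column s
        u = np.random.random() * q
        acc = 0.0
        dest = s
        for j in range(ns):
            if j == s:
                continue
            acc += K[j, s]
            if u < acc:
                dest = j
                break
        s = dest
    return states


@njit(cache=True)
def simulate_state_path(radii, w0, K0, K1, p0, dt, seed):
    """Stochastic state path on a track; exact Gillespie within each dt step.

    The generator K(r) = K0 + I(r) K1 is frozen at the sample position for the
    duration of each step.  The recorded state is the state occupied at the
    beginning of the step.
    """
    np.random.seed(seed)
    n = radii.size
    ns = p0.size
    states = np.empty(n, dtype=np.int64)

    # draw initial state from p0
    u = np.random.random()
    s = ns - 1
    acc = 0.0
    for i in range(ns):
        acc += p0[i]
        if u < acc:
            s = i
            break

    inv_w2 = 2.0 / (w0 * w0)
    r_cut = 3.75 * w0  # I(r) < 1e-12 beyond; treat as zero intensity
    for k in range(n):
        states[k] = s
        r = radii[k]
        Ir = np.exp(-r * r * inv_w2) if r < r_cut else 0.0
        t_rem = dt
        while True:
            q = -(K0[s, s] + Ir * K1[s, s])
            if q <= 0.0:
                break
            wait = -np.log(np.random.random()) / q
            if wait >= t_rem:
                break
            t_rem -= wait
            # destination drawn proportional to off-diagonal column s
            u = np.random.random() * q
            acc = 0.0
            dest = s
            for j in range(ns):
                if j == s:
                    continue
                acc += K0[j, s] + Ir * K1[j, s]
                if u < acc:
                    dest = j
                    break
            s = dest
    return states


@njit(cache=True)
def emit_photons(
    radii,
    states,
    birth_time,
    dt,
    w0,
    rate_a,
    rate_d,
    rate_aa,
    beta_da,
    beta_ad,
    seed,
):
    """Poisson photon emission along one track.

    rate_a / rate_d: per-state acceptor / donor photon rates at the beam
    centre under donor excitation (direct excitation already folded in);
    rate_aa: per-state acceptor rate under acceptor excitation (0 disables the
    Aex slot).  Crosstalk reassigns the detection channel photon by photon.
    Arrival times are uniform within a step.
    """
    np.random.seed(seed)
    n = radii.size
    ns = rate_a.size
    cap = 256
    times = np.empty(cap)
    chans = np.empty(cap, dtype=np.int8)
    slots = np.empty(cap, dtype=np.int8)
    m = 0
    inv_w2 = 2.0 / (w0 * w0)
    r_cut = 3.75 * w0  # emission probability < 1e-12 per step beyond
    # one Poisson draw per step on the total rate; channels split afterwards
    rate_tot = np.empty(ns)
    p_a = np.empty(ns)
    p_ad = np.empty(ns)  # cumulative: acceptor then donor, remainder = Aex
    for s in range(ns):
        rate_tot[s] = rate_a[s] + rate_d[s] + rate_aa[s]
        if rate_tot[s] > 0.0:
            p_a[s] = rate_a[s] / rate_tot[s]
            p_ad[s] = (rate_a[s] + rate_d[s]) / rate_tot[s]
        else:
            p_a[s] = 0.0
            p_ad[s] = 0.0
    for k in range(n):
        r = radii[k]
        if r >= r_cut:
            continue
        s = states[k]
        if rate_tot[s] <= 0.0:
            continue
        Ir = np.exp(-r * r * inv_w2)
        tot = np.random.poisson(rate_tot[s] * Ir * dt)
        if tot == 0:
            continue
        while m + tot > cap:
            cap *= 2
            t2 = np.empty(cap)
            c2 = np.empty(cap, dtype=np.int8)
            s2 = np.empty(cap, dtype=np.int8)
            t2[:m] = times[:m]
            c2[:m] = chans[:m]
            s2[:m] = slots[:m]
            times, chans, slots = t2, c2, s2
        t0 = birth_time + k * dt
        for _ in range(tot):
            times[m] = t0 + np.random.random() * dt
            u = np.random.random()
            if u < p_a[s]:  # acceptor emission, Dex
                chans[m] = 0 if np.random.random() < beta_ad else 1
                slots[m] = 0
            elif u < p_ad[s]:  # donor emission, Dex
                chans[m] = 1 if np.random.random() < beta_da else 0
                slots[m] = 0
            else:  # acceptor emission after acceptor excitation
                chans[m] = 1
                slots[m] = 1
            m += 1
    return times[:m].copy(), chans[:m].copy(), slots[:m].copy()


@njit(cache=True)
def count_pairs(times, chans, dets, edges, uniform, exclude_same_detector, counts):
    """Accumulate ordered photon-pair counts into lag bins.

    ``times`` must be sorted.  For every pair i < j with lag = t_j - t_i in
    [edges[0], edges[-1]) the count of the ordered type (chan_i, chan_j) is
    incremented in the covering bin.  Sweep is output-sensitive: the inner
    loop stops at the largest lag of interest.

    counts: int64 array (4, len(edges) - 1), accumulated in place.
    """
    n = times.size
    nb = edges.size - 1
    lo = edges[0]
    hi = edges[nb]
    width = (hi - lo) / nb
    for i in range(n):
        ti = times[i]
        for j in range(i + 1, n):
            lag = times[j] - ti
            if lag >= hi:
                break
            if lag < lo:
                continue
            if exclude_same_detector and dets[i] == dets[j]:
                continue
            if uniform:
                b = int((lag - lo) / width)
                if b >= nb:
                    b = nb - 1
            else:
                # binary search: rightmost edge <= lag
                a, z = 0, nb
                while z - a > 1:
                    mid = (a + z) // 2
                    if edges[mid] <= lag:
                        a = mid
                    else:
                        z = mid
                b = a
            ci = chans[i]
            cj = chans[j]
            if ci == 1 and cj == 1:
                counts[0, b] += 1
            elif ci == 0 and cj == 0:
                counts[1, b] += 1
            elif ci == 1 and cj == 0:
                counts[2, b] += 1
            else:
                counts[3, b] += 1


@njit(cache=True)
def loglik_two_state(tau, chans, is_first, k12, k21, e1, e2, n_rate):
    """Total photon-by-photon log-likelihood of a symmetric-detection 2-state model.

    Propagator between photons: exp((K - n I) tau) = e^{-n tau} (Pi +
    e^{-lambda tau} (I - Pi)) with lambda = k12 + k21 and Pi the projector
    onto equilibrium.  The propagated vector is renormalised after every
    photon with log-accumulation, so bursts of arbitrary length are safe.
    """
    lam = k12 + k21
    p1 = k21 / lam
    p2 = k12 / lam
    # detection weights: F(A) = n diag(e), F(D) = n diag(1-e)
    fa1, fa2 = n_rate * e1, n_rate * e2
    fd1, fd2 = n_rate * (1.0 - e1), n_rate * (1.0 - e2)
    logl = 0.0
    v1 = 0.0
    v2 = 0.0
    for i in range(tau.size):
        if is_first[i] == 1:
            w1, w2 = p1, p2
        else:
            t = tau[i]
            decay = np.exp(-lam * t)
            m = v1 + v2
            w1 = p1 * m + decay * (v1 - p1 * m)
            w2 = p2 * m + decay * (v2 - p2 * m)
            logl += -n_rate * t
        if chans[i] == 1:
            v1 = fa1 * w1
            v2 = fa2 * w2
        else:
            v1 = fd1 * w1
            v2 = fd2 * w2
        s = v1 + v2
        if not (s > 0.0) or not np.isfinite(s):
            return -np.inf
        logl += np.log(s)
        v1 /= s
        v2 /= s
    return logl


@njit(cache=True)
def recolor_two_state(tau, is_first, k12, k21, e1, e2, seed):
    """Redraw photon colours from an unconditional 2-state Markov path.

    The state at each photon time is propagated with the exact transition
    probabilities of the chain; colours are Bernoulli(eps_state).  Timestamps
    are untouched by construction (only inter-photon gaps are read).
    """
    np.random.seed(seed)
    lam = k12 + k21
    p1 = k21 / lam
    out = np.empty(tau.size, dtype=np.int8)
    s = 0
    for i in range(tau.size):
        if is_first[i] == 1:
            s = 0 if np.random.random() < p1 else 1
        else:
            decay = np.exp(-lam * tau[i])
            if s == 0:
                stay = p1 + decay * (1.0 - p1)
            else:
                stay = 1.0 - (p1 - decay * p1)
            if np.random.random() >= stay:
                s = 1 - s
        eps = e1 if s == 0 else e2
        out[i] = 1 if np.random.random() < eps else 0
    return out
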