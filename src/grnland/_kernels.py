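"""Numba-compiled inner loops for stochastic simulation.

All kernels integrate the Hill-kinetics Langevin equation with the
Euler-Maruyama scheme

    x <- x + F(x) dt + sqrt(2 D dt) xi,   xi ~ N(0, 1) per component,

matching the noise convention <eta(t) eta(t')> = 2 D delta(t - t').
States are clamped at zero from below (expression levels are
concentrations).  Seeding goes through ``np.random.seed`` inside the jitted
function, so a given seed reproduces the trajectory bit-for-bit.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def hill_force(x, W_act, W_rep, k, Sn, n):
    N = x.shape[0]
    act = np.empty(N)
    for j in range(N):
        xn = x[j] ** n
        act[j] = xn / (Sn + xn)
    f = np.empty(N)
    for i in range(N):
        s = -k * x[i]
        for j in range(N):
            if W_act[i, j] != 0.0:
                s += W_act[i, j] * act[j]
            if W_rep[i, j] != 0.0:
                s += W_rep[i, j] * (1.0 - act[j])
        f[i] = s
    return f


@njit(cache=True)
def euler_maruyama(x0, W_act, W_rep, k, Sn, n, D, dt, n_steps, record_every, seed):
    """Simulate and record every ``record_every``-th state (plus the start).

    Returns (times, states); raises nothing — a non-finite state aborts the
    loop and the caller detects the truncated output via the returned step
    count in times[-1].
    """
    np.random.seed(seed)
    N = x0.shape[0]
    n_rec = n_steps // record_every + 1
    times = np.empty(n_rec)
    states = np.empty((n_rec, N))
    x = x0.copy()
    times[0] = 0.0
    states[0] = x
    amp = np.sqrt(2.0 * D * dt)
    r = 1
    for step in range(1, n_steps + 1):
        f = hill_force(x, W_act, W_rep, k, Sn, n)
        ok = True
        for i in range(N):
            x[i] += f[i] * dt + amp * np.random.normal()
            if x[i] < 0.0:
                x[i] = 0.0
            if not np.isfinite(x[i]):
                ok = False
        if not ok:
            return times[:r], states[:r], step
        if step % record_every == 0 and r < n_rec:
            times[r] = step * dt
            states[r] = x
            r += 1
    return times[:r], states[:r], -1


@njit(cache=True)
def first_passages(
    x0, targets, radius, W_act, W_rep, k, Sn, n, D, dt, n_passages, max_steps, seed
):
    """First-passage times from ``x0`` into the max-norm ball of ``radius``
    around any row of ``targets``; NaN marks an exhausted step budget."""
    np.random.seed(seed)
    N = x0.shape[0]
    amp = np.sqrt(2.0 * D * dt)
    out = np.empty(n_passages)
    for p in range(n_passages):
        x = x0.copy()
        out[p] = np.nan
        for step in range(1, max_steps + 1):
            f = hill_force(x, W_act, W_rep, k, Sn, n)
            for i in range(N):
                x[i] += f[i] * dt + amp * np.random.normal()
                if x[i] < 0.0:
                    x[i] = 0.0
            for t in range(targets.shape[0]):
                hit = True
                for i in range(N):
                    if abs(x[i] - targets[t, i]) >= radius:
                        hit = False
                        break
                if hit:
                    out[p] = step * dt
                    break
            if not np.isnan(out[p]):
                break
    return out


@njit(cache=True)
def anneal_run(
    x0,
    W_act_unit,
    W_rep,
    k,
    Sn,
    n,
    a_start,
    a_end,
    rate,
    exponential,
    D,
    dt,
    record_every,
    seed,
):
    """Langevin run while the global activation constant follows a schedule.

    ``W_act_unit`` is the activation matrix normalised to unit global
    strength; the instantaneous matrix is ``a(t) * W_act_unit``.  Linear
    schedule: a(t) = a_start + (a_end - a_start) * t/T with
    T = |a_end - a_start| / rate.  Exponential: a(t) = a_start *
    (a_end/a_start)**(t/T), same terminal time.
    Records (a, state) every ``record_every`` steps.
    """
    np.random.seed(seed)
    N = x0.shape[0]
    T = abs(a_end - a_start) / rate
    n_steps = int(T / dt)
    n_rec = n_steps // record_every
    a_out = np.empty(n_rec)
    states = np.empty((n_rec, N))
    x = x0.copy()
    amp = np.sqrt(2.0 * D * dt)
    W_act = np.empty_like(W_act_unit)
    r = 0
    for step in range(n_steps):
        t = step * dt
        if exponential:
            a = a_start * (a_end / a_start) ** (t / T)
        else:
            a = a_start + (a_end - a_start) * (t / T)
        for i in range(N):
            for j in range(N):
                W_act[i, j] = a * W_act_unit[i, j]
        f = hill_force(x, W_act, W_rep, k, Sn, n)
        for i in range(N):
            x[i] += f[i] * dt + amp * np.random.normal()
            if x[i] < 0.0:
                x[i] = 0.0
        if step % record_every == 0 and r < n_rec:
            a_out[r] = a
            states[r] = x
            r += 1
    return a_out[:r], states[:r]


@njit(cache=True)
def euler_maruyama_1d(x0, coeffs, D, dt, n_steps, record_every, seed):
    """1-D Langevin dynamics for a polynomial force field (oracle systems).

    ``coeffs`` are polynomial coefficients of F(x), lowest order first.
    No clamping: oracle potentials are defined on the whole line.
    """
    np.random.seed(seed)
    n_rec = n_steps // record_every + 1
    out = np.empty(n_rec)
    x = x0
    out[0] = x
    amp = np.sqrt(2.0 * D * dt)
    r = 1
    for step in range(1, n_steps + 1):
        f = 0.0
        xp = 1.0
        for c in coeffs:
            f += c * xp
            xp *= x
        x += f * dt + amp * np.random.normal()
        if step % record_every == 0 and r < n_rec:
            out[r] = x
            r += 1
    return out[:r]


@njit(cache=True)
def first_passage_1d(x0, target, radius, coeffs, D, dt, n_passages, max_steps, seed):
    np.random.seed(seed)
    amp = np.sqrt(2.0 * D * dt)
    out = np.empty(n_passages)
    for p in range(n_passages):
        x = x0
        out[p] = np.nan
        for step in range(1, max_steps + 1):
            f = 0.0
            xp = 1.0
            for c in coeffs:
                f += c * xp
                xp *= x
            x += f * dt + amp * np.random.normal()
            if abs(x - target) < radius:
                out[p] = step * dt
                break
    return out
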