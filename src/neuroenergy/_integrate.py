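"""Compiled fixed-step integrators for the coupled HH network.

The network right-hand side is evaluated with the adjacency stored in
CSR-by-target form: ``indices[indptr[j]:indptr[j+1]]`` are the presynaptic
neurons of ``j``, so the gap-junction drive onto ``j`` is
``k * (sum_i V_i - indeg_j * V_j)``.

Noise is one independent N(mean, sigma) current draw per neuron per
integration step, held constant across the Runge-Kutta stages of that
step (optionally scaled by 1/sqrt(dt) for a spectral-density reading of
"unit-variance white noise").
"""

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_GATING = 1
STATUS_NONFINITE = 2


@njit(cache=False)
def _rates(V):
    """Six HH opening/closing rates at potential V (1/ms).

    The removable singularities at V = -40 (alpha_m) and V = -55
    (alpha_n) are patched with their analytic limits.
    """
    x = V + 40.0
    if abs(x) < 1e-7:
        am = 1.0
    else:
        am = 0.1 * x / (1.0 - np.exp(-x / 10.0))
    bm = 4.0 * np.exp(-(V + 65.0) / 18.0)
    y = V + 55.0
    if abs(y) < 1e-7:
        an = 0.1
    else:
        an = 0.01 * y / (1.0 - np.exp(-y / 10.0))
    bn = 0.125 * np.exp(-(V + 65.0) / 80.0)
    ah = 0.07 * np.exp(-(V + 65.0) / 20.0)
    bh = 1.0 / (1.0 + np.exp(-(V + 35.0) / 10.0))
    return am, bm, an, bn, ah, bh


@njit(cache=False)
def _deriv(V, m, n, h, I_eff, k, indptr, indices,
           C, gNa, gK, gl, ENa, EK, El, dV, dm, dn, dh):
    nn = V.shape[0]
    for j in range(nn):
        s = 0.0
        cnt = indptr[j + 1] - indptr[j]
        for p in range(indptr[j], indptr[j + 1]):
            s += V[indices[p]]
        coup = k * (s - cnt * V[j])
        am, bm, an, bn, ah, bh = _rates(V[j])
        iNa = gNa * m[j] ** 3 * h[j] * (V[j] - ENa)
        iK = gK * n[j] ** 4 * (V[j] - EK)
        il = gl * (V[j] - El)
        dV[j] = (I_eff[j] - iNa - iK - il + coup) / C
        dm[j] = am * (1.0 - m[j]) - bm * m[j]
        dn[j] = an * (1.0 - n[j]) - bn * n[j]
        dh[j] = ah * (1.0 - h[j]) - bh * h[j]


@njit(cache=False)
def integrate(V0, m0, n0, h0, I, k, indptr, indices,
              C, gNa, gK, gl, ENa, EK, El,
              dt, n_steps, stride,
              noise_on, noise_mean, noise_sigma, noise_sqrt_dt, noise_seed,
              use_euler):
    """Integrate the coupled network; record every ``stride`` steps.

    Returns (times, V, m, n, h, noise_rec, status, bad_step); the record
    arrays have shape (n_rec, n_neurons) with sample 0 the initial state.
    """
    nn = V0.shape[0]
    n_rec = n_steps // stride + 1
    recV = np.empty((n_rec, nn))
    recm = np.empty((n_rec, nn))
    recn = np.empty((n_rec, nn))
    rech = np.empty((n_rec, nn))
    rec_noise = np.zeros((n_rec, nn))
    times = np.empty(n_rec)

    V = V0.copy(); m = m0.copy(); n = n0.copy(); h = h0.copy()
    noise = np.zeros(nn)
    I_eff = np.empty(nn)

    dV = np.empty(nn); dm = np.empty(nn); dn = np.empty(nn); dh = np.empty(nn)
    k2V = np.empty(nn); k2m = np.empty(nn); k2n = np.empty(nn); k2h = np.empty(nn)
    k3V = np.empty(nn); k3m = np.empty(nn); k3n = np.empty(nn); k3h = np.empty(nn)
    k4V = np.empty(nn); k4m = np.empty(nn); k4n = np.empty(nn); k4h = np.empty(nn)
    tV = np.empty(nn); tm = np.empty(nn); tn = np.empty(nn); th = np.empty(nn)

    if noise_on:
        np.random.seed(noise_seed)
    scale = noise_sigma
    if noise_sqrt_dt:
        scale = noise_sigma / np.sqrt(dt)

    recV[0] = V; recm[0] = m; recn[0] = n; rech[0] = h
    times[0] = 0.0
    rec = 1

    for step in range(n_steps):
        if noise_on:
            for j in range(nn):
                noise[j] = noise_mean + scale * np.random.standard_normal()
            if step % stride == 0:
                rec_noise[step // stride] = noise
        for j in range(nn):
            I_eff[j] = I[j] + noise[j]

        if use_euler:
            _deriv(V, m, n, h, I_eff, k, indptr, indices,
                   C, gNa, gK, gl, ENa, EK, El, dV, dm, dn, dh)
            for j in range(nn):
                V[j] += dt * dV[j]
                m[j] += dt * dm[j]
                n[j] += dt * dn[j]
                h[j] += dt * dh[j]
        else:
            _deriv(V, m, n, h, I_eff, k, indptr, indices,
                   C, gNa, gK, gl, ENa, EK, El, dV, dm, dn, dh)
            for j in range(nn):
                tV[j] = V[j] + 0.5 * dt * dV[j]
                tm[j] = m[j] + 0.5 * dt * dm[j]
                tn[j] = n[j] + 0.5 * dt * dn[j]
                th[j] = h[j] + 0.5 * dt * dh[j]
            _deriv(tV, tm, tn, th, I_eff, k, indptr, indices,
                   C, gNa, gK, gl, ENa, EK, El, k2V, k2m, k2n, k2h)
            for j in range(nn):
                tV[j] = V[j] + 0.5 * dt * k2V[j]
                tm[j] = m[j] + 0.5 * dt * k2m[j]
                tn[j] = n[j] + 0.5 * dt * k2n[j]
                th[j] = h[j] + 0.5 * dt * k2h[j]
            _deriv(tV, tm, tn, th, I_eff, k, indptr, indices,
                   C, gNa, gK, gl, ENa, EK, El, k3V, k3m, k3n, k3h)
            for j in range(nn):
                tV[j] = V[j] + dt * k3V[j]
                tm[j] = m[j] + dt * k3m[j]
                tn[j] = n[j] + dt * k3n[j]
                th[j] = h[j] + dt * k3h[j]
            _deriv(tV, tm, tn, th, I_eff, k, indptr, indices,
                   C, gNa, gK, gl, ENa, EK, El, k4V, k4m, k4n, k4h)
            for j in range(nn):
                V[j] += dt / 6.0 * (dV[j] + 2.0 * k2V[j] + 2.0 * k3V[j] + k4V[j])
                m[j] += dt / 6.0 * (dm[j] + 2.0 * k2m[j] + 2.0 * k3m[j] + k4m[j])
                n[j] += dt / 6.0 * (dn[j] + 2.0 * k2n[j] + 2.0 * k3n[j] + k4n[j])
                h[j] += dt / 6.0 * (dh[j] + 2.0 * k2h[j] + 2.0 * k3h[j] + k4h[j])

        for j in range(nn):
            if not np.isfinite(V[j]):
                return times, recV, recm, recn, rech, rec_noise, STATUS_NONFINITE, step
            if (m[j] < -1e-6 or m[j] > 1.0 + 1e-6 or
                    n[j] < -1e-6 or n[j] > 1.0 + 1e-6 or
                    h[j] < -1e-6 or h[j] > 1.0 + 1e-6):
                return times, recV, recm, recn, rech, rec_noise, STATUS_GATING, step

        if (step + 1) % stride == 0:
            recV[rec] = V; recm[rec] = m; recn[rec] = n; rech[rec] = h
            times[rec] = (step + 1) * dt
            rec += 1

    return times, recV, recm, recn, rech, rec_noise, STATUS_OK, n_steps
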