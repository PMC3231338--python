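"""Fixed-step RK4 integration kernels (numba-compiled).

All kernels work in the V / uA / pF / us unit system, in which uA/pF equals
V/us exactly, so no conversion factors appear anywhere.

Coupling convention: synaptic and global-inhibitor terms are evaluated from
the state at the start of each accepted step and held constant through the
four RK4 stages (a one-step latency of one dt, ~0.2 ns simulated).  This
breaks the algebraic loop between cells the way real gate delay does, and the
results are dt-convergent.
"""

import math

import numpy as np
from numba import njit

# Status codes returned by the network kernel.
STATUS_OK = 0
STATUS_UNSTABLE = 1


@njit(inline="always")
def _rhs(v1, v2, it, ia, ib, ic, id_, a, b, c, d, c1, c2):
    tc2 = ic * math.tanh(c * v2)
    dv1 = (ia * math.tanh(a * v1) - ib * math.tanh(b * v1) - tc2 + it) / c1
    dv2 = (id_ * math.tanh(d * v1) - tc2) / c2
    return dv1, dv2


@njit(inline="always")
def _rk4_cell(v1, v2, it, ia, ib, ic, id_, a, b, c, d, c1, c2, dt):
    k1a, k1b = _rhs(v1, v2, it, ia, ib, ic, id_, a, b, c, d, c1, c2)
    k2a, k2b = _rhs(v1 + 0.5 * dt * k1a, v2 + 0.5 * dt * k1b,
                    it, ia, ib, ic, id_, a, b, c, d, c1, c2)
    k3a, k3b = _rhs(v1 + 0.5 * dt * k2a, v2 + 0.5 * dt * k2b,
                    it, ia, ib, ic, id_, a, b, c, d, c1, c2)
    k4a, k4b = _rhs(v1 + dt * k3a, v2 + dt * k3b,
                    it, ia, ib, ic, id_, a, b, c, d, c1, c2)
    v1n = v1 + dt / 6.0 * (k1a + 2.0 * k2a + 2.0 * k3a + k4a)
    v2n = v2 + dt / 6.0 * (k1b + 2.0 * k2b + 2.0 * k3b + k4b)
    return v1n, v2n


@njit(cache=False)
def integrate_single(v1_0, v2_0, it, ia, ib, ic, id_, a, b, c, d, c1, c2,
                     dt, n_steps, rail):
    """Integrate one oscillator at constant total excitation.

    Returns full-resolution V1 and V2 series of length n_steps + 1
    (sample k is the state at t = k * dt).  rail <= 0 disables clamping.
    """
    v1_out = np.empty(n_steps + 1)
    v2_out = np.empty(n_steps + 1)
    v1 = v1_0
    v2 = v2_0
    v1_out[0] = v1
    v2_out[0] = v2
    for k in range(n_steps):
        v1, v2 = _rk4_cell(v1, v2, it, ia, ib, ic, id_, a, b, c, d,
                           c1, c2, dt)
        if rail > 0.0:
            if v1 > rail:
                v1 = rail
            elif v1 < -rail:
                v1 = -rail
            if v2 > rail:
                v2 = rail
            elif v2 < -rail:
                v2 = -rail
        v1_out[k + 1] = v1
        v2_out[k + 1] = v2
    return v1_out, v2_out


@njit(cache=False)
def integrate_network(v1, v2, ia, ib, ic, id_, ie, iout,
                      a, b, c, d, c1, c2, i_f, i_gi,
                      nbr, drives_gi, dt, n_steps, rec_stride,
                      record_voltages, v1_rec, v2_rec, v3_rec, gi_rec,
                      watch_idx, watch_phases, rail):
    """Integrate the coupled oscillator grid (plus the Os cell).

    v1, v2          : state vectors, modified in place (length nc)
    ia..ie, iout    : per-cell currents, uA
    nbr             : (nc, 4) int32 neighbor indices, -1 for missing
    drives_gi       : per-cell flag; GI = 1 iff any driving cell has V1 > 0
    rec_stride      : record every rec_stride-th step (step 0 included)
    v1_rec, v2_rec  : (max_rec, nc) float32 output (ignored unless
                      record_voltages)
    v3_rec          : (max_rec, nc) uint8 output, binarized V1 (> 0)
    gi_rec          : (max_rec,) uint8 output
    watch_idx       : cell whose completed active phases end the run early
                      (-1 disables the stop rule)
    watch_phases    : number of completed active phases triggering the stop

    Returns (status, steps_done, n_recorded, phases_completed).
    """
    nc = v1.shape[0]
    it = np.empty(nc)
    n_rec = 0
    phases = 0
    watch_active = watch_idx >= 0 and v1[watch_idx] > 0.0
    status = STATUS_OK
    steps_done = 0
    for step in range(n_steps):
        # Coupling terms from the previous accepted state.
        gi = False
        for i in range(nc):
            if drives_gi[i] and v1[i] > 0.0:
                gi = True
                break
        for i in range(nc):
            nb = False
            for j in range(4):
                k = nbr[i, j]
                if k >= 0 and v1[k] > 0.0:
                    nb = True
                    break
            cur = iout[i] - ie[i]
            if nb:
                cur += i_f
            if gi:
                cur -= i_gi
            it[i] = cur

        if step % rec_stride == 0:
            for i in range(nc):
                if record_voltages:
                    v1_rec[n_rec, i] = v1[i]
                    v2_rec[n_rec, i] = v2[i]
                v3_rec[n_rec, i] = 1 if v1[i] > 0.0 else 0
            gi_rec[n_rec] = 1 if gi else 0
            n_rec += 1

        for i in range(nc):
            nv1, nv2 = _rk4_cell(v1[i], v2[i], it[i], ia[i], ib[i], ic[i],
                                 id_[i], a, b, c, d, c1, c2, dt)
            if rail > 0.0:
                if nv1 > rail:
                    nv1 = rail
                elif nv1 < -rail:
                    nv1 = -rail
                if nv2 > rail:
                    nv2 = rail
                elif nv2 < -rail:
                    nv2 = -rail
            if abs(nv1) > 10.0 or abs(nv2) > 10.0:
                status = STATUS_UNSTABLE
            v1[i] = nv1
            v2[i] = nv2
        steps_done = step + 1
        if status != STATUS_OK:
            break

        if watch_idx >= 0:
            now_active = v1[watch_idx] > 0.0
            if watch_active and not now_active:
                phases += 1
                if phases >= watch_phases:
                    break
            watch_active = now_active
    return status, steps_done, n_rec, phases
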