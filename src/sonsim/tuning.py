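"""Inter-oscillator mismatch and the free-frequency tuning procedure.

Analog mismatch between cells spreads the free oscillation frequencies and
breaks synchronization of long objects.  The chip's remedy reuses the input
circuit: the pixel drive of an object cell is attenuated through a per-cell
coefficient k in [0, 1],

    I_out(i,j) = I_G tanh(g (3 V * k_ij - 1.5 V)),

background stays at -I_G regardless of k.  The procedure disables synapses
and the global inhibitor (I_F = 0, I_GI = 0), finds the slowest free
frequency f_s at k = 1, and tunes every other cell's k down (frequency is
monotone in I_out) until all free frequencies agree with f_s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernel
from .model import OscillatorParams, simulate_oscillator, _upcrossings
from .network import (ExcitationParams, Network, V1_INIT, V2_INIT_CENTER)

__all__ = [
    "MismatchSpec",
    "TuningResult",
    "apply_mismatch",
    "apply_tuning",
    "tuned_input_current",
    "free_frequency",
    "free_run_frequencies",
    "tune_network",
    "save_tuning_matrix",
    "load_tuning_matrix",
]

#: Step size for free-frequency runs, us.  Coarser than the coupled-network
#: default (still ~6x below the explicit stability bound); only frequency
#: consistency across cells matters here and all cells share the same dt.
TUNING_DT_US = 5e-4
TUNING_T_MAX_US = 45.0
TUNING_RECORD_STRIDE = 4


@dataclass(frozen=True)
class MismatchSpec:
    """Multiplicative Gaussian mismatch on the five bias currents
    (I_A..I_D, I_E) of every grid cell: each is scaled by 1 + eps with
    eps ~ N(0, sigma_m^2), independently per cell and per current.  Current
    mirrors dominate device mismatch in this circuit, so the gains a..d and
    the capacitances are left untouched.  Os is unperturbed."""

    sigma_m: float
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.sigma_m <= 0.2:
            raise ValueError("sigma_m must lie in [0, 0.2]")


def apply_mismatch(net: Network, m: MismatchSpec) -> Network:
    """Return a copy of the network with seeded per-cell current mismatch."""
    out = net.copy()
    if m.sigma_m == 0.0:
        return out
    rng = np.random.default_rng(m.seed)
    n = net.n_cells
    for arr in (out.I_A, out.I_B, out.I_C, out.I_D, out.I_E):
        arr[:n] *= 1.0 + rng.normal(0.0, m.sigma_m, size=n)
        if np.any(arr[:n] <= 0):
            raise ValueError("mismatch drove a bias current non-positive; "
                             "reduce sigma_m")
    return out


def tuned_input_current(k: float, is_object: bool,
                        e: ExcitationParams | None = None) -> float:
    """Input current of one pixel under tuning coefficient k in [0, 1].

    Object pixels: I_G tanh(g (3 k - 1.5)) (voltages in V), spanning the
    full tuning range -I_G..+I_G; background pixels are driven with -I_G
    regardless of k.
    """
    if e is None:
        e = ExcitationParams()
    if not 0.0 <= k <= 1.0:
        raise ValueError("k must lie in [0, 1]")
    if not is_object:
        return -e.I_G
    return e.I_G * float(np.tanh(e.g * (3.0 * k - 1.5)))


def free_frequency(cell_params: OscillatorParams | None = None,
                   I_out: float = 1.0,
                   e: ExcitationParams | None = None,
                   t_max: float = TUNING_T_MAX_US,
                   dt: float = TUNING_DT_US) -> float:
    """Free oscillation frequency (MHz) of one isolated cell.

    Synapses and global inhibitor are off (I_F = I_GI = 0), so the total
    excitation is I_T = I_out - I_E.  Returns 0.0 for silent cells (the
    explicit no-oscillation marker).
    """
    if e is None:
        e = ExcitationParams()
    t, v1, _ = simulate_oscillator(cell_params, I_out - e.I_E,
                                   t_max=t_max, dt=dt,
                                   state0=(V1_INIT, V2_INIT_CENTER))
    ups = _upcrossings(t, v1)
    if ups.size < 3:
        return 0.0
    period = float(np.mean(np.diff(ups[1:])))  # discard first onset
    return 1.0 / period


def free_run_frequencies(net: Network, K: np.ndarray | None = None,
                         treat_all_as_objects: bool = True,
                         t_max: float = TUNING_T_MAX_US,
                         dt: float = TUNING_DT_US) -> np.ndarray:
    """Free frequencies (MHz) of all grid cells, measured in one uncoupled
    ensemble integration (I_F = I_GI = 0, no Os).

    K is the per-cell tuning coefficient grid (default all ones).  During
    tuning every cell is driven through the object transfer; pass
    treat_all_as_objects=False to pin background pixels at -I_G instead.
    Silent cells report 0.0.
    """
    n = net.n_cells
    e = net.excitation
    if K is None:
        K = np.ones((net.height, net.width))
    kflat = np.asarray(K, dtype=float).ravel()
    if kflat.shape != (n,):
        raise ValueError("K shape must match the grid")
    if np.any((kflat < 0) | (kflat > 1)):
        raise ValueError("tuning coefficients must lie in [0, 1]")
    iout = e.I_G * np.tanh(e.g * (3.0 * kflat - 1.5))
    if not treat_all_as_objects:
        iout = np.where(net.image.ravel() == 1, iout, -e.I_G)

    v1 = np.full(n, V1_INIT)
    v2 = np.full(n, V2_INIT_CENTER)
    n_steps = int(round(t_max / dt))
    max_rec = n_steps // TUNING_RECORD_STRIDE + 1
    v3_rec = np.empty((max_rec, n), dtype=np.uint8)
    gi_rec = np.empty(max_rec, dtype=np.uint8)
    dummy = np.empty((1, 1), dtype=np.float32)
    nbr = np.full((n, 4), -1, dtype=np.int32)
    drives = np.zeros(n, dtype=np.bool_)
    p = net.params
    status, _done, n_rec, _ = _kernel.integrate_network(
        v1, v2, net.I_A[:n], net.I_B[:n], net.I_C[:n], net.I_D[:n],
        net.I_E[:n], iout, p.a, p.b, p.c, p.d, p.C1, p.C2,
        0.0, 0.0, nbr, drives, float(dt), n_steps, TUNING_RECORD_STRIDE,
        False, dummy, dummy, v3_rec, gi_rec, -1, 0, float(net.rail))
    assert status == _kernel.STATUS_OK

    t_rec = np.arange(n_rec) * (dt * TUNING_RECORD_STRIDE)
    v3 = v3_rec[:n_rec]
    freqs = np.zeros(n)
    rising = (v3[1:] == 1) & (v3[:-1] == 0)
    for i in range(n):
        idx = np.nonzero(rising[:, i])[0]
        if idx.size < 3:
            continue
        onsets = t_rec[idx + 1][1:]  # discard first onset as transient
        freqs[i] = 1.0 / float(np.mean(np.diff(onsets)))
    return freqs.reshape(net.height, net.width)


@dataclass
class TuningResult:
    K: np.ndarray                 # per-cell coefficients in [0, 1]
    k_os: float                   # coefficient for the auxiliary Os cell
    f_s: float                    # slowest free frequency, MHz
    freqs_pre: np.ndarray         # free frequencies at K = 1, MHz
    freqs_post: np.ndarray        # free frequencies at the returned K
    residual_rel: np.ndarray      # |f_post - f_s| / f_s per cell
    ie_scale: float               # global I_E attenuation applied (step 1)
    converged: np.ndarray         # per-cell bool
    tunable: np.ndarray           # per-cell bool; False = silent at k=1

    @property
    def pre_spread(self) -> float:
        """Max relative deviation of the untuned free frequencies from f_s
        (over tunable cells)."""
        d = np.abs(self.freqs_pre[self.tunable] - self.f_s)
        return float(d.max() / self.f_s)

    @property
    def post_spread(self) -> float:
        """Max relative deviation after tuning (over tunable cells)."""
        return float(np.max(self.residual_rel[self.tunable]))


def tune_network(net: Network, tol: float = 0.005, max_iter: int = 20,
                 t_max: float = TUNING_T_MAX_US,
                 dt: float = TUNING_DT_US) -> TuningResult:
    """Equalize free frequencies by per-cell bisection on k.

    Step 1: with k = 1 everywhere all cells must oscillate freely; if not,
    I_E is reduced in 2% steps (at most 10).  Step 2: the slowest frequency
    f_s is the common target.  Step 3: each cell's k is bisected on [0, 1]
    (frequency is monotone non-decreasing in I_out, hence in k) until its
    free frequency is within tol of f_s or max_iter iterations pass; cells
    that cannot reach f_s keep their best k and report a residual.
    """
    work = net.copy()
    ones = np.ones((net.height, net.width))
    ie_scale = 1.0
    for _attempt in range(11):
        freqs_pre = free_run_frequencies(work, ones, t_max=t_max, dt=dt)
        oscillating = freqs_pre > 0
        # healthy network: everyone oscillates, and the slowest cell is not
        # parked next to the oscillation threshold (tuning can only slow
        # cells down, so a near-stalled reference would drag the whole
        # network into a glacial regime)
        if oscillating.all() and \
                freqs_pre.min() >= 0.25 * np.median(freqs_pre):
            break
        ie_scale *= 0.98
        work.I_E *= 0.98
    else:
        freqs_pre = free_run_frequencies(work, ones, t_max=t_max, dt=dt)
        oscillating = freqs_pre > 0
        if not oscillating.any():
            raise RuntimeError("no cell oscillates at k=1 even after ten "
                               "2% reductions of I_E")
    # cells still silent at k=1 cannot be tuned (k only attenuates the
    # drive); they are excluded from the target and reported unconverged
    f_s = float(freqs_pre[oscillating].min())

    lo = np.zeros_like(ones)
    hi = np.ones_like(ones)
    k = np.ones_like(ones)
    freqs = freqs_pre.copy()
    tunable = oscillating
    converged = tunable & (np.abs(freqs - f_s) / f_s <= tol)
    for _it in range(max_iter):
        if (converged | ~tunable).all():
            break
        mid = 0.5 * (lo + hi)
        active = tunable & ~converged
        k = np.where(active, mid, k)
        freqs_mid = free_run_frequencies(work, k, t_max=t_max, dt=dt)
        freqs = np.where(active, freqs_mid, freqs)
        newly = active & (np.abs(freqs - f_s) / f_s <= tol)
        too_fast = active & (freqs > f_s)
        hi = np.where(too_fast, mid, hi)
        lo = np.where(active & ~too_fast, mid, lo)
        converged = converged | newly
    residual = np.abs(freqs - f_s) / f_s

    # The auxiliary Os cell must tick at the common frequency too: its
    # cycles bracket one segmentation round, so a mistimed Os clock makes
    # the readout window miss the (slowed-down) oscillator groups.  Os has
    # nominal parameters, so a single-cell bisection suffices.
    from dataclasses import replace as _replace

    e_eff = _replace(net.excitation,
                     I_E=net.excitation.I_E * ie_scale)
    k_os = 1.0
    f_os = free_frequency(net.params,
                          tuned_input_current(k_os, True, e_eff), e_eff,
                          t_max=t_max, dt=dt)
    if f_os > 0 and abs(f_os - f_s) / f_s > tol:
        lo_s, hi_s = 0.0, 1.0
        for _ in range(max_iter):
            mid_s = 0.5 * (lo_s + hi_s)
            f_os = free_frequency(net.params,
                                  tuned_input_current(mid_s, True, e_eff),
                                  e_eff, t_max=t_max, dt=dt)
            k_os = mid_s
            if f_os > 0 and abs(f_os - f_s) / f_s <= tol:
                break
            if f_os > f_s:
                hi_s = mid_s
            else:
                lo_s = mid_s

    return TuningResult(K=k, k_os=k_os, f_s=f_s, freqs_pre=freqs_pre,
                        freqs_post=freqs, residual_rel=residual,
                        ie_scale=ie_scale, converged=converged,
                        tunable=tunable)


def apply_tuning(net: Network, K: np.ndarray,
                 ie_scale: float = 1.0,
                 k_os: float | None = None) -> Network:
    """Return a copy of the network with tuned input currents.

    Object pixels are driven through the tuning transfer at their k; the
    background stays at -I_G.  ie_scale propagates a step-1 global I_E
    reduction, and k_os (if given) retimes the auxiliary Os cell to the
    common frequency so its cycles keep bracketing one segmentation round.
    """
    out = net.copy()
    n = net.n_cells
    e = net.excitation
    kflat = np.asarray(K, dtype=float).ravel()
    if kflat.shape != (n,):
        raise ValueError("K shape must match the grid")
    tuned = e.I_G * np.tanh(e.g * (3.0 * kflat - 1.5))
    out.I_out[:n] = np.where(net.image.ravel() == 1, tuned, -e.I_G)
    if k_os is not None:
        out.I_out[n] = tuned_input_current(k_os, True, e)
    if ie_scale != 1.0:
        out.I_E *= ie_scale
    return out


def save_tuning_matrix(K: np.ndarray, path) -> None:
    """CSV, row-major, with 1-based row/column headers (i, j = 1..H/W)."""
    K = np.asarray(K, dtype=float)
    h, w = K.shape
    with open(path, "w") as fh:
        fh.write("i\\j," + ",".join(str(j + 1) for j in range(w)) + "\n")
        for i in range(h):
            fh.write(str(i + 1) + ","
                     + ",".join(f"{K[i, j]:.8g}" for j in range(w)) + "\n")


def load_tuning_matrix(path) -> np.ndarray:
    rows = []
    with open(path) as fh:
        next(fh)  # header
        for line in fh:
            parts = line.strip().split(",")
            rows.append([float(x) for x in parts[1:]])
    return np.asarray(rows)
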