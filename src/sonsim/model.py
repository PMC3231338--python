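"""Single relaxation-oscillator model: dynamics, nullclines, amplitude, OTA.

The oscillator is a two-variable fast-slow system built from saturating
(tanh) transconductances:

    C1 dV1/dt = I_A tanh(a V1) - I_B tanh(b V1) - I_C tanh(c V2) + I_T
    C2 dV2/dt = I_D tanh(d V1) - I_C tanh(c V2)

V1 is the excitatory (fast) variable and V2 the inhibitory (slow) one; I_T is
the total external excitation.  With I_A < I_B and a > b the fast-variable
current I_A tanh(a V1) - I_B tanh(b V1) is N-shaped, which together with the
time-scale separation C2 >> C1 produces relaxation oscillations: abrupt jumps
of V1 between a silent (V1 < 0) and an active (V1 > 0) branch, paced by the
slow drift of V2.

Unit system: V, uA, pF, us (uA/pF = V/us exactly), so every printed circuit
constant is used verbatim; 50 fF is stored as 0.05 pF.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import brentq

from ._kernel import integrate_single

__all__ = [
    "OscillatorParams",
    "OTAParams",
    "Nullclines",
    "DEFAULT_DT_US",
    "DEFAULT_RAIL_V",
    "fast_branch_current",
    "oscillator_rhs",
    "compute_nullclines",
    "simulate_oscillator",
    "amplitude_oracle",
    "oscillation_period",
    "ota_transfer",
]

#: Default RK4 step, us.  The fastest linearized rate of the default cell is
#: I_D*d/C2 ~ 909 /us, so the explicit stability bound is ~3e-3 us; 2e-4 us
#: keeps the local truncation error far below the measurement tolerances.
DEFAULT_DT_US = 2e-4

#: Supply-rail clamp, V.  The chip runs from a 3 V supply with signals
#: referenced to mid-rail, so node voltages physically cannot leave
#: +/-1.5 V.  The clamp matters only for strongly hyperpolarized cells
#: (background pixels), whose fast equation has no fixed point in the
#: unclamped model.
DEFAULT_RAIL_V = 1.5


@dataclass(frozen=True)
class OscillatorParams:
    """Constants of the oscillator equations (currents uA, gains 1/V,
    capacitances pF).  Defaults are the values chosen for the 0.35 um
    implementation, selected for a 0.5 V oscillation amplitude."""

    I_A: float = 1.2
    I_B: float = 2.0
    I_C: float = 2.0
    I_D: float = 2.0
    a: float = 10.0
    b: float = 2.44
    c: float = 2.44
    d: float = 500.0
    C1: float = 0.05  # pF (50 fF)
    C2: float = 1.1   # pF

    def __post_init__(self) -> None:
        for name in ("I_A", "I_B", "I_C", "I_D", "a", "b", "c", "d",
                     "C1", "C2"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be strictly positive, got {v}")
        if not self.I_A < self.I_B:
            raise ValueError("need I_A < I_B for the N-shaped fast branch")
        if not self.a > self.b:
            raise ValueError("need a > b for the inner rising segment")
        if self.C2 / self.C1 < 10:
            raise ValueError("need C2/C1 >= 10 for fast-slow separation")

    def to_dict(self) -> dict:
        return {
            "I_A": self.I_A, "I_B": self.I_B, "I_C": self.I_C,
            "I_D": self.I_D, "a": self.a, "b": self.b, "c": self.c,
            "d": self.d, "C1_pF": self.C1, "C2_pF": self.C2,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "OscillatorParams":
        d = dict(d)
        kw = {}
        for key in ("I_A", "I_B", "I_C", "I_D", "a", "b", "c", "d"):
            if key in d:
                kw[key] = float(d[key])
        if "C1_pF" in d:
            kw["C1"] = float(d["C1_pF"])
        if "C2_pF" in d:
            kw["C2"] = float(d["C2_pF"])
        return cls(**kw)

    def scaled_currents(self, factors: Sequence[float]) -> "OscillatorParams":
        """Return a copy with (I_A, I_B, I_C, I_D) multiplied elementwise."""
        fa, fb, fc, fd = factors
        return replace(self, I_A=self.I_A * fa, I_B=self.I_B * fb,
                       I_C=self.I_C * fc, I_D=self.I_D * fd)


def fast_branch_current(V1, p: OscillatorParams | None = None):
    """N-shaped fast-branch current I_A tanh(a V1) - I_B tanh(b V1), uA.

    Odd in V1; saturates to -(I_B - I_A) for V1 -> +inf.  Accepts scalars or
    arrays; non-finite input is rejected.
    """
    if p is None:
        p = OscillatorParams()
    v = np.asarray(V1, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("V1 must be finite")
    out = p.I_A * np.tanh(p.a * v) - p.I_B * np.tanh(p.b * v)
    return float(out) if np.isscalar(V1) else out


def oscillator_rhs(state, I_T: float, p: OscillatorParams | None = None):
    """Time derivatives (dV1/dt, dV2/dt) in V/us for one oscillator."""
    if p is None:
        p = OscillatorParams()
    v1, v2 = state
    if not (math.isfinite(v1) and math.isfinite(v2) and math.isfinite(I_T)):
        raise ValueError("state and I_T must be finite")
    slow_in = p.I_C * math.tanh(p.c * v2)
    dv1 = (fast_branch_current(v1, p) - slow_in + I_T) / p.C1
    dv2 = (p.I_D * math.tanh(p.d * v1) - slow_in) / p.C2
    return dv1, dv2


@dataclass(frozen=True)
class Nullclines:
    """Sampled nullclines over a common V1 grid.

    v1_nullcline_v2[i] is the V2 value where dV1/dt = 0 at v1[i]; NaN where
    the required tanh argument leaves (-1, 1) (marked absent, not clamped).
    Likewise v2_nullcline_v2 for dV2/dt = 0.
    """

    v1: np.ndarray
    v1_nullcline_v2: np.ndarray
    v2_nullcline_v2: np.ndarray


def _atanh_or_nan(u: np.ndarray) -> np.ndarray:
    out = np.full_like(u, np.nan)
    ok = np.abs(u) < 1.0 - 1e-12
    out[ok] = np.arctanh(u[ok])
    return out


def compute_nullclines(p: OscillatorParams, I_T: float,
                       v1_grid) -> Nullclines:
    """Sample both nullclines in the (V1, V2) phase plane.

    The V1-nullcline solves I_C tanh(c V2) = fast_branch(V1) + I_T, the
    V2-nullcline solves I_C tanh(c V2) = I_D tanh(d V1).
    """
    v1 = np.asarray(v1_grid, dtype=float)
    if v1.size == 0:
        raise ValueError("empty V1 grid")
    u1 = (fast_branch_current(v1, p) + I_T) / p.I_C
    u2 = p.I_D * np.tanh(p.d * v1) / p.I_C
    return Nullclines(v1=v1,
                      v1_nullcline_v2=_atanh_or_nan(u1) / p.c,
                      v2_nullcline_v2=_atanh_or_nan(u2) / p.c)


def simulate_oscillator(p: OscillatorParams | None = None,
                        I_T: float = -1.5,
                        t_max: float = 20.0,
                        dt: float = DEFAULT_DT_US,
                        state0=(0.0, 0.0),
                        rail: float = DEFAULT_RAIL_V):
    """Integrate one oscillator at constant I_T with fixed-step RK4.

    Returns (t, V1, V2) at full step resolution.  The default -1.5 uA is the
    total excitation of an isolated object pixel (I_G - I_E = 1 - 2.5 uA).
    """
    if p is None:
        p = OscillatorParams()
    if dt <= 0 or t_max <= 0:
        raise ValueError("dt and t_max must be positive")
    n_steps = int(round(t_max / dt))
    v1, v2 = integrate_single(float(state0[0]), float(state0[1]), float(I_T),
                              p.I_A, p.I_B, p.I_C, p.I_D,
                              p.a, p.b, p.c, p.d, p.C1, p.C2,
                              float(dt), n_steps, float(rail))
    t = np.arange(n_steps + 1) * dt
    return t, v1, v2


def _upcrossings(t: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Times where v crosses zero upward, linearly interpolated."""
    s = v > 0.0
    idx = np.nonzero(~s[:-1] & s[1:])[0]
    if idx.size == 0:
        return np.empty(0)
    frac = -v[idx] / (v[idx + 1] - v[idx])
    return t[idx] + frac * (t[idx + 1] - t[idx])


def amplitude_oracle(p: OscillatorParams | None = None,
                     I_T: float = -1.5,
                     t_max: float = 20.0,
                     dt: float = DEFAULT_DT_US) -> float | None:
    """Settled oscillation amplitude max |V1|, by long integration.

    This is the operational definition of the amplitude: the second half of a
    t_max-long trajectory is taken as settled and its max |V1| returned.
    Returns None when no limit cycle exists (fewer than two settled zero
    up-crossings, or a collapsed V1 range).
    """
    if p is None:
        p = OscillatorParams()
    t, v1, _ = simulate_oscillator(p, I_T, t_max=t_max, dt=dt)
    half = v1.size // 2
    tail_t, tail_v = t[half:], v1[half:]
    if _upcrossings(tail_t, tail_v).size < 2:
        return None
    if np.ptp(tail_v) < 1e-3:
        return None
    return float(np.max(np.abs(tail_v)))


def oscillation_period(p: OscillatorParams | None = None,
                       I_T: float = -1.5,
                       t_max: float = 20.0,
                       dt: float = DEFAULT_DT_US) -> float | None:
    """Settled period in us: mean gap between V1 zero up-crossings in the
    second half of the trajectory.  None if fewer than two crossings."""
    if p is None:
        p = OscillatorParams()
    t, v1, _ = simulate_oscillator(p, I_T, t_max=t_max, dt=dt)
    half = v1.size // 2
    ups = _upcrossings(t[half:], v1[half:])
    if ups.size < 2:
        return None
    return float(np.mean(np.diff(ups)))


@dataclass(frozen=True)
class OTAParams:
    """Operational-transconductance-amplifier transfer parameters.

    B_r (uA/V^n_r) is the differential-pair saturation current factor, W_r
    and L_EFFr (um) its geometry, n_r the short-channel saturation exponent,
    I_sat (uA) the tail current.  The saturation voltage sigma (V) follows
    from the others (the differential-pair relation at I_o = +/-I_sat); pass
    sigma=None to derive it.  No specific device values are normative here;
    the defaults describe a representative 0.35 um pair.
    """

    B_r: float = 0.213
    W_r: float = 10.0
    L_EFFr: float = 0.35
    n_r: float = 1.5
    I_sat: float = 1.0
    sigma: float | None = None

    def __post_init__(self) -> None:
        for name in ("B_r", "W_r", "L_EFFr", "I_sat"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (1.0 < self.n_r <= 2.0):
            raise ValueError("n_r must lie in (1, 2]")
        derived = (self.I_sat * self.L_EFFr
                   / (self.W_r * self.B_r)) ** (1.0 / self.n_r)
        if self.sigma is None:
            object.__setattr__(self, "sigma", derived)
        elif not math.isclose(self.sigma, derived, rel_tol=1e-6):
            raise ValueError(
                f"sigma={self.sigma} inconsistent with the pair parameters "
                f"(expected {derived:.6g})")

    def inverse_transfer(self, I_o: float) -> float:
        """V_r as a function of I_o on (-I_sat, I_sat): the alpha-power
        differential-pair form.  Monotone increasing in I_o."""
        q = self.L_EFFr / (2.0 * self.W_r * self.B_r)
        e = 1.0 / self.n_r
        return (((self.I_sat + I_o) * q) ** e
                - ((self.I_sat - I_o) * q) ** e)

    @property
    def small_signal_gain(self) -> float:
        """dI_o/dV_r at the origin, uA/V."""
        q = self.L_EFFr / (2.0 * self.W_r * self.B_r)
        e = 1.0 / self.n_r
        # d(Vr)/d(Io) at 0 = 2 * e * q**e * I_sat**(e-1)
        return 1.0 / (2.0 * e * q ** e * self.I_sat ** (e - 1.0))


def ota_transfer(V_r, q: OTAParams | None = None,
                 mode: Literal["exact", "tanh"] = "exact"):
    """OTA output current I_o(V_r), uA.

    exact: numerically inverts the differential-pair V_r(I_o) relation on
    (-sigma, sigma) by bracketed root finding and clamps to +/-I_sat outside.
    tanh:  single tanh whose slope at the origin matches the exact curve's
    (gain-matched approximation).  Both are odd in V_r.
    """
    if q is None:
        q = OTAParams()
    scalar = np.isscalar(V_r)
    v = np.atleast_1d(np.asarray(V_r, dtype=float))
    if not np.all(np.isfinite(v)):
        raise ValueError("V_r must be finite")
    out = np.empty_like(v)
    if mode == "tanh":
        k = q.small_signal_gain / q.I_sat
        out = q.I_sat * np.tanh(k * v)
    elif mode == "exact":
        for i, vr in enumerate(v):
            if vr >= q.sigma:
                out[i] = q.I_sat
            elif vr <= -q.sigma:
                out[i] = -q.I_sat
            elif vr == 0.0:
                out[i] = 0.0
            else:
                lo, hi = -q.I_sat, q.I_sat
                try:
                    out[i] = brentq(lambda io: q.inverse_transfer(io) - vr,
                                    lo, hi, xtol=1e-12)
                except ValueError as exc:  # pragma: no cover - guarded above
                    raise RuntimeError(
                        f"OTA inverse transfer root find failed at "
                        f"V_r={vr}") from exc
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return float(out[0]) if scalar else out
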