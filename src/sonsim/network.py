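"""Coupled oscillator grid: assembly, integration, trace analysis.

One oscillator per image pixel, excitatory synapses to the four grid
neighbors, one global inhibitor (GI) shared by the whole grid, and one
auxiliary oscillator Os outside the grid.  The total excitation of a cell is

    I_T = I_out + I_F * [any 4-neighbor active] - I_GI * [GI active] - I_E

with I_out = +I_G for object pixels and -I_G for background.  The synapse is
OR-gated: one switched current source per cell, so a single I_F regardless of
how many neighbors are active.  GI is active exactly when at least one grid
cell has V1 > 0 (Heaviside with Hev(0) = 0); Os is excited, has no neighbors,
is inhibited by GI but does not drive it — its free cycles bracket one
complete segmentation round of the image.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np

from . import _kernel
from .model import DEFAULT_DT_US, DEFAULT_RAIL_V, OscillatorParams

__all__ = [
    "ExcitationParams",
    "Network",
    "Trace",
    "PeriodDuty",
    "InsufficientCyclesError",
    "SimulationUnstableError",
    "build_network",
    "external_current",
    "gi_state",
    "simulate",
    "active_windows",
    "measure_period_and_duty",
]

# Initial conditions: all cells start on the silent branch at a common V1,
# with seeded uniform V2 jitter of +/-10% of the settled V2 swing (the
# chip's power-up phases are uncontrolled; the seed makes runs reproducible).
V1_INIT = -0.5
V2_INIT_CENTER = -0.55
V2_SWING = 0.72  # settled V2 excursion of the default cell at I_T = -1.5 uA
V2_JITTER_FRACTION = 0.10

DEFAULT_T_MAX_US = 50.0
DEFAULT_STOP_OS_PHASES = 3
DEFAULT_RECORD_STRIDE = 10

#: Residual per-cell dispersion of the bias currents applied by simulate(),
#: relative SD.  A network of mathematically identical oscillators is a
#: measure-zero idealization with a pathological symmetry: object groups
#: that once fire together can never separate, because their dynamics are
#: exactly degenerate.  The hardware is never ideal - after frequency
#: tuning it retains a residual free-frequency spread up to the tuning
#: tolerance (0.5%) - and that tiny diversity is what lets coincidentally
#: merged groups drift apart.  The default models the tuned chip; pass
#: residual_sigma=0 for the strictly ideal network.
DEFAULT_RESIDUAL_SIGMA = 0.005


class InsufficientCyclesError(RuntimeError):
    """Raised when a trace holds too few complete cycles for a measurement."""


class SimulationUnstableError(RuntimeError):
    """Raised when the integrator detects a diverging state (|V| > 10 V)."""


@dataclass(frozen=True)
class ExcitationParams:
    """Excitation / coupling currents, uA, and the input-circuit gain g
    (1/V) used by the tuning transfer I_out = I_G tanh(g (3 k - 1.5))."""

    I_G: float = 1.0
    I_F: float = 0.8
    I_GI: float = 0.22
    I_E: float = 2.5
    g: float = 5.0

    def __post_init__(self) -> None:
        for name in ("I_G", "I_F", "I_GI", "I_E"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.g <= 0:
            raise ValueError("g must be positive")

    def to_dict(self) -> dict:
        return {"I_G": self.I_G, "I_F": self.I_F, "I_GI": self.I_GI,
                "I_E": self.I_E, "g": self.g}

    @classmethod
    def from_dict(cls, d: dict) -> "ExcitationParams":
        return cls(**{k: float(v) for k, v in d.items()
                      if k in ("I_G", "I_F", "I_GI", "I_E", "g")})


def _neighbor_table(height: int, width: int) -> np.ndarray:
    """4-neighbor flat indices, -1 where the chip boundary cuts a neighbor
    (missing neighbors are permanently inactive)."""
    n = height * width
    nbr = np.full((n, 4), -1, dtype=np.int32)
    idx = np.arange(n).reshape(height, width)
    nbr[idx[1:, :].ravel(), 0] = idx[:-1, :].ravel()   # up
    nbr[idx[:-1, :].ravel(), 1] = idx[1:, :].ravel()   # down
    nbr[idx[:, 1:].ravel(), 2] = idx[:, :-1].ravel()   # left
    nbr[idx[:, :-1].ravel(), 3] = idx[:, 1:].ravel()   # right
    return nbr


@dataclass
class Network:
    """Oscillator grid plus the auxiliary Os cell (stored at flat index
    n_cells, after the row-major grid cells).

    Per-cell current arrays allow inter-cell mismatch; the gains a..d and
    capacitances are shared (mismatch acts on the bias currents).
    """

    height: int
    width: int
    params: OscillatorParams
    excitation: ExcitationParams
    image: np.ndarray            # {0,1}, (height, width)
    I_A: np.ndarray              # (n_cells + 1,), grid cells then Os
    I_B: np.ndarray
    I_C: np.ndarray
    I_D: np.ndarray
    I_E: np.ndarray
    I_out: np.ndarray
    neighbors: np.ndarray        # (n_cells + 1, 4) int32
    drives_gi: np.ndarray        # (n_cells + 1,) bool; Os does not drive GI
    rail: float = DEFAULT_RAIL_V

    @property
    def n_cells(self) -> int:
        return self.height * self.width

    @property
    def os_index(self) -> int:
        return self.n_cells

    def copy(self) -> "Network":
        return Network(self.height, self.width, self.params, self.excitation,
                       self.image.copy(), self.I_A.copy(), self.I_B.copy(),
                       self.I_C.copy(), self.I_D.copy(), self.I_E.copy(),
                       self.I_out.copy(), self.neighbors, self.drives_gi,
                       self.rail)


def build_network(binary_image,
                  excitation: ExcitationParams | None = None,
                  params: OscillatorParams | None = None) -> Network:
    """Assemble the network for a binary image: object pixels are driven
    with I_out = +I_G, background with -I_G; the Os cell is excited
    (+I_G), has no neighbors, is inhibited by GI and does not drive it."""
    if excitation is None:
        excitation = ExcitationParams()
    if params is None:
        params = OscillatorParams()
    img = np.asarray(binary_image)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("binary image must be a non-empty 2-D array")
    if not np.isin(img, (0, 1)).all():
        raise ValueError("image entries must be 0 or 1")
    img = img.astype(np.uint8)
    h, w = img.shape
    n = h * w

    def fill(value: float) -> np.ndarray:
        return np.full(n + 1, value, dtype=float)

    iout = np.empty(n + 1)
    iout[:n] = np.where(img.ravel() == 1, excitation.I_G, -excitation.I_G)
    iout[n] = excitation.I_G  # Os

    nbr = np.full((n + 1, 4), -1, dtype=np.int32)
    nbr[:n] = _neighbor_table(h, w)
    drives = np.ones(n + 1, dtype=np.bool_)
    drives[n] = False

    return Network(height=h, width=w, params=params, excitation=excitation,
                   image=img,
                   I_A=fill(params.I_A), I_B=fill(params.I_B),
                   I_C=fill(params.I_C), I_D=fill(params.I_D),
                   I_E=fill(excitation.I_E), I_out=iout,
                   neighbors=nbr, drives_gi=drives)


def external_current(I_out: float, neighbor_V3: Iterable[bool], GI: bool,
                     e: ExcitationParams | None = None) -> float:
    """Total excitation I_T (uA) of one cell from its coupling state.

    The synapse is OR-gated: one I_F whether one or four neighbors are
    active (a single switched current source feeds the cell).
    """
    if e is None:
        e = ExcitationParams()
    any_nb = any(bool(f) for f in neighbor_V3)
    return (I_out + (e.I_F if any_nb else 0.0)
            - (e.I_GI if GI else 0.0) - e.I_E)


def gi_state(V1_grid) -> int:
    """Global-inhibitor state: 1 iff any grid cell has V1 > 0 (Hev(0)=0).
    The Os cell is excluded by construction (it does not drive GI)."""
    v = np.asarray(V1_grid, dtype=float)
    return int(np.any(v > 0.0))


@dataclass
class Trace:
    """Recorded time series of a network simulation.

    Grid arrays have one column per grid cell in row-major order; the Os
    cell is stored separately.  V3 is the binarized V1 (threshold zero) and
    GI the global-inhibitor flag, both evaluated from the state at the start
    of each recorded step.
    """

    t: np.ndarray                 # (n_rec,), us
    V3: np.ndarray                # (n_rec, n_cells) bool
    GI: np.ndarray                # (n_rec,) bool
    os_V1: np.ndarray             # (n_rec,) float32
    os_V3: np.ndarray             # (n_rec,) bool
    shape: tuple[int, int]
    dt: float
    record_stride: int
    V1: np.ndarray | None = None  # (n_rec, n_cells) float32, optional
    V2: np.ndarray | None = None

    @property
    def n_cells(self) -> int:
        return self.shape[0] * self.shape[1]

    def flat_index(self, cell) -> int:
        if np.isscalar(cell):
            return int(cell)
        r, c = cell
        return int(r) * self.shape[1] + int(c)

    def to_csv(self, path) -> None:
        """Columnar text export: time, row, col, V1, V2, V3, GI (one line
        per cell per recorded step; V1/V2 blank when not recorded)."""
        h, w = self.shape
        with open(path, "w", newline="") as fh:
            wr = csv.writer(fh)
            wr.writerow(["time_us", "row", "col", "V1", "V2", "V3", "GI"])
            for k, tk in enumerate(self.t):
                for i in range(self.n_cells):
                    v1 = "" if self.V1 is None else f"{self.V1[k, i]:.6g}"
                    v2 = "" if self.V2 is None else f"{self.V2[k, i]:.6g}"
                    wr.writerow([f"{tk:.6g}", i // w, i % w, v1, v2,
                                 int(self.V3[k, i]), int(self.GI[k])])

    def to_npz(self, path) -> None:
        """Compact binary container (NumPy .npz)."""
        data = {"t": self.t, "V3": self.V3, "GI": self.GI,
                "os_V1": self.os_V1, "os_V3": self.os_V3,
                "shape": np.asarray(self.shape), "dt": self.dt,
                "record_stride": self.record_stride}
        if self.V1 is not None:
            data["V1"] = self.V1
            data["V2"] = self.V2
        np.savez_compressed(path, **data)


def simulate(net: Network,
             t_max: float = DEFAULT_T_MAX_US,
             dt: float = DEFAULT_DT_US,
             seed: int = 0,
             record_stride: int = DEFAULT_RECORD_STRIDE,
             record_voltages: bool = True,
             stop_os_phases: int | None = DEFAULT_STOP_OS_PHASES,
             residual_sigma: float = DEFAULT_RESIDUAL_SIGMA) -> Trace:
    """Integrate the coupled network with fixed-step RK4.

    Runs until the Os cell completes stop_os_phases active phases or t_max
    is reached, whichever comes first (stop_os_phases=None disables the
    early stop).  Initial state: common silent-branch V1, seeded uniform V2
    jitter.  The same seed also draws the residual per-cell bias-current
    dispersion (the tuned chip's leftover mismatch; see
    DEFAULT_RESIDUAL_SIGMA).  Coupling terms use the previous accepted step
    (one-dt lag).
    """
    if dt <= 0 or dt > 3e-3:
        raise ValueError("dt must be positive and below the ~3e-3 us "
                         "explicit stability bound")
    n_steps = int(round(t_max / dt))
    n_cells = net.n_cells
    n_tot = n_cells + 1

    rng = np.random.default_rng(seed)
    v1 = np.full(n_tot, V1_INIT, dtype=float)
    jitter = V2_JITTER_FRACTION * V2_SWING
    v2 = V2_INIT_CENTER + rng.uniform(-jitter, jitter, size=n_tot)

    currents = [net.I_A, net.I_B, net.I_C, net.I_D, net.I_E]
    if residual_sigma > 0.0:
        disp = []
        for arr in currents:
            out = arr.copy()
            # grid cells only; Os stays at nominal (reference cell)
            out[:n_cells] *= 1.0 + rng.normal(0.0, residual_sigma,
                                              size=n_cells)
            disp.append(out)
        currents = disp

    max_rec = n_steps // record_stride + 1
    if record_voltages:
        v1_rec = np.empty((max_rec, n_tot), dtype=np.float32)
        v2_rec = np.empty((max_rec, n_tot), dtype=np.float32)
    else:
        v1_rec = np.empty((1, 1), dtype=np.float32)
        v2_rec = np.empty((1, 1), dtype=np.float32)
    v3_rec = np.empty((max_rec, n_tot), dtype=np.uint8)
    gi_rec = np.empty(max_rec, dtype=np.uint8)

    watch_idx = net.os_index if stop_os_phases else -1
    watch_phases = stop_os_phases if stop_os_phases else 0

    p = net.params
    i_a, i_b, i_c, i_d, i_e = currents
    status, steps_done, n_rec, _phases = _kernel.integrate_network(
        v1, v2, i_a, i_b, i_c, i_d, i_e, net.I_out,
        p.a, p.b, p.c, p.d, p.C1, p.C2,
        net.excitation.I_F, net.excitation.I_GI,
        net.neighbors, net.drives_gi, float(dt), n_steps,
        int(record_stride), bool(record_voltages),
        v1_rec, v2_rec, v3_rec, gi_rec,
        watch_idx, watch_phases, float(net.rail))
    if status == _kernel.STATUS_UNSTABLE:
        raise SimulationUnstableError(
            f"state diverged (|V| > 10 V) at t = {steps_done * dt:.4g} us; "
            f"reduce dt or check parameters")

    t = np.arange(n_rec) * (dt * record_stride)
    n = net.n_cells
    return Trace(
        t=t,
        V3=v3_rec[:n_rec, :n].astype(bool),
        GI=gi_rec[:n_rec].astype(bool),
        os_V1=(v1_rec[:n_rec, n].copy() if record_voltages
               else np.zeros(n_rec, dtype=np.float32)),
        os_V3=v3_rec[:n_rec, n].astype(bool),
        shape=(net.height, net.width),
        dt=dt, record_stride=record_stride,
        V1=v1_rec[:n_rec, :n] if record_voltages else None,
        V2=v2_rec[:n_rec, :n] if record_voltages else None,
    )


def _bool_windows(t: np.ndarray, flags: np.ndarray) -> list[tuple[float, float]]:
    """Maximal [t_on, t_off) intervals where flags is True."""
    if flags.size == 0:
        return []
    f = flags.astype(np.int8)
    d = np.diff(f)
    onsets = list(np.nonzero(d == 1)[0] + 1)
    offsets = list(np.nonzero(d == -1)[0] + 1)
    if f[0]:
        onsets.insert(0, 0)
    if f[-1]:
        offsets.append(flags.size)
    step = t[1] - t[0] if t.size > 1 else 0.0
    out = []
    for on, off in zip(onsets, offsets):
        t_off = t[off] if off < t.size else t[-1] + step
        out.append((float(t[on]), float(t_off)))
    return out


def active_windows(tr: Trace, cell) -> list[tuple[float, float]]:
    """Maximal half-open [t_on, t_off) intervals where the cell's binarized
    output V3 is high, ordered in time."""
    i = tr.flat_index(cell)
    return _bool_windows(tr.t, tr.V3[:, i])


class PeriodDuty(NamedTuple):
    period: float    # us, mean onset-to-onset gap over settled cycles
    duty: float      # active time / period
    capacity: int    # floor((1 - duty) / duty): max separable objects


def os_active_windows(tr: Trace) -> list[tuple[float, float]]:
    """Active windows of the auxiliary Os oscillator."""
    return _bool_windows(tr.t, tr.os_V3)


def measure_period_and_duty(tr: Trace, cell=None) -> PeriodDuty:
    """Oscillation period and duty cycle of one cell (default: Os).

    The first window is discarded as transient; period is the mean
    onset-to-onset gap, duty the mean active-window length over the period.
    The capacity floor((1-duty)/duty) is the duty-cycle bound on how many
    image objects can share the cycle by time multiplexing.
    """
    wins = (os_active_windows(tr) if cell is None
            else active_windows(tr, cell))
    # need >= 3 complete cycles => >= 4 onsets (first discarded as transient)
    if len(wins) < 4:
        raise InsufficientCyclesError(
            f"insufficient cycles: {len(wins)} active windows, need >= 4")
    wins = wins[1:]
    onsets = np.array([w[0] for w in wins])
    period = float(np.mean(np.diff(onsets)))
    active = float(np.mean([w[1] - w[0] for w in wins[:-1]]))
    duty = active / period
    capacity = int(math.floor((1.0 - duty) / duty)) if duty > 0 else 0
    return PeriodDuty(period=period, duty=duty, capacity=capacity)
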