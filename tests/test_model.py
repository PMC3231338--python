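"""Single-oscillator model: fast branch, rhs, nullclines, amplitude, OTA."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from sonsim.model import (
    OscillatorParams,
    OTAParams,
    amplitude_oracle,
    compute_nullclines,
    fast_branch_current,
    oscillation_period,
    oscillator_rhs,
    ota_transfer,
    simulate_oscillator,
)

P = OscillatorParams()

finite_v = st.floats(-2.0, 2.0, allow_nan=False)


class TestFastBranch:
    def test_zero_at_origin(self):
        assert fast_branch_current(0.0, P) == 0.0

    def test_saturates_to_negative_current(self):
        # tanh fully saturated far out: I_A - I_B = -0.8 uA
        assert fast_branch_current(50.0, P) == pytest.approx(-0.8, abs=1e-9)
        assert fast_branch_current(-50.0, P) == pytest.approx(0.8, abs=1e-9)

    @given(finite_v)
    def test_odd(self, v):
        assert fast_branch_current(-v, P) == pytest.approx(
            -fast_branch_current(v, P), abs=1e-12)

    def test_positive_local_maximum(self):
        # oracle: dense grid search over (0, 0.5)
        grid = np.linspace(1e-4, 0.5, 20001)
        vals = fast_branch_current(grid, P)
        i = int(np.argmax(vals))
        assert 0.05 < grid[i] < 0.2          # near V1 ~ 0.1 V
        assert vals[i] == pytest.approx(0.43676, rel=1e-3)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            fast_branch_current(float("nan"), P)


class TestRHS:
    def test_origin_fixed_point_unforced(self):
        assert oscillator_rhs((0.0, 0.0), 0.0, P) == (0.0, 0.0)

    def test_pure_drive_slew(self):
        # -1.5 uA into 0.05 pF = -30 V/us
        dv1, dv2 = oscillator_rhs((0.0, 0.0), -1.5, P)
        assert dv1 == pytest.approx(-30.0)
        assert dv2 == 0.0

    @given(finite_v, finite_v, st.floats(-4, 4, allow_nan=False))
    def test_odd_symmetry(self, v1, v2, it):
        d1, d2 = oscillator_rhs((v1, v2), it, P)
        m1, m2 = oscillator_rhs((-v1, -v2), -it, P)
        assert m1 == pytest.approx(-d1, abs=1e-9)
        assert m2 == pytest.approx(-d2, abs=1e-9)

    def test_rejects_bad_capacitance(self):
        with pytest.raises(ValueError):
            OscillatorParams(C1=-0.05)


class TestParams:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            OscillatorParams(I_A=2.5)  # needs I_A < I_B
        with pytest.raises(ValueError):
            OscillatorParams(a=2.0)    # needs a > b
        with pytest.raises(ValueError):
            OscillatorParams(C2=0.2)   # needs C2/C1 >= 10

    def test_dict_round_trip(self):
        d = P.to_dict()
        assert d["C1_pF"] == 0.05 and d["C2_pF"] == 1.1
        assert OscillatorParams.from_dict(d) == P


class TestNullclines:
    def test_pass_through_origin_unforced(self):
        nc = compute_nullclines(P, 0.0, np.linspace(-0.5, 0.5, 1001))
        i0 = np.argmin(np.abs(nc.v1))
        assert abs(nc.v1_nullcline_v2[i0]) < 1e-6
        assert abs(nc.v2_nullcline_v2[i0]) < 1e-6

    def test_two_folds_at_operating_point(self):
        nc = compute_nullclines(P, -1.5, np.linspace(-0.5, 0.5, 4001))
        v2 = nc.v1_nullcline_v2
        assert np.isfinite(v2).all()
        signs = np.sign(np.diff(v2))
        changes = int(np.sum(signs[1:] * signs[:-1] < 0))
        assert changes == 2

    def test_v2_nullcline_near_binary(self):
        # d = 500 makes the V2-nullcline a near-step around V1 = 0: just
        # outside a tiny neighborhood the required atanh argument leaves
        # (-1, 1) and the curve is marked absent, not clamped.
        nc = compute_nullclines(P, 0.0, np.array([-0.05, 0.0, 0.05]))
        assert np.isnan(nc.v2_nullcline_v2[0])
        assert nc.v2_nullcline_v2[1] == 0.0
        assert np.isnan(nc.v2_nullcline_v2[2])

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            compute_nullclines(P, 0.0, [])


class TestAmplitude:
    def test_operating_point_amplitude(self):
        # design value of the parameter set: 0.5 V (behavioral tolerance)
        amp = amplitude_oracle(P, -1.5)
        assert amp == pytest.approx(0.5, rel=0.2)

    def test_no_limit_cycle_without_n_shape(self):
        # shrinking I_A towards zero removes the N-shape
        p = OscillatorParams(I_A=0.01)
        assert amplitude_oracle(p, -1.5) is None

    def test_dt_convergence(self):
        a1 = amplitude_oracle(P, -1.5)
        a2 = amplitude_oracle(P, -1.5, dt=1e-4)
        assert abs(a2 - a1) / a1 < 1e-3
        p1 = oscillation_period(P, -1.5)
        p2 = oscillation_period(P, -1.5, dt=1e-4)
        assert abs(p2 - p1) / p1 < 1e-3

    def test_boundedness(self):
        # trajectories stay inside the supply rails for |I_T| <= 4 uA
        for it in (-4.0, -1.5, 0.0, 4.0):
            _t, v1, v2 = simulate_oscillator(P, it, t_max=10.0)
            assert np.max(np.abs(v1)) <= 1.5 + 1e-9
            assert np.max(np.abs(v2)) <= 1.5 + 1e-9

    def test_limit_cycle_brackets_nullcline_folds(self):
        # fast-slow consistency: the settled V1 extrema bracket the two
        # fold V1-locations of the V1-nullcline
        nc = compute_nullclines(P, -1.5, np.linspace(-0.5, 0.5, 4001))
        dv = np.diff(nc.v1_nullcline_v2)
        fold_idx = np.nonzero(np.sign(dv[1:]) * np.sign(dv[:-1]) < 0)[0]
        folds = nc.v1[fold_idx + 1]
        _t, v1, _ = simulate_oscillator(P, -1.5)
        tail = v1[v1.size // 2:]
        assert tail.min() < folds.min() and tail.max() > folds.max()


class TestOTA:
    Q = OTAParams()

    def test_zero_at_origin(self):
        assert ota_transfer(0.0, self.Q, "exact") == 0.0
        assert ota_transfer(0.0, self.Q, "tanh") == 0.0

    def test_clamps_at_saturation_voltage(self):
        assert ota_transfer(self.Q.sigma, self.Q, "exact") == self.Q.I_sat
        assert ota_transfer(-2 * self.Q.sigma, self.Q,
                            "exact") == -self.Q.I_sat

    @given(st.floats(-0.6, 0.6, allow_nan=False))
    def test_odd(self, vr):
        io = ota_transfer(vr, self.Q, "exact")
        assert ota_transfer(-vr, self.Q, "exact") == pytest.approx(
            -io, abs=1e-9)

    def test_round_trip_through_inverse(self):
        for io in (-0.9, -0.3, 0.0, 0.5, 0.99):
            vr = self.Q.inverse_transfer(io)
            assert ota_transfer(vr, self.Q, "exact") == pytest.approx(
                io, abs=1e-6)

    def test_monotone(self):
        vr = np.linspace(-0.5, 0.5, 101)
        io = ota_transfer(vr, self.Q, "exact")
        assert np.all(np.diff(io) >= -1e-12)

    def test_tanh_approximation_deviation(self):
        # sweep oracle: the gain-matched tanh tracks the exact curve at the
        # origin exactly and deviates most near saturation
        vr = np.linspace(-self.Q.sigma, self.Q.sigma, 801)
        ex = ota_transfer(vr, self.Q, "exact")
        th = ota_transfer(vr, self.Q, "tanh")
        dev = np.max(np.abs(ex - th)) / self.Q.I_sat
        assert dev < 0.2
        # slopes agree at the origin
        mid = len(vr) // 2
        s_ex = (ex[mid + 1] - ex[mid - 1]) / (vr[mid + 1] - vr[mid - 1])
        s_th = (th[mid + 1] - th[mid - 1]) / (vr[mid + 1] - vr[mid - 1])
        assert s_th == pytest.approx(s_ex, rel=1e-3)

    def test_sigma_consistency_enforced(self):
        with pytest.raises(ValueError):
            OTAParams(sigma=0.123)
        with pytest.raises(ValueError):
            OTAParams(n_r=2.5)
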