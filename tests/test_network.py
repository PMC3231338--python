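"""Network assembly, excitation arithmetic, simulation and trace analysis."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from sonsim import (
    ExcitationParams,
    OscillatorParams,
    build_network,
    external_current,
    gi_state,
    simulate,
)
from sonsim.network import (
    InsufficientCyclesError,
    Trace,
    active_windows,
    measure_period_and_duty,
    os_active_windows,
)

E = ExcitationParams()


def make_trace(v3_grid, os_v3=None, dt_rec=0.01, shape=None):
    """Craft a Trace from a (n_rec, n_cells) boolean activity pattern."""
    v3 = np.asarray(v3_grid, dtype=bool)
    n_rec, n_cells = v3.shape
    if shape is None:
        shape = (1, n_cells)
    if os_v3 is None:
        os_v3 = np.zeros(n_rec, dtype=bool)
    return Trace(t=np.arange(n_rec) * dt_rec, V3=v3,
                 GI=v3.any(axis=1), os_V1=np.zeros(n_rec, np.float32),
                 os_V3=np.asarray(os_v3, dtype=bool), shape=shape,
                 dt=dt_rec, record_stride=1)


class TestBuildNetwork:
    def test_single_cell(self):
        net = build_network(np.ones((1, 1), np.uint8))
        assert net.n_cells == 1
        assert net.I_out[0] == pytest.approx(1.0)
        assert (net.neighbors[0] == -1).all()
        # Os: excited, no neighbors, silent on the GI drive side
        assert net.I_out[net.os_index] == pytest.approx(1.0)
        assert not net.drives_gi[net.os_index]

    def test_neighbor_degrees(self):
        net = build_network(np.ones((32, 32), np.uint8))
        deg = (net.neighbors[:net.n_cells] >= 0).sum(axis=1).reshape(32, 32)
        assert deg[0, 0] == 2 and deg[0, 5] == 3 and deg[5, 5] == 4
        assert (deg[1:-1, 1:-1] == 4).all()
        # adjacency is symmetric and irreflexive
        nbr = net.neighbors[:net.n_cells]
        for i in range(net.n_cells):
            for j in nbr[i]:
                if j >= 0:
                    assert j != i
                    assert i in nbr[j]

    def test_checkerboard_polarity(self):
        img = np.indices((8, 8)).sum(axis=0) % 2
        net = build_network(img.astype(np.uint8))
        iout = net.I_out[:net.n_cells]
        # every object cell's neighbors are all background
        for i in np.nonzero(iout > 0)[0]:
            for j in net.neighbors[i]:
                if j >= 0:
                    assert iout[j] == pytest.approx(-1.0)

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            build_network(np.zeros((0, 4)))
        with pytest.raises(ValueError):
            build_network(np.full((2, 2), 2))


class TestExternalCurrent:
    def test_isolated_object_pixel(self):
        # the single-oscillator operating point: 1 - 2.5 = -1.5 uA
        assert external_current(1.0, [0, 0, 0, 0], False, E) == \
            pytest.approx(-1.5)

    def test_recruited_object_pixel(self):
        assert external_current(1.0, [1, 0, 0, 0], True, E) == \
            pytest.approx(-0.92)

    def test_background_under_inhibition(self):
        assert external_current(-1.0, [0, 0, 0, 0], True, E) == \
            pytest.approx(-3.72)

    @given(st.lists(st.booleans(), min_size=1, max_size=4))
    def test_or_gated_synapse(self, flags):
        # one I_F regardless of how many neighbors are active
        it = external_current(1.0, flags, False, E)
        expected = 1.0 + (0.8 if any(flags) else 0.0) - 2.5
        assert it == pytest.approx(expected)


class TestGIState:
    def test_silent_grid(self):
        assert gi_state([-0.3, -0.5, -1.0]) == 0

    def test_single_active_cell(self):
        assert gi_state([-0.3, 1e-6, -1.0]) == 1

    def test_zero_is_inactive(self):
        # Hev(0) = 0
        assert gi_state([0.0, -0.1]) == 0


class TestSimulate:
    def test_single_pixel_oscillates_at_half_volt(self, single_pixel_trace):
        tr = single_pixel_trace
        assert np.max(np.abs(tr.V1[:, 0])) == pytest.approx(0.5, rel=0.2)
        assert len(active_windows(tr, 0)) >= 3

    def test_background_image_silent(self, background_trace):
        tr = background_trace
        assert not tr.V3.any()
        assert not tr.GI.any()
        # while the Os cell free-runs
        assert len(os_active_windows(tr)) >= 2

    def test_dt_step_limit(self):
        net = build_network(np.ones((1, 1), np.uint8))
        with pytest.raises(ValueError):
            simulate(net, dt=0.01)

    def test_seed_reproducibility(self):
        net = build_network(np.ones((2, 2), np.uint8))
        t1 = simulate(net, t_max=5.0, seed=7, stop_os_phases=None)
        t2 = simulate(net, t_max=5.0, seed=7, stop_os_phases=None)
        assert np.array_equal(t1.V3, t2.V3)
        assert np.array_equal(t1.V1, t2.V1)

    def test_two_pixel_object_synchronizes(self):
        img = np.zeros((3, 4), np.uint8)
        img[1, 1:3] = 1
        net = build_network(img)
        tr = simulate(net, t_max=40.0, seed=5, stop_os_phases=6)
        wa = active_windows(tr, (1, 1))
        wb = active_windows(tr, (1, 2))
        assert len(wa) >= 3 and len(wb) >= 3
        # settled windows of the two member cells overlap strongly
        a_on, a_off = wa[-1]
        best = 0.0
        for b_on, b_off in wb:
            inter = max(0.0, min(a_off, b_off) - max(a_on, b_on))
            union = (a_off - a_on) + (b_off - b_on) - inter
            best = max(best, inter / union)
        assert best >= 0.9

    def test_runs_without_global_inhibitor(self):
        # disabling GI is allowed (desynchronization is then NOT expected);
        # the simulation must simply complete
        img = np.zeros((6, 6), np.uint8)
        img[1:3, 1:3] = 1
        img[4:6, 4:6] = 1
        e = ExcitationParams(I_GI=0.0)
        net = build_network(img, e)
        tr = simulate(net, t_max=10.0, seed=8, stop_os_phases=None)
        assert tr.t[-1] >= 10.0 - tr.dt * tr.record_stride

    def test_translation_equivariance(self):
        # translating the image translates the settled partition (label
        # numbers may differ; phases are seed-controlled)
        from sonsim import label_by_synchrony
        from .conftest import partitions_equal

        base = np.zeros((10, 10), np.uint8)
        base[1:4, 1:3] = 1
        base[2:4, 6:9] = 1
        shifted = np.roll(base, (3, 1), axis=(0, 1))
        maps = []
        for img in (base, shifted):
            net = build_network(img)
            tr = simulate(net, t_max=60.0, seed=17, record_voltages=False,
                          stop_os_phases=6)
            labels, _ = label_by_synchrony(tr)
            maps.append(labels)
        assert partitions_equal(np.roll(maps[0], (3, 1), axis=(0, 1)),
                                maps[1])

    def test_active_window_dt_convergence(self):
        net = build_network(np.ones((1, 1), np.uint8))
        tr1 = simulate(net, t_max=20.0, dt=2e-4, seed=6,
                       record_stride=2, stop_os_phases=None)
        tr2 = simulate(net, t_max=20.0, dt=1e-4, seed=6,
                       record_stride=4, stop_os_phases=None)
        w1 = np.array(active_windows(tr1, 0)[-3:])
        w2 = np.array(active_windows(tr2, 0)[-3:])
        period = measure_period_and_duty(tr1, 0).period
        assert np.max(np.abs(w1 - w2)) < 0.01 * period


class TestActiveWindows:
    def test_silent_cell_empty(self):
        tr = make_trace(np.zeros((10, 2)))
        assert active_windows(tr, 0) == []

    def test_windows_ordered_half_open(self):
        pattern = np.zeros((10, 1), dtype=bool)
        pattern[2:4, 0] = True
        pattern[6:9, 0] = True
        tr = make_trace(pattern)
        wins = active_windows(tr, 0)
        assert wins == [(pytest.approx(0.02), pytest.approx(0.04)),
                        (pytest.approx(0.06), pytest.approx(0.09))]
        onsets = [w[0] for w in wins]
        assert onsets == sorted(onsets)


class TestPeriodDuty:
    def test_requires_three_cycles(self):
        pattern = np.zeros((20, 1), dtype=bool)
        pattern[2:4, 0] = True
        pattern[10:12, 0] = True
        tr = make_trace(pattern)
        with pytest.raises(InsufficientCyclesError):
            measure_period_and_duty(tr, 0)

    def test_period_of_single_oscillator(self, single_pixel_trace):
        pd = measure_period_and_duty(single_pixel_trace, 0)
        # timescale: about 1 us (order of magnitude)
        assert 0.2 < pd.period < 5.0
        assert 0.0 < pd.duty < 0.5
        assert pd.capacity >= 1

    def test_period_time_shift_invariant(self, single_pixel_trace):
        tr = single_pixel_trace
        shifted = Trace(t=tr.t + 3.3, V3=tr.V3, GI=tr.GI, os_V1=tr.os_V1,
                        os_V3=tr.os_V3, shape=tr.shape, dt=tr.dt,
                        record_stride=tr.record_stride, V1=tr.V1, V2=tr.V2)
        a = measure_period_and_duty(tr, 0)
        b = measure_period_and_duty(shifted, 0)
        assert a.period == pytest.approx(b.period)

    def test_period_matches_slow_variable_cycle(self, single_pixel_trace):
        # independent estimator: upward crossings of V2 through its midrange
        tr = single_pixel_trace
        v2 = tr.V2[:, 0].astype(float)
        mid = 0.5 * (v2.max() + v2.min())
        s = v2 > mid
        idx = np.nonzero(~s[:-1] & s[1:])[0]
        crossings = tr.t[idx + 1]
        assert crossings.size >= 3
        p_v2 = float(np.mean(np.diff(crossings[1:])))
        p_v3 = measure_period_and_duty(tr, 0).period
        assert p_v3 == pytest.approx(p_v2, rel=0.02)
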