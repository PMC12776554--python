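"""Permeation detection, block currents, Poisson intervals, gate metrics."""

import numpy as np
import pandas as pd
import pytest

from porekinetics import pathway_profiles as pp
from porekinetics import permeation_analysis as pa
from porekinetics.core_io import Trajectory


def _ion_traj(z_traces):
    """Trajectory whose ions move only along z (one row per ion trace)."""
    z = np.atleast_2d(np.asarray(z_traces, float))
    n_ions, n_frames = z.shape
    coords = np.zeros((n_frames, n_ions, 3))
    coords[:, :, 2] = z.T
    return Trajectory(times=0.25 * (1 + np.arange(n_frames)), coords=coords,
                      species=np.array(["ion:Cl"] * n_ions),
                      ids=np.arange(n_ions),
                      box=np.array([20.0, 20.0, 140.0]))


PATH = pp.straight_path(-60.0, 60.0, 0.5)


class TestDetectPermeation:
    def test_oscillation_without_traversal_is_no_event(self):
        events = pa.detect_permeation(
            _ion_traj([[-20, -5, -20, -5, -20, -5]]), PATH, -15.0, 15.0)
        assert len(events) == 0

    def test_single_outward_traversal(self):
        events = pa.detect_permeation(
            _ion_traj([[-20, -5, 5, 20]]), PATH, -15.0, 15.0)
        assert events.n_outward == 1
        assert events.n_inward == 0
        assert events.rows.entry_time[0] == pytest.approx(0.5)
        assert events.rows.exit_time[0] == pytest.approx(1.0)

    def test_reentries_do_not_double_count(self):
        # below -> inside -> (wiggle inside) -> above: exactly one event
        events = pa.detect_permeation(
            _ion_traj([[-20, -5, 5, -5, 5, 20]]), PATH, -15.0, 15.0)
        assert events.n_outward == 1

    def test_return_to_origin_is_no_event(self):
        events = pa.detect_permeation(
            _ion_traj([[-20, 0, -20, 0, 20]]), PATH, -15.0, 15.0)
        # second excursion completes outward; first does not
        assert events.n_outward == 1
        assert events.n_inward == 0

    def test_direct_bulk_jump_is_not_an_event(self):
        # a periodic wrap jumps bulk-to-bulk with no interior frame
        events = pa.detect_permeation(
            _ion_traj([[-20, 20, -20]]), PATH, -15.0, 15.0)
        assert len(events) == 0

    def test_bounds_must_lie_inside_path(self):
        with pytest.raises(ValueError, match="path"):
            pa.detect_permeation(_ion_traj([[0.0, 1.0]]), PATH, -80.0, 15.0)

    def test_matches_bruteforce_on_random_walks(self, random_walk_traces):
        traces = random_walk_traces[:100]
        events = pa.detect_permeation(_ion_traj(traces), PATH, -15.0, 15.0)
        for i, trace in enumerate(traces):
            out_bf, in_bf = pa.count_crossings_bruteforce(trace, -15.0, 15.0)
            rows = events.rows[events.rows.id == i]
            assert (rows.direction == "outward").sum() == out_bf
            assert (rows.direction == "inward").sum() == in_bf

    def test_net_count_bookkeeping(self, random_walk_traces):
        events = pa.detect_permeation(_ion_traj(random_walk_traces[:50]),
                                      PATH, -15.0, 15.0)
        assert events.net_outward == events.n_outward - events.n_inward


def _events(rows):
    return pa.EventTable(rows=pd.DataFrame(rows, columns=pa.EventTable.COLUMNS),
                         s_lo=-15.0, s_hi=15.0)


class TestBlockCurrents:
    def test_single_event_current_arithmetic(self):
        ev = _events([(0, "ion:Cl", "outward", 10.0, 50.0)])
        currents = pa.block_currents(ev, total_time_ns=200.0, block_ns=200.0)
        assert currents.shape == (1,)
        # I = e / 200 ns = 1.602e-19 C / 2e-7 s = 0.801 pA
        assert currents[0] == pytest.approx(0.801, rel=1e-3)
        assert currents[0] == pytest.approx(pa.PA_PER_EVENT_PER_NS / 200.0)

    def test_zero_events_zero_current(self):
        ev = _events([])
        assert np.all(pa.block_currents(ev, 400.0) == 0.0)

    def test_signed_net_count(self):
        ev = _events([(0, "ion:Cl", "outward", 1.0, 2.0),
                      (1, "ion:Cl", "outward", 3.0, 4.0),
                      (2, "ion:Cl", "inward", 5.0, 6.0)])
        signed = pa.block_currents(ev, 200.0, signed=True)
        unsigned = pa.block_currents(ev, 200.0, signed=False)
        assert signed[0] == pytest.approx(1 * pa.PA_PER_EVENT_PER_NS / 200.0)
        assert unsigned[0] == pytest.approx(3 * pa.PA_PER_EVENT_PER_NS / 200.0)

    def test_event_credited_to_exit_block(self):
        ev = _events([(0, "ion:Cl", "outward", 150.0, 250.0)])
        currents = pa.block_currents(ev, 400.0, block_ns=200.0)
        assert currents[0] == 0.0
        assert currents[1] > 0.0


class TestConductance:
    def test_arithmetic(self):
        g, _ = pa.conductance([0.801], 350.0)
        assert g == pytest.approx(2.2886, rel=1e-3)

    def test_zero_currents(self):
        g, spread = pa.conductance([0.0, 0.0, 0.0], 100.0)
        assert g == 0.0

    def test_antisymmetric_currents_give_equal_conductance(self):
        g_pos, _ = pa.conductance([1.0, 1.2], 100.0)
        g_neg, _ = pa.conductance([-1.0, -1.2], -100.0)
        assert g_pos == pytest.approx(g_neg)

    def test_zero_voltage_rejected(self):
        with pytest.raises(ValueError):
            pa.conductance([1.0], 0.0)


class TestPoissonCI:
    def test_zero_count_interval(self):
        lo, hi = pa.poisson_ci(0)
        assert lo == 0.0
        assert hi == pytest.approx(3.689, abs=1e-3)

    def test_frozen_chi_square_values(self):
        lo, hi = pa.poisson_ci(54)
        assert lo == pytest.approx(40.56, abs=0.01)
        assert hi == pytest.approx(70.45, abs=0.01)

    def test_exact_interval_coverage_guarantee(self):
        rng = np.random.default_rng(0)
        draws = rng.poisson(5.0, 10_000)
        cis = {n: pa.poisson_ci(int(n)) for n in np.unique(draws)}
        cov = np.mean([cis[n][0] <= 5.0 <= cis[n][1] for n in draws])
        assert cov >= 0.94

    def test_score_interval_and_bad_input(self):
        lo, hi = pa.poisson_ci(0, method="score")
        assert lo == 0.0 and hi > 0.0
        with pytest.raises(ValueError):
            pa.poisson_ci(-1)
        with pytest.raises(ValueError):
            pa.poisson_ci(5, method="nosuch")


class TestFitIV:
    def test_exact_line_recovered(self):
        V = np.array([-350.0, -175.0, 175.0, 350.0])
        curve = pa.fit_iv(pd.DataFrame({"V_mV": V, "current_pA": 0.0044 * V}))
        assert curve.slope_pS == pytest.approx(4.4)
        assert curve.intercept_pA == pytest.approx(0.0, abs=1e-12)

    def test_two_points_exact_interpolation(self):
        curve = pa.fit_iv([(100.0, 1.0), (-100.0, -1.0)])
        assert curve.slope_pS == pytest.approx(10.0)

    def test_confidence_bounds_bracket_current(self):
        pts = pd.DataFrame({"V_mV": [100.0, 200.0, -100.0],
                            "n_events": [10, 25, 12],
                            "time_ns": [1000.0, 1000.0, 1000.0]})
        pts["current_pA"] = (np.sign(pts.V_mV) * pts.n_events
                             * pa.PA_PER_EVENT_PER_NS / pts.time_ns)
        curve = pa.fit_iv(pts)
        t = curve.table
        assert ((t.ci_low <= t.current_pA) & (t.current_pA <= t.ci_high)).all()

    def test_slope_estimator_unbiased(self):
        rng = np.random.default_rng(11)
        V = np.array([-300.0, -150.0, 150.0, 300.0])
        slopes = []
        for _ in range(1000):
            I = 0.0044 * V + rng.normal(0, 0.1, V.size)
            slopes.append(pa.fit_iv(
                pd.DataFrame({"V_mV": V, "current_pA": I})).slope_pS)
        se = np.std(slopes) / np.sqrt(len(slopes))
        assert abs(np.mean(slopes) - 4.4) < 3 * se

    def test_single_voltage_rejected(self):
        with pytest.raises(ValueError):
            pa.fit_iv([(100.0, 1.0), (100.0, 1.1)])


class TestWaterFlux:
    def _water_traj(self, z_trace):
        z = np.asarray(z_trace, float)
        coords = np.zeros((z.size, 1, 3))
        coords[:, 0, 2] = z
        return Trajectory(times=0.25 * (1 + np.arange(z.size)), coords=coords,
                          species=np.array(["water"]), ids=np.array([0]),
                          box=np.array([20.0, 20.0, 140.0]))

    def test_static_water_zero_flux(self):
        traj = self._water_traj([0.5] * 10)
        assert pa.water_flux(traj, PATH) == 0.0

    def test_single_crossing_rate(self):
        traj = self._water_traj([0.5, 0.5, 5.0, 5.0, 5.0])
        rate = pa.water_flux(traj, PATH, bin_width=3.5, boundary_at=0.0)
        assert rate == pytest.approx(1.0 / 1.0)  # 1 exit / 1 ns span


class TestContactsAndGates:
    def _protein_ion_traj(self, ion_z, protein_pos=(0.0, 0.0, 0.0),
                          n_frames=None):
        ion_z = np.asarray(ion_z, float)
        n_frames = n_frames or ion_z.size
        coords = np.zeros((n_frames, 2, 3))
        coords[:, 0, :] = protein_pos
        coords[:, 1, 2] = ion_z
        return Trajectory(times=0.25 * (1 + np.arange(n_frames)),
                          coords=coords,
                          species=np.array(["protein", "ion:Cl"]),
                          ids=np.array([0, 1]),
                          box=np.array([20.0, 20.0, 60.0]),
                          resnames=np.array(["LEU", "CLA"]),
                          resids=np.array([547, 9000]),
                          atomnames=np.array(["CB", "CLA"]))

    def test_contact_fraction_and_dwell(self):
        # contact (|z| <= 3.5) in frames 3..7 of 10 -> 50%, one 1.25 ns dwell
        z = np.array([9, 9, 9, 1, 1, 1, 1, 1, 9, 9], float)
        traj = self._protein_ion_traj(z)
        frac, dwells = pa.contact_stats(traj, [547])[547]
        assert frac == pytest.approx(0.5)
        assert dwells == [pytest.approx(1.25)]

    def test_no_contact(self):
        traj = self._protein_ion_traj(np.full(10, 9.0))
        frac, dwells = pa.contact_stats(traj, [547])[547]
        assert frac == 0.0
        assert dwells == []

    def test_two_disjoint_contact_runs(self):
        z = np.array([1, 1, 9, 9, 1, 1, 1, 9], float)
        frac, dwells = pa.contact_stats(self._protein_ion_traj(z), [547])[547]
        assert len(dwells) == 2

    def test_gate_min_distance(self):
        coords = np.zeros((1, 2, 3))
        coords[0, 1, 2] = 9.0
        traj = Trajectory(times=[0.25], coords=coords,
                          species=np.array(["protein", "protein"]),
                          ids=np.array([0, 1]),
                          box=np.array([20.0, 20.0, 60.0]),
                          resnames=np.array(["LEU", "ILE"]),
                          resids=np.array([547, 641]),
                          atomnames=np.array(["CB", "CD1"]))
        series = pa.gate_metrics(traj, 547, 641)
        assert series.values[0] == pytest.approx(9.0)


def _helix_ca(n_res, bend_at=None, bend_deg=0.0):
    """Ideal Calpha helix along z, optionally bent at one residue."""
    idx = np.arange(n_res, dtype=float)
    omega = np.deg2rad(100.0)
    pts = np.column_stack([2.3 * np.cos(omega * idx),
                           2.3 * np.sin(omega * idx), 1.5 * idx])
    if bend_at is not None and bend_deg:
        th = np.deg2rad(bend_deg)
        R = np.array([[1, 0, 0],
                      [0, np.cos(th), -np.sin(th)],
                      [0, np.sin(th), np.cos(th)]])
        pivot = pts[bend_at]
        pts[bend_at + 1:] = pivot + (pts[bend_at + 1:] - pivot) @ R.T
    return pts


def _helix_traj(pts):
    n = len(pts)
    return Trajectory(times=[0.25], coords=pts[None],
                      species=np.array(["protein"] * n),
                      ids=np.arange(n), box=np.array([60.0, 60.0, 80.0]),
                      resnames=np.array(["ALA"] * n),
                      resids=np.arange(1, n + 1),
                      atomnames=np.array(["CA"] * n))


class TestKinkAngle:
    def test_straight_helix_is_straight(self):
        traj = _helix_traj(_helix_ca(17))
        series = pa.kink_angle(traj, resid=9)
        assert series.values[0] == pytest.approx(180.0, abs=2.0)

    def test_constructed_bend_recovered(self):
        traj = _helix_traj(_helix_ca(17, bend_at=8, bend_deg=30.0))
        series = pa.kink_angle(traj, resid=9)
        assert series.values[0] == pytest.approx(150.0, abs=3.0)

    def test_insufficient_flank_raises(self):
        traj = _helix_traj(_helix_ca(17))
        with pytest.raises(ValueError, match="flank"):
            pa.kink_angle(traj, resid=2)
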