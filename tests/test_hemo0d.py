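import numpy as np
import pytest

from conftest import constant_inflow, single_rcr
from pulmshear.arterial_tree import generate_tree, outlets
from pulmshear.hemo0d import (
    BloodModel,
    FlowWaveform,
    SolverConfig,
    SolverInstabilityError,
    make_inflow,
    segment_resistance,
    solve,
    summarize_pressures,
    write_solution,
)
from pulmshear.units import LPM, MMHG
from pulmshear.windkessel import (
    assemble_rcr,
    distribute_compliance,
    distribute_resistance,
)


class TestMakeInflow:
    def test_peak_flow_closed_form(self):
        wf = make_inflow(5.0, 60.0, systolic_fraction=0.35)
        # Q_peak = CO_cgs * pi * T / (2 Ts) = 83.333 * pi / 0.7
        assert wf.flow.max() == pytest.approx(373.99, rel=5e-3)

    def test_mean_equals_cardiac_output_exactly(self):
        for co, hr in [(5.0, 60.0), (3.2, 88.0), (7.7, 64.0)]:
            wf = make_inflow(co, hr)
            assert wf.mean_flow == pytest.approx(co * LPM, rel=1e-12)

    def test_long_systole_limit(self):
        wf = make_inflow(5.0, 60.0, systolic_fraction=0.999)
        assert wf.flow.max() == pytest.approx(5.0 * LPM * np.pi / 2, rel=2e-3)

    @pytest.mark.parametrize("kwargs", [
        {"CO": 0.0, "HR": 60}, {"CO": 5, "HR": -1},
        {"CO": 5, "HR": 60, "systolic_fraction": 0.0},
        {"CO": 5, "HR": 60, "systolic_fraction": 1.0},
    ])
    def test_invalid_parameters(self, kwargs):
        with pytest.raises(ValueError):
            make_inflow(**kwargs)

    def test_nonuniform_grid_rejected(self):
        with pytest.raises(ValueError):
            FlowWaveform(period=1.0, times=np.array([0.0, 0.1, 0.5]), flow=np.ones(3))


class TestSegmentResistance:
    def test_hand_value(self, blood):
        # mu = 0.035 poise, L = 5 cm, r = 1 cm -> 1.4/pi
        assert segment_resistance(blood, 5.0, 2.0) == pytest.approx(1.4 / np.pi, rel=1e-12)

    def test_quartic_radius_law(self, blood):
        assert segment_resistance(blood, 5.0, 4.0) == pytest.approx(
            segment_resistance(blood, 5.0, 2.0) / 16, rel=1e-12
        )

    def test_zero_length(self, blood):
        assert segment_resistance(blood, 0.0, 2.0) == 0.0


class TestSolve:
    def test_dc_windkessel_exact(self, single_segment_tree, tight_solver):
        Q, Rp, Rd, Pd = 80.0, 10.0, 90.0, 1000.0
        rcr = single_rcr(Rp, 1e-3, Rd, distal=Pd)
        sol = solve(single_segment_tree, rcr, constant_inflow(Q), config=tight_solver)
        r_seg = segment_resistance(BloodModel(), 1e-6, 2.0)
        expected = Q * (Rp + Rd + r_seg) + Pd
        assert sol.converged and sol.cycles_run >= 6
        assert np.allclose(sol.root_pressure, expected, rtol=1e-5)

    def test_symmetric_outlets_identical_flows(self, symmetric_tree):
        outs = outlets(symmetric_tree)
        d = np.array([s.diameter for s in outs])
        rcr = assemble_rcr([s.id for s in outs], distribute_resistance(d, 150.0),
                           distribute_compliance(d, 2e-3), 0.1, 9.0)
        sol = solve(symmetric_tree, rcr, make_inflow(5.2, 75.0))
        flows = [sol.flows[s.id] for s in outs]
        for f in flows[1:]:
            assert np.allclose(f, flows[0], rtol=1e-9, atol=1e-9)

    def test_sinusoidal_drive_matches_impedance_modulus(self, single_segment_tree, tight_solver):
        Rp, Rd, C = 20.0, 100.0, 5e-4
        T = 0.8
        omega = 2 * np.pi / T
        n = 4000
        t = np.arange(n) * T / n
        q0, qa = 60.0, 20.0
        wf = FlowWaveform(period=T, times=t, flow=q0 + qa * np.sin(omega * t))
        sol = solve(single_segment_tree, single_rcr(Rp, C, Rd), wf, config=tight_solver)
        amp = (sol.root_pressure.max() - sol.root_pressure.min()) / 2
        z_mod = abs(Rp + Rd / (1 + 1j * omega * Rd * C))
        assert amp == pytest.approx(qa * z_mod, rel=0.01)

    def test_cycle_mean_flow_conservation(self):
        tree = generate_tree(3.0, 3, 2.25, 0.3, seed=5)
        outs = outlets(tree)
        d = np.array([s.diameter for s in outs])
        rcr = assemble_rcr([s.id for s in outs], distribute_resistance(d, 300.0),
                           distribute_compliance(d, 1.5e-3), 0.1, 9.0)
        cfg = SolverConfig(max_cycles=60, periodicity_tol=1e-5)
        sol = solve(tree, rcr, make_inflow(5.15, 75.0), config=cfg)
        assert sol.converged
        q_in = np.mean(sol.flows[tree.root_id])
        q_out = sum(np.mean(sol.flows[s.id]) for s in outs)
        assert q_out == pytest.approx(q_in, rel=0.005)

    def test_grid_refinement_mpap_stable(self, symmetric_tree):
        outs = outlets(symmetric_tree)
        d = np.array([s.diameter for s in outs])
        rcr = assemble_rcr([s.id for s in outs], distribute_resistance(d, 150.0),
                           distribute_compliance(d, 2e-3), 0.1, 9.0)
        inflow = make_inflow(5.2, 75.0, n_samples=4000)
        mpaps = []
        for dt in (1e-3, 5e-4):
            cfg = SolverConfig(dt=dt, max_cycles=60, periodicity_tol=1e-6)
            sol = solve(symmetric_tree, rcr, inflow, config=cfg)
            mpaps.append(summarize_pressures(sol)[2])
        assert abs(mpaps[1] - mpaps[0]) / mpaps[0] < 0.002

    def test_resistance_scaling_scales_gradient(self, symmetric_tree):
        outs = outlets(symmetric_tree)
        d = np.array([s.diameter for s in outs])
        inflow = make_inflow(5.2, 75.0)
        cfg = SolverConfig(max_cycles=60, periodicity_tol=1e-6)
        means = []
        pd_mmhg = 9.0
        for k in (1.0, 2.0):
            # scale both segment and outlet resistances by k via blood viscosity
            rcr = assemble_rcr([s.id for s in outs], distribute_resistance(d, k * 150.0),
                               distribute_compliance(d, 2e-3), 0.1, pd_mmhg)
            blood = BloodModel(viscosity=0.0035 * k)
            sol = solve(symmetric_tree, rcr, inflow, blood=blood, config=cfg)
            means.append(np.mean(sol.root_pressure) - pd_mmhg * MMHG)
        assert means[1] == pytest.approx(2.0 * means[0], rel=1e-3)

    def test_pressure_ordering(self, symmetric_tree):
        outs = outlets(symmetric_tree)
        d = np.array([s.diameter for s in outs])
        rcr = assemble_rcr([s.id for s in outs], distribute_resistance(d, 150.0),
                           distribute_compliance(d, 2e-3), 0.1, 9.0)
        sol = solve(symmetric_tree, rcr, make_inflow(5.2, 75.0))
        assert np.mean(sol.root_pressure) >= rcr.distal_pressure

    def test_instability_raises_named_error(self):
        # with several outlets, a tiny compliance makes the explicit
        # flow-redistribution coupling blow up at dt=1e-3
        tree = generate_tree(3.0, 1, asymmetry=0.0, seed=0)
        outs = outlets(tree)
        rcr = assemble_rcr([s.id for s in outs], np.array([200.0, 200.0]),
                           np.array([1e-7, 1e-7]), 0.01, 9.0)
        with pytest.raises(SolverInstabilityError, match="cycle"):
            solve(tree, rcr, make_inflow(5.0, 75.0))

    def test_missing_outlet_rejected(self, symmetric_tree):
        rcr = single_rcr(10.0, 1e-3, 90.0)
        with pytest.raises(ValueError, match="missing outlets"):
            solve(symmetric_tree, rcr, make_inflow(5.0, 75.0))


class TestSummarize:
    def _solution_with_root_pressure(self, p):
        from pulmshear.hemo0d import HemoSolution

        n = len(p)
        return HemoSolution(
            times=np.arange(n) / n, pressures={"MPA": np.asarray(p, float)},
            flows={"MPA": np.zeros(n)}, root_id="MPA", cycles_run=6,
            periodicity_error=0.0, converged=True,
        )

    def test_constant_pressure(self):
        sol = self._solution_with_root_pressure(np.full(100, 20 * MMHG))
        assert summarize_pressures(sol) == pytest.approx((20.0, 20.0, 20.0))

    def test_sinusoid(self):
        t = np.arange(1000) / 1000
        p = (20 + 5 * np.sin(2 * np.pi * t)) * MMHG
        spap, dpap, mpap = summarize_pressures(sol := self._solution_with_root_pressure(p))
        assert spap == pytest.approx(25.0, rel=1e-4)
        assert dpap == pytest.approx(15.0, rel=1e-4)
        assert mpap == pytest.approx(20.0, rel=1e-9)
        assert dpap <= mpap <= spap

    def test_export_round_readable(self, single_segment_tree, tmp_path):
        import pandas as pd

        sol = solve(single_segment_tree, single_rcr(10.0, 1e-3, 90.0),
                    make_inflow(5.0, 75.0))
        path = tmp_path / "sol.csv"
        write_solution(sol, path)
        df = pd.read_csv(path, comment="#")
        assert set(df.columns) == {"segment_id", "time_s", "pressure_dyn_cm2", "flow_cm3_s"}
        assert len(df) == len(sol.times)
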