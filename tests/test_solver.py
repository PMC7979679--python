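import math

import numpy as np
import pytest

from pulsetwin import _kernel
from pulsetwin.network import (FluidProperties, WindkesselOutlet,
                               load_default_network, single_vessel_network)
from pulsetwin.solver import (SolverConfig, junction_coupling,
                              run_prescribed_inflow, run_to_periodic,
                              stable_dt, tube_law_pressure,
                              windkessel_outlet_update)
from pulsetwin.units import MMHG
from pulsetwin.waveforms import extract_features, resample_cycle

RHO = 1060.0


def _segment(c0=5.0, b=2.0, P0=0.0, Gamma=0.0, diameter=0.02):
    net = single_vessel_network(diameter=diameter, c0=c0, b=b,
                                Gamma=Gamma, P0=P0)
    return net.segments[1], net.fluid


class TestTubeLaw:
    def test_reference_state_is_stress_free(self):
        seg, fluid = _segment(P0=80.0 * MMHG)
        P = tube_law_pressure(seg.A0_prox, 0.0, seg, fluid)
        assert P == pytest.approx(seg.P0 + seg.Pext)

    def test_hand_value_ten_percent_distension(self):
        # rho=1060, c0=5, b=2, A/A0=1.1: P = (2*1060*25/2)*0.1 = 2650 Pa
        seg, fluid = _segment(c0=5.0, b=2.0, P0=0.0)
        P = tube_law_pressure(1.1 * seg.A0_prox, 0.0, seg, fluid)
        assert P == pytest.approx(2650.0, rel=1e-12)

    @pytest.mark.parametrize("b", [1.0, 2.0, 4.0])
    def test_elastic_slope_independent_of_b(self, b):
        seg, fluid = _segment(c0=5.0, b=b, P0=0.0)
        A0 = seg.A0_prox
        h = 1e-9 * A0
        dPdA = (tube_law_pressure(A0 + h, 0.0, seg, fluid)
                - tube_law_pressure(A0 - h, 0.0, seg, fluid)) / (2 * h)
        assert dPdA == pytest.approx(RHO * 25.0 / A0, rel=1e-5)

    def test_viscous_term_adds_rate_pressure(self):
        seg, fluid = _segment(P0=0.0)
        seg.Gamma = 100.0
        dAdt = 1e-5
        extra = tube_law_pressure(seg.A0_prox, dAdt, seg, fluid) \
            - tube_law_pressure(seg.A0_prox, 0.0, seg, fluid)
        expected = seg.Gamma / (seg.A0_prox * math.sqrt(seg.A0_prox)) * dAdt
        assert extra == pytest.approx(expected, rel=1e-12)

    def test_nonpositive_area_rejected(self):
        seg, fluid = _segment()
        with pytest.raises(ValueError, match="positive"):
            tube_law_pressure(-1e-5, 0.0, seg, fluid)


class TestWindkesselOutlet:
    OUT = WindkesselOutlet(segment_id=1, Zc=2e7, R=1e8, C=1e-9,
                           Pout=10.0 * MMHG)

    def test_analytic_steady_state(self):
        q = 1e-5
        dt = 1e-4
        pc = 0.0
        for _ in range(int(20 * self.OUT.R * self.OUT.C / dt)):
            pb, pc = windkessel_outlet_update(q, self.OUT, dt, pc)
        expected = self.OUT.Pout + q * (self.OUT.Zc + self.OUT.R)
        assert pb == pytest.approx(expected, rel=1e-3)

    def test_rc_decay_from_charged_compartment(self):
        pc0 = 5000.0
        dt = 1e-4
        pc = pc0
        t_end = 0.05
        for _ in range(int(t_end / dt)):
            _, pc = windkessel_outlet_update(0.0, self.OUT, dt, pc)
        assert pc == pytest.approx(pc0 * math.exp(-t_end /
                                                  (self.OUT.R * self.OUT.C)),
                                   rel=1e-2)

    def test_infinite_compliance_freezes_compartment(self):
        big_c = WindkesselOutlet(segment_id=1, Zc=2e7, R=1e8, C=1e6,
                                 Pout=0.0)
        pb, pc = windkessel_outlet_update(1e-5, big_c, 1e-4, 1234.0)
        assert pc == pytest.approx(1234.0, rel=1e-9)


class TestJunctionCoupling:
    def _ends(self, diameter, c0, A=None, W=0.0, b=2.0):
        from pulsetwin.units import area_from_diameter
        A0 = area_from_diameter(diameter)
        return ((A if A is not None else A0), A0, c0, b, W)

    def test_symmetric_bifurcation_splits_flow_equally(self):
        fluid = FluidProperties()
        u_in = 0.3
        parent = self._ends(0.02, 5.0, W=u_in + 0.0)   # W+ carries u
        kids = [self._ends(0.014, 6.0), self._ends(0.014, 6.0)]
        A, u = junction_coupling(parent, kids, fluid, P0=0.0)
        q_parent = A[0] * u[0]
        assert A[1] * u[1] == pytest.approx(A[2] * u[2], rel=1e-10)
        assert A[1] * u[1] + A[2] * u[2] == pytest.approx(q_parent, rel=1e-10)

    def test_quiescent_junction_keeps_static_pressure(self):
        fluid = FluidProperties()
        parent = self._ends(0.02, 5.0, W=0.0)
        kids = [self._ends(0.01, 6.0, W=0.0), self._ends(0.012, 6.5, W=0.0)]
        A, u = junction_coupling(parent, kids, fluid, P0=0.0)
        assert np.allclose(u, 0.0, atol=1e-12)
        assert A[0] == pytest.approx(parent[1], rel=1e-12)

    def test_asymmetric_split_matches_admittance_ratio(self):
        """Linearized transmission: child flows split in proportion to
        characteristic admittance Y = A0/(rho*c0)."""
        fluid = FluidProperties()
        from pulsetwin.units import area_from_diameter
        d1, d2 = 0.014, 0.0099   # ~2:1 area ratio
        c1 = c2 = 6.0
        parent = self._ends(0.02, 5.0, W=1e-3)  # small-amplitude pulse
        kids = [self._ends(d1, c1), self._ends(d2, c2)]
        A, u = junction_coupling(parent, kids, fluid, P0=0.0)
        q1, q2 = A[1] * u[1], A[2] * u[2]
        y1 = area_from_diameter(d1) / (RHO * c1)
        y2 = area_from_diameter(d2) / (RHO * c2)
        assert q1 / q2 == pytest.approx(y1 / y2, rel=1e-3)

    def test_total_pressure_continuity(self):
        fluid = FluidProperties()
        parent = self._ends(0.02, 5.0, W=0.5)
        kids = [self._ends(0.012, 6.0), self._ends(0.015, 6.5)]
        A, u = junction_coupling(parent, kids, fluid, P0=0.0)

        def ptot(i, ref):
            _, A0, c0, b, _ = ref
            pel = (2 * RHO * c0 ** 2 / b) * ((A[i] / A0) ** (b / 2) - 1)
            return pel + 0.5 * RHO * u[i] ** 2
        pt = [ptot(0, parent), ptot(1, kids[0]), ptot(2, kids[1])]
        assert pt[0] == pytest.approx(pt[1], rel=1e-8)
        assert pt[0] == pytest.approx(pt[2], rel=1e-8)


class TestWavePropagation:
    def test_equilibrium_is_preserved(self):
        net = single_vessel_network(length=0.5, n_elements=50, Gamma=0.0,
                                    Pout=80.0 * MMHG)
        cfg = SolverConfig(cfl=0.5)
        dt = stable_dt(net, cfg)
        qin = np.zeros(int(0.1 / dt))
        t, P, Q, flat, _ = run_prescribed_inflow(net, qin, cfg, n_passes=1)
        assert np.max(np.abs(P[-1] - 80.0 * MMHG)) < 1.0   # Pa
        assert np.max(np.abs(Q[-1])) < 1e-10

    def test_pulse_travels_at_intrinsic_wave_speed(self):
        c0 = 6.0
        net = single_vessel_network(length=2.0, diameter=0.02, c0=c0,
                                    gamma=0.0, Gamma=0.0, n_elements=400)
        cfg = SolverConfig(cfl=0.5)
        dt = stable_dt(net, cfg)
        steps = int(round(0.32 / dt))
        tt = np.arange(steps) * dt
        qin = 1e-5 * np.exp(-(((tt - 0.03) / 0.008) ** 2))
        t, P, Q, flat, _ = run_prescribed_inflow(
            net, qin, cfg, outlet_kinds={1: _kernel.OUT_ABSORBING})
        x = np.linspace(0, 2.0, 401)
        i1, i2 = 60, 300

        def arrival(col):
            p = P[:, col]
            thresh = 80 * MMHG + 0.5 * (p.max() - 80 * MMHG)
            return t[np.argmax(p > thresh)]
        c_meas = (x[i2] - x[i1]) / (arrival(i2) - arrival(i1))
        assert abs(c_meas - c0) / c0 < 0.02

    def test_closed_end_doubles_incident_pulse(self):
        net = single_vessel_network(length=1.5, diameter=0.02, c0=6.0,
                                    gamma=0.0, Gamma=0.0, n_elements=300)
        cfg = SolverConfig(cfl=0.5)
        dt = stable_dt(net, cfg)
        steps = int(round(0.55 / dt))
        tt = np.arange(steps) * dt
        qin = 5e-6 * np.exp(-(((tt - 0.04) / 0.012) ** 2))
        t, P, Q, flat, _ = run_prescribed_inflow(
            net, qin, cfg, outlet_kinds={1: _kernel.OUT_CLOSED})
        p_incident = P[:, 150].max() - 80 * MMHG
        p_end = P[:, -1].max() - 80 * MMHG
        assert p_end / p_incident == pytest.approx(2.0, rel=0.05)

    def test_steady_friction_balance(self):
        """Rigid-limit steady flow: dP/dx = -2*pi*gamma*nu*rho*Q/A^2."""
        net = single_vessel_network(length=0.5, diameter=0.01, c0=50.0,
                                    gamma=9.0, Gamma=0.0, n_elements=50,
                                    R=5e7, C=1e-9)
        cfg = SolverConfig(max_cycles=40, periodicity_tol_mmhg=0.01)
        dt = stable_dt(net, cfg)
        q0 = 2e-6
        qin = np.full(int(round(0.5 / dt)), q0)
        t, P, Q, flat, _ = run_prescribed_inflow(net, qin, cfg, n_passes=20)
        seg = net.segments[1]
        dpdx = (P[-1, 40] - P[-1, 10]) / (30 * seg.dx)
        nu = net.fluid.kinematic_viscosity
        expected = -2 * math.pi * 9.0 * nu * RHO * q0 / seg.A0_prox ** 2
        assert dpdx == pytest.approx(expected, rel=0.02)

    def test_wk3_outlet_reaches_analytic_mean(self):
        net = single_vessel_network(length=0.3, n_elements=30,
                                    R=1.0e8, C=5e-9)
        cfg = SolverConfig(max_cycles=30, periodicity_tol_mmhg=0.01)
        dt = stable_dt(net, cfg)
        q0 = 1e-5
        qin = np.full(int(round(1.0 / dt)), q0)
        t, P, Q, flat, _ = run_prescribed_inflow(net, qin, cfg, n_passes=25)
        out = net.outlets[1]
        expected = out.Pout + q0 * (out.R + out.Zc)
        assert abs(P[-1, -1] - expected) / expected < 0.005


class TestRunToPeriodic:
    def test_healthy_network_converges_with_sane_pressures(self, default_net):
        res = run_to_periodic(default_net, SolverConfig(max_cycles=12))
        assert res.converged
        assert res.junction_mass_residual < 1e-6
        for rec in res.records.values():
            assert np.all(rec.pressure_mmhg > 0)
            assert np.all(rec.pressure_mmhg < 300)

    def test_stroke_volume_consistency(self, reference_patient):
        """Simulated EF and CO match the requested profile within the
        5% calibration contract."""
        prof = reference_patient.profile
        assert reference_patient.ef_simulated == pytest.approx(
            prof.ejection_fraction, rel=0.05)
        assert reference_patient.co_simulated_l_min == pytest.approx(
            prof.cardiac_output_l_min, rel=0.05)

    def test_reference_subject_morphology(self, reference_patient):
        """Systolic peak in early systole and a detectable dicrotic
        notch after it (illustrative anchors: ~0.25 s / ~0.36 s)."""
        cyc = reference_patient.cycles["aortic_root"]
        f = extract_features(cyc)
        assert 0.10 < f.t_peak < 0.35
        assert f.notch_found
        assert f.t_peak < f.t_notch < 0.50

    def test_grid_refinement_sensitivity(self, default_net):
        """Halving dx and dt moves the aortic cycle by a bounded amount
        (the boundary closures are first order; see methods note)."""
        res1 = run_to_periodic(default_net,
                               SolverConfig(max_cycles=16,
                                            periodicity_tol_mmhg=0.05))
        net2 = load_default_network()
        for seg in net2.segments.values():
            seg.n_elements *= 2
        res2 = run_to_periodic(net2,
                               SolverConfig(cfl=0.4, max_cycles=16,
                                            periodicity_tol_mmhg=0.05))
        c1 = resample_cycle(res1.records["aortic_root"], 400).pressure_mmhg
        c2 = resample_cycle(res2.records["aortic_root"], 400).pressure_mmhg
        assert np.max(np.abs(c1 - c2)) < 3.0
        assert np.mean(np.abs(c1 - c2)) < 1.0
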