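"""Rheology, waveform, profile, Windkessel and junction mass-balance tests."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate

import mdtsim as m
from mdtsim.hemodynamics import (
    PRINTED_WAVEFORM_BRANCHES,
    repaired_waveform_branches,
    windkessel_pressure_series,
)


class TestCarreau:
    def test_limits_match_printed_parameters(self):
        assert m.carreau_viscosity(0.0) == pytest.approx(0.056)
        assert m.carreau_viscosity(1e14) == pytest.approx(0.0035, rel=1e-3)

    def test_unit_shear_rate_value(self):
        # independent scalar evaluation of the closed form
        assert m.carreau_viscosity(1.0) == pytest.approx(0.0271, abs=2e-4)

    def test_negative_strain_rate_rejected(self):
        with pytest.raises(ValueError):
            m.carreau_viscosity(-1.0)

    @given(st.floats(min_value=0.0, max_value=1e8),
           st.floats(min_value=0.0, max_value=1e8))
    @settings(max_examples=200, derandomize=True)
    def test_monotone_and_bounded(self, g1, g2):
        lo, hi = sorted([g1, g2])
        v_lo, v_hi = m.carreau_viscosity(lo), m.carreau_viscosity(hi)
        assert v_lo >= v_hi  # shear thinning
        for v in (v_lo, v_hi):
            assert 0.0035 <= v <= 0.056

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            m.CarreauParams(mu_inf=0.06, mu_zero=0.056)
        with pytest.raises(ValueError):
            m.CarreauParams(power_index=1.5)


class TestWaveform:
    def test_first_branch_at_zero(self):
        assert m.inlet_waveform(1.0)(0.0) == pytest.approx(0.1375)

    @pytest.mark.parametrize("scale", [1.0, 1.4, 1.5])
    def test_linear_scaling(self, scale):
        w = m.inlet_waveform(scale)
        assert w(0.0) == pytest.approx(0.1375 * scale)

    def test_near_periodicity_of_printed_last_branch(self):
        # value of the last printed branch at the period end vs branch 1 at 0
        w = m.inlet_waveform(1.0)
        end_val = np.polyval(PRINTED_WAVEFORM_BRANCHES[-1][2], 0.8)
        assert w(0.8 - 1e-12) == pytest.approx(end_val, rel=1e-6)
        # the waveform is only approximately periodic as printed (~5% gap)
        assert abs(end_val - 0.1375) < 0.01

    def test_period_reduction(self):
        w = m.inlet_waveform(1.0)
        assert w(0.8) == pytest.approx(w(0.0))
        assert w(1.6 + 0.1) == pytest.approx(w(0.1))

    def test_repaired_set_is_continuous_and_physiological(self):
        w = m.inlet_waveform(1.0, repaired=True)
        for bp in (0.15, 0.24, 0.42, 0.47):
            assert w(bp - 1e-9) == pytest.approx(w(bp + 1e-9), abs=1e-6)
        vals = w.mean_velocity(np.linspace(0.0, 0.8, 1601))
        assert vals.min() > 0.05 and vals.max() < 0.7

    def test_repaired_keeps_printed_branches_1_3_5(self):
        rep = repaired_waveform_branches()
        for k in (0, 2, 4):
            assert rep[k] == PRINTED_WAVEFORM_BRANCHES[k]

    def test_printed_branches_2_and_4_are_discontinuous(self):
        # documents the published defect the repaired set fixes
        w = m.inlet_waveform(1.0)
        assert abs(w(0.15 - 1e-9) - w(0.15 + 1e-9)) > 1.0
        assert abs(w(0.42 - 1e-9) - w(0.42 + 1e-9)) > 100.0


class TestParabolicProfile:
    def test_wall_centerline_and_outside(self, steady_tube):
        seg = steady_tube.segments["tube"]
        ubar = lambda t: steady_tube.mean_velocity("tube", t)
        assert m.axial_velocity_profile(seg.radius, 0.0, seg, ubar) == 0.0
        assert m.axial_velocity_profile(0.0, 0.0, seg, ubar) \
            == pytest.approx(2 * 0.2)
        with pytest.raises(m.hemodynamics.OutsideLumenError):
            m.axial_velocity_profile(1.1 * seg.radius, 0.0, seg, ubar)

    def test_cross_section_average_equals_mean(self, tube):
        # 2π ∫ u(r) r dr / (πR²) == ū by quadrature
        seg = tube.segments["tube"]
        t = 0.3
        ubar = tube.mean_velocity("tube", t)
        val, _ = integrate.quad(
            lambda r: 2 * np.pi * r * 2 * ubar * (1 - (r / seg.radius) ** 2),
            0.0, seg.radius)
        assert val / seg.area == pytest.approx(ubar, rel=1e-6)


class TestSampleFlow:
    def test_centerline_speed_basilar_scale(self):
        net = m.straight_tube_network(scale=1.0, repaired=True)
        fs = m.sample_flow((0.0, 0.0, 0.0), 0.0, net)
        assert np.linalg.norm(fs.velocity) == pytest.approx(2 * 0.1375)
        assert fs.strain_rate == 0.0
        assert fs.viscosity == pytest.approx(0.056)

    def test_wall_point_shear_rate(self, tube):
        seg = tube.segments["tube"]
        pos = (seg.radius * (1 - 1e-12), 0.0, 0.0)
        fs = m.sample_flow(pos, 0.0, tube)
        ubar = tube.mean_velocity("tube", 0.0)
        assert np.linalg.norm(fs.velocity) == pytest.approx(0.0, abs=1e-9)
        assert fs.strain_rate == pytest.approx(4 * ubar / seg.radius, rel=1e-9)
        assert fs.viscosity == pytest.approx(
            m.carreau_viscosity(fs.strain_rate))

    def test_outside_domain_raises(self, tube):
        with pytest.raises(m.hemodynamics.OutsideLumenError):
            m.sample_flow((0.01, 0.0, 0.0), 0.0, tube)


class TestJunctions:
    def test_mass_balance_everywhere(self):
        net = m.cow_network()
        for t in np.linspace(0.0, 0.8, 17):
            for parent, kids in net.junctions.items():
                q_routed = sum(net.volumetric_flow(parent, t) * f
                               for f in kids.values())
                assert q_routed == pytest.approx(
                    net.volumetric_flow(parent, t), rel=1e-12)
            # global: inflow == outflow
            q_in = sum(net.volumetric_flow(i, t) for i in net.inlets)
            q_out = sum(net.volumetric_flow(o, t) for o in net.outlets)
            assert q_out == pytest.approx(q_in, rel=1e-10)

    def test_equal_split_equal_radii_conserves_mean_flow(self):
        # Y junction: parent radius R, daughters radius R/sqrt(2) so that
        # a 50/50 split preserves mean velocity
        r = 1e-3
        rd = r / np.sqrt(2)
        segs = {
            "p": m.VesselSegment("p", (0, 0, 0), (0, 0.01, 0), r),
            "a": m.VesselSegment("a", (0, 0.01, 0), (-0.01, 0.02, 0), rd),
            "b": m.VesselSegment("b", (0, 0.01, 0), (0.01, 0.02, 0), rd),
        }
        net = m.VesselNetwork(segments=segs, inlets={"p": 1.0},
                              junctions={"p": {"a": 0.5, "b": 0.5}},
                              waveform_repaired=True)
        t = 0.1
        qp = net.volumetric_flow("p", t)
        assert net.volumetric_flow("a", t) + net.volumetric_flow("b", t) \
            == pytest.approx(qp, rel=1e-12)
        assert net.mean_velocity("a", t) == pytest.approx(
            net.mean_velocity("p", t), rel=1e-12)

    def test_bad_split_fractions_rejected(self):
        segs = {
            "p": m.VesselSegment("p", (0, 0, 0), (0, 0.01, 0), 1e-3),
            "a": m.VesselSegment("a", (0, 0.01, 0), (0, 0.02, 0), 1e-3),
        }
        with pytest.raises(ValueError, match="sum"):
            m.VesselNetwork(segments=segs, inlets={"p": 1.0},
                            junctions={"p": {"a": 0.7}})


class TestWindkessel:
    def test_steady_state_closed_form(self):
        wk = m.WindkesselParams(r_proximal=1e9, r_distal=1e10,
                                capacitance=1e-10)
        i0 = 2e-6
        p = 0.0
        tau = wk.r_distal * wk.capacitance
        dt = tau / 10
        for _ in range(250):  # 25 time constants
            p = m.windkessel_advance(p, i0, 0.0, dt, wk)
        assert p == pytest.approx(i0 * (wk.r_proximal + wk.r_distal),
                                  rel=1e-6)

    def test_zero_inflow_exponential_decay(self):
        wk = m.WindkesselParams()
        tau = wk.r_distal * wk.capacitance
        p0 = 1e4
        p = m.windkessel_advance(p0, 0.0, 0.0, tau, wk)
        assert p == pytest.approx(p0 * np.exp(-1.0), rel=1e-12)

    def test_self_convergence_on_sinusoidal_inflow(self):
        # halving dt should shrink the error ~2x (first-order in i(t)
        # variation); Richardson-style self-convergence against dt/8
        wk = m.WindkesselParams(r_proximal=1e9, r_distal=5e9,
                                capacitance=2e-10)

        def run(n):
            ts = np.linspace(0.0, 1.0, n + 1)
            p = 0.0
            for k in range(n):
                t_mid = 0.5 * (ts[k] + ts[k + 1])
                i = 2e-6 * (1 + np.sin(2 * np.pi * t_mid))
                didt = 2e-6 * 2 * np.pi * np.cos(2 * np.pi * t_mid)
                p = m.windkessel_advance(p, i, didt, ts[1] - ts[0], wk)
            return p

        ref = run(4096)
        e1, e2 = abs(run(128) - ref), abs(run(256) - ref)
        assert e2 < e1 / 1.7

    def test_nonpositive_dt_rejected(self):
        with pytest.raises(ValueError):
            m.windkessel_advance(0.0, 1e-6, 0.0, 0.0, m.WindkesselParams())

    def test_pressure_series_is_bounded_and_periodicish(self, tube):
        ts = np.arange(0.0, 2.4, 1e-3)
        p = windkessel_pressure_series(tube, "tube", ts)
        assert np.all(np.isfinite(p)) and p.min() > 0.0


class TestDiagnostics:
    def test_wss_closed_form(self, steady_tube):
        seg = steady_tube.segments["tube"]
        gw = 4 * 0.2 / seg.radius
        expected = m.carreau_viscosity(gw) * gw
        assert m.wall_shear_stress("tube", 0.0, steady_tube) \
            == pytest.approx(expected, rel=1e-12)

    def test_wss_zero_flow_and_newtonian_linearity(self):
        net0 = m.straight_tube_network(constant_mean_velocity=0.0)
        assert m.wall_shear_stress("tube", 0.0, net0) == 0.0
        # near-Newtonian limit: tiny time constant makes µ effectively flat
        rheo = m.CarreauParams(time_const=1e-12)
        n1 = m.straight_tube_network(constant_mean_velocity=0.1)
        n2 = m.straight_tube_network(constant_mean_velocity=0.2)
        t1 = m.wall_shear_stress("tube", 0.0, n1, rheo)
        t2 = m.wall_shear_stress("tube", 0.0, n2, rheo)
        assert t2 == pytest.approx(2 * t1, rel=1e-6)

    def test_vorticity_centerline_wall_and_fd_oracle(self, steady_tube):
        seg = steady_tube.segments["tube"]
        R = seg.radius
        assert m.vorticity((0, 0, 0), 0.0, steady_tube) == 0.0
        w_wall = m.vorticity((R * (1 - 1e-9), 0, 0), 0.0, steady_tube)
        assert w_wall == pytest.approx(4 * 0.2 / R, rel=1e-6)
        # central-difference curl of the sampled axial velocity
        x0, h = 0.4 * R, 1e-7
        up = m.sample_flow((x0 + h, 0, 0), 0.0, steady_tube).velocity[1]
        um = m.sample_flow((x0 - h, 0, 0), 0.0, steady_tube).velocity[1]
        curl = abs((up - um) / (2 * h))
        assert m.vorticity((x0, 0, 0), 0.0, steady_tube) \
            == pytest.approx(curl, rel=1e-4)
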