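"""1-D pulse-wave model: dimensionless numbers, the annular-resistance
closed form against a brute-force annular-profile oracle, solver
conservation/convergence, and the catheter-obstruction pressure effect."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from cathfidelity import (CatheterInsertion, FlowWaveform, VesselSpec,
                          WindkesselSpec, annular_resistance_ratio,
                          conservation_residual, moens_korteweg_speed,
                          pressure_at, reynolds_number, simulate_pulse_wave,
                          womersley_number)
from cathfidelity.errors import DomainError, ParameterError, StabilityError


def annular_ratio_oracle(k: float) -> float:
    """Brute-force resistance ratio: numerically integrate the steady annular
    velocity profile u(r) for pressure-driven flow between radii b = k a and
    a, compute Q = int 2 pi r u dr, and compare with the open Poiseuille tube."""
    a, b = 1.0, k
    ln = math.log(a / b)

    def u(r):  # profile up to the common factor G/(4 mu)
        return a * a - r * r + (a * a - b * b) * math.log(r / a) / ln

    q_annulus, _ = quad(lambda r: 2 * math.pi * r * u(r), b, a)
    q_open = math.pi * a ** 4 / 2  # same normalization
    return q_open / q_annulus


class TestDimensionlessNumbers:
    def test_reynolds_round_trip(self):
        """U inverted from the printed Re = 1308 reproduces it to 4 figures."""
        U = 1308 * 0.001002 / (2 * 0.008 * 998)
        assert reynolds_number(0.008, U, 998.0, 0.001002) == pytest.approx(
            1308.0, rel=1e-4)

    def test_reynolds_zero_and_linearity(self):
        assert reynolds_number(0.008, 0.0, 998.0, 0.001002) == 0.0
        r1 = reynolds_number(0.008, 0.1, 998.0, 0.001002)
        assert reynolds_number(0.008, 0.2, 998.0, 0.001002) == pytest.approx(
            2 * r1, rel=1e-12)

    def test_womersley_phantom_value(self):
        assert womersley_number(0.008, 1.0, 998.0, 0.001002) == pytest.approx(
            20.0, abs=0.1)

    def test_womersley_sqrt_scaling(self):
        a1 = womersley_number(0.008, 1.0, 998.0, 0.001002)
        assert womersley_number(0.008, 4.0, 998.0, 0.001002) == pytest.approx(
            2 * a1, rel=1e-12)

    def test_womersley_half_radius(self):
        assert womersley_number(0.004, 1.0, 998.0, 0.001002) == pytest.approx(
            10.0, abs=0.05)


class TestMoensKorteweg:
    def test_phantom_tube_speed(self, phantom_vessel):
        # direct arithmetic oracle: sqrt(384e3 * 1.5e-3 / (2 * 998 * 8e-3))
        assert moens_korteweg_speed(phantom_vessel) == pytest.approx(
            6.006, abs=0.005)

    def test_stiffness_scaling(self, phantom_vessel):
        stiff = VesselSpec(length=0.8, R_i=0.008, R_o=0.0095, E_s=4 * 384e3)
        assert moens_korteweg_speed(stiff) == pytest.approx(
            2 * moens_korteweg_speed(phantom_vessel), rel=1e-12)

    def test_thin_wall_limit(self):
        thin = VesselSpec(length=0.8, R_i=0.008, R_o=0.008 + 1e-7, E_s=384e3)
        assert moens_korteweg_speed(thin) < 0.1


class TestAnnularResistance:
    def test_open_tube_is_unity(self):
        assert annular_resistance_ratio(0.0) == 1.0

    @pytest.mark.parametrize("k", np.round(np.arange(0.05, 0.91, 0.05), 2))
    def test_matches_profile_oracle_to_four_figures(self, k):
        assert annular_resistance_ratio(float(k)) == pytest.approx(
            annular_ratio_oracle(float(k)), rel=1e-4)

    @pytest.mark.parametrize("k, expected", [
        (0.3, 3.2885), (0.7, 32.611), (0.125, 1.8735)])
    def test_worked_values(self, k, expected):
        # frozen from the annular-profile oracle
        assert annular_resistance_ratio(k) == pytest.approx(expected, rel=1e-4)

    def test_domain_errors(self):
        for bad in (-0.1, 1.0, 1.5, float("nan")):
            with pytest.raises(DomainError):
                annular_resistance_ratio(bad)

    @settings(deadline=None, max_examples=50)
    @given(st.floats(0.01, 0.93), st.floats(0.005, 0.05))
    def test_strictly_increasing(self, k, dk):
        k2 = min(k + dk, 0.949)
        assert annular_resistance_ratio(k2) > annular_resistance_ratio(k)


class TestSolver:
    def test_rest_state_stays_at_rest(self, phantom_vessel):
        flow = FlowWaveform(np.zeros(1000), 1000.0)
        wk = WindkesselSpec(Rp=1e8, C=1e-9, P_venous=0.0)
        res = simulate_pulse_wave(phantom_vessel, wk, flow, n_cycles=1)
        assert np.abs(res.pressure).max() < 1e-9
        assert np.abs(res.flow).max() < 1e-12

    def test_cfl_violation_rejected(self, phantom_vessel, inlet_flow):
        wk = WindkesselSpec(Rp=1e8, C=1e-9)
        with pytest.raises(StabilityError, match="CFL"):
            simulate_pulse_wave(phantom_vessel, wk, inlet_flow, dt=2e-3)

    def test_mass_conservation_below_one_percent(self, wire_result, cath_result):
        assert conservation_residual(wire_result) < 0.01
        assert conservation_residual(cath_result) < 0.01

    def test_catheter_raises_tip_pressure(self, exp_config, wire_result,
                                          cath_result):
        """Obstruction raises both the time-averaged and the peak pressure at
        the tip probe, the direction of the phantom study's finding."""
        tip = exp_config.catheter.tip_position
        pw = pressure_at(wire_result, tip, 1000.0).samples
        pc = pressure_at(cath_result, tip, 1000.0).samples
        assert pc.mean() > pw.mean()
        assert pc.max() > pw.max()

    def test_peak_pressure_monotone_in_catheter_radius(
            self, exp_config, wire_result, catheter_sweep_results):
        tip = exp_config.catheter.tip_position
        peaks = [pressure_at(wire_result, tip, 1000.0).samples.max()]
        for R_c in sorted(catheter_sweep_results):
            peaks.append(pressure_at(catheter_sweep_results[R_c], tip,
                                     1000.0).samples.max())
        assert all(b > a for a, b in zip(peaks, peaks[1:]))

    def test_grid_convergence(self, exp_config, inlet_flow, wire_result):
        """Halving dx and dt changes the tip peak pressure by < 1%."""
        cfg = exp_config
        fine = simulate_pulse_wave(
            cfg.vessel, cfg.windkessel, inlet_flow, catheter=None,
            n_cycles=cfg.numerics.n_cycles, dx=cfg.numerics.dx / 2,
            dt=cfg.numerics.dt / 2, art_visc=cfg.numerics.art_visc)
        tip = cfg.catheter.tip_position
        p_coarse = pressure_at(wire_result, tip, 1000.0).samples.max()
        p_fine = pressure_at(fine, tip, 1000.0).samples.max()
        assert abs(p_fine - p_coarse) / p_coarse < 0.01

    def test_catheter_tip_outside_tube_rejected(self, phantom_vessel,
                                                inlet_flow):
        wk = WindkesselSpec(Rp=1e8, C=1e-9)
        cath = CatheterInsertion(R_c=1e-3, tip_position=1.5)
        with pytest.raises(ParameterError, match="tip_position"):
            simulate_pulse_wave(phantom_vessel, wk, inlet_flow, catheter=cath)


class TestProbeExtraction:
    def test_grid_node_identity(self, wire_result):
        j = 10
        x = wire_result.x_grid[j]
        w = pressure_at(wire_result, float(x), 1000.0)
        # resampled in time, so compare against time-interpolated column
        col = np.interp(w.times, wire_result.t_grid, wire_result.pressure[:, j])
        assert np.allclose(w.samples, col, atol=1e-9)

    def test_midpoint_linear_interpolation(self, wire_result):
        x0, x1 = wire_result.x_grid[10], wire_result.x_grid[11]
        mid = pressure_at(wire_result, float((x0 + x1) / 2), 1000.0)
        a = pressure_at(wire_result, float(x0), 1000.0)
        b = pressure_at(wire_result, float(x1), 1000.0)
        assert np.allclose(mid.samples, (a.samples + b.samples) / 2, atol=1e-9)

    def test_probe_layout_ten_positions(self, wire_result):
        # the phantom protocol: 10 axial positions at 20 mm intervals
        positions = np.arange(0.08, 0.2601, 0.02)
        waves = [pressure_at(wire_result, float(x), 100.0) for x in positions]
        assert len(waves) == 10

    def test_out_of_range_probe_rejected(self, wire_result):
        with pytest.raises(ParameterError, match="x"):
            pressure_at(wire_result, 5.0, 100.0)
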