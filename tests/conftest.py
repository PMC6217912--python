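"""Shared fixtures: the phantom-like operating point and (expensive)
session-scoped simulation results reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from cathfidelity import (CatheterInsertion, CatheterSpec, VesselSpec,
                          WaveformParams, generate_inlet_flow,
                          generate_pressure_waveform, simulate_pulse_wave)
from cathfidelity.pipeline import default_config

# mean flow velocity obtained by inverting the printed Re = 1308
U_MEAN = 1308 * 0.001002 / (2 * 0.008 * 998)


@pytest.fixture(scope="session")
def default_params() -> WaveformParams:
    return WaveformParams()


@pytest.fixture(scope="session")
def default_waveform(default_params):
    return generate_pressure_waveform(default_params)


@pytest.fixture(scope="session")
def phantom_vessel() -> VesselSpec:
    return VesselSpec(length=0.8, R_i=0.008, R_o=0.0095, E_s=384e3,
                      rho_s=1250.0, mu=0.001002, rho_f=998.0)


@pytest.fixture(scope="session")
def reference_catheter() -> CatheterSpec:
    # 6F fluid-filled catheter: l = 800 mm, lumen R = 0.32 mm, R_c = 1 mm
    return CatheterSpec(l=0.8, R=0.32e-3, R_c=1e-3, t=0.68e-3, E_cath=32e6,
                        mu=0.001002, rho=998.0)


@pytest.fixture(scope="session")
def exp_config():
    return default_config()


@pytest.fixture(scope="session")
def inlet_flow(exp_config):
    cfg = exp_config
    return generate_inlet_flow(
        cfg.heart_rate, cfg.inflow.mean_velocity, cfg.vessel.R_i,
        n_cycles=1, rate=cfg.inflow.rate,
        ejection_frac=cfg.inflow.ejection_frac,
        rise_frac=cfg.inflow.rise_frac)


def _simulate(cfg, inflow, catheter):
    return simulate_pulse_wave(
        cfg.vessel, cfg.windkessel, inflow, catheter=catheter,
        n_cycles=cfg.numerics.n_cycles, dx=cfg.numerics.dx,
        dt=cfg.numerics.dt, art_visc=cfg.numerics.art_visc)


@pytest.fixture(scope="session")
def wire_result(exp_config, inlet_flow):
    """Uncatheterized (wire-reference) simulation of the default experiment."""
    return _simulate(exp_config, inlet_flow, None)


@pytest.fixture(scope="session")
def cath_result(exp_config, inlet_flow):
    """Catheterized simulation (6F catheter, tip at z = 140 mm)."""
    return _simulate(exp_config, inlet_flow, exp_config.catheter)


@pytest.fixture(scope="session")
def catheter_sweep_results(exp_config, inlet_flow, cath_result):
    """Simulations over increasing catheter radius (clinical 2F-6F range)."""
    out = {}
    for R_c in (0.25e-3, 0.5e-3, 0.75e-3):
        cath = CatheterInsertion(
            R_c=R_c, tip_position=exp_config.catheter.tip_position,
            outlet_fitting_radius=exp_config.catheter.outlet_fitting_radius)
        out[R_c] = _simulate(exp_config, inlet_flow, cath)
    out[1e-3] = cath_result
    return out
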