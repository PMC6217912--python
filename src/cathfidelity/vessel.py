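"""Reduced-order 1-D pulse-wave model of a compliant tube with an optional
coaxial catheter, plus the dimensionless-number and annular-resistance
closed forms.

Model
-----
Cross-sectionally averaged mass and momentum balance on a straight elastic
tube of lumen area A(x, t) carrying flow Q(x, t):

    dA/dt + dQ/dx = 0
    dQ/dt + d(Q^2/Af)/dx + (Af/rho) dp/dx = -K(x) * 8 pi nu * Q / Af

with a linear tube law p = (A - A0) / C_A, where the cross-sectional
compliance C_A = 2 pi R_i^3 / (E_s h) reproduces the Moens-Korteweg wave
speed c0 = sqrt(E_s h / (2 rho R_i)). An inserted catheter is a rigid
coaxial rod from its tip to the outlet: there the fluid area is
Af = A - pi R_c^2 and the Poiseuille friction is multiplied by the
annular-obstruction ratio K = annular_resistance_ratio(R_c / R_i).

Boundary conditions: prescribed inlet flow; a Windkessel afterload at the
outlet (two-element, or three-element when a proximal/characteristic
resistance is set). A catheter, inserted from the distal end, additionally
obstructs the outlet fitting that couples the tube to the afterload; the
proximal afterload resistance is scaled by the annular ratio at the
fitting bore. The scheme is explicit MacCormack (predictor forward /
corrector backward differences) on a uniform grid with optional
second-difference smoothing; the CFL bound dt <= dx / (c + |u|) is
enforced at initialization and re-checked during the run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DomainError, ParameterError, StabilityError
from .units import MMHG_TO_PA, pa_to_mmhg
from .waveforms import FlowWaveform, PressureWaveform

__all__ = [
    "VesselSpec",
    "WindkesselSpec",
    "CatheterInsertion",
    "SimulationResult",
    "reynolds_number",
    "womersley_number",
    "moens_korteweg_speed",
    "annular_resistance_ratio",
    "simulate_pulse_wave",
    "pressure_at",
    "tune_windkessel",
    "conservation_residual",
]


@dataclass(frozen=True)
class VesselSpec:
    """Compliant-tube geometry, wall material and working fluid (SI units)."""

    length: float            # m
    R_i: float               # inner radius (m)
    R_o: float               # outer radius (m)
    E_s: float               # wall Young's modulus (Pa)
    rho_s: float = 1250.0    # wall density (kg/m^3)
    mu: float = 0.001002     # fluid viscosity (Pa s)
    rho_f: float = 998.0     # fluid density (kg/m^3)

    def __post_init__(self):
        for name in ("length", "R_i", "R_o", "E_s", "rho_s", "mu", "rho_f"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ParameterError(f"{name}: must be finite and > 0")
        if self.R_i >= self.R_o:
            raise ParameterError("R_i: inner radius must be < outer radius R_o")

    @property
    def wall_thickness(self) -> float:
        """h = R_o - R_i (m)."""
        return self.R_o - self.R_i

    @property
    def reference_area(self) -> float:
        """Unstressed lumen area A0 = pi R_i^2 (m^2)."""
        return math.pi * self.R_i ** 2

    @property
    def area_compliance(self) -> float:
        """Cross-sectional compliance C_A = dA/dp = 2 pi R_i^3 / (E_s h) (m^2/Pa)."""
        return 2.0 * math.pi * self.R_i ** 3 / (self.E_s * self.wall_thickness)


@dataclass(frozen=True)
class WindkesselSpec:
    """Windkessel afterload.

    With ``R_prox = 0`` (default) this is the classic two-element
    resistance-compliance afterload. A positive ``R_prox`` places a
    proximal resistor between the tube outlet and the compliance
    (three-element form); setting it to the tube's characteristic
    impedance makes the termination wave-absorbing, the standard choice in
    1-D pulse-wave modelling when the physical termination is a localized
    resistive constriction rather than a strong reflector.
    """

    Rp: float                # peripheral resistance (Pa s / m^3)
    C: float                 # compliance (m^3 / Pa)
    P_venous: float = 0.0    # reference outflow pressure (mmHg)
    R_prox: float = 0.0      # proximal (characteristic) resistance (Pa s / m^3)

    def __post_init__(self):
        if not (np.isfinite(self.Rp) and self.Rp > 0):
            raise ParameterError("Rp: must be finite and > 0")
        if not (np.isfinite(self.C) and self.C > 0):
            raise ParameterError("C: must be finite and > 0")
        if not np.isfinite(self.P_venous):
            raise ParameterError("P_venous: must be finite")
        if not (np.isfinite(self.R_prox) and self.R_prox >= 0):
            raise ParameterError("R_prox: must be finite and >= 0")


@dataclass(frozen=True)
class CatheterInsertion:
    """A rigid coaxial catheter occupying [tip_position, outlet].

    The catheter enters from the distal end, so its body also passes
    through the outlet fitting that couples the tube to the afterload.
    ``outlet_fitting_radius`` is the bore of that fitting: the proximal
    afterload resistance is multiplied by
    ``annular_resistance_ratio(R_c / outlet_fitting_radius)`` to account
    for the catheter partially blocking it — the dominant share of the
    extra downstream resistance, since the fitting is much narrower than
    the vessel. Set it to None to model the in-tube annulus only.
    """

    R_c: float               # catheter external radius (m)
    tip_position: float      # axial coordinate of the tip, from the inlet (m)
    outlet_fitting_radius: float | None = 4e-3   # bore of the outlet fitting (m)

    def validate_against(self, vessel: VesselSpec) -> None:
        if not (np.isfinite(self.R_c) and 0 < self.R_c < vessel.R_i):
            raise ParameterError("R_c: must satisfy 0 < R_c < vessel R_i")
        if not (np.isfinite(self.tip_position)
                and 0.0 <= self.tip_position <= vessel.length):
            raise ParameterError("tip_position: must lie inside the tube")
        if self.outlet_fitting_radius is not None:
            if not (np.isfinite(self.outlet_fitting_radius)
                    and self.R_c < self.outlet_fitting_radius):
                raise ParameterError(
                    "outlet_fitting_radius: must exceed R_c (catheter would "
                    "plug the outlet fitting)")


@dataclass(frozen=True)
class SimulationResult:
    """Space-time fields from the 1-D solver over the reported cycle.

    ``pressure`` is in mmHg; ``flow`` in m^3/s; ``area`` (lumen area) in
    m^2. Rows index time, columns axial position.
    """

    x_grid: np.ndarray       # (nx,) m
    t_grid: np.ndarray       # (nt,) s
    pressure: np.ndarray     # (nt, nx) mmHg
    flow: np.ndarray         # (nt, nx) m^3/s
    area: np.ndarray         # (nt, nx) m^2
    inflow_volume: float = float("nan")   # cycle-integrated inlet volume (m^3)
    outflow_volume: float = float("nan")  # cycle-integrated outlet volume (m^3)
    storage_change: float = float("nan")  # change in stored volume over the cycle (m^3)

    def __post_init__(self):
        nt, nx = len(self.t_grid), len(self.x_grid)
        for name in ("pressure", "flow", "area"):
            f = getattr(self, name)
            if f.shape != (nt, nx):
                raise ParameterError(f"{name}: shape {f.shape} != ({nt}, {nx})")
            if not np.all(np.isfinite(f)):
                raise StabilityError(f"{name}: non-finite values in result")
        if np.any(self.area <= 0):
            raise StabilityError("area: non-positive values in result")


def _require_positive(**kwargs: float) -> None:
    for name, v in kwargs.items():
        if not (np.isfinite(v) and v > 0):
            raise ParameterError(f"{name}: must be finite and > 0")


def reynolds_number(R_i: float, U: float, rho_f: float, mu: float) -> float:
    """Re = 2 R_i U rho_f / mu (mean-velocity based, diameter length scale)."""
    _require_positive(R_i=R_i, rho_f=rho_f, mu=mu)
    if not (np.isfinite(U) and U >= 0):
        raise ParameterError("U: must be finite and >= 0")
    return 2.0 * R_i * U * rho_f / mu


def womersley_number(R_i: float, f: float, rho_f: float, mu: float) -> float:
    """alpha = R_i sqrt(2 pi f rho_f / mu)."""
    _require_positive(R_i=R_i, f=f, rho_f=rho_f, mu=mu)
    return R_i * math.sqrt(2.0 * math.pi * f * rho_f / mu)


def moens_korteweg_speed(v: VesselSpec) -> float:
    """Linearized pulse wave speed c0 = sqrt(E_s h / (2 rho_f R_i)) (m/s)."""
    return math.sqrt(v.E_s * v.wall_thickness / (2.0 * v.rho_f * v.R_i))


def annular_resistance_ratio(k: float) -> float:
    """Steady flow-resistance increase caused by a coaxial rod, vs the open tube.

    For pressure-driven laminar flow in the annulus between the vessel wall
    (radius a) and a coaxial rod (radius b = k a), the resistance relative to
    the open Poiseuille tube is

        1 / (1 - k^4 - (1 - k^2)^2 / ln(1/k)),

    which is 1 at k = 0 and strictly increasing in k (about 3x at k = 0.3,
    about 33x at k = 0.7).
    """
    if not np.isfinite(k) or k < 0 or k >= 1:
        raise DomainError("k: radius ratio must satisfy 0 <= k < 1")
    if k == 0:
        return 1.0
    denom = 1.0 - k ** 4 - (1.0 - k * k) ** 2 / math.log(1.0 / k)
    return 1.0 / denom


def _periodic_interp(t: np.ndarray, flow: FlowWaveform) -> np.ndarray:
    """Sample a flow waveform at arbitrary times, extending it periodically."""
    period = flow.samples.size / flow.rate
    tq = np.mod(t - flow.t0, period)
    tf = np.arange(flow.samples.size + 1) / flow.rate
    qf = np.concatenate([flow.samples, flow.samples[:1]])  # wrap for continuity
    return np.interp(tq, tf, qf)


def simulate_pulse_wave(v: VesselSpec, wk: WindkesselSpec, inflow: FlowWaveform,
                        catheter: CatheterInsertion | None = None,
                        n_cycles: int = 4, dx: float = 2e-3,
                        dt: float = 2e-4, art_visc: float = 0.02,
                        store_rate: float = 1000.0) -> SimulationResult:
    """Solve the 1-D pulse-wave system and return fields over the final cycle.

    Runs ``n_cycles`` heart cycles (period taken from the inflow record,
    which must hold an integer number of identical cycles) from rest,
    discards all but the last cycle as transient, and returns the fields
    sub-sampled to approximately ``store_rate`` Hz.

    ``art_visc`` is the coefficient of the usual fourth-argument MacCormack
    smoothing (a second-difference filter applied each step) that keeps
    nonlinearly steepening compression fronts monotone; 0 disables it.

    Raises :class:`StabilityError` if the CFL bound is violated at
    initialization or the solution loses positivity/finiteness.
    """
    if int(n_cycles) != n_cycles or n_cycles < 1:
        raise ParameterError("n_cycles: must be an integer >= 1")
    _require_positive(dx=dx, dt=dt, store_rate=store_rate)
    if not (np.isfinite(art_visc) and 0 <= art_visc < 0.5):
        raise ParameterError("art_visc: must be in [0, 0.5)")
    if catheter is not None:
        catheter.validate_against(v)

    rho = v.rho_f
    A0 = v.reference_area
    CA = v.area_compliance
    c0 = math.sqrt(A0 / (rho * CA))

    nx = int(round(v.length / dx)) + 1
    x = np.linspace(0.0, v.length, nx)

    # catheter occupancy: rigid rod area and annular friction multiplier,
    # ramped over ~2 cells to avoid a grid-scale discontinuity at the tip
    A_cath = np.zeros(nx)
    K_fric = np.ones(nx)
    R_prox_eff = wk.R_prox
    if catheter is not None:
        k_ratio = catheter.R_c / v.R_i
        ramp = np.clip((x - catheter.tip_position) / (2.0 * dx), 0.0, 1.0)
        A_cath = ramp * math.pi * catheter.R_c ** 2
        K_fric = 1.0 + ramp * (annular_resistance_ratio(k_ratio) - 1.0)
        if catheter.outlet_fitting_radius is not None:
            R_prox_eff = wk.R_prox * annular_resistance_ratio(
                catheter.R_c / catheter.outlet_fitting_radius)

    # CFL at initialization (rest state; re-checked against the evolving
    # state during the run)
    u_scale = np.max(np.abs(inflow.samples)) / max(A0 - A_cath.max(), 1e-12)
    if dt > dx / (c0 + u_scale):
        raise StabilityError(
            f"CFL violated at initialization: dt={dt:g} s exceeds "
            f"dx/(c0+u) = {dx / (c0 + u_scale):g} s (c0={c0:.3g} m/s)")

    # cycle period: the inflow record holds one or more identical tiled
    # cycles; find the smallest repeating block
    n_rec = inflow.samples.size
    period = n_rec / inflow.rate
    q_scale = np.max(np.abs(inflow.samples))
    for m in range(2, n_rec + 1):
        if n_rec % m == 0:
            seg = inflow.samples.reshape(m, n_rec // m)
            if np.allclose(seg, seg[0], atol=1e-12 + 1e-9 * q_scale):
                period = (n_rec // m) / inflow.rate
                break

    n_steps_cycle = int(round(period / dt))
    if abs(n_steps_cycle * dt - period) > 1e-9:
        n_steps_cycle = max(1, n_steps_cycle)
    total_steps = n_steps_cycle * int(n_cycles)

    # storage of the final cycle
    store_every = max(1, int(round(1.0 / (store_rate * dt))))
    rec_idx = list(range(total_steps - n_steps_cycle, total_steps + 1, store_every))
    if rec_idx[-1] != total_steps:
        rec_idx.append(total_steps)
    rec_set = {i: j for j, i in enumerate(rec_idx)}
    nt = len(rec_idx)
    P_rec = np.empty((nt, nx))
    Q_rec = np.empty((nt, nx))
    A_rec = np.empty((nt, nx))
    t_rec = np.empty(nt)

    A = np.full(nx, A0)
    Q = np.zeros(nx)
    p_wk = wk.P_venous * MMHG_TO_PA
    pv = wk.P_venous * MMHG_TO_PA

    nu8pi = 8.0 * math.pi * v.mu / rho
    inv_dx = 1.0 / dx

    q_in_all = _periodic_interp(np.arange(total_steps + 1) * dt, inflow)
    Q[0] = q_in_all[0]

    vol_in = 0.0
    vol_out = 0.0
    A_cycle_start = None

    def rhs_terms(A_, Q_):
        Af = A_ - A_cath
        p_ = (A_ - A0) / CA
        G = Q_ * Q_ / Af
        fric = K_fric * nu8pi * Q_ / Af
        return Af, p_, G, fric

    def record(step, A_, Q_):
        j = rec_set.get(step)
        if j is None:
            return
        P_rec[j] = pa_to_mmhg((A_ - A0) / CA)
        Q_rec[j] = Q_
        A_rec[j] = A_
        t_rec[j] = step * dt

    record(0, A, Q)

    for step in range(total_steps):
        if step == total_steps - n_steps_cycle:
            A_cycle_start = A.copy()
            vol_in = 0.0
            vol_out = 0.0

        Af, p, G, fric = rhs_terms(A, Q)
        if not (np.all(np.isfinite(Q)) and np.all(Af > 0)):
            raise StabilityError(
                f"solver diverged at t={step * dt:.4f} s; check CFL margin "
                f"(dt={dt:g}, dx={dx:g})")

        # ---- predictor (forward differences) ----
        As = A.copy()
        Qs = Q.copy()
        As[:-1] = A[:-1] - dt * inv_dx * (Q[1:] - Q[:-1])
        Qs[:-1] = Q[:-1] - dt * (
            inv_dx * (G[1:] - G[:-1])
            + (Af[:-1] / rho) * inv_dx * (p[1:] - p[:-1])
            + fric[:-1])
        # inlet flow prescribed at the new time level
        Qs[0] = q_in_all[step + 1]
        # outlet: one-sided momentum, then predictor Windkessel update
        Qs[-1] = Q[-1] - dt * (
            inv_dx * (G[-1] - G[-2])
            + (Af[-1] / rho) * inv_dx * (p[-1] - p[-2])
            + fric[-1])
        p_wk_s = p_wk + dt * (Q[-1] - (p_wk - pv) / wk.Rp) / wk.C
        As[-1] = A0 + CA * (p_wk_s + R_prox_eff * Qs[-1])

        Afs, ps, Gs, frics = rhs_terms(As, Qs)
        if not (np.all(np.isfinite(Qs)) and np.all(Afs > 0)):
            raise StabilityError(
                f"solver diverged at t={step * dt:.4f} s; check CFL margin "
                f"(dt={dt:g}, dx={dx:g})")

        # ---- corrector (backward differences) ----
        A_new = A.copy()
        Q_new = Q.copy()
        A_new[1:] = 0.5 * (A[1:] + As[1:]) - 0.5 * dt * inv_dx * (Qs[1:] - Qs[:-1])
        Q_new[1:] = 0.5 * (Q[1:] + Qs[1:]) - 0.5 * dt * (
            inv_dx * (Gs[1:] - Gs[:-1])
            + (Afs[1:] / rho) * inv_dx * (ps[1:] - ps[:-1])
            + frics[1:])
        # inlet
        Q_new[0] = q_in_all[step + 1]
        A_new[0] = A[0] - dt * inv_dx * (Qs[1] - Qs[0])
        # outlet: corrector Windkessel update
        p_wk_new = 0.5 * (p_wk + p_wk_s) + 0.5 * dt * (
            Qs[-1] - (p_wk_s - pv) / wk.Rp) / wk.C
        A_new[-1] = A0 + CA * (p_wk_new + R_prox_eff * Q_new[-1])

        # runtime CFL check against the evolving state
        c_loc = np.sqrt(np.maximum(A_new, 1e-12) / (rho * CA))
        u_loc = np.abs(Q_new) / np.maximum(A_new - A_cath, 1e-12)
        if dt > dx / float(np.max(c_loc + u_loc)):
            raise StabilityError(
                f"CFL violated at t={(step + 1) * dt:.4f} s: "
                f"dt={dt:g} s exceeds dx/(c+u) = {dx / float(np.max(c_loc + u_loc)):g} s")

        if step >= total_steps - n_steps_cycle:
            # trapezoid-consistent volume bookkeeping over the final cycle
            vol_in += 0.5 * dt * (Q[0] + Q_new[0])
            vol_out += 0.5 * dt * (Q[-1] + Q_new[-1])

        if art_visc > 0:
            # second-difference smoothing (interior nodes only)
            A_new[1:-1] += art_visc * (A_new[2:] - 2 * A_new[1:-1] + A_new[:-2])
            Q_new[1:-1] += art_visc * (Q_new[2:] - 2 * Q_new[1:-1] + Q_new[:-2])

        A, Q, p_wk = A_new, Q_new, p_wk_new
        record(step + 1, A, Q)

    storage = float(np.trapezoid(A - A_cycle_start, dx=dx))
    return SimulationResult(
        x_grid=x, t_grid=t_rec, pressure=P_rec, flow=Q_rec, area=A_rec,
        inflow_volume=vol_in, outflow_volume=vol_out, storage_change=storage)


def conservation_residual(res: SimulationResult) -> float:
    """|inflow - outflow - storage change| over the cycle, as a fraction of stroke volume."""
    stroke = res.inflow_volume
    if not np.isfinite(stroke) or stroke <= 0:
        raise ParameterError("result carries no cycle volume bookkeeping")
    return abs(res.inflow_volume - res.outflow_volume - res.storage_change) / stroke


def pressure_at(res: SimulationResult, x: float, rate: float) -> PressureWaveform:
    """Extract the pressure waveform at axial position ``x`` (the ideal
    wire-like measurement), resampled to ``rate`` Hz.

    Linear interpolation in space between grid nodes, then linear
    resampling in time onto a uniform grid starting at the cycle start.
    """
    if not (np.isfinite(x) and res.x_grid[0] <= x <= res.x_grid[-1]):
        raise ParameterError(f"x: probe position {x} outside the tube "
                             f"[{res.x_grid[0]}, {res.x_grid[-1]}]")
    _require_positive(rate=rate)
    j = int(np.searchsorted(res.x_grid, x))
    if j == 0:
        series = res.pressure[:, 0]
    else:
        x0, x1 = res.x_grid[j - 1], res.x_grid[j]
        w = 0.0 if x1 == x0 else (x - x0) / (x1 - x0)
        series = (1.0 - w) * res.pressure[:, j - 1] + w * res.pressure[:, j]
    t0, t1 = res.t_grid[0], res.t_grid[-1]
    n = max(2, int(math.floor((t1 - t0) * rate)) + 1)
    tq = t0 + np.arange(n) / rate
    return PressureWaveform(np.interp(tq, res.t_grid, series), rate, t0)


def tune_windkessel(v: VesselSpec, inflow: FlowWaveform, target_peak: float,
                    probe_x: float, tau: float = 0.25,
                    P_venous: float = 0.0, R_prox: float | None = None,
                    tol: float = 0.5, max_iter: int = 20,
                    **sim_kwargs) -> WindkesselSpec:
    """Find a Windkessel whose simulated peak pressure at ``probe_x`` hits
    ``target_peak`` (mmHg).

    The afterload is parameterized by the peripheral resistance Rp with the
    decay time constant tau = Rp C held fixed; since the simulated peak is
    monotone in Rp, a bracketing bisection matches the target (physically:
    the phantom's resistance screw was adjusted until the desired systolic
    pressure was reached). ``R_prox=None`` uses the tube's characteristic
    impedance rho c0 / A0 (wave-absorbing termination); pass 0 for the pure
    two-element form. Tolerance in mmHg.
    """
    _require_positive(target_peak=target_peak, tau=tau, tol=tol)
    q_mean = float(np.mean(inflow.samples))
    if q_mean <= 0:
        raise ParameterError("inflow: cycle-mean flow must be > 0 for tuning")
    if R_prox is None:
        c0 = math.sqrt(v.reference_area / (v.rho_f * v.area_compliance))
        R_prox = v.rho_f * c0 / v.reference_area

    def peak_for(Rp: float) -> float:
        wk = WindkesselSpec(Rp=Rp, C=tau / Rp, P_venous=P_venous, R_prox=R_prox)
        res = simulate_pulse_wave(v, wk, inflow, catheter=None, **sim_kwargs)
        return float(np.max(pressure_at(res, probe_x, 200.0).samples))

    # bracket the target, expanding geometrically from the mean-pressure scale
    Rp_lo = 0.2 * target_peak * MMHG_TO_PA / q_mean
    Rp_hi = 2.0 * Rp_lo
    f_lo = peak_for(Rp_lo) - target_peak
    f_hi = peak_for(Rp_hi) - target_peak
    n_eval = 2
    while f_lo > 0 and n_eval < max_iter:
        Rp_hi, f_hi = Rp_lo, f_lo
        Rp_lo /= 4.0
        f_lo = peak_for(Rp_lo) - target_peak
        n_eval += 1
    while f_hi < 0 and n_eval < max_iter:
        Rp_lo, f_lo = Rp_hi, f_hi
        Rp_hi *= 4.0
        f_hi = peak_for(Rp_hi) - target_peak
        n_eval += 1
    if f_lo > 0 or f_hi < 0:
        raise ParameterError(
            f"target_peak: {target_peak} mmHg not bracketable with this inflow")
    Rp_mid, f_mid = Rp_hi, f_hi
    while abs(f_mid) > tol and n_eval < max_iter:
        Rp_mid = math.sqrt(Rp_lo * Rp_hi)  # bisect in log space
        f_mid = peak_for(Rp_mid) - target_peak
        n_eval += 1
        if f_mid < 0:
            Rp_lo = Rp_mid
        else:
            Rp_hi = Rp_mid
    return WindkesselSpec(Rp=Rp_mid, C=tau / Rp_mid, P_venous=P_venous,
                          R_prox=R_prox)
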