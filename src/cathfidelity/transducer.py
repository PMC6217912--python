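"""Fluid-filled catheter-manometer dynamics.

A fluid-filled catheter coupled to an external transducer behaves as a
second-order mass-spring-damper: the fluid column is the mass, the lumped
compliance of the catheter/transducer the spring, and viscous lumen flow
the damper. With lumen radius R, length l, lumen-fluid density rho and
viscosity mu, and inverse compliance dP/dV:

    f_n  = (1 / 2 pi) * sqrt(pi R^2 dP/dV / (rho l))
    zeta = (4 mu l / R^3) / sqrt(rho l pi dP/dV)

Signals well below f_n pass faithfully; near f_n an underdamped system
resonates, and above f_n the system low-passes the signal.

The relation between dP/dV and the catheter wall modulus is implemented as

    E_cath = dP/dV * 2 t V / (3 pi l),    V = pi R^2 l

which is the unique dimensionally consistent grouping of the published
form (checked by :func:`audit_modulus_relation_units`). Note that for the
reference 6F catheter this relation and the stated modulus do not reproduce
the measured natural frequency, so all derived dynamics in this package
route through the f_n/zeta formulas above (see docs/methods.md); the
modulus relation is provided for completeness as an exact inverse pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DimensionalError, ParameterError
from .waveforms import PressureWaveform

__all__ = [
    "CatheterSpec",
    "compliance_from_modulus",
    "modulus_from_compliance",
    "implied_compliance_inverse",
    "natural_frequency",
    "damping_coefficient",
    "amplitude_response",
    "measure_with_catheter",
    "audit_modulus_relation_units",
]

# Exponent bookkeeping for the modulus relation E = dPdV * 2 t V / (3 pi l).
# Base dimensions as (kg, m, s) exponents.
_DIMENSIONS = {
    "dPdV": (1, -4, -2),   # Pa / m^3 = kg m^-1 s^-2 / m^3
    "t": (0, 1, 0),        # m
    "V": (0, 3, 0),        # m^3
    "l": (0, 1, 0),        # m
    "Pa": (1, -1, -2),
}


def audit_modulus_relation_units() -> None:
    """Verify that dPdV * t * V / l has the dimensions of a pressure.

    Raises :class:`DimensionalError` if the configured grouping is not a
    pressure; called by the compliance/modulus conversions.
    """
    total = tuple(
        _DIMENSIONS["dPdV"][i] + _DIMENSIONS["t"][i]
        + _DIMENSIONS["V"][i] - _DIMENSIONS["l"][i]
        for i in range(3)
    )
    if total != _DIMENSIONS["Pa"]:
        raise DimensionalError(
            f"modulus relation grouping has dimensions kg^{total[0]} m^{total[1]} "
            f"s^{total[2]}, expected a pressure (kg^1 m^-1 s^-2)")


def _require_positive(**kwargs: float) -> None:
    for name, v in kwargs.items():
        if not (np.isfinite(v) and v > 0):
            raise ParameterError(f"{name}: must be finite and > 0")


@dataclass(frozen=True)
class CatheterSpec:
    """Geometry, material and lumen fluid of a fluid-filled catheter.

    Lengths in m, modulus in Pa, viscosity in Pa s, density in kg/m^3.
    ``dPdV`` (Pa/m^3), ``f_n`` (Hz) and ``zeta`` may be given directly or
    derived; if stored values are given alongside a ``dPdV`` they must be
    consistent with the mass-spring formulas within 1%.
    """

    l: float                  # total length (m)
    R: float                  # lumen internal radius (m)
    R_c: float                # external radius (m)
    t: float                  # annulus wall thickness (m)
    E_cath: float | None = None   # catheter Young's modulus (Pa)
    mu: float = 0.001002      # lumen-fluid viscosity (Pa s)
    rho: float = 998.0        # lumen-fluid density (kg/m^3)
    dPdV: float | None = None     # inverse compliance (Pa/m^3)
    f_n: float | None = None      # natural frequency (Hz)
    zeta: float | None = None     # damping coefficient (-)

    def __post_init__(self):
        _require_positive(l=self.l, R=self.R, R_c=self.R_c, t=self.t,
                          mu=self.mu, rho=self.rho)
        if self.R >= self.R_c:
            raise ParameterError("R: lumen radius must be < external radius R_c")
        for name in ("E_cath", "dPdV", "f_n", "zeta"):
            v = getattr(self, name)
            if v is not None and not (np.isfinite(v) and v > 0):
                raise ParameterError(f"{name}: must be finite and > 0 when set")
        if self.dPdV is not None:
            if self.f_n is not None:
                fn_derived = natural_frequency(self, self.dPdV)
                if abs(fn_derived - self.f_n) > 0.01 * self.f_n:
                    raise ParameterError(
                        f"f_n: stored value {self.f_n} Hz inconsistent with dPdV "
                        f"(implies {fn_derived:.3g} Hz)")
            if self.zeta is not None:
                z_derived = damping_coefficient(self, self.dPdV)
                if abs(z_derived - self.zeta) > 0.01 * self.zeta:
                    raise ParameterError(
                        f"zeta: stored value {self.zeta} inconsistent with dPdV "
                        f"(implies {z_derived:.3g})")

    @property
    def lumen_volume(self) -> float:
        """Fluid volume of the lumen, V = pi R^2 l (m^3)."""
        return math.pi * self.R ** 2 * self.l


def compliance_from_modulus(c: CatheterSpec) -> float:
    """Inverse compliance dP/dV (Pa/m^3) from the catheter wall modulus.

    Uses dP/dV = 3 pi l E_cath / (2 t V) with V = pi R^2 l; exact inverse
    of :func:`modulus_from_compliance`.
    """
    audit_modulus_relation_units()
    if c.E_cath is None:
        raise ParameterError("E_cath: required to derive dP/dV")
    return 3.0 * math.pi * c.l * c.E_cath / (2.0 * c.t * c.lumen_volume)


def modulus_from_compliance(c: CatheterSpec, dPdV: float) -> float:
    """Catheter wall modulus (Pa) from the inverse compliance dP/dV."""
    audit_modulus_relation_units()
    _require_positive(dPdV=dPdV)
    return dPdV * 2.0 * c.t * c.lumen_volume / (3.0 * math.pi * c.l)


def implied_compliance_inverse(f_n: float, R: float, l: float, rho: float) -> float:
    """Invert the natural-frequency formula for dP/dV (Pa/m^3).

    dP/dV = (2 pi f_n)^2 rho l / (pi R^2). This is the route used to anchor
    the reference catheter's compliance to its measured f_n.
    """
    _require_positive(f_n=f_n, R=R, l=l, rho=rho)
    return (2.0 * math.pi * f_n) ** 2 * rho * l / (math.pi * R ** 2)


def natural_frequency(c: CatheterSpec, dPdV: float) -> float:
    """Undamped natural frequency f_n (Hz) of the catheter-manometer system."""
    _require_positive(dPdV=dPdV)
    return math.sqrt(math.pi * c.R ** 2 * dPdV / (c.rho * c.l)) / (2.0 * math.pi)


def damping_coefficient(c: CatheterSpec, dPdV: float) -> float:
    """Damping coefficient zeta (dimensionless) of the catheter-manometer system."""
    _require_positive(dPdV=dPdV)
    return (4.0 * c.mu * c.l / c.R ** 3) / math.sqrt(c.rho * c.l * math.pi * dPdV)


def amplitude_response(f: float, f_n: float, zeta: float) -> float:
    """Steady-state amplitude gain |H(f)| of the second-order system.

    |H| = 1 / sqrt((1 - r^2)^2 + (2 zeta r)^2), r = f/f_n. Unity at DC;
    1/(2 zeta) at resonance; for zeta >= 1/sqrt(2) the response is
    monotone (no resonance peaking).
    """
    _require_positive(f_n=f_n, zeta=zeta)
    if not (np.isfinite(f) and f >= 0):
        raise ParameterError("f: must be finite and >= 0")
    r = f / f_n
    return 1.0 / math.sqrt((1.0 - r * r) ** 2 + (2.0 * zeta * r) ** 2)


def measure_with_catheter(true_p: PressureWaveform, f_n: float,
                          zeta: float) -> PressureWaveform:
    """Distort a true pressure waveform through the catheter-manometer response.

    Integrates y'' + 2 zeta w_n y' + w_n^2 y = w_n^2 p(t), w_n = 2 pi f_n,
    with fixed-step RK4 at the waveform rate (internally sub-stepped when
    f_n/rate > 0.1 so the integrator resolves the system dynamics). The
    output starts at the first input sample with zero velocity, has unit DC
    gain, and keeps the input's length, rate and t0.

    The first ~2/(zeta w_n) seconds of output are the settling transient of
    the initial condition; downstream feature extraction should skip them.
    """
    if not (np.isfinite(f_n) and f_n > 0):
        raise ParameterError("f_n: must be finite and > 0")
    if not (np.isfinite(zeta) and zeta > 0):
        raise ParameterError("zeta: must be > 0 (undamped system is unstable)")

    p = true_p.samples
    dt = 1.0 / true_p.rate
    wn = 2.0 * math.pi * f_n
    nsub = max(1, math.ceil(f_n * dt / 0.1))
    h = dt / nsub

    def deriv(y, v, pin):
        return v, wn * wn * (pin - y) - 2.0 * zeta * wn * v

    out = np.empty_like(p)
    y, v = p[0], 0.0
    out[0] = y
    for i in range(p.size - 1):
        p0, p1 = p[i], p[i + 1]
        for k in range(nsub):
            # linear interpolation of the input inside the sample interval
            pa = p0 + (p1 - p0) * (k / nsub)
            pm = p0 + (p1 - p0) * ((k + 0.5) / nsub)
            pb = p0 + (p1 - p0) * ((k + 1.0) / nsub)
            k1y, k1v = deriv(y, v, pa)
            k2y, k2v = deriv(y + 0.5 * h * k1y, v + 0.5 * h * k1v, pm)
            k3y, k3v = deriv(y + 0.5 * h * k2y, v + 0.5 * h * k2v, pm)
            k4y, k4v = deriv(y + h * k3y, v + h * k3v, pb)
            y += h * (k1y + 2 * k2y + 2 * k3y + k4y) / 6.0
            v += h * (k1v + 2 * k2v + 2 * k3v + k4v) / 6.0
        out[i + 1] = y
    return true_p.with_samples(out)
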