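"""Standard boundary-value DEP theory for homogeneous particles.

The macroscopic Clausius-Mossotti (CM) factor of a sphere,

    [CM] = (eps_p* - eps_m*)/(eps_p* + 2 eps_m*),

with the Maxwell-Wagner complex permittivity eps* = eps - j*sigma/(omega*eps_0),
controls the frequency dependence of the DEP force F = eps_0*chi_DEP*grad(E^2)
through the volume-scaled susceptibility chi_DEP = (3/2) V_p eps_m Re[CM].
Re[CM] is bounded in (-0.5, 1.0) for any physical permittivity/conductivity
pair, so negative DEP can never exceed half the strength of the strongest
positive response.

Spheroids are handled through the depolarization factor A (sphere 1/3;
field-aligned prolate spheroids approach 0, thin oblate platelets approach 1).
Two susceptibility conventions circulate for spheroids: the moment-normalized
factor used for the sphere, and the depolarization form
(eps_p - eps_m)/(eps_m + A(eps_p - eps_m)) commonly quoted with A = 0.2 / 0.8
for globular proteins (equal to three times the sphere factor at A = 1/3).
``chi_dep`` follows the second convention for non-spherical A because the
published Brownian-threshold curves for protein-shaped spheroids are computed
with it; the sphere route uses [CM] itself.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

from .constants import DEFAULT_TEMPERATURE, EPS_0, K_B, WATER_EPS_STATIC, debye_to_si
from .dispersion import SpectrumModel, eps_of_frequency

__all__ = [
    "Medium",
    "ParticleMaterial",
    "ParticleGeometry",
    "FieldDrive",
    "Environment",
    "cm_factor",
    "cm_factor_conductivity",
    "cm_crossover_profile",
    "interface_moment_spheroid",
    "chi_dep",
    "dep_force",
    "threshold_grad_E2",
    "chi_rigid_dipole",
    "rigid_to_induced_ratio",
    "crossover_frequency",
    "depolarization_factor",
]

SPHERE_A = 1.0 / 3.0
#: below this frequency displacement currents no longer dominate and the
#: permittivity-only CM factor loses meaning
LOW_FREQ_GUARD_HZ = 1e3


@dataclass(frozen=True)
class Medium:
    """Suspending medium: relative permittivity and conductivity (S/m)."""

    eps_r: float
    sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.eps_r < 1.0:
            raise ValueError(f"eps_r must be >= 1, got {self.eps_r}")
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")

    def complex_eps(self, f: float) -> complex:
        """Relative complex permittivity eps_r - j*sigma/(omega*eps_0)."""
        if f <= 0:
            raise ValueError("frequency must be positive")
        return self.eps_r - 1j * self.sigma / (2.0 * math.pi * f * EPS_0)


class ParticleMaterial(Medium):
    """Particle material; same fields and validation as :class:`Medium`."""


@dataclass(frozen=True)
class ParticleGeometry:
    """Spheroid geometry: semiaxes, depolarization factor, volume.

    ``depolarization_A`` is an input (common presets: 1/3 sphere, 0.2
    field-aligned prolate, 0.8 oblate); :func:`depolarization_factor`
    computes it from semiaxes for a general ellipsoid.
    """

    a: float
    b: float
    c: float
    depolarization_A: float = SPHERE_A

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("semiaxes must be positive")
        if not 0.0 <= self.depolarization_A <= 1.0:
            raise ValueError(
                f"depolarization_A must be in [0, 1], got {self.depolarization_A}"
            )

    @property
    def volume(self) -> float:
        """Spheroid volume (4*pi/3)*a*b*c, m^3."""
        return 4.0 * math.pi / 3.0 * self.a * self.b * self.c

    @property
    def radius(self) -> float:
        """Sphere-equivalent radius (abc)^(1/3), m."""
        return (self.a * self.b * self.c) ** (1.0 / 3.0)

    @property
    def is_sphere(self) -> bool:
        return math.isclose(self.depolarization_A, SPHERE_A, rel_tol=1e-9)

    @classmethod
    def sphere(cls, radius: float) -> "ParticleGeometry":
        return cls(a=radius, b=radius, c=radius, depolarization_A=SPHERE_A)

    @classmethod
    def spheroid(cls, a: float, b: float, c: float, A: float) -> "ParticleGeometry":
        return cls(a=a, b=b, c=c, depolarization_A=A)


@dataclass(frozen=True)
class FieldDrive:
    """Applied field: magnitude, gradient-of-E^2 factor, and frequency."""

    E_m: float = 0.0
    grad_E2: float = 0.0
    frequency: float = 0.0

    def __post_init__(self) -> None:
        if self.grad_E2 < 0:
            raise ValueError("grad_E2 must be >= 0")


@dataclass(frozen=True)
class Environment:
    """Thermal environment; temperature in kelvin."""

    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def kT(self) -> float:
        return K_B * self.temperature


def _cm_complex(eps_p, sigma_p, eps_m, sigma_m, f):
    """Vectorized complex CM factor; internal workhorse for grids."""
    omega_eps0 = 2.0 * math.pi * np.asarray(f, dtype=float) * EPS_0
    ep = np.asarray(eps_p, dtype=complex) - 1j * np.asarray(sigma_p) / omega_eps0
    em = np.asarray(eps_m, dtype=complex) - 1j * np.asarray(sigma_m) / omega_eps0
    return (ep - em) / (ep + 2.0 * em)


def cm_factor(p: Medium, m: Medium, f: float | str = "static") -> complex:
    """Clausius-Mossotti factor of a sphere at frequency ``f``.

    ``f="static"`` returns the lossless real value from permittivities only;
    requesting it with nonzero conductivities is ambiguous (the DC limit is
    conductivity-dominated) and raises.  Numeric ``f`` below ~1 kHz with a
    permittivity-only model triggers a regime warning: interfacial double
    layers and conduction dominate there.
    """
    if isinstance(f, str):
        if f != "static":
            raise ValueError(f"frequency must be positive or 'static', got {f!r}")
        if p.sigma != 0 or m.sigma != 0:
            raise ValueError(
                "static CM with nonzero conductivity is undefined; use the "
                "conductivity limit cm_factor_conductivity(p, m) instead"
            )
        return complex((p.eps_r - m.eps_r) / (p.eps_r + 2.0 * m.eps_r))
    if f <= 0:
        raise ValueError("frequency must be positive")
    if f < LOW_FREQ_GUARD_HZ and p.sigma == 0 and m.sigma == 0:
        warnings.warn(
            "permittivity-only CM below ~1 kHz: conduction and double-layer "
            "effects dominate this regime",
            stacklevel=2,
        )
    return complex(_cm_complex(p.eps_r, p.sigma, m.eps_r, m.sigma, f))


def cm_factor_conductivity(p: Medium, m: Medium) -> float:
    """Low-frequency (conductivity-dominated) CM limit."""
    denom = p.sigma + 2.0 * m.sigma
    if denom == 0:
        raise ValueError("both conductivities are zero; conductivity limit undefined")
    return (p.sigma - m.sigma) / denom


def cm_crossover_profile(f, f_xo: float):
    """Re[CM] near a crossover: (f^2 - f_xo^2)/(f^2 + 2 f_xo^2).

    Negative below ``f_xo`` (-0.5 limit), positive above (+1 limit).
    """
    f = np.asarray(f, dtype=float)
    if f_xo <= 0 or np.any(f <= 0):
        raise ValueError("frequencies must be positive")
    out = (f**2 - f_xo**2) / (f**2 + 2.0 * f_xo**2)
    return out if out.ndim else float(out)


def interface_moment_spheroid(
    p: Medium, m: Medium, geom: ParticleGeometry, drive: FieldDrive
) -> float:
    """Induced interface dipole moment of a field-aligned spheroid, C.m.

    M = (4*pi*abc/3) * eps_0 * eps_m * (eps_p - eps_m) /
        (eps_m + A(eps_p - eps_m)) * E_m

    Reduces exactly to the spherical result 3*V_p*eps_0*eps_m*[CM]*E_m at
    A = 1/3.  A -> 0 removes interfacial shielding (moment ~ (eps_p-eps_m)/
    eps_m); A -> 1 gives the fully shielded platelet (~ (eps_p-eps_m)/eps_p).
    """
    A = geom.depolarization_A
    denom = m.eps_r + A * (p.eps_r - m.eps_r)
    if abs(denom) < 1e-300:
        raise ValueError("vanishing depolarization denominator (pathological eps)")
    return geom.volume * EPS_0 * m.eps_r * (p.eps_r - m.eps_r) / denom * drive.E_m


def chi_dep(
    p: Medium, m: Medium, geom: ParticleGeometry, f: float | str = "static"
) -> float:
    """DEP susceptibility chi_DEP (m^3) of a homogeneous spheroid.

    Sphere (A = 1/3): chi = (3/2) V_p eps_m Re[CM].
    Spheroid: chi = (3/2) V_p eps_m Re[(eps_p* - eps_m*)/(eps_m* +
    A(eps_p* - eps_m*))], which reproduces the standard A = 0.2 prolate form
    5(eps_p - eps_m)/(eps_p + 4 eps_m) and A = 0.8 oblate form
    5(eps_p - eps_m)/(4 eps_p + eps_m).  See module docstring for the
    convention difference between the two branches.
    """
    if geom.is_sphere:
        factor = cm_factor(p, m, f).real
    else:
        if isinstance(f, str):
            if f != "static":
                raise ValueError(f"frequency must be positive or 'static', got {f!r}")
            ep: complex = complex(p.eps_r)
            em: complex = complex(m.eps_r)
        else:
            ep = p.complex_eps(f)
            em = m.complex_eps(f)
        A = geom.depolarization_A
        denom = em + A * (ep - em)
        if abs(denom) < 1e-300:
            raise ValueError("vanishing depolarization denominator (pathological eps)")
        factor = ((ep - em) / denom).real
    return 1.5 * geom.volume * m.eps_r * factor


def dep_force(chi: float, drive: FieldDrive) -> float:
    """Time-averaged DEP force F = eps_0 * chi * grad(E^2), newtons."""
    return EPS_0 * chi * drive.grad_E2


def threshold_grad_E2(chi: float, env: Environment = Environment()) -> float:
    """grad(E^2) needed for the DEP force to beat thermal energy (3/2)kT.

    3kT/(2*eps_0*|chi|); scales as R^-3 for fixed materials.
    """
    if chi == 0:
        raise ValueError("chi must be nonzero for a Brownian threshold")
    return 3.0 * env.kT / (2.0 * EPS_0 * abs(chi))


def chi_rigid_dipole(m_p_debye: float, env: Environment = Environment()) -> float:
    """DEP susceptibility of a freely tumbling permanent dipole, m^3.

    chi_d = m^2/(6*eps_0*kT), the orientational-polarizability route with
    the dipole moment given in debye.
    """
    if m_p_debye < 0:
        raise ValueError("dipole moment must be >= 0")
    m_si = debye_to_si(m_p_debye)
    return m_si**2 / (6.0 * EPS_0 * env.kT)


def rigid_to_induced_ratio(
    m_p_debye: float, chi_induced: float, env: Environment = Environment()
) -> float:
    """Ratio of rigid-dipole to induced-moment DEP force magnitudes."""
    if chi_induced == 0:
        raise ValueError(
            "chi_induced is zero (eps_p = eps_m degenerate case); ratio undefined"
        )
    return chi_rigid_dipole(m_p_debye, env) / abs(chi_induced)


def crossover_frequency(
    model: SpectrumModel,
    eps_solvent: float = WATER_EPS_STATIC,
    f_min: float = 1e-2,
    f_max: float = 1e13,
    rtol: float = 1e-6,
) -> float | None:
    """Frequency where the mixture permittivity falls to the solvent value.

    The dispersion is a monotone non-increasing function of frequency, so
    the root is unique when it exists.  Returns None when the static
    permittivity never exceeds ``eps_solvent`` (no dielectric increment) or
    the high-frequency limit stays above it (no decrement in range).
    """
    if model.eps_static <= eps_solvent or model.eps_hf >= eps_solvent:
        return None

    def g(logf: float) -> float:
        return eps_of_frequency(model, 10.0**logf) - eps_solvent

    grid = np.linspace(math.log10(f_min), math.log10(f_max), 400)
    vals = eps_of_frequency(model, 10.0**grid) - eps_solvent
    idx = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
    if idx.size == 0:
        return None
    lo, hi = grid[idx[0]], grid[idx[0] + 1]
    root = brentq(g, lo, hi, xtol=1e-12)
    # brentq works in log-space; polish tolerance is far tighter than rtol
    return float(10.0**root)


def depolarization_factor(a: float, b: float, c: float) -> float:
    """Depolarization factor along the a-axis of a general ellipsoid.

    A_a = (abc/2) * int_0^inf ds / ((s+a^2)^(3/2) sqrt((s+b^2)(s+c^2)))

    Provided as a helper; the common presets (1/3, 0.2, 0.8) can be given
    directly to :class:`ParticleGeometry`.
    """
    if min(a, b, c) <= 0:
        raise ValueError("semiaxes must be positive")

    # substitute s = a^2 * t/(1-t) to map to a finite interval
    def integrand(t: float) -> float:
        s = a * a * t / (1.0 - t)
        jac = a * a / (1.0 - t) ** 2
        return jac / ((s + a * a) ** 1.5 * math.sqrt((s + b * b) * (s + c * c)))

    val, _ = quad(integrand, 0.0, 1.0, limit=200)
    return a * b * c / 2.0 * val
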