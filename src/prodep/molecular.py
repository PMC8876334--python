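"""Molecular dielectrics: from the Clausius-Mossotti law to protein dipoles.

This module collects the classical chain that links a polar liquid's static
permittivity to the dipole moments of its molecules:

* the Clausius-Mossotti law eps = (1+2g)/(1-g) and its Lorentz local-field
  form (eps-1)/(eps+2) = N*alpha/(3*eps_0), with the ferroelectric
  ("Mossotti catastrophe") singularity at g -> 1;
* Lorentz (virtual) and Maxwell (real) cavity susceptibilities;
* Debye-Langevin orientational polarization L(x) = coth x - 1/x;
* Onsager's reaction field acting back on a cavity dipole;
* the Kirkwood correlation factor g_k = <M^2>/(N m^2) and the
  Kirkwood-Froehlich equation (eps-1)(2eps+1)/(9eps) = N_dip*g_k;
* Froehlich's fluctuation relations connecting <M^2> in zero field to the
  permittivity of an embedded region;
* the Oncley and South-Grant relations between a protein's beta-dispersion
  strength and its permanent dipole moment.

Dipole moments cross these interfaces in debye (1 D = 3.335641e-30 C.m)
except where a mean-square moment in SI is the natural MD-facing quantity.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .constants import DEBYE, EPS_0, K_B, N_A, debye_to_si
from .dispersion import DebyeMode
from .macroscopic import Environment

__all__ = [
    "ProteinRecord",
    "DipoleEnsemble",
    "SolventRef",
    "cm_law_eps",
    "polarizability_side",
    "eps_from_polarizability",
    "lorentz_cavity_chi",
    "maxwell_cavity_chi",
    "langevin",
    "orientation_parameter",
    "onsager_interface_moment",
    "kirkwood_g",
    "kirkwood_g_central",
    "kirkwood_tetrahedral",
    "kirkwood_frohlich_solve",
    "kirkwood_frohlich_product",
    "n_dip_static",
    "n_dip_of_omega",
    "frohlich_eps_self",
    "frohlich_eps_embedded",
    "frohlich_msq_from_eps",
    "moment_fluctuation_error",
    "oncley_delta_eps",
    "dipole_from_beta",
    "south_grant_delta_eps",
    "gkp_from_b",
    "south_grant_mixture_eps",
    "two_polar_mixture_spectrum",
]


@dataclass(frozen=True)
class ProteinRecord:
    """Physical summary of a globular protein for dielectric/DEP work."""

    name: str
    molecular_weight: float | None = None  # g/mol
    mass_density: float | None = None  # g/cm^3
    dipole_moment: float | None = None  # debye, point estimate
    moment_mean: float | None = None  # debye, ensemble mean
    moment_width: float | None = None  # debye, Gaussian width
    hydrodynamic_radius: float | None = None  # m
    shape: str = "sphere"
    depolarization_A: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        for attr in (
            "molecular_weight",
            "mass_density",
            "dipole_moment",
            "moment_mean",
            "hydrodynamic_radius",
        ):
            v = getattr(self, attr)
            if v is not None and v <= 0:
                raise ValueError(f"{attr} must be positive, got {v}")
        if self.moment_width is not None and self.moment_width < 0:
            raise ValueError("moment_width must be >= 0")
        if (
            self.moment_width is not None
            and self.moment_mean is not None
            and self.moment_width > self.moment_mean
        ):
            raise ValueError("moment_width must not exceed moment_mean")

    @property
    def molar_volume(self) -> float:
        """Molar volume M_W/rho, cm^3/mol."""
        if self.molecular_weight is None or self.mass_density is None:
            raise ValueError(f"{self.name}: need molecular_weight and mass_density")
        return self.molecular_weight / self.mass_density


@dataclass(frozen=True)
class DipoleEnsemble:
    """Dipole vectors: a snapshot (N, 3) or a trajectory (T, N, 3) / (T, 3).

    ``unit`` flags whether components are in C.m ("si") or debye ("debye").
    """

    vectors: np.ndarray
    kind: str = "snapshot"
    unit: str = "si"

    def __post_init__(self) -> None:
        v = np.asarray(self.vectors, dtype=float)
        if v.size == 0:
            raise ValueError("vectors must be non-empty")
        if v.shape[-1] != 3:
            raise ValueError("last axis must have length 3")
        if self.kind not in ("snapshot", "trajectory"):
            raise ValueError(f"kind must be snapshot|trajectory, got {self.kind!r}")
        if self.unit not in ("si", "debye"):
            raise ValueError(f"unit must be si|debye, got {self.unit!r}")
        object.__setattr__(self, "vectors", v)

    def as_si(self) -> np.ndarray:
        return self.vectors * (DEBYE if self.unit == "debye" else 1.0)


@dataclass(frozen=True)
class SolventRef:
    """Reference polar solvent (water): static/high-f permittivity, dipole."""

    eps_static: float
    eps_inf: float = 1.0
    dipole_moment: float | None = None  # debye
    number_density: float | None = None  # m^-3
    g_k: float | None = None

    def __post_init__(self) -> None:
        if not self.eps_static > self.eps_inf >= 1.0:
            raise ValueError("require eps_static > eps_inf >= 1")


# ---------------------------------------------------------------------------
# Clausius-Mossotti law and cavity fields
# ---------------------------------------------------------------------------


def cm_law_eps(g: float) -> float:
    """Static permittivity from the Clausius-Mossotti packing factor g.

    eps = (1 + 2g)/(1 - g).  The law diverges as g -> 1 (the 'Mossotti
    catastrophe': infinite polarization / ferroelectric transition), so
    g >= 1 raises.
    """
    if g < 0:
        raise ValueError("g must be >= 0")
    if g >= 1:
        raise ValueError(
            "Mossotti catastrophe: g >= 1 implies infinite polarization"
        )
    return (1.0 + 2.0 * g) / (1.0 - g)


def polarizability_side(N: float, alpha: float) -> float:
    """Right-hand side of the Lorentz form: N*alpha/(3*eps_0)."""
    return N * alpha / (3.0 * EPS_0)


def eps_from_polarizability(side: float) -> float:
    """Solve (eps-1)/(eps+2) = side for eps; side >= 1 is catastrophic."""
    if side < 0:
        raise ValueError("N*alpha/(3 eps_0) must be >= 0")
    if side >= 1:
        raise ValueError("Mossotti catastrophe: N*alpha/(3 eps_0) >= 1")
    return (1.0 + 2.0 * side) / (1.0 - side)


def lorentz_cavity_chi(eps_m: float, s: float = 0.0) -> float:
    """Lorentz (virtual cavity) susceptibility (1/3)[eps+2+s(eps-1)].

    Field-enhancing: >= 1 for all eps_m >= 1, s >= 0. The s-term is the
    near-field correction, zero for a cubic or uncorrelated isotropic
    lattice.
    """
    if eps_m < 1:
        raise ValueError("eps_m must be >= 1")
    return (eps_m + 2.0 + s * (eps_m - 1.0)) / 3.0


def maxwell_cavity_chi(eps_m: float) -> float:
    """Maxwell (real cavity) susceptibility 3*eps/(2*eps+1), in [1, 1.5)."""
    if eps_m < 1:
        raise ValueError("eps_m must be >= 1")
    return 3.0 * eps_m / (2.0 * eps_m + 1.0)


# ---------------------------------------------------------------------------
# Orientational polarization
# ---------------------------------------------------------------------------


def langevin(x):
    """Langevin function L(x) = coth(x) - 1/x, series-expanded for |x| small.

    Odd, bounded in (-1, 1), L(x) ~ x/3 - x^3/45 near zero.
    """
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = np.abs(x) < 1e-4
    xs = x[small]
    out[small] = xs / 3.0 - xs**3 / 45.0
    xl = x[~small]
    out[~small] = 1.0 / np.tanh(xl) - 1.0 / xl
    return out if out.ndim else float(out)


def orientation_parameter(
    m_debye: float, E: float, env: Environment = Environment()
) -> float:
    """Dimensionless Langevin argument x = m*E/kT (moment in debye)."""
    if E < 0:
        raise ValueError("field magnitude must be >= 0")
    return debye_to_si(m_debye) * E / env.kT


def onsager_interface_moment(eps_m: float, m_o_debye: float) -> float:
    """Reaction-field interface moment -2(eps-1)/(2eps+1) * m_o, debye.

    Opposes the cavity dipole and approaches -m_o for strongly polar media.
    """
    if eps_m < 1:
        raise ValueError("eps_m must be >= 1")
    return -2.0 * (eps_m - 1.0) / (2.0 * eps_m + 1.0) * m_o_debye


# ---------------------------------------------------------------------------
# Kirkwood correlation
# ---------------------------------------------------------------------------


def kirkwood_g(ens: DipoleEnsemble, m_single_debye: float) -> float:
    """Kirkwood correlation factor g_k = <M^2>/(N m^2).

    For a snapshot (N, 3) the estimate is |sum m_i|^2/(N m^2) from that one
    configuration; for a trajectory (T, N, 3) the configurational average
    over T frames is used.  Equals 1 in expectation for uncorrelated
    isotropic dipoles, and N for N perfectly parallel dipoles.
    """
    if m_single_debye <= 0:
        raise ValueError("single-molecule moment must be positive")
    m_si = debye_to_si(m_single_debye)
    v = ens.as_si()
    if v.ndim == 2:  # one configuration of N dipoles
        n = v.shape[0]
        msq = float(np.sum(v.sum(axis=0) ** 2))
    elif v.ndim == 3:  # T configurations of N dipoles
        n = v.shape[1]
        total = v.sum(axis=1)
        msq = float(np.mean(np.sum(total**2, axis=1)))
    else:
        raise ValueError("vectors must have shape (N, 3) or (T, N, 3)")
    return msq / (n * m_si**2)


def kirkwood_g_central(ens: DipoleEnsemble, m_single_debye: float) -> float:
    """Central-dipole Kirkwood estimator <m_0 . M>/m^2 = 1 + z<cos theta>.

    The first dipole of each configuration is the reference; M is the total
    moment of the configuration (reference included).  Requires trajectory
    data (T, N, 3) for a meaningful average.
    """
    if m_single_debye <= 0:
        raise ValueError("single-molecule moment must be positive")
    v = ens.as_si()
    if v.ndim == 2:
        v = v[None, :, :]
    if v.ndim != 3:
        raise ValueError("vectors must have shape (N, 3) or (T, N, 3)")
    m_si = debye_to_si(m_single_debye)
    central = v[:, 0, :]
    total = v.sum(axis=1)
    return float(np.mean(np.sum(central * total, axis=1))) / m_si**2


def kirkwood_tetrahedral(z: float, theta_deg: float) -> float:
    """g_k of a rigid H-bonded network: 1 + z*cos^2(theta/2).

    ``theta`` is the H-O-H bond angle in degrees and ``z`` the coordination
    number.  This is the enhancement reading of the tetrahedral-network
    formula (free rotation about bonds, no bond bending); the alternative
    rendering 1 + z*cos(2*theta)/2 cannot produce g_k > 1 at tetrahedral
    angles and is rejected.
    """
    if z < 0:
        raise ValueError("coordination number must be >= 0")
    return 1.0 + z * math.cos(math.radians(theta_deg) / 2.0) ** 2


# ---------------------------------------------------------------------------
# Kirkwood-Froehlich equation
# ---------------------------------------------------------------------------


def kirkwood_frohlich_product(eps_m: float) -> float:
    """Evaluate (eps-1)(2eps+1)/(9eps), the N_dip*g_k side of the equation."""
    if eps_m < 1:
        raise ValueError("eps_m must be >= 1")
    return (eps_m - 1.0) * (2.0 * eps_m + 1.0) / (9.0 * eps_m)


def kirkwood_frohlich_solve(n_dip: float, g_k: float = 1.0) -> float:
    """Solve (eps-1)(2eps+1)/(9eps) = N_dip*g_k for the physical root.

    The quadratic 2eps^2 - (1+9P)eps - 1 = 0 (P = N_dip*g_k) has exactly one
    root >= 1; the solution is strictly increasing in P and equals 1 at P=0.
    """
    P = n_dip * g_k
    if P < 0:
        raise ValueError("N_dip * g_k must be >= 0")
    return ((1.0 + 9.0 * P) + math.sqrt((1.0 + 9.0 * P) ** 2 + 8.0)) / 4.0


def n_dip_static(N: float, m_debye: float, env: Environment = Environment()) -> float:
    """Dimensionless dipole polarizability density N*m^2/(9*eps_0*kT)."""
    if N < 0:
        raise ValueError("number density must be >= 0")
    m_si = debye_to_si(m_debye)
    return N * m_si**2 / (9.0 * EPS_0 * env.kT)


def n_dip_of_omega(n_dip: float, tau: float, f):
    """Dispersed polarizability density N_dip/(1 + omega^2 tau^2)."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    f = np.asarray(f, dtype=float)
    omega = 2.0 * math.pi * f
    out = n_dip / (1.0 + (omega * tau) ** 2)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Froehlich fluctuation relations
# ---------------------------------------------------------------------------


def frohlich_eps_self(msq: float, volume: float, env: Environment = Environment()) -> float:
    """Permittivity of a region from its zero-field moment fluctuation.

    Solves eps - 1 = <M^2>/(3kT eps_0 V) * 3eps/(2eps+1) self-consistently
    (the embedding medium is the material itself).  <M^2> in (C.m)^2.
    """
    if msq < 0:
        raise ValueError("<M^2> must be >= 0")
    if volume <= 0:
        raise ValueError("volume must be positive")
    S = msq / (3.0 * env.kT * EPS_0 * volume)
    # (eps-1)(2eps+1) = 3 S eps  ->  2eps^2 - (1+3S) eps - 1 = 0
    return ((1.0 + 3.0 * S) + math.sqrt((1.0 + 3.0 * S) ** 2 + 8.0)) / 4.0


def frohlich_eps_embedded(
    msq: float, volume: float, eps_m: float, env: Environment = Environment()
) -> float:
    """Permittivity of a fluctuating region embedded in a medium eps_m.

    Solves eps_p - 1 = <M_p^2>/(3kT eps_0 V_p) * (2eps_m+eps_p)/(2eps_m+1)
    for eps_p; with eps_p = eps_m the relation collapses to
    :func:`frohlich_eps_self` (the cavity factor becomes the Maxwell cavity
    susceptibility).
    """
    if msq < 0:
        raise ValueError("<M^2> must be >= 0")
    if volume <= 0:
        raise ValueError("volume must be positive")
    if eps_m < 1:
        raise ValueError("eps_m must be >= 1")
    S = msq / (3.0 * env.kT * EPS_0 * volume)
    denom = 2.0 * eps_m + 1.0 - S
    if denom <= 0:
        raise ValueError("no physical root: fluctuation too large for embedding")
    return (2.0 * eps_m + 1.0 + 2.0 * S * eps_m) / denom


def frohlich_msq_from_eps(
    eps_p: float, volume: float, eps_m: float, env: Environment = Environment()
) -> float:
    """Invert :func:`frohlich_eps_embedded`: <M_p^2> implied by eps_p."""
    if eps_p < 1 or eps_m < 1:
        raise ValueError("permittivities must be >= 1")
    if volume <= 0:
        raise ValueError("volume must be positive")
    S = (eps_p - 1.0) * (2.0 * eps_m + 1.0) / (2.0 * eps_m + eps_p)
    return S * 3.0 * env.kT * EPS_0 * volume


def moment_fluctuation_error(mean_debye: float, width_debye: float) -> float:
    """Percent error of assuming M^2 ~ <M>^2 under Gaussian fluctuation.

    100 * width^2 / mean^2, the relative difference between the mean-square
    moment and the squared mean.
    """
    if mean_debye <= 0:
        raise ValueError("mean moment must be positive")
    if width_debye < 0:
        raise ValueError("width must be >= 0")
    return 100.0 * (width_debye / mean_debye) ** 2


# ---------------------------------------------------------------------------
# Protein beta-dispersion <-> dipole moment
# ---------------------------------------------------------------------------


def _number_density(C_p_g_per_L: float, M_w: float) -> float:
    """Molecules per m^3 from concentration in g/L and molar mass in g/mol."""
    return N_A * C_p_g_per_L * 1e3 / M_w


def oncley_delta_eps(
    protein: ProteinRecord,
    C_p: float,
    b: float = 4.5,
    env: Environment = Environment(temperature=298.0),
) -> float:
    """Oncley's semiempirical beta-dispersion strength.

    delta_eps(beta) = b * N * m_p^2 / (9 eps_0 kT) with N the protein
    number density from concentration ``C_p`` (g/L).  b = 4.5 is the
    calibration that brings dispersion-derived protein moments into line
    with structural estimates (Oncley's original amino-acid value was 5.8).
    """
    if C_p <= 0:
        raise ValueError("concentration must be positive")
    if protein.molecular_weight is None or protein.dipole_moment is None:
        raise ValueError("protein needs molecular_weight and dipole_moment")
    N = _number_density(C_p, protein.molecular_weight)
    m_si = debye_to_si(protein.dipole_moment)
    return b * N * m_si**2 / (9.0 * EPS_0 * env.kT)


def dipole_from_beta(
    delta_eps_beta: float,
    C_p: float,
    M_w: float,
    b: float = 4.5,
    env: Environment = Environment(temperature=298.0),
) -> float:
    """Invert Oncley's relation: protein dipole moment in debye."""
    if delta_eps_beta < 0 or C_p <= 0 or M_w <= 0 or b <= 0:
        raise ValueError("all inputs must be positive (delta_eps >= 0)")
    N = _number_density(C_p, M_w)
    m_si = math.sqrt(delta_eps_beta * 9.0 * EPS_0 * env.kT / (b * N))
    return m_si / DEBYE


def gkp_from_b(b: float, h: float) -> float:
    """Bridge Oncley's b to the South-Grant protein-water Kirkwood factor.

    Equating the two beta-dispersion expressions gives g_kp = b/(9h);
    h = 1/2 (point-dipole solvent) or 3/4 (continuum solvent).
    """
    if h <= 0:
        raise ValueError("h must be positive")
    return b / (9.0 * h)


def south_grant_delta_eps(
    protein: ProteinRecord,
    C_p: float,
    h: float = 0.5,
    g_kp: float = 1.0,
    env: Environment = Environment(temperature=298.0),
) -> float:
    """South-Grant beta-dispersion strength with explicit cross-correlation.

    delta_eps(beta) = h * N * g_kp * m_p^2 / (eps_0 kT); h = 1/2 for a
    point-dipole solvent, 3/4 for the continuum approximation (other values
    accepted with a warning).
    """
    if C_p <= 0:
        raise ValueError("concentration must be positive")
    if protein.molecular_weight is None or protein.dipole_moment is None:
        raise ValueError("protein needs molecular_weight and dipole_moment")
    if h not in (0.5, 0.75):
        warnings.warn(f"nonstandard h = {h}; canonical values are 0.5 and 0.75",
                      stacklevel=2)
    N = _number_density(C_p, protein.molecular_weight)
    m_si = debye_to_si(protein.dipole_moment)
    return h * N * g_kp * m_si**2 / (EPS_0 * env.kT)


def south_grant_mixture_eps(
    N_p: float,
    g_kp: float,
    m_p_debye: float,
    volume: float,
    solvent: SolventRef,
    env: Environment = Environment(temperature=298.0),
) -> float:
    """Static permittivity of a protein-water mixture (self-consistent).

    Solves  eps_mix - eps_sw = S * 3 eps_mix/(2 eps_mix + eps_sw)  with
    S = N_p g_kp m_p^2/(3 kT eps_0 V); N_p is the number of protein
    molecules in volume V (m^3).  Returns eps_mix >= eps_sw for m_p > 0.
    """
    if N_p < 0 or volume <= 0:
        raise ValueError("N_p must be >= 0 and volume positive")
    m_si = debye_to_si(m_p_debye)
    S = N_p * g_kp * m_si**2 / (3.0 * env.kT * EPS_0 * volume)
    if S < 0:
        raise ValueError("no physical root: negative correlation strength")
    e_sw = solvent.eps_static
    # 2 eps^2 - (eps_sw + 3S) eps - eps_sw^2 = 0
    disc = (e_sw + 3.0 * S) ** 2 + 8.0 * e_sw**2
    return ((e_sw + 3.0 * S) + math.sqrt(disc)) / 4.0


def two_polar_mixture_spectrum(
    v_p: float,
    protein_mode: DebyeMode,
    g_kp: float,
    m_p_debye: float,
    water_mode: DebyeMode,
    g_kw: float,
    m_w_debye: float,
    f,
):
    """Relative two-dispersion spectrum of a dilute polar-polar mixture.

    Proportional to
    v_p g_kp m_p^2/(1 + w^2 tau_p^2) + (1-v_p) g_kw m_w^2/(1 + w^2 tau_w^2);
    the absolute scale is unnormalized (moments in debye, result in D^2).
    Between the two relaxations (e.g. ~250 MHz for protein solutions) the
    protein term is fully dispersed while the water term is still static, so
    the level there reads out (1 - v_p) g_kw m_w^2.
    """
    if not 0.0 <= v_p <= 1.0:
        raise ValueError("v_p must be in [0, 1]")
    f = np.asarray(f, dtype=float)
    omega = 2.0 * math.pi * f
    p_term = v_p * g_kp * m_p_debye**2 / (1.0 + (omega * protein_mode.tau) ** 2)
    w_term = (1.0 - v_p) * g_kw * m_w_debye**2 / (1.0 + (omega * water_mode.tau) ** 2)
    out = p_term + w_term
    return out if out.ndim else float(out)
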