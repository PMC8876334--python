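"""Protein-specific DEP predictors.

Two routes replace the macroscopic Clausius-Mossotti factor for solvated
macromolecules with a permanent dipole moment:

1. The **empirical theory**: the measured beta-dispersion strength of the
   protein solution defines an effective factor

       (kappa+2)[CM]_empirical = (delta_eps_beta/eps_m) * (C_w rho_p)/(C_p rho_w)

   which, inserted into chi_DEP = (3/2) V_p eps_m (kappa+2)[CM]_emp, predicts
   force magnitudes; the polarity follows the dielectric increment/decrement
   criterion (positive DEP while the solution permittivity exceeds the
   solvent's, crossing over at f_xo).

2. The **K-factor theory** (Heyden-Matyushov): the boundary-value problem is
   replaced by the dipole cross-correlation of the protein with its hydration
   shell.  The cavity susceptibility chi_c^HM = 1 + <Mp.Mw>/<Mp^2> ties the
   beta and delta dispersion strengths together
   (delta_eps_beta = (9/2) v_p N_dip; delta_eps_delta = 9 v_p N_dip (chi_c-1)),
   and the DEP response is chi_DEP = (3/2) V_p eps_m Re[K] with
   K(w) = (2/9) eps(w) delta_eps(w) / v_p evaluated from complex Debye
   quantities of the mixture spectrum.  For a particle without a permanent
   dipole (N_dip = 0) the K route degenerates to [CM]_macro.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .constants import EPS_0, WATER_EPS_STATIC
from .dispersion import DebyeMode, SpectrumModel, complex_debye, eps_of_frequency
from .macroscopic import Environment, FieldDrive, Medium, cm_factor
from .molecular import DipoleEnsemble, lorentz_cavity_chi, n_dip_of_omega

__all__ = [
    "EmpiricalMixture",
    "HMParams",
    "empirical_cm_factor",
    "chi_dep_empirical",
    "dep_force_empirical",
    "chi_c_from_trajectory",
    "chi_c_hm_endpoint",
    "dispersion_strengths",
    "chi_c_from_dispersions",
    "delta_eps_delta_moment_form",
    "mixture_dispersion",
    "k_factor",
    "chi_dep_hm",
    "dep_susceptibility",
]


@dataclass(frozen=True)
class EmpiricalMixture:
    """Inputs of the empirical (kappa+2)[CM] predictor.

    Concentrations ``C_p``/``C_w`` are mole-volume fractions; ``kappa`` is 1
    for a particle without a permanent dipole and >> 1 (never a specific
    number here - only the product (kappa+2)[CM] is ever used) for polar
    macromolecules.
    """

    delta_eps_beta: float
    eps_m: float
    C_p: float
    C_w: float
    rho_p: float  # g/cm^3
    rho_w: float = 1.0  # g/cm^3
    kappa: float = 1.0

    def __post_init__(self) -> None:
        if self.eps_m <= 0:
            raise ValueError("eps_m must be positive")
        if self.C_w <= 0 or self.rho_p <= 0 or self.rho_w <= 0:
            raise ValueError("concentrations and densities must be positive")
        if self.C_p < 0:
            raise ValueError("C_p must be >= 0")
        if self.kappa < 1:
            raise ValueError("kappa must be >= 1")


@dataclass(frozen=True)
class HMParams:
    """Parameter bundle of the K-factor susceptibility stack."""

    n_dip: float
    chi_c: float
    v_p: float
    alpha: int = 0
    delta_eps_beta: float | None = None
    delta_eps_delta: float | None = None
    delta_eps_w: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.v_p <= 1.0:
            raise ValueError("v_p must be in (0, 1]")
        if self.alpha not in (0, 1):
            raise ValueError("alpha must be 0 or 1")
        if self.chi_c < 0:
            raise ValueError("chi_c must be >= 0")


# ---------------------------------------------------------------------------
# Empirical theory
# ---------------------------------------------------------------------------


def empirical_cm_factor(mix: EmpiricalMixture) -> float:
    """(kappa+2)[CM]_empirical from the beta-dispersion strength.

    (delta_eps_beta/eps_m) * (C_w rho_p)/(C_p rho_w).  The absolute scale is
    convention-dependent (it rides on the mole-volume-fraction definition of
    the concentrations); ratios and frequency profiles are the robust use.
    """
    if mix.C_p == 0:
        raise ValueError("C_p must be nonzero")
    return (mix.delta_eps_beta / mix.eps_m) * (mix.C_w * mix.rho_p) / (
        mix.C_p * mix.rho_w
    )


def chi_dep_empirical(V_p: float, mix: EmpiricalMixture) -> float:
    """Empirical DEP susceptibility chi = (3/2) V_p eps_m (kappa+2)[CM]_emp."""
    if V_p <= 0:
        raise ValueError("particle volume must be positive")
    return 1.5 * V_p * mix.eps_m * empirical_cm_factor(mix)


def dep_force_empirical(
    V_p: float,
    mix: EmpiricalMixture,
    model: SpectrumModel,
    drive: FieldDrive,
    eps_solvent: float = WATER_EPS_STATIC,
) -> float:
    """Signed empirical DEP force at the drive frequency, newtons.

    Magnitude (3/2) V_p eps_0 eps_m(f) (kappa+2)[CM]_emp grad(E^2) with
    eps_m(f) the dispersed mixture permittivity; the sign is positive in the
    dielectric-increment band (eps_m(f) > eps_solvent) and negative beyond
    the crossover.
    """
    if drive.frequency <= 0:
        raise ValueError("drive.frequency must be positive")
    eps_f = eps_of_frequency(model, drive.frequency)
    magnitude = (
        1.5 * V_p * EPS_0 * eps_f * empirical_cm_factor(mix) * drive.grad_E2
    )
    sign = 1.0 if eps_f > eps_solvent else -1.0
    return sign * magnitude


# ---------------------------------------------------------------------------
# K-factor theory
# ---------------------------------------------------------------------------


def chi_c_from_trajectory(mp: DipoleEnsemble, mw: DipoleEnsemble) -> float:
    """Cavity susceptibility 1 + <Mp.Mw>/<Mp^2> from paired dipole series.

    ``mp`` is the protein+shell moment, ``mw`` the induced water moment;
    equal-length (T, 3) series.  Uncorrelated series give 1 in expectation.
    """
    p = mp.as_si()
    w = mw.as_si()
    if p.ndim != 2 or w.ndim != 2:
        raise ValueError("expected (T, 3) time series for both ensembles")
    if p.shape != w.shape:
        raise ValueError("paired series must have equal length")
    if p.shape[0] < 2:
        warnings.warn("fewer than 2 samples: estimator is unreliable", stacklevel=2)
    var_p = float(np.mean(np.sum(p * p, axis=1)))
    if var_p == 0:
        raise ValueError("<Mp^2> is zero; chi_c undefined")
    cov_pw = float(np.mean(np.sum(p * w, axis=1)))
    return 1.0 + cov_pw / var_p


def chi_c_hm_endpoint(eps_m: float, alpha: int) -> float:
    """Anchored endpoints of the cavity susceptibility.

    alpha = 0: no physical interface, chi_c = Lorentz cavity (eps_m+2)/3;
    alpha = 1: a real interface with its induced moment, chi_c = 3/(2eps_m+1)
    (the Maxwell cavity referenced to the vacuum field).  Intermediate alpha
    is rejected: only the two limits are physically anchored.
    """
    if alpha == 0:
        return lorentz_cavity_chi(eps_m)
    if alpha == 1:
        if eps_m < 1:
            raise ValueError("eps_m must be >= 1")
        return 3.0 / (2.0 * eps_m + 1.0)
    raise ValueError(f"alpha must be 0 or 1, got {alpha}")


def dispersion_strengths(n_dip: float, v_p: float, chi_c: float) -> tuple[float, float]:
    """Beta and delta dispersion strengths of a dilute protein solution.

    delta_eps_beta  = (9/2) v_p N_dip        (protein tumbling)
    delta_eps_delta = 9 v_p N_dip (chi_c-1)  (hydration-shell cross term)

    chi_c = 1 (no protein-water correlation) makes the delta term vanish.
    """
    if v_p <= 0:
        raise ValueError("v_p must be positive")
    beta = 4.5 * v_p * n_dip
    delta = 9.0 * v_p * n_dip * (chi_c - 1.0)
    return beta, delta


def chi_c_from_dispersions(delta_eps_beta: float, delta_eps_delta: float) -> float:
    """Invert the strength pair: chi_c = 1 + delta_eps_delta/(2 delta_eps_beta)."""
    if delta_eps_beta == 0:
        raise ValueError("delta_eps_beta must be nonzero")
    return 1.0 + delta_eps_delta / (2.0 * delta_eps_beta)


def delta_eps_delta_moment_form(
    v_p: float,
    cross_moment: float,
    V_p: float,
    env: Environment = Environment(),
) -> float:
    """Delta-dispersion strength from the protein-water cross moment.

    delta_eps_delta = v_p * <Mp.Mw> / (V_p eps_0 kT), cross moment in
    (C.m)^2 and particle volume in m^3.
    """
    if v_p <= 0 or V_p <= 0:
        raise ValueError("volume fraction and particle volume must be positive")
    return v_p * cross_moment / (V_p * EPS_0 * env.kT)


def mixture_dispersion(
    f,
    v_p: float,
    n_dip: float,
    tau_p: float,
    chi_c: float,
    water: DebyeMode,
):
    """Collective dispersion delta_eps_mix(f) of a protein solution.

    Three terms: beta (protein tumbling, (9/2) v_p N_dip(w)), delta
    (cross-correlation, 9 v_p N_dip(w) (chi_c-1)) and gamma (bulk water,
    attenuated by (1 - v_p) for the volume the proteins exclude).
    """
    if not 0.0 <= v_p <= 1.0:
        raise ValueError("v_p must be in [0, 1]")
    f = np.asarray(f, dtype=float)
    nd = n_dip_of_omega(n_dip, tau_p, f) if n_dip > 0 else np.zeros_like(f)
    beta = 4.5 * v_p * nd
    delta = 9.0 * v_p * nd * (chi_c - 1.0)
    omega = 2.0 * math.pi * f
    gamma = (1.0 - v_p) * water.delta_eps / (1.0 + (omega * water.tau) ** 2)
    out = beta + delta + gamma
    return out if out.ndim else float(out)


def k_factor(model: SpectrumModel, v_p: float, f):
    """Complex DEP susceptibility factor K(w) of a dilute protein mixture.

    K(w) = (2/9) eps(w) delta_eps(w) / v_p with both factors evaluated as
    complex Debye quantities of the mixture spectrum (delta_eps(w) =
    sum_i delta_eps_i/(1 + i w tau_i)).  Re[K] in chi_DEP plays the role of
    Re[CM]_macro but is not bounded by (-0.5, 1): for strong protein
    beta-dispersions it reaches 1e4-1e5.
    """
    if v_p <= 0:
        raise ValueError("v_p must be positive")
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0):
        raise ValueError("frequency must be positive")
    omega = 2.0 * math.pi * f
    delta = np.zeros_like(f, dtype=complex)
    for mode in model.modes:
        delta = delta + mode.delta_eps / (1.0 + 1j * omega * mode.tau)
    eps = complex_debye(model, f)
    out = (2.0 / 9.0) * eps * delta / v_p
    return out if out.ndim else complex(out)


def chi_dep_hm(V_p: float, eps_m: float, K: complex) -> float:
    """K-factor DEP susceptibility chi = (3/2) V_p eps_m Re[K], m^3."""
    if V_p <= 0:
        raise ValueError("particle volume must be positive")
    if eps_m <= 0:
        raise ValueError("eps_m must be positive")
    return 1.5 * V_p * eps_m * np.real(K)


def dep_susceptibility(
    V_p: float,
    medium: Medium,
    f: float,
    model: SpectrumModel | None = None,
    v_p: float | None = None,
    n_dip: float = 0.0,
    particle: Medium | None = None,
) -> float:
    """Route to the appropriate DEP susceptibility, m^3.

    With a finite dipolar density (``n_dip > 0``) and a mixture spectrum,
    the K-factor route applies; a particle without a permanent dipole
    (``n_dip = 0``) falls back to the macroscopic CM route, for which the
    particle material must be given.
    """
    if n_dip > 0:
        if model is None or v_p is None:
            raise ValueError("K-factor route needs the mixture spectrum and v_p")
        K = k_factor(model, v_p, f)
        return chi_dep_hm(V_p, medium.eps_r, K)
    if particle is None:
        raise ValueError("macroscopic route needs the particle material")
    return 1.5 * V_p * medium.eps_r * cm_factor(particle, medium, f).real
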