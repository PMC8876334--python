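"""Synthetic fixtures: parametric spectra, dipole series, preset catalogue.

Every pipeline stage is testable without measured data. The spectrum
generator emulates instrument output for a known multi-mode Debye ground
truth with multiplicative Gaussian noise (instrument noise is
scale-proportional); the dipole generator produces paired Gaussian series
with prescribed second moments for the cross-correlation estimators. All
randomness flows through an explicit seed - there is no global RNG state.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import yaml

from .dispersion import DebyeMode, SpectrumModel, SpectrumSample, complex_debye
from .molecular import DipoleEnsemble, ProteinRecord, SolventRef

__all__ = [
    "GeneratorConfig",
    "generate_spectrum",
    "generate_dipole_pair_series",
    "generate_correlated_dipole_configs",
    "preset_catalogue",
    "spectrum_preset",
    "protein_preset",
    "solvent_preset",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Ground-truth model plus grid/noise/seed for spectrum synthesis."""

    model: SpectrumModel
    f_min: float = 1e3
    f_max: float = 1e9
    n_points: int = 50
    noise_rel: float = 0.0
    seed: int = 0
    include_imag: bool = False

    def __post_init__(self) -> None:
        if self.noise_rel < 0:
            raise ValueError("noise_rel must be >= 0")
        if not 0 < self.f_min < self.f_max:
            raise ValueError("need 0 < f_min < f_max")
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")


def generate_spectrum(cfg: GeneratorConfig) -> SpectrumSample:
    """Synthesize a spectrum sample; noiseless output equals the model exactly."""
    f = np.logspace(np.log10(cfg.f_min), np.log10(cfg.f_max), cfg.n_points)
    eps = complex_debye(cfg.model, f)
    rng = np.random.default_rng(cfg.seed)
    real = eps.real.copy()
    imag = (-eps.imag).copy()
    if cfg.noise_rel > 0:
        real *= 1.0 + cfg.noise_rel * rng.standard_normal(f.size)
        if cfg.include_imag:
            imag *= 1.0 + cfg.noise_rel * rng.standard_normal(f.size)
    return SpectrumSample(
        freq_hz=f,
        eps_real=real,
        eps_imag=imag if cfg.include_imag else None,
        provenance=f"synthetic (seed={cfg.seed}, noise_rel={cfg.noise_rel})",
    )


def generate_dipole_pair_series(
    n: int, var_p: float, cov_pw: float, seed: int = 0, var_w: float | None = None
) -> tuple[DipoleEnsemble, DipoleEnsemble]:
    """Paired Gaussian dipole time series with prescribed second moments.

    ``var_p``/``var_w`` are the target total variances <|Mp|^2>/<|Mw|^2>
    and ``cov_pw`` the target <Mp.Mw> (all in SI, (C.m)^2); each Cartesian
    component carries a third of the total.  Raises if the 2x2 per-component
    covariance matrix is not positive semi-definite.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if var_w is None:
        var_w = var_p
    cov = np.array([[var_p, cov_pw], [cov_pw, var_w]]) / 3.0
    if np.any(np.linalg.eigvalsh(cov) < -1e-15 * max(var_p, var_w, 1.0)):
        raise ValueError("requested covariance matrix is not positive semi-definite")
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_normal(
        np.zeros(2), cov, size=(n, 3), method="cholesky", check_valid="ignore"
    )
    mp = DipoleEnsemble(vectors=draws[:, :, 0], kind="trajectory")
    mw = DipoleEnsemble(vectors=draws[:, :, 1], kind="trajectory")
    return mp, mw


def generate_correlated_dipole_configs(
    n_configs: int,
    z: int,
    cos_theta: float,
    m_debye: float = 1.0,
    seed: int = 0,
) -> DipoleEnsemble:
    """Configurations of a central dipole with z neighbours at <cos> = c.

    Each configuration has 1 + z unit-magnitude dipoles (scaled by
    ``m_debye``): a random central direction u and z neighbours tilted so
    that their projection on u is exactly ``cos_theta`` with random azimuth.
    The central-dipole Kirkwood estimator on this ensemble converges to
    1 + z*cos_theta.
    """
    if not -1.0 <= cos_theta <= 1.0:
        raise ValueError("cos_theta must be in [-1, 1]")
    rng = np.random.default_rng(seed)
    u = rng.standard_normal((n_configs, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)

    # orthonormal frame (u, e1, e2) per configuration
    helper = np.where(np.abs(u[:, [0]]) < 0.9, [[1.0, 0, 0]], [[0, 1.0, 0]])
    e1 = np.cross(u, helper)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(u, e1)

    sin_theta = np.sqrt(1.0 - cos_theta**2)
    phi = rng.uniform(0.0, 2.0 * np.pi, size=(n_configs, z))
    neigh = (
        cos_theta * u[:, None, :]
        + sin_theta * np.cos(phi)[:, :, None] * e1[:, None, :]
        + sin_theta * np.sin(phi)[:, :, None] * e2[:, None, :]
    )
    configs = np.concatenate([u[:, None, :], neigh], axis=1) * m_debye
    return DipoleEnsemble(vectors=configs, kind="trajectory", unit="debye")


# ---------------------------------------------------------------------------
# Preset catalogue
# ---------------------------------------------------------------------------

_CATALOGUE_CACHE: dict | None = None


def _load_catalogue() -> dict:
    global _CATALOGUE_CACHE
    if _CATALOGUE_CACHE is None:
        text = (
            importlib.resources.files("prodep") / "data" / "presets.yaml"
        ).read_text()
        _CATALOGUE_CACHE = yaml.safe_load(text)
    return _CATALOGUE_CACHE


def preset_catalogue() -> dict:
    """The full raw catalogue (spectra, proteins, mixtures, solvents)."""
    return _load_catalogue()


def _lookup(section: str, name: str) -> dict:
    cat = _load_catalogue()
    entries = cat.get(section, {})
    if name not in entries:
        raise KeyError(
            f"unknown {section} preset {name!r}; available: {sorted(entries)}"
        )
    return entries[name]


def spectrum_preset(name: str) -> tuple[SpectrumModel, float]:
    """Named spectrum preset -> (SpectrumModel, volume_fraction)."""
    entry = _lookup("spectra", name)
    modes = tuple(
        DebyeMode.from_f_char(
            float(m["delta_eps"]), float(m["f_char_hz"]), m.get("label", "")
        )
        for m in entry["modes"]
    )
    model = SpectrumModel(
        eps_hf=float(entry["eps_hf"]),
        modes=modes,
        sigma_dc=float(entry.get("sigma_dc", 0.0)),
    )
    return model, float(entry.get("volume_fraction", 0.0))


def protein_preset(name: str) -> ProteinRecord:
    """Named protein preset -> :class:`ProteinRecord`."""
    entry = _lookup("proteins", name)
    return ProteinRecord(
        name=name,
        molecular_weight=entry.get("molecular_weight"),
        mass_density=entry.get("mass_density"),
        dipole_moment=entry.get("dipole_moment_debye"),
        moment_mean=entry.get("moment_mean_debye"),
        moment_width=entry.get("moment_width_debye"),
        hydrodynamic_radius=entry.get("hydrodynamic_radius_m"),
        shape=entry.get("shape", "sphere"),
        depolarization_A=entry.get("depolarization_A", 1.0 / 3.0),
    )


def solvent_preset(name: str = "water") -> SolventRef:
    """Named solvent preset -> :class:`SolventRef`."""
    entry = _lookup("solvents", name)
    return SolventRef(
        eps_static=entry["eps_static"],
        eps_inf=entry.get("eps_inf", 1.0),
        dipole_moment=entry.get("dipole_moment_debye"),
        g_k=entry.get("g_k"),
    )
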