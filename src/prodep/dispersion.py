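"""Debye relaxation machinery and dispersion-parameter fitting.

A dielectric spectrum of a polar solution is modelled as a high-frequency
baseline ``eps_hf`` plus a sum of Debye modes, each contributing a
dispersion step ``delta_eps`` centred at the characteristic frequency
``1/(2*pi*tau)``::

    eps'(f)  = eps_hf + sum_i delta_eps_i / (1 + (f/f_i)^2)
    eps*(f)  = eps_hf + sum_i delta_eps_i / (1 + i*2*pi*f*tau_i)
                      - i*sigma_dc/(2*pi*f*eps_0)

The complex convention is eps* = eps' - i*eps''; the loss eps'' of a single
mode peaks at omega*tau = 1 with height delta_eps/2.

Effective-medium mixture relations (the Maxwell-Garnett form and its dilute
linearization ``delta_eps = 3*c_v*eps_m*[CM]``) live here too, as does the
statsmodels-style ``DebyeRelaxationModel`` for extracting dispersion
parameters from measured or synthetic spectra.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .constants import EPS_0

__all__ = [
    "DebyeMode",
    "SpectrumModel",
    "SpectrumSample",
    "MixtureSpec",
    "eps_of_frequency",
    "complex_debye",
    "mixture_delta_eps",
    "cm_from_delta_eps",
    "effective_medium_eps",
    "DebyeRelaxationModel",
    "DebyeFitResult",
    "fit_debye_modes",
]

TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class DebyeMode:
    """A single Debye relaxation: dispersion strength and relaxation time.

    Parameters
    ----------
    delta_eps : float
        Dimensionless dispersion strength (>= 0).
    tau : float
        Relaxation time in seconds (> 0).
    label : str
        Free-text tag, conventionally one of alpha/beta/delta/gamma.
    """

    delta_eps: float
    tau: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.delta_eps < 0:
            raise ValueError(f"delta_eps must be >= 0, got {self.delta_eps}")
        if self.tau <= 0:
            raise ValueError(f"tau must be > 0, got {self.tau}")

    @property
    def f_char(self) -> float:
        """Characteristic (mid-point) frequency 1/(2*pi*tau), Hz."""
        return 1.0 / (TWO_PI * self.tau)

    @classmethod
    def from_f_char(cls, delta_eps: float, f_char: float, label: str = "") -> "DebyeMode":
        """Build a mode from its characteristic frequency in Hz."""
        if f_char <= 0:
            raise ValueError(f"f_char must be > 0, got {f_char}")
        return cls(delta_eps=delta_eps, tau=1.0 / (TWO_PI * f_char), label=label)


@dataclass(frozen=True)
class SpectrumModel:
    """Multi-mode Debye spectrum: baseline + ordered list of modes.

    ``sigma_dc`` (S/m) adds a conduction-loss term to the imaginary part
    only; the real permittivity is unaffected.
    """

    eps_hf: float
    modes: tuple[DebyeMode, ...] = ()
    sigma_dc: float = 0.0

    def __post_init__(self) -> None:
        if self.eps_hf < 1.0:
            raise ValueError(f"eps_hf must be >= 1, got {self.eps_hf}")
        if self.sigma_dc < 0:
            raise ValueError(f"sigma_dc must be >= 0, got {self.sigma_dc}")
        object.__setattr__(self, "modes", tuple(self.modes))

    @property
    def eps_static(self) -> float:
        """Zero-frequency permittivity: eps_hf + sum of mode strengths."""
        return self.eps_hf + sum(m.delta_eps for m in self.modes)

    def eps_real(self, f):
        return eps_of_frequency(self, f)

    def eps_complex(self, f):
        return complex_debye(self, f)

    def to_json(self) -> str:
        """Serialize to the interchange JSON schema."""
        doc = {
            "eps_hf": self.eps_hf,
            "sigma_dc": self.sigma_dc,
            "modes": [
                {"label": m.label, "delta_eps": m.delta_eps, "tau_s": m.tau}
                for m in self.modes
            ],
        }
        return json.dumps(doc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SpectrumModel":
        doc = json.loads(text)
        modes = tuple(
            DebyeMode(delta_eps=m["delta_eps"], tau=m["tau_s"], label=m.get("label", ""))
            for m in doc["modes"]
        )
        return cls(eps_hf=doc["eps_hf"], modes=modes, sigma_dc=doc.get("sigma_dc", 0.0))


@dataclass(frozen=True)
class SpectrumSample:
    """A measured or synthetic spectrum: frequencies and permittivity values.

    Frequencies must be strictly increasing and positive; ``eps_imag`` is the
    loss eps'' (positive numbers) and is optional.
    """

    freq_hz: np.ndarray
    eps_real: np.ndarray
    eps_imag: np.ndarray | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        f = np.asarray(self.freq_hz, dtype=float)
        er = np.asarray(self.eps_real, dtype=float)
        object.__setattr__(self, "freq_hz", f)
        object.__setattr__(self, "eps_real", er)
        if f.ndim != 1 or f.size == 0:
            raise ValueError("freq_hz must be a non-empty 1-D array")
        if np.any(f <= 0):
            raise ValueError("frequencies must be positive")
        if np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if er.shape != f.shape:
            raise ValueError("eps_real length must match freq_hz")
        if self.eps_imag is not None:
            ei = np.asarray(self.eps_imag, dtype=float)
            if ei.shape != f.shape:
                raise ValueError("eps_imag length must match freq_hz")
            object.__setattr__(self, "eps_imag", ei)

    def __len__(self) -> int:
        return self.freq_hz.size


@dataclass(frozen=True)
class MixtureSpec:
    """Dilute-suspension mixture: volume fraction plus phase permittivities."""

    volume_fraction: float
    eps_m: float
    eps_p: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.volume_fraction <= 1.0:
            raise ValueError(
                f"volume_fraction must be in [0, 1], got {self.volume_fraction}"
            )
        if self.eps_m <= 0 or self.eps_p <= 0:
            raise ValueError("permittivities must be positive")


def _check_freq(f) -> np.ndarray:
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0):
        raise ValueError("frequency must be positive")
    return f


def eps_of_frequency(model: SpectrumModel, f):
    """Real permittivity eps'(f) of a multi-mode Debye model.

    Monotonically non-increasing in f; the static limit is
    ``model.eps_static`` and the high-frequency limit is ``model.eps_hf``.
    Accepts scalar or array frequency (Hz, > 0).
    """
    f = _check_freq(f)
    out = np.full_like(f, model.eps_hf, dtype=float)
    for m in model.modes:
        out = out + m.delta_eps / (1.0 + (f / m.f_char) ** 2)
    return out if out.ndim else float(out)


def complex_debye(model: SpectrumModel, f):
    """Complex permittivity eps*(f) = eps' - i*eps'' of the model.

    Each mode contributes ``delta_eps/(1 + i*omega*tau)``; a nonzero
    ``sigma_dc`` adds the conduction loss ``sigma/(omega*eps_0)`` to eps''.
    """
    f = _check_freq(f)
    omega = TWO_PI * f
    out = np.full_like(f, model.eps_hf, dtype=complex)
    for m in model.modes:
        out = out + m.delta_eps / (1.0 + 1j * omega * m.tau)
    if model.sigma_dc > 0:
        out = out - 1j * model.sigma_dc / (omega * EPS_0)
    return out if out.ndim else complex(out)


def mixture_delta_eps(cm_real: float, volume_fraction: float, eps_m: float) -> float:
    """Dispersion strength of a dilute suspension: 3*c_v*eps_m*[CM]."""
    if eps_m <= 0:
        raise ValueError("eps_m must be positive")
    return 3.0 * volume_fraction * eps_m * cm_real


def cm_from_delta_eps(delta_eps: float, volume_fraction: float, eps_m: float) -> float:
    """Invert the dilute mixture relation for the real [CM] factor."""
    if eps_m <= 0:
        raise ValueError("eps_m must be positive")
    if volume_fraction <= 0:
        raise ValueError("volume_fraction must be > 0 to invert the mixture relation")
    return delta_eps / (3.0 * volume_fraction * eps_m)


def effective_medium_eps(mix: MixtureSpec) -> float:
    """Maxwell-Garnett effective permittivity of a dilute suspension.

    Solves ``(e_eff - e_m)/(e_eff + 2 e_m) = v_p (e_p - e_m)/(e_p + 2 e_m)``
    in closed form. Reduces to ``eps_m`` at v_p = 0 and ``eps_p`` at v_p = 1.
    """
    q = mix.volume_fraction * (mix.eps_p - mix.eps_m) / (mix.eps_p + 2.0 * mix.eps_m)
    return mix.eps_m * (1.0 + 2.0 * q) / (1.0 - q)


# ---------------------------------------------------------------------------
# Dispersion-parameter fitting
# ---------------------------------------------------------------------------


class DebyeRelaxationModel:
    """Nonlinear least-squares extraction of Debye dispersion parameters.

    Fits ``(eps_hf, {delta_eps_i, tau_i})`` to a :class:`SpectrumSample`.
    The real part is always fitted; if loss data are present the objective
    is the equally weighted concatenation of real and imaginary residuals.

    Initialization seeds mode positions at the ``n_modes`` largest peaks of
    the numerical derivative ``-d eps'/d log f`` with amplitudes from the
    local permittivity drops, then runs multi-start refinement with jittered
    initial values (seeded RNG) under the box constraints
    ``delta_eps >= 0``, ``tau > 0``, ``eps_hf >= 1``.

    Parameters
    ----------
    sample : SpectrumSample
    n_modes : int
        Number of Debye modes to fit (>= 1).
    """

    #: modes whose relaxation times differ by less than this are merged
    MERGE_RTOL = 0.01

    def __init__(self, sample: SpectrumSample, n_modes: int = 1):
        if n_modes < 1:
            raise ValueError("n_modes must be >= 1")
        needed = 4 * n_modes + 2
        if len(sample) < needed:
            raise ValueError(
                f"need at least {needed} points to fit {n_modes} modes, "
                f"got {len(sample)}"
            )
        self.sample = sample
        self.n_modes = n_modes

    # -- initialization ----------------------------------------------------

    def _initial_guess(self) -> np.ndarray:
        s = self.sample
        logf = np.log10(s.freq_hz)
        deriv = -np.gradient(s.eps_real, logf)
        deriv = np.clip(deriv, 0.0, None)

        # local maxima of the derivative, strongest first
        interior = np.arange(1, len(s) - 1)
        is_peak = (deriv[interior] >= deriv[interior - 1]) & (
            deriv[interior] >= deriv[interior + 1]
        )
        peaks = interior[is_peak]
        peaks = peaks[np.argsort(deriv[peaks])[::-1]]

        total_drop = max(s.eps_real[0] - s.eps_real[-1], 1e-12)
        f_chars: list[float] = [float(s.freq_hz[i]) for i in peaks[: self.n_modes]]
        # pad with log-spaced positions if too few derivative peaks
        while len(f_chars) < self.n_modes:
            f_chars.append(
                float(
                    10
                    ** (
                        logf[0]
                        + (len(f_chars) + 0.5) * (logf[-1] - logf[0]) / (self.n_modes + 1)
                    )
                )
            )
        f_chars.sort()

        weights = np.ones(self.n_modes)
        for k, fc in enumerate(f_chars):
            i = int(np.argmin(np.abs(s.freq_hz - fc)))
            weights[k] = max(deriv[i], 1e-12)
        amps = total_drop * weights / weights.sum()

        eps_hf0 = max(float(s.eps_real[-1]), 1.0)
        taus = 1.0 / (TWO_PI * np.asarray(f_chars))
        return np.concatenate([[eps_hf0], amps, np.log10(taus)])

    # -- objective ---------------------------------------------------------

    def _unpack(self, theta: np.ndarray) -> SpectrumModel:
        n = self.n_modes
        eps_hf = theta[0]
        amps = theta[1 : 1 + n]
        taus = 10.0 ** theta[1 + n :]
        modes = tuple(
            DebyeMode(delta_eps=float(a), tau=float(t)) for a, t in zip(amps, taus)
        )
        return SpectrumModel(eps_hf=float(max(eps_hf, 1.0)), modes=modes)

    def _residuals(self, theta: np.ndarray) -> np.ndarray:
        model = self._unpack(theta)
        s = self.sample
        pred = complex_debye(model, s.freq_hz)
        res = pred.real - s.eps_real
        if s.eps_imag is not None:
            res = np.concatenate([res, (-pred.imag) - s.eps_imag])
        return res

    # -- fit ---------------------------------------------------------------

    def fit(self, n_starts: int = 8, seed: int = 0) -> "DebyeFitResult":
        """Run multi-start bounded least squares; never fails silently.

        Returns a :class:`DebyeFitResult` whose ``success`` flag is False if
        no start converged.
        """
        n = self.n_modes
        theta0 = self._initial_guess()
        # relaxation times are only identifiable within (a decade around)
        # the measured window; beyond it a mode degenerates with eps_hf
        lt_lo = math.log10(1.0 / (TWO_PI * self.sample.freq_hz[-1])) - 1.0
        lt_hi = math.log10(1.0 / (TWO_PI * self.sample.freq_hz[0])) + 1.0
        lo = np.concatenate([[1.0], np.zeros(n), np.full(n, lt_lo)])
        hi = np.concatenate([[np.inf], np.full(n, np.inf), np.full(n, lt_hi)])
        rng = np.random.default_rng(seed)

        best = None
        for start in range(max(n_starts, 1)):
            t0 = theta0.copy()
            if start > 0:  # jitter subsequent starts
                t0[0] *= 1.0 + 0.02 * rng.standard_normal()
                t0[1 : 1 + n] *= np.exp(0.3 * rng.standard_normal(n))
                t0[1 + n :] += 0.4 * rng.standard_normal(n)
            t0 = np.clip(t0, lo + 1e-12, np.where(np.isfinite(hi), hi - 1e-12, t0))
            try:
                sol = least_squares(
                    self._residuals,
                    t0,
                    bounds=(lo, hi),
                    xtol=1e-15,
                    ftol=1e-15,
                    gtol=1e-15,
                    max_nfev=2000,
                )
            except Exception:  # numerical failure of one start is not fatal
                continue
            if sol.status > 0 and (best is None or sol.cost < best.cost):
                best = sol

        if best is None:
            return DebyeFitResult(
                model=self._unpack(theta0),
                success=False,
                message="no multi-start converged",
                rms=math.inf,
                n_obs=len(self.sample),
                n_starts=n_starts,
            )

        model = self._merge_and_sort(self._unpack(best.x))
        nres = best.fun.size
        rms = float(np.sqrt(2.0 * best.cost / nres))
        return DebyeFitResult(
            model=model,
            success=True,
            message="converged",
            rms=rms,
            n_obs=len(self.sample),
            n_starts=n_starts,
        )

    def _merge_and_sort(self, model: SpectrumModel) -> SpectrumModel:
        """Merge near-degenerate relaxation times, sort by increasing f_char."""
        modes = sorted(model.modes, key=lambda m: m.tau, reverse=True)
        merged: list[DebyeMode] = []
        for m in modes:
            if merged and abs(merged[-1].tau - m.tau) < self.MERGE_RTOL * merged[-1].tau:
                prev = merged.pop()
                merged.append(
                    DebyeMode(
                        delta_eps=prev.delta_eps + m.delta_eps,
                        tau=prev.tau,
                        label=prev.label,
                    )
                )
            else:
                merged.append(m)
        return replace(model, modes=tuple(merged))


@dataclass(frozen=True)
class DebyeFitResult:
    """Result of a Debye dispersion fit: model, diagnostics, summary."""

    model: SpectrumModel
    success: bool
    message: str
    rms: float
    n_obs: int
    n_starts: int

    def summary(self) -> str:
        lines = [
            "Debye dispersion fit",
            "=" * 44,
            f"observations: {self.n_obs}    multi-starts: {self.n_starts}",
            f"converged:    {self.success} ({self.message})",
            f"residual RMS: {self.rms:.6g}",
            f"eps_hf:       {self.model.eps_hf:.6g}",
            f"eps_static:   {self.model.eps_static:.6g}",
            f"sigma_dc:     {self.model.sigma_dc:.6g} S/m",
            "-" * 44,
            f"{'mode':>4} {'delta_eps':>12} {'tau_s':>12} {'f_char_Hz':>12}",
        ]
        for k, m in enumerate(self.model.modes):
            lines.append(
                f"{k:>4} {m.delta_eps:>12.5g} {m.tau:>12.5g} {m.f_char:>12.5g}"
            )
        return "\n".join(lines)


def fit_debye_modes(
    sample: SpectrumSample, n_modes: int, n_starts: int = 8, seed: int = 0
) -> DebyeFitResult:
    """Functional wrapper: fit ``n_modes`` Debye modes to a spectrum sample."""
    return DebyeRelaxationModel(sample, n_modes).fit(n_starts=n_starts, seed=seed)
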