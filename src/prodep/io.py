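"""File formats, run configuration and the end-to-end JSON report.

Spectrum CSV dialect: header ``frequency_hz,eps_real[,eps_imag]``, plain
decimal or scientific notation, ``#`` comment lines ignored.  All numbers in
reports are serialized with 9 significant digits and units embedded in key
names, because the domain mixes scales across many decades.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from .constants import DEFAULT_TEMPERATURE, EPS_0, WATER_EPS_STATIC
from .dispersion import SpectrumModel, SpectrumSample, fit_debye_modes
from .macroscopic import Environment, crossover_frequency, threshold_grad_E2
from .protein_dep import chi_dep_hm, k_factor

__all__ = [
    "read_spectrum_csv",
    "write_spectrum_csv",
    "RunConfig",
    "run_report",
    "round_sig",
]

REPORT_SCHEMA_VERSION = "1.0"


def round_sig(x: float, sig: int = 9) -> float:
    """Round to ``sig`` significant digits (report serialization policy)."""
    if x == 0 or not math.isfinite(x):
        return x
    return float(f"{x:.{sig}g}")


def read_spectrum_csv(path: str | Path) -> SpectrumSample:
    """Read a spectrum CSV; errors name the offending line."""
    path = Path(path)
    header: list[str] | None = None
    rows: list[list[float]] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p.strip() for p in line.split(",")]
            if header is None:
                header = [p.lower() for p in parts]
                if header[:2] != ["frequency_hz", "eps_real"] or (
                    len(header) == 3 and header[2] != "eps_imag"
                ) or len(header) > 3:
                    raise ValueError(
                        f"{path}:{lineno}: header must be "
                        "'frequency_hz,eps_real[,eps_imag]', got "
                        f"{','.join(parts)!r}"
                    )
                continue
            if len(parts) != len(header):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(parts)}"
                )
            try:
                vals = [float(p) for p in parts]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed number ({exc})") from None
            if vals[0] <= 0:
                raise ValueError(f"{path}:{lineno}: non-positive frequency {vals[0]}")
            rows.append(vals)
    if header is None or not rows:
        raise ValueError(f"{path}: no data rows found")
    arr = np.asarray(rows, dtype=float)
    f = arr[:, 0]
    if np.any(np.diff(f) <= 0):
        bad = int(np.nonzero(np.diff(f) <= 0)[0][0])
        raise ValueError(
            f"{path}: frequencies must be strictly increasing "
            f"(violated between rows {bad + 1} and {bad + 2} of the data)"
        )
    return SpectrumSample(
        freq_hz=f,
        eps_real=arr[:, 1],
        eps_imag=arr[:, 2] if arr.shape[1] == 3 else None,
        provenance=str(path),
    )


def write_spectrum_csv(sample: SpectrumSample, path: str | Path) -> None:
    """Write a spectrum sample in the package CSV dialect."""
    path = Path(path)
    with path.open("w") as fh:
        if sample.provenance:
            fh.write(f"# {sample.provenance}\n")
        cols = "frequency_hz,eps_real" + (",eps_imag" if sample.eps_imag is not None else "")
        fh.write(cols + "\n")
        for i in range(len(sample)):
            row = f"{sample.freq_hz[i]:.9g},{sample.eps_real[i]:.9g}"
            if sample.eps_imag is not None:
                row += f",{sample.eps_imag[i]:.9g}"
            fh.write(row + "\n")


_ALLOWED_KEYS = {
    "temperature_K",
    "eps_solvent",
    "volume_fraction",
    "particle_volume_m3",
    "grad_E2_V2_per_m3",
    "n_modes",
    "seed",
    "spectrum_csv",
    "spectrum_model_json",
    "freq_min_hz",
    "freq_max_hz",
    "n_freq",
}


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration of an end-to-end DEP prediction run."""

    temperature_K: float = DEFAULT_TEMPERATURE
    eps_solvent: float = WATER_EPS_STATIC
    volume_fraction: float | None = None
    particle_volume_m3: float | None = None
    grad_E2_V2_per_m3: float | None = None
    n_modes: int = 1
    seed: int = 0
    spectrum_csv: str | None = None
    spectrum_model_json: str | None = None
    freq_min_hz: float = 1e3
    freq_max_hz: float = 1e8
    n_freq: int = 25

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        unknown = set(raw) - _ALLOWED_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def __post_init__(self) -> None:
        if self.temperature_K <= 0:
            raise ValueError("temperature_K must be positive")
        if self.eps_solvent <= 0:
            raise ValueError("eps_solvent must be positive")
        if self.volume_fraction is not None and not 0 < self.volume_fraction <= 1:
            raise ValueError("volume_fraction must be in (0, 1]")
        if not 0 < self.freq_min_hz < self.freq_max_hz:
            raise ValueError("need 0 < freq_min_hz < freq_max_hz")


def run_report(config: RunConfig) -> dict:
    """End-to-end prediction: fit (if needed), K(f) table, crossover, verdict.

    Returns a versioned, JSON-serializable document with echoed inputs.
    Deterministic for a fixed config and seed.
    """
    env = Environment(temperature=config.temperature_K)

    if config.spectrum_model_json:
        model = SpectrumModel.from_json(Path(config.spectrum_model_json).read_text())
        fit_doc: dict[str, Any] = {"fitted": False}
    elif config.spectrum_csv:
        sample = read_spectrum_csv(config.spectrum_csv)
        res = fit_debye_modes(sample, config.n_modes, seed=config.seed)
        if not res.success:
            raise RuntimeError(f"dispersion fit failed: {res.message}")
        model = res.model
        fit_doc = {"fitted": True, "residual_rms": round_sig(res.rms)}
    else:
        raise ValueError("config needs spectrum_csv or spectrum_model_json")

    report: dict[str, Any] = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "inputs": {
            "temperature_K": config.temperature_K,
            "eps_solvent": config.eps_solvent,
            "volume_fraction": config.volume_fraction,
            "particle_volume_m3": config.particle_volume_m3,
            "grad_E2_V2_per_m3": config.grad_E2_V2_per_m3,
            "seed": config.seed,
        },
        "fit": fit_doc,
        "model": {
            "eps_hf": round_sig(model.eps_hf),
            "eps_static": round_sig(model.eps_static),
            "sigma_dc_S_per_m": round_sig(model.sigma_dc),
            "modes": [
                {
                    "label": m.label,
                    "delta_eps": round_sig(m.delta_eps),
                    "tau_s": round_sig(m.tau),
                    "f_char_hz": round_sig(m.f_char),
                }
                for m in model.modes
            ],
        },
    }

    f_xo = crossover_frequency(model, config.eps_solvent)
    report["crossover_hz"] = round_sig(f_xo) if f_xo is not None else None

    freqs = np.logspace(
        math.log10(config.freq_min_hz), math.log10(config.freq_max_hz), config.n_freq
    )
    dipolar = model.eps_static > model.eps_hf
    table = []
    for f in freqs:
        row: dict[str, Any] = {"frequency_hz": round_sig(float(f))}
        eps_f = float(np.real(model.eps_complex(float(f))))
        row["eps_real"] = round_sig(eps_f)
        if dipolar and config.volume_fraction:
            K = k_factor(model, config.volume_fraction, float(f))
            row["re_K"] = round_sig(float(np.real(K)))
            if config.particle_volume_m3:
                chi = chi_dep_hm(config.particle_volume_m3, config.eps_solvent, K)
                row["chi_dep_m3"] = round_sig(chi)
                if config.grad_E2_V2_per_m3:
                    row["force_N"] = round_sig(EPS_0 * chi * config.grad_E2_V2_per_m3)
        row["dep_sign"] = "positive" if eps_f > config.eps_solvent else "negative"
        table.append(row)
    report["response_table"] = table
    report["route"] = "k_factor" if (dipolar and config.volume_fraction) else "cm_macro"

    verdict_bits = []
    if f_xo is not None:
        verdict_bits.append(
            f"positive DEP expected below f_xo = {round_sig(f_xo):.3g} Hz, "
            "negative above"
        )
    else:
        verdict_bits.append("no dielectric-increment crossover in range")
    if (
        config.particle_volume_m3
        and config.grad_E2_V2_per_m3
        and dipolar
        and config.volume_fraction
    ):
        K0 = k_factor(model, config.volume_fraction, freqs[0])
        chi0 = chi_dep_hm(config.particle_volume_m3, config.eps_solvent, K0)
        thr = threshold_grad_E2(chi0, env)
        report["threshold_grad_E2_V2_per_m3"] = round_sig(thr)
        if config.grad_E2_V2_per_m3 < thr:
            verdict_bits.append("drive below Brownian threshold: Brownian-dominated")
        else:
            verdict_bits.append("drive exceeds Brownian threshold")
    report["verdict"] = "; ".join(verdict_bits)
    return report


def report_to_json(report: dict) -> str:
    return json.dumps(report, indent=2)
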