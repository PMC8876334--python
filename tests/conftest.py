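import pytest

from prodep import (
    DebyeMode,
    Environment,
    Medium,
    ParticleMaterial,
    SpectrumModel,
    spectrum_preset,
)


@pytest.fixture
def water() -> Medium:
    return Medium(eps_r=78.0)


@pytest.fixture
def protein_interior() -> ParticleMaterial:
    """Low-permittivity protein interior (MD-derived value ~25)."""
    return ParticleMaterial(eps_r=25.0)


@pytest.fixture
def bsa_model() -> SpectrumModel:
    model, _ = spectrum_preset("bsa_monomer")
    return model


@pytest.fixture
def bsa_vp() -> float:
    _, vp = spectrum_preset("bsa_monomer")
    return vp


@pytest.fixture
def room() -> Environment:
    return Environment(temperature=295.0)


@pytest.fixture
def two_mode_truth() -> SpectrumModel:
    """Protein-like beta + hydration-shell delta dispersion pair."""
    return SpectrumModel(
        eps_hf=72.4,
        modes=(
            DebyeMode.from_f_char(21.0, 1e6, "beta"),
            DebyeMode.from_f_char(2.0, 7e7, "delta"),
        ),
    )
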