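"""Physical constants and unit conversions used throughout the package.

All interfaces are SI unless a function explicitly takes debye; the debye
conversion is pinned to a fixed literal so that serialized results never
drift with a constants-library update.
"""

from scipy import constants as _const

#: Vacuum permittivity, F/m.
EPS_0: float = _const.epsilon_0

#: Boltzmann constant, J/K.
K_B: float = _const.Boltzmann

#: Avogadro constant, 1/mol.
N_A: float = _const.Avogadro

#: One debye in C.m (fixed convention).
DEBYE: float = 3.335641e-30

#: Default ambient temperature, K (room-temperature DEP experiments).
DEFAULT_TEMPERATURE: float = 295.0

#: Static relative permittivity of pure water at 25 C.
WATER_EPS_STATIC: float = 78.4


def debye_to_si(m_debye: float) -> float:
    """Convert a dipole moment from debye to C.m."""
    return m_debye * DEBYE


def si_to_debye(m_si: float) -> float:
    """Convert a dipole moment from C.m to debye."""
    return m_si / DEBYE
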