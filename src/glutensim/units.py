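"""Internal units of the coarse-grained model and conversions to metric.

The model works in reduced units: length in nm, energy in the contact
well depth ``EPSILON`` (about 1.5 kcal/mol), mass in units of the average
amino-acid mass (m = 1), and time in the intrinsic unit ``tau`` (about
1 ns).  All conversions to laboratory units flow through this module so
that a single choice of EPSILON fixes forces (pN/nN), stresses (Pa) and
speeds consistently.
"""

from __future__ import annotations

import numpy as np

#: Energy unit in kcal/mol (well depth of a single sidechain contact).
EPSILON_KCAL_PER_MOL = 1.5

#: Time unit in nanoseconds.
TAU_NS = 1.0

AVOGADRO = 6.02214076e23
KCAL_TO_J = 4184.0

#: One energy unit in joules.
EPSILON_J = EPSILON_KCAL_PER_MOL * KCAL_TO_J / AVOGADRO

#: Force unit eps/nm expressed in piconewtons (~10.4 pN).
FORCE_UNIT_PN = EPSILON_J / 1e-9 * 1e12

#: Force unit eps/nm expressed in nanonewtons.
FORCE_UNIT_NN = FORCE_UNIT_PN * 1e-3

#: Boltzmann constant is 1 in reduced units; temperatures are in eps/k_B.
ROOM_TEMPERATURE = 0.3


def mm_per_s_to_nm_per_tau(v_mm_s: float) -> float:
    """Convert a boundary speed from mm/s to nm per time unit (1 mm/s = 1e-3 nm/tau)."""
    return v_mm_s * 1e6 * (TAU_NS * 1e-9)


def force_to_nN(f_internal: float | np.ndarray) -> float | np.ndarray:
    """Convert force from eps/nm to nN."""
    return f_internal * FORCE_UNIT_NN


def force_to_pN(f_internal: float | np.ndarray) -> float | np.ndarray:
    """Convert force from eps/nm to pN."""
    return f_internal * FORCE_UNIT_PN


def stress_nN_per_nm2_to_MPa(stress: float | np.ndarray) -> float | np.ndarray:
    """Convert stress from nN/nm^2 (= GPa) to MPa."""
    return stress * 1e3


def pressure_force_nN(pressure_pa: float, area_nm2: float) -> float:
    """Force in nN that a given pressure exerts on a wall of given area.

    Atmospheric pressure (101325 Pa) on a ~100 nm^2 wall gives ~0.01 nN,
    a useful scale reference for the measured wall forces.
    """
    return pressure_pa * area_nm2 * 1e-18 * 1e9


def period_us_to_frequency_kHz(period_us: float) -> float:
    """Drive frequency in kHz for an oscillation period given in microseconds."""
    return 1.0 / (period_us * 1e-6) / 1e3
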