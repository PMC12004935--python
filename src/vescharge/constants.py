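"""Physical constants and fixed experimental conditions.

All energies are expressed in units of kT at the reference temperature
(298 K) unless stated otherwise; potentials in mV; lengths in nm.
"""

from scipy import constants as _sc

#: elementary charge, C
E_CHARGE: float = _sc.elementary_charge
#: Boltzmann constant, J/K
K_BOLTZMANN: float = _sc.Boltzmann
#: Avogadro number, 1/mol
N_AVOGADRO: float = _sc.Avogadro
#: vacuum permittivity, F/m
EPS0: float = _sc.epsilon_0

#: reference temperature, K
T_REF: float = 298.0
#: relative permittivity of water at 298 K
EPS_R_WATER: float = 78.4
#: area per lipid in a fluid-phase PC/PG bilayer, nm^2
AREA_PER_LIPID_NM2: float = 0.70
#: default ionic strength of PBS-like buffer, mM (1:1 electrolyte)
IONIC_STRENGTH_MM: float = 150.0


def kT_joules(T: float = T_REF) -> float:
    """Thermal energy k_B*T in Joules."""
    return K_BOLTZMANN * T


def thermal_voltage_mV(T: float = T_REF) -> float:
    """k_B*T/e in millivolts (~25.7 mV at 298 K)."""
    return K_BOLTZMANN * T / E_CHARGE * 1e3
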