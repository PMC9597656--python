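"""Physical constants and unit conversions used throughout the package.

Internal units: length Å, charge e (elementary charge), mass u, time ns,
potential mV, energy kcal/mol, temperature K.  All constants derive from
``scipy.constants`` (CODATA) so there is exactly one source of truth.
"""

from scipy import constants as _c

#: e / ε0, expressed so that integrating a charge density in e/Å³ twice
#: over z in Å yields a potential in mV:  1 (e/Å)/ε0 = 1.8095e5 mV.
E_OVER_EPS0_MV_ANG: float = (
    _c.elementary_charge / (_c.epsilon_0 * 1e-10) * 1e3
)  # mV·Å² per (e/Å)

#: Boltzmann constant per mole in kcal/(mol·K): R / 4184.
KB_KCAL_MOL_K: float = _c.R / 4184.0

#: Avogadro constant (1/mol), for molarity → ion-count conversions.
N_AVOGADRO: float = _c.N_A

#: Litres per cubic ångström.
L_PER_A3: float = 1e-27


def kbt_kcal_mol(temperature_k: float) -> float:
    """Thermal energy k_B·T in kcal/mol at the given temperature."""
    return KB_KCAL_MOL_K * temperature_k
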