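"""Physical constants in the unit system used throughout the package.

Lengths are in nm, charges in units of the elementary charge e, energies in
kcal mol^-1 inside the capping model, kJ mol^-1 for restraint force constants,
kT for free-energy profiles, and potentials in mV.
"""

#: Coulomb constant e^2/(4 pi eps0) expressed in kcal mol^-1 nm e^-2.
KE_KCAL_NM_E2 = 33.206

#: e/(4 pi eps0) expressed in mV nm e^-1: the potential (mV) of a unit point
#: charge at 1 nm in vacuum.
KE_MV_NM_E = 1439.964

#: Boltzmann constant, kJ mol^-1 K^-1.
KB_KJ_MOL_K = 8.31446261815324e-3

#: Boltzmann constant, kcal mol^-1 K^-1.
KB_KCAL_MOL_K = KB_KJ_MOL_K / 4.184

#: Avogadro constant, mol^-1.
N_AVOGADRO = 6.02214076e23

#: Elementary charge, C.
E_CHARGE_C = 1.602176634e-19

#: Vacuum permittivity, C^2 J^-1 m^-1.
EPS0_SI = 8.8541878128e-12

#: Boltzmann constant, J K^-1.
KB_SI = 1.380649e-23

#: Default simulation temperature, K.
T_DEFAULT = 310.0

#: Relative permittivity of bulk water used as default continuum background.
EPS_WATER = 78.5


def kt_kj_mol(temperature: float = T_DEFAULT) -> float:
    """Thermal energy kT in kJ mol^-1 at ``temperature``."""
    return KB_KJ_MOL_K * temperature


def kt_kcal_mol(temperature: float = T_DEFAULT) -> float:
    """Thermal energy kT in kcal mol^-1 at ``temperature``."""
    return KB_KCAL_MOL_K * temperature


def bjerrum_length(rel_permittivity: float = EPS_WATER,
                   temperature: float = T_DEFAULT) -> float:
    """Bjerrum length in nm: separation at which two unit charges interact
    with thermal energy kT in the given dielectric."""
    return KE_KCAL_NM_E2 / (rel_permittivity * kt_kcal_mol(temperature))
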