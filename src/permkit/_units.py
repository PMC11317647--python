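"""Internal unit conventions and physical constants.

Everything inside permkit uses a single set of units: lengths in Å, times in
ns, voltages in mV, charges in units of the elementary charge e, conductance
in pS, energies in kcal/mol, temperatures in K.  Quantities arriving in other
conventional MD units (kJ/mol, kJ mol⁻¹ nm⁻², ps) are converted at ingest.
"""

from __future__ import annotations

from scipy import constants as _c

#: Boltzmann constant in kcal mol^-1 K^-1.
KB_KCAL: float = _c.k * _c.N_A / 1000.0 / _c.calorie

#: Elementary charge in C.
E_CHARGE: float = _c.e

#: kJ/mol per kcal/mol.
KJ_PER_KCAL: float = _c.calorie  # 4.184

#: Conversion factor: N_event * z / (t[ns] * V[mV]) -> conductance in pS.
#: e[C] / (1e-9 s * 1e-3 V) * 1e12 pS/S = e * 1e24.
COND_PS: float = _c.e * 1e24  # 1.602177e5


def kT(temperature: float) -> float:
    """Thermal energy k_B*T in kcal/mol at the given temperature (K)."""
    return KB_KCAL * temperature


def kj_nm2_to_kcal_A2(k: float) -> float:
    """Convert a harmonic force constant from kJ mol^-1 nm^-2 to kcal mol^-1 Å^-2."""
    return k / KJ_PER_KCAL / 100.0


def kj_to_kcal(e: float) -> float:
    """Convert an energy from kJ/mol to kcal/mol."""
    return e / KJ_PER_KCAL
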