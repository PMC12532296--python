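"""Internal unit system and exact conversion constants.

Lengths are nm, time ps, mass u (g/mol), energy kJ/mol.  Derived units:
force kJ/mol/nm, velocity nm/ps, stress kJ/mol/nm^3.
"""

#: Boltzmann constant, kJ/mol/K (CODATA, via R = 8.31446261815324 J/mol/K).
KB = 8.31446261815324e-3

#: Coulomb prefactor e^2/(4 pi eps0) in kJ/mol * nm / e^2.
COULOMB_CONSTANT = 138.935458

#: 1 kJ/mol/nm^3 expressed in MPa (exact to the stated precision).
KJ_MOL_NM3_TO_MPA = 1.66054

#: 1 kJ/mol/nm^3 expressed in GPa.
KJ_MOL_NM3_TO_GPA = KJ_MOL_NM3_TO_MPA * 1e-3

#: 1 nm/ps expressed in m/s.
NM_PS_TO_M_S = 1000.0


def m_per_s_to_nm_per_ps(v: float) -> float:
    """Convert a laboratory rate in m/s to internal nm/ps (8.3 m/s -> 0.0083)."""
    return v / NM_PS_TO_M_S


def nm_per_ps_to_m_per_s(v: float) -> float:
    return v * NM_PS_TO_M_S
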