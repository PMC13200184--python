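"""Physical constants and unit conversions.

Internal working units are kcal/mol, Angstrom and elementary charge; observable
modules work in the conventional simulation-output units (bar, nm, ps, K) and
convert at the boundaries.
"""

# Gas constant
R_J_PER_MOL_K = 8.314462618      # J/(mol K)
R_KJ_PER_MOL_K = 8.314462618e-3  # kJ/(mol K)
R_KCAL_PER_MOL_K = 1.987204259e-3  # kcal/(mol K)

# Boltzmann constant
KB_J_PER_K = 1.380649e-23  # J/K

# Coulomb prefactor for q in e, r in Angstrom, energy in kcal/mol
COULOMB_KCAL_A_E2 = 332.0637

# Standard-state pressure (1 atm), configurable at call sites
P_STANDARD_PA = 101325.0
ATM_BAR = 1.01325

# Molar mass of cyclohexene, g/mol
M_CYCLOHEXENE = 82.143

# bar*nm -> mN/m  (1 bar*nm = 1e5 Pa * 1e-9 m = 1e-4 N/m)
BAR_NM_TO_MN_PER_M = 0.1

# amu/Angstrom^3 -> g/L
AMU_PER_A3_TO_G_PER_L = 1660.53906717

# Angstrom^2/ps -> cm^2/s
A2_PER_PS_TO_CM2_PER_S = 1e-4

ATOMIC_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
}
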