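"""Physical constants (CODATA 2018) and energy-unit conversion factors.

Every module pulls constants from here; nothing hard-codes its own copy.
"""

#: Boltzmann constant, J/K
KB = 1.380649e-23
#: elementary charge, C
E_CHARGE = 1.602176634e-19
#: vacuum permittivity, F/m
EPS0 = 8.8541878128e-12
#: Avogadro constant, 1/mol
N_A = 6.02214076e23
#: molar gas constant, J/(mol K)
R_GAS = 8.314462618
#: Faraday constant, C/mol
FARADAY = 96485.33212

#: hartree in electronvolt
HARTREE_EV = 27.211386245988
#: hartree in joule
HARTREE_J = 4.3597447222071e-18
#: thermochemical kilocalorie-per-mole in joule (per particle)
KCAL_MOL_J = 4184.0 / N_A
#: standard atmosphere in pascal
ATM_PA = 101325.0
#: bar in pascal
BAR_PA = 1.0e5
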