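"""Physical constants and unit conventions.

Global unit system: energies in kcal/mol, lengths in Angstrom, charges in
elementary charge units (e), time in fs, temperature in Kelvin, masses and
moments of inertia in amu (amu*A^2 for rotors).  Dipole moments are reported
in Debye.
"""

#: Boltzmann constant, kcal/(mol*K)
KB_KCAL_MOL_K = 0.0019872041

#: Coulomb constant, kcal*A/(mol*e^2)  (CHARMM/AKMA electrostatic prefactor)
COULOMB_KCAL_A_E2 = 332.0637

#: 1 e*A in Debye
EA_TO_DEBYE = 4.80320

#: 1 kcal/mol expressed in internal dynamic units (amu*A^2/fs^2)
KCAL_MOL_TO_INTERNAL = 4.184e-4
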