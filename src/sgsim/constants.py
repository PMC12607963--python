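"""Physical constants and the internal unit system.

Internal units are the AKMA-style set common in biomolecular simulation codes:
length in Angstrom (A), time in picoseconds (ps), mass in atomic mass units
(amu), energy in kcal/mol.  Because 1 amu*A^2/ps^2 = 10 J/mol, one kcal/mol
equals 418.4 amu*A^2/ps^2; forces read from the potential in kcal/mol/A are
converted with :data:`KCAL_TO_INTERNAL` before they enter the equations of
motion, where momenta are amu*A/ps and accelerations A/ps^2.

Correctness of the conversion chain is validated by the equipartition tests
on Langevin baselines rather than asserted here.
"""

#: Boltzmann constant, kcal/mol/K.
KB = 0.0019872041

#: 1 kcal/mol expressed in internal energy units (amu*A^2/ps^2).
KCAL_TO_INTERNAL = 418.4

#: Mass of an argon atom, amu.
ARGON_MASS = 39.948

#: Lennard-Jones well depth of argon, K (converted to kcal/mol via KB).
ARGON_EPSILON_K = 119.8

#: Lennard-Jones diameter of argon, A.
ARGON_SIGMA = 3.405
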