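"""Physical constants and unit conversions.

Internal unit system: length nm, time ps, mass amu, energy kJ/mol,
charge e, temperature K.  Pressure appears externally in bar.
"""

#: Boltzmann constant, kJ/mol/K.
KB = 0.0083144621

#: Boltzmann constant, J/K (for bending moduli reported in joules).
KB_J = 1.380649e-23

#: Coulomb prefactor 1/(4 pi eps0), kJ mol^-1 nm e^-2.
COULOMB = 138.935485

#: 1 kJ/mol/nm^3 expressed in bar.
BAR_PER_KJMOLNM3 = 16.6054

#: Default isothermal compressibility used by the weak-coupling barostat, bar^-1.
WATER_COMPRESSIBILITY = 4.5e-5
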