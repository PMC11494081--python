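"""Physical constants in the package's internal unit system.

Internal units: energy in eV, length in nm, time in fs.  Cross sections are
stored in cm^2 (the unit the field's tabulations use) and converted to inverse
mean free paths in nm^-1 at the transport boundary.
"""

#: electron rest energy, eV
M0C2 = 510998.95
#: speed of light, nm/fs
C_LIGHT = 299.792458
#: electron mass, eV fs^2 / nm^2  (= m0c^2 / c^2)
M_ELECTRON = M0C2 / C_LIGHT**2
#: water molecule mass, eV fs^2 / nm^2 (18.0153 u)
M_WATER = 18.0153 * 931.49410242e6 / C_LIGHT**2
#: Coulomb constant e^2/(4 pi eps0), eV nm
K_COULOMB = 1.43996
#: Boltzmann constant, eV/K
K_BOLTZMANN = 8.617333262e-5
#: classical electron radius, cm
R_ELECTRON_CM = 2.8179e-13
#: Bohr radius, cm
BOHR_CM = 5.29177210903e-9
#: Hartree energy, eV
HARTREE = 27.211386245988

#: default liquid-water molecular density, molecules / cm^3
WATER_DENSITY_CM3 = 3.318565e22
#: default effective atomic number of the water molecule
WATER_EFFECTIVE_Z = 7.42
#: Moliere screening constant below 50 keV
ETA_C_LOW = 1.198
#: energy above which the high-energy screening constant applies, eV
ETA_C_SWITCH_EV = 50e3

#: cm^2 -> nm^2
CM2_TO_NM2 = 1.0e14
#: cm^-1 -> nm^-1
PER_CM_TO_PER_NM = 1.0e-7
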