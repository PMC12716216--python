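"""Physical constants and unit conversions.

Internal conventions: coordinates are handled in Å at the I/O boundary and
converted to bohr for every electrostatic evaluation; charges are in
elementary-charge units; transition dipoles in e·bohr; couplings in Hartree
(converted to cm⁻¹ only for reporting); lifetimes in ns; Förster radii in Å.
"""

# CODATA 2018
BOHR_ANGSTROM = 0.529177210903  # 1 bohr in Å
ANGSTROM_TO_BOHR = 1.0 / BOHR_ANGSTROM
HARTREE_TO_CM = 219474.6313632  # 1 Hartree in cm⁻¹

# e·Å -> e·bohr
EANG_TO_EBOHR = ANGSTROM_TO_BOHR

# Å³ -> bohr³ (polarizability conversion)
ANG3_TO_BOHR3 = ANGSTROM_TO_BOHR**3

# Förster radius prefactor: R0^6 [Å^6] = FORSTER_PREFACTOR · κ² n⁻⁴ Φ_D J
# with J in M⁻¹ cm⁻¹ nm⁴ (equivalently R0 = 0.211 (κ² n⁻⁴ Φ_D J)^(1/6) Å).
FORSTER_PREFACTOR = 8.79e-5
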