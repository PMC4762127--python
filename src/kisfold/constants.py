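"""Physical constants and model defaults shared across modules.

All energies are in kcal/mol, lengths in Angstrom, temperatures in Kelvin,
and conformational entropies in units of the Boltzmann constant k_B.
"""

# Boltzmann constant -- the single place kcal/mol <-> k_B*T conversions come from.
KB_KCAL_PER_MOL_K: float = 0.0019872

#: Default temperature, 37 degrees Celsius.
T_DEFAULT: float = 310.15

#: Coil-entropy reference ln(omega_coil) = COIL_SLOPE * l + COIL_INTERCEPT,
#: with l the single-stranded chain length in nucleotides.
COIL_SLOPE: float = 2.05
COIL_INTERCEPT: float = 0.1

#: Virtual-bond length for the P-C4' and C4'-P pseudo-bonds (Angstrom).
#: A typical RNA backbone virtual-bond length; configurable through RunConfig.
VIRTUAL_BOND_LENGTH: float = 3.9

#: Minimum allowed distance between non-bonded pseudo-atoms in a scaffold.
CLASH_DISTANCE: float = 3.5

#: Ideal A-form helix parameters: rise per base pair h, radius r, and the
#: helical period (base pairs per turn) fixing the twist 2*pi/11 per step.
HELIX_RISE: float = 2.7
HELIX_RADIUS: float = 9.9
HELIX_BP_PER_TURN: int = 11

#: Strand-association initiation free energy (kcal/mol).
DG_INIT: float = 4.1

#: Exhaustive-enumeration caps (kept at desk scale on purpose).
LOOP_ENUMERATION_CAP_NT: int = 12
DIMER_LENGTH_CAP_NT: int = 30


def kbt(temperature: float) -> float:
    """k_B*T in kcal/mol at the given temperature."""
    return KB_KCAL_PER_MOL_K * temperature
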