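"""Physical constants and package-wide unit conventions.

Units are fixed across the package: energies in kcal/mol, lengths in Å,
temperatures in K, masses in internal units (all 1 by default), and time in
internal units.  Only equilibrium averages enter the analysis, so the
absolute time scale never matters.
"""

#: Boltzmann constant / gas constant in kcal mol^-1 K^-1.
KB = 1.9872041e-3

#: Alias used where the molar-gas-constant name reads more naturally.
R_GAS = KB

#: CODATA Boltzmann constant, J/K (for the Eyring prefactor).
KB_SI = 1.380649e-23

#: CODATA Planck constant, J*s.
PLANCK_SI = 6.62607015e-34

#: Default reference temperature (K) at which T*dS terms are quoted.
T_REF_DEFAULT = 298.0


def beta(temperature: float) -> float:
    """Inverse temperature 1/(k_B T) in mol/kcal."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return 1.0 / (KB * temperature)
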