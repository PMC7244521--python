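"""Unit conventions and physical constants.

Positions are in Å, charges in elementary charge e.  Potentials and fields
are kept in the "native" units of the bare Coulomb sum (e/Å and e/Å²
respectively); the 1/4πε0 prefactor is absorbed into a single conversion
constant applied once, at the energy level, so every intermediate number is
auditable against the raw sum over charges.
"""

#: Coulomb conversion constant, kcal·mol⁻¹·Å·e⁻².  Multiplying q·φ (e × e/Å)
#: by this constant yields an energy in kcal/mol.
K_COUL = 332.0636

#: Equilibrium C≡O bond length used by the constant-dipole model, Å.
DEFAULT_BOND_LENGTH = 1.14

#: Hard singularity guard: an environment charge closer than this to an
#: evaluation point signals a malformed scene, not a physical configuration.
MIN_SEPARATION = 0.5
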