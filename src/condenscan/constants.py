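"""Physical constants shared across modules."""

AVOGADRO = 6.02214076e23  # molecules per mole

# Molecules per µm³ for a 1 µM solution: 1e-6 mol/L × N_A × 1e-15 L/µm³.
MOLECULES_PER_UM3_PER_UM = AVOGADRO * 1e-6 * 1e-15  # ≈ 602.214
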