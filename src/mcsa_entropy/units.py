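"""Physical constants and unit conversions.

Everything internal uses the MD unit system: lengths in nm, masses in u
(g/mol), energies in kJ/mol, time in ps.  In these units energy/mass has
units of nm^2/ps^2, so frequencies derived from mass-weighted variances
come out directly in 1/ps.

Entropies are carried in nats (dimensionless differential entropy) and
converted to molar entropy by the gas constant R.
"""

# molar gas constant, J/(mol K); one nat of entropy per particle = R per mole
GAS_CONSTANT_R = 8.31446

# Boltzmann constant in MD units, kJ/(mol K)
KB_KJ_PER_MOL_K = 8.31446e-3

# reduced Planck constant in MD units, kJ/mol * ps
HBAR_KJ_PS_PER_MOL = 6.35077993e-2

NATS = "nats"
J_PER_MOL_K = "J_per_molK"


def nats_to_molar(value_nats: float) -> float:
    """Convert a dimensionless entropy in nats to J/(mol K)."""
    return value_nats * GAS_CONSTANT_R


def convert(value: float, from_units: str, to_units: str) -> float:
    if from_units == to_units:
        return value
    if (from_units, to_units) == (NATS, J_PER_MOL_K):
        return value * GAS_CONSTANT_R
    if (from_units, to_units) == (J_PER_MOL_K, NATS):
        return value / GAS_CONSTANT_R
    raise ValueError(f"unknown unit conversion {from_units!r} -> {to_units!r}")
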