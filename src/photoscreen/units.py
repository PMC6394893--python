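"""Small unit conversions used when preparing assay solutions."""

from __future__ import annotations

#: berberine (as the chloride-free cation formulation used for dosing), g/mol
BERBERINE_MOLAR_MASS = 336.36


def mass_conc_to_micromolar(mass_ug_per_ml: float, molar_mass_g_per_mol: float) -> float:
    """Convert a mass concentration (ug/mL) to uM given the molar mass.

    ug/mL equals mg/L, so uM = 1000 * (mg/L) / (g/mol).
    """
    if molar_mass_g_per_mol <= 0:
        raise ValueError("molar mass must be > 0")
    return 1000.0 * mass_ug_per_ml / molar_mass_g_per_mol


def volume_percent(part_ul: float, total_ul: float) -> float:
    """Volume fraction of a component in a mixture, in percent (v/v)."""
    if total_ul <= 0 or part_ul < 0 or part_ul > total_ul:
        raise ValueError("need 0 <= part <= total and total > 0")
    return 100.0 * part_ul / total_ul
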