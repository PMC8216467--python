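"""Unit conventions and conversions.

Concentrations are stored in molar internally; user-facing tables and
manifests use nM (kinetics) or uM (melts), the units experimentalists
quote. Temperatures are degrees Celsius at the instrument interface and
kelvin inside thermodynamic formulas. The gas constant is kept in kcal
units so that enthalpies and entropies come out in the field's
conventional kcal/mol and kcal/(mol K).
"""

R_KCAL = 1.987e-3
"""Gas constant, kcal mol^-1 K^-1."""

KELVIN_OFFSET = 273.15

NM = 1e-9
UM = 1e-6


def nm_to_molar(value_nm: float) -> float:
    return value_nm * NM


def molar_to_nm(value_m: float) -> float:
    return value_m / NM


def um_to_molar(value_um: float) -> float:
    return value_um * UM


def molar_to_um(value_m: float) -> float:
    return value_m / UM


def celsius_to_kelvin(temp_c):
    return temp_c + KELVIN_OFFSET


def kelvin_to_celsius(temp_k):
    return temp_k - KELVIN_OFFSET
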