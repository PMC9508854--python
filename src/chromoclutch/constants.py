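"""Physical constants and unit conversions used throughout the package.

Internal energy unit is kcal/mol, length is nm, force is pN.
"""

from scipy import constants as _sc

#: Boltzmann constant in kcal/(mol K).
KB_KCAL_MOL_K: float = _sc.R / _sc.calorie / 1000.0  # 0.0019872...

#: Thermal energy at 300 K, kcal/mol (0.596 to three digits).
KT_300K: float = KB_KCAL_MOL_K * 300.0

#: Force conversion: 1 kcal/(mol nm) expressed in pN.
PN_PER_KCAL_MOL_NM: float = 6.948

#: Base pairs wrapped around a histone octamer.
WRAPPED_BP: int = 147

#: Rise of B-form DNA per base pair, nm.
NM_PER_BP: float = 0.34

#: Lowest allowed wrap fraction: the inner DNA layer never detaches.
W_MIN: float = 0.5


def kt(temperature_K: float) -> float:
    """Thermal energy kB*T in kcal/mol."""
    if temperature_K <= 0:
        raise ValueError("temperature must be positive")
    return KB_KCAL_MOL_K * temperature_K


def force_to_energy_slope(force_pN: float) -> float:
    """Energy gradient (kcal/mol per nm) equivalent to a constant force in pN."""
    return force_pN / PN_PER_KCAL_MOL_NM
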