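"""Solvent-box composition arithmetic for micro-aqueous organic solvent media.

A MAOS box is characterised by its water volume fraction: with ``n_w`` water
and ``n_o`` organic-solvent molecules of molar volumes ``V_w`` and ``V_o``
(cm³/mol), the water content is ``100 · n_w V_w / (n_w V_w + n_o V_o)`` % v/v.
Default molar volumes derive from 25 °C liquid densities.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["CompositionSpec", "water_volume_fraction", "MOLAR_VOLUMES"]

# Molar volumes (cm³/mol) from molecular weight / density at 25 °C:
# water 18.015 g/mol / 0.997 g/cm³; n-heptane 100.205 / 0.6795;
# toluene 92.141 / 0.8669.
MOLAR_VOLUMES = {
    "water": 18.069,
    "n-heptane": 147.469,
    "toluene": 106.288,
}


@dataclass(frozen=True)
class CompositionSpec:
    """Counts and molar volumes describing a binary water/organic box."""

    n_water: int
    n_organic: int
    molar_volume_water: float = MOLAR_VOLUMES["water"]
    molar_volume_organic: float = MOLAR_VOLUMES["n-heptane"]

    def __post_init__(self) -> None:
        if self.n_water < 0 or self.n_organic < 0:
            raise ValueError("molecule counts must be non-negative")
        if self.molar_volume_water <= 0 or self.molar_volume_organic <= 0:
            raise ValueError("molar volumes must be positive")


def water_volume_fraction(spec: CompositionSpec) -> float:
    """Water content of the box in % v/v.

    Raises ``ValueError`` when both molecule counts are zero.
    """
    vw = spec.n_water * spec.molar_volume_water
    vo = spec.n_organic * spec.molar_volume_organic
    if vw + vo == 0:
        raise ValueError("at least one molecule count must be positive")
    return 100.0 * vw / (vw + vo)
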