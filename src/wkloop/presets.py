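"""Named Windkessel parameter sets from the rat cardiovascular literature.

Values are stored in literature units (GPa·s·m⁻³ for resistances,
pm³·Pa⁻¹ for compliance) and converted to SI on retrieval.
"""

from __future__ import annotations

from dataclasses import dataclass

from .windkessel import WindkesselParams

__all__ = ["Preset", "PRESETS", "get_preset", "preset_names"]


@dataclass(frozen=True)
class Preset:
    name: str
    Rp_GPa: float
    C_pm3: float
    Zc_GPa: float
    note: str

    @property
    def params(self) -> WindkesselParams:
        return WindkesselParams.from_literature_units(self.Rp_GPa, self.C_pm3,
                                                 self.Zc_GPa)


_ALL = [
    Preset("normotensive", 14.5, 32.0, 0.5,
           "healthy rat systemic vasculature (literature reference set)"),
    Preset("hypertensive", 21.4, 15.0, 0.76,
           "raised resistance/impedance, stiffened arteries"),
    Preset("hypotensive", 9.18, 42.0, 0.31,
           "lowered resistance/impedance, more compliant arteries"),
    Preset("room_temp_base", 150.0, 32.0, 5.0,
           "base load matched to slow 1 Hz room-temperature twitches"),
]

PRESETS: dict[str, Preset] = {p.name: p for p in _ALL}


def preset_names() -> list[str]:
    return list(PRESETS)


def get_preset(name: str) -> WindkesselParams:
    """Return the SI parameter triplet for a registered preset name."""
    try:
        return PRESETS[name].params
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(PRESETS)}"
        ) from None
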