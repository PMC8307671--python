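"""Named fixture presets: curated parameter bundles for each module.

The presets are the reference cases exercised by the documentation and the
test suite; their names index the package's gallery of standard scenarios
(antisymmetric charged plates at two salt concentrations, a zwitterionic
bilayer facing an oppositely charged wall, and free/adhered vesicle shape
families at several reduced volumes).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Dict

__all__ = ["FixturePreset", "PRESETS", "get_preset", "list_presets"]


@dataclass(frozen=True)
class FixturePreset:
    """A complete, runnable parameter bundle for one module task."""

    name: str
    module: str  # 'edl' | 'headgroup' | 'vesicle'
    task: str    # 'solve' | 'pressure-curve' | 'minimize' | 'scan'
    params: Dict[str, Any] = field(default_factory=dict)
    note: str = ""

    def config_dict(self) -> Dict[str, Any]:
        """Plain-dict form consumed by config.RunConfig."""
        return dict(
            module=self.module,
            task=self.task,
            preset=self.name,
            params=dict(self.params),
        )


_EDL_COMMON = dict(
    temperature=298.0,
    water_molar=55.0,
    p0_debye=3.1,
    refractive_index=1.33,
)

PRESETS: Dict[str, FixturePreset] = {
    p.name: p
    for p in [
        FixturePreset(
            name="fig8_low_salt",
            module="edl",
            task="pressure-curve",
            params=dict(
                sigma1=0.2,
                sigma2=-0.2,
                salt_molar=0.01,
                gaps_nm=[1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0, 10.0],
                **_EDL_COMMON,
            ),
            note=(
                "Osmotic pressure vs distance between oppositely charged "
                "plates (sigma = +/-0.2 As/m^2) at low screening, 0.01 M salt."
            ),
        ),
        FixturePreset(
            name="fig8_high_salt",
            module="edl",
            task="pressure-curve",
            params=dict(
                sigma1=0.2,
                sigma2=-0.2,
                salt_molar=0.15,
                gaps_nm=[1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0, 10.0],
                **_EDL_COMMON,
            ),
            note=(
                "Same plate pair at physiological screening, 0.15 M salt; "
                "the attraction decays faster with distance."
            ),
        ),
        FixturePreset(
            name="fig10_alpha5",
            module="headgroup",
            task="solve",
            params=dict(
                alpha=5.0,
                sigma1=-0.30,
                sigma2=0.30,
                D_nm=0.42,
                gap_nm=4.0,
                salt_molar=0.01,
                **_EDL_COMMON,
            ),
            note=(
                "Zwitterionic headgroup layer (partition parameter alpha = 5, "
                "phosphate plane -0.30 As/m^2) facing a +0.30 As/m^2 wall."
            ),
        ),
        FixturePreset(
            name="fig12_v05",
            module="vesicle",
            task="scan",
            params=dict(v=0.5, c0=0.0, w_list=[0.0, 1.0, 2.0, 4.0, 8.0, 16.0]),
            note="Adhesion family of a strongly deflated vesicle, v = 0.5.",
        ),
        FixturePreset(
            name="fig12_v06",
            module="vesicle",
            task="scan",
            params=dict(v=0.6, c0=0.0, w_list=[0.0, 1.0, 2.0, 4.0, 8.0, 16.0]),
            note="Adhesion family near the oblate window, v = 0.6.",
        ),
        FixturePreset(
            name="fig12_v08",
            module="vesicle",
            task="scan",
            params=dict(v=0.8, c0=0.0, w_list=[0.0, 1.0, 2.0, 4.0, 8.0, 16.0]),
            note="Adhesion family of a prolate vesicle, v = 0.8.",
        ),
        FixturePreset(
            name="fig12_v095",
            module="vesicle",
            task="scan",
            params=dict(v=0.95, c0=0.0, w_list=[0.0, 1.0, 2.0, 4.0, 8.0, 16.0]),
            note=(
                "Adhesion family of a nearly spherical vesicle, v = 0.95; "
                "large w gives a spherical cap with a small contact disc."
            ),
        ),
        FixturePreset(
            name="fig13_pear",
            module="vesicle",
            task="scan",
            params=dict(
                v=0.8, c0=2.4, w_list=[0.0, 1.0, 2.0, 4.0, 8.0, 16.0],
                seed="pear",
            ),
            note=(
                "Pear-shaped free vesicle (c0 = 2.4, v = 0.8) deforming into "
                "adhered shapes with a growing contact disc."
            ),
        ),
    ]
}


def get_preset(name: str) -> FixturePreset:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset '{name}'; available: {', '.join(sorted(PRESETS))}"
        ) from None


def list_presets() -> list:
    return sorted(PRESETS)
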