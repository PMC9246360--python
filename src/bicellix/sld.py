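"""Scattering length densities of molecular components and mixtures.

X-ray SLD is electron density times the classical electron radius
(r_e = 2.8179403e-5 Å); neutron SLD is the summed coherent scattering
length over the molecular volume.  Units are Å⁻² throughout, the scale on
which lipid-water contrasts are a few 1e-6 Å⁻².

The module also houses the fixed DMPC/CHAPSO bilayer geometry used by the
bicelle and ribbon models: hydrophobic core thickness H_tail = 28.8 Å,
area per lipid A_L = 61.8 Å², CHAPSO belt thickness ΔR = 11.4 Å, and the
ribbon shell rule T_shell = max(H_head, ΔR).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import pandas as pd

from .curves import ValidationError

__all__ = [
    "R_ELECTRON_A",
    "CompositionSpec",
    "BilayerConstants",
    "DMPC_CHAPSO",
    "xray_sld",
    "neutron_sld",
    "mixture_sld",
    "load_compositions",
]

#: Classical electron radius (Thomson scattering length) in Å.
R_ELECTRON_A = 2.8179403e-5


@dataclass(frozen=True)
class CompositionSpec:
    """Scattering content of one molecular species.

    ``sum_b`` is the coherent neutron scattering length per molecule in Å
    (tabulated values in fm are 1e-5 Å).
    """

    n_electrons: float
    sum_b: float
    molecular_volume: float
    name: str = ""

    def __post_init__(self) -> None:
        if self.molecular_volume <= 0:
            raise ValidationError("molecular_volume must be > 0")
        if self.n_electrons < 0:
            raise ValidationError("n_electrons must be >= 0")


@dataclass(frozen=True)
class BilayerConstants:
    """Fixed DMPC/CHAPSO geometric constants of the bicelle/ribbon models.

    All lengths in Å, areas in Å².  ``t_shell`` follows the rule
    max(H_head, ΔR): when ribbons form, lipid heads and detergent
    redistribute into one hydrophilic shell whose thickness is set by the
    thicker of the two.
    """

    h_tail: float = 28.8
    area_per_lipid: float = 61.8
    delta_r: float = 11.4
    h_head: float = 8.1

    def __post_init__(self) -> None:
        for name in ("h_tail", "area_per_lipid", "delta_r"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if self.h_head < 0:
            raise ValidationError("h_head must be >= 0")

    @property
    def t_shell(self) -> float:
        """Ribbon hydrophilic shell thickness, max(H_head, ΔR) [Å]."""
        return max(self.h_head, self.delta_r)

    @property
    def tail_volume_per_lipid(self) -> float:
        """Hydrophobic volume per lipid, A_L x H_tail / 2 [Å³]."""
        return self.area_per_lipid * self.h_tail / 2.0


#: Default constants: one-leaflet tail slab 14.4 Å deep at 61.8 Å² per lipid.
DMPC_CHAPSO = BilayerConstants()


def xray_sld(comp: CompositionSpec) -> float:
    """X-ray SLD = n_electrons x r_e / V [Å⁻²]."""
    return comp.n_electrons * R_ELECTRON_A / comp.molecular_volume


def neutron_sld(comp: CompositionSpec) -> float:
    """Neutron SLD = sum of coherent scattering lengths / V [Å⁻²]."""
    return comp.sum_b / comp.molecular_volume


def mixture_sld(components: Sequence[tuple[float, float]]) -> float:
    """Volume-fraction-weighted SLD of a mixture.

    Parameters
    ----------
    components : sequence of (sld, volume_fraction)
        Fractions must be non-negative and sum to 1 within 1e-9.
    """
    if not components:
        raise ValidationError("mixture needs at least one component")
    fracs = [phi for _, phi in components]
    if any(phi < 0 for phi in fracs):
        raise ValidationError("volume fractions must be >= 0")
    total = sum(fracs)
    if abs(total - 1.0) > 1e-9:
        raise ValidationError(f"volume fractions sum to {total}, not 1")
    return sum(rho * phi for rho, phi in components)


def load_compositions() -> pd.DataFrame:
    """Load the shipped composition fixtures (name, n_electrons, sum_b, volume).

    These are physically derived defaults for water, heavy water, DMPC
    head/tail moieties and CHAPSO, indexed by name.
    """
    with resources.files("bicellix.data").joinpath("compositions.csv").open() as fh:
        df = pd.read_csv(fh, comment="#")
    return df.set_index("name")


def composition(name: str) -> CompositionSpec:
    """Look one fixture up by name and return it as a CompositionSpec."""
    df = load_compositions()
    if name not in df.index:
        raise ValidationError(f"unknown composition {name!r}; have {list(df.index)}")
    row = df.loc[name]
    return CompositionSpec(
        n_electrons=float(row["n_electrons"]),
        sum_b=float(row["sum_b"]),
        molecular_volume=float(row["volume"]),
        name=name,
    )
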