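"""Conceptual-DFT global reactivity descriptors from frontier-orbital energies.

Given the HOMO and LUMO energies of a molecule, this module evaluates the
standard global reactivity panel: the HOMO–LUMO gap, ionization potential
I = -eps_HOMO and electron affinity A = -eps_LUMO (Koopmans-style), chemical
potential mu = (eps_L + eps_H)/2, global hardness eta = (eps_L - eps_H)/2,
global softness S = 1/(2 eta), electronegativity chi = -mu, the Parr
electrophilicity index omega = mu^2 / (2 eta), the electron-acceptor and
electron-donor powers

    omega+ = (I + 3A)^2 / (16 (I - A))
    omega- = (3I + A)^2 / (16 (I - A))

and the net electrophilicity omega+ + omega-.

All descriptors are returned in the unit of the input orbital energies.
Softness is additionally exposed in a "table convention" in which the
inverse gap is rescaled by the square of the hartree->kcal/mol constant
(``softness_table = 627.5095**2 / gap``); some published descriptor tables
use this convention when the orbital energies are tabulated in kcal/mol,
and it is kept here so such tables remain auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable

import math

import pandas as pd

from .units import HARTREE_TO_KCAL, ENERGY_UNITS, convert_energy

#: descriptor columns of a panel table, in canonical order
PANEL_COLUMNS = [
    "gap",
    "ionization_potential",
    "electron_affinity",
    "chemical_potential",
    "hardness",
    "softness",
    "softness_table",
    "electronegativity",
    "electrophilicity",
    "omega_plus",
    "omega_minus",
    "net_electrophilicity",
]


@dataclass(frozen=True)
class OrbitalEnergies:
    """Frontier orbital energies of one molecule, with a declared unit."""

    molecule_id: str
    eps_homo: float
    eps_lumo: float
    unit: str = "kcal_per_mol"

    def __post_init__(self) -> None:
        if self.unit not in ENERGY_UNITS:
            raise ValueError(f"unknown energy unit {self.unit!r}")
        if not (math.isfinite(self.eps_homo) and math.isfinite(self.eps_lumo)):
            raise ValueError(f"{self.molecule_id}: non-finite orbital energy")
        if self.eps_homo >= self.eps_lumo:
            raise ValueError(
                f"{self.molecule_id}: eps_homo ({self.eps_homo}) must lie "
                f"below eps_lumo ({self.eps_lumo}); degenerate gap rejected"
            )

    def to_unit(self, unit: str) -> "OrbitalEnergies":
        return OrbitalEnergies(
            self.molecule_id,
            convert_energy(self.eps_homo, self.unit, unit),
            convert_energy(self.eps_lumo, self.unit, unit),
            unit,
        )


@dataclass(frozen=True)
class ReactivityPanel:
    """Global reactivity descriptor panel of one molecule.

    Energies carry the unit of the orbital energies the panel was computed
    from; ``softness`` is the physical 1/(2 eta) in inverse energy units,
    ``softness_table`` the rescaled table convention (see module docstring).
    """

    molecule_id: str
    unit: str
    gap: float
    ionization_potential: float
    electron_affinity: float
    chemical_potential: float
    hardness: float
    softness: float
    softness_table: float
    electronegativity: float
    electrophilicity: float
    omega_plus: float
    omega_minus: float
    net_electrophilicity: float

    def as_dict(self) -> dict:
        return asdict(self)


def compute_panel(orb: OrbitalEnergies) -> ReactivityPanel:
    """Evaluate the full reactivity descriptor panel for one molecule."""
    eh, el = orb.eps_homo, orb.eps_lumo
    gap = el - eh
    ip = -eh
    ea = -el
    mu = 0.5 * (el + eh)
    eta = 0.5 * gap
    softness = 1.0 / (2.0 * eta)
    # gap rescaled to kcal/mol before inverting, then reported as if it were
    # an energy: the convention some kcal/mol descriptor tables follow.
    gap_kcal = convert_energy(gap, orb.unit, "kcal_per_mol")
    softness_table = HARTREE_TO_KCAL**2 / gap_kcal
    softness_table = convert_energy(softness_table, "kcal_per_mol", orb.unit)
    chi = -mu
    omega = mu * mu / (2.0 * eta)
    denom = 16.0 * (ip - ea)  # == 16 * gap
    omega_plus = (ip + 3.0 * ea) ** 2 / denom
    omega_minus = (3.0 * ip + ea) ** 2 / denom
    return ReactivityPanel(
        molecule_id=orb.molecule_id,
        unit=orb.unit,
        gap=gap,
        ionization_potential=ip,
        electron_affinity=ea,
        chemical_potential=mu,
        hardness=eta,
        softness=softness,
        softness_table=softness_table,
        electronegativity=chi,
        electrophilicity=omega,
        omega_plus=omega_plus,
        omega_minus=omega_minus,
        net_electrophilicity=omega_plus + omega_minus,
    )


def panel_table(rows: Iterable[OrbitalEnergies]) -> pd.DataFrame:
    """Descriptor matrix (molecules x descriptors) for a set of molecules.

    Row order follows the input; columns follow :data:`PANEL_COLUMNS`.
    Duplicate molecule ids are rejected.
    """
    rows = list(rows)
    if not rows:
        raise ValueError("panel_table requires at least one molecule")
    ids = [r.molecule_id for r in rows]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise ValueError(f"duplicate molecule ids: {sorted(dupes)}")
    records = []
    for orb in rows:
        panel = compute_panel(orb)
        d = panel.as_dict()
        d.pop("unit")
        records.append(d)
    df = pd.DataFrame.from_records(records, index="molecule_id")
    return df[PANEL_COLUMNS]


def write_panel(df: pd.DataFrame, path, decimals: int = 3, sep: str = "\t") -> None:
    """Serialize a descriptor matrix, rounding only at this boundary."""
    df.round(decimals).to_csv(path, sep=sep, index_label="molecule_id")
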