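"""Energy and length unit conversions used at I/O boundaries.

Internally each module works in a single declared unit (kcal/mol for
reactivity and MMGBSA, nm for trajectories, atomic units for NCI grids);
conversions happen exactly once, at the boundary.
"""

from __future__ import annotations

HARTREE_TO_KCAL = 627.5095
EV_TO_KCAL = 23.0609
ANGSTROM_TO_BOHR = 1.0 / 0.529177210903
ANGSTROM_TO_NM = 0.1

ENERGY_UNITS = ("hartree", "eV", "kcal_per_mol")

# conversion factors to kcal/mol
_TO_KCAL = {
    "hartree": HARTREE_TO_KCAL,
    "eV": EV_TO_KCAL,
    "kcal_per_mol": 1.0,
}


def convert_energy(value: float, from_unit: str, to_unit: str) -> float:
    """Convert an energy between hartree, eV and kcal/mol.

    Round-trips are exact to better than 1e-12 relative.
    """
    for u in (from_unit, to_unit):
        if u not in _TO_KCAL:
            raise ValueError(
                f"unknown energy unit {u!r}; expected one of {ENERGY_UNITS}"
            )
    if from_unit == to_unit:
        return value
    return value * _TO_KCAL[from_unit] / _TO_KCAL[to_unit]
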