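"""Per-element property tables used by descriptor and trajectory code.

Covers the organic subset relevant to flavanol metabolites (H, C, N, O, S
plus a few common extras). Electronegativities are Pauling and Sanderson
scales; polarizabilities are atomic dipole polarizabilities in A^3;
masses in amu.
"""

from __future__ import annotations

ATOMIC_NUMBER = {
    "H": 1, "C": 6, "N": 7, "O": 8, "F": 9, "P": 15, "S": 16, "Cl": 17,
}

MASS = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998,
    "P": 30.974, "S": 32.06, "Cl": 35.45,
}

PAULING_EN = {
    "H": 2.20, "C": 2.55, "N": 3.04, "O": 3.44, "F": 3.98,
    "P": 2.19, "S": 2.58, "Cl": 3.16,
}

SANDERSON_EN = {
    "H": 2.592, "C": 2.746, "N": 3.194, "O": 3.654, "F": 4.000,
    "P": 2.515, "S": 2.957, "Cl": 3.475,
}

POLARIZABILITY = {  # A^3
    "H": 0.667, "C": 1.76, "N": 1.10, "O": 0.802, "F": 0.557,
    "P": 3.63, "S": 2.90, "Cl": 2.18,
}

VALENCE_ELECTRONS = {
    "H": 1, "C": 4, "N": 5, "O": 6, "F": 7, "P": 5, "S": 6, "Cl": 7,
}

PRINCIPAL_QUANTUM_NUMBER = {
    "H": 1, "C": 2, "N": 2, "O": 2, "F": 2, "P": 3, "S": 3, "Cl": 3,
}


def require(table: dict, element: str, what: str):
    try:
        return table[element]
    except KeyError:
        raise KeyError(f"no {what} tabulated for element {element!r}") from None
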