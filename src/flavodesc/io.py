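"""Readers and writers for the external text formats.

Formats: whitespace XYZ (single or concatenated multi-frame blocks, Angstrom
by convention), a minimal PDB subset (ATOM records, read-only), Gaussian
cube volumetric files (bohr, innermost axis fastest), and the TSV/CSV tables
the analysis modules exchange. Typographic minus signs (U+2212), as found in
typeset tables, are normalized to ASCII on read. Conversions between
Angstrom / nm / bohr happen here, exactly once.
"""

from __future__ import annotations

import hashlib
import io as _stdio
import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import _elements as el
from .mmgbsa import COMPONENTS, EnergyFrameTable
from .nci import NciGrid
from .reactivity import OrbitalEnergies
from .trajectory import Trajectory
from .units import ANGSTROM_TO_BOHR, ANGSTROM_TO_NM

_MINUS = "−"


def _normalized_text(path) -> _stdio.StringIO:
    text = Path(path).read_text()
    return _stdio.StringIO(text.replace(_MINUS, "-"))


# ---------------------------------------------------------------------------
# tables

def read_table(path, required: list[str], sep: str = "\t") -> pd.DataFrame:
    """Typed table read with schema validation by column name.

    Missing columns are reported by name; unknown extra columns produce a
    warning-level log entry but are kept.
    """
    df = pd.read_csv(_normalized_text(path), sep=sep)
    df.columns = [c.strip() for c in df.columns]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    extra = [c for c in df.columns if c not in required]
    if extra:
        import logging

        logging.getLogger(__name__).warning("%s: ignoring extra columns %s", path, extra)
    return df


def write_table(df: pd.DataFrame, path, sep: str = "\t", index: bool = False) -> None:
    df.to_csv(path, sep=sep, index=index)


def read_orbital_table(path) -> list[OrbitalEnergies]:
    """Orbital-energy TSV: ``molecule_id  eps_homo  eps_lumo  unit``."""
    df = read_table(path, ["molecule_id", "eps_homo", "eps_lumo", "unit"])
    return [
        OrbitalEnergies(
            str(r.molecule_id), float(r.eps_homo), float(r.eps_lumo), str(r.unit)
        )
        for r in df.itertuples()
    ]


def read_energy_frames(path, system_label: str) -> EnergyFrameTable:
    """Per-frame MMGBSA component TSV: ``frame`` plus the five components."""
    df = read_table(path, ["frame", *COMPONENTS])
    return EnergyFrameTable(system_label, df[["frame", *COMPONENTS]])


def load_published_orbitals() -> list[OrbitalEnergies]:
    """Packaged frontier-orbital energies (kcal/mol) of (-)-Epicatechin and
    its six metabolites."""
    with resources.as_file(
        resources.files("flavodesc.data") / "epicatechin_orbitals.tsv"
    ) as p:
        return read_orbital_table(p)


def load_published_panel() -> pd.DataFrame:
    """Packaged published reactivity-descriptor table (descriptor x molecule,
    kcal/mol) for auditing; includes one known-typo cell (3'ME5S
    omega_minus) documented in the methods note."""
    with resources.as_file(
        resources.files("flavodesc.data") / "epicatechin_panel_published.tsv"
    ) as p:
        return pd.read_csv(_normalized_text(p), sep="\t", index_col="descriptor")


# ---------------------------------------------------------------------------
# XYZ

def read_xyz(path, to_unit: str = "angstrom"):
    """Multi-frame XYZ; returns (elements, frames) with frames shaped
    (n_frames, n_atoms, 3) in Angstrom, nm, or bohr."""
    scale = {"angstrom": 1.0, "nm": ANGSTROM_TO_NM, "bohr": ANGSTROM_TO_BOHR}[to_unit]
    lines = _normalized_text(path).read().splitlines()
    frames = []
    elements = None
    pos = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            natoms = int(lines[pos].split()[0])
        except ValueError:
            raise ValueError(f"{path}: malformed atom count at line {pos + 1}") from None
        block = lines[pos + 2 : pos + 2 + natoms]
        if len(block) < natoms:
            raise ValueError(f"{path}: truncated frame starting at line {pos + 1}")
        els, coords = [], []
        for off, line in enumerate(block):
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(f"{path}: malformed atom record at line {pos + 3 + off}")
            if parts[0] not in el.ATOMIC_NUMBER:
                raise ValueError(
                    f"{path}: unknown element {parts[0]!r} at line {pos + 3 + off}"
                )
            els.append(parts[0])
            coords.append([float(x) for x in parts[1:4]])
        arr = np.asarray(coords, float)
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"{path}: non-finite coordinates in frame at line {pos + 1}")
        if elements is None:
            elements = els
        elif els != elements:
            raise ValueError(f"{path}: inconsistent atoms across frames at line {pos + 1}")
        frames.append(arr * scale)
        pos += 2 + natoms
    if not frames:
        raise ValueError(f"{path}: no frames found")
    return elements, np.stack(frames)


def write_xyz(path, elements, frames, comment: str = "") -> None:
    """Write (multi-)frame XYZ in Angstrom."""
    frames = np.asarray(frames, float)
    if frames.ndim == 2:
        frames = frames[None]
    with open(path, "w") as fh:
        for frame in frames:
            fh.write(f"{len(elements)}\n{comment}\n")
            for e, (x, y, z) in zip(elements, frame):
                fh.write(f"{e} {x:.6f} {y:.6f} {z:.6f}\n")


def trajectory_from_xyz(path, default_mass: float = 12.011) -> Trajectory:
    """Build a Trajectory (nm) from an XYZ file (Angstrom on disk); element
    masses from the internal table, one residue per atom."""
    elements, frames = read_xyz(path, to_unit="nm")
    masses = np.array([el.MASS.get(e, default_mass) for e in elements])
    return Trajectory(
        atom_names=list(elements),
        masses=masses,
        residue_index=np.arange(len(elements)),
        frames=frames,
    )


# ---------------------------------------------------------------------------
# minimal PDB subset (read-only)

def read_pdb_atoms(path):
    """ATOM/HETATM records only: returns (names, elements, residue_index,
    coords-Angstrom). Fixed-column PDB slicing."""
    names, elements, resseq, coords = [], [], [], []
    for line in Path(path).read_text().splitlines():
        if not line.startswith(("ATOM", "HETATM")):
            continue
        name = line[12:16].strip()
        names.append(name)
        resseq.append(int(line[22:26]))
        coords.append(
            [float(line[30:38]), float(line[38:46]), float(line[46:54])]
        )
        symbol = line[76:78].strip() or name[:1]
        elements.append(symbol)
    if not names:
        raise ValueError(f"{path}: no ATOM records found")
    return names, elements, np.asarray(resseq, int), np.asarray(coords, float)


# ---------------------------------------------------------------------------
# Gaussian cube

def write_cube(grid: NciGrid, path, which: str = "signed_density", comment: str = "") -> None:
    """Export one field of an NCI grid as a Gaussian cube file (bohr,
    innermost/z axis fastest)."""
    values = getattr(grid, which)
    atoms = grid.atoms
    nx, ny, nz = grid.dims
    with open(path, "w") as fh:
        fh.write(f"flavodesc cube: {which}\n{comment}\n")
        ox, oy, oz = grid.origin
        fh.write(f"{len(atoms):5d} {ox:12.6f} {oy:12.6f} {oz:12.6f}\n")
        for n, axis in zip((nx, ny, nz), np.diag(grid.spacing)):
            fh.write(f"{n:5d} {axis[0]:12.6f} {axis[1]:12.6f} {axis[2]:12.6f}\n")
        for element, pos in atoms:
            z = el.ATOMIC_NUMBER[element]
            fh.write(
                f"{z:5d} {float(z):12.6f} {pos[0]:12.6f} {pos[1]:12.6f} {pos[2]:12.6f}\n"
            )
        flat = np.asarray(values, float).reshape(-1)  # x slowest, z fastest
        for start in range(0, flat.size, 6):
            fh.write(" ".join(f"{v:13.5E}" for v in flat[start : start + 6]) + "\n")


def read_cube(path):
    """Companion cube reader; returns (atoms, origin, spacing, values)."""
    lines = Path(path).read_text().splitlines()
    natoms, ox, oy, oz = lines[2].split()
    natoms = int(natoms)
    origin = np.array([float(ox), float(oy), float(oz)])
    dims, spacing = [], []
    for k in range(3):
        parts = lines[3 + k].split()
        dims.append(int(parts[0]))
        spacing.append(float(parts[1 + k]))
    atoms = []
    sym = {z: s for s, z in el.ATOMIC_NUMBER.items()}
    for line in lines[6 : 6 + natoms]:
        parts = line.split()
        atoms.append((sym[int(parts[0])], np.array([float(x) for x in parts[2:5]])))
    values = np.array(
        [float(v) for line in lines[6 + natoms :] for v in line.split()]
    ).reshape(dims)
    return atoms, origin, np.array(spacing), values


# ---------------------------------------------------------------------------
# provenance

def write_provenance(path, config: dict, input_paths=()) -> None:
    """Record package version, run configuration and input checksums."""
    from . import __version__

    checksums = {}
    for p in input_paths:
        p = Path(p)
        if p.exists():
            checksums[str(p)] = hashlib.sha256(p.read_bytes()).hexdigest()
    payload = {"version": __version__, "config": config, "input_sha256": checksums}
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
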