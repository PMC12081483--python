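"""Synthetic inputs with known ground truth for every analysis stage.

Each generator emulates one input kind of the pipeline — frontier-orbital
tables, per-frame MMGBSA component tables, toy trajectories, linear QSAR
datasets, small molecules, and a diatomic for NCI grids — and returns the
planted truth alongside the data so recovery can be asserted. All
randomness flows through one ``numpy.random.default_rng(seed)`` per call;
no global state is touched, and a given (spec, seed) is bit-reproducible.

The defaults mirror the study conditions of the flavanol-metabolite
analyses: 7 molecules with HOMO-LUMO gaps spanning 114-133 kcal/mol,
MMGBSA binding energies near -27 kcal/mol averaged over thousands of MD
frames, and 7-molecule / 3-descriptor QSAR fits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .descriptors import Atom, MoleculeRecord
from .mmgbsa import COMPONENTS, EnergyFrameTable
from .reactivity import OrbitalEnergies
from .trajectory import Trajectory, pair_rmsd

KINDS = (
    "orbital_table",
    "energy_frames",
    "trajectory",
    "linear_dataset",
    "toy_molecules",
    "diatomic_nci",
)


@dataclass(frozen=True)
class GeneratorSpec:
    seed: int
    kind: str
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown generator kind {self.kind!r}")


# ---------------------------------------------------------------------------
# orbital tables

def gen_orbital_table(
    n_molecules: int = 7,
    gap_range: tuple[float, float] = (114.0, 133.0),
    homo_range: tuple[float, float] = (-162.0, -134.0),
    seed: int = 0,
):
    """Random HOMO/LUMO pairs (kcal/mol) with eps_H < eps_L < 0, plus the
    reactivity panel recomputed by direct arithmetic as planted truth."""
    lo, hi = gap_range
    if not (0 < lo <= hi):
        raise ValueError("gap_range must be positive and ordered")
    rng = np.random.default_rng(seed)
    rows = []
    truth = []
    for i in range(n_molecules):
        gap = rng.uniform(lo, hi)
        eh = rng.uniform(*homo_range)
        el = eh + gap
        if el >= 0:  # keep LUMO bound; shift HOMO down instead
            eh -= el + 1.0
            el = eh + gap
        rows.append(OrbitalEnergies(f"MOL{i:03d}", eh, el, "kcal_per_mol"))
        # independent direct-arithmetic oracle for the descriptor panel
        I, A = -eh, -el
        truth.append(
            {
                "molecule_id": f"MOL{i:03d}",
                "gap": el - eh,
                "ionization_potential": I,
                "electron_affinity": A,
                "chemical_potential": (el + eh) / 2,
                "hardness": (el - eh) / 2,
                "softness": 1.0 / (el - eh),
                "electronegativity": -(el + eh) / 2,
                "electrophilicity": ((el + eh) / 2) ** 2 / (el - eh),
                "omega_plus": (I + 3 * A) ** 2 / (16 * (I - A)),
                "omega_minus": (3 * I + A) ** 2 / (16 * (I - A)),
                "net_electrophilicity": ((I + 3 * A) ** 2 + (3 * I + A) ** 2)
                / (16 * (I - A)),
            }
        )
    truth_df = pd.DataFrame(truth).set_index("molecule_id") if truth else pd.DataFrame()
    return rows, truth_df


# ---------------------------------------------------------------------------
# MMGBSA frame tables

#: default split of a planted dG_bind over the five components
_DEFAULT_SPLIT = {"E_internal": 0.10, "E_ele": 0.30, "E_vdw": 0.40, "G_GB": 0.15, "G_SA": 0.05}


def gen_energy_frames(
    planted=-26.98,
    n_frames: int = 2000,
    sigma: float = 1.0,
    seed: int = 0,
):
    """Three-trajectory MMGBSA tables with a planted binding energy.

    ``planted`` is either a full per-component delta dict or a total
    dG_bind (kcal/mol) split over components in fixed proportions. Complex
    frames are receptor-baseline + ligand-baseline + planted delta, and all
    three systems get i.i.d. Gaussian noise of sd ``sigma`` per frame and
    component. Returns ``(tables, truth)`` where truth records the exact
    planted components and their sum.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if isinstance(planted, dict):
        missing = [c for c in COMPONENTS if c not in planted]
        if missing:
            raise ValueError(f"planted dict missing components: {missing}")
        delta = {c: float(planted[c]) for c in COMPONENTS}
    else:
        delta = {c: float(planted) * _DEFAULT_SPLIT[c] for c in COMPONENTS}
    rng = np.random.default_rng(seed)
    base_receptor = {"E_internal": 5200.0, "E_ele": -8200.0, "E_vdw": -640.0,
                     "G_GB": -3100.0, "G_SA": 110.0}
    base_ligand = {"E_internal": 45.0, "E_ele": -60.0, "E_vdw": -4.0,
                   "G_GB": -30.0, "G_SA": 4.0}
    frames = np.arange(1, n_frames + 1)

    def make(label: str, means: dict) -> EnergyFrameTable:
        cols = {"frame": frames}
        for c in COMPONENTS:
            cols[c] = means[c] + sigma * rng.standard_normal(n_frames)
        return EnergyFrameTable(label, pd.DataFrame(cols))

    complex_means = {
        c: base_receptor[c] + base_ligand[c] + delta[c] for c in COMPONENTS
    }
    tables = {
        "complex": make("complex", complex_means),
        "receptor": make("receptor", base_receptor),
        "ligand": make("ligand", base_ligand),
    }
    truth = {"delta_components": delta, "dG_bind": sum(delta.values())}
    return tables, truth


# ---------------------------------------------------------------------------
# trajectories

def _base_structure(n_atoms: int, rng) -> np.ndarray:
    """Non-degenerate random structure (nm) with ~0.3 nm spread."""
    return 0.3 * rng.standard_normal((n_atoms, 3))


def gen_trajectory(mode: str = "static", params: dict | None = None, seed: int = 0, **extra):
    """Toy trajectories with analytically known RMSD/RMSF/cluster truth.

    Modes: ``static`` (identical frames), ``wobble`` (atom 0 oscillates
    along x with amplitude ``a`` over full periods), ``two_state`` (frames
    alternate between two conformers at a stated superposed-RMSD
    separation, with small jitter).
    """
    params = {**(params or {}), **extra}
    rng = np.random.default_rng(seed)
    n_atoms = int(params.pop("n_atoms", 10))
    n_frames = int(params.pop("n_frames", 100))
    base = _base_structure(n_atoms, rng)
    meta = dict(
        atom_names=[f"CA{i}" for i in range(n_atoms)],
        masses=np.full(n_atoms, 12.011),
        residue_index=np.arange(n_atoms),
    )
    if mode == "static":
        frames = np.repeat(base[None], n_frames, axis=0)
        truth = {"rmsd": np.zeros(n_frames), "rmsf": np.zeros(n_atoms)}
    elif mode == "wobble":
        a = float(params.pop("amplitude", 0.05))
        phases = 2.0 * np.pi * np.arange(n_frames) / n_frames
        frames = np.repeat(base[None], n_frames, axis=0).copy()
        frames[:, 0, 0] += a * np.sin(phases)
        s = a * np.sin(phases)
        # raw (non-superposed) closed forms
        rmsd = np.abs(s) / math.sqrt(n_atoms)
        rmsf0 = math.sqrt(float(np.mean((s - s.mean()) ** 2)))
        rmsf = np.zeros(n_atoms)
        rmsf[0] = rmsf0
        truth = {"amplitude": a, "rmsd_raw": rmsd, "rmsf_raw": rmsf}
    elif mode == "two_state":
        sep = float(params.pop("separation", 0.5))
        jitter = float(params.pop("jitter", 0.01))
        direction = rng.standard_normal((n_atoms, 3))
        # scale the displacement so the *superposed* RMSD equals `sep`
        lo_s, hi_s = 0.0, 1.0
        while pair_rmsd(base + hi_s * direction, base) < sep:
            hi_s *= 2.0
        for _ in range(200):
            mid = 0.5 * (lo_s + hi_s)
            if pair_rmsd(base + mid * direction, base) < sep:
                lo_s = mid
            else:
                hi_s = mid
        other = base + 0.5 * (lo_s + hi_s) * direction
        labels = np.arange(n_frames) % 2
        frames = np.where(labels[:, None, None] == 0, base[None], other[None]).copy()
        frames += jitter * rng.standard_normal(frames.shape)
        truth = {
            "separation": pair_rmsd(other, base),
            "jitter": jitter,
            "state_labels": labels,
            "n_clusters": 2,
        }
    else:
        raise ValueError(f"unknown trajectory mode {mode!r}")
    return Trajectory(frames=frames, **meta), truth


# ---------------------------------------------------------------------------
# linear QSAR datasets

def gen_linear_dataset(
    n: int = 7,
    p: int = 20,
    active: dict[str, float] | None = None,
    intercept: float = -20.0,
    sigma: float = 0.0,
    seed: int = 0,
):
    """Descriptor matrix plus linear response with planted coefficients.

    ``active`` maps descriptor names (``X00`` .. style) to coefficients;
    defaults to three active terms. Truth records intercept, coefficients
    and noise level.
    """
    if active is None:
        active = {"X00": -5.0, "X01": 2.5, "X02": -1.25}
    if n <= len(active) + 1:
        raise ValueError("n must exceed number of active terms + 1")
    rng = np.random.default_rng(seed)
    names = [f"X{j:02d}" for j in range(p)]
    for name in active:
        if name not in names:
            raise ValueError(f"active descriptor {name!r} outside the X00..X{p-1:02d} set")
    X = pd.DataFrame(rng.standard_normal((n, p)), columns=names)
    y = intercept + sum(coef * X[name] for name, coef in active.items())
    y = y + sigma * rng.standard_normal(n)
    truth = {"intercept": intercept, "coefficients": dict(active), "sigma": sigma}
    return X, y.to_numpy(), truth


# ---------------------------------------------------------------------------
# toy molecules

def _chain(mol_id: str, n_c: int, charges: list[float]) -> MoleculeRecord:
    """Zig-zag n-alkane heavy-atom chain with idealized sp3 geometry."""
    atoms = []
    bond_len, angle = 1.526, math.radians(111.0)
    dx = bond_len * math.sin(angle / 2)
    dy = bond_len * math.cos(angle / 2)
    for i in range(n_c):
        n_h = 3 if i in (0, n_c - 1) and n_c > 1 else (4 if n_c == 1 else 2)
        atoms.append(
            Atom(
                "C",
                partial_charge=charges[i],
                n_hydrogens=n_h,
                position=np.array([i * dx, (i % 2) * dy, 0.0]),
            )
        )
    bonds = [(i, i + 1, 1) for i in range(n_c - 1)]
    return MoleculeRecord(mol_id, atoms, bonds)


def gen_toy_molecules() -> dict[str, MoleculeRecord]:
    """Deterministic fixture set for descriptor oracles.

    Partial charges are synthetic round numbers chosen to exercise the
    charge descriptors (terminal carbons slightly negative), not outputs of
    any charge model. Geometries are idealized.
    """
    mols = {
        "methane": _chain("methane", 1, [-0.40]),
        "ethane": _chain("ethane", 2, [-0.30, -0.30]),
        "propane": _chain("propane", 3, [-0.30, -0.10, -0.30]),
        "butane": _chain("butane", 4, [-0.30, -0.10, -0.10, -0.30]),
    }
    # benzene-like 6-ring: alternating formal bond orders, one H per carbon
    r = 1.39
    ring_atoms = [
        Atom(
            "C",
            partial_charge=-0.05,
            n_hydrogens=1,
            position=np.array(
                [r * math.cos(k * math.pi / 3), r * math.sin(k * math.pi / 3), 0.0]
            ),
        )
        for k in range(6)
    ]
    ring_bonds = [(k, (k + 1) % 6, 1 + k % 2) for k in range(6)]
    mols["ring6"] = MoleculeRecord("ring6", ring_atoms, ring_bonds)
    # diatomic at exactly 10.5 A: unit-RDF fixture at coded radius 105
    mols["diatomic105"] = MoleculeRecord(
        "diatomic105",
        [
            Atom("C", partial_charge=-0.20, n_hydrogens=3, position=np.zeros(3)),
            Atom("C", partial_charge=0.20, n_hydrogens=3, position=np.array([10.5, 0.0, 0.0])),
        ],
        [(0, 1, 1)],
    )
    return mols


# ---------------------------------------------------------------------------
# NCI diatomic

def gen_diatomic_nci(
    elements: tuple[str, str] = ("O", "O"), separation: float = 5.6, seed: int = 0
):
    """Symmetric diatomic (bohr) for NCI grid tests; truth holds the
    midpoint, where the density gradient vanishes by symmetry."""
    half = separation / 2.0
    atoms = [
        (elements[0], np.array([-half, 0.0, 0.0])),
        (elements[1], np.array([+half, 0.0, 0.0])),
    ]
    truth = {"midpoint": np.zeros(3), "separation": separation}
    return atoms, truth


_DISPATCH = {
    "orbital_table": gen_orbital_table,
    "energy_frames": gen_energy_frames,
    "trajectory": gen_trajectory,
    "linear_dataset": gen_linear_dataset,
    "toy_molecules": lambda **kw: gen_toy_molecules(),
    "diatomic_nci": gen_diatomic_nci,
}


def generate(spec: GeneratorSpec):
    """Dispatch a :class:`GeneratorSpec` to its generator."""
    fn = _DISPATCH[spec.kind]
    kwargs = dict(spec.parameters)
    if spec.kind not in ("toy_molecules",):
        kwargs.setdefault("seed", spec.seed)
    return fn(**kwargs)
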