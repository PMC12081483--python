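"""Post-simulation structural analysis: RMSD, Rg, RMSF, cutoff clustering.

Coordinates are in nm throughout. Superposition uses least-squares rigid
alignment (Kabsch); clustering is the gromos-style neighbor-count algorithm:
the frame with the most neighbors within an RMSD cutoff seeds a cluster, its
neighborhood is removed, and the procedure repeats.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class Trajectory:
    """In-memory trajectory: per-atom metadata plus frames of coordinates (nm)."""

    atom_names: list[str]
    masses: np.ndarray  # amu, per atom
    residue_index: np.ndarray  # per atom
    frames: np.ndarray  # (n_frames, n_atoms, 3), nm

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, float)
        if frames.ndim != 3 or frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if frames.shape[0] < 1:
            raise ValueError("at least one frame required")
        n = len(self.atom_names)
        if frames.shape[1] != n or len(self.masses) != n or len(self.residue_index) != n:
            raise ValueError("atom metadata and frame atom counts disagree")
        if np.any(np.asarray(self.masses) <= 0):
            raise ValueError("masses must be positive")
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "masses", np.asarray(self.masses, float))
        object.__setattr__(self, "residue_index", np.asarray(self.residue_index, int))

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]


@dataclass(frozen=True)
class ClusterResult:
    """Frame->cluster assignment with per-cluster medoid representatives."""

    assignments: np.ndarray  # cluster id per frame
    representatives: dict[int, int]  # cluster id -> frame index
    cutoff: float  # nm

    @property
    def n_clusters(self) -> int:
        return len(self.representatives)


def _resolve_selection(selection, n_atoms: int) -> np.ndarray:
    if selection is None:
        return np.arange(n_atoms)
    idx = np.asarray(selection)
    if idx.dtype == bool:
        idx = np.flatnonzero(idx)
    if idx.size == 0:
        raise ValueError("empty atom selection")
    return idx.astype(int)


def kabsch_superpose(mobile, reference, weights=None):
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best matches ``reference`` in the
    weighted least-squares sense. The rotation is proper (det +1).
    """
    X = np.asarray(mobile, float)
    Y = np.asarray(reference, float)
    if X.shape != Y.shape or X.ndim != 2 or X.shape[1] != 3:
        raise ValueError("mobile and reference must both be (n_atoms, 3)")
    n = X.shape[0]
    if n < 3:
        raise ValueError("superposition requires at least 3 atoms")
    w = np.ones(n) if weights is None else np.asarray(weights, float)
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    w = w / w.sum()
    xbar = w @ X
    ybar = w @ Y
    Xc = X - xbar
    Yc = Y - ybar
    # reject (near-)collinear references: rotation about the line is free
    sv_ref = np.linalg.svd(Yc * np.sqrt(w)[:, None], compute_uv=False)
    if sv_ref[1] <= 1e-10 * max(sv_ref[0], 1e-300):
        raise ValueError("degenerate (collinear) reference geometry")
    H = (Xc * w[:, None]).T @ Yc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = ybar - R @ xbar
    diff = Xc @ R.T - Yc
    rmsd = float(np.sqrt(np.sum(w * np.einsum("ij,ij->i", diff, diff))))
    return R, t, rmsd


def pair_rmsd(a, b, weights=None, superpose: bool = True) -> float:
    """RMSD between two coordinate sets, optionally after superposition."""
    if superpose:
        return kabsch_superpose(a, b, weights)[2]
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    n = a.shape[0]
    w = np.ones(n) if weights is None else np.asarray(weights, float)
    w = w / w.sum()
    diff = a - b
    return float(np.sqrt(np.sum(w * np.einsum("ij,ij->i", diff, diff))))


def rmsd_series(
    traj: Trajectory,
    reference_frame: int = 0,
    selection=None,
    weights=None,
    superpose: bool = True,
) -> np.ndarray:
    """Per-frame RMSD (nm) to a reference frame over an atom selection.

    With ``superpose`` (default) each frame is first rigidly aligned to the
    reference over the selection; without it, raw displacement RMSD is
    reported, which is the quantity with simple closed forms for planted
    perturbations.
    """
    if not (0 <= reference_frame < traj.n_frames):
        raise ValueError("reference frame out of range")
    idx = _resolve_selection(selection, traj.n_atoms)
    ref = traj.frames[reference_frame][idx]
    return np.array(
        [
            pair_rmsd(frame[idx], ref, weights=weights, superpose=superpose)
            for frame in traj.frames
        ]
    )


def radius_of_gyration(frame, masses) -> float:
    """Mass-weighted radius of gyration (nm) of a single frame."""
    X = np.atleast_2d(np.asarray(frame, float))
    m = np.atleast_1d(np.asarray(masses, float))
    if np.any(m <= 0):
        raise ValueError("masses must be positive")
    com = m @ X / m.sum()
    d2 = np.einsum("ij,ij->i", X - com, X - com)
    return float(np.sqrt(np.sum(m * d2) / m.sum()))


def rg_series(traj: Trajectory, selection=None) -> np.ndarray:
    idx = _resolve_selection(selection, traj.n_atoms)
    return np.array(
        [radius_of_gyration(f[idx], traj.masses[idx]) for f in traj.frames]
    )


def rmsf_per_atom(
    traj: Trajectory, selection=None, superpose: bool = True
) -> np.ndarray:
    """Per-atom RMSF (nm): fluctuation around the time-averaged position,
    optionally after superposing every frame onto frame 0 over the selection."""
    if traj.n_frames < 2:
        raise ValueError("RMSF requires at least 2 frames")
    idx = _resolve_selection(selection, traj.n_atoms)
    coords = traj.frames[:, idx, :]
    if superpose:
        ref = coords[0]
        aligned = np.empty_like(coords)
        for k, frame in enumerate(coords):
            R, t, _ = kabsch_superpose(frame, ref)
            aligned[k] = frame @ R.T + t
        coords = aligned
    mean = coords.mean(axis=0)
    d2 = np.einsum("tij,tij->ti", coords - mean, coords - mean)
    return np.sqrt(d2.mean(axis=0))


def rmsf_per_residue(traj: Trajectory, atom_rmsf: np.ndarray, selection=None):
    """Aggregate atomic RMSF to residues by unweighted mean; returns
    (residue_ids, values)."""
    idx = _resolve_selection(selection, traj.n_atoms)
    res = traj.residue_index[idx]
    ids = np.unique(res)
    vals = np.array([atom_rmsf[res == r].mean() for r in ids])
    return ids, vals


def pairwise_rmsd_matrix(
    traj: Trajectory, selection=None, superpose: bool = True
) -> np.ndarray:
    idx = _resolve_selection(selection, traj.n_atoms)
    F = traj.n_frames
    M = np.zeros((F, F))
    for i in range(F):
        for j in range(i + 1, F):
            M[i, j] = M[j, i] = pair_rmsd(
                traj.frames[i][idx], traj.frames[j][idx], superpose=superpose
            )
    return M


def gromos_cluster(
    traj: Trajectory, cutoff: float, selection=None, superpose: bool = True
) -> ClusterResult:
    """Neighbor-count clustering of frames at an RMSD cutoff (nm).

    Repeatedly takes the unassigned frame with the most unassigned neighbors
    within the cutoff (ties -> lowest frame index) as a cluster center and
    assigns its neighborhood to a new cluster.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    M = pairwise_rmsd_matrix(traj, selection=selection, superpose=superpose)
    F = traj.n_frames
    assignments = np.full(F, -1, dtype=int)
    representatives: dict[int, int] = {}
    unassigned = np.ones(F, dtype=bool)
    cluster_id = 0
    while unassigned.any():
        neigh = (M <= cutoff) & unassigned[None, :]
        counts = np.where(unassigned, neigh.sum(axis=1), -1)
        center = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = np.flatnonzero(neigh[center] & unassigned)
        assignments[members] = cluster_id
        representatives[cluster_id] = center
        unassigned[members] = False
        cluster_id += 1
    return ClusterResult(assignments=assignments, representatives=representatives, cutoff=cutoff)
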