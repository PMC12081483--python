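"""MMGBSA binding free-energy bookkeeping (three-trajectory scheme).

An end-point MMGBSA estimate decomposes the binding free energy of a
ligand-receptor complex into per-frame molecular-mechanics and implicit
solvation components,

    dG_bind ~ dE_MM + dG_sol,      (conformational entropy -TdS excluded)
    dE_MM   = dE_internal + dE_ele + dE_vdw,
    dG_sol  = dG_GB + dG_SA,

where every "d" term is mean(complex) - mean(receptor) - mean(ligand), each
mean taken over that system's own trajectory (three-trajectory approach, so
frame counts may differ between systems). Inputs are parsed per-frame
component tables, not raw MD logs; a minimal two-column ``step value`` log
converter is provided as a convenience.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

COMPONENTS = ["E_internal", "E_ele", "E_vdw", "G_GB", "G_SA"]
SYSTEM_LABELS = ("complex", "receptor", "ligand")


@dataclass(frozen=True)
class EnergyFrameTable:
    """Per-frame energy components (kcal/mol) of one system."""

    system_label: str
    frames: pd.DataFrame  # columns: frame + COMPONENTS

    def __post_init__(self) -> None:
        if self.system_label not in SYSTEM_LABELS:
            raise ValueError(
                f"system_label must be one of {SYSTEM_LABELS}, "
                f"got {self.system_label!r}"
            )
        missing = [c for c in ["frame", *COMPONENTS] if c not in self.frames.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        if len(self.frames) < 1:
            raise ValueError("at least one frame required")
        idx = self.frames["frame"].to_numpy()
        if not np.all(np.diff(idx) > 0):
            raise ValueError("frame indices must be strictly increasing")
        vals = self.frames[COMPONENTS].to_numpy(float)
        bad = ~np.isfinite(vals)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"non-finite {COMPONENTS[j]} at frame index "
                f"{int(self.frames['frame'].iloc[i])}"
            )

    @property
    def n_frames(self) -> int:
        return len(self.frames)


@dataclass(frozen=True)
class BindingEnergyResult:
    """Assembled MMGBSA result, kcal/mol.

    ``TdS`` is always 0.0 and carries a provenance note: the entropy term is
    excluded by construction, matching common MMGBSA practice.
    """

    delta_components: dict[str, float]
    delta_component_se: dict[str, float]
    dE_MM: float
    dG_sol: float
    dG_bind: float
    dG_bind_se: float
    TdS: float = 0.0
    entropy_note: str = "conformational entropy term excluded by construction"


def component_means(table: EnergyFrameTable) -> tuple[dict[str, float], dict[str, float]]:
    """Arithmetic mean and standard error (sd/sqrt(n), 0 for n=1) of each
    energy component over frames."""
    vals = table.frames[COMPONENTS]
    n = len(vals)
    means = vals.mean().to_dict()
    if n == 1:
        ses = {c: 0.0 for c in COMPONENTS}
    else:
        ses = (vals.std(ddof=1) / math.sqrt(n)).to_dict()
    return means, ses


def binding_free_energy(
    complex: EnergyFrameTable,
    receptor: EnergyFrameTable,
    ligand: EnergyFrameTable,
) -> BindingEnergyResult:
    """Assemble dG_bind from three independent trajectories.

    Negative dG_bind means favorable binding. The standard error of
    dG_bind combines the per-system standard errors of the per-frame
    component totals (systems and frames independent).
    """
    tables = {"complex": complex, "receptor": receptor, "ligand": ligand}
    for label, t in tables.items():
        if t.system_label != label:
            raise ValueError(
                f"expected a table labelled {label!r}, got {t.system_label!r}"
            )
    stats = {label: component_means(t) for label, t in tables.items()}
    delta = {}
    delta_se = {}
    for c in COMPONENTS:
        delta[c] = (
            stats["complex"][0][c] - stats["receptor"][0][c] - stats["ligand"][0][c]
        )
        delta_se[c] = math.sqrt(
            sum(stats[label][1][c] ** 2 for label in tables)
        )
    dE_MM = delta["E_internal"] + delta["E_ele"] + delta["E_vdw"]
    dG_sol = delta["G_GB"] + delta["G_SA"]
    var = 0.0
    for t in tables.values():
        total = t.frames[COMPONENTS].sum(axis=1)
        n = len(total)
        if n > 1:
            var += total.var(ddof=1) / n
    return BindingEnergyResult(
        delta_components=delta,
        delta_component_se=delta_se,
        dE_MM=dE_MM,
        dG_sol=dG_sol,
        dG_bind=dE_MM + dG_sol,
        dG_bind_se=math.sqrt(var),
    )


def rank_ligands(results: dict[str, BindingEnergyResult]) -> list[tuple[str, float]]:
    """Ligands ordered most-favorable (most negative dG_bind) first; ties
    broken lexicographically by id."""
    if not results:
        raise ValueError("no results to rank")
    return sorted(
        ((lid, r.dG_bind) for lid, r in results.items()),
        key=lambda t: (t[1], t[0]),
    )


def frames_from_step_logs(
    system_label: str, logs: dict[str, "pd.DataFrame | str"]
) -> EnergyFrameTable:
    """Convenience converter from per-component two-column ``step value``
    logs (one log per component, whitespace-separated, ``#`` comments) to an
    :class:`EnergyFrameTable`. Steps must agree across components."""
    series = {}
    steps = None
    for comp in COMPONENTS:
        if comp not in logs:
            raise ValueError(f"missing log for component {comp}")
        src = logs[comp]
        if isinstance(src, pd.DataFrame):
            df = src
        else:
            df = pd.read_csv(
                src, sep=r"\s+", comment="#", header=None, names=["step", "value"]
            )
        if steps is None:
            steps = df["step"].to_numpy()
        elif not np.array_equal(steps, df["step"].to_numpy()):
            raise ValueError(f"step column of {comp} log disagrees with others")
        series[comp] = df["value"].to_numpy(float)
    out = pd.DataFrame({"frame": steps, **series})
    return EnergyFrameTable(system_label, out)
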