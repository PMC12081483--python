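"""Promolecular noncovalent-interaction (NCI) analysis.

The promolecular electron density is a sum of unrelaxed spherical free-atom
densities, each modelled as a short sum of exponentials

    rho_atom(r) = sum_k c_k * exp(-alpha_k * r)        (atomic units)

which makes the molecular density, its gradient and its Hessian analytic.
Noncovalent contacts show up as regions of low density where the reduced
density gradient

    s = |grad rho| / (2 (3 pi^2)^(1/3) rho^(4/3))

drops toward zero; the sign of the middle Hessian eigenvalue lambda_2
separates attractive (lambda_2 < 0), van der Waals (lambda_2 ~ 0) and
repulsive (lambda_2 > 0) contacts via the signed density sign(lambda_2)*rho.

All lengths are bohr and densities atomic units; converters live at the I/O
boundary (`flavodesc.io`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_RDG_CONST = 2.0 * (3.0 * np.pi**2) ** (1.0 / 3.0)
_R_CLAMP = 1e-6  # bohr; density is evaluated no closer to a nucleus

# Exponential free-atom density fits in the promolecular style used for NCI
# analysis: rho(r) = sum c_k exp(-r/z_k), r in bohr, rho in a.u.  The first
# term captures the core (decay length ~ 1/(2Z)), the later terms the
# valence shell. Fits cover the elements of the flavanol metabolite systems.
_PROMOLECULAR = {
    #          (c_k, z_k) pairs
    "H": ((0.2815, 0.5288),),
    "C": ((120.2, 0.0884), (1.172, 0.5480)),
    "N": ((190.9, 0.0767), (2.247, 0.4532)),
    "O": ((289.5, 0.0669), (2.879, 0.3974)),
    "S": ((2501.0, 0.0335), (158.0, 0.2461), (2.170, 0.6358)),
}


@dataclass(frozen=True)
class AtomicDensityParams:
    """Exponential shells (c_k, alpha_k) of one element's free-atom density."""

    element: str
    shells: tuple[tuple[float, float], ...]  # (coefficient, exponent 1/bohr)

    def __post_init__(self) -> None:
        for c, a in self.shells:
            if c <= 0 or a <= 0:
                raise ValueError("shell coefficients and exponents must be positive")


def density_params(element: str) -> AtomicDensityParams:
    try:
        shells = _PROMOLECULAR[element]
    except KeyError:
        raise KeyError(
            f"no promolecular density parameters for element {element!r}"
        ) from None
    return AtomicDensityParams(
        element, tuple((c, 1.0 / z) for c, z in shells)
    )


@dataclass(frozen=True)
class NciGrid:
    """Regular 3D grid of rho, sign(lambda2)*rho and RDG (atomic units)."""

    origin: np.ndarray  # (3,), bohr
    spacing: np.ndarray  # (3,), bohr
    dims: tuple[int, int, int]
    rho: np.ndarray  # dims
    signed_density: np.ndarray  # dims
    rdg: np.ndarray  # dims
    atoms: tuple = ()  # (element, position-bohr) records, kept for cube export

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.dims))


def _accumulate(points: np.ndarray, atoms) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """rho, gradient and Hessian of the promolecular density at ``points``
    ((M,3), bohr). Vectorized over points; loops over atoms and shells."""
    M = points.shape[0]
    rho = np.zeros(M)
    grad = np.zeros((M, 3))
    hess = np.zeros((M, 3, 3))
    eye = np.eye(3)
    for element, pos in atoms:
        params = density_params(element)
        dvec = points - np.asarray(pos, float)
        r = np.sqrt(np.einsum("ij,ij->i", dvec, dvec))
        r = np.maximum(r, _R_CLAMP)
        rhat = dvec / r[:, None]
        for c, a in params.shells:
            f = c * np.exp(-a * r)
            fp = -a * f  # df/dr
            fpp = a * a * f  # d2f/dr2
            rho += f
            grad += fp[:, None] * rhat
            outer = np.einsum("ij,ik->ijk", rhat, rhat)
            hess += (
                fpp[:, None, None] * outer
                + (fp / r)[:, None, None] * (eye[None, :, :] - outer)
            )
    return rho, grad, hess


def promolecular_density(point, atoms):
    """Density, gradient and Hessian at one point (bohr, a.u.).

    ``atoms`` is a sequence of ``(element, position)`` pairs. Distances are
    clamped to 1e-6 bohr so points coinciding with a nucleus stay finite.
    """
    if not atoms:
        raise ValueError("at least one atom required")
    pts = np.asarray(point, float).reshape(1, 3)
    rho, grad, hess = _accumulate(pts, atoms)
    return float(rho[0]), grad[0], hess[0]


def reduced_density_gradient(rho, gradient):
    """s = |grad rho| / (2 (3 pi^2)^(1/3) rho^(4/3)); rho must be positive."""
    rho_arr = np.asarray(rho, float)
    if np.any(rho_arr <= 0):
        raise ValueError("rho must be positive")
    g = np.asarray(gradient, float)
    gnorm = np.sqrt(np.einsum("...i,...i->...", g, g))
    s = gnorm / (_RDG_CONST * rho_arr ** (4.0 / 3.0))
    return s if s.ndim else float(s)


def sign_lambda2_rho(rho, hessian):
    """sign(lambda2) * rho from a symmetric 3x3 density Hessian."""
    H = np.asarray(hessian, float)
    if H.shape[-2:] != (3, 3):
        raise ValueError("hessian must be 3x3 (or a stack of 3x3)")
    asym = np.abs(H - np.swapaxes(H, -1, -2)).max()
    scale = max(np.abs(H).max(), 1e-300)
    if asym > 1e-8 * scale:
        raise ValueError("hessian is not symmetric within tolerance")
    lam = np.linalg.eigvalsh(0.5 * (H + np.swapaxes(H, -1, -2)))
    lam2 = lam[..., 1]
    out = np.sign(lam2) * np.asarray(rho, float)
    return out if out.ndim else float(out)


def scan_grid(
    atoms,
    spacing: float = 0.2,
    margin: float = 4.0,
    box=None,
    max_voxels: int = 4_000_000,
) -> NciGrid:
    """Evaluate rho, sign(lambda2)*rho and RDG on a regular grid (bohr).

    The box defaults to the atom bounding box plus ``margin`` on every side;
    ``dims = floor(extent/spacing) + 1`` per axis. Grids above ``max_voxels``
    are rejected with the budget that would be required.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    atoms = [(el, np.asarray(pos, float)) for el, pos in atoms]
    if not atoms:
        raise ValueError("at least one atom required")
    positions = np.array([pos for _, pos in atoms])
    if box is None:
        lo = positions.min(axis=0) - margin
        hi = positions.max(axis=0) + margin
    else:
        lo, hi = (np.asarray(b, float) for b in box)
        if np.any(positions < lo) or np.any(positions > hi):
            raise ValueError("box must enclose all atoms")
    dims = tuple(int(np.floor((hi[k] - lo[k]) / spacing)) + 1 for k in range(3))
    n_vox = int(np.prod(dims))
    if n_vox > max_voxels:
        raise ValueError(
            f"grid of {n_vox} voxels exceeds the budget of {max_voxels}; "
            f"raise max_voxels to at least {n_vox} or coarsen the spacing"
        )
    axes = [lo[k] + spacing * np.arange(dims[k]) for k in range(3)]
    mesh = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    rho, grad, hess = _accumulate(mesh, atoms)
    rdg = reduced_density_gradient(rho, grad)
    signed = sign_lambda2_rho(rho, hess)
    return NciGrid(
        origin=np.asarray(lo, float),
        spacing=np.full(3, float(spacing)),
        dims=dims,
        rho=rho.reshape(dims),
        signed_density=np.asarray(signed).reshape(dims),
        rdg=np.asarray(rdg).reshape(dims),
        atoms=tuple((el, pos) for el, pos in atoms),
    )


def classify_voxels(
    grid: NciGrid,
    density_window: float = 0.05,
    rdg_threshold: float = 0.5,
    eps_vdw: float = 0.005,
):
    """Partition low-RDG, low-density voxels into attractive / van der Waals
    / repulsive classes by the signed density.

    Returns ``(counts, masks)``; counts sum to the selected-voxel total.
    An empty selection yields empty masks, not an error.
    """
    if density_window <= 0 or rdg_threshold <= 0 or eps_vdw <= 0:
        raise ValueError("thresholds must be positive")
    selected = (grid.rdg < rdg_threshold) & (np.abs(grid.signed_density) <= density_window)
    masks = {
        "attractive": selected & (grid.signed_density < -eps_vdw),
        "repulsive": selected & (grid.signed_density > eps_vdw),
    }
    masks["vanderwaals"] = selected & ~masks["attractive"] & ~masks["repulsive"]
    counts = {k: int(m.sum()) for k, m in masks.items()}
    counts["selected"] = int(selected.sum())
    return counts, masks
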