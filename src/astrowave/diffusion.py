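"""2D extracellular ATP field: FTCS reaction–diffusion plus point sources.

The field A(x, t) obeys ∂A/∂t = D ∇²A − α A + Σ_i δ(x − x_i) j_ATP,i and is
discretized on a regular square grid (default spacing 2 μm) with zero-flux
(Neumann) boundaries, advanced by an explicit forward-time centered-space
(FTCS) step.  Cells are point sources *and* point sensors: release from a
cell is split over the four grid nodes enclosing it with bilinear
(cloud-in-cell) weights, and the local concentration a cell senses is the
bilinear interpolation with the same weights (so deposit and sample are
adjoint).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ModelParams

__all__ = [
    "ATPField",
    "NetworkGeometry",
    "make_field_for_positions",
    "build_weights",
    "deposit",
    "sample",
    "ftcs_step",
    "ftcs_stable_dt",
]


@dataclass
class ATPField:
    """Scalar concentration field on an (ny, nx) grid.

    ``values[j, i]`` is the concentration (μM) at physical position
    ``origin + spacing * (i, j)``.
    """

    values: np.ndarray   # (ny, nx), μM
    spacing: float       # μm
    origin: np.ndarray   # (2,), μm, position of node (0, 0)
    boundary: str = "no-flux"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.spacing <= 0:
            raise ValueError("grid spacing must be > 0")
        if self.boundary != "no-flux":
            raise ValueError(f"unsupported boundary rule {self.boundary!r}")

    @property
    def shape(self):
        return self.values.shape

    def copy(self) -> "ATPField":
        return ATPField(self.values.copy(), self.spacing, self.origin.copy(),
                        self.boundary)

    def total_mass(self) -> float:
        """Total ATP mass in concentration·area units (μM·μm²)."""
        return float(self.values.sum()) * self.spacing ** 2


@dataclass
class NetworkGeometry:
    """Per-cell deposition/sampling stencils on a grid.

    ``node_index[c, k]`` are the flat indices of the four grid nodes
    enclosing cell c and ``weights[c, k]`` the bilinear weights (each row
    sums to 1).
    """

    positions: np.ndarray    # (N, 2), μm
    node_index: np.ndarray   # (N, 4), int, flat indices into values.ravel()
    weights: np.ndarray      # (N, 4), nonnegative, rows sum to 1
    grid_shape: tuple        # (ny, nx)


def make_field_for_positions(positions: np.ndarray, spacing: float = 2.0,
                             pad: float = 50.0) -> ATPField:
    """Empty field covering the bounding box of ``positions`` plus ``pad``
    μm of margin on every side (waves terminate by degradation well before
    the boundary matters, but the margin keeps cells off the edge)."""
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    lo = positions.min(axis=0) - pad
    hi = positions.max(axis=0) + pad
    nx = int(np.ceil((hi[0] - lo[0]) / spacing)) + 1
    ny = int(np.ceil((hi[1] - lo[1]) / spacing)) + 1
    return ATPField(np.zeros((ny, nx)), spacing, lo)


def build_weights(positions: np.ndarray, field: ATPField) -> NetworkGeometry:
    """Bilinear (cloud-in-cell) stencil of each cell over its four
    enclosing grid nodes.

    Raises ``ValueError`` if any cell lies outside the grid interior or
    within half a spacing of the boundary.
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    ny, nx = field.shape
    rel = (positions - field.origin) / field.spacing
    margin = 0.5
    ok = (
        (rel[:, 0] >= margin) & (rel[:, 0] <= nx - 1 - margin)
        & (rel[:, 1] >= margin) & (rel[:, 1] <= ny - 1 - margin)
    )
    if not np.all(ok):
        bad = np.flatnonzero(~ok)
        raise ValueError(
            f"cells {bad.tolist()} lie outside the grid interior "
            "(or within half a spacing of the boundary)"
        )
    i0 = np.minimum(np.floor(rel[:, 0]).astype(np.int64), nx - 2)
    j0 = np.minimum(np.floor(rel[:, 1]).astype(np.int64), ny - 2)
    u = rel[:, 0] - i0
    v = rel[:, 1] - j0
    # corners ordered (i0,j0), (i0+1,j0), (i0,j0+1), (i0+1,j0+1)
    w = np.stack([(1 - u) * (1 - v), u * (1 - v), (1 - u) * v, u * v], axis=1)
    idx = np.stack(
        [j0 * nx + i0, j0 * nx + i0 + 1, (j0 + 1) * nx + i0,
         (j0 + 1) * nx + i0 + 1],
        axis=1,
    )
    return NetworkGeometry(positions, idx, w, (ny, nx))


def deposit(field: ATPField, geom: NetworkGeometry,
            per_cell_amount: np.ndarray) -> None:
    """Scatter-add per-cell concentration increments onto the grid.

    ``per_cell_amount`` is the concentration added to a single grid cell
    (μM); it is split over the four stencil nodes by the bilinear weights,
    conserving the injected total.  Modifies ``field`` in place.
    """
    amounts = np.broadcast_to(
        np.asarray(per_cell_amount, dtype=float), (geom.weights.shape[0],)
    )
    np.add.at(field.values.ravel(), geom.node_index.ravel(),
              (geom.weights * amounts[:, None]).ravel())


def sample(field: ATPField, geom: NetworkGeometry) -> np.ndarray:
    """Bilinear interpolation of the field at each cell position (μM)."""
    flat = field.values.ravel()
    return (flat[geom.node_index] * geom.weights).sum(axis=1)


def ftcs_stable_dt(spacing: float, D: float) -> float:
    """Largest stable FTCS time step, spacing²/(4D), for 2D diffusion."""
    return spacing ** 2 / (4.0 * D)


def ftcs_step(field: ATPField, dt: float, p: ModelParams) -> None:
    """One explicit FTCS update with first-order decay, in place.

    Zero-flux boundaries are realized by mirroring the edge values in the
    5-point Laplacian.  Raises ``ValueError`` if ``dt`` violates the
    stability bound dt ≤ spacing²/(4D).
    """
    if dt > ftcs_stable_dt(field.spacing, p.D) * (1 + 1e-12):
        raise ValueError(
            f"dt={dt} violates FTCS stability bound "
            f"{ftcs_stable_dt(field.spacing, p.D):.6g} s"
        )
    A = field.values
    padded = np.pad(A, 1, mode="edge")
    lap = (
        padded[:-2, 1:-1] + padded[2:, 1:-1]
        + padded[1:-1, :-2] + padded[1:-1, 2:]
        - 4.0 * A
    ) / field.spacing ** 2
    A += dt * (p.D * lap - p.alpha * A)
    np.maximum(A, 0.0, out=A)
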