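"""Cell fields: coordinate-table I/O and random hard-core placement.

Network simulations run either on measured cell coordinates (two-column
delimited text, μm) or on random fields generated by dart throwing with a
minimum inter-cell distance, matching the density and spacing statistics
of cultured astrocyte networks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CellField", "load_positions", "save_positions", "random_field"]


@dataclass
class CellField:
    positions: np.ndarray          # (N, 2), μm
    extent: tuple | None = None    # ((xmin, xmax), (ymin, ymax)), μm
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if self.positions.shape[1] != 2:
            raise ValueError("positions must be an (N, 2) array")

    @property
    def n(self) -> int:
        return self.positions.shape[0]

    def min_pair_distance(self) -> float:
        from scipy.spatial.distance import pdist

        if self.n < 2:
            return np.inf
        return float(pdist(self.positions).min())

    def nearest_neighbor_distances(self) -> np.ndarray:
        from scipy.spatial import cKDTree

        d, _ = cKDTree(self.positions).query(self.positions, k=2)
        return d[:, 1]


def load_positions(path) -> CellField:
    """Read a two-column delimited coordinate table (x μm, y μm).

    Accepts comma or whitespace delimiters and an optional single header
    line.  Raises ``ValueError`` with the offending line number on parse
    errors, duplicated positions, or an empty file.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.split("#", 1)[0].strip()
            if not text:
                continue
            parts = text.replace(",", " ").split()
            try:
                vals = [float(x) for x in parts]
            except ValueError:
                if lineno == 1 and not rows:
                    continue  # header line
                raise ValueError(f"{path}: cannot parse line {lineno}: {line!r}")
            if len(vals) != 2:
                raise ValueError(
                    f"{path}: line {lineno}: expected 2 columns, got {len(vals)}"
                )
            rows.append((lineno, vals))
    if not rows:
        raise ValueError(f"{path}: no coordinate rows found")
    pos = np.array([v for _, v in rows], dtype=float)
    _, first = np.unique(pos, axis=0, return_index=True)
    if len(first) != len(pos):
        dup = sorted(set(range(len(pos))) - set(first))
        lines = [rows[i][0] for i in dup]
        raise ValueError(f"{path}: duplicated position(s) at line(s) {lines}")
    return CellField(pos, provenance={"source": "file", "path": str(path)})


def save_positions(path, cells: CellField) -> None:
    np.savetxt(path, cells.positions, fmt="%.6f", delimiter="\t",
               header="x_um\ty_um")


def random_field(n: int, extent=(400.0, 400.0), min_dist: float = 20.0,
                 seed=None, max_attempts: int = 100_000) -> CellField:
    """Dart-throwing placement of ``n`` cells with a hard-core constraint.

    Candidate positions are drawn uniformly over ``extent`` (μm) and
    rejected if closer than ``min_dist`` to an accepted cell.  The default
    density (100 cells in 400×400 μm, min_dist 20 μm) is a fixture choice
    typical of sparse dissociated cultures.
    """
    rng = np.random.default_rng(seed)
    ex, ey = float(extent[0]), float(extent[1])
    accepted = np.empty((n, 2))
    count = 0
    attempts = 0
    md2 = min_dist * min_dist
    while count < n:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"placed only {count}/{n} cells after {max_attempts} attempts; "
                "density too high for the requested min_dist"
            )
        cand = rng.uniform((0.0, 0.0), (ex, ey))
        attempts += 1
        if count:
            d2 = np.sum((accepted[:count] - cand) ** 2, axis=1)
            if d2.min() < md2:
                continue
        accepted[count] = cand
        count += 1
    return CellField(
        accepted,
        extent=((0.0, ex), (0.0, ey)),
        provenance={
            "source": "random",
            "seed": seed,
            "n": n,
            "extent": (ex, ey),
            "min_dist": min_dist,
        },
    )
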