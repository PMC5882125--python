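"""Periodic cell lattices with explicit apoplast (interface) compartments.

Cells live on a 1D ring or a 2D hexagonal torus. Every cell-cell interface
carries one apoplast compartment, indexed by an undirected edge id. Directed
quantities (PIN1 densities) are addressed by (cell, neighbor-slot), so each
undirected edge is flanked by two directed slots.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = ["Lattice", "LatticeError", "build_ring", "build_hex_torus"]


class LatticeError(ValueError):
    """Raised for degenerate lattice requests (e.g. a ring of fewer than 3 cells)."""


@dataclass(frozen=True)
class Lattice:
    """Adjacency structure of a periodic cell sheet.

    Attributes
    ----------
    n_cells : int
        Number of cells.
    K : int
        Neighbors per cell (2 for a ring, 6 for a hex torus).
    neighbors : (n_cells, K) int array
        ``neighbors[i, s]`` is the cell id of cell ``i``'s ``s``-th neighbor.
    reverse_slot : (n_cells, K) int array
        Slot of ``i`` in ``neighbors[j]`` where ``j = neighbors[i, s]``.
    edge_cells : (n_edges, 2) int array
        The two cells flanking each undirected edge.
    edge_slots : (n_edges, 2) int array
        ``edge_slots[e, 0]`` is the slot in cell ``edge_cells[e, 0]`` that
        points across edge ``e`` (likewise for index 1).
    edge_at : (n_cells, K) int array
        Edge id of the interface between cell ``i`` and ``neighbors[i, s]``.
    edge_neighbors : (n_edges, 2) int array or None
        Adjacent apoplast compartments; defined for 1D rings only, where the
        edge graph is itself a ring.
    kind : str
        ``"ring"`` or ``"hex_torus"``.
    """

    n_cells: int
    K: int
    neighbors: np.ndarray
    reverse_slot: np.ndarray
    edge_cells: np.ndarray
    edge_slots: np.ndarray
    edge_at: np.ndarray
    kind: str
    edge_neighbors: np.ndarray | None = None
    shape: tuple[int, ...] = field(default=())

    @property
    def n_edges(self) -> int:
        return self.edge_cells.shape[0]

    def edge_of(self, i: int, j: int) -> int:
        """Undirected edge id of the interface between adjacent cells i and j."""
        slots = np.nonzero(self.neighbors[i] == j)[0]
        if slots.size == 0:
            raise LatticeError(f"cells {i} and {j} are not adjacent")
        return int(self.edge_at[i, slots[0]])

    def to_json(self) -> str:
        """Serialize cells, neighbor lists and edge list (debugging/fixtures)."""
        return json.dumps(
            {
                "kind": self.kind,
                "n_cells": self.n_cells,
                "K": self.K,
                "shape": list(self.shape),
                "neighbors": self.neighbors.tolist(),
                "edges": self.edge_cells.tolist(),
            }
        )


def _finish(neighbors: np.ndarray, kind: str, shape: tuple[int, ...],
            edge_neighbors: np.ndarray | None = None) -> Lattice:
    """Derive edge indexing and reverse slots from a neighbor table."""
    n_cells, K = neighbors.shape
    reverse_slot = np.empty((n_cells, K), dtype=np.intp)
    for i in range(n_cells):
        for s in range(K):
            j = neighbors[i, s]
            back = np.nonzero(neighbors[j] == i)[0]
            if back.size != 1:
                raise LatticeError(
                    f"adjacency not symmetric/simple at cells ({i}, {j})"
                )
            reverse_slot[i, s] = back[0]

    edge_ids: dict[tuple[int, int], int] = {}
    edge_cells: list[tuple[int, int]] = []
    edge_slots: list[tuple[int, int]] = []
    edge_at = np.empty((n_cells, K), dtype=np.intp)
    for i in range(n_cells):
        for s in range(K):
            j = int(neighbors[i, s])
            key = (min(i, j), max(i, j))
            if key not in edge_ids:
                edge_ids[key] = len(edge_cells)
                edge_cells.append((i, j))
                edge_slots.append((s, int(reverse_slot[i, s])))
            edge_at[i, s] = edge_ids[key]

    lat = Lattice(
        n_cells=n_cells,
        K=K,
        neighbors=neighbors,
        reverse_slot=reverse_slot,
        edge_cells=np.asarray(edge_cells, dtype=np.intp),
        edge_slots=np.asarray(edge_slots, dtype=np.intp),
        edge_at=edge_at,
        kind=kind,
        edge_neighbors=edge_neighbors,
        shape=shape,
    )
    if lat.n_edges * 2 != n_cells * K:
        raise LatticeError("edge multiplicity degenerate (doubled edges)")
    return lat


def build_ring(N: int) -> Lattice:
    """Periodic 1D array of ``N`` cells (K = 2, N interfaces).

    Cell ``i`` neighbors ``i-1`` (slot 0) and ``i+1`` (slot 1), mod N; the
    interface between cells ``i`` and ``i+1`` gets edge id ``i``, so the
    apoplast compartments form a ring of their own with neighbors
    ``(e-1, e+1) mod N``.
    """
    if N < 3:
        raise LatticeError(f"ring needs N >= 3 cells, got {N}")
    idx = np.arange(N)
    neighbors = np.stack([(idx - 1) % N, (idx + 1) % N], axis=1)
    edge_neighbors = np.stack([(idx - 1) % N, (idx + 1) % N], axis=1)
    lat = _finish(neighbors, "ring", (N,), edge_neighbors=edge_neighbors)
    # _finish assigns edge ids in discovery order: cell 0 slot 0 is edge (0, N-1),
    # so renumber such that edge i == interface (i, i+1), the documented contract.
    perm = np.empty(N, dtype=np.intp)
    for i in range(N):
        perm[lat.edge_at[i, 1]] = i
    edge_at = perm[lat.edge_at]
    order = np.argsort(perm)
    return Lattice(
        n_cells=N,
        K=2,
        neighbors=lat.neighbors,
        reverse_slot=lat.reverse_slot,
        edge_cells=lat.edge_cells[order],
        edge_slots=lat.edge_slots[order],
        edge_at=edge_at,
        kind="ring",
        edge_neighbors=edge_neighbors,
        shape=(N,),
    )


def build_hex_torus(nx: int, ny: int) -> Lattice:
    """Rhombic hexagonal sheet of nx*ny cells with periodic wrapping (K = 6).

    Axial coordinates: cell (u, v) has id v*nx + u and neighbors
    (u±1, v), (u, v±1), (u+1, v-1), (u-1, v+1), all modulo (nx, ny).
    """
    if nx < 3 or ny < 3:
        raise LatticeError(f"hex torus needs nx, ny >= 3, got ({nx}, {ny})")
    offs = [(1, 0), (-1, 0), (0, 1), (0, -1), (1, -1), (-1, 1)]
    neighbors = np.empty((nx * ny, 6), dtype=np.intp)
    for v in range(ny):
        for u in range(nx):
            i = v * nx + u
            for s, (du, dv) in enumerate(offs):
                neighbors[i, s] = ((v + dv) % ny) * nx + (u + du) % nx
    for i in range(nx * ny):
        if len(set(neighbors[i].tolist())) != 6:
            raise LatticeError("hex wrap collision: neighbors not distinct")
    return _finish(neighbors, "hex_torus", (nx, ny))
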