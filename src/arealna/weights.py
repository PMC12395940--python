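"""Binary contiguity weights for areal units.

Builds, validates, and transforms the symmetric 0/1 adjacency matrix W used
by Moran's I, the ICAR prior, and the neighborhood smoother.  Supports
construction from edge lists, polygon geometries (rook/queen), GAL files,
and GeoJSON feature collections.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

__all__ = [
    "ContiguityMatrix",
    "from_edge_list",
    "from_polygons",
    "read_gal",
    "read_geojson",
]


@dataclass(frozen=True)
class ContiguityMatrix:
    """Symmetric binary adjacency over ``n`` areal units.

    Attributes
    ----------
    unit_ids
        Ordered unit labels; row/column ``i`` of ``W`` corresponds to
        ``unit_ids[i]``.
    W
        Sparse CSR 0/1 matrix, symmetric with zero diagonal.
    """

    unit_ids: tuple[str, ...]
    W: sp.csr_matrix = field(repr=False)

    def __post_init__(self) -> None:
        W = self.W
        if W.shape[0] != W.shape[1] or W.shape[0] != len(self.unit_ids):
            raise ValueError("W shape inconsistent with unit_ids")
        if W.diagonal().any():
            raise ValueError("adjacency matrix has nonzero diagonal")
        if (W != W.T).nnz != 0:
            raise ValueError("adjacency matrix is not symmetric")
        data = W.data
        if data.size and not np.all((data == 0) | (data == 1)):
            raise ValueError("adjacency weights must be 0/1")

    # -- basic views -------------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.unit_ids)

    @property
    def degrees(self) -> np.ndarray:
        """Neighbor count per unit."""
        return np.asarray(self.W.sum(axis=1)).ravel()

    @property
    def s0(self) -> float:
        """Sum of all weights (twice the undirected edge count)."""
        return float(self.W.sum())

    @property
    def n_edges(self) -> int:
        return int(self.s0 // 2)

    @property
    def islands(self) -> np.ndarray:
        """Indices of units with no neighbors."""
        return np.flatnonzero(self.degrees == 0)

    def edge_array(self) -> np.ndarray:
        """Undirected edges as an (m, 2) index array with i < j."""
        coo = sp.triu(self.W, k=1).tocoo()
        out = np.column_stack([coo.row, coo.col])
        order = np.lexsort((out[:, 1], out[:, 0]))
        return out[order]

    def to_edge_list(self) -> list[tuple[str, str]]:
        """Canonicalized (sorted) list of unit-id pairs."""
        return [
            (self.unit_ids[i], self.unit_ids[j]) for i, j in self.edge_array()
        ]

    # -- transforms --------------------------------------------------------

    def row_standardized(self) -> sp.csr_matrix:
        """Row-stochastic view; island rows are all zero."""
        d = self.degrees.astype(float)
        inv = np.divide(1.0, d, out=np.zeros_like(d), where=d > 0)
        return sp.diags(inv) @ self.W

    def components(self) -> np.ndarray:
        """Connected-component label per unit (0-based)."""
        _, labels = connected_components(self.W, directed=False)
        return labels

    @property
    def n_components(self) -> int:
        return int(self.components().max()) + 1 if self.n else 0

    @property
    def is_connected(self) -> bool:
        return self.n_components <= 1

    def dense(self) -> np.ndarray:
        return self.W.toarray()

    def subset(self, indices: Sequence[int]) -> "ContiguityMatrix":
        """Induced subgraph on the given unit indices (order preserved)."""
        idx = np.asarray(indices, dtype=int)
        return ContiguityMatrix(
            tuple(self.unit_ids[i] for i in idx),
            self.W[idx][:, idx].tocsr(),
        )

    # -- I/O ---------------------------------------------------------------

    def write_gal(self, path: str | Path) -> None:
        """Write GAL contiguity format (header line then id/degree blocks)."""
        lines = [f"{self.n}"]
        Wlil = self.W.tolil()
        for i, uid in enumerate(self.unit_ids):
            nbrs = Wlil.rows[i]
            lines.append(f"{uid} {len(nbrs)}")
            lines.append(" ".join(self.unit_ids[j] for j in nbrs))
        Path(path).write_text("\n".join(lines) + "\n")

    def write_edge_csv(self, path: str | Path) -> None:
        lines = ["from_id,to_id"]
        lines += [f"{a},{b}" for a, b in self.to_edge_list()]
        Path(path).write_text("\n".join(lines) + "\n")


def _build(unit_ids: Sequence[str], edges: set[tuple[int, int]]) -> ContiguityMatrix:
    n = len(unit_ids)
    if edges:
        idx = np.array(sorted(edges))
        rows = np.concatenate([idx[:, 0], idx[:, 1]])
        cols = np.concatenate([idx[:, 1], idx[:, 0]])
        data = np.ones(rows.size)
        W = sp.csr_matrix((data, (rows, cols)), shape=(n, n))
    else:
        W = sp.csr_matrix((n, n))
    return ContiguityMatrix(tuple(str(u) for u in unit_ids), W)


def from_edge_list(
    pairs: Iterable[tuple[str, str]], unit_ids: Sequence[str]
) -> ContiguityMatrix:
    """Build weights from unordered unit-id pairs.

    Applies symmetric closure, collapses duplicates, and rejects
    self-loops and unknown ids.  Units absent from ``pairs`` become
    islands (degree 0).
    """
    unit_ids = [str(u) for u in unit_ids]
    if len(set(unit_ids)) != len(unit_ids):
        raise ValueError("duplicate unit ids")
    pos = {u: i for i, u in enumerate(unit_ids)}
    edges: set[tuple[int, int]] = set()
    for a, b in pairs:
        a, b = str(a), str(b)
        for u in (a, b):
            if u not in pos:
                raise KeyError(f"unknown unit id {u!r} in edge list")
        if a == b:
            raise ValueError(f"self-loop on unit {a!r}")
        i, j = pos[a], pos[b]
        edges.add((min(i, j), max(i, j)))
    return _build(unit_ids, edges)


def from_polygons(
    geometries: Sequence,
    unit_ids: Sequence[str],
    rule: str = "queen",
) -> ContiguityMatrix:
    """Contiguity from shapely polygons.

    rook
        neighbors share a boundary of positive length (1-D intersection).
    queen
        a shared point suffices.
    """
    from shapely.geometry.base import BaseGeometry
    from shapely.strtree import STRtree

    if rule not in ("queen", "rook"):
        raise ValueError(f"rule must be 'queen' or 'rook', got {rule!r}")
    if len(geometries) != len(unit_ids):
        raise ValueError("geometries and unit_ids differ in length")
    for uid, g in zip(unit_ids, geometries):
        if not isinstance(g, BaseGeometry) or g.is_empty or not g.is_valid:
            raise ValueError(f"invalid geometry for unit {uid!r}")

    tree = STRtree(list(geometries))
    edges: set[tuple[int, int]] = set()
    for i, g in enumerate(geometries):
        for j in tree.query(g):
            j = int(j)
            if j <= i:
                continue
            inter = g.intersection(geometries[j])
            if inter.is_empty:
                continue
            if rule == "queen" or inter.length > 0:
                edges.add((i, j))
    return _build(list(unit_ids), edges)


def read_gal(path: str | Path) -> ContiguityMatrix:
    """Read a GAL file written by :meth:`ContiguityMatrix.write_gal`."""
    tokens_by_line = [
        ln.split() for ln in Path(path).read_text().splitlines() if ln.strip()
    ]
    header = tokens_by_line[0]
    n = int(header[-1]) if len(header) > 1 else int(header[0])
    unit_ids: list[str] = []
    nbrs: dict[str, list[str]] = {}
    k = 1
    while k < len(tokens_by_line):
        uid, deg = tokens_by_line[k][0], int(tokens_by_line[k][1])
        if deg > 0:
            nbrs[uid] = tokens_by_line[k + 1]
            k += 2
        else:
            nbrs[uid] = []
            # degree-0 blocks may or may not carry an (empty) neighbor line
            k += 1
        unit_ids.append(uid)
    if len(unit_ids) != n:
        raise ValueError(f"GAL header says {n} units, found {len(unit_ids)}")
    pairs = [(u, v) for u, vs in nbrs.items() for v in vs]
    return from_edge_list(pairs, unit_ids)


def read_geojson(
    path: str | Path, id_property: str = "id", rule: str = "queen"
) -> ContiguityMatrix:
    """Contiguity from a GeoJSON FeatureCollection of polygons."""
    from shapely.geometry import shape

    obj = json.loads(Path(path).read_text())
    feats = obj["features"]
    unit_ids = [str(f["properties"][id_property]) for f in feats]
    geoms = [shape(f["geometry"]) for f in feats]
    return from_polygons(geoms, unit_ids, rule=rule)
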