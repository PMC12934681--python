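"""Radius-threshold spatial-contact graph over cell centroids.

Two cells are in spatial contact when their centroid Euclidean distance is
at most the contact radius (default 40 um) *and* they share the graph's
scope unit — the same FOV under ``per_fov`` (the default, matching local
coordinate frames), or the same sample under ``per_sample`` (requires a
global frame or FOV offsets).  The boundary is inclusive: distance exactly
equal to the radius counts as contact.  Construction uses a KD-tree per
scope unit but is defined — and tested — to equal all-pairs distance
thresholding exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .io_model import CellTable, ConfigurationError, VocabularyError

logger = logging.getLogger("spatialcoloc")

DEFAULT_RADIUS_UM = 40.0


@dataclass
class NeighborGraph:
    """Undirected spatial-contact graph (no self-edges, symmetric)."""

    radius_um: float
    scope: str  # per_fov | per_sample
    n_cells: int
    edge_i: np.ndarray  # edge endpoints as cell row indices, edge_i < edge_j
    edge_j: np.ndarray
    distance_um: np.ndarray
    group_codes: np.ndarray  # scope-unit code per cell
    group_ids: np.ndarray    # code -> scope-unit name
    cell_ids: np.ndarray

    @property
    def n_edges(self) -> int:
        return len(self.edge_i)

    @property
    def degree(self) -> np.ndarray:
        d = np.bincount(self.edge_i, minlength=self.n_cells)
        d += np.bincount(self.edge_j, minlength=self.n_cells)
        return d

    def adjacency(self):
        """Binary symmetric adjacency as sparse CSR."""
        import scipy.sparse as sp
        ones = np.ones(2 * self.n_edges, dtype=np.int8)
        rows = np.concatenate([self.edge_i, self.edge_j])
        cols = np.concatenate([self.edge_j, self.edge_i])
        return sp.csr_matrix((ones, (rows, cols)), shape=(self.n_cells, self.n_cells))


def build_neighbor_graph(
    cells: CellTable,
    radius_um: float = DEFAULT_RADIUS_UM,
    scope: str = "per_fov",
) -> NeighborGraph:
    """Build the contact graph from a cell table.

    ``per_sample`` scope needs a global coordinate frame; with local frames
    a ``fov_offsets`` table on the cell table is required, otherwise a
    :class:`ConfigurationError` is raised.
    """
    if radius_um <= 0:
        raise ConfigurationError("radius_um must be positive")
    if scope not in ("per_fov", "per_sample"):
        raise ConfigurationError(f"unknown scope {scope!r}")
    df = cells.df
    if scope == "per_fov":
        keys = df["fov_id"].to_numpy()
        xy = df[["x_um", "y_um"]].to_numpy(dtype=float)
    else:
        keys = df["sample_id"].to_numpy()
        xy = cells.global_xy()

    group_ids, group_codes = np.unique(keys, return_inverse=True)
    ei_parts, ej_parts, d_parts = [], [], []
    for g in range(len(group_ids)):
        idx = np.flatnonzero(group_codes == g)
        if idx.size < 2:
            continue
        pts = xy[idx]
        pairs = cKDTree(pts).query_pairs(r=radius_um, output_type="ndarray")
        if pairs.size == 0:
            continue
        a, b = idx[pairs[:, 0]], idx[pairs[:, 1]]
        lo, hi = np.minimum(a, b), np.maximum(a, b)
        ei_parts.append(lo)
        ej_parts.append(hi)
        d_parts.append(np.hypot(*(xy[lo] - xy[hi]).T))

    if ei_parts:
        ei = np.concatenate(ei_parts)
        ej = np.concatenate(ej_parts)
        dist = np.concatenate(d_parts)
        order = np.lexsort((ej, ei))
        ei, ej, dist = ei[order], ej[order], dist[order]
    else:
        ei = np.array([], dtype=np.int64)
        ej = np.array([], dtype=np.int64)
        dist = np.array([], dtype=float)

    graph = NeighborGraph(
        radius_um=float(radius_um),
        scope=scope,
        n_cells=len(df),
        edge_i=ei,
        edge_j=ej,
        distance_um=dist,
        group_codes=group_codes,
        group_ids=group_ids,
        cell_ids=df["cell_id"].to_numpy(),
    )
    logger.info(
        "graph: %d cells, %d edges at radius %.1f um (%s)",
        graph.n_cells, graph.n_edges, graph.radius_um, scope,
    )
    return graph


def pair_neighbor_count(
    graph: NeighborGraph,
    labels: np.ndarray,
    type_a: str,
    type_b: str,
    vocabulary=None,
) -> int:
    """Ordered neighbor count: sum over type-A cells of their type-B contacts.

    When ``type_a == type_b`` each unordered same-type edge contributes 2
    (both endpoints are index cells) — halve externally if an unordered
    count is wanted.
    """
    labels = np.asarray(labels, dtype=object)
    if len(labels) != graph.n_cells:
        raise ValueError("labels do not align with the graph's cell set")
    vocab = set(vocabulary) if vocabulary is not None else set(labels.tolist())
    for t in (type_a, type_b):
        if t not in vocab:
            raise VocabularyError(f"unknown cell type {t!r}")
    li, lj = labels[graph.edge_i], labels[graph.edge_j]
    count = int(((li == type_a) & (lj == type_b)).sum())
    count += int(((lj == type_a) & (li == type_b)).sum())
    return count


def export_graph(graph: NeighborGraph, edges_path: str | Path, degrees_path: str | Path) -> None:
    """Write edge list (cell ids + distance) and per-cell degrees as TSV."""
    pd.DataFrame({
        "cell_id_i": graph.cell_ids[graph.edge_i],
        "cell_id_j": graph.cell_ids[graph.edge_j],
        "distance_um": np.round(graph.distance_um, 4),
    }).to_csv(edges_path, sep="\t", index=False)
    pd.DataFrame({
        "cell_id": graph.cell_ids,
        "degree": graph.degree,
    }).to_csv(degrees_path, sep="\t", index=False)
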