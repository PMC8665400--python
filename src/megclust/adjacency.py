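"""Spatial adjacency between source nodes, and node -> ROI assignment.

The cluster statistic needs a notion of which source nodes are spatial
neighbours. On a regular grid the natural choice is a Euclidean distance
threshold just above the grid spacing (6-connectivity); a k-nearest-neighbour
rule is offered for irregular source layouts.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
from scipy.spatial import cKDTree

from .datatypes import SourceGraph


def build_spatial_adjacency(
    coords: np.ndarray,
    d_max: float | None = None,
    k: int | None = None,
    spacing: float | None = None,
) -> SourceGraph:
    """Build an undirected spatial-neighbour graph over source nodes.

    Exactly one of ``d_max`` (edge iff Euclidean distance <= d_max, in the
    units of ``coords``) or ``k`` (symmetrised k-nearest neighbours) must be
    given.
    """
    coords = np.asarray(coords, float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("coords must be (n_nodes, 3)")
    n = coords.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nodes")
    if (d_max is None) == (k is None):
        raise ValueError("specify exactly one of d_max or k")

    tree = cKDTree(coords)
    if d_max is not None:
        if d_max <= 0:
            raise ValueError("d_max must be > 0")
        pairs = tree.query_pairs(r=d_max, output_type="ndarray")
        edges = pairs.astype(int)
    else:
        assert k is not None
        if k < 1:
            raise ValueError("k must be >= 1")
        if k >= n:
            raise ValueError(f"k={k} must be < node count {n}")
        _, idx = tree.query(coords, k=k + 1)  # first neighbour is the node itself
        src = np.repeat(np.arange(n), k)
        dst = idx[:, 1:].reshape(-1)
        edges = np.column_stack([src, dst])
    return SourceGraph(coords=coords, edges=edges, spacing=spacing)


def grid_adjacency(coords: np.ndarray, spacing: float) -> SourceGraph:
    """Default rule for a regular grid: distance threshold 1.05 x spacing."""
    return build_spatial_adjacency(coords, d_max=1.05 * spacing, spacing=spacing)


def assign_nodes_to_rois(
    graph: SourceGraph, roi_map: Mapping[int, str]
) -> SourceGraph:
    """Attach ROI labels to a graph; nodes absent from the map are "unassigned".

    ``roi_map`` maps node index -> ROI name (an anatomical-atlas region).
    """
    n = graph.n_nodes
    labels = np.array(["unassigned"] * n, dtype=object)
    for node, name in roi_map.items():
        node = int(node)
        if not 0 <= node < n:
            raise ValueError(f"roi map references unknown node index {node}")
        name = str(name)
        if not name:
            raise ValueError(f"empty ROI name for node {node}")
        labels[node] = name
    return SourceGraph(
        coords=graph.coords,
        edges=graph.edges,
        roi_labels=labels,
        spacing=graph.spacing,
    )
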