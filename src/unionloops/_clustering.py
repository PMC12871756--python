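"""Radius clustering of pixels, shared by the per-sample and pooled callers.

Clusters are connected components of the graph whose edges join pixel
coordinates at Euclidean bp distance <= radius (points ``(bin1*res, bin2*res)``).
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

__all__ = ["radius_cluster_labels"]


def radius_cluster_labels(
    bin1: np.ndarray, bin2: np.ndarray, radius_bp: float, resolution: int
) -> np.ndarray:
    """Connected-component labels for pixel coordinates at a bp radius.

    Labels are renumbered deterministically: clusters are ordered by their
    lexicographically smallest member coordinate.
    """
    if radius_bp <= 0:
        raise ValueError("radius must be > 0")
    b1 = np.asarray(bin1, dtype=float)
    b2 = np.asarray(bin2, dtype=float)
    npts = len(b1)
    if npts == 0:
        return np.empty(0, dtype=int)
    pts = np.column_stack([b1 * resolution, b2 * resolution])
    tree = cKDTree(pts)
    pairs = tree.query_pairs(r=radius_bp, output_type="ndarray")
    if len(pairs):
        ones = np.ones(len(pairs))
        graph = sp.coo_matrix(
            (ones, (pairs[:, 0], pairs[:, 1])), shape=(npts, npts)
        )
    else:
        graph = sp.coo_matrix((npts, npts))
    _, labels = connected_components(graph, directed=False)
    # deterministic renumbering by smallest (bin1, bin2) member
    order = np.lexsort((b2, b1))
    remap = {}
    for idx in order:
        lab = labels[idx]
        if lab not in remap:
            remap[lab] = len(remap)
    return np.array([remap[l] for l in labels], dtype=int)
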