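"""Triangle-mesh connectivity helpers (edge adjacency on shared topology)."""

from __future__ import annotations

import numpy as np
from scipy import sparse


def vertex_adjacency(triangles: np.ndarray, n_vertices: int) -> sparse.csr_matrix:
    """Symmetric boolean vertex adjacency from a triangle list."""
    triangles = np.asarray(triangles, dtype=np.int64)
    i = np.concatenate([triangles[:, 0], triangles[:, 1], triangles[:, 2]])
    j = np.concatenate([triangles[:, 1], triangles[:, 2], triangles[:, 0]])
    data = np.ones(i.size, dtype=bool)
    adj = sparse.coo_matrix((data, (i, j)), shape=(n_vertices, n_vertices))
    adj = (adj + adj.T).tocsr()
    adj.data[:] = True
    adj.setdiag(False)
    adj.eliminate_zeros()
    return adj


def triangle_areas(vertices: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Area of every triangle (mm^2)."""
    a = vertices[triangles[:, 0]]
    b = vertices[triangles[:, 1]]
    c = vertices[triangles[:, 2]]
    return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)
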