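"""Surface parcellation of FI by thresholding microstructure maps.

The chain mirrors a mesh-attribute parcellation: Laplacian-smooth the
vertex map (2 iterations, lambda = 0.3), apply a strict threshold
inside a restriction mask (ODI: vertices *below* threshold, FA:
vertices *above*), regularize with a majority mode filter, keep the
largest edge-connected component, and report parcel area, area-weighted
mean thickness, volume, and percent-of-cortex metrics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components

from .mesh import vertex_adjacency
from .types import ParcelResult, VertexMorphometry, VertexScalarMap

DIRECTION_FOR_PARAM = {"odi": "below", "fa": "above"}


@dataclass
class SmoothingConfig:
    iterations: int = 2
    lam: float = 0.3

    def __post_init__(self) -> None:
        if self.iterations < 0:
            raise ValueError("iterations must be >= 0")
        if not 0 < self.lam < 1:
            raise ValueError("lambda must lie in (0, 1)")


@dataclass
class RestrictionMask:
    """Vertex-index restriction on a named topology (e.g. the roughly
    circular anterior-insula region limiting where FI may appear)."""

    topology: str
    indices: np.ndarray

    def __post_init__(self) -> None:
        self.indices = np.unique(np.asarray(self.indices, dtype=int))
        if self.indices.size == 0:
            raise ValueError("restriction mask is empty")
        if self.indices.min() < 0:
            raise ValueError("negative vertex index in restriction mask")

    def as_bool(self, n_vertices: int) -> np.ndarray:
        if self.indices.max() >= n_vertices:
            raise ValueError("restriction index out of range for topology")
        out = np.zeros(n_vertices, dtype=bool)
        out[self.indices] = True
        return out

    def save(self, path: str) -> None:
        np.savetxt(path, self.indices, fmt="%d", header="vertex_index",
                   comments="")

    @classmethod
    def load(cls, path: str, topology: str = "atlas") -> "RestrictionMask":
        return cls(topology, np.loadtxt(path, skiprows=1, dtype=int, ndmin=1))

    @classmethod
    def default_insula(cls) -> "RestrictionMask":
        """Packaged synthetic stand-in for a manually drawn anterior-insula
        restriction: a roughly circular cap on the level-4 icosphere atlas
        topology (2562 vertices)."""
        from importlib import resources

        path = resources.files("ficmap.data").joinpath(
            "insula_restriction_ico4_synthetic.csv"
        )
        with resources.as_file(path) as p:
            return cls.load(str(p), topology="atlas-ico4")


def laplacian_smooth(
    vertex_map: VertexScalarMap,
    adjacency: sparse.spmatrix,
    config: SmoothingConfig | None = None,
) -> VertexScalarMap:
    """Iterative Laplacian smoothing: v <- v + lambda (nbr_mean - v).

    Missing vertices are excluded from neighbour averages and stay
    missing; isolated vertices are left unchanged.
    """
    config = config or SmoothingConfig()
    adj = adjacency.tocsr().astype(float)
    v = vertex_map.values.astype(float).copy()
    finite = np.isfinite(v)
    for _ in range(config.iterations):
        vfin = np.where(finite, v, 0.0)
        nsum = adj @ vfin
        ncnt = adj @ finite.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            nmean = nsum / ncnt
        has_nbr = ncnt > 0
        upd = v + config.lam * (nmean - v)
        v = np.where(finite & has_nbr, upd, v)
    return VertexScalarMap(v, topology=vertex_map.topology)


def threshold_mask(
    vertex_map: VertexScalarMap,
    threshold: float,
    direction: str,
    restriction: np.ndarray,
) -> np.ndarray:
    """Strict threshold in the stated direction, within the restriction."""
    if direction not in ("below", "above"):
        raise ValueError("direction must be 'below' or 'above'")
    v = vertex_map.values
    with np.errstate(invalid="ignore"):
        hit = v < threshold if direction == "below" else v > threshold
    hit &= np.isfinite(v)
    return hit & np.asarray(restriction, dtype=bool)


def mode_filter(
    mask: np.ndarray, adjacency: sparse.spmatrix, iterations: int = 1
) -> np.ndarray:
    """Majority-label regularization over closed neighbourhoods.

    Each vertex takes the majority label of itself plus its edge
    neighbours; exact ties keep the current label.  Iterations are
    applied synchronously.
    """
    adj = adjacency.tocsr().astype(float)
    m = np.asarray(mask, dtype=bool).copy()
    deg = np.asarray(adj.sum(axis=1)).ravel()
    for _ in range(iterations):
        true_votes = adj @ m.astype(float) + m
        total = deg + 1.0
        new = m.copy()
        new[2 * true_votes > total] = True
        new[2 * true_votes < total] = False
        m = new
    return m


def largest_component(
    mask: np.ndarray,
    adjacency: sparse.spmatrix,
    vertex_area: np.ndarray | None = None,
) -> np.ndarray:
    """Keep only the largest edge-connected true component.

    Size ties are broken by largest summed vertex area (when supplied),
    then by lowest minimum vertex index.  An empty mask stays empty.
    """
    m = np.asarray(mask, dtype=bool)
    idx = np.flatnonzero(m)
    if idx.size == 0:
        return m.copy()
    sub = adjacency.tocsr()[idx][:, idx]
    n_comp, labels = connected_components(sub, directed=False)
    best = None
    for c in range(n_comp):
        members = idx[labels == c]
        area = float(vertex_area[members].sum()) if vertex_area is not None else 0.0
        key = (members.size, area, -members.min())
        if best is None or key > best[0]:
            best = (key, members)
    out = np.zeros_like(m)
    out[best[1]] = True
    return out


def parcel_metrics(
    mask: np.ndarray,
    morphometry: VertexMorphometry,
    threshold: float = np.nan,
    parameter: str = "odi",
    direction: str = "below",
    total_area: float | None = None,
    total_volume: float | None = None,
) -> ParcelResult:
    """Summary metrics over a parcel mask.

    Percent metrics divide by whole-cortex totals (defaults: the totals
    of the supplied morphometry).  Mean thickness is area-weighted.  An
    empty mask reports zeros with the ``empty`` flag set.
    """
    m = np.asarray(mask, dtype=bool)
    if m.size != morphometry.area.size:
        raise ValueError("mask and morphometry topologies differ")
    total_area = morphometry.total_area if total_area is None else total_area
    total_volume = morphometry.total_volume if total_volume is None else total_volume
    area = float(morphometry.area[m].sum())
    volume = float(morphometry.volume[m].sum())
    if area > 0:
        mean_thickness = float(
            (morphometry.area[m] * morphometry.thickness[m]).sum() / area
        )
    else:
        mean_thickness = 0.0
    return ParcelResult(
        mask=m,
        threshold=float(threshold),
        parameter=parameter,
        direction=direction,
        area=area,
        mean_thickness=mean_thickness,
        volume=volume,
        percent_area=100.0 * area / total_area if total_area > 0 else 0.0,
        percent_volume=100.0 * volume / total_volume if total_volume > 0 else 0.0,
        empty=not m.any(),
    )


def parcellate(
    vertex_map: VertexScalarMap,
    triangles: np.ndarray,
    restriction: RestrictionMask | np.ndarray,
    morphometry: VertexMorphometry,
    threshold: float,
    parameter: str = "odi",
    direction: str | None = None,
    smoothing: SmoothingConfig | None = None,
    mode_iterations: int = 1,
) -> ParcelResult:
    """Full parcellation chain: smooth, threshold, mode-filter, largest
    component, metrics."""
    if direction is None:
        direction = DIRECTION_FOR_PARAM[parameter]
    n = vertex_map.n_vertices
    adj = vertex_adjacency(triangles, n)
    if isinstance(restriction, RestrictionMask):
        restriction = restriction.as_bool(n)
    smoothed = laplacian_smooth(vertex_map, adj, smoothing)
    mask = threshold_mask(smoothed, threshold, direction, restriction)
    mask = mode_filter(mask, adj, iterations=mode_iterations)
    mask &= np.asarray(restriction, dtype=bool)
    mask = largest_component(mask, adj, vertex_area=morphometry.area)
    return parcel_metrics(
        mask, morphometry, threshold=threshold, parameter=parameter,
        direction=direction,
    )
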