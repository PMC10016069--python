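"""Core in-memory containers shared across the pipeline.

Conventions: world coordinates are RAS millimetres, voxel indices are
0-based, and vertex indices are 0-based.  Missing values are encoded as
NaN throughout and propagate as "flagged missing" rather than zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np


@dataclass
class ScalarVolume3D:
    """A scalar grid with a voxel-to-world affine.

    Parameters
    ----------
    data : (I, J, K) float array
    affine : (4, 4) voxel-to-world (RAS mm) matrix
    """

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D data, got shape {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("singular voxel-to-world affine")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        """Map (N, 3) world RAS mm points to continuous voxel indices."""
        points = np.atleast_2d(points)
        inv = np.linalg.inv(self.affine)
        return points @ inv[:3, :3].T + inv[:3, 3]

    def voxel_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(idx)
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.data.astype(np.float32), self.affine)

    def save(self, path: str) -> None:
        nib.save(self.to_nifti(), path)

    @classmethod
    def load(cls, path: str) -> "ScalarVolume3D":
        img = nib.load(path)
        return cls(np.asarray(img.get_fdata(), dtype=float), img.affine)


@dataclass
class SurfacePair:
    """White and pial triangle meshes with shared vertex/triangle indexing."""

    white: np.ndarray      # (V, 3) mm
    pial: np.ndarray       # (V, 3) mm
    triangles: np.ndarray  # (T, 3) int

    def __post_init__(self) -> None:
        self.white = np.asarray(self.white, dtype=float)
        self.pial = np.asarray(self.pial, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        if self.white.shape != self.pial.shape:
            raise ValueError("white and pial must share vertex indexing")
        if self.white.ndim != 2 or self.white.shape[1] != 3:
            raise ValueError("vertices must be (V, 3)")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise ValueError("triangles must be (T, 3)")
        if self.triangles.size and self.triangles.max() >= self.n_vertices:
            raise ValueError("triangle index out of range")

    @property
    def n_vertices(self) -> int:
        return self.white.shape[0]

    @property
    def midthickness(self) -> np.ndarray:
        """Per-vertex average of white and pial positions."""
        return 0.5 * (self.white + self.pial)

    def save(self, white_path: str, pial_path: str) -> None:
        """Write both meshes as GIFTI surface files."""
        for verts, path in ((self.white, white_path), (self.pial, pial_path)):
            darrays = [
                nib.gifti.GiftiDataArray(
                    verts.astype(np.float32), intent="NIFTI_INTENT_POINTSET"
                ),
                nib.gifti.GiftiDataArray(
                    self.triangles.astype(np.int32), intent="NIFTI_INTENT_TRIANGLE"
                ),
            ]
            nib.save(nib.gifti.GiftiImage(darrays=darrays), path)

    @classmethod
    def load(cls, white_path: str, pial_path: str) -> "SurfacePair":
        """Read a GIFTI (.gii) or FreeSurfer binary surface pair."""
        def read(path: str) -> tuple[np.ndarray, np.ndarray]:
            if path.endswith(".gii"):
                img = nib.load(path)
                return img.agg_data("pointset"), img.agg_data("triangle")
            verts, faces = nib.freesurfer.read_geometry(path)
            return verts, faces

        wv, wt = read(white_path)
        pv, pt = read(pial_path)
        if not np.array_equal(wt, pt):
            raise ValueError("white and pial triangle lists differ")
        return cls(wv, pv, wt)


@dataclass
class VertexScalarMap:
    """One scalar per vertex on a named topology; NaN marks missing vertices.

    ``sd`` and ``n_retained`` are populated by the robust cortical sampler
    and are optional elsewhere.
    """

    values: np.ndarray
    topology: str = "subject"
    sd: np.ndarray | None = None
    n_retained: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float).ravel()
        if self.n_retained is not None:
            self.n_retained = np.asarray(self.n_retained, dtype=int).ravel()

    @property
    def n_vertices(self) -> int:
        return self.values.shape[0]

    @property
    def missing(self) -> np.ndarray:
        return ~np.isfinite(self.values)

    def save(self, path: str) -> None:
        """Write as GIFTI functional (.gii), FreeSurfer curv, or CSV."""
        if path.endswith(".gii"):
            da = nib.gifti.GiftiDataArray(
                self.values.astype(np.float32), intent="NIFTI_INTENT_NONE"
            )
            nib.save(nib.gifti.GiftiImage(darrays=[da]), path)
        elif path.endswith(".csv"):
            np.savetxt(path, self.values, delimiter=",", header="value", comments="")
        else:
            nib.freesurfer.write_morph_data(path, self.values)

    @classmethod
    def load(cls, path: str, topology: str = "subject") -> "VertexScalarMap":
        if path.endswith(".gii"):
            values = nib.load(path).agg_data()
        elif path.endswith(".csv"):
            values = np.loadtxt(path, delimiter=",", skiprows=1)
        else:
            values = nib.freesurfer.read_morph_data(path)
        return cls(np.asarray(values, dtype=float), topology=topology)


@dataclass
class VertexMorphometry:
    """Per-vertex surface area (mm^2), thickness (mm), and volume (mm^3)."""

    area: np.ndarray
    thickness: np.ndarray
    volume: np.ndarray
    n_clamped: int = 0

    @property
    def total_area(self) -> float:
        return float(np.sum(self.area))

    @property
    def total_volume(self) -> float:
        return float(np.sum(self.volume))


@dataclass
class ParcelResult:
    """A single-component boolean vertex parcel and its summary metrics."""

    mask: np.ndarray
    threshold: float
    parameter: str           # "odi" or "fa"
    direction: str           # "below" or "above"
    area: float              # mm^2
    mean_thickness: float    # mm, area-weighted
    volume: float            # mm^3
    percent_area: float
    percent_volume: float
    empty: bool = False

    def as_row(self) -> dict:
        return {
            "threshold": self.threshold,
            "parameter": self.parameter,
            "direction": self.direction,
            "n_vertices": int(np.sum(self.mask)),
            "area_mm2": self.area,
            "mean_thickness_mm": self.mean_thickness,
            "volume_mm3": self.volume,
            "percent_area": self.percent_area,
            "percent_volume": self.percent_volume,
        }
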