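"""Synthetic phantoms and cohorts with known ground truth.

Every downstream stage of the pipeline has a parameter-recovery test
against data built here: concentric icosphere white/pial pairs, ribbon
microstructure volumes with a planted low-dispersion patch (emulating
the FI signature), multi-shell DWI signals from the NODDI forward
model, threshold-sweep cohorts with a planted skewness optimum, and
twin/retest cohort tables drawn from an ACE variance-components model.

The noise model is additive Gaussian (high-SNR regime; keeps the
oracles analytic); a Rician option is available for the DWI phantom.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import trimesh

from .mesh import vertex_adjacency  # noqa: F401  (re-exported for callers)
from .microstructure import DiffusionProtocol, NODDIParams, noddi_forward
from .types import ScalarVolume3D, SurfacePair, VertexScalarMap

# ---------------------------------------------------------------------------
# phantom geometry and parameter volumes
# ---------------------------------------------------------------------------


@dataclass
class PhantomSpec:
    """Concentric-sphere cortical phantom with a planted low-ODI patch.

    Defaults emulate gray-matter values: background cortex ODI ~ 0.52
    and FA ~ 0.12, with a patch (ODI 0.28, FA 0.25) whose dispersion is
    lower and anisotropy higher than its surround, as in FI.
    """

    subdivision_level: int = 4
    white_radius: float = 30.0           # mm
    pial_radius: float = 33.0            # mm
    patch_center: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 0.0, 1.0])
    )
    patch_angular_radius: float = 0.5    # radians
    odi_background: float = 0.52
    odi_patch: float = 0.28
    fa_background: float = 0.12
    fa_patch: float = 0.25
    voxel_size: float = 1.0              # mm
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.subdivision_level < 1:
            raise ValueError("subdivision_level must be >= 1")
        if not 0 < self.white_radius < self.pial_radius:
            raise ValueError("require pial_radius > white_radius > 0")
        for name in ("odi_background", "odi_patch", "fa_background", "fa_patch"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name}={v} outside (0, 1)")
        if self.odi_patch >= self.odi_background:
            raise ValueError("patch must have lower ODI than background")
        c = np.asarray(self.patch_center, dtype=float)
        n = np.linalg.norm(c)
        if n < 1e-12:
            raise ValueError("patch_center must be a nonzero direction")
        self.patch_center = c / n


def make_phantom_surfaces(spec: PhantomSpec) -> SurfacePair:
    """Concentric white/pial icospheres sharing vertex and triangle lists."""
    ico = trimesh.creation.icosphere(subdivisions=spec.subdivision_level, radius=1.0)
    unit = np.asarray(ico.vertices, dtype=float)
    unit /= np.linalg.norm(unit, axis=1, keepdims=True)
    tris = np.asarray(ico.faces, dtype=np.int64)
    return SurfacePair(
        white=unit * spec.white_radius, pial=unit * spec.pial_radius, triangles=tris
    )


def patch_vertex_mask(spec: PhantomSpec, surfaces: SurfacePair) -> np.ndarray:
    """Ground-truth patch membership: mid-thickness direction within
    ``patch_angular_radius`` of ``patch_center``."""
    mid = surfaces.midthickness
    u = mid / np.linalg.norm(mid, axis=1, keepdims=True)
    ang = np.arccos(np.clip(u @ spec.patch_center, -1.0, 1.0))
    return ang <= spec.patch_angular_radius


def _phantom_grid(spec: PhantomSpec) -> tuple[tuple[int, int, int], np.ndarray]:
    margin = 3.0 * spec.voxel_size
    half = spec.pial_radius + margin
    n = int(np.ceil(2 * half / spec.voxel_size))
    affine = np.diag([spec.voxel_size] * 3 + [1.0])
    affine[:3, 3] = -spec.voxel_size * (n - 1) / 2.0  # grid centred on origin
    return (n, n, n), affine


def make_microstructure_phantom(
    spec: PhantomSpec, surfaces: SurfacePair
) -> dict[str, ScalarVolume3D]:
    """ODI and FA parameter volumes on a grid containing the phantom.

    Ribbon voxels (white_radius <= r <= pial_radius) within the patch
    cone get the patch value, the rest of the volume the background
    value; additive Gaussian noise with ``noise_sd`` is applied and
    values are clipped to (0, 1).
    """
    thickness = spec.pial_radius - spec.white_radius
    if spec.voxel_size > thickness:
        raise ValueError(
            f"voxel_size {spec.voxel_size} mm exceeds ribbon thickness "
            f"{thickness} mm: ribbon unresolvable"
        )
    shape, affine = _phantom_grid(spec)
    idx = np.indices(shape).reshape(3, -1).T
    world = idx @ affine[:3, :3].T + affine[:3, 3]
    r = np.linalg.norm(world, axis=1)
    cosang = np.divide(
        world @ spec.patch_center, r, out=np.zeros_like(r), where=r > 0
    )
    in_patch = (r >= spec.white_radius) & (r <= spec.pial_radius) & (
        np.arccos(np.clip(cosang, -1, 1)) <= spec.patch_angular_radius
    )
    rng = np.random.default_rng(spec.seed)
    out: dict[str, ScalarVolume3D] = {}
    for name, bg, patch in (
        ("odi", spec.odi_background, spec.odi_patch),
        ("fa", spec.fa_background, spec.fa_patch),
    ):
        vals = np.full(idx.shape[0], bg)
        vals[in_patch] = patch
        if spec.noise_sd > 0:
            vals = vals + rng.normal(0.0, spec.noise_sd, vals.shape)
        vals = np.clip(vals, 1e-6, 1 - 1e-6)
        out[name] = ScalarVolume3D(vals.reshape(shape), affine)
    return out


# ---------------------------------------------------------------------------
# DWI phantom
# ---------------------------------------------------------------------------


def hcp_like_protocol(
    n_per_shell: int = 24,
    shells: tuple[float, ...] = (1000.0, 2000.0, 3000.0),
    n_b0: int = 6,
    seed: int = 12345,
) -> DiffusionProtocol:
    """Multi-shell protocol with pseudo-uniform directions per shell."""
    rng = np.random.default_rng(seed)
    bvals = [np.zeros(n_b0)]
    bvecs = [np.zeros((n_b0, 3))]
    for b in shells:
        v = rng.normal(size=(n_per_shell, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        bvals.append(np.full(n_per_shell, b))
        bvecs.append(v)
    return DiffusionProtocol(np.concatenate(bvals), np.vstack(bvecs))


def make_dwi_phantom(
    ndi: np.ndarray,
    odi: np.ndarray,
    v_iso: np.ndarray,
    protocol: DiffusionProtocol,
    noise_sd: float = 0.0,
    seed: int = 0,
    orientation: np.ndarray | None = None,
    rician: bool = False,
) -> np.ndarray:
    """Normalized multi-shell DWI signals from the NODDI forward model.

    Parameter arrays share an arbitrary spatial shape; the output gains
    a trailing measurement axis.  Noise is additive Gaussian by default
    (``rician=True`` takes the magnitude of a complex-noise signal).
    """
    ndi = np.asarray(ndi, dtype=float)
    odi = np.asarray(odi, dtype=float)
    v_iso = np.asarray(v_iso, dtype=float)
    if not (ndi.shape == odi.shape == v_iso.shape):
        raise ValueError("parameter volumes must share a shape")
    spatial = ndi.shape
    if orientation is None:
        orientation = np.broadcast_to(
            np.array([0.0, 0.0, 1.0]), spatial + (3,)
        )
    signal = np.empty(spatial + (protocol.n_measurements,))
    for idx in np.ndindex(*spatial):
        params = NODDIParams(
            ndi=float(ndi[idx]),
            odi=float(np.clip(odi[idx], 1e-6, 1.0)),
            v_iso=float(v_iso[idx]),
            mean_orientation=np.asarray(orientation[idx], dtype=float),
        )
        signal[idx] = noddi_forward(params, protocol)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        if rician:
            re = signal + rng.normal(0, noise_sd, signal.shape)
            im = rng.normal(0, noise_sd, signal.shape)
            signal = np.hypot(re, im)
        else:
            signal = signal + rng.normal(0, noise_sd, signal.shape)
    return signal


# ---------------------------------------------------------------------------
# threshold-sweep cohort
# ---------------------------------------------------------------------------


@dataclass
class SweepCohort:
    """Per-subject vertex maps with a planted skewness-optimal threshold."""

    surfaces: SurfacePair
    maps: list[VertexScalarMap]
    restriction_indices: np.ndarray
    optimum: float


def make_sweep_cohort(
    n_subjects: int = 40,
    optimum: float = 0.4,
    subject_sd: float = 0.05,
    vertex_noise_sd: float = 0.03,
    patch_angular_radius: float = 0.9,
    restriction_angular_radius: float = 0.65,
    background: float = 0.6,
    subdivision_level: int = 4,
    white_radius: float = 30.0,
    pial_radius: float = 33.0,
    seed: int = 0,
) -> SweepCohort:
    """Cohort of vertex ODI maps whose parcel-volume distribution has
    minimal skewness at a known threshold.

    Subject i's patch takes the uniform value ``optimum + delta_i``
    (delta ~ N(0, subject_sd)) plus per-vertex noise; vertices outside
    the patch sit at ``background``.  The restriction mask is eroded
    inside the patch so smoothing cannot bleed background values into
    it.  At threshold t, each subject's parcel volume is then (nearly)
    all-or-nothing in delta, so the cohort volume distribution is a
    two-mass mixture whose skewness decreases monotonically through
    zero exactly where half the offsets are crossed — i.e. at
    t = optimum.  Thresholds where all parcels saturate give constant
    volumes (skewness undefined) and drop out of the sweep.
    """
    if restriction_angular_radius >= patch_angular_radius:
        raise ValueError("restriction must sit strictly inside the patch")
    spec = PhantomSpec(
        subdivision_level=subdivision_level,
        white_radius=white_radius,
        pial_radius=pial_radius,
        patch_angular_radius=patch_angular_radius,
        seed=seed,
    )
    surfaces = make_phantom_surfaces(spec)
    mid = surfaces.midthickness
    u = mid / np.linalg.norm(mid, axis=1, keepdims=True)
    theta = np.arccos(np.clip(u[:, 2], -1.0, 1.0))
    in_patch = theta <= patch_angular_radius

    rng = np.random.default_rng(seed)
    offsets = rng.normal(0.0, subject_sd, n_subjects)
    maps = []
    for delta in offsets:
        values = np.where(in_patch, optimum + delta, background)
        values = values + rng.normal(0.0, vertex_noise_sd, theta.size)
        maps.append(VertexScalarMap(values, topology="atlas"))
    return SweepCohort(
        surfaces=surfaces,
        maps=maps,
        restriction_indices=np.flatnonzero(theta <= restriction_angular_radius),
        optimum=optimum,
    )


# ---------------------------------------------------------------------------
# twin/retest cohorts
# ---------------------------------------------------------------------------


@dataclass
class CohortSpec:
    """ACE twin-cohort generator settings.

    The latent trait is A + C + E with variance fractions (a2, c2, e2)
    summing to 1: MZ pairs share A and C fully, DZ pairs share half of
    A and all of C; non-twin (NT) sibling pairs share genetics like DZ
    but are labelled distinctly, mirroring how cohort tables separate
    them.  Observed values add measurement noise; the retest table is a
    second noisy draw of the same latent trait.
    """

    n_mz_pairs: int = 100
    n_dz_pairs: int = 100
    n_nt_pairs: int = 0
    n_singletons: int = 0
    a2: float = 0.5
    c2: float = 0.2
    e2: float = 0.3
    retest_noise_sd: float = 0.0
    behavioral_beta: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_mz_pairs, self.n_dz_pairs, self.n_nt_pairs,
               self.n_singletons) < 0:
            raise ValueError("pair counts must be non-negative")
        total = self.a2 + self.c2 + self.e2
        if abs(total - 1.0) > 1e-8:
            raise ValueError(f"a2 + c2 + e2 = {total}, must equal 1")
        if min(self.a2, self.c2, self.e2) < 0:
            raise ValueError("variance fractions must be non-negative")


def make_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a twin cohort; returns (cohort table, retest table).

    The cohort table has one row per subject with family structure
    (mother/father IDs shared within a pair), zygosity group, sex, age,
    the observed trait value, and a behavioral score with standardized
    slope ``behavioral_beta`` against the latent trait.
    """
    rng = np.random.default_rng(spec.seed)
    a, c, e = np.sqrt([spec.a2, spec.c2, spec.e2])

    rows = []
    subj = 0
    fam = 0

    def draw_pair(group: str, genetic_share: float):
        nonlocal subj, fam
        a_shared = rng.normal()
        c_shared = rng.normal()
        for _ in range(2):
            a_ind = rng.normal()
            g = np.sqrt(genetic_share) * a_shared + np.sqrt(1 - genetic_share) * a_ind
            latent = a * g + c * c_shared + e * rng.normal()
            rows.append((subj, fam, group, latent))
            subj += 1
        fam += 1

    for _ in range(spec.n_mz_pairs):
        draw_pair("MZ", 1.0)
    for _ in range(spec.n_dz_pairs):
        draw_pair("DZ", 0.5)
    for _ in range(spec.n_nt_pairs):
        draw_pair("NT", 0.5)
    for _ in range(spec.n_singletons):
        latent = a * rng.normal() + c * rng.normal() + e * rng.normal()
        rows.append((subj, fam, "SINGLE", latent))
        subj += 1
        fam += 1

    n = len(rows)
    latent = np.array([r[3] for r in rows])
    noise_test = rng.normal(0, spec.retest_noise_sd, n) if spec.retest_noise_sd else 0
    noise_retest = rng.normal(0, spec.retest_noise_sd, n) if spec.retest_noise_sd else 0
    behavior = spec.behavioral_beta * latent + np.sqrt(
        max(0.0, 1.0 - spec.behavioral_beta**2)
    ) * rng.normal(size=n)

    cohort = pd.DataFrame(
        {
            "subject_id": [f"S{r[0]:05d}" for r in rows],
            "mother_id": [f"M{r[1]:05d}" for r in rows],
            "father_id": [f"F{r[1]:05d}" for r in rows],
            "group": [r[2] for r in rows],
            "sex": rng.choice(["F", "M"], size=n),
            "age": rng.uniform(22, 36, n).round(1),
            "value": latent + noise_test,
            "behavior": behavior,
        }
    )
    retest = pd.DataFrame(
        {"subject_id": cohort["subject_id"], "value": latent + noise_retest}
    )
    return cohort, retest


# ---------------------------------------------------------------------------
# ground-truth sidecar
# ---------------------------------------------------------------------------


def write_ground_truth(
    path: str, spec: PhantomSpec, surfaces: SurfacePair
) -> None:
    """JSON sidecar with the planted patch vertex set and true parameters."""
    truth = {
        "patch_vertices": np.flatnonzero(patch_vertex_mask(spec, surfaces)).tolist(),
        "odi_patch": spec.odi_patch,
        "odi_background": spec.odi_background,
        "fa_patch": spec.fa_patch,
        "fa_background": spec.fa_background,
        "white_radius": spec.white_radius,
        "pial_radius": spec.pial_radius,
        "patch_angular_radius": spec.patch_angular_radius,
        "seed": spec.seed,
    }
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2)
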