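"""End-to-end subject and cohort runs driven by a manifest.

A manifest lists per-subject inputs (either a fitted parameter volume,
or a 4D DWI with bval/bvec to fit), the surface pair, optional rigid
transform and atlas correspondence, the parameter/direction pairing
(ODI thresholds select *below*, FA *above*), and the parcellation
threshold (a number, or "sweep" to optimize it on the cohort).  Every
output is regenerated deterministically from the manifest plus seed,
and each run writes a provenance JSON capturing versions and
configuration.

Hemispheres are treated as independent subjects here (label them in
the subject id); cross-hemisphere averaging belongs to the stats layer.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .microstructure import DiffusionProtocol, fit_fwdti, fit_noddi
from .morphometry import compute_morphometry
from .parcellation import (
    DIRECTION_FOR_PARAM,
    RestrictionMask,
    SmoothingConfig,
    parcellate,
)
from .sampling import SamplingConfig, identity_correspondence, resample_to_atlas, sample_cortex
from .stats import probability_map, select_threshold, sweep_thresholds
from .types import ParcelResult, ScalarVolume3D, SurfacePair

log = logging.getLogger("ficmap")


@dataclass
class SubjectEntry:
    subject_id: str
    white: str
    pial: str
    param_volume: str | None = None     # pre-fitted parameter map (NIfTI)
    dwi: str | None = None              # else: 4D DWI + gradient table
    bval: str | None = None
    bvec: str | None = None
    mask: str | None = None
    transform: str | None = None        # 4x4 rigid, world->world, text file
    correspondence: str | None = None   # CSV: 3 indices + 3 weights per row

    def validate(self) -> None:
        if self.param_volume is None and (
            self.dwi is None or self.bval is None or self.bvec is None
        ):
            raise ValueError(
                f"subject {self.subject_id}: need param_volume or dwi+bval+bvec"
            )
        for name in ("white", "pial", "param_volume", "dwi", "bval", "bvec",
                     "mask", "transform", "correspondence"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"subject {self.subject_id}: {name}={p}")


@dataclass
class RunManifest:
    subjects: list[SubjectEntry]
    parameter: str = "odi"
    direction: str | None = None
    threshold: float | str = 0.375
    restriction: str | None = None
    out_dir: str = "ficmap_out"
    seed: int = 0
    sampling: SamplingConfig = field(default_factory=SamplingConfig)
    smoothing: SmoothingConfig = field(default_factory=SmoothingConfig)

    def __post_init__(self) -> None:
        if self.parameter not in DIRECTION_FOR_PARAM:
            raise ValueError(f"parameter must be one of {sorted(DIRECTION_FOR_PARAM)}")
        expected = DIRECTION_FOR_PARAM[self.parameter]
        if self.direction is None:
            self.direction = expected
        elif self.direction != expected:
            raise ValueError(
                f"{self.parameter} thresholding must use direction "
                f"{expected!r}, got {self.direction!r}"
            )

    @classmethod
    def load(cls, path: str) -> "RunManifest":
        with open(path) as fh:
            raw = json.load(fh)
        subjects = [SubjectEntry(**s) for s in raw.pop("subjects")]
        sampling = SamplingConfig(**raw.pop("sampling", {}))
        smoothing = SmoothingConfig(**raw.pop("smoothing", {}))
        return cls(subjects=subjects, sampling=sampling, smoothing=smoothing, **raw)


def _load_correspondence(path: str | None, n_vertices: int):
    if path is None:
        return identity_correspondence(n_vertices)
    arr = np.loadtxt(path, delimiter=",", skiprows=1)
    return arr[:, :3].astype(int), arr[:, 3:6]


def _parameter_volume(entry: SubjectEntry, manifest: RunManifest) -> ScalarVolume3D:
    if entry.param_volume is not None:
        return ScalarVolume3D.load(entry.param_volume)
    protocol = DiffusionProtocol.from_fsl(entry.bval, entry.bvec)
    import nibabel as nib

    img = nib.load(entry.dwi)
    data = np.asarray(img.get_fdata(), dtype=float)
    mask = None
    if entry.mask is not None:
        mask = ScalarVolume3D.load(entry.mask).data > 0.5
    if manifest.parameter == "odi":
        fit = fit_noddi(data, protocol, mask=mask)
        return ScalarVolume3D(fit.odi, img.affine)
    fit = fit_fwdti(data, protocol, mask=mask)
    return ScalarVolume3D(fit.fa, img.affine)


def run_subject(manifest: RunManifest, subject_id: str) -> ParcelResult:
    """Run fit -> sample -> atlas resample -> morphometry -> parcellation
    for one subject, writing per-vertex maps, the parcel, and provenance."""
    entry = next(
        (s for s in manifest.subjects if s.subject_id == subject_id), None
    )
    if entry is None:
        raise KeyError(f"subject {subject_id} not in manifest")
    entry.validate()
    if manifest.threshold == "sweep":
        raise ValueError("run_subject needs a numeric threshold; run the cohort")
    t0 = time.time()
    out = Path(manifest.out_dir) / subject_id
    out.mkdir(parents=True, exist_ok=True)

    volume = _parameter_volume(entry, manifest)
    surfaces = SurfacePair.load(entry.white, entry.pial)
    if entry.transform is not None:
        xfm = np.loadtxt(entry.transform)
        from .sampling import resample_volume

        volume = resample_volume(volume, xfm, volume.shape, volume.affine)

    vmap = sample_cortex(volume, surfaces, manifest.sampling)
    idx, w = _load_correspondence(entry.correspondence, surfaces.n_vertices)
    amap = resample_to_atlas(vmap, idx, w)
    morph = compute_morphometry(surfaces)

    if manifest.restriction is not None:
        restriction = RestrictionMask.load(manifest.restriction)
    else:
        restriction = RestrictionMask("atlas", np.arange(amap.n_vertices))
    parcel = parcellate(
        amap,
        surfaces.triangles,
        restriction,
        morph,
        threshold=float(manifest.threshold),
        parameter=manifest.parameter,
        direction=manifest.direction,
        smoothing=manifest.smoothing,
    )

    amap.save(str(out / f"{manifest.parameter}_atlas.csv"))
    np.savetxt(out / "parcel_vertices.csv", np.flatnonzero(parcel.mask),
               fmt="%d", header="vertex_index", comments="")
    provenance = {
        "ficmap_version": __version__,
        "subject_id": subject_id,
        "parameter": manifest.parameter,
        "direction": manifest.direction,
        "threshold": float(manifest.threshold),
        "seed": manifest.seed,
        "sampling": vars(manifest.sampling),
        "smoothing": vars(manifest.smoothing),
        "elapsed_s": round(time.time() - t0, 3),
    }
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2)
    log.info("subject %s done in %.2fs (%d parcel vertices)",
             subject_id, time.time() - t0, int(parcel.mask.sum()))
    return parcel


def run_cohort(manifest: RunManifest) -> pd.DataFrame:
    """Per-subject runs plus optional threshold sweep and the population
    probability map; failures are recorded and survivors analysed."""
    if len(manifest.subjects) < 3:
        raise ValueError("cohort run requires at least 3 subjects")
    out = Path(manifest.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    threshold = manifest.threshold
    if threshold == "sweep":
        maps, morph, surfaces, restriction = _cohort_maps(manifest)
        sweep = sweep_thresholds(
            maps, surfaces.triangles, restriction, morph,
            parameter=manifest.parameter, direction=manifest.direction,
            smoothing=manifest.smoothing,
        )
        threshold = select_threshold(sweep)
        pd.DataFrame(
            {"threshold": sweep.thresholds, "skewness": sweep.skewness}
        ).to_csv(out / "sweep.csv", index=False)
        log.info("selected threshold %.3f by skewness minimization", threshold)
        manifest = RunManifest(
            subjects=manifest.subjects, parameter=manifest.parameter,
            threshold=threshold, restriction=manifest.restriction,
            out_dir=manifest.out_dir, seed=manifest.seed,
            sampling=manifest.sampling, smoothing=manifest.smoothing,
        )

    rows, masks, failures = [], [], []
    for entry in manifest.subjects:
        try:
            parcel = run_subject(manifest, entry.subject_id)
        except Exception as exc:  # failures recorded, cohort continues
            log.warning("subject %s failed: %s", entry.subject_id, exc)
            failures.append({"subject_id": entry.subject_id, "error": str(exc)})
            continue
        row = {"subject_id": entry.subject_id, **parcel.as_row()}
        rows.append(row)
        masks.append(parcel.mask)
    cohort = pd.DataFrame(rows)
    cohort.to_csv(out / "cohort.csv", index=False)
    if failures:
        pd.DataFrame(failures).to_csv(out / "failures.csv", index=False)
        log.warning("%d of %d subjects failed", len(failures),
                    len(manifest.subjects))
    if masks:
        np.savetxt(out / "probability_map.csv", probability_map(masks),
                   delimiter=",", header="fraction", comments="")
    return cohort


def _cohort_maps(manifest: RunManifest):
    """Sampled atlas maps for every subject (used by the sweep)."""
    maps = []
    surfaces = None
    for entry in manifest.subjects:
        entry.validate()
        volume = _parameter_volume(entry, manifest)
        surfaces = SurfacePair.load(entry.white, entry.pial)
        vmap = sample_cortex(volume, surfaces, manifest.sampling)
        idx, w = _load_correspondence(entry.correspondence, surfaces.n_vertices)
        maps.append(resample_to_atlas(vmap, idx, w))
    morph = compute_morphometry(surfaces)
    if manifest.restriction is not None:
        restriction = RestrictionMask.load(manifest.restriction)
    else:
        restriction = RestrictionMask("atlas", np.arange(maps[0].n_vertices))
    return maps, morph, surfaces, restriction
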