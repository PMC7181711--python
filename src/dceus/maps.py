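"""Volumetric perfusion maps from 4D contrast-ultrasound data.

For each dataset the pipeline produces eight aligned 3D maps inside the
volume of interest (VOI): five tracer-kinetic maps from voxel-by-voxel
lognormal fits (PE, AUC, TP, MTT, T0) and three temporal intensity
projections (MaxIP, AvgIP, StdIP).  Voxels outside the VOI, and in-mask
voxels whose fit failed the quality floor, carry NaN.  Maps persist as
NIfTI-1 volumes with a JSON provenance sidecar.

Internally arrays are (t, z, y, x); NIfTI stores (x, y, z) per convention
with the transposition confined to the I/O boundary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from joblib import Parallel, delayed

from dceus.bolus import FitConfig, derived_params, fit_curves

__all__ = [
    "MAP_NAMES",
    "PerfusionMapSet",
    "fit_voxelwise",
    "intensity_projections",
    "compute_mapset",
    "write_mapset",
    "read_mapset",
    "FormatError",
]

#: Fixed map order used everywhere downstream (feature catalog relies on it).
MAP_NAMES = ("PE", "AUC", "TP", "MTT", "T0", "MaxIP", "AvgIP", "StdIP")

_TRACER_NAMES = MAP_NAMES[:5]

#: Voxels per fitting chunk.  Fixed (never derived from the worker count) so
#: that the chunking, and hence the floating-point result, is identical for
#: any degree of parallelism.
_CHUNK = 2048


class FormatError(RuntimeError):
    """Raised when persisted maps are mutually inconsistent."""


@dataclass
class PerfusionMapSet:
    """The 8 aligned perfusion maps of one dataset plus fit quality."""

    maps: dict[str, np.ndarray]
    spacing_zyx: tuple[float, float, float]
    voi_mask: np.ndarray
    fit_quality: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {m.shape for m in self.maps.values()}
        shapes.add(self.voi_mask.shape)
        shapes.add(self.fit_quality.shape)
        if len(shapes) != 1:
            raise ValueError("all maps must share one shape")
        missing = set(MAP_NAMES) - set(self.maps)
        if missing:
            raise ValueError(f"missing maps: {sorted(missing)}")

    @property
    def shape(self):
        return self.voi_mask.shape


def fit_voxelwise(volume4d, mask, frame_times, fit_config: FitConfig | None = None,
                  workers: int = 1):
    """Voxel-by-voxel lognormal fits inside the mask.

    Returns (tracer_maps, fit_quality): a dict of the five tracer maps and
    the per-voxel r² map.  Unconverged voxels are NaN.  The result is
    bit-identical for any ``workers`` value: voxels are processed in fixed
    chunks of pure, deterministic batch fits, so the parallelism degree can
    only change wall time, never values.
    """
    volume4d = np.asarray(volume4d, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    frame_times = np.asarray(frame_times, dtype=float)
    if volume4d.ndim != 4:
        raise ValueError("volume4d must be 4-D (t, z, y, x)")
    if volume4d.shape[0] != frame_times.size:
        raise ValueError("frame_times length does not match time dimension")
    if volume4d.shape[1:] != mask.shape:
        raise ValueError("mask shape does not match volume")
    if workers < 1:
        raise ValueError("workers must be >= 1")
    cfg = fit_config or FitConfig()

    idx = np.flatnonzero(mask.ravel())
    curves = volume4d.reshape(volume4d.shape[0], -1)[:, idx].T  # (n_vox, T)
    chunks = [slice(s, min(s + _CHUNK, idx.size)) for s in range(0, idx.size, _CHUNK)]

    def _one(sl):
        return fit_curves(frame_times, curves[sl], cfg)

    if workers == 1 or len(chunks) <= 1:
        results = [_one(sl) for sl in chunks]
    else:
        results = Parallel(n_jobs=workers, prefer="processes")(
            delayed(_one)(sl) for sl in chunks
        )

    n = idx.size
    params = np.empty((n, 4))
    r2 = np.empty(n)
    conv = np.empty(n, dtype=bool)
    for sl, (p, r, c) in zip(chunks, results):
        params[sl], r2[sl], conv[sl] = p, r, c

    pe, tp, mtt = derived_params(params[:, 0], params[:, 1], params[:, 2], params[:, 3])
    values = {"PE": pe, "AUC": params[:, 0], "TP": tp, "MTT": mtt, "T0": params[:, 3]}

    shape = mask.shape
    tracer_maps = {}
    for name in _TRACER_NAMES:
        m = np.full(shape, np.nan)
        v = np.where(conv, values[name], np.nan)
        m.ravel()[idx] = v
        tracer_maps[name] = m
    quality = np.full(shape, np.nan)
    quality.ravel()[idx] = r2
    return tracer_maps, quality


def intensity_projections(volume4d, mask):
    """Per-voxel maximum, mean and population-std over time, NaN off-mask."""
    volume4d = np.asarray(volume4d, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if volume4d.ndim != 4 or volume4d.shape[0] < 2:
        raise ValueError("need a 4-D volume with at least 2 frames")
    if volume4d.shape[1:] != mask.shape:
        raise ValueError("mask shape does not match volume")
    out = {
        "MaxIP": volume4d.max(axis=0),
        "AvgIP": volume4d.mean(axis=0),
        "StdIP": volume4d.std(axis=0),  # population (divide-by-N)
    }
    for k in out:
        out[k] = np.where(mask, out[k], np.nan)
    return out


def compute_mapset(volume4d, mask, frame_times, spacing_zyx=(0.5, 0.5, 0.5),
                   fit_config: FitConfig | None = None, workers: int = 1,
                   provenance: dict | None = None) -> PerfusionMapSet:
    """Full 8-map perfusion map set for one dataset."""
    tracer, quality = fit_voxelwise(volume4d, mask, frame_times, fit_config, workers)
    proj = intensity_projections(volume4d, mask)
    maps = {**tracer, **proj}
    return PerfusionMapSet(
        maps=maps,
        spacing_zyx=tuple(float(s) for s in spacing_zyx),
        voi_mask=np.asarray(mask, dtype=bool),
        fit_quality=quality,
        provenance=dict(provenance or {}),
    )


# ---------------------------------------------------------------------------
# NIfTI persistence
# ---------------------------------------------------------------------------

def _affine(spacing_zyx):
    # RAS+ with voxel sizes from spacing; internal (z, y, x) maps to NIfTI (x, y, z)
    sz, sy, sx = spacing_zyx
    return np.diag([sx, sy, sz, 1.0])


def _to_nifti_array(vol_zyx):
    return np.ascontiguousarray(np.transpose(vol_zyx, (2, 1, 0)))


def _from_nifti_array(vol_xyz):
    return np.ascontiguousarray(np.transpose(vol_xyz, (2, 1, 0)))


def write_mapset(mapset: PerfusionMapSet, path) -> Path:
    """Write 8 maps + quality + mask as NIfTI-1 plus a JSON sidecar."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    aff = _affine(mapset.spacing_zyx)
    for name in MAP_NAMES:
        img = nib.Nifti1Image(_to_nifti_array(mapset.maps[name]), aff)
        nib.save(img, path / f"{name}.nii")
    nib.save(nib.Nifti1Image(_to_nifti_array(mapset.fit_quality), aff),
             path / "fit_quality.nii")
    nib.save(nib.Nifti1Image(_to_nifti_array(mapset.voi_mask.astype(np.uint8)), aff),
             path / "voi_mask.nii")
    sidecar = {"spacing_zyx": list(mapset.spacing_zyx),
               "provenance": mapset.provenance,
               "maps": list(MAP_NAMES)}
    (path / "mapset.json").write_text(json.dumps(sidecar, indent=2))
    return path


def read_mapset(path) -> PerfusionMapSet:
    """Read a map set written by :func:`write_mapset`; validates alignment."""
    path = Path(path)
    sidecar = json.loads((path / "mapset.json").read_text())
    maps, affines, shapes = {}, [], []
    for name in MAP_NAMES:
        img = nib.load(path / f"{name}.nii")
        maps[name] = _from_nifti_array(np.asarray(img.dataobj, dtype=float))
        affines.append(img.affine)
        shapes.append(maps[name].shape)
    qimg = nib.load(path / "fit_quality.nii")
    quality = _from_nifti_array(np.asarray(qimg.dataobj, dtype=float))
    mimg = nib.load(path / "voi_mask.nii")
    mask = _from_nifti_array(np.asarray(mimg.dataobj)).astype(bool)
    affines += [qimg.affine, mimg.affine]
    shapes += [quality.shape, mask.shape]
    if len(set(shapes)) != 1:
        raise FormatError("maps in the set have mismatched shapes")
    for a in affines[1:]:
        if not np.allclose(a, affines[0], atol=1e-6):
            raise FormatError("maps in the set have mismatched affines")
    return PerfusionMapSet(
        maps=maps,
        spacing_zyx=tuple(sidecar["spacing_zyx"]),
        voi_mask=mask,
        fit_quality=quality,
        provenance=sidecar.get("provenance", {}),
    )
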