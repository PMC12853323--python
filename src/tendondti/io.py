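"""NIfTI and gradient-table I/O.

Volumes are written with a diagonal affine built from the voxel
dimensions and world origin.  Mask orientation metadata (slice axis,
proximal end, limb side, anatomical left direction) does not fit in a
NIfTI header and travels in a small JSON sidecar next to the image.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .masks import TendonMask
from .protocols import DWIVolume, read_fsl_gradients, write_fsl_gradients
from .roi_geometry import RegionSet

__all__ = [
    "write_mask", "read_mask", "write_scalar", "read_scalar",
    "write_dwi", "read_dwi", "write_labelmap", "read_labelmap",
]

LABEL_CODES = {"medial": 1, "central": 2, "lateral": 3}


def _affine(voxel_dims, origin) -> np.ndarray:
    aff = np.diag(list(voxel_dims) + [1.0])
    # voxel (0,0,0) center sits half a voxel in from the grid corner
    aff[:3, 3] = np.asarray(origin) + 0.5 * np.asarray(voxel_dims)
    return aff


def _grid_from(img) -> tuple[tuple, tuple]:
    aff = img.affine
    dims = tuple(float(d) for d in np.abs(np.diag(aff)[:3]))
    origin = tuple(float(o) for o in (aff[:3, 3] - 0.5 * np.diag(aff)[:3]))
    return dims, origin


def write_mask(mask: TendonMask, path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8),
                          _affine(mask.voxel_dims, mask.origin))
    nib.save(img, path)
    sidecar = {
        "slice_axis": mask.slice_axis,
        "proximal_end": mask.proximal_end,
        "limb_side": mask.limb_side,
        "left_direction": mask.left_direction,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return path


def read_mask(path) -> TendonMask:
    path = Path(path)
    img = nib.load(path)
    dims, origin = _grid_from(img)
    meta = {}
    sc = _sidecar_path(path)
    if sc.exists():
        meta = json.loads(sc.read_text())
    return TendonMask(
        np.asarray(img.dataobj) > 0, dims, origin,
        slice_axis=int(meta.get("slice_axis", 2)),
        proximal_end=meta.get("proximal_end", "low"),
        limb_side=meta.get("limb_side"),
        left_direction=meta.get("left_direction"),
    )


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def write_scalar(array: np.ndarray, voxel_dims, origin, path) -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(np.asarray(array, dtype=np.float64),
                             _affine(voxel_dims, origin)), path)
    return path


def read_scalar(path):
    img = nib.load(path)
    dims, origin = _grid_from(img)
    return np.asarray(img.dataobj, dtype=float), dims, origin


def write_dwi(dwi: DWIVolume, nifti_path, bval_path=None, bvec_path=None) -> Path:
    nifti_path = Path(nifti_path)
    stem = str(nifti_path)
    for suffix in (".nii.gz", ".nii"):
        if stem.endswith(suffix):
            stem = stem[: -len(suffix)]
            break
    bval_path = Path(bval_path) if bval_path else Path(stem + ".bval")
    bvec_path = Path(bvec_path) if bvec_path else Path(stem + ".bvec")
    nib.save(nib.Nifti1Image(dwi.data, _affine(dwi.voxel_dims, dwi.origin)),
             nifti_path)
    write_fsl_gradients(dwi.protocol, bval_path, bvec_path)
    return nifti_path


def read_dwi(nifti_path, bval_path=None, bvec_path=None) -> DWIVolume:
    nifti_path = Path(nifti_path)
    stem = str(nifti_path)
    for suffix in (".nii.gz", ".nii"):
        if stem.endswith(suffix):
            stem = stem[: -len(suffix)]
            break
    bval_path = Path(bval_path) if bval_path else Path(stem + ".bval")
    bvec_path = Path(bvec_path) if bvec_path else Path(stem + ".bvec")
    img = nib.load(nifti_path)
    dims, origin = _grid_from(img)
    protocol = read_fsl_gradients(bval_path, bvec_path)
    return DWIVolume(np.asarray(img.dataobj, dtype=float), protocol,
                     dims[:3], origin[:3])


def write_labelmap(regions: RegionSet, path) -> Path:
    """Longitudinal regions as one labelmap (0 bg, 1 medial, 2 central,
    3 lateral); proximal/distal masks go to separate files by the caller."""
    lab = np.zeros(regions["whole"].shape, dtype=np.uint8)
    for name, code in LABEL_CODES.items():
        if name in regions.masks:
            lab[regions[name]] = code
    path = Path(path)
    nib.save(nib.Nifti1Image(lab, _affine(regions.voxel_dims, regions.origin)),
             path)
    return path


def read_labelmap(path) -> RegionSet:
    img = nib.load(path)
    dims, origin = _grid_from(img)
    lab = np.asarray(img.dataobj).astype(int)
    masks = {name: lab == code for name, code in LABEL_CODES.items()}
    masks["whole"] = lab > 0
    return RegionSet(masks, dims, origin)
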