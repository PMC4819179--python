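"""NIfTI + FSL bval/bvec I/O and dataset bundles.

Conventions: internal units are b in ms/um^2 and D in um^2/ms; b-values
given in s/mm^2 (detected when max > 100) are converted on read.  bvecs are
interpreted in image coordinates (FSL dialect: three whitespace-separated
rows of N columns); the NIfTI affine is carried through unchanged to every
map written.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .exceptions import InvalidInputError, InvalidSchemeError
from .model import AcquisitionScheme

__all__ = ["DatasetBundle", "read_dwi", "write_maps", "write_dataset",
           "read_bvals_bvecs"]


@dataclass
class DatasetBundle:
    """A 4-D DWI volume with its acquisition scheme and provenance."""

    data: np.ndarray              # (x, y, z, n_meas)
    scheme: AcquisitionScheme
    affine: np.ndarray
    mask: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.data.ndim != 4:
            raise InvalidInputError("expected a 4-D volume")
        if self.data.shape[-1] != len(self.scheme):
            raise InvalidInputError(
                f"volume has {self.data.shape[-1]} frames, scheme has "
                f"{len(self.scheme)} measurements")

    @property
    def shape(self):
        return self.data.shape[:3]


def read_bvals_bvecs(bval_path, bvec_path, n_volumes: int | None = None
                     ) -> AcquisitionScheme:
    """Read an FSL-dialect bval/bvec pair into an acquisition scheme.

    b-values with max > 100 are assumed to be s/mm^2 and divided by 1000.
    Zero-norm bvecs are allowed only at b = 0.
    """
    try:
        bvals = np.loadtxt(bval_path).ravel()
    except OSError as exc:
        raise InvalidInputError(f"cannot read bval file: {exc}") from exc
    try:
        bvecs = np.loadtxt(bvec_path)
    except OSError as exc:
        raise InvalidInputError(f"cannot read bvec file: {exc}") from exc
    if bvecs.ndim != 2:
        raise InvalidSchemeError("bvec file must be 2-D (3 rows x N columns)")
    if bvecs.shape[0] == 3:
        # FSL dialect: rows are x, y, z components (covers the 3x3 case too)
        bvecs = bvecs.T
    elif bvecs.shape[1] != 3:
        raise InvalidSchemeError("bvec file must have 3 rows (or 3 columns)")
    if bvals.shape[0] != bvecs.shape[0]:
        raise InvalidSchemeError(
            f"{bvals.shape[0]} b-values vs {bvecs.shape[0]} directions")
    if n_volumes is not None and bvals.shape[0] != n_volumes:
        raise InvalidSchemeError(
            f"{bvals.shape[0]} scheme entries vs {n_volumes} volumes")
    if bvals.max(initial=0) > 100:  # s/mm^2 dialect
        bvals = bvals / 1000.0
    norms = np.linalg.norm(bvecs, axis=1)
    nz = bvals > 0
    if np.any(np.abs(norms[nz] - 1.0) > 1e-3):
        raise InvalidSchemeError("non-unit bvec at nonzero b (> 1e-3 off)")
    if np.any((~nz) & (norms > 1e-3) & (np.abs(norms - 1.0) > 1e-3)):
        raise InvalidSchemeError("malformed b=0 bvec row")
    # re-normalize to exact unit length for downstream algebra
    bvecs = np.where(norms[:, None] > 1e-3, bvecs / np.where(
        norms[:, None] > 1e-3, norms[:, None], 1.0), 0.0)
    return AcquisitionScheme(bvals, bvecs)


def read_dwi(image_path, bval_path, bvec_path) -> DatasetBundle:
    """Load a 4-D NIfTI DWI volume with its FSL bval/bvec pair."""
    try:
        img = nib.load(str(image_path))
    except Exception as exc:
        raise InvalidInputError(f"cannot read image: {exc}") from exc
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise InvalidInputError(f"expected 4-D image, got {data.ndim}-D")
    scheme = read_bvals_bvecs(bval_path, bvec_path, n_volumes=data.shape[-1])
    return DatasetBundle(data=data, scheme=scheme, affine=img.affine,
                         meta={"source": str(image_path)})


def write_maps(maps: dict, reference: DatasetBundle | np.ndarray,
               out_dir, mask: np.ndarray | None = None,
               fill_value: float = 0.0, sidecar: dict | None = None) -> list:
    """Write one NIfTI per scalar map plus a JSON provenance sidecar.

    ``reference`` supplies the affine (a bundle or a 4x4 matrix).  Values
    outside ``mask`` are replaced by ``fill_value``.  Returns written paths.
    """
    affine = reference.affine if isinstance(reference, DatasetBundle) \
        else np.asarray(reference, dtype=float)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    shapes = {np.asarray(m).shape for m in maps.values()}
    if len(shapes) != 1:
        raise InvalidInputError(f"maps have mismatched shapes: {shapes}")
    written = []
    for name, arr in maps.items():
        arr = np.asarray(arr, dtype=np.float32)
        if mask is not None:
            arr = np.where(np.asarray(mask, bool), arr,
                           np.float32(fill_value))
        path = out_dir / f"{name}.nii.gz"
        nib.save(nib.Nifti1Image(arr, affine), str(path))
        written.append(path)
    meta = dict(sidecar or {})
    meta.setdefault("maps", sorted(maps))
    meta["fill_value"] = fill_value
    side = out_dir / "maps.json"
    side.write_text(json.dumps(meta, indent=2, default=str))
    written.append(side)
    return written


def write_dataset(bundle: DatasetBundle, out_dir, stem: str = "dwi",
                  ground_truth=None) -> list:
    """Write a (simulated) dataset as NIfTI 4-D + bval/bvec (+ truth CSV)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    img_path = out_dir / f"{stem}.nii.gz"
    nib.save(nib.Nifti1Image(bundle.data.astype(np.float32), bundle.affine),
             str(img_path))
    written.append(img_path)
    bval_path = out_dir / f"{stem}.bval"
    np.savetxt(bval_path, bundle.scheme.bvals[None, :], fmt="%.6g")
    written.append(bval_path)
    bvec_path = out_dir / f"{stem}.bvec"
    np.savetxt(bvec_path, bundle.scheme.bvecs.T, fmt="%.8f")
    written.append(bvec_path)
    if bundle.meta:
        meta_path = out_dir / f"{stem}.json"
        meta_path.write_text(json.dumps(bundle.meta, indent=2, default=str))
        written.append(meta_path)
    if ground_truth is not None:
        gt_path = out_dir / f"{stem}_truth.csv"
        ground_truth.to_csv(gt_path, index=False)
        written.append(gt_path)
    return written
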