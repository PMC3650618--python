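"""Diffusion-volume, gradient-table, mask and streamline I/O, plus isotropic
resampling.

Conventions
-----------
* All tracking happens in world millimetres through the NIfTI affine.
* Voxel lookup is nearest-voxel: a world point maps to ``round(A^-1 p)``
  (voxel *centers* sit at integer voxel coordinates).
* Gradient tables use the FSL dialect: whitespace-separated ``bval`` (1 x N)
  and ``bvec`` (3 x N) text files, b-vectors already in the image frame.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import FormatError

__all__ = [
    "GradientTable",
    "DWIVolume",
    "BinaryMask",
    "read_gradient_table",
    "write_gradient_table",
    "read_dwi",
    "write_dwi",
    "read_mask",
    "write_mask",
    "resample_isotropic",
    "resample_mask",
    "world_to_voxel",
    "write_tractogram",
    "read_tractogram",
]

B0_THRESHOLD = 50.0      # s/mm^2: below this a volume counts as b=0
LOW_B_THRESHOLD = 500.0  # s/mm^2: b0 < b <= this counts as low-b


@dataclass(frozen=True)
class GradientTable:
    """Acquisition scheme: one direction and b-value per volume.

    Volumes are partitioned into high-b (diffusion-weighting proper, here
    b ~ 1000 s/mm^2), low-b (b ~ 100, acquired to avoid perfusion
    contamination and add signal averages) and b0 baseline volumes.
    """

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self):
        bvals = np.atleast_1d(np.asarray(self.bvals, dtype=float))
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvecs.ndim != 2 or bvecs.shape[1] != 3:
            raise FormatError(f"bvecs must be (N, 3), got {bvecs.shape}")
        if len(bvals) != len(bvecs):
            raise FormatError(
                f"bval/bvec count mismatch: {len(bvals)} vs {len(bvecs)}"
            )
        weighted = bvals > B0_THRESHOLD
        norms = np.linalg.norm(bvecs[weighted], axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-3):
            raise FormatError("non-b0 gradient directions must be unit-norm")
        if not np.any(~weighted | (bvals <= LOW_B_THRESHOLD)):
            raise FormatError(
                "need at least one b0 or low-b volume for signal normalization"
            )
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)

    @property
    def n_volumes(self) -> int:
        return len(self.bvals)

    @property
    def is_b0(self) -> np.ndarray:
        return self.bvals <= B0_THRESHOLD

    @property
    def is_lowb(self) -> np.ndarray:
        return (self.bvals > B0_THRESHOLD) & (self.bvals <= LOW_B_THRESHOLD)

    @property
    def is_highb(self) -> np.ndarray:
        return self.bvals > LOW_B_THRESHOLD

    @property
    def counts(self) -> tuple:
        """(n_high, n_low, n_b0) partition sizes."""
        return (
            int(self.is_highb.sum()),
            int(self.is_lowb.sum()),
            int(self.is_b0.sum()),
        )


@dataclass(frozen=True)
class DWIVolume:
    """4-D diffusion-weighted data with its voxel->world (mm) affine."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        affine = np.asarray(self.affine, dtype=float)
        if data.ndim != 4:
            raise FormatError(f"DWI data must be 4-D, got shape {data.shape}")
        if affine.shape != (4, 4) or abs(np.linalg.det(affine)) < 1e-12:
            raise FormatError("affine must be an invertible 4x4 matrix")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "affine", affine)

    @property
    def shape(self) -> tuple:
        return self.data.shape[:3]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def voxel_size(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)


@dataclass(frozen=True)
class BinaryMask:
    """3-D boolean mask on a voxel grid."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "data", np.asarray(self.data).astype(bool))
        object.__setattr__(self, "affine", np.asarray(self.affine, dtype=float))

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def same_grid(self, affine, shape, tol: float = 1e-4) -> bool:
        return tuple(self.shape) == tuple(shape) and np.allclose(
            self.affine, affine, atol=tol
        )

    def contains_points(self, points_mm: np.ndarray) -> np.ndarray:
        """Nearest-voxel membership test for an (N, 3) array of world points."""
        ijk = world_to_voxel(points_mm, self.affine)
        inside = np.all((ijk >= 0) & (ijk < np.array(self.shape)), axis=1)
        out = np.zeros(len(ijk), dtype=bool)
        if np.any(inside):
            sel = ijk[inside]
            out[inside] = self.data[sel[:, 0], sel[:, 1], sel[:, 2]]
        return out


def world_to_voxel(points_mm, affine) -> np.ndarray:
    """Map world-mm points to nearest 0-based voxel indices."""
    pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
    inv = np.linalg.inv(affine)
    vox = pts @ inv[:3, :3].T + inv[:3, 3]
    return np.round(vox).astype(int)


# ---------------------------------------------------------------------------
# gradient tables


def read_gradient_table(bval_path, bvec_path) -> GradientTable:
    bvals = np.atleast_1d(np.loadtxt(bval_path, dtype=float))
    bvecs = np.loadtxt(bvec_path, dtype=float)
    if bvecs.ndim == 1:
        bvecs = bvecs.reshape(3, -1)
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    elif bvecs.shape == (3, 3):
        # FSL writes 3 rows x N columns; with N == 3 this is ambiguous but
        # row-major 3x3 is taken as the FSL layout.
        bvecs = bvecs.T
    if len(bvals) != len(bvecs):
        raise FormatError(
            f"bval/bvec count mismatch: {len(bvals)} vs {len(bvecs)}"
        )
    weighted = bvals > B0_THRESHOLD
    norms = np.linalg.norm(bvecs, axis=1)
    if np.any(weighted & (norms < 1e-6)):
        raise FormatError("zero gradient direction with nonzero b-value")
    bvecs = bvecs.copy()
    off_unit = weighted & (np.abs(norms - 1.0) > 1e-12)
    bvecs[off_unit] /= norms[off_unit, None]
    return GradientTable(bvals=bvals, bvecs=bvecs)


def write_gradient_table(gtab: GradientTable, bval_path, bvec_path) -> None:
    np.savetxt(bval_path, gtab.bvals[None, :], fmt="%.17g")
    np.savetxt(bvec_path, gtab.bvecs.T, fmt="%.17g")


# ---------------------------------------------------------------------------
# volumes and masks


def read_dwi(image_path, bval_path, bvec_path):
    """Read a 4-D NIfTI and its FSL-style gradient table.

    Returns a consistent ``(DWIVolume, GradientTable)`` pair; b-vectors are
    re-normalized to unit length wherever b > 0.
    """
    for p in (image_path, bval_path, bvec_path):
        if not os.path.exists(p):
            raise IOError(f"missing file: {p}")
    img = nib.load(str(image_path))
    if img.ndim != 4:
        raise FormatError(f"expected 4-D image, got {img.ndim}-D")
    gtab = read_gradient_table(bval_path, bvec_path)
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.shape[3] != gtab.n_volumes:
        raise FormatError(
            f"image has {data.shape[3]} volumes but gradient table has "
            f"{gtab.n_volumes}"
        )
    return DWIVolume(data=data, affine=img.affine), gtab


def write_dwi(vol: DWIVolume, gtab: GradientTable, image_path, bval_path, bvec_path):
    if vol.n_volumes != gtab.n_volumes:
        raise FormatError("volume count does not match gradient table")
    nib.save(nib.Nifti1Image(vol.data, vol.affine), str(image_path))
    write_gradient_table(gtab, bval_path, bvec_path)


def read_mask(path) -> BinaryMask:
    img = nib.load(str(path))
    return BinaryMask(data=np.asarray(img.dataobj) > 0.5, affine=img.affine)


def write_mask(mask: BinaryMask, path) -> None:
    nib.save(nib.Nifti1Image(mask.data.astype(np.uint8), mask.affine), str(path))


# ---------------------------------------------------------------------------
# resampling


def _iso_grid(shape, voxel_size, target_mm):
    scale = target_mm / np.asarray(voxel_size, dtype=float)
    new_shape = tuple(int(np.floor((n - 1) / s)) + 1 for n, s in zip(shape, scale))
    return scale, new_shape


def _resample_3d(data, scale, new_shape, order):
    coords = np.meshgrid(
        *(np.arange(n) * s for n, s in zip(new_shape, scale)), indexing="ij"
    )
    return ndimage.map_coordinates(
        data, np.stack(coords), order=order, mode="nearest"
    )


def resample_isotropic(vol: DWIVolume, target_mm: float) -> DWIVolume:
    """Trilinearly resample every volume onto an isotropic grid.

    Voxel centers stay center-aligned: output voxel (0,0,0) coincides with
    input voxel (0,0,0), and the output lattice spans the same world extent
    of voxel centers.  Trilinear interpolation reproduces constant and
    linear intensity fields exactly.
    """
    if target_mm <= 0:
        raise ValueError(f"target voxel size must be positive, got {target_mm}")
    if target_mm > float(np.min(vol.voxel_size)) * 4:
        raise ValueError("target voxel size too coarse (> 4x the input)")
    scale, new_shape = _iso_grid(vol.shape, vol.voxel_size, target_mm)
    out = np.empty(new_shape + (vol.n_volumes,), dtype=float)
    for v in range(vol.n_volumes):
        out[..., v] = _resample_3d(vol.data[..., v], scale, new_shape, order=1)
    new_affine = vol.affine.copy()
    new_affine[:3, :3] = vol.affine[:3, :3] * scale[None, :]
    return DWIVolume(data=out, affine=new_affine)


def resample_mask(mask: BinaryMask, target_mm: float) -> BinaryMask:
    """Nearest-neighbor resampling of a binary mask (labels, not intensities)."""
    if target_mm <= 0:
        raise ValueError(f"target voxel size must be positive, got {target_mm}")
    voxel_size = np.linalg.norm(mask.affine[:3, :3], axis=0)
    scale, new_shape = _iso_grid(mask.shape, voxel_size, target_mm)
    out = _resample_3d(mask.data.astype(np.uint8), scale, new_shape, order=0)
    new_affine = mask.affine.copy()
    new_affine[:3, :3] = mask.affine[:3, :3] * scale[None, :]
    return BinaryMask(data=out > 0.5, affine=new_affine)


# ---------------------------------------------------------------------------
# tractograms


def write_tractogram(tractogram, path) -> None:
    """Write streamlines (world mm) to TrackVis .trk or MRtrix .tck."""
    from .tracking import Tractogram  # local import avoids a cycle

    path = str(path)
    nt = nib.streamlines.Tractogram(
        streamlines=[np.asarray(s.points, dtype=np.float32)
                     for s in tractogram.streamlines],
        affine_to_rasmm=np.eye(4),
    )
    if path.endswith(".trk"):
        header = {}
        if tractogram.affine is not None:
            header[nib.streamlines.trk.Field.VOXEL_TO_RASMM] = np.asarray(
                tractogram.affine, dtype=np.float32
            )
            header[nib.streamlines.trk.Field.VOXEL_SIZES] = np.linalg.norm(
                np.asarray(tractogram.affine)[:3, :3], axis=0
            ).astype(np.float32)
        if tractogram.shape is not None:
            header[nib.streamlines.trk.Field.DIMENSIONS] = np.asarray(
                tractogram.shape, dtype=np.int16
            )
        nib.streamlines.save(nt, path, header=header)
    elif path.endswith(".tck"):
        nib.streamlines.save(nt, path)
    else:
        raise FormatError(f"unknown tractogram extension: {path}")


def read_tractogram(path):
    """Read a .trk/.tck file back into a Tractogram (points in world mm)."""
    from .tracking import Streamline, Tractogram

    path = str(path)
    if not (path.endswith(".trk") or path.endswith(".tck")):
        raise FormatError(f"unknown tractogram extension: {path}")
    tf = nib.streamlines.load(path)
    affine = None
    shape = None
    if path.endswith(".trk"):
        affine = np.asarray(tf.header[nib.streamlines.trk.Field.VOXEL_TO_RASMM],
                            dtype=float)
        shape = tuple(int(d) for d in
                      tf.header[nib.streamlines.trk.Field.DIMENSIONS])
    streamlines = [
        Streamline(points=np.asarray(pts, dtype=float))
        for pts in tf.tractogram.streamlines
    ]
    return Tractogram(streamlines=streamlines, affine=affine, shape=shape)
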