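"""Extraction of displacement-PDF maxima by multi-start gradient ascent.

The PDF is known only at the 642 level-3 icosphere vertices, so the ascent
is a hill climb on the vertex graph: from each of 42 starting vertices (the
level-1 icosphere, which is an index-prefix of the level-3 one), move to the
neighboring vertex with the greatest PDF value while it improves on the
current vertex.  Surviving maxima are folded for antipodal symmetry,
deduplicated, sorted by probability and truncated; they become the tracking
directions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

from .dwi_io import BinaryMask
from .geometry import SphereTessellation, antipodal_fold, icosphere
from .mow import PDFConfig, WeightField, WishartBasis, pdf_kernel

__all__ = [
    "PeakSet",
    "PeaksField",
    "find_maxima",
    "compute_peaks_field",
    "save_peaks_field",
    "load_peaks_field",
]

N_STARTS = 42
DEFAULT_MAX_PEAKS = 3
DEFAULT_DEDUP_DEG = 15.0  # level-3 grid spacing is ~8 deg; closer peaks are unresolvable
CONSTANT_PDF_TOL = 1e-12


@dataclass(frozen=True)
class PeakSet:
    """Up to K peak directions of one voxel, sorted by PDF value."""

    directions: np.ndarray  # (K, 3) unit vectors, canonical hemisphere
    values: np.ndarray      # (K,)
    isotropic: bool = False

    def __len__(self) -> int:
        return len(self.directions)


_EMPTY = PeakSet(
    directions=np.empty((0, 3)), values=np.empty(0), isotropic=True
)


def _hill_climb(values: np.ndarray, neighbors, start: int) -> int:
    """Strict ascent on the vertex graph; ties go to the lower vertex index."""
    cur = start
    for _ in range(len(values)):  # strict ascent terminates within n moves
        nbrs = neighbors[cur]
        vals = values[nbrs]
        best = int(nbrs[int(np.argmax(vals))])  # argmax -> first = lowest index
        if values[best] > values[cur]:
            cur = best
        else:
            return cur
    return cur


def find_maxima(
    pdf: np.ndarray,
    tess3: SphereTessellation,
    starts: np.ndarray | None = None,
    max_peaks: int = DEFAULT_MAX_PEAKS,
    dedup_deg: float = DEFAULT_DEDUP_DEG,
    min_peak_ratio: float | None = None,
) -> PeakSet:
    """Find the PDF's local maxima on the 642-point grid.

    Parameters
    ----------
    pdf : (642,) array
        PDF values at the tessellation vertices.
    tess3 : SphereTessellation
        The level-3 evaluation tessellation.
    starts : array of int, optional
        Starting vertex indices; defaults to the 42 level-1 vertices, which
        are the first 42 vertices of the nested level-3 mesh.
    min_peak_ratio : float, optional
        If set, voxels whose max/mean PDF contrast falls below this ratio
        are flagged isotropic (no preferred direction).  Off by default.

    A constant PDF (all values equal within 1e-12) has no preferred
    direction and yields an empty, isotropic-flagged PeakSet.
    """
    pdf = np.asarray(pdf, dtype=float)
    if len(pdf) != tess3.n_vertices:
        raise ValueError(
            f"PDF has {len(pdf)} values for {tess3.n_vertices} vertices"
        )
    if float(np.ptp(pdf)) < CONSTANT_PDF_TOL:
        return _EMPTY
    if min_peak_ratio is not None and float(np.max(pdf) / np.mean(pdf)) < min_peak_ratio:
        return _EMPTY
    if starts is None:
        starts = np.arange(N_STARTS)

    summits = sorted({_hill_climb(pdf, tess3.neighbors, int(s)) for s in starts})
    dirs = [antipodal_fold(tess3.vertices[i]) for i in summits]
    vals = [float(pdf[i]) for i in summits]

    # sort by value descending (ties by vertex index for determinism),
    # then greedily deduplicate axially-close maxima keeping the larger
    order = sorted(range(len(dirs)), key=lambda i: (-vals[i], summits[i]))
    cos_tol = np.cos(np.radians(dedup_deg))
    kept_dirs, kept_vals = [], []
    for i in order:
        d = dirs[i]
        if any(abs(d @ k) > cos_tol for k in kept_dirs):
            continue
        kept_dirs.append(d)
        kept_vals.append(vals[i])
        if len(kept_dirs) == max_peaks:
            break
    return PeakSet(
        directions=np.array(kept_dirs), values=np.array(kept_vals),
        isotropic=False,
    )


@dataclass
class PeaksField:
    """Per-voxel peak directions/values on a grid, for reuse by tracking."""

    directions: np.ndarray  # (X, Y, Z, K, 3), NaN-padded
    values: np.ndarray      # (X, Y, Z, K), NaN-padded
    affine: np.ndarray

    @property
    def shape(self) -> tuple:
        return self.directions.shape[:3]

    @property
    def max_peaks(self) -> int:
        return self.directions.shape[3]

    def peak_count(self, i, j, k) -> int:
        return int(np.sum(np.isfinite(self.values[i, j, k])))

    def voxel_peaks(self, i, j, k):
        """(directions, values) of the valid peaks in one voxel."""
        n = self.peak_count(i, j, k)
        return self.directions[i, j, k, :n], self.values[i, j, k, :n]


def compute_peaks_field(
    wfield: WeightField,
    basis: WishartBasis,
    cfg: PDFConfig | None = None,
    mask: BinaryMask | None = None,
    max_peaks: int = DEFAULT_MAX_PEAKS,
    dedup_deg: float = DEFAULT_DEDUP_DEG,
    min_peak_ratio: float | None = None,
) -> PeaksField:
    """Evaluate the PDF and extract peaks for every voxel of a weight field."""
    tess3 = icosphere(3)
    kernel = pdf_kernel(basis, cfg, eval_dirs=tess3.vertices)
    shape = wfield.weights.shape[:3]
    inside = np.ones(shape, dtype=bool) if mask is None else mask.data
    dirs = np.full(shape + (max_peaks, 3), np.nan)
    vals = np.full(shape + (max_peaks,), np.nan)
    for ijk in np.argwhere(inside & ~wfield.flags):
        i, j, k = ijk
        w = wfield.weights[i, j, k]
        if not np.any(w > 0):
            continue
        ps = find_maxima(
            kernel @ w, tess3,
            max_peaks=max_peaks, dedup_deg=dedup_deg,
            min_peak_ratio=min_peak_ratio,
        )
        n = len(ps)
        dirs[i, j, k, :n] = ps.directions
        vals[i, j, k, :n] = ps.values
    return PeaksField(directions=dirs, values=vals, affine=wfield.affine.copy())


def save_peaks_field(pf: PeaksField, path) -> None:
    """Save as 4-D NIfTI: 3K direction components, then K values."""
    shape = pf.shape
    k = pf.max_peaks
    flat = np.concatenate(
        [pf.directions.reshape(shape + (3 * k,)), pf.values], axis=-1
    )
    nib.save(nib.Nifti1Image(flat, pf.affine), str(path))


def load_peaks_field(path) -> PeaksField:
    img = nib.load(str(path))
    flat = np.asarray(img.dataobj, dtype=float)
    k = flat.shape[-1] // 4
    shape = flat.shape[:3]
    return PeaksField(
        directions=flat[..., : 3 * k].reshape(shape + (k, 3)),
        values=flat[..., 3 * k :],
        affine=img.affine,
    )
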