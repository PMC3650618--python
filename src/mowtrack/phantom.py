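"""Synthetic multi-tensor DWI phantoms with known fiber geometry.

Phantoms provide ground truth that no in-vivo acquisition can: per-voxel
fiber directions, exact bundle membership and known connectivity.  The
forward signal uses the same Wishart attenuation as the reconstruction
model,

    S = S0 * sum_c f_c (1 + b g^T (D_c / p) g)^(-p),

with one compartment per bundle whose tube contains the voxel center
(volume fractions summing to 1) and an isotropic compartment filling the
background.  Magnitude noise is Rician with SNR defined as S0/sigma at b0.

The default acquisition scheme mirrors a clinical HARDI protocol: 64
directions at b = 1000 s/mm^2, 6 at b = 100, and 2 b0 volumes, on a 2 mm
isotropic grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .dwi_io import BinaryMask, DWIVolume, GradientTable
from .errors import PhantomSpecError
from .geometry import antipodal_fold, icosphere
from .mow import (
    DEFAULT_EIGENVALUES,
    DEFAULT_P,
    UM2_PER_MS_TO_MM2_PER_S,
    _rotation_to,
    wishart_attenuation,
)

__all__ = [
    "Bundle",
    "ROISpec",
    "PhantomSpec",
    "GroundTruth",
    "default_scheme",
    "simulate_dwi",
    "standard_phantoms",
    "ground_truth_directions",
    "rasterize_roi",
    "spec_to_yaml",
    "spec_from_yaml",
]

DEFAULT_ISO_DIFFUSIVITY = 0.8  # um^2/ms, gray-matter-like background
DEFAULT_S0 = 1000.0
DEFAULT_SNR = 30.0


@dataclass(frozen=True)
class Bundle:
    """A tube of fibers around a polyline centerline (world mm)."""

    name: str
    centerline: np.ndarray           # (M, 3) mm
    radius: float                    # mm
    axial_diffusivity: float = DEFAULT_EIGENVALUES[0]   # um^2/ms
    radial_diffusivity: float = DEFAULT_EIGENVALUES[1]  # um^2/ms
    volume_fraction: float | None = None  # None = equal split among bundles

    def __post_init__(self):
        object.__setattr__(
            self, "centerline", np.asarray(self.centerline, dtype=float)
        )
        if self.axial_diffusivity <= 0 or self.radial_diffusivity <= 0:
            raise PhantomSpecError("diffusivities must be positive")

    def dense_centerline(self, spacing: float):
        """Resample the centerline at ~``spacing`` mm; returns (points,
        unit tangents)."""
        pts = self.centerline
        segs = np.diff(pts, axis=0)
        seg_len = np.linalg.norm(segs, axis=1)
        out_p, out_t = [], []
        for p0, seg, ln in zip(pts[:-1], segs, seg_len):
            n = max(1, int(np.ceil(ln / spacing)))
            ts = np.arange(n) / n
            out_p.append(p0 + ts[:, None] * seg)
            out_t.append(np.tile(seg / ln, (n, 1)))
        out_p.append(pts[-1:])
        out_t.append(out_t[-1][-1:])
        return np.vstack(out_p), np.vstack(out_t)


@dataclass(frozen=True)
class ROISpec:
    """Axis-aligned box ("box": center + half_size) or sphere ("sphere":
    center + radius), in world mm."""

    name: str
    kind: str
    center: np.ndarray
    half_size: np.ndarray | None = None
    radius: float | None = None

    def __post_init__(self):
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        if self.kind == "box":
            if self.half_size is None:
                raise PhantomSpecError(f"box ROI {self.name!r} needs half_size")
            object.__setattr__(
                self, "half_size", np.asarray(self.half_size, dtype=float)
            )
        elif self.kind == "sphere":
            if self.radius is None:
                raise PhantomSpecError(f"sphere ROI {self.name!r} needs radius")
        else:
            raise PhantomSpecError(f"unknown ROI kind {self.kind!r}")


@dataclass(frozen=True)
class PhantomSpec:
    """Declarative description of a synthetic DWI dataset."""

    name: str
    shape: tuple
    voxel_size: float
    bundles: tuple
    rois: tuple = ()
    iso_diffusivity: float = DEFAULT_ISO_DIFFUSIVITY  # um^2/ms
    snr: float = DEFAULT_SNR
    seed: int = 0
    s0: float = DEFAULT_S0
    p: float = DEFAULT_P

    def __post_init__(self):
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "bundles", tuple(self.bundles))
        object.__setattr__(self, "rois", tuple(self.rois))
        if self.snr <= 0:
            raise PhantomSpecError(f"snr must be positive, got {self.snr}")
        if self.iso_diffusivity <= 0:
            raise PhantomSpecError("iso_diffusivity must be positive")
        for b in self.bundles:
            if b.radius < self.voxel_size / 2:
                raise PhantomSpecError(
                    f"bundle {b.name!r} radius {b.radius} < half a voxel"
                )

    @property
    def affine(self) -> np.ndarray:
        a = np.eye(4)
        a[0, 0] = a[1, 1] = a[2, 2] = self.voxel_size
        return a


@dataclass
class GroundTruth:
    """Per-voxel true fiber directions (NaN-padded) and their count."""

    directions: np.ndarray  # (X, Y, Z, Kmax, 3)
    counts: np.ndarray      # (X, Y, Z) int

    def voxel_dirs(self, i, j, k) -> np.ndarray:
        return self.directions[i, j, k, : self.counts[i, j, k]]


def _canonical_axes(level: int) -> np.ndarray:
    """Unique antipodally-folded vertices of an icosphere, in vertex order."""
    verts = icosphere(level).vertices
    kept = []
    for v in verts:
        f = antipodal_fold(v)
        if not any(np.allclose(f, k, atol=1e-9) for k in kept):
            kept.append(f)
    return np.array(kept)


def default_scheme() -> GradientTable:
    """2 x b0, 6 x b=100, 64 x b=1000 s/mm^2 (in that order)."""
    low_dirs = _canonical_axes(0)          # 6 axes of the icosahedron
    high_dirs = _canonical_axes(2)[:64]    # first 64 of the 81 level-2 axes
    bvals = np.concatenate([[0.0, 0.0], np.full(6, 100.0), np.full(64, 1000.0)])
    bvecs = np.vstack([np.zeros((2, 3)), low_dirs, high_dirs])
    return GradientTable(bvals=bvals, bvecs=bvecs)


def _voxel_centers(shape, affine) -> np.ndarray:
    idx = np.indices(shape).reshape(3, -1).T.astype(float)
    return idx @ affine[:3, :3].T + affine[:3, 3]


def _bundle_membership(bundle: Bundle, centers: np.ndarray, spacing: float):
    """(inside mask, unit tangent at nearest centerline sample) for all
    voxel centers."""
    cpts, ctan = bundle.dense_centerline(spacing)
    # pairwise distances voxel-centers x centerline-samples (grids are small)
    d2 = np.sum((centers[:, None, :] - cpts[None, :, :]) ** 2, axis=2)
    nearest = np.argmin(d2, axis=1)
    dist = np.sqrt(d2[np.arange(len(centers)), nearest])
    return dist < bundle.radius, ctan[nearest]


def ground_truth_directions(
    spec: PhantomSpec, shape=None, affine=None
) -> GroundTruth:
    """True fiber directions rasterized onto an arbitrary grid (defaults to
    the phantom's own grid), for scoring angular recovery after resampling."""
    shape = spec.shape if shape is None else tuple(shape)
    affine = spec.affine if affine is None else np.asarray(affine, dtype=float)
    centers = _voxel_centers(shape, affine)
    spacing = spec.voxel_size / 4
    kmax = max(1, len(spec.bundles))
    dirs = np.full((len(centers), kmax, 3), np.nan)
    counts = np.zeros(len(centers), dtype=int)
    for b in spec.bundles:
        inside, tangents = _bundle_membership(b, centers, spacing)
        for v in np.flatnonzero(inside):
            dirs[v, counts[v]] = antipodal_fold(tangents[v])
            counts[v] += 1
    return GroundTruth(
        directions=dirs.reshape(shape + (kmax, 3)),
        counts=counts.reshape(shape),
    )


def rasterize_roi(roi: ROISpec, shape, affine) -> BinaryMask:
    centers = _voxel_centers(shape, affine)
    if roi.kind == "box":
        inside = np.all(np.abs(centers - roi.center) <= roi.half_size, axis=1)
    else:
        inside = np.linalg.norm(centers - roi.center, axis=1) <= roi.radius
    return BinaryMask(data=inside.reshape(shape), affine=np.asarray(affine))


def _fiber_tensors(bundle: Bundle, tangents: np.ndarray) -> np.ndarray:
    lam = np.array(
        [bundle.radial_diffusivity, bundle.radial_diffusivity,
         bundle.axial_diffusivity]
    )
    out = np.empty((len(tangents), 3, 3))
    for i, t in enumerate(tangents):
        r = _rotation_to(t)
        out[i] = r @ np.diag(lam) @ r.T * UM2_PER_MS_TO_MM2_PER_S
    return out


def simulate_dwi(spec: PhantomSpec, gtab: GradientTable | None = None):
    """Generate a phantom dataset.

    Returns ``(DWIVolume, GradientTable, brain_mask, rois, GroundTruth)``.
    Deterministic given the spec (including its RNG seed).
    """
    gtab = gtab or default_scheme()
    shape, affine = spec.shape, spec.affine
    centers = _voxel_centers(shape, affine)
    n_vox, n_vol = len(centers), gtab.n_volumes
    spacing = spec.voxel_size / 4

    memberships = []
    for b in spec.bundles:
        inside, tangents = _bundle_membership(b, centers, spacing)
        memberships.append((b, inside, tangents))

    n_in = np.zeros(n_vox, dtype=int)
    frac_sum = np.zeros(n_vox)
    for b, inside, _ in memberships:
        n_in += inside
        if b.volume_fraction is not None:
            frac_sum[inside] += b.volume_fraction
    if np.any(frac_sum > 1.0 + 1e-9):
        raise PhantomSpecError("overlapping bundle volume fractions exceed 1")

    signal = np.zeros((n_vox, n_vol))
    fiber_frac = np.zeros(n_vox)
    for b, inside, tangents in memberships:
        if not np.any(inside):
            continue
        if b.volume_fraction is not None:
            frac = np.full(int(inside.sum()), b.volume_fraction)
        else:
            frac = 1.0 / np.maximum(n_in[inside], 1)
        tensors = _fiber_tensors(b, tangents[inside])
        atten = wishart_attenuation(gtab.bvals, gtab.bvecs, tensors, spec.p).T
        signal[inside] += frac[:, None] * atten
        fiber_frac[inside] += frac

    iso_d = np.eye(3) * spec.iso_diffusivity * UM2_PER_MS_TO_MM2_PER_S
    iso_atten = wishart_attenuation(
        gtab.bvals, gtab.bvecs, iso_d[None], spec.p
    )[:, 0]
    signal += (1.0 - fiber_frac)[:, None] * iso_atten[None, :]
    signal *= spec.s0

    if np.isfinite(spec.snr):
        rng = np.random.default_rng(spec.seed)
        sigma = spec.s0 / spec.snr
        n1 = rng.normal(0.0, sigma, signal.shape)
        n2 = rng.normal(0.0, sigma, signal.shape)
        signal = np.sqrt((signal + n1) ** 2 + n2**2)

    vol = DWIVolume(data=signal.reshape(shape + (n_vol,)), affine=affine)
    brain = BinaryMask(data=np.ones(shape, dtype=bool), affine=affine)
    rois = {r.name: rasterize_roi(r, shape, affine) for r in spec.rois}
    gt = ground_truth_directions(spec)
    return vol, gtab, brain, rois, gt


# ---------------------------------------------------------------------------
# the standard phantom set


def _line(p0, p1):
    return np.array([p0, p1], dtype=float)


def standard_phantoms(snr: float = np.inf, seed: int = 0) -> dict:
    """Named phantoms exercising each tracking regime.

    STRAIGHT  one bundle with ROIs at both ends;
    CROSS90   two orthogonal bundles crossing at the center;
    BRANCH    a Y fork with a 40 degree branch angle;
    CURVE     a smooth ~90 degree turn spread over many steps;
    DISJOINT  two parallel, non-touching bundles (ground-truth zero
              connectivity: the false-positive control).

    Noiseless by default: these validate geometry recovery; noise robustness
    is a separate axis studied by overriding ``snr``.
    """
    vs = 2.0
    r = 2.2
    ph = {}

    # STRAIGHT: 10x4x4 voxels (20x8x8 mm), bundle along x at y=z=3
    bundles = (Bundle("main", _line((-2, 3, 3), (22, 3, 3)), r),)
    rois = (
        ROISpec("roi_a", "box", (1, 3, 3), half_size=(1.5, 4, 4)),
        ROISpec("roi_b", "box", (17, 3, 3), half_size=(1.5, 4, 4)),
    )
    ph["STRAIGHT"] = PhantomSpec(
        "STRAIGHT", (10, 4, 4), vs, bundles, rois, snr=snr, seed=seed
    )

    # CROSS90: 12x12x4 voxels, bundles along x and y crossing at (11, 11, 3)
    bundles = (
        Bundle("a", _line((-2, 11, 3), (24, 11, 3)), r),
        Bundle("b", _line((11, -2, 3), (11, 24, 3)), r),
    )
    rois = (
        ROISpec("a1", "box", (1, 11, 3), half_size=(1.5, 3, 4)),
        ROISpec("a2", "box", (21, 11, 3), half_size=(1.5, 3, 4)),
        ROISpec("b1", "box", (11, 1, 3), half_size=(3, 1.5, 4)),
        ROISpec("b2", "box", (11, 21, 3), half_size=(3, 1.5, 4)),
    )
    ph["CROSS90"] = PhantomSpec(
        "CROSS90", (12, 12, 4), vs, bundles, rois, snr=snr, seed=seed
    )

    # BRANCH: stem along x forking at (11, 8, 3) into +/-20 deg branches
    ang = np.radians(20.0)
    fork = np.array([11.0, 8.0, 3.0])
    d1 = np.array([np.cos(ang), np.sin(ang), 0.0])
    d2 = np.array([np.cos(ang), -np.sin(ang), 0.0])
    end1, end2 = fork + 12 * d1, fork + 12 * d2
    bundles = (
        Bundle("stem", _line((-2, 8, 3), fork), r),
        Bundle("branch1", np.array([fork, end1 + 2 * d1]), r),
        Bundle("branch2", np.array([fork, end2 + 2 * d2]), r),
    )
    rois = (
        ROISpec("stem", "box", (1, 8, 3), half_size=(1.5, 3, 4)),
        ROISpec("branch1", "sphere", end1, radius=2.5),
        ROISpec("branch2", "sphere", end2, radius=2.5),
    )
    ph["BRANCH"] = PhantomSpec(
        "BRANCH", (13, 9, 4), vs, bundles, rois, snr=snr, seed=seed
    )

    # CURVE: quarter-circle of radius 10 mm from (3, 1) (tangent +x) to
    # (13, 11) (tangent +y); per-0.25 mm-step turn is ~1.4 deg
    arc_c = np.array([3.0, 11.0, 3.0])
    theta = np.linspace(-np.pi / 2, 0.0, 61)
    arc = arc_c + 10.0 * np.column_stack(
        [np.sin(theta + np.pi / 2), np.sin(theta), np.zeros_like(theta)]
    )
    bundles = (Bundle("curve", arc, r),)
    rois = (
        ROISpec("start", "sphere", arc[0], radius=2.5),
        ROISpec("end", "sphere", arc[-1], radius=2.5),
    )
    ph["CURVE"] = PhantomSpec(
        "CURVE", (10, 8, 4), vs, bundles, rois, snr=snr, seed=seed
    )

    # DISJOINT: two parallel bundles along x at y = 3 and y = 11
    bundles = (
        Bundle("one", _line((-2, 3, 3), (22, 3, 3)), r),
        Bundle("two", _line((-2, 11, 3), (22, 11, 3)), r),
    )
    rois = (
        ROISpec("roi_a", "box", (17, 3, 3), half_size=(1.5, 3, 4)),
        ROISpec("roi_b", "box", (17, 11, 3), half_size=(1.5, 3, 4)),
    )
    ph["DISJOINT"] = PhantomSpec(
        "DISJOINT", (10, 8, 4), vs, bundles, rois, snr=snr, seed=seed
    )
    return ph


# ---------------------------------------------------------------------------
# YAML serialization


def _roi_to_dict(r: ROISpec) -> dict:
    d = {"name": r.name, "kind": r.kind, "center": [float(x) for x in r.center]}
    if r.kind == "box":
        d["half_size"] = [float(x) for x in r.half_size]
    else:
        d["radius"] = float(r.radius)
    return d


def spec_to_yaml(spec: PhantomSpec, path) -> None:
    doc = {
        "name": spec.name,
        "shape": list(spec.shape),
        "voxel_size": float(spec.voxel_size),
        "iso_diffusivity": float(spec.iso_diffusivity),
        "snr": "inf" if np.isinf(spec.snr) else float(spec.snr),
        "seed": int(spec.seed),
        "s0": float(spec.s0),
        "p": float(spec.p),
        "bundles": [
            {
                "name": b.name,
                "centerline": [[float(x) for x in p] for p in b.centerline],
                "radius": float(b.radius),
                "axial_diffusivity": float(b.axial_diffusivity),
                "radial_diffusivity": float(b.radial_diffusivity),
                "volume_fraction": b.volume_fraction,
            }
            for b in spec.bundles
        ],
        "rois": [_roi_to_dict(r) for r in spec.rois],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def spec_from_yaml(path) -> PhantomSpec:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    bundles = tuple(
        Bundle(
            name=b["name"],
            centerline=np.asarray(b["centerline"], dtype=float),
            radius=float(b["radius"]),
            axial_diffusivity=float(b.get("axial_diffusivity",
                                          DEFAULT_EIGENVALUES[0])),
            radial_diffusivity=float(b.get("radial_diffusivity",
                                           DEFAULT_EIGENVALUES[1])),
            volume_fraction=b.get("volume_fraction"),
        )
        for b in doc["bundles"]
    )
    rois = tuple(
        ROISpec(
            name=r["name"], kind=r["kind"], center=np.asarray(r["center"]),
            half_size=r.get("half_size"), radius=r.get("radius"),
        )
        for r in doc.get("rois", [])
    )
    return PhantomSpec(
        name=doc["name"],
        shape=tuple(doc["shape"]),
        voxel_size=float(doc["voxel_size"]),
        bundles=bundles,
        rois=rois,
        iso_diffusivity=float(doc.get("iso_diffusivity",
                                      DEFAULT_ISO_DIFFUSIVITY)),
        snr=float(doc.get("snr", DEFAULT_SNR)),
        seed=int(doc.get("seed", 0)),
        s0=float(doc.get("s0", DEFAULT_S0)),
        p=float(doc.get("p", DEFAULT_P)),
    )
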