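"""Dense seeding and deterministic bidirectional streamline propagation.

Each brain voxel is seeded with a 4x4x4 lattice of points (64 seeds/voxel)
at fractional offsets (k + 0.5)/4, forming a globally uniform field that is
continuous across voxel boundaries.  From each seed a streamline is launched
bidirectionally along a PDF maximum of the seed voxel and stepped by Euler
integration in 0.25 mm increments.  At every step the direction is the
current voxel's peak most inline with the direction of travel (maximal
|dot|; ties broken by higher PDF value).  Propagation stops when the
required turn exceeds 50 degrees, the streamline leaves the brain mask,
enters a stop mask, or reaches a voxel with no peaks.  Fractional anisotropy
plays no role in any stopping decision; it is ambiguous in crossing-fiber
voxels, which is precisely where a multi-peak model must keep going.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dwi_io import BinaryMask
from .peaks import PeaksField

__all__ = [
    "TrackingConfig",
    "Streamline",
    "Tractogram",
    "generate_seeds",
    "propagate",
    "track_whole_brain",
]

REASONS = ("angle", "brain_boundary", "stop_mask", "max_steps", "no_peak")


@dataclass(frozen=True)
class TrackingConfig:
    """Propagation parameters.

    step in mm; max_turn in degrees per step; seeds_per_voxel must be a
    perfect cube (a lattice); seed_mode is "per-peak" (one bidirectional
    streamline per seed-voxel maximum) or "primary" (largest maximum only).
    """

    step: float = 0.25
    max_turn: float = 50.0
    seeds_per_voxel: int = 64
    max_steps: int = 2000
    min_points: int = 2
    seed_mode: str = "per-peak"
    stop_masks: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0 < self.step <= 1:
            raise ValueError(f"step must be in (0, 1] mm, got {self.step}")
        if not 0 < self.max_turn < 90:
            raise ValueError(f"max_turn must be in (0, 90) deg, got {self.max_turn}")
        n = round(self.seeds_per_voxel ** (1 / 3))
        if n**3 != self.seeds_per_voxel:
            raise ValueError(
                f"seeds_per_voxel must be a perfect cube, got {self.seeds_per_voxel}"
            )
        if self.seed_mode not in ("per-peak", "primary"):
            raise ValueError(f"unknown seed_mode {self.seed_mode!r}")

    @property
    def lattice_n(self) -> int:
        return round(self.seeds_per_voxel ** (1 / 3))


@dataclass
class Streamline:
    """Ordered world-mm points with provenance."""

    points: np.ndarray
    seed_index: int = -1
    reasons: tuple = ("", "")  # (backward, forward) termination reasons

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class Tractogram:
    streamlines: list
    affine: np.ndarray | None = None
    shape: tuple | None = None
    config: TrackingConfig | None = None

    def __len__(self) -> int:
        return len(self.streamlines)

    def termination_histogram(self) -> dict:
        hist = {r: 0 for r in REASONS}
        for s in self.streamlines:
            for r in s.reasons:
                if r:
                    hist[r] = hist.get(r, 0) + 1
        return hist


def generate_seeds(brain: BinaryMask, cfg: TrackingConfig) -> np.ndarray:
    """Uniform seed lattice over the brain mask, in world mm.

    Within each voxel the lattice sits at voxel-coordinate offsets
    (k + 0.5)/n - 0.5, so the spacing equals voxel/n both inside a voxel and
    across voxel boundaries.  Ordering is deterministic: voxels in index
    order, offsets in lattice order.
    """
    n = cfg.lattice_n
    voxels = np.argwhere(brain.data)
    if len(voxels) == 0:
        return np.empty((0, 3))
    off = (np.arange(n) + 0.5) / n - 0.5
    oi, oj, ok = np.meshgrid(off, off, off, indexing="ij")
    offsets = np.column_stack([oi.ravel(), oj.ravel(), ok.ravel()])
    coords = (voxels[:, None, :] + offsets[None, :, :]).reshape(-1, 3)
    return coords @ brain.affine[:3, :3].T + brain.affine[:3, 3]


class _Grid:
    """Cached nearest-voxel peak lookup for one peaks field."""

    def __init__(self, pf: PeaksField):
        self.pf = pf
        self.inv = np.linalg.inv(pf.affine)
        self.shape = np.array(pf.shape)

    def voxel_of(self, p: np.ndarray):
        ijk = np.round(self.inv[:3, :3] @ p + self.inv[:3, 3]).astype(int)
        if np.any(ijk < 0) or np.any(ijk >= self.shape):
            return None
        return tuple(ijk)

    def peaks_at(self, ijk):
        d, v = self.pf.voxel_peaks(*ijk)
        if np.any(~np.isfinite(d)):
            return None  # corrupted voxel: flagged, treated as trackless
        return d, v


def _pick_direction(direction, peak_dirs, peak_vals, cos_max_turn):
    """Most-inline peak: maximal |dot|, ties by higher PDF value then rank."""
    dots = peak_dirs @ direction
    score = np.abs(dots)
    best = np.flatnonzero(score >= score.max() - 1e-9)
    if len(best) > 1:  # tie: highest PDF value, then peak rank (= array order)
        best = best[np.argsort(-peak_vals[best], kind="stable")]
    m = int(best[0])
    chosen = -peak_dirs[m] if dots[m] < 0 else peak_dirs[m]
    cos_turn = float(chosen @ direction)
    if cos_turn < cos_max_turn:
        return None
    return chosen


def _march(start, d0, grid: _Grid, brain: BinaryMask, cfg: TrackingConfig):
    """March one direction; returns (points beyond start, reason)."""
    cos_max = np.cos(np.radians(cfg.max_turn))
    inv_brain = np.linalg.inv(brain.affine)
    bshape = np.array(brain.shape)
    stop_masks = list(cfg.stop_masks.values())

    pos = np.asarray(start, dtype=float)
    d = np.asarray(d0, dtype=float)
    pts = []
    last_ijk = None
    cached = None
    for _ in range(cfg.max_steps):
        ijk = grid.voxel_of(pos)
        if ijk is None:
            return pts, "brain_boundary"
        if ijk != last_ijk:
            cached = grid.peaks_at(ijk)
            last_ijk = ijk
        if cached is None or len(cached[0]) == 0:
            return pts, "no_peak"
        step_dir = _pick_direction(d, cached[0], cached[1], cos_max)
        if step_dir is None:
            return pts, "angle"
        nxt = pos + cfg.step * step_dir
        bijk = np.round(inv_brain[:3, :3] @ nxt + inv_brain[:3, 3]).astype(int)
        outside = np.any(bijk < 0) or np.any(bijk >= bshape) or not brain.data[
            bijk[0], bijk[1], bijk[2]
        ]
        if outside:
            return pts, "brain_boundary"
        in_stop = any(m.contains_points(nxt[None])[0] for m in stop_masks)
        pts.append(nxt)
        if in_stop:
            return pts, "stop_mask"
        d = step_dir
        pos = nxt
    return pts, "max_steps"


def propagate(
    seed,
    peaks_field: PeaksField,
    brain: BinaryMask,
    cfg: TrackingConfig | None = None,
    peak_index: int = 0,
    seed_index: int = -1,
) -> Streamline:
    """Launch one bidirectional streamline from a seed point (world mm).

    The initial direction is the seed voxel's ``peak_index``-th PDF maximum;
    the two half-streamlines (along +/- that axis) are concatenated with the
    backward half reversed.  A seed in a voxel with no usable peak returns a
    zero-length (single-point) streamline with reason "no_peak".
    """
    cfg = cfg or TrackingConfig()
    seed = np.asarray(seed, dtype=float)
    if not brain.contains_points(seed[None])[0]:
        raise ValueError("seed lies outside the brain mask")
    grid = _Grid(peaks_field)
    ijk = grid.voxel_of(seed)
    peaks = grid.peaks_at(ijk) if ijk is not None else None
    if peaks is None or len(peaks[0]) <= peak_index:
        return Streamline(
            points=seed[None, :].copy(), seed_index=seed_index,
            reasons=("no_peak", "no_peak"),
        )
    d0 = peaks[0][peak_index]
    fwd, fwd_reason = _march(seed, d0, grid, brain, cfg)
    bwd, bwd_reason = _march(seed, -d0, grid, brain, cfg)
    points = np.array(bwd[::-1] + [seed] + fwd)
    return Streamline(
        points=points, seed_index=seed_index, reasons=(bwd_reason, fwd_reason)
    )


def track_whole_brain(
    peaks_field: PeaksField,
    brain: BinaryMask,
    cfg: TrackingConfig | None = None,
) -> Tractogram:
    """Propagate from every seed (and, in per-peak mode, every seed-voxel
    maximum); streamlines shorter than ``cfg.min_points`` are discarded."""
    cfg = cfg or TrackingConfig()
    seeds = generate_seeds(brain, cfg)
    grid = _Grid(peaks_field)
    streamlines = []
    for si, seed in enumerate(seeds):
        ijk = grid.voxel_of(seed)
        if ijk is None:
            continue
        peaks = grid.peaks_at(ijk)
        n_peaks = 0 if peaks is None else len(peaks[0])
        if n_peaks == 0:
            continue
        n_launch = n_peaks if cfg.seed_mode == "per-peak" else 1
        for pi in range(n_launch):
            s = propagate(
                seed, peaks_field, brain, cfg, peak_index=pi, seed_index=si
            )
            if len(s) >= cfg.min_points:
                streamlines.append(s)
    return Tractogram(
        streamlines=streamlines,
        affine=peaks_field.affine.copy(),
        shape=tuple(peaks_field.shape),
        config=cfg,
    )
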