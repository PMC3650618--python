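"""ROI-based streamline selection, track volumes and their summary stats.

A streamline belongs to a pathway when at least one of its points falls in
every inclusion mask and none falls in any exclusion mask (nearest-voxel
lookup).  The volume of a pathway is the binary visitation map of its
streamlines on the reference grid times the voxel volume, in mm^3.  Pathway
volumes across participants are summarized as mean and sample (n-1) standard
deviation, with untraceable participants counted as zeros.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dwi_io import BinaryMask, world_to_voxel
from .errors import GridMismatchError
from .tracking import Tractogram

__all__ = [
    "PathwaySelection",
    "filter_streamlines",
    "track_volume",
    "summarize_volumes",
    "reference_track_volumes",
]


@dataclass(frozen=True)
class PathwaySelection:
    """Named inclusion and exclusion masks defining one pathway."""

    include: dict
    exclude: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.include:
            raise ValueError("at least one inclusion mask is required")
        overlap = set(self.include) & set(self.exclude)
        if overlap:
            raise ValueError(
                f"masks cannot be both included and excluded: {sorted(overlap)}"
            )


def _check_grid(mask: BinaryMask, t: Tractogram, name: str) -> None:
    if t.affine is None or t.shape is None:
        return  # tractogram carries no grid (e.g. read from .tck): trust caller
    if not mask.same_grid(t.affine, t.shape):
        raise GridMismatchError(
            f"mask {name!r} is not on the tractogram's reference grid"
        )


def filter_streamlines(t: Tractogram, sel: PathwaySelection) -> Tractogram:
    """Keep streamlines touching every include mask and no exclude mask."""
    for name, m in {**sel.include, **sel.exclude}.items():
        _check_grid(m, t, name)
    kept = []
    for s in t.streamlines:
        pts = s.points
        if all(np.any(m.contains_points(pts)) for m in sel.include.values()) \
                and not any(np.any(m.contains_points(pts))
                            for m in sel.exclude.values()):
            kept.append(s)
    return Tractogram(streamlines=kept, affine=t.affine, shape=t.shape,
                      config=t.config)


def track_volume(t: Tractogram, affine=None, shape=None) -> float:
    """Volume (mm^3) of the set of reference-grid voxels visited by the
    tractogram: distinct-voxel count x voxel volume.  Invariant to streamline
    order and duplication; an empty tractogram has volume 0."""
    affine = t.affine if affine is None else np.asarray(affine, dtype=float)
    shape = t.shape if shape is None else tuple(shape)
    if affine is None or shape is None:
        raise ValueError("tractogram carries no reference grid")
    if not t.streamlines:
        return 0.0
    pts = np.vstack([s.points for s in t.streamlines])
    ijk = world_to_voxel(pts, affine)
    inside = np.all((ijk >= 0) & (ijk < np.array(shape)), axis=1)
    visited = np.unique(ijk[inside], axis=0)
    voxel_volume = float(abs(np.linalg.det(affine[:3, :3])))
    return len(visited) * voxel_volume


def summarize_volumes(table: pd.DataFrame, decimals: int = 1) -> pd.DataFrame:
    """Per-pathway mean and sample (n-1) standard deviation of track volumes.

    Rows are participants, columns are pathways; zeros (participants in whom
    no pathway could be traced) are real observations and enter the average.
    """
    if len(table) < 2:
        raise ValueError(
            "need at least 2 participants for a sample standard deviation"
        )
    out = pd.DataFrame(
        {"mean": table.mean(axis=0), "sd": table.std(axis=0, ddof=1)}
    ).T
    return out.round(decimals)


def reference_track_volumes() -> pd.DataFrame:
    """Published per-participant track volumes (mm^3) for the four pathways
    between Broca's area subdivisions (pars triangularis / pars opercularis)
    and the putamen / thalamus, in ten participants.  Zeros mark participants
    in whom a pathway could not be traced."""
    data = {
        "triangularis_putamen": [1913, 1539, 2439, 766, 841,
                                 2482, 1341, 1622, 1670, 562],
        "triangularis_thalamus": [2594, 1730, 3439, 2479, 863,
                                  0, 1849, 0, 1302, 1874],
        "opercularis_putamen": [1337, 1148, 2468, 2083, 811,
                                1534, 605, 870, 2171, 379],
        "opercularis_thalamus": [342, 382, 2996, 2045, 901,
                                 0, 0, 0, 170, 0],
    }
    return pd.DataFrame(data, index=pd.RangeIndex(1, 11, name="participant"),
                        dtype=float)
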