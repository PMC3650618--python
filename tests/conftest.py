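"""Session-scoped fixtures: tessellations, the Wishart basis, and fully
processed phantom pipelines (simulate at 2 mm -> resample to 1 mm -> MOW fit
-> peak extraction) reused across the test modules."""

from types import SimpleNamespace

import numpy as np
import pytest

from mowtrack import (
    BinaryMask,
    Bundle,
    PhantomSpec,
    TrackingConfig,
    build_basis,
    fit_volume,
    icosphere,
    rasterize_roi,
    resample_isotropic,
    simulate_dwi,
    standard_phantoms,
    track_whole_brain,
)
from mowtrack.peaks import compute_peaks_field
from mowtrack.phantom import (
    _bundle_membership,
    _voxel_centers,
    ground_truth_directions,
)

# The isotropy filter (max/mean PDF contrast) used when tracking phantoms:
# background voxels are isotropic by construction and carry no direction.
ISO_RATIO = 1.02
TEST_CFG = TrackingConfig(seeds_per_voxel=8)


@pytest.fixture(scope="session")
def tess1():
    return icosphere(1)


@pytest.fixture(scope="session")
def tess2():
    return icosphere(2)


@pytest.fixture(scope="session")
def tess3():
    return icosphere(3)


@pytest.fixture(scope="session")
def basis():
    return build_basis()


def run_pipeline(spec, basis, resample_mm=1.0):
    """Simulate a phantom and run it through fit + peak extraction."""
    vol, gtab, brain, _, gt = simulate_dwi(spec)
    if resample_mm is not None:
        vol1 = resample_isotropic(vol, resample_mm)
    else:
        vol1 = vol
    gt1 = ground_truth_directions(spec, vol1.shape, vol1.affine)
    wf = fit_volume(vol1, gtab, basis)
    pf = compute_peaks_field(wf, basis, min_peak_ratio=ISO_RATIO)
    rois = {
        r.name: rasterize_roi(r, vol1.shape, vol1.affine) for r in spec.rois
    }
    centers = _voxel_centers(vol1.shape, vol1.affine)
    in_bundle = {}
    for b in spec.bundles:
        inside, _ = _bundle_membership(b, centers, spec.voxel_size / 4)
        in_bundle[b.name] = inside.reshape(vol1.shape)
    return SimpleNamespace(
        spec=spec,
        vol=vol,
        gtab=gtab,
        vol1=vol1,
        gt1=gt1,
        wf=wf,
        pf=pf,
        rois=rois,
        affine=vol1.affine,
        shape=vol1.shape,
        brain=BinaryMask(np.ones(vol1.shape, dtype=bool), vol1.affine),
        bundle_mask=BinaryMask(gt1.counts > 0, vol1.affine),
        in_bundle=in_bundle,
    )


def _std_run(name, basis):
    return run_pipeline(standard_phantoms()[name], basis)


@pytest.fixture(scope="session")
def straight_run(basis):
    return _std_run("STRAIGHT", basis)


@pytest.fixture(scope="session")
def cross_run(basis):
    return _std_run("CROSS90", basis)


@pytest.fixture(scope="session")
def branch_run(basis):
    return _std_run("BRANCH", basis)


@pytest.fixture(scope="session")
def disjoint_run(basis):
    return _std_run("DISJOINT", basis)


@pytest.fixture(scope="session")
def curve_run(basis):
    return _std_run("CURVE", basis)


@pytest.fixture(scope="session")
def straight_tract(straight_run):
    return track_whole_brain(straight_run.pf, straight_run.bundle_mask, TEST_CFG)


def oblique_single_fiber_spec(direction, shape=(9, 9, 9), snr=np.inf, seed=7):
    """A single-fiber phantom whose bundle fills the whole (1 mm) grid along
    an oblique, non-grid-aligned axis."""
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    c = (np.asarray(shape, dtype=float) - 1) / 2
    return PhantomSpec(
        name="OBLIQUE",
        shape=shape,
        voxel_size=1.0,
        bundles=(Bundle("fiber", np.array([c - 20 * d, c + 20 * d]), 10.0),),
        snr=snr,
        seed=seed,
    )


@pytest.fixture(scope="session")
def snr30_run(basis):
    """>= 500 single-fiber voxels at Rician SNR 30 (fit at native 1 mm)."""
    spec = oblique_single_fiber_spec((2.0, 1.0, 0.5), snr=30.0)
    return run_pipeline(spec, basis, resample_mm=None)
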