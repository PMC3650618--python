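import numpy as np
import pytest
from scipy.optimize import nnls

from mowtrack import build_basis, design_matrix, evaluate_pdf, fit_weights
from mowtrack.geometry import axial_angle, icosphere
from mowtrack.mow import PDFConfig, fit_volume, normalize_signal, pdf_kernel
from mowtrack.phantom import default_scheme

from _helpers import random_sparse_weights


@pytest.fixture(scope="module")
def gtab():
    return default_scheme()


@pytest.fixture(scope="module")
def design(gtab, basis):
    return design_matrix(gtab, basis)


def _embed(gtab, s_weighted):
    """Full-length normalized signal with unit b0 rows."""
    s = np.ones(gtab.n_volumes)
    s[~gtab.is_b0] = s_weighted
    return s


# ---------------------------------------------------------------------------
# basis


def test_basis_tensor_invariants(basis):
    evals = np.sort(np.linalg.eigvalsh(basis.tensors), axis=1)
    assert np.allclose(evals, np.array([0.4, 0.4, 1.5]) * 1e-3, atol=1e-12)
    assert np.allclose(
        basis.tensors.trace(axis1=1, axis2=2), 2.3e-3, atol=1e-12
    )
    assert np.allclose(
        np.linalg.det(basis.tensors), 1.5 * 0.4 * 0.4 * 1e-9, atol=1e-18
    )
    # principal eigenvector equals the basis direction (arccos resolution)
    for d, t in zip(basis.basis_dirs, basis.tensors):
        w, v = np.linalg.eigh(t)
        assert axial_angle(v[:, -1], d) < 1e-5


def test_basis_requires_level2():
    with pytest.raises(ValueError):
        build_basis(icosphere(1))
    with pytest.raises(ValueError):
        build_basis(eigenvalues=(1.5, -0.4, 0.4))


def test_basis_atom_along_z(basis):
    j = int(np.argmax(np.abs(basis.basis_dirs @ [0, 0, 1])))
    assert axial_angle(basis.basis_dirs[j], [0, 0, 1]) < 1e-9
    assert np.allclose(basis.tensors[j], np.diag([0.4, 0.4, 1.5]) * 1e-3,
                       atol=1e-12)


# ---------------------------------------------------------------------------
# design matrix and NNLS fit


def test_design_matrix_entries(gtab, basis, design):
    assert design.shape == (70, 162)  # b0 rows are the normalizer, not rows
    assert np.all(design > 0) and np.all(design <= 1)
    # spot value: gradient parallel to an atom's principal axis at b = 1000
    bsel = gtab.bvals[~gtab.is_b0]
    gsel = gtab.bvecs[~gtab.is_b0]
    i = int(np.argmax(bsel))
    j = int(np.argmax(np.abs(basis.basis_dirs @ gsel[i])))
    cos2 = float(basis.basis_dirs[j] @ gsel[i]) ** 2
    expected = (1 + 1000 * (1.5 * cos2 + 0.4 * (1 - cos2)) * 1e-3 / 2) ** -2
    assert design[i, j] == pytest.approx(expected, rel=1e-12)


@pytest.mark.parametrize("j", [0, 37, 101, 161])
def test_single_atom_recovery(gtab, basis, design, j):
    w, flagged, _ = fit_weights(_embed(gtab, design[:, j]), gtab, basis,
                                design=design)
    assert not flagged
    assert np.linalg.norm(design @ w - design[:, j]) < 1e-8
    # recovered orientation: weight-weighted mean of the dominant atoms
    top = w > 0.1 * w.max()
    dirs = basis.basis_dirs[top]
    signs = np.sign(dirs @ basis.basis_dirs[j])
    mean_dir = (w[top][:, None] * signs[:, None] * dirs).sum(axis=0)
    mean_dir /= np.linalg.norm(mean_dir)
    assert axial_angle(mean_dir, basis.basis_dirs[j]) < 8.0


def test_two_atom_mixture_recovers_both(gtab, basis, design):
    dots = np.abs(basis.basis_dirs @ basis.basis_dirs[0])
    k = int(np.argmin(dots))  # atom most orthogonal to atom 0
    s = 0.5 * (design[:, 0] + design[:, k])
    w, _, _ = fit_weights(_embed(gtab, s), gtab, basis, design=design)
    for target in (0, k):
        near = np.abs(basis.basis_dirs @ basis.basis_dirs[target]) > np.cos(
            np.radians(20)
        )
        assert w[near].sum() > 0.25  # a weight cluster around each true atom


def test_flat_signal_fits_near_isotropic(gtab, basis, design):
    s = np.ones(gtab.n_volumes)
    w, flagged, _ = fit_weights(s, gtab, basis, design=design)
    assert not flagged
    resid = np.linalg.norm(design @ w - s[~gtab.is_b0])
    # better than the best single-atom fit
    best_single = np.inf
    target = s[~gtab.is_b0]
    for j in range(design.shape[1]):
        a = design[:, j]
        alpha = max(0.0, float(a @ target) / float(a @ a))
        best_single = min(best_single, np.linalg.norm(alpha * a - target))
    assert resid < best_single
    assert resid <= np.linalg.norm(target)  # never worse than the zero fit


def test_degenerate_signals_flagged(gtab, basis, design):
    w, flagged, _ = fit_weights(np.zeros(gtab.n_volumes), gtab, basis,
                                design=design)
    assert flagged and np.all(w == 0)
    s = np.ones(gtab.n_volumes)
    s[5] = np.nan
    w, flagged, _ = fit_weights(s, gtab, basis, design=design)
    assert flagged and np.all(w == 0)
    s = np.ones(gtab.n_volumes)
    s[10] = -0.2  # noise can push normalized samples below zero
    w, flagged, n_clipped = fit_weights(s, gtab, basis, design=design)
    assert not flagged and n_clipped == 1


def test_nnls_residual_monotone_in_dictionary_size(gtab, basis, design):
    # adding atoms never increases the optimal residual
    rng = np.random.default_rng(2)
    s = design @ random_sparse_weights(rng) + rng.normal(0, 0.01, 70)
    atoms = rng.choice(162, size=12, replace=False)
    prev = np.inf
    for k in range(4, 13, 4):
        _, resid = nnls(design[:, atoms[:k]], s)
        assert resid <= prev + 1e-12
        prev = resid


# ---------------------------------------------------------------------------
# PDF evaluation


def test_pdf_single_atom_peak(basis, tess3):
    j = int(np.argmax(np.abs(basis.basis_dirs @ [0, 0, 1])))
    w = np.zeros(162)
    w[j] = 1.0
    pdf = evaluate_pdf(w, basis)
    peak = tess3.vertices[int(np.argmax(pdf))]
    assert axial_angle(peak, [0, 0, 1]) < 1e-9


def test_pdf_uniform_weights_near_isotropic(basis):
    pdf = evaluate_pdf(np.ones(162), basis)
    assert float(pdf.max() / pdf.min()) < 1.05


def test_pdf_antipodal_symmetry_exact(basis, tess3):
    rng = np.random.default_rng(3)
    kernel = pdf_kernel(basis)
    v = tess3.vertices
    # pair each vertex with its exact antipode
    anti = np.argmin(np.linalg.norm(v[:, None, :] + v[None, :, :], axis=2),
                     axis=1)
    for _ in range(20):
        pdf = kernel @ random_sparse_weights(rng)
        assert np.all(pdf > 0)
        # symmetric to rounding error (far tighter than the 1e-9 contract)
        assert np.allclose(pdf, pdf[anti], rtol=1e-12, atol=0)


def test_pdf_peak_location_insensitive_to_diffusion_time(basis, tess3):
    # Diffusion time only rescales per-atom contrast, so for resolvable
    # mixtures the peak set that tracking consumes is stable across t: same
    # peak count, every peak matched far inside the 15-degree dedup
    # tolerance.  (Longer t flattens the displacement profile and lowers
    # angular resolution: lobes closer than ~75 degrees can merge at
    # t = 40 ms.  The *global* argmax may also hop between near-equal lobes;
    # neither affects which directions are available to the tracker.)
    from mowtrack.peaks import find_maxima

    rng = np.random.default_rng(4)
    dirs = basis.basis_dirs
    for _ in range(20):
        w = np.zeros(162)
        j = rng.integers(162)
        w[j] = rng.uniform(0.5, 1.0)
        if rng.random() < 0.5:  # add a second, resolvable atom (>= 75 deg)
            far = np.flatnonzero(np.abs(dirs @ dirs[j]) < np.cos(np.radians(75)))
            w[rng.choice(far)] = rng.uniform(0.5, 1.0)
        peak_sets = [
            find_maxima(evaluate_pdf(w, basis, PDFConfig(t_ms=t)), tess3)
            for t in (15.0, 25.0, 40.0)
        ]
        ref = peak_sets[0]
        for ps in peak_sets[1:]:
            assert len(ps) == len(ref)
            for d in ps.directions:
                assert min(axial_angle(d, r) for r in ref.directions) < 15.0


def test_pdf_config_validation(basis):
    with pytest.raises(ValueError):
        PDFConfig(t_ms=0.0)
    with pytest.raises(ValueError):
        evaluate_pdf(-np.ones(162), basis)


# ---------------------------------------------------------------------------
# volume-level fit


def test_fit_volume_flags_background(gtab, basis):
    from mowtrack.dwi_io import DWIVolume

    data = np.zeros((2, 2, 1, gtab.n_volumes))
    data[0, 0, 0] = 1000.0  # flat voxel
    vol = DWIVolume(data=data, affine=np.eye(4))
    wf = fit_volume(vol, gtab, basis)
    assert not wf.flags[0, 0, 0]
    assert np.all(wf.flags[1:, :, 0] | (wf.weights[1:, :, 0].sum(-1) == 0))


def test_normalize_signal_uses_mean_b0(gtab):
    data = np.ones((1, 1, 1, gtab.n_volumes)) * 500.0
    data[..., gtab.is_b0] = 1000.0
    s = normalize_signal(data, gtab)
    assert np.allclose(s[0, 0, 0, ~gtab.is_b0], 0.5)
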