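"""Per-voxel fiber-orientation estimation by mixture-of-Wisharts (MOW)
spherical deconvolution.

Model
-----
The ensemble of diffusion tensors in a voxel is modelled as a mixture of
Wishart distributions whose expected tensors form a fixed dictionary: 162
rank-2 tensors with eigenvalues (1.5, 0.4, 0.4) um^2/ms and principal
eigenvectors on the level-2 icosphere.  The Laplace transform of a Wishart
gives the closed-form attenuation of each dictionary atom,

    E_j(b, g) = (1 + b g^T (D_j / p) g)^(-p),

where ``p`` is the Wishart shape parameter and D_j the expected tensor.
Mixture weights are recovered per voxel with non-negative least squares
(Lawson-Hanson active set), which is sparse and robust to noise.  The
water-displacement probability at radius ``r`` and diffusion time ``t``
(t = Delta - delta/3) is then the corresponding Gaussian mixture

    P(r u) = sum_j w_j (4 pi t)^(-3/2) |D_j|^(-1/2)
             exp(-r^2 u^T D_j^{-1} u / (4 t)),

evaluated on the 642 level-3 icosphere directions; its maxima are the fiber
orientations.

Units: tensors are stored in mm^2/s (um^2/ms x 1e-3), b in s/mm^2, r in um,
t in ms; everything is converted internally so b.D and r^2/(t.D) are
dimensionless.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

from .dwi_io import DWIVolume, GradientTable, BinaryMask
from .geometry import SphereTessellation, icosphere

__all__ = [
    "WishartBasis",
    "PDFConfig",
    "WeightField",
    "build_basis",
    "design_matrix",
    "normalize_signal",
    "fit_weights",
    "fit_volume",
    "pdf_kernel",
    "evaluate_pdf",
]

DEFAULT_EIGENVALUES = (1.5, 0.4, 0.4)  # um^2/ms, single-fiber atom
DEFAULT_P = 2.0  # Wishart shape parameter
UM2_PER_MS_TO_MM2_PER_S = 1e-3


@dataclass(frozen=True)
class WishartBasis:
    """The deconvolution dictionary: 162 expected diffusion tensors."""

    tensors: np.ndarray       # (162, 3, 3), mm^2/s
    basis_dirs: np.ndarray    # (162, 3) principal eigenvectors
    eigenvalues: tuple        # um^2/ms
    p: float

    @property
    def n_atoms(self) -> int:
        return len(self.tensors)


@dataclass(frozen=True)
class PDFConfig:
    """Displacement-PDF evaluation parameters.

    ``t_ms`` is the effective diffusion time t = Delta - delta/3; ``r_um``
    the displacement probe radius.  Peak *locations* on this basis are
    insensitive to both; they only rescale the PDF contrast.
    """

    t_ms: float = 20.0
    r_um: float = 12.0
    eval_level: int = 3

    def __post_init__(self):
        if self.t_ms <= 0:
            raise ValueError(f"diffusion time must be positive, got {self.t_ms}")
        if self.r_um <= 0:
            raise ValueError(f"probe radius must be positive, got {self.r_um}")


@dataclass
class WeightField:
    """Per-voxel NNLS weights on the dictionary atoms."""

    weights: np.ndarray       # (X, Y, Z, n_atoms)
    affine: np.ndarray
    flags: np.ndarray         # (X, Y, Z) bool: True where the fit was degenerate
    n_clipped: int = 0        # negative normalized samples clipped to zero


def _rotation_to(direction: np.ndarray) -> np.ndarray:
    """Deterministic rotation taking +z to ``direction``."""
    d = direction / np.linalg.norm(direction)
    z = np.array([0.0, 0.0, 1.0])
    c = np.cross(z, d)
    nc = np.linalg.norm(c)
    if nc < 1e-12:
        e1 = np.array([1.0, 0.0, 0.0])
    else:
        e1 = c / nc
    e2 = np.cross(d, e1)
    return np.column_stack([e1, e2, d])


def build_basis(
    tessellation: SphereTessellation | None = None,
    eigenvalues=DEFAULT_EIGENVALUES,
    p: float = DEFAULT_P,
) -> WishartBasis:
    """Create the 162-tensor dictionary from the level-2 icosphere."""
    if tessellation is None:
        tessellation = icosphere(2)
    if tessellation.n_vertices != 162:
        raise ValueError(
            "basis requires the level-2 tessellation (162 vertices), got "
            f"{tessellation.n_vertices}"
        )
    lam = np.asarray(eigenvalues, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("eigenvalues must be positive")
    if p < 1:
        raise ValueError(f"Wishart shape parameter must be >= 1, got {p}")
    dirs = tessellation.vertices
    tensors = np.empty((len(dirs), 3, 3))
    diag = np.diag([lam[1], lam[2], lam[0]])  # principal axis along local z
    for j, d in enumerate(dirs):
        r = _rotation_to(d)
        tensors[j] = r @ diag @ r.T * UM2_PER_MS_TO_MM2_PER_S
    return WishartBasis(
        tensors=tensors, basis_dirs=dirs.copy(),
        eigenvalues=tuple(lam), p=float(p),
    )


def wishart_attenuation(bvals, bvecs, tensors, p: float) -> np.ndarray:
    """Atom attenuations (1 + b g^T (D/p) g)^(-p), rows=volumes, cols=atoms."""
    bvals = np.asarray(bvals, dtype=float)
    bvecs = np.asarray(bvecs, dtype=float)
    quad = np.einsum("ik,jkl,il->ij", bvecs, tensors, bvecs)  # g^T D g
    return (1.0 + bvals[:, None] * quad / p) ** (-p)


def design_matrix(gtab: GradientTable, basis: WishartBasis) -> np.ndarray:
    """Design matrix over the diffusion-weighted (b > 0) volumes only.

    b0 volumes are the normalizer, not fit rows; low-b volumes enter as
    ordinary rows with their own b.
    """
    sel = ~gtab.is_b0
    return wishart_attenuation(
        gtab.bvals[sel], gtab.bvecs[sel], basis.tensors, basis.p
    )


def normalize_signal(data: np.ndarray, gtab: GradientTable) -> np.ndarray:
    """Divide by the mean baseline signal (mean over b0 volumes; falls back
    to low-b volumes when no b0 was acquired)."""
    base = gtab.is_b0 if np.any(gtab.is_b0) else gtab.is_lowb
    s0 = np.mean(np.asarray(data, dtype=float)[..., base], axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.asarray(data, dtype=float) / s0[..., None]


def fit_weights(
    signal: np.ndarray,
    gtab: GradientTable,
    basis: WishartBasis,
    design: np.ndarray | None = None,
):
    """NNLS fit of one voxel's normalized signal.

    ``signal`` is the full per-volume vector already divided by the mean b0;
    only b > 0 rows enter the fit.  Returns ``(w, flagged, n_clipped)``:
    degenerate voxels (all-zero or non-finite signal) come back flagged with
    w = 0 rather than raising, and negative normalized samples are clipped
    to zero (counted in ``n_clipped``).
    """
    signal = np.asarray(signal, dtype=float)
    a = design_matrix(gtab, basis) if design is None else design
    s = signal[~gtab.is_b0]
    if not np.all(np.isfinite(s)) or np.all(s == 0):
        return np.zeros(basis.n_atoms), True, 0
    n_clipped = int(np.sum(s < 0))
    if n_clipped:
        s = np.clip(s, 0.0, None)
    w, _ = nnls(a, s)
    return w, False, n_clipped


def fit_volume(
    vol: DWIVolume,
    gtab: GradientTable,
    basis: WishartBasis,
    mask: BinaryMask | None = None,
) -> WeightField:
    """Fit mixture weights for every voxel inside the mask."""
    if vol.n_volumes != gtab.n_volumes:
        raise ValueError("volume count does not match gradient table")
    shape = vol.shape
    inside = np.ones(shape, dtype=bool) if mask is None else mask.data
    normalized = normalize_signal(vol.data, gtab)
    a = design_matrix(gtab, basis)
    weights = np.zeros(shape + (basis.n_atoms,))
    flags = np.zeros(shape, dtype=bool)
    n_clipped = 0
    for ijk in np.argwhere(inside):
        i, j, k = ijk
        w, bad, nc = fit_weights(normalized[i, j, k], gtab, basis, design=a)
        weights[i, j, k] = w
        flags[i, j, k] = bad
        n_clipped += nc
    return WeightField(
        weights=weights, affine=vol.affine.copy(), flags=flags,
        n_clipped=n_clipped,
    )


def pdf_kernel(
    basis: WishartBasis,
    cfg: PDFConfig | None = None,
    eval_dirs: np.ndarray | None = None,
) -> np.ndarray:
    """Precompute the (n_dirs, n_atoms) map from weights to PDF values.

    Row k, column j holds the zero-mean Gaussian density of atom j at
    displacement r * u_k, so the voxel PDF is simply ``kernel @ w``.
    """
    cfg = cfg or PDFConfig()
    if eval_dirs is None:
        eval_dirs = icosphere(cfg.eval_level).vertices
    r_mm = cfg.r_um * 1e-3
    t_s = cfg.t_ms * 1e-3
    inv = np.linalg.inv(basis.tensors)           # (J, 3, 3), s/mm^2
    dets = np.linalg.det(basis.tensors)          # (J,)
    quad = np.einsum("ik,jkl,il->ij", eval_dirs, inv, eval_dirs)  # (K, J)
    norm = (4.0 * np.pi * t_s) ** (-1.5) / np.sqrt(dets)          # (J,)
    return norm[None, :] * np.exp(-(r_mm ** 2) * quad / (4.0 * t_s))


def evaluate_pdf(
    w: np.ndarray,
    basis: WishartBasis,
    cfg: PDFConfig | None = None,
    kernel: np.ndarray | None = None,
) -> np.ndarray:
    """Displacement-PDF values at the 642 evaluation directions.

    Antipodal symmetry P(u) = P(-u) is exact because each mixture component
    is a zero-mean Gaussian.
    """
    w = np.asarray(w, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    if kernel is None:
        kernel = pdf_kernel(basis, cfg)
    return kernel @ w
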