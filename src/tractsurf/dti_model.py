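"""Diffusion-tensor fitting and fractional anisotropy.

The single-tensor model: ``S_k = S0 * exp(-b_k g_k' D g_k)`` for gradient
direction ``g_k`` and b-value ``b_k``.  Fitting is log-linear least squares
per voxel — ``ln S = ln S0 - b g' D g`` is linear in the six unique tensor
components and ``ln S0`` — which recovers the tensor exactly from noiseless
signals.  FA is computed from the tensor eigenvalues.

The default acquisition scheme mirrors a clinical protocol: 30 directions
at b = 700 s/mm^2 plus 5 volumes at minimal weighting (b = 33 s/mm^2).
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class DwiScheme:
    """Gradient directions (unit vectors, (n, 3)) and b-values (s/mm^2, (n,))."""

    bvecs: np.ndarray
    bvals: np.ndarray

    def __post_init__(self) -> None:
        bvecs = np.asarray(self.bvecs, dtype=np.float64)
        bvals = np.asarray(self.bvals, dtype=np.float64)
        if bvecs.ndim != 2 or bvecs.shape[1] != 3 or len(bvecs) != len(bvals):
            raise ValueError("bvecs must be (n, 3) with one b-value per row")
        norms = np.linalg.norm(bvecs, axis=1)
        nz = norms > 0
        if not np.allclose(norms[nz], 1.0, atol=1e-6):
            raise ValueError("nonzero gradient directions must be unit vectors")
        object.__setattr__(self, "bvecs", bvecs)
        object.__setattr__(self, "bvals", bvals)

    @property
    def n_volumes(self) -> int:
        return len(self.bvals)


def default_scheme() -> DwiScheme:
    """30 quasi-uniform directions at b=700 plus 5 at b=33 along +z.

    Directions come from a Fibonacci sphere — deterministic and close to
    uniform without an electrostatic-repulsion optimization.
    """
    n = 30
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5 ** 0.5) * i
    dirs = np.stack([np.sin(phi) * np.cos(theta),
                     np.sin(phi) * np.sin(theta),
                     np.cos(phi)], axis=1)
    low = np.tile([0.0, 0.0, 1.0], (5, 1))
    bvecs = np.vstack([low, dirs])
    bvals = np.concatenate([np.full(5, 33.0), np.full(30, 700.0)])
    return DwiScheme(bvecs=bvecs, bvals=bvals)


def _design_matrix(scheme: DwiScheme) -> np.ndarray:
    """Rows ``[1, -b gx^2, -b gy^2, -b gz^2, -2b gx gy, -2b gx gz, -2b gy gz]``."""
    g = scheme.bvecs
    b = scheme.bvals
    return np.column_stack([
        np.ones(len(b)),
        -b * g[:, 0] ** 2,
        -b * g[:, 1] ** 2,
        -b * g[:, 2] ** 2,
        -2 * b * g[:, 0] * g[:, 1],
        -2 * b * g[:, 0] * g[:, 2],
        -2 * b * g[:, 1] * g[:, 2],
    ])


def _tensors_from_components(comp: np.ndarray) -> np.ndarray:
    """(..., 6) Dxx,Dyy,Dzz,Dxy,Dxz,Dyz -> (..., 3, 3) symmetric tensors."""
    D = np.empty(comp.shape[:-1] + (3, 3))
    D[..., 0, 0] = comp[..., 0]
    D[..., 1, 1] = comp[..., 1]
    D[..., 2, 2] = comp[..., 2]
    D[..., 0, 1] = D[..., 1, 0] = comp[..., 3]
    D[..., 0, 2] = D[..., 2, 0] = comp[..., 4]
    D[..., 1, 2] = D[..., 2, 1] = comp[..., 5]
    return D


def fit_tensor(signals: np.ndarray, scheme: DwiScheme) -> np.ndarray:
    """Log-linear least-squares tensor fit.

    ``signals`` has shape ``(..., n_volumes)``; returns symmetric tensors of
    shape ``(..., 3, 3)`` in mm^2/s.  Non-positive signals are masked out of
    the fit per voxel (all-masked voxels get a zero tensor).  A
    rank-deficient design (fewer than 6 non-collinear weighted directions)
    raises.
    """
    X = _design_matrix(scheme)
    if np.linalg.matrix_rank(X) < 7:
        raise ValueError("gradient scheme is rank-deficient: need >= 6 "
                         "non-collinear weighted directions plus a low-b volume")
    signals = np.asarray(signals, dtype=np.float64)
    flat = signals.reshape(-1, scheme.n_volumes)
    comp = np.zeros((len(flat), 6))
    ok = flat > 0
    full = ok.all(axis=1)
    if full.any():
        beta = np.linalg.lstsq(X, np.log(flat[full]).T, rcond=None)[0]
        comp[full] = beta[1:].T
    for i in np.flatnonzero(~full):
        m = ok[i]
        if m.sum() >= 7 and np.linalg.matrix_rank(X[m]) == 7:
            beta = np.linalg.lstsq(X[m], np.log(flat[i, m]), rcond=None)[0]
            comp[i] = beta[1:]
    return _tensors_from_components(comp).reshape(signals.shape[:-1] + (3, 3))


def tensor_eigenvalues(tensors: np.ndarray) -> np.ndarray:
    """Eigenvalues of symmetric tensors, descending order, shape (..., 3)."""
    return np.linalg.eigvalsh(np.asarray(tensors))[..., ::-1]


def fa_from_eigenvalues(l1, l2, l3) -> np.ndarray:
    """Fractional anisotropy from tensor eigenvalues.

    ``FA = sqrt(3/2) * ||lambda - mean(lambda)|| / ||lambda||``; 0 for an
    isotropic tensor, 1 in the single-nonzero-eigenvalue limit, and defined
    as 0 when all eigenvalues vanish.  Negative eigenvalues (degenerate
    fits) are clamped to zero.
    """
    lam = np.stack(np.broadcast_arrays(np.asarray(l1, dtype=np.float64),
                                       np.asarray(l2, dtype=np.float64),
                                       np.asarray(l3, dtype=np.float64)), axis=-1)
    lam = np.clip(lam, 0.0, None)
    norm = np.linalg.norm(lam, axis=-1)
    dev = lam - lam.mean(axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * np.linalg.norm(dev, axis=-1) / norm
    fa = np.where(norm > 0, fa, 0.0)
    return np.clip(fa, 0.0, 1.0)


def fa_map(tensors: np.ndarray) -> np.ndarray:
    """FA of every tensor in a field."""
    lam = tensor_eigenvalues(tensors)
    return fa_from_eigenvalues(lam[..., 0], lam[..., 1], lam[..., 2])


def synth_dwi(tensors: np.ndarray, scheme: DwiScheme, s0: float = 1000.0,
              noise_sd: float = 0.0,
              rng: np.random.Generator | None = None) -> np.ndarray:
    """Forward DWI signals ``S = s0 exp(-b g' D g)`` with optional Gaussian noise."""
    D = np.asarray(tensors, dtype=np.float64)
    g = scheme.bvecs
    # quadratic form g' D g per direction, batched over voxels
    quad = np.einsum("ki,...ij,kj->...k", g, D, g)
    signals = s0 * np.exp(-scheme.bvals * quad)
    if noise_sd > 0:
        rng = rng or np.random.default_rng()
        signals = signals + rng.normal(0.0, noise_sd, signals.shape)
    return signals


# ---------------------------------------------------------------------------
# FSL-style bvec/bval text I/O
# ---------------------------------------------------------------------------

def write_scheme(scheme: DwiScheme, bvec_path, bval_path) -> None:
    """Write 3 x n bvecs and 1 x n bvals, whitespace-separated."""
    np.savetxt(os.fspath(bvec_path), scheme.bvecs.T, fmt="%.10g")
    np.savetxt(os.fspath(bval_path), scheme.bvals[None, :], fmt="%.10g")


def read_scheme(bvec_path, bval_path) -> DwiScheme:
    bvecs = np.loadtxt(os.fspath(bvec_path)).T
    bvals = np.atleast_1d(np.loadtxt(os.fspath(bval_path)).ravel())
    return DwiScheme(bvecs=bvecs, bvals=bvals)
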