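"""Atlas-based tract segmentation: multi-channel intensity registration.

A subject's tract segmentation is obtained by deforming a labelled atlas
onto the subject.  Two intensity channels drive the match — an FA-like
channel that anchors the white matter and a b0-like channel that anchors
the global brain shape — under a greedy viscous-fluid scheme: at every
iteration the summed-squared-difference force is smoothed by the inverse of
the elliptic operator ``L = -alpha * Laplacian + gamma * I`` (applied in
the Fourier domain) and a small step of the resulting velocity is composed
into the running deformation, with the step size guarded so the grid
Jacobian stays positive.

Elasticity is controlled by the ratio ``alpha / gamma`` and relaxed over a
cascade of stages (default 0.01, 0.005, 0.0025): each stage warm-starts
from the previous one, so matching quality improves monotonically while
each stage only adds a small, well-conditioned increment of deformation.

Labels ride along by nearest-neighbour resampling through the inverse map;
tract boundary meshes ride along by transporting their vertices through
the forward map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage, optimize

from .mesh_core import TriMesh


@dataclass
class MultiChannelImage:
    """Named scalar volumes on a shared grid, with voxel size (mm) and affine."""

    channels: dict[str, np.ndarray]
    voxel_size: np.ndarray = field(default_factory=lambda: np.ones(3))
    world_affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        shapes = {np.asarray(v).shape for v in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError("all channels must share one grid shape")
        self.channels = {k: np.asarray(v, dtype=np.float64) for k, v in self.channels.items()}
        self.voxel_size = np.asarray(self.voxel_size, dtype=np.float64)
        if self.world_affine is None:
            aff = np.eye(4)
            aff[:3, :3] = np.diag(self.voxel_size)
            self.world_affine = aff
        else:
            self.world_affine = np.asarray(self.world_affine, dtype=np.float64)
        fa = self.channels.get("FA")
        if fa is not None and (fa.min() < -1e-9 or fa.max() > 1 + 1e-9):
            raise ValueError("FA channel must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, ...]:
        return next(iter(self.channels.values())).shape


@dataclass(frozen=True)
class ElasticitySchedule:
    """Strictly decreasing alpha/gamma ratios, one registration stage each."""

    ratios: tuple[float, ...] = (0.01, 0.005, 0.0025)

    def __post_init__(self) -> None:
        r = tuple(float(x) for x in self.ratios)
        if not r or any(x <= 0 for x in r):
            raise ValueError("ratios must be positive")
        if any(b >= a for a, b in zip(r, r[1:])):
            raise ValueError("ratios must be strictly decreasing")
        object.__setattr__(self, "ratios", r)


@dataclass
class GridDeformation:
    """Dense deformation on the atlas/subject grid (voxel coordinates).

    ``forward`` maps atlas voxel positions into subject voxel positions
    (used to transport mesh vertices); ``inverse`` maps subject voxel
    positions back into atlas coordinates (used to resample atlas volumes
    into the subject frame).  Both are (nx, ny, nz, 3) arrays.
    """

    forward: np.ndarray
    inverse: np.ndarray
    world_affine: np.ndarray
    stage_costs: list[float] = field(default_factory=list)
    folded: bool = False

    @classmethod
    def identity(cls, shape, world_affine) -> "GridDeformation":
        grid = _identity_grid(shape)
        return cls(forward=grid.copy(), inverse=grid.copy(),
                   world_affine=np.asarray(world_affine, dtype=np.float64))

    def transform_points(self, points_mm: np.ndarray) -> np.ndarray:
        """Transport world-mm points through the forward map (linear interp)."""
        inv_aff = np.linalg.inv(self.world_affine)
        pts = np.atleast_2d(np.asarray(points_mm, dtype=np.float64))
        vox = pts @ inv_aff[:3, :3].T + inv_aff[:3, 3]
        out_vox = np.stack([
            ndimage.map_coordinates(self.forward[..., k], vox.T, order=1, mode="nearest")
            for k in range(3)], axis=1)
        return out_vox @ self.world_affine[:3, :3].T + self.world_affine[:3, 3]

    def pull_volume(self, volume: np.ndarray, order: int = 1) -> np.ndarray:
        """Resample an atlas-frame volume into the subject frame."""
        coords = np.moveaxis(self.inverse, -1, 0)
        return ndimage.map_coordinates(np.asarray(volume, dtype=np.float64),
                                       coords, order=order, mode="nearest")

    def min_jacobian(self) -> float:
        return float(_grid_jacobian_det(self.inverse).min())


def _identity_grid(shape) -> np.ndarray:
    axes = [np.arange(n, dtype=np.float64) for n in shape]
    return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)


def _grid_jacobian_det(phi: np.ndarray) -> np.ndarray:
    """Determinant of the spatial Jacobian of a (..., 3) grid map."""
    J = np.empty(phi.shape[:-1] + (3, 3))
    for comp in range(3):
        grads = np.gradient(phi[..., comp])
        for ax in range(3):
            J[..., comp, ax] = grads[ax]
    return np.linalg.det(J)


# ---------------------------------------------------------------------------
# Affine pre-alignment
# ---------------------------------------------------------------------------

def _affine_from_params(params: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """12 params -> (3x3 matrix, translation), voxel coordinates."""
    t = params[0:3]
    rx, ry, rz = params[3:6]
    scale = np.exp(params[6:9])
    sxy, sxz, syz = params[9:12]
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    shear = np.array([[1, sxy, sxz], [0, 1, syz], [0, 0, 1]])
    return Rz @ Ry @ Rx @ shear @ np.diag(scale), t


def affine_prealign(subject: MultiChannelImage, atlas: MultiChannelImage,
                    max_iter: int = 400) -> np.ndarray:
    """12-parameter affine ``A`` (4x4, voxel coords) with ``subject(A x) ~ atlas(x)``.

    Minimizes the summed squared channel difference by direct search, coarse
    (smoothed, downsampled) then fine.  On optimizer divergence the identity
    is returned with a warning.
    """
    if subject.shape != atlas.shape:
        raise ValueError("affine_prealign expects subject and atlas on the same grid")
    center = (np.asarray(atlas.shape) - 1) / 2.0

    def _cost(params, sub_ch, atl_ch):
        M, t = _affine_from_params(params)
        # resample about the grid center so rotations/scales act centrally
        offset = center + t - M @ center
        total = 0.0
        for s, a in zip(sub_ch, atl_ch):
            warped = ndimage.affine_transform(s, M, offset=offset, order=1, mode="nearest")
            total += float(np.mean((warped - a) ** 2))
        return total

    keys = sorted(subject.channels)
    params = np.zeros(12)
    try:
        for smooth, zoom in ((2.0, 0.5), (0.0, 1.0)):
            sub_ch, atl_ch = [], []
            for k in keys:
                s, a = subject.channels[k], atlas.channels[k]
                if smooth > 0:
                    s = ndimage.gaussian_filter(s, smooth)
                    a = ndimage.gaussian_filter(a, smooth)
                if zoom != 1.0:
                    s = ndimage.zoom(s, zoom, order=1)
                    a = ndimage.zoom(a, zoom, order=1)
                sub_ch.append(s)
                atl_ch.append(a)
            scale_fix = zoom if zoom != 1.0 else 1.0
            p = params.copy()
            p[0:3] *= scale_fix
            saved_center = center
            # re-center for the downsampled grid
            center = (np.asarray(sub_ch[0].shape) - 1) / 2.0
            res = optimize.minimize(_cost, p, args=(sub_ch, atl_ch), method="Powell",
                                    options={"maxiter": max_iter, "xtol": 1e-4, "ftol": 1e-8})
            center = saved_center
            params = res.x
            params[0:3] /= scale_fix
        if not np.all(np.isfinite(params)):
            raise FloatingPointError
    except (FloatingPointError, np.linalg.LinAlgError):
        warnings.warn("affine pre-alignment diverged; returning identity")
        return np.eye(4)
    M, t = _affine_from_params(params)
    A = np.eye(4)
    A[:3, :3] = M
    A[:3, 3] = center + t - M @ center
    return A


# ---------------------------------------------------------------------------
# Greedy fluid registration with cascading elasticity
# ---------------------------------------------------------------------------

def _smoothing_kernel_hat(shape, ratio: float, gamma: float = 1.0) -> np.ndarray:
    """Fourier symbol of ``(gamma * I - alpha * Laplacian)^-1`` with alpha = ratio*gamma."""
    alpha = ratio * gamma
    lap = np.zeros(shape)
    for ax, n in enumerate(shape):
        freq = np.fft.fftfreq(n)
        symbol = 2.0 - 2.0 * np.cos(2.0 * np.pi * freq)
        sl = [None] * len(shape)
        sl[ax] = slice(None)
        lap = lap + symbol[tuple(sl)]
    return 1.0 / (gamma + alpha * lap)


def _ssd_cost(warped: list[np.ndarray], subject: list[np.ndarray]) -> float:
    return float(sum(np.sum((w - s) ** 2) for w, s in zip(warped, subject)))


def image_lddmm(atlas: MultiChannelImage, subject: MultiChannelImage,
                schedule: ElasticitySchedule = ElasticitySchedule(),
                iters_per_stage: int = 40, step_voxels: float = 0.4,
                min_jac: float = 0.05) -> GridDeformation:
    """Deform the atlas channels onto the subject's (greedy fluid cascade).

    Each stage minimizes the multi-channel SSD under the smoothing operator
    of its alpha/gamma ratio, warm-starting from the previous stage.  Steps
    that would fold the grid (min Jacobian of the running inverse map below
    ``min_jac``) are rejected; if no admissible step remains the stage is
    aborted and the last valid deformation returned with ``folded=True``.
    """
    if atlas.shape != subject.shape:
        raise ValueError("atlas and subject must share the grid")
    keys = sorted(atlas.channels)
    sub = [subject.channels[k] for k in keys]
    atl = [atlas.channels[k] for k in keys]
    shape = atlas.shape
    deform = GridDeformation.identity(shape, atlas.world_affine)
    grid = _identity_grid(shape)

    def _warped():
        return [deform.pull_volume(a, order=1) for a in atl]

    cost = _ssd_cost(_warped(), sub)
    for ratio in schedule.ratios:
        khat = _smoothing_kernel_hat(shape, ratio)
        for _ in range(iters_per_stage):
            warped = _warped()
            # SSD gradient force, summed over channels
            force = np.zeros(shape + (3,))
            for w, s in zip(warped, sub):
                diff = w - s
                gx, gy, gz = np.gradient(w)
                force[..., 0] += diff * gx
                force[..., 1] += diff * gy
                force[..., 2] += diff * gz
            vel = np.empty_like(force)
            for k in range(3):
                vel[..., k] = np.real(np.fft.ifftn(np.fft.fftn(force[..., k]) * khat))
            vmax = np.abs(vel).max()
            if vmax < 1e-12:
                break
            eps = step_voxels / vmax
            improved = False
            for _try in range(6):
                disp = -eps * vel
                new_inverse = _compose_inverse(deform.inverse, disp, grid)
                if _grid_jacobian_det(new_inverse).min() <= min_jac:
                    eps *= 0.5
                    continue
                new_forward = _compose_forward(deform.forward, disp)
                trial = GridDeformation(new_forward, new_inverse, deform.world_affine)
                new_cost = _ssd_cost([trial.pull_volume(a, order=1) for a in atl], sub)
                if new_cost < cost:
                    deform.forward, deform.inverse = new_forward, new_inverse
                    cost = new_cost
                    improved = True
                    break
                eps *= 0.5
            if not improved:
                break
        deform.stage_costs.append(cost)
    return deform


def _compose_inverse(inverse: np.ndarray, disp: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """psi_new(x) = psi(x + disp(x)), sampled by linear interpolation."""
    coords = np.moveaxis(grid + disp, -1, 0)
    out = np.empty_like(inverse)
    for k in range(3):
        out[..., k] = ndimage.map_coordinates(inverse[..., k], coords, order=1, mode="nearest")
    return out


def _compose_forward(forward: np.ndarray, disp: np.ndarray) -> np.ndarray:
    """phi_new(x) = phi(x) - disp(phi(x)) (first-order inverse of the update)."""
    coords = np.moveaxis(forward, -1, 0)
    out = forward.copy()
    for k in range(3):
        out[..., k] -= ndimage.map_coordinates(disp[..., k], coords, order=1, mode="nearest")
    return out


# ---------------------------------------------------------------------------
# Label and mesh propagation
# ---------------------------------------------------------------------------

def propagate_labels(deform: GridDeformation, label_volume: np.ndarray,
                     meshes: list[TriMesh]) -> tuple[np.ndarray, list[TriMesh]]:
    """Carry the atlas segmentation into the subject frame.

    Labels are resampled nearest-neighbour through the inverse map; tract
    boundary meshes are transported by mapping their vertices through the
    forward map.
    """
    coords = np.moveaxis(deform.inverse, -1, 0)
    labels = ndimage.map_coordinates(np.asarray(label_volume), coords, order=0,
                                     mode="constant", cval=0)
    out_meshes = [m.with_vertices(deform.transform_points(m.vertices)) for m in meshes]
    return labels.astype(np.asarray(label_volume).dtype), out_meshes


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap of two binary masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    return 2.0 * float(np.logical_and(a, b).sum()) / denom if denom else 1.0


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def save_nifti(volume: np.ndarray, affine: np.ndarray, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(volume), np.asarray(affine)), str(path))


def load_nifti(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), np.asarray(img.affine)
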