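"""Synthetic atlas and two-group cohort with planted shape and FA effects.

The generator emulates the study design the pipeline is built for: an atlas
of labelled tract volumes with boundary surfaces and two intensity channels
(FA-like and b0-like), and a cohort of controls and AD-like subjects
produced by smooth invertible warps of that atlas.  AD subjects
additionally receive a regional compression of one tract and a regional FA
reduction, both with per-subject severity; MMSE scores are linearly coupled
to severity so cognition tracks the planted pathology.

Every tract is defined by a smooth implicit function: the label volume is
its positive set and the boundary mesh its zero isosurface (marching
cubes), so mesh and labels are consistent by construction.  Random subject
warps are sums of Gaussian-kernel momenta integrated with the same flow
integrator the surface-matching stage uses — the analysis model class
contains the generating truth, which is what makes parameter-recovery
tests meaningful.

All randomness flows through a single integer seed; per-subject substreams
are derived with fixed offsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage import measure

from .lddmm_surface import Diffeomorphism, integrate_flow, flow_points
from .mesh_core import TriMesh


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass
class AtlasBundle:
    """Tract meshes + label volume + FA/b0 channels on one grid."""

    tract_meshes: list[TriMesh]
    label_volume: np.ndarray
    channels: dict[str, np.ndarray]
    voxel_size: np.ndarray
    world_affine: np.ndarray

    @property
    def n_tracts(self) -> int:
        return len(self.tract_meshes)

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return self.label_volume.shape


@dataclass(frozen=True)
class EffectSpec:
    """Generative parameters of the planted group differences.

    ``compression_scale`` < 1 shrinks AD tract tissue radially inside a
    spherical patch (Gaussian profile); ``fa_delta`` is subtracted from the
    FA channel inside a second patch.  ``mmse_coupling`` (MMSE points per
    unit of severity deviation) ties cognition to the per-subject severity
    draw.  Patch centers default to the first tract's centroid.
    """

    compression_center: tuple[float, float, float] | None = None
    compression_radius: float = 6.0
    compression_scale: float = 0.8
    fa_center: tuple[float, float, float] | None = None
    fa_radius: float = 6.0
    fa_delta: float = 0.08
    severity_sd: float = 0.2
    mmse_coupling: float = 4.0
    mmse_noise_sd_con: float = 1.2
    mmse_noise_sd_ad: float = 2.5
    mmse_mean_con: float = 28.8
    mmse_mean_ad: float = 21.9
    icv_mean: float = 1.4e6
    icv_sd: float = 1.2e5

    def __post_init__(self) -> None:
        if not 0 < self.compression_scale <= 1:
            raise ValueError("compression scale must lie in (0, 1]")
        if self.fa_delta < 0:
            raise ValueError("fa_delta must be non-negative")

    @classmethod
    def null(cls) -> "EffectSpec":
        """No planted shape/FA effect and no cognition coupling (groups exchangeable)."""
        return cls(compression_scale=1.0, fa_delta=0.0, mmse_coupling=0.0)


@dataclass
class SubjectRecord:
    subject_id: str
    group: str                       # "CON" or "AD"
    warp: "SubjectWarp"
    tract_meshes: list[TriMesh]
    fa_volume: np.ndarray
    b0_volume: np.ndarray
    label_volume: np.ndarray
    icv_mm3: float
    mmse: float
    severity: float


# ---------------------------------------------------------------------------
# Ground-truth warps
# ---------------------------------------------------------------------------

@dataclass
class CompressionPatch:
    """Radial contraction toward ``center`` with a Gaussian profile.

    ``x -> c + (x - c) * (1 - A * exp(-r^2 / tau^2))`` with amplitude
    ``A = 1 - scale`` and ``tau = radius``; smooth, and invertible for
    A < ~0.6.
    """

    center: np.ndarray
    radius: float
    scale: float

    def transform_points(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        d = pts - self.center
        r2 = np.sum(d ** 2, axis=1, keepdims=True)
        factor = 1.0 - (1.0 - self.scale) * np.exp(-r2 / self.radius ** 2)
        return self.center + d * factor


@dataclass
class SubjectWarp:
    """Ground-truth atlas-to-subject map: kernel flow, then (AD) compression."""

    flow: Diffeomorphism
    patch: CompressionPatch | None = None

    def transform_points(self, points: np.ndarray) -> np.ndarray:
        out = flow_points(self.flow, points)
        if self.patch is not None:
            out = self.patch.transform_points(out)
        return out

    def inverse_points(self, points: np.ndarray, n_refine: int = 3) -> np.ndarray:
        """Inverse map: backward flow initialization + fixed-point refinement.

        The time-reversed negated flow gives an O(dt)-accurate inverse of
        the kernel flow; the compression patch is inverted by a radial
        fixed point; a few global refinements ``x += y - warp(x)`` then
        drive the residual to interpolation-level error.
        """
        y = np.atleast_2d(np.asarray(points, dtype=np.float64))
        x = y
        if self.patch is not None:
            x = self._patch_inverse(x)
        x = flow_points(self.flow, x, inverse=True)
        for _ in range(n_refine):
            x += y - self.transform_points(x)
        return x

    def _patch_inverse(self, y: np.ndarray, n_iter: int = 20) -> np.ndarray:
        p = self.patch
        d = y - p.center
        r = np.linalg.norm(d, axis=1, keepdims=True)
        amp = 1.0 - p.scale
        # solve s * (1 - amp * exp(-(s*r)^2 / radius^2)) = 1 for the radial stretch s
        s = np.ones_like(r)
        for _ in range(n_iter):
            s = 1.0 / (1.0 - amp * np.exp(-(s * r) ** 2 / p.radius ** 2))
        return p.center + d * s


def grid_min_jacobian(warp, shape, world_affine, stride: int = 2,
                      h: float = 0.5) -> float:
    """Minimum Jacobian determinant of a point map over a strided grid."""
    axes = [np.arange(0, n, stride, dtype=np.float64) for n in shape]
    vox = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    aff = np.asarray(world_affine)
    pts = vox @ aff[:3, :3].T + aff[:3, 3]
    n = len(pts)
    probes = np.empty((6 * n, 3))
    for k in range(3):
        e = np.zeros(3)
        e[k] = h
        probes[2 * k * n:(2 * k + 1) * n] = pts + e
        probes[(2 * k + 1) * n:(2 * k + 2) * n] = pts - e
    moved = warp.transform_points(probes)
    J = np.empty((n, 3, 3))
    for k in range(3):
        J[:, :, k] = (moved[2 * k * n:(2 * k + 1) * n]
                      - moved[(2 * k + 1) * n:(2 * k + 2) * n]) / (2 * h)
    return float(np.linalg.det(J).min())


# ---------------------------------------------------------------------------
# Atlas generation
# ---------------------------------------------------------------------------

def _tract_field(shape, center, semi_axes, bumps, bump_amp=0.18):
    """Smooth implicit function: positive inside the tract, zero at its boundary."""
    axes = [np.arange(n, dtype=np.float64) for n in shape]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    u = np.stack([(X - center[0]) / semi_axes[0],
                  (Y - center[1]) / semi_axes[1],
                  (Z - center[2]) / semi_axes[2]], axis=-1)
    r = np.linalg.norm(u, axis=-1)
    # angular bumps deform the ellipsoid into an irregular smooth blob
    pert = np.zeros(shape)
    with np.errstate(invalid="ignore", divide="ignore"):
        direction = u / np.where(r[..., None] > 0, r[..., None], 1.0)
    for b_dir, b_width in bumps:
        cosang = direction @ b_dir
        pert += bump_amp * np.exp((cosang - 1.0) / b_width)
    return 1.0 + pert - r


def generate_atlas(n_tracts: int = 3, grid_shape=(48, 48, 48), seed: int = 0,
                   voxel_size=(1.0, 1.0, 1.0), mesh_step: int = 2) -> AtlasBundle:
    """Synthetic tract atlas: implicit blobs -> labels + marching-cubes meshes.

    Tracts are irregular smooth closed blobs placed on a lattice inside a
    brain-like ellipsoid; the FA channel is high inside tracts over a low
    white-matter background, the b0 channel follows the brain mask.
    Deterministic given the seed.  Raises when the grid cannot hold
    ``n_tracts`` non-overlapping tracts.

    ``mesh_step`` is the marching-cubes sampling stride: 1 extracts the
    isosurface at full grid resolution, 2 (default) at half resolution,
    giving ~4x fewer faces at a sub-voxel geometric cost.
    """
    if n_tracts < 1:
        raise ValueError("n_tracts must be >= 1")
    shape = tuple(int(n) for n in grid_shape)
    if min(shape) < 16:
        raise ValueError("grid_shape must be at least 16 voxels per axis")
    rng = np.random.default_rng(seed)
    margin = 0.22 * min(shape)
    # lattice of candidate centers, spaced so blobs cannot touch
    spacing = 0.30 * min(shape)
    coords = []
    for gx in np.arange(margin, shape[0] - margin + 1e-9, spacing):
        for gy in np.arange(margin, shape[1] - margin + 1e-9, spacing):
            for gz in np.arange(margin, shape[2] - margin + 1e-9, spacing):
                coords.append((gx, gy, gz))
    if len(coords) < n_tracts:
        raise ValueError(
            f"grid {shape} too small for {n_tracts} non-overlapping tracts "
            f"(room for {len(coords)})")
    centers = [coords[i] for i in rng.choice(len(coords), n_tracts, replace=False)]

    label = np.zeros(shape, dtype=np.int16)
    meshes: list[TriMesh] = []
    max_semi = 0.115 * min(shape)
    affine = np.eye(4)
    affine[:3, :3] = np.diag(voxel_size)
    for k, center in enumerate(centers, start=1):
        semi = max_semi * rng.uniform(0.65, 1.0, 3)
        bumps = [(u / np.linalg.norm(u), w)
                 for u, w in zip(rng.standard_normal((3, 3)), rng.uniform(0.15, 0.4, 3))]
        f = _tract_field(shape, np.asarray(center), semi, bumps)
        inside = f > 0
        if (label[inside] != 0).any():
            raise ValueError("tract supports overlap; grid too small for n_tracts")
        label[inside] = k
        verts, faces, _, _ = measure.marching_cubes(f, level=0.0, step_size=mesh_step)
        verts_mm = verts * np.asarray(voxel_size)
        meshes.append(_outward_oriented(TriMesh(verts_mm, faces.astype(np.int64))))

    # brain-like ellipsoid for the b0 channel
    c = (np.asarray(shape) - 1) / 2.0
    axes = [np.arange(n, dtype=np.float64) for n in shape]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    brain_r = np.sqrt(((X - c[0]) / (0.47 * shape[0])) ** 2
                      + ((Y - c[1]) / (0.45 * shape[1])) ** 2
                      + ((Z - c[2]) / (0.43 * shape[2])) ** 2)
    brain = brain_r < 1.0
    fa = np.where(brain, 0.15, 0.0)
    fa[label > 0] = 0.45
    fa = ndimage.gaussian_filter(fa, 0.8)
    fa = np.clip(fa, 0.0, 1.0)
    b0 = ndimage.gaussian_filter(np.where(brain, 1000.0, 0.0), 1.2)
    return AtlasBundle(tract_meshes=meshes, label_volume=label,
                       channels={"FA": fa, "b0": b0},
                       voxel_size=np.asarray(voxel_size, dtype=np.float64),
                       world_affine=affine)


def _outward_oriented(mesh: TriMesh) -> TriMesh:
    """Flip faces if the signed divergence-theorem volume is negative."""
    from .mesh_core import compute_current

    cur = compute_current(mesh)
    signed = float(np.sum(cur.centers * cur.normals) / 3.0)
    return mesh.flipped() if signed < 0 else mesh


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _random_flow(atlas: AtlasBundle, rng: np.random.Generator,
                 n_control: int = 30, sigma_v: float = 10.0,
                 momentum_sd: float = 0.6, n_steps: int = 8) -> Diffeomorphism:
    """Random smooth warp: Gaussian momenta at control points scattered over the brain."""
    shape = np.asarray(atlas.grid_shape, dtype=np.float64)
    lo, hi = 0.15 * shape, 0.85 * shape
    q = rng.uniform(lo, hi, (n_control, 3)) * atlas.voxel_size
    alpha = rng.normal(0.0, momentum_sd, (n_control, 3))
    return integrate_flow(q, alpha, sigma_v, n_steps)


def _default_patch_center(atlas: AtlasBundle) -> np.ndarray:
    return atlas.tract_meshes[0].vertices.mean(axis=0)


def resolve_effect(atlas: AtlasBundle, effect: EffectSpec) -> EffectSpec:
    """Fill patch centers that default to the first tract's centroid."""
    c = tuple(_default_patch_center(atlas))
    out = effect
    if out.compression_center is None:
        out = replace(out, compression_center=c)
    if out.fa_center is None:
        out = replace(out, fa_center=c)
    return out


def generate_cohort(atlas: AtlasBundle, n_con: int = 19, n_ad: int = 13,
                    effect: EffectSpec = EffectSpec(), seed: int = 0,
                    warp_kwargs: dict | None = None,
                    noise_free_mmse: bool = False) -> list[SubjectRecord]:
    """Warp the atlas into ``n_con + n_ad`` subjects with planted AD effects.

    Controls get a random smooth invertible warp; AD subjects additionally
    get the compression patch (with per-subject severity) and an FA
    reduction inside the FA patch.  A draw whose grid Jacobian is not
    strictly positive is regenerated, with an error after 10 failures.
    """
    if n_con < 1 or n_ad < 1:
        raise ValueError("need at least one subject per group")
    effect = resolve_effect(atlas, effect)
    warp_kwargs = warp_kwargs or {}
    subjects: list[SubjectRecord] = []
    groups = ["CON"] * n_con + ["AD"] * n_ad
    fa_atlas = atlas.channels["FA"]
    b0_atlas = atlas.channels["b0"]
    grid = _world_grid(atlas)

    for i, group in enumerate(groups):
        rng = np.random.default_rng([int(seed), 1000 + i])
        severity = 0.0
        patch = None
        if group == "AD":
            severity = float(np.clip(rng.normal(1.0, effect.severity_sd), 0.2, 2.0))
            scale_i = 1.0 - severity * (1.0 - effect.compression_scale)
            if scale_i < 1.0:
                patch = CompressionPatch(center=np.asarray(effect.compression_center),
                                         radius=effect.compression_radius,
                                         scale=scale_i)
        warp = None
        for _attempt in range(10):
            flow = _random_flow(atlas, rng, **warp_kwargs)
            cand = SubjectWarp(flow=flow, patch=patch)
            if grid_min_jacobian(cand, atlas.grid_shape, atlas.world_affine) > 0:
                warp = cand
                break
        if warp is None:
            raise RuntimeError("could not draw an invertible warp in 10 attempts")

        fa_src = fa_atlas
        if group == "AD" and effect.fa_delta > 0:
            fa_src = fa_atlas.copy()
            mask = _sphere_mask(atlas, effect.fa_center, effect.fa_radius)
            fa_src[mask] = np.clip(fa_src[mask] - severity * effect.fa_delta, 0.0, 1.0)

        inv = warp.inverse_points(grid).reshape(atlas.grid_shape + (3,))
        inv_vox = (inv - atlas.world_affine[:3, 3]) / atlas.voxel_size
        coords = np.moveaxis(inv_vox, -1, 0)
        fa_vol = ndimage.map_coordinates(fa_src, coords, order=1, mode="nearest")
        b0_vol = ndimage.map_coordinates(b0_atlas, coords, order=1, mode="nearest")
        lab_vol = ndimage.map_coordinates(atlas.label_volume, coords, order=0,
                                          mode="constant", cval=0)
        meshes = [m.with_vertices(warp.transform_points(m.vertices))
                  for m in atlas.tract_meshes]

        icv = float(rng.normal(effect.icv_mean, effect.icv_sd))
        mean = effect.mmse_mean_con if group == "CON" else effect.mmse_mean_ad
        noise_sd = effect.mmse_noise_sd_con if group == "CON" else effect.mmse_noise_sd_ad
        mmse = mean + effect.mmse_coupling * (1.0 - severity) * (group == "AD")
        if not noise_free_mmse:
            mmse += rng.normal(0.0, noise_sd)
        mmse = float(np.clip(mmse, 0.0, 30.0))
        subjects.append(SubjectRecord(
            subject_id=f"{group.lower()}{i:03d}", group=group, warp=warp,
            tract_meshes=meshes, fa_volume=np.clip(fa_vol, 0.0, 1.0),
            b0_volume=b0_vol, label_volume=lab_vol.astype(atlas.label_volume.dtype),
            icv_mm3=icv, mmse=mmse, severity=severity))
    return subjects


def _world_grid(atlas: AtlasBundle) -> np.ndarray:
    axes = [np.arange(n, dtype=np.float64) for n in atlas.grid_shape]
    vox = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    aff = atlas.world_affine
    return vox @ aff[:3, :3].T + aff[:3, 3]


def _sphere_mask(atlas: AtlasBundle, center, radius: float) -> np.ndarray:
    grid = _world_grid(atlas).reshape(atlas.grid_shape + (3,))
    d2 = np.sum((grid - np.asarray(center)) ** 2, axis=-1)
    return d2 < radius ** 2


def planted_patch_vertices(atlas: AtlasBundle, effect: EffectSpec,
                           tract: int = 0) -> np.ndarray:
    """Boolean mask of atlas vertices inside the planted compression patch."""
    effect = resolve_effect(atlas, effect)
    v = atlas.tract_meshes[tract].vertices
    d = np.linalg.norm(v - np.asarray(effect.compression_center), axis=1)
    return d < effect.compression_radius


# ---------------------------------------------------------------------------
# Cohort export
# ---------------------------------------------------------------------------

def write_cohort(atlas: AtlasBundle, subjects: list[SubjectRecord], out_dir) -> str:
    """Write NIfTI volumes, VTK meshes, and a CSV manifest; returns manifest path."""
    import os

    import pandas as pd

    from .atlas_registration import save_nifti
    from .mesh_core import write_mesh

    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    atlas_dir = os.path.join(out_dir, "atlas")
    os.makedirs(atlas_dir, exist_ok=True)
    save_nifti(atlas.label_volume.astype(np.int16), atlas.world_affine,
               os.path.join(atlas_dir, "labels.nii.gz"))
    for name, ch in atlas.channels.items():
        save_nifti(ch, atlas.world_affine, os.path.join(atlas_dir, f"{name}.nii.gz"))
    for k, mesh in enumerate(atlas.tract_meshes, start=1):
        write_mesh(mesh, os.path.join(atlas_dir, f"tract{k}.vtk"))

    rows = []
    for s in subjects:
        sdir = os.path.join(out_dir, s.subject_id)
        os.makedirs(sdir, exist_ok=True)
        save_nifti(s.fa_volume, atlas.world_affine, os.path.join(sdir, "fa.nii.gz"))
        save_nifti(s.b0_volume, atlas.world_affine, os.path.join(sdir, "b0.nii.gz"))
        save_nifti(s.label_volume.astype(np.int16), atlas.world_affine,
                   os.path.join(sdir, "labels.nii.gz"))
        for k, mesh in enumerate(s.tract_meshes, start=1):
            write_mesh(mesh, os.path.join(sdir, f"tract{k}.vtk"))
        rows.append({"subject_id": s.subject_id, "group": s.group,
                     "icv_mm3": s.icv_mm3, "mmse": s.mmse,
                     "path": sdir})
    manifest = os.path.join(out_dir, "cohort.csv")
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
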