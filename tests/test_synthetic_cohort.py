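"""Atlas/cohort generator: determinism, geometry, planted effects."""

import numpy as np
import pytest

from tractsurf.mesh_core import is_closed, mesh_volume
from tractsurf.synthetic_cohort import (
    AtlasBundle, EffectSpec, generate_atlas, generate_cohort, grid_min_jacobian,
    planted_patch_vertices, resolve_effect, write_cohort,
)


@pytest.fixture(scope="module")
def atlas():
    return generate_atlas(n_tracts=2, grid_shape=(32, 32, 32), seed=5)


@pytest.fixture(scope="module")
def small_cohort(atlas):
    return generate_cohort(atlas, n_con=2, n_ad=2, seed=5)


class TestGenerateAtlas:
    def test_deterministic(self, atlas):
        again = generate_atlas(n_tracts=2, grid_shape=(32, 32, 32), seed=5)
        np.testing.assert_array_equal(again.label_volume, atlas.label_volume)
        for a, b in zip(again.tract_meshes, atlas.tract_meshes):
            np.testing.assert_array_equal(a.vertices, b.vertices)

    def test_labels_disjoint_and_complete(self, atlas):
        assert set(np.unique(atlas.label_volume)) == {0, 1, 2}

    def test_meshes_closed_and_outward(self, atlas):
        for mesh in atlas.tract_meshes:
            assert is_closed(mesh)
            vol, outward = mesh_volume(mesh, return_orientation=True)
            assert outward and vol > 0

    def test_mesh_volume_close_to_label_volume(self):
        # at full marching-cubes resolution the mesh volume tracks the
        # labelled-voxel volume closely; the default half-resolution
        # extraction trades some of that accuracy for speed
        fine = generate_atlas(1, (32, 32, 32), seed=5, mesh_step=1)
        voxvol = float(np.prod(fine.voxel_size))
        lab_vol = np.sum(fine.label_volume == 1) * voxvol
        assert mesh_volume(fine.tract_meshes[0]) == pytest.approx(lab_vol, rel=0.12)
        coarse = generate_atlas(1, (32, 32, 32), seed=5, mesh_step=2)
        assert mesh_volume(coarse.tract_meshes[0]) == pytest.approx(lab_vol, rel=0.4)

    def test_fa_channel_in_range(self, atlas):
        fa = atlas.channels["FA"]
        assert fa.min() >= 0.0 and fa.max() <= 1.0
        assert fa[atlas.label_volume > 0].mean() > fa[atlas.label_volume == 0].mean()

    def test_grid_too_small_raises(self):
        with pytest.raises(ValueError, match="at least 16"):
            generate_atlas(1, (12, 12, 12))

    def test_too_many_tracts_raises(self):
        with pytest.raises(ValueError, match="too small"):
            generate_atlas(30, (32, 32, 32))


class TestGenerateCohort:
    def test_deterministic(self, atlas, small_cohort):
        again = generate_cohort(atlas, n_con=2, n_ad=2, seed=5)
        for a, b in zip(again, small_cohort):
            np.testing.assert_array_equal(a.fa_volume, b.fa_volume)
            assert a.mmse == b.mmse and a.icv_mm3 == b.icv_mm3

    def test_groups_and_ids(self, small_cohort):
        assert [s.group for s in small_cohort] == ["CON", "CON", "AD", "AD"]
        assert len({s.subject_id for s in small_cohort}) == 4

    def test_warps_are_invertible_on_grid(self, atlas, small_cohort):
        for s in small_cohort:
            assert grid_min_jacobian(s.warp, atlas.grid_shape,
                                     atlas.world_affine) > 0

    def test_meshes_track_the_warp(self, atlas, small_cohort):
        s = small_cohort[0]
        expected = s.warp.transform_points(atlas.tract_meshes[0].vertices)
        np.testing.assert_allclose(s.tract_meshes[0].vertices, expected, atol=1e-12)

    def test_inverse_points_round_trip(self, atlas, small_cohort):
        rng = np.random.default_rng(0)
        pts = rng.uniform(8, 24, (50, 3))
        for s in small_cohort[:2]:
            back = s.warp.inverse_points(s.warp.transform_points(pts))
            assert np.max(np.linalg.norm(back - pts, axis=1)) < 5e-3

    def test_controls_have_no_patch(self, small_cohort):
        assert all(s.warp.patch is None for s in small_cohort[:2])
        assert all(s.warp.patch is not None for s in small_cohort[2:])

    def test_null_effect_removes_patch_and_fa_change(self, atlas):
        null = generate_cohort(atlas, 1, 1, EffectSpec.null(), seed=9)
        ad = null[1]
        assert ad.warp.patch is None
        # with the same seed, an AD subject differs from the null one only
        # through the planted patch and FA reduction
        full = generate_cohort(atlas, 1, 1, EffectSpec(), seed=9)[1]
        assert full.warp.patch is not None
        assert full.fa_volume[atlas.label_volume > 0].mean() <= \
            ad.fa_volume[atlas.label_volume > 0].mean() + 1e-12

    def test_fa_delta_doubling_doubles_the_drop(self, atlas):
        base = resolve_effect(atlas, EffectSpec())
        # small deltas stay clear of the clip at FA = 0, so the planted
        # reduction is linear in fa_delta
        e0 = EffectSpec(fa_delta=0.0, compression_scale=base.compression_scale)
        e1 = EffectSpec(fa_delta=0.02, compression_scale=base.compression_scale)
        e2 = EffectSpec(fa_delta=0.04, compression_scale=base.compression_scale)
        f0, f1, f2 = (generate_cohort(atlas, 1, 1, e, seed=3,
                                      noise_free_mmse=True)[1].fa_volume
                      for e in (e0, e1, e2))
        drop1 = float(np.sum(f0 - f1))
        drop2 = float(np.sum(f0 - f2))
        assert drop1 > 0
        assert drop2 == pytest.approx(2 * drop1, rel=1e-6)

    def test_mmse_noise_free_equals_coupling_formula(self, atlas):
        effect = EffectSpec()
        subs = generate_cohort(atlas, 1, 2, effect, seed=4, noise_free_mmse=True)
        assert subs[0].mmse == pytest.approx(effect.mmse_mean_con)
        for s in subs[1:]:
            expected = effect.mmse_mean_ad + effect.mmse_coupling * (1 - s.severity)
            assert s.mmse == pytest.approx(np.clip(expected, 0, 30))

    def test_mmse_group_means_plausible(self, atlas):
        effect = EffectSpec()
        subs = generate_cohort(atlas, 8, 8, effect, seed=10)
        con = np.mean([s.mmse for s in subs if s.group == "CON"])
        ad = np.mean([s.mmse for s in subs if s.group == "AD"])
        # 3 standard errors around the generative means
        assert abs(con - effect.mmse_mean_con) < 3 * effect.mmse_noise_sd_con / np.sqrt(8)
        sd_ad = np.hypot(effect.mmse_noise_sd_ad,
                         effect.mmse_coupling * effect.severity_sd)
        assert abs(ad - effect.mmse_mean_ad) < 3 * sd_ad / np.sqrt(8)
        assert con > ad

    def test_compression_shrinks_first_tract(self, atlas):
        strong = EffectSpec(compression_scale=0.7, severity_sd=1e-9)
        subs = generate_cohort(atlas, 1, 1, strong, seed=6,
                               warp_kwargs={"momentum_sd": 0.0})
        v_atlas = mesh_volume(atlas.tract_meshes[0])
        v_ad = mesh_volume(subs[1].tract_meshes[0])
        v_con = mesh_volume(subs[0].tract_meshes[0])
        assert v_con == pytest.approx(v_atlas, rel=1e-9)   # zero-momentum warp
        assert v_ad < 0.97 * v_atlas

    def test_needs_one_subject_per_group(self, atlas):
        with pytest.raises(ValueError, match="at least one subject"):
            generate_cohort(atlas, 0, 3)


class TestPlantedPatch:
    def test_patch_vertices_nonempty_and_within_radius(self, atlas):
        effect = resolve_effect(atlas, EffectSpec())
        mask = planted_patch_vertices(atlas, EffectSpec())
        assert mask.any()
        v = atlas.tract_meshes[0].vertices[mask]
        d = np.linalg.norm(v - np.asarray(effect.compression_center), axis=1)
        assert d.max() < effect.compression_radius

    def test_small_patch_covers_part_of_the_surface(self, atlas):
        # a radius between the nearest and farthest vertex distance must
        # select a strict, non-empty subset of the surface
        v = atlas.tract_meshes[0].vertices
        d = np.linalg.norm(v - v.mean(axis=0), axis=1)
        radius = 0.5 * (d.min() + d.max())
        mask = planted_patch_vertices(atlas, EffectSpec(compression_radius=radius))
        assert mask.any() and not mask.all()

    def test_resolve_effect_fills_centers(self, atlas):
        effect = resolve_effect(atlas, EffectSpec())
        centroid = atlas.tract_meshes[0].vertices.mean(axis=0)
        np.testing.assert_allclose(effect.compression_center, centroid)
        np.testing.assert_allclose(effect.fa_center, centroid)

    def test_effect_validation(self):
        with pytest.raises(ValueError, match="compression scale"):
            EffectSpec(compression_scale=0.0)
        with pytest.raises(ValueError, match="fa_delta"):
            EffectSpec(fa_delta=-0.1)


class TestWriteCohort:
    def test_files_and_manifest(self, atlas, small_cohort, tmp_path):
        import os

        import pandas as pd

        manifest = write_cohort(atlas, small_cohort, tmp_path / "cohort")
        df = pd.read_csv(manifest)
        assert len(df) == 4
        assert set(df["group"]) == {"CON", "AD"}
        for s in small_cohort:
            sdir = tmp_path / "cohort" / s.subject_id
            for fname in ("fa.nii.gz", "b0.nii.gz", "labels.nii.gz",
                          "tract1.vtk", "tract2.vtk"):
                assert os.path.exists(sdir / fname)
        assert (tmp_path / "cohort" / "atlas" / "labels.nii.gz").exists()
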