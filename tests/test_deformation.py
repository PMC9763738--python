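"""Deformation pipeline: masking, smoothing, extrapolation, feature extraction."""

import numpy as np
import pytest
import trimesh

from impedyn import deformation as dfm
from impedyn.perturbation import TriSurface


def make_series(disp, spacing=0.004, mask=None, box_center=True):
    n = disp.shape[1]
    origin = (-n * spacing / 2,) * 3 if box_center else (0.0, 0.0, 0.0)
    return dfm.DeformationSeries(
        disp=disp, spacing=(spacing,) * 3, mask=mask, origin=origin
    )


def grid_coords(n, spacing=0.004):
    c = (np.arange(n) + 0.5) * spacing - n * spacing / 2
    return np.meshgrid(c, c, c, indexing="ij")


def ball_mask(n, radius, spacing=0.004):
    X, Y, Z = grid_coords(n, spacing)
    return X**2 + Y**2 + Z**2 <= radius**2


def icosphere(radius=0.05, subdiv=2):
    return TriSurface.from_trimesh(trimesh.creation.icosphere(subdiv, radius=radius))


class TestBackgroundRemoval:
    def test_shared_offset_removed_exactly(self):
        rng = np.random.default_rng(0)
        truth = rng.normal(scale=2e-5, size=(3, 8, 8, 8, 3))
        bg = rng.normal(scale=5e-5, size=(3, 8, 8, 8, 3))
        pos = make_series(truth + bg)
        neg = make_series(-truth + bg)
        out = dfm.remove_background(pos, neg)
        assert np.allclose(out.disp, truth)

    def test_zero_fields_stay_zero(self):
        z = make_series(np.zeros((2, 4, 4, 4, 3)))
        assert not dfm.remove_background(z, z).disp.any()

    def test_mismatched_grids_rejected(self):
        a = make_series(np.zeros((2, 4, 4, 4, 3)), spacing=0.004)
        b = make_series(np.zeros((2, 4, 4, 4, 3)), spacing=0.005)
        with pytest.raises(ValueError):
            dfm.remove_background(a, b)

    def test_non_physiological_magnitudes_rejected(self):
        with pytest.raises(ValueError):
            make_series(np.full((1, 4, 4, 4, 3), 0.02))


class TestMask:
    def test_all_tissue_volume_keeps_interior(self):
        gm = np.ones((12, 12, 12))
        wm = np.zeros_like(gm)
        csf = np.zeros_like(gm)
        mask = dfm.build_mask(gm, wm, csf)
        assert mask.all()
        eroded = dfm.erode(mask, 3)
        # a 3-voxel boundary shell is removed
        assert not eroded[0].any() and not eroded[:, :3, :].any()
        assert eroded[6, 6, 6]

    def test_empty_probabilities_rejected(self):
        z = np.zeros((6, 6, 6))
        with pytest.raises(ValueError):
            dfm.build_mask(z, z, z)

    def test_erosion_to_empty_mask_raises(self):
        mask = np.zeros((8, 8, 8), dtype=bool)
        mask[3:5, 3:5, 3:5] = True
        with pytest.raises(ValueError):
            dfm.erode(mask, 3)

    def test_csf_adjacent_voxels_excluded(self):
        # spherical brain in a CSF shell: eroded mask stays >= 3 voxels inside
        n = 24
        X, Y, Z = grid_coords(n)
        R = np.sqrt(X**2 + Y**2 + Z**2)
        brain = R <= 0.036
        gm = brain.astype(float)
        csf = ((R > 0.036) & (R < 0.044)).astype(float)
        mask = dfm.erode(dfm.build_mask(gm, np.zeros_like(gm), csf), 3)
        from scipy.ndimage import distance_transform_cdt

        dist = distance_transform_cdt(brain, metric="taxicab")
        assert (dist[mask] > 3).all()


class TestKnnSmooth:
    def test_constant_field_unchanged(self):
        n = 16
        mask = ball_mask(n, 0.025)
        disp = np.tile([1e-5, -2e-5, 3e-6], (2, n, n, n, 1))
        out = dfm.knn_smooth(make_series(disp, mask=mask), k=50)
        assert np.allclose(out.disp[:, mask], disp[:, mask])

    def test_linear_field_preserved_in_interior(self):
        n = 20
        X, Y, Z = grid_coords(n)
        mask = ball_mask(n, 0.03)
        field = np.stack([2e-4 * X, -1e-4 * Y, 5e-5 * Z], axis=-1)[None]
        out = dfm.knn_smooth(make_series(field, mask=mask), k=30)
        core = ball_mask(n, 0.015)
        err = np.linalg.norm(out.disp[0][core] - field[0][core], axis=-1)
        scale = np.linalg.norm(field[0][core], axis=-1).max()
        assert np.median(err) < 0.05 * scale

    def test_noise_reduced_by_sqrt_k(self):
        rng = np.random.default_rng(3)
        n = 20
        mask = ball_mask(n, 0.03)
        sigma = 1e-5
        noise = rng.normal(scale=sigma, size=(1, n, n, n, 3))
        out = dfm.knn_smooth(make_series(noise, mask=mask), k=100)
        core = ball_mask(n, 0.015)
        resid = out.disp[0][core].std()
        assert resid < 2.5 * sigma / np.sqrt(100)


class TestExtrapolation:
    def test_nn_constant_field(self):
        n = 16
        mask = ball_mask(n, 0.025)
        disp = np.tile([4e-5, 0, -1e-5], (1, n, n, n, 1))
        sds = dfm.nn_extrapolate(make_series(disp, mask=mask), icosphere(0.03))
        assert np.allclose(sds.disp, [4e-5, 0, -1e-5])

    def test_nn_requires_mask(self):
        with pytest.raises(ValueError):
            dfm.nn_extrapolate(make_series(np.zeros((1, 8, 8, 8, 3))), icosphere())

    def test_rejection_of_excessive_surface_motion(self):
        n = 16
        mask = ball_mask(n, 0.025)
        disp = np.tile([5e-4, 0, 0], (1, n, n, n, 1))  # 500 um >> 100 um
        with pytest.raises(ValueError, match="rejection cap"):
            dfm.nn_extrapolate(make_series(disp, mask=mask), icosphere(0.03))

    def test_fft_band_limited_field_is_exact(self):
        # a field inside the retained band with a full mask: machine-level fit
        n = 20
        X, Y, Z = grid_coords(n)
        mask = np.ones((n, n, n), dtype=bool)
        series = make_series(np.zeros((1, n, n, n, 3)), mask=mask)
        ex = dfm.FourierExtrapolator(series.masked_coordinates(), n_harmonics=3, pad=0.25)
        L = ex.box_len
        lo = ex.box_lo
        f = np.cos(2 * np.pi * (X - lo[0]) / L[0]) * np.sin(4 * np.pi * (Y - lo[1]) / L[1])
        disp = 1e-5 * np.stack([f, 0 * f, 0 * f], axis=-1)[None]
        series = make_series(disp, mask=mask)
        surf_pts = series.masked_coordinates()[:50]
        coeffs = ex.fit(series.masked_values()[:, :, 0])
        recon = ex.evaluate(coeffs, surf_pts)
        truth = 1e-5 * np.cos(2 * np.pi * (surf_pts[:, 0] - lo[0]) / L[0]) * np.sin(
            4 * np.pi * (surf_pts[:, 1] - lo[1]) / L[1]
        )
        assert np.max(np.abs(recon - truth)) < 1e-8 * 1e-5 / 1e-5 * np.abs(truth).max() + 1e-13

    def test_fft_masked_reconstruction_of_smooth_field(self):
        # 40% of voxels removed: surface reconstruction error < 5%
        rng = np.random.default_rng(5)
        n = 20
        X, Y, Z = grid_coords(n)
        full = np.ones((n, n, n), dtype=bool)
        keep = rng.random((n, n, n)) > 0.4
        k = 2 * np.pi / (n * 0.004 * 1.25)
        f = np.cos(k * X) * np.cos(k * Y) + 0.5 * np.sin(k * Z)
        disp = 2e-5 * np.stack([f, f, f], axis=-1)[None]
        sfull = make_series(disp, mask=full)
        smask = make_series(disp, mask=keep)
        surf = icosphere(0.035, subdiv=1)
        ex = dfm.FourierExtrapolator(smask.masked_coordinates(), n_harmonics=3, pad=0.25)
        sds = dfm.fft_extrapolate(smask, surf, extrapolator=ex)
        truth = dfm.fft_extrapolate(
            sfull, surf,
            extrapolator=dfm.FourierExtrapolator(sfull.masked_coordinates(), 3, 0.25),
        )
        err = np.linalg.norm(sds.disp - truth.disp) / np.linalg.norm(truth.disp)
        assert err < 0.05

    def test_fft_rank_collapse_raises(self):
        # many samples confined to a 1D line cannot constrain a 3D basis
        t = np.linspace(-0.04, 0.04, 400)
        coords = np.stack([t, 0 * t, 0 * t], axis=1)
        with pytest.raises(RuntimeError, match="rank collapse"):
            dfm.FourierExtrapolator(coords, n_harmonics=3)

    def test_fft_underdetermined_raises(self):
        coords = np.zeros((40, 3))
        with pytest.raises(ValueError, match="cannot constrain"):
            dfm.FourierExtrapolator(coords, n_harmonics=3)


class TestFeatures:
    def test_uniform_translation(self):
        surf = icosphere(0.05)
        delta = np.array([3e-5, -1e-5, 2e-5])
        sds = dfm.SurfaceDisplacementSeries(surf, np.tile(delta, (1, surf.n_faces, 1)))
        feats = dfm.extract_features(sds)
        assert feats.ts[0] == pytest.approx(delta, rel=1e-9)
        assert abs(feats.dvcsf[0]) < 1e-6 * surf.area * np.linalg.norm(delta)
        assert feats.rs_magnitude[0] < 1e-9 * np.linalg.norm(delta) / 0.05

    def test_radial_expansion_volume(self):
        # uniform outward displacement delta: dVCSF = -area * delta (first order)
        surf = icosphere(0.05, subdiv=3)
        delta = 2e-5
        sds = dfm.SurfaceDisplacementSeries(surf, delta * surf.face_normals[None])
        feats = dfm.extract_features(sds)
        assert feats.dvcsf[0] == pytest.approx(-surf.area * delta, rel=1e-6)
        # for a near-spherical mesh this is -4 pi r^2 delta within mesh error
        assert feats.dvcsf[0] == pytest.approx(-4 * np.pi * 0.05**2 * delta, rel=0.01)

    def test_small_rigid_rotation(self):
        surf = icosphere(0.05, subdiv=3)
        theta = np.array([0, 0, 3e-4])
        disp = np.cross(theta, surf.face_centroids)[None]
        feats = dfm.extract_features(
            dfm.SurfaceDisplacementSeries(surf, disp)
        )
        assert feats.rs_magnitude[0] == pytest.approx(np.linalg.norm(theta), rel=0.01)
        assert feats.ts_magnitude[0] < 1e-3 * np.linalg.norm(theta) * 0.05
        assert abs(feats.dvcsf[0]) < 1e-6 * surf.area * np.linalg.norm(theta) * 0.05

    def test_rigid_body_gives_zero_volume_change(self):
        # closed-surface invariant: |dVCSF| < 1e-6 * area * |d| for rigid motion
        surf = icosphere(0.04, subdiv=2)
        rng = np.random.default_rng(11)
        t = rng.normal(scale=2e-5, size=3)
        theta = rng.normal(scale=4e-4, size=3)
        disp = (t + np.cross(theta, surf.face_centroids))[None]
        feats = dfm.extract_features(dfm.SurfaceDisplacementSeries(surf, disp))
        dmax = np.linalg.norm(disp, axis=-1).max()
        assert abs(feats.dvcsf[0]) < 1e-6 * surf.area * dmax

    def test_feature_extraction_is_linear(self):
        surf = icosphere(0.05)
        rng = np.random.default_rng(2)
        a = rng.normal(scale=1e-5, size=(2, surf.n_faces, 3))
        b = rng.normal(scale=1e-5, size=(2, surf.n_faces, 3))
        fa = dfm.extract_features(dfm.SurfaceDisplacementSeries(surf, a))
        fb = dfm.extract_features(dfm.SurfaceDisplacementSeries(surf, b))
        fab = dfm.extract_features(dfm.SurfaceDisplacementSeries(surf, a + 2 * b))
        assert np.allclose(fab.dvcsf, fa.dvcsf + 2 * fb.dvcsf, rtol=1e-10)
        assert np.allclose(fab.ts, fa.ts + 2 * fb.ts, rtol=1e-10)
        assert np.allclose(fab.rs, fa.rs + 2 * fb.rs, rtol=1e-10)


class TestSubintervals:
    def test_intervals_tile_the_cycle(self):
        surf = icosphere(0.03, subdiv=1)
        rng = np.random.default_rng(4)
        disp = rng.normal(scale=1e-5, size=(20, surf.n_faces, 3))
        sds = dfm.SurfaceDisplacementSeries(surf, disp)
        sub = dfm.subinterval_motion(sds, 6)
        assert sub.shape[0] == 6
        assert np.allclose(sub.sum(axis=0), disp[-1] - disp[0])

    def test_periodic_series_sums_to_zero(self):
        surf = icosphere(0.03, subdiv=1)
        t = np.arange(20)
        wave = np.sin(2 * np.pi * t / 19)  # first == last
        disp = 1e-5 * wave[:, None, None] * surf.face_normals[None]
        sub = dfm.subinterval_motion(dfm.SurfaceDisplacementSeries(surf, disp), 6)
        assert np.abs(sub.sum(axis=0)).max() < 1e-18
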