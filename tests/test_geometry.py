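"""Geometry tests: Laplace relaxation against analytic harmonics,
gradient stencils against Taylor expansions, orientation extraction,
cosine-similarity anchors, surface construction and sampling, and the
macrostructure metrics."""

import numpy as np
import pytest

from hippodiff import geometry as geo
from hippodiff import synthetic_cohort as sc
from hippodiff import signal_models as sm
from hippodiff import model_fitting as mf


class TestLaplace:
    def test_rectangular_slab_linear_ramp(self, rect_domain):
        """Opposite Dirichlet faces on a slab give the linear harmonic."""
        m = rect_domain.mask
        for axis, ax_idx in (("AP", 0), ("PD", 1), ("IO", 2)):
            psi = rect_domain.psi[axis]
            idx = np.indices(m.shape)[ax_idx]
            lo, hi = idx[m].min(), idx[m].max()
            ramp = (idx - lo) / (hi - lo)
            assert np.abs(psi[m] - ramp[m]).max() <= 1e-5

    def test_maximum_principle(self, rect_domain, curved_domain):
        for dom in (rect_domain, curved_domain):
            for axis in ("AP", "PD", "IO"):
                psi = dom.psi[axis]
                src, snk = dom.boundary_masks(axis)
                interior = dom.mask & ~src & ~snk
                assert psi[interior].min() > 0.0
                assert psi[interior].max() < 1.0

    def test_monotone_along_streamlines(self, curved_domain):
        """psi increases monotonically along source-to-sink streamlines
        traced through the gradient field (independent RK oracle)."""
        dom = curved_domain
        psi = geo._filled_field(dom.psi["AP"], dom.mask)
        grad = np.stack(np.gradient(psi), axis=-1)
        src, _ = dom.boundary_masks("AP")
        starts = np.argwhere(src)[::3].astype(float)
        n_traced = 0
        for p in starts:
            g0 = np.array([geo._trilinear(grad[..., c], p[None])[0]
                           for c in range(3)])
            if np.linalg.norm(g0) < 1e-6:
                continue  # flat corner voxel of the extended field
            n_traced += 1
            vals = [geo._trilinear(psi, p[None])[0]]
            for _ in range(400):
                g = np.array([geo._trilinear(grad[..., c], p[None])[0]
                              for c in range(3)])
                n = np.linalg.norm(g)
                if n < 1e-10:
                    break
                p = p + 0.25 * g / n
                v = geo._trilinear(psi, p[None])[0]
                vals.append(v)
                if v >= 1 - 1e-6:
                    break
            diffs = np.diff(vals)
            assert np.all(diffs > -1e-9)
            assert vals[-1] > 0.95
        assert n_traced >= 5

    def test_nonconvergence_raises(self, rect_domain):
        dom = sc.generate_domain((16, 12, 10), seed=0, curved=False)
        with pytest.raises(RuntimeError):
            geo.solve_laplace(dom, "AP", tol=1e-14, max_iter=3)


class TestGradientField:
    def test_linear_ramp_constant_gradient(self):
        mask = np.ones((10, 8, 6), dtype=bool)
        x = np.indices(mask.shape)[0].astype(float)
        L = 9.0
        vf = geo.gradient_field(x / L, mask, voxel_size=1.0)
        assert np.allclose(vf.vectors[..., 0], 1.0 / L)
        assert np.allclose(vf.vectors[..., 1:], 0.0)

    def test_constant_field_flagged_degenerate(self):
        mask = np.ones((8, 8, 8), dtype=bool)
        vf = geo.gradient_field(np.ones(mask.shape), mask)
        assert not vf.valid.any()

    def test_quadratic_taylor_error(self):
        """Central differences on psi = x^2 return 2x exactly (the O(h^2)
        truncation term of a quadratic vanishes)."""
        mask = np.ones((12, 6, 6), dtype=bool)
        x = np.indices(mask.shape)[0].astype(float)
        vf = geo.gradient_field(x ** 2, mask)
        interior = np.zeros_like(mask)
        interior[1:-1] = True
        assert np.allclose(vf.vectors[interior][:, 0],
                           2.0 * x[interior], atol=1e-10)

    def test_voxel_size_scaling(self):
        mask = np.ones((8, 6, 6), dtype=bool)
        x = np.indices(mask.shape)[0].astype(float)
        vf = geo.gradient_field(x, mask, voxel_size=0.5)
        assert np.allclose(vf.vectors[..., 0], 2.0)


class TestPrimaryPeak:
    def test_stick_tensor_peak_along_axis(self):
        D = sm.tensor_from_eigen([1.7, 0.0, 0.0], e1=(0, 0, 1))
        field = np.broadcast_to(D, (2, 2, 2, 3, 3))
        vf = geo.primary_peak(tensor_field=field)
        assert np.allclose(np.abs(vf.vectors[..., 2]), 1.0)

    def test_sign_canonicalization(self):
        peaks = np.array([[[[-1.0, 0.0, 0.0]]], [[[0.0, -2.0, 0.0]]]])
        vf = geo.primary_peak(peak_volume=peaks)
        assert vf.vectors[0, 0, 0, 0] == 1.0
        assert vf.vectors[1, 0, 0, 1] == 1.0

    def test_zero_peak_excluded(self):
        peaks = np.zeros((1, 1, 1, 3))
        vf = geo.primary_peak(peak_volume=peaks)
        assert not vf.valid.any()

    def test_external_peak_roundtrip(self, tmp_path):
        rng = np.random.default_rng(0)
        peaks = rng.normal(size=(3, 3, 3, 3))
        peaks /= np.linalg.norm(peaks, axis=-1, keepdims=True)
        np.save(tmp_path / "peaks.npy", peaks)
        back = np.load(tmp_path / "peaks.npy")
        a = geo.primary_peak(peak_volume=peaks)
        b = geo.primary_peak(peak_volume=back)
        assert np.array_equal(a.vectors, b.vectors)

    def test_fit_then_extract_angular_error(self, scheme):
        """Noiseless tensor signals with a known orientation: fitting and
        extracting the principal eigenvector recovers mu within 1 deg."""
        rng = np.random.default_rng(1)
        n = 20
        sig = np.zeros((n, 1, 1, scheme.n_volumes))
        mus = np.zeros((n, 3))
        for i in range(n):
            mu = rng.normal(size=3)
            mu /= np.linalg.norm(mu)
            mus[i] = mu
            D = sm.tensor_from_eigen([1.7, 0.3, 0.3], e1=mu)
            sig[i, 0, 0] = sm.dti_signal(sm.TensorParams(D=D), scheme)
        mask = np.ones((n, 1, 1), dtype=bool)
        fit = mf.fit_dti(sig, scheme, mask)
        vf = geo.primary_peak(tensor_field=fit.maps["D"], mask=mask)
        dots = np.abs(np.einsum("ni,ni->n", vf.vectors[:, 0, 0], mus))
        assert np.all(np.degrees(np.arccos(np.clip(dots, -1, 1))) <= 1.0)

    def test_requires_exactly_one_source(self):
        with pytest.raises(ValueError):
            geo.primary_peak()


class TestCosineSimilarity:
    @staticmethod
    def _fields(peak, grads):
        pv = np.array(peak, float).reshape(1, 1, 1, 3)
        peaks = geo.VectorField(pv, provenance="fODF-peak1")
        gfs = {ax: geo.VectorField(np.array(g, float).reshape(1, 1, 1, 3),
                                   provenance="gradient-of-psi")
               for ax, g in grads.items()}
        return peaks, gfs

    def test_orthogonal_gives_zero(self):
        peaks, grads = self._fields([1, 0, 0], {"AP": [0, 1, 0],
                                                "PD": [0, 1, 0],
                                                "IO": [0, 1, 0]})
        maps = geo.cosine_similarity_maps(peaks, grads)
        assert maps["long_axis"][0, 0, 0] == 0.0

    def test_parallel_gives_one(self):
        peaks, grads = self._fields([0, 0, 1], {"AP": [0, 0, 1],
                                                "PD": [0, 0, 1],
                                                "IO": [0, 0, 1]})
        maps = geo.cosine_similarity_maps(peaks, grads)
        assert maps["long_axis"][0, 0, 0] == pytest.approx(1.0)

    def test_antiparallel_gives_one(self):
        peaks, grads = self._fields([0, 0, 1], {"AP": [0, 0, -1],
                                                "PD": [0, 0, -1],
                                                "IO": [0, 0, -1]})
        maps = geo.cosine_similarity_maps(peaks, grads)
        assert maps["radial"][0, 0, 0] == pytest.approx(1.0)

    def test_invariant_to_sign_flip_and_scaling(self, rng):
        v = rng.normal(size=3)
        w = rng.normal(size=3)
        base, grads = self._fields(v, {"AP": w, "PD": w, "IO": w})
        m1 = geo.cosine_similarity_maps(base, grads)
        flipped, grads2 = self._fields(-2.5 * v, {"AP": 0.3 * w,
                                                  "PD": -w, "IO": 4 * w})
        m2 = geo.cosine_similarity_maps(flipped, grads2)
        for key in m1:
            assert m1[key][0, 0, 0] == pytest.approx(m2[key][0, 0, 0],
                                                     rel=1e-12)

    def test_zero_vector_excluded(self):
        peaks, grads = self._fields([0, 0, 0], {"AP": [1, 0, 0],
                                                "PD": [1, 0, 0],
                                                "IO": [1, 0, 0]})
        maps = geo.cosine_similarity_maps(peaks, grads)
        assert np.isnan(maps["long_axis"][0, 0, 0])

    def test_peak_parallel_to_ap_gradient_field(self, curved_domain):
        """A peak field constructed parallel to grad(psi_AP) gives a
        long-axis map of 1 and tangential/radial maps consistent with the
        local axis angles, up to discretization."""
        dom = curved_domain
        grads = {ax: geo.gradient_field(dom.psi[ax], dom.mask)
                 for ax in ("AP", "PD", "IO")}
        peaks = geo.primary_peak(peak_volume=grads["AP"].vectors,
                                 mask=dom.mask)
        maps = geo.cosine_similarity_maps(peaks, grads)
        interior = dom.mask.copy()
        for axis in ("AP", "PD", "IO"):
            src, snk = dom.boundary_masks(axis)
            interior &= ~src & ~snk
        vals = maps["long_axis"][interior]
        assert np.nanmedian(vals) > 0.99


class TestSurface:
    def test_rectangular_midthickness_is_midplane(self, rect_domain):
        surf = geo.build_midthickness_surface(rect_domain, n_ap=12, n_pd=8)
        m = rect_domain.mask
        k = np.indices(m.shape)[2]
        k_lo, k_hi = k[m].min(), k[m].max()
        mid = (k_lo + k_hi) / 2.0 + 0.5  # voxel-centre native coordinate
        z = surf.vertices_native[surf.valid, 2]
        assert np.allclose(z, mid, atol=1e-3)

    def test_default_grid_has_7260_vertices(self, full_surface):
        assert full_surface.n_vertices == 7260
        assert full_surface.grid_shape == (121, 60)

    def test_labels_partition_vertices(self, surface):
        assert surface.subfield.min() >= 0
        assert surface.subfield.max() < len(geo.SUBFIELD_LABELS)
        assert surface.ap_band.min() >= 0
        assert surface.ap_band.max() < len(geo.AP_LABELS)
        # every vertex has exactly one label per scheme by construction
        assert surface.subfield.shape == (surface.n_vertices,)

    def test_unfolded_coordinates_form_regular_grid(self, surface):
        uf = surface.vertices_unfolded
        n_ap, n_pd = surface.grid_shape
        assert len(np.unique(np.round(uf[:, 0], 12))) == n_ap
        assert len(np.unique(np.round(uf[:, 1], 12))) == n_pd


class TestSampling:
    def test_constant_volume(self, curved_domain, surface):
        vol = np.full(curved_domain.mask.shape, 3.25)
        vals = geo.sample_to_surface(vol, surface, curved_domain)
        sampled = vals[surface.valid]
        finite = np.isfinite(sampled)
        # vertices whose enclosing voxel leaves the mask are missing
        assert finite.mean() > 0.9
        assert np.allclose(sampled[finite], 3.25)

    def test_enclosing_voxel_lookup(self, curved_domain, surface):
        """Checkerboard volume sampled with the enclosing method equals
        direct floor-division index arithmetic."""
        shape = curved_domain.mask.shape
        ii, jj, kk = np.indices(shape)
        vol = ((ii + jj + kk) % 2).astype(float)
        vals = geo.sample_to_surface(vol, surface, curved_domain)
        idx = np.floor(surface.vertices_native
                       / curved_domain.voxel_size).astype(int)
        expect = ((idx.sum(axis=1)) % 2).astype(float)
        ok = surface.valid & np.isfinite(vals)
        assert np.array_equal(vals[ok], expect[ok])

    def test_vertex_at_voxel_centre(self, rect_domain):
        surf = geo.build_midthickness_surface(rect_domain, n_ap=10, n_pd=8)
        rng = np.random.default_rng(0)
        vol = rng.normal(size=rect_domain.mask.shape)
        vals = geo.sample_to_surface(vol, surf, rect_domain)
        v0 = np.nonzero(surf.valid)[0][0]
        i, j, k = np.floor(surf.vertices_native[v0]).astype(int)
        assert vals[v0] == vol[i, j, k]

    def test_out_of_bounds_vertex_raises(self, curved_domain, surface):
        bad = geo.SurfaceModel(
            vertices_native=surface.vertices_native + 1000.0,
            vertices_unfolded=surface.vertices_unfolded,
            faces=surface.faces, subfield=surface.subfield,
            ap_band=surface.ap_band, native_area=surface.native_area,
            unfolded_area=surface.unfolded_area,
            grid_shape=surface.grid_shape, valid=surface.valid)
        with pytest.raises(ValueError):
            geo.sample_to_surface(np.zeros(curved_domain.mask.shape), bad,
                                  curved_domain)


class TestMacrostructure:
    def test_slab_thickness(self, rect_domain):
        surf = geo.build_midthickness_surface(rect_domain, n_ap=10, n_pd=8)
        thickness, gyr, vol = geo.macrostructure(rect_domain, surf)
        m = rect_domain.mask
        k = np.indices(m.shape)[2]
        true_t = float(k[m].max() - k[m].min())  # psi=0 to psi=1 layers
        med = np.nanmedian(thickness)
        assert med == pytest.approx(true_t, abs=0.75)

    def test_undistorted_gyrification_is_one(self, rect_domain):
        surf = geo.build_midthickness_surface(rect_domain, n_ap=10, n_pd=8)
        _, gyr, _ = geo.macrostructure(rect_domain, surf)
        # interior vertices of a flat slab: area ratio exactly uniform
        n_ap, n_pd = surf.grid_shape
        interior = np.ones(surf.n_vertices, dtype=bool).reshape(n_ap, n_pd)
        interior[[0, -1], :] = False
        interior[:, [0, -1]] = False
        assert np.allclose(gyr[interior.ravel()], 1.0, atol=0.05)

    def test_volume_conservation(self, curved_domain, surface):
        _, _, vol = geo.macrostructure(curved_domain, surface)
        total = curved_domain.n_voxels * curved_domain.voxel_size ** 3
        assert vol["volume"].sum() == pytest.approx(total)


class TestGiftiIO:
    def test_surface_and_func_roundtrip(self, surface, tmp_path):
        geo.save_surface_gifti(surface, tmp_path / "mid.surf.gii")
        vals = np.linspace(0, 1, surface.n_vertices)
        geo.save_func_gifti(vals, tmp_path / "map.func.gii")
        back = geo.load_func_gifti(tmp_path / "map.func.gii")
        assert np.allclose(back, vals, atol=1e-6)
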