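import numpy as np
import pytest

import myelinmap as mm
from myelinmap.errors import InvalidArgumentError


def auc_threshold_loop(values, pct):
    """Brute-force sort-and-accumulate oracle for the AUC threshold."""
    vals = np.sort(values[np.isfinite(values)])
    p3, p97 = np.percentile(vals, [3, 97])
    trunc = vals[(vals >= p3) & (vals <= p97)]
    k = pct / 100.0 * (len(trunc) - 1)
    lo = int(np.floor(k))
    hi = int(np.ceil(k))
    return trunc[lo] + (k - lo) * (trunc[hi] - trunc[lo])


class TestAucThreshold:
    def test_endpoints_are_percentiles(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=2000)
        p3, p97 = np.percentile(vals, [3, 97])
        # endpoints sit at the band edges up to one sample spacing
        tol = 0.01 * (p97 - p3)
        assert mm.auc_threshold(vals, 0) == pytest.approx(p3, abs=tol)
        assert mm.auc_threshold(vals, 100) == pytest.approx(p97, abs=tol)

    def test_uniform_closed_form(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(0, 100, size=100_000)
        # p3 + 0.75 * (p97 - p3) = 3 + 0.75 * 94 = 73.5
        assert mm.auc_threshold(vals, 75) == pytest.approx(73.5, abs=0.5)

    def test_monotone_in_pct(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=500)
        thrs = [mm.auc_threshold(vals, p) for p in range(0, 101, 5)]
        assert np.all(np.diff(thrs) >= 0)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(3)
        vals = rng.exponential(size=997)
        for pct in (10, 50, 75, 80, 85, 90):
            want = auc_threshold_loop(vals, pct)
            assert mm.auc_threshold(vals, pct) == pytest.approx(want, abs=1e-9)

    def test_out_of_range_pct_rejected(self):
        with pytest.raises(InvalidArgumentError):
            mm.auc_threshold(np.arange(10.0), 101)


class TestCoverageProfile:
    def test_threshold_below_minimum_gives_full_coverage(self, ico3, ico3_atlas):
        rng = np.random.default_rng(4)
        vals = rng.uniform(10, 20, ico3.n_vertices)
        lb = ico3_atlas.region_labels[0]
        vals[ico3_atlas.vertices_of(lb)] = 25.0  # above the global p97
        prof = mm.coverage_profile(vals, ico3_atlas, lb, [0])
        assert prof[0] == pytest.approx(100.0)

    def test_counting(self):
        from myelinmap.atlas import ROIAtlas, RegionInfo
        labels = np.array([1, 1, 1, 1] + [0] * 96)
        atlas = ROIAtlas(labels, {0: RegionInfo("BG", "light", None),
                                  1: RegionInfo("A", "heavy", 0)})
        vals = np.concatenate([[1.0, 2.0, 3.0, 4.0],
                               np.linspace(0, 5, 96)])
        thr = mm.auc_threshold(vals, 50)
        prof = 100.0 * np.mean(np.array([1.0, 2.0, 3.0, 4.0]) >= thr)
        got = mm.coverage_profile(vals, atlas, 1, [50])
        assert got[0] == pytest.approx(prof)

    def test_profile_non_increasing(self, ico3, ico3_atlas):
        rng = np.random.default_rng(5)
        vals = rng.normal(size=ico3.n_vertices)
        for lb in ico3_atlas.region_labels[:4]:
            prof = mm.coverage_profile(vals, ico3_atlas, lb,
                                       range(60, 91, 5))
            assert np.all(np.diff(prof) <= 1e-12)


class TestContours:
    def test_uniform_masks_give_empty_contour(self, ico3):
        vals = np.full(ico3.n_vertices, 1.0)
        _, edges = mm.binarize_and_contour(ico3, vals, 0.0)
        assert len(edges) == 0
        _, edges = mm.binarize_and_contour(ico3, vals, 2.0)
        assert len(edges) == 0

    def test_single_vertex_star(self, planar):
        interior = np.setdiff1d(np.arange(planar.n_vertices),
                                planar.boundary_vertices())
        v = int(interior[0])
        vals = np.zeros(planar.n_vertices)
        vals[v] = 1.0
        bp, edges = mm.binarize_and_contour(planar, vals, 0.5)
        assert bp.mask.sum() == 1
        assert len(edges) == len(planar.neighbors[v])
        assert all(v in pair for pair in edges.tolist())

    def test_contours_close_on_sphere(self, ico3):
        # every triangle of a closed mesh has 0 or 2 straddling edges,
        # so contour edges chain into closed loops
        rng = np.random.default_rng(6)
        vals = rng.normal(size=ico3.n_vertices)
        bp, edges = mm.binarize_and_contour(ico3, vals, 0.3)
        straddle = {tuple(sorted(e)) for e in edges.tolist()}
        for tri in ico3.triangles:
            cnt = sum(tuple(sorted((int(tri[i]), int(tri[(i + 1) % 3]))))
                      in straddle for i in range(3))
            assert cnt in (0, 2)

    def test_nan_vertices_are_false(self, ico3):
        vals = np.full(ico3.n_vertices, 5.0)
        vals[0] = np.nan
        bp, _ = mm.binarize_and_contour(ico3, vals, 1.0)
        assert not bp.mask[0] and bp.mask[1:].all()


class TestJaccard:
    def test_identical_masks(self):
        m = np.array([True, False, True])
        assert mm.jaccard(m, m) == 1.0

    def test_disjoint_masks(self):
        assert mm.jaccard(np.array([True, False]), np.array([False, True])) == 0.0

    def test_counting(self):
        a = np.array([True, True, False, False])
        b = np.array([True, False, True, False])
        assert mm.jaccard(a, b) == pytest.approx(1 / 3)

    def test_empty_empty_convention(self):
        z = np.zeros(5, bool)
        assert mm.jaccard(z, z) == 1.0

    def test_symmetry_and_identity(self):
        rng = np.random.default_rng(7)
        a = rng.random(50) > 0.5
        b = rng.random(50) > 0.5
        assert mm.jaccard(a, b) == mm.jaccard(b, a)
        assert (mm.jaccard(a, b) == 1.0) == np.array_equal(a, b)

    def test_mismatched_vertex_sets_rejected(self):
        with pytest.raises(InvalidArgumentError):
            mm.jaccard(np.zeros(3, bool), np.zeros(4, bool))


class TestSurfaceGradient:
    def test_constant_field_zero_gradient(self, planar):
        g = mm.surface_gradient(planar, np.full(planar.n_vertices, 3.0))
        assert np.nanmax(g) == pytest.approx(0.0, abs=1e-12)

    def test_linear_field_exact(self, planar):
        # f(x, y) = 3x + 4y has |grad| = 5 everywhere
        vals = 3.0 * planar.vertices[:, 0] + 4.0 * planar.vertices[:, 1]
        g = mm.surface_gradient(planar, vals)
        interior = np.setdiff1d(np.arange(planar.n_vertices),
                                planar.boundary_vertices())
        assert np.allclose(g[interior], 5.0, rtol=1e-12, atol=1e-10)

    def test_scaling_linearity(self, planar):
        rng = np.random.default_rng(8)
        vals = rng.normal(size=planar.n_vertices)
        g1 = mm.surface_gradient(planar, vals)
        g2 = mm.surface_gradient(planar, -2.5 * vals)
        assert np.allclose(g2, 2.5 * g1, equal_nan=True)

    def test_step_field_localized(self):
        mesh = mm.build_mesh("planar_patch", 18, spacing=1.0)  # 20x20 grid
        x = mesh.vertices[:, 0]
        step_at = 9.5
        vals = (x > step_at).astype(float)
        g = mm.surface_gradient(mesh, vals)
        strong = np.flatnonzero(np.nan_to_num(g) > 0.25)
        assert len(strong) > 0
        assert np.all(np.abs(x[strong] - step_at) <= 1.0 + 1e-9)

    def test_angle_weighted_normals_variant(self, planar):
        vals = 2.0 * planar.vertices[:, 0]
        g = mm.surface_gradient(planar, vals, normal_weighting="angle")
        interior = np.setdiff1d(np.arange(planar.n_vertices),
                                planar.boundary_vertices())
        assert np.allclose(g[interior], 2.0, atol=1e-10)


class TestGradientBorders:
    def test_zero_threshold_keeps_all_defined(self, planar):
        rng = np.random.default_rng(9)
        g = mm.surface_gradient(planar, rng.normal(size=planar.n_vertices))
        bp = mm.gradient_borders(g, 0.0)
        assert bp.mask.sum() == np.isfinite(g).sum()

    def test_threshold_above_max_empty(self, planar):
        rng = np.random.default_rng(10)
        g = mm.surface_gradient(planar, rng.normal(size=planar.n_vertices))
        assert mm.gradient_borders(g, np.nanmax(g) + 1).mask.sum() == 0

    def test_negative_threshold_rejected(self):
        with pytest.raises(InvalidArgumentError):
            mm.gradient_borders(np.zeros(4), -0.1)
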