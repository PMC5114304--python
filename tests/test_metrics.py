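import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import myelinmap as mm
from myelinmap.errors import (DegenerateContrastError,
                              DegenerateDistributionError,
                              InvalidArgumentError)
from myelinmap.metrics import GAUSSIAN_FWHM_FACTOR


# ---------------------------------------------------------------------------
# independent straight-loop oracles
# ---------------------------------------------------------------------------

def cov_loop(stack, fwhm):
    out = []
    for v in range(stack.shape[1]):
        vals = stack[:, v]
        mu = sum(vals) / len(vals)
        sd = (sum((x - mu) ** 2 for x in vals) / (len(vals) - 1)) ** 0.5
        out.append(sd / mu / fwhm if mu > 0 else float("nan"))
    return np.array(out)


def pv_loop(stacks, fwhm_raw):
    n_vert = stacks[0].shape[1]
    out = []
    for v in range(n_vert):
        sds = []
        for s in stacks:
            vals = s[:, v]
            mu = sum(vals) / len(vals)
            sds.append((sum((x - mu) ** 2 for x in vals) / (len(vals) - 1)) ** 0.5)
        out.append(sum(sds) / len(sds) / fwhm_raw)
    return np.array(out)


def cnr_loop(values, roi_idx, nb_idx, refs, minutes):
    pooled = [values[i] for i in roi_idx] + [values[i] for i in nb_idx]
    mu = sum(pooled) / len(pooled)
    sd = (sum((x - mu) ** 2 for x in pooled) / (len(pooled) - 1)) ** 0.5
    return np.array([abs(values[i] - r) / sd / minutes ** 0.5
                     for i, r in zip(roi_idx, refs)])


class TestRescaleUnit:
    def test_integers_0_to_100(self):
        vals = np.arange(101, dtype=float)
        out = mm.rescale_unit(vals)
        assert out[50] == pytest.approx((50 - 3) / 94)
        assert out[3] == pytest.approx(0.0)
        assert out[97] == pytest.approx(1.0)

    def test_affine_invariance(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=500)
        assert np.allclose(mm.rescale_unit(vals),
                           mm.rescale_unit(3.2 * vals + 7.0), atol=1e-12)

    def test_values_outside_band_not_clamped(self):
        out = mm.rescale_unit(np.arange(101, dtype=float))
        assert out[0] < 0 and out[100] > 1

    def test_constant_input_rejected(self):
        with pytest.raises(DegenerateDistributionError):
            mm.rescale_unit(np.full(10, 2.0))


@settings(max_examples=30, derandomize=True, deadline=None)
@given(a=st.floats(0.01, 1e3), b=st.floats(-1e3, 1e3))
def test_rescale_affine_invariance_property(a, b):
    """Rescaled values are unchanged by any positive affine input transform."""
    vals = np.linspace(-5, 17, 200)
    assert np.allclose(mm.rescale_unit(vals), mm.rescale_unit(a * vals + b),
                       atol=1e-9)


@settings(max_examples=30, derandomize=True, deadline=None)
@given(c=st.floats(0.01, 1e3), seed=st.integers(0, 10_000))
def test_cov_scale_invariance_property(c, seed):
    """sigma/mu and the rescaled FWHM both cancel a positive global scale."""
    stack = np.random.default_rng(seed).uniform(1, 9, size=(3, 12))
    assert np.allclose(mm.cov_vertexwise(stack, 0.4, "inter"),
                       mm.cov_vertexwise(c * stack, 0.4, "inter"), rtol=1e-9)


class TestEstimateFWHM:
    @pytest.mark.parametrize("method", ["histogram", "kde"])
    def test_gaussian_closed_form(self, method):
        rng = np.random.default_rng(1)
        sigma = 0.7
        n = 1_000_000 if method == "histogram" else 100_000
        vals = rng.normal(0.0, sigma, size=n)
        fwhm = mm.estimate_fwhm(vals, method)
        assert fwhm == pytest.approx(GAUSSIAN_FWHM_FACTOR * sigma, rel=0.02)

    def test_point_mass_with_jitter_tends_to_zero(self):
        rng = np.random.default_rng(2)
        vals = 5.0 + 1e-6 * rng.normal(size=10_000)
        assert mm.estimate_fwhm(vals) < 1e-5

    def test_degenerate_rejected(self):
        with pytest.raises(DegenerateDistributionError):
            mm.estimate_fwhm(np.full(100, 1.0))

    def test_summary_has_consistent_fields(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(10.0, 2.0, size=5000)
        s = mm.summarize_distribution(vals)
        assert s.p3 < s.p97
        assert s.fwhm_raw > 0 and 0 < s.fwhm_rescaled <= 1.2
        band = s.p97 - s.p3
        assert s.auc_quantile(0) == pytest.approx(s.p3, abs=0.01 * band)
        assert s.auc_quantile(100) == pytest.approx(s.p97, abs=0.01 * band)
        # rescaled FWHM = raw FWHM / (p97 - p3) for a linear rescale
        assert s.fwhm_rescaled == pytest.approx(s.fwhm_raw / (s.p97 - s.p3),
                                                rel=0.05)


class TestCOV:
    def test_two_subject_arithmetic(self):
        # values {9, 11}: sd/mean = 1.4142/10, normalized by 0.4026
        stack = np.array([[9.0], [11.0]])
        cov = mm.cov_vertexwise(stack, fwhm_rescaled=0.4026, kind="inter")
        assert cov[0] == pytest.approx(np.sqrt(2) / 10 / 0.4026, rel=1e-12)
        assert cov[0] == pytest.approx(0.3513, abs=1e-4)

    def test_identical_sessions_zero_intra(self):
        m = np.random.default_rng(0).normal(10, 1, size=20)
        cov = mm.cov_vertexwise([np.stack([m, m])], 0.4, kind="intra")
        assert np.allclose(cov, 0.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(4)
        stack = rng.uniform(5, 15, size=(4, 30))
        a = mm.cov_vertexwise(stack, 0.5, "inter")
        b = mm.cov_vertexwise(7.3 * stack, 0.5, "inter")
        assert np.allclose(a, b, rtol=1e-12)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(5)
        stack = rng.uniform(1, 3, size=(5, 17))
        got = mm.cov_vertexwise(stack, 0.37, "inter")
        assert np.allclose(got, cov_loop(stack, 0.37), atol=1e-12)

    def test_nonpositive_mean_marked(self):
        stack = np.array([[-1.0, 1.0], [-3.0, 2.0]])
        cov = mm.cov_vertexwise(stack, 0.5, "inter")
        assert np.isnan(cov[0]) and np.isfinite(cov[1])

    def test_single_subject_rejected(self):
        with pytest.raises(InvalidArgumentError):
            mm.cov_vertexwise(np.ones((1, 5)), 0.5, "inter")


class TestPV:
    def test_zero_sd_zero_pv(self):
        assert np.allclose(mm.pv_vertexwise(np.zeros(10), 0.05), 0.0)

    def test_arithmetic(self):
        pv = mm.pv_vertexwise(np.array([0.005]), 0.0503)
        assert pv[0] == pytest.approx(0.0994, abs=1e-4)

    def test_affine_invariance(self):
        # affine map x -> a x + b scales both scan-rescan sd and raw FWHM by a
        rng = np.random.default_rng(6)
        stacks = [rng.normal(10, 1, size=(2, 25)) for _ in range(3)]
        sd1 = mm.scan_rescan_sd(stacks)
        sd2 = mm.scan_rescan_sd([2.5 * s + 4.0 for s in stacks])
        assert np.allclose(mm.pv_vertexwise(sd1, 0.1),
                           mm.pv_vertexwise(sd2, 0.25), rtol=1e-12)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(7)
        stacks = [rng.uniform(1, 2, size=(3, 12)) for _ in range(3)]
        got = mm.pv_vertexwise(mm.scan_rescan_sd(stacks), 0.08)
        assert np.allclose(got, pv_loop(stacks, 0.08), atol=1e-12)


class TestCNR:
    def _two_region_atlas(self, roi_vals, nb_vals):
        from myelinmap.atlas import ROIAtlas, RegionInfo
        labels = np.array([1] * len(roi_vals) + [0] * len(nb_vals))
        table = {0: RegionInfo("BG", "light", None),
                 1: RegionInfo("A", "heavy", 0)}
        atlas = ROIAtlas(labels, table)
        values = np.concatenate([roi_vals, nb_vals]).astype(float)
        return values, atlas

    def test_worked_example(self):
        # roi {3,3} vs neighbor {1,1}, 4 minutes: pooled sd sqrt(4/3)
        values, atlas = self._two_region_atlas([3.0, 3.0], [1.0, 1.0])
        _, (mean, se, n) = mm.cnr_per_time(values, atlas, 1, minutes=4.0,
                                           ref_mode="region_median")
        assert mean == pytest.approx(2 / np.sqrt(4 / 3) / 2, rel=1e-12)
        assert mean == pytest.approx(0.8660, abs=1e-4)
        assert n == 2

    def test_identical_regions_near_zero(self):
        rng = np.random.default_rng(8)
        vals = rng.normal(5, 1, 20)
        values, atlas = self._two_region_atlas(vals, vals)
        _, (mean, _, _) = mm.cnr_per_time(values, atlas, 1, minutes=1.0,
                                          ref_mode="region_median")
        assert mean < 1.0  # no systematic contrast

    def test_scale_invariance(self):
        rng = np.random.default_rng(9)
        values, atlas = self._two_region_atlas(rng.normal(8, 1, 10),
                                               rng.normal(4, 1, 10))
        _, (m1, _, _) = mm.cnr_per_time(values, atlas, 1, 2.0,
                                        ref_mode="random_vertex", seed=3)
        _, (m2, _, _) = mm.cnr_per_time(5.0 * values, atlas, 1, 2.0,
                                        ref_mode="random_vertex", seed=3)
        assert m1 == pytest.approx(m2, rel=1e-12)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(10)
        roi_vals = rng.uniform(2, 3, 8)
        nb_vals = rng.uniform(0, 1, 9)
        values, atlas = self._two_region_atlas(roi_vals, nb_vals)
        cnr_map, _ = mm.cnr_per_time(values, atlas, 1, 3.0,
                                     ref_mode="region_median")
        refs = np.full(8, np.median(nb_vals))
        want = cnr_loop(values, range(8), range(8, 17), refs, 3.0)
        assert np.allclose(cnr_map[:8], want, atol=1e-12)

    def test_degenerate_contrast_rejected(self):
        values, atlas = self._two_region_atlas([1.0, 1.0], [1.0, 1.0])
        with pytest.raises(DegenerateContrastError):
            mm.cnr_per_time(values, atlas, 1, 1.0)

    def test_seeded_reference_is_deterministic(self):
        rng = np.random.default_rng(11)
        values, atlas = self._two_region_atlas(rng.normal(8, 1, 10),
                                               rng.normal(4, 1, 10))
        a, _ = mm.cnr_per_time(values, atlas, 1, 1.0, seed=42)
        b, _ = mm.cnr_per_time(values, atlas, 1, 1.0, seed=42)
        assert np.array_equal(a, b, equal_nan=True)


class TestDepthwiseCorrelation:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(12)
        m = rng.normal(size=(30, 11))
        r_depth, r_avg = mm.depthwise_correlation(m, m)
        assert np.allclose(r_depth, 1.0)
        assert r_avg == pytest.approx(1.0)

    def test_negation_gives_minus_one(self):
        rng = np.random.default_rng(13)
        m = rng.normal(size=(30, 11))
        r_depth, r_avg = mm.depthwise_correlation(m, -m)
        assert np.allclose(r_depth, -1.0)
        assert r_avg == pytest.approx(-1.0)

    def test_constant_map_undefined_marker(self):
        rng = np.random.default_rng(14)
        a = rng.normal(size=(10, 11))
        b = np.ones((10, 11))
        r_depth, r_avg = mm.depthwise_correlation(a, b)
        assert np.isnan(r_depth).all() and np.isnan(r_avg)

    def test_exclusion_mask_applied(self):
        rng = np.random.default_rng(15)
        a = rng.normal(size=(20, 11))
        b = a.copy()
        b[:5] = -b[:5]  # corrupt some vertices, then exclude them
        excl = np.zeros(20, bool)
        excl[:5] = True
        r_depth, r_avg = mm.depthwise_correlation(a, b, exclude=excl)
        assert np.allclose(r_depth, 1.0)
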