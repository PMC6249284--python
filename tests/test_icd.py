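"""ICD survival curves, stretched-exponential fits, voxelwise inference,
cluster correction and influence diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage, stats

from readnet.icd import (
    DEFAULT_TAU_GRID, cluster_correct, cluster_size_threshold,
    correlation_survival, estimate_fwhm, fit_stretched_exponential,
    icd_subject, influence_check, simulate_max_cluster_sizes, smooth_map,
    stretched_exponential, voxelwise_model,
)
from readnet.motion import censor, nuisance_regress
from readnet.simulate import generate_bold, node_masks
from conftest import scaled_bold_spec

TAU = np.arange(0.0, 1.0, 0.02)


class TestSurvival:
    def test_matches_brute_force_oracle(self, rng):
        ts = rng.standard_normal((50, 30))
        curves, valid = correlation_survival(ts, TAU)
        C = np.corrcoef(ts)
        for v in range(50):
            for g, tau in enumerate(TAU):
                expect = np.mean([C[v, w] > tau for w in range(50) if w != v])
                assert abs(curves[v, g] - expect) <= 1e-12

    def test_perfectly_correlated_voxel(self, rng):
        base = rng.standard_normal(40)
        ts = np.outer(np.linspace(1, 3, 10), base)  # all r = 1
        curves, valid = correlation_survival(ts, TAU)
        assert valid.all()
        assert np.allclose(curves, 1.0)

    def test_monotone_nonincreasing_and_s0(self, rng):
        ts = rng.standard_normal((30, 25))
        curves, _ = correlation_survival(ts, TAU)
        assert np.all(np.diff(curves, axis=1) <= 1e-12)
        C = np.corrcoef(ts)
        off = ~np.eye(30, dtype=bool)
        s0 = np.array([(C[v][off[v]] > 0).mean() for v in range(30)])
        np.testing.assert_allclose(curves[:, 0], s0, atol=1e-12)

    def test_zero_variance_voxel_flagged(self, rng):
        ts = rng.standard_normal((10, 20))
        ts[3] = 5.0
        curves, valid = correlation_survival(ts, TAU)
        assert not valid[3]
        assert np.isnan(curves[3]).all()
        assert np.isfinite(curves[0]).all()

    def test_tau_grid_domain_enforced(self, rng):
        with pytest.raises(ValueError):
            correlation_survival(rng.standard_normal((5, 10)),
                                 np.array([0.5, 1.0]))


class TestStretchedExponential:
    @pytest.mark.parametrize("alpha,beta", [(2.0, 1.0), (1.5, 2.0), (0.5, 0.7)])
    def test_noiseless_recovery(self, alpha, beta):
        y = stretched_exponential(TAU, alpha, beta)
        a, b, diag = fit_stretched_exponential(TAU, y)
        assert diag["converged"]
        assert a == pytest.approx(alpha, abs=1e-6)
        assert b == pytest.approx(beta, abs=1e-6)

    def test_half_point_identity(self):
        # S(0.5) = exp(-1) when alpha = 2, beta = 1
        y = stretched_exponential(np.array([0.5]), 2.0, 1.0)
        assert y[0] == pytest.approx(np.exp(-1))

    def test_tau_zero_is_one_for_any_parameters(self, rng):
        for _ in range(20):
            a, b = rng.uniform(0.1, 5, 2)
            assert stretched_exponential(np.array([0.0]), a, b)[0] == 1.0

    def test_noisy_recovery_median_error(self, rng):
        alpha, beta = 1.5, 2.0
        errs_a, errs_b = [], []
        for _ in range(300):
            y = stretched_exponential(TAU, alpha, beta) + rng.normal(0, 0.01,
                                                                     TAU.size)
            a, b, _ = fit_stretched_exponential(TAU, np.clip(y, 0, 1))
            errs_a.append(abs(a - alpha))
            errs_b.append(abs(b - beta))
        assert np.median(errs_a) < 0.05
        assert np.median(errs_b) < 0.05

    def test_curve_domain_validated(self):
        with pytest.raises(ValueError):
            fit_stretched_exponential(TAU, np.full(TAU.size, 1.5))
        with pytest.raises(ValueError):
            fit_stretched_exponential(TAU[:3], np.ones(3))


def _residualized_subject(seed=5, carrier=True):
    spec = scaled_bold_spec(grid=(12, 14, 12), n_volumes_per_run=100,
                            n_runs=1, seed=seed)
    sb = generate_bold(spec, [carrier])[0]
    masks = sb.masks
    cm = censor(sb.motion, [r.data for r in sb.runs], masks["gm"])
    resid, _ = nuisance_regress(sb.runs[0].data, sb.motion[0], cm.keep[0],
                                masks["wm"], masks["vent"], spec.tr_s,
                                analysis_mask=masks["gm"])
    return spec, sb, resid


class TestIcdSubject:
    def test_node_voxels_have_higher_connectivity(self):
        spec, sb, resid = _residualized_subject()
        tau = np.arange(0, 1, 0.05)
        maps = icd_subject(resid, sb.masks["gm"], tau)
        nodes = node_masks(spec)
        in_node = np.any(nodes, axis=0)
        node_alpha = np.nanmedian(maps.alpha[nodes[0]])
        bg_alpha = np.nanmedian(maps.alpha[sb.masks["gm"] & ~in_node])
        assert node_alpha < bg_alpha
        # survival at tau=0.25 larger inside the planted node
        curves, _ = correlation_survival(resid[sb.masks["gm"]],
                                         np.array([0.25]))
        flat_nodes = nodes[0][sb.masks["gm"]]
        assert (np.nanmedian(curves[flat_nodes])
                > np.nanmedian(curves[~flat_nodes]))

    def test_deterministic_and_voxel_order_invariant(self):
        spec, sb, resid = _residualized_subject(seed=6)
        tau = np.arange(0, 1, 0.1)
        m1 = icd_subject(resid, sb.masks["gm"], tau)
        m2 = icd_subject(resid, sb.masks["gm"], tau)
        np.testing.assert_array_equal(m1.alpha, m2.alpha)
        # permuting voxels permutes the maps identically: check via a
        # spatial permutation of the data grid along x
        perm = np.random.default_rng(0).permutation(resid.shape[0])
        m3 = icd_subject(resid[perm], sb.masks["gm"][perm], tau)
        np.testing.assert_allclose(m1.alpha[perm], m3.alpha, equal_nan=True)


class TestSmoothing:
    def test_zero_fwhm_is_identity(self, rng):
        m = rng.standard_normal((8, 8, 8))
        mask = np.ones((8, 8, 8), bool)
        np.testing.assert_array_equal(smooth_map(m, 0.0, mask), m)

    def test_delta_half_maximum_at_half_fwhm(self):
        shape = (31, 31, 31)
        mask = np.ones(shape, bool)
        m = np.zeros(shape)
        m[15, 15, 15] = 1.0
        fwhm, vox = 12.0, 3.0
        sm = smooth_map(m, fwhm, mask, voxel_size_mm=vox)
        peak = sm[15, 15, 15]
        at_half = sm[15 + int(fwhm / 2 / vox), 15, 15]
        assert at_half / peak == pytest.approx(0.5, abs=0.02)

    def test_constant_map_unchanged_under_mask_renormalization(self):
        mask = np.zeros((10, 10, 10), bool)
        mask[2:8, 2:8, 2:8] = True
        m = np.where(mask, 3.7, np.nan)
        sm = smooth_map(m, 9.0, mask)
        np.testing.assert_allclose(sm[mask], 3.7, atol=1e-9)


def _null_maps(n, shape, mask, rng, smooth=1.0):
    return [ndimage.gaussian_filter(rng.standard_normal(shape), smooth)
            for _ in range(n)]


class TestVoxelwiseModel:
    def test_location_invariance_of_t_map(self, rng):
        shape = (8, 9, 8)
        mask = np.ones(shape, bool)
        maps = _null_maps(15, shape, mask, rng)
        covs = pd.DataFrame({"phenotype": rng.standard_normal(15)})
        t1, *_ = voxelwise_model(maps, covs, "phenotype", mask)
        covs2 = covs + 100.0
        t2, *_ = voxelwise_model(maps, covs2, "phenotype", mask)
        np.testing.assert_allclose(t1, t2, atol=1e-8)

    def test_planted_slope_detected_in_node_only(self, rng):
        shape = (10, 10, 8)
        mask = np.ones(shape, bool)
        pheno = rng.standard_normal(30)
        node = np.zeros(shape, bool)
        node[4:7, 4:7, 3:5] = True
        maps = []
        for i in range(30):
            m = rng.standard_normal(shape)
            m[node] += -1.5 * pheno[i]  # planted negative slope
            maps.append(m)
        covs = pd.DataFrame({"phenotype": pheno})
        t, p, _, dof = voxelwise_model(maps, covs, "phenotype", mask)
        assert np.median(t[node]) < stats.t.ppf(0.001, dof)
        # matched false-positive rate outside the node
        alpha = 0.01
        fpr = (p[~node] < alpha).mean()
        assert fpr < 3 * alpha + 0.01

    def test_permuted_phenotype_calibration(self, rng):
        shape = (8, 8, 6)
        mask = np.ones(shape, bool)
        maps = _null_maps(20, shape, mask, rng, smooth=0.0)
        fracs = []
        voxel_p = 0.05
        for _ in range(100):
            covs = pd.DataFrame({"phenotype": rng.permutation(20).astype(float)})
            _, p, _, _ = voxelwise_model(maps, covs, "phenotype", mask)
            fracs.append((p[mask] < voxel_p).mean())
        assert np.mean(fracs) == pytest.approx(voxel_p, abs=0.02)

    def test_too_few_subjects_rejected(self, rng):
        mask = np.ones((4, 4, 4), bool)
        maps = _null_maps(3, (4, 4, 4), mask, rng)
        covs = pd.DataFrame({"phenotype": rng.standard_normal(3),
                             "a": rng.standard_normal(3),
                             "b": rng.standard_normal(3)})
        with pytest.raises(ValueError):
            voxelwise_model(maps, covs, "phenotype", mask)


class TestClusterCorrection:
    def test_planted_cluster_recovered_at_center(self, rng):
        shape = (14, 14, 12)
        mask = np.ones(shape, bool)
        pheno = rng.standard_normal(24)
        node = np.zeros(shape, bool)
        node[5:8, 5:8, 5:8] = True  # 27-voxel block
        maps = []
        for i in range(24):
            m = ndimage.gaussian_filter(rng.standard_normal(shape), 1.0)
            m[node] += 2.0 * pheno[i]
            maps.append(m)
        covs = pd.DataFrame({"phenotype": pheno})
        t, p, resid, dof = voxelwise_model(maps, covs, "phenotype", mask)
        affine = np.diag([3.0, 3, 3, 1])
        res = cluster_correct(t, resid, mask, dof, affine, iters=500, seed=3)
        assert res.clusters, "planted cluster not detected"
        peak = np.asarray(res.clusters[0]["peak_ijk"])
        assert np.all(np.abs(peak - np.array([6, 6, 6])) <= 1)

    def test_threshold_monotone_in_fwhm(self, rng):
        mask = np.ones((12, 12, 10), bool)
        thresholds = []
        for fwhm in (3.0, 6.0, 12.0):
            sizes = simulate_max_cluster_sizes(
                mask, np.full(3, fwhm), voxel_p=0.01, iters=400,
                rng=np.random.default_rng(7))
            thresholds.append(cluster_size_threshold(sizes, 0.05))
        assert thresholds[0] <= thresholds[1] <= thresholds[2]

    def test_fwhm_estimator_recovers_smoothness(self, rng):
        shape = (20, 20, 16)
        mask = np.ones(shape, bool)
        sigma = 1.2
        maps = [ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
                for _ in range(10)]
        est = estimate_fwhm(maps, mask, voxel_size_mm=3.0)
        true_fwhm = sigma * 2 * np.sqrt(2 * np.log(2)) * 3.0
        np.testing.assert_allclose(est, true_fwhm, rtol=0.15)

    def test_small_iteration_count_warns(self):
        mask = np.ones((6, 6, 6), bool)
        with pytest.warns(UserWarning):
            simulate_max_cluster_sizes(mask, np.zeros(3), 0.01, iters=10,
                                       rng=np.random.default_rng(0))


class TestInfluence:
    def test_planted_outlier_flagged_and_slope_sign_stable(self, rng):
        n = 80
        x = rng.normal(0, 10, n)
        y = 0.5 * x + rng.normal(0, 2, n)
        x[0], y[0] = 60.0, -60.0  # extreme contrary point
        out = influence_check(y, x)
        assert 0 in out["flagged"]
        # the refit without flagged points recovers the true positive slope
        assert out["excluded_slope"] > 0
        assert out["excluded_slope"] == pytest.approx(0.5, abs=0.15)
        assert out["excluded_p"] < 0.05

    def test_clean_data_flags_few_points(self, rng):
        n = 100
        x = rng.normal(0, 10, n)
        y = 0.8 * x + rng.normal(0, 1, n)
        out = influence_check(y, x)
        assert len(out["flagged"]) <= 0.15 * n

    def test_restriction_noop_when_data_within_range(self, rng):
        n = 60
        x = rng.uniform(-15, 15, n)
        y = 0.3 * x + rng.normal(0, 1, n)
        out = influence_check(y, x, restrict_abs=20.0)
        assert out["restricted_p"] == pytest.approx(out["full_p"])
        assert out["restricted_slope"] == pytest.approx(out["full_slope"])
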