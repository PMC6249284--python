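"""Seed correlation maps, peak/sphere geometry, backward selection and
node-level genotype regressions."""

import numpy as np
import pandas as pd
import pytest

from readnet.motion import censor, nuisance_regress
from readnet.network import (
    NodeSet, analyze_network_nodes, backward_select, build_node_set,
    find_peaks, group_network, node_regression, node_values, seed_corr_map,
    sphere_roi,
)
from readnet.simulate import generate_bold, node_masks
from conftest import scaled_bold_spec

AFFINE3 = np.diag([3.0, 3.0, 3.0, 1.0])


def _centered_affine(shape, vox=3.0):
    A = np.diag([vox] * 3 + [1.0])
    A[:3, 3] = -(np.array(shape) - 1) * vox / 2.0
    return A


class TestSeedCorrMap:
    def test_closed_form_fisher_z(self, rng):
        # construct voxels with known correlation to the seed
        T = 5000
        seed_ts = rng.standard_normal(T)
        noise = rng.standard_normal(T)
        shape = (3, 1, 1)
        data = np.zeros(shape + (T,))
        data[0, 0, 0] = seed_ts
        data[1, 0, 0] = 0.5 * seed_ts + np.sqrt(1 - 0.25) * noise
        data[2, 0, 0] = rng.standard_normal(T)
        seed_mask = np.zeros(shape, bool)
        seed_mask[0, 0, 0] = True
        mask = np.ones(shape, bool)
        z = seed_corr_map(data, seed_mask, mask)
        assert z[1, 0, 0] == pytest.approx(np.arctanh(0.5), abs=0.05)
        assert abs(z[2, 0, 0]) < 0.05
        assert z[1, 0, 0] == pytest.approx(np.log(3) / 2, abs=0.05)

    def test_seed_voxel_clipped_not_infinite(self, rng):
        shape = (2, 1, 1)
        data = np.zeros(shape + (50,))
        data[0, 0, 0] = rng.standard_normal(50)
        data[1, 0, 0] = rng.standard_normal(50)
        seed_mask = np.zeros(shape, bool)
        seed_mask[0, 0, 0] = True
        z = seed_corr_map(data, seed_mask, np.ones(shape, bool))
        assert np.isfinite(z[0, 0, 0])
        assert z[0, 0, 0] > 7  # arctanh(1 - 1e-7)/2-ish: large but finite

    def test_empty_seed_rejected(self):
        with pytest.raises(ValueError):
            seed_corr_map(np.zeros((2, 2, 2, 10)), np.zeros((2, 2, 2), bool),
                          np.ones((2, 2, 2), bool))


class TestGroupNetwork:
    def test_identical_nonzero_maps_capped(self):
        shape = (4, 4, 4)
        mask = np.ones(shape, bool)
        maps = [np.full(shape, 0.5)] * 5
        t, net = group_network(maps, mask, p_thresh=1e-6)
        assert np.all(np.isfinite(t[mask]))
        assert net[mask].all()

    def test_null_maps_calibrated(self, rng):
        shape = (10, 10, 8)
        mask = np.ones(shape, bool)
        p_thresh = 0.01
        fracs = []
        for _ in range(50):
            maps = [rng.standard_normal(shape) for _ in range(12)]
            _, net = group_network(maps, mask, p_thresh=p_thresh)
            fracs.append(net[mask].mean())
        # one-sided positive mask at two-sided p: expect p_thresh / 2
        assert np.mean(fracs) == pytest.approx(p_thresh / 2, abs=0.005)

    def test_minimum_subjects(self):
        with pytest.raises(ValueError):
            group_network([np.zeros((2, 2, 2))] * 2, np.ones((2, 2, 2), bool))


class TestFindPeaks:
    def _map_with_peaks(self, shape=(20, 12, 12)):
        t = np.zeros(shape)
        return t

    def test_distant_maxima_both_kept(self):
        t = self._map_with_peaks()
        t[2, 6, 6], t[18, 6, 6] = 5.0, 4.0  # 48 mm apart
        mask = np.ones(t.shape, bool)
        peaks = find_peaks(t, mask, AFFINE3, min_sep_mm=30)
        assert len([p for p in peaks if p["value"] >= 4.0]) == 2

    def test_close_maxima_larger_wins(self):
        t = self._map_with_peaks()
        t[5, 6, 6], t[11, 6, 6] = 5.0, 4.0  # 18 mm apart
        mask = np.zeros(t.shape, bool)
        mask[4:13, 5:8, 5:8] = True
        peaks = find_peaks(t, mask, AFFINE3, min_sep_mm=30)
        vals = [p["value"] for p in peaks]
        assert 5.0 in vals and 4.0 not in vals

    def test_empty_mask_gives_empty_list(self):
        assert find_peaks(np.zeros((4, 4, 4)), np.zeros((4, 4, 4), bool),
                          AFFINE3) == []


class TestSphereRoi:
    def test_canonical_33_voxel_sphere(self):
        shape = (15, 15, 15)
        affine = _centered_affine(shape)
        roi = sphere_roi((0.0, 0.0, 0.0), shape, affine, radius_mm=6.0)
        assert roi.sum() == 33

    def test_radius_zero_single_voxel(self):
        shape = (9, 9, 9)
        affine = _centered_affine(shape)
        assert sphere_roi((0, 0, 0), shape, affine, radius_mm=0.0).sum() == 1

    def test_radius_three_face_neighbours(self):
        shape = (9, 9, 9)
        affine = _centered_affine(shape)
        assert sphere_roi((0, 0, 0), shape, affine, radius_mm=3.0).sum() == 7

    def test_matches_brute_force_offset_enumeration(self):
        shape = (15, 15, 15)
        affine = _centered_affine(shape)
        roi = sphere_roi((0.0, 0.0, 0.0), shape, affine, radius_mm=6.0)
        # voxel offsets with squared distance <= (6/3)^2 = 4
        count = sum(
            1
            for i in range(-2, 3) for j in range(-2, 3) for k in range(-2, 3)
            if i * i + j * j + k * k <= 4
        )
        assert roi.sum() == count == 33

    def test_out_of_grid_peak_rejected(self):
        shape = (9, 9, 9)
        affine = _centered_affine(shape)
        with pytest.raises(ValueError):
            sphere_roi((100.0, 0.0, 0.0), shape, affine)

    def test_edge_clipping_warns(self):
        shape = (9, 9, 9)
        affine = _centered_affine(shape)
        with pytest.warns(UserWarning):
            sphere_roi((-12.0, 0.0, 0.0), shape, affine, radius_mm=6.0)


class TestNodeValues:
    def test_constant_map(self, rng):
        shape = (9, 9, 9)
        affine = _centered_affine(shape)
        nodes = build_node_set([{"mm": (0.0, 0.0, 0.0)}], shape, affine, 6.0)
        vals = node_values([np.full(shape, 2.5)], nodes)
        assert vals.iloc[0, 0] == pytest.approx(2.5)

    def test_disjoint_spheres_read_their_regions(self):
        shape = (21, 9, 9)
        affine = _centered_affine(shape)
        m = np.zeros(shape)
        m[:10] = 1.0
        m[10:] = 3.0
        nodes = build_node_set(
            [{"mm": (-24.0, 0.0, 0.0)}, {"mm": (24.0, 0.0, 0.0)}],
            shape, affine, 3.0)
        vals = node_values([m], nodes)
        assert vals.iloc[0, 0] == pytest.approx(1.0)
        assert vals.iloc[0, 1] == pytest.approx(3.0)

    def test_matches_brute_force_mean(self, rng):
        shape = (15, 15, 15)
        affine = _centered_affine(shape)
        m = rng.standard_normal(shape)
        nodes = build_node_set([{"mm": (3.0, -3.0, 0.0)}], shape, affine, 6.0)
        vals = node_values([m], nodes)
        total, count = 0.0, 0
        for i in range(15):
            for j in range(15):
                for k in range(15):
                    if nodes.spheres[0][i, j, k]:
                        total += m[i, j, k]
                        count += 1
        assert vals.iloc[0, 0] == pytest.approx(total / count, abs=1e-12)


class TestBackwardSelection:
    def test_alpha_one_retains_everything(self, rng):
        X = pd.DataFrame(rng.standard_normal((100, 5)),
                         columns=list("abcde"))
        y = rng.standard_normal(100)
        assert backward_select(y, X, alpha=1.0) == list("abcde")

    def test_strong_covariate_retained(self, rng):
        n = 300
        X = pd.DataFrame(rng.standard_normal((n, 4)), columns=list("abcd"))
        y = 1.0 * X["b"].to_numpy() + rng.standard_normal(n)  # R^2 ~ 0.5
        retained = backward_select(y, X, alpha=0.05)
        assert "b" in retained

    def test_null_retention_rate_near_alpha(self, rng):
        counts = {c: 0 for c in "abcd"}
        n_rep = 150
        for _ in range(n_rep):
            X = pd.DataFrame(rng.standard_normal((120, 4)),
                             columns=list("abcd"))
            y = rng.standard_normal(120)
            for c in backward_select(y, X, alpha=0.05):
                counts[c] += 1
        rates = np.array(list(counts.values())) / n_rep
        assert rates.mean() == pytest.approx(0.05, abs=0.035)

    def test_empty_pool_rejected(self, rng):
        with pytest.raises(ValueError):
            backward_select(rng.standard_normal(50), pd.DataFrame())


class TestNodeRegression:
    def test_shift_invariance_of_carrier_effect(self, rng):
        n = 60
        carrier = rng.integers(0, 2, n)
        y = 0.2 * carrier + rng.normal(0, 0.1, n)
        m1 = node_regression(y, carrier)
        m2 = node_regression(y + 5.0, carrier)
        assert m1.term("carrier")["B"] == pytest.approx(m2.term("carrier")["B"])
        assert m2.term("const")["B"] == pytest.approx(
            m1.term("const")["B"] + 5.0)

    def test_constant_carrier_rejected(self, rng):
        with pytest.raises(ValueError):
            node_regression(rng.standard_normal(20), np.ones(20))

    def test_analyze_nodes_returns_model_per_node(self, rng):
        n = 80
        vals = pd.DataFrame({
            "R_SMG": rng.standard_normal(n), "ACC": rng.standard_normal(n)})
        pool = pd.DataFrame(rng.standard_normal((n, 3)), columns=list("abc"))
        carrier = rng.integers(0, 2, n)
        models = analyze_network_nodes(vals, carrier, pool)
        assert set(models) == {"R_SMG", "ACC"}
        for m in models.values():
            assert "carrier" in set(m.results["term"])


class TestEndToEndNetwork:
    def test_planted_network_recovered_and_carrier_edge_detected(self):
        """Seeding from the planted ICD node recovers all fellow nodes, and
        the carrier-dependent seed-R_SMG connection shows a positive carrier
        coefficient."""
        spec = scaled_bold_spec(grid=(14, 16, 14), n_volumes_per_run=120,
                                n_runs=2, seed=21)
        rng = np.random.default_rng(22)
        n = 24
        carriers = np.r_[np.ones(n // 2, bool), np.zeros(n // 2, bool)]
        subs = generate_bold(spec, carriers)
        masks = subs[0].masks
        nodes = node_masks(spec)
        z_maps = []
        for sb in subs:
            cm = censor(sb.motion, [r.data for r in sb.runs], masks["gm"])
            rs = [nuisance_regress(r.data, tr, k, masks["wm"], masks["vent"],
                                   spec.tr_s, analysis_mask=masks["gm"])[0]
                  for r, tr, k in zip(sb.runs, sb.motion, cm.keep)]
            resid = np.concatenate(rs, axis=-1)
            z_maps.append(seed_corr_map(resid, nodes[0], masks["gm"]))
        t_map, net = group_network(z_maps, masks["gm"], p_thresh=1e-4)
        # every planted node region intersects the network mask
        for nm in nodes:
            assert (net & nm).any()
        peaks = find_peaks(t_map, net, spec.affine, min_sep_mm=9.0)
        centers = np.array(spec.node_centers_mm)
        recovered = 0
        for c in centers:
            if any(np.linalg.norm(np.array(p["mm"]) - c) <= 6.0
                   for p in peaks):
                recovered += 1
        assert recovered >= 4
        node_set = build_node_set(peaks[:5], spec.grid_shape, spec.affine,
                                  radius_mm=spec.node_radius_mm)
        vals = node_values(z_maps, node_set)
        # the peak nearest the planted carrier-edge node (R_SMG)
        smg = np.argmin([np.linalg.norm(np.array(p) - centers[2])
                         for p in node_set.peaks_mm])
        model = node_regression(vals.iloc[:, smg], carriers.astype(float),
                                node="R_SMG")
        assert model.term("carrier")["B"] > 0
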