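"""Group-level FC, permutation inference, seed maps, modules, SNR."""

import numpy as np
import pytest
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from ratfc import analysis, filters, phantom
from ratfc.analysis import (FCMatrix, fc_vs_distance, group_fc, ic_modules, jaccard_fc_sc,
                            permutation_fwer, reproducibility, roi_timecourses, scan_fc,
                            seed_map, snr_maps, specificity_classify,
                            truncate_to_common_length, ward_linkage)
from ratfc.io_core import ROIAtlas, ValidationError, Volume4D


def _fc_from(z, sid):
    m = (z + z.T) / 2
    np.fill_diagonal(m, 0)
    return FCMatrix(z=m, roi_ids=list(range(1, z.shape[0] + 1)), subject_id=sid)


def _null_group(rng, n_subj=8, n_roi=6, t_len=80):
    fc = []
    for s in range(n_subj):
        fc.append(scan_fc(rng.standard_normal((n_roi, t_len)), subject_id=str(s)))
    return fc


class TestTruncation:
    def _scan(self, rng, t):
        return Volume4D(rng.standard_normal((3, 3, 2, t)), (1, 1, 1), 1.0)

    def test_segment_rules(self, rng):
        scans = [self._scan(rng, 600), self._scan(rng, 900), self._scan(rng, 1200),
                 self._scan(rng, 500)]
        segments, origin = truncate_to_common_length(scans, target=540)
        assert [s.n_frames for s in segments] == [540, 540, 540, 540]
        assert origin == [0, 1, 2, 2]  # the 1200-frame scan contributes twice
        np.testing.assert_array_equal(segments[3].data, scans[2].data[..., 540:1080])


class TestROITimecourses:
    def test_whole_brain_roi_is_global_mean(self, rng):
        vol = Volume4D(rng.standard_normal((4, 4, 2, 20)), (1, 1, 1), 1.0)
        labels = np.ones((4, 4, 2), np.int32)
        atlas = ROIAtlas(labels=labels, names={1: "all"})
        tc, ids = roi_timecourses(vol, atlas)
        np.testing.assert_allclose(tc[0], vol.data.mean(axis=(0, 1, 2)))

    def test_piecewise_constant_exact_recovery(self, rng):
        labels = np.zeros((4, 4, 1), np.int32)
        labels[:2] = 1
        labels[2:] = 2
        planted = rng.standard_normal((2, 30))
        data = np.zeros((4, 4, 1, 30))
        data[:2] = planted[0]
        data[2:] = planted[1]
        atlas = ROIAtlas(labels=labels, names={1: "a", 2: "b"})
        tc, ids = roi_timecourses(Volume4D(data, (1, 1, 1), 1.0), atlas)
        np.testing.assert_allclose(tc, planted, atol=1e-12)

    def test_single_voxel_roi(self, rng):
        labels = np.zeros((3, 3, 1), np.int32)
        labels[1, 1, 0] = 5
        vol = Volume4D(rng.standard_normal((3, 3, 1, 10)), (1, 1, 1), 1.0)
        atlas = ROIAtlas(labels=labels, names={5: "pt"})
        tc, ids = roi_timecourses(vol, atlas)
        np.testing.assert_array_equal(tc[0], vol.data[1, 1, 0])


class TestScanFC:
    def test_matches_brute_force_oracle(self):
        tc = np.array([[1.0, 2.0, 1.5, 0.5, 1.0],
                       [0.2, 0.9, 0.6, 0.1, 0.4],
                       [5.0, 4.1, 4.8, 5.5, 4.9]])
        fc = scan_fc(tc)
        for i in range(3):
            for j in range(3):
                if i == j:
                    assert fc.z[i, j] == 0
                else:
                    xi, xj = tc[i] - tc[i].mean(), tc[j] - tc[j].mean()
                    r = (xi @ xj) / np.sqrt((xi @ xi) * (xj @ xj))
                    assert fc.z[i, j] == pytest.approx(np.arctanh(r), abs=1e-12)

    def test_identical_rows_hit_clip_cap(self):
        tc = np.vstack([np.arange(5.0), np.arange(5.0)])
        fc = scan_fc(tc)
        assert fc.z[0, 1] == pytest.approx(np.arctanh(1 - 1e-7))

    def test_fisher_variance_approximation(self):
        rng = np.random.default_rng(7)
        zs = []
        for _ in range(500):
            tc = rng.standard_normal((2, 540))
            zs.append(scan_fc(tc).z[0, 1])
        assert np.std(zs) == pytest.approx(1 / np.sqrt(537), rel=0.1)

    def test_affine_rescaling_invariance(self, rng):
        tc = rng.standard_normal((4, 50))
        scaled = tc * rng.uniform(0.5, 3, (4, 1)) + rng.uniform(-5, 5, (4, 1))
        np.testing.assert_allclose(scan_fc(tc).z, scan_fc(scaled).z, atol=1e-10)


class TestGroupFC:
    def test_reduces_to_one_sample_t(self, rng):
        for _ in range(5):
            z = rng.standard_normal((6, 4, 4))
            fc = [_fc_from(m, str(i)) for i, m in enumerate(z)]
            res = group_fc(fc)
            stack = np.stack([f.z for f in fc])
            ref = stats.ttest_1samp(stack[:, 0, 1], 0).statistic
            assert res.t[0, 1] == pytest.approx(ref, abs=1e-10)

    def test_constant_entry_reported_capped(self, rng):
        z = np.zeros((5, 3, 3))
        z[:, 0, 1] = z[:, 1, 0] = 0.4
        fc = [_fc_from(m, str(i)) for i, m in enumerate(z)]
        res = group_fc(fc)
        assert res.t[0, 1] == analysis.T_CAP
        assert res.capped[0, 1]

    def test_scan_order_irrelevant(self, rng):
        z = rng.standard_normal((6, 4, 4))
        fc = [_fc_from(m, str(i)) for i, m in enumerate(z)]
        r1 = group_fc(fc)
        order = rng.permutation(6)
        r2 = group_fc([fc[i] for i in order])
        np.testing.assert_allclose(r1.t, r2.t, atol=1e-10)

    def test_single_subject_rejected(self, rng):
        fc = [_fc_from(rng.standard_normal((3, 3)), "same") for _ in range(4)]
        with pytest.raises(ValidationError):
            group_fc(fc)


class TestPermutationFWER:
    def test_alpha_one_everything_significant(self, rng):
        fc = _null_group(rng)
        res = permutation_fwer(fc, n_perm=100, alpha=1.0, seed=0)
        off = ~np.eye(res.sig.shape[0], dtype=bool)
        assert res.sig[off].all()

    def test_significance_shrinks_with_alpha(self, rng):
        fc = []
        for s in range(10):
            tc = rng.standard_normal((6, 80))
            shared = rng.standard_normal(80)
            tc[0] += shared
            tc[1] += shared
            fc.append(scan_fc(tc, subject_id=str(s)))
        counts = []
        for alpha in (0.2, 0.05, 0.01):
            res = permutation_fwer(fc, n_perm=200, alpha=alpha, seed=1)
            counts.append(res.sig.sum())
        assert counts[0] >= counts[1] >= counts[2]

    def test_planted_connection_detected(self, rng):
        fc = []
        for s in range(12):
            tc = rng.standard_normal((6, 100))
            shared = rng.standard_normal(100)
            tc[2] += 1.5 * shared
            tc[4] += 1.5 * shared
            fc.append(scan_fc(tc, subject_id=str(s)))
        res = permutation_fwer(fc, n_perm=300, alpha=0.05, seed=2)
        assert res.sig[2, 4]
        assert res.density < 0.2


class TestSeedMap:
    def test_seed_inside_network_lights_partner(self, quiet_phantom):
        _, truth = quiet_phantom
        rois = truth.spec.networks[0].rois
        lab = truth.atlas.labels
        xs, ys, zs = np.nonzero(lab == rois[0])
        cx, cy, cz = int(np.median(xs)), int(np.median(ys)), int(np.median(zs))
        scans = [filters.gaussian_smooth(
            phantom.make_phantom(phantom.PhantomSpec(nt=150, seed=600 + s, artefacts=[]))[0],
            1.0) for s in range(6)]
        tmap, sig, tcrit = seed_map(scans, ((cx - 1, cx + 2), (cy - 1, cy + 2), (cz - 1, cz + 1)),
                                    truth.masks.brain, n_perm=200, seed=3)
        partner = lab == rois[1]
        dice = 2 * np.sum(sig & partner) / (sig.sum() + partner.sum())
        assert np.sum(sig & partner) / partner.sum() > 0.7
        assert dice > 0.3  # seed ROI itself is also significant

    def test_seed_outside_mask_raises(self, quiet_phantom, rng):
        _, truth = quiet_phantom
        vol = Volume4D(rng.standard_normal((*truth.masks.brain.shape, 20)), (1, 1, 1), 1.0)
        with pytest.raises(ValidationError):
            seed_map([vol], ((0, 2), (0, 2), (0, 1)), truth.masks.brain, n_perm=10)


class TestFCDistance:
    def test_exponential_decay_strongly_negative(self, rng):
        cent = rng.uniform(0, 8, (10, 3))
        d = np.linalg.norm(cent[:, None] - cent[None, :], axis=-1)
        fcm = np.exp(-d / 10)  # gentle decay: near-linear over this range
        r, p = fc_vs_distance(fcm, cent)
        assert r < -0.9 and p < 1e-6

    def test_three_roi_hand_computation(self):
        cent = np.array([[0, 0, 0], [3, 0, 0], [0, 4, 0]], float)
        fcm = np.zeros((3, 3))
        fcm[0, 1] = fcm[1, 0] = 0.8
        fcm[0, 2] = fcm[2, 0] = 0.5
        fcm[1, 2] = fcm[2, 1] = 0.2
        r, _ = fc_vs_distance(fcm, cent)
        d = np.array([3.0, 4.0, 5.0])
        f = np.array([0.8, 0.5, 0.2])
        assert r == pytest.approx(stats.pearsonr(f, d)[0], abs=1e-12)

    def test_p_matches_permutation_oracle(self, rng):
        cent = rng.uniform(0, 10, (8, 3))
        fcm = rng.standard_normal((8, 8))
        fcm = (fcm + fcm.T) / 2
        np.fill_diagonal(fcm, 0)
        r, p = fc_vs_distance(fcm, cent)
        d = np.linalg.norm(cent[:, None] - cent[None, :], axis=-1)
        iu = np.triu_indices(8, 1)
        fv, dv = fcm[iu], d[iu]
        perm_r = []
        rng2 = np.random.default_rng(0)
        for _ in range(2000):
            perm_r.append(abs(stats.pearsonr(fv, rng2.permutation(dv))[0]))
        p_perm = np.mean(np.array(perm_r) >= abs(r))
        assert p == pytest.approx(p_perm, abs=0.05)


class TestJaccard:
    def _sym(self, n, edges):
        m = np.zeros((n, n), bool)
        for i, j in edges:
            m[i, j] = m[j, i] = True
        return m

    def test_identical_is_one(self, rng):
        m = self._sym(5, [(0, 1), (2, 3)])
        j, p = jaccard_fc_sc(m, m, n_perm=50, seed=0)
        assert j == 1.0

    def test_disjoint_is_zero(self):
        a = self._sym(5, [(0, 1)])
        b = self._sym(5, [(2, 3)])
        j, _ = jaccard_fc_sc(a, b, n_perm=50, seed=0)
        assert j == 0.0

    def test_definition_arithmetic(self):
        a = self._sym(5, [(0, 1), (1, 2), (2, 3)])
        b = self._sym(5, [(0, 1), (1, 2), (3, 4)])
        j, _ = jaccard_fc_sc(a, b, n_perm=50, seed=0)
        assert j == pytest.approx(2 / 4)

    def test_empty_union_raises(self):
        z = np.zeros((4, 4), bool)
        with pytest.raises(ValidationError):
            jaccard_fc_sc(z, z)


class TestReproducibility:
    def _common_structure_group(self, rng, n_subj=8, noise=0.05):
        base = rng.standard_normal((6, 6))
        base = (base + base.T) / 2
        np.fill_diagonal(base, 0)
        return [_fc_from(base + noise * rng.standard_normal((6, 6)), str(s))
                for s in range(n_subj)]

    def test_common_structure_high_similarity(self, rng):
        fc = self._common_structure_group(rng)
        r = reproducibility(fc, mode="split_half", seed=0)
        assert r > 0.9

    def test_independent_structures_near_zero(self, rng):
        rs = []
        for rep in range(20):
            fc = [_fc_from(np.random.default_rng(100 * rep + s).standard_normal((6, 6)),
                           str(s)) for s in range(8)]
            rs.append(reproducibility(fc, mode="split_half", seed=rep))
        assert abs(np.mean(rs)) < 0.2

    def test_distance_regression_no_coupling_unchanged(self, rng):
        fc = self._common_structure_group(rng)
        cent = rng.uniform(0, 10, (6, 3))
        r_with = reproducibility(fc, mode="split_half", centroids_mm=cent, seed=1)
        r_without = reproducibility(fc, mode="split_half", seed=1)
        assert r_with == pytest.approx(r_without, abs=0.05)

    def test_leave_one_out_returns_per_subject(self, rng):
        fc = self._common_structure_group(rng)
        r, per = reproducibility(fc, mode="leave_one_out", seed=0)
        assert len(per) == 8
        assert r == pytest.approx(np.mean(per))

    def test_too_few_subjects(self, rng):
        fc = self._common_structure_group(rng, n_subj=3)
        with pytest.raises(ValidationError):
            reproducibility(fc, mode="split_half")


class TestSpecificity:
    @pytest.mark.parametrize("zs,zn,expected", [
        (0.3, 0.05, "specific"),
        (0.3, 0.3, "unspecific"),
        (0.0, 0.0, "none"),
        (0.05, 0.3, "spurious"),
    ])
    def test_rule_table(self, zs, zn, expected):
        assert specificity_classify(zs, zn, thresh=0.1).category == expected

    def test_nonfinite_rejected(self):
        with pytest.raises(ValidationError):
            specificity_classify(np.nan, 0.1)

    def test_phantom_seed_specific_coupling(self, rng):
        """Scans with planted seed<->specific-ROI coupling classify as specific."""
        categories = []
        for s in range(20):
            r = np.random.default_rng(s)
            shared = r.standard_normal(200)
            seed_tc = shared + 0.4 * r.standard_normal(200)
            spec_tc = shared + 0.4 * r.standard_normal(200)
            non_tc = r.standard_normal(200)
            z_s = np.arctanh(np.corrcoef(seed_tc, spec_tc)[0, 1])
            z_n = np.arctanh(np.corrcoef(seed_tc, non_tc)[0, 1])
            categories.append(specificity_classify(z_s, z_n).category)
        assert np.mean([c == "specific" for c in categories]) >= 0.9


class TestWardAndModules:
    def brute_ward(self, d):
        """Lance-Williams agglomeration, straight from the recurrence."""
        n = d.shape[0]
        sizes = {i: 1 for i in range(n)}
        dist = {(i, j): d[i, j] for i in range(n) for j in range(i + 1, n)}
        get = lambda i, j: dist[(min(i, j), max(i, j))]
        active = list(range(n))
        nxt = n
        out = []
        while len(active) > 1:
            best = min(((get(i, j), i, j) for idx, i in enumerate(active)
                        for j in active[idx + 1:]), key=lambda x: x[0])
            v, i, j = best
            out.append([min(i, j), max(i, j), v, sizes[i] + sizes[j]])
            for k in active:
                if k in (i, j):
                    continue
                si, sj, sk = sizes[i], sizes[j], sizes[k]
                dn = np.sqrt(((si + sk) * get(i, k) ** 2 + (sj + sk) * get(j, k) ** 2
                              - sk * v * v) / (si + sj + sk))
                dist[(min(nxt, k), max(nxt, k))] = dn
            sizes[nxt] = sizes[i] + sizes[j]
            active = [k for k in active if k not in (i, j)] + [nxt]
            nxt += 1
        return np.array(out)

    def test_ward_matches_lance_williams_oracle(self, rng):
        for _ in range(20):
            x = rng.standard_normal((6, 3))
            d = np.linalg.norm(x[:, None] - x[None, :], axis=-1)
            z_scipy = ward_linkage(d)
            z_brute = self.brute_ward(d)
            np.testing.assert_allclose(z_scipy[:, 2:], z_brute[:, 2:], atol=1e-10)
            for row_s, row_b in zip(z_scipy, z_brute):
                assert {row_s[0], row_s[1]} == {row_b[0], row_b[1]}

    def test_two_block_partition_recovered(self, rng):
        tcs = []
        for s in range(8):
            r = np.random.default_rng(s)
            a, b = r.standard_normal(120), r.standard_normal(120)
            tc = np.column_stack([a + 0.3 * r.standard_normal(120) for _ in range(3)]
                                 + [b + 0.3 * r.standard_normal(120) for _ in range(3)])
            tcs.append(tc)
        res, link, labels = ic_modules(tcs, subjects=[str(s) for s in range(8)],
                                       n_perm=100, seed=0, n_modules=2)
        assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1
        assert labels[0] != labels[3]

    def test_single_block_single_module(self, rng):
        tcs = []
        for s in range(6):
            r = np.random.default_rng(50 + s)
            a = r.standard_normal(100)
            tcs.append(np.column_stack([a + 0.2 * r.standard_normal(100) for _ in range(4)]))
        res, link, labels = ic_modules(tcs, subjects=[str(s) for s in range(6)],
                                       n_perm=100, seed=0, cut_height=1e9)
        assert len(set(labels)) == 1


class TestSNR:
    def test_definition_arithmetic(self, rng):
        data = rng.standard_normal((12, 12, 3, 15))
        # plant noise std in the corner cubes of frame 10 (index 9)
        corners = np.zeros((12, 12, 3), bool)
        corners[:5, -5:, :] = True
        corners[-5:, -5:, :] = True
        brain = np.zeros((12, 12, 3), bool)
        brain[5, 5, 1] = True
        vol = Volume4D(data, (1, 1, 1), 1.0)
        noise_sd = data[..., 9][corners].std()
        res = snr_maps(vol, brain)
        assert res.ssnr[5, 5, 1] == pytest.approx(data[5, 5, 1, 9] / noise_sd)
        expected_tsnr = data[5, 5, 1].mean() / data[5, 5, 1].std()
        assert res.tsnr[5, 5, 1] == pytest.approx(expected_tsnr)
        assert res.mean_tsnr == pytest.approx(expected_tsnr)

    def test_constant_voxel_excluded_from_mean(self, rng):
        data = rng.standard_normal((12, 12, 2, 15)) + 10
        data[6, 6, 0, :] = 42.0  # zero temporal variance
        brain = np.zeros((12, 12, 2), bool)
        brain[6, 6, 0] = True
        brain[7, 7, 0] = True
        res = snr_maps(Volume4D(data, (1, 1, 1), 1.0), brain)
        assert np.isfinite(res.mean_tsnr)
        assert res.mean_tsnr == pytest.approx(data[7, 7, 0].mean() / data[7, 7, 0].std())

    def test_needs_ten_frames(self, rng):
        vol = Volume4D(rng.standard_normal((12, 12, 2, 5)), (1, 1, 1), 1.0)
        with pytest.raises(ValidationError):
            snr_maps(vol, np.ones((12, 12, 2), bool))


class TestGroupFCREML:
    def test_reml_close_to_subject_mean_t_when_balanced(self, rng):
        """Random-intercept REML fit agrees with the subject-mean t on a
        balanced two-scans-per-subject design."""
        z = rng.standard_normal((8, 3, 3)) + 0.3
        subjects = [str(i // 2) for i in range(8)]
        fc = [_fc_from(m, s) for m, s in zip(z, subjects)]
        res_fast = group_fc(fc, subjects)
        res_reml = group_fc(fc, subjects, method="reml")
        iu = np.triu_indices(3, 1)
        np.testing.assert_allclose(res_reml.t[iu], res_fast.t[iu], rtol=0.3, atol=0.5)
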