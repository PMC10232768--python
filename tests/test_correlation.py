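"""HRF, convolution, correlation mapping, group test and cluster extraction."""

import numpy as np
import pytest

from painmap.cohort import Atlas, BoldRun, PainTrace
from painmap.correlation import (CorrelationMap, GroupMap, canonical_hrf,
                                 convolve_trace, distinct_regions,
                                 extract_clusters, fisher_z, group_map,
                                 subject_correlation_map)

TR = 1.98


def make_run(data, tr=TR):
    return BoldRun(data=np.asarray(data, float), tr=tr,
                   affine=np.diag([3.0, 3, 3, 1]), session="tracking")


class TestCanonicalHrf:
    def test_peak_near_five_to_six_seconds(self):
        h = canonical_hrf(0.1)
        t_peak = np.argmax(h.kernel) * 0.1
        assert 5.0 <= t_peak <= 6.0

    def test_zero_at_origin(self):
        assert canonical_hrf(0.5).kernel[0] == 0.0

    def test_single_sign_change(self):
        k = canonical_hrf(0.5).kernel
        signs = np.sign(k[np.abs(k) > 1e-12])
        changes = np.sum(np.diff(signs) != 0)
        assert changes == 1

    def test_positive_kernel_sum(self):
        assert canonical_hrf(TR).kernel.sum() > 0

    def test_invalid_tr(self):
        with pytest.raises(ValueError):
            canonical_hrf(0.0)

    def test_shape_matches_spm_reference(self):
        # independent reference implementation of the same double-gamma form;
        # the two kernels may differ by a sub-second sampling offset, so
        # compare at the best alignment within +-0.5 s
        from nilearn.glm.first_level.hemodynamic_models import spm_hrf

        ours = canonical_hrf(0.1).kernel
        ref = spm_hrf(0.1, oversampling=1)
        n = min(len(ours), len(ref))
        best = max(np.corrcoef(ours[lag:n], ref[:n - lag])[0, 1]
                   for lag in range(0, 6))
        assert best > 0.999


class TestConvolveTrace:
    def trace(self, values, tr=TR):
        values = np.asarray(values, float)
        return PainTrace("s", times=np.arange(len(values)) * tr, ratings=values)

    def test_impulse_reproduces_kernel(self):
        n = 60
        vals = np.zeros(n + 20)
        vals[0] = 50.0
        run = make_run(np.zeros((1, 1, 1, n)))
        # impulse at the first volume time via a trace spiking there
        trace = PainTrace("s", times=(np.arange(len(vals)) + 0.5) * TR,
                          ratings=vals)
        reg = convolve_trace(trace, canonical_hrf(TR), run)
        kernel = canonical_hrf(TR).kernel
        assert np.allclose(reg[:len(kernel)], 50.0 * kernel, atol=1e-10)

    def test_constant_trace_reaches_steady_state(self):
        n = 120
        run = make_run(np.zeros((1, 1, 1, n)))
        trace = self.trace(np.full(n + 5, 20.0))
        reg = convolve_trace(trace, canonical_hrf(TR), run)
        ksum = canonical_hrf(TR).kernel.sum()
        assert np.allclose(reg[30:], 20.0 * ksum, rtol=1e-10)

    def test_matches_direct_convolution_sum(self, rng):
        n = 80
        run = make_run(np.zeros((1, 1, 1, n)))
        vals = rng.uniform(0, 100, n + 10)
        trace = self.trace(vals)
        hrf = canonical_hrf(TR)
        reg = convolve_trace(trace, hrf, run)
        resampled = trace.resample((np.arange(n) + 0.5) * TR)
        oracle = np.zeros(n)
        for i in range(n):  # O(n^2) direct sum
            for j in range(len(hrf.kernel)):
                if i - j >= 0:
                    oracle[i] += resampled[i - j] * hrf.kernel[j]
        assert np.allclose(reg, oracle, atol=1e-10)

    def test_short_trace_rejected(self):
        run = make_run(np.zeros((1, 1, 1, 100)))
        trace = self.trace(np.zeros(10))
        with pytest.raises(ValueError, match="trace ends"):
            convolve_trace(trace, canonical_hrf(TR), run)


class TestSubjectCorrelationMap:
    def test_self_and_anti_correlation(self, rng):
        reg = rng.normal(size=50)
        data = np.stack([reg, -reg]).reshape(2, 1, 1, 50)
        cm = subject_correlation_map(make_run(data), reg)
        assert cm.r[0, 0, 0] == pytest.approx(1.0)
        assert cm.r[1, 0, 0] == pytest.approx(-1.0)

    def test_matches_covariance_formula(self, rng):
        n = 300
        reg = rng.normal(size=n)
        vox = rng.normal(size=n)
        cm = subject_correlation_map(make_run(vox.reshape(1, 1, 1, n)), reg)
        oracle = (np.mean(vox * reg) - vox.mean() * reg.mean()) / \
            (vox.std() * reg.std())
        assert cm.r[0, 0, 0] == pytest.approx(oracle, abs=1e-12)

    def test_flat_voxel_flagged(self, rng):
        data = np.zeros((1, 1, 1, 40))
        cm = subject_correlation_map(make_run(data), rng.normal(size=40))
        assert cm.r[0, 0, 0] == 0.0 and cm.flat_voxels[0, 0, 0]

    def test_constant_regressor_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            subject_correlation_map(make_run(np.zeros((1, 1, 1, 40))),
                                    np.ones(40))


class TestFisherZ:
    def test_known_values(self):
        assert fisher_z(0.0) == 0.0
        assert fisher_z(0.5) == pytest.approx(np.arctanh(0.5), abs=1e-12)
        assert fisher_z(0.5) == pytest.approx(0.549306, abs=1e-6)

    def test_antisymmetry(self, rng):
        r = rng.uniform(-0.99, 0.99, 50)
        assert np.allclose(fisher_z(r) + fisher_z(-r), 0.0, atol=1e-12)

    def test_clamped_at_unity(self):
        assert np.isfinite(fisher_z(1.0))
        assert fisher_z(1.0) == pytest.approx(np.arctanh(1 - 1e-7))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fisher_z(1.5)


def maps_from_z(zvals, shape=(1, 1, 1)):
    return [CorrelationMap(r=np.full(shape, np.tanh(z)), subject_id=str(i))
            for i, z in enumerate(zvals)]


class TestGroupMap:
    def test_matches_textbook_t(self):
        z = np.array([0.5, 0.6, 0.7, 0.4, 0.55])
        gm = group_map(maps_from_z(z))
        t_oracle = z.mean() / (z.std(ddof=1) / np.sqrt(len(z)))
        assert gm.t[0, 0, 0] == pytest.approx(t_oracle, abs=1e-10)

    def test_degenerate_voxel_flagged(self):
        gm = group_map(maps_from_z([0.0, 0.0, 0.0]))
        assert gm.degenerate[0, 0, 0]
        assert gm.p[0, 0, 0] == 1.0

    def test_negation_flips_t(self):
        z = [0.2, 0.5, 0.3, 0.4]
        a = group_map(maps_from_z(z))
        b = group_map(maps_from_z([-v for v in z]))
        assert a.t[0, 0, 0] == pytest.approx(-b.t[0, 0, 0], abs=1e-12)

    def test_too_few_subjects(self):
        with pytest.raises(ValueError):
            group_map(maps_from_z([0.1, 0.2]))


def toy_atlas(shape):
    labels = np.zeros(shape, dtype=int)
    labels[:shape[0] // 2] = 1
    labels[shape[0] // 2:] = 2
    return Atlas(labels=labels, names={1: "front", 2: "back"},
                 affine=np.diag([3.0, 3, 3, 1]))


class TestExtractClusters:
    def test_size_filter_keeps_only_large_blob(self):
        shape = (10, 10, 10)
        t = np.zeros(shape)
        p = np.ones(shape)
        t[1:4, 1:3, 1:3] = 3.0   # 12 voxels
        p[1:4, 1:3, 1:3] = 0.001
        t[7:9, 7:9, 7] = 3.0     # 4 voxels
        p[7:9, 7:9, 7] = 0.001
        gm = GroupMap(t=t, p=p, n_subjects=10)
        rows = extract_clusters(gm, toy_atlas(shape), min_voxels=10)
        assert len(rows) == 1 and rows[0].volume_voxels == 12

    def test_volume_arithmetic_on_3mm_grid(self):
        # a 203-voxel suprathreshold cluster occupies 5,481 mm^3
        shape = (20, 20, 20)
        t = np.zeros(shape)
        p = np.ones(shape)
        idx = np.unravel_index(np.arange(203), (7, 6, 5))
        t[idx] = 3.74
        p[idx] = 1e-4
        gm = GroupMap(t=t, p=p, n_subjects=39)
        rows = extract_clusters(gm, toy_atlas(shape))
        assert rows[0].volume_voxels == 203
        assert rows[0].volume_mm3 == pytest.approx(5481.0)
        assert rows[0].volume_mm3 / rows[0].volume_voxels == pytest.approx(27.0)

    def test_peak_location_and_region_name(self):
        shape = (8, 8, 8)
        t = np.zeros(shape)
        p = np.ones(shape)
        t[1:4, 1:4, 1:4] = 2.0
        p[1:4, 1:4, 1:4] = 0.01
        t[2, 2, 2] = 5.0
        gm = GroupMap(t=t, p=p, n_subjects=5)
        rows = extract_clusters(gm, toy_atlas(shape))
        assert rows[0].region == "front"
        assert rows[0].peak_mm == (6.0, 6.0, 6.0)
        assert rows[0].peak_t == pytest.approx(5.0)

    def test_sign_selection(self):
        shape = (8, 8, 8)
        t = np.zeros(shape)
        p = np.ones(shape)
        t[0:3, 0:3, 0:3] = -3.0
        p[0:3, 0:3, 0:3] = 0.001
        gm = GroupMap(t=t, p=p, n_subjects=5)
        assert extract_clusters(gm, toy_atlas(shape), sign="positive") == []
        neg = extract_clusters(gm, toy_atlas(shape), sign="negative")
        assert len(neg) == 1 and neg[0].sign == "negative"

    def test_matches_flood_fill_oracle(self, rng):
        # exhaustive component check on random binary grids
        from scipy import ndimage

        def flood(mask, neighbours):
            seen = np.zeros_like(mask, bool)
            comps = []
            for start in np.argwhere(mask):
                start = tuple(start)
                if seen[start]:
                    continue
                stack, comp = [start], set()
                seen[start] = True
                while stack:
                    v = stack.pop()
                    comp.add(v)
                    for d in neighbours:
                        u = tuple(np.add(v, d))
                        if all(0 <= u[i] < mask.shape[i] for i in range(3)) \
                                and mask[u] and not seen[u]:
                            seen[u] = True
                            stack.append(u)
                comps.append(frozenset(comp))
            return set(comps)

        deltas26 = [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1)
                    for k in (-1, 0, 1) if (i, j, k) != (0, 0, 0)]
        for _ in range(100):
            mask = rng.random((8, 8, 8)) < 0.2
            lab, n = ndimage.label(mask, structure=np.ones((3, 3, 3)))
            got = {frozenset(map(tuple, np.argwhere(lab == c)))
                   for c in range(1, n + 1)}
            assert got == flood(mask, deltas26)

    def test_full_chain_noise_free_voxel_is_significant(self, rng):
        # convolve -> correlate -> Fisher -> group t on a planted voxel
        n = 120
        maps = []
        for i in range(5):
            vals = rng.uniform(0, 60, n + 5)
            trace = PainTrace("s", times=np.arange(n + 5) * TR, ratings=vals)
            run = make_run(np.zeros((2, 1, 1, n)))
            reg = convolve_trace(trace, canonical_hrf(TR), run)
            data = np.zeros((2, 1, 1, n))
            data[0, 0, 0] = reg
            data[1, 0, 0] = rng.normal(size=n)
            maps.append(subject_correlation_map(make_run(data), reg, str(i)))
        gm = group_map(maps)
        assert gm.p[0, 0, 0] < 1e-8


class TestDistinctRegions:
    def row(self, name, sign="positive"):
        from painmap.correlation import ClusterRow
        return ClusterRow(region=name, peak_mm=(0, 0, 0), volume_voxels=10,
                          volume_mm3=270.0, peak_t=2.5, sign=sign)

    def test_disjoint_union(self):
        pos = [self.row(n) for n in "abc"]
        neg = [self.row(n, "negative") for n in "defg"]
        assert len(distinct_regions(pos, neg)) == 7

    def test_idempotent_union(self):
        pos = [self.row(n) for n in "abc"]
        neg = [self.row(n, "negative") for n in "abc"]
        assert distinct_regions(pos, neg) == {"a", "b", "c"}

    def test_reported_tables_give_21_regions(self):
        from painmap.reference import reported_cluster_regions
        union = reported_cluster_regions("positive") | \
            reported_cluster_regions("negative")
        assert len(union) == 21
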