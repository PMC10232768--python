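"""Window graphs: ROI averaging, dynamic connectivity, GIN properties."""

import numpy as np
import pytest

from painmap.cohort import Atlas, BoldRun, PainTrace
from painmap.gcnn import (GinConfig, GinPainDecoder, RoiTimeSeries,
                          WindowGraph, binarize, build_window_graphs,
                          gin_forward, label_windows, roi_average,
                          window_connectivity)
from painmap.gcnn import _GinNet

TR = 1.98


def two_region_atlas():
    labels = np.zeros((4, 2, 2), dtype=int)
    labels[0:2] = 1
    labels[2:4] = 2
    return Atlas(labels=labels, names={1: "a", 2: "b"})


class TestRoiAverage:
    def test_identical_voxels_give_their_course(self, rng):
        atlas = two_region_atlas()
        v = rng.normal(size=20)
        data = np.zeros((4, 2, 2, 20))
        data[atlas.mask(1)] = v
        run = BoldRun(data=data, tr=TR, affine=np.eye(4), session="tracking")
        ts = roi_average(run, atlas)
        assert np.allclose(ts.data[0], v)

    def test_mean_of_two_courses(self, rng):
        atlas = Atlas(labels=np.array([[[1, 1]]]), names={1: "a"})
        a, b = rng.normal(size=(2, 15))
        run = BoldRun(data=np.stack([a, b]).reshape(1, 1, 2, 15), tr=TR,
                      affine=np.eye(4), session="tracking")
        ts = roi_average(run, atlas)
        assert np.allclose(ts.data[0], (a + b) / 2)

    def test_background_not_a_row(self, rng):
        atlas = two_region_atlas()
        run = BoldRun(data=rng.normal(size=(4, 2, 2, 10)), tr=TR,
                      affine=np.eye(4), session="tracking")
        ts = roi_average(run, atlas)
        assert ts.data.shape[0] == 2 and ts.codes == [1, 2]

    def test_shape_mismatch_rejected(self, rng):
        atlas = two_region_atlas()
        run = BoldRun(data=rng.normal(size=(5, 2, 2, 10)), tr=TR,
                      affine=np.eye(4), session="tracking")
        with pytest.raises(ValueError, match="match"):
            roi_average(run, atlas)


class TestWindowConnectivity:
    def test_window_length_is_fifteen_volumes_at_default(self):
        ts = RoiTimeSeries(data=np.random.default_rng(0).normal(size=(3, 60)),
                           codes=[1, 2, 3], tr=TR)
        mats, centers = window_connectivity(ts, window_s=30.0)
        assert mats.shape[0] == 60 - 15 + 1  # floor(30/1.98) = 15
        assert centers[0] == 15 // 2

    def test_window_count_closed_form(self, rng):
        for n_t, stride in [(60, 1), (60, 2), (45, 3)]:
            ts = RoiTimeSeries(data=rng.normal(size=(2, n_t)), codes=[1, 2],
                               tr=TR)
            mats, _ = window_connectivity(ts, stride=stride)
            length = int(np.floor(30.0 / TR))
            assert mats.shape[0] == (n_t - length) // stride + 1

    def test_identical_rows_fully_correlated(self, rng):
        v = rng.normal(size=40)
        ts = RoiTimeSeries(data=np.stack([v, v]), codes=[1, 2], tr=TR)
        mats, _ = window_connectivity(ts)
        assert np.allclose(mats[:, 0, 1], 1.0)

    def test_matches_per_window_pearson_oracle(self, rng):
        ts = RoiTimeSeries(data=rng.normal(size=(4, 50)), codes=[1, 2, 3, 4],
                           tr=TR)
        mats, centers = window_connectivity(ts, stride=2)
        length = int(np.floor(30.0 / TR))
        for w, c in enumerate(centers):
            s0 = c - length // 2
            seg = ts.data[:, s0:s0 + length]
            oracle = np.corrcoef(seg)
            assert np.allclose(mats[w], oracle, atol=1e-10)

    def test_run_shorter_than_window_rejected(self, rng):
        ts = RoiTimeSeries(data=rng.normal(size=(2, 10)), codes=[1, 2], tr=TR)
        with pytest.raises(ValueError, match="shorter"):
            window_connectivity(ts)


class TestBinarize:
    def test_strict_inequality_at_threshold(self):
        m = np.array([[1.0, 0.3], [0.3, 1.0]])
        assert binarize(m, 0.3)[0, 1] == 0.0
        assert binarize(m, 0.299)[0, 1] == 1.0

    def test_extreme_thresholds(self, rng):
        m = np.corrcoef(rng.normal(size=(6, 30)))
        hi = binarize(m, 0.99)
        lo = binarize(m, -0.99)
        assert hi.sum() <= 2  # near-empty off-diagonal
        assert lo.sum() == 6 * 5  # complete graph minus diagonal

    def test_monotone_in_threshold_on_random_matrices(self, rng):
        for _ in range(100):
            m = np.corrcoef(rng.normal(size=(8, 20)))
            t1, t2 = sorted(rng.uniform(-0.9, 0.9, 2))
            a_lo, a_hi = binarize(m, t1), binarize(m, t2)
            assert np.all(a_hi <= a_lo)  # raising threshold never adds edges

    def test_diagonal_forced_to_zero(self, rng):
        m = np.corrcoef(rng.normal(size=(5, 20)))
        assert np.all(np.diag(binarize(m, -0.5)) == 0)


class TestLabelWindows:
    def trace(self, values):
        return PainTrace("s", times=np.arange(len(values), dtype=float),
                         ratings=np.asarray(values, float))

    def test_threshold_rule(self):
        labels, kept = label_windows(self.trace([15.0, 16.0, 10.0]),
                                     np.array([0.0, 1.0, 2.0]))
        assert labels.tolist() == [0, 1, 0] and kept.all()

    def test_monotone_trace_single_step(self):
        vals = np.linspace(0, 40, 30)
        labels, _ = label_windows(self.trace(vals), np.arange(30.0))
        assert np.all(np.diff(labels) >= 0) and labels[0] == 0 and labels[-1] == 1

    def test_centres_outside_trace_dropped(self):
        labels, kept = label_windows(self.trace([20.0, 20.0]),
                                     np.array([-1.0, 0.5, 9.0]))
        assert kept.tolist() == [False, True, False] and len(labels) == 1


def random_graph(rng, n=10, f=5):
    feats = rng.normal(size=(n, f))
    a = (rng.random((n, n)) < 0.3).astype(float)
    a = np.triu(a, 1)
    a = a + a.T
    return feats, a


class TestGin:
    def test_permutation_invariance_on_100_graphs(self, rng):
        cfg = GinConfig(hidden=8)
        for i in range(100):
            feats, adj = random_graph(rng)
            g = WindowGraph(features=feats, adjacency=adj, label=0,
                            subject_id="s", center_time=0.0)
            base = gin_forward(g, cfg, seed=3)
            perm = rng.permutation(len(feats))
            gp = WindowGraph(features=feats[perm], adjacency=adj[perm][:, perm],
                             label=0, subject_id="s", center_time=0.0)
            assert np.allclose(gin_forward(gp, cfg, seed=3), base, atol=1e-6)

    def test_empty_adjacency_is_nodewise_transform(self, rng):
        # with no edges the readout is the mean of MLP((1+eps) h_v)
        feats = rng.normal(size=(6, 4))
        adj = np.zeros((6, 6))
        net = _GinNet(4, GinConfig(n_layers=1, hidden=8),
                      np.random.default_rng(2))
        out_all = net.forward((feats[None], adj[None]), train=False)
        per_node = [net.forward((feats[i:i + 1][None], np.zeros((1, 1, 1))),
                                train=False) for i in range(6)]
        assert np.allclose(out_all, np.mean(per_node, axis=0), atol=1e-6)

    def test_feature_adjacency_mismatch_rejected(self, rng):
        g = WindowGraph(features=rng.normal(size=(5, 3)),
                        adjacency=np.zeros((5, 5)), label=0,
                        subject_id="s", center_time=0.0)
        g.features = rng.normal(size=(4, 3))  # corrupt after construction
        with pytest.raises(ValueError, match="match"):
            gin_forward(g)

    def test_adjacency_invariants_enforced(self, rng):
        with pytest.raises(ValueError):
            WindowGraph(features=rng.normal(size=(3, 2)),
                        adjacency=np.array([[0, 1, 0], [0, 0, 1], [0, 1, 0]],
                                           float),
                        label=0, subject_id="s", center_time=0.0)


class TestGraphBuildingAndDecoding:
    def test_build_window_graphs_end_to_end(self, small_cohort):
        cfg, subjects, atlas = small_cohort
        s = subjects[0]
        graphs = build_window_graphs(s.run("tracking"), atlas, s.trace,
                                     stride=4, subject_id=s.id)
        length = int(np.floor(30.0 / TR))
        n_t = s.run("tracking").n_volumes
        assert len(graphs) <= (n_t - length) // 4 + 1
        g = graphs[0]
        assert g.features.shape == (atlas.n_regions, length)
        assert g.adjacency.shape == (atlas.n_regions, atlas.n_regions)

    def test_decoder_learns_separable_graphs(self, rng):
        # label encoded in node-feature magnitude of the first three nodes
        X_feats, X_adj, y, groups = [], [], [], []
        for s in range(8):
            for i in range(20):
                label = i % 2
                f, a = random_graph(rng, n=8, f=6)
                f[:3] += 1.5 * (2 * label - 1)
                X_feats.append(f); X_adj.append(a)
                y.append(label); groups.append(f"s{s}")
        X = (np.array(X_feats), np.array(X_adj))
        dec = GinPainDecoder(hidden=16, learning_rate=1e-2, epochs=6,
                             batch_size=8, patience=6, n_folds=8,
                             random_state=0)
        dec.fit(X, np.array(y), np.array(groups))
        assert dec.metrics_.mean_accuracy > 0.85
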