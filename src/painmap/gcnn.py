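"""Sliding-window functional-connectivity graphs and GIN decoding.

BOLD signals are averaged within each atlas region; pairwise Pearson
correlation in 30 s moving windows gives a dynamic connectivity matrix per
window, which is binarized at a threshold to form a graph. The window's
node features are the regions' BOLD segments, and a two-layer Graph
Isomorphism Network with a 2-unit linear head classifies the window as low
or high pain according to the rating at the window's centre time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._nn import GinLayer, Layer, Linear, ReLU
from .base import FoldedDecoderBase
from .cohort import Atlas, BoldRun, PainTrace
from .samples import DEFAULT_THRESHOLD, FoldPlan, TrainConfig

__all__ = [
    "RoiTimeSeries", "WindowGraph", "GinConfig",
    "roi_average", "window_connectivity", "binarize", "label_windows",
    "gin_forward", "GinPainDecoder", "train_gcnn", "build_window_graphs",
]


@dataclass
class RoiTimeSeries:
    """Mean BOLD per region: matrix (R regions x T volumes)."""

    data: np.ndarray
    codes: list[int]
    tr: float
    empty_regions: list[int] | None = None

    def __post_init__(self) -> None:
        if self.data.shape[0] != len(self.codes):
            raise ValueError("one row per region code required")


def roi_average(run: BoldRun, atlas: Atlas) -> RoiTimeSeries:
    """Average the BOLD signal over each region's voxels (background code 0
    excluded); an empty region yields a zero row and is flagged."""
    if run.spatial_shape != atlas.labels.shape:
        raise ValueError(
            f"run grid {run.spatial_shape} does not match atlas {atlas.labels.shape}")
    codes = atlas.codes
    rows = np.zeros((len(codes), run.n_volumes))
    empty = []
    flat = run.data.reshape(-1, run.n_volumes)
    lab = atlas.labels.reshape(-1)
    for i, code in enumerate(codes):
        sel = lab == code
        if not sel.any():
            empty.append(code)
            continue
        rows[i] = flat[sel].mean(axis=0)
    return RoiTimeSeries(data=rows, codes=codes, tr=run.tr,
                         empty_regions=empty or None)


def window_connectivity(ts: RoiTimeSeries, window_s: float = 30.0,
                        tr: float | None = None,
                        stride: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Per-window pairwise Pearson correlation of the region segments.

    Returns (matrices, centers): matrices is (n_windows, R, R) with unit
    diagonal, centers the window-centre volume indices. The window length in
    volumes is floor(window_s / tr); windows advance by ``stride`` volumes.
    """
    tr = tr or ts.tr
    length = int(np.floor(window_s / tr))
    if length < 3:
        raise ValueError(f"window of {window_s} s at TR {tr} s has "
                         f"{length} volumes; need at least 3")
    n_r, n_t = ts.data.shape
    if n_t < length:
        raise ValueError(f"run of {n_t} volumes shorter than one window ({length})")
    starts = np.arange(0, n_t - length + 1, stride)
    mats = np.empty((len(starts), n_r, n_r))
    for w, s0 in enumerate(starts):
        seg = ts.data[:, s0:s0 + length]
        seg = seg - seg.mean(axis=1, keepdims=True)
        sd = seg.std(axis=1)
        safe = np.where(sd == 0, 1.0, sd)
        z = seg / safe[:, None]
        c = (z @ z.T) / length
        c[sd == 0, :] = 0.0
        c[:, sd == 0] = 0.0
        np.fill_diagonal(c, 1.0)
        mats[w] = np.clip(c, -1.0, 1.0)
    centers = starts + length // 2
    return mats, centers


def binarize(matrix: np.ndarray, threshold: float = 0.3) -> np.ndarray:
    """Edge iff correlation strictly greater than threshold; zero diagonal."""
    if not (-1.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (-1, 1)")
    adj = (np.asarray(matrix) > threshold).astype(np.float64)
    if adj.ndim == 2:
        np.fill_diagonal(adj, 0.0)
    else:
        for a in adj:
            np.fill_diagonal(a, 0.0)
    return adj


def label_windows(trace: PainTrace, center_times: np.ndarray,
                  threshold: float = DEFAULT_THRESHOLD
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Low/high label from the rating at each window's centre time.

    Returns (labels, kept_mask); centres outside the trace span are dropped.
    """
    t = np.asarray(center_times, dtype=float)
    kept = (t >= trace.times[0]) & (t <= trace.times[-1])
    ratings = trace.resample(t[kept])
    labels = (ratings > threshold).astype(int)
    return labels, kept


@dataclass
class WindowGraph:
    """One decoding sample: node features + binary adjacency + label."""

    features: np.ndarray  # (R, window length)
    adjacency: np.ndarray  # (R, R) binary, symmetric, zero diagonal
    label: int
    subject_id: str
    center_time: float

    def __post_init__(self) -> None:
        a = self.adjacency
        if not np.array_equal(a, a.T) or np.any(np.diag(a) != 0):
            raise ValueError("adjacency must be symmetric with zero diagonal")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency entries must be 0/1")


@dataclass
class GinConfig:
    """GIN decoder shape: two GIN layers and a 2-unit linear head."""

    n_layers: int = 2
    hidden: int = 32
    eps: float = 0.0
    learn_eps: bool = False
    n_classes: int = 2

    def __post_init__(self) -> None:
        if self.n_layers < 1:
            raise ValueError("need at least one GIN layer")


class _GinNet(Layer):
    def __init__(self, in_features: int, cfg: GinConfig, rng: np.random.Generator):
        self.layers: list[GinLayer] = []
        self.relus: list[ReLU] = []
        f = in_features
        for _ in range(cfg.n_layers):
            self.layers.append(GinLayer(f, cfg.hidden, hidden=cfg.hidden,
                                        eps=cfg.eps, learn_eps=cfg.learn_eps,
                                        rng=rng))
            self.relus.append(ReLU())
            f = cfg.hidden
        self.head = Linear(f, cfg.n_classes, rng=rng)

    def params(self):
        ps = []
        for l in self.layers:
            ps += l.params()
        return ps + self.head.params()

    def forward(self, inputs, train=True):
        x, adj = inputs
        for gin, relu in zip(self.layers, self.relus):
            x = relu.forward(gin.forward((x, adj), train), train)
        self._n_nodes = x.shape[1]
        pooled = x.mean(axis=1)  # graph readout: mean over nodes
        return self.head.forward(pooled, train)

    def backward(self, grad):
        g = self.head.backward(grad)
        g = np.repeat(g[:, None, :], self._n_nodes, axis=1) / self._n_nodes
        for gin, relu in zip(reversed(self.layers), reversed(self.relus)):
            g = gin.backward(relu.backward(g))
        return g

    @property
    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.params())


def gin_forward(graph: WindowGraph, cfg: GinConfig | None = None,
                seed: int = 0) -> np.ndarray:
    """Forward one window graph through a freshly initialized GIN; returns
    the 2 class scores. Mainly for inspection/testing of the architecture."""
    cfg = cfg or GinConfig()
    if graph.features.shape[0] != graph.adjacency.shape[0]:
        raise ValueError("feature rows must match adjacency size")
    net = _GinNet(graph.features.shape[1], cfg, np.random.default_rng(seed))
    scores = net.forward((graph.features[None].astype(float),
                          graph.adjacency[None].astype(float)), train=False)
    return scores[0]


class GinPainDecoder(FoldedDecoderBase):
    """sklearn-style classifier over window graphs.

    X is a tuple ``(features, adjacency)`` with shapes (n, R, L) and
    (n, R, R). Fold handling is identical to the CNN decoder (shared base).
    """

    def __init__(self, hidden=32, n_layers=2, eps=0.0, learn_eps=False,
                 learning_rate=1e-3, momentum=0.9, weight_decay=5e-4,
                 epochs=50, batch_size=1, patience=10, n_folds=8,
                 random_state=0):
        super().__init__(learning_rate=learning_rate, momentum=momentum,
                         weight_decay=weight_decay, epochs=epochs,
                         batch_size=batch_size, patience=patience,
                         n_folds=n_folds, random_state=random_state)
        self.hidden = hidden
        self.n_layers = n_layers
        self.eps = eps
        self.learn_eps = learn_eps

    def _build_model(self, rng, X):
        feats, _ = X
        cfg = GinConfig(n_layers=self.n_layers, hidden=self.hidden,
                        eps=self.eps, learn_eps=self.learn_eps)
        return _GinNet(feats.shape[2], cfg, rng)

    def _n_samples(self, X):
        return len(X[0])

    def _take(self, X, idx):
        return (X[0][idx], X[1][idx])

    def _as_batch(self, X_subset):
        from ._nn import DTYPE

        return (np.asarray(X_subset[0], dtype=DTYPE),
                np.asarray(X_subset[1], dtype=DTYPE))


def window_graph_inputs(run: BoldRun, atlas: Atlas, window_s: float = 30.0,
                        stride: int = 1, bin_threshold: float = 0.3
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unlabelled per-window graph inputs for a run: (features, adjacency,
    window centre times). Used directly for sessions without a rating trace
    (e.g. resting state)."""
    ts = roi_average(run, atlas)
    mats, centers = window_connectivity(ts, window_s, run.tr, stride)
    length = int(np.floor(window_s / run.tr))
    starts = centers - length // 2
    feats = np.stack([ts.data[:, s0:s0 + length] for s0 in starts])
    adjs = binarize(mats, bin_threshold)
    center_times = (centers + 0.5) * run.tr
    return feats, adjs, center_times


def build_window_graphs(run: BoldRun, atlas: Atlas, trace: PainTrace,
                        window_s: float = 30.0, stride: int = 1,
                        bin_threshold: float = 0.3,
                        label_threshold: float = DEFAULT_THRESHOLD,
                        subject_id: str = "") -> list[WindowGraph]:
    """Full per-run graph construction: ROI averaging, windowed correlation,
    binarization, and centre-time labelling."""
    feats, adjs, center_times = window_graph_inputs(
        run, atlas, window_s, stride, bin_threshold)
    labels, kept = label_windows(trace, center_times, label_threshold)
    graphs = []
    li = 0
    for w, keep in enumerate(kept):
        if not keep:
            continue
        graphs.append(WindowGraph(
            features=feats[w],
            adjacency=adjs[w],
            label=int(labels[li]),
            subject_id=subject_id or trace.subject_id,
            center_time=float(center_times[w]),
        ))
        li += 1
    return graphs


def stack_graphs(graphs: list[WindowGraph]):
    """(features, adjacency), labels, groups arrays from a graph list."""
    X = (np.stack([g.features for g in graphs]),
         np.stack([g.adjacency for g in graphs]))
    y = np.array([g.label for g in graphs], dtype=int)
    groups = np.array([g.subject_id for g in graphs])
    return X, y, groups


def train_gcnn(graphs: list[WindowGraph], folds: FoldPlan | int,
               cfg: TrainConfig, gin: GinConfig | None = None) -> GinPainDecoder:
    """Train the folded GIN ensemble on window graphs."""
    gin = gin or GinConfig()
    k = folds if isinstance(folds, int) else folds.k
    dec = GinPainDecoder(
        hidden=gin.hidden, n_layers=gin.n_layers, eps=gin.eps,
        learn_eps=gin.learn_eps, learning_rate=cfg.learning_rate,
        momentum=cfg.momentum, weight_decay=cfg.weight_decay, epochs=cfg.epochs,
        batch_size=cfg.batch_size, patience=cfg.patience, n_folds=k,
        random_state=cfg.seed)
    X, y, groups = stack_graphs(graphs)
    if isinstance(folds, FoldPlan):
        dec._preset_plan = folds
    return dec.fit(X, y, groups)
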