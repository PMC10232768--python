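"""Volumetric residual-network decoding of low vs high pain.

A grouped-convolution ("cardinalized") residual network classifies each 3-D
BOLD volume as low or high pain. The architecture is parametric: a strided
stem convolution, ``n_stages`` residual stages whose 3x3x3 convolutions are
split into ``cardinality`` independent grouped paths, batch normalization
throughout, global average pooling, and a 2-unit linear head. The default
configuration is a desk-scale network; a deep 4-stage, 32-path variant is
reachable through the same parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._nn import BatchNorm3d, Conv3d, GlobalAvgPool3d, Layer, Linear, ReLU
from .base import DecoderMetrics, FoldedDecoderBase
from .samples import FoldPlan, LabeledVolume, TrainConfig

__all__ = ["CnnArchConfig", "build_cnn", "CnnPainDecoder", "train_cnn", "evaluate"]


@dataclass
class CnnArchConfig:
    """Architecture of the volumetric residual network."""

    n_stages: int = 2
    cardinality: int = 4
    base_width: int = 16
    stem_stride: int = 2
    input_shape: tuple[int, int, int] = (26, 12, 12)
    n_classes: int = 2

    def stage_widths(self) -> list[int]:
        widths = []
        for s in range(self.n_stages):
            w = self.base_width * 2**s
            if w % self.cardinality:
                raise ValueError(
                    f"stage width {w} not divisible by cardinality {self.cardinality}")
            widths.append(w)
        return widths


class _ResBlock(Layer):
    """Grouped residual block: two 3x3x3 grouped convs + projected shortcut."""

    def __init__(self, in_ch: int, out_ch: int, stride: int, groups: int,
                 rng: np.random.Generator):
        self.conv1 = Conv3d(in_ch, out_ch, 3, stride=stride, padding=1,
                            groups=groups, rng=rng)
        self.bn1 = BatchNorm3d(out_ch)
        self.relu1 = ReLU()
        self.conv2 = Conv3d(out_ch, out_ch, 3, stride=1, padding=1,
                            groups=groups, rng=rng)
        self.bn2 = BatchNorm3d(out_ch)
        self.proj = Conv3d(in_ch, out_ch, 1, stride=stride, padding=0, rng=rng)
        self.bn_proj = BatchNorm3d(out_ch)
        self.relu_out = ReLU()

    def params(self):
        return (self.conv1.params() + self.bn1.params() + self.conv2.params()
                + self.bn2.params() + self.proj.params() + self.bn_proj.params())

    def forward(self, x, train=True):
        main = self.bn2.forward(
            self.conv2.forward(
                self.relu1.forward(
                    self.bn1.forward(self.conv1.forward(x, train), train), train),
                train), train)
        short = self.bn_proj.forward(self.proj.forward(x, train), train)
        return self.relu_out.forward(main + short, train)

    def backward(self, grad):
        g = self.relu_out.backward(grad)
        g_short = self.proj.backward(self.bn_proj.backward(g))
        g_main = self.conv1.backward(
            self.bn1.backward(
                self.relu1.backward(
                    self.conv2.backward(self.bn2.backward(g)))))
        return g_main + g_short


class _CnnNet(Layer):
    def __init__(self, arch: CnnArchConfig, rng: np.random.Generator):
        n_down = arch.n_stages + (1 if arch.stem_stride > 1 else 0)
        min_extent = 2 ** n_down
        if min(arch.input_shape) < min_extent:
            raise ValueError(
                f"input shape {arch.input_shape} too small for "
                f"{n_down} downsampling steps; minimum extent is {min_extent}")
        widths = arch.stage_widths()
        self.stem = Conv3d(1, widths[0], 3, stride=arch.stem_stride, padding=1,
                           rng=rng, input_grad=False)
        self.stem_bn = BatchNorm3d(widths[0])
        self.stem_relu = ReLU()
        self.blocks: list[_ResBlock] = []
        in_ch = widths[0]
        for w in widths:
            self.blocks.append(_ResBlock(in_ch, w, stride=2,
                                         groups=arch.cardinality, rng=rng))
            in_ch = w
        self.pool = GlobalAvgPool3d()
        self.head = Linear(in_ch, arch.n_classes, rng=rng)

    def params(self):
        ps = self.stem.params() + self.stem_bn.params()
        for b in self.blocks:
            ps += b.params()
        return ps + self.head.params()

    def forward(self, x, train=True):
        h = self.stem_relu.forward(
            self.stem_bn.forward(self.stem.forward(x, train), train), train)
        for b in self.blocks:
            h = b.forward(h, train)
        return self.head.forward(self.pool.forward(h, train), train)

    def backward(self, grad):
        g = self.pool.backward(self.head.backward(grad))
        for b in reversed(self.blocks):
            g = b.backward(g)
        return self.stem.backward(self.stem_bn.backward(self.stem_relu.backward(g)))

    @property
    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.params())


def build_cnn(arch: CnnArchConfig, seed: int = 0) -> _CnnNet:
    """Instantiate the volumetric residual network with seeded init."""
    return _CnnNet(arch, np.random.default_rng(seed))


class CnnPainDecoder(FoldedDecoderBase):
    """sklearn-style classifier: 3-D volumes -> {low, high} pain.

    ``fit(X, y, groups)`` with subject ids in ``groups`` trains one model
    per held-out subject group (subject-grouped k-fold) and records pooled
    cross-validated metrics in ``metrics_``; with ``n_folds=None`` a single
    model is trained on everything (used for subgroup-transfer tests).
    X is an array of shape (n_samples, dx, dy, dz).
    """

    def __init__(self, n_stages=2, cardinality=4, base_width=16, stem_stride=2,
                 learning_rate=1e-3, momentum=0.9, weight_decay=5e-4,
                 epochs=50, batch_size=2, patience=10, n_folds=8,
                 random_state=0):
        super().__init__(learning_rate=learning_rate, momentum=momentum,
                         weight_decay=weight_decay, epochs=epochs,
                         batch_size=batch_size, patience=patience,
                         n_folds=n_folds, random_state=random_state)
        self.n_stages = n_stages
        self.cardinality = cardinality
        self.base_width = base_width
        self.stem_stride = stem_stride

    def _build_model(self, rng, X):
        arch = CnnArchConfig(n_stages=self.n_stages, cardinality=self.cardinality,
                             base_width=self.base_width,
                             stem_stride=self.stem_stride,
                             input_shape=tuple(X.shape[1:4]))
        return _CnnNet(arch, rng)

    def _n_samples(self, X):
        return len(X)

    def _take(self, X, idx):
        return X[idx]

    def _as_batch(self, X_subset):
        from ._nn import DTYPE
        return np.asarray(X_subset, dtype=DTYPE)[:, None]


def _stack_samples(samples: list[LabeledVolume]):
    X = np.stack([s.volume for s in samples])
    y = np.array([s.label for s in samples], dtype=int)
    groups = np.array([s.subject_id for s in samples])
    return X, y, groups


def train_cnn(samples: list[LabeledVolume], folds: FoldPlan | int,
              cfg: TrainConfig, arch: CnnArchConfig | None = None) -> CnnPainDecoder:
    """Train the 8-fold CNN ensemble on labelled volumes; returns the fitted
    decoder whose ``models_`` and ``metrics_`` hold the per-fold results."""
    arch = arch or CnnArchConfig()
    k = folds if isinstance(folds, int) else folds.k
    dec = CnnPainDecoder(
        n_stages=arch.n_stages, cardinality=arch.cardinality,
        base_width=arch.base_width, stem_stride=arch.stem_stride,
        learning_rate=cfg.learning_rate,
        momentum=cfg.momentum, weight_decay=cfg.weight_decay, epochs=cfg.epochs,
        batch_size=cfg.batch_size, patience=cfg.patience, n_folds=k,
        random_state=cfg.seed)
    X, y, groups = _stack_samples(samples)
    if isinstance(folds, FoldPlan):
        dec._preset_plan = folds
    return dec.fit(X, y, groups)


def evaluate(decoder: CnnPainDecoder, samples: list[LabeledVolume]) -> DecoderMetrics:
    """Cross-fitted metrics on the given samples (each sample scored by the
    model whose fold held its subject out)."""
    X, y, groups = _stack_samples(samples)
    scores = decoder.decision_scores(X, groups)
    pred = scores.argmax(axis=1)
    conf = np.zeros((2, 2), dtype=int)
    for t, p in zip(y, pred):
        conf[t, p] += 1
    from sklearn.metrics import roc_auc_score

    auc = {}
    for cls, name in ((0, "low"), (1, "high")):
        try:
            auc[name] = float(roc_auc_score((y == cls).astype(int), scores[:, cls]))
        except ValueError:
            auc[name] = float("nan")
    accs = []
    for fold in range(decoder.fold_plan_.k):
        accs.append(decoder.fold_accuracy(fold, X, y, groups))
    return DecoderMetrics(fold_accuracies=accs, confusion=conf, auc=auc)
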