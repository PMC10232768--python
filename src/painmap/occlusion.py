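"""Occlusion sensitivity analysis: region importance for the decoders.

For each atlas region, the region's input is zeroed (voxels for the CNN;
node features and incident edges for the GIN) and each fold model is
re-evaluated on its held-out samples. The per-region drop in accuracy
(full-data minus occluded), averaged over folds, is the region's importance;
regions are ranked by mean drop with ties broken by region code.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .base import FoldedDecoderBase
from .cohort import Atlas
from .gcnn import WindowGraph
from .samples import LabeledVolume

__all__ = ["OcclusionHeatmap", "occlude_volume", "occlude_graph",
           "importance_map", "identified_regions"]


@dataclass
class OcclusionHeatmap:
    """Per-region mean accuracy drop with the per-fold drops retained."""

    codes: list[int]
    names: dict[int, str]
    mean_drop: dict[int, float]
    fold_drops: dict[int, np.ndarray]
    full_accuracy: np.ndarray  # per-fold accuracy with no occlusion

    def ranking(self) -> list[int]:
        """Region codes ordered by decreasing mean drop; ties by code."""
        return sorted(self.codes, key=lambda c: (-self.mean_drop[c], c))


def occlude_volume(sample: LabeledVolume, atlas: Atlas, region: int) -> LabeledVolume:
    """Copy of the sample with the region's voxels set to zero."""
    if region not in atlas.names:
        raise ValueError(f"unknown region code {region}")
    vol = sample.volume.copy()
    vol[atlas.mask(region)] = 0
    return LabeledVolume(volume=vol, label=sample.label,
                         subject_id=sample.subject_id, session=sample.session,
                         time_index=sample.time_index)


def occlude_graph(sample: WindowGraph, region_index: int) -> WindowGraph:
    """Copy with the node's feature row and incident edges zeroed."""
    n = sample.features.shape[0]
    if not (0 <= region_index < n):
        raise ValueError(f"region index {region_index} out of range 0..{n - 1}")
    feats = sample.features.copy()
    adj = sample.adjacency.copy()
    feats[region_index] = 0
    adj[region_index, :] = 0
    adj[:, region_index] = 0
    return WindowGraph(features=feats, adjacency=adj, label=sample.label,
                       subject_id=sample.subject_id, center_time=sample.center_time)


def _occlude_cnn_batch(atlas: Atlas, region: int):
    mask = atlas.mask(region)

    def transform(X):
        Xo = np.array(X, copy=True)
        Xo[:, mask] = 0
        return Xo

    return transform


def _occlude_gin_batch(region_index: int):
    def transform(X):
        feats, adj = np.array(X[0], copy=True), np.array(X[1], copy=True)
        feats[:, region_index, :] = 0
        adj[:, region_index, :] = 0
        adj[:, :, region_index] = 0
        return (feats, adj)

    return transform


def importance_map(decoder: FoldedDecoderBase, X, y, groups,
                   atlas: Atlas) -> OcclusionHeatmap:
    """Occlusion heatmap over all atlas regions for a folded decoder.

    Works for both decoders through the shared fold bookkeeping: each fold
    model is evaluated only on its held-out subjects, first on the full
    inputs and then with each region occluded.
    """
    if decoder.fold_plan_ is None:
        raise ValueError("decoder must be fitted with folds")
    is_graph = isinstance(X, tuple)
    codes = atlas.codes
    k = decoder.fold_plan_.k
    full = np.array([decoder.fold_accuracy(f, X, y, groups) for f in range(k)])
    fold_drops: dict[int, np.ndarray] = {}
    mean_drop: dict[int, float] = {}
    for i, code in enumerate(codes):
        transform = _occlude_gin_batch(i) if is_graph else _occlude_cnn_batch(atlas, code)
        occ = np.array([decoder.fold_accuracy(f, X, y, groups, transform=transform)
                        for f in range(k)])
        drops = full - occ
        fold_drops[code] = drops
        mean_drop[code] = float(np.nanmean(drops))
    return OcclusionHeatmap(codes=codes, names=dict(atlas.names),
                            mean_drop=mean_drop, fold_drops=fold_drops,
                            full_accuracy=full)


def identified_regions(heatmap: OcclusionHeatmap, rule: str = "ttest",
                       alpha: float = 0.05, top_k: int | None = None) -> set[str]:
    """Convert a heatmap into the set of identified region names.

    rule="ttest": regions whose fold drops are positive at a one-sided
    one-sample t test (p < alpha). rule="topk": the top_k regions by mean
    drop (ties by code).
    """
    if not heatmap.codes:
        raise ValueError("empty heatmap")
    if rule == "ttest":
        out = set()
        for code in heatmap.codes:
            drops = heatmap.fold_drops[code]
            drops = drops[~np.isnan(drops)]
            if len(drops) < 2 or np.all(drops == drops[0]):
                continue
            res = stats.ttest_1samp(drops, 0.0, alternative="greater")
            if res.pvalue < alpha:
                out.add(heatmap.names[code])
        return out
    if rule == "topk":
        if top_k is None:
            raise ValueError("top_k required for rule='topk'")
        return {heatmap.names[c] for c in heatmap.ranking()[:top_k]}
    raise ValueError(f"unknown rule {rule!r}")
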