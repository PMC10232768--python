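"""Labelled decoding samples and subject-grouped cross-validation folds.

Continuous ratings are dichotomized into low pain (rating <= threshold,
label 0) and high pain (rating > threshold, label 1); the default threshold
of 15 VAS follows the convention of balancing the two classes across the
cohort, and ``choose_threshold`` recomputes that balancing cut for any set
of traces. Folds partition *subjects*, never samples, so no individual
contributes to both the training and the test side of any fold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .cohort import BoldRun, PainTrace, volume_times

__all__ = ["LabeledVolume", "FoldPlan", "TrainConfig",
           "label_samples", "choose_threshold", "make_folds"]

log = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 15.0


@dataclass
class LabeledVolume:
    """One 3-D volume with its low/high pain label."""

    volume: np.ndarray
    label: int  # 0 = low pain, 1 = high pain
    subject_id: str
    session: str
    time_index: int

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError("label must be 0 (low) or 1 (high)")


def label_samples(run: BoldRun, trace: PainTrace,
                  threshold: float = DEFAULT_THRESHOLD,
                  subject_id: str = "", lag_s: float = 0.0,
                  stride: int = 1) -> list[LabeledVolume]:
    """One labelled sample per volume (label 1 iff rating > threshold).

    ``lag_s`` optionally shifts the rating lookup earlier in time to
    compensate hemodynamic delay (0 by default). Volumes whose (shifted)
    rating time falls outside the trace are dropped and logged. ``stride``
    keeps every stride-th volume (temporal subsampling for desk-scale runs).
    """
    t = volume_times(run) - lag_s
    inside = (t >= trace.times[0]) & (t <= trace.times[-1])
    n_dropped = int((~inside).sum())
    if n_dropped:
        log.info("dropping %d volumes without a rating", n_dropped)
    ratings = trace.resample(t)
    out = []
    for i in range(0, run.n_volumes, stride):
        if not inside[i]:
            continue
        out.append(LabeledVolume(
            volume=run.data[..., i],
            label=int(ratings[i] > threshold),
            subject_id=subject_id or trace.subject_id,
            session=run.session,
            time_index=i,
        ))
    return out


def choose_threshold(traces: list[PainTrace]) -> tuple[int, dict]:
    """Integer cut that best balances the pooled low/high class counts.

    Scans integer thresholds and returns the one minimizing |#high - #low|
    over all pooled rating samples, together with the class counts. Raises
    if all ratings are identical (no balancing cut exists); flags the result
    as degenerate when the best achievable imbalance exceeds 50%.
    """
    if not traces:
        raise ValueError("need at least one trace")
    pooled = np.concatenate([t.ratings for t in traces])
    if np.ptp(pooled) == 0:
        raise ValueError("all ratings identical: no balancing threshold exists")
    best, best_gap = None, None
    for cut in range(0, 100):
        high = int((pooled > cut).sum())
        low = len(pooled) - high
        gap = abs(high - low)
        if best_gap is None or gap < best_gap:
            best, best_gap = cut, gap
    high = int((pooled > best).sum())
    low = len(pooled) - high
    info = {
        "threshold": best,
        "n_low": low,
        "n_high": high,
        "imbalance": best_gap / len(pooled),
        "degenerate": best_gap / len(pooled) > 0.5,
    }
    if info["degenerate"]:
        log.warning("no well-balancing cut: imbalance %.2f at threshold %d",
                    info["imbalance"], best)
    return best, info


@dataclass
class FoldPlan:
    """Disjoint subject groups covering the cohort (subject-grouped k-fold)."""

    groups: list[list[str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        flat = [s for g in self.groups for s in g]
        if len(flat) != len(set(flat)):
            raise ValueError("fold groups must be disjoint")

    @property
    def k(self) -> int:
        return len(self.groups)

    def fold_of(self, subject_id: str) -> int:
        for i, g in enumerate(self.groups):
            if subject_id in g:
                return i
        raise KeyError(f"subject {subject_id} not in the fold plan")

    def train_subjects(self, fold: int) -> set[str]:
        return {s for i, g in enumerate(self.groups) if i != fold for s in g}

    def test_subjects(self, fold: int) -> set[str]:
        return set(self.groups[fold])

    def subjects(self) -> set[str]:
        return {s for g in self.groups for s in g}


def make_folds(subject_ids: list[str], k: int = 8, seed: int = 0) -> FoldPlan:
    """Random subject-level partition into k groups of near-equal size."""
    n = len(subject_ids)
    if n < k:
        raise ValueError(f"cannot split {n} subjects into {k} groups")
    rng = np.random.default_rng(seed)
    order = [subject_ids[i] for i in rng.permutation(n)]
    groups = [list(g) for g in np.array_split(np.array(order, dtype=object), k)]
    return FoldPlan(groups=[[str(s) for s in g] for g in groups])


@dataclass
class TrainConfig:
    """Decoder training recipe: class-weighted CE + SGD with momentum.

    Defaults are the full-scale recipe (50 epochs, batch 2, lr 1e-3); the
    desk-scale synthetic experiments use a shorter, larger-batch variant.
    """

    learning_rate: float = 1.0e-3
    momentum: float = 0.9
    weight_decay: float = 5.0e-4
    epochs: int = 50
    batch_size: int = 2
    patience: int = 10  # early stop when held-out accuracy stalls this long
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.momentum < 1):
            raise ValueError("momentum must be in [0, 1)")
        for name in ("learning_rate", "weight_decay", "epochs", "batch_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
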