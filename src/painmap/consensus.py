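"""Cross-method consensus and validation analyses.

The three branches (correlation mapping, CNN occlusion, GIN occlusion) each
produce a set of region names; regions found by at least two branches form
the consensus ("signature centre") table. Additional validations: the
correlation between per-subject mean predicted and mean reported pain, the
correlation between resting-state and tracking-session predictions, the
pain- vs motion-tracking control, and subgroup-transfer decoding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .base import FoldedDecoderBase
from .stats import binomial_chance_test, pearson

__all__ = [
    "ConsensusTable", "SubjectPrediction", "consensus",
    "predicted_vs_reported", "rest_vs_tracking",
    "control_motion_tracking", "subgroup_transfer",
]


@dataclass
class ConsensusTable:
    """Region x method flags for regions identified by >= 2 methods."""

    table: pd.DataFrame  # index: region, columns: correlation, cnn, gcnn (bool)
    n_all_three: int
    n_exactly_two: int
    n_at_least_two: int


def consensus(regions_corr: set[str], regions_cnn: set[str],
              regions_gcnn: set[str]) -> ConsensusTable:
    """Consensus table over the three methods' region sets.

    Counts satisfy n_at_least_two = n_all_three + n_exactly_two.
    """
    all_regions = sorted(regions_corr | regions_cnn | regions_gcnn)
    rows = []
    for r in all_regions:
        flags = (r in regions_corr, r in regions_cnn, r in regions_gcnn)
        if sum(flags) >= 2:
            rows.append((r, *flags))
    df = pd.DataFrame(rows, columns=["region", "correlation", "cnn", "gcnn"])
    df = df.set_index("region")
    n_methods = df.sum(axis=1) if len(df) else pd.Series(dtype=int)
    n3 = int((n_methods == 3).sum())
    n2 = int((n_methods == 2).sum())
    return ConsensusTable(table=df, n_all_three=n3, n_exactly_two=n2,
                          n_at_least_two=n3 + n2)


@dataclass
class SubjectPrediction:
    """Per-subject session means of predicted and reported pain."""

    subject_id: str
    mean_predicted_tracking: float | None = None  # mean class-1 probability
    mean_predicted_resting: float | None = None
    mean_reported_tracking: float | None = None  # VAS units


def predicted_vs_reported(predictions: list[SubjectPrediction]) -> tuple[float, float]:
    """Pearson r (+ two-sided p) between per-subject mean predicted pain and
    mean reported rating over the tracking session."""
    pairs = [(p.mean_predicted_tracking, p.mean_reported_tracking)
             for p in predictions
             if p.mean_predicted_tracking is not None
             and p.mean_reported_tracking is not None]
    if len(pairs) < 3:
        raise ValueError("need tracking-session values from at least 3 subjects")
    x, y = map(np.array, zip(*pairs))
    return pearson(x, y)


def rest_vs_tracking(predictions: list[SubjectPrediction]) -> tuple[float, float]:
    """Pearson r (+ p) between resting and tracking model-predicted means."""
    pairs = [(p.mean_predicted_resting, p.mean_predicted_tracking)
             for p in predictions
             if p.mean_predicted_resting is not None
             and p.mean_predicted_tracking is not None]
    if len(pairs) < 3:
        raise ValueError("need both session predictions from at least 3 subjects")
    x, y = map(np.array, zip(*pairs))
    return pearson(x, y)


@dataclass
class MotionControlResult:
    tracking_accuracy: float
    tracking_p: float  # one-sided binomial vs 0.5 on pooled samples
    motion_accuracy: float | None
    motion_p: float | None  # two-sided binomial vs 0.5 on pooled samples
    n_tracking: int = 0
    n_motion: int = 0
    # per-subject accuracies and subject-level t tests vs 50%: samples within
    # a subject are autocorrelated, so the subject is the exchangeable unit
    tracking_subject_acc: np.ndarray | None = None
    motion_subject_acc: np.ndarray | None = None
    tracking_subject_p: float | None = None  # one-sided (above chance)
    motion_subject_p: float | None = None    # two-sided (at chance?)
    degenerate: bool = False  # single-class motion labels, no test possible


def control_motion_tracking(decoder: FoldedDecoderBase,
                            X_track, y_track, groups_track,
                            X_motion, y_motion, groups_motion) -> MotionControlResult:
    """Fold-respecting accuracies on pain-tracking vs motion-tracking samples.

    Motion-tracking labels come from the replayed cursor trace; by design
    of the paradigm the motion-session BOLD carries no pain coupling, so its
    accuracy should sit at chance while tracking accuracy lies above it.
    """
    from scipy import stats as _stats

    def _subject_acc(correct, groups):
        groups = np.asarray(groups)
        return np.array([correct[groups == s].mean()
                         for s in sorted(set(groups.tolist()))])

    y_track = np.asarray(y_track)
    pred_t = decoder.predict(X_track, groups_track)
    correct_t = pred_t == y_track
    acc_t = float(correct_t.mean())
    p_t = binomial_chance_test(int(correct_t.sum()), len(y_track))
    sub_t = _subject_acc(correct_t, groups_track)
    p_sub_t = float(_stats.ttest_1samp(sub_t, 0.5, alternative="greater").pvalue)
    y_motion = np.asarray(y_motion)
    if len(np.unique(y_motion)) < 2:
        return MotionControlResult(acc_t, p_t, None, None,
                                   n_tracking=len(y_track),
                                   tracking_subject_acc=sub_t,
                                   tracking_subject_p=p_sub_t, degenerate=True)
    pred_m = decoder.predict(X_motion, groups_motion)
    correct_m = pred_m == y_motion
    acc_m = float(correct_m.mean())
    p_m = binomial_chance_test(int(correct_m.sum()), len(y_motion),
                               alternative="two-sided")
    sub_m = _subject_acc(correct_m, groups_motion)
    p_sub_m = float(_stats.ttest_1samp(sub_m, 0.5).pvalue)
    return MotionControlResult(acc_t, p_t, acc_m, p_m,
                               n_tracking=len(y_track), n_motion=len(y_motion),
                               tracking_subject_acc=sub_t,
                               motion_subject_acc=sub_m,
                               tracking_subject_p=p_sub_t,
                               motion_subject_p=p_sub_m)


def subgroup_transfer(decoder_factory, X, y, groups, subject_attr: dict[str, bool],
                      train_side: bool, min_train_subjects: int = 4
                      ) -> tuple[float, float]:
    """Train on one subgroup, test on the other; accuracy + test vs chance.

    ``subject_attr`` maps subject id -> bool (e.g. surgery flag);
    ``train_side`` picks which value forms the training subgroup. Training
    subgroups smaller than ``min_train_subjects`` are refused, mirroring the
    practice of not training on a subgroup too small to fit a model.
    """
    groups = np.asarray(groups)
    y = np.asarray(y)
    train_subjects = {s for s, v in subject_attr.items() if v == train_side}
    test_subjects = {s for s, v in subject_attr.items() if v != train_side}
    if not train_subjects or not test_subjects:
        raise ValueError("both subgroups must be nonempty")
    if len(train_subjects) < min_train_subjects:
        raise ValueError(
            f"training subgroup has {len(train_subjects)} subjects, below the "
            f"minimum of {min_train_subjects}; refusing to train")
    tr = np.flatnonzero(np.isin(groups, list(train_subjects)))
    te = np.flatnonzero(np.isin(groups, list(test_subjects)))
    dec = decoder_factory()
    if dec.n_folds is not None:
        raise ValueError("subgroup transfer uses a single model: set n_folds=None")
    dec.fit(_take(X, tr), y[tr])
    pred = dec.predict(_take(X, te))
    acc = float((pred == y[te]).mean())
    p = binomial_chance_test(int((pred == y[te]).sum()), len(te))
    return acc, p


def _take(X, idx):
    if isinstance(X, tuple):
        return (X[0][idx], X[1][idx])
    return X[idx]
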