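"""End-to-end desk-scale experiment: cohort -> three branches -> consensus.

This module wires the full analysis together on a synthetic cohort:
preprocessing, the correlation branch, both decoders with subject-grouped
8-fold cross-validation, occlusion importance, the cross-method consensus,
and the validation analyses (predicted-vs-reported pain, resting-vs-tracking
prediction, motion-tracking control).

The desk-scale training recipe (fewer epochs, larger batches, higher
learning rate than the full-scale recipe) and the volume subsampling stride
are deliberate scaled-down run sizes chosen so a complete multi-seed
experiment runs on a single CPU; docs/methods.md discusses the choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import Atlas, CohortConfig, SubjectRecord, generate_cohort
from .consensus import (ConsensusTable, MotionControlResult, SubjectPrediction,
                        consensus, control_motion_tracking, predicted_vs_reported,
                        rest_vs_tracking)
from .correlation import ClusterRow, PainCorrelationAnalysis
from .gcnn import (GinPainDecoder, build_window_graphs, stack_graphs,
                   window_graph_inputs)
from .cnn import CnnPainDecoder
from .occlusion import OcclusionHeatmap, identified_regions, importance_map
from .preprocess import preprocess_run
from .samples import TrainConfig, choose_threshold, label_samples

__all__ = ["DeskTrainConfig", "PipelineResult", "run_pipeline",
           "DESK_CNN_STRIDE", "desk_train_config"]

# Desk-scale recipe: see module docstring. The CNN trains on every 2nd
# volume and is evaluated/occluded on a denser subsample than it trains on.
DESK_CNN_STRIDE = 2
DESK_EVAL_STRIDE = 2


def desk_train_config(seed: int = 0) -> TrainConfig:
    return TrainConfig(learning_rate=1e-2, momentum=0.9, weight_decay=5e-4,
                       epochs=3, batch_size=16, patience=3, seed=seed)


DeskTrainConfig = desk_train_config  # backwards-friendly alias


@dataclass
class PipelineResult:
    atlas: Atlas
    threshold: float
    corr_regions: set[str]
    positive_clusters: list[ClusterRow]
    negative_clusters: list[ClusterRow]
    cnn: CnnPainDecoder
    gcnn: GinPainDecoder
    cnn_heatmap: OcclusionHeatmap | None
    gcnn_heatmap: OcclusionHeatmap | None
    cnn_regions: set[str] | None
    gcnn_regions: set[str] | None
    consensus: ConsensusTable | None
    predictions: dict[str, list[SubjectPrediction]] = field(default_factory=dict)
    validation: dict = field(default_factory=dict)
    motion_control: MotionControlResult | None = None


def _preprocessed(subjects: list[SubjectRecord], session: str) -> dict[str, object]:
    out = {}
    for s in subjects:
        if s.has_run(session):
            out[s.id] = preprocess_run(s.run(session))
    return out


def _cnn_xy(subjects, runs, threshold, stride):
    samples = []
    for s in subjects:
        if s.id not in runs:
            continue
        samples.extend(label_samples(runs[s.id], s.trace, threshold,
                                     subject_id=s.id, stride=stride))
    X = np.stack([v.volume for v in samples])
    y = np.array([v.label for v in samples], dtype=int)
    groups = np.array([v.subject_id for v in samples])
    return X, y, groups


def run_pipeline(config: CohortConfig | None = None,
                 train: TrainConfig | None = None,
                 cnn_stride: int = DESK_CNN_STRIDE,
                 eval_stride: int = DESK_EVAL_STRIDE,
                 window_s: float = 30.0,
                 window_stride: int = 2,
                 bin_threshold: float = 0.3,
                 n_folds: int = 8,
                 with_validation: bool = True,
                 with_occlusion: bool = True,
                 subjects: list[SubjectRecord] | None = None,
                 atlas: Atlas | None = None) -> PipelineResult:
    """Run the complete analysis on a (generated or supplied) cohort."""
    config = config or CohortConfig()
    if subjects is None:
        subjects, atlas = generate_cohort(config)
    train = train or desk_train_config(config.seed)

    track = _preprocessed(subjects, "tracking")

    # --- correlation branch ---------------------------------------------
    corr = PainCorrelationAnalysis().fit(
        [track[s.id] for s in subjects], [s.trace for s in subjects], atlas)

    # --- labels ----------------------------------------------------------
    threshold, _info = choose_threshold([s.trace for s in subjects])

    # --- CNN branch ------------------------------------------------------
    Xc, yc, gc = _cnn_xy(subjects, track, threshold, cnn_stride)
    cnn = CnnPainDecoder(
        learning_rate=train.learning_rate, momentum=train.momentum,
        weight_decay=train.weight_decay, epochs=train.epochs,
        batch_size=train.batch_size, patience=train.patience,
        n_folds=n_folds, random_state=train.seed)
    cnn.fit(Xc, yc, gc)
    if eval_stride == cnn_stride:
        Xe, ye, ge = Xc, yc, gc
    else:
        Xe, ye, ge = _cnn_xy(subjects, track, threshold, eval_stride)
    cnn_heat = cnn_regions = None
    if with_occlusion:
        cnn_heat = importance_map(cnn, Xe, ye, ge, atlas)
        cnn_regions = identified_regions(cnn_heat)

    # --- GCNN branch -----------------------------------------------------
    graphs = []
    for s in subjects:
        graphs.extend(build_window_graphs(
            track[s.id], atlas, s.trace, window_s=window_s,
            stride=window_stride, bin_threshold=bin_threshold,
            label_threshold=threshold, subject_id=s.id))
    Xg, yg, gg = stack_graphs(graphs)
    gcnn = GinPainDecoder(
        learning_rate=train.learning_rate, momentum=train.momentum,
        weight_decay=train.weight_decay, epochs=train.epochs,
        batch_size=max(train.batch_size, 8), patience=train.patience,
        n_folds=n_folds, random_state=train.seed)
    gcnn.fit(Xg, yg, gg)
    gcnn_heat = gcnn_regions = None
    if with_occlusion:
        gcnn_heat = importance_map(gcnn, Xg, yg, gg, atlas)
        gcnn_regions = identified_regions(gcnn_heat)

    cons = (consensus(corr.regions_, cnn_regions, gcnn_regions)
            if with_occlusion else None)

    result = PipelineResult(
        atlas=atlas, threshold=threshold, corr_regions=corr.regions_,
        positive_clusters=corr.positive_clusters_,
        negative_clusters=corr.negative_clusters_,
        cnn=cnn, gcnn=gcnn, cnn_heatmap=cnn_heat, gcnn_heatmap=gcnn_heat,
        cnn_regions=cnn_regions, gcnn_regions=gcnn_regions, consensus=cons)

    if with_validation:
        result.predictions, result.validation, result.motion_control = \
            _validation(subjects, atlas, cnn, gcnn, Xe, ye, ge, Xg, yg, gg,
                        threshold, eval_stride, window_s, window_stride,
                        bin_threshold)
    return result


def _branch_predictions(subjects, decoder, X, groups, rest_inputs):
    """Per-subject mean predicted pain for one decoder branch."""
    preds: list[SubjectPrediction] = []
    proba = decoder.predict_proba(X, groups)[:, 1]
    groups = np.asarray(groups)
    for s in subjects:
        sp = SubjectPrediction(
            subject_id=s.id,
            mean_predicted_tracking=float(proba[groups == s.id].mean()),
            mean_reported_tracking=float(s.trace.ratings.mean()))
        if s.id in rest_inputs:
            Xr, gr = rest_inputs[s.id]
            sp.mean_predicted_resting = float(
                decoder.predict_proba(Xr, gr)[:, 1].mean())
        preds.append(sp)
    return preds


def _validation(subjects, atlas, cnn, gcnn, Xc, yc, gc, Xg, yg, gg,
                threshold, stride, window_s, window_stride, bin_threshold):
    rest = _preprocessed(subjects, "resting")
    rest_cnn, rest_gcnn = {}, {}
    for s in subjects:
        if s.id not in rest:
            continue
        run = rest[s.id]
        Xr = np.moveaxis(run.data, -1, 0)[::stride]
        rest_cnn[s.id] = (Xr, np.array([s.id] * len(Xr)))
        feats, adjs, _ = window_graph_inputs(run, atlas, window_s,
                                             window_stride, bin_threshold)
        rest_gcnn[s.id] = ((feats, adjs), np.array([s.id] * len(feats)))

    predictions = {
        "cnn": _branch_predictions(subjects, cnn, Xc, gc, rest_cnn),
        "gcnn": _branch_predictions(subjects, gcnn, Xg, gg, rest_gcnn),
    }
    validation = {}
    for branch, preds in predictions.items():
        r, p = predicted_vs_reported(preds)
        validation[f"predicted_vs_reported_{branch}"] = {"r": r, "p": p,
                                                         "n": len(preds)}
        r, p = rest_vs_tracking(preds)
        validation[f"rest_vs_tracking_{branch}"] = {"r": r, "p": p,
                                                    "n": len(preds)}

    # motion-tracking control is run with the CNN models
    motion_result = None
    motion_subjects = [s for s in subjects if s.has_run("motion_tracking")]
    if motion_subjects:
        motion = _preprocessed(motion_subjects, "motion_tracking")
        msamples = []
        for s in motion_subjects:
            msamples.extend(label_samples(motion[s.id], s.motion_trace, threshold,
                                          subject_id=s.id, stride=stride))
        Xm = np.stack([v.volume for v in msamples])
        ym = np.array([v.label for v in msamples], dtype=int)
        gm = np.array([v.subject_id for v in msamples])
        motion_result = control_motion_tracking(cnn, Xc, yc, np.asarray(gc),
                                                Xm, ym, gm)
    return predictions, validation, motion_result
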