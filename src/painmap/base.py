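"""Subject-grouped cross-validated decoder scaffolding.

Both decoders (volumetric CNN and graph GIN) share one code path for fold
bookkeeping, training, out-of-fold evaluation and occlusion scoring: a
sample is only ever scored by the model whose fold held its subject out,
and train/test subject sets are asserted disjoint for every fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import roc_auc_score

from ._nn import DTYPE, SGD, softmax, weighted_cross_entropy
from .samples import FoldPlan, make_folds
from .stats import fold_accuracy_ttest

__all__ = ["DecoderMetrics", "FoldedDecoderBase"]

EVAL_BATCH = 512


@dataclass
class DecoderMetrics:
    """Per-fold accuracies, pooled confusion counts and per-class AUC."""

    fold_accuracies: list[float]
    confusion: np.ndarray  # (2, 2): rows = true (low, high), cols = predicted
    auc: dict[str, float]
    epoch_accuracy: list[list[float]] = field(default_factory=list)
    epoch_loss: list[list[float]] = field(default_factory=list)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def pooled_accuracy(self) -> float:
        return float(np.trace(self.confusion) / self.confusion.sum())

    @property
    def n_samples(self) -> int:
        return int(self.confusion.sum())

    def chance_ttest(self) -> tuple[float, float]:
        """One-sided t test of the fold accuracies against 50% chance."""
        return fold_accuracy_ttest(np.asarray(self.fold_accuracies))


class FoldedDecoderBase(BaseEstimator, ClassifierMixin):
    """Common fit/predict/occlusion machinery for the two decoders.

    Subclasses implement ``_build_model`` (returns a Layer with
    forward/backward), ``_n_samples``, ``_take`` (index into X), and
    ``_as_batch`` (convert an X subset to the model's input format).

    With ``n_folds`` set, ``fit`` trains one model per held-out subject
    group and records cross-validated metrics; with ``n_folds=None`` a
    single model is trained on all data (used for subgroup transfer).
    """

    def __init__(self, learning_rate=1e-3, momentum=0.9, weight_decay=5e-4,
                 epochs=50, batch_size=2, patience=10, n_folds=8,
                 random_state=0):
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.epochs = epochs
        self.batch_size = batch_size
        self.patience = patience
        self.n_folds = n_folds
        self.random_state = random_state

    # ---- subclass hooks -------------------------------------------------
    def _build_model(self, rng: np.random.Generator, X):
        raise NotImplementedError

    def _n_samples(self, X) -> int:
        raise NotImplementedError

    def _take(self, X, idx: np.ndarray):
        raise NotImplementedError

    def _as_batch(self, X_subset):
        """Convert an X subset into the array(s) fed to the model."""
        raise NotImplementedError

    # ---- training -------------------------------------------------------
    def fit(self, X, y, groups=None):
        y = np.asarray(y, dtype=int)
        n = self._n_samples(X)
        if len(y) != n:
            raise ValueError("X and y length mismatch")
        self.classes_ = np.array([0, 1])
        if self.n_folds is None:
            rng = np.random.default_rng(self.random_state)
            self.model_, losses, _ = self._train_one(
                X, y, np.arange(n), None, None, rng)
            self.train_loss_ = losses
            self.fold_plan_ = None
            return self

        if groups is None:
            raise ValueError("groups (subject ids) required for folded training")
        groups = np.asarray(groups)
        subjects = sorted(set(groups.tolist()))
        plan = getattr(self, "_preset_plan", None)
        if plan is None:
            plan = make_folds(subjects, k=self.n_folds, seed=self.random_state)
        elif set(subjects) - plan.subjects():
            raise ValueError("samples from subjects outside the preset fold plan")
        self.fold_plan_ = plan
        self.models_ = []
        fold_accs, epoch_accs, epoch_losses = [], [], []
        oof_scores = np.full((n, 2), np.nan)
        for fold in range(plan.k):
            tr_subj = plan.train_subjects(fold)
            te_subj = plan.test_subjects(fold)
            assert not (tr_subj & te_subj), "subject leakage between train and test"
            tr_idx = np.flatnonzero(np.isin(groups, list(tr_subj)))
            te_idx = np.flatnonzero(np.isin(groups, list(te_subj)))
            rng = np.random.default_rng(self.random_state + fold)
            model, losses, val_accs = self._train_one(
                X, y, tr_idx, te_idx, fold, rng)
            self.models_.append(model)
            epoch_losses.append(losses)
            epoch_accs.append(val_accs)
            scores = self._scores(model, self._take(X, te_idx))
            oof_scores[te_idx] = scores
            fold_accs.append(float((scores.argmax(axis=1) == y[te_idx]).mean()))
        self.oof_scores_ = oof_scores
        self.oof_proba_ = softmax(oof_scores)
        pred = oof_scores.argmax(axis=1)
        conf = np.zeros((2, 2), dtype=int)
        for t, p in zip(y, pred):
            conf[t, p] += 1
        auc = {}
        for cls, name in ((0, "low"), (1, "high")):
            try:
                auc[name] = float(roc_auc_score((y == cls).astype(int),
                                                oof_scores[:, cls]))
            except ValueError:
                auc[name] = float("nan")
        self.metrics_ = DecoderMetrics(fold_accuracies=fold_accs, confusion=conf,
                                       auc=auc, epoch_accuracy=epoch_accs,
                                       epoch_loss=epoch_losses)
        self._groups_fit_ = groups
        return self

    def _train_one(self, X, y, tr_idx, te_idx, fold, rng):
        y_tr = y[tr_idx]
        classes, counts = np.unique(y_tr, return_counts=True)
        if len(classes) < 2:
            where = f"fold {fold}" if fold is not None else "the training set"
            raise ValueError(f"training split for {where} contains a single class")
        # inverse class frequency weights
        cw = np.zeros(2)
        cw[classes] = len(y_tr) / (2.0 * counts)
        model = self._build_model(rng, X)
        opt = SGD(model.params(), lr=self.learning_rate, momentum=self.momentum,
                  weight_decay=self.weight_decay)
        losses, val_accs = [], []
        best_acc, best_state, since_best = -np.inf, None, 0
        for _epoch in range(self.epochs):
            order = rng.permutation(len(tr_idx))
            epoch_loss, n_batches = 0.0, 0
            for start in range(0, len(order), self.batch_size):
                bidx = tr_idx[order[start:start + self.batch_size]]
                batch = self._as_batch(self._take(X, bidx))
                scores = model.forward(batch, train=True)
                loss, grad = weighted_cross_entropy(scores, y[bidx], cw)
                opt.zero_grad()
                model.backward(grad.astype(DTYPE, copy=False))
                opt.step()
                epoch_loss += loss
                n_batches += 1
            losses.append(epoch_loss / max(n_batches, 1))
            if te_idx is not None:
                scores = self._scores(model, self._take(X, te_idx))
                acc = float((scores.argmax(axis=1) == y[te_idx]).mean())
                val_accs.append(acc)
                if acc > best_acc + 1e-12:
                    best_acc, since_best = acc, 0
                    best_state = [p.value.copy() for p in model.params()]
                else:
                    since_best += 1
                    if since_best >= self.patience:
                        break
        if best_state is not None:
            for p, v in zip(model.params(), best_state):
                p.value = v
        self._calibrate(model, X, y, tr_idx)
        return model, losses, val_accs

    def _calibrate(self, model, X, y, tr_idx) -> None:
        """Set the model's decision offset so that its prediction rate on its
        own training split equals the training label fraction.

        Class-weighted losses bias raw decisions toward the training
        minority class; without this calibration a fold model carries its
        training prior onto held-out subjects, which shows up as spurious
        above-chance accuracy on label-uncoupled data (e.g. the
        motion-tracking control) and as shared-model variance in
        per-subject prediction means."""
        if len(tr_idx) > 1024:  # an evenly spaced subsample fixes the quantile
            tr_idx = tr_idx[np.linspace(0, len(tr_idx) - 1, 1024).astype(int)]
        scores = self._scores(model, self._take(X, tr_idx), raw=True)
        margins = scores[:, 1] - scores[:, 0]
        frac_high = float(np.mean(y[tr_idx] == 1))
        model.calib_offset = float(np.quantile(margins, 1.0 - frac_high))

    # ---- scoring --------------------------------------------------------
    def _scores(self, model, X_subset, raw: bool = False) -> np.ndarray:
        """2-unit output scores, batched, in eval mode; unless ``raw``, the
        model's calibration offset is folded into the class-1 score."""
        n = self._n_samples(X_subset)
        out = np.empty((n, 2))
        for start in range(0, n, EVAL_BATCH):
            idx = np.arange(start, min(start + EVAL_BATCH, n))
            out[idx] = model.forward(self._as_batch(self._take(X_subset, idx)),
                                     train=False)
        if not raw:
            out[:, 1] -= getattr(model, "calib_offset", 0.0)
        return out

    def _model_for(self, subject) -> object:
        if self.fold_plan_ is None:
            return self.model_
        return self.models_[self.fold_plan_.fold_of(subject)]

    def decision_scores(self, X, groups=None) -> np.ndarray:
        """Raw output scores; cross-fitted models require ``groups`` so each
        sample is scored by the model that held its subject out."""
        if getattr(self, "fold_plan_", None) is None:
            return self._scores(self.model_, X)
        if groups is None:
            raise ValueError("groups required: decoder was trained with folds")
        groups = np.asarray(groups)
        unknown = set(groups.tolist()) - self.fold_plan_.subjects()
        if unknown:
            raise ValueError(f"samples from untrained subjects: {sorted(unknown)}")
        n = self._n_samples(X)
        out = np.empty((n, 2))
        for subject in set(groups.tolist()):
            idx = np.flatnonzero(groups == subject)
            out[idx] = self._scores(self._model_for(subject), self._take(X, idx))
        return out

    def predict_proba(self, X, groups=None) -> np.ndarray:
        return softmax(self.decision_scores(X, groups))

    def predict(self, X, groups=None) -> np.ndarray:
        return self.decision_scores(X, groups).argmax(axis=1)

    def score(self, X, y, groups=None) -> float:
        return float((self.predict(X, groups) == np.asarray(y)).mean())

    def fold_accuracy(self, fold: int, X, y, groups, transform=None) -> float:
        """Accuracy of fold ``fold``'s model on its held-out samples,
        optionally transforming (e.g. occluding) the inputs first."""
        groups = np.asarray(groups)
        te = np.flatnonzero(np.isin(groups, list(self.fold_plan_.test_subjects(fold))))
        if len(te) == 0:
            return float("nan")
        Xs = self._take(X, te)
        if transform is not None:
            Xs = transform(Xs)
        scores = self._scores(self.models_[fold], Xs)
        return float((scores.argmax(axis=1) == np.asarray(y)[te]).mean())
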