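"""Leave-one-subject-out evaluation and diagnostic performance statistics.

Every subject is held out in turn; hyperparameters are re-tuned, the
concept pool rebuilt and the 1-norm SVM refitted on the remaining
subjects only, and the held-out subject's recordings are scored by that
model.  Pooled out-of-fold scores give the ROC curve and C-statistic
(with a subject-stratified percentile bootstrap CI), the Youden-optimal
operating threshold, and the per-subject confusion matrix.  A subject's
score is the mean of their recordings' scores: confusion counts are per
person, while a recording-level ROC is reported alongside.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

from .miles import (DEFAULT_LAMBDA_GRID, DEFAULT_POOL_CAP, DEFAULT_SIGMA_GRID,
                    _signed_labels, build_concept_pool, embed_bags,
                    fit_sparse_linear, min_sq_distances, tune_hyperparams)
from .morphometry import RecordingBag

__all__ = [
    "CVResult",
    "logo_folds",
    "run_logo_cv",
    "roc_curve_auc",
    "auc_ci_bootstrap",
    "youden_threshold",
]

logger = logging.getLogger("ppgmiles.evaluate")

POSITIVE = "oHCM"


@dataclass
class CVResult:
    """Pooled out-of-fold scores and the derived diagnostics."""

    recording_scores: pd.DataFrame      # subject_id, recording_id, label, score
    subject_scores: pd.DataFrame        # subject_id, label, score
    roc_points: list[tuple[float, float]]            # subject-level
    recording_roc_points: list[tuple[float, float]]
    c_statistic: float
    recording_c_statistic: float
    ci_low: float
    ci_high: float
    threshold: float
    sensitivity: float
    specificity: float
    accuracy: float
    confusion: tuple[int, int, int, int]             # TP, FN, TN, FP
    fold_hyperparams: list[dict] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps({
            "c_statistic": self.c_statistic,
            "recording_c_statistic": self.recording_c_statistic,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
            "threshold": self.threshold,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "accuracy": self.accuracy,
            "confusion": {"TP": self.confusion[0], "FN": self.confusion[1],
                          "TN": self.confusion[2], "FP": self.confusion[3]},
            "roc_points": self.roc_points,
            "recording_roc_points": self.recording_roc_points,
            "subject_scores": self.subject_scores.to_dict(orient="records"),
            "recording_scores": self.recording_scores.to_dict(orient="records"),
            "fold_hyperparams": self.fold_hyperparams,
        }, indent=1)


def logo_folds(subject_ids: Sequence[str]) -> list[tuple[np.ndarray, str]]:
    """One fold per subject: (training subjects, held-out subject)."""
    subjects = np.unique(np.asarray(subject_ids))
    if len(subjects) < 3:
        raise ValueError("need at least three subjects for leave-one-out")
    return [(subjects[subjects != s], str(s)) for s in subjects]


def roc_curve_auc(scores: Sequence[float], labels: Sequence[str]
                  ) -> tuple[list[tuple[float, float]], float]:
    """ROC points (FPR, TPR) by threshold sweep and the C-statistic
    (pair-counting AUC, ties counted half)."""
    y = (_signed_labels(np.asarray(labels)) > 0).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required for a ROC curve")
    s = np.asarray(scores, dtype=float)
    fpr, tpr, _ = roc_curve(y, s, drop_intermediate=False)
    return list(zip(fpr.tolist(), tpr.tolist())), float(roc_auc_score(y, s))


def auc_ci_bootstrap(subject_scores: Sequence[float], labels: Sequence[str],
                     n_boot: int = 2000, seed: int = 0
                     ) -> tuple[float, float]:
    """Percentile 95% CI of the subject-level AUC.

    Resampling is stratified within class (subjects are resampled with
    replacement separately among positives and negatives), so every
    resample keeps both classes.  The scheme is deliberately simple and
    documented: one ``default_rng(seed)``, and per replicate one
    ``integers`` draw per class, positives first.
    """
    s = np.asarray(subject_scores, dtype=float)
    y = _signed_labels(np.asarray(labels)) > 0
    pos, neg = s[y], s[~y]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes required")
    rng = np.random.default_rng(seed)
    aucs = np.empty(n_boot)
    for i in range(n_boot):
        p = pos[rng.integers(0, len(pos), len(pos))]
        q = neg[rng.integers(0, len(neg), len(neg))]
        diff = p[:, None] - q[None, :]
        aucs[i] = (np.sign(diff).mean() + 1.0) / 2.0
    lo, hi = np.percentile(aucs, [2.5, 97.5])
    return float(lo), float(hi)


def youden_threshold(scores: Sequence[float], labels: Sequence[str]
                     ) -> tuple[float, float, float, tuple[int, int, int, int]]:
    """Threshold maximising sensitivity + specificity.

    Candidate cuts are midpoints between adjacent distinct scores plus
    cuts below and above all scores; a recording/subject is called
    positive when score >= threshold.  Ties are resolved toward higher
    specificity, then the higher threshold.  Returns
    ``(threshold, sensitivity, specificity, (TP, FN, TN, FP))``.
    """
    s = np.asarray(scores, dtype=float)
    y = _signed_labels(np.asarray(labels)) > 0
    if y.all() or (~y).all():
        raise ValueError("both classes required")
    distinct = np.unique(s)
    cuts = np.concatenate([[distinct[0] - 1.0],
                           (distinct[:-1] + distinct[1:]) / 2.0,
                           [distinct[-1] + 1.0]])
    best = None
    for thr in cuts:
        pred = s >= thr
        tp = int(np.sum(pred & y)); fn = int(np.sum(~pred & y))
        tn = int(np.sum(~pred & ~y)); fp = int(np.sum(pred & ~y))
        sens = tp / (tp + fn)
        spec = tn / (tn + fp)
        key = (sens + spec, spec, thr)
        if best is None or key > best[0]:
            best = (key, float(thr), sens, spec, (tp, fn, tn, fp))
    return best[1], best[2], best[3], best[4]


def run_logo_cv(
    bags: Sequence[RecordingBag],
    sigma_grid: Sequence[float] = DEFAULT_SIGMA_GRID,
    lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
    pool_cap: int = DEFAULT_POOL_CAP,
    n_inner_splits: int = 68,
    train_frac: float = 0.7,
    n_boot: int = 2000,
    seed: int = 0,
) -> CVResult:
    """Leave-one-subject-out cross-validation of the full MILES pipeline.

    Per fold: tune (sigma, lambda) on the training subjects with
    ``n_inner_splits`` seeded subject-level splits, rebuild the concept
    pool, fit the exact 1-norm SVM, and score the held-out subject's
    recordings.  No recording of the held-out subject influences
    standardisation, the pool, tuning or the fit of its own fold.
    """
    subject_ids = np.asarray([b.subject_id for b in bags])
    labels = np.asarray([b.label for b in bags])
    subj_labels = pd.Series(labels, index=subject_ids).groupby(level=0).first()
    if (subj_labels == POSITIVE).sum() < 2 or (subj_labels != POSITIVE).sum() < 2:
        raise ValueError("need at least two subjects per class")

    folds = logo_folds(subject_ids)
    master = np.random.SeedSequence(seed)
    fold_seeds = master.generate_state(2 * len(folds)) % (2**31)

    rows = []
    fold_hp: list[dict] = []
    for i, (train_subjects, held_out) in enumerate(folds):
        tr_mask = subject_ids != held_out
        te_mask = ~tr_mask
        tr_bags = [b for b, m in zip(bags, tr_mask) if m]
        te_bags = [b for b, m in zip(bags, te_mask) if m]
        try:
            pool = build_concept_pool(tr_bags, pool_cap=pool_cap,
                                      seed=int(fold_seeds[2 * i]))
            sig, lam = tune_hyperparams(
                tr_bags, subject_ids[tr_mask], labels[tr_mask],
                sigma_grid=sigma_grid, lambda_grid=lambda_grid,
                n_splits=n_inner_splits, train_frac=train_frac,
                seed=int(fold_seeds[2 * i + 1]), pool=pool)
            M_tr = min_sq_distances(tr_bags, pool)
            E_tr = embed_bags(M_tr, sig)
            w, b, obj = fit_sparse_linear(E_tr, labels[tr_mask], lam)
            M_te = min_sq_distances(te_bags, pool)
            E_te = embed_bags(M_te, sig)
            scores = E_te @ w + b
        except ValueError as err:
            logger.error("fold %s skipped: %s", held_out, err)
            continue
        fold_hp.append({"held_out": held_out, "sigma": sig, "lam": lam,
                        "nonzero_weights": int(np.sum(w != 0))})
        for bag, sc in zip(te_bags, scores):
            rows.append({"subject_id": bag.subject_id,
                         "recording_id": bag.recording_id,
                         "label": bag.label, "score": float(sc)})

    rec_df = pd.DataFrame(rows)
    subj_df = (rec_df.groupby("subject_id")
               .agg(label=("label", "first"), score=("score", "mean"))
               .reset_index())

    rec_roc, rec_auc = roc_curve_auc(rec_df["score"], rec_df["label"])
    subj_roc, subj_auc = roc_curve_auc(subj_df["score"], subj_df["label"])
    ci_lo, ci_hi = auc_ci_bootstrap(subj_df["score"], subj_df["label"],
                                    n_boot=n_boot,
                                    seed=int(master.generate_state(1)[0] % 2**31))
    thr, sens, spec, conf = youden_threshold(subj_df["score"], subj_df["label"])
    tp, fn, tn, fp = conf
    acc = (tp + tn) / len(subj_df)
    logger.info("LOGO AUC %.4f (CI %.4f-%.4f) sens %.3f spec %.3f acc %.3f "
                "confusion TP=%d FN=%d TN=%d FP=%d",
                subj_auc, ci_lo, ci_hi, sens, spec, acc, tp, fn, tn, fp)
    return CVResult(
        recording_scores=rec_df, subject_scores=subj_df,
        roc_points=subj_roc, recording_roc_points=rec_roc,
        c_statistic=subj_auc, recording_c_statistic=rec_auc,
        ci_low=ci_lo, ci_high=ci_hi, threshold=thr,
        sensitivity=sens, specificity=spec, accuracy=acc,
        confusion=conf, fold_hyperparams=fold_hp)
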