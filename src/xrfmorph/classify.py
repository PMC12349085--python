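"""Linear discriminant analysis of clade labels on PCA scores.

Classical LDA with a pooled within-class covariance: discriminant axes solve
the generalised eigenproblem ``Sb a = lambda Sw a`` (scalings normalised so
``a' Sw a = 1``, i.e. unit within-class variance along each axis), posteriors
are Gaussian class-conditionals under the pooled covariance, and accuracy is
estimated by leave-one-out cross-validation.

Manifest clades are free text; the grouping into analysis classes (order
level vs high-level clade, sediment as its own class) is a label mapping
applied here, so analysis granularity is configuration rather than code.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.linalg

from .ordination import fit_pca, project
from .spectra import LandmarkMatrix

logger = logging.getLogger(__name__)

SEDIMENT_CLASS = "sediment"
_RIDGE = 1e-8  # stabilising ridge on the pooled covariance diagonal


@dataclass
class LDAModel:
    classes: np.ndarray            # class labels, sorted
    means: np.ndarray              # (C, d) class means in score space
    pooled_cov: np.ndarray         # (d, d)
    scalings: np.ndarray           # (d, r) discriminant axes, a' Sw a = 1
    axis_separation: np.ndarray    # (r,) between-class variance fraction per axis
    priors: np.ndarray             # (C,)
    n_pcs: int
    label_mapping: dict = field(default_factory=dict)

    @property
    def n_axes(self) -> int:
        return self.scalings.shape[1]


@dataclass
class LOOCVReport:
    accuracy: float
    confusion: pd.DataFrame        # rows = true class, columns = predicted
    per_class_recall: pd.Series
    mode: str = "pca_outside"
    n_failed_folds: int = 0


def analysis_classes(
    meta: pd.DataFrame, label_mapping: Mapping[str, str] | None = None
) -> np.ndarray:
    """Analysis class per row: sediment zones get their own class, fossil
    zones the (optionally remapped) clade label."""
    mapping = dict(label_mapping or {})
    labels = [
        SEDIMENT_CLASS if zt == "sediment" else mapping.get(clade, clade)
        for zt, clade in zip(meta["zone_type"], meta["clade"])
    ]
    return np.asarray(labels, dtype=object)


def singleton_class_mask(meta: pd.DataFrame, labels: np.ndarray) -> np.ndarray:
    """True for rows whose class is represented by a single specimen.

    Used to drop statistically unusable singleton groups (their spectra also
    leave the ordination refit that precedes the final discriminant model).
    """
    df = pd.DataFrame({"label": labels, "specimen": meta["specimen_id"].to_numpy()})
    n_spec = df.groupby("label")["specimen"].nunique()
    singletons = set(n_spec[n_spec < 2].index) - {SEDIMENT_CLASS}
    return df["label"].isin(singletons).to_numpy()


def fit_lda(
    scores: np.ndarray,
    labels: Sequence,
    priors_mode: str = "proportional",
    allow_singleton: bool = False,
    n_pcs: int | None = None,
    label_mapping: Mapping[str, str] | None = None,
) -> LDAModel:
    """Classical pooled-covariance LDA on PCA scores.

    Classes must have >= 2 rows each unless ``allow_singleton`` (needed inside
    LOOCV folds, where leaving one spectrum out can make a class a singleton).
    """
    x = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if x.ndim != 2 or x.shape[0] != y.size:
        raise ValueError("scores and labels disagree in length")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("LDA needs at least 2 classes")
    if not allow_singleton and np.any(counts < 2):
        bad = classes[counts < 2].tolist()
        raise ValueError(
            f"singleton class(es) {bad}: drop them (or pass allow_singleton=True) — "
            "a single-specimen group cannot support a discriminant model"
        )
    n, d = x.shape
    grand = x.mean(axis=0)
    means = np.vstack([x[y == c].mean(axis=0) for c in classes])
    sw = np.zeros((d, d))
    sb = np.zeros((d, d))
    for c, mu, nk in zip(classes, means, counts):
        dev = x[y == c] - mu
        sw += dev.T @ dev
        db = (mu - grand)[:, None]
        sb += nk * (db @ db.T)
    sw /= max(n - classes.size, 1)
    sb /= n
    sw_r = sw + _RIDGE * np.eye(d)
    evals, evecs = scipy.linalg.eigh(sb, sw_r)
    order = np.argsort(evals)[::-1]
    r = min(classes.size - 1, d)
    evals = np.clip(evals[order][:r], 0.0, None)
    scal = evecs[:, order][:, :r]
    # sign convention: largest-|.| entry of each axis positive
    flip = np.sign(scal[np.abs(scal).argmax(axis=0), np.arange(r)])
    flip[flip == 0] = 1.0
    scal = scal * flip
    total = evals.sum()
    separation = evals / total if total > 0 else np.full(r, 1.0 / r)
    if priors_mode == "proportional":
        priors = counts / n
    elif priors_mode == "uniform":
        priors = np.full(classes.size, 1.0 / classes.size)
    else:
        raise ValueError(f"unknown priors_mode {priors_mode!r}")
    return LDAModel(
        classes=classes,
        means=means,
        pooled_cov=sw_r,
        scalings=scal,
        axis_separation=separation,
        priors=priors,
        n_pcs=n_pcs if n_pcs is not None else d,
        label_mapping=dict(label_mapping or {}),
    )


def predict_posterior(model: LDAModel, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian class-conditional posteriors under the pooled covariance.

    Returns (posteriors (n, C), hard labels).  Posterior rows sum to 1; exact
    ties go to the first class in sort order, with a warning.
    """
    x = np.atleast_2d(np.asarray(scores, dtype=float))
    if x.shape[1] != model.means.shape[1]:
        raise ValueError(
            f"dimension mismatch: scores have {x.shape[1]} columns, model expects {model.means.shape[1]}"
        )
    cho = scipy.linalg.cho_factor(model.pooled_cov)
    log_p = np.empty((x.shape[0], model.classes.size))
    for c in range(model.classes.size):
        dev = x - model.means[c]
        maha = np.sum(dev * scipy.linalg.cho_solve(cho, dev.T).T, axis=1)
        log_p[:, c] = np.log(model.priors[c]) - 0.5 * maha
    log_p -= log_p.max(axis=1, keepdims=True)
    post = np.exp(log_p)
    post /= post.sum(axis=1, keepdims=True)
    hard_idx = post.argmax(axis=1)
    ties = (post == post.max(axis=1, keepdims=True)).sum(axis=1) > 1
    if ties.any():
        logger.warning("%d observation(s) tied between classes; first class chosen", int(ties.sum()))
    return post, model.classes[hard_idx]


def transform(model: LDAModel, scores: np.ndarray) -> np.ndarray:
    """Project score rows onto the discriminant axes (centered on the grand mean)."""
    x = np.atleast_2d(np.asarray(scores, dtype=float))
    grand = (model.priors[:, None] * model.means).sum(axis=0)
    return (x - grand) @ model.scalings


def _report(y_true: np.ndarray, y_pred: np.ndarray, classes: np.ndarray, mode: str, failed: int) -> LOOCVReport:
    extra = sorted(set(y_pred) - set(classes))  # e.g. folds that lost a class
    conf = pd.DataFrame(0, index=list(classes), columns=list(classes) + extra, dtype=int)
    for t, p in zip(y_true, y_pred):
        conf.loc[t, p] += 1
    diag = np.array([conf.at[c, c] for c in classes], dtype=float)
    accuracy = float(diag.sum()) / len(y_true)
    row_sums = conf.sum(axis=1).to_numpy(dtype=float)
    recall = pd.Series(diag / np.where(row_sums == 0, 1, row_sums), index=classes)
    return LOOCVReport(accuracy=accuracy, confusion=conf, per_class_recall=recall, mode=mode, n_failed_folds=failed)


def loocv(
    matrix,
    labels: Sequence,
    n_pcs: int = 21,
    mode: str = "pca_outside",
    priors_mode: str = "proportional",
) -> LOOCVReport:
    """Leave-one-out cross-validation of the LDA on PCA scores.

    ``matrix`` is a LandmarkMatrix or (n, p) array of landmark rows.  With
    ``mode="pca_outside"`` the PCA is computed once on all rows and only the
    LDA is refit per fold (the conventional procedure, slightly optimistic
    because the held-out row influences the ordination); ``mode="pca_inside"``
    refits the PCA within each fold as well (leakage-free).  A fold whose
    training set loses an entire class is counted as an error and logged.
    """
    if mode not in ("pca_outside", "pca_inside"):
        raise ValueError(f"unknown LOOCV mode {mode!r}")
    data = matrix.values if isinstance(matrix, LandmarkMatrix) else np.asarray(matrix, dtype=float)
    y = np.asarray(labels)
    n = data.shape[0]
    classes = np.unique(y)
    if mode == "pca_outside":
        pca = fit_pca(data)
        all_scores = pca.scores[:, :n_pcs]
    preds = np.empty(n, dtype=object)
    failed = 0
    for i in range(n):
        train = np.ones(n, dtype=bool)
        train[i] = False
        if (y[train] == y[i]).sum() == 0:
            logger.warning("LOOCV fold %d: class %r vanished from training; counted as error", i, y[i])
            preds[i] = "__missing_class__"
            failed += 1
            continue
        if mode == "pca_outside":
            x_train, x_test = all_scores[train], all_scores[i]
        else:
            fold_pca = fit_pca(data[train])
            x_train = fold_pca.scores[:, :n_pcs]
            x_test = project(fold_pca, data[i])[0, :n_pcs]
        model = fit_lda(x_train, y[train], priors_mode=priors_mode, allow_singleton=True, n_pcs=n_pcs)
        _, hard = predict_posterior(model, x_test)
        preds[i] = hard[0]
    return _report(y, preds, classes, mode, failed)
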