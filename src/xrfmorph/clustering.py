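"""Unsupervised grouping of PCA scores.

Three methods, matching standard practice for morphometric ordinations:

* k-means (total within-cluster variance, best of several k-means++ starts);
* Ward hierarchical clustering (Ward.D2 on Euclidean distances, dendrogram
  cut at the requested cluster count);
* Gaussian mixture models fitted by EM under mclust-style covariance
  constraints, with model selection by BIC (maximised, ``2 loglik - p log n``).

Covariance families, in mclust's volume/shape/orientation nomenclature:

========  ==========================================  cov parameters (d dims, k comps)
EII       spherical, shared variance                  1
EEE       one full covariance shared by all comps     d(d+1)/2
EEV       shared eigenvalues (equal volume + shape),  d(d+1)/2 + (k-1) d(d-1)/2
          free per-component orientations
VVV       unconstrained per-component covariances     k d(d+1)/2
========  ==========================================  ================================

The EEV M-step eigendecomposes each component's weighted scatter, pools the
eigenvalue spectra across components and keeps the per-component eigenvectors
— the standard estimator for that constraint.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.linalg import solve_triangular
from scipy.optimize import linear_sum_assignment
from scipy.special import logsumexp
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)

FAMILIES = ("EII", "EEE", "EEV", "VVV")
_REG = 1e-6  # diagonal regularisation added on degenerate covariances


@dataclass
class ClusterResult:
    labels: np.ndarray
    method: str
    k: int
    diagnostics: dict = field(default_factory=dict)


@dataclass
class GMMSpec:
    """A fitted constrained Gaussian mixture."""

    family: str
    k: int
    means: np.ndarray        # (k, d)
    covariances: np.ndarray  # (k, d, d)
    weights: np.ndarray      # (k,)
    loglik: float
    bic: float

    def posteriors(self, x: np.ndarray) -> np.ndarray:
        log_r = _log_resp(np.asarray(x, dtype=float), self.weights, self.means, self.covariances)[0]
        return np.exp(log_r)


def kmeans_cluster(scores: np.ndarray, k: int, n_init: int = 10, seed: int = 0) -> ClusterResult:
    """Best-of-``n_init`` k-means++ runs by total within-cluster sum of squares."""
    x = np.asarray(scores, dtype=float)
    if k > x.shape[0]:
        raise ValueError(f"k={k} exceeds the {x.shape[0]} available rows")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(x)
    return ClusterResult(labels=labels, method="kmeans", k=k, diagnostics={"inertia": float(km.inertia_)})


def ward_cluster(scores: np.ndarray, k: int) -> ClusterResult:
    """Ward.D2 agglomeration on Euclidean distances, cut at k clusters."""
    x = np.asarray(scores, dtype=float)
    if k > x.shape[0]:
        raise ValueError(f"k={k} exceeds the {x.shape[0]} available rows")
    merge = linkage(x, method="ward")
    labels = fcluster(merge, t=k, criterion="maxclust") - 1
    return ClusterResult(labels=labels, method="ward", k=k, diagnostics={"linkage": merge})


def n_free_parameters(family: str, k: int, d: int) -> int:
    """Free-parameter count of a constrained mixture (means + weights + covariances)."""
    base = k * d + (k - 1)
    cov = {
        "EII": 1,
        "EEE": d * (d + 1) // 2,
        "EEV": d * (d + 1) // 2 + (k - 1) * d * (d - 1) // 2,
        "VVV": k * d * (d + 1) // 2,
    }
    if family not in cov:
        raise ValueError(f"unknown covariance family {family!r}")
    return base + cov[family]


def _log_gaussian(x: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    d = x.shape[1]
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        chol = np.linalg.cholesky(cov + _REG * np.eye(d))
    z = solve_triangular(chol, (x - mean).T, lower=True).T
    logdet = 2.0 * np.log(np.diag(chol)).sum()
    return -0.5 * (d * np.log(2 * np.pi) + logdet + (z**2).sum(axis=1))


def _log_resp(x, weights, means, covs):
    k = len(weights)
    log_p = np.empty((x.shape[0], k))
    for g in range(k):
        log_p[:, g] = np.log(weights[g]) + _log_gaussian(x, means[g], covs[g])
    norm = logsumexp(log_p, axis=1)
    return log_p - norm[:, None], float(norm.sum())


def _m_step(x: np.ndarray, resp: np.ndarray, family: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n, d = x.shape
    k = resp.shape[1]
    nk = resp.sum(axis=0) + 1e-12
    weights = nk / n
    means = (resp.T @ x) / nk[:, None]
    scatters = np.empty((k, d, d))
    for g in range(k):
        dev = x - means[g]
        scatters[g] = (resp[:, g][:, None] * dev).T @ dev
    covs = np.empty((k, d, d))
    eye = np.eye(d)
    if family == "EII":
        sigma2 = np.trace(scatters.sum(axis=0)) / (n * d)
        covs[:] = max(sigma2, _REG) * eye
    elif family == "EEE":
        covs[:] = scatters.sum(axis=0) / n + _REG * eye
    elif family == "VVV":
        for g in range(k):
            covs[g] = scatters[g] / nk[g] + _REG * eye
    elif family == "EEV":
        # per-component eigenvectors, pooled (shared) eigenvalue spectrum
        eigvecs = np.empty((k, d, d))
        pooled = np.zeros(d)
        for g in range(k):
            vals, vecs = np.linalg.eigh(scatters[g])
            order = np.argsort(vals)[::-1]
            eigvecs[g] = vecs[:, order]
            pooled += vals[order]
        pooled = np.maximum(pooled / n, _REG)
        for g in range(k):
            covs[g] = eigvecs[g] @ np.diag(pooled) @ eigvecs[g].T
    else:
        raise ValueError(f"unknown covariance family {family!r}")
    return weights, means, covs


def fit_gmm(
    x: np.ndarray,
    k: int,
    family: str,
    seed: int = 0,
    n_init: int = 5,
    tol: float = 1e-7,
    max_iter: int = 500,
) -> GMMSpec:
    """EM fit of one (k, family) mixture; k-means initialisation, best of n_init."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("scores must be finite")
    n, d = x.shape
    best: GMMSpec | None = None
    for trial in range(n_init):
        labels = KMeans(n_clusters=k, n_init=1, random_state=seed + 1000 * trial).fit_predict(x)
        resp = np.zeros((n, k))
        resp[np.arange(n), labels] = 1.0
        loglik = -np.inf
        trace = []
        try:
            for _ in range(max_iter):
                weights, means, covs = _m_step(x, resp, family)
                log_r, new_loglik = _log_resp(x, weights, means, covs)
                resp = np.exp(log_r)
                trace.append(new_loglik)
                if new_loglik < loglik - 1e-6 * max(1.0, abs(loglik)):
                    logger.warning("EM log-likelihood decreased (%s, k=%d); regularised step", family, k)
                if abs(new_loglik - loglik) < tol * max(1.0, abs(new_loglik)):
                    loglik = new_loglik
                    break
                loglik = new_loglik
        except np.linalg.LinAlgError:
            logger.warning("EM degenerate covariance (%s, k=%d, trial %d); restart", family, k, trial)
            continue
        p = n_free_parameters(family, k, d)
        bic = 2.0 * loglik - p * np.log(n)
        spec = GMMSpec(family=family, k=k, means=means, covariances=covs, weights=weights, loglik=loglik, bic=bic)
        spec.loglik_trace = np.asarray(trace)  # type: ignore[attr-defined]
        if best is None or spec.loglik > best.loglik:
            best = spec
    if best is None:
        raise RuntimeError(f"all EM restarts failed for family {family}, k={k}")
    return best


def gmm_cluster_bic(
    scores: np.ndarray,
    k_range: Sequence[int],
    families: Sequence[str] = FAMILIES,
    seed: int = 0,
    n_init: int = 5,
    tol: float = 1e-7,
    max_iter: int = 500,
) -> tuple[ClusterResult, GMMSpec]:
    """Fit every (k, family) mixture and select the maximum-BIC model.

    Returns hard labels (argmax posterior), the full BIC table and the soft
    posteriors of the winning model.
    """
    x = np.asarray(scores, dtype=float)
    if len(k_range) == 0:
        raise ValueError("k_range is empty")
    rows = []
    best: GMMSpec | None = None
    for k in k_range:
        for family in families:
            spec = fit_gmm(x, k, family, seed=seed, n_init=n_init, tol=tol, max_iter=max_iter)
            rows.append({"k": k, "family": family, "loglik": spec.loglik,
                         "n_params": n_free_parameters(family, k, x.shape[1]), "bic": spec.bic})
            if best is None or spec.bic > best.bic:
                best = spec
    assert best is not None
    post = best.posteriors(x)
    labels = post.argmax(axis=1)
    table = pd.DataFrame(rows)
    result = ClusterResult(
        labels=labels,
        method="gmm",
        k=best.k,
        diagnostics={"bic_table": table, "posteriors": post, "family": best.family},
    )
    logger.info("GMM-BIC selected %s with k=%d (BIC=%.2f)", best.family, best.k, best.bic)
    return result, best


def match_labels(predicted: np.ndarray, truth: np.ndarray) -> tuple[dict, float]:
    """Optimal one-to-one label matching (Hungarian on the confusion matrix).

    Returns the predicted->truth label mapping and the agreement rate under it.
    """
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape:
        raise ValueError("label vectors differ in length")
    pred_levels = np.unique(predicted)
    true_levels = np.unique(truth)
    conf = np.zeros((pred_levels.size, true_levels.size))
    for i, p in enumerate(pred_levels):
        for j, t in enumerate(true_levels):
            conf[i, j] = np.sum((predicted == p) & (truth == t))
    ri, ci = linear_sum_assignment(-conf)
    mapping = {pred_levels[i]: true_levels[j] for i, j in zip(ri, ci)}
    agreement = conf[ri, ci].sum() / predicted.size
    return mapping, float(agreement)
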