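"""Principal component analysis of landmark matrices.

Covariance PCA (column centering, no per-landmark rescaling: rows are already
standardised spectra, so rescaling would distort relative peak heights).
Component signs are fixed so each loading column's largest-magnitude entry is
positive, making results deterministic bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

from .spectra import LandmarkMatrix


@dataclass(frozen=True)
class PCAResult:
    scores: np.ndarray               # (n, n_components)
    loadings: np.ndarray             # (p, n_components), orthonormal columns
    explained_variance_ratio: np.ndarray
    center: np.ndarray               # column means (p,)
    labels: tuple[str, ...] = field(default_factory=tuple)

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def cumulative_ratio(self, k: int) -> float:
        return float(self.explained_variance_ratio[:k].sum())


def _as_array(matrix) -> np.ndarray:
    if isinstance(matrix, LandmarkMatrix):
        return matrix.values
    return np.asarray(matrix, dtype=float)


def fit_pca(matrix, row_filter: np.ndarray | None = None) -> PCAResult:
    """Column-centered covariance PCA of a landmark matrix (or plain array).

    ``row_filter`` is an optional boolean/index mask applied before fitting
    (sub-ordinations such as the sediment-gradient PCA are the same operation
    with a row filter).  All min(n-1, p) components are retained; the
    explained-variance ratios therefore sum to 1.
    """
    data = _as_array(matrix)
    if row_filter is not None:
        data = data[np.asarray(row_filter)]
    if data.shape[0] < 2:
        raise ValueError("PCA needs at least 2 rows")
    pca = PCA(n_components=None, svd_solver="full")
    scores = pca.fit_transform(data)
    loadings = pca.components_.T  # (p, k)
    # sign convention: largest-|.| entry of each loading column positive
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(loadings.shape[1])])
    flip[flip == 0] = 1.0
    loadings = loadings * flip
    scores = scores * flip
    ratio = pca.explained_variance_ratio_
    labels = tuple(f"PC{i + 1}" for i in range(loadings.shape[1]))
    return PCAResult(
        scores=scores,
        loadings=loadings,
        explained_variance_ratio=ratio,
        center=pca.mean_,
        labels=labels,
    )


def project(pca: PCAResult, new_rows) -> np.ndarray:
    """Place new landmark rows in an existing ordination: (x - center) @ loadings."""
    x = np.atleast_2d(_as_array(new_rows))
    if x.shape[1] != pca.center.size:
        raise ValueError(
            f"grid mismatch: rows have {x.shape[1]} landmarks, PCA expects {pca.center.size}"
        )
    return (x - pca.center) @ pca.loadings


def landmark_contributions(pca: PCAResult, components: int) -> np.ndarray:
    """Squared loadings: contribution of each landmark to each PC (columns sum to 1)."""
    if components > pca.n_components:
        raise ValueError(f"only {pca.n_components} components available")
    return pca.loadings[:, :components] ** 2
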