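"""PCA-fed linear discriminant analysis.

The standard chemometric route for two-group Raman discrimination:

1. mean-center the processed spectra and run PCA;
2. screen the first 10 principal-component score columns with per-PC
   Welch t-tests under Benjamini-Hochberg FDR control (Q = 0.01);
3. fit Fisher's two-class linear discriminant on the selected scores,
   ``w ∝ S_w^{-1}(mu2 - mu1)``;
4. back-project the discriminant weights through the PCA loadings to get
   the LDF loading — a pseudo-spectrum whose positive bands associate with
   the second (exercised) group and negative bands with the first.

Sign conventions are fixed so fitted models are bit-reproducible: each PCA
component has its largest-magnitude loading element positive, and the LDF
direction gives the second group the higher mean score, with scores
centered on the grand mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .preprocess import SpectralMatrix

__all__ = [
    "PCAModel",
    "SelectionResult",
    "DiscriminantModel",
    "fit_pca",
    "select_components",
    "fit_lda",
    "ldf_loading",
    "fit_pipeline",
]

logger = logging.getLogger(__name__)


@dataclass
class PCAModel:
    """Mean-centered PCA basis: orthonormal loadings, scores, variance shares."""

    mean: np.ndarray                 # (p,)
    loadings: np.ndarray             # (k, p), rows orthonormal
    scores: np.ndarray               # (n, k)
    explained_variance_ratio: np.ndarray  # (k,), non-increasing


@dataclass
class SelectionResult:
    """FDR-screened choice of PC score columns for the discriminant."""

    n_candidates: int
    p_values: np.ndarray             # per candidate PC
    q: float
    selected: np.ndarray             # sorted indices into the PC axis
    fallback_used: bool = False


@dataclass
class DiscriminantModel:
    """Fitted two-class discriminant over selected PC scores."""

    selection: SelectionResult
    weights: np.ndarray              # over selected PCs, unit norm
    scores: np.ndarray               # per-acquisition LDF score, grand mean 0
    group_order: tuple[str, str]     # (reference, positive) label order
    ldf_loading: np.ndarray | None = None  # over wavenumber, once back-projected
    provenance: dict = field(default_factory=dict)


def fit_pca(matrix: SpectralMatrix | np.ndarray, n_components: int) -> PCAModel:
    """PCA of the column-centered data (leading right singular vectors)."""
    X = matrix.intensities if isinstance(matrix, SpectralMatrix) else np.asarray(matrix, float)
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least 2 rows")
    if n_components > min(n - 1, p):
        raise ValueError(
            f"n_components {n_components} too large for a {n}x{p} matrix"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_.copy()
    # deterministic sign: largest-|.| element of each loading made positive
    for k in range(loadings.shape[0]):
        j = np.argmax(np.abs(loadings[k]))
        if loadings[k, j] < 0:
            loadings[k] *= -1.0
            scores[:, k] *= -1.0
    return PCAModel(
        mean=pca.mean_,
        loadings=loadings,
        scores=scores,
        explained_variance_ratio=pca.explained_variance_ratio_,
    )


def _two_group_masks(groups: Sequence[str]) -> tuple[np.ndarray, np.ndarray, tuple[str, str]]:
    labels = list(dict.fromkeys(groups))  # appearance order
    if len(labels) != 2:
        raise ValueError(f"exactly two groups required, got {labels}")
    g = np.asarray(groups)
    m1, m2 = g == labels[0], g == labels[1]
    if not m1.any() or not m2.any():
        raise ValueError("one group empty")
    return m1, m2, (labels[0], labels[1])


def select_components(
    pca: PCAModel,
    groups: Sequence[str],
    n_candidates: int = 10,
    q: float = 0.01,
) -> SelectionResult:
    """Screen the first PCs by Welch t-test with Benjamini-Hochberg FDR.

    Selected components are the rejected hypotheses at level ``q``.  If
    nothing survives, the single smallest-p PC is kept so the pipeline can
    proceed (logged loudly).
    """
    m1, m2, _ = _two_group_masks(groups)
    k = min(n_candidates, pca.scores.shape[1])
    pvals = np.empty(k)
    for j in range(k):
        pvals[j] = sps.ttest_ind(
            pca.scores[m1, j], pca.scores[m2, j], equal_var=False
        ).pvalue
    reject, _, _, _ = multipletests(pvals, alpha=q, method="fdr_bh")
    selected = np.flatnonzero(reject)
    fallback = selected.size == 0
    if fallback:
        selected = np.array([int(np.argmin(pvals))])
        logger.warning(
            "no PC survived FDR screening at q=%g; falling back to the "
            "single smallest-p component (PC%d, p=%.3g)",
            q, selected[0] + 1, pvals[selected[0]],
        )
    return SelectionResult(k, pvals, q, selected, fallback)


def fit_lda(
    scores: np.ndarray,
    groups: Sequence[str],
    ridge: float = 0.0,
) -> DiscriminantModel:
    """Fisher's two-class discriminant on (selected) PC scores.

    ``w ∝ S_w^{-1}(mu2 - mu1)`` with the pooled within-class covariance
    ``S_w``; if ``S_w`` is numerically singular a ridge of
    ``1e-8 tr(S_w)/dim`` is added (logged).  The weight vector is unit
    norm; LDF scores are projections centered on the grand mean, with the
    second group's mean score positive by construction.
    """
    X = np.asarray(scores, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    m1, m2, order = _two_group_masks(groups)
    if m1.sum() < 2 or m2.sum() < 2:
        raise ValueError("each group needs at least 2 rows")
    X1, X2 = X[m1], X[m2]
    mu1, mu2 = X1.mean(axis=0), X2.mean(axis=0)
    n1, n2 = X1.shape[0], X2.shape[0]
    Sw = (
        (X1 - mu1).T @ (X1 - mu1) + (X2 - mu2).T @ (X2 - mu2)
    ) / (n1 + n2 - 2)
    d = Sw.shape[0]
    eff_ridge = ridge
    if eff_ridge == 0.0 and (
        d > 0 and np.linalg.cond(Sw) > 1e12
    ):
        eff_ridge = 1e-8 * np.trace(Sw) / d
        logger.warning("singular within-class covariance; adding ridge %g", eff_ridge)
    if eff_ridge:
        Sw = Sw + eff_ridge * np.eye(d)
    try:
        w = np.linalg.solve(Sw, mu2 - mu1)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular within-class covariance") from exc
    norm = np.linalg.norm(w)
    if norm == 0:
        raise ValueError("degenerate discriminant: identical group means")
    w = w / norm
    ldf = X @ w
    ldf = ldf - ldf.mean()
    return DiscriminantModel(
        selection=SelectionResult(X.shape[1], np.array([]), np.nan, np.arange(X.shape[1])),
        weights=w,
        scores=ldf,
        group_order=order,
    )


def ldf_loading(pca: PCAModel, model: DiscriminantModel) -> np.ndarray:
    """Back-project discriminant weights into wavenumber space.

    ``loading = sum_k w_k * loading_k`` over the selected components;
    positive entries associate with the second (exercised) group.
    """
    sel = model.selection.selected
    if sel.size != model.weights.size:
        raise ValueError("dimension mismatch between selection and weights")
    if sel.size and sel.max() >= pca.loadings.shape[0]:
        raise ValueError("selection refers to components the PCA model lacks")
    return model.weights @ pca.loadings[sel]


def fit_pipeline(
    matrix: SpectralMatrix,
    n_candidates: int = 10,
    q: float = 0.01,
) -> tuple[PCAModel, DiscriminantModel]:
    """Full PCA -> FDR screening -> LDA -> loading back-projection chain."""
    groups = matrix.group_labels
    n, p = matrix.intensities.shape
    n_comp = min(n - 1, p)
    pca = fit_pca(matrix, n_comp)
    selection = select_components(pca, groups, n_candidates=n_candidates, q=q)
    model = fit_lda(pca.scores[:, selection.selected], groups)
    model.selection = selection
    model.ldf_loading = ldf_loading(pca, model)
    model.provenance = {
        "n_candidates": n_candidates,
        "q": q,
        "n_components": n_comp,
        "selected_pcs": [int(i) + 1 for i in selection.selected],
        "fallback_used": bool(selection.fallback_used),
        "group_order": list(model.group_order),
    }
    return pca, model
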