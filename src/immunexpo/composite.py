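"""Composite exposures via correlation thresholding, Ward clustering and a
PLS path model.

The exposure Spearman matrix is denoised (entries with Bonferroni p >= alpha
or |r| <= threshold set to 0), exposures are Ward-clustered on the rows of
the thresholded matrix, one latent variable per cluster is extracted by an
iterative PLS path algorithm (mode A outer model, saturated inner model,
centroid scheme), and the cluster count is grown until no two latent
variables are significantly correlated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

from immunexpo.errors import DegenerateDataError


@dataclass
class ThresholdedCorrelation:
    matrix: pd.DataFrame
    threshold_r: float
    alpha_bonf: float
    zeroed: pd.DataFrame  # True where an off-diagonal entry was zeroed


@dataclass
class CompositeModel:
    k: int
    clusters: pd.Series           # exposure -> cluster label (1..k)
    outer_weights: pd.Series      # exposure -> weight within its block
    loadings: pd.Series           # exposure -> cor(exposure, its LV)
    scores: pd.DataFrame          # samples x k, standardized, columns LV1..LVk
    n_iterations: int
    final_change: float


def thresholded_spearman(exposure_table: pd.DataFrame,
                         threshold_r: float = 0.2,
                         alpha_bonf: float = 0.05) -> ThresholdedCorrelation:
    """Spearman matrix with insignificant/weak entries zeroed.

    Off-diagonal entries are set to 0 when the Bonferroni-adjusted p
    (m = p(p-1)/2 tests) is >= alpha or |r| <= threshold_r.
    """
    p = exposure_table.shape[1]
    if p < 2:
        raise DegenerateDataError("need at least 2 exposures")
    arr = exposure_table.to_numpy(float)
    rho, pval = stats.spearmanr(arr, nan_policy="omit")
    rho = np.atleast_2d(np.asarray(rho, float))
    pval = np.atleast_2d(np.asarray(pval, float))
    if rho.shape != (p, p):  # spearmanr collapses the 2-column case
        r = float(rho.ravel()[0])
        q = float(pval.ravel()[0])
        rho = np.array([[1.0, r], [r, 1.0]])
        pval = np.array([[0.0, q], [q, 0.0]])
    m = p * (p - 1) / 2.0
    p_adj = np.minimum(pval * m, 1.0)
    drop = (p_adj >= alpha_bonf) | (np.abs(rho) <= threshold_r)
    np.fill_diagonal(drop, False)
    out = rho.copy()
    out[drop] = 0.0
    np.fill_diagonal(out, 1.0)
    cols = exposure_table.columns
    return ThresholdedCorrelation(
        matrix=pd.DataFrame(out, index=cols, columns=cols),
        threshold_r=threshold_r, alpha_bonf=alpha_bonf,
        zeroed=pd.DataFrame(drop, index=cols, columns=cols))


def ward_cluster(tc: ThresholdedCorrelation, k: int) -> pd.Series:
    """Ward linkage on Euclidean distances between thresholded-matrix rows."""
    p = tc.matrix.shape[0]
    if not 2 <= k <= p:
        raise ValueError(f"k must lie in [2, {p}], got {k}")
    Z = linkage(tc.matrix.to_numpy(float), method="ward", metric="euclidean")
    labels = fcluster(Z, t=k, criterion="maxclust")
    return pd.Series(labels, index=tc.matrix.index, name="cluster")


def _standardize_cols(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise DegenerateDataError("constant exposure cannot enter the path model")
    return (X - mu) / sd


def fit_pls_path(exposure_table: pd.DataFrame, clusters: pd.Series,
                 tol: float = 1e-6, max_iter: int = 300) -> CompositeModel:
    """One latent variable per exposure cluster by iterative PLS path fitting.

    Mode A (reflective) outer estimation, saturated inner model with the
    centroid scheme. Each LV is the standardized weighted sum of its block;
    signs are canonicalized so every LV correlates positively with its
    largest-|loading| exposure.
    """
    if exposure_table.isna().to_numpy().any():
        raise DegenerateDataError("path model requires complete (imputed) exposures")
    clusters = clusters.loc[exposure_table.columns]
    labels = sorted(clusters.unique())
    X = _standardize_cols(exposure_table.to_numpy(float))
    n = X.shape[0]
    blocks = {lab: np.flatnonzero((clusters == lab).to_numpy()) for lab in labels}
    if any(idx.size == 0 for idx in blocks.values()):
        raise DegenerateDataError("empty cluster")

    # initialize at each block's first right singular vector: this is already
    # the fixed point for a block with no significant cross-LV correlation,
    # and it resolves PC1 eigenvalue ties deterministically
    weights = {}
    for lab, idx in blocks.items():
        _, _, vt = np.linalg.svd(X[:, idx], full_matrices=False)
        weights[lab] = vt[0]
    scores = np.empty((n, len(labels)))

    def block_scores() -> np.ndarray:
        for j, lab in enumerate(labels):
            s = X[:, blocks[lab]] @ weights[lab]
            sd = s.std(ddof=1)
            if sd == 0:
                raise DegenerateDataError(f"degenerate block {lab}")
            scores[:, j] = (s - s.mean()) / sd
        return scores

    block_scores()
    change = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        corr = np.corrcoef(scores, rowvar=False)
        corr = np.atleast_2d(corr)
        new_weights = {}
        for j, lab in enumerate(labels):
            # centroid scheme over the saturated inner model, with the
            # block's own score included so an uncorrelated block reduces
            # to first-principal-component extraction instead of chasing
            # cross-block noise; correlations within sampling noise of zero
            # get sign 0 so the sign pattern cannot oscillate
            e = np.where(np.abs(corr[j]) > 2.0 / np.sqrt(n),
                         np.sign(corr[j]), 0.0)
            e[j] = 1.0
            z = scores @ e
            z = (z - z.mean()) / z.std(ddof=1)
            w = X[:, blocks[lab]].T @ z / (n - 1)  # mode A: cov(indicator, inner proxy)
            nrm = np.linalg.norm(w)
            if nrm == 0:
                raise DegenerateDataError(f"zero outer weights in block {lab}")
            new_weights[lab] = w / nrm
        change = max(np.max(np.abs(np.abs(new_weights[lab]) - np.abs(weights[lab])))
                     for lab in labels)
        weights = new_weights
        block_scores()
        if change < tol:
            break
    else:
        raise DegenerateDataError(
            f"PLS path model did not converge in {max_iter} iterations "
            f"(last change {change:.2e})")

    # sign convention: LV correlates positively with its top-|loading| indicator
    w_ser = pd.Series(0.0, index=exposure_table.columns)
    load_ser = pd.Series(0.0, index=exposure_table.columns)
    for j, lab in enumerate(labels):
        idx = blocks[lab]
        lv = scores[:, j]
        loads = np.array([np.corrcoef(X[:, i], lv)[0, 1] for i in idx])
        top = int(np.argmax(np.abs(loads)))
        if loads[top] < 0:
            scores[:, j] = -lv
            weights[lab] = -weights[lab]
            loads = -loads
        w_ser.iloc[idx] = weights[lab]
        load_ser.iloc[idx] = loads
    score_df = pd.DataFrame(scores, index=exposure_table.index,
                            columns=[f"LV{j + 1}" for j in range(len(labels))])
    return CompositeModel(k=len(labels), clusters=clusters,
                          outer_weights=w_ser, loadings=load_ser,
                          scores=score_df, n_iterations=it,
                          final_change=float(change))


def lv_correlation_significant(scores: pd.DataFrame, alpha: float = 0.05) -> bool:
    """Any Spearman LV-pair correlation significant at Bonferroni alpha?"""
    k = scores.shape[1]
    if k < 2:
        return False
    m = k * (k - 1) / 2.0
    for i in range(k):
        for j in range(i + 1, k):
            _, p = stats.spearmanr(scores.iloc[:, i], scores.iloc[:, j])
            if p * m < alpha:
                return True
    return False


def select_cluster_count(exposure_table: pd.DataFrame, k_start: int = 2,
                         threshold_r: float = 0.2, alpha_bonf: float = 0.05,
                         lv_alpha: float = 0.05) -> tuple[int, CompositeModel]:
    """Grow k from ``k_start`` until no LV pair is significantly correlated."""
    tc = thresholded_spearman(exposure_table, threshold_r, alpha_bonf)
    p = exposure_table.shape[1]
    for k in range(k_start, p + 1):
        clusters = ward_cluster(tc, k)
        model = fit_pls_path(exposure_table, clusters)
        if not lv_correlation_significant(model.scores, lv_alpha):
            return k, model
    raise DegenerateDataError(
        "no cluster count up to the number of exposures yields uncorrelated "
        "latent variables; consider revising the correlation threshold")


def composite_ewas(model: CompositeModel, phenotypes: pd.DataFrame,
                   covariates: pd.DataFrame | None, **kwargs) -> pd.DataFrame:
    """Associate LV scores with phenotypes via the standard EWAS machinery."""
    from immunexpo.ewas import run_ewas
    if model.scores.shape[1] == 0:
        return pd.DataFrame()
    return run_ewas(phenotypes, model.scores, covariates, **kwargs)
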