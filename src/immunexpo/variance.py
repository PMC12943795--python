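"""Distance-matrix variance decomposition of the immunome (PERMANOVA).

Single-factor and sequential multi-factor permutational MANOVA on a
Euclidean distance matrix, permutation p-values with the +1 correction,
BH-FDR screening of exposures and |Spearman r| redundancy pruning.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations as iter_permutations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from immunexpo.errors import AlignmentError, DegenerateDataError
from immunexpo.stats_util import bh_adjust


@dataclass
class VarianceComponent:
    factor: str
    r2: float
    pseudo_f: float
    permutation_p: float
    df: int
    n_permutations: int
    fdr: float = np.nan


def euclidean_distance(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Euclidean distance matrix; requires complete data."""
    if matrix.isna().to_numpy().any():
        raise DegenerateDataError("distance matrix requires complete data")
    d = squareform(pdist(matrix.to_numpy(float), metric="euclidean"))
    return pd.DataFrame(d, index=matrix.index, columns=matrix.index)


def residualize_covariates(matrix: pd.DataFrame,
                           covariates: pd.DataFrame | None) -> pd.DataFrame:
    """Per-feature residuals from OLS on the covariate design (plus intercept).

    With no covariates this centers each feature.
    """
    y = matrix.to_numpy(float)
    n = y.shape[0]
    if covariates is None or covariates.shape[1] == 0:
        return matrix - matrix.mean()
    if not matrix.index.equals(covariates.index):
        raise AlignmentError("covariate rows do not align with the feature matrix")
    X = np.column_stack([np.ones(n), covariates.to_numpy(float)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return pd.DataFrame(y - X @ beta, index=matrix.index, columns=matrix.columns)


def _gower_center(dist: np.ndarray) -> np.ndarray:
    a = -0.5 * dist ** 2
    n = a.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def _term_matrix(values: pd.Series) -> np.ndarray:
    v = values
    if v.dtype == object or isinstance(v.dtype, pd.CategoricalDtype):
        dummies = pd.get_dummies(v, drop_first=True)
        if dummies.shape[1] == 0:
            raise DegenerateDataError(f"factor {v.name!r} is constant")
        return dummies.to_numpy(float)
    arr = v.to_numpy(float)
    if np.ptp(arr) == 0:
        raise DegenerateDataError(f"factor {v.name!r} is constant")
    return arr[:, None]


def _hat(X: np.ndarray) -> tuple[np.ndarray, int]:
    q, r = np.linalg.qr(X)
    rank = int(np.sum(np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(r).max())))
    q = q[:, :rank]
    return q @ q.T, rank


def permanova(dist: pd.DataFrame, design: pd.DataFrame,
              n_perm: int = 1000, seed: int | None = 0,
              permutations: str = "random") -> list[VarianceComponent]:
    """Sequential PERMANOVA of a distance matrix on the design's factors.

    Terms enter in column order (sequential sums of squares); the returned
    list carries one component per term plus a ``Residual`` row, with
    R^2 = SS_term/SS_total and permutation p = (1 + #{F* >= F})/(1 + n_perm)
    under free row permutation. ``permutations="exact"`` enumerates all n!
    label permutations (n <= 9) and reports the exhaustive p
    (#{F* >= F}/n!, identity included).
    """
    if not dist.index.equals(design.index):
        raise AlignmentError("design rows do not align with the distance matrix")
    d = dist.to_numpy(float)
    if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0.0):
        raise DegenerateDataError("not a valid distance matrix")
    n = d.shape[0]
    g = _gower_center(d)
    ss_total = float(np.trace(g))

    terms = list(design.columns)
    hats, dfs = [], []
    X = np.ones((n, 1))
    prev_rank = 1
    prev_hat, _ = _hat(X)
    for t in terms:
        X = np.column_stack([X, _term_matrix(design[t])])
        h, rank = _hat(X)
        hats.append((prev_hat, h))
        dfs.append(rank - prev_rank)
        prev_hat, prev_rank = h, rank
    h_full = prev_hat
    df_res = n - prev_rank
    if df_res <= 0:
        raise DegenerateDataError("saturated design: no residual degrees of freedom")
    resid_proj = np.eye(n) - h_full

    def term_stats(gm: np.ndarray) -> tuple[np.ndarray, float]:
        ss_res = float(np.sum(resid_proj * gm))
        f = np.empty(len(terms))
        for j, (h0, h1) in enumerate(hats):
            ss_j = float(np.sum((h1 - h0) * gm))
            f[j] = (ss_j / dfs[j]) / (ss_res / df_res)
        return f, ss_res

    f_obs, ss_res = term_stats(g)
    ss_terms = [float(np.sum((h1 - h0) * g)) for h0, h1 in hats]

    if permutations == "exact":
        if n > 9:
            raise DegenerateDataError("exact permutations limited to n <= 9")
        perms = list(iter_permutations(range(n)))
        exceed = np.zeros(len(terms))
        for p in perms:
            idx = np.asarray(p)
            f_p, _ = term_stats(g[np.ix_(idx, idx)])
            exceed += f_p >= f_obs - 1e-12
        pvals = exceed / len(perms)
        n_used = len(perms)
    else:
        rng = np.random.default_rng(seed)
        exceed = np.zeros(len(terms))
        for _ in range(n_perm):
            idx = rng.permutation(n)
            f_p, _ = term_stats(g[np.ix_(idx, idx)])
            exceed += f_p >= f_obs - 1e-12
        pvals = (1.0 + exceed) / (1.0 + n_perm)
        n_used = n_perm

    out = [VarianceComponent(factor=t, r2=ss_terms[j] / ss_total,
                             pseudo_f=float(f_obs[j]),
                             permutation_p=float(pvals[j]),
                             df=dfs[j], n_permutations=n_used)
           for j, t in enumerate(terms)]
    out.append(VarianceComponent(factor="Residual", r2=ss_res / ss_total,
                                 pseudo_f=np.nan, permutation_p=np.nan,
                                 df=df_res, n_permutations=n_used))
    return out


def single_factor_scan(dist: pd.DataFrame, factors: pd.DataFrame,
                       n_perm: int = 1000, seed: int = 0) -> list[VarianceComponent]:
    """One single-term PERMANOVA per factor column, BH-FDR across factors."""
    comps = []
    for j, col in enumerate(factors.columns):
        res = permanova(dist, factors[[col]], n_perm=n_perm,
                        seed=None if seed is None else seed + j)
        comps.append(res[0])
    fdrs = bh_adjust(np.array([c.permutation_p for c in comps]))
    for c, f in zip(comps, fdrs):
        c.fdr = float(f)
    return comps


def screen_and_prune(components: list[VarianceComponent],
                     exposure_table: pd.DataFrame,
                     fdr_cut: float = 0.05, r_cut: float = 0.4) -> list[str]:
    """FDR-screen exposures then collapse correlated groups.

    BH-FDR over permutation p-values; among survivors, exposures linked by
    |Spearman r| > r_cut form connected components, and only the component
    member with the largest R^2 is retained.
    """
    comps = [c for c in components if c.factor in exposure_table.columns]
    pvals = np.array([c.permutation_p for c in comps])
    if pvals.size == 0:
        return []
    fdrs = bh_adjust(pvals)
    for c, f in zip(comps, fdrs):
        c.fdr = float(f)
    survivors = [c for c in comps if c.fdr < fdr_cut]
    if not survivors:
        return []
    names = [c.factor for c in survivors]
    sub = exposure_table[names]
    rho = stats.spearmanr(sub.to_numpy(float), nan_policy="omit")[0]
    rho = np.atleast_2d(rho)
    if rho.shape != (len(names), len(names)):  # two-column spearmanr returns scalar
        r = float(rho.ravel()[0])
        rho = np.array([[1.0, r], [r, 1.0]])

    parent = list(range(len(names)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if abs(rho[i, j]) > r_cut:
                parent[find(i)] = find(j)

    best: dict[int, VarianceComponent] = {}
    for i, c in enumerate(survivors):
        root = find(i)
        if root not in best or c.r2 > best[root].r2:
            best[root] = c
    return sorted((c.factor for c in best.values()),
                  key=lambda f: names.index(f))


def components_table(components: list[VarianceComponent]) -> pd.DataFrame:
    return pd.DataFrame([{
        "factor": c.factor, "R2": c.r2, "pseudo_F": c.pseudo_f,
        "permutation_p": c.permutation_p, "FDR": c.fdr, "df": c.df,
        "n_permutations": c.n_permutations,
    } for c in components]).set_index("factor")
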