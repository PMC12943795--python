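"""Exposure-wide association of exposures with immunophenotypes.

Covariate-adjusted linear models (coefficient t-test and likelihood-ratio
test against the covariate-only null), Benjamini-Hochberg FDR across all
pairs, gender/age stratification, subsample-stability checks, sensitivity
covariate sets, age/gender/season basic-factor tests, and 12-month cosinor
fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from immunexpo.errors import AlignmentError, DegenerateDataError
from immunexpo.stats_util import bh_adjust, floor_p

DEFAULT_COVARIATES = ("age", "gender", "season")


@dataclass
class AssociationResult:
    exposure: str
    phenotype: str
    coefficient: float
    se: float
    t_p: float
    lrt_p: float
    n_used: int
    fdr_coef: float = np.nan
    fdr_lrt: float = np.nan
    stratum: str | None = None


@dataclass
class CosinorFit:
    mesor: float
    amplitude: float
    phase: float  # peak month in [0, 12)
    rhythm_p: float
    period: float = 12.0


def covariate_design(covariates: pd.DataFrame,
                     terms=DEFAULT_COVARIATES,
                     season_coding: str = "month") -> pd.DataFrame:
    """Numeric design columns for the requested covariate terms.

    ``season`` expands the ``month`` column per ``season_coding``:
    ``month`` (11 dummies, default), ``quarter`` (3 dummies) or
    ``harmonic`` (cos/sin pair).
    """
    cols = {}
    for term in terms:
        if term == "season":
            m = covariates["month"].astype(int)
            if season_coding == "month":
                d = pd.get_dummies(m, prefix="month", drop_first=True)
                cols.update({c: d[c].to_numpy(float) for c in d.columns})
            elif season_coding == "quarter":
                q = ((m - 1) // 3 + 1)
                d = pd.get_dummies(q, prefix="quarter", drop_first=True)
                cols.update({c: d[c].to_numpy(float) for c in d.columns})
            elif season_coding == "harmonic":
                cols["season_cos"] = np.cos(2 * np.pi * m / 12.0)
                cols["season_sin"] = np.sin(2 * np.pi * m / 12.0)
            else:
                raise ValueError(f"unknown season coding {season_coding!r}")
        else:
            cols[term] = covariates[term].to_numpy(float)
    return pd.DataFrame(cols, index=covariates.index)


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    r = np.linalg.qr(X, mode="r")
    diag = np.abs(np.diag(r))
    bad = diag < 1e-9 * max(1.0, diag.max())
    if bad.any():
        cols = [names[i] for i in np.flatnonzero(bad)]
        raise DegenerateDataError(f"rank-deficient design; collinear columns: {cols}")


def fit_association(y, x, covariates: pd.DataFrame | None,
                    exposure: str = "exposure", phenotype: str = "phenotype",
                    stratum: str | None = None) -> AssociationResult:
    """OLS of phenotype on exposure plus covariates, listwise deletion.

    Reports the exposure coefficient with its t-test p and the LRT p of the
    full model against the covariate-only null (chi-square, 1 df).
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    C = (covariates.to_numpy(float) if covariates is not None
         else np.empty((y.size, 0)))
    cov_names = list(covariates.columns) if covariates is not None else []
    keep = ~(np.isnan(y) | np.isnan(x) | np.isnan(C).any(axis=1))
    y, x, C = y[keep], x[keep], C[keep]
    n = y.size
    p_full = C.shape[1] + 2
    if n < p_full + 10:
        raise DegenerateDataError(f"too few complete cases (n={n}) for {p_full} predictors")
    X_full = np.column_stack([np.ones(n), x, C])
    _check_rank(X_full, ["intercept", exposure] + cov_names)
    beta, _, _, _ = np.linalg.lstsq(X_full, y, rcond=None)
    resid = y - X_full @ beta
    rss_full = float(resid @ resid)
    df = n - p_full
    xtx_inv = np.linalg.inv(X_full.T @ X_full)
    se = float(np.sqrt(rss_full / df * xtx_inv[1, 1]))
    t_p = 2.0 * stats.t.sf(abs(beta[1] / se), df) if se > 0 else 0.0

    X_null = np.column_stack([np.ones(n), C])
    b0, _, _, _ = np.linalg.lstsq(X_null, y, rcond=None)
    r0 = y - X_null @ b0
    rss_null = float(r0 @ r0)
    lrt = n * np.log(max(rss_null, 1e-300) / max(rss_full, 1e-300))
    lrt_p = stats.chi2.sf(max(lrt, 0.0), df=1)
    return AssociationResult(
        exposure=exposure, phenotype=phenotype,
        coefficient=float(beta[1]), se=se,
        t_p=float(floor_p(t_p)), lrt_p=float(floor_p(lrt_p)),
        n_used=n, stratum=stratum)


def _residualize(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return Y - X @ beta


def _run_ewas_fast(P: np.ndarray, E: np.ndarray, C: np.ndarray,
                   pheno_names, expo_names) -> pd.DataFrame:
    """Complete-data EWAS via Frisch-Waugh-Lovell; exact OLS equivalence."""
    n = P.shape[0]
    X = np.column_stack([np.ones(n), C])
    q = X.shape[1]
    Pt = _residualize(P, X)
    Et = _residualize(E, X)
    see = (Et ** 2).sum(axis=0)
    syy = (Pt ** 2).sum(axis=0)
    if np.any(see <= 0):
        bad = expo_names[int(np.argmin(see))]
        raise DegenerateDataError(f"exposure {bad!r} collinear with covariates")
    cross = Et.T @ Pt  # E x P
    beta = cross / see[:, None]
    rss_full = np.maximum(syy[None, :] - cross ** 2 / see[:, None], 1e-300)
    df = n - q - 1
    se = np.sqrt(rss_full / df / see[:, None])
    tstat = np.abs(beta / se)
    t_p = floor_p(2.0 * stats.t.sf(tstat, df))
    lrt = n * np.log(np.maximum(syy[None, :], 1e-300) / rss_full)
    lrt_p = floor_p(stats.chi2.sf(np.maximum(lrt, 0.0), df=1))
    ei, pi = np.meshgrid(np.arange(len(expo_names)), np.arange(len(pheno_names)),
                         indexing="ij")
    return pd.DataFrame({
        "exposure": np.asarray(expo_names)[ei.ravel()],
        "phenotype": np.asarray(pheno_names)[pi.ravel()],
        "coefficient": beta.ravel(),
        "se": se.ravel(),
        "t_p": t_p.ravel(),
        "lrt_p": lrt_p.ravel(),
        "n_used": n,
    })


def run_ewas(phenotypes: pd.DataFrame, exposures: pd.DataFrame,
             covariates: pd.DataFrame | None,
             covariate_terms=DEFAULT_COVARIATES,
             season_coding: str = "month",
             fdr_threshold: float = 0.05,
             stratum: str | None = None) -> pd.DataFrame:
    """Fit every exposure x phenotype pair and BH-adjust across all pairs.

    The coefficient-p FDR is the significance standard (``significant`` =
    fdr_coef < threshold); the LRT FDR is reported alongside.
    """
    if exposures.shape[1] == 0 or phenotypes.shape[1] == 0:
        return pd.DataFrame(columns=["exposure", "phenotype", "coefficient",
                                     "se", "t_p", "lrt_p", "n_used",
                                     "fdr_coef", "fdr_lrt", "significant"])
    if not phenotypes.index.equals(exposures.index):
        raise AlignmentError("phenotype and exposure sample IDs do not align")
    design = None
    if covariates is not None:
        if not phenotypes.index.equals(covariates.index):
            raise AlignmentError("covariate sample IDs do not align")
        design = covariate_design(covariates, covariate_terms, season_coding)

    complete = (not phenotypes.isna().to_numpy().any()
                and not exposures.isna().to_numpy().any()
                and (design is None or not design.isna().to_numpy().any()))
    if complete:
        table = _run_ewas_fast(
            phenotypes.to_numpy(float), exposures.to_numpy(float),
            design.to_numpy(float) if design is not None
            else np.empty((len(phenotypes), 0)),
            list(phenotypes.columns), list(exposures.columns))
    else:
        rows = []
        for e in exposures.columns:
            for p in phenotypes.columns:
                r = fit_association(phenotypes[p], exposures[e], design,
                                    exposure=e, phenotype=p)
                rows.append(vars(r))
        table = pd.DataFrame(rows).drop(columns=["fdr_coef", "fdr_lrt", "stratum"])
    table["fdr_coef"] = bh_adjust(table["t_p"].to_numpy())
    table["fdr_lrt"] = bh_adjust(table["lrt_p"].to_numpy())
    table["significant"] = table["fdr_coef"] < fdr_threshold
    if stratum is not None:
        table["stratum"] = stratum
    return table


def stratified_ewas(phenotypes: pd.DataFrame, exposures: pd.DataFrame,
                    covariates: pd.DataFrame, strata: str,
                    min_stratum_n: int = 30, **kwargs) -> pd.DataFrame:
    """Per-stratum EWAS for gender (male/female) or age (<40 / >=40).

    The stratification variable is dropped from the covariate set for
    gender strata (it is constant within a stratum). Strata with fewer
    than ``min_stratum_n`` samples are skipped with a warning.
    """
    if strata == "gender":
        groups = {"male": covariates["gender"] == 1,
                  "female": covariates["gender"] == 0}
        terms = tuple(t for t in DEFAULT_COVARIATES if t != "gender")
    elif strata == "age":
        groups = {"age_lt40": covariates["age"] < 40,
                  "age_ge40": covariates["age"] >= 40}
        terms = DEFAULT_COVARIATES
    else:
        raise ValueError(f"unknown stratification {strata!r}")
    tables = []
    for label, mask in groups.items():
        if int(mask.sum()) < min_stratum_n:
            warnings.warn(f"stratum {label!r} has n={int(mask.sum())} < "
                          f"{min_stratum_n}; skipped", stacklevel=2)
            continue
        tables.append(run_ewas(phenotypes[mask.to_numpy()],
                               exposures[mask.to_numpy()],
                               covariates[mask.to_numpy()],
                               covariate_terms=terms, stratum=label, **kwargs))
    if not tables:
        return pd.DataFrame()
    return pd.concat(tables, ignore_index=True)


def resample_stability(y, x, covariates: pd.DataFrame | None,
                       fraction: float = 0.9, n_iter: int = 100,
                       seed: int = 0, alpha: float = 0.05) -> dict:
    """Subsample (without replacement) stability of one association."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    y = np.asarray(y, dtype=float)
    n = y.size
    rng = np.random.default_rng(seed)
    m = int(round(fraction * n))
    n_sig, pvals, coefs = 0, [], []
    for _ in range(n_iter):
        idx = rng.choice(n, size=m, replace=False)
        sub_cov = covariates.iloc[idx] if covariates is not None else None
        r = fit_association(y[idx], np.asarray(x, float)[idx], sub_cov)
        pvals.append(r.t_p)
        coefs.append(r.coefficient)
        n_sig += r.t_p < alpha
    return {"fraction": fraction, "n_iter": n_iter,
            "n_significant": int(n_sig),
            "mean_p": float(np.mean(pvals)),
            "mean_coefficient": float(np.mean(coefs))}


def sensitivity_adjust(y, x, covariates: pd.DataFrame,
                       extra: pd.DataFrame | None = None,
                       genetic_pcs: pd.DataFrame | None = None,
                       pc_alpha: float = 0.05,
                       covariate_terms=DEFAULT_COVARIATES,
                       season_coding: str = "month") -> AssociationResult:
    """Refit one association with extra covariates.

    ``genetic_pcs`` are first screened: only PCs associated with the
    phenotype (per-PC regression p < ``pc_alpha``) enter the adjustment.
    """
    design = covariate_design(covariates, covariate_terms, season_coding)
    blocks = [design]
    if extra is not None and extra.shape[1] > 0:
        blocks.append(extra.astype(float))
    if genetic_pcs is not None and genetic_pcs.shape[1] > 0:
        selected = []
        for pc in genetic_pcs.columns:
            r = fit_association(y, genetic_pcs[pc], None)
            if r.t_p < pc_alpha:
                selected.append(pc)
        if selected:
            blocks.append(genetic_pcs[selected].astype(float))
    full = pd.concat(blocks, axis=1)
    return fit_association(y, x, full)


def basic_factor_tests(phenotypes: pd.DataFrame,
                       covariates: pd.DataFrame,
                       season_coding: str = "month") -> pd.DataFrame:
    """Age (Spearman) and gender (Welch t) tests per phenotype, BH-adjusted.

    Each test residualizes the phenotype on the other two basic factors
    first. The gender comparison is between disjoint male/female groups, so
    it is a two-sample (Welch) t test.
    """
    rows = []
    gender = covariates["gender"].to_numpy(float)
    age = covariates["age"].to_numpy(float)
    for col in phenotypes.columns:
        y = phenotypes[col].to_numpy(float)
        if np.nanstd(y) == 0:
            raise DegenerateDataError(f"phenotype {col!r} is constant")
        obs = ~np.isnan(y)
        d_g = covariate_design(covariates[obs], ("gender", "season"), season_coding)
        X = np.column_stack([np.ones(obs.sum()), d_g.to_numpy(float)])
        y_age = _residualize(y[obs, None], X).ravel()
        rho, p_age = stats.spearmanr(age[obs], y_age)
        d_a = covariate_design(covariates[obs], ("age", "season"), season_coding)
        Xa = np.column_stack([np.ones(obs.sum()), d_a.to_numpy(float)])
        y_gen = _residualize(y[obs, None], Xa).ravel()
        g = gender[obs]
        t, p_gen = stats.ttest_ind(y_gen[g == 1], y_gen[g == 0], equal_var=False)
        rows.append({"phenotype": col, "age_rho": float(rho),
                     "age_p": float(floor_p(p_age)), "gender_t": float(t),
                     "gender_p": float(floor_p(p_gen))})
    out = pd.DataFrame(rows).set_index("phenotype")
    out["age_fdr"] = bh_adjust(out["age_p"].to_numpy())
    out["gender_fdr"] = bh_adjust(out["gender_p"].to_numpy())
    return out


def cosinor_fit(y, month) -> CosinorFit:
    """12-month cosinor on the min-max normalized phenotype.

    Fits y = k + b1*cos(2*pi*t/12) + b2*sin(2*pi*t/12) on the normalized
    values; amplitude is sqrt(b1^2+b2^2), phase the peak month in [0, 12),
    and rhythm_p the F-test of b1 = b2 = 0. Mesor and amplitude are mapped
    back to the input scale before returning.
    """
    y = np.asarray(y, dtype=float)
    t = np.asarray(month, dtype=float)
    obs = ~(np.isnan(y) | np.isnan(t))
    y, t = y[obs], t[obs]
    if np.unique(t).size < 3:
        raise DegenerateDataError("cosinor requires >= 3 distinct months")
    rng_y = np.ptp(y)
    if rng_y == 0:
        ynorm = np.zeros_like(y)
    else:
        ynorm = (y - y.min()) / rng_y
    w = 2.0 * np.pi * t / 12.0
    X = np.column_stack([np.ones(y.size), np.cos(w), np.sin(w)])
    beta, *_ = np.linalg.lstsq(X, ynorm, rcond=None)
    resid = ynorm - X @ beta
    rss = float(resid @ resid)
    rss0 = float(np.sum((ynorm - ynorm.mean()) ** 2))
    df2 = y.size - 3
    if rss <= 1e-30:
        p = 0.0
    else:
        f = ((rss0 - rss) / 2.0) / (rss / df2)
        p = float(stats.f.sf(max(f, 0.0), 2, df2))
    scale = rng_y if rng_y > 0 else 1.0
    amp = float(np.hypot(beta[1], beta[2]) * scale)
    phase = float((12.0 / (2.0 * np.pi)) * np.arctan2(beta[2], beta[1]) % 12.0)
    return CosinorFit(mesor=float(beta[0] * scale + y.min()), amplitude=amp,
                      phase=phase, rhythm_p=float(floor_p(p)))


def meq_stratify(meq_scores) -> np.ndarray:
    """Chronotype labels from MEQ score: <=41 evening, >=59 morning, else middle."""
    s = np.asarray(meq_scores, dtype=float)
    out = np.where(s <= 41, "evening", np.where(s >= 59, "morning", "middle"))
    return np.where(np.isnan(s), "NA", out)
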