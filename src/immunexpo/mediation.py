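"""Bidirectional causal mediation for (exposure, omic, immunophenotype) triples.

Two OLS models per direction -- mediator ~ exposure and
outcome ~ exposure + mediator + exposure:mediator (variables centered, so
the mediator and exposure slopes are average-level effects) -- with
ACME = beta1*beta2, ADE = gamma1, total = ADE + ACME, mediation proportion
ACME/total, nonparametric row-resampling bootstrap percentile CIs, and the
D1/D2 classification rule (direction assigned when its FDR < 0.05 and its
|proportion| exceeds the other direction's).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from immunexpo.errors import DegenerateDataError
from immunexpo.stats_util import bh_adjust

D1 = "D1"
D2 = "D2"
NONE = "none"


@dataclass
class MediationFit:
    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    gamma1: float
    delta2: float
    resid_sd1: float
    resid_sd2: float
    acme: float
    ade: float
    total: float
    proportion: float           # capped to [-1, 1] when |total| < |ACME|
    proportion_uncapped: float
    ci_low: float
    ci_high: float
    boot_p: float
    n_boot: int


def _center(v: np.ndarray, name: str) -> np.ndarray:
    sd = v.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise DegenerateDataError(f"variable {name!r} has degenerate variance")
    return v - v.mean()


def _ols_pair(x: np.ndarray, m: np.ndarray, y: np.ndarray):
    """Point estimates of the two mediation models on one sample."""
    n = x.size
    Xm = np.column_stack([np.ones(n), x])
    bm, *_ = np.linalg.lstsq(Xm, m, rcond=None)
    r1 = m - Xm @ bm
    Xy = np.column_stack([np.ones(n), x, m, x * m])
    by, *_ = np.linalg.lstsq(Xy, y, rcond=None)
    r2 = y - Xy @ by
    return bm, by, float(r1.std(ddof=1)), float(r2.std(ddof=1))


def mediation_proportion(acme: float, total: float) -> tuple[float, float]:
    """(capped, uncapped) ACME/total; capped to [-1, 1] for unstable ratios."""
    if total == 0:
        return np.nan, np.nan
    raw = acme / total
    return float(np.clip(raw, -1.0, 1.0)), float(raw)


def fit_mediation(x, m, y, n_boot: int = 1000, seed: int | None = 0) -> MediationFit:
    """Fit both mediation models and bootstrap the ACME.

    Inputs are centered internally (slopes stay on the input scale, and the
    mediator/exposure slopes are average-level effects in the presence of
    the interaction term). The bootstrap resamples complete
    rows, refits both models, and reports the percentile 95% CI plus the
    two-sided sign-crossing p-value, floored at 1/n_boot. The point
    estimates do not depend on the bootstrap seed.
    """
    x = np.asarray(x, dtype=float)
    m = np.asarray(m, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(m) | np.isnan(y))
    x, m, y = x[keep], m[keep], y[keep]
    n = x.size
    if n < 50:
        raise DegenerateDataError(f"need >= 50 complete triples, got {n}")
    if n_boot < 100:
        warnings.warn(f"n_boot={n_boot} < 100: bootstrap CI will be unstable",
                      stacklevel=2)
    x = _center(x, "x")
    m = _center(m, "m")
    y = _center(y, "y")

    bm, by, sd1, sd2 = _ols_pair(x, m, y)
    beta1 = float(bm[1])
    gamma1, beta2, delta2 = float(by[1]), float(by[2]), float(by[3])
    acme = beta1 * beta2
    ade = gamma1
    total = ade + acme
    prop, prop_raw = mediation_proportion(acme, total)

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    # both models only need 12 resampled moment sums; gathering precomputed
    # product vectors is far cheaper than materializing the design per draw
    xm = x * m
    moments = np.column_stack([
        x, m, xm, x * x, x * xm, m * m, m * xm, xm * xm,
        y, x * y, m * y, xm * y])
    S = np.empty((n_boot, moments.shape[1]))
    for j in range(moments.shape[1]):  # column-wise keeps the gather small
        S[:, j] = moments[:, j][idx].sum(axis=1)
    (sx, sm, sxm, sxx, sxxm, smm, smxm, sxmxm,
     sy, sxy, smy, sxmy) = S.T
    beta1_b = (sxm - sx * sm / n) / (sxx - sx * sx / n)
    XtX = np.empty((n_boot, 4, 4))
    XtX[:, 0, 0] = n
    XtX[:, 0, 1] = XtX[:, 1, 0] = sx
    XtX[:, 0, 2] = XtX[:, 2, 0] = sm
    XtX[:, 0, 3] = XtX[:, 3, 0] = sxm
    XtX[:, 1, 1] = sxx
    XtX[:, 1, 2] = XtX[:, 2, 1] = sxm
    XtX[:, 1, 3] = XtX[:, 3, 1] = sxxm
    XtX[:, 2, 2] = smm
    XtX[:, 2, 3] = XtX[:, 3, 2] = smxm
    XtX[:, 3, 3] = sxmxm
    Xty = np.stack([sy, sxy, smy, sxmy], axis=1)
    coef = np.linalg.solve(XtX, Xty[..., None])[..., 0]
    acme_b = beta1_b * coef[:, 2]

    ci_low, ci_high = np.percentile(acme_b, [2.5, 97.5])
    p = 2.0 * min(float(np.mean(acme_b <= 0)), float(np.mean(acme_b >= 0)))
    p = float(np.clip(p, 1.0 / n_boot, 1.0))
    return MediationFit(
        alpha1=float(bm[0]), beta1=beta1, alpha2=float(by[0]), beta2=beta2,
        gamma1=gamma1, delta2=delta2, resid_sd1=sd1, resid_sd2=sd2,
        acme=acme, ade=ade, total=total,
        proportion=prop, proportion_uncapped=prop_raw,
        ci_low=float(ci_low), ci_high=float(ci_high),
        boot_p=p, n_boot=n_boot)


def screen_candidates(exposure, phenotype, omics_matrix: pd.DataFrame,
                      fdr_threshold: float = 0.05) -> list[str]:
    """Omics passing BH-FDR < threshold for Spearman correlation with both
    the exposure and the phenotype (FDR computed across all omics per screen).
    """
    if omics_matrix.shape[1] == 0:
        return []
    x = np.asarray(exposure, dtype=float)
    ph = np.asarray(phenotype, dtype=float)
    p_x, p_ph = [], []
    for col in omics_matrix.columns:
        o = omics_matrix[col].to_numpy(float)
        ok = ~(np.isnan(o) | np.isnan(x))
        p_x.append(stats.spearmanr(x[ok], o[ok])[1])
        ok = ~(np.isnan(o) | np.isnan(ph))
        p_ph.append(stats.spearmanr(ph[ok], o[ok])[1])
    fdr_x = bh_adjust(np.asarray(p_x))
    fdr_ph = bh_adjust(np.asarray(p_ph))
    keep = (fdr_x < fdr_threshold) & (fdr_ph < fdr_threshold)
    return [c for c, k in zip(omics_matrix.columns, keep) if k]


def classify_direction(fdr_d1: float, prop_d1: float,
                       fdr_d2: float, prop_d2: float,
                       fdr_threshold: float = 0.05,
                       use_abs: bool = True) -> str:
    """D1 if its FDR < threshold and its proportion dominates; D2 symmetric.

    Proportions are compared in absolute value by default (inconsistent
    mediation can make them negative). Equal proportions classify as none.
    """
    a1 = abs(prop_d1) if use_abs else prop_d1
    a2 = abs(prop_d2) if use_abs else prop_d2
    if np.isnan(a1) or np.isnan(a2):
        return NONE
    if fdr_d1 < fdr_threshold and a1 > a2:
        return D1
    if fdr_d2 < fdr_threshold and a2 > a1:
        return D2
    return NONE


_FIT_FIELDS = ("beta1", "beta2", "gamma1", "delta2", "acme", "ade", "total",
               "proportion", "proportion_uncapped", "ci_low", "ci_high",
               "boot_p")


def run_bidirectional_scan(pairs, exposures: pd.DataFrame,
                           phenotypes: pd.DataFrame, omics: pd.DataFrame,
                           n_boot: int = 1000, seed: int = 0,
                           screen: bool = True,
                           fdr_threshold: float = 0.05) -> pd.DataFrame:
    """Fit both mediation directions for every (pair, candidate omic) triple.

    ``pairs`` is an iterable of (exposure_id, phenotype_id) from the EWAS
    stage. BH-FDR is applied separately across all D1 and all D2 bootstrap
    p-values before classification. Deterministic given ``seed``.
    """
    ss = np.random.SeedSequence(seed)
    rows = []
    triples = []
    for exposure_id, phenotype_id in pairs:
        x = exposures[exposure_id]
        ph = phenotypes[phenotype_id]
        cands = (screen_candidates(x, ph, omics, fdr_threshold) if screen
                 else list(omics.columns))
        for omic_id in cands:
            triples.append((exposure_id, phenotype_id, omic_id))
    children = ss.spawn(2 * len(triples))
    for t, (exposure_id, phenotype_id, omic_id) in enumerate(triples):
        x = exposures[exposure_id].to_numpy(float)
        ph = phenotypes[phenotype_id].to_numpy(float)
        o = omics[omic_id].to_numpy(float)
        d1 = fit_mediation(x, o, ph, n_boot=n_boot, seed=children[2 * t])
        d2 = fit_mediation(x, ph, o, n_boot=n_boot, seed=children[2 * t + 1])
        row = {"exposure": exposure_id, "phenotype": phenotype_id,
               "omic": omic_id}
        for f in _FIT_FIELDS:
            row[f"d1_{f}"] = getattr(d1, f)
            row[f"d2_{f}"] = getattr(d2, f)
        rows.append(row)
    if not rows:
        cols = (["exposure", "phenotype", "omic"]
                + [f"d{d}_{f}" for d in (1, 2) for f in _FIT_FIELDS]
                + ["fdr_d1", "fdr_d2", "direction"])
        return pd.DataFrame(columns=cols)
    table = pd.DataFrame(rows)
    table["fdr_d1"] = bh_adjust(table["d1_boot_p"].to_numpy())
    table["fdr_d2"] = bh_adjust(table["d2_boot_p"].to_numpy())
    table["direction"] = [
        classify_direction(r.fdr_d1, r.d1_proportion, r.fdr_d2, r.d2_proportion,
                           fdr_threshold)
        for r in table.itertuples()]
    return table
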