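"""Mediation-weighted omics indexes (T-index for transcripts, M-index for
metabolites).

Per omics feature the weight PropSum is the sum of signed mediation
proportions over its classified triples for one exposure (sign = ACME
direction); a sample's index is the weighted sum of its standardized
feature levels over the weighted features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from immunexpo.errors import DegenerateDataError
from immunexpo.mediation import D1, D2
from immunexpo.stats_util import bh_adjust, floor_p


@dataclass
class IndexWeights:
    exposure: str
    prop_sum: pd.Series                  # feature -> summed signed proportion
    triples: pd.DataFrame                # feature, phenotype, proportion, sign


@dataclass
class IndexScores:
    exposure: str
    values: pd.Series                    # per-sample index
    n_features_used: int
    overlap_fraction: float


def compute_weights(records: pd.DataFrame, exposure: str) -> IndexWeights:
    """PropSum_k per feature from classified mediation records of one exposure.

    For each triple the classified direction's mediation proportion enters
    with the sign of its ACME; both D1 and D2 triples contribute.
    """
    sub = records[(records["exposure"] == exposure)
                  & (records["direction"].isin([D1, D2]))]
    if len(sub) == 0:
        warnings.warn(f"no classified mediation records for {exposure!r}",
                      stacklevel=2)
        return IndexWeights(exposure=exposure,
                            prop_sum=pd.Series(dtype=float),
                            triples=pd.DataFrame(
                                columns=["feature", "phenotype",
                                         "proportion", "sign"]))
    rows = []
    for r in sub.itertuples():
        d = r.direction.lower()
        acme = getattr(r, f"{d}_acme")
        prop = getattr(r, f"{d}_proportion")
        sign = -1.0 if acme < 0 else 1.0
        rows.append({"feature": r.omic, "phenotype": r.phenotype,
                     "proportion": abs(prop), "sign": sign})
    triples = pd.DataFrame(rows)
    prop_sum = (triples["sign"] * triples["proportion"]).groupby(
        triples["feature"]).sum()
    prop_sum.name = "prop_sum"
    return IndexWeights(exposure=exposure, prop_sum=prop_sum, triples=triples)


def _weighted_score(omics: pd.DataFrame, weights: pd.Series,
                    exposure: str, total_features: int,
                    standardize: bool = True) -> IndexScores:
    present = [f for f in weights.index if f in omics.columns]
    if not present:
        raise DegenerateDataError("no weighted feature present in the omics matrix")
    sub = omics[present].copy()
    sub = sub.fillna(sub.mean())  # per-feature mean imputation
    if standardize:
        sd = sub.std(ddof=1).replace(0.0, 1.0)
        sub = (sub - sub.mean()) / sd
    values = sub.to_numpy(float) @ weights.loc[present].to_numpy(float)
    return IndexScores(exposure=exposure,
                       values=pd.Series(values, index=omics.index, name="index"),
                       n_features_used=len(present),
                       overlap_fraction=len(present) / total_features)


def compute_index(omics_matrix: pd.DataFrame, weights: IndexWeights,
                  standardize: bool = True) -> IndexScores:
    """Per-sample weighted sum of (mean-imputed, standardized) feature levels."""
    if len(weights.prop_sum) == 0:
        raise DegenerateDataError("empty weights")
    return _weighted_score(omics_matrix, weights.prop_sum, weights.exposure,
                           len(weights.prop_sum), standardize)


def transfer_index(weights: IndexWeights,
                   external_omics: pd.DataFrame) -> IndexScores:
    """Score an external cohort on the overlapping weighted features.

    Weights are frozen; external features are standardized internally and
    the realized overlap fraction is reported.
    """
    if len(weights.prop_sum) == 0:
        raise DegenerateDataError("empty weights")
    overlap = weights.prop_sum.index.intersection(external_omics.columns)
    if len(overlap) == 0:
        raise DegenerateDataError("no overlap between weights and external features")
    return _weighted_score(external_omics, weights.prop_sum.loc[overlap],
                           weights.exposure, len(weights.prop_sum))


def index_outcome_model(index, outcome, covariates: pd.DataFrame | None,
                        family: str = "linear") -> dict:
    """GLM of an outcome on the index plus covariates.

    ``family`` is ``linear`` (OLS), ``logistic`` or ``multinomial``; returns
    the index coefficient(s) and p-value(s).
    """
    import statsmodels.api as sm

    idx = np.asarray(index, dtype=float)
    out = np.asarray(outcome, dtype=float)
    C = (covariates.to_numpy(float) if covariates is not None
         else np.empty((idx.size, 0)))
    keep = ~(np.isnan(idx) | np.isnan(out) | np.isnan(C).any(axis=1))
    idx, out, C = idx[keep], out[keep], C[keep]
    if np.ptp(out) == 0:
        raise DegenerateDataError("constant outcome")
    X = np.column_stack([np.ones(idx.size), idx, C])
    if family == "linear":
        fit = sm.OLS(out, X).fit()
        coef, p = fit.params[1], fit.pvalues[1]
    elif family == "logistic":
        fit = sm.Logit(out, X).fit(disp=0)
        coef, p = fit.params[1], fit.pvalues[1]
    elif family == "multinomial":
        fit = sm.MNLogit(out, X).fit(disp=0)
        coef = fit.params.iloc[1].to_numpy()
        p = fit.pvalues.iloc[1].to_numpy()
        return {"family": family, "coefficient": coef.tolist(),
                "p": floor_p(p).tolist(), "n_used": int(idx.size)}
    else:
        raise ValueError(f"unknown family {family!r}")
    return {"family": family, "coefficient": float(coef),
            "p": float(floor_p(p)), "n_used": int(idx.size)}


def evaluate_outcome_panel(index, outcomes: pd.DataFrame,
                           covariates: pd.DataFrame | None,
                           family: str = "linear") -> pd.DataFrame:
    """index_outcome_model across an outcome panel with BH adjustment."""
    rows = []
    for col in outcomes.columns:
        r = index_outcome_model(index, outcomes[col], covariates, family)
        rows.append({"outcome": col, **{k: r[k] for k in ("coefficient", "p", "n_used")}})
    table = pd.DataFrame(rows).set_index("outcome")
    table["fdr"] = bh_adjust(table["p"].to_numpy())
    return table


def index_group_test(index, group_labels, subject_ids=None) -> dict:
    """Two-sided Wilcoxon rank-sum between two groups of index values.

    Subjects with repeated measures are averaged first when ``subject_ids``
    is given.
    """
    df = pd.DataFrame({"index": np.asarray(index, dtype=float),
                       "group": np.asarray(group_labels)})
    if subject_ids is not None:
        df["subject"] = np.asarray(subject_ids)
        df = df.groupby(["subject", "group"], as_index=False)["index"].mean()
    groups = df["group"].unique()
    if len(groups) != 2:
        raise DegenerateDataError(f"need exactly 2 groups, got {len(groups)}")
    a = df.loc[df["group"] == groups[0], "index"]
    b = df.loc[df["group"] == groups[1], "index"]
    if len(a) == 0 or len(b) == 0:
        raise DegenerateDataError("empty group")
    stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    return {"groups": list(map(str, groups)), "statistic": float(stat),
            "p": float(p), "n": [int(len(a)), int(len(b))]}


def weights_to_table(weights: IndexWeights) -> pd.DataFrame:
    """Two-column serialization (feature, PropSum)."""
    return weights.prop_sum.rename_axis("feature").reset_index()
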