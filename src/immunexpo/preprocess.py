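"""Data-handling rules for phenotypes, exposures and omics tables.

Implements skewness-gated cleaning (reflection of left-skewed columns,
iterative long-tail outlier removal), sampling-day batch correction via
shrunken random-intercept estimates, rank-based inverse normal transform
with Blom offsets, kNN imputation, single-pass SD clipping, detection
filters, energy-extreme exclusion, energy adjustment and plant-based diet
index scoring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.impute import KNNImputer

from immunexpo.errors import ConfigError, DegenerateDataError

MALE = "male"
FEMALE = "female"

# kcal/day inclusion windows, bounds inclusive
ENERGY_BOUNDS = {MALE: (800.0, 4200.0), FEMALE: (500.0, 3500.0)}

HEALTHFUL_PLANT = "healthful_plant"
UNHEALTHFUL_PLANT = "unhealthful_plant"
ANIMAL = "animal"

PDI = "PDI"
HPDI = "hPDI"
UPDI = "uPDI"

# which food classes score in the positive direction (high intake -> 5)
_POSITIVE_CLASSES = {
    PDI: {HEALTHFUL_PLANT, UNHEALTHFUL_PLANT},
    HPDI: {HEALTHFUL_PLANT},
    UPDI: {UNHEALTHFUL_PLANT},
}


@dataclass(frozen=True)
class QCParams:
    skew_outlier_threshold: float = 2.15
    int_skew_threshold: float = 1.0
    knn_k: int = 5
    sd_clip: float = 3.0
    detection_min_fraction: float = 0.2
    low_expression_max_fraction: float = 0.3
    max_outlier_fraction: float = 0.05

    def validate(self) -> None:
        for name in self.__dataclass_fields__:
            if getattr(self, name) <= 0:
                raise ConfigError(name, "must be > 0")


@dataclass(frozen=True)
class DietScoreSpec:
    """16 food groups classified into plant/animal classes, scored 5/3/1
    by intake tertile (5/1 for binary groups) with variant-dependent
    direction."""

    group_class: dict
    variant: str = UPDI
    binary_groups: frozenset = field(default_factory=frozenset)

    def validate(self) -> None:
        if self.variant not in _POSITIVE_CLASSES:
            raise ConfigError("variant", f"must be one of {sorted(_POSITIVE_CLASSES)}")
        bad = {c for c in self.group_class.values()
               if c not in (HEALTHFUL_PLANT, UNHEALTHFUL_PLANT, ANIMAL)}
        if bad:
            raise ConfigError("group_class", f"unknown class {sorted(bad)[0]!r}")
        if len(self.group_class) != 16:
            raise ConfigError("group_class", f"expected 16 groups, got {len(self.group_class)}")


def default_diet_spec(variant: str = UPDI) -> DietScoreSpec:
    """The 16-group classification used for PDI/hPDI/uPDI scoring."""
    group_class = {
        "whole_grains": HEALTHFUL_PLANT,
        "fresh_fruits": HEALTHFUL_PLANT,
        "fresh_vegetables": HEALTHFUL_PLANT,
        "nuts": HEALTHFUL_PLANT,
        "legumes": HEALTHFUL_PLANT,
        "vegetable_oils": HEALTHFUL_PLANT,
        "tea": HEALTHFUL_PLANT,
        "garlic": HEALTHFUL_PLANT,
        "refined_grains": UNHEALTHFUL_PLANT,
        "preserved_vegetables": UNHEALTHFUL_PLANT,
        "sugar": UNHEALTHFUL_PLANT,
        "milk_dairy": ANIMAL,
        "meat": ANIMAL,
        "fish_aquatic": ANIMAL,
        "eggs": ANIMAL,
        "animal_fat": ANIMAL,
    }
    return DietScoreSpec(group_class=group_class, variant=variant)


# ---------------------------------------------------------------------------
# skewness and reflection

def sample_skewness(x) -> float:
    """Adjusted Fisher-Pearson sample skewness g1*sqrt(n(n-1))/(n-2)."""
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 3:
        raise DegenerateDataError(f"skewness undefined for n={x.size} (<3)")
    if np.ptp(x) == 0 or np.var(x) == 0:
        raise DegenerateDataError("skewness undefined for a constant vector")
    return float(stats.skew(x, bias=False))


def reflect_left_skewed(x, threshold: float = 2.15):
    """If skewness(x) < -threshold, mirror to max(x)+1-x; else unchanged."""
    x = np.asarray(x, dtype=float)
    if sample_skewness(x) < -threshold:
        return np.nanmax(x) + 1.0 - x
    return x.copy()


def remove_skew_outliers(x, params: QCParams | None = None):
    """Iterative long-tail removal for columns with skewness > threshold.

    Reflection is applied first. While skewness exceeds the threshold, the
    single most extreme point (largest |x - median|, ties broken toward the
    larger value) is masked, stopping at the threshold or after masking
    ``max_outlier_fraction`` of the points, whichever comes first.

    Returns ``(x_clean, removal_mask, capped)`` where masked entries are NaN
    in ``x_clean`` and ``capped`` flags an exhausted removal budget.
    """
    params = params or QCParams()
    x = np.asarray(x, dtype=float)
    n_missing = int(np.isnan(x).sum())
    if n_missing > 0.5 * x.size:
        raise DegenerateDataError(f">50% missing ({n_missing}/{x.size})")
    x = reflect_left_skewed(x, params.skew_outlier_threshold)
    mask = np.zeros(x.size, dtype=bool)
    budget = int(np.ceil(params.max_outlier_fraction * np.sum(~np.isnan(x))))
    capped = False
    while sample_skewness(x) > params.skew_outlier_threshold:
        if mask.sum() >= budget:
            capped = True
            warnings.warn("skew-outlier removal budget exhausted before "
                          "reaching the skewness threshold", stacklevel=2)
            break
        med = np.nanmedian(x)
        dev = np.abs(x - med)
        dev[np.isnan(x)] = -np.inf
        worst = np.flatnonzero(dev == np.nanmax(dev))
        drop = worst[np.nanargmax(x[worst])]  # ties -> larger value
        mask[drop] = True
        x[drop] = np.nan
    return x, mask, capped


# ---------------------------------------------------------------------------
# batch correction

def batch_correct_day(matrix: pd.DataFrame, day_labels) -> pd.DataFrame:
    """Remove sampling-day batch shifts via a random-intercept day model.

    Per feature a one-way random-effects model (value ~ (1|day)) is fitted
    by the ANOVA method of moments; the shrunken (BLUP-style) day intercept
    lambda_d*(mean_d - grand_mean) with lambda_d = sb2/(sb2 + se2/n_d) is
    subtracted from each value, so the grand mean is preserved and within-day
    ordering is untouched. NaNs pass through unchanged.
    """
    day_labels = np.asarray(day_labels)
    if day_labels.shape[0] != matrix.shape[0]:
        raise DegenerateDataError("day labels do not align with samples")
    days = np.unique(day_labels)
    if days.size < 2:
        warnings.warn("single sampling day: batch correction is the identity",
                      stacklevel=2)
        return matrix.copy()
    out = matrix.copy()
    groups = {d: day_labels == d for d in days}
    for col in matrix.columns:
        y = matrix[col].to_numpy(float)
        obs = ~np.isnan(y)
        grand = np.nanmean(y)
        n_d, means, sse = {}, {}, 0.0
        for d, g in groups.items():
            v = y[g & obs]
            if v.size == 0:
                continue
            n_d[d] = v.size
            means[d] = v.mean()
            sse += np.sum((v - means[d]) ** 2)
        n_total = sum(n_d.values())
        k = len(n_d)
        if k < 2 or n_total <= k:
            continue
        se2 = sse / (n_total - k)
        ssb = sum(n * (means[d] - grand) ** 2 for d, n in n_d.items())
        msb = ssb / (k - 1)
        n0 = (n_total - sum(n * n for n in n_d.values()) / n_total) / (k - 1)
        sb2 = max(0.0, (msb - se2) / n0)
        if sb2 == 0.0:
            continue
        adj = y.copy()
        for d, g in groups.items():
            if d not in n_d:
                continue
            lam = sb2 / (sb2 + se2 / n_d[d])
            adj[g] = y[g] - lam * (means[d] - grand)
        out[col] = adj
    return out


# ---------------------------------------------------------------------------
# transforms

def inverse_normal_transform(x):
    """Rank-based INT with Blom offsets: Phi^-1((rank - 3/8)/(n + 1/4)).

    Average ranks for ties; missing entries are preserved.
    """
    x = np.asarray(x, dtype=float)
    out = np.full(x.shape, np.nan)
    obs = ~np.isnan(x)
    v = x[obs]
    if v.size < 2 or np.ptp(v) == 0:
        raise DegenerateDataError("INT undefined: fewer than 2 distinct values")
    ranks = stats.rankdata(v, method="average")
    out[obs] = stats.norm.ppf((ranks - 0.375) / (v.size + 0.25))
    return out


def standardize(x):
    """Center to mean 0 and scale to sample SD 1 on non-missing entries."""
    x = np.asarray(x, dtype=float)
    obs = ~np.isnan(x)
    sd = np.std(x[obs], ddof=1) if obs.sum() > 1 else 0.0
    if sd == 0:
        raise DegenerateDataError("cannot standardize a constant vector")
    out = np.full(x.shape, np.nan)
    out[obs] = (x[obs] - np.mean(x[obs])) / sd
    return out


def knn_impute(matrix: pd.DataFrame, k: int = 5) -> pd.DataFrame:
    """Distance-weighted kNN imputation over rows (samples).

    Distances are Euclidean over shared observed features on internally
    standardized columns; imputed values are returned on the original scale.
    Observed cells are untouched.
    """
    if matrix.isna().all(axis=0).any():
        bad = matrix.columns[matrix.isna().all(axis=0)][0]
        raise DegenerateDataError(f"feature {bad!r} is missing in every row")
    if matrix.isna().all(axis=1).any():
        raise DegenerateDataError("a sample has no observed values")
    if not matrix.isna().to_numpy().any():
        return matrix.copy()
    mu = matrix.mean()
    sd = matrix.std(ddof=1).replace(0.0, 1.0).fillna(1.0)
    z = (matrix - mu) / sd
    imputer = KNNImputer(n_neighbors=min(k, len(matrix) - 1), weights="distance")
    filled = imputer.fit_transform(z.to_numpy(float))
    out = pd.DataFrame(filled, index=matrix.index, columns=matrix.columns)
    out = out * sd + mu
    out[~matrix.isna()] = matrix
    return out


def clip_sd_outliers(matrix: pd.DataFrame, sd_clip: float = 3.0):
    """Mask values beyond sd_clip standard deviations from the feature mean.

    Mean/SD are computed once on the pre-clip values (single pass). Returns
    the masked matrix and the boolean clip mask.
    """
    mu = matrix.mean()
    sd = matrix.std(ddof=1)
    mask = (matrix.sub(mu).abs() > sd_clip * sd).fillna(False)
    out = matrix.mask(mask)
    return out, mask


def filter_detection(matrix: pd.DataFrame, min_fraction: float = 0.2):
    """Drop features observed in fewer than ``min_fraction`` of samples."""
    if matrix.shape[1] == 0 or matrix.shape[0] == 0:
        return matrix.copy(), list(matrix.columns)
    frac = matrix.notna().mean(axis=0)
    kept = list(matrix.columns[frac >= min_fraction])
    return matrix[kept].copy(), kept


# ---------------------------------------------------------------------------
# exposures

def filter_energy_extremes(energy, gender) -> np.ndarray:
    """Inclusion mask for daily energy intake, bounds inclusive per gender."""
    energy = np.asarray(energy, dtype=float)
    gender = np.asarray(gender)
    keep = np.zeros(energy.shape, dtype=bool)
    seen = set(map(str, np.unique(gender)))
    unknown = seen - set(ENERGY_BOUNDS)
    if unknown:
        raise ConfigError("gender", f"unknown label {sorted(unknown)[0]!r}")
    for label, (lo, hi) in ENERGY_BOUNDS.items():
        g = gender == label
        keep[g] = (energy[g] >= lo) & (energy[g] <= hi)
    return keep


def energy_adjust(diet_matrix: pd.DataFrame, energy) -> pd.DataFrame:
    """Residualize standardized diet variables on standardized energy intake."""
    e = standardize(np.asarray(energy, dtype=float))
    out = {}
    for col in diet_matrix.columns:
        y = standardize(diet_matrix[col].to_numpy(float))
        obs = ~(np.isnan(y) | np.isnan(e))
        beta = float(np.dot(e[obs], y[obs]) / np.dot(e[obs], e[obs]))
        resid = y - beta * e
        out[col] = resid
    return pd.DataFrame(out, index=diet_matrix.index)


def _tertile_scores(freq: np.ndarray) -> np.ndarray:
    """5/3/1 by intake tertile; ties stay in the lower tertile."""
    obs = ~np.isnan(freq)
    v = freq[obs]
    n = v.size
    r = stats.rankdata(v, method="min")
    c1 = np.ceil(n / 3.0)
    c2 = np.ceil(2.0 * n / 3.0)
    s = np.where(r <= c1, 1.0, np.where(r <= c2, 3.0, 5.0))
    out = np.full(freq.shape, np.nan)
    out[obs] = s
    return out


def score_pdi(food_frequencies: pd.DataFrame, spec: DietScoreSpec) -> pd.Series:
    """Plant-based diet index: sum of 16 oriented 5/3/1 group scores."""
    spec.validate()
    missing = [g for g in spec.group_class if g not in food_frequencies.columns]
    if missing:
        raise ConfigError("food_groups", f"missing group column {missing[0]!r}")
    if (food_frequencies[list(spec.group_class)] < 0).any().any():
        raise ConfigError("food_frequencies", "frequencies must be nonnegative")
    positive = _POSITIVE_CLASSES[spec.variant]
    total = pd.Series(0.0, index=food_frequencies.index)
    for group, klass in spec.group_class.items():
        freq = food_frequencies[group].to_numpy(float)
        if group in spec.binary_groups:
            s = np.where(freq > 0, 5.0, 1.0)
            s = np.where(np.isnan(freq), np.nan, s)
        else:
            s = _tertile_scores(freq)
        if klass not in positive:
            s = 6.0 - s  # 5<->1, 3<->3
        total = total + s
    total.name = f"{spec.variant}_score"
    return total


def exposure_inclusion_filter(exposure_table: pd.DataFrame,
                              min_observations: int = 30) -> pd.DataFrame:
    """Keep exposures with more than ``min_observations`` non-missing values."""
    counts = exposure_table.notna().sum(axis=0)
    return exposure_table.loc[:, counts > min_observations].copy()


# ---------------------------------------------------------------------------
# full phenotype pipeline

def preprocess_phenotypes(matrix: pd.DataFrame, day_labels=None,
                          params: QCParams | None = None):
    """Fixed-order phenotype cleaning:

    reflect -> skew-outlier removal -> day batch correction ->
    re-removal -> INT (|skew| > 1) or standardize -> kNN imputation.

    Returns the cleaned matrix and a per-feature QC report (skewness before
    and after, points removed, transform applied). Idempotent on its own
    output for batch-balanced designs.
    """
    params = params or QCParams()
    params.validate()
    report = []
    stage1 = {}
    for col in matrix.columns:
        x = matrix[col].to_numpy(float)
        skew_before = sample_skewness(x)
        x, mask, capped = remove_skew_outliers(x, params)
        stage1[col] = x
        report.append({"feature": col, "skew_before": skew_before,
                       "n_removed": int(mask.sum()), "capped": capped})
    cleaned = pd.DataFrame(stage1, index=matrix.index)

    if day_labels is not None:
        cleaned = batch_correct_day(cleaned, day_labels)
        for rec in report:
            x, mask, _ = remove_skew_outliers(
                cleaned[rec["feature"]].to_numpy(float), params)
            cleaned[rec["feature"]] = x
            rec["n_removed"] += int(mask.sum())

    for rec in report:
        col = rec["feature"]
        x = cleaned[col].to_numpy(float)
        skew = sample_skewness(x)
        if abs(skew) > params.int_skew_threshold:
            # rescale after INT so every output column has unit sample SD,
            # which also makes the pipeline a fixed point of itself
            cleaned[col] = standardize(inverse_normal_transform(x))
            rec["transform"] = "INT"
        else:
            cleaned[col] = standardize(x)
            rec["transform"] = "scale"
        rec["skew_after"] = sample_skewness(cleaned[col].to_numpy(float))

    cleaned = knn_impute(cleaned, params.knn_k)
    # imputed cells shift column moments slightly; restore unit scale so the
    # pipeline output is exactly standardized (and a fixed point of itself)
    for col in cleaned.columns:
        cleaned[col] = standardize(cleaned[col].to_numpy(float))
    return cleaned, pd.DataFrame(report).set_index("feature")
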