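"""Self-contained verification benchmarks for the pipeline's core claims.

Each function recomputes one quantitative property from scratch -- oracle
agreement, parameter recovery, calibration, determinism -- and returns a
metrics dict. They back both the acceptance test suite and the standalone
acceptance report script.
"""

from __future__ import annotations

import tempfile
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from immunexpo.composite import fit_pls_path, select_cluster_count, \
    thresholded_spearman, ward_cluster
from immunexpo.ewas import cosinor_fit, run_ewas
from immunexpo.indexes import IndexWeights, compute_index, compute_weights
from immunexpo.mediation import fit_mediation, mediation_proportion, \
    run_bidirectional_scan
from immunexpo.pipeline import run_pipeline
from immunexpo.preprocess import QCParams, batch_correct_day, \
    inverse_normal_transform, knn_impute, remove_skew_outliers, sample_skewness
from immunexpo.variance import euclidean_distance, permanova


# ---------------------------------------------------------------------------
# 1. PERMANOVA vs exhaustive-enumeration oracle

def _oracle_f(dist: np.ndarray, labels: np.ndarray) -> float:
    """Direct group-sum PERMANOVA pseudo-F (independent of the hat-matrix
    implementation)."""
    n = dist.shape[0]
    d2 = dist ** 2
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    a = len(np.unique(labels))
    return ((ss_total - ss_within) / (a - 1)) / (ss_within / (n - a))


def permanova_oracle_check(seed: int = 0, n_cases: int = 20) -> dict:
    rng = np.random.default_rng(seed)
    f_match = p_match = 0
    for case in range(n_cases):
        n = int(rng.choice([4, 6, 8]))
        X = pd.DataFrame(rng.standard_normal((n, 3)),
                         index=[f"S{i}" for i in range(n)])
        d = euclidean_distance(X)
        labels = np.array([0] * (n // 2) + [1] * (n // 2))
        design = pd.DataFrame({"g": labels.astype(str)}, index=X.index)
        res = permanova(d, design, permutations="exact")[0]
        f_oracle = _oracle_f(d.to_numpy(), labels)
        count = total = 0
        for comb in combinations(range(n), n // 2):
            lab = np.ones(n, dtype=int)
            lab[list(comb)] = 0
            total += 1
            count += _oracle_f(d.to_numpy(), lab) >= f_oracle - 1e-12
        f_match += abs(res.pseudo_f - f_oracle) < 1e-10 * max(1.0, abs(f_oracle))
        p_match += abs(res.permutation_p - count / total) < 1e-12
    return {"n_cases": n_cases, "f_match": int(f_match), "p_match": int(p_match)}


# ---------------------------------------------------------------------------
# 2. mediation parameter recovery + CI coverage

def mediation_recovery(seed: int = 0, n: int = 2000, n_rep: int = 200,
                       n_boot: int = 200) -> dict:
    rng = np.random.default_rng(seed)
    cells = []
    for a in (0.2, 0.4):
        for b in (0.2, 0.4):
            for inter in (0.0, 0.2):
                true_acme = a * b
                acmes, covered = [], 0
                for rep in range(n_rep):
                    x = rng.standard_normal(n)
                    m = a * x + rng.standard_normal(n)
                    y = (0.2 * x + b * m + inter * x * m
                         + rng.standard_normal(n))
                    fit = fit_mediation(x, m, y, n_boot=n_boot,
                                        seed=int(rng.integers(2 ** 31)))
                    acmes.append(fit.acme)
                    covered += fit.ci_low <= true_acme <= fit.ci_high
                cells.append({"a": a, "b": b, "interaction": inter,
                              "bias": float(np.mean(acmes) - true_acme),
                              "coverage": covered / n_rep})
    return {"cells": cells,
            "max_abs_bias": max(abs(c["bias"]) for c in cells),
            "min_coverage": min(c["coverage"] for c in cells),
            "max_coverage": max(c["coverage"] for c in cells),
            # pooled over the whole grid (8 x n_rep replicates)
            "grid_coverage": float(np.mean([c["coverage"] for c in cells]))}


# ---------------------------------------------------------------------------
# 3. bidirectional direction recovery

def direction_recovery(seed: int = 0, n_seeds: int = 20, n: int = 1000,
                       n_null_omics: int = 50, n_boot: int = 200) -> dict:
    ok_seeds = 0
    correct_counts = []
    null_directed_total = 0
    for s in range(n_seeds):
        rng = np.random.default_rng(seed + 1000 * s)
        expos, phenos, omics, pairs = {}, {}, {}, []
        truth = {}
        for c in range(5):  # D1: exposure -> omic -> phenotype
            x = rng.standard_normal(n)
            m = 0.4 * x + rng.standard_normal(n)
            y = 0.2 * x + 0.4 * m + rng.standard_normal(n)
            expos[f"E{c}"] = x
            omics[f"OM{c}"] = m
            phenos[f"P{c}"] = y
            pairs.append((f"E{c}", f"P{c}"))
            truth[(f"E{c}", f"P{c}", f"OM{c}")] = "D1"
        for c in range(5, 10):  # D2: exposure -> phenotype -> omic
            x = rng.standard_normal(n)
            m = 0.4 * x + rng.standard_normal(n)
            y = 0.2 * x + 0.4 * m + rng.standard_normal(n)
            expos[f"E{c}"] = x
            phenos[f"P{c}"] = m
            omics[f"OM{c}"] = y
            pairs.append((f"E{c}", f"P{c}"))
            truth[(f"E{c}", f"P{c}", f"OM{c}")] = "D2"
        for j in range(n_null_omics):
            omics[f"NULL{j}"] = rng.standard_normal(n)
        table = run_bidirectional_scan(
            pairs, pd.DataFrame(expos), pd.DataFrame(phenos),
            pd.DataFrame(omics), n_boot=n_boot, seed=seed + s)
        correct = 0
        null_directed = 0
        for r in table.itertuples():
            key = (r.exposure, r.phenotype, r.omic)
            if key in truth:
                correct += r.direction == truth[key]
            elif r.direction != "none":
                null_directed += 1
        correct_counts.append(correct)
        null_directed_total += null_directed
        ok_seeds += (correct >= 8) and (null_directed == 0)
    return {"n_seeds": n_seeds, "ok_seeds": int(ok_seeds),
            "frac_ok": ok_seeds / n_seeds,
            "mean_correct_of_10": float(np.mean(correct_counts)),
            "null_directed_total": int(null_directed_total)}


# ---------------------------------------------------------------------------
# 4. EWAS FDR calibration under the full null

def ewas_fdr_calibration(seed: int = 0, n_rep: int = 100, n: int = 500,
                         n_exposures: int = 200, n_phenotypes: int = 50) -> dict:
    rates = []
    for rep in range(n_rep):
        rng = np.random.default_rng(seed + rep)
        idx = [f"S{i}" for i in range(n)]
        expos = pd.DataFrame(rng.standard_normal((n, n_exposures)),
                             index=idx,
                             columns=[f"E{j}" for j in range(n_exposures)])
        phenos = pd.DataFrame(rng.standard_normal((n, n_phenotypes)),
                              index=idx,
                              columns=[f"P{j}" for j in range(n_phenotypes)])
        covars = pd.DataFrame({"age": rng.uniform(20, 60, n),
                               "gender": rng.integers(0, 2, n),
                               "month": rng.integers(1, 13, n)}, index=idx)
        t = run_ewas(phenos, expos, covars)
        rates.append(float(t["significant"].mean()))
    return {"n_replicates": n_rep, "mean_flag_rate": float(np.mean(rates)),
            "max_flag_rate": float(np.max(rates))}


# ---------------------------------------------------------------------------
# 5. composite-exposure recovery

def composite_recovery(seed: int = 0, n_seeds: int = 50, n: int = 1000,
                       n_select_seeds: int = 10) -> dict:
    from sklearn.metrics import adjusted_rand_score
    ari_perfect = lv_ok = 0
    k_ok = 0
    for s in range(n_seeds):
        rng = np.random.default_rng(seed + 31 * s)
        cols, labels, factors = {}, [], []
        j = 0
        for b in range(3):
            f = rng.standard_normal(n)
            factors.append(f)
            for _ in range(5):
                cols[f"E{j:02d}"] = (np.sqrt(0.6) * f
                                     + np.sqrt(0.4) * rng.standard_normal(n))
                labels.append(b)
                j += 1
        table = pd.DataFrame(cols, index=[f"S{i}" for i in range(n)])
        tc = thresholded_spearman(table)
        got = ward_cluster(tc, 3)
        ari_perfect += adjusted_rand_score(labels, got.to_numpy()) == 1.0
        model = fit_pls_path(table, got)
        # match each LV to its best factor
        ok = True
        for lv in model.scores.columns:
            best = max(abs(np.corrcoef(model.scores[lv], f)[0, 1])
                       for f in factors)
            ok = ok and best >= 0.9
        lv_ok += ok
        if s < n_select_seeds:
            # the uncorrelated-LV rule stops at its first satisfying k, which
            # for independent blocks is k_start itself ~95% of the time; a
            # spurious significant pair at low k can force k past all block
            # structure and exhaust the range entirely
            try:
                k, _ = select_cluster_count(table, k_start=2)
            except Exception:
                k = -1
            k_ok += k == 3
    return {"n_seeds": n_seeds,
            "ari_perfect_frac": ari_perfect / n_seeds,
            "lv_recovery_frac": lv_ok / n_seeds,
            "k_selected_3_frac": k_ok / n_select_seeds}


# ---------------------------------------------------------------------------
# 6. formula identities

def formula_identities(seed: int = 0) -> dict:
    prop, _ = mediation_proportion(0.5 * 0.4, 0.1 + 0.5 * 0.4)
    eq5_err = abs(prop - 2.0 / 3.0)

    records = pd.DataFrame([
        {"exposure": "E", "omic": "G", "phenotype": "P1", "direction": "D1",
         "d1_acme": 0.1, "d1_proportion": 0.2, "d2_acme": 0.0,
         "d2_proportion": 0.0},
        {"exposure": "E", "omic": "G", "phenotype": "P2", "direction": "D1",
         "d1_acme": -0.1, "d1_proportion": 0.4, "d2_acme": 0.0,
         "d2_proportion": 0.0}])
    w = compute_weights(records, "E")
    propsum_err = abs(w.prop_sum["G"] - (0.2 - 0.4))

    rng = np.random.default_rng(seed)
    om = pd.DataFrame(rng.standard_normal((60, 2)), columns=["G1", "G2"])
    w1 = IndexWeights("E", pd.Series({"G1": 0.4}), pd.DataFrame())
    w2 = IndexWeights("E", pd.Series({"G2": -0.3}), pd.DataFrame())
    w12 = IndexWeights("E", pd.Series({"G1": 0.4, "G2": -0.3}), pd.DataFrame())
    lin_err = float(np.max(np.abs(
        compute_index(om, w12).values
        - compute_index(om, w1).values - compute_index(om, w2).values)))

    x = rng.standard_normal(300)
    m = 0.4 * x + rng.standard_normal(300)
    y = 0.2 * x + 0.4 * m + rng.standard_normal(300)
    fit = fit_mediation(x, m, y, n_boot=100, seed=1)
    acme_total_err = abs(fit.total - (fit.acme + fit.ade))
    return {"eq5_err": float(eq5_err), "propsum_err": float(propsum_err),
            "index_linearity_err": lin_err,
            "acme_plus_ade_err": float(acme_total_err),
            "max_err": float(max(eq5_err, propsum_err, lin_err,
                                 acme_total_err))}


# ---------------------------------------------------------------------------
# 7. preprocessing contracts

def preprocessing_contracts(seed: int = 0) -> dict:
    rng = np.random.default_rng(seed)
    # INT normality
    int_pass = 0
    n_int = 40
    for _ in range(n_int):
        x = np.exp(rng.standard_normal(200) * rng.uniform(0.5, 2.0))
        int_pass += stats.shapiro(inverse_normal_transform(x)).pvalue > 0.01

    # skew-outlier removal on heavy-tailed vectors
    skew_ok = 0
    for _ in range(10):
        x = np.concatenate([rng.standard_normal(300),
                            rng.standard_normal(5) * 40 + 100])
        clean, _, capped = remove_skew_outliers(x, QCParams())
        skew_ok += (sample_skewness(clean) <= 2.15) or capped

    # kNN vs mean imputation on smooth data
    f = rng.standard_normal((200, 2))
    load = rng.standard_normal((2, 10))
    truth = f @ load + 0.1 * rng.standard_normal((200, 10))
    arr = truth.copy()
    mask = rng.random(arr.shape) < 0.05
    arr[mask] = np.nan
    df = pd.DataFrame(arr)
    knn_rmse = float(np.sqrt(np.nanmean(
        (knn_impute(df, 5).to_numpy()[mask] - truth[mask]) ** 2)))
    mean_rmse = float(np.sqrt(np.nanmean(
        (df.fillna(df.mean()).to_numpy()[mask] - truth[mask]) ** 2)))

    # batch correction removes a planted +1.0 day shift
    days = np.repeat([0, 1], 200)
    y = rng.normal(0, 0.1, 400) + np.where(days == 1, 1.0, 0.0)
    corr = batch_correct_day(pd.DataFrame({"f": y}), days)
    resid_shift = float(abs(corr["f"][days == 1].mean()
                            - corr["f"][days == 0].mean()))
    return {"int_normal_frac": int_pass / n_int,
            "skew_reduced_frac": skew_ok / 10,
            "knn_rmse": knn_rmse, "mean_rmse": mean_rmse,
            "knn_beats_mean": bool(knn_rmse < mean_rmse),
            "batch_residual_shift": resid_shift}


# ---------------------------------------------------------------------------
# 8. cosinor recovery

def cosinor_recovery(seed: int = 0) -> dict:
    rng = np.random.default_rng(seed)
    m = rng.integers(1, 13, 600)
    y = 0.5 + 0.3 * np.cos(2 * np.pi * (m - 3.0) / 12.0)
    fit = cosinor_fit(y, m)
    err = max(abs(fit.mesor - 0.5), abs(fit.amplitude - 0.3),
              abs(fit.phase - 3.0))
    y2 = 0.5 + 0.3 * np.cos(2 * np.pi * (m - 11.5) / 12.0)
    fit2 = cosinor_fit(y2, m)
    wrap_err = min(abs(fit2.phase - 11.5), 12.0 - abs(fit2.phase - 11.5))
    return {"max_param_err": float(err), "phase_wrap_err": float(wrap_err)}


# ---------------------------------------------------------------------------
# 9. end-to-end index recovery

def index_recovery(seed: int = 0, n_seeds: int = 20, n: int = 1000,
                   n_boot: int = 1000) -> dict:
    # n_boot must stay large here: the bootstrap p floor is 1/n_boot, and BH
    # across the several hundred scanned triples needs p floors well below
    # 0.05 * (n_true / n_triples) for the true chains to survive
    sig_seeds = 0
    pvals = []
    for s in range(n_seeds):
        rng = np.random.default_rng(seed + 77 * s)
        x = rng.standard_normal(n)
        omics, phenos, pairs = {}, {}, []
        for c in range(20):  # one exposure drives 20 mediated omics
            m = 0.4 * x + rng.standard_normal(n)
            y = 0.2 * x + 0.4 * m + rng.standard_normal(n)
            omics[f"OM{c}"] = m
            phenos[f"P{c}"] = y
            pairs.append(("E0", f"P{c}"))
        for j in range(20):
            omics[f"NULL{j}"] = rng.standard_normal(n)
        expos = pd.DataFrame({"E0": x})
        omics = pd.DataFrame(omics)
        table = run_bidirectional_scan(pairs, expos, pd.DataFrame(phenos),
                                       omics, n_boot=n_boot, seed=seed + s)
        weights = compute_weights(table, "E0")
        if len(weights.prop_sum) == 0:
            pvals.append(1.0)
            continue
        scores = compute_index(omics, weights)
        q1, q3 = np.quantile(x, [0.25, 0.75])
        lo = scores.values[x <= q1]
        hi = scores.values[x >= q3]
        p = stats.mannwhitneyu(lo, hi, alternative="two-sided").pvalue
        pvals.append(float(p))
        sig_seeds += p < 0.01
    return {"n_seeds": n_seeds, "sig_seeds": int(sig_seeds),
            "frac_significant": sig_seeds / n_seeds,
            "median_p": float(np.median(pvals))}


# ---------------------------------------------------------------------------
# 10. pipeline determinism

def pipeline_determinism(seed: int = 0) -> dict:
    config = {
        "seed": int(seed),
        "synthetic": {
            "n_samples": 150, "n_exposures": 8,
            "exposure_block_sizes": [3, 3], "within_block_r": 0.6,
            "n_phenotypes": 5, "n_omics": 10, "batch_count": 3,
            "batch_sd": 0.3, "seasonal_amplitude": 0.3,
            "seasonal_phase": 2.0, "missing_rate": 0.02,
            "skew_fraction": 0.2,
            "mediation_chains": [
                {"direction": "D1", "exposure_id": "EXP001",
                 "mediator_id": "OMX0001", "outcome_id": "IP001",
                 "a_path": 0.6, "b_path": 0.6, "direct_path": 0.2,
                 "noise_sd": 0.6}]},
        "variance": {"n_perm": 49},
        "mediation": {"n_boot": 120, "max_pairs": 5},
    }
    with tempfile.TemporaryDirectory() as td:
        m1 = run_pipeline(config, Path(td) / "a")
        m2 = run_pipeline(config, Path(td) / "b")
    return {"n_artifacts": len(m1["files"]),
            "manifests_identical": m1["files"] == m2["files"]}
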