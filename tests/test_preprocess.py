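import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from immunexpo.errors import ConfigError, DegenerateDataError
from immunexpo.preprocess import (DietScoreSpec, QCParams, batch_correct_day,
                                  clip_sd_outliers, default_diet_spec,
                                  energy_adjust, exposure_inclusion_filter,
                                  filter_detection, filter_energy_extremes,
                                  inverse_normal_transform, knn_impute,
                                  preprocess_phenotypes, reflect_left_skewed,
                                  remove_skew_outliers, sample_skewness,
                                  score_pdi, standardize)


def skew_oracle(x):
    """Direct evaluation of adjusted Fisher-Pearson skewness."""
    x = np.asarray(x, float)
    n = len(x)
    m = x.mean()
    m2 = np.mean((x - m) ** 2)
    m3 = np.mean((x - m) ** 3)
    g1 = m3 / m2 ** 1.5
    return g1 * np.sqrt(n * (n - 1)) / (n - 2)


class TestSkewness:
    def test_symmetric(self):
        assert sample_skewness([1, 2, 3]) == pytest.approx(0.0, abs=1e-12)

    def test_hand_formula_oracle(self):
        x = [1, 2, 3, 4, 100]
        assert sample_skewness(x) == pytest.approx(skew_oracle(x), abs=1e-12)

    @given(st.lists(st.floats(-100, 100), min_size=4, max_size=50))
    @settings(max_examples=50, deadline=None)
    def test_odd_function(self, xs):
        x = np.asarray(xs)
        if np.std(x) < 1e-6:
            return
        assert sample_skewness(-x) == pytest.approx(-sample_skewness(x),
                                                    abs=1e-8)

    def test_degenerate(self):
        with pytest.raises(DegenerateDataError):
            sample_skewness([1.0, 1.0, 1.0])
        with pytest.raises(DegenerateDataError):
            sample_skewness([1.0, 2.0])


class TestReflect:
    def test_right_skewed_unchanged(self, rng):
        x = np.exp(rng.standard_normal(200))
        np.testing.assert_array_equal(reflect_left_skewed(x, 2.15), x)

    def test_hand_formula(self):
        # skewness of (0, 8, 9) is about -1.65 < -0.5 -> max+1-x = (10, 2, 1)
        out = reflect_left_skewed(np.array([0.0, 8.0, 9.0]), 0.5)
        np.testing.assert_allclose(out, [10.0, 2.0, 1.0])

    def test_reflection_flips_skew_sign(self, rng):
        x = -np.exp(rng.standard_normal(500))  # left-skewed
        out = reflect_left_skewed(x, 1.0)
        assert sample_skewness(out) == pytest.approx(-sample_skewness(x),
                                                     abs=1e-8)


class TestSkewOutlierRemoval:
    def test_normal_sample_untouched(self, rng):
        x = rng.standard_normal(500)
        _, mask, capped = remove_skew_outliers(x)
        assert mask.sum() == 0 and not capped

    def test_single_spike_removed(self):
        x = np.array([1.0, 1, 2, 2, 3, 1000])
        assert skew_oracle(x) > 2.15
        clean, mask, _ = remove_skew_outliers(x)
        assert mask.tolist() == [False] * 5 + [True]
        assert sample_skewness(clean) <= 2.15

    def test_cap_respected(self):
        x = np.concatenate([np.zeros(90), np.full(10, 1e6)])
        x[:90] = np.linspace(0, 1, 90)
        with pytest.warns(UserWarning, match="budget"):
            _, mask, capped = remove_skew_outliers(x)
        assert capped
        assert mask.sum() == int(np.ceil(0.05 * 100))

    def test_too_many_missing(self):
        x = np.full(100, np.nan)
        x[:40] = np.arange(40)
        with pytest.raises(DegenerateDataError, match="missing"):
            remove_skew_outliers(x)


class TestBatchCorrect:
    def test_single_day_identity(self, rng):
        m = pd.DataFrame(rng.standard_normal((30, 2)))
        with pytest.warns(UserWarning, match="single"):
            out = batch_correct_day(m, np.zeros(30))
        pd.testing.assert_frame_equal(out, m)

    def test_planted_shift_removed(self):
        rng = np.random.default_rng(11)
        days = np.repeat([0, 1], 200)
        y = rng.normal(0, 0.1, 400) + np.where(days == 1, 1.0, 0.0)
        out = batch_correct_day(pd.DataFrame({"f": y}), days)
        diff = out["f"][days == 1].mean() - out["f"][days == 0].mean()
        assert abs(diff) < 0.05

    def test_within_day_order_preserved(self, rng):
        days = np.repeat(np.arange(4), 25)
        m = pd.DataFrame({"f": rng.standard_normal(100) + days})
        out = batch_correct_day(m, days)
        for d in range(4):
            a = m["f"][days == d].to_numpy()
            b = out["f"][days == d].to_numpy()
            np.testing.assert_array_equal(np.argsort(a), np.argsort(b))

    def test_grand_mean_preserved(self, rng):
        days = np.repeat(np.arange(5), 40)
        m = pd.DataFrame({"f": rng.standard_normal(200) + 0.8 * days})
        out = batch_correct_day(m, days)
        assert out["f"].mean() == pytest.approx(m["f"].mean(), abs=1e-8)


class TestINT:
    def test_median_maps_to_zero(self):
        out = inverse_normal_transform([10.0, 20, 30, 40, 50])
        assert out[2] == pytest.approx(0.0, abs=1e-12)

    def test_rank_invariance(self, rng):
        x = rng.standard_normal(100)
        np.testing.assert_allclose(inverse_normal_transform(x),
                                   inverse_normal_transform(np.exp(x)))

    def test_blom_quantile_oracle(self):
        out = inverse_normal_transform([1.0, 2, 3, 4, 5])
        assert out[-1] == pytest.approx(stats.norm.ppf((5 - 0.375) / 5.25),
                                        abs=1e-12)

    def test_missing_preserved(self):
        out = inverse_normal_transform([1.0, np.nan, 3.0])
        assert np.isnan(out[1]) and not np.isnan(out[0])

    def test_constant_errors(self):
        with pytest.raises(DegenerateDataError):
            inverse_normal_transform([2.0, 2.0, 2.0])

    def test_output_normality(self):
        # INT output passes Shapiro-Wilk at n=200 on >= 95% of random inputs
        rng = np.random.default_rng(21)
        passed = 0
        for _ in range(40):
            x = np.exp(rng.standard_normal(200) * rng.uniform(0.5, 2))
            w = stats.shapiro(inverse_normal_transform(x))
            passed += w.pvalue > 0.01
        assert passed >= 38


class TestStandardize:
    def test_hand_arithmetic(self):
        np.testing.assert_allclose(standardize([1.0, 2, 3]), [-1, 0, 1])

    def test_idempotent(self, rng):
        x = rng.standard_normal(100)
        z = standardize(x)
        np.testing.assert_allclose(standardize(z), z, atol=1e-12)

    @given(st.floats(0.1, 10), st.floats(-5, 5))
    @settings(max_examples=25, deadline=None)
    def test_affine_invariance(self, a, b):
        x = np.linspace(-2, 5, 40)
        np.testing.assert_allclose(standardize(a * x + b), standardize(x),
                                   atol=1e-8)

    def test_constant_errors(self):
        with pytest.raises(DegenerateDataError):
            standardize([3.0, 3.0])


class TestKnnImpute:
    def test_no_missing_identity(self, rng, frame_of):
        m = frame_of(rng.standard_normal((20, 4)))
        pd.testing.assert_frame_equal(knn_impute(m, 5), m)

    def test_duplicated_row_exact(self, frame_of):
        row = np.array([1.0, 2.0, 3.0])
        m = frame_of(np.tile(row, (6, 1)) + 0.0)
        m.iloc[0, 1] = np.nan
        out = knn_impute(m, 5)
        assert out.iloc[0, 1] == pytest.approx(2.0, abs=1e-9)

    def test_beats_mean_imputation(self):
        # DERIVED: smooth low-rank data, kNN RMSE < mean-imputation RMSE
        rng = np.random.default_rng(8)
        f = rng.standard_normal((200, 2))
        load = rng.standard_normal((2, 10))
        truth = f @ load + 0.1 * rng.standard_normal((200, 10))
        m = pd.DataFrame(truth.copy())
        mask = rng.random(m.shape) < 0.05
        arr = m.to_numpy()
        arr[mask] = np.nan
        out = knn_impute(pd.DataFrame(arr), 5)
        rmse_knn = np.sqrt(np.nanmean((out.to_numpy()[mask] - truth[mask]) ** 2))
        mean_fill = pd.DataFrame(arr).fillna(pd.DataFrame(arr).mean())
        rmse_mean = np.sqrt(np.nanmean(
            (mean_fill.to_numpy()[mask] - truth[mask]) ** 2))
        assert rmse_knn < rmse_mean

    def test_all_missing_feature_errors(self, frame_of):
        m = frame_of(np.ones((5, 2)))
        m.iloc[:, 1] = np.nan
        with pytest.raises(DegenerateDataError, match="1"):
            knn_impute(m, 2)


class TestClipAndFilters:
    def test_normal_tail_fraction(self):
        rng = np.random.default_rng(17)
        m = pd.DataFrame({"f": rng.standard_normal(10000)})
        _, mask = clip_sd_outliers(m, 3.0)
        frac = mask["f"].mean()
        assert 0.001 < frac < 0.006  # ~0.27% for a normal

    def test_spike_removed_only(self):
        m = pd.DataFrame({"f": [1.0] * 20 + [1.1] * 20 + [100.0]})
        out, mask = clip_sd_outliers(m, 3.0)
        assert mask["f"].sum() == 1 and np.isnan(out["f"].iloc[-1])

    def test_infinite_clip_identity(self, rng):
        m = pd.DataFrame({"f": rng.standard_normal(50)})
        out, mask = clip_sd_outliers(m, np.inf)
        pd.testing.assert_frame_equal(out, m)
        assert mask.to_numpy().sum() == 0

    def test_detection_filter_rule(self):
        n = 100
        a = np.full(n, np.nan); a[:19] = 1.0
        b = np.full(n, np.nan); b[:21] = 1.0
        m = pd.DataFrame({"low": a, "ok": b})
        out, kept = filter_detection(m, 0.2)
        assert kept == ["ok"]

    def test_detection_filter_empty(self):
        m = pd.DataFrame()
        out, kept = filter_detection(m, 0.2)
        assert out.empty and kept == []


class TestEnergy:
    def test_bounds(self):
        genders = np.array(["male", "female", "male", "female", "male"])
        energy = np.array([4500.0, 400.0, 800.0, 3500.0, 4200.0])
        keep = filter_energy_extremes(energy, genders)
        assert keep.tolist() == [False, False, True, True, True]

    def test_unknown_gender(self):
        with pytest.raises(ConfigError, match="gender"):
            filter_energy_extremes([1000.0], ["other"])

    def test_energy_adjust_orthogonal_unchanged(self, rng):
        e = rng.standard_normal(500)
        d = rng.standard_normal(500)
        ec = e - e.mean()
        d = d - (np.dot(ec, d - d.mean()) / np.dot(ec, ec)) * ec  # exact orthogonality
        out = energy_adjust(pd.DataFrame({"d": d}), e)
        np.testing.assert_allclose(out["d"], standardize(d), atol=1e-10)

    def test_energy_adjust_self_zero(self, rng):
        e = rng.standard_normal(100)
        out = energy_adjust(pd.DataFrame({"d": e}), e)
        np.testing.assert_allclose(out["d"], 0.0, atol=1e-10)

    def test_energy_adjust_partial_correlation_recovered(self):
        # DERIVED: d = 0.5*z + 0.5*e; after adjustment corr(d, z) ~ known value
        rng = np.random.default_rng(31)
        n = 2000
        e = rng.standard_normal(n)
        z = rng.standard_normal(n)
        d = 0.5 * z + 0.5 * e + 0.1 * rng.standard_normal(n)
        out = energy_adjust(pd.DataFrame({"d": d}), e)
        r = np.corrcoef(out["d"], z)[0, 1]
        assert r > 0.9  # energy component removed, z structure kept


class TestDietScores:
    def test_all_median_gives_48(self, rng):
        spec = default_diet_spec("PDI")
        base = {g: rng.permutation(np.arange(1.0, 31.0))
                for g in spec.group_class}
        df = pd.DataFrame(base)
        # subject with every group at the population median -> all 3s
        mid = {g: 15.5 for g in spec.group_class}
        df = pd.concat([df, pd.DataFrame([mid])], ignore_index=True)
        score = score_pdi(df, spec)
        assert score.iloc[-1] == 48.0

    def test_tertile_rule_by_hand(self):
        spec = default_diet_spec("uPDI")
        df = pd.DataFrame({g: np.ones(9) for g in spec.group_class})
        df["sugar"] = np.arange(1.0, 10.0)  # unhealthful plant group
        scores = score_pdi(df, spec)
        base = scores - scores.min()
        # subjects 1-3 score 1, 4-6 score 3, 7-9 score 5 on the sugar group
        np.testing.assert_array_equal(base.to_numpy(),
                                      [0, 0, 0, 2, 2, 2, 4, 4, 4])

    def test_updi_hpdi_reversal_symmetry(self, rng):
        hp = default_diet_spec("hPDI")
        up = default_diet_spec("uPDI")
        df = pd.DataFrame({g: rng.integers(0, 10, 30).astype(float)
                           for g in hp.group_class})
        # isolate one healthful group: zero out tertile variation elsewhere
        s_h = score_pdi(df, hp)
        s_u = score_pdi(df, up)
        # healthful groups reverse between variants; scores are complementary
        # per group (5<->1, 3<->3): verify on a single-group frame
        one = pd.DataFrame({g: (df[g] if g == "fresh_fruits" else np.ones(30))
                            for g in hp.group_class})
        total = score_pdi(one, hp) + score_pdi(one, up)
        assert total.nunique() == 1  # per-subject sums constant

    def test_missing_group_errors(self):
        spec = default_diet_spec()
        with pytest.raises(ConfigError, match="whole_grains"):
            score_pdi(pd.DataFrame({"meat": [1.0]}), spec)

    def test_binary_groups(self):
        spec = DietScoreSpec(group_class=default_diet_spec().group_class,
                             variant="PDI", binary_groups=frozenset({"garlic"}))
        df = pd.DataFrame({g: np.ones(4) for g in spec.group_class})
        df["garlic"] = [0.0, 1.0, 0.0, 1.0]
        s = score_pdi(df, spec)
        assert (s.iloc[1] - s.iloc[0]) == 4.0  # 5 vs 1 on one positive group


def test_exposure_inclusion_filter():
    n = 100
    a = np.full(n, np.nan); a[:30] = 1.0
    b = np.full(n, np.nan); b[:31] = np.arange(31)
    c = np.full(n, np.nan)
    t = exposure_inclusion_filter(pd.DataFrame({"a": a, "b": b, "c": c}))
    assert list(t.columns) == ["b"]


class TestFullPipeline:
    def test_idempotent_balanced_days(self):
        rng = np.random.default_rng(12)
        days = np.repeat(np.arange(4), 50)
        m = pd.DataFrame({f"f{j}": rng.standard_normal(200)
                          + 0.5 * rng.standard_normal(4)[days]
                          for j in range(5)})
        out1, _ = preprocess_phenotypes(m, days)
        out2, _ = preprocess_phenotypes(out1, days)
        np.testing.assert_allclose(out1.to_numpy(), out2.to_numpy(), atol=1e-10)

    def test_idempotent_skewed_no_batch(self):
        rng = np.random.default_rng(13)
        m = pd.DataFrame({"f": np.exp(rng.standard_normal(200)),
                          "g": rng.standard_normal(200)})
        out1, rep1 = preprocess_phenotypes(m)
        out2, rep2 = preprocess_phenotypes(out1)
        np.testing.assert_allclose(out1.to_numpy(), out2.to_numpy(), atol=1e-10)
        assert rep1.loc["f", "transform"] == "INT"
        assert rep2.loc["f", "transform"] == "scale"

    def test_report_contents(self, small_cohort):
        out, rep = preprocess_phenotypes(
            small_cohort.phenotypes,
            small_cohort.covariates["sampling_day"].to_numpy())
        assert set(rep.columns) >= {"skew_before", "skew_after", "n_removed",
                                    "transform"}
        assert not out.isna().to_numpy().any()
        assert (rep["skew_after"].abs() <= 2.15).all()

    def test_qcparams_validation(self):
        with pytest.raises(ConfigError, match="knn_k"):
            QCParams(knn_k=0).validate()
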