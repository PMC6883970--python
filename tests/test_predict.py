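import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from pathbench.predict import (
    binary_cv,
    concordance_index,
    outer_splits,
    pairwise_wilcoxon_bh,
    performance_anova,
    subtype_cv,
    survival_cv,
)

SMALL_GRID = dict(l1_ratio_grid=(0.5,), c_grid=(1.0,), inner_folds=3)


def separated_activity(rng, n=60, n_features=6, shift=3.0):
    X = rng.normal(size=(n, n_features))
    y = np.array([0, 1] * (n // 2))
    X[y == 1, :2] += shift
    frame = pd.DataFrame(X, columns=[f"p{i}" for i in range(n_features)])
    return frame, y


class TestBinaryCv:
    def test_separable_classes_reach_high_auc(self):
        rng = np.random.default_rng(0)
        activity, y = separated_activity(rng)
        report = binary_cv(activity, y, repeats=1, folds=3, seed=1, **SMALL_GRID)
        assert report["auc"].mean() >= 0.95
        assert len(report) == 3

    def test_permuted_labels_give_chance_auc(self):
        rng = np.random.default_rng(1)
        activity, y = separated_activity(rng, n=120)
        permuted = rng.permutation(y)
        report = binary_cv(activity, permuted, repeats=2, folds=3, seed=1, **SMALL_GRID)
        assert 0.3 <= report["auc"].mean() <= 0.7

    def test_constant_features_give_exact_half_auc(self):
        y = np.array([0, 1] * 20)
        activity = pd.DataFrame(np.ones((40, 3)), columns=list("abc"))
        report = binary_cv(activity, y, repeats=1, folds=2, seed=0, **SMALL_GRID)
        np.testing.assert_allclose(report["auc"], 0.5)

    def test_single_class_input_rejected(self):
        activity = pd.DataFrame(np.ones((10, 2)))
        with pytest.raises(ValueError, match="2 classes"):
            binary_cv(activity, np.zeros(10))

    def test_heldout_labels_never_influence_fitting(self):
        """Corrupting a fold's held-out labels leaves every fitted model alone."""
        rng = np.random.default_rng(5)
        activity, y = separated_activity(rng, n=60)
        splits = outer_splits(y, repeats=1, folds=3, seed=2)
        grid = dict(l1_ratio_grid=(0.1, 0.9), c_grid=(0.1, 1.0), inner_folds=3)
        baseline = binary_cv(activity, y, seed=2, splits=splits, **grid)
        corrupted = y.copy()
        corrupted[splits[0][3]] = 1 - corrupted[splits[0][3]]  # flip fold-0 test labels
        report = binary_cv(activity, corrupted, seed=2, splits=splits, **grid)
        # fold 0's hyperparameters come from its training data only, so the
        # corruption of its held-out labels cannot change them ...
        assert baseline.loc[0, ["l1_ratio", "C"]].tolist() == \
            report.loc[0, ["l1_ratio", "C"]].tolist()
        # ... while its held-out metric must flip (labels were inverted)
        assert report.loc[0, "auc"] == pytest.approx(1.0 - baseline.loc[0, "auc"])

    def test_bit_reproducible_under_fixed_seed(self):
        rng = np.random.default_rng(7)
        activity, y = separated_activity(rng)
        first = binary_cv(activity, y, repeats=1, folds=3, seed=3, **SMALL_GRID)
        second = binary_cv(activity, y, repeats=1, folds=3, seed=3, **SMALL_GRID)
        pd.testing.assert_frame_equal(first, second)


class TestSubtypeCv:
    def subtype_data(self, rng, n_per_class=15, k=4):
        X = rng.normal(size=(n_per_class * k, 8))
        y = np.repeat([f"S{i}" for i in range(k)], n_per_class)
        for i in range(k):
            X[y == f"S{i}", i] += 4.0
        return pd.DataFrame(X, columns=[f"p{i}" for i in range(8)]), y

    def test_separated_subtypes_reach_high_accuracy(self):
        rng = np.random.default_rng(2)
        activity, y = self.subtype_data(rng)
        report = subtype_cv(activity, y, repeats=1, folds=3, c_grid=(1.0,),
                            inner_folds=3, seed=0)
        assert report["accuracy"].mean() >= 0.9
        assert {"precision", "recall"} <= set(report.columns)

    def test_permuted_labels_near_chance(self):
        rng = np.random.default_rng(3)
        activity, y = self.subtype_data(rng, n_per_class=25)
        permuted = rng.permutation(y)
        report = subtype_cv(activity, permuted, repeats=2, folds=5, c_grid=(1.0,),
                            inner_folds=3, seed=0)
        # chance accuracy for 4 balanced classes is 0.25
        assert abs(report["accuracy"].mean() - 0.25) < 0.15

    def test_undersized_class_rejected_by_name(self):
        activity = pd.DataFrame(np.random.default_rng(0).normal(size=(12, 3)))
        y = np.array(["A"] * 10 + ["B"] * 2)
        with pytest.raises(ValueError, match="'B'"):
            subtype_cv(activity, y, folds=5)

    def test_two_class_problem_supported(self):
        rng = np.random.default_rng(4)
        activity, y = self.subtype_data(rng, k=2, n_per_class=20)
        report = subtype_cv(activity, y, repeats=1, folds=3, c_grid=(1.0,),
                            inner_folds=3, seed=0)
        assert report["accuracy"].mean() >= 0.9


class TestConcordanceIndex:
    def test_perfect_concordance(self):
        assert concordance_index([3, 2, 1], [1, 2, 3], [1, 1, 1]) == 1.0

    def test_perfect_anticoncordance(self):
        assert concordance_index([1, 2, 3], [1, 2, 3], [1, 1, 1]) == 0.0

    def test_risk_tie_counts_half(self):
        assert concordance_index([1, 1], [1, 2], [1, 1]) == 0.5

    def test_censored_sample_not_comparable_when_earlier(self):
        # earlier sample censored: the pair is not comparable
        with pytest.raises(ValueError):
            concordance_index([1, 2], [1, 2], [0, 0])

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(6)
        risk = rng.normal(size=30)
        time = rng.exponential(size=30)
        event = rng.integers(0, 2, size=30)
        event[0] = 1
        base = concordance_index(risk, time, event)
        assert concordance_index(np.exp(risk), time, event) == pytest.approx(base)

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(9)
        for _ in range(25):
            n = int(rng.integers(5, 51))
            risk = np.round(rng.normal(size=n), 1)  # ties in risk
            time = np.round(rng.exponential(size=n), 1) + 0.1  # ties in time
            event = rng.integers(0, 2, size=n)
            if not event.any():
                continue
            num = comp = 0.0
            for i in range(n):
                for j in range(n):
                    if time[i] < time[j] and event[i]:
                        comp += 1
                        if risk[i] > risk[j]:
                            num += 1
                        elif risk[i] == risk[j]:
                            num += 0.5
            if comp == 0:
                continue
            assert concordance_index(risk, time, event) == pytest.approx(num / comp)


def test_auc_matches_pair_counting():
    rng = np.random.default_rng(10)
    for _ in range(20):
        n = int(rng.integers(10, 101))
        y = rng.integers(0, 2, size=n)
        if y.min() == y.max():
            continue
        scores = np.round(rng.normal(size=n), 1)
        pos, neg = scores[y == 1], scores[y == 0]
        wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
        assert roc_auc_score(y, scores) == pytest.approx(wins / (len(pos) * len(neg)))


class TestSurvivalCv:
    def survival_data(self, rng, n=120, signal=2.0):
        X = rng.normal(size=(n, 5))
        eta = signal * X[:, 0]
        time = rng.exponential(1.0 / (0.1 * np.exp(eta)))
        censor = rng.exponential(np.quantile(time, 0.9), size=n)
        frame = pd.DataFrame(X, columns=[f"p{i}" for i in range(5)])
        survival = pd.DataFrame({
            "time": np.minimum(time, censor),
            "event": (time <= censor).astype(int),
        })
        return frame, survival

    def test_planted_hazard_signal_recovered(self):
        rng = np.random.default_rng(12)
        activity, survival = self.survival_data(rng)
        report = survival_cv(
            activity, survival, repeats=1, folds=3, seed=0,
            l1_ratio_grid=(0.5,), alpha_grid=(0.01, 0.1), inner_folds=3,
        )
        assert report["c_index"].mean() >= 0.65

    def test_nonpositive_times_rejected(self):
        activity = pd.DataFrame(np.ones((4, 2)))
        survival = pd.DataFrame({"time": [1.0, 0.0, 2.0, 3.0], "event": [1, 1, 1, 1]})
        with pytest.raises(ValueError, match="positive"):
            survival_cv(activity, survival)

    def test_bit_reproducible_under_fixed_seed(self):
        rng = np.random.default_rng(13)
        activity, survival = self.survival_data(rng, n=80)
        kwargs = dict(repeats=1, folds=3, seed=4, l1_ratio_grid=(0.5,),
                      alpha_grid=(0.05,), inner_folds=3)
        pd.testing.assert_frame_equal(
            survival_cv(activity, survival, **kwargs),
            survival_cv(activity, survival, **kwargs),
        )


def balanced_table(rng, n_db=2, n_ds=2, reps=5):
    rows = []
    for db in range(n_db):
        for ds in range(n_ds):
            for _ in range(reps):
                rows.append({
                    "performance": rng.normal(0.8 + 0.02 * db - 0.03 * ds, 0.05),
                    "database": f"db{db}",
                    "dataset": f"ds{ds}",
                })
    return pd.DataFrame(rows)


def anova_oracle(table):
    """Textbook balanced two-way ANOVA sums of squares, by cell means."""
    grand = table["performance"].mean()
    cell = table.groupby(["database", "dataset"])["performance"]
    a_means = table.groupby("database")["performance"].mean()
    b_means = table.groupby("dataset")["performance"].mean()
    counts = cell.size()
    r = counts.iloc[0]
    a, b = len(a_means), len(b_means)
    ss_a = b * r * ((a_means - grand) ** 2).sum()
    ss_b = a * r * ((b_means - grand) ** 2).sum()
    cell_means = cell.mean()
    ss_cells = r * ((cell_means - grand) ** 2).sum()
    ss_ab = ss_cells - ss_a - ss_b
    ss_total = ((table["performance"] - grand) ** 2).sum()
    ss_err = ss_total - ss_cells
    df_a, df_err = a - 1, a * b * (r - 1)
    f_a = (ss_a / df_a) / (ss_err / df_err)
    return ss_a, ss_b, ss_ab, ss_err, ss_total, f_a


class TestPerformanceAnova:
    def test_matches_textbook_sums_of_squares(self):
        table = balanced_table(np.random.default_rng(20))
        f_db, p_db, anova = performance_anova(table)
        ss_a, ss_b, ss_ab, ss_err, ss_total, f_a = anova_oracle(table)
        assert f_db == pytest.approx(f_a, abs=1e-8)
        assert anova.loc["C(database)", "sum_sq"] == pytest.approx(ss_a, abs=1e-9)
        assert anova.loc["C(database):C(dataset)", "sum_sq"] == pytest.approx(ss_ab, abs=1e-9)
        assert anova["sum_sq"].sum() == pytest.approx(ss_total, abs=1e-9)
        assert 0 <= p_db <= 1

    def test_location_invariance_of_f(self):
        table = balanced_table(np.random.default_rng(21))
        shifted = table.assign(performance=table["performance"] + 10.0)
        f_base, _, _ = performance_anova(table)
        f_shift, _, _ = performance_anova(shifted)
        assert f_shift == pytest.approx(f_base, rel=1e-9)

    def test_single_level_factor_rejected(self):
        table = balanced_table(np.random.default_rng(22))
        table["database"] = "only"
        with pytest.raises(ValueError, match="single level"):
            performance_anova(table)

    def test_empty_cell_named_in_error(self):
        table = balanced_table(np.random.default_rng(23))
        table = table[~((table["database"] == "db1") & (table["dataset"] == "ds0"))]
        with pytest.raises(ValueError, match=r"db1.*ds0"):
            performance_anova(table)

    def test_constant_response_rejected(self):
        table = balanced_table(np.random.default_rng(25))
        table["performance"] = 1.0  # e.g. a fully saturated AUC
        with pytest.raises(ValueError, match="constant"):
            performance_anova(table)

    def test_underreplicated_cell_rejected(self):
        table = balanced_table(np.random.default_rng(24), reps=5)
        drop = table[(table["database"] == "db0") & (table["dataset"] == "ds0")].index[1:]
        with pytest.raises(ValueError, match="<2 replicates"):
            performance_anova(table.drop(drop))


class TestPairwiseWilcoxonBh:
    def test_identical_vectors_give_unit_q(self):
        x = np.array([0.7, 0.8, 0.9, 0.85])
        result = pairwise_wilcoxon_bh({"a": x, "b": x.copy()})
        assert result["p_value"][0] == pytest.approx(1.0)
        assert result["q_value"][0] == pytest.approx(1.0)

    def test_all_pairs_tested(self):
        rng = np.random.default_rng(30)
        result = pairwise_wilcoxon_bh({f"db{i}": rng.normal(size=8) for i in range(4)})
        assert len(result) == 6
        assert np.all(result["q_value"] >= result["p_value"] - 1e-12)

    def test_short_vector_skipped_with_warning(self, caplog):
        rng = np.random.default_rng(31)
        with caplog.at_level("WARNING"):
            result = pairwise_wilcoxon_bh(
                {"a": rng.normal(size=8), "b": [0.1, 0.2], "c": rng.normal(size=8)}
            )
        assert len(result) == 1
        assert "fewer than 3" in caplog.text

    def test_single_database_rejected(self):
        with pytest.raises(ValueError):
            pairwise_wilcoxon_bh({"a": np.ones(5)})
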