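import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from poolsig import (
    EvalReport,
    auc_rank,
    balance_check,
    evaluate,
    fit_ann,
    fit_composite,
    fit_dt,
    fit_lr,
    integrate_importance,
    make_splits,
    select_cv_sets,
)
from poolsig.models import Split


def noisy_dataset(rng, n=160, p=30, n_signal=4, shift=0.8, prevalence=0.35):
    """Weak-signal classification set where flexible models overfit."""
    y = (rng.random(n) < prevalence).astype(int)
    x = rng.standard_normal((n, p))
    x[y == 1, :n_signal] += shift
    cols = [f"v{i:02d}" for i in range(p)]
    return pd.DataFrame(x, columns=cols), y


class TestSplits:
    def test_partition_property(self, rng):
        ids = [f"s{i}" for i in range(757)]
        splits = make_splits(ids, (370, 387), rounds=3, rng=rng)
        for s in splits:
            assert len(s.train_ids) == 370 and len(s.test_ids) == 387
            assert not set(s.train_ids) & set(s.test_ids)
            assert set(s.train_ids) | set(s.test_ids) == set(ids)

    def test_deterministic_per_seed(self):
        ids = list(range(20))
        a = make_splits(ids, (9, 11), rounds=1, rng=np.random.default_rng(5))
        b = make_splits(ids, (9, 11), rounds=1, rng=np.random.default_rng(5))
        assert a[0].train_ids == b[0].train_ids

    def test_size_mismatch_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            make_splits(list(range(10)), (4, 5), rounds=1)

    def test_empty_partition_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            make_splits(list(range(10)), (0, 10), rounds=1)


class TestBalanceCheck:
    def test_identical_halves_give_p_one(self):
        base = pd.DataFrame(
            {"x": np.r_[np.arange(10.0), np.arange(10.0)], "g": [1, 2] * 10},
            index=[f"s{i}" for i in range(20)],
        )
        split = Split([f"s{i}" for i in range(10)], [f"s{i}" for i in range(10, 20)])
        report = balance_check(split, base, categorical=("g",))
        assert (report["p"] > 0.95).all()

    def test_perfect_separation_flags_low_p(self):
        data = pd.DataFrame(
            {"x": np.r_[np.zeros(30), np.ones(30) * 5]},
            index=[f"s{i}" for i in range(60)],
        )
        split = Split([f"s{i}" for i in range(30)], [f"s{i}" for i in range(30, 60)])
        report = balance_check(split, data)
        assert report.loc[0, "p"] < 1e-6

    def test_constant_variable_flagged(self):
        data = pd.DataFrame({"x": np.ones(10)}, index=[f"s{i}" for i in range(10)])
        split = Split([f"s{i}" for i in range(5)], [f"s{i}" for i in range(5, 10)])
        report = balance_check(split, data)
        assert report.loc[0, "p"] == 1.0 and bool(report.loc[0, "flagged"])

    def test_null_variables_imbalanced_at_alpha_rate(self, rng):
        """~5% of null variables show p < 0.05 between random halves."""
        n, v = 300, 106
        data = pd.DataFrame(
            rng.standard_normal((n, v)),
            index=[f"s{i}" for i in range(n)],
            columns=[f"x{i}" for i in range(v)],
        )
        counts = []
        for split in make_splits(data.index, (150, 150), rounds=10, rng=rng):
            counts.append((balance_check(split, data)["p"] < 0.05).sum())
        assert 1 <= np.mean(counts) <= 11  # binomial(106, .05): mean 5.3


class TestSelectCvSets:
    def _with_counts(self, counts):
        splits = []
        for i, c in enumerate(counts):
            s = Split([i], [i])
            s.balance = pd.DataFrame({"variable": range(20), "p": [0.01] * c + [0.5] * (20 - c)})
            splits.append(s)
        return splits

    def test_ties_resolve_by_index(self):
        splits = self._with_counts([2, 2, 2, 2])
        out = select_cv_sets(splits, m=2)
        assert out == splits[:2]

    def test_most_balanced_first(self):
        splits = self._with_counts([5, 0, 7, 3])
        out = select_cv_sets(splits, m=2)
        assert out[0] is splits[1] and out[1] is splits[3]

    def test_too_few_candidates_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            select_cv_sets(self._with_counts([1]), m=2)


class TestDecisionTree:
    def test_perfect_separator_gives_depth_one_full_accuracy(self):
        x = pd.DataFrame({"a": np.r_[np.zeros(20), np.ones(20)], "b": np.zeros(40)})
        y = np.r_[np.zeros(20), np.ones(20)].astype(int)
        m = fit_dt(x, y)
        assert m.estimator.get_depth() == 1
        assert (m.predict_proba(x).round() == y).all()
        assert m.importance["b"] == 0.0

    def test_pure_noise_prunes_to_majority(self, rng):
        x = pd.DataFrame(rng.standard_normal((200, 10)), columns=[f"v{i}" for i in range(10)])
        y = (rng.random(200) < 0.3).astype(int)
        m = fit_dt(x, y, seed=0)
        preds = (m.predict_proba(x) >= 0.5).astype(int)
        assert (preds == 0).mean() > 0.9  # collapses to the majority class

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single-class"):
            fit_dt(pd.DataFrame({"a": [1.0, 2.0]}), [1, 1])


class TestLogisticRegression:
    def test_null_predictors_give_prevalence_intercept(self, rng):
        x = pd.DataFrame(rng.standard_normal((400, 5)), columns=list("abcde"))
        y = (rng.random(400) < 0.3).astype(int)
        m = fit_lr(x, y)
        prev = y.mean()
        assert m.estimator.intercept_[0] == pytest.approx(np.log(prev / (1 - prev)), abs=0.3)
        assert m.importance.max() < 0.4

    def test_strong_predictor_ranks_first(self, rng):
        x = pd.DataFrame(rng.standard_normal((300, 6)), columns=list("abcdef"))
        y = (x["c"] + 0.3 * rng.standard_normal(300) > 0).astype(int)
        m = fit_lr(x, y)
        assert m.importance.idxmax() == "c"

    def test_separable_data_finite_coefficients(self):
        x = pd.DataFrame({"a": np.r_[-np.arange(1, 21.0), np.arange(1, 21.0)]})
        y = np.r_[np.zeros(20), np.ones(20)].astype(int)
        m = fit_lr(x, y)
        assert np.isfinite(m.estimator.coef_).all()
        assert ((m.predict_proba(x) >= 0.5).astype(int) == y).all()


class TestAnn:
    def test_linearly_separable_reaches_full_accuracy(self):
        x = pd.DataFrame({"a": np.r_[-np.arange(1, 31.0), np.arange(1, 31.0)],
                          "b": np.zeros(60)})
        y = np.r_[np.zeros(30), np.ones(30)].astype(int)
        m = fit_ann(x, y, f=1.0, seed=0)
        assert ((m.predict_proba(x) >= 0.5).astype(int) == y).mean() == 1.0

    def test_null_labels_give_chance_auc(self, rng):
        x = pd.DataFrame(rng.standard_normal((200, 8)))
        x.columns = [f"v{i}" for i in range(8)]
        y = (rng.random(200) < 0.5).astype(int)
        m = fit_ann(x, y, f=1.0, seed=1)
        x_test = pd.DataFrame(rng.standard_normal((200, 8)), columns=x.columns)
        y_test = (rng.random(200) < 0.5).astype(int)
        auc = auc_rank(m.predict_proba(x_test), y_test)
        assert 0.35 < auc < 0.65

    def test_invalid_prevention_fraction(self):
        with pytest.raises(ValueError, match="fraction"):
            fit_ann(pd.DataFrame({"a": [1.0, 2.0]}), [0, 1], f=0.0)

    def test_overtraining_prevention_reduces_extrapolation_gap(self):
        """The held-out early-stopped network extrapolates better (smaller
        train-test ACC difference) than the fixed-budget network, on
        average over seeds."""
        gaps80, gaps100 = [], []
        for seed in range(4):
            rng = np.random.default_rng(100 + seed)
            x, y = noisy_dataset(rng)
            xt, yt = noisy_dataset(rng)
            m80 = fit_ann(x, y, f=0.8, seed=seed)
            m100 = fit_ann(x, y, f=1.0, seed=seed)
            gaps80.append(evaluate(m80, x, y, xt, yt).d_acc)
            gaps100.append(evaluate(m100, x, y, xt, yt).d_acc)
        assert np.mean(gaps80) <= np.mean(gaps100)


class TestComposites:
    def test_head_uses_subset_of_tree_variables(self, rng):
        x, y = noisy_dataset(rng)
        m = fit_composite(x, y, head="lr", seed=0, fallback_genes=list(x.columns))
        assert m.selected_variables is not None
        assert set(m.variables) <= set(x.columns)
        assert m.variables == m.selected_variables

    def test_single_selected_variable_gives_univariate_head(self):
        x = pd.DataFrame({"a": np.r_[np.zeros(30), np.ones(30)],
                          "b": np.zeros(60)})
        y = np.r_[np.zeros(30), np.ones(30)].astype(int)
        m = fit_composite(x, y, head="lr", fallback_genes=["a", "b"])
        assert m.variables == ["a"]

    def test_da80_extrapolates_best_among_composites(self):
        """Early-stopped composite shows the smallest train-test gap."""
        gaps = {"dl": [], "da80": [], "da100": []}
        for seed in range(4):
            rng = np.random.default_rng(200 + seed)
            x, y = noisy_dataset(rng)
            xt, yt = noisy_dataset(rng)
            for kind, head, f in (("dl", "lr", 1.0), ("da80", "ann", 0.8), ("da100", "ann", 1.0)):
                m = fit_composite(x, y, head=head, f=f, seed=seed, fallback_genes=list(x.columns))
                gaps[kind].append(evaluate(m, x, y, xt, yt).d_acc)
        assert np.mean(gaps["da80"]) <= np.mean(gaps["da100"])
        assert np.mean(gaps["da80"]) <= min(np.mean(gaps["dl"]), np.mean(gaps["da100"])) + 2.0


class TestEvaluate:
    def test_three_of_four_correct_is_75(self):
        class Fixed:
            variables = ["a"]
            scaler = None
            kind = "dt"

            def predict_proba(self, df):
                return np.array([0.9, 0.9, 0.9, 0.1])

        data = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0]})
        rep = evaluate(Fixed(), data, [1, 1, 0, 0], data, [1, 1, 0, 0])
        assert rep.acc_test == 75.0

    def test_perfect_ordering_gives_auc_100(self):
        class Fixed:
            kind = "lr"

            def predict_proba(self, df):
                return df["a"].to_numpy() / 10.0

        data = pd.DataFrame({"a": [1.0, 2.0, 8.0, 9.0]})
        rep = evaluate(Fixed(), data, [0, 0, 1, 1], data, [0, 0, 1, 1])
        assert rep.auc_test == 100.0

    def test_delta_identities(self):
        rep = EvalReport("dt", 93.63, 63.45, 94.02, 56.90)
        assert rep.d_acc == pytest.approx(30.18)
        assert rep.d_auc == pytest.approx(37.12, abs=1e-9)

    def test_auc_rank_matches_trapezoidal(self, rng):
        for _ in range(20):
            scores = rng.standard_normal(50)
            scores[:10] = np.round(scores[:10], 1)  # ties
            labels = rng.random(50) < 0.4
            if labels.all() or (~labels).all():
                continue
            assert auc_rank(scores, labels) == pytest.approx(
                roc_auc_score(labels, scores), abs=1e-10
            )


class TestIntegrateImportance:
    def _imp(self, order):
        return pd.Series(np.linspace(1, 0, len(order)), index=order)

    def test_identical_rankings_preserved(self):
        order = ["g1", "g2", "g3", "g4"]
        table = integrate_importance({k: self._imp(order) for k in ("dt", "lr", "ann80", "ann100")})
        assert list(table.index) == order
        assert list(table["integrated_rank"]) == [1, 2, 3, 4]

    def test_majority_top_rank_wins(self):
        """A variable ranked first in three of four models integrates to
        rank 1 when the models otherwise disagree uniformly."""
        g = ["ga", "gb", "gc", "gd"]
        imps = {
            "dt": self._imp(["gb", "ga", "gc", "gd"]),
            "lr": self._imp(["ga", "gc", "gd", "gb"]),
            "ann80": self._imp(["ga", "gd", "gb", "gc"]),
            "ann100": self._imp(["ga", "gb", "gc", "gd"]),
        }
        table = integrate_importance(imps)
        assert table.index[0] == "ga"

    def test_reversal_equivariance(self):
        order = ["g1", "g2", "g3"]
        fwd = integrate_importance({k: self._imp(order) for k in ("dt", "lr")})
        rev = integrate_importance({k: self._imp(order[::-1]) for k in ("dt", "lr")})
        assert list(rev.index) == list(fwd.index)[::-1]

    def test_missing_variable_gets_worst_rank_and_flag(self):
        imps = {
            "dt": self._imp(["g1", "g2", "g3"]),
            "lr": self._imp(["g1", "g2"]),  # g3 missing
        }
        table = integrate_importance(imps)
        assert bool(table.loc["g3", "flagged"])
        assert table.loc["g3", "lr"] == 3
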