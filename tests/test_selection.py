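import numpy as np
import pandas as pd
import pytest

from bgem.selection import (EnsembleFeatureSelector, drop_correlated,
                            ensemble_select, majority_vote, rank_features)


def _noise_matrix(n=200, p=60, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    y = rng.integers(0, 2, n)
    names = [f"F{i+1}" for i in range(p)]
    return pd.DataFrame(X, columns=names), y


class TestRankFeatures:
    @pytest.mark.parametrize("method", ["anova", "mutual_info", "lasso", "gbt"])
    def test_perfect_separator_ranks_first(self, method):
        X, y = _noise_matrix(seed=1)
        rng = np.random.default_rng(2)
        X["F7"] = y + 0.01 * rng.standard_normal(len(y))
        top = rank_features(X, y, method, random_state=0)
        assert top[0] == "F7"

    def test_deterministic_on_pure_noise(self):
        X, y = _noise_matrix(seed=3)
        for method in ("anova", "mutual_info", "rfe", "lasso", "gbt",
                       "dispersion_ratio"):
            a = rank_features(X, y, method, random_state=5)
            b = rank_features(X, y, method, random_state=5)
            assert a == b and len(a) == 30 and len(set(a)) == 30

    def test_anova_power_recovers_injected_effects(self):
        # 5 informative features at d = 1.0, n = 400
        hits = 0
        reps = 10
        for rep in range(reps):
            rng = np.random.default_rng(100 + rep)
            y = rng.integers(0, 2, 400)
            X = rng.standard_normal((400, 248))
            informative = [3, 50, 120, 200, 247]
            for j in informative:
                X[:, j] += 1.0 * y
            names = [f"F{i+1}" for i in range(248)]
            top = rank_features(pd.DataFrame(X, columns=names), y, "anova")
            hits += all(f"F{j+1}" in top for j in informative)
        assert hits >= 9  # >= 90% of replicates recover all five

    def test_constant_columns_rank_last_without_crashing(self):
        X, y = _noise_matrix(n=100, p=20, seed=4)
        X["F3"] = 1.0
        for method in ("anova", "dispersion_ratio", "lasso"):
            top = rank_features(X, y, method, top_k=20)
            assert top[-1] == "F3"


class TestMajorityVote:
    def test_vote_counts_and_exclusions(self):
        lists = {f"m{i}": ["A", "B", "C"] for i in range(6)}
        lists["m5"] = ["B", "C", "D"]  # D appears once only
        voted, counts = majority_vote(lists)
        assert counts["A"] == 5 and counts["D"] == 1
        assert "D" not in voted
        assert voted[0] in ("B", "C")  # vote 6 beats vote 5

    def test_tie_break_by_mean_rank(self):
        lists = {
            "m1": ["A", "X1", "B"], "m2": ["A", "X2", "B"],
            "m3": ["X3", "A", "B"],
        }
        # A: votes 3, mean rank (1+1+2)/3 = 1.33; B: votes 3, mean rank 3
        voted, _ = majority_vote(lists)
        assert voted.index("A") < voted.index("B")

    def test_hand_traced_mean_ranks(self):
        lists = {
            "m1": ["P", "Q"], "m2": ["P", "Q"], "m3": ["Q", "P"],
            "m4": ["R"], "m5": ["R"], "m6": [],
        }
        # P mean rank 4/3, Q mean rank 5/3 (both vote 3); R vote 2
        voted, counts = majority_vote(lists)
        assert voted == ["P", "Q", "R"]


class TestDropCorrelated:
    def test_identical_columns_keep_higher_ranked(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal(100)
        X = pd.DataFrame({"A": a, "B": a.copy(), "C": rng.standard_normal(100)})
        kept = drop_correlated(X, ["A", "B", "C"], threshold=0.9)
        assert kept == ["A", "C"]

    def test_orthogonal_columns_all_survive(self):
        X = pd.DataFrame(np.eye(4), columns=list("ABCD"))
        kept = drop_correlated(X, list("ABCD"), threshold=0.9)
        assert kept == list("ABCD")

    def test_greedy_chain_keeps_ends(self):
        rng = np.random.default_rng(1)
        n = 4000
        a = rng.standard_normal(n)
        c = rng.standard_normal(n)
        lam = 0.95
        b = lam * a + np.sqrt(1 - lam**2) * (0.55 * c + np.sqrt(1 - 0.55**2)
                                             * rng.standard_normal(n))
        X = pd.DataFrame({"A": a, "B": b, "C": c})
        r_ab = np.corrcoef(a, b)[0, 1]
        r_ac = abs(np.corrcoef(a, c)[0, 1])
        assert r_ab > 0.9 and r_ac < 0.9  # fixture sanity
        kept = drop_correlated(X, ["A", "B", "C"], threshold=0.9)
        assert kept == ["A", "C"]


class TestEnsembleSelector:
    def test_same_input_same_result(self):
        X, y = _noise_matrix(n=150, p=40, seed=6)
        y = (X["F1"] + 0.5 * np.random.default_rng(0).standard_normal(150)
             > 0).astype(int)
        r1 = ensemble_select(X, y, seed=17)
        r2 = ensemble_select(X, y, seed=17)
        assert r1.per_method_top30 == r2.per_method_top30
        assert r1.pruned_set == r2.pruned_set

    def test_recovers_injected_informative_features(self):
        # 12 independent informative columns, d ~ 1.2, n = 400
        rng = np.random.default_rng(7)
        y = rng.integers(0, 2, 400)
        X = rng.standard_normal((400, 100))
        informative = list(range(0, 60, 5))
        for j in informative:
            X[:, j] += 1.2 * y
        names = [f"F{i+1}" for i in range(100)]
        res = ensemble_select(pd.DataFrame(X, columns=names), y, seed=0)
        recovered = sum(f"F{j+1}" in res.pruned_set for j in informative)
        assert recovered >= 9

    def test_force_include_adds_unvoted_feature(self):
        X, y = _noise_matrix(n=150, p=40, seed=8)
        sel = EnsembleFeatureSelector(random_state=0,
                                      force_include=("F40",))
        sel.fit(X, y)
        assert "F40" in sel.result_.pruned_set

    def test_pruned_set_pairwise_correlation_bound(self):
        rng = np.random.default_rng(9)
        y = rng.integers(0, 2, 300)
        base = rng.standard_normal((300, 30))
        X = np.hstack([base, base[:, :10] + 0.05 * rng.standard_normal((300, 10))])
        names = [f"F{i+1}" for i in range(40)]
        sel = EnsembleFeatureSelector(random_state=0)
        sel.fit(pd.DataFrame(X, columns=names), y + 0)
        kept = sel.result_.pruned_set
        mat = pd.DataFrame(X, columns=names)[kept].corr().abs().to_numpy()
        np.fill_diagonal(mat, 0.0)
        assert mat.max() <= sel.corr_threshold + 1e-12

    def test_transform_selects_pruned_columns(self):
        X, y = _noise_matrix(n=120, p=30, seed=10)
        sel = EnsembleFeatureSelector(random_state=1)
        Xt = sel.fit(X, y).transform(X.to_numpy())
        assert Xt.shape == (120, len(sel.result_.pruned_set))

    def test_nan_rows_handled_by_median_imputation(self):
        X, y = _noise_matrix(n=150, p=30, seed=11)
        X.iloc[:20, 25:] = np.nan  # e.g. missing MSE block
        res = ensemble_select(X, y, seed=0)
        assert len(res.per_method_top30) == 6
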