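"""Differential-expression calling: exact test, normalization, DE rule,
time-specificity accounting."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cerna_scope import (
    TimeSpecificitySummary,
    call_de,
    exact_null_pvalue_distribution,
    mann_whitney_exact,
    quantile_normalize,
    time_specificity,
)
from conftest import make_matrix


def mw_brute_force(case, control):
    """Independent oracle: pair-counting U enumerated over all assignments."""
    pooled = list(case) + list(control)
    n1 = len(case)

    def u_stat(c_idx):
        c = [pooled[i] for i in c_idx]
        d = [pooled[i] for i in range(len(pooled)) if i not in c_idx]
        return sum(
            1.0 if x > y else 0.5 if x == y else 0.0 for x in c for y in d
        )

    all_u = [u_stat(set(idx)) for idx in itertools.combinations(range(len(pooled)), n1)]
    u_obs = u_stat(set(range(n1)))
    p_le = sum(u <= u_obs + 1e-9 for u in all_u) / len(all_u)
    p_ge = sum(u >= u_obs - 1e-9 for u in all_u) / len(all_u)
    return min(1.0, 2.0 * min(p_le, p_ge))


class TestMannWhitneyExact:
    def test_complete_separation_is_two_over_seventy(self):
        p = mann_whitney_exact([8, 9, 10, 11], [1, 2, 3, 4])
        assert math.isclose(p, 2 / 70)

    def test_equal_multisets_give_p_one(self):
        assert mann_whitney_exact([1, 2, 3, 4], [4, 3, 2, 1]) == 1.0

    def test_all_tied_values_give_p_one_not_error(self):
        assert mann_whitney_exact([5, 5, 5], [5, 5, 5, 5]) == 1.0

    def test_minimum_attainable_p_at_4v4(self):
        dist = exact_null_pvalue_distribution(4, 4)
        assert math.isclose(dist.index.min(), 2 / 70)
        # any call at p <= 0.05 therefore needs (near-)complete separation
        assert all(p > 0.05 for p in dist.index if p != pytest.approx(2 / 70))
        assert math.isclose(dist.sum(), 1.0)

    def test_matches_brute_force_with_ties(self, rng):
        for _ in range(50):
            vals = rng.integers(0, 6, size=8)  # heavy ties
            p = mann_whitney_exact(vals[:4], vals[4:])
            assert math.isclose(p, mw_brute_force(vals[:4], vals[4:]), rel_tol=1e-12)

    def test_large_samples_use_normal_approximation(self, rng):
        case = rng.normal(1.0, 1.0, size=10)
        control = rng.normal(0.0, 1.0, size=10)
        expected = stats.mannwhitneyu(
            case, control, alternative="two-sided", method="asymptotic"
        ).pvalue
        assert math.isclose(mann_whitney_exact(case, control), expected, rel_tol=1e-12)

    def test_rejects_tiny_groups(self):
        with pytest.raises(ValueError):
            mann_whitney_exact([1.0], [2.0, 3.0])


class TestQuantileNormalize:
    def test_identical_columns_unchanged(self):
        mat = make_matrix(np.array([[1.0, 1.0, 1.0, 1.0], [2, 2, 2, 2], [3, 3, 3, 3]]))
        out = quantile_normalize(mat)
        np.testing.assert_allclose(out.values.to_numpy(), mat.values.to_numpy())

    def test_rank_mean_by_hand(self):
        # two columns at (1,2,3) and two at (4,5,6): per-rank means 2.5, 3.5, 4.5
        mat = make_matrix(
            np.array([[1.0, 1.0, 4.0, 4.0], [2.0, 2.0, 5.0, 5.0], [3.0, 3.0, 6.0, 6.0]])
        )
        out = quantile_normalize(mat)
        expected = np.tile([[2.5], [3.5], [4.5]], (1, 4))
        np.testing.assert_allclose(out.values.to_numpy(), expected)

    def test_columns_share_sorted_multiset(self, rng):
        mat = make_matrix(rng.lognormal(3, 1, size=(40, 8)))
        out = quantile_normalize(mat).values.to_numpy()
        ref = np.sort(out[:, 0])
        for j in range(1, out.shape[1]):
            np.testing.assert_allclose(np.sort(out[:, j]), ref)


class TestCallDE:
    def _planted(self, fc, sep=True):
        # 4 vs 4 with complete separation (p = 2/70) and exact mean ratio fc
        control = np.array([10.0, 10.0, 10.0, 10.0])
        case = control * fc + (np.array([0.1, 0.2, 0.3, 0.4]) if sep else 0.0)
        case = case - case.mean() + 10.0 * fc  # keep exact mean ratio
        return np.concatenate([case, control])

    def test_direction_rule(self):
        rows = np.vstack(
            [
                self._planted(3.54),     # up
                self._planted(1.49),     # separated but below FC threshold
                self._planted(1.0 / 2),  # down
                np.array([10, 11, 9, 10.5, 10.2, 9.8, 10.1, 10.6]),  # no separation
            ]
        )
        de = call_de(make_matrix(rows), fc_threshold=1.5, p_threshold=0.05)
        assert list(de["direction"]) == ["up", "none", "down", "none"]
        assert de.loc[0, "fold_change"] == pytest.approx(3.54)
        assert de.loc[1, "p_value"] <= 0.05  # fails on FC alone

    def test_fdr_at_least_p(self, rng):
        de = call_de(make_matrix(rng.lognormal(3, 0.3, size=(100, 8))))
        assert (de["fdr"] >= de["p_value"] - 1e-12).all()

    def test_fc_symmetry_under_label_swap(self, rng):
        values = rng.lognormal(3, 0.5, size=(30, 8))
        de_fwd = call_de(make_matrix(values))
        de_rev = call_de(make_matrix(np.concatenate([values[:, 4:], values[:, :4]], axis=1)))
        np.testing.assert_allclose(
            de_rev["fold_change"], 1.0 / de_fwd["fold_change"], rtol=1e-12
        )
        np.testing.assert_allclose(de_rev["p_value"], de_fwd["p_value"], rtol=1e-12)
        flip = {"up": "down", "down": "up", "none": "none"}
        assert list(de_rev["direction"]) == [flip[d] for d in de_fwd["direction"]]

    def test_raising_fc_threshold_never_adds_calls(self, rng):
        mat = make_matrix(rng.lognormal(3, 0.8, size=(200, 8)))
        counts = [
            (call_de(mat, fc_threshold=fc)["direction"] != "none").sum()
            for fc in (1.0, 1.5, 2.0, 3.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_log_scale_fold_change_option(self):
        values = np.array([[2.0, 8.0, 4.0, 4.0, 1.0, 1.0, 1.0, 1.0]])
        de = call_de(make_matrix(values), log_scale_fc=True)
        assert de.loc[0, "fold_change"] == pytest.approx(4.0)  # geometric mean ratio

    def test_null_pvalues_follow_exact_null_distribution(self, rng):
        """Goodness of fit of null p-values to the attainable 4-vs-4 set."""
        mat = make_matrix(rng.lognormal(3, 0.5, size=(2000, 8)))
        de = call_de(mat)
        dist = exact_null_pvalue_distribution(4, 4)
        observed = de["p_value"].round(10).value_counts()
        obs = np.array([observed.get(round(p, 10), 0) for p in dist.index])
        chi2_p = stats.chisquare(obs, dist.to_numpy() * len(de)).pvalue
        assert obs.sum() == len(de)
        assert chi2_p > 0.001


class TestTimeSpecificity:
    @pytest.mark.parametrize(
        "n1, n2, n_both, distinct, specific, pct",
        [
            (101, 12, 2, 111, 109, 98.2),
            (163, 121, 65, 219, 154, 70.3),
            (1108, 1534, 228, 2414, 2186, 90.6),
            (10, 5, 0, 15, 15, 100.0),
        ],
    )
    def test_counts_arithmetic(self, n1, n2, n_both, distinct, specific, pct):
        s = TimeSpecificitySummary.from_counts(n1, n2, n_both)
        assert (s.n_distinct, s.n_specific) == (distinct, specific)
        assert round(s.fraction_specific, 1) == pct

    def test_from_de_tables(self):
        def table(dirs):
            return pd.DataFrame(
                {
                    "feature_id": [f"g{i}" for i in range(len(dirs))],
                    "fold_change": 1.0,
                    "p_value": 1.0,
                    "fdr": 1.0,
                    "direction": dirs,
                }
            )

        t1 = table(["up", "down", "none", "up", "none"])
        t2 = table(["none", "down", "up", "none", "none"])
        s = time_specificity(t1, t2)
        assert (s.n_time1, s.n_time2, s.n_both) == (3, 2, 1)
        assert s.fraction_specific == pytest.approx(100 * 3 / 4)

    def test_disjoint_universes_error_names_mismatch(self):
        t1 = pd.DataFrame({"feature_id": ["a"], "direction": ["up"]})
        t2 = pd.DataFrame({"feature_id": ["b"], "direction": ["up"]})
        with pytest.raises(ValueError, match="universes differ"):
            time_specificity(t1, t2)
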