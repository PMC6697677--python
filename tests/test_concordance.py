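"""Contingency construction, odds-ratio/Woolf/chi-square statistics and the
miRNA-adjusted logistic model."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cerna_scope import (
    ContingencyTable,
    adjusted_logistic,
    build_contingency,
    odds_ratio_test,
    relevant_direction,
)


def de_table(ids, directions):
    return pd.DataFrame(
        {"feature_id": list(ids), "fold_change": 1.0, "p_value": 1.0,
         "fdr": 1.0, "direction": list(directions)}
    )


class TestDirectionRules:
    @pytest.mark.parametrize(
        "up, relation, expected",
        [
            ("up", "miRNA->mRNA", "down"),
            ("down", "miRNA->mRNA", "up"),
            ("up", "circRNA->miRNA", "down"),
            ("up", "circRNA->mRNA", "up"),
            ("down", "circRNA->mRNA", "down"),
        ],
    )
    def test_sponge_model_defaults(self, up, relation, expected):
        assert relevant_direction(up, relation) == expected


class TestBuildContingency:
    def test_manual_count(self):
        # universe of 10 mRNAs: 4 targeted (2 up), 6 untargeted (1 up)
        ids = [f"g{i}" for i in range(10)]
        dirs = ["up", "up", "none", "none", "up", "none", "none", "none", "none", "none"]
        table = build_contingency(set(ids[:4]), de_table(ids, dirs), "up")
        assert (table.a, table.b, table.c, table.d) == (2, 2, 1, 5)

    def test_cells_partition_universe(self, rng):
        ids = [f"g{i}" for i in range(200)]
        dirs = rng.choice(["up", "down", "none"], size=200)
        targeted = set(rng.choice(ids, size=60, replace=False))
        table = build_contingency(targeted, de_table(ids, dirs), "down")
        assert table.universe_size == 200

    def test_no_upstream_targets_is_degenerate(self):
        table = build_contingency(set(), de_table(["g1", "g2"], ["up", "none"]), "up")
        assert (table.a, table.b) == (0, 0) and table.degenerate

    def test_targeted_equals_universe_is_degenerate(self):
        ids = ["g1", "g2", "g3"]
        table = build_contingency(set(ids), de_table(ids, ["up", "none", "none"]), "up")
        assert (table.c, table.d) == (0, 0) and table.degenerate

    def test_empty_universe_errors(self):
        with pytest.raises(ValueError, match="empty universe"):
            build_contingency(set(), de_table([], []), "up", universe=set())


class TestOddsRatioTest:
    def test_woolf_hand_arithmetic(self):
        res = odds_ratio_test(ContingencyTable(20, 80, 10, 890))
        assert res.odds_ratio == pytest.approx(22.25)
        assert res.ci_low == pytest.approx(10.07, abs=0.01)
        assert res.ci_high == pytest.approx(49.17, abs=0.01)
        assert res.p_value < 1e-10 and not res.correction_applied

    @pytest.mark.parametrize("k", [1, 5, 40])
    def test_symmetric_table_is_null(self, k):
        res = odds_ratio_test(ContingencyTable(k, k, k, k))
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)

    def test_zero_cell_gets_haldane_correction(self):
        res = odds_ratio_test(ContingencyTable(0, 10, 5, 85))
        assert res.correction_applied and not res.undefined
        assert res.odds_ratio == pytest.approx((0.5 * 85.5) / (10.5 * 5.5))
        # p still from the uncorrected chi-square
        expected_p = stats.chi2_contingency(
            [[0, 10], [5, 85]], correction=False
        )[1]
        assert res.p_value == pytest.approx(expected_p)

    def test_zero_margin_is_undefined_with_p_one(self):
        res = odds_ratio_test(ContingencyTable(0, 0, 5, 95))
        assert res.undefined and res.p_value == 1.0 and math.isnan(res.odds_ratio)

    def test_or_invariance_under_swaps(self, rng):
        for _ in range(20):
            a, b, c, d = rng.integers(1, 50, size=4)
            base = odds_ratio_test(ContingencyTable(a, b, c, d))
            both = odds_ratio_test(ContingencyTable(d, c, b, a))  # swap rows AND columns
            rows = odds_ratio_test(ContingencyTable(c, d, a, b))  # swap one
            assert both.odds_ratio == pytest.approx(base.odds_ratio)
            assert rows.odds_ratio == pytest.approx(1.0 / base.odds_ratio)
            assert rows.p_value == pytest.approx(base.p_value)

    def test_ci_brackets_or(self, rng):
        for _ in range(20):
            a, b, c, d = rng.integers(1, 50, size=4)
            res = odds_ratio_test(ContingencyTable(a, b, c, d))
            assert res.ci_low <= res.odds_ratio <= res.ci_high


class TestAdjustedLogistic:
    @staticmethod
    def _population(rng, n=4000, beta_circ=1.2, beta_mir=0.0, confounded=False):
        x_circ = rng.random(n) < 0.3
        if confounded:
            x_mir = np.where(x_circ, rng.random(n) < 0.6, rng.random(n) < 0.2)
        else:
            x_mir = rng.random(n) < 0.3
        logit = -2.0 + beta_circ * x_circ + beta_mir * x_mir
        y = rng.random(n) < 1 / (1 + np.exp(-logit))
        ids = [f"g{i}" for i in range(n)]
        de = de_table(ids, np.where(y, "up", "none"))
        circ_t = {i for i, f in zip(ids, x_circ) if f}
        mir_t = {i for i, f in zip(ids, x_mir) if f}
        return de, circ_t, mir_t, ids

    def test_no_confounding_matches_univariate(self, rng):
        de, circ_t, mir_t, ids = self._population(rng)
        adj = adjusted_logistic(de, "up", circ_t, mir_t)
        uni = odds_ratio_test(build_contingency(circ_t, de, "up"))
        assert adj.odds_ratio == pytest.approx(uni.odds_ratio, rel=0.15)
        assert adj.method == "logit"

    def test_empty_mirna_indicator_reduces_to_univariate(self, rng):
        de, circ_t, _, ids = self._population(rng, n=1000)
        adj = adjusted_logistic(de, "up", circ_t, set())
        uni = odds_ratio_test(build_contingency(circ_t, de, "up"))
        # one-binary-predictor logistic MLE equals the sample odds ratio
        assert adj.odds_ratio == pytest.approx(uni.odds_ratio, rel=1e-4)

    def test_confounding_shrinks_circ_or_toward_truth(self, rng):
        de, circ_t, mir_t, ids = self._population(
            rng, n=8000, beta_circ=0.8, beta_mir=1.5, confounded=True
        )
        adj = adjusted_logistic(de, "up", circ_t, mir_t)
        uni = odds_ratio_test(build_contingency(circ_t, de, "up"))
        truth = math.exp(0.8)
        assert abs(math.log(adj.odds_ratio) - math.log(truth)) < abs(
            math.log(uni.odds_ratio) - math.log(truth)
        )

    def test_separation_falls_back_to_firth(self):
        ids = [f"g{i}" for i in range(60)]
        circ_t = set(ids[:30])
        de = de_table(ids, ["up"] * 30 + ["none"] * 30)  # y == x_circ exactly
        adj = adjusted_logistic(de, "up", circ_t, set())
        assert adj.method == "firth"
        assert np.isfinite(adj.odds_ratio) and adj.odds_ratio > 1

    def test_constant_circ_indicator_flagged_undefined(self):
        de = de_table(["g1", "g2", "g3"], ["up", "none", "none"])
        adj = adjusted_logistic(de, "up", set(), set())
        assert adj.undefined and adj.p_value == 1.0
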