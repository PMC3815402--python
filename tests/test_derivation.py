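"""Pooling, association statistics and CPT derivation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from syncopebayes import (
    CARDIAC,
    FULL_MODEL,
    NONCARDIAC,
    PredictorSpec,
    chi_square,
    counts_from_mean_sd,
    derive_cpts,
    likelihood_ratio,
    pool_counts,
    select_predictors,
)
from syncopebayes.datasets import (
    load_pooled_tables,
    load_study_counts,
    load_study_significance,
)
from syncopebayes.derivation import AssociationResult, PooledTable, StudyCounts
from syncopebayes.errors import (
    AlignmentError,
    DegenerateTableError,
    UndefinedRatioError,
)

BINARY = PredictorSpec("supine_syncope", ("yes", "no"), "yes")


def table(car, non, spec=BINARY):
    return PooledTable(spec, (tuple(car), tuple(non)))


# ---------------------------------------------------------------- pooling
class TestPooling:
    def test_pooled_cells_sum_study_cells(self):
        grouped = load_study_counts()
        supine = pool_counts(grouped["supine_syncope"])
        assert supine.row(CARDIAC) == (17, 153)  # 9 + 2 + 6 supine faints
        assert supine.row(NONCARDIAC) == (12, 495)
        effort = pool_counts(grouped["effort_syncope"])
        assert effort.row(CARDIAC) == (16, 106)  # 10 + 6
        assert effort.counts == ((16, 106), (9, 466))

    def test_single_study_pools_to_itself(self):
        s = StudyCounts("one", BINARY, {CARDIAC: (3, 4), NONCARDIAC: (1, 9)})
        pooled = pool_counts([s])
        assert pooled.counts == ((3, 4), (1, 9))

    def test_order_independent(self):
        grouped = load_study_counts()
        for tables in grouped.values():
            fwd = pool_counts(tables)
            rev = pool_counts(list(reversed(tables)))
            assert fwd == rev

    def test_unavailable_class_contributes_zero(self):
        a = StudyCounts("a", BINARY, {CARDIAC: (3, 4)})
        b = StudyCounts("b", BINARY, {CARDIAC: (1, 1), NONCARDIAC: (2, 5)})
        assert pool_counts([a, b]).counts == ((4, 5), (2, 5))

    def test_mismatched_predictors_rejected(self):
        other = PredictorSpec("effort_syncope", ("yes", "no"), "yes")
        a = StudyCounts("a", BINARY, {CARDIAC: (3, 4)})
        b = StudyCounts("b", other, {CARDIAC: (1, 1)})
        with pytest.raises(AlignmentError):
            pool_counts([a, b])

    def test_totals_are_consistent(self):
        for t in load_pooled_tables().values():
            arr = t.as_array()
            assert t.row_totals == tuple(arr.sum(axis=1).astype(int))
            assert t.col_totals == tuple(arr.sum(axis=0).astype(int))
            assert t.grand_total == int(arr.sum())


# ---------------------------------------------------------- chi-square
PRINTED_CHI2 = {
    "age_category": (171.7, 2),
    "gender": (25.4, 1),
    "number_of_spells": (44.0, 1),
    "nausea": (32.3, 1),
    "diaphoresis": (92.6, 1),
    "prodrome": (89.7, 1),
    "blurred_vision": (13.5, 1),
    "palpitations": (3.4, 1),
    "supine_syncope": (18.1, 1),
    "effort_syncope": (30.5, 1),
}


class TestChiSquare:
    @pytest.mark.parametrize("name", sorted(PRINTED_CHI2))
    def test_reproduces_published_statistics(self, pooled, name):
        expected, df = PRINTED_CHI2[name]
        res = chi_square(pooled[name])
        assert res.df == df
        assert round(res.chi2, 1) == pytest.approx(expected)
        assert 0.0 <= res.p_value <= 1.0

    def test_identical_row_proportions_give_zero(self):
        res = chi_square(table((10, 30), (20, 60)))
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_zero_marginal_is_degenerate(self):
        with pytest.raises(DegenerateTableError):
            chi_square(table((10, 0), (20, 0)))

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.integers(min_value=1, max_value=50), min_size=4, max_size=4))
    def test_agrees_with_observed_expected_oracle(self, cells):
        t = table(cells[:2], cells[2:])
        obs = t.as_array()
        row = obs.sum(axis=1, keepdims=True)
        col = obs.sum(axis=0, keepdims=True)
        exp = row * col / obs.sum()
        oracle = ((obs - exp) ** 2 / exp).sum()
        res = chi_square(t)
        assert res.chi2 == pytest.approx(oracle, abs=1e-9)
        assert res.p_value == pytest.approx(stats.chi2.sf(oracle, 1), abs=1e-12)


# ----------------------------------------------------- likelihood ratio
class TestLikelihoodRatio:
    @pytest.mark.parametrize(
        "name, expected",
        [
            ("gender", 1.30),
            ("number_of_spells", 1.84),
            ("diaphoresis", 1.42),
            ("supine_syncope", 4.23),
            ("effort_syncope", 6.92),
            ("nausea", 1.15),
            ("prodrome", 1.66),
            ("blurred_vision", 1.12),
        ],
    )
    def test_reproduces_published_ratios_at_cardiac_level(self, pooled, name, expected):
        assert round(likelihood_ratio(pooled[name]), 2) == pytest.approx(expected)

    def test_equal_class_proportions_give_one(self):
        assert likelihood_ratio(table((10, 30), (5, 15)), "yes") == pytest.approx(1.0)

    def test_ratio_times_noncardiac_probability_is_cardiac_probability(self, pooled):
        for t in pooled.values():
            if not t.predictor.is_binary:
                continue
            lr = likelihood_ratio(t)
            j = t.predictor.levels.index(t.predictor.cardiac_level)
            p_non = t.counts[1][j] / t.row_totals[1]
            p_car = t.counts[0][j] / t.row_totals[0]
            assert lr * p_non == pytest.approx(p_car, rel=1e-12)

    def test_zero_denominator_is_undefined(self):
        with pytest.raises(UndefinedRatioError):
            likelihood_ratio(table((5, 5), (0, 10)), "yes")

    def test_three_level_predictor_has_no_ratio(self, pooled):
        with pytest.raises(UndefinedRatioError):
            likelihood_ratio(pooled["age_category"])


# ------------------------------------------------- age-bin reconstruction
class TestCountsFromMeanSd:
    def test_normal_cdf_allocation(self):
        # CDF at one sd on either side of the mean: 15.9% / 68.3% / 15.9%
        assert counts_from_mean_sd(100, 50.0, 10.0, (40.0, 60.0)) == (16, 68, 16)

    def test_mass_far_below_first_edge(self):
        assert counts_from_mean_sd(10, 30.0, 1.0, (40.0, 60.0)) == (10, 0, 0)

    def test_zero_sd_goes_to_bin_containing_mean(self):
        assert counts_from_mean_sd(7, 50.0, 0.0, (40.0, 60.0)) == (0, 7, 0)
        # a mean on an edge falls in the upper bin
        assert counts_from_mean_sd(7, 60.0, 0.0, (40.0, 60.0)) == (0, 0, 7)

    @settings(max_examples=100, derandomize=True)
    @given(
        n=st.integers(min_value=1, max_value=5000),
        mean=st.floats(min_value=0, max_value=100, allow_nan=False),
        sd=st.floats(min_value=0, max_value=40, allow_nan=False),
    )
    def test_counts_always_sum_to_n(self, n, mean, sd):
        counts = counts_from_mean_sd(n, mean, sd, (40.0, 60.0))
        assert sum(counts) == n
        assert all(c >= 0 for c in counts)

    def test_invalid_edges_rejected(self):
        with pytest.raises(ValueError):
            counts_from_mean_sd(10, 50, 5, (60, 40))


# ------------------------------------------------------ predictor selection
class TestSelection:
    def test_bundled_fixtures_retain_the_ten_model_predictors(self, pooled):
        sig = load_study_significance()
        assoc = {n: chi_square(t) for n, t in pooled.items()}
        retained = select_predictors(sig, assoc)
        assert set(retained) == set(FULL_MODEL)

    def test_nonsignificant_pooled_association_excluded(self, pooled):
        sig = load_study_significance()
        assoc = {"palpitations": chi_square(pooled["palpitations"])}
        assert assoc["palpitations"].p_value > 0.05
        assert select_predictors(sig, assoc) == []

    def test_below_study_threshold_excluded(self):
        assoc = {"supine_syncope": AssociationResult(BINARY, 20.0, 1, 1e-5)}
        assert select_predictors({"supine_syncope": {"a", "b"}}, assoc) == []
        assert select_predictors({"supine_syncope": {"a", "b", "c"}}, assoc) == [
            "supine_syncope"
        ]


# ------------------------------------------------------------------ CPTs
class TestDeriveCpts:
    def test_nausea_class_conditional_probabilities(self, pooled):
        cpts = derive_cpts({"nausea": pooled["nausea"]}, {"pop": 0.21})
        assert cpts.prob("nausea", CARDIAC, "yes") == pytest.approx(34 / 424)
        assert cpts.prob("nausea", NONCARDIAC, "yes") == pytest.approx(307 / 1552)
        assert round(cpts.prob("nausea", CARDIAC, "yes"), 2) == 0.08
        assert round(cpts.prob("nausea", NONCARDIAC, "yes"), 2) == 0.20

    def test_rows_sum_to_one(self, results):
        for name, by_class in results.cpts.tables.items():
            for cls, probs in by_class.items():
                assert sum(probs.values()) == pytest.approx(1.0, abs=1e-12)
                assert all(0.0 <= p <= 1.0 for p in probs.values())

    def test_zero_column_gives_certain_level(self):
        t = table((8, 0), (5, 0))
        cpts = derive_cpts({"supine_syncope": t}, {"pop": 0.1})
        assert cpts.prob("supine_syncope", CARDIAC, "yes") == 1.0
        assert cpts.prob("supine_syncope", NONCARDIAC, "yes") == 1.0

    def test_zero_class_total_is_degenerate(self):
        spec = PredictorSpec("supine_syncope", ("yes", "no"), "yes")
        bad = PooledTable(spec, ((0, 0), (5, 5)))
        with pytest.raises(DegenerateTableError):
            derive_cpts({"supine_syncope": bad}, {"pop": 0.1})

    def test_priors_copied_through(self, results):
        priors = results.cpts.priors
        assert priors["calgary"] == pytest.approx(138 / 663)
        assert priors["milan"] == pytest.approx(37 / 689)
        assert all(0 < p < 1 for p in priors.values())
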