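"""Prevalence, conservation, Welch comparisons, concordance."""

import numpy as np
import pytest
from scipy import stats as sps

from hmoscreen.cohort_stats import (
    CohortStatsError,
    compare_groups,
    concordance,
    conservation,
    prevalence,
    welch_t_test,
)
from hmoscreen.growth import GrowthRecord
from hmoscreen.rules import PredictionRecord


def _table(n, carriers, gene="g"):
    return {f"s{i}": {gene: i < carriers} for i in range(n)}


class TestPrevalence:
    @pytest.mark.parametrize(
        "carriers,n,pct",
        [(43, 67, 64), (5, 13, 38), (47, 67, 70), (51, 67, 76), (0, 10, 0)],
    )
    def test_round_half_up_integer_percent(self, carriers, n, pct):
        res = prevalence(_table(n, carriers), "g")
        assert res.carrier_count == carriers
        assert res.cohort_size == n
        assert res.prevalence_pct == pct
        assert abs(res.prevalence_exact - res.prevalence_pct) <= 0.5

    def test_species_filter(self):
        table = _table(6, 3)
        species = {f"s{i}": ("B. longum" if i < 4 else "B. breve")
                   for i in range(6)}
        res = prevalence(table, "g", species, "B. longum")
        assert (res.carrier_count, res.cohort_size) == (3, 4)

    def test_empty_cohort_is_error(self):
        with pytest.raises(CohortStatsError):
            prevalence(_table(3, 1), "g", {f"s{i}": "x" for i in range(3)},
                       "B. breve")


class TestConservation:
    def test_constant_identities(self):
        res = conservation({"a": 99.0, "b": 99.0, "c": 99.0})
        assert (res.identity_mean, res.identity_sd) == (99.0, 0.0)

    def test_hand_computed_mean_and_sample_sd(self):
        # mean = 99.1; sample sd = sqrt((0.36 + 0 + 0.36)/2) = 0.6
        res = conservation({"a": 98.5, "b": 99.1, "c": 99.7})
        assert res.identity_mean == pytest.approx(99.1)
        assert res.identity_sd == pytest.approx(0.6)

    def test_single_carrier_flags_undefined_sd(self):
        res = conservation({"a": 97.0, "b": None})
        assert res.identity_mean == 97.0
        assert res.identity_sd == 0.0
        assert not res.sd_defined

    def test_no_carriers_is_error(self):
        with pytest.raises(CohortStatsError):
            conservation({"a": None})


def _growth(strain, substrate, delta, blank=0.10):
    reps = tuple(blank + delta for _ in range(3))
    category = "none" if delta < 0.4 else ("moderate" if delta < 1 else "good")
    return GrowthRecord(strain, substrate, reps, blank, delta, category)


class TestWelch:
    def test_hand_computed_example(self):
        t, df, p = welch_t_test([0.6, 0.7, 0.8], [0.2, 0.3, 0.4])
        assert t == pytest.approx(4.899, abs=1e-3)
        assert df == pytest.approx(4.0, abs=1e-9)
        assert p == pytest.approx(0.0081, abs=5e-4)

    def test_identical_groups(self):
        t, _, p = welch_t_test([0.5, 0.6, 0.7], [0.5, 0.6, 0.7])
        assert t == 0.0 and p == 1.0

    def test_equal_means_unequal_variances(self):
        t, _, _ = welch_t_test([0.4, 0.6], [0.1, 0.9])
        assert t == 0.0

    def test_antisymmetric(self):
        t1, df1, p1 = welch_t_test([1, 2, 3], [4, 5, 6.5])
        t2, df2, p2 = welch_t_test([4, 5, 6.5], [1, 2, 3])
        assert t1 == pytest.approx(-t2)
        assert df1 == pytest.approx(df2)
        assert p1 == pytest.approx(p2)

    def test_small_group_is_error(self):
        with pytest.raises(CohortStatsError):
            welch_t_test([1.0], [1.0, 2.0])

    def test_agrees_with_scipy_reference_on_random_pairs(self):
        """100 seeded random group pairs: |diff| < 1e-6 against
        scipy.stats.ttest_ind(equal_var=False) as the independent
        implementation."""
        rng = np.random.default_rng(12)
        for _ in range(100):
            a = rng.normal(rng.uniform(-1, 1), rng.uniform(0.5, 2),
                           size=rng.integers(3, 30))
            b = rng.normal(rng.uniform(-1, 1), rng.uniform(0.5, 2),
                           size=rng.integers(3, 30))
            t, _, p = welch_t_test(a, b)
            ref = sps.ttest_ind(a, b, equal_var=False)
            assert t == pytest.approx(ref.statistic, abs=1e-6)
            assert p == pytest.approx(ref.pvalue, abs=1e-6)


class TestCompareGroups:
    def test_strain_level(self):
        records = [_growth(f"a{i}", "LNT", d)
                   for i, d in enumerate([0.6, 0.7, 0.8])]
        records += [_growth(f"b{i}", "LNT", d)
                    for i, d in enumerate([0.2, 0.3, 0.4])]
        cmp = compare_groups(records, lambda s: s.startswith("a"), "LNT")
        assert cmp.welch_t == pytest.approx(4.899, abs=1e-3)
        assert (cmp.n_a, cmp.n_b) == (3, 3)

    def test_replicate_level_uses_wells(self):
        records = [_growth("a", "LNT", 0.7), _growth("a2", "LNT", 0.75),
                   _growth("b", "LNT", 0.3), _growth("b2", "LNT", 0.35)]
        cmp = compare_groups(records, lambda s: s.startswith("a"), "LNT",
                             level="replicate")
        assert (cmp.n_a, cmp.n_b) == (6, 6)

    def test_empty_group_is_error(self):
        records = [_growth("a", "LNT", 0.7)]
        with pytest.raises(CohortStatsError):
            compare_groups(records, lambda s: True, "LNT")


class TestConcordance:
    def _pred(self, strain, substrate, predicted):
        return PredictionRecord(strain, substrate, predicted, "r", ("x",))

    def test_perfect_agreement(self):
        preds = [self._pred("s1", "LNT", "growth"),
                 self._pred("s2", "LNT", "no_growth")]
        records = [_growth("s1", "LNT", 1.2), _growth("s2", "LNT", 0.1)]
        res = concordance(preds, records)
        assert res.agreement_pct == 100.0
        assert res.discordant == ()

    def test_false_negative_recorded_with_strain(self):
        preds = [self._pred("s1", "LNT", "no_growth")]
        records = [_growth("s1", "LNT", 1.3)]
        res = concordance(preds, records)
        assert res.per_substrate["LNT"]["FN"] == 1
        assert res.discordant == (("s1", "LNT", "FN"),)

    def test_missing_growth_record_names_strain_and_substrate(self):
        preds = [self._pred("s9", "LNnT", "growth")]
        with pytest.raises(CohortStatsError, match="s9.*LNnT"):
            concordance(preds, [])

    def test_empty_predictions_is_error(self):
        with pytest.raises(CohortStatsError):
            concordance([], [])
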