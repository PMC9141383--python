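"""TGS arithmetic, scheme definitions, distribution summaries and quartiles."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from tgsmdr import (
    GenotypeRecord,
    builtin_scheme,
    expected_tgs_distribution,
    expected_tgs_mean,
    load_published_frequencies,
    quartile_membership,
    score_cohort,
    score_individual,
    summarize_tgs,
    tgs_display,
)
from tgsmdr.scoring import TgsResult, kurtosis_se
from tgsmdr.simulate import published_study_spec, simulate_cohort

from conftest import make_record

NORM = 100.0 / 14.0


class TestBuiltinSchemes:
    def test_literature_maps(self):
        s = builtin_scheme("literature")
        assert s.component("COMT").as_dict() == {"AA": 2, "AG": 1, "GG": 0}
        assert s.component("ANKK1").as_dict() == {"GG": 2, "AG": 1, "AA": 0}
        assert s.component("APOE_e").as_dict() == {"e4-": 2, "e4+": 0}
        assert s.component("NOS3").as_dict() == {"TT": 2, "CT": 1, "CC": 0}
        assert s.normaliser == pytest.approx(NORM)

    def test_data_led_maps(self):
        s = builtin_scheme("data_led")
        assert s.component("COMT").as_dict() == {"GG": 2, "AG": 1, "AA": 0}
        assert s.component("APOE_rs405509").as_dict() == {"TT": 2, "GT": 1, "GG": 0}
        assert s.component("NOS3").as_dict() == {"TT": 2, "CT": 1, "CC": 0}

    def test_scheme_swap_changes_exactly_two_components(self):
        lit = builtin_scheme("literature")
        led = builtin_scheme("data_led")
        differing = {
            a.source
            for a, b in zip(lit.components, led.components)
            if a.as_dict() != b.as_dict()
        }
        assert differing == {"APOE_rs405509", "COMT"}

    def test_nos3_flipped_differs_only_in_nos3(self):
        lit = builtin_scheme("literature")
        flip = builtin_scheme("literature_nos3_flipped")
        differing = {
            a.source
            for a, b in zip(lit.components, flip.components)
            if a.as_dict() != b.as_dict()
        }
        assert differing == {"NOS3"}
        assert flip.component("NOS3").as_dict() == {"CC": 2, "CT": 1, "TT": 0}

    def test_unknown_scheme_lists_valid_names(self):
        with pytest.raises(ValueError, match="literature"):
            builtin_scheme("bogus")


class TestScoreIndividual:
    def test_perfect_profile_scores_100(self, perfect_record):
        res = score_individual(perfect_record, builtin_scheme("literature"))
        assert res.complete
        assert res.tgs == pytest.approx(100.0)
        assert set(res.component_scores.values()) == {2}

    def test_worst_profile_scores_0(self):
        rec = make_record(
            ANKK1="AA",
            APOE_rs429358="CC",
            APOE_rs7412="CC",  # e4/e4
            APOE_rs405509="TT",
            BDNF_AS="TT",
            COMT="GG",
            MAPT="TT",
            NOS3="CC",
        )
        res = score_individual(rec, builtin_scheme("literature"))
        assert res.tgs == pytest.approx(0.0)

    def test_sum_13_displays_92_9(self, perfect_record):
        rec = make_record(COMT="AG")  # six components at 2, one at 1
        res = score_individual(rec, builtin_scheme("literature"))
        assert sum(res.component_scores.values()) == 13
        assert tgs_display(res.tgs) == 92.9

    def test_sum_3_displays_21_4(self):
        # component scores (1, 0, 0, 1, 1, 0, 0)
        rec = make_record(
            ANKK1="AG",
            APOE_rs429358="CT",
            APOE_rs7412="CC",  # e3/e4 -> 0
            APOE_rs405509="TT",
            BDNF_AS="CT",
            COMT="AG",
            MAPT="TT",
            NOS3="CC",
        )
        res = score_individual(rec, builtin_scheme("literature"))
        assert sum(res.component_scores.values()) == 3
        assert tgs_display(res.tgs) == 21.4

    def test_all_scores_are_multiples_of_100_over_14(self):
        records = simulate_cohort(published_study_spec(2, athletes=100, non_athletes=100))
        grid = {round(k * NORM, 9) for k in range(15)}
        for res in score_cohort(records, builtin_scheme("data_led")):
            assert round(res.tgs, 9) in grid

    def test_monotone_in_component_scores(self):
        lit = builtin_scheme("literature")
        base = score_individual(make_record(COMT="GG"), lit)
        better = score_individual(make_record(COMT="AG"), lit)
        best = score_individual(make_record(COMT="AA"), lit)
        assert base.tgs < better.tgs < best.tgs

    def test_missing_component_complete_case(self):
        res = score_individual(make_record(COMT=None), builtin_scheme("literature"))
        assert not res.complete
        assert res.tgs is None
        assert res.component_scores["COMT"] is None

    def test_unresolvable_apoe_counts_as_missing(self):
        rec = make_record(APOE_rs429358="CC", APOE_rs7412="TT")  # forces e1/e1
        res = score_individual(rec, builtin_scheme("literature"))
        assert not res.complete

    def test_imputation_policy(self, published_table):
        rec = make_record(COMT=None)
        res = score_individual(
            rec, builtin_scheme("literature"), policy="impute",
            frequencies=published_table,
        )
        assert not res.complete
        f = published_table.frequencies["athlete"]["COMT"]
        expected = 2 * f["AA"] + 1 * f["AG"]
        assert res.component_scores["COMT"] == pytest.approx(expected)
        assert res.tgs == pytest.approx(NORM * (12 + expected))


class TestSummaries:
    @staticmethod
    def _results(values, group="g"):
        return [TgsResult(str(i), group, {}, v, True) for i, v in enumerate(values)]

    def test_constant_sample_kurtosis_not_applicable(self):
        s = summarize_tgs(self._results([50.0] * 10))
        assert s.sd == 0.0
        assert s.kurtosis is None and s.kurtosis_se is None

    def test_normal_sample_kurtosis_near_zero(self, rng):
        x = rng.normal(size=200_00)
        s = summarize_tgs(self._results(x))
        assert s.kurtosis == pytest.approx(0.0, abs=0.1)
        assert s.mean == pytest.approx(0.0, abs=0.05)

    def test_kurtosis_matches_manual_bias_corrected_formula(self, rng):
        x = rng.normal(size=500)
        n = len(x)
        m2 = np.mean((x - x.mean()) ** 2)
        m4 = np.mean((x - x.mean()) ** 4)
        g2 = m4 / m2**2 - 3
        manual = ((n + 1) * g2 + 6) * (n - 1) / ((n - 2) * (n - 3))
        s = summarize_tgs(self._results(x))
        assert s.kurtosis == pytest.approx(manual, rel=1e-10)

    def test_kurtosis_se_closed_form(self):
        n = 1000
        se_skew = np.sqrt(6 * n * (n - 1) / ((n - 2) * (n + 1) * (n + 3)))
        expected = 2 * se_skew * np.sqrt((n**2 - 1) / ((n - 3) * (n + 5)))
        assert kurtosis_se(n) == pytest.approx(expected, rel=1e-12)

    def test_kurtosis_se_matches_sampling_spread(self):
        """The closed-form SE should match the Monte-Carlo spread of the
        sample kurtosis of normal samples to ~10%."""
        rng = np.random.default_rng(12)
        n, reps = 200, 2000
        ks = sps.kurtosis(rng.normal(size=(reps, n)), axis=1, fisher=True, bias=False)
        assert np.std(ks) == pytest.approx(kurtosis_se(n), rel=0.12)

    def test_requires_four_complete(self):
        with pytest.raises(ValueError):
            summarize_tgs(self._results([1.0, 2.0, 3.0]))


class TestQuartiles:
    @staticmethod
    def _results(values, group="g"):
        return [TgsResult(str(i), group, {}, float(v), True) for i, v in enumerate(values)]

    def test_hand_enumerated_cutpoints(self):
        # pooled 1..8: interpolated Q1 = 2.75, Q3 = 6.25
        a = self._results([1, 2, 3, 4], "A")
        b = self._results([5, 6, 7, 8], "B")
        qt = quartile_membership(a, b)
        assert qt.cutpoints == (2.75, 6.25)
        assert qt.counts.tolist() == [[0, 2], [2, 0]]

    def test_identical_groups_symmetric(self):
        vals = list(range(20))
        qt = quartile_membership(self._results(vals, "A"), self._results(vals, "B"))
        assert qt.counts[0].tolist() == qt.counts[1].tolist()

    def test_separated_groups(self):
        a = self._results(range(100, 120), "A")
        b = self._results(range(20), "B")
        qt = quartile_membership(a, b)
        assert qt.counts[0, 0] > 0 and qt.counts[0, 1] == 0
        assert qt.counts[1, 0] == 0 and qt.counts[1, 1] > 0


class TestExpectedTgs:
    def test_enumeration_matches_component_expectation(self, published_table):
        scheme = builtin_scheme("data_led")
        # independent components: E[TGS] = norm * sum of per-component means
        total = 0.0
        for comp in scheme.components:
            freqs = published_table.frequencies["athlete"][comp.source]
            total += sum(p * comp.score(cat) for cat, p in freqs.items())
        assert expected_tgs_mean(scheme, published_table, "athlete") == pytest.approx(
            NORM * total, rel=1e-12
        )

    def test_distribution_is_proper_and_on_grid(self, published_table):
        dist = expected_tgs_distribution(
            builtin_scheme("literature"), published_table, "non_athlete"
        )
        assert sum(dist.values()) == pytest.approx(1.0, abs=1e-9)
        grid = {k * NORM for k in range(15)}
        assert all(any(abs(v - g) < 1e-9 for g in grid) for v in dist)

    def test_simulated_mean_converges_to_enumeration(self, published_table):
        scheme = builtin_scheme("data_led")
        expected = expected_tgs_mean(scheme, published_table, "athlete")
        spec = published_study_spec(77, athletes=20000, non_athletes=10)
        results = score_cohort(
            [r for r in simulate_cohort(spec) if r.group == "athlete"], scheme
        )
        mean = np.mean([r.tgs for r in results])
        # MC error: sd ~12.4 at n=20000 -> 3 SE ~ 0.26
        assert mean == pytest.approx(expected, abs=0.3)
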