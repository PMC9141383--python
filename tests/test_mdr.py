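"""MDR cell labelling, cross-validated search and carrier combinations."""

import itertools

import numpy as np
import pytest

from tgsmdr import (
    GenotypeRecord,
    carrier_combination_frequency,
    cell_table,
    label_cells,
    mdr_search,
    plant_labels,
    simulate_cohort,
)
from tgsmdr.mdr import _balanced_accuracy, _encode
from tgsmdr.simulate import SimulationSpec, balanced_validation_table, xor_penetrance

from conftest import make_record

SIX_SNPS = ("ANKK1", "APOE_rs405509", "BDNF_AS", "COMT", "MAPT", "NOS3")


def _null_population(n, seed, group="pop"):
    spec = SimulationSpec(
        group_sizes={group: n}, frequency_group={group: "non_athlete"}, seed=seed
    )
    return simulate_cohort(spec)


class TestLabelCells:
    def test_ratio_above_threshold_high(self):
        t = label_cells({("x",): (10, 5)}, threshold=1.0)
        assert t.cells[("x",)] == (10, 5, "high")

    def test_ratio_below_threshold_low(self):
        t = label_cells({("x",): (5, 10)}, threshold=1.0)
        assert t.cells[("x",)][2] == "low"

    def test_tie_labelled_high_and_no_controls_high(self):
        t = label_cells({("a",): (5, 5), ("b",): (1, 0), ("c",): (0, 0)}, threshold=1.0)
        assert t.cells[("a",)][2] == "high"
        assert t.cells[("b",)][2] == "high"
        assert t.cells[("c",)][2] == "empty"

    def test_threshold_labelling_maximises_balanced_accuracy(self):
        """On a 4-cell toy table the case:control-ratio rule beats or ties
        every one of the 2^4 possible labellings on training balanced accuracy."""
        rng = np.random.default_rng(4)
        for _ in range(20):
            cases = rng.integers(0, 10, size=4)
            controls = rng.integers(0, 10, size=4)
            n_case, n_ctrl = cases.sum(), controls.sum()
            if n_case == 0 or n_ctrl == 0:
                continue
            threshold = n_case / n_ctrl

            def ba(high_mask):
                sens = cases[list(high_mask)].sum() / n_case
                spec = controls[[not h for h in high_mask]].sum() / n_ctrl
                return 0.5 * (sens + spec)

            t = label_cells(
                {(str(i),): (int(cases[i]), int(controls[i])) for i in range(4)},
                threshold,
            )
            ours = ba([t.cells[(str(i),)][2] == "high" for i in range(4)])
            best = max(ba(mask) for mask in itertools.product([False, True], repeat=4))
            assert ours == pytest.approx(best, abs=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            label_cells({("x",): (1, 1)}, threshold=0)
        with pytest.raises(ValueError):
            label_cells({("x",): (-1, 1)}, threshold=1)


class TestCellTable:
    def test_default_threshold_is_cohort_ratio(self):
        records = _null_population(50, 3)
        records = [
            GenotypeRecord(r.sample_id, "case" if i < 20 else "control", r.calls)
            for i, r in enumerate(records)
        ]
        t = cell_table(records, ("COMT",), case_groups=("case",))
        assert t.threshold == pytest.approx(20 / 30)
        total = sum(c + k for c, k, _ in t.cells.values())
        assert total == 50


class TestMdrSearch:
    def test_null_testing_accuracy_near_half(self):
        """Labels independent of every genotype: the selected model's mean
        testing balanced accuracy sits at chance level."""
        records = _null_population(1000, 21)
        rng = np.random.default_rng(22)
        records = [
            GenotypeRecord(r.sample_id, "case" if rng.random() < 0.45 else "control", r.calls)
            for r in records
        ]
        res = mdr_search(
            records, case_groups=("case",), attributes=SIX_SNPS, k_range=(1, 2),
            folds=10, seed=23,
        )
        assert abs(res.best.mean_testing_ba - 0.5) <= 0.05

    def test_planted_xor_interaction_recovered(self):
        """A two-locus XOR penetrance plant (risk iff exactly one locus
        heterozygous) has essentially no marginal effects, so only a genuine
        interaction search finds it."""
        records = simulate_cohort(
            SimulationSpec(
                group_sizes={"pop": 800},
                frequencies=balanced_validation_table(),
                seed=31,
                plant=xor_penetrance("COMT", "MAPT", high=0.9, low=0.1),
            )
        )
        res = mdr_search(
            records, case_groups=("case",), attributes=SIX_SNPS, k_range=(1, 2),
            folds=10, seed=31,
        )
        assert res.best.combination == ("COMT", "MAPT")
        assert res.best.cvc >= 8
        assert res.best.mean_testing_ba > 0.6
        # the plant is marginal-free: no single locus comes close
        assert res.by_size[1].mean_testing_ba < 0.56

    def test_single_attribute_complete_separation(self):
        records = [
            make_record(sample_id=f"c{i}", group="case", COMT="AA") for i in range(20)
        ] + [
            make_record(sample_id=f"k{i}", group="control", COMT="GG") for i in range(20)
        ]
        res = mdr_search(
            records, case_groups=("case",), attributes=("COMT",), k_range=(1,),
            folds=10, seed=1,
        )
        assert res.best.mean_testing_ba == pytest.approx(1.0)

    def test_folds_1_matches_brute_force_enumeration(self):
        """Without CV, model selection must agree with an exhaustive
        whole-sample balanced-accuracy oracle."""
        records = _null_population(50, 41)
        rng = np.random.default_rng(42)
        records = [
            GenotypeRecord(r.sample_id, "case" if rng.random() < 0.5 else "control", r.calls)
            for r in records
        ]
        attrs = SIX_SNPS[:5]
        res = mdr_search(
            records, case_groups=("case",), attributes=attrs, k_range=(2,),
            folds=1, seed=0,
        )

        X, y, attr_defs = _encode(records, list(attrs), ("case",))
        best_ba = -1.0
        for combo in itertools.combinations(range(len(attr_defs)), 2):
            cells = {}
            for row, is_case in zip(X, y):
                key = (row[combo[0]], row[combo[1]])
                c, k = cells.get(key, (0, 0))
                cells[key] = (c + int(is_case), k + int(not is_case))
            threshold = y.sum() / (~y).sum()
            pred = np.array(
                [cells[(r[combo[0]], r[combo[1]])][0] >= threshold * cells[(r[combo[0]], r[combo[1]])][1]
                 for r in X]
            )
            best_ba = max(best_ba, _balanced_accuracy(pred, y))
        assert res.best.mean_training_ba == pytest.approx(best_ba, abs=1e-12)
        assert res.best.mean_testing_ba == pytest.approx(res.best.mean_training_ba)

    def test_seed_determinism(self):
        records = _null_population(300, 8)
        rng = np.random.default_rng(9)
        records = [
            GenotypeRecord(r.sample_id, "case" if rng.random() < 0.5 else "control", r.calls)
            for r in records
        ]
        r1 = mdr_search(records, case_groups=("case",), attributes=SIX_SNPS, seed=5)
        r2 = mdr_search(records, case_groups=("case",), attributes=SIX_SNPS, seed=5)
        assert r1 == r2

    def test_attribute_order_invariance(self):
        records = simulate_cohort(
            SimulationSpec(
                group_sizes={"pop": 400},
                frequency_group={"pop": "non_athlete"},
                seed=51,
                plant=xor_penetrance("COMT", "MAPT"),
            )
        )
        r1 = mdr_search(records, case_groups=("case",), attributes=SIX_SNPS, seed=3)
        r2 = mdr_search(
            records, case_groups=("case",), attributes=tuple(reversed(SIX_SNPS)), seed=3
        )
        assert r1.best.combination == r2.best.combination
        assert r1.best.mean_testing_ba == pytest.approx(r2.best.mean_testing_ba)

    def test_training_ba_at_least_half(self):
        records = _null_population(200, 61)
        rng = np.random.default_rng(62)
        records = [
            GenotypeRecord(r.sample_id, "case" if rng.random() < 0.3 else "control", r.calls)
            for r in records
        ]
        res = mdr_search(records, case_groups=("case",), attributes=SIX_SNPS, seed=7)
        for model in res.by_size.values():
            assert model.mean_training_ba >= 0.5

    def test_single_level_attribute_excluded_with_warning(self):
        records = [
            make_record(sample_id=f"c{i}", group="case", COMT="AA" if i % 2 else "GG",
                        ANKK1="GG")
            for i in range(10)
        ] + [
            make_record(sample_id=f"k{i}", group="control",
                        COMT="GG" if i % 2 else "AA", ANKK1="GG")
            for i in range(10)
        ]
        with pytest.warns(UserWarning, match="ANKK1"):
            res = mdr_search(
                records, case_groups=("case",), attributes=("ANKK1", "COMT"),
                k_range=(1,), folds=2, seed=0,
            )
        assert res.best.combination == ("COMT",)


class TestCarrierCombination:
    def test_all_carriers(self):
        records = [
            make_record(sample_id=f"S{i}", COMT="GG", MAPT="CC") for i in range(5)
        ]
        out = carrier_combination_frequency(records, [("COMT", "G"), ("MAPT", "C")])
        assert out["athlete"].proportion == 1.0

    def test_hand_enumerated_toy(self):
        genotypes = [("AA", "CC"), ("AG", "TT"), ("GG", "CT"), ("AA", "TT")]
        records = [
            make_record(sample_id=f"S{i}", COMT=c, MAPT=m)
            for i, (c, m) in enumerate(genotypes)
        ]
        out = carrier_combination_frequency(records, [("COMT", "G"), ("MAPT", "C")])
        assert out["athlete"].carriers == 1  # only GG/CT carries both G and C
        assert out["athlete"].proportion == 0.25

    def test_missing_calls_excluded(self):
        records = [
            make_record(sample_id="S1", COMT="GG", MAPT="CC"),
            make_record(sample_id="S2", COMT=None, MAPT="CC"),
        ]
        out = carrier_combination_frequency(records, [("COMT", "G"), ("MAPT", "C")])
        assert out["athlete"].n == 1

    def test_simulated_matches_product_of_marginals(self):
        """Under linkage equilibrium the carrier proportion factorises:
        P = (1 - P(COMT AA)) * (P(MAPT CC) + P(MAPT CT))."""
        records = _null_population(100_000, 71, group="non_athlete")
        out = carrier_combination_frequency(records, [("COMT", "G"), ("MAPT", "C")])
        expected = (1 - 0.302) * (0.047 + 0.314)
        assert out["non_athlete"].proportion == pytest.approx(expected, abs=0.006)

    def test_allele_mode_denominator(self):
        records = [make_record(sample_id="S1", COMT="AG", MAPT="CT")]
        out = carrier_combination_frequency(
            records, [("COMT", "G"), ("MAPT", "C")], mode="allele"
        )
        assert out["athlete"].proportion == pytest.approx(0.5)

    def test_unknown_locus_or_allele(self):
        with pytest.raises(ValueError):
            carrier_combination_frequency([make_record()], [("NOPE", "G")])
        with pytest.raises(ValueError):
            carrier_combination_frequency([make_record()], [("COMT", "T")])
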