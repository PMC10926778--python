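import numpy as np
import pandas as pd
import pytest

from domfinger.rank import (
    ArmUniqueResult,
    DominanceClassification,
    RankTable,
    arm_unique_formulas,
    classify_dominance,
    classify_treatment,
    common_formulas,
    rank_formulas,
    species_count_table,
    unique_across_treatments,
)
from tests.conftest import make_assigned


class TestRankFormulas:
    def test_descending_ranks(self):
        s = make_assigned("s", {"C6H12O6": 10, "C10H12O7": 5, "C8H10N4O2": 1})
        ranks = rank_formulas(s).ranks
        assert ranks["C6H12O6"] == 1
        assert ranks["C10H12O7"] == 2
        assert ranks["C8H10N4O2"] == 3

    def test_ties_get_average_rank(self):
        s = make_assigned("s", {"C6H12O6": 10, "C10H12O7": 10, "C8H10N4O2": 1})
        ranks = rank_formulas(s).ranks
        assert ranks["C6H12O6"] == 1.5
        assert ranks["C10H12O7"] == 1.5
        assert ranks["C8H10N4O2"] == 3

    def test_invariant_to_intensity_rescaling(self):
        a = make_assigned("s", {"C6H12O6": 10, "C10H12O7": 5, "C8H10N4O2": 1})
        b = make_assigned("s", {"C6H12O6": 20, "C10H12O7": 10, "C8H10N4O2": 2})
        pd.testing.assert_series_equal(rank_formulas(a).ranks, rank_formulas(b).ranks)


class TestCommonFormulas:
    def test_identical_samples_full_coverage(self):
        s1 = make_assigned("a", {"C6H12O6": 2, "C10H12O7": 1})
        s2 = make_assigned("b", {"C6H12O6": 1, "C10H12O7": 5})
        common, cov = common_formulas([s1, s2])
        assert common == {"C6H12O6", "C10H12O7"}
        assert cov == pytest.approx(1.0)

    def test_set_intersection(self):
        s1 = make_assigned("a", {"C6H12O6": 1, "C10H12O7": 1, "C8H10N4O2": 1})
        s2 = make_assigned("b", {"C10H12O7": 1, "C8H10N4O2": 1, "C8H16O2S1": 1})
        with pytest.warns(UserWarning, match="coverage"):
            common, cov = common_formulas([s1, s2])
        assert common == {"C10H12O7", "C8H10N4O2"}
        assert cov == pytest.approx(2 / 3)

    def test_no_overlap_is_empty_not_error(self):
        s1 = make_assigned("a", {"C6H12O6": 1})
        s2 = make_assigned("b", {"C8H16O2S1": 1})
        with pytest.warns(UserWarning):
            common, cov = common_formulas([s1, s2])
        assert common == set() and cov == 0.0

    def test_antitone_in_sample_list(self, seed42_dataset):
        """Adding a sample can never enlarge the common set."""
        _, _, assigned = seed42_dataset
        sub = [s for s in assigned if s.meta.arm is None][:6]
        prev = None
        for k in range(2, len(sub) + 1):
            common, _ = common_formulas(sub[:k], coverage_threshold=0.01)
            if prev is not None:
                assert common <= prev
            prev = common


TOY_RANKS = {
    # formula: ranks on (day 0, day 4, day 60); hand-worked classes
    "C10H16O4": ((2, 5, 9), "preformed"),
    "C11H14O6": ((9, 1, 4), "intermediated"),
    "C12H12O8": ((7, 6, 2), "remaining"),
    "C13H18O5": ((1, 8, 1), "ambiguous"),  # tie between day 0 and day 60
    "C14H20O3": ((3, 2, 6), "intermediated"),
    "C15H10O7": ((5, 9, 3), "remaining"),
}


class TestClassifyDominance:
    def _tables(self):
        days = (0.0, 4.0, 60.0)
        tables = {}
        for i, d in enumerate(days):
            ranks = pd.Series({f: r[i] for f, (r, _) in TOY_RANKS.items()}, dtype=float)
            tables[d] = RankTable(sample_id=f"d{d:g}", ranks=ranks)
        return tables

    def test_toy_fixture_matches_hand_worked_answers(self):
        cl = classify_dominance(self._tables(), TOY_RANKS.keys(), treatment="glucose")
        for f, (_, expected) in TOY_RANKS.items():
            assert cl.classes[f] == expected, f

    def test_missing_timepoint_rejected(self):
        tables = self._tables()
        del tables[60.0]
        with pytest.raises(ValueError, match="three timepoints"):
            classify_dominance(tables, TOY_RANKS.keys())

    def test_classification_invariant_to_intensity_rescaling(self):
        base = {"C10H16O4": 8.0, "C11H14O6": 4.0, "C12H12O8": 1.0}
        days = (0.0, 4.0, 60.0)
        mults = {0.0: (1, 0.3, 0.1), 4.0: (0.4, 1, 0.3), 60.0: (0.1, 0.4, 1)}

        def classify(scale):
            samples = []
            for d in days:
                intens = {
                    f: base[f] * m * scale
                    for f, m in zip(base, mults[d])
                }
                samples.append(make_assigned(f"g_d{d:g}_r1", intens, treatment="g", day=d))
            return classify_treatment(samples, coverage_threshold=0.01)

        assert classify(1.0).classes == classify(137.0).classes


class TestUniqueAcrossTreatments:
    def _cl(self, treatment, mapping):
        return DominanceClassification(treatment=treatment, classes=mapping, coverage=1.0)

    def test_consistent_class_enters_unique_set(self):
        cls = [self._cl(t, {"C6H12O6": "preformed"}) for t in "abcde"]
        uniq = unique_across_treatments(cls)
        assert uniq.per_class["preformed"] == {"C6H12O6"}
        assert uniq.n_conflicting == 0

    def test_conflicting_classes_excluded_and_counted(self):
        cls = [
            self._cl("a", {"C6H12O6": "preformed"}),
            self._cl("b", {"C6H12O6": "remaining"}),
        ]
        uniq = unique_across_treatments(cls)
        assert all(not s for s in uniq.per_class.values())
        assert uniq.n_conflicting == 1
        assert uniq.conflicting == {"C6H12O6"}

    def test_ambiguous_ignored_not_conflicting(self):
        cls = [
            self._cl("a", {"C6H12O6": "preformed"}),
            self._cl("b", {"C6H12O6": "ambiguous"}),
        ]
        uniq = unique_across_treatments(cls)
        assert uniq.per_class["preformed"] == {"C6H12O6"}

    def test_unique_sets_pairwise_disjoint(self, seed42_dataset):
        _, _, assigned = seed42_dataset
        substrate = [s for s in assigned if s.meta.arm is None]
        treatments = sorted({s.meta.treatment for s in substrate})
        cls = [
            classify_treatment([s for s in substrate if s.meta.treatment == t])
            for t in treatments
        ]
        uniq = unique_across_treatments(cls)
        sets = list(uniq.per_class.values())
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                assert not (sets[i] & sets[j])


class TestSpeciesCountTable:
    def test_counts_by_species_and_class(self):
        uniq = unique_across_treatments([
            DominanceClassification("t", {
                "C10H12O4": "preformed", "C11H14O4": "preformed", "C12H16O4": "preformed",
                "C10H14N2O1": "remaining",
            }, coverage=1.0)
        ])
        species, elemental = species_count_table(uniq)
        assert species.loc["O4", "preformed"] == 3
        assert species.loc["N2O", "remaining"] == 1
        assert species.loc["O4", "remaining"] == 0
        assert elemental.loc["CHO", "preformed"] == 3
        assert elemental.loc["CHON", "remaining"] == 1

    def test_empty_class_is_zero_column(self):
        uniq = unique_across_treatments([
            DominanceClassification("t", {"C10H12O4": "preformed"}, coverage=1.0)
        ])
        species, _ = species_count_table(uniq)
        assert (species["intermediated"] == 0).all()


class TestArmUnique:
    def test_formula_only_in_viral_arm_detected(self):
        ex = make_assigned("e", {"C6H12O6": 1}, arm="exudate")
        me = make_assigned("m", {"C6H12O6": 1}, arm="mechanical")
        vi = make_assigned("v", {"C6H12O6": 1, "C10H14N2O1": 1}, arm="viral")
        res = arm_unique_formulas({"exudate": [ex], "mechanical": [me], "viral": [vi]})
        assert res.unique["viral"] == {"C10H14N2O1"}
        assert res.unique["exudate"] == set()
        assert res.common == {"C6H12O6"}

    def test_identical_arms_have_empty_unique_sets(self):
        a = make_assigned("a", {"C6H12O6": 1, "C10H12O7": 2}, arm="exudate")
        b = make_assigned("b", {"C6H12O6": 2, "C10H12O7": 1}, arm="viral")
        res = arm_unique_formulas({"exudate": [a], "viral": [b]})
        assert res.unique == {"exudate": set(), "viral": set()}
        assert res.coverage == pytest.approx(1.0)

    def test_synthetic_viral_unique_recovered(self, seed42_dataset):
        library, _, assigned = seed42_dataset
        arms = {a: [s for s in assigned if s.meta.arm == a]
                for a in ("exudate", "mechanical", "viral")}
        res = arm_unique_formulas(arms)
        latent = {str(e.formula) for e in library.by_label("viral_unique")}
        assert latent <= res.unique["viral"]
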