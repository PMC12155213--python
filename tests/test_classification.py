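"""Categorization rules, depth QC, fixed-cutoff classifiers, ROC/AUC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from rrsburn.classification import (
    WoundRecord,
    adjust_depth_score,
    classify_hi,
    depth_score_qc,
    primary_categorize,
    roc,
    secondary_categorize,
    youden_cutoff,
)
from rrsburn.synthetic import make_wound_table_fixture


def auc_by_pair_counting(pos, neg):
    wins = ties = 0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1
            elif p == n:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestPrimaryCategorize:
    @pytest.mark.parametrize(
        "temp,dur,expect",
        [
            (45, None, "Superficial"),
            (96, 30, "Full-thickness"),
            (63, 18, "PT-Superficial"),
            (63, 15, "PT-Superficial"),
            (63, 20, "PT-Superficial"),
            (63, 30, "PT-Deep"),
            (63, 45, "PT-Deep"),
        ],
    )
    def test_protocol_mapping(self, temp, dur, expect):
        assert primary_categorize(temp, dur) == expect

    @pytest.mark.parametrize("dur", [25, 10, 50])
    def test_protocol_gap_rejected(self, dur):
        with pytest.raises(ValueError, match="protocol"):
            primary_categorize(63, dur)

    def test_unknown_temperature_rejected(self):
        with pytest.raises(ValueError, match="temperature"):
            primary_categorize(70, 20)


class TestSecondaryCategorize:
    def rec(self, cat, heal):
        r = WoundRecord(1, 1, 63, 18, heal_pod=heal)
        r.primary_category = cat
        return r

    def test_pt_superficial_healed_in_time_retained(self):
        r = secondary_categorize(self.rec("PT-Superficial", 43))
        assert r.final_category == "PT-Superficial"

    def test_pt_superficial_unhealed_excluded(self):
        r = secondary_categorize(self.rec("PT-Superficial", None))
        assert r.final_category == "Excluded"
        assert r.exclusion_reason == "secondary-criterion"

    def test_pt_deep_healing_early_excluded(self):
        r = secondary_categorize(self.rec("PT-Deep", 50))
        assert r.final_category == "Excluded"

    def test_superficial_passes_through(self):
        r = secondary_categorize(self.rec("Superficial", 2))
        assert r.final_category == "Superficial"

    def test_fixture_attrition_matches_study(self):
        """Primary + secondary criteria on the 24-wound fixture: exactly 3
        partial-thickness exclusions and final counts 4/6/5/6."""
        df = make_wound_table_fixture()
        finals = []
        for _, row in df.iterrows():
            r = WoundRecord(
                int(row.pig_id), int(row.wound_id), row.block_temp_c,
                row.contact_s,
                heal_pod=None if pd.isna(row.heal_pod) else int(row.heal_pod),
            )
            r.primary_category = primary_categorize(r.block_temp_c, r.contact_s)
            finals.append(secondary_categorize(r).final_category)
        counts = {c: finals.count(c) for c in set(finals)}
        assert counts["Excluded"] == 3
        assert counts["Superficial"] == 4
        assert counts["PT-Superficial"] == 6
        assert counts["PT-Deep"] == 5
        assert counts["Full-thickness"] == 6


class TestDepthScore:
    def test_epidermis_addition(self):
        assert adjust_depth_score(500, True) == 600
        assert adjust_depth_score(500, False) == 500

    def test_negative_depth_rejected(self):
        with pytest.raises(ValueError):
            adjust_depth_score(-5, True)

    @pytest.mark.parametrize(
        "cat,depth,expect",
        [
            ("Superficial", 102.5, True),
            ("Superficial", 250, False),
            ("PT-Superficial", 562.9, True),
            ("PT-Superficial", 680, True),   # boundary kept superficial side
            ("PT-Superficial", 900, False),
            ("PT-Deep", 870, True),
            ("PT-Deep", 680, False),
            ("Full-thickness", 2261, True),
            ("Full-thickness", 1750, False),
        ],
    )
    def test_qc_windows(self, cat, depth, expect):
        assert depth_score_qc(cat, depth) is expect

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError, match="category"):
            depth_score_qc("mystery", 100)

    def test_fixture_qc_discards_no_retained_wound(self):
        """Depth-score QC confirms but never further excludes wounds that
        already passed both categorization criteria."""
        df = make_wound_table_fixture()
        for _, row in df.iterrows():
            r = WoundRecord(
                int(row.pig_id), int(row.wound_id), row.block_temp_c,
                row.contact_s,
                heal_pod=None if pd.isna(row.heal_pod) else int(row.heal_pod),
            )
            r.primary_category = primary_categorize(r.block_temp_c, r.contact_s)
            secondary_categorize(r)
            if r.included:
                depth = adjust_depth_score(row.depth_um, bool(row.epidermis_missing))
                assert depth_score_qc(r.final_category, depth)


class TestClassifyHI:
    def test_partial_thickness_call(self):
        assert classify_hi(5.0, 3.54, "greater") is True

    def test_value_at_threshold_is_negative_class(self):
        assert classify_hi(3.54, 3.54, "greater") is False
        assert classify_hi(6.58, 6.58, "less") is False

    def test_pt_deep_call(self):
        assert classify_hi(5.0, 6.58, "less") is True


class TestROC:
    def test_perfect_separation(self):
        r = roc([5, 6, 7], [1, 2])
        assert r.auc == 1.0

    def test_identical_groups_chance(self):
        r = roc([1, 2, 3], [1, 2, 3])
        assert r.auc == 0.5 and r.degenerate

    def test_hand_counted_case(self):
        r = roc([2, 4], [1, 3])
        assert r.auc == 0.75

    def test_symmetry(self, rng):
        for _ in range(20):
            pos = rng.normal(1, 1, rng.integers(2, 10))
            neg = rng.normal(0, 1, rng.integers(2, 10))
            assert roc(pos, neg).auc == pytest.approx(1 - roc(neg, pos).auc)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            roc([], [1.0])

    @given(
        pos=st.lists(st.integers(-5, 5), min_size=1, max_size=20),
        neg=st.lists(st.integers(-5, 5), min_size=1, max_size=20),
    )
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_auc_matches_pair_counting_oracle(self, pos, neg):
        if len(pos) * len(neg) > 400:
            pos, neg = pos[:20], neg[:20]
        r = roc(np.array(pos, float), np.array(neg, float))
        assert r.auc == pytest.approx(auc_by_pair_counting(pos, neg), abs=1e-12)

    def test_less_direction_flips_scale(self):
        # deeper burns have LOWER HI: positives below negatives -> AUC 1
        r = roc([0.1, 0.2], [5.0, 6.0], direction="less")
        assert r.auc == 1.0


class TestYouden:
    def test_separated_groups_midpoint(self):
        r = roc([8, 10], [1, 2])
        assert youden_cutoff(r) == pytest.approx(5.0)

    def test_degenerate_returns_lowest_threshold(self):
        r = roc([1, 2], [1, 2])
        assert youden_cutoff(r) == 1.0

    def test_hand_enumerated_case(self):
        r = roc([2, 4], [1, 3])
        assert youden_cutoff(r) == pytest.approx(3.5)

    def test_cutoff_reproduces_roc_point(self, rng):
        for _ in range(20):
            pos = rng.normal(2, 1, 8)
            neg = rng.normal(0, 1, 6)
            r = roc(pos, neg)
            t = youden_cutoff(r)
            sens = np.mean([classify_hi(v, t, "greater") for v in pos])
            spec = np.mean([not classify_hi(v, t, "greater") for v in neg])
            j_direct = sens + spec - 1
            assert j_direct == pytest.approx(
                np.max(r.sensitivity + r.specificity - 1), abs=1e-12
            )
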