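"""Copy-number rules, activity score, and phenotype classification."""

from __future__ import annotations

import math
from io import StringIO

import pytest
from hypothesis import given
from hypothesis import strategies as st

from haplostar.errors import ConfigError
from haplostar.phasing import PhasedPair
from haplostar.phenotype import (
    ActivityScore,
    Band,
    PhenotypeThresholds,
    activity_score,
    apply_cnv,
    assemble_call,
    classify_phenotype,
)
from haplostar.stars import StarMatch


def _pair(table, s1, s2, sid="S1"):
    h1 = table.by_star[s1].haplotype
    h2 = table.by_star[s2].haplotype
    lo, hi = sorted((h1, h2))
    return PhasedPair(sid, lo, hi, 1.0, 1)


def _matches(table, pair):
    return (
        StarMatch(table.by_haplotype.get(pair.h1, ())),
        StarMatch(table.by_haplotype.get(pair.h2, ())),
    )


class TestThresholds:
    def test_default_partition_classifies_canonically(self):
        t = PhenotypeThresholds.default()
        assert t.classify_value(0.0) == "PM"
        assert t.classify_value(0.5) == "IM"
        assert t.classify_value(1.25) == "NM"
        assert t.classify_value(2.25) == "NM"
        assert t.classify_value(3.0) == "UM"

    @pytest.mark.parametrize(
        "bands",
        [
            # gap between IM and NM
            (Band("PM", 0, 0, False, False), Band("IM", 0, 1.0, True, True),
             Band("NM", 1.25, math.inf, False, True)),
            # boundary owned by both sides
            (Band("PM", 0, 0, False, False), Band("IM", 0, 1.25, True, False),
             Band("NM", 1.25, math.inf, False, True)),
            # does not start at zero
            (Band("IM", 0.5, math.inf, False, True),),
            # does not reach infinity
            (Band("PM", 0, 2.0, False, False),),
        ],
        ids=["gap", "overlap", "no-zero", "finite"],
    )
    def test_malformed_partitions_fail_at_load_time(self, bands):
        with pytest.raises(ConfigError):
            PhenotypeThresholds(bands=tuple(bands))

    def test_from_file_round_trip_with_header(self):
        text = (
            "category,lower,upper,lower_end,upper_end\n"
            "PM,0,0,closed,closed\n"
            "IM,0,1.25,open,open\n"
            "NM,1.25,2.25,closed,closed\n"
            "UM,2.25,inf,open,open\n"
        )
        t = PhenotypeThresholds.from_file(StringIO(text))
        assert t == PhenotypeThresholds.default()


class TestClassifyPhenotype:
    def test_zero_is_pm(self):
        assert classify_phenotype(ActivityScore.of(0.0), PhenotypeThresholds.default()) == "PM"

    def test_triplication_is_um(self):
        assert classify_phenotype(ActivityScore.of(3.0), PhenotypeThresholds.default()) == "UM"

    def test_bounds_within_one_category_classify(self):
        score = ActivityScore.indeterminate((0.25, 0.5))
        assert classify_phenotype(score, PhenotypeThresholds.default()) == "IM"

    def test_bounds_spanning_categories_stay_indeterminate(self):
        score = ActivityScore.indeterminate((1.0, 2.0))
        assert classify_phenotype(score, PhenotypeThresholds.default()) == "Indeterminate"

    def test_unbounded_indeterminate_stays_indeterminate(self):
        assert (
            classify_phenotype(ActivityScore.indeterminate(), PhenotypeThresholds.default())
            == "Indeterminate"
        )

    @given(
        st.tuples(
            st.floats(min_value=0, max_value=5, allow_nan=False),
            st.floats(min_value=0, max_value=5, allow_nan=False),
        )
    )
    def test_monotone_in_activity(self, pair):
        """A lower AS never maps to a faster metabolizer category."""
        order = {"PM": 0, "IM": 1, "NM": 2, "UM": 3}
        a, b = sorted(pair)
        t = PhenotypeThresholds.default()
        assert order[t.classify_value(a)] <= order[t.classify_value(b)]


class TestApplyCnv:
    def test_two_copies_unchanged(self, toy_table):
        pair = _pair(toy_table, "*1", "*4")
        adj = apply_cnv(_matches(toy_table, pair), pair, 2)
        assert adj.kind == "normal"
        assert adj.diplotype == "*1/*4"
        assert adj.flags == ()

    def test_deletion_replaces_one_allele_with_star5(self, toy_table):
        pair = _pair(toy_table, "*4", "*4")
        adj = apply_cnv(_matches(toy_table, pair), pair, 1)
        assert adj.kind == "deletion"
        assert adj.labels == ("*4", "*5")
        assert adj.diplotype == "*4/*5"

    def test_heterozygous_deletion_keeps_calls_and_flags_conflict(self, toy_table):
        pair = _pair(toy_table, "*1", "*4")
        adj = apply_cnv(_matches(toy_table, pair), pair, 1)
        assert "hemizygosity_conflict" in adj.flags
        assert adj.diplotype == "*1/*4"

    def test_zero_copies_is_homozygous_deletion(self, toy_table):
        pair = _pair(toy_table, "*1", "*1")
        adj = apply_cnv(_matches(toy_table, pair), pair, 0)
        assert adj.diplotype == "*5/*5"
        assert "cnv_zero_deletion" in adj.flags

    def test_homozygous_duplication_is_assigned(self, toy_table):
        pair = _pair(toy_table, "*1", "*1")
        adj = apply_cnv(_matches(toy_table, pair), pair, 3)
        assert adj.kind == "duplication"
        assert adj.diplotype == "*1x2/*1"

    def test_heterozygous_duplication_is_indeterminate(self, toy_table):
        pair = _pair(toy_table, "*1", "*4")
        adj = apply_cnv(_matches(toy_table, pair), pair, 3)
        assert adj.kind == "indeterminate_duplication"
        assert "indeterminate_duplication" in adj.flags


class TestActivityScore:
    def test_default_two_copy_sum(self, toy_table):
        pair = _pair(toy_table, "*1", "*4")
        adj = apply_cnv(_matches(toy_table, pair), pair, 2)
        assert activity_score(adj, toy_table).value == pytest.approx(1.0)

    def test_deletion_leaves_remaining_activity(self, toy_table):
        pair = _pair(toy_table, "*4", "*4")
        adj = apply_cnv(_matches(toy_table, pair), pair, 1)
        assert activity_score(adj, toy_table).value == pytest.approx(0.0)

    def test_homozygous_triplication_is_three_times_activity(self, toy_table):
        pair = _pair(toy_table, "*1", "*1")
        adj = apply_cnv(_matches(toy_table, pair), pair, 3)
        assert activity_score(adj, toy_table).value == pytest.approx(3.0)

    def test_deletion_law_for_every_star(self, toy_table):
        """AS(h, *5) = act(h) across the whole table."""
        for d in toy_table.definitions:
            pair = _pair(toy_table, d.star, d.star)
            adj = apply_cnv(_matches(toy_table, pair), pair, 1)
            assert activity_score(adj, toy_table).value == pytest.approx(d.activity)

    @pytest.mark.parametrize("n", [3, 4, 5])
    def test_homozygous_duplication_law(self, toy_table, n):
        for d in toy_table.definitions:
            pair = _pair(toy_table, d.star, d.star)
            adj = apply_cnv(_matches(toy_table, pair), pair, n)
            assert activity_score(adj, toy_table).value == pytest.approx(n * d.activity)

    def test_indeterminate_duplication_bounds(self, toy_table):
        # *1 (1.0) + *4 (0.0), cnv=3: the third copy is one of the two
        pair = _pair(toy_table, "*1", "*4")
        adj = apply_cnv(_matches(toy_table, pair), pair, 3)
        score = activity_score(adj, toy_table)
        assert score.is_indeterminate
        assert score.bounds == (1.0, 2.0)

    def test_no_call_copy_makes_score_indeterminate(self, toy_table):
        pair = PhasedPair("S1", ("C", "G", "G"), ("T", "A", "G"), 1.0, 1)
        adj = apply_cnv(_matches(toy_table, pair), pair, 2)
        score = activity_score(adj, toy_table)
        assert score.is_indeterminate
        assert score.bounds is None

    def test_order_never_changes_score(self, toy_table):
        stars = [d.star for d in toy_table.definitions]
        for s1 in stars:
            for s2 in stars:
                p12 = _pair(toy_table, s1, s2)
                p21 = _pair(toy_table, s2, s1)
                a12 = activity_score(apply_cnv(_matches(toy_table, p12), p12, 2), toy_table)
                a21 = activity_score(apply_cnv(_matches(toy_table, p21), p21, 2), toy_table)
                assert a12.value == a21.value


class TestAssembleCall:
    def test_full_call_im(self, toy_table):
        pair = _pair(toy_table, "*1", "*4")
        call = assemble_call(
            pair, _matches(toy_table, pair), 2, toy_table, PhenotypeThresholds.default()
        )
        assert call.diplotype == "*1/*4"
        assert call.activity.value == pytest.approx(1.0)
        assert call.phenotype == "IM"

    def test_bounds_subsumption_adds_note_flag(self, toy_table):
        # *10 (0.25) + *41 (0.5), cnv=3 → bounds [1.0, 1.25]... spans IM/NM?
        # use *4 (0.0) + *10 (0.25): bounds [0.25, 0.5] inside IM
        pair = _pair(toy_table, "*4", "*10")
        call = assemble_call(
            pair, _matches(toy_table, pair), 3, toy_table, PhenotypeThresholds.default()
        )
        assert call.activity.is_indeterminate
        assert call.phenotype == "IM"
        assert "bounds_classified" in call.flags

    def test_indeterminate_duplication_reported_indeterminate(self, toy_table):
        pair = _pair(toy_table, "*1", "*4")
        call = assemble_call(
            pair, _matches(toy_table, pair), 3, toy_table, PhenotypeThresholds.default()
        )
        assert str(call.activity) == "indeterminate"
        assert call.phenotype == "Indeterminate"
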