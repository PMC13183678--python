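import itertools

import pytest
from hypothesis import given, strategies as st

from g4annotate.rules import (
    ALL_TOPOLOGIES,
    RuleQuery,
    allowed_topologies,
    diagonal_compatible,
    diagonal_min_length_rule,
    duplex_capable,
    four_tetrad_loop_check,
    predict_extremity_sides,
    tetrad_count_tendency,
)


class TestAllowedTopologies:
    def test_two_1nt_loops_parallel_only(self):
        pred = allowed_topologies(RuleQuery(1, 7, 1))
        assert pred.allowed_topologies() == ["parallel"]

    @pytest.mark.parametrize("L2", range(1, 16))
    def test_l1_l3_one(self, L2):
        pred = allowed_topologies(RuleQuery(1, L2, 1))
        assert pred.allowed_topologies() == ["parallel"]

    def test_212_parallel(self):
        assert allowed_topologies(RuleQuery(2, 1, 2)).allowed_topologies() == ["parallel"]

    def test_222_parallel_major_chair_minor(self):
        pred = allowed_topologies(RuleQuery(2, 2, 2))
        assert pred.allowed_topologies() == ["parallel", "antiparallel-chair"]
        labels = dict(pred.allowed)
        assert "73" in labels["parallel"] and "27" in labels["antiparallel-chair"]

    def test_232_chair(self):
        assert allowed_topologies(RuleQuery(2, 3, 2)).allowed_topologies() == [
            "antiparallel-chair"
        ]

    @pytest.mark.parametrize("L2", [4, 5])
    def test_2x2_basket(self, L2):
        assert allowed_topologies(RuleQuery(2, L2, 2)).allowed_topologies() == [
            "antiparallel-basket"
        ]

    def test_2_15_2_duplex_chair(self):
        pred = allowed_topologies(RuleQuery(2, 15, 2))
        assert pred.allowed_topologies() == ["antiparallel-chair"]

    def test_313_parallel(self):
        assert allowed_topologies(RuleQuery(3, 1, 3)).allowed_topologies() == ["parallel"]

    def test_323_hybrid3(self):
        assert allowed_topologies(RuleQuery(3, 2, 3)).allowed_topologies() == ["hybrid3"]

    def test_333_four_topologies(self):
        pred = allowed_topologies(RuleQuery(3, 3, 3))
        assert set(pred.allowed_topologies()) == {
            "hybrid1",
            "hybrid3",
            "antiparallel-chair",
            "antiparallel-basket2",
        }
        # ordered by printed frequency
        assert pred.allowed_topologies()[0] == "hybrid1"

    @pytest.mark.parametrize("L2", [4, 5])
    def test_3x3_baskets(self, L2):
        pred = allowed_topologies(RuleQuery(3, L2, 3))
        assert pred.allowed_topologies() == ["antiparallel-basket", "antiparallel-basket2"]

    def test_modified_g_flag_lifts_exclusion(self):
        pred = allowed_topologies(RuleQuery(1, 1, 9, has_modified_guanines=True))
        allowed = pred.allowed_topologies()
        assert "parallel" in allowed and len(allowed) == 8
        assert pred.excluded == []
        assert any("modified guanines" in c for c in pred.caveats)

    def test_unmatched_returns_all_eight_with_caveat(self):
        pred = allowed_topologies(RuleQuery(5, 5, 4))
        assert set(pred.allowed_topologies()) == set(ALL_TOPOLOGIES)
        assert any("no rule" in c for c in pred.caveats)

    def test_negative_length_rejected(self):
        with pytest.raises(ValueError):
            RuleQuery(2, -1, 2)

    def test_totality_and_consistency_exhaustive(self):
        # every (L1, L2, L3) in 0..15^3: non-empty allowed, no topology both
        # allowed and excluded, provenance always present
        for L1, L2, L3 in itertools.product(range(16), repeat=3):
            pred = allowed_topologies(RuleQuery(L1, L2, L3))
            allowed = set(pred.allowed_topologies())
            excluded = {t for t, _ in pred.excluded}
            assert allowed, (L1, L2, L3)
            assert not (allowed & excluded), (L1, L2, L3)
            assert pred.matched_rules, (L1, L2, L3)
            if "antiparallel-basket" in allowed and L1 == L3 and L2 >= 4:
                # a basket with diagonal central loop satisfies the 4-nt rule
                assert diagonal_min_length_rule(L2).ok or len(allowed) == 8


class TestDiagonalRules:
    def test_compatible_set(self):
        compatible = {t for t in ALL_TOPOLOGIES if diagonal_compatible(t)}
        assert compatible == {"antiparallel-basket", "antiparallel-basket2", "hybrid2"}

    def test_parallel_incompatible(self):
        assert not diagonal_compatible("parallel")

    def test_unknown_topology(self):
        with pytest.raises(ValueError):
            diagonal_compatible("sideways")

    @pytest.mark.parametrize("n,ok", [(0, False), (3, False), (4, True), (26, True)])
    def test_min_length(self, n, ok):
        assert diagonal_min_length_rule(n).ok is ok


class TestExtremitySides:
    @pytest.mark.parametrize(
        "topology,nature,snap,expected",
        [
            ("parallel", "DNA", False, "opposite"),
            ("antiparallel-chair", "DNA", False, "same"),
            ("antiparallel-basket", "DNA", False, "same"),
            ("antiparallel-basket2", "DNA", False, "same"),
            ("hybrid1", "DNA", False, "opposite"),
            ("hybrid2", "DNA", False, "opposite"),
            ("hybrid2", "RNA", False, "same"),
            ("hybrid3", "DNA", False, "opposite"),
            ("hybrid3", "RNA", False, "same"),
            ("hybrid4", "DNA", True, "middle"),
            ("hybrid4", "DNA", False, "same"),
        ],
    )
    def test_table_map(self, topology, nature, snap, expected):
        assert predict_extremity_sides(topology, nature, snap) == expected

    def test_unknown(self):
        with pytest.raises(ValueError):
            predict_extremity_sides("nope")


class TestTetradTendency:
    def test_parallel_dna(self):
        assert tetrad_count_tendency("parallel", "DNA")[0] == 3

    def test_chair_dna(self):
        assert tetrad_count_tendency("antiparallel-chair", "DNA")[0] == 2

    def test_hybrid2_rna(self):
        assert tetrad_count_tendency("hybrid2", "RNA")[0] == 2

    def test_hybrid1_dna(self):
        assert tetrad_count_tendency("hybrid1", "DNA")[0] == 3


class TestDuplexCapable:
    @pytest.mark.parametrize("n,capable", [(10, True), (9, False), (15, True), (0, False)])
    def test_threshold(self, n, capable):
        assert duplex_capable(n) is capable


class TestFourTetradCheck:
    def test_short_propeller_warned(self):
        warnings = four_tetrad_loop_check(4, (1, 2, 2))
        assert len(warnings) == 1 and "loop 1" in warnings[0]

    def test_three_tetrads_silent(self):
        assert four_tetrad_loop_check(3, (1, 2, 1)) == []

    def test_all_two_nt_silent(self):
        assert four_tetrad_loop_check(4, (2, 2, 2)) == []

    def test_only_propeller_loops_counted(self):
        assert four_tetrad_loop_check(4, (1, 2, 2), loop_kinds=("l", "p", "p")) == []


@given(
    st.integers(min_value=0, max_value=30),
    st.integers(min_value=0, max_value=30),
    st.integers(min_value=0, max_value=30),
    st.booleans(),
    st.booleans(),
)
def test_prediction_invariants_property(L1, L2, L3, mod, lig):
    pred = allowed_topologies(
        RuleQuery(L1, L2, L3, has_modified_guanines=mod, has_ligand=lig)
    )
    allowed = set(pred.allowed_topologies())
    assert allowed <= set(ALL_TOPOLOGIES)
    assert allowed
    assert not (allowed & {t for t, _ in pred.excluded})
    if mod or lig:
        assert pred.excluded == []
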