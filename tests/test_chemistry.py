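"""Trait formulas, motif matching, mutagenic copying and pair classification."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from riboworld.chemistry import (
    BASE_ACTIVITY,
    ActivityRule,
    ChemistryParams,
    MotifMatch,
    RuleTable,
    classify_pair,
    complement,
    degradation_rate,
    folding_probability,
    load_rules,
    match_motif,
    motif_alpha,
    mutate_copy,
    replicability,
    strand_activities,
)
from riboworld.folding import Loop, enumerate_loops


class TestRuleTable:
    def test_packaged_table_matches_published_rules(self):
        rules = load_rules()
        assert len(rules) == 10
        expected = [
            (1, "loop", 7, "AGC"),
            (2, "interloop", 11, "CCG"),
            (3, "interloop", 5, "GCG"),
            (4, "interloop", 15, "CCC"),
            (5, "loop", 15, "UGU"),
            (6, "interloop", 13, "CUG"),
            (7, "loop", 9, "CUU"),
            (8, "loop", 17, "UAA"),
            (9, "interloop", 9, "CUC"),
            (10, "loop", 13, "AUG"),
        ]
        got = [(r.id, r.motif_kind, r.loop_length, r.triplet) for r in rules]
        assert got == expected

    def test_A_bounds(self):
        with pytest.raises(ValueError):
            RuleTable(load_rules(), 11)


class TestTraitFormulas:
    @pytest.mark.parametrize(
        "dG,expected",
        [
            (0.0, 0.9),                                 # open-chain maximum
            (-1000.0, 0.1),                             # stable-fold floor
            (-25.0, 0.1 + 0.8 * math.exp(-5.0)),        # 0.10539
        ],
    )
    def test_degradation_rate(self, dG, expected):
        assert degradation_rate(dG, 0.2) == pytest.approx(expected, abs=1e-5)

    def test_degradation_clamps_positive_energy(self):
        with pytest.warns(UserWarning):
            assert degradation_rate(5.0, 0.2) == pytest.approx(0.9)

    @given(st.floats(min_value=-200, max_value=0))
    def test_degradation_bounded(self, dG):
        assert 0.1 <= degradation_rate(dG, 0.2) <= 0.9

    @pytest.mark.parametrize(
        "dG,expected",
        [
            (-25.0, 1.0),     # clamped at the empirical minimum energy
            (0.0, 0.5),       # sigmoid midpoint
            (-10.0, 1.0 - 1.0 / (1.0 + math.exp(3.0))),  # 0.95257
        ],
    )
    def test_folding_probability(self, dG, expected):
        assert folding_probability(dG, 0.3, -25.0) == pytest.approx(expected, abs=1e-5)

    @given(st.floats(min_value=-100, max_value=0), st.floats(min_value=-100, max_value=0))
    def test_folding_probability_monotone_nonincreasing(self, a, b):
        lo, hi = min(a, b), max(a, b)
        assert folding_probability(lo) >= folding_probability(hi)

    @pytest.mark.parametrize(
        "L,P_fold,expected",
        [
            (45, 1.0, 10.0 / 0.975),          # 10.2564
            (45, 0.0, 20.0 / 0.975),          # 20.5128
            (15, 0.5, 15.0 / 0.825),          # 18.1818
        ],
    )
    def test_replicability(self, L, P_fold, expected, params):
        assert replicability(L, P_fold, params) == pytest.approx(expected, rel=1e-6)

    @given(
        L1=st.integers(min_value=8, max_value=200),
        L2=st.integers(min_value=8, max_value=200),
        p1=st.floats(min_value=0, max_value=1),
        p2=st.floats(min_value=0, max_value=1),
    )
    def test_replicability_monotone_decreasing(self, L1, L2, p1, p2, params):
        R = lambda L, p: replicability(L, p, params)
        assert R(min(L1, L2), p1) >= R(max(L1, L2), p1) > 0
        assert R(L1, min(p1, p2)) >= R(L1, max(p1, p2)) > 0


def _hairpin(length: int, start: int = 3) -> Loop:
    return Loop("hairpin", tuple(range(start, start + length)))


class TestMotifMatching:
    rule1 = ActivityRule(1, "loop", 7, "AGC")

    def test_full_triplet_match(self):
        a_bar, n_gc = match_motif(_hairpin(7), "UUAGCUU", self.rule1)
        assert a_bar == 1.0
        assert n_gc == 0

    def test_two_of_three_matches(self):
        a_bar, n_gc = match_motif(_hairpin(7), "UUAGGUU", self.rule1)
        assert a_bar == 0.8
        # the non-matching central G is not a flanking base: all four
        # flanking bases are U, so no GC bonus counts
        assert n_gc == 0

    def test_flanking_gc_counted(self):
        a_bar, n_gc = match_motif(_hairpin(7), "GUAGGUC", self.rule1)
        assert a_bar == 0.8
        assert n_gc == 2

    def test_length_mismatch_is_no_match(self):
        assert match_motif(_hairpin(9), "UUUAGCUUU", self.rule1) is None

    def test_kind_mismatch_is_no_match(self):
        interior = Loop("interior", tuple(range(2, 9)))
        assert match_motif(interior, "UUAGCUU", self.rule1) is None

    def test_base_activity_levels(self):
        for core, expected in [("UUU", 0.0), ("AUU", 0.1), ("AGU", 0.8), ("AGC", 1.0)]:
            a_bar, _ = match_motif(_hairpin(7), "UU" + core + "UU", self.rule1)
            assert a_bar == expected
        assert BASE_ACTIVITY == (0.0, 0.1, 0.8, 1.0)

    @pytest.mark.parametrize(
        "a_bar,n_gc,expected",
        [
            (0.8, 0, 1.05),
            (0.8, 4, 0.8 + 0.5 / (1 + math.exp(-1.2))),  # 1.18424
            (1.0, 1000, 1.5),                             # sigmoid limit a_bar + 0.5
        ],
    )
    def test_motif_alpha(self, a_bar, n_gc, expected):
        assert motif_alpha(a_bar, n_gc, -0.3) == pytest.approx(expected, abs=1e-5)

    def test_exhaustive_scan_oracle(self, chem7, rules7):
        """The trait pipeline agrees with an independent loop x rule scan."""
        rng = np.random.default_rng(11)
        checked_any = False
        for _ in range(40):
            seq = "".join(rng.choice(list("ACGU"), size=40))
            rep = chem7.replicator(seq)
            # independent scan over every loop and rule
            expected = []
            for loop in enumerate_loops(rep.structure):
                for rule in rules7.active_rules:
                    scored = match_motif(loop, loop.sequence(seq), rule)
                    if scored and scored[0] > 0:
                        expected.append((rule.id, loop.unpaired_positions))
            got = [(m.rule_id, m.loop.unpaired_positions) for m in rep.traits.matched_motifs]
            assert sorted(got) == sorted(expected)
            checked_any = checked_any or bool(expected)


class TestStrandActivities:
    def _match(self, rule_id, alpha):
        return MotifMatch(rule_id, _hairpin(7), 1.0, 0, alpha)

    def test_single_motif_no_penalty(self, rules7):
        a = strand_activities([self._match(1, 1.05)], 1.0, 1.1, 7, rules7)
        assert a[0] == pytest.approx(1.05)
        assert a[1:].sum() == 0

    @pytest.mark.parametrize("m,expected", [(2, 2**-1.1), (3, 3**-1.1)])
    def test_subadditive_penalty(self, m, expected, rules7):
        matches = [self._match(i + 1, 1.0) for i in range(m)]
        a = strand_activities(matches, 1.0, 1.1, 7, rules7)
        assert a[:m] == pytest.approx([expected] * m)

    def test_inactive_motifs_do_not_count_toward_m(self, rules7):
        matches = [
            MotifMatch(1, _hairpin(7), 0.0, 2, 0.25),  # dead motif
            self._match(2, 1.0),
        ]
        a = strand_activities(matches, 1.0, 1.1, 7, rules7)
        assert a[1] == pytest.approx(1.0)  # m == 1: no penalty

    def test_repeated_rule_accumulates_in_one_slot(self, rules7):
        matches = [self._match(1, 1.0), self._match(1, 1.0)]
        a = strand_activities(matches, 1.0, 1.1, 7, rules7)
        assert a[0] == pytest.approx(2.0 / 2**1.1)
        assert np.count_nonzero(a) == 1

    @given(m=st.integers(min_value=1, max_value=8))
    def test_total_output_decreases_with_m(self, m, rules7):
        """Sum of activities strictly decreases in m at fixed total alpha."""
        total_alpha = 4.0
        matches = [self._match((i % 7) + 1, total_alpha / m) for i in range(m)]
        out_m = strand_activities(matches, 1.0, 1.1, 7, rules7).sum()
        assert out_m == pytest.approx(total_alpha / m**0.1 / m, rel=1e-9)
        if m > 1:
            fewer = [self._match((i % 7) + 1, total_alpha / (m - 1)) for i in range(m - 1)]
            out_fewer = strand_activities(fewer, 1.0, 1.1, 7, rules7).sum()
            assert out_fewer > out_m


class TestCopying:
    def test_complement_examples(self):
        assert complement("AAA") == "UUU"
        assert complement("GACU") == "AGUC"

    @given(st.text(alphabet="ACGU", min_size=1, max_size=60))
    def test_complement_is_involution(self, seq):
        assert complement(complement(seq)) == seq

    def test_zero_rates_give_exact_reverse_complement(self, rng):
        p = ChemistryParams(p_sub=0.0, p_ins=0.0, p_del=0.0)
        seq = "GAUCGAUCGGAUUACG"
        assert mutate_copy(seq, p, rng) == complement(seq)

    def test_full_deletion_gives_empty_copy(self, rng):
        p = ChemistryParams(p_sub=0.0, p_ins=0.0, p_del=1.0)
        assert mutate_copy("ACGUACGU", p, rng) == ""

    def test_mean_length_change_is_zero(self, params):
        """p_ins == p_del, so the expected length change per copy is 0."""
        rng = np.random.default_rng(123)
        n, L = 20_000, 45
        template = "".join(np.random.default_rng(5).choice(list("ACGU"), size=L))
        deltas = np.array(
            [len(mutate_copy(template, params, rng)) - L for i in range(n)]
        )
        # per base: +1 w.p. p_ins, -1 w.p. p_del -> var per base ~ p_ins + p_del
        se = math.sqrt(L * (params.p_ins + params.p_del) / n)
        assert abs(deltas.mean()) < 3 * se

    def test_substitutions_never_reproduce_the_correct_base(self):
        p = ChemistryParams(p_sub=1.0, p_ins=0.0, p_del=0.0)
        rng = np.random.default_rng(9)
        seq = "GGGGGGGGGG"
        copy = mutate_copy(seq, p, rng)
        assert len(copy) == len(seq)
        assert "C" not in copy  # the correct complementary base is excluded


class TestClassifyPair:
    def _traits(self, chem, seq):
        return chem.replicator(seq).traits

    def test_flag_combinations(self, rules7):
        def fake(n_active):
            matches = tuple(
                MotifMatch(i + 1, _hairpin(7), 1.0, 0, 1.25) for i in range(n_active)
            )
            from riboworld.chemistry import ReplicatorTraits

            a = strand_activities(list(matches), 1.0, 1.1, 7, rules7)
            return ReplicatorTraits(45, -10.0, 0.2, 0.9, 10.0, a, matches)

        specialist = classify_pair(fake(1), fake(0))
        assert specialist.specialist
        assert specialist.functional_parasite_complement
        assert not specialist.cis_promiscuous and not specialist.trans_promiscuous

        parasite = classify_pair(fake(0), fake(0))
        assert parasite.real_parasite
        assert parasite.label == "real_parasite"

        promiscuous = classify_pair(fake(2), fake(1))
        assert promiscuous.cis_promiscuous and promiscuous.trans_promiscuous
        assert not promiscuous.real_parasite

    def test_symmetric_up_to_cis_labels(self, rules7):
        def fake(n_active):
            matches = tuple(
                MotifMatch(i + 1, _hairpin(7), 1.0, 0, 1.25) for i in range(n_active)
            )
            from riboworld.chemistry import ReplicatorTraits

            a = strand_activities(list(matches), 1.0, 1.1, 7, rules7)
            return ReplicatorTraits(45, -10.0, 0.2, 0.9, 10.0, a, matches)

        ab = classify_pair(fake(2), fake(1))
        ba = classify_pair(fake(1), fake(2))
        assert ab.trans_promiscuous == ba.trans_promiscuous
        assert ab.real_parasite == ba.real_parasite
        assert ab.specialist == ba.specialist
        assert ab.cis_promiscuous and not ba.cis_promiscuous
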