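from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, strategies as st

from shiftannot.context_assign import (
    TURN_TYPES,
    AnnotationError,
    ContextConfig,
    StrandTopology,
    TurnAssignment,
    angular_deviation,
    annotation_tsv,
    charge_pattern,
    classify_turn,
    detect_hairpins,
    edge_criteria,
    find_turns,
    ha_alternation,
    hydropathy_periodicity,
    merge_annotation,
)
from shiftannot.dynamics import FasaProfile, OrderProfile
from shiftannot.shift_profiles import SSAssignment, SecondaryShiftProfile
from shiftannot.shiftio import TorsionEntry, TorsionTable

CFG = ContextConfig()
CANON = CFG.canonical_turn_angles


class TestAngularDeviation:
    def test_wraparound(self):
        assert angular_deviation(-170, 175) == pytest.approx(15)

    def test_identity(self):
        assert angular_deviation(37.5, 37.5) == 0.0

    def test_long_way_round(self):
        assert angular_deviation(-60, 60) == pytest.approx(120)


class TestClassifyTurn:
    @pytest.mark.parametrize("ttype", TURN_TYPES)
    def test_exact_canonical_self_match(self, ttype):
        got, devs = classify_turn(*CANON[ttype])
        assert got == ttype
        assert devs == (0.0, 0.0, 0.0, 0.0)

    @pytest.mark.parametrize("ttype", TURN_TYPES)
    @pytest.mark.parametrize("slot", range(4))
    def test_one_angle_at_44_accepted(self, ttype, slot):
        angles = list(CANON[ttype])
        angles[slot] += 44.0
        assert classify_turn(*angles)[0] == ttype

    @pytest.mark.parametrize("ttype", TURN_TYPES)
    def test_one_angle_at_45_boundary_inclusive(self, ttype):
        angles = list(CANON[ttype])
        angles[3] += 45.0
        assert classify_turn(*angles)[0] == ttype

    @pytest.mark.parametrize("ttype", TURN_TYPES)
    def test_one_angle_at_46_rejected(self, ttype):
        angles = list(CANON[ttype])
        angles[3] += 46.0
        got, _ = classify_turn(*angles)
        assert got != ttype

    def test_two_angles_at_31_rejected_brute_force(self):
        angles = list(CANON["I"])
        angles[0] += 31.0
        angles[1] += 31.0
        # independent brute force over the canonical table
        for ttype in TURN_TYPES:
            devs = [angular_deviation(a, c) for a, c in zip(angles, CANON[ttype])]
            ok = sum(d <= 30 for d in devs) >= 3 and max(devs) <= 45
            assert not ok, ttype
        assert classify_turn(*angles)[0] is None

    def test_smallest_total_deviation_wins(self):
        # nudge type-I angles slightly; I must beat everything else
        got, devs = classify_turn(-55, -25, -85, 5)
        assert got == "I"
        assert sum(devs) == pytest.approx(20.0)

    @pytest.mark.parametrize(
        "a,b", [("I", "I'"), ("I'", "I"), ("II", "II'"), ("II'", "II")]
    )
    def test_mirror_on_exact_canonicals(self, a, b):
        negated = [-x for x in CANON[a]]
        assert classify_turn(*negated)[0] == b

    @given(
        st.sampled_from(["I", "II", "I'", "II'"]),
        st.tuples(*[st.floats(-20, 20) for _ in range(4)]),
    )
    def test_mirror_under_perturbation(self, ttype, offsets):
        mirror = {"I": "I'", "I'": "I", "II": "II'", "II'": "II"}
        angles = [c + o for c, o in zip(CANON[ttype], offsets)]
        assert classify_turn(*angles)[0] == ttype
        assert classify_turn(*[-a for a in angles])[0] == mirror[ttype]


def _turn_fixture(n=6):
    ss = SSAssignment("C" * n)
    order = OrderProfile([0.9] * n, {})
    return ss, order


class TestFindTurns:
    def test_gate_is_strictly_above_0_70(self):
        ss, order = _turn_fixture()
        order.s2[2] = 0.70  # exactly at the gate -> excluded
        torsions = TorsionTable(
            {i: TorsionEntry(*CANON["I"][(i - 3) % 2 * 2 : (i - 3) % 2 * 2 + 2])
             for i in (3, 4)}
        )
        assert find_turns(ss, order, torsions) == []
        order.s2[2] = 0.71
        assert len(find_turns(ss, order, torsions)) == 1

    def test_single_coil_residue_never_evaluated(self):
        ss = SSAssignment("BBBCBBB")
        order = OrderProfile([0.95] * 7, {})
        torsions = TorsionTable({i: TorsionEntry(-60, -30) for i in range(1, 8)})
        assert find_turns(ss, order, torsions) == []

    def test_missing_torsions_skip_window(self):
        ss, order = _turn_fixture()
        assert find_turns(ss, order, TorsionTable({})) == []

    def test_greedy_prefers_smaller_total_deviation(self):
        ss, order = _turn_fixture()
        torsions = TorsionTable(
            {
                3: TorsionEntry(-60.0, -30.0),   # exact I central-1
                4: TorsionEntry(-70.0, 0.0),     # I central-2, 20 deg off phi
                5: TorsionEntry(-90.0, -25.0),
            }
        )
        turns = find_turns(ss, order, torsions)
        assert len(turns) == 1
        assert turns[0].central == (3, 4)
        assert turns[0].total_deviation == pytest.approx(20.0)

    def test_undefined_s2_fails_gate(self):
        ss, order = _turn_fixture()
        order.s2[2] = None
        torsions = TorsionTable(
            {3: TorsionEntry(-60, -30), 4: TorsionEntry(-90, 0)}
        )
        assert find_turns(ss, order, torsions) == []

    def test_gate_monotonicity(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = 14
            ss = SSAssignment("C" * n)
            order = OrderProfile(list(rng.uniform(0.6, 1.0, n)), {})
            entries = {}
            for i in range(1, n + 1):
                base = CANON[str(rng.choice(list(TURN_TYPES)))]
                slot = int(rng.integers(0, 2))
                entries[i] = TorsionEntry(
                    base[2 * slot] + rng.normal(0, 20),
                    base[2 * slot + 1] + rng.normal(0, 20),
                )
            torsions = TorsionTable(entries)
            counts = [
                len(find_turns(ss, order, torsions, CFG.replace(s2_turn_gate=g)))
                for g in (0.6, 0.7, 0.8, 0.9)
            ]
            assert counts == sorted(counts, reverse=True)


class TestDetectHairpins:
    def _ss(self, loop_len: int) -> SSAssignment:
        return SSAssignment("BBBB" + "C" * loop_len + "BBBB")

    def _turn_in_loop(self, loop_start: int) -> TurnAssignment:
        return TurnAssignment(
            start=loop_start - 1, turn_type="I'",
            deviations=(0, 0, 0, 0), total_deviation=0.0,
        )

    @pytest.mark.parametrize("loop_len", [2, 4, 6])
    def test_short_loop_with_turn(self, loop_len):
        hp = detect_hairpins(self._ss(loop_len), [self._turn_in_loop(5)])
        assert len(hp) == 1
        assert hp[0].strand1 == (1, 4)
        assert hp[0].loop == (5, 4 + loop_len)
        assert hp[0].turn.turn_type == "I'"

    def test_loop_of_seven_rejected(self):
        assert detect_hairpins(self._ss(7), [self._turn_in_loop(5)]) == []

    def test_loop_without_turn_rejected(self):
        assert detect_hairpins(self._ss(4), []) == []

    def test_turn_central_must_sit_inside_loop(self):
        # central pair (4,5) straddles the strand/loop boundary
        t = TurnAssignment(3, "I", (0, 0, 0, 0), 0.0)
        assert detect_hairpins(self._ss(4), [t]) == []

    def test_strict_mirror_mode(self):
        t = TurnAssignment(5, "I", (0, 0, 0, 0), 0.0)
        assert detect_hairpins(self._ss(4), [t]) != []
        cfg = CFG.replace(strict_mirror_turns=True)
        assert detect_hairpins(self._ss(4), [t], cfg) == []


class TestHaAlternation:
    def _profile(self, deltas):
        return SecondaryShiftProfile(
            {(i, "HA"): d for i, d in enumerate(deltas, 1) if d is not None},
            len(deltas),
        )

    def test_perfect_alternation(self):
        p = self._profile([0.3, -0.2, 0.4, -0.1])
        assert ha_alternation((1, 4), p) is True

    def test_uniform_downfield(self):
        p = self._profile([0.3, 0.2, 0.4, 0.1])
        assert ha_alternation((1, 4), p) is False

    def test_two_of_three_pairs_below_cutoff(self):
        p = self._profile([0.3, -0.2, 0.4, 0.1])
        assert ha_alternation((1, 4), p) is False

    def test_missing_ha_pairs_unavailable(self):
        # only one available pair, and it alternates
        p = self._profile([0.3, -0.2, None, 0.1])
        assert ha_alternation((1, 4), p) is True

    def test_no_available_pairs(self):
        p = self._profile([None, None, None])
        assert ha_alternation((1, 3), p) is False


class TestSequencePatterns:
    def test_hydropathy_perfect_alternation(self):
        assert hydropathy_periodicity("VKLEI") is True

    def test_hydropathy_all_hydrophobic(self):
        assert hydropathy_periodicity("VLIAF") is False

    def test_hydropathy_half_alternating(self):
        assert hydropathy_periodicity("VKLLI") is False  # 2/4 pairs < 0.7

    def test_charge_central(self):
        assert charge_pattern("VVKVVV") is True  # K in central third

    def test_no_charges(self):
        assert charge_pattern("VVVVVV") is False

    def test_charge_proportion_at_termini(self):
        assert charge_pattern("DVVVVVVE") is True  # 2/8 = 0.25 proportion


class TestEdgeCriteria:
    def _topo(self, seq, ha, s2, fasa, cfg=None):
        n = len(seq)
        p = SecondaryShiftProfile(
            {(i, "HA"): d for i, d in enumerate(ha, 1)}, n
        )
        return edge_criteria(
            (1, n), p, OrderProfile(list(s2), {}), FasaProfile(list(fasa)),
            seq, cfg or CFG,
        )

    def test_short_strand_boundary(self):
        t4 = self._topo("VVVV", [0.1] * 4, [0.95] * 4, [0.1] * 4)
        t5 = self._topo("VVVVV", [0.1] * 5, [0.95] * 5, [0.1] * 5)
        assert t4.criteria["short_strand"] is True
        assert t5.criteria["short_strand"] is False

    def test_mean_fasa_strictly_above_030(self):
        lo = self._topo("VVVV", [0.1] * 4, [0.95] * 4, [0.30] * 4)
        hi = self._topo("VVVV", [0.1] * 4, [0.95] * 4, [0.31] * 4)
        assert lo.criteria["high_avg_fasa"] is False
        assert hi.criteria["high_avg_fasa"] is True

    def test_exposed_majority_strict(self):
        half = self._topo("VVVV", [0.1] * 4, [0.95] * 4, [0.26, 0.26, 0.2, 0.2])
        most = self._topo("VVVV", [0.1] * 4, [0.95] * 4, [0.26, 0.26, 0.26, 0.2])
        assert half.criteria["exposed_majority"] is False
        assert most.criteria["exposed_majority"] is True

    def test_rigid_fraction_strict(self):
        # 2/5 = 0.40 rigid is not < 0.40
        at = self._topo("VVVVV", [0.1] * 5, [0.95, 0.95, 0.5, 0.5, 0.5], [0.1] * 5)
        below = self._topo("VVVVV", [0.1] * 5, [0.95, 0.5, 0.5, 0.5, 0.5], [0.1] * 5)
        assert at.criteria["low_rigid_fraction"] is False
        assert below.criteria["low_rigid_fraction"] is True

    def test_score_five_is_edge_four_is_interior(self):
        # KVKV: alternating HA, high fasa, hydropathy, charge, short = 5
        edge = self._topo(
            "KVKV", [0.3, -0.2, 0.4, -0.3], [0.95] * 4, [0.9, 0.9, 0.2, 0.2]
        )
        assert edge.edge_score == 5
        assert edge.call == "edge"
        # KVKVK: same signals but length 5 drops the short-strand point
        interior = self._topo(
            "KVKVK", [0.3, -0.2, 0.4, -0.3, 0.2], [0.95] * 5,
            [0.9, 0.9, 0.2, 0.2, 0.2],
        )
        assert interior.edge_score == 4
        assert interior.call == "interior"


class TestMergeAnnotation:
    def test_helix_only(self):
        ss = SSAssignment("CHHHHC")
        ann = merge_annotation(ss, [], [], [], "AAAAAA")
        assert ann.turns == [] and ann.hairpins == [] and ann.strands == []
        assert ann.states == "CHHHHC"

    def test_turn_on_helix_residue_raises(self):
        ss = SSAssignment("CHHHHC")
        t = TurnAssignment(1, "I", (0, 0, 0, 0), 0.0)
        with pytest.raises(AnnotationError):
            merge_annotation(ss, [t], [], [], "AAAAAA")

    def test_topology_span_mismatch_raises(self):
        ss = SSAssignment("BBBBCC")
        topo = StrandTopology((1, 3), {}, 0, "interior")
        with pytest.raises(AnnotationError):
            merge_annotation(ss, [], [], [topo], "AAAAAA")

    def test_hairpin_fixture_merges(self, hairpin_result):
        ann = hairpin_result.truth
        assert len(ann.hairpins) == 1
        assert sum(ann.hairpin_flags) == 14  # strand+loop+strand span
        assert annotation_tsv(ann).startswith("residue\t")


class TestDeterminism:
    def test_byte_identical_annotation(self, hairpin_result):
        from shiftannot.pipeline_cli import annotate_dataset

        a = annotate_dataset(hairpin_result.dataset, hairpin_result.torsion_table)
        b = annotate_dataset(hairpin_result.dataset, hairpin_result.torsion_table)
        assert annotation_tsv(a.annotation) == annotation_tsv(b.annotation)
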