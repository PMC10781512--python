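import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from miredit._sequences import (
    ANTA_E_DNA,
    ANTA_N_DNA,
    MIR376A_3P_EDIT_POSITION,
    MIR376A_3P_EDITED,
    MIR376A_3P_UNEDITED,
    reverse_complement_rna,
    reverse_complement_to_dna,
)
from miredit.simulate import simulate_utrs
from miredit.target_switch import (
    SiteMatch,
    apply_edit,
    compare_target_pools,
    locate_edits,
    scan_utr,
    scan_utr_set,
    seed_of,
    site_patterns,
    target_switch_analysis,
)

rna = st.text(alphabet="ACGU", min_size=1, max_size=80)


class TestApplyEdit:
    def test_mir376a_edit_reproduces_edited_mature(self):
        assert apply_edit(MIR376A_3P_UNEDITED, 6) == MIR376A_3P_EDITED

    def test_non_adenosine_position_rejected(self):
        with pytest.raises(ValueError, match="not A"):
            apply_edit(MIR376A_3P_UNEDITED, 7)  # G there

    @given(rna)
    def test_edit_changes_exactly_one_base(self, seq):
        positions = [i + 1 for i, b in enumerate(seq) if b == "A"]
        if not positions:
            return
        edited = apply_edit(seq, positions[0])
        assert sum(a != b for a, b in zip(seq, edited)) == 1


class TestSeed:
    def test_edited_mir376a_seed(self):
        assert seed_of(MIR376A_3P_EDITED) == "UCAUGGA"

    def test_unedited_mir376a_seed(self):
        assert seed_of(MIR376A_3P_UNEDITED) == "UCAUAGA"

    def test_seed_edit_changes_seed_at_one_position(self):
        s1, s2 = seed_of(MIR376A_3P_UNEDITED), seed_of(MIR376A_3P_EDITED)
        assert sum(a != b for a, b in zip(s1, s2)) == 1

    def test_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            seed_of("ACGUACG")


class TestAntimirConsistency:
    """The printed antimirs are DNA antisense to mature positions 2-16."""

    def test_anta_e_matches_edited_mature(self):
        assert reverse_complement_to_dna(MIR376A_3P_EDITED[1:16]) == ANTA_E_DNA

    def test_anta_n_matches_unedited_mature(self):
        assert reverse_complement_to_dna(MIR376A_3P_UNEDITED[1:16]) == ANTA_N_DNA


class TestSitePatterns:
    def test_edited_seed_patterns(self):
        pats = site_patterns("UCAUGGA")
        assert pats == {"8mer": "UCCAUGAA", "7mer-m8": "UCCAUGA", "7mer-A1": "CCAUGAA"}

    def test_unedited_seed_7mer_m8(self):
        assert site_patterns("UCAUAGA")["7mer-m8"] == "UCUAUGA"

    def test_edit_changes_m8_pattern_at_one_position(self):
        a = site_patterns(seed_of(MIR376A_3P_UNEDITED))["7mer-m8"]
        b = site_patterns(seed_of(MIR376A_3P_EDITED))["7mer-m8"]
        assert sum(x != y for x, y in zip(a, b)) == 1

    def test_seed_recoverable_from_m8_pattern(self):
        seed = "UCAUGGA"
        assert reverse_complement_rna(site_patterns(seed)["7mer-m8"]) == seed

    def test_non_acgu_seed_rejected(self):
        with pytest.raises(ValueError):
            site_patterns("UCAUGGN")

    @given(st.text(alphabet="ACGU", min_size=7, max_size=7))
    def test_revcomp_involution(self, seed):
        assert reverse_complement_rna(reverse_complement_rna(seed)) == seed


class TestScanUtr:
    patterns = site_patterns("UCAUGGA")

    def test_8mer_reported_once_with_strongest_type(self):
        utr = "CCCC" + "UCCAUGAA" + "CCCC"
        matches = scan_utr("u1", utr, self.patterns)
        assert matches == [SiteMatch("u1", 5, "8mer")]

    def test_7mer_m8_without_trailing_a(self):
        utr = "CCCC" + "UCCAUGA" + "CCCC"  # next base C, not A
        matches = scan_utr("u1", utr, self.patterns)
        assert matches == [SiteMatch("u1", 5, "7mer-m8")]

    def test_7mer_a1_alone(self):
        utr = "CCCG" + "CCAUGAA" + "CCCC"  # no m8 match upstream
        matches = scan_utr("u1", utr, self.patterns)
        assert matches == [SiteMatch("u1", 5, "7mer-A1")]

    def test_all_c_utr_has_no_matches(self):
        assert scan_utr("u1", "C" * 200, self.patterns) == []

    def test_matches_bruteforce_oracle_on_random_utr(self):
        rng = np.random.default_rng(3)
        utr = "".join(rng.choice(list("ACGU"), size=10_000))

        def oracle(utr, patterns):
            found = []
            eight = set()
            for s in range(len(utr)):
                if utr.startswith(patterns["8mer"], s):
                    eight.add(s)
                    found.append((s + 1, "8mer"))
            for s in range(len(utr)):
                if utr.startswith(patterns["7mer-m8"], s) and s not in eight:
                    found.append((s + 1, "7mer-m8"))
            for s in range(len(utr)):
                if utr.startswith(patterns["7mer-A1"], s) and (s - 1) not in eight:
                    found.append((s + 1, "7mer-A1"))
            return sorted(found)

        got = sorted((m.start, m.site_type) for m in scan_utr("u", utr, self.patterns))
        assert got == oracle(utr, self.patterns)
        assert got  # a 10-kb random UTR contains seed matches


class TestComparePools:
    def test_set_arithmetic(self):
        a = [SiteMatch(u, 1, "8mer") for u in "abc"]
        b = [SiteMatch(u, 1, "8mer") for u in "cd"]
        cmp = compare_target_pools(a, b)
        assert cmp.n_shared == 1
        assert cmp.shared_fraction == pytest.approx(0.25)  # 1 of union {a,b,c,d}
        assert cmp.shared_of_b == pytest.approx(0.5)

    def test_identical_pools(self):
        a = [SiteMatch("x", 3, "7mer-m8"), SiteMatch("y", 9, "8mer")]
        cmp = compare_target_pools(a, list(a))
        assert cmp.shared_fraction == 1.0

    def test_empty_pools(self):
        cmp = compare_target_pools([], [])
        assert cmp.n_shared == 0 and cmp.shared_fraction == 0.0

    def test_disjoint_planted_fixture(self):
        # UTRs carrying only edited-seed sites vs only unedited-seed sites
        edited = site_patterns(seed_of(MIR376A_3P_EDITED))
        unedited = site_patterns(seed_of(MIR376A_3P_UNEDITED))
        planted = {
            "utr-0001": [edited["8mer"]],
            "utr-0002": [edited["7mer-m8"]],
            "utr-0003": [unedited["8mer"]],
            "utr-0004": [unedited["7mer-A1"]],
        }
        utrs = [
            (uid, seq.replace("A", "C") if uid == "utr-0005" else seq)
            for uid, seq in simulate_utrs(5, 80, rng_seed=99, planted_patterns=planted)
        ]
        # scrub chance cross-matches so the pools are disjoint by design
        utrs = [
            (uid, _scrub(seq, unedited) if uid in ("utr-0001", "utr-0002") else
             _scrub(seq, edited) if uid in ("utr-0003", "utr-0004") else seq)
            for uid, seq in utrs
        ]
        m_non = scan_utr_set(utrs, unedited)
        m_edit = scan_utr_set(utrs, edited)
        cmp = compare_target_pools(m_non, m_edit)
        assert cmp.n_shared == 0 and cmp.shared_fraction == 0.0


def _scrub(seq: str, patterns: dict) -> str:
    """Remove any chance occurrences of the given site patterns."""
    for pat in patterns.values():
        while pat in seq:
            seq = seq.replace(pat, "C" * len(pat), 1)
    return seq


class TestLocateEdits:
    def test_single_edit_found(self):
        assert locate_edits(MIR376A_3P_UNEDITED, MIR376A_3P_EDITED) == [
            MIR376A_3P_EDIT_POSITION
        ]

    def test_non_ag_difference_rejected(self):
        with pytest.raises(ValueError, match="non-A->G"):
            locate_edits("AAAA", "AUAA")

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            locate_edits("AAAA", "AAAAA")


def test_target_switch_analysis_end_to_end():
    edited = site_patterns(seed_of(MIR376A_3P_EDITED))
    unedited = site_patterns(seed_of(MIR376A_3P_UNEDITED))
    planted = {
        "utr-0001": [edited["8mer"]],
        "utr-0002": [unedited["8mer"]],
        "utr-0003": [edited["7mer-m8"], unedited["7mer-m8"]],  # shared target
    }
    utrs = simulate_utrs(3, 120, rng_seed=7, planted_patterns=planted)
    utrs = [(u, _scrub_except(s, u)) for u, s in utrs]
    table, cmp = target_switch_analysis(
        "hsa-miR-376a-3p", MIR376A_3P_UNEDITED, 6, utrs
    )
    assert {"hsa-miR-376a-3p", "hsa-miR-376a-3p(+6)"} == set(table.isomir)
    assert cmp.n_shared == 1  # exactly the doubly-planted UTR


def _scrub_except(seq: str, uid: str) -> str:
    edited = site_patterns(seed_of(MIR376A_3P_EDITED))
    unedited = site_patterns(seed_of(MIR376A_3P_UNEDITED))
    if uid == "utr-0001":
        return _scrub(seq, unedited)
    if uid == "utr-0002":
        return _scrub(seq, edited)
    return seq
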