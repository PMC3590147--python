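"""Consensus calling, classification, bimodality guard and correction."""

from collections import Counter
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from _oracle import classify_oracle
from orfclean import (
    AMINO_ACIDS,
    ConsensusCall,
    CorrectionCall,
    CorrectionParams,
    EndOverhangs,
    FIVE_PRIME,
    THREE_PRIME,
    OrthologSet,
    PairwiseHit,
    ProteinSequence,
    apply_correction,
    bimodal_guard,
    classify_end,
    consensus_end,
    correct_set,
    generate_donor_pool,
    generate_family,
    inject_errors,
    qualifying_hits,
    SimulationProfile,
)


def _hit(ref_id, identity, bitscore=100.0):
    return PairwiseHit("q", ref_id, 1, 50, 1, 50, identity, 1e-30, bitscore)


class TestQualifyingHits:
    def test_all_above_threshold_kept(self, params):
        hits = [_hit(f"r{i}", 0.95) for i in range(6)]
        assert qualifying_hits(hits, params) == hits

    def test_below_min_refs_signals_uncorrectable(self, params):
        hits = [_hit(f"r{i}", 0.95) for i in range(4)]
        assert qualifying_hits(hits, params) == []

    def test_comparison_cap(self):
        params = CorrectionParams(max_comparisons=10)
        hits = [_hit(f"r{i:03d}", 0.95) for i in range(25)]
        assert len(qualifying_hits(hits, params)) == 10

    def test_identity_filter(self, params):
        hits = [_hit(f"lo{i}", 0.85) for i in range(3)] + \
               [_hit(f"hi{i}", 0.92) for i in range(6)]
        kept = qualifying_hits(hits, params)
        assert all(h.ref_id.startswith("hi") for h in kept)


def _ov5(pairs):
    return [EndOverhangs(q5=q, r5=r, q3=0, r3=0) for q, r in pairs]


class TestConsensusEnd:
    def test_longest_candidate_wins(self, params):
        """With two pairs above 33%, the one implying the longer corrected
        sequence is chosen — verified by exhaustive enumeration."""
        pairs = [(5, 0)] * 4 + [(3, 0)] * 2
        call = consensus_end(_ov5(pairs), FIVE_PRIME, params)
        # brute-force: enumerate candidates, maximize corrected length
        n = len(pairs)
        cands = [p for p, c in Counter(pairs).items() if c / n >= 0.33]
        assert set(cands) == {(5, 0), (3, 0)}
        # (5,0) implies trim 5; (3,0) implies a 2-residue-longer result
        assert (call.q_overhang, call.r_overhang) == (3, 0)
        assert call.support == pytest.approx(2 / 6)

    def test_unanimous_identity_case(self, params):
        call = consensus_end(_ov5([(0, 0)] * 10), FIVE_PRIME, params)
        assert (call.q_overhang, call.r_overhang) == (0, 0)
        assert call.support == 1.0
        assert call.n_comparisons == 10

    def test_no_pair_reaches_threshold(self, params):
        call = consensus_end(_ov5([(1, 0), (2, 0), (3, 0), (4, 0)]),
                             FIVE_PRIME, params)
        assert call is None


class TestClassifyEnd:
    def _call(self, end, q, r):
        return ConsensusCall(end, q, r, support=0.9, n_comparisons=10)

    def test_chimeric_when_both_overhangs_large(self, params):
        out = classify_end("s", self._call(FIVE_PRIME, 12, 11), params)
        assert (out.kind, out.trim, out.pad) == ("chimeric", 12, 11)

    def test_overextended_on_query_overhang(self, params):
        out = classify_end("s", self._call(FIVE_PRIME, 6, 0), params)
        assert (out.kind, out.trim, out.pad) == ("overextended", 6, 0)

    def test_truncated_on_reference_overhang(self, params):
        out = classify_end("s", self._call(THREE_PRIME, 0, 25), params)
        assert (out.kind, out.trim, out.pad) == ("truncated", 0, 25)

    def test_thresholds_inclusive(self, params):
        # exactly at threshold: the shortest detectable error fires
        out = classify_end("s", self._call(FIVE_PRIME, 5, 0), params)
        assert out.kind == "overextended"
        out = classify_end("s", self._call(FIVE_PRIME, 4, 0), params)
        assert out.kind == "ok"

    def test_chimera_precedence_over_single_end_rules(self, params):
        out = classify_end("s", self._call(FIVE_PRIME, 10, 10), params)
        assert out.kind == "chimeric"


def _trim_call(i):
    return CorrectionCall(f"s{i}", FIVE_PRIME, "overextended", trim=4 + i % 2)


def _pad_call(i):
    return CorrectionCall(f"p{i}", FIVE_PRIME, "truncated", pad=6)


def _ok_call(i):
    return CorrectionCall(f"o{i}", FIVE_PRIME, "ok")


class TestBimodalGuard:
    def test_even_split_suppresses_trims(self, params):
        calls = [_trim_call(i) for i in range(5)] + [_pad_call(i) for i in range(5)]
        out = bimodal_guard(calls, params)
        assert sum(1 for c in out if c.trim > 0) == 0
        assert sum(1 for c in out if c.pad > 0) == 5
        assert all(c.kind == "ok" for c in out[:5])

    def test_unimodal_passes_through(self, params):
        calls = [_trim_call(0)] + [_ok_call(i) for i in range(9)]
        assert bimodal_guard(calls, params) == calls

    def test_exact_forty_percent_boundary_triggers(self, params):
        calls = ([_trim_call(i) for i in range(4)]
                 + [_pad_call(i) for i in range(4)]
                 + [_ok_call(i) for i in range(2)])
        out = bimodal_guard(calls, params)
        assert sum(1 for c in out if c.trim > 0) == 0
        assert sum(1 for c in out if c.pad > 0) == 4


class TestApplyCorrection:
    def test_trim5(self):
        seq = ProteinSequence("s", "AAAAMSTPK")
        out = apply_correction(
            seq,
            CorrectionCall("s", FIVE_PRIME, "overextended", trim=4),
            CorrectionCall("s", THREE_PRIME, "ok"))
        assert out.residues == "MSTPK"

    def test_pad5(self):
        seq = ProteinSequence("s", "MKL")
        out = apply_correction(
            seq,
            CorrectionCall("s", FIVE_PRIME, "truncated", pad=3),
            CorrectionCall("s", THREE_PRIME, "ok"))
        assert out.residues == "XXXMKL"

    def test_identity(self):
        seq = ProteinSequence("s", "MKL")
        out = apply_correction(
            seq, CorrectionCall("s", FIVE_PRIME, "ok"),
            CorrectionCall("s", THREE_PRIME, "ok"))
        assert out.residues == "MKL"

    def test_consuming_trims_rejected(self):
        seq = ProteinSequence("s", "MKL")
        with pytest.raises(ValueError, match="consume"):
            apply_correction(
                seq,
                CorrectionCall("s", FIVE_PRIME, "overextended", trim=2),
                CorrectionCall("s", THREE_PRIME, "overextended", trim=1))

    @given(core=st.text(alphabet=AMINO_ACIDS, min_size=1, max_size=40),
           trim5=st.integers(0, 5), trim3=st.integers(0, 5),
           pad5=st.integers(0, 5), pad3=st.integers(0, 5))
    def test_conservation(self, core, trim5, trim3, pad5, pad3):
        """Undoing trims and pads restores the original exactly: internal
        residues are never edited."""
        seq = ProteinSequence("s", "W" * trim5 + core + "W" * trim3)
        c5 = (CorrectionCall("s", FIVE_PRIME, "chimeric", trim=trim5, pad=pad5)
              if trim5 else
              CorrectionCall("s", FIVE_PRIME, "truncated", pad=pad5)
              if pad5 else CorrectionCall("s", FIVE_PRIME, "ok"))
        c3 = (CorrectionCall("s", THREE_PRIME, "chimeric", trim=trim3, pad=pad3)
              if trim3 else
              CorrectionCall("s", THREE_PRIME, "truncated", pad=pad3)
              if pad3 else CorrectionCall("s", THREE_PRIME, "ok"))
        out = apply_correction(seq, c5, c3)
        assert out.residues == "X" * pad5 + core + "X" * pad3
        undone = out.residues[pad5:len(out.residues) - pad3 or None]
        assert undone == core


class TestCorrectSet:
    def test_identical_sequences_untouched(self, params):
        members = [ProteinSequence(f"s{i}", "M" + "ACDEFGHIKL" * 6)
                   for i in range(10)]
        oset = OrthologSet("f", members)
        corrected, calls = correct_set(oset, params)
        assert all(a.residues == b.residues for a, b in zip(oset, corrected))
        assert {c.kind for c in calls} == {"ok"}

    def test_overextended_member_trimmed(self, params, small_family):
        junk = "WYWHKDWY"
        m0 = replace(small_family.members[0],
                     residues=junk + small_family.members[0].residues)
        oset = OrthologSet("f", (m0,) + small_family.members[1:])
        corrected, calls = correct_set(oset, params)
        c5 = next(c for c in calls if c.seq_id == m0.id and c.end == FIVE_PRIME)
        assert (c5.kind, c5.trim) == ("overextended", len(junk))
        assert corrected.members[0].residues == small_family.members[0].residues

    def test_too_few_members_uncorrectable(self, params):
        members = [ProteinSequence(f"s{i}", "M" + "ACDEFGHIKL" * 4)
                   for i in range(4)]
        _corr, calls = correct_set(OrthologSet("f", members), params)
        assert {c.kind for c in calls} == {"uncorrectable"}

    def test_matches_brute_force_oracle(self):
        """End-to-end classification equals an independent exhaustive
        reimplementation on a small family with injected errors."""
        rng = np.random.default_rng(23)
        fam = generate_family("f", 12, 60, 0.95, rng)
        donors = generate_donor_pool(4, 60, rng)
        params = CorrectionParams(trim3_min=10, chimera3_min=15)
        profile = SimulationProfile(
            rate_over5=0.3, rate_trunc5=0.3, rate_over3=0.2, rate_trunc3=0.2,
            rate_chim5=0.1, rate_chim3=0.0,
            min_len={("overextension", "5prime"): 5,
                     ("truncation", "5prime"): 5,
                     ("overextension", "3prime"): 10,
                     ("truncation", "3prime"): 10,
                     ("chimera", "5prime"): 10,
                     ("chimera", "3prime"): 15},
            poisson_lambda=2.0)
        [modified], _records = inject_errors([fam], profile, params, donors, rng)
        _corr, calls = correct_set(modified, params)
        got = {(c.seq_id, c.end): (c.kind, c.trim, c.pad) for c in calls}
        expected = classify_oracle(
            [(m.id, m.residues) for m in modified],
            d=params.min_identity, a=params.trim5_min, b=params.trim3_min,
            f=params.chimera5_min, g=params.chimera3_min,
            min_refs=params.min_refs)
        assert got == expected
        assert any(kind != "ok" for kind, _t, _p in got.values())

    def test_monotonicity_in_identity_threshold(self):
        """Raising d never enlarges the set of correctable queries."""
        rng = np.random.default_rng(31)
        fam = generate_family("f", 8, 80, 0.90, rng)
        eligible = {}
        for d in (0.70, 0.80, 0.90, 0.97):
            params = CorrectionParams(min_identity=d)
            _corr, calls = correct_set(fam, params)
            eligible[d] = {c.seq_id for c in calls if c.kind != "uncorrectable"}
        assert eligible[0.97] <= eligible[0.90] <= eligible[0.80] <= eligible[0.70]

    def test_idempotent_on_own_output(self, params, small_family):
        """Padded X ends count as aligned mismatches, so a corrected set
        proposes no further changes."""
        m0 = replace(small_family.members[0],
                     residues=small_family.members[0].residues[7:])
        m1 = replace(small_family.members[1],
                     residues="WHKDWYKW" + small_family.members[1].residues)
        oset = OrthologSet("f", (m0, m1) + small_family.members[2:])
        corrected, calls = correct_set(oset, params)
        kinds = {c.seq_id: c.kind for c in calls if c.end == FIVE_PRIME}
        assert kinds[m0.id] == "truncated"
        assert kinds[m1.id] == "overextended"
        again, calls2 = correct_set(corrected, params)
        assert all(a.residues == b.residues for a, b in zip(corrected, again))
        assert {c.kind for c in calls2} == {"ok"}


class TestCallInvariants:
    @pytest.mark.parametrize("kind,trim,pad", [
        ("overextended", 0, 0),
        ("truncated", 1, 1),
        ("ok", 1, 0),
        ("uncorrectable", 0, 2),
    ])
    def test_kind_amount_consistency_enforced(self, kind, trim, pad):
        with pytest.raises(ValueError):
            CorrectionCall("s", FIVE_PRIME, kind, trim=trim, pad=pad)
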