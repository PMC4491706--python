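"""Sample-specific reference construction: read grouping, consensus calls,
pairing and ISV window scanning."""

import numpy as np
import pytest

import singpcr as s
from singpcr import refbuild
from singpcr.models import COMPETITOR, TARGET
from singpcr.simulate import reverse_complement


def pad(seq, length=100, rng=None, prefix=0):
    rng = rng or np.random.default_rng(0)
    bases = "ACGT"
    left = "".join(bases[i] for i in rng.integers(0, 4, size=prefix))
    right = "".join(bases[i] for i in rng.integers(0, 4, size=length - prefix - len(seq)))
    return left + seq + right


class TestGroupPureReads:
    def test_padded_and_reverse_reads_grouped(self, small_panel):
        _, pairs = small_panel
        refs = {f"{p.amplicon_id}|target": p.target_seq for p in pairs}
        rng = np.random.default_rng(3)
        reads = []
        for p in pairs[:5]:
            reads.append(("r+", pad(p.target_seq, rng=rng)))
            reads.append(("r-", reverse_complement(pad(p.target_seq, rng=rng))))
        groups, stats = s.group_pure_reads(reads, refs)
        assert stats["assigned"] == len(reads)
        for p in pairs[:5]:
            assert len(groups[p.amplicon_id]) == 2
            assert all(seg == p.target_seq for off, seg in groups[p.amplicon_id])

    def test_short_read_unassigned(self, small_panel):
        _, pairs = small_panel
        p = pairs[0]
        refs = {p.amplicon_id: p.target_seq}
        fragment = p.target_seq[:30]  # below min(75 bp, 90% of reference)
        groups, stats = s.group_pure_reads([("r", fragment)], refs)
        assert stats["unassigned"] == 1 and not groups

    def test_read_matching_two_amplicons_discarded(self, small_panel):
        _, pairs = small_panel
        seq = pairs[0].target_seq
        refs = {"ampA": seq, "ampB": seq}  # duplicated amplicon content
        groups, stats = s.group_pure_reads([("r", pad(seq))], refs)
        assert stats["ambiguous"] == 1 and not groups

    def test_empty_input_warns_and_returns_empty(self, small_panel, caplog):
        _, pairs = small_panel
        refs = {pairs[0].amplicon_id: pairs[0].target_seq}
        with caplog.at_level("WARNING"):
            groups, stats = s.group_pure_reads([], refs)
        assert groups == {} and stats["total"] == 0
        assert any("no reads" in r.message for r in caplog.records)

    def test_mismatched_read_still_grouped_below_divergence_cap(self, small_panel):
        _, pairs = small_panel
        p = pairs[0]
        mutated = list(p.target_seq)
        mutated[len(mutated) // 2] = "A" if mutated[len(mutated) // 2] != "A" else "C"
        groups, stats = s.group_pure_reads(
            [("r", pad("".join(mutated)))], {p.amplicon_id: p.target_seq}
        )
        assert stats["assigned"] == 1


class TestBuildConsensus:
    def test_unanimous_pileup_retained(self):
        call = s.build_consensus(["ACGTACGT"] * 100, "a", TARGET, min_depth=100)
        assert call.retained and call.monomorphic
        assert call.sequence == "ACGTACGT"

    def test_depth_threshold_inclusive_at_100(self):
        ok = s.build_consensus(["ACGT"] * 100, min_depth=100)
        low = s.build_consensus(["ACGT"] * 99, min_depth=100)
        assert ok.retained
        assert not low.retained and low.reason == "low_depth"

    def test_heterozygous_position_rejected(self):
        # 60/40 split: both bases reach the 25% retention rule
        pileup = ["ACGT"] * 60 + ["AGGT"] * 40
        call = s.build_consensus(pileup, min_depth=50)
        assert not call.retained and call.reason == "heterozygous"
        # a 80/20 minority below 25% is treated as sequencing noise
        pileup = ["ACGT"] * 80 + ["AGGT"] * 20
        call = s.build_consensus(pileup, min_depth=50)
        assert call.retained and call.sequence == "ACGT"

    def test_zero_reads_rejected_with_reason(self):
        call = s.build_consensus([], "a", TARGET)
        assert not call.retained and call.reason == "no_reads"

    @pytest.mark.parametrize("extra", [1, 50, 500])
    def test_retention_monotone_in_depth(self, extra):
        base = ["TTAACC"] * 100
        assert s.build_consensus(base).retained
        assert s.build_consensus(base + ["TTAACC"] * extra).retained

    def test_offset_pileup_positions_counted_per_coverage(self):
        pileup = [(0, "ACGTACGT")] * 100 + [(4, "ACGT")] * 30
        call = s.build_consensus(pileup, ref_length=8, min_depth=100)
        assert call.retained and call.sequence == "ACGTACGT"


class TestPairReferences:
    def _call(self, amp, species, seq, retained=True):
        return s.ConsensusCall(amp, species, seq, 200, retained, retained,
                               None if retained else "low_depth")

    def test_differing_pair_yields_isv(self):
        t = {"a": self._call("a", TARGET, "ACGTACGT")}
        c = {"a": self._call("a", COMPETITOR, "ACGTTCGT")}
        pairs, dropped = s.pair_references(t, c)
        assert len(pairs) == 1 and pairs[0].isv_positions == (4,)
        assert not dropped

    def test_identical_pair_dropped_isv_deficient(self):
        t = {"a": self._call("a", TARGET, "ACGTACGT")}
        c = {"a": self._call("a", COMPETITOR, "ACGTACGT")}
        pairs, dropped = s.pair_references(t, c)
        assert not pairs and dropped[0]["reason"] == "isv_deficient"

    def test_missing_or_unretained_species_dropped(self):
        t = {"a": self._call("a", TARGET, "ACGTACGT"),
             "b": self._call("b", TARGET, "ACGTACGT", retained=False)}
        c = {"b": self._call("b", COMPETITOR, "ACGTTCGT")}
        pairs, dropped = s.pair_references(t, c)
        reasons = {d["amplicon_id"]: d["reason"] for d in dropped}
        assert not pairs
        assert reasons == {"a": "not_amplified", "b": "not_amplified"}

    def test_length_mismatch_dropped(self):
        t = {"a": self._call("a", TARGET, "ACGTACGT")}
        c = {"a": self._call("a", COMPETITOR, "ACGTACG")}
        pairs, dropped = s.pair_references(t, c)
        assert not pairs and dropped[0]["reason"] == "length_mismatch"


class TestRoundTripRecovery:
    def test_consensus_recovers_simulated_references_exactly(self, emitted_sample):
        """Error-free pure-sample reads at depth >= 100 reconstruct every
        simulated pair, including the exact ISV positions."""
        pairs, counts, truth, files = emitted_sample
        init = {f"{p.amplicon_id}|target": p.target_seq for p in pairs}
        init |= {f"{p.amplicon_id}|competitor": p.competitor_seq for p in pairs}
        built, rejects = s.build_reference_library(
            files["G10"], files["G0"], init, min_depth=100
        )
        by_id = {p.amplicon_id: p for p in built}
        assert len(built) == len(pairs)
        for p in pairs:
            b = by_id[p.amplicon_id]
            assert b.target_seq == p.target_seq
            assert b.competitor_seq == p.competitor_seq
            assert b.isv_positions == p.isv_positions


def brute_force_windows(t, c, lo, hi, flank, max_mm):
    """Independent enumeration of valid ISV windows for the oracle check."""
    out = set()
    for start in range(len(t)):
        for end in range(start + lo, min(start + hi, len(t)) + 1):
            if end > len(t):
                continue
            cols = list(zip(t[start:end], c[start:end]))
            fl = cols[:flank] + cols[end - start - flank:]
            mm = sum(a != b or a == "-" or b == "-" for a, b in fl)
            interior = cols[flank: end - start - flank]
            if mm > max_mm:
                continue
            if any(a == "-" or b == "-" for a, b in interior):
                continue
            isv = [i for i, (a, b) in enumerate(interior) if a != b]
            if isv:
                out.add((start, end))
    return out


class TestFindIsvWindows:
    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(17)
        bases = "ACGT"
        t = "".join(bases[i] for i in rng.integers(0, 4, size=220))
        c = list(t)
        for pos in (40, 90, 91, 150):
            c[pos] = bases[(bases.index(c[pos]) + 1) % 4]
        c = "".join(c)
        got = s.find_isv_windows(t, c, window_len_range=(30, 50), flank_len=10)
        expected = brute_force_windows(t, c, 30, 50, 10, 0)
        assert {(w.start, w.end) for w in got} == expected

    def test_fewest_interior_isvs_ranked_first(self):
        t = "A" * 200
        c = list(t)
        c[50] = "C"           # lone ISV
        c[120] = c[122] = c[124] = "G"  # 3-ISV cluster
        got = s.find_isv_windows("".join(t), "".join(c), window_len_range=(41, 41), flank_len=10)
        assert got[0].n_isv == 1
        assert 50 in got[0].isv_positions

    def test_no_isv_returns_empty(self):
        t = "ACGT" * 30
        assert s.find_isv_windows(t, t) == []

    def test_gap_in_interior_disqualifies_window(self):
        t = "A" * 100
        c = "A" * 50 + "-" + "A" * 49
        assert s.find_isv_windows(t, c, window_len_range=(41, 41), flank_len=10) == []
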