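import numpy as np
import pytest

from beprofiler.edit_caller import (
    MemberReadGroup,
    aggregate_replicates,
    call_edits,
    classify_read,
    demultiplex,
    quantify,
)
from beprofiler.errors import ConfigurationError, DataError
from beprofiler.library_design import (
    ContextLibrarySpec,
    enumerate_context_library,
    protospacer_offset,
    umi_offset,
)
from beprofiler.synthetic_reads import ReadSimConfig, SimulatedRead, simulate_reads
from .conftest import hamming


@pytest.fixture(scope="module")
def lib4():
    spec = ContextLibrarySpec(target_bases=("C",), positions=(6,), flank_alphabet="AT")
    return enumerate_context_library(spec, seed=5)


def perfect_read(member, rid="r0", quality=30):
    return SimulatedRead(rid, member.amplicon, chr(quality + 33) * len(member.amplicon))


def mutate(read, pos0, base):
    seq = read.sequence[:pos0] + base + read.sequence[pos0 + 1:]
    return SimulatedRead(read.read_id, seq, read.quality)


def edit_distance(a, b):
    # Needleman-Wunsch unit-cost DP oracle
    dp = np.arange(len(b) + 1)
    for i, ca in enumerate(a, 1):
        prev, dp[0] = dp[0], i
        for j, cb in enumerate(b, 1):
            prev, dp[j] = dp[j], min(dp[j] + 1, dp[j - 1] + 1, prev + (ca != cb))
    return int(dp[-1])


class TestDemultiplex:
    def test_clean_reads_all_assigned(self, lib4):
        sim = simulate_reads(lib4, ReadSimConfig(p_target=0.5, depth=50, seed=1))
        groups, unassigned = demultiplex(sim.reads[0], lib4, max_umi_mismatch=0)
        assert unassigned == 0
        for m in lib4:
            assert groups[m.member_id].n_total == 50

    def test_one_mismatch_unassigned_at_zero_tolerance(self, lib4):
        m = lib4.members[0]
        read = mutate(perfect_read(m), umi_offset(lib4.spec), _other(m.umi[0]))
        groups, unassigned = demultiplex([read], lib4, max_umi_mismatch=0)
        assert unassigned == 1

    def test_one_mismatch_assigned_at_tolerance_one(self, lib4):
        m = lib4.members[0]
        read = mutate(perfect_read(m), umi_offset(lib4.spec), _other(m.umi[0]))
        groups, unassigned = demultiplex([read], lib4, max_umi_mismatch=1)
        assert unassigned == 0
        assert groups[m.member_id].n_total == 1
        # brute-force nearest-neighbor oracle agrees
        u = read.sequence[umi_offset(lib4.spec):umi_offset(lib4.spec) + 10]
        dists = {mm.member_id: hamming(u, mm.umi) for mm in lib4}
        assert min(dists, key=dists.get) == m.member_id

    def test_distance_precondition_enforced(self, lib4):
        import dataclasses

        # craft UMIs at Hamming distance 1: tolerance 1 needs distance > 2
        m0 = dataclasses.replace(lib4.members[0], umi="AAAAAAAAAA")
        m1 = dataclasses.replace(lib4.members[1], umi="AAAAAAAAAC")
        from beprofiler.library_design import LibraryTable

        close = LibraryTable(members=[m0, m1], spec=lib4.spec)
        with pytest.raises(ConfigurationError):
            demultiplex([], close, max_umi_mismatch=1)

    def test_totals_conserved_with_errors(self, lib4):
        sim = simulate_reads(lib4, ReadSimConfig(p_target=0.5, error_rate=0.02,
                                                 depth=200, seed=3))
        groups, unassigned = demultiplex(sim.reads[0], lib4, max_umi_mismatch=1)
        assert sum(g.n_total for g in groups.values()) + unassigned == len(sim.reads[0])

    def test_equivalence_with_brute_force(self, lib448):
        sim = simulate_reads(lib448, ReadSimConfig(p_target=0.5, error_rate=0.05,
                                                   depth=2, seed=8))
        reads = sim.reads[0][:1000]
        groups, _ = demultiplex(reads, lib448, max_umi_mismatch=1)
        assignment = {}
        for mid, g in groups.items():
            for i in g.reads:
                assignment[i] = mid
        start = umi_offset(lib448.spec)
        for i, r in enumerate(reads):
            u = r.sequence[start:start + 10]
            dists = sorted((hamming(u, m.umi), m.member_id) for m in lib448)
            expected = dists[0][1] if dists[0][0] <= 1 else None
            assert assignment.get(i) == expected


def _other(base):
    return "A" if base != "A" else "C"


class TestClassify:
    def test_identical_read_zero_calls(self, lib4):
        m = lib4.members[0]
        cls = classify_read(perfect_read(m), m)
        assert cls.calls == [] and not cls.indel and not cls.lowq

    def test_single_target_conversion_called(self, lib4):
        m = lib4.members[0]
        col = protospacer_offset() + m.target_position - 1
        cls = classify_read(mutate(perfect_read(m), col, "T"), m)
        assert cls.calls == [(m.target_position, "C", "T")]

    def test_deletion_flagged_indel(self, lib4):
        m = lib4.members[0]
        seq = m.amplicon[:20] + m.amplicon[21:]
        read = SimulatedRead("r", seq, "?" * len(seq))
        cls = classify_read(read, m)
        assert cls.indel
        # edit-distance oracle: the read needs a gap to align
        assert edit_distance(seq, m.amplicon) == 1
        assert hamming(seq + "N", m.amplicon) > 1

    def test_low_quality_read_flagged(self, lib4):
        m = lib4.members[0]
        read = SimulatedRead("r", m.amplicon, chr(5 + 33) * len(m.amplicon))
        cls = classify_read(read, m)
        assert cls.lowq

    def test_per_base_quality_masking(self, lib4):
        m = lib4.members[0]
        col = protospacer_offset() + m.target_position - 1
        qual = list(chr(30 + 33) * len(m.amplicon))
        qual[col] = chr(5 + 33)
        read = SimulatedRead("r", m.amplicon, "".join(qual))
        cls = classify_read(read, m, qmin=20)
        assert m.target_position in cls.masked_positions

    def test_empty_read_rejected(self, lib4):
        with pytest.raises(DataError):
            classify_read(SimulatedRead("r", "", ""), lib4.members[0])


class TestQuantify:
    def _run(self, member, reads, **kw):
        group = MemberReadGroup(member.member_id, reads=list(range(len(reads))))
        return quantify(group, member, reads, **kw)

    def test_three_of_four_reads_gives_75pct(self, lib4):
        m = lib4.members[0]
        col = protospacer_offset() + m.target_position - 1
        reads = [mutate(perfect_read(m, f"r{i}"), col, "T") for i in range(3)]
        reads.append(perfect_read(m, "r3"))
        df = self._run(m, reads, min_reads=1)
        row = df[(df["position"] == m.target_position) & (df["conversion"] == "C2T")]
        assert row["efficiency_pct"].iloc[0] == 75.0
        assert row["edited"].iloc[0] == 3 and row["aligned"].iloc[0] == 4

    def test_independent_conversions(self, lib4):
        m = lib4.members[0]
        off = protospacer_offset()
        reads = [perfect_read(m, f"r{i}") for i in range(10)]
        for i in range(2):
            reads[i] = mutate(reads[i], off + 5, "T")  # C→T at position 6
        ref4 = m.amplicon[off + 3]
        reads[5] = mutate(reads[5], off + 3, "A" if ref4 != "A" else "G")
        df = self._run(m, reads, min_reads=1)
        at6 = df[(df["position"] == 6) & (df["conversion"] == "C2T")]
        assert at6["efficiency_pct"].iloc[0] == 20.0
        conv4 = f"{ref4}2" + ("A" if ref4 != "A" else "G")
        at4 = df[(df["position"] == 4) & (df["conversion"] == conv4)]
        assert at4["efficiency_pct"].iloc[0] == 10.0

    def test_zero_reads_flags_low_coverage(self, lib4):
        m = lib4.members[0]
        df = self._run(m, [])
        assert df["flags"].str.contains("low_coverage").all()
        assert df["efficiency_pct"].isna().all()

    def test_indel_reads_excluded_from_denominator(self, lib4):
        m = lib4.members[0]
        good = [perfect_read(m, f"g{i}") for i in range(4)]
        dele = SimulatedRead("d", m.amplicon[1:], "?" * (len(m.amplicon) - 1))
        df = self._run(m, good + [dele], min_reads=1)
        assert (df["aligned"] == 4).all()
        assert df["indel_fraction"].iloc[0] == pytest.approx(0.2)

    def test_raising_qmin_never_grows_denominator(self, lib4):
        m = lib4.members[0]
        rng = np.random.default_rng(0)
        reads = []
        for i in range(30):
            quals = rng.integers(10, 40, size=len(m.amplicon))
            reads.append(SimulatedRead(f"r{i}", m.amplicon,
                                       "".join(chr(q + 33) for q in quals)))
        lo = self._run(m, reads, qmin=15, min_reads=1)
        hi = self._run(m, reads, qmin=30, min_reads=1)
        assert (hi["aligned"].to_numpy() <= lo["aligned"].to_numpy()).all()


class TestRoundTrip:
    def test_exact_recovery_with_no_error(self, lib4):
        sim = simulate_reads(lib4, ReadSimConfig(p_target=0.37, depth=400, seed=6))
        edits, summary = call_edits(sim.reads[0], lib4, min_reads=10)
        off = protospacer_offset()
        for m in lib4:
            col = off + m.target_position - 1
            expected = sum(
                r.sequence[col] == "T"
                for r in sim.reads[0] if r.read_id.startswith(m.member_id + "|")
            ) / 400
            got = edits[(edits["member_id"] == m.member_id)
                        & (edits["position"] == m.target_position)
                        & (edits["conversion"] == "C2T")]["efficiency_pct"].iloc[0]
            assert got == pytest.approx(100 * expected, abs=1e-9)

    def test_accounting_conserved(self, lib4):
        sim = simulate_reads(lib4, ReadSimConfig(p_target=0.5, error_rate=0.01,
                                                 indel_rate=0.05, depth=300, seed=2))
        edits, summary = call_edits(sim.reads[0], lib4, min_reads=10)
        assert summary["assigned"] + summary["unassigned"] == summary["n_reads"]
        for acc in summary["per_member"].values():
            assert acc["used"] + acc["indel"] + acc["lowq"] == acc["total"]


class TestAggregate:
    def _frame(self, eff, flags=""):
        import pandas as pd

        return pd.DataFrame([
            {"member_id": "m", "position": 6, "ref": "C", "alt": "T",
             "conversion": "C2T", "edited": 0, "aligned": 100,
             "efficiency_pct": eff, "flags": flags, "indel_fraction": 0.0}
        ])

    def test_mean_of_three_replicates(self):
        agg = aggregate_replicates([self._frame(70.0), self._frame(80.0), self._frame(90.0)])
        assert agg["efficiency_pct"].iloc[0] == 80.0
        assert agg["n_replicates"].iloc[0] == 3

    def test_single_replicate_passthrough(self):
        agg = aggregate_replicates([self._frame(55.5)])
        assert agg["efficiency_pct"].iloc[0] == 55.5

    def test_low_coverage_replicate_dropped(self):
        agg = aggregate_replicates(
            [self._frame(70.0), self._frame(80.0), self._frame(5.0, flags="low_coverage")])
        assert agg["efficiency_pct"].iloc[0] == 75.0
        assert "replicates_dropped" in agg["flags"].iloc[0]

    def test_all_invalid_raises(self):
        with pytest.raises(DataError):
            aggregate_replicates([self._frame(5.0, flags="low_coverage")])
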