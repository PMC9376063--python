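import copy

import pytest

from mutevol.filtering import (
    FilterConfig,
    consensus_filter,
    filter_pipeline,
    quality_filter,
    subtract_ancestral,
    sv_dedup,
    sv_parallel_filter,
)
from mutevol.io import MutationCall


def snm(line, pos, depth=150, qual=60.0, alt="T", info=None):
    return MutationCall(
        line, "chr1", pos, "C", alt, "SNM", depth, qual,
        info=info or {},
    )


def simc(line, pos):
    return MutationCall(line, "chr1", pos, "CA", "C", "SIM", 150, 60.0)


def sv(line, start, end, sv_type="DEL", source="lumpy"):
    return MutationCall(
        line, "chr1", start, "N", f"<{sv_type}>", "SV", 150, 60.0,
        sv_type=sv_type, sv_start=start, sv_end=end, source=source,
    )


class TestQualityFilter:
    def test_low_depth_removed(self):
        kept, removed = quality_filter([snm("L1", 10, depth=3, qual=30)])
        assert not kept
        assert removed[0].reason == "low-depth"

    def test_boundary_inclusive(self):
        kept, removed = quality_filter([snm("L1", 10, depth=4, qual=10.0)])
        assert len(kept) == 1

    def test_low_qual_removed(self):
        _, removed = quality_filter([snm("L1", 10, depth=9, qual=9.9)])
        assert removed[0].reason == "low-qual"

    def test_missing_evidence(self):
        call = MutationCall("L1", "chr1", 5, "C", "T", "SNM")
        _, removed = quality_filter([call])
        assert removed[0].reason == "missing-evidence"

    def test_empty_input(self):
        assert quality_filter([]) == ([], [])

    def test_partition_exhaustive(self):
        calls = [snm("L1", p, depth=d) for p, d in [(1, 3), (2, 4), (3, 200)]]
        kept, removed = quality_filter(calls)
        assert len(kept) + len(removed) == len(calls)


class TestSubtractAncestral:
    def test_matching_key_removed(self):
        anc = [snm("P0", 10)]
        assert subtract_ancestral([snm("L1", 10)], anc) == []

    def test_different_alt_kept(self):
        anc = [snm("P0", 10, alt="G")]
        assert len(subtract_ancestral([snm("L1", 10, alt="T")], anc)) == 1

    def test_empty_ancestral(self):
        calls = [snm("L1", 10)]
        assert subtract_ancestral(calls, []) == calls

    def test_removed_across_all_lines(self):
        calls = [snm("L1", 10), snm("L2", 10), snm("L3", 99)]
        kept = subtract_ancestral(calls, [snm("P0", 10)])
        assert [c.pos for c in kept] == [99]


class TestConsensusFilter:
    def test_snm_in_three_lines_removed(self):
        calls = [snm(f"L{i}", 10) for i in range(3)]
        kept, removed = consensus_filter(calls)
        assert not kept
        assert len(removed) == 3

    def test_snm_in_two_lines_kept(self):
        calls = [snm("L1", 10), snm("L2", 10)]
        kept, _ = consensus_filter(calls)
        assert len(kept) == 2

    def test_sim_boundary_four_kept_five_removed(self):
        four = [simc(f"L{i}", 20) for i in range(4)]
        kept, _ = consensus_filter(four)
        assert len(kept) == 4
        five = [simc(f"L{i}", 20) for i in range(5)]
        kept, removed = consensus_filter(five)
        assert not kept
        assert all(r.reason == "consensus" for r in removed)

    def test_same_line_repeats_do_not_count(self):
        # the limit counts distinct lines, not occurrences
        calls = [snm("L1", 10), snm("L1", 10), snm("L1", 10)]
        kept, _ = consensus_filter(calls)
        assert len(kept) == 3


class TestSvDedup:
    def test_window_match_dropped(self):
        first = sv("L1", 1000, 2000, source="lumpy")
        second = sv("L1", 1400, 2300, source="cnvnator")
        kept = sv_dedup({"lumpy": [first], "cnvnator": [second]})
        assert kept == [first]

    def test_beyond_window_both_kept(self):
        first = sv("L1", 1000, 2000, source="lumpy")
        second = sv("L1", 1601, 2601, source="cnvnator")
        kept = sv_dedup({"lumpy": [first], "cnvnator": [second]})
        assert len(kept) == 2

    def test_different_type_both_kept(self):
        first = sv("L1", 1000, 2000, "DEL", source="lumpy")
        second = sv("L1", 1000, 2000, "DUP", source="cnvnator")
        assert len(sv_dedup({"lumpy": [first], "cnvnator": [second]})) == 2

    def test_unknown_source_rejected(self):
        with pytest.raises(ValueError):
            sv_dedup({"mystery": [sv("L1", 1, 2, source="mystery")]})

    def test_precedence_order(self):
        lumpy = sv("L1", 1000, 2000, source="lumpy")
        breakd = sv("L1", 1100, 2100, source="breakdancer")
        kept = sv_dedup({"breakdancer": [breakd], "lumpy": [lumpy]})
        assert kept == [lumpy]


class TestSvParallelFilter:
    def test_ancestral_match_removed(self):
        anc = sv("P0", 1000, 2000)
        call = sv("L1", 1300, 2400)
        assert sv_parallel_filter([call], [anc]) == []

    def test_three_parallel_lines_removed(self):
        calls = [sv(f"L{i}", 1000 + 10 * i, 2000 + 10 * i) for i in range(3)]
        assert sv_parallel_filter(calls, []) == []

    def test_two_parallel_lines_kept(self):
        calls = [sv("L1", 1000, 2000), sv("L2", 1010, 2010)]
        assert len(sv_parallel_filter(calls, [])) == 2

    def test_single_linkage_chains(self):
        # a-b and b-c match pairwise; a-c does not: one class of 3 lines
        a = sv("L1", 1000, 2000)
        b = sv("L2", 1400, 2400)
        c = sv("L3", 1800, 2800)
        assert sv_parallel_filter([a, b, c], []) == []


class TestPipeline:
    def test_idempotent(self, ma_fixture):
        _, _, calls, _ = ma_fixture
        kept1, _ = filter_pipeline(calls)
        kept2, removed2 = filter_pipeline(kept1)
        assert kept2 == kept1
        assert removed2 == []

    def test_calls_never_modified(self, ma_fixture):
        _, _, calls, _ = ma_fixture
        before = copy.deepcopy(calls)
        filter_pipeline(calls)
        assert calls == before

    def test_all_artifacts_removed_no_clean_losses(self, ma_fixture):
        _, plan, calls, _ = ma_fixture
        n_artifacts = sum(1 for c in calls if c.info.get("ARTIFACT"))
        assert n_artifacts == plan.n_shared_snm * plan.shared_in_lines + \
            plan.n_lowdepth
        kept, removed = filter_pipeline(calls)
        assert not any(c.info.get("ARTIFACT") for c in kept)
        assert sum(1 for r in removed if r.call.info.get("ARTIFACT")) == \
            n_artifacts
        clean_small_removed = [
            r for r in removed
            if r.call.mclass in ("SNM", "SIM")
            and not r.call.info.get("ARTIFACT")
        ]
        assert clean_small_removed == []


class TestFilterConfig:
    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            FilterConfig(min_depth=-1)
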