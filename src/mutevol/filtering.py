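"""Post-calling filters for MA-line variant tables.

SNM/SIM calls pass through quality filtering (depth/phred thresholds),
ancestral subtraction, and a cross-line consensus filter that removes calls
shared by suspiciously many lines of the same progenitor.  SV calls from
multiple callers are deduplicated by source precedence with a windowed
both-ends match, then screened against ancestral SVs and parallel-line
recurrence.

Filters never modify a call; they only partition the input.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .io import MutationCall, log_stage


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for all filter stages.

    Consensus limits are strict: an SNM key is removed when present in MORE
    than ``snm_consensus_limit`` lines (i.e. at >= limit+1 lines), likewise
    for SIMs.  SVs recurring in at least ``sv_parallel_limit`` lines are
    removed.
    """

    min_depth: int = 4
    min_qual: float = 10.0
    snm_consensus_limit: int = 2
    sim_consensus_limit: int = 4
    sv_parallel_limit: int = 3
    sv_window: int = 500
    max_sim_len: int = 4

    def __post_init__(self):
        for name in (
            "min_depth",
            "min_qual",
            "snm_consensus_limit",
            "sim_consensus_limit",
            "sv_parallel_limit",
            "sv_window",
            "max_sim_len",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class RemovedCall:
    """A filtered-out call together with the rule that removed it."""

    call: MutationCall
    reason: str


def quality_filter(
    calls: Iterable[MutationCall], config: FilterConfig = FilterConfig()
) -> tuple[list[MutationCall], list[RemovedCall]]:
    """Discard calls with depth < min_depth or qual < min_qual.

    Both boundaries are inclusive on the keep side (the discard rule uses
    strict inequalities).  Calls missing depth or qual are removed with
    reason "missing-evidence".
    """
    kept: list[MutationCall] = []
    removed: list[RemovedCall] = []
    calls = list(calls)
    for call in calls:
        if call.depth is None or call.qual is None:
            removed.append(RemovedCall(call, "missing-evidence"))
        elif call.depth < config.min_depth:
            removed.append(RemovedCall(call, "low-depth"))
        elif call.qual < config.min_qual:
            removed.append(RemovedCall(call, "low-qual"))
        else:
            kept.append(call)
    log_stage("quality_filter", len(calls), len(kept))
    return kept, removed


def subtract_ancestral(
    calls: Iterable[MutationCall], ancestral_calls: Iterable[MutationCall]
) -> list[MutationCall]:
    """Remove calls whose (chrom, pos, ref, alt) key is ancestral."""
    ancestral_keys = {c.key for c in ancestral_calls}
    calls = list(calls)
    kept = [c for c in calls if c.key not in ancestral_keys]
    log_stage("subtract_ancestral", len(calls), len(kept))
    return kept


def consensus_filter(
    calls: Iterable[MutationCall], config: FilterConfig = FilterConfig()
) -> tuple[list[MutationCall], list[RemovedCall]]:
    """Remove SNM/SIM keys recurring across too many lines of one progenitor.

    A key present in more than ``snm_consensus_limit`` (SNM) or
    ``sim_consensus_limit`` (SIM) distinct lines is removed from every line:
    such sharing indicates an ancestral variant or systematic artifact
    rather than independent mutations.
    """
    calls = list(calls)
    lines_by_key: dict[tuple, set[str]] = defaultdict(set)
    for call in calls:
        if call.mclass in ("SNM", "SIM"):
            lines_by_key[call.key].add(call.line_id)
    kept: list[MutationCall] = []
    removed: list[RemovedCall] = []
    for call in calls:
        if call.mclass == "SNM":
            limit = config.snm_consensus_limit
        elif call.mclass == "SIM":
            limit = config.sim_consensus_limit
        else:
            kept.append(call)
            continue
        if len(lines_by_key[call.key]) > limit:
            removed.append(RemovedCall(call, "consensus"))
        else:
            kept.append(call)
    log_stage("consensus_filter", len(calls), len(kept))
    return kept, removed


def _intervals_match(
    a: MutationCall, b: MutationCall, window: int, match_type: bool = True
) -> bool:
    """True when both interval ends lie within ``window`` bases of each other."""
    if match_type and a.sv_type != b.sv_type:
        return False
    a1, a2 = a.interval
    b1, b2 = b.interval
    return abs(a1 - b1) <= window and abs(a2 - b2) <= window


def sv_dedup(
    sv_calls_by_source: Mapping[str, Sequence[MutationCall]],
    precedence: Sequence[str] = ("lumpy", "cnvnator", "breakdancer"),
    window: int = 500,
    match_type: bool = True,
) -> list[MutationCall]:
    """Merge SV predictions from multiple callers by precedence.

    Sources are visited in precedence order; a prediction from a later
    source is redundant (dropped) iff a retained same-type prediction from
    an earlier source has both interval ends within ``window`` bases.
    """
    unknown = set(sv_calls_by_source) - set(precedence)
    if unknown:
        raise ValueError(f"unknown source tag(s): {sorted(unknown)}")
    retained: list[MutationCall] = []
    n_in = sum(len(v) for v in sv_calls_by_source.values())
    for source in precedence:
        for call in sv_calls_by_source.get(source, []):
            if any(
                _intervals_match(call, prior, window, match_type)
                for prior in retained
            ):
                continue
            retained.append(call)
    log_stage("sv_dedup", n_in, len(retained))
    return retained


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        self.parent[self.find(i)] = self.find(j)


def sv_parallel_filter(
    sv_calls: Sequence[MutationCall],
    ancestral_svs: Sequence[MutationCall],
    config: FilterConfig = FilterConfig(),
) -> list[MutationCall]:
    """Drop SVs that are ancestral or recur across parallel MA lines.

    Match classes are single-linkage components of the pairwise
    both-ends-within-window, same-type relation.  A whole class is removed
    when any member matches an ancestral SV or the class spans at least
    ``sv_parallel_limit`` distinct lines.
    """
    sv_calls = list(sv_calls)
    n = len(sv_calls)
    uf = _UnionFind(n)
    for i in range(n):
        for j in range(i + 1, n):
            if _intervals_match(sv_calls[i], sv_calls[j], config.sv_window):
                uf.union(i, j)
    members: dict[int, list[int]] = defaultdict(list)
    for i in range(n):
        members[uf.find(i)].append(i)

    kept_idx: list[int] = []
    for idx in members.values():
        lines = {sv_calls[i].line_id for i in idx}
        ancestral = any(
            _intervals_match(sv_calls[i], anc, config.sv_window)
            for i in idx
            for anc in ancestral_svs
        )
        if ancestral or len(lines) >= config.sv_parallel_limit:
            continue
        kept_idx.extend(idx)
    kept = [sv_calls[i] for i in sorted(kept_idx)]
    log_stage("sv_parallel_filter", n, len(kept))
    return kept


def filter_pipeline(
    calls: Iterable[MutationCall],
    ancestral_calls: Iterable[MutationCall] = (),
    config: FilterConfig = FilterConfig(),
    sv_precedence: Sequence[str] = ("lumpy", "cnvnator", "breakdancer"),
) -> tuple[list[MutationCall], list[RemovedCall]]:
    """Run the full filter cascade and report removals with reasons.

    SNM/SIM route: quality -> ancestral subtraction -> consensus.
    SV route: per-source dedup -> ancestral/parallel screen.
    Re-running the pipeline on its own output changes nothing.
    """
    calls = list(calls)
    ancestral_calls = list(ancestral_calls)
    small = [c for c in calls if c.mclass in ("SNM", "SIM")]
    svs = [c for c in calls if c.mclass == "SV"]

    removed: list[RemovedCall] = []
    kept_small, rm = quality_filter(small, config)
    removed.extend(rm)

    anc_keys = {c.key for c in ancestral_calls if c.mclass in ("SNM", "SIM")}
    survivors = []
    for call in kept_small:
        if call.key in anc_keys:
            removed.append(RemovedCall(call, "ancestral"))
        else:
            survivors.append(call)
    kept_small, rm = consensus_filter(survivors, config)
    removed.extend(rm)

    by_source: dict[str, list[MutationCall]] = defaultdict(list)
    for call in svs:
        by_source[call.source or sv_precedence[0]].append(call)
    deduped = sv_dedup(by_source, sv_precedence, config.sv_window)
    deduped_ids = {id(c) for c in deduped}
    for call in svs:
        if id(call) not in deduped_ids:
            removed.append(RemovedCall(call, "sv-redundant"))
    ancestral_svs = [c for c in ancestral_calls if c.mclass == "SV"]
    kept_sv = sv_parallel_filter(deduped, ancestral_svs, config)
    kept_sv_ids = {id(c) for c in kept_sv}
    for call in deduped:
        if id(call) not in kept_sv_ids:
            removed.append(RemovedCall(call, "sv-ancestral-or-parallel"))

    return kept_small + kept_sv, removed
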