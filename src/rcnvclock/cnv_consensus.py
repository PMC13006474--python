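"""Dual-caller consensus CNV calls and cohort summaries.

A CNV is retained only when both callers report it for the same sample,
same state, with reciprocal overlap of the inferred breakpoints >= 50%,
and the consensus segment spans >= 10 probes and >= 10 kb — the standard
dual-algorithm filter against platform and batch artifacts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .io_formats import CNVCall, CallSet, state_from_copy_number

logger = logging.getLogger("rcnvclock")

__all__ = [
    "ConsensusParams",
    "CohortSummary",
    "reciprocal_overlap",
    "merge_consensus",
    "summarize_calls",
]


@dataclass(frozen=True)
class ConsensusParams:
    min_reciprocal_overlap: float = 0.5
    min_probes: int = 10
    min_size: int = 10_000
    #: consensus segment rule: intersection of the matched pair (default,
    #: conservative), their union, or caller A's endpoints
    endpoint_rule: str = "intersection"

    def __post_init__(self) -> None:
        if not 0 < self.min_reciprocal_overlap <= 1:
            raise ValueError("min_reciprocal_overlap must be in (0, 1]")
        if self.min_probes < 1 or self.min_size < 1:
            raise ValueError("min_probes and min_size must be >= 1")
        if self.endpoint_rule not in ("intersection", "union", "caller_a"):
            raise ValueError(f"unknown endpoint rule {self.endpoint_rule!r}")


@dataclass
class CohortSummary:
    """Cohort-level CNV profile in the shape such studies tabulate."""

    n_events: int
    mean_per_person: float | None
    n_del: int
    n_dup: int
    pct_del: int | None
    pct_dup: int | None
    mean_size_kb: float | None

    @classmethod
    def from_counts(
        cls,
        n_events: int,
        n_del: int,
        n_individuals: int,
        mean_size_kb: float | None = None,
    ) -> "CohortSummary":
        """Summary arithmetic from event counts alone (no interval data):
        mean events/person to 1 dp, deletion/duplication shares as rounded
        percentages."""
        if n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        n_dup = n_events - n_del
        if n_events == 0:
            return cls(0, 0.0, 0, 0, None, None, None)
        return cls(
            n_events=n_events,
            mean_per_person=round(n_events / n_individuals, 1),
            n_del=n_del,
            n_dup=n_dup,
            pct_del=round(100.0 * n_del / n_events),
            pct_dup=round(100.0 * n_dup / n_events),
            mean_size_kb=mean_size_kb,
        )


def reciprocal_overlap(a, b) -> float:
    """min(|a∩b|/|a|, |a∩b|/|b|) for 1-based inclusive intervals.

    Accepts ``CNVCall`` objects or (chrom, start, end) triples; 0 when the
    intervals are disjoint or on different chromosomes.
    """
    ca, sa, ea = _as_interval(a)
    cb, sb, eb = _as_interval(b)
    if ca != cb:
        logger.debug("reciprocal_overlap across chromosomes %s vs %s -> 0", ca, cb)
        return 0.0
    ov = min(ea, eb) - max(sa, sb) + 1
    if ov <= 0:
        return 0.0
    return min(ov / (ea - sa + 1), ov / (eb - sb + 1))


def _as_interval(x) -> tuple[str, int, int]:
    if isinstance(x, CNVCall):
        return x.chrom, x.start, x.end
    chrom, start, end = x
    if start > end:
        raise ValueError(f"start {start} > end {end}")
    return str(chrom), int(start), int(end)


def merge_consensus(
    set_a: CallSet,
    set_b: CallSet,
    params: ConsensusParams = ConsensusParams(),
    probe_positions: np.ndarray | None = None,
) -> CallSet:
    """Pair same-sample, same-state calls across callers and keep the
    consensus segments that survive the probe-count and size filters.

    Matching is greedy by descending reciprocal overlap within each sample
    (ties: leftmost start, then shortest), each input call used at most
    once.  The consensus probe count is recounted from ``probe_positions``
    when given, otherwise the smaller of the pair's counts.
    """
    by_a = _dedup_warn(set_a).by_sample()
    by_b = _dedup_warn(set_b).by_sample()
    out: list[CNVCall] = []
    for sample in sorted(set(by_a) | set(by_b)):
        cas = by_a.get(sample, [])
        cbs = by_b.get(sample, [])
        pairs = []
        for i, ca in enumerate(cas):
            for j, cb in enumerate(cbs):
                if ca.state != cb.state:
                    continue
                ro = reciprocal_overlap(ca, cb)
                if ro >= params.min_reciprocal_overlap:
                    pairs.append((-ro, min(ca.start, cb.start),
                                  min(ca.size, cb.size), i, j))
        used_a: set[int] = set()
        used_b: set[int] = set()
        for _, _, _, i, j in sorted(pairs):
            if i in used_a or j in used_b:
                continue
            used_a.add(i)
            used_b.add(j)
            out.extend(_consensus_call(cas[i], cbs[j], params, probe_positions))
    return CallSet(out)


def _dedup_warn(calls: CallSet) -> CallSet:
    seen = {}
    dropped = 0
    for c in calls:
        key = (c.sample_id, c.caller, c.chrom, c.start, c.end)
        if key in seen:
            dropped += 1
        else:
            seen[key] = c
    if dropped:
        warnings.warn(f"deduplicated {dropped} repeated call record(s)", stacklevel=3)
    return CallSet(seen.values())


def _consensus_call(ca, cb, params, probe_positions):
    if params.endpoint_rule == "intersection":
        start, end = max(ca.start, cb.start), min(ca.end, cb.end)
    elif params.endpoint_rule == "union":
        start, end = min(ca.start, cb.start), max(ca.end, cb.end)
    else:
        start, end = ca.start, ca.end  # caller A priority
    if probe_positions is not None:
        pp = np.asarray(probe_positions)
        n_probes = int(np.count_nonzero((pp >= start) & (pp <= end)))
    else:
        n_probes = min(ca.n_probes, cb.n_probes)
    size = end - start + 1
    if n_probes < params.min_probes or size < params.min_size:
        return []
    cn = ca.copy_number
    return [
        CNVCall(
            sample_id=ca.sample_id,
            chrom=ca.chrom,
            start=start,
            end=end,
            state=state_from_copy_number(cn),
            copy_number=cn,
            n_probes=max(1, n_probes),
            caller="consensus",
        )
    ]


def summarize_calls(calls: CallSet, n_individuals: int) -> CohortSummary:
    """Cohort summary of a call set: event count, events/person (1 dp),
    deletion/duplication split and mean size in kb."""
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    n_events = len(calls)
    n_del = sum(1 for c in calls if c.copy_number < 2)
    mean_size = (
        float(np.mean([c.size for c in calls])) / 1000.0 if n_events else None
    )
    summary = CohortSummary.from_counts(n_events, n_del, n_individuals, mean_size)
    return summary
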