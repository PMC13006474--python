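"""Recurrent CNV (rCNV) loci: clustering, cross-population sharing, genes.

Consensus calls from many individuals are clustered by single-linkage on
reciprocal overlap; a locus carried by >= 2 distinct individuals is
recurrent.  Because array breakpoints are approximate (~10 kb), an
optional endpoint tolerance can link calls whose start and end both fall
within the tolerance even when reciprocal overlap misses the threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import CNVCall, CallSet
from .cnv_consensus import reciprocal_overlap

__all__ = [
    "RCNVLocus",
    "GeneAnnotation",
    "SharingResult",
    "group_recurrent",
    "cross_population_share",
    "annotate_genes",
    "read_band_table",
]


@dataclass
class RCNVLocus:
    """A cluster of overlapping same-state calls across individuals."""

    locus_id: str
    chrom: str
    start: int
    end: int
    state: str
    carriers: frozenset[str]
    carrier_frequency: float
    band: str | None = None
    member_calls: list[CNVCall] = field(default_factory=list)

    @property
    def carrier_count(self) -> int:
        return len(self.carriers)

    @property
    def recurrent(self) -> bool:
        return self.carrier_count >= 2

    @property
    def size(self) -> int:
        return self.end - self.start + 1


@dataclass
class GeneAnnotation:
    """Genes fully contained in vs partially overlapped by a locus."""

    locus_id: str
    full: list[str]
    partial: list[str]

    @property
    def genic(self) -> bool:
        return bool(self.full or self.partial)


@dataclass
class SharingResult:
    pairs: list[tuple[RCNVLocus, RCNVLocus]]
    a_only: int
    b_only: int
    shared: int


def _linked(a: CNVCall, b: CNVCall, grouping_ro: float, tol: int) -> bool:
    if a.chrom != b.chrom or a.state != b.state:
        return False
    if reciprocal_overlap(a, b) >= grouping_ro:
        return True
    return tol > 0 and abs(a.start - b.start) <= tol and abs(a.end - b.end) <= tol


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def group_recurrent(
    calls: CallSet,
    cohort_size: int,
    grouping_ro: float = 0.5,
    endpoint_tolerance_bp: int = 0,
    bands: pd.DataFrame | None = None,
) -> list[RCNVLocus]:
    """Single-linkage clustering of consensus calls into candidate loci.

    Calls are canonically sorted first, so the clustering is independent
    of input order.  Locus boundaries are the coordinate-wise median of
    member segments (robust to breakpoint jitter); carrier frequency is
    ``carrier_count / cohort_size``.
    """
    if cohort_size < 1:
        raise ValueError("cohort_size must be >= 1")
    members = sorted(
        calls, key=lambda c: (c.chrom, c.state, c.start, c.end, c.sample_id, c.caller)
    )
    n = len(members)
    uf = _UnionFind(n)
    # only calls on the same chromosome with compatible coordinates can link;
    # a sorted sweep keeps this near-linear for jittered recurrent loci
    for i in range(n):
        ci = members[i]
        reach = ci.end + max(endpoint_tolerance_bp, 0)
        for j in range(i + 1, n):
            cj = members[j]
            if (cj.chrom, cj.state) != (ci.chrom, ci.state) or cj.start > reach:
                break
            if _linked(ci, cj, grouping_ro, endpoint_tolerance_bp):
                uf.union(i, j)
    clusters: dict[int, list[CNVCall]] = {}
    for i in range(n):
        clusters.setdefault(uf.find(i), []).append(members[i])

    loci = []
    for k, root in enumerate(sorted(clusters)):
        group = clusters[root]
        start = int(round(float(np.median([c.start for c in group]))))
        end = int(round(float(np.median([c.end for c in group]))))
        carrier_list = [c.sample_id for c in group]
        carriers = frozenset(carrier_list)
        if len(carrier_list) > len(carriers):
            warnings.warn(
                f"sample(s) with multiple member calls in one cluster at "
                f"{group[0].chrom}:{start}; counted once as carriers",
                stacklevel=2,
            )
        locus = RCNVLocus(
            locus_id=f"L{k + 1:04d}",
            chrom=group[0].chrom,
            start=start,
            end=end,
            state=group[0].state,
            carriers=carriers,
            carrier_frequency=len(carriers) / cohort_size,
            member_calls=group,
        )
        if bands is not None:
            locus.band = _band_of(locus, bands)
        loci.append(locus)
    return loci


def _band_of(locus: RCNVLocus, bands: pd.DataFrame) -> str | None:
    mid = (locus.start + locus.end) // 2
    hit = bands[
        (bands["chrom"].astype(str) == locus.chrom)
        & (bands["start"] <= mid)
        & (bands["end"] >= mid)
    ]
    return str(hit.iloc[0]["band"]) if len(hit) else None


def read_band_table(path) -> pd.DataFrame:
    """Cytogenetic band intervals: TSV with chrom, start, end, band
    (1-based inclusive)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "band": str})
    missing = {"chrom", "start", "end", "band"} - set(df.columns)
    if missing:
        raise ValueError(f"band table missing columns: {sorted(missing)}")
    return df


def cross_population_share(
    loci_a: list[RCNVLocus],
    loci_b: list[RCNVLocus],
    rule: str = "band_or_overlap",
    min_ro: float = 0.0,
) -> SharingResult:
    """Match rCNV loci across two cohorts one-to-one, best overlap first.

    ``band``: same cytogenetic band and state.  ``overlap``: physically
    overlapping with reciprocal overlap >= ``min_ro``.  The default
    ``band_or_overlap`` accepts either, because breakpoints typed on
    different arrays can be disjoint for what is plainly the same locus.
    """
    if rule not in ("band", "overlap", "band_or_overlap"):
        raise ValueError(f"unknown sharing rule {rule!r}")
    if rule in ("band", "band_or_overlap"):
        missing = [l.locus_id for l in (*loci_a, *loci_b) if l.band is None]
        if rule == "band" and missing:
            raise ValueError(f"rule=band requires band labels; missing for {missing}")

    candidates = []
    for i, la in enumerate(loci_a):
        for j, lb in enumerate(loci_b):
            if la.state != lb.state or la.chrom != lb.chrom:
                continue
            ro = reciprocal_overlap(
                (la.chrom, la.start, la.end), (lb.chrom, lb.start, lb.end)
            )
            by_overlap = ro > 0 and ro >= min_ro
            by_band = la.band is not None and la.band == lb.band
            ok = {
                "band": by_band,
                "overlap": by_overlap,
                "band_or_overlap": by_band or by_overlap,
            }[rule]
            if ok:
                candidates.append((-ro, la.start, lb.start, i, j))
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs = []
    for _, _, _, i, j in sorted(candidates):
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((loci_a[i], loci_b[j]))
    return SharingResult(
        pairs=pairs,
        a_only=len(loci_a) - len(used_a),
        b_only=len(loci_b) - len(used_b),
        shared=len(pairs),
    )


def annotate_genes(locus: RCNVLocus, genes: pd.DataFrame) -> GeneAnnotation:
    """Classify each gene as fully contained, partially overlapped, or
    outside a locus.  ``genes`` has 1-based inclusive chrom/start/end/name
    columns (see :func:`rcnvclock.io_formats.read_gene_bed`)."""
    if (genes["end"] < genes["start"]).any():
        bad = genes[genes["end"] < genes["start"]]["name"].tolist()
        raise ValueError(f"invalid gene interval(s): {bad}")
    on_chrom = genes[genes["chrom"].astype(str) == locus.chrom]
    full, partial = [], []
    for row in on_chrom.itertuples(index=False):
        if row.start >= locus.start and row.end <= locus.end:
            full.append(row.name)
        elif row.start <= locus.end and row.end >= locus.start:
            partial.append(row.name)
    return GeneAnnotation(locus_id=locus.locus_id, full=full, partial=partial)
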