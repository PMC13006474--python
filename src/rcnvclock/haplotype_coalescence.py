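"""Shared-haplotype extension and Gamma-method coalescence dating of rCNVs.

The age of a recurrent CNV is estimated from the genetic lengths of the
ancestral haplotype still shared by its carriers.  Scanning outward from
the CNV on each side, a carrier haplotype remains "shared" while it
matches the inferred ancestral (modal) haplotype; a single mismatch is
rescued — attributed to mutation or genotyping error — when the next
``rescue_len`` SNPs all match.  The first unrescued mismatch marks the
historical recombination breakpoint.

Under lineage independence (star genealogy) each side's shared genetic
length is Exponential(rate tau), the per-haplotype 5' + 3' total is
Gamma(shape 2, rate tau), and the sum over n haplotypes is Gamma(2n, tau).
Hence tau_hat = 2 / l_ave with quantile-based confidence intervals, where
l_ave is the weighted mean of per-haplotype total shared lengths in
Morgans.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import MISSING, GeneticMap, PhasedHaplotypeSet
from .rcnv_detection import RCNVLocus

__all__ = [
    "FlankingWindows",
    "SharedLengthSummary",
    "AgeEstimate",
    "select_flanking_snps",
    "carrier_cnv_haplotypes",
    "max_shared_haplotype",
    "weighted_mean_length",
    "estimate_age",
    "compare_ages",
    "age_abundance_correlation",
    "share_support",
    "date_rcnv",
]


@dataclass
class FlankingWindows:
    """Flanking SNP windows around a locus, ordered outward from the CNV.

    ``idx_5`` indexes SNPs upstream (5'), nearest first (decreasing bp);
    ``idx_3`` downstream, nearest first (increasing bp).
    """

    idx_5: np.ndarray
    idx_3: np.ndarray
    positions: np.ndarray  # full SNP position vector the indices refer to
    locus_start: int
    locus_end: int
    truncated_5: bool = False
    truncated_3: bool = False

    @property
    def pos_5(self) -> np.ndarray:
        return self.positions[self.idx_5]

    @property
    def pos_3(self) -> np.ndarray:
        return self.positions[self.idx_3]


@dataclass
class SharedLengthSummary:
    """Per-haplotype maximum shared haplotype breakpoints and lengths.

    ``table`` columns: hap_label, n_shared_5, n_shared_3, censored_5,
    censored_3, breakpoint_bp_5, breakpoint_bp_3 and — once genetic
    lengths are attached — genetic_length_5_cm, genetic_length_3_cm.
    ``groups`` maps a breakpoint signature to its weight (haplotype count).
    """

    table: pd.DataFrame
    windows: FlankingWindows
    groups: dict[tuple, int] = field(default_factory=dict)
    l_ave: float | None = None  # Morgans

    @property
    def n_haplotypes(self) -> int:
        return len(self.table)

    @property
    def censoring_fraction(self) -> float:
        c = self.table[["censored_5", "censored_3"]].to_numpy()
        return float(c.any(axis=1).mean())


@dataclass
class AgeEstimate:
    """Coalescence-time estimate for one rCNV."""

    tau_hat: float  # generations
    ci: tuple[float, float]
    level: float
    n_haplotypes: int
    censoring_fraction: float = 0.0
    years: float | None = None
    #: tau_hat rescaled under recombination rates ±20%, a sensitivity band
    #: for map uncertainty (not a sampling interval)
    rate_sensitivity: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        lo, hi = self.ci
        if not (lo <= self.tau_hat <= hi):
            raise ValueError("CI must contain the point estimate")


# ---------------------------------------------------------------------------
# Window selection and haplotype extraction
# ---------------------------------------------------------------------------


def select_flanking_snps(
    locus: RCNVLocus, haps: PhasedHaplotypeSet, k_per_side: int = 60
) -> FlankingWindows:
    """The ``k_per_side`` SNPs nearest the locus on each side, ordered
    outward.  Fewer than k available → all of them, flagged truncated;
    zero on a side is an error."""
    if k_per_side < 1:
        raise ValueError("k_per_side must be >= 1")
    pos = haps.positions
    up = np.nonzero(pos < locus.start)[0]
    down = np.nonzero(pos > locus.end)[0]
    if up.size == 0 or down.size == 0:
        raise ValueError(
            f"no flanking SNPs {'upstream' if up.size == 0 else 'downstream'} "
            f"of locus {locus.locus_id}"
        )
    idx_5 = up[::-1][:k_per_side]  # nearest first: decreasing position
    idx_3 = down[:k_per_side]
    return FlankingWindows(
        idx_5=idx_5,
        idx_3=idx_3,
        positions=pos,
        locus_start=locus.start,
        locus_end=locus.end,
        truncated_5=up.size < k_per_side,
        truncated_3=down.size < k_per_side,
    )


def carrier_cnv_haplotypes(
    haps: PhasedHaplotypeSet, locus: RCNVLocus, carrier_ids: list[str] | None = None
) -> tuple[np.ndarray, list[str]]:
    """Pick the CNV-bearing haplotype of each carrier.

    Deletion carriers are hemizygous, so the haplotype with more missing
    alleles inside the locus is the deleted one.  When missingness does
    not discriminate (duplications), the haplotype agreeing better with
    the carrier-modal haplotype over the nearest 10 flanking SNPs per side
    is taken.  Returns (n_carriers x n_snps) allele matrix and labels.
    """
    carriers = list(carrier_ids) if carrier_ids is not None else sorted(locus.carriers)
    pos = haps.positions
    inside = (pos >= locus.start) & (pos <= locus.end)
    rows, labels, undecided = [], [], []
    for sid in carriers:
        i = haps.sample_ids.index(sid)
        h0, h1 = haps.alleles[2 * i], haps.alleles[2 * i + 1]
        m0 = int(np.count_nonzero(h0[inside] == MISSING))
        m1 = int(np.count_nonzero(h1[inside] == MISSING))
        if m0 != m1:
            which = 0 if m0 > m1 else 1
        else:
            which = None  # decide against the modal flank below
        rows.append((h0, h1))
        labels.append(sid)
        undecided.append(which)
    win = select_flanking_snps(locus, haps, k_per_side=10)
    near = np.concatenate([win.idx_5, win.idx_3])
    provisional = np.stack(
        [r[w if w is not None else 0][near] for r, w in zip(rows, undecided)]
    )
    modal = _modal_haplotype(provisional)
    out = []
    for r, w in zip(rows, undecided):
        if w is None:
            scores = [
                int(np.count_nonzero((r[h][near] == modal) & (r[h][near] != MISSING)))
                for h in (0, 1)
            ]
            w = 0 if scores[0] >= scores[1] else 1
        out.append(r[w])
    return np.stack(out), [f"{s}|cnv" for s in labels]


def _modal_haplotype(mat: np.ndarray) -> np.ndarray:
    """Column-wise majority allele over non-missing entries (ties -> 0;
    all-missing columns stay missing)."""
    n1 = np.count_nonzero(mat == 1, axis=0)
    n0 = np.count_nonzero(mat == 0, axis=0)
    modal = np.where(n1 > n0, 1, 0).astype(np.int8)
    modal[(n0 == 0) & (n1 == 0)] = MISSING
    return modal


# ---------------------------------------------------------------------------
# Shared-haplotype extension
# ---------------------------------------------------------------------------


def _scan_breakpoints(
    sub: np.ndarray, rescue_len: int, reference: str
) -> np.ndarray:
    """First unrescued mismatch index per haplotype in an outward-ordered
    window (-1 = shared to the window edge, censored).

    ``reference='progressive'`` re-estimates the ancestral allele at each
    position as the majority over haplotypes still extending there, so the
    reference keeps tracking the ancestral haplotype even after most
    carriers have recombined; ``'static'`` uses the whole-window modal of
    all carrier haplotypes.  Missing alleles are neutral: they neither
    terminate extension nor spoil a rescue.
    """
    n_h, L = sub.shape
    if reference == "static":
        modal = _modal_haplotype(sub)
        neutral_all = (sub == modal) | (sub == MISSING) | (modal == MISSING)
        out = np.full(n_h, -1, dtype=np.int64)
        for h in range(n_h):
            row = neutral_all[h]
            for j in np.nonzero(~row)[0]:
                tail = row[j + 1 : j + 1 + rescue_len]
                if rescue_len > 0 and bool(tail.all()):
                    continue  # rescued point mutation / genotyping error
                out[h] = j
                break
        return out

    # progressive: states per haplotype, leave-one-out reference so no
    # haplotype votes for its own extension
    TERM = 2
    state = np.zeros(n_h, dtype=np.int8)
    pending_at = np.full(n_h, -1, dtype=np.int64)  # first-mismatch index
    pending_ok = np.zeros(n_h, dtype=np.int64)  # matches seen since
    bp = np.full(n_h, -1, dtype=np.int64)
    for j in range(L):
        live = np.nonzero(state != TERM)[0]
        if live.size == 0:
            break
        col = sub[live, j]
        n1 = int(np.count_nonzero(col == 1))
        n0 = int(np.count_nonzero(col == 0))
        terminated_here = False
        for h in live:
            a = sub[h, j]
            # reference = majority over the *other* active haplotypes
            o0 = n0 - (1 if a == 0 else 0)
            o1 = n1 - (1 if a == 1 else 0)
            if o0 == 0 and o1 == 0:
                ref = MISSING
            else:
                ref = np.int8(1) if o1 > o0 else np.int8(0)
            neutral = a == MISSING or ref == MISSING or a == ref
            if neutral:
                if pending_at[h] >= 0:
                    pending_ok[h] += 1
                    if pending_ok[h] >= rescue_len:
                        pending_at[h] = -1  # rescued
            else:
                if pending_at[h] >= 0:
                    # second mismatch within the rescue lookahead:
                    # the first mismatch stands as the breakpoint
                    state[h] = TERM
                    bp[h] = pending_at[h]
                    terminated_here = True
                elif rescue_len > 0:
                    pending_at[h] = j
                    pending_ok[h] = 0
                else:
                    state[h] = TERM
                    bp[h] = j
                    terminated_here = True
        # sharing needs >= 2 haplotypes: once a single survivor remains it
        # has nothing left to share with, so it stops where the last pair
        # diverged (its own pending mismatch if one is open)
        if terminated_here:
            survivors = np.nonzero(state != TERM)[0]
            if survivors.size == 1:
                s = int(survivors[0])
                state[s] = TERM
                bp[s] = pending_at[s] if pending_at[s] >= 0 else j
                break
    # pending haplotypes at the window edge kept their extension: the
    # truncated lookahead saw only matches
    return bp


def max_shared_haplotype(
    carrier_haps: np.ndarray,
    windows: FlankingWindows,
    rescue_len: int = 5,
    hap_labels: list[str] | None = None,
    reference: str = "progressive",
) -> SharedLengthSummary:
    """Per-haplotype maximum shared haplotype breakpoints on both sides.

    The reference is the modal carrier haplotype — an estimate of the
    ancestral haplotype, consistent with the star-shaped sharing model.
    By default the modal is re-estimated progressively over the
    haplotypes still extending at each SNP, which keeps it anchored to
    the ancestral haplotype beyond the distance where most carriers have
    already recombined (a whole-window ``'static'`` modal drifts to the
    population major allele there and truncates long segments).  A
    haplotype's breakpoint is the last concordant SNP before the first
    unrescued mismatch — this offsets the chance-match overrun past the
    true recombination point; with no breakpoint in the window the side
    is censored at the window edge.  ``rescue_len=0`` disables the rescue
    rule.
    """
    if reference not in ("progressive", "static"):
        raise ValueError(f"unknown reference mode {reference!r}")
    carrier_haps = np.asarray(carrier_haps, dtype=np.int8)
    if carrier_haps.ndim != 2 or carrier_haps.shape[0] < 2:
        raise ValueError("need >= 2 carrier haplotypes")
    n_h = carrier_haps.shape[0]
    if hap_labels is None:
        hap_labels = [f"hap{i}" for i in range(n_h)]

    records = []
    side_data = {}
    for side, idx, edge in (
        ("5", windows.idx_5, windows.locus_start),
        ("3", windows.idx_3, windows.locus_end),
    ):
        sub = carrier_haps[:, idx]
        all_missing = (sub == MISSING).all(axis=1)
        if all_missing.any():
            warnings.warn(
                f"{int(all_missing.sum())} haplotype(s) all-missing in the "
                f"{side}' window; excluded from dating",
                stacklevel=2,
            )
        bp = _scan_breakpoints(sub, rescue_len, reference)
        side_data[side] = (idx, edge, bp, all_missing)

    excluded = side_data["5"][3] | side_data["3"][3]
    for h in range(n_h):
        if excluded[h]:
            continue
        rec = {"hap_label": hap_labels[h]}
        for side in ("5", "3"):
            idx, edge, bp, _ = side_data[side]
            pos = windows.positions[idx].astype(float)
            j = int(bp[h])
            if j < 0:
                rec[f"n_shared_{side}"] = int(idx.size)
                rec[f"censored_{side}"] = True
                rec[f"breakpoint_bp_{side}"] = float(pos[-1])
            else:
                rec[f"n_shared_{side}"] = j
                rec[f"censored_{side}"] = False
                rec[f"breakpoint_bp_{side}"] = pos[j - 1] if j > 0 else float(edge)
        records.append(rec)
    table = pd.DataFrame.from_records(records)
    return SharedLengthSummary(table=table, windows=windows)


def weighted_mean_length(summary: SharedLengthSummary, gmap: GeneticMap) -> float:
    """Weighted mean of per-haplotype total shared genetic lengths, in
    Morgans; weights are the numbers of haplotypes sharing each exact
    (5', 3') breakpoint signature.

    Also attaches per-side genetic lengths (cM) to ``summary.table`` and
    fills ``summary.groups`` / ``summary.l_ave``.  Censored sides
    contribute the window's genetic length as a lower bound.
    """
    t = summary.table
    if t.empty:
        raise ValueError("no haplotypes with breakpoints to average")
    g_start = float(gmap.genetic_position(summary.windows.locus_start))
    g_end = float(gmap.genetic_position(summary.windows.locus_end))
    g5 = g_start - np.asarray(gmap.genetic_position(t["breakpoint_bp_5"].to_numpy()))
    g3 = np.asarray(gmap.genetic_position(t["breakpoint_bp_3"].to_numpy())) - g_end
    t["genetic_length_5_cm"] = np.maximum(g5, 0.0)
    t["genetic_length_3_cm"] = np.maximum(g3, 0.0)
    if bool(t[["censored_5", "censored_3"]].to_numpy().all()):
        raise ValueError("all haplotypes censored on both sides: no recombination observed")

    totals_m = (t["genetic_length_5_cm"] + t["genetic_length_3_cm"]).to_numpy() / 100.0
    sig = list(
        zip(
            t["n_shared_5"], t["censored_5"], t["n_shared_3"], t["censored_3"],
        )
    )
    groups: dict[tuple, int] = {}
    group_len: dict[tuple, float] = {}
    for s, l in zip(sig, totals_m):
        groups[s] = groups.get(s, 0) + 1
        group_len[s] = l  # identical signature -> identical length
    w = np.array([groups[s] for s in groups], dtype=float)
    l_g = np.array([group_len[s] for s in groups])
    l_ave = float(np.sum(w * l_g) / np.sum(w))
    summary.groups = groups
    summary.l_ave = l_ave
    return l_ave


# ---------------------------------------------------------------------------
# Age estimation and comparisons
# ---------------------------------------------------------------------------


def estimate_age(
    l_ave: float,
    n_haplotypes: int,
    level: float = 0.95,
    censoring_fraction: float = 0.0,
    years_per_generation: float | None = None,
    region_genetic_span: float | None = None,
) -> AgeEstimate:
    """Gamma-method age: tau_hat = 2 / l_ave generations.

    Under independence the total shared length over n haplotypes is
    Gamma(shape 2n, rate tau), so the CI is
    (q(alpha/2; 2n) / (n l_ave), q(1 - alpha/2; 2n) / (n l_ave)) with q
    the unit-rate Gamma quantile.  ``region_genetic_span`` (Morgans), when
    given, guards against inconsistent inputs.  Censoring > 20% triggers a
    warning: tau_hat is then biased downward.
    """
    if l_ave <= 0:
        raise ValueError("l_ave must be > 0")
    if n_haplotypes < 2:
        raise ValueError("need >= 2 haplotypes")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    if region_genetic_span is not None and l_ave > region_genetic_span:
        raise ValueError(
            f"l_ave {l_ave} M exceeds the region's genetic span "
            f"{region_genetic_span} M — inconsistent inputs"
        )
    if censoring_fraction > 0.2:
        warnings.warn(
            f"censoring fraction {censoring_fraction:.2f} > 0.2: shared lengths "
            "are lower bounds, tau_hat is biased downward",
            stacklevel=2,
        )
    tau_hat = 2.0 / l_ave
    alpha = 1.0 - level
    shape = 2 * n_haplotypes
    denom = n_haplotypes * l_ave
    lo = float(stats.gamma.ppf(alpha / 2.0, a=shape) / denom)
    hi = float(stats.gamma.ppf(1.0 - alpha / 2.0, a=shape) / denom)
    return AgeEstimate(
        tau_hat=tau_hat,
        ci=(lo, hi),
        level=level,
        n_haplotypes=n_haplotypes,
        censoring_fraction=censoring_fraction,
        years=tau_hat * years_per_generation if years_per_generation else None,
        rate_sensitivity=(tau_hat / 1.2, tau_hat / 0.8),
    )


def compare_ages(ages_a, ages_b) -> tuple[float, float]:
    """Two-sided Mann–Whitney U on two groups of age estimates: exact
    enumeration when both n <= 8 and there are no ties, tie-corrected
    normal approximation otherwise.  Returns (U, p)."""
    a = np.asarray(ages_a, dtype=float)
    b = np.asarray(ages_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size <= 8 and b.size <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def age_abundance_correlation(ages, carrier_counts) -> tuple[float, float, float]:
    """Pearson correlation and least-squares slope of carrier frequency
    (or count) on age; p from the t distribution on n - 2 df.
    Returns (r, slope, p)."""
    x = np.asarray(ages, dtype=float)
    y = np.asarray(carrier_counts, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors with >= 3 entries")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    res = stats.linregress(x, y)
    return float(res.rvalue), float(res.slope), float(res.pvalue)


def share_support(
    carrier_haps: np.ndarray, windows: FlankingWindows, k: int = 10
) -> float:
    """Mean concordance of carrier haplotypes with their modal haplotype
    over the ``k`` SNPs nearest the CNV on each side (missing is neutral).

    High support (> 0.9 on simulated rCNVs) confirms a common haplotype
    background — the "same ancestral origin" check for an rCNV; pooled
    non-IBD haplotypes concentrate near the chance-match rate (~0.6-0.7
    for array SNPs), well below.  Per-SNP concordance is used rather than
    an all-SNP exact match so that a genuine recombination just inside
    the flank does not disqualify an otherwise concordant carrier.
    """
    carrier_haps = np.asarray(carrier_haps, dtype=np.int8)
    near = np.concatenate([windows.idx_5[:k], windows.idx_3[:k]])
    sub = carrier_haps[:, near]
    modal = _modal_haplotype(sub)
    neutral = (sub == modal) | (sub == MISSING) | (modal == MISSING)
    return float(neutral.mean())


def date_rcnv(
    locus: RCNVLocus,
    haps: PhasedHaplotypeSet,
    gmap: GeneticMap,
    carrier_ids: list[str] | None = None,
    k_per_side: int = 60,
    rescue_len: int = 5,
    level: float = 0.95,
    years_per_generation: float | None = None,
) -> tuple[AgeEstimate, SharedLengthSummary]:
    """End-to-end dating of one rCNV locus from phased haplotypes."""
    windows = select_flanking_snps(locus, haps, k_per_side)
    mat, labels = carrier_cnv_haplotypes(haps, locus, carrier_ids)
    summary = max_shared_haplotype(mat, windows, rescue_len, labels)
    l_ave = weighted_mean_length(summary, gmap)
    span_m = (
        float(gmap.genetic_position(windows.pos_3[-1]))
        - float(gmap.genetic_position(windows.pos_5[-1]))
    ) / 100.0
    est = estimate_age(
        l_ave,
        summary.n_haplotypes,
        level=level,
        censoring_fraction=summary.censoring_fraction,
        years_per_generation=years_per_generation,
        region_genetic_span=span_m,
    )
    return est, summary
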