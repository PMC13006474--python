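"""Synthetic founder-population cohorts with a dated CNV haplotype.

The generator emulates the data-generating process the downstream dating
model assumes: a single founder haplotype carrying a CNV is transmitted
``tau_true`` generations, recombination against a local genetic map erodes
the shared flanking haplotype, per-SNP genotyping error is applied, and two
noisy callers emit CNV call sets.  Under the default star genealogy each
carrier lineage recombines independently, so each side's breakpoint
distance (in Morgans) is Exponential(rate = tau_true) and per-haplotype
5' + 3' totals are Gamma(shape 2, rate tau_true) — exactly the model the
Gamma-method age estimator inverts.

Background haplotypes are drawn per SNP from its allele frequency with no
linkage disequilibrium: an LD-free background is the conservative easy
case for shared-haplotype detection and is deliberate (see docs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io_formats import (
    DELETION,
    DUPLICATION,
    MISSING,
    CNVCall,
    CallSet,
    GeneticMap,
    PhasedHaplotypeSet,
    PhenotypeTable,
)

import pandas as pd

__all__ = [
    "CallerNoise",
    "PhenotypeModel",
    "SimulationConfig",
    "SimTruth",
    "simulate_cohort",
    "emit_callsets",
    "draw_phenotypes",
]


@dataclass(frozen=True)
class CallerNoise:
    """Per-caller corruption: Gaussian breakpoint jitter (bp, snapped to the
    nearest simulated probe), per-carrier dropout and per-sample spurious
    calls."""

    breakpoint_jitter_sd: float = 5_000.0
    fn_rate: float = 0.05
    fp_rate: float = 0.05

    def __post_init__(self) -> None:
        if not (0 <= self.fn_rate <= 1 and 0 <= self.fp_rate <= 1):
            raise ValueError("rates must be in [0, 1]")
        if self.breakpoint_jitter_sd < 0:
            raise ValueError("jitter SD must be >= 0")


@dataclass(frozen=True)
class PhenotypeModel:
    """Logistic disease model: log-odds = logit(baseline) + log(OR)·carrier."""

    baseline_prevalence: float = 0.60
    carrier_odds_ratio: float = 3.0

    def __post_init__(self) -> None:
        if not 0 < self.baseline_prevalence < 1:
            raise ValueError("baseline prevalence must be in (0, 1)")
        if self.carrier_odds_ratio <= 0:
            raise ValueError("odds ratio must be > 0")


@dataclass
class SimulationConfig:
    """Study conditions for one simulated cohort.

    Defaults describe a founder-population rCNV of moderate age: a 500 kb
    deletion carried by 50 of 200 individuals, transmitted 100 generations
    over a uniform 1 cM/Mb map, typed at 40 SNPs/cM (Illumina-array scale)
    with MAF ~ U(0.1, 0.5) and allele flip probability 0.002.
    """

    seed: int = 0
    n_samples: int = 200
    n_carriers: int = 50
    tau_true: float = 100.0
    region_length: int = 30_000_000
    snp_density: float = 40.0  # SNPs per cM
    map_profile: float | Sequence[tuple[int, float]] = 1.0  # cM/Mb or knots
    maf_range: tuple[float, float] = (0.1, 0.5)
    genotyping_error: float = 0.002
    cnv_interval: tuple[int, int] = (14_750_001, 15_250_000)
    cnv_state: str = DELETION
    caller_noise: CallerNoise = field(default_factory=CallerNoise)
    phenotype_model: PhenotypeModel = field(default_factory=PhenotypeModel)
    genealogy: str = "star"
    chrom: str = "1"

    def __post_init__(self) -> None:
        if self.n_carriers > self.n_samples:
            raise ValueError("n_carriers must be <= n_samples")
        if self.tau_true < 0:
            raise ValueError("tau_true must be >= 0")
        if not 0 <= self.genotyping_error <= 1:
            raise ValueError("genotyping_error must be a probability")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if self.genealogy not in ("star", "tree"):
            raise ValueError("genealogy must be 'star' or 'tree'")
        if self.cnv_state not in (DELETION, DUPLICATION):
            raise ValueError("cnv_state must be deletion or duplication")
        s, e = self.cnv_interval
        if not (1 <= s <= e <= self.region_length):
            raise ValueError("cnv_interval must lie inside the region")


@dataclass
class SimTruth:
    """Ground truth of one simulated cohort, reproducible from the seed."""

    carrier_ids: list[str]
    tau_true: float
    cnv_interval: tuple[int, int]
    cnv_state: str
    chrom: str
    founder_haplotype: np.ndarray
    #: per carrier: genetic distance (Morgans) from the CNV edge to the first
    #: recombination on each side, and the corresponding physical positions
    breakpoint_morgans_5: np.ndarray = field(default=None)
    breakpoint_morgans_3: np.ndarray = field(default=None)
    breakpoint_bp_5: np.ndarray = field(default=None)
    breakpoint_bp_3: np.ndarray = field(default=None)


def _build_map(config: SimulationConfig) -> GeneticMap:
    if np.isscalar(config.map_profile):
        rate = float(config.map_profile)  # cM/Mb
        pos = np.array([1, config.region_length], dtype=np.int64)
        cm = np.array([0.0, (config.region_length - 1) * rate / 1e6])
        return GeneticMap(config.chrom, pos, cm)
    knots = sorted((int(p), float(c)) for p, c in config.map_profile)
    pos = np.array([p for p, _ in knots], dtype=np.int64)
    cm = np.array([c for _, c in knots])
    return GeneticMap(config.chrom, pos, cm)


def _snp_positions(config: SimulationConfig, gmap: GeneticMap) -> np.ndarray:
    """Place SNPs at equal genetic spacing 1/snp_density cM."""
    span_cm = float(gmap.genetic_position(config.region_length) - gmap.genetic_position(1))
    n_snps = max(2, int(np.floor(span_cm * config.snp_density)))
    grid_cm = gmap.genetic_position(1) + (np.arange(n_snps) + 0.5) / config.snp_density
    bp = np.asarray(gmap.physical_position(grid_cm))
    bp = np.unique(np.round(bp).astype(np.int64))
    return bp[(bp >= 1) & (bp <= config.region_length)]


def _star_breakpoints(n: int, tau: float, rng: np.random.Generator) -> np.ndarray:
    if tau == 0:
        return np.full(n, np.inf)
    return rng.exponential(scale=1.0 / tau, size=n)


def _tree_breakpoints(n: int, tau: float, rng: np.random.Generator) -> np.ndarray:
    """Kingman-tree breakpoint distances: recombination events accumulate as
    a Poisson process (rate = branch generations per Morgan) along each
    lineage's path to the root, so shared branches induce correlated
    distances across carriers — the known failure mode of the independence
    assumption.  The coalescent timescale is set so E[TMRCA] = tau."""
    if tau == 0:
        return np.full(n, np.inf)
    if n == 1:
        return rng.exponential(scale=1.0 / tau, size=1)
    N = tau / (2.0 * (1.0 - 1.0 / n))
    # active lineages hold (member leaf indices, accumulated candidate distance)
    active: list[tuple[list[int], float]] = [([i], np.inf) for i in range(n)]
    t = 0.0
    dist = np.full(n, np.inf)
    while len(active) > 1:
        k = len(active)
        dt = rng.exponential(scale=2.0 * N / (k * (k - 1)))
        # extend every active branch by dt generations of meioses
        for idx, (leaves, best) in enumerate(active):
            cand = rng.exponential(scale=1.0 / dt) if dt > 0 else np.inf
            active[idx] = (leaves, min(best, cand))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        leaves_j, best_j = active.pop(j)
        leaves_i, best_i = active[i]
        for leaf in leaves_i:
            dist[leaf] = min(dist[leaf], best_i)
        for leaf in leaves_j:
            dist[leaf] = min(dist[leaf], best_j)
        active[i] = (leaves_i + leaves_j, np.inf)
        t += dt
    return dist


def draw_phenotypes(
    carrier_mask: np.ndarray,
    model: PhenotypeModel,
    rng: np.random.Generator,
    sample_ids: Sequence[str] | None = None,
) -> PhenotypeTable:
    """Draw ages, sexes and diagnoses for a cohort.

    AUD follows the logistic model; a second, CNV-independent diagnosis
    flag (``other_psych``, prevalence 0.2) exists so that the derived
    ``any_psych`` outcome differs from AUD alone.
    """
    carrier_mask = np.asarray(carrier_mask, dtype=bool)
    n = carrier_mask.size
    if sample_ids is None:
        sample_ids = [f"S{i + 1:05d}" for i in range(n)]
    logit0 = np.log(model.baseline_prevalence / (1 - model.baseline_prevalence))
    eta = logit0 + np.log(model.carrier_odds_ratio) * carrier_mask
    p = 1.0 / (1.0 + np.exp(-eta))
    aud = rng.random(n) < p
    other = rng.random(n) < 0.2
    age = rng.integers(18, 81, size=n)
    sex = np.where(rng.random(n) < 0.5, "M", "F")
    df = pd.DataFrame(
        {
            "sample_id": list(sample_ids),
            "age": age,
            "sex": sex,
            "aud": aud,
            "other_psych": other,
        }
    )
    return PhenotypeTable(df)


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[PhasedHaplotypeSet, GeneticMap, SimTruth, PhenotypeTable]:
    """Simulate one cohort: phased haplotypes, map, truth and phenotypes.

    Carrier haplotype 0 of the first ``n_carriers`` samples descends from
    the founder: founder alleles from the CNV outward to that side's
    recombination breakpoint, population background beyond.  Deletion
    carriers are hemizygous, so SNPs inside the CNV are missing on the
    carrier haplotype.  Genotyping error flips alleles after descent.
    """
    rng = np.random.default_rng(config.seed)
    gmap = _build_map(config)
    positions = _snp_positions(config, gmap)
    m = positions.size
    n = config.n_samples
    sample_ids = [f"S{i + 1:05d}" for i in range(n)]
    carrier_ids = sample_ids[: config.n_carriers]

    maf = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
    founder = (rng.random(m) < maf).astype(np.int8)
    alleles = (rng.random((2 * n, m)) < maf).astype(np.int8)

    cnv_start, cnv_end = config.cnv_interval
    g_start = float(gmap.genetic_position(cnv_start))
    g_end = float(gmap.genetic_position(cnv_end))
    g_snp = np.asarray(gmap.genetic_position(positions))
    inside = (positions >= cnv_start) & (positions <= cnv_end)

    nc = config.n_carriers
    if config.genealogy == "star":
        d5 = _star_breakpoints(nc, config.tau_true, rng)
        d3 = _star_breakpoints(nc, config.tau_true, rng)
    else:
        d5 = _tree_breakpoints(nc, config.tau_true, rng)
        d3 = _tree_breakpoints(nc, config.tau_true, rng)

    if config.tau_true > 0:
        side_cm = min(g_start - float(gmap.genetic_position(1)),
                      float(gmap.genetic_position(config.region_length)) - g_end)
        if side_cm < 2 * 100.0 / config.tau_true:
            warnings.warn(
                "flanking window is small relative to the expected shared "
                "haplotype at tau_true; consider a wider region",
                stacklevel=2,
            )

    bp5 = np.empty(nc)
    bp3 = np.empty(nc)
    for k in range(nc):
        row = 2 * k  # haplotype 0 of carrier k carries the CNV
        lim5_cm = g_start - 100.0 * d5[k]
        lim3_cm = g_end + 100.0 * d3[k]
        shared = np.zeros(m, dtype=bool)
        shared[(positions < cnv_start) & (g_snp >= lim5_cm)] = True
        shared[(positions > cnv_end) & (g_snp <= lim3_cm)] = True
        alleles[row, shared] = founder[shared]
        alleles[row, inside] = founder[inside]
        bp5[k] = float(np.clip(gmap.physical_position(lim5_cm), 1, cnv_start - 1))
        bp3[k] = float(np.clip(gmap.physical_position(lim3_cm), cnv_end + 1,
                               config.region_length))

    if config.genotyping_error > 0:
        flips = rng.random(alleles.shape) < config.genotyping_error
        valid = alleles != MISSING
        alleles[flips & valid] = 1 - alleles[flips & valid]

    if config.cnv_state == DELETION:
        for k in range(nc):
            alleles[2 * k, inside] = MISSING

    haps = PhasedHaplotypeSet(sample_ids, positions, alleles, config.chrom)
    carrier_mask = np.zeros(n, dtype=bool)
    carrier_mask[:nc] = True
    pheno = draw_phenotypes(carrier_mask, config.phenotype_model, rng, sample_ids)
    truth = SimTruth(
        carrier_ids=carrier_ids,
        tau_true=config.tau_true,
        cnv_interval=config.cnv_interval,
        cnv_state=config.cnv_state,
        chrom=config.chrom,
        founder_haplotype=founder,
        breakpoint_morgans_5=d5,
        breakpoint_morgans_3=d3,
        breakpoint_bp_5=bp5.astype(np.int64),
        breakpoint_bp_3=bp3.astype(np.int64),
    )
    return haps, gmap, truth, pheno


def emit_callsets(
    truth: SimTruth,
    haps: PhasedHaplotypeSet,
    noise: CallerNoise,
    seed: int,
) -> tuple[CallSet, CallSet]:
    """Corrupt the true CNV into two callers' call sets.

    Per carrier and caller: the true endpoints receive independent Gaussian
    jitter snapped to the nearest simulated probe (exact endpoints when the
    jitter SD is 0) and the call is dropped with probability ``fn_rate``.
    Non-carriers gain a spurious call with probability ``fp_rate``.
    ``n_probes`` is the number of simulated probes inside the call.
    """
    rng = np.random.default_rng(seed)
    positions = haps.positions
    cn = 1 if truth.cnv_state == DELETION else 3
    start_true, end_true = truth.cnv_interval
    out: list[list[CNVCall]] = [[], []]
    carrier_set = set(truth.carrier_ids)

    def _snap(x: float) -> int:
        i = int(np.argmin(np.abs(positions - x)))
        return int(positions[i])

    def _n_probes(s: int, e: int) -> int:
        return int(np.count_nonzero((positions >= s) & (positions <= e)))

    for caller_idx, caller in enumerate(("callerA", "callerB")):
        for sid in truth.carrier_ids:
            dropped = rng.random() < noise.fn_rate
            if noise.breakpoint_jitter_sd > 0:
                s = _snap(start_true + rng.normal(0, noise.breakpoint_jitter_sd))
                e = _snap(end_true + rng.normal(0, noise.breakpoint_jitter_sd))
                if s > e:
                    s, e = e, s
            else:
                s, e = start_true, end_true
            if dropped:
                continue
            np_probes = max(1, _n_probes(s, e))
            out[caller_idx].append(
                CNVCall(sid, truth.chrom, s, e, truth.cnv_state, cn, np_probes, caller)
            )
        for i, sid in enumerate(haps.sample_ids):
            if sid in carrier_set:
                continue
            if rng.random() < noise.fp_rate:
                center = int(rng.integers(0, positions.size))
                half = int(rng.integers(5, 26))
                lo = max(0, center - half)
                hi = min(positions.size - 1, center + half)
                fp_cn = int(rng.choice([1, 3]))
                state = DELETION if fp_cn == 1 else DUPLICATION
                out[caller_idx].append(
                    CNVCall(
                        sid,
                        truth.chrom,
                        int(positions[lo]),
                        int(positions[hi]),
                        state,
                        fp_cn,
                        hi - lo + 1,
                        caller,
                    )
                )
    return CallSet(out[0]), CallSet(out[1])
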