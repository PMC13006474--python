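"""KING-robust kinship and kinship-aware carrier association testing.

The KING-robust between-family estimator infers pairwise kinship phi from
SNP genotypes without allele-frequency estimates, making it robust to
population structure:

    phi_ij = (N_Aa,Aa - 2 N_AA,aa) / (N_Aa(i) + N_Aa(j))

over pairwise-complete SNPs, where N_Aa,Aa counts SNPs heterozygous in
both, N_AA,aa opposite homozygotes, and N_Aa(i) heterozygous sites in i.
Duplicates/MZ twins give 0.5, first-degree pairs ~0.25, unrelated ~0.

Carrier-phenotype association is the 2x2 chi-square / Fisher machinery
with Bonferroni adjustment; relatedness is absorbed by adding the leading
kinship eigenvectors as fixed effects to a logistic model — a stated
approximation to a full mixed model with a kinship random effect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

__all__ = [
    "KinshipMatrix",
    "AssociationResult",
    "KinshipComparison",
    "king_kinship",
    "kinship_compare",
    "exclude_relatives",
    "assoc_2x2",
    "expected_carrier_cases",
    "bonferroni_adjust",
    "min_detectable_frequency",
    "kinship_adjusted_assoc",
]

#: standard KING cutoff above which a pair is 2nd-degree or closer
SECOND_DEGREE_PHI = 0.0884


@dataclass
class KinshipMatrix:
    sample_ids: list[str]
    phi: np.ndarray  # symmetric, diag 0.5, NaN where undefined

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        n = len(self.sample_ids)
        if self.phi.shape != (n, n):
            raise ValueError("phi must be n x n")

    def pair(self, a: str, b: str) -> float:
        i, j = self.sample_ids.index(a), self.sample_ids.index(b)
        return float(self.phi[i, j])


@dataclass
class AssociationResult:
    locus_id: str
    table: tuple[int, int, int, int]  # (carrier-case, carrier-ctrl, noncarrier-case, noncarrier-ctrl)
    or_hat: float
    ci95: tuple[float, float]
    p_raw: float
    p_adjusted: float
    test: str
    m_tests: int = 1


@dataclass
class KinshipComparison:
    carrier_pair_phi: np.ndarray
    noncarrier_pair_phi: np.ndarray
    carrier_median: float
    noncarrier_median: float
    p_value: float


# ---------------------------------------------------------------------------
# KING-robust kinship
# ---------------------------------------------------------------------------


def king_kinship(
    genotypes,
    sample_ids: list[str] | None = None,
    maf_min: float = 0.01,
    miss_max: float = 0.1,
) -> KinshipMatrix:
    """KING-robust between-family kinship from a sample x SNP dosage matrix.

    Genotypes are 0/1/2 minor-allele counts with NaN for missing.  SNPs
    with missing rate > ``miss_max`` or MAF < ``maf_min`` are excluded
    first; phi is computed over pairwise-complete SNPs.  A pair in which
    either member has no heterozygous site gets phi = NaN with a warning.
    """
    G = np.asarray(genotypes, dtype=float)
    if G.ndim != 2 or G.shape[0] < 2:
        raise ValueError("need a 2-D matrix with >= 2 samples")
    n = G.shape[0]
    if sample_ids is None:
        sample_ids = [f"S{i + 1:05d}" for i in range(n)]

    valid = ~np.isnan(G)
    miss_rate = 1.0 - valid.mean(axis=0)
    with np.errstate(invalid="ignore"):
        freq = np.nansum(G, axis=0) / (2.0 * np.maximum(valid.sum(axis=0), 1))
    maf = np.minimum(freq, 1.0 - freq)
    keep = (miss_rate <= miss_max) & (maf >= maf_min)
    G = G[:, keep]
    valid = valid[:, keep]
    if G.shape[1] < 1:
        raise ValueError("no SNPs left after MAF/missingness filters")

    het = (G == 1) & valid
    hom0 = (G == 0) & valid
    hom2 = (G == 2) & valid
    H = het.astype(np.float64)
    V = valid.astype(np.float64)
    n_hh = H @ H.T
    n_opp = hom0.astype(np.float64) @ hom2.astype(np.float64).T
    n_opp = n_opp + n_opp.T
    het_i = H @ V.T  # het sites of i that are callable in j
    denom = het_i + het_i.T
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = (n_hh - 2.0 * n_opp) / denom
    phi[denom == 0] = np.nan
    np.fill_diagonal(phi, 0.5)
    off = ~np.eye(n, dtype=bool)
    n_undef = int(np.count_nonzero(denom[off] == 0)) // 2
    if n_undef:
        warnings.warn(
            f"{n_undef} pair(s) with no heterozygous sites in either member: "
            "phi undefined (NaN)",
            stacklevel=2,
        )
    return KinshipMatrix(sample_ids=list(sample_ids), phi=phi)


def kinship_compare(kin: KinshipMatrix, carriers: set[str]) -> KinshipComparison:
    """Carrier-pair vs noncarrier-pair phi distributions with a two-sided
    rank-sum comparison — the "are carriers just one family?" check.

    Caveat: pairs sharing an individual are correlated, so under the null
    the rank-sum p is anti-conservative; treat it as descriptive and read
    the medians/histograms alongside it.
    """
    ids = kin.sample_ids
    is_carr = np.array([s in carriers for s in ids])
    if is_carr.sum() < 2:
        raise ValueError("need >= 2 carriers")
    if (~is_carr).sum() < 2:
        raise ValueError("need >= 2 noncarriers: comparison degenerate")
    iu = np.triu_indices(len(ids), k=1)
    phi = kin.phi[iu]
    both_carr = is_carr[iu[0]] & is_carr[iu[1]]
    both_non = ~is_carr[iu[0]] & ~is_carr[iu[1]]
    cp = phi[both_carr & ~np.isnan(phi)]
    np_ = phi[both_non & ~np.isnan(phi)]
    res = stats.mannwhitneyu(cp, np_, alternative="two-sided")
    return KinshipComparison(
        carrier_pair_phi=cp,
        noncarrier_pair_phi=np_,
        carrier_median=float(np.median(cp)),
        noncarrier_median=float(np.median(np_)),
        p_value=float(res.pvalue),
    )


def exclude_relatives(
    kin: KinshipMatrix,
    phi_threshold: float = SECOND_DEGREE_PHI,
    missingness: dict[str, float] | None = None,
) -> list[str]:
    """Prune to no pair with phi >= threshold (default: 2nd-degree cutoff
    0.0884), dropping the member of each offending pair with the higher
    genotype missingness (ties/unknown: the later sample id)."""
    ids = list(kin.sample_ids)
    phi = kin.phi.copy()
    keep = np.ones(len(ids), dtype=bool)

    def miss(i: int) -> float:
        return missingness.get(ids[i], 0.0) if missingness else 0.0

    while True:
        masked = np.where(np.isnan(phi), -np.inf, phi)
        np.fill_diagonal(masked, -np.inf)
        masked[~keep, :] = -np.inf
        masked[:, ~keep] = -np.inf
        i, j = np.unravel_index(int(np.argmax(masked)), masked.shape)
        if masked[i, j] < phi_threshold:
            break
        drop = (
            i
            if (miss(i), ids[i]) > (miss(j), ids[j])
            else j
        )
        keep[drop] = False
    return [s for s, k in zip(ids, keep) if k]


# ---------------------------------------------------------------------------
# 2x2 association
# ---------------------------------------------------------------------------


def assoc_2x2(
    n_carrier_case: int,
    n_carrier_ctrl: int,
    n_noncarrier_case: int,
    n_noncarrier_ctrl: int,
    locus_id: str = "",
    m_tests: int = 1,
) -> AssociationResult:
    """Carrier x case 2x2 association.

    Pearson chi-square (no continuity correction) when every expected cell
    exceeds 5, Fisher's exact test otherwise; the path taken is recorded in
    ``test``.  The odds ratio uses the Haldane–Anscombe 0.5 correction iff
    any cell is zero; the 95% CI is the Woolf log-OR Wald interval.
    """
    a, b, c, d = (int(x) for x in
                  (n_carrier_case, n_carrier_ctrl, n_noncarrier_case, n_noncarrier_ctrl))
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be >= 0")
    table = np.array([[a, b], [c, d]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero margin in 2x2 table")
    n_tot = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n_tot
    if (expected > 5).all():
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        test = "chi2"
    else:
        _, p = stats.fisher_exact(table, alternative="two-sided")
        test = "fisher"
    cells = np.array([a, b, c, d], dtype=float)
    if (cells == 0).any():
        cells = cells + 0.5
    or_hat = (cells[0] * cells[3]) / (cells[1] * cells[2])
    se = float(np.sqrt(np.sum(1.0 / cells)))
    ci = (float(or_hat * np.exp(-1.96 * se)), float(or_hat * np.exp(1.96 * se)))
    return AssociationResult(
        locus_id=locus_id,
        table=(a, b, c, d),
        or_hat=float(or_hat),
        ci95=ci,
        p_raw=float(p),
        p_adjusted=float(min(1.0, m_tests * p)),
        test=test,
        m_tests=m_tests,
    )


def expected_carrier_cases(n_carriers: int, prevalence: float) -> tuple[float, int]:
    """Expected number of affected carriers under the cohort prevalence:
    n x prevalence, with its nearest-integer rounding."""
    if not 0 <= prevalence <= 1:
        raise ValueError("prevalence must be in [0, 1]")
    expected = n_carriers * prevalence
    return expected, int(round(expected))


def bonferroni_adjust(p_values, m: int | None = None) -> list[float]:
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must be in [0, 1]")
    m_eff = len(p) if m is None else m
    return [float(min(1.0, m_eff * x)) for x in p]


# ---------------------------------------------------------------------------
# Power-based frequency threshold
# ---------------------------------------------------------------------------


def _solve_p0(f: float, case_fraction: float, or_target: float) -> float:
    """Noncarrier case probability p0 such that the cohort-wide case
    fraction is matched given carrier frequency f and carrier OR."""
    lo, hi = 1e-12, 1.0 - 1e-12
    for _ in range(200):
        mid = (lo + hi) / 2.0
        p1 = or_target * mid / (1.0 + (or_target - 1.0) * mid)
        tot = f * p1 + (1.0 - f) * mid
        if tot < case_fraction:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def _wald_power(
    f: float, n: int, case_fraction: float, or_target: float, alpha: float
) -> float:
    p0 = _solve_p0(f, case_fraction, or_target)
    p1 = or_target * p0 / (1.0 + (or_target - 1.0) * p0)
    alt = np.array(
        [n * f * p1, n * f * (1 - p1), n * (1 - f) * p0, n * (1 - f) * (1 - p0)]
    )
    null = np.array(
        [
            n * f * case_fraction,
            n * f * (1 - case_fraction),
            n * (1 - f) * case_fraction,
            n * (1 - f) * (1 - case_fraction),
        ]
    )
    if (alt <= 0).any() or (null <= 0).any():
        return 0.0
    se1 = float(np.sqrt(np.sum(1.0 / alt)))
    se0 = float(np.sqrt(np.sum(1.0 / null)))
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    delta = abs(np.log(or_target))
    return float(
        stats.norm.cdf((delta - z * se0) / se1)
        + stats.norm.cdf((-delta - z * se0) / se1)
    )


def min_detectable_frequency(
    n: int,
    case_fraction: float,
    or_target: float,
    power: float = 0.8,
    alpha: float = 0.05,
) -> float:
    """Smallest carrier frequency at which a two-sided Wald test on the
    log odds ratio reaches the target power.

    Uses the standard two-variance Wald power approximation
    power = Phi((|log OR| - z_{1-alpha/2} SE0) / SE1) with SE0 from
    null-expected and SE1 from alternative-expected cell counts, solved
    for f by bisection to 1e-4.
    """
    if or_target <= 1:
        raise ValueError("or_target must be > 1")
    if not 0 < power < 1:
        raise ValueError("power must be in (0, 1)")
    grid = np.linspace(1e-4, 0.95, 400)
    powers = [ _wald_power(f, n, case_fraction, or_target, alpha) for f in grid ]
    above = [i for i, pw in enumerate(powers) if pw >= power]
    if not above:
        raise ValueError("target power unattainable at any carrier frequency <= 1")
    i = above[0]
    lo = grid[i - 1] if i > 0 else 1e-6
    hi = grid[i]
    while hi - lo > 1e-4:
        mid = (lo + hi) / 2.0
        if _wald_power(mid, n, case_fraction, or_target, alpha) >= power:
            hi = mid
        else:
            lo = mid
    return float(hi)


# ---------------------------------------------------------------------------
# Kinship-adjusted logistic association
# ---------------------------------------------------------------------------


def _kinship_eigenvectors(kin: KinshipMatrix, var_target: float = 0.8, k_max: int = 10):
    """Leading eigenvectors of the off-diagonal kinship structure.

    Eigen-decomposes phi with a zeroed diagonal (NaN -> 0); since
    sum(lambda^2) equals the off-diagonal Frobenius mass exactly, vectors
    are added by decreasing lambda^2 until >= ``var_target`` of that mass
    is captured (at most ``k_max``).  Zero off-diagonal mass -> no
    adjustment, so an unrelated cohort reduces to plain logistic
    regression.
    """
    K = np.where(np.isnan(kin.phi), 0.0, kin.phi).copy()
    np.fill_diagonal(K, 0.0)
    total = float(np.sum(K**2))
    if total < 1e-12:
        return np.empty((K.shape[0], 0))
    vals, vecs = np.linalg.eigh(K)
    order = np.argsort(vals**2)[::-1]
    cum = np.cumsum(vals[order] ** 2) / total
    k = int(np.searchsorted(cum, var_target) + 1)
    k = min(k, k_max, K.shape[0])
    return vecs[:, order[:k]]


def _firth_logit(X: np.ndarray, y: np.ndarray, max_iter: int = 100, tol: float = 1e-10):
    """Firth-penalised logistic regression (Jeffreys prior), for separated
    tables where plain maximum likelihood diverges."""
    n, p = X.shape
    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        W = mu * (1 - mu)
        XW = X * W[:, None]
        info = X.T @ XW
        info_inv = np.linalg.pinv(info)
        sqw = np.sqrt(W)
        H = (sqw[:, None] * X) @ info_inv @ (X * sqw[:, None]).T
        h = np.diag(H)
        score = X.T @ (y - mu + h * (0.5 - mu))
        step = info_inv @ score
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    eta = X @ beta
    mu = expit(eta)
    W = mu * (1 - mu)
    info_inv = np.linalg.pinv(X.T @ (X * W[:, None]))
    se = np.sqrt(np.diag(info_inv))
    return beta, se


def kinship_adjusted_assoc(
    phenotype,
    carrier,
    covariates: pd.DataFrame,
    kin: KinshipMatrix,
    locus_id: str = "",
    m_tests: int = 1,
) -> AssociationResult:
    """Logistic regression of a binary phenotype on carrier status with age,
    sex and the leading kinship eigenvectors as fixed effects — an
    approximation to a mixed model with kinship as a random effect.

    ``covariates`` needs ``age`` and ``sex`` ('M'/'F') columns aligned with
    ``kin.sample_ids``.  Perfect separation falls back to Firth-penalised
    estimation, flagged in ``test``.
    """
    import statsmodels.api as sm

    y = np.asarray(phenotype, dtype=float)
    carr = np.asarray(carrier, dtype=float)
    if np.ptp(carr) == 0:
        raise ValueError("carrier indicator is constant: no variation to test")
    if len(y) != len(kin.sample_ids) or len(carr) != len(y):
        raise ValueError("phenotype/carrier/kinship dimensions disagree")
    age = covariates["age"].to_numpy(dtype=float)
    sex = (covariates["sex"].astype(str) == "M").to_numpy(dtype=float)
    if np.isnan(age).any():
        raise ValueError("covariates must be complete")
    evs = _kinship_eigenvectors(kin)
    X = np.column_stack([np.ones_like(y), carr, age, sex, evs])

    beta = se = None
    test = "kinship_adjusted"
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        beta, se = fit.params, fit.bse
        if not np.all(np.isfinite(se)) or np.abs(beta[1]) > 15:
            raise RuntimeError("separation suspected")
    except Exception:
        beta, se = _firth_logit(X, y)
        test = "kinship_adjusted_firth"

    b, s = float(beta[1]), float(se[1])
    or_hat = float(np.exp(b))
    ci = (float(np.exp(b - 1.96 * s)), float(np.exp(b + 1.96 * s)))
    z = b / s if s > 0 else np.inf
    p = float(2.0 * stats.norm.sf(abs(z)))
    a_cell = int(np.sum((carr == 1) & (y == 1)))
    b_cell = int(np.sum((carr == 1) & (y == 0)))
    c_cell = int(np.sum((carr == 0) & (y == 1)))
    d_cell = int(np.sum((carr == 0) & (y == 0)))
    return AssociationResult(
        locus_id=locus_id,
        table=(a_cell, b_cell, c_cell, d_cell),
        or_hat=or_hat,
        ci95=ci,
        p_raw=p,
        p_adjusted=float(min(1.0, m_tests * p)),
        test=test,
        m_tests=m_tests,
    )
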