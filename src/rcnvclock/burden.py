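"""Per-individual CNV burden and nonparametric case-control comparison.

Burden is measured two ways: the number of consensus CNV events a person
carries, and the gene load — the number of distinct genes whose copy
number any of their CNVs alters (full or partial overlap, each gene
counted once per person).  Case-control comparisons are unadjusted
Mann-Whitney tests and labelled exploratory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import CallSet

__all__ = ["BurdenResult", "burden_metrics", "burden_test"]


@dataclass
class MetricComparison:
    metric: str
    case_mean: float
    case_sd: float
    control_mean: float
    control_sd: float
    u_statistic: float
    p_value: float

    def formatted(self) -> str:
        """'mean ± SD' presentation for tables."""
        return (
            f"{self.metric}: cases {self.case_mean:.2f} ± {self.case_sd:.2f}, "
            f"controls {self.control_mean:.2f} ± {self.control_sd:.2f} "
            f"(U={self.u_statistic:.1f}, p={self.p_value:.3g})"
        )


@dataclass
class BurdenResult:
    per_sample: pd.DataFrame  # sample_id, cnv_count, gene_load
    comparisons: dict[str, MetricComparison]
    note: str = "exploratory: unadjusted for age, sex or ancestry"


def burden_metrics(
    calls: CallSet, genes: pd.DataFrame, sample_ids: list[str] | None = None
) -> pd.DataFrame:
    """Per-sample CNV count and gene load.

    ``genes`` holds 1-based inclusive chrom/start/end/name intervals.
    ``sample_ids`` fixes the roster so samples without calls appear with
    zeros (the "no gene altered" class must be representable).
    """
    by_sample = calls.by_sample()
    roster = list(sample_ids) if sample_ids is not None else sorted(by_sample)
    gchrom = genes["chrom"].astype(str).to_numpy()
    gstart = genes["start"].to_numpy()
    gend = genes["end"].to_numpy()
    gname = genes["name"].to_numpy()
    rows = []
    for sid in roster:
        sample_calls = by_sample.get(sid, [])
        hit: set[str] = set()
        for c in sample_calls:
            sel = (gchrom == c.chrom) & (gstart <= c.end) & (gend >= c.start)
            hit.update(gname[sel])
        rows.append((sid, len(sample_calls), len(hit)))
    return pd.DataFrame(rows, columns=["sample_id", "cnv_count", "gene_load"])


def _mann_whitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact for both group sizes <= 8 (no ties), tie-corrected normal
    approximation otherwise."""
    pooled = np.concatenate([x, y])
    ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size <= 8 and y.size <= 8 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def burden_test(metrics: pd.DataFrame, phenotype) -> BurdenResult:
    """Two-sided Mann-Whitney comparison of each burden metric between
    cases (phenotype True) and controls."""
    pheno = np.asarray(phenotype, dtype=bool)
    if pheno.size != len(metrics):
        raise ValueError("phenotype length must match metrics rows")
    if not pheno.any() or pheno.all():
        raise ValueError("both groups must be non-empty")
    comparisons = {}
    for metric in ("cnv_count", "gene_load"):
        vals = metrics[metric].to_numpy(dtype=float)
        x, y = vals[pheno], vals[~pheno]
        u, p = _mann_whitney(x, y)
        comparisons[metric] = MetricComparison(
            metric=metric,
            case_mean=float(x.mean()),
            case_sd=float(x.std(ddof=1)) if x.size > 1 else 0.0,
            control_mean=float(y.mean()),
            control_sd=float(y.std(ddof=1)) if y.size > 1 else 0.0,
            u_statistic=u,
            p_value=p,
        )
    return BurdenResult(per_sample=metrics.copy(), comparisons=comparisons)
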