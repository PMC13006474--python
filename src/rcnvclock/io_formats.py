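"""Readers, writers and domain containers for CNV pipelines.

All genomic coordinates are 1-based inclusive base pairs internally; BED
output converts to 0-based half-open at the boundary only.  Genetic map
positions are centimorgans at interfaces; age arithmetic downstream works
in Morgans (1 M = 100 cM).
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("rcnvclock")

DELETION = "deletion"
DUPLICATION = "duplication"

#: copy numbers accepted for autosomal CNV calls; 2 is the diploid reference
#: state and is not a CNV.
_VALID_CN = {0, 1, 3, 4}

MISSING = np.int8(-1)


def state_from_copy_number(cn: int) -> str:
    if cn < 2:
        return DELETION
    if cn > 2:
        return DUPLICATION
    raise ValueError(f"copy number {cn} is the diploid state, not a CNV")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CNVCall:
    """One caller's copy-number segment for one sample (1-based inclusive)."""

    sample_id: str
    chrom: str
    start: int
    end: int
    state: str
    copy_number: int
    n_probes: int
    caller: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")
        if self.n_probes < 1:
            raise ValueError("n_probes must be >= 1")
        if self.copy_number not in _VALID_CN:
            raise ValueError(f"unknown copy-number state {self.copy_number}")
        if state_from_copy_number(self.copy_number) != self.state:
            raise ValueError(
                f"state {self.state!r} inconsistent with copy number "
                f"{self.copy_number}"
            )

    @property
    def size(self) -> int:
        """Segment size in bp (inclusive coordinates)."""
        return self.end - self.start + 1


class CallSet:
    """A collection of CNV calls with per-sample access."""

    def __init__(self, calls: Iterable[CNVCall] = ()):  # noqa: D107
        self.calls: list[CNVCall] = list(calls)

    def __len__(self) -> int:
        return len(self.calls)

    def __iter__(self) -> Iterator[CNVCall]:
        return iter(self.calls)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CallSet):
            return NotImplemented
        return sorted(self.calls, key=_call_key) == sorted(other.calls, key=_call_key)

    @property
    def samples(self) -> list[str]:
        return sorted({c.sample_id for c in self.calls})

    def by_sample(self) -> dict[str, list[CNVCall]]:
        out: dict[str, list[CNVCall]] = {}
        for c in sorted(self.calls, key=_call_key):
            out.setdefault(c.sample_id, []).append(c)
        return out

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (c.sample_id, c.chrom, c.start, c.end, c.copy_number, c.n_probes, c.caller)
                for c in self.calls
            ],
            columns=["sample_id", "chrom", "start", "end", "cn", "n_probes", "caller"],
        )


def _call_key(c: CNVCall) -> tuple:
    return (c.sample_id, c.chrom, c.start, c.end, c.caller, c.copy_number)


@dataclass
class GeneticMap:
    """Physical → genetic coordinate map for one chromosome.

    ``positions`` are bp (1-based, strictly increasing) and ``cm`` the
    cumulative genetic position in centimorgans (non-decreasing).
    Interpolation between knots is piecewise linear; beyond the terminal
    knots the terminal interval's rate is extrapolated.
    """

    chrom: str
    positions: np.ndarray
    cm: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.cm = np.asarray(self.cm, dtype=float)
        if self.positions.size < 2:
            raise ValueError("genetic map needs >= 2 knots per chromosome")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("map positions must be strictly increasing")
        if np.any(np.diff(self.cm) < 0):
            raise ValueError("genetic positions must be non-decreasing")

    def genetic_position(self, bp) -> np.ndarray | float:
        """Genetic position (cM) of physical position(s), extrapolating
        beyond the outermost knots at the terminal interval's rate."""
        bp_arr = np.asarray(bp, dtype=float)
        pos = self.positions.astype(float)
        out = np.interp(bp_arr, pos, self.cm)
        lo_rate = (self.cm[1] - self.cm[0]) / (pos[1] - pos[0])
        hi_rate = (self.cm[-1] - self.cm[-2]) / (pos[-1] - pos[-2])
        out = np.where(bp_arr < pos[0], self.cm[0] + (bp_arr - pos[0]) * lo_rate, out)
        out = np.where(bp_arr > pos[-1], self.cm[-1] + (bp_arr - pos[-1]) * hi_rate, out)
        return float(out) if np.isscalar(bp) or out.ndim == 0 else out

    def physical_position(self, cm) -> np.ndarray | float:
        """Inverse lookup: bp at a genetic position (requires a strictly
        increasing map; plateaus return the leftmost bp of the plateau)."""
        cm_arr = np.asarray(cm, dtype=float)
        out = np.interp(cm_arr, self.cm, self.positions.astype(float))
        if self.cm[-1] > self.cm[0]:
            hi_rate = (self.cm[-1] - self.cm[-2]) / float(
                self.positions[-1] - self.positions[-2]
            )
            if hi_rate > 0:
                over = cm_arr > self.cm[-1]
                out = np.where(
                    over, self.positions[-1] + (cm_arr - self.cm[-1]) / hi_rate, out
                )
        return float(out) if np.isscalar(cm) or out.ndim == 0 else out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneticMap):
            return NotImplemented
        return (
            self.chrom == other.chrom
            and np.array_equal(self.positions, other.positions)
            and np.allclose(self.cm, other.cm)
        )


class PhasedHaplotypeSet:
    """Phased biallelic SNP haplotypes: two rows per sample.

    ``alleles`` is an int8 matrix of shape (2 * n_samples, n_snps) holding
    0/1 allele codes with -1 for missing.  Row ``2*i`` and ``2*i + 1`` are
    the two haplotypes of ``sample_ids[i]``.
    """

    def __init__(self, sample_ids: Sequence[str], positions, alleles, chrom: str = "1"):
        self.sample_ids = list(sample_ids)
        self.positions = np.asarray(positions, dtype=np.int64)
        self.alleles = np.asarray(alleles, dtype=np.int8)
        self.chrom = chrom
        if self.alleles.shape != (2 * len(self.sample_ids), self.positions.size):
            raise ValueError("alleles must be (2*n_samples, n_snps)")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("SNP positions must be sorted and deduplicated")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return int(self.positions.size)

    def haplotype(self, sample_id: str, which: int) -> np.ndarray:
        i = self.sample_ids.index(sample_id)
        return self.alleles[2 * i + which]

    def hap_labels(self) -> list[str]:
        return [f"{s}|{h}" for s in self.sample_ids for h in (0, 1)]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PhasedHaplotypeSet):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.chrom == other.chrom
            and np.array_equal(self.positions, other.positions)
            and np.array_equal(self.alleles, other.alleles)
        )


class PhenotypeTable:
    """Sample phenotypes: age, sex, AUD and further binary diagnoses.

    ``any_psych`` is always derived as the OR over all diagnosis flags
    (including AUD), never stored.
    """

    def __init__(self, df: pd.DataFrame):
        required = {"sample_id", "age", "sex", "aud"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
        if df["sample_id"].duplicated().any():
            dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValueError(f"duplicate sample ids: {dupes}")
        bad_sex = set(df["sex"]) - {"M", "F"}
        if bad_sex:
            raise ValueError(f"sex must be M or F, got {sorted(bad_sex)}")
        self.df = df.reset_index(drop=True).copy()
        for col in self.diagnosis_columns:
            self.df[col] = self.df[col].astype(bool)

    @property
    def diagnosis_columns(self) -> list[str]:
        return [c for c in self.df.columns if c not in ("sample_id", "age", "sex")]

    @property
    def any_psych(self) -> pd.Series:
        return self.df[self.diagnosis_columns].any(axis=1)

    @property
    def sample_ids(self) -> list[str]:
        return self.df["sample_id"].tolist()

    def outcome(self, name: str) -> pd.Series:
        """Binary outcome vector by name; ``any_psych`` is computed on the fly."""
        if name == "any_psych":
            return self.any_psych
        return self.df[name].astype(bool)

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PhenotypeTable):
            return NotImplemented
        return self.df.sort_values("sample_id").reset_index(drop=True).equals(
            other.df.sort_values("sample_id").reset_index(drop=True)
        )


# ---------------------------------------------------------------------------
# CNV call I/O
# ---------------------------------------------------------------------------

_PENNCNV_REGION = re.compile(r"^(?P<chrom>[\w.]+):(?P<start>\d+)-(?P<end>\d+)$")


def read_cnv_calls(path, dialect: str) -> CallSet:
    """Read CNV calls from ``penncnv_raw`` or ``bed_tsv`` (TSV) files.

    Both dialects are normalised to 1-based inclusive coordinates.  Rows
    that cannot be parsed raise with their line numbers; duplicate
    (sample, caller, interval) records are dropped with a warning.
    """
    if dialect == "bed_tsv":
        calls = _read_calls_tsv(path)
    elif dialect == "penncnv_raw":
        calls = _read_calls_penncnv(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return _dedup_calls(calls)


def _dedup_calls(calls: list[CNVCall]) -> CallSet:
    seen: dict[tuple, CNVCall] = {}
    dropped = 0
    for c in calls:
        key = (c.sample_id, c.caller, c.chrom, c.start, c.end)
        if key in seen:
            dropped += 1
        else:
            seen[key] = c
    if dropped:
        warnings.warn(
            f"dropped {dropped} duplicate (sample, caller, interval) record(s)",
            stacklevel=3,
        )
    return CallSet(seen.values())


def _read_calls_tsv(path) -> list[CNVCall]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "chrom": str})
    required = ["sample_id", "chrom", "start", "end", "cn", "n_probes", "caller"]
    missing = set(required) - set(df.columns)
    if missing:
        raise ValueError(f"call TSV missing columns: {sorted(missing)}")
    calls, bad = [], []
    for line_no, row in enumerate(df.itertuples(index=False), start=2):
        try:
            cn = int(row.cn)
            calls.append(
                CNVCall(
                    sample_id=str(row.sample_id),
                    chrom=str(row.chrom),
                    start=int(row.start),
                    end=int(row.end),
                    state=state_from_copy_number(cn),
                    copy_number=cn,
                    n_probes=int(row.n_probes),
                    caller=str(row.caller) if not pd.isna(row.caller) else "",
                )
            )
        except (ValueError, TypeError) as exc:
            bad.append((line_no, str(exc)))
    if bad:
        detail = "; ".join(f"line {n}: {msg}" for n, msg in bad[:5])
        raise ValueError(f"{len(bad)} malformed call row(s): {detail}")
    return calls


def _read_calls_penncnv(path) -> list[CNVCall]:
    """PennCNV .rawcnv-style lines:
    ``chr6:31355318-31451476 numsnp=40 length=96,159 state2,cn=1 sampleA ...``
    """
    calls, bad = [], []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                calls.append(_parse_penncnv_line(line))
            except ValueError as exc:
                bad.append((line_no, str(exc)))
    if bad:
        detail = "; ".join(f"line {n}: {msg}" for n, msg in bad[:5])
        raise ValueError(f"{len(bad)} malformed PennCNV row(s): {detail}")
    return calls


def _parse_penncnv_line(line: str) -> CNVCall:
    tokens = line.split()
    m = _PENNCNV_REGION.match(tokens[0])
    if not m:
        raise ValueError(f"cannot parse region token {tokens[0]!r}")
    numsnp = cn = None
    sample = None
    for tok in tokens[1:]:
        if tok.startswith("numsnp="):
            numsnp = int(tok.split("=", 1)[1])
        elif "cn=" in tok:  # bare "cn=1" or PennCNV's "state2,cn=1"
            cn = int(tok.rsplit("cn=", 1)[1])
        elif "=" not in tok and sample is None:
            sample = tok
    if numsnp is None or cn is None or sample is None:
        raise ValueError(f"missing numsnp/cn/sample in {line!r}")
    chrom = m["chrom"].removeprefix("chr")
    return CNVCall(
        sample_id=sample,
        chrom=chrom,
        start=int(m["start"]),
        end=int(m["end"]),
        state=state_from_copy_number(cn),
        copy_number=cn,
        n_probes=numsnp,
        caller="penncnv",
    )


def write_cnv_calls(calls: CallSet, path) -> None:
    """Write the TSV call dialect (1-based inclusive)."""
    df = calls.to_dataframe().sort_values(
        ["sample_id", "chrom", "start", "end", "caller"]
    )
    df.to_csv(path, sep="\t", index=False)


def write_bed(calls: CallSet, path) -> None:
    """Export calls as BED (0-based half-open) — the only place the
    internal 1-based inclusive convention is converted."""
    with open(path, "w") as fh:
        for c in sorted(calls, key=_call_key):
            name = f"{c.sample_id}:{c.state}:cn{c.copy_number}"
            fh.write(f"{c.chrom}\t{c.start - 1}\t{c.end}\t{name}\n")


# ---------------------------------------------------------------------------
# Genetic map I/O
# ---------------------------------------------------------------------------


def read_genetic_map(path) -> GeneticMap:
    """Read a PLINK-style 3-column (chrom, bp, cM) map for one chromosome.

    Rows are sorted by bp; a cM column that decreases after sorting is a
    hard error naming the offending row.
    """
    df = pd.read_csv(path, sep=r"\s+", header=None, names=["chrom", "bp", "cm"],
                     dtype={"chrom": str}, comment="#")
    if df.empty:
        raise ValueError("empty genetic map")
    chroms = df["chrom"].unique()
    if len(chroms) > 1:
        raise ValueError(f"one chromosome per map file, got {list(chroms)}")
    df = df.sort_values("bp").reset_index(drop=True)
    cm = df["cm"].to_numpy(float)
    dec = np.nonzero(np.diff(cm) < 0)[0]
    if dec.size:
        i = int(dec[0]) + 1
        raise ValueError(
            f"genetic position decreases at bp {int(df['bp'][i])} "
            f"(row {i + 1} after sorting): {cm[i]} < {cm[i - 1]}"
        )
    return GeneticMap(chrom=str(chroms[0]), positions=df["bp"].to_numpy(np.int64), cm=cm)


def write_genetic_map(gmap: GeneticMap, path) -> None:
    pd.DataFrame(
        {"chrom": gmap.chrom, "bp": gmap.positions, "cm": gmap.cm}
    ).to_csv(path, sep="\t", index=False, header=False)


# ---------------------------------------------------------------------------
# Phased haplotype I/O
# ---------------------------------------------------------------------------


def read_phased_haplotypes(path, dialect: str) -> PhasedHaplotypeSet:
    """Read phased biallelic haplotypes from ``hap_tsv`` or ``phased_vcf``.

    phased_vcf: any unphased genotype is an error naming sample and site;
    multiallelic sites are skipped with a warning.
    """
    if dialect == "hap_tsv":
        return _read_hap_tsv(path)
    if dialect == "phased_vcf":
        return _read_phased_vcf(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_hap_tsv(path) -> PhasedHaplotypeSet:
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "hap_id":
        raise ValueError("hap_tsv must start with a hap_id column")
    chrom = "1"
    cols = list(df.columns[1:])
    if cols and ":" in cols[0]:
        chrom = cols[0].split(":", 1)[0]
        positions = np.array([int(c.split(":", 1)[1]) for c in cols], dtype=np.int64)
    else:
        positions = np.array([int(c) for c in cols], dtype=np.int64)
    order = np.argsort(positions, kind="stable")
    keep = np.concatenate([[True], np.diff(positions[order]) > 0])
    order = order[keep]
    sample_ids: list[str] = []
    for hap_id in df["hap_id"]:
        sid = str(hap_id).rsplit("|", 1)[0]
        if sid not in sample_ids:
            sample_ids.append(sid)
    mat = df.iloc[:, 1:].to_numpy()
    alleles = np.full(mat.shape, MISSING, dtype=np.int8)
    for v, code in ((0, 0), (1, 1)):
        alleles[mat == v] = code
    if 2 * len(sample_ids) != alleles.shape[0]:
        raise ValueError("expected exactly two haplotype rows per sample")
    return PhasedHaplotypeSet(sample_ids, positions[order], alleles[:, order], chrom)


def _read_phased_vcf(path) -> PhasedHaplotypeSet:
    import pysam

    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        positions, rows, chrom = [], [], None
        n_multi = 0
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                n_multi += 1
                continue
            chrom = rec.chrom if chrom is None else chrom
            col = np.full(2 * len(samples), MISSING, dtype=np.int8)
            for i, s in enumerate(samples):
                sgt = rec.samples[s]
                gt = sgt["GT"]
                if gt is None or len(gt) != 2:
                    raise ValueError(f"sample {s} at {rec.chrom}:{rec.pos} lacks a diploid GT")
                if not sgt.phased and not all(a is None for a in gt):
                    raise ValueError(
                        f"unphased genotype for sample {s} at {rec.chrom}:{rec.pos}"
                    )
                for h in (0, 1):
                    if gt[h] is not None:
                        col[2 * i + h] = gt[h]
            positions.append(rec.pos)
            rows.append(col)
    if n_multi:
        warnings.warn(f"skipped {n_multi} multiallelic site(s)", stacklevel=2)
    if not positions:
        raise ValueError("no biallelic phased sites in VCF")
    pos = np.asarray(positions, dtype=np.int64)
    alleles = np.stack(rows, axis=1)
    order = np.argsort(pos, kind="stable")
    keep = np.concatenate([[True], np.diff(pos[order]) > 0])
    order = order[keep]
    return PhasedHaplotypeSet(samples, pos[order], alleles[:, order], chrom or "1")


def write_hap_tsv(haps: PhasedHaplotypeSet, path) -> None:
    cols = [f"{haps.chrom}:{p}" for p in haps.positions]
    df = pd.DataFrame(haps.alleles, columns=cols)
    df.insert(0, "hap_id", haps.hap_labels())
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Genes, phenotypes
# ---------------------------------------------------------------------------


def read_gene_bed(path) -> pd.DataFrame:
    """Gene intervals from BED (0-based half-open) → 1-based inclusive frame
    with columns chrom, start, end, name.  Zero-length records are rejected."""
    rows = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"line {line_no}: BED needs >= 3 columns")
            chrom, start0, end0 = parts[0], int(parts[1]), int(parts[2])
            if end0 <= start0:
                raise ValueError(f"line {line_no}: zero-length gene interval")
            name = parts[3] if len(parts) > 3 else f"gene_{line_no}"
            rows.append((chrom.removeprefix("chr"), start0 + 1, end0, name))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def read_phenotypes(path) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "sex": str})
    return PhenotypeTable(df)


def write_phenotypes(pheno: PhenotypeTable, path) -> None:
    df = pheno.df.copy()
    for col in pheno.diagnosis_columns:
        df[col] = df[col].astype(int)
    df.to_csv(path, sep="\t", index=False)
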