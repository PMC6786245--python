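"""Phased SNP panels, genotype matrices, and the text formats around them.

The central container is :class:`HaplotypePanel`: a (2·n_samples × L) matrix
of 0/1 alleles over mapped biallelic SNPs, with per-sample population labels.
Haplotype statistics (EHH, iHS, XP-EHH) operate on panels; genotype-level
summaries and QC operate on the derived :class:`GenotypeMatrix` whose dosages
are the per-sample sums of the two haplotype rows.

Coordinates are 1-based inclusive internally (VCF convention); BED output is
0-based half-open.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class PanelError(ValueError):
    """Raised for malformed panels or unreadable inputs."""


@dataclass(frozen=True)
class SiteInfo:
    """One biallelic SNP: chromosome, 1-based position, id, and allele labels.

    ``allele1`` is the VCF ALT allele; panel entries code 0 = REF, 1 = ALT.
    """

    chrom: str
    pos: int
    site_id: str
    allele0: str = "A"
    allele1: str = "G"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise PanelError(f"site {self.site_id}: pos must be >= 1, got {self.pos}")


@dataclass
class HaplotypePanel:
    """Phased 0/1 allele matrix of shape (2·n_samples, L).

    Haplotype rows 2k and 2k+1 belong to sample k. No missing data: panels
    represent post-phasing input. Sites must be strictly increasing in
    position within each chromosome.
    """

    alleles: np.ndarray
    samples: list[str]
    sample_pop: dict[str, str]
    sites: list[SiteInfo]

    def __post_init__(self) -> None:
        self.alleles = np.ascontiguousarray(self.alleles, dtype=np.uint8)
        if self.alleles.ndim != 2:
            raise PanelError("alleles must be a 2-D matrix")
        if self.alleles.shape[0] != 2 * len(self.samples):
            raise PanelError(
                f"{self.alleles.shape[0]} haplotypes for {len(self.samples)} samples"
                " (need exactly 2 per sample)"
            )
        if self.alleles.shape[1] != len(self.sites):
            raise PanelError("allele matrix width != number of sites")
        if self.alleles.size and self.alleles.max() > 1:
            raise PanelError("panel entries must be 0/1")
        missing = [s for s in self.samples if s not in self.sample_pop]
        if missing:
            raise PanelError(f"samples without population label: {missing[:5]}")
        if len(set(self.samples)) != len(self.samples):
            raise PanelError("duplicated sample ids")
        _check_sorted_sites(self.sites)

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    @property
    def positions(self) -> np.ndarray:
        return np.asarray([s.pos for s in self.sites], dtype=np.int64)

    @property
    def chroms(self) -> np.ndarray:
        return np.asarray([s.chrom for s in self.sites])

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(self.sample_pop[s], None)
        return list(seen)

    def haplotype_rows(self, pop: str | None = None) -> np.ndarray:
        """Row indices of the haplotypes belonging to ``pop`` (all if None)."""
        if pop is None:
            return np.arange(self.n_haplotypes)
        idx = [i for i, s in enumerate(self.samples) if self.sample_pop[s] == pop]
        if not idx:
            raise PanelError(f"unknown population {pop!r}")
        return np.asarray([2 * i + k for i in idx for k in (0, 1)], dtype=np.int64)

    def subset_sites(self, keep: np.ndarray) -> "HaplotypePanel":
        keep = np.asarray(keep)
        return HaplotypePanel(
            alleles=self.alleles[:, keep],
            samples=list(self.samples),
            sample_pop=dict(self.sample_pop),
            sites=[self.sites[int(i)] for i in keep],
        )

    def to_genotype_matrix(self) -> "GenotypeMatrix":
        dosage = (
            self.alleles[0::2, :].astype(np.float64)
            + self.alleles[1::2, :].astype(np.float64)
        )
        return GenotypeMatrix(
            dosage=dosage,
            samples=list(self.samples),
            sample_pop=dict(self.sample_pop),
            sites=list(self.sites),
        )


@dataclass
class GenotypeMatrix:
    """Per-sample ALT-dosage matrix (n_samples × L); NaN encodes missing."""

    dosage: np.ndarray
    samples: list[str]
    sample_pop: dict[str, str]
    sites: list[SiteInfo]

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.float64)
        if self.dosage.shape != (len(self.samples), len(self.sites)):
            raise PanelError("dosage shape mismatch")
        finite = self.dosage[np.isfinite(self.dosage)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            raise PanelError("dosages must lie in {0,1,2} or NaN")

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_sites(self) -> int:
        return self.dosage.shape[1]

    @property
    def positions(self) -> np.ndarray:
        return np.asarray([s.pos for s in self.sites], dtype=np.int64)

    @property
    def chroms(self) -> np.ndarray:
        return np.asarray([s.chrom for s in self.sites])

    def sample_rows(self, pop: str) -> np.ndarray:
        idx = [i for i, s in enumerate(self.samples) if self.sample_pop[s] == pop]
        if not idx:
            raise PanelError(f"unknown population {pop!r}")
        return np.asarray(idx, dtype=np.int64)

    def subset_sites(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        return GenotypeMatrix(
            dosage=self.dosage[:, keep],
            samples=list(self.samples),
            sample_pop=dict(self.sample_pop),
            sites=[self.sites[int(i)] for i in keep],
        )

    def subset_samples(self, keep: Sequence[int]) -> "GenotypeMatrix":
        keep = list(keep)
        samples = [self.samples[i] for i in keep]
        return GenotypeMatrix(
            dosage=self.dosage[keep, :],
            samples=samples,
            sample_pop={s: self.sample_pop[s] for s in samples},
            sites=list(self.sites),
        )


#: column order of the per-site scan table written by :func:`write_scan_table`
SCAN_COLUMNS = ["chrom", "pos", "site_id", "raw", "standardized", "neglog10_p", "valid", "reason"]


@dataclass
class ScanResult:
    """Per-SNP scores for one selection test in one population (or pair).

    ``table`` has the columns of :data:`SCAN_COLUMNS`. For the F_ST-outlier
    test, ``raw`` holds the posterior odds and ``standardized`` the posterior
    mean locus effect alpha; for iHS/XP-EHH they hold the unstandardized and
    standardized scores. Invalid sites carry NaN scores and a reason code.
    """

    test: str
    population: str
    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SCAN_COLUMNS if c not in self.table.columns]
        if missing:
            raise PanelError(f"scan table missing columns {missing}")
        ok = self.table["valid"].astype(bool)
        neg = self.table.loc[ok, "neglog10_p"]
        if len(neg) and (neg < 0).any():
            raise PanelError("neglog10_p must be >= 0 on valid sites")


@dataclass(frozen=True)
class Region:
    """Candidate selected interval bounded by its outermost significant SNPs."""

    population: str
    test: str
    chrom: str
    start: int
    end: int
    n_sig_snps: int
    peak_score: float
    peak_neglog10p: float
    size_kb: float

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise PanelError(f"region end {self.end} < start {self.start}")
        if self.n_sig_snps < 2:
            raise PanelError("regions require at least 2 significant SNPs")


def _check_sorted_sites(sites: Sequence[SiteInfo]) -> None:
    prev: dict[str, int] = {}
    last_chrom = None
    seen_chroms = set()
    for s in sites:
        if s.chrom != last_chrom:
            if s.chrom in seen_chroms:
                raise PanelError(f"chromosome {s.chrom} appears in two blocks")
            seen_chroms.add(s.chrom)
            last_chrom = s.chrom
        if s.chrom in prev and s.pos <= prev[s.chrom]:
            raise PanelError(
                f"sites not strictly increasing on {s.chrom} at pos {s.pos}"
            )
        prev[s.chrom] = s.pos


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

_SNP_ALLELES = frozenset("ACGT")


def read_phased_vcf(path: str) -> tuple[HaplotypePanel, dict[str, int]]:
    """Read a phased diploid VCF into a panel, skipping unusable records.

    Returns ``(panel, skip_report)`` where the report counts records skipped
    as ``multiallelic``, ``non_snp``, ``unphased`` (covers missing or
    non-diploid GT too) and ``duplicate_pos``. Raises :class:`PanelError` if
    no record survives or sample ids are duplicated.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if len(set(samples)) != len(samples):
        raise PanelError("duplicated sample ids in VCF header")

    skip = {"multiallelic": 0, "non_snp": 0, "unphased": 0, "duplicate_pos": 0}
    columns: list[np.ndarray] = []
    sites: list[SiteInfo] = []
    last_pos: dict[str, int] = {}
    for v in vcf:
        if len(v.ALT) != 1:
            skip["multiallelic"] += 1
            continue
        ref, alt = v.REF.upper(), v.ALT[0].upper()
        if len(ref) != 1 or len(alt) != 1 or ref not in _SNP_ALLELES or alt not in _SNP_ALLELES:
            skip["non_snp"] += 1
            continue
        gts = v.genotypes  # [[a, b, phased], ...]
        col = np.empty(2 * len(samples), dtype=np.uint8)
        ok = True
        for i, g in enumerate(gts):
            if len(g) != 3 or not g[2] or g[0] < 0 or g[1] < 0:
                ok = False
                break
            col[2 * i] = g[0]
            col[2 * i + 1] = g[1]
        if not ok:
            skip["unphased"] += 1
            continue
        if v.CHROM in last_pos and v.POS <= last_pos[v.CHROM]:
            if v.POS == last_pos[v.CHROM]:
                skip["duplicate_pos"] += 1
                continue
            raise PanelError(f"VCF not position-sorted at {v.CHROM}:{v.POS}")
        last_pos[v.CHROM] = v.POS
        sid = v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}"
        sites.append(SiteInfo(chrom=v.CHROM, pos=v.POS, site_id=sid, allele0=ref, allele1=alt))
        columns.append(col)
    if not sites:
        raise PanelError(f"no parsable phased biallelic SNP records in {path}")
    alleles = np.stack(columns, axis=1)
    pops = {s: "NA" for s in samples}
    return (
        HaplotypePanel(alleles=alleles, samples=samples, sample_pop=pops, sites=sites),
        skip,
    )


def read_pop_map(path: str) -> tuple[dict[str, str], list[str]]:
    """Read a two-column TSV mapping sample id -> population.

    A header row is recognised when the first cell is one of the usual
    sample-column names. Returns ``(mapping, warnings)``; conflicting
    duplicate assignments raise, consistent duplicates are deduplicated with
    a warning, and populations with fewer than 2 samples are flagged.
    """
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise PanelError("population map needs two tab-separated columns")
    df = df.iloc[:, :2]
    if str(df.iat[0, 0]).strip().lower() in {"sample", "sample_id", "id", "iid", "individual"}:
        df = df.iloc[1:, :]
    warnings: list[str] = []
    mapping: dict[str, str] = {}
    for sample, pop in df.itertuples(index=False):
        sample, pop = str(sample).strip(), str(pop).strip()
        if sample in mapping:
            if mapping[sample] != pop:
                raise PanelError(
                    f"sample {sample!r} assigned to both {mapping[sample]!r} and {pop!r}"
                )
            warnings.append(f"duplicate row for sample {sample!r}")
            continue
        mapping[sample] = pop
    counts: dict[str, int] = {}
    for pop in mapping.values():
        counts[pop] = counts.get(pop, 0) + 1
    for pop, n in counts.items():
        if n < 2:
            warnings.append(f"population {pop!r} has only {n} sample(s)")
    return mapping, warnings


def attach_populations(panel: HaplotypePanel, mapping: Mapping[str, str]) -> HaplotypePanel:
    """Return a copy of ``panel`` with populations taken from ``mapping``."""
    missing = [s for s in panel.samples if s not in mapping]
    if missing:
        raise PanelError(f"population map misses samples: {missing[:5]}")
    return HaplotypePanel(
        alleles=panel.alleles,
        samples=list(panel.samples),
        sample_pop={s: mapping[s] for s in panel.samples},
        sites=list(panel.sites),
    )


def subset_by_population(panel: HaplotypePanel, pop: str) -> HaplotypePanel:
    """Panel restricted to the haplotypes of samples labelled ``pop``."""
    rows = panel.haplotype_rows(pop)
    samples = [s for s in panel.samples if panel.sample_pop[s] == pop]
    return HaplotypePanel(
        alleles=panel.alleles[rows, :],
        samples=samples,
        sample_pop={s: pop for s in samples},
        sites=list(panel.sites),
    )


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_scan_table(result: ScanResult, path: str) -> None:
    """Write one row per site (tab-separated, header, stable column order)."""
    df = result.table.loc[:, SCAN_COLUMNS].copy()
    invalid = ~df["valid"].astype(bool)
    for col in ("raw", "standardized", "neglog10_p"):
        df[col] = df[col].map(lambda x: "" if pd.isna(x) else f"{x:.6g}")
        df.loc[invalid, col] = ""
    df["valid"] = df["valid"].astype(bool).map({True: "1", False: "0"})
    df.to_csv(path, sep="\t", index=False)


def write_regions_bed(regions: Sequence[Region], path: str) -> None:
    """Write regions as BED (0-based half-open) with name and score fields.

    name = ``pop|test|n_sig|size_kb``; score = peak −log10 p × 100, capped
    at 1000. Input must already be sorted by (chrom, start).
    """
    keys = [(r.chrom, r.start) for r in regions]
    if keys != sorted(keys):
        raise PanelError("regions must be sorted by (chrom, start)")
    with open(path, "w", encoding="utf-8") as fh:
        for r in regions:
            score = int(min(1000, round(r.peak_neglog10p * 100)))
            name = f"{r.population}|{r.test}|{r.n_sig_snps}|{r.size_kb}"
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{name}\t{score}\n")


def write_phased_vcf(panel: HaplotypePanel, path: str) -> None:
    """Write a panel back out as a minimal phased VCF 4.2 file."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        seen: dict[str, int] = {}
        for s in panel.sites:
            seen[s.chrom] = max(seen.get(s.chrom, 0), s.pos)
        for chrom, length in seen.items():
            fh.write(f"##contig=<ID={chrom},length={length + 1}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(panel.samples) + "\n")
        for j, s in enumerate(panel.sites):
            col = panel.alleles[:, j]
            gts = "\t".join(
                f"{col[2 * i]}|{col[2 * i + 1]}" for i in range(len(panel.samples))
            )
            fh.write(
                f"{s.chrom}\t{s.pos}\t{s.site_id}\t{s.allele0}\t{s.allele1}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def write_pop_map(sample_pop: Mapping[str, str], samples: Iterable[str], path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample_id\tpopulation\n")
        for s in samples:
            fh.write(f"{s}\t{sample_pop[s]}\n")
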