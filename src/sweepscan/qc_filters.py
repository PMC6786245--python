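"""Marker and sample QC: call-rate, MAF floor, HWE exact test, LD pruning.

Two named filter profiles mirror the two marker sets a structure-vs-scan
analysis needs: the *structure* profile (MAF + HWE + LD pruning, for PCA and
diversity) and the *scan* profile (MAF only, for the haplotype and F_ST
scans).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .haplo_io import GenotypeMatrix, PanelError

_REMOVED_CAP = 200


@dataclass
class FilterReport:
    """Bookkeeping for one filter stage."""

    stage: str
    n_in: int
    n_out: int
    threshold: float
    removed: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_out > self.n_in:
            raise PanelError("filter cannot add items")

    @property
    def n_removed(self) -> int:
        return self.n_in - self.n_out


def _cap(ids: list[str]) -> list[str]:
    return ids[:_REMOVED_CAP]


def filter_call_rate(
    genotypes: GenotypeMatrix,
    snp_min: float = 0.95,
    sample_min: float = 0.90,
) -> tuple[GenotypeMatrix, list[FilterReport]]:
    """Drop SNPs with call rate < ``snp_min``, then samples < ``sample_min``.

    SNP filtering runs first; sample call rates are evaluated on the
    surviving SNPs only.
    """
    d = genotypes.dosage
    called = np.isfinite(d)
    snp_rate = called.mean(axis=0)
    keep_snps = snp_rate >= snp_min
    if not keep_snps.any():
        raise PanelError("call-rate filter removed every SNP")
    removed_snps = [genotypes.sites[i].site_id for i in np.flatnonzero(~keep_snps)]
    gm = genotypes.subset_sites(np.flatnonzero(keep_snps))
    rep_snp = FilterReport(
        stage="call_rate_snp",
        n_in=genotypes.n_sites,
        n_out=gm.n_sites,
        threshold=snp_min,
        removed=_cap(removed_snps),
    )

    sample_rate = np.isfinite(gm.dosage).mean(axis=1)
    keep_samples = sample_rate >= sample_min
    removed_samples = [gm.samples[i] for i in np.flatnonzero(~keep_samples)]
    gm2 = gm.subset_samples(list(np.flatnonzero(keep_samples)))
    rep_sample = FilterReport(
        stage="call_rate_sample",
        n_in=gm.n_samples,
        n_out=gm2.n_samples,
        threshold=sample_min,
        removed=_cap(removed_samples),
    )
    return gm2, [rep_snp, rep_sample]


def _alt_freq(dosage: np.ndarray) -> np.ndarray:
    """Per-SNP ALT allele frequency over non-missing genotypes."""
    called = np.isfinite(dosage)
    n_alleles = 2.0 * called.sum(axis=0)
    alt = np.nansum(dosage, axis=0)
    with np.errstate(invalid="ignore"):
        return np.where(n_alleles > 0, alt / n_alleles, np.nan)


def minor_allele_frequency(dosage: np.ndarray) -> np.ndarray:
    p = _alt_freq(dosage)
    return np.minimum(p, 1.0 - p)


def filter_maf(
    genotypes: GenotypeMatrix,
    min_maf: float = 0.05,
    scope: str = "pooled",
) -> tuple[GenotypeMatrix, FilterReport]:
    """Keep SNPs with minor allele frequency strictly above ``min_maf``.

    ``scope="pooled"`` computes MAF on the combined sample; ``scope="each"``
    requires MAF > min_maf within every population.
    """
    if scope == "pooled":
        maf = minor_allele_frequency(genotypes.dosage)
        keep = maf > min_maf
    elif scope == "each":
        keep = np.ones(genotypes.n_sites, dtype=bool)
        pops = sorted(set(genotypes.sample_pop.values()))
        for pop in pops:
            rows = genotypes.sample_rows(pop)
            keep &= minor_allele_frequency(genotypes.dosage[rows, :]) > min_maf
    else:
        raise PanelError(f"unknown MAF scope {scope!r}")
    removed = [genotypes.sites[i].site_id for i in np.flatnonzero(~keep)]
    gm = genotypes.subset_sites(np.flatnonzero(keep))
    report = FilterReport(
        stage=f"maf_{scope}",
        n_in=genotypes.n_sites,
        n_out=gm.n_sites,
        threshold=min_maf,
        removed=_cap(removed),
    )
    return gm, report


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact two-sided Hardy–Weinberg test on the heterozygote count.

    Conditional on the observed allele counts, the number of heterozygotes
    has a known exact sampling distribution under random union of gametes;
    the p-value sums the probabilities of all heterozygote counts no more
    probable than the observed one. Monomorphic sites return 1.0.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise PanelError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise PanelError("need at least one genotype")
    n_a = 2 * n_aa + n_Aa  # rarer-or-not allele count; symmetric below
    n_A = 2 * n_AA + n_Aa
    rare = min(n_A, n_a)
    if rare == 0:
        return 1.0

    # log P(het = h | allele counts) up to a constant:
    #   log n! - log n_AA! - log n_Aa! - log n_aa! + h*log 2
    def logprob(h: int) -> float:
        hom_rare = (rare - h) // 2
        hom_common = n - h - hom_rare
        return (
            h * math.log(2.0)
            - math.lgamma(h + 1)
            - math.lgamma(hom_rare + 1)
            - math.lgamma(hom_common + 1)
        )

    hs = range(rare % 2, rare + 1, 2)
    logps = np.array([logprob(h) for h in hs])
    logps -= logps.max()
    probs = np.exp(logps)
    probs /= probs.sum()
    obs = probs[(n_Aa - rare % 2) // 2]
    return float(min(1.0, probs[probs <= obs * (1 + 1e-12)].sum()))


def hwe_pvalues(genotypes: GenotypeMatrix) -> np.ndarray:
    """HWE exact-test p-value per SNP, pooled across samples."""
    d = genotypes.dosage
    out = np.empty(genotypes.n_sites)
    for j in range(genotypes.n_sites):
        col = d[:, j]
        col = col[np.isfinite(col)]
        n_aa = int((col == 2).sum())
        n_Aa = int((col == 1).sum())
        n_AA = int((col == 0).sum())
        out[j] = hwe_exact_test(n_AA, n_Aa, n_aa) if (n_AA + n_Aa + n_aa) else 1.0
    return out


def filter_hwe(
    genotypes: GenotypeMatrix, p_min: float = 1e-6
) -> tuple[GenotypeMatrix, FilterReport]:
    """Drop SNPs whose pooled HWE exact-test p-value falls below ``p_min``."""
    p = hwe_pvalues(genotypes)
    keep = p >= p_min
    removed = [genotypes.sites[i].site_id for i in np.flatnonzero(~keep)]
    gm = genotypes.subset_sites(np.flatnonzero(keep))
    report = FilterReport(
        stage="hwe",
        n_in=genotypes.n_sites,
        n_out=gm.n_sites,
        threshold=p_min,
        removed=_cap(removed),
    )
    return gm, report


def _window_r2(d: np.ndarray) -> np.ndarray:
    """Pairwise squared dosage correlation within a window (mean-imputed)."""
    x = d.copy()
    mask = ~np.isfinite(x)
    if mask.any():
        means = np.nanmean(x, axis=0)
        x[mask] = np.take(means, np.nonzero(mask)[1])
    x = x - x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = np.nan
    c = (x.T @ x) / x.shape[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        r = c / np.outer(sd, sd)
    r2 = r**2
    np.fill_diagonal(r2, 0.0)
    return r2


def ld_prune(
    genotypes: GenotypeMatrix,
    r2_max: float = 0.4,
    window_snps: int = 50,
    step: int = 5,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Greedy sliding-window LD pruning on dosage r².

    Within each window of surviving SNPs, while any pair exceeds ``r2_max``,
    the member of the worst pair with the lower MAF is removed (tie: the
    later position). Passes repeat until no window removes anything, so the
    result is a fixed point: re-running reports zero removals.
    """
    if genotypes.n_sites < 2:
        raise PanelError("LD pruning needs at least 2 SNPs")
    maf = minor_allele_frequency(genotypes.dosage)
    chrom = genotypes.chroms
    alive = np.ones(genotypes.n_sites, dtype=bool)

    changed = True
    while changed:
        changed = False
        for c in _unique_stable(chrom):
            idx_all = np.flatnonzero((chrom == c) & alive)
            start = 0
            while start < len(idx_all):
                idx_all = np.flatnonzero((chrom == c) & alive)
                if start >= len(idx_all):
                    break
                window = idx_all[start : start + window_snps]
                if len(window) >= 2:
                    r2 = _window_r2(genotypes.dosage[:, window])
                    while True:
                        with np.errstate(invalid="ignore"):
                            worst = np.nanmax(r2) if np.isfinite(r2).any() else 0.0
                        if not (worst > r2_max):
                            break
                        i, j = np.unravel_index(np.nanargmax(r2), r2.shape)
                        a, b = window[i], window[j]
                        # drop lower MAF; tie -> later position
                        if maf[a] < maf[b] or (maf[a] == maf[b] and a > b):
                            drop_local, drop = i, a
                        else:
                            drop_local, drop = j, b
                        alive[drop] = False
                        changed = True
                        r2[drop_local, :] = np.nan
                        r2[:, drop_local] = np.nan
                start += step
    removed = [genotypes.sites[i].site_id for i in np.flatnonzero(~alive)]
    gm = genotypes.subset_sites(np.flatnonzero(alive))
    report = FilterReport(
        stage="ld_prune",
        n_in=genotypes.n_sites,
        n_out=gm.n_sites,
        threshold=r2_max,
        removed=_cap(removed),
    )
    return gm, report


def _unique_stable(values: np.ndarray) -> list:
    seen: dict = {}
    for v in values:
        seen.setdefault(v, None)
    return list(seen)


def structure_profile(
    genotypes: GenotypeMatrix,
    min_maf: float = 0.05,
    hwe_p_min: float = 1e-6,
    r2_max: float = 0.4,
) -> tuple[GenotypeMatrix, list[FilterReport]]:
    """MAF + HWE + LD-pruning filter set used for structure analyses."""
    gm, rep1 = filter_maf(genotypes, min_maf=min_maf)
    gm, rep2 = filter_hwe(gm, p_min=hwe_p_min)
    gm, rep3 = ld_prune(gm, r2_max=r2_max)
    return gm, [rep1, rep2, rep3]


def scan_profile(
    genotypes: GenotypeMatrix, min_maf: float = 0.05, scope: str = "pooled"
) -> tuple[GenotypeMatrix, list[FilterReport]]:
    """MAF-only filter set used for the selection scans."""
    gm, rep = filter_maf(genotypes, min_maf=min_maf, scope=scope)
    return gm, [rep]
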