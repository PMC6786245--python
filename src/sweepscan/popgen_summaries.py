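"""Diversity, LD-decay, and structure summaries of a genotyped panel.

These reproduce the descriptive layer of an array-based population survey:
per-population observed/expected heterozygosity with a Kruskal–Wallis
comparison, binned r² decay with physical distance within chromosomes, and
genotype PCA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .haplo_io import GenotypeMatrix, PanelError


@dataclass
class DiversitySummary:
    """Per-SNP H_O/H_E vectors for one population plus their mean ± SD."""

    population: str
    h_obs: np.ndarray
    h_exp: np.ndarray
    mean_h_obs: float
    sd_h_obs: float
    mean_h_exp: float
    sd_h_exp: float


@dataclass
class LDDecayProfile:
    """Mean r² per 100-kb (by default) distance bin for one population."""

    population: str
    bin_edges_kb: np.ndarray  # length n_bins + 1, starting at 0
    mean_r2: np.ndarray  # NaN where a bin has no pairs
    pair_count: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_start_kb": self.bin_edges_kb[:-1],
                "bin_end_kb": self.bin_edges_kb[1:],
                "mean_r2": self.mean_r2,
                "pair_count": self.pair_count,
            }
        )


def _het_summaries(dosage: np.ndarray, correction: bool) -> tuple[np.ndarray, np.ndarray]:
    called = np.isfinite(dosage)
    n_called = called.sum(axis=0).astype(float)
    n_called[n_called == 0] = np.nan
    h_obs = (dosage == 1).sum(axis=0) / n_called
    p = np.nansum(dosage, axis=0) / (2.0 * n_called)
    h_exp = 2.0 * p * (1.0 - p)
    if correction:
        n2 = 2.0 * n_called
        h_exp = h_exp * n2 / (n2 - 1.0)
    return h_obs, h_exp


def heterozygosity_summary(
    genotypes: GenotypeMatrix,
    populations: list[str] | None = None,
    bias_correction: bool = False,
) -> list[DiversitySummary]:
    """Observed and expected heterozygosity per SNP, per population.

    H_O is the fraction of non-missing genotypes that are heterozygous; H_E
    is 2p(1−p) with p the sample allele frequency (optionally scaled by
    2n/(2n−1) when ``bias_correction`` is on).
    """
    if populations is None:
        seen: dict[str, None] = {}
        for s in genotypes.samples:
            seen.setdefault(genotypes.sample_pop[s], None)
        populations = list(seen)
    out = []
    for pop in populations:
        rows = genotypes.sample_rows(pop)  # raises on unknown pop
        h_obs, h_exp = _het_summaries(genotypes.dosage[rows, :], bias_correction)
        out.append(
            DiversitySummary(
                population=pop,
                h_obs=h_obs,
                h_exp=h_exp,
                mean_h_obs=float(np.nanmean(h_obs)),
                sd_h_obs=float(np.nanstd(h_obs)),
                mean_h_exp=float(np.nanmean(h_exp)),
                sd_h_exp=float(np.nanstd(h_exp)),
            )
        )
    return out


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Kruskal–Wallis H (tie-corrected) and its chi-square p-value.

    Degenerate input where every value across all groups is identical
    returns (0, 1) rather than raising.
    """
    if len(groups) < 2:
        raise PanelError("need at least two groups")
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) == 0 for g in groups):
        raise PanelError("groups must be non-empty")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def genotype_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Computed over jointly non-missing samples; returns NaN when either locus
    is constant there (undefined, excluded from decay profiles).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise PanelError("dosage vectors differ in length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 2 or x.std() == 0 or y.std() == 0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def _pairwise_r2_matrix(dosage: np.ndarray) -> np.ndarray:
    """All-pairs r² for complete or mean-imputed dosage columns."""
    x = dosage.copy()
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
    return r**2


def ld_decay_profile(
    genotypes: GenotypeMatrix,
    population: str,
    bin_kb: float = 100.0,
    max_dist_kb: float | None = None,
) -> LDDecayProfile:
    """Binned decay of dosage r² with physical distance, within chromosomes.

    All within-chromosome SNP pairs (up to ``max_dist_kb`` apart, if set)
    contribute to contiguous ``bin_kb`` distance bins starting at 0; pairs
    with undefined r² (a constant locus) are excluded.
    """
    rows = genotypes.sample_rows(population)
    d = genotypes.dosage[rows, :]
    chrom = genotypes.chroms
    pos = genotypes.positions

    dists: list[np.ndarray] = []
    r2s: list[np.ndarray] = []
    for c in dict.fromkeys(chrom):
        idx = np.flatnonzero(chrom == c)
        if len(idx) < 2:
            continue
        r2 = _pairwise_r2_matrix(d[:, idx])
        p = pos[idx].astype(float)
        dd = np.abs(p[:, None] - p[None, :])
        iu = np.triu_indices(len(idx), k=1)
        dist, val = dd[iu], r2[iu]
        ok = np.isfinite(val)
        if max_dist_kb is not None:
            ok &= dist <= max_dist_kb * 1000.0
        dists.append(dist[ok])
        r2s.append(val[ok])

    if not dists or not sum(len(a) for a in dists):
        return LDDecayProfile(
            population=population,
            bin_edges_kb=np.array([0.0, bin_kb]),
            mean_r2=np.array([np.nan]),
            pair_count=np.array([0]),
        )
    dist = np.concatenate(dists) / 1000.0  # kb
    val = np.concatenate(r2s)
    n_bins = int(np.floor(dist.max() / bin_kb)) + 1
    edges = np.arange(n_bins + 1) * bin_kb
    which = np.minimum((dist / bin_kb).astype(int), n_bins - 1)
    count = np.bincount(which, minlength=n_bins)
    total = np.bincount(which, weights=val, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return LDDecayProfile(
        population=population, bin_edges_kb=edges, mean_r2=mean, pair_count=count
    )


def pca_genotypes(
    genotypes: GenotypeMatrix,
    n_components: int | None = None,
    scale: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Genotype PCA via SVD of the column-centred dosage matrix.

    Missing dosages are mean-imputed per SNP. With ``scale`` the columns are
    divided by sqrt(p(1−p)) before decomposition. Returns (coordinates,
    variance-explained fractions), components ordered by decreasing
    variance.
    """
    if genotypes.n_samples < 2 or genotypes.n_sites < 2:
        raise PanelError("PCA needs at least 2 samples and 2 SNPs")
    x = genotypes.dosage.copy()
    mask = ~np.isfinite(x)
    if mask.any():
        means = np.nanmean(x, axis=0)
        x[mask] = np.take(means, np.nonzero(mask)[1])
    x = x - x.mean(axis=0)
    if scale:
        freq = np.nansum(genotypes.dosage, axis=0) / (
            2.0 * np.isfinite(genotypes.dosage).sum(axis=0)
        )
        denom = np.sqrt(freq * (1.0 - freq))
        denom[denom == 0] = np.nan
        x = x / denom
        x = np.nan_to_num(x, nan=0.0)
    if not np.any(x):
        raise PanelError("zero-variance genotype matrix")
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    var = s**2
    frac = var / var.sum()
    coords = u * s
    if n_components is not None:
        coords = coords[:, :n_components]
        frac = frac[:n_components]
    return coords, frac
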