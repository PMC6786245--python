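"""Turn per-SNP scan results into candidate selected regions.

The clustering rule: consecutive significant SNPs on a chromosome no more
than 500 kb apart chain into one cluster; clusters with at least two SNPs
become regions bounded by their outermost significant SNPs. Overlapping
regions (e.g. from different scans being combined) merge.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .haplo_io import PanelError, Region, ScanResult


def region_size_kb(start: int, end: int) -> float:
    """(end − start)/1000, rounded half-away-from-zero to 1 decimal."""
    if end < start:
        raise PanelError(f"end {end} < start {start}")
    kb = (end - start) / 1000.0
    return math.floor(kb * 10.0 + 0.5) / 10.0


def call_significant(
    result: ScanResult,
    neglogp_min: float = 3.0,
    sign: int | None = None,
    po_min: float = 32.0,
) -> pd.DataFrame:
    """Rows of the scan table passing the significance rule, position-sorted.

    For iHS/XP-EHH the rule is −log10 p ≥ ``neglogp_min``; ``sign`` (+1/−1)
    optionally restricts XP-EHH calls to one direction (positive =
    observed population, negative = reference). For the F_ST-outlier test
    the rule is posterior odds (``raw``) ≥ ``po_min`` with positive mean α
    (``standardized``) — the directional-selection decision.
    """
    df = result.table
    ok = df["valid"].astype(bool)
    if result.test == "FST-outlier":
        sig = ok & (df["raw"] >= po_min) & (df["standardized"] > 0)
    else:
        sig = ok & (df["neglog10_p"] >= neglogp_min)
        if sign is not None:
            if sign > 0:
                sig &= df["standardized"] > 0
            else:
                sig &= df["standardized"] < 0
    out = df.loc[sig].copy()
    return out.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


def cluster_regions(
    sig_sites: pd.DataFrame,
    population: str = "",
    test: str = "",
    max_gap_bp: int = 500_000,
    min_snps: int = 2,
) -> list[Region]:
    """Chain significant SNPs ≤ ``max_gap_bp`` apart into candidate regions.

    Chaining applies to consecutive significant SNPs, so a region's span may
    far exceed the gap limit. Clusters smaller than ``min_snps`` (lone
    SNPs by default) are discarded.
    """
    regions: list[Region] = []
    if sig_sites.empty:
        return regions
    for chrom, grp in sig_sites.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        if not np.all(np.diff(pos) >= 0):
            raise PanelError("significant sites must be position-sorted")
        breaks = np.flatnonzero(np.diff(pos) > max_gap_bp)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [len(pos) - 1]])
        for s, e in zip(starts, ends):
            n = e - s + 1
            if n < min_snps:
                continue
            block = grp.iloc[s : e + 1]
            peak_score = float(np.nanmax(np.abs(block["standardized"].to_numpy())))
            if block["neglog10_p"].notna().any():
                peak_p = float(np.nanmax(block["neglog10_p"].to_numpy()))
            else:
                peak_p = float("nan")
            start, end = int(pos[s]), int(pos[e])
            regions.append(
                Region(
                    population=population,
                    test=test,
                    chrom=str(chrom),
                    start=start,
                    end=end,
                    n_sig_snps=int(n),
                    peak_score=peak_score,
                    peak_neglog10p=peak_p,
                    size_kb=region_size_kb(start, end),
                )
            )
    regions.sort(key=lambda r: (r.chrom, r.start))
    return regions


def merge_regions(regions: list[Region]) -> list[Region]:
    """Merge overlapping or bookended regions on the same chromosome.

    Merged regions sum significant-SNP counts and take the peak statistics;
    the operation is idempotent and the output is sorted, non-overlapping.
    """
    keys = [(r.chrom, r.start) for r in regions]
    if keys != sorted(keys):
        raise PanelError("regions must be sorted by (chrom, start)")
    merged: list[Region] = []
    for r in regions:
        if merged and merged[-1].chrom == r.chrom and merged[-1].end >= r.start:
            prev = merged.pop()
            start = prev.start
            end = max(prev.end, r.end)
            merged.append(
                Region(
                    population=prev.population if prev.population == r.population else f"{prev.population}+{r.population}",
                    test=prev.test if prev.test == r.test else f"{prev.test}+{r.test}",
                    chrom=prev.chrom,
                    start=start,
                    end=end,
                    n_sig_snps=prev.n_sig_snps + r.n_sig_snps,
                    peak_score=max(prev.peak_score, r.peak_score),
                    peak_neglog10p=max(prev.peak_neglog10p, r.peak_neglog10p),
                    size_kb=region_size_kb(start, end),
                )
            )
        else:
            merged.append(r)
    return merged


_REGION_COLUMNS = [
    "population", "test", "chrom", "start", "end",
    "peak_neglog10p", "peak_score", "n_snps", "size_kb",
]


def regions_to_frame(regions: list[Region]) -> pd.DataFrame:
    """Region list as the tabular layout of the result tables."""
    if not regions:
        return pd.DataFrame(columns=_REGION_COLUMNS)
    return pd.DataFrame(
        [
            {
                "population": r.population,
                "test": r.test,
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "peak_neglog10p": r.peak_neglog10p,
                "peak_score": r.peak_score,
                "n_snps": r.n_sig_snps,
                "size_kb": r.size_kb,
            }
            for r in regions
        ]
    )
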