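"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import math

import numpy as np
import pytest

from sweepscan.haplo_io import HaplotypePanel, SiteInfo


def make_panel(alleles, positions=None, chrom="1", pops=None):
    """Build a small panel from a 2-D 0/1 array (haplotypes × sites)."""
    alleles = np.asarray(alleles, dtype=np.uint8)
    n_hap, n_sites = alleles.shape
    assert n_hap % 2 == 0
    if positions is None:
        positions = [1000 * (j + 1) for j in range(n_sites)]
    samples = [f"s{i}" for i in range(n_hap // 2)]
    if pops is None:
        pops = {s: "A" for s in samples}
    sites = [
        SiteInfo(chrom=chrom, pos=int(p), site_id=f"snp{j}")
        for j, p in enumerate(positions)
    ]
    return HaplotypePanel(alleles=alleles, samples=samples, sample_pop=pops, sites=sites)


@pytest.fixture
def small_panel():
    rng = np.random.default_rng(0)
    return make_panel(rng.integers(0, 2, size=(20, 30)))


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def brute_force_ehh(panel, core, target, cutoff=0.05):
    """EHH by explicit haplotype-string hashing and pair counting.

    Independent of the production partition-refinement walk: at every marker
    it rebuilds the full core-to-marker allele tuple per carrier and counts
    identical pairs directly.
    """
    alleles = panel.alleles
    positions = panel.positions
    chroms = panel.chroms
    c = chroms[core]
    if target == "site":
        rows = list(range(alleles.shape[0]))
    else:
        rows = list(np.flatnonzero(alleles[:, core] == target))
    n = len(rows)
    if n < 2:
        return None

    def side(step):
        pos_out, ehh_out = [], []
        t = core + step
        while 0 <= t < alleles.shape[1] and chroms[t] == c:
            lo, hi = (t, core) if step < 0 else (core, t)
            groups: dict[tuple, int] = {}
            for h in rows:
                key = tuple(alleles[h, lo : hi + 1])
                groups[key] = groups.get(key, 0) + 1
            pairs = sum(k * (k - 1) // 2 for k in groups.values())
            ehh = pairs / (n * (n - 1) // 2)
            pos_out.append(int(positions[t]))
            ehh_out.append(ehh)
            if ehh < cutoff:
                break
            t += step
        return np.array(pos_out), np.array(ehh_out)

    lp, le = side(-1)
    rp, re = side(+1)
    return le, re


def brute_force_hwe(n_AA, n_Aa, n_aa):
    """Exact HWE p-value via explicit factorial enumeration.

    Uses math.factorial directly (the implementation uses log-gamma), so the
    two share no code path.
    """
    n = n_AA + n_Aa + n_aa
    n_a = 2 * n_aa + n_Aa
    n_A = 2 * n_AA + n_Aa
    rare = min(n_A, n_a)
    if rare == 0:
        return 1.0

    def weight(h):
        hom_rare = (rare - h) // 2
        hom_common = n - h - hom_rare
        return (
            2**h
            * math.factorial(n)
            // (
                math.factorial(h)
                * math.factorial(hom_rare)
                * math.factorial(hom_common)
            )
        )

    hs = list(range(rare % 2, rare + 1, 2))
    ws = [weight(h) for h in hs]
    total = sum(ws)
    obs = ws[hs.index(n_Aa)]
    return sum(w for w in ws if w <= obs) / total


def wc_fst(a, n):
    """Weir & Cockerham ANOVA F_ST from per-population allele counts.

    Returns (per-locus ratio, multi-locus ratio-of-sums). Treats each
    sampled allele copy as an observation (counts carry no heterozygote
    information).
    """
    a = np.asarray(a, dtype=float)
    n = np.asarray(n, dtype=float)
    r = a.shape[1]
    N = n.sum(axis=1)
    p = a / n
    pbar = a.sum(axis=1) / N
    msp = (n * (p - pbar[:, None]) ** 2).sum(axis=1) / (r - 1)
    msg = (n * p * (1 - p)).sum(axis=1) / (N - r)
    nc = (N - (n**2).sum(axis=1) / N) / (r - 1)
    num = msp - msg
    den = msp + (nc - 1) * msg
    with np.errstate(invalid="ignore", divide="ignore"):
        per_locus = np.where(den != 0, num / den, 0.0)
    return per_locus, num.sum() / den.sum()
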