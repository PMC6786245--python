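"""Extended haplotype homozygosity statistics: EHH, iHH, iHS, XP-EHH.

EHH at distance x from a core SNP is the probability that two randomly
chosen haplotypes (from a carrier set) are identical at every marker from
the core out to x. iHS integrates EHH separately for the two alleles of the
core SNP and contrasts them, ln(iHH_major/iHH_minor); XP-EHH integrates the
site EHH (all haplotypes) in two populations and contrasts those,
ln(I_obs/I_ref). Raw scores are standardized — iHS within minor-allele-
frequency bins, XP-EHH genome-wide — and mapped to −log10 p assuming a
standard normal null.

The major allele is treated as the ancestral state (array data carry no
outgroup polarization); a frequency tie at exactly 0.5 resolves to allele 0
(REF).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .haplo_io import SCAN_COLUMNS, HaplotypePanel, PanelError, ScanResult


@dataclass
class IhsConfig:
    """Tunables for the haplotype scans.

    ``ehh_cutoff`` truncates the EHH integral; ``freq_bin_width`` and
    ``min_snps_per_bin`` govern iHS standardization; ``max_extension_bp``
    optionally caps how far EHH is followed from the core.
    """

    maf_min: float = 0.05
    ehh_cutoff: float = 0.05
    freq_bin_width: float = 0.025
    min_snps_per_bin: int = 10
    max_extension_bp: int | None = None
    two_sided: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.ehh_cutoff < 1:
            raise PanelError("ehh_cutoff must be in (0,1)")
        if not 0 < self.freq_bin_width <= 0.5:
            raise PanelError("freq_bin_width must be in (0, 0.5]")


@dataclass
class EHHProfile:
    """EHH values extending left/right of a core site, outward order.

    The core itself is not stored (its EHH is 1 by definition); the arrays
    hold the markers beyond it on each side. ``*_stop`` records why the walk
    ended: ``"cutoff"`` (EHH fell below the cutoff), ``"chrom_end"`` or
    ``"max_extension"``.
    """

    core_index: int
    core_pos: int
    target: object  # 0, 1 or "site"
    n_carriers: int
    left_pos: np.ndarray
    left_ehh: np.ndarray
    right_pos: np.ndarray
    right_ehh: np.ndarray
    left_stop: str
    right_stop: str
    valid: bool = True
    reason: str = ""


def _chrom_span(chroms: np.ndarray, core: int) -> tuple[int, int]:
    """[lo, hi) index range of the core's chromosome (sites are grouped)."""
    c = chroms[core]
    lo = core
    while lo > 0 and chroms[lo - 1] == c:
        lo -= 1
    hi = core + 1
    n = len(chroms)
    while hi < n and chroms[hi] == c:
        hi += 1
    return lo, hi


def _walk_side(
    alleles: np.ndarray,
    rows: np.ndarray,
    positions: np.ndarray,
    core: int,
    step: int,
    bound: int,
    cutoff: float,
    max_extension_bp: int | None,
    init_labels: np.ndarray,
) -> tuple[list[int], list[float], str]:
    """March outward from the core refining the haplotype partition.

    ``init_labels`` is the partition at the core (all-zero for an allele
    target whose carriers share the core allele; the core-allele column for
    the site target). Returns positions, EHH values, and the stop reason.
    """
    n = len(rows)
    denom = n * (n - 1) / 2.0
    labels = init_labels.astype(np.int64)
    pos_out: list[int] = []
    ehh_out: list[float] = []
    t = core + step
    core_pos = positions[core]
    stop = "chrom_end"
    while (t < bound) if step > 0 else (t >= bound):
        if max_extension_bp is not None and abs(int(positions[t]) - int(core_pos)) > max_extension_bp:
            stop = "max_extension"
            break
        labels = labels * 2 + alleles[rows, t]
        _, labels = np.unique(labels, return_inverse=True)
        counts = np.bincount(labels)
        ehh = float((counts * (counts - 1)).sum() / 2.0 / denom)
        pos_out.append(int(positions[t]))
        ehh_out.append(ehh)
        if ehh < cutoff:
            stop = "cutoff"
            break
        t += step
    return pos_out, ehh_out, stop


def ehh_profile(
    panel: HaplotypePanel,
    core: int,
    target: object,
    ehh_cutoff: float = 0.05,
    max_extension_bp: int | None = None,
) -> EHHProfile:
    """EHH profile around site ``core`` for an allele (0/1) or "site" target.

    For an allele target the carrier set is the haplotypes bearing that
    allele at the core; for "site" all haplotypes are used and the core
    allele itself enters the identity requirement of every off-core marker.
    EHH at the core is 1 by definition in both cases. The walk stops once
    EHH drops below ``ehh_cutoff`` (the sub-cutoff value is kept for
    interpolation) or the chromosome (or extension cap) ends.
    """
    alleles = panel.alleles
    positions = panel.positions
    chroms = panel.chroms
    if not 0 <= core < panel.n_sites:
        raise PanelError(f"core index {core} out of range")

    if target == "site":
        rows = np.arange(panel.n_haplotypes)
        init = alleles[rows, core].astype(np.int64)
    elif target in (0, 1):
        rows = np.flatnonzero(alleles[:, core] == target)
        init = np.zeros(len(rows), dtype=np.int64)
    else:
        raise PanelError(f"target must be 0, 1 or 'site', got {target!r}")

    if len(rows) < 2:
        return EHHProfile(
            core_index=core,
            core_pos=int(positions[core]),
            target=target,
            n_carriers=len(rows),
            left_pos=np.array([], dtype=np.int64),
            left_ehh=np.array([]),
            right_pos=np.array([], dtype=np.int64),
            right_ehh=np.array([]),
            left_stop="none",
            right_stop="none",
            valid=False,
            reason="mono/insufficient carriers",
        )

    lo, hi = _chrom_span(chroms, core)
    lp, le, lstop = _walk_side(
        alleles, rows, positions, core, -1, lo, ehh_cutoff, max_extension_bp, init
    )
    rp, re_, rstop = _walk_side(
        alleles, rows, positions, core, +1, hi, ehh_cutoff, max_extension_bp, init
    )
    return EHHProfile(
        core_index=core,
        core_pos=int(positions[core]),
        target=target,
        n_carriers=len(rows),
        left_pos=np.asarray(lp, dtype=np.int64),
        left_ehh=np.asarray(le),
        right_pos=np.asarray(rp, dtype=np.int64),
        right_ehh=np.asarray(re_),
        left_stop=lstop,
        right_stop=rstop,
    )


def _side_area(core_pos: int, pos: np.ndarray, ehh: np.ndarray, cutoff: float) -> float:
    """Trapezoid area of one side down to the interpolated cutoff crossing."""
    xs = np.concatenate([[0.0], np.abs(pos.astype(float) - core_pos)])
    ys = np.concatenate([[1.0], ehh])
    area = 0.0
    for k in range(1, len(xs)):
        if ys[k] < cutoff:
            # linear interpolation of the crossing inside this segment
            frac = (ys[k - 1] - cutoff) / (ys[k - 1] - ys[k])
            dx = (xs[k] - xs[k - 1]) * frac
            area += 0.5 * (ys[k - 1] + cutoff) * dx
            return area
        area += 0.5 * (ys[k - 1] + ys[k]) * (xs[k] - xs[k - 1])
    return area


def integrate_ehh(profile: EHHProfile, cutoff: float = 0.05) -> tuple[float, bool, str]:
    """Integrate EHH against bp distance on both sides of the core.

    Returns ``(ihh, valid, reason)``. A side that ran out of chromosome (or
    hit the extension cap) before decaying below ``cutoff`` makes the
    integral non-comparable; such profiles are flagged invalid with reason
    "uncapped decay".
    """
    if not profile.valid:
        return float("nan"), False, profile.reason
    for stop in (profile.left_stop, profile.right_stop):
        if stop != "cutoff":
            return float("nan"), False, "uncapped decay"
    area = _side_area(profile.core_pos, profile.left_pos, profile.left_ehh, cutoff)
    area += _side_area(profile.core_pos, profile.right_pos, profile.right_ehh, cutoff)
    return float(area), True, ""


def neglog10_p_from_z(z: float, two_sided: bool = True) -> float:
    """Map a standardized score to −log10 p under a standard normal null.

    Two-sided by default: −log10(2(1−Φ(|z|))), evaluated through the
    log-survival function so extreme scores do not suffer 1−CDF
    cancellation.
    """
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise PanelError("z must be finite")
    logp = stats.norm.logsf(np.abs(z))
    if two_sided:
        logp = logp + math.log(2.0)
    out = -(np.minimum(logp, 0.0)) / math.log(10.0)
    return float(out) if out.ndim == 0 else out


def _site_ihh(
    panel: HaplotypePanel, core: int, target: object, config: IhsConfig
) -> tuple[float, bool, str]:
    prof = ehh_profile(
        panel,
        core,
        target,
        ehh_cutoff=config.ehh_cutoff,
        max_extension_bp=config.max_extension_bp,
    )
    return integrate_ehh(prof, cutoff=config.ehh_cutoff)


def _standardize_binned(
    raw: np.ndarray, maf: np.ndarray, valid: np.ndarray, config: IhsConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Z-score raw values within MAF bins; merge sparse bins with neighbours.

    Returns (standardized, still_valid): sites whose merged bin ends up with
    fewer than 2 values cannot be standardized and are invalidated.
    """
    std = np.full_like(raw, np.nan, dtype=float)
    ok = valid.copy()
    n_bins = int(np.ceil(0.5 / config.freq_bin_width))
    bin_of = np.minimum((maf / config.freq_bin_width).astype(int), n_bins - 1)

    counts = np.bincount(bin_of[valid], minlength=n_bins)
    # merge bins under the occupancy floor into their nearest occupied neighbour
    merged = np.arange(n_bins)
    occupied = [b for b in range(n_bins) if counts[b] >= config.min_snps_per_bin]
    if occupied:
        for b in range(n_bins):
            if counts[b] < config.min_snps_per_bin:
                merged[b] = min(occupied, key=lambda o: (abs(o - b), o))
    group = merged[bin_of]
    for g in np.unique(group[valid]):
        members = valid & (group == g)
        vals = raw[members]
        if len(vals) < 2:
            ok[members] = False
            continue
        mu = vals.mean()
        sd = vals.std(ddof=1)
        if sd == 0:
            ok[members] = False
            continue
        std[members] = (raw[members] - mu) / sd
    std[~ok] = np.nan
    return std, ok


def _empty_scan_frame(panel: HaplotypePanel) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": panel.chroms,
            "pos": panel.positions,
            "site_id": [s.site_id for s in panel.sites],
            "raw": np.nan,
            "standardized": np.nan,
            "neglog10_p": np.nan,
            "valid": False,
            "reason": "",
        },
        columns=SCAN_COLUMNS,
    )


def ihs_scan(
    panel: HaplotypePanel, config: IhsConfig | None = None, population: str = ""
) -> ScanResult:
    """Within-population iHS scan over every site of a phased panel.

    Raw score: ln(iHH_major / iHH_minor), the major allele standing in for
    the ancestral state. Standardization is within minor-allele-frequency
    bins; −log10 p from the normal null.
    """
    config = config or IhsConfig()
    df = _empty_scan_frame(panel)
    L = panel.n_sites
    freq1 = panel.alleles.mean(axis=0)  # ALT frequency across haplotypes
    maf = np.minimum(freq1, 1.0 - freq1)

    raw = np.full(L, np.nan)
    valid = np.zeros(L, dtype=bool)
    reasons = [""] * L
    for j in range(L):
        if maf[j] <= config.maf_min:
            reasons[j] = "maf"
            continue
        major = 0 if freq1[j] <= 0.5 else 1  # tie at 0.5 -> allele 0 (REF)
        minor = 1 - major
        ihh_major, ok1, r1 = _site_ihh(panel, j, major, config)
        if not ok1:
            reasons[j] = r1
            continue
        ihh_minor, ok2, r2 = _site_ihh(panel, j, minor, config)
        if not ok2:
            reasons[j] = r2
            continue
        if ihh_major <= 0 or ihh_minor <= 0:
            reasons[j] = "zero iHH"
            continue
        raw[j] = math.log(ihh_major / ihh_minor)
        valid[j] = True

    std, still_ok = _standardize_binned(raw, maf, valid, config)
    for j in np.flatnonzero(valid & ~still_ok):
        reasons[j] = "unstandardizable bin"
    valid = still_ok
    neglog = np.full(L, np.nan)
    if valid.any():
        neglog[valid] = neglog10_p_from_z(std[valid], two_sided=config.two_sided)

    df["raw"] = raw
    df["standardized"] = std
    df["neglog10_p"] = neglog
    df["valid"] = valid
    df["reason"] = reasons
    return ScanResult(test="iHS", population=population, table=df)


def xpehh_scan(
    panel_obs: HaplotypePanel,
    panel_ref: HaplotypePanel,
    config: IhsConfig | None = None,
    contrast: str = "",
) -> ScanResult:
    """Cross-population XP-EHH scan: ln(I_obs/I_ref) per shared site.

    Positive standardized scores point to selection in the observed
    population, negative to the reference. Standardization is genome-wide
    over valid sites.
    """
    config = config or IhsConfig()
    if [(s.chrom, s.pos) for s in panel_obs.sites] != [
        (s.chrom, s.pos) for s in panel_ref.sites
    ]:
        raise PanelError("XP-EHH panels must share an identical site list")
    df = _empty_scan_frame(panel_obs)
    L = panel_obs.n_sites

    n_obs = panel_obs.n_haplotypes
    n_ref = panel_ref.n_haplotypes
    pooled = (panel_obs.alleles.sum(axis=0) + panel_ref.alleles.sum(axis=0)) / float(
        n_obs + n_ref
    )
    maf = np.minimum(pooled, 1.0 - pooled)

    raw = np.full(L, np.nan)
    valid = np.zeros(L, dtype=bool)
    reasons = [""] * L
    for j in range(L):
        if maf[j] <= config.maf_min:
            reasons[j] = "maf"
            continue
        i_obs, ok1, r1 = _site_ihh(panel_obs, j, "site", config)
        if not ok1:
            reasons[j] = f"obs: {r1}"
            continue
        i_ref, ok2, r2 = _site_ihh(panel_ref, j, "site", config)
        if not ok2:
            reasons[j] = f"ref: {r2}"
            continue
        if i_obs <= 0 or i_ref <= 0:
            reasons[j] = "zero iHH"
            continue
        raw[j] = math.log(i_obs / i_ref)
        valid[j] = True

    std = np.full(L, np.nan)
    if valid.sum() >= 2:
        mu = raw[valid].mean()
        sd = raw[valid].std(ddof=1)
        if sd > 0:
            std[valid] = (raw[valid] - mu) / sd
        else:
            for j in np.flatnonzero(valid):
                reasons[j] = "degenerate genome-wide SD"
            valid[:] = False
    else:
        for j in np.flatnonzero(valid):
            reasons[j] = "too few valid sites"
        valid[:] = False
    neglog = np.full(L, np.nan)
    if valid.any():
        neglog[valid] = neglog10_p_from_z(std[valid], two_sided=config.two_sided)

    df["raw"] = raw
    df["standardized"] = std
    df["neglog10_p"] = neglog
    df["valid"] = valid
    df["reason"] = reasons
    return ScanResult(test="XP-EHH", population=contrast, table=df)
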