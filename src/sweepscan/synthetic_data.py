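"""Synthetic inputs with known truth for every stage of the pipeline.

Two generators cover the two statistical substrates the analysis runs on:

* an island model of population divergence (Beta-distributed subpopulation
  frequencies around an ancestral frequency, with locus effects α and
  population effects β on logit F_ST) whose planted outliers exercise the
  Bayesian F_ST machinery, and
* a forward Wright–Fisher haplotype simulator with recombination and
  optional positive selection, plus a deterministic sweep injector, which
  exercise the EHH statistics.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .fst_outlier import AlleleCountTable
from .haplo_io import HaplotypePanel, PanelError, SiteInfo


@dataclass
class IslandModelSpec:
    """Island-model divergence with planted locus-specific outliers.

    ``beta`` gives each population's baseline effect on logit F_ST (so
    beta = logit(0.05) yields F_ST ≈ 0.05 at neutral loci); ``outlier_alpha``
    maps locus index → α. Ancestral frequencies are Uniform(anc_low,
    anc_high), mirroring a usable-MAF array spectrum.
    """

    n_pops: int
    n_loci: int
    beta: list[float]
    sample_sizes: list[int]
    outlier_alpha: dict[int, float] = field(default_factory=dict)
    anc_low: float = 0.05
    anc_high: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pops < 2 or self.n_loci < 1:
            raise PanelError("need >= 2 populations and >= 1 locus")
        if len(self.beta) != self.n_pops or len(self.sample_sizes) != self.n_pops:
            raise PanelError("beta and sample_sizes must have one entry per population")
        for i, a in self.outlier_alpha.items():
            if not 0 <= i < self.n_loci:
                raise PanelError(f"outlier locus {i} out of range")
            for b in self.beta:
                f = expit(a + b)
                if not 0 < f < 1:
                    raise PanelError("implied F_ST outside (0,1)")


def simulate_island_model(spec: IslandModelSpec) -> tuple[AlleleCountTable, dict]:
    """Draw per-population allele counts under the island model.

    Per locus i: ancestral frequency p_i ~ Uniform(anc_low, anc_high); per
    population j: F_ST_ij = logistic(α_i + β_j), θ_ij = (1−F)/F,
    subpopulation frequency ~ Beta(θp, θ(1−p)), count ~ Binomial(2n_j, ·).
    Returns the counts plus a truth record with p, α, β and outlier flags.
    """
    rng = np.random.default_rng(spec.seed)
    I, J = spec.n_loci, spec.n_pops
    alpha = np.zeros(I)
    for i, a in spec.outlier_alpha.items():
        alpha[i] = a
    beta = np.asarray(spec.beta, dtype=float)

    p = rng.uniform(spec.anc_low, spec.anc_high, size=I)
    fst = expit(alpha[:, None] + beta[None, :])
    if np.any(fst <= 0) or np.any(fst >= 1):
        raise PanelError("implied F_ST outside (0,1)")
    theta = (1.0 - fst) / fst
    sub_freq = rng.beta(theta * p[:, None], theta * (1.0 - p[:, None]))
    sub_freq = np.clip(sub_freq, 1e-12, 1 - 1e-12)
    n_alleles = 2 * np.asarray(spec.sample_sizes, dtype=np.int64)
    a = rng.binomial(n_alleles[None, :], sub_freq)
    n = np.broadcast_to(n_alleles[None, :], a.shape).copy()

    sites = [
        SiteInfo(chrom="1", pos=int(1000 * (i + 1)), site_id=f"L{i}") for i in range(I)
    ]
    pops = [f"Pop{j + 1}" for j in range(J)]
    truth = {
        "p": p,
        "alpha": alpha,
        "beta": beta,
        "fst": fst,
        "sub_freq": sub_freq,
        "is_outlier": alpha != 0,
    }
    return AlleleCountTable(a=a, n=n, sites=sites, pops=pops), truth


@dataclass
class SweepSpec:
    """Forward Wright–Fisher simulation of ≥1 populations from a common pool.

    Founders carry alleles drawn independently per site from a neutral
    spectrum (density ∝ 1/f truncated to [0.05, 0.95]); ``burn_in``
    (default N_anc) generations of random mating with recombination build
    ancestral LD before the split. Without mutation, heterozygosity decays
    as (1−1/(2N))^g during burn-in, so burn-ins much beyond ~N generations
    drive most of the usable MAF spectrum to fixation; the N-generation
    default keeps ≈60% of founder heterozygosity while establishing
    drift-generated background LD. The default recombination rate is high
    for a per-generation per-bp value because the simulated time depth is
    shallow: it places neutral EHH decay at the ~100-kb scale. Each population then evolves independently for
    ``generations`` generations; allele 1 at ``selected_pos`` confers
    fitness 1+s (het) / 1+2s (hom) in the populations listed in
    ``selected_pops`` (all, when None). When a per-population target
    frequency is set, selection switches off once the target is reached.
    """

    n_haplotypes: list[int]
    chrom_length_bp: int = 25_000_000
    n_sites: int = 1_500
    recomb_rate: float = 2e-7
    selected_pos: int | None = None
    s: float = 0.0
    generations: int = 30
    target_freq: list[float] | None = None
    selected_pops: list[int] | None = None
    n_anc_diploid: int = 200
    burn_in: int | None = None
    spectrum_low: float = 0.05
    spectrum_high: float = 0.95
    max_attempts: int = 10
    chrom: str = "1"
    seed: int = 0

    def __post_init__(self) -> None:
        if any(h < 2 or h % 2 for h in self.n_haplotypes):
            raise PanelError("n_haplotypes entries must be even and >= 2")
        if self.selected_pos is not None and not 1 <= self.selected_pos <= self.chrom_length_bp:
            raise PanelError("selected position outside chromosome")
        if self.target_freq is not None:
            if len(self.target_freq) != len(self.n_haplotypes):
                raise PanelError("one target frequency per population")
            if any(not 0 <= f <= 1 for f in self.target_freq):
                raise PanelError("target frequencies must lie in [0,1]")


def _spectrum_freqs(rng: np.random.Generator, n: int, lo: float, hi: float) -> np.ndarray:
    """Frequencies with density ∝ 1/f on [lo, hi] (inverse-CDF sampling)."""
    u = rng.random(n)
    return lo * (hi / lo) ** u


def _gametes(
    haps: np.ndarray,
    parent_pairs: np.ndarray,
    positions: np.ndarray,
    chrom_length: int,
    recomb_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One gamete per parent pair via Poisson crossovers at uniform positions."""
    n_off = parent_pairs.shape[0]
    L = haps.shape[1]
    out = np.empty((n_off, L), dtype=np.uint8)
    n_cross = rng.poisson(recomb_rate * chrom_length, size=n_off)
    start_hap = rng.integers(0, 2, size=n_off)
    for k in range(n_off):
        h0 = haps[parent_pairs[k, start_hap[k]]]
        if n_cross[k] == 0:
            out[k] = h0
            continue
        h1 = haps[parent_pairs[k, 1 - start_hap[k]]]
        cuts = np.sort(rng.uniform(0, chrom_length, size=n_cross[k]))
        parity = np.searchsorted(cuts, positions) % 2
        out[k] = np.where(parity == 0, h0, h1)
    return out


def _evolve(
    haps: np.ndarray,
    n_gen: int,
    positions: np.ndarray,
    chrom_length: int,
    recomb_rate: float,
    rng: np.random.Generator,
    sel_idx: int | None = None,
    s: float = 0.0,
    target: float | None = None,
) -> tuple[np.ndarray, list[float]]:
    """Random-mating WF evolution of a diploid population of fixed size.

    ``haps`` has 2N rows; haplotypes 2k, 2k+1 form diploid k. Returns the
    final haplotypes and the selected-allele frequency trajectory.
    """
    n_hap = haps.shape[0]
    n_dip = n_hap // 2
    traj: list[float] = []
    selecting = sel_idx is not None and s != 0.0
    for _ in range(n_gen):
        if sel_idx is not None:
            freq = float(haps[:, sel_idx].mean())
            traj.append(freq)
        if selecting and target is not None and traj and traj[-1] >= target:
            selecting = False
        if selecting:
            dos = haps[0::2, sel_idx].astype(float) + haps[1::2, sel_idx].astype(float)
            w = 1.0 + s * dos
            w = np.maximum(w, 0.0)
            probs = w / w.sum()
        else:
            probs = None
        parents = rng.choice(n_dip, size=(n_hap, 1), p=probs)
        pairs = np.concatenate([2 * parents, 2 * parents + 1], axis=1)
        haps = _gametes(haps, pairs, positions, chrom_length, recomb_rate, rng)
    if sel_idx is not None:
        traj.append(float(haps[:, sel_idx].mean()))
    return haps, traj


def simulate_wf_sweep(spec: SweepSpec) -> tuple[HaplotypePanel, dict]:
    """Simulate phased panels for each population, with known truth.

    Returns a combined panel (populations labelled Pop1…PopK) plus a truth
    record: site positions, the selected site index, founder frequencies and
    per-population selected-allele trajectories. If the selected allele is
    lost in a population under selection, the whole simulation retries with
    a fresh substream, up to ``max_attempts``.
    """
    for attempt in range(spec.max_attempts):
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, attempt]))
        result = _simulate_once(spec, rng)
        if result is not None:
            return result
    raise PanelError(
        f"selected allele lost in every one of {spec.max_attempts} attempts"
    )


def _simulate_once(spec: SweepSpec, rng: np.random.Generator):
    # site map: distinct integer positions, selected site forced onto the map
    pos = np.sort(
        rng.choice(spec.chrom_length_bp, size=spec.n_sites, replace=False) + 1
    ).astype(np.int64)
    sel_idx: int | None = None
    if spec.selected_pos is not None:
        sel_idx = int(np.argmin(np.abs(pos - spec.selected_pos)))
        pos[sel_idx] = spec.selected_pos
        pos = np.sort(np.unique(pos))
        if len(pos) < spec.n_sites:  # collision after the move: resample extras
            extra = rng.choice(spec.chrom_length_bp, size=spec.n_sites, replace=False) + 1
            pos = np.sort(np.unique(np.concatenate([pos, extra])))[: spec.n_sites]
        sel_idx = int(np.searchsorted(pos, spec.selected_pos))

    founder_freq = _spectrum_freqs(
        rng, len(pos), spec.spectrum_low, spec.spectrum_high
    )
    n_anc_hap = 2 * spec.n_anc_diploid
    haps = (rng.random((n_anc_hap, len(pos))) < founder_freq).astype(np.uint8)

    burn = spec.burn_in if spec.burn_in is not None else spec.n_anc_diploid
    haps, _ = _evolve(
        haps, burn, pos, spec.chrom_length_bp, spec.recomb_rate, rng
    )

    if sel_idx is not None and not 0 < haps[:, sel_idx].mean() < 1:
        return None  # selected allele fixed or lost during burn-in

    panels: list[np.ndarray] = []
    trajs: list[list[float]] = []
    selected_pops = (
        set(spec.selected_pops)
        if spec.selected_pops is not None
        else set(range(len(spec.n_haplotypes)))
    )
    for j, n_hap in enumerate(spec.n_haplotypes):
        # found population j by sampling diploids (with replacement) from the pool
        founders = rng.choice(spec.n_anc_diploid, size=n_hap // 2)
        pop = haps[np.concatenate([2 * founders, 2 * founders + 1]).reshape(2, -1).T.ravel()]
        use_sel = sel_idx if (j in selected_pops and spec.s != 0.0) else None
        target = spec.target_freq[j] if spec.target_freq is not None else None
        pop, traj = _evolve(
            pop,
            spec.generations,
            pos,
            spec.chrom_length_bp,
            spec.recomb_rate,
            rng,
            sel_idx=sel_idx,
            s=spec.s if use_sel is not None else 0.0,
            target=target,
        )
        if use_sel is not None and pop[:, sel_idx].sum() == 0:
            return None  # selected allele lost under selection
        panels.append(pop)
        trajs.append(traj)

    alleles = np.concatenate(panels, axis=0)
    samples: list[str] = []
    sample_pop: dict[str, str] = {}
    for j, n_hap in enumerate(spec.n_haplotypes):
        pname = f"Pop{j + 1}"
        for k in range(n_hap // 2):
            sid = f"{pname}_s{k}"
            samples.append(sid)
            sample_pop[sid] = pname
    sites = [
        SiteInfo(chrom=spec.chrom, pos=int(p), site_id=f"{spec.chrom}:{int(p)}")
        for p in pos
    ]
    panel = HaplotypePanel(
        alleles=alleles, samples=samples, sample_pop=sample_pop, sites=sites
    )
    truth = {
        "positions": pos,
        "selected_index": sel_idx,
        "selected_pos": None if sel_idx is None else int(pos[sel_idx]),
        "founder_freq": founder_freq,
        "trajectories": trajs,
    }
    return panel, truth


def central_polymorphic_site(panel: HaplotypePanel, min_maf: float = 0.2) -> int:
    """Position of the most central site with MAF ≥ ``min_maf``.

    Sweeps are planted on standing variants at usable frequency; this picks
    the natural core for injection. Raises if no site qualifies.
    """
    freq = panel.alleles.mean(axis=0)
    maf = np.minimum(freq, 1.0 - freq)
    ok = np.flatnonzero(maf >= min_maf)
    if len(ok) == 0:
        raise PanelError(f"no site with MAF >= {min_maf}")
    centre = (len(panel.sites) - 1) / 2.0
    best = ok[np.argmin(np.abs(ok - centre))]
    return int(panel.sites[int(best)].pos)


def inject_sweep(
    panel: HaplotypePanel,
    core_pos: int,
    carrier_fraction: float,
    taper_bp: float,
    seed: int = 0,
) -> tuple[HaplotypePanel, dict]:
    """Copy a donor haplotype onto a fraction of haplotypes around a core.

    Each carrier takes the donor's alleles over a window centred on
    ``core_pos`` whose per-side half-width is Exponential(mean
    ``taper_bp``); all carriers share the donor allele at the core. This is
    a deterministic stand-in for a partial sweep, useful when the EHH signal
    must sit at a known position with a known carrier frequency.
    """
    if not 0 < carrier_fraction <= 1:
        raise PanelError("carrier_fraction must lie in (0,1]")
    positions = panel.positions
    match = np.flatnonzero(positions == core_pos)
    if len(match) != 1:
        raise PanelError(f"core position {core_pos} not on the site map")
    core = int(match[0])
    chrom = panel.sites[core].chrom

    rng = np.random.default_rng(seed)
    n = panel.n_haplotypes
    # prefer a donor carrying the minor core allele: a sweep lifts a rare
    # haplotype, and this keeps the core site polymorphic after injection
    core_col = panel.alleles[:, core]
    minor = 1 if core_col.mean() < 0.5 else 0
    pool = np.flatnonzero(core_col == minor)
    if len(pool) == 0:
        pool = np.arange(n)
    donor = int(rng.choice(pool))
    n_carriers = max(2, int(round(carrier_fraction * n)))
    order = rng.permutation(n)
    carriers = order[order != donor][: n_carriers - 1]

    alleles = panel.alleles.copy()
    on_chrom = panel.chroms == chrom
    for h in carriers:
        left = rng.exponential(taper_bp)
        right = rng.exponential(taper_bp)
        window = (
            on_chrom
            & (positions >= core_pos - left)
            & (positions <= core_pos + right)
        )
        alleles[h, window] = panel.alleles[donor, window]
        alleles[h, core] = panel.alleles[donor, core]
    out = HaplotypePanel(
        alleles=alleles,
        samples=list(panel.samples),
        sample_pop=dict(panel.sample_pop),
        sites=list(panel.sites),
    )
    truth = {
        "donor": donor,
        "carriers": np.concatenate([[donor], carriers]),
        "core_index": core,
        "core_pos": core_pos,
    }
    return out, truth
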