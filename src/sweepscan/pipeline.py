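"""End-to-end orchestration: simulate/load → QC → summaries → scans → regions.

A single YAML config drives the run; all randomness flows from one
top-level seed through named substreams per stage, so identical config +
seed gives byte-identical outputs. The run manifest records the config
hash, seed, and package/library versions.
"""

from __future__ import annotations

import hashlib
import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import ehh_scan, fst_outlier, popgen_summaries, qc_filters, region_caller
from .haplo_io import (
    HaplotypePanel,
    PanelError,
    attach_populations,
    read_phased_vcf,
    read_pop_map,
    subset_by_population,
    write_phased_vcf,
    write_pop_map,
    write_regions_bed,
    write_scan_table,
)
from .synthetic_data import SweepSpec, inject_sweep, simulate_wf_sweep

_STAGES = ("diversity", "ld_decay", "pca", "ihs", "xpehh", "bayescan", "regions")


def _substream(seed: int, name: str) -> int:
    """Deterministic per-stage seed below 2**31 derived from the master seed."""
    h = hashlib.sha256(f"{seed}:{name}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def load_inputs(config: dict, seed: int) -> HaplotypePanel:
    """Materialize the input panel: read a VCF+map or run the simulator."""
    if "input" in config:
        panel, _ = read_phased_vcf(config["input"]["vcf"])
        mapping, _ = read_pop_map(config["input"]["pop_map"])
        return attach_populations(panel, mapping)
    if "simulate" not in config:
        raise PanelError("config needs an 'input' or 'simulate' section")
    sim = dict(config["simulate"])
    inject = sim.pop("inject_sweep", None)
    sim.setdefault("seed", _substream(seed, "simulate"))
    spec = SweepSpec(**sim)
    panel, _ = simulate_wf_sweep(spec)
    if inject:
        inj = dict(inject)
        pop = inj.pop("population", None)
        inj.setdefault("seed", _substream(seed, "inject"))
        if pop is None:
            panel, _ = inject_sweep(panel, **inj)
        else:
            sub = subset_by_population(panel, pop)
            swept, _ = inject_sweep(sub, **inj)
            rows = panel.haplotype_rows(pop)
            alleles = panel.alleles.copy()
            alleles[rows, :] = swept.alleles
            panel = HaplotypePanel(
                alleles=alleles,
                samples=list(panel.samples),
                sample_pop=dict(panel.sample_pop),
                sites=list(panel.sites),
            )
    return panel


def run_full_pipeline(config: dict | str | Path, outdir: str | Path) -> Path:
    """Run the configured stages and write all outputs under ``outdir``.

    Returns the output directory. Fails before any compute when a contrast
    names an unknown population.
    """
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text())
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    stages = config.get("stages", list(_STAGES))
    contrasts = [tuple(c) for c in config.get("contrasts", [])]
    thresholds = config.get("thresholds", {})
    neglogp_min = float(thresholds.get("neglog10_p", 3.0))
    po_min = float(thresholds.get("posterior_odds", 32.0))
    max_gap_bp = int(thresholds.get("max_gap_bp", 500_000))
    min_snps = int(thresholds.get("min_snps", 2))

    panel = load_inputs(config, seed)
    pops = panel.populations
    for obs, ref in contrasts:
        for p in (obs, ref):
            if p not in pops:
                raise PanelError(f"contrast population {p!r} not in panel ({pops})")
    need_scans = {"ihs", "xpehh", "bayescan"} & set(stages)
    if need_scans and not contrasts and "ihs" not in stages:
        raise PanelError("scan stages need contrasts in the config")

    write_phased_vcf(panel, str(outdir / "panel.vcf"))
    write_pop_map(panel.sample_pop, panel.samples, str(outdir / "pop_map.tsv"))

    gm = panel.to_genotype_matrix()
    qc_cfg = config.get("qc", {})
    scan_gm, scan_reports = qc_filters.scan_profile(
        gm, min_maf=float(qc_cfg.get("min_maf", 0.05)), scope=qc_cfg.get("maf_scope", "pooled")
    )
    reports = list(scan_reports)
    keep_ids = {s.site_id for s in scan_gm.sites}
    keep_idx = np.asarray([i for i, s in enumerate(panel.sites) if s.site_id in keep_ids])
    scan_panel = panel.subset_sites(keep_idx)

    if "diversity" in stages:
        rows = []
        summaries = popgen_summaries.heterozygosity_summary(gm)
        for s in summaries:
            rows.append(
                {
                    "population": s.population,
                    "mean_h_obs": round(s.mean_h_obs, 6),
                    "sd_h_obs": round(s.sd_h_obs, 6),
                    "mean_h_exp": round(s.mean_h_exp, 6),
                    "sd_h_exp": round(s.sd_h_exp, 6),
                }
            )
        h, p = popgen_summaries.kruskal_wallis([s.h_obs for s in summaries])
        pd.DataFrame(rows).to_csv(outdir / "diversity.tsv", sep="\t", index=False)
        (outdir / "diversity_test.json").write_text(
            json.dumps({"kruskal_H": round(h, 6), "p_value": float(f"{p:.6g}")}) + "\n"
        )

    if "ld_decay" in stages:
        frames = []
        for pop in pops:
            prof = popgen_summaries.ld_decay_profile(gm, pop)
            f = prof.to_frame()
            f.insert(0, "population", pop)
            frames.append(f)
        pd.concat(frames).to_csv(
            outdir / "ld_decay.tsv", sep="\t", index=False, float_format="%.6g"
        )

    if "pca" in stages:
        structure_gm, st_reports = qc_filters.structure_profile(gm)
        reports.extend(st_reports)
        coords, frac = popgen_summaries.pca_genotypes(structure_gm, n_components=10)
        dfc = pd.DataFrame(coords, columns=[f"PC{i+1}" for i in range(coords.shape[1])])
        dfc.insert(0, "sample_id", structure_gm.samples)
        dfc.insert(1, "population", [structure_gm.sample_pop[s] for s in structure_gm.samples])
        dfc.to_csv(outdir / "pca.tsv", sep="\t", index=False, float_format="%.6g")
        pd.DataFrame({"component": np.arange(1, len(frac) + 1), "var_frac": frac}).to_csv(
            outdir / "pca_variance.tsv", sep="\t", index=False, float_format="%.6g"
        )

    ihs_cfg = ehh_scan.IhsConfig(**config.get("ehh", {}))
    all_regions: list = []

    if "ihs" in stages:
        for pop in pops:
            sub = subset_by_population(scan_panel, pop)
            res = ehh_scan.ihs_scan(sub, ihs_cfg, population=pop)
            write_scan_table(res, str(outdir / f"ihs_{pop}.tsv"))
            if "regions" in stages:
                sig = region_caller.call_significant(res, neglogp_min=neglogp_min)
                all_regions += region_caller.cluster_regions(
                    sig, population=pop, test="iHS", max_gap_bp=max_gap_bp, min_snps=min_snps
                )

    if "xpehh" in stages:
        for obs, ref in contrasts:
            res = ehh_scan.xpehh_scan(
                subset_by_population(scan_panel, obs),
                subset_by_population(scan_panel, ref),
                ihs_cfg,
                contrast=f"{obs}/{ref}",
            )
            write_scan_table(res, str(outdir / f"xpehh_{obs}_vs_{ref}.tsv"))
            if "regions" in stages:
                sig = region_caller.call_significant(res, neglogp_min=neglogp_min)
                all_regions += region_caller.cluster_regions(
                    sig,
                    population=f"{obs}/{ref}",
                    test="XP-EHH",
                    max_gap_bp=max_gap_bp,
                    min_snps=min_snps,
                )

    if "bayescan" in stages:
        mcmc_kwargs = dict(config.get("mcmc", {}))
        for obs, ref in contrasts:
            counts = fst_outlier.counts_from_genotypes(scan_gm, [obs, ref])
            kwargs = dict(mcmc_kwargs)
            kwargs.setdefault("seed", _substream(seed, f"bayescan:{obs}:{ref}"))
            mcfg = fst_outlier.McmcConfig(**kwargs)
            chain = fst_outlier.rjmcmc_run(counts, mcfg)
            summary = fst_outlier.posterior_summaries(chain, mcfg, po_threshold=po_min)
            loci = summary.loci.copy()
            loci.insert(0, "chrom", [s.chrom for s in counts.sites])
            loci.insert(1, "pos", [s.pos for s in counts.sites])
            loci.insert(2, "site_id", [s.site_id for s in counts.sites])
            loci.to_csv(
                outdir / f"bayescan_{obs}_vs_{ref}.tsv",
                sep="\t",
                index=False,
                float_format="%.6g",
            )
            summary.populations.to_csv(
                outdir / f"bayescan_{obs}_vs_{ref}_pops.tsv",
                sep="\t",
                index=False,
                float_format="%.6g",
            )
            if "regions" in stages:
                res = fst_scan_result(counts, summary, contrast=f"{obs}/{ref}")
                sig = region_caller.call_significant(res, po_min=po_min)
                all_regions += region_caller.cluster_regions(
                    sig,
                    population=f"{obs}/{ref}",
                    test="FST-outlier",
                    max_gap_bp=max_gap_bp,
                    min_snps=min_snps,
                )

    if "regions" in stages:
        all_regions.sort(key=lambda r: (r.test, r.population, r.chrom, r.start))
        region_caller.regions_to_frame(all_regions).to_csv(
            outdir / "regions.tsv", sep="\t", index=False, float_format="%.6g"
        )
        by_key: dict[tuple, list] = {}
        for r in all_regions:
            by_key.setdefault((r.test, r.population), []).append(r)
        merged_all = []
        for key, regs in by_key.items():
            regs.sort(key=lambda r: (r.chrom, r.start))
            merged_all += region_caller.merge_regions(regs)
        merged_all.sort(key=lambda r: (r.chrom, r.start, r.test, r.population))
        write_regions_bed(merged_all, str(outdir / "regions.bed"))

    manifest = {
        "config_hash": _config_hash(config),
        "seed": seed,
        "versions": {
            "sweepscan": __version__,
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "n_samples": len(panel.samples),
        "n_sites_input": panel.n_sites,
        "n_sites_scan": scan_gm.n_sites,
        "filters": [
            {
                "stage": r.stage,
                "n_in": r.n_in,
                "n_out": r.n_out,
                "threshold": r.threshold,
            }
            for r in reports
        ],
        "stages": list(stages),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return outdir


def fst_scan_result(counts, summary, contrast: str = ""):
    """Adapt a PosteriorSummary to the common ScanResult layout.

    ``raw`` holds the posterior odds, ``standardized`` the posterior mean α,
    and ``neglog10_p`` −log10 q.
    """
    from .haplo_io import SCAN_COLUMNS, ScanResult

    q = summary.loci["q"].to_numpy()
    neglog_q = -np.log10(np.maximum(q, 1e-300))
    df = pd.DataFrame(
        {
            "chrom": [s.chrom for s in counts.sites],
            "pos": [s.pos for s in counts.sites],
            "site_id": [s.site_id for s in counts.sites],
            "raw": summary.loci["PO"].to_numpy(),
            "standardized": summary.loci["alpha_mean"].to_numpy(),
            "neglog10_p": neglog_q,
            "valid": True,
            "reason": "",
        },
        columns=SCAN_COLUMNS,
    )
    return ScanResult(test="FST-outlier", population=contrast, table=df)
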