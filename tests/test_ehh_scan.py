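"""EHH statistics: profiles, integration, iHS, XP-EHH, p-value mapping."""

import numpy as np
import pytest

from sweepscan.ehh_scan import (
    EHHProfile,
    IhsConfig,
    ehh_profile,
    ihs_scan,
    integrate_ehh,
    neglog10_p_from_z,
    xpehh_scan,
)
from sweepscan.haplo_io import PanelError
from sweepscan.synthetic_data import (
    SweepSpec,
    inject_sweep,
    simulate_wf_sweep,
)

from conftest import brute_force_ehh, make_panel


class TestEhhProfile:
    def test_identical_haplotypes_keep_ehh_at_one(self):
        panel = make_panel(np.tile([0, 1, 0, 1, 1], (6, 1)))
        prof = ehh_profile(panel, 2, "site")
        assert np.all(prof.right_ehh == 1.0)
        assert np.all(prof.left_ehh == 1.0)
        assert prof.right_stop == "chrom_end"

    def test_partition_2_1_1_gives_one_sixth(self):
        # 4 carriers of allele 0 at the core split {2,1,1} two markers on
        alleles = np.array(
            [
                [0, 0, 0],
                [0, 0, 0],
                [0, 1, 0],
                [0, 1, 1],
                [1, 0, 0],
                [1, 0, 0],
            ]
        )
        panel = make_panel(alleles)
        prof = ehh_profile(panel, 0, 0, ehh_cutoff=0.01)
        # marker 2: groups {(0,0),(0,0)}, {(1,0)}, {(1,1)} -> C(2,2)/C(4,2)
        assert prof.right_ehh[1] == pytest.approx(1 / 6)

    def test_integration_anchors_at_core_with_ehh_one(self):
        # a profile dropping straight below cutoff still integrates the
        # interpolated wedge from (0 bp, EHH = 1)
        alleles = np.array(
            [
                [0, 0, 0],
                [1, 0, 1],
                [0, 0, 0],
                [1, 0, 1],
                [0, 1, 1],
                [1, 1, 0],
            ]
        )
        prof = ehh_profile(make_panel(alleles), 1, 0, ehh_cutoff=0.5)
        # 4 carriers split {2,2} one marker out on each side: EHH = 1/3 < 0.5
        assert prof.right_ehh[0] == pytest.approx(1 / 3)
        assert prof.left_ehh[0] == pytest.approx(1 / 3)
        ihh, ok, _ = integrate_ehh(prof, cutoff=0.5)
        frac = (1 - 0.5) / (1 - 1 / 3)
        assert ok
        assert ihh == pytest.approx(2 * 0.5 * (1 + 0.5) * 1000 * frac, rel=1e-9)

    def test_single_carrier_is_invalid(self):
        alleles = np.zeros((6, 3), dtype=int)
        alleles[0, 1] = 1
        panel = make_panel(alleles)
        prof = ehh_profile(panel, 1, 1)
        assert not prof.valid
        assert "carriers" in prof.reason

    @pytest.mark.parametrize("target", [0, 1, "site"])
    def test_matches_brute_force_oracle(self, target):
        rng = np.random.default_rng(5)
        for _ in range(25):
            n_hap = 2 * rng.integers(3, 13)
            n_sites = rng.integers(5, 40)
            alleles = (rng.random((n_hap, n_sites)) < rng.uniform(0.2, 0.8)).astype(int)
            core = int(rng.integers(n_sites))
            oracle = brute_force_ehh(make_panel(alleles), core, target)
            prof = ehh_profile(make_panel(alleles), core, target)
            if oracle is None:
                assert not prof.valid
                continue
            le, re = oracle
            assert np.allclose(prof.left_ehh, le)
            assert np.allclose(prof.right_ehh, re)

    def test_ehh_is_non_increasing_outward(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            alleles = rng.integers(0, 2, size=(24, 50))
            panel = make_panel(alleles)
            prof = ehh_profile(panel, 25, "site", ehh_cutoff=1e-9)
            for arr in (prof.left_ehh, prof.right_ehh):
                assert np.all(np.diff(arr) <= 1e-12)


class TestIntegrateEhh:
    def _profile(self, pos, ehh, stop="cutoff"):
        return EHHProfile(
            core_index=0, core_pos=0, target=0, n_carriers=10,
            left_pos=np.array([], dtype=np.int64), left_ehh=np.array([]),
            right_pos=np.asarray(pos, dtype=np.int64), right_ehh=np.asarray(ehh, float),
            left_stop="cutoff", right_stop=stop,
        )

    def test_hand_computed_trapezoid_with_interpolated_cutoff(self):
        prof = self._profile([10_000, 20_000], [0.5, 0.04])
        ihh, ok, _ = integrate_ehh(prof, cutoff=0.05)
        dx = 10_000 * (0.5 - 0.05) / (0.5 - 0.04)
        expected = 7_500 + 0.5 * (0.5 + 0.05) * dx
        assert ok
        assert ihh == pytest.approx(expected, abs=0.1)
        assert ihh == pytest.approx(10190.2, abs=0.1)

    def test_side_not_reaching_cutoff_is_invalid(self):
        prof = self._profile([10_000, 20_000], [0.9, 0.8], stop="chrom_end")
        ihh, ok, reason = integrate_ehh(prof)
        assert not ok
        assert reason == "uncapped decay"

    def test_doubling_distances_doubles_integral(self):
        p1 = self._profile([5_000, 10_000, 15_000], [0.6, 0.3, 0.02])
        p2 = self._profile([10_000, 20_000, 30_000], [0.6, 0.3, 0.02])
        i1, ok1, _ = integrate_ehh(p1)
        i2, ok2, _ = integrate_ehh(p2)
        assert ok1 and ok2
        assert i2 == pytest.approx(2 * i1)


class TestNeglog10P:
    @pytest.mark.parametrize(
        "z,expected",
        [
            (3.8634, 3.9515),
            (-5.0365, 6.324),
            (0.0, 0.0),
        ],
    )
    def test_two_sided_mapping_matches_printed_values(self, z, expected):
        assert neglog10_p_from_z(z) == pytest.approx(expected, abs=5e-4)

    def test_one_tailed_option(self):
        from scipy.stats import norm

        z = 2.5
        assert neglog10_p_from_z(z, two_sided=False) == pytest.approx(
            -np.log10(norm.sf(z)), abs=1e-10
        )

    def test_extreme_scores_keep_precision(self):
        # far beyond where 1 - CDF would round to zero in float64
        val = neglog10_p_from_z(40.0)
        assert 340 < val < 360

    def test_non_finite_raises(self):
        with pytest.raises(PanelError):
            neglog10_p_from_z(float("nan"))


class TestIhsScan:
    def test_mirror_symmetric_panel_gives_zero_raw_score(self):
        # carriers of allele 0 and allele 1 have identical internal structure
        # (pairs at distance one, singletons at distance two) so the two iHH
        # integrals coincide and the log-ratio vanishes
        blockA = np.array(
            [
                [0, 0, 0, 0, 0, 0, 0],
                [0, 1, 0, 0, 0, 1, 0],
                [0, 0, 1, 0, 1, 0, 0],
                [0, 1, 1, 0, 1, 1, 0],
            ]
        )
        blockB = blockA.copy()
        blockB[:, 3] = 1  # same flank structure, opposite core allele
        panel = make_panel(np.vstack([blockA, blockB]))
        cfg = IhsConfig(maf_min=0.01, ehh_cutoff=0.05)
        res = ihs_scan(panel, cfg)
        core_row = res.table.iloc[3]
        assert core_row["raw"] == pytest.approx(0.0, abs=1e-12)

    def test_scores_invariant_to_sample_relabeling(self):
        spec = SweepSpec(
            n_haplotypes=[60], chrom_length_bp=6_000_000, n_sites=300,
            recomb_rate=4e-7, n_anc_diploid=80, burn_in=80, generations=15, seed=3,
        )
        panel, _ = simulate_wf_sweep(spec)
        res1 = ihs_scan(panel, IhsConfig())
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(panel.samples))
        rows = np.concatenate([[2 * i, 2 * i + 1] for i in perm])
        shuffled = make_panel(panel.alleles[rows], positions=panel.positions)
        res2 = ihs_scan(shuffled, IhsConfig())
        assert np.allclose(
            res1.table["raw"].to_numpy(), res2.table["raw"].to_numpy(), equal_nan=True
        )
        assert np.allclose(
            res1.table["standardized"].to_numpy(),
            res2.table["standardized"].to_numpy(),
            equal_nan=True,
        )

    def test_low_maf_sites_are_flagged(self):
        alleles = np.zeros((20, 5), dtype=int)
        alleles[0, 2] = 1  # MAF 0.05 exactly -> excluded (strict >)
        res = ihs_scan(make_panel(alleles), IhsConfig())
        assert not res.table["valid"][2]
        assert res.table["reason"][2] == "maf"

    def test_neutral_panel_calibration_and_tail(self):
        """Standardized scores are ~N(0,1) and the far tail is not inflated.

        Scaled-down version of the genome-scan calibration: several small
        neutral panels pooled.
        """
        stds = []
        for seed in (21, 22, 23, 24):
            spec = SweepSpec(
                n_haplotypes=[120], chrom_length_bp=13_000_000, n_sites=800,
                recomb_rate=2e-7, n_anc_diploid=150, burn_in=150,
                generations=30, seed=seed,
            )
            panel, _ = simulate_wf_sweep(spec)
            res = ihs_scan(panel, IhsConfig())
            t = res.table
            stds.append(t.loc[t["valid"], "standardized"].to_numpy())
        z = np.concatenate(stds)
        assert len(z) > 800
        assert abs(z.mean()) < 0.05
        assert 0.9 < z.std(ddof=1) < 1.1
        assert (np.abs(z) >= 3.2905) .mean() <= 0.005  # two-sided p <= 0.001


class TestXpehhScan:
    def test_identical_panels_give_zero_raw_scores(self):
        spec = SweepSpec(
            n_haplotypes=[40], chrom_length_bp=4_000_000, n_sites=200,
            recomb_rate=4e-7, n_anc_diploid=60, burn_in=60, generations=10, seed=5,
        )
        panel, _ = simulate_wf_sweep(spec)
        res = xpehh_scan(panel, panel, IhsConfig())
        raw = res.table.loc[res.table["raw"].notna(), "raw"]
        assert np.allclose(raw, 0.0, atol=1e-12)

    def test_swapping_populations_negates_raw_scores(self):
        spec = SweepSpec(
            n_haplotypes=[40, 40], chrom_length_bp=4_000_000, n_sites=200,
            recomb_rate=4e-7, n_anc_diploid=60, burn_in=60, generations=10, seed=6,
        )
        panel, _ = simulate_wf_sweep(spec)
        from sweepscan import subset_by_population

        a = subset_by_population(panel, "Pop1")
        b = subset_by_population(panel, "Pop2")
        r_ab = xpehh_scan(a, b, IhsConfig()).table["raw"].to_numpy()
        r_ba = xpehh_scan(b, a, IhsConfig()).table["raw"].to_numpy()
        assert np.allclose(r_ab, -r_ba, equal_nan=True)

    def test_mismatched_site_lists_raise(self):
        p1 = make_panel(np.zeros((4, 3)), positions=[100, 200, 300])
        p2 = make_panel(np.zeros((4, 3)), positions=[100, 200, 400])
        with pytest.raises(PanelError, match="identical site list"):
            xpehh_scan(p1, p2)


class TestInjectedSweepDetection:
    """Monte-Carlo behaviour of the scanners on deterministic injected sweeps."""

    def _panel(self, seed, two_pops=False):
        spec = SweepSpec(
            n_haplotypes=[100, 100] if two_pops else [100],
            chrom_length_bp=8_000_000, n_sites=2000, recomb_rate=1e-6,
            n_anc_diploid=150, burn_in=150, generations=30, seed=seed,
        )
        panel, _ = simulate_wf_sweep(spec)
        return panel

    @staticmethod
    def _core(panel):
        f = panel.alleles.mean(axis=0)
        maf = np.minimum(f, 1 - f)
        cand = np.flatnonzero((maf > 0.05) & (maf < 0.25))
        centre = panel.n_sites / 2
        idx = int(cand[np.argmin(np.abs(cand - centre))])
        return idx, int(panel.positions[idx])

    def test_ihs_ranks_injected_core_near_the_top(self):
        hits = 0
        seeds = range(6)
        for seed in seeds:
            panel = self._panel(seed)
            core_idx, core_pos = self._core(panel)
            swept, _ = inject_sweep(panel, core_pos, 0.5, 500_000, seed=seed + 50)
            res = ihs_scan(swept, IhsConfig())
            t = res.table
            if not t["valid"][core_idx]:
                continue
            v = t[t["valid"]]
            rank = (v["standardized"].abs() >= abs(t["standardized"][core_idx])).mean()
            hits += rank <= 0.05
        assert hits >= 5

    def test_xpehh_flags_sweep_in_observed_population_only(self):
        hits = 0
        seeds = range(6)
        for seed in seeds:
            panel = self._panel(seed, two_pops=True)
            from sweepscan import subset_by_population

            ref = subset_by_population(panel, "Pop1")
            obs = subset_by_population(panel, "Pop2")
            core_idx, core_pos = self._core(obs)
            swept, _ = inject_sweep(obs, core_pos, 0.8, 500_000, seed=seed + 50)
            res = xpehh_scan(swept, ref, IhsConfig())
            t = res.table
            if not t["valid"][core_idx]:
                continue
            v = t[t["valid"]]
            z = t["standardized"][core_idx]
            rank = (v["standardized"] >= z).mean()
            hits += (z > 0) and rank <= 0.10
        assert hits >= 5
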