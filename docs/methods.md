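# Methods

`sweepscan` detects signatures of recent positive selection in phased SNP-array
panels from structured populations, using three complementary statistics:
within-population iHS, cross-population XP-EHH, and a Bayesian F_ST outlier
model. This note records the models, the numerical conventions, the synthetic
data the package is validated on, and the design choices that were genuinely
open.

## Haplotype statistics

### EHH

For a core SNP and a carrier set C of n haplotypes (the carriers of one core
allele, or all haplotypes for the "site" variant), the extended haplotype
homozygosity at marker t is

    EHH(t) = Σ_g C(k_g, 2) / C(n, 2),

where the k_g are the sizes of the groups of haplotypes identical at every
marker from the core out to t (the core allele included). EHH equals 1 at the
core by definition and is non-increasing outward. The implementation walks
outward refining an integer partition label per haplotype (label ← 2·label +
allele, relabelled via `np.unique` each step), which is O(n) per marker; a
brute-force oracle that hashes full core-to-marker haplotype strings verifies
it exactly in the test suite.

### iHH and truncation

iHH is the trapezoid integral of EHH against physical distance (bp), taken on
each side from the core out to the point where EHH crosses the cutoff
(default 0.05); the crossing is linearly interpolated inside the last
segment, which reduces sensitivity to marker spacing. A side that reaches the
chromosome end (or the optional `max_extension_bp` cap) while EHH is still at
or above the cutoff makes the integral non-comparable across sites; such
sites are flagged invalid ("uncapped decay") rather than extrapolated.
Distances are physical only — array panels rarely come with a reliable
genetic map.

### iHS

Raw score: ln(iHH_major / iHH_minor). The major allele stands in for the
ancestral state, the standard fallback when no outgroup polarization exists;
a frequency tie at exactly 0.5 resolves deterministically to allele 0 (REF).
Raw scores are standardized to z-scores within minor-allele-frequency bins
(width 0.025; bins holding fewer than 10 valid scores are merged into the
nearest occupied bin; sample SD with ddof=1), because the expected magnitude
of ln(iHH ratio) depends strongly on allele frequency.

### XP-EHH

Per shared site, the site-EHH (all haplotypes, core allele included in the
identity requirement) is integrated within each population and the raw score
is ln(I_obs / I_ref). Positive standardized scores indicate candidate
selection in the observed population, negative in the reference.
Standardization is genome-wide over valid sites (a single mean/SD), not
frequency-binned — the statistic is already a between-population contrast at
a common frequency.

### p-value convention

Standardized scores map to −log10(2(1−Φ(|z|))) — the two-sided normal tail —
computed through the log-survival function so that |z| of 30+ loses no
precision. Although scans of this kind are sometimes described as one-tailed,
the two-sided form is the one whose (score, −log p) pairs reproduce published
tables to the printed precision, and is the default; a one-tailed option sits
behind a flag.

## Bayesian F_ST outlier model

Allele counts a_ij (allele 1 of n_ij sampled alleles at locus i in
population j) follow a beta-binomial: the subpopulation frequency is
Beta(θ_ij p_i, θ_ij (1−p_i)) around an ancestral frequency p_i, with
θ_ij = (1−F_ST_ij)/F_ST_ij, and

    logit(F_ST_ij) = α_i + β_j,

a locus effect (selection) plus a population effect (drift/demography).
A reversible-jump MCMC toggles a per-locus indicator δ_i (δ_i = 0 forces
α_i = 0):

* p_i — logit-space random walk, uniform prior on (0,1) (the Jacobian term
  p(1−p) is included);
* α_i (active loci) — random walk with a Normal(0, 1) prior;
* β_j — random walk with a Normal(−1, 1.8) prior;
* δ_i — toggle with α proposed from its prior on birth (the proposal density
  cancels the prior, so the move needs no Jacobian), with prior inclusion
  probability 1/(1+prior_odds), prior_odds = 10 by default.

Proposal scales adapt toward 25–45% acceptance during burn-in and freeze
afterwards. Defaults: 5,000 burn-in sweeps, 10,000 post-burn-in sweeps,
thinning 10 → 1,000 retained samples. All likelihood evaluations are
vectorised over the locus × population matrix via log-gamma identities; one
2,000-locus × 4-population run takes roughly a minute on one core.

Summaries per locus: inclusion probability P_i (mean δ_i), posterior odds
PO_i = P_i/(1−P_i) (capped at (S−0.5)/0.5 and flagged when P_i = 1 with S
samples), posterior mean α_i over included samples, and a q-value (mean
posterior error probability 1−P over the top-k loci by P, made monotone).
Decision rule: "directional" iff PO ≥ 32 and mean α > 0; PO ≥ 32 with mean
α < 0 is "balancing/purifying". PO = 32 corresponds to P = 32/33 ≈ 0.97 and
log10 ≈ 1.5 ("very strong" evidence).

### Attainable power under the island model

A planted α = 3 on a logit(0.03) background lifts the locus F_ST to ≈ 0.38
(≈ 0.78 against a 0.15 background). Frequencies that divergent often drift
to fixation in the *same* direction in every population, leaving the locus
monomorphic or nearly so — and such a locus carries almost no divergence
information, regardless of sampler. Direct numerical integration of the
per-locus Bayes factor (quadrature over p and α) matches the chain's
posterior odds, confirming that the equivocal posteriors of roughly 40% of
planted outliers are a property of the model and data, not a mixing deficit:
with 4 populations of 50 diploids the detection rate of surviving α = 3
outliers at PO ≥ 32 is ≈ 55–68% depending on the background F_ST mix. Power
and false-positive rates are therefore quoted over the planted loci that
survive the pooled-MAF filter (a SNP array contains no monomorphic loci).

## QC filters

* Call rate: SNPs with call rate < 0.95 are removed first, then samples with
  call rate < 0.90 on the surviving SNPs.
* MAF: strictly greater than 0.05, computed on the pooled sample by default
  ("each"-population mode is available; the phrase "among all populations"
  is ambiguous and pooled is the adopted reading).
* HWE: the exact conditional test on the heterozygote count (the sum of
  probabilities of all heterozygote counts no more probable than the one
  observed, given the allele counts); the removal threshold defaults to
  p < 1e-6. Monomorphic sites return p = 1.
* LD pruning: greedy sliding windows (50 SNPs, step 5) on squared dosage
  correlation; while any within-window pair exceeds r² = 0.4 the lower-MAF
  member of the worst pair is dropped (tie → later position); passes repeat
  until a fixed point, so re-running reports zero removals.

Two named profiles mirror the two marker sets such analyses use: *structure*
(MAF + HWE + LD ≤ 0.4, for PCA/diversity) and *scan* (MAF only, for the
selection statistics).

## Summaries

H_O is the heterozygous fraction of non-missing genotypes; H_E = 2p(1−p)
without small-sample correction by default (a 2n/(2n−1) option exists; the
common tooling default is ambiguous). r² is the squared Pearson correlation
of dosages (composite LD on unphased genotypes, matching what array pipelines
compute), binned by 100-kb physical distance within chromosomes. PCA
mean-imputes missing dosages, centres columns, and takes the SVD; variance
fractions are squared singular values over their total, and no frequency
scaling is applied by default. The Kruskal–Wallis comparison (tie-corrected,
chi-square p) is applied to per-SNP H_O distributions across populations.

## Region calling

Significant sites (−log10 p ≥ 3 for the haplotype tests; PO ≥ 32 with mean
α > 0 for the F_ST test) chain into a cluster while consecutive significant
SNPs are ≤ 500 kb apart — chaining, not span-limiting, which is the only
reading that produces the multi-Mb regions such scans report. Clusters need
at least 2 SNPs; boundaries are the outermost significant SNPs; the size
column is (end − start)/1000 rounded half-away-from-zero to one decimal.
Overlapping or bookended regions merge (SNP counts add, peaks take maxima);
merging is idempotent. BED output is 0-based half-open; everything else is
1-based inclusive (VCF convention).

## Synthetic data

### Island model

Per locus: p_i ~ Uniform(0.05, 0.95) (the usable spectrum of an array with a
MAF floor), F_ST_ij = logistic(α_i + β_j), subpopulation frequency ~
Beta(θp, θ(1−p)), counts ~ Binomial(2n_j, ·). The truth record carries p, α,
β and outlier flags. This is exactly the generative model of the outlier
detector, so it tests calibration, not robustness to model misspecification.

### Wright–Fisher haplotype simulator

Founders draw alleles independently per site from a 1/f spectrum truncated
to [0.05, 0.95]; an ancestral pool of N diploids then mates randomly with
Poisson crossovers for a burn-in (default N generations), after which each
population is founded by sampling diploids and evolves independently.
Selection at a designated site uses fitnesses 1 : 1+s : 1+2s and can be
stopped at a per-population target frequency; losing the selected allele
triggers a retry with a fresh substream (capped). Two defaults deserve
comment:

* **Burn-in of N (not 4N) generations.** Without mutation, heterozygosity
  decays as (1−1/2N)^g; a 4N burn-in keeps only e⁻² ≈ 13% of founder
  diversity and leaves the survivors as near-clonal IBD families whose EHH
  never decays below the cutoff. N generations keep ≈ 61% of heterozygosity
  while still building drift LD.
* **Recombination default 2×10⁻⁷ /bp/generation.** Deliberately above a
  per-meiosis physical rate: the simulated time depth (tens to hundreds of
  generations) is orders of magnitude shallower than the coalescent depth of
  a real population, and the higher rate compensates so that neutral EHH
  decays on the ~100-kb scale — the scale on which array data show LD decay.

The validation conditions used by the tests and the acceptance script are:
neutral iHS calibration on one population of 200 haplotypes, 5,000 sites on
83 Mb (16.7-kb spacing); end-to-end sweep recovery on two populations of 100
diploids, 6,000 sites on 100 Mb, a sweep injected at a central standing
variant with carrier fraction 0.6 and taper 2 Mb, 10 replicate seeds (5 in
the acceptance script). Multi-Mb shared haplotypes are what a handful of
generations of strong artificial selection at ~1 cM/Mb actually produce.

### Deterministic sweep injection

`inject_sweep` copies one donor haplotype onto a chosen fraction of
haplotypes over windows around a core whose per-side half-widths are
Exponential(taper); all carriers share the donor's core allele. The donor is
drawn among carriers of the *minor* core allele — a sweep lifts a rare
haplotype, and this keeps the core polymorphic after injection. The injector
gives an EHH signal at a known position with a known carrier frequency,
decoupled from the vagaries of forward-simulated selection. Carrier pairs
remain identical out to the minimum of their half-widths, so the signal
decays as exp(−2d/taper): the *pairwise* sweep scale is half the taper, which
matters when choosing a taper relative to background LD.

### What the generators do not emulate

No mutation, no gene conversion, no ascertainment bias of a commercial
array, no genotyping error, no phasing error (panels are perfectly phased by
construction), and the island model has no linkage at all. Passing tests
therefore demonstrate correctness of the statistics and calibration under
the model assumptions, not robustness of the pipeline to the artefacts of
real array data.

## Numerical details and edge cases

* Sites with identical positions on a chromosome: first kept, rest skipped
  (EHH integration needs strictly increasing positions).
* Monomorphic cores or allele classes with < 2 carriers are invalid with
  reason codes, as are sites whose standardization bin ends with < 2 scores.
* The HWE exact test works in log-space and normalises the conditional
  distribution explicitly; equality of probabilities uses a 1+1e-12 relative
  guard against float ties.
* All generators and the sampler are pure functions of (spec, seed); the
  pipeline derives per-stage substreams from one master seed by hashing, so
  identical config + seed gives byte-identical outputs.
* q-values use the posterior-error-probability average (mean 1−P over the
  top-k ranking), the convention matching the "−log10 q" plots of
  Bayesian outlier scans.

## Known limitations

* The RJ-MCMC is single-chain; convergence diagnostics beyond acceptance
  rates (e.g. split-half agreement) are left to the caller.
* XP-EHH standardization is genome-wide; very skewed pooled-frequency
  spectra could warrant binned standardization (flag-gated in principle but
  not implemented).
* The forward simulator is desk-scale (hundreds of haplotypes); it is a
  testbed for detection behaviour, not a demographic model of any real
  population.
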