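"""Bayesian F_ST outlier detection under the Dirichlet island model.

Subpopulation allele frequencies are modelled as Beta-distributed around an
ancestral frequency p_i with concentration θ_ij = (1−F_ST_ij)/F_ST_ij, and
logit(F_ST_ij) decomposes into a locus effect α_i (selection) plus a
population effect β_j (drift/demography). Observed allele counts then follow
a beta-binomial. A reversible-jump MCMC toggles a per-locus indicator δ_i
(δ_i = 0 forces α_i = 0); the posterior mean of δ_i gives the inclusion
probability, hence posterior odds, and α_i > 0 with high odds is called
directional selection, α_i < 0 balancing/purifying.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln, logit

from .haplo_io import PanelError, SiteInfo


@dataclass
class AlleleCountTable:
    """Counts of allele 1 (``a``) out of ``n`` sampled alleles, locus × pop."""

    a: np.ndarray  # (I, J) ints
    n: np.ndarray  # (I, J) ints
    sites: list[SiteInfo]
    pops: list[str]

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=np.int64)
        self.n = np.asarray(self.n, dtype=np.int64)
        if self.a.shape != self.n.shape or self.a.ndim != 2:
            raise PanelError("count matrices must share a 2-D shape")
        if self.a.shape != (len(self.sites), len(self.pops)):
            raise PanelError("count shape must be (n_loci, n_pops)")
        if (self.a < 0).any() or (self.a > self.n).any():
            raise PanelError("need 0 <= a <= n")

    @property
    def n_loci(self) -> int:
        return self.a.shape[0]

    @property
    def n_pops(self) -> int:
        return self.a.shape[1]


@dataclass
class McmcConfig:
    """Chain lengths, priors and proposal scales for the RJ-MCMC.

    ``iterations`` counts post-burn-in sweeps; with the default thinning of
    10 the 10,000 iterations retain 1,000 samples. ``prior_odds`` is the
    neutral:selected prior ratio, so the prior inclusion probability is
    1/(1+prior_odds).
    """

    burn_in: int = 5_000
    iterations: int = 10_000
    thinning: int = 10
    prior_odds: float = 10.0
    alpha_prior_sd: float = 1.0
    beta_prior_mean: float = -1.0
    beta_prior_sd: float = 1.8
    prop_sd_alpha: float = 0.4
    prop_sd_beta: float = 0.15
    prop_sd_p: float = 0.6
    adapt: bool = True
    likelihood_on: bool = True  # test hook: False samples the prior
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.burn_in, self.iterations, self.thinning) <= 0:
            raise PanelError("chain length settings must be positive")
        if self.iterations % self.thinning:
            raise PanelError("thinning must divide iterations")


@dataclass
class McmcChain:
    """Thinned post-burn-in samples plus acceptance diagnostics."""

    delta: np.ndarray  # (S, I) int8
    alpha: np.ndarray  # (S, I) float32, 0 where delta == 0
    beta: np.ndarray  # (S, J)
    p: np.ndarray  # (S, I) float32 ancestral frequencies
    acceptance: dict[str, float] = field(default_factory=dict)
    pops: list[str] = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return self.delta.shape[0]


@dataclass
class PosteriorSummary:
    """Per-locus and per-population posterior summaries."""

    loci: pd.DataFrame  # P, PO, po_capped, alpha_mean, q, decision
    populations: pd.DataFrame  # beta_mean, beta_lo, beta_hi, fst_mean


def fst_from_effects(alpha, beta):
    """F_ST_ij = logistic(α_i + β_j) — the logit-linear decomposition."""
    return expit(np.asarray(alpha, dtype=float) + np.asarray(beta, dtype=float))


def betabinom_loglik(a, n, p, theta):
    """Log beta-binomial probability of ``a`` of ``n`` alleles, shapes θp, θ(1−p).

    This is the marginal likelihood of the island model at one locus in one
    population: the subpopulation frequency is Beta(θp, θ(1−p))-distributed
    and the sampled alleles binomial given it. Broadcasts over arrays.
    """
    a = np.asarray(a, dtype=float)
    n = np.asarray(n, dtype=float)
    p = np.asarray(p, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if np.any(p <= 0) or np.any(p >= 1):
        raise PanelError("ancestral frequency must lie strictly inside (0,1)")
    if np.any(theta <= 0):
        raise PanelError("theta must be positive")
    x, y = theta * p, theta * (1.0 - p)
    choose = gammaln(n + 1) - gammaln(a + 1) - gammaln(n - a + 1)
    return (
        choose
        + gammaln(a + x)
        + gammaln(n - a + y)
        - gammaln(n + theta)
        - gammaln(x)
        - gammaln(y)
        + gammaln(theta)
    )


class _Model:
    """Cached-likelihood state for the sampler (internal)."""

    def __init__(self, counts: AlleleCountTable, likelihood_on: bool):
        self.a = counts.a.astype(float)
        self.n = counts.n.astype(float)
        self.likelihood_on = likelihood_on
        self.choose = gammaln(self.n + 1) - gammaln(self.a + 1) - gammaln(self.n - self.a + 1)

    def loglik_matrix(self, p: np.ndarray, alpha: np.ndarray, beta: np.ndarray) -> np.ndarray:
        """(I, J) log-likelihood for ancestral freqs p, effects alpha/beta."""
        if not self.likelihood_on:
            return np.zeros_like(self.a)
        theta = np.exp(-(alpha[:, None] + beta[None, :]))  # (1-F)/F
        x = theta * p[:, None]
        y = theta * (1.0 - p[:, None])
        return (
            self.choose
            + gammaln(self.a + x)
            + gammaln(self.n - self.a + y)
            - gammaln(self.n + theta)
            - gammaln(x)
            - gammaln(y)
            + gammaln(theta)
        )

    def loglik_cols(self, p: np.ndarray, alpha: np.ndarray, beta_j: float, j: int) -> np.ndarray:
        if not self.likelihood_on:
            return np.zeros(self.a.shape[0])
        theta = np.exp(-(alpha + beta_j))
        x = theta * p
        y = theta * (1.0 - p)
        return (
            self.choose[:, j]
            + gammaln(self.a[:, j] + x)
            + gammaln(self.n[:, j] - self.a[:, j] + y)
            - gammaln(self.n[:, j] + theta)
            - gammaln(x)
            - gammaln(y)
            + gammaln(theta)
        )


def rjmcmc_run(counts: AlleleCountTable, config: McmcConfig) -> McmcChain:
    """Run the reversible-jump sampler and return thinned samples.

    Per sweep: logit random-walk on every p_i, random-walk on β_j and on the
    active α_i, and a reversible-jump toggle of every δ_i with α proposed
    from its prior (so the move needs no Jacobian). Proposal scales adapt
    toward 25–45% acceptance during burn-in, then freeze. Fully seeded.
    """
    if counts.n_pops < 2 or counts.n_loci < 2:
        raise PanelError("need at least 2 populations and 2 loci")
    fixed = np.all((counts.a == 0) | (counts.a == counts.n), axis=0)
    if config.likelihood_on and fixed.any():
        bad = [counts.pops[j] for j in np.flatnonzero(fixed)]
        raise PanelError(f"population(s) with every locus fixed: {bad}")

    rng = np.random.default_rng(config.seed)
    I, J = counts.n_loci, counts.n_pops
    model = _Model(counts, config.likelihood_on)

    # initial state: pooled frequency estimate, neutral loci, mildly drifted pops
    tot_a = counts.a.sum(axis=1)
    tot_n = counts.n.sum(axis=1)
    p = np.clip((tot_a + 1.0) / (tot_n + 2.0), 1e-4, 1 - 1e-4)
    alpha = np.zeros(I)
    delta = np.zeros(I, dtype=np.int8)
    beta = np.full(J, config.beta_prior_mean)
    L = model.loglik_matrix(p, alpha, beta)
    row_sum = L.sum(axis=1)

    pi_incl = 1.0 / (1.0 + config.prior_odds)
    log_prior_ratio_birth = math.log(pi_incl) - math.log1p(-pi_incl)

    sd_p = config.prop_sd_p
    sd_a = config.prop_sd_alpha
    sd_b = config.prop_sd_beta
    acc = {"p": [0, 0], "alpha": [0, 0], "beta": [0, 0], "rj": [0, 0]}

    n_keep = config.iterations // config.thinning
    out_delta = np.empty((n_keep, I), dtype=np.int8)
    out_alpha = np.empty((n_keep, I), dtype=np.float32)
    out_beta = np.empty((n_keep, J))
    out_p = np.empty((n_keep, I), dtype=np.float32)
    keep = 0

    total_iters = config.burn_in + config.iterations
    adapt_block = 200

    for it in range(total_iters):
        # --- ancestral frequencies: logit random walk, uniform prior on p
        lp = logit(p)
        lp_new = lp + rng.normal(0.0, sd_p, size=I)
        p_new = expit(lp_new)
        p_new = np.clip(p_new, 1e-12, 1 - 1e-12)
        L_new = model.loglik_matrix(p_new, alpha, beta)
        row_new = L_new.sum(axis=1)
        # Jacobian of the logit transform: uniform prior => density p(1-p) in logit space
        logr = (row_new - row_sum) + (np.log(p_new) + np.log1p(-p_new)) - (
            np.log(p) + np.log1p(-p)
        )
        accept = np.log(rng.random(I)) < logr
        p[accept] = p_new[accept]
        L[accept, :] = L_new[accept, :]
        row_sum[accept] = row_new[accept]
        acc["p"][0] += int(accept.sum())
        acc["p"][1] += I

        # --- locus effects alpha (active loci only)
        active = np.flatnonzero(delta == 1)
        if len(active):
            a_new = alpha.copy()
            a_new[active] = alpha[active] + rng.normal(0.0, sd_a, size=len(active))
            L_new = model.loglik_matrix(p, a_new, beta)
            row_new = L_new.sum(axis=1)
            pr = (alpha[active] ** 2 - a_new[active] ** 2) / (
                2.0 * config.alpha_prior_sd**2
            )
            logr = (row_new[active] - row_sum[active]) + pr
            accept_idx = active[np.log(rng.random(len(active))) < logr]
            alpha[accept_idx] = a_new[accept_idx]
            L[accept_idx, :] = L_new[accept_idx, :]
            row_sum[accept_idx] = row_new[accept_idx]
            acc["alpha"][0] += len(accept_idx)
            acc["alpha"][1] += len(active)

        # --- population effects beta
        for j in range(J):
            b_new = beta[j] + rng.normal(0.0, sd_b)
            col_new = model.loglik_cols(p, alpha, b_new, j)
            pr = ((beta[j] - config.beta_prior_mean) ** 2 - (b_new - config.beta_prior_mean) ** 2) / (
                2.0 * config.beta_prior_sd**2
            )
            logr = (col_new.sum() - L[:, j].sum()) + pr
            if math.log(rng.random()) < logr:
                row_sum += col_new - L[:, j]
                L[:, j] = col_new
                beta[j] = b_new
                acc["beta"][0] += 1
            acc["beta"][1] += 1

        # --- reversible-jump toggle of delta (alpha proposed from its prior)
        a_cand = np.where(
            delta == 0, rng.normal(0.0, config.alpha_prior_sd, size=I), 0.0
        )
        L_new = model.loglik_matrix(p, a_cand, beta)
        row_new = L_new.sum(axis=1)
        sign = np.where(delta == 0, 1.0, -1.0)  # birth vs death
        logr = (row_new - row_sum) + sign * log_prior_ratio_birth
        accept = np.log(rng.random(I)) < logr
        if accept.any():
            delta[accept] = 1 - delta[accept]
            alpha[accept] = a_cand[accept]
            L[accept, :] = L_new[accept, :]
            row_sum[accept] = row_new[accept]
        acc["rj"][0] += int(accept.sum())
        acc["rj"][1] += I

        # --- adaptation during burn-in
        if config.adapt and it < config.burn_in and (it + 1) % adapt_block == 0:
            for key, sd_name in (("p", "sd_p"), ("alpha", "sd_a"), ("beta", "sd_b")):
                tried = acc[key][1]
                if not tried:
                    continue
                rate = acc[key][0] / tried
                scale = 1.0
                if rate < 0.25:
                    scale = 0.7
                elif rate > 0.45:
                    scale = 1.4
                if sd_name == "sd_p":
                    sd_p = min(5.0, max(1e-3, sd_p * scale))
                elif sd_name == "sd_a":
                    sd_a = min(5.0, max(1e-3, sd_a * scale))
                else:
                    sd_b = min(5.0, max(1e-3, sd_b * scale))
            for key in acc:
                acc[key] = [0, 0]

        if it == config.burn_in - 1:
            for key in acc:
                acc[key] = [0, 0]

        post = it - config.burn_in
        if post >= 0 and (post + 1) % config.thinning == 0:
            out_delta[keep] = delta
            out_alpha[keep] = alpha
            out_beta[keep] = beta
            out_p[keep] = p
            keep += 1

    rates = {k: (v[0] / v[1] if v[1] else float("nan")) for k, v in acc.items()}
    return McmcChain(
        delta=out_delta,
        alpha=out_alpha,
        beta=out_beta,
        p=out_p,
        acceptance=rates,
        pops=list(counts.pops),
    )


def qvalues(inclusion_probs: np.ndarray) -> np.ndarray:
    """Locus-wise q-values from posterior error probabilities 1 − P.

    Loci are ranked by decreasing P; the q-value at rank k is the mean
    posterior error probability of the top k loci, made monotone
    non-decreasing down the ranking.
    """
    P = np.asarray(inclusion_probs, dtype=float)
    if np.any((P < 0) | (P > 1)):
        raise PanelError("inclusion probabilities must lie in [0,1]")
    order = np.argsort(-P, kind="stable")
    pep = 1.0 - P[order]
    q_sorted = np.cumsum(pep) / np.arange(1, len(P) + 1)
    q_sorted = np.maximum.accumulate(q_sorted)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


#: posterior-odds decision threshold: "very strong" evidence, P = 32/33 ≈ 0.97
PO_THRESHOLD = 32.0


def posterior_summaries(
    chain: McmcChain, config: McmcConfig, po_threshold: float = PO_THRESHOLD
) -> PosteriorSummary:
    """Per-locus inclusion probabilities, odds, q-values and decisions.

    PO_i = P_i/(1−P_i), capped at (S−0.5)/0.5 for P_i = 1 with S retained
    samples (flagged). Decision: "directional" iff PO ≥ threshold and the
    posterior mean α (over included samples) is positive;
    "balancing/purifying" iff PO ≥ threshold with negative mean α; else
    "neutral".
    """
    if chain.n_samples == 0:
        raise PanelError("empty chain")
    S = chain.n_samples
    P = chain.delta.astype(float).mean(axis=0)
    capped = P >= 1.0
    PO = np.where(capped, (S - 0.5) / 0.5, P / np.maximum(1.0 - P, 1e-300))

    incl = chain.delta.astype(bool)
    alpha_sum = np.where(incl, chain.alpha, 0.0).sum(axis=0)
    n_incl = incl.sum(axis=0)
    with np.errstate(invalid="ignore"):
        alpha_mean = np.where(n_incl > 0, alpha_sum / np.maximum(n_incl, 1), 0.0)

    q = qvalues(P)
    decision = np.where(
        (PO >= po_threshold) & (alpha_mean > 0),
        "directional",
        np.where((PO >= po_threshold) & (alpha_mean < 0), "balancing/purifying", "neutral"),
    )
    loci = pd.DataFrame(
        {
            "P": P,
            "PO": PO,
            "po_capped": capped,
            "alpha_mean": alpha_mean,
            "q": q,
            "decision": decision,
        }
    )
    beta_mean = chain.beta.mean(axis=0)
    lo, hi = np.percentile(chain.beta, [2.5, 97.5], axis=0)
    fst_mean = expit(chain.beta).mean(axis=0)
    populations = pd.DataFrame(
        {
            "population": chain.pops if chain.pops else range(chain.beta.shape[1]),
            "beta_mean": beta_mean,
            "beta_lo": lo,
            "beta_hi": hi,
            "fst_mean": fst_mean,
        }
    )
    return PosteriorSummary(loci=loci, populations=populations)


def counts_from_genotypes(genotypes, pops: list[str]) -> AlleleCountTable:
    """Per-population allele-1 counts from a genotype matrix."""
    a = np.zeros((genotypes.n_sites, len(pops)), dtype=np.int64)
    n = np.zeros_like(a)
    for j, pop in enumerate(pops):
        rows = genotypes.sample_rows(pop)
        d = genotypes.dosage[rows, :]
        called = np.isfinite(d)
        a[:, j] = np.nansum(d, axis=0).astype(np.int64)
        n[:, j] = 2 * called.sum(axis=0)
    return AlleleCountTable(a=a, n=n, sites=list(genotypes.sites), pops=list(pops))
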