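"""Desk-scale re-implementations of four matched cancer-normal SNV callers.

All four models operate in the reduced reference/variant (A/B) genotype space
with nine joint genotypes per site, and share a single per-read likelihood
kernel that weighs each read by its base and mapping quality:

    P(read | g) = m_r * [ f_g * P(b | ref) + (1 - f_g) * P(b | var) ] + (1 - m_r) / 4

where e_r = 10^(-baseQ/10), m_r = 1 - 10^(-mapQ/10), P(b | a) = 1 - e_r if
b = a else e_r / 3, and f_g is the reference-allele fraction of genotype g.

The models:

* ``call_varscan`` -- heuristic per-sample genotyping on observed variant
  frequency followed by a one-tailed Fisher exact test on the 2x2 read-count
  table when the genotypes disagree.
* ``call_somaticsniper`` -- joint-genotype Bayesian posterior; the somatic
  score S is the phred-scaled posterior probability that normal and tumour
  genotypes are identical.
* ``train_jsm_em`` / ``call_jointsnvmix`` -- mixture of nine joint genotypes
  with a Dirichlet prior on the mixture weights and Beta priors on the
  per-genotype binomial reference-read probabilities, fit by MAP-EM; JSM1
  uses raw allele counts, JSM2 the quality-weighted per-read kernel.
* ``call_strelka_like`` -- an explicitly simplified Strelka-style model: the
  normal is diploid with a noise term; the somatic hypothesis marginalises
  the tumour variant fraction over a uniform grid at any frequency.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import betaln, gammaln, logsumexp
from scipy.stats import binom, hypergeom

from .core import (
    BASE_TO_INDEX,
    BASES,
    GENOTYPES,
    MAX_PHRED_SCORE,
    AlleleSummary,
    CandidateCall,
    PairedSite,
    ReadObservation,
    ReadStack,
    _PHRED_PROB,
    site_stacks,
    summarize_stack,
)

_N_INDEX = 4


# ---------------------------------------------------------------------------
# likelihood kernel
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenotypeLikelihoodModel:
    """Reference-allele fractions per genotype for the read kernel.

    ``epsilon`` absorbs residual error in a nominally homozygous genotype:
    f_AA = 1 - epsilon, f_AB = 0.5, f_BB = epsilon.
    """

    epsilon: float = 0.001

    @property
    def f_values(self) -> np.ndarray:
        e = self.epsilon
        return np.array([1.0 - e, 0.5, e])


def read_likelihood(
    obs: ReadObservation,
    genotype: str,
    model: GenotypeLikelihoodModel,
    variant_base: str | None,
    ref: str,
) -> float:
    """P(one read | genotype) under the shared quality-weighted kernel.

    A read spanning a deletion carries no base call and returns 1 (neutral).
    A base matching neither ref nor variant is generic error evidence e/3.
    """
    if obs.spans_deletion:
        return 1.0
    f = model.f_values[GENOTYPES.index(genotype)]
    e = _PHRED_PROB[obs.base_quality]
    m = 1.0 - _PHRED_PROB[obs.map_quality]
    p_ref = (1.0 - e) if obs.base == ref else e / 3.0
    p_var = (1.0 - e) if (variant_base is not None and obs.base == variant_base) else e / 3.0
    return m * (f * p_ref + (1.0 - f) * p_var) + (1.0 - m) * 0.25


def _stack_log_likelihoods(
    stack: ReadStack, ref_idx: int, var_idx: int | None, f_values: np.ndarray
) -> np.ndarray:
    """Total log-likelihood of a read stack for each reference fraction in f_values."""
    use = ~stack.spans_deletion
    if not use.any():
        return np.zeros(len(f_values))
    bidx = stack.base_index[use]
    e = _PHRED_PROB[stack.base_quality[use]]
    m = 1.0 - _PHRED_PROB[stack.map_quality[use]]
    p_ref = np.where(bidx == ref_idx, 1.0 - e, e / 3.0)
    if var_idx is None:
        p_var = e / 3.0
    else:
        p_var = np.where(bidx == var_idx, 1.0 - e, e / 3.0)
    f = np.asarray(f_values, dtype=float)[:, None]
    per_read = m[None, :] * (f * p_ref[None, :] + (1.0 - f) * p_var[None, :]) + (
        1.0 - m[None, :]
    ) * 0.25
    return np.log(per_read).sum(axis=1)


def _ref_depth_counts(stack: ReadStack, ref_idx: int) -> tuple[int, int]:
    """(reads supporting reference, qualifying depth) for the binomial models."""
    mask = ~stack.spans_deletion & (stack.base_index != _N_INDEX)
    return int((stack.base_index[mask] == ref_idx).sum()), int(mask.sum())


def _pick_variant(site: PairedSite, min_base_quality: int = 0) -> int | None:
    """Site-level variant base index: most common tumour variant, else normal."""
    stack_n, stack_t = site_stacks(site)
    ref_idx = BASE_TO_INDEX[site.ref]
    for stack in (stack_t, stack_n):
        s = summarize_stack(stack, ref_idx, min_base_quality)
        if s.variant_base is not None:
            return BASE_TO_INDEX[s.variant_base]
    return None


# ---------------------------------------------------------------------------
# priors and configs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PriorConfig:
    """Site-level priors shared by the Bayesian callers.

    ``theta`` is the population heterozygosity prior: P(normal = AB) = theta,
    P(normal = BB) = theta/2, P(normal = AA) = 1 - 3*theta/2.  ``mu_somatic``
    is the prior probability of any somatic genotype change.  ``loh_prior``
    is reserved for callers that weight LOH separately; the current models
    split ``mu_somatic`` evenly over the non-matching genotypes.
    """

    theta: float = 0.001
    mu_somatic: float = 1e-4
    loh_prior: float = 1e-4

    def __post_init__(self):
        for name in ("theta", "mu_somatic", "loh_prior"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.theta + self.mu_somatic + self.loh_prior >= 1.0:
            raise ValueError("priors must sum below 1")

    @property
    def log_normal_prior(self) -> np.ndarray:
        t = self.theta
        return np.log(np.array([1.0 - 1.5 * t, t, t / 2.0]))


@dataclass(frozen=True)
class VarscanConfig:
    min_var_freq: float = 0.20
    hom_threshold: float = 0.75
    min_base_quality: int = 15
    p_threshold: float = 0.05
    min_variant_reads: int = 2

    def __post_init__(self):
        if not 0.0 < self.min_var_freq < self.hom_threshold < 1.0:
            raise ValueError("require 0 < min_var_freq < hom_threshold < 1")


# ---------------------------------------------------------------------------
# VarScan-style heuristic genotyping + Fisher exact test
# ---------------------------------------------------------------------------

def fisher_exact_one_tailed(
    ref_normal: int, var_normal: int, ref_tumour: int, var_tumour: int,
    alternative: str = "tumour",
) -> float:
    """One-tailed Fisher exact p for a (normal, tumour) x (ref, var) table.

    ``alternative="tumour"``: variant enrichment in the tumour (the somatic
    direction); ``"normal"``: variant enrichment in the normal (the LOH
    direction).  Conditioned on the margins the normal variant count is
    hypergeometric, so the p-value is the corresponding exact tail sum.
    Accepts scalars or equal-shaped integer arrays.
    """
    ref_normal, var_normal = np.asarray(ref_normal), np.asarray(var_normal)
    ref_tumour, var_tumour = np.asarray(ref_tumour), np.asarray(var_tumour)
    total = ref_normal + var_normal + ref_tumour + var_tumour
    n_var = var_normal + var_tumour
    n_normal = ref_normal + var_normal
    if alternative == "tumour":
        p = hypergeom.cdf(var_normal, total, n_var, n_normal)
    elif alternative == "normal":
        p = hypergeom.sf(var_normal - 1, total, n_var, n_normal)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    p = np.minimum(1.0, p)
    return float(p) if p.ndim == 0 else p


def _varscan_genotype(summary: AlleleSummary, cfg: VarscanConfig) -> str:
    denom = summary.v + summary.ref_count
    if denom == 0:
        return "AA"
    vp = summary.v / denom
    if vp >= cfg.min_var_freq and summary.v >= cfg.min_variant_reads:
        return "AB" if vp < cfg.hom_threshold else "BB"
    return "AA"


def call_varscan(site: PairedSite, cfg: VarscanConfig | None = None) -> CandidateCall | None:
    """Heuristic genotyping per sample; Fisher exact test where they disagree.

    Significant mismatches are classified somatic (normal homozygous
    reference), LOH (normal heterozygous) or unknown (normal homozygous
    variant); the score is 1 - p.  Returns None when there is no call.
    """
    cfg = cfg or VarscanConfig()
    stack_n, stack_t = site_stacks(site)
    if len(stack_n) == 0 or len(stack_t) == 0:
        return None
    ref_idx = BASE_TO_INDEX[site.ref]
    var_idx = _pick_variant(site, cfg.min_base_quality)
    s_n = summarize_stack(stack_n, ref_idx, cfg.min_base_quality, var_idx)
    s_t = summarize_stack(stack_t, ref_idx, cfg.min_base_quality, var_idx)
    g_n = _varscan_genotype(s_n, cfg)
    g_t = _varscan_genotype(s_t, cfg)
    if g_n == g_t:
        return None
    alternative = "tumour" if g_n == "AA" else "normal"
    p = fisher_exact_one_tailed(s_n.ref_count, s_n.v, s_t.ref_count, s_t.v, alternative)
    if p > cfg.p_threshold:
        return None
    call_class = {"AA": "somatic", "AB": "LOH", "BB": "unknown"}[g_n]
    return CandidateCall(
        chrom=site.chrom, pos=site.pos, ref=site.ref,
        caller_id="varscan", call_class=call_class, score=1.0 - p,
        normal_genotype=g_n, tumour_genotype=g_t,
        normal_summary=s_n, tumour_summary=s_t,
        normal_depth=site.normal_depth, tumour_depth=site.tumour_depth,
        raw_score=1.0 - p,
    )


# ---------------------------------------------------------------------------
# SomaticSniper-style joint genotype posterior
# ---------------------------------------------------------------------------

def _joint_log_posterior(
    site: PairedSite,
    priors: PriorConfig,
    model: GenotypeLikelihoodModel,
) -> tuple[np.ndarray, int | None]:
    """3x3 normalised log posterior over joint genotypes (normal x tumour)."""
    stack_n, stack_t = site_stacks(site)
    ref_idx = BASE_TO_INDEX[site.ref]
    var_idx = _pick_variant(site)
    f = model.f_values
    ll_n = _stack_log_likelihoods(stack_n, ref_idx, var_idx, f)
    ll_t = _stack_log_likelihoods(stack_t, ref_idx, var_idx, f)
    mu = priors.mu_somatic
    log_trans = np.log(np.where(np.eye(3, dtype=bool), 1.0 - mu, mu / 2.0))
    joint = priors.log_normal_prior[:, None] + log_trans + ll_n[:, None] + ll_t[None, :]
    return joint - logsumexp(joint), var_idx


def call_somaticsniper(
    site: PairedSite,
    priors: PriorConfig | None = None,
    model: GenotypeLikelihoodModel | None = None,
) -> CandidateCall:
    """Somatic score S = phred-scaled posterior P(normal and tumour genotypes equal)."""
    priors = priors or PriorConfig()
    model = model or GenotypeLikelihoodModel()
    log_post, var_idx = _joint_log_posterior(site, priors, model)
    post = np.exp(log_post)
    p_same = float(np.clip(np.trace(post), 1e-30, 1.0))
    s = min(MAX_PHRED_SCORE, max(0, round(-10.0 * np.log10(p_same))))
    j, k = np.unravel_index(np.argmax(post), (3, 3))
    g_n, g_t = GENOTYPES[j], GENOTYPES[k]
    if g_n == g_t:
        call_class = "reference" if g_n == "AA" else "germline"
    elif g_n == "AA":
        call_class = "somatic"
    elif g_n == "AB":
        call_class = "LOH"
    else:
        call_class = "unknown"
    stack_n, stack_t = site_stacks(site)
    ref_idx = BASE_TO_INDEX[site.ref]
    return CandidateCall(
        chrom=site.chrom, pos=site.pos, ref=site.ref,
        caller_id="somaticsniper", call_class=call_class,
        score=1.0 - 10.0 ** (-s / 10.0), phred_score=int(s),
        normal_genotype=g_n, tumour_genotype=g_t,
        normal_summary=summarize_stack(stack_n, ref_idx, 0, var_idx),
        tumour_summary=summarize_stack(stack_t, ref_idx, 0, var_idx),
        normal_depth=site.normal_depth, tumour_depth=site.tumour_depth,
        raw_score=1.0 - p_same,
    )


# ---------------------------------------------------------------------------
# JointSNVMix: MAP-EM training and calling
# ---------------------------------------------------------------------------

@dataclass
class JsmParams:
    """Joint-genotype mixture parameters.

    ``pi`` are the nine joint-genotype probabilities (normal-major order),
    ``delta`` their Dirichlet pseudocounts; ``mu_*`` the per-genotype binomial
    reference-read probabilities with Beta pseudocounts ``alpha_*``/``beta_*``.
    """

    pi: np.ndarray
    delta: np.ndarray
    mu_normal: np.ndarray
    mu_tumour: np.ndarray
    alpha_normal: np.ndarray
    beta_normal: np.ndarray
    alpha_tumour: np.ndarray
    beta_tumour: np.ndarray

    def validate(self) -> None:
        if abs(self.pi.sum() - 1.0) > 1e-9:
            raise ValueError("pi must sum to 1")
        for mu in (self.mu_normal, self.mu_tumour):
            if np.any(mu <= 0.0) or np.any(mu >= 1.0):
                raise ValueError("mu values must lie in (0, 1)")
        for pc in (self.alpha_normal, self.beta_normal, self.alpha_tumour,
                   self.beta_tumour, self.delta):
            if np.any(pc <= 0.0):
                raise ValueError("pseudocounts must be positive")

    def copy(self) -> "JsmParams":
        return JsmParams(**{
            f.name: getattr(self, f.name).copy() for f in dataclasses.fields(self)
        })


def default_jsm_params() -> JsmParams:
    """Defaults: mixture mass concentrated on (AA, AA), Beta priors per genotype."""
    delta = np.full(9, 2.0)
    delta[0] = 1e6  # joint (AA, AA)
    mu = np.array([0.99, 0.5, 0.01])
    alpha = np.array([1000.0, 500.0, 10.0])
    beta = np.array([10.0, 500.0, 1000.0])
    params = JsmParams(
        pi=delta / delta.sum(), delta=delta,
        mu_normal=mu.copy(), mu_tumour=mu.copy(),
        alpha_normal=alpha.copy(), beta_normal=beta.copy(),
        alpha_tumour=alpha.copy(), beta_tumour=beta.copy(),
    )
    params.validate()
    return params


def site_allele_counts(sites: Sequence[PairedSite]) -> tuple[np.ndarray, ...]:
    """(a_normal, d_normal, a_tumour, d_tumour) reference-support count arrays."""
    n = len(sites)
    a_n = np.zeros(n, dtype=np.int64)
    d_n = np.zeros(n, dtype=np.int64)
    a_t = np.zeros(n, dtype=np.int64)
    d_t = np.zeros(n, dtype=np.int64)
    for i, site in enumerate(sites):
        stack_n, stack_t = site_stacks(site)
        ref_idx = BASE_TO_INDEX[site.ref]
        a_n[i], d_n[i] = _ref_depth_counts(stack_n, ref_idx)
        a_t[i], d_t[i] = _ref_depth_counts(stack_t, ref_idx)
    return a_n, d_n, a_t, d_t


def _penalized_loglik(
    params: JsmParams, a_n, d_n, a_t, d_t
) -> tuple[float, np.ndarray]:
    """(penalized log-likelihood, per-site 3x3 log joint) for the current params."""
    l_n = binom.logpmf(a_n[:, None], d_n[:, None], params.mu_normal[None, :])
    l_t = binom.logpmf(a_t[:, None], d_t[:, None], params.mu_tumour[None, :])
    log_pi = np.log(params.pi).reshape(3, 3)
    joint = log_pi[None, :, :] + l_n[:, :, None] + l_t[:, None, :]
    site_ll = logsumexp(joint.reshape(len(a_n), 9), axis=1)
    d = params.delta
    log_prior = (
        gammaln(d.sum()) - gammaln(d).sum() + ((d - 1.0) * np.log(params.pi)).sum()
    )
    for mu, alpha, beta in (
        (params.mu_normal, params.alpha_normal, params.beta_normal),
        (params.mu_tumour, params.alpha_tumour, params.beta_tumour),
    ):
        log_prior += float(
            np.sum((alpha - 1.0) * np.log(mu) + (beta - 1.0) * np.log1p(-mu) - betaln(alpha, beta))
        )
    return float(site_ll.sum() + log_prior), joint - site_ll[:, None, None]


_MU_CLIP = (1e-6, 1.0 - 1e-6)


def _map_mu(w, a, d, alpha, beta) -> np.ndarray:
    num = w.T @ a + alpha - 1.0
    den = w.T @ d + alpha + beta - 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        mu = num / den
    bad = ~np.isfinite(mu) | (mu <= _MU_CLIP[0]) | (mu >= _MU_CLIP[1])
    if bad.any() and (np.any(alpha <= 1.0) or np.any(beta <= 1.0)):
        warnings.warn("degenerate Beta pseudocounts; clamping mu into (0, 1)")
    return np.clip(np.nan_to_num(mu, nan=0.5), *_MU_CLIP)


def train_jsm_em(
    sites: Sequence[PairedSite],
    params0: JsmParams | None = None,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> tuple[JsmParams, list[float]]:
    """MAP-EM for the joint-genotype mixture; returns (params, loglik trace).

    The trace holds the penalized log-likelihood at the initial parameters
    and after every M-step; it is asserted non-decreasing.
    """
    if len(sites) == 0:
        raise ValueError("cannot train on an empty site list")
    params = (params0 or default_jsm_params()).copy()
    params.validate()
    a_n, d_n, a_t, d_t = site_allele_counts(sites)
    n = len(sites)
    ll, log_gamma = _penalized_loglik(params, a_n, d_n, a_t, d_t)
    trace = [ll]
    for _ in range(max_iter):
        gamma = np.exp(log_gamma)  # (n, 3, 3)
        params.pi = (gamma.sum(axis=0).ravel() + params.delta - 1.0) / (
            n + params.delta.sum() - 9.0
        )
        params.pi = np.clip(params.pi, 1e-300, None)
        params.pi /= params.pi.sum()
        w_n = gamma.sum(axis=2)  # weight of normal genotype j
        w_t = gamma.sum(axis=1)
        params.mu_normal = _map_mu(w_n, a_n, d_n, params.alpha_normal, params.beta_normal)
        params.mu_tumour = _map_mu(w_t, a_t, d_t, params.alpha_tumour, params.beta_tumour)
        ll, log_gamma = _penalized_loglik(params, a_n, d_n, a_t, d_t)
        if ll - trace[-1] < -1e-8 * max(1.0, abs(trace[-1])):
            raise RuntimeError(
                f"EM penalized log-likelihood decreased: {trace[-1]} -> {ll}"
            )
        improved = ll - trace[-1]
        trace.append(ll)
        if improved < tol:
            break
    return params, trace


def call_jointsnvmix(
    site: PairedSite,
    params: JsmParams | None = None,
    mode: str = "jsm2",
    model: GenotypeLikelihoodModel | None = None,
) -> CandidateCall:
    """Posterior over the nine joint genotypes for one site.

    ``score`` is the somatic posterior gamma(AA,AB) + gamma(AA,BB);
    ``loh_score`` is gamma(AB,AA) + gamma(AB,BB).  JSM1 uses the binomial
    count likelihood; JSM2 the per-read quality-weighted kernel with the
    trained mu_g as reference fractions.
    """
    params = params or default_jsm_params()
    stack_n, stack_t = site_stacks(site)
    ref_idx = BASE_TO_INDEX[site.ref]
    var_idx = _pick_variant(site)
    if mode == "jsm1":
        a_n, d_n = _ref_depth_counts(stack_n, ref_idx)
        a_t, d_t = _ref_depth_counts(stack_t, ref_idx)
        ll_n = binom.logpmf(a_n, d_n, params.mu_normal)
        ll_t = binom.logpmf(a_t, d_t, params.mu_tumour)
    elif mode == "jsm2":
        ll_n = _stack_log_likelihoods(stack_n, ref_idx, var_idx, params.mu_normal)
        ll_t = _stack_log_likelihoods(stack_t, ref_idx, var_idx, params.mu_tumour)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    joint = np.log(params.pi).reshape(3, 3) + ll_n[:, None] + ll_t[None, :]
    joint -= logsumexp(joint)
    gamma = np.exp(joint)
    somatic = float(gamma[0, 1] + gamma[0, 2])
    loh = float(gamma[1, 0] + gamma[1, 2])
    other = 1.0 - somatic - loh
    call_class = {0: "somatic", 1: "LOH", 2: "germline"}[
        int(np.argmax([somatic, loh, other]))
    ]
    j, k = np.unravel_index(np.argmax(gamma), (3, 3))
    return CandidateCall(
        chrom=site.chrom, pos=site.pos, ref=site.ref,
        caller_id="jointsnvmix", call_class=call_class,
        score=min(1.0, somatic),
        normal_genotype=GENOTYPES[j], tumour_genotype=GENOTYPES[k],
        normal_summary=summarize_stack(stack_n, ref_idx, 0, var_idx),
        tumour_summary=summarize_stack(stack_t, ref_idx, 0, var_idx),
        normal_depth=site.normal_depth, tumour_depth=site.tumour_depth,
        raw_score=somatic, loh_score=loh,
    )


# ---------------------------------------------------------------------------
# Strelka-like marginalised somatic fraction model
# ---------------------------------------------------------------------------

def call_strelka_like(
    site: PairedSite,
    priors: PriorConfig | None = None,
    model: GenotypeLikelihoodModel | None = None,
    grid_step: float = 0.01,
) -> CandidateCall:
    """Simplified Strelka-style call: diploid normal, tumour somatic fraction
    marginalised uniformly over a grid of variant fractions.

    The reported score is the joint posterior probability of the most likely
    normal genotype and the somatic event, quantised through its phred image.
    """
    priors = priors or PriorConfig()
    model = model or GenotypeLikelihoodModel()
    stack_n, stack_t = site_stacks(site)
    ref_idx = BASE_TO_INDEX[site.ref]
    var_idx = _pick_variant(site)
    f = model.f_values
    ll_n = _stack_log_likelihoods(stack_n, ref_idx, var_idx, f)
    ll_t_diploid = _stack_log_likelihoods(stack_t, ref_idx, var_idx, f)
    s_grid = np.arange(grid_step, 1.0 + grid_step / 2.0, grid_step)
    ll_t_grid = _stack_log_likelihoods(stack_t, ref_idx, var_idx, 1.0 - s_grid)
    log_l_somatic = logsumexp(ll_t_grid) - np.log(len(s_grid))
    mu = priors.mu_somatic
    log_joint = np.empty((3, 2))
    log_joint[:, 0] = priors.log_normal_prior + ll_n + np.log1p(-mu) + ll_t_diploid
    log_joint[:, 1] = priors.log_normal_prior + ll_n + np.log(mu) + log_l_somatic
    log_joint -= logsumexp(log_joint)
    post = np.exp(log_joint)
    g_hat = int(np.argmax(post.sum(axis=1)))
    raw = float(post[g_hat, 1])
    phred = min(MAX_PHRED_SCORE, max(0, round(-10.0 * np.log10(max(1.0 - raw, 1e-30)))))
    return CandidateCall(
        chrom=site.chrom, pos=site.pos, ref=site.ref,
        caller_id="strelka_like",
        call_class="somatic" if g_hat == 0 else "unknown",
        score=1.0 - 10.0 ** (-phred / 10.0), phred_score=int(phred),
        normal_genotype=GENOTYPES[g_hat], tumour_genotype=None,
        normal_summary=summarize_stack(stack_n, ref_idx, 0, var_idx),
        tumour_summary=summarize_stack(stack_t, ref_idx, 0, var_idx),
        normal_depth=site.normal_depth, tumour_depth=site.tumour_depth,
        raw_score=raw,
    )


# ---------------------------------------------------------------------------
# driving all four callers
# ---------------------------------------------------------------------------

@dataclass
class CallerSuiteConfig:
    """Configuration for one run of all four callers over a site list.

    Inclusion thresholds are deliberately low to generate large candidate
    sets (the raw-output regime of the comparison).
    """

    varscan: VarscanConfig = field(default_factory=VarscanConfig)
    priors: PriorConfig = field(default_factory=PriorConfig)
    model: GenotypeLikelihoodModel = field(default_factory=GenotypeLikelihoodModel)
    jsm_params0: JsmParams | None = None
    jsm_mode: str = "jsm2"
    jsm_train_fraction: float = 1.0
    jsm_max_iter: int = 50
    jsm_tol: float = 1e-4
    strelka_grid_step: float = 0.01
    min_sniper_score: int = 15
    min_jsm_score: float = 0.001
    min_strelka_phred: int = 1
    subsample_seed: int = 0


@dataclass
class CallerRunResult:
    calls: dict[str, list[CandidateCall]]
    jsm_params: JsmParams
    jsm_trace: list[float]


def run_all_callers(
    sites: Sequence[PairedSite], config: CallerSuiteConfig | None = None
) -> CallerRunResult:
    """Train the mixture model, then emit each caller's candidate set."""
    config = config or CallerSuiteConfig()
    if not 0.0 < config.jsm_train_fraction <= 1.0:
        raise ValueError("jsm_train_fraction must lie in (0, 1]")
    if config.jsm_train_fraction < 1.0:
        rng = np.random.default_rng([config.subsample_seed & 0x7FFFFFFF, 0x715])
        k = max(1, int(round(config.jsm_train_fraction * len(sites))))
        idx = np.sort(rng.choice(len(sites), k, replace=False))
        train_sites = [sites[i] for i in idx]
    else:
        train_sites = list(sites)
    jsm_params, trace = train_jsm_em(
        train_sites, config.jsm_params0, config.jsm_max_iter, config.jsm_tol
    )
    calls: dict[str, list[CandidateCall]] = {
        "varscan": [], "somaticsniper": [], "jointsnvmix": [], "strelka_like": []
    }
    for site in sites:
        vs = call_varscan(site, config.varscan)
        if vs is not None:
            calls["varscan"].append(vs)
        ss = call_somaticsniper(site, config.priors, config.model)
        if ss.phred_score >= config.min_sniper_score and ss.call_class in ("somatic", "LOH"):
            calls["somaticsniper"].append(ss)
        jm = call_jointsnvmix(site, jsm_params, config.jsm_mode, config.model)
        if jm.score >= config.min_jsm_score:
            calls["jointsnvmix"].append(
                dataclasses.replace(jm, call_class="somatic")
            )
        if jm.loh_score >= config.min_jsm_score:
            calls["jointsnvmix"].append(
                dataclasses.replace(jm, call_class="LOH", score=jm.loh_score, raw_score=jm.loh_score)
            )
        st = call_strelka_like(site, config.priors, config.model, config.strelka_grid_step)
        if st.phred_score >= config.min_strelka_phred:
            calls["strelka_like"].append(st)
    return CallerRunResult(calls=calls, jsm_params=jsm_params, jsm_trace=trace)
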