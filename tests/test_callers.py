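"""Caller models against independent oracles and limiting-case behaviour."""

import math

import numpy as np
import pytest
from scipy.stats import binom
import scipy.stats

from snvcompare.callers import (
    CallerSuiteConfig,
    GenotypeLikelihoodModel,
    JsmParams,
    PriorConfig,
    VarscanConfig,
    call_jointsnvmix,
    call_somaticsniper,
    call_strelka_like,
    call_varscan,
    default_jsm_params,
    fisher_exact_one_tailed,
    read_likelihood,
    run_all_callers,
    train_jsm_em,
    _penalized_loglik,
    site_allele_counts,
)
from snvcompare.core import GENOTYPES
from snvcompare.simulate import DiscreteDistribution, SimConfig, simulate_pair

from conftest import STUDY_SEED, obs, reads, site

MODEL = GenotypeLikelihoodModel()
PRIORS = PriorConfig()


# ---------------------------------------------------------------------------
# independent per-read / joint-posterior oracles (pure python, no shared code)
# ---------------------------------------------------------------------------

def oracle_read_likelihood(base, bq, mq, f, ref, var):
    e = 10.0 ** (-bq / 10.0)
    m = 1.0 - 10.0 ** (-mq / 10.0)
    p_ref = (1.0 - e) if base == ref else e / 3.0
    p_var = (1.0 - e) if (var is not None and base == var) else e / 3.0
    return m * (f * p_ref + (1.0 - f) * p_var) + (1.0 - m) * 0.25


def oracle_sniper_posterior(site_, priors, model, var):
    """Direct 9-term joint posterior, naive loops and plain floats."""
    t = priors.theta
    prior_n = {"AA": 1.0 - 1.5 * t, "AB": t, "BB": t / 2.0}
    fs = {"AA": 1.0 - model.epsilon, "AB": 0.5, "BB": model.epsilon}
    post = {}
    for gn in GENOTYPES:
        for gt in GENOTYPES:
            p = prior_n[gn]
            p *= (1.0 - priors.mu_somatic) if gn == gt else priors.mu_somatic / 2.0
            for o in site_.normal:
                if not o.spans_deletion:
                    p *= oracle_read_likelihood(
                        o.base, o.base_quality, o.map_quality, fs[gn], site_.ref, var
                    )
            for o in site_.tumour:
                if not o.spans_deletion:
                    p *= oracle_read_likelihood(
                        o.base, o.base_quality, o.map_quality, fs[gt], site_.ref, var
                    )
            post[(gn, gt)] = p
    z = sum(post.values())
    return {k: v / z for k, v in post.items()}


def oracle_jsm_posterior(a_n, d_n, a_t, d_t, params):
    post = {}
    for j, gn in enumerate(GENOTYPES):
        for k, gt in enumerate(GENOTYPES):
            post[(gn, gt)] = (
                params.pi[3 * j + k]
                * binom.pmf(a_n, d_n, params.mu_normal[j])
                * binom.pmf(a_t, d_t, params.mu_tumour[k])
            )
    z = sum(post.values())
    return {key: v / z for key, v in post.items()}


# ---------------------------------------------------------------------------
# shared likelihood kernel
# ---------------------------------------------------------------------------

def test_read_likelihood_noise_free_limits():
    high = dict(bq=93, mq=93)
    r = obs("A", **high)
    v = obs("C", **high)
    assert read_likelihood(r, "AA", MODEL, "C", "A") == pytest.approx(0.999, rel=1e-6)
    assert read_likelihood(v, "AB", MODEL, "C", "A") == pytest.approx(0.5, rel=1e-6)
    # an unmapped read carries no information, whatever the base or genotype
    unmapped = obs("G", bq=93, mq=0)
    for g in GENOTYPES:
        assert read_likelihood(unmapped, g, MODEL, "C", "A") == pytest.approx(0.25)


def test_read_likelihood_monotone_in_base_quality_for_concordant_read():
    vals = [
        read_likelihood(obs("A", bq=q, mq=60), "AA", MODEL, "C", "A") for q in range(0, 94, 3)
    ]
    assert all(b >= a for a, b in zip(vals, vals[1:]))


def test_read_likelihood_spanning_deletion_is_neutral():
    o = obs("A", spans_deletion=True)
    assert read_likelihood(o, "BB", MODEL, "C", "A") == 1.0


@pytest.mark.parametrize("n_reads", [0, 3, 17])
def test_read_likelihood_matches_oracle_on_random_sites(rng, n_reads):
    for _ in range(20):
        b = str(rng.choice(list("ACGTN")))
        bq, mq = int(rng.integers(0, 94)), int(rng.integers(0, 94))
        o = obs(b, bq=bq, mq=mq)
        for g, f in zip(GENOTYPES, MODEL.f_values):
            assert read_likelihood(o, g, MODEL, "C", "A") == pytest.approx(
                oracle_read_likelihood(b, bq, mq, f, "A", "C"), rel=1e-12
            )


# ---------------------------------------------------------------------------
# VarScan model
# ---------------------------------------------------------------------------

def test_fisher_one_tailed_matches_scipy(rng):
    for _ in range(200):
        rn, vn, rt, vt = (int(x) for x in rng.integers(0, 30, 4))
        table = [[rn, vn], [rt, vt]]
        assert fisher_exact_one_tailed(rn, vn, rt, vt, "tumour") == pytest.approx(
            scipy.stats.fisher_exact(table, alternative="greater")[1], abs=1e-12
        )
        assert fisher_exact_one_tailed(rn, vn, rt, vt, "normal") == pytest.approx(
            scipy.stats.fisher_exact(table, alternative="less")[1], abs=1e-12
        )


def test_varscan_calls_clear_somatic_site():
    s = site(normal=reads(30, 0), tumour=reads(15, 15))
    call = call_varscan(s)
    assert call is not None
    assert call.call_class == "somatic"
    assert (call.normal_genotype, call.tumour_genotype) == ("AA", "AB")
    assert 1.0 - call.score < 0.001  # p < 0.001


def test_varscan_minimum_variant_frequency_gate():
    # tumour variant proportion 0.19 stays below the 0.20 default
    s = site(normal=reads(100, 0), tumour=reads(81, 19))
    assert call_varscan(s) is None


def test_varscan_loh_direction():
    s = site(normal=reads(10, 10), tumour=reads(20, 0))
    call = call_varscan(s)
    assert call is not None
    assert call.call_class == "LOH"
    assert call.normal_genotype == "AB" and call.tumour_genotype == "AA"


def test_varscan_homozygous_and_minimum_read_support():
    # 80% variant in tumour => homozygous-variant genotype
    s = site(normal=reads(40, 0), tumour=reads(8, 32))
    call = call_varscan(s)
    assert call is not None and call.tumour_genotype == "BB"
    # a single variant read never supports a variant genotype
    s2 = site(normal=reads(30, 0), tumour=reads(3, 1))
    assert call_varscan(s2) is None


def test_varscan_requires_coverage_in_both_samples():
    assert call_varscan(site(normal=[], tumour=reads(10, 10))) is None


# ---------------------------------------------------------------------------
# SomaticSniper model
# ---------------------------------------------------------------------------

def test_sniper_no_data_returns_prior_and_zero_score():
    call = call_somaticsniper(site(normal=[], tumour=[]))
    assert call.phred_score == 0
    assert call.score == 0.0


def test_sniper_deep_somatic_site_hits_cap():
    # at moderate depth the score is bounded by the (AB,AB) diagonal term
    # (a het normal emitting all-reference reads costs only 0.5^depth), so
    # the phred cap is reached once the normal stack is deep enough
    s = site(normal=reads(50, 0, bq=93, mq=93), tumour=reads(25, 25, bq=93, mq=93))
    call = call_somaticsniper(s)
    assert (call.normal_genotype, call.tumour_genotype) == ("AA", "AB")
    assert call.call_class == "somatic"
    assert call.phred_score >= 100
    deep = site(normal=reads(100, 0, bq=93, mq=93), tumour=reads(50, 50, bq=93, mq=93))
    assert call_somaticsniper(deep).phred_score == 255


def test_sniper_identical_stacks_score_zero():
    stack = reads(20, 20)
    call = call_somaticsniper(site(normal=list(stack), tumour=list(stack)))
    assert call.phred_score == 0
    assert call.normal_genotype == call.tumour_genotype


def test_sniper_posterior_matches_nine_term_oracle(rng):
    for _ in range(25):
        dn, dt = (int(x) for x in rng.integers(0, 15, 2))
        vn, vt = int(rng.integers(0, dn + 1)), int(rng.integers(0, dt + 1))
        bq = int(rng.integers(5, 45))
        s = site(normal=reads(dn - vn, vn, bq=bq), tumour=reads(dt - vt, vt, bq=bq))
        call = call_somaticsniper(s)
        var = "C" if (vn or vt) else None
        post = oracle_sniper_posterior(s, PRIORS, MODEL, var)
        p_same = sum(post[(g, g)] for g in GENOTYPES)
        expected_s = min(255, max(0, round(-10.0 * math.log10(max(p_same, 1e-30)))))
        assert call.phred_score == expected_s
        assert call.raw_score == pytest.approx(1.0 - p_same, abs=1e-9)


# ---------------------------------------------------------------------------
# JointSNVMix model
# ---------------------------------------------------------------------------

def test_jsm_posterior_normalised_and_matches_oracle(rng):
    params = default_jsm_params()
    for _ in range(25):
        dn, dt = (int(x) for x in rng.integers(0, 40, 2))
        vn = int(rng.integers(0, dn + 1))
        vt = int(rng.integers(0, dt + 1))
        s = site(normal=reads(dn - vn, vn), tumour=reads(dt - vt, vt))
        call = call_jointsnvmix(s, params, mode="jsm1")
        post = oracle_jsm_posterior(dn - vn, dn, dt - vt, dt, params)
        somatic = post[("AA", "AB")] + post[("AA", "BB")]
        loh = post[("AB", "AA")] + post[("AB", "BB")]
        assert call.raw_score == pytest.approx(somatic, abs=1e-9)
        assert call.loh_score == pytest.approx(loh, abs=1e-9)
        assert call.raw_score + call.loh_score <= 1.0 + 1e-9


def test_jsm1_and_jsm2_agree_in_noise_free_limit(rng):
    params = default_jsm_params()
    for _ in range(10):
        dn, dt = (int(x) for x in rng.integers(1, 30, 2))
        vn = int(rng.integers(0, dn + 1))
        vt = int(rng.integers(0, dt + 1))
        s = site(
            normal=reads(dn - vn, vn, bq=93, mq=93),
            tumour=reads(dt - vt, vt, bq=93, mq=93),
        )
        one = call_jointsnvmix(s, params, mode="jsm1")
        two = call_jointsnvmix(s, params, mode="jsm2")
        assert two.raw_score == pytest.approx(one.raw_score, abs=1e-6)
        assert two.loh_score == pytest.approx(one.loh_score, abs=1e-6)


def test_jsm_deep_somatic_site_scores_high():
    s = site(normal=reads(60, 0), tumour=reads(30, 30))
    call = call_jointsnvmix(s, default_jsm_params(), mode="jsm2")
    assert call.score > 0.99
    assert call.call_class == "somatic"


def test_jsm_zero_depth_sample_is_uninformative():
    s = site(normal=[], tumour=reads(20, 20))
    call = call_jointsnvmix(s, default_jsm_params(), mode="jsm2")
    # tumour clearly AB; normal genotype follows the prior, which favours AA
    assert call.tumour_genotype == "AB"


# ---------------------------------------------------------------------------
# EM training
# ---------------------------------------------------------------------------

def _sites_from_counts(count_rows):
    return [
        site(normal=reads(an, dn - an), tumour=reads(at, dt - at), pos=100 * (i + 1))
        for i, (an, dn, at, dt) in enumerate(count_rows)
    ]


def test_em_zero_iterations_returns_initial_params():
    sites = _sites_from_counts([(10, 10, 5, 10), (8, 8, 8, 8)])
    params0 = default_jsm_params()
    params, trace = train_jsm_em(sites, params0, max_iter=0)
    for name in ("pi", "mu_normal", "mu_tumour"):
        np.testing.assert_array_equal(getattr(params, name), getattr(params0, name))
    assert len(trace) == 1


def test_em_trace_monotone_on_random_datasets(rng):
    for _ in range(20):
        n = int(rng.integers(5, 40))
        rows = []
        for _ in range(n):
            dn, dt = (int(x) for x in rng.integers(1, 40, 2))
            rows.append((int(rng.integers(0, dn + 1)), dn, int(rng.integers(0, dt + 1)), dt))
        _, trace = train_jsm_em(_sites_from_counts(rows), max_iter=25, tol=1e-9)
        diffs = np.diff(trace)
        assert np.all(diffs >= -1e-7 * np.maximum(1.0, np.abs(trace[:-1])))


def test_em_fixed_point_is_local_maximum(rng):
    # converge on a tiny instance, then check the MAP objective cannot be
    # improved by one more sweep nor by random parameter perturbations
    sites = _sites_from_counts([(30, 30, 15, 30), (28, 28, 28, 28), (14, 28, 13, 27)])
    params, trace = train_jsm_em(sites, max_iter=500, tol=1e-12)
    again, trace2 = train_jsm_em(sites, params, max_iter=1, tol=0.0)
    assert abs(trace2[-1] - trace[-1]) < 1e-6
    np.testing.assert_allclose(again.mu_normal, params.mu_normal, atol=1e-6)
    counts = site_allele_counts(sites)
    best, _ = _penalized_loglik(params, *counts)
    for _ in range(50):
        trial = params.copy()
        trial.mu_normal = np.clip(
            trial.mu_normal + rng.normal(0, 0.01, 3), 1e-6, 1 - 1e-6
        )
        trial.mu_tumour = np.clip(
            trial.mu_tumour + rng.normal(0, 0.01, 3), 1e-6, 1 - 1e-6
        )
        pi = np.clip(trial.pi + rng.normal(0, 1e-4, 9), 1e-12, None)
        trial.pi = pi / pi.sum()
        ll, _ = _penalized_loglik(trial, *counts)
        assert ll <= best + 1e-9


def test_em_on_empty_input_rejected():
    with pytest.raises(ValueError):
        train_jsm_em([])


# ---------------------------------------------------------------------------
# Strelka-like model
# ---------------------------------------------------------------------------

def test_strelka_reference_tumour_scores_near_prior():
    s = site(normal=reads(200, 0, bq=93, mq=93), tumour=reads(200, 0, bq=93, mq=93))
    call = call_strelka_like(s)
    assert call.raw_score < PRIORS.mu_somatic * 10
    assert call.score < 1e-3


def test_strelka_detects_five_percent_candidate():
    s = site(normal=reads(200, 0, bq=93, mq=93), tumour=reads(190, 10, bq=40, mq=60))
    call = call_strelka_like(s)
    assert call.raw_score > 0.5
    assert call.normal_genotype == "AA"
    assert call.call_class == "somatic"


def test_strelka_score_stable_under_grid_refinement(rng):
    for _ in range(20):
        dn, dt = (int(x) for x in rng.integers(5, 60, 2))
        vt = int(rng.integers(0, dt + 1))
        vn = int(rng.integers(0, 3))
        bq = int(rng.integers(20, 45))
        s = site(normal=reads(dn - vn, vn, bq=bq), tumour=reads(dt - vt, vt, bq=bq))
        coarse = call_strelka_like(s, grid_step=0.01).raw_score
        fine = call_strelka_like(s, grid_step=0.005).raw_score
        assert abs(coarse - fine) <= 0.02


def test_strelka_zero_tumour_depth_returns_prior():
    s = site(normal=reads(50, 0), tumour=[])
    call = call_strelka_like(s)
    assert call.raw_score == pytest.approx(PRIORS.mu_somatic, rel=1e-6)


# ---------------------------------------------------------------------------
# cross-model properties
# ---------------------------------------------------------------------------

def test_bayesian_scores_monotone_in_variant_count():
    depth = 40
    sniper, jsm, strelka = [], [], []
    params = default_jsm_params()
    for v in range(21):
        s = site(normal=reads(depth, 0), tumour=reads(depth - v, v))
        sniper.append(call_somaticsniper(s).raw_score)
        jsm.append(call_jointsnvmix(s, params).raw_score)
        strelka.append(call_strelka_like(s).raw_score)
    for series in (sniper, jsm, strelka):
        assert all(b >= a - 1e-9 for a, b in zip(series, series[1:]))


def test_swapping_samples_maps_somatic_to_loh():
    normal, tumour = reads(50, 0, bq=93, mq=93), reads(25, 25, bq=93, mq=93)
    fwd = site(normal=normal, tumour=tumour)
    rev = site(normal=tumour, tumour=normal)
    assert call_somaticsniper(fwd).call_class == "somatic"
    assert call_somaticsniper(rev).call_class == "LOH"
    params = default_jsm_params()
    assert call_jointsnvmix(fwd, params).call_class == "somatic"
    assert call_jointsnvmix(rev, params).call_class == "LOH"


def test_strelka_outscores_varscan_on_subclonal_sites(rng):
    # low-allelic-fraction candidates: VAF 0.05-0.15 at depth 100
    n_rep = 500
    strelka_scores = np.zeros(n_rep)
    varscan_scores = np.zeros(n_rep)
    for i in range(n_rep):
        vaf = rng.uniform(0.05, 0.15)
        v = int(rng.binomial(100, vaf))
        s = site(normal=reads(100, 0), tumour=reads(100 - v, v))
        strelka_scores[i] = call_strelka_like(s).raw_score
        call = call_varscan(s)
        varscan_scores[i] = 0.0 if call is None else call.score
    assert strelka_scores.mean() > varscan_scores.mean()


# ---------------------------------------------------------------------------
# running the suite of callers
# ---------------------------------------------------------------------------

def _quiet_sim(**kw):
    base = dict(
        germline_het_rate=0.0, germline_hom_rate=0.0,
        n_clonal_somatic=0, n_subclonal_somatic=0,
        systematic_error_site_rate=0.0, spanning_deletion_rate=0.0,
        adjacent_indel_rate=0.0,
        base_quality_distribution=DiscreteDistribution.fixed(93),
        map_quality_distribution=DiscreteDistribution.fixed(93),
    )
    base.update(kw)
    return SimConfig(**base)


def test_no_caller_fires_on_noise_free_null():
    result = simulate_pair(_quiet_sim(n_sites=200, seed=STUDY_SEED,
                                      mean_depth_normal=40, mean_depth_tumour=40))
    run = run_all_callers(result.sites)
    for caller, calls in run.calls.items():
        assert not [c for c in calls if c.call_class == "somatic" and c.score >= 0.99]


def test_all_four_callers_find_a_clonal_site():
    result = simulate_pair(_quiet_sim(n_sites=60, seed=STUDY_SEED, n_clonal_somatic=1,
                                      tumour_purity=1.0, mean_depth_normal=60,
                                      mean_depth_tumour=60))
    (target,) = [t for t in result.truth if t.truth_class == "somatic_clonal"]
    run = run_all_callers(result.sites)
    for caller, calls in run.calls.items():
        match = [c for c in calls if c.pos == target.pos and c.call_class == "somatic"]
        assert match, f"{caller} missed the clonal site"
        assert match[0].score > 0.99, f"{caller} scored {match[0].score}"


def test_subclonal_site_splits_varscan_and_strelka():
    s = site(normal=reads(200, 0), tumour=reads(180, 20))  # VAF 0.10, depth 200
    assert call_varscan(s) is None
    assert call_strelka_like(s).phred_score >= 1
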