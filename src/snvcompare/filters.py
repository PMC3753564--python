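"""Post-calling filter suite and the strand-bias null expectation.

Candidate sites are removed if any of eight criteria are met, evaluated on
the variant reads of the relevant sample (tumour for somatic candidates,
normal for LOH candidates):

1. variant bases emanate exclusively from one strand;
2. mean variant base quality < 15;
3. no variant base quality over 30 (strict);
4. mean variant mapping quality < 15;
5. no variant mapping quality over 40 (strict);
6. more than two other candidate SNVs (from any caller) within 50 bp;
7. spanning deletions contribute > 20% of overall depth in either sample;
8. reads with an immediately adjacent indel exceed 20% in either sample.

Complete strand bias can also arise from fair random strand sampling: a site
with v variant reads is one-sided with probability (1/2)^(v-1), which gives
the null expectation against which the observed count of 100%-biased sites
is compared.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .core import (
    BASE_TO_INDEX,
    FILTER_RULES,
    AlleleSummary,
    CandidateCall,
    FilterVerdict,
    PairedSite,
    ReadStack,
    RuleResult,
    site_stacks,
    summarize_stack,
)


@dataclass(frozen=True)
class FilterConfig:
    min_mean_baseq: float = 15.0
    min_max_baseq: int = 30
    min_mean_mapq: float = 15.0
    min_max_mapq: int = 40
    snv_window: int = 50
    max_nearby_snvs: int = 2
    max_spanning_deletion_fraction: float = 0.20
    max_adjacent_indel_fraction: float = 0.20

    def __post_init__(self):
        for name in self.__dataclass_fields__:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def _relevant_sample(call: CandidateCall) -> str:
    # variant bases in the cancer sample for somatic candidates,
    # in the normal sample for LOH candidates
    return "normal" if call.call_class == "LOH" else "tumour"


def _variant_index(call: CandidateCall, stack: ReadStack, ref_idx: int) -> int | None:
    summary = call.normal_summary if _relevant_sample(call) == "normal" else call.tumour_summary
    if summary is not None and summary.variant_base is not None:
        return BASE_TO_INDEX[summary.variant_base]
    s = summarize_stack(stack, ref_idx, 0)
    return None if s.variant_base is None else BASE_TO_INDEX[s.variant_base]


def _fraction(mask: np.ndarray) -> float:
    return float(mask.mean()) if mask.size else 0.0


def count_nearby_candidates(
    chrom: str, pos: int, all_candidate_positions: set[tuple[str, int]], window: int
) -> int:
    """Other candidate positions within ``window`` bp either side (inclusive)."""
    return sum(
        1
        for p in range(pos - window, pos + window + 1)
        if p != pos and (chrom, p) in all_candidate_positions
    )


def apply_filters(
    call: CandidateCall,
    site: PairedSite,
    all_candidate_positions: set[tuple[str, int]],
    cfg: FilterConfig | None = None,
) -> FilterVerdict:
    """Evaluate the eight filter rules for one candidate call.

    ``all_candidate_positions`` is the union of raw candidate positions from
    every caller.  With zero variant reads the quality and strand rules pass
    vacuously.  ``overall_pass`` is the conjunction of all eight rules.
    """
    cfg = cfg or FilterConfig()
    stack_n, stack_t = site_stacks(site)
    stack = stack_n if _relevant_sample(call) == "normal" else stack_t
    ref_idx = BASE_TO_INDEX[site.ref]
    var_idx = _variant_index(call, stack, ref_idx)

    if var_idx is None:
        var_mask = np.zeros(len(stack), dtype=bool)
    else:
        var_mask = (stack.base_index == var_idx) & ~stack.spans_deletion
    v = int(var_mask.sum())
    rules: dict[str, RuleResult] = {}

    if v == 0:
        rules["strand_bias"] = RuleResult(True, None)
        rules["mean_base_quality"] = RuleResult(True, None)
        rules["max_base_quality"] = RuleResult(True, None)
        rules["mean_map_quality"] = RuleResult(True, None)
        rules["max_map_quality"] = RuleResult(True, None)
    else:
        v_fwd = int((var_mask & stack.forward).sum())
        one_sided = v_fwd == 0 or v_fwd == v
        rules["strand_bias"] = RuleResult(not one_sided, max(v_fwd, v - v_fwd) / v)
        bq = stack.base_quality[var_mask]
        mq = stack.map_quality[var_mask]
        mean_bq = float(bq.mean())
        mean_mq = float(mq.mean())
        rules["mean_base_quality"] = RuleResult(mean_bq >= cfg.min_mean_baseq, mean_bq)
        rules["max_base_quality"] = RuleResult(
            bool((bq > cfg.min_max_baseq).any()), float(bq.max())
        )
        rules["mean_map_quality"] = RuleResult(mean_mq >= cfg.min_mean_mapq, mean_mq)
        rules["max_map_quality"] = RuleResult(
            bool((mq > cfg.min_max_mapq).any()), float(mq.max())
        )

    nearby = count_nearby_candidates(call.chrom, call.pos, all_candidate_positions, cfg.snv_window)
    rules["nearby_candidates"] = RuleResult(nearby <= cfg.max_nearby_snvs, float(nearby))

    del_frac = max(_fraction(stack_n.spans_deletion), _fraction(stack_t.spans_deletion))
    rules["spanning_deletions"] = RuleResult(
        del_frac <= cfg.max_spanning_deletion_fraction, del_frac
    )
    indel_frac = max(_fraction(stack_n.adjacent_indel), _fraction(stack_t.adjacent_indel))
    rules["adjacent_indels"] = RuleResult(
        indel_frac <= cfg.max_adjacent_indel_fraction, indel_frac
    )
    assert set(rules) == set(FILTER_RULES)
    return FilterVerdict(
        chrom=call.chrom, pos=call.pos, caller_id=call.caller_id,
        call_class=call.call_class, rules=rules,
    )


def strand_bias_null_probability(v: int) -> float:
    """P(all v variant reads on one strand) under fair strand assignment.

    Both the all-forward and all-reverse outcomes count: 2 * (1/2)^v.
    """
    if v < 1:
        raise ValueError("v must be a positive integer")
    return 0.5 ** (v - 1)


@dataclass
class StrandBiasAccounting:
    """Observed vs expected counts of 100% strand-biased candidate sites."""

    expected: float
    observed: int
    variance: float  # Poisson-binomial variance of the null count
    n_sites: int
    n_excluded: int  # candidates with v = 0, excluded from the accounting

    @property
    def ratio(self) -> float:
        return self.observed / self.expected if self.expected > 0 else float("nan")


def _relevant_summary(call: CandidateCall) -> AlleleSummary | None:
    return call.normal_summary if _relevant_sample(call) == "normal" else call.tumour_summary


def expected_strand_bias_count(calls: Iterable[CandidateCall]) -> StrandBiasAccounting:
    """Null expectation of one-sided sites across candidates, plus the observed count.

    Uses each call's relevant-sample allele summary; calls with v = 0 are
    excluded and counted separately.
    """
    expected = 0.0
    variance = 0.0
    observed = 0
    n = 0
    excluded = 0
    for call in calls:
        s = _relevant_summary(call)
        if s is None or s.v < 1:
            excluded += 1
            continue
        p = strand_bias_null_probability(s.v)
        expected += p
        variance += p * (1.0 - p)
        n += 1
        if s.v_forward == 0 or s.v_reverse == 0:
            observed += 1
    return StrandBiasAccounting(expected, observed, variance, n, excluded)


def filter_report_rows(verdicts: Sequence[FilterVerdict]) -> list[dict]:
    """One row per site per rule, for the filter report TSV."""
    rows = []
    for verdict in verdicts:
        for rule in FILTER_RULES:
            r = verdict.rules[rule]
            rows.append(
                {
                    "chrom": verdict.chrom,
                    "pos": verdict.pos,
                    "caller": verdict.caller_id,
                    "class": verdict.call_class,
                    "rule": rule,
                    "passed": int(r.passed),
                    "metric": "" if r.metric is None else f"{r.metric:.6g}",
                }
            )
    return rows
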