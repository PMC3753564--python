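"""Cross-caller comparison and characterization statistics.

Builds a site-by-caller comparison matrix from each caller's candidate set
and derives: overlap counts over all caller subsets; pairwise Pearson
correlations of probability scores on shared sites; threshold sweeps of
multi-caller support and known-site (dbSNP-analog) membership; sorted
variant-allele-fraction profiles of caller-unique sites; filter pass-rate
tables with pairwise significance tests; and truth-based sensitivity /
germline-leak evaluation on simulated data.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency, fisher_exact

from .core import CandidateCall, FilterVerdict, TruthRecord, FILTER_RULES

SOMATIC_TRUTH_CLASSES = ("somatic_clonal", "somatic_subclonal")
GERMLINE_TRUTH_CLASSES = ("germline_het", "germline_hom")


@dataclass
class ComparisonMatrix:
    """Scores and classes per (chrom, pos) site and caller.

    ``scores`` and ``classes`` are DataFrames indexed by (chrom, pos) with
    one column per caller; a NaN/None entry means the caller did not return
    the site.  ``calls`` maps (chrom, pos, caller) to the CandidateCall.
    """

    scores: pd.DataFrame
    classes: pd.DataFrame
    calls: dict[tuple[str, int, str], CandidateCall]

    @classmethod
    def from_calls(
        cls,
        calls_by_caller: Mapping[str, Sequence[CandidateCall]],
        class_filter: str | None = None,
    ) -> "ComparisonMatrix":
        """Assemble the matrix, optionally restricted to one call class."""
        records: dict[tuple[str, int, str], CandidateCall] = {}
        for caller, calls in calls_by_caller.items():
            for c in calls:
                if class_filter is not None and c.call_class != class_filter:
                    continue
                records[(c.chrom, c.pos, caller)] = c
        sites = sorted({(c, p) for (c, p, _) in records})
        callers = list(calls_by_caller)
        index = pd.MultiIndex.from_tuples(sites, names=["chrom", "pos"]) if sites else (
            pd.MultiIndex.from_arrays([[], []], names=["chrom", "pos"])
        )
        scores = pd.DataFrame(np.nan, index=index, columns=callers)
        classes = pd.DataFrame(None, index=index, columns=callers, dtype=object)
        for (chrom, pos, caller), call in records.items():
            scores.loc[(chrom, pos), caller] = call.score
            classes.loc[(chrom, pos), caller] = call.call_class
        return cls(scores=scores, classes=classes, calls=records)

    @property
    def callers(self) -> list[str]:
        return list(self.scores.columns)

    def sites_of(self, caller: str) -> set[tuple[str, int]]:
        mask = self.scores[caller].notna()
        return set(self.scores.index[mask])


def overlap_counts(
    matrix: ComparisonMatrix, class_filter: str | None = None
) -> dict[tuple[str, ...], int]:
    """Counts of sites partitioned by the exact subset of callers reporting them.

    All 15 non-empty caller subsets are keyed (sorted caller tuples); counts
    sum to the number of distinct sites.
    """
    present = matrix.scores.notna()
    if class_filter is not None:
        present = present & (matrix.classes == class_filter)
    callers = matrix.callers
    counts: dict[tuple[str, ...], int] = {}
    for r in range(1, len(callers) + 1):
        for subset in combinations(callers, r):
            counts[tuple(sorted(subset))] = 0
    for _, row in present.iterrows():
        subset = tuple(sorted(c for c in callers if row[c]))
        if subset:
            counts[subset] += 1
    return counts


def pairwise_score_correlation(matrix: ComparisonMatrix, min_shared: int = 3) -> pd.DataFrame:
    """Pearson r of probability scores over shared sites, for each caller pair.

    Pairs with fewer than ``min_shared`` shared sites, or with a
    zero-variance score vector, are reported as undefined (NaN) and flagged.
    """
    rows = []
    for a, b in combinations(matrix.callers, 2):
        shared = matrix.scores[[a, b]].dropna()
        n = len(shared)
        r = np.nan
        defined = False
        if n >= min_shared:
            x = shared[a].to_numpy()
            y = shared[b].to_numpy()
            if x.std() > 0 and y.std() > 0:
                r = float(np.corrcoef(x, y)[0, 1])
                defined = True
        rows.append({"caller_a": a, "caller_b": b, "n_shared": n, "pearson_r": r,
                     "defined": defined})
    return pd.DataFrame(rows)


def threshold_sweep(
    matrix: ComparisonMatrix,
    known_sites: set[tuple[str, int]],
    thresholds: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Effect of raising each caller's score threshold towards 1.

    For each caller and threshold t: ``n_retained`` sites with score >= t;
    ``fraction_multicaller`` = share of retained sites found by at least one
    other caller at any score; ``fraction_known`` = share present in
    ``known_sites`` (the dbSNP analog).  Empty retained sets give NaN.
    """
    if thresholds is None:
        thresholds = np.linspace(0.0, 1.0, 101)
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any(np.diff(thresholds) < 0):
        raise ValueError("thresholds must be ascending")
    membership = {c: matrix.sites_of(c) for c in matrix.callers}
    rows = []
    for caller in matrix.callers:
        col = matrix.scores[caller].dropna()
        others = set().union(*(membership[c] for c in matrix.callers if c != caller)) if (
            len(matrix.callers) > 1
        ) else set()
        for t in thresholds:
            retained = col.index[col.to_numpy() >= t]
            n = len(retained)
            if n == 0:
                multi = np.nan
                known = np.nan
            else:
                sites = set(retained)
                multi = len(sites & others) / n
                known = len(sites & known_sites) / n
            rows.append(
                {"caller": caller, "threshold": float(t), "n_retained": n,
                 "fraction_multicaller": multi, "fraction_known": known}
            )
    return pd.DataFrame(rows)


def vaf_profile(
    calls_by_caller: Mapping[str, Sequence[CandidateCall]]
) -> dict[str, np.ndarray]:
    """Sorted tumour/normal variant-proportion profiles of caller-unique sites.

    For each caller, sites reported by that caller alone are sorted by tumour
    variant proportion; rows are (scaled_index, tumour_vp, normal_vp), with
    scaled_index = i / (n - 1) (a single site sits at 0).  The normal-sample
    proportion is carried along un-sorted-by-itself (the "jagged" trace).
    """
    site_sets = {
        caller: {(c.chrom, c.pos) for c in calls}
        for caller, calls in calls_by_caller.items()
    }
    profiles: dict[str, np.ndarray] = {}
    for caller, calls in calls_by_caller.items():
        others = set().union(
            *(s for name, s in site_sets.items() if name != caller)
        ) if len(site_sets) > 1 else set()
        unique = {}
        for c in calls:
            if (c.chrom, c.pos) not in others:
                unique[(c.chrom, c.pos)] = c
        if not unique:
            profiles[caller] = np.empty((0, 3))
            continue
        tumour_vp = []
        normal_vp = []
        for c in unique.values():
            tumour_vp.append(c.tumour_summary.variant_proportion if c.tumour_summary else 0.0)
            normal_vp.append(c.normal_summary.variant_proportion if c.normal_summary else 0.0)
        order = np.argsort(tumour_vp, kind="stable")
        n = len(order)
        scaled = np.zeros(n) if n == 1 else np.arange(n) / (n - 1)
        profiles[caller] = np.column_stack(
            [scaled, np.asarray(tumour_vp)[order], np.asarray(normal_vp)[order]]
        )
    return profiles


def _two_proportion_test(
    pass_a: int, n_a: int, pass_b: int, n_b: int, method: str
) -> float:
    table = np.array([[pass_a, n_a - pass_a], [pass_b, n_b - pass_b]])
    if method == "fisher":
        return float(fisher_exact(table, alternative="two-sided")[1])
    if method == "chi2":
        if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            return 1.0
        return float(chi2_contingency(table, correction=True)[1])
    raise ValueError(f"unknown method {method!r}")


def pass_rate_table(
    verdicts_by_caller: Mapping[str, Sequence[FilterVerdict]],
    method: str = "chi2",
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Filter pass rates per caller, with pairwise significance tests.

    The first column is the strand-bias pass percentage over all candidates;
    the second is the pass percentage through the combination of all other
    rules computed on strand-bias survivors only.  Percentages are reported
    to one decimal.  Each column is compared between all caller pairs with a
    two-proportion chi-square test with continuity correction (or Fisher
    exact with ``method="fisher"``).
    """
    stats = {}
    for caller, verdicts in verdicts_by_caller.items():
        n = len(verdicts)
        survivors = [v for v in verdicts if v.rules["strand_bias"].passed]
        other_rules = [r for r in FILTER_RULES if r != "strand_bias"]
        n_other_pass = sum(
            1 for v in survivors if all(v.rules[r].passed for r in other_rules)
        )
        stats[caller] = {
            "n_candidates": n,
            "n_strand_pass": len(survivors),
            "n_other_pass": n_other_pass,
        }
    rows = []
    for caller, s in stats.items():
        defined = s["n_candidates"] > 0
        strand_pct = round(100.0 * s["n_strand_pass"] / s["n_candidates"], 1) if defined else np.nan
        other_defined = s["n_strand_pass"] > 0
        other_pct = (
            round(100.0 * s["n_other_pass"] / s["n_strand_pass"], 1) if other_defined else np.nan
        )
        rows.append(
            {"caller": caller, "n_candidates": s["n_candidates"],
             "strand_bias_pass_pct": strand_pct,
             "n_strand_survivors": s["n_strand_pass"],
             "other_filters_pass_pct": other_pct,
             "defined": defined}
        )
    table = pd.DataFrame(rows).set_index("caller")
    sig_rows = []
    for a, b in combinations(stats, 2):
        for column, num, den in (
            ("strand_bias", "n_strand_pass", "n_candidates"),
            ("other_filters", "n_other_pass", "n_strand_pass"),
        ):
            if stats[a][den] == 0 or stats[b][den] == 0:
                p = np.nan
            else:
                p = _two_proportion_test(
                    stats[a][num], stats[a][den], stats[b][num], stats[b][den], method
                )
            sig_rows.append(
                {"caller_a": a, "caller_b": b, "column": column, "p_value": p,
                 "significant": bool(p < alpha) if np.isfinite(p) else False}
            )
    return table, pd.DataFrame(sig_rows)


def evaluate_against_truth(
    calls_by_caller: Mapping[str, Sequence[CandidateCall]],
    truth: Sequence[TruthRecord],
    vaf_bins: Sequence[float] | None = None,
    score_threshold: float = 0.95,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Truth-based sensitivity per tumour-VAF bin and germline-leak summary.

    Sensitivity in a bin = somatic truth sites in the bin for which the
    caller emitted a somatic call with score >= ``score_threshold``, divided
    by the number of somatic truth sites in the bin (NaN for empty bins).
    The summary reports, per caller, the fraction of its somatic calls that
    land on germline-truth sites (the dbSNP-proportion analog) and on
    sites with no planted variant at all.
    """
    if vaf_bins is None:
        vaf_bins = (0.0, 0.05, 0.10, 0.20, 0.50, 1.0)
    edges = np.asarray(vaf_bins, dtype=float)
    truth_by_pos = {(t.chrom, t.pos): t for t in truth}
    somatic_truth = [t for t in truth if t.truth_class in SOMATIC_TRUTH_CLASSES]
    germline_pos = {
        (t.chrom, t.pos) for t in truth if t.truth_class in GERMLINE_TRUTH_CLASSES
    }
    bin_rows = []
    summary_rows = []
    for caller, calls in calls_by_caller.items():
        called = {
            (c.chrom, c.pos)
            for c in calls
            if c.call_class == "somatic" and c.score >= score_threshold
        }
        for lo, hi in zip(edges[:-1], edges[1:]):
            in_bin = [t for t in somatic_truth if lo < t.true_vaf_tumour <= hi]
            n = len(in_bin)
            hits = sum(1 for t in in_bin if (t.chrom, t.pos) in called)
            bin_rows.append(
                {"caller": caller, "vaf_lo": lo, "vaf_hi": hi, "n_truth": n,
                 "n_called": hits, "sensitivity": (hits / n) if n else np.nan}
            )
        somatic_calls = [c for c in calls if c.call_class == "somatic"]
        n_calls = len(somatic_calls)
        n_germ = sum(1 for c in somatic_calls if (c.chrom, c.pos) in germline_pos)
        n_empty = sum(
            1 for c in somatic_calls
            if truth_by_pos.get((c.chrom, c.pos)) is not None
            and truth_by_pos[(c.chrom, c.pos)].truth_class in ("none", "systematic_error")
        )
        summary_rows.append(
            {"caller": caller, "n_somatic_calls": n_calls,
             "germline_leak": (n_germ / n_calls) if n_calls else np.nan,
             "no_variant_fraction": (n_empty / n_calls) if n_calls else np.nan}
        )
    return pd.DataFrame(bin_rows), pd.DataFrame(summary_rows)
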