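#!/usr/bin/env python
"""Compare the four candidate sets: overlaps, score correlations, threshold
sweeps, VAF profiles of caller-unique sites, and truth-based evaluation.

Writes the comparison tables plus SVG figures (score distributions for
unique vs shared sites, multi-caller support and germline-site proportion
versus score threshold, and the sorted VAF profiles of caller-unique sites).
"""

import argparse
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from snvcompare.concordance import (
    ComparisonMatrix,
    GERMLINE_TRUTH_CLASSES,
    evaluate_against_truth,
    overlap_counts,
    pairwise_score_correlation,
    threshold_sweep,
    vaf_profile,
)
from snvcompare.core import read_candidates
from snvcompare.simulate import read_truth

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--in-dir", type=Path, default=Path("results/demo"))
args = parser.parse_args()

calls_by_caller = {
    path.stem.removeprefix("raw_"): list(read_candidates(path))
    for path in sorted(args.in_dir.glob("raw_*.tsv"))
}
truth = list(read_truth(args.in_dir / "truth.tsv"))
germline = {(t.chrom, t.pos) for t in truth if t.truth_class in GERMLINE_TRUTH_CLASSES}

matrix = ComparisonMatrix.from_calls(calls_by_caller, class_filter="somatic")
overlaps = overlap_counts(matrix)
pd.DataFrame(
    [{"callers": "&".join(k), "n_sites": v} for k, v in sorted(overlaps.items())]
).to_csv(args.in_dir / "overlaps.tsv", sep="\t", index=False)
total = sum(overlaps.values())
four_way = overlaps.get(tuple(sorted(calls_by_caller)), 0)
unique = sum(v for k, v in overlaps.items() if len(k) == 1)
print(f"{total} distinct somatic candidate sites; {four_way} returned by all four "
      f"callers, {unique} unique to one caller")

correlations = pairwise_score_correlation(matrix)
correlations.to_csv(args.in_dir / "correlations.tsv", sep="\t", index=False)
print("\npairwise Pearson r of probability scores on shared sites:")
for _, row in correlations.iterrows():
    r = f"{row.pearson_r:.2f}" if row.defined else "undefined"
    print(f"  {row.caller_a} & {row.caller_b}: {r}  (n={row.n_shared})")

sweep = threshold_sweep(matrix, germline)
sweep.to_csv(args.in_dir / "sweep.tsv", sep="\t", index=False)
profiles = vaf_profile(calls_by_caller)
pd.DataFrame(
    [{"caller": c, "scaled_index": r[0], "tumour_vp": r[1], "normal_vp": r[2]}
     for c, arr in profiles.items() for r in arr]
).to_csv(args.in_dir / "vaf_profiles.tsv", sep="\t", index=False)

bins, summary = evaluate_against_truth(calls_by_caller, truth)
bins.to_csv(args.in_dir / "truth_eval.tsv", sep="\t", index=False)
summary.to_csv(args.in_dir / "truth_summary.tsv", sep="\t", index=False)
print("\nsensitivity by true tumour VAF bin (score >= 0.95):")
print(bins.pivot_table(index=["vaf_lo", "vaf_hi"], columns="caller",
                       values="sensitivity").round(2))

# ---------------------------------------------------------------- figures
colors = {"varscan": "tab:red", "somaticsniper": "tab:green",
          "jointsnvmix": "tab:orange", "strelka_like": "tab:blue"}

fig, axes = plt.subplots(2, 2, figsize=(9, 7), sharex=True)
site_sets = {c: matrix.sites_of(c) for c in matrix.callers}
for ax, caller in zip(axes.ravel(), matrix.callers):
    scores = matrix.scores[caller].dropna()
    others = set().union(*(s for c, s in site_sets.items() if c != caller))
    is_unique = [idx not in others for idx in scores.index]
    ax.hist([scores[np.array(is_unique)], scores[~np.array(is_unique)]],
            bins=20, stacked=True,
            color=[colors[caller], "0.3"], label=["unique", "shared"])
    ax.set_title(caller)
    ax.legend(fontsize=8)
fig.suptitle("somatic probability scores: caller-unique vs shared sites")
fig.savefig(args.in_dir / "score_distributions.svg")

fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
for caller in matrix.callers:
    d = sweep[sweep.caller == caller]
    ax1.plot(d.threshold, d.fraction_multicaller, color=colors[caller], label=caller)
    ax2.plot(d.threshold, d.fraction_known, color=colors[caller], label=caller)
ax1.set_xlabel("score threshold"); ax1.set_ylabel("fraction found by another caller")
ax2.set_xlabel("score threshold"); ax2.set_ylabel("fraction at germline truth sites")
ax1.legend(fontsize=8)
fig.tight_layout()
fig.savefig(args.in_dir / "threshold_sweep.svg")

fig, ax = plt.subplots(figsize=(6, 4))
for caller, arr in profiles.items():
    if len(arr):
        ax.plot(arr[:, 0], arr[:, 1], color=colors[caller], label=f"{caller} tumour")
        ax.plot(arr[:, 0], arr[:, 2], color=colors[caller], alpha=0.4, lw=0.8)
ax.set_xlabel("scaled index"); ax.set_ylabel("variant proportion")
ax.legend(fontsize=8)
fig.tight_layout()
fig.savefig(args.in_dir / "vaf_profiles.svg")
print(f"\nwrote tables and SVG figures to {args.in_dir}")
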