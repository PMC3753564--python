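"""End-to-end pipeline: simulate -> call -> filter -> compare -> split null.

Every stage writes a plain-text file into the output directory, so each
stage can equally be re-run standalone on real pileup data.  A manifest
records the configuration echo, per-stage counts and a content hash of every
output file; with an identical configuration and seed the manifest is
byte-identical across runs (no timestamps or absolute paths are recorded).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import concordance as conc
from .callers import CallerSuiteConfig, JsmParams, run_all_callers
from .core import CandidateCall, write_candidates, write_paired_pileup
from .filters import (
    FilterConfig,
    apply_filters,
    expected_strand_bias_count,
    filter_report_rows,
)
from .simulate import (
    SimConfig,
    SimResult,
    sim_config_from_dict,
    sim_config_to_dict,
    simulate_pair,
    split_null,
    write_truth,
)

logger = logging.getLogger("snvcompare")


def derive_seed(seed: int, k: int) -> int:
    """Deterministic sub-seed below 2^31 for stage ``k``."""
    return (int(seed) * 1000003 + k) % (2**31)


@dataclass
class PipelineConfig:
    """Composition of all stage configurations under a single master seed."""

    sim: SimConfig = field(default_factory=SimConfig)
    caller_config: CallerSuiteConfig = field(default_factory=CallerSuiteConfig)
    filter_config: FilterConfig = field(default_factory=FilterConfig)
    seed: int = 0
    score_threshold: float = 0.95
    n_thresholds: int = 101
    run_split_null: bool = True
    split_null_n_sites: int = 5000


def _jsm_params_to_dict(p: JsmParams | None) -> dict | None:
    if p is None:
        return None
    return {f.name: getattr(p, f.name).tolist() for f in dataclasses.fields(p)}


def _jsm_params_from_dict(d: dict | None) -> JsmParams | None:
    if d is None:
        return None
    return JsmParams(**{k: np.asarray(v, dtype=float) for k, v in d.items()})


def pipeline_config_to_dict(cfg: PipelineConfig) -> dict:
    caller = dataclasses.asdict(cfg.caller_config)
    caller["jsm_params0"] = _jsm_params_to_dict(cfg.caller_config.jsm_params0)
    return {
        "sim": sim_config_to_dict(cfg.sim),
        "caller_config": caller,
        "filter_config": dataclasses.asdict(cfg.filter_config),
        "seed": cfg.seed,
        "score_threshold": cfg.score_threshold,
        "n_thresholds": cfg.n_thresholds,
        "run_split_null": cfg.run_split_null,
        "split_null_n_sites": cfg.split_null_n_sites,
    }


def pipeline_config_from_dict(d: dict) -> PipelineConfig:
    from .callers import GenotypeLikelihoodModel, PriorConfig, VarscanConfig

    d = dict(d)
    caller_d = dict(d.get("caller_config", {}))
    caller_kwargs = {}
    if caller_d:
        caller_kwargs["varscan"] = VarscanConfig(**caller_d.pop("varscan", {}))
        caller_kwargs["priors"] = PriorConfig(**caller_d.pop("priors", {}))
        caller_kwargs["model"] = GenotypeLikelihoodModel(**caller_d.pop("model", {}))
        caller_kwargs["jsm_params0"] = _jsm_params_from_dict(caller_d.pop("jsm_params0", None))
        caller_kwargs.update(caller_d)
    return PipelineConfig(
        sim=sim_config_from_dict(d.get("sim", {})),
        caller_config=CallerSuiteConfig(**caller_kwargs),
        filter_config=FilterConfig(**d.get("filter_config", {})),
        seed=d.get("seed", 0),
        score_threshold=d.get("score_threshold", 0.95),
        n_thresholds=d.get("n_thresholds", 101),
        run_split_null=d.get("run_split_null", True),
        split_null_n_sites=d.get("split_null_n_sites", 5000),
    )


def load_pipeline_config(path) -> PipelineConfig:
    with open(path) as fh:
        return pipeline_config_from_dict(yaml.safe_load(fh) or {})


def save_pipeline_config(cfg: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(pipeline_config_to_dict(cfg), fh, sort_keys=True)


def demo_config(seed: int = 0) -> PipelineConfig:
    """The demonstration study: full default conditions at reduced scale
    (5000 sites plus a 2000-site split null) so the whole pipeline runs in
    well under a minute."""
    return PipelineConfig(
        sim=dataclasses.replace(SimConfig(), n_sites=5000),
        seed=seed,
        split_null_n_sites=2000,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_df(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")


def candidate_positions(calls_by_caller) -> set[tuple[str, int]]:
    """Union of raw candidate positions from every caller."""
    return {
        (c.chrom, c.pos) for calls in calls_by_caller.values() for c in calls
    }


def filter_candidates(calls_by_caller, sites_by_pos, cfg: FilterConfig):
    """Apply the filter suite to every candidate of every caller.

    Returns (verdicts_by_caller, filtered_calls_by_caller); the nearby-SNV
    rule sees the union of raw candidate positions from all callers.
    """
    all_positions = candidate_positions(calls_by_caller)
    verdicts = {}
    filtered = {}
    for caller, calls in calls_by_caller.items():
        vs = []
        keep = []
        for call in calls:
            site = sites_by_pos[(call.chrom, call.pos)]
            verdict = apply_filters(call, site, all_positions, cfg)
            vs.append(verdict)
            if verdict.overall_pass:
                keep.append(call)
        verdicts[caller] = vs
        filtered[caller] = keep
    return verdicts, filtered


def _count_by_class(calls) -> dict[str, int]:
    out: dict[str, int] = {}
    for c in calls:
        out[c.call_class] = out.get(c.call_class, 0) + 1
    return out


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run the full study; returns (and writes) the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": pipeline_config_to_dict(config),
        "stages": [],
        "counts": {},
        "files": {},
    }

    def record(name: str, path: Path):
        manifest["files"][name] = _sha256(path)

    # -- stage 1: simulate ---------------------------------------------------
    sim_cfg = dataclasses.replace(config.sim, seed=derive_seed(config.seed, 1))
    logger.info("simulating %d sites (seed %d)", sim_cfg.n_sites, sim_cfg.seed)
    result = simulate_pair(sim_cfg)
    write_paired_pileup(result.sites, out / "pileup.tsv")
    write_truth(result.truth, out / "truth.tsv")
    record("pileup.tsv", out / "pileup.tsv")
    record("truth.tsv", out / "truth.tsv")
    manifest["stages"].append("simulate")

    # -- stage 2: call -------------------------------------------------------
    caller_cfg = dataclasses.replace(
        config.caller_config, subsample_seed=derive_seed(config.seed, 2)
    )
    run = run_all_callers(result.sites, caller_cfg)
    for caller, calls in run.calls.items():
        write_candidates(calls, out / f"raw_{caller}.tsv", "tsv")
        write_candidates(calls, out / f"raw_{caller}.vcf", "vcf")
        record(f"raw_{caller}.tsv", out / f"raw_{caller}.tsv")
        record(f"raw_{caller}.vcf", out / f"raw_{caller}.vcf")
        manifest["counts"][f"raw_{caller}"] = _count_by_class(calls)
    manifest["counts"]["jsm_em_iterations"] = len(run.jsm_trace) - 1
    manifest["stages"].append("call")

    # -- stage 3: filter -----------------------------------------------------
    sites_by_pos = result.sites_by_position()
    verdicts, filtered = filter_candidates(run.calls, sites_by_pos, config.filter_config)
    report = pd.DataFrame(
        [row for caller in verdicts for row in filter_report_rows(verdicts[caller])]
    )
    _write_df(report, out / "filter_report.tsv")
    record("filter_report.tsv", out / "filter_report.tsv")
    for caller, calls in filtered.items():
        write_candidates(calls, out / f"filtered_{caller}.tsv", "tsv")
        record(f"filtered_{caller}.tsv", out / f"filtered_{caller}.tsv")
        manifest["counts"][f"filtered_{caller}"] = _count_by_class(calls)
    pooled = [c for calls in run.calls.values() for c in calls]
    acc = expected_strand_bias_count(pooled)
    manifest["counts"]["strand_bias"] = {
        "observed": acc.observed,
        "expected": round(acc.expected, 3),
        "n_sites": acc.n_sites,
        "n_excluded": acc.n_excluded,
    }
    manifest["stages"].append("filter")

    # -- stage 4: compare ----------------------------------------------------
    matrix = conc.ComparisonMatrix.from_calls(run.calls, class_filter="somatic")
    overlaps = conc.overlap_counts(matrix)
    overlap_df = pd.DataFrame(
        [{"callers": "&".join(k), "n_sites": v} for k, v in sorted(overlaps.items())]
    )
    _write_df(overlap_df, out / "overlaps.tsv")
    _write_df(conc.pairwise_score_correlation(matrix), out / "correlations.tsv")
    germline_pos = {
        (t.chrom, t.pos)
        for t in result.truth
        if t.truth_class in conc.GERMLINE_TRUTH_CLASSES
    }
    sweep = conc.threshold_sweep(
        matrix, germline_pos, np.linspace(0.0, 1.0, config.n_thresholds)
    )
    _write_df(sweep, out / "sweep.tsv")
    profiles = conc.vaf_profile(run.calls)
    profile_df = pd.DataFrame(
        [
            {"caller": caller, "scaled_index": row[0], "tumour_vp": row[1], "normal_vp": row[2]}
            for caller, arr in profiles.items()
            for row in arr
        ]
    )
    _write_df(profile_df, out / "vaf_profiles.tsv")
    rates, significance = conc.pass_rate_table(verdicts)
    _write_df(rates, out / "pass_rates.tsv", index=True)
    _write_df(significance, out / "pass_rate_tests.tsv")
    bins, summary = conc.evaluate_against_truth(
        run.calls, result.truth, score_threshold=config.score_threshold
    )
    _write_df(bins, out / "truth_eval.tsv")
    _write_df(summary, out / "truth_summary.tsv")
    for name in (
        "overlaps.tsv", "correlations.tsv", "sweep.tsv", "vaf_profiles.tsv",
        "pass_rates.tsv", "pass_rate_tests.tsv", "truth_eval.tsv", "truth_summary.tsv",
    ):
        record(name, out / name)
    manifest["stages"].append("compare")

    # -- stage 5: normal-normal split null ------------------------------------
    if config.run_split_null:
        null_cfg = dataclasses.replace(
            config.sim,
            n_sites=config.split_null_n_sites,
            seed=derive_seed(config.seed, 5),
        )
        pseudo, _parent = split_null(null_cfg)
        null_run = run_all_callers(pseudo.sites, caller_cfg)
        null_sites = pseudo.sites_by_position()
        null_verdicts, null_filtered = filter_candidates(
            null_run.calls, null_sites, config.filter_config
        )
        rows = []
        for caller, calls in null_run.calls.items():
            kept = null_filtered[caller]
            rows.append(
                {
                    "caller": caller,
                    "raw_somatic": sum(c.call_class == "somatic" for c in calls),
                    "filtered_somatic": sum(c.call_class == "somatic" for c in kept),
                    "filtered_somatic_high_score": sum(
                        c.call_class == "somatic" and c.score >= config.score_threshold
                        for c in kept
                    ),
                }
            )
        null_df = pd.DataFrame(rows)
        _write_df(null_df, out / "splitnull_summary.tsv")
        record("splitnull_summary.tsv", out / "splitnull_summary.tsv")
        manifest["counts"]["split_null_false_positives"] = int(
            null_df["filtered_somatic_high_score"].sum()
        )
        manifest["stages"].append("split_null")

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
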