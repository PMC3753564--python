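"""Synthetic matched cancer-normal paired pileups with known ground truth.

The generator emulates the statistical structure of an Illumina exome pair:
per-site read stacks with base quality, mapping quality and strand for both
samples; germline heterozygotes and homozygotes; clonal somatic SNVs whose
tumour VAF is scaled by tumour purity (a heterozygous mutation in a diploid
tumour has expected VAF purity/2); subclonal somatic SNVs at low VAF; random
base-call error driven by phred scores; and systematic errors confined to one
strand at susceptible sites.  It also provides the normal-normal split null:
one non-cancer sample simulated at double depth and randomly halved into a
pseudo-pair, so that every "somatic" call on the pseudo-pair is a false
positive by construction.

It does not attempt exome capture geometry, GC bias, mappability or
read-position error profiles.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import yaml

from .core import (
    BASES,
    FORWARD,
    REVERSE,
    INDEX_TO_BASE,
    PairedSite,
    ReadObservation,
    TruthRecord,
    _PHRED_PROB,
    _open_maybe,
)


@dataclass(frozen=True)
class DiscreteDistribution:
    """A small discrete distribution over integer quality values."""

    values: tuple[int, ...]
    probs: tuple[float, ...]

    def __post_init__(self):
        if len(self.values) != len(self.probs) or not self.values:
            raise ValueError("values and probs must be non-empty and equal length")
        if any(p < 0 for p in self.probs):
            raise ValueError("probabilities must be non-negative")
        if abs(sum(self.probs) - 1.0) > 1e-9:
            raise ValueError("probabilities must sum to 1")

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        cum = np.cumsum(self.probs)
        idx = np.searchsorted(cum, rng.random(size), side="right")
        return np.asarray(self.values, dtype=np.int16)[np.minimum(idx, len(self.values) - 1)]

    @property
    def mean(self) -> float:
        return float(np.dot(self.values, self.probs))

    @classmethod
    def fixed(cls, value: int) -> "DiscreteDistribution":
        return cls((value,), (1.0,))


def default_base_quality_distribution() -> DiscreteDistribution:
    # loosely HiSeq-like: most calls Q30+, a small low-quality tail
    return DiscreteDistribution((10, 15, 20, 25, 30, 35, 40), (0.02, 0.02, 0.04, 0.07, 0.15, 0.30, 0.40))


def default_map_quality_distribution() -> DiscreteDistribution:
    # bwa-like: mostly uniquely mapped (60), some repetitive/ambiguous mass
    return DiscreteDistribution((0, 20, 37, 60), (0.02, 0.04, 0.14, 0.80))


@dataclass
class SimConfig:
    """Study conditions for one simulated cancer-normal pair.

    Rates are per site (``germline_*``, ``systematic_error_site_rate``) or per
    read (``systematic_error_read_rate``, ``spanning_deletion_rate``,
    ``adjacent_indel_rate``).  ``subclonal_vaf_range`` bounds the tumour VAF
    drawn uniformly per subclonal site.  ``normal_contamination`` is the
    fraction of tumour cells contaminating the normal sample.
    """

    n_sites: int = 50_000
    seed: int = 0
    mean_depth_normal: float = 60.0
    mean_depth_tumour: float = 60.0
    depth_model: str = "poisson"  # or "negative_binomial"
    depth_dispersion: float = 3.0  # NB size parameter (smaller => more dispersed)
    germline_het_rate: float = 1e-3
    germline_hom_rate: float = 5e-4
    n_clonal_somatic: int = 30
    tumour_purity: float = 0.8
    n_subclonal_somatic: int = 30
    subclonal_vaf_range: tuple[float, float] = (0.03, 0.15)
    systematic_error_site_rate: float = 1e-3
    systematic_error_read_rate: float = 0.1
    base_quality_distribution: DiscreteDistribution = field(
        default_factory=default_base_quality_distribution
    )
    map_quality_distribution: DiscreteDistribution = field(
        default_factory=default_map_quality_distribution
    )
    normal_contamination: float = 0.0
    spanning_deletion_rate: float = 0.01
    adjacent_indel_rate: float = 0.01
    chrom: str = "chr1"
    position_step: int = 100

    def validate(self) -> None:
        rates = {
            "germline_het_rate": self.germline_het_rate,
            "germline_hom_rate": self.germline_hom_rate,
            "systematic_error_site_rate": self.systematic_error_site_rate,
            "systematic_error_read_rate": self.systematic_error_read_rate,
            "normal_contamination": self.normal_contamination,
            "spanning_deletion_rate": self.spanning_deletion_rate,
            "adjacent_indel_rate": self.adjacent_indel_rate,
            "tumour_purity": self.tumour_purity,
        }
        for name, r in rates.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {r}")
        lo, hi = self.subclonal_vaf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("subclonal_vaf_range must lie within (0, 0.5]")
        if self.n_sites < 1:
            raise ValueError("n_sites must be positive")
        if self.depth_model not in ("poisson", "negative_binomial"):
            raise ValueError(f"unknown depth model {self.depth_model!r}")
        expected_mutated = (
            self.n_clonal_somatic
            + self.n_subclonal_somatic
            + (self.germline_het_rate + self.germline_hom_rate) * self.n_sites
        )
        if expected_mutated > self.n_sites:
            raise ValueError(
                "infeasible config: more mutation sites than n_sites "
                f"({expected_mutated:.0f} > {self.n_sites})"
            )


@dataclass
class SimResult:
    """Simulated paired sites plus aligned ground truth."""

    sites: list[PairedSite]
    truth: list[TruthRecord]

    def __post_init__(self):
        if len(self.sites) != len(self.truth):
            raise ValueError("sites and truth must be aligned")

    def truth_by_position(self) -> dict[tuple[str, int], TruthRecord]:
        return {(t.chrom, t.pos): t for t in self.truth}

    def sites_by_position(self) -> dict[tuple[str, int], PairedSite]:
        return {(s.chrom, s.pos): s for s in self.sites}


# integer truth codes used internally during assignment
_CLASS_CODES = ("none", "germline_het", "germline_hom", "somatic_clonal",
                "somatic_subclonal", "systematic_error")


def _draw_depths(rng: np.random.Generator, cfg: SimConfig, mean: float) -> np.ndarray:
    if mean <= 0:
        return np.zeros(cfg.n_sites, dtype=np.int64)
    if cfg.depth_model == "poisson":
        return rng.poisson(mean, cfg.n_sites)
    k = cfg.depth_dispersion
    return rng.negative_binomial(k, k / (k + mean), cfg.n_sites)


def _draw_reads(
    rng: np.random.Generator,
    depth: int,
    ref_idx: int,
    var_idx: int,
    vaf: float,
    cfg: SimConfig,
    sys_strand_forward: bool | None,
) -> list[ReadObservation]:
    """Draw one sample's read stack at one site.

    Each read: true allele ~ Bernoulli(vaf), strand ~ Bernoulli(1/2),
    qualities from the configured distributions, the observed base corrupted
    to a uniform other base with probability 10^(-baseQ/10), then systematic
    corruption to the variant base on the susceptible strand when applicable.
    """
    if depth == 0:
        return []
    is_var = rng.random(depth) < vaf
    fwd = rng.random(depth) < 0.5
    bq = cfg.base_quality_distribution.draw(rng, depth)
    mq = cfg.map_quality_distribution.draw(rng, depth)
    true_idx = np.where(is_var, var_idx, ref_idx)
    err = rng.random(depth) < _PHRED_PROB[bq]
    shift = rng.integers(1, 4, depth)
    obs_idx = np.where(err, (true_idx + shift) % 4, true_idx)
    if sys_strand_forward is not None:
        hit = (fwd == sys_strand_forward) & (rng.random(depth) < cfg.systematic_error_read_rate)
        obs_idx = np.where(hit, var_idx, obs_idx)
    dels = rng.random(depth) < cfg.spanning_deletion_rate
    indels = rng.random(depth) < cfg.adjacent_indel_rate
    return [
        ReadObservation(
            base=INDEX_TO_BASE[obs_idx[i]],
            base_quality=int(bq[i]),
            map_quality=int(mq[i]),
            strand=FORWARD if fwd[i] else REVERSE,
            spans_deletion=bool(dels[i]),
            adjacent_indel=bool(indels[i]),
        )
        for i in range(depth)
    ]


def simulate_pair(config: SimConfig) -> SimResult:
    """Simulate a matched cancer-normal pair; deterministic under fixed seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_sites

    positions = 1 + config.position_step * np.arange(n)
    ref_idx = rng.integers(0, 4, n)
    var_idx = (ref_idx + rng.integers(1, 4, n)) % 4

    # per-site truth class: somatic sites are planted first (exclusively),
    # the rest draw germline / systematic-error / none labels
    classes = np.zeros(n, dtype=np.int8)
    u = rng.random(n)
    het, hom, sys_ = (
        config.germline_het_rate,
        config.germline_hom_rate,
        config.systematic_error_site_rate,
    )
    classes[u < het] = 1
    classes[(u >= het) & (u < het + hom)] = 2
    classes[(u >= het + hom) & (u < het + hom + sys_)] = 5
    n_somatic = config.n_clonal_somatic + config.n_subclonal_somatic
    if n_somatic > 0:
        somatic_sites = rng.choice(n, n_somatic, replace=False)
        classes[somatic_sites[: config.n_clonal_somatic]] = 3
        classes[somatic_sites[config.n_clonal_somatic :]] = 4

    lo, hi = config.subclonal_vaf_range
    subclonal_vaf = rng.uniform(lo, hi, n)
    sys_forward = rng.random(n) < 0.5

    vaf_t = np.zeros(n)
    vaf_n = np.zeros(n)
    vaf_t[classes == 1] = 0.5
    vaf_n[classes == 1] = 0.5
    vaf_t[classes == 2] = 1.0
    vaf_n[classes == 2] = 1.0
    clonal_vaf = config.tumour_purity / 2.0
    vaf_t[classes == 3] = clonal_vaf
    vaf_n[classes == 3] = config.normal_contamination * clonal_vaf
    vaf_t[classes == 4] = subclonal_vaf[classes == 4]
    vaf_n[classes == 4] = config.normal_contamination * subclonal_vaf[classes == 4]

    depth_n = _draw_depths(rng, config, config.mean_depth_normal)
    depth_t = _draw_depths(rng, config, config.mean_depth_tumour)

    sites: list[PairedSite] = []
    truth: list[TruthRecord] = []
    for i in range(n):
        cls = _CLASS_CODES[classes[i]]
        sys_strand = bool(sys_forward[i]) if classes[i] == 5 else None
        normal = _draw_reads(
            rng, int(depth_n[i]), int(ref_idx[i]), int(var_idx[i]),
            float(vaf_n[i]), config, sys_strand,
        )
        tumour = _draw_reads(
            rng, int(depth_t[i]), int(ref_idx[i]), int(var_idx[i]),
            float(vaf_t[i]), config, sys_strand,
        )
        sites.append(
            PairedSite(config.chrom, int(positions[i]), BASES[ref_idx[i]], normal, tumour)
        )
        truth.append(
            TruthRecord(
                chrom=config.chrom,
                pos=int(positions[i]),
                truth_class=cls,
                true_vaf_tumour=float(vaf_t[i]),
                true_vaf_normal=float(vaf_n[i]),
                error_strand=(
                    "none" if classes[i] != 5 else (FORWARD if sys_forward[i] else REVERSE)
                ),
                variant_base=BASES[var_idx[i]] if classes[i] != 0 else None,
            )
        )
    return SimResult(sites, truth)


def split_null(config: SimConfig) -> tuple[SimResult, SimResult]:
    """Normal-normal split null: one normal sample halved into a pseudo-pair.

    A single non-cancer sample is simulated at mean depth
    ``2 * mean_depth_normal`` with no somatic truth; each read is then
    independently assigned to the pseudo-normal or pseudo-tumour with
    probability 1/2.  Returns ``(pseudo_pair, parent)``; the parent carries
    the full stack in its normal slot for audit.
    """
    parent_cfg = dataclasses.replace(
        config,
        n_clonal_somatic=0,
        n_subclonal_somatic=0,
        mean_depth_normal=2.0 * config.mean_depth_normal,
        mean_depth_tumour=0.0,
    )
    parent = simulate_pair(parent_cfg)
    split_rng = np.random.default_rng([int(config.seed) & 0x7FFFFFFF, 0x5B117])
    pseudo_sites: list[PairedSite] = []
    pseudo_truth: list[TruthRecord] = []
    for site, t in zip(parent.sites, parent.truth):
        coins = split_rng.random(len(site.normal)) < 0.5
        left = [o for o, c in zip(site.normal, coins) if c]
        right = [o for o, c in zip(site.normal, coins) if not c]
        pseudo_sites.append(PairedSite(site.chrom, site.pos, site.ref, left, right))
        pseudo_truth.append(
            TruthRecord(
                chrom=t.chrom,
                pos=t.pos,
                truth_class=t.truth_class,
                true_vaf_tumour=t.true_vaf_normal,
                true_vaf_normal=t.true_vaf_normal,
                error_strand=t.error_strand,
                variant_base=t.variant_base,
            )
        )
    return SimResult(pseudo_sites, pseudo_truth), parent


# ---------------------------------------------------------------------------
# truth + config serialization
# ---------------------------------------------------------------------------

_TRUTH_HEADER = "#chrom\tpos\ttruth_class\ttrue_vaf_tumour\ttrue_vaf_normal\terror_strand\tvariant_base"


def write_truth(truth: Iterable[TruthRecord], dest) -> None:
    fh, close = _open_maybe(dest, "w")
    try:
        fh.write(_TRUTH_HEADER + "\n")
        for t in truth:
            fh.write(
                f"{t.chrom}\t{t.pos}\t{t.truth_class}\t{t.true_vaf_tumour:.8g}\t"
                f"{t.true_vaf_normal:.8g}\t{t.error_strand}\t{t.variant_base or '.'}\n"
            )
    finally:
        if close:
            fh.close()


def read_truth(source) -> Iterator[TruthRecord]:
    fh, close = _open_maybe(source, "r")
    try:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            yield TruthRecord(
                chrom=f[0], pos=int(f[1]), truth_class=f[2],
                true_vaf_tumour=float(f[3]), true_vaf_normal=float(f[4]),
                error_strand=f[5], variant_base=None if f[6] == "." else f[6],
            )
    finally:
        if close:
            fh.close()


def sim_config_to_dict(config: SimConfig) -> dict:
    d = dataclasses.asdict(config)
    for key in ("base_quality_distribution", "map_quality_distribution"):
        d[key] = {
            "values": list(d[key]["values"]),
            "probs": [float(p) for p in d[key]["probs"]],
        }
    d["subclonal_vaf_range"] = [float(x) for x in d["subclonal_vaf_range"]]
    return d


def sim_config_from_dict(d: dict) -> SimConfig:
    d = dict(d)
    for key in ("base_quality_distribution", "map_quality_distribution"):
        if key in d and isinstance(d[key], dict):
            d[key] = DiscreteDistribution(
                tuple(d[key]["values"]), tuple(d[key]["probs"])
            )
    if "subclonal_vaf_range" in d:
        d["subclonal_vaf_range"] = tuple(d["subclonal_vaf_range"])
    return SimConfig(**d)


def load_sim_config(path) -> SimConfig:
    with open(path) as fh:
        return sim_config_from_dict(yaml.safe_load(fh))


def save_sim_config(config: SimConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(sim_config_to_dict(config), fh, sort_keys=True)
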