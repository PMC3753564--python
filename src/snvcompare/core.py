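"""Shared domain types, phred arithmetic and text I/O for paired pileups.

The unit of analysis is one genomic position carrying two read stacks, one
from the normal sample and one from the tumour sample.  Coordinates are
1-based and fully closed, following pileup convention.  All genotype work
downstream happens in the reduced reference/variant ("A"/"B") space: each
sample is AA (homozygous reference), AB (heterozygous) or BB (homozygous
variant), giving nine joint genotypes per site.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence

import numpy as np

BASES = "ACGT"
BASE_TO_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
INDEX_TO_BASE = "ACGTN"
N_INDEX = 4
FORWARD = "+"
REVERSE = "-"

GENOTYPES = ("AA", "AB", "BB")
JOINT_GENOTYPES = tuple((gn, gt) for gn in GENOTYPES for gt in GENOTYPES)

CALL_CLASSES = ("somatic", "LOH", "germline", "reference", "unknown")
CALLER_IDS = ("varscan", "somaticsniper", "jointsnvmix", "strelka_like")

MAX_BASE_QUALITY = 93
MAX_MAP_QUALITY = 254
MAX_PHRED_SCORE = 255

# lookup table: error probability for integer phred 0..255
_PHRED_PROB = 10.0 ** (-np.arange(256) / 10.0)


class PileupParseError(ValueError):
    """A pileup stream could not be decoded; names the offending line."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


@dataclass(frozen=True)
class JointGenotype:
    """A (normal, tumour) genotype pair in reduced A/B space."""

    normal_g: str
    tumour_g: str

    def __post_init__(self):
        if self.normal_g not in GENOTYPES or self.tumour_g not in GENOTYPES:
            raise ValueError(f"invalid joint genotype {self.normal_g}/{self.tumour_g}")


@dataclass(slots=True)
class ReadObservation:
    """One read's evidence at one site.

    ``spans_deletion`` marks a read whose alignment deletes this base: such a
    read contributes to overall depth but never to allele counts (a deleted
    base has no base call).  ``adjacent_indel`` marks a read carrying an indel
    immediately adjacent to the site.
    """

    base: str
    base_quality: int
    map_quality: int
    strand: str
    spans_deletion: bool = False
    adjacent_indel: bool = False

    def __post_init__(self):
        if self.base not in BASE_TO_INDEX:
            raise ValueError(f"invalid base {self.base!r}")
        if not 0 <= self.base_quality <= MAX_BASE_QUALITY:
            raise ValueError(f"base quality {self.base_quality} outside [0, {MAX_BASE_QUALITY}]")
        if not 0 <= self.map_quality <= MAX_MAP_QUALITY:
            raise ValueError(f"mapping quality {self.map_quality} outside [0, {MAX_MAP_QUALITY}]")
        if self.strand not in (FORWARD, REVERSE):
            raise ValueError(f"strand must be {FORWARD!r} or {REVERSE!r}, got {self.strand!r}")


@dataclass(slots=True)
class PairedSite:
    """One position's reference base plus normal and tumour read stacks."""

    chrom: str
    pos: int
    ref: str
    normal: list[ReadObservation]
    tumour: list[ReadObservation]
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError("positions are 1-based; pos must be >= 1")
        if self.ref not in BASES:
            raise ValueError(f"reference base must be one of {BASES}, got {self.ref!r}")

    @property
    def normal_depth(self) -> int:
        return len(self.normal)

    @property
    def tumour_depth(self) -> int:
        return len(self.tumour)


@dataclass(slots=True)
class ReadStack:
    """Column-oriented view of a read stack for vectorised likelihoods."""

    base_index: np.ndarray
    base_quality: np.ndarray
    map_quality: np.ndarray
    forward: np.ndarray
    spans_deletion: np.ndarray
    adjacent_indel: np.ndarray

    def __len__(self) -> int:
        return self.base_index.shape[0]


def stack_reads(observations: Sequence[ReadObservation]) -> ReadStack:
    """Pack a list of observations into parallel numpy arrays."""
    n = len(observations)
    return ReadStack(
        base_index=np.fromiter((BASE_TO_INDEX[o.base] for o in observations), np.int8, n),
        base_quality=np.fromiter((o.base_quality for o in observations), np.int16, n),
        map_quality=np.fromiter((o.map_quality for o in observations), np.int16, n),
        forward=np.fromiter((o.strand == FORWARD for o in observations), bool, n),
        spans_deletion=np.fromiter((o.spans_deletion for o in observations), bool, n),
        adjacent_indel=np.fromiter((o.adjacent_indel for o in observations), bool, n),
    )


def site_stacks(site: PairedSite) -> tuple[ReadStack, ReadStack]:
    """Cached column views of a site's two read stacks."""
    if "stacks" not in site._cache:
        site._cache["stacks"] = (stack_reads(site.normal), stack_reads(site.tumour))
    return site._cache["stacks"]


# ---------------------------------------------------------------------------
# phred arithmetic
# ---------------------------------------------------------------------------

def phred_to_prob(q):
    """Error probability 10^(-q/10) for a phred-scaled quality ``q`` >= 0."""
    arr = np.asarray(q)
    if np.any(arr < 0):
        raise ValueError("phred quality must be non-negative")
    out = 10.0 ** (-arr / 10.0)
    return float(out) if np.isscalar(q) else out


def prob_to_phred(p):
    """Inverse of :func:`phred_to_prob`: -10*log10(p) for p in (0, 1]."""
    arr = np.asarray(p, dtype=float)
    if np.any(arr <= 0) or np.any(arr > 1):
        raise ValueError("probability must lie in (0, 1]")
    out = -10.0 * np.log10(arr)
    return float(out) if np.isscalar(p) else out


# ---------------------------------------------------------------------------
# allele summaries
# ---------------------------------------------------------------------------

@dataclass(slots=True)
class AlleleSummary:
    """Variant-allele evidence at one site in one sample.

    ``v`` counts reads carrying the variant base (``v = v_forward +
    v_reverse``); ``variant_proportion`` is v / (v + ref_count) over the
    qualifying reads, or 0 when there is no evidence at all.
    """

    variant_base: str | None
    v: int
    ref_count: int
    v_forward: int
    v_reverse: int
    variant_proportion: float


def summarize_stack(
    stack: ReadStack,
    ref_index: int,
    min_base_quality: int = 0,
    variant_index: int | None = None,
) -> AlleleSummary:
    """Allele summary over a column stack.

    Qualifying reads have base quality >= ``min_base_quality``, do not span a
    deletion and are not N calls.  The variant base is the most frequent
    qualifying non-reference base, ties broken in fixed A<C<G<T order; a
    specific base may be forced with ``variant_index``.
    """
    qual = (
        (stack.base_quality >= min_base_quality)
        & ~stack.spans_deletion
        & (stack.base_index != N_INDEX)
    )
    bidx = stack.base_index[qual]
    counts = np.bincount(bidx, minlength=4)[:4]
    ref_count = int(counts[ref_index])
    if variant_index is None:
        nonref = counts.copy()
        nonref[ref_index] = -1
        variant_index = int(np.argmax(nonref))  # first max => alphabetical tie-break
        if counts[variant_index] == 0 or variant_index == ref_index:
            variant_index = None
    if variant_index is None:
        return AlleleSummary(None, 0, ref_count, 0, 0, 0.0)
    var_mask = bidx == variant_index
    v = int(var_mask.sum())
    v_forward = int((var_mask & stack.forward[qual]).sum())
    denom = v + ref_count
    return AlleleSummary(
        variant_base=BASES[variant_index],
        v=v,
        ref_count=ref_count,
        v_forward=v_forward,
        v_reverse=v - v_forward,
        variant_proportion=(v / denom) if denom > 0 else 0.0,
    )


def summarize_alleles(
    observations: Sequence[ReadObservation],
    ref: str,
    min_base_quality: int = 0,
    variant_base: str | None = None,
) -> AlleleSummary:
    """Allele summary over a list of read observations (see summarize_stack)."""
    if min_base_quality < 0:
        raise ValueError("min_base_quality must be >= 0")
    vidx = None if variant_base is None else BASE_TO_INDEX[variant_base]
    return summarize_stack(stack_reads(observations), BASE_TO_INDEX[ref], min_base_quality, vidx)


# ---------------------------------------------------------------------------
# candidate calls / filter verdicts / truth records
# ---------------------------------------------------------------------------

@dataclass(slots=True)
class CandidateCall:
    """One caller's verdict at one site.

    ``score`` is the probability the caller assigns to the event class it
    reports (somatic probability for somatic candidates, LOH probability for
    LOH candidates).  When ``phred_score`` is present, ``score`` is its exact
    probability image 1 - 10^(-phred/10); the unrounded posterior, if any, is
    kept in ``raw_score``.
    """

    chrom: str
    pos: int
    ref: str
    caller_id: str
    call_class: str
    score: float
    phred_score: int | None = None
    normal_genotype: str | None = None
    tumour_genotype: str | None = None
    normal_summary: AlleleSummary | None = None
    tumour_summary: AlleleSummary | None = None
    normal_depth: int = 0
    tumour_depth: int = 0
    raw_score: float | None = None
    loh_score: float | None = None

    def __post_init__(self):
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score {self.score} outside [0, 1]")
        if self.call_class not in CALL_CLASSES:
            raise ValueError(f"invalid call class {self.call_class!r}")
        if self.phred_score is not None:
            implied = 1.0 - 10.0 ** (-self.phred_score / 10.0)
            if abs(self.score - implied) > 1e-6:
                raise ValueError(
                    f"score {self.score} inconsistent with phred {self.phred_score}"
                )

    @property
    def site_key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)


FILTER_RULES = (
    "strand_bias",
    "mean_base_quality",
    "max_base_quality",
    "mean_map_quality",
    "max_map_quality",
    "nearby_candidates",
    "spanning_deletions",
    "adjacent_indels",
)


@dataclass(slots=True)
class RuleResult:
    passed: bool
    metric: float | None = None


@dataclass(slots=True)
class FilterVerdict:
    """Per-site, per-rule pass/fail record for the post-calling filter suite."""

    chrom: str
    pos: int
    caller_id: str
    call_class: str
    rules: dict[str, RuleResult]

    @property
    def overall_pass(self) -> bool:
        return all(self.rules[name].passed for name in FILTER_RULES)


TRUTH_CLASSES = (
    "none",
    "germline_het",
    "germline_hom",
    "somatic_clonal",
    "somatic_subclonal",
    "systematic_error",
)


@dataclass(slots=True)
class TruthRecord:
    """Simulator ground truth for one site."""

    chrom: str
    pos: int
    truth_class: str
    true_vaf_tumour: float = 0.0
    true_vaf_normal: float = 0.0
    error_strand: str = "none"
    variant_base: str | None = None

    def __post_init__(self):
        if self.truth_class not in TRUTH_CLASSES:
            raise ValueError(f"invalid truth class {self.truth_class!r}")
        if self.truth_class == "none" and (self.true_vaf_tumour or self.true_vaf_normal):
            raise ValueError("truth class 'none' requires zero VAFs")


# ---------------------------------------------------------------------------
# pileup I/O
# ---------------------------------------------------------------------------

_INTERNAL_HEADER = "#chrom\tpos\tref\tnormal\ttumour"


def _open_maybe(source, mode: str):
    if isinstance(source, (str, Path)):
        return open(source, mode), True
    return source, False


def _encode_observation(o: ReadObservation) -> str:
    return (
        f"{o.base}:{o.base_quality}:{o.map_quality}:{o.strand}:"
        f"{int(o.spans_deletion)}:{int(o.adjacent_indel)}"
    )


def _decode_observation(token: str, line_number: int) -> ReadObservation:
    parts = token.split(":")
    if len(parts) != 6:
        raise PileupParseError(f"bad read token {token!r}", line_number)
    try:
        return ReadObservation(
            base=parts[0],
            base_quality=int(parts[1]),
            map_quality=int(parts[2]),
            strand=parts[3],
            spans_deletion=bool(int(parts[4])),
            adjacent_indel=bool(int(parts[5])),
        )
    except ValueError as exc:
        raise PileupParseError(f"bad read token {token!r}: {exc}", line_number) from exc


def write_paired_pileup(sites: Iterable[PairedSite], dest) -> None:
    """Write sites in the package's lossless internal TSV pileup format."""
    fh, close = _open_maybe(dest, "w")
    try:
        fh.write(_INTERNAL_HEADER + "\n")
        for s in sites:
            nfield = ",".join(_encode_observation(o) for o in s.normal) or "."
            tfield = ",".join(_encode_observation(o) for o in s.tumour) or "."
            fh.write(f"{s.chrom}\t{s.pos}\t{s.ref}\t{nfield}\t{tfield}\n")
    finally:
        if close:
            fh.close()


def _read_internal_tsv(fh) -> Iterator[PairedSite]:
    for line_number, line in enumerate(fh, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 5:
            raise PileupParseError(f"expected 5 columns, got {len(cols)}", line_number)
        chrom, pos, ref, nfield, tfield = cols
        normal = [] if nfield == "." else [
            _decode_observation(t, line_number) for t in nfield.split(",")
        ]
        tumour = [] if tfield == "." else [
            _decode_observation(t, line_number) for t in tfield.split(",")
        ]
        try:
            yield PairedSite(chrom, int(pos), ref, normal, tumour)
        except ValueError as exc:
            raise PileupParseError(str(exc), line_number) from exc


def decode_mpileup_column(
    bases: str, quals: str, mapquals: str, ref: str, line_number: int = 0
) -> list[ReadObservation]:
    """Decode one sample's mpileup base string into read observations.

    Handles the samtools read-base dialect: ``.``/``,`` reference match on
    forward/reverse strand, letter case for strand of mismatches, ``^X`` read
    start (mapping quality char consumed), ``$`` read end, ``+n``/``-n`` indel
    runs (attached to the preceding read as ``adjacent_indel``) and ``*``/``#``
    for a deletion spanning the site.
    """
    obs: list[ReadObservation] = []
    i = 0
    qi = 0
    n = len(bases)
    while i < n:
        c = bases[i]
        if c == "^":
            if i + 1 >= n:
                raise PileupParseError("dangling '^' clip marker", line_number)
            i += 2
            continue
        if c == "$":
            i += 1
            continue
        if c in "+-":
            j = i + 1
            num = ""
            while j < n and bases[j].isdigit():
                num += bases[j]
                j += 1
            if not num:
                raise PileupParseError(f"indel marker {c!r} without length", line_number)
            j += int(num)
            if j > n:
                raise PileupParseError("indel sequence runs past end of base string", line_number)
            if not obs:
                raise PileupParseError("indel marker before any read", line_number)
            obs[-1].adjacent_indel = True
            i = j
            continue
        if qi >= len(quals) or qi >= len(mapquals):
            raise PileupParseError("quality string shorter than base string", line_number)
        bq = ord(quals[qi]) - 33
        mq = ord(mapquals[qi]) - 33
        qi += 1
        spans_deletion = False
        if c == ".":
            base, strand = ref, FORWARD
        elif c == ",":
            base, strand = ref, REVERSE
        elif c in "*#":
            base, strand, spans_deletion = ref, (FORWARD if c == "*" else REVERSE), True
        elif c.upper() in "ACGTN":
            base, strand = c.upper(), (FORWARD if c.isupper() else REVERSE)
        else:
            raise PileupParseError(f"undecodable base-string character {c!r}", line_number)
        try:
            obs.append(ReadObservation(base, bq, mq, strand, spans_deletion=spans_deletion))
        except ValueError as exc:
            raise PileupParseError(str(exc), line_number) from exc
        i += 1
    if qi != len(quals):
        raise PileupParseError("base and quality strings disagree in length", line_number)
    return obs


def _read_mpileup2(fh) -> Iterator[PairedSite]:
    # samtools mpileup -s with two BAMs: chrom pos ref, then per sample
    # depth / bases / base-quals / map-quals => 11 columns.
    for line_number, line in enumerate(fh, start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        cols = line.split("\t")
        if len(cols) != 11:
            raise PileupParseError(f"expected 11 columns, got {len(cols)}", line_number)
        chrom, pos, ref = cols[0], cols[1], cols[2].upper()
        stacks = []
        for k in (3, 7):
            depth, bases, quals, mapquals = cols[k : k + 4]
            if bases == "*" and quals == "*":  # samtools placeholder for depth 0
                stacks.append([])
                continue
            decoded = decode_mpileup_column(bases, quals, mapquals, ref, line_number)
            if int(depth) != len(decoded):
                raise PileupParseError(
                    f"declared depth {depth} != {len(decoded)} decoded reads", line_number
                )
            stacks.append(decoded)
        try:
            yield PairedSite(chrom, int(pos), ref, stacks[0], stacks[1])
        except ValueError as exc:
            raise PileupParseError(str(exc), line_number) from exc


def read_paired_pileup(source, format: str = "internal_tsv") -> Iterator[PairedSite]:
    """Yield :class:`PairedSite` records from a pileup stream or path.

    ``format`` is ``"internal_tsv"`` (the package's lossless column dump) or
    ``"mpileup2"`` (two-sample ``samtools mpileup -s`` text).
    """
    fh, close = _open_maybe(source, "r")
    try:
        if format == "internal_tsv":
            yield from _read_internal_tsv(fh)
        elif format == "mpileup2":
            yield from _read_mpileup2(fh)
        else:
            raise ValueError(f"unknown pileup format {format!r}")
    finally:
        if close:
            fh.close()


# ---------------------------------------------------------------------------
# candidate I/O (TSV and VCF 4.2)
# ---------------------------------------------------------------------------

_TSV_COLUMNS = (
    "chrom pos ref caller class score phred normal_genotype tumour_genotype "
    "n_variant_base n_v n_ref n_v_forward n_v_reverse "
    "t_variant_base t_v t_ref t_v_forward t_v_reverse "
    "normal_depth tumour_depth raw_score loh_score"
).split()


def _check_sorted(calls: Sequence[CandidateCall]) -> None:
    keys = [(c.chrom, c.pos) for c in calls]
    if keys != sorted(keys):
        raise ValueError("candidate calls must be sorted by (chrom, pos)")


def _fmt_opt(x, fmt="{:.10g}") -> str:
    return "." if x is None else fmt.format(x)


def _summary_fields(s: AlleleSummary | None) -> list[str]:
    if s is None:
        return [".", ".", ".", ".", "."]
    return [s.variant_base or ".", str(s.v), str(s.ref_count), str(s.v_forward), str(s.v_reverse)]


def _summary_from_fields(fields: list[str]) -> AlleleSummary | None:
    if fields[1] == ".":
        return None
    v, ref_count, vf, vr = (int(x) for x in fields[1:])
    denom = v + ref_count
    return AlleleSummary(
        variant_base=None if fields[0] == "." else fields[0],
        v=v,
        ref_count=ref_count,
        v_forward=vf,
        v_reverse=vr,
        variant_proportion=(v / denom) if denom else 0.0,
    )


def _vcf_header(chroms: Sequence[str]) -> str:
    lines = [
        "##fileformat=VCFv4.2",
        "##source=snvcompare",
        '##INFO=<ID=CALLER,Number=1,Type=String,Description="Calling model">',
        '##INFO=<ID=CLASS,Number=1,Type=String,Description="Call class">',
        '##INFO=<ID=SCORE,Number=1,Type=Float,Description="Probability score of the reported class">',
        '##INFO=<ID=PHRED,Number=1,Type=Integer,Description="Phred-scaled score">',
        '##INFO=<ID=RAW,Number=1,Type=Float,Description="Unrounded posterior probability">',
        '##INFO=<ID=LOH,Number=1,Type=Float,Description="LOH posterior probability">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype in reduced A/B space">',
        '##FORMAT=<ID=AD,Number=2,Type=Integer,Description="Reference and variant read counts">',
        '##FORMAT=<ID=ADF,Number=1,Type=Integer,Description="Forward-strand variant reads">',
        '##FORMAT=<ID=ADR,Number=1,Type=Integer,Description="Reverse-strand variant reads">',
        '##FORMAT=<ID=VB,Number=1,Type=String,Description="Per-sample variant base">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total read depth">',
    ]
    lines += [f"##contig=<ID={c}>" for c in chroms]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tNORMAL\tTUMOUR")
    return "\n".join(lines) + "\n"


_GT_CODE = {"AA": "0/0", "AB": "0/1", "BB": "1/1", None: "./."}
_CODE_GT = {v: k for k, v in _GT_CODE.items()}


def _vcf_sample_field(genotype, summary: AlleleSummary | None, depth: int) -> str:
    gt = _GT_CODE[genotype]
    if summary is None:
        return f"{gt}:.,.:.:.:.:{depth}"
    return (
        f"{gt}:{summary.ref_count},{summary.v}:{summary.v_forward}:{summary.v_reverse}:"
        f"{summary.variant_base or '.'}:{depth}"
    )


def write_candidates(calls: Sequence[CandidateCall], dest, format: str = "tsv") -> None:
    """Write candidate calls as TSV or VCF 4.2; input must be position-sorted."""
    _check_sorted(calls)
    fh, close = _open_maybe(dest, "w")
    try:
        if format == "tsv":
            fh.write("#" + "\t".join(_TSV_COLUMNS) + "\n")
            for c in calls:
                row = [
                    c.chrom, str(c.pos), c.ref, c.caller_id, c.call_class,
                    f"{c.score:.6f}", _fmt_opt(c.phred_score, "{:d}"),
                    c.normal_genotype or ".", c.tumour_genotype or ".",
                    *_summary_fields(c.normal_summary),
                    *_summary_fields(c.tumour_summary),
                    str(c.normal_depth), str(c.tumour_depth),
                    _fmt_opt(c.raw_score, "{:.17g}"), _fmt_opt(c.loh_score, "{:.17g}"),
                ]
                fh.write("\t".join(row) + "\n")
        elif format == "vcf":
            chroms = list(dict.fromkeys(c.chrom for c in calls))
            fh.write(_vcf_header(chroms))
            for c in calls:
                alt = None
                for s in (c.tumour_summary, c.normal_summary):
                    if s is not None and s.variant_base:
                        alt = s.variant_base
                        break
                info = [
                    f"CALLER={c.caller_id}", f"CLASS={c.call_class}", f"SCORE={c.score:.6f}",
                ]
                if c.phred_score is not None:
                    info.append(f"PHRED={c.phred_score}")
                if c.raw_score is not None:
                    info.append(f"RAW={c.raw_score:.17g}")
                if c.loh_score is not None:
                    info.append(f"LOH={c.loh_score:.17g}")
                qual = "." if c.phred_score is None else str(c.phred_score)
                row = [
                    c.chrom, str(c.pos), ".", c.ref, alt or ".", qual, ".",
                    ";".join(info), "GT:AD:ADF:ADR:VB:DP",
                    _vcf_sample_field(c.normal_genotype, c.normal_summary, c.normal_depth),
                    _vcf_sample_field(c.tumour_genotype, c.tumour_summary, c.tumour_depth),
                ]
                fh.write("\t".join(row) + "\n")
        else:
            raise ValueError(f"unknown candidate format {format!r}")
    finally:
        if close:
            fh.close()


def _parse_opt(token: str, cast):
    return None if token == "." else cast(token)


def _read_candidates_tsv(fh) -> Iterator[CandidateCall]:
    for line in fh:
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        yield CandidateCall(
            chrom=f[0], pos=int(f[1]), ref=f[2], caller_id=f[3], call_class=f[4],
            score=float(f[5]), phred_score=_parse_opt(f[6], int),
            normal_genotype=_parse_opt(f[7], str), tumour_genotype=_parse_opt(f[8], str),
            normal_summary=_summary_from_fields(f[9:14]),
            tumour_summary=_summary_from_fields(f[14:19]),
            normal_depth=int(f[19]), tumour_depth=int(f[20]),
            raw_score=_parse_opt(f[21], float), loh_score=_parse_opt(f[22], float),
        )


def _sample_from_vcf(field: str) -> tuple[str | None, AlleleSummary | None, int]:
    gt, ad, adf, adr, vb, dp = field.split(":")
    genotype = _CODE_GT.get(gt)
    depth = int(dp)
    if ad == ".,.":
        return genotype, None, depth
    ref_count, v = (int(x) for x in ad.split(","))
    denom = v + ref_count
    summary = AlleleSummary(
        variant_base=None if vb == "." else vb,
        v=v, ref_count=ref_count, v_forward=int(adf), v_reverse=int(adr),
        variant_proportion=(v / denom) if denom else 0.0,
    )
    return genotype, summary, depth


def _read_candidates_vcf(fh) -> Iterator[CandidateCall]:
    for line in fh:
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        info = dict(kv.split("=", 1) for kv in f[7].split(";"))
        ngt, nsum, ndp = _sample_from_vcf(f[9])
        tgt, tsum, tdp = _sample_from_vcf(f[10])
        yield CandidateCall(
            chrom=f[0], pos=int(f[1]), ref=f[3],
            caller_id=info["CALLER"], call_class=info["CLASS"], score=float(info["SCORE"]),
            phred_score=int(info["PHRED"]) if "PHRED" in info else None,
            normal_genotype=ngt, tumour_genotype=tgt,
            normal_summary=nsum, tumour_summary=tsum,
            normal_depth=ndp, tumour_depth=tdp,
            raw_score=float(info["RAW"]) if "RAW" in info else None,
            loh_score=float(info["LOH"]) if "LOH" in info else None,
        )


def read_candidates(source, format: str = "tsv") -> Iterator[CandidateCall]:
    """Read candidate calls written by :func:`write_candidates`."""
    fh, close = _open_maybe(source, "r")
    try:
        if format == "tsv":
            yield from _read_candidates_tsv(fh)
        elif format == "vcf":
            yield from _read_candidates_vcf(fh)
        else:
            raise ValueError(f"unknown candidate format {format!r}")
    finally:
        if close:
            fh.close()
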