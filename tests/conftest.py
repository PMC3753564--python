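"""Shared builders for hand-constructed pileup sites."""

from __future__ import annotations

import numpy as np
import pytest

from snvcompare.core import FORWARD, REVERSE, PairedSite, ReadObservation

# pre-registered seed for every stochastic study in the suite
STUDY_SEED = 20130709


def obs(
    base: str,
    bq: int = 40,
    mq: int = 60,
    strand: str = FORWARD,
    spans_deletion: bool = False,
    adjacent_indel: bool = False,
) -> ReadObservation:
    return ReadObservation(base, bq, mq, strand, spans_deletion, adjacent_indel)


def reads(
    n_ref: int,
    n_var: int,
    ref: str = "A",
    var: str = "C",
    bq: int = 40,
    mq: int = 60,
    var_strands: str | None = None,
) -> list[ReadObservation]:
    """A stack of n_ref reference and n_var variant reads.

    Strands alternate to stay balanced unless ``var_strands`` forces the
    variant reads onto one strand ('+' or '-').
    """
    out = [obs(ref, bq, mq, FORWARD if i % 2 == 0 else REVERSE) for i in range(n_ref)]
    for i in range(n_var):
        strand = var_strands if var_strands else (FORWARD if i % 2 == 0 else REVERSE)
        out.append(obs(var, bq, mq, strand))
    return out


def site(
    normal: list[ReadObservation],
    tumour: list[ReadObservation],
    ref: str = "A",
    chrom: str = "chr1",
    pos: int = 100,
) -> PairedSite:
    return PairedSite(chrom, pos, ref, normal, tumour)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(STUDY_SEED)
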