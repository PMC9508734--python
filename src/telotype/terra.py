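"""TERRA (telomeric repeat-containing RNA) quantification from RNA-seq.

A read counts toward a variant v in {TTAGGG, TGAGGG, TCAGGG, TTGGGG}
if it contains at least ``min_repeats`` occurrences of v or its reverse
complement (a read may count toward several variants). Per-variant
counts are normalized by the total number of reads and multiplied by
1e6; the sample's total TERRA value is the sum of the four per-variant
values. Counting operates on raw read sequences, so FASTQ input is
accepted directly; a spliced alignment upstream is optional.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .errors import ConfigError, InputError
from .reads import AlignedRead, reverse_complement
from .tvr import COMMON_TVRS


@dataclass(frozen=True)
class TerraProfile:
    sample_id: str
    per_tvr: dict[str, float]  # reads per million, keyed by variant
    total: float
    total_reads: int


def terra_profile(
    rna_reads: Iterable[AlignedRead],
    min_repeats: int = 4,
    sample_id: str = "sample",
    scale: float = 1e6,
) -> TerraProfile:
    """Count TERRA-bearing reads per common TVR and normalize."""
    if min_repeats < 1:
        raise ConfigError(f"min_repeats must be >= 1, got {min_repeats}")
    motifs = {v: (v, reverse_complement(v)) for v in COMMON_TVRS}
    counts = {v: 0 for v in COMMON_TVRS}
    total = 0
    for read in rna_reads:
        total += 1
        seq = read.seq.upper()
        for v, (fwd, rev) in motifs.items():
            if seq.count(fwd) + seq.count(rev) >= min_repeats:
                counts[v] += 1
    if total == 0:
        raise InputError("empty RNA read stream: cannot compute TERRA")
    per_tvr = {v: counts[v] / total * scale for v in COMMON_TVRS}
    return TerraProfile(
        sample_id=sample_id,
        per_tvr=per_tvr,
        total=sum(per_tvr.values()),
        total_reads=total,
    )
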