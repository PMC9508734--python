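"""Telomere content estimation from WGS reads.

A read is *telomeric* if it contains at least ``min_repeats`` (default 4)
t-type repeats, counting non-overlapping occurrences of the canonical
telomeric hexamer TTAGGG together with its reverse complement CCCTAA
(a read is single-stranded, so either orientation evidences telomeric
origin). Telomere content is the telomeric read count normalized by the
total number of reads, reported per million reads by default; with a
matched normal the tumor/normal content ratio is the sample-level
statistic used to discriminate ALT-positive tumors.
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable

from .errors import ConfigError, InputError
from .reads import AlignedRead

T_TYPE = "TTAGGG"
T_TYPE_RC = "CCCTAA"

_DNA_RE = re.compile(r"[ACGTN]*\Z")


@dataclass(frozen=True)
class TelomereCount:
    """Per-sample telomeric read counts and normalized content
    (telomeric reads per ``scale`` total reads)."""

    sample_id: str
    role: str  # "tumor" | "normal"
    telomeric_reads: int
    total_reads: int
    content: float


@dataclass(frozen=True)
class TelomereContentRatio:
    """Tumor/normal normalized telomere content ratio."""

    sample_id: str
    ratio: float


def count_t_type_repeats(seq: str) -> int:
    """Number of non-overlapping t-type repeats (TTAGGG plus CCCTAA) in
    ``seq``, scanning left to right.

    Raises :class:`InputError` for characters other than A/C/G/T/N.
    """
    s = seq.upper()
    if not _DNA_RE.match(s):
        bad = sorted(set(s) - set("ACGTN"))
        raise InputError(f"non-DNA characters in sequence: {bad}")
    return s.count(T_TYPE) + s.count(T_TYPE_RC)


def is_telomeric_read(read: AlignedRead, min_repeats: int = 4) -> bool:
    """True iff the read carries at least ``min_repeats`` t-type repeats."""
    if min_repeats < 1:
        raise ConfigError(f"min_repeats must be >= 1, got {min_repeats}")
    return count_t_type_repeats(read.seq) >= min_repeats


def telomere_content(
    reads: Iterable[AlignedRead],
    min_repeats: int = 4,
    scale: float = 1e6,
    sample_id: str = "sample",
    role: str = "tumor",
) -> TelomereCount:
    """Count telomeric reads in a stream and normalize by the total read
    count (content = telomeric/total x scale)."""
    if min_repeats < 1:
        raise ConfigError(f"min_repeats must be >= 1, got {min_repeats}")
    total = 0
    telomeric = 0
    for read in reads:
        total += 1
        if count_t_type_repeats(read.seq) >= min_repeats:
            telomeric += 1
    if total == 0:
        raise InputError("empty read stream: cannot compute telomere content")
    return TelomereCount(
        sample_id=sample_id,
        role=role,
        telomeric_reads=telomeric,
        total_reads=total,
        content=telomeric / total * scale,
    )


def tc_ratio(tumor: TelomereCount, normal: TelomereCount) -> TelomereContentRatio:
    """Tumor/normal telomere content ratio.

    Undefined when the normal has zero content; in that case use the
    tumor-only normalized content directly instead.
    """
    if normal.content <= 0:
        raise InputError(
            "normal telomere content is zero: the tumor/normal ratio is "
            "undefined; use tumor-only mode (the normalized tumor content) "
            "instead"
        )
    return TelomereContentRatio(
        sample_id=tumor.sample_id, ratio=tumor.content / normal.content
    )
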