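"""Telomere variant repeats (TVRs) and TVR singletons.

Telomeres are arrays of the canonical hexamer TTAGGG interspersed with
variant repeats of the form NNNGGG (TGAGGG, TCAGGG, TTGGGG and rarer
ones). A *singleton* is a single variant hexamer embedded in otherwise
canonical sequence, (TTAGGG)3-NNNGGG-(TTAGGG)3. Singleton rates differ
between telomere maintenance subgroups: TTTGGG (and, in neuroblastoma,
TGAGGG) singletons are depleted in ALT-positive tumors. Because raw
singleton counts scale with telomere content, the subgroup comparison
uses the tumor/normal singleton rate ratio divided by the telomere
content ratio, on a log2 scale.
"""
from __future__ import annotations

import math
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .content import T_TYPE, T_TYPE_RC, TelomereContentRatio, is_telomeric_read
from .errors import InputError
from .reads import AlignedRead, reverse_complement

COMMON_TVRS = ("TTAGGG", "TGAGGG", "TCAGGG", "TTGGGG")
HEX = 6

_NNNGGG = re.compile(r"[ACGT]{3}GGG\Z")
_FLANK = T_TYPE * 3


@dataclass
class TVRProfile:
    """Per-sample TVR occurrence and singleton counts within telomeric
    reads. ``tvr_counts``/``singleton_counts`` map exact hexamers to
    counts; :func:`pool_tvr_counts` aggregates non-common variants."""

    sample_id: str
    role: str
    tvr_counts: Counter = field(default_factory=Counter)
    singleton_counts: Counter = field(default_factory=Counter)
    total_reads: int = 0
    telomeric_reads: int = 0


@dataclass(frozen=True)
class SingletonRatio:
    sample_id: str
    variant: str
    log2_ratio: float
    used_pseudocount: bool = False


def orient_to_g_strand(seq: str) -> str:
    """Return ``seq`` oriented so the G-rich strand reads forward: the
    sequence itself if it has at least as many TTAGGG as CCCTAA
    occurrences (ties keep the input), else its reverse complement."""
    s = seq.upper()
    if s.count(T_TYPE) >= s.count(T_TYPE_RC):
        return s
    return reverse_complement(s)


def count_tvr_occurrences(seq: str) -> Counter:
    """Tally NNNGGG hexamers in the telomeric-repeat frame.

    Scanning is anchored on TTAGGG occurrences and extends in 6-mer
    steps in both directions through contiguous NNNGGG-compatible
    hexamers; GGG triplets outside any telomeric run are ignored. The
    input must already be G-strand oriented. Returns a Counter keyed by
    exact hexamer.
    """
    s = seq.upper()
    counts: Counter = Counter()
    visited: set[int] = set()
    i = s.find(T_TYPE)
    while i != -1:
        if i not in visited:
            # extend the hexamer frame left and right of the anchor
            j = i - HEX
            while j >= 0 and _NNNGGG.match(s[j : j + HEX]):
                j -= HEX
            start = j + HEX
            k = i + HEX
            while _NNNGGG.match(s[k : k + HEX]):
                k += HEX
            for p in range(start, k, HEX):
                if p not in visited:
                    visited.add(p)
                    counts[s[p : p + HEX]] += 1
        i = s.find(T_TYPE, i + 1)
    return counts


def pool_tvr_counts(counts: Mapping[str, int]) -> dict[str, int]:
    """Aggregate exact hexamer counts into the four common TVRs plus an
    ``other`` pool of all remaining NNNGGG variants."""
    pooled = {v: int(counts.get(v, 0)) for v in COMMON_TVRS}
    pooled["other"] = int(
        sum(c for v, c in counts.items() if v not in COMMON_TVRS)
    )
    return pooled


def find_tvr_singletons(seq: str) -> list[tuple[str, int]]:
    """All TVR singletons (TTAGGG)3-NNNGGG-(TTAGGG)3 in a G-strand
    oriented sequence, as (variant, offset-of-variant) pairs.

    Flanking repeats may be shared between adjacent singletons
    (overlap-tolerant scan).
    """
    s = seq.upper()
    out: list[tuple[str, int]] = []
    span = 7 * HEX  # 3 + 1 + 3 hexamers
    for i in range(0, len(s) - span + 1):
        if not s.startswith(_FLANK, i):
            continue
        var = s[i + 3 * HEX : i + 4 * HEX]
        if var == T_TYPE or not _NNNGGG.match(var):
            continue
        if s.startswith(_FLANK, i + 4 * HEX):
            out.append((var, i + 3 * HEX))
    return out


def tvr_profile(
    reads: Iterable[AlignedRead],
    sample_id: str = "sample",
    role: str = "tumor",
    min_repeats: int = 4,
) -> TVRProfile:
    """Scan telomeric reads (the telomere-content rule) for TVR
    occurrences and singletons after G-strand orientation."""
    profile = TVRProfile(sample_id=sample_id, role=role)
    for read in reads:
        profile.total_reads += 1
        if not is_telomeric_read(read, min_repeats):
            continue
        profile.telomeric_reads += 1
        oriented = orient_to_g_strand(read.seq)
        profile.tvr_counts.update(count_tvr_occurrences(oriented))
        for variant, _ in find_tvr_singletons(oriented):
            profile.singleton_counts[variant] += 1
    if profile.total_reads == 0:
        raise InputError("empty read stream: cannot build TVR profile")
    return profile


def singleton_ratio(
    tumor: TVRProfile,
    normal: TVRProfile,
    tc: TelomereContentRatio,
    variant: str,
    pseudocount: float | None = 0.5,
) -> SingletonRatio:
    """TC-normalized log2 singleton ratio for one variant:

        log2( (tumor_singletons/tumor_reads) /
              (normal_singletons/normal_reads) / tc_ratio )

    When either singleton count is zero, ``pseudocount`` is added to
    both counts and the result is flagged; with ``pseudocount=None`` a
    zero count is an error.
    """
    if tc.ratio <= 0:
        raise InputError("telomere content ratio must be positive")
    ts = tumor.singleton_counts.get(variant, 0)
    ns = normal.singleton_counts.get(variant, 0)
    flagged = False
    if ts == 0 or ns == 0:
        if pseudocount is None:
            raise InputError(
                f"zero singleton count for {variant} "
                f"(tumor={ts}, normal={ns}) and no pseudocount"
            )
        ts += pseudocount
        ns += pseudocount
        flagged = True
    rate_ratio = (ts / tumor.total_reads) / (ns / normal.total_reads)
    return SingletonRatio(
        sample_id=tumor.sample_id,
        variant=variant,
        log2_ratio=math.log2(rate_ratio / tc.ratio),
        used_pseudocount=flagged,
    )
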