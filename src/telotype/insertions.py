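"""Intrachromosomal telomere insertion detection.

Telomere insertions leave two sequence-level footprints in paired-end
WGS data: read pairs with one telomeric mate whose partner maps to a
unique non-telomeric/non-centromeric locus (discordant *insertion
pairs*), and soft-clipped alignments whose clipped tail is telomeric,
marking the breakpoint at base resolution.

The caller proceeds in three stages: (1) anchor positions of insertion
pairs are screened in fixed 1 kb genome windows, keeping windows with
at least three tumor anchors and none in the matched normal; (2) within
each candidate window, telomeric soft clips (>= 15 bp, >= 2 t-type
repeats) starting at the same position (+/- 1 bp) are clustered into
breakpoints requiring >= 2 supporting reads, then passed through an
automated reference-context filter that rejects breakpoints inside
telomere-like or low-complexity reference sequence (replacing the
manual inspection step of the original procedure); (3) breakpoints of
opposite direction within a pairing distance merge into one two-sided
insertion, all others are one-sided.
"""
from __future__ import annotations

import re
from bisect import bisect_right
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .content import count_t_type_repeats, is_telomeric_read
from .errors import InputError
from .reads import AlignedRead

_HOMOPOLYMER_RE = re.compile(r"A{20,}|C{20,}|G{20,}|T{20,}")


@dataclass(frozen=True)
class InsertionCallerConfig:
    window_size: int = 1000
    min_tumor_pairs: int = 3
    max_normal_pairs: int = 0
    min_clip_len: int = 15
    min_clip_repeats: int = 2
    clip_start_tolerance: int = 1
    min_clip_reads: int = 2
    pairing_distance: int = 5000
    context_filter_window: int = 100
    min_repeats: int = 4  # telomeric-read rule for the discordant mate


@dataclass(frozen=True)
class InsertionBreakpoint:
    chrom: str
    pos: int  # 0-based; right_clip: first clipped base, left_clip: base left of the aligned start
    direction: str  # "right_clip" | "left_clip"
    n_clip_reads: int
    n_support_pairs: int
    window: tuple[int, int]


@dataclass(frozen=True)
class TelomereInsertion:
    breakpoints: tuple[InsertionBreakpoint, ...]
    sidedness: str  # "one_sided" | "two_sided"


@dataclass
class ExclusionRegions:
    """Per-chromosome sorted, merged half-open intervals (telomeric and
    centromeric regions to exclude from anchor collection)."""

    intervals: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    @classmethod
    def from_intervals(
        cls, raw: Mapping[str, Iterable[tuple[int, int]]]
    ) -> "ExclusionRegions":
        merged: dict[str, list[tuple[int, int]]] = {}
        for chrom, ivs in raw.items():
            ordered = sorted(ivs)
            out: list[tuple[int, int]] = []
            for start, end in ordered:
                if out and start <= out[-1][1]:
                    out[-1] = (out[-1][0], max(out[-1][1], end))
                else:
                    out.append((start, end))
            merged[chrom] = out
        return cls(intervals=merged)

    @classmethod
    def from_bed(cls, path: str) -> "ExclusionRegions":
        raw: dict[str, list[tuple[int, int]]] = defaultdict(list)
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise InputError(f"{path}:{lineno}: not a BED interval")
                raw[parts[0]].append((int(parts[1]), int(parts[2])))
        return cls.from_intervals(raw)

    def contains(self, chrom: str, pos: int) -> bool:
        ivs = self.intervals.get(chrom)
        if not ivs:
            return False
        idx = bisect_right(ivs, (pos, float("inf"))) - 1
        return idx >= 0 and ivs[idx][0] <= pos < ivs[idx][1]


def collect_insertion_pairs(
    alignments: Iterable[AlignedRead],
    excluded: ExclusionRegions,
    min_repeats: int = 4,
) -> tuple[list[tuple[str, int]], int]:
    """Anchor positions of telomere-insertion read pairs.

    A pair contributes one anchor when exactly one mate is telomeric and
    the other maps outside the excluded regions; the anchor is the 5'
    mapping coordinate of the non-telomeric mate. Returns the anchor
    list and the number of reads skipped for missing mates.
    """
    by_id: dict[str, list[AlignedRead]] = defaultdict(list)
    for read in alignments:
        by_id[read.read_id].append(read)
    anchors: list[tuple[str, int]] = []
    skipped = 0
    for reads in by_id.values():
        if len(reads) != 2:
            skipped += len(reads)
            continue
        r1, r2 = reads
        t1 = is_telomeric_read(r1, min_repeats)
        t2 = is_telomeric_read(r2, min_repeats)
        if t1 == t2:
            continue
        anchor_read = r2 if t1 else r1
        if not anchor_read.is_mapped:
            continue
        pos = anchor_read.five_prime_position()
        if excluded.contains(anchor_read.chrom, pos):
            continue
        anchors.append((anchor_read.chrom, pos))
    return anchors, skipped


def screen_windows(
    tumor_anchors: Sequence[tuple[str, int]],
    normal_anchors: Sequence[tuple[str, int]],
    cfg: InsertionCallerConfig = InsertionCallerConfig(),
) -> list[tuple[str, int, int]]:
    """Fixed-tiling window screen: half-open windows
    [k*window_size, (k+1)*window_size) with >= min_tumor_pairs tumor
    anchors and <= max_normal_pairs normal anchors."""
    ws = cfg.window_size
    tumor_counts = Counter((chrom, pos // ws) for chrom, pos in tumor_anchors)
    normal_counts = Counter((chrom, pos // ws) for chrom, pos in normal_anchors)
    candidates = [
        (chrom, k * ws, (k + 1) * ws)
        for (chrom, k), n in sorted(tumor_counts.items())
        if n >= cfg.min_tumor_pairs
        and normal_counts.get((chrom, k), 0) <= cfg.max_normal_pairs
    ]
    return candidates


def _clip_events(
    read: AlignedRead, cfg: InsertionCallerConfig
) -> list[tuple[int, str]]:
    """Qualifying telomeric soft-clip events of one read as
    (breakpoint position, direction)."""
    events = []
    if (
        read.clip_right_len >= cfg.min_clip_len
        and count_t_type_repeats(read.clip_right_seq) >= cfg.min_clip_repeats
    ):
        events.append((read.ref_end, "right_clip"))
    if (
        read.clip_left_len >= cfg.min_clip_len
        and count_t_type_repeats(read.clip_left_seq) >= cfg.min_clip_repeats
    ):
        events.append((read.pos - 1, "left_clip"))
    return events


def _context_rejects(
    reference: Mapping[str, str], chrom: str, pos: int, window: int
) -> bool:
    """Automated stand-in for manual breakpoint review: reject when the
    surrounding reference sequence is itself telomere-like (>= 2 t-type
    repeats) or a long homopolymer run (>= 20 bp)."""
    seq = reference.get(chrom)
    if seq is None:
        return False
    ctx = seq[max(0, pos - window) : pos + window + 1].upper()
    if count_t_type_repeats(ctx) >= 2:
        return True
    return bool(_HOMOPOLYMER_RE.search(ctx))


def refine_breakpoints(
    window: tuple[str, int, int],
    tumor_alignments: Iterable[AlignedRead],
    cfg: InsertionCallerConfig = InsertionCallerConfig(),
    reference: Optional[Mapping[str, str]] = None,
    n_support_pairs: int = 0,
) -> list[InsertionBreakpoint]:
    """Cluster qualifying telomeric soft clips inside one candidate
    window into breakpoints.

    Clips of the same direction whose start positions agree within
    ``clip_start_tolerance`` form a cluster; clusters with at least
    ``min_clip_reads`` reads are emitted at their modal position (ties
    toward the smaller coordinate) and then context-filtered against
    the reference, when provided.
    """
    chrom, start, end = window
    per_direction: dict[str, Counter] = {
        "right_clip": Counter(),
        "left_clip": Counter(),
    }
    for read in tumor_alignments:
        if not read.is_mapped or read.chrom != chrom:
            continue
        for pos, direction in _clip_events(read, cfg):
            if start <= pos < end:
                per_direction[direction][pos] += 1

    breakpoints: list[InsertionBreakpoint] = []
    for direction, position_counts in per_direction.items():
        remaining = dict(position_counts)
        while remaining:
            # modal position, ties toward the smaller coordinate
            pivot = min(remaining, key=lambda p: (-remaining[p], p))
            cluster = [
                p
                for p in remaining
                if abs(p - pivot) <= cfg.clip_start_tolerance
            ]
            size = sum(remaining[p] for p in cluster)
            for p in cluster:
                del remaining[p]
            if size < cfg.min_clip_reads:
                continue
            if reference is not None and _context_rejects(
                reference, chrom, pivot, cfg.context_filter_window
            ):
                continue
            breakpoints.append(
                InsertionBreakpoint(
                    chrom=chrom,
                    pos=pivot,
                    direction=direction,
                    n_clip_reads=size,
                    n_support_pairs=n_support_pairs,
                    window=(start, end),
                )
            )
    breakpoints.sort(key=lambda b: (b.chrom, b.pos, b.direction))
    return breakpoints


def assemble_insertions(
    breakpoints: Sequence[InsertionBreakpoint],
    cfg: InsertionCallerConfig = InsertionCallerConfig(),
) -> list[TelomereInsertion]:
    """Merge opposite-direction breakpoint pairs within
    ``pairing_distance`` into two-sided insertions; all remaining
    breakpoints become one-sided insertions."""
    by_chrom: dict[str, list[InsertionBreakpoint]] = defaultdict(list)
    for bp in breakpoints:
        by_chrom[bp.chrom].append(bp)
    insertions: list[TelomereInsertion] = []
    for chrom in sorted(by_chrom):
        rights = sorted(
            (b for b in by_chrom[chrom] if b.direction == "right_clip"),
            key=lambda b: b.pos,
        )
        lefts = sorted(
            (b for b in by_chrom[chrom] if b.direction == "left_clip"),
            key=lambda b: b.pos,
        )
        used_left: set[int] = set()
        for right in rights:
            best = None
            for i, left in enumerate(lefts):
                if i in used_left:
                    continue
                dist = abs(left.pos - right.pos)
                if dist <= cfg.pairing_distance and (
                    best is None or dist < best[0]
                ):
                    best = (dist, i)
            if best is not None:
                used_left.add(best[1])
                insertions.append(
                    TelomereInsertion(
                        breakpoints=(right, lefts[best[1]]),
                        sidedness="two_sided",
                    )
                )
            else:
                insertions.append(
                    TelomereInsertion(breakpoints=(right,), sidedness="one_sided")
                )
        for i, left in enumerate(lefts):
            if i not in used_left:
                insertions.append(
                    TelomereInsertion(breakpoints=(left,), sidedness="one_sided")
                )
    return insertions


def call_insertions(
    tumor_alignments: Sequence[AlignedRead],
    normal_alignments: Sequence[AlignedRead],
    excluded: ExclusionRegions,
    cfg: InsertionCallerConfig = InsertionCallerConfig(),
    reference: Optional[Mapping[str, str]] = None,
) -> tuple[list[TelomereInsertion], list[InsertionBreakpoint], dict]:
    """Full caller: pair collection, window screen, breakpoint
    refinement, insertion assembly. Returns (insertions, breakpoints,
    per-stage counters)."""
    tumor_anchors, t_skip = collect_insertion_pairs(
        tumor_alignments, excluded, cfg.min_repeats
    )
    normal_anchors, n_skip = collect_insertion_pairs(
        normal_alignments, excluded, cfg.min_repeats
    )
    windows = screen_windows(tumor_anchors, normal_anchors, cfg)
    ws = cfg.window_size
    anchor_counts = Counter(
        (chrom, pos // ws) for chrom, pos in tumor_anchors
    )
    breakpoints: list[InsertionBreakpoint] = []
    for window in windows:
        chrom, start, _ = window
        breakpoints.extend(
            refine_breakpoints(
                window,
                tumor_alignments,
                cfg,
                reference,
                n_support_pairs=anchor_counts[(chrom, start // ws)],
            )
        )
    insertions = assemble_insertions(breakpoints, cfg)
    stats = {
        "tumor_anchors": len(tumor_anchors),
        "normal_anchors": len(normal_anchors),
        "candidate_windows": len(windows),
        "breakpoints": len(breakpoints),
        "insertions": len(insertions),
        "reads_skipped_missing_mate": t_skip + n_skip,
    }
    return insertions, breakpoints, stats
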