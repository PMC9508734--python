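"""Read container and SAM/BAM/FASTQ ingestion.

All sequence-level metrics operate on :class:`AlignedRead`, a minimal
view of one sequencing record: mapping position, mate information, the
soft-clipped segments and the full read sequence. Records are produced
from SAM/BAM via pysam or from FASTQ (then unmapped).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

import pysam

from .errors import InputError

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

SOFT_CLIP = 4  # CIGAR op code


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA sequence (N-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class AlignedRead:
    """One sequencing record (mapped or unmapped).

    ``pos`` is the 0-based leftmost aligned reference position and is
    ``None`` iff ``chrom`` is ``None`` (unmapped). ``ref_end`` is the
    0-based exclusive end of the aligned span; when not supplied it is
    inferred from the sequence length minus the soft clips (exact for
    gapless alignments).
    """

    read_id: str
    seq: str
    chrom: Optional[str] = None
    pos: Optional[int] = None
    is_reverse: bool = False
    mate_chrom: Optional[str] = None
    mate_pos: Optional[int] = None
    clip_left_len: int = 0
    clip_right_len: int = 0
    clip_left_seq: str = ""
    clip_right_seq: str = ""
    sample_role: str = "tumor"
    ref_end: Optional[int] = field(default=None)

    def __post_init__(self) -> None:
        if (self.chrom is None) != (self.pos is None):
            raise InputError(
                f"read {self.read_id}: pos must be null iff chrom is null"
            )
        if self.clip_left_len != len(self.clip_left_seq):
            raise InputError(
                f"read {self.read_id}: clip_left_len != len(clip_left_seq)"
            )
        if self.clip_right_len != len(self.clip_right_seq):
            raise InputError(
                f"read {self.read_id}: clip_right_len != len(clip_right_seq)"
            )
        if self.pos is not None and self.pos < 0:
            raise InputError(f"read {self.read_id}: negative position")
        if self.ref_end is None and self.pos is not None:
            aligned = len(self.seq) - self.clip_left_len - self.clip_right_len
            self.ref_end = self.pos + aligned

    @property
    def is_mapped(self) -> bool:
        return self.chrom is not None

    def five_prime_position(self) -> Optional[int]:
        """0-based reference coordinate of the 5' end of the read."""
        if not self.is_mapped:
            return None
        if self.is_reverse:
            return self.ref_end - 1
        return self.pos


def _from_pysam(aln: pysam.AlignedSegment, sample_role: str) -> AlignedRead:
    seq = aln.query_sequence or ""
    cig = aln.cigartuples or []
    left = cig[0][1] if cig and cig[0][0] == SOFT_CLIP else 0
    right = cig[-1][1] if len(cig) > 1 and cig[-1][0] == SOFT_CLIP else 0
    if len(cig) == 1 and cig[0][0] == SOFT_CLIP:  # fully clipped
        left, right = cig[0][1], 0
    mapped = not aln.is_unmapped
    return AlignedRead(
        read_id=aln.query_name,
        seq=seq,
        chrom=aln.reference_name if mapped else None,
        pos=aln.reference_start if mapped else None,
        is_reverse=bool(aln.is_reverse),
        mate_chrom=(
            aln.next_reference_name
            if aln.is_paired and not aln.mate_is_unmapped
            else None
        ),
        mate_pos=(
            aln.next_reference_start
            if aln.is_paired and not aln.mate_is_unmapped
            else None
        ),
        clip_left_len=left,
        clip_right_len=right,
        clip_left_seq=seq[:left],
        clip_right_seq=seq[len(seq) - right :] if right else "",
        sample_role=sample_role,
        ref_end=aln.reference_end if mapped else None,
    )


def iter_alignments(
    path: str, sample_role: str = "tumor", primary_only: bool = True
) -> Iterator[AlignedRead]:
    """Stream AlignedRead records from a SAM/BAM file.

    With ``primary_only`` (default) secondary and supplementary records
    are dropped so reads are not double counted.
    """
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        for aln in fh.fetch(until_eof=True):
            if primary_only and (aln.is_secondary or aln.is_supplementary):
                continue
            yield _from_pysam(aln, sample_role)


def iter_fastq(path: str, sample_role: str = "tumor") -> Iterator[AlignedRead]:
    """Stream unmapped AlignedRead records from a FASTQ/FASTA file
    (gzip transparently handled by pysam)."""
    with pysam.FastxFile(path) as fh:
        for rec in fh:
            yield AlignedRead(
                read_id=rec.name, seq=rec.sequence or "", sample_role=sample_role
            )


def iter_reads(
    path: str, sample_role: str = "tumor", primary_only: bool = True
) -> Iterator[AlignedRead]:
    """Dispatch on file extension: SAM/BAM/CRAM via htslib, anything else
    is treated as FASTQ/FASTA."""
    lowered = path.lower()
    for suffix in (".sam", ".bam", ".cram"):
        if lowered.endswith(suffix):
            return iter_alignments(path, sample_role, primary_only)
    return iter_fastq(path, sample_role)


def write_sam(
    reads: list[AlignedRead],
    path: str,
    reference_lengths: dict[str, int],
) -> None:
    """Write AlignedRead records to a SAM file (used by the simulator and
    round-trip tests). Gapless alignments only."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [
            {"SN": name, "LN": length}
            for name, length in reference_lengths.items()
        ],
    }
    with pysam.AlignmentFile(path, "wh", header=header) as out:
        tid = {name: i for i, name in enumerate(reference_lengths)}
        for read in reads:
            a = pysam.AlignedSegment(out.header)
            a.query_name = read.read_id
            a.query_sequence = read.seq
            a.query_qualities = pysam.qualitystring_to_array("I" * len(read.seq))
            a.flag = 0
            if read.is_reverse:
                a.flag |= 16
            if read.mate_chrom is not None or read.mate_pos is not None:
                a.flag |= 1  # paired
            if read.is_mapped:
                a.reference_id = tid[read.chrom]
                a.reference_start = read.pos
                aligned = (
                    len(read.seq) - read.clip_left_len - read.clip_right_len
                )
                cigar = []
                if read.clip_left_len:
                    cigar.append((SOFT_CLIP, read.clip_left_len))
                cigar.append((0, aligned))
                if read.clip_right_len:
                    cigar.append((SOFT_CLIP, read.clip_right_len))
                a.cigar = cigar
                a.mapping_quality = 60
            else:
                a.flag |= 4
                a.reference_id = -1
                a.reference_start = -1
            if read.mate_chrom is not None:
                a.next_reference_id = tid[read.mate_chrom]
                a.next_reference_start = read.mate_pos
            elif a.flag & 1:
                a.flag |= 8  # mate unmapped
                a.next_reference_id = -1
                a.next_reference_start = -1
            out.write(a)
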