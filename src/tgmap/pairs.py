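"""Read-pair classification and soft-clip extraction.

Reproduces the capture of read pairs that cannot be placed concordantly on
the reference (inter-chromosomal, aberrant insert size, aberrant
orientation) and of soft-clipped "split" reads whose clip boundary marks a
candidate breakpoint.  Insert-size concordance bounds are estimated robustly
from the data (median +/- k * 1.4826 * MAD) rather than delegated to an
aligner, and "uniquely mapped" is operationalised as a mapping-quality
threshold (default 20).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pysam


class PairClass(enum.Enum):
    CONCORDANT = "concordant"
    DISCORDANT_INTERCHROM = "discordant_interchrom"
    DISCORDANT_SIZE = "discordant_size"
    DISCORDANT_ORIENTATION = "discordant_orientation"
    ONE_END_UNMAPPED = "one_end_unmapped"


@dataclass
class AlignmentRecord:
    """One read's mapping in 1-based reference coordinates."""

    read_id: str
    contig: str
    pos: int
    strand: str
    mapq: int
    aligned_span: int
    clips: list[tuple[str, int, str]] = field(default_factory=list)
    mate_contig: str = "*"
    mate_pos: int = 0
    is_mapped: bool = True
    mate_mapped: bool = True
    mate: int = 1

    @property
    def end(self) -> int:
        """1-based inclusive rightmost aligned base."""
        return self.pos + self.aligned_span - 1


@dataclass
class ClipEvent:
    """A soft-clip of length >= min_clip at a putative breakpoint.

    ``boundary_pos`` is the last aligned base for a right clip and the first
    aligned base for a left clip, i.e. always the retained reference base
    adjacent to the clipped tail.
    """

    contig: str
    boundary_pos: int
    side: str            # 'left' | 'right' (side of the read that is clipped)
    clipped_seq: str
    mapq: int
    read_id: str = ""


@dataclass
class InsertSizeModel:
    median: float
    mad: float
    lower: float
    upper: float


class InsufficientPairsError(ValueError):
    pass


def read_sam(path: str) -> list[AlignmentRecord]:
    """Load primary alignments from a SAM/BAM file."""
    records = []
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        for seg in fh:
            if seg.is_secondary or seg.is_supplementary:
                continue
            if seg.is_unmapped:
                records.append(
                    AlignmentRecord(
                        seg.query_name, "*", 0, "+", 0, 0, [],
                        seg.next_reference_name or "*",
                        (seg.next_reference_start or -1) + 1,
                        is_mapped=False,
                        mate_mapped=not seg.mate_is_unmapped,
                        mate=1 if seg.is_read1 else 2,
                    )
                )
                continue
            clips = []
            ct = seg.cigartuples or []
            seq = seg.query_sequence or ""
            if ct and ct[0][0] in (4, 5):
                clips.append(("left", ct[0][1], seq[: ct[0][1]]))
            if len(ct) > 1 and ct[-1][0] in (4, 5):
                clips.append(("right", ct[-1][1], seq[len(seq) - ct[-1][1]:]))
            records.append(
                AlignmentRecord(
                    seg.query_name,
                    seg.reference_name,
                    seg.reference_start + 1,
                    "-" if seg.is_reverse else "+",
                    seg.mapping_quality,
                    seg.reference_length or 1,
                    clips,
                    seg.next_reference_name or "*",
                    (seg.next_reference_start or -1) + 1,
                    is_mapped=True,
                    mate_mapped=not seg.mate_is_unmapped,
                    mate=1 if seg.is_read1 else 2,
                )
            )
    return records


def pair_up(
    records: list[AlignmentRecord],
) -> list[tuple[AlignmentRecord, AlignmentRecord]]:
    """Group primary records into (mate1, mate2) tuples by read id."""
    seen: dict[str, AlignmentRecord] = {}
    pairs = []
    for rec in records:
        other = seen.pop(rec.read_id, None)
        if other is None:
            seen[rec.read_id] = rec
        else:
            a, b = (other, rec) if other.mate <= rec.mate else (rec, other)
            pairs.append((a, b))
    return pairs


def outer_insert(a: AlignmentRecord, b: AlignmentRecord) -> int:
    """Outer fragment span of a same-contig pair."""
    return max(a.end, b.end) - min(a.pos, b.pos) + 1


def _inward(a: AlignmentRecord, b: AlignmentRecord) -> bool:
    left, right = (a, b) if a.pos <= b.pos else (b, a)
    return left.strand == "+" and right.strand == "-"


def estimate_insert_model(
    pairs: list[tuple[AlignmentRecord, AlignmentRecord]],
    k: float = 3.0,
    min_pairs: int = 200,
) -> InsertSizeModel:
    """Robust insert-size bounds from same-contig inward-facing pairs.

    bounds = median +/- k * max(1.4826 * MAD, 1 bp).  Raises
    InsufficientPairsError below ``min_pairs`` usable pairs; supply explicit
    bounds in that case.
    """
    inserts = [
        outer_insert(a, b)
        for a, b in pairs
        if a.is_mapped and b.is_mapped and a.contig == b.contig and _inward(a, b)
    ]
    if len(inserts) < min_pairs:
        raise InsufficientPairsError(
            f"only {len(inserts)} same-contig inward pairs (need >= "
            f"{min_pairs}); pass explicit insert bounds"
        )
    arr = np.asarray(inserts, dtype=float)
    med = float(np.median(arr))
    mad = float(np.median(np.abs(arr - med)))
    sigma = max(1.4826 * mad, 1.0)
    return InsertSizeModel(med, mad, med - k * sigma, med + k * sigma)


def classify_pair(
    a: AlignmentRecord,
    b: AlignmentRecord,
    model: InsertSizeModel,
) -> PairClass:
    """Classify one read pair against the concordance model.

    Symmetric in its two record arguments.
    """
    if a.read_id != b.read_id:
        raise ValueError(f"mismatched read ids {a.read_id!r} / {b.read_id!r}")
    if not (a.is_mapped and b.is_mapped):
        return PairClass.ONE_END_UNMAPPED
    if a.contig != b.contig:
        return PairClass.DISCORDANT_INTERCHROM
    if not _inward(a, b):
        return PairClass.DISCORDANT_ORIENTATION
    ins = outer_insert(a, b)
    if model.lower <= ins <= model.upper:
        return PairClass.CONCORDANT
    return PairClass.DISCORDANT_SIZE


def is_unique_pair(a: AlignmentRecord, b: AlignmentRecord, min_mapq: int = 20) -> bool:
    """Both mates pass the uniqueness (mapping-quality) threshold."""
    return a.mapq >= min_mapq and b.mapq >= min_mapq


def extract_clips(a: AlignmentRecord, min_clip: int = 10) -> list[ClipEvent]:
    """Clip events of length >= min_clip from one mapped record."""
    if not a.is_mapped:
        return []
    events = []
    for side, length, seq in a.clips:
        if length < min_clip:
            continue
        boundary = a.pos if side == "left" else a.end
        events.append(ClipEvent(a.contig, boundary, side, seq, a.mapq, a.read_id))
    return events
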