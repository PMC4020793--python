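"""Paired-end read simulation and oracle local alignments.

The simulator draws uniform-coverage 101-bp paired-end fragments from the
diploid genotype (hom / het / wt) of a :class:`~tgmap.locus.SimulatedGenome`
and emits, instead of running an external aligner, the alignments a
local-mode aligner would produce against the reference contigs: reads wholly
inside the tandem array map to the single cassette copy on the donor contig,
junction-spanning reads map to the side holding the longer exact match with
the remainder soft-clipped exactly at the junction, and mates on opposite
sides of a junction become inter-contig discordant pairs.  Reads spanning a
copy-copy junction of the same cassette are ambiguous among the m-1
equivalent placements and get mapping quality 0; every other read gets 60.

All randomness flows from a single :class:`numpy.random.Generator` seeded by
``ReadSimParams.seed`` (default 8), so runs are byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pysam

from .locus import SimulatedGenome, revcomp

DEFAULT_BASEQ = 40


@dataclass
class ReadSimParams:
    """Sequencing-run parameters.

    insert_mean/insert_sd describe the outer fragment length; depth is the
    total diploid fold-coverage over single-copy sequence.
    """

    read_length: int = 101
    insert_mean: int = 370
    insert_sd: float = 37.0
    depth: float = 8.0
    error_rate: float = 0.01
    seed: int = 8
    diploid_genotype: str = "hom"  # 'hom' | 'het' | 'wt'

    def validate(self) -> None:
        if self.read_length > self.insert_mean:
            raise ValueError("read_length must not exceed insert_mean")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if not (0 <= self.error_rate < 0.1):
            raise ValueError("error_rate must be in [0, 0.1)")
        if self.diploid_genotype not in ("hom", "het", "wt"):
            raise ValueError("diploid_genotype must be hom, het or wt")


@dataclass
class SimulatedRead:
    """One sequenced read with its truth tag.

    ``seq_forward`` is the read in reference-forward orientation (errors
    applied); the as-sequenced read is its reverse complement when
    strand == '-'.  ``origin_start/origin_end`` are 1-based inclusive
    positions on the *source* sequence named by ``source``.
    """

    read_id: str
    mate: int
    source: str
    origin_start: int
    origin_end: int
    strand: str
    seq_forward: str

    @property
    def seq_sequenced(self) -> str:
        return self.seq_forward if self.strand == "+" else revcomp(self.seq_forward)


@dataclass
class OracleAlignment:
    read_id: str
    mate: int
    contig: str
    pos: int            # 1-based reported leftmost aligned base
    strand: str
    mapq: int
    span: int           # aligned reference span
    lclip: int
    rclip: int
    seq_forward: str
    mate_contig: str = "*"
    mate_pos: int = 0
    mate_strand: str = "+"
    proper: bool = False


@dataclass
class _Source:
    """A contiguous stretch of sample sequence reads can be drawn from."""

    name: str
    seq: str
    kind: str           # 'tg' | 'wt' | 'ref'
    contig: str = ""    # for kind='ref': reference contig the stretch copies
    ref_start: int = 1  # reported position of source base 1 on that contig


def _haplotype_sources(genome: SimulatedGenome, allele: str, hap: int) -> list[_Source]:
    spec = genome.truth
    sources = []
    if allele == "tg":
        sources.append(_Source(f"hap{hap}:tg", genome.transgenic_allele, "tg"))
    else:
        sources.append(
            _Source(
                f"hap{hap}:wt",
                genome.wildtype_allele,
                "ref",
                contig=spec.insertion_chrom_name,
                ref_start=spec.coordinate_offset + 1,
            )
        )
    for unit in spec.cassette_units:
        cid = unit.cassette_id
        donor = spec.donor_contigs.get(cid, f"donor_{cid}")
        dseq = genome.reference_contigs[donor]
        pad = spec.donor_pad
        ulen = len(unit.seq)
        if spec.endogenous_copies.get(cid, 0):
            sources.append(
                _Source(f"hap{hap}:{donor}", dseq, "ref", contig=donor, ref_start=1)
            )
        else:
            # sample donor chromosome lacks the cassette: keep the unique
            # pads (as separate stretches, so no artificial junction arises)
            sources.append(
                _Source(
                    f"hap{hap}:{donor}:L", dseq[:pad], "ref", contig=donor, ref_start=1
                )
            )
            sources.append(
                _Source(
                    f"hap{hap}:{donor}:R",
                    dseq[pad + ulen:],
                    "ref",
                    contig=donor,
                    ref_start=pad + ulen + 1,
                )
            )
    return sources


def _apply_errors(seq: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    if hits.size == 0:
        return seq
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in hits:
        choices = bases[bases != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return arr.tobytes().decode()


def simulate_read_pairs(
    genome: SimulatedGenome, params: ReadSimParams
) -> list[tuple[SimulatedRead, SimulatedRead]]:
    """Draw read pairs uniformly from the diploid genotype's sequences.

    Fragment count per haplotype is (depth/2) * total_length / (2 *
    read_length), so mean coverage over single-copy sequence matches
    ``params.depth``.  Returns (mate1, mate2) tuples; mate1 is the
    forward-strand read of the fragment.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    rl = params.read_length

    allele_by_hap = {
        "hom": ("tg", "tg"),
        "het": ("tg", "wt"),
        "wt": ("wt", "wt"),
    }[params.diploid_genotype]

    pairs = []
    counter = 0
    for hap, allele in enumerate(allele_by_hap, start=1):
        sources = [
            s for s in _haplotype_sources(genome, allele, hap) if len(s.seq) >= rl
        ]
        # per-source fragment count proportional to the number of valid
        # fragment start positions, so interior coverage is depth/2 per
        # haplotype regardless of source length
        n_per_src = [
            int(round(
                (params.depth / 2.0)
                * max(len(s.seq) - params.insert_mean + 1, 1)
                / (2.0 * rl)
            ))
            for s in sources
        ]
        src_idx = np.repeat(np.arange(len(sources)), n_per_src)
        n_frags = len(src_idx)
        isizes = np.maximum(
            rl, np.rint(rng.normal(params.insert_mean, params.insert_sd, n_frags))
        ).astype(int)
        for k in range(n_frags):
            src = sources[src_idx[k]]
            isize = min(int(isizes[k]), len(src.seq))
            if len(src.seq) < isize:
                raise ValueError(f"source {src.name} shorter than insert")
            start = int(rng.integers(1, len(src.seq) - isize + 2))
            rid = f"sim{counter:07d}"
            counter += 1
            f1 = src.seq[start - 1: start - 1 + rl]
            s2 = start + isize - rl
            f2 = src.seq[s2 - 1: s2 - 1 + rl]
            r1 = SimulatedRead(
                rid, 1, src.name, start, start + rl - 1, "+",
                _apply_errors(f1, rng, params.error_rate),
            )
            r2 = SimulatedRead(
                rid, 2, src.name, s2, s2 + rl - 1, "-",
                _apply_errors(f2, rng, params.error_rate),
            )
            pairs.append((r1, r2))
    return pairs


# ---------------------------------------------------------------------------
# oracle alignment


class _TgMap:
    """Coordinate machinery for mapping transgenic-allele reads."""

    def __init__(self, genome: SimulatedGenome):
        spec = genome.truth
        self.spec = spec
        self.genome = genome
        self.L = spec.flank_length
        self.ldup = len(spec.left_dup_seq)
        self.rdup = len(spec.right_dup_seq)
        self.segments = spec.array_segments()
        self.E = self.segments[-1]["end"] if self.segments else 0
        # last tg-allele base attributable to the array
        self.T = self.L + self.E - self.ldup
        self.offset = spec.coordinate_offset
        self.chrom = spec.insertion_chrom_name
        self.right_boundary = spec.right_boundary
        self.seg_starts = [seg["start"] for seg in self.segments]

    def _seg_at(self, a: int) -> int:
        import bisect

        return bisect.bisect_right(self.seg_starts, a) - 1

    def _donor_block(self, seg: dict, w1: int, w2: int) -> tuple[str, int, bool]:
        """Map unit-internal positions [w1, w2] to donor coordinates.

        Returns (contig, reported_start, flipped).
        """
        spec = self.spec
        cid = seg["cassette_id"]
        donor = spec.donor_contigs.get(cid, f"donor_{cid}")
        pad = spec.donor_pad
        ulen = seg["unit_length"]
        if seg["orientation"] == "forward":
            return donor, pad + w1, False
        return donor, pad + (ulen - w2 + 1), True

    def map_read(self, s: int, e: int) -> tuple[str, int, int, int, int, int, bool]:
        """Oracle-align a tg-allele interval [s, e].

        Returns (contig, reported_pos, span, lclip, rclip, mapq, flipped);
        ``flipped`` means the aligned strand is inverted relative to the
        allele (reverse-oriented cassette copy).
        """
        L, T, ldup, rdup = self.L, self.T, self.ldup, self.rdup
        length = e - s + 1

        if self.E == 0:  # zero-copy array: pure deletion allele
            if e <= L:
                return self.chrom, s + self.offset, length, 0, 0, 60, False
            if s > L:
                pos = self.right_boundary + (s - L - 1)
                return self.chrom, pos, length, 0, 0, 60, False
            f, c = L - s + 1, e - L
            if f >= c:
                return self.chrom, s + self.offset, f, 0, c, 60, False
            return self.chrom, self.right_boundary, c, f, 0, 60, False

        if e <= L:
            return self.chrom, s + self.offset, length, 0, 0, 60, False
        if s >= T - rdup + 1:
            pos = self.right_boundary + (s - (T - rdup + 1))
            return self.chrom, pos, length, 0, 0, 60, False
        if s >= L - ldup + 1 and e <= T:
            a_s, a_e = s - L + ldup, e - L + ldup
            i = self._seg_at(a_s)
            seg = self.segments[i]
            if a_e <= seg["end"]:
                w1, w2 = a_s - seg["start"] + 1, a_e - seg["start"] + 1
                contig, pos, flipped = self._donor_block(seg, w1, w2)
                return contig, pos, length, 0, 0, 60, flipped
            nxt = self.segments[i + 1]
            left_part = seg["end"] - a_s + 1
            right_part = a_e - nxt["start"] + 1
            ambiguous = seg["cassette_id"] == nxt["cassette_id"]
            mapq = 0 if ambiguous else 60
            if left_part >= right_part:
                w1 = a_s - seg["start"] + 1
                contig, pos, flipped = self._donor_block(seg, w1, seg["unit_length"])
                lcl, rcl = (right_part, 0) if flipped else (0, right_part)
                return contig, pos, left_part, lcl, rcl, mapq, flipped
            contig, pos, flipped = self._donor_block(nxt, 1, right_part)
            lcl, rcl = (0, left_part) if flipped else (left_part, 0)
            return contig, pos, right_part, lcl, rcl, mapq, flipped
        if s <= L - ldup and e > L:
            f, c = L - s + 1, e - L
            if f >= c:
                return self.chrom, s + self.offset, f, 0, c, 60, False
            a_e = e - L + ldup
            seg = self.segments[0]
            span = a_e
            lclip = (L - ldup) - s + 1
            contig, pos, flipped = self._donor_block(seg, 1, a_e)
            if flipped:
                return contig, pos, span, 0, lclip, 60, True
            return contig, pos, span, lclip, 0, 60, flipped
        # right junction: s within array, e beyond T
        c = T - s + 1
        f = e - (T - rdup)
        if f > c:
            lclip = (T - rdup + 1) - s
            span = e - (T - rdup)
            return self.chrom, self.right_boundary, span, lclip, 0, 60, False
        a_s = s - L + ldup
        seg = self.segments[-1]
        w1 = a_s - seg["start"] + 1
        rclip = e - T
        contig, pos, flipped = self._donor_block(seg, w1, seg["unit_length"])
        if flipped:
            return contig, pos, c, rclip, 0, 60, True
        return contig, pos, c, 0, rclip, 60, flipped


def emit_oracle_alignments(
    genome: SimulatedGenome, pairs: list[tuple[SimulatedRead, SimulatedRead]]
) -> list[OracleAlignment]:
    """Assign every simulated read to reference contigs by its true origin."""
    tgmap = _TgMap(genome)
    spec = genome.truth

    # pre-index ref-copy sources by name prefix handled per read below
    out = []
    for r1, r2 in pairs:
        recs = []
        for rd in (r1, r2):
            if ":tg" in rd.source:
                contig, pos, span, lcl, rcl, mapq, flipped = tgmap.map_read(
                    rd.origin_start, rd.origin_end
                )
                strand = rd.strand
                seq = rd.seq_forward
                if flipped:
                    strand = "+" if strand == "-" else "-"
                    seq = revcomp(seq)
                recs.append(
                    OracleAlignment(
                        rd.read_id, rd.mate, contig, pos, strand, mapq,
                        span, lcl, rcl, seq,
                    )
                )
            else:
                # source copies a reference stretch verbatim
                parts = rd.source.split(":")
                if parts[1] == "wt":
                    contig = spec.insertion_chrom_name
                    start = spec.coordinate_offset + rd.origin_start
                else:
                    contig = parts[1]
                    if len(parts) == 3 and parts[2] == "R":
                        unit_len = next(
                            len(u.seq)
                            for u in spec.cassette_units
                            if spec.donor_contigs.get(u.cassette_id) == contig
                            or f"donor_{u.cassette_id}" == contig
                        )
                        start = spec.donor_pad + unit_len + rd.origin_start
                    else:
                        start = rd.origin_start
                recs.append(
                    OracleAlignment(
                        rd.read_id, rd.mate, contig, start, rd.strand, 60,
                        rd.origin_end - rd.origin_start + 1, 0, 0,
                        rd.seq_forward,
                    )
                )
        a, b = recs
        a.mate_contig, a.mate_pos, a.mate_strand = b.contig, b.pos, b.strand
        b.mate_contig, b.mate_pos, b.mate_strand = a.contig, a.pos, a.strand
        proper = (
            a.contig == b.contig
            and a.strand != b.strand
            and abs(b.pos - a.pos) < 10 * max(1, int(genome.truth.flank_length))
        )
        a.proper = b.proper = proper
        out.extend(recs)
    return out


# ---------------------------------------------------------------------------
# writers


def sam_header(genome: SimulatedGenome) -> pysam.AlignmentHeader:
    sq = [
        {"SN": name, "LN": genome.reported_length(name)}
        for name in genome.reference_contigs
    ]
    return pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6", "SO": "unsorted"}, "SQ": sq}
    )


def write_sam(
    genome: SimulatedGenome, alignments: list[OracleAlignment], path: str
) -> None:
    """Write oracle alignments as plain-text SAM."""
    header = sam_header(genome)
    with pysam.AlignmentFile(path, "w", header=header) as fh:
        for al in alignments:
            seg = pysam.AlignedSegment(header)
            seg.query_name = al.read_id
            flag = 0x1
            if al.proper:
                flag |= 0x2
            if al.strand == "-":
                flag |= 0x10
            if al.mate_strand == "-":
                flag |= 0x20
            flag |= 0x40 if al.mate == 1 else 0x80
            seg.flag = flag
            seg.reference_id = header.get_tid(al.contig)
            seg.reference_start = al.pos - 1
            seg.mapping_quality = al.mapq
            cigar = []
            if al.lclip:
                cigar.append((4, al.lclip))
            cigar.append((0, al.span))
            if al.rclip:
                cigar.append((4, al.rclip))
            seg.cigartuples = cigar
            seg.next_reference_id = header.get_tid(al.mate_contig)
            seg.next_reference_start = al.mate_pos - 1
            seg.template_length = 0
            seg.query_sequence = al.seq_forward
            seg.query_qualities = pysam.qualitystring_to_array(
                chr(DEFAULT_BASEQ + 33) * len(al.seq_forward)
            )
            fh.write(seg)


def write_fastq(
    pairs: list[tuple[SimulatedRead, SimulatedRead]], path1: str, path2: str
) -> None:
    """Paired FASTQ (Phred+33, constant base quality)."""
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for r1, r2 in pairs:
            for rd, fh in ((r1, f1), (r2, f2)):
                q = chr(DEFAULT_BASEQ + 33) * len(rd.seq_forward)
                fh.write(f"@{rd.read_id}/{rd.mate}\n{rd.seq_sequenced}\n+\n{q}\n")


def write_truth(
    pairs: list[tuple[SimulatedRead, SimulatedRead]], path: str
) -> None:
    """Truth sidecar TSV: read_id, mate, source, origin_pos, strand."""
    with open(path, "w") as fh:
        fh.write("read_id\tmate\tsource\torigin_pos\tstrand\n")
        for r1, r2 in pairs:
            for rd in (r1, r2):
                fh.write(
                    f"{rd.read_id}\t{rd.mate}\t{rd.source}\t"
                    f"{rd.origin_start}\t{rd.strand}\n"
                )
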