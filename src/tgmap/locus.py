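"""Ground-truth synthetic transgenic locus construction.

A transgenic integration locus is modelled as a host chromosome in which a
tandem array of transgene cassette units replaces a short stretch of native
sequence.  The junctions are flanked by short *duplicated sequences*
(microhomologies): a string that is simultaneously a suffix of the retained
left flank and a prefix of the first cassette unit (left boundary), and,
mirror-wise, a suffix of the last unit and a prefix of the retained right
flank (right boundary).  The duplicated string is stored once in the physical
allele; its "duplication" is an alignment ambiguity, which is exactly the
ambiguity the breakpoint resolver has to cope with.

Coordinates are 1-based inclusive throughout.  The insertion chromosome can
be placed in an arbitrary reporting frame via ``coordinate_offset`` so that a
few-kilobase synthetic window reports positions like a real chromosome does
(e.g. chr2 positions around 68.2 Mb).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

ALPHABET = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse-complement a DNA string."""
    return seq.translate(_COMP)[::-1]


def random_seq(rng: np.random.Generator, length: int) -> str:
    """Uniform random DNA of the given length."""
    return "".join(np.array(list(ALPHABET))[rng.integers(0, 4, size=length)])


class LocusConstructionError(ValueError):
    """Raised when a LocusSpec violates a boundary-consistency invariant."""


@dataclass
class CassetteUnit:
    """One transgene cassette unit as it appears in the tandem array."""

    cassette_id: str
    seq: str
    orientation: str = "forward"  # 'forward' | 'reverse'

    @property
    def oriented_seq(self) -> str:
        return self.seq if self.orientation == "forward" else revcomp(self.seq)

    def __post_init__(self) -> None:
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(f"bad orientation {self.orientation!r}")


@dataclass
class LocusSpec:
    """Complete description of a synthetic transgenic locus.

    Parameters
    ----------
    insertion_chrom_name : str
        Name of the host (insertion) chromosome surrogate.
    coordinate_offset : int
        Reported position = raw contig position + offset.  Lets a small
        synthetic window report coordinates in a chosen chromosome frame.
    left_boundary : int
        1-based reported coordinate of the last retained base of the left
        flank.
    right_boundary : int
        1-based reported coordinate of the first retained base of the right
        flank.  ``right_boundary - left_boundary`` is the deletion length as
        conventionally printed; the count of physically removed bases is that
        value minus one.
    left_dup_seq, right_dup_seq : str
        Boundary duplicated sequences (may be empty).
    cassette_units : list of CassetteUnit
        Ordered distinct units of the array (e.g. beta then alpha).
    array_multiplicities : dict
        cassette_id -> tandem copy count in the array.
    endogenous_copies : dict
        cassette_id -> 0/1, whether a divergence-free endogenous copy of the
        unit is present on its donor chromosome in the *sample* (the
        reference donor contig always carries one copy).
    flank_length : int
        Retained flank length on each side of the insertion.
    donor_contigs : dict
        cassette_id -> donor contig name.
    donor_pad : int
        Unique donor sequence padded on each side of the cassette unit.
    """

    insertion_chrom_name: str = "chr2"
    coordinate_offset: int = 0
    left_boundary: int = 6000
    right_boundary: int = 6157
    left_dup_seq: str = ""
    right_dup_seq: str = ""
    cassette_units: list[CassetteUnit] = field(default_factory=list)
    array_multiplicities: dict[str, int] = field(default_factory=dict)
    endogenous_copies: dict[str, int] = field(default_factory=dict)
    flank_length: int = 6000
    donor_contigs: dict[str, str] = field(default_factory=dict)
    donor_pad: int = 3000

    # sequences filled by the factory (or supplied by the user)
    left_flank_seq: str = ""
    deleted_seq: str = ""
    right_flank_seq: str = ""

    @property
    def deletion_length(self) -> int:
        """Deletion length as printed: coordinate difference of boundaries."""
        return self.right_boundary - self.left_boundary

    @property
    def deleted_bases(self) -> int:
        """Number of physically removed native bases."""
        return self.right_boundary - self.left_boundary - 1

    def validate(self) -> None:
        if self.right_boundary <= self.left_boundary:
            raise LocusConstructionError(
                "right_boundary must exceed left_boundary"
            )
        if len(self.left_flank_seq) != self.flank_length:
            raise LocusConstructionError("left flank length mismatch")
        if len(self.right_flank_seq) != self.flank_length:
            raise LocusConstructionError("right flank length mismatch")
        if len(self.deleted_seq) != self.deleted_bases:
            raise LocusConstructionError(
                f"deleted segment must hold {self.deleted_bases} bases"
            )
        for unit in self.cassette_units:
            if set(unit.seq) - set(ALPHABET):
                raise LocusConstructionError(
                    f"cassette {unit.cassette_id} has non-ACGT characters"
                )
        for cid, m in self.array_multiplicities.items():
            if m < 0:
                raise LocusConstructionError(f"multiplicity of {cid} < 0")
        expansion = self.array_expansion()
        if expansion:
            if not self.left_flank_seq.endswith(self.left_dup_seq):
                raise LocusConstructionError(
                    "left boundary: left_dup_seq is not a suffix of the "
                    "retained left flank"
                )
            if not expansion.startswith(self.left_dup_seq):
                raise LocusConstructionError(
                    "left boundary: left_dup_seq is not a prefix of the "
                    "first cassette unit"
                )
            if not expansion.endswith(self.right_dup_seq):
                raise LocusConstructionError(
                    "right boundary: right_dup_seq is not a suffix of the "
                    "last cassette unit"
                )
            if not self.right_flank_seq.startswith(self.right_dup_seq):
                raise LocusConstructionError(
                    "right boundary: right_dup_seq is not a prefix of the "
                    "retained right flank"
                )

    def array_expansion(self) -> str:
        """Concatenated oriented array sequence, copy by copy."""
        parts = []
        for unit in self.cassette_units:
            m = self.array_multiplicities.get(unit.cassette_id, 0)
            parts.extend([unit.oriented_seq] * m)
        return "".join(parts)

    def array_segments(self) -> list[dict]:
        """Per-copy segment table over the expansion coordinate (1-based).

        Each entry: cassette_id, copy_index, orientation, start, end
        (positions within the expansion string), unit_length.
        """
        segs = []
        pos = 1
        for unit in self.cassette_units:
            m = self.array_multiplicities.get(unit.cassette_id, 0)
            ulen = len(unit.seq)
            for k in range(m):
                segs.append(
                    {
                        "cassette_id": unit.cassette_id,
                        "copy_index": k,
                        "orientation": unit.orientation,
                        "start": pos,
                        "end": pos + ulen - 1,
                        "unit_length": ulen,
                    }
                )
                pos += ulen
        return segs


@dataclass
class SimulatedGenome:
    """Reference contigs plus the two haplotype alleles and the truth record.

    ``reference_contigs`` maps contig name -> sequence: the wild-type
    insertion chromosome window plus one donor contig per cassette (pad +
    unit + pad).  ``offsets`` maps contig name -> reporting offset (reported
    position = raw position + offset).  ``cassette_intervals`` maps
    cassette_id -> (contig, start, end) of the reference cassette copy in
    reported coordinates.
    """

    reference_contigs: dict[str, str]
    offsets: dict[str, int]
    transgenic_allele: str
    wildtype_allele: str
    truth: LocusSpec
    cassette_intervals: dict[str, tuple[str, int, int]]

    @property
    def insertion_contig(self) -> str:
        return self.truth.insertion_chrom_name

    def reported_length(self, contig: str) -> int:
        return self.offsets.get(contig, 0) + len(self.reference_contigs[contig])

    def flank_window(self, side: str, length: int) -> str:
        """Retained flank sequence adjacent to a boundary.

        side='left': suffix of the retained left flank ending at
        left_boundary; side='right': prefix of the retained right flank
        starting at right_boundary.
        """
        t = self.truth
        if side == "left":
            return t.left_flank_seq[-length:]
        return t.right_flank_seq[:length]

    def cassette_end_seqs(self, length: int = 200) -> dict[str, dict[str, str]]:
        """Oriented start/end sequences of the array's outer units."""
        out = {}
        for unit in self.truth.cassette_units:
            s = unit.oriented_seq
            out[unit.cassette_id] = {"start": s[:length], "end": s[-length:]}
        return out


def build_alleles(spec: LocusSpec) -> SimulatedGenome:
    """Assemble reference contigs and both alleles from a LocusSpec.

    The wild-type allele equals the insertion contig exactly.  The
    transgenic allele is leftFlank + expansion + rightFlank with each
    boundary duplicated sequence present once (the expansion's leading
    left-dup and the right flank's leading right-dup are elided, which are
    no-ops at the string level because both neighbours carry the string).
    """
    spec.validate()
    expansion = spec.array_expansion()

    wildtype = spec.left_flank_seq + spec.deleted_seq + spec.right_flank_seq
    if expansion:
        transgenic = (
            spec.left_flank_seq
            + expansion[len(spec.left_dup_seq):]
            + spec.right_flank_seq[len(spec.right_dup_seq):]
        )
    else:
        transgenic = spec.left_flank_seq + spec.right_flank_seq

    contigs = {spec.insertion_chrom_name: wildtype}
    offsets = {spec.insertion_chrom_name: spec.coordinate_offset}
    cassette_intervals = {}
    for unit in spec.cassette_units:
        donor = spec.donor_contigs.get(unit.cassette_id, f"donor_{unit.cassette_id}")
        # donor contig always carries one (forward-stored) cassette copy;
        # pads derive from a stable checksum so rebuilds are byte-identical
        rng_pad = np.random.default_rng(
            zlib.crc32((unit.cassette_id + unit.seq[:64]).encode()) % (2**31)
        )
        left_pad = random_seq(rng_pad, spec.donor_pad)
        right_pad = random_seq(rng_pad, spec.donor_pad)
        contigs[donor] = left_pad + unit.seq + right_pad
        offsets[donor] = 0
        cassette_intervals[unit.cassette_id] = (
            donor,
            spec.donor_pad + 1,
            spec.donor_pad + len(unit.seq),
        )

    expected_offset = spec.left_boundary - spec.flank_length
    if spec.coordinate_offset != expected_offset:
        raise LocusConstructionError(
            "coordinate_offset inconsistent with left_boundary and "
            f"flank_length (expected {expected_offset})"
        )

    return SimulatedGenome(
        reference_contigs=contigs,
        offsets=offsets,
        transgenic_allele=transgenic,
        wildtype_allele=wildtype,
        truth=spec,
        cassette_intervals=cassette_intervals,
    )


def _embed(seq: str, motif: str, where: str) -> str:
    """Overwrite the start/end of seq with motif."""
    if not motif:
        return seq
    if where == "prefix":
        return motif + seq[len(motif):]
    return seq[: len(seq) - len(motif)] + motif


def _guard_no_extension(flank: str, cassette: str, dup_len: int, side: str) -> tuple[str, str]:
    """Mutate one base so the duplicated sequence cannot extend by chance.

    For a left boundary the microhomology is the longest suffix of ``flank``
    equal to a prefix of ``cassette``; this forces it to be exactly
    ``dup_len`` by breaking the length dup_len+1 match if present.
    """
    def mh_left(f: str, c: str) -> int:
        k = min(len(f), len(c))
        while k > 0 and f[-k:] != c[:k]:
            k -= 1
        return k

    def mh_right(c: str, f: str) -> int:
        k = min(len(f), len(c))
        while k > 0 and c[-k:] != f[:k]:
            k -= 1
        return k

    for _ in range(20):
        k = mh_left(flank, cassette) if side == "left" else mh_right(flank, cassette)
        if k <= dup_len:
            break
        if side == "left":
            i = len(flank) - k  # first base of the over-long match, flank side
            repl = next(b for b in ALPHABET if b != flank[i] and b != cassette[0])
            flank = flank[:i] + repl + flank[i + 1:]
        else:
            i = len(flank) - k  # here ``flank`` is the cassette (left input)
            repl = next(b for b in ALPHABET if b != flank[i] and b != cassette[0])
            flank = flank[:i] + repl + flank[i + 1:]
    return flank, cassette


def default_locus_spec(
    seed: int = 8,
    *,
    left_boundary: int = 68_208_872,
    right_boundary: int = 68_209_029,
    left_dup_seq: str = "CCAGCAG",
    right_dup_seq: str = "TGGAT",
    flank_length: int = 6000,
    unit_length: int = 3000,
    alpha_copies: int = 16,
    beta_copies: int = 4,
    endogenous: bool = True,
    insertion_chrom_name: str = "chr2",
    donor_pad: int = 3000,
) -> LocusSpec:
    """Default study locus: a beta-then-alpha tandem array inserted in a host
    chromosome window with a 157-bp deletion and 7-bp / 5-bp boundary
    duplicated sequences, reported in a chr2-like coordinate frame.

    The left boundary abuts the beta array (donor surrogate "chr6"), the
    right boundary abuts the alpha array (donor surrogate "chr14").
    """
    rng = np.random.default_rng(seed)
    left_flank = random_seq(rng, flank_length)
    deleted = random_seq(rng, right_boundary - left_boundary - 1)
    right_flank = random_seq(rng, flank_length)
    beta = random_seq(rng, unit_length)
    alpha = random_seq(rng, unit_length)

    # embed the duplicated sequences once on each side of each junction
    left_flank = _embed(left_flank, left_dup_seq, "suffix")
    beta = _embed(beta, left_dup_seq, "prefix")
    alpha = _embed(alpha, right_dup_seq, "suffix")
    right_flank = _embed(right_flank, right_dup_seq, "prefix")

    left_flank, beta = _guard_no_extension(
        left_flank, beta, len(left_dup_seq), "left"
    )
    alpha, right_flank = _guard_no_extension(
        alpha, right_flank, len(right_dup_seq), "right"
    )

    spec = LocusSpec(
        insertion_chrom_name=insertion_chrom_name,
        coordinate_offset=left_boundary - flank_length,
        left_boundary=left_boundary,
        right_boundary=right_boundary,
        left_dup_seq=left_dup_seq,
        right_dup_seq=right_dup_seq,
        cassette_units=[
            CassetteUnit("beta", beta, "forward"),
            CassetteUnit("alpha", alpha, "forward"),
        ],
        array_multiplicities={"beta": beta_copies, "alpha": alpha_copies},
        endogenous_copies={
            "beta": 1 if endogenous else 0,
            "alpha": 1 if endogenous else 0,
        },
        flank_length=flank_length,
        donor_contigs={"beta": "chr6", "alpha": "chr14"},
        donor_pad=donor_pad,
        left_flank_seq=left_flank,
        deleted_seq=deleted,
        right_flank_seq=right_flank,
    )
    return spec


def spec_to_dict(spec: LocusSpec) -> dict:
    """Plain-dict form of a LocusSpec (YAML/JSON serialisable)."""
    return {
        "insertion_chrom_name": spec.insertion_chrom_name,
        "coordinate_offset": spec.coordinate_offset,
        "left_boundary": spec.left_boundary,
        "right_boundary": spec.right_boundary,
        "left_dup_seq": spec.left_dup_seq,
        "right_dup_seq": spec.right_dup_seq,
        "cassette_units": [
            {"cassette_id": u.cassette_id, "seq": u.seq, "orientation": u.orientation}
            for u in spec.cassette_units
        ],
        "array_multiplicities": dict(spec.array_multiplicities),
        "endogenous_copies": dict(spec.endogenous_copies),
        "flank_length": spec.flank_length,
        "donor_contigs": dict(spec.donor_contigs),
        "donor_pad": spec.donor_pad,
        "left_flank_seq": spec.left_flank_seq,
        "deleted_seq": spec.deleted_seq,
        "right_flank_seq": spec.right_flank_seq,
    }


def spec_from_dict(d: dict) -> LocusSpec:
    d = dict(d)
    d["cassette_units"] = [CassetteUnit(**u) for u in d.get("cassette_units", [])]
    return LocusSpec(**d)


def load_spec(path: str) -> LocusSpec:
    """Load a LocusSpec from a YAML (or JSON) document."""
    import yaml

    with open(path) as fh:
        return spec_from_dict(yaml.safe_load(fh))


def save_spec(spec: LocusSpec, path: str) -> None:
    import yaml

    with open(path, "w") as fh:
        yaml.safe_dump(spec_to_dict(spec), fh, sort_keys=True)
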