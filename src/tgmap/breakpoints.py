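"""Exact junction resolution from soft-clip consensus and microhomology.

A boundary call takes the mode of the clip boundary coordinates (ties to
the smaller coordinate), builds a per-column majority consensus of the
clipped tails anchored at the boundary, and identifies the partner cassette
as the one whose junction-proximal sequence matches the consensus with the
fewest mismatches (allowing a shift of up to the microhomology length,
since the duplicated boundary sequence makes the exact breakpoint ambiguous
within its span).  The deletion at the insertion site is the coordinate
difference of the two boundaries — the convention under which the printed
boundary pair (68,208,872 / 68,209,029) yields 157 bp; the inclusive base
count would be one larger.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .locus import revcomp
from .pairs import ClipEvent


@dataclass
class BoundaryCall:
    contig: str
    coordinate: int
    side: str                      # 'left' | 'right'
    partner_cassette: str | None
    n_discordant: int
    n_softclip: int
    clip_consensus: str
    exact: bool = True


@dataclass
class InsertionCall:
    left: BoundaryCall
    right: BoundaryCall
    deletion_length: int
    left_microhomology: tuple[str, int] = ("", 0)
    right_microhomology: tuple[str, int] = ("", 0)

    @property
    def status(self) -> str:
        return "exact" if (self.left.exact and self.right.exact) else "approximate"

    @property
    def contig(self) -> str:
        return self.left.contig


def consensus_from_clips(seqs: list[str], anchor: str) -> str:
    """Per-column majority consensus of clipped tails.

    anchor='left': sequences start at the boundary (right-clip tails) and
    are compared column by column from the left; anchor='right': sequences
    end at the boundary (left-clip tails) and are compared from the right.
    A column needs >= 50% agreement among the reads covering it; the
    consensus is truncated at the first dissenting column.
    """
    if not seqs:
        return ""
    if anchor == "right":
        rev = [s[::-1] for s in seqs]
        return consensus_from_clips(rev, "left")[::-1]
    out = []
    maxlen = max(len(s) for s in seqs)
    for i in range(maxlen):
        col = [s[i] for s in seqs if len(s) > i]
        common = Counter(col).most_common(2)
        base, n = common[0]
        if n * 2 < len(col):
            break
        if len(common) > 1 and common[1][1] == n:
            break  # tied column: no unique majority
        out.append(base)
    return "".join(out)


def _best_shifted_match(
    consensus: str, target: str, anchor: str, max_shift: int = 50
) -> tuple[int, int]:
    """Fewest mismatches of consensus against target allowing a shift.

    anchor='left': consensus is compared to target[shift:] (prefix side);
    anchor='right': consensus tail compared to target's suffix shifted
    inwards.  Returns (mismatches, shift) of the best placement.
    """
    best = (len(consensus) + 1, 0)
    for shift in range(0, max_shift + 1):
        if anchor == "left":
            window = target[shift: shift + len(consensus)]
        else:
            end = len(target) - shift
            window = target[max(0, end - len(consensus)): end]
        if len(window) < len(consensus):
            break
        mm = sum(1 for x, y in zip(consensus, window) if x != y)
        if mm < best[0]:
            best = (mm, shift)
        if mm == 0:
            break
    return best


def resolve_boundary(
    clips: list[ClipEvent],
    side: str,
    cassette_end_seqs: dict[str, dict[str, str]] | None = None,
    n_discordant: int = 0,
    fallback_interval: tuple[str, int, int] | None = None,
    fallback_partner: str | None = None,
    max_mismatch_frac: float = 0.1,
) -> BoundaryCall:
    """Resolve one insertion boundary from clip events.

    ``side`` is the boundary side on the insertion contig: a *left* boundary
    is evidenced by right-clipped reads (aligned flank, clipped cassette
    tail) and a *right* boundary by left-clipped reads.  With no usable
    clips, an approximate call is made from the midpoint of
    ``fallback_interval`` (the discordant cluster's insertion-side span).
    """
    want = "right" if side == "left" else "left"
    usable = [c for c in clips if c.side == want]
    if not usable:
        if fallback_interval is None:
            raise ValueError("no clip events and no fallback interval")
        contig, lo, hi = fallback_interval
        return BoundaryCall(
            contig, (lo + hi) // 2, side, fallback_partner,
            n_discordant, 0, "", exact=False,
        )
    counts = Counter(c.boundary_pos for c in usable)
    top = max(counts.values())
    coordinate = min(p for p, n in counts.items() if n == top)
    at_boundary = [c for c in usable if c.boundary_pos == coordinate]
    anchor = "left" if side == "left" else "right"
    consensus = consensus_from_clips(
        [c.clipped_seq for c in at_boundary if c.clipped_seq], anchor
    )

    partner = None
    exact = True
    if consensus and cassette_end_seqs:
        # left boundary: clipped tail continues into the partner cassette's
        # start; right boundary: tail is the partner cassette's end
        results = {}
        for cid, ends in cassette_end_seqs.items():
            target = ends["start"] if side == "left" else ends["end"]
            results[cid] = _best_shifted_match(consensus, target, anchor)
        cid_best = min(results, key=lambda c: (results[c][0], c))
        if results[cid_best][0] < max_mismatch_frac * max(len(consensus), 1):
            partner = cid_best
        else:
            partner = None
            exact = False
    elif fallback_partner is not None:
        partner = fallback_partner

    return BoundaryCall(
        usable[0].contig, coordinate, side, partner,
        n_discordant, len(at_boundary), consensus, exact=exact,
    )


def compute_microhomology(
    flank_side_seq: str, cassette_junction_seq: str, side: str = "left",
    max_len: int = 50,
) -> tuple[str, int]:
    """Duplicated sequence at a junction, exact matching only.

    side='left': longest string that is simultaneously a suffix of the
    retained flank and a prefix of the cassette side; side='right': longest
    string that is a suffix of the cassette side and a prefix of the
    retained flank.
    """
    if side == "left":
        left, right = flank_side_seq, cassette_junction_seq
    else:
        left, right = cassette_junction_seq, flank_side_seq
    k = min(max_len, len(left), len(right))
    while k > 0 and left[-k:] != right[:k]:
        k -= 1
    return (left[-k:] if k else "", k)


def microhomology_revcomp_mirror(
    flank_side_seq: str, cassette_junction_seq: str, side: str
) -> tuple[str, int]:
    """Reverse-complement mirror of compute_microhomology (helper used by
    the symmetry property: rc both inputs, swap the side)."""
    other = "right" if side == "left" else "left"
    seq, n = compute_microhomology(
        revcomp(flank_side_seq), revcomp(cassette_junction_seq), other
    )
    return revcomp(seq), n


def assemble_insertion_call(
    left: BoundaryCall,
    right: BoundaryCall,
    flank_seqs: tuple[str, str] | None = None,
    cassette_end_seqs: dict[str, dict[str, str]] | None = None,
    max_mh: int = 50,
) -> InsertionCall:
    """Pair two boundary calls into an insertion call.

    deletion_length = right.coordinate - left.coordinate.  Microhomologies
    are computed against the partner cassettes' junction sequences when
    available, else against each boundary's own clip consensus.
    ``flank_seqs`` = (sequence ending at the left boundary, sequence
    starting at the right boundary).
    """
    if left.contig != right.contig:
        raise ValueError(
            "boundaries on different contigs: not a simple insertion "
            f"({left.contig} vs {right.contig})"
        )
    if right.coordinate < left.coordinate:
        raise ValueError("right boundary upstream of left boundary")

    call = InsertionCall(left, right, right.coordinate - left.coordinate)
    if flank_seqs is not None:
        lflank, rflank = flank_seqs
        ltarget = None
        if cassette_end_seqs and left.partner_cassette in (cassette_end_seqs or {}):
            ltarget = cassette_end_seqs[left.partner_cassette]["start"]
        elif left.clip_consensus:
            ltarget = left.clip_consensus
        if ltarget:
            call.left_microhomology = compute_microhomology(
                lflank, ltarget, "left", max_mh
            )
        rtarget = None
        if cassette_end_seqs and right.partner_cassette in (cassette_end_seqs or {}):
            rtarget = cassette_end_seqs[right.partner_cassette]["end"]
        elif right.clip_consensus:
            rtarget = right.clip_consensus
        if rtarget:
            call.right_microhomology = compute_microhomology(
                rflank, rtarget, "right", max_mh
            )
    return call
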