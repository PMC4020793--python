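"""Discordant-pair clustering, read-depth duplication scoring and candidate
filtering/ranking.

Discordant pairs are clustered by single linkage: two pairs join the same
cluster iff their footprints on *both* sides lie within a window
(default twice the insert mean) of each other and bridge the same contig
pair.  Depth duplications are contiguous runs of bins at >= 1.5x the
genome-wide mean, scored by the normalised read count rc = run mean /
genome mean.  Filters codify the manual review rules: support outside
[5, 16] rejected, excluded (mitochondrial/centromeric) contigs rejected,
intra-chromosomal links optionally rejected, and clusters crowded by
adjacent rearrangements rejected.  Ranking is by split-read support, then
by whether the cassette side is bridged by a depth-duplication call, then
by pair support, with a deterministic coordinate tie-break.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pairs import AlignmentRecord, ClipEvent


@dataclass
class DiscordantPair:
    """A classified discordant pair in canonical (A <= B) side order."""

    a: AlignmentRecord
    b: AlignmentRecord

    def __post_init__(self) -> None:
        if (self.a.contig, self.a.pos) > (self.b.contig, self.b.pos):
            self.a, self.b = self.b, self.a

    @property
    def key(self) -> tuple[str, str]:
        return (self.a.contig, self.b.contig)


@dataclass
class LinkCluster:
    contig_a: str
    interval_a: tuple[int, int]
    contig_b: str
    interval_b: tuple[int, int]
    support: int
    mean_mapq: float
    split_support: int = 0
    members: list[DiscordantPair] = field(default_factory=list)

    @property
    def sort_key(self) -> tuple:
        return (self.contig_a, self.interval_a[0], self.contig_b, self.interval_b[0])


@dataclass
class DepthDuplicationCall:
    contig: str
    start: int
    end: int
    rc: float  # normalised high-quality read count: run mean / genome mean

    @property
    def score(self) -> float:
        return self.rc


@dataclass
class FilterConfig:
    min_support: int = 5
    max_support: int = 16
    excluded_contigs: frozenset[str] = frozenset()
    drop_intra_chrom: bool = True
    drop_adjacent: bool = True
    adjacent_n: int = 3
    adjacent_window: int = 10_000

    def validate(self) -> None:
        if self.min_support > self.max_support:
            raise ValueError("min_support exceeds max_support")


@dataclass
class Rejection:
    cluster: LinkCluster
    reason: str


def _footprints_close(
    i1: tuple[int, int], i2: tuple[int, int], window: int
) -> bool:
    gap = max(i1[0], i2[0]) - min(i1[1], i2[1])
    return gap <= window


def cluster_discordant_pairs(
    pairs: list[DiscordantPair], window: int = 740
) -> list[LinkCluster]:
    """Single-linkage clustering of discordant pairs.

    Two pairs are linked iff they bridge the same (contigA, contigB) pair
    and both their A-side and B-side footprints are within ``window`` bp.
    Union-find over the (small) candidate set; output sorted by
    (contigA, startA, contigB, startB).
    """
    if not pairs:
        return []
    n = len(pairs)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    # group by contig pair first; O(m^2) within groups is fine at desk scale
    by_key: dict[tuple[str, str], list[int]] = {}
    for i, p in enumerate(pairs):
        by_key.setdefault(p.key, []).append(i)
    for idxs in by_key.values():
        for ii, i in enumerate(idxs):
            pi = pairs[i]
            fa_i = (pi.a.pos, pi.a.end)
            fb_i = (pi.b.pos, pi.b.end)
            for j in idxs[ii + 1:]:
                pj = pairs[j]
                if _footprints_close(fa_i, (pj.a.pos, pj.a.end), window) and \
                        _footprints_close(fb_i, (pj.b.pos, pj.b.end), window):
                    union(i, j)

    groups: dict[int, list[DiscordantPair]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(pairs[i])

    clusters = []
    for members in groups.values():
        sa = min(p.a.pos for p in members)
        ea = max(p.a.end for p in members)
        sb = min(p.b.pos for p in members)
        eb = max(p.b.end for p in members)
        mapqs = [q for p in members for q in (p.a.mapq, p.b.mapq)]
        clusters.append(
            LinkCluster(
                members[0].a.contig, (sa, ea),
                members[0].b.contig, (sb, eb),
                len(members), float(np.mean(mapqs)), 0, members,
            )
        )
    clusters.sort(key=lambda c: c.sort_key)
    return clusters


def annotate_split_support(
    clusters: list[LinkCluster], clips: list[ClipEvent]
) -> None:
    """Count clip events falling inside each cluster's two intervals."""
    for c in clusters:
        n = 0
        for ev in clips:
            if (
                ev.contig == c.contig_a
                and c.interval_a[0] <= ev.boundary_pos <= c.interval_a[1]
            ) or (
                ev.contig == c.contig_b
                and c.interval_b[0] <= ev.boundary_pos <= c.interval_b[1]
            ):
                n += 1
        c.split_support = n


def scan_depth_duplications(
    profile: "DepthProfile", threshold: float = 1.5
) -> list[DepthDuplicationCall]:
    """Merge runs of bins at >= threshold x genome mean into DUP calls.

    rc = mean depth over the run / genome mean; calls sorted by rc
    descending (ties by coordinate).
    """
    from .depth import DepthProfile  # noqa: F401  (type only)

    if profile.genome_mean <= 0:
        raise ValueError("genome-wide mean depth is zero")
    cut = threshold * profile.genome_mean
    calls = []
    for contig, (start0, depths) in profile.bins.items():
        above = depths >= cut
        i = 0
        n = len(depths)
        while i < n:
            if above[i]:
                j = i
                while j + 1 < n and above[j + 1]:
                    j += 1
                run = depths[i: j + 1]
                calls.append(
                    DepthDuplicationCall(
                        contig,
                        start0 + i * profile.bin_width,
                        start0 + (j + 1) * profile.bin_width - 1,
                        float(np.mean(run)) / profile.genome_mean,
                    )
                )
                i = j + 1
            else:
                i += 1
    calls.sort(key=lambda c: (-c.rc, c.contig, c.start))
    return calls


def _is_adjacent(c: LinkCluster, other: LinkCluster, window: int) -> bool:
    for ctg, iv in ((c.contig_a, c.interval_a), (c.contig_b, c.interval_b)):
        mid = (iv[0] + iv[1]) // 2
        for octg, oiv in (
            (other.contig_a, other.interval_a),
            (other.contig_b, other.interval_b),
        ):
            if octg == ctg and abs((oiv[0] + oiv[1]) // 2 - mid) <= window:
                return True
    return False


def apply_filters(
    clusters: list[LinkCluster], cfg: FilterConfig
) -> tuple[list[LinkCluster], list[Rejection]]:
    """Apply the codified manual-review rules; keep a rejection log.

    Two phases: support bounds, excluded contigs and intra-chromosomal
    links first; then adjacency crowding evaluated among the survivors
    only (the review the rule codifies was performed on an
    already-filtered candidate list, so links that fail the basic rules
    do not count as "adjacent rearrangements").
    """
    cfg.validate()
    survivors = []
    rejections = []
    for c in clusters:
        if c.support < cfg.min_support:
            rejections.append(Rejection(c, f"support<{cfg.min_support}"))
            continue
        if c.support > cfg.max_support:
            rejections.append(Rejection(c, f"support>{cfg.max_support}"))
            continue
        if c.contig_a in cfg.excluded_contigs or c.contig_b in cfg.excluded_contigs:
            rejections.append(Rejection(c, "excluded_contig"))
            continue
        if cfg.drop_intra_chrom and c.contig_a == c.contig_b:
            rejections.append(Rejection(c, "intra_chromosomal"))
            continue
        survivors.append(c)

    if not cfg.drop_adjacent:
        return survivors, rejections
    kept = []
    for c in survivors:
        n_adj = sum(
            1
            for other in survivors
            if other is not c and _is_adjacent(c, other, cfg.adjacent_window)
        )
        if n_adj >= cfg.adjacent_n:
            rejections.append(Rejection(c, "adjacent_rearrangements"))
        else:
            kept.append(c)
    return kept, rejections


def _bridged(cluster: LinkCluster, calls: list[DepthDuplicationCall],
             proximity: int = 10_000) -> bool:
    for call in calls:
        if call.contig == cluster.contig_b and _footprints_close(
            cluster.interval_b, (call.start, call.end), proximity
        ):
            return True
    return False


def rank_candidates(
    clusters: list[LinkCluster], calls: list[DepthDuplicationCall]
) -> list[LinkCluster]:
    """Deterministic total order on filtered candidates.

    Primary: split-read support (desc); secondary: cassette-side proximity
    to a depth-duplication call (bridged first); tertiary: pair support
    (desc); ties broken by coordinates ascending.
    """
    return sorted(
        clusters,
        key=lambda c: (
            -c.split_support,
            0 if _bridged(c, calls) else 1,
            -c.support,
            c.sort_key,
        ),
    )
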