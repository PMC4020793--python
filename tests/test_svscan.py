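import itertools

import numpy as np
import pytest

from tgmap.depth import DepthProfile
from tgmap.pairs import AlignmentRecord, ClipEvent
from tgmap.svscan import (
    DepthDuplicationCall,
    DiscordantPair,
    FilterConfig,
    LinkCluster,
    _footprints_close,
    annotate_split_support,
    apply_filters,
    cluster_discordant_pairs,
    rank_candidates,
    scan_depth_duplications,
)


def _dpair(rid, ca, pa, cb, pb, mapq=60, span=101):
    a = AlignmentRecord(rid, ca, pa, "+", mapq, span, mate=1)
    b = AlignmentRecord(rid, cb, pb, "-", mapq, span, mate=2)
    return DiscordantPair(a, b)


def _cluster(ca="c1", ia=(1000, 1400), cb="c2", ib=(5000, 5400), support=8,
             split=0, mapq=60.0):
    return LinkCluster(ca, ia, cb, ib, support, mapq, split)


class TestClustering:
    def test_eight_pairs_one_link(self):
        pairs = [
            _dpair(f"r{i}", "chr2", 1000 + 40 * i, "chr6", 5000 + 40 * i)
            for i in range(8)
        ]
        (c,) = cluster_discordant_pairs(pairs, window=400)
        assert c.support == 8
        assert c.contig_a == "chr2" and c.contig_b == "chr6"
        assert c.interval_a[0] == 1000 and c.interval_a[1] == 1000 + 280 + 100

    def test_five_pairs_second_contig_pair(self):
        pairs = [
            _dpair(f"r{i}", "chr2", 2000 + 10 * i, "chr14", 7000) for i in range(5)
        ]
        (c,) = cluster_discordant_pairs(pairs, window=400)
        assert c.support == 5

    def test_distant_pairs_split(self):
        pairs = [
            _dpair("r0", "c1", 1000, "c2", 5000),
            _dpair("r1", "c1", 1000 + 4000, "c2", 5000),
        ]
        assert len(cluster_discordant_pairs(pairs, window=400)) == 2

    def test_members_partition_input(self):
        rng = np.random.default_rng(7)
        pairs = [
            _dpair(f"r{i}", "c1", int(rng.integers(1, 20000)),
                   "c2", int(rng.integers(1, 20000)))
            for i in range(40)
        ]
        clusters = cluster_discordant_pairs(pairs, window=500)
        members = [p.a.read_id for c in clusters for p in c.members]
        assert sorted(members) == sorted(p.a.read_id for p in pairs)

    def test_equivalence_with_brute_force_single_linkage(self):
        """Union-find clustering equals O(n^2) transitive closure."""
        rng = np.random.default_rng(42)
        for trial in range(10):
            n = int(rng.integers(2, 50))
            pairs = [
                _dpair(
                    f"t{trial}r{i}",
                    rng.choice(["c1", "c2"]),
                    int(rng.integers(1, 8000)),
                    rng.choice(["c3", "c4"]),
                    int(rng.integers(1, 8000)),
                )
                for i in range(n)
            ]
            window = 400

            def linked(p, q):
                return (
                    p.key == q.key
                    and _footprints_close((p.a.pos, p.a.end), (q.a.pos, q.a.end), window)
                    and _footprints_close((p.b.pos, p.b.end), (q.b.pos, q.b.end), window)
                )

            # brute-force transitive closure
            groups = [{i} for i in range(n)]
            changed = True
            while changed:
                changed = False
                for gi, gj in itertools.combinations(range(len(groups)), 2):
                    if any(
                        linked(pairs[i], pairs[j])
                        for i in groups[gi]
                        for j in groups[gj]
                    ):
                        groups[gi] |= groups[gj]
                        del groups[gj]
                        changed = True
                        break
            expected = {
                frozenset(pairs[i].a.read_id for i in g) for g in groups
            }
            got = {
                frozenset(p.a.read_id for p in c.members)
                for c in cluster_discordant_pairs(pairs, window)
            }
            assert got == expected

    def test_split_support_counts_clips_in_intervals(self):
        c = _cluster(ia=(1000, 1400), ib=(5000, 5400))
        clips = [
            ClipEvent("c1", 1200, "right", "A" * 20, 60),
            ClipEvent("c2", 5100, "left", "C" * 20, 60),
            ClipEvent("c1", 9999, "right", "G" * 20, 60),
        ]
        annotate_split_support([c], clips)
        assert c.split_support == 2


class TestDepthDuplications:
    def _profile(self, depths, bin_width=500, gm=None):
        arr = np.asarray(depths, dtype=float)
        p = DepthProfile(bin_width, {"c1": (1, arr)})
        p.genome_mean = float(np.median(arr)) if gm is None else gm
        return p

    def test_uniform_depth_yields_no_calls(self):
        assert scan_depth_duplications(self._profile([8.0] * 50)) == []

    def test_sixteen_fold_plateau(self):
        depths = [8.0] * 10 + [128.0] * 6 + [8.0] * 10
        (call,) = scan_depth_duplications(self._profile(depths, gm=8.0))
        assert call.rc == pytest.approx(16.0)
        assert call.start == 1 + 10 * 500
        assert call.end == 1 + 16 * 500 - 1

    def test_boundaries_match_run_length_oracle(self):
        rng = np.random.default_rng(3)
        depths = rng.choice([4.0, 8.0, 30.0], size=80)
        profile = self._profile(depths, gm=8.0)
        calls = scan_depth_duplications(profile, threshold=1.5)
        # oracle: explicit run-length scan at the same cut
        runs = []
        i = 0
        while i < 80:
            if depths[i] >= 12.0:
                j = i
                while j + 1 < 80 and depths[j + 1] >= 12.0:
                    j += 1
                runs.append((i, j))
                i = j + 1
            else:
                i += 1
        assert len(calls) == len(runs)
        got = sorted((c.start, c.end) for c in calls)
        expected = sorted((1 + i * 500, 1 + (j + 1) * 500 - 1) for i, j in runs)
        assert got == expected

    def test_zero_coverage_errors(self):
        with pytest.raises(ValueError, match="zero"):
            scan_depth_duplications(self._profile([0.0] * 10, gm=0.0))


class TestFilters:
    @pytest.mark.parametrize(
        "support,reason", [(4, "support<5"), (17, "support>16")]
    )
    def test_support_bounds_mirror_manual_rule(self, support, reason):
        kept, rej = apply_filters([_cluster(support=support)], FilterConfig())
        assert kept == []
        assert rej[0].reason == reason

    def test_support_bounds_inclusive(self):
        for s in (5, 16):
            kept, _ = apply_filters([_cluster(support=s)], FilterConfig())
            assert len(kept) == 1

    def test_excluded_contig_rejected(self):
        cfg = FilterConfig(excluded_contigs=frozenset({"chrM"}))
        kept, rej = apply_filters([_cluster(ca="chrM")], cfg)
        assert kept == [] and rej[0].reason == "excluded_contig"

    def test_intra_chromosomal_rejected(self):
        kept, rej = apply_filters([_cluster(cb="c1")], FilterConfig())
        assert kept == [] and rej[0].reason == "intra_chromosomal"

    def test_adjacent_crowding(self):
        clusters = [
            _cluster(ia=(1000 + 100 * i, 1100 + 100 * i), cb=f"x{i}")
            for i in range(4)
        ]
        kept, rej = apply_filters(clusters, FilterConfig())
        assert kept == []
        assert all(r.reason == "adjacent_rearrangements" for r in rej)
        # far apart: all kept
        spread = [
            _cluster(ia=(1000 + 50_000 * i, 1100 + 50_000 * i), cb=f"x{i}")
            for i in range(4)
        ]
        kept, _ = apply_filters(spread, FilterConfig())
        assert len(kept) == 4

    def test_invalid_bounds_raise(self):
        with pytest.raises(ValueError):
            apply_filters([], FilterConfig(min_support=10, max_support=5))

    def test_tightening_bounds_is_monotone(self):
        rng = np.random.default_rng(11)
        clusters = [
            _cluster(
                ia=(int(p), int(p) + 100),
                cb=f"c{i}",
                support=int(rng.integers(1, 25)),
            )
            for i, p in enumerate(rng.integers(1, 10**6, size=30))
        ]
        kept_wide, _ = apply_filters(
            clusters, FilterConfig(min_support=3, max_support=20)
        )
        kept_narrow, _ = apply_filters(
            clusters, FilterConfig(min_support=5, max_support=16)
        )
        assert set(id(c) for c in kept_narrow) <= set(id(c) for c in kept_wide)


class TestRanking:
    def test_split_and_bridged_outrank(self):
        dup = [DepthDuplicationCall("c2", 5000, 7000, 16.0)]
        strong = _cluster(split=5)
        weak = _cluster(ia=(90_000, 90_400), cb="c9", split=0)
        assert rank_candidates([weak, strong], dup)[0] is strong

    def test_tie_broken_by_coordinates(self):
        c_late = _cluster(ia=(2000, 2400))
        c_early = _cluster(ia=(1000, 1400))
        ranked = rank_candidates([c_late, c_early], [])
        assert ranked[0] is c_early

    def test_order_matches_exhaustive_key_oracle(self):
        dup = [DepthDuplicationCall("c2", 5000, 7000, 16.0)]
        a = _cluster(split=3, support=8)                      # split+bridged
        b = _cluster(ia=(1, 400), cb="c9", split=3, support=10)  # split only
        c = _cluster(ia=(10, 410), split=0, support=12)       # bridged only
        cands = [c, b, a]

        def key(cl):
            bridged = any(
                d.contig == cl.contig_b
                and _footprints_close(cl.interval_b, (d.start, d.end), 10_000)
                for d in dup
            )
            return (-cl.split_support, 0 if bridged else 1, -cl.support, cl.sort_key)

        expected = sorted(cands, key=key)
        assert rank_candidates(cands, dup) == expected
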