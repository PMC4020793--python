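import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tgmap.breakpoints import (
    assemble_insertion_call,
    BoundaryCall,
    compute_microhomology,
    consensus_from_clips,
    resolve_boundary,
)
from tgmap.locus import random_seq, revcomp
from tgmap.pairs import ClipEvent

dna = st.text(alphabet="ACGT", min_size=0, max_size=60)


class TestMicrohomology:
    @pytest.mark.parametrize(
        "flank,cassette,side,expected",
        [
            ("TTTTTCCAGCAG", "CCAGCAGTTTTT", "left", ("CCAGCAG", 7)),
            ("TGGATGCGCA", "AAAAATGGAT", "right", ("TGGAT", 5)),
            ("AAAA", "CCCC", "left", ("", 0)),
            ("AAAA", "CCCC", "right", ("", 0)),
        ],
    )
    def test_printed_motifs_and_null_case(self, flank, cassette, side, expected):
        assert compute_microhomology(flank, cassette, side) == expected

    def test_agrees_with_quadratic_oracle_on_random_cases(self):
        """1000 random cases against an all-prefix/suffix character scan."""
        rng = np.random.default_rng(99)

        def oracle_left(f, c, cap):
            best = 0
            for k in range(1, min(cap, len(f), len(c)) + 1):
                if all(f[len(f) - k + i] == c[i] for i in range(k)):
                    best = k
            return best

        for _ in range(1000):
            f = random_seq(rng, int(rng.integers(0, 30)))
            c = random_seq(rng, int(rng.integers(0, 30)))
            # bias towards shared junction content half the time
            if rng.random() < 0.5 and f:
                c = f[-int(rng.integers(1, len(f) + 1)):] + c
            seq, n = compute_microhomology(f, c, "left", max_len=25)
            assert n == oracle_left(f, c, 25)
            assert seq == (f[-n:] if n else "")

    @given(flank=dna, cassette=dna, side=st.sampled_from(["left", "right"]))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_reverse_complement_mirror_symmetry(self, flank, cassette, side):
        """rc-ing both sequences and swapping the side preserves the
        microhomology (up to rc of the string itself)."""
        seq, n = compute_microhomology(flank, cassette, side)
        other = "right" if side == "left" else "left"
        seq2, n2 = compute_microhomology(revcomp(flank), revcomp(cassette), other)
        assert n2 == n
        assert seq2 == revcomp(seq)

    def test_cap_at_max_len(self):
        s = "A" * 80
        _, n = compute_microhomology(s, s, "left", max_len=50)
        assert n == 50


class TestConsensus:
    def test_majority_with_truncation_at_dissent(self):
        seqs = ["ACGTAA", "ACGTCC", "ACGG"]
        # columns: A,C,G agree; column 4 T/T/G majority T; column 5 A/C split
        assert consensus_from_clips(seqs, "left") == "ACGT"

    def test_right_anchor_mirrors(self):
        seqs = ["AACGT", "ACGT", "TTTACGT"]
        assert consensus_from_clips(seqs, "right").endswith("ACGT")


class TestResolveBoundary:
    def _clips(self, positions, side="right", seq="CCAGCAGAAAA"):
        return [
            ClipEvent("chr2", p, side, seq, 60, f"r{i}")
            for i, p in enumerate(positions)
        ]

    def test_mode_with_tie_to_smaller_coordinate(self):
        call = resolve_boundary(self._clips([100, 100, 101]), "left")
        assert call.coordinate == 100
        call = resolve_boundary(self._clips([100, 101, 101, 100]), "left")
        assert call.coordinate == 100

    def test_partner_from_consensus_match(self):
        ends = {
            "beta": {"start": "CCAGCAGAAAATTTT", "end": "X" * 15},
            "alpha": {"start": "GGGGGGGGGG", "end": "Y" * 10},
        }
        call = resolve_boundary(
            self._clips([500, 500]), "left", cassette_end_seqs=ends
        )
        assert call.partner_cassette == "beta"
        assert call.exact

    def test_consensus_mismatch_flags_approximate(self):
        ends = {"beta": {"start": "GGGGGGGGGGGGGG", "end": ""}}
        call = resolve_boundary(
            self._clips([500]), "left", cassette_end_seqs=ends
        )
        assert call.partner_cassette is None
        assert not call.exact

    def test_no_clips_falls_back_to_interval_midpoint(self):
        call = resolve_boundary(
            [], "left", fallback_interval=("chr2", 100, 300),
            fallback_partner="beta", n_discordant=7,
        )
        assert not call.exact
        assert call.coordinate == 200
        assert call.partner_cassette == "beta"
        assert call.n_discordant == 7

    def test_no_clips_no_fallback_raises(self):
        with pytest.raises(ValueError):
            resolve_boundary([], "left")


class TestAssemble:
    def _bc(self, coord, side, contig="chr2"):
        return BoundaryCall(contig, coord, side, "beta", 8, 4, "")

    def test_printed_boundary_arithmetic(self):
        call = assemble_insertion_call(
            self._bc(68_208_872, "left"), self._bc(68_209_029, "right")
        )
        assert call.deletion_length == 157
        assert call.status == "exact"

    def test_equal_coordinates_zero_deletion(self):
        call = assemble_insertion_call(self._bc(500, "left"), self._bc(500, "right"))
        assert call.deletion_length == 0

    def test_cross_contig_boundaries_rejected(self):
        with pytest.raises(ValueError, match="different contigs"):
            assemble_insertion_call(
                self._bc(100, "left"), self._bc(200, "right", contig="chr7")
            )

    def test_microhomology_against_cassette_ends(self):
        ends = {"beta": {"start": "CCAGCAGTTTT", "end": ""},
                "alpha": {"start": "", "end": "AAAATGGAT"}}
        left = BoundaryCall("chr2", 1000, "left", "beta", 8, 4, "")
        right = BoundaryCall("chr2", 1157, "right", "alpha", 5, 1, "")
        call = assemble_insertion_call(
            left, right, flank_seqs=("GGGGGCCAGCAG", "TGGATGGGGG"),
            cassette_end_seqs=ends,
        )
        assert call.left_microhomology == ("CCAGCAG", 7)
        assert call.right_microhomology == ("TGGAT", 5)


class TestSyntheticRecovery:
    def test_default_run_recovers_truth_field_for_field(self, fitted, genome):
        call = fitted.insertion_call
        spec = genome.truth
        assert call is not None and call.status == "exact"
        assert call.contig == "chr2"
        assert call.left.coordinate == spec.left_boundary == 68_208_872
        assert call.right.coordinate == spec.right_boundary == 68_209_029
        assert call.deletion_length == spec.deletion_length == 157
        assert call.left.partner_cassette == "beta"
        assert call.right.partner_cassette == "alpha"
        assert call.left_microhomology == ("CCAGCAG", 7)
        assert call.right_microhomology == ("TGGAT", 5)
        assert call.left.n_softclip >= 1 and call.right.n_softclip >= 1

    def test_error_free_multiseed_recovery(self, multiseed_clean_runs, genome):
        """Across 20 seeds at zero error rate: every produced call is exact
        and coordinate-perfect, calls are produced in >= 95% of seeds, and
        deletion-length recovery is unbiased."""
        spec = genome.truth
        produced = 0
        errors = []
        for seed, res in multiseed_clean_runs:
            call = res.insertion_call
            if call is None:
                continue
            produced += 1
            assert call.status == "exact", f"seed {seed} not exact"
            assert call.left.coordinate == spec.left_boundary, f"seed {seed}"
            assert call.right.coordinate == spec.right_boundary, f"seed {seed}"
            errors.append(call.deletion_length - spec.deletion_length)
        assert produced >= 19
        assert np.mean(errors) == 0
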