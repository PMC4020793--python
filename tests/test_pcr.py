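import numpy as np
import pytest

from tgmap.locus import random_seq, revcomp
from tgmap.pcr import (
    Assay,
    DesignConstraints,
    Primer,
    PrimerDesignError,
    PMEL1_ASSAY_PRIMERS,
    call_zygosity,
    design_primers,
    find_primer_sites,
    genotype_alleles,
    predict_amplicons,
)


class TestPrimer:
    def test_wallace_tm(self):
        # 2(A+T) + 4(G+C)
        p = Primer("p", "ATATATATATGCGCGCGCGC")
        assert p.tm == 2 * 10 + 4 * 10

    def test_validation(self):
        with pytest.raises(ValueError):
            Primer("short", "ACGTACGT")
        with pytest.raises(ValueError):
            Primer("bad", "ACGTNACGTNACGTNACGT")

    def test_pmel1_assay_primer_sequences_are_wellformed(self):
        for name, seq in PMEL1_ASSAY_PRIMERS.items():
            p = Primer(name, seq)
            assert 15 <= len(p.seq) <= 35


class TestFindSites:
    def test_forward_and_reverse_occurrences(self, rng):
        p = Primer("p", "ACGTACGTACGTACGTAC")
        template = random_seq(rng, 200) + p.seq + random_seq(rng, 200)
        sites = find_primer_sites(template, p)
        assert (201, "+") in sites
        template_rc = random_seq(rng, 100) + revcomp(p.seq) + random_seq(rng, 100)
        sites = find_primer_sites(template_rc, p)
        assert (101, "-") in sites

    def test_three_prime_terminal_bases_must_match(self, rng):
        p = Primer("p", "ACGTACGTACGTACGTAC")
        mutated = p.seq[:-1] + ("G" if p.seq[-1] != "G" else "T")
        template = random_seq(rng, 50) + mutated + random_seq(rng, 50)
        # a 3'-terminal mismatch is never tolerated, even with allowance
        assert (51, "+") not in find_primer_sites(template, p, max_mismatch=2)
        # an internal mismatch is tolerated within the allowance
        internal = p.seq[:5] + ("G" if p.seq[5] != "G" else "T") + p.seq[6:]
        template = random_seq(rng, 50) + internal + random_seq(rng, 50)
        assert (51, "+") in find_primer_sites(template, p, max_mismatch=1)

    def test_matches_brute_force_scan_on_random_template(self, rng):
        template = random_seq(rng, 10_000)
        p = Primer("p", template[5000:5022])

        def brute(t, probe):
            hits = []
            for i in range(len(t) - len(probe) + 1):
                if all(t[i + j] == probe[j] for j in range(len(probe))):
                    hits.append(i + 1)
            return hits

        sites = find_primer_sites(template, p)
        assert [pos for pos, s in sites if s == "+"] == brute(template, p.seq)
        assert [pos for pos, s in sites if s == "-"] == brute(
            template, revcomp(p.seq)
        )


class TestPredictAmplicons:
    def test_constructed_geometry_yields_203(self, rng):
        f = Primer("F", random_seq(rng, 23))
        r = Primer("R", random_seq(rng, 25))
        # F occupies template[10:33] (pos 11); reverse site's 5' base at 213
        template = (
            random_seq(rng, 10)
            + f.seq
            + random_seq(rng, 213 - 33 - 25)
            + revcomp(r.seq)
            + random_seq(rng, 300)
        )
        preds = [
            p for p in predict_amplicons(template, [f, r])
            if (p.forward_primer, p.reverse_primer) == ("F", "R")
        ]
        assert len(preds) == 1
        assert preds[0].start == 11 and preds[0].end == 213
        assert preds[0].length == 203

    def test_no_reverse_site_no_product(self, rng):
        f = Primer("F", random_seq(rng, 20))
        template = random_seq(rng, 100) + f.seq + random_seq(rng, 400)
        assert predict_amplicons(template, [f]) == []

    def test_length_invariant_under_template_shift(self, rng):
        f = Primer("F", random_seq(rng, 20))
        r = Primer("R", random_seq(rng, 20))
        core = f.seq + random_seq(rng, 150) + revcomp(r.seq)
        t1 = random_seq(rng, 30) + core + random_seq(rng, 30)
        t2 = random_seq(rng, 1000) + t1
        l1 = {p.length for p in predict_amplicons(t1, [f, r])}
        l2 = {p.length for p in predict_amplicons(t2, [f, r])}
        assert l1 == l2

    def test_products_beyond_max_len_dropped(self, rng):
        f = Primer("F", random_seq(rng, 20))
        r = Primer("R", random_seq(rng, 20))
        template = f.seq + random_seq(rng, 4000) + revcomp(r.seq)
        assert predict_amplicons(template, [f, r], max_len=3000) == []


class TestZygosityCalls:
    @pytest.fixture()
    def assay(self):
        return Assay(
            Primer("F", "A" * 20), Primer("Rwt", "C" * 20), Primer("Rtg", "G" * 20),
            endogenous_band=203, transgenic_band=308,
        )

    def _preds(self, lengths):
        from tgmap.pcr import AmpliconPrediction

        return [AmpliconPrediction("t", "F", "R", 1, n) for n in lengths]

    @pytest.mark.parametrize(
        "bands,call",
        [
            ([308], "homozygous"),
            ([203, 308], "heterozygous"),
            ([203], "wildtype"),
            ([], "uninterpretable"),
            ([308, 550], "uninterpretable"),
        ],
    )
    def test_band_pattern_mapping(self, assay, bands, call):
        assert call_zygosity(assay, self._preds(bands)).call == call


class TestDesign:
    def test_design_round_trip_on_fitted_model(self, fitted):
        assay = fitted.design_genotyping_assay()
        assert abs(assay.transgenic_band - assay.endogenous_band) >= 30
        for genotype, expected in (
            ("hom", "homozygous"), ("het", "heterozygous"), ("wt", "wildtype")
        ):
            assert fitted.genotype(assay, genotype).call == expected

    def test_short_flank_rejected(self, fitted):
        call = fitted.insertion_call
        with pytest.raises(PrimerDesignError, match="flank"):
            design_primers(call, "ACGT" * 100, "ACGT" * 200, call.left.coordinate - 200)

    def test_empty_tm_window_rejected(self, fitted):
        with pytest.raises(PrimerDesignError, match="Tm"):
            fitted.design_genotyping_assay(
                constraints=DesignConstraints(tm_min=70, tm_max=60)
            )
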