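"""In-silico PCR: primer-site finding, amplicon prediction, zygosity calls
and three-primer assay design.

The zygosity assay uses one forward primer upstream of the left insertion
boundary (binding both alleles), one reverse primer whose site lies in the
sequence deleted by the insertion (wild-type allele only) and one reverse
primer in the junction-proximal cassette sequence (transgenic allele only).
Band patterns then map directly to genotype: transgenic band only ->
homozygous, endogenous band only -> wild type, both -> heterozygous.
Product length follows the gel convention: inclusive span from the forward
primer's 5' base to the reverse primer's 5' base.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .breakpoints import InsertionCall
from .locus import revcomp

# genotyping primers of the validated pmel-1 TCR-transgene zygosity assay
# (308-bp transgenic band, 203-bp endogenous band on mm9 chr2)
PMEL1_ASSAY_PRIMERS = {
    "Ch2Pmel-F1": "CTTTAGACCTCCGGCACTGTTGC",
    "Ch2Pmel-R1": "GCAAGTAGCAGTGTATCAAATATGC",
    "PmelTCR-R1": "GTAGCTTTGTAAGGCTGTGGAGAG",
}


@dataclass
class Primer:
    name: str
    seq: str

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if not (15 <= len(self.seq) <= 35):
            raise ValueError(f"primer {self.name}: length must be 15-35 nt")
        if set(self.seq) - set("ACGT"):
            raise ValueError(f"primer {self.name}: non-ACGT characters")

    @property
    def tm(self) -> float:
        """Wallace-rule melting temperature, 2(A+T) + 4(G+C)."""
        gc = sum(self.seq.count(b) for b in "GC")
        return 2.0 * (len(self.seq) - gc) + 4.0 * gc


@dataclass
class AmpliconPrediction:
    template_name: str
    forward_primer: str
    reverse_primer: str
    start: int   # 1-based position of the forward primer's 5' base
    end: int     # 1-based position of the reverse primer's 5' base
    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class GenotypeCall:
    bands: frozenset[int]
    call: str  # homozygous | heterozygous | wildtype | uninterpretable


@dataclass
class Assay:
    """A designed three-primer zygosity assay."""

    forward: Primer
    reverse_endogenous: Primer
    reverse_transgenic: Primer
    endogenous_band: int
    transgenic_band: int
    max_product: int = 1000

    @property
    def primers(self) -> list[Primer]:
        return [self.forward, self.reverse_endogenous, self.reverse_transgenic]


class PrimerDesignError(ValueError):
    pass


def _matches(template: str, probe: str, pos: int, max_mismatch: int) -> bool:
    """probe vs template[pos:pos+len], 3'-terminal 3 bases always exact."""
    mm = 0
    n = len(probe)
    for i in range(n):
        if template[pos + i] != probe[i]:
            if i >= n - 3:
                return False
            mm += 1
            if mm > max_mismatch:
                return False
    return True


def find_primer_sites(
    template: str, p: Primer, max_mismatch: int = 0
) -> list[tuple[int, str]]:
    """(1-based position, strand) of all binding sites of ``p``.

    '+' sites are occurrences of the primer itself; '-' sites are
    occurrences of its reverse complement (position of the site's leftmost
    template base).  With mismatches allowed, the 3 bases at the primer's
    3' end must still match exactly.
    """
    template = template.upper()
    sites = []
    for strand, probe in (("+", p.seq), ("-", revcomp(p.seq))):
        n = len(probe)
        if max_mismatch == 0:
            i = template.find(probe)
            while i != -1:
                sites.append((i + 1, strand))
                i = template.find(probe, i + 1)
        else:
            probe_chk = probe if strand == "+" else probe  # scanned as-is
            for i in range(len(template) - n + 1):
                if strand == "+":
                    if _matches(template, probe_chk, i, max_mismatch):
                        sites.append((i + 1, strand))
                else:
                    # 3' end of a minus-strand primer is the site's left edge
                    seg = template[i: i + n]
                    mm = sum(1 for a, b in zip(seg, probe) if a != b)
                    three_prime_ok = seg[:3] == probe[:3]
                    if mm <= max_mismatch and three_prime_ok:
                        sites.append((i + 1, strand))
    sites.sort(key=lambda s: (s[0], s[1]))
    return sites


def predict_amplicons(
    template: str,
    primers: list[Primer],
    template_name: str = "template",
    max_len: int = 3000,
    max_mismatch: int = 0,
) -> list[AmpliconPrediction]:
    """All products of any (+ site, downstream - site) primer pairing.

    Product length is measured 5' end to 5' end inclusive; products longer
    than ``max_len`` are dropped (assumed not to amplify).
    """
    plus, minus = [], []
    for p in primers:
        for pos, strand in find_primer_sites(template, p, max_mismatch):
            if strand == "+":
                plus.append((pos, p))
            else:
                minus.append((pos, p))
    out = []
    for fpos, fp in plus:
        for rpos, rp in minus:
            r5 = rpos + len(rp.seq) - 1   # 5' base of the reverse primer
            if r5 <= fpos:
                continue
            if rpos < fpos + len(fp.seq):
                continue  # overlapping sites cannot form a product
            length = r5 - fpos + 1
            if length > max_len:
                continue
            out.append(AmpliconPrediction(template_name, fp.name, rp.name, fpos, r5))
    out.sort(key=lambda a: (a.start, a.end))
    return out


def call_zygosity(
    assay: Assay, predictions: list[AmpliconPrediction], tol: int = 0
) -> GenotypeCall:
    """Map a band pattern to a genotype.

    ``predictions`` are the pooled amplicons over the genotype's allele
    set.  Transgenic band only -> homozygous; endogenous band only ->
    wildtype; both -> heterozygous; anything else -> uninterpretable.
    """
    bands = frozenset(p.length for p in predictions)

    def has(size: int) -> bool:
        return any(abs(b - size) <= tol for b in bands)

    tg = has(assay.transgenic_band)
    en = has(assay.endogenous_band)
    extra = [
        b for b in bands
        if abs(b - assay.transgenic_band) > tol
        and abs(b - assay.endogenous_band) > tol
    ]
    if extra:
        call = "uninterpretable"
    elif tg and en:
        call = "heterozygous"
    elif tg:
        call = "homozygous"
    elif en:
        call = "wildtype"
    else:
        call = "uninterpretable"
    return GenotypeCall(bands, call)


@dataclass
class DesignConstraints:
    min_len: int = 18
    max_len: int = 27
    tm_min: float = 55.0
    tm_max: float = 65.0
    min_band_gap: int = 30
    max_product: int = 1000
    min_product: int = 120


def _candidate_windows(seq: str, cons: DesignConstraints) -> list[tuple[int, str]]:
    """(0-based start, subseq) windows meeting length+Tm constraints."""
    out = []
    for n in range(cons.min_len, cons.max_len + 1):
        for i in range(0, len(seq) - n + 1):
            sub = seq[i: i + n]
            if set(sub) - set("ACGT"):
                continue
            gc = sum(sub.count(b) for b in "GC")
            tm = 2.0 * (n - gc) + 4.0 * gc
            if cons.tm_min <= tm <= cons.tm_max:
                out.append((i, sub))
    return out


def _unique_in_all(primer: Primer, templates: dict[str, str]) -> bool:
    for t in templates.values():
        if len(find_primer_sites(t, primer)) > 1:
            return False
    return True


def design_primers(
    call: InsertionCall,
    wildtype_seq: str,
    junction_seq: str,
    wildtype_offset: int,
    templates: dict[str, str] | None = None,
    constraints: DesignConstraints | None = None,
) -> Assay:
    """Design the three-primer zygosity assay from a resolved insertion.

    Parameters
    ----------
    wildtype_seq : str
        Wild-type sequence spanning the insertion site (>= 400 bp on each
        side of the deleted segment); position ``i`` (1-based) corresponds
        to reported coordinate ``wildtype_offset + i``.
    junction_seq : str
        Transgenic-allele sequence starting at the left boundary's first
        cassette base and extending >= 400 bp into the array.
    templates : dict
        name -> full allele sequence; every primer must bind each template
        at most once and predicted products must reproduce the expected
        band pattern per allele.
    """
    cons = constraints or DesignConstraints()
    if cons.tm_min > cons.tm_max:
        raise PrimerDesignError("empty Tm window")
    left_b = call.left.coordinate - wildtype_offset     # 1-based in wildtype_seq
    right_b = call.right.coordinate - wildtype_offset
    if left_b < 400:
        raise PrimerDesignError(
            "left flank shorter than 400 bp upstream of the boundary"
        )
    if len(wildtype_seq) - right_b + 1 < 400:
        raise PrimerDesignError(
            "right flank shorter than 400 bp downstream of the boundary"
        )
    if len(junction_seq) < 400:
        raise PrimerDesignError("junction sequence shorter than 400 bp")
    templates = templates or {}

    # forward candidates: left flank, 3' end 30-250 bp upstream of the boundary
    fw_region_start = max(0, left_b - 280)
    fw_seq = wildtype_seq[fw_region_start: left_b - 30]
    fw_cands = []
    for i, sub in _candidate_windows(fw_seq, cons):
        p = Primer("insF", sub)
        if _unique_in_all(p, templates):
            fw_cands.append((fw_region_start + i, p))  # 0-based on wildtype_seq
    if not fw_cands:
        raise PrimerDesignError(
            "no unique forward primer in the left flank satisfied the "
            "length/Tm constraints"
        )

    # endogenous reverse candidates: inside the deleted segment (preferred),
    # else just downstream of the right boundary
    del_seq = wildtype_seq[left_b: right_b - 1]
    rev_regions = [(left_b, del_seq)]
    rev_regions.append((right_b - 1, wildtype_seq[right_b - 1: right_b - 1 + 400]))
    rev_en_cands = []
    for base0, region in rev_regions:
        for i, sub in _candidate_windows(region, cons):
            p = Primer("wtR", revcomp(sub))
            if _unique_in_all(p, templates):
                # 5' base of the reverse primer = rightmost base of the window
                rev_en_cands.append((base0 + i + len(sub) - 1, p))

    # transgenic reverse candidates: junction-proximal cassette sequence.
    # The site necessarily recurs once per tandem-array copy on the
    # transgenic allele; those repeats sit >= one unit length downstream and
    # fall above max_product, so uniqueness is only demanded off-array
    # (wild-type template).
    wt_only = {k: v for k, v in templates.items() if "tg" not in k}
    rev_tg_cands = []
    tg_scan = junction_seq[: min(len(junction_seq), cons.max_product)]
    for i, sub in _candidate_windows(tg_scan, cons):
        p = Primer("tgR", revcomp(sub))
        if _unique_in_all(p, wt_only):
            rev_tg_cands.append((i + len(sub) - 1, p))  # 0-based in junction_seq

    if not rev_en_cands:
        raise PrimerDesignError(
            "no unique endogenous reverse primer satisfied the constraints"
        )
    if not rev_tg_cands:
        raise PrimerDesignError(
            "no unique junction reverse primer satisfied the constraints"
        )

    # deterministic search order; caps keep the combinatorial search small
    fw_cands = fw_cands[:40]
    rev_en_cands = rev_en_cands[:40]
    rev_tg_cands = rev_tg_cands[:40]
    for f0, fp in fw_cands:
        for e5, ep in rev_en_cands:
            band_en = e5 - f0 + 1  # inclusive 5'-to-5' span on wild-type allele
            if not (cons.min_product <= band_en <= cons.max_product):
                continue
            for t5, tp in rev_tg_cands:
                # transgenic product: flank part up to left boundary plus
                # cassette part (position within junction_seq, 1-based t5+1)
                band_tg = (left_b - f0) + (t5 + 1)
                if not (cons.min_product <= band_tg <= cons.max_product):
                    continue
                if abs(band_tg - band_en) < cons.min_band_gap:
                    continue
                assay = Assay(
                    Primer("insF", fp.seq),
                    Primer("wtR", ep.seq),
                    Primer("tgR", tp.seq),
                    endogenous_band=band_en,
                    transgenic_band=band_tg,
                    max_product=cons.max_product,
                )
                if _assay_validates(assay, templates):
                    return assay
    raise PrimerDesignError(
        "no primer triple produced distinct clean bands on the provided "
        "templates (band-geometry constraint failed)"
    )


def _assay_validates(assay: Assay, templates: dict[str, str]) -> bool:
    """Each allele template must show exactly its expected single band."""
    if not templates:
        return True
    for name, seq in templates.items():
        preds = predict_amplicons(
            seq, assay.primers, name, max_len=assay.max_product
        )
        lens = sorted(p.length for p in preds)
        expected = (
            [assay.transgenic_band] if "tg" in name else [assay.endogenous_band]
        )
        if lens != expected:
            return False
    return True


def genotype_alleles(
    assay: Assay, allele_templates: dict[str, str], genotype: str,
) -> GenotypeCall:
    """Predict the band pattern of a genotype's allele mixture and call it.

    ``allele_templates`` must contain 'tg' and 'wt' sequences.
    """
    mixture = {"hom": ["tg"], "het": ["tg", "wt"], "wt": ["wt"]}[genotype]
    preds = []
    for allele in mixture:
        preds.extend(
            predict_amplicons(
                allele_templates[allele], assay.primers, allele,
                max_len=assay.max_product,
            )
        )
    return call_zygosity(assay, preds)
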