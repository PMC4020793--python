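# Methods

This note documents the model behind `tgmap`, the choices that were
genuinely open, and what the synthetic benchmark does and does not show.

## Locus model

A transgenic integration locus is modelled as a host chromosome window in
which the segment between two boundaries is replaced by a tandem array of
transgene cassette units:

```
wild type:   ...flankL | deleted segment | flankR...
transgenic:  ...flankL | [unit_b x m_b][unit_a x m_a] | flankR...
```

Coordinates are 1-based inclusive throughout; the window can report
positions in an arbitrary chromosome frame via a constant offset (writers
converting to 0-based half-open BED live at the output layer only).  The
*left boundary* is the last retained flank base, the *right boundary* the
first retained base of the right flank, and the deletion length is their
coordinate difference — the convention under which the pair
68,208,872 / 68,209,029 yields 157 bp.  The count of physically removed
bases is one less (156); the difference convention matches how such
coordinates are conventionally printed and is asserted nowhere against the
±1 alternative.

Each junction carries a short **duplicated sequence** (microhomology): a
string that is simultaneously a suffix of the retained flank and a prefix
of the first cassette unit (left side; mirror definition on the right).
It is stored **once** in the physical allele — the "duplication" is an
alignment ambiguity, not two copies of sequence — which is exactly why a
local aligner can place the breakpoint anywhere within its span and why
the resolver has to handle it.  The default locus embeds CCAGCAG (7 bp,
left/β side) and TGGAT (5 bp, right/α side), and the generator verifies
after embedding that the microhomology is *maximal* at the stated length
(chance extensions are mutated away), so truth comparisons are exact.

Donor chromosome surrogates ("chr6" for β, "chr14" for α) carry one
reference copy of each cassette between unique pads.  `endogenous_copies`
controls whether the *sample* also carries that copy: on (default) mimics
the real animal, off isolates the array's contribution to coverage.

## Read simulation and oracle alignment

Fragments are drawn per haplotype (hom/het/wt genotype → tg/tg, tg/wt,
wt/wt) with outer insert length ~ Normal(370, 37) truncated at the read
length, 101-bp reads, i.i.d. substitution errors, and a per-source
fragment count proportional to the number of valid start positions so that
interior coverage is exactly depth/2 per haplotype regardless of source
length.  All randomness flows from one seeded generator; a fixed seed
(default 8) makes FASTQ/SAM output byte-identical across runs.

Rather than invoking an aligner, the simulator emits the alignments a
local-mode aligner would produce, derived from each read's true origin:

- reads wholly in flank/pads map in place; reads wholly inside one cassette
  copy map to the single reference copy on the donor contig (MAPQ 60 —
  their *reference* placement is unique even though the originating copy
  is not);
- reads spanning a copy–copy junction of the same cassette are ambiguous
  among the m−1 equivalent placements: clipped at the unit edge, MAPQ 0;
- junction-spanning reads map to the side holding the longer match, with
  the rest soft-clipped exactly at the boundary (the aligned side includes
  the duplicated sequence, as score-maximising local alignment would);
- mates falling on opposite sides of a junction become inter-contig pairs.

This removes the external aligner from the test surface; externally
aligned SAM can be substituted for real-data runs.  The idealisation to
note: oracle clips land exactly on the boundary, whereas a real aligner
extends through chance matches into the deleted reference sequence
(expected extension ~1/3 bp); the same ambiguity re-enters through
partner-anchored clips (below), so the benchmark does not overstate
attainable precision beyond ~±1 bp.

## Inference chain

**Insert model.** Concordance bounds are median ± k·1.4826·MAD (k = 3)
over same-contig inward pairs, with a 1-bp floor on the MAD scale so
degenerate inputs still give strict bounds.  Requires ≥ 200 pairs, else
explicit bounds must be supplied.

**Classification.** Different contigs → inter-chromosomal; wrong
orientation → orientation; outer insert outside bounds → size; otherwise
concordant.  Classification is symmetric in the mates.  Pairs with either
MAPQ < 20 are excluded from SV evidence ("uniquely mapped" proxy; the
threshold is configurable).

**Clustering.** Single linkage over discordant pairs: two pairs join iff
they bridge the same contig pair and both side footprints lie within the
window (default 2× insert median ≈ 740 bp — wide enough to capture every
pair whose fragment spans one junction).  Clusters carry support (pair
count), mean MAPQ and split-read support (clip events inside either
interval).

**Depth duplications.** Aligned bases are binned (500 bp for scanning,
200 bp for copy number); runs of bins ≥ 1.5× the genome level merge into
DUP calls scored by rc = run mean / genome level.  The 1.5× threshold
detects ≥ 2-fold gains comfortably at 8X.

**Genome level.** The normaliser for rc and copy-fold is the mean over
*masked* bins: bins within 500 bp of a covered-span end or of an excluded
interval are dropped — they sit on the coverage ramps that finite
simulated contigs produce at sequence ends and have no analogue in a
whole-genome average — and the fitted model also masks the insertion-site
neighbourhood (junction dip plus deleted segment).  A bin median was
evaluated instead but sits ~2 % below the plateau because per-bin depth is
Poisson-skewed; the masked mean is unbiased within ~1 %.

**Filters** (all reasons logged per cluster): support outside [5, 16];
either side on an excluded (mitochondrial/centromeric) contig;
intra-chromosomal links (configurable); adjacency crowding, codified as
≥ 3 other clusters within 10 kb — evaluated among clusters that already
passed the other rules, since counting raw clusters lets tandem-array-
internal links and insert-size outliers crowd out true junction clusters
on a desk-scale genome.  Tightening the support window never adds
candidates (monotonicity is tested).

**Ranking.** split_support desc, then duplication-bridged (cassette side
within 10 kb of a DUP call) before unbridged, then support desc, ties by
coordinates — a deterministic total order.

**Junction candidates and boundary sides.** Candidates with exactly one
side overlapping an annotated cassette region are junction candidates (a
cluster with both sides in cassette regions is an array-internal link).
The boundary side comes from the strand of the insertion-side mates:
fragments extend rightwards from a + mate, so +-strand clusters abut a
left boundary.

**Resolution.** Coordinate = mode of clip boundary positions (ties to the
smaller coordinate); consensus = per-column majority of the clipped tails
anchored at the boundary, truncated at the first column without a unique
≥ 50 % majority — robust in the 1–5 supporting-read regime.  The partner
cassette is the one whose junction-proximal sequence matches the consensus
with fewest mismatches over a 0–50 bp shift (the shift absorbs the
microhomology); a best match ≥ 10 % mismatches flags the call approximate.
When the insertion side has no direct clips, **partner-anchored rescue**
matches the flank-side tails of donor-contig clips into the candidate
flank window and extends the placement through the microhomology using the
cassette junction sequence; rescued votes are used only in that fallback
because their extension can over-run by chance matches against the deleted
reference sequence.  When only one boundary survives filtering, the
opposite boundary is resolved from junction evidence within 50 kb of the
nominated site even if its cluster fell outside the support window —
mirroring regional review of a nominated candidate, and protecting the
call from a single Poisson excursion in one junction's pair count.

**Microhomology** is the longest *exact* suffix/prefix match between the
retained flank and the partner cassette's junction sequence (mirror
definition on the right side), capped at 50 bp.  When the cassette
sequence is unavailable the clip consensus is used instead; note the
consensus starts *after* the duplicated sequence, so consensus-only
microhomologies are lower bounds.

**Copy-fold** = mean depth over the cassette interval, trimmed 200 bp per
side (junction soft-clip dips), divided by the genome level; CI from a
percentile bootstrap over bins (n = 1000, seeded).  The ratio is reported
as-is: converting to a per-haploid copy count requires zygosity and
endogenous-copy knowledge and is deliberately left to the caller (a
homozygote's endogenous locus adds 1 to the ratio, which is why the
default benchmark reads ~17×/~5× and the endogenous-off configuration
reads ~16×/~4×).

## Genotyping assay design

Primer sites require an exact match (optionally ≤ k mismatches with the
3'-terminal 3 bases always exact — extension chemistry); product sizes are
5'-to-5' inclusive.  Melting temperature uses the Wallace rule
2(A+T)+4(G+C), adequate for ranking 18–27-mers but not a thermodynamic
prediction.  The designer searches deterministically for: a forward primer
30–280 bp upstream of the left boundary, a reverse primer in the deleted
segment (preferred) or just downstream of the right boundary, and a
reverse primer in the junction-proximal cassette sequence; constraints are
length 18–27, Tm 55–65 °C, off-array uniqueness, bands ≥ 30 bp apart and
within [120, 1000] bp.  The 1000-bp product ceiling is load-bearing on a
tandem array: the cassette-side primer site recurs once per unit, so
products to the second copy (≥ one unit length larger) must exceed the
ceiling for the assay to stay three-band-clean; the default 3-kb units
guarantee this.  Validation predicts amplicons on both allele templates
and requires exactly the expected single band per allele; hom/het/wt
mixtures then give transgenic-only / both / endogenous-only patterns.

## Study conditions and problem sizes

Defaults were chosen once as the package's benchmark conditions: 101-bp
pairs at 8-fold total depth; insert 370 ± 37 bp (this centres the
junction-bridging pair support expectation near 10, the middle of the
[5, 16] review window, at this depth and read length); substitution error
rate 1 %; 6-kb retained flanks, 3-kb cassette units (β×4 then α×16), 3-kb
donor pads; boundary coordinates in the chr2 frame.  A full synthetic run
is ~3,500 read pairs and fits in ~1 s; the test suite's multi-seed sweeps
(20 seeds) run in under a minute.

## What the benchmark shows — and does not

Passing tests demonstrate that the chain recovers exact junction
coordinates, microhomologies, deletion length and copy-folds from
uniform-coverage, single-end-clean, GC-unbiased reads with ideal local
alignments over a small genome with one integration event.  Real data add
aligner-specific clip placement (±microhomology), mappability and GC
structure, PCR duplicates, repeat-associated false candidates (handled
here only via user-supplied exclusion lists), and possible internal array
rearrangements, which this pipeline deliberately does not model
(no de-novo assembly of the insert).  The discordant-pair *fraction* is
dataset-specific and is asserted nowhere.

Known stochastic limits at 8X, measured over seed sweeps: the insertion
call is exact in ~97 % of runs; ~2 % of runs lose one junction cluster to
the support window faster than the second-boundary rescue can compensate,
and ~1 % shift by ±1 bp through the microhomology-extension ambiguity.
Copy-fold estimates land within ±10 % of the configured multiplicity in
≥ 19/20 seeds for the default array sizes.
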