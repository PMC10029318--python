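# Methods

This note records the models, conventions and parameter choices behind
`ssrscape`, and what the synthetic-data validation does and does not show.

## SSR detection

A perfect SSR is a maximal tandem run of a primitive unit of size
*k* ∈ {1..6} with at least `min_repeats[k]` whole units. The defaults
{1: 10, 2: 7, 3: 6, 4: 5, 5: 4, 6: 4} are the thresholds conventionally
used in plant genome microsatellite surveys (MISA-style screens).
Conventions that matter for exactness:

- **Maximality and anchoring.** A periodic region of period *k* and
  length *L* with *L* mod *k* = *r* > 0 contains *r* + 1 shifted starts
  whose runs all have ⌊*L*/*k*⌋ units and cannot be extended by a whole
  unit. The scanner (and the brute-force oracle it is tested against)
  reports one locus per region, anchored at the region's leftmost base;
  the repeat count is ⌊*L*/*k*⌋ and partial trailing units never extend a
  locus. A consequence checked by the strand-symmetry test: on the
  reverse complement, truncation happens at the opposite region end, so
  mirrored coordinates may shift by up to *k* − 1 when *r* > 0.
- **Primitivity.** A unit that is a whole-number repetition of a shorter
  unit ((AT)₂, (A)₆, …) is never counted at the larger size; each run is
  reported once, at its smallest period.
- **Alphabet.** Input is uppercased (soft-masking ignored); N and any
  other non-ACGT character terminates runs and can never be part of one.
- **Coordinates.** 0-based half-open internally, 1-based inclusive in
  every emitted table.
- **Compound loci.** After greedy overlap resolution (longest run first,
  ties to the smaller unit, then leftmost), surviving runs separated by at
  most `max_interruption` bp merge into a compound locus. The default of
  100 bp is the conventional interruption distance for this kind of
  screen; it is configurable and nothing downstream depends on the exact
  value. Compound loci span their members plus interruptions; GC content
  uses repeat-run bases only (GC is a property of the repeat DNA), while
  length-class binning uses the full span as screens conventionally
  report it.

Motif classes are equivalence classes under cyclic rotation and reverse
complementation, named by the lexicographically smallest member, which
reproduces the standard strand-pair labels (AG/CT, ACT/AGT,
AACCCT/AGGGTT). One source table we checked prints both "AACCTT/AGGGTT"
and "(AACCCT/AGGGTT)n" for the same class; reverse-complement arithmetic
supports AACCCT, and the other form is treated as a typo (we do not
silently alter any input data).

## Region partition and density

Annotation is flattened across transcripts into four labels that exactly
partition each sequence: CDS = union of CDS records; UTR = explicit UTR
records when present (5′ and 3′ pooled), else exon − CDS, minus CDS;
intron = gene span − CDS − UTR; intergenic = complement of gene spans.
The subtraction chain guarantees the partition property
(Σ label lengths = genome length) for any input, including overlapping
isoforms, where the priority CDS > UTR > intron decides contested bases.

A locus is assigned to the label covering most of its bases; ties follow
the same priority. Boundary-spanning loci have no unambiguous home and
max-overlap is the least surprising deterministic rule; it is verified
against a per-base painting oracle in the tests.

Density is SSR bp per Mbp **of the label's own length**. Using per-label
denominators (not genome length) is what exposes the 6–9× genic
enrichment: intergenic DNA has the most loci in absolute number and the
lowest density at the same time.

## LTR insertion dating

The two LTRs of an element are identical on insertion; each accumulates
substitutions at rate *r* per site per year, so the expected pairwise
divergence after *T* years is 2*rT* and *T* = *D*/(2*r*). The default
*r* = 1.3 × 10⁻⁸ is the rate conventionally applied to maize transposable
elements. *D* is the p-distance over ungapped columns of a global
alignment; a Jukes–Cantor correction (−¾ ln(1 − 4*p*/3), undefined at
*p* ≥ 0.75) is available by flag for older cohorts, but at the < 3%
divergences of sub-Mya elements the two are nearly identical and
p-distance is the default.

Alignment uses Needleman–Wunsch with affine gaps (match +2, mismatch −3,
gap open −5, gap extend −2 per additional position; `Bio.Align`).
Scores are verified against an independent full-matrix Gotoh
implementation in the tests. Among co-optimal alignments the first one in
the aligner's deterministic enumeration is used; divergence is computed
from ungapped columns only, so co-optimal choice does not affect the
score and, on substitution-only data, essentially never the estimate.
Near-identical termini make the results insensitive to the scoring
constants.

Age bins default to 0.1-Mya widths over 0–1 Mya, with older elements
routed to an overflow bin excluded from the default report. An SSR counts
toward an element only if fully contained in the element span, because
the density denominator is LTR bp. Three per-bin densities are reported:
SSR/element count ratio, SSR bp per Mbp of element bp, and the ratio of
mean SSR length to mean element length. A helper fits
*y* = −*b* ln(*x*) + *a* to per-bin quantities for trend summaries.

## Cross-genome summaries

CV is 100 × sample SD (n − 1 denominator) / mean. The sample-SD choice is
deliberate: applied to the embedded five-genome maize survey counts it
reproduces every printed CV cell (9.47, 1.92, 8.00, 1.33, 3.78, 13.77,
5.88) to printed precision, which population SD does not. Quartiles use
linear interpolation (numpy default); any standard convention matches the
integer-bp values such tables print. Length classes are the conventional
ten bins 10–20, 21–30, …, 91–100, 101+; the first bin spans 11 lengths,
kept exactly as conventionally printed.

## Synthetic genomes

The generator builds what the analysis assumes, at desk scale, with a
complete ledger. Defaults describe a 2 × 2.5 Mb genome:

- **Gene models**: 80 genes per chromosome, 200 bp UTRs, 5 CDS exons of
  330 bp, 900 bp introns — coding bp ≈ 2× UTR bp, as in compact plant
  gene models. Genes are placed with a telomeric bias (70% of mass in the
  outer 30% of each arm).
- **Planted SSRs**: per-region bp/Mbp targets UTR 10 000 > CDS 6 500 >
  intron 5 000 > intergenic 900, matching the qualitative genic/intergenic
  contrast of repeat-rich plant genomes (intergenic ~700–1000, genic
  ~5 000–10 000 bp/Mbp); tri/hexanucleotide motifs in CDS (frame-
  preserving), mono/dinucleotide-rich UTRs. Repeat counts are geometric
  (p = 0.35) above the scanner threshold, capped at threshold + 8, giving
  the short-locus-dominated length spectrum real screens see.
- **Exact recoverability**: background sequence is rejection-sampled
  until it contains no qualifying run of its own; planted loci are spaced
  > 110 bp apart (beyond the merge distance) and each plant is locally
  re-scanned, with flank re-randomization, until it reads back at exactly
  its planted coordinates. This is what lets the acceptance suite demand
  100% recovery with exact coordinates rather than approximate overlap.
- **LTR elements**: 40 elements of 8 kb with 700 bp termini, placed with
  a centromeric bias, nominal ages cycling through the ten 0.1-Mya bin
  midpoints 0.05…0.95. The 3′ terminus is a copy of the 5′ one mutated by
  independent per-site substitution with probability 2·*r*·age (always to
  a different base), so the ledger's realized mismatch count is the exact
  estimand of the aligner and dating is a deterministic round trip.
  Substitution-only mutation is the default because it makes p-distance
  exact; the aligner's gap handling is exercised separately by its DP
  oracle tests. Every element carries a fixed SSR complement
  ((AG)₈ + (AAT)₇ = 37 bp), so SSR density inside elements is flat across
  age bins by construction, at 4625 bp/Mbp — inside the 4 498–4 992
  band observed for young maize LTR-RTs.

What passing these tests shows: the detector, partition, dating and
binning machinery are exact on data that satisfies their model
assumptions. What it does not show: performance on real genomes with
imperfect (mismatch-interrupted) repeats, nested or solo LTRs, indel
divergence, sequencing gaps, or annotation errors — none of which the
generator emulates (it has no indel, nesting or recombination model).

## Problem sizes and determinism

The validation suite uses a 5 Mb profile genome, 1 000 oracle-checked
random sequences (≤ 1 kb), and 10 dating cohorts × 200 replicates of
1 kb terminus pairs — sizes at which every statistical check has
comfortable resolution while the whole suite runs in well under a minute
of compute per component. All randomness flows through
`numpy.random.default_rng` seeds; identical spec + seed reproduce every
output byte-for-byte, and the pipeline writes a manifest of parameters
and input checksums with each run.

## Known limitations

- No mismatch-tolerant ("imperfect") run detection beyond compound
  merging; no unit sizes above 6 bp.
- Region statistics are transcript-flattened; no per-isoform statistics
  and no 5′/3′ UTR separation.
- De novo LTR discovery is out of scope: element and terminus coordinates
  are inputs (from LTR_Finder/LTRharvest-class tools upstream).
- The dating model assumes neutral, clock-like, substitution-driven
  divergence; gene conversion between LTRs or indel-dominated divergence
  will bias ages low or high respectively.
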