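# Methods

## The statistical model

The caller treats background mismatches as a homogeneous per-base error
process. Sequencing, reverse-transcription and SNP-derived substitutions hit
any sequenced base with a small probability, spread over the 12 possible
substitution types; crosslinking adds T→C events concentrated at binding
sites. Pooling all quality-passing bases genome-wide gives the totals
N (sequenced bases) and M (non-T→C mismatches), and the null T→C rate is
estimated as the per-substitution-type background rate

    R = M / (11 · N),

there being exactly 11 non-T→C substitution types. Dividing the pooled
background rate by 11 makes R the rate at which *one specific* substitution
type (in particular T→C) arises by error at an arbitrary sequenced base,
which is the correct exposure-based null for the test below. The divisor is
exposed as a parameter (`divisor`, default 11) because other conventions
(M/N, per-strand pooling) are conceivable; the per-type reading is the one
that makes the test dimensionally coherent.

For read group *i* with n_i sequenced bases and O_i observed T→C events, the
p-value is the exact one-sided Poisson rate test

    p_i = P(X >= O_i),  X ~ Poisson(R · n_i),

computed through the regularised incomplete gamma function (`scipy.stats.
poisson.sf`), which is the same quantity as a direct pmf summation — the
test suite verifies agreement to 1e-12 relative error. Benjamini–Hochberg is
applied once over all tested read groups, both strands together, and groups
with q ≤ 0.05 (inclusive) are clusters. Groups with O_i = 0 are retained
through testing with p = 1 so that the BH family size honestly reflects the
number of hypotheses examined.

Degenerate case: when M = 0 (noise-free simulations) R is floored at
1/(11·N), the smallest non-zero rate the data could have produced; otherwise
every group with a single T→C would get p = 0.

### Assumptions and their limits

* Errors are independent across bases and reads. Clustered artefacts (SNPs,
  misalignment around indels/repeats) violate this and produce false
  positives; no SNP masking is performed.
* The null exposure is n_i sequenced bases, not the number of sequenced Ts.
  Read groups with unusually T-rich sequence have a higher true accidental
  T→C expectation than R·n_i, a mild anticonservatism inherent to the
  pooled-rate design.
* One pooled background rate serves both strands and all chromosomes.

## Pipeline parameters

| parameter | default | meaning |
|---|---|---|
| `min_mapq` | 55 | minimum mapping quality; with STAR's convention (255 = unique) this restricts to uniquely mapped reads |
| `min_baseq` | 20 | minimum base quality; applied to depth and mismatch counts alike, so numerator and denominator of every rate see the same bases |
| `min_depth` | 3 | coverage threshold defining read groups |
| `gap` | 0 | merge distance; 0 = book-ended intervals only |
| `max_width` | 50 nt | maximum cluster width; longer regions are tiled into ceil(L/50) near-equal pieces (widths differ by ≤ 1), avoiding an underpowered terminal sliver |
| `alpha` | 0.05 | BH FDR threshold, inclusive |
| `min_len` | 13 nt | preprocessing length filter, applied both before and after UMI trimming |

Strand handling: plus-track reads have FLAG 0x10 and 0x100 clear; minus-track
reads have 0x10 set and 0x100 clear (the include-16/exclude-256 and
exclude-272 mask pair). Duplicate (0x400) and supplementary (0x800) records
are additionally excluded by default — duplicates are collapsed upstream and
supplementary records would double-count — and this extension is switchable.
Insertions, deletions and spliced gaps contribute nothing; N read bases and
N reference positions are excluded from all counts. There is no maximum
depth cap.

Coordinates are 0-based half-open everywhere internally and in all BED and
bedGraph output; GTF input (1-based closed) is converted on parse.

## Annotation

Gene models come from an ENSEMBL-style GTF (`pyranges` parser). Introns are
derived as gene span minus the union of the gene's exons. Overlap is
strand-matched with a 1 bp minimum (clusters are built strand-specifically;
antisense assignment would contradict the crosslinking chemistry) and is
resolved across the union of a gene's transcripts. Resolution order:
more than one overlapping gene → `multigenic` (the same tag covers
"multiple types of genes"); a single non-coding gene → its biotype; a single
coding gene → the first of 3'UTR, CDS, 5'UTR, intron that the interval
touches. A GTF dialect emitting plain `UTR` records has UTR sidedness
inferred from position relative to the CDS on the gene strand. tRNAs are not
assigned, being absent from canonical GTFs.

## The simulator

The generator emulates exactly the features the caller measures: a uniform
random reference (composition configurable), non-overlapping planted sites
each guaranteed ≥ 3 strand-local Ts, site reads that always span their site
at a fixed depth, uniform background coverage, strand-local T→C conversion
at the configured rate inside sites, and a uniform substitution error
process (each erroneous base uniform over the 3 alternatives). Uniform
errors over uniform composition split 11:1 between background and accidental
T→C, so the background estimator has the closed-form limit R → error_rate/12
— a law-of-large-numbers check the tests exercise.

Defaults (200 kb genome, 50 sites of 25 nt, conversion 0.3, site depth 15×,
background 8×, error 0.001, reads 30 nt, half the sites on the minus strand)
describe the desk-scale experiment used throughout the test suite; the null
calibration runs use error 0.002 and no sites. Reads are ungapped with
constant quality (Q40), MAPQ 255, emitted as coordinate-sorted SAM text —
byte-stable per seed and diffable. What the simulator does *not* model:
fragment-length and positional bias, quality-score variation, PCR
duplicates, splicing, indels, SNPs, repeats and multi-mapping. Passing
tests therefore demonstrate the statistical machinery and interval algebra
are correct, not that real-library artefacts (the main source of false
calls in practice) are handled.

## Numerical and design notes

* The Poisson tail is computed in double precision; below ~1e-290 the value
  underflows and comparisons against summation oracles are restricted to the
  representable range.
* BH is `statsmodels.stats.multitest.multipletests(method="fdr_bh")`; tests
  cross-check it against a hand-rolled sorted cumulative-min construction.
* Null calibration: by construction the per-replicate false-discovery
  proportion on a fully-null simulation is an indicator (any call → 1), so
  the 20-replicate mean moves in steps of 0.05. Measured over 80 null
  replicates the per-replicate probability of any false call is ≈ 2.5%,
  within the BH guarantee of ≤ 5%; the rare false calls are genuine extreme
  tail events (e.g. 3 T→C in a ~130-base group, p ≈ 2e-6 against a BH floor
  of ≈ 5e-6 at m ≈ 10⁴ groups).
* Problem sizes in the test-suite simulations (20–200 kb genomes, ≤ 10⁵
  reads) were chosen as the smallest at which the calibration and recovery
  statistics are stable.
* CPM export normalises by the number of quality-passing uniquely mapped
  reads recorded at track construction — the conventional library-size
  denominator for genome signal tracks; it is overridable since other
  denominators (e.g. total mismatches) are defensible.
* Coordinate-mode Venn counts are reported from each input set's
  perspective *and* as merged-union regions, because multi-way interval
  Venn membership has no single canonical convention; gene-mode counts are
  plain exclusive set algebra.
* Known limitation: collapsing duplicates before UMI trimming (the upstream
  pipeline's order, kept deliberately) under-collapses reads whose UMIs
  differ; the preprocessing module reproduces that order rather than
  correcting it.
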