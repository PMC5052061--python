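# Methods

## Model and procedure

`endseq` quantifies libraries in which each cDNA fragment yields a single
read anchored near one transcript terminus (3′ or 5′), so that read counts
are proportional to molecule counts. The analysis has two passes.

**Gene models.** Transcript annotations (BED6/BED12 or UCSC-style gene
tables) are collapsed per gene symbol into a union "metatranscript": the
interval union of all isoform exons. The first transcript seen fixes a
gene's chromosome and strand; isoforms that disagree are dropped with a
warning rather than aborting the run, because public annotation tables
routinely contain a few such rows. With BED input every transcript is its
own model (isoforms intentionally uncollapsed). All internal coordinates
are 0-based half-open; SAM positions are converted on ingest. Annotation
content is taken as given: restricting a RefSeq table to coding
transcripts (small and noncoding RNAs tend to have poor end annotations)
is an upstream filter — e.g. keep rows whose `name` starts with `NM_` —
not tool logic.

**Extension.** Because annotated termini are frequently wrong for exactly
the libraries this tool targets, each model is extended `wExt` bases past
its 3′ end (`score3p`) or 5′ end (`score5p`) in the strand-appropriate
direction. The extension is truncated at the genomic span of the nearest
*annotated* same-strand gene (opposite-strand genes never truncate;
abutting genes get a zero-length extension). Truncating against annotated
rather than extended neighbour spans keeps the result independent of
processing order and keeps same-strand models pairwise disjoint — a
property the test suite checks. Defaults of 5000 (3′) and 1000 (5′) bases
are surfaced as documented presets.

**Counting positions.** Each alignment is reduced to its biological 5′
terminus: the first aligned base of a forward alignment, the last aligned
base of a reverse alignment. This strand-aware reduction makes pileups
accumulate at homologous transcript-space positions on either strand.
Spliced alignments are split into blocks (N operations); a read is
assigned to a gene iff its counting position falls inside the gene's
exonic blocks or extension. Read-to-gene strand matching defaults to
same-strand and can be flipped or disabled for reverse-stranded protocols,
which the input data alone cannot identify.

**Window scan (pass 1).** Reads from all experiments are pooled. Each
gene's counting positions are laid on its spliced transcript axis
(length L = exonic + extension bases, oriented 5′→3′) and scanned with
windows of `wLen` bases advancing by `wLen − wOlap`; a trailing partial
window covers the transcript end with its actual length. A window holding
k of the gene's N pooled reads is scored by the scan statistic
`P(max over all wLen-windows ≥ k)` under the null that the N reads fall
independently and uniformly on the L positions — i.e. conditioning on the
gene's expression level, so highly expressed genes need proportionally
stronger pileups. Windows with `p ≤ sigTest` and at least one read are
retained; at `sigTest = 1.0` every window containing a read is retained
(the single-cell setting). Runs of overlapping or abutting significant
windows are merged, and within each merged region a `wLen` window slides
one base at a time; the start maximising the alignment-start count (ties:
smallest transcript coordinate, for determinism) represents the region.
Representative windows are mapped back to genomic coordinates; a window
crossing a splice junction reports the genomic span of its bases.

**Quantification (pass 2).** Per experiment, reads are re-counted inside
each representative window and over the whole (extended) model, yielding
`<prefix>.window.txt` and `<prefix>.gene.txt` (tab-delimited, one count
column per experiment). Under the `scale` multimapper policy counts may be
fractional. The exact output columns are this package's documented
dialect: Symbol/chr/strand(+counts) and
Symbol/chr/start/end/strand/pvalue(+counts).

## Scan p-value approximation

The conditional scan statistic has no closed form; the implementation uses
a Poisson-clumping approximation with two exact ingredients, written for
the discrete case (N reads on L positions, integer window of w bases):

1. **Exact upcrossing rate.** For adjacent windows W₁, W₂ (sharing w−1
   positions), `J(k) = P(W₁ < k ≤ W₂)` is computed exactly from the
   trinomial joint of (first cell, shared w−1 cells, entering cell) under
   the multinomial null, and the single-window tail `P(W₁ ≥ k)` is
   Binomial(N, w/L).
2. **Declumping (extremal index).** Exceedance clusters produce several
   upcrossings, so the raw rate over-counts. Starting from an upcrossing,
   the window count evolves as a random walk (one cell leaves ~
   Bin(k, 1/w), one enters ~ Bin(N−k, 1/(L−w)) per slide); θ is the
   probability that this walk, having dropped below the level, does not
   re-cross it within w slides — the horizon at which the window content
   has fully turned over.

The expected number of exceedance clusters is
`E = P(W₁ ≥ k) + (L − w)·J(k)·θ` and `p = 1 − exp(−E)`, floored by the
single-window tail, capped by the union bound over the L − w + 1 window
starts, and monotonised in k (the caps can produce microscopic dips at
small k where p ≈ 1). Tails per (N, L, w) are cached; in the p ≈ 1 regime
(E ≥ 20 before declumping) and the deep tail (E ≤ 1e−8) the θ computation
is skipped or reused from the transition zone.

Against a Monte-Carlo oracle (10⁵ uniform placements; exhaustive
enumeration when Lᴺ ≤ 10⁶) the approximation stays within
|Δlog₁₀ p| ≤ 0.09 wherever the true tail is ≥ 10⁻³ over
N ∈ {10, 100, 1000}, L ∈ {10³, 10⁴}, w ∈ {50, 100} — comfortably inside
the factor-2 band the test suite enforces. A simpler independence
approximation (per-window Poisson tail with `1−(1−p₀)^(L−w+1)`) was
evaluated first and rejected: it misses the empirical tail by up to ~18×
in this regime because overlapping windows are strongly dependent.
Significance is corrected per gene (L is that gene's scanned length), not
genome-wide.

## Multimapper policies

`normal` counts every alignment at every gene it hits (a read with loci in
two genes contributes to both; two loci inside one gene count twice —
the literal per-locus reading). `scale` gives each alignment weight
1/NH. `ignore` drops NH > 1 reads, and is exactly equivalent to filtering
them out and running `normal` (enforced as a test oracle). `proper`
buffers multimapped alignments, groups them by read id, and rescues a read
iff exactly one (alignment, gene) hit exists over the extended spliced
models — intronic hits do not rescue; a single alignment inside two
overlapping models counts as two hits and blocks rescue. The original
two-temporary-file mechanics are a performance detail; grouping in memory
implements the same contract at desk scale.

## Single-cell preprocessing

Read names carry `<name>:<barcode>:<UMI>`; the *last two* colon-separated
fields are used because Illumina read names contain colons, and no length
assumption is made about either field. Improper names are skipped with a
warning. PCR duplicates are reads sharing (barcode, UMI, gene); the first
occurrence in stream order is kept — any occurrence is equivalent under
the counting contract. Barcode validity uses an explicit `-bcMin`
(count ≥ bcMin) or an automatic knee: the point of maximum distance below
the chord of the sorted log₁₀-count curve locates the ambient boundary
region, and the threshold is then placed at the geometric mean of the
widest log-count gap at or above the knee. The gap step matters because
the chord distance peaks just *inside* the ambient plateau; splitting the
widest gap recovers a bimodal table exactly and degrades gracefully to the
knee count on smooth curves. Barcode error correction is assumed done
upstream. QC defaults: cells need ≥ 1000 total UMI-filtered reads
(applied first), then genes need ≥ 3 UMI-filtered reads in ≥ 2 remaining
cells; both thresholds are settable.

## Differential end usage

Genes testable for end-usage shifts are selected on the reference sample
only: ≥ 250 reads across significant windows, ≥ 2 windows, terminal-window
share ≥ 20%, and max/min window counts ≤ 1.5 (windows with zero reference
reads fail the ratio rule). The terminal window is the most 3′ (or, for 5′
tasks, most 5′) representative window in transcript orientation,
strand-aware; ties go to the larger genomic extent. The statistic is the
fraction of a gene's window reads *not* in the terminal window, in [0, 1];
a sample with zero reads for a gene yields a missing entry. The primary
test is the Wilcoxon signed-rank matched by gene between each sample and
the reference — the paired design is the natural choice since the same
genes are measured in every sample — with an unpaired Mann-Whitney option.
Only this global test is in scope; per-locus differential TSS/TTS calls
are not.

## Synthetic study conditions

The generator lays ~200 reads per gene (Poisson) on genes of 1–3 exons
(400–1200 bases each) spaced 20–40 kb apart on one chromosome, with ~30%
of genes given a second isoform sharing the first exon, ~10% of
consecutive same-strand pairs squeezed to a 2 kb gap to exercise extension
truncation, and ~20% of genes expressing an unannotated 3′ end 500–4500
bases downstream. Counting positions sit |N(60, 30)| bases upstream of the
expressed end — the order of real 3′-pileup widths. 20% of reads are
internal poly(A) artifacts carrying a planted 12-base A run at the gene
midpoint (only in genes of ≥ 900 spliced bases, so the artifact pileup
stays a window distinct from the terminal pileup); other sequences are
random with homopolymer runs capped at 4. 10% of reads are NH=2 decoys
whose second locus is intergenic (rescuable) or inside a partner gene
(unrescuable), labelled with the genic-locus count. Single-cell mode emits
per-molecule UMIs with an exact PCR copy factor and ambient barcodes.
Reads are written directly as aligned SAM records — no sequencing-error or
alignment simulation — with simple-match CIGARs that splice across exon
junctions; this exercises the block arithmetic but says nothing about
aligner behaviour, soft-clipping, or base-quality effects on real data.
Fixture sizes (500 genes for recovery rates, 50/200 replicates for the
shift test's power and calibration) keep full runs to a few minutes while
leaving binomial noise small relative to the tested margins.

## Known limitations

* The scan p-value is an approximation validated in the N/L/w regime
  above; extreme regimes (w close to L, or N in the millions) rely on the
  floor/cap bounds rather than the calibrated core.
* `normal` mode can count one read several times; totals across genes are
  then not read counts.
* The knee threshold assumes a reasonably bimodal barcode table; shallow
  ambient/cell separation warrants an explicit `-bcMin`.
* Window tables from different runs are comparable only when produced with
  identical window parameters; the differential end-usage test expects a
  single run with one column per sample.
* Protocol read orientation is protocol-specific and exposed as a switch
  (`-strand`), not inferred.
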