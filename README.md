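# endseq

Quantification of 3′/5′ end-sequencing (digital gene expression) RNA-seq,
for bulk and single-cell libraries.

End-sequencing protocols capture one read per cDNA fragment at a fixed
transcript terminus, so read counts approximate molecule counts — but
analytical methods built for full-length RNA-seq misbehave on such data:
internal poly(A) priming creates artifact pileups, annotated 3′/5′ ends are
often wrong or incomplete, and multimapped reads are either discarded or
miscounted. `endseq` addresses these failure modes directly:

* **Union gene models.** All isoforms of a gene are collapsed into a single
  metatranscript (the interval union of their exons), or each transcript is
  scored independently for BED input.
* **End extension.** The scanned region extends a user-chosen distance
  (`-wExt`) past the annotated terminus — truncated at the nearest
  same-strand neighbour — so unannotated 3′ UTRs are discovered de novo.
  Recommended values: 5000 for 3′ libraries, 1000 for 5′ libraries.
* **Scan-statistic windows.** In a first pass, reads pooled over all
  experiments are reduced to strand-aware counting positions and scanned
  with fixed-length windows (`-wLen`, `-wOlap`) along the spliced
  transcript. Each window count *k* out of the gene's *N* reads on *L*
  spliced bases is scored by `P(max window count ≥ k)` under uniform
  placement of the *N* reads — conditioning on expression level — and
  windows with `p ≤ -sigTest` are consolidated into representative end
  windows. A second pass counts each experiment's reads per window and per
  gene.
* **Multimapper policies.** `-multimap normal|scale|ignore|proper`, where
  `scale` assigns 1/N per locus and `proper` rescues a multimapped read iff
  exactly one of its alignments falls inside one (extended, spliced) gene
  model.
* **Poly(A) artifact filter.** `-filtAT n` discards reads containing an A
  or T homopolymer run of length ≥ n.
* **Single-cell preprocessing.** `-scPrep` parses `<name>:<barcode>:<UMI>`
  read names, removes PCR duplicates per (barcode, UMI, gene), thresholds
  barcodes by an explicit `-bcMin` or by the knee of the sorted log-count
  curve, and emits the cell × gene UMI matrix.
* **Differential end usage.** For genes with multiple significant windows,
  the fraction of reads *outside* the terminal window measures short- vs
  long-isoform usage; a paired Wilcoxon signed-rank test (matched by gene)
  detects global shifts between conditions.

## Worked example

Simulate a small annotated genome with planted unannotated 3′ ends,
internal poly(A) pileups and multimapped decoys, then quantify it:

```bash
endseq simulate -seed 7 -nGenes 30 -output sim
endseq quantify -input sim.sam -geneMapping sim.genes.txt -output out \
    -task score3p -multimap proper -wExt 5000 -sigTest 0.05 \
    -wLen 100 -wOlap 50 -filtAT 10
```

The run logs its parameters and passes, e.g.:

```
[INFO] built 30 gene models (34 transcripts), task=score3p wExt=5000
[INFO] pass 1: 33 significant windows (sigTest=0.05)
[INFO] wrote out.gene.txt and out.window.txt
```

`out.gene.txt` holds one row per gene with one count column per experiment;
`out.window.txt` holds the discovered end windows:

```
Symbol  chr   start   end     strand  pvalue         exp1
G0000   chrS  12892   12992   +       3.21752e-203   120
G0002   chrS  83280   83380   -       1.79077e-220   136
G0002   chrS  87547   87647   -       1.92915e-06    16
```

Each row is a consolidated significant window: `G0002` shows two expressed
3′ ends — the second is only found because the 5 kb extension reaches past
the annotated terminus. The p-value is the scan statistic of the window's
pooled count given the gene's expression; with `-sigTest 1.0` every window
containing a read is reported (the single-cell setting).

With several conditions, use an alignment list file
(`<experiment id>TAB<alignment file>`, one line per file) instead of
`-input`; each experiment becomes a count column. Differential end usage
then runs on the window table (here on a toy two-column table from
identical inputs, with thresholds relaxed for the tiny example):

```bash
printf 't0\tsim.sam\nt4\tsim.sam\n' > exps.txt
endseq quantify -alignments exps.txt -geneMapping sim.genes.txt -output out2 \
    -multimap proper -wExt 5000 -sigTest 0.05 -wLen 100 -wOlap 50 -filtAT 10
endseq diffends -windows out2.window.txt -reference t0 -output shift \
    -minReads 100 -maxRatio 10 -minFinalFrac 0.05
```

```
[INFO] tested 2 genes; p-values: t4=1
```

`shift.fractions.txt` holds each testable gene's fraction of reads outside
its terminal window per sample, and `shift.shift.txt` the paired
signed-rank result per non-reference sample — p = 1 here, as both columns
came from the same reads. At the defaults (250 reads, ≥2 windows, 20%
terminal share, ratio ≤ 1.5) the filters are deliberately strict: they
select genes whose alternative ends are balanced enough for a usage shift
to be measurable.

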