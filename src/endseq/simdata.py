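"""Synthetic end-sequencing fixtures with planted ground truth.

Generates annotation sets and aligned reads that reproduce the failure
modes end-sequencing quantification must handle: tight read pileups at
annotated transcript ends, pileups at UNannotated ends up to a few kb
downstream, internal poly(A)-priming artifact pileups (reads carrying long
A runs), multimapped reads with decoy loci, and PCR-duplicated barcoded
reads in single-cell mode.  Every emitted read carries exactly one origin
label in the returned truth table, so recovery can be checked exactly.

Also houses brute-force oracles: the Monte-Carlo / exhaustive scan-statistic
tail used to calibrate the analytic p-value, and direct generators for
barcode-count tables and differential end-usage window tables.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

from .annotations import GeneModel, TranscriptRecord, build_gene_models

BASES = np.array(list("ACGT"))


@dataclass
class SimSpec:
    """Study conditions for the synthetic fixtures.

    Defaults describe a desk-scale 3'-end library: ~200 reads per gene,
    end pileups with ~30 base spread a few tens of bases upstream of the
    terminus, 20% internal poly(A) artifact reads, 10% multimappers, and a
    fifth of genes expressing an unannotated 3' end within 5 kb.
    """

    seed: int                      # mandatory: all generators derive from it
    n_genes: int = 50
    chrom: str = "chrS"
    # gene architecture
    exon_length: tuple[int, int] = (400, 1200)   # per-exon span (uniform)
    intron_length: tuple[int, int] = (200, 2000)
    max_exons: int = 3
    gene_gap: tuple[int, int] = (20000, 40000)   # intergenic spacing
    close_pair_frac: float = 0.1   # same-strand pairs ~2 kb apart (truncation)
    close_pair_gap: int = 2000
    multi_isoform_frac: float = 0.3
    novel_end_gene_frac: float = 0.2   # genes whose true 3' end is unannotated
    novel_end_distance: tuple[int, int] = (500, 4500)
    # read emission
    reads_per_gene: float = 200.0
    polya_frac: float = 0.2
    multimap_frac: float = 0.1
    multimap_both_genic_frac: float = 0.3  # decoys whose 2nd locus is genic
    end_offset_mean: float = 60.0   # counting-position offset from the end
    end_offset_sd: float = 30.0
    read_length: int = 25
    polya_run: int = 12             # planted homopolymer length
    # genes shorter than this (spliced) emit no internal poly(A) reads:
    # the artifact pileup must sit clear of the terminal pileup to be a
    # distinct window
    min_polya_gene_length: int = 900
    # single-cell block
    n_cells: int = 50
    umis_per_cell: float = 100.0
    pcr_factor: int = 1
    n_ambient: int = 500
    ambient_umis: float = 5.0


@dataclass
class SimulatedTranscriptome:
    records: list[TranscriptRecord]
    gene_info: pd.DataFrame        # per gene: strand, ends, planted features
    chrom_length: int
    decoy_region_start: int
    chrom: str


def _rng(spec_seed: int, salt: int) -> np.random.Generator:
    return np.random.default_rng([salt, spec_seed])


# ---------------------------------------------------------------------------
# annotations


def simulate_transcriptome(spec: SimSpec) -> SimulatedTranscriptome:
    """Lay genes along one chromosome with planted structure.

    Some genes get a second isoform sharing their first exon (so union
    models differ from single isoforms); a fraction of consecutive gene
    pairs is placed on the same strand closer than typical extensions to
    exercise extension truncation; novel-end genes reserve downstream
    clearance for their unannotated terminus.
    """
    rng = _rng(spec.seed, 1)
    records: list[TranscriptRecord] = []
    info_rows = []
    cursor = 10000
    prev_forced_strand: str | None = None
    for i in range(spec.n_genes):
        gene = f"G{i:04d}"
        follows_close_pair = prev_forced_strand is not None
        if follows_close_pair:
            strand = prev_forced_strand
            prev_forced_strand = None
        else:
            strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(1, spec.max_exons + 1))
        exon_starts, exon_ends = [], []
        pos = cursor
        for j in range(n_exons):
            length = int(rng.integers(*spec.exon_length))
            exon_starts.append(pos)
            exon_ends.append(pos + length)
            pos += length
            if j < n_exons - 1:
                pos += int(rng.integers(*spec.intron_length))
        tx_start, tx_end = exon_starts[0], exon_ends[-1]
        records.append(
            TranscriptRecord(
                transcript_id=f"T{i:04d}a",
                gene_symbol=gene,
                chrom=spec.chrom,
                strand=strand,
                tx_start=tx_start,
                tx_end=tx_end,
                exon_starts=list(exon_starts),
                exon_ends=list(exon_ends),
            )
        )
        multi = rng.random() < spec.multi_isoform_frac and n_exons > 1
        if multi:
            # second isoform: shares the first exon, shifts the last end
            delta = int(rng.integers(50, 200))
            alt_ends = list(exon_ends)
            alt_ends[-1] = exon_ends[-1] + delta
            records.append(
                TranscriptRecord(
                    transcript_id=f"T{i:04d}b",
                    gene_symbol=gene,
                    chrom=spec.chrom,
                    strand=strand,
                    tx_start=tx_start,
                    tx_end=alt_ends[-1],
                    exon_starts=list(exon_starts),
                    exon_ends=alt_ends,
                )
            )
            tx_end = alt_ends[-1]
        # a gene squeezed against its upstream partner cannot host a novel
        # end (its extension zone is truncated by construction)
        has_novel = (
            rng.random() < spec.novel_end_gene_frac and not follows_close_pair
        )
        novel_distance = (
            int(rng.integers(*spec.novel_end_distance)) if has_novel else 0
        )
        # genomic position of the unannotated 3' end
        if has_novel:
            novel_pos = tx_end + novel_distance if strand == "+" else tx_start - novel_distance
        else:
            novel_pos = -1
        close_pair = rng.random() < spec.close_pair_frac and not has_novel
        info_rows.append(
            {
                "gene": gene,
                "strand": strand,
                "tx_start": tx_start,
                "tx_end": tx_end,
                "n_isoforms": 2 if multi else 1,
                "has_novel_end": has_novel,
                "novel_end_pos": novel_pos,
                "close_pair_downstream": close_pair,
            }
        )
        if close_pair:
            # next gene abuts on the same strand to force extension truncation
            cursor = tx_end + spec.close_pair_gap
            prev_forced_strand = strand
        else:
            clearance = max(spec.gene_gap[0], novel_distance + 6000)
            cursor = tx_end + int(rng.integers(clearance, clearance + spec.gene_gap[1]))
    gene_end = cursor
    decoy_start = gene_end + 100000
    chrom_length = decoy_start + 10000 * max(1, spec.n_genes // 10) + 100000
    return SimulatedTranscriptome(
        records=records,
        gene_info=pd.DataFrame(info_rows).set_index("gene"),
        chrom_length=chrom_length,
        decoy_region_start=decoy_start,
        chrom=spec.chrom,
    )


def write_bed(records: Sequence[TranscriptRecord], path: str) -> None:
    """Write transcripts as BED12."""
    with open(path, "w") as fh:
        for r in records:
            sizes = ",".join(str(e - s) for s, e in r.exons) + ","
            offs = ",".join(str(s - r.tx_start) for s in r.exon_starts) + ","
            fh.write(
                "\t".join(
                    map(
                        str,
                        [
                            r.chrom, r.tx_start, r.tx_end, r.transcript_id,
                            0, r.strand, r.tx_start, r.tx_end, "0",
                            len(r.exon_starts), sizes, offs,
                        ],
                    )
                )
                + "\n"
            )


def write_gene_table(records: Sequence[TranscriptRecord], path: str) -> None:
    """Write transcripts as a UCSC-style tab-delimited gene table."""
    with open(path, "w") as fh:
        fh.write(
            "#name\tchrom\tstrand\ttxStart\ttxEnd\texonStarts\texonEnds\tname2\n"
        )
        for r in records:
            starts = ",".join(map(str, r.exon_starts)) + ","
            ends = ",".join(map(str, r.exon_ends)) + ","
            fh.write(
                f"{r.transcript_id}\t{r.chrom}\t{r.strand}\t{r.tx_start}\t"
                f"{r.tx_end}\t{starts}\t{ends}\t{r.gene_symbol}\n"
            )


# ---------------------------------------------------------------------------
# reads


def _random_sequence(rng: np.random.Generator, length: int, max_run: int = 4) -> str:
    """Random sequence with homopolymer runs capped (no poly(A/T) artifact)."""
    out = []
    run = 0
    prev = ""
    for _ in range(length):
        b = str(BASES[rng.integers(0, 4)])
        if b == prev:
            run += 1
            if run >= max_run:
                choices = [c for c in "ACGT" if c != b]
                b = choices[int(rng.integers(0, 3))]
                run = 1
        else:
            run = 1
        prev = b
        out.append(b)
    return "".join(out)


def _polya_sequence(rng: np.random.Generator, length: int, run: int) -> str:
    head_len = int(rng.integers(2, max(3, length - run - 2)))
    head = _random_sequence(rng, head_len)
    tail = _random_sequence(rng, length - head_len - run)
    return (head + "A" * run + tail)[:length]


def _transcript_interval_blocks(
    model: GeneModel, t_start: int, length: int
) -> list[tuple[int, int]]:
    """Genomic blocks of transcript interval [t_start, t_start+length),
    given in 5'->3' transcript orientation."""
    L = model.effective_length
    t_end = min(t_start + length, L)
    if model.strand == "+":
        g_lo, g_hi = t_start, t_end - 1
    else:
        g_lo, g_hi = L - t_end, L - 1 - t_start
    positions = [model.offset_to_genomic(g) for g in range(g_lo, g_hi + 1)]
    blocks: list[list[int]] = []
    for p in positions:
        if blocks and p == blocks[-1][1]:
            blocks[-1][1] = p + 1
        else:
            blocks.append([p, p + 1])
    return [(s, e) for s, e in blocks]


def _sam_header(chrom: str, length: int) -> dict:
    return {"HD": {"VN": "1.6", "SO": "unsorted"}, "SQ": [{"SN": chrom, "LN": length}]}


def _make_segment(
    header: pysam.AlignmentHeader,
    name: str,
    blocks: list[tuple[int, int]],
    strand: str,
    sequence: str,
    nh: int,
    secondary: bool = False,
) -> pysam.AlignedSegment:
    seg = pysam.AlignedSegment(header)
    seg.query_name = name
    seg.reference_id = 0
    seg.reference_start = blocks[0][0]
    seg.mapping_quality = 50
    flag = 0
    if strand == "-":
        flag |= 16
    if secondary:
        flag |= 256
    seg.flag = flag
    cigar = []
    prev_end = None
    aligned = 0
    for s, e in blocks:
        if prev_end is not None:
            cigar.append((3, s - prev_end))  # N: intron
        cigar.append((0, e - s))  # M
        aligned += e - s
        prev_end = e
    seg.cigartuples = cigar
    seg.query_sequence = sequence[:aligned].ljust(aligned, "C")
    seg.set_tag("NH", nh)
    return seg


def simulate_end_reads(
    transcriptome: SimulatedTranscriptome,
    spec: SimSpec,
    sam_path: str,
) -> pd.DataFrame:
    """Emit bulk 3'-end reads for every gene into a SAM file.

    Per-gene reads are a mixture of: pileup at the gene's expressed 3' end
    (the annotated end, or the planted unannotated end for novel-end
    genes), internal poly(A) artifact reads carrying a long A run, and
    multimapped decoys (NH=2, second locus either intergenic or inside a
    partner gene).  Returns the per-read truth table.
    """
    rng = _rng(spec.seed, 2)
    models = build_gene_models(transcriptome.records, "metatranscript")
    model_by_gene = {m.gene_symbol: m for m in models}
    info = transcriptome.gene_info
    header = pysam.AlignmentHeader.from_dict(
        _sam_header(transcriptome.chrom, transcriptome.chrom_length)
    )
    truth_rows = []
    read_no = 0
    decoy_cursor = transcriptome.decoy_region_start
    genes = list(info.index)
    with pysam.AlignmentFile(sam_path, "w", header=header) as out:
        for gi, gene in enumerate(genes):
            model = model_by_gene[gene]
            row = info.loc[gene]
            L = model.effective_length
            n_reads = int(rng.poisson(spec.reads_per_gene))
            labels = rng.choice(
                ["end", "internal_polyA", "multimap_decoy"],
                size=n_reads,
                p=[
                    1.0 - spec.polya_frac - spec.multimap_frac,
                    spec.polya_frac,
                    spec.multimap_frac,
                ],
            )
            if L < spec.min_polya_gene_length:
                labels = np.where(labels == "internal_polyA", "end", labels)
            for label in labels:
                read_no += 1
                name = f"R{read_no:07d}"
                if label == "end":
                    offset = int(abs(rng.normal(spec.end_offset_mean, spec.end_offset_sd)))
                    if row["has_novel_end"]:
                        # counting position in the downstream extension zone
                        dist = abs(
                            row["novel_end_pos"]
                            - (row["tx_end"] if row["strand"] == "+" else row["tx_start"])
                        )
                        offset = min(offset, int(dist) - 1)
                        offset = max(offset, 1)
                        if row["strand"] == "+":
                            cpos = int(row["novel_end_pos"]) - offset
                            blocks = [(cpos, cpos + spec.read_length)]
                        else:
                            cpos = int(row["novel_end_pos"]) + offset
                            blocks = [(cpos - spec.read_length + 1, cpos + 1)]
                        out_label = "novel_end"
                    else:
                        offset = min(offset, L - 1)
                        t_cp = L - 1 - offset
                        blocks = _transcript_interval_blocks(
                            model, t_cp, spec.read_length
                        )
                        out_label = "annotated_end"
                        cpos = (
                            blocks[0][0] if model.strand == "+" else blocks[-1][1] - 1
                        )
                    seq = _random_sequence(rng, spec.read_length)
                    out.write(
                        _make_segment(header, name, blocks, row["strand"], seq, 1)
                    )
                    truth_rows.append(
                        dict(read_id=name, gene=gene, label=out_label,
                             n_genic_loci=1, position=cpos)
                    )
                elif label == "internal_polyA":
                    t_mid = L // 2 + int(rng.normal(0, 5))
                    t_mid = min(max(t_mid, 0), L - 1)
                    blocks = _transcript_interval_blocks(model, t_mid, spec.read_length)
                    cpos = blocks[0][0] if model.strand == "+" else blocks[-1][1] - 1
                    seq = _polya_sequence(rng, spec.read_length, spec.polya_run)
                    out.write(
                        _make_segment(header, name, blocks, row["strand"], seq, 1)
                    )
                    truth_rows.append(
                        dict(read_id=name, gene=gene, label="internal_polyA",
                             n_genic_loci=1, position=cpos)
                    )
                else:  # multimap decoy
                    offset = int(
                        min(abs(rng.normal(spec.end_offset_mean, spec.end_offset_sd)), L - 1)
                    )
                    t_cp = L - 1 - offset
                    blocks = _transcript_interval_blocks(model, t_cp, spec.read_length)
                    cpos = blocks[0][0] if model.strand == "+" else blocks[-1][1] - 1
                    seq = _random_sequence(rng, spec.read_length)
                    both_genic = rng.random() < spec.multimap_both_genic_frac
                    out.write(
                        _make_segment(header, name, blocks, row["strand"], seq, 2)
                    )
                    if both_genic and spec.n_genes > 1:
                        partner = genes[(gi + 1) % spec.n_genes]
                        pmodel = model_by_gene[partner]
                        pL = pmodel.effective_length
                        p_off = int(min(50, pL - 1))
                        pblocks = _transcript_interval_blocks(
                            pmodel, pL - 1 - p_off, spec.read_length
                        )
                        out.write(
                            _make_segment(
                                header, name, pblocks, pmodel.strand, seq, 2,
                                secondary=True,
                            )
                        )
                        n_genic = 2
                    else:
                        dblocks = [(decoy_cursor, decoy_cursor + spec.read_length)]
                        decoy_cursor += 200
                        out.write(
                            _make_segment(
                                header, name, dblocks, row["strand"], seq, 2,
                                secondary=True,
                            )
                        )
                        n_genic = 1
                    truth_rows.append(
                        dict(read_id=name, gene=gene, label="multimap_decoy",
                             n_genic_loci=n_genic, position=cpos)
                    )
    return pd.DataFrame(truth_rows)


def simulate_single_cell_reads(
    transcriptome: SimulatedTranscriptome,
    spec: SimSpec,
    sam_path: str,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emit barcoded, UMI-tagged reads with PCR duplication.

    Each true cell samples ~``umis_per_cell`` molecules across the genes;
    each molecule becomes ``pcr_factor`` identical reads (PCR copies) with
    the ``:<barcode>:<UMI>`` read-name suffix.  Ambient barcodes emit a few
    molecules each.  Returns (truth cell x gene molecule counts, per-read
    truth table).
    """
    rng = _rng(spec.seed, 3)
    models = build_gene_models(transcriptome.records, "metatranscript")
    model_by_gene = {m.gene_symbol: m for m in models}
    genes = list(transcriptome.gene_info.index)
    gene_weights = rng.dirichlet(np.ones(len(genes)) * 2.0)
    header = pysam.AlignmentHeader.from_dict(
        _sam_header(transcriptome.chrom, transcriptome.chrom_length)
    )
    barcodes = [f"CB{i:04d}" for i in range(spec.n_cells)]
    ambient = [f"AB{i:04d}" for i in range(spec.n_ambient)]
    truth_counts: dict[tuple[str, str], int] = {}
    read_rows = []
    mol_no = 0

    def _emit(out, bc: str, n_mols: int, label: str):
        nonlocal mol_no
        gene_idx = rng.choice(len(genes), size=n_mols, p=gene_weights)
        for g_i in gene_idx:
            mol_no += 1
            gene = genes[g_i]
            model = model_by_gene[gene]
            L = model.effective_length
            umi = "".join(BASES[rng.integers(0, 4, size=8)])
            offset = int(min(abs(rng.normal(spec.end_offset_mean, spec.end_offset_sd)), L - 1))
            blocks = _transcript_interval_blocks(model, L - 1 - offset, spec.read_length)
            seq = _random_sequence(rng, spec.read_length)
            key = (bc, gene)
            # distinct UMIs define molecules; a UMI collision within
            # (cell, gene) merges molecules, exactly as dedup will see it
            new_molecule = (key, umi) not in seen_umis
            if new_molecule:
                seen_umis.add((key, umi))
                truth_counts[key] = truth_counts.get(key, 0) + 1
            for copy in range(max(1, spec.pcr_factor)):
                name = f"M{mol_no:07d}c{copy}:{bc}:{umi}"
                out.write(
                    _make_segment(header, name, blocks, model.strand, seq, 1)
                )
                read_rows.append(
                    dict(
                        read_id=name, gene=gene, barcode=bc, umi=umi,
                        label=(label if copy == 0 and new_molecule else "pcr_duplicate"),
                    )
                )

    seen_umis: set[tuple[tuple[str, str], str]] = set()
    with pysam.AlignmentFile(sam_path, "w", header=header) as out:
        for bc in barcodes:
            _emit(out, bc, int(rng.poisson(spec.umis_per_cell)), "sc_molecule")
        for bc in ambient:
            _emit(out, bc, int(rng.poisson(spec.ambient_umis)), "ambient_molecule")
    truth = pd.DataFrame(
        [
            {"barcode": bc, "gene": g, "molecules": c}
            for (bc, g), c in sorted(truth_counts.items())
        ]
    )
    return truth, pd.DataFrame(read_rows)


# ---------------------------------------------------------------------------
# oracles and direct fixtures


def mc_scan_oracle(
    N: int, L: int, w: int, reps: int = 100_000, seed: int = 0
) -> np.ndarray:
    """Empirical tail P(max w-window count >= k), k = 0..N.

    Places N reads uniformly on L positions ``reps`` times and tabulates
    the maximum sliding-window count.  When the full configuration space
    L**N is at most 1e6 the exhaustive enumeration is used instead.
    """
    if w < 1 or w > L:
        raise ValueError("need 1 <= w <= L")
    if N == 0:
        out = np.zeros(2)
        out[0] = 1.0
        return out
    if L**N <= 1_000_000:
        maxes = np.zeros(N + 1)
        total = 0
        for combo in itertools.product(range(L), repeat=N):
            counts = np.bincount(combo, minlength=L)
            cs = np.concatenate([[0], np.cumsum(counts)])
            m = int((cs[w:] - cs[:-w]).max())
            maxes[m] += 1
            total += 1
        tail = np.cumsum(maxes[::-1])[::-1] / total
        return tail
    rng = np.random.default_rng(seed)
    maxes = np.empty(reps, dtype=np.int64)
    done = 0
    chunk = max(1, min(1000, int(2e7 // L)))
    while done < reps:
        c = min(chunk, reps - done)
        pos = rng.integers(0, L, size=(c, N))
        counts = np.zeros((c, L), dtype=np.int32)
        np.add.at(counts, (np.repeat(np.arange(c), N), pos.ravel()), 1)
        cs = np.zeros((c, L + 1), dtype=np.int32)
        np.cumsum(counts, axis=1, out=cs[:, 1:])
        maxes[done:done + c] = (cs[:, w:] - cs[:, :-w]).max(axis=1)
        done += c
    ks = np.arange(N + 1)
    return (maxes[None, :] >= ks[:, None]).mean(axis=1)


def simulate_barcode_table(
    seed: int,
    n_cells: int = 200,
    cell_mean: float = 5000.0,
    n_ambient: int = 5000,
    ambient_mean: float = 50.0,
) -> tuple[dict[str, int], set[str]]:
    """Bimodal barcode count table: true cells vs ambient barcodes."""
    rng = np.random.default_rng([4, seed])
    table: dict[str, int] = {}
    true_cells = set()
    for i in range(n_cells):
        bc = f"CB{i:04d}"
        table[bc] = max(1, int(rng.poisson(cell_mean)))
        true_cells.add(bc)
    for i in range(n_ambient):
        table[f"AB{i:04d}"] = max(1, int(rng.poisson(ambient_mean)))
    return table, true_cells


def simulate_window_table(
    seed: int,
    n_genes: int = 500,
    n_reads: int = 300,
    delta: float = 0.0,
    samples: Sequence[str] = ("t0", "t4"),
    reference_fraction: tuple[float, float] = (0.42, 0.58),
) -> pd.DataFrame:
    """Two-window-per-gene table for end-usage shift simulations.

    Each gene has a terminal and a non-terminal window on the + strand.
    In the reference sample (first of ``samples``) the fraction of reads
    outside the terminal window is uniform on ``reference_fraction``; each
    later sample shifts it by ``delta``.  Window counts are binomial draws
    of ``n_reads`` reads.
    """
    rng = np.random.default_rng([5, seed])
    rows = []
    for i in range(n_genes):
        gene = f"G{i:04d}"
        f0 = rng.uniform(*reference_fraction)
        fracs = [f0] + [float(np.clip(f0 + delta, 0.01, 0.99))] * (len(samples) - 1)
        counts_final = [int(rng.binomial(n_reads, 1.0 - f)) for f in fracs]
        base = 100000 * i
        for start, is_final in ((base + 1000, False), (base + 2000, True)):
            row = {
                "Symbol": gene, "chr": "chrS", "start": start,
                "end": start + 100, "strand": "+", "pvalue": 0.001,
            }
            for s, cf in zip(samples, counts_final):
                row[s] = cf if is_final else n_reads - cf
            rows.append(row)
    return pd.DataFrame(rows)
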