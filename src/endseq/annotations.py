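"""Transcript annotations and union gene models.

Transcripts are read from BED6/BED12 files or from UCSC Table Browser style
tab-delimited gene tables.  For gene-table input all isoforms of a gene are
collapsed into a single "metatranscript" whose exonic blocks are the interval
union of the isoform exons; for BED input each transcript is treated as its
own gene.  Models can then be extended past their annotated 5' or 3' end to
capture unannotated termini, with the extension truncated at the nearest
same-strand neighbour.

All coordinates are 0-based half-open throughout (the native convention of
BED and UCSC tables; SAM positions are converted on ingest).
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

logger = logging.getLogger("endseq")

GENE_TABLE_COLUMNS = (
    "name",
    "chrom",
    "strand",
    "txStart",
    "txEnd",
    "exonStarts",
    "exonEnds",
    "name2",
)


@dataclass
class TranscriptRecord:
    """One transcript: an isoform of a gene with its exon structure."""

    transcript_id: str
    gene_symbol: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exon_starts: list[int]
    exon_ends: list[int]

    def validate(self, context: str = "") -> None:
        where = f" ({context})" if context else ""
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"strand must be '+' or '-' for end-sequencing, got "
                f"{self.strand!r}{where}"
            )
        if not self.tx_start < self.tx_end:
            raise ValueError(f"txStart must be < txEnd{where}")
        if len(self.exon_starts) != len(self.exon_ends):
            raise ValueError(f"exonStarts/exonEnds length mismatch{where}")
        if not self.exon_starts:
            raise ValueError(f"transcript has no exons{where}")
        prev_end = None
        for s, e in zip(self.exon_starts, self.exon_ends):
            if not s < e:
                raise ValueError(f"empty or inverted exon [{s}, {e}){where}")
            if s < self.tx_start or e > self.tx_end:
                raise ValueError(f"exon [{s}, {e}) outside transcript span{where}")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"exons unsorted or overlapping{where}")
            prev_end = e

    @property
    def exons(self) -> list[tuple[int, int]]:
        return list(zip(self.exon_starts, self.exon_ends))


@dataclass
class GeneModel:
    """Per-gene union model: disjoint exonic blocks plus an optional
    end extension searched for unannotated termini."""

    gene_symbol: str
    chrom: str
    strand: str
    exonic_blocks: list[tuple[int, int]]
    extension_block: tuple[int, int] | None = None
    # cached coordinate maps, rebuilt on construction
    _starts: list[int] = field(init=False, default_factory=list, repr=False, compare=False)
    _ends: list[int] = field(init=False, default_factory=list, repr=False, compare=False)
    _offsets: list[int] = field(init=False, default_factory=list, repr=False, compare=False)

    def __post_init__(self) -> None:
        self._rebuild()

    def _rebuild(self) -> None:
        blocks = self.all_blocks
        self._starts = [b[0] for b in blocks]
        self._ends = [b[1] for b in blocks]
        off = [0]
        for s, e in blocks:
            off.append(off[-1] + (e - s))
        self._offsets = off

    @property
    def all_blocks(self) -> list[tuple[int, int]]:
        """Exonic blocks plus the extension, sorted genomically."""
        blocks = list(self.exonic_blocks)
        if self.extension_block is not None:
            blocks.append(self.extension_block)
        return sorted(blocks)

    @property
    def span(self) -> tuple[int, int]:
        """Genomic span of the annotated (unextended) model."""
        return self.exonic_blocks[0][0], self.exonic_blocks[-1][1]

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exonic_blocks)

    @property
    def extension_length(self) -> int:
        if self.extension_block is None:
            return 0
        return self.extension_block[1] - self.extension_block[0]

    @property
    def effective_length(self) -> int:
        """Spliced length scanned: exonic blocks plus extension."""
        return self._offsets[-1]

    def contains(self, pos: int) -> bool:
        """Is the genomic position inside the (extended, spliced) model?"""
        i = bisect.bisect_right(self._starts, pos) - 1
        return i >= 0 and pos < self._ends[i]

    def genomic_to_offset(self, pos: int) -> int | None:
        """Map a genomic position to its spliced offset (genomic order),
        or None when the position falls outside the model."""
        i = bisect.bisect_right(self._starts, pos) - 1
        if i < 0 or pos >= self._ends[i]:
            return None
        return self._offsets[i] + (pos - self._starts[i])

    def offset_to_genomic(self, offset: int) -> int:
        """Inverse of :meth:`genomic_to_offset` (genomic-order offsets)."""
        if not 0 <= offset < self.effective_length:
            raise IndexError(f"offset {offset} outside model of length "
                             f"{self.effective_length}")
        i = bisect.bisect_right(self._offsets, offset) - 1
        return self._starts[i] + (offset - self._offsets[i])


# ---------------------------------------------------------------------------
# readers


def _parse_int(text: str, what: str, lineno: int, path: str) -> int:
    try:
        return int(text)
    except ValueError:
        raise ValueError(
            f"{path}: line {lineno}: cannot parse {what} from {text!r}"
        ) from None


def read_bed(path: str) -> list[TranscriptRecord]:
    """Read transcripts from a BED6/BED12 file.

    With 12 columns, blocks (columns 10-12) give the exon structure; with
    6-11 columns the whole [start, end) span is a single exon.  A strand of
    '.' is rejected: end-sequencing counting is strand-aware.
    """
    records: list[TranscriptRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(
                    f"{path}: line {lineno}: BED needs >= 6 columns, "
                    f"got {len(fields)}"
                )
            chrom = fields[0]
            start = _parse_int(fields[1], "chromStart", lineno, path)
            end = _parse_int(fields[2], "chromEnd", lineno, path)
            name = fields[3]
            strand = fields[5]
            if len(fields) >= 12:
                n_blocks = _parse_int(fields[9], "blockCount", lineno, path)
                sizes = [
                    _parse_int(x, "blockSizes", lineno, path)
                    for x in fields[10].rstrip(",").split(",")
                ]
                offs = [
                    _parse_int(x, "blockStarts", lineno, path)
                    for x in fields[11].rstrip(",").split(",")
                ]
                if not (len(sizes) == len(offs) == n_blocks):
                    raise ValueError(
                        f"{path}: line {lineno}: blockCount {n_blocks} does "
                        f"not match block lists"
                    )
                exon_starts = [start + o for o in offs]
                exon_ends = [s + sz for s, sz in zip(exon_starts, sizes)]
            else:
                exon_starts, exon_ends = [start], [end]
            rec = TranscriptRecord(
                transcript_id=name,
                gene_symbol=name,
                chrom=chrom,
                strand=strand,
                tx_start=start,
                tx_end=end,
                exon_starts=exon_starts,
                exon_ends=exon_ends,
            )
            try:
                rec.validate()
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
            records.append(rec)
    return records


def _split_coord_list(text: str, what: str, lineno: int, path: str) -> list[int]:
    # UCSC writes exon lists with a trailing comma: "100,500,"
    parts = [p for p in text.strip().split(",") if p != ""]
    return [_parse_int(p, what, lineno, path) for p in parts]


def read_gene_table(path: str) -> list[TranscriptRecord]:
    """Read a UCSC Table Browser style tab-delimited transcript table.

    The header row must name at least ``name``, ``chrom``, ``strand``,
    ``txStart``, ``txEnd``, ``exonStarts``, ``exonEnds`` and ``name2`` (the
    gene symbol); column order is free and extra columns are ignored.
    """
    records: list[TranscriptRecord] = []
    with open(path) as fh:
        header_line = fh.readline()
        if not header_line:
            raise ValueError(f"{path}: empty gene table")
        header = header_line.lstrip("#").rstrip("\n").split("\t")
        col = {name: i for i, name in enumerate(header)}
        missing = [c for c in GENE_TABLE_COLUMNS if c not in col]
        if missing:
            raise ValueError(
                f"{path}: gene table is missing required column(s): "
                + ", ".join(missing)
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < len(header):
                raise ValueError(
                    f"{path}: line {lineno}: expected {len(header)} columns, "
                    f"got {len(fields)}"
                )
            exon_starts = _split_coord_list(
                fields[col["exonStarts"]], "exonStarts", lineno, path
            )
            exon_ends = _split_coord_list(
                fields[col["exonEnds"]], "exonEnds", lineno, path
            )
            rec = TranscriptRecord(
                transcript_id=fields[col["name"]],
                gene_symbol=fields[col["name2"]],
                chrom=fields[col["chrom"]],
                strand=fields[col["strand"]],
                tx_start=_parse_int(fields[col["txStart"]], "txStart", lineno, path),
                tx_end=_parse_int(fields[col["txEnd"]], "txEnd", lineno, path),
                exon_starts=exon_starts,
                exon_ends=exon_ends,
            )
            try:
                rec.validate()
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
            records.append(rec)
    return records


# ---------------------------------------------------------------------------
# model construction


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of intervals: sorted, disjoint (touching intervals merge)."""
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def build_gene_models(
    records: Sequence[TranscriptRecord],
    collapse: str = "metatranscript",
) -> list[GeneModel]:
    """Build gene models from transcript records.

    ``collapse="metatranscript"`` groups records by gene symbol and unions
    their exons; the first transcript seen fixes the gene's chromosome and
    strand, and later isoforms that disagree are dropped with a warning.
    ``collapse="per_transcript"`` turns every record into its own model
    (keyed by transcript ID), the behaviour for plain BED input.
    """
    if collapse not in ("metatranscript", "per_transcript"):
        raise ValueError(f"unknown collapse mode {collapse!r}")
    models: list[GeneModel] = []
    if collapse == "per_transcript":
        for rec in records:
            models.append(
                GeneModel(
                    gene_symbol=rec.transcript_id,
                    chrom=rec.chrom,
                    strand=rec.strand,
                    exonic_blocks=merge_intervals(rec.exons),
                )
            )
        return models

    by_gene: dict[str, dict] = {}
    for rec in records:
        entry = by_gene.get(rec.gene_symbol)
        if entry is None:
            by_gene[rec.gene_symbol] = {
                "chrom": rec.chrom,
                "strand": rec.strand,
                "exons": list(rec.exons),
            }
            continue
        if rec.chrom != entry["chrom"] or rec.strand != entry["strand"]:
            logger.warning(
                "New isoform mismatch for %s: %s:%d-%d(%s) dropped",
                rec.gene_symbol,
                rec.chrom,
                rec.tx_start,
                rec.tx_end,
                rec.strand,
            )
            continue
        entry["exons"].extend(rec.exons)
    for symbol, entry in by_gene.items():
        models.append(
            GeneModel(
                gene_symbol=symbol,
                chrom=entry["chrom"],
                strand=entry["strand"],
                exonic_blocks=merge_intervals(entry["exons"]),
            )
        )
    return models


def _extension_interval(
    model: GeneModel, w_ext: int, task: str
) -> tuple[int, int, str]:
    """Untruncated extension interval and the direction it grows in."""
    start, end = model.span
    # score3p extends past the 3' end, score5p past the 5' end;
    # genomic direction depends on the strand.
    rightward = (model.strand == "+") == (task == "score3p")
    if rightward:
        return end, end + w_ext, "right"
    return max(0, start - w_ext), start, "left"


def extend_gene_model(
    model: GeneModel,
    w_ext: int,
    task: str,
    same_strand_neighbors: Sequence[GeneModel] = (),
) -> GeneModel:
    """Append an extension of up to ``w_ext`` bases past the task end.

    The extension is truncated at the nearest same-strand neighbour's
    annotated span (abutting genes give a zero-length extension, which is
    dropped).  Opposite-strand genes never truncate.
    """
    if task not in ("score3p", "score5p"):
        raise ValueError(f"unknown task {task!r}")
    if w_ext < 0:
        raise ValueError("wExt must be >= 0")
    if w_ext == 0:
        return replace(model, extension_block=None)
    lo, hi, direction = _extension_interval(model, w_ext, task)
    for nb in same_strand_neighbors:
        if nb.chrom != model.chrom or nb.strand != model.strand:
            continue
        if nb is model or nb.span == model.span and nb.gene_symbol == model.gene_symbol:
            continue
        ns, ne = nb.span
        if direction == "right":
            if ns < hi and ne > lo:  # neighbour reaches into the extension
                hi = max(lo, min(hi, ns))
        else:
            if ns < hi and ne > lo:
                lo = min(hi, max(lo, ne))
    if hi <= lo:
        return replace(model, extension_block=None)
    return replace(model, extension_block=(lo, hi))


def extend_gene_models(
    models: Sequence[GeneModel], w_ext: int, task: str
) -> list[GeneModel]:
    """Extend every model, truncating at same-strand neighbours."""
    by_key: dict[tuple[str, str], list[GeneModel]] = {}
    for m in models:
        by_key.setdefault((m.chrom, m.strand), []).append(m)
    out = []
    for m in models:
        neighbors = by_key[(m.chrom, m.strand)]
        out.append(extend_gene_model(m, w_ext, task, neighbors))
    return out
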