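"""Multimapped-read policies.

A read aligned to N genomic loci (NH tag = N) can be counted in four ways:

* ``normal`` — every alignment counts with weight 1 at each gene it hits;
* ``scale`` — each alignment counts with weight 1/N;
* ``ignore`` — reads with N > 1 are discarded;
* ``proper`` — a multimapped read is rescued iff exactly one of its
  alignments falls inside one (extended, spliced) gene model; it is then
  assigned there with weight 1, otherwise discarded.

``proper`` mirrors a two-pass implementation (buffer multimapped records,
group by read id, re-inject the rescued ones as uniquely mapped); here the
grouping is done in memory, which is the same contract.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

from .alignments import AlignedRead, counting_position
from .annotations import GeneModel

MULTIMAP_MODES = ("normal", "scale", "ignore", "proper")
STRAND_MODES = ("same", "opposite", "ignore")


@dataclass
class WeightedAssignment:
    """One (read, gene) assignment with a counting weight."""

    read_id: str
    gene_symbol: str
    position: int  # genomic counting coordinate
    weight: float
    barcode: str | None = None
    umi: str | None = None


class GeneIndex:
    """Point lookup: which gene models contain a genomic position."""

    def __init__(self, models: Sequence[GeneModel]):
        self.models = list(models)
        # per (chrom, strand): blocks sorted by start, with a running
        # maximum of block ends to bound the leftward scan (per-transcript
        # models may overlap, so a pure bisect is not enough)
        self._by_key: dict[
            tuple[str, str], tuple[list[int], list[int], list[int], list[int]]
        ] = {}
        per_key: dict[tuple[str, str], list[tuple[int, int, int]]] = {}
        for idx, m in enumerate(self.models):
            for s, e in m.all_blocks:
                per_key.setdefault((m.chrom, m.strand), []).append((s, e, idx))
        for key, blocks in per_key.items():
            blocks.sort()
            starts = [b[0] for b in blocks]
            ends = [b[1] for b in blocks]
            idxs = [b[2] for b in blocks]
            maxend = []
            running = 0
            for e in ends:
                running = max(running, e)
                maxend.append(running)
            self._by_key[key] = (starts, ends, idxs, maxend)

    def _lookup(self, chrom: str, strand: str, pos: int) -> list[GeneModel]:
        entry = self._by_key.get((chrom, strand))
        if entry is None:
            return []
        starts, ends, idxs, maxend = entry
        hits = []
        i = bisect.bisect_right(starts, pos) - 1
        while i >= 0 and maxend[i] > pos:
            if starts[i] <= pos < ends[i]:
                hits.append(self.models[idxs[i]])
            i -= 1
        return hits

    def genes_at(
        self, chrom: str, read_strand: str, pos: int, strand_mode: str = "same"
    ) -> list[GeneModel]:
        if strand_mode not in STRAND_MODES:
            raise ValueError(f"unknown strand mode {strand_mode!r}")
        other = "-" if read_strand == "+" else "+"
        if strand_mode == "same":
            strands = [read_strand]
        elif strand_mode == "opposite":
            strands = [other]
        else:
            strands = [read_strand, other]
        hits: list[GeneModel] = []
        for st in strands:
            hits.extend(self._lookup(chrom, st, pos))
        return hits


def apply_multimap_policy(
    reads: Iterable[AlignedRead],
    mode: str,
    gene_index: GeneIndex,
    strand_mode: str = "same",
    task: str = "score3p",
) -> Iterator[WeightedAssignment]:
    """Assign reads to genes under one of the four multimapper policies."""
    if mode not in MULTIMAP_MODES:
        raise ValueError(
            f"unknown multimap mode {mode!r}; expected one of {MULTIMAP_MODES}"
        )
    # proper: buffer multimapped alignments' genic hits, grouped by read id
    buffered: dict[str, list[WeightedAssignment]] = {}
    order: list[str] = []
    for read in reads:
        if mode == "ignore" and read.nh_count > 1:
            continue
        pos = counting_position(read, task)
        genes = gene_index.genes_at(read.chrom, read.genomic_strand, pos, strand_mode)
        if mode == "proper" and read.nh_count > 1:
            if read.read_id not in buffered:
                buffered[read.read_id] = []
                order.append(read.read_id)
            for g in genes:
                buffered[read.read_id].append(
                    WeightedAssignment(
                        read_id=read.read_id,
                        gene_symbol=g.gene_symbol,
                        position=pos,
                        weight=1.0,
                        barcode=read.barcode,
                        umi=read.umi,
                    )
                )
            continue
        weight = 1.0 / read.nh_count if mode == "scale" else 1.0
        for g in genes:
            yield WeightedAssignment(
                read_id=read.read_id,
                gene_symbol=g.gene_symbol,
                position=pos,
                weight=weight,
                barcode=read.barcode,
                umi=read.umi,
            )
    if mode == "proper":
        # rescue reads whose alignments hit exactly one genic locus
        for read_id in order:
            hits = buffered[read_id]
            if len(hits) == 1:
                yield hits[0]
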