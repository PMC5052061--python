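"""Streaming of genomic alignments and per-read reductions.

End-sequencing libraries tag a fixed transcript terminus, so each alignment
is reduced to a single counting coordinate: its biological 5' terminus
(first aligned base on the + strand, last aligned base on the - strand).
Reads whose sequence contains a long A or T homopolymer are presumed to be
internal poly(A) priming artifacts and can be discarded (-filtAT).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Iterator

import pysam

logger = logging.getLogger("endseq")


@dataclass
class AlignedRead:
    """One genomic alignment with introns spliced out."""

    read_id: str
    chrom: str
    genomic_strand: str  # '+' or '-'
    aligned_blocks: list[tuple[int, int]]  # sorted, disjoint, 0-based half-open
    nh_count: int = 1
    sequence: str | None = None
    barcode: str | None = None
    umi: str | None = None

    @property
    def start(self) -> int:
        return self.aligned_blocks[0][0]

    @property
    def end(self) -> int:
        return self.aligned_blocks[-1][1]


class ExperimentSet(dict):
    """Mapping experiment id -> list of alignment file paths."""

    @classmethod
    def from_list_file(cls, path: str) -> "ExperimentSet":
        """Parse an alignment list file: one ``<experiment id>\\t<path>``
        per line; multiple lines may share an experiment id."""
        exps: "ExperimentSet" = cls()
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                if "\t" not in line:
                    raise ValueError(
                        f"{path}: line {lineno}: expected "
                        f"'<experiment id>\\t<alignment file>'"
                    )
                exp_id, file_path = line.split("\t", 1)
                exps.setdefault(exp_id, []).append(file_path)
        if not exps:
            raise ValueError(f"{path}: no experiments listed")
        return exps

    @classmethod
    def single(cls, path: str, experiment_id: str = "exp1") -> "ExperimentSet":
        return cls({experiment_id: [path]})


def _merge_touching(blocks: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[list[int]] = []
    for s, e in blocks:
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def read_alignments(
    paths: str | Iterable[str],
    sc_prep: bool = False,
) -> Iterator[AlignedRead]:
    """Stream mapped alignments from one or more SAM/BAM files.

    Unmapped records are skipped; spliced alignments are split into blocks;
    the NH tag gives the multimapping multiplicity (1 when absent, in which
    case multimapped reads cannot be identified).  With ``sc_prep`` the cell
    barcode and UMI are parsed from the read name (``<name>:<barcode>:<UMI>``);
    reads with improper names are skipped with a warning.
    """
    from .single_cell import parse_barcoded_name  # local import, no cycle at module load

    if isinstance(paths, str):
        paths = [paths]
    for path in paths:
        try:
            afile = pysam.AlignmentFile(path, check_sq=False)
        except (OSError, ValueError) as exc:
            raise OSError(f"cannot read alignment file {path}: {exc}") from exc
        with afile:
            for rec in afile:
                if rec.is_unmapped:
                    continue
                barcode = umi = None
                name = rec.query_name or ""
                if sc_prep:
                    try:
                        name, barcode, umi = parse_barcoded_name(name)
                    except ValueError:
                        logger.warning("Improper read name: %s", rec.query_name)
                        continue
                blocks = _merge_touching(rec.get_blocks())
                if not blocks:
                    continue
                try:
                    nh = int(rec.get_tag("NH"))
                except KeyError:
                    nh = 1
                yield AlignedRead(
                    read_id=name,
                    chrom=rec.reference_name,
                    genomic_strand="-" if rec.is_reverse else "+",
                    aligned_blocks=blocks,
                    nh_count=max(1, nh),
                    sequence=rec.query_sequence,
                    barcode=barcode,
                    umi=umi,
                )


def at_run_filter(read: AlignedRead, threshold: int) -> bool:
    """True when the read should be kept under the poly(A/T) filter.

    Discards reads whose sequence contains a homopolymer run of A or of T
    of length >= ``threshold`` (case-insensitive).  A read without a stored
    sequence cannot be tested and is kept with a warning.
    """
    if threshold < 1:
        raise ValueError("filtAT threshold must be >= 1")
    if not read.sequence:
        logger.warning(
            "read %s has no sequence; poly(A/T) filter not applied", read.read_id
        )
        return True
    pattern = re.compile(r"A{%d,}|T{%d,}" % (threshold, threshold), re.IGNORECASE)
    return pattern.search(read.sequence) is None


def counting_position(read: AlignedRead, task: str = "score3p") -> int:
    """The read's counting coordinate: its biological 5' alignment terminus.

    For a + strand alignment this is the first aligned base; for a - strand
    alignment the last aligned base, so that pileups accumulate at positions
    homologous in transcript coordinates on either strand.  The task does
    not change the reduction (both library types sequence into the fragment
    from the captured end); it is accepted for interface symmetry.
    """
    if read.genomic_strand == "+":
        return read.aligned_blocks[0][0]
    return read.aligned_blocks[-1][1] - 1
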