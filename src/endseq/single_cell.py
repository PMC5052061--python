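"""Single-cell barcode/UMI preprocessing.

Droplet end-sequencing protocols tag every read with a cell barcode and a
unique molecular identifier (UMI), carried here in the read name as
``<name>:<barcode>:<UMI>``.  Reads sharing (barcode, UMI, gene) are PCR
copies of one captured molecule: a single instance suffices, the rest are
discarded.  After deduplication, barcodes are split into true cells and
ambient noise either by an explicit count threshold (-bcMin) or by the knee
of the sorted log-count curve, and the cell x gene UMI matrix is subjected
to light QC (cells with too few total UMIs, genes seen in too few cells).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .multimap import WeightedAssignment

logger = logging.getLogger("endseq")


def parse_barcoded_name(read_name: str) -> tuple[str, str, str]:
    """Split ``<name>:<barcode>:<UMI>`` into (base name, barcode, UMI).

    The LAST two colon-separated fields are the UMI and the barcode — read
    names themselves may contain colons (Illumina instrument coordinates) —
    and no assumption is made about barcode or UMI length.  Raises
    ``ValueError`` when fewer than three fields are present.
    """
    fields = read_name.split(":")
    if len(fields) < 3 or not fields[-1] or not fields[-2]:
        raise ValueError(f"Improper read name: {read_name}")
    return ":".join(fields[:-2]), fields[-2], fields[-1]


def dedup_umis(
    assignments: Iterable[WeightedAssignment],
) -> tuple[list[WeightedAssignment], dict[str, int]]:
    """Remove PCR duplicates: keep the first read per (barcode, UMI, gene).

    Returns the retained assignments (input order preserved) and the
    barcode table counting retained reads per barcode.
    """
    seen: set[tuple[str, str, str]] = set()
    retained: list[WeightedAssignment] = []
    barcode_table: dict[str, int] = {}
    for a in assignments:
        if a.barcode is None or a.umi is None:
            raise ValueError(
                f"assignment for read {a.read_id} lacks barcode/UMI; "
                "was the input read with sc_prep enabled?"
            )
        key = (a.barcode, a.umi, a.gene_symbol)
        if key in seen:
            continue
        seen.add(key)
        retained.append(a)
        barcode_table[a.barcode] = barcode_table.get(a.barcode, 0) + 1
    return retained, barcode_table


def knee_threshold(counts: Sequence[int]) -> int:
    """Count threshold at the knee of the sorted log10 count curve.

    The knee is the point of maximum distance below the chord joining the
    curve's endpoints (axes normalised to [0, 1]).  Because the chord
    distance peaks just past the corner of the ambient plateau, the
    threshold is then placed inside the widest log-count gap at or above
    the knee (geometric-mean split): on a bimodal table this is the cliff
    separating true cells from ambient barcodes, and on a smooth curve the
    widest local gap keeps the threshold at the knee itself.
    """
    counts = sorted(counts, reverse=True)
    n = len(counts)
    if n < 3 or counts[0] == counts[-1]:
        return counts[-1]
    y = np.log10(np.maximum(counts, 1)).astype(float)
    x = np.arange(n, dtype=float)
    x /= x[-1]
    yn = (y - y[-1]) / (y[0] - y[-1])
    # signed distance below the chord from (0, 1) to (1, 0); the 1/sqrt(2)
    # scale is constant and does not move the argmax
    below = 1.0 - x - yn
    knee = int(np.argmax(below))
    if knee == 0:
        return counts[0]
    gaps = y[:knee] - y[1: knee + 1]
    j = int(np.argmax(gaps))
    hi, lo = counts[j], counts[j + 1]
    if hi == lo:
        return lo + 1
    return int(math.sqrt(hi * lo)) + 1


def barcode_threshold(
    table: dict[str, int], bc_min: int | None = None
) -> tuple[int, set[str]]:
    """Split barcodes into valid cells and ambient noise.

    With an explicit ``bc_min``, barcodes with at least that many
    UMI-filtered reads are valid.  Otherwise the threshold is placed at the
    knee of the sorted log-count curve.  Raises when no barcode qualifies.
    """
    if not table:
        raise ValueError("no valid cells: barcode table is empty")
    if bc_min is not None:
        threshold = bc_min
    else:
        threshold = knee_threshold(list(table.values()))
    valid = {bc for bc, c in table.items() if c >= threshold}
    if not valid:
        raise ValueError(f"no valid cells: all barcodes below threshold {threshold}")
    return threshold, valid


def build_cell_gene_matrix(
    assignments: Iterable[WeightedAssignment],
    valid_barcodes: set[str] | None = None,
) -> pd.DataFrame:
    """UMI count matrix (cells x genes) from deduplicated assignments."""
    counts: dict[tuple[str, str], int] = {}
    for a in assignments:
        if valid_barcodes is not None and a.barcode not in valid_barcodes:
            continue
        key = (a.barcode, a.gene_symbol)
        counts[key] = counts.get(key, 0) + 1
    if not counts:
        return pd.DataFrame()
    cells = sorted({bc for bc, _ in counts})
    genes = sorted({g for _, g in counts})
    mat = pd.DataFrame(0, index=cells, columns=genes, dtype=int)
    for (bc, g), c in counts.items():
        mat.at[bc, g] = c
    mat.index.name = "barcode"
    return mat


def qc_filter(
    matrix: pd.DataFrame,
    min_cell_umis: int = 1000,
    min_reads: int = 3,
    min_cells: int = 2,
) -> pd.DataFrame:
    """Drop low-coverage cells, then uninformative genes.

    Cells with fewer than ``min_cell_umis`` total UMI-filtered reads are
    removed first; then genes lacking at least ``min_reads`` UMI-filtered
    reads in at least ``min_cells`` of the remaining cells.
    """
    if matrix.empty:
        raise ValueError("QC filter applied to an empty cell x gene matrix")
    kept_cells = matrix.sum(axis=1) >= min_cell_umis
    out = matrix.loc[kept_cells]
    gene_ok = (out >= min_reads).sum(axis=0) >= min_cells
    out = out.loc[:, gene_ok]
    if out.empty:
        raise ValueError("QC filter removed all cells or all genes")
    return out


# ---------------------------------------------------------------------------
# text outputs


def write_barcode_table(table: dict[str, int], path: str) -> None:
    df = pd.DataFrame(
        sorted(table.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["barcode", "umi_filtered_reads"],
    )
    df.to_csv(path, sep="\t", index=False)


def write_cell_gene_matrix(matrix: pd.DataFrame, prefix: str) -> tuple[str, str]:
    """Write the matrix as TSV and as MatrixMarket-style triplet text."""
    tsv_path = f"{prefix}.cellgene.txt"
    mtx_path = f"{prefix}.cellgene.mtx"
    matrix.to_csv(tsv_path, sep="\t")
    with open(mtx_path, "w") as fh:
        fh.write("%%MatrixMarket matrix coordinate integer general\n")
        fh.write(f"%rows=cells cols=genes\n")
        nnz = int((matrix.values != 0).sum())
        fh.write(f"{matrix.shape[0]} {matrix.shape[1]} {nnz}\n")
        for i, bc in enumerate(matrix.index, start=1):
            row = matrix.loc[bc]
            for j, g in enumerate(matrix.columns, start=1):
                v = int(row[g])
                if v:
                    fh.write(f"{i} {j} {v}\n")
    return tsv_path, mtx_path
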