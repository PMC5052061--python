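"""Differential transcript end usage across samples.

For genes with several significant end windows, the fraction of a gene's
reads falling OUTSIDE its terminal window (the most 3' window for 3'-end
libraries, the most 5' window for 5'-end libraries) measures relative use
of shorter versus longer isoforms.  A global shift of this fraction between
a reference sample and treated samples — without any single locus changing
significantly — is the signature of a burst-associated ("telescripting")
shortening of 3' UTRs.

Genes are selected on the reference sample only: enough reads, at least
two significant windows, a terminal window carrying a meaningful share of
the reads, and reasonably balanced windows, so that a usage shift after
treatment is measurable.  The per-sample fraction distributions are then
compared with a paired (gene-matched) Wilcoxon signed-rank test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("endseq")

WINDOW_META_COLUMNS = ["Symbol", "chr", "start", "end", "strand", "pvalue"]


@dataclass
class EligibilityConfig:
    """Reference-sample filters selecting genes with testable end usage."""

    min_total_reads: float = 250.0   # discard very low expression
    min_windows: int = 2             # need alternative ends to compare
    min_final_fraction: float = 0.20  # terminal window must carry >= 20%
    max_window_ratio: float = 1.5    # max/min window counts balanced


def read_window_table(path: str) -> pd.DataFrame:
    """Load a ``<prefix>.window.txt`` table."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in WINDOW_META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: window table missing column(s): {missing}")
    return df


def sample_columns(window_df: pd.DataFrame) -> list[str]:
    return [c for c in window_df.columns if c not in WINDOW_META_COLUMNS]


def _terminal_index(gene_rows: pd.DataFrame, task: str) -> int:
    """Positional index of the gene's terminal window.

    Transcript orientation is strand-aware: for a 3'-end task on the +
    strand the terminal (most 3') window has the largest genomic start, on
    the - strand the smallest; a 5'-end task mirrors this.  Ties go to the
    window with the larger genomic extent.
    """
    strand = gene_rows["strand"].iloc[0]
    # most 3' window in transcript orientation
    want_high_coord = (strand == "+") == (task == "score3p")
    starts = gene_rows["start"].to_numpy()
    extents = (gene_rows["end"] - gene_rows["start"]).to_numpy()
    key = starts if want_high_coord else -starts
    best = np.flatnonzero(key == key.max())
    if len(best) > 1:
        best = best[np.argsort(-extents[best], kind="stable")]
    return int(best[0])


def select_testable_genes(
    window_df: pd.DataFrame,
    reference_sample: str,
    config: EligibilityConfig | None = None,
    task: str = "score3p",
) -> list[str]:
    """Genes whose end usage is testable, judged on the reference sample.

    A gene is kept iff, in the reference sample: total reads over its
    significant windows >= ``min_total_reads``; it has >= ``min_windows``
    windows; the terminal window holds >= ``min_final_fraction`` of the
    reads; and max/min window counts <= ``max_window_ratio``.
    """
    if reference_sample not in window_df.columns:
        raise ValueError(f"reference sample {reference_sample!r} not in table")
    config = config or EligibilityConfig()
    testable = []
    for gene, rows in window_df.groupby("Symbol", sort=True):
        counts = rows[reference_sample].to_numpy(dtype=float)
        total = counts.sum()
        if total < config.min_total_reads:
            continue
        if len(rows) < config.min_windows:
            continue
        term = _terminal_index(rows, task)
        if counts[term] / total < config.min_final_fraction:
            continue
        if counts.min() <= 0 or counts.max() / counts.min() > config.max_window_ratio:
            continue
        testable.append(gene)
    return testable


def end_usage_fractions(
    window_df: pd.DataFrame,
    genes: list[str] | None = None,
    task: str = "score3p",
) -> pd.DataFrame:
    """Per-gene, per-sample fraction of reads NOT in the terminal window.

    Entries are in [0, 1]; a sample with zero reads for a gene yields NaN.
    """
    samples = sample_columns(window_df)
    sub = window_df if genes is None else window_df[window_df["Symbol"].isin(genes)]
    rows = {}
    for gene, grp in sub.groupby("Symbol", sort=True):
        term = _terminal_index(grp, task)
        vals = {}
        for s in samples:
            counts = grp[s].to_numpy(dtype=float)
            total = counts.sum()
            vals[s] = 1.0 - counts[term] / total if total > 0 else np.nan
        rows[gene] = vals
    out = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
    out.index.name = "Symbol"
    return out


def shift_test(
    fractions: pd.DataFrame,
    reference_sample: str,
    paired: bool = True,
) -> pd.DataFrame:
    """Test each sample's fraction distribution against the reference.

    Paired mode (default) uses the Wilcoxon signed-rank test matched by
    gene; ``paired=False`` uses the unpaired Mann-Whitney rank-sum test.
    Returns one row per non-reference sample with the p-value and
    distribution summaries suitable for boxplots.
    """
    if reference_sample not in fractions.columns:
        raise ValueError(f"reference sample {reference_sample!r} not in matrix")
    if len(fractions.columns) < 2:
        raise ValueError("shift test needs the reference and at least one other sample")
    ref = fractions[reference_sample]
    rows = []
    for s in fractions.columns:
        if s == reference_sample:
            continue
        pair = pd.concat([ref, fractions[s]], axis=1).dropna()
        if pair.empty:
            raise ValueError(
                f"no genes with data in both {reference_sample!r} and {s!r}"
            )
        x = pair[reference_sample].to_numpy()
        y = pair[s].to_numpy()
        if paired:
            diffs = y - x
            if np.allclose(diffs, 0):
                pval = 1.0
            else:
                pval = float(stats.wilcoxon(y, x).pvalue)
        else:
            pval = float(stats.mannwhitneyu(y, x, alternative="two-sided").pvalue)
        q1, med, q3 = np.percentile(y, [25, 50, 75])
        rows.append(
            {
                "sample": s,
                "n_genes": len(pair),
                "pvalue": pval,
                "median": med,
                "mean": float(np.mean(y)),
                "q1": q1,
                "q3": q3,
                "median_shift": float(np.median(y - x)),
            }
        )
    out = pd.DataFrame(rows).set_index("sample")
    return out


def run_diffends(
    window_table_path: str,
    reference_sample: str,
    task: str = "score3p",
    config: EligibilityConfig | None = None,
    paired: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full analysis from a window table: (fractions, test results)."""
    window_df = read_window_table(window_table_path)
    genes = select_testable_genes(window_df, reference_sample, config, task)
    if not genes:
        raise ValueError("no testable genes pass the eligibility filters")
    fractions = end_usage_fractions(window_df, genes, task)
    results = shift_test(fractions, reference_sample, paired=paired)
    return fractions, results


def plot_fractions(fractions: pd.DataFrame, path: str) -> None:
    """Optional boxplot of per-sample fraction distributions."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1.2 * len(fractions.columns) + 2, 4))
    data = [fractions[c].dropna().to_numpy() for c in fractions.columns]
    ax.boxplot(data, tick_labels=list(fractions.columns))
    ax.set_ylabel("fraction of reads outside terminal window")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
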