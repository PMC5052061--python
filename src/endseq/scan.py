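"""Scan-statistic window discovery and two-pass quantification.

A gene's reads are reduced to counting positions on its spliced
(exon-union + extension) coordinate system of length L.  Under the null
that the gene's N pooled reads fall independently and uniformly on the L
positions — i.e. conditioning on the gene's expression level — the maximum
count over all w-base windows follows the (conditional, discrete) scan
statistic.  Each scanned window's count k is converted to
``P(max window count >= k)``; windows at or below the significance
threshold are consolidated and re-counted per experiment in a second pass.

The scan p-value is approximated by Poisson clumping with an exact
upcrossing rate and a declumping (extremal-index) correction:

* upcrossing rate ``P(W_j < k <= W_{j+1})`` is computed exactly from the
  trinomial joint of two adjacent window counts under the multinomial null;
* the expected number of exceedance clusters is
  ``E = P(W_1 >= k) + (L - w) * rate * theta`` where ``theta`` is the
  probability that the local sliding-window random walk (one cell leaves,
  one enters per slide) does not re-exceed its level within w slides;
* ``p = 1 - exp(-E)``, floored by the single-window tail and capped by the
  union bound, monotonised in k.

Against a Monte-Carlo oracle (1e5 placements) the approximation stays well
within a factor of 2 of the empirical tail for p >= 1e-3 over
N in 10..1000, L in 1e3..1e4, w in 50..100.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .annotations import GeneModel

logger = logging.getLogger("endseq")

#: recommended extensions: 5 kb for 3'-end libraries, 1 kb for 5'-end
RECOMMENDED_EXTENSION = {"score3p": 5000, "score5p": 1000}


@dataclass
class ScanConfig:
    """Window-scanning parameters (flag names follow the CLI)."""

    w_len: int = 50          # -wLen: scanning window length, bases
    w_olap: int = 0          # -wOlap: overlap between successive windows
    w_ext: int = 0           # -wExt: extension past the annotated end
    sig_test: float = 1.0    # -sigTest: window significance threshold
    task: str = "score3p"    # -task: score3p | score5p
    filt_at: int | None = None   # -filtAT: poly(A/T) run filter, None = off
    multimap: str = "normal"     # -multimap: normal | scale | ignore | proper
    strand_mode: str = "same"    # read/gene strand matching
    sc_prep: bool = False        # -scPrep: single-cell barcode/UMI mode
    bc_min: int | None = None    # -bcMin: minimum UMI-filtered reads/barcode

    def __post_init__(self) -> None:
        if self.w_len < 1:
            raise ValueError("wLen must be >= 1")
        if not 0 <= self.w_olap < self.w_len:
            raise ValueError("wOlap must satisfy 0 <= wOlap < wLen")
        if self.w_ext < 0:
            raise ValueError("wExt must be >= 0")
        if not 0.0 <= self.sig_test <= 1.0:
            raise ValueError("sigTest must be in [0, 1]")
        if self.task not in ("score3p", "score5p"):
            raise ValueError(f"unknown task {self.task!r}")


@dataclass
class ScanTest:
    """One scan-statistic evaluation: observed window count k out of N
    reads on L positions with window length w."""

    k: float
    N: float
    L: int
    w: int

    @property
    def lam(self) -> float:
        """Expected window count N*w/L under uniform placement."""
        return self.N * self.w / self.L


@dataclass
class WindowRecord:
    """A consolidated significant window (the unit of end discovery)."""

    gene_symbol: str
    chrom: str
    strand: str
    start: int   # genomic, 0-based half-open span of the window
    end: int
    t_start: int  # transcript-space (5'->3'), half-open
    t_end: int
    pooled_count: float
    pvalue: float
    counts: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# scan-statistic p-value


def _upcrossing_rate(N: int, L: int, w: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact single-window tail P(W1 >= k) and adjacent-window upcrossing
    probability P(W1 < k <= W2) for all k, under the multinomial null."""
    psi = w / L
    ks = np.arange(N + 1)
    tail1 = stats.binom.sf(ks - 1, N, psi)
    if w >= L or L - w == 0 or w < 1:
        return tail1, np.zeros(N + 1)
    p1 = 1.0 / L
    p2 = (w - 1) / L
    p3 = 1.0 / L
    p4 = 1.0 - p1 - p2 - p3
    xmax = int(min(N, max(10, stats.poisson.isf(1e-16, N / L) + 5)))
    if p2 > 0:
        smax = int(min(N, stats.binom.isf(1e-16, N, p2) + xmax + 5))
    else:
        smax = 0
    x1 = np.arange(xmax + 1)[:, None, None]
    s = np.arange(smax + 1)[None, :, None]
    x2 = np.arange(xmax + 1)[None, None, :]
    r = N - x1 - s - x2
    valid = r >= 0
    rr = np.where(valid, r, 0)
    logp = (
        gammaln(N + 1)
        - gammaln(x1 + 1)
        - gammaln(s + 1)
        - gammaln(x2 + 1)
        - gammaln(rr + 1)
        + x1 * math.log(p1)
        + (s * math.log(p2) if p2 > 0 else 0.0)
        + x2 * math.log(p3)
        + rr * math.log(p4)
    )
    P = np.where(valid, np.exp(logp), 0.0)
    A = np.broadcast_to(x1 + s, P.shape).ravel()      # W1 = x1 + s
    B = np.broadcast_to(s + x2, P.shape).ravel()      # W2 = s + x2
    amax = int(xmax + smax)
    M = np.zeros((amax + 1, amax + 1))
    np.add.at(M, (A, B), P.ravel())
    Ca = np.cumsum(M, axis=0)                  # prefix over W1
    Sb = np.cumsum(Ca[:, ::-1], axis=1)[:, ::-1]   # suffix over W2
    J = np.zeros(N + 1)
    kk = np.arange(1, N + 1)
    a_idx = np.minimum(kk - 1, amax)
    inb = kk <= amax
    J[1:][inb] = Sb[a_idx[inb], kk[inb]]
    return tail1, J


def _extremal_index(N: int, L: int, w: int, k: int) -> float:
    """Probability that the local sliding walk, started at an exceedance,
    does not produce a new upcrossing within w further slides.

    Per slide one cell leaves the window (count ~ Bin(k, 1/w)) and one
    enters (~ Bin(N-k, 1/(L-w))); after w slides the window content has
    fully turned over, which bounds the cluster horizon.
    """
    if k >= N or w <= 1 or L - w <= 0:
        return 1.0
    kout = np.arange(k + 1)
    pout = stats.binom.pmf(kout, k, 1.0 / w)
    nin = N - k
    kin_max = int(min(nin, stats.binom.isf(1e-12, nin, 1.0 / (L - w)) + 2))
    kin = np.arange(kin_max + 1)
    pin = stats.binom.pmf(kin, nin, 1.0 / (L - w))
    f = np.convolve(pin, pout[::-1])  # step pmf; index i -> step (i - k)
    off = -k
    hi = max(30, 4 * int(math.sqrt(k)) + 10)
    lo = -hi
    npos = hi - lo + 1  # positions lo..hi at index pos - lo
    zero_idx = -lo
    above = np.zeros(npos)  # walk never yet below its level
    below = np.zeros(npos)  # below the level, not yet returned
    above[zero_idx] = 1.0
    u = 0.0
    for _ in range(w):
        if above.sum() + below.sum() < 1e-7:
            break
        na = np.convolve(above, f)
        nb = np.convolve(below, f)
        # convolution index t -> position lo + t + off

        def _rebin(arr: np.ndarray) -> np.ndarray:
            out = np.zeros(npos)
            t0 = -off  # position lo maps to t = t0
            seg = arr[max(0, t0): t0 + npos]
            sidx = max(0, t0) - t0
            out[sidx: sidx + len(seg)] = seg
            out[-1] += arr[t0 + npos:].sum()  # clip far-above mass into hi
            return out

        na = _rebin(na)
        nb = _rebin(nb)
        u += nb[zero_idx:].sum()  # below-phase mass re-reaching the level
        above_next = np.zeros(npos)
        above_next[zero_idx:] = na[zero_idx:]
        below_next = np.zeros(npos)
        below_next[:zero_idx] = na[:zero_idx] + nb[:zero_idx]
        above, below = above_next, below_next
    return max(0.0, 1.0 - u)


@lru_cache(maxsize=64)
def _scan_tail(N: int, L: int, w: int) -> np.ndarray:
    """Monotone tail P(max w-window count >= k) for k = 0..N."""
    if N <= 0:
        return np.ones(max(N, 0) + 1)
    w = min(w, L)
    tail1, J = _upcrossing_rate(N, L, w)
    out = np.ones(N + 1)
    # k = 0, 1: the max window count is >= 1 whenever any read exists
    e0 = tail1 + (L - w) * J  # cluster rate without declumping (theta = 1)
    theta = 1.0
    for k in range(2, N + 1):
        t1 = tail1[k]
        if t1 <= 0.0:
            out[k] = 0.0
            continue
        if e0[k] >= 20.0:
            out[k] = 1.0
            continue
        if e0[k] > 1e-8:
            theta = _extremal_index(N, L, w, k)
        # else: deep tail, reuse the last transition-zone theta (conservative)
        E = t1 + (L - w) * J[k] * theta
        p = 1.0 - math.exp(-E)
        p = max(p, t1)                      # max >= k implied by W1 >= k
        p = min(p, (L - w + 1) * t1, 1.0)   # union bound over window starts
        out[k] = p
    # monotonise: spurious dips at small k (from the caps) are raised to the
    # running maximum of the more extreme tail values
    return np.maximum.accumulate(out[::-1])[::-1]


def scan_pvalue(test: ScanTest) -> float:
    """P(max window count >= k) for N uniform reads on L positions.

    Monotone non-increasing in k and non-decreasing in N at fixed k;
    returns 1 for k <= 0 or N == 0, and 0 for k > N.
    """
    N = int(round(test.N))
    k = int(math.ceil(test.k - 1e-9))
    L, w = int(test.L), int(test.w)
    if k <= 0 or N <= 0 or L <= 0:
        return 1.0
    if k > N:
        return 0.0
    if w >= L:
        return 1.0  # the single full-length window holds all N >= k reads
    return float(_scan_tail(N, L, w)[k])


# ---------------------------------------------------------------------------
# pass 1: pooled window discovery


def _transcript_counts(
    model: GeneModel, position_counts: Mapping[int, float]
) -> np.ndarray:
    """Counting-position weights on the spliced 5'->3' transcript axis."""
    L = model.effective_length
    arr = np.zeros(L)
    for pos, weight in position_counts.items():
        g = model.genomic_to_offset(pos)
        if g is None:
            continue
        t = g if model.strand == "+" else L - 1 - g
        arr[t] += weight
    return arr


def _window_starts(L: int, w_len: int, step: int) -> list[int]:
    starts = list(range(0, max(L - w_len, 0) + 1, step))
    # a trailing partial window covers the transcript end
    if starts and starts[-1] + w_len < L:
        starts.append(starts[-1] + step)
    if not starts:
        starts = [0]
    return starts


def pooled_scan(
    model: GeneModel,
    pooled_position_counts: Mapping[int, float],
    config: ScanConfig,
) -> list[tuple[int, int, float, float]]:
    """Scan the spliced transcript (plus extension) with fixed windows.

    Returns candidate windows ``(t_start, t_end, count, pvalue)`` in
    transcript coordinates whose scan p-value is at or below
    ``config.sig_test``; windows without reads are never reported.
    """
    counts = _transcript_counts(model, pooled_position_counts)
    L = model.effective_length
    N = float(counts.sum())
    if N <= 0:
        return []
    step = config.w_len - config.w_olap
    cum = np.concatenate([[0.0], np.cumsum(counts)])
    candidates = []
    for s in _window_starts(L, config.w_len, step):
        e = min(s + config.w_len, L)
        k = float(cum[e] - cum[s])
        if k <= 0:
            continue
        p = scan_pvalue(ScanTest(k=k, N=N, L=L, w=e - s))
        if p <= config.sig_test:
            candidates.append((s, e, k, p))
    return candidates


def _window_genomic_span(model: GeneModel, t0: int, t1: int) -> tuple[int, int]:
    """Genomic [start, end) of transcript window [t0, t1)."""
    L = model.effective_length
    if model.strand == "+":
        g0, g1 = t0, t1 - 1
    else:
        g0, g1 = L - t1 + 1 - 1, L - t0 - 1
    a = model.offset_to_genomic(g0)
    b = model.offset_to_genomic(g1)
    return min(a, b), max(a, b) + 1


def consolidate_windows(
    candidates: Sequence[tuple[int, int, float, float]],
    pooled_position_counts: Mapping[int, float],
    model: GeneModel,
    config: ScanConfig,
) -> list[WindowRecord]:
    """Merge runs of overlapping/adjacent significant windows and pick one
    representative window per run by a one-base sliding scan.

    Within each merged region the wLen window slides one base at a time and
    the start maximising the alignment-start count represents the region
    (ties: smallest transcript coordinate).  Isolated candidates still go
    through the same argmax, which returns them unchanged.
    """
    if not candidates:
        return []
    counts = _transcript_counts(model, pooled_position_counts)
    L = model.effective_length
    N = float(counts.sum())
    cum = np.concatenate([[0.0], np.cumsum(counts)])
    # group candidates into contiguous (overlapping or abutting) runs
    runs: list[list[int]] = []
    for s, e, _k, _p in sorted(candidates):
        if runs and s <= runs[-1][1]:
            runs[-1][1] = max(runs[-1][1], e)
        else:
            runs.append([s, e])
    records = []
    for a, b in runs:
        w = min(config.w_len, b - a)
        sums = cum[a + w: b + 1] - cum[a: b - w + 1]
        best = int(np.argmax(sums))  # argmax takes the first (5'-most) tie
        t0 = a + best
        t1 = t0 + w
        k = float(sums[best])
        p = scan_pvalue(ScanTest(k=k, N=N, L=L, w=w))
        start, end = _window_genomic_span(model, t0, t1)
        records.append(
            WindowRecord(
                gene_symbol=model.gene_symbol,
                chrom=model.chrom,
                strand=model.strand,
                start=start,
                end=end,
                t_start=t0,
                t_end=t1,
                pooled_count=k,
                pvalue=p,
            )
        )
    return records


def discover_windows(
    model: GeneModel,
    pooled_position_counts: Mapping[int, float],
    config: ScanConfig,
) -> list[WindowRecord]:
    """Pass 1 for one gene: pooled scan then consolidation."""
    cands = pooled_scan(model, pooled_position_counts, config)
    return consolidate_windows(cands, pooled_position_counts, model, config)


# ---------------------------------------------------------------------------
# pass 2: per-experiment quantification


def quantify(
    experiment_assignments: Mapping[str, Sequence],
    windows: Sequence[WindowRecord],
    models: Sequence[GeneModel],
    config: ScanConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Count each experiment's reads in the pass-1 windows and gene models.

    ``experiment_assignments`` maps experiment id -> WeightedAssignment
    sequence (from :func:`endseq.multimap.apply_multimap_policy`).  Returns
    the gene-level and window-level tables; window per-experiment counts are
    also filled into the ``WindowRecord`` objects.
    """
    exp_ids = list(experiment_assignments)
    model_by_symbol = {m.gene_symbol: m for m in models}
    gene_counts: dict[str, dict[str, float]] = {
        m.gene_symbol: {e: 0.0 for e in exp_ids} for m in models
    }
    # per gene/experiment transcript-position weights for window counting
    windows_by_gene: dict[str, list[WindowRecord]] = {}
    for wrec in windows:
        wrec.counts = {e: 0.0 for e in exp_ids}
        windows_by_gene.setdefault(wrec.gene_symbol, []).append(wrec)
    for exp_id, assignments in experiment_assignments.items():
        n_assigned = 0
        for a in assignments:
            model = model_by_symbol.get(a.gene_symbol)
            if model is None:
                continue
            gene_counts[a.gene_symbol][exp_id] += a.weight
            n_assigned += 1
            gene_windows = windows_by_gene.get(a.gene_symbol)
            if not gene_windows:
                continue
            g = model.genomic_to_offset(a.position)
            if g is None:
                continue
            L = model.effective_length
            t = g if model.strand == "+" else L - 1 - g
            for wrec in gene_windows:
                if wrec.t_start <= t < wrec.t_end:
                    wrec.counts[exp_id] += a.weight
        if n_assigned == 0:
            logger.warning("experiment %s has no surviving reads", exp_id)

    gene_rows = []
    for m in sorted(models, key=lambda m: (m.gene_symbol, m.chrom, m.span)):
        row = {"Symbol": m.gene_symbol, "chr": m.chrom, "strand": m.strand}
        row.update(gene_counts[m.gene_symbol])
        gene_rows.append(row)
    gene_df = pd.DataFrame(
        gene_rows, columns=["Symbol", "chr", "strand", *exp_ids]
    )
    window_rows = []
    for wrec in sorted(windows, key=lambda r: (r.gene_symbol, r.chrom, r.start)):
        row = {
            "Symbol": wrec.gene_symbol,
            "chr": wrec.chrom,
            "start": wrec.start,
            "end": wrec.end,
            "strand": wrec.strand,
            "pvalue": wrec.pvalue,
        }
        row.update(wrec.counts)
        window_rows.append(row)
    window_df = pd.DataFrame(
        window_rows,
        columns=["Symbol", "chr", "start", "end", "strand", "pvalue", *exp_ids],
    )
    return gene_df, window_df


def write_tables(
    gene_df: pd.DataFrame, window_df: pd.DataFrame, output_prefix: str
) -> tuple[str, str]:
    """Write ``<prefix>.gene.txt`` and ``<prefix>.window.txt``."""
    gene_path = f"{output_prefix}.gene.txt"
    window_path = f"{output_prefix}.window.txt"
    gene_df.to_csv(gene_path, sep="\t", index=False, float_format="%.6g")
    window_df.to_csv(window_path, sep="\t", index=False, float_format="%.6g")
    return gene_path, window_path
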