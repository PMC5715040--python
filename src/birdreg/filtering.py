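"""Selection of DNase I hypersensitive sites from candidate 200-bp bins.

Three filters run in order on the depth-normalized (pre-log) count matrix,
using training cell types only:

1. keep bins with normalized count > ``min_norm_count`` (default 10) in at
   least one cell type;
2. drop bins with normalized count > ``max_norm_count`` (default 10,000)
   in any cell type (abnormal signal);
3. keep bins with log2 signal-to-noise ratio > ``min_log2_snr`` (default 2)
   in at least one cell type, where the noise background of a bin is the
   log2(mean + 1) of the normalized counts over the ``snr_window_bins``
   (default 500) nearest bins on the same chromosome, excluding the bin
   itself, balanced half on each side and slid inward at chromosome ends.

All thresholds are strict inequalities. The retained index set is data
(training)-dependent and is meant to be frozen into a trained model so
test samples are never consulted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import log2_pseudocount


@dataclass
class FilterConfig:
    min_norm_count: float = 10.0
    max_norm_count: float = 10_000.0
    snr_window_bins: int = 500
    min_log2_snr: float = 2.0

    def __post_init__(self) -> None:
        if self.min_norm_count >= self.max_norm_count:
            raise ValueError("min_norm_count must be below max_norm_count")
        if self.snr_window_bins <= 0:
            raise ValueError("snr_window_bins must be positive")


@dataclass
class FilterReport:
    retained: np.ndarray                  # indices into the input bins
    exclusions: dict                      # filter name -> count excluded
    max_log2_snr: np.ndarray              # per input locus, over cell types

    def __post_init__(self) -> None:
        self.retained = np.asarray(self.retained, dtype=int)

    @property
    def n_retained(self) -> int:
        return len(self.retained)


def _window_start(pos: np.ndarray, n: int, window: int) -> np.ndarray:
    """Start of the (window+1)-wide slice containing each position.

    The slice covers ``window`` neighbors plus the bin itself; it is
    centred (window//2 on each side) and slid inward at chromosome ends.
    """
    return np.clip(pos - window // 2, 0, max(n - (window + 1), 0))


def compute_background(
    norm_counts: np.ndarray, bins: pd.DataFrame, locus: int, window: int
) -> np.ndarray:
    """Per-cell-type background log2(mean normalized count + 1) around a bin.

    The window is the ``window`` nearest bins on the locus's chromosome
    excluding the locus itself. On chromosomes with fewer than window+1
    bins all other bins are used (with a warning).
    """
    norm_counts = np.asarray(norm_counts, dtype=float)
    chrom = bins["chrom"].iloc[locus]
    on_chrom = np.flatnonzero((bins["chrom"] == chrom).to_numpy())
    pos = int(np.searchsorted(on_chrom, locus))
    n = len(on_chrom)
    if n - 1 < window:
        warnings.warn(
            f"chromosome {chrom} has only {n - 1} neighbor bins; using all of them"
        )
        idx = np.delete(on_chrom, pos)
    else:
        start = int(_window_start(np.array([pos]), n, window)[0])
        sl = on_chrom[start : start + window + 1]
        idx = sl[sl != locus]
    if idx.size == 0:
        return np.zeros(norm_counts.shape[1])
    return np.log2(norm_counts[idx].mean(axis=0) + 1.0)


def compute_log2_snr(
    norm_counts: np.ndarray, bins: pd.DataFrame, locus: int, window: int
) -> np.ndarray:
    """log2(SNR) per cell type: log2(n~ + 1) minus the window background."""
    norm_counts = np.asarray(norm_counts, dtype=float)
    signal = np.log2(norm_counts[locus] + 1.0)
    return signal - compute_background(norm_counts, bins, locus, window)


def _log2_snr_matrix(norm_counts: np.ndarray, bins: pd.DataFrame, window: int) -> np.ndarray:
    """Vectorized log2(SNR) for every bin and cell type via per-chromosome
    sliding-window sums (equivalent to compute_log2_snr bin by bin)."""
    norm_counts = np.asarray(norm_counts, dtype=float)
    out = np.empty_like(norm_counts)
    for chrom, grp in bins.groupby("chrom", sort=False):
        rows = grp.index.to_numpy()
        sub = norm_counts[rows]
        n = len(rows)
        if n - 1 < window:
            if n == 1:
                bg = np.zeros((1, sub.shape[1]))
            else:
                tot = sub.sum(axis=0, keepdims=True)
                bg = np.log2((tot - sub) / (n - 1) + 1.0)
        else:
            csum = np.vstack([np.zeros((1, sub.shape[1])), np.cumsum(sub, axis=0)])
            starts = _window_start(np.arange(n), n, window)
            win_sum = csum[starts + window + 1] - csum[starts] - sub
            bg = np.log2(win_sum / window + 1.0)
        out[rows] = np.log2(sub + 1.0) - bg
    return out


def select_dhs_loci(
    norm_counts, bins: pd.DataFrame, cfg: FilterConfig | None = None
) -> FilterReport:
    """Apply the three DHS filters in order and report exclusions.

    ``norm_counts`` must be on the depth-normalized pre-log scale with one
    column per (training) cell type, rows aligned with ``bins``.
    """
    cfg = cfg or FilterConfig()
    vals = (
        norm_counts.to_numpy(dtype=float)
        if isinstance(norm_counts, pd.DataFrame)
        else np.asarray(norm_counts, dtype=float)
    )
    bins = bins.reset_index(drop=True)
    n = vals.shape[0]
    max_count = vals.max(axis=1)

    pass_signal = max_count > cfg.min_norm_count
    pass_abnormal = max_count <= cfg.max_norm_count
    snr = _log2_snr_matrix(vals, bins, cfg.snr_window_bins)
    max_snr = snr.max(axis=1)
    pass_snr = max_snr > cfg.min_log2_snr

    excl_signal = int((~pass_signal).sum())
    excl_abnormal = int((pass_signal & ~pass_abnormal).sum())
    excl_snr = int((pass_signal & pass_abnormal & ~pass_snr).sum())
    retained = np.flatnonzero(pass_signal & pass_abnormal & pass_snr)
    return FilterReport(
        retained=retained,
        exclusions={
            "min_signal": excl_signal,
            "abnormal": excl_abnormal,
            "snr": excl_snr,
        },
        max_log2_snr=max_snr,
    )
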