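"""Matrix and interval I/O plus the signal-preprocessing primitives.

Two text formats are supported throughout the package:

``dh_bed_tsv``
    Tab-separated with a header line ``chrom  start  end  <sample> ...``.
    Coordinates are 0-based half-open; DH bins are 200 bp wide and
    non-overlapping within a chromosome.

``plain_tsv``
    A row-id column (genes or arbitrary ids) followed by one numeric
    column per sample, with a header line.

In-memory containers are plain pandas objects: a signal matrix is a
DataFrame with rows = loci/genes and columns = samples/cell types.
Raw bin counts keep their per-sample sequencing depths in
:class:`BinCountMatrix` so that depth normalization can be replayed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BIN_WIDTH = 200
DEFAULT_EXCLUDED_CHROMS = ("chrY",)


class MatrixParseError(ValueError):
    """Raised when a matrix file is malformed (message names the line)."""


# ---------------------------------------------------------------------------
# containers


@dataclass
class BinCountMatrix:
    """Raw per-bin read counts with per-sample sequencing depths.

    Parameters
    ----------
    bins : DataFrame with columns ``chrom``, ``start``, ``end``.
    counts : DataFrame (loci x samples) of non-negative integers.
    depths : per-sample total read counts ``N_i``; defaults to the column
        sums of ``counts`` when not supplied.
    """

    bins: pd.DataFrame
    counts: pd.DataFrame
    depths: pd.Series = None

    def __post_init__(self) -> None:
        if self.depths is None:
            self.depths = self.counts.sum(axis=0).astype(float)
        self.depths = pd.Series(self.depths, index=self.counts.columns, dtype=float)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("bin counts must be non-negative")
        if (self.depths <= 0).any():
            raise ValueError("all sample depths must be positive")
        validate_bins(self.bins)

    @property
    def scale_constant(self) -> float:
        """N = min_i N_i, the depth every sample is rescaled to."""
        return float(self.depths.min())

    def normalized(self) -> pd.DataFrame:
        """Depth-normalized counts: n~_li = N * n_li / N_i (pre-log scale)."""
        scale = self.scale_constant / self.depths.to_numpy()
        return self.counts.astype(float) * scale[np.newaxis, :]


@dataclass
class RowStandardizer:
    """Per-row location/scale transform fitted on a training matrix.

    Means and SDs use the population (divide-by-n) convention; the choice
    cancels in the standardize/unstandardize round trip. Rows with zero SD
    are flagged and map to 0 in the forward direction (their inverse image
    is the training mean).
    """

    row_ids: pd.Index
    means: np.ndarray
    sds: np.ndarray

    def __post_init__(self) -> None:
        if len(self.means) != len(self.row_ids) or len(self.sds) != len(self.row_ids):
            raise ValueError("means/sds length must match row_ids")
        if (self.sds < 0).any():
            raise ValueError("row SDs must be non-negative")

    @property
    def zero_variance_mask(self) -> np.ndarray:
        return self.sds == 0

    @classmethod
    def fit(cls, m: pd.DataFrame) -> "RowStandardizer":
        vals = m.to_numpy(dtype=float)
        return cls(m.index, vals.mean(axis=1), vals.std(axis=1, ddof=0))

    def transform(self, m: pd.DataFrame, direction: str = "forward") -> pd.DataFrame:
        if not m.index.equals(pd.Index(self.row_ids)):
            raise ValueError("row ids do not match the fitted standardizer")
        vals = m.to_numpy(dtype=float)
        if direction == "forward":
            out = forward_standardize(vals, self.means, self.sds)
        elif direction == "inverse":
            out = vals * self.sds[:, None] + self.means[:, None]
        else:
            raise ValueError(f"unknown direction {direction!r}")
        return pd.DataFrame(out, index=m.index, columns=m.columns)


def forward_standardize(vals: np.ndarray, means: np.ndarray, sds: np.ndarray) -> np.ndarray:
    """(x - a) / s with zero-SD rows mapped to 0. ``vals`` is rows x cols."""
    safe = np.where(sds == 0, 1.0, sds)
    out = (vals - means[..., None]) / safe[..., None]
    out[sds == 0] = 0.0
    return out


def fit_row_standardizer(m: pd.DataFrame) -> RowStandardizer:
    return RowStandardizer.fit(m)


def apply_standardizer(
    m: pd.DataFrame, std: RowStandardizer, direction: str = "forward"
) -> pd.DataFrame:
    return std.transform(m, direction)


# ---------------------------------------------------------------------------
# parsing


def validate_bins(bins: pd.DataFrame) -> None:
    """Check bins are 0-based half-open, sorted, non-overlapping per chromosome."""
    if not {"chrom", "start", "end"}.issubset(bins.columns):
        raise ValueError("bins need chrom/start/end columns")
    if (bins["end"].to_numpy() <= bins["start"].to_numpy()).any():
        raise ValueError("bins must satisfy end > start")
    for chrom, grp in bins.groupby("chrom", sort=False):
        s = grp["start"].to_numpy()
        e = grp["end"].to_numpy()
        if len(s) > 1 and (s[1:] < e[:-1]).any():
            raise ValueError(f"bins on {chrom} are unsorted or overlapping")


def _read_table(path, n_id_cols: int):
    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline()
        if not header.strip():
            raise MatrixParseError(f"{path}: no data rows")
        cols = header.rstrip("\n").split("\t")
        ids, rows = [], []
        n_cols = len(cols)
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != n_cols:
                raise MatrixParseError(
                    f"{path}:{lineno}: expected {n_cols} columns, got {len(parts)}"
                )
            try:
                rows.append([float(v) for v in parts[n_id_cols:]])
            except ValueError as err:
                raise MatrixParseError(f"{path}:{lineno}: non-numeric value ({err})") from None
            ids.append(parts[:n_id_cols])
    if not rows:
        raise MatrixParseError(f"{path}: no data rows")
    return cols, ids, np.asarray(rows, dtype=float)


def read_matrix(path, kind: str = "plain_tsv", counts: bool = False):
    """Read a matrix file.

    Parameters
    ----------
    kind : ``"dh_bed_tsv"`` (chrom/start/end + sample columns) or
        ``"plain_tsv"`` (row-id column + sample columns).
    counts : parse values as integer read counts and return a
        :class:`BinCountMatrix` (``dh_bed_tsv`` only); depths default to
        column sums.

    Returns
    -------
    ``plain_tsv`` -> DataFrame (rows x samples).
    ``dh_bed_tsv`` -> (bins DataFrame, values DataFrame), or a
    BinCountMatrix when ``counts=True``.
    """
    if kind == "plain_tsv":
        cols, ids, vals = _read_table(path, 1)
        index = pd.Index([i[0] for i in ids], name=cols[0])
        if index.has_duplicates:
            dup = index[index.duplicated()][0]
            raise MatrixParseError(f"{path}: duplicate row id {dup!r}")
        return pd.DataFrame(vals, index=index, columns=cols[1:])
    if kind == "dh_bed_tsv":
        cols, ids, vals = _read_table(path, 3)
        try:
            bins = pd.DataFrame(
                {
                    "chrom": [i[0] for i in ids],
                    "start": [int(i[1]) for i in ids],
                    "end": [int(i[2]) for i in ids],
                }
            )
        except ValueError as err:
            raise MatrixParseError(f"{path}: bad coordinate ({err})") from None
        validate_bins(bins)
        index = pd.Index(
            [f"{c}:{s}-{e}" for c, s, e in zip(bins.chrom, bins.start, bins.end)]
        )
        if index.has_duplicates:
            raise MatrixParseError(f"{path}: duplicate bin")
        values = pd.DataFrame(vals, index=index, columns=cols[3:])
        if counts:
            if not np.allclose(vals, np.round(vals)):
                raise MatrixParseError(f"{path}: count file has non-integer values")
            return BinCountMatrix(bins, values.astype(np.int64))
        return bins, values
    raise ValueError(f"unknown matrix kind {kind!r}")


def write_matrix(path, m: pd.DataFrame, bins: pd.DataFrame | None = None) -> None:
    """Write ``plain_tsv`` (default) or ``dh_bed_tsv`` when bins are given."""
    if bins is None:
        m.to_csv(path, sep="\t", index_label=m.index.name or "id")
    else:
        out = bins.reset_index(drop=True).copy()
        for c in m.columns:
            out[c] = m[c].to_numpy()
        out.to_csv(path, sep="\t", index=False)


def write_bedgraph(path, bins: pd.DataFrame, values: np.ndarray) -> None:
    out = bins.reset_index(drop=True).copy()
    out["value"] = np.asarray(values)
    out.to_csv(path, sep="\t", index=False, header=False)


# ---------------------------------------------------------------------------
# preprocessing


def log2_pseudocount(values):
    """Elementwise log2(x + 1); rejects negative input."""
    arr = np.asarray(values, dtype=float)
    if (arr < 0).any():
        raise ValueError("log2_pseudocount requires non-negative values")
    out = np.log2(arr + 1.0)
    if isinstance(values, pd.DataFrame):
        return pd.DataFrame(out, index=values.index, columns=values.columns)
    return out


def normalize_bin_counts(counts: BinCountMatrix) -> pd.DataFrame:
    """log2(N * n_li / N_i + 1): depth scaling to N = min_i N_i, then log2."""
    return log2_pseudocount(counts.normalized())


def average_replicates(m: pd.DataFrame, groups: dict) -> pd.DataFrame:
    """Average replicate columns into one column per cell type.

    ``groups`` maps every sample id to its cell type; the average is the
    arithmetic mean on whatever scale ``m`` is on (normalized counts for
    DH, processed log2 expression for arrays). Cell types keep first-seen
    order.
    """
    missing = [c for c in m.columns if c not in groups]
    if missing:
        raise ValueError(f"samples without a replicate group: {missing}")
    order: list = []
    for c in m.columns:
        if groups[c] not in order:
            order.append(groups[c])
    out = {}
    for ct in order:
        cols = [c for c in m.columns if groups[c] == ct]
        out[ct] = m[cols].mean(axis=1)
    return pd.DataFrame(out, index=m.index)


def exclude_chromosomes(
    bins: pd.DataFrame, m: pd.DataFrame, exclude=DEFAULT_EXCLUDED_CHROMS
):
    """Drop bins on excluded chromosomes (chrY by default, which is absent
    from many samples)."""
    keep = ~bins["chrom"].isin(exclude).to_numpy()
    return bins.loc[keep].reset_index(drop=True), m.loc[keep]


# ---------------------------------------------------------------------------
# quantile normalization


def _map_to_reference(values: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Replace value of rank k by ref[k]; ties get the mean of their ref span."""
    values = np.asarray(values, dtype=float)
    order = np.argsort(values, kind="stable")
    assigned = np.empty_like(values)
    assigned[order] = ref
    # ties: average the reference values across each tied block
    sorted_vals = values[order]
    boundaries = np.flatnonzero(np.diff(sorted_vals) != 0) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [len(values)]))
    out = assigned.copy()
    for s, e in zip(starts, ends):
        if e - s > 1:
            out[order[s:e]] = ref[s:e].mean()
    return out


def quantile_normalize(m: pd.DataFrame):
    """Quantile-normalize columns to their common per-rank mean.

    Returns the normalized matrix and the reference quantile vector
    (non-decreasing, one entry per row). With a single column the input is
    returned unchanged (with a warning) and its own sorted values are the
    reference.
    """
    vals = m.to_numpy(dtype=float)
    if m.shape[1] < 2:
        warnings.warn("quantile_normalize with a single column is a no-op")
        return m.copy(), np.sort(vals[:, 0])
    ref = np.sort(vals, axis=0).mean(axis=1)
    out = np.column_stack([_map_to_reference(vals[:, j], ref) for j in range(vals.shape[1])])
    return pd.DataFrame(out, index=m.index, columns=m.columns), ref


def quantile_normalize_to_reference(x, ref: np.ndarray):
    """Map a new profile onto training reference quantiles.

    Length mismatches are handled by linear interpolation of the reference
    on rank fraction, so the minimum maps to ref.min() and the maximum to
    ref.max().
    """
    ref = np.asarray(ref, dtype=float)
    if ref.size == 0:
        raise ValueError("empty reference quantiles")
    arr = np.asarray(x, dtype=float)
    n = arr.shape[0]
    if n != ref.size:
        frac = np.linspace(0.0, 1.0, n) if n > 1 else np.array([0.5])
        ref = np.interp(frac, np.linspace(0.0, 1.0, ref.size), ref)
    out = _map_to_reference(arr, ref)
    if isinstance(x, pd.Series):
        return pd.Series(out, index=x.index)
    return out
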