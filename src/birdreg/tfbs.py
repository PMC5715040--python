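"""Transcription-factor binding-site evaluation from accessibility scores.

A candidate motif site is scored by the maximum predicted accessibility
over the retained 200-bp bins it overlaps (sites hitting no retained bin
receive a -inf sentinel and rank last). Against a binary gold standard
(e.g. motif-containing reproducible ChIP-seq peaks) the module computes
the sensitivity-FDR curve and its area (AUSFC), the ROC curve and AUROC,
and predicted-site counts at requested FDR levels. Tied scores are always
processed as a block: no ordering credit is granted within a tie, and
AUROC uses the half-credit tie convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from sklearn.metrics import auc, roc_curve as _sk_roc_curve

UNSCORED = -np.inf


@dataclass
class ScoredSiteSet:
    """Motif-site intervals with accessibility scores and gold labels."""

    sites: pd.DataFrame               # chrom, start, end (0-based half-open)
    scores: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.sites) != len(self.scores) or len(self.scores) != len(self.labels):
            raise ValueError("sites, scores and labels must have equal length")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary")
        if np.isnan(self.scores).any():
            raise ValueError("scores must not be NaN")


@dataclass
class CurveMetrics:
    fdr: np.ndarray = None
    sensitivity: np.ndarray = None
    fpr: np.ndarray = None
    tpr: np.ndarray = None
    ausfc: float = np.nan
    auroc: float = np.nan
    counts_at_fdr: dict = field(default_factory=dict)


def score_sites(
    prediction: np.ndarray, bins: pd.DataFrame, sites: pd.DataFrame
) -> np.ndarray:
    """Score each site interval by the max predicted value over the bins it
    overlaps; sites overlapping no bin get -inf (ranked last)."""
    prediction = np.asarray(prediction, dtype=float)
    if len(prediction) != len(bins):
        raise ValueError("prediction length must match the bin count")
    if ((sites["end"].to_numpy() - sites["start"].to_numpy()) <= 0).any():
        raise ValueError("malformed site interval (end <= start)")
    trees: dict[str, IntervalTree] = {}
    for chrom, grp in bins.reset_index(drop=True).groupby("chrom", sort=False):
        trees[chrom] = IntervalTree.from_tuples(
            zip(grp["start"], grp["end"], grp.index)
        )
    scores = np.full(len(sites), UNSCORED)
    for i, (chrom, start, end) in enumerate(
        zip(sites["chrom"], sites["start"], sites["end"])
    ):
        tree = trees.get(chrom)
        if tree is None:
            continue
        hits = tree.overlap(start, end)
        if hits:
            scores[i] = max(prediction[h.data] for h in hits)
    return scores


def _block_sweep(scores: np.ndarray, labels: np.ndarray):
    """Cumulative TP/FP at each distinct descending-score threshold."""
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    cum_tp = np.cumsum(y)
    cum_fp = np.cumsum(1 - y)
    last = np.flatnonzero(np.diff(s) != 0)
    block_ends = np.concatenate([last, [len(s) - 1]])
    return cum_tp[block_ends], cum_fp[block_ends]


def sensitivity_fdr_curve(s: ScoredSiteSet, fdr_levels=()) -> CurveMetrics:
    """Sensitivity-versus-FDR analysis of ranked site predictions.

    At each distinct score threshold the empirical FDR = FP/(TP+FP) and
    sensitivity = TP/P are computed; "sensitivity at FDR q" is the maximum
    sensitivity over thresholds with FDR <= q, which makes the reported
    curve the monotone envelope. AUSFC is the area of that envelope over
    FDR in [0, 1].
    """
    p = int(s.labels.sum())
    n = int(len(s.labels) - p)
    if p == 0:
        raise ValueError("curve metrics need at least one positive site")
    if n == 0:
        raise ValueError("curve metrics need at least one negative site")
    tp, fp = _block_sweep(s.scores, s.labels)
    fdr = fp / (tp + fp)
    sens = tp / p

    # monotone envelope: best sensitivity attainable at each FDR budget
    order = np.argsort(fdr, kind="stable")
    env_fdr, env_sens = [], []
    best = 0.0
    for i in order:
        best = max(best, sens[i])
        if env_fdr and fdr[i] == env_fdr[-1]:
            env_sens[-1] = best
        else:
            env_fdr.append(float(fdr[i]))
            env_sens.append(best)
    env_fdr = np.asarray(env_fdr)
    env_sens = np.asarray(env_sens)

    # step integral of the right-continuous envelope over [0, 1]
    xs = np.concatenate([env_fdr, [1.0]])
    widths = np.diff(xs)
    ausfc = float((widths * env_sens).sum())

    counts = {q: count_predictions_at_fdr(s, q) for q in fdr_levels}
    return CurveMetrics(fdr=env_fdr, sensitivity=env_sens, ausfc=ausfc, counts_at_fdr=counts)


def sensitivity_at_fdr(s: ScoredSiteSet, q: float) -> float:
    """Max sensitivity over thresholds with empirical FDR <= q (0 if none)."""
    m = sensitivity_fdr_curve(s)
    ok = m.fdr <= q
    return float(m.sensitivity[ok].max()) if ok.any() else 0.0


def count_predictions_at_fdr(s: ScoredSiteSet, q: float) -> int:
    """Number of sites called at the deepest threshold with FDR <= q."""
    tp, fp = _block_sweep(s.scores, s.labels)
    fdr = fp / (tp + fp)
    ok = fdr <= q
    return int((tp + fp)[ok].max()) if ok.any() else 0


def roc_curve(s: ScoredSiteSet) -> CurveMetrics:
    """ROC sweep and AUROC (trapezoid; equals the rank statistic with
    half credit for ties)."""
    if s.labels.sum() == 0 or s.labels.sum() == len(s.labels):
        raise ValueError("ROC needs both positive and negative sites")
    finite = np.where(np.isfinite(s.scores), s.scores, np.nextafter(-np.inf, 0))
    fpr, tpr, _ = _sk_roc_curve(s.labels, finite)
    return CurveMetrics(fpr=fpr, tpr=tpr, auroc=float(auc(fpr, tpr)))


def pseudo_replicate_combine(observed, predicted):
    """Average an observed signal track with its prediction used as a
    pseudo-replicate (elementwise unweighted mean, both on log2 scale)."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted tracks differ in length")
    out = (obs + pred) / 2.0
    if isinstance(observed, pd.Series):
        return pd.Series(out, index=observed.index)
    return out
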