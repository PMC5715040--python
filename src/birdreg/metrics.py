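"""Evaluation statistics for predicted accessibility.

All matrix arguments follow the estimator orientation: rows are samples
(test cell types), columns are loci. Three headline statistics:

* r_L — cross-locus correlation: corr(pred, truth) across loci within one
  test cell type (one value per cell type);
* r_C — cross-cell-type correlation: corr(pred, truth) across cell types
  at one locus (one value per locus);
* tau — total squared prediction error scaled by the total variance of
  the truth around its grand mean.

Correlations with a zero-variance argument are reported as NaN and
excluded (but counted) in summaries — they are never coerced to 0 here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import clone


def _as_array(m) -> np.ndarray:
    return m.to_numpy(dtype=float) if isinstance(m, pd.DataFrame) else np.asarray(m, dtype=float)


def _paired_correlation(a: np.ndarray, b: np.ndarray, method: str) -> np.ndarray:
    """Row-wise correlation; zero-variance rows give NaN."""
    if method == "spearman":
        a = np.apply_along_axis(stats.rankdata, 1, a)
        b = np.apply_along_axis(stats.rankdata, 1, b)
    elif method != "pearson":
        raise ValueError(f"unknown correlation method {method!r}")
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    denom = np.sqrt((ac**2).sum(axis=1) * (bc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (ac * bc).sum(axis=1) / denom
    r[denom == 0] = np.nan
    return r


def cross_locus_correlation(pred, truth, method: str = "pearson") -> np.ndarray:
    """r_L per test cell type (across loci)."""
    p, t = _as_array(pred), _as_array(truth)
    if p.shape != t.shape:
        raise ValueError("pred and truth shapes differ")
    return _paired_correlation(p, t, method)


def cross_cell_correlation(pred, truth, method: str = "pearson") -> np.ndarray:
    """r_C per locus (across test cell types)."""
    p, t = _as_array(pred), _as_array(truth)
    if p.shape != t.shape:
        raise ValueError("pred and truth shapes differ")
    if p.shape[0] < 3:
        raise ValueError("r_C needs at least 3 test cell types")
    return _paired_correlation(p.T, t.T, method)


def squared_prediction_error(pred, truth) -> float:
    """tau = sum (y - yhat)^2 / sum (y - ybar)^2 with ybar the grand mean
    of the truth over all loci and test cell types."""
    p, t = _as_array(pred), _as_array(truth)
    if p.shape != t.shape:
        raise ValueError("pred and truth shapes differ")
    denom = ((t - t.mean()) ** 2).sum()
    if denom == 0:
        raise ValueError("truth is constant; tau is undefined")
    return float(((t - p) ** 2).sum() / denom)


@dataclass
class EvaluationReport:
    r_l: np.ndarray
    r_c: np.ndarray
    tau: float
    grand_mean: float
    method: str = "pearson"

    @property
    def mean_r_l(self) -> float:
        return float(np.nanmean(self.r_l))

    @property
    def mean_r_c(self) -> float:
        return float(np.nanmean(self.r_c))

    @property
    def n_undefined_r_c(self) -> int:
        return int(np.isnan(self.r_c).sum())

    def summary(self) -> dict:
        return {
            "mean_r_l": self.mean_r_l,
            "mean_r_c": self.mean_r_c,
            "tau": self.tau,
            "n_undefined_r_l": int(np.isnan(self.r_l).sum()),
            "n_undefined_r_c": self.n_undefined_r_c,
            "method": self.method,
        }


def evaluate_predictions(pred, truth, method: str = "pearson") -> EvaluationReport:
    t = _as_array(truth)
    return EvaluationReport(
        r_l=cross_locus_correlation(pred, truth, method),
        r_c=cross_cell_correlation(pred, truth, method),
        tau=squared_prediction_error(pred, truth),
        grand_mean=float(t.mean()),
        method=method,
    )


def permutation_baseline(
    X_train,
    Y_train,
    X_test,
    Y_test,
    estimator,
    n_permutations: int = 10,
    random_state: int | None = None,
    method: str = "pearson",
):
    """Random prediction models by cell-type-label permutation.

    Each replicate permutes the cell-type labels (sample rows) of the
    training DH matrix — breaking the expression/DH pairing — retrains a
    clone of ``estimator``, and evaluates on the test set. Returns
    (per-replicate reports, dict of averaged summary statistics).
    """
    rng = np.random.default_rng(random_state)
    Yt = Y_train.to_numpy() if isinstance(Y_train, pd.DataFrame) else np.asarray(Y_train)
    reports = []
    for _ in range(n_permutations):
        perm = rng.permutation(Yt.shape[0])
        est = clone(estimator)
        est.fit(_as_array(X_train), Yt[perm])
        pred = est.predict(_as_array(X_test))
        reports.append(evaluate_predictions(pred, Y_test, method))
    means = {
        "mean_r_l": float(np.mean([r.mean_r_l for r in reports])),
        "mean_r_c": float(np.mean([r.mean_r_c for r in reports])),
        "tau": float(np.mean([r.tau for r in reports])),
    }
    return reports, means


# ---------------------------------------------------------------------------
# differential accessibility


@dataclass
class DifferentialResult:
    delta_pred: np.ndarray
    delta_true: np.ndarray
    differential_mask: np.ndarray
    r_all: float
    r_differential: float          # NaN when the differential set is empty


def differential_dh(
    pred_a,
    pred_b,
    truth_a,
    truth_b,
    active_threshold: float = 2.0,
    diff_threshold: float = 1.0,
) -> DifferentialResult:
    """Differential-accessibility evaluation between two cell types.

    delta-hat = pred_a - pred_b is correlated with delta = truth_a -
    truth_b over all loci, and separately over "differential" loci: those
    with log2 DH >= ``active_threshold`` in at least one of the two cell
    types and |delta| > ``diff_threshold``.
    """
    pa, pb = np.asarray(pred_a, float), np.asarray(pred_b, float)
    ta, tb = np.asarray(truth_a, float), np.asarray(truth_b, float)
    if not (pa.shape == pb.shape == ta.shape == tb.shape):
        raise ValueError("all four vectors must share the same loci")
    d_pred, d_true = pa - pb, ta - tb
    active = (ta >= active_threshold) | (tb >= active_threshold)
    mask = active & (np.abs(d_true) > diff_threshold)
    r_all = _paired_correlation(d_pred[None, :], d_true[None, :], "pearson")[0]
    if mask.sum() >= 2:
        r_diff = _paired_correlation(
            d_pred[None, mask], d_true[None, mask], "pearson"
        )[0]
    else:
        r_diff = np.nan
    return DifferentialResult(d_pred, d_true, mask, float(r_all), float(r_diff))


def stratify_pairs_by_similarity(truth) -> pd.DataFrame:
    """Group cell-type pairs into quartile strata of DH-profile similarity.

    Similarity of a pair is the Pearson correlation of their true DH
    profiles across all loci. Stratum 0 holds the least similar quartile;
    values tied with a quartile edge fall into the lower stratum.
    """
    t = _as_array(truth)
    n = t.shape[0]
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    if len(pairs) < 4:
        raise ValueError("need at least 4 cell-type pairs to form quartiles")
    sims = np.array(
        [_paired_correlation(t[i][None], t[j][None], "pearson")[0] for i, j in pairs]
    )
    edges = np.quantile(sims, [0.25, 0.5, 0.75])
    strata = (sims[:, None] > edges[None, :]).sum(axis=1)
    ids = None
    if isinstance(truth, pd.DataFrame):
        ids = [(truth.index[i], truth.index[j]) for i, j in pairs]
    return pd.DataFrame(
        {
            "cell_a": [p[0] for p in (ids or pairs)],
            "cell_b": [p[1] for p in (ids or pairs)],
            "similarity": sims,
            "stratum": strata,
        }
    )


def stratify_loci(truth, active_threshold: float = 2.0) -> pd.DataFrame:
    """Classify loci by factors that drive cross-cell-type predictability.

    A locus active (log2 DH >= threshold) in no test cell type is "noisy".
    Non-noisy loci are split at the median into low/high classes of:
    max-min spread, coefficient of variation (SD/mean), and cell-type
    specificity, operationalized as min(#active, #inactive) so that both
    broadly shared and broadly absent signals count as unspecific.
    """
    t = _as_array(truth)  # samples x loci
    active = t >= active_threshold
    n_active = active.sum(axis=0)
    noisy = n_active == 0
    spread = t.max(axis=0) - t.min(axis=0)
    mean = t.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = t.std(axis=0, ddof=0) / mean
    specificity = np.minimum(n_active, t.shape[0] - n_active)
    out = pd.DataFrame(
        {
            "noisy": noisy,
            "spread": spread,
            "cv": cv,
            "specificity": specificity,
        }
    )
    if isinstance(truth, pd.DataFrame):
        out.index = truth.columns
    for col in ("spread", "cv", "specificity"):
        cls = np.full(t.shape[1], "", dtype=object)
        vals = out.loc[~noisy, col]
        med = vals.median()
        cls[~noisy] = np.where(vals <= med, "low", "high")
        out[f"{col}_class"] = cls
    return out
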