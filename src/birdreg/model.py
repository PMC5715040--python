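"""The BIRD estimator: big-data regression from expression to DNase I
hypersensitivity.

The model predicts the DH level of every retained genomic locus from a
single gene-expression profile. Training proceeds on row-standardized
matrices (genes x cell types and loci x cell types):

1. genes are grouped into K clusters by k-means (Euclidean distance) and
   each expression profile is reduced to the K cluster means X-bar;
2. *locus-level model* — for each locus, the N gene clusters whose mean
   expression correlates most strongly with the locus's DH profile across
   training cell types are screened in, and an ordinary least-squares
   regression on those N cluster means is fitted;
3. *pathway-level models* — loci are themselves k-means clustered into H
   "DHS pathways" for each H in ``pathway_sizes``; the mean DH of each
   pathway is regressed on gene-cluster means exactly as in step 2, and a
   pathway's predicted activity serves as a (biased, low-variance)
   prediction for each member locus;
4. *aggregation* — the final standardized prediction for locus l is the
   weighted average (sum_H d_l^H Yhat_l^(H)) / (sum_H d_l^H) over the
   pathway layers plus the locus-level layer, where d_l^H is the Pearson
   correlation between the locus's standardized training profile and its
   pathway's mean profile, and the locus-level weight is identically 1.

Predictions are returned on the normalized log2 DH scale via the stored
per-locus unstandardization (s_l * y + a_l).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.cluster import KMeans
from sklearn.utils.validation import check_is_fitted

from .io import (
    RowStandardizer,
    forward_standardize,
    quantile_normalize_to_reference,
)

ARCHIVE_FORMAT_VERSION = 1


# ---------------------------------------------------------------------------
# numerical primitives


def zscore_rows(m: np.ndarray) -> np.ndarray:
    """Row z-scores with the n-denominator; zero-variance rows become 0."""
    m = np.asarray(m, dtype=float)
    return forward_standardize(m, m.mean(axis=1), m.std(axis=1, ddof=0))


def pearson_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation of two equally shaped matrices.

    Any row pair involving a zero-variance vector gets correlation 0 (the
    package-wide convention for degenerate correlations inside the model).
    """
    az, bz = zscore_rows(a), zscore_rows(b)
    return (az * bz).mean(axis=1)


def correlation_matrix(rows_a: np.ndarray, rows_b: np.ndarray) -> np.ndarray:
    """Pearson correlations between every row of ``rows_a`` and of ``rows_b``
    across columns (zero-variance rows correlate 0)."""
    az, bz = zscore_rows(rows_a), zscore_rows(rows_b)
    return az @ bz.T / az.shape[1]


def cluster_rows_kmeans(
    m: np.ndarray, k: int, seed: int, restarts: int = 3, max_iter: int = 300
):
    """k-means on matrix rows; returns (labels, cluster-mean matrix).

    Empty clusters are removed and ids re-indexed contiguously; the
    returned means are recomputed as the arithmetic mean of member rows
    (not the solver's centers), so mean rows satisfy the cluster-mean
    definition exactly. Deterministic given the seed.
    """
    m = np.asarray(m, dtype=float)
    if k > m.shape[0]:
        raise ValueError(f"k={k} exceeds the number of rows {m.shape[0]}")
    km = KMeans(
        n_clusters=k, n_init=restarts, max_iter=max_iter, random_state=int(seed)
    ).fit(m)
    labels = km.labels_
    present = np.unique(labels)
    remap = np.full(k, -1, dtype=int)
    remap[present] = np.arange(len(present))
    labels = remap[labels]
    means = np.stack([m[labels == j].mean(axis=0) for j in range(len(present))])
    return labels, means


def screen_predictors(
    response_row: np.ndarray, cluster_means: np.ndarray, n_keep: int
) -> np.ndarray:
    """Ids of the ``n_keep`` clusters with the largest |Pearson r| to the
    response across training cell types (ties broken by lower id)."""
    r = correlation_matrix(np.atleast_2d(response_row), cluster_means)[0]
    order = np.argsort(-np.abs(r), kind="stable")
    return order[:n_keep]


def screen_predictors_batch(
    responses: np.ndarray, cluster_means: np.ndarray, n_keep: int
) -> np.ndarray:
    """Vectorized screening for many responses; rows of the result are the
    selected cluster ids in rank order."""
    r = correlation_matrix(responses, cluster_means)
    return np.argsort(-np.abs(r), axis=1, kind="stable")[:, :n_keep]


def fit_linear_model(y: np.ndarray, x_rows: np.ndarray):
    """OLS of a response vector on predictor rows (plus intercept).

    Returns (intercept, coefficients). Rank-deficient designs get the
    minimum-norm least-squares solution; with no usable predictors the fit
    degenerates to the intercept-only model (the mean).
    """
    y = np.asarray(y, dtype=float)
    x_rows = np.atleast_2d(np.asarray(x_rows, dtype=float))
    if x_rows.size == 0:
        return float(y.mean()), np.zeros(0)
    design = np.column_stack([np.ones(len(y)), x_rows.T])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return float(beta[0]), beta[1:]


def _fit_models_batch(
    responses: np.ndarray, cluster_means: np.ndarray, selected: np.ndarray
):
    """Per-row OLS on each row's selected cluster-mean predictors."""
    n, n_keep = selected.shape
    intercepts = np.empty(n)
    coefs = np.empty((n, n_keep))
    for i in range(n):
        b0, b = fit_linear_model(responses[i], cluster_means[selected[i]])
        intercepts[i] = b0
        coefs[i] = b
    return intercepts, coefs


def aggregate_predictions(
    locus_pred: np.ndarray,
    pathway_preds: dict,
    weights: dict,
    clamp_weights: bool = True,
) -> np.ndarray:
    """Weighted per-locus average of the locus-level and pathway-level
    predictions, with the locus-level weight fixed at 1.

    With ``clamp_weights`` (default) negative correlations are clamped to 0
    before averaging, which keeps the denominator >= 1 and makes the output
    a convex combination of the component predictions.
    """
    num = np.array(locus_pred, dtype=float, copy=True)
    den = np.ones_like(num)
    for h, pred in pathway_preds.items():
        w = np.asarray(weights[h], dtype=float)
        if clamp_weights:
            w = np.maximum(w, 0.0)
        num += w * pred
        den += w
    return num / den


@dataclass
class PathwayLayer:
    """One pathway-level model: loci clustered into ``size`` DHS pathways,
    a regression per pathway, and per-locus aggregation weights."""

    size: int                       # requested H
    labels: np.ndarray              # locus -> pathway id (contiguous)
    selected: np.ndarray            # (H', N) screened gene-cluster ids
    intercepts: np.ndarray          # (H',)
    coefs: np.ndarray               # (H', N)
    weights: np.ndarray             # (L,) d_l^H, stored pre-clamp

    @property
    def n_clusters(self) -> int:
        return len(self.intercepts)


# ---------------------------------------------------------------------------
# estimator


class BIRD(RegressorMixin, BaseEstimator):
    """Predict genome-wide chromatin accessibility from gene expression.

    Follows the scikit-learn convention: rows of ``X`` and ``Y`` are
    samples (cell types), columns are genes and loci respectively.

    Parameters
    ----------
    n_gene_clusters : K, number of k-means gene clusters used as the
        predictor pool (field-scale default 1500; reduce for small data).
    n_predictors : N, predictors screened in per regression (default 7).
    pathway_sizes : iterable of H values for the pathway-level models
        (default (1000, 2000, 5000)); entries above the locus count are
        clipped to it (with a warning), the empty tuple disables the
        pathway layers and leaves the pure locus-level model.
    clamp_weights : clamp negative aggregation weights d_l^H to 0.
    map_to_training_quantiles : at predict time, quantile-normalize each
        incoming profile onto the training reference quantiles.
    kmeans_restarts, kmeans_max_iter : k-means configuration (best of
        ``restarts`` seeded initializations).
    random_state : integer seed; training is deterministic given it.

    Attributes
    ----------
    gene_ids_, locus_ids_ : training column labels.
    reference_quantiles_ : per-rank mean of sorted training expression.
    gene_standardizer_, locus_standardizer_ : row location/scale params.
    gene_labels_ : gene -> cluster assignment.
    cluster_means_ : (K', C) standardized training cluster-mean matrix.
    locus_selected_, locus_intercepts_, locus_coefs_ : locus-level models.
    pathway_layers_ : dict H -> :class:`PathwayLayer`.
    """

    def __init__(
        self,
        n_gene_clusters: int = 1500,
        n_predictors: int = 7,
        pathway_sizes=(1000, 2000, 5000),
        clamp_weights: bool = True,
        map_to_training_quantiles: bool = True,
        kmeans_restarts: int = 3,
        kmeans_max_iter: int = 300,
        random_state: int | None = None,
    ):
        self.n_gene_clusters = n_gene_clusters
        self.n_predictors = n_predictors
        self.pathway_sizes = pathway_sizes
        self.clamp_weights = clamp_weights
        self.map_to_training_quantiles = map_to_training_quantiles
        self.kmeans_restarts = kmeans_restarts
        self.kmeans_max_iter = kmeans_max_iter
        self.random_state = random_state

    # -- helpers ---------------------------------------------------------

    @staticmethod
    def _to_matrix(data, what: str):
        if isinstance(data, pd.DataFrame):
            return data.to_numpy(dtype=float), pd.Index(data.columns)
        arr = np.asarray(data, dtype=float)
        if arr.ndim != 2:
            raise ValueError(f"{what} must be 2-D (samples x features)")
        return arr, pd.Index([f"{what}{i}" for i in range(arr.shape[1])])

    def _seeds(self, n: int) -> np.ndarray:
        ss = np.random.SeedSequence(self.random_state)
        return ss.generate_state(n) % (2**31)

    # -- fitting ---------------------------------------------------------

    def fit(self, X, Y):
        """Train on expression ``X`` (C x G) and DH signal ``Y`` (C x L),
        both on the normalized log2 scale with matching sample rows."""
        Xm, gene_ids = self._to_matrix(X, "gene")
        Ym, locus_ids = self._to_matrix(Y, "locus")
        if Xm.shape[0] != Ym.shape[0]:
            raise ValueError("X and Y must cover the same cell types (rows)")
        if isinstance(X, pd.DataFrame) and isinstance(Y, pd.DataFrame):
            if not X.index.equals(Y.index):
                raise ValueError("X and Y sample ids differ or are misaligned")
        if Xm.shape[0] < 2:
            raise ValueError("training requires at least 2 cell types")
        if self.n_predictors < 1 or self.n_gene_clusters < self.n_predictors:
            raise ValueError("need n_gene_clusters >= n_predictors >= 1")

        expr = Xm.T  # genes x cell types
        dh = Ym.T    # loci x cell types
        self.gene_ids_, self.locus_ids_ = gene_ids, locus_ids
        self.n_training_cell_types_ = Xm.shape[0]

        # per-sample sorted expression, averaged across samples -> reference
        self.reference_quantiles_ = np.sort(expr, axis=0).mean(axis=1)
        self.gene_standardizer_ = RowStandardizer(
            gene_ids, expr.mean(axis=1), expr.std(axis=1, ddof=0)
        )
        self.locus_standardizer_ = RowStandardizer(
            locus_ids, dh.mean(axis=1), dh.std(axis=1, ddof=0)
        )
        expr_std = forward_standardize(
            expr, self.gene_standardizer_.means, self.gene_standardizer_.sds
        )
        dh_std = forward_standardize(
            dh, self.locus_standardizer_.means, self.locus_standardizer_.sds
        )

        sizes = list(dict.fromkeys(int(h) for h in self.pathway_sizes))
        seeds = self._seeds(1 + len(sizes))

        self.gene_labels_, self.cluster_means_ = cluster_rows_kmeans(
            expr_std,
            self.n_gene_clusters,
            seeds[0],
            self.kmeans_restarts,
            self.kmeans_max_iter,
        )
        n_keep = min(self.n_predictors, self.cluster_means_.shape[0])

        # locus-level models
        self.locus_selected_ = screen_predictors_batch(dh_std, self.cluster_means_, n_keep)
        self.locus_intercepts_, self.locus_coefs_ = _fit_models_batch(
            dh_std, self.cluster_means_, self.locus_selected_
        )

        # pathway-level models
        L = dh_std.shape[0]
        self.pathway_layers_ = {}
        for h_req, seed in zip(sizes, seeds[1:]):
            if h_req < 1:
                raise ValueError("pathway sizes must be >= 1")
            h = h_req
            if h > L:
                warnings.warn(f"pathway size {h} clipped to the locus count {L}")
                h = L
            if h in self.pathway_layers_:
                continue
            self.pathway_layers_[h] = self._fit_pathway_layer(dh_std, h, seed, n_keep)
        return self

    def _fit_pathway_layer(self, dh_std, h, seed, n_keep) -> PathwayLayer:
        L = dh_std.shape[0]
        if h == L:
            # singleton pathways: the layer coincides with the locus-level
            # model and every aggregation weight is exactly 1
            return PathwayLayer(
                size=h,
                labels=np.arange(L),
                selected=self.locus_selected_.copy(),
                intercepts=self.locus_intercepts_.copy(),
                coefs=self.locus_coefs_.copy(),
                weights=np.ones(L),
            )
        labels, means = cluster_rows_kmeans(
            dh_std, h, seed, self.kmeans_restarts, self.kmeans_max_iter
        )
        selected = screen_predictors_batch(means, self.cluster_means_, n_keep)
        intercepts, coefs = _fit_models_batch(means, self.cluster_means_, selected)
        weights = pearson_rows(dh_std, means[labels])
        return PathwayLayer(h, labels, selected, intercepts, coefs, weights)

    # -- prediction ------------------------------------------------------

    def prepare_sample(self, x, gene_index: pd.Index | None = None) -> np.ndarray:
        """Map one raw expression profile to the standardized gene-cluster
        mean vector X-bar (length K').

        The profile is aligned to the model's gene list by id (when ids are
        available), quantile-normalized onto the training reference, and
        standardized with the training per-gene mean/SD. Genes missing from
        the sample are imputed at the training mean (standardized 0); an
        error is raised when fewer than half the model's genes are present.
        """
        check_is_fitted(self, "cluster_means_")
        if isinstance(x, pd.Series):
            gene_index, x = pd.Index(x.index), x.to_numpy(dtype=float)
        x = np.asarray(x, dtype=float)
        G = len(self.gene_ids_)
        if gene_index is None:
            if len(x) != G:
                raise ValueError(f"profile has {len(x)} genes, model expects {G}")
            present = np.arange(G)
            values = x
        else:
            pos = self.gene_ids_.get_indexer(gene_index)
            keep = pos >= 0
            present, values = pos[keep], x[keep]
            frac = len(present) / G
            if frac < 0.5:
                raise ValueError(
                    f"only {frac:.0%} of model genes present in the sample"
                )
            if frac < 1.0:
                warnings.warn(
                    f"{1 - frac:.1%} of model genes missing; imputing their "
                    "training mean"
                )
        if self.map_to_training_quantiles:
            values = quantile_normalize_to_reference(values, self.reference_quantiles_)
        std = forward_standardize(
            values[None, :].T,
            self.gene_standardizer_.means[present],
            self.gene_standardizer_.sds[present],
        )[:, 0]
        full = np.zeros(G)
        full[present] = std
        k = self.cluster_means_.shape[0]
        sums = np.bincount(self.gene_labels_, weights=full, minlength=k)
        counts = np.bincount(self.gene_labels_, minlength=k)
        return sums / counts

    def predict_locus_level(self, xbar: np.ndarray) -> np.ndarray:
        """Standardized locus-level predictions for one X-bar vector."""
        check_is_fitted(self, "locus_coefs_")
        return self.locus_intercepts_ + np.einsum(
            "ln,ln->l", self.locus_coefs_, xbar[self.locus_selected_]
        )

    def predict_pathway_activity(self, xbar: np.ndarray, h: int) -> np.ndarray:
        """Standardized predicted activity of each DHS pathway of layer h."""
        layer = self._layer(h)
        return layer.intercepts + np.einsum(
            "cn,cn->c", layer.coefs, xbar[layer.selected]
        )

    def predict_pathway_level(self, xbar: np.ndarray, h: int) -> np.ndarray:
        """Per-locus standardized prediction from pathway layer h (each
        locus receives its pathway's predicted activity)."""
        layer = self._layer(h)
        return self.predict_pathway_activity(xbar, h)[layer.labels]

    def _layer(self, h: int) -> PathwayLayer:
        check_is_fitted(self, "pathway_layers_")
        if h not in self.pathway_layers_:
            raise KeyError(f"no pathway layer with H={h}; have {sorted(self.pathway_layers_)}")
        return self.pathway_layers_[h]

    def predict_standardized(self, X) -> np.ndarray:
        """Aggregated predictions on the standardized scale (samples x loci)."""
        check_is_fitted(self, "cluster_means_")
        if isinstance(X, pd.Series):
            X = X.to_frame().T
        if isinstance(X, pd.DataFrame):
            rows = [self.prepare_sample(X.iloc[i]) for i in range(len(X))]
        else:
            arr = np.atleast_2d(np.asarray(X, dtype=float))
            rows = [self.prepare_sample(arr[i]) for i in range(arr.shape[0])]
        out = np.empty((len(rows), len(self.locus_ids_)))
        for i, xbar in enumerate(rows):
            locus_pred = self.predict_locus_level(xbar)
            pathway_preds = {
                h: self.predict_pathway_level(xbar, h) for h in self.pathway_layers_
            }
            weights = {h: layer.weights for h, layer in self.pathway_layers_.items()}
            out[i] = aggregate_predictions(
                locus_pred, pathway_preds, weights, self.clamp_weights
            )
        return out

    def predict(self, X):
        """Predict DH on the normalized log2 scale (samples x loci)."""
        std = self.predict_standardized(X)
        s, a = self.locus_standardizer_.sds, self.locus_standardizer_.means
        vals = std * s[None, :] + a[None, :]
        if isinstance(X, pd.DataFrame):
            return pd.DataFrame(vals, index=X.index, columns=self.locus_ids_)
        return vals

    def pathway_activity_truth(self, Y, h: int) -> np.ndarray:
        """Observed standardized pathway activities (samples x H') for DH
        matrix ``Y``, using the training standardizer and layer-h pathways."""
        layer = self._layer(h)
        Ym, _ = self._to_matrix(Y, "locus")
        dh_std = forward_standardize(
            Ym.T, self.locus_standardizer_.means, self.locus_standardizer_.sds
        )
        k = layer.n_clusters
        counts = np.bincount(layer.labels, minlength=k)
        out = np.empty((Ym.shape[0], k))
        for i in range(Ym.shape[0]):
            out[i] = np.bincount(layer.labels, weights=dh_std[:, i], minlength=k) / counts
        return out

    # -- persistence -----------------------------------------------------

    def save(self, path) -> None:
        """Write the fitted model to a directory (JSON manifest + one NPZ
        of numeric tables). The archive round-trips predictions exactly."""
        check_is_fitted(self, "cluster_means_")
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        manifest = {
            "format_version": ARCHIVE_FORMAT_VERSION,
            "params": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in self.get_params().items()
            },
            "gene_ids": [str(g) for g in self.gene_ids_],
            "locus_ids": [str(l) for l in self.locus_ids_],
            "pathway_sizes_fitted": sorted(self.pathway_layers_),
            "n_training_cell_types": int(self.n_training_cell_types_),
        }
        (path / "manifest.json").write_text(json.dumps(manifest, indent=1))
        arrays = {
            "reference_quantiles": self.reference_quantiles_,
            "gene_means": self.gene_standardizer_.means,
            "gene_sds": self.gene_standardizer_.sds,
            "locus_means": self.locus_standardizer_.means,
            "locus_sds": self.locus_standardizer_.sds,
            "gene_labels": self.gene_labels_,
            "cluster_means": self.cluster_means_,
            "locus_selected": self.locus_selected_,
            "locus_intercepts": self.locus_intercepts_,
            "locus_coefs": self.locus_coefs_,
        }
        for h, layer in self.pathway_layers_.items():
            for name in ("labels", "selected", "intercepts", "coefs", "weights"):
                arrays[f"pathway_{h}_{name}"] = getattr(layer, name)
        np.savez(path / "arrays.npz", **arrays)

    @classmethod
    def load(cls, path) -> "BIRD":
        path = Path(path)
        manifest = json.loads((path / "manifest.json").read_text())
        params = manifest["params"]
        if isinstance(params.get("pathway_sizes"), list):
            params["pathway_sizes"] = tuple(params["pathway_sizes"])
        model = cls(**params)
        with np.load(path / "arrays.npz") as z:
            arrays = {k: z[k] for k in z.files}
        model.gene_ids_ = pd.Index(manifest["gene_ids"])
        model.locus_ids_ = pd.Index(manifest["locus_ids"])
        model.n_training_cell_types_ = manifest["n_training_cell_types"]
        model.reference_quantiles_ = arrays["reference_quantiles"]
        model.gene_standardizer_ = RowStandardizer(
            model.gene_ids_, arrays["gene_means"], arrays["gene_sds"]
        )
        model.locus_standardizer_ = RowStandardizer(
            model.locus_ids_, arrays["locus_means"], arrays["locus_sds"]
        )
        model.gene_labels_ = arrays["gene_labels"]
        model.cluster_means_ = arrays["cluster_means"]
        model.locus_selected_ = arrays["locus_selected"]
        model.locus_intercepts_ = arrays["locus_intercepts"]
        model.locus_coefs_ = arrays["locus_coefs"]
        model.pathway_layers_ = {}
        for h in manifest["pathway_sizes_fitted"]:
            model.pathway_layers_[int(h)] = PathwayLayer(
                size=int(h),
                labels=arrays[f"pathway_{h}_labels"],
                selected=arrays[f"pathway_{h}_selected"],
                intercepts=arrays[f"pathway_{h}_intercepts"],
                coefs=arrays[f"pathway_{h}_coefs"],
                weights=arrays[f"pathway_{h}_weights"],
            )
        return model
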