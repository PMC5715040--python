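"""Baseline: predict a locus's accessibility from its nearest genes.

Instead of screening the whole transcriptome, each locus is regressed on
the standardized expression of the ``n_genes`` genes whose transcription
start sites lie closest to the locus center (strand ignored; ties broken
by lower TSS coordinate, then gene id). This is the classical local model
that the whole-transcriptome regression is compared against.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .io import RowStandardizer, forward_standardize, quantile_normalize_to_reference
from .model import _fit_models_batch


def nearest_genes(locus_center: float, annotation: pd.DataFrame, n: int) -> list:
    """Ids of the n genes with smallest |TSS - locus center|.

    Ties are broken by lower TSS coordinate, then by gene id. Asking for
    more genes than exist returns all of them with a warning.
    """
    if len(annotation) == 0:
        raise ValueError("empty gene annotation")
    if n > len(annotation):
        warnings.warn(f"requested {n} genes but only {len(annotation)} annotated")
        n = len(annotation)
    tss = annotation["tss"].to_numpy(dtype=float)
    ids = annotation["gene_id"].to_numpy()
    dist = np.abs(tss - locus_center)
    order = np.lexsort((ids, tss, dist))
    return list(ids[order[:n]])


class NearestGenesRegressor(RegressorMixin, BaseEstimator):
    """Per-locus OLS on the n nearest genes' standardized expression.

    Parameters
    ----------
    annotation : DataFrame with ``gene_id``, ``tss`` (and optionally
        ``chrom``) columns; distance is |TSS - locus center| (same-
        chromosome genes only when both sides carry ``chrom``).
    bins : DataFrame of locus coordinates (chrom/start/end), aligned with
        the columns of ``Y`` passed to :meth:`fit`.
    n_genes : number of nearest genes per locus (the field's reference
        choice is 15; any value in 1-20 is reasonable).
    """

    def __init__(
        self,
        annotation: pd.DataFrame = None,
        bins: pd.DataFrame = None,
        n_genes: int = 15,
        map_to_training_quantiles: bool = True,
    ):
        self.annotation = annotation
        self.bins = bins
        self.n_genes = n_genes
        self.map_to_training_quantiles = map_to_training_quantiles

    def fit(self, X, Y):
        if self.annotation is None or self.bins is None:
            raise ValueError("annotation and bins are required")
        Xdf = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, float))
        Ydf = Y if isinstance(Y, pd.DataFrame) else pd.DataFrame(np.asarray(Y, float))
        if len(self.bins) != Ydf.shape[1]:
            raise ValueError("bins must align with the loci (columns of Y)")
        self.gene_ids_ = pd.Index(Xdf.columns)
        self.locus_ids_ = pd.Index(Ydf.columns)
        expr = Xdf.to_numpy(dtype=float).T  # genes x cells
        dh = Ydf.to_numpy(dtype=float).T    # loci x cells

        self.reference_quantiles_ = np.sort(expr, axis=0).mean(axis=1)
        self.gene_standardizer_ = RowStandardizer(
            self.gene_ids_, expr.mean(axis=1), expr.std(axis=1, ddof=0)
        )
        self.locus_standardizer_ = RowStandardizer(
            self.locus_ids_, dh.mean(axis=1), dh.std(axis=1, ddof=0)
        )
        expr_std = forward_standardize(
            expr, self.gene_standardizer_.means, self.gene_standardizer_.sds
        )
        dh_std = forward_standardize(
            dh, self.locus_standardizer_.means, self.locus_standardizer_.sds
        )

        annot = self.annotation[self.annotation["gene_id"].isin(self.gene_ids_)]
        gene_pos = {g: i for i, g in enumerate(self.gene_ids_)}
        centers = (self.bins["start"].to_numpy() + self.bins["end"].to_numpy()) / 2.0
        chroms = self.bins["chrom"].to_numpy()
        selected = np.empty((dh.shape[0], min(self.n_genes, len(annot))), dtype=int)
        for l, (center, chrom) in enumerate(zip(centers, chroms)):
            sub = annot
            if "chrom" in annot.columns:
                on = annot[annot["chrom"] == chrom]
                if len(on) >= selected.shape[1]:
                    sub = on
            picks = nearest_genes(center, sub, selected.shape[1])
            selected[l] = [gene_pos[g] for g in picks]
        self.selected_ = selected
        self.intercepts_, self.coefs_ = _fit_models_batch(dh_std, expr_std, selected)
        return self

    def predict(self, X):
        check_is_fitted(self, "coefs_")
        Xdf = X if isinstance(X, pd.DataFrame) else pd.DataFrame(
            np.asarray(X, float), columns=self.gene_ids_
        )
        Xal = Xdf.reindex(columns=self.gene_ids_)
        if Xal.isna().any().any():
            raise ValueError("input is missing model genes")
        vals = Xal.to_numpy(dtype=float)
        out = np.empty((len(vals), len(self.locus_ids_)))
        for i, row in enumerate(vals):
            if self.map_to_training_quantiles:
                row = quantile_normalize_to_reference(row, self.reference_quantiles_)
            xt = forward_standardize(
                row[None, :].T,
                self.gene_standardizer_.means,
                self.gene_standardizer_.sds,
            )[:, 0]
            std = self.intercepts_ + np.einsum(
                "ln,ln->l", self.coefs_, xt[self.selected_]
            )
            out[i] = (
                std * self.locus_standardizer_.sds + self.locus_standardizer_.means
            )
        if isinstance(X, pd.DataFrame):
            return pd.DataFrame(out, index=X.index, columns=self.locus_ids_)
        return out
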