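"""Synthetic expression/accessibility data with the latent structure the
model assumes.

The generative story mirrors the biology the regression exploits:
co-expressed gene modules share a latent activity per cell type; each
"DHS pathway" (a co-activated group of loci) is driven by a sparse linear
combination of those module activities; each locus adds a cell-type-
independent propensity offset (its baseline tendency to be open) plus
observation noise. Expression and DH matrices are emitted directly on the
normalized log2 signal scale; a Poisson count emitter is provided
separately for filter tests.

Defaults (40 training / 17 test cell types, 2000 genes in 30 modules,
5000 loci in 50 pathways, DH noise SD 0.2) define the package's standard
simulation conditions.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import BIN_WIDTH, BinCountMatrix, write_matrix


@dataclass
class SimulationConfig:
    n_train: int = 40
    n_test: int = 17
    n_genes: int = 2000
    n_gene_clusters: int = 30          # latent co-expression modules
    n_loci: int = 5000
    n_pathways: int = 50               # latent co-activation pathways
    predictors_per_pathway: int = 3
    expression_noise_sd: float = 0.5
    dh_noise_sd: float = 0.2
    propensity_sd: float = 1.0
    n_replicates: int = 1
    replicate_noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_train", "n_test", "n_genes", "n_gene_clusters", "n_loci",
            "n_pathways", "predictors_per_pathway", "n_replicates",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in (
            "expression_noise_sd", "dh_noise_sd", "propensity_sd",
            "replicate_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_gene_clusters > self.n_genes:
            raise ValueError("more gene clusters than genes")
        if self.n_pathways > self.n_loci:
            raise ValueError("more pathways than loci")
        if self.predictors_per_pathway > self.n_gene_clusters:
            raise ValueError("predictors_per_pathway exceeds gene clusters")


@dataclass
class SyntheticTruth:
    """Ground truth and generated matrices for one simulation."""

    config: SimulationConfig
    cluster_activity: np.ndarray       # (K_true, C) latent module activities
    gene_cluster: np.ndarray           # gene -> module
    locus_pathway: np.ndarray          # locus -> pathway
    pathway_coefs: np.ndarray          # (P_true, K_true), unit l2 rows
    propensity: np.ndarray             # (L,)
    bins: pd.DataFrame                 # locus coordinates (contiguous bins)
    gene_annotation: pd.DataFrame      # gene_id, chrom, tss, strand
    expr_train: pd.DataFrame           # samples x genes
    expr_test: pd.DataFrame
    dh_train: pd.DataFrame             # samples x loci (log2 scale)
    dh_test: pd.DataFrame
    dh_clean_train: pd.DataFrame       # noise-free DH (propensity + pathway)
    dh_clean_test: pd.DataFrame
    replicates: dict = field(default_factory=dict)


def _nonempty_labels(n_items: int, n_groups: int, rng) -> np.ndarray:
    """Random assignment guaranteed to hit every group."""
    labels = np.concatenate(
        [np.arange(n_groups), rng.integers(0, n_groups, size=n_items - n_groups)]
    )
    return rng.permutation(labels)


def simulate(cfg: SimulationConfig | None = None, **overrides) -> SyntheticTruth:
    """Draw one dataset from the latent-module model, deterministically
    reproducible from ``cfg.seed``."""
    if cfg is None:
        cfg = SimulationConfig(**overrides)
    elif overrides:
        raise TypeError("pass either a config or keyword overrides, not both")
    rng = np.random.default_rng(cfg.seed)
    C = cfg.n_train + cfg.n_test
    K, G, L, P = cfg.n_gene_clusters, cfg.n_genes, cfg.n_loci, cfg.n_pathways

    activity = rng.standard_normal((K, C))
    gene_cluster = _nonempty_labels(G, K, rng)
    expr = activity[gene_cluster] + rng.normal(0, cfg.expression_noise_sd, (G, C))

    # sparse signed pathway loadings, normalized so each pathway activity
    # has unit variance across cell types (activities are iid standard
    # normal), keeping signal scale comparable across pathways
    coefs = np.zeros((P, K))
    for p in range(P):
        picks = rng.choice(K, size=cfg.predictors_per_pathway, replace=False)
        w = rng.uniform(0.5, 1.5, size=cfg.predictors_per_pathway)
        w *= rng.choice([-1.0, 1.0], size=cfg.predictors_per_pathway)
        coefs[p, picks] = w / np.linalg.norm(w)
    pathway_activity = coefs @ activity  # (P, C)

    locus_pathway = _nonempty_labels(L, P, rng)
    propensity = rng.normal(0, cfg.propensity_sd, L)
    dh_clean = propensity[:, None] + pathway_activity[locus_pathway]
    dh = dh_clean + rng.normal(0, cfg.dh_noise_sd, (L, C))

    gene_ids = pd.Index([f"gene{g:05d}" for g in range(G)], name="gene_id")
    locus_ids = pd.Index(
        [f"chr1:{i * BIN_WIDTH}-{(i + 1) * BIN_WIDTH}" for i in range(L)]
    )
    cells = [f"T{i:02d}" for i in range(cfg.n_train)] + [
        f"S{i:02d}" for i in range(cfg.n_test)
    ]
    tr, te = slice(0, cfg.n_train), slice(cfg.n_train, C)

    bins = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": np.arange(L) * BIN_WIDTH,
            "end": (np.arange(L) + 1) * BIN_WIDTH,
        }
    )
    annot = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "chrom": "chr1",
            "tss": rng.integers(0, L * BIN_WIDTH, size=G),
            "strand": rng.choice(["+", "-"], size=G),
        }
    )

    def frame(mat, cols_slice, feat_ids):
        return pd.DataFrame(
            mat[:, cols_slice].T, index=cells[cols_slice], columns=feat_ids
        )

    replicates = {}
    if cfg.n_replicates > 1:
        rep_ids, expr_rep, dh_rep, groups = [], [], [], {}
        for i in range(cfg.n_train):
            for r in range(cfg.n_replicates):
                rid = f"{cells[i]}_rep{r + 1}"
                rep_ids.append(rid)
                groups[rid] = cells[i]
                expr_rep.append(
                    expr[:, i] + rng.normal(0, cfg.replicate_noise_sd, G)
                )
                dh_rep.append(dh[:, i] + rng.normal(0, cfg.replicate_noise_sd, L))
        replicates = {
            "expr_train": pd.DataFrame(expr_rep, index=rep_ids, columns=gene_ids),
            "dh_train": pd.DataFrame(dh_rep, index=rep_ids, columns=locus_ids),
            "groups": groups,
        }

    return SyntheticTruth(
        config=cfg,
        cluster_activity=activity,
        gene_cluster=gene_cluster,
        locus_pathway=locus_pathway,
        pathway_coefs=coefs,
        propensity=propensity,
        bins=bins,
        gene_annotation=annot,
        expr_train=frame(expr, tr, gene_ids),
        expr_test=frame(expr, te, gene_ids),
        dh_train=frame(dh, tr, locus_ids),
        dh_test=frame(dh, te, locus_ids),
        dh_clean_train=frame(dh_clean, tr, locus_ids),
        dh_clean_test=frame(dh_clean, te, locus_ids),
        replicates=replicates,
    )


def poisson_bin_counts(
    signal_log2: pd.DataFrame, bins: pd.DataFrame, depths, rng
) -> BinCountMatrix:
    """Emit raw bin counts whose normalized expectation matches a log2
    signal matrix (loci as columns, samples as rows).

    The expected normalized count is 2**y - 1; raw counts are Poisson
    draws of that mean rescaled by each sample's depth relative to the
    minimum depth N.
    """
    depths = np.asarray(depths, dtype=float)
    if (depths <= 0).any():
        raise ValueError("depths must be positive")
    mean_norm = np.maximum(2.0 ** signal_log2.to_numpy(dtype=float) - 1.0, 0.0)
    scale = depths / depths.min()
    lam = mean_norm.T * scale[None, :]  # loci x samples
    counts = rng.poisson(lam)
    return BinCountMatrix(
        bins,
        pd.DataFrame(counts, index=signal_log2.columns, columns=signal_log2.index),
        depths=pd.Series(depths, index=signal_log2.index),
    )


def export(truth: SyntheticTruth, out_dir) -> dict:
    """Write the simulated dataset as package-readable text files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name in ("expr_train", "expr_test"):
        df = getattr(truth, name).T  # genes x cells on disk
        df.index.name = "gene_id"
        paths[name] = out / f"{name}.tsv"
        write_matrix(paths[name], df)
    for name in ("dh_train", "dh_test"):
        df = getattr(truth, name).T  # loci x cells on disk
        paths[name] = out / f"{name}.tsv"
        write_matrix(paths[name], df, bins=truth.bins)
    annot_path = out / "gene_annotation.tsv"
    truth.gene_annotation.to_csv(annot_path, sep="\t", index=False)
    paths["gene_annotation"] = annot_path
    meta = {
        "config": asdict(truth.config),
        "gene_cluster": truth.gene_cluster.tolist(),
        "locus_pathway": truth.locus_pathway.tolist(),
        "propensity": truth.propensity.tolist(),
    }
    truth_path = out / "truth.json"
    truth_path.write_text(json.dumps(meta))
    paths["truth"] = truth_path
    return paths
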