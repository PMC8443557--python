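"""Differential expression over development and logFC-trajectory clustering.

Starting from a normalized log2 expression matrix (probes or genes ×
samples) with per-sample metadata (age ∈ {0M, 3M, 6M}, group ∈ {UE, VPA},
area), the pipeline:

1. flags genes as expressed when their mean log2 value exceeds 5;
2. per age, computes logFC = mean(log2 VPA) − mean(log2 UE) and a
   two-sided Welch t-test p-value, Benjamini-Hochberg adjusted across the
   expressed genes of that age;
3. collapses multi-probe genes to the probe with the lowest adjusted p;
4. flags DEGs: |logFC| > 0.4 and p_adj < 0.05 at either age (strict);
5. clusters DEG logFC trajectories (ordered triples over 0M, 3M, 6M) with
   k-means, choosing k by the Akaike information criterion
   AIC(k) = RSS(k) + 2·k·d (d = 3), which penalizes each extra centroid;
   cluster labels are renumbered 1..k by ascending centroid value at 0M.

Fisher's exact test (one-sided, enrichment) serves both the between-age
DEG-overlap comparison and gene-set (SFARI / critical-period) enrichment
within clusters.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from ._util import AGES, AnalysisError, ConfigurationError, require

__all__ = [
    "ExpressionStudy",
    "ClusterModel",
    "EXPRESSED_LOG2_THRESHOLD",
    "DEG_LOGFC_THRESHOLD",
    "DEG_PADJ_THRESHOLD",
    "filter_expressed",
    "diff_expression",
    "collapse_probes",
    "select_degs",
    "cluster_trajectories",
    "deg_pipeline",
    "age_overlap_fisher",
    "geneset_enrichment",
]

logger = logging.getLogger(__name__)

EXPRESSED_LOG2_THRESHOLD = 5.0
DEG_LOGFC_THRESHOLD = 0.4
DEG_PADJ_THRESHOLD = 0.05


@dataclass
class ExpressionStudy:
    """log2 expression matrix plus sample metadata.

    ``matrix``: rows are probes (or genes), columns are sample ids.
    ``metadata``: indexed by sample id with columns age, group, area.
    ``probe_to_gene``: optional probe -> gene-symbol map; when absent the
    matrix rows are taken to be genes already.
    """

    matrix: pd.DataFrame
    metadata: pd.DataFrame
    probe_to_gene: pd.Series | None = None

    def __post_init__(self) -> None:
        missing = set(self.matrix.columns) - set(self.metadata.index)
        if missing:
            raise ConfigurationError(
                f"metadata: no entry for samples {sorted(missing)[:5]}")
        bad_ages = set(self.metadata["age"]) - set(AGES)
        if bad_ages:
            raise ConfigurationError(f"metadata.age: unknown ages {sorted(bad_ages)}")

    def samples(self, age: str, group: str) -> list[str]:
        meta = self.metadata.loc[list(self.matrix.columns)]
        sel = meta[(meta["age"] == age) & (meta["group"] == group)]
        return list(sel.index)

    @property
    def ages(self) -> list[str]:
        present = set(self.metadata.loc[list(self.matrix.columns), "age"])
        return [a for a in AGES if a in present]


@dataclass
class ClusterModel:
    k: int
    centroids: pd.DataFrame          # index 1..k, columns logFC_<age>
    assignments: pd.Series           # gene -> cluster label 1..k
    aic_by_k: pd.Series              # candidate k -> AIC
    rss_by_k: pd.Series              # candidate k -> total within-cluster RSS


def filter_expressed(study: ExpressionStudy,
                     threshold: float = EXPRESSED_LOG2_THRESHOLD) -> pd.Series:
    """Expressed iff the mean log2 value across all samples is > threshold."""
    if study.matrix.empty:
        raise AnalysisError("expression matrix is empty")
    return study.matrix.mean(axis=1) > threshold


def diff_expression(study: ExpressionStudy, age: str,
                    expressed: pd.Series | None = None) -> pd.DataFrame:
    """Per-gene logFC, Welch p and BH-adjusted p for one age.

    The BH family is the set of expressed, testable genes within this age.
    Zero-variance genes with equal group means get p = 1; zero-variance
    genes with unequal means are flagged and excluded from the family.
    """
    ue = study.samples(age, "UE")
    vpa = study.samples(age, "VPA")
    if len(ue) < 2 or len(vpa) < 2:
        raise AnalysisError(
            f"need >= 2 samples per group at {age} (UE={len(ue)}, VPA={len(vpa)})")
    if expressed is None:
        expressed = filter_expressed(study)
    mat = study.matrix.loc[expressed[expressed].index]
    a = mat[ue].to_numpy(dtype=float)
    b = mat[vpa].to_numpy(dtype=float)
    logfc = b.mean(axis=1) - a.mean(axis=1)  # log2 scale: difference of means
    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)
    degenerate = (va == 0) & (vb == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(b, a, axis=1, equal_var=False)
        p_raw = np.asarray(res.pvalue, dtype=float)
    p_raw[degenerate & (logfc == 0)] = 1.0
    flagged = degenerate & (logfc != 0)
    p_raw[flagged] = np.nan
    n_flagged = int(flagged.sum())
    if n_flagged:
        logger.info("diff_expression(%s): %d zero-variance genes with unequal "
                    "means excluded from the BH family", age, n_flagged)
    p_adj = np.full_like(p_raw, np.nan)
    family = ~np.isnan(p_raw)
    if family.any():
        _, adj, _, _ = multipletests(p_raw[family], method="fdr_bh")
        p_adj[family] = adj
    return pd.DataFrame(
        {f"logFC_{age}": logfc, f"p_raw_{age}": p_raw, f"p_adj_{age}": p_adj},
        index=mat.index)


def collapse_probes(table: pd.DataFrame,
                    probe_to_gene: pd.Series) -> pd.DataFrame:
    """Collapse probe-level results to genes, keeping the probe with the
    lowest p_adj (minimum across ages; ties by lowest raw p, then probe id).

    Probes without a gene mapping are dropped with a logged count.
    """
    padj_cols = [c for c in table.columns if c.startswith("p_adj_")]
    praw_cols = [c for c in table.columns if c.startswith("p_raw_")]
    if not padj_cols:
        raise AnalysisError("table has no p_adj_* columns to collapse on")
    mapped = table.index.intersection(probe_to_gene.index)
    dropped = len(table) - len(mapped)
    if dropped:
        logger.info("collapse_probes: dropped %d unmapped probes", dropped)
    sub = table.loc[mapped].copy()
    sub["_gene"] = probe_to_gene.loc[mapped].to_numpy()
    sub["_min_padj"] = sub[padj_cols].min(axis=1)
    sub["_min_praw"] = sub[praw_cols].min(axis=1) if praw_cols else np.nan
    sub["_probe"] = sub.index.astype(str)
    sub = sub.sort_values(["_min_padj", "_min_praw", "_probe"],
                          na_position="last", kind="mergesort")
    out = sub.groupby("_gene", sort=True).head(1)
    out = out.set_index("_gene").drop(
        columns=["_min_padj", "_min_praw", "_probe"])
    out.index.name = "gene"
    return out.sort_index()


def select_degs(table: pd.DataFrame,
                logfc_threshold: float = DEG_LOGFC_THRESHOLD,
                padj_threshold: float = DEG_PADJ_THRESHOLD) -> pd.Series:
    """DEG iff |logFC| > 0.4 and p_adj < 0.05 at either age (both strict)."""
    hits = pd.Series(False, index=table.index)
    for age in AGES:
        lc, pc = f"logFC_{age}", f"p_adj_{age}"
        if lc not in table.columns or pc not in table.columns:
            continue
        hits |= (table[lc].abs() > logfc_threshold) & (table[pc] < padj_threshold)
    return hits


def cluster_trajectories(logfc: pd.DataFrame, k_range=range(1, 9),
                         n_init: int = 50, seed: int = 0) -> ClusterModel:
    """k-means over logFC trajectories with AIC-selected cluster number.

    For each candidate k, k-means runs with ``n_init`` k-means++ restarts;
    AIC(k) = RSS(k) + 2·k·d with d the trajectory length.  The smallest k
    attaining the minimum AIC wins, so on noiseless one-cluster data k = 1
    is selected and AIC rises strictly past the planted k.  Labels 1..k are
    ordered by ascending centroid value at the first age, making cluster 1
    the most strongly downregulated at birth.
    """
    X = logfc.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise AnalysisError("logFC trajectories contain NaN")
    n, d = X.shape
    ks = [k for k in k_range if k <= n]
    if not ks:
        raise AnalysisError(f"fewer trajectories ({n}) than any candidate k")
    aic, rss, fits = {}, {}, {}
    for k in ks:
        km = KMeans(n_clusters=k, n_init=n_init, init="k-means++",
                    random_state=seed % (2 ** 32)).fit(X)
        rss[k] = float(km.inertia_)
        aic[k] = rss[k] + 2.0 * k * d
        fits[k] = km
    best_k = min(ks, key=lambda k: (aic[k], k))
    km = fits[best_k]
    order = np.argsort(km.cluster_centers_[:, 0], kind="stable")
    relabel = np.empty(best_k, dtype=int)
    relabel[order] = np.arange(1, best_k + 1)
    labels = relabel[km.labels_]
    centroids = pd.DataFrame(km.cluster_centers_[order],
                             index=pd.Index(range(1, best_k + 1), name="cluster"),
                             columns=list(logfc.columns))
    return ClusterModel(
        k=best_k,
        centroids=centroids,
        assignments=pd.Series(labels, index=logfc.index, name="cluster"),
        aic_by_k=pd.Series(aic, name="aic").sort_index(),
        rss_by_k=pd.Series(rss, name="rss").sort_index(),
    )


def deg_pipeline(study: ExpressionStudy, k_range=range(1, 9), n_init: int = 50,
                 seed: int = 0, cluster: bool = True
                 ) -> tuple[pd.DataFrame, ClusterModel | None]:
    """Expressed filter -> per-age Welch+BH -> probe collapse -> DEG rule ->
    trajectory clustering.  Returns the gene-level table and the model."""
    expressed = filter_expressed(study)
    parts = [diff_expression(study, age, expressed=expressed)
             for age in study.ages]
    table = pd.concat(parts, axis=1)
    if study.probe_to_gene is not None:
        table = collapse_probes(table, study.probe_to_gene)
    table["is_deg"] = select_degs(table)
    model = None
    if cluster and table["is_deg"].any():
        cols = [f"logFC_{a}" for a in study.ages]
        traj = table.loc[table["is_deg"], cols]
        model = cluster_trajectories(traj, k_range=k_range, n_init=n_init,
                                     seed=seed)
        table["cluster"] = model.assignments.reindex(table.index)
    else:
        table["cluster"] = np.nan
    return table, model


def _fisher_enrichment(in_both: int, a_only: int, b_only: int, neither: int
                       ) -> float:
    odds_table = [[in_both, a_only], [b_only, neither]]
    return float(stats.fisher_exact(odds_table, alternative="greater")[1])


def age_overlap_fisher(set_a, set_b, universe) -> float:
    """One-sided Fisher p for enrichment of shared genes between two DEG
    sets (e.g. upregulated at 3M vs upregulated at 6M) over the universe of
    expressed genes."""
    uni = set(universe)
    if not uni:
        raise AnalysisError("universe of expressed genes is empty")
    a = set(set_a) & uni
    b = set(set_b) & uni
    both = len(a & b)
    return _fisher_enrichment(both, len(a) - both, len(b) - both,
                              len(uni) - len(a | b) )


def geneset_enrichment(cluster_genes, gene_set, universe
                       ) -> tuple[float, float, float]:
    """Over-representation of a gene set within a cluster.

    Returns (one-sided Fisher p, in-cluster ratio, universe ratio); the
    universe ratio is the baseline fraction of the gene set among all
    expressed genes.
    """
    uni = set(universe)
    cluster = set(cluster_genes) & uni
    gset = set(gene_set) & uni
    if not cluster:
        raise AnalysisError("cluster is empty (after restricting to universe)")
    if not gset:
        raise AnalysisError("gene set does not intersect the universe")
    both = len(cluster & gset)
    p = _fisher_enrichment(both, len(cluster) - both, len(gset) - both,
                           len(uni) - len(cluster | gset))
    return p, both / len(cluster), len(gset) / len(uni)
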