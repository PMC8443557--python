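"""Phenotype-transcriptome linkage and cross-species concordance.

A phenotype or gene-cluster trajectory is the ordered triple of logFC
values over the ages (0M, 3M, 6M).  The linkage metric between a synaptic
phenotype and a gene cluster is the mean absolute logFC difference,
Σ_t |logFC_syn(t) − logFC_gene(t)| / 3; the distance matrix also carries a
"3r" column, the distance to the *negated* cluster-3 centroid, exposing
phenotypes that are inversely correlated with cluster 3.

Cross-species comparison takes paired per-gene logFC tables (model vs
human or rodent datasets): gene-wise agreement is Spearman correlation on
genes modulated (p_adj < 0.1) in both datasets; module-wise agreement is a
one-sided binomial test of the fraction of sign-concordant genes within
each co-expression module against chance (0.5).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._util import AnalysisError, ConfigurationError

__all__ = [
    "Trajectory",
    "SpearmanResult",
    "trajectory_distance",
    "distance_matrix",
    "cross_species_spearman",
    "module_concordance",
    "harmonize_symbols",
]

logger = logging.getLogger(__name__)

EXACT_SPEARMAN_MAX_N = 8


@dataclass
class Trajectory:
    """logFC values at ages (0M, 3M, 6M) for a phenotype or gene cluster."""

    values: tuple[float, float, float]
    label: str = ""

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in np.asarray(self.values, dtype=float))
        if len(vals) != 3:
            raise ConfigurationError(
                f"values: trajectory needs exactly 3 components, got {len(vals)}")
        if any(math.isnan(v) for v in vals):
            raise AnalysisError(f"trajectory {self.label!r} has missing components")
        self.values = vals

    def reversed(self) -> "Trajectory":
        return Trajectory(tuple(-v for v in self.values),
                          label=f"{self.label}r")


def _values(t) -> np.ndarray:
    v = np.asarray(t.values if isinstance(t, Trajectory) else t, dtype=float)
    if v.shape != (3,):
        raise ConfigurationError(f"trajectory must have 3 components, got {v.shape}")
    if np.isnan(v).any():
        raise AnalysisError("trajectory has missing components")
    return v


def trajectory_distance(a, b) -> float:
    """Mean absolute logFC difference across the three ages."""
    return float(np.abs(_values(a) - _values(b)).mean())


def distance_matrix(cluster_means: pd.DataFrame, phenotypes: pd.DataFrame,
                    reversed_clusters=("3",)) -> pd.DataFrame:
    """All phenotype × cluster trajectory distances.

    ``cluster_means``: cluster label (index, stringable) × 3 age columns.
    ``phenotypes``: phenotype name × the same 3 age columns.  For each
    label in ``reversed_clusters`` present in the index, a negated column
    labeled e.g. "3r" is appended.
    """
    clusters = cluster_means.copy()
    clusters.index = clusters.index.astype(str)
    for lab in reversed_clusters:
        if lab in clusters.index:
            rlab = f"{lab}r"
            if rlab in clusters.index:
                raise ConfigurationError(f"label collision: {rlab!r} already present")
            clusters.loc[rlab] = -clusters.loc[lab]
    if phenotypes.index.has_duplicates or clusters.index.has_duplicates:
        raise ConfigurationError("duplicate trajectory labels")
    out = pd.DataFrame(index=phenotypes.index, columns=clusters.index,
                       dtype=float)
    for ph in phenotypes.index:
        for cl in clusters.index:
            out.loc[ph, cl] = trajectory_distance(
                phenotypes.loc[ph].to_numpy(), clusters.loc[cl].to_numpy())
    return out


@dataclass
class SpearmanResult:
    rho: float
    p_value: float
    n_genes: int
    insufficient: bool = False


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact p by full enumeration of rank permutations."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    n = len(rx)
    count = 0
    total = 0
    target = abs(rho_obs) - 1e-12
    for perm in itertools.permutations(range(n)):
        r = stats.pearsonr(rx[list(perm)], ry).statistic
        total += 1
        if abs(r) >= target:
            count += 1
    return count / total


def cross_species_spearman(table: pd.DataFrame, p_cut: float = 0.1,
                           require_both: bool = True) -> SpearmanResult:
    """Spearman correlation of model vs external logFC on modulated genes.

    Genes enter when p_adj < ``p_cut`` in both datasets (or either, with
    ``require_both=False``).  Ties get average ranks.  For n <= 8 the
    two-sided p is exact (full permutation enumeration); larger n uses the
    asymptotic approximation.  Fewer than 3 qualifying genes flags the
    result insufficient.
    """
    if require_both:
        sel = (table["padj_model"] < p_cut) & (table["padj_ext"] < p_cut)
    else:
        sel = (table["padj_model"] < p_cut) | (table["padj_ext"] < p_cut)
    sub = table[sel]
    n = len(sub)
    if n < 3:
        return SpearmanResult(math.nan, math.nan, n, insufficient=True)
    x = sub["logFC_model"].to_numpy(dtype=float)
    y = sub["logFC_ext"].to_numpy(dtype=float)
    res = stats.spearmanr(x, y)
    rho = float(res.statistic)
    if n <= EXACT_SPEARMAN_MAX_N:
        p = _spearman_exact_p(x, y, rho)
    else:
        p = float(res.pvalue)
    return SpearmanResult(rho, p, n)


def module_concordance(table: pd.DataFrame, module_map: pd.Series
                       ) -> pd.DataFrame:
    """Per-module sign concordance of model vs external logFC.

    For each module: the number of genes whose logFC signs agree, the total
    after excluding genes with logFC = 0 in either dataset (excluded counts
    are logged and reported), a one-sided binomial p against chance
    agreement 0.5, and the module direction (majority sign of the model
    logFC, 0 on a tie).  Modules left empty after exclusions are flagged.
    """
    genes = table.index.intersection(module_map.index)
    rows = []
    for module, members in module_map.loc[genes].groupby(module_map.loc[genes]):
        sub = table.loc[members.index]
        sm = np.sign(sub["logFC_model"].to_numpy(dtype=float))
        se = np.sign(sub["logFC_ext"].to_numpy(dtype=float))
        nonzero = (sm != 0) & (se != 0)
        excluded = int((~nonzero).sum())
        if excluded:
            logger.info("module_concordance(%s): excluded %d zero-logFC genes",
                        module, excluded)
        total = int(nonzero.sum())
        if total == 0:
            rows.append((module, 0, 0, math.nan, 0, excluded, True))
            continue
        agree = int((sm[nonzero] == se[nonzero]).sum())
        p = float(stats.binomtest(agree, total, 0.5,
                                  alternative="greater").pvalue)
        direction = int(np.sign(sm[nonzero].sum()))
        rows.append((module, agree, total, p, direction, excluded, False))
    return pd.DataFrame(rows, columns=["module", "agree_n", "total_n",
                                       "p_value", "direction",
                                       "excluded_zero", "empty"]
                        ).set_index("module")


def harmonize_symbols(table: pd.DataFrame, homolog_map: pd.DataFrame
                      ) -> pd.DataFrame:
    """Map external gene symbols onto model symbols via a homolog table.

    ``homolog_map`` must have two columns (source, target).  Unmapped rows
    are dropped (logged).  One-to-many source mappings resolve to the
    lexicographically first target; duplicate targets after mapping keep
    the first occurrence, so symbols are unique afterwards.
    """
    if homolog_map.shape[1] != 2:
        raise ConfigurationError(
            f"homolog_map: expected 2 columns, got {homolog_map.shape[1]}")
    src, tgt = homolog_map.columns
    resolved = (homolog_map.sort_values([src, tgt], kind="mergesort")
                .drop_duplicates(subset=src, keep="first")
                .set_index(src)[tgt])
    mapped_idx = table.index.intersection(resolved.index)
    dropped = len(table) - len(mapped_idx)
    if dropped:
        logger.info("harmonize_symbols: dropped %d unmapped genes", dropped)
    out = table.loc[mapped_idx].copy()
    out.index = resolved.loc[mapped_idx]
    dup = out.index.duplicated(keep="first")
    if dup.any():
        logger.info("harmonize_symbols: dropped %d duplicate targets",
                    int(dup.sum()))
        out = out[~dup]
    out.index.name = "gene"
    return out.sort_index()
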