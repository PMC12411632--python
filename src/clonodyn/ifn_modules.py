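"""Interferon gene-panel module discovery and per-cell module scoring.

The panel (canonically 100 interferon-stimulated genes) is profiled as a
genes x cell-types matrix of log2 fold changes (disease vs control, on
linear counts-per-10k group means with a pseudocount), then partitioned by
K-means over the fold-change rows; the number of modules K is chosen by the
mean silhouette score over a candidate range.  Per-cell module scores are
the mean normalized log1p expression of a module's genes, by default minus
the mean of an expression-bin-matched control gene set (the Seurat
AddModuleScore convention, via :func:`scanpy.tl.score_genes`), then
z-scored across all scored cells.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import anndata as ad
import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .de_and_composition import (
    FC_THRESHOLD,
    P_ADJ_THRESHOLD,
    PSEUDOCOUNT,
    de_test,
    normalize_cp10k,
)
from .io_formats import CountsMatrix

logger = logging.getLogger(__name__)

DEFAULT_K_RANGE = tuple(range(2, 9))
DEFAULT_N_RESTARTS = 50
CONTROL_BINS = 24
CONTROL_SIZE = 100


@dataclass
class FoldChangeProfile:
    """Panel genes x cell types log2 fold changes with significance flags."""

    log2fc: pd.DataFrame          # rows: genes, columns: cell types
    significant: pd.DataFrame     # same shape, boolean


@dataclass
class ModulePartition:
    """Gene -> module assignment from silhouette-selected K-means."""

    K: int
    assignment: dict[str, str]           # gene -> "C1".."CK", C1 the largest
    silhouette_by_K: dict[int, float]
    seed: int

    def gene_sets(self) -> dict[str, list[str]]:
        sets: dict[str, list[str]] = {}
        for g, c in self.assignment.items():
            sets.setdefault(c, []).append(g)
        return dict(sorted(sets.items()))


def log2fc_profile(
    counts: CountsMatrix,
    meta: pd.DataFrame,
    panel: Sequence[str],
    group_field: str = "group",
    celltype_field: str = "cell_type",
    pseudocount: float = PSEUDOCOUNT,
    min_cells_per_group: int = 3,
) -> FoldChangeProfile:
    """Per-cell-type log2 fold change of each panel gene (disease over control).

    Cell types missing either group (fewer than ``min_cells_per_group``
    cells) are dropped with a log entry; panel genes absent from the matrix
    are dropped with a warning.  Significance flags come from the strict
    fold-change / BH-adjusted-p conjunction applied per cell type.
    """
    present = [g for g in panel if g in set(counts.gene_ids)]
    absent = sorted(set(panel) - set(present))
    if absent:
        logger.warning("%d panel genes absent from matrix, dropped: %s...", len(absent), absent[:5])
    if not present:
        raise ValueError("no panel genes present in the matrix")

    barcodes = np.array(counts.barcodes)
    labels = meta.loc[barcodes, celltype_field].to_numpy()
    groups = meta.loc[barcodes, group_field].to_numpy()
    uniq_groups = sorted(set(groups))
    if len(uniq_groups) != 2:
        raise ValueError(f"need exactly two groups, found {uniq_groups}")
    g_num = "SLE" if "SLE" in uniq_groups else uniq_groups[0]
    g_den = [g for g in uniq_groups if g != g_num][0]

    fc_cols, sig_cols = {}, {}
    for ct in sorted(set(labels)):
        in_ct = labels == ct
        n_a = int((in_ct & (groups == g_num)).sum())
        n_b = int((in_ct & (groups == g_den)).sum())
        if n_a < min_cells_per_group or n_b < min_cells_per_group:
            logger.info("cell type %s dropped: groups sized %d/%d", ct, n_a, n_b)
            continue
        res = de_test(
            counts, meta, group_field=group_field,
            cells_subset=np.flatnonzero(in_ct), groups=(g_num, g_den),
            pseudocount=pseudocount,
        )
        by_gene = {r.gene: r for r in res}
        fc_cols[ct] = [
            by_gene[g].log2fc if g in by_gene else 0.0 for g in present
        ]
        # BH within the cell type across panel genes only
        panel_res = [by_gene[g] for g in present if g in by_gene]
        from .de_and_composition import benjamini_hochberg

        if panel_res:
            adj = benjamini_hochberg([r.p_raw for r in panel_res])
            sig_map = {
                r.gene: bool(r.fold_change > FC_THRESHOLD and a < P_ADJ_THRESHOLD)
                for r, a in zip(panel_res, adj)
            }
        else:
            sig_map = {}
        sig_cols[ct] = [sig_map.get(g, False) for g in present]

    if not fc_cols:
        raise ValueError("no cell type has both groups represented")
    return FoldChangeProfile(
        log2fc=pd.DataFrame(fc_cols, index=present),
        significant=pd.DataFrame(sig_cols, index=present),
    )


def cluster_panel(
    profile: FoldChangeProfile,
    k_range: Sequence[int] = DEFAULT_K_RANGE,
    n_restarts: int = DEFAULT_N_RESTARTS,
    seed: int = 0,
) -> ModulePartition:
    """K-means over fold-change rows with silhouette-based K selection.

    For each K the best of ``n_restarts`` greedy-k-means++ initializations
    (lowest within-cluster sum of squares) is kept; K* maximizes the mean
    silhouette (ties to the smaller K).  Cluster labels are renumbered C1,
    C2, ... by descending size (ties by lexicographically smallest member
    gene) so the labelling is deterministic and row-order invariant.
    """
    X = profile.log2fc.to_numpy(dtype=float)
    genes = list(profile.log2fc.index)
    if len(genes) < 3:
        raise ValueError("need at least 3 genes to cluster")
    k_range = sorted(set(int(k) for k in k_range))
    if min(k_range) < 2 or max(k_range) > len(genes) - 1:
        raise ValueError(f"k_range must lie within [2, {len(genes) - 1}]")
    if np.allclose(X, X[0]):
        raise ValueError("no cluster structure: all fold-change rows identical")

    sil: dict[int, float] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    for k in k_range:
        km = KMeans(n_clusters=k, n_init=n_restarts, init="k-means++", random_state=seed)
        lab = km.fit_predict(X)
        labels_by_k[k] = lab
        if len(set(lab)) < 2:
            sil[k] = -1.0
        else:
            sil[k] = float(silhouette_score(X, lab))
    k_star = max(sil, key=lambda k: (sil[k], -k))
    lab = labels_by_k[k_star]

    order = sorted(
        set(lab),
        key=lambda c: (-(lab == c).sum(),
                       min(genes[i] for i in np.flatnonzero(lab == c))),
    )
    rename = {c: f"C{i + 1}" for i, c in enumerate(order)}
    assignment = {g: rename[c] for g, c in zip(genes, lab)}
    return ModulePartition(K=k_star, assignment=assignment, silhouette_by_K=sil, seed=seed)


def module_scores(
    counts: CountsMatrix,
    gene_sets: Mapping[str, Sequence[str]],
    control: bool = True,
    n_bins: int = CONTROL_BINS,
    ctrl_size: int = CONTROL_SIZE,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-cell module scores, z-normalized per module across all cells.

    ``control=True`` subtracts an expression-bin-matched random control gene
    set before z-scoring (AddModuleScore convention); ``control=False`` is
    the plain mean of the module genes' normalized log1p expression.  A
    module with zero genes present is dropped with a warning; a module whose
    raw score has zero variance scores 0 everywhere (guarded z-score).
    """
    lognorm = normalize_cp10k(counts, log1p=True)  # genes x cells
    gene_set_present: dict[str, list[str]] = {}
    gene_lookup = {g: i for i, g in enumerate(counts.gene_ids)}
    for mod, genes in gene_sets.items():
        present = [g for g in genes if g in gene_lookup]
        if not present:
            logger.warning("module %s: no genes present in matrix, dropped", mod)
            continue
        if len(present) < len(genes):
            logger.warning("module %s: %d/%d genes present", mod, len(present), len(genes))
        gene_set_present[mod] = present
    if not gene_set_present:
        raise ValueError("no module has genes present in the matrix")

    raw = {}
    if control:
        adata = ad.AnnData(
            X=lognorm.T.copy(),
            obs=pd.DataFrame(index=list(counts.barcodes)),
            var=pd.DataFrame(index=list(counts.gene_ids)),
        )
        import scanpy as sc

        for mod, genes in gene_set_present.items():
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sc.tl.score_genes(
                    adata, genes, score_name="_score", ctrl_size=ctrl_size,
                    n_bins=min(n_bins, max(2, counts.n_genes // 2)),
                    random_state=seed,
                )
            raw[mod] = adata.obs["_score"].to_numpy(dtype=float)
    else:
        for mod, genes in gene_set_present.items():
            idx = [gene_lookup[g] for g in genes]
            raw[mod] = lognorm[idx].mean(axis=0)

    out = {}
    for mod, v in raw.items():
        sd = v.std()
        if sd <= 1e-12 * max(1.0, abs(float(v.mean()))):  # zero-variance guard
            out[mod] = np.zeros_like(v)
        else:
            out[mod] = (v - v.mean()) / sd
    return pd.DataFrame(out, index=list(counts.barcodes))


def compare_scores_by_group(
    scores: pd.DataFrame,
    meta: pd.DataFrame,
    grouping: str,
    modules: Optional[Sequence[str]] = None,
    cells_subset: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Per-group score summaries with rank tests, BH-adjusted across modules.

    Two groups use a two-sided Mann-Whitney U; more use Kruskal-Wallis.
    ``cells_subset`` restricts to a barcode subset (e.g. one cell type).
    """
    from scipy.stats import kruskal, mannwhitneyu

    from .de_and_composition import benjamini_hochberg

    idx = scores.index if cells_subset is None else pd.Index(cells_subset)
    idx = idx.intersection(scores.index).intersection(meta.index)
    labels = meta.loc[idx, grouping]
    uniq = sorted(labels.unique())
    if len(uniq) < 2:
        raise ValueError(f"need at least two groups, found {uniq}")
    modules = list(scores.columns) if modules is None else list(modules)

    rows, pvals = [], []
    for mod in modules:
        groups = [scores.loc[idx[labels == g], mod].to_numpy() for g in uniq]
        for g, v in zip(uniq, groups):
            rows.append(
                dict(module=mod, group=g, n=len(v),
                     mean=float(np.mean(v)) if len(v) else np.nan,
                     sd=float(np.std(v, ddof=1)) if len(v) > 1 else np.nan)
            )
        if any(len(v) < 2 for v in groups):
            pvals.append(np.nan)
            continue
        if all(np.array_equal(np.sort(groups[0]), np.sort(v)) for v in groups[1:]):
            pvals.append(1.0)
        elif len(uniq) == 2:
            pvals.append(float(mannwhitneyu(groups[0], groups[1], alternative="two-sided").pvalue))
        else:
            pvals.append(float(kruskal(*groups).pvalue))

    valid = ~np.isnan(pvals)
    adj = np.full(len(pvals), np.nan)
    if valid.any():
        adj[valid] = benjamini_hochberg(np.array(pvals)[valid])
    p_by_mod = dict(zip(modules, zip(pvals, adj)))
    df = pd.DataFrame(rows)
    df["p_raw"] = [p_by_mod[m][0] for m in df["module"]]
    df["p_adj"] = [p_by_mod[m][1] for m in df["module"]]
    return df
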