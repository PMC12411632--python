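"""Two-group differential expression and cell-type composition statistics.

Differential expression uses a distribution-free two-sided Mann-Whitney U
test per gene on counts-per-10k log1p expression; a model-based single-cell
hurdle test would be the heavier alternative, and the recorded test name
makes the substitution explicit.  A gene is significant when its linear
fold change exceeds 1.25 (strict) and its Benjamini-Hochberg adjusted p
value is below 1e-6 (strict).

Composition tests operate on per-sample cell-type fractions, not on cells,
because samples — not cells — are the independent units; per cell type an
SLE-vs-CTL Mann-Whitney on the fractions is BH-adjusted across cell types.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .io_formats import CountsMatrix

logger = logging.getLogger(__name__)

FC_THRESHOLD = 1.25       # strict: fold_change > 1.25
P_ADJ_THRESHOLD = 1e-6    # strict: p_adj < 1e-6
PSEUDOCOUNT = 0.01
DE_TEST_NAME = "mann-whitney-u"


def normalize_cp10k(counts: CountsMatrix, log1p: bool = False) -> np.ndarray:
    """Dense genes x cells counts-per-10k matrix, optionally log1p."""
    x = counts.values.astype(float).toarray()
    libsize = x.sum(axis=0)
    x = x / np.maximum(libsize, 1.0) * 1e4
    return np.log1p(x) if log1p else x


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values, in input order.

    adj_(i) = min_{j >= i} ( m * p_(j) / j ), capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj


@dataclass(frozen=True)
class DEResult:
    gene: str
    mean_a: float            # normalized (CP10K) group means, linear scale
    mean_b: float
    fold_change: float       # (mean_a + eps) / (mean_b + eps)
    log2fc: float
    p_raw: float
    p_adj: float
    significant: bool
    test: str = DE_TEST_NAME


def de_test(
    counts: CountsMatrix,
    meta: pd.DataFrame,
    group_field: str = "group",
    cells_subset: Optional[np.ndarray] = None,
    groups: Optional[tuple[str, str]] = None,
    pseudocount: float = PSEUDOCOUNT,
) -> list[DEResult]:
    """Per-gene two-group test with the strict FC/adjusted-p significance rule.

    ``groups`` fixes (A, B) in the fold-change ratio A/B; defaults to the
    sorted group labels reversed so that ("SLE", "CTL") compares SLE over
    CTL.  Genes with all-zero counts in both groups are skipped and logged.
    """
    barcodes = np.array(counts.barcodes)
    if cells_subset is not None:
        counts = counts.subset_cells(np.asarray(cells_subset))
        barcodes = np.array(counts.barcodes)
    labels = meta.loc[barcodes, group_field].to_numpy()
    uniq = sorted(set(labels))
    if groups is None:
        if len(uniq) != 2:
            raise ValueError(f"need exactly two groups, found {uniq}")
        groups = (uniq[1], uniq[0]) if uniq == ["CTL", "SLE"] else (uniq[0], uniq[1])
    mask_a = labels == groups[0]
    mask_b = labels == groups[1]
    if mask_a.sum() < 3 or mask_b.sum() < 3:
        raise ValueError("each group needs at least 3 cells")

    norm = normalize_cp10k(counts)
    lognorm = np.log1p(norm)
    row_sums = np.asarray(counts.values.sum(axis=1)).ravel()
    tested_idx = [i for i in range(counts.n_genes) if row_sums[i] > 0]
    n_skipped = counts.n_genes - len(tested_idx)
    if n_skipped:
        logger.info("%d all-zero genes skipped in DE", n_skipped)

    a = lognorm[np.ix_(tested_idx, np.flatnonzero(mask_a))]
    b = lognorm[np.ix_(tested_idx, np.flatnonzero(mask_b))]
    # vectorized MWU across genes; constant genes give p=1 by construction
    res = mannwhitneyu(a, b, alternative="two-sided", axis=1)
    p_raw = np.asarray(res.pvalue, dtype=float)
    identical = np.array([np.array_equal(np.sort(x), np.sort(y)) for x, y in zip(a, b)])
    p_raw[identical] = 1.0
    p_adj = benjamini_hochberg(p_raw)

    mean_a = norm[np.ix_(tested_idx, np.flatnonzero(mask_a))].mean(axis=1)
    mean_b = norm[np.ix_(tested_idx, np.flatnonzero(mask_b))].mean(axis=1)
    fc = (mean_a + pseudocount) / (mean_b + pseudocount)

    out = []
    for k, gi in enumerate(tested_idx):
        sig = bool(fc[k] > FC_THRESHOLD and p_adj[k] < P_ADJ_THRESHOLD)
        out.append(
            DEResult(
                gene=counts.gene_ids[gi],
                mean_a=float(mean_a[k]),
                mean_b=float(mean_b[k]),
                fold_change=float(fc[k]),
                log2fc=float(np.log2(fc[k])),
                p_raw=float(p_raw[k]),
                p_adj=float(p_adj[k]),
                significant=sig,
            )
        )
    return out


@dataclass
class CompositionTable:
    """Per-sample cell-type counts/fractions plus per-type group tests."""

    per_sample: pd.DataFrame       # rows: sample, columns: cell types, fractions
    counts: pd.DataFrame           # same shape, raw counts
    tests: pd.DataFrame            # per cell type: p_raw, p_adj, direction, significant


def composition_table(meta: pd.DataFrame, celltype_field: str = "cell_type") -> tuple[pd.DataFrame, pd.DataFrame]:
    counts = (
        meta.groupby(["sample_id", celltype_field]).size().unstack(fill_value=0).sort_index()
    )
    fractions = counts.div(counts.sum(axis=1), axis=0)
    return counts, fractions


def composition_compare(
    meta: pd.DataFrame,
    group_field: str = "group",
    celltype_field: str = "cell_type",
    alpha: float = 0.05,
) -> CompositionTable:
    """Group comparison of per-sample cell-type fractions (BH across types)."""
    counts, fractions = composition_table(meta, celltype_field)
    sample_group = meta.groupby("sample_id")[group_field].first().loc[fractions.index]
    uniq = sorted(sample_group.unique())
    if len(uniq) != 2:
        raise ValueError(f"need exactly two groups, found {uniq}")
    g_hi = "SLE" if "SLE" in uniq else uniq[0]
    g_lo = [g for g in uniq if g != g_hi][0]
    for g in uniq:
        if (sample_group == g).sum() < 2:
            raise ValueError(f"group {g} has fewer than 2 samples")

    rows = []
    pvals = []
    for ct in fractions.columns:
        x = fractions.loc[sample_group == g_hi, ct].to_numpy()
        y = fractions.loc[sample_group == g_lo, ct].to_numpy()
        if np.array_equal(np.sort(x), np.sort(y)):
            p = 1.0
        else:
            p = float(mannwhitneyu(x, y, alternative="two-sided").pvalue)
        pvals.append(p)
        rows.append(
            dict(
                cell_type=ct,
                mean_frac_a=float(x.mean()),
                mean_frac_b=float(y.mean()),
                direction=g_hi if x.mean() > y.mean() else g_lo,
                p_raw=p,
            )
        )
    tests = pd.DataFrame(rows).set_index("cell_type")
    tests["p_adj"] = benjamini_hochberg(np.array(pvals))
    tests["significant"] = tests["p_adj"] < alpha
    return CompositionTable(per_sample=fractions, counts=counts, tests=tests)


def subtype_ratio(
    meta: pd.DataFrame,
    numerator_type: str,
    denominator_type: str,
    within: Optional[Sequence[str]] = None,
    group_field: str = "group",
) -> tuple[pd.DataFrame, float]:
    """Per-sample numerator/denominator cell-count ratio plus a group test.

    ``within`` optionally restricts to a parent population (list of cell
    types) before counting.  Samples with a zero denominator are excluded
    with a log entry; if all samples are excluded this is an error.
    """
    sub = meta if within is None else meta[meta["cell_type"].isin(within)]
    counts, _ = composition_table(sub)
    rows = []
    for sample in counts.index:
        n_num = int(counts.loc[sample].get(numerator_type, 0))
        n_den = int(counts.loc[sample].get(denominator_type, 0))
        if n_den == 0:
            logger.warning("sample %s: zero %s cells, ratio excluded", sample, denominator_type)
            continue
        rows.append(
            dict(
                sample_id=sample,
                group=meta.loc[meta["sample_id"] == sample, group_field].iloc[0],
                ratio=n_num / n_den,
            )
        )
    if not rows:
        raise ValueError("all samples excluded: denominator type absent everywhere")
    table = pd.DataFrame(rows).set_index("sample_id")
    uniq = sorted(table["group"].unique())
    p = float("nan")
    if len(uniq) == 2:
        x = table.loc[table["group"] == uniq[0], "ratio"].to_numpy()
        y = table.loc[table["group"] == uniq[1], "ratio"].to_numpy()
        if len(x) >= 2 and len(y) >= 2:
            if np.array_equal(np.sort(x), np.sort(y)):
                p = 1.0
            else:
                p = float(mannwhitneyu(x, y, alternative="two-sided").pvalue)
    return table, p
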