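"""Cell- and gene-level quality control.

Cells are kept when they show more than ``min_genes_per_cell`` detected genes
(strictly greater; detection means >= 1 UMI), strictly less than
``max_mito_fraction`` mitochondrial UMI content, and no expression of the
platelet markers.  All three rules are evaluated on the original matrix, not
sequentially, so the filter is idempotent and a cell's rejection is
attributed to the first rule it fails (genes -> mito -> platelet).

Mitochondrial genes are recognised by the GRCh38 "MT-" symbol prefix
(case-insensitive, configurable).  The gene blacklist removes TCR/Ig
variable genes, ribosomal and mitochondrial genes, and a dissociation-stress
signature before variable-feature style analyses.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io_formats import CountsMatrix

logger = logging.getLogger(__name__)

#: immediate-early / heat-shock dissociation-stress signature.  This is a
#: synthetic stand-in list assembled from the conventional FOS/JUN/HSP gene
#: families; override it to use a specific published signature.
DISSOCIATION_STRESS_GENES = (
    "FOS", "FOSB", "JUN", "JUNB", "JUND", "EGR1", "ATF3", "HSPA1A", "HSPA1B",
    "HSPA5", "HSPA6", "HSPA8", "HSPB1", "HSPH1", "HSP90AA1", "HSP90AB1",
    "DNAJA1", "DNAJB1", "IER2", "IER3", "ZFP36", "SOCS3", "DUSP1", "KLF6",
)

#: variable-feature blacklist: TCR variable, Ig variable, ribosomal,
#: mitochondrial, dissociation-stress.
DEFAULT_BLACKLIST_PATTERNS = (
    r"^TR[ABGD][VDJ]",          # TCR variable/diversity/joining segments
    r"^IG[HKL][VDJ]",           # immunoglobulin variable segments
    r"^RP[SL]\d",               # ribosomal proteins
    r"^MT-",                    # mitochondrial
    r"^(?:" + "|".join(DISSOCIATION_STRESS_GENES) + r")$",
)


@dataclass(frozen=True)
class QCParams:
    """Cell-filter thresholds; defaults are the strict printed cutoffs."""

    min_genes_per_cell: int = 500          # keep if detected genes > this
    max_mito_fraction: float = 0.05        # keep if mito UMI fraction < this
    platelet_markers: tuple[str, ...] = ("PPBP", "PF4", "NRGN")
    platelet_threshold: int = 0            # flag if any marker count > this
    mito_prefix: str = "MT-"
    blacklist_patterns: tuple[str, ...] = DEFAULT_BLACKLIST_PATTERNS

    def __post_init__(self) -> None:
        if not (0 < self.max_mito_fraction < 1):
            raise ValueError("max_mito_fraction must be in (0, 1)")
        if self.min_genes_per_cell < 0:
            raise ValueError("min_genes_per_cell must be >= 0")


@dataclass
class QCReport:
    """Per-rule rejection counts; first-failing-rule attribution."""

    n_input: int
    n_retained: int
    n_rejected_min_genes: int
    n_rejected_mito: int
    n_rejected_platelet: int
    mito_rule_applied: bool
    detection_rule: str = "gene detected iff >= 1 UMI"

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def filter_cells(counts: CountsMatrix, params: QCParams = QCParams()) -> tuple[CountsMatrix, QCReport]:
    """Apply the three cell filters and return the retained matrix plus a report.

    If no mitochondrial genes are present the mito rule is skipped with a
    warning, recorded in the report.
    """
    csc = counts.values.tocsc()
    genes_detected = np.asarray((csc > 0).sum(axis=0)).ravel()
    total = np.asarray(csc.sum(axis=0)).ravel().astype(float)

    mito_idx = np.array(
        [i for i, g in enumerate(counts.gene_ids)
         if g.upper().startswith(params.mito_prefix.upper())],
        dtype=int,
    )
    mito_applied = mito_idx.size > 0
    if mito_applied:
        mito = np.asarray(csc[mito_idx].sum(axis=0)).ravel().astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            mito_frac = np.where(total > 0, mito / np.maximum(total, 1), 0.0)
        fail_mito = ~(mito_frac < params.max_mito_fraction)
    else:
        logger.warning("no genes with prefix %r: mitochondrial rule skipped", params.mito_prefix)
        fail_mito = np.zeros(counts.n_cells, dtype=bool)

    plt_idx = counts.gene_index(params.platelet_markers)
    if plt_idx.size:
        plt_max = np.asarray(csc[plt_idx].max(axis=0).todense()).ravel()
        fail_platelet = plt_max > params.platelet_threshold
    else:
        fail_platelet = np.zeros(counts.n_cells, dtype=bool)

    fail_genes = ~(genes_detected > params.min_genes_per_cell)
    keep = ~(fail_genes | fail_mito | fail_platelet)

    # first-failing-rule attribution: genes -> mito -> platelet
    rej_genes = int(fail_genes.sum())
    rej_mito = int((fail_mito & ~fail_genes).sum())
    rej_plt = int((fail_platelet & ~fail_genes & ~fail_mito).sum())

    report = QCReport(
        n_input=counts.n_cells,
        n_retained=int(keep.sum()),
        n_rejected_min_genes=rej_genes,
        n_rejected_mito=rej_mito,
        n_rejected_platelet=rej_plt,
        mito_rule_applied=mito_applied,
    )
    return counts.subset_cells(keep), report


def blacklist_genes(gene_ids: Sequence[str], patterns: Sequence[str] = DEFAULT_BLACKLIST_PATTERNS) -> list[str]:
    """Return genes NOT matching any blacklist pattern, order preserved."""
    if not patterns:
        raise ValueError("patterns must be nonempty")
    compiled = [re.compile(p) for p in patterns]
    return [g for g in gene_ids if not any(c.search(g) for c in compiled)]
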