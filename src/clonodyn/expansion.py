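"""Flare-expansion classification and clonotype fate tracking.

A clonotype is called expanded between a before-flare (BF) and flare (FL)
repertoire of the same patient when it shows at least a ``fold_threshold``
(default 2.0) increase in cell count, or is absent at baseline but present
during the flare (de novo).  To suppress spurious signals, a would-be
expanded clonotype must additionally be represented by >= ``min_flare_cells``
(default 3) cells in the flare state and, for fold-type expansions, show a
proportional increase (its within-repertoire frequency must rise, not just
its raw count).  The minimum-cell gate applies only to clones that would
otherwise be called expanded; it never reclassifies a non-expanded clone.

Both the count fold and the proportion fold are recorded on every call so
either reading of "increase in size" is auditable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .clonotypes import ClonotypeCall
from .repertoire import RepertoireProfile

logger = logging.getLogger(__name__)

EXPANDED_STATUSES = ("expanded_fold", "expanded_de_novo")
STATUSES = EXPANDED_STATUSES + ("not_expanded", "excluded_min_cells")


@dataclass(frozen=True)
class ExpansionParams:
    fold_threshold: float = 2.0      # tau: FL count >= tau * BF count
    min_flare_cells: int = 3         # m: would-be expanded clones need >= m FL cells
    require_proportional: bool = True

    def __post_init__(self) -> None:
        if self.fold_threshold < 1:
            raise ValueError("fold_threshold must be >= 1")
        if self.min_flare_cells < 1:
            raise ValueError("min_flare_cells must be >= 1")


@dataclass(frozen=True)
class ExpansionCall:
    patient_id: str
    clonotype_id: str
    n_bf: int
    n_fl: int
    p_bf: float
    p_fl: float
    status: str

    @property
    def expanded(self) -> bool:
        return self.status in EXPANDED_STATUSES

    @property
    def count_fold(self) -> float:
        return self.n_fl / self.n_bf if self.n_bf else float("inf")

    @property
    def proportion_fold(self) -> float:
        return self.p_fl / self.p_bf if self.p_bf else float("inf")


def classify_expansion(
    bf: RepertoireProfile,
    fl: RepertoireProfile,
    params: ExpansionParams = ExpansionParams(),
) -> list[ExpansionCall]:
    """Classify every clonotype of the BF/FL union for one patient."""
    if not fl.counts:
        raise ValueError("flare repertoire is empty")
    if bf.patient_id is not None and fl.patient_id is not None and bf.patient_id != fl.patient_id:
        raise ValueError(
            f"patient mismatch: BF={bf.patient_id!r} vs FL={fl.patient_id!r}"
        )
    patient = bf.patient_id or fl.patient_id or "?"
    N_bf, N_fl = max(bf.N, 1), fl.N
    tau, m = params.fold_threshold, params.min_flare_cells

    calls = []
    for clone in sorted(set(bf.counts) | set(fl.counts)):
        n_bf = int(bf.counts.get(clone, 0))
        n_fl = int(fl.counts.get(clone, 0))
        p_bf = n_bf / N_bf
        p_fl = n_fl / N_fl
        if n_bf == 0:
            would_be = n_fl > 0
            kind = "expanded_de_novo"
        else:
            would_be = n_fl >= tau * n_bf and (not params.require_proportional or p_fl > p_bf)
            kind = "expanded_fold"
        if would_be and n_fl < m:
            status = "excluded_min_cells"
        elif would_be:
            status = kind
        else:
            status = "not_expanded"
        calls.append(ExpansionCall(patient, clone, n_bf, n_fl, p_bf, p_fl, status))
    return calls


def expanded_set(calls: Sequence[ExpansionCall]) -> set[str]:
    return {c.clonotype_id for c in calls if c.expanded}


def fate_table(
    calls: Sequence[ClonotypeCall],
    meta: pd.DataFrame,
    expansion: Sequence[ExpansionCall],
    weighting: str = "clonotype",
) -> pd.DataFrame:
    """BF-subtype x FL-subtype transition mass of expanded clonotypes.

    Each expanded clonotype contributes weight 1 (``weighting="clonotype"``)
    or its FL cell count (``weighting="cells"``), split across (BF subtype,
    FL subtype) pairs proportionally to its cell-type distributions at the
    two timepoints.  Clonotypes absent at baseline contribute to the
    ``absent`` row.  Row/column sums conserve the total weight.
    """
    if weighting not in ("clonotype", "cells"):
        raise ValueError("weighting must be 'clonotype' or 'cells'")
    expanded = {c.clonotype_id: c for c in expansion if c.expanded}

    # per-clonotype cell-type distribution at each timepoint
    by_clone: dict[str, dict[str, dict[str, int]]] = {}
    for call in calls:
        if call.barcode not in meta.index:
            continue
        row = meta.loc[call.barcode]
        clone = f"{row['patient_id']}::{call.clonotype_id}"
        if clone not in expanded:
            continue
        tp = row["timepoint"]
        by_clone.setdefault(clone, {"BF": {}, "FL": {}})
        if tp in ("BF", "FL"):
            d = by_clone[clone][tp]
            d[row["cell_type"]] = d.get(row["cell_type"], 0) + 1

    bf_types = sorted({t for d in by_clone.values() for t in d["BF"]})
    fl_types = sorted({t for d in by_clone.values() for t in d["FL"]})
    table = pd.DataFrame(0.0, index=bf_types + ["absent"], columns=fl_types)

    for clone, dists in by_clone.items():
        fl_total = sum(dists["FL"].values())
        assert fl_total > 0, f"expanded clonotype {clone} has no flare cells"
        weight = 1.0 if weighting == "clonotype" else float(fl_total)
        bf_total = sum(dists["BF"].values())
        fl_frac = {t: n / fl_total for t, n in dists["FL"].items()}
        if bf_total == 0:
            for t, f in fl_frac.items():
                table.loc["absent", t] += weight * f
        else:
            for bt, nb in dists["BF"].items():
                for ft, f in fl_frac.items():
                    table.loc[bt, ft] += weight * (nb / bf_total) * f
    return table


def compare_expanded_scores(
    module_scores: pd.DataFrame,
    expansion: Sequence[ExpansionCall],
    calls: Sequence[ClonotypeCall],
    meta: pd.DataFrame,
) -> pd.DataFrame:
    """Per (timepoint x expanded status) summary of module scores, with tests.

    ``module_scores`` is a barcode-indexed cells x modules frame.  For each
    score and timepoint, expanded vs non-expanded cells are compared with a
    two-sided Mann-Whitney U test; p values are Benjamini-Hochberg adjusted
    across scores within each timepoint.  Groups with n < 2 have their
    statistic omitted with a log entry.
    """
    from .de_and_composition import benjamini_hochberg

    exp_clones = expanded_set(expansion)
    rows = []
    cell_status: dict[str, tuple[str, bool]] = {}
    for call in calls:
        if call.barcode not in meta.index or call.barcode not in module_scores.index:
            continue
        r = meta.loc[call.barcode]
        if r["timepoint"] not in ("BF", "FL"):
            continue
        clone = f"{r['patient_id']}::{call.clonotype_id}"
        cell_status[call.barcode] = (r["timepoint"], clone in exp_clones)

    status_df = pd.DataFrame.from_dict(
        cell_status, orient="index", columns=["timepoint", "expanded"]
    )
    for tp in ("BF", "FL"):
        sub = status_df[status_df["timepoint"] == tp]
        if sub.empty:
            continue
        pvals, keys = [], []
        for score in module_scores.columns:
            vals = {
                flag: module_scores.loc[sub.index[sub["expanded"] == flag], score].to_numpy()
                for flag in (True, False)
            }
            for flag in (True, False):
                v = vals[flag]
                rows.append(
                    dict(
                        timepoint=tp,
                        score=score,
                        expanded=flag,
                        n=len(v),
                        mean=float(np.mean(v)) if len(v) else np.nan,
                        sd=float(np.std(v, ddof=1)) if len(v) > 1 else np.nan,
                    )
                )
            if len(vals[True]) >= 2 and len(vals[False]) >= 2:
                if np.array_equal(np.sort(vals[True]), np.sort(vals[False])):
                    p = 1.0
                else:
                    p = float(mannwhitneyu(vals[True], vals[False], alternative="two-sided").pvalue)
                pvals.append(p)
                keys.append((tp, score))
            else:
                logger.warning("timepoint %s score %s: a group has n<2, test omitted", tp, score)
        if pvals:
            adj = benjamini_hochberg(np.array(pvals))
            lut_raw = dict(zip(keys, pvals))
            lut_adj = dict(zip(keys, adj))
            for row in rows:
                k = (row["timepoint"], row["score"])
                if k in lut_raw and row["timepoint"] == tp:
                    row["p_raw"] = lut_raw[k]
                    row["p_adj"] = float(lut_adj[k])
    return pd.DataFrame(rows)
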