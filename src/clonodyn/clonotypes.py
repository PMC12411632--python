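"""Paired alpha/beta clonotype calling from TCR contig tables.

Four filtering rules, applied in order:

1. drop contigs not flagged high-confidence (and, by default, contigs not
   flagged productive — the 10x filtered-contig convention; switch off with
   ``require_productive=False`` to apply the literal four rules only);
2. per barcode and chain, keep only the contig with the highest UMI count
   (equal-UMI ties broken lexicographically over the full chain identity,
   (cdr3_nt, v_gene, j_gene, d_gene, cdr3_aa), so the result never depends
   on row order);
3. drop barcodes lacking either a TRA or a TRB;
4. assign a clonotype key from the surviving chain pair.

Two key modes exist because the field keys clonotypes on V(D)J genes plus
CDR3 amino-acid sequence, while the sparser genes-only key (V/J of the alpha
chain with V/D/J of the beta chain) is also in use.  The mode is recorded in
every output.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io_formats import ContigRecord

logger = logging.getLogger(__name__)

KEY_MODES = ("genes_only", "genes_plus_cdr3aa")


@dataclass(frozen=True)
class ChainCall:
    v_gene: str
    d_gene: str
    j_gene: str
    cdr3_aa: str
    cdr3_nt: str
    umis: int


@dataclass(frozen=True)
class ClonotypeCall:
    """Per-cell paired-chain call with its clonotype key."""

    barcode: str
    tra: ChainCall
    trb: ChainCall
    clonotype_id: str
    key_mode: str


@dataclass
class FilterReport:
    """Removal counts per rule; conserves the input cell count."""

    n_contigs_in: int = 0
    n_cells_in: int = 0
    n_contigs_low_confidence: int = 0
    n_contigs_nonproductive: int = 0
    n_contigs_secondary_chain: int = 0
    n_contigs_other_chain: int = 0
    n_cells_all_contigs_removed: int = 0
    n_cells_unpaired: int = 0
    n_cells_called: int = 0
    n_umi_ties: int = 0
    key_mode: str = "genes_plus_cdr3aa"
    require_productive: bool = True

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def clonotype_key(tra: ChainCall, trb: ChainCall, mode: str) -> str:
    """Canonical clonotype string for a chain pair under ``mode``."""
    if mode == "genes_only":
        parts_a = (tra.v_gene, tra.j_gene)
        parts_b = (trb.v_gene, trb.d_gene, trb.j_gene)
    elif mode == "genes_plus_cdr3aa":
        parts_a = (tra.v_gene, tra.j_gene, tra.cdr3_aa)
        parts_b = (trb.v_gene, trb.d_gene, trb.j_gene, trb.cdr3_aa)
    else:
        raise ValueError(f"unknown key mode {mode!r}; expected one of {KEY_MODES}")
    return "TRA:" + ".".join(parts_a) + "|TRB:" + ".".join(parts_b)


def _tie_key(c: ContigRecord) -> tuple:
    """Total order for equal-UMI chains: lexicographic over the full identity."""
    return (c.cdr3_nt, c.v_gene, c.j_gene, c.d_gene, c.cdr3_aa)


def call_clonotypes(
    contigs: Sequence[ContigRecord],
    mode: str = "genes_plus_cdr3aa",
    require_productive: bool = True,
) -> tuple[list[ClonotypeCall], FilterReport]:
    """Run the four-rule pipeline and return one call per paired cell."""
    if mode not in KEY_MODES:
        raise ValueError(f"unknown key mode {mode!r}")
    report = FilterReport(
        n_contigs_in=len(contigs),
        n_cells_in=len({c.barcode for c in contigs}),
        key_mode=mode,
        require_productive=require_productive,
    )

    # rule 1: confidence (and productive, when required)
    surviving: list[ContigRecord] = []
    for c in contigs:
        if not c.high_confidence:
            report.n_contigs_low_confidence += 1
        elif require_productive and not c.productive:
            report.n_contigs_nonproductive += 1
        else:
            surviving.append(c)

    # rule 2: best chain per (barcode, chain); deterministic tie-break
    surviving_barcodes = {c.barcode for c in surviving}
    report.n_cells_all_contigs_removed = report.n_cells_in - len(surviving_barcodes)
    best: dict[str, dict[str, ContigRecord]] = {bc: {} for bc in surviving_barcodes}
    for c in surviving:
        if c.chain not in ("TRA", "TRB"):
            report.n_contigs_other_chain += 1
            continue
        cur = best[c.barcode].get(c.chain)
        if cur is None:
            best[c.barcode][c.chain] = c
        else:
            report.n_contigs_secondary_chain += 1
            if c.umis > cur.umis:
                best[c.barcode][c.chain] = c
            elif c.umis == cur.umis:
                report.n_umi_ties += 1
                if _tie_key(c) < _tie_key(cur):
                    best[c.barcode][c.chain] = c

    # rules 3-4: pairing and key assignment
    calls: list[ClonotypeCall] = []
    for barcode in sorted(best):
        chains = best[barcode]
        if "TRA" not in chains or "TRB" not in chains:
            report.n_cells_unpaired += 1
            continue
        a, b = chains["TRA"], chains["TRB"]
        tra = ChainCall(a.v_gene, a.d_gene, a.j_gene, a.cdr3_aa, a.cdr3_nt, a.umis)
        trb = ChainCall(b.v_gene, b.d_gene, b.j_gene, b.cdr3_aa, b.cdr3_nt, b.umis)
        calls.append(
            ClonotypeCall(barcode, tra, trb, clonotype_key(tra, trb, mode), mode)
        )
    report.n_cells_called = len(calls)
    return calls, report


def repertoire_from_calls(
    calls: Sequence[ClonotypeCall],
    meta: pd.DataFrame,
    stratify_by: Sequence[str] = ("sample_id",),
) -> dict[tuple, "RepertoireProfile"]:
    """Aggregate calls into per-stratum clonotype cell-count profiles.

    ``meta`` is a barcode-indexed metadata frame.  Strata are the distinct
    value tuples of ``stratify_by`` among called cells; barcodes missing from
    the metadata are excluded with a log entry.  Clonotype identifiers are
    namespaced by patient — clonotypes are only ever tracked within a
    patient, never merged across patients.
    """
    from .repertoire import RepertoireProfile  # local import avoids a cycle

    missing = [c.barcode for c in calls if c.barcode not in meta.index]
    if missing:
        logger.warning("%d called barcodes missing from metadata; excluded", len(missing))
    present = [c for c in calls if c.barcode in meta.index]

    counts: dict[tuple, dict[str, int]] = defaultdict(lambda: defaultdict(int))
    patients: dict[tuple, set] = defaultdict(set)
    for c in present:
        row = meta.loc[c.barcode]
        stratum = tuple(row[f] for f in stratify_by)
        clone = f"{row['patient_id']}::{c.clonotype_id}"
        counts[stratum][clone] += 1
        patients[stratum].add(row["patient_id"])

    out: dict[tuple, RepertoireProfile] = {}
    for stratum in sorted(counts):
        pats = patients[stratum]
        out[stratum] = RepertoireProfile(
            stratum_id=stratum,
            counts=dict(sorted(counts[stratum].items())),
            patient_id=next(iter(pats)) if len(pats) == 1 else None,
        )
    return out
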