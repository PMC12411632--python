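"""Readers and writers for every external format the pipeline touches.

Canonical on-disk forms:

* expression — MatrixMarket coordinate triplets (genes x cells, integer UMI
  counts) with ``genes.tsv`` and ``barcodes.tsv`` sidecars, the 10x-style
  layout;
* TCR contigs — either the 10x ``filtered_contig_annotations.csv`` dialect or
  an AIRR rearrangement TSV (``locus``/``v_call``/``junction_aa``/
  ``duplicate_count`` columns mapped onto the same record type);
* per-cell metadata — CSV keyed by barcode;
* gene panels — one symbol per line, or a CSV with a ``gene`` column.

All indices are 0-based in memory; MTX is 1-based on disk only.  Gene
identity is by symbol, case-sensitive, whitespace-stripped — the synthetic
cohorts control their own symbols, so no alias resolution is attempted.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

TIMEPOINTS = ("BF", "FL", "NA")
GROUPS = ("SLE", "CTL")
CHAINS = ("TRA", "TRB", "other")

#: columns required of a metadata CSV, beyond the barcode key
META_COLUMNS = ("sample_id", "patient_id", "timepoint", "group", "cell_type")

_TENX_COLUMNS = (
    "barcode", "chain", "v_gene", "d_gene", "j_gene",
    "cdr3", "cdr3_nt", "umis", "high_confidence", "productive",
)
# AIRR Rearrangement schema fields -> internal names.  Booleans are encoded
# "T"/"F"/empty per the AIRR spec; empty means unknown and is treated as False
# for ``productive`` and True for the optional ``is_cell``-style confidence
# column (absent from core AIRR; accepted when present as ``high_confidence``).
_AIRR_MAP = {
    "cell_id": "barcode",
    "locus": "chain",
    "v_call": "v_gene",
    "d_call": "d_gene",
    "j_call": "j_gene",
    "junction_aa": "cdr3_aa",
    "junction": "cdr3_nt",
    "duplicate_count": "umis",
}
_AIRR_REQUIRED = ("cell_id", "locus", "v_call", "j_call", "junction_aa")


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass(frozen=True)
class CountsMatrix:
    """Sparse gene x cell UMI count matrix with its gene/barcode indices."""

    values: sp.csr_matrix
    gene_ids: tuple[str, ...]
    barcodes: tuple[str, ...]

    def __post_init__(self) -> None:
        vals = sp.csr_matrix(self.values)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        object.__setattr__(self, "barcodes", tuple(self.barcodes))
        n_genes, n_cells = vals.shape
        if len(self.gene_ids) != n_genes:
            raise FormatError(
                f"{len(self.gene_ids)} gene ids for a matrix with {n_genes} rows"
            )
        if len(self.barcodes) != n_cells:
            raise FormatError(
                f"{len(self.barcodes)} barcodes for a matrix with {n_cells} columns"
            )
        if len(set(self.gene_ids)) != n_genes:
            raise FormatError("gene ids are not unique")
        if len(set(self.barcodes)) != n_cells:
            raise FormatError("barcodes are not unique")
        if vals.nnz and vals.data.min() < 0:
            raise FormatError("negative UMI counts")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def gene_index(self, symbols: Iterable[str]) -> np.ndarray:
        """Row indices of ``symbols`` (case-sensitive, stripped); absent symbols skipped."""
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        return np.array(
            [lookup[s.strip()] for s in symbols if s.strip() in lookup], dtype=int
        )

    def subset_cells(self, mask_or_index: np.ndarray) -> "CountsMatrix":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return CountsMatrix(
            self.values[:, idx],
            self.gene_ids,
            tuple(self.barcodes[i] for i in idx),
        )


@dataclass(frozen=True)
class ContigRecord:
    """One TCR contig row: a single assembled chain of one cell."""

    barcode: str
    chain: str  # "TRA" | "TRB" | "other"
    v_gene: str
    d_gene: str  # empty for TRA
    j_gene: str
    cdr3_aa: str
    cdr3_nt: str
    umis: int
    high_confidence: bool
    productive: bool

    def __post_init__(self) -> None:
        if self.chain not in CHAINS:
            raise FormatError(f"unparseable chain {self.chain!r}")
        if self.umis < 0:
            raise FormatError("negative UMI count on contig")


def _read_lines(path: Path) -> list[str]:
    return [ln.rstrip("\n") for ln in Path(path).read_text().splitlines()]


# ---------------------------------------------------------------------------
# expression matrices


def read_mtx_triplet(matrix_path, genes_path, barcodes_path) -> CountsMatrix:
    """Read a 10x-style MTX triplet (matrix + genes.tsv + barcodes.tsv).

    The sidecar files carry one symbol/barcode per line (first tab-separated
    field used, so two-column 10x ``genes.tsv`` files also parse).
    """
    matrix_path, genes_path, barcodes_path = (
        Path(matrix_path), Path(genes_path), Path(barcodes_path))
    for p in (matrix_path, genes_path, barcodes_path):
        if not p.exists():
            raise FileNotFoundError(p)
    try:
        mat = scipy.io.mmread(str(matrix_path))
    except Exception as exc:  # scipy raises bare ValueError on bad headers
        raise FormatError(f"{matrix_path}: invalid MatrixMarket file: {exc}") from exc
    mat = sp.coo_matrix(mat)
    if mat.nnz and not np.allclose(mat.data, np.round(mat.data)):
        raise FormatError(f"{matrix_path}: non-integer values in UMI matrix")
    mat = sp.csr_matrix((mat.data.astype(np.int64), (mat.row, mat.col)), shape=mat.shape)
    genes = [ln.split("\t")[0].strip() for ln in _read_lines(genes_path) if ln.strip()]
    barcodes = [ln.split("\t")[0].strip() for ln in _read_lines(barcodes_path) if ln.strip()]
    if len(genes) != mat.shape[0]:
        raise FormatError(
            f"{genes_path}: {len(genes)} genes but matrix has {mat.shape[0]} rows"
        )
    if len(barcodes) != mat.shape[1]:
        raise FormatError(
            f"{barcodes_path}: {len(barcodes)} barcodes but matrix has {mat.shape[1]} columns"
        )
    return CountsMatrix(mat, tuple(genes), tuple(barcodes))


def write_mtx_triplet(counts: CountsMatrix, matrix_path, genes_path, barcodes_path) -> None:
    """Write the triplet back out (1-based MTX on disk, integer field)."""
    coo = sp.coo_matrix(counts.values)
    scipy.io.mmwrite(str(matrix_path), coo, field="integer")
    Path(genes_path).write_text("".join(g + "\n" for g in counts.gene_ids))
    Path(barcodes_path).write_text("".join(b + "\n" for b in counts.barcodes))


# ---------------------------------------------------------------------------
# TCR contigs


def _parse_bool_tenx(v) -> bool:
    s = str(v).strip().lower()
    if s in ("true", "1"):
        return True
    if s in ("false", "0", ""):
        return False
    raise FormatError(f"unparseable boolean {v!r} (expected True/False)")


def _parse_bool_airr(v, default: bool) -> bool:
    s = str(v).strip().upper()
    if s in ("T", "TRUE"):
        return True
    if s in ("F", "FALSE"):
        return False
    if s in ("", "NAN", "NONE"):
        return default
    raise FormatError(f"unparseable AIRR boolean {v!r} (expected T/F/empty)")


def _chain_of(locus: str) -> str:
    locus = str(locus).strip().upper()
    return locus if locus in ("TRA", "TRB") else "other"


def read_contigs(path, dialect: str = "tenx_csv") -> list[ContigRecord]:
    """Parse a contig annotation table into :class:`ContigRecord` rows.

    ``tenx_csv`` is the 10x ``filtered_contig_annotations.csv`` layout;
    ``airr_tsv`` is an AIRR rearrangement TSV (locus -> chain, v/d/j_call ->
    genes, junction_aa -> cdr3_aa, duplicate_count -> umis).  Chains other
    than TRA/TRB map to ``other``; no row is silently dropped.
    """
    path = Path(path)
    if dialect == "tenx_csv":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        missing = [c for c in _TENX_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: missing columns {missing}")
        return [
            ContigRecord(
                barcode=r["barcode"],
                chain=_chain_of(r["chain"]),
                v_gene=r["v_gene"].strip(),
                d_gene=r["d_gene"].strip().replace("None", ""),
                j_gene=r["j_gene"].strip(),
                cdr3_aa=r["cdr3"].strip(),
                cdr3_nt=r["cdr3_nt"].strip(),
                umis=int(r["umis"]),
                high_confidence=_parse_bool_tenx(r["high_confidence"]),
                productive=_parse_bool_tenx(r["productive"]),
            )
            for r in df.to_dict("records")
        ]
    if dialect == "airr_tsv":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        missing = [c for c in _AIRR_REQUIRED if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: missing columns {missing}")
        records = []
        for r in df.to_dict("records"):
            records.append(
                ContigRecord(
                    barcode=r["cell_id"],
                    chain=_chain_of(r["locus"]),
                    v_gene=r["v_call"].strip(),
                    d_gene=r.get("d_call", "").strip(),
                    j_gene=r["j_call"].strip(),
                    cdr3_aa=r["junction_aa"].strip(),
                    cdr3_nt=r.get("junction", "").strip(),
                    umis=int(r["duplicate_count"]) if r.get("duplicate_count", "") else 0,
                    high_confidence=_parse_bool_airr(r.get("high_confidence", ""), True),
                    productive=_parse_bool_airr(r.get("productive", ""), False),
                )
            )
        return records
    raise ValueError(f"unknown contig dialect {dialect!r}")


def write_contigs(records: Sequence[ContigRecord], path) -> None:
    """Write contigs in the 10x CSV dialect (round-trips through read_contigs)."""
    df = pd.DataFrame(
        {
            "barcode": [r.barcode for r in records],
            "chain": [r.chain for r in records],
            "v_gene": [r.v_gene for r in records],
            "d_gene": [r.d_gene for r in records],
            "j_gene": [r.j_gene for r in records],
            "cdr3": [r.cdr3_aa for r in records],
            "cdr3_nt": [r.cdr3_nt for r in records],
            "umis": [r.umis for r in records],
            "high_confidence": [r.high_confidence for r in records],
            "productive": [r.productive for r in records],
        }
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# cell metadata


def validate_cell_meta(meta: pd.DataFrame) -> pd.DataFrame:
    """Check a per-cell metadata table and return it indexed by barcode.

    Accepts either a ``barcode`` column or a barcode index.  Enforces barcode
    uniqueness, one sample per barcode (trivially true for a unique key) and
    the timepoint/group vocabularies.
    """
    meta = meta.copy()
    if "barcode" in meta.columns:
        meta = meta.set_index("barcode")
    meta.index = meta.index.astype(str)
    meta.index.name = "barcode"
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise FormatError(f"cell metadata missing columns {missing}")
    if meta.index.duplicated().any():
        dup = meta.index[meta.index.duplicated()][:3].tolist()
        raise FormatError(f"duplicate barcodes in metadata, e.g. {dup}")
    meta["timepoint"] = meta["timepoint"].fillna("NA").astype(str)
    bad_tp = set(meta["timepoint"]) - set(TIMEPOINTS)
    if bad_tp:
        raise FormatError(f"unknown timepoints {sorted(bad_tp)}; expected {TIMEPOINTS}")
    bad_grp = set(meta["group"].astype(str)) - set(GROUPS)
    if bad_grp:
        raise FormatError(f"unknown groups {sorted(bad_grp)}; expected {GROUPS}")
    return meta


def read_cell_meta(path) -> pd.DataFrame:
    return validate_cell_meta(pd.read_csv(path, dtype=str, keep_default_na=False))


def write_cell_meta(meta: pd.DataFrame, path) -> None:
    validate_cell_meta(meta).to_csv(path, index=True)


# ---------------------------------------------------------------------------
# gene panels


def read_gene_panel(path) -> list[str]:
    """Read an ordered gene panel (one symbol per line, or CSV with a ``gene`` column).

    Duplicates are removed order-preservingly with a logged warning; an empty
    panel is an error.
    """
    path = Path(path)
    lines = _read_lines(path)
    symbols: list[str]
    if lines and ("," in lines[0] or lines[0].strip().lower() == "gene"):
        df = pd.read_csv(path, dtype=str)
        if "gene" not in df.columns:
            raise FormatError(f"{path}: CSV panel needs a 'gene' column")
        symbols = [s.strip() for s in df["gene"].dropna().tolist()]
    else:
        symbols = [ln.strip() for ln in lines if ln.strip()]
    seen: dict[str, None] = {}
    n_dup = 0
    for s in symbols:
        if s in seen:
            n_dup += 1
        else:
            seen[s] = None
    if n_dup:
        logger.warning("gene panel %s: %d duplicate symbols collapsed", path, n_dup)
    if not seen:
        raise FormatError(f"{path}: empty gene panel")
    return list(seen)


def write_gene_panel(symbols: Sequence[str], path) -> None:
    Path(path).write_text("".join(s + "\n" for s in symbols))


# ---------------------------------------------------------------------------
# small JSON helper used by ground truth / reports


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True, default=_jsonable) + "\n")


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
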