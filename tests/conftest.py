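import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from clonodyn import CountsMatrix, ContigRecord
from clonodyn.synthetic_data import SimConfig, simulate_cohort


def make_counts(dense, gene_ids=None, barcodes=None) -> CountsMatrix:
    """CountsMatrix from a dense genes x cells array."""
    dense = np.asarray(dense)
    g, c = dense.shape
    return CountsMatrix(
        sp.csr_matrix(dense),
        gene_ids or tuple(f"G{i}" for i in range(g)),
        barcodes or tuple(f"BC{i}" for i in range(c)),
    )


def make_contig(barcode="BC1", chain="TRA", v="TRAV1", d="", j="TRAJ1",
                cdr3="CASSF", cdr3_nt="TGTGCT", umis=5, hc=True, prod=True) -> ContigRecord:
    if chain == "TRB" and not d:
        d = "TRBD1"
    return ContigRecord(barcode, chain, v, d, j, cdr3, cdr3_nt, umis, hc, prod)


def make_meta(rows) -> pd.DataFrame:
    """Metadata frame from (barcode, sample, patient, timepoint, group, cell_type) tuples."""
    df = pd.DataFrame(
        rows, columns=["barcode", "sample_id", "patient_id", "timepoint", "group", "cell_type"]
    )
    return df.set_index("barcode")


@pytest.fixture(scope="session")
def small_cohort():
    """A small but complete cohort exercising every pipeline stage."""
    cfg = SimConfig(seed=11, n_patients=2, n_controls=3,
                    n_cells_per_sample=500, n_genes=800)
    return cfg, simulate_cohort(cfg)


@pytest.fixture(scope="session")
def calibration_cohort():
    """Cohort sized for score/fold-change calibration checks (>= 2000 cells)."""
    cfg = SimConfig(seed=21, n_patients=2, n_controls=2, n_cells_per_sample=1200)
    return cfg, simulate_cohort(cfg)
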