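"""Synthetic paired scRNA-seq + scTCR-seq cohorts with planted ground truth.

The generator emulates a flare-relapse cohort: control donors contribute one
sample each, every patient contributes a before-flare (BF) and a flare (FL)
sample.  Cell types are drawn from group-specific composition fractions;
expression is negative-binomial (gamma-Poisson) around lognormal library
sizes, with the genes of each interferon module multiplied by ``exp(delta)``
in that module's elevated cell types of disease cells; each T cell carries a
clonotype from a per-patient, per-compartment (CD4 / CD8) power-law
repertoire and emits one TRA and one TRB contig whose V/J genes and CDR3
are a deterministic function of the clonotype identity.

Clone sizes are realized by deterministic largest-remainder quota allocation
of the power-law frequencies rather than by multinomial draws.  This makes
the planted truth exact: planted expanded clones carry flare frequency
``expansion_fold x`` their realized baseline frequency (de novo clones have
baseline zero) and switch phenotype naive -> Tem at flare, while no
background clone can cross the expansion rule by sampling chance (quota
error is below one cell, so a non-planted clone can never double).
Randomness enters through cell-type assignment, expression sampling and the
configurable contig noise (missing chains, low-UMI secondary chains,
low-confidence flags).
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .clonotypes import ChainCall, clonotype_key
from .io_formats import (
    ContigRecord,
    CountsMatrix,
    read_cell_meta,
    read_contigs,
    read_mtx_triplet,
    write_cell_meta,
    write_contigs,
    write_json,
    write_mtx_triplet,
)

# ---------------------------------------------------------------------------
# configuration

CD8_TYPES = ("CD8 naive", "CD8 Tem", "CD8 GZMK")
CD4_TYPES = ("CD4 naive", "CD4 Tem", "CD4 Treg")
MITO_GENES = ("MT-ND1", "MT-ND2", "MT-CO1", "MT-CO2", "MT-CYB")
PLATELET_GENES = ("PPBP", "PF4", "NRGN")

DEFAULT_FRACTIONS = {
    "SLE": {
        "CD8 naive": 0.10, "CD8 Tem": 0.16, "CD8 GZMK": 0.06,
        "CD4 naive": 0.14, "CD4 Tem": 0.10, "CD4 Treg": 0.06,
        "B naive": 0.10, "B mem": 0.04, "ABC": 0.06,
        "cM": 0.12, "NK": 0.04, "pDC": 0.02,
    },
    "CTL": {
        "CD8 naive": 0.14, "CD8 Tem": 0.10, "CD8 GZMK": 0.06,
        "CD4 naive": 0.20, "CD4 Tem": 0.10, "CD4 Treg": 0.04,
        "B naive": 0.12, "B mem": 0.06, "ABC": 0.01,
        "cM": 0.11, "NK": 0.04, "pDC": 0.02,
    },
}


@dataclass(frozen=True)
class ModuleSpec:
    """One planted gene module: genes, where it is elevated, and how much."""

    module_id: str
    genes: tuple[str, ...]
    elevated_cell_types: tuple[str, ...] | str  # tuple of labels, or "all"
    delta: float                                # log-space effect: mean x exp(delta)
    timepoints: Optional[tuple[str, ...]] = None  # None: all disease samples


def default_module_spec(delta: float = math.log(2)) -> tuple[ModuleSpec, ...]:
    """A 100-gene interferon panel in four cell-type-specific modules.

    Mirrors the canonical structure: a broadly induced module (C1), a
    lymphocyte/CD8 module (C2), a classical-monocyte module (C3) and a pDC
    module (C4).
    """
    isg = [f"ISG{i:03d}" for i in range(1, 101)]
    return (
        ModuleSpec("C1", tuple(isg[0:40]), "all", delta),
        ModuleSpec("C2", tuple(isg[40:65]), CD8_TYPES, delta),
        ModuleSpec("C3", tuple(isg[65:85]), ("cM",), delta),
        ModuleSpec("C4", tuple(isg[85:100]), ("pDC",), delta),
    )


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of the synthetic cohort."""

    n_patients: int = 4                      # flare patients (two samples each)
    n_controls: int = 6
    n_cells_per_sample: int = 1600
    cell_type_fractions: dict = field(default_factory=lambda: {
        g: dict(v) for g, v in DEFAULT_FRACTIONS.items()})
    clonotype_alpha: float = 1.0             # Zipf exponent of clone ranks
    n_clonotypes: int = 200                  # per patient per T compartment
    n_expanded_clones: int = 5
    expansion_fold: float = 4.0
    de_novo_fraction: float = 0.4            # of planted clones absent at baseline
    de_novo_baseline_equiv: int = 3          # de novo flare freq = fold * this / N_bf
    module_spec: tuple[ModuleSpec, ...] = field(default_factory=default_module_spec)
    nb_dispersion: float = 2.0               # NB size theta; var = mu + mu^2/theta
    library_size_mean: int = 2500            # median UMI per cell (lognormal)
    library_size_sigma: float = 0.25
    n_genes: int = 1000                      # total genes incl. panel/mito/platelet
    gene_weight_sigma: float = 0.8           # lognormal spread of gene abundances
    mito_fraction: float = 0.02              # baseline mito UMI share
    # contig noise (fractions of T cells per sample)
    frac_missing_chain: float = 0.05
    frac_secondary_chain: float = 0.03
    frac_low_confidence: float = 0.02
    # low-quality cell classes (fractions of cells per sample; no TCR emitted)
    frac_low_quality: float = 0.02
    frac_high_mito: float = 0.02
    frac_platelet: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        for grp, fr in self.cell_type_fractions.items():
            s = sum(fr.values())
            if abs(s - 1.0) > 1e-9:
                raise ValueError(f"cell type fractions of group {grp} sum to {s}, not 1")
        if self.expansion_fold < 1:
            raise ValueError("expansion_fold must be >= 1")
        seen: set[str] = set()
        for m in self.module_spec:
            overlap = seen & set(m.genes)
            if overlap:
                raise ValueError(f"module gene lists overlap: {sorted(overlap)[:3]}")
            seen |= set(m.genes)
        n_special = len(seen) + len(MITO_GENES) + len(PLATELET_GENES)
        if n_special > self.n_genes:
            raise ValueError(
                f"{n_special} module/marker genes exceed n_genes={self.n_genes}")

    @property
    def panel_genes(self) -> list[str]:
        return [g for m in self.module_spec for g in m.genes]


@dataclass
class GroundTruth:
    """Planted truth: clone fates, module assignment, composition."""

    clonotype_table: pd.DataFrame  # per patient x CD8 clone: counts, flags, phenotypes
    module_assignment: dict[str, str]
    composition: dict[str, dict[str, float]]

    def expanded_clonotypes(self, patient_id: Optional[str] = None) -> set[str]:
        t = self.clonotype_table
        if patient_id is not None:
            t = t[t["patient_id"] == patient_id]
        return set(t.loc[t["is_expanded"], "clonotype_id"])


class Cohort(NamedTuple):
    counts: CountsMatrix
    meta: pd.DataFrame
    contigs: list[ContigRecord]
    truth: GroundTruth


# ---------------------------------------------------------------------------
# deterministic clonotype identities

_AA = "ACDEFGHIKLMNPQRSTVWY"
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}


def _clone_chains(patient: str, compartment: str, rank: int) -> tuple[ChainCall, ChainCall]:
    """Deterministic TRA/TRB identity of a simulated clonotype."""
    h = hashlib.md5(f"{patient}|{compartment}|{rank}".encode()).digest()
    cdr3a = "C" + "".join(_AA[b % 20] for b in h[5:13]) + "F"
    cdr3b = "C" + "".join(_AA[b % 20] for b in h[8:16]) + "F"
    tra = ChainCall(
        v_gene=f"TRAV{1 + h[0] % 45}", d_gene="", j_gene=f"TRAJ{1 + h[1] % 56}",
        cdr3_aa=cdr3a, cdr3_nt="".join(_CODON[a] for a in cdr3a), umis=0,
    )
    trb = ChainCall(
        v_gene=f"TRBV{1 + h[2] % 30}", d_gene=f"TRBD{1 + h[3] % 2}",
        j_gene=f"TRBJ{1 + h[4] % 13}",
        cdr3_aa=cdr3b, cdr3_nt="".join(_CODON[a] for a in cdr3b), umis=0,
    )
    return tra, trb


def _quota_counts(weights: np.ndarray, total: int) -> np.ndarray:
    """Largest-remainder integer allocation of ``total`` over ``weights``."""
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    target = w * total
    base = np.floor(target).astype(int)
    rem = target - base
    short = int(total - base.sum())
    if short:
        order = np.argsort(-rem, kind="stable")
        base[order[:short]] += 1
    return base


def power_law_weights(n: int, alpha: float) -> np.ndarray:
    """Rank-frequency power law p_i proportional to i^-alpha, normalized."""
    w = np.arange(1, n + 1, dtype=float) ** (-alpha)
    return w / w.sum()


# ---------------------------------------------------------------------------
# generator


def simulate_cohort(config: SimConfig = SimConfig()) -> Cohort:
    """Generate (counts, meta, contigs, truth) for one synthetic cohort."""
    rng = np.random.default_rng(config.seed)

    # gene universe: panel + mito + platelet + background, fixed order
    panel = config.panel_genes
    n_bg = config.n_genes - len(panel) - len(MITO_GENES) - len(PLATELET_GENES)
    genes = list(panel) + list(MITO_GENES) + list(PLATELET_GENES) + [
        f"G{i:04d}" for i in range(1, n_bg + 1)]
    gene_idx = {g: i for i, g in enumerate(genes)}

    base_w = rng.lognormal(mean=0.0, sigma=config.gene_weight_sigma, size=len(genes))
    mito_ix = np.array([gene_idx[g] for g in MITO_GENES])
    plt_ix = np.array([gene_idx[g] for g in PLATELET_GENES])
    base_w[plt_ix] = 0.0  # platelet markers silent outside platelets
    other_sum = base_w.sum() - base_w[mito_ix].sum()
    base_w[mito_ix] = (config.mito_fraction / (1 - config.mito_fraction)) * other_sum / len(mito_ix)

    # sample plan
    samples: list[tuple[str, str, str, str]] = []  # sample, patient, timepoint, group
    for i in range(1, config.n_patients + 1):
        pid = f"P{i:02d}"
        samples.append((f"{pid}_BF", pid, "BF", "SLE"))
        samples.append((f"{pid}_FL", pid, "FL", "SLE"))
    for i in range(1, config.n_controls + 1):
        cid = f"C{i:02d}"
        samples.append((cid, cid, "NA", "CTL"))

    meta_rows: list[dict] = []
    contigs: list[ContigRecord] = []
    truth_rows: list[dict] = []
    blocks: list[sp.csr_matrix] = []

    # per-patient CD8 baseline state carried from BF to FL
    cd8_state: dict[str, dict] = {}

    qc_classes = np.array(["ok", "low_quality", "high_mito", "platelet"])
    qc_probs = np.array([
        1 - config.frac_low_quality - config.frac_high_mito - config.frac_platelet,
        config.frac_low_quality, config.frac_high_mito, config.frac_platelet,
    ])

    for sample, patient, timepoint, group in samples:
        n = config.n_cells_per_sample
        fr = config.cell_type_fractions[group]
        labels = np.array(list(fr))
        cell_types = rng.choice(labels, size=n, p=np.array(list(fr.values()))).astype(object)
        qc_class = rng.choice(qc_classes, size=n, p=qc_probs)
        cell_types[qc_class == "platelet"] = "Platelet"
        barcodes = [f"{sample}-{i:05d}" for i in range(1, n + 1)]

        # ---- clonotype assignment per T compartment (ok cells only)
        clone_of = np.full(n, -1, dtype=int)          # rank, or -1
        compartment_of = np.full(n, "", dtype=object)
        for compartment, types in (("CD8", CD8_TYPES), ("CD4", CD4_TYPES)):
            cells = np.flatnonzero(np.isin(cell_types, types) & (qc_class == "ok"))
            rng.shuffle(cells)
            K = cells.size
            if K == 0:
                continue
            if compartment == "CD8" and group == "SLE":
                ranks, counts = _cd8_counts(config, patient, timepoint, K, cd8_state, rng)
            else:
                w = power_law_weights(config.n_clonotypes, config.clonotype_alpha)
                counts = _quota_counts(w, K)
                ranks = np.arange(config.n_clonotypes)
            assign = np.repeat(ranks, counts)
            clone_of[cells] = assign
            compartment_of[cells] = compartment
            if compartment == "CD8" and group == "SLE":
                st = cd8_state[patient]
                # phenotype switch of planted clones: naive at BF, Tem at FL
                planted = st["planted_fold"] if timepoint == "BF" else (
                    st["planted_fold"] | st["planted_denovo"])
                forced = "CD8 naive" if timepoint == "BF" else "CD8 Tem"
                for cell, rk in zip(cells, assign):
                    if rk in planted:
                        cell_types[cell] = forced
                st[f"celltypes_{timepoint}"] = {
                    int(c): str(cell_types[c]) for c in cells}
                st[f"assign_{timepoint}"] = dict(zip(cells.tolist(), assign.tolist()))

        # ---- expression
        blocks.append(
            _expression_block(config, rng, genes, base_w, mito_ix, plt_ix,
                              cell_types, qc_class, group, timepoint)
        )

        # ---- contigs with noise
        t_cells = np.flatnonzero(clone_of >= 0)
        perm = rng.permutation(t_cells)
        n_miss = int(round(config.frac_missing_chain * t_cells.size))
        n_sec = int(round(config.frac_secondary_chain * t_cells.size))
        n_low = int(round(config.frac_low_confidence * t_cells.size))
        missing = set(perm[:n_miss].tolist())
        secondary = set(perm[n_miss:n_miss + n_sec].tolist())
        lowconf = set(perm[n_miss + n_sec:n_miss + n_sec + n_low].tolist())
        drop_tra = rng.random(n) < 0.5  # which chain a missing-chain cell loses

        for cell in t_cells:
            bc = barcodes[cell]
            tra, trb = _clone_chains(patient, compartment_of[cell], int(clone_of[cell]))
            umis_a = 2 + int(rng.poisson(2))
            umis_b = 2 + int(rng.poisson(2))
            hc_a = cell not in lowconf
            if not (cell in missing and drop_tra[cell]):
                contigs.append(ContigRecord(bc, "TRA", tra.v_gene, "", tra.j_gene,
                                            tra.cdr3_aa, tra.cdr3_nt, umis_a, hc_a, True))
            if not (cell in missing and not drop_tra[cell]):
                contigs.append(ContigRecord(bc, "TRB", trb.v_gene, trb.d_gene, trb.j_gene,
                                            trb.cdr3_aa, trb.cdr3_nt, umis_b, True, True))
            if cell in secondary:
                h = hashlib.md5(bc.encode()).digest()
                alt = "C" + "".join(_AA[b % 20] for b in h[:9]) + "F"
                contigs.append(ContigRecord(
                    bc, "TRA", f"TRAV{1 + h[9] % 45}", "", f"TRAJ{1 + h[10] % 56}",
                    alt, "".join(_CODON[a] for a in alt), 1, True, True))

        for i in range(n):
            meta_rows.append(dict(
                barcode=barcodes[i], sample_id=sample, patient_id=patient,
                timepoint=timepoint, group=group, cell_type=str(cell_types[i]),
            ))

    # ---- ground truth for the CD8 compartment of each patient
    for i in range(1, config.n_patients + 1):
        pid = f"P{i:02d}"
        st = cd8_state[pid]
        truth_rows.extend(_truth_for_patient(config, pid, st))

    truth = GroundTruth(
        clonotype_table=pd.DataFrame(truth_rows),
        module_assignment={g: m.module_id for m in config.module_spec for g in m.genes},
        composition={g: dict(v) for g, v in config.cell_type_fractions.items()},
    )

    counts = CountsMatrix(
        sp.hstack(blocks, format="csr"),
        tuple(genes),
        tuple(r["barcode"] for r in meta_rows),
    )
    meta = pd.DataFrame(meta_rows).set_index("barcode")
    return Cohort(counts, meta, contigs, truth)


def _cd8_counts(config, patient, timepoint, K, cd8_state, rng):
    """Clone ranks and quota counts for a disease patient's CD8 compartment."""
    n_c = config.n_clonotypes
    if timepoint == "BF":
        w = power_law_weights(n_c, config.clonotype_alpha)
        counts = _quota_counts(w, K)
        # plant expansions among mid-sized baseline clones; the size band
        # scales with repertoire size so the planted mass stays bounded
        n_denovo = int(round(config.de_novo_fraction * config.n_expanded_clones))
        n_fold = config.n_expanded_clones - n_denovo
        lo, hi = max(3, K // 128), max(4, K // 40)
        eligible = [r for r in range(n_c) if lo <= counts[r] <= hi]
        if len(eligible) < n_fold:
            # fall back to the clones closest to the target size band
            eligible = sorted(range(n_c), key=lambda r: abs(int(counts[r]) - hi))
        planted_fold = set(eligible[:n_fold])
        planted_denovo = set(range(n_c, n_c + n_denovo))
        cd8_state[patient] = dict(
            K_bf=K, counts_bf=counts,
            planted_fold=planted_fold, planted_denovo=planted_denovo,
        )
        return np.arange(n_c), counts
    # FL: planted clones at fold x realized baseline frequency
    st = cd8_state[patient]
    counts_bf, K_bf = st["counts_bf"], st["K_bf"]
    fold = config.expansion_fold
    n_denovo = len(st["planted_denovo"])
    p = np.zeros(n_c + n_denovo)
    nonplanted_mass = 0.0
    for r in range(n_c):
        if r in st["planted_fold"]:
            p[r] = fold * counts_bf[r] / K_bf
        else:
            p[r] = counts_bf[r] / K_bf
            nonplanted_mass += p[r]
    for j, r in enumerate(sorted(st["planted_denovo"])):
        p[r] = fold * config.de_novo_baseline_equiv / K_bf
    planted_mass = p.sum() - nonplanted_mass
    if planted_mass >= 0.8:
        raise ValueError("planted expansions exceed the repertoire budget; "
                         "reduce n_expanded_clones or expansion_fold")
    scale = (1.0 - planted_mass) / nonplanted_mass
    for r in range(n_c):
        if r not in st["planted_fold"]:
            p[r] *= scale
    counts_fl = _quota_counts(p, K)
    st["K_fl"] = K
    st["counts_fl"] = counts_fl
    return np.arange(n_c + n_denovo), counts_fl


def _expression_block(config, rng, genes, base_w, mito_ix, plt_ix,
                      cell_types, qc_class, group, timepoint) -> sp.csr_matrix:
    """NB counts for one sample; cells grouped by identical mean profile."""
    n = len(cell_types)
    lib = rng.lognormal(mean=math.log(config.library_size_mean),
                        sigma=config.library_size_sigma, size=n)
    lib = np.where(qc_class == "low_quality", lib * 0.1, lib)

    profile_key = [f"{ct}|{qc}" for ct, qc in zip(cell_types, qc_class)]
    out = np.zeros((len(genes), n))
    gene_idx = {g: i for i, g in enumerate(genes)}
    for key in sorted(set(profile_key)):
        cells = np.array([i for i, k in enumerate(profile_key) if k == key])
        ct, qc = key.split("|")
        w = base_w.copy()
        if group == "SLE":
            for m in config.module_spec:
                tp_ok = m.timepoints is None or timepoint in m.timepoints
                ct_ok = m.elevated_cell_types == "all" or ct in m.elevated_cell_types
                if tp_ok and ct_ok:
                    ix = np.array([gene_idx[g] for g in m.genes])
                    w[ix] *= math.exp(m.delta)
        if qc == "high_mito":
            other = w.sum() - w[mito_ix].sum()
            w[mito_ix] = 0.25 / 0.75 * other / len(mito_ix)  # ~25% mito content
        if ct == "Platelet":
            w[plt_ix] = 0.05 * w.sum()
        rel = w / w.sum()
        mu = rel[:, None] * lib[cells][None, :]
        theta = config.nb_dispersion
        lam = rng.gamma(theta, mu / theta)
        out[:, cells] = rng.poisson(lam)
    return sp.csr_matrix(out.astype(np.int64))


def _truth_for_patient(config, pid, st) -> list[dict]:
    """Per-clone truth rows; is_expanded is the expansion rule on true counts."""
    from .expansion import ExpansionParams, classify_expansion
    from .repertoire import RepertoireProfile

    counts_bf, counts_fl = st["counts_bf"], st["counts_fl"]
    n_total = len(counts_fl)
    bf_map = {r: int(counts_bf[r]) for r in range(len(counts_bf)) if counts_bf[r] > 0}
    fl_map = {r: int(counts_fl[r]) for r in range(n_total) if counts_fl[r] > 0}
    bf_prof = RepertoireProfile((pid, "BF"), {str(r): c for r, c in bf_map.items()}, pid)
    fl_prof = RepertoireProfile((pid, "FL"), {str(r): c for r, c in fl_map.items()}, pid)
    calls = classify_expansion(bf_prof, fl_prof, ExpansionParams())
    status = {int(c.clonotype_id): c.expanded for c in calls}

    # dominant realized phenotype per clone at each timepoint
    pheno: dict[str, dict[int, dict[str, int]]] = {"BF": {}, "FL": {}}
    for tp in ("BF", "FL"):
        assign = st.get(f"assign_{tp}", {})
        ctypes = st.get(f"celltypes_{tp}", {})
        for cell, rk in assign.items():
            d = pheno[tp].setdefault(rk, {})
            ct = ctypes[cell]
            d[ct] = d.get(ct, 0) + 1

    rows = []
    for r in sorted(set(bf_map) | set(fl_map)):
        tra, trb = _clone_chains(pid, "CD8", r)
        key = f"{pid}::" + clonotype_key(tra, trb, "genes_plus_cdr3aa")
        planted = r in st["planted_fold"] or r in st["planted_denovo"]
        rows.append(dict(
            patient_id=pid,
            sim_clone=f"{pid}.CD8.{r}",
            clonotype_id=key,
            baseline_count=bf_map.get(r, 0),
            flare_count=fl_map.get(r, 0),
            is_expanded=bool(status.get(r, False)),
            planted=bool(planted),
            baseline_phenotype=_dominant(pheno["BF"].get(r)) or "absent",
            flare_phenotype=_dominant(pheno["FL"].get(r)) or "absent",
        ))
    return rows


def _dominant(dist: Optional[dict]) -> Optional[str]:
    if not dist:
        return None
    return max(sorted(dist), key=lambda k: dist[k])


# ---------------------------------------------------------------------------
# fixture emission


FIXTURE_FILES = ("matrix.mtx", "genes.tsv", "barcodes.tsv",
                 "contigs.csv", "cell_meta.csv", "ground_truth.json")


def emit_fixture(outdir, cohort: Cohort) -> list[Path]:
    """Write the cohort as the six canonical files readable by io_formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_mtx_triplet(cohort.counts, outdir / "matrix.mtx",
                      outdir / "genes.tsv", outdir / "barcodes.tsv")
    write_contigs(cohort.contigs, outdir / "contigs.csv")
    write_cell_meta(cohort.meta, outdir / "cell_meta.csv")
    write_json(
        dict(
            clonotype_table=cohort.truth.clonotype_table.to_dict("records"),
            module_assignment=cohort.truth.module_assignment,
            composition=cohort.truth.composition,
        ),
        outdir / "ground_truth.json",
    )
    return [outdir / f for f in FIXTURE_FILES]


def load_fixture(outdir) -> Cohort:
    """Read a fixture directory back into memory."""
    import json

    outdir = Path(outdir)
    counts = read_mtx_triplet(outdir / "matrix.mtx", outdir / "genes.tsv",
                              outdir / "barcodes.tsv")
    meta = read_cell_meta(outdir / "cell_meta.csv")
    contigs = read_contigs(outdir / "contigs.csv", dialect="tenx_csv")
    gt = json.loads((outdir / "ground_truth.json").read_text())
    truth = GroundTruth(
        clonotype_table=pd.DataFrame(gt["clonotype_table"]),
        module_assignment=gt["module_assignment"],
        composition=gt["composition"],
    )
    return Cohort(counts, meta, contigs, truth)
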