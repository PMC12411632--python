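"""End-to-end orchestration: QC -> clonotypes -> repertoire -> expansion ->
interferon modules -> DE/composition, with a reproducibility manifest.

Every stage is a pure function of (inputs, parameters, seed); the manifest
echoes all parameters, the seed and per-stage record counts so a run can be
reproduced byte-for-byte.  All the headline thresholds live in one place
(the dataclass defaults surfaced through :class:`RunConfig`): >500 genes,
<5% mito, fold change >1.25, adjusted p < 1e-6, expansion fold 2, minimum
3 flare cells, top-10 clonal proportion.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clonotypes import call_clonotypes, repertoire_from_calls
from .de_and_composition import composition_compare, de_test
from .expansion import ExpansionParams, classify_expansion, expanded_set, fate_table
from .ifn_modules import (
    DEFAULT_K_RANGE,
    cluster_panel,
    compare_scores_by_group,
    log2fc_profile,
    module_scores,
)
from .io_formats import read_cell_meta, read_contigs, read_gene_panel, read_mtx_triplet, write_json
from .qc import QCParams, filter_cells
from .repertoire import (
    shannon_diversity,
    similarity_matrix,
    top_n_proportion,
    unique_clonotypes,
)

logger = logging.getLogger(__name__)

STAGES = ("qc", "clonotypes", "repertoire", "expansion", "ifn_modules", "de_and_composition")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Paths and parameters of a full run; see ``RunConfig.from_yaml``."""

    counts_mtx: str
    genes_tsv: str
    barcodes_tsv: str
    contigs_csv: str
    meta_csv: str
    panel_txt: Optional[str]
    outdir: str
    contig_dialect: str = "tenx_csv"
    key_mode: str = "genes_plus_cdr3aa"
    qc: QCParams = field(default_factory=QCParams)
    expansion: ExpansionParams = field(default_factory=ExpansionParams)
    k_range: tuple[int, ...] = DEFAULT_K_RANGE
    top_n: int = 10
    cd8_prefix: str = "CD8"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "qc" in raw:
            raw["qc"] = QCParams(**raw["qc"])
        if "expansion" in raw:
            raw["expansion"] = ExpansionParams(**raw["expansion"])
        if "k_range" in raw:
            raw["k_range"] = tuple(raw["k_range"])
        return cls(**raw)

    def validate(self) -> None:
        required = [self.counts_mtx, self.genes_tsv, self.barcodes_tsv,
                    self.contigs_csv, self.meta_csv]
        if self.panel_txt:
            required.append(self.panel_txt)
        missing = [p for p in required if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"missing input files: {missing}")

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        d["qc"] = dataclasses.asdict(self.qc)
        d["expansion"] = dataclasses.asdict(self.expansion)
        return d


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages, write artifacts under ``config.outdir``, return the manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = dict(
        tool="clonodyn", version=__version__, seed=config.seed,
        parameters=config.echo(), stages={},
    )

    counts = read_mtx_triplet(config.counts_mtx, config.genes_tsv, config.barcodes_tsv)
    meta = read_cell_meta(config.meta_csv)
    contigs = read_contigs(config.contigs_csv, config.contig_dialect)
    panel = read_gene_panel(config.panel_txt) if config.panel_txt else None

    stage = "qc"
    try:
        counts_qc, qc_report = filter_cells(counts, config.qc)
        meta_qc = meta.loc[list(counts_qc.barcodes)]
        write_json(qc_report.as_dict(), outdir / "qc_report.json")
        manifest["stages"][stage] = dict(
            n_in=counts.n_cells, n_out=counts_qc.n_cells, report=qc_report.as_dict())
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    stage = "clonotypes"
    try:
        calls, filt_report = call_clonotypes(contigs, mode=config.key_mode)
        calls = [c for c in calls if c.barcode in meta_qc.index]
        pd.DataFrame(
            dict(barcode=[c.barcode for c in calls],
                 clonotype_id=[c.clonotype_id for c in calls],
                 key_mode=[c.key_mode for c in calls])
        ).to_csv(outdir / "clonotype_calls.tsv", sep="\t", index=False)
        write_json(filt_report.as_dict(), outdir / "contig_filter_report.json")
        manifest["stages"][stage] = dict(
            n_contigs_in=filt_report.n_contigs_in, n_cells_called=len(calls),
            report=filt_report.as_dict())
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    stage = "repertoire"
    try:
        cd8_meta = meta_qc[meta_qc["cell_type"].str.startswith(config.cd8_prefix)]
        cd8_calls = [c for c in calls if c.barcode in cd8_meta.index]
        profiles = repertoire_from_calls(cd8_calls, cd8_meta, stratify_by=("sample_id",))
        rows = []
        for stratum, prof in profiles.items():
            rows.append(dict(
                sample_id=stratum[0],
                n_cells=prof.N,
                shannon=shannon_diversity(prof),
                unique_clonotypes=unique_clonotypes(prof),
                top10_proportion=top_n_proportion(prof, config.top_n),
            ))
        rep_table = pd.DataFrame(rows)
        rep_table.to_csv(outdir / "repertoire_metrics.tsv", sep="\t", index=False)
        if len(profiles) >= 2:
            similarity_matrix(list(profiles.values())).to_csv(
                outdir / "similarity_matrix.tsv", sep="\t")
        manifest["stages"][stage] = dict(n_strata=len(profiles))
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    stage = "expansion"
    try:
        exp_rows = []
        fate_tables = {}
        sample_tp = meta_qc.groupby("sample_id")[["patient_id", "timepoint"]].first()
        for patient, sub in sample_tp.groupby("patient_id"):
            bf = sub.index[sub["timepoint"] == "BF"]
            fl = sub.index[sub["timepoint"] == "FL"]
            if len(bf) != 1 or len(fl) != 1:
                continue
            bf_prof = profiles.get((bf[0],))
            fl_prof = profiles.get((fl[0],))
            if bf_prof is None or fl_prof is None:
                continue
            exp_calls = classify_expansion(bf_prof, fl_prof, config.expansion)
            exp_rows.extend(dataclasses.asdict(c) for c in exp_calls)
            fate_tables[patient] = fate_table(cd8_calls, cd8_meta, exp_calls)
        exp_df = pd.DataFrame(exp_rows)
        exp_df.to_csv(outdir / "expansion_calls.tsv", sep="\t", index=False)
        for patient, tbl in fate_tables.items():
            tbl.to_csv(outdir / f"fate_table_{patient}.tsv", sep="\t")
        n_exp = int((exp_df["status"].isin(("expanded_fold", "expanded_de_novo"))).sum()) if len(exp_df) else 0
        manifest["stages"][stage] = dict(
            n_patients=len(fate_tables), n_clonotypes=len(exp_df), n_expanded=n_exp)
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    stage = "ifn_modules"
    try:
        if panel:
            profile = log2fc_profile(counts_qc, meta_qc, panel)
            profile.log2fc.to_csv(outdir / "panel_log2fc.tsv", sep="\t")
            partition = cluster_panel(profile, k_range=config.k_range, seed=config.seed)
            pd.Series(partition.assignment, name="module").rename_axis("gene").to_csv(
                outdir / "module_partition.tsv", sep="\t")
            pd.Series(partition.silhouette_by_K, name="silhouette").rename_axis("K").to_csv(
                outdir / "silhouette_by_K.tsv", sep="\t")
            scores = module_scores(counts_qc, partition.gene_sets(), seed=config.seed)
            scores.to_csv(outdir / "module_scores.tsv", sep="\t")
            manifest["stages"][stage] = dict(
                n_panel_genes=len(partition.assignment), K=partition.K,
                silhouette_by_K=partition.silhouette_by_K)
        else:
            manifest["stages"][stage] = dict(skipped="no gene panel provided")
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    stage = "de_and_composition"
    try:
        comp = composition_compare(meta_qc)
        comp.per_sample.to_csv(outdir / "composition_fractions.tsv", sep="\t")
        comp.tests.to_csv(outdir / "composition_tests.tsv", sep="\t")
        de = de_test(counts_qc, meta_qc)
        pd.DataFrame([dataclasses.asdict(r) for r in de]).to_csv(
            outdir / "de_results.tsv", sep="\t", index=False)
        manifest["stages"][stage] = dict(
            n_cell_types=comp.per_sample.shape[1],
            n_genes_tested=len(de),
            n_significant=sum(r.significant for r in de),
        )
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    write_json(manifest, outdir / "manifest.json")
    return manifest
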