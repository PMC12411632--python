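# clonodyn

Paired single-cell RNA + TCR analysis of T-cell clonotype dynamics across
autoimmune disease flares.

In relapsing–remitting autoimmune disease such as systemic lupus
erythematosus (SLE), flares are accompanied by clonal expansion of cytotoxic
CD8 T cells and a strong interferon (IFN) transcriptional signature.
`clonodyn` implements the analysis chain needed to quantify this from
10x-style data — a gene × cell UMI count matrix plus per-cell TCR contig
annotations for paired before-flare (BF) and flare (FL) samples:

* **QC** — keep cells with more than 500 detected genes and <5%
  mitochondrial UMI content, and drop platelet-marker-positive cells
  (*PPBP*, *PF4*, *NRGN*); blacklist TCR/Ig variable, ribosomal,
  mitochondrial and dissociation-stress genes for feature-level analyses.
* **Clonotype calling** — the four-rule contig filter: keep high-confidence
  contigs; per cell and chain keep the highest-UMI contig; keep only cells
  with a paired α and β chain; key clonotypes on V(D)J genes (optionally
  plus CDR3 amino-acid sequence).
* **Repertoire statistics** — Shannon entropy H = −Σ pᵢ ln pᵢ over clonotype
  proportions, richness, top-10 clonal proportion, and the Morisita–Horn
  similarity index between repertoires,
  MH = 2 Σ xᵢyᵢ / [(Σxᵢ²/X² + Σyᵢ²/Y²)·X·Y].
* **Flare-expansion classification** — a clonotype is expanded when it shows
  a ≥2-fold increase in cell count from BF to FL (or is absent at BF and
  present at FL), expands proportionally (its repertoire frequency rises),
  and is represented by ≥3 cells in the flare state; expanded clones are
  tracked across CD8 subtypes (naive → effector-memory fate tables).
* **IFN modules** — per-cell-type log2 fold-change profiles of a 100-gene
  IFN panel, partitioned by K-means with silhouette-based selection of K;
  per-cell module scores (mean normalized expression minus an
  expression-bin-matched control set, z-scored).
* **DE and composition** — per-gene two-group Mann–Whitney tests with the
  strict significance rule (fold change > 1.25 and Benjamini–Hochberg
  adjusted p < 10⁻⁶), per-sample cell-type composition tests, and subtype
  ratios (e.g. ABC / memory B).

Because the matched patient data underlying such studies are access
controlled, the package ships a first-class synthetic cohort generator
(`clonodyn.synthetic_data`) that emits paired expression + TCR + metadata
cohorts with *planted* ground truth — expanded clones with known fold and
phenotype switch, cell-type-specific IFN module activation, and group
composition shifts — so every stage is testable end to end.

## Worked example

```python
from clonodyn import (SimConfig, simulate_cohort, call_clonotypes,
                      repertoire_from_calls, classify_expansion,
                      shannon_diversity, top_n_proportion, morisita_horn)

cfg = SimConfig(seed=7, n_patients=1, n_controls=0,
                n_cells_per_sample=1600, n_genes=150, module_spec=())
cohort = simulate_cohort(cfg)

calls, report = call_clonotypes(cohort.contigs)
print(f"{report.n_contigs_in} contigs -> {report.n_cells_called} paired cells")

cd8 = cohort.meta[cohort.meta.cell_type.str.startswith("CD8")]
profiles = repertoire_from_calls(
    [c for c in calls if c.barcode in cd8.index], cd8, ("sample_id",))
bf, fl = profiles[("P01_BF",)], profiles[("P01_FL",)]
print(f"BF: N={bf.N}  H={shannon_diversity(bf):.3f}  top10={top_n_proportion(bf):.3f}")
print(f"FL: N={fl.N}  H={shannon_diversity(fl):.3f}  top10={top_n_proportion(fl):.3f}")
print(f"Morisita-Horn(BF, FL) = {morisita_horn(bf, fl):.3f}")

expanded = [c for c in classify_expansion(bf, fl) if c.expanded]
print(f"expanded clonotypes: {len(expanded)} "
      f"(planted: {len(cohort.truth.expanded_clonotypes('P01'))})")
```

prints

```
3770 contigs -> 1771 paired cells
BF: N=463  H=4.052  top10=0.508
FL: N=468  H=3.891  top10=0.590
Morisita-Horn(BF, FL) = 0.820
expanded clonotypes: 5 (planted: 5)
```

The flare repertoire is measurably more clonal than baseline — entropy drops
(4.05 → 3.89) while the share of the ten largest clonotypes rises
(0.51 → 0.59) — and the expansion rule recovers exactly the five planted
clones.  The Morisita–Horn index of 0.82 reflects the within-patient
stability of the repertoire across the flare.

## Command line

```bash
clonodyn simulate --seed 1 --out fixture/        # synthetic cohort + panel
clonodyn run --config run.yaml                   # full pipeline + manifest
clonodyn clonotype --contigs contigs.csv --out calls.tsv
clonodyn qc --counts matrix.mtx --genes genes.tsv --barcodes barcodes.tsv --out qc/
```

`clonodyn run` executes QC → clonotypes → repertoire → expansion → IFN
modules → DE/composition, writing every intermediate table plus a
`manifest.json` echoing all parameters, seeds and per-stage counts; reruns
with the same config are byte-identical.

## Ground-truth JSON schema

`emit_fixture` writes `ground_truth.json` with three keys:
`clonotype_table` (records of `patient_id`, `sim_clone`, `clonotype_id`,
`baseline_count`, `flare_count`, `is_expanded`, `planted`,
`baseline_phenotype`, `flare_phenotype`), `module_assignment`
(gene → module label), and `composition` (group → cell type → fraction).
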