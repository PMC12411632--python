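# Methods

This note records the models, conventions and numerical choices behind
`clonodyn`, and what the synthetic cohorts do and do not establish about
real data.

## Cell and gene quality control

Cells are retained when all three conditions hold on the *original* matrix
(the rules are not applied sequentially, so filtering is idempotent):
strictly more than `min_genes_per_cell` (default 500) genes with ≥1 UMI;
mitochondrial UMI fraction strictly below `max_mito_fraction` (default
0.05); and no platelet-marker expression (any count above
`platelet_threshold`, default 0, in *PPBP*, *PF4* or *NRGN*).  Both
thresholds are deliberately strict inequalities.  Mitochondrial genes are
recognised by the GRCh38 "MT-" symbol prefix (case-insensitive,
configurable).  A cell failing several rules is attributed to the first
failing rule (genes → mito → platelet) in the QC report, so the per-rule
rejection counts plus retained cells always sum to the input.  The
detection rule (≥1 UMI) is recorded in the report because other detection
conventions exist.  When no mitochondrial genes are present the rule is
skipped with a warning rather than silently passing everything.

The variable-feature blacklist removes TCR and immunoglobulin variable
segments, ribosomal proteins, mitochondrial genes, and a dissociation-stress
signature.  The shipped stress list is a synthetic stand-in assembled from
the conventional immediate-early/heat-shock families (FOS/JUN/EGR/HSP…);
analyses tied to a specific published signature should override it.

## Clonotype calling

Four rules, in order: (1) drop contigs not flagged high-confidence — and by
default also non-productive contigs, the 10x filtered-contig convention
(`require_productive=False` restores the literal four rules); (2) per cell
and chain keep the highest-UMI contig, breaking exact UMI ties
lexicographically over the full chain identity `(cdr3_nt, v_gene, j_gene,
d_gene, cdr3_aa)` so the output is invariant to row order (the original
two-field tie-break is not a total order); (3) drop cells lacking either
chain; (4) build the clonotype key.  Two key modes are supported and always
recorded: `genes_only` (TRA V/J + TRB V/D/J — the sparser key) and the
field-standard default `genes_plus_cdr3aa`, which appends the CDR3
amino-acid sequences.  Whether the original convention included CDR3 is
ambiguous; both are first-class rather than guessing intent.  Clonotype
identifiers are namespaced per patient: clonotypes are compared across
timepoints within a patient and across samples only through similarity
indices, never by merging identifiers across patients.

## Repertoire statistics

Diversity is Shannon entropy over clonotype cell-count proportions
(natural log by default; the base is a parameter and is recorded).
Diversity is computed on cells per clonotype, not UMIs.  No
rarefaction is applied by default — diversity comparisons across unequal
depths are depth-sensitive, so a subsample-to-common-depth option
(`RepertoireProfile.subsample`) exists but is off unless requested.  The
Morisita–Horn index is computed over the union of clonotype keys with
absent clones as zero; it is symmetric, bounded in [0, 1] and invariant to
proportional scaling of either repertoire.  The top-n proportion resolves
count ties lexicographically by clonotype id so results are deterministic.

## Expansion classification

For each clonotype of the BF ∪ FL union, with counts `n_bf`, `n_fl` and
frequencies `p_bf`, `p_fl`: a clone absent at baseline and present at flare
is a de novo candidate; a clone with `n_fl ≥ τ·n_bf` (τ default 2, on raw
cell counts) *and* `p_fl > p_bf` (the proportional conjunct, on by default)
is a fold-expansion candidate.  Candidates with fewer than `m` (default 3)
flare cells are recorded as `excluded_min_cells`; the gate never relabels a
clone that would not have been called expanded.  De novo clones must also
meet `m` — a "present at flare" clone with fewer than 3 cells would be
spurious by the filter's own logic.  Both the count fold and the proportion
fold are emitted on every call so either reading of "increase in size" is
auditable.  Fate tables attribute transitions at the clonotype level: each
expanded clonotype contributes unit weight split over (BF subtype, FL
subtype) pairs proportionally to its cell-type distributions, preventing
large clones from dominating the transition structure; a cell-weighted
variant is available.  Patients with multiple flare cycles are analyzed one
BF→FL pair at a time.

## Interferon modules

Fold-change profiles are per cell type: log2 of the ratio of linear
counts-per-10k group means with pseudocount ε = 0.01.  (Rank tests and
module-score averaging use log1p CP10K; the fold change itself is on linear
means, which is what makes a planted log-space effect δ appear as
log2FC ≈ δ/ln 2.)  Significance flags apply the strict FC > 1.25 ∧ BH
p < 10⁻⁶ conjunction per cell type across the panel.  K-means runs on the
raw log2FC rows (Euclidean, no row scaling), 50 greedy-k-means++ restarts
per K, best within-cluster sum of squares kept; K* maximizes the mean
silhouette over the candidate range (ties to the smaller K).  Cluster
labels are renumbered C1, C2, … by descending size with ties broken by the
lexicographically smallest member gene, making the labelling deterministic
and row-order invariant.  An all-identical profile raises "no cluster
structure" rather than returning an arbitrary partition.

Module scores default to the expression-bin-matched control convention
(24 bins, 100 control genes per bin, via `scanpy.tl.score_genes`), mirroring
the Seurat-style `AddModuleScore`; a plain-mean mode matches the simpler
"average expression of the gene set" description.  Scores are z-normalized
across all scored cells; a zero-variance module scores 0 everywhere (the
guard uses a relative tolerance because a numerically constant score can
retain ~1e-16 float residue).  The scoring mode is recorded.

## Differential expression and composition

Model-based single-cell DE (hurdle models) is out of scope; `de_test` is a
per-gene two-sided Mann–Whitney U on log1p CP10K expression, with the test
name stored in every result row so the substitution is explicit.  Fold
change is on linear normalized means with ε = 0.01; significance is the
strict conjunction above.  Benjamini–Hochberg is implemented directly
(step-up with monotone enforcement, order-preserving) because it is a named
primitive of the pipeline; tests cross-check it against both an enumeration
oracle and `statsmodels`.  Composition tests compare per-sample cell-type
fractions between groups with Mann–Whitney, BH-corrected across cell types
— samples, not cells, are the independent units, avoiding pseudoreplication.
Subtype ratios exclude samples with a zero denominator, with a log entry.

## Synthetic cohorts

The generator emulates the study design: each control contributes one
sample, each patient a BF and an FL sample (default 4 patients, 6 controls,
1600 cells/sample, 1000 genes).  Cell types are drawn from group-specific
fractions chosen to reflect the disease-associated shifts the statistics
must detect (ABC enrichment, lower CD4 fraction, higher CD8 Tem in
disease).  Expression is gamma-Poisson (negative binomial, shared
dispersion θ = 2) around lognormal library sizes (median 2500, σ = 0.25);
gene relative abundances are lognormal (σ = 0.8), with ~2% mitochondrial
content and dedicated low-quality / high-mito / platelet cell classes so QC
has real work to do.  The default 100-gene IFN panel is partitioned into
four planted modules with effect δ = ln 2 in their elevated cell types of
disease cells only: a broadly induced module, a CD8/lymphocyte module, a
classical-monocyte module and a pDC module — the cell-type-specific
structure the clustering stage must rediscover.

Clone sizes follow a rank-frequency power law pᵢ ∝ i^(−α).  The clone-size
law is not constrained by published parameter values, so α is a modeling
choice: the default is α = 1 (Zipf), under which the planted flare
expansion produces the expected repertoire concentration (entropy falls,
top-10 share rises).  Steeper exponents concentrate the baseline into one
giant clone, and expanding mid-sized clones then *flattens* the
distribution — the opposite of the flare phenotype being modeled.

Clone counts are realized by deterministic largest-remainder quota
allocation rather than multinomial draws.  This is the generator's central
design decision: planted expansions are exact (flare frequency =
fold × realized baseline frequency; de novo clones enter at
fold × 3/N_bf), the planted set is *provably* the only set crossing the
expansion rule (quota error is under one cell, so a non-planted clone can
never double), and `is_expanded` in the ground truth — the rule applied to
the true counts — coincides with the planted flags.  Planted fold-clones
are chosen from a mid-size band that scales with repertoire size
(≈ N/128 … N/40 cells) so their total flare mass stays bounded; exceeding
an 80% mass budget is a configuration error.  Planted clones are naive at
baseline and switch wholly to CD8 Tem at flare.  Randomness enters through
cell-type assignment, expression sampling and injected contig noise
(per-cell missing chains, low-UMI secondary chains, low-confidence flags;
defaults 5% / 3% / 2%).  TCR chain identities (V/J genes, CDR3) are a
deterministic hash of the clonotype identity, so clonotype keys are
unambiguous and fixtures are byte-reproducible.

What passing tests do **not** show about real data: no V(D)J recombination
model, no somatic hypermutation, no batch effects or ambient RNA, no
doublets, shared NB dispersion across genes, total (not partial) phenotype
switching, and clone realization without multinomial sampling noise — so
real-data expansion calls near the rule boundaries will be noisier than the
planted-recovery results suggest.

## Problem sizes and determinism

Tests run the generator at 400–2400 cells per sample (up to ~7k cells) and
recovery checks over 20–50 seeds; the acceptance script runs the default
cohort (22,400 cells, 1000 genes) once.  These sizes were chosen so the
planted effects sit well inside their detection limits while the whole
suite stays interactive.  Every stage is a pure function of (inputs,
parameters, seed); pipeline reruns are byte-identical, and the manifest
echoes every parameter and per-stage count.
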