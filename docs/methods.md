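# Methods

## Coordinate and strand conventions

All internal coordinates are 0-based half-open; GFF3/GTF 1-based
inclusive coordinates are converted at the I/O boundary only, and BED is
consumed as-is. Transcription-unit identifiers follow the field's
`chrom_start_end` convention with 1-based inclusive coordinates, so the
unit spanning internal `[268286, 269650)` on chrIII is named
`chrIII_268287_269650`.

The library protocol is modelled explicitly. For dUTP (reverse-stranded)
single-end libraries — the default — the sequenced read aligns opposite
to the originating transcript, so the transcript strand is the reverse of
the alignment strand (SAM FLAG bit 0x10). `stranded_forward` inverts the
rule; `unstranded` libraries raise, because sense/antisense calls are
then undefined rather than silently wrong.

## Read filtering and classification

Unmapped, secondary (0x100) and supplementary (0x800) records are dropped,
as are reads below a MAPQ floor (default 10). The floor is a package
decision: multimapper policy is rarely printed in analyses of this kind,
and unique-alignment filtering is the conservative default; it is
configurable everywhere it appears.

A gene "qualifies" for a read when it covers at least `min_overlap_frac`
(default 0.5) of the read's aligned length. The default keeps boundary
reads from flipping category on a 1-bp overlap. Reads whose qualifying
genes sit on both strands are *ambiguous* and are excluded from assembly
and counting — with overlapping gene pairs there is no defensible single
call, and exclusion avoids double counting. Category assignment is a
partition: every filtered read gets exactly one of
sense/antisense/intergenic/ambiguous.

## Assembly of antisense transcription units

Antisense and intergenic reads are pooled first (the two signals are
merged before assembly, and each resulting model is then labelled by the
origin of its member reads), then merged per (chromosome, transcript
strand): reads sorted by start are greedily clustered while the gap to
the running cluster end is ≤ `max_gap`. Clusters with fewer than
`min_reads` members or spanning less than `min_length` are discarded.

Defaults — `max_gap` 50 bp, `min_reads` 3, `min_length` 100 bp — suppress
singleton noise while keeping genuine low-abundance units; they are
surfaced in the configuration and the run log because the downstream
counts depend on them. The merge is equivalent to a per-base
coverage-union with the same gap rule (the test suite checks this against
an independent per-base oracle), which also makes assembly idempotent.
Yeast antisense units are treated as contiguous intervals; there is no
intron-aware assembly.

## Differential expression

The engine is a conditional exact test for negative-binomial counts,
applied identically to antisense units and to sense genes.

With replicate counts summed per condition (sums S_a, S_b; summed library
sizes L_a, L_b; pooled total T = S_a + S_b):

* log2 fold change: `log2(((S_b + c)/L_b) / ((S_a + c)/L_a))` with
  pseudocount c = 0.5, so zero counts give finite ratios.
* p-value: the distribution of the split of T between conditions, given
  T. At dispersion φ = 0 this is exactly Binomial(T, L_b/(L_a+L_b)). For
  φ > 0 the null weight of split k is the normalised product
  NB(k; μ_b, φ_b)·NB(T−k; μ_a, φ_a) with μ proportional to library
  share. Since the sum of r iid NB(m, φ) draws is NB(rm, φ/r), the
  per-replicate dispersion is divided by each condition's replicate
  count. The two-sided p doubles the smaller tail and is capped at 1;
  T = 0 returns p = 1, log2FC = 0.

Dispersion is estimated by method of moments on counts rescaled to the
mean library size: per condition with ≥ 2 replicates,
φ = (var − mean)/mean², pooled with degree-of-freedom weights and floored
at 0 (Poisson limit). Three estimators are exposed:

* **per-feature** — the raw moment estimate; unbiased in direction but
  extremely noisy at 2–3 replicates (a large fraction collapses to 0,
  which makes the exact test anticonservative for those features);
* **common** — the mean of the unclipped per-feature estimates shared by
  all features (averaging before clipping avoids the upward bias of
  averaging floored values); stable, but understates genuinely variable
  features;
* **moderated** (default) — per-feature estimates shrunk toward the
  common value with prior weight 10 df against the data's residual df,
  the standard compromise for count data at small replicate numbers.

Screening thresholds are |FC| ≥ 2 with raw p < 0.05 for the up/down
calls, with BH q-values reported alongside; term enrichment uses
adjusted p < 0.05. These cut-offs live in one `Thresholds` object and are
logged by the pipeline. Library-size normalisation only — no trimmed-mean
composition scaling; the `lib_sizes` field on the count matrix is the
hook for callers who need an alternative.

Auxiliary statistics: Pearson correlation between replicate expression
profiles; two-sided Wilcoxon rank-sum for class-abundance comparisons,
exact by enumeration for tie-free samples of ≤ 10 and the tie-corrected
normal approximation otherwise (degenerate all-equal input returns 1).

## Association, cross-tabulation and enrichment

An antisense unit is associated with every gene it overlaps by ≥ 1 bp on
the opposite strand; a gene with at least one association is an ATE
(antisense-transcript-enriched) gene. All gene-level summaries
deduplicate: a gene overlapped by two units counts once. The cross-tab
partitions the sense-DE universe by (sense status) × (has an upregulated
antisense unit), with per-cell gene lists, and long-form cell listings
carry both features' log2FC and p per (gene, unit) pair.

Enrichment takes a flat term → gene TSV plus an explicit universe — the
choice of universe (all genes vs expressed genes) materially changes
hypergeometric p-values and is therefore the caller's explicit input, not
a hidden default. There is no ontology-graph propagation.

## Synthetic data

The generator emulates the study conditions end to end: 3 chromosomes of
60 kb carrying 60 non-overlapping genes (1–2 kb, gaps 200–800 bp, random
strands); 3 WT + 3 mutant replicates; single-end 75-bp dUTP reads; NB
noise with dispersion 0.1; mean sense depth 100 reads/gene; an antisense
baseline of 8 reads/gene in every gene (so the null background contains
assembled antisense units, as real data does); and 10% of genes spiked at
4-fold antisense in the mutant. The baseline of 8 reads/gene puts
antisense at a few percent of sense abundance, matching the low-abundance
character of these transcripts while leaving enough signal for assembly
at the default `min_reads`. Spiked units occupy the central 60% of the
gene body — always more than half the gene — so every spike is
associable with its gene.

Reads are emitted pre-aligned (perfect alignment, CIGAR `75M`, MAPQ 60):
the aligner is out of scope, so the simulator produces exactly what the
pipeline consumes. No sequencing error, splicing or PCR-duplicate
modelling. Consequently, passing recovery tests demonstrates the
correctness of the strand logic, assembly and statistics — not robustness
to alignment artefacts, mappability gaps or overdispersion beyond the NB
family.

Determinism: every random stream derives from the configuration seed via
independent child seeds (genome, truth, one per sample), so SAM output is
byte-identical across runs and annotation structure is independent of
read noise.

## Evaluation

`evaluate_calls` maps up-called models to truth by same-strand interval
overlap with the spiked antisense intervals: sensitivity is the fraction
of spiked genes hit by ≥ 1 up-called model; the false-discovery
proportion is the fraction of up-called models hitting no spiked
interval (0 by convention when there are no calls). On the default
configuration and seed the pipeline reaches sensitivity 1.0 with FDP
≤ 0.2, and a spike-free null run yields no up calls with < 7% of
features at p < 0.05; the problem sizes above (60 genes, ~40 k reads per
dataset) keep the full suite and the acceptance script fast while leaving
enough features for the calibration checks to be meaningful.

## Known limitations

* Counting assumes antisense models are non-overlapping within a strand
  (guaranteed by assembly); user-supplied overlapping features would
  multi-count boundary reads.
* The exact test conditions on per-condition sums; it has no GLM layer,
  so batch covariates are out of scope.
* The moment dispersion estimator degrades below 3 replicates; with a
  single replicate everywhere a prior (0.1) is applied with a warning.
* Enrichment treats terms as flat sets; hierarchical term structure is
  the caller's responsibility.
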