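# Methods

## Feature catalogs and coordinates

Gene models are parsed from an Ensembl-dialect GTF (gffutils) and validated
against the FASTA index; biotypes come from `gene_biotype`/`gene_type`
attributes ("unknown" when absent). Five catalogs are derived:

* **collapsed_exon** — genome-wide union of all exons;
* **intron** — per-gene span minus that gene's exon union, merged across
  genes, then minus the global exon union (so a base exonic in *any* gene is
  never intronic);
* **intergenic** — per-chromosome complement of gene spans (each optionally
  extended by a flank; default 0 bp), excluding organellar chromosomes;
* **rRNA_exon** — exon union of genes with biotype in
  {rRNA, rRNA_pseudogene, Mt_rRNA} (configurable);
* **organellar** — one region per listed chromosome (default {MT}).

With zero flank the first three partition every non-organellar chromosome
exactly; this is asserted by tests on randomized annotations. GTF and SAF
are 1-based inclusive on disk; all internal arithmetic is 0-based half-open.
GC content is (G+C)/(A+C+G+T) with ambiguous bases excluded from both
numerator and denominator; a region without ACGT bases carries NaN and
downstream falls back to the global contamination estimate.

## Fragment summarization

The counting unit is the fragment (template): a read pair counts once, a
single-end read counts once. Secondary, supplementary, unmapped and QC-fail
alignments are skipped; duplicate-marked reads are counted by default
(configurable). Category assignment follows the precedence
exon ≻ intron ≻ intergenic on any-block overlap by either mate; rRNA and
organellar overlap is tallied independently. Within a category a fragment
counts once, to its largest-overlap region (ties to the leftmost) — no
fractional assignment. Gene counts use union-exon overlap honoring the
strandedness mode; under the 'reverse' convention read 1 is antisense to the
transcript. Junction support of a gene is the number of overlapping
fragments with an N CIGAR operation.

Strandedness inference uses fragments overlapping exons of exactly one
stranded gene: the reported proportion p is the fraction matching the
'reverse' convention; the library is called stranded iff max(p, 1−p) > 0.9,
with the direction read off from which side exceeds. Fewer than 100
evaluable fragments yields an explicit "inconclusive" status rather than a
number.

## Contamination estimation and correction

**Global.** FPB = count/length per intergenic region; the sample's level is
the median over regions with non-zero counts. All-zero intergenic counts are
an error ("no evidence of contamination") rather than a silent zero.
Corrected counts are `round(max(0, count − FPB·L_g))`: clamping and rounding
keep the matrix usable by count-based DE tools, which require non-negative
integers.

**GC%.** A locally-weighted regression of FPB on GC over the non-zero
intergenic regions (statsmodels lowess, span 0.75, local-linear — no
installed smoother offers local-quadratic loess, and the bin medians taken
next make the local degree immaterial at these scales). For each of 20
equal-width GC bins (bin = ⌊20·GC⌋, GC = 1.0 closed into bin 19) the
estimate is the median of fitted values over member regions; empty bins
inherit the nearest populated bin (ties to the lower); estimates are clamped
at zero. Fewer than 20 usable regions or fewer than 3 distinct bins triggers
a warned fallback to the global estimate in every bin. Genes are charged the
estimate of their own GC bin; constant bins reduce exactly to the global
method (tested as an identity).

**IR%.** Counts are transformed to y = log2((count+0.5)/(libsize+1)·1e6).
A first unweighted pass on the design [intercept | group dummies |
centered IR%] yields residual SDs; the mean–variance trend (lowess of
√SD on mean log2 count, span 0.5) is interpolated at each observation's
fitted log-count and inverted to fourth-power precision weights, after the
published voom recipe. Weighted least squares per gene estimates the IR%
coefficient, and only that term is removed: the covariate is centered so the
intercept stays at the clean-sample baseline. Constant IR% and
rank-deficient designs are errors that name the offending columns. Note
that a covariate constant within groups lies in the span of the group
dummies — callers modelling a pure titration (one biological condition)
should use a single group.

**Stranded.** `max(0, sense − antisense)` elementwise, after confirming the
library is stranded. Gene lengths for the subtraction methods are per-sample
effective lengths when a quantifier triplet is imported, else union-exon
lengths from the annotation.

**Filters.** (1) Multi-exonic genes whose junction support is below the
threshold in every sample are dropped; mono-exonic genes are always kept.
(2) Genes at or below a CPM cutoff in all uncontaminated samples of every
condition are dropped; each condition must retain at least one
uncontaminated sample. Both filters are optional and conservative use is
advised — sparse junction coverage inflates false negatives.

## Diagnostics

Category percentages use the fragments assigned to the
exon/intron/intergenic partition as denominator, so those three sum to 100
and IR% is the intergenic entry; rRNA/organellar/gene overlap is reported
against the same denominator outside the sum. "% expressed" uses a strict
comparison (value > cutoff) on CPM or TPM. Expression distributions come in
two transforms: log2(median-of-ratios-normalized + 1), and log2(CPM + p)
with p = one tenth of the smallest *positive* CPM (the matrix minimum would
zero the pseudocount). Sample similarity reports Pearson correlation and
Euclidean distances between sample columns of the transformed matrix plus a
PCA on the gene-wise centered, unit-variance matrix (zero-variance genes
dropped) — log2(normalized+1) stands in for a variance-stabilizing
transform, a documented simplification. Complete-linkage leaf order is
returned for heatmaps.

## The simulator

The generator emulates a gDNA titration experiment: five groups
(0, 0.01, 0.1, 1, 10% of fragments of gDNA origin) × 3 replicates with a
shared log-normal expression truth (σ = 1.5) over the main-chromosome genes.
Defaults: 2 chromosomes × 1 Mb plus a 20 kb organellar chromosome, 150
genes (1–5 exons of 200–1000 bp, introns 200–2000 bp, gaps 2–12 kb, one
rRNA-biotype gene), 200,000 single-end fragments of fixed length 200 bp per
sample, intergenic space tiled into 500 bp windows (~2,900 windows, ~7
expected fragments per window at 10% contamination — enough for a stable
median while keeping simulation under a minute per bundle).

RNA fragments are drawn uniformly within each gene's spliced exon space
(multinomial over expression weights), acquiring N-CIGAR junctions when they
span exon boundaries, with orientation following the 'reverse' library
convention at the configured purity. gDNA fragments are placed over
genome-wide 500 bp windows with weights either uniform or proportional to
max(0, a + b·GC); strands are Bernoulli(1/2), or exactly balanced
(each position emitted once per strand) for noiseless stranded scenarios.
The per-sample truth records RNA-origin gene counts and the contamination
level as fragment-start density (gDNA fragments / genome bp) — with
exclusive largest-overlap window assignment that density is precisely what
the median window FPB estimates.

The base-composition landscape defaults to an isochore-like sinusoid
(GC 0.30–0.70, eight periods per chromosome). A monotone gradient is
available but deliberately not the default: genes are placed from the
chromosome start, so a monotone landscape correlates GC with gene occupancy
and leaves a gene-free high-GC intergenic tail that biases the global FPB
median relative to gene-level contamination rates — a benchmark confound,
not a property of either correction.

What the simulator does **not** model: sequencing errors and quality
scores, PCR duplicates, multi-mapping, variable fragment lengths, isoform
structure, rRNA-depletion chemistry, or batch effects. Passing tests
therefore demonstrate algorithmic correctness against a clean generative
model, not robustness to every artifact of real libraries.

## Numerical choices and known limitations

* Negative corrected counts are clamped to zero, then rounded to the
  nearest integer; the alternative (truncation) is not used.
* Overlap-based gene counting charges a gene approximately
  n_blocks × (fragment length − 1) bp of contamination beyond FPB × L_g, so
  all subtraction methods under-correct by that margin; it is shared across
  methods and does not affect their comparison.
* The IR% method returns log2CPM, not counts; downstream DE should either
  consume the adjusted matrix with limma-style tools or include IR% directly
  in its own design matrix (the covariate table is emitted for this).
* The loess span (0.75), voom trend span (0.5), and the 500 bp window size
  are defaults chosen for stability at the simulator's scale; all are
  exposed as parameters.
* Intron derivation subtracts the *global* exon union, an interpretation
  choice where annotations of overlapping genes disagree about a base.
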