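# gdnaclean

Detection and correction of genomic-DNA (gDNA) contamination in bulk RNA-seq
count data.

## The problem

Residual genomic DNA co-extracted with RNA survives library preparation —
especially in rRNA-depletion protocols, which lack the polyA selection that
would exclude it — and contributes sequencing fragments that do not come from
transcripts. Those fragments land nearly uniformly over the genome, so they
inflate every gene's count roughly in proportion to gene length, flatten
expression distributions, and generate large numbers of spurious
differentially expressed genes. `gdnaclean` is for analysts who align bulk
RNA-seq, suspect contamination (the tell-tale sign is an elevated fraction of
reads in intergenic space), and want to diagnose it and correct the count
matrix before differential expression.

## The model

Let $c_{gs}$ be the count of gene $g$ in sample $s$ and $L_g$ its
(effective or union-exon) length. Intergenic regions receive no
transcription, so their fragment coverage measures contamination directly.
With $n_r$ fragments in intergenic region $r$ of length $\ell_r$, the
coverage in **fragments per base** is $\mathrm{FPB}_r = n_r/\ell_r$, and

* **Global** — the per-sample contamination level is
  $\hat\lambda_s = \mathrm{median}\{\mathrm{FPB}_r : n_r > 0\}$; the
  corrected count is
  $\max(0,\; c_{gs} - \hat\lambda_s L_g)$, rounded.
* **GC%** — gDNA coverage is GC-biased: a loess of $\mathrm{FPB}_r$ on
  region GC is summarized into 20 equal-width GC bins (median of fitted
  values per bin, empty bins inherit their nearest neighbour), and each gene
  is charged the estimate $\hat\lambda_{s,b(g)}$ of its own GC bin.
* **IR%** — the **intergenic read percentage**
  $\mathrm{IR\%}_s = 100\cdot\frac{\text{intergenic}}{\text{exon}+\text{intron}+\text{intergenic}}$
  enters a voom-style precision-weighted linear model on
  $y_{gs}=\log_2\!\big(\tfrac{c_{gs}+0.5}{N_s+1}\cdot 10^6\big)$ as a
  centered covariate; the fitted IR% term is subtracted, yielding an
  adjusted log2CPM matrix (not counts).
* **Stranded** — double-stranded gDNA templates both strands equally while
  transcription is directional, so for libraries whose stranded-read
  proportion exceeds 0.9 the antisense quantification estimates the
  contamination: corrected $= \max(0,\; \text{sense} - \text{antisense})$.

Around the correctors sit the supporting pipeline: GTF/FASTA →
coordinate-collapsed exon/intron/intergenic/rRNA/organellar catalogs (SAF
I/O), fragment-level BAM summarization with strandedness inference, a
six-part diagnostic battery (read distribution incl. IR%, expression
distributions, % expressed genes, pairwise correlation, clustered distances,
PCA), two optional post-correction gene filters (splice-junction support for
multi-exonic genes; minimum expression in uncontaminated samples), and a
deterministic simulator that reproduces a gDNA titration experiment
(0%–10% contamination) with full ground truth.

## Worked example

```python
import gdnaclean as gd

# a 15-sample titration: 5 contamination groups x 3 replicates, shared truth
bundle = gd.make_dataset_I_analog(seed=1)
print(bundle.ir_percent.groupby(bundle.groups).mean())
#   0%       0.000
#   0.01%    0.006
#   0.1%     0.070
#   1%       0.682
#   10%      6.846

heavy = [s for s in bundle.groups.index if bundle.groups[s] == "10%"]
fpb = gd.estimate_global_fpb(bundle.intergenic_counts[heavy], bundle.region_lengths)
print(fpb)            # F1 0.01, F2 0.01, F3 0.01
# truth for these samples: 0.009901 fragments/base

corrected = gd.global_correction(
    bundle.expression.counts[heavy], fpb,
    lengths=bundle.reference.models.union_exon_lengths())
# mean |error| vs true counts, raw: 23.04   corrected: 5.95
```

IR% climbs monotonically with the injected gDNA fraction — the diagnostic
signal — and the median intergenic FPB recovers the injected contamination
level (0.0099 fragments/base at 10%) within 1%, cutting the mean absolute
count error by ~4x after subtraction. The same objects drive the sklearn-style
estimators (`GlobalCorrector`, `GCCorrector`, `IRPercentCorrector`,
`StrandedCorrector`) for pipeline composition, and the `gdnaclean` CLI
(`annotate`, `count`, `diagnose`, `correct`, `simulate`) exposes the
file-based workflow.

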