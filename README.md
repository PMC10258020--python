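# granuleseq

Analysis toolkit for stress-granule (SG) transcriptomics: which RNAs
partition into stress granules, how that partitioning relates to
transcript physical features and to direct binding by the SG core
proteins G3BP1/G3BP2 (eCLIP), and how SG-resident RNA classes associate
with protein co-expression changes across Alzheimer's disease (AD)
diagnosis groups.

It is written for computational biologists who have (or want to
simulate) four kinds of inputs: a gene annotation with sequences
(GTF + FASTA), replicate eCLIP peak tracks (BED6/narrowPeak), SG/Total
and perturbation RNA-seq quantifications, and a brain proteomics bundle
(abundance matrix, Control/AsymAD/AD metadata with Braak and CERAD
scores, and a protein→module map in the M1–M44 style).

## What it computes

**SG partition.** TPM is computed per sample as
`tpm_i = 10^6 · (c_i/ℓ_i) / Σ_j (c_j/ℓ_j)` (ℓ in kb) and each gene is
classified from its SG/Total pair: *enriched* (FC > 2 and TPM_SG > 1),
*depleted* (FC < 0.5 and TPM_Total > 1), *low* (both TPMs ≤ 1), else
*neither*, with FC = (TPM_SG + ε)/(TPM_Total + ε), ε = 0.01 by default.

**Peak integration.** Replicate tracks are reduced to common peaks by
strand-aware interval intersection (mean score), assigned to the
5′UTR/CDS/3′UTR/non-coding exon of each gene's canonical (longest)
transcript by maximal overlap with 3′UTR-first tie-breaking, and
summarised per gene as peak count and mean log2 enrichment.  An IUPAC
utility verifies that the G3BP consensus motif CCAGSCUGG is its own RNA
reverse complement (a sequence palindrome).

**Statistics.** Wilcoxon rank-sum (exact permutation enumeration for
n₁+n₂ ≤ 12, tie-corrected normal approximation otherwise), Pearson r
with t-based p, one-way ANOVA with Tukey–Kramer HSD, Benjamini–Hochberg
FDR, and a hypergeometric over-representation test.

**Disease / module stage.** Genes are cross-classified by SG class and
a disease gene list (DisGeNET-style), with within-class Wilcoxon
comparisons of length/GC/abundance.  Proteins are grouped into
(module × SG class) sets; each set with ≥ 3 proteins is summarised by
its eigenprotein (first principal component of the row-standardized
abundance sub-matrix) and tested with a diagnosis ANOVA + Tukey, BH FDR
across all evaluated sets, and Pearson correlations against Braak and
CERAD scores.  A 44-module table crossed with the three SG classes
yields 132 evaluated sets.

**Synthetic studies.** A seeded generator produces every input above
with planted, recoverable structure: peak counts rising with length and
AT content, SG enrichment favouring long/AT-rich/low-abundance
transcripts, disease labels biased toward long genes, and proteomics
modules with per-diagnosis shifts in chosen (module, class) cells.  See
`docs/methods.md` for the models and defaults.

## Worked example

Simulate a full study at the default scale (5,000 genes) and run every
stage:

```bash
granuleseq run-all --seed 1 --outdir run1
```

`run1/report.md` then contains, among other tables (numbers from this
exact command):

```
## SG class composition

   label  count  fraction
depleted   1025    0.2050
enriched   1986    0.3972
     low      1    0.0002
 neither   1988    0.3976

## Peak region distribution

       biotype         region  count  fraction
           any           3UTR  20927  0.643472
           any           5UTR    838  0.025767
           any            CDS   6547  0.201310
           any noncoding_exon   4210  0.129451
```

The composition table says ~40% of simulated genes classify as
SG-enriched and ~21% depleted under the FC/TPM rules; the region table
shows the planted 3′UTR binding preference (64% of assigned common
peaks) that the assignment stage recovers.  The module stage evaluates
all 132 (module × SG class) sets; with the default planted effects the
SG-enriched cells of M1/M5/M8 fall with diagnosis (e.g. M1-enriched:
ANOVA q ≈ 1.5e-10, Braak r ≈ −0.28) and those of M11/M20/M42 rise
(M11-enriched: Braak r ≈ +0.28), exactly the planted pattern.

All tables land as TSVs under the run directory with a `manifest.json`
of input/output SHA-256 digests; re-running with the same seed
reproduces identical digests.

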