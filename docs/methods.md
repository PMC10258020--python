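# Methods

`granuleseq` analyses which transcripts partition into stress granules
(SGs), how that partitioning relates to transcript physical features and
to direct binding by the SG core proteins G3BP1/G3BP2, and how
SG-resident RNA classes associate with protein co-expression changes in
Alzheimer's disease (AD) brains.  This note records the models, the
defaults and why they were chosen, the numerical conventions, and what
the synthetic data do and do not establish.

## Transcript features

Annotation is read from GENCODE-dialect GTF; coordinates are converted
to 0-based half-open intervals internally (GTF is 1-based inclusive).
UTRs are not taken from the annotation but inferred by interval
arithmetic: exonic sequence genomically left/right of the CDS span,
oriented by strand.  This guarantees the bookkeeping identity
`len(5'UTR) + len(CDS) + len(3'UTR) = spliced length` for every
protein-coding transcript, which downstream statistics rely on.

One feature row is produced per gene using a longest-isoform canonical
rule (largest summed exon length, ties broken lexicographically by
transcript id).  This is a deliberate, documented choice — annotation
pipelines variously use longest, MANE, or per-source canonical
transcripts, and the choice only shifts per-gene length/GC by isoform
differences.  GC fraction is computed over the spliced, strand-corrected
transcript sequence as (G+C)/(A+C+G+T), with ambiguity codes excluded
from both numerator and denominator (a transcript with no unambiguous
bases gets NaN and a warning).  Biotypes are collapsed to
`protein_coding` / `lncRNA` / `other` via an editable mapping that puts
the GENCODE long-non-coding umbrella under `lncRNA`.

## eCLIP peak integration

Peak tracks are BED6 or narrowPeak (signalValue used as the score when
present); scores are log2 enrichments over the size-matched input.
Strandless (`.`) peaks are rejected rather than double-counted, because
every downstream overlap is strand-aware.

Duplicate experiments are reduced to "common peaks" by pairwise interval
intersection: each same-chromosome, same-strand pair with at least 1 nt
of overlap contributes the intersected interval with the mean of the two
scores.  The alternative convention (interval union) is deliberately not
the default: intersection is conservative about binding-site extent and
makes the containment property (every common peak lies inside a source
peak of each replicate) testable.

Common peaks are assigned to the exonic sub-regions (5'UTR / CDS / 3'UTR
for coding, `noncoding_exon` otherwise) of each gene's canonical
transcript.  The gene with the largest total overlap wins; within the
gene, the region with the largest overlap wins, with ties resolved by
the precedence 3'UTR > 5'UTR > CDS > noncoding exon (the community
convention for 3'UTR-biased RBPs such as the G3BP paralogs).  Peaks
touching no annotated exon are retained as `unassigned` so that counts
are conserved and category pies can carry an "other" slice.

Cross-sample peak overlaps (UpSet-style) merge overlapping peaks from
different sets into connected components; each component is counted once
under the union of the set names it contains.  This treats a binding
site shared by two tracks as one region rather than two.

Per-gene binding is summarised as `peak_count` and `binding_level`
(mean common-peak score).  "Binding level" in the source figure legends
could also denote read density; mean peak score is implemented because
it is computable from peak tracks alone, and the interpretation is
recorded here rather than silently mixed.

The motif utility implements IUPAC RNA reverse complementation
(A<->U, C<->G, S<->S, W<->W, R<->Y, K<->M, B<->V, D<->H, N<->N); a motif
is a palindrome iff it equals its own reverse complement.  The G3BP
consensus CCAGSCUGG satisfies this.

## SG partition

TPM is computed as `rate_i = count_i / (length_i/1000)`,
`tpm_i = 1e6 * rate_i / sum(rate)`.  Genes are classified from paired
SG/Total TPM:

| class    | rule                                           |
|----------|------------------------------------------------|
| enriched | fold change > 2 and SG TPM > 1                 |
| depleted | fold change < 0.5 and Total TPM > 1            |
| low      | neither rule fires and both TPMs <= 1          |
| neither  | everything else                                |

Fold change uses a pseudocount (default 0.01 TPM) so zero abundances are
defined; `pseudocount=0` reproduces the strict published thresholds
exactly, and the boundary uses strict `>` as printed.  "Low" requires
*both* TPMs at or below the floor — the published scatter marks
low-abundance dots without stating the conjunction, and requiring both
keeps the classes a partition.  Differential response to knockdown or
arsenite stress uses the same symmetric rule (|FC| > 2, TPM floor 1 on
the relevant side); the source work does not state whether its up/down
calls added a statistical test, so the thresholds are configurable and
echoed into output provenance.

## Statistical kernel

* **Wilcoxon rank-sum**: the U statistic uses midranks.  Exact mode
  enumerates all C(n1+n2, n1) assignments of the (doubled, hence
  integer) midranks — the exact permutation null, valid under ties — and
  is the default for n1+n2 <= 12.  Larger samples use the tie-corrected
  normal approximation with continuity correction.  Two-sided p for the
  discrete statistic is `min(1, 2*min(P(U<=u), P(U>=u)))`.
* **Pearson**: r with the two-sided t-transform p on n-2 df; zero
  variance raises an error naming the degenerate vector.
* **One-way ANOVA + Tukey**: F = MS_between/MS_within; pairwise
  comparisons use the Tukey-Kramer studentized-range statistic (exact
  for unbalanced designs such as the 106/200/182 diagnosis groups).
  Pairwise p-values are interpolated from the tabulated
  studentized-range quantiles, which is accurate to about 1e-2 in the
  middle of the distribution and better in the tails, and clipped to the
  tables' supported range [0.001, 0.9].  Family-level inference never
  uses the Tukey p's — the BH family is the ANOVA p-values.
* **BH FDR**: step-up q-values, order-preserving, capped at 1.
* **Over-representation**: hypergeometric upper tail
  P(overlap >= observed), replacing tool-specific GO machinery with the
  generic test it reduces to.

## Disease and module stage

The disease cross-classification reports, per SG class, counts and
fractions of disease-listed vs other genes, and Wilcoxon comparisons of
transcript length, GC, and Total abundance between the two groups within
each class.  Strata with fewer than two genes on a side are skipped with
a logged note (the source analysis likewise skipped a one-gene stratum).

The module stage maps proteins onto SG classes through their coding
genes (`low` genes are excluded; a protein mapping to several genes uses
the first mapping with a warning).  For each (module, SG class) set with
at least `min_set_size = 3` proteins — below that an ANOVA on the
eigenprotein is ill-posed — the set is summarised by its eigenprotein:
rows standardized to zero mean and unit variance (population SD,
ddof=0), first right singular vector, scaled to unit variance and
oriented to correlate positively with the mean standardized profile.
Eigenproteins are recomputed on the subset abundance matrix
(WGCNA-style) rather than imported, because upstream studies ship
whole-module eigenproteins and the subset is what is being tested here;
an import path exists for precomputed scores.  Each set gets a
diagnosis ANOVA (Control / AsymAD / AD) with Tukey pairs, BH q over all
evaluated sets, and Pearson correlations of the eigenprotein with the
Braak and CERAD scores, treated as numeric despite being ordinal —
matching how those scores are commonly correlated in the proteomics
literature.

## Synthetic data generator

The generator emulates the study's data-generating structure, not its
exact measurements.  Defaults (a single seed fixes everything):

* 5,000 genes, 25% lncRNA; region lengths log-normal
  (5'UTR ~150 nt, CDS ~1.2 kb, 3'UTR ~0.9 kb medians, lncRNA ~0.8 kb);
  per-gene GC ~ Beta(9, 11) (mean 0.45); genes laid on synthetic
  chromosomes, both strands, 1-4 exons, 1 kb spacing, no overlaps
  (chromosome sequences match each gene's drawn GC in its exons).
* eCLIP peak counts per gene ~ Poisson with
  log-rate = -6.8 + 0.8·ln(length) + 2.0·(1-GC); peak positions uniform
  over exon pieces with half the mass on the 3'UTR; widths 30-80 nt;
  replicate 2 is a jittered (±10 nt) resample keeping ~80% of peaks.
* ln(SG/Total) = 0.6·ln(length) + 2.0·AT - 0.5·ln(abundance) (centred
  covariates) + N(0, 0.8); Total abundance log-normal; counts Poisson at
  5e6 reads with rate proportional to TPM × length.  Because both TPM
  columns are renormalised to 1e6, realized fold changes are the planted
  ratios relative to their abundance-weighted mean — the compositional
  behaviour real TPM data have.
* disease labels sampled with weight (length quantile)^2, 15% of genes.
* proteomics: 106/200/182 samples (Control/AsymAD/AD), 44 modules, five
  proteins per (module, SG class) cell sampled from classified genes
  (guaranteeing the full 132-set grid), abundance = loading × (module
  latent + per-diagnosis shift for planted cells) + N(0, 1); Braak and
  CERAD are noisy increasing functions of diagnosis (slopes 1.8 and 1.0,
  clipped to 0-6 and 0-3).  The default planted table mirrors the
  qualitative published pattern: SG-enriched cells of M1/M5/M8 shifted
  down and of M11/M20/M42 shifted up with diagnosis.

Poisson counts (no overdispersion) are the default for analytic
tractability; real SG RNA-seq is overdispersed, so planted-effect
recovery rates here are optimistic relative to equally-sized real data.
The generator also omits isoform mixtures, mapping bias, batch effects,
and sequence-motif-driven peak placement.  Passing tests therefore
establish that the operational code recovers planted structure of the
stated form at the stated sizes — not that the biological effect sizes
in real data are detectable at these rates.

## Problem sizes used by the checks

Simulation studies run at the defaults above: feature-effect recovery
uses 50 independent studies of 5,000 genes; module-stage null
calibration uses 200 simulated bundles (132 sets each) and the planted
single-shift study 25 bundles.  These sizes give Monte-Carlo standard
errors well below the decision margins they are compared against.

## Known limitations

* Gene-level only: no isoform quantification; the canonical-transcript
  rule is a modelling choice, not a reconstruction of the source data's
  (unstated) isoform rule.
* "Binding level" = mean common-peak score; read-density-based levels
  would need alignments, which are out of scope.
* Tukey p-values are table-interpolated and clipped to [0.001, 0.9].
* Braak/CERAD are correlated as numeric scores; rank correlations would
  be the conservative alternative for ordinal data.
* The threshold-based differential classes carry no error model; they
  reproduce the published rule rather than a count-model test.
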