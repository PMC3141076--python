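# choreseq

A tested, reusable re-implementation of the computational chain behind a
ChIP-seq + expression study of a glucose-responsive transcription factor
(ChREBP-style): threshold-based peak calling against an input library,
peak-to-gene annotation, ChoRE/E-box motif modelling and de novo discovery,
moderated-t differential-expression ranking, and a running-sum
Kolmogorov–Smirnov enrichment that links binding to glucose-regulated
expression. A first-class synthetic-data generator plants ground truth
(binding sites, bound genes, direction of regulation) so every stage can be
scored exactly.

## Who this is for

Regulatory-genomics analysts who want a small, fully specified, reproducible
pipeline for the classic "where does the factor bind, and are the bound genes
the regulated ones?" question — either to analyse toy/teaching data or to
benchmark parts of a larger stack against planted truth.

## The methods at the core

- **Peak calling.** Tags (36 nt) are extended to the mean fragment size
  (200 bp) and piled up per base. Peaks are maximal runs where ChIP coverage
  ≥ 8 tags *and* the ratio of ChIP to library-scaled, locally averaged input
  coverage ≥ 5, with nearby runs merged; the summit is the base of maximal
  ChIP coverage.
- **Motifs.** PWMs score windows with the max-normalized probability sum, so
  every consensus window (e.g. a perfect E-box CACGTG) scores exactly 1.
  Match thresholds come from the *exact* background score distribution
  (full enumeration for short motifs, grid convolution otherwise). The ChoRE
  element is detected as a bipartite pair: an E-box-family match and, after a
  fixed 5-nt spacer, a reverse-complement match. De novo discovery is
  ZOOPS-EM (zero or one site per sequence) with phase-shift moves.
- **Expression ranking.** Per gene: log2 fold change, an empirical-Bayes
  moderated t with variance shrinkage s̃² = (ν₀s₀² + d·s²)/(ν₀ + d), and a
  posterior probability of differential expression (PPDE) from a
  beta-uniform mixture f(p) = λ + (1−λ)·a·p^(a−1) fitted by EM.
- **Integration.** Walking the PPDE-ranked gene list, the running sum gains
  1/Nh at each ChIP target and loses 1/(N−Nh) otherwise; the enrichment
  score ES is the maximum prefix value, with exact (full enumeration) and
  permutation p-values, plus the up/down split of bound, significantly
  regulated genes and a hypergeometric over-representation test (BH-FDR).

## Worked example

```sh
choreseq run-all --seed 11 --outdir out/
```

runs simulate → coverage → peaks → annotate → motifs → DE → KS on the default
synthetic study (1 Mb genome, 100 genes, 20 planted ChoRE sites, 100k ChIP +
100k input tags, 6 replicates per condition) and prints:

```
choreseq pipeline summary
  seed: 11   config: 636f6fc91001
  tags: ChIP 100000 / input 100000 (scale 1)
  peaks: 20 (mean width 298.9 bp)
  planted-site recovery: 100.0%
  peak categories: proximal_promoter 95%, utr5 5%
  peaks with ChoRE pair: 100.0%
  KS enrichment: ES = 0.975, Nh/N = 20/100, p_perm = 0.0001
  bound DE genes: 10 up / 10 down
```

Reading: all 20 planted sites were recovered as peaks (~300 bp wide, mostly
in proximal promoters because sites are planted near TSSs); every peak
contains the bipartite ChoRE element; the 20 ChIP target genes crowd the top
of the differential-expression ranking (ES 0.975, permutation p ≈ 10⁻⁴);
and the bound regulated genes split evenly into activated and repressed, as
configured. `out/` holds the per-stage files (peaks.bed, annotations.tsv,
motif TSVs, DE TSV, running_sum.tsv, summary.json).

The same stages are available as library functions
(`choreseq.call_peaks`, `choreseq.ks_enrichment`, ...) and as individual
subcommands (`simulate`, `callpeaks`, `annotate`, `motifscan`,
`motifdiscover`, `rank`, `enrich`).

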