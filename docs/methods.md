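# Methods

This note documents the models, defaults and numerical choices behind each
stage of the pipeline, what the synthetic-data generator does and does not
emulate, and the package's known limitations.

## Coordinates and conventions

All intervals are 0-based half-open; 1-based coordinates appear only in
human-readable output. The TSS of a minus-strand gene is `tx_end − 1` (the
last transcript base). Signed TSS distances are taken in the gene's
orientation: negative upstream, positive downstream. Duplicate tags are
retained by default (only multi-mapping reads are assumed removed upstream,
and the generator produces no PCR duplicates); `read_tags` exposes a
`collapse_duplicates` flag, off by default, for libraries where collapsing
is wanted.

## Synthetic study generator

The generator emulates the data a ChIP-seq + two-condition expression study
rests on, at a scale where every stage runs in seconds and every answer is
known:

- **Genome.** One chromosome of 1 Mb (default), iid bases with configurable
  GC (default 0.5). An iid background makes exact motif p-values analytic.
- **Genes.** 100 non-overlapping genes, 2–5 kb, 2–4 exons each, a CDS nested
  inside the outer exons, random strand, ≥2 kb intergene gaps so promoters
  and planted sites do not collide with neighbours.
- **Binding sites.** 20 instances of the tandem ChoRE-like element
  `CACGTGGCCGGCGCGTG` (perfect E-box, 5-nt spacer, imperfect E-box), written
  into the sequence at Normal(−500, 200) bp from the TSS of distinct genes,
  on a random strand. The TSS-centric placement reflects the observed
  concentration of binding near promoters; an `intergenic_fraction` knob
  (default 0) places unlinked sites uniformly instead. Occupancy weights are
  equal by default.
- **Tags.** Fragments are 200 bp (the sonication target length); each is
  reported as a 36-nt tag from the fragment's 5′ end on a Bernoulli(0.5)
  strand. Input fragments have uniform midpoints. ChIP is a mixture: 10% of
  tags are site-derived with midpoints Normal(site centre, 200/4 = 50 bp),
  split among sites by occupancy; the rest are background. The 10% ChIP
  efficiency is a deliberate default — real efficiencies are unknown and
  vary widely; at 10% each default site receives ~500 tags, giving summit
  pileups an order of magnitude above the ~20× background, comfortably
  inside the regime the stated thresholds (8 tags, 5-fold) were designed
  for. Halving it to 5% still leaves ~12-fold site enrichment.
- **Expression.** log2 intensities Normal(μ_g, 0.5) with μ_g ~ Normal(8,
  1.5), six replicates per condition. Half the bound genes (configurable)
  gain +2 log2 units in condition 2, the rest −2; 2% of unbound genes are
  differentially expressed independently of binding. The ±2 (four-fold)
  effect at noise 0.5 gives per-gene t ≈ 7 — strong but not degenerate, so
  ranking and calibration are both exercised. A `decouple_expression` switch
  draws the regulated set from the *unbound* genes instead, which is the
  null for the integration stage.

Everything is deterministic given the seed (per-stage substreams), and the
planted truth (site coordinates, bound genes, directions) is emitted as
TSVs.

What the generator does **not** emulate: sequencing error, GC and
mappability bias, PCR duplicates, copy-number artefacts, dinucleotide
sequence structure, correlated replicates, probe-level microarray effects.
Tests passing on this generator show the algorithms are correct under their
stated model, not that the thresholds are optimal for any real library.

## Peak calling

Coverage counts extended fragments per base: a + tag covers
`[start, start+200)`, a − tag `[start+36−200, start+36)`, clipped at
chromosome ends. Peaks are maximal runs of bases with ChIP coverage ≥ 8
**and** ChIP / max(background, 1) ≥ 5, where the background is the input
coverage scaled by total-tag ratio and then averaged over a centred 1 kb
window. The local averaging matters: input coverage is Poisson per base
(~20× at default depth), and raw per-base dips below chip/5 occur several
times per Mb by chance alone, so a per-base denominator produces spurious
calls in every null run; the smoothed denominator estimates the local
background rate (the local-λ idea of standard callers) and eliminates them
without touching genuine enrichment. Runs separated by ≤ 100 bp are merged
(single-base dropouts should not split a site); the summit is the leftmost
argmax of ChIP coverage; the reported ratio uses the maximum denominator
across the merged interval. Setting `input_smooth=1` recovers the raw
per-base behaviour.

A brute-force per-base oracle (independent re-implementation, plain loops)
reproduces `call_peaks` exactly on fuzzed tracks. Raising either threshold
can only shrink the passing base set, so total peak bp is monotone
non-increasing; the peak *count* is not monotone in general, because a
shrinking mask can split one merged peak into two.

## Peak annotation

The summit (a single unambiguous point) determines both the nearest gene
and the category. Nearest gene = closest TSS within 20 kb, ties to the
lexicographically smaller id. Categories use strand-aware windows — proximal
promoter: 2 kb of 5′-flanking DNA; distal: 2–5 kb — and transcript anatomy
(5′/3′ UTR by CDS position in transcription order, CDS exon, first/second
vs later introns). One summit can overlap features of several genes; the
single label takes the highest-precedence feature (promoters first), and
the full multi-label set is kept because the real fractions overlap (their
sum may exceed 1).

## Motifs

**Scores.** The normalized score of window w is
`Σᵢ pᵢ(wᵢ) / Σᵢ maxᵦ pᵢ(b)` — consensus windows score exactly 1, which
anchors the "PWM score = 1" convention for perfect E-boxes. Log-odds scores
(base-2, against the background) are kept for combined site scores and
discovery. Windows containing N are skipped.

**Exact p-values.** The background score distribution is computed exactly by
convolving per-column score distributions (identical sums collapsed), which
equals scoring all 4^w windows and is feasible to w = 12; beyond that a
grid-discretised convolution (10⁴ points by default) is used, and the two
agree to grid resolution. The threshold for level α is the smallest
attainable score t with P(score ≥ t) ≤ α. Because the distribution is
discrete, the achieved exceedance can be strictly below α; calibration
checks must use the achieved exceedance, not α. If even the maximal score
has mass above α (e.g. the degenerate E-box family PWM has consensus mass
8/4096 ≈ 0.002), the threshold is infeasible and an error says so.

**ChoRE pairs.** The carbohydrate response element is two E-box-like
hexamers separated by exactly 5 nt. Since the second hexamer family is the
reverse complement of the first, detection is: direct PWM match at p and
reverse-complement match at p+11, both at the site threshold (default
α = 0.002, i.e. consensus-family stringency). Orientation is decided by
which side is closer to the perfect E-box CACGTG (falling back to the family
score): the reverse complement of a '+' element is the same element in '−'
orientation.

**Discovery.** ZOOPS-EM over both strands: each sequence holds 0 or 1 site;
E-step computes per-offset posteriors against an iid background estimated
from the input; M-step re-estimates letter probabilities with pseudocount
0.01 and the site prior γ. The monotone quantity is the data log-likelihood
plus the Dirichlet term the pseudocounted M-step maximises; that objective
is recorded and never decreases. EM is prone to column-shifted local optima,
so after each converged start the matrix is re-run from ±1..3-column slides
until no shift improves the objective (the standard phase-shift move). The
best of `n_starts` seeded restarts wins. Motif quality is reported as
relative entropy (total bits vs background); the MEME-style E-value is out
of scope, and null calibration (comparing against discovery on matched
background sequences) replaces it.

## Differential expression

For each gene, log2 fold change is the difference of condition means. The
moderated t uses the shrunken variance s̃² = (ν₀s₀² + d·s²)/(ν₀ + d) with
d = n₁+n₂−2 and two-sided p from t with ν₀+d df. When (ν₀, s₀²) is not
supplied it is estimated by moment matching on log s² (digamma/trigamma
inversion, the standard empirical-Bayes recipe; an excess-spread of zero
gives ν₀ = ∞, i.e. complete shrinkage and a normal reference). ν₀ = 0
reduces exactly to the ordinary pooled t. The estimated prior keeps null
p-values uniform under the generator's constant-variance model, where a
fixed small ν₀ would not.

PPDE comes from the beta-uniform mixture f(p) = λ + (1−λ)·a·p^(a−1), fitted
by EM from (λ, a) = (0.5, 0.5), tolerance 1e−8, ≤ 500 iterations. Two
identifiability guards, both decided from the structure of the likelihood:
(1) a is constrained to (0, 0.8] — at a = 1 the beta component *is* the
uniform and λ is unidentifiable (EM stalls wherever it starts), and a < 1
also makes PPDE strictly monotone non-increasing in p; (2) after EM the
mixture is kept only if it beats the pure-null model (λ = 1, log-likelihood
0) by its BIC margin (2 parameters), otherwise the pure-null fit is
returned — without this, λ̂ absorbs sampling noise on all-null data.
P-values are floored at 1e−300 before taking powers.

Ranking is by PPDE (or fold change, or |t|), descending, with deterministic
tie-breaks: |log2FC|, then gene id. Genes with fewer than two observed
replicates in a condition are dropped with a warning.

## KS integration

Walking the ranked list, hits step +1/Nh and misses −1/(N−Nh); the running
sum therefore ends at exactly 0, and ES = max(prefix sums, 0) ∈ [0, 1], so
ES measures *top* enrichment (activation-side), with the minimum reported
separately. The leading edge is the targets at or before the first argmax.
Unweighted steps are the classic KS form; score-weighted GSEA is a
non-goal.

Significance permutes the *placement* of the target set among ranks (gene
labels), not the expression values: the question is where targets sit in the
list. p_perm uses the add-one estimator (never exactly 0); p_exact
enumerates all C(N, Nh) placements when that count is ≤ 10⁶, using the fact
that the running-sum maximum always occurs immediately after a hit. The
over-representation stand-in is a one-sided hypergeometric per gene set with
Benjamini–Hochberg FDR across sets.

## Problem sizes in the test suite

The acceptance-style tests use the generator's default scale (1 Mb / 100k
tags) for single-run checks; multi-seed calibration loops use the same
depth-per-base at reduced extent (e.g. 500 kb, 80 genes, 50k tags for the
fifty causal and fifty decoupled end-to-end runs; 2 000 genes for
expression-calibration runs), chosen so the whole suite runs in a couple of
minutes on one CPU while keeping every per-base and per-gene regime
identical to the defaults.

## Known limitations

- The peak caller has no FDR calibration (no Poisson/NB model); thresholds
  are the stated tag-count and fold-enrichment minima.
- One TSS per gene; alternative promoters and enhancer assignment for
  distal sites are out of scope.
- The exact promoter/2-kb-upstream distinction in published category
  percentages is ambiguous; both windows are exposed (proximal = 2 kb
  strand-aware upstream) rather than resolved.
- The BUM mixture is a ranking device, not a full Bayesian posterior over
  per-gene effects; λ̂ is interpretable as a null fraction only under the
  mixture model.
- Motif discovery assumes an iid background; on repetitive or GC-skewed
  real sequence it will find compositional artefacts a dinucleotide model
  would suppress.
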