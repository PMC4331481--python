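# Methods

This note documents the models, statistics and numerical conventions behind
`tdmrlink`, the choices that were genuinely open, and what the synthetic
data can and cannot show.

## Coordinates and data model

All coordinates are 0-based half-open (BED convention) everywhere inside
the package; GTF's 1-based inclusive coordinates are converted at the I/O
boundary and nowhere else.  The TSS of a `-`-strand gene is
`interval.end − 1` and its regulatory window extends rightward of the gene
end, so "upstream" is always strand-aware.  The tissue order is fixed by
configuration (tissue 1, tissue 2) and both differences are taken the same
way — ΔM = m₁ − m₂, ΔE = mean(log₂ reps₁) − mean(log₂ reps₂) — so only
sign *agreement* is meaningful, never the absolute direction.  Expression
may be supplied linear (microarray intensities) or already log₂; a flag
controls the transform, and replicates are aggregated by the arithmetic
mean of log₂ values.

## Sign classification

A pair is classified only when |ΔE| > log₂(1.25) (a 25% linear fold
change) and both differences are nonzero; otherwise it is `excluded` and
enters no fraction.  The threshold is interpreted on the log₂ scale, which
is the only reading under which a "25% fold change" cutoff is symmetric in
the two tissues.  Overlap semantics are ≥ 1 bp intersection between the DMR
and the gene window; a DMR overlapping k windows yields k pairs.  Fractions
are reported both over pairs and over unique DMRs (majority vote across a
DMR's pairs; ties dropped), because the two denominators answer different
questions and neither is canonical.

The expected split under no methylation–expression coupling is estimated by
permuting the ΔM values across pairs (ΔE stays attached to its gene, so the
|ΔE| filter selects the same pairs in every shuffle).  For marginal
positive-sign fractions p (ΔM) and q (ΔE) the expectation converges to
p·q + (1−p)(1−q); the permutation estimate is used rather than the closed
form so that the observed and null statistics share every filtering step.

## Coherence of multi-DMR genes

Genes with ≥ 2 classified pairs are `coherent_positive`, `coherent_negative`
or `incoherent`.  The null keeps each gene's ΔE fixed and permutes — a true
shuffle, without replacement — the multiset of ΔM values across the DMR
slots *of the multi-DMR genes only*; each slot's sign class is then
recomputed from the shuffled ΔM against its gene's own ΔE.  Class counts
are conserved in every shuffle.  Z = (n − S̄)/std(S) with the sample
(n−1) standard deviation; at 10,000 shuffles the sample/population
distinction is negligible and the sample estimator is standard.  A
degenerate null (all ΔM one sign) yields an undefined-Z flag, never an
infinity.  Under an independent-sign null, a gene with k slots is coherent
with probability qᵏ + (1−q)ᵏ; the permutation null agrees with this closed
form up to the small without-replacement correction, which the test suite
verifies at study scale.

## Genomic context

**Feature categories.**  Each DMR receives exactly one label, decided by
its midpoint (a DMR may straddle features; the midpoint forces mutually
exclusive percentages).  Precedence: first-exon/5′UTR > exon > intron >
upstream > downstream > intergenic, with any gene body beating a
neighbouring gene's flank.  Flank windows default to 4 kb on each side.
The category set and precedence are configurable interpretations — the
labels are standard, but no single convention is canonical in the field.

**DHS calling and overlap.**  Per tissue, a region is a DHS when covered by
≥ k of n replicate peak sets (k = 3 of 7 is a typical deep-replicate
choice; k = 1 when a single consensus set is supplied).  A DHS overlapping
the other tissue's DHS set by ≥ 1 bp is *shared* (shared pieces merged),
otherwise tissue-specific.  "Within a DHS" likewise means ≥ 1 bp overlap,
not containment.  The random expectation for DMR/DHS overlap is computed by
length-preserving uniform placement of each DMR within the probe space (the
array-assayable intervals), repeated (default 1,000×) rather than in closed
form, so that irregular probe spaces need no special casing; the tail is an
exact binomial at the expected per-DMR rate, upper for enrichment and lower
for depletion.

**Conservation.**  Per-class ECDFs are evaluated on a fixed 101-point grid
over [0, 1] so curves from different classes are directly comparable and
plot-stable.  A curve lying *below* another is more conserved.

**CpG ratio.**  ratio = (n_CpG · L)/(n_C · n_G) with an overlapping "CG"
scan on the given strand — the standard observed/expected definition, which
resolves the length-normalization ambiguity of the bare frequency-ratio
phrasing.  Sequences with no C or no G return 0 with a `defined=False`
flag.  Non-ACGT positions are excluded from every count.

## Statistical kernels

All enrichment tails are exact and inclusive: P(X ≥ k), no normal
approximation, no continuity correction.  Binomial tails use the
regularized incomplete beta; hypergeometric tails the exact survival
function; both are verified against brute-force pmf summation for all
n ≤ 20 at 1e−12.  Benjamini–Hochberg q-values use the step-up
q₍ᵢ₎ = min₍j≥i₎ p₍ⱼ₎·m/j; Bonferroni is min(1, p·m) with m the number of
*tested* hypotheses.  The two-class location comparison ("15% vs 10%
upstream") is a one-sided binomial test of the first class's count against
the second class's proportion as reference — the second set is the
reference by convention here; a 2×2 exact test would be the other
defensible reading, but the binomial model matches the intended "proportion
against a fixed rate" framing.

## Motif discovery

Counting is forward-strand with overlapping matches, pooled over sequences
(totals, not per-sequence presence/absence); positions containing non-ACGT
characters are excluded from numerator and denominator alike.  No
reverse-complement canonicalization: the CpG-universe figure of
1,185/4,096 = 28.9% is over raw 6-mers, which fixes that convention.  The
background is sampled from gene windows with the exact multiset of target
lengths repeated `multiplier` (default 10) times, so target and background
share the length distribution by construction — this is also why motif
planting *overwrites* bases instead of inserting them.  The binomial n is
the total number of valid positions in the target set and p₀ the pooled
background rate; a zero background count with a nonzero target count gives
p = 0 and a boundary flag.  The log₂ enrichment score carries a 0.5
pseudocount on both counts for plotting stability; the test never does.
FDR thresholds default to 0.01 for whole-set analyses and 0.05 for
DHS-restricted ones.  The consistency null between two analyses draws each
set's size uniformly from the universe, preserving each set's role
proportions; the analytic expected overlap is |A||B|/U.

## Synthetic data generator

The generator emulates a two-tissue methylation-array study: one
chromosome, non-overlapping genes of 3–12 kb alternating strand, with
intergenic gaps large enough (> 8.2 kb) that 4 kb regulatory windows never
reach a neighbouring gene — so every planted (DMR, gene) pair is
unambiguous and recovery can be scored exactly.  Defaults follow the
study-scale regime: 2,498 DMRs of 200–2,000 bp, 34% planted
sign-concordant pairs, triplicate vs duplicate expression with replicate
noise SD 0.2 log₂ units, an 18% DMR/DHS overlap against a 13% placement
null, 35% shared DHS peaks, and a coherence bias of 0.8.  Methylation is
generated directly as per-tissue levels in [0, 1] (the pipeline consumes
DMRs, not probes), with a |ΔM| floor of 0.1 so planted signs are never
ambiguous.  Informative genes get true |ΔE| strictly above the
log₂(1.25) filter; a configurable fraction (default 0.15) is planted below
it to exercise exclusion.  Background DHS peaks are placed away from all
DMRs and topped up until the *analytic* probability that a random
length-preserving placement hits a peak reaches the target, so the planted
overlap fraction and the null rate are independently controlled.
Conservation scores are Gaussian with class-dependent mean shifts
(positive > negative > background; exons highest as a positive control),
clipped to [0, 1].  Every stage draws from its own fixed substream of the
seed, so outputs are byte-identical given a configuration and skipping one
stage never perturbs another.

What the generator does *not* emulate: array probe-level intensities,
bisulfite reads, sequence composition beyond i.i.d. bases at fixed GC,
spatially correlated methylation, realistic chromatin landscapes, or
enhancer biology.  Passing tests therefore demonstrate correctness of the
*pipeline logic and statistics* under planted truth, not biological
performance on real tissues; the headline percentages of any particular
tissue pair (the exact positive/negative split, motif counts, DHS overlap
rates) depend on that dataset and its annotation versions, and synthetic
runs reproduce them only in direction and shape.

## Problem sizes

The shipped tests and the acceptance script run the full pipeline at the
default study scale (≈2,500 DMRs on 1,800 genes) for single-pass checks,
with 10,000 shuffles for the sign null, 5,000 for coherence and 500–1,000
placements for DHS enrichment; multi-seed calibration checks (20 seeds) use
smaller replicates (250–700 DMRs, 300–400 shuffles), chosen as the smallest
sizes at which the planted effects are unambiguous.

## Known limitations

- Enhancer–promoter maps are consumed, never predicted; distal association
  quality is bounded by the supplied map.
- The midpoint rule assigns a single category to DMRs that genuinely span a
  feature boundary.
- The motif engine tests 6-mers independently; overlapping k-mers from one
  planted motif can drag neighbours over the significance line at high
  planting rates.
- With very few shuffles the sample SD in Z is noisy; the defaults (10⁴)
  make this negligible.
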