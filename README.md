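# tdmrlink

Linking **tissue-specific differentially methylated regions (T-DMRs)** to
gene expression.

When the same genomic region is methylated differently in two tissues, the
sign of that difference can agree or disagree with the sign of the
expression difference of a nearby gene.  Classically DNA methylation
represses transcription (a *negative* T-DMR: ΔM and ΔE of opposite sign),
but a sizeable minority of regions correlate *positively* with expression.
`tdmrlink` is a toolkit for characterizing both classes in a two-tissue
design:

- **Association & sign classification.**  Each T-DMR is paired with every
  gene whose strand-aware window `[TSS − 4 kb, transcription end]` it
  overlaps (proximal), or with genes reached through an enhancer–promoter
  map (distal).  With ΔM = m₁ − m₂ and ΔE = mean log₂ expression
  difference, a pair is *positive* when sign(ΔM) = sign(ΔE), *negative*
  otherwise, and excluded when |ΔE| ≤ log₂(1.25).  The observed split is
  compared against a null that permutes ΔM across pairs.
- **Coherence of multi-DMR genes.**  Genes with ≥ 2 classified T-DMRs are
  *coherent* (all pairs share one sign) or *incoherent*; observed class
  counts are scored with Z = (n − S̄)/std(S) against 10,000 ΔM shuffles.
- **Genomic context.**  Mutually exclusive feature categories (first
  exon/5′UTR, exon, intron, upstream, downstream, intergenic), DNase I
  hypersensitivity (DHS) overlap enrichment against a length-preserving
  placement null, conservation-score ECDFs per class, and the CpG
  observed/expected ratio (n_CpG · L)/(n_C · n_G).
- **Set enrichment.**  Hypergeometric term enrichment with Bonferroni
  correction for the gene sets behind each T-DMR class.
- **Motif discovery.**  All 4,096 6-mers are counted in each T-DMR class
  and in a 10× length-matched random background from gene windows; exact
  binomial upper tails with Benjamini–Hochberg FDR yield *negative*,
  *positive* and *dual* motif sets, whose CpG content is tested against the
  1,185/4,096 (28.9%) CpG-bearing 6-mer universe.
- **Synthetic data.**  A generator plants every structure the pipeline
  measures — sign-concordant fractions, coherent multi-DMR genes, DHS
  overlap, conservation shifts, spiked 6-mers — with truth tables, so the
  whole analysis runs and is testable without any external download.

## Worked example

```sh
tdmrlink simulate --outdir run/sim --seed 3 --n-genes 150 --n-dmrs 180
tdmrlink associate --dmrs run/sim/dmrs.tsv --genes run/sim/genes.bed \
    --expression run/sim/expression.tsv --outdir run/assoc
tdmrlink coherence --pairs run/assoc/pairs.tsv --seed 1 --outdir run/coh
```

`run/assoc/sign_summary.tsv` from this exact invocation:

```
proximity  n_pairs  n_excluded  n_positive_pairs  n_negative_pairs  positive_pair_fraction  ...
proximal   180      20          50                110               0.3125
```

Of 180 (T-DMR, gene) pairs, 20 fail the |ΔE| > log₂(1.25) filter; 31% of
the rest are positively correlated (the generator's planted fraction is
0.34), against a shuffle expectation of ~50% (`shuffle_summary.tsv`).
`run/coh/coherence_summary.tsv`:

```
class              observed  expected  sd    z      n_shuffles
incoherent         4         19.72     2.06  -7.62  10000
coherent_negative  16        3.78      1.70  7.19   10000
coherent_positive  7         3.50      1.63  2.15   10000
```

Far fewer genes carry incoherent T-DMR sets than the shuffle null expects
(Z ≈ −7.6) and coherent-negative genes are in excess (Z ≈ +7.2) — the
generator planted a coherence bias of 0.8 with a negative-majority sign
split, and the pipeline recovers both directions.

The same stages are available as library calls (`tdmrlink.assign_proximal`,
`classify_sign`, `coherence_null_test`, `dhs_overlap_enrichment`,
`kmer_enrichment`, ...); see `docs/methods.md` for the statistical detail.

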