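# Methods

## The mapping model

`bsa_mapping` implements the classic bulk-segregant mapping-by-sequencing
scan for a recessive causal mutation induced by EMS. The genetic setting is
an outcross F2: a homozygous mutant line (carrying the causal mutation plus
a few hundred background EMS sites) is crossed to wild type, F2 individuals
showing the phenotype are pooled, and the pool is sequenced. Selection
fixes the mutant haplotype at the causal locus in every pool member, so at
a marker a genetic distance *d* (Morgans) away each of the 2·*n* sampled
gametes carries the mutant allele with probability 1 − *r*(*d*), where
*r*(*d*) = (1 − e^(−2d))/2 is Haldane's map function (no interference).
Unlinked markers segregate at 1/2. The pooled variant frequency therefore
decays from 1 at the causal locus to 0.5 far away, and the
homozygote:heterozygote classification of each site turns that decay into
the window ratio that the scan maximises.

Stages and their rules:

- **EMS-spectrum filter**: keep (ref=G, alt=A) and (ref=C, alt=T) only —
  the two strand readings of the same guanine-alkylation event. Indels and
  ambiguity codes are rejected with a warning, never an exception, so a
  dirty VCF degrades gracefully.
- **Zygosity bands**: homozygous iff f ≥ 0.80; heterozygous iff
  0.45 ≤ f ≤ 0.55; otherwise discarded. All boundaries are inclusive
  exactly as the inequality signs state (unit-tested at 0.80, 0.45, 0.55,
  0.7999, 0.5501, 0.4499). Frequencies are recomputed from AD/DP when the
  VCF provides depths; the AF field is only a fallback.
- **Window scan**: non-overlapping 500-kb tiling windows per chromosome
  (terminal window may be shorter; counts are not length-normalised).
  Ratio = n_hom / max(n_het, 1): flooring the denominator keeps the
  statistic finite in windows without heterozygous calls, which at
  realistic EMS densities is most of the causal chromosome. Empty windows
  score 0. Tiling (rather than sliding) keeps the partition invariant:
  every classified variant is counted in exactly one window.
- **Interval call**: the peak is the genome-wide maximum-ratio window
  (ties broken toward the smallest coordinate on the earliest chromosome);
  the interval spans from the first to the last window on the peak's
  chromosome with ratio ≥ τ·peak (τ = 0.5). We deliberately do **not**
  require the above-threshold windows to be contiguous: with ~400 EMS
  sites on a 150-Mb genome a 500-kb window holds 1–2 variants on average,
  so many interior windows hold none at all, and an evidence gap is not
  evidence against linkage. Requiring contiguity collapses the interval to
  the single (noisy) peak window and loses the causal locus in most
  simulated pools; the bounding-span rule recovers it in ≥ 99/100 at the
  default design, while giving identical answers on dense scans (e.g.
  ratios [1,1,5,6,5,1] at τ = 0.5 still yield windows 3–5). The cost is a
  wide interval (≈ 10–12 Mb at the default density) — honest, given how
  little recombination a 60-individual pool samples; a candidate-gene step
  downstream of the interval is expected.

An optional exclusion list of (chrom, pos) pairs lets users subtract known
parental-background SNPs before filtering; no subtraction is applied by
default.

## The synthetic-data generator

`synthetic_data` emulates the study conditions end to end; it is the
package's test bed and demo input, not a read-level simulator.

- **Genome**: five 30-Mb chromosomes, centred pericentromeres covering 30%
  of each, uniform 4 cM/Mb. This is a deliberately simplified cartoon of
  the *A. thaliana* karyotype (real pericentromere boundaries and the real
  recombination landscape are config inputs when available, as a YAML
  genome model). Genes are placed uniformly; TEs with 4× density inside
  pericentromeres, matching the compartment contrast the enrichment tests
  exercise.
- **Pool**: n_mutations = 400 uniform EMS sites (plus the causal site),
  pool size 60, Poisson(50) depth, Binomial(depth, pooled frequency)
  alternate reads, zero sequencing error by default (a symmetric
  `error_rate` is available; the zygosity bands tolerate small error
  rates by construction). Pool size and depth are not reported for the
  original mapping populations; 60 individuals at 50× is a realistic
  design for this genome size and is used consistently as the default.
- **Promoters**: i.i.d. uniform ACGT sequence of 1 kb; a promoter is made
  a carrier with the stated per-set probability by embedding one exact
  copy of the motif consensus at a uniform position on a uniform strand.
  Real promoters are not uniform-random (GC skew, TATA context, repeats),
  so passing tests demonstrate correctness of the scanning and resampling
  machinery, not biological motif discovery — which is out of scope; the
  motif is always an input, and the bundled default (`TGACGTCA`, and the
  12-mer used in tests) is a synthetic stand-in, not a biological motif.
- **DE tables**: exactly n_up planted rows with log2FC ≥ 2 ∧ padj < 0.01,
  n_down with log2FC ≤ −2 ∧ padj < 0.01, all other rows drawn with
  padj ≥ 0.011 so they fail the filter regardless of fold change.
- **Determinism**: every operation draws from
  `default_rng(seed + operation_offset)` with fixed per-operation offsets,
  so outputs are byte-identical for a fixed seed and adding a new
  operation never shifts the existing streams.

## Enrichment, overlap and motif statistics

- **Compartments** partition the genome, so membership is by locus
  midpoint (boundary inclusive). **Chromatin states** are fragmented
  blocks, so membership is by ≥ 50% length overlap against merged blocks
  of the selected states (8 and 9 — the heterochromatic,
  H3K9me2/DNA-methylation-associated categories of the common nine-state
  segmentation). Two conventions for two topologies; both configurable.
- **Chi-square** is the plain goodness-of-fit Σ(O−E)²/E with df = 1 and no
  continuity correction; at the set sizes in practice (tens to hundreds of
  loci) the type-I error at α = 0.05 is within Monte-Carlo error of
  nominal (checked over 2,000 simulated background sets). Significance
  labels: `**` p ≤ 0.01, `*` p ≤ 0.05, `n.s` otherwise.
- **Fisher overlap** is one-sided (enrichment) by default because the
  question asked of a Venn diagram is whether the overlap is larger than
  chance; a two-sided alternative is a flag. The universe is a required
  input — overlap p-values are meaningless without one — and should match
  the sets' class (all annotated genes for gene sets, all TEs for TE
  sets). Implementation uses the scipy hypergeometric survival function;
  tests verify it against an exhaustive tail sum to 1e-12 relative error.
- **Motif scanning** matches IUPAC consensus by regex (overlapping hits
  included, both strands by default, N never matches) or scores a PWM by
  base-2 log-odds against a uniform background, with a hit iff
  score ≥ threshold × maximal achievable score. At threshold 1.0 PWM mode
  reduces exactly to consensus matching of the per-column argmax (for
  tie-free columns), which the tests use as an equivalence oracle. A small
  numerical tolerance (1e-9) guards the threshold comparison against
  floating-point rounding.
- **Promoter anchoring** is at the translation start (the `start`
  coordinate of plus-strand records, `end` of minus-strand), because
  carrier-rate background sets in this field are conventionally built from
  upstream-of-ATG files; a TSS-anchored extraction only requires passing
  TSS coordinates in those fields. Promoters truncated at a chromosome
  edge are returned short with a warning.
- **Resampling null**: draws are gene sets of the observed size sampled
  without replacement from the promoter universe; the empirical p uses the
  add-one rule so it is never 0 and its floor is 1/(draws + 1). With
  10,000 draws the floor is ~1e-4; enrichments like 25 carriers of 26
  genes at a 12.46% background rate are far beyond it (exact binomial tail
  ≈ 4e-21), so the reported p is the floor, by design.

## Expression utilities

- **DE filter**: padj strictly < 0.01, log2FC boundaries inclusive.
  Whether upstream fold changes were shrunken is the caller's concern; the
  filter applies to whatever table is supplied.
- **2^−ΔΔCt**: replicate Ct values are averaged *before* differencing
  (mean target Ct − mean reference Ct per group, then sample − calibrator).
  Averaging on the Ct scale makes the calibrator-vs-itself fold exactly
  1.0 and the reciprocal folds multiply to 1 — properties the tests pin
  down. Aggregation order is a convention; averaging per-replicate folds
  instead would give the geometric-mean behaviour.
- **NSAF**: SAF_i = count_i/length_i, normalised to sum to 1 and scaled by
  1e5 (the "e5" convention common in IP-MS tables). The formula is the
  standard spectral-count definition; values are scale-invariant under
  uniform count changes and sum to the scale constant.

## Problem sizes and numerical choices

The test suite and the acceptance script run entirely on simulated data at
the default design: 100 replicate pools for the recovery rate, 200 pools
per distance for the frequency law, 1,000–2,000 random tables/layouts for
the arithmetic oracles, 10,000 resampling draws. These sizes put the
Monte-Carlo checks at 3 standard errors of their expectations and complete
in well under a minute on one CPU. Statistical tolerances in tests are
stated as standard errors computed from the data, never absolute fudge
factors; arithmetic identities are checked to 1e-9 (chi-square) and 1e-12
(hypergeometric tails).

## Known limitations

- No read-level simulation (FASTQ, base quality, mapping bias); depth is
  Poisson and reads are Binomial, which understates real overdispersion.
- One uniform recombination rate; real pericentromeres are recombination
  cold spots, which would widen intervals spanning them.
- The pool design is a selected outcross F2; selfing-derived M2 pools or
  dominant phenotypes need a different frequency law and are not modelled.
- Pairwise Fisher tests only; no exact multi-set overlap statistics.
- The chi-square test is asymptotic; for sets of fewer than ~20 loci an
  exact binomial test would be preferable.
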