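# Methods

This note documents the models and procedures implemented in `tnseqkit`,
the defaults they use, and the choices made where the design was genuinely
open. Coordinates are 1-based inclusive everywhere; an insertion site is the
pair (position, orientation), where the position is the base adjacent to the
transposon I end after duplication correction and the orientation is the
direction in which the transposon-borne promoter transcribes on the genome.

## Junction-read processing

**Trimming.** A read is kept only if it contains the O-end marker string
(default: the 19-bp Tn5 mosaic-end-like sequence `CTGTCTCTTATACACATCT`);
the genomic fragment starts right after the marker, and any downstream
occurrence of a semiarbitrary-primer sequence is cut off. Both marker and
primers are plain configuration values: they are vector-specific and must be
set to match the construct that made the library. A minimal length filter
(fragment ≥ seed length) and an N-content filter (≤ 10%) replace external
quality trimming, which simulated reads do not need; real data should be
adapter/quality-trimmed upstream. An optional decoy screen for delivery-
plasmid reads is not built in — plasmid reads simply fail to find a seed
match on the genome and are counted as unaligned.

**Alignment.** The aligner indexes every 15-mer of the genome and requires
an exact match of the fragment's first 15 bases (the bases sequenced
directly out of the transposon, where base quality is highest and where the
site is defined) on either strand, then extends without gaps. Hits are
ranked by (coverage, identity); an exact tie means the fragment cannot be
placed uniquely and the read is discarded rather than assigned arbitrarily.
There is no gapped or quality-aware alignment: junction fragments are short,
and a substitution outside the seed only lowers identity without moving the
site.

**Duplication correction.** Tn5 duplicates 9 bp of target DNA, so the base
adjacent to the O end (the first read base) and the base adjacent to the I
end (the site, by convention) are the two ends of the same 9-bp word in
pre-insertion coordinates. For a hit on strand `+` at contig position *c*
the site is (*c* + d − 1, `−`) with d the duplication length (default 9);
strand `−` gives (*c* − d + 1, `+`). The simulator writes reads under
exactly this convention, and the error-free round trip (reads → sites) is
required by tests to be exact. Corrected positions that fall off the end of
a circular genome wrap around.

**Summaries.** Insertion density is genome length divided by the number of
unique (position, orientation) sites, rounded half away from zero, as
integer bp/insertion. The intragenic fraction is the integer percent of
unique sites inside any annotated gene span. Gap statistics collapse sites
by position (both orientations count once), take differences minus one
between consecutive positions, and add the wrap-around gap by default
(circular chromosome); the gaps therefore sum to genome length minus the
number of distinct positions.

## Essentiality calling

Sites are assigned to every gene whose span contains them (overlapping
genes each receive the site; double counting is the conservative choice for
essentiality). The offset is measured from the gene's own 5′ end, and an
insertion is *sense* when the site orientation equals the gene strand.

Filters for protein-coding genes, applied before classification:

* sense insertions with offset ≡ 0 (mod 3) — the "+1 reading frame". The
  transposon carries a promoter, Shine-Dalgarno and ATG at its I end, so a
  sense insertion at a codon boundary can express the remaining ORF portion
  in frame and mask essentiality. The register is configurable
  (`plus1_frame_offset_mod3`) because the frame arithmetic depends on the
  construct.
* any insertion in the stop codon (last 3 bp), both orientations;
* sense insertions in the last 9 bp and antisense insertions in the first
  9 bp (`edge_window`, with an optional stricter both-ends mode).

RNA genes have no reading frame or stop codon; only the edge windows apply.

Classification, in precedence order: **non-hit** (zero surviving
insertions), **last-10%** (all surviving offsets ≥ 0.9 × length),
**gap-80%** (largest insertion-free interval ≥ 0.8 × length, counting the
flanks from the gene start to the first insertion and from the last
insertion to the gene end), else nonessential. The thresholds
(`last_fraction_rule`, `gap_fraction_rule`) are deliberately stringent to
keep false essential calls low; both are exposed in `FilterPolicy`.
Classification is monotone: adding an insertion can never turn a
nonessential gene essential.

## Cluster permutation test

Essential genes concentrate in operons, so the observed binary sequence of
essential/nonessential protein-coding genes in genomic order is compared
against uniform label permutations (default 100,000). For each run length n,
p(n) is the add-one estimate (count of permutations whose longest essential
run is ≥ n, plus one, over n_perm + 1) — never zero, and counting the
observed arrangement as one permutation. One hypothesis is tested per
*distinct* observed run length, not per cluster instance, and the family is
controlled by step-down Holm at α = 0.05; each observed cluster then
inherits the decision for its length. Gene order is treated as linear by
default (a circular mode exists) since a wrap-around cluster is vanishingly
unlikely on a ~4,000-gene chromosome. With 4,054 genes and 616 essential,
runs of ≥ 6 are significant (p(6) ≈ 0.04, Monte-Carlo SE ≈ 6 × 10⁻⁴).

## Differential abundance

Counts are the per-gene sums of read counts of filter-surviving insertions,
per sample, with putatively essential genes excluded. Normalisation is
median-of-ratios: s_j = median over all-positive genes of count_ij divided
by the gene's geometric mean across samples.

Dispersion (NB variance μ + αμ²) is estimated in three steps: a pooled
within-condition method-of-moments estimate α_i = (v − m)/m² clipped at 0;
a parametric trend α(μ) = a₁/μ + a₀ fitted by iteratively trimmed least
squares over genes with positive estimates; and a weighted geometric
combination of trend and gene-wise values (default weight 0.5). Gene-wise
estimates *below* the trend are floored at it before combining: with three
replicates per group a method-of-moments zero is overwhelmingly sampling
noise, and letting it drag the final dispersion toward Poisson makes the
Wald test anti-conservative (realized FDR more than doubles in simulation).
This asymmetric shrinkage costs a little power for genuinely low-dispersion
genes and buys calibration; there is no empirical-Bayes prior, no outlier
refitting and no independent filtering.

The per-gene model is an NB GLM with log link, size-factor offsets and a
two-group design (reference library vs selected library), fitted by
iteratively reweighted least squares with Fisher weights μ/(1 + αμ); the
log2 fold change and its standard error come from the inverse information
at convergence, and the two-sided p-value is normal on the Wald statistic.
Genes with zero counts throughout one group get a 0.5-count continuity
correction and a `zero_group` flag. Benjamini-Hochberg adjusts the p-values;
the default significance level is α = 0.1, and significant genes are called
enriched or depleted by the sign of the fold change.

## Synthetic data generator

The generator emulates the study design the analysis targets: a high-GC
(default 68%) bacterial chromosome; protein-coding gene lengths log-normal
(median ≈ 900 bp, mean ≈ 975 bp, matching typical bacterial annotations)
plus a small fraction (5%) of shorter RNA genes; operons of 1–6 genes on a
single strand with 5–50 bp internal and ≥ 60 bp external spacers, any
slack spread uniformly between operons (plan on roughly 1.3–1.5 kb of
genome per gene, or `generate_genome` raises a sizing error); 15% of genes
essential, placed both as whole operons (60% of the quota, producing the
contiguous runs the cluster test looks for) and singly.

Candidate insertions are uniform with random orientation; an insertion
inside an essential gene is lethal unless the optional sense-rescue rule is
on (sense orientation in a configurable codon register), which models
promoter read-through keeping downstream operon members transcribed. The
mechanistic basis of such rescue (read-through vs a functional truncated
protein) is not settled, so it is off by default and the default truth is
simply "disrupting an essential gene is lethal". Mutant abundances are
log-normal (σ = 1); passage and selection are discrete Wright-Fisher with
multinomial resampling at a bottleneck (default 10⁵) and per-generation
weights exp(s), with |s| = ln(effect_fold)/generations so an affected mutant
changes ~effect_fold-fold (default 4×) over the episode (default 20
generations). Reads are the O-end marker plus the genomic fragment under
the duplication convention above, with iid substitution errors (default
10⁻³) and multinomial read counts; replicates are independent read
samplings of the same pool, mimicking DNA-extraction triplicates. A single
seed fixes everything; identical configurations give byte-identical files.

**What the generator does not model** — PCR and GC bias, chimeras,
quality-score realism, paired ends, multi-contig assemblies, delivery-
plasmid reads, and insertion-site sequence preferences. Passing tests on
this synthetic data therefore demonstrate the correctness of the
coordinate conventions, filters and statistics, not robustness to every
artefact of real libraries.

## Numerical choices and degenerate inputs

* Rounding of printed densities and percentages: nearest integer, half away
  from zero.
* Permutation p-values use the add-one estimator; lengths that exceed the
  number of essential genes get the add-one floor 1/(n_perm + 1).
* IRLS: max 50 iterations, convergence at 1e-10 on coefficients, linear
  predictor clipped at ±30; non-convergence keeps the estimate but reports a
  missing p-value.
* Empty site table: density and intragenic fraction are reported as missing;
  gap statistics require ≥ 1 site and raise otherwise.
* All-zero genes have undefined dispersion and are skipped (missing
  p-value); a sample with zero total counts is an error.
* Ambiguous alignments (exact (coverage, identity) ties) are dropped, since
  a best-hit rule without a tie-breaker cannot place them.

## Problem sizes used in the test suite

The suite exercises the pipeline on 30–160 kb genomes with 18–140 genes,
pools of 500–6,400 insertions and libraries of up to 40,000 reads, chosen
so the full battery (including the 100,000-permutation genome-scale
threshold check and a 2,000-gene differential-abundance calibration) runs
in well under a minute per module on a single core while leaving the
statistical assertions decisive (3-SE Monte-Carlo bounds, exhaustive
enumeration up to 20 genes).

## Known limitations

* The essentiality caller is rule-based; it has no probabilistic model of
  insertion density, so very short genes (< ~300 bp) can be called essential
  from sampling gaps alone — mirror the analysis convention of reporting
  sensitivity/false-call rates for genes ≥ 300 bp.
* The differential-abundance module supports exactly one two-group contrast
  at a time (reference vs condition); no multi-factor designs, shrunken-LFC
  estimators or likelihood-ratio tests.
* The cluster test works on gene order only, not on base-pair distance, and
  assumes protein-coding genes; RNA genes are excluded from the label
  sequence.
* Per-contig processing only: multi-contig genomes must be analysed contig
  by contig.
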