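# Methods

`apfind` studies how replacing a generic reference genome with a
personalized genome changes ChIP-seq peak calls. The pipeline builds a
modified personal genome (MPG) from phased variants, aligns one read set to
both genomes, calls peaks on each alignment, projects the annotations into a
common coordinate frame through chain files, and classifies every peak as
*common* (any ≥ 1 bp overlap between the two calls), *personal-only*
(called only on the personal genome) or *ref-only* (called only on the
reference). Altered peaks (APs) are the personal-only and ref-only calls.
Because the required real datasets are deep ENCODE/WGS resources, the
package ships a first-class synthetic-data module that generates every
input under stated study conditions with full seed control.

## The synthetic study

**Genome and variants.** The reference is an i.i.d. nucleotide sequence
(default 1 Mb, GC 0.41). The call set holds `n_snv` SNVs and `n_indel`
indels (defaults 1,750 / 250) at uniform positions with non-overlapping
reference footprints. Phases are uniform over hap1 / hap2 / both
(heterozygous on either haplotype, or homozygous-alternative). Indel sizes
follow a truncated geometric law (mean 4 bp, range [1, 50]), the size
spectrum of real short-indel call sets; insertions and deletions are
equally likely and anchored VCF-style on the preceding base.

**Enriched regions.** `n_enriched` regions (default 200, mean width 500 bp)
are planted in four mutually exclusive content categories — no variants,
SNVs only, indels only, both — with equal default quotas. Regions in
variant categories are anchored on an actual variant placed near the region
midpoint, and every label is re-verified against the variant list after
placement. Read pileups are summit-shaped: the read-start density rises
linearly from the background level at the region edges to
`background_depth × fold` at the midpoint. Per-region summit folds are
drawn log-uniformly between `fold_min` (default 2) and `enrichment_fold`
(default 10). Both choices mirror real data: ChIP pileups have summits, and
empirical peak-strength spectra pile up near the caller's significance
threshold — which is exactly where altered peaks live. A constant fold
would place every region far from threshold and the phenomenon under study
would vanish.

**Reads.** Single-end reads (36 bp default; 100 bp supported) are drawn
from the two haplotypes with equal probability at a combined start density
of `background_depth` (default 0.5 reads/bp) outside regions. A uniform
per-base substitution error (default 1%) is applied. Reads carry hidden
truth fields (haplotype, origin position) used only by tests.

**Toy aligner.** A gapless exact-seed aligner reports each read at its
best (fewest-mismatch) position when that is within `max_mismatches`
(pipeline default 1), ties broken leftmost; coordinate-identical placements
(contig, start, end, strand) collapse to one record, as coordinate
duplicate-marking would do. Gapless alignment means indel-spanning reads go
unmapped against the non-matching genome — the cleanest toy mechanism for
the *rescued read*: a read lost to reference bias that maps once the genome
carries its allele. The mismatch budget interacts with the error rate to
grade the SNV effect: a read carrying a non-reference SNV still maps unless
a sequencing error consumes the budget, so SNVs cost a minority of their
overlapping reads while indels cost all of them. This is the mechanism
behind the indel > SNV ordering of alteration probabilities.

**Toy peak caller.** Fixed-width windows (2 × read length, a
fragment-length surrogate for model-free calling) slide base by base and
are scored by the count of overlapping reads against a Poisson expectation
`λ = max(λ_global, λ_local)`, with
`λ_global = total_reads × (window + read_length) / (0.8 × genome size)` —
the 80% factor emulates setting the effective genome size to 80% of the
assembly and keeps the global rate conservative — and `λ_local` the read
rate in a 10 kb window, as real callers floor a local lambda with the
genome-wide one. Upper-tail p-values become q-values by Benjamini–Hochberg;
windows with q ≤ FDR (default 0.05) merge into peaks carrying
−log10(q), an integer score = round(10 × −log10 q), and fold-over-background
signal. Three details matter for cross-genome comparisons and were chosen
for that reason:

* *base-step sliding windows* — a coarser grid flips threshold-level calls
  on grid phase alone when the same reads are binned in two coordinate
  systems offset by indels;
* *local lambda* — with a single global Poisson rate, p-values are discrete
  by count level, and entire count-levels of borderline regions flip
  together when the BH cutoff moves microscopically between the two calls;
  the continuous local term removes these mass ties;
* *shared background total* — the two calls of a paired design (one
  library, two assemblies) use one background total (the mean of the two
  alignments' retained read counts). The personalized alignment retains
  ~1% more reads; letting that raise its lambda systematically handicaps
  marginal personal calls and reverses the direction of the personal-only
  excess for reasons unrelated to any local signal.

**Degraded assembly.** DPG mode removes random segments (exponential mean
2 kb) totalling `dropout_fraction` of each haplotype contig before
alignment, emulating an incomplete de novo assembly, and emits exact chains
for the surviving coordinates. Lifting to/from degraded chains uses the
permissive 0.85 minMatch; everything else uses the 0.95 default.

## Genome forging and liftover

`apply_phased_variants` substitutes each haplotype's alleles into the
reference. SNVs substitute in place and never break a chain block; an indel
closes the current block at the shared allele prefix (the anchor base) and
opens the next with offset `len(alt) − len(ref)`. Chains satisfy: block
source length = target length, strictly increasing non-overlapping blocks,
haplotype length = reference length + Σ(len(alt) − len(ref)).

`lift_intervals` projects an interval through a chain set: it lifts iff the
fraction of its bases covered by blocks of a single chain reaches
`min_match`, to the span of its first-to-last mapped target base. Because
the package's chains are exact by construction, base-level mappability
equals sequence identity; for alignment-derived chains the two can diverge
(not modelled here). Intervals spanning two chains stay unlifted (peak
semantics require contiguity). Inversion and composition of chains are
exact block operations.

The pipeline lifts *reference-frame annotations into the personal frame*
(peaks, per-read coverage, variant tracks), the direction used for MPGs,
and compares in personal coordinates. The alternative direction would
discard strong personal-only peaks whose causal indel breaks the minMatch
rule, converting them into spurious ref-only calls. Variant tracks lift
under an any-mapped-base rule: their chains are exact and a deletion's own
reference footprint survives only through its anchor base.

## Peak comparison, skew, characterization

*Categorization* uses ≥ 1 bp overlap, read depth ignored; a personal peak
overlapping several reference peaks is one common peak, counted from the
personal side. *Annotation* counts overlapping features per peak
(bedtools `intersect -c` semantics, half-open intervals). In the pipeline,
read counts use the exact peak interval while variant counts use the
interval padded by one window (2 × read length): a variant alters a call
through reads whose spans reach beyond the called run, and without the
margin the causal variant of a threshold-level flip frequently sits
18–60 bp outside the reported peak.

*AP fraction* is `100 × n_category / (n_common + n_category)`, the
same-genome-total convention, reported to one decimal.

*Coverage skew* per peak is a two-cell goodness-of-fit χ² (1 df) of the two
read counts against library-size-proportional expectations, α = 0.05, no
multiple-testing correction (each peak is one pre-specified comparison of
one dataset mapped twice, so overdispersion across libraries does not
apply). Zero counts receive a single pseudocount read. No continuity
correction; the pseudocount already guards the zero cell. Significant peaks
are ref-skewed or personal-skewed by the library-normalized direction.

*Variant-combination probabilities* divide each combination's altered count
by its total peak count. Because per-study AP counts are small at megabase
scale (a few peaks per run), the headline probabilities are estimated by
pooling replicate simulations that differ only in seed.

*Logistic AP model*: response altered/common, covariates peak width (per
100 bp), SNV count, indel count. Each refit downsamples the common class to
the AP count, standardizes covariates, fits an L1-penalized logistic
regression with the penalty chosen at the cross-validated minimum deviance,
and unscales the coefficients; the median over refits is reported. Pure L1
and CV-min were chosen as the plainest members of the elastic-net family;
at the default sizes the penalty shrinks null coefficients to zero while
biasing true effects by under 5%.

*Replication null*: the observed AP overlap between two genome
implementations is compared with the distribution obtained by repeatedly
sampling the same numbers of peaks uniformly without replacement from each
genome's full peak track (default 1,000 iterations) and counting
cross-overlaps; the empirical p-value is add-one smoothed. The Monte-Carlo
mean matches exhaustive subset enumeration on small universes.

*Gene distances* are boundary-to-boundary and strand-agnostic, binned as
overlapping / ≤ 10 kb / 10–100 kb / > 100 kb. *Repeat enrichment* compares
each repeat family's frequency among repeats overlapping AP peaks with its
frequency among repeats overlapping random control intervals whose width
multiset replicates the AP widths exactly; families are name prefixes
(leading alphabetic run), and families under 5% of AP overlaps merge into
"other". *Confident peaks* require natural-log(score) ≥ 4.0 (score ≈ 55);
the log base is a package decision, configurable.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| `contig_lengths` | 1 Mb | bp | desk-scale study size |
| `n_snv`, `n_indel` | 1750, 250 | count | ~7:1 SNV:indel ratio of deep call sets, 2 variants/kb |
| `indel_size_mean` | 4 | bp | geometric size law of short-indel call sets |
| `n_enriched`, quotas | 200, even | count | balanced content categories for the combination analysis |
| `enrichment_fold`, `fold_min` | 10, 2 | ratio | summit folds log-uniform: strengths span the detection limit upward |
| `background_depth` | 0.5 | reads/bp | combined diploid start density |
| `read_length` | 36 | bp | short-read mode; 100 bp supported |
| `error_rate` | 0.01 | per base | grades the SNV effect under a 1-mismatch budget |
| `max_mismatches` | 1 (pipeline) | count | tolerate an isolated variant or error, never an indel |
| `fdr` | 0.05 | q cutoff | permissive peak-calling threshold |
| `min_match` / `alt_min_match` | 0.95 / 0.85 | fraction | default and degraded-assembly lifting stringency |
| `dropout_fraction` | 0 (0.10 in DPG studies) | fraction | assembly incompleteness |

## What the simulator does and does not emulate

It reproduces, at megabase scale, the mechanisms the pipeline is built to
detect: allele-dependent read loss and rescue, coordinate shifts from
indels, threshold-level call flipping, assembly dropout, and the resulting
excess of personal-only over ref-only calls with
P(altered | indel) > P(altered | SNV only) > P(altered | no variants) ≈ 0.
It does not emulate paired-end reads, base-quality-structured or
position-dependent error profiles, GC or mappability bias, repetitive
sequence (the reference is i.i.d., so multi-mapping is essentially absent),
structural variation beyond 50 bp indels, or graph-genome alignment.
Passing tests therefore show that the pipeline's logic is correct and that
the reference-bias mechanisms behave as described under controlled
conditions — not that effect sizes on real data will match.

## Numerical choices and degenerate inputs

Poisson survival probabilities are floored at 1e−300 before logs. BH
q-values are clipped to [0, 1]. Peak merging treats overlapping or
adjacent significant windows as one peak. The aligner breaks score ties by
leftmost coordinate; candidate positions crossing contig boundaries are
discarded explicitly. Empty inputs return empty outputs of the documented
shape (empty read set → empty track; empty track → no peaks; empty peak
set → empty skew summary). Zero-length contigs, unphased or half-called
genotypes, multi-allelic records, overlapping variant footprints, REF
mismatches, and oversampling requests raise errors naming the offending
record. `replication_null` with one iteration is flagged degenerate rather
than reporting an undefined standard deviation.

## Known limitations

Alteration probabilities at megabase scale rest on a handful of peaks per
study; the package pools replicate seeds, but single-study estimates are
noisy by nature. Heterozygous SNVs are nearly invisible to a single-haploid
analysis under exact matching (each genome retains exactly one haplotype's
reads), so the SNV effect is carried by homozygous sites and error
coupling; analysing both haplotypes and merging, as a full MPG analysis
would, is supported by running the pipeline per haplotype but not wired
into one call. Reverse-strand chain blocks, net/axt formats, IDR replicate
correction and graph genomes are out of scope.
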