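# Methods

## Variant model and normalization

All internal coordinates are 0-based half-open; VCF positions are converted
on read/write and BED is consumed natively. A `VariantRecord` carries the
alleles verbatim as read; comparisons always go through
`normalize_variant`, which trims the common allele prefix/suffix to a
minimal representation (deletion: `ref = deleted bases, alt = ""`;
insertion: the converse) and left-aligns indels against the reference by
repeated single-base shifts — the textbook normalization that makes two
callers' reports of the same indel in a homopolymer run comparable.
Normalization is idempotent, and the equivalence key
`(chrom, pos, ref, alt, class, size)` deliberately excludes line and caller
so that sharing and deduplication are well defined. `size_bp` is redundant
for allele-bearing classes but lets allele-free events (inversions, tandem
duplications) compare on their span.

Structural-variant events are ingested from a simple tab-delimited dialect
(event code, chrom, 1-based start/end, size, inserted sequence, supporting
reads) defined by this package and emitted by its own simulator; deletions
and replacements arrive without allele sequence and have the deleted allele
filled from the reference during normalization so they can deduplicate
against the SNV caller's representation of the same event.

## Line-specific extraction

Sharing is computed over the *raw* (normalized but unfiltered) calls of the
whole cohort supplied in one run, so the ledger's "common" column is counted
before read-support filtering — shared-variant removal therefore does not
commute with the record filters, and the pipeline fixes the order. The
defaults are: shared if present in ≥ 2 lines; keep records with ≥ 10
variant-supporting reads ("support" means alt reads, not total depth,
switchable via `support_mode`); drop records with > 5% reference-type reads;
drop multi-allelic records. Cohorts below 4 lines proceed with a warning,
since intracultivar removal weakens.

Two sample designs exist: homozygous individual mutants, and pooled M₂
samples in which every mutation segregates and is observed heterozygous at
~50% allele fraction. The 5% reference-read test would reject every call in
the pooled design, so `pooled_het_mode` replaces it with a minimum
alt-allele-fraction test (default ≥ 0.20). Whether the original filtering
applied the reference-fraction test to pooled cohorts is not documented;
both modes are provided and the strict mode is the default.

A line whose unique-mutation count exceeds 10× the cohort median is flagged
as a possible outcross or seed contamination — such lines carry tens of
thousands of private variants rather than tens, so any threshold in that
range separates them cleanly; the fold-based rule was chosen over a z-score
because the per-line count distribution is tight and a single contaminant
would inflate a variance estimate.

SV-caller breakpoint wobble is *not* absorbed: sharing uses exact key
equality. A ±10 bp jitter mode was considered and dropped — the simulator
emits exact breakpoints, so the mode would be untestable here, and exact
matching is the conservative choice (wobbling duplicates remain as separate
candidates rather than being silently merged).

## Coverage-gap deletions

Input is a per-base depth track (bedGraph), not alignments; producing depth
from BAM is standard tooling and out of scope. Per target, the detector
computes mean depth and the fraction of bases with depth > 0 (verified
against a per-base brute-force accumulator on randomized layouts). Targets
with zero covered fraction (or mean depth ≤ a configurable `max_depth`) are
grouped when consecutive *in target order* on a chromosome — genomic gap
length between targets is ignored unless `max_gap_bp` is set, because real
multi-exon deletions bridge intergenic gaps. Each group becomes one
candidate whose span runs from the first uncovered target's start to the
last's end: a minimum bound, since the true breakpoints lie in unobserved
flanking sequence. `min_flank_covered` (default on) requires the targets
flanking a run to be covered, suppressing chromosome-end artifacts.
Heterozygous deletions halve depth rather than zeroing it and are invisible
at the default threshold — by design; depth-ratio CNV modeling is a
non-goal.

## Effect classification

One representative transcript per gene. For an SNV in CDS the affected
codon is rebuilt from the spliced coding sequence (GFF3 phases honored,
minus-strand alleles complemented) and translated with the standard nuclear
code: synonymous / missense / nonsense / stop-loss. Indels in CDS are
frameshift when `size mod 3 ≠ 0`, else in-frame; inversions preserve length
and count as in-frame coding disruptions. Variants within 2 bp of an
intron edge are splice-disrupting. Exonic non-CDS intervals are 5′ or 3′
UTR by their side of the CDS in transcript orientation; variants within
`flank_bp` (default 5000, the convention of the annotator this classifier
replaces; the original window is undocumented) of the gene span are
upstream/downstream by strand. Across overlapping genes the worst effect
wins, with severity order
nonsense > frameshift > stop-loss > splice > missense > in-frame >
utr5 > utr3 > upstream > downstream > synonymous > intronic > intergenic.

The four reporting buckets are total over details; intergenic folds into
silent-or-intronic (the bucket enum is total) but is always reported as its
own detail, and `summarize_effects(separate_intergenic=True)` splits it
out, since whether the original "synonymous and intronic" category absorbed
in-target intergenic variants is unknowable from the published breakdown.
Classification is strand-symmetric: reverse-complementing genome, gene and
variant leaves every call unchanged (property-tested base by base over a
two-exon gene).

## Spectrum and dose-response statistics

- Transition/transversion is classified on normalized single-base SNVs
  only; multi-base replacements are excluded from the substitution matrix.
- GC preference: `ratio_mut = (n_C+n_G)/(n_A+n_T)` at mutated sites,
  enrichment = `ratio_mut / (GC/AT of the target space)`. The target
  composition is computed from sequence, verified against a per-base count.
- Gaussian fit of per-line counts: the default `mle` method is the closed
  form (sample mean, √central second moment); `histogram_ls` least-squares
  fits a Gaussian to the unit-binned histogram, which can sit below the
  mean when the count distribution is right-skewed — the reason a
  histogram-fitted μ can differ from the arithmetic mean of the same data.
  Both are exposed; reports label which was used.
- Per-Gy rate is `mean/dose` with the SE scaled identically; genome
  extrapolation is linear, `count × genome_bases/target_bases`, with the
  rice constants 373,245,519 and 34,040,553 as defaults (ratio 10.96). Both
  are homogeneity-tested.
- Per-chromosome frequency is `count / (target Mb on chromosome × lines)`;
  chromosomes without targets are excluded from the max/min ratio. The
  cohort-average "per Mb per line" figure published for the original cohort
  is not reproducible from its own totals and is deliberately not a target;
  this package reports its definition explicitly.
- CDM rate is `100 × Σ class counts / lines harvested`, with class counts
  validated against the harvest total.
- SE vs SD: groups report `SD/√n` as SE; every table labels which is shown.

## The synthetic cohort generator

The generator's defaults are the study conditions: 150 Gy dry-seed
irradiation at 30 keV μm⁻¹ with per-line in-target counts drawn as a
zero-floored rounded Normal(9.06, 4.37) (Poisson mode available); class
probabilities (SNV .575, DEL .373, INS .036, RPL .013, INV .003); deletion
sizes 1 bp w.p. .333, 2–10 bp w.p. .534, geometric tail; insertion sizes
1 bp w.p. .639, 2–11 bp w.p. .333, rare larger; transition fraction
271/573; GC-biased site selection with enrichment 1.60; a shared background
of 1,300 variants present in every line; mean on-target depth 80. The
dose→mean map for other conditions (75→2.80, 100→4.44, 175→10.33,
200→11.75, imbibed 15→2.75) ships as `DOSE_MEAN_DEFAULTS`. Defaults for
quantities the study does not state were fixed once at field-realistic
values: genome GC 0.44 (rice-like), 2×300 kb chromosomes with 60 multi-exon
genes for desk-scale fixtures, exon CDS segments of 90–300 bp with 80–300 bp
introns, capture targets = exons ± 50 bp merged.

Variants are emitted directly as call files (VCF and the SV dialect), not
as reads: read simulation and alignment are out of scope, which keeps the
full 110-line cohort generation plus pipeline under ten seconds. Small
indels (≤ 10 bp) are written to *both* callers' files to exercise
cross-caller deduplication; larger events, replacements and inversions are
SV-only; SNVs are VCF-only. Injected variants are normalized at injection
time and collision-checked (12 bp margin) so the truth table's keys are
exactly the keys the pipeline should recover. In the homozygous depth
model, reference reads are drawn as Binomial(depth, 0.005) capped at 4% of
depth — true homozygous sites have only mismapping-level reference reads,
and an uncapped draw would occasionally straddle the 5% filter and make
clean-mode recovery probabilistic rather than exact. Heterozygous mode
draws alt reads at ~50%.

What passing tests therefore show: the pipeline's bookkeeping (sharing,
filtering, dedup, intersection, detection, classification) is exact on
inputs matching its assumptions. What they do not show: robustness to
caller-specific artifacts — breakpoint wobble, multi-allelic noise near
repeats, capture-efficiency bias, index hopping — none of which the
generator models beyond depth noise.

## Liftover refinement

Best-hit assignment discards hits with e-value > 1e-10 and takes maximum
identity (ties: higher bitscore, then leftmost subject coordinate),
verified against an exhaustive argmax oracle on randomized tables. The
synteny pass uses a window of 5 placed neighbors each side in source order
(the original procedure names no window; 5 is conservative and
configurable): a query whose chromosome disagrees with the simple majority
of its neighbors — or whose position falls outside the interval spanned by
its majority-chromosome neighbors, padded by one query length — is
re-searched among its remaining significant hits for the highest-identity
hit inside that interval (`synteny_adjusted`) and otherwise keeps its
original locus flagged as a putative translocation. The positional check
requires flanking concordant neighbors on *both* sides, so block-edge
queries are judged on chromosome agreement alone; and only `unique` entries
are re-examined, which makes refinement idempotent on its own output.

## Numerical conventions and degenerate inputs

Fractions are reported over nonzero totals and as `None`/undefined
otherwise (empty effect summaries, zero A/T counts). Degenerate Gaussian
inputs (constant counts, < 2 points) raise. Ties in the severity order
cannot occur (the order is total). Reported published-value comparisons use
one unit in the last printed digit as tolerance, because a few published
roundings are truncations of their own arithmetic.

## Problem sizes

Unit and property tests run on 2×300 kb genomes with 8–60 lines; the
acceptance suite simulates 110 lines on a 3×400 kb genome with 120 genes
(~99 kb of capture targets) and a 1,300-variant background — large enough
that the shared:private ratio matches the realistic regime while the whole
suite stays under half a minute.
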