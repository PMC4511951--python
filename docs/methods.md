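# Methods

This note records the models behind each analysis stage, the generative
model of the synthetic-data module, the parameter defaults and why they were
chosen, and the numerical and design decisions a maintainer would want to
know. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Read context classification and the mRNA filter

Coordinates are 0-based half-open everywhere internally (BED native; GTF is
converted on read, VCF variant tables keep their 1-based positions since no
interval arithmetic touches them). The mRNA region set is the union of all
exons per chromosome, merged with overlapping *and adjacent* intervals
coalesced; gene territory is the merged union of transcript spans; intronic
space is gene territory minus exons and intergenic is the complement. A read
is **MRNA** when its overlap with the merged exon set reaches
`min_overlap_bp` (default 1 bp — any spliced read touches exons, so a
single-base rule is the permissive reading of "reads outside of mRNA
regions"; a `min_overlap_fraction` switch is provided for stricter use),
otherwise **INTRONIC** when it touches any gene span, otherwise
**INTERGENIC**. Strand is ignored for classification — the filter is purely
positional — and carried only for coverage orientation.

Overlap queries run on sorted merged interval arrays with binary search and
length prefix sums; tests cross-check the classification against a
per-base boolean-mask oracle on toy genomes.

GC histograms use 101 integer-percent bins; a read with GC fraction *g*
lands in bin round(100·g) with half-up ties. Reads without a defined GC are
excluded and counted separately. The `histogram_max_diff` statistic (max
absolute per-bin density difference, argmax bin, lowest bin on ties)
quantifies the artifact peak before and after filtering.

## Transcript-body coverage

Per-base coverage of each spliced transcript is binned into 100 equal-width
bins of normalized position by `floor(i·100/L)`, reversed for minus-strand
transcripts so bins always run 5′→3′, averaged per bin and normalized by
the profile mean (bin mean = 1 ± 1e-9 whenever raw mean coverage is
positive). Transcripts shorter than the bin count are skipped with a logged
reason. Length classes are half-open — [500, 4000), [4000, 8000),
[8000, ∞), below 500 bp excluded — so the published class intervals, which
overlap at their printed boundaries, partition cleanly; the boundary
assignment (4000 → MEDIUM, 8000 → LONG) is a package decision.

Aggregates weight each transcript equally (the plot is per-transcript
normalized, not expression-weighted); transcripts below raw mean coverage 1
are excluded as unexpressed. The bias score is
`bias_3p = mean(bins 91–100) / mean(bins 1–10)`; 1.0 is flat, and a zero
first-decile mean is reported as NaN rather than inf. An optional
stratification by raw-mean-coverage quartile exposes the
expression-level-independence check.

## Expression concordance

*Quantile normalization* is the classic rank-mean procedure: the per-rank
reference is the mean of the samples' sorted values and each value is
replaced by the reference at its rank, ties receiving the mean of their tied
ranks' references. Note these two contracts interact: with heavy ties (raw
counts) a tie block is replaced by its block mean, so columns share sorted
values exactly only on tie-free input; column means are always equalized.

*Correlation* defaults to Pearson on log2(x+1) (the transform is a package
decision — only the normalization step is prescribed upstream), with raw
and Spearman switches. Zero-variance columns produce flagged NaNs, never a
silent 0. *Clustering* is agglomerative average linkage on distance
d = 1 − r; sample labels are lexicographically sorted before linkage so
distance ties resolve deterministically toward lexicographically smallest
members, and leaf order is deterministic. Dendrograms export as Newick with
branch lengths from merge-height differences.

*Size factors* are the DESeq median-of-ratios: per-gene reference is the
geometric mean over samples restricted to genes positive everywhere; a
sample's factor is the median ratio to that reference. Fold changes are not
a negative-binomial fit — the pipeline deliberately consumes externally
computed differential-expression p-values — but the ratio of size-factor-
normalized means with a 0.5 pseudocount:
`log2((mean_T + 0.5)/(mean_N + 0.5))`, with A = log2(overall normalized
mean + 0.5) and an expression floor on the overall normalized mean.

*Lowess* is degree-1 locally weighted regression with tricube weights over
the span-nearest neighbors (span 0.3 default), no robustness iterations,
evaluated on a 200-point grid over the observed A range (statsmodels
backend). Edge windows contain half the usual neighbors, so null-trend
bounds in the tests are asserted on the interior 80% of the A range.

*Set overlap* reports |A|, |A∩B| and 100·|A∩B|/|A| rounded to one decimal.

## Variant concordance

RNA calls join DNA evidence exactly on (chrom, pos, ref, alt); multi-allelic
records must be split upstream and indels are rejected (SNVs only). RNA loci
with no DNA record of any depth get dna_depth = 0 — hence AMBIGUOUS — and a
missing-evidence report. Pairs below the 10% RNA AF floor are excluded from
classification and counted. The three-way rule, with inclusive boundaries
("at least 10%", "at least 10X") — the overlap of the concordant and
discordant definitions at exactly 10% DNA AF is resolved toward CONCORDANT:

* DNA depth < 10X → AMBIGUOUS
* else DNA AF ≥ 0.10 → CONCORDANT
* else → DISCORDANT

Substitutions are the literal ref>alt on the plus strand (12 classes, no
strand collapsing) because the deamination filter names the two complementary
classes C>T and G>A jointly and explicitly. The filter removes a pair iff
its class is deamination **and** RNA AF < 0.50 (boundary kept); everything
else passes at any AF. Removal is monotone in the threshold. Concordant
deamination calls below AF 0.5 are removed by design — that is the small
concordant loss the before/after table shape exhibits.

The summary table reports per-sample concordant/discordant/ambiguous counts
before and after filtering, a totals row,
`retained_pct = 100·concordant_after/concordant_before` and
`discordant_reduction_pct = 100·(1 − after/before)`, both to two decimals.
On the published per-sample cells this formula yields 91.37% discordant
reduction while the source table prints −91.14% by an unstated derivation
(it is also not the mean of per-sample reductions); the formula is kept and
the discrepancy documented rather than reproduced. Likewise the quoted ≈4%
false-positive rate has no stated denominator and is not targeted.

## The synthetic-data generator

No generative model is published for these contrasts, so the generator uses
the simplest forms that reproduce them; every parameter is exposed on
`SimulationConfig` and all randomness flows from one seed through fixed
per-stage `numpy.random.default_rng` streams (annotation → reads → coverage
→ counts → variants), making outputs bit-identical for identical
config + seed.

**Annotation** — one toy chromosome; spliced lengths log-uniform over
(500, 30000) bp; 1–8 exons split uniformly at random, introns 200–2000 bp,
intergenic gaps 2–10 kbp, one gene per transcript.

**Reads** (default 100 000/sample, 100 bp) — each read is intronic with
probability `intronic_fraction_ffpe` = 0.4 (FFPE) or
`intronic_fraction_ff` = 0 (FF), placed uniformly inside a single
length-weighted intron or exon, with GC drawn truncated-normal:
intronic N(0.53, 0.02), exonic N(0.45, 0.08) — the intron mode matches the
observed 53% artifact peak, the exonic parameters a typical mRNA GC
distribution. GC is simulated per read directly since nothing downstream
consumes nucleotides; `emit_read_sequences` exists solely for round-trip
tests. Because reads sit wholly inside one feature, truth labels coincide
exactly with positional classification — by construction there are no
junction-straddling reads, which real libraries do contain.

**Coverage** — expected coverage at normalized position x ∈ [0,1] is
∝ exp(β·x) with `β = bias_coeff · max(0, 10 − RIN) · log2(L/1 kbp)` for FF
(clipped at 0 below 1 kbp) and β = 0 for FFPE; observations are Poisson
around depth 50. `bias_coeff` = 0.2 gives β = 4 for a 16 kbp transcript at
RIN 5, a strong but not degenerate 3′ skew, and β = 0 at RIN 10 — the
highest-integrity FF sample behaves like FFPE.

**Counts** — per-gene baselines log-normal (log2 mean 7, sd 2.5); a 10%
fraction of genes carries a shared tumor log2 fold change φ ~ N(0, 2) (tumor
vs normal differences are large; the sd also gives the fold-change-recovery
signal a realistic dynamic range); each tumor subject adds a per-gene
heterogeneity effect N(0, 0.3) shared by its FF and FFPE columns — this is
what makes matched pairs cluster together; FFPE tumor means are multiplied
by `lowexpr_attenuation` = 0.7 for genes with baseline log2 mean < 10 (the
attenuation magnitude is a free parameter — only its existence and the
cutoff are reported upstream); counts are negative-binomial with dispersion
0.05 and per-sample log-normal library factors (sd 0.15). Six tumor pairs
and seven normals mirror the study design. Optional NanoString-style columns
resample tumor expression on a random gene subset with per-gene probe
-efficiency noise. Known limitation: at the default baseline most genes sit
below the attenuation cutoff, so median-of-ratios size factors absorb the
constant attenuation; the MA-step behavior is therefore demonstrated with a
high-expression baseline where attenuated genes are a minority.

**Variants** — 100 true somatic SNVs with DNA AF from a clonal/subclonal
mixture (AF 0.5 with probability 0.5, else Uniform(0.1, 0.4)); DNA depth
Poisson(60) with 10% of loci forced below 10X; RNA evidence is a binomial
resample of the true AF. True variants draw from the ten non-deamination
substitution classes so that artifact truth coincides exactly with the
deamination-filter action; fixtures with clonal C>T calls near AF 0.5 are
constructed directly in tests to exercise the filter's (intended)
false-removal behavior. FFPE samples add 150 artifact loci: C>T or G>A,
RNA AF uniform on (0.12, 0.45), zero DNA alt depth. FF samples get none.

### What passing tests do and do not show

The generator reproduces the *direction and structure* of the published
contrasts — intronic GC mode, flat FFPE vs length/RIN-dependent FF coverage,
matched-pair clustering, sub-50% deamination artifacts — under clean
assumptions: no junction reads, no sequencing error, no indels, no mapping
ambiguity, single-transcript genes, and artifact/true-variant classes kept
disjoint by default. Passing tests therefore validate the *rules and
arithmetic* of the analysis stages and their behavior under the stated
generative model, not performance on real libraries; headline real-data
quantities (cross-sample correlation magnitudes, per-sample concordance
counts) depend on access-restricted tumor data and are only reproduced as
arithmetic on their published summary cells.

## Pipeline

The run config is a flat YAML mapping; thresholds default to the published
values (RNA/DNA AF floors 0.10, DNA coverage 10X, deamination AF threshold
0.50, 100 profile bins, lowess span 0.3). Validation aggregates all errors
(range checks, path existence, cross-field stage dependencies) instead of
failing on the first. Stages run in dependency order; a failure aborts
dependents and is recorded in the report, which carries a provenance block
(config hash excluding the output directory, seed, package version) and no
timestamps, so identical config + seed reproduces every artifact
byte-for-byte. Problem sizes in the acceptance script (100 000 reads, 300
transcripts, 5000 genes, 6 × 250 variants) match the generator defaults and
keep a full run in the low seconds.

## Acceptance quantities

`scripts/acceptance.py` writes, per quantity, the value and problem size:
published-cell arithmetic (concordance totals 1201/1197/684/59, retention
99.67%, overlaps 63.3%/55.9% — computed by the summarizer and overlap
operations from the printed inputs, never assigned) and synthetic-suite
measurements (GC mode bin, post-filter residual ratio, intronic read
percentage, 3′-bias scores, matched-pair first-merge percentage, fold-change
truth-recovery r, FF/FFPE fold-change r, filter rule agreement).
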