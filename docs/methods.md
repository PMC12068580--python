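# Methods

## The analysis model

The pipeline analyses mutation-accumulation (MA) lines of a heterozygous
diploid hybrid. The parental SNP map — positions where the two founder
genomes (S288c and YJM789 by convention) carry different alleles — is
the coordinate system; everything else is expressed as per-line states
at those markers. A marker in an MA line is HET, fixed to one parent
(S- or Y-homozygous), or missing. Only markers heterozygous in the
parent hybrid **and** genotyped in every line of an environment enter
the analysis; this is applied per environment, so different environments
may use slightly different marker sets.

### LOH tract calling

A tract is a maximal run of consecutive map SNPs all fixed to the same
parent. A heterozygous SNP terminates a run. Missing genotypes inside a
run neither break it nor count toward support — missingness is treated
as a technical dropout, but the ≥ `min_support` (default 3) requirement
counts observed fixed SNPs only. Tract extent defaults to the inner
bound (first to last supporting SNP), which is conservative and
reproducible; an optional midpoint-extension mode grows each end to the
midpoint between the boundary SNP and the nearest flanking heterozygous
SNP (clipped at chromosome ends) for users who prefer an unbiased
point estimate of the true breakpoint.

Tracts with identical (chromosome, start, end) in *every* line of an
environment are removed everywhere: independent events do not recur at
base-pair-identical coordinates, so such tracts are systematic
genotyping artifacts. The literal every-line rule is the default; a
stricter ≥ k-lines mode is available. Environments with a single line
are left untouched (the rule would degenerate to removing everything).

### Classification

* **Extent.** A tract is TERMINAL when a supporting-SNP boundary lies
  within 20 kb of either chromosome end, INTERSTITIAL otherwise.
  Tracts lying entirely inside the 20 kb window are TERMINAL: they
  reach the chromosome-end region, and the alternative (interstitial)
  would misrepresent events contiguous with the telomere.
* **Size.** Half-open, lower-inclusive bands: short [1 bp, 1 kb),
  medium [1 kb, 10 kb), long [10 kb, 100 kb), super-long ≥ 100 kb.
  Lower-inclusive was chosen so every size falls in exactly one band.
* **Mechanism.** Normalized allele coverage is the tract-mean
  allele-specific depth divided by the genome-wide mean total (S+Y)
  depth. Copy-neutral LOH yields ~1.0 for the retained allele and ~0
  for the lost one; a hemizygous deletion yields ~0.5 and ~0. A tract
  is DELETION when the retained allele is within [0.4, 0.6]
  (inclusive) and the lost allele ≤ 0.1; everything else with usable
  depth is RECOMBINATION; tracts with no depth at any supporting SNP
  are UNCLASSIFIED. Thresholds are inclusive at the boundaries.

### Small variants

The de-novo filter keeps a call iff it is biallelic, GQ ≥ 30, DP ≥ 40,
and its allelic ratio is ≤ 0.1 or ≥ 0.9 for homozygous calls or
strictly inside (0.4, 0.6) for heterozygous calls; shared calls —
present in the parent or at the same (chromosome, position, alt) in
another line — and calls overlapping repeat intervals are removed.
The homozygous arm is inclusive and the heterozygous arm strict,
matching the thresholds as written. Filters are evaluated in a fixed
order (quality → parent → other-line → repeat) so each rejection
carries a single reason; the kept/rejected partition is exhaustive and
order-independent. Indels pass the same GQ/DP/ratio gates as SNMs, as
no separate rule is defined for them.

Substitutions are strand-collapsed into six classes (two transitions,
four transversions); with equal class counts Ts/Tv = 2/4 = 0.5, the
bias-free null. The AT/GC bias defaults to the transition-class ratio
G:C>A:T / A:T>G:C; an alternative definition including transversions
(all GC-losing over all AT-losing classes) is a flag, since the label
"GC > AT / AT > GC" admits both readings. Mutation rates divide counts
by generations × 24.04 Mb (the diploid genome size, also used —
configurably — for % genome covered by LOH).

Structural-variant records are filtered at the record level: precise,
no strand bias, length ≥ 50 bp, read support ≥ 10, quality ≥ 30,
absent from the ancestor, and not coordinate-identical across all
lines. Support/quality/length thresholds are inclusive.

### Aneuploidy

Coverage is summed in 5 kb bins (final partial bin kept with its true
width). The candidate statistic is the per-chromosome median bin count
over the genome-wide median; medians make the statistic robust to
focal CNVs and to uniform depth rescaling. Thresholds 1.35× (gain) and
0.65× (loss) sit midway between the euploid expectation (1.0) and the
trisomy/monosomy expectations (1.5 / 0.5) with symmetric margin; they
are parameters, not estimates. Verification uses the mean S288c allele
fraction at the chromosome's heterozygous map SNPs, with ±0.07 windows
around 1/3 and 2/3 (gain) or 0 and 1 (loss). The window excludes the
euploid value 0.5 decisively at ≥ 10 informative SNPs and 100×
coverage. A chromosome already homozygotized by LOH keeps fraction 0/1
whether disomic or trisomic, so gains there are UNVERIFIABLE rather
than guessed. Sub-chromosomal (segmental) events are out of scope for
automatic classification.

### Statistics

Per-line continuous metrics are compared to the control environment by
a two-sided Wilcoxon rank-sum test — exact when both groups have ≤ 15
values and no ties, normal approximation with continuity correction
otherwise — with Bonferroni correction over the family of
environment-vs-control comparisons for one metric (6 comparisons in a
seven-environment design). Categorical compositions use Pearson
chi-square without continuity correction on the 2 × k table of
environment vs control counts. Significance stars follow the usual
0.05 / 0.01 / 0.001 / 0.0001 ladder; Bonferroni-adjusted p-values are
clipped at 1.

## The simulator

The simulator generates the study conditions the analysis assumes: a
16-chromosome, ~12.07 Mb diploid genome (standard *S. cerevisiae*
nuclear chromosome lengths and centromere midpoints), a heterozygous
marker map at 6.1 SNPs/kb with per-10 kb gamma-distributed density
multipliers (dispersion 0.3, mean 1) to emulate patchy local density,
lines of 1000 generations, and sequencing at 100×.

Events accrue as independent Poisson processes, `N ~ Poisson(rate ×
generations)` per line, applied in generation order to per-position
copy-number arrays (one per parental haplotype):

| event | default rate/gen | effect |
|---|---|---|
| interstitial LOH | 0.013 | copies transferred to kept haplotype over a log-normal tract (median 0.5 kb, σ = 1.5) |
| terminal LOH | 0.003 | same, from a uniform breakpoint to the chromosome end |
| deletion LOH | 0.007 | lost haplotype zeroed (total copy halves) |
| SNM | 3.75e-3 | logged with a substitution class drawn from the configured spectrum |
| small indel | 3.85e-4 | logged only |
| chromosome gain | 1.57e-4 | +1 copy of one homolog where it still has copies |
| chromosome loss | 2.9e-5 | −1 copy of one homolog |

The three LOH rates sum to 0.023/generation with ~69% copy-neutral
(recombination) events and interstitial events outnumbering terminal
ones, a wild-type control profile; SNM and indel rates are the
wild-type per-bp rates (1.56e-10 and 0.16e-10 per bp per generation)
scaled by the 24.04 Mb genome; gain/loss rates correspond to ~13
aneuploidies per 70 line-millennia at 11:2 gain:loss. The generative
tract-length distribution is a modelling choice — only observed tract
sizes are known empirically, so a log-normal with median 0.5 kb is used
and all parameters are config-exposed. Note that the event *injection*
rate and the *called* tract rate differ by detectability: with median
0.5 kb tracts at 6.1 SNPs/kb, roughly half of injected events span
fewer than 3 markers and are invisible to the caller by design.

Sequencing is modelled at the allele-count level: the total read count
at a SNP is `depth × copy/2` (deterministic), and the split between
parental alleles is binomial in the true allele copy ratio. Binned
coverage counts are Poisson with mean proportional to the bin's mean
copy number (`depth × copy/2 × width / 150`, i.e. ~150 bp reads).
Genotypes follow the copy state exactly (both alleles present → HET,
one → homozygous, none → missing), optionally masked at a configurable
missingness rate (default 0). The simulator does **not** model
read-level errors, mapping artifacts, GC bias, bottleneck population
dynamics, selection, or indel sequence content; passing recovery tests
therefore demonstrates correctness of the tract/aneuploidy logic under
the stated noise model, not robustness to alignment or caller error on
real reads.

Bottlenecks are not simulated cell-by-cell: each event fixes
immediately, which is the relevant limit when only the final
bottleneck genome is analysed.

### Ground truth and recovery scoring

Every injected event is logged. Because later events can overwrite
earlier ones (tract coalescence, splitting by an opposite-parent
event), raw events are not directly comparable to calls. The truth
resolver replays the event log alone — independently of the emitted
genotype row — through the same copy semantics at SNP resolution,
yielding the expected genotype vector and from it the expected tract
set. Two events separated by a marker-free gap coalesce at this
resolution, as no observable data could distinguish them. A call
matches a truth tract at reciprocal overlap ≥ 50% (configurable),
matched greedily best-overlap-first, one-to-one. Sensitivity is
computed over truth tracts spanning ≥ `min_support` markers
(detectable events); both sensitivity and precision are reported as
NaN when their denominator is empty. On noise-free genotypes recovery
is exact: sensitivity, precision 1.0 with zero boundary error.

## Numerical and interface choices

* Coordinates are 1-based inclusive everywhere (VCF convention); BED
  input is converted on read.
* VCF reading uses cyvcf2; interval queries use intervaltree; rank-sum
  and chi-square tests use scipy. The VCF writer emits plain
  VCF 4.2 text (GT:AD:DP:GQ) readable by the package's own reader and
  standard tools; GT round-trips losslessly.
* Multi-allelic VCF records are dropped (counted and logged), since
  the biallelic parental-marker model does not apply to them.
* Percent genome covered uses the 24.04 Mb diploid size by default,
  consistent with the mutation-rate denominator; it is a parameter.
* A coverage ratio of 0 (both homologs lost) is representable; the
  resulting call is UNVERIFIABLE rather than an error.
* Degenerate statistical inputs (groups of < 2 values, all-zero or
  single-category tables, no transversions, empty denominators) yield
  NaN with an "NA" label rather than exceptions.

## Problem sizes used in the test suite

End-to-end checks run at the study's scale: 100 simulated lines on the
full 12.07 Mb genome for detector recovery, ≥ 1000 injected tracts for
mechanism classification, 100 euploid + 50 aneuploid lines for
aneuploidy sensitivity/specificity, 10⁴ random genotype vectors against
the brute-force oracle, and 1000 null replicates for type-I error
control. Unit tests use two-chromosome genomes (0.2–0.5 Mb) for speed;
the algorithms are scale-free.

## Known limitations

* The recurrent-tract filter requires base-pair-identical coordinates;
  artifacts with slightly jittered boundaries would not be removed.
* Mechanism classification assumes the genome-wide mean depth is a
  valid euploid baseline; heavily aneuploid genomes would bias the
  normalized coverage.
* The gain model duplicates a homolog's current copies chromosome-wide;
  interactions between aneuploidy and prior partial-chromosome LOH are
  simplified (a gained homolog does not restore alleles lost earlier).
* Per-line generation counts default to the nominal 1000; per-line
  totals from bottleneck records can be supplied where known.
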