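# Methods

This note documents the models, statistics and numerical choices behind
`genectx`, what the synthetic-data generator does and does not emulate,
and the open design points that were decided while building the package.

## Coordinate model and track handling

All internal coordinates are 0-based, half-open; GFF3 (1-based,
inclusive) is converted on read and BED/bedGraph pass through. A single
convention everywhere removes the most common source of off-by-one
drift in interval arithmetic. Strands are `+`, `-` or unstranded
(`.` in files). A gene's TSS is its stranded 5′ end.

Coverage tracks are stored per chromosome as binned vectors
(`ceil(length / bin_size)` bins; the last bin may be truncated).
Rebinning uses the coverage-weighted mean — each source interval
distributes value × bases into the bins it touches and each bin divides
by its width — because the inputs are *coverage* tracks: the mean, not
the sum, is the quantity whose value should not depend on bin size.
Uncovered bases count as zero, so total signal (value × bases) is
conserved to machine precision; the test suite checks conservation to
one part in 10⁶ across bin sizes. The source experiments do not fix a
bin size, so it is configuration (default 50 bp for ChIP; nucleosome
tracks use 1 bp — see below).

## DE-set construction

A locus is called differentially expressed when three conditions hold
simultaneously: (i) fold change ≥ `min_fc` (default 1.5; down-calls use
the reciprocal), (ii) FDR ≤ `max_fdr` (default 0.05), and (iii) every
replicate of the *higher* condition exceeds an expression floor
(default 0, i.e. strictly nonzero). Condition (iii) reads "expression
observed in each biological replicate" as a per-replicate detectability
check on the condition driving the call; applying it to the lower
condition as well would veto genuine on/off switches, which is exactly
the class of loci the filter should keep. The floor is configurable for
data on other scales.

FDR adjustment is Benjamini–Hochberg step-up (via
`statsmodels.stats.multitest`), the standard "calculated false
discovery rate" of mainstream count-based DE frameworks; the test suite
verifies it against a brute-force step-up scan. The compound rule is
deliberately conservative under the null: a BH rejection at desk-scale
replicate counts requires an extreme t, but condition (i) additionally
demands a large effect, so the realised false-discovery proportion on
null data sits well below the nominal 5% (checked over 100 null
simulations).

Near-identical retrotransposon copies (the 13 Tf2 elements) cannot be
quantified individually from short reads, so their replicate counts are
summed into one record *before* testing; the merged fold change is the
ratio of summed condition means — recomputed, never averaged — and the
p-value is recomputed from the summed replicates, after which the whole
table's FDR must be re-adjusted (`recompute_statistics`). tRNAs are
excluded for paralogue cross-mapping, rRNAs for depletion artefacts.

The significance test bundled for synthetic replicate tables is a Welch
t-test on log2(x + 0.5). Dispersion-aware negative-binomial testing
belongs upstream of this package: it consumes statistics tables, it
does not produce them.

### Convergent genes and qPCR

A convergent pair is defined as two adjacent genes on opposite strands
whose 3′ ends face each other across an intergenic gap ≤ 1 kb
(configurable); the term is used loosely in the literature, so the
definition is explicit and the cap prevents distant opposite-strand
neighbours from counting. An antisense transcript maps to the
opposite-strand gene with the largest overlap.

qPCR relative quantification is 2^(−ΔΔCt) with the reference ΔCt taken
against the arithmetic mean Ct of the two reference genes (*act1*,
*tbp1*) — equivalent to normalising expression by the geometric mean of
the references, the standard multi-reference convention.

## Overlap and enrichment statistics

Gene-set overlap uses the exact upper-tail hypergeometric probability
P(X ≥ k) (enrichment only; depletion is not the question being asked).
Both sets are intersected with the declared universe first, so only
genes included in both analyses are compared. The universe is an
explicit required argument: whether it should be all annotated genes or
all genes passing expression filters depends on how the input lists
were built, and silently defaulting would invite mismatched universes.
Because the test is discrete, its p-values are superuniform under the
null; the calibration test therefore checks uniformity of the
randomized p-value P(X > k) + U·P(X = k), which is exact.

Domain enrichment is a 2×2 chi-squared contingency test (DE membership
× domain membership, df = 1) with the Yates continuity correction by
default (the correction is the reference implementation's default and
matters at the small in-domain counts typical here); a flag disables
it. Degenerate margins return statistic 0 with a warning flag, as does
any expected cell below 1. Positional domains: subtelomeres are the
100 kb from each end of the first two chromosomes (chromosome III ends
in rDNA arrays, not canonical subtelomeric heterochromatin); centromere
intervals are configuration, never computed. Domain membership is any
overlap — the simplest rule that can be stated exactly.

## Distance statistics

Tandem-repeat records are optionally merged (overlapping same-
chromosome records become one region, taking the motif length of the
highest-scoring constituent, ties to the shorter motif) and classed
short (motif < 7 bp) or long (≥ 7 bp). Merging is on by default because
downstream counts are about *regions*; both merging and the tie rule
are configurable.

Gene-to-feature distance is the interval-to-interval gap in bp, zero on
overlap. Gap distance (rather than midpoint or TSS anchoring) is the
common convention and makes "touching" well-defined; the monotonicity
property (adding a feature can only reduce distances) holds exactly.
Internally features are merged into disjoint sorted intervals, which
preserves minimal gaps and allows a binary-search lookup; a quadratic
all-pairs scan serves as the test oracle. Genes on chromosomes without
features are recorded as missing and excluded from summaries.

DE vs NDE distances are compared with the two-sided Mann–Whitney U
test: the distributions are long-tailed and the question is stochastic
ordering, so a rank test is the defensible default where no test is
prescribed. Distance–fold-change association is Spearman rank
correlation with midranks for ties.

## TSS metagene profiles

Anchored matrices extract ±(upstream, downstream) windows (default
−1000/+1500 bp) around each TSS at track resolution, reversing
minus-strand rows so downstream is always to the right; windows that
leave the chromosome are dropped and counted. Each replicate track is
first scaled to genome-wide mean 1 (sequencing depth is arbitrary), and
the mean profile averages over loci within a replicate, then equally
over replicates.

Profile metrics: the NDR is the minimum within [−spacing, +spacing/2]
of the anchor (spacing hint 165 bp, the canonical fission-yeast
repeat); +1 is the first local maximum downstream of the NDR, −1/−2 the
successive maxima upstream. Local maxima must dominate a half-spacing
neighbourhood, which suppresses bin-level noise bumps. NDR width is the
span around the minimum where the profile stays below the midpoint
between NDR depth and the mean of the −1/+1 amplitudes. Flat or
monotone profiles are an error, not a metric.

Genotype comparison uses the two-sample Kolmogorov–Smirnov test in one
of two modes. The default compares the distributions of *per-locus
mean signal* between genotypes: loci are the exchangeable sampling
units, so this is a genuine two-sample test and it is well powered
against localized occupancy changes. The alternative (`values` mode)
hands the two mean-profile value vectors to the KS test — the literal
result of giving two curve arrays to a stock implementation. It is kept
for comparability but documented as weak: depth normalisation turns a
one-sided occupancy gain into a nearly mean-preserving stretch of the
value distribution, which KS barely registers regardless of amplitude.

## ChIP ratio analysis

Each H3K9me2 track is normalised to its matched total-H3 track as
log2((K9 + pc)/(H3 + pc)) per bin, pseudocount 1 coverage unit —
enough to keep uncovered bins finite, negligible against real coverage
(~100 units in the synthetic data). Mutant log-ratios are then
normalised to the wild-type log-ratio *of the same biological
replicate* by subtraction; the double ratio cancels any per-sample
multiplicative scaling exactly as the pseudocount vanishes.

Enriched domains are called on the wild-type ratio with a robust
relative threshold, genome median + z·MAD (default z = 2) — a fixed
absolute cutoff would not transfer across normalisations. Threshold
exceedances shorter than a seed length (150 bp) are discarded *before*
gap merging (≤ 1 kb) and the final length filter (≥ 2 kb): a
median + z·MAD rule flags a fixed tail fraction of bins (~9% for z = 2
under Gaussian noise), and merging isolated single-bin exceedances
first would chain that noise into arbitrarily long pseudo-domains. With
the seed filter, null tracks yield no domains while planted multi-kb
blocks are recovered to within a bin.

Matched random control loci replicate a feature set's count, lengths
and chromosomes, placed uniformly while avoiding the features, a
declared exclusion set (the called enriched domains, so controls sample
euchromatic background) and each other, with bounded retries and full
determinism per seed. Anchored summaries use scaled-body geometry —
flanks (default 1 kb) in real base pairs, feature bodies rescaled to a
common column count (default 20) by linear interpolation — and the
centre-excess statistic is the mean ratio over feature bodies minus the
mean over control bodies.

## The synthetic-data generator

The generator is the package's test bed: a 3 Mb genome (three 1 Mb
chromosomes) whose feature densities track the real annotation scaled
by length — 500 disjoint stranded genes (lengths log-normal, median
~1.2 kb), 150 antisense transcripts mirroring random sense genes on the
opposite strand, 13 retrotransposon copies, 60 LTRs of 350 bp, ~400
tandem-repeat regions split ~1:5 short:long with motif lengths
straddling the 7 bp threshold, and 100 G4 motifs. All placement,
selection and noise derives from per-stage PCG64 streams spawned from
one seed; identical seeds give bit-identical bundles.

**Expression.** A planted fraction (default 0.1) of records is
upregulated. With a proximity effect (default scale 10 kb), DE records
are drawn without replacement with weights logistic in log-distance to
the target feature class (LTRs), producing the monotone DE-closer-
to-repeats shift without determinism; zero scale gives uniform
selection (the null). DE fold changes are log-normal with a planted
floor of 2.0; replicate noise is Gaussian on log2 signal with sd 0.25,
a realistic biological replicate spread for yeast RNA-seq, and makes
null t-test p-values exactly uniform. The generator records the
selected ids and the planted DE/NDE distance medians for recovery
checks.

**Nucleosome occupancy** is built at 1 bp resolution — required to
resolve 165 bp phasing — as baseline 1 plus, per gene, a strand-
oriented template: damped phased peaks
m·A·exp(−|u|/τ)·(1 − cos(πu/T))/2 (A = 1, τ = 700 bp, T = 165 bp,
u = position relative to the NDR centre at TSS − 60 bp) minus a
genotype-independent Gaussian NDR dip (depth 0.4, width 80 bp). The
genotype multiplier m scales the peak component only: the mutant
effect is an occupancy *gain at arrays*, and because sequencing
measures relative occupancy, each genotype's true signal is rescaled to
genome mean 1 — the gain at peaks is compensated in linkers and
survives analysis-side depth normalisation. Values give an NDR at
~0.6× and a +1 peak at ~1.7× genome mean, canonical for yeast
metagenes. Poisson resampling at depth 100 counts per occupancy unit
adds shot noise; depth 0 disables noise.

**ChIP.** H3 is flat base coverage (100 units) with log-normal noise
(sd 0.3 log2 per channel); H3K9me2 carries the same base plus planted
log2 enrichment: +2.0 inside the heterochromatin domain set (30 kb at
each end of chromosomes I and II plus one interior 20 kb block, in
*both* genotypes — wild-type enrichment is what defines the domains)
and +1.0 over LTR bodies in the mutant only. Two replicates per
genotype, paired for the double normalisation.

**What the generator does not emulate:** sequence content (no FASTQ,
no mappability structure), overdispersed count noise, co-location of
LTRs with subtelomeres, antisense-specific regulation, and replication-
timing or condition effects. Passing tests therefore demonstrate that
the *statistics recover planted structure at realistic noise levels*,
not that any biological conclusion transfers to real libraries.

## Pipeline, determinism, problem sizes

`run_bundle` executes stages in dependency order (DE sets feed overlap
and distance; tracks feed metagene and ChIP; the wild-type-defined
domains feed the domain-overlap test), logs one line per stage with
counts, aborts with the stage name on error, and emits a JSON report
that is byte-identical across reruns of the same seed and inputs. A
single config seed feeds all stochastic steps through derived
sub-seeds. Synthetic bundles can be written to disk in the same formats
the loaders read (GFF3/BED/TSV/bedGraph), so the on-disk path is
exercised by the same tests.

Calibration and recovery checks run at deliberately desk-scale problem
sizes chosen as part of the study design: 500 hypergeometric draws for
null uniformity, 100 null expression simulations for the realised FDP,
50 seeds for the ChIP centre-excess null and for proximity and
amplitude recovery, 30 for domain recovery, 40 full null pipeline runs
for the global α = 0.01 check. Under these conditions every planted
effect is recovered within its stated tolerance and no null stage
produces spurious significance beyond the nominal rate.

## Known limitations

- The hypergeometric and chi-squared tests are reported raw; no
  correction across the several context tests is applied (each is a
  separate question, reported as such).
- Domain calling assumes a unimodal background; a genome that is
  mostly heterochromatic would shift the median + MAD threshold.
- The metagene peak finder reports the first three peaks around the
  NDR only; it is not a nucleosome caller.
- `values`-mode KS p-values treat profile points as independent, which
  they are not; that mode is for descriptive comparability only.
- Control matching balances count, length and chromosome but not GC,
  gene density or replication timing, which real studies may need.
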