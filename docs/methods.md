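# Methods

This note documents the statistical model behind `halomut`, the choices
made where the design was genuinely open, and what the synthetic-data
validation does and does not demonstrate.

## Experimental design being modelled

A mutation-accumulation (MA) experiment propagates many lines from a
single progenitor colony through repeated single-colony bottlenecks.
With an effective population size of ~1 per transfer, selection is
powerless against all but strongly deleterious mutations, so mutations
accumulate neutrally and independently in each line.  After roughly a
thousand generations the surviving lines are whole-genome sequenced and
compared with each other to identify line-private changes.

The package targets halophilic archaea specifically in its defaults: a
~2.57 Mb genome in three replicons (a GC-rich main chromosome ~2 Mb at
~68 % GC and two mini-chromosomes of ~365 kb and ~191 kb at ~58–59 % GC,
overall ~66 % GC), 67 lines, ~1,267 generations per line, ~200× read
depth, ~96.8 % of sites callable, and per-class mutation rates around
10⁻¹⁰ per site per generation.  Nothing in the code is specific to these
values; they are defaults of the generator and worked examples.

## Generations from CFU counts

Cell divisions per transfer are estimated as *n* = log₂(CFU) from plating
counts of single colonies: a colony of *N* cells has undergone ~log₂ *N*
doublings from its single founder.  The package averages the
*per-observation* estimates (mean of log₂ CFU, not log of mean CFU),
because each plating is an independent estimate of the same growth
process and the quantity of interest is the mean number of doublings.  A
line's total generations is this mean times its transfer count.  Both an
experiment-wide mean (default) and per-line means are supported; the
experiment-wide mean matches how such experiments typically pool sparse
monthly CFU observations across lines.

CFU noise in the generator is multiplicative lognormal on the count
scale (`CFU = round(2^g · e^ε)`, ε ~ N(0, σ²)): plating counts are
positive and right-skewed, and a σ on the natural-log scale converts to
σ/ln 2 on the generations scale.

## Consensus calling

The caller never sees reads; its input is a per-line, per-site summary
of allele read counts (the contract with the upstream trimming/mapping
pipeline, which is out of scope).  Three rules, in order:

1. **Line consensus.**  At a site, a line's consensus allele is the
   majority allele if depth ≥ `min_depth` (default 10) and the majority
   fraction is ≥ `consensus_fraction` (default 0.99); otherwise NO_CALL.
   The ~1 % slack tolerates aberrant reads (sequencing error, index
   contamination, barcode degeneracy).  The fraction comparison carries a
   1e-9 relative guard so that exact boundary cases (198/200 = 0.99) are
   kept; a tied majority can never reach a fraction > 0.5 and so never
   passes.
2. **Ancestral inference.**  Because all lines descend from one colony,
   the progenitor allele at a site is taken to be the *unanimous*
   consensus of the non-focal lines, requiring at least `min_other_lines`
   (default 3) of them to be called.  Any disagreement leaves the site
   unresolved for that focal line.  Unanimity rather than majority is
   deliberate: a majority vote would silently absorb shared artifacts.
3. **Mutation calls and exclusions.**  A focal consensus differing from
   the resolved ancestral allele is a mutation.  If two or more lines
   share the same non-ancestral allele at a site, the site is excluded
   and logged: independent recurrence of the same change at one site is
   vanishingly unlikely at ~10⁻¹⁰ rates, so such sites indicate
   progenitor polymorphism or a mapping artifact.

**Callable sites.**  A site counts toward a line's callable-site total
when that line has a consensus call there *and* the ancestral allele is
resolved.  A consequence worth noting: at a genuinely mutated site, the
ancestral allele is unresolved for every *other* line (their non-focal
sets contain the mutated line), so each mutation removes one site from
the other lines' denominators — a negligible correction at realistic
mutation counts.  The aggregate "sites surveyed" headline is the per-line
mean; the intersection and union across lines are reported alongside,
since published tables rarely state which of the three they contain.

**Indels** are text-encoded at their VCF-style anchor base (`+SEQ`
insertion after the anchor, `-SEQ` deletion of the following bases) and
pass through the same depth/fraction thresholds applied to the
indel-supporting read count; no indel-specific thresholds are used.
Calls are emitted with anchored ref/alt alleles, so VCF output needs no
re-normalization.  Indels longer than 30 bp are outside the modelled
regime (structural variation is out of scope).

## Rate estimation

For *m* mutations over the site-generations denominator
*D* = Σ_lines callable_sites × total_generations:

- rate = *m*/*D*, per site per generation;
- per-genome rate = rate × genome size;
- exact 95 % CI = [½χ²₀.₀₂₅(2m), ½χ²₀.₉₇₅(2m+2)]/*D* (Garwood), with
  the m = 0 upper bound ½χ²₀.₉₇₅(2) = −ln 0.025 ≈ 3.689 events.  Exact
  intervals are conservative at small counts (true coverage ~0.98 at a
  mean of 5, approaching the nominal 0.95 as counts grow); the test
  suite checks coverage from below accordingly.
- two standard errors: the among-line SE (SD of per-line rates/√L),
  which captures overdispersion across lines and is the appropriate SE
  for a design with line-level heterogeneity, and the pooled-Poisson SE
  √m/D.  Both are reported when per-line counts are available.

**Conditional spectrum.**  Each of the six strand-collapsed
base-substitution classes gets a denominator restricted to the sites at
which it can occur: *D* × GC-fraction for G:C-origin classes, *D* ×
AT-fraction otherwise.  The genome-wide base composition is used for the
scaling when per-site composition of the callable set is unavailable;
at ~97 % callability the two differ negligibly.  The directional rates
are sums over the two classes in each direction; the GC- and
AT-conservative transversions (G:C→C:G, A:T→T:A) change composition in
neither direction and belong to neither union.  Equilibrium GC content is
µ(AT→GC)/(µ(AT→GC)+µ(GC→AT)); its SEM is computed by the delta method
over the two Poisson counts, with a bootstrap-over-lines alternative
available.  Ts/Tv is reported both count-based and rate-based (the two
agree exactly when GC-fraction = 0.5).

## Partition tests

- **Spectrum homogeneity**: Pearson χ² on the 2×6 class-count table,
  df = 5, no continuity correction.  Classes empty in both spectra
  contribute O = E = 0 and the df stays k−1; an entirely empty spectrum
  is an error.  Expected cells below 5 warn but do not fail.
- **Replicon partition**: observed per-replicon counts against
  expectations proportional to replicon lengths (or callable-site
  weights), Pearson χ², df = k−1, uncorrected — the uncorrected statistic
  is what published small-count replicon comparisons report.
- **Coding vs noncoding**: the 2×2 table
  [[m_coding, coding_sites−m_coding], [m_noncoding, …]] under a
  two-sided Fisher exact test (minimum-likelihood rule: sum of all
  tables with the observed margins no more probable than the observed
  one), alongside per-stratum rates with exact Poisson CIs.

Statistical routines are backed by `scipy.stats`; the test suite verifies
them against independent brute-force oracles (literal Σ(O−E)²/E sums and
full hypergeometric enumeration).

## Synthetic-data generator

What it emulates: i.i.d. genome composition at per-replicon GC targets;
per-line, per-class Poisson mutation counts with positions uniform over
class-eligible sites; indel lengths on 1–30 bp with a geometric-decay
default; Poisson(200) read depth; uniform sequencing error (each
non-contaminant read errs with probability `error_rate`, reporting one of
the three other bases uniformly); aberrant-read contamination in which a
contaminating read reports the *progenitor* base — the worst case for
the consensus-fraction rule, chosen deliberately to stress the exact
threshold; per-line random site omission at 1 − callability; and
lognormal CFU noise.  Mutations are injected as fixed line-consensus
alleles (the cell is treated as effectively haploid at fixation;
polyploid copy-number dynamics are not modelled).  Within-line double
hits are removed by rejection so the truth set stays unambiguous.

What it does not emulate: mapping bias and mapping-quality structure,
base-quality variation, GC-dependent coverage, clustered errors,
structural variants and mobile elements, reduced coverage across
deleted segments (a deletion is represented only at its anchor site),
and selection during the bottlenecks.  Passing end-to-end tests
therefore demonstrates the correctness of the calling/estimation logic
under the stated noise model, not robustness to alignment pathologies.

A deliberately sharp property of this model: with contamination at
exactly 1 % — the same magnitude as the consensus cutoff — a truly
mutated site shows an expected aberrant-read fraction of ~1.1 % (contamination
plus error) and passes the ≥ 99 % rule only ~half the time at 200×.
Detection of true mutations under these worst-case settings is therefore
~50 %, while precision remains 1.0 (errors can never push a wrong allele
to 99 %).  Precision and recall in the validation suite are accordingly
measured against truth records at *line-callable* sites (focal consensus
called and ancestral resolved), the standard convention for
callability-limited benchmarks; and the end-to-end rate-recovery check
documents that under these settings the estimated rate is biased low by
the detection fraction — an honest property of the threshold rule under
boundary-level contamination, visible in the test results, not hidden.
With contamination well below the cutoff (the realistic regime for
modern barcoded sequencing), detection approaches 1 and the bias
vanishes.

## Validation problem sizes

The end-to-end tests scale the genome, not the design: the caller
correctness run uses a 1 Mb genome, 20 lines, 500 generations at full
study noise; the 100-replicate parameter-recovery run uses the
three-replicon design scaled to ~150 kb (per-replicon GC preserved) with
67 lines, 1,267 generations, 200× depth, 10⁻³ error, 10⁻² contamination
and 96.8 % callability.  These sizes keep the full suite to a few
minutes while leaving every per-site computation identical to a
full-genome run.

## Numerical and degenerate-input conventions

Coordinates are 1-based inclusive everywhere internally (GFF3/VCF
convention); half-open conversions are confined to writers.  Non-ACGT
characters in input genomes are retained in sequences but excluded from
composition counts and callable-site denominators.  Equilibrium GC with
both directional rates zero, and Ts/Tv with zero transversions, are
reported as NaN (with a warning for the latter).  A zero mutation count
yields rate 0 with CI (0, 3.689/D).  Every pipeline stage logs its
in/out counts and the thresholds used at INFO level.
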