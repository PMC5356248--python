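# Methods

## Scope and data model

The pipeline consumes PennCNV `rawcnv` call files (one call per line:
interval, probe count, length, HMM state / copy number, sample id), a
case/control sample sheet with per-sample array QC metrics, and a UCSC
refGene-style transcript table. Copy number 2 is rejected at parse time:
a call is by definition a departure from the diploid state, and the
state classes are loss (copy number 0 or 1) and gain (3 or 4). The
`state` token is parsed but only `cn=` is authoritative; the optional
PennCNV confidence score is parsed and retained but used by no filter.

Coordinates: `rawcnv` files are treated as 1-based inclusive (so the
call length equals end − start + 1, consistent with the file's `length=`
token), UCSC transcript tables as 0-based half-open. Internally
everything is normalised to 0-based half-open, which makes the ≥ 1 bp
overlap predicate a plain `a.start < b.end and b.start < a.end` and
removes a whole class of off-by-one bugs; writers convert back to each
format's native convention. Chromosome names are matched by exact string
equality — no `chr` prefix harmonisation is attempted.

## Quality control

Sample-level exclusion criteria (any one suffices; an excluded sample
reports *all* criteria it failed):

| criterion | threshold | comparison |
|---|---|---|
| LRR standard deviation | 0.28 | strict (> fails) |
| BAF drift | 0.01 | strict |
| waviness factor | 0.04 | strict, on the absolute value |
| raw CNV call count | 70 | strict |

Call-level criteria: fewer than 5 probes (strict below), or length
≥ 1 Mb (inclusive at the bound). The mixed strict/inclusive convention
follows the criteria's standard phrasing ("< 5 probes", "≥ 1000 kb").

Ordering: sample filters run first, on *raw* per-sample call counts
(the sample sheet's `n_calls` column when present, else a recount of
the input calls); call filters then apply to calls of surviving
samples. Whether the call-count criterion should see pre- or
post-filter counts is genuinely ambiguous; raw counts were chosen
because the count criterion is an array-quality proxy, and an array's
quality does not improve by discarding its calls. Both filter stages
are idempotent and monotone in their thresholds.

## Gene regions and rarity

All transcripts of a gene symbol on one chromosome collapse to a single
interval from the minimum txStart to the maximum txEnd; a symbol
appearing on two chromosomes yields two intervals and a warning.
Regions are the gene intervals themselves — overlapping genes are *not*
merged into super-regions, so one call overlapping k genes contributes
one event to each of k regions. This keeps adjacent genes separately
testable, at the cost of correlated tests for co-located genes (which
is one reason the FDR correction must tolerate dependence, see below).

A region is *rare* when its cohort-wide count is below
ceiling(rare_fraction × N) with rare_fraction = 0.01; at N = 493 the
cut is 5, i.e. regions with ≥ 5 events are common. The count unit is
**events** by default; a `unit="carriers"` switch counts distinct
samples instead. The two differ only when one sample has two events in
one region, which the event-based default counts twice.

## Burden comparison

Every burden metric is per sample: call counts, genic-call counts,
distinct genes hit, and mean call size, each for all calls, deletions
and gains, plus rare-restricted variants of the gene-overlap counts.
Group comparison is a self-implemented Welch unequal-variance t-test
(two-sided, Welch–Satterthwaite df, 95% CI of the difference at that
df). The per-sample mean size — not the pooled per-call size — is the
unit of the size comparison, so every metric gives each sample exactly
one observation and sample independence justifies the t-test. Two
degenerate conventions: equal constant groups give t = 0, p = 1;
unequal constant groups give |t| = ∞, p = 0. Extremely small p-values
are reported in full scientific notation, never floored to a display
limit. Call size is always derived from coordinates; a `length=` token
disagreeing with them triggers a warning.

## Exact association statistics

Carriers are counted at sample level. By default (`mode="each_state"`)
each region emits one table per state class present, so a region with
both deletions and gains is tested twice; `mode="dominant_state"`
tests only the class with more events (ties resolve to loss). The
each-state default was chosen because reporting deletion and gain rows
separately for the same gene is the informative output; the dominant
mode exists for compatibility with the stricter "most numerous state"
reading.

*Fisher p*: the two-sided p is the total central hypergeometric mass of
tables (with the observed margins) whose probability is ≤ that of the
observed table, with relative tolerance 1e-7 on the tie comparison —
the convention shared by R and scipy. Computation is in log space
(`gammaln` + `logsumexp`), so large cohorts cannot overflow.

*Odds ratio*: the conditional MLE — the noncentral hypergeometric
parameter ψ for which E_ψ[X | margins] equals the observed first cell —
with CI limits inverting the one-sided exact tests at α/2 per side.
This convention (rather than the sample odds ratio ad/bc or a Wald
interval) was chosen because exact carrier tables can have zero cells,
where the conditional MLE degenerates gracefully: first cell at the
bottom of its support gives estimate 0 with lower limit 0, at the top
gives ∞ with a finite lower limit. Roots are found by Brent's method on
log ψ with an expanding bracket; agreement with an independent
reference implementation is ~1e-13 on random tables.

*Multiplicity*: Benjamini–Yekutieli step-up over **all** emitted tables
jointly (losses and gains pooled into one family); m is the number of
tables actually tested in the run, recorded in the manifest. BY was
retained over Benjamini–Hochberg because region tests are positively
and negatively correlated in unknown ways (shared calls across
overlapping genes), and BY controls FDR under arbitrary dependence. All
regions with at least one event are tested by default; a `min_events`
knob restricts testing to better-populated regions.

## Synthetic cohorts

The generator's defaults encode the cohort it emulates: 200 cases and
293 controls; control samples carry Poisson(12.4) deletions and
Poisson(8.5) gains per genome; cases have the deletion mean multiplied
by 1.5 and the gain mean by 0.9; 34% of calls are placed to overlap a
gene; call sizes are log-normal with log-mean 10.4 and log-sd 1.1
(median ≈ 33 kb, central 95% ≈ 4–280 kb, upper tail reaching ~1 Mb),
floored at 600 bp. Poisson counts and log-normal sizes are the simplest
laws consistent with the reported means and the 0.6–998 kb size range;
both are config parameters, not constants. Deletions are hemizygous
(cn = 1) with probability 0.9, else homozygous; gains are cn = 3 with
probability 0.9, else cn = 4. Probe counts follow a fixed density of
one probe per 4 kb with a floor of 3, so the < 5-probe QC filter
removes the small-call tail (~29% of calls at default sizes) naturally;
because this thinning is independent of group, burden *ratios* are
unaffected. The default genome is 8 chromosomes × 30 Mb with 500
non-overlapping genes — large enough that random gene overlap is
uncommon, small enough to simulate hundreds of cohorts per minute.

Spiked risk loci add, per carrier (drawn per group with the configured
carrier probabilities), one call spanning the whole gene plus a 1–10 kb
pad and at least 20 kb total — a recurrent CNV polymorphism that always
survives QC. Spiked genes are excluded from *background* genic
placement so the realised carrier sets match the configured
probabilities rather than being inflated by background hits; intergenic
background calls can still overlap a spiked gene by chance, but at the
default geometry this is a < 0.2% effect per sample.

A configurable fraction of samples receives QC metrics violating one
randomly chosen threshold (for the call-count criterion, the sample is
padded with extra calls past 70). The recorded truth contains the
*emitted* per-sample counts — background plus spiked plus padding — so
recounting the written rawcnv file reproduces the truth exactly.

Randomness: one root seed spawns a child generator per sample
(`numpy.random.SeedSequence.spawn`), so outputs are bit-identical for
identical configs and per-sample streams are stable under reordering.

What the simulator does **not** model: LRR/BAF signal noise and
call-boundary uncertainty, linkage disequilibrium and recurrent
breakpoint structure, population stratification, batch effects, and
size–genicity correlation. A green recovery test therefore establishes
that the *statistical machinery* is calibrated (type-I error, CI
coverage, enrichment recovery), not that the pipeline is robust to
array artefacts.

## Numerical and interface choices

- Rarity, association mode, rare fraction, α and all QC thresholds are
  run parameters surfaced in the CLI; summary ratios print at 1 dp,
  machine-readable TSVs keep full precision.
- Pipeline outputs contain no timestamps; the manifest records the tool
  version, a config hash, and entering/leaving counts per stage, so
  reruns on identical inputs are byte-identical and every excluded
  sample or call is accounted for exactly once.
- The CLI exits 0 on success, 1 on validation errors, 2 on runtime
  errors.

## Limitations

- Carrier-level association ignores event multiplicity within a region
  and CNV boundaries; two different deletions in one gene are the same
  carrier state.
- Rarity is frequency in *this* cohort, not population frequency; small
  cohorts call common polymorphisms rare.
- The Welch test on count data relies on cohort sizes in the hundreds;
  for very small cohorts a count model (Poisson/negative-binomial
  regression) would be preferable, and is out of scope here.
- No genome-build lift-over: calls, transcripts and gene lists must
  share one build and one symbol vocabulary.
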