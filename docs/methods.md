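# Methods

## Scope and genome abstraction

`tumortime` reconstructs the relative and calendar-time order of somatic
driver events in a tumor cohort from mutation read counts, allelic copy
number and purity. Variant calling, purity/ploidy estimation and copy
segmentation are upstream of the package: it consumes their output schema
(mutation TSV, SEG-style allelic copy table, metadata TSV).

The genome is modeled as 39 autosomal arms (acrocentric short arms
excluded) with fixed approximate physical lengths summing to ~2,800 Mb;
coordinates are arm-relative, 0-based half-open. Arm-level events are the
unit of copy-number analysis throughout, which is the resolution at which
recurrent gains/losses in squamous head-and-neck tumors are interpreted.

## Multiplicity and CCF annotation

For a mutation with alt/ref counts (a, r), purity p and local allelic
copy state (major, minor), the expected variant allele fraction at
multiplicity m and cancer-cell fraction c is

    VAF(m, c) = m c p / (2(1 − p) + p N),   N = major + minor.

The posterior over the grid m ∈ {1..max(major, minor)} × c ∈ {0, 0.01,
…, 1} combines a Binomial(a + r, VAF) likelihood with a prior that is
uniform over the grid plus a point mass on the c = 1 column holding half
the total prior weight (the *clonal spike*). The spike is not cosmetic:
the likelihood is a ridge in the product m·c, and under a flat prior the
broad (m = 2, c ≈ 0.5) branch of the ridge dominates the boundary-pinned
(m = 1, c = 1) peak whenever sampling noise pushes the observed VAF above
its clonal expectation. At purity 0.5–0.7 and depth ~120 this mislabels
the majority of clonal multiplicity-1 mutations as subclonal and destroys
downstream timing; with the spike, simulated truth is recovered (MAP
multiplicity correct for ≥ 95% of clonal mutations at depth ≥ 100).

Calls derived from the posterior:

- **clonal** iff P(c ≥ 0.85) ≥ 0.5; ties at exactly 0.5 are clonal. The
  threshold is configurable; 0.85 is a conventional choice, not an
  upstream-published constant.
- **MAP multiplicity**: for clonal mutations, the mode of P(m | c ≥ 0.85)
  — conditioning removes the same ridge degeneracy; for subclonal
  mutations, the marginal mode.
- **power**: P(detect) = P(Binomial(depth, VAF(m̂, 1)) ≥ 3). Sites with
  depth < 10 are unpowered and excluded from timing (they still enter
  MATH, which uses raw MAFs). Timing counts weight each mutation by
  1/P(detect), capped at 20, to undo detection bias at low VAF.

## Per-tumor timing on the π scale

Molecular time t ∈ [0, 1] indexes the clonal mutation accumulation of one
tumor (0 = first, 1 = last clonal event). On a segment whose final state
implies a duplication — d pre-gain copies duplicated, u left single, C
total copies after — a clonal mutation is *high-multiplicity* (m ≥ 2)
exactly when it arose on a to-be-duplicated copy before the gain. Under
constant accrual per copy, the expected high-multiplicity fraction among
informative mutations at gain time t is

    φ(t) = d t / ((d + u) t + C (1 − t)).

With power-weighted counts (n_hi, n_1), the posterior is Beta(n_hi + 1,
n_1 + 1) on φ, truncated to the attainable range [0, d/(d+u)] and mapped
through φ⁻¹ — represented as 2,048 deterministic mid-quantiles. The
truncation matters: without it the posterior carries an atom at t = 1 and
its mean disagrees with direct numerical integration of the likelihood by
up to 0.2 at small counts. With no informative mutations the posterior is
uniform (unpowered). Copy states map to (d, u, C) as: 2:1 → (1,1,3),
2:2 → (2,0,4), 2:0 → (1,0,2); higher states are approximated as a single
d-copy duplication.

Other event classes:

- **Whole-genome events**: arms matching the genome-wide profile (2:2 for
  a tetraploid/WGD call, 2:1 for triploid/WGT) pool their (n_hi, n_1)
  counts — the Beta posterior sharpens exactly as pooled counts grow. The
  2:1 transform is identical whether the arm reached 2:1 by a single gain
  or by doubling followed by loss of one copy, so WGT arms time the
  originating doubling. Arms whose individual posteriors disagree by more
  than 0.5 in mean raise a QC flag (e.g. one all-pre and one all-post
  arm).
- **Copy-neutral LOH (2:0)**: the loss is reported at the posterior of
  its duplication — an upper bound on the loss time. Plain losses (1:0)
  and homozygous deletions carry no multiplicity signal and get uniform
  π.
- **Driver SNVs**: multiplicity ≥ 2 on a gained segment → uniform on
  [0, t_gain], sampled jointly with the gain; multiplicity 1 → uniform on
  [t_gain, 1]; no informative copy context → uniform on [0, 1];
  subclonal → δ(π − 1).
- **HPV integration**: breakpoint read support is annotated exactly like
  an SNV and timed by the driver rules; APOBEC-context mutations are
  excluded from the local gain counts because they cluster at integration
  sites and would corrupt the local clock. When several sites are timed
  per participant, the one with the earliest real-time estimate is the
  representative.

Joint sampling: each tumor draws 1,000 aligned posterior samples; a
constrained event (pre-gain driver, cn-LOH loss) references the same gain
draw in every joint sample, so ordering constraints hold sample by
sample. π histograms use 100 uniform bins. The per-tumor π coordinate is
the latent molecular time itself (anchored at the first/last clonal
event by construction of t); an alternative normalization by clonal
mutation mass per Mb gives the same ranks and is not separately
implemented.

## League model

Per-tumor π posteriors of shared events are combined over 200 iterations.
Each iteration includes every tumor independently with probability 0.63
(binomial inclusion without replacement — the scheme behind an *average*
63% resample), draws one π per event per included carrier, averages
across carriers, and rescales so the earliest event of the iteration sits
at 0 and the latest at 1. Iterations with fewer than two events present
are discarded. The union of per-iteration scores is the event's
relative-timing trace; its median is the mRT. Randomness is streamed per
entity (one stream per event name, one for inclusions), so results are
invariant to input order at a fixed seed.

Cohort comparison runs the same iterations in both cohorts and differences
the per-iteration scores. One-way p is the fraction of the Δ-trace above
zero, with exact zeros counted half (a mid-p; without this, events that
anchor the rescaling in both cohorts would return a spurious p = 0);
two-way p = 1 − 2|0.5 − P_1way|; q values are Benjamini–Hochberg across
compared events (statsmodels implementation). Events below the prevalence
floor (default 3 carriers per cohort) are excluded.

Calibration: under the null, two-way p values are approximately uniform
in the well-powered regime (≳100 informative mutations per event-tumor;
verified by KS test over 200 simulated nulls). With weakly informed
per-tumor posteriors the Δ-trace width exceeds split-to-split
variability and the test becomes conservative (p values pile near 1) —
a safe failure direction, documented rather than corrected.

## Real-time conversion

Clonal CpG>T mutations (C>T at NCG trinucleotides, pyrimidine strand;
TCG C>T sites count as clock rather than APOBEC) accrue approximately
linearly with age. The per-tumor burden per megabase at risk weights each
mutation by 2m/N, normalizing to diploid-equivalent Mb-years: a
multiplicity-2 mutation on a 2:2 region counts once (it arose once,
pre-doubling), a multiplicity-1 mutation on four copies counts one half
(twice the copies were at risk). Under the generator's lineage-copy
accrual model this weighting is unbiased for every arm history used.

The cohort clock rate is a trimmed zero-intercept regression: per-tumor
slopes burden/age are ranked, the top and bottom 5% dropped, and the rate
is the least-squares zero-intercept slope of the retained tumors (the
IQR of retained slopes is reported). Zero intercept encodes burden 0 at
age 0. Below 20 tumors no trimming is applied (with a warning). The
cohort rate is used for every tumor by default; a per-tumor rate can be
passed instead.

An event with π posterior and tumor burden B converts to years before
diagnosis as years = (1 − π) B / r, truncated to [0, age]. For strict
clock purity the π posterior passed here should be computed from CpG>T
mutations only.

Whole-genome amplifications present as WGD (tetraploid) or, after
erosion, WGT (triploid). With a fixed annual conversion rate λ and a
never-converting fraction f, an event of age τ years shows WGT with
probability P(WGT | τ) = (1 − f)(1 − e^{−λτ}). The two parameters are
fitted by maximum likelihood (grid scan λ ∈ [10⁻⁴, 2] × f ∈ [0, 0.999]
refined by L-BFGS-B) with 95% profile-likelihood intervals. The MLE at
n ≈ 100 events is right-skewed in λ (λ and f trade off along a
likelihood ridge), so recovery experiments pool replicates into one joint
fit rather than averaging per-replicate estimates.

## Heterogeneity metrics

- MATH = 100 · 1.4826 · MAD(MAF) / median(MAF) on raw observed MAFs at
  depth ≥ 20, no purity correction; 1.4826 = 1/Φ⁻¹(0.75) makes the MAD of
  a normal equal its σ. Undefined (NaN) when the median MAF is 0.
- Ploidy fractions are length-weighted genome fractions at total copy
  2/3/4; the class cascade is: diploid fraction > 0.65 → diploid, else
  triploid fraction > 0.35 → triploid, else tetraploid.
- A whole-genome event is called when ≥ half of arms are amplified (total
  copy > 2 over ≥ 50% of arm length) or ≥ 4 arms are amplified on both
  alleles (both ≥ 2 over ≥ 50% of length); the label follows the ploidy
  class (triploid → WGT, tetraploid → WGD). An event call in a
  diploid-class tumor is labeled `none` and QC-flagged.
- FGA is the length fraction with either allelic copy deviating by more
  than 0.2 from baseline (1 per allele; 2 after a whole-genome event).
  Genomic segment length is the weight; allelic values may be
  purity-corrected reals.
- Pre/post-doubling MATH: the pre set is clonal multiplicity ≥ 2
  mutations on doubled regions, the post set the remaining clonal
  mutations; either score requires ≥ 10 qualifying mutations.
- Paired samples of one tumor merge by averaging MATH (and FGA, a
  documented extension); discordant classes are QC-flagged.

## Synthetic cohorts

The generator is the package's validation instrument: its defaults are
the study conditions, not tuning knobs.

Each tumor draws age ~ U(40, 80) years, purity ~ U(0.3, 0.9) and a
coverage mean of 120 reads. Clonal CpG>T mutations accrue at 0.37
mutations per CpG-megabase at risk per year over 30 covered CpG-Mb
(0.39 models HPV-positive-like cohorts); background clonal SNVs at 0.2
per Mb lifetime with 25% APOBEC context; an optional subclone carries
~30% extra mutations at CCF 0.35. Menu events (ten staggered arm events
and a whole-genome doubling, prevalences 0.4–0.85, mirroring the
early-loss → late-gain → late-doubling progression of HPV-negative
head-and-neck tumors) occur inside fixed molecular-time windows. Losses
present as copy-neutral LOH with probability 0.8, with the duplication
following the loss within 0.05 molecular time — which is what makes them
timeable and keeps the reported upper bound tight. A whole-genome
doubling at molecular time t (years before diagnosis τ = (1 − t)·age)
converts to a triploid WGT profile with annual rate 0.11 unless immune
(fraction 0.35).

Mutations are generated per arm from explicit lineage phases (time range,
copies at risk, final multiplicity), so multiplicity truth follows the
same accrual model the analysis inverts, and the 2m/N clock correction is
exactly unbiased. Read counts are Binomial(depth ~ Poisson(coverage),
VAF) with the purity-dilution VAF. Calendar truth uses years = (1 − t) ·
age, consistent with the zero-intercept clock.

What the generator does *not* emulate — and hence what passing recovery
tests do not establish for real data: sequencing artifacts and mapping
error, subclonal copy number, multi-gain arm histories, kataegis-style
local mutation clustering, purity estimation error (purity is passed
through exactly), and exome capture footprints (mutation density is
uniform per arm).

Focused simulators generate the calibration experiments directly:
per-tumor Poisson CpG>T counts for the clock regression; uniform-age
whole-genome events with exponential conversion for the conversion model;
and direct per-tumor π posteriors (Binomial counts around φ(t)) for
league-model calibration, bypassing read-level simulation where only the
ordering machinery is under test.

## Problem sizes and reproducibility

Default experiment sizes are desk-scale choices that keep every recovery
sharp: 400/100 tumors for the clock fits, 25 × 103 events for the
conversion model, 100 tumors × 10 events for ordering recovery (Kendall
τ ≥ 0.8 between true order and mRT ranking), 200 simulated nulls for
comparison calibration. Every random draw descends from a single seed via
`numpy` `SeedSequence` spawning; identical seeds give byte-identical
cohort files and pipeline outputs, and league results are invariant to
input order.

## Known limitations

- Losses without a subsequent duplication are untimeable and enter the
  league as uniform π, shrinking their mRT toward the middle; cohorts
  dominated by such losses will compress the recovered order.
- Arm states beyond a single duplication (e.g. 4:2, 3:1) are approximated
  by one effective duplication; multi-gain timing (two distinct gain
  times per arm) is out of scope.
- In whole-genome-amplified tumors, an independently gained arm that
  matches the genome-wide profile is absorbed into the whole-genome
  event's pool — a real identifiability limit, not an implementation
  shortcut.
- The comparison p values are conservative for weakly informed events
  (see League model).
- MATH is computed on raw MAFs, so cross-cohort MATH comparisons inherit
  purity differences, as in the underlying definition.
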