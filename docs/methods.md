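# Methods

This note documents the models, conventions and numerical choices behind
each stage of the pipeline, what the synthetic-data generators do and do not
emulate, and the known limitations.

## Cohort life tables

**Model.** A cohort of `n` individually-reared, parthenogenetic female
aphids is censused once per day from birth to death. Ages are integer days
with age 0 = day of birth. The observed schedules are

- `l_x` — fraction of the initial cohort alive at age `x` (so `l_0 = 1` and
  `l_x` is non-increasing);
- `m_x` — total offspring produced at age `x` divided by the number alive at
  age `x` (per-capita among survivors; defined as 0 when nobody is alive).
  This convention makes `R0 = Σ l_x m_x` equal exactly to mean lifetime
  offspring per *initial* individual, including those dying before
  reproduction;
- `s_xj` — fraction of the initial cohort alive **and** in stage `j`
  (N1…N4, Adult) at age `x`; `Σ_j s_xj = l_x` at every age.

**Day counting.** `death_age` is the last day alive; total longevity is
`death_age + 1` days. The nymph period is the adult-molt age; the adult
period is `death_age − adult_entry + 1` (the entry day counts as an adult
day). Nymph/adult periods average only over individuals that reached
adulthood; longevity averages over everyone.

**Euler–Lotka convention.** The intrinsic rate `r` solves
`Σ_x exp(−r (x+1)) l_x m_x = 1`. With ages indexed from 0, the exponent
`x+1` is the standard convention of the age-stage life-table software
ecosystem; because published work rarely prints the formula, the bare-`x`
alternative is available via `solve_intrinsic_rate(..., exponent_offset=0)`.
The left side is strictly decreasing in `r`, so bisection from the bracket
[−1, 2] day⁻¹ — doubled outward (at most 60 times) until the residual
changes sign — converges unconditionally. Tolerances: 1e−12 on `r`, with the
returned root verified to leave an equation residual below 1e−10. The
solver covers all biologically plausible rates; it refuses schedules with
zero total fecundity (`r` undefined) and fecundity values so extreme that
the root leaves double-precision range (~|r| > 700).

**Bootstrap.** `B` resamples of `n` individuals with replacement
(default `B = 10,000`; experiments in the tests and acceptance script use
`B = 200` with `n = 500`, which already stabilizes the SE of `r` to ~3
significant figures). Every parameter is recomputed per resample; the SE is
the standard deviation (ddof 1) over valid resamples. Point estimates come
from the original cohort, not the bootstrap mean (the bootstrap means are
also reported). Resamples with zero total offspring leave `r`, `λ` and `T`
undefined; they are dropped from those summaries and counted, rather than
raising, so SEs stay defined for high-mortality treatments. A single
`numpy.random.default_rng(seed)` generator drives the resampling, and the
seed is recorded in the output.

## EPG summaries and comparisons

Recordings are event lists of non-overlapping `(code, start_s, end_s)`
intervals within a nominal session of 18,000 s (5 h). Time ratios always
divide by the nominal length; incomplete annotation appears as an explicit
`unannotated` fraction and is never redistributed. Internally durations are
summed as exact rationals, so `Σ ratios + unannotated = 1` holds exactly.
The waveform vocabulary is closed to {np, C, E1, E2, F, G}; unknown codes
are rejected unless `allow_extra_codes` is set.

Pairwise comparisons default to Welch's unequal-variance t-test (Student's
variant behind `equal_var=True`) — a robust default where the original
analysis software's settings are unknowable. Multi-group comparisons use
one-way ANOVA with a Tukey HSD all-pairs post-hoc at α = 0.05, summarized
by an insert-and-absorb compact letter display; the post-hoc choice is ours
and documented rather than guessed from published figures. Waveforms with
zero variance everywhere are reported as undefined, not errors.

## Replicate-free differential expression

Each condition is a single pooled library, so the sampling model is Poisson
per gene. Conditional on observing `x` reads in library 1, the count in
library 2 follows a negative binomial,
`p(y|x) = C(x+y, y) (N2/N1)^y / (1 + N2/N1)^(x+y+1)`,
evaluated in log space through `scipy.stats.nbinom`. The one-sided tail
accumulates `p(k|x)` from `y` outward, away from the conditional
expectation `x·N2/N1`; the two-sided p doubles the smaller tail, capped
at 1. Exchange of `(x, N1)` with `(y, N2)` changes which index the tail
runs over, so the p-value is exchange-*equivariant* only approximately
(same order of magnitude, same calls in practice) — an intrinsic property
of this classical construction, covered by a dedicated test.

Normalization: TMM factors with the method's standard defaults — genes with
a zero in either library dropped, 30% trimmed from each tail of the M
(log-ratio) distribution and 5% from each tail of A (mean log-abundance),
precision weights from the delta-method binomial variance, factors rescaled
to geometric mean 1, reference sample chosen by the upper-quartile rule.
The implementation reproduces edgeR's `calcNormFactors(method="TMM")` to
5+ significant digits (cross-checked in the test suite). Fewer than 20
genes surviving the trim triggers a warning and an untrimmed fallback.

Calling: normalized abundance is CPM on effective (TMM-scaled) library
sizes; the expression ratio uses a 0.5 pseudocount on normalized CPM (an
RPKM-based ratio is available via `ratio_on="rpkm"`); the exact test runs
on raw counts with effective library sizes — one coherent normalization
path. Genes with zero counts in both samples are untestable and excluded
from testing and from the BH denominator. BH runs per contrast. A gene is
called up/down only when the ratio is ≥ 2 in that direction **and**
adjusted P < 0.001. The pseudocount affects ratios only, never p-values.

## GO enrichment

Per term with at least `min_count` (default 3) background genes, the 2×2
table (in-list / out-of-list × has-term / lacks-term) is tested by the
Pearson chi-square statistic `Σ (O−E)²/E` without continuity correction;
whenever **any** expected cell is below 5 the two-sided Fisher exact test
is used instead, computed as twice the smaller hypergeometric tail (capped
at 1). Tests are two-sided; the over/under direction is reported from `k`
versus the expected count `nK/N`. BH FDR runs across tested terms only.
Annotation propagation follows the true-path rule over `is_a` edges alone
(other OBO relations are ignored); term *level* is the shortest `is_a`
path to the namespace root (root = 0, its children = 1), with a
longest-path alternative behind a flag. Propagation is applied when an
ontology is supplied; whether published analyses propagated is usually
unknowable, so both behaviors are reachable.

## Synthetic-data generators

All generators are deterministic under their seed and emit ground truth
next to the data.

**Cohorts.** Four instar durations are drawn as `max(1, round(Gamma(shape,
scale)))`; each day alive survives to the next with a stage-dependent daily
probability (nymph vs adult); adult days produce Poisson offspring with a
triangular mean profile over adult age (peak `f_max`, center `peak_age`,
half-width `width`; an optional second peak reproduces double-peaked
fecundity curves seen on marginal hosts). Age is capped at 200 days. The
defaults (`n = 80`, instar Gamma(9, 0.21) ≈ 1.9 d each, nymph survival
0.99/day, adult survival 0.94/day, `f_max = 14`, peak 7 d after molt,
width 14 d) were chosen to mimic a thriving colony on a favorable host —
nymph period ≈ 7.5 d, adult period ≈ 17 d, longevity ≈ 24 d, R₀ ≈ 100,
r ≈ 0.38 day⁻¹. The truth schedules are computed by an exact dynamic
program over (stage, days-remaining) and (adult, adult-age) states that
mirrors the sampling scheme — not by averaging simulations — and `r_true`
is obtained by running the Euler–Lotka solver on those expected schedules.
The cohort estimator of `r` is a ratio estimator, so it carries O(1/n)
bias relative to `r_true`; at `n = 500` this is far below one bootstrap SE.

**EPG.** A Markov-renewal process over the six waveforms with log-normal
dwell times, truncated at 18,000 s; intervals tile the session, so ratios
sum to 1 by construction. The default transition matrix and dwells sketch a
successfully feeding aphid (short np, pathway C, long E2 bouts).

**Counts.** Gene-level mean proportions are log-normal (σ = 1.5 over 5,000
genes, libraries of 10⁷ reads — robustly detected genes, median count a
few hundred); counts are Poisson (the model the exact test assumes), with a
negative-binomial option for robustness experiments. A designated fraction
of genes (default 4% = 200) has its proportion multiplied by the fold
change (default 4, half up, half down) in sample B, without renormalizing —
the resulting composition shift is precisely what TMM corrects. Because the
test is exact but discrete, its null rejection rate at 0.05 is slightly
conservative (~0.045–0.049 at the default expression levels, approaching
0.05 as counts grow).

**Annotations.** Each of `n_terms` terms annotates every gene independently
with probability `genes_per_term / n_genes`; spiked terms raise that
probability among designated DE genes to the requested odds ratio.

**What the generators do not emulate:** overdispersion beyond Poisson in
the default counts (real pooled libraries carry biological variability the
replicate-free design cannot see), waveform autocorrelation structure
beyond first-order Markov, correlated GO terms (real ontologies induce
strong term-term dependence), and real stage-dependent fecundity-mortality
trade-offs. Passing tests therefore demonstrate correctness of the
*computations* under each method's own sampling assumptions, not robustness
of the methods on real data.

## Problem sizes used in tests and the acceptance script

Chosen as the smallest sizes at which each check is decisive: 1,000 random
schedules for the solver residual; 100 cohorts of `n = 500` with `B = 200`
bootstrap resamples for recovery coverage; all count pairs `x, y ≤ 50` at
library ratios {1, 2, 10} plus 10⁴ null gene pairs for the exact test;
100 random vectors for BH and all ~6.4 × 10⁵ tables with `N ≤ 60` for
Fisher; 5,000-gene DE runs; 50 annotation replicates for GO spike recovery.

## Known limitations

- Single-sex (parthenogenetic female) bookkeeping only; no male/female
  age-stage matrices, reproductive values or life expectancies beyond
  `s_xj`.
- The EPG stage consumes annotated waveform intervals; raw-voltage
  classification and potential-drop events are upstream of this package.
- The DE stage offers no replicate-aware (negative-binomial GLM) models —
  by design, since the target study design is one pooled library per
  condition.
- GO support is `is_a`-only; `part_of` and other relations are ignored
  with a warning.
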