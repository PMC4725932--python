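# aphidfit

Host-plant fitness analytics for aphids: when a piercing-sucking insect is
moved onto a new host plant, how well does it do? Studies of host-plant
specialization answer that with three complementary kinds of data, and this
package implements the complete computational pipeline for all three —
each stage exercisable on synthetic data with known ground truth:

1. **Cohort life tables** (`aphidfit.lifetable`) — individually-reared aphids
   censused daily from birth to death give the age-specific survival rate
   *l<sub>x</sub>*, age-specific fecundity *m<sub>x</sub>* and age-stage
   occupancy *s<sub>xj</sub>*, from which the population parameters follow:

   - net reproductive rate  *R₀ = Σ<sub>x</sub> l<sub>x</sub> m<sub>x</sub>*
   - intrinsic rate of increase *r* solving the Euler–Lotka equation
     *Σ<sub>x</sub> e<sup>−r(x+1)</sup> l<sub>x</sub> m<sub>x</sub> = 1*
     (iterative bisection)
   - finite rate of increase *λ = e<sup>r</sup>*
   - mean generation time *T = ln R₀ / r*

   Standard errors of every parameter come from bootstrap resampling of
   individuals.

2. **EPG feeding behavior** (`aphidfit.epg`) — electrical penetration graph
   recordings annotate a fixed 5 h session with waveforms np (non-probing),
   C (pathway), E1 (salivation), E2 (passive phloem ingestion), F (derailed
   stylet), G (xylem). The package computes per-waveform time ratios
   (time / 5 h), group mean ± SEM summaries, Welch t-tests or one-way ANOVA
   with Tukey-HSD compact letter displays, and the feeding-step attainment
   matrix (fraction of individuals reaching each waveform).

3. **Salivary-gland gene expression** (`aphidfit.de`, `aphidfit.enrich`) —
   each condition is one pooled RNA-seq library, so differential expression
   uses the exact Poisson-based Audic–Claverie test on raw counts with
   TMM-normalized effective library sizes, BH FDR, and the stringent call
   rule (ratio ≥ 2 **and** adjusted P < 0.001), plus direction-aware Venn
   partitions across contrasts and GO-term enrichment (chi-square with
   Fisher-exact fallback when any expected cell < 5, BH FDR, is_a
   propagation and ontology-level filtering).

`aphidfit.synthdata` generates realistic synthetic inputs for every stage —
stage-structured life histories, Markov-renewal EPG recordings, Poisson
pooled-library counts with a designated DE subset, spiked GO annotations —
with the ground truth emitted alongside, so estimator recovery is measurable.

## Worked example

```bash
python examples/life_table_demography.py
```

simulates an 80-aphid cohort on a favorable host and prints:

```
                                             synthetic
Net reproductive rate, R0 (offspring)      98.5 ± 7.60
Intrinsic rate of increase, r (day^-1)    0.37 ± 0.007
Finite rate of increase, lambda (day^-1)  1.45 ± 0.011
Mean generation time, T (day)              12.2 ± 0.26
Nymph period (day)                          7.6 ± 0.14
Adult period (day)                         18.2 ± 2.46
Total longevity (day)                      24.1 ± 2.37

generator truth: R0 = 102.3, r = 0.380 /day
```

Each cell is mean ± bootstrap SE over 2,000 resamples of the cohort. The
generator's analytic truth (R₀ = 102.3, r = 0.380 day⁻¹) sits within a few
SE of the cohort estimates, and λ always equals e<sup>r</sup> before
rounding. The other scripts in `examples/` walk through the EPG comparison,
the replicate-free DE calling (99% recall of 4-fold genes at zero false
calls on the default simulation), GO enrichment (three spiked terms
recovered as the top three), and an end-to-end pipeline run with a
checksummed manifest.

A thin umbrella CLI wraps the same API:

```bash
aphidfit simulate cohort --seed 3 --out sim/
aphidfit lifetable --input sim/cohort.tsv --bootstrap 10000 --seed 1 --out results/
aphidfit de --counts counts.tsv --contrast A:B --out results/
```

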