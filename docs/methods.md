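# Methods

This note documents the statistical models behind `invmix`, the defaults
they ship with, the design choices that were genuinely open, and what the
synthetic experiments in the test suite do and do not demonstrate.

## Data model

Microsatellite genotypes are stored as *allele multisets*: a hexaploid
individual contributes up to six allele calls per locus, with dosage
treated as unresolved (duplicated values in the input encode whatever
dosage the scoring produced, but no statistic depends on it). A fully
unscored cell is an explicit missing value and is excluded from every
denominator. This dosage-free representation is the only one that is
well-defined at arbitrary ploidy; it means `Ho` here is "share of
individuals carrying at least two distinct alleles", which is *not*
comparable to a dosage-aware heterozygosity and will differ from
diploid-convention software run on collapsed polyploid data.

Chloroplast alignments are reduced to characters before haplotype calling:
a run of gap columns sharing one gap pattern collapses to a single
fifth-state character, so a multi-base indel counts as one polymorphism.
Haplotypes are identity classes over the variable characters, labelled
`H1, H2, …` by decreasing global frequency (ties by first occurrence).
Pairwise haplotype distance is the number of differing variable
characters; π divides by the full alignment length.

## Clone filtering

Within each population, individuals are compared in input order and one
representative is kept per multilocus genotype; identity under missing
data requires at least one shared scored locus and equality on all shared
scored loci (a conservative rule: a sparsely scored individual that could
be a clone of an earlier one is treated as one). Clonal diversity is
distinct genotypes over sample size on the *pre-filter* matrix; the group
value is the mean over member populations, which is how the quantity is
conventionally reported. The filter is idempotent by construction.

## Diversity indices

Per locus and unit: `Ae = 1/Σp²`, `I = −Σ p ln p`, `He = 1 − Σp²`,
`Ho` as above, `F = 1 − Ho/He`. Values are averaged over loci;
monomorphic loci contribute `Ae = 1, I = 0, He = 0` but are excluded from
the `F` average (undefined at `He = 0`, logged). Group-level values pool
allele calls across member populations rather than averaging population
values, so a group can exceed every member in `Ae` when populations are
differentiated. Private alleles are those with nonzero count in a focal
unit and zero count in every reference unit.

## Gst/Nst and the permutation test

`HS` and `HT` use the small-sample haploid estimators (harmonic-mean
sample size ñ, S populations):

```
HS = ñ/(ñ−1) · mean_s (1 − Σ_i p_si²)
HT = 1 − Σ_i p̄_i² + HS/(ñS)
```

`Gst = (HT − HS)/HT`. `Nst` replaces the identity complement with the
haplotype distance matrix (`VS`, `VT` defined analogously); when all
pairwise distances are equal the two statistics coincide exactly, and the
test reports p = 1 with a warning rather than permuting a degenerate
matrix. Under these unbiased estimators `Gst` can dip slightly below zero
on undifferentiated data; that is estimator noise, not an error.

The test permutes haplotype identities on the distance matrix (the
frequency table is untouched, so `Gst` is invariant) and reports the
one-sided add-one-smoothed p-value `(b+1)/(m+1)` for `Nst − Gst` at least
as large as observed. Default 999 permutations. Calibration: over 500
synthetic datasets with no haplotype–geography association the rejection
rate at α = 0.05 is ≈ 0.056 (checked in the test suite at 199
permutations). Power depends heavily on the number of distinct haplotypes:
with ≤ 4 haplotypes the permutation space is so small that even perfect
block structure cannot reach p < 0.05.

## Source-contribution likelihood

The invasive allele counts enter a three-component mixture log-likelihood
(see README). Numerical choices:

- **Orphan alleles** — invasive alleles absent from all three sources make
  the likelihood identically zero. They are excluded from the sum and
  reported on the estimate (`excluded_alleles`); an optional pseudo-
  frequency ε re-admits them (default off, because it silently biases the
  weights). An allele whose only carrier has mixing weight 0 yields −∞ at
  that lattice point, which the search simply never selects.
- **Grid** — the simplex lattice includes the boundary (a or b equal to 0
  or 1); default step 0.01 matches the two-decimal resolution at which
  contributions are conventionally reported. Ties break toward smallest
  a, then smallest b, making the search deterministic. An optional single
  refinement pass re-scans at step/10 around the coarse optimum.
- **Concavity caveat** — the objective is concave, but near-flat ridges
  occur whenever two sources are nearly interchangeable for the observed
  counts; on a ridge the *coordinates* of the lattice argmax are not
  stable between grid resolutions even though the likelihood value is.
  Consistency checks therefore compare optima on the likelihood-ratio
  scale (a displacement accompanied by a lnP gain below 0.01 is a tie).

Parameter recovery: with 20 loci × 8 alleles at source divergence
F = 0.2 and 500 invasive individuals sampled directly from the mixture,
the grid search recovers a = 0.22 and b = 0.76 within ±0.05 in well over
90% of seeds (asserted over 100 seeds in the test suite; sources are
estimated from 300 accessions each so that source-frequency noise does
not dominate the measurement). Under a 61-founder bottleneck plus drift
the spread is substantially larger — that spread is a property of the
demography, not the estimator.

## ABC founder-size scan

`founder_composition(a, b, N)` rounds `a·2N` and `b·2N` half away from
zero and forces the remainder onto the third component (decrementing the
largest component if rounding overshoots), so the total is exactly `2N`.
Per replicate and locus, `k_s` multinomial draws from each source are
pooled and the drawn allele set is compared with the observed spectrum.

Match criteria: `exact-set` (per-locus presence sets identical everywhere)
and `tolerant(k)` (at most k allele mismatches, counted as symmetric
differences summed over loci). The matching frequency is matches/reps;
the optimal N is the argmax (ties toward smaller N), and a scan with zero
matches everywhere is flagged `no_signal` with guidance to loosen the
criterion.

Scale matters here. At study scale (≈ 9–20 loci × 8 alleles) the exact-set
matching probability peaks around 10⁻⁵ — resolvable only with billions of
replicates. The desk-scale default is therefore 10⁵ replicates with the
tolerant criterion for real scans (`tolerant(4)` in the shipped
experiments, ≈ 5% of a typical observed spectrum); exact-set remains the
default criterion of the API and is what the enumeration-oracle tests
check (empirical frequency within 3 Monte-Carlo standard errors of the
inclusion–exclusion probability on 1–2-locus cases).

A known limitation, measured rather than hidden: the argmax of the
matching-frequency curve is an intrinsically dispersed estimator of the
generating N. On the standard scenario the bell shape is reliable, but the
mode lands within one 10-unit grid step of the true N = 50 in only about
half of Monte-Carlo scans at 10⁴ replicates (and ~80% even for the exact
probability argmax). Single presence spectra at 8 alleles/locus simply
carry little information about N above ≈ 60, where the spectrum
saturates. Point estimates of N from one spectrum should be read as
order-of-magnitude statements.

## Shannon rarefaction and saturation fit

Individuals are drawn *without replacement* (so the proportion reaches
exactly 1 at the full group size) along the default size gradient 2, 5,
25, 50, 100, 200, 400 with 10 replicates per size; sizes exceeding the
group are skipped with a warning. The proportion is the locus-averaged
Shannon index of the draw over the full-group index. The default fitted
model is the half-saturation curve `x/(k+x)` (one interpretable
parameter; the size reaching 95% saturation is `19k`), with
`1 − exp(−λx)` as an alternative; the model id is recorded in the output.
By default the fit uses all replicate rows; `aggregate="mean"` fits
per-size means instead — on balanced designs the least-squares solutions
coincide, and both orderings are exposed because neither is canonical.
Constant proportions (a monomorphic or saturated design) are a fit error,
not a silent asymptote.

## Skyline growth rates

`r = ln(Nt/N0)/t` exactly. `fastest_growth_interval` scans every
contiguous window of at least two points (or a fixed window length),
normalising the series to chronological order first. For each window the
start is the window's leading point *or* a strictly lower immediate
predecessor — the minimum immediately preceding the growth phase — with
whichever gives the larger rate; the elapsed time runs from that start.
This makes the estimator exact on exponential series (every window returns
the true rate) while still anchoring N0 at a pre-growth dip when one
exists. Ties go to the earliest window; an all-flat series returns r = 0
with a warning.

## Synthetic-data generator

What it emulates: three source populations diverged from a common
ancestor by a Balding–Nichols draw (Dirichlet with concentration
(1−F)/F around ancestral frequencies, giving expected among-source
FST ≈ F, checked at F = 0.2); an admixed founding pool of `2N` allele
copies per locus; frequency-level Wright–Fisher drift (multinomial
resampling of 2N copies per generation); multinomial genotype sampling at
any ploidy; within-population clonal duplication at a set fraction; a
haplotype ladder panel (haplotype k differs from haplotype 1 at k−1 fixed
sites, so the true distance matrix is |i−j|) with multinomial assignment
per population; and flat-then-exponential skyline series. Defaults are
study-scale: 9 loci, 8 alleles per locus, F = 0.2, contributions
(0.22, 0.76, 0.02), 61 founders, eleven invasive demes of 50, 15% clonal
fraction, hexaploid calls. Every dataset carries a truth record
(parameters, composition, founder and final frequencies, seed) sufficient
to re-create it bit-exactly.

What it does not emulate — and hence what passing tests do not show about
field data: genotyping artefacts (null alleles, stutter, allele dropout),
microsatellite mutation (no IAM/SMM/TPM), selection, linkage, migration
between demes after founding, individual-based drift (drift acts on
frequencies at constant 2N), clone spatial structure, and recombination or
homoplasy in the chloroplast panel. Real data also violate the clean
"three known sources" premise whenever an unsampled source contributed.

## Problem sizes in the shipped experiments

The statistical experiments in the test suite run at sizes chosen to give
stable Monte-Carlo answers on a single CPU in minutes: 100 seeds for
mixture recovery, 200 random instances for likelihood exactness, 50 scans
at 10⁴ replicates for ABC self-consistency, 500 null simulations at 199
permutations for test calibration, and 50 seeds for the clone-filter
check. The acceptance script runs one full pipeline pass at the default
study-scale scenario.
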