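# invmix

Population-genetics inference for clonal, polyploid plant invasions.

`invmix` implements the analysis chain used to reconstruct the colonization
history of an invasive hexaploid cordgrass from codominant microsatellite
genotypes and chloroplast haplotypes: clonal filtering and dosage-free
diversity statistics, a maximum-likelihood estimate of how much each of
three native source populations contributed to the invasive gene pool, an
approximate-Bayesian-computation (ABC) scan for the effective number of
founding individuals, a Gst/Nst permutation test for phylogeographic
structure, a Shannon-index rarefaction analysis, and exponential growth
rates on Bayesian-skyline output. A synthetic-data generator reproduces the
statistical structure of such a study (diverged sources, admixed founding,
drift, clonal duplication), so every stage is testable without restricted
field data.

It is written for population geneticists working on invasion biology and
clonal plants, where individuals are polyploid (allele dosage unresolved),
sampling is clone-contaminated, and the colonization scenario — *which*
sources, *how many* founders — is the scientific question.

## The models

**Source contributions.** With three candidate source populations and
pooled invasive allele counts, the invasive gene pool is modelled as a
mixture with weights (a, b, c = 1 − a − b):

```
ln P(a, b) = Σ_i Σ_j  n_ij · ln[ a·f_ij,1 + b·f_ij,2 + (1 − a − b)·f_ij,3 ]
```

where `f_ij,s` is the frequency of allele *j* at locus *i* in source *s*
and `n_ij` the invasive count of that allele. The objective is concave, and
is maximized by a grid search over the simplex (default step 0.01).

**Founder sample size.** A founding event of *N* individuals draws
`a·2N`, `b·2N` and `(1 − a − b)·2N` allele copies per locus from the three
sources (conventional diploid counting). The per-locus allele *presence*
spectrum of such a draw is compared with the observed invasive spectrum;
the matching frequency over Monte-Carlo replicates, scanned over *N*,
rises while small samples still miss observed alleles and falls once large
samples import source alleles the invaders lack — a bell-shaped curve
whose mode estimates the founding sample size.

**Diversity and structure.** Dosage-free per-locus indices
(`Ae = 1/Σp²`, `I = −Σ p ln p`, `He = 1 − Σp²`, `Ho` = share of individuals
with ≥ 2 distinct alleles, `F = 1 − Ho/He`), clonal diversity
(distinct multilocus genotypes / sample size), private alleles, haplotype
diversity `Hd` and nucleotide diversity π, and the Nei–Chesser/Pons–Petit
`HS`/`HT`/`Gst`/`Nst` estimators with a one-sided permutation test of
`Nst > Gst` (phylogeographic structure). Growth rates on skyline series use
`r = ln(Nt/N0)/t`.

## Worked example

```python
from invmix import (simulate_sources, simulate_invasion, deduplicate_clones,
                    allele_frequencies, grid_search)
from invmix.synthetic_data import InvasionScenario

model = simulate_sources(n_loci=9, alleles_per_locus=8, divergence=0.2, seed=42)
scenario = InvasionScenario(a=0.22, b=0.76, n_founders=61,
                            n_generations=5, clonal_fraction=0.15, seed=42)
matrix, truth = simulate_invasion(model, scenario)
print(f"simulated {len(matrix.individuals)} individuals, "
      f"{len(matrix.loci)} loci, {len(matrix.populations)} populations")

clones = deduplicate_clones(matrix)
print(f"clone filter removed {clones.removed} accessions; "
      f"invasive-group clonal diversity = "
      f"{clones.group_clonal_diversity['introduced']:.2f}")

pops = allele_frequencies(clones.filtered, "population")
groups = allele_frequencies(clones.filtered, "group")
est = grid_search(pops, groups, ["SRC1", "SRC2", "SRC3"], "introduced",
                  step=0.01)
print(f"estimated contributions: a = {est.a:.2f}, b = {est.b:.2f}, "
      f"c = {est.c:.2f}  (truth: 0.22, 0.76, 0.02)")
```

prints

```
simulated 700 individuals, 9 loci, 14 populations
clone filter removed 88 accessions; invasive-group clonal diversity = 0.84
estimated contributions: a = 0.18, b = 0.78, c = 0.04  (truth: 0.22, 0.76, 0.02)
```

The simulated invasion seeds eleven demes from 61 founders drawn from three
diverged sources at proportions (0.22, 0.76, 0.02), drifts five
generations, and duplicates 15% of sampled individuals as clones. The clone
filter removes the duplicates (clonal diversity 0.84 ≈ 1 − 0.15), and the
grid search recovers the generating contributions to within the noise a
61-founder bottleneck plus drift leaves in the data.

The same steps are available from a shell:

```sh
invmix simulate --out demo/ --seed 42
invmix stats --genotypes demo/genotypes.tsv
invmix contribute --genotypes demo/genotypes.tsv --sources SRC1,SRC2,SRC3
invmix abc --genotypes demo/genotypes.tsv --sources SRC1,SRC2,SRC3 \
    --a 0.22 --b 0.76 --n-grid 10:150:10 --criterion "tolerant(4)"
invmix haplo --fasta demo/alignment.fa --perm 999 --seed 7
invmix rarefy --genotypes demo/genotypes.tsv --group source
invmix growth --skyline demo/skyline.tsv
```

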