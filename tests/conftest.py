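import numpy as np
import pytest

from invmix import GenotypeMatrix, allele_frequencies, simulate_sources
from invmix.synthetic_data import InvasionScenario


def make_matrix(cells, ploidy=6, groups=None):
    """Build a GenotypeMatrix from {(ind, pop): {locus: alleles}}."""
    individuals, population, calls = [], {}, {}
    loci = []
    for (ind, pop), locus_calls in cells.items():
        individuals.append(ind)
        population[ind] = pop
        for locus, alleles in locus_calls.items():
            if locus not in loci:
                loci.append(locus)
            calls[(ind, locus)] = tuple(sorted(alleles))
    for ind in individuals:
        for locus in loci:
            calls.setdefault((ind, locus), ())
    group = groups or {p: "ungrouped" for p in set(population.values())}
    return GenotypeMatrix(individuals, population, group, loci, calls, ploidy)


@pytest.fixture
def toy_matrix():
    return make_matrix(
        {
            ("i1", "P1"): {"L1": (100, 100, 102), "L2": (200, 202)},
            ("i2", "P1"): {"L1": (100, 102, 102), "L2": (200, 200)},
            ("i3", "P2"): {"L1": (102, 102, 102), "L2": (202, 202)},
        },
        ploidy=3,
    )


@pytest.fixture
def source_model():
    return simulate_sources(n_loci=9, alleles_per_locus=8, divergence=0.2, seed=11)


@pytest.fixture
def default_scenario():
    return InvasionScenario(seed=11)


def random_matrix(rng, n_ind=12, n_loci=3, n_pops=2, ploidy=4, n_alleles=5,
                  missing_rate=0.0):
    cells = {}
    for i in range(n_ind):
        pop = f"P{i % n_pops + 1}"
        locus_calls = {}
        for l in range(n_loci):
            if missing_rate and rng.random() < missing_rate:
                continue
            k = int(rng.integers(1, ploidy + 1))
            locus_calls[f"L{l + 1}"] = tuple(
                sorted(int(a) for a in rng.integers(100, 100 + n_alleles, size=k))
            )
        cells[(f"i{i + 1}", pop)] = locus_calls
    return make_matrix(cells, ploidy=ploidy)


def pooled_tables(matrix):
    """(population-level table, group-level table) convenience pair."""
    return allele_frequencies(matrix, "population"), allele_frequencies(matrix, "group")
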