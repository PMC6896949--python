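"""Synthetic data with the statistical structure the analysis assumes.

The generator emulates the study design end to end: three source
populations diverged from a common ancestor (Balding–Nichols style, with a
divergence parameter F controlling the expected among-source FST), an
admixed founding event drawing allele copies from the sources in
proportions (a, b, 1 − a − b), Wright–Fisher drift of the founder allele
frequencies, expansion into multiple invasive demes, clonal duplication of
sampled genotypes, and a small chloroplast haplotype panel with a known
pairwise distance matrix.  Every generated dataset carries a truth record
(parameters + seed) sufficient to re-create it bit-exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .founder_abc import founder_composition
from .genio import GenotypeMatrix, HaplotypeAlignment, SkylineSeries, build_alignment

logger = logging.getLogger("invmix")

# Default study-scale conditions: nine microsatellite loci (as genotyped in
# the study system), moderately divergent sources, hexaploid calls.
DEFAULT_N_LOCI = 9
DEFAULT_ALLELES_PER_LOCUS = 8
DEFAULT_DIVERGENCE = 0.2
DEFAULT_PLOIDY = 6


@dataclass
class SourceModel:
    """Three diverged source populations' per-locus allele frequencies."""

    n_loci: int
    alleles_per_locus: int
    divergence: float
    ancestral_freqs: list[np.ndarray]
    source_freqs: list[list[np.ndarray]]   # [source][locus]
    seed: int | None = None

    def __post_init__(self) -> None:
        for vec in self.ancestral_freqs:
            _check_probs(vec)
        for src in self.source_freqs:
            for vec in src:
                _check_probs(vec)

    @property
    def n_sources(self) -> int:
        return len(self.source_freqs)


def _check_probs(vec: np.ndarray) -> None:
    if np.any(vec < 0) or abs(float(vec.sum()) - 1.0) > 1e-9:
        raise ValueError("frequency vector must be nonnegative and sum to 1")


@dataclass
class InvasionScenario:
    """Demographic knobs of a simulated invasion."""

    a: float = 0.22
    b: float = 0.76
    n_founders: int = 61
    n_generations: int = 5
    deme_sizes: Sequence[int] = (50,) * 11
    clonal_fraction: float = 0.15
    ploidy: int = DEFAULT_PLOIDY
    seed: int = 0

    def __post_init__(self) -> None:
        if self.a < 0 or self.b < 0 or self.a + self.b > 1 + 1e-12:
            raise ValueError("(a, b) must satisfy a, b >= 0 and a + b <= 1")
        if any(d < 1 for d in self.deme_sizes):
            raise ValueError("deme sizes must all be >= 1")
        if not 0 <= self.clonal_fraction < 1:
            raise ValueError("clonal_fraction must lie in [0, 1)")


def simulate_sources(
    n_loci: int = DEFAULT_N_LOCI,
    alleles_per_locus: int = DEFAULT_ALLELES_PER_LOCUS,
    divergence: float = DEFAULT_DIVERGENCE,
    seed: int | None = None,
    n_sources: int = 3,
) -> SourceModel:
    """Draw each source's per-locus frequencies from a Dirichlet centred on
    a shared ancestral vector with concentration (1 − F)/F, so the expected
    among-source FST is about F."""
    if not 0.0 < divergence < 1.0:
        raise ValueError("divergence F must lie in (0, 1)")
    if alleles_per_locus < 2:
        raise ValueError("need at least 2 alleles per locus")
    rng = np.random.default_rng(seed)
    conc = (1.0 - divergence) / divergence
    ancestral = [
        rng.dirichlet(np.ones(alleles_per_locus)) for _ in range(n_loci)
    ]
    sources = [
        [rng.dirichlet(conc * anc) for anc in ancestral] for _ in range(n_sources)
    ]
    return SourceModel(
        n_loci=n_loci,
        alleles_per_locus=alleles_per_locus,
        divergence=divergence,
        ancestral_freqs=ancestral,
        source_freqs=sources,
        seed=seed,
    )


def _alleles_for(locus_idx: int, k: int) -> list[int]:
    """Integer allele labels for a simulated locus (disjoint label blocks
    per locus, microsatellite-fragment style)."""
    base = 100 + 10 * k * locus_idx
    return [base + 2 * j for j in range(k)]


def sample_population(
    freqs: Sequence[np.ndarray],
    n_individuals: int,
    ploidy: int = DEFAULT_PLOIDY,
    seed: int | np.random.Generator | None = None,
    pop: str = "P1",
    group: str = "ungrouped",
    loci: Sequence[str] | None = None,
    prefix: str | None = None,
) -> GenotypeMatrix:
    """Sample genotypes: each cell is ``ploidy`` independent draws from the
    locus's allele-frequency vector (the allele multiset is retained)."""
    if n_individuals <= 0:
        raise ValueError("n_individuals must be positive")
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    loci = list(loci) if loci is not None else [
        f"L{i + 1:02d}" for i in range(len(freqs))
    ]
    prefix = prefix if prefix is not None else pop
    individuals = [f"{prefix}_{i + 1:04d}" for i in range(n_individuals)]
    calls: dict[tuple[str, str], tuple[int, ...]] = {}
    for li, (locus, p) in enumerate(zip(loci, freqs)):
        _check_probs(np.asarray(p))
        labels = _alleles_for(li, len(p))
        draws = rng.choice(len(p), size=(n_individuals, ploidy), p=p)
        for ii, ind in enumerate(individuals):
            calls[(ind, locus)] = tuple(sorted(labels[j] for j in draws[ii]))
    return GenotypeMatrix(
        individuals=individuals,
        population={i: pop for i in individuals},
        group={pop: group},
        loci=loci,
        calls=calls,
        ploidy=ploidy,
    )


def _merge(matrices: Sequence[GenotypeMatrix]) -> GenotypeMatrix:
    first = matrices[0]
    individuals: list[str] = []
    population: dict[str, str] = {}
    group: dict[str, str] = {}
    calls: dict[tuple[str, str], tuple[int, ...]] = {}
    for m in matrices:
        if m.loci != first.loci or m.ploidy != first.ploidy:
            raise ValueError("cannot merge matrices with different loci or ploidy")
        individuals.extend(m.individuals)
        population.update(m.population)
        group.update(m.group)
        calls.update(m.calls)
    return GenotypeMatrix(individuals, population, group, first.loci, calls, first.ploidy)


def wright_fisher_drift(
    freqs: np.ndarray,
    pop_size_2n: int,
    n_generations: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Frequency-level Wright–Fisher: multinomial resampling of 2N allele
    copies per generation."""
    p = np.asarray(freqs, dtype=float)
    for _ in range(n_generations):
        counts = rng.multinomial(pop_size_2n, p)
        p = counts / pop_size_2n
    return p


@dataclass
class InvasionTruth:
    """Ground truth of one simulated invasion, for recovery tests."""

    a: float
    b: float
    n_founders: int
    composition: tuple[int, int, int]
    n_generations: int
    seed: int
    source_freqs: list[list[np.ndarray]]
    founder_freqs: list[np.ndarray]
    final_freqs: list[np.ndarray]
    founder_spectrum: dict[str, frozenset] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "a": self.a, "b": self.b, "N_founders": self.n_founders,
            "composition": list(self.composition),
            "n_generations": self.n_generations, "seed": self.seed,
            "founder_freqs": [list(map(float, v)) for v in self.founder_freqs],
            "final_freqs": [list(map(float, v)) for v in self.final_freqs],
        }
        return json.dumps(payload, indent=2)


def simulate_invasion(
    model: SourceModel,
    scenario: InvasionScenario,
    source_sample_size: int = 50,
) -> tuple[GenotypeMatrix, InvasionTruth]:
    """Simulate the whole design and return the combined genotype matrix
    (sources + invasive demes) plus the truth record.

    Per locus the founder allele pool takes round(a·2N) copies from source
    1, round(b·2N) from source 2 and the remainder from source 3; founder
    frequencies then drift ``n_generations`` by Wright–Fisher resampling at
    size 2N, and every invasive deme is sampled from the final frequencies.
    """
    rng = np.random.default_rng(scenario.seed)
    comp = founder_composition(scenario.a, scenario.b, scenario.n_founders)
    total = 2 * scenario.n_founders

    loci = [f"L{i + 1:02d}" for i in range(model.n_loci)]
    founder_freqs: list[np.ndarray] = []
    founder_spectrum: dict[str, frozenset] = {}
    for li in range(model.n_loci):
        counts = np.zeros(model.alleles_per_locus, dtype=np.int64)
        for s, k in enumerate(comp):
            if k > 0:
                counts += rng.multinomial(k, model.source_freqs[s][li])
        founder_freqs.append(counts / total)
        labels = _alleles_for(li, model.alleles_per_locus)
        founder_spectrum[loci[li]] = frozenset(
            lab for lab, c in zip(labels, counts) if c > 0
        )
    final_freqs = [
        wright_fisher_drift(f, total, scenario.n_generations, rng)
        for f in founder_freqs
    ]

    parts: list[GenotypeMatrix] = []
    for s in range(model.n_sources):
        parts.append(
            sample_population(
                model.source_freqs[s], source_sample_size, scenario.ploidy,
                seed=rng, pop=f"SRC{s + 1}", group="source", loci=loci,
            )
        )
    for d, size in enumerate(scenario.deme_sizes):
        parts.append(
            sample_population(
                final_freqs, size, scenario.ploidy,
                seed=rng, pop=f"INV{d + 1:02d}", group="introduced", loci=loci,
            )
        )
    matrix = _merge(parts)
    if scenario.clonal_fraction > 0:
        matrix = inject_clones(
            matrix, scenario.clonal_fraction, seed=rng,
            populations=[f"INV{d + 1:02d}" for d in range(len(scenario.deme_sizes))],
        )
    truth = InvasionTruth(
        a=scenario.a, b=scenario.b, n_founders=scenario.n_founders,
        composition=comp, n_generations=scenario.n_generations,
        seed=scenario.seed, source_freqs=model.source_freqs,
        founder_freqs=founder_freqs, final_freqs=final_freqs,
        founder_spectrum=founder_spectrum,
    )
    return matrix, truth


def inject_clones(
    matrix: GenotypeMatrix,
    clonal_fraction: float,
    seed: int | np.random.Generator | None = None,
    populations: Sequence[str] | None = None,
) -> GenotypeMatrix:
    """Replace a fraction of each population's individuals with exact copies
    of other same-population individuals, emulating clonal (rhizome)
    spread; expected clonal diversity is about 1 − clonal_fraction."""
    if not 0 <= clonal_fraction < 1:
        raise ValueError("clonal_fraction must lie in [0, 1)")
    if clonal_fraction == 0:
        return matrix
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    targets = set(populations) if populations is not None else set(matrix.populations)
    calls = dict(matrix.calls)
    for pop in matrix.populations:
        if pop not in targets:
            continue
        members = matrix.individuals_of(pop)
        if len(members) < 2:
            if clonal_fraction > 0:
                logger.warning("population %s has one individual; skipped", pop)
            continue
        n_clone = int(round(clonal_fraction * len(members)))
        n_clone = min(n_clone, len(members) - 1)
        if n_clone == 0:
            continue
        clones = rng.choice(len(members), size=n_clone, replace=False)
        clone_set = set(int(c) for c in clones)
        donors = [m for i, m in enumerate(members) if i not in clone_set]
        for c in clone_set:
            donor = donors[int(rng.integers(len(donors)))]
            for locus in matrix.loci:
                calls[(members[c], locus)] = matrix.calls[(donor, locus)]
    return GenotypeMatrix(
        individuals=list(matrix.individuals),
        population=dict(matrix.population),
        group=dict(matrix.group),
        loci=list(matrix.loci),
        calls=calls,
        ploidy=matrix.ploidy,
    )


def simulate_haplotypes(
    pop_haplotype_freqs: Mapping[str, Sequence[float]],
    n_haplotypes: int,
    seq_length: int = 500,
    seed: int | None = None,
    n_per_pop: int | Mapping[str, int] = 20,
) -> tuple[HaplotypeAlignment, np.ndarray]:
    """Generate an alignment of ``n_haplotypes`` known sequences assigned to
    individuals multinomially per population.

    Haplotype k differs from haplotype 1 at variable positions 1..k−1, so
    the true pairwise distance matrix is D[i, j] = |i − j|; it is returned
    alongside the alignment.
    """
    if n_haplotypes < 1:
        raise ValueError("need at least one haplotype")
    if seq_length < n_haplotypes - 1:
        raise ValueError("seq_length too short to place distinct variable sites")
    rng = np.random.default_rng(seed)
    backbone = "".join(rng.choice(list("ACGT"), size=seq_length))
    var_positions = list(range(n_haplotypes - 1))
    hap_seqs = []
    for k in range(n_haplotypes):
        s = list(backbone)
        for p in var_positions[:k]:
            s[p] = "T" if backbone[p] != "T" else "C"
        hap_seqs.append("".join(s))
    truth_dist = np.abs(
        np.arange(n_haplotypes)[:, None] - np.arange(n_haplotypes)[None, :]
    ).astype(float)

    sequences: dict[str, str] = {}
    population: dict[str, str] = {}
    for pop, freqs in pop_haplotype_freqs.items():
        p = np.asarray(freqs, dtype=float)
        if len(p) != n_haplotypes:
            raise ValueError(f"frequency vector for {pop!r} has wrong length")
        _check_probs(p)
        n = n_per_pop[pop] if isinstance(n_per_pop, Mapping) else n_per_pop
        assigns = rng.choice(n_haplotypes, size=n, p=p)
        for i, h in enumerate(assigns):
            ind = f"{pop}_{i + 1:03d}"
            sequences[ind] = hap_seqs[h]
            population[ind] = pop
    alignment = build_alignment(sequences, population)
    return alignment, truth_dist


def simulate_skyline(
    n0: float,
    growth_rate: float,
    t_start: float,
    t_growth: float,
    n_points: int = 100,
    seed: int | None = None,
    noise_sd: float = 0.0,
) -> SkylineSeries:
    """Skyline series flat at ``n0`` until ``t_growth`` years before present,
    then exponential growth at ``growth_rate``/year toward the present;
    optional lognormal noise emulates posterior-summary wiggle."""
    rng = np.random.default_rng(seed)
    times = np.linspace(t_start, 0.0, n_points)
    ne = np.where(
        times >= t_growth, n0, n0 * np.exp(growth_rate * (t_growth - times))
    )
    if noise_sd > 0:
        ne = ne * np.exp(rng.normal(0.0, noise_sd, size=n_points))
    return SkylineSeries(times=list(map(float, times)), ne=list(map(float, ne)))
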