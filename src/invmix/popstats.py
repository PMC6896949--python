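"""Clonal filtering and diversity statistics for polyploid microsatellite
data plus chloroplast haplotype statistics with a Gst/Nst permutation test.

Allele-level indices are dosage-free: frequencies are tallied over all
scored allele calls in a cell's multiset, and an individual counts as
heterozygous at a locus iff its multiset holds at least two distinct
alleles.  Per-locus indices (Ae = 1/Σp², I = −Σ p ln p, He = 1 − Σp²,
F = 1 − Ho/He) are averaged over loci per population; group-level values
are computed on pooled calls.

Haplotype differentiation uses the haploid Nei & Chesser small-sample
estimators for HS/HT (Gst = (HT − HS)/HT) and their distance-weighted
analogues VS/VT for Nst (Pons & Petit); the phylogeographic test permutes
haplotype identities on the distance matrix and reports a one-sided
add-one-smoothed p-value for Nst − Gst > 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genio import MISSING, GenotypeMatrix, HaplotypeAlignment

logger = logging.getLogger("invmix")


# ---------------------------------------------------------------------------
# Clonal filtering
# ---------------------------------------------------------------------------

def _genotypes_identical(
    a: Mapping[str, tuple[int, ...]], b: Mapping[str, tuple[int, ...]]
) -> bool:
    """Identity under missing data: equality on all shared scored loci,
    requiring at least one shared scored locus."""
    shared = [l for l in a if a[l] != MISSING and b[l] != MISSING]
    return bool(shared) and all(a[l] == b[l] for l in shared)


@dataclass
class CloneReport:
    filtered: GenotypeMatrix
    removed: int
    clonal_diversity: dict[str, float]          # per population
    group_clonal_diversity: dict[str, float]    # mean of member populations
    removed_individuals: list[str] = field(default_factory=list)


def deduplicate_clones(matrix: GenotypeMatrix) -> CloneReport:
    """Keep one representative (first by input order) per identical
    multilocus genotype within each population.

    Clonal diversity — number of distinct genotypes divided by sample
    size — is computed per population on the pre-filter matrix; the group
    value is the mean over member populations (how the field reports it).
    """
    keep: list[str] = []
    removed: list[str] = []
    diversity: dict[str, float] = {}
    for pop in matrix.populations:
        members = matrix.individuals_of(pop)
        if not members:
            logger.warning("population %s is empty; excluded from clone report", pop)
            continue
        reps: list[dict[str, tuple[int, ...]]] = []
        rep_ids: list[str] = []
        for ind in members:
            geno = {l: matrix.calls[(ind, l)] for l in matrix.loci}
            if any(_genotypes_identical(geno, r) for r in reps):
                removed.append(ind)
            else:
                reps.append(geno)
                rep_ids.append(ind)
        keep.extend(rep_ids)
        diversity[pop] = len(rep_ids) / len(members)
    groups: dict[str, list[float]] = {}
    for pop, cd in diversity.items():
        groups.setdefault(matrix.group[pop], []).append(cd)
    group_cd = {g: float(np.mean(v)) for g, v in groups.items()}
    return CloneReport(
        filtered=matrix.subset(keep),
        removed=len(removed),
        clonal_diversity=diversity,
        group_clonal_diversity=group_cd,
        removed_individuals=removed,
    )


# ---------------------------------------------------------------------------
# Allele frequencies
# ---------------------------------------------------------------------------

@dataclass
class AlleleTable:
    """Per unit (population or group) and locus: allele -> count and frequency.

    ``counts[unit][locus][allele]`` is the number of scored allele calls;
    frequencies divide by the unit/locus total (missing cells excluded from
    denominators).  Loci with zero scored calls in a unit are flagged in
    ``undefined``.
    """

    counts: dict[str, dict[str, dict[int, int]]]
    loci: list[str]
    undefined: list[tuple[str, str]] = field(default_factory=list)

    @property
    def units(self) -> list[str]:
        return list(self.counts)

    def frequencies(self, unit: str, locus: str) -> dict[int, float]:
        tally = self.counts[unit][locus]
        total = sum(tally.values())
        if total == 0:
            raise ValueError(f"no scored calls for unit {unit!r} at locus {locus!r}")
        return {a: c / total for a, c in tally.items()}

    def total_calls(self, unit: str, locus: str) -> int:
        return sum(self.counts[unit][locus].values())

    def alleles(self, locus: str) -> list[int]:
        seen: set[int] = set()
        for unit in self.counts:
            seen.update(self.counts[unit][locus])
        return sorted(seen)


def allele_frequencies(
    matrix: GenotypeMatrix, grouping: str = "population"
) -> AlleleTable:
    """Tally allele calls per unit and locus.

    ``grouping`` is ``"population"``, ``"group"``, or a mapping
    individual -> unit label.
    """
    if grouping == "population":
        unit_of = matrix.population
    elif grouping == "group":
        unit_of = {i: matrix.group[matrix.population[i]] for i in matrix.individuals}
    elif isinstance(grouping, Mapping):
        unit_of = {i: grouping[i] for i in matrix.individuals}
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    units: dict[str, dict[str, dict[int, int]]] = {}
    for ind in matrix.individuals:
        unit = unit_of[ind]
        per_locus = units.setdefault(
            unit, {l: {} for l in matrix.loci}
        )
        for locus in matrix.loci:
            for a in matrix.calls[(ind, locus)]:
                per_locus[locus][a] = per_locus[locus].get(a, 0) + 1
    undefined = [
        (u, l) for u, per in units.items() for l in matrix.loci
        if sum(per[l].values()) == 0
    ]
    for u, l in undefined:
        logger.warning("unit %s has no scored calls at locus %s", u, l)
    return AlleleTable(counts=units, loci=list(matrix.loci), undefined=undefined)


# ---------------------------------------------------------------------------
# Diversity indices
# ---------------------------------------------------------------------------

@dataclass
class DiversityReport:
    per_population: pd.DataFrame   # rows: populations; cols: n, Ae, I, Ho, He, F
    per_group: pd.DataFrame
    per_locus: dict[str, pd.DataFrame] = field(default_factory=dict)


def _locus_indices(p: np.ndarray) -> tuple[float, float, float]:
    """(Ae, I, He) from an allele-frequency vector."""
    p = p[p > 0]
    sum_p2 = float(np.sum(p ** 2))
    ae = 1.0 / sum_p2
    shannon = float(-np.sum(p * np.log(p)))
    he = 1.0 - sum_p2
    return ae, shannon, he


def _observed_het(matrix: GenotypeMatrix, members: Sequence[str], locus: str) -> float | None:
    scored = [
        matrix.calls[(i, locus)] for i in members if matrix.calls[(i, locus)] != MISSING
    ]
    if not scored:
        return None
    het = sum(1 for cell in scored if len(set(cell)) >= 2)
    return het / len(scored)


def diversity_indices(
    table: AlleleTable, matrix: GenotypeMatrix
) -> DiversityReport:
    """Locus-averaged Ae, I, Ho, He and fixation index F per population,
    plus group-level values on pooled calls.

    Monomorphic loci contribute Ae = 1, I = 0, He = 0 and are excluded from
    the F average (F undefined at He = 0).
    """
    group_table = allele_frequencies(matrix, "group")

    def unit_row(
        tab: AlleleTable, unit: str, members: Sequence[str]
    ) -> tuple[dict[str, float], pd.DataFrame]:
        rows = []
        for locus in tab.loci:
            if (unit, locus) in tab.undefined:
                continue
            p = np.array(list(tab.frequencies(unit, locus).values()))
            ae, shannon, he = _locus_indices(p)
            ho = _observed_het(matrix, members, locus)
            f = (1.0 - ho / he) if (ho is not None and he > 0) else math.nan
            if math.isnan(f):
                logger.debug("F undefined at monomorphic locus %s in %s", locus, unit)
            rows.append(
                {"locus": locus, "Ae": ae, "I": shannon,
                 "Ho": math.nan if ho is None else ho, "He": he, "F": f}
            )
        per_locus = pd.DataFrame(rows).set_index("locus")
        means = {
            "n": float(len(members)),
            "Ae": float(per_locus["Ae"].mean()),
            "I": float(per_locus["I"].mean()),
            "Ho": float(per_locus["Ho"].mean()),
            "He": float(per_locus["He"].mean()),
            "F": float(per_locus["F"].mean()),   # nan-aware mean over defined loci
        }
        return means, per_locus

    pop_rows: dict[str, dict[str, float]] = {}
    per_locus: dict[str, pd.DataFrame] = {}
    pop_table = allele_frequencies(matrix, "population")
    for pop in matrix.populations:
        means, locus_df = unit_row(pop_table, pop, matrix.individuals_of(pop))
        pop_rows[pop] = means
        per_locus[pop] = locus_df
    grp_rows: dict[str, dict[str, float]] = {}
    for grp in group_table.units:
        members = [
            i for i in matrix.individuals
            if matrix.group[matrix.population[i]] == grp
        ]
        means, locus_df = unit_row(group_table, grp, members)
        grp_rows[grp] = means
        per_locus[grp] = locus_df
    return DiversityReport(
        per_population=pd.DataFrame(pop_rows).T,
        per_group=pd.DataFrame(grp_rows).T,
        per_locus=per_locus,
    )


def private_alleles(
    table: AlleleTable,
    focal_units: Sequence[str],
    reference_units: Sequence[str],
) -> dict[str, list[tuple[str, int]]]:
    """Alleles with nonzero count in a focal unit and zero count in every
    reference unit, as ``{focal_unit: [(locus, allele), ...]}``."""
    for unit in list(focal_units) + list(reference_units):
        if unit not in table.counts:
            raise ValueError(f"unit {unit!r} absent from the allele table")
    result: dict[str, list[tuple[str, int]]] = {}
    for focal in focal_units:
        found: list[tuple[str, int]] = []
        for locus in table.loci:
            for allele, count in table.counts[focal][locus].items():
                if count == 0:
                    continue
                if all(
                    table.counts[ref][locus].get(allele, 0) == 0
                    for ref in reference_units
                ):
                    found.append((locus, allele))
        result[focal] = sorted(found)
    return result


# ---------------------------------------------------------------------------
# Haplotype statistics
# ---------------------------------------------------------------------------

@dataclass
class HaploStats:
    per_population: pd.DataFrame   # rows: populations; cols: n, Ha, Hd, pi
    hs: float
    ht: float
    gst: float
    nst: float | None = None
    p_value: float | None = None
    n_perm: int | None = None
    seed: int | None = None
    degenerate: bool = False


def _pop_haplotype_freqs(
    alignment: HaplotypeAlignment, pops: Sequence[str]
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """(haplotype labels, pops x haplotypes frequency matrix, sample sizes)."""
    labels = alignment.haplotypes
    idx = {h: k for k, h in enumerate(labels)}
    freqs = np.zeros((len(pops), len(labels)))
    sizes = np.zeros(len(pops))
    for i, pop in enumerate(pops):
        members = [
            ind for ind in alignment.individuals if alignment.population[ind] == pop
        ]
        sizes[i] = len(members)
        for ind in members:
            freqs[i, idx[alignment.haplotype_of[ind]]] += 1
        if members:
            freqs[i] /= len(members)
    return labels, freqs, sizes


def _hs_ht(freqs: np.ndarray, sizes: np.ndarray, dist: np.ndarray) -> tuple[float, float]:
    """Nei & Chesser style small-sample HS/HT, generalized to a distance
    weighting (identity-complement distance recovers gene diversity)."""
    n_pops = freqs.shape[0]
    n_tilde = n_pops / np.sum(1.0 / sizes)           # harmonic mean sample size
    within = np.array([f @ dist @ f for f in freqs])
    hs = (n_tilde / (n_tilde - 1.0)) * float(np.mean(within))
    pbar = freqs.mean(axis=0)
    ht = float(pbar @ dist @ pbar) + hs / (n_tilde * n_pops)
    return hs, ht


def haplotype_stats(
    alignment: HaplotypeAlignment,
    grouping: Mapping[str, Sequence[str]] | None = None,
) -> dict[str, HaploStats]:
    """Per-population Hd, π and haplotype counts, plus per-group HS, HT, Gst.

    ``grouping`` maps group label -> population codes; default is one group
    holding every population.  π is the mean pairwise sequence difference
    per site, over the full alignment length.  Populations with n = 1 get an
    undefined (NaN) Hd and are excluded from HS.
    """
    pops_all = sorted(set(alignment.population.values()))
    if grouping is None:
        grouping = {"all": pops_all}

    hap_of = alignment.haplotype_of
    dm = alignment.distance_matrix()
    labels = list(dm.index)
    dist = dm.to_numpy()

    rows = {}
    for pop in pops_all:
        members = [i for i in alignment.individuals if alignment.population[i] == pop]
        n = len(members)
        counts = pd.Series([hap_of[i] for i in members]).value_counts()
        p = counts.to_numpy(dtype=float) / n
        if n >= 2:
            hd = n / (n - 1.0) * (1.0 - float(np.sum(p ** 2)))
            # π: mean pairwise difference per site over all ordered pairs
            vec = np.zeros(len(labels))
            for h, c in counts.items():
                vec[labels.index(h)] = c
            total_diff = vec @ dist @ vec   # counts each unordered pair twice
            pi = total_diff / (n * (n - 1.0)) / alignment.alignment_length
        else:
            hd = math.nan
            pi = math.nan
            logger.warning("population %s has n=1; Hd undefined", pop)
        rows[pop] = {"n": float(n), "Ha": float(len(counts)), "Hd": hd, "pi": pi}
    per_pop = pd.DataFrame(rows).T

    results: dict[str, HaploStats] = {}
    identity = 1.0 - np.eye(len(labels))
    for grp, pops in grouping.items():
        usable = [
            p for p in pops
            if sum(1 for i in alignment.individuals if alignment.population[i] == p) >= 2
        ]
        if len(usable) < 1:
            raise ValueError(f"group {grp!r} has no population with n >= 2")
        _, freqs, sizes = _pop_haplotype_freqs(alignment, usable)
        hs, ht = _hs_ht(freqs, sizes, identity)
        gst = (ht - hs) / ht if ht > 0 else math.nan
        results[grp] = HaploStats(
            per_population=per_pop.loc[[p for p in pops if p in per_pop.index]],
            hs=hs, ht=ht, gst=gst,
        )
    return results


def gst_nst_test(
    alignment: HaplotypeAlignment,
    populations: Sequence[str] | None = None,
    n_perm: int = 999,
    seed: int | None = None,
) -> HaploStats:
    """Test for phylogeographic structure by comparing Nst against Gst.

    Nst weights differentiation by pairwise haplotype distances; under
    phylogeographic structure closely related haplotypes co-occur and
    Nst > Gst.  The null distribution permutes haplotype identities on the
    distance matrix ``n_perm`` times; the one-sided p-value for
    Nst − Gst ≥ observed uses add-one smoothing, (b + 1)/(m + 1).
    """
    pops_all = sorted(set(alignment.population.values()))
    if populations is None:
        populations = [
            p for p in pops_all
            if sum(1 for i in alignment.individuals if alignment.population[i] == p) >= 2
        ]
    if len(populations) < 2:
        raise ValueError("need at least 2 populations with n >= 2")
    labels, freqs, sizes = _pop_haplotype_freqs(alignment, populations)
    if len(labels) < 2:
        raise ValueError("need at least 2 haplotypes")
    dist = alignment.distance_matrix().to_numpy()
    identity = 1.0 - np.eye(len(labels))

    hs, ht = _hs_ht(freqs, sizes, identity)
    gst = (ht - hs) / ht
    vs, vt = _hs_ht(freqs, sizes, dist)
    nst = (vt - vs) / vt

    off = dist[~np.eye(len(labels), dtype=bool)]
    if np.allclose(off, off[0]):
        logger.warning(
            "all haplotype distances equal: Nst = Gst identically; test degenerate"
        )
        return HaploStats(
            per_population=pd.DataFrame(), hs=hs, ht=ht, gst=gst, nst=nst,
            p_value=1.0, n_perm=n_perm, seed=seed, degenerate=True,
        )

    rng = np.random.default_rng(seed)
    observed = nst - gst
    exceed = 0
    k = len(labels)
    for _ in range(n_perm):
        perm = rng.permutation(k)
        d_perm = dist[np.ix_(perm, perm)]
        vs_p, vt_p = _hs_ht(freqs, sizes, d_perm)
        if (vt_p - vs_p) / vt_p - gst >= observed:
            exceed += 1
    p = (exceed + 1) / (n_perm + 1)
    return HaploStats(
        per_population=pd.DataFrame(), hs=hs, ht=ht, gst=gst, nst=nst,
        p_value=p, n_perm=n_perm, seed=seed,
    )
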