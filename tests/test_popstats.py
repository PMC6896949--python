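"""Clone filtering, diversity indices, private alleles, haplotype
statistics and the Gst/Nst permutation test, checked against independent
brute-force oracles and closed forms."""

import math

import numpy as np
import pytest

from invmix import (
    allele_frequencies,
    build_alignment,
    deduplicate_clones,
    diversity_indices,
    gst_nst_test,
    haplotype_stats,
    private_alleles,
    simulate_haplotypes,
)

from conftest import make_matrix, random_matrix


# ---------------------------------------------------------------------------
# Clonal filter
# ---------------------------------------------------------------------------

class TestCloneFilter:
    def test_direct_count(self):
        cells = {
            (f"i{k}", "P1"): {"L1": (100, 102), "L2": (200,)} for k in range(2)
        }
        cells.update({
            (f"j{k}", "P1"): {"L1": (100 + 2 * k, 104), "L2": (202,)}
            for k in range(8)
        })
        m = make_matrix(cells, ploidy=2)
        rep = deduplicate_clones(m)
        assert rep.removed == 1
        assert rep.clonal_diversity["P1"] == pytest.approx(0.9)

    def test_all_distinct_unchanged(self, toy_matrix):
        rep = deduplicate_clones(toy_matrix)
        assert rep.removed == 0
        assert all(v == 1.0 for v in rep.clonal_diversity.values())
        assert rep.filtered == toy_matrix

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        m = random_matrix(rng, n_ind=30, n_alleles=2, n_loci=2, ploidy=2)
        once = deduplicate_clones(m)
        twice = deduplicate_clones(once.filtered)
        assert twice.removed == 0
        assert twice.filtered == once.filtered

    def test_first_representative_kept(self):
        m = make_matrix({
            ("first", "P1"): {"L1": (100,)},
            ("second", "P1"): {"L1": (100,)},
        }, ploidy=1)
        rep = deduplicate_clones(m)
        assert rep.filtered.individuals == ["first"]
        assert rep.removed_individuals == ["second"]

    def test_missing_tolerant_identity(self):
        # i2 is unscored at L2; equal to i1 on the shared locus L1 -> clone
        m = make_matrix({
            ("i1", "P1"): {"L1": (100, 102), "L2": (200,)},
            ("i2", "P1"): {"L1": (100, 102)},
        }, ploidy=2)
        assert deduplicate_clones(m).removed == 1

    def test_group_diversity_is_mean_of_populations(self):
        m = make_matrix({
            ("a1", "P1"): {"L1": (100,)}, ("a2", "P1"): {"L1": (100,)},
            ("b1", "P2"): {"L1": (100,)}, ("b2", "P2"): {"L1": (102,)},
        }, ploidy=1, groups={"P1": "g", "P2": "g"})
        rep = deduplicate_clones(m)
        assert rep.group_clonal_diversity["g"] == pytest.approx((0.5 + 1.0) / 2)


# ---------------------------------------------------------------------------
# Allele frequencies
# ---------------------------------------------------------------------------

class TestAlleleFrequencies:
    def test_single_individual_hexaploid(self):
        m = make_matrix({("i1", "P1"): {"L1": (1, 1, 1, 2, 2, 2)}}, ploidy=6)
        t = allele_frequencies(m)
        assert t.frequencies("P1", "L1") == {1: 0.5, 2: 0.5}

    def test_group_counts_are_sum_of_population_counts(self):
        rng = np.random.default_rng(4)
        m = random_matrix(rng, n_pops=2)
        m.group.update({p: "G" for p in m.populations})
        pop_t = allele_frequencies(m, "population")
        grp_t = allele_frequencies(m, "group")
        for locus in m.loci:
            for allele in grp_t.alleles(locus):
                assert grp_t.counts["G"][locus].get(allele, 0) == sum(
                    pop_t.counts[p][locus].get(allele, 0) for p in m.populations
                )

    def test_matches_brute_force_tally(self):
        rng = np.random.default_rng(5)
        m = random_matrix(rng, missing_rate=0.1)
        t = allele_frequencies(m)
        for pop in m.populations:
            members = m.individuals_of(pop)
            for locus in m.loci:
                tally = {}
                for ind in members:
                    for a in m.calls[(ind, locus)]:
                        tally[a] = tally.get(a, 0) + 1
                assert t.counts[pop][locus] == tally

    def test_zero_scored_locus_flagged(self):
        m = make_matrix({("i1", "P1"): {"L1": (1,)}, ("i2", "P2"): {"L2": (2,)}},
                        ploidy=1)
        t = allele_frequencies(m)
        assert ("P1", "L2") in t.undefined
        with pytest.raises(ValueError):
            t.frequencies("P1", "L2")


# ---------------------------------------------------------------------------
# Diversity indices
# ---------------------------------------------------------------------------

def brute_force_indices(matrix, pop):
    """Direct per-locus computation from first principles."""
    members = matrix.individuals_of(pop)
    out = {}
    for locus in matrix.loci:
        calls = [a for i in members for a in matrix.calls[(i, locus)]]
        if not calls:
            continue
        alleles = sorted(set(calls))
        p = np.array([calls.count(a) / len(calls) for a in alleles])
        ae = 1.0 / sum(x * x for x in p)
        shannon = -sum(x * math.log(x) for x in p if x > 0)
        he = 1.0 - sum(x * x for x in p)
        scored = [matrix.calls[(i, locus)] for i in members
                  if matrix.calls[(i, locus)]]
        ho = sum(1 for c in scored if len(set(c)) > 1) / len(scored)
        out[locus] = (ae, shannon, ho, he)
    return out


class TestDiversityIndices:
    def test_uniform_k_allele_closed_form(self):
        m = make_matrix({
            ("i1", "P1"): {"L1": (1, 2)}, ("i2", "P1"): {"L1": (3, 4)},
        }, ploidy=2)
        rep = diversity_indices(allele_frequencies(m), m)
        assert rep.per_population.loc["P1", "Ae"] == pytest.approx(4.0)
        assert rep.per_population.loc["P1", "I"] == pytest.approx(math.log(4))

    def test_all_heterozygote_fixation_index(self):
        # two equifrequent alleles, every individual heterozygous:
        # He = 0.5, Ho = 1, F = 1 - 1/0.5 = -1
        m = make_matrix({
            (f"i{k}", "P1"): {"L1": (1, 2)} for k in range(10)
        }, ploidy=2)
        rep = diversity_indices(allele_frequencies(m), m)
        assert rep.per_population.loc["P1", "He"] == pytest.approx(0.5)
        assert rep.per_population.loc["P1", "Ho"] == pytest.approx(1.0)
        assert rep.per_population.loc["P1", "F"] == pytest.approx(-1.0)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(6)
        m = random_matrix(rng, n_ind=20, n_loci=4, n_pops=2)
        rep = diversity_indices(allele_frequencies(m), m)
        for pop in m.populations:
            oracle = brute_force_indices(m, pop)
            df = rep.per_locus[pop]
            for locus, (ae, shannon, ho, he) in oracle.items():
                assert df.loc[locus, "Ae"] == pytest.approx(ae, abs=1e-12)
                assert df.loc[locus, "I"] == pytest.approx(shannon, abs=1e-12)
                assert df.loc[locus, "Ho"] == pytest.approx(ho, abs=1e-12)
                assert df.loc[locus, "He"] == pytest.approx(he, abs=1e-12)

    def test_monomorphic_locus_excluded_from_f_average(self):
        m = make_matrix({
            ("i1", "P1"): {"L1": (1, 1), "L2": (1, 2)},
            ("i2", "P1"): {"L1": (1, 1), "L2": (1, 2)},
        }, ploidy=2)
        rep = diversity_indices(allele_frequencies(m), m)
        df = rep.per_locus["P1"]
        assert math.isnan(df.loc["L1", "F"])
        assert df.loc["L1", "He"] == 0.0
        assert rep.per_population.loc["P1", "F"] == pytest.approx(
            df.loc["L2", "F"]
        )

    def test_invariance_to_order_and_relabeling(self):
        rng = np.random.default_rng(7)
        m = random_matrix(rng, n_ind=16, n_loci=3)
        rep = diversity_indices(allele_frequencies(m), m)
        # reverse individual order
        rev = make_matrix({}, ploidy=m.ploidy)
        from invmix import GenotypeMatrix
        rev = GenotypeMatrix(
            individuals=m.individuals[::-1], population=dict(m.population),
            group=dict(m.group), loci=list(m.loci), calls=dict(m.calls),
            ploidy=m.ploidy,
        )
        rep_rev = diversity_indices(allele_frequencies(rev), rev)
        # bijective allele relabeling
        remap = {a: 1000 - a for locus in m.loci
                 for a in allele_frequencies(m).alleles(locus)}
        relabeled = GenotypeMatrix(
            individuals=list(m.individuals), population=dict(m.population),
            group=dict(m.group), loci=list(m.loci),
            calls={k: tuple(sorted(remap[a] for a in v))
                   for k, v in m.calls.items()},
            ploidy=m.ploidy,
        )
        rep_rel = diversity_indices(allele_frequencies(relabeled), relabeled)
        for col in ["Ae", "I", "Ho", "He"]:
            for pop in m.populations:
                base = rep.per_population.loc[pop, col]
                assert rep_rev.per_population.loc[pop, col] == pytest.approx(base)
                assert rep_rel.per_population.loc[pop, col] == pytest.approx(base)


class TestPrivateAlleles:
    def test_shared_allele_not_private(self):
        m = make_matrix({
            ("i1", "P1"): {"L1": (1,)}, ("i2", "P2"): {"L1": (1,)},
        }, ploidy=1)
        t = allele_frequencies(m)
        assert private_alleles(t, ["P1"], ["P2"])["P1"] == []

    def test_exclusive_allele_private(self):
        m = make_matrix({
            ("i1", "P1"): {"L1": (1, 2)}, ("i2", "P2"): {"L1": (2,)},
        }, ploidy=2)
        t = allele_frequencies(m)
        assert private_alleles(t, ["P1"], ["P2"])["P1"] == [("L1", 1)]

    def test_unknown_unit_rejected(self, toy_matrix):
        t = allele_frequencies(toy_matrix)
        with pytest.raises(ValueError):
            private_alleles(t, ["P1"], ["NOPE"])


# ---------------------------------------------------------------------------
# Haplotype statistics
# ---------------------------------------------------------------------------

def brute_pi(alignment, pop):
    """All-pairs oracle for nucleotide diversity."""
    members = [i for i in alignment.individuals if alignment.population[i] == pop]
    profiles = {
        i: alignment.haplotype_profile[alignment.haplotype_of[i]] for i in members
    }
    n = len(members)
    total = 0
    for x in range(n):
        for y in range(x + 1, n):
            a, b = profiles[members[x]], profiles[members[y]]
            total += sum(u != v for u, v in zip(a, b))
    return total / (n * (n - 1) / 2) / alignment.alignment_length


class TestHaplotypeStats:
    def test_monomorphic_population(self):
        aln = build_alignment(
            {f"i{k}": "ACGT" for k in range(5)}, {f"i{k}": "P1" for k in range(5)}
        )
        res = haplotype_stats(aln)["all"]
        assert res.per_population.loc["P1", "Hd"] == 0.0
        assert res.per_population.loc["P1", "pi"] == 0.0

    def test_two_distinct_haplotypes_n2(self):
        aln = build_alignment(
            {"i1": "ACGT", "i2": "AGGT"}, {"i1": "P1", "i2": "P1"}
        )
        res = haplotype_stats(aln)["all"]
        assert res.per_population.loc["P1", "Hd"] == pytest.approx(1.0)

    def test_pi_matches_all_pairs_oracle(self):
        aln, _ = simulate_haplotypes(
            {"P1": [0.5, 0.3, 0.2], "P2": [0.2, 0.2, 0.6]}, 3,
            seq_length=40, seed=8, n_per_pop=15,
        )
        res = haplotype_stats(aln)["all"]
        for pop in ["P1", "P2"]:
            assert res.per_population.loc[pop, "pi"] == pytest.approx(
                brute_pi(aln, pop), abs=1e-12
            )

    def test_hs_le_ht_under_differentiation(self):
        aln, _ = simulate_haplotypes(
            {"P1": [0.8, 0.2, 0.0, 0.0], "P2": [0.0, 0.0, 0.3, 0.7],
             "P3": [0.1, 0.6, 0.3, 0.0]}, 4,
            seq_length=30, seed=9, n_per_pop=25,
        )
        res = haplotype_stats(aln)["all"]
        assert res.hs <= res.ht + 1e-12
        assert res.gst > 0

    def test_gst_noise_bounded_under_null(self):
        """Identical true frequencies everywhere: the unbiased estimators may
        dip slightly negative but stay above -0.05."""
        for seed in range(10):
            aln, _ = simulate_haplotypes(
                {f"P{k}": [0.25] * 4 for k in range(1, 5)}, 4,
                seq_length=30, seed=seed, n_per_pop=25,
            )
            res = haplotype_stats(aln)["all"]
            assert res.gst >= -0.05


class TestGstNst:
    def test_equidistant_distances_nst_equals_gst(self):
        # 3 haplotypes all one mutation apart from each other at distinct sites
        seqs = {
            "a1": "ACGTAC", "a2": "ACGTAC",
            "b1": "TCGTAC", "b2": "TCGTAC",
            "c1": "AGGTAC", "c2": "AGGTAC",
        }
        # distances: H(a)-H(b)=2? construct truly equidistant: pairwise = 2
        seqs = {
            "a1": "AAGG", "a2": "AAGG",
            "b1": "ATCG", "b2": "ATCG",
            "c1": "TACG", "c2": "TACG",
        }
        pops = {k: ("P1" if k[0] in "ab" else "P2") for k in seqs}
        pops["a2"] = "P2"
        pops["b2"] = "P1"
        aln = build_alignment(seqs, pops)
        dm = aln.distance_matrix().to_numpy()
        off = dm[~np.eye(3, dtype=bool)]
        assert np.allclose(off, off[0])
        res = gst_nst_test(aln, n_perm=49, seed=0)
        assert res.degenerate
        assert res.nst == pytest.approx(res.gst, abs=1e-12)
        assert res.p_value == 1.0

    def test_positive_control_detects_structure(self):
        """Each population fixed for its own haplotype, distances block-
        correlated with geography -> Nst > Gst, p < 0.05 at 999 perms."""
        freqs = {}
        # two geographic blocks; each population mixes the two *similar*
        # haplotypes of its block (1,2 vs 5,6, four mutations apart), so
        # within-population distances are small relative to between-block
        # block A mixes haplotypes 0-4, block B haplotypes 10-14 of a
        # 15-haplotype ladder: within-block distances <= 4, across >= 6
        block_a = [0.2] * 5 + [0.0] * 10
        block_b = [0.0] * 10 + [0.2] * 5
        for k in range(1, 4):
            freqs[f"A{k}"] = block_a
            freqs[f"B{k}"] = block_b
        aln, _ = simulate_haplotypes(freqs, 15, seq_length=30, seed=10, n_per_pop=20)
        res = gst_nst_test(aln, n_perm=999, seed=11)
        assert res.nst > res.gst
        assert res.p_value < 0.05

    def test_requires_two_populations(self):
        aln = build_alignment(
            {"i1": "ACGT", "i2": "AGGT"}, {"i1": "P1", "i2": "P1"}
        )
        with pytest.raises(ValueError):
            gst_nst_test(aln)

    def test_records_nperm_and_seed(self):
        aln, _ = simulate_haplotypes(
            {"P1": [0.5, 0.25, 0.25], "P2": [0.2, 0.3, 0.5]}, 3,
            seq_length=20, seed=12, n_per_pop=12,
        )
        res = gst_nst_test(aln, n_perm=99, seed=42)
        assert (res.n_perm, res.seed) == (99, 42)
        res2 = gst_nst_test(aln, n_perm=99, seed=42)
        assert res.p_value == res2.p_value
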