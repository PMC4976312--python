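"""Haplotype pair enumeration, EM frequency estimation and LD."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_h
from scipy.optimize import minimize

from nsfcnv.haplotypes import (
    EmConfig,
    Haplotype,
    HaplotypeFrequencyTable,
    IndividualGenotype,
    em_haplotype_frequencies,
    enumerate_compatible_pairs,
    haploallele_copy_association,
    ld_r2,
    observed_data_log_likelihood,
)
from nsfcnv.synthetic import SimulationConfig, simulate_population

# ---------------------------------------------------------------------------
# independent oracles


def brute_force_pairs(genotype, copy_support=(1, 2, 3)):
    """Filter the full haplotype-pair cross product for compatibility."""
    alleles_per_locus = [sorted(set(g)) for g in genotype.snp_genotypes]
    candidates = [
        Haplotype(tuple(combo), c)
        for combo in itertools.product(*alleles_per_locus)
        for c in copy_support
    ]
    seen = set()
    for h1, h2 in itertools.product(candidates, repeat=2):
        if h1.copies + h2.copies != genotype.total_copies:
            continue
        ok = all(
            tuple(sorted((a1, a2))) == g
            for a1, a2, g in zip(h1.alleles, h2.alleles, genotype.snp_genotypes)
        )
        if ok:
            seen.add((h1, h2) if h1 <= h2 else (h2, h1))
    return sorted(seen)


def simplex_mle(genotypes, copy_support=(1, 2, 3), restarts=5, seed=0):
    """Direct numerical maximization of the observed-data likelihood over the
    haplotype simplex (softmax parametrization, multi-start BFGS)."""
    universe = sorted(
        {h for g in genotypes for pair in enumerate_compatible_pairs(g, copy_support) for h in pair}
    )
    pair_idx = [
        [(universe.index(h1), universe.index(h2), 1.0 if h1 == h2 else 2.0)
         for h1, h2 in enumerate_compatible_pairs(g, copy_support)]
        for g in genotypes
    ]

    def negloglik(z):
        f = np.exp(z - z.max())
        f = f / f.sum()
        total = 0.0
        for pairs in pair_idx:
            p = sum(m * f[i] * f[j] for i, j, m in pairs)
            total += math.log(max(p, 1e-300))
        return -total

    rng = np.random.default_rng(seed)
    best = None
    for _ in range(restarts):
        z0 = rng.normal(0, 1, size=len(universe))
        res = minimize(negloglik, z0, method="Nelder-Mead",
                       options={"maxiter": 20000, "xatol": 1e-10, "fatol": 1e-12})
        if best is None or res.fun < best.fun:
            best = res
    f = np.exp(best.x - best.x.max())
    f = f / f.sum()
    return dict(zip(universe, f))


# ---------------------------------------------------------------------------
# pair enumeration


class TestEnumerateCompatiblePairs:
    def test_homozygous_two_copies_is_forced(self):
        g = IndividualGenotype("x", (("A", "A"),), 2)
        assert enumerate_compatible_pairs(g) == [
            (Haplotype(("A",), 1), Haplotype(("A",), 1))
        ]

    def test_het_total_four_has_three_unordered_pairs(self):
        g = IndividualGenotype("x", (("A", "G"),), 4)
        pairs = enumerate_compatible_pairs(g)
        assert pairs == [
            (Haplotype(("A",), 1), Haplotype(("G",), 3)),
            (Haplotype(("A",), 2), Haplotype(("G",), 2)),
            (Haplotype(("A",), 3), Haplotype(("G",), 1)),
        ]

    def test_double_heterozygote_matches_brute_force(self):
        g = IndividualGenotype("x", (("A", "G"), ("C", "T")), 4)
        assert enumerate_compatible_pairs(g) == brute_force_pairs(g)
        # phase ambiguity (2 allele pairings) x partition ambiguity (3)
        assert len(enumerate_compatible_pairs(g)) == 6

    @pytest.mark.parametrize("total", [2, 3, 4, 5, 6])
    @pytest.mark.parametrize(
        "genotypes",
        [(("A", "A"),), (("A", "G"),), (("A", "G"), ("C", "C")), (("A", "G"), ("C", "T"))],
    )
    def test_enumeration_equals_brute_force(self, genotypes, total):
        g = IndividualGenotype("x", genotypes, total)
        assert enumerate_compatible_pairs(g) == brute_force_pairs(g)

    def test_copy_partitions(self):
        g = IndividualGenotype("x", (("A", "A"),), 5)
        assert {(h1.copies, h2.copies) for h1, h2 in enumerate_compatible_pairs(g)} == {(2, 3)}

    def test_total_out_of_range_raises(self):
        with pytest.raises(ValueError, match="outside"):
            enumerate_compatible_pairs(IndividualGenotype("x", (("A", "A"),), 7))


# ---------------------------------------------------------------------------
# EM


class TestEmHaplotypeFrequencies:
    def test_unambiguous_cohort_converges_immediately(self):
        cohort = [IndividualGenotype(f"s{i}", (("A", "A"),), 2) for i in range(10)]
        table = em_haplotype_frequencies(cohort)
        assert table[Haplotype(("A",), 1)] == pytest.approx(1.0)
        assert table.converged
        assert table.iteration_count == 1

    def test_equals_direct_counting_when_no_ambiguity(self):
        # single locus, all totals 2, no double heterozygotes: each individual
        # resolves to exactly one pair, so EM must equal allele counting.
        cohort = (
            [IndividualGenotype(f"a{i}", (("A", "A"),), 2) for i in range(6)]
            + [IndividualGenotype(f"b{i}", (("A", "G"),), 2) for i in range(3)]
            + [IndividualGenotype(f"c{i}", (("G", "G"),), 2) for i in range(1)]
        )
        table = em_haplotype_frequencies(cohort)
        assert table.iteration_count == 1
        assert table[Haplotype(("A",), 1)] == pytest.approx(15 / 20)
        assert table[Haplotype(("G",), 1)] == pytest.approx(5 / 20)

    def test_matches_brute_force_simplex_maximizer(self, small_cohort):
        em = em_haplotype_frequencies(small_cohort, EmConfig(tolerance=1e-10))
        mle = simplex_mle(small_cohort)
        for h, f in mle.items():
            assert em[h] == pytest.approx(f, abs=1e-4)
        # and the likelihoods agree
        assert observed_data_log_likelihood(small_cohort, em) == pytest.approx(
            observed_data_log_likelihood(small_cohort, mle), abs=1e-6
        )

    def test_log_likelihood_is_monotone_and_freqs_normalized(self, small_cohort):
        table = em_haplotype_frequencies(small_cohort, EmConfig(tolerance=1e-12))
        trace = table.log_likelihood_trace
        assert all(b >= a - 1e-9 for a, b in zip(trace, trace[1:]))
        assert sum(f for _, f in table.items()) == pytest.approx(1.0, abs=1e-9)

    def test_zero_support_haplotypes_retained(self, small_cohort):
        table = em_haplotype_frequencies(small_cohort)
        # universe = {A,G} x {1,2,3}; all six present in the output schema
        assert len(table) == 6

    def test_parameter_recovery_from_reference_table(self, reference_table):
        """Simulating 407 unphased individuals from the reference frequencies,
        the EM re-estimates each frequency within 3 multinomial SE."""
        cfg = SimulationConfig(n_individuals=407, seed=11)
        individuals = simulate_population(cfg)
        est = em_haplotype_frequencies(individuals)
        two_n = 2 * 407
        for h in reference_table:
            f = reference_table[h]
            se = math.sqrt(f * (1 - f) / two_n)
            assert abs(est[h] - f) < 3 * se + 1e-12, h

    def test_typically_converges_within_twenty_iterations(self, reference_table):
        """At tolerance 1e-5 (five decimal places) the EM should converge by
        iteration 20 for the vast majority of cohort draws."""
        hits = 0
        for seed in range(50):
            cfg = SimulationConfig(n_individuals=407, seed=seed)
            est = em_haplotype_frequencies(simulate_population(cfg), EmConfig(tolerance=1e-5))
            assert est.converged
            hits += est.iteration_count <= 20
        assert hits >= 45

    def test_no_compatible_pair_is_rejected(self):
        good = IndividualGenotype("ok", (("A", "A"),), 2)
        with pytest.raises(ValueError, match="no genotypes"):
            em_haplotype_frequencies([])
        # corrupt copy totals cannot even be enumerated
        with pytest.raises(ValueError):
            em_haplotype_frequencies([good, IndividualGenotype("bad", (("A", "A"),), 9)])

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(st_h.lists(
        st_h.tuples(
            st_h.sampled_from(["AA", "AG", "GG"]),
            st_h.integers(min_value=2, max_value=6),
        ),
        min_size=2,
        max_size=10,
    ))
    def test_em_matches_simplex_mle_on_random_small_cohorts(self, layout):
        cohort = [
            IndividualGenotype(f"s{i}", ((tuple(g)),), total)
            for i, (g, total) in enumerate(layout)
        ]
        em = em_haplotype_frequencies(cohort, EmConfig(tolerance=1e-10, max_iterations=2000))
        mle = simplex_mle(cohort, restarts=4)
        ll_em = observed_data_log_likelihood(cohort, em)
        ll_mle = observed_data_log_likelihood(cohort, mle)
        # EM must do at least as well as the numerical maximizer (ties within
        # numerical tolerance); frequencies agree when the optimum is unique.
        assert ll_em >= ll_mle - 1e-4


# ---------------------------------------------------------------------------
# LD


class TestLdR2:
    def test_reference_table_risk_haploallele_vs_one_copy(self, reference_table):
        res = ld_r2(reference_table, lambda a: a == ("G", "T"), lambda c: c == 1)
        assert round(res.r_squared, 2) == 0.61

    def test_perfect_ld(self):
        table = HaplotypeFrequencyTable({
            Haplotype(("G",), 1): 0.5,
            Haplotype(("A",), 2): 0.5,
        })
        res = ld_r2(table, lambda a: a == ("G",), lambda c: c == 1)
        assert res.r_squared == pytest.approx(1.0)

    def test_independence_gives_zero(self):
        table = HaplotypeFrequencyTable({
            Haplotype(("G",), 1): 0.25,
            Haplotype(("G",), 2): 0.25,
            Haplotype(("A",), 1): 0.25,
            Haplotype(("A",), 2): 0.25,
        })
        res = ld_r2(table, lambda a: a == ("G",), lambda c: c == 1)
        assert res.r_squared == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_and_complement_invariant(self, reference_table):
        a = lambda al: al == ("G", "T")
        b = lambda c: c == 1
        base = ld_r2(reference_table, a, b).r_squared
        assert ld_r2(reference_table, lambda al: not a(al), b).r_squared == pytest.approx(base)
        assert ld_r2(reference_table, a, lambda c: not b(c)).r_squared == pytest.approx(base)
        assert ld_r2(reference_table, lambda al: not a(al), lambda c: not b(c)).r_squared == pytest.approx(base)

    def test_monomorphic_class_raises(self):
        table = HaplotypeFrequencyTable({
            Haplotype(("G",), 1): 0.6,
            Haplotype(("G",), 2): 0.4,
        })
        with pytest.raises(ValueError, match="monomorphic"):
            ld_r2(table, lambda a: a == ("G",), lambda c: c == 1)


class TestHaploalleleCopyAssociation:
    def test_independent_classes_give_null_statistic(self):
        table = HaplotypeFrequencyTable({
            Haplotype(("G",), 1): 0.25,
            Haplotype(("G",), 2): 0.25,
            Haplotype(("A",), 1): 0.25,
            Haplotype(("A",), 2): 0.25,
        })
        res = haploallele_copy_association(table, 100, lambda a: a == ("G",), lambda c: c == 1)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_statistic_matches_hand_computed_chi_square(self, reference_table):
        n = 407
        res = haploallele_copy_association(
            reference_table, n, lambda a: a == ("G", "T"), lambda c: c == 1
        )
        # independent closed form: chi2 = 2N * r^2 for a 2x2 table
        r2 = ld_r2(reference_table, lambda a: a == ("G", "T"), lambda c: c == 1).r_squared
        assert res.statistic == pytest.approx(2 * n * r2, rel=1e-9)

    def test_perfect_ld_is_overwhelming(self):
        table = HaplotypeFrequencyTable({
            Haplotype(("G",), 1): 0.5,
            Haplotype(("A",), 2): 0.5,
        })
        res = haploallele_copy_association(table, 50, lambda a: a == ("G",), lambda c: c == 1)
        assert res.p_value < 1e-20

    def test_small_expected_cell_warns(self):
        table = HaplotypeFrequencyTable({
            Haplotype(("G",), 1): 0.02,
            Haplotype(("G",), 2): 0.48,
            Haplotype(("A",), 1): 0.02,
            Haplotype(("A",), 2): 0.48,
        })
        res = haploallele_copy_association(table, 20, lambda a: a == ("G",), lambda c: c == 1)
        assert res.warnings
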