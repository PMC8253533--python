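"""AMOVA variance components, Rst, and permutation significance, checked
against naive double-sum oracles and hand-computed limits."""

import itertools
import math

import numpy as np
import pytest

from ystrkit import (
    Allele,
    Haplotype,
    YFILER_PLUS_27,
    amova_two_level,
    bonferroni,
    haplotype_sq_distance,
    pairwise_rst,
    permutation_p,
    simulate_populations,
    SimConfig,
)
from ystrkit.amova import amova_from_distances, score_matrix, squared_distance_matrix
from ystrkit.core import PopulationSample
from tests.conftest import make_single_locus_pop


def _hap(sample_id, **overrides):
    calls = {m.name: (Allele(10),) * m.copy_number for m in YFILER_PLUS_27.markers}
    for marker, alleles in overrides.items():
        calls[marker] = tuple(Allele(a) if isinstance(a, int) else a for a in alleles)
    return Haplotype(sample_id, calls)


class TestSquaredDistance:
    def test_identical_haplotypes_zero(self):
        a, b = _hap("a"), _hap("b")
        assert haplotype_sq_distance(a, b, YFILER_PLUS_27) == 0.0

    def test_single_locus_difference(self):
        a = _hap("a", DYS391=[13])
        b = _hap("b", DYS391=[15])
        assert haplotype_sq_distance(a, b, YFILER_PLUS_27) == 4.0

    def test_multicopy_sorted_pairing_minimizes(self):
        a = _hap("a", **{"DYS385a/b": [13, 17]})
        b = _hap("b", **{"DYS385a/b": [14, 18]})
        got = haplotype_sq_distance(a, b, YFILER_PLUS_27)
        assert got == 2.0
        # exhaustive pairing oracle: sorted pairing is the minimum over all
        # ways to match the two copies
        best = min(
            sum((x - y) ** 2 for x, y in zip((13, 17), perm))
            for perm in itertools.permutations((14, 18))
        )
        assert got == best

    def test_microvariant_scores_enter_numerically(self):
        a = _hap("a", DYS448=[Allele(18, 2)])
        b = _hap("b", DYS448=[Allele(19, 0)])
        assert haplotype_sq_distance(a, b, YFILER_PLUS_27) == pytest.approx(0.8**2)

    def test_matches_score_matrix_route(self):
        pops = simulate_populations(
            SimConfig(populations=[("A", 6)], divergence_generations=500, mu=0.01, seed=4)
        )
        pop = pops[0]
        X = score_matrix(pop)
        D = squared_distance_matrix(X)
        for i, j in itertools.combinations(range(pop.n), 2):
            direct = haplotype_sq_distance(
                pop.haplotypes[i], pop.haplotypes[j], YFILER_PLUS_27
            )
            assert D[i, j] == pytest.approx(direct, abs=1e-9)


def naive_amova(D, sizes):
    """Pure-python double-sum AMOVA oracle (spec algebra, no vectorization)."""
    N = sum(sizes)
    k = len(sizes)
    bounds = [0]
    for s in sizes:
        bounds.append(bounds[-1] + s)
    ssd_total = sum(D[i][j] for i in range(N) for j in range(i + 1, N)) / N
    ssd_within = sum(
        sum(
            D[i][j]
            for i in range(bounds[p], bounds[p + 1])
            for j in range(i + 1, bounds[p + 1])
        )
        / sizes[p]
        for p in range(k)
    )
    ssd_among = ssd_total - ssd_within
    sigma2_b = ssd_within / (N - k)
    n0 = (N - sum(s * s for s in sizes) / N) / (k - 1)
    sigma2_a = (ssd_among / (k - 1) - sigma2_b) / n0
    denom = sigma2_a + sigma2_b
    return 0.0 if denom == 0 else sigma2_a / denom


class TestAmova:
    def test_full_fixation_gives_rst_one(self):
        popA = make_single_locus_pop("A", [10, 10])
        popB = make_single_locus_pop("B", [12, 12])
        res = amova_two_level([popA, popB])
        assert res.sigma2_within == 0.0
        assert res.rst == pytest.approx(1.0)

    def test_hand_computed_toy(self):
        # A = {10, 10}, B = {10, 12}: SSD_total=3, SSD_within=2, Rst=0
        popA = make_single_locus_pop("A", [10, 10])
        popB = make_single_locus_pop("B", [10, 12])
        res = amova_two_level([popA, popB])
        assert res.ssd_total == pytest.approx(3.0)
        assert res.ssd_within == pytest.approx(2.0)
        assert res.sigma2_within == pytest.approx(1.0)
        assert res.n0 == pytest.approx(2.0)
        assert res.sigma2_among == pytest.approx(0.0)
        assert res.rst == pytest.approx(0.0)

    def test_identical_populations_clamp_to_zero(self):
        popA = make_single_locus_pop("A", [10, 12])
        popB = make_single_locus_pop("B", [10, 12])
        res = amova_two_level([popA, popB])
        assert res.rst <= 0.0
        assert res.rst_clamped == 0.0

    def test_degenerate_zero_variance_flagged(self):
        popA = make_single_locus_pop("A", [10, 10])
        popB = make_single_locus_pop("B", [10, 10])
        res = amova_two_level([popA, popB])
        assert res.degenerate and res.rst == 0.0

    def test_small_population_rejected(self):
        popA = make_single_locus_pop("A", [10])
        popB = make_single_locus_pop("B", [10, 12])
        with pytest.raises(ValueError):
            amova_two_level([popA, popB])

    @pytest.mark.parametrize("sizes", [[10, 10], [25, 15, 10], [40, 80, 50, 30]])
    def test_oracle_equivalence_up_to_n_200(self, sizes):
        cfg = SimConfig(
            populations=[(f"P{i}", n) for i, n in enumerate(sizes)],
            divergence_generations=800,
            mu=0.004,
            seed=11,
        )
        pops = simulate_populations(cfg)
        X = np.vstack([score_matrix(p) for p in pops])
        D = squared_distance_matrix(X)
        res = amova_from_distances(D, sizes)
        assert res.rst == pytest.approx(naive_amova(D.tolist(), sizes), abs=1e-9)
        assert res.ssd_among + res.ssd_within == pytest.approx(res.ssd_total, abs=1e-9)
        assert res.rst <= 1.0

    def test_sample_order_invariance(self):
        cfg = SimConfig(
            populations=[("A", 12), ("B", 12)],
            divergence_generations=600,
            mu=0.005,
            seed=2,
        )
        popA, popB = simulate_populations(cfg)
        base = amova_two_level([popA, popB]).rst
        rng = np.random.default_rng(0)
        for _ in range(3):
            shufA = PopulationSample(
                "A", popA.panel, list(rng.permutation(np.array(popA.haplotypes, dtype=object)))
            )
            shufB = PopulationSample(
                "B", popB.panel, list(rng.permutation(np.array(popB.haplotypes, dtype=object)))
            )
            assert amova_two_level([shufA, shufB]).rst == base


class TestPermutation:
    def test_determinism_same_seed(self):
        cfg = SimConfig(populations=[("A", 10), ("B", 10)], seed=5)
        popA, popB = simulate_populations(cfg)
        r1 = permutation_p(popA, popB, n_perm=200, seed=42)
        r2 = permutation_p(popA, popB, n_perm=200, seed=42)
        assert r1 == r2

    def test_fully_differentiated_pair_minimal_p(self):
        # fixed 10s vs fixed 12s at one locus: no permutation mixing groups
        # can reach Rst = 1, so p = (b+1)/(m+1) stays at its floor only if
        # the identity split recurs; with n=2+2 there are C(4,2)=6 splits,
        # 2 of which reproduce the original partition (A/B or B/A)
        popA = make_single_locus_pop("A", [10, 10, 10, 10, 10])
        popB = make_single_locus_pop("B", [12, 12, 12, 12, 12])
        obs, p = permutation_p(popA, popB, n_perm=999, seed=1)
        assert obs == pytest.approx(1.0)
        # exact tie probability: a uniform split reproduces the partition
        # with probability 2/C(10,5) = 1/126; p stays near the floor
        assert p <= (1 + 999 / 126 * 3) / 1000

    def test_p_floor_on_toy_enumeration(self):
        # 999 permutations of a perfectly separated pair: permuted Rst can
        # equal 1 only when the permutation restores the original bipartition
        popA = make_single_locus_pop("A", [10] * 12)
        popB = make_single_locus_pop("B", [12] * 12)
        obs, p = permutation_p(popA, popB, n_perm=999, seed=3)
        assert obs == pytest.approx(1.0)
        assert p == pytest.approx(1 / 1000, abs=2.5e-3)


class TestPairwiseRst:
    def test_diagonal_and_symmetry(self):
        cfg = SimConfig(
            populations=[("A", 8), ("B", 8), ("C", 8)],
            divergence_generations=400,
            mu=0.005,
            seed=9,
        )
        pops = simulate_populations(cfg)
        res = pairwise_rst(pops, n_perm=99, seed=0)
        assert np.all(np.diag(res.rst) == 0.0)
        assert np.all(np.diag(res.p_values) == 1.0)
        assert np.allclose(res.rst, res.rst.T)
        assert np.allclose(res.p_values, res.p_values.T)
        assert np.all(res.rst_clamped >= 0.0)
        assert np.all((res.p_values > 0) & (res.p_values <= 1))

    def test_divergence_ordering(self):
        # two populations from one source vs one strongly diverged: the
        # diverged pair entries exceed the within-source entry
        close = simulate_populations(
            SimConfig(populations=[("A", 30), ("B", 30)], divergence_generations=0, seed=21)
        )
        far = simulate_populations(
            SimConfig(
                populations=[("C", 30)], divergence_generations=5000, mu=0.01, seed=22
            )
        )
        res = pairwise_rst(close + far, n_perm=99, seed=1)
        i, j, c = 0, 1, 2
        assert res.rst[i, c] > res.rst[i, j]
        assert res.rst[j, c] > res.rst[i, j]

    def test_corrected_alpha_conventions(self):
        cfg = SimConfig(populations=[("A", 6), ("B", 6)], seed=3)
        pops = simulate_populations(cfg)
        res = pairwise_rst(pops, n_perm=19, seed=0, bonferroni_m=431)
        assert res.alpha_corrected == pytest.approx(0.05 / 431)
        res_default = pairwise_rst(pops, n_perm=19, seed=0)
        assert res_default.bonferroni_m == 1  # one pair


class TestBonferroni:
    @pytest.mark.parametrize(
        "alpha, m, expected",
        [
            (0.05, 431, 0.05 / 431),
            (0.05, 1, 0.05),
            (0.05, 11, 0.05 / 11),
        ],
    )
    def test_values(self, alpha, m, expected):
        assert bonferroni(alpha, m) == pytest.approx(expected, abs=1e-15)

    def test_cohort_convention_rounds_to_printed_threshold(self):
        assert round(bonferroni(0.05, 431), 4) == 0.0001

    @pytest.mark.parametrize("alpha, m", [(0.0, 5), (1.0, 5), (0.05, 0), (0.05, 2.5)])
    def test_domain_errors(self, alpha, m):
        with pytest.raises(ValueError):
            bonferroni(alpha, m)
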