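"""Diversity and forensic parameters against hand-computed oracles."""

from collections import Counter

import pytest
from hypothesis import given, strategies as st

from ystrkit import (
    Allele,
    Haplotype,
    HaplotypeSpectrum,
    PopulationSample,
    YFILER_17,
    YFILER_PLUS_27,
    allele_frequencies,
    discrimination_capacity,
    forensic_report,
    from_spectrum,
    gene_diversity,
    haplotype_diversity,
    haplotype_spectrum,
    proportion_unique,
    random_match_probability,
)
from ystrkit.forensic import UndefinedStatisticError
from tests.conftest import make_single_locus_pop

# printed multiplicity spectra for the 431-male reference cohort
SPECTRUM_27 = {1: 405, 2: 10, 3: 2}
SPECTRUM_17 = {1: 328, 2: 33, 3: 6, 4: 1, 5: 3}

spectra = st.dictionaries(
    st.integers(1, 6), st.integers(1, 30), min_size=1, max_size=5
)


class TestAlleleFrequencies:
    def test_single_copy_direct_counting(self):
        pop = make_single_locus_pop("p", [10, 10, 10, 11])
        ft = allele_frequencies(pop, "DYS391")
        assert ft.entries["10"] == (3, 0.75)
        assert ft.entries["11"] == (1, 0.25)

    def test_multicopy_pair_unit_counting(self):
        pairs = [(13, 17), (13, 17), (14, 18)]
        haps = []
        for i, pair in enumerate(pairs):
            calls = {m.name: (Allele(10),) * m.copy_number for m in YFILER_PLUS_27.markers}
            calls["DYS385a/b"] = tuple(Allele(x) for x in pair)
            haps.append(Haplotype(f"s{i}", calls))
        ft = allele_frequencies(
            PopulationSample("p", YFILER_PLUS_27, haps), "DYS385a/b"
        )
        assert ft.entries["13-17"] == (2, pytest.approx(2 / 3))
        assert ft.n_units == 2

    @pytest.mark.parametrize("seed", [0, 1])
    def test_frequencies_sum_to_one_vs_brute_tally(self, seed):
        pop = from_spectrum({1: 150, 2: 20, 5: 2}, YFILER_PLUS_27, seed=seed)
        for m in pop.panel.markers:
            ft = allele_frequencies(pop, m.name)
            assert sum(ft.frequencies) == pytest.approx(1.0, abs=1e-12)
            # brute-force tally of unit labels
            tally = Counter(
                "-".join(str(a) for a in h.alleles(m.name)) for h in pop.haplotypes
            )
            assert {k: c for k, (c, _) in ft.entries.items()} == dict(tally)


class TestGeneDiversity:
    def test_monomorphic_is_zero(self):
        pop = make_single_locus_pop("p", [10] * 8)
        assert gene_diversity(allele_frequencies(pop, "DYS391")) == pytest.approx(0.0)

    def test_two_samples_two_alleles_is_one(self):
        pop = make_single_locus_pop("p", [10, 11])
        assert gene_diversity(allele_frequencies(pop, "DYS391")) == pytest.approx(1.0)

    def test_hand_arithmetic_counts_2_1_1(self):
        # sum p^2 = (2/4)^2 + 2*(1/4)^2 = 0.375; GD = (4/3)*0.625
        pop = make_single_locus_pop("p", [10, 10, 11, 12])
        gd = gene_diversity(allele_frequencies(pop, "DYS391"))
        assert gd == pytest.approx(4 / 3 * 0.625, abs=1e-12)

    def test_undefined_below_two_samples(self):
        pop = make_single_locus_pop("p", [10])
        with pytest.raises(UndefinedStatisticError):
            gene_diversity(allele_frequencies(pop, "DYS391"))


class TestSpectrum:
    def test_census_of_small_multiset(self):
        # haplotypes {A, A, B, C, D} -> spectrum {1:3, 2:1}, k=4
        pop = make_single_locus_pop("p", [10, 10, 11, 12, 13])
        spec = haplotype_spectrum(pop)
        assert spec.counts == {1: 3, 2: 1}
        assert spec.k == 4 and spec.n == 5

    def test_spectrum_consistency_invariants(self):
        spec = HaplotypeSpectrum(SPECTRUM_27)
        assert spec.n == 431 and spec.k == 417

    @pytest.mark.parametrize("seed", range(3))
    def test_projection_census_brute_force(self, seed):
        pop = from_spectrum({1: 30, 2: 5}, YFILER_PLUS_27, seed=seed)
        k27 = len(set(h.key(YFILER_PLUS_27) for h in pop.haplotypes))
        k17 = len(set(h.key(YFILER_17) for h in pop.haplotypes))
        assert haplotype_spectrum(pop).k == k27
        assert haplotype_spectrum(pop, YFILER_17).k == k17
        assert k17 <= k27


class TestHaplotypeStatistics:
    def test_hd_hand_arithmetic(self):
        # {1:3, 2:1}, n=5: sum p^2 = 3*(0.2^2) + 0.4^2 = 0.28 -> HD = 1.25*0.72
        assert haplotype_diversity(HaplotypeSpectrum({1: 3, 2: 1})) == pytest.approx(0.9)

    def test_hd_all_unique_is_exactly_one(self):
        for n in (2, 5, 100):
            assert haplotype_diversity(HaplotypeSpectrum({1: n})) == pytest.approx(
                1.0, abs=1e-15
            )

    def test_hd_from_printed_27_locus_spectrum(self):
        # sum p^2 = (405 + 10*4 + 2*9)/431^2 = 463/431^2
        hd = haplotype_diversity(HaplotypeSpectrum(SPECTRUM_27))
        assert hd == pytest.approx(431 / 430 * (1 - 463 / 431**2), abs=1e-15)
        assert round(hd, 6) == 0.999827

    @pytest.mark.parametrize(
        "spectrum, expected_dc",
        [(SPECTRUM_27, 0.9675), (SPECTRUM_17, 0.8608)],
    )
    def test_dc_matches_published_4dp(self, spectrum, expected_dc):
        assert round(discrimination_capacity(HaplotypeSpectrum(spectrum)), 4) == expected_dc

    @pytest.mark.parametrize(
        "spectrum, expected",
        [(SPECTRUM_27, 0.9712), (SPECTRUM_17, 0.8841)],
    )
    def test_proportion_unique_matches_published_4dp(self, spectrum, expected):
        assert round(proportion_unique(HaplotypeSpectrum(spectrum)), 4) == expected

    def test_rmp_17_locus_matches_published_4dp(self):
        # sum p^2 = (328 + 33*4 + 6*9 + 16 + 3*25)/431^2 = 605/431^2
        rmp = random_match_probability(HaplotypeSpectrum(SPECTRUM_17))
        assert rmp == pytest.approx(605 / 431**2, abs=1e-15)
        assert round(rmp, 4) == 0.0033

    def test_rmp_single_shared_haplotype_is_one(self):
        assert random_match_probability(HaplotypeSpectrum({7: 1})) == pytest.approx(1.0)

    def test_rmp_hand_arithmetic(self):
        assert random_match_probability(HaplotypeSpectrum({1: 3, 2: 1})) == pytest.approx(0.28)

    @given(spectra)
    def test_rmp_hd_algebraic_identity(self, counts):
        spec = HaplotypeSpectrum(counts)
        if spec.n < 2:
            return
        n = spec.n
        rmp = random_match_probability(spec)
        hd = haplotype_diversity(spec)
        assert rmp + hd * (n - 1) / n == pytest.approx(1.0, abs=1e-12)

    def test_brute_force_pairwise_identity_equals_sum_p_squared(self):
        pop = from_spectrum({1: 300, 2: 60, 3: 20, 5: 4}, YFILER_PLUS_27, seed=7)
        spec = haplotype_spectrum(pop)
        keys = [h.key(YFILER_PLUS_27) for h in pop.haplotypes]
        n = len(keys)
        matches = sum(keys[i] == keys[j] for i in range(n) for j in range(n))
        assert spec.sum_p_squared() == pytest.approx(matches / n**2, abs=1e-12)


class TestForensicReport:
    def test_monotonicity_17_vs_27(self, maoming_fixture):
        rep17, rep27 = forensic_report(maoming_fixture)
        assert rep27.k >= rep17.k
        assert rep27.hd >= rep17.hd
        assert rep27.dc >= rep17.dc

    def test_identical_haplotype_population(self):
        pop = make_single_locus_pop("p", [10] * 6)
        rep17, rep27 = forensic_report(pop)
        for rep in (rep17, rep27):
            assert rep.dc == pytest.approx(1 / 6)
            assert rep.hd == pytest.approx(0.0)
            assert rep.rmp == pytest.approx(1.0)

    def test_report_agrees_with_direct_recomputation(self, maoming_fixture):
        rep17, rep27 = forensic_report(maoming_fixture)
        spec = haplotype_spectrum(maoming_fixture)
        assert rep27.spectrum.counts == spec.counts
        assert rep27.hd == pytest.approx(haplotype_diversity(spec))
        assert rep27.locus_gd["DYS391"] == pytest.approx(
            gene_diversity(allele_frequencies(maoming_fixture, "DYS391"))
        )
        assert set(rep17.locus_gd) == set(YFILER_17.marker_names)
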