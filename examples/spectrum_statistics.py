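"""Diversity statistics straight from a haplotype multiplicity spectrum.

HD, DC, RMP and the proportion of unique haplotypes depend on the data only
through the multiplicity spectrum (how many haplotypes were seen once,
twice, ...), so published spectra can be analysed directly.
"""

from ystrkit import (
    HaplotypeSpectrum,
    discrimination_capacity,
    haplotype_diversity,
    proportion_unique,
    random_match_probability,
)

# 431 males: 17-locus panel saw 328 singletons, 33 doubletons, 6 tripletons,
# 1 quadrupleton and 3 quintupletons; 27 loci resolved this to 405/10/2.
spectra = {
    "17 loci": HaplotypeSpectrum({1: 328, 2: 33, 3: 6, 4: 1, 5: 3}),
    "27 loci": HaplotypeSpectrum({1: 405, 2: 10, 3: 2}),
}

print("panel     n    k    HD       DC       RMP      unique")
for name, spec in spectra.items():
    print(
        f"{name:<8}{spec.n:>5}{spec.k:>5}"
        f"{haplotype_diversity(spec):>9.4f}"
        f"{discrimination_capacity(spec):>9.4f}"
        f"{random_match_probability(spec):>9.4f}"
        f"{proportion_unique(spec):>9.4f}"
    )

# DC = k/n is the fraction of males carrying a distinguishable profile;
# RMP = sum p_i^2 is the chance a random pair shares a haplotype.
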