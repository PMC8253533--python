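"""Direct-counting frequency estimation and forensic summary parameters.

All statistics follow the standard forensic definitions:

* gene diversity (GD) per locus: ``n/(n-1) * (1 - sum p_i^2)`` over allele
  frequencies (Nei's unbiased heterozygosity);
* haplotype diversity (HD): the same statistic over whole-haplotype
  frequencies;
* discrimination capacity (DC): distinct haplotypes / sample size;
* random match probability (RMP): ``sum p_i^2`` over haplotype frequencies
  (so ``RMP + HD*(n-1)/n = 1`` identically).

Multi-copy markers (DYS385a/b, DYF387S1a/b) are counted as unordered pair
configurations ("13-17") with denominator n, matching how forensic kits
report them.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .core import (
    Haplotype,
    Panel,
    PopulationSample,
    YFILER_17,
    YFILER_PLUS_27,
)

__all__ = [
    "FrequencyTable",
    "HaplotypeSpectrum",
    "ForensicReport",
    "allele_frequencies",
    "gene_diversity",
    "haplotype_spectrum",
    "haplotype_diversity",
    "discrimination_capacity",
    "random_match_probability",
    "proportion_unique",
    "forensic_report",
]


class UndefinedStatisticError(ValueError):
    """Raised when a diversity statistic is undefined (e.g. n < 2)."""


@dataclass
class FrequencyTable:
    """Direct-count allele (or allele-pair) frequencies at one marker."""

    marker: str
    entries: dict[str, tuple[int, float]]  # unit label -> (count, frequency)
    n: int  # denominator

    def __post_init__(self) -> None:
        total = sum(c for c, _ in self.entries.values())
        if total != self.n:
            raise ValueError(
                f"{self.marker}: counts sum to {total}, expected denominator {self.n}"
            )

    @property
    def frequencies(self) -> list[float]:
        return [f for _, f in self.entries.values()]

    @property
    def n_units(self) -> int:
        return len(self.entries)

    def sum_p_squared(self) -> float:
        return sum(c * c for c, _ in self.entries.values()) / (self.n * self.n)


@dataclass
class HaplotypeSpectrum:
    """Multiplicity -> number-of-distinct-haplotypes map.

    E.g. ``{1: 405, 2: 10, 3: 2}`` means 405 singletons, 10 haplotypes seen
    twice and 2 seen three times (n = 431, k = 417).
    """

    counts: dict[int, int]

    def __post_init__(self) -> None:
        for mult, cnt in self.counts.items():
            if mult < 1 or cnt < 0:
                raise ValueError(f"invalid spectrum entry {mult}: {cnt}")
        self.counts = {m: c for m, c in sorted(self.counts.items()) if c > 0}

    @property
    def n(self) -> int:
        """Total sample size."""
        return sum(mult * cnt for mult, cnt in self.counts.items())

    @property
    def k(self) -> int:
        """Number of distinct haplotypes."""
        return sum(self.counts.values())

    @property
    def n_singletons(self) -> int:
        return self.counts.get(1, 0)

    def sum_p_squared(self) -> float:
        n = self.n
        return sum(cnt * mult * mult for mult, cnt in self.counts.items()) / (n * n)


def allele_frequencies(pop: PopulationSample, marker: str) -> FrequencyTable:
    """Direct-counting allele frequencies at one marker.

    Single-copy markers count alleles with denominator n.  Multi-copy markers
    count canonical sorted pair configurations (unit "13-17") with denominator
    n, so DYS385a/b's units are genotype configurations, not individual
    alleles.
    """
    mdef = pop.panel.marker(marker)
    haps = pop.complete_haplotypes()
    if not haps:
        raise UndefinedStatisticError(f"no complete haplotypes for {marker}")
    counter: Counter[str] = Counter()
    for h in haps:
        alleles = h.alleles(mdef.name)
        if mdef.copy_number == 1:
            counter[str(alleles[0])] += 1
        else:
            counter["-".join(str(a) for a in alleles)] += 1
    n = len(haps)

    def sort_key(label: str) -> tuple[float, ...]:
        return tuple(float(part) for part in label.split("-"))

    entries = {
        label: (counter[label], counter[label] / n)
        for label in sorted(counter, key=sort_key)
    }
    return FrequencyTable(mdef.name, entries, n)


def gene_diversity(freqs: FrequencyTable) -> float:
    """GD = n/(n-1) * (1 - sum p_i^2); 0 iff the marker is monomorphic."""
    n = freqs.n
    if n < 2:
        raise UndefinedStatisticError(f"GD undefined for n={n} (< 2)")
    return n / (n - 1) * (1.0 - freqs.sum_p_squared())


def haplotype_spectrum(
    pop: PopulationSample, panel: Panel | None = None
) -> HaplotypeSpectrum:
    """Exact multiset census of canonical haplotypes on *panel*.

    *panel* defaults to the population's own panel; passing a sub-panel
    censuses the projected haplotypes.
    """
    panel = panel or pop.panel
    if panel is not pop.panel and not panel.is_subpanel_of(pop.panel):
        raise ValueError(f"{panel.name} is not a sub-panel of {pop.panel.name}")
    keys = [h.key(panel) for h in pop.complete_haplotypes()]
    multiplicity = Counter(Counter(keys).values())
    return HaplotypeSpectrum(dict(multiplicity))


def haplotype_diversity(spec: HaplotypeSpectrum) -> float:
    """HD = n/(n-1) * (1 - sum p_i^2) over haplotype frequencies."""
    n = spec.n
    if n < 2:
        raise UndefinedStatisticError(f"HD undefined for n={n} (< 2)")
    return n / (n - 1) * (1.0 - spec.sum_p_squared())


def discrimination_capacity(spec: HaplotypeSpectrum) -> float:
    """DC = k/n: distinct haplotypes divided by sample size."""
    if spec.n < 1:
        raise UndefinedStatisticError("DC undefined for empty sample")
    return spec.k / spec.n


def random_match_probability(spec: HaplotypeSpectrum) -> float:
    """RMP = sum p_i^2: the chance two random males share a haplotype."""
    if spec.n < 1:
        raise UndefinedStatisticError("RMP undefined for empty sample")
    return spec.sum_p_squared()


def proportion_unique(spec: HaplotypeSpectrum) -> float:
    """Singleton haplotypes as a fraction of distinct haplotypes (k)."""
    if spec.k < 1:
        raise UndefinedStatisticError("proportion unique undefined for k=0")
    return spec.n_singletons / spec.k


@dataclass
class ForensicReport:
    """Per-panel forensic summary: locus GD plus haplotype-level statistics."""

    panel_name: str
    n: int
    spectrum: HaplotypeSpectrum
    locus_gd: dict[str, float] = field(default_factory=dict)

    @property
    def k(self) -> int:
        return self.spectrum.k

    @property
    def hd(self) -> float:
        return haplotype_diversity(self.spectrum)

    @property
    def dc(self) -> float:
        return discrimination_capacity(self.spectrum)

    @property
    def rmp(self) -> float:
        return random_match_probability(self.spectrum)

    @property
    def proportion_unique(self) -> float:
        return proportion_unique(self.spectrum)


def _single_panel_report(pop: PopulationSample) -> ForensicReport:
    spec = haplotype_spectrum(pop)
    gd = {
        m.name: gene_diversity(allele_frequencies(pop, m.name))
        for m in pop.panel.markers
    }
    return ForensicReport(pop.panel.name, spec.n, spec, gd)


def forensic_report(
    pop: PopulationSample,
) -> tuple[ForensicReport, ForensicReport]:
    """Forensic reports on the 17-locus projection and the full 27-locus panel.

    Both are computed from the same samples, so adding loci can only split
    haplotype classes: k, HD and DC on 27 loci are >= their 17-locus values.
    """
    if pop.panel.name != YFILER_PLUS_27.name:
        raise ValueError(
            f"forensic_report expects a {YFILER_PLUS_27.name} population, got {pop.panel.name}"
        )
    return _single_panel_report(pop.project(YFILER_17)), _single_panel_report(pop)
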