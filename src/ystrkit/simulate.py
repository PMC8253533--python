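"""Synthetic Y-STR data generators.

Two kinds of synthetic data feed the tests and worked examples:

* exact-spectrum constructions: given a haplotype multiplicity spectrum
  (e.g. 405 singletons, 10 doubletons, 2 tripletons), build a population
  whose haplotype census reproduces it exactly;
* a stepwise-mutation-model (SMM) simulator of diverging male populations:
  independent paternal lineages (star genealogy) mutate each locus with
  per-generation probability mu, each mutation adding or removing one full
  repeat with equal probability.  Divergence time t tunes differentiation,
  so pairwise Rst can be dialled from ~0 up to strong structure.

Founder allele ranges per locus are hard-coded plausible ranges from
published allele ladders — synthetic values, not estimates of any real
population's frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    Allele,
    Haplotype,
    Panel,
    PopulationSample,
    YFILER_PLUS_27,
)
from .forensic import HaplotypeSpectrum

__all__ = [
    "SimConfig",
    "FOUNDER_ALLELE_RANGES",
    "from_spectrum",
    "simulate_populations",
    "maoming_like_fixture",
]

# Plausible full-repeat ranges (lo, hi inclusive) per marker, from published
# allele ladders.  Synthetic: founders are drawn uniformly from these.
FOUNDER_ALLELE_RANGES: dict[str, tuple[int, int]] = {
    "DYS19": (13, 17),
    "DYS385a/b": (11, 20),
    "DYS389I": (12, 14),
    "DYS389II": (28, 32),
    "DYS390": (21, 25),
    "DYS391": (9, 12),
    "DYS392": (11, 15),
    "DYS393": (12, 15),
    "DYS437": (14, 16),
    "DYS438": (9, 12),
    "DYS439": (10, 13),
    "DYS448": (18, 21),
    "DYS456": (14, 17),
    "DYS458": (15, 19),
    "DYS635": (20, 24),
    "YGATAH4": (11, 13),
    "DYS449": (27, 34),
    "DYS460": (10, 12),
    "DYS481": (22, 27),
    "DYS518": (36, 42),
    "DYS533": (11, 13),
    "DYS570": (16, 20),
    "DYS576": (16, 20),
    "DYS627": (18, 23),
    "DYF387S1a/b": (35, 40),
}


def _random_haplotype(
    sample_id: str, panel: Panel, rng: np.random.Generator
) -> Haplotype:
    calls: dict[str, tuple[Allele, ...]] = {}
    for m in panel.markers:
        lo, hi = FOUNDER_ALLELE_RANGES[m.name]
        reps = rng.integers(lo, hi + 1, size=m.copy_number)
        calls[m.name] = tuple(Allele(int(r)) for r in reps)
    return Haplotype(sample_id, calls)


def from_spectrum(
    spectrum: HaplotypeSpectrum | dict[int, int],
    panel: Panel = YFILER_PLUS_27,
    seed: int = 0,
) -> PopulationSample:
    """Build a population whose haplotype census equals *spectrum* exactly.

    Generates k pairwise-distinct random haplotypes on the panel and
    replicates each to its multiplicity.  Deterministic given the seed.
    """
    if not isinstance(spectrum, HaplotypeSpectrum):
        spectrum = HaplotypeSpectrum(dict(spectrum))
    rng = np.random.default_rng(seed)
    k = spectrum.k
    distinct: list[Haplotype] = []
    seen: set[Haplotype] = set()
    attempts = 0
    while len(distinct) < k:
        h = _random_haplotype(f"D{len(distinct):04d}", panel, rng)
        if h not in seen:
            seen.add(h)
            distinct.append(h)
        attempts += 1
        if attempts > 50 * k + 1000:
            raise RuntimeError("could not generate enough distinct haplotypes")
    haplotypes: list[Haplotype] = []
    idx = 0
    sample_no = 0
    for mult, count in sorted(spectrum.counts.items()):
        for _ in range(count):
            template = distinct[idx]
            idx += 1
            for _ in range(mult):
                haplotypes.append(
                    Haplotype(f"S{sample_no:04d}", template.calls)
                )
                sample_no += 1
    return PopulationSample("synthetic", panel, haplotypes)


@dataclass
class SimConfig:
    """Stepwise-mutation simulation settings.

    mu is the per-locus per-generation mutation probability (Y-STRs mutate at
    roughly 1e-3 to 1e-2 per generation; rapidly mutating loci at the high
    end).  Each population diverges independently from a common founder for
    ``divergence_generations`` generations.
    """

    populations: list[tuple[str, int]]
    panel: Panel = YFILER_PLUS_27
    divergence_generations: int = 200
    within_generations: int = 200
    mu: float = 0.002
    microvariant_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mu <= 0.05:
            raise ValueError(f"mu must be in [0, 0.05], got {self.mu}")
        if not 0.0 <= self.microvariant_rate <= 1.0:
            raise ValueError("microvariant_rate must be in [0, 1]")
        for name, n in self.populations:
            if n < 2:
                raise ValueError(f"population {name!r} needs n >= 2, got {n}")


def simulate_populations(cfg: SimConfig) -> list[PopulationSample]:
    """Simulate diverging populations under the single-step SMM.

    One founder haplotype is drawn per run.  Each population first inherits a
    population ancestor: the founder evolved for ``divergence_generations``
    (t) — this shared random walk is what creates among-population
    differentiation, so expected Rst grows with t and is ~0 at t = 0.  Each
    of the population's n lineages then evolves independently from that
    ancestor for ``within_generations`` (a star genealogy within populations
    — lineages share no post-ancestor drift, a deliberate simplification).
    Mutation counts per branch/slot are Binomial(generations, mu); each
    mutation steps the repeat count by +/-1 with equal probability.  Fully
    reproducible from the seed.
    """
    rng = np.random.default_rng(cfg.seed)
    panel = cfg.panel
    slots: list[str] = []
    for m in panel.markers:
        slots.extend([m.name] * m.copy_number)
    founder = np.array(
        [
            rng.integers(
                FOUNDER_ALLELE_RANGES[name][0],
                FOUNDER_ALLELE_RANGES[name][1] + 1,
            )
            for name in slots
        ],
        dtype=np.int64,
    )
    t = cfg.divergence_generations
    tw = cfg.within_generations
    out: list[PopulationSample] = []
    for pop_name, n in cfg.populations:
        # shared ancestral random walk: founder -> population ancestor
        anc_mut = rng.binomial(t, cfg.mu, size=len(slots))
        ancestor = founder + 2 * rng.binomial(anc_mut, 0.5) - anc_mut
        # independent lineage walks: ancestor -> sampled males
        n_mut = rng.binomial(tw, cfg.mu, size=(n, len(slots)))
        ups = rng.binomial(n_mut, 0.5)
        repeats = ancestor + 2 * ups - n_mut
        repeats = np.maximum(repeats, 1)  # repeat counts cannot hit zero
        partial = np.zeros_like(repeats)
        if cfg.microvariant_rate > 0.0:
            mask = rng.random(repeats.shape) < cfg.microvariant_rate
            partial = np.where(mask, rng.integers(1, 4, size=repeats.shape), 0)
        haplotypes = []
        for i in range(n):
            calls: dict[str, list[Allele]] = {}
            for s, name in enumerate(slots):
                calls.setdefault(name, []).append(
                    Allele(int(repeats[i, s]), int(partial[i, s]))
                )
            haplotypes.append(
                Haplotype(f"{pop_name}_{i:04d}", {k: tuple(v) for k, v in calls.items()})
            )
        out.append(PopulationSample(pop_name, panel, haplotypes))
    return out


# The nine off-ladder occurrences reported for the 431-male reference cohort:
# marker -> list of microvariant alleles, one occurrence each.
_FIXTURE_MICROVARIANTS: list[tuple[str, Allele]] = [
    ("DYS448", Allele(18, 2)),
    ("DYS448", Allele(18, 2)),
    ("DYS448", Allele(19, 2)),
    ("DYS458", Allele(18, 2)),
    ("DYS449", Allele(34, 2)),
    ("DYS518", Allele(37, 2)),
    ("DYF387S1a/b", Allele(37, 2)),
    ("DYS627", Allele(17, 2)),
    ("DYS627", Allele(18, 2)),
]


def maoming_like_fixture(seed: int = 0) -> PopulationSample:
    """A 431-male, 27-locus synthetic population with the reference cohort's
    statistical shape: haplotype spectrum {1: 405, 2: 10, 3: 2} and exactly
    nine microvariant occurrences at six markers (DYS448 18.2 x2 and 19.2,
    DYS458 18.2, DYS449 34.2, DYS518 37.2, DYF387S1 37.2, DYS627 17.2 and
    18.2); no null alleles or copy-number variants.
    """
    pop = from_spectrum({1: 405, 2: 10, 3: 2}, YFILER_PLUS_27, seed)
    haplotypes = list(pop.haplotypes)
    # singletons occupy the first 405 slots of the generated ordering; give
    # each of the first nine a single microvariant occurrence
    for i, (marker, allele) in enumerate(_FIXTURE_MICROVARIANTS):
        h = haplotypes[i]
        alleles = list(h.alleles(marker))
        mdef = YFILER_PLUS_27.marker(marker)
        if mdef.copy_number == 1:
            alleles = [allele]
        else:
            alleles[0] = allele  # replace one copy of the pair
        calls = dict(h.calls)
        calls[marker] = tuple(alleles)
        haplotypes[i] = Haplotype(h.sample_id, calls)
    out = PopulationSample("MaomingLike", YFILER_PLUS_27, haplotypes)
    # microvariant placement must not merge haplotype classes
    from .forensic import haplotype_spectrum

    if haplotype_spectrum(out).counts != {1: 405, 2: 10, 3: 2}:
        raise RuntimeError("fixture spectrum perturbed by microvariant placement")
    return out
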