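"""Domain types for Y-STR forensic haplotype data.

A Y-STR allele is a repeat designation: a number of full repeat units plus,
for microvariant ("off-ladder" / intermediate) alleles, 1-3 extra nucleotides
beyond the last full repeat, written in the standard decimal nomenclature
("18.2" = 18 full repeats + 2 nt).  A haplotype is one male's joint profile
across a marker panel; multi-copy markers (DYS385a/b, DYF387S1a/b) amplify two
Y-chromosome loci and yield an unordered allele pair per sample.

Two marker panels are built in: the 17-locus Yfiler set and the 27-locus
Yfiler Plus set (a strict superset, so a 27-locus population can be projected
onto the 17-locus panel).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Allele",
    "MarkerDef",
    "Panel",
    "Haplotype",
    "PopulationSample",
    "QCReport",
    "YFILER_17",
    "YFILER_PLUS_27",
    "AlleleParseError",
    "HaplotypeError",
    "parse_allele",
    "canonicalize_haplotype",
    "qc_screen",
    "normalize_marker_name",
]


class AlleleParseError(ValueError):
    """Raised when an allele token cannot be interpreted."""


class HaplotypeError(ValueError):
    """Raised for incomplete haplotypes or copy-number violations in strict mode."""


_ALLELE_RE = re.compile(r"^(\d+)(?:\.(\d))?$")


@dataclass(frozen=True, order=True)
class Allele:
    """A repeat designation: full repeat count plus 0-3 partial nucleotides.

    Ordering is lexicographic in (full_repeats, partial_nt), which coincides
    with ordering by numeric score.
    """

    full_repeats: int
    partial_nt: int = 0

    def __post_init__(self) -> None:
        if self.full_repeats < 0:
            raise AlleleParseError(f"negative repeat count: {self.full_repeats}")
        if not 0 <= self.partial_nt <= 3:
            raise AlleleParseError(
                f"partial_nt must be 0-3 (tetranucleotide nomenclature), got {self.partial_nt}"
            )

    def score(self, mode: str = "decimal", motif_length: int = 4) -> float:
        """Numeric repeat score used in molecular distances.

        ``decimal`` (default) reads the printed designation as a number
        (18.2 -> 18.2); ``proportional`` scores partial repeats as a fraction
        of the repeat motif (18.2 -> 18 + 2/4).
        """
        if mode == "decimal":
            return self.full_repeats + self.partial_nt / 10.0
        if mode == "proportional":
            return self.full_repeats + self.partial_nt / motif_length
        raise ValueError(f"unknown score mode: {mode!r}")

    @property
    def is_microvariant(self) -> bool:
        return self.partial_nt > 0

    def __str__(self) -> str:
        if self.partial_nt == 0:
            return str(self.full_repeats)
        return f"{self.full_repeats}.{self.partial_nt}"


def parse_allele(token: str) -> Allele:
    """Parse an allele designation such as ``"12"`` or ``"18.2"``.

    Raises :class:`AlleleParseError` for malformed tokens (letters, negatives,
    partial repeats outside 1-3).
    """
    token = token.strip()
    m = _ALLELE_RE.match(token)
    if m is None:
        raise AlleleParseError(f"malformed allele token: {token!r}")
    full = int(m.group(1))
    partial = int(m.group(2)) if m.group(2) is not None else 0
    if not 0 <= partial <= 3:
        raise AlleleParseError(
            f"malformed allele token: {token!r} (partial repeat {partial} outside 0-3)"
        )
    return Allele(full, partial)


@dataclass(frozen=True)
class MarkerDef:
    """A marker (locus) in a panel; copy_number is the value slots it contributes."""

    name: str
    copy_number: int = 1

    def __post_init__(self) -> None:
        if self.copy_number not in (1, 2):
            raise ValueError(f"copy_number must be 1 or 2, got {self.copy_number}")


# Canonical internal marker names.  Dialect variants are normalized on input.
_MARKER_ALIASES = {
    "DYS385": "DYS385a/b",
    "DYS385AB": "DYS385a/b",
    "DYS385A/B": "DYS385a/b",
    "DYF387S1": "DYF387S1a/b",
    "DYF387S1AB": "DYF387S1a/b",
    "DYF387S1A/B": "DYF387S1a/b",
    "YGATAH4": "YGATAH4",
    "YGATA H4": "YGATAH4",
    "Y GATA H4": "YGATAH4",
    "Y-GATA-H4": "YGATAH4",
    "GATAH4": "YGATAH4",
    "GATA H4": "YGATAH4",
}


def normalize_marker_name(name: str) -> str:
    """Map marker-name dialects onto one internal name.

    ``"Y GATA H4"``, ``"YGATAH4"`` and ``"Y-GATA-H4"`` all map to ``YGATAH4``;
    ``"DYS385"`` maps to the two-copy marker ``DYS385a/b``.
    """
    key = name.strip()
    upper = key.upper()
    if upper in _MARKER_ALIASES:
        return _MARKER_ALIASES[upper]
    compact = upper.replace(" ", "").replace("-", "").replace("_", "")
    if compact in _MARKER_ALIASES:
        return _MARKER_ALIASES[compact]
    return key


@dataclass(frozen=True)
class Panel:
    """An ordered marker panel; slot count = sum of copy numbers."""

    name: str
    markers: tuple[MarkerDef, ...]

    @property
    def n_slots(self) -> int:
        return sum(m.copy_number for m in self.markers)

    @property
    def marker_names(self) -> tuple[str, ...]:
        return tuple(m.name for m in self.markers)

    def marker(self, name: str) -> MarkerDef:
        name = normalize_marker_name(name)
        for m in self.markers:
            if m.name == name:
                return m
        raise KeyError(f"marker {name!r} not in panel {self.name}")

    def __contains__(self, name: str) -> bool:
        return normalize_marker_name(name) in self.marker_names

    def is_subpanel_of(self, other: "Panel") -> bool:
        return set(self.marker_names) <= set(other.marker_names)


_YFILER_17_ORDER = [
    "DYS19",
    "DYS385a/b",
    "DYS389I",
    "DYS389II",
    "DYS390",
    "DYS391",
    "DYS392",
    "DYS393",
    "DYS437",
    "DYS438",
    "DYS439",
    "DYS448",
    "DYS456",
    "DYS458",
    "DYS635",
    "YGATAH4",
]

_YFILER_PLUS_EXTRA = [
    "DYS449",
    "DYS460",
    "DYS481",
    "DYS518",
    "DYS533",
    "DYS570",
    "DYS576",
    "DYS627",
    "DYF387S1a/b",
]

_MULTI_COPY = {"DYS385a/b", "DYF387S1a/b"}

YFILER_17 = Panel(
    "YFILER_17",
    tuple(MarkerDef(m, 2 if m in _MULTI_COPY else 1) for m in _YFILER_17_ORDER),
)

YFILER_PLUS_27 = Panel(
    "YFILER_PLUS_27",
    tuple(
        MarkerDef(m, 2 if m in _MULTI_COPY else 1)
        for m in _YFILER_17_ORDER + _YFILER_PLUS_EXTRA
    ),
)

PANELS = {p.name: p for p in (YFILER_17, YFILER_PLUS_27)}


class Haplotype:
    """One sample's marker -> allele-multiset mapping.

    Multi-copy allele pairs are stored sorted ascending (canonical form): the
    kit cannot distinguish the a/b chromosomal copies, so (17, 13) and
    (13, 17) are the same genotype.  Equality and hashing ignore the sample id
    and compare canonical calls marker-by-marker.
    """

    __slots__ = ("sample_id", "calls", "_key")

    def __init__(self, sample_id: str, calls: Mapping[str, Sequence[Allele]]):
        self.sample_id = sample_id
        self.calls: dict[str, tuple[Allele, ...]] = {
            marker: tuple(sorted(alleles)) for marker, alleles in calls.items()
        }
        self._key = tuple(sorted(self.calls.items()))

    def alleles(self, marker: str) -> tuple[Allele, ...]:
        return self.calls.get(marker, ())

    def key(self, panel: Panel) -> tuple[tuple[Allele, ...], ...]:
        """Canonical identity tuple restricted to *panel*, in panel order."""
        return tuple(self.calls.get(m.name, ()) for m in panel.markers)

    def is_complete(self, panel: Panel) -> bool:
        return all(
            len(self.calls.get(m.name, ())) == m.copy_number for m in panel.markers
        )

    def project(self, panel: Panel) -> "Haplotype":
        return Haplotype(
            self.sample_id,
            {m.name: self.calls.get(m.name, ()) for m in panel.markers},
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Haplotype):
            return NotImplemented
        return self._key == other._key

    def __hash__(self) -> int:
        return hash(self._key)

    def __repr__(self) -> str:
        return f"Haplotype({self.sample_id!r}, {len(self.calls)} markers)"


def canonicalize_haplotype(
    sample_id: str,
    raw: Mapping[str, Sequence[Allele | str]],
    panel: Panel,
    mode: str = "strict",
) -> Haplotype:
    """Build a canonical :class:`Haplotype` from raw per-marker allele lists.

    ``strict`` mode (the default for statistics) rejects missing markers and
    copy-number violations; ``lenient`` mode retains the sample as-is so the
    anomalies can be surfaced by :func:`qc_screen`.
    """
    if mode not in ("strict", "lenient"):
        raise ValueError(f"mode must be 'strict' or 'lenient', got {mode!r}")
    calls: dict[str, tuple[Allele, ...]] = {}
    for marker_name, alleles in raw.items():
        name = normalize_marker_name(marker_name)
        parsed = tuple(
            a if isinstance(a, Allele) else parse_allele(a) for a in alleles
        )
        calls[name] = parsed
    if mode == "strict":
        for m in panel.markers:
            got = calls.get(m.name, ())
            if len(got) == 0:
                raise HaplotypeError(
                    f"sample {sample_id!r}: missing marker {m.name} (incomplete haplotype)"
                )
            if len(got) != m.copy_number:
                raise HaplotypeError(
                    f"sample {sample_id!r}: marker {m.name} has {len(got)} allele(s), "
                    f"expected {m.copy_number}"
                )
    return Haplotype(sample_id, calls)


@dataclass
class PopulationSample:
    """A named collection of haplotypes sharing a panel.

    ``n`` (the total sample size in the diversity formulas) is the number of
    haplotypes, counting repeats.
    """

    population_name: str
    panel: Panel
    haplotypes: list[Haplotype] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [h.sample_id for h in self.haplotypes]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise HaplotypeError(
                f"population {self.population_name!r}: duplicate sample ids {dupes}"
            )

    @property
    def n(self) -> int:
        return len(self.haplotypes)

    def complete_haplotypes(self) -> list[Haplotype]:
        """Haplotypes fully typed on the panel (the unit of the statistics)."""
        return [h for h in self.haplotypes if h.is_complete(self.panel)]

    def project(self, panel: Panel) -> "PopulationSample":
        """Restrict every haplotype to a sub-panel (e.g. 27 -> 17 loci)."""
        if not panel.is_subpanel_of(self.panel):
            raise ValueError(
                f"{panel.name} is not a sub-panel of {self.panel.name}"
            )
        return PopulationSample(
            self.population_name,
            panel,
            [h.project(panel) for h in self.haplotypes],
        )


@dataclass
class QCReport:
    """Per-population quality-control screen results.

    * null alleles: markers with no call in a sample;
    * copy-number variants: samples with more alleles at a marker than the
      panel's copy number (e.g. two alleles at a single-copy locus);
    * microvariant census: occurrence totals of off-ladder alleles
      (partial_nt > 0) per marker.
    """

    population_name: str
    null_allele_records: list[tuple[str, str]]
    cnv_records: list[tuple[str, str, int]]
    microvariant_census: list[tuple[str, Allele, int]]

    @property
    def n_null_alleles(self) -> int:
        return len(self.null_allele_records)

    @property
    def n_cnv(self) -> int:
        return len(self.cnv_records)

    @property
    def n_microvariant_occurrences(self) -> int:
        return sum(count for _, _, count in self.microvariant_census)

    @property
    def n_microvariant_markers(self) -> int:
        return len({marker for marker, _, _ in self.microvariant_census})

    @property
    def is_clean(self) -> bool:
        return not self.null_allele_records and not self.cnv_records


def qc_screen(pop: PopulationSample) -> QCReport:
    """Screen a population for null alleles, copy-number variants and
    microvariant (off-ladder) alleles.

    Always returns a report; a population parsed in lenient mode keeps its
    anomalous samples so they show up here.
    """
    nulls: list[tuple[str, str]] = []
    cnvs: list[tuple[str, str, int]] = []
    census: dict[tuple[str, Allele], int] = {}
    for h in pop.haplotypes:
        for m in pop.panel.markers:
            alleles = h.alleles(m.name)
            if len(alleles) < m.copy_number:
                nulls.append((h.sample_id, m.name))
            elif len(alleles) > m.copy_number:
                cnvs.append((h.sample_id, m.name, len(alleles)))
            for a in alleles:
                if a.is_microvariant:
                    census[(m.name, a)] = census.get((m.name, a), 0) + 1
    micro = sorted(
        [(marker, allele, count) for (marker, allele), count in census.items()],
        key=lambda rec: (rec[0], rec[1]),
    )
    return QCReport(pop.population_name, nulls, cnvs, micro)
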