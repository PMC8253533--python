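"""Readers and writers for haplotype tables, frequency tables, distance
matrices, Newick trees, and run configuration.

Haplotype tables follow the YHRD submission style: one row per male sample,
one column per marker, tab-delimited by default.  Multi-copy markers may
appear either as one combined column ("13-17") or as two split columns
(DYS385a, DYS385b); both dialects parse to identical populations.

All writers are deterministic: identical inputs give byte-identical files.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import (
    Allele,
    Haplotype,
    HaplotypeError,
    Panel,
    PopulationSample,
    parse_allele,
    normalize_marker_name,
)
from .forensic import FrequencyTable
from .nj import NJTree

__all__ = [
    "HaplotypeTableDialect",
    "read_haplotype_table",
    "write_haplotype_table",
    "write_frequency_table",
    "read_frequency_table",
    "write_distance_matrix",
    "read_distance_matrix",
    "write_newick",
    "load_config",
]

_MISSING_TOKENS = {"", "NA", "na", "N/A", "-", "."}


@dataclass(frozen=True)
class HaplotypeTableDialect:
    """Column conventions for haplotype tables."""

    delimiter: str = "\t"
    multicopy_style: str = "combined"  # "combined" ("13-17") or "split" (two columns)
    id_column: str = "SampleID"

    def __post_init__(self) -> None:
        if self.multicopy_style not in ("combined", "split"):
            raise ValueError(
                f"multicopy_style must be 'combined' or 'split', got {self.multicopy_style!r}"
            )


def _resolve_columns(
    columns: list[str], panel: Panel, dialect: HaplotypeTableDialect
) -> dict[str, list[str]]:
    """Map each panel marker to the table column(s) that carry it."""
    norm = {}
    for col in columns:
        if col == dialect.id_column:
            continue
        base = col
        copy_suffix = None
        # split-column names like DYS385a / DYF387S1b
        if col[-1:] in ("a", "b") and normalize_marker_name(col[:-1]) in panel:
            base, copy_suffix = col[:-1], col[-1]
        name = normalize_marker_name(base)
        if name not in panel:
            raise KeyError(f"unknown column {col!r} for panel {panel.name}")
        norm.setdefault(name, []).append((copy_suffix or "", col))
    mapping: dict[str, list[str]] = {}
    for m in panel.markers:
        if m.name not in norm:
            raise KeyError(f"missing column for marker {m.name!r} in table header")
        cols = [c for _, c in sorted(norm[m.name])]
        if m.copy_number == 2 and len(cols) not in (1, 2):
            raise KeyError(f"marker {m.name!r}: expected 1 combined or 2 split columns")
        if m.copy_number == 1 and len(cols) != 1:
            raise KeyError(f"marker {m.name!r}: duplicate columns {cols}")
        mapping[m.name] = cols
    return mapping


def _parse_cell(token: str) -> list[Allele]:
    token = str(token).strip()
    if token in _MISSING_TOKENS:
        return []
    return [parse_allele(part) for part in token.split("-")]


def read_haplotype_table(
    path: str | os.PathLike,
    panel: Panel,
    dialect: HaplotypeTableDialect | None = None,
    population_name: str | None = None,
    mode: str = "strict",
) -> PopulationSample:
    """Read a YHRD-style haplotype table into a :class:`PopulationSample`.

    Missing tokens ("", "NA") yield absent calls: an error in strict mode,
    retained for QC in lenient mode.  Errors name the offending row/column.
    """
    dialect = dialect or HaplotypeTableDialect()
    path = Path(path)
    df = pd.read_csv(path, sep=dialect.delimiter, dtype=str, keep_default_na=False)
    if dialect.id_column not in df.columns:
        raise KeyError(f"id column {dialect.id_column!r} not in {path.name}")
    mapping = _resolve_columns(list(df.columns), panel, dialect)
    haplotypes: list[Haplotype] = []
    for row_no, row in enumerate(df.itertuples(index=False, name=None), start=2):
        record = dict(zip(df.columns, row))
        sid = record[dialect.id_column]
        calls: dict[str, tuple[Allele, ...]] = {}
        for m in panel.markers:
            alleles: list[Allele] = []
            for col in mapping[m.name]:
                try:
                    alleles.extend(_parse_cell(record[col]))
                except Exception as exc:
                    raise HaplotypeError(
                        f"{path.name} row {row_no}, column {col!r}: {exc}"
                    ) from exc
            if mode == "strict" and len(alleles) != m.copy_number:
                raise HaplotypeError(
                    f"{path.name} row {row_no} (sample {sid!r}): marker {m.name} "
                    f"has {len(alleles)} allele(s), expected {m.copy_number}"
                )
            calls[m.name] = tuple(alleles)
        haplotypes.append(Haplotype(sid, calls))
    name = population_name or path.stem
    return PopulationSample(name, panel, haplotypes)


def write_haplotype_table(
    pop: PopulationSample,
    path: str | os.PathLike,
    dialect: HaplotypeTableDialect | None = None,
) -> None:
    """Write a population as a haplotype table (inverse of the reader)."""
    dialect = dialect or HaplotypeTableDialect()
    columns: list[str] = [dialect.id_column]
    for m in pop.panel.markers:
        if m.copy_number == 2 and dialect.multicopy_style == "split":
            base = m.name.replace("a/b", "")
            columns.extend([f"{base}a", f"{base}b"])
        else:
            columns.append(m.name)
    rows = []
    for h in pop.haplotypes:
        row: list[str] = [h.sample_id]
        for m in pop.panel.markers:
            alleles = h.alleles(m.name)
            if m.copy_number == 2 and dialect.multicopy_style == "split":
                padded = [str(a) for a in alleles] + [""] * (2 - len(alleles))
                row.extend(padded[:2])
            else:
                row.append("-".join(str(a) for a in alleles))
        rows.append(row)
    pd.DataFrame(rows, columns=columns).to_csv(
        path, sep=dialect.delimiter, index=False, lineterminator="\n"
    )


def write_frequency_table(
    freqs: list[FrequencyTable], path: str | os.PathLike, decimals: int = 4
) -> None:
    """Write per-marker frequency tables as CSV.

    Columns: marker, allele, count, frequency (rounded to *decimals*) and
    frequency_raw (full precision, machine-readable).
    """
    rows = []
    for ft in freqs:
        total = sum(f for _, f in ft.entries.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"{ft.marker}: frequencies sum to {total}, not 1")
        for label, (count, freq) in ft.entries.items():
            rows.append(
                {
                    "marker": ft.marker,
                    "allele": label,
                    "count": count,
                    "frequency": f"{freq:.{decimals}f}",
                    "frequency_raw": repr(freq),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False, lineterminator="\n")


def read_frequency_table(path: str | os.PathLike) -> list[FrequencyTable]:
    """Read back a frequency-table CSV (counts reproduce exactly)."""
    df = pd.read_csv(path, dtype={"allele": str})
    out = []
    for marker, grp in df.groupby("marker", sort=False):
        n = int(grp["count"].sum())
        entries = {
            str(allele): (int(count), int(count) / n)
            for allele, count in zip(grp["allele"], grp["count"])
        }
        out.append(FrequencyTable(str(marker), entries, n))
    return out


def write_distance_matrix(
    matrix: np.ndarray,
    labels: list[str],
    path: str | os.PathLike,
    format: str = "csv",
) -> None:
    """Write a square symmetric distance matrix as labeled CSV or PHYLIP square."""
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    if matrix.shape != (n, n) or len(labels) != n:
        raise ValueError("matrix must be square with matching labels")
    if not np.allclose(matrix, matrix.T, rtol=0, atol=1e-12):
        raise ValueError("matrix is not symmetric (beyond 1e-12)")
    if not np.allclose(np.diag(matrix), 0.0, rtol=0, atol=1e-12):
        raise ValueError("matrix diagonal is not zero")
    path = Path(path)
    if format == "csv":
        df = pd.DataFrame(matrix, index=labels, columns=labels)
        df = df.map(lambda x: repr(float(x)))
        df.to_csv(path, index_label="", lineterminator="\n")
    elif format == "phylip":
        with open(path, "w") as fh:
            fh.write(f"{n}\n")
            for label, row in zip(labels, matrix):
                safe = label.replace(" ", "_")
                fh.write(safe + "\t" + "\t".join(repr(float(x)) for x in row) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_distance_matrix(
    path: str | os.PathLike, format: str = "csv"
) -> tuple[np.ndarray, list[str]]:
    """Read a distance matrix written by :func:`write_distance_matrix`."""
    path = Path(path)
    if format == "csv":
        df = pd.read_csv(path, index_col=0)
        return df.to_numpy(dtype=float), [str(x) for x in df.index]
    if format == "phylip":
        with open(path) as fh:
            n = int(fh.readline().strip())
            labels, rows = [], []
            for _ in range(n):
                parts = fh.readline().rstrip("\n").split("\t")
                labels.append(parts[0].replace("_", " "))
                rows.append([float(x) for x in parts[1:]])
        return np.asarray(rows), labels
    raise ValueError(f"unknown format {format!r}")


def write_newick(tree: NJTree | str, path: str | os.PathLike) -> None:
    """Write a tree (or a pre-rendered Newick string) to a file."""
    newick = tree if isinstance(tree, str) else tree.to_newick()
    with open(path, "w") as fh:
        fh.write(newick + "\n")


def load_config(path: str | os.PathLike) -> dict:
    """Load a YAML run-configuration file into a plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return cfg
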