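"""End-to-end orchestration: QC -> forensic parameters -> pairwise Rst with
permutation significance -> MDS coordinates -> NJ tree.

A run is driven by one configuration mapping (usually loaded from YAML) and
produces a :class:`RunManifest` recording the config snapshot, input file
digests, seeds and per-stage outputs, so a rerun with the same manifest is
byte-identical.

Single-population runs stop after the forensic report (there is nothing to
compare); multi-population runs add the Rst/MDS/NJ stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .amova import pairwise_rst
from .core import PANELS, YFILER_PLUS_27, PopulationSample, qc_screen
from .forensic import (
    allele_frequencies,
    forensic_report,
    haplotype_spectrum,
    _single_panel_report,
)
from .io_tables import (
    HaplotypeTableDialect,
    read_haplotype_table,
    write_distance_matrix,
    write_frequency_table,
    write_newick,
)
from .mds import classical_mds
from .nj import neighbor_joining

__all__ = ["RunManifest", "run_pipeline"]

log = logging.getLogger("ystrkit")


@dataclass
class RunManifest:
    """Reproducibility record for one pipeline run."""

    config: dict
    input_digests: dict[str, str]
    seed: int
    version: str
    outputs: dict[str, list[str]] = field(default_factory=dict)  # names relative to the run dir

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "config": self.config,
                    "input_digests": self.input_digests,
                    "seed": self.seed,
                    "version": self.version,
                    "outputs": self.outputs,
                },
                fh,
                indent=2,
                sort_keys=True,
            )
            fh.write("\n")


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _fmt(x: float, decimals: int = 4) -> str:
    return f"{x:.{decimals}f}"


def _forensic_stage(
    pop: PopulationSample, out_dir: Path, manifest: RunManifest
) -> None:
    outputs: list[str] = []
    if pop.panel.name == YFILER_PLUS_27.name:
        reports = forensic_report(pop)
    else:
        reports = (_single_panel_report(pop),)
    summary_lines = []
    for rep in reports:
        summary_lines.append(
            json.dumps(
                {
                    "panel": rep.panel_name,
                    "n": rep.n,
                    "k": rep.k,
                    "spectrum": {str(m): c for m, c in rep.spectrum.counts.items()},
                    "HD": rep.hd,
                    "HD_4dp": _fmt(rep.hd),
                    "DC": rep.dc,
                    "DC_4dp": _fmt(rep.dc),
                    "RMP": rep.rmp,
                    "RMP_4dp": _fmt(rep.rmp),
                    "proportion_unique": rep.proportion_unique,
                    "proportion_unique_4dp": _fmt(rep.proportion_unique),
                    "locus_GD": {m: g for m, g in sorted(rep.locus_gd.items())},
                },
                sort_keys=True,
            )
        )
    summary_path = out_dir / f"forensic_{pop.population_name}.jsonl"
    summary_path.write_text("\n".join(summary_lines) + "\n")
    outputs.append(summary_path.name)

    freqs = [allele_frequencies(pop, m.name) for m in pop.panel.markers]
    freq_path = out_dir / f"frequencies_{pop.population_name}.csv"
    write_frequency_table(freqs, freq_path)
    outputs.append(freq_path.name)
    manifest.outputs[f"forensic:{pop.population_name}"] = outputs


def run_pipeline(config: dict, out_dir: str | Path) -> RunManifest:
    """Run the full analysis described by *config* into *out_dir*.

    Config keys: ``populations`` (list of {name, path}), ``panel``
    (YFILER_17 | YFILER_PLUS_27), ``dialect`` ({delimiter, multicopy_style,
    id_column}), ``n_perm``, ``seed``, ``alpha``, ``bonferroni_m`` (optional
    override, e.g. a cohort-size convention), ``mds_dims``, ``nj_clamp``.
    Stages run in order and fail fast; every seed and output path lands in
    the returned manifest.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    panel = PANELS[config.get("panel", "YFILER_PLUS_27")]
    dialect = HaplotypeTableDialect(**config.get("dialect", {}))
    seed = int(config.get("seed", 0))
    pop_specs = config.get("populations", [])
    if not pop_specs:
        raise ValueError("config must name at least one population table")

    manifest = RunManifest(config=config, input_digests={}, seed=seed, version=__version__)

    pops: list[PopulationSample] = []
    for spec in pop_specs:
        path = Path(spec["path"])
        manifest.input_digests[str(path)] = _digest(path)
        pops.append(
            read_haplotype_table(
                path, panel, dialect, population_name=spec.get("name"), mode="lenient"
            )
        )
    log.info("stage read: %d population(s)", len(pops))

    # QC on the lenient parse; statistics use complete haplotypes only
    qc_lines = []
    for pop in pops:
        rep = qc_screen(pop)
        qc_lines.append(
            json.dumps(
                {
                    "population": rep.population_name,
                    "null_alleles": rep.null_allele_records,
                    "copy_number_variants": rep.cnv_records,
                    "microvariants": [
                        {"marker": m, "allele": str(a), "occurrences": c}
                        for m, a, c in rep.microvariant_census
                    ],
                },
                sort_keys=True,
            )
        )
    qc_path = out_dir / "qc.jsonl"
    qc_path.write_text("\n".join(qc_lines) + "\n")
    manifest.outputs["qc"] = [qc_path.name]
    log.info("stage qc: done")

    for pop in pops:
        _forensic_stage(pop, out_dir, manifest)
    log.info("stage forensic: done")

    if len(pops) < 2:
        log.info("single population: skipping Rst/MDS/NJ stages")
        manifest.write(out_dir / "manifest.json")
        return manifest

    result = pairwise_rst(
        pops,
        n_perm=int(config.get("n_perm", 10000)),
        seed=seed,
        alpha=float(config.get("alpha", 0.05)),
        bonferroni_m=config.get("bonferroni_m"),
    )
    rst_path = out_dir / "rst.csv"
    write_distance_matrix(result.rst_clamped, result.labels, rst_path)
    p_path = out_dir / "rst_p_values.csv"
    pd.DataFrame(result.p_values, index=result.labels, columns=result.labels).map(
        lambda x: repr(float(x))
    ).to_csv(p_path, index_label="", lineterminator="\n")
    amova_path = out_dir / "amova_components.jsonl"
    amova_path.write_text(
        "\n".join(
            json.dumps(
                {
                    "pair": list(pair),
                    "rst_raw": res.rst,
                    "sigma2_among": res.sigma2_among,
                    "sigma2_within": res.sigma2_within,
                    "ssd_total": res.ssd_total,
                    "degenerate": res.degenerate,
                },
                sort_keys=True,
            )
            for pair, res in sorted(result.amova.items())
        )
        + "\n"
    )
    manifest.outputs["rst"] = [rst_path.name, p_path.name, amova_path.name]
    log.info(
        "stage rst: done (alpha=%g, corrected=%g, m=%d)",
        result.alpha,
        result.alpha_corrected,
        result.bonferroni_m,
    )

    emb = classical_mds(
        result.rst_clamped, int(config.get("mds_dims", 2)), result.labels
    )
    mds_path = out_dir / "mds.csv"
    with open(mds_path, "w") as fh:
        axes = ",".join(f"axis{i + 1}" for i in range(emb.n_axes))
        fh.write(f"population,{axes}\n")
        for label, row in zip(emb.labels, emb.coordinates):
            fh.write(label + "," + ",".join(repr(float(x)) for x in row) + "\n")
    manifest.outputs["mds"] = [mds_path.name]
    log.info("stage mds: done (%d axes)", emb.n_axes)

    tree = neighbor_joining(
        result.rst_clamped, result.labels, clamp=bool(config.get("nj_clamp", False))
    )
    nwk_path = out_dir / "tree.nwk"
    write_newick(tree, nwk_path)
    manifest.outputs["nj"] = [nwk_path.name]
    log.info("stage nj: done")

    manifest.write(out_dir / "manifest.json")
    return manifest
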