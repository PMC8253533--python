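# ystrkit

Forensic Y-STR population analysis in Python: haplotype quality control,
direct-counting diversity statistics, AMOVA-based pairwise Rst with
permutation significance, classical MDS ordination, neighbor-joining trees,
and a stepwise-mutation-model simulator of diverging male populations.

## The problem

Y-chromosomal short tandem repeats (Y-STRs) are paternally inherited as a
single haplotype, so a panel of Y-STR markers characterises a male lineage.
Forensic labs that type a population with a kit such as the 17-locus Yfiler
or the 27-locus Yfiler Plus need to answer two kinds of questions:

1. **How useful is the panel in this population?**  Summarised by per-locus
   gene diversity and by haplotype-level parameters computed from the
   multiplicity spectrum (how many haplotypes were seen once, twice, ...):

   - gene diversity at a locus, `GD = n/(n-1) * (1 - Σ p_i²)` over allele
     frequencies (Nei's unbiased heterozygosity);
   - haplotype diversity `HD`, the same statistic over whole-haplotype
     frequencies;
   - discrimination capacity `DC = k/n` (distinct haplotypes over sample
     size);
   - random match probability `RMP = Σ p_i²` over haplotype frequencies, the
     chance that two random males share a profile (`RMP + HD·(n-1)/n = 1`).

2. **How does the population relate to others?**  Measured by pairwise Rst —
   the among-population fraction of variance in repeat scores, estimated by
   a two-level analysis of molecular variance (AMOVA) on squared
   repeat-count differences — with significance from a permutation test and
   Bonferroni correction, visualised by classical multidimensional scaling
   and a Saitou–Nei neighbor-joining tree on the Rst matrix.

`ystrkit` implements this whole workflow as a library (with a thin
`ystrkit` CLI on top), including the domain plumbing forensic data needs:
microvariant ("off-ladder") alleles such as 18.2, multi-copy markers
(DYS385a/b, DYF387S1a/b) reported as unordered pairs, YHRD-style haplotype
tables in combined (`13-17`) or split-column dialects, and QC screens for
null alleles and copy-number variants.

Because real genotype tables are typically deposited in databases (YHRD)
rather than shipped with papers, the package includes first-class synthetic
data generators: exact-spectrum cohort constructions and a single-step
stepwise-mutation-model (SMM) simulator whose divergence time tunes the true
Rst between populations.

## Worked example

`examples/spectrum_statistics.py` computes the forensic parameters of a
431-male cohort directly from its published haplotype multiplicity spectra
(17-locus panel: 328 singletons, 33 doubletons, 6 tripletons, 1 quadrupleton,
3 quintupletons; 27-locus panel: 405/10/2):

```text
panel     n    k    HD       DC       RMP      unique
17 loci   431  371   0.9991   0.8608   0.0033   0.8841
27 loci   431  417   0.9998   0.9675   0.0025   0.9712
```

Adding the ten extra loci resolves 371 distinct haplotypes into 417, raising
DC from 0.8608 to 0.9675 and the unique fraction from 88.4% to 97.1%, while
RMP drops from 0.0033 to 0.0025 — the panel-upgrade effect these parameters
exist to quantify.

`examples/population_comparison.py` simulates four populations (two sharing
an ancestor, two progressively diverged) and runs the comparison stack:

```text
  NearA vs NearB: Rst= 0.0106, p=0.0770
  NearA vs Mid: Rst= 0.8152, p=0.0010*
  ...
NJ tree: (NearA:0.0064...,NearB:0.0042...,(Mid:0.408...,Far:0.536...):0.400...);
```

The undiverged pair is non-significant while every diverged pair is
significant after Bonferroni correction (`*`), and the NJ tree attaches the
diverged populations via long branches.  The other examples cover QC +
Table-style reporting on the 431-male synthetic cohort
(`forensic_parameters.py`) and simulator/IO round trips
(`simulate_and_roundtrip.py`).

## Command line

```bash
ystrkit qc --in cohort.tsv
ystrkit forensic-params --in cohort.tsv --panel YFILER_PLUS_27
ystrkit rst --pops a.tsv --pops b.tsv --perms 10000 --seed 42 --out rst/
ystrkit mds --dist rst/rst.csv --dims 2 --out mds.csv
ystrkit njtree --dist rst/rst.csv --out tree.nwk
ystrkit simulate --config sim.yaml --out pops/
ystrkit run --config run.yaml --out results/
```

`run` executes the full QC → forensic → Rst → MDS → NJ pipeline and writes a
manifest (config snapshot, input digests, seeds) that makes reruns
byte-identical.

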