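# Methods

This note documents the statistical models, conventions and design choices
behind `ystrkit`, and what the synthetic-data generators do and do not
emulate.

## Domain model

**Alleles.**  A Y-STR allele is a count of full repeat units plus 0–3 extra
nucleotides (microvariant / off-ladder alleles, written `18.2`).  The
numeric repeat score used in molecular distances reads the decimal
nomenclature as a number (`18.2` → 18.2).  This follows the printed allele
names for transparency; a biologically proportional alternative
(`partial/motif_length`, so `18.2` → 18.5 for a tetranucleotide) is
available via `score(mode="proportional")`.  Parsing rejects partial counts
above 3, consistent with tetranucleotide nomenclature.

**Multi-copy markers.**  DYS385a/b and DYF387S1a/b amplify two Y-chromosome
loci; electropherograms cannot assign alleles to a specific copy, so pairs
are stored sorted ascending and treated as unordered.  Frequency estimation
at these markers counts *pair configurations* (unit `"13-17"`, denominator
n), which matches how kits and databases report them and reproduces their
high apparent diversity.

**Panels.**  `YFILER_17` (15 single-copy markers + DYS385a/b = 17 value
slots) and `YFILER_PLUS_27` (adds DYS449, DYS460, DYS481, DYS518, DYS533,
DYS570, DYS576, DYS627 and DYF387S1a/b = 27 slots).  The 17-locus panel is a
strict sub-panel, so 27-locus populations project onto it; projection can
only merge haplotype classes, giving the monotonicity k₂₇ ≥ k₁₇,
HD₂₇ ≥ HD₁₇, DC₂₇ ≥ DC₁₇ that the tests enforce.

**DYS389II** values are used exactly as reported (the YHRD convention, in
which DYS389II includes the DYS389I stretch); no subtraction is applied.

**Strict vs lenient parsing.**  Statistics run on strictly parsed, complete
haplotypes.  QC runs parse leniently: samples with missing calls (null
alleles) or extra alleles at single-copy markers (copy-number variants) are
retained and routed to the QC report; incomplete haplotypes are excluded
from spectra and diversity statistics.

## Diversity statistics

All frequencies are direct counts.  Per-locus gene diversity is
`GD = n/(n-1)·(1 − Σ p_i²)`; haplotype diversity HD applies the same formula
to whole-haplotype frequencies; `DC = k/n`; `RMP = Σ p_i²` over haplotype
frequencies.  The identity `RMP + HD·(n-1)/n = 1` holds to machine precision
and is property-tested.  Reported values are rounded to 4 decimals alongside
full-precision values.

Note on published tables for the 431-male reference cohort: its printed
multiplicity spectra (328/33/6/1/3 and 405/10/2) reproduce DC (0.8608 /
0.9675), the proportion of unique haplotypes (0.8841 / 0.9712) and the
17-locus RMP (605/431² → 0.0033) exactly at 4 dp, but are *not* consistent
with the printed HD values (0.9994 / 0.9997; the formula gives 0.9991 /
0.9998) or the printed 27-locus RMP (0.0027; the spectrum gives
463/431² = 0.0025).  The internally consistent cells are asserted in tests;
the discordant cells are recomputed for the record but not asserted, since
the computation path behind them is not reconstructible.  Similarly, a
printed minimum allele frequency of 0.0004 cannot arise from denominator 431
or 862 and is not used.

## AMOVA and Rst

The molecular distance between two haplotypes is the sum over value slots of
squared repeat-score differences (the Slatkin-type metric underlying Rst for
microsatellites).  Multi-copy pairs are matched after ascending sort, which
minimises the squared-difference sum over the two copies.  Microvariant
scores enter numerically by default.

Two-level AMOVA is computed directly from the squared-distance matrix:

```
SSD_total  = (1/N)  Σ_{i<j}          δ²_ij
SSD_within = Σ_pop (1/n_p) Σ_{i<j∈pop} δ²_ij
σ²_b = SSD_within/(N−k);   n₀ = (N − Σn_p²/N)/(k−1)
σ²_a = (SSD_among/(k−1) − σ²_b)/n₀;   Rst = σ²_a/(σ²_a+σ²_b)
```

Sums use exact (`math.fsum`) accumulation, so results are independent of
sample ordering.  A zero-variance input is reported as Rst = 0 with a
`degenerate` flag.  Negative Rst estimates (sampling noise around 0) are
retained in reports and clamped to 0 only where a dissimilarity is required
(MDS, NJ).

**Permutation test.**  Individuals are pooled and reassigned uniformly at
random to the original group sizes; `p = (#{Rst* ≥ Rst_obs} + 1)/(n_perm+1)`
(add-one estimator; ties count as ≥, with a 1e-12 tolerance against the
vectorised recomputation path).  The batch permutation statistic is computed
via group-indicator matrices against the distance matrix (`einsum`), making
the calibration experiment (500 replicates × 999 permutations) run in
seconds.  Each population pair draws an independent RNG stream spawned from
the user seed, so results do not depend on pair order.  Default
`n_perm = 10000`.

**Multiple testing.**  Bonferroni correction defaults to m = number of
pairwise comparisons.  Some studies instead divide by the cohort sample size
(e.g. 0.05/431 ≈ 0.0001); that convention is reproducible via the
`bonferroni_m` override and is reported explicitly in output metadata.

## Ordination and trees

**Classical (Torgerson) MDS**: Gower double-centering
`B = −½·J·(D∘D)·J`, eigendecomposition, coordinates = eigenvectors scaled by
√(positive eigenvalues).  Metric MDS was chosen over non-metric stress
minimisation because it is deterministic and has no convergence concerns.
Rst matrices are generally non-Euclidean; negative eigenvalues are dropped
(standard PCoA practice) and reported as a distortion diagnostic.  Axes
requested beyond the positive eigencount are returned as zeros with a
`truncated` flag.  Sign convention: the largest-magnitude loading per axis
is made positive, so runs are reproducible.

**Neighbor joining** (Saitou–Nei): minimise
`Q(i,j) = (m−2)d(i,j) − Σd(i,·) − Σd(j,·)`, standard limb-length formulas,
reduction `d(u,k) = (d(i,k)+d(j,k)−d(i,j))/2`.  Q-ties are broken by the
lexicographically smallest label pair (clusters labelled by their smallest
contained taxon) for cross-platform reproducibility.  The tree is unrooted
(internal degree 3); the 2-taxon base case splits the distance evenly.
Negative estimated branch lengths are reported; with `clamp=True` they are
zeroed and the difference moved to the sister branch of the same join
(Kuhner–Felsenstein convention).  On additive matrices NJ recovers the
generating topology exactly and branch lengths to 1e-9 (tested on hundreds
of random trees).

## Synthetic data

**Exact-spectrum construction** (`from_spectrum`): k pairwise-distinct
random haplotypes drawn per-marker from hard-coded plausible allele-ladder
ranges, replicated to their multiplicities.  The output census equals the
requested spectrum exactly (property-tested).  `maoming_like_fixture` builds
the 431-male, 27-locus cohort shape — spectrum {1:405, 2:10, 3:2} with
exactly nine microvariant occurrences at six markers (DYS448 18.2×2 and
19.2; DYS458 18.2; DYS449 34.2; DYS518 37.2; DYF387S1 37.2; DYS627 17.2 and
18.2) and no null alleles or CNVs.  Microvariants are placed in singleton
haplotypes and the spectrum is re-verified after placement.

**SMM simulator** (`simulate_populations`): one founder haplotype per run;
each population inherits a population ancestor via a shared random walk of
`divergence_generations` (t) — this shared drift is what creates
among-population differentiation — then each of its n lineages evolves
independently for `within_generations` (default 200).  Mutations occur per
branch and slot with probability μ per generation (default 0.002, within the
1e-3–1e-2 range typical of Y-STRs) and step the repeat count by ±1 with
equal probability (single-step SMM; multi-step models are out of scope).
Optional microvariant injection sets `partial_nt ∈ {1,2,3}` at a configured
per-slot rate.  Repeat counts are floored at 1.

What the simulator does *not* emulate: coalescent-correlated genealogies
within populations (lineages are a star from the population ancestor), locus-
specific mutation rates, mutation-rate heterogeneity among lineages,
directional/boundary mutation bias, and real allele-frequency distributions
(founders are uniform on ladder ranges).  Consequently, passing calibration
and monotonicity tests demonstrates the correctness of the statistics under
SMM assumptions, not distributional realism of any real population.  With
μ = 0.003 and n = 50 per group, divergence times 0 → ~8000 generations span
mean pairwise Rst from ≈ 0 to > 0.9, comfortably covering the ~0.0007–0.16
range seen between real regional populations.

## Numerical and reproducibility choices

- All randomness flows through `numpy.random.Generator` seeded from
  user-supplied seeds; derived streams use `SeedSequence.spawn`.
- Writers emit byte-identical output for identical inputs (fixed float
  formatting: `repr` of Python floats for machine files, 4 dp for report
  files).
- Distance-matrix validation uses absolute tolerance 1e-12 (symmetry, zero
  diagonal); MDS distance recovery and NJ additivity are tested at 1e-9.
- Problem sizes in the test suite (populations ≤ 200 individuals, 500
  calibration replicates, 200 random trees) were chosen to exercise the
  asymptotics the statistics rely on while keeping the default suite fast.

## Known limitations

- Published between-population Rst values for real reference populations
  cannot be regenerated without their haplotype data and the exact settings
  of the database tool that produced them (inclusion/exclusion of multi-copy
  markers and microvariant handling are undocumented); the Rst machinery is
  therefore validated by hand-computed limits, a naive double-sum oracle,
  and simulation instead.
- No haplotype-frequency interval estimators (kappa/Brenner), no Fst
  (allele-identity) variant, no hierarchical three-level AMOVA, no bootstrap
  support values on NJ trees.
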