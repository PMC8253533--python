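"""Two-level AMOVA on squared repeat-score distances, pairwise Rst, and
permutation significance.

The molecular distance between two haplotypes is the sum over value slots of
squared repeat-score differences (Slatkin-type, the metric underlying Rst for
microsatellites).  Multi-copy markers contribute two slots, paired after
ascending sort — the pairing that minimises the squared-difference sum for two
copies.  Microvariant scores enter numerically by default (18.2 as 18.2).

AMOVA partitions those squared distances into among- and within-population
sums of squares (Excoffier-style algebra computed directly from the distance
matrix):

    SSD_total  = (1/N)   * sum_{i<j over all N} d2_ij
    SSD_within = sum_pop (1/n_p) * sum_{i<j in pop} d2_ij
    SSD_among  = SSD_total - SSD_within
    sigma2_b   = SSD_within / (N - k)                       (within pops)
    n0         = (N - sum n_p^2 / N) / (k - 1)
    sigma2_a   = (SSD_among/(k-1) - sigma2_b) / n0          (among pops)
    Rst        = sigma2_a / (sigma2_a + sigma2_b)

Significance is assessed by permuting individuals between populations
(keeping group sizes) and counting permuted Rst >= observed with the add-one
estimator (b+1)/(m+1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .core import Haplotype, Panel, PopulationSample

__all__ = [
    "AmovaResult",
    "PairwiseRstResult",
    "haplotype_sq_distance",
    "score_matrix",
    "squared_distance_matrix",
    "amova_two_level",
    "permutation_p",
    "pairwise_rst",
    "bonferroni",
]


def score_matrix(
    pop: PopulationSample, score_mode: str = "decimal"
) -> np.ndarray:
    """Repeat-score matrix (n samples x panel slots), canonical slot order."""
    haps = pop.complete_haplotypes()
    rows = []
    for h in haps:
        row: list[float] = []
        for m in pop.panel.markers:
            for a in h.alleles(m.name):
                row.append(a.score(score_mode))
        rows.append(row)
    return np.asarray(rows, dtype=float)


def haplotype_sq_distance(
    h1: Haplotype, h2: Haplotype, panel: Panel, score_mode: str = "decimal"
) -> float:
    """Sum over value slots of squared repeat-score differences."""
    total = 0.0
    for m in panel.markers:
        a1, a2 = h1.alleles(m.name), h2.alleles(m.name)
        if len(a1) != m.copy_number or len(a2) != m.copy_number:
            raise ValueError(
                f"haplotype incomplete at {m.name} "
                f"({h1.sample_id!r} or {h2.sample_id!r})"
            )
        # canonical form is already sorted ascending
        for x, y in zip(a1, a2):
            d = x.score(score_mode) - y.score(score_mode)
            total += d * d
    return total


def squared_distance_matrix(X: np.ndarray) -> np.ndarray:
    """Pairwise squared Euclidean distances between score rows."""
    return cdist(X, X, metric="sqeuclidean")


@dataclass
class AmovaResult:
    """Two-level AMOVA variance decomposition."""

    ssd_total: float
    ssd_among: float
    ssd_within: float
    df_among: int
    df_within: int
    sigma2_among: float
    sigma2_within: float
    n0: float
    rst: float
    degenerate: bool = False  # zero total molecular variance

    @property
    def rst_clamped(self) -> float:
        return max(self.rst, 0.0)


def _pair_sum(D: np.ndarray, idx: np.ndarray) -> float:
    """Exact (order-independent) sum over i<j pairs of D restricted to idx."""
    sub = D[np.ix_(idx, idx)]
    return math.fsum(sub[np.triu_indices_from(sub, k=1)]) if len(idx) > 1 else 0.0


def amova_from_distances(D: np.ndarray, sizes: list[int]) -> AmovaResult:
    """AMOVA from a full individual-level squared-distance matrix.

    *sizes* gives consecutive population block sizes along D's rows.
    """
    N = int(sum(sizes))
    k = len(sizes)
    if k < 2:
        raise ValueError("AMOVA needs at least 2 populations")
    if any(s < 2 for s in sizes):
        raise ValueError("every population needs n >= 2")
    bounds = np.cumsum([0] + list(sizes))
    ssd_total = _pair_sum(D, np.arange(N)) / N
    ssd_within = math.fsum(
        _pair_sum(D, np.arange(bounds[p], bounds[p + 1])) / sizes[p]
        for p in range(k)
    )
    ssd_among = ssd_total - ssd_within
    df_among, df_within = k - 1, N - k
    sigma2_b = ssd_within / df_within
    n0 = (N - sum(s * s for s in sizes) / N) / (k - 1)
    sigma2_a = (ssd_among / df_among - sigma2_b) / n0
    denom = sigma2_a + sigma2_b
    if denom == 0.0:
        return AmovaResult(
            ssd_total, ssd_among, ssd_within, df_among, df_within,
            sigma2_a, sigma2_b, n0, 0.0, degenerate=True,
        )
    return AmovaResult(
        ssd_total, ssd_among, ssd_within, df_among, df_within,
        sigma2_a, sigma2_b, n0, sigma2_a / denom,
    )


def amova_two_level(
    pops: list[PopulationSample], score_mode: str = "decimal"
) -> AmovaResult:
    """Two-level AMOVA across >= 2 populations sharing a panel."""
    if len(pops) < 2:
        raise ValueError("AMOVA needs at least 2 populations")
    panel = pops[0].panel
    if any(p.panel.name != panel.name for p in pops):
        raise ValueError("all populations must share a panel")
    X = np.vstack([score_matrix(p, score_mode) for p in pops])
    sizes = [len(p.complete_haplotypes()) for p in pops]
    return amova_from_distances(squared_distance_matrix(X), sizes)


def _batch_permuted_rst(
    D: np.ndarray, n_a: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Rst for *n_perm* random reassignments of individuals to groups (n_a, N-n_a).

    Vectorised: group-membership indicator matrices against D via einsum.
    """
    N = D.shape[0]
    n_b = N - n_a
    # each row: random permutation, first n_a indices -> group A
    order = np.argsort(rng.random((n_perm, N)), axis=1)
    in_a = np.zeros((n_perm, N))
    np.put_along_axis(in_a, order[:, :n_a], 1.0, axis=1)
    in_b = 1.0 - in_a
    q_a = np.einsum("bi,ij,bj->b", in_a, D, in_a)  # 2 * sum_{i<j in A}
    q_b = np.einsum("bi,ij,bj->b", in_b, D, in_b)
    total_pairsum = D.sum() / 2.0
    ssd_total = total_pairsum / N
    ssd_within = q_a / (2.0 * n_a) + q_b / (2.0 * n_b)
    ssd_among = ssd_total - ssd_within
    sigma2_b = ssd_within / (N - 2)
    n0 = N - (n_a * n_a + n_b * n_b) / N
    sigma2_a = (ssd_among - sigma2_b) / n0  # df_among = 1
    denom = sigma2_a + sigma2_b
    with np.errstate(invalid="ignore", divide="ignore"):
        rst = np.where(denom != 0.0, sigma2_a / denom, 0.0)
    return rst


def permutation_p(
    popA: PopulationSample,
    popB: PopulationSample,
    n_perm: int = 10000,
    seed: int | np.random.SeedSequence = 0,
    score_mode: str = "decimal",
) -> tuple[float, float]:
    """Permutation p-value for the pairwise Rst between two populations.

    Individuals are pooled and reassigned uniformly at random to the original
    group sizes; ``p = (#{permuted Rst >= observed} + 1) / (n_perm + 1)``.
    Returns ``(observed_rst, p)``; deterministic given the seed.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    X = np.vstack([score_matrix(popA, score_mode), score_matrix(popB, score_mode)])
    n_a = len(popA.complete_haplotypes())
    sizes = [n_a, len(popB.complete_haplotypes())]
    D = squared_distance_matrix(X)
    observed = amova_from_distances(D, sizes).rst
    rng = np.random.default_rng(seed)
    permuted = _batch_permuted_rst(D, n_a, n_perm, rng)
    exceed = int(np.count_nonzero(permuted >= observed - 1e-12))
    p = (exceed + 1) / (n_perm + 1)
    return observed, p


@dataclass
class PairwiseRstResult:
    """All-pairs Rst matrix with permutation p-values and significance flags."""

    labels: list[str]
    rst: np.ndarray  # raw values (may be negative)
    p_values: np.ndarray
    n_permutations: int
    seed: int
    alpha: float
    alpha_corrected: float
    bonferroni_m: int
    amova: dict[tuple[str, str], AmovaResult] = field(default_factory=dict)

    @property
    def rst_clamped(self) -> np.ndarray:
        """Negative Rst clamped to 0 — the dissimilarity input for MDS/NJ."""
        return np.maximum(self.rst, 0.0)

    @property
    def significant_raw(self) -> np.ndarray:
        return self.p_values < self.alpha

    @property
    def significant_corrected(self) -> np.ndarray:
        return self.p_values < self.alpha_corrected


def bonferroni(alpha: float, m: int) -> float:
    """Bonferroni-corrected per-test threshold alpha/m."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if m < 1 or int(m) != m:
        raise ValueError(f"m must be a positive integer, got {m}")
    return alpha / m


def pairwise_rst(
    pops: list[PopulationSample],
    n_perm: int = 10000,
    seed: int = 0,
    alpha: float = 0.05,
    bonferroni_m: int | None = None,
    score_mode: str = "decimal",
) -> PairwiseRstResult:
    """Pairwise Rst with permutation p-values across >= 2 populations.

    *bonferroni_m* defaults to the number of pairwise comparisons; pass an
    explicit m to reproduce other conventions (e.g. the cohort sample size).
    Diagonals are Rst = 0 and p = 1.  Each pair draws an independent
    RNG stream spawned from *seed*, so results do not depend on pair order.
    """
    if len(pops) < 2:
        raise ValueError("need at least 2 populations")
    k = len(pops)
    labels = [p.population_name for p in pops]
    if len(set(labels)) != k:
        raise ValueError("population names must be unique")
    m_pairs = k * (k - 1) // 2
    m = bonferroni_m if bonferroni_m is not None else m_pairs
    rst = np.zeros((k, k))
    pmat = np.ones((k, k))
    components: dict[tuple[str, str], AmovaResult] = {}
    streams = iter(np.random.SeedSequence(seed).spawn(m_pairs))
    for i in range(k):
        for j in range(i + 1, k):
            child = next(streams)
            obs, p = permutation_p(pops[i], pops[j], n_perm, child, score_mode)
            rst[i, j] = rst[j, i] = obs
            pmat[i, j] = pmat[j, i] = p
            components[(labels[i], labels[j])] = amova_two_level(
                [pops[i], pops[j]], score_mode
            )
    return PairwiseRstResult(
        labels, rst, pmat, n_perm, seed, alpha, bonferroni(alpha, m), m, components
    )
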