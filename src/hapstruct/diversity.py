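"""Diversity indices and neutrality tests.

Per-population and pooled summaries: haplotype diversity (Nei's unbiased
estimator with its sampling variance), nucleotide diversity from
model-corrected pairwise distances, private-haplotype counts, segregating
sites, and the Tajima's D / Fu's Fs neutrality statistics with coalescent
null p-values. Strongly negative D and Fs with small simulated p indicate
an excess of rare variants, the classic footprint of demographic expansion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterator, Sequence

import mpmath
import numpy as np
import pandas as pd

from .dataio import CountTable, DataError, HaplotypeCatalog
from .distances import DistanceMatrix, step_matrix, tn93_matrix


class UndefinedStatisticError(ValueError):
    """The requested statistic is undefined for this input (e.g. D at S=0)."""


class InfiniteStatisticError(ValueError):
    """Fu's Fs tail probability is 0 or 1 within working precision."""

    def __init__(self, sign: int, s_prime: float):
        self.sign = sign
        self.s_prime = s_prime
        super().__init__(
            f"Fs diverges to {'+' if sign > 0 else '-'}inf (S' = {s_prime!r})"
        )


# ---------------------------------------------------------------------------
# diversity estimators


def haplotype_diversity(counts: Sequence[int]) -> tuple[float, float]:
    """Nei's unbiased haplotype diversity h = n(1 - sum p_i^2)/(n - 1).

    Returns (h, sd) where sd is the square root of Nei's (1987) sampling
    variance of the heterozygosity estimator:

        V(h) = 2/(n(n-1)) * { 2(n-2)[sum p^3 - (sum p^2)^2]
                              + sum p^2 - (sum p^2)^2 }
    """
    c = np.asarray([x for x in counts if x > 0], dtype=float)
    n = c.sum()
    if n < 2:
        raise DataError("haplotype diversity requires n >= 2")
    p = c / n
    s2 = float(np.sum(p**2))
    s3 = float(np.sum(p**3))
    h = n * (1.0 - s2) / (n - 1.0)
    var = 2.0 / (n * (n - 1.0)) * (2.0 * (n - 2.0) * (s3 - s2**2) + s2 - s2**2)
    return h, math.sqrt(max(var, 0.0))


def mean_pairwise_difference(counts: Sequence[int], dist: DistanceMatrix) -> float:
    """Unbiased mean pairwise distance k = n/(n-1) sum_{i<j} 2 p_i p_j d_ij."""
    c = np.asarray(counts, dtype=float)
    if c.shape != (len(dist.ids),):
        raise DataError("counts must align with the distance matrix ids")
    n = c.sum()
    if n < 2:
        raise DataError("need n >= 2")
    p = c / n
    return float(n / (n - 1.0) * p @ dist.d @ p)


def nucleotide_diversity(
    counts: Sequence[int], dist: DistanceMatrix, L: int, per_site: bool = True
) -> tuple[float, float]:
    """Nucleotide diversity per site with its standard sampling deviation.

    ``dist`` holds model-corrected per-site distances when ``per_site`` is
    true (TN93), or raw step counts otherwise (then divided by L). The
    variance follows the standard (Nei 1987, eq. 10.7) total variance of pi:

        V(pi) = (n+1)/(3(n-1)L) * pi + 2(n^2+n+3)/(9n(n-1)) * pi^2
    """
    if L <= 0:
        raise DataError("L must be positive")
    n = float(np.sum(np.asarray(counts, dtype=float)))
    k = mean_pairwise_difference(counts, dist)
    pi = k if per_site else k / L
    var = (n + 1.0) / (3.0 * (n - 1.0) * L) * pi + (
        2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    ) * pi**2
    return pi, math.sqrt(max(var, 0.0))


def private_haplotypes(ct: CountTable, pop: str) -> int:
    """Number of haplotypes observed in ``pop`` and nowhere else."""
    j = ct.populations.index(pop) if pop in ct.populations else None
    if j is None:
        raise DataError(f"unknown population {pop!r}")
    here = ct.counts[:, j] > 0
    elsewhere = (ct.counts.sum(axis=1) - ct.counts[:, j]) > 0
    return int(np.sum(here & ~elsewhere))


# ---------------------------------------------------------------------------
# Tajima's D


def _tajima_constants(n: int) -> dict[str, float]:
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    return {"a1": a1, "a2": a2, "e1": c1 / a1, "e2": c2 / (a1**2 + a2)}


def tajimas_d(S: int, mean_pairwise_diff: float, n: int) -> float:
    """Tajima's D = (kbar - S/a1) / sqrt(e1 S + e2 S(S-1)).

    Raises :class:`UndefinedStatisticError` when S = 0 (the statistic has no
    value for an invariant sample, rather than being zero).
    """
    if n < 4:
        raise DataError("Tajima's D requires n >= 4")
    if S < 0:
        raise DataError("S must be non-negative")
    if S == 0:
        raise UndefinedStatisticError("Tajima's D undefined at S = 0")
    c = _tajima_constants(n)
    denom = math.sqrt(c["e1"] * S + c["e2"] * S * (S - 1))
    return (mean_pairwise_diff - S / c["a1"]) / denom


# ---------------------------------------------------------------------------
# Fu's Fs


@lru_cache(maxsize=32)
def _stirling_row(n: int) -> tuple[int, ...]:
    """Unsigned Stirling numbers of the first kind |s(n, k)| for k = 0..n."""
    row = [1]  # n = 0
    for m in range(1, n + 1):
        prev = row
        row = [0] * (m + 1)
        for k in range(1, m + 1):
            row[k] = prev[k - 1] + (m - 1) * (prev[k] if k < m else 0)
    return tuple(row)


def ewens_k_distribution(theta: float, n: int) -> np.ndarray:
    """P(K = k | theta, n) for k = 1..n under the Ewens sampling formula."""
    if theta <= 0:
        raise DataError("theta must be positive")
    with mpmath.workdps(max(30, int(2.5 * n))):
        th = mpmath.mpf(theta)
        rising = mpmath.mpf(1)
        for i in range(n):
            rising *= th + i
        row = _stirling_row(n)
        probs = [mpmath.mpf(row[k]) * th**k / rising for k in range(1, n + 1)]
        return np.array([float(p) for p in probs])


def fus_fs(k_obs: int, theta_pi: float, n: int) -> float:
    """Fu's (1997) Fs = ln(S'/(1 - S')) with S' = P(K >= k_obs | theta, n).

    K follows the Ewens sampling distribution with theta set to the observed
    mean pairwise difference. Computed with exact Stirling integers and
    arbitrary-precision arithmetic; a tail probability indistinguishable from
    0 or 1 raises :class:`InfiniteStatisticError` with the offending S'.
    """
    if not 1 <= k_obs <= n:
        raise DataError("k_obs must lie in 1..n")
    if theta_pi <= 0:
        raise DataError("theta_pi must be positive")
    with mpmath.workdps(max(30, int(2.5 * n))):
        th = mpmath.mpf(theta_pi)
        rising = mpmath.mpf(1)
        for i in range(n):
            rising *= th + i
        row = _stirling_row(n)
        tail = mpmath.mpf(0)
        power = th**k_obs
        for k in range(k_obs, n + 1):
            tail += mpmath.mpf(row[k]) * power
            power *= th
        s_prime = tail / rising
        if s_prime <= 0:
            raise InfiniteStatisticError(1, float(s_prime))
        if s_prime >= 1:
            raise InfiniteStatisticError(-1, float(s_prime))
        return float(mpmath.log(s_prime / (1 - s_prime)))


# ---------------------------------------------------------------------------
# coalescent null distributions


def simulate_neutral_samples(
    n: int, theta: float, n_sims: int, seed: int | None = None
) -> Iterator[tuple[int, float, int]]:
    """Constant-size neutral coalescent replicates of size n.

    Yields (S, kbar, K) per replicate: segregating sites, mean pairwise
    difference and number of distinct haplotypes, under infinite-sites
    mutation calibrated so the expected pairwise difference equals theta.
    """
    import msprime

    if theta <= 0:
        raise DataError("theta must be positive")
    rng = np.random.default_rng(seed)
    anc_seed, mut_seed = (int(x) for x in rng.integers(1, 2**31 - 1, size=2))
    reps = msprime.sim_ancestry(
        samples=n,
        ploidy=1,
        population_size=1.0,
        sequence_length=1.0,
        num_replicates=n_sims,
        random_seed=anc_seed,
    )
    for i, ts in enumerate(reps):
        mts = msprime.sim_mutations(
            ts, rate=theta / 2.0, discrete_genome=False,
            random_seed=(mut_seed + i) % (2**31 - 1) + 1,
        )
        S = mts.num_sites
        if S == 0:
            yield 0, 0.0, 1
            continue
        kbar = float(mts.diversity(span_normalise=False))
        G = mts.genotype_matrix()
        K = np.unique(G.T, axis=0).shape[0]
        yield S, kbar, K


@dataclass
class NeutralityResult:
    """Observed neutrality statistics with simulated lower-tail p-values."""

    D: float | None
    p_D: float | None
    Fs: float | None
    p_Fs: float | None
    n_sims: int
    alpha_D: float = 0.05
    alpha_Fs: float = 0.02

    @property
    def D_significant(self) -> bool | None:
        return None if self.p_D is None else self.p_D <= self.alpha_D

    @property
    def Fs_significant(self) -> bool | None:
        return None if self.p_Fs is None else self.p_Fs <= self.alpha_Fs


def _replicate_d(S: int, kbar: float, n: int) -> float:
    # invariant replicate: no deviation signal; score as 0
    if S == 0:
        return 0.0
    return tajimas_d(S, kbar, n)


def _replicate_fs(K: int, kbar: float, n: int) -> float:
    if kbar <= 0:
        return 0.0
    try:
        return fus_fs(K, kbar, n)
    except InfiniteStatisticError as err:
        return math.inf * err.sign


def neutrality_pvalues(
    cat: HaplotypeCatalog,
    counts: Sequence[int],
    n_sims: int = 20000,
    seed: int | None = None,
    theta: float | None = None,
) -> NeutralityResult:
    """Tajima's D and Fu's Fs with coalescent-simulation p-values.

    The null is a constant-size coalescent with infinite-sites mutation at
    theta = the observed mean pairwise difference (theta_pi) unless
    overridden. p is the lower-tail proportion of simulated statistics <=
    the observed one — the expansion signal is a deficit, so small p flags
    significantly negative statistics (assessed at alpha = 0.05 for D and
    0.02 for Fs). Observed kbar uses raw step counts so it is the mean
    number of pairwise differences, matching the infinite-sites null.
    """
    if n_sims < 100:
        raise DataError("n_sims must be at least 100")
    c = np.asarray(counts)
    n = int(c.sum())
    dist = step_matrix(cat)
    kbar_obs = mean_pairwise_difference(counts, dist)
    S_obs, _, _ = segregating_sites(cat, counts)
    K_obs = int(np.sum(c > 0))
    theta = kbar_obs if theta is None else theta
    try:
        D_obs = tajimas_d(S_obs, kbar_obs, n) if S_obs > 0 else None
    except UndefinedStatisticError:
        D_obs = None
    Fs_obs = _replicate_fs(K_obs, kbar_obs, n) if kbar_obs > 0 else None
    if theta <= 0:
        return NeutralityResult(D_obs, None, Fs_obs, None, 0)
    hits_d = hits_fs = 0
    for S, kbar, K in simulate_neutral_samples(n, theta, n_sims, seed):
        if D_obs is not None and _replicate_d(S, kbar, n) <= D_obs:
            hits_d += 1
        if Fs_obs is not None and _replicate_fs(K, kbar, n) <= Fs_obs:
            hits_fs += 1
    p_D = hits_d / n_sims if D_obs is not None else None
    p_Fs = hits_fs / n_sims if Fs_obs is not None else None
    return NeutralityResult(D_obs, p_D, Fs_obs, p_Fs, n_sims)


# ---------------------------------------------------------------------------
# per-population summary


@dataclass
class DiversitySummary:
    """One row of a diversity table (per population or pooled)."""

    population: str
    n: int
    n_H: int
    n_Hq: int | None
    h: float
    h_sd: float
    pi: float
    pi_sd: float
    S: int
    transitions: int
    transversions: int


def segregating_sites(cat: HaplotypeCatalog, counts: Sequence[int]) -> tuple[int, int, int]:
    """(S, transitions, transversions) over haplotypes with nonzero counts.

    Multi-state sites contribute one site to S and one tally per unordered
    state pair to the transition/transversion counts.
    """
    from .dataio import polymorphic_site_table

    keep = {
        hid: seq
        for (hid, seq), c in zip(cat.entries.items(), counts)
        if c > 0
    }
    if not keep:
        raise DataError("no haplotypes with positive count")
    if len(keep) == 1:
        return 0, 0, 0
    table = polymorphic_site_table(HaplotypeCatalog(keep))
    if table.empty:
        return 0, 0, 0
    return (
        int(len(table)),
        int(table["transitions"].sum()),
        int(table["transversions"].sum()),
    )


def diversity_summary(
    cat: HaplotypeCatalog,
    ct: CountTable,
    pop: str | None = None,
    metric: str = "tn93",
) -> DiversitySummary:
    """Assemble the standard diversity row for one population (or pooled).

    ``metric`` selects the distance model behind pi: 'tn93' (per-site,
    model-corrected — the default) or 'raw' (p-distances from step counts).
    """
    if list(cat.ids) != list(ct.haplotypes):
        raise DataError("catalog and count table haplotype order differ")
    counts = ct.pooled() if pop is None else ct.pop_counts(pop)
    n = int(counts.sum())
    if n < 2:
        raise DataError("diversity summary requires n >= 2")
    n_H = int(np.sum(counts > 0))
    n_Hq = private_haplotypes(ct, pop) if pop is not None else None
    h, h_sd = haplotype_diversity(counts)
    if metric == "tn93":
        dist = tn93_matrix(cat, ct.pooled())
        pi, pi_sd = nucleotide_diversity(counts, dist, cat.L, per_site=True)
    elif metric == "raw":
        dist = step_matrix(cat)
        pi, pi_sd = nucleotide_diversity(counts, dist, cat.L, per_site=False)
    else:
        raise DataError(f"unknown metric {metric!r}")
    S, ts, tv = segregating_sites(cat, counts)
    return DiversitySummary(
        population=pop if pop is not None else "Pooled",
        n=n, n_H=n_H, n_Hq=n_Hq, h=h, h_sd=h_sd, pi=pi, pi_sd=pi_sd,
        S=S, transitions=ts, transversions=tv,
    )


def diversity_table(
    cat: HaplotypeCatalog, ct: CountTable, metric: str = "tn93"
) -> pd.DataFrame:
    """Per-population + pooled diversity table (Table-3-shaped layout)."""
    rows = [diversity_summary(cat, ct, p, metric) for p in ct.populations]
    rows.append(diversity_summary(cat, ct, None, metric))
    return pd.DataFrame([r.__dict__ for r in rows])
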