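"""Population structure: AMOVA fixation indices, permutation inference,
sequential Bonferroni, and Mantel isolation-by-distance.

The one-group AMOVA partitions squared inter-haplotype distances among and
within populations. With model-corrected distances the fixation index is
Phi_ST; with the 0/1 identity metric the identical arithmetic yields the
classical frequency-based F_ST. Significance comes from permuting
individuals among populations (sample sizes fixed); the reported p is the
plain proportion of permuted indices >= the observed one, without a +1
correction, so a p of exactly 0 is possible (as printed by Arlequin).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .dataio import CountTable, DataError
from .distances import DistanceMatrix, distance_matrix_for

_PERM_BATCH = 2000  # permutations vectorised per block


def _seed_sequence(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


@dataclass
class AmovaResult:
    """Variance partition with fixation index and permutation p."""

    df_among: int
    df_within: int
    ss_among: float
    ss_within: float
    var_among: float
    var_within: float
    fixation_index: float
    p: float | None
    p_sd: float | None
    n_perm: int
    metric: str = ""

    @property
    def pct_variation(self) -> tuple[float, float]:
        total = self.var_among + self.var_within
        return 100.0 * self.var_among / total, 100.0 * self.var_within / total

    def to_frame(self) -> pd.DataFrame:
        pa, pw = self.pct_variation
        return pd.DataFrame(
            {
                "source": ["Among populations", "Within populations"],
                "df": [self.df_among, self.df_within],
                "sum_of_squares": [self.ss_among, self.ss_within],
                "variance_component": [self.var_among, self.var_within],
                "pct_variation": [pa, pw],
            }
        )


def _amova_components(
    pop_hap_counts: np.ndarray, dsq: np.ndarray
) -> tuple[float, float, float, float, float, float]:
    """Variance partition from per-population haplotype counts.

    pop_hap_counts: (J, K) counts; dsq: (K, K) squared distances.
    Returns (ss_among, ss_within, sigma_a, sigma_b, n_prime, index).
    """
    nj = pop_hap_counts.sum(axis=1).astype(float)
    N = nj.sum()
    J = len(nj)
    pooled = pop_hap_counts.sum(axis=0).astype(float)
    # sum over unordered pairs of d^2 = c' Dsq c / 2 (diagonal of Dsq is 0)
    ss_total = float(pooled @ dsq @ pooled) / 2.0 / N
    within = np.einsum("jk,kl,jl->j", pop_hap_counts, dsq, pop_hap_counts) / 2.0
    ss_within = float(np.sum(within / nj))
    ss_among = ss_total - ss_within
    sigma_b = ss_within / (N - J)
    n_prime = (N - float(np.sum(nj**2)) / N) / (J - 1)
    sigma_a = (ss_among / (J - 1) - sigma_b) / n_prime
    index = sigma_a / (sigma_a + sigma_b)
    return ss_among, ss_within, sigma_a, sigma_b, n_prime, index


def _batched_permutation_indices(
    hap_of_ind: np.ndarray,
    nj: np.ndarray,
    dsq: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Fixation indices for n_perm random reassignments of individuals.

    Individuals (their haplotype ids) are shuffled and split into groups of
    the original sizes; each block of permutations is evaluated with one
    einsum per population.
    """
    N = len(hap_of_ind)
    K = dsq.shape[0]
    J = len(nj)
    bounds = np.concatenate(([0], np.cumsum(nj)))
    pooled = np.bincount(hap_of_ind, minlength=K).astype(float)
    ss_total = float(pooled @ dsq @ pooled) / 2.0 / N
    n_prime = (N - float(np.sum(nj.astype(float) ** 2)) / N) / (J - 1)
    out = np.empty(n_perm)
    done = 0
    while done < n_perm:
        B = min(_PERM_BATCH, n_perm - done)
        keys = rng.random((B, N))
        order = np.argsort(keys, axis=1)
        perm = hap_of_ind[order]  # (B, N)
        ss_within = np.zeros(B)
        offsets = np.arange(B)[:, None] * K
        for j in range(J):
            block = perm[:, bounds[j] : bounds[j + 1]]
            cj = np.bincount((block + offsets).ravel(), minlength=B * K).reshape(B, K)
            cj = cj.astype(float)
            ss_within += np.einsum("bk,kl,bl->b", cj, dsq, cj) / 2.0 / nj[j]
        ss_among = ss_total - ss_within
        sigma_b = ss_within / (N - J)
        sigma_a = (ss_among / (J - 1) - sigma_b) / n_prime
        out[done : done + B] = sigma_a / (sigma_a + sigma_b)
        done += B
    return out


def amova(
    ct: CountTable,
    dist: DistanceMatrix,
    n_perm: int = 20000,
    seed: int | None = None,
    metric: str = "",
) -> AmovaResult:
    """One-group AMOVA over the populations of a count table.

    ``dist`` must cover ``ct.haplotypes`` in order. Negative variance
    components (and hence negative fixation indices) are retained
    unmodified. ``n_perm = 0`` skips the permutation test (p is None).
    """
    if list(dist.ids) != list(ct.haplotypes):
        raise DataError("distance matrix ids must match count table haplotypes")
    if len(ct.populations) < 2:
        raise DataError("AMOVA needs at least two populations")
    nj = ct.n_per_pop
    if (nj < 1).any():
        raise DataError("every population needs at least one individual")
    N, J = int(nj.sum()), len(ct.populations)
    if N == J:
        raise DataError("AMOVA degenerate: one individual per population")
    dsq = dist.d**2
    pop_hap = ct.counts.T.astype(float)  # (J, K)
    ss_a, ss_w, sa, sb, _, index = _amova_components(pop_hap, dsq)
    p = p_sd = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        # individuals ordered by population, for the split bounds
        hap_of_ind = np.concatenate(
            [np.repeat(np.arange(len(ct.haplotypes)), ct.counts[:, j]) for j in range(J)]
        )
        perm_idx = _batched_permutation_indices(hap_of_ind, nj, dsq, n_perm, rng)
        p = float(np.mean(perm_idx >= index))
        p_sd = math.sqrt(p * (1.0 - p) / n_perm)
    return AmovaResult(
        df_among=J - 1, df_within=N - J, ss_among=ss_a, ss_within=ss_w,
        var_among=sa, var_within=sb, fixation_index=index,
        p=p, p_sd=p_sd, n_perm=n_perm, metric=metric,
    )


@dataclass
class PairwiseMatrix:
    """Lower-triangle pairwise fixation indices with permutation p-values."""

    labels: list[str]
    stat: dict[tuple[str, str], float]
    p: dict[tuple[str, str], float]
    significant_after_holm: dict[tuple[str, str], bool] = field(default_factory=dict)
    metric: str = ""

    def pairs(self) -> list[tuple[str, str]]:
        return list(self.stat)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "pop_a": a,
                "pop_b": b,
                "stat": self.stat[(a, b)],
                "p": self.p[(a, b)],
                "significant_after_holm": self.significant_after_holm.get((a, b)),
            }
            for a, b in self.pairs()
        ]
        return pd.DataFrame(rows)

    def stat_matrix(self) -> DistanceMatrix:
        """Symmetric matrix of pairwise statistics (negatives floored at 0).

        Suitable as the genetic-distance input to a Mantel test.
        """
        k = len(self.labels)
        d = np.zeros((k, k))
        for (a, b), v in self.stat.items():
            i, j = self.labels.index(a), self.labels.index(b)
            d[i, j] = d[j, i] = max(v, 0.0)
        return DistanceMatrix(list(self.labels), d)


def pairwise_structure(
    ct: CountTable,
    dist: DistanceMatrix,
    n_perm: int = 20000,
    seed: int | None = None,
    alpha: float = 0.05,
    metric: str = "",
) -> PairwiseMatrix:
    """Two-population AMOVA for every pair of populations.

    Each pair gets an independent seeded random stream, so results do not
    depend on evaluation order. Holm (sequential Bonferroni) significance
    flags at family level ``alpha`` are attached across the set of pairs.
    """
    labels = list(ct.populations)
    streams = _seed_sequence(seed).spawn(math.comb(len(labels), 2))
    stat: dict[tuple[str, str], float] = {}
    pvals: dict[tuple[str, str], float] = {}
    for stream, (a, b) in zip(streams, itertools.combinations(labels, 2)):
        sub = ct.subset([a, b])
        res = amova(sub, dist, n_perm=n_perm, seed=stream, metric=metric)
        stat[(a, b)] = res.fixation_index
        pvals[(a, b)] = res.p
    flags = {}
    if n_perm > 0:
        keys = list(pvals)
        rejected = sequential_bonferroni([pvals[k] for k in keys], alpha)
        flags = dict(zip(keys, (bool(r) for r in rejected)))
    return PairwiseMatrix(labels, stat, pvals, flags, metric=metric)


def pairwise_structure_for_metric(
    ct: CountTable, cat, metric: str, n_perm: int = 20000, seed: int | None = None
) -> PairwiseMatrix:
    """Convenience wrapper: build the metric's distance matrix, then test."""
    dist = distance_matrix_for(metric, cat, ct)
    return pairwise_structure(ct, dist, n_perm=n_perm, seed=seed, metric=metric)


def holm_initial_alpha(k: int, alpha: float = 0.05) -> float:
    """First (most stringent) threshold of the Holm step-down chain: alpha/k."""
    if k < 1:
        raise DataError("k must be positive")
    return alpha / k


def sequential_bonferroni(p_list, alpha: float = 0.05) -> np.ndarray:
    """Holm step-down rejection flags at family-wise level alpha.

    Sort p ascending; p_(i) is significant iff every p_(j<=i) satisfies
    p_(j) <= alpha/(k - j + 1). The first threshold is alpha/k.
    """
    p = np.asarray(p_list, dtype=float)
    if p.size == 0:
        raise DataError("p_list must be non-empty")
    reject, *_ = multipletests(p, alpha=alpha, method="holm")
    return reject


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    exact: bool = False

    @property
    def r2(self) -> float:
        return self.r**2


def mantel_test(
    gen: DistanceMatrix,
    geo: DistanceMatrix,
    n_perm: int = 9999,
    seed: int | None = None,
    exact: bool | None = None,
) -> MantelResult:
    """Mantel matrix correlation between genetic and geographic distances.

    r is the Pearson correlation over lower-triangle entries; p is the
    one-tailed (positive association) proportion of joint row/column
    permutations of one matrix with r_perm >= r_obs. With ``exact`` (the
    default for <= 7 labels when n_perm would exceed the number of distinct
    permutations) all n! permutations are enumerated.
    """
    if list(gen.ids) != list(geo.ids):
        raise DataError("matrices must share the same labels in order")
    k = len(gen.ids)
    if k < 3:
        raise DataError("Mantel test needs at least three labels")
    tri = np.tril_indices(k, -1)
    x = gen.d[tri]
    if np.allclose(x, x[0]) or np.allclose(geo.d[tri], geo.d[tri][0]):
        raise DataError("constant distance matrix: correlation undefined")

    def corr(perm: np.ndarray) -> float:
        y = geo.d[np.ix_(perm, perm)][tri]
        return float(np.corrcoef(x, y)[0, 1])

    r_obs = corr(np.arange(k))
    if exact is None:
        exact = k <= 7 and math.factorial(k) <= n_perm
    if exact:
        perms = list(itertools.permutations(range(k)))
        hits = sum(corr(np.array(p)) >= r_obs for p in perms)
        return MantelResult(r_obs, hits / len(perms), len(perms), exact=True)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if corr(rng.permutation(k)) >= r_obs:
            hits += 1
    return MantelResult(r_obs, hits / n_perm, n_perm)
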