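"""Subsample-robustness simulation and Hurlbert rarefaction.

The robustness simulation asks how stable a pairwise differentiation call
is to the sampling imbalance between two populations: the focal
population is repeatedly subsampled without replacement at reduced sizes,
the two-population fixation index and its permutation p are recomputed per
replicate, and the "contradiction likelihood" is the proportion of
replicates whose significance call flips relative to the original
full-sample analysis.

Hurlbert rarefaction gives the exact expected number of haplotypes in a
random subsample of size m, used to judge whether sampling saturated the
available haplotype diversity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataio import CountTable, DataError
from .distances import DistanceMatrix
from .structure import amova


@dataclass
class ResampleConfig:
    """Settings for the subsample-robustness simulation."""

    focal_pop: str
    other_pop: str
    subsample_sizes: tuple[int, ...] = (150, 100, 60)
    n_reps: int = 10000
    n_perm_per_rep: int = 20000
    alpha: float = 0.05
    seed: int | None = None


@dataclass
class SizeReport:
    """Per-subsample-size distributions and the contradiction likelihood."""

    size: int
    stats: np.ndarray
    pvalues: np.ndarray
    contradiction_likelihood: float

    @property
    def stat_mean(self) -> float:
        return float(self.stats.mean())

    @property
    def stat_envelope(self) -> tuple[float, float]:
        return tuple(np.percentile(self.stats, [2.5, 97.5]))

    def histogram(self, bins: int = 40) -> tuple[np.ndarray, np.ndarray]:
        return np.histogram(self.stats, bins=bins)


@dataclass
class ResampleReport:
    config: ResampleConfig
    original_stat: float
    original_p: float
    per_size: list[SizeReport] = field(default_factory=list)

    @property
    def original_significant(self) -> bool:
        return self.original_p <= self.config.alpha

    def to_frame(self) -> pd.DataFrame:
        lo_hi = [s.stat_envelope for s in self.per_size]
        return pd.DataFrame(
            {
                "subsample_size": [s.size for s in self.per_size],
                "stat_mean": [s.stat_mean for s in self.per_size],
                "stat_lo95": [lh[0] for lh in lo_hi],
                "stat_hi95": [lh[1] for lh in lo_hi],
                "p_mean": [float(s.pvalues.mean()) for s in self.per_size],
                "contradiction_likelihood": [
                    s.contradiction_likelihood for s in self.per_size
                ],
            }
        )


def subsample_robustness(
    ct: CountTable, dist: DistanceMatrix, cfg: ResampleConfig
) -> ResampleReport:
    """Run the subsample-robustness simulation for one population pair.

    Per replicate: draw a simple random subsample (without replacement, so
    subsample haplotype counts are multivariate hypergeometric) of the focal
    population's individuals, keep the other population intact, and rerun
    the two-population permutation AMOVA. The contradiction likelihood per
    size is the proportion of replicate p-values on the opposite side of
    alpha from the original call.
    """
    focal = ct.pop_counts(cfg.focal_pop)
    n_focal = int(focal.sum())
    for m in cfg.subsample_sizes:
        if m < 2:
            raise DataError("subsample sizes must be at least 2")
        if m > n_focal:
            raise DataError(
                f"subsample size {m} exceeds focal population size {n_focal}"
            )
    if cfg.n_reps < 1:
        raise DataError("n_reps must be positive")
    pair = ct.subset([cfg.focal_pop, cfg.other_pop])
    rng_root = np.random.SeedSequence(cfg.seed)
    orig_stream, *size_streams = rng_root.spawn(1 + len(cfg.subsample_sizes))
    original = amova(pair, dist, n_perm=cfg.n_perm_per_rep, seed=orig_stream)
    report = ResampleReport(cfg, original.fixation_index, original.p)
    focal_individuals = np.repeat(np.arange(len(ct.haplotypes)), focal)
    K = len(ct.haplotypes)
    for m, stream in zip(cfg.subsample_sizes, size_streams):
        rng = np.random.default_rng(stream)
        rep_streams = stream.spawn(cfg.n_reps)
        stats = np.empty(cfg.n_reps)
        pvals = np.empty(cfg.n_reps)
        for r in range(cfg.n_reps):
            take = rng.permutation(focal_individuals)[:m]
            sub_counts = np.bincount(take, minlength=K)
            sub_ct = CountTable(
                [cfg.focal_pop, cfg.other_pop],
                list(ct.haplotypes),
                np.column_stack([sub_counts, pair.pop_counts(cfg.other_pop)]),
            )
            res = amova(sub_ct, dist, n_perm=cfg.n_perm_per_rep, seed=rep_streams[r])
            stats[r] = res.fixation_index
            pvals[r] = res.p
        if original.p <= cfg.alpha:
            contradiction = float(np.mean(pvals > cfg.alpha))
        else:
            contradiction = float(np.mean(pvals <= cfg.alpha))
        report.per_size.append(SizeReport(m, stats, pvals, contradiction))
    return report


# ---------------------------------------------------------------------------
# rarefaction


@dataclass
class RarefactionCurve:
    m: np.ndarray
    expected_haplotypes: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"m": self.m, "expected_haplotypes": self.expected_haplotypes}
        )


def rarefaction_curve(counts) -> RarefactionCurve:
    """Hurlbert's exact rarefaction curve E[h_m] for m = 1..N.

    E[h_m] = sum_i [1 - C(N - N_i, m) / C(N, m)] — the expected number of
    distinct haplotypes in a uniform random subsample of m individuals drawn
    without replacement. Each binomial ratio is accumulated as a running
    product of exact rational factors, so there is no overflow at any N.

    E[h_1] = 1, E[h_N] = the observed haplotype count, and the curve is
    nondecreasing and concave.
    """
    c = np.asarray([x for x in counts if x > 0], dtype=np.int64)
    if c.size == 0 or (c < 0).any():
        raise DataError("counts must be non-negative with at least one nonzero")
    N = int(c.sum())
    ms = np.arange(1, N + 1)
    expected = np.zeros(N, dtype=float)
    for Ni in c:
        # ratio_m = C(N - Ni, m) / C(N, m); ratio_0 = 1,
        # ratio_m = ratio_{m-1} * (N - Ni - m + 1) / (N - m + 1)
        ratio = 1.0
        for m in ms:
            num = N - int(Ni) - m + 1
            ratio = ratio * num / (N - m + 1) if num > 0 else 0.0
            expected[m - 1] += 1.0 - ratio
    return RarefactionCurve(ms, expected)


def rarefaction_monte_carlo_curve(
    counts, n_draws: int = 2000, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Monte-Carlo rarefaction curve for every m at once (cross-check).

    Each draw is one random permutation of the individuals; the running
    count of first occurrences gives the number of distinct haplotypes in
    the nested subsamples of every size m = 1..N simultaneously. Returns
    (mean_curve, standard_error_curve), each of length N.
    """
    c = np.asarray([x for x in counts if x > 0], dtype=np.int64)
    individuals = np.repeat(np.arange(c.size), c)
    N = individuals.size
    rng = np.random.default_rng(seed)
    acc = np.zeros(N)
    acc2 = np.zeros(N)
    for _ in range(n_draws):
        perm = rng.permutation(individuals)
        first = np.zeros(N, dtype=bool)
        first[np.unique(perm, return_index=True)[1]] = True
        seen = np.cumsum(first)
        acc += seen
        acc2 += seen.astype(float) ** 2
    mean = acc / n_draws
    var = np.maximum(acc2 / n_draws - mean**2, 0.0)
    return mean, np.sqrt(var / n_draws)


def rarefaction_monte_carlo(
    counts, m: int, n_draws: int = 50000, seed: int | None = None
) -> tuple[float, float]:
    """Monte-Carlo estimate of E[h_m] with its standard error (cross-check)."""
    c = np.asarray([x for x in counts if x > 0], dtype=np.int64)
    individuals = np.repeat(np.arange(c.size), c)
    rng = np.random.default_rng(seed)
    draws = np.empty(n_draws)
    for i in range(n_draws):
        take = rng.choice(individuals, size=m, replace=False)
        draws[i] = np.unique(take).size
    return float(draws.mean()), float(draws.std(ddof=1) / math.sqrt(n_draws))
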