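"""Mismatch distributions and the sudden demographic expansion model.

The mismatch distribution is the histogram of raw pairwise sequence
differences over all unordered individual pairs. Under a sudden expansion
(scaled mutation parameter theta0 jumping to theta1 >= theta0 at tau
mutational units before present) its expectation is a smooth, unimodal
wave; demographic stability leaves a ragged, multimodal profile. Fit
quality is summarised by Harpending's raggedness index with a parametric
bootstrap under the fitted expansion demography.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .dataio import CountTable, DataError, HaplotypeCatalog
from .distances import step_matrix

THETA1_CAP = 9999.0  # conventional upper bound for the post-expansion parameter


@dataclass
class MismatchDistribution:
    """Pairwise-difference histogram over classes 0..d_max."""

    class_counts: np.ndarray  # integer pair counts per difference class

    def __post_init__(self) -> None:
        self.class_counts = np.asarray(self.class_counts, dtype=np.int64)
        if self.class_counts.ndim != 1 or (self.class_counts < 0).any():
            raise DataError("class counts must be a non-negative vector")
        if self.class_counts.sum() == 0:
            raise DataError("mismatch distribution needs at least one pair")

    @property
    def n_pairs(self) -> int:
        return int(self.class_counts.sum())

    @property
    def class_freqs(self) -> np.ndarray:
        return self.class_counts / self.n_pairs

    @property
    def d_max(self) -> int:
        return len(self.class_counts) - 1

    @property
    def mean(self) -> float:
        return float(np.arange(len(self.class_counts)) @ self.class_freqs)


def mismatch_distribution(
    cat: HaplotypeCatalog, ct: CountTable, pop: str | None = None
) -> MismatchDistribution:
    """Mismatch distribution for one population (or pooled over all).

    Pairs are expanded combinatorially from haplotype counts: C(c_i, 2)
    within-haplotype pairs land in class 0 and c_i * c_j cross pairs in the
    class given by the raw step count between haplotypes i and j.
    """
    if list(cat.ids) != list(ct.haplotypes):
        raise DataError("catalog and count table haplotype order differ")
    counts = ct.pooled() if pop is None else ct.pop_counts(pop)
    n = int(counts.sum())
    if n < 2:
        raise DataError("mismatch distribution requires n >= 2")
    steps = step_matrix(cat).d.astype(int)
    d_max = int(steps[np.outer(counts > 0, counts > 0)].max())
    hist = np.zeros(d_max + 1, dtype=np.int64)
    idx = np.nonzero(counts)[0]
    for a, i in enumerate(idx):
        ci = int(counts[i])
        hist[0] += ci * (ci - 1) // 2
        for j in idx[a + 1 :]:
            hist[steps[i, j]] += ci * int(counts[j])
    return MismatchDistribution(hist)


# ---------------------------------------------------------------------------
# sudden-expansion expectation and fit


def expected_mismatch(
    tau: float, theta0: float, theta1: float, n_classes: int
) -> np.ndarray:
    """Expected class probabilities F_j under the sudden-expansion model.

    Classes j = 0..n_classes-1, with all probability mass beyond the last
    class folded into it, so the vector sums to 1 for any parameters.

    The closed form follows from mixing the Poisson(number of differences |
    pair coalescence time) over the two-epoch exponential coalescence-time
    density: with beta = (theta1 + 1)/theta1,

        F_j = Fhat_j(theta1) * P[Pois(beta tau) > j]
              + e^(-tau/theta1) * sum_{i=0}^{j} Pois(j - i; tau) Fhat_i(theta0)

    where Fhat_j(theta) = theta^j / (theta + 1)^(j+1) is the equilibrium
    (geometric) distribution. theta0 = 0 is allowed (point mass before the
    expansion); theta1 must be positive.
    """
    if tau < 0 or theta0 < 0 or theta1 <= 0 or theta0 > theta1:
        raise DataError("need 0 <= theta0 <= theta1, theta1 > 0, tau >= 0")
    if n_classes < 1:
        raise DataError("need at least one class")
    j = np.arange(n_classes)
    beta = (theta1 + 1.0) / theta1

    def geometric(theta: float) -> np.ndarray:
        if theta == 0:
            out = np.zeros(n_classes)
            out[0] = 1.0
            return out
        # log-space: theta^j / (theta+1)^(j+1) overflows for large theta
        return np.exp(j * math.log(theta) - (j + 1) * math.log(theta + 1.0))

    recent = geometric(theta1) * stats.poisson.sf(j, beta * tau)
    pois = stats.poisson.pmf(j, tau) if tau > 0 else np.eye(1, n_classes)[0]
    old = math.exp(-tau / theta1) * np.convolve(pois, geometric(theta0))[:n_classes]
    F = recent + old
    F[-1] += max(0.0, 1.0 - F.sum())  # fold the truncated tail into the last class
    return F


@dataclass
class ExpansionFit:
    """Least-squares sudden-expansion fit to an observed mismatch distribution."""

    tau: float
    theta0: float
    theta1: float
    sse: float
    degenerate: bool = False  # single-class input: tau pinned at 0


def fit_sudden_expansion(
    md: MismatchDistribution, n_starts: int = 8, seed: int = 0
) -> ExpansionFit:
    """Fit (tau, theta0, theta1) by bounded multi-start least squares.

    Minimises the sum of squared deviations between observed class
    frequencies and the model expectation. Starts include the
    method-of-moments guess (tau at the distribution mean) plus seeded
    random draws; theta1 is capped at 9999. A single-class (monomorphic)
    distribution short-circuits to tau = 0, flagged as degenerate.
    """
    x = md.class_freqs
    if int(np.sum(md.class_counts > 0)) < 2:
        return ExpansionFit(0.0, 0.0, 1e-6, 0.0, degenerate=True)
    n_classes = len(x)

    def sse(params: np.ndarray) -> float:
        tau, th0, dth = params
        try:
            F = expected_mismatch(tau, th0, th0 + dth, n_classes)
        except DataError:
            return 1e6
        return float(np.sum((x - F) ** 2))

    mean = md.mean
    bounds = [(0.0, 4.0 * max(mean, md.d_max, 1.0)), (0.0, THETA1_CAP), (1e-6, THETA1_CAP)]
    rng = np.random.default_rng(seed)
    starts = [np.array([mean, 0.1, max(10.0, 5.0 * mean)])]
    for _ in range(n_starts - 1):
        starts.append(
            np.array(
                [
                    rng.uniform(0, 2.0 * max(mean, 1.0)),
                    rng.uniform(0, max(mean, 1.0)),
                    rng.uniform(1.0, 100.0),
                ]
            )
        )
    best = None
    for s0 in starts:
        res = optimize.minimize(sse, s0, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    tau, th0, dth = best.x
    return ExpansionFit(float(tau), float(th0), float(th0 + dth), float(best.fun))


# ---------------------------------------------------------------------------
# raggedness


def raggedness(md: MismatchDistribution | Sequence[float]) -> float:
    """Harpending's raggedness index r = sum_{i=1}^{d+1} (x_i - x_{i-1})^2.

    x are the observed class frequencies over 0..d with a terminal zero
    class appended (x_{d+1} = 0). Smooth unimodal distributions give small
    r; ragged multimodal ones inflate it. Trailing zero classes do not
    change the value.
    """
    x = md.class_freqs if isinstance(md, MismatchDistribution) else np.asarray(md, float)
    x = np.append(x, 0.0)
    return float(np.sum(np.diff(x) ** 2))


@dataclass
class RaggednessResult:
    H_RI: float
    p: float
    n_boot: int

    @property
    def consistent_with_expansion(self) -> bool:
        return self.p > 0.05


def simulate_expansion_mismatch(
    n: int, fit: ExpansionFit, n_boot: int, seed: int | None = None
):
    """Yield per-replicate mismatch histograms under a fitted expansion.

    Coalescent units: present-day size 1 and per-lineage mutation rate
    theta1/2, so the expansion time in coalescent units is tau/theta1 and
    the ancestral size is theta0/theta1.
    """
    import msprime

    theta1 = max(fit.theta1, 1e-6)
    old_size = max(fit.theta0 / theta1, 1e-9)
    demography = msprime.Demography()
    demography.add_population(name="pop", initial_size=1.0)
    if fit.tau > 0:
        demography.add_population_parameters_change(
            time=fit.tau / theta1, initial_size=old_size, population="pop"
        )
    rng = np.random.default_rng(seed)
    anc_seed, mut_seed = (int(v) for v in rng.integers(1, 2**31 - 1, size=2))
    reps = msprime.sim_ancestry(
        samples={"pop": n},
        ploidy=1,
        demography=demography,
        sequence_length=1.0,
        num_replicates=n_boot,
        random_seed=anc_seed,
    )
    for i, ts in enumerate(reps):
        mts = msprime.sim_mutations(
            ts, rate=theta1 / 2.0, discrete_genome=False,
            random_seed=(mut_seed + i) % (2**31 - 1) + 1,
        )
        if mts.num_sites == 0:
            yield np.array([n * (n - 1) // 2])
            continue
        G = mts.genotype_matrix()  # sites x samples, infinite sites -> 0/1
        yield _pairwise_difference_histogram(G)


def _pairwise_difference_histogram(G: np.ndarray) -> np.ndarray:
    """Histogram of pairwise Hamming distances between sample columns."""
    uniq, inverse = np.unique(G.T, axis=0, return_inverse=True)
    counts = np.bincount(inverse)
    # Hamming distances between unique haplotypes (binary states)
    H = (uniq[:, None, :] != uniq[None, :, :]).sum(axis=2)
    d_max = int(H.max())
    hist = np.zeros(d_max + 1)
    for i in range(len(uniq)):
        hist[0] += counts[i] * (counts[i] - 1) / 2
        for j in range(i + 1, len(uniq)):
            hist[H[i, j]] += counts[i] * counts[j]
    return hist


def raggedness_pvalue(
    md: MismatchDistribution,
    fit: ExpansionFit,
    n: int,
    n_boot: int = 20000,
    seed: int | None = None,
) -> RaggednessResult:
    """Parametric-bootstrap p for the raggedness index.

    Simulates coalescent samples of size n under the fitted sudden-expansion
    demography, recomputes the raggedness index per replicate, and reports
    p = proportion of simulated indices >= the observed one. Large p (> 0.05
    by convention) means the data are as smooth as expansion predicts.
    """
    if n_boot < 1:
        raise DataError("n_boot must be positive")
    obs = raggedness(md)
    hits = 0
    for hist in simulate_expansion_mismatch(n, fit, n_boot, seed):
        if raggedness(hist / hist.sum()) >= obs:
            hits += 1
    return RaggednessResult(obs, hits / n_boot, n_boot)
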