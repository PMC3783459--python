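"""Inter-haplotype genetic distances.

Three metrics feed the downstream variance analyses:

* Tamura–Nei (TN93) model-corrected distances, which separate the two
  transition classes (A<->G among purines, C<->T among pyrimidines) from
  transversions and weight them by empirical base frequencies. Used for
  the distance-based fixation index (Phi_ST) and nucleotide diversity.
* The 0/1 haplotype-identity metric, under which the same variance
  partition reduces to the classical frequency-based F_ST.
* Raw mutational step counts (number of differing, jointly non-missing
  sites), used for mismatch distributions and the haplotype network.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .dataio import MISSING_CHARS, CountTable, DataError, HaplotypeCatalog

NUCS = "ACGT"


class SaturationError(ValueError):
    """TN93 correction undefined: a log argument is non-positive.

    Raised instead of clamping or returning infinity — a silently clamped
    distance would bias the downstream variance partition.
    """


@dataclass(frozen=True)
class PairCounts:
    """Site-difference tallies between two equal-length sequences.

    P1: A<->G differences, P2: C<->T differences, Q: transversion
    differences, M: jointly non-missing compared sites.
    """

    P1: int
    P2: int
    Q: int
    M: int

    def __post_init__(self) -> None:
        if min(self.P1, self.P2, self.Q) < 0 or self.P1 + self.P2 + self.Q > self.M:
            raise DataError("inconsistent pair counts")


def pair_counts(
    seq_a: str, seq_b: str, missing_policy: str = "pairwise_ignore"
) -> PairCounts:
    """Classify the differences between two aligned sequences.

    Under ``pairwise_ignore`` (the default, and the conventional choice for
    model-based distances) any site with N or - in either sequence is
    excluded from the comparison; ``strict`` demands fully resolved
    sequences and errors on missing data.
    """
    if len(seq_a) != len(seq_b):
        raise DataError("sequences must have equal length")
    p1 = p2 = q = m = 0
    for ca, cb in zip(seq_a, seq_b):
        if ca in MISSING_CHARS or cb in MISSING_CHARS:
            if missing_policy == "strict":
                raise DataError("missing data not allowed under strict policy")
            continue
        m += 1
        if ca == cb:
            continue
        pair = frozenset((ca, cb))
        if pair == frozenset("AG"):
            p1 += 1
        elif pair == frozenset("CT"):
            p2 += 1
        else:
            q += 1
    if m == 0:
        raise DataError("no jointly non-missing sites to compare")
    return PairCounts(p1, p2, q, m)


def base_frequencies(cat: HaplotypeCatalog, counts: Sequence[int] | None = None) -> np.ndarray:
    """Empirical A/C/G/T frequencies, count-weighted over individuals.

    ``counts`` gives the pooled number of individuals per haplotype (in
    catalog order); omitted, each haplotype is weighted equally. Missing
    states are excluded.
    """
    seqs = cat.sequences()
    if counts is None:
        w = np.ones(len(seqs))
    else:
        w = np.asarray(counts, dtype=float)
        if w.shape != (len(seqs),) or (w < 0).any() or w.sum() == 0:
            raise DataError("counts must be non-negative with positive sum")
    tally = dict.fromkeys(NUCS, 0.0)
    for seq, wi in zip(seqs, w):
        for c in seq:
            if c in tally:
                tally[c] += wi
    total = sum(tally.values())
    if total == 0:
        raise DataError("no resolved bases in catalog")
    return np.array([tally[c] / total for c in NUCS])


def tn93_distance(pc: PairCounts, base_freqs: Sequence[float]) -> float:
    """Tamura–Nei (1993) distance from difference tallies and base frequencies.

    d = -k1 ln(w1) - k2 ln(w2) - k3 ln(w3) with

        k1 = 2 gA gG / gR,  k2 = 2 gC gT / gY,
        k3 = 2 (gR gY - gA gG gY/gR - gC gT gR/gY),
        w1 = 1 - p1 gR/(2 gA gG) - q/(2 gR),
        w2 = 1 - p2 gY/(2 gC gT) - q/(2 gY),
        w3 = 1 - q/(2 gR gY),

    where p1 = P1/M, p2 = P2/M, q = Q/M, gR = gA + gG, gY = gC + gT.
    Identical sequences give 0; a non-positive log argument raises
    :class:`SaturationError`.
    """
    g = np.asarray(base_freqs, dtype=float)
    if g.shape != (4,) or (g <= 0).any() or abs(g.sum() - 1.0) > 1e-8:
        raise DataError("base_freqs must be 4 positive values summing to 1")
    gA, gC, gG, gT = g
    gR, gY = gA + gG, gC + gT
    p1, p2, q = pc.P1 / pc.M, pc.P2 / pc.M, pc.Q / pc.M
    if p1 == 0 and p2 == 0 and q == 0:
        return 0.0
    w1 = 1.0 - p1 * gR / (2.0 * gA * gG) - q / (2.0 * gR)
    w2 = 1.0 - p2 * gY / (2.0 * gC * gT) - q / (2.0 * gY)
    w3 = 1.0 - q / (2.0 * gR * gY)
    if min(w1, w2, w3) <= 0.0:
        raise SaturationError(
            f"saturated pair: log arguments w1={w1:.4g}, w2={w2:.4g}, w3={w3:.4g}"
        )
    k1 = 2.0 * gA * gG / gR
    k2 = 2.0 * gC * gT / gY
    k3 = 2.0 * (gR * gY - gA * gG * gY / gR - gC * gT * gR / gY)
    return -k1 * math.log(w1) - k2 * math.log(w2) - k3 * math.log(w3)


def p_distance(pc: PairCounts) -> float:
    """Uncorrected proportion of differing sites."""
    return (pc.P1 + pc.P2 + pc.Q) / pc.M


def step_count(seq_a: str, seq_b: str) -> int:
    """Number of differing, jointly non-missing sites (mutational steps)."""
    if len(seq_a) != len(seq_b):
        raise DataError("sequences must have equal length")
    return sum(
        1
        for ca, cb in zip(seq_a, seq_b)
        if ca != cb and ca not in MISSING_CHARS and cb not in MISSING_CHARS
    )


@dataclass
class DistanceMatrix:
    """Symmetric non-negative inter-haplotype distance matrix."""

    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        k = len(self.ids)
        if self.d.shape != (k, k):
            raise DataError("distance matrix shape does not match ids")
        if not np.allclose(self.d, self.d.T):
            raise DataError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise DataError("distance matrix must have zero diagonal")
        if (self.d < 0).any() or not np.isfinite(self.d).all():
            raise DataError("distances must be finite and non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.ids, columns=self.ids)

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="id")

    @classmethod
    def read(cls, path: str | Path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col="id")
        return cls(list(df.index), df.to_numpy())


def _pairwise(cat: HaplotypeCatalog, fn) -> np.ndarray:
    seqs = cat.sequences()
    k = len(seqs)
    d = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            d[i, j] = d[j, i] = fn(seqs[i], seqs[j])
    return d


def tn93_matrix(
    cat: HaplotypeCatalog,
    counts: Sequence[int] | None = None,
    missing_policy: str = "pairwise_ignore",
) -> DistanceMatrix:
    """TN93 distance matrix over a haplotype catalog.

    Base frequencies are estimated empirically from the catalog, weighted by
    ``counts`` (pooled individuals per haplotype) when given.
    """
    g = base_frequencies(cat, counts)
    return DistanceMatrix(
        cat.ids,
        _pairwise(cat, lambda a, b: tn93_distance(pair_counts(a, b, missing_policy), g)),
    )


def step_matrix(cat: HaplotypeCatalog) -> DistanceMatrix:
    """Raw mutational-step distance matrix over a haplotype catalog."""
    return DistanceMatrix(cat.ids, _pairwise(cat, step_count))


def identity_matrix(ids: Sequence[str]) -> DistanceMatrix:
    """0/1 haplotype-identity metric: 0 on the diagonal, 1 elsewhere."""
    k = len(ids)
    return DistanceMatrix(list(ids), np.ones((k, k)) - np.eye(k))


def distance_matrix_for(
    metric: str, cat: HaplotypeCatalog | None, ct: CountTable
) -> DistanceMatrix:
    """Build the distance matrix named by ``metric`` ('tn93' or 'identity')."""
    if metric == "identity":
        return identity_matrix(ct.haplotypes)
    if metric == "tn93":
        if cat is None:
            raise DataError("tn93 metric requires a haplotype catalog")
        pooled = [int(ct.pooled()[ct.haplotypes.index(h)]) for h in cat.ids]
        return tn93_matrix(cat, pooled)
    raise DataError(f"unknown metric {metric!r}")
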