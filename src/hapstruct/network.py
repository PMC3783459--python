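"""Statistical-parsimony-style haplotype networks.

Observed haplotypes are linked through single-mutation steps, with
unobserved intermediate haplotypes inferred along multi-step connections,
up to a parsimony connection limit: the largest number of steps at which
two haplotypes can be joined while the probability that the connection is
free of superimposed (homoplasious) change stays above a confidence level
(0.95 by default).

The classic cladogram-estimation order of TCS is approximated here by the
union of all minimum spanning trees of the step-distance graph (ties kept
as flagged alternative connections) followed by deterministic path
expansion; the output is meant for descriptive displays of star-like
genealogies, not for nested clade analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .dataio import CountTable, DataError, HaplotypeCatalog
from .distances import step_matrix


@dataclass
class ParsimonyLimit:
    j_max: int
    confidence: float
    L: int


def _distinct_site_occupancy(m: int, L: int) -> np.ndarray:
    """P(s distinct sites hit | m mutations uniform over L sites), s = 0..m."""
    probs = np.zeros(m + 1)
    probs[0] = 1.0
    for _ in range(m):
        new = np.zeros(m + 1)
        for s in range(m):
            if probs[s] == 0:
                continue
            new[s + 1] += probs[s] * (L - s) / L
            new[s] += probs[s] * s / L
        probs = new
    return probs


def parsimony_probability(j: int, L: int, lam: float, m_cap: int | None = None) -> float:
    """P(no superimposed change | j observed differences) over L sites.

    Model: the true number of mutations M separating a pair is Poisson with
    mean ``lam`` (estimated from the data's corrected divergence); mutations
    hit sites uniformly and independently. A connection is parsimonious when
    all M mutations hit distinct sites, in which case the observed
    difference count equals M. Bayes over M >= j gives

        P(pars | j) = P(M = j) P(distinct = j | j)
                      / sum_{m >= j} P(M = m) P(distinct = j | m)
    """
    if j < 0 or L <= 0 or lam < 0:
        raise DataError("need j >= 0, L > 0, lam >= 0")
    if j == 0:
        return 1.0
    if m_cap is None:
        m_cap = j + max(25, int(lam + 10.0 * np.sqrt(lam + 1.0)))
    numer = 0.0
    denom = 0.0
    for m in range(j, m_cap + 1):
        pm = stats.poisson.pmf(m, lam) if lam > 0 else (1.0 if m == 0 else 0.0)
        if pm == 0.0 and m > lam:
            if denom > 0:
                break
            continue
        occ = _distinct_site_occupancy(m, L)
        p_obs = occ[j] if j < len(occ) else 0.0
        denom += pm * p_obs
        if m == j:
            numer = pm * p_obs
    if denom == 0.0:
        return 0.0
    return numer / denom


def parsimony_limit(
    L: int, pairwise_steps, confidence: float = 0.95
) -> ParsimonyLimit:
    """Connection limit: largest j with parsimony probability >= confidence.

    ``pairwise_steps`` is the collection of observed pairwise step counts;
    the per-pair mutation intensity lam is estimated from their mean with a
    Jukes-Cantor multiple-hit correction. The scan runs from 1 step upward
    and is capped at the maximum observed distance, so as confidence falls
    to 0 the limit grows to span the whole dataset.
    """
    steps = np.asarray(list(pairwise_steps), dtype=float)
    if L <= 0:
        raise DataError("L must be positive")
    if steps.size == 0 or (steps < 0).any():
        raise DataError("pairwise step counts required")
    max_obs = int(steps.max())
    if max_obs == 0:
        return ParsimonyLimit(1, confidence, L)
    q = float(steps.mean()) / L
    lam = -L * 0.75 * np.log1p(-4.0 * q / 3.0) if q < 0.75 else float(steps.mean())
    j_max = 0
    for j in range(1, max_obs + 1):
        if parsimony_probability(j, L, lam) >= confidence:
            j_max = j
        else:
            break
    return ParsimonyLimit(max(j_max, 1), confidence, L)


# ---------------------------------------------------------------------------
# network construction


@dataclass
class HaplotypeNetwork:
    """Graph of observed haplotypes plus inferred intermediates.

    Node attributes: ``kind`` ('observed' or 'inferred'), ``count`` (pooled;
    0 for intermediates), ``pop_proportions`` (dict, observed nodes only)
    and ``sequence``. Edges are single mutational steps; ``alt`` marks
    alternative connections of equal length beyond the chosen spanning tree.
    """

    graph: nx.Graph
    components: int

    def observed_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["kind"] == "observed"]

    def inferred_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["kind"] == "inferred"]

    def node_table(self) -> pd.DataFrame:
        rows = []
        for n, d in self.graph.nodes(data=True):
            row = {"node": n, "kind": d["kind"], "count": d["count"]}
            row.update(
                {f"prop_{p}": v for p, v in (d.get("pop_proportions") or {}).items()}
            )
            rows.append(row)
        return pd.DataFrame(rows)

    def edge_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"node_a": a, "node_b": b, "alt": d.get("alt", False)}
                for a, b, d in self.graph.edges(data=True)
            ]
        )

    def write_graphml(self, path: str | Path) -> None:
        g = self.graph.copy()
        for _, d in g.nodes(data=True):  # graphml cannot store dicts
            props = d.pop("pop_proportions", None) or {}
            for p, v in props.items():
                d[f"prop_{p}"] = float(v)
        nx.write_graphml(g, str(path))


def _mst_union_edges(
    ids: list[str], steps: np.ndarray, limit: int
) -> tuple[list[tuple[str, str, int]], set[tuple[str, str]]]:
    """Edges in the union of all MSTs of the step graph (weights <= limit).

    Kruskal weight classes: an edge belongs to some MST iff its endpoints
    lie in different components of the graph built from strictly smaller
    weights. Also returns the edge set of one deterministic MST
    (lexicographic tie-break) so the remainder can be flagged ``alt``.
    """
    k = len(ids)
    edges = sorted(
        (int(steps[i, j]), ids[i], ids[j])
        for i in range(k)
        for j in range(i + 1, k)
        if 0 < steps[i, j] <= limit
    )
    uf = {n: n for n in ids}

    def find(x):
        while uf[x] != x:
            uf[x] = uf[uf[x]]
            x = uf[x]
        return x

    union_edges: list[tuple[str, str, int]] = []
    primary: set[tuple[str, str]] = set()
    i = 0
    while i < len(edges):
        w = edges[i][0]
        group = []
        while i < len(edges) and edges[i][0] == w:
            group.append(edges[i])
            i += 1
        # union-of-MSTs membership is judged against pre-class components
        in_union = [
            (w0, a, b) for w0, a, b in group if find(a) != find(b)
        ]
        union_edges.extend((a, b, w0) for w0, a, b in in_union)
        for w0, a, b in in_union:  # lexicographic order fixes the primary MST
            ra, rb = find(a), find(b)
            if ra != rb:
                uf[rb] = ra
                primary.add((a, b))
    return union_edges, primary


def _mutation_path(seq_a: str, seq_b: str) -> list[str]:
    """Intermediate sequences from a to b, mutating sites in ascending order."""
    diffs = [i for i, (x, y) in enumerate(zip(seq_a, seq_b)) if x != y]
    out = []
    cur = list(seq_a)
    for pos in diffs[:-1]:
        cur[pos] = seq_b[pos]
        out.append("".join(cur))
    return out


def build_network(
    cat: HaplotypeCatalog, ct: CountTable, limit: ParsimonyLimit | int
) -> HaplotypeNetwork:
    """Build the haplotype network under a parsimony connection limit.

    Multi-step connections in the spanning structure are expanded by
    inserting inferred intermediate nodes (one per extra step) along the
    deterministic ascending-position mutational path. If the limit leaves
    the graph disconnected, each component is returned and a warning is
    issued.
    """
    j_max = limit.j_max if isinstance(limit, ParsimonyLimit) else int(limit)
    if j_max < 1:
        raise DataError("connection limit must be at least 1")
    if list(cat.ids) != list(ct.haplotypes):
        raise DataError("catalog and count table haplotype order differ")
    steps = step_matrix(cat).d.astype(int)
    union_edges, primary = _mst_union_edges(cat.ids, steps, j_max)
    g = nx.Graph()
    pooled = ct.pooled()
    n_per_pop = ct.n_per_pop
    for i, hid in enumerate(cat.ids):
        props = {
            p: float(ct.counts[i, j]) / pooled[i] if pooled[i] else 0.0
            for j, p in enumerate(ct.populations)
        }
        g.add_node(
            hid,
            kind="observed",
            count=int(pooled[i]),
            sequence=cat.entries[hid],
            pop_proportions=props,
        )
    n_inferred = 0
    for a, b, w in union_edges:
        alt = (a, b) not in primary
        if w == 1:
            g.add_edge(a, b, alt=alt)
            continue
        path = _mutation_path(cat.entries[a], cat.entries[b])
        prev = a
        for seq in path:
            n_inferred += 1
            mid = f"mv{n_inferred}"
            g.add_node(mid, kind="inferred", count=0, sequence=seq)
            g.add_edge(prev, mid, alt=alt)
            prev = mid
        g.add_edge(prev, b, alt=alt)
    n_comp = nx.number_connected_components(g)
    if n_comp > 1:
        warnings.warn(
            f"network disconnected under limit {j_max}: {n_comp} components",
            stacklevel=2,
        )
    return HaplotypeNetwork(g, n_comp)


def write_edge_list(net: HaplotypeNetwork, path: str | Path) -> None:
    net.edge_table().to_csv(path, sep="\t", index=False)


def write_node_table(net: HaplotypeNetwork, path: str | Path) -> None:
    net.node_table().to_csv(path, sep="\t", index=False)
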