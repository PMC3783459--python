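"""Sequence and tabular input handling.

Reads aligned FASTA + population maps, collapses aligned sequences into
haplotypes, tabulates polymorphic sites, and reconstructs integer haplotype
counts from published relative-frequency tables (frequencies printed as
count/n round back to integers exactly when the table was printed to enough
decimals).

The central exchange object is :class:`CountTable`: a haplotype × population
matrix of non-negative integer counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_CHARS = set("ACGTN-")
MISSING_CHARS = set("N-")


class DataError(ValueError):
    """Invalid or inconsistent input data."""


@dataclass(frozen=True)
class SampleRecord:
    """One aligned sequence with its sample id and population label."""

    sample_id: str
    population: str
    sequence: str

    def __post_init__(self) -> None:
        bad = set(self.sequence.upper()) - VALID_CHARS
        if bad:
            raise DataError(
                f"sample {self.sample_id!r}: invalid characters {sorted(bad)}"
            )
        object.__setattr__(self, "sequence", self.sequence.upper())


@dataclass
class Alignment:
    """An ordered collection of equal-length sequences with population labels."""

    records: list[SampleRecord]

    def __post_init__(self) -> None:
        if not self.records:
            raise DataError("alignment must contain at least one record")
        L = len(self.records[0].sequence)
        for rec in self.records:
            if len(rec.sequence) != L:
                raise DataError(
                    f"sequence length mismatch: {rec.sample_id!r} has "
                    f"{len(rec.sequence)} bp, expected {L}"
                )
        seen: set[str] = set()
        for rec in self.records:
            if rec.sample_id in seen:
                raise DataError(f"duplicate sample id {rec.sample_id!r}")
            seen.add(rec.sample_id)

    @property
    def L(self) -> int:
        return len(self.records[0].sequence)

    @property
    def populations(self) -> list[str]:
        """Population labels in order of first appearance."""
        out: list[str] = []
        for rec in self.records:
            if rec.population not in out:
                out.append(rec.population)
        return out

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class HaplotypeCatalog:
    """Map from haplotype id (SP1, SP2, ...) to representative sequence.

    Ids are assigned in decreasing pooled-frequency order, ties broken by
    first occurrence in the input.
    """

    entries: dict[str, str]

    def __post_init__(self) -> None:
        if not self.entries:
            raise DataError("catalog must contain at least one haplotype")
        lengths = {len(s) for s in self.entries.values()}
        if len(lengths) != 1:
            raise DataError("catalog sequences must share one length")

    @property
    def ids(self) -> list[str]:
        return list(self.entries)

    @property
    def L(self) -> int:
        return len(next(iter(self.entries.values())))

    def sequences(self) -> list[str]:
        return list(self.entries.values())


@dataclass
class CountTable:
    """Haplotype × population integer count matrix.

    ``counts[i, j]`` is the number of individuals in population
    ``populations[j]`` carrying haplotype ``haplotypes[i]``.
    """

    populations: list[str]
    haplotypes: list[str]
    counts: np.ndarray  # shape (n_hap, n_pop), non-negative ints

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.haplotypes), len(self.populations)):
            raise DataError("counts shape does not match labels")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise DataError("counts must be integers")
            self.counts = np.round(self.counts).astype(np.int64)
        if (self.counts < 0).any():
            raise DataError("counts must be non-negative")

    @property
    def n_per_pop(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())

    def pop_counts(self, pop: str) -> np.ndarray:
        """Count vector over haplotypes for one population."""
        return self.counts[:, self._pop_index(pop)]

    def pooled(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def subset(self, pops: Sequence[str]) -> "CountTable":
        idx = [self._pop_index(p) for p in pops]
        return CountTable(list(pops), list(self.haplotypes), self.counts[:, idx])

    def _pop_index(self, pop: str) -> int:
        try:
            return self.populations.index(pop)
        except ValueError:
            raise DataError(f"unknown population {pop!r}") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self.haplotypes, columns=self.populations
        )

    def frequencies(self) -> "FrequencyTable":
        freqs = self.counts / self.n_per_pop[np.newaxis, :]
        return FrequencyTable(list(self.populations), list(self.haplotypes), freqs)


@dataclass
class FrequencyTable:
    """Relative haplotype frequencies per population (columns sum to ~1)."""

    populations: list[str]
    haplotypes: list[str]
    freqs: np.ndarray  # shape (n_hap, n_pop), values in [0, 1]

    ROW_SUM_TOL = 0.01  # printed 3-decimal tables can sum to 0.99-1.01

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.shape != (len(self.haplotypes), len(self.populations)):
            raise DataError("frequency shape does not match labels")
        if (self.freqs < 0).any() or (self.freqs > 1).any():
            raise DataError("frequencies must lie in [0, 1]")
        sums = self.freqs.sum(axis=0)
        if (np.abs(sums - 1.0) > self.ROW_SUM_TOL).any():
            raise DataError(f"per-population frequency sums {sums} too far from 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.freqs, index=self.haplotypes, columns=self.populations)


# ---------------------------------------------------------------------------
# reading


def read_popmap(popmap_path: str | Path) -> dict[str, str]:
    """Read a two-column (sample_id <TAB> population) map."""
    popmap: dict[str, str] = {}
    for lineno, line in enumerate(Path(popmap_path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise DataError(f"{popmap_path}:{lineno}: expected 2 tab-separated fields")
        sid, pop = parts
        if sid in popmap:
            raise DataError(f"duplicate sample id {sid!r} in popmap")
        popmap[sid] = pop
    if not popmap:
        raise DataError(f"empty popmap {popmap_path}")
    return popmap


def read_alignment(fasta_path: str | Path, popmap_path: str | Path) -> Alignment:
    """Read an aligned FASTA plus popmap into an :class:`Alignment`.

    Every FASTA id must appear in the popmap; all sequences must share one
    length. FASTA order is preserved.
    """
    popmap = read_popmap(popmap_path)
    records = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id not in popmap:
            raise DataError(f"sample {rec.id!r} missing from popmap")
        records.append(SampleRecord(rec.id, popmap[rec.id], str(rec.seq)))
    if not records:
        raise DataError(f"no sequences in {fasta_path}")
    return Alignment(records)


# ---------------------------------------------------------------------------
# haplotype collapsing


def _compatible(a: str, b: str) -> bool:
    """True when a and b agree at every site non-missing in both."""
    return all(
        ca == cb or ca in MISSING_CHARS or cb in MISSING_CHARS
        for ca, cb in zip(a, b)
    )


def collapse_haplotypes(
    aln: Alignment, missing_policy: str = "strict"
) -> tuple[HaplotypeCatalog, CountTable]:
    """Collapse an alignment into distinct haplotypes with per-population counts.

    ``strict`` treats N/- as ordinary (distinct) states so two sequences share
    a haplotype only when their strings are identical. ``pairwise_ignore``
    merges sequences that agree at every jointly non-missing site (greedy, in
    input order, against each class representative).

    Haplotype ids are SP1, SP2, ... in decreasing pooled-count order with ties
    broken by first occurrence.
    """
    if missing_policy not in ("strict", "pairwise_ignore"):
        raise DataError(f"unknown missing policy {missing_policy!r}")
    pops = aln.populations
    classes: list[dict] = []  # {"seq": representative, "counts": {pop: n}, "order": i}
    for i, rec in enumerate(aln.records):
        hit = None
        for cl in classes:
            if missing_policy == "strict":
                if rec.sequence == cl["seq"]:
                    hit = cl
                    break
            elif _compatible(rec.sequence, cl["seq"]):
                hit = cl
                break
        if hit is None:
            hit = {"seq": rec.sequence, "counts": dict.fromkeys(pops, 0), "order": i}
            classes.append(hit)
        hit["counts"][rec.population] = hit["counts"].get(rec.population, 0) + 1
    classes.sort(key=lambda c: (-sum(c["counts"].values()), c["order"]))
    ids = [f"SP{k + 1}" for k in range(len(classes))]
    cat = HaplotypeCatalog({hid: cl["seq"] for hid, cl in zip(ids, classes)})
    counts = np.array(
        [[cl["counts"].get(p, 0) for p in pops] for cl in classes], dtype=np.int64
    )
    return cat, CountTable(list(pops), ids, counts)


def expand_counts(cat: HaplotypeCatalog, ct: CountTable) -> Alignment:
    """Inverse of :func:`collapse_haplotypes`: repeat each haplotype by its count."""
    records = []
    k = 0
    for j, pop in enumerate(ct.populations):
        for i, hid in enumerate(ct.haplotypes):
            for _ in range(int(ct.counts[i, j])):
                records.append(SampleRecord(f"ind{k}", pop, cat.entries[hid]))
                k += 1
    return Alignment(records)


# ---------------------------------------------------------------------------
# polymorphic sites

TRANSITION_PAIRS = {frozenset("AG"), frozenset("CT")}


def classify_pair(a: str, b: str) -> str:
    """Classify an unordered nucleotide state pair as transition/transversion."""
    if a == b:
        raise ValueError("states must differ")
    return "transition" if frozenset((a, b)) in TRANSITION_PAIRS else "transversion"


def polymorphic_site_table(cat: HaplotypeCatalog) -> pd.DataFrame:
    """Tabulate variable alignment columns (1-based positions).

    One row per polymorphic site with the observed (non-missing) states, a
    classification — transition, transversion, or multi-state — and the
    per-state-pair transition/transversion tallies. Missing states (N/-) are
    ignored when deciding whether a site is polymorphic.
    """
    seqs = cat.sequences()
    rows = []
    for pos in range(cat.L):
        states = sorted({s[pos] for s in seqs} - MISSING_CHARS)
        if len(states) < 2:
            continue
        pairs = [
            (a, b, classify_pair(a, b))
            for i, a in enumerate(states)
            for b in states[i + 1 :]
        ]
        n_ts = sum(1 for *_, c in pairs if c == "transition")
        n_tv = len(pairs) - n_ts
        if len(states) == 2:
            klass = pairs[0][2]
        else:
            klass = "multi-state"
        rows.append(
            {
                "position": pos + 1,
                "states": "/".join(states),
                "class": klass,
                "transitions": n_ts,
                "transversions": n_tv,
            }
        )
    return pd.DataFrame(
        rows, columns=["position", "states", "class", "transitions", "transversions"]
    )


# ---------------------------------------------------------------------------
# frequency-table reconstruction


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def counts_from_frequencies(
    ft: FrequencyTable,
    n_per_pop: Sequence[int],
    corrections: Mapping[tuple[str, str], int] | None = None,
) -> CountTable:
    """Reconstruct integer counts from a printed relative-frequency table.

    Each cell is ``round(freq * n)`` (nearest integer, half-up). The
    reconstruction is validated: if a population's counts do not sum to its
    declared n, a :class:`DataError` names the population; ``corrections``
    maps ``(population, haplotype)`` to an explicit count override.
    """
    n_per_pop = np.asarray(n_per_pop, dtype=np.int64)
    if n_per_pop.shape != (len(ft.populations),) or (n_per_pop <= 0).any():
        raise DataError("n_per_pop must give one positive size per population")
    counts = np.array(
        [[_round_half_up(f * n) for f, n in zip(row, n_per_pop)] for row in ft.freqs],
        dtype=np.int64,
    )
    if corrections:
        for (pop, hap), value in corrections.items():
            i = ft.haplotypes.index(hap)
            j = ft.populations.index(pop)
            counts[i, j] = value
    sums = counts.sum(axis=0)
    bad = [
        f"{p}: reconstructed {s}, declared {n}"
        for p, s, n in zip(ft.populations, sums, n_per_pop)
        if s != n
    ]
    if bad:
        raise DataError("count reconstruction mismatch — " + "; ".join(bad))
    return CountTable(list(ft.populations), list(ft.haplotypes), counts)


# ---------------------------------------------------------------------------
# writing


def write_count_table(ct: CountTable, path: str | Path) -> None:
    ct.to_frame().to_csv(path, sep="\t", index_label="haplotype")


def read_count_table(path: str | Path) -> CountTable:
    df = pd.read_csv(path, sep="\t", index_col="haplotype")
    return CountTable(list(df.columns), list(df.index), df.to_numpy())


def write_frequency_table(ft: FrequencyTable, path: str | Path) -> None:
    ft.to_frame().to_csv(path, sep="\t", index_label="haplotype")


def read_frequency_table(path: str | Path) -> FrequencyTable:
    df = pd.read_csv(path, sep="\t", index_col="haplotype")
    return FrequencyTable(list(df.columns), list(df.index), df.to_numpy())


def write_haplotype_fasta(cat: HaplotypeCatalog, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=hid, description="") for hid, seq in cat.entries.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_haplotype_fasta(path: str | Path) -> HaplotypeCatalog:
    return HaplotypeCatalog(
        {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    )


def write_popmap(aln: Alignment, path: str | Path) -> None:
    Path(path).write_text(
        "".join(f"{r.sample_id}\t{r.population}\n" for r in aln.records)
    )


def write_alignment_fasta(aln: Alignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(r.sequence), id=r.sample_id, description="")
        for r in aln.records
    ]
    SeqIO.write(records, str(path), "fasta")
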