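"""Synthetic datasets with the statistical structure the pipeline assumes.

Three generators cover the regimes the analyses are designed for:

* a star-burst expansion sample — one ancestral sequence with independent
  Poisson mutation loads per lineage, giving the high-h / low-pi pattern
  of a recent demographic expansion;
* a two-deme structured-coalescent sample (split time + migration),
  exercising the weak-differentiation regime (fixation indices of order
  0.01-0.04);
* the published spinner-shark ND4 frequency table (37 haplotypes, four
  populations) paired with deterministic synthetic sequences built to show
  exactly 41 polymorphic sites (40 transitions, one transversion) in a
  shallow star configuration.

The fixture sequences are synthetic stand-ins for the real GenBank
haplotypes: statistics that depend only on haplotype frequencies (h, F_ST,
rarefaction, private haplotypes) match the published values; distance-based
statistics (Phi_ST, pi, mismatch shape) do not, and are labelled as such.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .dataio import (
    Alignment,
    CountTable,
    DataError,
    FrequencyTable,
    HaplotypeCatalog,
    SampleRecord,
    counts_from_frequencies,
)

NUCS = np.array(list("ACGT"))
TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


@dataclass
class StarExpansionParams:
    n: int = 100
    L: int = 857
    theta_star: float = 1.0  # expected mutations per lineage (pairwise E = 2x)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n < 1 or self.L < 1 or self.theta_star < 0:
            raise DataError("star-expansion parameters must be positive")


def simulate_star_expansion(p: StarExpansionParams) -> Alignment:
    """Star-genealogy sample: each lineage mutates independently.

    Every individual receives Poisson(theta_star / 2) mutations at distinct
    uniformly-chosen sites of a random ancestral sequence (infinite-sites
    approximation: within-lineage site collisions are redrawn), so the
    expected pairwise difference is theta_star. All individuals carry the
    single population label 'star'.
    """
    rng = np.random.default_rng(p.seed)
    ancestor = rng.choice(NUCS, size=p.L)
    records = []
    for i in range(p.n):
        k = int(rng.poisson(p.theta_star / 2.0))
        if k > p.L:
            raise DataError(
                f"lineage drew {k} mutations but only {p.L} sites exist"
            )
        seq = ancestor.copy()
        sites = rng.choice(p.L, size=k, replace=False)
        for s in sites:
            alts = [c for c in "ACGT" if c != seq[s]]
            seq[s] = alts[rng.integers(3)]
        records.append(SampleRecord(f"star{i}", "star", "".join(seq)))
    return Alignment(records)


@dataclass
class TwoPopParams:
    n1: int = 50
    n2: int = 50
    L: int = 857
    theta: float = 2.0  # expected within-deme pairwise difference
    t_split: float = 1.0  # split time, coalescent units of the deme size
    mig: float = 0.0  # scaled symmetric migration rate (lineages per unit time)
    seed: int | None = None

    def __post_init__(self) -> None:
        if min(self.n1, self.n2, self.L) < 1 or self.theta <= 0:
            raise DataError("invalid two-population parameters")
        if self.t_split < 0 or self.mig < 0:
            raise DataError("t_split and mig must be non-negative")


def simulate_two_pop_split(p: TwoPopParams) -> Alignment:
    """Two-deme structured-coalescent sample with infinite-sites mutation.

    Demes of equal size exchange migrants at scaled rate ``mig`` and merge
    into a single ancestral deme ``t_split`` coalescent units ago. Mutations
    are dropped on the genealogy at rate theta/2 per lineage and mapped onto
    distinct columns of an L-bp nucleotide alignment (ancestral state random,
    derived state a random transition/transversion).
    """
    import msprime

    dem = msprime.Demography()
    dem.add_population(name="pop1", initial_size=1.0)
    dem.add_population(name="pop2", initial_size=1.0)
    dem.add_population(name="anc", initial_size=1.0)
    if p.mig > 0:
        dem.set_symmetric_migration_rate(["pop1", "pop2"], p.mig)
    dem.add_population_split(time=max(p.t_split, 1e-9), derived=["pop1", "pop2"], ancestral="anc")
    rng = np.random.default_rng(p.seed)
    anc_seed, mut_seed = (int(v) for v in rng.integers(1, 2**31 - 1, size=2))
    ts = msprime.sim_ancestry(
        samples={"pop1": p.n1, "pop2": p.n2},
        ploidy=1,
        demography=dem,
        sequence_length=1.0,
        random_seed=anc_seed,
    )
    mts = msprime.sim_mutations(
        ts, rate=p.theta / 2.0, discrete_genome=False, random_seed=mut_seed
    )
    n_sites = mts.num_sites
    if n_sites > p.L:
        raise DataError(f"{n_sites} mutations exceed alignment length {p.L}")
    ancestor = rng.choice(NUCS, size=p.L)
    columns = rng.choice(p.L, size=n_sites, replace=False)
    seqs = np.tile(ancestor, (p.n1 + p.n2, 1))
    if n_sites:
        G = mts.genotype_matrix()  # (sites, samples)
        for s in range(n_sites):
            col = columns[s]
            alts = [c for c in "ACGT" if c != ancestor[col]]
            derived = alts[rng.integers(3)]
            seqs[G[s] > 0, col] = derived
    records = []
    for i in range(p.n1 + p.n2):
        pop = "pop1" if i < p.n1 else "pop2"
        records.append(SampleRecord(f"{pop}_{i}", pop, "".join(seqs[i])))
    return Alignment(records)


def simulate_multinomial_counts(
    ft: FrequencyTable, n_per_pop, seed: int | None = None
) -> CountTable:
    """Independent multinomial count draws per population (null calibration)."""
    rng = np.random.default_rng(seed)
    n_per_pop = np.asarray(n_per_pop, dtype=np.int64)
    if n_per_pop.shape != (len(ft.populations),) or (n_per_pop <= 0).any():
        raise DataError("need one positive n per population")
    cols = []
    for j, n in enumerate(n_per_pop):
        probs = ft.freqs[:, j] / ft.freqs[:, j].sum()
        cols.append(rng.multinomial(int(n), probs))
    return CountTable(
        list(ft.populations), list(ft.haplotypes), np.column_stack(cols)
    )


# ---------------------------------------------------------------------------
# published spinner-shark ND4 table


def _data_path(name: str) -> Path:
    return Path(resources.files("hapstruct").joinpath("data", name))


def load_spinner_frequency_table() -> tuple[FrequencyTable, np.ndarray, dict[str, str]]:
    """The published ND4 haplotype relative-frequency table.

    Returns (FrequencyTable, n_per_pop, accession map). Population sample
    sizes: NSW 208, QLD 63, NT 97, South Africa 62.
    """
    df = pd.read_csv(_data_path("spinner_nd4_frequencies.tsv"), sep="\t")
    pop_cols = ["NSW", "QLD", "NT", "South Africa"]
    n_per_pop = np.array([208, 63, 97, 62])
    ft = FrequencyTable(
        pop_cols, list(df["haplotype"]), df[pop_cols].to_numpy(dtype=float)
    )
    accessions = dict(zip(df["haplotype"], df["accession"]))
    return ft, n_per_pop, accessions


def spinner_count_table() -> CountTable:
    """Integer haplotype counts reconstructed from the published frequencies."""
    ft, n_per_pop, _ = load_spinner_frequency_table()
    return counts_from_frequencies(ft, n_per_pop)


def _fixture_sequences(haplotypes: list[str], L: int = 857) -> dict[str, str]:
    """Deterministic synthetic 857-bp haplotype sequences (star layout).

    SP1 is the central sequence. 31 variants carry one private mutation and
    5 carry two, for exactly 41 polymorphic sites; all mutations are
    transitions except one transversion on the final variant. Positions are
    deterministic, spread evenly across the sequence.
    """
    rng = np.random.default_rng(20130925)  # fixed: fixture is a versioned constant
    ancestor = rng.choice(NUCS, size=L)
    variants = haplotypes[1:]
    n_single = len(variants) - 5
    site_iter = iter(range(10, L - 10, (L - 20) // 41))
    entries = {haplotypes[0]: "".join(ancestor)}
    tv_assigned = False
    for idx, hid in enumerate(variants):
        n_mut = 1 if idx < n_single else 2
        seq = ancestor.copy()
        for _ in range(n_mut):
            pos = next(site_iter)
            base = seq[pos]
            if idx == len(variants) - 1 and not tv_assigned:
                seq[pos] = "C" if base in "AG" else "A"  # one transversion
                tv_assigned = True
            else:
                seq[pos] = TRANSITION[base]
        entries[hid] = "".join(seq)
    return entries


def table2_fixture() -> tuple[HaplotypeCatalog, CountTable]:
    """Synthetic stand-in for the published 37-haplotype dataset.

    The count table is the exact reconstruction of the published relative
    frequencies (row sums 208/63/97/62); the sequences are deterministic
    synthetic constructs with the published polymorphism summary (41 sites:
    40 transitions, 1 transversion) in a shallow star shape. Frequency-only
    statistics computed on this fixture match the published values;
    distance-based ones (Phi_ST, pi) deliberately do not.
    """
    ct = spinner_count_table()
    cat = HaplotypeCatalog(_fixture_sequences(list(ct.haplotypes)))
    return cat, ct


def fixture_alignment() -> Alignment:
    """The table2 fixture expanded to one record per individual."""
    from .dataio import expand_counts

    cat, ct = table2_fixture()
    return expand_counts(cat, ct)
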