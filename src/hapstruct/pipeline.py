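"""End-to-end orchestration, run manifests, and the observer-accuracy table.

``run_pipeline`` executes the full analysis chain — haplotype collapsing,
distances, diversity and neutrality, mismatch/expansion, AMOVA and pairwise
differentiation with Holm correction, rarefaction, and optionally the
Mantel test, subsample-robustness simulation and haplotype network — and
writes every table plus a JSON manifest (inputs, parameters, seeds,
package version) from which the run is reproducible.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dataio import (
    Alignment,
    CountTable,
    DataError,
    HaplotypeCatalog,
    collapse_haplotypes,
    polymorphic_site_table,
    write_count_table,
    write_haplotype_fasta,
)
from .distances import DistanceMatrix, distance_matrix_for
from .diversity import diversity_table, neutrality_pvalues
from .mismatch import fit_sudden_expansion, mismatch_distribution, raggedness, raggedness_pvalue
from .network import build_network, parsimony_limit, write_edge_list, write_node_table
from .sampling import ResampleConfig, rarefaction_curve, subsample_robustness
from .structure import amova, mantel_test, pairwise_structure
from .distances import step_matrix

log = logging.getLogger("hapstruct")

REFERENCE_DEFAULTS = {
    "n_perm": 20000,
    "n_boot": 20000,
    "n_reps": 10000,
    "n_mantel_perm": 9999,
    "n_neutrality_sims": 20000,
}


@dataclass
class AccuracyTable:
    """Genetic identity breakdown of observer-identified individuals."""

    focal: str
    rows: pd.DataFrame  # columns: genetic_label, count, percentage
    n_total: int

    def to_frame(self) -> pd.DataFrame:
        return self.rows


def accuracy_table(pairs, focal: str) -> AccuracyTable:
    """Cross-tabulate genetic identifications among observer-called ``focal``.

    ``pairs`` is an iterable of (observer_label, genetic_label). Percentages
    are reported to one decimal. The focal species itself sorts first, then
    decreasing count.
    """
    subset = [g for o, g in pairs if o == focal]
    if not subset:
        raise DataError(f"no pairs with observer label {focal!r}")
    counts = pd.Series(subset).value_counts()
    counts = counts.reindex(
        sorted(counts.index, key=lambda g: (g != focal, -counts[g], g))
    )
    n = int(counts.sum())
    rows = pd.DataFrame(
        {
            "genetic_label": counts.index,
            "count": counts.to_numpy(),
            "percentage": np.round(100.0 * counts.to_numpy() / n, 1),
        }
    )
    return AccuracyTable(focal, rows.reset_index(drop=True), n)


@dataclass
class RunConfig:
    """Full-pipeline settings (mirrors the documented YAML schema)."""

    fasta: str | None = None
    popmap: str | None = None
    out_dir: str = "hapstruct_out"
    metric: str = "tn93"  # distance model behind Phi_ST and pi
    missing_policy: str = "strict"
    n_perm: int = 20000
    n_boot: int = 20000
    n_neutrality_sims: int = 20000
    n_mantel_perm: int = 9999
    alpha_pairwise: float = 0.05
    alpha_d: float = 0.05
    alpha_fs: float = 0.02
    seed: int = 1
    geo_matrix: str | None = None  # TSV of pairwise km distances (optional)
    resample: ResampleConfig | None = None
    skip_neutrality: bool = False
    skip_mismatch: bool = False
    skip_network: bool = False
    skip_resample: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        resample = raw.pop("resample", None)
        cfg = cls(**raw)
        if resample:
            cfg.resample = ResampleConfig(**resample)
            cfg.skip_resample = False
        return cfg


def _warn_scaled_down(cfg: RunConfig) -> list[str]:
    notes = []
    for attr, key in (
        ("n_perm", "n_perm"),
        ("n_boot", "n_boot"),
        ("n_neutrality_sims", "n_neutrality_sims"),
        ("n_mantel_perm", "n_mantel_perm"),
    ):
        if getattr(cfg, attr) < REFERENCE_DEFAULTS[key]:
            notes.append(
                f"{attr}={getattr(cfg, attr)} below reference setting "
                f"{REFERENCE_DEFAULTS[key]}; Monte-Carlo error is correspondingly larger"
            )
    for n in notes:
        log.warning(n)
    return notes


def run_pipeline(
    cfg: RunConfig,
    aln: Alignment | None = None,
    cat: HaplotypeCatalog | None = None,
    ct: CountTable | None = None,
) -> dict:
    """Execute the analysis chain and write all outputs under cfg.out_dir.

    Inputs may be given as files (cfg.fasta + cfg.popmap) or as in-memory
    objects: either an Alignment, or a pre-collapsed catalog + count table.
    Returns the manifest dict (also written as manifest.json). Identical
    configs and seeds produce byte-identical outputs.
    """
    t0 = time.time()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": {"name": "hapstruct", "version": __version__},
        "config": {
            k: (v if not isinstance(v, ResampleConfig) else v.__dict__)
            for k, v in cfg.__dict__.items()
        },
        "stages": {},
        "warnings": _warn_scaled_down(cfg),
    }
    seeds = np.random.SeedSequence(cfg.seed).spawn(8)

    def stage(name):
        log.info("stage %s", name)
        manifest["stages"][name] = {"status": "done"}
        return manifest["stages"][name]

    try:
        if cat is None or ct is None:
            if aln is None:
                if not cfg.fasta or not cfg.popmap:
                    raise DataError("no input: give fasta+popmap or in-memory objects")
                from .dataio import read_alignment

                aln = read_alignment(cfg.fasta, cfg.popmap)
            cat, ct = collapse_haplotypes(aln, cfg.missing_policy)
        info = stage("haplotypes")
        write_haplotype_fasta(cat, out / "haplotypes.fasta")
        write_count_table(ct, out / "haplotype_counts.tsv")
        sites = polymorphic_site_table(cat)
        sites.to_csv(out / "polymorphic_sites.tsv", sep="\t", index=False)
        info.update(n_haplotypes=len(cat.ids), n_sites=int(len(sites)))

        stage("distances")
        dist = distance_matrix_for(cfg.metric, cat, ct)
        dist.write(out / f"distance_{cfg.metric}.tsv")

        stage("diversity")
        div_metric = "tn93" if cfg.metric == "tn93" else "raw"
        div = diversity_table(cat, ct, metric=div_metric)
        div.to_csv(out / "diversity.tsv", sep="\t", index=False)

        if not cfg.skip_neutrality:
            info = stage("neutrality")
            rows = []
            pops = list(ct.populations) + [None]
            for pop, s in zip(pops, seeds[0].spawn(len(pops))):
                counts = ct.pooled() if pop is None else ct.pop_counts(pop)
                res = neutrality_pvalues(
                    cat, counts, n_sims=cfg.n_neutrality_sims, seed=s
                )
                rows.append(
                    {
                        "population": pop or "Pooled",
                        "D": res.D, "p_D": res.p_D,
                        "Fs": res.Fs, "p_Fs": res.p_Fs,
                        "n_sims": res.n_sims,
                    }
                )
            pd.DataFrame(rows).to_csv(out / "neutrality.tsv", sep="\t", index=False)
        else:
            manifest["stages"]["neutrality"] = {"status": "skipped"}

        if not cfg.skip_mismatch:
            stage("mismatch")
            rows = []
            for pop, s in zip(
                list(ct.populations) + [None], seeds[1].spawn(len(ct.populations) + 1)
            ):
                md = mismatch_distribution(cat, ct, pop)
                fit = fit_sudden_expansion(md)
                rag = raggedness_pvalue(
                    md, fit, int((ct.pooled() if pop is None else ct.pop_counts(pop)).sum()),
                    n_boot=cfg.n_boot, seed=s,
                )
                rows.append(
                    {
                        "population": pop or "Pooled",
                        "tau": fit.tau, "theta0": fit.theta0, "theta1": fit.theta1,
                        "sse": fit.sse, "H_RI": rag.H_RI, "p_HRI": rag.p,
                        "consistent_with_expansion": rag.consistent_with_expansion,
                    }
                )
            pd.DataFrame(rows).to_csv(out / "mismatch.tsv", sep="\t", index=False)
        else:
            manifest["stages"]["mismatch"] = {"status": "skipped"}

        info = stage("amova")
        res = amova(ct, dist, n_perm=cfg.n_perm, seed=seeds[2], metric=cfg.metric)
        res.to_frame().to_csv(out / "amova.tsv", sep="\t", index=False)
        info.update(fixation_index=res.fixation_index, p=res.p)

        stage("pairwise")
        pw = pairwise_structure(
            ct, dist, n_perm=cfg.n_perm, seed=seeds[3],
            alpha=cfg.alpha_pairwise, metric=cfg.metric,
        )
        pw.to_frame().to_csv(out / "pairwise.tsv", sep="\t", index=False)

        stage("rarefaction")
        frames = []
        for pop in ct.populations:
            curve = rarefaction_curve(ct.pop_counts(pop)).to_frame()
            curve.insert(0, "population", pop)
            frames.append(curve)
        pd.concat(frames).to_csv(out / "rarefaction.tsv", sep="\t", index=False)

        if cfg.geo_matrix:
            info = stage("mantel")
            geo = DistanceMatrix.read(cfg.geo_matrix)
            gen = pw.stat_matrix()
            geo = DistanceMatrix(gen.ids, geo.to_frame().loc[gen.ids, gen.ids].to_numpy())
            mr = mantel_test(gen, geo, n_perm=cfg.n_mantel_perm, seed=int(seeds[4].generate_state(1)[0] % 2**31))
            info.update(r=mr.r, r2=mr.r2, p=mr.p)
            (out / "mantel.json").write_text(
                json.dumps({"r": mr.r, "r2": mr.r2, "p": mr.p, "n_perm": mr.n_perm})
            )
        else:
            manifest["stages"]["mantel"] = {"status": "skipped"}

        if not cfg.skip_resample and cfg.resample is not None:
            stage("resample")
            rcfg = cfg.resample
            if rcfg.seed is None:
                rcfg.seed = int(seeds[5].generate_state(1)[0] % 2**31)
            rep = subsample_robustness(ct, dist, rcfg)
            rep.to_frame().to_csv(out / "resample.tsv", sep="\t", index=False)
        else:
            manifest["stages"]["resample"] = {"status": "skipped"}

        if not cfg.skip_network:
            stage("network")
            steps = step_matrix(cat).d
            limit = parsimony_limit(cat.L, steps[np.triu_indices(len(cat.ids), 1)])
            net = build_network(cat, ct, limit)
            write_edge_list(net, out / "network_edges.tsv")
            write_node_table(net, out / "network_nodes.tsv")
            net.write_graphml(out / "network.graphml")
            manifest["stages"]["network"].update(
                limit=limit.j_max, components=net.components
            )
        else:
            manifest["stages"]["network"] = {"status": "skipped"}
    except Exception as err:
        failed = [k for k, v in manifest["stages"].items() if v.get("status") == "done"]
        current = failed[-1] if failed else "input"
        raise RuntimeError(f"pipeline stage {current!r} failed: {err}") from err

    manifest["elapsed_s"] = round(time.time() - t0, 3)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
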