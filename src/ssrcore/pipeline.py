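"""One-command orchestration of the full analysis flow.

``run_pipeline`` executes, in order: input loading (or simulation),
per-locus and per-population diversity tables, AMOVA with permutations and
per-locus Fst/Nm, admixture runs over a K grid with Evanno delta-K, the
neighbor-joining tree and PCoA on the shared-allele distance, the
phenotypic core grid (distances x linkages x samplings x ratios), the two
molecular cores, evaluations and the combined final core.  Every output is
a delimited table (or newick), reproducible byte-for-byte from the inputs
and the master seed; a JSON manifest records all parameters.

Stage seeds are derived deterministically from the master seed and a stage
tag so any stage can be re-run in isolation.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .amova import amova, fst_and_nm, genotype_distance_matrix
from .core import (
    combine_cores,
    compare_core_original,
    diversity_core_search,
    evaluate_phenotype_core,
    m_strategy_core,
    phenotype_core,
)
from .diversity import locus_stats, population_stats
from .io import (
    read_genotypes,
    read_phenotypes,
    write_genotypes,
    write_phenotypes,
)
from .simulate import SimulationConfig, simulate_dataset
from .structure import (
    evanno_delta_k,
    neighbor_joining,
    pcoa,
    replicate_admixture_runs,
    shared_allele_distance,
)

log = logging.getLogger("ssrcore")

DEFAULT_RATIOS = (0.10, 0.15, 0.20, 0.25, 0.30, 0.35, 0.40)


@dataclass
class RunConfig:
    """Pipeline settings; either input paths or a simulation config is required."""

    out_dir: str = "ssrcore_out"
    seed: int = 0
    genotype_path: str | None = None
    genotype_dialect: str = "two-column-csv"
    phenotype_path: str | None = None
    simulate: SimulationConfig | None = None
    k_min: int = 1
    k_max: int = 5
    k_replicates: int = 3
    amova_permutations: int = 999
    core_distances: tuple[str, ...] = ("euclidean", "mahalanobis")
    core_linkages: tuple[str, ...] = ("upgma", "ward", "median")
    core_samplings: tuple[str, ...] = ("random", "deviation", "preferred")
    core_ratios: tuple[float, ...] = DEFAULT_RATIOS
    molecular_ratio: float = 0.55
    search_iterations: int = 10_000
    alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulate", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulate = SimulationConfig(**sim)
        return cfg


def stage_seed(master: int, tag: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (int(master) * 2654435761 + zlib.crc32(tag.encode())) % (2**31 - 1)


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", float_format="%.6g")


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages; returns a manifest dict (also written to the bundle)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": cfg.seed, "stages": []}

    def stage(name: str):
        log.info("stage: %s", name)
        manifest["stages"].append(name)

    # ---- inputs ----------------------------------------------------------
    stage("load")
    if cfg.simulate is not None:
        sim = SimulationConfig(**{**asdict(cfg.simulate), "seed": stage_seed(cfg.seed, "simulate")})
        gm, pm, pt = simulate_dataset(sim)
        manifest["simulation"] = asdict(sim)
        write_genotypes(gm, out / "genotypes.csv", pm)
        write_phenotypes(pt, out / "phenotypes.csv")
    else:
        if cfg.genotype_path is None:
            raise ValueError("either genotype_path or a simulation config is required")
        gm, pm = read_genotypes(cfg.genotype_path, cfg.genotype_dialect)
        if pm is None:
            raise ValueError("genotype file carries no population labels")
        pt = read_phenotypes(cfg.phenotype_path) if cfg.phenotype_path else None
    manifest["n_entries"] = gm.n_entries
    manifest["n_loci"] = gm.n_loci
    manifest["missing_rate"] = gm.missing_rate()

    # ---- diversity -------------------------------------------------------
    stage("diversity")
    loci = locus_stats(gm)
    loci.loc["Mean"] = loci.mean(axis=0)
    _write(loci, out / "diversity_loci.tsv")
    _write(population_stats(gm, pm), out / "diversity_populations.tsv")

    # ---- differentiation -------------------------------------------------
    stage("amova")
    dm = genotype_distance_matrix(gm)
    res = amova(dm, pm, n_perm=cfg.amova_permutations, seed=stage_seed(cfg.seed, "amova"))
    _write(res.to_frame(), out / "amova.tsv")
    _write(fst_and_nm(gm, pm), out / "fst_nm.tsv")
    manifest["amova"] = {"phi_pt": res.phi_pt, "p": res.p_value,
                         "pct_among": res.pct_among, "pct_within": res.pct_within}

    # ---- structure -------------------------------------------------------
    stage("structure")
    runs = replicate_admixture_runs(
        gm, range(cfg.k_min, cfg.k_max + 1), cfg.k_replicates,
        seed=stage_seed(cfg.seed, "structure"),
    )
    _write(runs.set_index("K"), out / "admixture_runs.tsv")
    if cfg.k_max - cfg.k_min >= 2 and cfg.k_replicates >= 2:
        dk = evanno_delta_k(runs)
        _write(dk.table, out / "delta_k.tsv")
        manifest["best_k"] = dk.best_k
        from .structure import admixture_em

        best = admixture_em(gm, dk.best_k, seed=stage_seed(cfg.seed, "best-k"))
        _write(best.q_frame(), out / f"qmatrix_K{dk.best_k}.tsv")

    stage("tree+pcoa")
    ids, sad = shared_allele_distance(gm)
    (out / "nj_tree.nwk").write_text(neighbor_joining(sad, ids) + "\n")
    ord_res = pcoa(sad, ids, n_axes=3)
    coords = ord_res.frame()
    coords["population"] = pm.labels_for(ids)
    _write(coords, out / "pcoa.tsv")
    manifest["pcoa_pct_variance"] = [float(x) for x in ord_res.pct_variance]

    # ---- cores -----------------------------------------------------------
    results = []
    best_pheno = None
    if pt is not None:
        stage("core-phenotype")
        for dist in cfg.core_distances:
            for link in cfg.core_linkages:
                for samp in cfg.core_samplings:
                    for ratio in cfg.core_ratios:
                        cs = phenotype_core(
                            pt, dist, link, samp, ratio,
                            seed=stage_seed(cfg.seed, f"pheno-{dist}-{link}-{samp}-{ratio}"),
                        )
                        ev = evaluate_phenotype_core(pt, cs, alpha=cfg.alpha)
                        results.append(
                            {"method": cs.method, "distance": dist, "linkage": link,
                             "sampling": samp, "ratio": ratio, "size": cs.size,
                             "MD": ev.MD, "VD": ev.VD, "CR": ev.CR, "VR": ev.VR,
                             "passes": ev.passes}
                        )
        grid = pd.DataFrame(results).set_index("method")
        _write(grid, out / "core_phenotype_grid.tsv")
        ok = grid[grid["passes"]]
        pick_from = ok if len(ok) else grid
        best_row = pick_from.sort_values(["VD", "CR"], ascending=False).iloc[0]
        best_pheno = phenotype_core(
            pt, best_row["distance"], best_row["linkage"], best_row["sampling"],
            float(best_row["ratio"]),
            seed=stage_seed(cfg.seed, f"pheno-{best_row['distance']}-{best_row['linkage']}-"
                                      f"{best_row['sampling']}-{best_row['ratio']}"),
        )
        (out / "core_phenotype_best.txt").write_text("\n".join(best_pheno.entry_ids) + "\n")
        manifest["best_phenotype_core"] = {"method": best_pheno.method, "size": best_pheno.size}

    stage("core-molecular")
    mc1 = m_strategy_core(gm)
    (out / "core_m_strategy.txt").write_text("\n".join(mc1.entry_ids) + "\n")
    mc2 = diversity_core_search(
        gm, cfg.molecular_ratio, seed=stage_seed(cfg.seed, "core-search"),
        n_iter=cfg.search_iterations,
    )
    (out / "core_search.txt").write_text("\n".join(mc2.entry_ids) + "\n")
    ev1 = compare_core_original(gm, mc1)
    ev2 = compare_core_original(gm, mc2)
    _write(ev1.table, out / "core_m_strategy_eval.tsv")
    _write(ev2.table, out / "core_search_eval.tsv")
    manifest["m_strategy_core"] = {"size": mc1.size, "sample_retention": ev1.sample_retention}
    manifest["search_core"] = {"size": mc2.size, "sample_retention": ev2.sample_retention}

    stage("combine")
    final = combine_cores(best_pheno, mc1) if best_pheno is not None else mc1
    (out / "core_final.txt").write_text("\n".join(final.entry_ids) + "\n")
    manifest["final_core"] = {"method": final.method, "size": final.size}

    cfg_dict = asdict(cfg)
    cfg_dict.pop("out_dir")  # keep the manifest independent of where it lives
    if cfg_dict.get("simulate") is not None:
        cfg_dict["simulate"] = asdict(cfg.simulate)
    manifest["config"] = cfg_dict
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
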