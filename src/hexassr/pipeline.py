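"""End-to-end orchestration: panels, accumulation, distances, trees, reports.

Runs the full workflow on either a genotype file pair or a simulated
panel: per-class locus statistics, genotype-accumulation resampling,
per-class Bruvo distance matrices, UPGMA trees, Mantel comparisons of the
raw and cophenetic matrices, and the marker-class comparison report.  All
randomness flows from one master seed through named substreams; the run
manifest records the configuration so any output can be regenerated.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from hexassr import __version__
from hexassr.accumulation import accumulation_curve, accumulation_to_frame
from hexassr.bruvo import BruvoModel, bruvo_matrix
from hexassr.compare import ComparisonReport, cv, ks_normality, two_sample_t
from hexassr.genotypes import (
    GenotypeMatrix,
    MarkerClass,
    read_genotypes,
    write_genotypes,
    write_locus_definitions,
)
from hexassr.locus_stats import locus_panel, panel_to_frame
from hexassr.simulate import SimulationConfig, simulate
from hexassr.trees import compare_trees, mantel, upgma

logger = logging.getLogger("hexassr")

__all__ = ["PipelineConfig", "run_all"]

_STAGE_NAMES = ("simulate", "accumulation", "mantel")


@dataclass
class PipelineConfig:
    """Inputs, analysis parameters and output location for one run."""

    output_dir: str | Path
    genotypes: str | Path | None = None  # genotype CSV; None -> simulate
    loci_meta: str | Path | None = None
    simulation: SimulationConfig | None = None
    k_rarefaction: int | None = None  # None -> smallest per-class copy count
    bruvo_model: BruvoModel = BruvoModel.COMBINATIONAL
    n_accumulation_resamples: int = 10000
    n_mantel_permutations: int = 9999
    collapse_clones: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genotypes is not None and self.loci_meta is None:
            raise ValueError("loci_meta required when genotypes is given")


def _substream_seeds(master: int) -> dict[str, int]:
    children = np.random.SeedSequence(master).spawn(len(_STAGE_NAMES))
    return {
        name: int(child.generate_state(1)[0] % 2**31)
        for name, child in zip(_STAGE_NAMES, children)
    }


def _stage(name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc_type is None:
                logger.info("stage %s: done in %.2fs", name, dt)
            else:
                logger.error("stage %s: FAILED after %.2fs: %s", name, dt, exc)
            return False

    return _Timer()


def _variety_representatives(gm: GenotypeMatrix, clone_map: dict[str, str]) -> GenotypeMatrix:
    """One sample per variety (the first listed), mirroring a design where
    duplicate plants confirm the variety genotype."""
    seen: dict[str, str] = {}
    for sid in gm.sample_ids:
        seen.setdefault(clone_map.get(sid, sid), sid)
    reps = gm.subset_samples(list(seen.values()))
    reps.sample_ids = list(seen.keys())
    return reps


_PANEL_COLUMNS = ["An", "1-D", "Ev", "AR", "GD", "Ho", "GH", "Hs", "En", "R"]


def run_all(cfg: PipelineConfig) -> dict:
    """Execute the full workflow; returns artifact paths and key results."""
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _substream_seeds(cfg.seed)
    artifacts: dict[str, str] = {}
    results: dict = {}

    def emit(name: str, path: Path) -> None:
        artifacts[name] = str(path)

    # --- input ------------------------------------------------------------
    clone_map: dict[str, str] = {}
    with _stage("input"):
        if cfg.genotypes is not None:
            gm = read_genotypes(cfg.genotypes, cfg.loci_meta)
        else:
            sim_cfg = cfg.simulation or SimulationConfig()
            sim_cfg = SimulationConfig(**{**vars(sim_cfg), "seed": seeds["simulate"]})
            gm, truth = simulate(sim_cfg)
            clone_map = truth.clone_map
            write_genotypes(gm, outdir / "genotypes.csv")
            write_locus_definitions(gm.loci, outdir / "loci.csv")
            truth.to_json(outdir / "truth.json")
            emit("genotypes", outdir / "genotypes.csv")
            emit("loci", outdir / "loci.csv")
            emit("truth", outdir / "truth.json")

    classes = {"EST": MarkerClass.EST, "genomic": MarkerClass.GENOMIC}
    class_loci = {name: gm.loci_of_class(mc) for name, mc in classes.items()}
    classes = {name: mc for name, mc in classes.items() if class_loci[name]}

    # --- locus panels -----------------------------------------------------
    panels: dict[str, pd.DataFrame] = {}
    with _stage("locus_panels"):
        for name, mc in classes.items():
            panel = locus_panel(gm, mc, k=cfg.k_rarefaction)
            frame = panel_to_frame(panel)
            path = outdir / f"panel_{name}.csv"
            frame.round(4).to_csv(path, index=False)
            panels[name] = frame
            emit(f"panel_{name}", path)

    # --- genotype accumulation --------------------------------------------
    with _stage("accumulation"):
        for i, (name, mc) in enumerate(classes.items()):
            sub = gm.subset_loci(class_loci[name])
            if len(sub.loci) < 2:
                continue
            curve = accumulation_curve(
                sub, n_resamples=cfg.n_accumulation_resamples, seed=seeds["accumulation"] + i
            )
            path = outdir / f"accumulation_{name}.csv"
            accumulation_to_frame(curve).to_csv(path, index=False)
            emit(f"accumulation_{name}", path)

    # --- Bruvo distances (per class, never pooled) -------------------------
    with _stage("bruvo"):
        dist_gm = _variety_representatives(gm, clone_map) if (cfg.collapse_clones and clone_map) else gm
        matrices = {}
        long_rows = []
        for name in classes:
            dm = bruvo_matrix(dist_gm, model=cfg.bruvo_model, loci=class_loci[name])
            matrices[name] = dm
            path = outdir / f"bruvo_{name}.csv"
            dm.to_csv(path)
            emit(f"bruvo_{name}", path)
            iu0, iu1 = np.triu_indices(dm.n, k=1)
            for a, b in zip(iu0, iu1):
                long_rows.append((name, dm.labels[a], dm.labels[b], dm.values[a, b]))
            results[f"mean_bruvo_{name}"] = float(dm.condensed().mean())
        long_path = outdir / "distances_long.csv"
        pd.DataFrame(long_rows, columns=["marker_class", "sample_1", "sample_2", "distance"]).to_csv(
            long_path, index=False
        )
        emit("distances_long", long_path)

    # --- trees ------------------------------------------------------------
    trees = {}
    with _stage("trees"):
        for name, dm in matrices.items():
            tree = upgma(dm)
            trees[name] = tree
            path = outdir / f"tree_{name}.nwk"
            tree.write_newick(path)
            emit(f"tree_{name}", path)

    # --- Mantel comparisons ------------------------------------------------
    with _stage("mantel"):
        mantel_rows = []
        if len(matrices) == 2:
            (n1, d1), (n2, d2) = matrices.items()
            res = mantel(d1, d2, n_permutations=cfg.n_mantel_permutations, seed=seeds["mantel"])
            mantel_rows.append(("distance", n1, n2, res.r, res.p, res.n_permutations))
            results["mantel_distance_r"] = res.r
            results["mantel_distance_p"] = res.p
            comp = compare_trees(
                trees[n1], trees[n2], n_permutations=cfg.n_mantel_permutations, seed=seeds["mantel"] + 1
            )
            mantel_rows.append(
                ("cophenetic", n1, n2, comp.mantel.r, comp.mantel.p, comp.mantel.n_permutations)
            )
            results["mantel_cophenetic_r"] = comp.mantel.r
            results["mantel_cophenetic_p"] = comp.mantel.p
            orders = pd.DataFrame(
                {f"leaf_order_{n1}": comp.leaf_order_1, f"leaf_order_{n2}": comp.leaf_order_2}
            )
            orders_path = outdir / "leaf_orders.tsv"
            orders.to_csv(orders_path, sep="\t", index=False)
            emit("leaf_orders", orders_path)
        mantel_path = outdir / "mantel_report.tsv"
        pd.DataFrame(
            mantel_rows, columns=["matrices", "class_1", "class_2", "r", "p", "n_permutations"]
        ).to_csv(mantel_path, sep="\t", index=False)
        emit("mantel_report", mantel_path)

    # --- class comparison ---------------------------------------------------
    with _stage("class_comparison"):
        comp_rows = []
        if len(panels) == 2:
            (n1, p1), (n2, p2) = panels.items()
            per_locus_1 = p1[p1["locus"] != "Mean"]
            per_locus_2 = p2[p2["locus"] != "Mean"]
            for col in _PANEL_COLUMNS:
                x = per_locus_1[col].astype(float).tolist()
                y = per_locus_2[col].astype(float).tolist()
                rep = two_sample_t(x, y, statistic_name=col)
                comp_rows.append(_report_row(rep, n1, n2))
            if len(matrices) == 2:
                dx = matrices[n1].condensed()
                dy = matrices[n2].condensed()
                rep = two_sample_t(dx, dy, statistic_name="bruvo_distance")
                comp_rows.append(_report_row(rep, n1, n2))
                for name, d in ((n1, dx), (n2, dy)):
                    ks_d, ks_p = ks_normality(d)
                    results[f"ks_normality_{name}_D"] = ks_d
                    results[f"ks_normality_{name}_p"] = ks_p
        comp_path = outdir / "class_comparison.tsv"
        pd.DataFrame(
            comp_rows,
            columns=[
                "statistic", "class_1", "class_2", "mean_1", "mean_2",
                "cv_1", "cv_2", "test", "t", "df", "p",
            ],
        ).to_csv(comp_path, sep="\t", index=False)
        emit("class_comparison", comp_path)

    # --- manifest -----------------------------------------------------------
    manifest = {
        "hexassr_version": __version__,
        "master_seed": cfg.seed,
        "substream_seeds": seeds,
        "bruvo_model": BruvoModel(cfg.bruvo_model).value,
        "k_rarefaction": cfg.k_rarefaction,
        "n_accumulation_resamples": cfg.n_accumulation_resamples,
        "n_mantel_permutations": cfg.n_mantel_permutations,
        "collapse_clones": cfg.collapse_clones,
        "n_samples": gm.n_samples,
        "loci": gm.locus_names,
        "artifacts": artifacts,
        "results": results,
    }
    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    emit("manifest", manifest_path)
    return {"artifacts": artifacts, "results": results, "genotypes": gm}


def _report_row(rep: ComparisonReport, n1: str, n2: str) -> tuple:
    return (
        rep.statistic_name, n1, n2, rep.mean_x, rep.mean_y,
        rep.cv_x, rep.cv_y, rep.test_name, rep.test_statistic, rep.df, rep.p,
    )
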