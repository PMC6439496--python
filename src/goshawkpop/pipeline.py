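"""End-to-end orchestration: simulate/ingest -> filter -> structure ->
differentiation -> AIM panel -> ancestry -> mtDNA, from one declarative
config, with a JSON run manifest.

A single global seed is expanded into per-stage seeds as
``(seed * 1000 + stage_index) % 2**31`` so each stage is individually
reproducible; rerunning with the same config and seed is bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from . import ancestry as anc
from . import differentiation as diff
from . import f3 as f3mod
from . import filtering, haplotypes, io, panel as panelmod, structure
from .simulate import SimulationConfig, simulate_study

log = logging.getLogger("goshawkpop")

_KNOWN_KEYS = {
    "seed", "out_dir", "simulation", "inputs", "filters", "analyses",
    "admixture", "dapc", "panel", "ancestry", "island_region",
}

_STAGES = ["data", "filter", "structure", "differentiation", "panel",
           "ancestry", "mtdna"]


class PipelineConfig:
    """Validated pipeline configuration (unknown keys rejected)."""

    def __init__(self, raw: dict) -> None:
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        self.seed = int(raw.get("seed", 0))
        self.out_dir = raw.get("out_dir", "goshawkpop_run")
        self.simulation = raw.get("simulation", {})
        self.inputs = raw.get("inputs")
        self.filters = raw.get("filters", {})
        self.analyses = {
            "pca": True, "admixture": True, "dapc": True, "fst": True,
            "f3": False, "panel": True, "ancestry": True, "mtdna": True,
        }
        self.analyses.update(raw.get("analyses", {}))
        self.admixture = {"K_range": [1, 2, 3], "folds": 3, "replicates": 2}
        self.admixture.update(raw.get("admixture", {}))
        self.dapc = {"max_axes": 5, "replicates": 5}
        self.dapc.update(raw.get("dapc", {}))
        self.panel = {"panel_size": 11, "flank_bp": 30}
        self.panel.update(raw.get("panel", {}))
        self.ancestry = {"min_loci": 7, "grid_step": 0.005}
        self.ancestry.update(raw.get("ancestry", {}))
        self.island_region = raw.get("island_region", "HG")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(yaml.safe_load(fh) or {})

    def stage_seed(self, stage: str) -> int:
        return (self.seed * 1000 + _STAGES.index(stage)) % (2**31)


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> Path:
    """Execute the enabled stages in order; returns the run directory.

    Every output TSV/VCF/newick lands in the run directory together with
    ``manifest.json`` recording the parameters that produced it.
    """
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "outputs": []}

    def emit(name: str) -> Path:
        manifest["outputs"].append(name)
        return out / name

    def fail(stage: str, exc: Exception) -> None:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    # ---- data ----
    try:
        if config.inputs:
            g = io.read_vcf(config.inputs["vcf"])
            meta = io.read_metadata(config.inputs["meta"])
            mt = (
                io.read_fasta_alignment(config.inputs["fasta"])
                if config.inputs.get("fasta")
                else None
            )
            if mt is not None and not mt.regions:
                mt.regions = dict(zip(meta["sample_id"], meta["region"]))
            manifest["stages"]["data"] = {"mode": "ingest", **config.inputs}
        else:
            sim_cfg = SimulationConfig(
                **{**config.simulation, "seed": config.stage_seed("data")}
            )
            study = simulate_study(sim_cfg)
            g, meta, mt = study.genotypes, study.metadata, study.mtdna
            io.write_vcf(g, emit("simulated.vcf"))
            io.write_metadata(meta, emit("samples.tsv"))
            io.write_fasta_alignment(mt, emit("mtdna.fasta"))
            manifest["stages"]["data"] = {
                "mode": "simulate",
                "config": {
                    k: v for k, v in dataclasses.asdict(sim_cfg).items()
                    if not isinstance(v, dict) or len(v) < 20
                },
            }
    except RuntimeError:
        raise
    except Exception as exc:
        fail("data", exc)

    # ---- filter ----
    try:
        g_f, reports = filtering.filter_chain(g, **config.filters)
        with open(emit("filter_report.tsv"), "w") as fh:
            fh.write("step\tsites_in\tsites_out\tsamples_in\tsamples_out\tdropped\n")
            for r in reports:
                fh.write(
                    f"{r.step}\t{r.sites_in}\t{r.sites_out}\t{r.samples_in}"
                    f"\t{r.samples_out}\t{','.join(r.dropped_ids)}\n"
                )
        io.write_vcf(g_f, emit("filtered.vcf"))
        manifest["stages"]["filter"] = {
            "params": config.filters,
            "sites_out": g_f.n_sites, "samples_out": g_f.n_samples,
        }
        meta = meta[meta["sample_id"].isin(g_f.sample_ids)].reset_index(drop=True)
    except RuntimeError:
        raise
    except Exception as exc:
        fail("filter", exc)

    regions = io.region_indices(g_f, meta)
    island = config.island_region
    labels = np.array(
        ["island" if r == island else "continent" for r in
         meta.set_index("sample_id").loc[g_f.sample_ids, "region"]]
    )

    # ---- structure ----
    if config.analyses["pca"]:
        pca = structure.run_pca(g_f)
        frame = pca.scores
        import pandas as pd

        pd.DataFrame(
            frame, index=pca.sample_ids,
            columns=[f"PC{i+1}" for i in range(frame.shape[1])],
        ).to_csv(emit("pca_scores.tsv"), sep="\t")
        manifest["stages"]["structure"] = {
            "pc_variance": [float(v) for v in pca.variance_explained[:5]]
        }
    if config.analyses["admixture"]:
        seed = config.stage_seed("structure")
        table, best_K = structure.admixture_cv(
            g_f, config.admixture["K_range"],
            folds=config.admixture["folds"],
            replicates=config.admixture["replicates"], seed=seed,
        )
        table.to_csv(emit("admixture_cv.tsv"), sep="\t", index=False)
        fit = structure.AdmixtureModel(g_f, best_K).fit(seed=seed)
        fit.q_frame().to_csv(emit("admixture_Q.tsv"), sep="\t")
        manifest["stages"].setdefault("structure", {})["best_K"] = best_K
    if config.analyses["dapc"] and len(set(labels)) >= 2:
        acc, grid = structure.dapc_assignment_cv(
            g_f, labels, max_axes=config.dapc["max_axes"],
            replicates=config.dapc["replicates"],
            seed=config.stage_seed("structure"),
        )
        grid.to_csv(emit("dapc_grid.tsv"), sep="\t", index=False)
        manifest["stages"].setdefault("structure", {})["dapc_accuracy"] = acc

    # ---- differentiation + panel + ancestry ----
    fst_table = None
    if config.analyses["fst"] and island in regions:
        other = np.concatenate([v for k, v in regions.items() if k != island])
        fst_table, weighted = diff.wc_fst(g_f, regions[island], other)
        fst_table.to_csv(emit("fst_sites.tsv"), sep="\t", index=False)
        thr = diff.fst_outlier_threshold(fst_table["ratio"].to_numpy())
        manifest["stages"]["differentiation"] = {
            "weighted_fst_island_vs_rest": weighted,
            "fst_outlier_threshold_q99": thr,
        }
    if config.analyses["f3"] and len(regions) >= 3:
        results = f3mod.f3_all(g_f, regions)
        with open(emit("f3.tsv"), "w") as fh:
            fh.write("X\tY\tZ\tf3\tse\tz\tn_blocks\n")
            for r in results:
                fh.write(f"{r.X}\t{r.Y}\t{r.Z}\t{r.f3}\t{r.se}\t{r.z}\t{r.n_blocks}\n")
        manifest["stages"]["f3"] = {"n_tests": len(results)}
    if config.analyses["panel"] and fst_table is not None:
        ranked = panelmod.rank_candidates(fst_table, g_f)
        aim = panelmod.apply_design_filters(
            ranked, g_f, flank_bp=config.panel["flank_bp"],
            panel_size=config.panel["panel_size"],
        )
        other = np.concatenate([v for k, v in regions.items() if k != island])
        aim = panelmod.panel_frequencies(aim, g_f, regions[island], other)
        aim.to_tsv(emit("aim_panel.tsv"))
        manifest["stages"]["panel"] = {"panel_size": len(aim)}
        if config.analyses["ancestry"]:
            res = anc.AncestryModel(
                g_f, aim, min_loci=min(config.ancestry["min_loci"], len(aim))
            ).fit(grid_step=config.ancestry["grid_step"])
            res.to_frame().to_csv(emit("ancestry_SH.tsv"), sep="\t", index=False)
            manifest["stages"]["ancestry"] = {
                "n_estimated": len(res.estimates), "n_skipped": len(res.skipped),
            }
    elif config.analyses["ancestry"] and not config.analyses["panel"]:
        log.warning("ancestry stage disabled: it depends on the panel stage")

    # ---- mtDNA ----
    if config.analyses["mtdna"] and mt is not None:
        table = haplotypes.collapse_haplotypes(mt)
        table.to_frame().to_csv(emit("haplotypes.tsv"), sep="\t", index=False)
        if table.n_haplotypes >= 2:
            edges = haplotypes.mst_haplotype_network(table)
            with open(emit("haplotype_network.tsv"), "w") as fh:
                fh.write("hap_a\thap_b\tsteps\n")
                for a, b, w in edges:
                    fh.write(f"{a}\t{b}\t{w}\n")
        if mt.n_sequences >= 3:
            dm = haplotypes.p_distance_matrix(mt)
            newick = haplotypes.neighbor_joining(dm, mt.sample_ids)
            (out / "mtdna_nj.nwk").write_text(newick + "\n")
            manifest["outputs"].append("mtdna_nj.nwk")
        manifest["stages"]["mtdna"] = {"n_haplotypes": table.n_haplotypes}

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
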