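"""End-to-end pipeline orchestration.

A run executes, under one output directory: simulation (or ingestion of
expression TSVs), preprocessing of the compendium, ISA module discovery with
(M2) and without (M1) the case/control samples, dysregulation testing with
permutation validation, the module subset hierarchy, functional enrichment,
frequent-gene counting, interaction-network statistics, and the
second-cell-type replication test. Every stage is recorded in a manifest
with its parameters, seed and output-file hashes; a rerun with the same
configuration reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .. import (
    enrichment,
    isa_core,
    module_graph,
    module_stats,
    network_analysis,
    preprocess,
    synthetic_data,
)
from . import io as pio

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Stage parameters for a full synthetic-study run."""

    simulation: synthetic_data.SimulationConfig = field(
        default_factory=synthetic_data.SimulationConfig
    )
    min_present_wbs: int = 6
    min_present_compendium: int = 10
    gene_thresholds: tuple[float, ...] = tuple(np.arange(2.0, 4.01, 0.2).round(10))
    sample_thresholds: tuple[float, ...] = tuple(np.arange(1.0, 2.01, 0.2).round(10))
    n_seeds: int = 50
    seed_size: int = 10
    corr_limit: float = 0.9
    min_genes: int = 10
    fdr_level: float = 0.05
    n_perm: int = 200
    network_background_genes: int = 100
    edge_prob_within: float = 0.6
    edge_prob_between: float = 0.02
    n_random_categories: int = 20
    category_size_range: tuple[int, int] = (10, 60)
    replication_arrays: int = 6
    replication_effect: float = 0.8
    replication_noise: float = 0.5
    hrg_steps: int = 2000
    hrg_random: int = 50
    rng_seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = synthetic_data.SimulationConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in (raw.pop("simulation", {}) or {}).items()
        })
        kwargs = {
            k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()
        }
        return cls(simulation=sim, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return json.loads(json.dumps(d, default=list))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Manifest:
    def __init__(self, run_dir: Path, config: PipelineConfig):
        self.run_dir = run_dir
        self.stages: list[dict] = []
        self.config = config

    def record(self, stage: str, params: dict, outputs: list[Path]) -> None:
        self.stages.append(
            {
                "stage": stage,
                "params": params,
                "outputs": {p.name: _sha256(p) for p in outputs},
            }
        )
        log.info("stage %s done (%d outputs)", stage, len(outputs))

    def write(self) -> Path:
        path = self.run_dir / "manifest.json"
        path.write_text(
            json.dumps(
                {"config": self.config.to_dict(), "stages": self.stages}, indent=1
            )
        )
        return path


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Run every stage on a simulated study; returns the run directory."""
    config.simulation.validate()
    run_dir = Path(out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(run_dir, config)
    grid = [
        isa_core.IsaThresholds(float(g), float(s))
        for g in config.gene_thresholds
        for s in config.sample_thresholds
    ]

    try:
        # --- simulate ---------------------------------------------------
        t0 = time.time()
        compendium, wbs, truth = synthetic_data.generate_study(config.simulation)
        truth_path = run_dir / "truth.json"
        pio.write_truth(truth, truth_path)
        wbs_values = run_dir / "wbs_values.tsv"
        pio.write_expression_tsv(
            wbs, wbs_values, run_dir / "wbs_flags.tsv", run_dir / "wbs_meta.tsv"
        )
        manifest.record(
            "simulate",
            {"rng_seed": config.simulation.rng_seed},
            [truth_path, wbs_values],
        )

        # --- preprocess -------------------------------------------------
        filtered = [
            preprocess.filter_features(m, config.min_present_compendium)
            for m in compendium
        ]
        merged = preprocess.merge_datasets(filtered)
        corrected = preprocess.combat_correct(
            merged, covariates=merged.sample_meta["disease_status"]
        )
        comp_values = run_dir / "compendium_corrected.tsv"
        pio.write_expression_tsv(corrected, comp_values)
        wbs_filtered = preprocess.filter_features(wbs, config.min_present_wbs)
        manifest.record(
            "preprocess",
            {
                "min_present_compendium": config.min_present_compendium,
                "min_present_wbs": config.min_present_wbs,
                "features_kept": corrected.n_features,
            },
            [comp_values],
        )

        # --- ISA: M1 (compendium only) and M2 (with case/control samples)
        m1 = isa_core.run_isa(
            corrected,
            grid,
            n_seeds=config.n_seeds,
            seed_size=config.seed_size,
            rng_seed=config.rng_seed,
            corr_limit=config.corr_limit,
            run_label="M1",
            source_matrix_id="compendium",
        )
        merged_m2 = preprocess.merge_datasets(filtered + [wbs_filtered])
        corrected_m2 = preprocess.combat_correct(
            merged_m2, covariates=merged_m2.sample_meta["disease_status"]
        )
        m2 = isa_core.run_isa(
            corrected_m2,
            grid,
            n_seeds=config.n_seeds,
            seed_size=config.seed_size,
            rng_seed=config.rng_seed + 1,
            corr_limit=config.corr_limit,
            run_label="M2",
            source_matrix_id="compendium+wbs",
        )
        m1_path = run_dir / "modules_m1.json"
        m2_path = run_dir / "modules_m2.json"
        pio.write_modules(m1, m1_path)
        pio.write_modules(m2, m2_path)
        manifest.record(
            "isa",
            {
                "n_seeds": config.n_seeds,
                "grid_size": len(grid),
                "modules_m1": len(m1),
                "modules_m2": len(m2),
            },
            [m1_path, m2_path],
        )

        # --- dysregulation + permutation validation ---------------------
        dys_tables = {}
        dys_modules = {}
        for label, ms in (("m1", m1), ("m2", m2)):
            results = module_stats.dysregulation_test(
                ms, wbs_filtered, config.min_genes, config.fdr_level
            )
            table = pd.DataFrame([dataclasses.asdict(r) for r in results])
            path = run_dir / f"dysregulation_{label}.tsv"
            table.to_csv(path, sep="\t", index=False)
            dys_tables[label] = (table, path)
            significant = {r.module_id for r in results if r.significant}
            dys_modules[label] = [m for m in ms if m.id in significant]
        perm = module_stats.permutation_validation(
            m1,
            wbs_filtered,
            config.min_genes,
            config.fdr_level,
            n_perm=config.n_perm,
            rng_seed=config.rng_seed,
        )
        perm_path = run_dir / "permutation_summary.json"
        perm_path.write_text(json.dumps(dataclasses.asdict(perm), indent=1))
        manifest.record(
            "dysregulation",
            {
                "min_genes": config.min_genes,
                "fdr_level": config.fdr_level,
                "n_perm": config.n_perm,
                "significant_m1": len(dys_modules["m1"]),
                "significant_m2": len(dys_modules["m2"]),
            },
            [dys_tables["m1"][1], dys_tables["m2"][1], perm_path],
        )

        # --- hierarchy ---------------------------------------------------
        hierarchy_outputs = []
        for label in ("m1", "m2"):
            if not dys_modules[label]:
                continue
            dag = module_graph.build_hierarchy(dys_modules[label])
            edge_path = run_dir / f"hierarchy_{label}.tsv"
            dot_path = run_dir / f"hierarchy_{label}.dot"
            dag.to_edge_tsv(edge_path)
            dag.to_dot(dot_path)
            hierarchy_outputs += [edge_path, dot_path]
        manifest.record("hierarchy", {}, hierarchy_outputs)

        # --- enrichment --------------------------------------------------
        ann = synthetic_data.generate_annotation(
            truth,
            config.n_random_categories,
            config.category_size_range,
            config.rng_seed,
        )
        gmt_path = run_dir / "annotation.gmt"
        pio.write_gmt(ann, gmt_path)
        enrichment_outputs = [gmt_path]
        universe = corrected.feature_ids
        for label in ("m1", "m2"):
            if not dys_modules[label]:
                continue
            table = enrichment.enrich_modules(dys_modules[label], ann, universe)
            path = run_dir / f"enrichment_{label}.tsv"
            table.to_csv(path, sep="\t", index=False)
            enrichment_outputs.append(path)
        manifest.record(
            "enrichment", {"n_categories": len(ann)}, enrichment_outputs
        )

        # --- frequent genes + network ------------------------------------
        freq = module_stats.gene_frequency(dys_modules["m1"], dys_modules["m2"])
        freq_path = run_dir / "gene_frequency.tsv"
        freq.rename_axis("gene").to_csv(freq_path, sep="\t")
        net = synthetic_data.generate_network(
            truth,
            config.network_background_genes,
            config.edge_prob_within,
            config.edge_prob_between,
            config.rng_seed,
        )
        net_path = run_dir / "network.tsv"
        pio.write_network_tsv(net, net_path)
        network_outputs = [freq_path, net_path]
        frequent = [g for g in freq.index if freq.loc[g, "total"] >= 2]
        stats_payload: dict = {"n_frequent_genes": len(frequent)}
        sub = network_analysis.extract_subnetwork(net, frequent)
        if sub.n_vertices:
            observed = network_analysis.total_evidence(sub)
            p_ev, _ = network_analysis.random_subnetwork_null(
                net, sub.n_vertices, 1000, observed, config.rng_seed
            )
            stats_payload.update(
                {"total_evidence": observed, "evidence_empirical_p": p_ev}
            )
            if 0 < sub.n_vertices < net.n_vertices:
                p_deg, _ = network_analysis.degree_centrality_compare(sub, net, "degree")
                p_pr, _ = network_analysis.degree_centrality_compare(sub, net, "pagerank")
                stats_payload.update({"wilcoxon_degree_p": p_deg, "wilcoxon_pagerank_p": p_pr})
            comp = sub.largest_component()
            if comp.n_vertices >= 4:
                obs_ll, _, p_hier = network_analysis.hierarchy_significance(
                    comp,
                    n_random=config.hrg_random,
                    n_steps=config.hrg_steps,
                    rng_seed=config.rng_seed,
                )
                stats_payload.update(
                    {"hrg_loglik": obs_ll, "hierarchy_empirical_p": p_hier}
                )
        net_stats_path = run_dir / "network_stats.json"
        net_stats_path.write_text(json.dumps(stats_payload, indent=1))
        network_outputs.append(net_stats_path)
        manifest.record("network", {"min_frequency": 2}, network_outputs)

        # --- replication -------------------------------------------------
        logfc = synthetic_data.generate_replication_logfc(
            truth,
            config.replication_arrays,
            config.replication_effect,
            config.replication_noise,
            config.rng_seed,
        )
        replication_outputs = []
        for label in ("m1", "m2"):
            if not dys_modules[label]:
                continue
            table = module_stats.replication_test(
                dys_modules[label], logfc, config.min_genes, config.fdr_level
            )
            path = run_dir / f"replication_{label}.tsv"
            table.to_csv(path, sep="\t", index=False)
            replication_outputs.append(path)
        manifest.record(
            "replication",
            {"n_arrays": config.replication_arrays},
            replication_outputs,
        )
        log.info("pipeline finished in %.1f s", time.time() - t0)
    except Exception as exc:  # halt with the stage context
        manifest.write()
        raise PipelineError(
            f"pipeline failed after stage "
            f"{manifest.stages[-1]['stage'] if manifest.stages else 'start'}: {exc}"
        ) from exc

    manifest.write()
    return run_dir
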