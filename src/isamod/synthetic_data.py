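"""Synthetic multi-dataset expression compendia with planted co-expression
modules, batch effects, a case/control contrast and a hemizygous gene set.

Every downstream stage of the pipeline is testable against the ground truth
returned alongside the generated matrices. All generators are deterministic
under their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .enrichment import AnnotationMap, Category
from .preprocess import ExpressionMatrix


class ConfigError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Parameters of the simulated study.

    The default is a scaled-down compendium: 2,000 genes over 4 datasets of
    12 samples each, 10 planted modules of 20-60 genes, and a separate
    case/control matrix of 8 cases vs 9 controls.
    """

    n_genes: int = 2000
    n_datasets: int = 4
    samples_per_dataset: tuple[int, ...] = (12, 12, 12, 12)
    n_planted_modules: int = 10
    module_gene_sizes: tuple[int, ...] = (20, 24, 28, 32, 36, 41, 45, 50, 55, 60)
    module_sample_fraction: float = 0.25
    module_amplitude: float = 4.0
    batch_shift_sd: float = 0.3
    batch_scale_sd: float = 0.1
    noise_sd: float = 0.5
    n_cases: int = 8
    n_controls: int = 9
    case_effect_modules: tuple[int, ...] = (0, 1, 2)
    case_effect_size: float = 1.5
    hemizygous_set_size: int = 13
    hemizygous_effect: float = -1.0
    detection_dropout_rate: float = 0.02
    sign_flip_prob: float = 0.5
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1 or self.n_datasets < 1:
            raise ConfigError("n_genes and n_datasets must be >= 1")
        if len(self.samples_per_dataset) != self.n_datasets:
            raise ConfigError("samples_per_dataset must have n_datasets entries")
        if any(s < 1 for s in self.samples_per_dataset):
            raise ConfigError("each dataset needs at least one sample")
        if len(self.module_gene_sizes) > self.n_planted_modules:
            raise ConfigError("module_gene_sizes longer than n_planted_modules")
        if any(s > self.n_genes for s in self.module_gene_sizes):
            raise ConfigError("module gene sizes cannot exceed n_genes")
        if not (0 < self.module_sample_fraction <= 1):
            raise ConfigError("module_sample_fraction must be in (0, 1]")
        for name in ("detection_dropout_rate", "sign_flip_prob"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ConfigError(f"{name} must be in [0, 1]")
        if self.hemizygous_set_size < 0:
            raise ConfigError("hemizygous_set_size must be >= 0")
        if self.n_planted_modules and any(
            i < 0 or i >= self.n_planted_modules for i in self.case_effect_modules
        ):
            raise ConfigError("case_effect_modules indices out of range")

    def module_sizes(self) -> list[int]:
        """Per-module gene counts, cycling the configured sizes if needed."""
        if self.n_planted_modules == 0:
            return []
        sizes = list(self.module_gene_sizes) or [20]
        return [sizes[i % len(sizes)] for i in range(self.n_planted_modules)]


@dataclass
class PlantedModule:
    genes: list[str]
    signs: list[int]
    samples: list[str]


@dataclass
class GroundTruth:
    planted_modules: list[PlantedModule]
    dysregulated_module_indices: list[int]
    hemizygous_genes: list[str]
    batch_assignments: dict[str, str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        bad = [
            i
            for i in self.dysregulated_module_indices
            if i < 0 or i >= len(self.planted_modules)
        ]
        if bad:
            raise ConfigError(f"dysregulated indices outside planted modules: {bad}")

    def module_gene_sets(self) -> list[frozenset]:
        return [frozenset(pm.genes) for pm in self.planted_modules]


def _gene_ids(n: int) -> list[str]:
    return [f"g{i:05d}" for i in range(n)]


def generate_study(
    config: SimulationConfig,
) -> tuple[list[ExpressionMatrix], ExpressionMatrix, GroundTruth]:
    """Generate the compendium (one matrix per dataset), the case/control
    matrix and the ground truth.

    Background cells are i.i.d. N(0, noise_sd). Planted-module member genes
    are shifted by ``sign * module_amplitude`` in member samples (signs allow
    anti-correlated module halves). Each dataset then receives gene-wise
    additive shifts N(0, batch_shift_sd) and multiplicative factors
    exp(N(0, batch_scale_sd)). In the case/control matrix the genes of
    ``case_effect_modules`` are shifted by ``sign * case_effect_size`` in
    cases and the hemizygous genes by ``hemizygous_effect``.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    genes = _gene_ids(config.n_genes)

    # sample ids per dataset and the concatenated compendium sample list
    dataset_ids = [f"d{i}" for i in range(config.n_datasets)]
    sample_ids = {
        d: [f"{d}_s{j:02d}" for j in range(ns)]
        for d, ns in zip(dataset_ids, config.samples_per_dataset)
    }
    all_samples = [s for d in dataset_ids for s in sample_ids[d]]
    n_total = len(all_samples)

    # planted modules: disjoint gene sets when possible, random sample subsets
    sizes = config.module_sizes()
    planted: list[PlantedModule] = []
    if sum(sizes) <= config.n_genes:
        pool = rng.permutation(config.n_genes)
        offset = 0
        gene_blocks = []
        for size in sizes:
            gene_blocks.append(sorted(pool[offset : offset + size]))
            offset += size
    else:
        gene_blocks = [
            sorted(rng.choice(config.n_genes, size=size, replace=False))
            for size in sizes
        ]
    n_member = max(2, round(config.module_sample_fraction * n_total))
    for block in gene_blocks:
        signs = np.where(rng.random(len(block)) < config.sign_flip_prob, -1, 1)
        members = sorted(rng.choice(n_total, size=min(n_member, n_total), replace=False))
        planted.append(
            PlantedModule(
                genes=[genes[i] for i in block],
                signs=[int(s) for s in signs],
                samples=[all_samples[i] for i in members],
            )
        )

    hemi_pool = sorted(set(range(config.n_genes)) - {i for b in gene_blocks for i in b})
    if len(hemi_pool) < config.hemizygous_set_size:
        hemi_pool = list(range(config.n_genes))
    hemi_idx = sorted(
        rng.choice(hemi_pool, size=config.hemizygous_set_size, replace=False)
    ) if config.hemizygous_set_size else []
    hemizygous = [genes[i] for i in hemi_idx]

    # compendium signal matrix on the concatenated samples
    signal = rng.normal(0.0, config.noise_sd, size=(config.n_genes, n_total))
    sample_pos = {s: j for j, s in enumerate(all_samples)}
    for pm in planted:
        cols = [sample_pos[s] for s in pm.samples]
        for g, sign in zip(pm.genes, pm.signs):
            gi = int(g[1:])
            signal[gi, cols] += sign * config.module_amplitude

    # split per dataset and apply batch effects
    compendium: list[ExpressionMatrix] = []
    batch_assignments: dict[str, str] = {}
    col = 0
    status_labels = {}
    for d, ns in zip(dataset_ids, config.samples_per_dataset):
        block = signal[:, col : col + ns].copy()
        col += ns
        shift = rng.normal(0.0, config.batch_shift_sd, size=config.n_genes)
        scale = np.exp(rng.normal(0.0, config.batch_scale_sd, size=config.n_genes))
        block = shift[:, None] + scale[:, None] * block
        detected = rng.random(block.shape) >= config.detection_dropout_rate
        # alternate disease statuses so covariate levels span datasets
        statuses = ["control" if j < ns // 2 else "affected" for j in range(ns)]
        meta = pd.DataFrame(
            {
                "dataset_id": d,
                "disease_status": statuses,
                "group": "other",
            },
            index=sample_ids[d],
        )
        for s in sample_ids[d]:
            batch_assignments[s] = d
        status_labels[d] = statuses
        compendium.append(
            ExpressionMatrix(
                pd.DataFrame(block, index=genes, columns=sample_ids[d]),
                pd.DataFrame(detected, index=genes, columns=sample_ids[d]),
                meta,
            )
        )

    # case/control matrix: own batch, dysregulated-module and hemizygous shifts
    case_ids = [f"wbs_case{i:02d}" for i in range(config.n_cases)]
    ctrl_ids = [f"wbs_ctrl{i:02d}" for i in range(config.n_controls)]
    wbs_samples = case_ids + ctrl_ids
    wbs = rng.normal(0.0, config.noise_sd, size=(config.n_genes, len(wbs_samples)))
    case_cols = np.arange(config.n_cases)
    for mi in config.case_effect_modules:
        pm = planted[mi] if planted else None
        if pm is None:
            continue
        for g, sign in zip(pm.genes, pm.signs):
            wbs[int(g[1:]), case_cols] += sign * config.case_effect_size
    for g in hemizygous:
        wbs[int(g[1:]), case_cols] += config.hemizygous_effect
    wbs_detected = rng.random(wbs.shape) >= config.detection_dropout_rate
    wbs_meta = pd.DataFrame(
        {
            "dataset_id": "wbs",
            "disease_status": ["affected"] * config.n_cases
            + ["control"] * config.n_controls,
            "group": ["case"] * config.n_cases + ["control"] * config.n_controls,
        },
        index=wbs_samples,
    )
    for s in wbs_samples:
        batch_assignments[s] = "wbs"
    wbs_matrix = ExpressionMatrix(
        pd.DataFrame(wbs, index=genes, columns=wbs_samples),
        pd.DataFrame(wbs_detected, index=genes, columns=wbs_samples),
        wbs_meta,
    )

    truth = GroundTruth(
        planted_modules=planted,
        dysregulated_module_indices=[i for i in config.case_effect_modules if planted],
        hemizygous_genes=hemizygous,
        batch_assignments=batch_assignments,
        gene_ids=genes,
    )
    return compendium, wbs_matrix, truth


def generate_network(
    truth: GroundTruth,
    n_background_genes: int,
    edge_prob_within: float,
    edge_prob_between: float,
    rng_seed: int,
):
    """Random evidence-weighted interaction network over the truth genes plus
    background genes: pairs within a planted module gene set are connected
    with ``edge_prob_within``, all other pairs with ``edge_prob_between``.
    Evidence scores are uniform in (0, 1]."""
    from .network_analysis import GeneNetwork

    for p in (edge_prob_within, edge_prob_between):
        if not (0 <= p <= 1):
            raise ConfigError("edge probabilities must be in [0, 1]")
    rng = np.random.default_rng(rng_seed)
    module_genes = sorted({g for pm in truth.planted_modules for g in pm.genes})
    vertices = module_genes + list(truth.hemizygous_genes)
    vertices += [f"bg{i:04d}" for i in range(n_background_genes)]
    vertices = sorted(dict.fromkeys(vertices))
    membership: dict[str, set[int]] = {}
    for mi, pm in enumerate(truth.planted_modules):
        for g in pm.genes:
            membership.setdefault(g, set()).add(mi)
    graph = nx.Graph()
    graph.add_nodes_from(vertices)
    for i, u in enumerate(vertices):
        for v in vertices[i + 1 :]:
            within = bool(membership.get(u, set()) & membership.get(v, set()))
            p = edge_prob_within if within else edge_prob_between
            if rng.random() < p:
                graph.add_edge(u, v, evidence=float(1.0 - rng.random()))
    return GeneNetwork(graph)


def generate_annotation(
    truth: GroundTruth,
    n_random_categories: int,
    category_size_range: tuple[int, int],
    rng_seed: int,
) -> AnnotationMap:
    """One category per planted module (its exact gene set) plus
    ``n_random_categories`` random gene sets drawn from the truth universe."""
    universe = truth.gene_ids
    if not universe:
        raise ConfigError("empty gene universe")
    lo, hi = category_size_range
    if lo < 1 or hi > len(universe) or lo > hi:
        raise ConfigError("category_size_range outside the universe")
    rng = np.random.default_rng(rng_seed)
    ann = AnnotationMap()
    for mi, pm in enumerate(truth.planted_modules):
        ann.add(f"planted_{mi}", Category(name=f"planted module {mi}", genes=pm.genes))
    for j in range(n_random_categories):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(len(universe), size=size, replace=False)
        ann.add(
            f"random_{j}",
            Category(name=f"random category {j}", genes=[universe[i] for i in members]),
        )
    return ann


def generate_replication_logfc(
    truth: GroundTruth,
    n_arrays: int,
    effect: float,
    noise_sd: float,
    rng_seed: int,
) -> pd.DataFrame:
    """Per-gene log fold changes over replication arrays: genes of the
    dysregulated modules carry ``sign * effect`` plus noise, others only
    noise. Used to exercise the second-cell-type replication test."""
    rng = np.random.default_rng(rng_seed)
    genes = truth.gene_ids
    logfc = rng.normal(0.0, noise_sd, size=(len(genes), n_arrays))
    for mi in truth.dysregulated_module_indices:
        pm = truth.planted_modules[mi]
        for g, sign in zip(pm.genes, pm.signs):
            logfc[genes.index(g), :] += sign * effect
    return pd.DataFrame(
        logfc, index=genes, columns=[f"rep{j:02d}" for j in range(n_arrays)]
    )
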