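"""Readers and writers for the plain-text formats used by the pipeline:
expression TSV (+ detection flags and sample metadata), GMT annotations,
evidence-weighted network TSV, module JSON and ground-truth JSON."""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from ..enrichment import AnnotationMap, Category
from ..isa_core import IsaThresholds, ModuleSet, TranscriptionModule
from ..network_analysis import GeneNetwork
from ..preprocess import ExpressionMatrix
from ..synthetic_data import GroundTruth, PlantedModule

log = logging.getLogger(__name__)


class ParseError(ValueError):
    pass


def _read_table(path: str | Path, expect_numeric: bool) -> tuple[list[str], list[str], list[list]]:
    """Strict TSV reader: header row of sample ids, first column row ids.
    Reports the 1-based line number of ragged rows and bad cells."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    header = lines[0].split("\t")
    n_cols = len(header)
    row_ids, rows = [], []
    for lineno, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        if len(cells) != n_cols:
            raise ParseError(
                f"{path}: ragged row at line {lineno} "
                f"({len(cells)} fields, expected {n_cols})"
            )
        row_ids.append(cells[0])
        if expect_numeric:
            try:
                rows.append([float(c) for c in cells[1:]])
            except ValueError as exc:
                raise ParseError(f"{path}: non-numeric cell at line {lineno}: {exc}")
        else:
            rows.append(cells[1:])
    if len(set(row_ids)) != len(row_ids):
        raise ParseError(f"{path}: duplicate row ids")
    sample_ids = header[1:]
    if len(set(sample_ids)) != len(sample_ids):
        raise ParseError(f"{path}: duplicate column ids")
    return row_ids, sample_ids, rows


def write_expression_tsv(
    m: ExpressionMatrix,
    values_path: str | Path,
    flags_path: str | Path | None = None,
    meta_path: str | Path | None = None,
) -> None:
    with open(values_path, "w") as fh:
        fh.write("feature_id\t" + "\t".join(m.sample_ids) + "\n")
        for fid, row in zip(m.feature_ids, m.values.to_numpy()):
            fh.write(fid + "\t" + "\t".join(repr(float(x)) for x in row) + "\n")
    if flags_path is not None:
        with open(flags_path, "w") as fh:
            fh.write("feature_id\t" + "\t".join(m.sample_ids) + "\n")
            for fid, row in zip(m.feature_ids, m.detected.to_numpy()):
                fh.write(fid + "\t" + "\t".join("P" if x else "A" for x in row) + "\n")
    if meta_path is not None:
        m.sample_meta.rename_axis("sample_id").to_csv(meta_path, sep="\t")


def read_expression_tsv(
    values_path: str | Path,
    flags_path: str | Path | None = None,
    meta_path: str | Path | None = None,
) -> ExpressionMatrix:
    row_ids, sample_ids, rows = _read_table(values_path, expect_numeric=True)
    values = pd.DataFrame(rows, index=row_ids, columns=sample_ids)
    detected = None
    if flags_path is not None and Path(flags_path).exists():
        f_rows, f_samples, f_cells = _read_table(flags_path, expect_numeric=False)
        if f_rows != row_ids or f_samples != sample_ids:
            raise ParseError(f"{flags_path}: ids do not match the values file")
        detected = pd.DataFrame(
            [[c == "P" for c in row] for row in f_cells],
            index=row_ids,
            columns=sample_ids,
        )
    elif flags_path is not None:
        log.warning("flags file %s missing; defaulting to all-detected", flags_path)
    meta = None
    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    return ExpressionMatrix(values, detected, meta)


def write_gmt(ann: AnnotationMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for cat_id, cat in ann.items():
            fh.write("\t".join([cat_id, cat.name] + sorted(cat.genes)) + "\n")


def read_gmt(path: str | Path) -> AnnotationMap:
    ann = AnnotationMap()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ParseError(f"{path}: malformed GMT line {lineno}")
        cat_id, name, *genes = parts
        ann.add(cat_id, Category(name=name, genes=[g for g in genes if g]))
    return ann


def write_network_tsv(net: GeneNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tevidence\n")
        for u, v, d in sorted(net.graph.edges(data=True)):
            fh.write(f"{u}\t{v}\t{d['evidence']:.6g}\n")


def read_network_tsv(path: str | Path) -> GeneNetwork:
    """Three-column network TSV; combined scores above 1 are assumed to be on
    the 0-1000 STRING scale and divided by 1000."""
    edges = []
    lines = Path(path).read_text().splitlines()
    for lineno, line in enumerate(lines, start=1):
        if lineno == 1 and line.lower().startswith(("gene_a", "protein")):
            continue
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ParseError(f"{path}: malformed network line {lineno}")
        u, v, score_s = parts
        try:
            score = float(score_s)
        except ValueError:
            raise ParseError(f"{path}: non-numeric score at line {lineno}")
        if score > 1:
            score /= 1000.0
        edges.append((u, v, score))
    return GeneNetwork.from_edges(edges)


def _sparse(series: pd.Series) -> dict:
    nz = series[series != 0]
    return {"ids": list(nz.index), "scores": [float(x) for x in nz.to_numpy()]}


def write_modules(ms: ModuleSet, path: str | Path) -> None:
    payload = {
        "source_matrix_id": ms.source_matrix_id,
        "run_label": ms.run_label,
        "grid": [[t.gene, t.sample] for t in ms.grid],
        "all_genes": list(ms.modules[0].gene_scores.index) if ms.modules else [],
        "all_samples": list(ms.modules[0].sample_scores.index) if ms.modules else [],
        "modules": [
            {
                "id": m.id,
                "thresholds": [m.thresholds.gene, m.thresholds.sample],
                "seed_id": m.seed_id,
                "sample_score_scale": m.sample_score_scale,
                "robustness": m.robustness,
                "gene_scores": _sparse(m.gene_scores),
                "sample_scores": _sparse(m.sample_scores),
            }
            for m in ms.modules
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_modules(path: str | Path) -> ModuleSet:
    payload = json.loads(Path(path).read_text())
    genes = payload["all_genes"]
    samples = payload["all_samples"]
    modules = []
    for spec in payload["modules"]:
        g = pd.Series(0.0, index=genes)
        g[spec["gene_scores"]["ids"]] = spec["gene_scores"]["scores"]
        s = pd.Series(0.0, index=samples)
        s[spec["sample_scores"]["ids"]] = spec["sample_scores"]["scores"]
        modules.append(
            TranscriptionModule(
                id=spec["id"],
                gene_scores=g,
                sample_scores=s,
                thresholds=IsaThresholds(*spec["thresholds"]),
                seed_id=spec["seed_id"],
                sample_score_scale=spec["sample_score_scale"],
                robustness=spec["robustness"],
            )
        )
    return ModuleSet(
        modules,
        payload["source_matrix_id"],
        [IsaThresholds(g, s) for g, s in payload["grid"]],
        payload["run_label"],
    )


def write_truth(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "planted_modules": [
            {"genes": pm.genes, "signs": pm.signs, "samples": pm.samples}
            for pm in truth.planted_modules
        ],
        "dysregulated_module_indices": list(truth.dysregulated_module_indices),
        "hemizygous_genes": list(truth.hemizygous_genes),
        "batch_assignments": dict(truth.batch_assignments),
        "gene_ids": list(truth.gene_ids),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_truth(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        planted_modules=[
            PlantedModule(pm["genes"], pm["signs"], pm["samples"])
            for pm in payload["planted_modules"]
        ],
        dysregulated_module_indices=payload["dysregulated_module_indices"],
        hemizygous_genes=payload["hemizygous_genes"],
        batch_assignments=payload["batch_assignments"],
        gene_ids=payload["gene_ids"],
    )


def read_feature_map(path: str | Path) -> dict:
    """Two-column feature -> gene TSV (optional header)."""
    mapping = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ParseError(f"{path}: malformed map line {lineno}")
        if lineno == 1 and parts[0].lower() in ("feature_id", "probeset"):
            continue
        if parts[0] in mapping:
            raise ParseError(f"{path}: duplicate feature id at line {lineno}")
        mapping[parts[0]] = parts[1]
    return mapping
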