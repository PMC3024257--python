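"""Module dysregulation statistics.

The sample score of a module is the weighted average expression of its genes
(weights = ISA gene scores, normalized by the sum of absolute weights).
Dysregulation is an unequal-variance t-test of case vs control sample scores
with BH correction over the tested modules, validated by case/control label
permutations. Replication in a second cell type uses weighted mean log fold
changes, and frequent-gene counting summarizes recurrence across dysregulated
modules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import bh_adjust
from .isa_core import ModuleSet, TranscriptionModule
from .preprocess import ExpressionMatrix, standardize

log = logging.getLogger(__name__)


class ModuleStatsError(ValueError):
    pass


@dataclass
class DysregulationResult:
    module_id: str
    t_stat: float
    raw_p: float
    adjusted_p: float
    direction: str  # "up-in-case" / "down-in-case"
    n_genes_used: int
    significant: bool = False


@dataclass
class PermutationSummary:
    n_perm: int
    n_perm_with_any_significant: int
    counts_per_permutation: list[int]
    mean_count: float
    median_count: float


def module_sample_scores(
    module: TranscriptionModule, m: ExpressionMatrix
) -> pd.Series:
    """Weighted average expression of the module genes for every sample of
    ``m`` (the extension to non-member samples): ``sum_g w_g x_gc / sum_g
    |w_g|``. Module genes missing from ``m`` are dropped with a warning."""
    weights = module.gene_scores[module.gene_scores != 0]
    present = [g for g in weights.index if g in m.values.index]
    if not present:
        raise ModuleStatsError(
            f"no genes of module {module.id} are present in the matrix"
        )
    if len(present) < len(weights):
        log.warning(
            "module %s: %d of %d genes missing from matrix",
            module.id,
            len(weights) - len(present),
            len(weights),
        )
    w = weights[present].to_numpy()
    X = m.values.loc[present].to_numpy()
    return pd.Series((w @ X) / np.abs(w).sum(), index=m.sample_ids)


def _usable_genes(module: TranscriptionModule, feature_index: pd.Index) -> list:
    return [g for g in module.gene_scores.index[module.gene_scores != 0]
            if g in feature_index]


def _score_matrix(
    modules: Sequence[TranscriptionModule],
    m_std: ExpressionMatrix,
    min_genes: int,
) -> tuple[list[TranscriptionModule], np.ndarray, list[int]]:
    """Sample-score rows for every module with >= min_genes usable genes."""
    tested, rows, n_used = [], [], []
    for module in modules:
        usable = _usable_genes(module, m_std.values.index)
        if len(usable) < min_genes:
            continue
        rows.append(module_sample_scores(module, m_std).to_numpy())
        tested.append(module)
        n_used.append(len(usable))
    return tested, (np.vstack(rows) if rows else np.empty((0, m_std.n_samples))), n_used


def _welch(scores: np.ndarray, case_ix: np.ndarray, ctrl_ix: np.ndarray):
    t, p = stats.ttest_ind(
        scores[:, case_ix], scores[:, ctrl_ix], axis=1, equal_var=False
    )
    return np.asarray(t), np.asarray(p)


def _drop_constant_rows(m: ExpressionMatrix) -> ExpressionMatrix:
    sd = m.values.std(axis=1, ddof=1)
    constant = sd == 0
    if constant.any():
        log.warning("dropping %d constant genes before standardization", constant.sum())
        return m.subset_features(list(m.values.index[~constant]))
    return m


def dysregulation_test(
    ms: ModuleSet | Sequence[TranscriptionModule],
    wbs: ExpressionMatrix,
    min_genes: int = 10,
    fdr_level: float = 0.05,
) -> list[DysregulationResult]:
    """Test each module with at least ``min_genes`` usable genes for
    case/control dysregulation of its weighted sample scores.

    The matrix is standardized per gene first; the BH family consists of the
    tested modules only.
    """
    modules = list(ms)
    case_ids = wbs.samples_in_group("case")
    ctrl_ids = wbs.samples_in_group("control")
    if len(case_ids) < 2 or len(ctrl_ids) < 2:
        raise ModuleStatsError("need >= 2 cases and >= 2 controls")
    m_std = standardize(_drop_constant_rows(wbs), axis="gene")
    tested, scores, n_used = _score_matrix(modules, m_std, min_genes)
    if not tested:
        log.warning("no module has >= %d usable genes", min_genes)
        return []
    sample_pos = {s: j for j, s in enumerate(m_std.sample_ids)}
    case_ix = np.array([sample_pos[s] for s in case_ids])
    ctrl_ix = np.array([sample_pos[s] for s in ctrl_ids])
    t, p = _welch(scores, case_ix, ctrl_ix)
    adj = bh_adjust(p)
    results = []
    for module, ti, pi, ai, n in zip(tested, t, p, adj, n_used):
        results.append(
            DysregulationResult(
                module_id=module.id,
                t_stat=float(ti),
                raw_p=float(pi),
                adjusted_p=float(ai),
                direction="up-in-case" if ti > 0 else "down-in-case",
                n_genes_used=n,
                significant=bool(ai <= fdr_level),
            )
        )
    return results


def permutation_validation(
    ms: ModuleSet | Sequence[TranscriptionModule],
    wbs: ExpressionMatrix,
    min_genes: int = 10,
    fdr_level: float = 0.05,
    n_perm: int = 1000,
    rng_seed: int = 0,
) -> PermutationSummary:
    """Repeat the dysregulation test under random case/control relabelings
    (group sizes preserved) and record how many modules come out significant
    in each permutation."""
    if n_perm < 1:
        raise ModuleStatsError("n_perm must be >= 1")
    modules = list(ms)
    case_ids = wbs.samples_in_group("case")
    ctrl_ids = wbs.samples_in_group("control")
    if len(case_ids) < 2 or len(ctrl_ids) < 2:
        raise ModuleStatsError("need >= 2 cases and >= 2 controls")
    m_std = standardize(_drop_constant_rows(wbs), axis="gene")
    tested, scores, _ = _score_matrix(modules, m_std, min_genes)
    if not tested:
        raise ModuleStatsError("no module has enough usable genes")
    sample_pos = {s: j for j, s in enumerate(m_std.sample_ids)}
    labelled = np.array([sample_pos[s] for s in case_ids + ctrl_ids])
    n_cases = len(case_ids)
    rng = np.random.default_rng(rng_seed)
    counts = []
    for _ in range(n_perm):
        perm = rng.permutation(labelled)
        _, p = _welch(scores, perm[:n_cases], perm[n_cases:])
        counts.append(int((bh_adjust(p) <= fdr_level).sum()))
    counts_arr = np.array(counts)
    nonzero = counts_arr[counts_arr > 0]
    return PermutationSummary(
        n_perm=n_perm,
        n_perm_with_any_significant=int((counts_arr > 0).sum()),
        counts_per_permutation=counts,
        mean_count=float(nonzero.mean()) if nonzero.size else float("nan"),
        median_count=float(np.median(nonzero)) if nonzero.size else float("nan"),
    )


def replication_test(
    ms: ModuleSet | Sequence[TranscriptionModule],
    logfc: pd.DataFrame,
    min_genes: int = 10,
    fdr_level: float = 0.05,
) -> pd.DataFrame:
    """Replication of module dysregulation from per-gene log fold changes on
    independent arrays: per module, the weighted mean logFC per array is
    tested against zero with a one-sample two-sided t-test, BH-corrected
    across the tested modules."""
    if logfc.shape[1] < 2:
        raise ModuleStatsError("need at least 2 replication arrays")
    rows = []
    for module in list(ms):
        weights = module.gene_scores[module.gene_scores != 0]
        present = [g for g in weights.index if g in logfc.index]
        if len(present) < min_genes:
            continue
        w = weights[present].to_numpy()
        per_array = (w @ logfc.loc[present].to_numpy()) / np.abs(w).sum()
        if np.allclose(per_array.std(ddof=1), 0):
            if np.allclose(per_array, 0):
                t_val, p_val = 0.0, 1.0
            else:
                log.warning("module %s: zero variance across arrays", module.id)
                t_val, p_val = float("nan"), 1.0
        else:
            t_val, p_val = stats.ttest_1samp(per_array, 0.0)
        rows.append(
            {
                "module_id": module.id,
                "n_genes_used": len(present),
                "mean_weighted_logfc": float(per_array.mean()),
                "t_stat": float(t_val),
                "raw_p": float(p_val),
            }
        )
    table = pd.DataFrame(rows)
    if len(table):
        table["adjusted_p"] = bh_adjust(table["raw_p"].to_numpy())
        table["direction"] = np.where(
            table["mean_weighted_logfc"] > 0, "up-in-case", "down-in-case"
        )
        table["significant"] = table["adjusted_p"] <= fdr_level
    return table


def gene_frequency(
    dys_m1: Sequence[TranscriptionModule],
    dys_m2: Sequence[TranscriptionModule],
) -> pd.DataFrame:
    """Count, per gene, its occurrence in the dysregulated M1 and M2 modules.

    Returns a dataframe indexed by gene with columns ``count_m1``,
    ``count_m2``, ``total`` and ``intersection`` (gene occurs in both sets),
    sorted by total count descending."""
    counts: dict[str, list[int]] = {}
    for module in dys_m1:
        for g in module.gene_set:
            counts.setdefault(g, [0, 0])[0] += 1
    for module in dys_m2:
        for g in module.gene_set:
            counts.setdefault(g, [0, 0])[1] += 1
    if not counts:
        return pd.DataFrame(
            columns=["count_m1", "count_m2", "total", "intersection"]
        )
    table = pd.DataFrame.from_dict(counts, orient="index", columns=["count_m1", "count_m2"])
    table["total"] = table["count_m1"] + table["count_m2"]
    table["intersection"] = (table["count_m1"] >= 1) & (table["count_m2"] >= 1)
    return table.sort_values(["total", "count_m1"], ascending=False, kind="stable")


def correlate_frequency(
    freq: pd.DataFrame, quantity: pd.Series, column: str = "total"
) -> tuple[float, float, float]:
    """Pearson correlation of module frequency against a per-gene quantity
    (e.g. |moderated t| or network degree); returns (r, slope, slope_p)."""
    common = [g for g in freq.index if g in quantity.index]
    if len(common) < 3:
        raise ModuleStatsError("need at least 3 genes in common")
    x = freq.loc[common, column].to_numpy(dtype=float)
    y = quantity.loc[common].to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ModuleStatsError("constant input in correlation")
    fit = stats.linregress(x, y)
    return float(fit.rvalue), float(fit.slope), float(fit.pvalue)
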