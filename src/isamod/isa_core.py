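"""Iterative Signature Algorithm.

Alternating thresholded projections between gene space and sample space:
a gene-score vector is projected onto the per-sample-standardized matrix to
obtain sample scores, thresholded, projected back onto the per-gene
standardized matrix, thresholded again, and iterated to a fixed point.
Modules are collected over a grid of (gene, sample) threshold pairs from many
random seeds and deduplicated by gene-score correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .preprocess import ExpressionMatrix, standardize

log = logging.getLogger(__name__)

#: score-change tolerance used to declare a seed converged
CONVERGENCE_TOL = 1e-8


class EmptySignatureError(RuntimeError):
    """All scores were thresholded to zero; the seed does not converge."""


@dataclass(frozen=True)
class IsaThresholds:
    gene: float
    sample: float

    def __post_init__(self) -> None:
        if self.gene <= 0 or self.sample <= 0:
            raise ValueError("ISA thresholds must be positive")


def default_grid(
    gene_thresholds: Sequence[float] = tuple(np.arange(2.0, 4.01, 0.2)),
    sample_thresholds: Sequence[float] = tuple(np.arange(1.0, 2.01, 0.2)),
) -> list[IsaThresholds]:
    """The full Cartesian threshold grid (defaults: genes 2..4 by 0.2,
    samples 1..2 by 0.2)."""
    return [
        IsaThresholds(round(float(g), 10), round(float(s), 10))
        for g in gene_thresholds
        for s in sample_thresholds
    ]


@dataclass
class TranscriptionModule:
    """Signed gene and sample scores; zero score means non-membership.

    Gene scores are scaled to max |score| = 1. ``sample_scores`` are likewise
    max-1 scaled; multiplying them by ``sample_score_scale`` recovers the raw
    weighted averages of member-gene standardized expression.
    """

    id: str
    gene_scores: pd.Series
    sample_scores: pd.Series
    thresholds: IsaThresholds
    seed_id: int = -1
    sample_score_scale: float = 1.0
    robustness: float = 0.0

    def __post_init__(self) -> None:
        if (self.gene_scores != 0).sum() == 0:
            raise ValueError("module must contain at least one gene")
        if (self.sample_scores != 0).sum() == 0:
            raise ValueError("module must contain at least one sample")

    @property
    def gene_set(self) -> frozenset:
        return frozenset(self.gene_scores.index[self.gene_scores != 0])

    @property
    def sample_set(self) -> frozenset:
        return frozenset(self.sample_scores.index[self.sample_scores != 0])

    @property
    def n_genes(self) -> int:
        return int((self.gene_scores != 0).sum())

    @property
    def n_samples(self) -> int:
        return int((self.sample_scores != 0).sum())


@dataclass
class ModuleSet:
    modules: list[TranscriptionModule]
    source_matrix_id: str = ""
    grid: list[IsaThresholds] = field(default_factory=list)
    run_label: str = "other"

    def __post_init__(self) -> None:
        ids = [m.id for m in self.modules]
        if len(set(ids)) != len(ids):
            raise ValueError("module ids must be unique")

    def __len__(self) -> int:
        return len(self.modules)

    def __iter__(self):
        return iter(self.modules)


def isa_normalize(E: ExpressionMatrix) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Double standardization: ``E_G`` has every gene (row) at mean 0 / sd 1,
    ``E_C`` every sample (column) at mean 0 / sd 1."""
    e_g = standardize(E, axis="gene").values
    e_c = standardize(E, axis="sample").values
    return e_g, e_c


def _threshold(raw: np.ndarray, thr: float) -> np.ndarray:
    """Keep entries further than ``thr`` sd from the mean of each column of
    ``raw`` (signed, others zeroed)."""
    raw = np.atleast_2d(raw.T).T if raw.ndim == 1 else raw
    mu = raw.mean(axis=0)
    sd = raw.std(axis=0, ddof=1)
    keep = np.abs(raw - mu) > thr * sd
    return np.where(keep, raw, 0.0)


def isa_step(
    g: np.ndarray,
    E_G: np.ndarray | pd.DataFrame,
    E_C: np.ndarray | pd.DataFrame,
    thr: IsaThresholds,
) -> tuple[np.ndarray, np.ndarray]:
    """One ISA iteration from gene scores ``g``: project to sample scores,
    threshold at ``thr.sample`` sd, project back and threshold at
    ``thr.gene`` sd. Returns (new gene scores scaled to max |.| = 1,
    thresholded raw sample scores)."""
    E_G = np.asarray(E_G, dtype=float)
    E_C = np.asarray(E_C, dtype=float)
    g = np.asarray(g, dtype=float)
    if np.sum(np.abs(g)) == 0:
        raise EmptySignatureError("gene seed has no nonzero entry")
    s_raw = E_G.T @ g / np.abs(g).sum()
    s = _threshold(s_raw[:, None], thr.sample)[:, 0]
    if np.abs(s).sum() == 0:
        raise EmptySignatureError("all sample scores thresholded to zero")
    g_raw = E_C @ s / np.abs(s).sum()
    g_new = _threshold(g_raw[:, None], thr.gene)[:, 0]
    if np.abs(g_new).sum() == 0:
        raise EmptySignatureError("all gene scores thresholded to zero")
    g_new = g_new / np.abs(g_new).max()
    return g_new, s


def _canonical_sign(gene: np.ndarray, sample: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # flip so the majority of member sample scores is positive (ties: sum >= 0)
    nz = sample[sample != 0]
    n_pos = (nz > 0).sum()
    n_neg = (nz < 0).sum()
    flip = n_neg > n_pos or (n_neg == n_pos and nz.sum() < 0)
    return (-gene, -sample) if flip else (gene, sample)


def _finalize(
    g: np.ndarray,
    E_G: np.ndarray,
    E_C: np.ndarray,
    thr: IsaThresholds,
) -> tuple[np.ndarray, np.ndarray, float, float] | None:
    """Compute a converged seed's final sample scores, scale and robustness."""
    s_raw = E_G.T @ g / np.abs(g).sum()
    s = _threshold(s_raw[:, None], thr.sample)[:, 0]
    if np.abs(s).sum() == 0:
        return None
    g, s = _canonical_sign(g, s)
    scale = float(np.abs(s).max())
    g_unit = g / np.linalg.norm(g)
    s_unit = s / np.linalg.norm(s)
    # mean coherence: bilinear signal strength per member gene/sample
    coherence = float(abs(g_unit @ (E_C @ s_unit)))
    coherence /= np.sqrt((g != 0).sum() * (s != 0).sum())
    return g, s / scale, scale, coherence


def merge_modules(
    candidates: list[TranscriptionModule], corr_limit: float = 0.9
) -> list[TranscriptionModule]:
    """Greedy deduplication: iterate candidates by decreasing robustness and
    drop any whose gene-score vector correlates (absolute Pearson) above
    ``corr_limit`` with an already-kept module."""
    if not (0 < corr_limit <= 1):
        raise ValueError("corr_limit must be in (0, 1]")
    if not candidates:
        return []
    ordered = sorted(
        range(len(candidates)), key=lambda i: -candidates[i].robustness
    )
    # centred unit vectors so Pearson correlation reduces to a dot product
    V = np.vstack([candidates[i].gene_scores.to_numpy() for i in ordered])
    V = V - V.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(V, axis=1)
    norms[norms == 0] = 1.0
    V /= norms[:, None]
    kept: list[TranscriptionModule] = []
    kept_rows: list[int] = []
    for row, i in enumerate(ordered):
        if kept_rows:
            corr = np.abs(V[kept_rows] @ V[row])
            if corr.max() > corr_limit:
                continue
        kept.append(candidates[i])
        kept_rows.append(row)
    return kept


def run_isa(
    E: ExpressionMatrix,
    grid: Sequence[IsaThresholds] | None = None,
    n_seeds: int = 100,
    seed_size: int = 10,
    rng_seed: int = 0,
    corr_limit: float = 0.9,
    max_iter: int = 100,
    run_label: str = "other",
    source_matrix_id: str = "",
) -> ModuleSet:
    """Run ISA over a threshold grid from random gene seeds.

    For each threshold pair ``n_seeds`` random binary seeds of ``seed_size``
    genes are iterated until both the membership sets are stable and the
    gene-score vector changes by less than ``CONVERGENCE_TOL`` (cap
    ``max_iter``; non-converged seeds are discarded). Converged signatures
    from all threshold pairs are pooled and deduplicated with
    :func:`merge_modules`.
    """
    if grid is None:
        grid = default_grid()
    if not grid:
        raise ValueError("threshold grid must be non-empty")
    values = E.values.to_numpy()
    if np.allclose(values, values.flat[0]):
        return ModuleSet([], source_matrix_id, list(grid), run_label)
    E_G_df, E_C_df = isa_normalize(E)
    E_G = E_G_df.to_numpy()
    E_C = E_C_df.to_numpy()
    n_genes, n_samples = E_G.shape
    rng = np.random.default_rng(rng_seed)

    candidates: list[TranscriptionModule] = []
    seed_counter = 0
    for thr in grid:
        # seed matrix: one binary column per seed
        G = np.zeros((n_genes, n_seeds))
        for j in range(n_seeds):
            idx = rng.choice(n_genes, size=min(seed_size, n_genes), replace=False)
            G[idx, j] = 1.0
        active = np.arange(n_seeds)
        converged_cols: list[np.ndarray] = []
        prev_support = G > 0
        for _ in range(max_iter):
            if active.size == 0:
                break
            Ga = G[:, active]
            denom = np.abs(Ga).sum(axis=0)
            S_raw = (E_G.T @ Ga) / denom
            S = _threshold(S_raw, thr.sample)
            s_mass = np.abs(S).sum(axis=0)
            alive = s_mass > 0
            with np.errstate(invalid="ignore", divide="ignore"):
                G_raw = (E_C @ S) / np.where(s_mass > 0, s_mass, 1.0)
            G_new = _threshold(G_raw, thr.gene)
            g_mass = np.abs(G_new).max(axis=0)
            alive &= g_mass > 0
            G_new = G_new / np.where(g_mass > 0, g_mass, 1.0)

            support_prev = prev_support[:, active]
            support_new = G_new != 0
            same_support = (support_new == support_prev).all(axis=0)
            delta = np.abs(G_new - Ga).max(axis=0)
            done = alive & same_support & (delta < CONVERGENCE_TOL)

            for k in np.flatnonzero(done):
                converged_cols.append(G_new[:, k].copy())
            G[:, active] = G_new
            prev_support[:, active] = support_new
            active = active[alive & ~done]

        for g_final in converged_cols:
            out = _finalize(g_final, E_G, E_C, thr)
            if out is None:
                continue
            g_scores, s_scores, scale, coherence = out
            try:
                module = TranscriptionModule(
                    id=f"cand{seed_counter:05d}",
                    gene_scores=pd.Series(g_scores, index=E.feature_ids),
                    sample_scores=pd.Series(s_scores, index=E.sample_ids),
                    thresholds=thr,
                    seed_id=seed_counter,
                    sample_score_scale=scale,
                    robustness=coherence,
                )
            except ValueError:
                continue
            candidates.append(module)
            seed_counter += 1

    # robustness = basin size of the signature (how many seeds across the
    # grid converged to exactly this gene support), tie-broken by coherence
    support_freq: dict[frozenset, int] = {}
    for cand in candidates:
        support_freq[cand.gene_set] = support_freq.get(cand.gene_set, 0) + 1
    for cand in candidates:
        cand.robustness = support_freq[cand.gene_set] + 1e-6 * cand.robustness

    merged = merge_modules(candidates, corr_limit)
    for i, module in enumerate(merged):
        module.id = f"m{i:04d}"
    log.info(
        "run_isa: %d candidate signatures, %d modules after merging",
        len(candidates),
        len(merged),
    )
    return ModuleSet(merged, source_matrix_id, list(grid), run_label)
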