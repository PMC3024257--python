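"""Expression matrix container and preprocessing.

Implements the steps that turn per-dataset probeset matrices into a single
analysable gene-level matrix: detection filtering, probeset-to-gene
collapsing, multi-dataset merging, empirical-Bayes (location/scale) batch
correction with protected covariates, and per-axis standardization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: metadata columns every matrix carries; missing ones are filled with defaults
META_COLUMNS = ("dataset_id", "disease_status", "group")


class PreprocessError(ValueError):
    """Raised on invalid preprocessing input (confounding, constant rows, ...)."""


@dataclass
class ExpressionMatrix:
    """Log2 expression values (features x samples) with detection flags and
    per-sample metadata.

    Parameters
    ----------
    values:
        Float dataframe, rows indexed by feature id, columns by sample id.
    detected:
        Boolean dataframe of the same shape; ``True`` marks a "Present" call.
        ``None`` defaults to all-detected.
    sample_meta:
        Per-sample metadata indexed by sample id with columns
        ``dataset_id``, ``disease_status`` and ``group`` (one of
        ``case``/``control``/``other``). Missing columns are filled.
    """

    values: pd.DataFrame
    detected: pd.DataFrame | None = None
    sample_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        self.values = self.values.astype(float)
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise PreprocessError(f"duplicate feature ids: {dups[:5]}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].tolist()
            raise PreprocessError(f"duplicate sample ids: {dups[:5]}")
        if not np.isfinite(self.values.to_numpy()).all():
            raise PreprocessError("expression values must be finite")

        if self.detected is None:
            self.detected = pd.DataFrame(
                True, index=self.values.index, columns=self.values.columns
            )
        else:
            self.detected = pd.DataFrame(self.detected).astype(bool)
            if self.detected.shape != self.values.shape:
                raise PreprocessError("detected flags must match values shape")
            self.detected.index = self.values.index
            self.detected.columns = self.values.columns

        if self.sample_meta is None:
            self.sample_meta = pd.DataFrame(index=self.values.columns)
        else:
            self.sample_meta = pd.DataFrame(self.sample_meta)
            if set(self.sample_meta.index) != set(self.values.columns):
                raise PreprocessError("sample_meta index must equal sample ids")
            self.sample_meta = self.sample_meta.loc[self.values.columns]
        defaults = {"dataset_id": "d0", "disease_status": "unknown", "group": "other"}
        for col in META_COLUMNS:
            if col not in self.sample_meta.columns:
                self.sample_meta[col] = defaults[col]

    # -- basic views -------------------------------------------------------

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def samples_in_group(self, group: str) -> list[str]:
        mask = self.sample_meta["group"] == group
        return list(self.sample_meta.index[mask])

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.copy(), self.detected.copy(), self.sample_meta.copy()
        )

    def subset_features(self, feature_ids: Sequence[str]) -> "ExpressionMatrix":
        ids = list(feature_ids)
        return ExpressionMatrix(
            self.values.loc[ids], self.detected.loc[ids], self.sample_meta.copy()
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        ids = list(sample_ids)
        return ExpressionMatrix(
            self.values[ids], self.detected[ids], self.sample_meta.loc[ids]
        )


#: many-to-one probeset/feature id -> gene id mapping
FeatureGeneMap = Mapping[str, str]


def filter_features(
    m: ExpressionMatrix,
    min_present: int,
    feature_map: FeatureGeneMap | None = None,
) -> ExpressionMatrix:
    """Keep features detected in at least ``min_present`` samples and, when a
    feature->gene map is supplied, mapped to a gene. Feature order preserved.
    """
    if min_present < 0:
        raise PreprocessError("min_present must be >= 0")
    n_present = m.detected.sum(axis=1)
    keep = n_present >= min_present
    if feature_map is not None:
        keep &= m.values.index.to_series().isin(feature_map).to_numpy()
    kept = list(m.values.index[keep])
    if not kept:
        log.warning("filter_features removed every feature")
    log.info("filter_features: kept %d of %d features", len(kept), m.n_features)
    return m.subset_features(kept)


def collapse_to_genes(m: ExpressionMatrix, feature_map: FeatureGeneMap) -> ExpressionMatrix:
    """One row per gene: for multi-feature genes keep the feature with the
    highest sample variance (ties broken by lexicographically smallest
    feature id). Row ids become gene ids; numeric values are untouched.
    """
    missing = [f for f in m.feature_ids if f not in feature_map]
    if missing:
        raise PreprocessError(f"unmapped features: {missing[:5]}")
    variances = m.values.var(axis=1, ddof=1)
    chosen: dict[str, str] = {}  # gene -> feature id
    order: list[str] = []  # genes in order of first appearance
    for fid in m.feature_ids:
        gene = feature_map[fid]
        if gene not in chosen:
            chosen[gene] = fid
            order.append(gene)
            continue
        cur = chosen[gene]
        v_new, v_cur = variances[fid], variances[cur]
        if v_new > v_cur or (v_new == v_cur and fid < cur):
            chosen[gene] = fid
    rows = [chosen[g] for g in order]
    values = m.values.loc[rows].copy()
    detected = m.detected.loc[rows].copy()
    values.index = order
    detected.index = order
    return ExpressionMatrix(values, detected, m.sample_meta.copy())


def merge_datasets(ms: Sequence[ExpressionMatrix]) -> ExpressionMatrix:
    """Merge matrices on the intersection of their features (order of the
    first input); samples are concatenated and keep their metadata.
    """
    if len(ms) < 2:
        raise PreprocessError("merge_datasets needs at least two matrices")
    all_samples = [s for m in ms for s in m.sample_ids]
    if len(set(all_samples)) != len(all_samples):
        raise PreprocessError("sample ids must be disjoint across datasets")
    common = set(ms[0].feature_ids)
    for m in ms[1:]:
        common &= set(m.feature_ids)
    features = [f for f in ms[0].feature_ids if f in common]
    if not features:
        raise PreprocessError("empty feature intersection")
    values = pd.concat([m.values.loc[features] for m in ms], axis=1)
    detected = pd.concat([m.detected.loc[features] for m in ms], axis=1)
    meta = pd.concat([m.sample_meta for m in ms], axis=0)
    log.info(
        "merge_datasets: %d common features, %d samples", len(features), len(all_samples)
    )
    return ExpressionMatrix(values, detected, meta)


# ---------------------------------------------------------------------------
# empirical-Bayes batch correction (parametric location/scale model)
# ---------------------------------------------------------------------------


def _check_confounding(batch: pd.Series, covariate: pd.Series) -> None:
    # a batch whose samples all share one covariate level that occurs nowhere
    # else makes the batch and covariate columns collinear
    for level in covariate.unique():
        batches_with_level = set(batch[covariate == level])
        if len(batches_with_level) == 1:
            b = next(iter(batches_with_level))
            levels_in_batch = set(covariate[batch == b])
            if levels_in_batch == {level}:
                raise PreprocessError(
                    f"covariate level {level!r} is confounded with batch {b!r}"
                )


def combat_correct(
    m: ExpressionMatrix,
    batch: Mapping[str, str] | pd.Series | None = None,
    covariates: Mapping[str, str] | pd.Series | None = None,
    *,
    allow_single_batch: bool = False,
    tol: float = 1e-4,
    max_iter: int = 100,
) -> ExpressionMatrix:
    """Remove additive and multiplicative batch effects per gene while
    protecting categorical covariate effects.

    Per gene the model is ``x = alpha + X beta + gamma_b + delta_b eps``.
    Batch location (gamma) and scale (delta) are shrunk across genes with
    parametric empirical Bayes (normal / inverse-gamma priors, iterated to
    ``tol``) and removed; covariate effects are retained.
    """
    samples = m.sample_ids
    if batch is None:
        batch_s = m.sample_meta["dataset_id"].astype(str)
    else:
        batch_s = pd.Series({s: str(batch[s]) for s in samples}).loc[samples]
    batch_levels = list(dict.fromkeys(batch_s))
    if len(batch_levels) < 2:
        if allow_single_batch:
            return m.copy()
        raise PreprocessError("combat_correct requires at least two batches")
    counts = batch_s.value_counts()
    small = counts[counts < 2]
    if len(small):
        raise PreprocessError(f"batches with fewer than 2 samples: {list(small.index)}")

    cov_s = None
    if covariates is not None:
        cov_s = pd.Series({s: str(covariates[s]) for s in samples}).loc[samples]
        _check_confounding(batch_s, cov_s)

    X = m.values.to_numpy()  # genes x samples
    n_genes, n = X.shape
    n_batches = len(batch_levels)
    batch_idx = [np.flatnonzero((batch_s == b).to_numpy()) for b in batch_levels]
    n_per_batch = np.array([len(ix) for ix in batch_idx], dtype=float)

    # design: batch one-hots plus drop-first covariate dummies
    design_cols = []
    for ix in batch_idx:
        col = np.zeros(n)
        col[ix] = 1.0
        design_cols.append(col)
    if cov_s is not None:
        for level in list(dict.fromkeys(cov_s))[1:]:
            design_cols.append((cov_s == level).to_numpy().astype(float))
    design = np.column_stack(design_cols)
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise PreprocessError("design matrix is singular (confounded batch/covariate)")

    beta, *_ = np.linalg.lstsq(design, X.T, rcond=None)  # (p, genes)
    grand_mean = (n_per_batch / n) @ beta[:n_batches]  # per gene
    stand_mean = np.tile(grand_mean[:, None], (1, n))
    if cov_s is not None and design.shape[1] > n_batches:
        cov_design = design[:, n_batches:]
        stand_mean = stand_mean + (cov_design @ beta[n_batches:]).T
    resid = X - (design @ beta).T
    var_pooled = (resid**2).sum(axis=1) / n
    if np.any(var_pooled <= 0):
        raise PreprocessError("genes with zero residual variance cannot be corrected")
    sd = np.sqrt(var_pooled)[:, None]
    Z = (X - stand_mean) / sd

    Z_adj = Z.copy()
    for b, ix in enumerate(batch_idx):
        nb = len(ix)
        Zb = Z[:, ix]
        gamma_hat = Zb.mean(axis=1)
        delta_hat = Zb.var(axis=1, ddof=1)
        gamma_bar = gamma_hat.mean()
        t2 = gamma_hat.var(ddof=1)
        d_mean = delta_hat.mean()
        d_var = delta_hat.var(ddof=1)
        # degenerate (all genes identical) priors: no shrinkage possible
        if t2 < 1e-12 or d_var < 1e-12:
            gamma_star, delta_star = gamma_hat, np.maximum(delta_hat, 1e-12)
        else:
            aprior = (2 * d_var + d_mean**2) / d_var
            bprior = (d_mean * d_var + d_mean**3) / d_var
            gamma_star = gamma_hat.copy()
            delta_star = delta_hat.copy()
            for _ in range(max_iter):
                g_new = (nb * t2 * gamma_hat + delta_star * gamma_bar) / (
                    nb * t2 + delta_star
                )
                sum2 = ((Zb - g_new[:, None]) ** 2).sum(axis=1)
                d_new = (0.5 * sum2 + bprior) / (nb / 2.0 + aprior - 1.0)
                change = max(
                    np.abs(g_new - gamma_star).max(), np.abs(d_new - delta_star).max()
                )
                gamma_star, delta_star = g_new, d_new
                if change < tol:
                    break
        Z_adj[:, ix] = (Zb - gamma_star[:, None]) / np.sqrt(delta_star)[:, None]

    corrected = Z_adj * sd + stand_mean
    values = pd.DataFrame(corrected, index=m.values.index, columns=m.values.columns)
    return ExpressionMatrix(values, m.detected.copy(), m.sample_meta.copy())


def standardize(m: ExpressionMatrix, axis: str = "gene") -> ExpressionMatrix:
    """Standardize each vector along ``axis`` ("gene" rows or "sample"
    columns) to mean 0 / sd 1 (denominator n-1)."""
    if axis not in ("gene", "sample"):
        raise PreprocessError("axis must be 'gene' or 'sample'")
    X = m.values.to_numpy()
    ax = 1 if axis == "gene" else 0
    mu = X.mean(axis=ax, keepdims=True)
    sd = X.std(axis=ax, ddof=1, keepdims=True)
    flat_sd = sd.ravel()
    if np.any(flat_sd == 0):
        ids = m.feature_ids if axis == "gene" else m.sample_ids
        bad = [ids[i] for i in np.flatnonzero(flat_sd == 0)]
        raise PreprocessError(f"constant vectors cannot be standardized: {bad[:5]}")
    Z = (X - mu) / sd
    values = pd.DataFrame(Z, index=m.values.index, columns=m.values.columns)
    return ExpressionMatrix(values, m.detected.copy(), m.sample_meta.copy())
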