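"""Single-gene differential expression.

Moderated two-sample t-statistics with empirical-Bayes variance shrinkage,
a fold-change + FDR filter for calling differential expression, Fisher
over-representation of gene classes, and a label-permutation test for the
aggregate behaviour of a gene set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .enrichment import bh_adjust
from .preprocess import ExpressionMatrix


class DiffExprError(ValueError):
    pass


@dataclass
class ShrinkageParams:
    """Prior degrees of freedom (may be ``inf``) and prior variance of the
    gene-wise variance distribution."""

    prior_df: float
    prior_var: float

    def __post_init__(self) -> None:
        if self.prior_df < 0:
            raise DiffExprError("prior_df must be >= 0")
        if self.prior_var <= 0:
            raise DiffExprError("prior_var must be > 0")


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y (Newton iteration)."""
    if x <= 0:
        return math.inf
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def estimate_shrinkage(sample_vars: Sequence[float], residual_df: float) -> ShrinkageParams:
    """Method-of-moments fit of a scaled F distribution to gene-wise sample
    variances: log variances have mean/variance matching
    ``log(s0^2 F(d, d0))``. Returns ``d0 = inf`` when the spread of the log
    variances does not exceed the theoretical trigamma(d/2) floor."""
    v = np.asarray(sample_vars, dtype=float)
    if v.size < 10:
        raise DiffExprError("need at least 10 genes to estimate shrinkage")
    if residual_df < 1:
        raise DiffExprError("residual_df must be >= 1")
    if np.any(v <= 0):
        raise DiffExprError("sample variances must be positive")
    z = np.log(v)
    e = z - special.digamma(residual_df / 2.0) + math.log(residual_df / 2.0)
    if z.var(ddof=1) < 1e-15:
        # degenerate: every gene has the same variance
        return ShrinkageParams(prior_df=math.inf, prior_var=float(np.exp(z.mean())))
    excess = z.var(ddof=1) - special.polygamma(1, residual_df / 2.0)
    if excess <= 0:
        return ShrinkageParams(prior_df=math.inf, prior_var=float(np.exp(e.mean())))
    d0 = 2.0 * _trigamma_inverse(float(excess))
    s0_sq = float(
        np.exp(e.mean() + special.digamma(d0 / 2.0) - math.log(d0 / 2.0))
    )
    return ShrinkageParams(prior_df=d0, prior_var=s0_sq)


def _group_arrays(
    m: ExpressionMatrix, groups: Mapping[str, str] | pd.Series | None
) -> tuple[np.ndarray, np.ndarray]:
    if groups is None:
        labels = m.sample_meta["group"]
    else:
        labels = pd.Series({s: groups[s] for s in m.sample_ids}).loc[m.sample_ids]
    case_ix = np.flatnonzero((labels == "case").to_numpy())
    ctrl_ix = np.flatnonzero((labels == "control").to_numpy())
    return case_ix, ctrl_ix


def _moderated_stats(
    X: np.ndarray, case_ix: np.ndarray, ctrl_ix: np.ndarray, params: ShrinkageParams | None
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray, ShrinkageParams]:
    n1, n2 = len(case_ix), len(ctrl_ix)
    mean_case = X[:, case_ix].mean(axis=1)
    mean_ctrl = X[:, ctrl_ix].mean(axis=1)
    ss1 = ((X[:, case_ix] - mean_case[:, None]) ** 2).sum(axis=1)
    ss2 = ((X[:, ctrl_ix] - mean_ctrl[:, None]) ** 2).sum(axis=1)
    d = n1 + n2 - 2
    s_sq = (ss1 + ss2) / d
    if params is None:
        params = estimate_shrinkage(np.maximum(s_sq, 1e-300), d)
    d0, s0_sq = params.prior_df, params.prior_var
    if math.isinf(d0):
        s_tilde_sq = np.full_like(s_sq, s0_sq)
    else:
        s_tilde_sq = (d0 * s0_sq + d * s_sq) / (d0 + d)
    se = np.sqrt(s_tilde_sq * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        mod_t = (mean_case - mean_ctrl) / se
        ord_t = (mean_case - mean_ctrl) / np.sqrt(s_sq * (1.0 / n1 + 1.0 / n2))
    total_df = d0 + d
    if math.isinf(total_df):
        p = 2.0 * stats.norm.sf(np.abs(mod_t))
    else:
        p = 2.0 * stats.t.sf(np.abs(mod_t), df=total_df)
    return mean_case, mean_ctrl, ord_t, mod_t, p, params


def moderated_t_test(
    m: ExpressionMatrix,
    groups: Mapping[str, str] | pd.Series | None = None,
    params: ShrinkageParams | str = "auto",
) -> pd.DataFrame:
    """Per-gene moderated t-test of case vs control.

    Returns a dataframe indexed by gene with columns ``mean_case``,
    ``mean_control``, ``log2_fold_change``, ``ordinary_t``, ``moderated_t``,
    ``raw_p``, ``adjusted_p`` (BH across genes) and ``is_DEG`` (False until
    :func:`fold_change_filter` is applied).
    """
    case_ix, ctrl_ix = _group_arrays(m, groups)
    if len(case_ix) < 2 or len(ctrl_ix) < 2:
        raise DiffExprError("each group needs at least 2 samples")
    fit_params = None if params == "auto" else params
    X = m.values.to_numpy()
    mean_case, mean_ctrl, ord_t, mod_t, p, used = _moderated_stats(
        X, case_ix, ctrl_ix, fit_params
    )
    table = pd.DataFrame(
        {
            "mean_case": mean_case,
            "mean_control": mean_ctrl,
            "log2_fold_change": mean_case - mean_ctrl,
            "ordinary_t": ord_t,
            "moderated_t": mod_t,
            "raw_p": p,
            "adjusted_p": bh_adjust(p),
            "is_DEG": False,
        },
        index=m.feature_ids,
    )
    table.attrs["shrinkage"] = used
    return table


def fold_change_filter(
    stats_table: pd.DataFrame, min_ratio: float = 1.5, fdr_level: float = 0.05
) -> frozenset:
    """Flag genes as differentially expressed when BH-adjusted p <= fdr and
    |log2 fold change| >= log2(min_ratio); returns the DEG gene set."""
    if min_ratio < 1:
        raise DiffExprError("min_ratio must be >= 1")
    is_deg = (stats_table["adjusted_p"] <= fdr_level) & (
        stats_table["log2_fold_change"].abs() >= math.log2(min_ratio)
    )
    stats_table["is_DEG"] = is_deg
    return frozenset(stats_table.index[is_deg])


def fisher_overrep(
    overlap: int, class_size: int, selected: int, universe: int
) -> tuple[float, float]:
    """One-sided (greater) Fisher/hypergeometric test of class
    over-representation in a selection; returns (odds_ratio, p)."""
    if overlap > min(class_size, selected):
        raise DiffExprError("overlap exceeds a margin")
    if class_size > universe or selected > universe:
        raise DiffExprError("margins exceed the universe")
    a = overlap
    b = class_size - overlap
    c = selected - overlap
    d = universe - class_size - selected + overlap
    if d < 0:
        raise DiffExprError("inconsistent margins")
    p = float(stats.hypergeom.sf(overlap - 1, universe, class_size, selected))
    aa, bb, cc, dd = (a, b, c, d)
    if min(aa, bb, cc, dd) == 0:
        aa, bb, cc, dd = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (aa * dd) / (bb * cc), p


def gene_set_label_permutation_test(
    m: ExpressionMatrix,
    groups: Mapping[str, str] | pd.Series | None,
    gene_set: Iterable,
    n_perm: int = 10000,
    rng_seed: int = 0,
) -> float:
    """Permutation p-value for the mean moderated t-statistic of a gene set.

    The case/control labels are permuted ``n_perm`` times; the two-sided
    p-value is ``(1 + #{|null| >= |observed|}) / (n_perm + 1)``.
    """
    if n_perm < 1:
        raise DiffExprError("n_perm must be >= 1")
    genes = [g for g in gene_set if g in m.values.index]
    if not genes:
        raise DiffExprError("gene_set is disjoint from the matrix")
    case_ix, ctrl_ix = _group_arrays(m, groups)
    if len(case_ix) < 2 or len(ctrl_ix) < 2:
        raise DiffExprError("each group needs at least 2 samples")
    X = m.values.to_numpy()
    set_rows = np.array([m.feature_ids.index(g) for g in genes])

    def set_stat(cix: np.ndarray, kix: np.ndarray) -> float:
        *_, mod_t, _p, _ = _moderated_stats(X, cix, kix, None)
        return float(mod_t[set_rows].mean())

    observed = set_stat(case_ix, ctrl_ix)
    rng = np.random.default_rng(rng_seed)
    n1 = len(case_ix)
    all_ix = np.concatenate([case_ix, ctrl_ix])
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(all_ix)
        null = set_stat(perm[:n1], perm[n1:])
        if abs(null) >= abs(observed):
            exceed += 1
    return (1 + exceed) / (n_perm + 1)
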