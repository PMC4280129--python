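"""Per-tissue SDE calling: three criteria on log2 expression values.

A probeset is called sexually dimorphically expressed (SDE) in a tissue
when all of the following hold, with strict inequalities:

1. the mean log2 expression exceeds a background floor (default 6.65)
   in at least one sex;
2. the absolute between-sex difference of mean log2 values exceeds 1
   (i.e. more than two-fold on the linear scale);
3. the Benjamini-Hochberg adjusted p-value of a pooled-variance
   two-sample Student t-test is below 0.05.

Means are taken of log-scale values (not of linear intensities), and
the log-ratio sign convention is male minus female throughout: positive
differences are male-biased.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats as _sps

from dimorph.io_formats import Dataset

__all__ = [
    "SdeCriteria",
    "TTestResult",
    "group_means",
    "student_t_two_tailed",
    "bh_fdr",
    "call_sde_tissue",
    "call_sde_all",
]


@dataclass(frozen=True)
class SdeCriteria:
    """Thresholds of the three-part SDE definition.

    expr_threshold: log2 background floor a sex mean must exceed.
    min_abs_log2_diff: minimum |mean_m - mean_f| in log2 units
        (1.0 == two-fold).
    max_q: BH-adjusted significance level.
    """

    expr_threshold: float = 6.65
    min_abs_log2_diff: float = 1.0
    max_q: float = 0.05

    def __post_init__(self) -> None:
        if not np.isfinite(self.expr_threshold):
            raise ValueError("expr_threshold must be finite")
        if self.min_abs_log2_diff < 0:
            raise ValueError("min_abs_log2_diff must be >= 0")
        if not (0 < self.max_q <= 1):
            raise ValueError("max_q must be in (0, 1]")


def group_means(matrix: pd.DataFrame, columns: list[str]) -> pd.Series:
    """Arithmetic mean of log2 values per probeset over ``columns``."""
    if len(columns) == 0:
        raise ValueError("group is empty")
    return matrix[list(columns)].mean(axis=1)


@dataclass
class TTestResult:
    """Pooled-variance two-sample t-test output.

    ``degenerate`` flags rows where the pooled variance is zero with
    unequal means (p is reported as 0 there rather than failing, so
    noise-free synthetic data can flow through the pipeline).
    """

    t_stat: np.ndarray
    p_value: np.ndarray
    degenerate: np.ndarray


def student_t_two_tailed(group_m, group_f) -> TTestResult:
    """Classical (equal-variance) Student t-test, two-tailed.

    Accepts 1-D value vectors or 2-D arrays with samples on the last
    axis (rows are tested independently). df = n_m + n_f - 2. Zero
    pooled variance yields t=0, p=1 when the means are equal and
    t=+/-inf, p=0 with the degenerate flag set otherwise.
    """
    a = np.atleast_2d(np.asarray(group_m, dtype=float))
    b = np.atleast_2d(np.asarray(group_f, dtype=float))
    n_m, n_f = a.shape[-1], b.shape[-1]
    if n_m < 2 or n_f < 2:
        raise ValueError(f"each group needs >=2 values (got {n_m} and {n_f})")
    mean_m = a.mean(axis=-1)
    mean_f = b.mean(axis=-1)
    ss = ((a - mean_m[..., None]) ** 2).sum(axis=-1) + ((b - mean_f[..., None]) ** 2).sum(axis=-1)
    df = n_m + n_f - 2
    pooled_var = ss / df
    se = np.sqrt(pooled_var * (1.0 / n_m + 1.0 / n_f))
    diff = mean_m - mean_f
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    zero_se = se == 0
    degenerate = zero_se & (diff != 0)
    t = np.where(zero_se & (diff == 0), 0.0, t)
    with np.errstate(invalid="ignore"):
        t = np.where(degenerate, np.sign(diff) * np.inf, t)
    p = 2.0 * _sps.t.sf(np.abs(t), df)
    p = np.where(zero_se & (diff == 0), 1.0, p)
    p = np.where(degenerate, 0.0, p)
    squeeze = np.asarray(group_m).ndim == 1
    if squeeze:
        return TTestResult(t[0], p[0], degenerate[0])
    return TTestResult(t, p, degenerate)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, in input order.

    q_(i) = min_{j>=i}(p_(j) * m / j), clipped to 1. NaN p-values are
    propagated as NaN q-values and excluded from the test count m.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("bh_fdr expects a 1-D vector")
    nan = np.isnan(p)
    valid = p[~nan]
    if ((valid < 0) | (valid > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = valid.size
    q = np.full(p.shape, np.nan)
    if m:
        order = np.argsort(valid, kind="stable")
        ranked = valid[order] * m / np.arange(1, m + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        adj = np.empty(m)
        adj[order] = np.minimum(ranked, 1.0)
        q[~nan] = adj
    return q


def _bias_labels(log2_diff: np.ndarray, sde: np.ndarray) -> np.ndarray:
    bias = np.where(log2_diff > 0, "male", "female")
    return np.where(sde, bias, "none")


def call_sde_tissue(
    dataset: Dataset,
    tissue: str,
    criteria: SdeCriteria = SdeCriteria(),
    bh_scope: str = "all",
    welch: bool = False,
) -> pd.DataFrame:
    """Apply the three SDE criteria to one tissue.

    Returns one row per probeset: means per sex, log2 difference
    (male - female), t, p, BH q, expression flags, the sde call and the
    bias label. ``bh_scope`` selects the BH test universe: "all"
    probesets with a computable p (default), or "expressed" restricting
    the correction to probesets passing the expression floor in this
    tissue (non-expressed q is then NaN). ``welch=True`` substitutes the
    unequal-variance t-test.
    """
    if bh_scope not in ("all", "expressed"):
        raise ValueError("bh_scope must be 'all' or 'expressed'")
    cols_m = dataset.group_columns(tissue, "M")
    cols_f = dataset.group_columns(tissue, "F")
    vals_m = dataset.matrix[cols_m].to_numpy()
    vals_f = dataset.matrix[cols_f].to_numpy()
    mean_m = vals_m.mean(axis=1)
    mean_f = vals_f.mean(axis=1)
    if welch:
        t_stat, p_value = _sps.ttest_ind(vals_m, vals_f, axis=1, equal_var=False)
        degenerate = np.zeros(mean_m.shape, dtype=bool)
        p_value = np.asarray(p_value)
        bad = ~np.isfinite(p_value)
        p_value[bad & (mean_m == mean_f)] = 1.0
        p_value[bad & (mean_m != mean_f)] = 0.0
        degenerate = bad & (mean_m != mean_f)
    else:
        res = student_t_two_tailed(vals_m, vals_f)
        t_stat, p_value, degenerate = res.t_stat, res.p_value, res.degenerate
    log2_diff = mean_m - mean_f
    expressed_m = mean_m > criteria.expr_threshold
    expressed_f = mean_f > criteria.expr_threshold
    expressed = expressed_m | expressed_f
    if bh_scope == "expressed":
        p_for_bh = np.where(expressed, p_value, np.nan)
        q_value = bh_fdr(p_for_bh)
    else:
        q_value = bh_fdr(p_value)
    sde = (
        expressed
        & (np.abs(log2_diff) > criteria.min_abs_log2_diff)
        & (q_value < criteria.max_q)
    )
    out = pd.DataFrame(
        {
            "tissue": tissue,
            "mean_m": mean_m,
            "mean_f": mean_f,
            "log2_diff": log2_diff,
            "t_stat": t_stat,
            "p_value": p_value,
            "q_value": q_value,
            "expressed_m": expressed_m,
            "expressed_f": expressed_f,
            "expressed": expressed,
            "sde": sde,
            "bias": _bias_labels(log2_diff, sde),
            "degenerate_variance": degenerate,
        },
        index=dataset.matrix.index.copy(),
    )
    out.index.name = "probeset_id"
    return out


def call_sde_all(
    dataset: Dataset,
    criteria: SdeCriteria = SdeCriteria(),
    bh_scope: str = "all",
    welch: bool = False,
) -> dict[str, pd.DataFrame]:
    """Per-tissue SDE calls for every tissue in the dataset.

    Each tissue is analysed independently; BH is applied within each
    tissue. Tissues lacking two samples of either sex are reported
    together in a single error.
    """
    bad = []
    for tissue in dataset.tissues:
        for sex in ("M", "F"):
            if len(dataset.groups.get((tissue, sex), [])) < 2:
                bad.append(tissue)
                break
    if bad:
        raise ValueError(f"tissues without >=2 samples per sex: {bad}")
    return {
        tissue: call_sde_tissue(dataset, tissue, criteria, bh_scope=bh_scope, welch=welch)
        for tissue in dataset.tissues
    }
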