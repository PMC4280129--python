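"""Validation checks that a tissue's SDE signal is biological rather
than artefactual.

Three complementary checks, all built on a tissue's SDE probeset
subset: (1) every unordered sample pair's Pearson correlation over
per-probeset-centered values, contrasted between same-sex and
cross-sex pairs; (2) hierarchical clustering of samples with a perfect
sex-segregation flag; (3) concordance of log2 fold differences with
other tissues (a genuine signal is attenuated-but-correlated in
adjacent tissue, uncorrelated in unrelated tissue).

Centering matters: raw log2 profiles of any two arrays correlate near
1 through the shared expression-level structure, so correlations are
taken after subtracting each probeset's mean across the tissue's
samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy as _h
from scipy.spatial.distance import pdist

from dimorph.io_formats import Dataset
from dimorph.sde_calling import student_t_two_tailed

__all__ = [
    "pairwise_sample_correlations",
    "sex_separation_test",
    "SexSeparation",
    "cross_tissue_concordance",
    "sample_cluster_check",
]


def _tissue_submatrix(
    dataset: Dataset, tissue: str, probeset_subset: Iterable[str]
) -> tuple[pd.DataFrame, pd.Series]:
    subset = list(probeset_subset)
    if len(subset) < 3:
        raise ValueError("need >=3 probesets for stable correlations")
    cols = dataset.group_columns(tissue, "M") + dataset.group_columns(tissue, "F")
    if len(cols) < 2:
        raise ValueError(f"tissue {tissue!r} has <2 samples")
    sub = dataset.matrix.loc[subset, cols]
    sex = dataset.annotation.set_index("sample_id").loc[cols, "sex"]
    centered = sub.sub(sub.mean(axis=1), axis=0)
    return centered, sex


def pairwise_sample_correlations(
    dataset: Dataset, tissue: str, probeset_subset: Iterable[str]
) -> pd.DataFrame:
    """Pearson r for every unordered pair of the tissue's samples.

    Values are per-probeset mean-centered across the tissue before
    correlating. Returns n*(n-1)/2 rows: sample_a, sample_b, same_sex,
    r.
    """
    centered, sex = _tissue_submatrix(dataset, tissue, probeset_subset)
    samples = list(centered.columns)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(centered.to_numpy().T)
    rows = []
    for i in range(len(samples)):
        for j in range(i + 1, len(samples)):
            rows.append(
                {
                    "sample_a": samples[i],
                    "sample_b": samples[j],
                    "same_sex": sex.iloc[i] == sex.iloc[j],
                    "r": corr[i, j],
                }
            )
    return pd.DataFrame(rows)


@dataclass
class SexSeparation:
    mean_same: float
    sd_same: float
    mean_cross: float
    sd_cross: float
    t_stat: float
    p_value: float


def sex_separation_test(correlations: pd.DataFrame) -> SexSeparation:
    """Student t-test contrasting same-sex vs cross-sex pair correlations."""
    same = correlations.loc[correlations["same_sex"], "r"].to_numpy()
    cross = correlations.loc[~correlations["same_sex"], "r"].to_numpy()
    if same.size < 2 or cross.size < 2:
        raise ValueError("need >=2 same-sex and >=2 cross-sex pairs")
    res = student_t_two_tailed(same, cross)
    return SexSeparation(
        mean_same=float(same.mean()),
        sd_same=float(same.std(ddof=1)),
        mean_cross=float(cross.mean()),
        sd_cross=float(cross.std(ddof=1)),
        t_stat=float(res.t_stat),
        p_value=float(res.p_value),
    )


def cross_tissue_concordance(
    stats_ref: pd.DataFrame, stats_other: pd.DataFrame
) -> tuple[float, float]:
    """Fold-difference concordance of another tissue with a reference.

    Over the reference tissue's SDE probesets: Pearson r between the
    two tissues' log2_diff values, and the fraction with matching sign
    (zero differences in the other tissue count as disagreement).
    The reference against itself gives (1.0, 1.0).
    """
    sde_ids = stats_ref.index[stats_ref["sde"].astype(bool)]
    if len(sde_ids) == 0:
        raise ValueError("reference tissue has no SDE probesets")
    missing = sde_ids.difference(stats_other.index)
    if len(missing):
        raise ValueError(f"other tissue lacks reference SDE probesets: {list(missing[:5])}")
    x = stats_ref.loc[sde_ids, "log2_diff"].to_numpy(dtype=float)
    y = stats_other.loc[sde_ids, "log2_diff"].to_numpy(dtype=float)
    if np.array_equal(x, y):
        return 1.0, 1.0
    if x.std() == 0 or y.std() == 0:
        r = float("nan")
    else:
        r = float(np.corrcoef(x, y)[0, 1])
    sign_agreement = float(np.mean(np.sign(x) == np.sign(y)))
    return r, sign_agreement


def sample_cluster_check(
    dataset: Dataset,
    tissue: str,
    probeset_subset: Iterable[str],
    method: str = "ward",
) -> tuple[np.ndarray, bool]:
    """Hierarchically cluster a tissue's samples on a probeset subset.

    Returns the scipy linkage matrix and a flag that is True iff
    cutting the tree into two clusters separates males from females
    perfectly.
    """
    centered, sex = _tissue_submatrix(dataset, tissue, probeset_subset)
    n_m = (sex == "M").sum()
    n_f = (sex == "F").sum()
    if n_m < 2 or n_f < 2:
        raise ValueError("need >=2 samples per sex")
    X = centered.to_numpy().T
    linkage = _h.linkage(pdist(X), method=method)
    labels = _h.fcluster(linkage, t=2, criterion="maxclust")
    sexes = sex.to_numpy()
    segregated = len(set(labels[sexes == "M"])) == 1 and len(set(labels[sexes == "F"])) == 1 and (
        labels[sexes == "M"][0] != labels[sexes == "F"][0]
    )
    return linkage, bool(segregated)
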