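"""Cross-tissue aggregation of per-tissue SDE calls.

Builds per-probeset profiles (expression breadth, SDE tissue set, bias
class), the tissue-count distribution by bias class, per-tissue
incidence tables with expression-breadth splits, ubiquitous-SDE
detection, and breadth statistics contrasting SDE with non-SDE
probesets. "Expressed in a tissue" always means the mean log2 value
exceeds the background floor in at least one sex in that tissue — the
same definition criterion 1 of the SDE call uses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from dimorph.io_formats import Dataset
from dimorph.sde_calling import SdeCriteria, call_sde_all

__all__ = [
    "CrossTissueProfiles",
    "build_profiles",
    "profiles_from_incidence",
    "tissue_count_distribution",
    "distribution_summary",
    "identify_ubiquitous_sde",
    "per_tissue_incidence",
    "breadth_statistics",
    "expression_summary",
    "gene_profile",
]

BIAS_CLASSES = ("always_male", "always_female", "opposite", "none")


@dataclass
class CrossTissueProfiles:
    """Per-probeset cross-tissue summary in matrix form.

    expressed / sde: boolean probeset x tissue frames; bias: int8 frame
    (+1 male-biased SDE, -1 female-biased SDE, 0 otherwise). All three
    share index and columns.
    """

    expressed: pd.DataFrame
    sde: pd.DataFrame
    bias: pd.DataFrame

    def __post_init__(self) -> None:
        for name, frame in (("sde", self.sde), ("bias", self.bias)):
            if not frame.index.equals(self.expressed.index) or not frame.columns.equals(
                self.expressed.columns
            ):
                raise ValueError(f"{name} frame not aligned with expressed frame")
        if (self.sde & ~self.expressed).any().any():
            raise ValueError("sde flags outside expressed tissues")

    @property
    def tissues(self) -> list[str]:
        return list(self.expressed.columns)

    @property
    def probesets(self) -> pd.Index:
        return self.expressed.index

    @property
    def n_expressed(self) -> pd.Series:
        return self.expressed.sum(axis=1)

    @property
    def n_sde(self) -> pd.Series:
        return self.sde.sum(axis=1)

    @property
    def bias_class(self) -> pd.Series:
        """always_male / always_female / opposite / none per probeset."""
        any_m = (self.bias == 1).any(axis=1)
        any_f = (self.bias == -1).any(axis=1)
        out = np.select(
            [any_m & any_f, any_m, any_f],
            ["opposite", "always_male", "always_female"],
            default="none",
        )
        return pd.Series(out, index=self.probesets, name="bias_class")

    def sde_tissue_sets(self) -> pd.Series:
        """Series of frozensets of SDE tissues per probeset."""
        cols = np.asarray(self.tissues)
        mask = self.sde.to_numpy()
        return pd.Series(
            [frozenset(cols[row]) for row in mask], index=self.probesets, name="sde_tissues"
        )


def build_profiles(all_stats: Mapping[str, pd.DataFrame]) -> CrossTissueProfiles:
    """Assemble profiles from per-tissue statistics tables.

    All tissues must share one probeset universe (same ids); column
    order follows the mapping's iteration order.
    """
    if not all_stats:
        raise ValueError("no per-tissue statistics supplied")
    tissues = list(all_stats)
    base = all_stats[tissues[0]].index
    for tissue in tissues[1:]:
        idx = all_stats[tissue].index
        if len(idx) != len(base) or not base.sort_values().equals(idx.sort_values()):
            raise ValueError(f"probeset universe of tissue {tissue!r} differs")
    expressed = pd.DataFrame(index=base.copy())
    sde = pd.DataFrame(index=base.copy())
    bias = pd.DataFrame(index=base.copy())
    for tissue in tissues:
        df = all_stats[tissue].reindex(base)
        expressed[tissue] = df["expressed"].astype(bool)
        sde[tissue] = df["sde"].astype(bool)
        bias[tissue] = np.where(
            df["sde"], np.where(df["log2_diff"] > 0, 1, -1), 0
        ).astype(np.int8)
    return CrossTissueProfiles(expressed=expressed, sde=sde, bias=bias)


def profiles_from_incidence(
    incidence: pd.DataFrame, expressed: pd.DataFrame | None = None
) -> CrossTissueProfiles:
    """Build profiles from a signed incidence matrix (+1/-1/0).

    Useful for supplementary-table recomputation where only the SDE
    incidence (not the full statistics) is available. When no expressed
    frame is given, expression defaults to the SDE cells themselves.
    """
    bias = incidence.astype(np.int8)
    sde = bias != 0
    if expressed is None:
        expressed = sde.copy()
    else:
        expressed = expressed.astype(bool) | sde
    return CrossTissueProfiles(expressed=expressed, sde=sde, bias=bias)


def tissue_count_distribution(profiles: CrossTissueProfiles) -> pd.DataFrame:
    """Counts of SDE probesets by (number of SDE tissues, bias class).

    Rows are k >= 1 (only values of k that occur); columns always_male,
    always_female, opposite, total. The opposite column is <NA> on the
    k=1 row, where it is not applicable. Empty when nothing is SDE.
    """
    n_sde = profiles.n_sde
    cls = profiles.bias_class
    mask = n_sde >= 1
    if not mask.any():
        return pd.DataFrame(
            columns=["always_male", "always_female", "opposite", "total"],
            index=pd.Index([], name="n_tissues_sde"),
            dtype="Int64",
        )
    tab = (
        pd.crosstab(n_sde[mask], cls[mask])
        .reindex(columns=["always_male", "always_female", "opposite"], fill_value=0)
        .astype("Int64")
    )
    tab.index.name = "n_tissues_sde"
    tab["total"] = tab.sum(axis=1)
    if 1 in tab.index:
        tab.loc[1, "opposite"] = pd.NA
    return tab


def distribution_summary(distribution: pd.DataFrame) -> dict[str, float]:
    """Headline numbers derived from the tissue-count distribution.

    Returns total SDE probesets, the single-tissue count and its
    fraction of the total, the multi-tissue (k >= 2) count, the count
    oppositely biased among multi-tissue probesets and its fraction,
    and per-class totals. Fractions are NaN for empty denominators.
    """
    if distribution.empty:
        return {
            "n_sde_total": 0,
            "n_single": 0,
            "frac_single": float("nan"),
            "n_multi": 0,
            "n_opposite_multi": 0,
            "frac_opposite_multi": float("nan"),
            "n_always_male": 0,
            "n_always_female": 0,
            "n_opposite": 0,
        }
    total = int(distribution["total"].sum())
    single = int(distribution.loc[1, "total"]) if 1 in distribution.index else 0
    multi_rows = distribution.loc[distribution.index >= 2]
    n_multi = int(multi_rows["total"].sum())
    n_opp_multi = int(multi_rows["opposite"].fillna(0).sum())
    return {
        "n_sde_total": total,
        "n_single": single,
        "frac_single": single / total if total else float("nan"),
        "n_multi": n_multi,
        "n_opposite_multi": n_opp_multi,
        "frac_opposite_multi": n_opp_multi / n_multi if n_multi else float("nan"),
        "n_always_male": int(distribution["always_male"].sum()),
        "n_always_female": int(distribution["always_female"].sum()),
        "n_opposite": int(distribution["opposite"].fillna(0).sum()),
    }


def identify_ubiquitous_sde(
    profiles: CrossTissueProfiles, majority_fraction: float = 0.5
) -> pd.DataFrame:
    """Probesets SDE in a strict majority of tissues.

    A probeset qualifies when n_sde > majority_fraction * n_tissues.
    These ubiquitously dimorphic probesets (Xist-like female-exclusive,
    Eif2s3y-like male-exclusive) dominate sharing and clustering
    analyses and are excluded from them by default. Returns a frame
    with n_sde, consistent_bias (single direction across all SDE
    tissues) and that direction.
    """
    n_tissues = len(profiles.tissues)
    hit = profiles.n_sde > majority_fraction * n_tissues
    ids = profiles.probesets[hit]
    bias = profiles.bias.loc[ids]
    any_m = (bias == 1).any(axis=1)
    any_f = (bias == -1).any(axis=1)
    direction = np.select([any_m & ~any_f, any_f & ~any_m], ["male", "female"], default="mixed")
    return pd.DataFrame(
        {
            "n_sde": profiles.n_sde[hit],
            "consistent_bias": ~(any_m & any_f),
            "direction": direction,
        },
        index=ids,
    )


def per_tissue_incidence(
    profiles: CrossTissueProfiles, exclude: Iterable[str] = ()
) -> pd.DataFrame:
    """Per-tissue SDE incidence with expression-breadth splits.

    For every tissue: male/female SDE totals over non-excluded
    probesets, the subsets expressed in this tissue only
    (single-tissue, single-sex genes) and expressed in all tissues
    (ubiquitous elsewhere), and the number of excluded (ubiquitous-SDE)
    probesets that are SDE here. Sorted by total SDE count, descending.
    """
    exclude = pd.Index(sorted(set(exclude)))
    keep = ~profiles.probesets.isin(exclude)
    bias = profiles.bias.loc[keep]
    n_expr = profiles.n_expressed[keep]
    single = n_expr == 1
    ubiq = n_expr == len(profiles.tissues)
    rows = []
    for tissue in profiles.tissues:
        b = bias[tissue]
        is_m = b == 1
        is_f = b == -1
        excluded_here = profiles.sde.loc[~keep, tissue]
        rows.append(
            {
                "tissue": tissue,
                "n_sde_male": int(is_m.sum()),
                "n_sde_female": int(is_f.sum()),
                "n_single_tissue_male": int((is_m & single).sum()),
                "n_single_tissue_female": int((is_f & single).sum()),
                "n_ubiquitous_elsewhere_male": int((is_m & ubiq).sum()),
                "n_ubiquitous_elsewhere_female": int((is_f & ubiq).sum()),
                "n_excluded_ubiquitous_sde": int(excluded_here.sum()),
            }
        )
    out = pd.DataFrame(rows).set_index("tissue")
    out["n_sde_total"] = out["n_sde_male"] + out["n_sde_female"]
    return out.sort_values("n_sde_total", ascending=False)


def breadth_statistics(profiles: CrossTissueProfiles) -> dict[str, float]:
    """Expression-breadth contrasts between SDE and non-SDE probesets.

    Universe: probesets expressed in >=1 tissue. Reports the fraction
    expressed in all tissues and in exactly one tissue, separately for
    SDE (>=1 tissue) and non-SDE probesets, plus the SDE rate among
    ubiquitously expressed vs other expressed probesets. Empty classes
    yield NaN rather than an error.
    """
    n_expr = profiles.n_expressed
    expressed_any = n_expr >= 1
    is_sde = profiles.n_sde >= 1
    n_tissues = len(profiles.tissues)

    def _frac(num: int, den: int) -> float:
        return num / den if den else float("nan")

    sde = expressed_any & is_sde
    non = expressed_any & ~is_sde
    all_t = n_expr == n_tissues
    one_t = n_expr == 1
    return {
        "frac_all_tissues_sde": _frac(int((sde & all_t).sum()), int(sde.sum())),
        "frac_all_tissues_non_sde": _frac(int((non & all_t).sum()), int(non.sum())),
        "frac_single_tissue_sde": _frac(int((sde & one_t).sum()), int(sde.sum())),
        "frac_single_tissue_non_sde": _frac(int((non & one_t).sum()), int(non.sum())),
        "sde_rate_ubiquitous": _frac(int((all_t & is_sde).sum()), int(all_t.sum())),
        "sde_rate_non_ubiquitous": _frac(
            int((expressed_any & ~all_t & is_sde).sum()), int((expressed_any & ~all_t).sum())
        ),
    }


def expression_summary(profiles: CrossTissueProfiles) -> dict[str, float]:
    """Chip-level expression and SDE counts.

    n_probesets on the chip, the number expressed above background in
    >=1 tissue/sex and its percentage, and the number SDE in >=1 tissue
    with its percentage of the expressed set.
    """
    n_total = len(profiles.probesets)
    n_expr = int((profiles.n_expressed >= 1).sum())
    n_sde = int((profiles.n_sde >= 1).sum())
    return {
        "n_probesets": n_total,
        "n_expressed": n_expr,
        "pct_expressed": 100.0 * n_expr / n_total if n_total else float("nan"),
        "n_sde": n_sde,
        "pct_sde_of_expressed": 100.0 * n_sde / n_expr if n_expr else float("nan"),
    }


def gene_profile(
    dataset: Dataset,
    probeset_id: str,
    criteria: SdeCriteria = SdeCriteria(),
    all_stats: Mapping[str, pd.DataFrame] | None = None,
) -> pd.DataFrame:
    """Per-tissue, per-sex expression profile of one probeset.

    Ordered rows of (mean_m, mean_f, sde, bias) per tissue, suitable
    for bar plotting against the expression floor. SDE flags come from
    the full per-tissue calls (pass ``all_stats`` to reuse ones already
    computed; q-values depend on the whole tissue, not just this row).
    """
    if probeset_id not in dataset.matrix.index:
        raise KeyError(f"unknown probeset {probeset_id!r}")
    if all_stats is None:
        all_stats = call_sde_all(dataset, criteria)
    rows = []
    for tissue, stats in all_stats.items():
        rec = stats.loc[probeset_id]
        rows.append(
            {
                "tissue": tissue,
                "mean_m": rec["mean_m"],
                "mean_f": rec["mean_f"],
                "sde": bool(rec["sde"]),
                "bias": rec["bias"],
            }
        )
    out = pd.DataFrame(rows).set_index("tissue")
    out.attrs["expr_threshold"] = criteria.expr_threshold
    out.attrs["probeset_id"] = probeset_id
    return out
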