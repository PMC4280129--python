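"""Two-way Ward clustering of male:female log-ratios and MA plots.

The ratio matrix holds each selected probeset's log2 male-minus-female
mean difference in every tissue — including tissues where it is not
called SDE, which is what lets the heatmap show cross-tissue patterns.
Rows default to probesets SDE in 1-4 tissues with the ubiquitous-SDE
set excluded (those rows would dominate the clustering). Colour is
globally normalized: one symmetric bound over all included cells.

MA coordinates: M = log2 male:female ratio (mean_m - mean_f), A = mean
average log2 expression of both sexes ((mean_m + mean_f)/2); the
transform is invertible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy as _h
from scipy.spatial.distance import pdist

from dimorph.cross_tissue import CrossTissueProfiles

__all__ = [
    "RatioMatrix",
    "build_ratio_matrix",
    "ward_cluster_2way",
    "TwoWayClustering",
    "linkage_to_newick",
    "ma_points",
    "plot_ratio_heatmap",
    "plot_ma",
]


@dataclass
class RatioMatrix:
    """Probeset x tissue log2-ratio matrix with its global colour bound."""

    values: pd.DataFrame
    color_bound: float


def build_ratio_matrix(
    all_stats: Mapping[str, pd.DataFrame],
    profiles: CrossTissueProfiles,
    exclude: Iterable[str] = (),
    min_tissues: int = 1,
    max_tissues: int = 4,
) -> RatioMatrix:
    """Select probesets SDE in min..max tissues and collect log2_diff.

    ``exclude`` removes the ubiquitous-SDE probesets. Raises on an
    empty selection.
    """
    n_sde = profiles.n_sde
    keep = (n_sde >= min_tissues) & (n_sde <= max_tissues)
    keep &= ~profiles.probesets.isin(set(exclude))
    ids = profiles.probesets[keep]
    if len(ids) == 0:
        raise ValueError("no probesets selected for the ratio matrix")
    data = {tissue: all_stats[tissue].loc[ids, "log2_diff"] for tissue in profiles.tissues}
    values = pd.DataFrame(data, index=ids)
    if not np.isfinite(values.to_numpy()).all():
        raise ValueError("ratio matrix contains non-finite values")
    return RatioMatrix(values=values, color_bound=float(np.abs(values.to_numpy()).max()))


@dataclass
class TwoWayClustering:
    row_order: list
    col_order: list
    row_linkage: np.ndarray
    col_linkage: np.ndarray


def ward_cluster_2way(ratio_matrix: RatioMatrix | pd.DataFrame) -> TwoWayClustering:
    """Ward-linkage clustering applied independently to rows and columns.

    Ward's variance-minimising criterion on Euclidean distances
    (the Ward.D2 convention: merge heights are root-mean increases in
    within-cluster sum of squares). Deterministic for a given input
    order; zero-distance ties resolve to the lower index first, and a
    constant matrix still clusters.
    """
    values = ratio_matrix.values if isinstance(ratio_matrix, RatioMatrix) else ratio_matrix
    if values.shape[0] < 2 or values.shape[1] < 2:
        raise ValueError("need >=2 rows and >=2 columns")
    X = values.to_numpy(dtype=float)
    row_linkage = _h.linkage(pdist(X), method="ward")
    col_linkage = _h.linkage(pdist(X.T), method="ward")
    row_order = [values.index[i] for i in _h.leaves_list(row_linkage)]
    col_order = [values.columns[i] for i in _h.leaves_list(col_linkage)]
    return TwoWayClustering(row_order, col_order, row_linkage, col_linkage)


def linkage_to_newick(linkage: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage as a Newick string with branch lengths."""
    tree = _h.to_tree(linkage)

    def _walk(node, parent_height: float) -> str:
        length = parent_height - (0.0 if node.is_leaf() else node.dist)
        if node.is_leaf():
            length = parent_height
            return f"{labels[node.id]}:{length:.6g}"
        left = _walk(node.left, node.dist)
        right = _walk(node.right, node.dist)
        return f"({left},{right}):{parent_height - node.dist:.6g}"

    return f"({_walk(tree.left, tree.dist)},{_walk(tree.right, tree.dist)});"


def ma_points(tissue_stats: pd.DataFrame, wide_sde_set: Iterable[str] = ()) -> pd.DataFrame:
    """MA-plot coordinates for one tissue's statistics table.

    m = mean_m - mean_f, a = (mean_m + mean_f)/2, with the tissue's sde
    flag and a wide_sde marker for probesets SDE in many tissues
    (conventionally more than 10) which are drawn with larger markers.
    """
    wide = set(wide_sde_set)
    out = pd.DataFrame(
        {
            "m": tissue_stats["mean_m"] - tissue_stats["mean_f"],
            "a": (tissue_stats["mean_m"] + tissue_stats["mean_f"]) / 2.0,
            "sde": tissue_stats["sde"].astype(bool),
            "wide_sde": tissue_stats.index.isin(sorted(wide)),
        },
        index=tissue_stats.index.copy(),
    )
    return out


# ---------------------------------------------------------------------------
# Figure rendering (matplotlib, Agg-safe)
# ---------------------------------------------------------------------------


def plot_ratio_heatmap(ratio_matrix: RatioMatrix, clustering: TwoWayClustering, path) -> None:
    """Clustered heatmap of log2 ratios, symmetric global colour scale.

    Blue = male-biased, red = female-biased (ratio sign is male minus
    female, so negative/red means higher in females).
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    ordered = ratio_matrix.values.loc[clustering.row_order, clustering.col_order]
    bound = ratio_matrix.color_bound or 1.0
    fig, ax = plt.subplots(figsize=(8, 10))
    im = ax.imshow(
        ordered.to_numpy(), aspect="auto", cmap="RdBu", vmin=-bound, vmax=bound,
        interpolation="nearest",
    )
    ax.set_xticks(range(len(clustering.col_order)))
    ax.set_xticklabels(clustering.col_order, rotation=90, fontsize=7)
    ax.set_yticks([])
    ax.set_ylabel(f"{ordered.shape[0]} SDE probesets")
    fig.colorbar(im, ax=ax, label="log2(M) - log2(F)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_ma(points: pd.DataFrame, path, title: str = "") -> None:
    """MA scatter: SDE probesets red, others grey, wide-SDE larger."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    rest = points[~points["sde"] & ~points["wide_sde"]]
    sde = points[points["sde"] & ~points["wide_sde"]]
    wide = points[points["wide_sde"]]
    ax.scatter(rest["a"], rest["m"], s=3, c="0.6", linewidths=0, label="not SDE")
    ax.scatter(sde["a"], sde["m"], s=5, c="red", linewidths=0, label="SDE")
    if len(wide):
        ax.scatter(
            wide["a"], wide["m"], s=40,
            c=["red" if f else "0.3" for f in wide["sde"]],
            edgecolors="black", linewidths=0.5, label="SDE in >10 tissues",
        )
    ax.axhline(0, color="black", lw=0.5)
    ax.set_xlabel("A: mean log2 expression (both sexes)")
    ax.set_ylabel("M: log2 male:female ratio")
    ax.set_title(title)
    ax.legend(fontsize=7, loc="upper right")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
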