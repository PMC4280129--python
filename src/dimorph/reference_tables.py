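"""Published summary counts from the 26-tissue rat SDE survey, as
worked-example inputs.

These are the printed cross-tissue tabulations of that survey: the
chip-level expression counts, the distribution of SDE probesets by
bias class and number of SDE tissues, headline per-tissue incidence
numbers, and two pairwise-sharing records. They serve as inputs for
arithmetic the tabulation and enrichment operations must reproduce,
and to construct a *synthetic* stand-in for the survey's supplementary
incidence workbook (the real workbook is not shipped): an explicit
probeset x tissue signed incidence matrix consistent with the printed
margins.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from dimorph.io_formats import S1Layout
from dimorph.synthetic import DEFAULT_TISSUES

__all__ = [
    "CHIP_PROBESETS",
    "EXPRESSED_PROBESETS",
    "TABLE1_DISTRIBUTION",
    "DUODENUM_INCIDENCE",
    "DUODENUM_KIDNEY_SHARED",
    "ADRENAL_PITUITARY_SHARED",
    "build_reference_incidence",
    "build_reference_expressed",
    "synthetic_s1_layout",
    "write_synthetic_s1_workbook",
]

CHIP_PROBESETS = 31042
EXPRESSED_PROBESETS = 19007

# k (number of SDE tissues) -> (always male, always female, opposite)
TABLE1_DISTRIBUTION: dict[int, tuple[int, int, int]] = {
    1: (1573, 849, 0),
    2: (115, 43, 132),
    3: (14, 4, 30),
    4: (1, 0, 4),
    19: (0, 2, 0),
    20: (0, 1, 0),
    22: (0, 2, 0),
    24: (1, 0, 0),
}

# Duodenum row of the per-tissue incidence table: male/female SDE totals
# with the six ubiquitous sex-exclusive probesets excluded.
DUODENUM_INCIDENCE = {"male": 896, "female": 274, "excluded_ubiquitous": 6}

# (observed shared count, printed enrichment factor)
DUODENUM_KIDNEY_SHARED = (101, 1.3)
ADRENAL_PITUITARY_SHARED = (31, 1.8)


def build_reference_incidence() -> pd.DataFrame:
    """Synthetic signed incidence matrix consistent with the printed
    margins.

    One row per SDE probeset (+1 male-biased, -1 female-biased, 0 not
    SDE), 26 tissue columns. The construction reproduces exactly: the
    full k-distribution by bias class, the duodenum male/female totals
    (896/274 after excluding the six ubiquitous probesets, which are
    all SDE in the duodenum), and a duodenum-kidney shared count of
    101 among non-ubiquitous probesets. Cells not pinned by those
    margins are placed deterministically in a handful of tissues.
    """
    tissues = list(DEFAULT_TISSUES)
    rows: list[np.ndarray] = []

    def row(assign: dict[str, int]) -> np.ndarray:
        r = np.zeros(len(tissues), dtype=np.int8)
        for tissue, sign in assign.items():
            r[tissues.index(tissue)] = sign
        return r

    def add(n: int, assign: dict[str, int]) -> None:
        template = row(assign)
        rows.extend([template.copy() for _ in range(n)])

    # single-tissue probesets: 1573 male / 849 female
    add(736, {"Duodenum": 1})
    add(300, {"Kidney": 1})
    add(300, {"Liver": 1})
    add(237, {"Pituitary": 1})
    add(220, {"Duodenum": -1})
    add(250, {"Kidney": -1})
    add(250, {"Liver": -1})
    add(129, {"Pituitary": -1})

    # two-tissue probesets: 115 male / 43 female / 132 opposite,
    # 101 of them shared between duodenum and kidney
    add(70, {"Duodenum": 1, "Kidney": 1})
    add(31, {"Duodenum": 1, "Kidney": -1})
    add(45, {"Duodenum": 1, "Liver": 1})
    add(14, {"Duodenum": 1, "Liver": -1})
    add(43, {"Duodenum": -1, "Pituitary": -1})
    add(11, {"Duodenum": -1, "Pituitary": 1})
    add(76, {"Liver": 1, "Pituitary": -1})

    # three- and four-tissue probesets (none touch the duodenum)
    add(14, {"Kidney": 1, "Liver": 1, "Pituitary": 1})
    add(4, {"Kidney": -1, "Liver": -1, "Pituitary": -1})
    add(30, {"Kidney": 1, "Liver": 1, "Pituitary": -1})
    add(1, {"Kidney": 1, "Liver": 1, "Pituitary": 1, "Adrenal": 1})
    add(4, {"Kidney": 1, "Liver": 1, "Pituitary": -1, "Adrenal": -1})

    # six ubiquitous sex-exclusive probesets, SDE in 19-24 tissues,
    # sets taken as leading runs of the tissue list (all include the
    # duodenum and kidney)
    for k, sign, n in ((19, -1, 2), (20, -1, 1), (22, -1, 2), (24, 1, 1)):
        add(n, {t: sign for t in tissues[:k]})

    data = np.vstack(rows)
    index = pd.Index([f"ref{i:05d}" for i in range(data.shape[0])], name="probeset_id")
    return pd.DataFrame(data, index=index, columns=tissues)


def build_reference_expressed(incidence: pd.DataFrame) -> pd.DataFrame:
    """Chip-scale expression flags around the reference incidence.

    Pads the SDE rows with enough expressed-but-never-SDE and
    never-expressed probesets to reproduce the chip totals (31,042
    probesets, 19,007 expressed in at least one tissue/sex). The
    padded rows are marked expressed in a single arbitrary tissue.
    """
    n_sde = incidence.shape[0]
    n_expressed_pad = EXPRESSED_PROBESETS - n_sde
    n_silent = CHIP_PROBESETS - EXPRESSED_PROBESETS
    pad_ids = [f"pad{i:05d}" for i in range(n_expressed_pad + n_silent)]
    pad = pd.DataFrame(
        False, index=pd.Index(pad_ids, name="probeset_id"), columns=incidence.columns
    )
    pad.iloc[:n_expressed_pad, incidence.columns.get_loc("Brain")] = True
    expressed = pd.concat([incidence != 0, pad])
    return expressed


def synthetic_s1_layout() -> S1Layout:
    """Layout of the synthetic supplementary workbook written below."""
    return S1Layout(
        probeset_column="Probeset ID",
        incidence_columns={f"SDE {t}": t for t in DEFAULT_TISSUES},
        sheet="SDE probesets",
        male_tokens=("M",),
        female_tokens=("F",),
        none_tokens=("",),
        fold_columns={f"Fold {t}": t for t in DEFAULT_TISSUES},
        q_columns=None,
    )


def write_synthetic_s1_workbook(path: str | Path, incidence: pd.DataFrame | None = None) -> Path:
    """Write a synthetic supplementary-style XLSX incidence workbook.

    Stand-in for the survey's real supplementary workbook: sheet "SDE
    probesets" with a probeset column, per-tissue incidence cells
    (M / F / blank) and illustrative fold-difference columns (2^1.5
    with the bias sign; the fold values are decoration, only the
    incidence is consumed downstream).
    """
    from openpyxl import Workbook

    if incidence is None:
        incidence = build_reference_incidence()
    layout = synthetic_s1_layout()
    wb = Workbook(write_only=True)
    ws = wb.create_sheet(str(layout.sheet))
    inc_cols = list(layout.incidence_columns)
    fold_cols = list(layout.fold_columns or {})
    ws.append([layout.probeset_column, *inc_cols, *fold_cols])
    tissue_order = [layout.incidence_columns[c] for c in inc_cols]
    arr = incidence[tissue_order].to_numpy()
    token = {1: "M", -1: "F", 0: ""}
    for pid, row in zip(incidence.index, arr):
        cells = [token[int(v)] for v in row]
        folds = [round(float(np.sign(v)) * 2**1.5, 3) if v else "" for v in row]
        ws.append([pid, *cells, *folds])
    path = Path(path)
    wb.save(path)
    return path
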