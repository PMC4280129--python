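"""Tabular I/O and joint validation of expression matrices and annotations.

All quantitative input is a probeset x sample grid of log2-scale
normalized intensities as tab-delimited text; samples are described by a
separate annotation table (sample_id, animal_id, tissue, sex).
Normalization (GC-RMA or otherwise) happens upstream of this package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Dataset",
    "S1Layout",
    "join_and_validate",
    "read_exclude_list",
    "read_expression_matrix",
    "read_s1_incidence",
    "read_sample_annotation",
    "write_expression_matrix",
    "write_stats_table",
    "read_stats_table",
]

ANNOTATION_COLUMNS = ("sample_id", "animal_id", "tissue", "sex")

_SEX_TOKENS = {"m": "M", "male": "M", "f": "F", "female": "F"}


class FormatError(ValueError):
    """A file violated the expected layout or an invariant (duplicates,
    non-numeric cells, unknown sex tokens, unresolvable samples)."""


def read_expression_matrix(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    """Read a probeset x sample matrix of log2 intensities.

    Layout: header row ``probeset_id`` + sample ids, one probeset per
    row, decimal-point numeric body. Returns a float DataFrame indexed
    by probeset id with sample ids as columns, in file order.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicated probeset ids {dups[:5]}")
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicated sample ids {dups[:5]}")
    try:
        values = df.astype(float)
    except ValueError:
        # locate the offending cell for the error message
        for col in df.columns:
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            if bad.any():
                row = df.index[bad][0]
                raise FormatError(
                    f"{path}: non-numeric value {df.loc[row, col]!r} "
                    f"at probeset {row!r}, sample {col!r}"
                ) from None
        raise
    if values.isna().any().any():
        row = values.index[values.isna().any(axis=1)][0]
        raise FormatError(f"{path}: missing value at probeset {row!r}")
    if not np.isfinite(values.to_numpy()).all():
        raise FormatError(f"{path}: non-finite values in matrix")
    values.index.name = "probeset_id"
    return values


def write_expression_matrix(matrix: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    """Write a matrix in the layout `read_expression_matrix` expects."""
    out = matrix.copy()
    out.index.name = "probeset_id"
    out.to_csv(path, sep=sep, float_format="%.6f")


def read_sample_annotation(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    """Read the sample annotation table.

    Columns sample_id, animal_id, tissue, sex are matched
    case-insensitively and order-free; sex is normalized to {M, F} from
    {m, f, male, female} in any case.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=sep, dtype=str)
    rename = {}
    lowered = {c.lower().strip(): c for c in df.columns}
    for want in ANNOTATION_COLUMNS:
        if want not in lowered:
            raise FormatError(f"{path}: missing required column {want!r}")
        rename[lowered[want]] = want
    df = df.rename(columns=rename)[list(ANNOTATION_COLUMNS)]
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise FormatError(f"{path}: duplicate sample_id {dups[:5]}")
    sex = df["sex"].str.strip().str.lower().map(_SEX_TOKENS)
    if sex.isna().any():
        bad = df.loc[sex.isna(), "sex"].unique().tolist()
        raise FormatError(f"{path}: unknown sex token(s) {bad[:5]}; expected M/F/male/female")
    df["sex"] = sex
    if (df["tissue"].isna() | (df["tissue"].str.strip() == "")).any():
        raise FormatError(f"{path}: empty tissue label")
    df["tissue"] = df["tissue"].str.strip()
    return df


def read_exclude_list(path: str | Path) -> list[str]:
    """Plain-text exclude list: one sample_id per line, blanks ignored."""
    lines = Path(path).read_text().splitlines()
    return [ln.strip() for ln in lines if ln.strip()]


@dataclass
class Dataset:
    """A validated expression matrix joined with its sample annotation.

    ``groups`` maps (tissue, sex) to the matrix columns in that group;
    ``small_groups`` lists groups with fewer than ``min_group_size``
    samples that were tolerated via ``allow_small_groups``.
    """

    matrix: pd.DataFrame
    annotation: pd.DataFrame
    groups: dict[tuple[str, str], list[str]] = field(default_factory=dict)
    small_groups: list[tuple[str, str]] = field(default_factory=list)

    @property
    def tissues(self) -> list[str]:
        seen: dict[str, None] = {}
        for tissue, _sex in self.groups:
            seen.setdefault(tissue, None)
        return list(seen)

    def group_columns(self, tissue: str, sex: str) -> list[str]:
        try:
            return self.groups[(tissue, sex)]
        except KeyError:
            raise KeyError(f"no samples for tissue={tissue!r} sex={sex!r}") from None


def join_and_validate(
    matrix: pd.DataFrame,
    annotation: pd.DataFrame,
    exclude: Iterable[str] | None = None,
    allow_small_groups: bool = False,
    min_group_size: int = 2,
) -> Dataset:
    """Join matrix columns to annotation rows and compute group mappings.

    Every matrix sample must resolve to exactly one annotation row.
    Columns named in ``exclude`` (upstream chip-QC failures) are dropped
    before grouping. Any (tissue, sex) group smaller than
    ``min_group_size`` is a hard error unless ``allow_small_groups``;
    tolerated small groups are recorded in ``Dataset.small_groups``.
    Group mappings are invariant to annotation row order (columns keep
    matrix order).
    """
    exclude = set(exclude or ())
    unknown = exclude - set(matrix.columns)
    if unknown:
        warnings.warn(f"exclude list names absent samples: {sorted(unknown)[:5]}")
    kept = [c for c in matrix.columns if c not in exclude]
    matrix = matrix[kept]
    ann = annotation.set_index("sample_id")
    missing = [c for c in matrix.columns if c not in ann.index]
    if missing:
        raise FormatError(f"matrix samples absent from annotation: {missing[:5]}")
    ann = ann.loc[list(matrix.columns)]
    groups: dict[tuple[str, str], list[str]] = {}
    for sample_id, row in ann.iterrows():
        groups.setdefault((row["tissue"], row["sex"]), []).append(sample_id)
    small = [key for key, cols in groups.items() if len(cols) < min_group_size]
    if small and not allow_small_groups:
        raise FormatError(
            f"(tissue, sex) groups below {min_group_size} samples: {sorted(small)}; "
            "pass allow_small_groups=True to proceed"
        )
    return Dataset(
        matrix=matrix,
        annotation=ann.reset_index(),
        groups=groups,
        small_groups=sorted(small),
    )


# ---------------------------------------------------------------------------
# Supplementary incidence-workbook reader
# ---------------------------------------------------------------------------


@dataclass
class S1Layout:
    """Layout description for a supplementary SDE-incidence workbook.

    The exact sheet layout of such workbooks varies, so the mapping is
    configuration: ``incidence_columns`` maps spreadsheet column header ->
    tissue label; cell tokens in ``male_tokens``/``female_tokens`` mark
    male-/female-biased SDE incidence, anything in ``none_tokens`` (or
    blank) marks no call. Optional fold-difference / q-value column
    maps are carried through unparsed-but-numeric.
    """

    probeset_column: str
    incidence_columns: Mapping[str, str]
    sheet: str | int = 0
    male_tokens: Sequence[str] = ("M", "male", "1")
    female_tokens: Sequence[str] = ("F", "female", "-1")
    none_tokens: Sequence[str] = ("", "0", "NA", "none")
    fold_columns: Mapping[str, str] | None = None
    q_columns: Mapping[str, str] | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "S1Layout":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def read_s1_incidence(path: str | Path, layout: S1Layout) -> pd.DataFrame:
    """Read a supplementary workbook into a signed incidence matrix.

    Returns a probeset x tissue DataFrame of int8 values: +1 male-biased
    SDE, -1 female-biased SDE, 0 not SDE.
    """
    raw = pd.read_excel(path, sheet_name=layout.sheet, dtype=str, engine="openpyxl")
    if layout.probeset_column not in raw.columns:
        raise FormatError(f"{path}: probeset column {layout.probeset_column!r} not found")
    missing = [c for c in layout.incidence_columns if c not in raw.columns]
    if missing:
        raise FormatError(f"{path}: incidence columns missing: {missing[:5]}")
    idx = raw[layout.probeset_column].astype(str)
    if idx.duplicated().any():
        raise FormatError(f"{path}: duplicated probeset ids in workbook")
    male = {t.lower() for t in layout.male_tokens}
    female = {t.lower() for t in layout.female_tokens}
    none = {t.lower() for t in layout.none_tokens}

    def _decode(cell: object) -> int:
        tok = "" if cell is None or (isinstance(cell, float) and np.isnan(cell)) else str(cell).strip()
        low = tok.lower()
        if low in male:
            return 1
        if low in female:
            return -1
        if low in none:
            return 0
        raise FormatError(f"unrecognized incidence token {tok!r}")

    data = {
        tissue: raw[col].map(_decode).to_numpy(dtype=np.int8)
        for col, tissue in layout.incidence_columns.items()
    }
    out = pd.DataFrame(data, index=pd.Index(idx, name="probeset_id"))
    return out


# ---------------------------------------------------------------------------
# Per-tissue statistics tables (long format)
# ---------------------------------------------------------------------------

STATS_COLUMNS = [
    "probeset_id",
    "tissue",
    "mean_m",
    "mean_f",
    "log2_diff",
    "t_stat",
    "p_value",
    "q_value",
    "expressed_m",
    "expressed_f",
    "expressed",
    "sde",
    "bias",
    "degenerate_variance",
]


def write_stats_table(all_stats: Mapping[str, pd.DataFrame], path: str | Path, sep: str = "\t") -> None:
    """Write per-tissue SDE statistics as one long TSV."""
    frames = []
    for tissue in all_stats:
        df = all_stats[tissue].reset_index()
        frames.append(df[STATS_COLUMNS])
    pd.concat(frames, ignore_index=True).to_csv(path, sep=sep, index=False, float_format="%.8g")


def read_stats_table(path: str | Path, sep: str = "\t") -> dict[str, pd.DataFrame]:
    """Read a long stats TSV back into a tissue -> DataFrame map."""
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in STATS_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: stats table missing columns {missing}")
    for col in ("expressed_m", "expressed_f", "expressed", "sde", "degenerate_variance"):
        df[col] = df[col].astype(bool)
    out = {}
    for tissue, sub in df.groupby("tissue", sort=False):
        out[str(tissue)] = sub.set_index("probeset_id")
    return out
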