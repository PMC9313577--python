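"""Marker-based T-cell subset phenotyping and cohort summary tables.

Cells arrive as boolean marker calls (thresholding on fluorescence happens
upstream and is out of scope).  The *analysis* scheme assigns the five
differentiation subsets from the CD45RA × CCR7 quadrant, with CD95 splitting
the CD45RA+CCR7+ quadrant into naive (CD95−) and stem-cell memory (CD95+):

    naive  CD45RA+ CCR7+ CD95−        CM  CD45RA− CCR7+
    SCM    CD45RA+ CCR7+ CD95+        EM  CD45RA− CCR7−
                                      EMRA CD45RA+ CCR7−

CD27/CD28 are descriptive (heterogeneous in EM, implied elsewhere) and never
change the assignment.  The *sorting* scheme additionally requires CD62L
concordant with CCR7; discordant cells are left "unassigned" and excluded
from frequency tables with a logged count.

Recent thymic emigrants (RTE) are operationally CD21+ naive cells.

Groups (donor, tissue, compartment) with fewer than ``min_cells`` (default
100) total cells are excluded from frequency tables; for Ki67 turnover
tables small subset groups are flagged low-confidence instead of dropped,
because rare-subset turnover estimates deserve caution, not silence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Union

import numpy as np
import pandas as pd

from .exceptions import ClassificationError, ValidationError

logger = logging.getLogger(__name__)

SUBSETS = ("naive", "SCM", "CM", "EM", "EMRA")
UNASSIGNED = "unassigned"

#: metadata columns every cell table must carry
METADATA_COLS = ("donor_id", "age_years", "tissue", "cmv_status", "compartment")

MARKERS = ("CD45RA", "CCR7", "CD27", "CD28", "CD95", "CD31", "CD21",
           "CD62L", "Ki67")


@dataclass(frozen=True)
class CellRecord:
    """One cell's boolean marker vector plus donor/tissue metadata."""

    donor_id: str
    age_years: float
    tissue: str
    compartment: str            # "CD4" or "CD8"
    markers: Mapping[str, bool]
    cmv_status: str = "unknown"

    def __post_init__(self) -> None:
        if self.age_years < 0:
            raise ValidationError("age_years must be non-negative")
        for required in ("CD45RA", "CCR7", "CD95"):
            if required not in self.markers:
                raise ValidationError(f"marker {required} missing from cell")


@dataclass(frozen=True)
class SubsetScheme:
    """An ordered rule list mapping marker requirements to subset labels.

    Each rule is (label, {marker: required boolean}); markers absent from a
    rule are wildcards.  Rules are applied in order; the first match wins.
    Cells matching no rule are labelled "unassigned".
    """

    name: str
    rules: tuple[tuple[str, Mapping[str, bool]], ...]

    @property
    def discriminating_markers(self) -> tuple[str, ...]:
        seen: list[str] = []
        for _, req in self.rules:
            for m in req:
                if m not in seen:
                    seen.append(m)
        return tuple(seen)


ANALYSIS_SCHEME = SubsetScheme(
    name="analysis",
    rules=(
        ("naive", {"CD45RA": True, "CCR7": True, "CD95": False}),
        ("SCM", {"CD45RA": True, "CCR7": True, "CD95": True}),
        ("CM", {"CD45RA": False, "CCR7": True}),
        ("EM", {"CD45RA": False, "CCR7": False}),
        ("EMRA", {"CD45RA": True, "CCR7": False}),
    ),
)

#: CD62L-concordant sorting definitions; discordant CCR7/CD62L -> unassigned
SORTING_SCHEME = SubsetScheme(
    name="sorting",
    rules=(
        ("naive", {"CD45RA": True, "CCR7": True, "CD62L": True, "CD95": False}),
        ("SCM", {"CD45RA": True, "CCR7": True, "CD62L": True, "CD95": True}),
        ("CM", {"CD45RA": False, "CCR7": True, "CD62L": True}),
        ("EM", {"CD45RA": False, "CCR7": False, "CD62L": False}),
        ("EMRA", {"CD45RA": True, "CCR7": False, "CD62L": False}),
    ),
)

SCHEMES = {"analysis": ANALYSIS_SCHEME, "sorting": SORTING_SCHEME}


def get_scheme(name_or_scheme) -> SubsetScheme:
    if isinstance(name_or_scheme, SubsetScheme):
        return name_or_scheme
    try:
        return SCHEMES[name_or_scheme]
    except KeyError:
        raise ValidationError(
            f"unknown scheme {name_or_scheme!r}; choose from {list(SCHEMES)}"
        ) from None


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify_cells(cells: pd.DataFrame, scheme="analysis") -> pd.Series:
    """Vectorized subset assignment: one label per row of a cell table.

    Raises :class:`ClassificationError` naming the first missing
    discriminating marker column.
    """
    scheme = get_scheme(scheme)
    for marker in scheme.discriminating_markers:
        if marker not in cells.columns:
            raise ClassificationError(
                f"scheme {scheme.name!r} needs marker {marker!r}, "
                "absent from the cell table")
    labels = pd.Series(UNASSIGNED, index=cells.index, dtype=object)
    open_mask = pd.Series(True, index=cells.index)
    for label, req in scheme.rules:
        mask = open_mask.copy()
        for marker, value in req.items():
            mask &= cells[marker].astype(bool) == value
        labels[mask] = label
        open_mask &= ~mask
    return labels


def classify_cell(cell: Union[CellRecord, Mapping[str, bool]],
                  scheme="analysis") -> str:
    """Subset label of a single cell (see :func:`classify_cells`)."""
    scheme = get_scheme(scheme)
    markers = cell.markers if isinstance(cell, CellRecord) else cell
    for marker in scheme.discriminating_markers:
        if marker not in markers:
            raise ClassificationError(
                f"scheme {scheme.name!r} needs marker {marker!r}, "
                "missing from cell")
    for label, req in scheme.rules:
        if all(bool(markers[m]) == v for m, v in req.items()):
            return label
    return UNASSIGNED


def flag_rte(cell: Union[CellRecord, Mapping[str, bool]],
             scheme="analysis") -> bool:
    """True iff the cell is naive and CD21+ (the operational RTE definition).

    CD21 on memory cells is a separate observable (see
    :func:`cd21_memory_fraction`), never RTE.
    """
    markers = cell.markers if isinstance(cell, CellRecord) else cell
    if "CD21" not in markers:
        raise ClassificationError("CD21 marker required to flag RTE cells")
    return classify_cell(cell, scheme) == "naive" and bool(markers["CD21"])


# ---------------------------------------------------------------------------
# cohort tables
# ---------------------------------------------------------------------------

_GROUP = ["donor_id", "tissue", "compartment"]


def _check_cells(cells: pd.DataFrame) -> None:
    if cells.empty:
        raise ValidationError("empty cell table")
    missing = [c for c in METADATA_COLS if c not in cells.columns]
    if missing:
        raise ValidationError(f"cell table missing metadata columns {missing}")


def _with_subset(cells: pd.DataFrame, scheme) -> pd.DataFrame:
    df = cells.copy()
    df["subset"] = classify_cells(df, scheme)
    n_un = int((df["subset"] == UNASSIGNED).sum())
    if n_un:
        logger.warning("%d cell(s) unassigned under scheme %s; excluded",
                       n_un, get_scheme(scheme).name)
        df = df[df["subset"] != UNASSIGNED]
    return df


def _group_meta(df: pd.DataFrame) -> pd.DataFrame:
    return (df.groupby(_GROUP, as_index=False)
              .agg(age_years=("age_years", "first"),
                   cmv_status=("cmv_status", "first"),
                   n_total_compartment=("subset", "size")))


def cohort_frequencies(cells: pd.DataFrame, scheme="analysis",
                       min_cells: int = 100) -> pd.DataFrame:
    """Subset frequencies per (donor, tissue, compartment).

    Output columns: donor_id, age_years, tissue, cmv_status, compartment,
    subset, n_cells, frequency, n_total_compartment — one row for each of the
    five subsets per group (zero rows included), frequencies summing to 1
    within each group.  Groups with fewer than ``min_cells`` total cells are
    excluded and logged, reproducing the <100-cell exclusion rule.
    """
    _check_cells(cells)
    df = _with_subset(cells, scheme)
    meta = _group_meta(df)
    small = meta[meta["n_total_compartment"] < min_cells]
    for row in small.itertuples(index=False):
        logger.warning(
            "excluding group donor=%s tissue=%s compartment=%s: "
            "%d cells < min_cells=%d", row.donor_id, row.tissue,
            row.compartment, row.n_total_compartment, min_cells)
    meta = meta[meta["n_total_compartment"] >= min_cells]

    counts = (df.groupby(_GROUP + ["subset"]).size().rename("n_cells")
                .reset_index())
    full = meta.merge(pd.DataFrame({"subset": list(SUBSETS)}), how="cross")
    full = full.merge(counts, on=_GROUP + ["subset"], how="left")
    full["n_cells"] = full["n_cells"].fillna(0).astype(int)
    full["frequency"] = full["n_cells"] / full["n_total_compartment"]
    full["subset"] = pd.Categorical(full["subset"], categories=SUBSETS,
                                    ordered=True)
    return (full.sort_values(_GROUP + ["subset"])
            [["donor_id", "age_years", "tissue", "cmv_status", "compartment",
              "subset", "n_cells", "frequency", "n_total_compartment"]]
            .reset_index(drop=True))


def ki67_by_subset(cells: pd.DataFrame, scheme="analysis",
                   min_cells: int = 100) -> pd.DataFrame:
    """Fraction of Ki67+ (cycling) cells per (donor, tissue, compartment,
    subset) group.

    Subset groups smaller than ``min_cells`` are kept but flagged
    ``low_confidence`` — turnover estimates in rare subsets warrant caution
    rather than removal.  Empty subset groups are absent.
    """
    _check_cells(cells)
    if "Ki67" not in cells.columns:
        raise ClassificationError("Ki67 marker column required")
    df = _with_subset(cells, scheme)
    out = (df.groupby(_GROUP + ["subset"], as_index=False)
             .agg(age_years=("age_years", "first"),
                  cmv_status=("cmv_status", "first"),
                  n_cells=("Ki67", "size"),
                  ki67_fraction=("Ki67", "mean")))
    out["ki67_fraction"] = out["ki67_fraction"].astype(float)
    out["low_confidence"] = out["n_cells"] < min_cells
    return out


def cd21_memory_fraction(cells: pd.DataFrame, scheme="analysis") -> pd.DataFrame:
    """Fraction of CD21+ cells among antigen-experienced (SCM/CM/EM/EMRA)
    cells per (donor, tissue, compartment).  All-naive input yields an
    empty table."""
    _check_cells(cells)
    if "CD21" not in cells.columns:
        raise ClassificationError("CD21 marker column required")
    df = _with_subset(cells, scheme)
    mem = df[df["subset"] != "naive"]
    if mem.empty:
        return pd.DataFrame(columns=_GROUP + ["age_years", "cmv_status",
                                              "n_memory", "cd21_fraction"])
    return (mem.groupby(_GROUP, as_index=False)
               .agg(age_years=("age_years", "first"),
                    cmv_status=("cmv_status", "first"),
                    n_memory=("CD21", "size"),
                    cd21_fraction=("CD21", "mean")))


def rte_frequencies(cells: pd.DataFrame, scheme="analysis") -> pd.DataFrame:
    """RTE (CD21+ naive) frequency among all cells and within the naive
    pool, per (donor, tissue, compartment)."""
    _check_cells(cells)
    if "CD21" not in cells.columns:
        raise ClassificationError("CD21 marker column required")
    df = _with_subset(cells, scheme)
    df = df.assign(is_naive=df["subset"] == "naive")
    df = df.assign(is_rte=df["is_naive"] & df["CD21"].astype(bool))
    out = (df.groupby(_GROUP, as_index=False)
             .agg(age_years=("age_years", "first"),
                  cmv_status=("cmv_status", "first"),
                  n_cells=("is_rte", "size"),
                  n_naive=("is_naive", "sum"),
                  n_rte=("is_rte", "sum")))
    out["rte_frequency"] = out["n_rte"] / out["n_cells"]
    out["rte_fraction_of_naive"] = np.where(
        out["n_naive"] > 0, out["n_rte"] / out["n_naive"], np.nan)
    return out


# ---------------------------------------------------------------------------
# cell-table I/O
# ---------------------------------------------------------------------------

_BOOL_MAP = {"0": False, "1": True, "-": False, "+": True,
             "false": False, "true": True, "f": False, "t": True}


def read_cell_table(path: Union[str, Path], sep: str = "\t") -> pd.DataFrame:
    """Read a delimited per-cell marker-call table.

    Marker columns accept {0,1}, {-,+} or true/false; metadata columns are
    donor_id, age_years, tissue, cmv_status, compartment.
    """
    df = pd.read_csv(path, sep=sep, dtype=str, comment="#",
                     keep_default_na=False)
    _check_cells(df)
    df["age_years"] = df["age_years"].astype(float)
    for col in df.columns:
        if col not in MARKERS:
            continue  # metadata and extra columns (e.g. ground truth) pass through
        df[col] = df[col].str.strip().str.lower().map(_BOOL_MAP)
        if df[col].isna().any():
            raise ValidationError(
                f"marker column {col!r} has values outside "
                "{0,1,-,+,true,false}")
        df[col] = df[col].astype(bool)
    return df


def write_cell_table(cells: pd.DataFrame, path: Union[str, Path],
                     sep: str = "\t", header_comment: str | None = None) -> None:
    df = cells.copy()
    for col in df.columns:
        if df[col].dtype == bool:
            df[col] = df[col].astype(int)
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep=sep, index=False)
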