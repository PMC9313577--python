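"""Reading, writing, and frame-partitioning of clonotype tables.

Two tab-separated dialects are supported:

* **airr** — AIRR Rearrangement-style columns ``junction``, ``junction_aa``,
  ``v_call``, ``j_call``, ``duplicate_count``, ``productive``;
* **immunoseq** — immunoSEQ-export-style columns ``nucleotide``,
  ``aminoAcid``, ``vGeneName``, ``jGeneName``, ``count`` (``templates`` or
  ``estimatedNumberGenomes`` accepted) and ``sequenceStatus`` (``frame_type``
  accepted) with values ``In`` / ``Out`` / ``Stop``.

Rows with identical identity keys are merged by summing template counts, so
row order never affects the result.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .exceptions import DialectError, ValidationError
from .records import (DEFAULT_IDENTITY, ClonotypeRecord, Frame, IdentityKey,
                      RepLabel, Repertoire)

logger = logging.getLogger(__name__)

DIALECTS = ("airr", "immunoseq")

_NT_ALPHABET = frozenset("ACGT")

# canonical column name -> (dialect column, accepted fallbacks)
_AIRR_COLS = {
    "cdr3_nt": ("junction", ()),
    "cdr3_aa": ("junction_aa", ()),
    "v_gene": ("v_call", ()),
    "j_gene": ("j_call", ()),
    "templates": ("duplicate_count", ()),
    "frame": ("productive", ()),
}
_IMMUNOSEQ_COLS = {
    "cdr3_nt": ("nucleotide", ()),
    "cdr3_aa": ("aminoAcid", ()),
    "v_gene": ("vGeneName", ()),
    "j_gene": ("jGeneName", ()),
    "templates": ("count", ("templates", "estimatedNumberGenomes")),
    "frame": ("sequenceStatus", ("frame_type",)),
}

_AIRR_TRUE = {"t", "true"}
_AIRR_FALSE = {"f", "false"}
_IMMUNOSEQ_FRAME = {"In": Frame.productive,
                    "Out": Frame.nonproductive,
                    "Stop": Frame.nonproductive,
                    "Unknown": Frame.unknown}


def _column_map(dialect: str) -> dict:
    if dialect == "airr":
        return _AIRR_COLS
    if dialect == "immunoseq":
        return _IMMUNOSEQ_COLS
    raise DialectError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")


def _resolve_columns(df: pd.DataFrame, dialect: str) -> dict:
    """Map canonical field -> actual column name, or raise naming the column."""
    spec = _column_map(dialect)
    resolved = {}
    for canon, (primary, fallbacks) in spec.items():
        for cand in (primary, *fallbacks):
            if cand in df.columns:
                if cand != primary and canon == "templates":
                    logger.warning(
                        "dialect %s: using column %r for template counts "
                        "(preferred column %r absent)", dialect, cand, primary)
                resolved[canon] = cand
                break
        else:
            raise DialectError(
                f"dialect {dialect!r}: required column {primary!r} missing "
                f"(accepted alternatives: {list(fallbacks)})")
    return resolved


def _parse_frame_airr(value) -> Frame:
    s = str(value).strip().lower()
    if s in _AIRR_TRUE:
        return Frame.productive
    if s in _AIRR_FALSE:
        return Frame.nonproductive
    if s in ("", "nan", "none"):
        return Frame.unknown
    raise ValidationError(f"unparseable AIRR 'productive' value {value!r}")


def _parse_frame_immunoseq(value) -> Frame:
    s = str(value).strip()
    if s in _IMMUNOSEQ_FRAME:
        return _IMMUNOSEQ_FRAME[s]
    if s.lower() in ("", "nan", "none"):
        return Frame.unknown
    raise ValidationError(f"unparseable sequenceStatus value {value!r}")


def read_clonotype_table(
    path: Union[str, Path],
    dialect: str,
    identity: IdentityKey = DEFAULT_IDENTITY,
    label: RepLabel = RepLabel(),
) -> Repertoire:
    """Read a clonotype TSV into a deduplicated :class:`Repertoire`.

    Rows sharing an identity key are merged by summing template counts.
    Lines starting with ``#`` are treated as provenance comments.

    Raises
    ------
    DialectError
        if a required column of the dialect is missing.
    ValidationError
        for a non-positive / non-integer count or an invalid CDR3, with the
        1-based data row number in the message; also for an empty table.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#",
                     keep_default_na=False)
    if df.empty:
        raise ValidationError(f"{path}: no data rows after header")
    cols = _resolve_columns(df, dialect)
    parse_frame = _parse_frame_airr if dialect == "airr" else _parse_frame_immunoseq

    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        raw = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        count_s = str(raw[cols["templates"]]).strip()
        try:
            count_f = float(count_s)
        except ValueError:
            raise ValidationError(
                f"{path} row {i}: count {count_s!r} is not a number") from None
        if count_f != int(count_f):
            raise ValidationError(
                f"{path} row {i}: count {count_s!r} is not an integer")
        count = int(count_f)
        if count < 1:
            raise ValidationError(
                f"{path} row {i}: count must be >= 1, got {count}")
        nt = str(raw[cols["cdr3_nt"]]).strip().upper()
        if not nt:
            raise ValidationError(f"{path} row {i}: empty CDR3 nucleotide sequence")
        if not set(nt) <= _NT_ALPHABET:
            raise ValidationError(
                f"{path} row {i}: CDR3 {nt!r} has characters outside ACGT")
        records.append(ClonotypeRecord(
            cdr3_nt=nt,
            templates=count,
            v_gene=str(raw[cols["v_gene"]]).strip(),
            j_gene=str(raw[cols["j_gene"]]).strip(),
            cdr3_aa=str(raw[cols["cdr3_aa"]]).strip(),
            frame=parse_frame(raw[cols["frame"]]),
        ))
    # merging makes the result invariant to row order and split clonotypes
    return Repertoire.from_records(records, label=label, identity=identity)


_FRAME_TO_AIRR = {Frame.productive: "T", Frame.nonproductive: "F",
                  Frame.unknown: ""}
_FRAME_TO_IMMUNOSEQ = {Frame.productive: "In", Frame.nonproductive: "Out",
                       Frame.unknown: "Unknown"}


def write_clonotype_table(
    rep: Repertoire, path: Union[str, Path], dialect: str,
    header_comment: str | None = None,
) -> None:
    """Write ``rep`` as a TSV in ``dialect``; round-trips through
    :func:`read_clonotype_table` up to frame granularity (``Stop`` and
    ``Out`` both denote nonproductive and are written as ``Out``).

    Refuses to write an empty repertoire.
    """
    if rep.R == 0:
        raise ValidationError("refusing to write an empty repertoire")
    spec = _column_map(dialect)
    frame_map = _FRAME_TO_AIRR if dialect == "airr" else _FRAME_TO_IMMUNOSEQ
    cols = {canon: primary for canon, (primary, _) in spec.items()}
    df = pd.DataFrame({
        cols["cdr3_nt"]: [r.cdr3_nt for r in rep.clonotypes],
        cols["cdr3_aa"]: [r.cdr3_aa for r in rep.clonotypes],
        cols["v_gene"]: [r.v_gene for r in rep.clonotypes],
        cols["j_gene"]: [r.j_gene for r in rep.clonotypes],
        cols["templates"]: [r.templates for r in rep.clonotypes],
        cols["frame"]: [frame_map[r.frame] for r in rep.clonotypes],
    })
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=False)


def infer_frame(cdr3_nt: str) -> Frame:
    """Frame of a bare CDR3 nucleotide sequence.

    Productive iff the length is divisible by 3 and the translation contains
    no stop codon; anything else is nonproductive.
    """
    if len(cdr3_nt) % 3 != 0:
        return Frame.nonproductive
    if "*" in str(Seq(cdr3_nt).translate()):
        return Frame.nonproductive
    return Frame.productive


def partition_by_frame(
    rep: Repertoire, fallback: bool = True
) -> tuple[Repertoire, Repertoire]:
    """Split a repertoire into (productive, nonproductive) fractions.

    Records with ``frame=unknown`` are resolved by :func:`infer_frame` when
    ``fallback`` is true, otherwise routed to the nonproductive fraction; in
    both cases the decision is logged, never silent.  The union of the two
    outputs equals the input.
    """
    prod, nonprod = [], []
    n_unknown = 0
    for rec in rep.clonotypes:
        frame = rec.frame
        if frame is Frame.unknown:
            n_unknown += 1
            frame = infer_frame(rec.cdr3_nt) if fallback else Frame.nonproductive
        (prod if frame is Frame.productive else nonprod).append(rec)
    if n_unknown:
        logger.warning(
            "repertoire %s: %d record(s) with unknown frame %s",
            rep.label, n_unknown,
            "resolved by length/stop-codon rule" if fallback
            else "routed to nonproductive")
    return (Repertoire._trusted(rep.label, tuple(prod), rep.identity),
            Repertoire._trusted(rep.label, tuple(nonprod), rep.identity))
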