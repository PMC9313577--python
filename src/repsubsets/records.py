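"""Core domain types: clonotypes, identity keys, repertoires.

A *clonotype* is one unique TCRα rearrangement (CDR3 nucleotide sequence in
its V/J context) and stands for one T-cell clone; its ``templates`` count is
the quantitative estimate of the number of input genomes (cells) carrying the
rearrangement.  A *repertoire* is the labelled collection of clonotypes
observed in one sorted (donor, compartment, subset, tissue) sample, with
``N`` total templates and ``R`` unique clonotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

from .exceptions import ValidationError


class Frame(str, Enum):
    """Productivity of a rearrangement.

    ``productive`` — in-frame, translatable (expressed receptor);
    ``nonproductive`` — out-of-frame or stop-codon-bearing (never expressed,
    hence never selected: sharing of nonproductive sequences between two
    sorted subsets marks common clonal origin);
    ``unknown`` — the export did not say.
    """

    productive = "productive"
    nonproductive = "nonproductive"
    unknown = "unknown"


#: Fields an identity key may draw on.
KEYABLE_FIELDS = ("cdr3_nt", "v_gene", "j_gene", "cdr3_aa")


def strip_allele(gene: str) -> str:
    """Reduce an allele-level gene call (``TRAV12-1*01``) to gene level."""
    return gene.split("*", 1)[0]


@dataclass(frozen=True)
class IdentityKey:
    """What makes two rearrangement rows "the same clonotype".

    The default — nucleotide CDR3 plus gene-level V and J calls — is the
    strictest key both supported dialects can express, and the one under
    which nonproductive-sequence sharing is a clonal-origin signal.
    Gene calls are stripped of allele suffixes before comparison.
    """

    fields: tuple[str, ...] = ("cdr3_nt", "v_gene", "j_gene")

    def __post_init__(self) -> None:
        if not self.fields:
            raise ValidationError("identity key must name at least one field")
        bad = [f for f in self.fields if f not in KEYABLE_FIELDS]
        if bad:
            raise ValidationError(f"unknown identity-key field(s): {bad}")
        if "cdr3_nt" not in self.fields and "cdr3_aa" not in self.fields:
            raise ValidationError(
                "identity key must include cdr3_nt or cdr3_aa")

    def of(self, record: "ClonotypeRecord") -> tuple[str, ...]:
        """The identity tuple of ``record`` under this key."""
        out = []
        for f in self.fields:
            v = getattr(record, f)
            if f in ("v_gene", "j_gene"):
                v = strip_allele(v)
            out.append(v)
        return tuple(out)


DEFAULT_IDENTITY = IdentityKey()


@dataclass(frozen=True)
class ClonotypeRecord:
    """One unique rearrangement with its template count and frame status."""

    cdr3_nt: str
    templates: int
    v_gene: str = ""
    j_gene: str = ""
    cdr3_aa: str = ""
    frame: Frame = Frame.unknown

    def __post_init__(self) -> None:
        # kept deliberately cheap: this constructor runs millions of times
        # in simulations; full character-level validation happens at I/O.
        if not self.cdr3_nt:
            raise ValidationError("cdr3_nt must be non-empty")
        t = self.templates
        if not isinstance(t, (int, np.integer)) or isinstance(t, bool) or t < 1:
            raise ValidationError(
                f"templates must be a positive integer, got {self.templates!r}")
        if not isinstance(self.frame, Frame):
            raise ValidationError(f"invalid frame {self.frame!r}")


@dataclass(frozen=True, order=True)
class RepLabel:
    """Identifies one sorted sample: (donor, compartment, subset, tissue)."""

    donor_id: str = ""
    compartment: str = ""  # "CD4" or "CD8"
    subset: str = ""       # naive / SCM / CM / EM / EMRA
    tissue: str = ""

    def __str__(self) -> str:
        return "/".join(
            p or "-" for p in
            (self.donor_id, self.compartment, self.subset, self.tissue))


def _merge_records(
    records: Iterable[ClonotypeRecord], identity: IdentityKey
) -> tuple[ClonotypeRecord, ...]:
    """Group records by identity key, summing template counts.

    First-seen field values win for non-key fields; conflicting frames within
    one key collapse to ``unknown``.
    """
    merged: dict[tuple, ClonotypeRecord] = {}
    for rec in records:
        k = identity.of(rec)
        prev = merged.get(k)
        if prev is None:
            merged[k] = rec
        else:
            frame = prev.frame if prev.frame is rec.frame else Frame.unknown
            merged[k] = ClonotypeRecord(
                cdr3_nt=prev.cdr3_nt,
                templates=prev.templates + rec.templates,
                v_gene=prev.v_gene,
                j_gene=prev.j_gene,
                cdr3_aa=prev.cdr3_aa,
                frame=frame,
            )
    return tuple(merged.values())


@dataclass(frozen=True)
class Repertoire:
    """A labelled multiset of clonotypes, unique under ``identity``.

    ``N`` (total templates, the paper's total cell count) and ``R`` (unique
    clonotypes) are derived, never stored independently, so the invariant
    N = Σ templates, R = #records holds by construction.
    """

    label: RepLabel
    clonotypes: tuple[ClonotypeRecord, ...]
    identity: IdentityKey = DEFAULT_IDENTITY

    def __post_init__(self) -> None:
        keys = [self.identity.of(r) for r in self.clonotypes]
        if len(set(keys)) != len(keys):
            raise ValidationError(
                f"repertoire {self.label} has duplicate identity keys; "
                "use Repertoire.from_records to merge them")

    @classmethod
    def from_records(
        cls,
        records: Iterable[ClonotypeRecord],
        label: RepLabel = RepLabel(),
        identity: IdentityKey = DEFAULT_IDENTITY,
    ) -> "Repertoire":
        """Build a repertoire, merging duplicate identity keys by count sum."""
        return cls._trusted(label, _merge_records(records, identity), identity)

    @classmethod
    def _trusted(cls, label: RepLabel, clonotypes: tuple, identity: IdentityKey
                 ) -> "Repertoire":
        # fast path for construction sites where key uniqueness holds by
        # construction (merge output, subsets of a valid repertoire)
        obj = object.__new__(cls)
        object.__setattr__(obj, "label", label)
        object.__setattr__(obj, "clonotypes", tuple(clonotypes))
        object.__setattr__(obj, "identity", identity)
        return obj

    # -- derived totals -------------------------------------------------
    @property
    def R(self) -> int:
        """Number of unique clonotypes."""
        return len(self.clonotypes)

    @property
    def N(self) -> int:
        """Total template count (Σ nᵢ)."""
        return int(self.counts().sum()) if self.clonotypes else 0

    def counts(self) -> np.ndarray:
        """Template counts nᵢ as an int64 array (repertoire order)."""
        return np.fromiter(
            (r.templates for r in self.clonotypes), dtype=np.int64,
            count=len(self.clonotypes))

    def key_set(self) -> frozenset:
        """The set of identity keys (abundance ignored)."""
        return frozenset(self.identity.of(r) for r in self.clonotypes)

    def keys(self) -> list[tuple]:
        """Identity keys in repertoire order."""
        return [self.identity.of(r) for r in self.clonotypes]

    def subset_by_indices(self, indices: Sequence[int]) -> "Repertoire":
        """A repertoire containing the records at ``indices`` (same label)."""
        recs = tuple(self.clonotypes[i] for i in indices)
        return Repertoire._trusted(self.label, recs, self.identity)

    def with_label(self, label: RepLabel) -> "Repertoire":
        return Repertoire._trusted(label, self.clonotypes, self.identity)
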